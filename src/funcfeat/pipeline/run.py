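"""Pipeline orchestration.

Stages (``generate -> fit -> evaluate -> revcor -> generalize -> report``)
communicate only through serialized artifacts under the run directory,
so each stage can run in a separate process. Every stage writes a
``provenance.json`` (config hash, stage name, seeds); deterministic
stages are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ..forward import (
    ForwardFit,
    nested_cv_fit,
    ridge_solve,
    space_from_components,
    srf_and_repredict,
)
from ..forward.nested_cv import FoldFit
from ..generalization import (
    FaithfulnessMatrix,
    TargetSpec,
    accuracy_error,
    build_generalization_set,
    classify_faithful,
    diagnostic_components,
    signed_distance,
    simulate_identification,
)
from ..gmf import fit_gmf, load_gmf, save_gmf
from ..gmf.model import FaceIdentity, project_components, synthesize_vertices
from ..infotheory import bin_equipopulated, mutual_information_mm, redundancy_iccs
from ..revcor import amplification_tuning, choose_faces, mass_univariate_fit, sphere_normals, template_metrics
from ..synth import (
    EmbeddingSpec,
    ObserverSpec,
    build_experiment_plan,
    embed_components,
    embedding_stats,
    generate_embedding,
    generate_face_database,
    generate_stimulus_set,
    simulate_session,
)
from .config import RunConfig

__all__ = ["run_pipeline", "run_stage", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["generate", "fit", "evaluate", "revcor", "generalize", "report"]


# ---------------------------------------------------------------- utilities


def _provenance(run_dir: Path, stage: str, cfg: RunConfig) -> None:
    (run_dir / stage / "provenance.json").write_text(
        json.dumps({"stage": stage, "config_hash": cfg.hash(), "seeds": cfg.seeds}, indent=2)
    )


def _save_fit(path: Path, fit: ForwardFit) -> None:
    arrays = {}
    for i, f in enumerate(fit.folds):
        arrays[f"w{i}"] = f.weights
        arrays[f"xm{i}"] = f.x_mean
        arrays[f"xs{i}"] = f.x_std
        arrays[f"lam{i}"] = f.lambdas
        arrays[f"tp{i}"] = f.test_pred
        arrays[f"il{i}"] = np.stack(f.inner_lambdas)
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "space_name": fit.space_name,
        "n_trials": fit.n_trials,
        "fold_len": fit.fold_len,
        "subspace_names": fit.subspace_names,
        "slices": [[sl.start, sl.stop] for sl in fit.slices],
        "y_means": [f.y_mean for f in fit.folds],
        "n_folds": len(fit.folds),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def _load_fit(path: Path) -> ForwardFit:
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    folds = []
    for i in range(meta["n_folds"]):
        folds.append(
            FoldFit(
                test_block=i,
                lambdas=arrays[f"lam{i}"],
                weights=arrays[f"w{i}"],
                x_mean=arrays[f"xm{i}"],
                x_std=arrays[f"xs{i}"],
                y_mean=meta["y_means"][i],
                test_pred=arrays[f"tp{i}"],
                inner_lambdas=list(arrays[f"il{i}"]),
            )
        )
    return ForwardFit(
        space_name=meta["space_name"],
        n_trials=meta["n_trials"],
        fold_len=meta["fold_len"],
        subspace_names=meta["subspace_names"],
        slices=[slice(a, b) for a, b in meta["slices"]],
        folds=folds,
    )


def _session_key(o: int, t: int) -> str:
    return f"obs{o:02d}_tgt{t:02d}"


# ------------------------------------------------------------------- stages


def _stage_generate(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "generate"
    out.mkdir(parents=True, exist_ok=True)
    dbc = dict(cfg.database)
    K, K_tex = dbc.pop("K", None), dbc.pop("K_tex", None)
    sdb = generate_face_database(**dbc, seed=cfg.seeds["database"])
    model = fit_gmf(sdb.db, K=K, K_tex=K_tex)
    save_gmf(model, out / "model")
    np.savez(out / "truth.npz", U0=sdb.U0, A0=sdb.A0)

    plan = build_experiment_plan(**cfg.experiment)
    n_targets = len(plan.targets)
    n_obs = cfg.observers["n_observers"]
    rng = np.random.default_rng(cfg.seeds["observers"])

    sexes = model.coding.sex_levels
    eths = model.coding.ethnicity_levels
    targets = []
    for t in range(n_targets):
        comps = rng.standard_normal(model.n_components)
        factors = {"sex": sexes[t % len(sexes)], "age": 40.0, "ethnicity": eths[t % len(eths)]}
        identity = FaceIdentity(components=comps, factors=factors, id=f"target_{t}")
        targets.append(identity)
        np.savez(out / f"target_{t}.npz", components=comps,
                 vertices=synthesize_vertices(identity, model))
        (out / f"target_{t}.json").write_text(json.dumps(factors))

    for o in range(n_obs):
        for t, target in enumerate(targets):
            key = _session_key(o, t)
            srf_w = rng.uniform(0.5, 1.5, model.n_components)
            jitter = cfg.observers.get("template_jitter", 0.0)
            obs_template = target.components + rng.normal(0.0, jitter, model.n_components)
            observer = ObserverSpec(
                template_components=obs_template,
                srf_weights=srf_w,
                noise_sd=cfg.observers["noise_sd"],
                seed=cfg.seeds["observers"] + 997 * o + 13 * t,
                kind=cfg.observers.get("kind", "distance"),
            )
            stimuli = generate_stimulus_set(
                model,
                plan.faces_per_session,
                component_sd=cfg.observers.get("component_sd", 1.0),
                factors=target.factors,
                seed=cfg.seeds["stimuli"] + 997 * o + 13 * t,
            )
            session = simulate_session(observer, stimuli, plan.trials_per_session, plan.array_size)
            session.to_tsv(out / f"session_{key}.tsv")
            comps = np.stack([s.components for s in stimuli])
            tex = (
                np.stack([s.texture_components for s in stimuli])
                if model.has_texture
                else np.zeros((len(stimuli), 0))
            )
            np.savez(
                out / f"session_{key}.npz",
                components=comps,
                texture_components=tex,
                ratings=session.ratings,
                chosen=session.chosen,
                candidate_indices=session.candidate_indices,
                observer_srf=srf_w,
                observer_template=obs_template,
            )
            for espec in cfg.embeddings:
                spec = EmbeddingSpec(**espec, seed=cfg.seeds["embeddings"])
                space = generate_embedding(spec, stimuli, model)
                np.save(out / f"embedding_{key}_{spec.name}.npy", space.values)
                mean, sd = embedding_stats(spec, stimuli, model)
                np.savez(out / f"embstats_{key}_{spec.name}.npz", mean=mean, sd=sd)
    _provenance(run_dir, "generate", cfg)


def _space_names(cfg: RunConfig) -> list[str]:
    return ["shape"] + [e["name"] for e in cfg.embeddings]


def _load_session(run_dir: Path, key: str):
    return np.load(run_dir / "generate" / f"session_{key}.npz")


def _load_space_values(run_dir: Path, cfg: RunConfig, key: str, space: str, chosen=None):
    sess = _load_session(run_dir, key)
    if space == "shape":
        values = sess["components"]
    else:
        values = np.load(run_dir / "generate" / f"embedding_{key}_{space}.npy")
    if chosen is not None:
        values = values[chosen]
    return values


def _iter_sessions(cfg: RunConfig):
    for o in range(cfg.observers["n_observers"]):
        for t in range(cfg.experiment["n_targets"]):
            yield o, t, _session_key(o, t)


def _stage_fit(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "fit"
    out.mkdir(parents=True, exist_ok=True)
    fold_len = cfg.cv["fold_len"]
    for o, t, key in _iter_sessions(cfg):
        sess = _load_session(run_dir, key)
        chosen_idx = sess["candidate_indices"][np.arange(len(sess["ratings"])), sess["chosen"]]
        for space_name in _space_names(cfg):
            X = _load_space_values(run_dir, cfg, key, space_name, chosen=chosen_idx)
            space = space_from_components(space_name, X)
            tic = time.perf_counter()
            fit = nested_cv_fit(space, sess["ratings"].astype(float), fold_len=fold_len)
            logger.info("fit %s space=%s folds=%d took %.2fs",
                        key, space_name, fit.n_outer_folds, time.perf_counter() - tic)
            _save_fit(out / f"fit_{key}_{space_name}", fit)
    _provenance(run_dir, "fit", cfg)


def _stage_evaluate(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    n_bins = cfg.infotheory.get("n_bins", 3)
    n_perm = cfg.infotheory.get("n_perm", 25)
    pct = cfg.infotheory.get("percentile", 95.0)
    fold_len = cfg.cv["fold_len"]
    rows = []
    srf_rows = []
    for o, t, key in _iter_sessions(cfg):
        sess = _load_session(run_dir, key)
        ratings = sess["ratings"].astype(float)
        chosen_idx = sess["candidate_indices"][np.arange(len(ratings)), sess["chosen"]]
        shape_fit = _load_fit(run_dir / "fit" / f"fit_{key}_shape")
        shape_oof = shape_fit.oof_predictions
        shape_X = _load_space_values(run_dir, cfg, key, "shape", chosen=chosen_idx)
        for space_name in _space_names(cfg):
            fit = _load_fit(run_dir / "fit" / f"fit_{key}_{space_name}")
            X = _load_space_values(run_dir, cfg, key, space_name, chosen=chosen_idx)
            oof = fit.oof_predictions

            # reduced permutation pipeline: refit per fold with the tuned
            # penalties (tuning not repeated). Surrogate fold-level MIs are
            # pooled so the threshold matches the observed statistic (MI of
            # one test fold).
            def refit_fold_mis(perm_ratings: np.ndarray) -> np.ndarray:
                n_blocks = len(perm_ratings) // fold_len
                mis = np.empty(n_blocks)
                for b in range(n_blocks):
                    te = slice(b * fold_len, (b + 1) * fold_len)
                    tr = np.r_[0 : b * fold_len, (b + 1) * fold_len : len(perm_ratings)]
                    mean, std = X[tr].mean(0), np.where(X[tr].std(0) > 0, X[tr].std(0), 1.0)
                    ym = perm_ratings[tr].mean()
                    w = ridge_solve((X[tr] - mean) / std, perm_ratings[tr] - ym,
                                    fit.folds[b].lambdas, fit.slices)
                    pred = (X[te] - mean) / std @ w + ym
                    mis[b] = mutual_information_mm(
                        bin_equipopulated(pred, n_bins),
                        bin_equipopulated(perm_ratings[te], n_bins),
                    )
                return mis

            null_rng = np.random.default_rng(cfg.seeds["permutation"] + 997 * o + 13 * t)
            surrogate = np.concatenate(
                [refit_fold_mis(null_rng.permutation(ratings)) for _ in range(n_perm)]
            )
            threshold = float(np.percentile(surrogate, pct))
            for b, f in enumerate(fit.folds):
                te = slice(b * fold_len, (b + 1) * fold_len)
                y_b = bin_equipopulated(ratings[te], n_bins)
                p_b = bin_equipopulated(oof[te], n_bins)
                mi = mutual_information_mm(p_b, y_b)
                red = redundancy_iccs(p_b, bin_equipopulated(shape_oof[te], n_bins), y_b)
                rows.append(dict(observer=o, target=t, space=space_name, fold=b,
                                 mi_bits=mi, redundancy_bits=red,
                                 threshold_bits=threshold, exceeds=mi > threshold))
            if space_name != "shape":
                rep = srf_and_repredict(
                    fit, space_from_components(space_name, X),
                    space_from_components("shape", shape_X), shape_fit=shape_fit,
                )
                for b in range(len(rep.pred_corr)):
                    srf_rows.append(dict(observer=o, target=t, space=space_name, fold=b,
                                         pred_corr=rep.pred_corr[b], srf_corr=rep.srf_corr[b]))
    pd.DataFrame(rows).to_csv(out / "info_results.tsv", sep="\t", index=False)
    pd.DataFrame(srf_rows).to_csv(out / "srf_results.tsv", sep="\t", index=False)
    _provenance(run_dir, "evaluate", cfg)


def _vertex_features(comps: np.ndarray, model) -> np.ndarray:
    """Vertex clouds of identity components under fixed factors (prototype-free)."""
    return (comps * model.component_scale) @ model.U_shape.T


def _stage_revcor(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "revcor"
    out.mkdir(parents=True, exist_ok=True)
    model = load_gmf(run_dir / "generate" / "model")
    normals = sphere_normals(model.n_vertices)
    amp_grid = np.arange(0.0, cfg.revcor.get("amp_max", 50.0) + 1e-9, cfg.revcor.get("amp_step", 0.5))
    estimator = cfg.revcor.get("estimator", "ols")
    rows = []
    for o, t, key in _iter_sessions(cfg):
        sess = _load_session(run_dir, key)
        ratings = sess["ratings"].astype(float)
        arrays = sess["candidate_indices"]
        factors = json.loads((run_dir / "generate" / f"target_{t}.json").read_text())
        proto = model.prototype(factors)
        truth = np.load(run_dir / "generate" / f"target_{t}.npz")["vertices"]
        obs_template_vertices = _vertex_features(sess["observer_template"][None, :], model)[0] + proto

        all_verts = _vertex_features(sess["components"], model) + proto
        chosen_obs = arrays[np.arange(len(ratings)), sess["chosen"]]

        def project_faces(faces: np.ndarray) -> np.ndarray:
            return np.stack([project_components(f, factors, model) for f in faces])

        # each system responds to its own amplified templates: the simulated
        # observer through its similarity function, fitted models through
        # their forward fits on the matching feature space
        srf_w, template = sess["observer_srf"], sess["observer_template"]

        def observer_responder(faces: np.ndarray) -> np.ndarray:
            comps = project_faces(faces)
            return -np.sum(srf_w * (comps - template) ** 2, axis=1)

        systems = {"human": (chosen_obs, ratings, observer_responder)}
        for space_name in _space_names(cfg):
            fit = _load_fit(run_dir / "fit" / f"fit_{key}_{space_name}")
            X_all = _load_space_values(run_dir, cfg, key, space_name)
            preds_all = fit.predict(X_all)
            _, chosen_stim, chosen_pred = choose_faces(preds_all, arrays)
            if space_name == "shape":
                responder = lambda faces, _f=fit: _f.predict(project_faces(faces))
            else:
                espec = next(e for e in cfg.embeddings if e["name"] == space_name)
                spec = EmbeddingSpec(**espec, seed=cfg.seeds["embeddings"])
                stats = np.load(run_dir / "generate" / f"embstats_{key}_{space_name}.npz")

                def responder(faces, _f=fit, _spec=spec, _m=stats["mean"], _s=stats["sd"]):
                    comps = project_faces(faces)
                    tex = np.zeros((len(comps), model.n_texture_components))
                    return _f.predict(embed_components(_spec, comps, tex, model, _m, _s))

            systems[space_name] = (chosen_stim, chosen_pred, responder)

        for system, (chosen_stim, resp, responder) in systems.items():
            rc = mass_univariate_fit(all_verts[chosen_stim], resp, estimator=estimator)
            curve = amplification_tuning(rc, responder, amp_grid)
            template = rc.reconstruct(curve.peak_amp)
            mae_h, r_h = template_metrics(template, obs_template_vertices, proto, normals)
            mae_v, r_v = template_metrics(template, truth, proto, normals)
            np.savez(out / f"template_{key}_{system}.npz", b0=rc.b0, b1=rc.b1,
                     template=template, peak_amp=curve.peak_amp)
            pd.DataFrame({"alpha": curve.amplifications, "response": curve.responses}).to_csv(
                out / f"tuning_{key}_{system}.tsv", sep="\t", index=False)
            rows.append(dict(observer=o, target=t, system=system, peak_amp=curve.peak_amp,
                             mae_humanness=mae_h, r_humanness=r_h,
                             mae_veridicality=mae_v, r_veridicality=r_v))
    pd.DataFrame(rows).to_csv(out / "template_metrics.tsv", sep="\t", index=False)
    _provenance(run_dir, "revcor", cfg)


def _stage_generalize(run_dir: Path, cfg: RunConfig) -> None:
    out = run_dir / "generalize"
    out.mkdir(parents=True, exist_ok=True)
    model = load_gmf(run_dir / "generate" / "model")
    normals = sphere_normals(model.n_vertices)
    gcfg = cfg.generalization
    n_targets = cfg.experiment["n_targets"]
    n_obs = cfg.observers["n_observers"]
    rng = np.random.default_rng(cfg.seeds["generalization"])

    # faithfulness matrix from simulated-observer reconstructions vs chance
    columns = []
    for o in range(n_obs):
        for t in range(n_targets):
            key = _session_key(o, t)
            rc = np.load(run_dir / "revcor" / f"template_{key}_human.npz")
            factors = json.loads((run_dir / "generate" / f"target_{t}.json").read_text())
            proto = model.prototype(factors)
            truth = np.load(run_dir / "generate" / f"target_{t}.npz")["vertices"]
            sess = _load_session(run_dir, key)
            ratings = sess["ratings"].astype(float)
            chosen_obs = sess["candidate_indices"][np.arange(len(ratings)), sess["chosen"]]
            verts = _vertex_features(sess["components"], model) + proto
            peak = float(rc["peak_amp"])
            recon = rc["b0"] + peak * rc["b1"]
            chance = np.zeros(model.n_vertices)
            n_chance = 10
            for _ in range(n_chance):
                perm = rng.permutation(ratings)
                rc_p = mass_univariate_fit(verts[chosen_obs], perm)
                chance += signed_distance(rc_p.reconstruct(peak), proto, normals) / n_chance
            columns.append(
                classify_faithful(
                    signed_distance(recon, proto, normals),
                    chance,
                    signed_distance(truth, proto, normals),
                ).astype(float)
            )
    # observer-major column order: observer varies slowest
    F = FaithfulnessMatrix(values=np.column_stack(columns), n_observers=n_obs, n_targets=n_targets)
    np.save(out / "faithfulness.npy", F.values)
    diags = diagnostic_components(F, k=gcfg.get("k", 8),
                                  loading_threshold=gcfg.get("loading_threshold", 0.1),
                                  seed=cfg.seeds["generalization"])

    target_specs = []
    for t in range(n_targets):
        factors = json.loads((run_dir / "generate" / f"target_{t}.json").read_text())
        truth = np.load(run_dir / "generate" / f"target_{t}.npz")["vertices"]
        target_specs.append(TargetSpec(name=f"target_{t}", ground_truth=truth,
                                       factors=factors, C_D=diags[t].C_D))
    from ..generalization.stimuli import DEFAULT_CONDITIONS

    stimuli = build_generalization_set(model, target_specs,
                                       amps=tuple(gcfg.get("amps", (0.33, 0.67, 1.0, 1.33, 1.67))),
                                       conditions=tuple(gcfg.get("conditions", DEFAULT_CONDITIONS)))
    true_targets = np.array([int(s.target.split("_")[1]) for s in stimuli])
    stim_comps = np.stack([project_components(s.vertices, s.factors, model) for s in stimuli])

    # reference cohort: 5 held-out distance observers per stimulus, mean accuracy
    ref_acc = np.zeros(len(stimuli))
    n_ref = 5
    for r in range(n_ref):
        sims = np.empty((n_targets, len(stimuli)))
        w = rng.uniform(0.5, 1.5, model.n_components)
        for t in range(n_targets):
            tmpl = np.load(run_dir / "generate" / f"target_{t}.npz")["components"]
            sims[t] = -np.sum(w * (stim_comps - tmpl) ** 2, axis=1)
        sims += rng.normal(0, 1.0, sims.shape)
        ref_acc += (np.argmax(sims, axis=0) == true_targets) / n_ref

    tex0 = np.zeros((len(stimuli), model.n_texture_components))
    rows = []
    for o in range(n_obs):
        for system in _space_names(cfg):
            preds = np.empty((n_targets, len(stimuli)))
            for t in range(n_targets):
                key = _session_key(o, t)
                fit = _load_fit(run_dir / "fit" / f"fit_{key}_{system}")
                if system == "shape":
                    features = stim_comps
                else:
                    espec = next(e for e in cfg.embeddings if e["name"] == system)
                    spec = EmbeddingSpec(**espec, seed=cfg.seeds["embeddings"])
                    stats = np.load(run_dir / "generate" / f"embstats_{key}_{system}.npz")
                    features = embed_components(spec, stim_comps, tex0, model,
                                                stats["mean"], stats["sd"])
                preds[t] = fit.predict(features)
            try:
                result = simulate_identification(preds, true_targets)
            except ValueError as exc:
                # e.g. a texture-only space is blind to vertex-only stimuli
                logger.warning("generalize: skipping system %s for observer %d (%s)", system, o, exc)
                continue
            errors = accuracy_error(result.accuracies, ref_acc)
            for i, s in enumerate(stimuli):
                rows.append(dict(observer=o, system=system, condition=s.condition,
                                 target=s.target, diagnosticity=s.diagnosticity, alpha=s.alpha,
                                 choice=int(result.choices[i]), accuracy=result.accuracies[i],
                                 reference_accuracy=ref_acc[i], abs_error=errors[i]))
    pd.DataFrame(rows).to_csv(out / "identification.tsv", sep="\t", index=False)
    _provenance(run_dir, "generalize", cfg)


def run_stage(stage: str, run_dir, cfg: RunConfig) -> None:
    run_dir = Path(run_dir)
    if stage == "report":
        from .report import report

        report(run_dir)
        _provenance(run_dir, "report", cfg)
        return
    fn = {
        "generate": _stage_generate,
        "fit": _stage_fit,
        "evaluate": _stage_evaluate,
        "revcor": _stage_revcor,
        "generalize": _stage_generalize,
    }[stage]
    fn(run_dir, cfg)


def run_pipeline(cfg: RunConfig, run_dir) -> Path:
    """Run all stages in order; halts on the failing stage, keeping artifacts."""
    cfg.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    for stage in STAGES:
        tic = time.perf_counter()
        try:
            run_stage(stage, run_dir, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed; partial artifacts kept in {run_dir}"
            ) from exc
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - tic)
    return run_dir
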