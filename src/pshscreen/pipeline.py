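"""End-to-end screening-and-selection pipeline.

Orchestrates the full prognostic workflow on a competing-risks dataset:

    stratified 4:1 split -> PSH-CSIS screening on the training cohort ->
    cross-validated component-wise boosting on the screened features ->
    final PSH model -> IPCW prediction-error / ROC evaluation on both
    cohorts -> median-cutoff risk stratification with cumulative-
    incidence comparison (Gray's test).

Four benchmark models are always emitted: the covariate-free
Aalen-Johansen null model, the clinical-controls-only PSH model, boosting
without screening, and screening followed by boosting.  All artifacts are
TSV tables plus a plain-text manifest with every seed, so each stage can
be re-run independently.
"""

from __future__ import annotations

import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boosting import boost_fit, cv_boost
from .censoring import km_censoring
from .data import CompetingRisksDataset, read_dataset, split_train_test, write_dataset
from .evaluation import brier_cif, dot632plus, roc_cif
from .incidence import aalen_johansen, gray_test, stratify
from .pshreg import psh_fit
from .screening import default_model_size, psh_csis
from .simdata import SimulationConfig, simulate

__all__ = ["run_pipeline", "load_config", "default_grid"]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_grid(data: CompetingRisksDataset, n_points: int = 20) -> np.ndarray:
    """Evaluation grid: quantiles of follow-up, clipped to where G > 0."""
    G = km_censoring(data)
    qs = np.quantile(data.time, np.linspace(0.05, 0.9, n_points))
    grid = np.unique(qs)
    return grid[np.atleast_1d(G(grid)) > 0]


def _get_data(config, rng_note):
    if ("clinical" in config) == ("simulate" in config):
        raise ValueError("config must contain exactly one of (clinical, features) paths or a simulate block")
    if "simulate" in config:
        sim = dict(config["simulate"])
        rng_note["simulate_seed"] = sim.get("seed", 0)
        beta1 = sim.pop("beta1", None)
        beta2 = sim.pop("beta2", None)
        if isinstance(beta1, dict):
            beta1 = {int(k): float(v) for k, v in beta1.items()}
        if isinstance(beta2, dict):
            beta2 = {int(k): float(v) for k, v in beta2.items()}
        return simulate(SimulationConfig(beta1=beta1, beta2=beta2, **sim))
    return read_dataset(config["clinical"], config["features"], **config.get("reader", {}))


def _model_recipes(d, boost_steps_screen, boost_steps_all, screened, penalty):
    """Refittable model recipes for the .632+ bootstrap.

    Boosting recipes reuse the step count tuned once on the full training
    cohort (a fixed-M refit per resample) to keep the bootstrap tractable.
    """

    def null_recipe(train):
        aj = aalen_johansen(train)
        cif1 = aj.cif.get(1)

        def predict(eval_data, times):
            vals = np.atleast_1d(cif1(np.asarray(times, float)))
            return np.tile(vals, (eval_data.n, 1))

        return predict

    def clinical_recipe(train):
        fit = psh_fit(train, feature_subset=[])

        def predict(eval_data, times):
            lp = fit.linear_predictor(None, eval_data.Z.to_numpy(float))
            H = np.atleast_1d(fit.baseline(np.asarray(times, float)))
            return 1.0 - np.exp(-np.outer(np.exp(lp), H))

        return predict

    def _boost_recipe(features, steps):
        def recipe(train):
            bf = boost_fit(train, features=features, steps=steps, penalty=penalty)

            def predict(eval_data, times):
                x = eval_data.X.iloc[:, features].to_numpy(float) if features else eval_data.X.to_numpy(float)
                lp = bf.fit.linear_predictor(x, eval_data.Z.to_numpy(float))
                H = np.atleast_1d(bf.fit.baseline(np.asarray(times, float)))
                return 1.0 - np.exp(-np.outer(np.exp(lp), H))

            return predict

        return recipe

    return {
        "null_aalen_johansen": null_recipe,
        "clinical_only": clinical_recipe,
        "boost_only": _boost_recipe(None, boost_steps_all),
        "screen_boost": _boost_recipe(list(screened), boost_steps_screen),
    }


def run_pipeline(config: dict, outdir) -> Path:
    """Run the full pipeline; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config,
        "seeds": {},
        "timings_s": {},
        "stages": [],
    }
    t0 = _time.time()
    stage = "load"
    try:
        data = _get_data(config, manifest["seeds"])
        write_dataset(data, outdir / "clinical.tsv", outdir / "features.tsv")
        _done(manifest, stage, t0)

        stage = "split"
        t0 = _time.time()
        split_cfg = config.get("split", {})
        ratio = tuple(split_cfg.get("ratio", (4, 1)))
        split_seed = int(split_cfg.get("seed", 0))
        manifest["seeds"]["split"] = split_seed
        split = split_train_test(data, ratio=ratio, seed=split_seed)
        train, test = data.subset(split.train_index), data.subset(split.test_index)
        split.strata_report.to_csv(outdir / "split_strata.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"id": data.subject_id, "cohort": np.where(np.isin(np.arange(data.n), split.train_index), "train", "test")}
        ).to_csv(outdir / "cohorts.tsv", sep="\t", index=False)
        manifest["n_train"], manifest["n_test"] = train.n, test.n
        _done(manifest, stage, t0)

        stage = "screen"
        t0 = _time.time()
        scr_cfg = config.get("screening", {})
        d = scr_cfg.get("d") or default_model_size(
            train.n, train.p0, scr_cfg.get("rule", "n_minus_p0_minus_1")
        )
        d = min(int(d), train.p)
        screening = psh_csis(train, d=d)
        screening.write_tsv(outdir / "screening.tsv")
        manifest["screening"] = {"d": d, "null_loglik": float(screening.null_loglik)}
        _done(manifest, stage, t0)

        stage = "boost"
        t0 = _time.time()
        boost_cfg = config.get("boosting", {})
        folds = int(boost_cfg.get("folds", 10))
        max_steps = int(boost_cfg.get("max_steps", 100))
        penalty = boost_cfg.get("penalty")
        boost_seed = int(boost_cfg.get("seed", 0))
        manifest["seeds"]["boost_cv"] = boost_seed
        screened = list(screening.selected)
        bf_screen = cv_boost(train, features=screened, max_steps=max_steps, penalty=penalty, folds=folds, seed=boost_seed)
        bf_all = cv_boost(train, features=None, max_steps=max_steps, penalty=penalty, folds=folds, seed=boost_seed)
        bf_screen.write_path_tsv(outdir / "boost_path_screen.tsv")
        bf_screen.fit.write_tsv(outdir / "model_screen_boost.tsv")
        bf_all.fit.write_tsv(outdir / "model_boost_only.tsv")
        psh_fit(train, feature_subset=[]).write_tsv(outdir / "model_clinical.tsv")
        manifest["boosting"] = {
            "steps_screen_boost": int(bf_screen.selected_steps),
            "steps_boost_only": int(bf_all.selected_steps),
            "penalty": float(bf_screen.penalty),
            "selected_features": [
                bf_screen.feature_names[j] for j in np.flatnonzero(bf_screen.beta_final)
            ],
        }
        _done(manifest, stage, t0)

        stage = "evaluate"
        t0 = _time.time()
        eval_cfg = config.get("evaluation", {})
        grid = np.asarray(eval_cfg.get("grid", default_grid(train)), float)
        horizons = eval_cfg.get("horizons", [float(np.quantile(data.time, q)) for q in (0.25, 0.5, 0.75)])
        recipes = _model_recipes(
            d, bf_screen.selected_steps, bf_all.selected_steps, screened, penalty
        )
        curves, rocs = [], []
        B = int(eval_cfg.get("bootstrap_draws", 20))
        eval_seed = int(eval_cfg.get("seed", 0))
        manifest["seeds"]["bootstrap"] = eval_seed
        for label, recipe in recipes.items():
            predict = recipe(train)
            for cohort_label, cohort in (("train", train), ("test", test)):
                grid_c = grid[np.atleast_1d(km_censoring(cohort)(grid)) > 0]
                pred = predict(cohort, grid_c)
                curve = brier_cif(cohort, pred, km_censoring(cohort), grid_c,
                                  model_label=label, estimator="apparent" if cohort_label == "train" else "test")
                curves.append(curve.to_frame())
            if eval_cfg.get("dot632plus", True):
                curve632 = dot632plus(train, recipe, grid, B=B, seed=eval_seed, model_label=label)
                curves.append(curve632.to_frame())
            for h in horizons:
                try:
                    marker = predict(test, [h])[:, 0]
                    roc = roc_cif(test, marker, h)
                except ValueError:
                    continue
                frame = roc.to_frame()
                frame["model"], frame["horizon"], frame["auc"] = label, h, roc.auc
                rocs.append(frame)
        pd.concat(curves).to_csv(outdir / "prediction_error.tsv", sep="\t", index=False)
        if rocs:
            pd.concat(rocs).to_csv(outdir / "roc.tsv", sep="\t", index=False)
        _done(manifest, stage, t0)

        stage = "stratify"
        t0 = _time.time()
        xsel = train.X.iloc[:, screened].to_numpy(float)
        xsel_test = test.X.iloc[:, screened].to_numpy(float)
        beta = bf_screen.beta_final
        strata = stratify(xsel @ beta, xsel_test @ beta)
        manifest["stratify"] = {"cutoff": float(strata.cutoff)}
        frames = []
        for cohort_label, cohort, groups in (
            ("train", train, strata.train_group),
            ("test", test, strata.test_group),
        ):
            for g in np.unique(groups):
                cif = aalen_johansen(cohort.subset(np.flatnonzero(groups == g)))
                cif.group_label = f"{cohort_label}:{g}"
                frames.append(cif.to_frame())
            try:
                res = gray_test(cohort, groups)
                manifest["stratify"][f"gray_{cohort_label}"] = {
                    "statistic": float(res.statistic), "df": res.df, "p": float(res.p_value)
                }
            except ValueError as exc:
                manifest["stratify"][f"gray_{cohort_label}"] = {"error": str(exc)}
        pd.concat(frames).to_csv(outdir / "cumulative_incidence.tsv", sep="\t", index=False)
        _done(manifest, stage, t0)
    except PipelineError:
        raise
    except Exception as exc:  # preserve partial outputs, name the stage
        _write_manifest(manifest, outdir)
        raise PipelineError(stage, exc) from exc

    _write_manifest(manifest, outdir)
    return outdir


def _done(manifest, stage, t0):
    manifest["stages"].append(stage)
    manifest["timings_s"][stage] = round(_time.time() - t0, 3)


def _write_manifest(manifest, outdir):
    with open(Path(outdir) / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
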