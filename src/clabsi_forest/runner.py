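"""Orchestration of the model comparison.

Pipeline per train/test split (admissions split 2/3 - 1/3, so that every
catheter episode and landmark of an admission falls on one side):

1. build the landmark table and its baseline (LM0) filtrate;
2. learn imputation values on the training rows, apply to both sides;
3. for each selected model: optionally tune (random search on out-of-bag
   binary logloss), fit, predict the 7-day CLABSI risk on the test side;
4. evaluate (overall metrics for static models; overall and per-landmark
   for dynamic models) and append tidy result rows.

Desk-scale defaults (a few thousand admissions, 100 trees, a handful of
splits) run a full static comparison in minutes; every knob scales up to
paper-scale settings through :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import landmarks as lmk
from . import metrics as met
from .forest import ForestHyperparams, fit_forest, tune
from .outcomes import ModelSpec, encode_frame, model_grid
from .synthetic import CohortConfig, cohort_frames, generate_cohort

log = logging.getLogger(__name__)


def subseed(master_seed: int, name: str) -> np.random.Generator:
    """Named independent RNG substream: adding a model or split never
    perturbs the draws of another."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig | None = None
    episodes_csv: str | None = None
    daily_csv: str | None = None
    n_splits: int = 5
    train_fraction: float = 2.0 / 3.0
    models: tuple | None = None  # names; None = full grid
    dynamic: bool = False
    n_trees: int = 100
    tuning_budget: int = 0  # 0 = use default hyperparameters
    search_space: dict = field(default_factory=dict)
    hyperparams: ForestHyperparams = ForestHyperparams()
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.models:
            known = {m.name for m in model_grid()}
            bad = set(self.models) - known
            if bad:
                raise ValueError(f"unknown model names {sorted(bad)}")


def split_admissions(admission_ids, fraction: float, rng) -> tuple:
    """Disjoint, exhaustive admission-level partition (train, test)."""
    ids = np.unique(np.asarray(admission_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 admissions to split")
    n_train = int(round(fraction * len(ids)))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("train fraction yields an empty side")
    perm = rng.permutation(len(ids))
    return ids[perm[:n_train]], ids[perm[n_train:]]


def _feature_names(table: pd.DataFrame, dynamic: bool) -> list:
    feats = [c for c in table.columns if c not in lmk.ID_COLS + lmk.OUTCOME_COLS]
    return (feats + ["lm"]) if dynamic else feats


def _select_models(config: RunConfig, dynamic: bool) -> list:
    grid = model_grid()
    if config.models:
        grid = [m for m in grid if m.name in config.models]
    return [m for m in grid if (m.dynamic if dynamic else m.static)]


def _fit_predict(
    model: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    feats: list,
    config: RunConfig,
    dynamic: bool,
    split_id: int,
):
    rng = subseed(config.seed, f"split{split_id}:{model.name}:{'dyn' if dynamic else 'static'}")
    hp = replace(
        config.hyperparams,
        n_trees=config.n_trees,
        sample_mode="subsample" if dynamic else "bootstrap",
        sample_fraction=0.5 if dynamic else 1.0,
    )
    timings = {}
    if config.tuning_budget > 0:
        space = dict(config.search_space)
        if dynamic:
            space.setdefault("sample_fraction", (0.30, 0.80))
        t0 = _time.perf_counter()
        hp = tune(train, feats, model, space, config.tuning_budget, rng, base_hp=hp)
        timings["tune_s"] = _time.perf_counter() - t0
    t0 = _time.perf_counter()
    forest = fit_forest(train, feats, model, hp, rng)
    timings["fit_s"] = _time.perf_counter() - t0
    t0 = _time.perf_counter()
    preds = forest.predict_risk7(test)
    timings["predict_s"] = _time.perf_counter() - t0
    return forest, preds, hp, timings


def run_comparison(config: RunConfig) -> dict:
    """Run the full comparison; returns dict with tidy ``results``,
    ``summary``, ``predictions`` and the run ``manifest`` (also written to
    ``config.outdir`` when set)."""
    if config.cohort is not None:
        cohort = generate_cohort(replace(config.cohort, seed=int(subseed(config.seed, "cohort").integers(2**31))))
        episodes, daily = cohort_frames(cohort)
    elif config.episodes_csv and config.daily_csv:
        episodes = pd.read_csv(config.episodes_csv)
        daily = pd.read_csv(config.daily_csv)
    else:
        raise ValueError("RunConfig needs either a cohort config or CSV paths")

    lm_table = lmk.build_landmark_table(episodes, daily)
    results_rows, pred_rows, model_meta = [], [], []

    for s in range(config.n_splits):
        rng = subseed(config.seed, f"split{s}")
        train_ids, test_ids = split_admissions(episodes["admission_id"], config.train_fraction, rng)
        train_mask = lm_table["admission_id"].isin(train_ids)
        dyn_train, dyn_test = lm_table[train_mask], lm_table[~train_mask]

        for dynamic in ([False, True] if config.dynamic else [False]):
            if dynamic:
                tr_raw, te_raw = dyn_train, dyn_test
            else:
                tr_raw, te_raw = lmk.filter_baseline(dyn_train), lmk.filter_baseline(dyn_test)
            tr, te, _ = lmk.impute(tr_raw, te_raw)
            feats = _feature_names(tr, dynamic)
            for model in _select_models(config, dynamic):
                tag = f"{model.name}{'_dyn' if dynamic else ''}"
                try:
                    forest, preds, hp, timings = _fit_predict(
                        model, tr, te, feats, config, dynamic, s
                    )
                    y_test = encode_frame(te, model.spec)["y_bin7"]
                    train_prev = float(encode_frame(tr, model.spec)["y_bin7"].mean())
                    suite = met.metric_suite(preds, y_test, train_prev)
                    for name, v in suite.items():
                        results_rows.append(
                            {"split_id": s, "model": tag, "landmark": "all", "metric": name, "value": v}
                        )
                    if dynamic:
                        per_lm = met.landmark_metrics(preds, y_test, te["lm"].to_numpy())
                        for _, r in per_lm.iterrows():
                            results_rows.append(
                                {
                                    "split_id": s,
                                    "model": tag,
                                    "landmark": int(r["landmark"]),
                                    "metric": r["metric"],
                                    "value": r["value"],
                                }
                            )
                    pred_rows.append(
                        pd.DataFrame(
                            {
                                "split_id": s,
                                "model": tag,
                                "episode_id": te["episode_id"].to_numpy(),
                                "lm": te["lm"].to_numpy(),
                                "pred_risk7": preds,
                                "y_bin7": y_test,
                            }
                        )
                    )
                    model_meta.append(
                        {
                            "split_id": s,
                            "model": tag,
                            "hyperparams": {
                                "mtry": hp.mtry,
                                "nodesize": hp.nodesize,
                                "sample_mode": hp.sample_mode,
                                "sample_fraction": hp.sample_fraction,
                                "n_trees": hp.n_trees,
                            },
                            "minimal_depth": forest.minimal_depth(),
                            "timings": timings,
                        }
                    )
                    log.info("split %d model %s done: %s", s, tag, timings)
                except Exception:
                    log.exception("split %d model %s failed; skipping", s, tag)

    results = pd.DataFrame(results_rows)
    summary = met.summarize(results) if not results.empty else pd.DataFrame()
    predictions = pd.concat(pred_rows, ignore_index=True) if pred_rows else pd.DataFrame()
    manifest = {
        "seed": config.seed,
        "n_splits": config.n_splits,
        "train_fraction": config.train_fraction,
        "n_trees": config.n_trees,
        "tuning_budget": config.tuning_budget,
        "dynamic": config.dynamic,
        "models": [m["model"] for m in model_meta],
        "model_meta": model_meta,
    }
    out = {"results": results, "summary": summary, "predictions": predictions, "manifest": manifest}

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "results.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        predictions.to_csv(outdir / "predictions.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out


def report(results_dir) -> dict:
    """Summaries and figures from a completed run directory (pure function
    of the results CSVs)."""
    results_dir = Path(results_dir)
    results_path = results_dir / "results.csv"
    if not results_path.exists():
        raise FileNotFoundError(f"no results.csv under {results_dir}")
    results = pd.read_csv(results_path)
    if results.empty:
        raise ValueError("results file is empty")
    summary = met.summarize(results)

    figures = {}
    per_lm = results[results["landmark"] != "all"].copy()
    if not per_lm.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        per_lm["landmark"] = per_lm["landmark"].astype(int)
        s = met.summarize(per_lm)
        for metric in s["metric"].unique():
            fig, ax = plt.subplots(figsize=(7, 4))
            for model, grp in s[s["metric"] == metric].groupby("model"):
                grp = grp.sort_values("landmark")
                ax.plot(grp["landmark"], grp["median"], marker="o", label=model)
                ax.vlines(grp["landmark"], grp["q25"], grp["q75"], alpha=0.4)
            ax.set_xlabel("landmark (days from episode onset)")
            ax.set_ylabel(metric)
            ax.legend(fontsize=7)
            path = results_dir / f"landmark_{metric}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            figures[metric] = str(path)

    summary.to_csv(results_dir / "summary.csv", index=False)
    return {"summary": summary, "figures": figures}
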