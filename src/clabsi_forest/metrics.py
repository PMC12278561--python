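"""Discrimination and calibration metrics for 7-day risk predictions.

The evaluation suite follows standard clinical-prediction practice:

* **AUROC** -- Mann-Whitney probability that a random event outranks a
  random non-event, ties counted 1/2;
* **AUPRC** -- average precision (the stepwise integral of precision over
  recall); its no-skill baseline is the event prevalence;
* **BSS** -- Brier skill score against a constant no-skill predictor that
  outputs the (training) prevalence; 0 = no skill, 1 = perfect, negative =
  worse than the prevalence.  ``1 - BS/BS_ref`` by default; the raw ratio
  ``BS/BS_ref`` is also exposed since both conventions appear in applied
  work;
* **E:O ratio** -- mean predicted risk over mean observed event rate
  (> 1: overestimation);
* **calibration slope** -- slope of a logistic regression of the outcome on
  the logit of the predicted risk (1 = well scaled);
* **ECI** -- estimated calibration index, 100 x the mean squared difference
  between the predictions and a loess-smoothed calibration curve.

Metrics that are undefined on a stratum (single-class labels, zero events,
non-convergence) are reported as NaN rather than raised, so landmark-wise
tables stay rectangular.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = ("AUROC", "AUPRC", "BSS", "EO", "cal_slope", "ECI")

_CLIP = 1e-6


def _check(preds, labels):
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have the same shape")
    return preds, labels


def auroc(preds, labels) -> float:
    """Mann-Whitney AUROC with ties counted 1/2; NaN if one class absent."""
    preds, labels = _check(preds, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(preds)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auprc(preds, labels) -> float:
    """Average precision; NaN without positives."""
    preds, labels = _check(preds, labels)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        return float("nan") if n_pos == 0 else 1.0
    order = np.argsort(-preds, kind="mergesort")
    y = labels[order]
    p = preds[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # collapse tied thresholds: keep the last index of each distinct value
    last = np.r_[np.flatnonzero(np.diff(p)), len(p) - 1]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    rec_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - rec_prev) * precision))


def brier_skill(preds, labels, reference_prevalence: float, form: str = "one_minus_ratio") -> float:
    """Brier skill score vs the constant-prevalence no-skill predictor."""
    preds, labels = _check(preds, labels)
    if not 0.0 < reference_prevalence < 1.0:
        raise ValueError("reference prevalence must be in (0, 1)")
    bs = float(np.mean((preds - labels) ** 2))
    bs_ref = float(np.mean((reference_prevalence - labels) ** 2))
    if form == "ratio":
        return bs / bs_ref
    if form == "one_minus_ratio":
        return 1.0 - bs / bs_ref
    raise ValueError(f"unknown BSS form {form!r}")


def eo_ratio(preds, labels) -> float:
    """Mean predicted risk / mean observed event rate; NaN if no events."""
    preds, labels = _check(preds, labels)
    o = labels.mean()
    if o == 0:
        return float("nan")
    return float(preds.mean() / o)


def calibration_slope(preds, labels) -> float:
    """Slope from regressing the outcome on logit(predicted risk).

    Predictions are clipped to [1e-6, 1 - 1e-6] before the logit.  Returns
    NaN (with a warning) when the logistic fit does not converge, e.g. on
    separable data.
    """
    import statsmodels.api as sm

    preds, labels = _check(preds, labels)
    if labels.min() == labels.max():
        return float("nan")
    lp = np.log(np.clip(preds, _CLIP, 1 - _CLIP) / (1 - np.clip(preds, _CLIP, 1 - _CLIP)))
    X = np.column_stack([np.ones_like(lp), lp])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(labels, X).fit(disp=0, maxiter=200)
        if not np.isfinite(res.params[1]):
            raise ValueError("non-finite slope")
        return float(res.params[1])
    except Exception as exc:  # non-convergence / separation
        warnings.warn(f"calibration slope unavailable: {exc}")
        return float("nan")


def loess_smooth(x, y, x_eval=None, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    Fits y on x at each evaluation point using the nearest ``ceil(span*n)``
    neighbours.  Degenerate neighbourhoods (no spread in x) fall back to
    the local weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = x if x_eval is None else np.asarray(x_eval, dtype=float)
    n = len(x)
    k = max(min(int(np.ceil(span * n)), n), degree + 1)
    # evaluate on unique x values and interpolate: O(u * k) instead of O(n * k)
    uniq = np.unique(x_eval)
    fitted_u = np.empty(len(uniq))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, x0 in enumerate(uniq):
        j = np.searchsorted(xs, x0)
        lo = max(0, min(j - k // 2, n - k))
        # slide to the contiguous window of k nearest neighbours
        while lo > 0 and x0 - xs[lo - 1] < xs[lo + k - 1] - x0:
            lo -= 1
        while lo + k < n and xs[lo + k] - x0 < x0 - xs[lo]:
            lo += 1
        window = slice(lo, lo + k)
        dx = np.abs(xs[window] - x0)
        h = dx.max()
        if h <= 0:
            fitted_u[i] = ys[xs == x0].mean()
            continue
        w = (1 - (dx / h) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        X = np.vander(xs[window] - x0, degree + 1, increasing=True)
        W = w[:, None]
        try:
            beta, *_ = np.linalg.lstsq(X * W, ys[window] * w, rcond=None)
            fitted_u[i] = beta[0]
        except np.linalg.LinAlgError:
            fitted_u[i] = np.average(ys[window], weights=w)
    return np.interp(x_eval, uniq, fitted_u)


def eci(preds, labels, span: float = 0.75, degree: int = 2) -> float:
    """Estimated calibration index.

    100 x mean squared difference between the predicted risks and the
    loess-smoothed observed outcome evaluated at those risks (smoother
    output clipped to [0, 1]).  NaN for degenerate inputs (single-class
    labels or fewer than 10 rows).
    """
    preds, labels = _check(preds, labels)
    if len(preds) < 10 or labels.min() == labels.max():
        return float("nan")
    try:
        smoothed = np.clip(loess_smooth(preds, labels, span=span, degree=degree), 0.0, 1.0)
    except Exception as exc:
        warnings.warn(f"ECI unavailable: {exc}")
        return float("nan")
    return float(100.0 * np.mean((preds - smoothed) ** 2))


def metric_suite(preds, labels, reference_prevalence: float | None = None) -> dict:
    """All six metrics on one prediction vector."""
    preds, labels = _check(preds, labels)
    prev = labels.mean() if reference_prevalence is None else reference_prevalence
    bss = brier_skill(preds, labels, prev) if 0.0 < prev < 1.0 else float("nan")
    return {
        "AUROC": auroc(preds, labels),
        "AUPRC": auprc(preds, labels),
        "BSS": bss,
        "EO": eo_ratio(preds, labels),
        "cal_slope": calibration_slope(preds, labels),
        "ECI": eci(preds, labels),
    }


def landmark_metrics(
    preds, labels, lm, reference_prevalence: dict | None = None, min_events: int = 5
) -> pd.DataFrame:
    """Metric suite within each landmark stratum.

    Strata with fewer than ``min_events`` events or a single label class get
    NaN for every metric.  ``reference_prevalence`` optionally maps landmark
    to the training prevalence used for BSS.
    """
    preds, labels = _check(preds, labels)
    lm = np.asarray(lm)
    rows = []
    for l in np.unique(lm):
        m = lm == l
        p, y = preds[m], labels[m]
        if y.sum() < min_events or y.min() == y.max():
            vals = {name: float("nan") for name in METRIC_NAMES}
        else:
            prev = reference_prevalence.get(l) if reference_prevalence else None
            vals = metric_suite(p, y, prev)
        for name, v in vals.items():
            rows.append({"landmark": int(l), "metric": name, "value": v, "n": int(m.sum())})
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, by=("model", "landmark", "metric")) -> pd.DataFrame:
    """Median and IQR (linear-interpolation quartiles) over repeated splits.

    Missing values are excluded pairwise; ``n`` reports how many splits
    contributed to each cell.
    """
    by = [c for c in by if c in results.columns]

    def agg(s):
        v = s.dropna()
        if v.empty:
            return pd.Series({"median": np.nan, "q25": np.nan, "q75": np.nan, "n": 0})
        return pd.Series(
            {
                "median": float(np.percentile(v, 50)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
                "n": int(len(v)),
            }
        )

    out = results.groupby(by)["value"].apply(agg).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()
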