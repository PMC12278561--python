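"""Random forests for classification, survival and competing-risks outcomes.

Written from scratch because no single installed library offers the full
combination this comparison needs: gini splits for binary/multinomial
labels, log-rank and cause-weighted log-rank splits, a Gray-type
("logrankCR") split on event-specific cumulative incidence with its
modified risk set, Kaplan-Meier and Aalen-Johansen terminal estimators,
and in-bag sampling clustered by hospital admission.

Split statistics
----------------
For survival-type rules, over the distinct (discretized) event days ``t_k``
with ``d_k`` events and ``Y_k`` subjects at risk, of which ``d_kL`` and
``Y_kL`` in the left child:

    U = sum_k (d_kL - d_k * Y_kL / Y_k)
    V = sum_{k: Y_k > 1} d_k * (Y_kL/Y_k) * (1 - Y_kL/Y_k) * (Y_k - d_k) / (Y_k - 1)
    score = |U| / sqrt(V)

The cause-specific rule computes (U_j, V_j) per cause, treating other
causes as censored at their event times, and combines them with cause
weights ``w_j`` as ``|sum_j w_j U_j| / sqrt(sum_j w_j^2 V_j)``.  The
Gray-type rule replaces the risk set by the modified risk set ``Y*``: a
subject with a prior competing event stays at risk until its
administrative-censoring day (here deterministic, as follow-up is
complete), which makes the statistic sensitive to differences in
cumulative incidence rather than cause-specific hazard.

Terminal estimates
------------------
Every leaf stores the 7-day CLABSI risk in the form its scheme implies:
class fraction (binary/multinomial), ``1 - KM(7)`` (survival), or the
Aalen-Johansen cumulative incidence ``CIF_clabsi(7)`` (competing risks,
together with the CIFs of the other causes).  A forest prediction is the
average of terminal estimates over trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .outcomes import CLASS_CLABSI, ModelSpec, OutcomeSpec, encode_frame

_EPS = 1e-12


@dataclass(frozen=True)
class ForestHyperparams:
    n_trees: int = 100
    mtry: int | None = None  # default: ceil(sqrt(p))
    nodesize: int = 60  # ~1 expected event of a 1-2% cause per leaf
    sample_mode: str = "bootstrap"  # or "subsample"
    sample_fraction: float = 1.0
    nsplit: int = 10  # 0 = exhaustive
    equalize_inbag: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.sample_mode not in ("bootstrap", "subsample"):
            raise ValueError(f"unknown sample_mode {self.sample_mode!r}")


class EncodedData:
    """Feature matrix + encoded outcomes + admission clustering for fitting."""

    def __init__(self, table: pd.DataFrame, feature_names, spec: OutcomeSpec):
        self.spec = spec
        self.feature_names = list(feature_names)
        X = table[self.feature_names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("features contain missing values; impute before fitting")
        self.X = X
        enc = encode_frame(table, spec)
        self.y_bin7 = enc["y_bin7"]
        self.y = enc.get("y")
        self.time = enc.get("time")
        self.status = enc.get("status")
        self.cause = enc.get("cause")
        adm = table["admission_id"].to_numpy()
        self.admission_codes, self.admission_idx = np.unique(adm, return_inverse=True)

    @property
    def n_rows(self):
        return self.X.shape[0]

    @property
    def n_admissions(self):
        return len(self.admission_codes)


# ---------------------------------------------------------------------------
# split scoring kernels (vectorized over candidate splits)
# ---------------------------------------------------------------------------

def _gini_impurity(counts, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n
    return 1.0 - np.sum(p * p, axis=0)


def _gini_scores(onehot: np.ndarray, left: np.ndarray) -> np.ndarray:
    """Impurity decrease for each candidate split.

    ``onehot``: (n, K) class indicators; ``left``: (n, m) membership.
    """
    n = onehot.shape[0]
    total = onehot.sum(axis=0)  # (K,)
    cl = onehot.T.astype(float) @ left  # (K, m)
    nl = left.sum(axis=0).astype(float)
    nr = n - nl
    cr = total[:, None] - cl
    g_parent = _gini_impurity(total[:, None], n)[0]
    gl = np.where(nl > 0, _gini_impurity(cl, np.maximum(nl, 1)), 0.0)
    gr = np.where(nr > 0, _gini_impurity(cr, np.maximum(nr, 1)), 0.0)
    return g_parent - (nl / n) * gl - (nr / n) * gr


def _logrank_uv(time, event, exit_day, left, C):
    """(U, V) per candidate for one cause.

    ``time``: event day per row; ``event``: bool, row has this cause;
    ``exit_day``: day through which each row is at risk; ``left``: (n, m).
    """
    days = np.arange(1, C + 1)
    d_k = np.bincount(time[event], minlength=C + 1)[1:].astype(float)  # (C,)
    ev_onehot = (event[:, None] & (time[:, None] == days)).astype(float)  # (n, C)
    atrisk = (exit_day[:, None] >= days).astype(float)  # (n, C)
    Y_k = atrisk.sum(axis=0)
    d_kL = ev_onehot.T @ left  # (C, m)
    Y_kL = atrisk.T @ left  # (C, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(Y_k[:, None] > 0, Y_kL / Y_k[:, None], 0.0)
    U = np.sum(d_kL - d_k[:, None] * r, axis=0)
    vmask = (Y_k > 1) & (d_k > 0)
    if vmask.any():
        Yv, dv = Y_k[vmask], d_k[vmask]
        rv = r[vmask]
        V = np.sum(dv[:, None] * rv * (1.0 - rv) * ((Yv - dv) / (Yv - 1.0))[:, None], axis=0)
    else:
        V = np.zeros(left.shape[1])
    return U, V


def _survival_scores(time, cause, left, C, rule, weights):
    """|U|/sqrt(V) per candidate for logrank / logrank_cs / logrank_cr.

    ``cause`` uses 0 for censored rows.  For the plain survival log-rank,
    pass status as ``cause`` and weights (1, 0, 0).
    """
    U_tot = np.zeros(left.shape[1])
    V_tot = np.zeros(left.shape[1])
    any_event = False
    for j, w in enumerate(np.asarray(weights, dtype=float), start=1):
        if w == 0.0:
            continue
        event = cause == j
        if not event.any():
            continue
        any_event = True
        if rule == "logrank_cr":
            exit_day = np.where((cause != 0) & (cause != j), C, time)
        else:
            exit_day = time
        U, V = _logrank_uv(time, event, exit_day, left, C)
        U_tot += w * U
        V_tot += w * w * V
    if not any_event:
        return None
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(V_tot > _EPS, np.abs(U_tot) / np.sqrt(V_tot), 0.0)
    return score


# public scalar scorers (the per-operation surface; tests pit these against
# independent brute-force oracles)

def _combine_lr(left_pairs, right_pairs):
    lt = np.asarray([p[0] for p in left_pairs], dtype=int)
    ls = np.asarray([p[1] for p in left_pairs], dtype=int)
    rt = np.asarray([p[0] for p in right_pairs], dtype=int)
    rs = np.asarray([p[1] for p in right_pairs], dtype=int)
    time = np.concatenate([lt, rt])
    cause = np.concatenate([ls, rs])
    left = np.zeros((len(time), 1))
    left[: len(lt), 0] = 1.0
    return time, cause, left


def score_split_gini(left_labels, right_labels, n_classes: int) -> float:
    """Weighted Gini impurity decrease of a candidate split."""
    y = np.concatenate([np.asarray(left_labels, int), np.asarray(right_labels, int)])
    onehot = y[:, None] == np.arange(n_classes)
    left = np.zeros((len(y), 1))
    left[: len(left_labels), 0] = 1.0
    return float(_gini_scores(onehot, left)[0])


def score_split_logrank(left_pairs, right_pairs) -> float:
    """Two-sample log-rank score |U|/sqrt(V) on (time, status) pairs."""
    time, status, left = _combine_lr(left_pairs, right_pairs)
    s = _survival_scores(time, status, left, int(time.max()), "logrank", (1.0, 0.0, 0.0))
    if s is None:
        raise ValueError("node has no events; not splittable by the log-rank rule")
    return float(s[0])


def score_split_logrank_cs(left_pairs, right_pairs, cause_weights) -> float:
    """Cause-weighted cause-specific log-rank score on (time, cause) pairs."""
    time, cause, left = _combine_lr(left_pairs, right_pairs)
    s = _survival_scores(time, cause, left, int(time.max()), "logrank_cs", cause_weights)
    if s is None:
        raise ValueError("no events of any positively weighted cause")
    return float(s[0])


def score_split_logrank_cr(left_pairs, right_pairs, cause_weights, admin_censor: int) -> float:
    """Gray-type score with the modified risk set (competing events stay at
    risk until the administrative-censoring day)."""
    time, cause, left = _combine_lr(left_pairs, right_pairs)
    s = _survival_scores(time, cause, left, int(admin_censor), "logrank_cr", cause_weights)
    if s is None:
        raise ValueError("no events of any positively weighted cause")
    return float(s[0])


# ---------------------------------------------------------------------------
# terminal estimates
# ---------------------------------------------------------------------------

def _km_risk(time, status, horizon):
    """1 - Kaplan-Meier survival at ``horizon`` from (time, status) arrays."""
    C = int(time.max())
    days = np.arange(1, C + 1)
    d_k = np.bincount(time[status == 1], minlength=C + 1)[1:].astype(float)
    Y_k = (time[:, None] >= days).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        haz = np.where(Y_k > 0, d_k / Y_k, 0.0)
    surv = np.cumprod(1.0 - haz)
    h = min(horizon, C)
    return float(1.0 - surv[h - 1]) if h >= 1 else 0.0


def _aj_cif(time, cause, horizon, n_causes=3):
    """Aalen-Johansen CIF_j(horizon) for all causes.

    ``CIF_j(t) = sum_{t_k <= t} S(t_k-) * d_jk / Y_k`` with S the all-cause
    Kaplan-Meier estimator.
    """
    C = int(time.max())
    days = np.arange(1, C + 1)
    Y_k = (time[:, None] >= days).sum(axis=0).astype(float)
    d_jk = np.stack(
        [np.bincount(time[cause == j], minlength=C + 1)[1:].astype(float) for j in range(1, n_causes + 1)]
    )  # (J, C)
    d_all = d_jk.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        haz_all = np.where(Y_k > 0, d_all / Y_k, 0.0)
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - haz_all)[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = np.where(Y_k > 0, d_jk / Y_k, 0.0) * surv_before
    h = min(horizon, C)
    if h < 1:
        return np.zeros(n_causes)
    return inc[:, :h].sum(axis=1)


def terminal_estimate(data: EncodedData, idx: np.ndarray) -> dict:
    """Leaf summary for the rows ``idx``: 7-day CLABSI risk (+ per-cause CIFs
    and class fractions where the scheme provides them)."""
    if len(idx) == 0:
        raise ValueError("terminal estimate of an empty node")
    spec = data.spec
    h = spec.horizon
    if spec.scheme == "binary":
        return {"risk7": float(data.y[idx].mean())}
    if spec.scheme == "multinomial":
        p = np.bincount(data.y[idx], minlength=4) / len(idx)
        return {"risk7": float(p[CLASS_CLABSI]), "class_probs": p}
    if spec.scheme == "survival":
        return {"risk7": _km_risk(data.time[idx], data.status[idx], h)}
    cif = _aj_cif(data.time[idx], data.cause[idx], h)
    return {"risk7": float(cif[0]), "cif7": cif}


# ---------------------------------------------------------------------------
# in-bag sampling (clustered by admission)
# ---------------------------------------------------------------------------

def sample_inbag(data: EncodedData, hp: ForestHyperparams, rng) -> list:
    """Per-tree (in-bag row indices, OOB row mask), sampled by whole admission.

    Bootstrap mode draws admissions with replacement (size = number of
    admissions); a drawn admission contributes all its rows once per draw.
    Subsample mode draws ``round(fraction * n_admissions)`` admissions
    without replacement.  With ``equalize_inbag`` all in-bags are trimmed to
    the smallest in-bag size by randomly dropping rows; dropped rows fall
    out-of-bag (this mirrors an equal-in-bag-size software constraint and is
    knowingly a mild leak, off by default).
    """
    if data.n_admissions < 2:
        raise ValueError("need at least 2 admissions for clustered sampling")
    A = data.n_admissions
    rows_of_adm = [np.flatnonzero(data.admission_idx == a) for a in range(A)]
    draws_per_tree = []
    for _ in range(hp.n_trees):
        if hp.sample_mode == "bootstrap":
            k = max(1, int(round(hp.sample_fraction * A)))
            draws = rng.integers(0, A, size=k)
        else:
            k = int(round(hp.sample_fraction * A))
            if k < 1:
                raise ValueError("sample_fraction yields an empty in-bag")
            draws = rng.permutation(A)[:k]
        draws_per_tree.append(draws)

    bags = []
    for draws in draws_per_tree:
        inbag = np.concatenate([rows_of_adm[a] for a in draws])
        oob = np.ones(data.n_rows, dtype=bool)
        oob[np.concatenate([rows_of_adm[a] for a in np.unique(draws)])] = False
        bags.append((inbag, oob))

    if hp.equalize_inbag:
        minsize = min(len(b[0]) for b in bags)
        eq = []
        for inbag, oob in bags:
            if len(inbag) > minsize:
                sel = rng.permutation(len(inbag))[:minsize]
                dropped = np.setdiff1d(inbag, inbag[sel])
                oob = oob.copy()
                oob[dropped] = True
                inbag = inbag[np.sort(sel)]
            eq.append((inbag, oob))
        bags = eq
    return bags


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    feature: list = field(default_factory=list)  # -1 for leaves
    threshold: list = field(default_factory=list)
    left: list = field(default_factory=list)
    right: list = field(default_factory=list)
    estimate: list = field(default_factory=list)  # dict for leaves, None otherwise
    depth: list = field(default_factory=list)

    def add_node(self, depth):
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.estimate.append(None)
        self.depth.append(depth)
        return len(self.feature) - 1


def _node_outcome_arrays(data, idx, rule):
    if rule == "gini":
        return data.y[idx]
    if rule == "logrank":
        return data.time[idx], data.status[idx]
    return data.time[idx], data.cause[idx]


def _best_split(data: EncodedData, idx, rule, hp, rng, weights, C):
    """Best admissible split for a node, or None.

    Candidate features are an mtry-sized random draw; candidate thresholds
    are up to ``nsplit`` random observed values per feature (all values when
    ``nsplit == 0``).  The best candidate is the first encountered maximum
    in (feature draw order, ascending threshold) -- deterministic under the
    tree's RNG.
    """
    n = len(idx)
    p = data.X.shape[1]
    mtry = hp.mtry or int(np.ceil(np.sqrt(p)))
    feats = rng.permutation(p)[: min(mtry, p)]

    cols, col_feat, col_thr = [], [], []
    Xn = data.X[idx]
    for f in feats:
        vals = np.unique(Xn[:, f])
        if len(vals) < 2:
            continue
        thr = vals[:-1]
        if hp.nsplit and len(thr) > hp.nsplit:
            thr = np.sort(rng.choice(thr, size=hp.nsplit, replace=False))
        cols.append(Xn[:, f][:, None] <= thr[None, :])
        col_feat.extend([f] * len(thr))
        col_thr.extend(thr.tolist())
    if not cols:
        return None
    left = np.concatenate(cols, axis=1).astype(float)

    if rule == "gini":
        K = 2 if data.spec.scheme == "binary" else 4
        onehot = data.y[idx][:, None] == np.arange(K)
        scores = _gini_scores(onehot, left)
    else:
        cause = data.status[idx] if rule == "logrank" else data.cause[idx]
        w = (1.0, 0.0, 0.0) if rule == "logrank" else weights
        scores = _survival_scores(data.time[idx], cause, left, C, rule, w)
        if scores is None:
            return None

    nl = left.sum(axis=0)
    ok = (nl >= hp.nodesize) & (n - nl >= hp.nodesize)
    scores = np.where(ok, scores, -np.inf)
    best = int(np.argmax(scores))
    if not np.isfinite(scores[best]) or scores[best] <= _EPS:
        return None
    mask = left[:, best].astype(bool)
    return col_feat[best], float(col_thr[best]), mask


def grow_tree(data: EncodedData, inbag_idx, rule, hp: ForestHyperparams, rng) -> Tree:
    """Recursive partitioning on the in-bag rows (duplicates allowed)."""
    tree = Tree()
    C = data.spec.admin_censor
    weights = data.spec.cause_weights
    root = tree.add_node(0)
    stack = [(root, np.asarray(inbag_idx))]
    while stack:
        node, idx = stack.pop()
        split = None
        if len(idx) >= max(2 * hp.nodesize, 2):
            split = _best_split(data, idx, rule, hp, rng, weights, C)
        if split is None:
            tree.estimate[node] = terminal_estimate(data, idx)
            continue
        f, thr, mask = split
        tree.feature[node] = f
        tree.threshold[node] = thr
        ln = tree.add_node(tree.depth[node] + 1)
        rn = tree.add_node(tree.depth[node] + 1)
        tree.left[node], tree.right[node] = ln, rn
        stack.append((ln, idx[mask]))
        stack.append((rn, idx[~mask]))
    return tree


def _tree_apply(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Leaf index for every row of X."""
    out = np.zeros(len(X), dtype=int)
    stack = [(0, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if tree.feature[node] == -1:
            out[idx] = node
            continue
        mask = X[idx, tree.feature[node]] <= tree.threshold[node]
        stack.append((tree.left[node], idx[mask]))
        stack.append((tree.right[node], idx[~mask]))
    return out


@dataclass
class Forest:
    trees: list
    feature_names: list
    spec: OutcomeSpec
    split_rule: str
    hyperparams: ForestHyperparams
    oob_risk7: np.ndarray | None = None  # per training row; NaN if never OOB

    def predict_risk7(self, table) -> np.ndarray:
        """Mean 7-day CLABSI risk over trees, in [0, 1]."""
        X = self._matrix(table)
        acc = np.zeros(len(X))
        for tree in self.trees:
            leaves = _tree_apply(tree, X)
            risk = np.array([e["risk7"] if e is not None else np.nan for e in tree.estimate])
            acc += risk[leaves]
        return acc / len(self.trees)

    def predict_cif7(self, table) -> np.ndarray:
        """Per-cause 7-day CIFs (n, 3); competing-risks forests only."""
        if self.spec.scheme != "competing_risks":
            raise ValueError("per-cause CIFs are only available for competing-risks forests")
        X = self._matrix(table)
        acc = np.zeros((len(X), 3))
        for tree in self.trees:
            leaves = _tree_apply(tree, X)
            cif = np.stack([e["cif7"] if e is not None else np.full(3, np.nan) for e in tree.estimate])
            acc += cif[leaves]
        return acc / len(self.trees)

    def _matrix(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in table.columns]
            if missing:
                raise ValueError(f"prediction table lacks features {missing}")
            X = table[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature count mismatch")
        if np.isnan(X).any():
            raise ValueError("prediction features contain missing values")
        return X

    def minimal_depth(self) -> dict:
        """Average depth of the first split on each variable (0 = root),
        over the trees in which the variable is used at all."""
        sums = np.zeros(len(self.feature_names))
        counts = np.zeros(len(self.feature_names), dtype=int)
        for tree in self.trees:
            best = {}
            for node, f in enumerate(tree.feature):
                if f >= 0:
                    d = tree.depth[node]
                    if f not in best or d < best[f]:
                        best[f] = d
            for f, d in best.items():
                sums[f] += d
                counts[f] += 1
        return {
            name: (sums[i] / counts[i] if counts[i] else None)
            for i, name in enumerate(self.feature_names)
        }

    def to_json(self) -> str:
        def enc(e):
            if e is None:
                return None
            out = {"risk7": e["risk7"]}
            if "cif7" in e:
                out["cif7"] = list(map(float, e["cif7"]))
            if "class_probs" in e:
                out["class_probs"] = list(map(float, e["class_probs"]))
            return out

        payload = {
            "feature_names": self.feature_names,
            "split_rule": self.split_rule,
            "spec": {
                "scheme": self.spec.scheme,
                "horizon": self.spec.horizon,
                "admin_censor": self.spec.admin_censor,
                "competing_censoring": self.spec.competing_censoring,
                "cause_weights": list(self.spec.cause_weights),
            },
            "hyperparams": {
                "n_trees": self.hyperparams.n_trees,
                "mtry": self.hyperparams.mtry,
                "nodesize": self.hyperparams.nodesize,
                "sample_mode": self.hyperparams.sample_mode,
                "sample_fraction": self.hyperparams.sample_fraction,
                "nsplit": self.hyperparams.nsplit,
                "equalize_inbag": self.hyperparams.equalize_inbag,
                "seed": self.hyperparams.seed,
            },
            "trees": [
                {
                    "feature": [int(f) for f in t.feature],
                    "threshold": [None if np.isnan(x) else float(x) for x in t.threshold],
                    "left": [int(x) for x in t.left],
                    "right": [int(x) for x in t.right],
                    "depth": [int(d) for d in t.depth],
                    "estimate": [enc(e) for e in t.estimate],
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)


def fit_forest(
    table: pd.DataFrame,
    feature_names,
    model: ModelSpec,
    hp: ForestHyperparams,
    rng=None,
    compute_oob: bool = True,
) -> Forest:
    """Fit a forest for one model-grid entry on an (imputed) landmark table."""
    data = EncodedData(table, feature_names, model.spec)
    return _fit_encoded(data, model.split_rule, hp, rng, compute_oob)


def _fit_encoded(data: EncodedData, rule, hp, rng=None, compute_oob=True) -> Forest:
    rng = np.random.default_rng(hp.seed) if rng is None else rng
    bags = sample_inbag(data, hp, rng)
    trees = []
    oob_sum = np.zeros(data.n_rows)
    oob_cnt = np.zeros(data.n_rows)
    for inbag, oob in bags:
        tree = grow_tree(data, inbag, rule, hp, rng)
        trees.append(tree)
        if compute_oob and oob.any():
            leaves = _tree_apply(tree, data.X[oob])
            risk = np.array([e["risk7"] if e is not None else np.nan for e in tree.estimate])
            oob_sum[oob] += risk[leaves]
            oob_cnt[oob] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        oob_risk = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    forest = Forest(
        trees=trees,
        feature_names=data.feature_names,
        spec=data.spec,
        split_rule=rule,
        hyperparams=hp,
        oob_risk7=oob_risk if compute_oob else None,
    )
    return forest


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def binary_logloss(p: np.ndarray, y: np.ndarray, clip: float = 1e-6) -> float:
    p = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def tune(
    table: pd.DataFrame,
    feature_names,
    model: ModelSpec,
    search_space: dict,
    budget: int,
    rng,
    base_hp: ForestHyperparams = ForestHyperparams(),
) -> ForestHyperparams:
    """Random-search hyperparameter tuning on out-of-bag binary logloss.

    ``search_space`` may bound ``mtry`` and ``nodesize`` (inclusive integer
    ranges) and, for subsample mode, ``sample_fraction`` (continuous range).
    The objective is the OOB logloss of the 7-day CLABSI indicator --
    identical across outcome schemes, so every model is tuned toward the
    clinically relevant target.  Ties break toward smaller nodesize, then
    smaller mtry.
    """
    if budget < 1:
        raise ValueError("tuning budget must be >= 1")
    data = EncodedData(table, feature_names, model.spec)
    p = data.X.shape[1]
    results = []
    for _ in range(budget):
        lo, hi = search_space.get("mtry", (1, p))
        mtry = int(rng.integers(lo, hi + 1))
        lo, hi = search_space.get("nodesize", (5, 50))
        nodesize = int(rng.integers(lo, hi + 1))
        hp = replace(base_hp, mtry=mtry, nodesize=nodesize)
        if "sample_fraction" in search_space:
            lo, hi = search_space["sample_fraction"]
            hp = replace(hp, sample_fraction=float(lo + (hi - lo) * rng.random()))
        forest = _fit_encoded(data, model.split_rule, hp, rng, compute_oob=True)
        seen = ~np.isnan(forest.oob_risk7)
        loss = binary_logloss(forest.oob_risk7[seen], data.y_bin7[seen]) if seen.any() else np.inf
        results.append((loss, hp.nodesize, hp.mtry, hp))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return results[0][3]
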