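"""Catheter episodes and the landmark (catheter-day) dataset.

A *catheter episode* is the unit of risk: a maximal period of central-line
exposure, formed by grouping catheters that overlap or are separated by
less than 48 h, ending in exactly one of CLABSI, death or discharge.  The
"discharge" event is hospital discharge or 48 h after the last catheter
removal, whichever happens first (the patient stays at risk of CLABSI for
48 h after removal).

Each episode is expanded into *landmarks*: LM0 at the first catheter
observation, LMk at k*24 h after it, up to LM30.  A landmark row carries
the covariate values as of the landmark day (no future information) and
the residual time to the terminal event measured from the landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: grouping gap and post-removal risk window, in days
GAP_DAYS = 2.0
MAX_LM = 30

ID_COLS = ["episode_id", "admission_id", "lm"]
OUTCOME_COLS = ["time_to_event", "event_type"]


@dataclass(frozen=True)
class CatheterEpisode:
    episode_id: str
    admission_id: str
    start_time: float  # days from admission
    event_type: str  # clabsi | death | discharge
    event_time: float  # days from episode start, > 0

    def __post_init__(self):
        if self.event_time <= 0:
            raise ValueError("event_time must be positive")
        if self.event_type not in ("clabsi", "death", "discharge"):
            raise ValueError(f"unknown event type {self.event_type!r}")


def build_episodes(registrations: pd.DataFrame, terminal: pd.DataFrame) -> pd.DataFrame:
    """Group raw catheter registrations into episodes and attach terminal events.

    Parameters
    ----------
    registrations : columns (admission_id, placement, removal), times in days
        from admission.  A still-present catheter may have NaN removal.
    terminal : columns (admission_id, clabsi_time, death_time, discharge_time),
        NaN when the event did not occur.  ``death_time`` is the first
        palliative-care contact or death; ``discharge_time`` is hospital
        discharge.

    Returns
    -------
    DataFrame with one row per episode: (admission_id, episode_id,
    start_day, event_type, event_time), ``event_time`` in days from the
    episode start.  Catheters overlapping or separated by < 48 h fall in the
    same episode; an episode with no catheter observation for 48 h ends as
    discharge at last removal + 48 h.  Episodes starting at/after an
    admission-terminating event (death, hospital discharge) are dropped.

    The function is a pure, order-invariant map of its inputs.
    """
    regs = registrations.copy()
    if (regs["removal"].notna() & (regs["removal"] < regs["placement"])).any():
        bad = regs[regs["removal"].notna() & (regs["removal"] < regs["placement"])]
        raise ValueError(f"catheter removal before placement: {bad.to_dict('records')}")
    term = terminal.set_index("admission_id")

    rows = []
    for adm_id, grp in regs.groupby("admission_id", sort=True):
        grp = grp.sort_values(["placement", "removal"], kind="mergesort")
        t = term.loc[adm_id] if adm_id in term.index else None
        clabsi_t = float(t["clabsi_time"]) if t is not None and pd.notna(t.get("clabsi_time")) else np.inf
        death_t = float(t["death_time"]) if t is not None and pd.notna(t.get("death_time")) else np.inf
        hosp_disc = float(t["discharge_time"]) if t is not None and pd.notna(t.get("discharge_time")) else np.inf

        # merge catheters into groups separated by >= 48 h
        groups = []
        for _, cat in grp.iterrows():
            placement = float(cat["placement"])
            removal = float(cat["removal"]) if pd.notna(cat["removal"]) else np.inf
            if groups and placement < groups[-1][1] + GAP_DAYS:
                groups[-1][1] = max(groups[-1][1], removal)
            else:
                groups.append([placement, removal])

        k = 0
        for start, last_removal in groups:
            if start >= min(death_t, hosp_disc):
                continue  # admission already over
            # candidate terminal events strictly after the episode start
            candidates = {
                "clabsi": clabsi_t,
                "death": death_t,
                "discharge": min(hosp_disc, last_removal + GAP_DAYS),
            }
            etype, etime = min(
                ((c, v) for c, v in candidates.items() if v > start),
                key=lambda cv: (cv[1], cv[0]),
            )
            rows.append(
                {
                    "admission_id": adm_id,
                    "episode_id": f"{adm_id}_E{k}",
                    "start_day": start,
                    "event_type": etype,
                    "event_time": etime - start,
                }
            )
            k += 1
            if etype in ("death",):
                break
    return pd.DataFrame(rows, columns=["admission_id", "episode_id", "start_day", "event_type", "event_time"])


def build_landmark_table(
    episodes: pd.DataFrame, daily: pd.DataFrame, max_lm: int = MAX_LM
) -> pd.DataFrame:
    """Expand episodes into the landmark dataset.

    One row per episode per landmark lm in {0, ..., min(max_lm,
    ceil(event_time) - 1)} -- a landmark at or after the event time is never
    created, so residual times are strictly positive.  Covariates are taken
    as of the landmark day: baseline covariates from the episode table,
    time-varying covariates from ``daily`` at day == lm (the last
    observation within the preceding 24 h window, at the 1-day resolution
    of this package).  The landmark index is kept as the feature column
    ``lm`` so dynamic models can learn time effects.

    Raises if a required (episode, day) row is absent from ``daily``.
    """
    if episodes.empty:
        cols = ID_COLS + [c for c in daily.columns if c not in ("episode_id", "day")] + OUTCOME_COLS
        return pd.DataFrame(columns=cols)
    ep = episodes.reset_index(drop=True)
    n_lm = np.minimum(np.ceil(ep["event_time"]).astype(int) - 1, max_lm) + 1
    idx = np.repeat(ep.index.to_numpy(), n_lm)
    lm = np.concatenate([np.arange(k) for k in n_lm])

    out = ep.loc[idx].reset_index(drop=True)
    out["lm"] = lm
    out["time_to_event"] = out["event_time"] - out["lm"]

    tv_cols = [c for c in daily.columns if c not in ("episode_id", "day")]
    if tv_cols:
        merged = out.merge(
            daily, left_on=["episode_id", "lm"], right_on=["episode_id", "day"], how="left", indicator=True
        )
        missing = merged["_merge"] == "left_only"
        if missing.any():
            first = merged.loc[missing, ["episode_id", "lm"]].iloc[0]
            raise ValueError(
                f"daily covariates missing for episode {first['episode_id']} day {int(first['lm'])}"
            )
        out = merged.drop(columns=["day", "_merge"])

    base_cols = [
        c
        for c in ep.columns
        if c not in ("admission_id", "episode_id", "start_day", "event_type", "event_time")
    ]
    return out[ID_COLS + base_cols + tv_cols + OUTCOME_COLS]


def filter_baseline(landmark_table: pd.DataFrame) -> pd.DataFrame:
    """The static (baseline) dataset: landmark-0 rows only, one per episode."""
    return landmark_table[landmark_table["lm"] == 0].reset_index(drop=True)


class Imputer:
    """Mean / mode / fixed normal-value imputation, learned on training rows.

    ``strategies`` maps covariate name to "mean", "mode" or ("normal_value",
    value).  Unlisted covariates with missing values default to mean for
    float-valued columns with >2 distinct values and mode otherwise.
    """

    def __init__(self, strategies: dict | None = None):
        self.strategies = dict(strategies or {})
        self.fill_values_: dict = {}

    def fit(self, train: pd.DataFrame, columns=None) -> "Imputer":
        columns = [c for c in (columns or train.columns) if c not in ID_COLS + OUTCOME_COLS]
        self.fill_values_ = {}
        for col in columns:
            strat = self.strategies.get(col)
            if isinstance(strat, tuple) and strat[0] == "normal_value":
                self.fill_values_[col] = float(strat[1])
                continue
            s = train[col].dropna()
            if s.empty:
                raise ValueError(f"covariate {col!r} is entirely missing on the training rows")
            if strat is None:
                strat = "mode" if set(s.unique()) <= {0, 1, 0.0, 1.0} else "mean"
            if strat == "mean":
                self.fill_values_[col] = float(s.mean())
            elif strat == "mode":
                self.fill_values_[col] = s.mode(dropna=True).iloc[0]
            else:
                raise ValueError(f"unknown imputation strategy {strat!r} for {col}")
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, v in self.fill_values_.items():
            if col in out.columns:
                out[col] = out[col].fillna(v)
        return out


def impute(
    train: pd.DataFrame, test: pd.DataFrame | None = None, strategies: dict | None = None
) -> tuple:
    """Convenience wrapper: learn fill values on ``train``, apply to both."""
    imp = Imputer(strategies).fit(train)
    if test is None:
        return imp.transform(train), imp
    return imp.transform(train), imp.transform(test), imp


def episodes_from_cohort(cohort) -> tuple:
    """Episode and daily frames straight from synthetic AdmissionRecords."""
    from .synthetic import cohort_frames

    return cohort_frames(cohort)
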