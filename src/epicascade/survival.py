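"""Kaplan-Meier estimation, log-rank testing, and outcome-driven cutpoints.

The cutpoint selector mirrors the X-tile protocol: split the cohort into
training and validation halves, scan every admissible marker split in
training for the maximal log-rank chi-square, then report the validation
log-rank p at the chosen cutpoint.  The split is what keeps the reported p
honest — optimizing and testing on the same samples is anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if (records["time"] < 0).any():
        raise ValueError("negative follow-up time")
    if not set(records["event"].unique()) <= {0, 1}:
        raise ValueError("event must be 0/1")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival table: time, survival, at_risk, events.

    Ties of events and censorings at the same time follow the events-first
    convention (censored subjects remain at risk for same-time events).
    """
    records = _validate(records)
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table.iloc[1:] if 0.0 not in records["time"].values else (
        kmf.event_table
    )
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
        }
    )
    out["survival"] = [float(surv.loc[t]) for t in out["time"]]
    return out


def logrank_chi2(
    times: np.ndarray, events: np.ndarray, in_group_a: np.ndarray
) -> float:
    """Two-group log-rank chi-square with hypergeometric tie accounting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    a = np.asarray(in_group_a, dtype=bool)
    event_times = np.unique(times[events == 1])
    observed = expected = variance = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & a).sum()
        observed += d_a
        expected += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0
    return float((observed - expected) ** 2 / variance)


def logrank_test(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, p) with 1 df."""
    group_a, group_b = _validate(group_a), _validate(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _lifelines_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    train_chi2: float
    validation_chi2: float
    validation_logrank_p: float
    n_below: int  # validation group sizes
    n_above: int
    km_below: pd.DataFrame
    km_above: pd.DataFrame


def scan_cutpoints(
    records: pd.DataFrame, min_group_fraction: float = 0.10
) -> pd.DataFrame:
    """Log-rank chi-square at every admissible marker split.

    Candidates are midpoints between adjacent distinct marker values that
    leave at least ``min_group_fraction`` of the samples on each side.
    """
    records = _validate(records)
    if "marker" not in records.columns:
        raise ValueError("records need a marker column")
    marker = records["marker"].to_numpy(dtype=float)
    times = records["time"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=int)
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("constant marker admits no cutpoint")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    min_n = max(1, int(np.ceil(min_group_fraction * len(records))))
    rows = []
    for c in cuts:
        below = marker <= c
        if below.sum() < min_n or (~below).sum() < min_n:
            continue
        rows.append({"cutpoint": float(c),
                     "chi2": logrank_chi2(times, events, below)})
    if not rows:
        raise ValueError("no admissible cutpoint under the group-size floor")
    return pd.DataFrame(rows)


def xtile_cutpoint(
    records: pd.DataFrame,
    seed: int,
    train_fraction: float = 0.5,
    min_group_fraction: float = 0.10,
) -> CutpointResult:
    """Train/validation optimal log-rank cutpoint for a continuous marker.

    Records are randomly split (seeded); the training argmax-chi2 cutpoint
    (ties toward the lower value) is then applied to the held-out
    validation samples, whose log-rank p is the reported measure of
    association.
    """
    records = _validate(records).reset_index(drop=True)
    if len(records) < 20 or records["event"].sum() < 5:
        raise ValueError("need >= 20 records with >= 5 events")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train = records.iloc[perm[:n_train]]
    valid = records.iloc[perm[n_train:]]

    scan = scan_cutpoints(train, min_group_fraction)
    # a training-optimal cut in an extreme tail can leave a degenerate
    # validation split; restrict to cuts admissible on both halves
    vmark = valid["marker"].to_numpy()
    ok = np.array([
        (vmark <= c).any() and (vmark > c).any() for c in scan["cutpoint"]
    ])
    if not ok.any():
        raise ValueError("no cutpoint admissible in both training and "
                         "validation halves")
    scan = scan[ok]
    best_chi2 = scan["chi2"].max()
    best = scan.loc[scan["chi2"] >= best_chi2 - 1e-12, "cutpoint"].min()

    below = valid[valid["marker"] <= best]
    above = valid[valid["marker"] > best]
    chi2, p = logrank_test(below, above)
    return CutpointResult(
        cutpoint=float(best),
        train_chi2=float(best_chi2),
        validation_chi2=chi2,
        validation_logrank_p=p,
        n_below=len(below),
        n_above=len(above),
        km_below=km_estimate(below),
        km_above=km_estimate(above),
    )
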