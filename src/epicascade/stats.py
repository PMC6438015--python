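"""Rank-based association statistics and clinical grouping logic.

Mann-Whitney U, Kruskal-Wallis, Bonferroni-adjusted Dunn post-hoc, paired
Wilcoxon signed-rank, Bonferroni thresholding, and Gleason grouping
(including the 3+4 "7a" vs 4+3 "7b" distinction).  Exact null distributions
are used for small samples (combined n <= 12, no ties); otherwise the normal
approximation with tie and continuity corrections applies — cohort-scale
comparisons always take the approximate path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_N_MAX = 12

GLEASON_SCHEMES = ("expr", "meth")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for ``x``.

    mode 'auto' picks the exact null when n_x + n_y <= 12 and there are no
    ties, else the tie-corrected normal approximation with continuity
    correction.  mode 'exact' with ties present is a contract violation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty group")
    ties = _has_ties(np.concatenate([x, y]))
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= EXACT_N_MAX and not ties) else "approx"
    if mode == "exact":
        if ties:
            raise ValueError(
                "exact Mann-Whitney is undefined with ties; use mode='approx'"
            )
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "approx":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(1.0, res.pvalue))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis: need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-sum post-hoc test for all group pairs.

    z_ij = (meanrank_i - meanrank_j) /
           sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) over tied-value groups.  Adjusted p is
    Bonferroni over the number of pairs, capped at 1.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    arrays = {k: np.asarray(groups[k], dtype=float) for k in names}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("dunn_posthoc: empty group")
    pooled = np.concatenate([arrays[k] for k in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    offset = 0
    for k in names:
        n_k = arrays[k].size
        mean_ranks[k] = ranks[offset : offset + n_k].mean()
        sizes[k] = n_k
        offset += n_k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        base_var -= tie_term / (12.0 * (n_total - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:  # all values tied
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
        rows.append(
            {"group_a": a, "group_b": b, "z": float(z),
             "p_raw": float(p_raw), "p_adjusted": float(p_adj)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    n_zero_dropped: int


def wilcoxon_signed_rank_paired(
    tumor: Sequence[float],
    normal: Sequence[float],
    continuity: bool = True,
    mode: str = "auto",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped from the test and counted in the result.
    Exact null when effective n <= 12 and no tied |differences|; else normal
    approximation with continuity correction.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = tumor - normal
    nonzero = diffs[diffs != 0]
    n_zero = int(diffs.size - nonzero.size)
    if nonzero.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    tied = _has_ties(np.abs(nonzero))
    if mode == "auto":
        mode = "exact" if (nonzero.size <= EXACT_N_MAX and not tied) else "approx"
    res = sps.wilcoxon(
        nonzero,
        zero_method="wilcox",
        correction=continuity,
        alternative="two-sided",
        method="exact" if mode == "exact" else "asymptotic",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n_effective=int(nonzero.size),
        n_zero_dropped=n_zero,
    )


def bonferroni_threshold(alpha: float = 0.05, m_tests: int = 1) -> float:
    """Per-test significance threshold alpha / m_tests."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m_tests


def gleason_group(primary: int, secondary: int, scheme: str = "expr") -> str:
    """Map a (primary, secondary) Gleason pattern to a risk group label.

    'expr' scheme: GS6 / GS7 / GS8+.  'meth' scheme splits GS7 into GS7a
    (3+4) and GS7b (4+3); normals never enter here (they carry no Gleason).
    """
    if scheme not in GLEASON_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if primary not in (3, 4, 5) or secondary not in (3, 4, 5):
        raise ValueError(f"invalid Gleason pattern {primary}+{secondary}")
    total = primary + secondary
    if total >= 8:
        return "GS8+"
    if total == 6:
        return "GS6"
    # total == 7
    if scheme == "expr":
        return "GS7"
    return "GS7a" if (primary, secondary) == (3, 4) else "GS7b"


def _group_values(
    values: pd.Series, clinical: pd.DataFrame, scheme: str
) -> dict[str, np.ndarray]:
    """Split one feature's per-sample values into Gleason groups.

    The 'meth' scheme appends normals as their own group, mirroring the
    probe-level comparisons that include normal tissue.
    """
    groups: dict[str, list[float]] = {}
    for row in clinical.itertuples():
        v = values.get(row.sample_id, np.nan)
        if np.isnan(v):
            continue
        if row.tissue == "normal":
            if scheme == "meth":
                groups.setdefault("normal", []).append(v)
            continue
        if pd.isna(row.gleason_primary) or pd.isna(row.gleason_secondary):
            continue
        label = gleason_group(int(row.gleason_primary), int(row.gleason_secondary),
                              scheme)
        groups.setdefault(label, []).append(v)
    order = ["GS6", "GS7", "GS7a", "GS7b", "GS8+", "normal"]
    return {k: np.asarray(groups[k]) for k in order if k in groups and groups[k]}


def run_association(
    values: pd.DataFrame,
    clinical: pd.DataFrame,
    scheme: str = "expr",
) -> pd.DataFrame:
    """Clinicopathological association table for a feature x sample matrix.

    For every feature (gene expression or probe beta row) computes:
    tumor-vs-normal Mann-Whitney (all samples and matched pairs only),
    recurrent-vs-non-recurrent and stage-group Mann-Whitney among tumors,
    Kruskal-Wallis across Gleason groups, and Bonferroni-adjusted Dunn
    pairwise comparisons.  Returns one row per feature.
    """
    clinical = clinical.set_index("sample_id", drop=False)
    tumors = clinical[clinical["tissue"] == "tumor"]
    normals = clinical[clinical["tissue"] == "normal"]
    matched = clinical[clinical["matched_pair_id"].notna()]
    rows = []
    for feature, series in values.iterrows():
        out: dict[str, object] = {"feature": feature}
        t_all = series.reindex(tumors["sample_id"]).dropna().to_numpy()
        n_all = series.reindex(normals["sample_id"]).dropna().to_numpy()
        if t_all.size and n_all.size:
            _, out["p_tumor_vs_normal_all"] = mann_whitney_u(t_all, n_all,
                                                             mode="approx")
        mt = matched[matched["tissue"] == "tumor"]["sample_id"]
        mn = matched[matched["tissue"] == "normal"]["sample_id"]
        t_m = series.reindex(mt).dropna().to_numpy()
        n_m = series.reindex(mn).dropna().to_numpy()
        if t_m.size and n_m.size:
            # unpaired by convention for expression/beta group comparisons
            _, out["p_tumor_vs_normal_matched"] = mann_whitney_u(t_m, n_m,
                                                                 mode="approx")
        rec = tumors[tumors["recurrence"].isin(["yes", "no"])]
        r_yes = series.reindex(rec[rec["recurrence"] == "yes"]["sample_id"]
                               ).dropna().to_numpy()
        r_no = series.reindex(rec[rec["recurrence"] == "no"]["sample_id"]
                              ).dropna().to_numpy()
        if r_yes.size and r_no.size:
            _, out["p_recurrence"] = mann_whitney_u(r_yes, r_no, mode="approx")
        stg = tumors[tumors["stage_group"].notna()]
        stage_labels = stg["stage_group"].unique()
        if len(stage_labels) == 2:
            a = series.reindex(stg[stg["stage_group"] == stage_labels[0]]
                               ["sample_id"]).dropna().to_numpy()
            b = series.reindex(stg[stg["stage_group"] == stage_labels[1]]
                               ["sample_id"]).dropna().to_numpy()
            if a.size and b.size:
                _, out["p_stage"] = mann_whitney_u(a, b, mode="approx")
        groups = _group_values(series, clinical, scheme)
        if len(groups) >= 2:
            _, out["p_gleason_kw"] = kruskal_wallis(list(groups.values()))
            dunn = dunn_posthoc(groups)
            for r in dunn.itertuples():
                key = f"p_dunn_{r.group_a}_vs_{r.group_b}".replace("+", "plus")
                out[key] = r.p_adjusted
        rows.append(out)
    return pd.DataFrame(rows).set_index("feature")
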