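"""The candidate-gene selection cascade.

Funnels knockout evidence through cohort concordance into a tiered candidate
panel: (1) significant expression loss in either KO line, (2) concordant
expression loss in the low-anchor (bottom TET2 decile) tumor subset below a
Bonferroni threshold derived from the actual number of tests, (3) promoter
methylation gain in either KO line, (4) membership of an externally supplied
prior list, (5) concordant differential methylation at array probes within
or proximal to the KO gain-DMRs, and (6, 7) tumor-vs-normal expression
discrimination in all tumors and in matched pairs.  Every flag is computed
independently of the prior-list stage so that dropping that input changes
nothing else; a gene's tier counts consecutive passes in cascade order.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, ProbeRecord, map_probes_to_regions
from .stats import bonferroni_threshold, mann_whitney_u

CASCADE_ORDER = [
    "ko_down_either",
    "cohort_expr_down",
    "ko_promoter_hypermeth_either",
    "prior_list_member",
    "cohort_probe_concordant",
    "tumor_normal_discriminant_all",
    "tumor_normal_discriminant_matched",
]


def select_low_anchor_subset(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    anchor_gene: str = "TET2",
    quantile: float = 0.10,
) -> list[str]:
    """Tumor samples in the bottom ``quantile`` of anchor-gene expression.

    Subset size is ceil(quantile * n_tumors); boundary ties resolve by
    expression rank then sample id, so the size is exact.
    """
    if anchor_gene not in expr.index:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from expression")
    tumors = clinical.loc[clinical["tissue"] == "tumor", "sample_id"].tolist()
    tumors = [t for t in tumors if t in expr.columns]
    if not tumors:
        raise ValueError("no tumor samples with expression")
    k = math.ceil(quantile * len(tumors))
    values = expr.loc[anchor_gene, tumors]
    order = sorted(tumors, key=lambda s: (values[s], s))
    return order[:k]


def cohort_expression_concordance(
    ko_down_genes: Sequence[str],
    expr: pd.DataFrame,
    subset_ids: Sequence[str],
    normal_ids: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney concordance screen of KO-down genes in the cohort.

    Each gene is tested two-sided (low-anchor tumor subset vs normals)
    against the Bonferroni threshold alpha / len(ko_down_genes); passing
    additionally requires the tumor direction to be down.  Returns a table
    indexed by gene with p_value, direction, and passes.
    """
    rows = []
    m = len(ko_down_genes)
    threshold = bonferroni_threshold(alpha, m) if m else float("nan")
    for gene in ko_down_genes:
        if gene not in expr.index:
            raise ValueError(f"gene {gene!r} absent from cohort expression")
        x = expr.loc[gene, list(subset_ids)].to_numpy(dtype=float)
        y = expr.loc[gene, list(normal_ids)].to_numpy(dtype=float)
        _, p = mann_whitney_u(x, y, mode="approx")
        down = np.median(x) < np.median(y) or (
            np.median(x) == np.median(y) and x.mean() < y.mean()
        )
        rows.append(
            {"gene_id": gene, "p_value": p, "direction": "down" if down else "up",
             "passes": bool(p < threshold and down)}
        )
    out = pd.DataFrame(rows, columns=["gene_id", "p_value", "direction", "passes"])
    out = out.set_index("gene_id") if len(out) else out
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["m_tests"] = m
    return out


def _ko_down_flags(
    ko_de: Mapping[str, pd.DataFrame], alpha: float, down_fc: float
) -> pd.Series:
    universes = [set(t.index) for t in ko_de.values()]
    universe = universes[0]
    for u in universes[1:]:
        if u != universe:
            diff = sorted(universe ^ u)
            raise ValueError(f"gene-universe mismatch across KO lines: {diff[:10]}")
    flags = pd.Series(False, index=sorted(universe))
    for table in ko_de.values():
        hit = (table["p_value"] < alpha) & (table["fold_change"] < down_fc)
        flags |= hit.reindex(flags.index, fill_value=False)
    return flags


def _promoter_gain_dmrs(
    ko_dmr: Mapping[str, pd.DataFrame]
) -> dict[str, list[GenomicInterval]]:
    """Per-gene promoter gain-DMR intervals, pooled over KO lines."""
    hits: dict[str, list[GenomicInterval]] = {}
    for table in ko_dmr.values():
        if "feature" not in table.columns:
            raise ValueError("DMR table lacks feature annotation; pass a gene "
                             "table to test_differential_methylation")
        sig = table[
            table["significant"]
            & (table["direction"] == "gain")
            & (table["feature"] == "promoter")
        ]
        for row in sig.itertuples():
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
            hits.setdefault(row.gene_id, []).append(iv)
    return hits


def assemble_panel(
    ko_de: Mapping[str, pd.DataFrame],
    ko_dmr: Mapping[str, pd.DataFrame],
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    probe_manifest: pd.DataFrame,
    probe_betas: pd.DataFrame,
    prior_list: Sequence[str] | None = None,
    anchor_gene: str = "TET2",
    quantile: float = 0.10,
    alpha: float = 0.05,
    down_fc: float = 0.75,
    probe_window: int = 500,
    strict_cascade: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade and return (panel table, provenance).

    The panel has one row per gene in the KO universe with boolean columns
    in cascade order, a tier column, and per-gene DMR/probe provenance.
    When ``prior_list`` is None that stage is omitted entirely.  With
    ``strict_cascade`` on, each flag is masked by all upstream flags.
    """
    missing = [g for g in next(iter(ko_de.values())).index if g not in expr.index]
    if missing:
        raise ValueError(f"gene-universe mismatch vs cohort expression: "
                         f"{missing[:10]}")

    order = [s for s in CASCADE_ORDER
             if prior_list is not None or s != "prior_list_member"]

    flags = pd.DataFrame(index=_ko_down_flags(ko_de, alpha, down_fc).index)
    flags["ko_down_either"] = _ko_down_flags(ko_de, alpha, down_fc)

    subset_ids = select_low_anchor_subset(expr, clinical, anchor_gene, quantile)
    normal_ids = clinical.loc[clinical["tissue"] == "normal", "sample_id"].tolist()
    ko_down_genes = flags.index[flags["ko_down_either"]].tolist()
    concordance = cohort_expression_concordance(
        ko_down_genes, expr, subset_ids, normal_ids, alpha
    )
    flags["cohort_expr_down"] = False
    if len(concordance):
        flags.loc[concordance.index, "cohort_expr_down"] = concordance["passes"]

    dmr_map = _promoter_gain_dmrs(ko_dmr)
    flags["ko_promoter_hypermeth_either"] = [g in dmr_map for g in flags.index]

    if prior_list is not None:
        prior = set(prior_list)
        flags["prior_list_member"] = [g in prior for g in flags.index]

    # probe concordance over genes with KO promoter gain-DMRs and upstream
    # expression evidence (the prior stage never gates this computation)
    probe_candidates = [
        g for g in flags.index
        if flags.loc[g, "ko_down_either"]
        and flags.loc[g, "cohort_expr_down"]
        and g in dmr_map
    ]
    probes = [
        ProbeRecord(r.probe_id, r.chrom, int(r.pos))
        for r in probe_manifest.itertuples()
    ]
    probe_tests: list[tuple[str, str, float]] = []  # gene, probe, p
    gene_probe_ids: dict[str, list[str]] = {g: [] for g in flags.index}
    for gene in probe_candidates:
        assignments = map_probes_to_regions(probes, dmr_map[gene], probe_window)
        for probe_id in assignments["probe_id"]:
            if probe_id not in probe_betas.index:
                continue
            x = probe_betas.loc[probe_id, list(subset_ids)].dropna().to_numpy()
            y = probe_betas.loc[probe_id, list(normal_ids)].dropna().to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            _, p = mann_whitney_u(x, y, mode="approx")
            probe_tests.append((gene, probe_id, p))
            gene_probe_ids[gene].append(probe_id)
    m_probe = len(probe_tests)
    probe_threshold = bonferroni_threshold(alpha, m_probe) if m_probe else np.nan
    flags["cohort_probe_concordant"] = False
    for gene, _, p in probe_tests:
        if p < probe_threshold:
            flags.loc[gene, "cohort_probe_concordant"] = True

    # tumor/normal discriminant tiers over probe-concordant genes
    disc_candidates = flags.index[flags["cohort_probe_concordant"]].tolist()
    tumor_ids = clinical.loc[clinical["tissue"] == "tumor", "sample_id"].tolist()
    matched = clinical[clinical["matched_pair_id"].notna()]
    mt = matched.loc[matched["tissue"] == "tumor", "sample_id"].tolist()
    mn = matched.loc[matched["tissue"] == "normal", "sample_id"].tolist()
    m_disc = 2 * len(disc_candidates)
    disc_threshold = bonferroni_threshold(alpha, m_disc) if m_disc else np.nan
    flags["tumor_normal_discriminant_all"] = False
    flags["tumor_normal_discriminant_matched"] = False
    for gene in disc_candidates:
        for flag, tum in (
            ("tumor_normal_discriminant_all", tumor_ids),
            ("tumor_normal_discriminant_matched", mt),
        ):
            norm = normal_ids if flag.endswith("all") else mn
            x = expr.loc[gene, tum].to_numpy(dtype=float)
            y = expr.loc[gene, norm].to_numpy(dtype=float)
            _, p = mann_whitney_u(x, y, mode="approx")
            down = np.median(x) < np.median(y)
            flags.loc[gene, flag] = bool(p < disc_threshold and down)

    flags = flags[order].astype(bool)
    if strict_cascade:
        mask = pd.Series(True, index=flags.index)
        for stage in order:
            flags[stage] &= mask
            mask &= flags[stage]

    tier = np.zeros(len(flags), dtype=int)
    alive = np.ones(len(flags), dtype=bool)
    for stage in order:
        alive &= flags[stage].to_numpy()
        tier += alive
    panel = flags.copy()
    panel["tier"] = tier
    panel["dmr_intervals"] = [
        ";".join(f"{iv.chrom}:{iv.start}-{iv.end}" for iv in dmr_map.get(g, []))
        for g in panel.index
    ]
    panel["probe_ids"] = [",".join(gene_probe_ids.get(g, [])) for g in panel.index]
    panel.index.name = "gene_id"

    provenance = {
        "alpha": alpha,
        "down_fc": down_fc,
        "anchor_gene": anchor_gene,
        "quantile": quantile,
        "subset_size": len(subset_ids),
        "expr_bonferroni": {
            "m": int(concordance.attrs.get("m_tests", 0)),
            "threshold": float(concordance.attrs.get("bonferroni_threshold",
                                                     np.nan)),
        },
        "probe_bonferroni": {"m": m_probe,
                             "threshold": float(probe_threshold)},
        "discriminant_bonferroni": {"m": m_disc,
                                    "threshold": float(disc_threshold)},
        "tier_counts": {
            stage: int((panel["tier"] >= i + 1).sum())
            for i, stage in enumerate(order)
        },
        "strict_cascade": strict_cascade,
    }
    return panel, provenance
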