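"""Windowed enrichment peak calling and differential methylation testing.

Capture-seq read counts arrive as fixed-width genomic windows x samples.
Peaks are windows whose treatment count exceeds a Poisson background
(scaled input or global rate, whichever is larger, plus a 0.5 pseudo-count);
significant windows are merged into regions.  Consensus regions across
samples are the merged union.  Differential methylation between conditions
reuses the exact negative-binomial machinery from the expression module on
region-aggregated counts, normalized by full-library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import nb_exact_test
from .genome import GeneModel, GenomicInterval, classify_region, merge_intervals

DEFAULT_WINDOW_WIDTH = 200
DEFAULT_PEAK_P = 1e-5


@dataclass
class RegionCountSet:
    """Genomic intervals x samples matrix of capture-seq read counts."""

    regions: list[GenomicInterval]
    counts: pd.DataFrame  # rows align with regions, columns are samples
    sample_info: pd.DataFrame  # index sample, columns condition + replicate
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.counts):
            raise ValueError("regions and count rows differ in length")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        missing = set(self.counts.columns) - set(self.sample_info.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        hits = [
            s for s in self.counts.columns
            if self.sample_info.loc[s, "condition"] == condition
        ]
        if not hits:
            raise ValueError(f"no samples with condition {condition!r}")
        return hits


@dataclass(frozen=True)
class DMRecord:
    """A differentially methylated region with direction and annotation."""

    interval: GenomicInterval
    log2_fold_change: float
    p_value: float
    direction: str  # gain | loss
    feature: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p outside [0,1]")
        expected = "gain" if self.log2_fold_change > 0 else "loss"
        if self.log2_fold_change != 0 and self.direction != expected:
            raise ValueError("direction inconsistent with fold change sign")


def call_peaks(
    windows: RegionCountSet,
    treatment_sample: str,
    input_sample: str,
    p_threshold: float = DEFAULT_PEAK_P,
    merge_gap_windows: int = 1,
) -> list[GenomicInterval]:
    """Poisson upper-tail enrichment peaks from fixed-width window counts.

    Per window, lambda = max(input count * depth ratio, global background
    rate) + 0.5 and p = P(Poisson(lambda) >= count).  Windows with
    p < p_threshold are merged when separated by at most merge_gap_windows
    intervening windows.
    """
    treat = windows.counts[treatment_sample].to_numpy(dtype=float)
    inp = windows.counts[input_sample].to_numpy(dtype=float)
    lib_t = float(windows.library_sizes[treatment_sample])
    lib_i = float(windows.library_sizes[input_sample])
    if lib_t <= 0 or lib_i <= 0:
        raise ValueError("zero-depth library")
    scaled_input = inp * (lib_t / lib_i)
    global_rate = lib_t / len(treat)
    lam = np.maximum(scaled_input, global_rate) + 0.5
    pvals = sps.poisson.sf(treat - 1, lam)  # upper tail P(X >= count)
    significant = pvals < p_threshold

    width = len(windows.regions[0])
    order = np.lexsort(
        ([iv.start for iv in windows.regions], [iv.chrom for iv in windows.regions])
    )
    # merge significant windows whose genomic separation is at most
    # merge_gap_windows window-widths (intervening windows need not exist)
    max_gap_bp = merge_gap_windows * width
    peaks: list[GenomicInterval] = []
    run_start = run_end = None
    run_chrom = None
    for idx in order:
        if not significant[idx]:
            continue
        iv = windows.regions[idx]
        if run_chrom == iv.chrom and iv.start - run_end <= max_gap_bp:
            run_end = max(run_end, iv.end)
        else:
            if run_chrom is not None:
                peaks.append(GenomicInterval(run_chrom, run_start, run_end))
            run_chrom, run_start, run_end = iv.chrom, iv.start, iv.end
    if run_chrom is not None:
        peaks.append(GenomicInterval(run_chrom, run_start, run_end))
    return merge_intervals(peaks) if peaks else []


def consensus_regions(
    peak_sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Merged union of peaks present in at least one sample."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    pooled = [iv for peaks in peak_sets for iv in peaks]
    return merge_intervals(pooled) if pooled else []


def aggregate_windows(
    windows: RegionCountSet, regions: Sequence[GenomicInterval]
) -> RegionCountSet:
    """Sum window counts within each region (window midpoint containment)."""
    mids = np.array([(iv.start + iv.end - 1) // 2 for iv in windows.regions])
    chroms = np.array([iv.chrom for iv in windows.regions])
    mat = windows.counts.to_numpy()
    rows = []
    for region in regions:
        mask = (
            (chroms == region.chrom) & (mids >= region.start) & (mids < region.end)
        )
        rows.append(mat[mask].sum(axis=0))
    counts = pd.DataFrame(
        rows, columns=windows.counts.columns,
        index=[f"{r.chrom}:{r.start}-{r.end}" for r in regions],
    )
    return RegionCountSet(
        regions=list(regions),
        counts=counts,
        sample_info=windows.sample_info,
        library_sizes=windows.library_sizes,
    )


def test_differential_methylation(
    counts: RegionCountSet,
    ko_condition: str,
    parental_condition: str,
    alpha: float = 0.05,
    dispersion: float | str = "auto",
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Exact NB test of region counts, KO vs parental.

    Returns one row per region: log2_fold_change, p_value, direction,
    significant (p < alpha), and feature/gene annotation when a gene table
    is supplied.  Normalization uses the full-library sizes of the count
    set so that region subsetting does not distort depth.
    """
    ko = counts.samples_for(ko_condition)
    par = counts.samples_for(parental_condition)
    if len(ko) < 2 or len(par) < 2:
        import warnings

        warnings.warn("fewer than 2 replicates per condition", stacklevel=2)
    res = nb_exact_test(
        counts.counts, ko, par, dispersion=dispersion,
        size_factors_override=counts.library_sizes,
    )
    out = pd.DataFrame(index=res.index)
    out["chrom"] = [iv.chrom for iv in counts.regions]
    out["start"] = [iv.start for iv in counts.regions]
    out["end"] = [iv.end for iv in counts.regions]
    out["log2_fold_change"] = np.log2(res["fold_change"])
    out["p_value"] = res["p_value"]
    out["direction"] = np.where(out["log2_fold_change"] > 0, "gain", "loss")
    out["significant"] = out["p_value"] < alpha
    if genes is not None:
        feats, gids = [], []
        for iv in counts.regions:
            feature, gid = classify_region(iv, list(genes))
            feats.append(feature)
            gids.append(gid)
        out["feature"] = feats
        out["gene_id"] = gids
    out.attrs["dispersion"] = res.attrs.get("dispersion")
    out.attrs["normalization"] = "library-size"
    return out


def dmrs_from_table(table: pd.DataFrame) -> list[DMRecord]:
    """Significant rows of a differential-methylation table as DMRecords."""
    records = []
    for row in table[table["significant"]].itertuples():
        records.append(
            DMRecord(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                log2_fold_change=float(row.log2_fold_change),
                p_value=float(row.p_value),
                direction=row.direction,
                feature=getattr(row, "feature", None),
                gene_id=getattr(row, "gene_id", None),
            )
        )
    return records


def tally_dmrs(
    dmrs: Iterable[DMRecord], genes: Sequence[GeneModel] | None = None
) -> pd.DataFrame:
    """Gain/loss DMR counts by feature class; overall sums all classes."""
    tallies = {
        d: {f: 0 for f in ("promoter", "gene_body", "intergenic", "overall")}
        for d in ("gain", "loss")
    }
    for dmr in dmrs:
        feature = dmr.feature
        if feature is None:
            if genes is None:
                raise ValueError("unclassified DMR and no gene table supplied")
            feature, _ = classify_region(dmr.interval, list(genes))
        tallies[dmr.direction][feature] += 1
        tallies[dmr.direction]["overall"] += 1
    return pd.DataFrame(tallies).T
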