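"""Gene/probe coordinate types, promoter derivation, and interval assignment.

Coordinates are 0-based half-open (BED convention) throughout.  The
transcription start site of a minus-strand gene is ``span_end - 1``.
Promoters default to the window -1500 bp to +500 bp around the TSS,
strand-aware and clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
PROBE_PROXIMITY_WINDOW = 500
NEAREST_TSS_CAP = 100_000


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to_point(self, chrom: str, pos: int) -> int | None:
        """Distance in bp from a point to the nearest interval edge.

        0 if the point lies inside the interval, None on another chromosome.
        Downstream distances are measured to the half-open end coordinate,
        so a probe at ``end + w`` has gap ``w``.
        """
        if chrom != self.chrom:
            return None
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span, strand, and derived TSS."""

    gene_id: str
    chrom: str
    span_start: int
    span_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.span_start >= self.span_end:
            raise ValueError(f"{self.gene_id}: span_start >= span_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1


@dataclass
class ProbeRecord:
    """A single-CpG methylation array probe with per-sample beta values."""

    probe_id: str
    chrom: str
    pos: int
    betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.probe_id}: negative position")
        for sample, b in self.betas.items():
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"{self.probe_id}/{sample}: beta {b} outside [0,1]")


def promoter_of(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at zero.

    On the + strand the window is [tss - upstream, tss + downstream);
    on the - strand it mirrors to [tss - downstream, tss + upstream) so that
    `upstream` bases lie 5' of the TSS in transcript orientation.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end)


def classify_region(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    nearest_tss_cap: int = NEAREST_TSS_CAP,
) -> tuple[str, str | None]:
    """Assign a region to {promoter, gene_body, intergenic} plus a gene.

    Precedence: promoter > gene_body > intergenic.  Within a class, ties go
    to the gene whose TSS is nearest (then lexicographic gene_id).  Regions
    overlapping nothing are assigned to the nearest TSS within
    ``nearest_tss_cap`` bp, else left unassigned.
    """
    if not genes:
        raise ValueError("empty gene table")
    mid = (region.start + region.end - 1) // 2

    def tss_key(g: GeneModel) -> tuple[int, str]:
        return (abs(g.tss - mid), g.gene_id)

    promoter_hits = [
        g for g in genes
        if promoter_of(g, upstream, downstream).overlaps(region)
    ]
    if promoter_hits:
        return "promoter", min(promoter_hits, key=tss_key).gene_id
    body_hits = [
        g for g in genes
        if GenomicInterval(g.chrom, g.span_start, g.span_end).overlaps(region)
    ]
    if body_hits:
        return "gene_body", min(body_hits, key=tss_key).gene_id
    same_chrom = [g for g in genes if g.chrom == region.chrom]
    if same_chrom:
        nearest = min(same_chrom, key=tss_key)
        if abs(nearest.tss - mid) <= nearest_tss_cap:
            return "intergenic", nearest.gene_id
    return "intergenic", None


def map_probes_to_regions(
    probes: Iterable[ProbeRecord],
    regions: Sequence[GenomicInterval],
    window: int = PROBE_PROXIMITY_WINDOW,
) -> pd.DataFrame:
    """Assign each probe to its nearest region when within ``window`` bp.

    A probe inside a region has gap 0; otherwise the gap is the distance to
    the nearest region edge, and assignment requires gap <= window
    (inclusive).  Returns a DataFrame (probe_id, region_index, gap) with one
    row per assigned probe; region ties break toward the lower index.
    """
    rows = []
    for probe in probes:
        best_gap, best_idx = None, None
        for idx, region in enumerate(regions):
            gap = region.gap_to_point(probe.chrom, probe.pos)
            if gap is None or gap > window:
                continue
            if best_gap is None or gap < best_gap:
                best_gap, best_idx = gap, idx
        if best_idx is not None:
            rows.append({"probe_id": probe.probe_id,
                         "region_index": best_idx, "gap": best_gap})
    return pd.DataFrame(rows, columns=["probe_id", "region_index", "gap"])


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def percent_conserved(n_conserved: int, n_total: int) -> float:
    """Percentage of conserved CpGs, rounded to one decimal (e.g. 5/7 -> 71.4)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_conserved <= n_total:
        raise ValueError("n_conserved outside [0, n_total]")
    return round(100.0 * n_conserved / n_total, 1)


def genes_from_frame(df: pd.DataFrame) -> list[GeneModel]:
    """Build GeneModel objects from a BED6-like frame.

    Expects columns chrom, start, end, gene_id, strand (score ignored).
    """
    return [
        GeneModel(
            gene_id=str(r.gene_id), chrom=str(r.chrom),
            span_start=int(r.start), span_end=int(r.end), strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.span_start for g in genes],
            "end": [g.span_end for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    )


def genes_from_gtf(path: str) -> list[GeneModel]:
    """Minimal GTF import: gene feature lines only, gene_id attribute required."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = parts[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene line without gene_id")
            # GTF is 1-based closed; convert to 0-based half-open
            genes.append(
                GeneModel(gene_id, parts[0], int(parts[3]) - 1, int(parts[4]),
                          parts[6])
            )
    return genes
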