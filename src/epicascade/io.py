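"""File readers/writers with schema validation, plus the run manifest.

All formats are plain text: TSV matrices (counts, expression, betas,
clinical), CSV (probe manifest, qPCR Ct), BED (peaks/DMRs), YAML config,
JSON manifest.  Readers fail with file and row references; a mix of
'chr'-prefixed and bare chromosome names in one table is rejected outright
because silent non-matching coordinates are the classic integration bug.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, GenomicInterval, genes_from_frame
from .methylation import RegionCountSet

FORMAT_VERSION = "1"


class InputError(ValueError):
    """A malformed input file; the message carries file and row context."""


def _check_chrom_naming(chroms: Iterable[str], path: str) -> None:
    names = set(str(c) for c in chroms)
    prefixed = {c for c in names if c.startswith("chr")}
    if prefixed and prefixed != names:
        raise InputError(
            f"{path}: mixed chromosome naming ({sorted(names)[:4]}...); "
            "use either 'chr1'-style or '1'-style consistently"
        )


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise InputError(f"{path}: empty count matrix")
    bad = df[(df < 0).any(axis=1)]
    if len(bad):
        raise InputError(f"{path}: negative count at gene {bad.index[0]!r}")
    return df


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """BED6-derived gene table: chrom, start, end, gene_id, score, strand."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    _check_chrom_naming(df["chrom"], str(path))
    for i, row in df.iterrows():
        if row["start"] >= row["end"]:
            raise InputError(f"{path}: row {i + 1}: start >= end")
        if row["strand"] not in ("+", "-"):
            raise InputError(f"{path}: row {i + 1}: bad strand {row['strand']!r}")
    return genes_from_frame(df)


def write_gene_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.span_start))
    with open(path, "w") as fh:
        for g in rows:
            fh.write(f"{g.chrom}\t{g.span_start}\t{g.span_end}\t"
                     f"{g.gene_id}\t0\t{g.strand}\n")


def read_region_counts(
    counts_path: str | Path, samples_path: str | Path
) -> RegionCountSet:
    """Window counts TSV (chrom, start, end, sample...) + sample-info TSV."""
    df = pd.read_csv(counts_path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise InputError(f"{counts_path}: missing column {col!r}")
    _check_chrom_naming(df["chrom"], str(counts_path))
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise InputError(f"{counts_path}: row {bad.index[0] + 1}: start >= end")
    regions = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    counts = df[sample_cols]
    counts.index = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    info = pd.read_csv(samples_path, sep="\t").set_index("sample")
    return RegionCountSet(regions=regions, counts=counts, sample_info=info)


def write_region_counts(rcs: RegionCountSet, counts_path: str | Path,
                        samples_path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in rcs.regions],
            "start": [iv.start for iv in rcs.regions],
            "end": [iv.end for iv in rcs.regions],
        }
    )
    out = pd.concat([df, rcs.counts.reset_index(drop=True)], axis=1)
    out.to_csv(counts_path, sep="\t", index=False)
    rcs.sample_info.to_csv(samples_path, sep="\t")


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    _check_chrom_naming(df["chrom"], str(path))
    if (df["pos"] < 0).any():
        row = df.index[df["pos"] < 0][0]
        raise InputError(f"{path}: row {row + 1}: negative position")
    return df


def read_betas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    if len(bad):
        i, j = bad[0]
        raise InputError(
            f"{path}: beta {arr[i, j]} outside [0,1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "followup_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if not set(df["tissue"].unique()) <= {"tumor", "normal"}:
        raise InputError(f"{path}: tissue must be tumor/normal")
    if not set(df["event"].dropna().unique()) <= {0, 1}:
        raise InputError(f"{path}: event must be 0/1")
    bad = df[(df["event"] == 1) & df["followup_time"].isna()]
    if len(bad):
        raise InputError(
            f"{path}: row {bad.index[0] + 1}: event=1 with missing time"
        )
    if (df["followup_time"].dropna() < 0).any():
        raise InputError(f"{path}: negative follow-up time")
    for col in ("matched_pair_id", "gleason_primary", "gleason_secondary",
                "stage_group", "recurrence"):
        if col not in df.columns:
            df[col] = None
    return df


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "target", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    bad = df[df["ct"].notna() & (df["ct"] <= 0)]
    if len(bad):
        raise InputError(f"{path}: row {bad.index[0] + 1}: non-positive Ct")
    return df


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """BED output sorted by (chrom, start); BED6 when names/scores given."""
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start),
    )
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0 if scores is None else scores[i]
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{names[i]}\t{score:.6g}\t.\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: fewer than 3 BED columns")
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            )
    _check_chrom_naming([iv.chrom for iv in intervals], str(path))
    return intervals


def dmr_scores(p_values: Sequence[float]) -> list[float]:
    """BED score convention for DMRs: -10 * log10(p), capped at 1000."""
    return [min(1000.0, -10.0 * np.log10(max(p, 1e-300))) for p in p_values]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run, written exactly once."""

    seed: int
    config: dict
    input_hashes: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = FORMAT_VERSION
    started: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": config_hash(self.config),
            "config": self.config,
            "input_hashes": self.input_hashes,
            "row_counts": self.row_counts,
            "warnings": self.warnings,
            "started": self.started,
            "finished": time.time(),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg
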