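"""End-to-end orchestration of the discovery pipeline.

Stage order: peak calling / differential methylation -> differential
expression -> candidate cascade -> clinicopathological association ->
tumor/normal classification -> survival cutpoints -> MethyLight.  Stages
can be toggled; a stage whose dependency is missing is skipped with a
warning recorded in the manifest.  Given identical inputs and config the
run is deterministic: the only randomness is the seeded survival split.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cascade as _cascade
from . import classify as _classify
from . import expression as _expression
from . import methylation as _methylation
from . import methylight as _methylight
from . import stats as _stats
from . import survival as _survival
from .genome import GeneModel
from .io import RunManifest
from .methylation import RegionCountSet

ALL_STAGES = (
    "dmr", "de", "integrate", "associate", "classify", "survival", "methylight"
)

STAGE_DEPS = {
    "integrate": ("dmr", "de"),
    "associate": ("integrate",),
    "classify": ("integrate",),
    "survival": ("integrate",),
}


@dataclass
class PipelineConfig:
    """Thresholds and options for a pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    down_fc: float = 0.75
    quantile: float = 0.10
    anchor_gene: str = "TET2"
    probe_window: int = 500
    peak_p_threshold: float = 1e-5
    merge_gap_windows: int = 1
    dispersion: str | float = "auto"
    min_cpm: float = 1.0
    min_expressed_samples: int = 2
    strict_cascade: bool = False
    train_fraction: float = 0.5
    min_group_fraction: float = 0.10
    alu_ct_max: float = 30.0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.quantile <= 1):
            raise ValueError("quantile must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineInputs:
    """In-memory datasets for one run; optional parts may be None."""

    meth_windows: RegionCountSet | None = None
    ko_expr: pd.DataFrame | None = None
    genes: Sequence[GeneModel] | None = None
    cohort_expr: pd.DataFrame | None = None
    probe_manifest: pd.DataFrame | None = None
    probe_betas: pd.DataFrame | None = None
    clinical: pd.DataFrame | None = None
    prior_list: Sequence[str] | None = None
    ct_table: pd.DataFrame | None = None


def _ko_lines(columns: Sequence[str]) -> dict[str, list[str]]:
    """Group expression sample columns by line prefix ('line_repN')."""
    lines: dict[str, list[str]] = {}
    for col in columns:
        prefix = col.rsplit("_rep", 1)[0]
        lines.setdefault(prefix, []).append(col)
    return lines


def run_pipeline(
    inputs: PipelineInputs, config: PipelineConfig | None = None
) -> dict:
    """Execute the configured stages and return a result bundle.

    The bundle maps stage names to their tables/objects and always contains
    a ``manifest`` RunManifest recording thresholds, row counts, and any
    skip warnings.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(seed=config.seed, config=asdict(config))
    results: dict = {"manifest": manifest}
    done: set[str] = set()

    def wants(stage: str) -> bool:
        if stage not in config.stages:
            return False
        missing = [d for d in STAGE_DEPS.get(stage, ()) if d not in done]
        if missing:
            msg = f"stage {stage!r} skipped: requires {missing}"
            manifest.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
            return False
        return True

    genes = list(inputs.genes) if inputs.genes is not None else None

    if wants("dmr"):
        if inputs.meth_windows is None or genes is None:
            manifest.warnings.append("stage 'dmr' skipped: no window counts")
        else:
            results["dmr"] = _run_dmr_stage(inputs.meth_windows, genes, config)
            manifest.row_counts["consensus_regions"] = len(
                results["dmr"]["consensus"]
            )
            done.add("dmr")

    if wants("de"):
        if inputs.ko_expr is None:
            manifest.warnings.append("stage 'de' skipped: no KO expression")
        else:
            results["de"] = _run_de_stage(inputs.ko_expr, config)
            manifest.row_counts["expressed_genes"] = len(
                next(iter(results["de"].values()))
            )
            done.add("de")

    if wants("integrate"):
        needed = (inputs.cohort_expr, inputs.probe_manifest, inputs.probe_betas,
                  inputs.clinical)
        if any(x is None for x in needed):
            manifest.warnings.append("stage 'integrate' skipped: cohort data "
                                     "missing")
        else:
            panel, provenance = _cascade.assemble_panel(
                ko_de=results["de"],
                ko_dmr=results["dmr"]["tables"],
                expr=inputs.cohort_expr,
                clinical=inputs.clinical,
                probe_manifest=inputs.probe_manifest,
                probe_betas=inputs.probe_betas,
                prior_list=inputs.prior_list,
                anchor_gene=config.anchor_gene,
                quantile=config.quantile,
                alpha=config.alpha,
                down_fc=config.down_fc,
                probe_window=config.probe_window,
                strict_cascade=config.strict_cascade,
            )
            results["panel"] = panel
            results["provenance"] = provenance
            manifest.row_counts["panel_final_tier"] = int(
                (panel["tier"] == panel["tier"].max()).sum()
                if len(panel) else 0
            )
            done.add("integrate")

    panel_genes: list[str] = []
    panel_probes: list[str] = []
    if "panel" in results and len(results["panel"]):
        full = len([c for c in results["panel"].columns
                    if c in _cascade.CASCADE_ORDER])
        final = results["panel"][results["panel"]["tier"] == full]
        panel_genes = final.index.tolist()
        for probe_csv in final["probe_ids"]:
            panel_probes.extend(p for p in probe_csv.split(",") if p)

    if wants("associate"):
        results["association"] = _run_association_stage(
            panel_genes, panel_probes, inputs
        )
        done.add("associate")

    if wants("classify"):
        results["classification"] = _classify.run_classification_suite(
            panel_genes, inputs.cohort_expr, inputs.probe_betas,
            panel_probes, inputs.clinical,
        )
        done.add("classify")

    if wants("survival"):
        results["survival"] = _run_survival_stage(
            panel_genes, inputs, config, manifest
        )
        done.add("survival")

    if "methylight" in config.stages:
        if inputs.ct_table is None:
            manifest.warnings.append("stage 'methylight' skipped: no Ct table")
        else:
            results["methylight"] = _run_methylight_stage(
                inputs.ct_table, config, manifest
            )
            done.add("methylight")

    return results


def _run_dmr_stage(
    windows: RegionCountSet, genes: list[GeneModel], config: PipelineConfig
) -> dict:
    info = windows.sample_info
    peak_sets = []
    for sample in windows.counts.columns:
        condition = info.loc[sample, "condition"]
        if condition == "input":
            continue
        input_sample = f"input_{condition}"
        if input_sample not in windows.counts.columns:
            raise ValueError(f"no input control for condition {condition!r}")
        peak_sets.append(
            _methylation.call_peaks(
                windows, sample, input_sample,
                p_threshold=config.peak_p_threshold,
                merge_gap_windows=config.merge_gap_windows,
            )
        )
    consensus = _methylation.consensus_regions(peak_sets)
    region_counts = _methylation.aggregate_windows(windows, consensus)
    ko_conditions = sorted(
        set(info["condition"]) - {"parental", "input"}
    )
    tables = {
        line: _methylation.test_differential_methylation(
            region_counts, line, "parental", alpha=config.alpha,
            dispersion=config.dispersion, genes=genes,
        )
        for line in ko_conditions
    }
    tallies = {
        line: _methylation.tally_dmrs(_methylation.dmrs_from_table(t))
        for line, t in tables.items()
    }
    return {"consensus": consensus, "tables": tables, "tallies": tallies}


def _run_de_stage(
    ko_expr: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    lines = _ko_lines(ko_expr.columns)
    if "parental" not in lines:
        raise ValueError("expression matrix lacks parental samples")
    keep = _expression.filter_expressed(
        ko_expr, min_cpm=config.min_cpm,
        min_samples=config.min_expressed_samples,
    )
    filtered = ko_expr.loc[keep]
    return {
        line: _expression.nb_exact_test(
            filtered, samples, lines["parental"], dispersion=config.dispersion
        )
        for line, samples in lines.items()
        if line != "parental"
    }


def _run_association_stage(
    panel_genes: list[str], panel_probes: list[str], inputs: PipelineInputs
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    if panel_genes and inputs.cohort_expr is not None:
        out["expression"] = _stats.run_association(
            inputs.cohort_expr.loc[panel_genes], inputs.clinical, scheme="expr"
        )
    if panel_probes and inputs.probe_betas is not None:
        out["methylation"] = _stats.run_association(
            inputs.probe_betas.loc[panel_probes], inputs.clinical, scheme="meth"
        )
    return out


def _run_survival_stage(
    panel_genes: list[str],
    inputs: PipelineInputs,
    config: PipelineConfig,
    manifest: RunManifest,
) -> dict[str, _survival.CutpointResult]:
    clin = inputs.clinical
    tumors = clin[clin["tissue"] == "tumor"]
    out = {}
    for i, gene in enumerate(panel_genes):
        marker = np.log2(
            inputs.cohort_expr.loc[gene, tumors["sample_id"]].astype(float) + 1
        )
        records = pd.DataFrame(
            {
                "time": tumors["followup_time"].to_numpy(dtype=float),
                "event": tumors["event"].to_numpy(dtype=int),
                "marker": marker.to_numpy(),
            }
        )
        try:
            out[gene] = _survival.xtile_cutpoint(
                records,
                seed=(config.seed * 1009 + i) % (2**31),
                train_fraction=config.train_fraction,
                min_group_fraction=config.min_group_fraction,
            )
        except ValueError as exc:
            manifest.warnings.append(f"survival skipped for {gene}: {exc}")
    return out


def _run_methylight_stage(
    ct_table: pd.DataFrame, config: PipelineConfig, manifest: RunManifest
) -> dict:
    quants = _methylight.quantify_ddct(ct_table)
    retained, exclusions = _methylight.qc_filter(
        quants, alu_ct_max=config.alu_ct_max
    )
    out: dict = {
        "quants": pd.DataFrame(
            [
                {
                    "sample_id": q.sample_id,
                    "gene": q.gene,
                    "value": q.value,
                    "qc_pass": q.qc_pass,
                    "flags": ";".join(q.flags),
                }
                for q in quants
            ]
        ),
        "exclusions": exclusions,
    }
    try:
        test, pairs = _methylight.paired_comparison(retained)
        out["paired_test"] = test
        out["pairs"] = pairs
        manifest.row_counts["methylight_effective_pairs"] = test.n_effective
    except ValueError as exc:
        manifest.warnings.append(f"methylight paired test skipped: {exc}")
    return out
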