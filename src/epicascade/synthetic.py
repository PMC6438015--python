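"""Synthetic inputs for every pipeline stage, with planted driver genes.

The generator emulates the data regimes the analysis assumes: a knockout
experiment (capture-seq window counts and RNA counts, two KO lines plus a
parental line, replicated), a tumor cohort with a continuous TET2-expression
gradient whose deficit drives both downregulation and promoter
hypermethylation of the planted drivers, probe beta values concordant with
those effects, recurrence/survival outcomes tied to driver expression, and
a MethyLight qPCR plate.  One gene id ("TET2") is reserved as the cohort
anchor and is never itself a planted driver.

All randomness flows through the config seed; every public generator
re-derives its own child stream, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, promoter_of
from .methylation import RegionCountSet

ANCHOR_GENE = "TET2"

# genome layout constants (bp)
GENE_SPACING = 10_000
GENE_SPAN = 2_000
WINDOW_WIDTH = 200


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Effect sizes: planted drivers have their expression mean multiplied by
    ``driver_expr_fc`` and their promoter methylation counts by
    ``driver_meth_fc`` in knockout samples.  In the cohort, the same drivers
    are downregulated and probe-hypermethylated in proportion to each
    tumor's TET2 deficit.
    """

    seed: int = 0
    n_genes: int = 500
    n_planted_drivers: int = 20
    ko_replicates: int = 2
    cohort_n_tumor: int = 200
    cohort_n_normal: int = 40
    expr_baseline_logmean: float = 5.5
    expr_baseline_logsd: float = 1.0
    nb_dispersion: float = 0.1
    driver_expr_fc: float = 0.5
    driver_meth_fc: float = 3.0
    probe_beta_normal: float = 0.2
    probe_beta_tumor: float = 0.6
    censor_rate: float = 0.5
    hazard_ratio_marker: float = 3.0
    # cohort gradient steepness: at full TET2 deficit the driver fold change
    # is driver_expr_fc ** cohort_effect_steepness
    cohort_effect_steepness: float = 2.0
    probe_logit_sd: float = 0.4
    library_factor_logsd: float = 0.1
    input_window_rate: float = 10.0
    methylated_enrichment: float = 6.0
    driver_parental_enrichment: float = 3.0
    prior_extra_fraction: float = 0.1
    # MethyLight plate
    methylight_pairs: int = 19
    methylight_meth_fc: float = 4.0
    methylight_noise_sd: float = 0.15
    methylight_slope: float = 1.0
    methylight_replicates: int = 2
    methylight_force_alu_fail: int = 1

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_planted_drivers", "ko_replicates",
                     "cohort_n_tumor", "cohort_n_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_drivers >= self.n_genes:
            raise ValueError("n_planted_drivers must be < n_genes "
                             "(one gene is reserved for the anchor)")
        if not (0 < self.driver_expr_fc <= 1):
            raise ValueError("driver_expr_fc must be in (0, 1]")
        if self.driver_meth_fc < 1:
            raise ValueError("driver_meth_fc must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("probe_beta_normal", "probe_beta_tumor", "censor_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: which genes are drivers, what was planted."""

    driver_gene_ids: set[str]
    effects: pd.DataFrame  # per driver: expr_fc, meth_fc, beta_shift
    anchor_gene: str = ANCHOR_GENE
    gene_ids: list[str] = field(default_factory=list)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _gene_models(config: SimulationConfig) -> list[GeneModel]:
    genes = []
    for i in range(config.n_genes):
        gene_id = ANCHOR_GENE if i == 0 else f"G{i:04d}"
        start = 5_000 + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gene_id, "chr1", start, start + GENE_SPAN, strand))
    return genes


def _nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with var = mu + phi mu^2 (Poisson when phi == 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))


def simulate_ko_experiment(
    config: SimulationConfig,
) -> tuple[RegionCountSet, pd.DataFrame, list[GeneModel], SyntheticTruth]:
    """Knockout-vs-parental methylation windows and expression counts.

    Returns (window counts, gene expression counts, gene models, truth).
    Windows tile every gene promoter at 200 bp resolution plus one distal
    background window per gene.  Half of all promoters are methylated at
    baseline; drivers are methylated at a moderate parental level and gain
    ``driver_meth_fc``-fold counts in both KO lines.  Driver expression is
    multiplied by ``driver_expr_fc`` in both KO lines; the anchor gene is
    knocked out (strong expression loss without methylation gain).
    """
    rng = _rng(config, 1)
    genes = _gene_models(config)
    gene_ids = [g.gene_id for g in genes]
    driver_idx = rng.choice(
        np.arange(1, config.n_genes), size=config.n_planted_drivers, replace=False
    )
    drivers = {gene_ids[i] for i in driver_idx}
    methylated = rng.random(config.n_genes) < 0.5

    # --- methylation windows ---
    regions: list[GenomicInterval] = []
    enrich_parental: list[float] = []
    enrich_ko: list[float] = []
    for i, gene in enumerate(genes):
        promoter = promoter_of(gene)
        is_driver = gene.gene_id in drivers
        if is_driver:
            base = config.driver_parental_enrichment
            ko = base * config.driver_meth_fc
        elif methylated[i]:
            base = ko = config.methylated_enrichment
        else:
            base = ko = 1.0
        n_win = (promoter.end - promoter.start) // WINDOW_WIDTH
        for w in range(n_win):
            s = promoter.start + w * WINDOW_WIDTH
            regions.append(GenomicInterval("chr1", s, s + WINDOW_WIDTH))
            enrich_parental.append(base)
            enrich_ko.append(ko)
        # distal background window between genes
        bg = gene.span_end + 3_000
        regions.append(GenomicInterval("chr1", bg, bg + WINDOW_WIDTH))
        enrich_parental.append(1.0)
        enrich_ko.append(1.0)

    enrich_parental = np.asarray(enrich_parental)
    enrich_ko = np.asarray(enrich_ko)
    rate = config.input_window_rate
    columns: dict[str, np.ndarray] = {}
    info_rows = []
    for line in ("parental", "KO1", "KO2"):
        enrich = enrich_parental if line == "parental" else enrich_ko
        for rep in range(1, config.ko_replicates + 1):
            lib = np.exp(rng.normal(0.0, config.library_factor_logsd))
            name = f"{line}_rep{rep}"
            columns[name] = _nb(rng, rate * enrich * lib, config.nb_dispersion)
            info_rows.append({"sample": name, "condition": line, "replicate": rep})
        lib = np.exp(rng.normal(0.0, config.library_factor_logsd))
        name = f"input_{line}"
        columns[name] = _nb(rng, rate * lib * np.ones(len(regions)),
                            config.nb_dispersion)
        info_rows.append({"sample": name, "condition": "input", "replicate": 1})
    meth = RegionCountSet(
        regions=regions,
        counts=pd.DataFrame(columns, index=[f"{r.chrom}:{r.start}-{r.end}"
                                            for r in regions]),
        sample_info=pd.DataFrame(info_rows).set_index("sample"),
    )

    # --- expression counts ---
    baseline = np.exp(
        rng.normal(config.expr_baseline_logmean, config.expr_baseline_logsd,
                   config.n_genes)
    )
    expr_cols: dict[str, np.ndarray] = {}
    for line in ("parental", "KO1", "KO2"):
        fc = np.ones(config.n_genes)
        if line != "parental":
            for i in driver_idx:
                fc[i] = config.driver_expr_fc
            fc[0] = 0.1  # the anchor gene itself is knocked out
        for rep in range(1, config.ko_replicates + 1):
            lib = np.exp(rng.normal(0.0, config.library_factor_logsd))
            expr_cols[f"{line}_rep{rep}"] = _nb(
                rng, baseline * fc * lib, config.nb_dispersion
            )
    expr = pd.DataFrame(expr_cols, index=gene_ids)
    expr.index.name = "gene_id"

    effects = pd.DataFrame(
        {
            "expr_fc": config.driver_expr_fc,
            "meth_fc": config.driver_meth_fc,
            "beta_shift": config.probe_beta_tumor - config.probe_beta_normal,
        },
        index=sorted(drivers),
    )
    truth = SyntheticTruth(driver_gene_ids=drivers, effects=effects,
                           gene_ids=gene_ids)
    return meth, expr, genes, truth


def _logit(p: float | np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1 - p))


def simulate_cohort(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tumor/normal cohort: expression, probe manifest, betas, clinical table.

    Tumors carry a uniform TET2-activity gradient; the deficit (1 - activity)
    scales driver downregulation, driver probe hypermethylation, Gleason and
    stage severity.  Event hazard is log-linear in mean driver expression;
    follow-up is exponential with independent exponential censoring tuned to
    the configured censor rate.  Returns (expression, probe manifest, betas,
    clinical).
    """
    if config.cohort_n_tumor < 2 or config.cohort_n_normal < 2:
        raise ValueError("need at least 2 tumors and 2 normals")
    rng = _rng(config, 2)
    genes = _gene_models(config)
    gene_ids = [g.gene_id for g in genes]
    n_t, n_n = config.cohort_n_tumor, config.cohort_n_normal
    tumor_ids = [f"T{i:04d}" for i in range(n_t)]
    normal_ids = [f"N{i:04d}" for i in range(n_n)]

    activity = rng.random(n_t)  # TET2 activity in (0,1); normals are 1
    deficit = 1.0 - activity

    baseline = np.exp(
        rng.normal(config.expr_baseline_logmean, config.expr_baseline_logsd,
                   config.n_genes)
    )
    driver_mask = np.array([g in truth.driver_gene_ids for g in gene_ids])
    anchor_i = gene_ids.index(truth.anchor_gene)

    means = np.tile(baseline[:, None], (1, n_t + n_n)).astype(float)
    log_fc_full = config.cohort_effect_steepness * np.log(config.driver_expr_fc)
    for j, d in enumerate(deficit):
        means[driver_mask, j] *= np.exp(log_fc_full * d)
        means[anchor_i, j] *= 0.1 + 0.9 * activity[j]
    lib = np.exp(rng.normal(0.0, config.library_factor_logsd, n_t + n_n))
    counts = _nb(rng, means * lib[None, :], config.nb_dispersion)
    expr = pd.DataFrame(counts, index=gene_ids, columns=tumor_ids + normal_ids)
    expr.index.name = "gene_id"

    # --- probes: three per driver promoter, one per other promoter ---
    manifest_rows = []
    beta_rows = []
    shift_full = _logit(config.probe_beta_tumor) - _logit(config.probe_beta_normal)
    for gene in genes:
        promoter = promoter_of(gene)
        is_driver = gene.gene_id in truth.driver_gene_ids
        n_probes = 3 if is_driver else 1
        offsets = np.linspace(0.25, 0.75, n_probes)
        for k, frac in enumerate(offsets):
            pos = int(promoter.start + frac * (promoter.end - promoter.start))
            probe_id = f"cg_{gene.gene_id}_{k}"
            manifest_rows.append(
                {"probe_id": probe_id, "chrom": gene.chrom, "pos": pos,
                 "gene_id": gene.gene_id}
            )
            mu_logit = np.full(n_t + n_n, _logit(config.probe_beta_normal))
            if is_driver:
                mu_logit[:n_t] += shift_full * deficit
            betas = 1.0 / (
                1.0 + np.exp(-rng.normal(mu_logit, config.probe_logit_sd))
            )
            beta_rows.append(betas)
    manifest = pd.DataFrame(manifest_rows)
    betas = pd.DataFrame(
        np.vstack(beta_rows),
        index=manifest["probe_id"],
        columns=tumor_ids + normal_ids,
    )

    # --- clinical table ---
    log_expr = np.log2(expr.loc[driver_mask, tumor_ids].to_numpy() + 1.0)
    marker = log_expr.mean(axis=0)
    z = (marker - marker.mean()) / max(marker.std(), 1e-12)
    base_hazard = np.log(2) / 5.0  # median 5 years at the cohort mean
    hazard = base_hazard * config.hazard_ratio_marker ** (-z)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_hazard = base_hazard * config.censor_rate / max(
            1 - config.censor_rate, 1e-9
        )
        censor_time = rng.exponential(1.0 / censor_hazard, n_t)
    else:
        censor_time = np.full(n_t, np.inf)
    event = (event_time <= censor_time).astype(int)
    followup = np.minimum(event_time, censor_time)

    severity = np.clip(deficit + rng.normal(0, 0.15, n_t), 0, None)
    gleason_primary = np.where(severity < 0.55, 3, 4)
    gleason_secondary = np.where(severity < 0.30, 3,
                                 np.where(severity < 0.55, 4,
                                          np.where(severity < 0.75, 3, 4)))
    stage_p = np.clip(0.2 + 0.4 * deficit, 0, 1)
    stage = np.where(rng.random(n_t) < stage_p, "non_confined", "organ_confined")

    clinical_rows = []
    for j, sid in enumerate(tumor_ids):
        clinical_rows.append(
            {
                "sample_id": sid,
                "tissue": "tumor",
                "matched_pair_id": f"P{j:04d}" if j < n_n else None,
                "gleason_primary": int(gleason_primary[j]),
                "gleason_secondary": int(gleason_secondary[j]),
                "stage_group": stage[j],
                "recurrence": "yes" if event[j] else "no",
                "followup_time": float(followup[j]),
                "event": int(event[j]),
            }
        )
    for j, sid in enumerate(normal_ids):
        clinical_rows.append(
            {
                "sample_id": sid,
                "tissue": "normal",
                "matched_pair_id": f"P{j:04d}",
                "gleason_primary": None,
                "gleason_secondary": None,
                "stage_group": None,
                "recurrence": "unknown",
                "followup_time": 0.0,
                "event": 0,
            }
        )
    clinical = pd.DataFrame(clinical_rows)
    return expr, manifest, betas, clinical


def simulate_prior_list(config: SimulationConfig, truth: SyntheticTruth) -> list[str]:
    """A prior candidate-gene list: all drivers plus a fraction of others.

    Emulates an externally supplied list from an earlier study that the
    cascade intersects with; drivers are always on it, plus
    ``prior_extra_fraction`` of non-driver genes.
    """
    rng = _rng(config, 3)
    others = [g for g in truth.gene_ids
              if g not in truth.driver_gene_ids and g != truth.anchor_gene]
    n_extra = int(round(config.prior_extra_fraction * len(others)))
    extras = list(rng.choice(others, size=n_extra, replace=False))
    return sorted(truth.driver_gene_ids) + sorted(extras)


def simulate_methylight_plate(config: SimulationConfig) -> pd.DataFrame:
    """MethyLight qPCR Ct table for matched tumor/normal pairs.

    Ct = intercept - slope * log2(template quantity) + Gaussian noise.  The
    gene target's methylated-template quantity is ``methylight_meth_fc``-fold
    higher in tumors than normals; ALU quantity tracks total DNA input and
    the supermethylated control ("M") has quantity 1 for both targets.  The
    first ``methylight_force_alu_fail`` normal samples get ALU Ct forced to
    31, marking them for downstream QC exclusion.
    """
    rng = _rng(config, 4)
    slope = config.methylight_slope
    gene_intercept, alu_intercept = 34.0, 22.0
    rows = []
    q_normal, q_tumor = 0.1, 0.1 * config.methylight_meth_fc

    def emit(sample: str, target: str, quantity: float, dna: float,
             force_ct: float | None = None) -> None:
        intercept = alu_intercept if target == "ALU" else gene_intercept
        for rep in range(1, config.methylight_replicates + 1):
            if force_ct is not None:
                ct = force_ct + rng.normal(0, config.methylight_noise_sd)
                ct = max(ct, 30.5)  # forced failures stay above the QC bar
            else:
                ct = (
                    intercept
                    - slope * np.log2(quantity * dna)
                    + rng.normal(0, config.methylight_noise_sd)
                )
            rows.append({"sample_id": sample, "target": target,
                         "replicate": rep, "ct": float(ct)})

    emit("M", "GENE", 1.0, 1.0)
    emit("M", "ALU", 1.0, 1.0)
    for i in range(1, config.methylight_pairs + 1):
        for tissue, q in (("T", q_tumor), ("N", q_normal)):
            sample = f"P{i:02d}_{tissue}"
            dna = float(np.exp(rng.normal(0, 0.2)))
            emit(sample, "GENE", q, dna)
            force = (
                31.0
                if tissue == "N" and i <= config.methylight_force_alu_fail
                else None
            )
            emit(sample, "ALU", 1.0, dna, force_ct=force)
    return pd.DataFrame(rows)
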