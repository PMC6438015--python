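"""MethyLight methylation-specific qPCR quantification.

Relative methylation is quantified by the delta-delta Ct method against an
ALU repeat reference and a supermethylated control sample: replicate Ct
values are averaged on the Ct scale, Delta Ct = Ct_gene - Ct_ALU per sample,
and the reported value is 100 * 2^-(DeltaCt_sample - DeltaCt_control),
i.e. percent of the fully methylated reference (PMR-like).  Samples whose
mean ALU Ct exceeds 30 cycles fail QC (insufficient amplifiable input) and
are excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import WilcoxonResult, wilcoxon_signed_rank_paired

ALU_CT_MAX = 30.0


@dataclass
class MethylationQuant:
    sample_id: str
    gene: str
    value: float  # percent of supermethylated reference
    qc_pass: bool
    exclusion_reason: str | None = None
    flags: tuple[str, ...] = ()
    alu_ct: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("quantification cannot be negative")
        if not self.qc_pass and self.exclusion_reason is None:
            raise ValueError("excluded samples must carry a reason")


def _mean_ct(ct_table: pd.DataFrame, sample: str, target: str) -> float | None:
    sub = ct_table[(ct_table["sample_id"] == sample)
                   & (ct_table["target"] == target)]
    cts = sub["ct"].dropna()
    return float(cts.mean()) if len(cts) else None


def quantify_ddct(
    ct_table: pd.DataFrame,
    control_sample: str = "M",
    gene_target: str = "GENE",
    alu_target: str = "ALU",
) -> list[MethylationQuant]:
    """Delta-delta Ct quantification of every sample against the control.

    Replicates average on the Ct scale before differencing.  Missing gene
    amplification yields value 0 with a flag; missing ALU amplification is
    a QC failure.  Values above 100% are permitted but flagged.
    """
    ctrl_gene = _mean_ct(ct_table, control_sample, gene_target)
    ctrl_alu = _mean_ct(ct_table, control_sample, alu_target)
    if ctrl_gene is None or ctrl_alu is None:
        raise ValueError("supermethylated control lacks gene or ALU Ct")
    dct_control = ctrl_gene - ctrl_alu
    quants = []
    for sample in ct_table["sample_id"].unique():
        if sample == control_sample:
            continue
        gene_ct = _mean_ct(ct_table, sample, gene_target)
        alu_ct = _mean_ct(ct_table, sample, alu_target)
        if alu_ct is None:
            quants.append(
                MethylationQuant(sample, gene_target, 0.0, qc_pass=False,
                                 exclusion_reason="no ALU amplification")
            )
            continue
        if gene_ct is None:
            quants.append(
                MethylationQuant(sample, gene_target, 0.0, qc_pass=True,
                                 flags=("no_gene_amplification",),
                                 alu_ct=alu_ct)
            )
            continue
        ddct = (gene_ct - alu_ct) - dct_control
        value = 100.0 * 2.0 ** (-ddct)
        flags = ("above_reference",) if value > 100.0 else ()
        quants.append(
            MethylationQuant(sample, gene_target, float(value), qc_pass=True,
                             flags=flags, alu_ct=alu_ct)
        )
    return quants


def qc_filter(
    quants: list[MethylationQuant], alu_ct_max: float = ALU_CT_MAX
) -> tuple[list[MethylationQuant], pd.DataFrame]:
    """Exclude samples whose mean ALU Ct exceeds ``alu_ct_max`` (strictly).

    Returns (retained quants, exclusion log).  A mean ALU Ct of exactly the
    limit is retained — the rule reads "exceeding".
    """
    retained, log_rows = [], []
    for q in quants:
        if not q.qc_pass:
            log_rows.append({"sample_id": q.sample_id,
                             "reason": q.exclusion_reason, "alu_ct": q.alu_ct})
            continue
        if q.alu_ct is not None and q.alu_ct > alu_ct_max:
            log_rows.append(
                {"sample_id": q.sample_id,
                 "reason": f"ALU Ct {q.alu_ct:.2f} > {alu_ct_max:g}",
                 "alu_ct": q.alu_ct}
            )
            continue
        retained.append(q)
    return retained, pd.DataFrame(log_rows, columns=["sample_id", "reason",
                                                     "alu_ct"])


def _pair_key(sample_id: str) -> tuple[str, str]:
    """Split ids like 'P07_T' into (patient, tissue)."""
    if "_" not in sample_id:
        raise ValueError(f"sample id {sample_id!r} lacks a patient_tissue form")
    patient, tissue = sample_id.rsplit("_", 1)
    return patient, tissue


def paired_comparison(
    quants: list[MethylationQuant],
) -> tuple[WilcoxonResult, pd.DataFrame]:
    """Paired Wilcoxon signed-rank test of tumor vs normal quantifications.

    Pairs by patient id; a pair contributes only if both members survived
    QC.  Returns the test result (two-sided, continuity-corrected) and the
    paired value table actually tested.
    """
    by_patient: dict[str, dict[str, float]] = {}
    for q in quants:
        patient, tissue = _pair_key(q.sample_id)
        by_patient.setdefault(patient, {})[tissue] = q.value
    rows = [
        {"patient": p, "tumor": v["T"], "normal": v["N"]}
        for p, v in sorted(by_patient.items())
        if "T" in v and "N" in v
    ]
    pairs = pd.DataFrame(rows, columns=["patient", "tumor", "normal"])
    if len(pairs) < 3:
        raise ValueError("fewer than 3 complete pairs after QC")
    result = wilcoxon_signed_rank_paired(pairs["tumor"], pairs["normal"])
    return result, pairs
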