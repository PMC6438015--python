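"""Peak calling, consensus merging, differential methylation, DMR tallies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epicascade.genome import GeneModel, GenomicInterval
from epicascade.methylation import (DMRecord, RegionCountSet, call_peaks,
                                    consensus_regions, dmrs_from_table,
                                    tally_dmrs)
from epicascade.methylation import test_differential_methylation as diff_meth


def window_set(treat_counts, input_counts, width=200):
    regions = [
        GenomicInterval("chr1", i * width, (i + 1) * width)
        for i in range(len(treat_counts))
    ]
    counts = pd.DataFrame(
        {"treat": treat_counts, "input": input_counts},
        index=[f"{r.chrom}:{r.start}-{r.end}" for r in regions],
    )
    info = pd.DataFrame(
        {"condition": ["KO1", "input"], "replicate": [1, 1]},
        index=pd.Index(["treat", "input"], name="sample"),
    )
    return RegionCountSet(regions=regions, counts=counts, sample_info=info)


class TestCallPeaks:
    def test_poisson_tail_oracle(self):
        """Window with count 20 over scaled expectation 5: p is the direct
        Poisson upper-tail sum at lambda 5.5."""
        n = 200
        treat = np.full(n, 5)
        treat[7] = 20
        ws = window_set(treat, np.full(n, 5))
        # equal library depths: scaled input expectation is the input count
        lam = 5.0 + 0.5
        p_oracle = sum(
            sps.poisson.pmf(k, lam) for k in range(20, 200)
        )
        assert p_oracle == pytest.approx(float(sps.poisson.sf(19, lam)))
        peaks = call_peaks(ws, "treat", "input", p_threshold=1e-5)
        if p_oracle < 1e-5:
            assert peaks == [GenomicInterval("chr1", 1400, 1600)]
        else:  # pragma: no cover - fixture chosen to be significant
            assert peaks == []

    def test_treatment_equal_to_input_no_peaks(self):
        ws = window_set(np.full(100, 10), np.full(100, 10))
        assert call_peaks(ws, "treat", "input") == []

    def test_merge_across_single_gap_window(self):
        treat = np.full(60, 10)
        treat[20] = treat[22] = 200  # separated by one non-significant window
        treat[40] = 200
        ws = window_set(treat, np.full(60, 10))
        peaks = call_peaks(ws, "treat", "input", merge_gap_windows=1)
        assert GenomicInterval("chr1", 20 * 200, 23 * 200) in peaks
        assert GenomicInterval("chr1", 40 * 200, 41 * 200) in peaks

    def test_no_merge_across_two_gap_windows(self):
        treat = np.full(60, 10)
        treat[20] = treat[23] = 200
        ws = window_set(treat, np.full(60, 10))
        peaks = call_peaks(ws, "treat", "input", merge_gap_windows=1)
        assert len(peaks) == 2

    def test_output_sorted_non_overlapping(self):
        rng = np.random.default_rng(0)
        treat = rng.poisson(10, 500)
        treat[rng.choice(500, 40, replace=False)] = 300
        ws = window_set(treat, np.full(500, 10))
        peaks = call_peaks(ws, "treat", "input")
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start


class TestConsensus:
    def test_union_merge(self):
        sets = [[GenomicInterval("chr1", 0, 100)],
                [GenomicInterval("chr1", 50, 150)]]
        assert consensus_regions(sets) == [GenomicInterval("chr1", 0, 150)]

    def test_empty_set_ignored(self):
        sets = [[], [GenomicInterval("chr1", 0, 100)]]
        assert consensus_regions(sets) == [GenomicInterval("chr1", 0, 100)]

    def test_disjoint_sorted(self):
        sets = [[GenomicInterval("chr1", 500, 600)],
                [GenomicInterval("chr1", 0, 100)]]
        assert consensus_regions(sets) == [
            GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)
        ]


def region_count_set(ko, par, starts=None, width=1_000, equal_depth=False):
    """Region-level count set; ``equal_depth`` emulates full libraries
    dominated by unchanged background (depth identical across samples)."""
    n = len(ko[0])
    starts = starts or [i * 10_000 for i in range(n)]
    regions = [GenomicInterval("chr1", s, s + width) for s in starts]
    data = {}
    info_rows = []
    for rep, col in enumerate(ko, 1):
        data[f"KO1_rep{rep}"] = col
        info_rows.append({"sample": f"KO1_rep{rep}", "condition": "KO1",
                          "replicate": rep})
    for rep, col in enumerate(par, 1):
        data[f"parental_rep{rep}"] = col
        info_rows.append({"sample": f"parental_rep{rep}",
                          "condition": "parental", "replicate": rep})
    counts = pd.DataFrame(data, index=[f"r{i}" for i in range(n)])
    libs = (
        pd.Series(1.0, index=counts.columns) if equal_depth else None
    )
    return RegionCountSet(
        regions=regions, counts=counts,
        sample_info=pd.DataFrame(info_rows).set_index("sample"),
        library_sizes=libs,
    )


class TestDifferentialMethylation:
    def test_identical_counts_not_significant(self):
        rcs = region_count_set([[100, 50]] * 2, [[100, 50]] * 2)
        table = diff_meth(rcs, "KO1", "parental")
        assert (table["p_value"] > 0.9).all()
        assert not table["significant"].any()

    def test_condition_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(4)
        ko = [list(rng.poisson(300, 30)) for _ in range(2)]
        par = [list(rng.poisson(150, 30)) for _ in range(2)]
        fwd = diff_meth(
            region_count_set(ko, par), "KO1", "parental", dispersion=0.05
        )
        swapped = region_count_set(par, ko)
        rev = diff_meth(swapped, "KO1", "parental",
                                            dispersion=0.05)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-9)
        changed = fwd["log2_fold_change"].abs() > 1e-6
        assert (
            fwd.loc[changed, "direction"].to_numpy()
            != rev.loc[changed, "direction"].to_numpy()
        ).all()

    def test_absent_condition_rejected(self):
        rcs = region_count_set([[10]], [[10]])
        with pytest.raises(ValueError, match="condition"):
            diff_meth(rcs, "KO9", "parental")

    def test_planted_gain_power(self):
        """3-fold promoter gain at n=2/condition is detected nearly always."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 60
        r = 1 / 0.02  # region-level dispersion after summing windows
        for _ in range(n_sim):
            ko = [list(rng.negative_binomial(r, r / (r + 900), 5)) for _ in range(2)]
            par = [list(rng.negative_binomial(r, r / (r + 300), 5)) for _ in range(2)]
            table = diff_meth(
                region_count_set(ko, par, equal_depth=True), "KO1", "parental"
            )
            hits += int(
                (table["significant"] & (table["direction"] == "gain")).sum()
            )
        assert hits / (n_sim * 5) >= 0.95


class TestTally:
    def make(self, direction, feature, start=0):
        lfc = 1.0 if direction == "gain" else -1.0
        return DMRecord(GenomicInterval("chr1", start, start + 100), lfc, 0.01,
                        direction, feature=feature, gene_id="g")

    def test_empty(self):
        table = tally_dmrs([])
        assert (table.to_numpy() == 0).all()

    def test_additivity(self):
        dmrs = (
            [self.make("gain", "promoter", i * 1000) for i in range(3)]
            + [self.make("gain", "gene_body", 10_000 + i * 1000) for i in range(2)]
            + [self.make("gain", "intergenic", 20_000)]
            + [self.make("loss", "promoter", 30_000)]
        )
        table = tally_dmrs(dmrs)
        assert table.loc["gain", "overall"] == 6
        assert table.loc["gain", "promoter"] == 3
        assert table.loc["loss", "overall"] == 1
        # partition: overall equals the sum of the feature classes
        for direction in ("gain", "loss"):
            assert table.loc[direction, "overall"] == (
                table.loc[direction, ["promoter", "gene_body", "intergenic"]].sum()
            )

    def test_unclassified_needs_gene_table(self):
        dmr = DMRecord(GenomicInterval("chr1", 0, 100), 1.0, 0.01, "gain")
        with pytest.raises(ValueError):
            tally_dmrs([dmr])
        genes = [GeneModel("A", "chr1", 500, 1_500, "+")]
        table = tally_dmrs([dmr], genes)
        assert table.loc["gain", "overall"] == 1


def test_dmr_direction_consistency_enforced():
    with pytest.raises(ValueError):
        DMRecord(GenomicInterval("chr1", 0, 100), -2.0, 0.01, "gain")


def test_dmrs_from_table_roundtrip(ko_experiment):
    meth, _, genes, _ = ko_experiment
    from epicascade.pipeline import PipelineConfig, PipelineInputs, run_pipeline

    res = run_pipeline(
        PipelineInputs(meth_windows=meth, genes=genes),
        PipelineConfig(stages=("dmr",)),
    )
    table = res["dmr"]["tables"]["KO1"]
    records = dmrs_from_table(table)
    assert len(records) == int(table["significant"].sum())
    for rec in records[:5]:
        assert rec.direction in ("gain", "loss")
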