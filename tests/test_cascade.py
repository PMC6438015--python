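"""The candidate cascade: subset rule, concordance screen, panel assembly."""

import numpy as np
import pandas as pd
import pytest

from epicascade.cascade import (assemble_panel, cohort_expression_concordance,
                                select_low_anchor_subset)
from epicascade.pipeline import PipelineConfig, PipelineInputs, run_pipeline


def make_cohort(n_tumors, n_normals, anchor_values=None, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"T{i}" for i in range(n_tumors)] + [
        f"N{i}" for i in range(n_normals)
    ]
    expr = pd.DataFrame(
        rng.poisson(100, size=(3, len(samples))),
        index=["TET2", "g1", "g2"],
        columns=samples,
    )
    if anchor_values is not None:
        expr.loc["TET2", samples[:n_tumors]] = anchor_values
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": ["tumor"] * n_tumors + ["normal"] * n_normals,
            "matched_pair_id": [None] * len(samples),
        }
    )
    return expr, clinical


class TestLowAnchorSubset:
    def test_published_cohort_arithmetic(self):
        """A 423-tumor cohort yields a 43-sample bottom-decile subset."""
        expr, clinical = make_cohort(423, 35)
        subset = select_low_anchor_subset(expr, clinical)
        assert len(subset) == 43

    def test_quantile_one_returns_all(self):
        expr, clinical = make_cohort(30, 5)
        assert len(select_low_anchor_subset(expr, clinical, quantile=1.0)) == 30

    def test_ceiling_rule_small_cohort(self):
        expr, clinical = make_cohort(10, 5)
        assert len(select_low_anchor_subset(expr, clinical, quantile=0.10)) == 1

    def test_lowest_values_selected(self):
        expr, clinical = make_cohort(10, 2, anchor_values=np.arange(10) * 10)
        subset = select_low_anchor_subset(expr, clinical, quantile=0.3)
        assert subset == ["T0", "T1", "T2"]

    def test_boundary_ties_resolved_by_sample_id(self):
        expr, clinical = make_cohort(10, 2, anchor_values=np.zeros(10))
        subset = select_low_anchor_subset(expr, clinical, quantile=0.2)
        assert subset == ["T0", "T1"]

    def test_missing_anchor_rejected(self):
        expr, clinical = make_cohort(10, 2)
        with pytest.raises(ValueError, match="anchor"):
            select_low_anchor_subset(expr.drop(index="TET2"), clinical)


class TestConcordance:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.subset = [f"T{i}" for i in range(20)]
        self.normals = [f"N{i}" for i in range(20)]
        cols = self.subset + self.normals
        self.expr = pd.DataFrame(
            {
                # strongly down in tumors
                "down": np.r_[rng.poisson(20, 20), rng.poisson(200, 20)],
                # strongly UP in tumors: must be excluded by the direction gate
                "up": np.r_[rng.poisson(200, 20), rng.poisson(20, 20)],
                # null
                "flat": rng.poisson(100, 40),
            },
            index=cols,
        ).T

    def test_direction_gate_excludes_up_genes(self):
        table = cohort_expression_concordance(
            ["down", "up", "flat"], self.expr, self.subset, self.normals
        )
        assert bool(table.loc["down", "passes"])
        assert not bool(table.loc["up", "passes"])
        assert table.loc["up", "p_value"] < 1e-6  # significant but wrong way
        assert not bool(table.loc["flat", "passes"])

    def test_threshold_derived_from_test_count(self):
        table = cohort_expression_concordance(
            ["down", "up", "flat"], self.expr, self.subset, self.normals
        )
        assert table.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 3)
        one = cohort_expression_concordance(
            ["down"], self.expr, self.subset, self.normals
        )
        assert one.attrs["bonferroni_threshold"] == pytest.approx(0.05)

    def test_empty_input_empty_output(self):
        table = cohort_expression_concordance(
            [], self.expr, self.subset, self.normals
        )
        assert len(table) == 0


@pytest.fixture(scope="module")
def pipeline_results(ko_experiment, cohort, prior_list):
    meth, expr, genes, truth = ko_experiment
    cexpr, manifest, betas, clinical = cohort
    inputs = PipelineInputs(
        meth_windows=meth, ko_expr=expr, genes=genes, cohort_expr=cexpr,
        probe_manifest=manifest, probe_betas=betas, clinical=clinical,
        prior_list=prior_list,
    )
    res = run_pipeline(inputs, PipelineConfig(seed=11,
                                              stages=("dmr", "de", "integrate")))
    return res, truth, inputs


class TestPanel:
    def test_tier_counts_monotone(self, pipeline_results):
        res, _, _ = pipeline_results
        counts = list(res["provenance"]["tier_counts"].values())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_drivers_dominate_final_tier(self, pipeline_results):
        res, truth, _ = pipeline_results
        panel = res["panel"]
        flags = [c for c in panel.columns if panel[c].dtype == bool]
        final = set(panel.index[panel["tier"] == len(flags)])
        assert final  # the cascade finds something
        fdp = len(final - truth.driver_gene_ids) / len(final)
        assert fdp <= 0.1

    def test_prior_list_stage_independent(self, pipeline_results):
        res, _, inputs = pipeline_results
        no_prior = PipelineInputs(**{**inputs.__dict__, "prior_list": None})
        res2 = run_pipeline(
            no_prior, PipelineConfig(seed=11, stages=("dmr", "de", "integrate"))
        )
        panel_with = res["panel"]
        panel_without = res2["panel"]
        assert "prior_list_member" not in panel_without.columns
        shared = [c for c in panel_without.columns
                  if panel_without[c].dtype == bool]
        for col in shared:
            pd.testing.assert_series_equal(panel_with[col], panel_without[col])

    def test_deterministic(self, pipeline_results):
        res, _, inputs = pipeline_results
        res2 = run_pipeline(
            inputs, PipelineConfig(seed=11, stages=("dmr", "de", "integrate"))
        )
        pd.testing.assert_frame_equal(res["panel"], res2["panel"])

    def test_strict_cascade_masks_downstream_flags(self, pipeline_results):
        _, _, inputs = pipeline_results
        res = run_pipeline(
            inputs,
            PipelineConfig(seed=11, stages=("dmr", "de", "integrate"),
                           strict_cascade=True),
        )
        panel = res["panel"]
        flags = [c for c in panel.columns if panel[c].dtype == bool]
        arr = panel[flags].to_numpy()
        # in strict mode a True flag requires every upstream flag True
        for row in arr:
            seen_false = False
            for v in row:
                if seen_false:
                    assert not v
                if not v:
                    seen_false = True

    def test_provenance_records_thresholds(self, pipeline_results):
        res, _, _ = pipeline_results
        prov = res["provenance"]
        assert prov["expr_bonferroni"]["threshold"] == pytest.approx(
            0.05 / prov["expr_bonferroni"]["m"]
        )
        assert prov["subset_size"] == 20  # ceil(0.1 * 200)


def test_empty_ko_evidence_gives_empty_panel():
    expr, clinical = make_cohort(20, 5)
    empty_de = pd.DataFrame(columns=["fold_change", "p_value"], dtype=float)
    empty_dmr = pd.DataFrame(
        columns=["chrom", "start", "end", "significant", "direction",
                 "feature", "gene_id"]
    )
    manifest = pd.DataFrame({"probe_id": [], "chrom": [], "pos": []})
    betas = pd.DataFrame(index=pd.Index([], name="probe_id"))
    panel, prov = assemble_panel(
        ko_de={"KO1": empty_de},
        ko_dmr={"KO1": empty_dmr},
        expr=expr,
        clinical=clinical,
        probe_manifest=manifest,
        probe_betas=betas,
    )
    assert len(panel) == 0
    assert all(v == 0 for v in prov["tier_counts"].values())


def test_universe_mismatch_reported():
    expr, clinical = make_cohort(20, 5)
    de = pd.DataFrame(
        {"fold_change": [0.5], "p_value": [0.001]}, index=["NOT_IN_COHORT"]
    )
    dmr = pd.DataFrame(
        columns=["chrom", "start", "end", "significant", "direction",
                 "feature", "gene_id"]
    )
    with pytest.raises(ValueError, match="NOT_IN_COHORT"):
        assemble_panel(
            ko_de={"KO1": de}, ko_dmr={"KO1": dmr}, expr=expr,
            clinical=clinical,
            probe_manifest=pd.DataFrame({"probe_id": [], "chrom": [],
                                         "pos": []}),
            probe_betas=pd.DataFrame(),
        )
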