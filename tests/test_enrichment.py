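"""Organ-enrichment calling, normalization, QC and protein-set assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organclocks import (
    ExpressionMatrix,
    build_protein_sets,
    call_enriched_genes,
    collapse_to_organs,
    normalize_expression,
    qc_filter_panel,
)
from organclocks.enrichment import ProteinSetCatalog, check_organ_map


def _expr(values: dict, mapping: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values), mapping)


class TestNormalize:
    def test_doubled_library_size_yields_proportional_size_factors(self):
        # sample2 = 2 x sample1 for every gene: median-of-ratios gives size
        # factors (1, 2) up to a common scale, so normalized columns agree
        g1 = np.array([10.0, 20.0, 5.0, 80.0])
        em = _expr({"s1": g1, "s2": 2 * g1}, {"s1": "liver", "s2": "liver"})
        out = normalize_expression(em)
        np.testing.assert_allclose(out.values["s1"], out.values["s2"], rtol=1e-12)
        # closed form: geometric mean = g*sqrt(2); ratios are 1/sqrt2, sqrt2
        np.testing.assert_allclose(
            out.values["s1"].to_numpy(), g1 * np.sqrt(2), rtol=1e-12
        )

    def test_single_sample_returned_unchanged(self):
        em = _expr({"s1": [1.0, 2.0]}, {"s1": "liver"})
        out = normalize_expression(em)
        np.testing.assert_array_equal(out.values, em.values)

    def test_gene_with_zero_is_excluded_from_reference_but_still_normalized(self):
        em = _expr(
            {"s1": [10.0, 0.0, 30.0], "s2": [10.0, 6.0, 30.0]},
            {"s1": "liver", "s2": "liver"},
        )
        out = normalize_expression(em)
        assert out.values.shape == em.values.shape
        # both samples identical on reference genes -> size factors equal
        np.testing.assert_allclose(out.values.iloc[0], [10.0, 10.0])
        assert out.values.iloc[1, 1] > 0

    def test_all_genes_zero_somewhere_raises(self):
        em = _expr(
            {"s1": [0.0, 5.0], "s2": [4.0, 0.0]}, {"s1": "liver", "s2": "liver"}
        )
        with pytest.raises(ValueError, match="geometric mean"):
            normalize_expression(em)

    def test_matches_deseq2_median_of_ratios_oracle(self):
        # independent implementation: pydeseq2's size factors
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(30, 4)).astype(float) + 1
        em = ExpressionMatrix(
            pd.DataFrame(counts, columns=[f"s{i}" for i in range(4)],
                         index=[f"g{i}" for i in range(30)]),
            {f"s{i}": "liver" for i in range(4)},
        )
        ours = normalize_expression(em).values.to_numpy()
        theirs, _ = deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(ours, np.asarray(theirs).T, rtol=1e-10)


class TestCollapse:
    MAP = {"brain": ("cortex", "cerebellum"), "immune": ("blood", "spleen")}

    def test_organ_value_is_max_over_subtissues(self):
        em = _expr(
            {"a": [10.0], "b": [30.0], "c": [5.0], "d": [8.0]},
            {"a": "cortex", "b": "cerebellum", "c": "blood", "d": "spleen"},
        )
        out = collapse_to_organs(em, self.MAP)
        assert out.loc[0, "brain"] == 30.0
        assert out.loc[0, "immune"] == 8.0  # max(blood, spleen)

    def test_tissue_summary_is_median_across_samples(self):
        em = _expr(
            {"a1": [1.0], "a2": [9.0], "a3": [2.0], "b": [0.0], "c": [0.0], "d": [0.0]},
            {"a1": "cortex", "a2": "cortex", "a3": "cortex",
             "b": "cerebellum", "c": "blood", "d": "spleen"},
        )
        out = collapse_to_organs(em, self.MAP)
        assert out.loc[0, "brain"] == 2.0

    def test_missing_tissue_raises_with_names(self):
        em = _expr({"a": [1.0]}, {"a": "cortex"})
        with pytest.raises(ValueError, match="cerebellum"):
            collapse_to_organs(em, self.MAP)

    def test_empty_organ_raises(self):
        with pytest.raises(ValueError, match="no tissues"):
            check_organ_map({"brain": ()})


class TestCallEnriched:
    def _mat(self, rows, organs=("brain", "heart", "liver")):
        return pd.DataFrame(rows, columns=list(organs))

    @pytest.mark.parametrize(
        "row, organ, fold",
        [
            ((100.0, 20.0, 10.0), "brain", 5.0),
            ((80.0, 20.0, 1.0), "brain", 4.0),  # "at least four times" inclusive
            ((79.0, 20.0, 1.0), None, 79 / 20),
            ((50.0, 50.0, 1.0), None, 1.0),  # tie: no dominating organ
            ((10.0, 0.0, 0.0), "brain", np.inf),
        ],
    )
    def test_fold_rule(self, row, organ, fold):
        out = call_enriched_genes(self._mat([row]), fold_threshold=4.0, min_expression=1.0)
        assert out["enriched_organ"].iloc[0] == organ
        assert out["fold_change"].iloc[0] == pytest.approx(fold)

    def test_min_expression_floor_suppresses_noise_genes(self):
        out = call_enriched_genes(
            self._mat([(0.5, 0.05, 0.0)]), fold_threshold=4.0, min_expression=1.0
        )
        assert out["enriched_organ"].iloc[0] is None

    def test_single_organ_raises(self):
        with pytest.raises(ValueError, match="2 organs"):
            call_enriched_genes(pd.DataFrame({"brain": [1.0]}))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_enriched_calls_satisfy_threshold_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(
            rng.gamma(2.0, 20.0, size=(15, 4)), columns=list("ABCD")
        )
        out = call_enriched_genes(mat, fold_threshold=4.0, min_expression=1.0)
        called = out[out["enriched_organ"].notna()]
        assert (called["fold_change"] >= 4.0).all()
        # ratio rule: global rescaling cannot change calls
        out2 = call_enriched_genes(mat * 7.3, fold_threshold=4.0, min_expression=1.0 * 7.3)
        pd.testing.assert_series_equal(out["enriched_organ"], out2["enriched_organ"])
        # organ-order permutation invariance
        out3 = call_enriched_genes(mat[list("DBCA")], 4.0, 1.0)
        pd.testing.assert_series_equal(out["enriched_organ"], out3["enriched_organ"])


class TestPanelQC:
    def _panel(self):
        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "gene_symbol": ["g1", "g2", "g3"],
                "cv": [0.05, 0.30, 0.05],
                "cross_version_r": [0.9, 0.9, 0.2],
            }
        )

    def test_qc_rule(self):
        out = qc_filter_panel(self._panel(), max_cv=0.15, min_cross_version_r=0.5)
        assert list(out["qc_pass"]) == [True, False, False]

    def test_infinite_thresholds_pass_everything(self):
        out = qc_filter_panel(self._panel(), max_cv=np.inf, min_cross_version_r=-1.0)
        assert out["qc_pass"].all()

    def test_missing_qc_columns_pass_with_warning(self, caplog):
        panel = self._panel().drop(columns=["cv", "cross_version_r"])
        with caplog.at_level("WARNING"):
            out = qc_filter_panel(panel)
        assert out["qc_pass"].all()
        assert "pass" in caplog.text


class TestProteinSets:
    def test_set_arithmetic(self):
        enrichment = call_enriched_genes(
            pd.DataFrame(
                {"brain": [100, 90, 80, 1, 1, 1, 1, 1, 1, 1],
                 "kidney": [1, 1, 1, 100, 90, 1, 1, 1, 1, 1],
                 "liver": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]},
                index=[f"g{i}" for i in range(10)],
                dtype=float,
            )
        )
        panel = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(10)],
             "gene_symbol": [f"g{i}" for i in range(10)],
             "qc_pass": True}
        )
        cat = build_protein_sets(enrichment, panel, ("brain", "kidney", "liver"))
        assert len(cat.organ_sets["brain"]) == 3
        assert len(cat.organ_sets["kidney"]) == 2
        assert len(cat.organismal_set) == 5
        assert len(cat.conventional_set) == 10

    def test_out_of_scope_enriched_gene_is_not_organismal(self):
        enrichment = call_enriched_genes(
            pd.DataFrame({"brain": [100.0, 1.0], "skin": [1.0, 100.0]},
                         index=["g0", "g1"])
        )
        panel = pd.DataFrame(
            {"probe_id": ["p0", "p1"], "gene_symbol": ["g0", "g1"], "qc_pass": True}
        )
        cat = build_protein_sets(enrichment, panel, ("brain",))
        assert cat.organ_sets["brain"] == {"p0"}
        assert "p1" not in cat.organismal_set  # skin-enriched: organ-specific
        assert "p1" in cat.conventional_set

    def test_catalog_invariants_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            ProteinSetCatalog(
                organ_sets={"a": frozenset("x"), "b": frozenset("x")},
                organismal_set=frozenset(),
                conventional_set=frozenset("x"),
            )

    def test_mutual_exclusivity_and_partition_on_simulated_catalog(self, small_inputs):
        expr, panel, cohort, truth = small_inputs
        from organclocks import DEFAULT_ORGAN_MAP

        organ_expr = collapse_to_organs(
            normalize_expression(expr),
            {o: DEFAULT_ORGAN_MAP[o] for o in ("brain", "kidney")},
        )
        enr = call_enriched_genes(organ_expr)
        cat = build_protein_sets(enr, qc_filter_panel(panel), ("brain", "kidney"))
        union = set().union(*cat.organ_sets.values())
        assert not union & set(cat.organismal_set)
        assert union | set(cat.organismal_set) == set(cat.conventional_set)
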