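import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from wfstox import (
    DrugFeatureSet,
    FeatureFingerprint,
    FeatureMatrix,
    WFSModel,
    build_fingerprint,
    fisher_enrichment_p,
    score_matrix,
    wfs_score,
)

from .oracles import hypergeom_tail_p


def _vectors(k_pos, n_pos, k_neg, n_neg):
    x = np.array([1] * k_pos + [0] * (n_pos - k_pos) + [1] * k_neg + [0] * (n_neg - k_neg), float)
    y = np.array([1] * n_pos + [0] * n_neg)
    return x, y


class TestFisherEnrichment:
    def test_enriched_feature_matches_exact_tail(self):
        # 8/10 ADE-positive vs 2/10 ADE-negative
        x, y = _vectors(8, 10, 2, 10)
        expected = Fraction(2126, 184756)
        assert fisher_enrichment_p(x, y) == pytest.approx(float(expected), abs=1e-12)

    def test_depleted_feature_pinned_to_one(self):
        x, y = _vectors(2, 10, 8, 10)
        assert fisher_enrichment_p(x, y) == 1.0

    def test_equal_frequencies_are_tested_not_pinned(self):
        x, y = _vectors(5, 10, 5, 10)
        p = fisher_enrichment_p(x, y)
        assert p == pytest.approx(float(hypergeom_tail_p(5, 10, 5, 10)), abs=1e-12)
        assert 0.5 <= p < 1.0

    def test_missing_rows_omitted_from_table(self):
        x, y = _vectors(8, 10, 2, 10)
        # masking two feature-present negatives turns the table into 8/10 vs 2/8... 0/8
        x_masked = x.copy()
        x_masked[10] = np.nan
        x_masked[11] = np.nan
        expected = hypergeom_tail_p(8, 10, 0, 8)
        assert fisher_enrichment_p(x_masked, y) == pytest.approx(float(expected), abs=1e-12)

    def test_all_missing_in_one_class_warns_and_returns_one(self):
        x = np.array([np.nan, np.nan, 1.0, 0.0])
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning):
            assert fisher_enrichment_p(x, y) == 1.0

    def test_exhaustive_oracle_agreement_small_tables(self):
        """All 2×2 tables up to n=16: exact-rational tail to 1e-12."""
        for n_pos in range(1, 16):
            for n_neg in range(1, 17 - n_pos):
                for k_pos in range(n_pos + 1):
                    for k_neg in range(n_neg + 1):
                        x, y = _vectors(k_pos, n_pos, k_neg, n_neg)
                        p = fisher_enrichment_p(x, y)
                        if k_pos / n_pos < k_neg / n_neg:
                            assert p == 1.0
                        else:
                            exact = hypergeom_tail_p(k_pos, n_pos, k_neg, n_neg)
                            assert p == pytest.approx(float(exact), abs=1e-12)

    @given(
        n_pos=st.integers(1, 15),
        n_neg=st.integers(1, 15),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_fisher_exact(self, n_pos, n_neg, data):
        """Cross-check against an independent library implementation."""
        k_pos = data.draw(st.integers(0, n_pos))
        k_neg = data.draw(st.integers(0, n_neg))
        x, y = _vectors(k_pos, n_pos, k_neg, n_neg)
        p = fisher_enrichment_p(x, y)
        if k_pos / n_pos >= k_neg / n_neg:
            table = [[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]]
            _, p_ref = fisher_exact(table, alternative="greater")
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestBuildFingerprint:
    def test_key_set_is_features_present_in_a_positive(self):
        data = pd.DataFrame(
            [[1, 0, 0], [0, 0, 1], [1, 1, 0], [0, 1, 0]],
            index=list("abcd"),
            columns=["f1", "f2", "f3"],
        )
        fm = FeatureMatrix(data, "assay")
        # positives are a, b: f2 never present in a positive
        fp = build_fingerprint(fm, np.array([1, 1, 0, 0]), "ade")
        assert set(fp.p_values) == {"f1", "f3"}

    def test_all_depleted_fingerprint_returned_with_unit_pvalues(self):
        data = pd.DataFrame(
            [[1, 1], [1, 1], [1, 1], [1, 1], [1, 0]],
            index=list("abcde"),
            columns=["f1", "f2"],
        )
        fm = FeatureMatrix(data, "assay")
        fp = build_fingerprint(fm, np.array([0, 0, 0, 1, 1]), "ade")
        # f1 equally frequent (tested, p=1 since always present), f2 depleted
        assert fp.p_values["f2"] == 1.0
        assert all(0 < p <= 1 for p in fp.p_values.values())

    def test_single_positive_defines_minimal_m(self):
        data = pd.DataFrame(
            [[1, 1, 0], [0, 0, 1], [0, 0, 0]],
            index=list("abc"),
            columns=["f1", "f2", "f3"],
        )
        fp = build_fingerprint(FeatureMatrix(data, "assay"), np.array([1, 0, 0]), "ade")
        assert set(fp.p_values) == {"f1", "f2"}

    def test_no_positive_compounds_error(self, tiny_features):
        with pytest.raises(ValueError, match="no ADE-positive"):
            build_fingerprint(tiny_features, np.zeros(4, dtype=int), "ade")

    def test_matches_scalar_fisher_on_matrix_with_missing(self, default_dataset):
        """Vectorised fingerprint p-values equal per-column scalar calls."""
        fm = default_dataset.assay
        y = default_dataset.ades.labels(default_dataset.ades.ade_ids[0])
        fp = build_fingerprint(fm, y, "ade")
        for fid in list(fp.p_values)[:10]:
            scalar = fisher_enrichment_p(fm.data[fid].to_numpy(), y)
            assert fp.p_values[fid] == pytest.approx(scalar, abs=1e-12)


class TestWfsScore:
    fp = FeatureFingerprint("ade", {"f1": 0.01, "f2": 0.1, "f3": 0.5})

    def test_worked_example_half(self):
        # numerator ln(0.001); denominator ln(0.01) × (1·1 + 2) → exactly 0.5
        model = WFSModel(self.fp, alpha=1.0)
        drug = DrugFeatureSet(frozenset({"f1", "f2", "f4"}))
        assert wfs_score(model, drug) == pytest.approx(0.5, abs=1e-12)

    def test_best_single_feature_scores_one(self):
        model = WFSModel(self.fp)
        assert wfs_score(model, DrugFeatureSet(frozenset({"f1"}))) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_disjoint_feature_set_scores_zero(self):
        model = WFSModel(self.fp)
        assert wfs_score(model, DrugFeatureSet(frozenset({"f9"}))) == 0.0
        assert wfs_score(model, DrugFeatureSet(frozenset())) == 0.0

    def test_all_unit_pvalues_degenerate_to_zero(self):
        model = WFSModel(FeatureFingerprint("ade", {"f1": 1.0, "f2": 1.0}))
        assert wfs_score(model, DrugFeatureSet(frozenset({"f1", "f2"}))) == 0.0

    def test_log_base_invariance(self):
        """The score ratio is identical under natural or base-10 logs."""
        model = WFSModel(self.fp)
        drug = DrugFeatureSet(frozenset({"f2", "f3", "f9"}))
        score = wfs_score(model, drug)
        num10 = math.log10(0.1) + math.log10(0.5)
        den10 = math.log10(0.01) * (1 * 1 + 2)
        assert score == pytest.approx(num10 / den10, abs=1e-12)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_penalised(self, data):
        """Score in [0,1] when C ⊆ M; adding an unannotated feature shrinks it."""
        n = data.draw(st.integers(2, 8))
        ps = data.draw(
            st.lists(st.floats(1e-6, 1.0, exclude_max=True), min_size=n, max_size=n)
        )
        fp = FeatureFingerprint("ade", {f"f{i}": p for i, p in enumerate(ps)})
        model = WFSModel(fp, alpha=1.0)
        subset = data.draw(
            st.sets(st.sampled_from(list(fp.p_values)), min_size=1)
        )
        score = wfs_score(model, DrugFeatureSet(frozenset(subset)))
        assert 0.0 <= score <= 1.0 + 1e-12
        if score > 0:
            widened = wfs_score(model, DrugFeatureSet(frozenset(subset) | {"zzz"}))
            assert widened < score

    def test_min_over_intersection_variant_lets_weak_feature_max_out(self):
        strict = WFSModel(self.fp, min_over="M")
        lax = WFSModel(self.fp, min_over="M∩C")
        weak = DrugFeatureSet(frozenset({"f3"}))
        assert wfs_score(strict, weak) < 1.0
        assert wfs_score(lax, weak) == pytest.approx(1.0, abs=1e-12)


class TestScoreMatrix:
    fp = FeatureFingerprint("ade", {"f1": 0.01, "f2": 0.1})

    def _fm(self, rows, cols=("f1", "f2", "f4")):
        return FeatureMatrix(
            pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))], columns=list(cols)),
            "assay",
        )

    def test_matches_scalar_scoring_and_handles_missing(self):
        model = WFSModel(self.fp)
        fm = self._fm([[1, 1, 1], [0, 0, 0], [1, np.nan, 0], [1, 1, 1]])
        scores = score_matrix(model, fm)
        assert scores["c1"] == 0.0
        # missing treated as not-present: row c2 is just {f1}
        assert scores["c2"] == pytest.approx(
            wfs_score(model, DrugFeatureSet(frozenset({"f1"}))), abs=1e-12
        )
        assert scores["c0"] == scores["c3"]

    def test_invariant_to_column_order(self):
        model = WFSModel(self.fp)
        fm1 = self._fm([[1, 0, 1]], cols=("f1", "f2", "f4"))
        fm2 = FeatureMatrix(fm1.data[["f4", "f2", "f1"]], "assay")
        assert score_matrix(model, fm1)["c0"] == score_matrix(model, fm2)["c0"]

    def test_fingerprint_feature_missing_from_matrix_errors(self):
        model = WFSModel(self.fp)
        fm = self._fm([[1, 0]], cols=("f1", "f4"))
        with pytest.raises(KeyError):
            score_matrix(model, fm)

    def test_agrees_with_setwise_scoring_on_synthetic_rows(self, default_dataset):
        fm = default_dataset.assay
        y = default_dataset.ades.labels(default_dataset.ades.ade_ids[1])
        model = WFSModel(build_fingerprint(fm, y, "ade"))
        scores = score_matrix(model, fm)
        for cid in fm.compound_ids[:15]:
            drug = DrugFeatureSet.from_row(fm.data.loc[cid])
            assert scores[cid] == pytest.approx(wfs_score(model, drug), abs=1e-12)
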