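"""Hypergeometric enrichment and correlation-pattern comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cernaforge.downstream import (
    EnrichmentThresholds,
    correlation_pattern,
    hypergeom_enrich,
    pattern_divergence,
)
from cernaforge.quantify import ExpressionMatrix


def em(values, groups, unit="tpm"):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index = [f"f{i}" for i in range(df.shape[0])]
    return ExpressionMatrix(df, pd.Series(groups, index=df.columns), unit=unit)


class TestHypergeomEnrich:
    def test_exact_combinatorial_value(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        out = hypergeom_enrich(term, {"T": term}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        out = hypergeom_enrich({"g0"}, {"T": {"g5", "g6"}}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_term_equal_to_universe_is_uninformative(self):
        universe = {f"g{i}" for i in range(8)}
        out = hypergeom_enrich({"g0", "g1"}, {"T": set(universe)}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"gX"}, {"T": {"g1"}}, {"g1", "g2"})

    def test_matches_exhaustive_enumeration_for_small_universes(self):
        """Oracle: count query draws with >= k term genes over all subsets."""
        rng = np.random.default_rng(6)
        for trial in range(6):
            N = int(rng.integers(5, 13))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            term = set(rng.choice(universe, K, replace=False))
            n = int(rng.integers(1, N + 1))
            query = set(rng.choice(universe, n, replace=False))
            k = len(query & term)
            total = hits = 0
            for draw in itertools.combinations(universe, n):
                total += 1
                hits += len(set(draw) & term) >= k
            out = hypergeom_enrich(query, {"T": term}, set(universe))
            assert out["p_value"].iloc[0] == pytest.approx(hits / total)

    def test_significance_is_conjunction_of_p_and_fdr(self, bundle):
        universe = set(bundle.mrna_counts.feature_ids)
        query = set(bundle.truth.true_de["mrna"])
        out = hypergeom_enrich(query, bundle.gene_sets, universe)
        expected = (out["fdr"] < 0.05) & (out["p_value"] < 0.01)
        assert (out["significant"] == expected).all()
        # a term with only chance overlap is not significant
        weak = out.set_index("term_id").drop(bundle.truth.enriched_term)
        assert not weak["significant"].all() or weak.empty

    def test_planted_term_detected_on_bundle(self, bundle):
        universe = set(bundle.mrna_counts.feature_ids)
        query = set(bundle.truth.true_de["mrna"])
        out = hypergeom_enrich(query, bundle.gene_sets, universe)
        top = out.iloc[0]
        assert top["term_id"] == bundle.truth.enriched_term
        assert bool(top["significant"])


class TestCorrelationPattern:
    G6 = ["case"] * 3 + ["control"] * 3

    def test_identical_vectors_correlate_perfectly(self):
        circ = em([[1, 2, 3, 9, 9, 9]], self.G6)
        mrna = em([[1, 2, 3, 4, 4, 4]], self.G6)
        pat = correlation_pattern(circ, mrna, "case")
        assert pat.matrix.iloc[0, 0] == pytest.approx(1.0)

    def test_constant_vector_flagged_undefined_and_excluded(self):
        circ = em([[5, 5, 5, 1, 2, 3], [1, 2, 3, 1, 2, 3]], self.G6)
        mrna = em([[1, 2, 3, 4, 5, 6]], self.G6)
        pat = correlation_pattern(circ, mrna, "case")
        assert np.isnan(pat.matrix.iloc[0, 0])
        assert pat.coherence == pytest.approx(1.0)  # only the defined entry

    def test_fewer_than_three_samples_rejected(self):
        circ = em([[1, 2, 3, 4]], ["case", "case", "control", "control"])
        with pytest.raises(ValueError, match=">= 3"):
            correlation_pattern(circ, circ, "case")

    def test_invariant_to_per_feature_affine_rescaling(self):
        rng = np.random.default_rng(1)
        circ = em(rng.normal(size=(4, 6)), self.G6)
        mrna = em(rng.normal(size=(5, 6)), self.G6)
        a = correlation_pattern(circ, mrna, "control").matrix
        scaled = ExpressionMatrix(circ.values * 7.0 + 3.0, circ.groups, unit="tpm")
        b = correlation_pattern(scaled, mrna, "control").matrix
        pd.testing.assert_frame_equal(a, b)

    def test_planted_shared_factor_raises_case_coherence(self, bundle):
        from cernaforge.quantify import bsj_tpm

        circ = bsj_tpm(bundle.circ_counts).subset(bundle.truth.coupled_circ)
        mrna = bundle.mrna_counts.subset(bundle.truth.coupled_mrna)
        case = correlation_pattern(circ, mrna, "case")
        control = correlation_pattern(circ, mrna, "control")
        assert case.coherence > control.coherence
        div = pattern_divergence(case, control)
        assert div["coherence_diff"] > 0


class TestPatternDivergence:
    def test_identical_patterns_have_zero_divergence(self):
        rng = np.random.default_rng(3)
        circ = em(rng.normal(size=(3, 8)), ["case"] * 4 + ["control"] * 4)
        mrna = em(rng.normal(size=(4, 8)), ["case"] * 4 + ["control"] * 4)
        pat = correlation_pattern(circ, mrna, "case")
        div = pattern_divergence(pat, pat)
        assert div["coherence_diff"] == 0.0
        assert div["frac_positive_diff"] == 0.0
        assert div["matrix_correlation"] == pytest.approx(1.0)

    def test_constructed_frac_positive_difference(self):
        from cernaforge.downstream import CorrelationPattern

        grid = pd.DataFrame(np.full((2, 2), 0.8), index=["c1", "c2"], columns=["g1", "g2"])
        a = CorrelationPattern("case", grid, 0.8, 1.0)
        signs = pd.DataFrame([[0.5, -0.5], [-0.5, 0.5]], index=["c1", "c2"],
                             columns=["g1", "g2"])
        b = CorrelationPattern("control", signs, 0.0, 0.5)
        div = pattern_divergence(a, b)
        assert div["frac_positive_diff"] == pytest.approx(0.5)

    def test_mismatched_grids_rejected(self):
        from cernaforge.downstream import CorrelationPattern

        a = CorrelationPattern("x", pd.DataFrame(np.eye(2)), 0.0, 0.5)
        b = CorrelationPattern("y", pd.DataFrame(np.eye(3)), 0.0, 0.5)
        with pytest.raises(ValueError, match="grid"):
            pattern_divergence(a, b)
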