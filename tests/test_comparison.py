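"""Paired comparisons, the exact binomial sign test, correlation, strata."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosym.comparison import (
    DegenerateCorrelationError,
    PairComparison,
    binom_upper_tail,
    compare_pair,
    gene_correlation,
    sign_test,
    stratified_summary,
)
from endosym.seq_io import EmptyProfileError
from conftest import make_profile, stats_from_values


def enumerate_head_counts(n):
    """Brute force: number of heads of every one of the 2^n coin-flip outcomes."""
    return [bin(outcome).count("1") for outcome in range(2**n)]


class TestBinomUpperTail:
    def test_matches_enumeration_all_n_up_to_16(self):
        for n in range(0, 17):
            heads = enumerate_head_counts(n)
            for k in range(0, n + 2):
                expected = sum(1 for h in heads if h >= k) / 2**n
                assert binom_upper_tail(k, n, 0.5) == pytest.approx(
                    expected, abs=1e-15
                )

    def test_boundaries(self):
        assert binom_upper_tail(0, 14, 0.5) == 1.0
        assert binom_upper_tail(15, 14, 0.5) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_upper_tail(-1, 14, 0.5)
        with pytest.raises(ValueError):
            binom_upper_tail(16, 14, 0.5)
        with pytest.raises(ValueError):
            binom_upper_tail(3, 14, 0.0)

    def test_scipy_cross_check_uneven_p(self):
        from scipy import stats

        for k, n, p in [(5, 20, 0.3), (13, 14, 0.5), (2, 7, 0.9)]:
            assert binom_upper_tail(k, n, p) == pytest.approx(
                stats.binom.sf(k - 1, n, p), rel=1e-12
            )

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(n=st.integers(1, 40), k=st.integers(1, 40))
    def test_monotone_decreasing_in_k(self, n, k):
        if k > n:
            k = n
        assert binom_upper_tail(k, n, 0.5) < binom_upper_tail(k - 1, n, 0.5)


class TestComparePair:
    def _pair(self, sym_values, rel_values, feature="hydrophobicity"):
        symbiont = make_profile(
            "S", "symbiont", stats=stats_from_values(sym_values, feature)
        )
        relative = make_profile(
            "R", "relative", stats=stats_from_values(rel_values, feature)
        )
        return symbiont, relative

    def test_unweighted_gene_means(self):
        symbiont, relative = self._pair([1.0, 2.0, 3.0], [0.0, 1.0])
        comp = compare_pair(symbiont, relative, "hydrophobicity")
        assert comp.difference == pytest.approx(1.5, abs=1e-12)
        assert comp.agrees is True

    def test_tie_counts_as_disagreement(self):
        symbiont, relative = self._pair([9.1, 9.3], [9.1, 9.3], "amino_pka")
        comp = compare_pair(symbiont, relative, "amino_pka")
        assert comp.difference == 0.0
        assert comp.agrees is False

    def test_predicted_directions(self):
        symbiont, relative = self._pair([8.0], [9.0], "amino_pka")
        assert compare_pair(symbiont, relative, "amino_pka").agrees is True
        symbiont, relative = self._pair([1.0], [2.0])
        assert compare_pair(symbiont, relative, "hydrophobicity").agrees is False

    def test_carboxyl_needs_explicit_sign(self):
        symbiont, relative = self._pair([2.1], [2.0], "carboxyl_pka")
        with pytest.raises(ValueError, match="predicted_sign"):
            compare_pair(symbiont, relative, "carboxyl_pka")
        comp = compare_pair(symbiont, relative, "carboxyl_pka", predicted_sign=+1)
        assert comp.agrees is True

    def test_unknown_feature_rejected(self):
        symbiont, relative = self._pair([1.0], [0.0])
        with pytest.raises(ValueError):
            compare_pair(symbiont, relative, "charge")

    def test_empty_profile_rejected(self, table):
        symbiont, _ = self._pair([1.0], [0.0])
        empty = make_profile("E", "relative", stats=[])
        with pytest.raises(EmptyProfileError):
            compare_pair(symbiont, empty, "hydrophobicity")

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        sym=st.lists(st.floats(-50, 100, allow_nan=False), min_size=1, max_size=20),
        rel=st.lists(st.floats(-50, 100, allow_nan=False), min_size=1, max_size=20),
    )
    def test_antisymmetry(self, sym, rel):
        """Swapping the two profiles negates the difference exactly."""
        s = make_profile("S", "symbiont", stats=stats_from_values(sym))
        r = make_profile("R", "relative", stats=stats_from_values(rel))
        s2 = make_profile("R", "symbiont", stats=stats_from_values(rel))
        r2 = make_profile("S", "relative", stats=stats_from_values(sym))
        forward = compare_pair(s, r, "hydrophobicity").difference
        backward = compare_pair(s2, r2, "hydrophobicity").difference
        assert forward == -backward


def make_comparison(symbiont_id, relative_id, feature, agrees):
    sign = {"hydrophobicity": 1, "amino_pka": -1}[feature]
    diff = sign * (1.0 if agrees else -1.0)
    return PairComparison(
        symbiont_id=symbiont_id, relative_id=relative_id, feature=feature,
        symbiont_mean=diff, relative_mean=0.0, difference=diff,
        predicted_sign=sign, agrees=agrees,
    )


class TestSignTest:
    def test_counts_and_exact_tail(self):
        comps = [
            make_comparison(f"S{i}", f"R{i}", feature, not (i == 6 and feature == "amino_pka"))
            for i in range(7)
            for feature in ("hydrophobicity", "amino_pka")
        ]
        result = sign_test(comps)
        assert (result.k, result.n) == (13, 14)
        assert result.p_value == pytest.approx(15 / 16384, rel=1e-12)

    def test_all_agree_closed_form(self):
        comps = [make_comparison(f"S{i}", f"R{i}", "hydrophobicity", True) for i in range(5)]
        result = sign_test(comps)
        assert result.p_value == pytest.approx(1 / 32, rel=1e-12)

    def test_merge_unanimous_group(self):
        comps = [
            make_comparison(f"S{i}", f"R{i}", feature, True)
            for i in range(4)
            for feature in ("hydrophobicity", "amino_pka")
        ]
        merged = sign_test(
            comps, merge_groups={"S0~R0": "spheroid", "S1~R1": "spheroid"}
        )
        assert (merged.k, merged.n) == (6, 6)

    def test_non_unanimous_group_counts_as_disagreement(self):
        comps = [
            make_comparison("S0", "R0", "hydrophobicity", True),
            make_comparison("S1", "R1", "hydrophobicity", False),
            make_comparison("S2", "R2", "hydrophobicity", True),
        ]
        merged = sign_test(comps, merge_groups={"S0~R0": "g", "S1~R1": "g"})
        assert (merged.k, merged.n) == (1, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sign_test([])


class TestGeneCorrelation:
    def test_collinear_points(self):
        from endosym.properties import GeneStats

        # amino pKa exactly 2 * hydrophobicity + 1 across genes
        stats = [
            GeneStats(
                gene_id=f"g{i}", mean_hydrophobicity=x,
                mean_amino_pka=2 * x + 1, mean_carboxyl_pka=2.0,
                length=10, n_scored=10,
            )
            for i, x in enumerate([0.0, 1.0, 2.0, 3.0, 4.0])
        ]
        profile = make_profile("O", "symbiont", stats=stats)
        result = gene_correlation([profile])
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.n_genes == 5

    def test_constant_x_degenerate(self):
        stats = stats_from_values([5.0] * 6, "hydrophobicity")
        profile = make_profile("O", "symbiont", stats=stats)
        with pytest.raises(DegenerateCorrelationError):
            gene_correlation([profile])

    def test_independent_features_give_weak_r_squared(self, table):
        """500 genes with independently sampled features: r^2 stays below
        0.05 in at least 95% of seeded replicates."""
        from endosym.properties import GeneStats

        weak = 0
        n_reps = 40
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            xs = rng.normal(0, 10, size=500)
            ys = rng.normal(9.3, 0.1, size=500)
            stats = [
                GeneStats(
                    gene_id=f"g{i}", mean_hydrophobicity=float(x),
                    mean_amino_pka=float(y), mean_carboxyl_pka=2.0,
                    length=10, n_scored=10,
                )
                for i, (x, y) in enumerate(zip(xs, ys))
            ]
            profile = make_profile("O", "symbiont", stats=stats)
            if gene_correlation([profile]).r_squared < 0.05:
                weak += 1
        assert weak >= 0.95 * n_reps


class TestStratifiedSummary:
    def test_partition_sizes(self, table):
        profile = make_profile(
            "O", "symbiont",
            sequences=["MAAC", "MKLF", "MWWY", "MDDE"],
            ribosomal=[True, False, False, False],
            table=table,
        )
        rib, other = stratified_summary(profile)
        assert rib.count == 1 and other.count == 3
        assert rib.count + other.count == len(profile)
        assert rib.means is not None

    def test_empty_stratum_flagged_absent(self, table):
        profile = make_profile("O", "symbiont", sequences=["MAAC"], table=table)
        rib, other = stratified_summary(profile)
        assert rib.count == 0 and rib.means is None
        assert other.count == 1
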