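"""Supervariant collapsing, background rate, exact tail p-values, and BH."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somaburden.burden import (
    FlagMatrix,
    background_rate,
    burden_test,
    collapse_supervariants,
    run_burden,
)
from somaburden.io_formats import MutationRecord, SiftPred, ValidationError, VariantClass

# Exact one-sided binomial upper tail P(X >= 21 | n=470, p=0.011649), computed
# once with Fraction arithmetic (sum_{j>=21} C(470,j) p^j (1-p)^(470-j)).
EXACT_TAIL_21_470 = 2.713954149650515e-07


def exact_upper_tail(k: int, S: int, p: Fraction) -> Fraction:
    """Independent arbitrary-precision enumeration oracle."""
    return sum(Fraction(comb(S, j)) * p**j * (1 - p) ** (S - j) for j in range(k, S + 1))


def rec(sample, gene, pos=100):
    return MutationRecord(
        sample_id=sample, gene=gene, chrom="chr1", pos=pos, ref="C", alt="T",
        variant_class=VariantClass.MISSENSE, sift_pred=SiftPred.DELETERIOUS,
    )


class TestCollapse:
    def test_no_records_gives_all_zero_matrix(self):
        m = collapse_supervariants([], ["s1", "s2", "s3", "s4"], gene_universe=["a", "b", "c"])
        assert m.d.shape == (3, 4) and not m.d.any()

    def test_two_mutations_same_cell_count_once(self):
        m = collapse_supervariants(
            [rec("s1", "g1", 100), rec("s1", "g1", 200)], ["s1", "s2"]
        )
        assert m.d.tolist() == [[1, 0]]

    def test_unknown_sample_strict_raises(self):
        with pytest.raises(ValidationError, match="strict"):
            collapse_supervariants([rec("sX", "g1")], ["s1"])

    def test_nonstrict_extends_cohort(self):
        m = collapse_supervariants([rec("sX", "g1")], ["s1"], strict=False)
        assert m.samples == ("s1", "sX") and m.d.tolist() == [[0, 1]]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 7)), max_size=50
        )
    )
    def test_matches_pair_set_oracle(self, pairs):
        """Matrix equals independent set-membership over (gene, sample) pairs."""
        genes = [f"g{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(8)]
        records = [rec(samples[s], genes[g], pos=100 + i) for i, (g, s) in enumerate(pairs)]
        m = collapse_supervariants(records, samples, gene_universe=genes)
        pair_set = {(g, s) for g, s in pairs}
        for gi in range(6):
            for si in range(8):
                assert m.d[gi, si] == ((gi, si) in pair_set)

    def test_record_order_irrelevant(self):
        records = [rec("s2", "g1"), rec("s1", "g2"), rec("s1", "g1")]
        a = collapse_supervariants(records, ["s1", "s2"], gene_universe=["g1", "g2"])
        b = collapse_supervariants(records[::-1], ["s1", "s2"], gene_universe=["g1", "g2"])
        assert np.array_equal(a.d, b.d)


class TestBackgroundRate:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (np.zeros((3, 4)), 0.0),
            (np.ones((3, 4)), 1.0),
            # G=2, S=4 with k=(1,3): (0.25 + 0.75) / 2 over 8 flags
            (np.array([[1, 0, 0, 0], [1, 1, 1, 0]]), 0.5),
        ],
    )
    def test_hand_arithmetic(self, d, expected):
        m = FlagMatrix(
            genes=tuple(f"g{i}" for i in range(d.shape[0])),
            samples=tuple(f"s{i}" for i in range(d.shape[1])),
            d=d,
        )
        assert background_rate(m) == expected

    def test_equals_mean_of_per_gene_rates(self, small_cohort):
        _, _, truth = small_cohort
        m = truth.flag_matrix
        rates = m.flagged_counts() / m.n_samples
        assert background_rate(m) == pytest.approx(rates.mean(), rel=0, abs=1e-15)


class TestBurdenTest:
    def test_k_zero_is_one(self):
        assert burden_test(0, 100, 0.3) == 1.0

    def test_enumeration_example(self):
        # 2^4 equiprobable flag vectors: 11 of 16 have >= 2 ones
        assert burden_test(2, 4, 0.5) == pytest.approx(11 / 16, rel=1e-15)

    def test_frozen_high_precision_oracle(self):
        assert burden_test(21, 470, 0.011649) == pytest.approx(
            EXACT_TAIL_21_470, rel=1e-12
        )

    @pytest.mark.parametrize("background", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("S", [1, 2, 5, 12])
    def test_matches_exact_enumeration_for_small_cohorts(self, S, background):
        p = Fraction(background).limit_denominator(10)
        for k in range(S + 1):
            expected = float(exact_upper_tail(k, S, p))
            assert burden_test(k, S, float(p)) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [burden_test(k, 470, 0.011649) for k in range(0, 60)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            burden_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            burden_test(1, 4, 1.5)
        with pytest.raises(ValueError):
            burden_test(1, 4, 0.5, method="gaussian")

    def test_poisson_alternative_close_for_rare_events(self):
        b = burden_test(21, 470, 0.011649, method="binomial")
        p = burden_test(21, 470, 0.011649, method="poisson")
        assert p == pytest.approx(b, rel=0.5)  # same order of magnitude


def bh_oracle(pvals):
    """Independent Benjamini–Hochberg step-up: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, pvals[idx] * m / rank))
        q[idx] = running
    return q


class TestRunBurden:
    def test_single_gene_q_equals_p(self):
        m = FlagMatrix(genes=("g",), samples=("a", "b", "c"), d=np.array([[1, 0, 1]]))
        (res,) = run_burden(m)
        assert res.q == res.p

    def test_identical_genes_share_p_and_q(self):
        d = np.tile(np.array([[1, 0, 0, 1]]), (5, 1))
        m = FlagMatrix(
            genes=tuple(f"g{i}" for i in range(5)),
            samples=tuple(f"s{i}" for i in range(4)),
            d=d,
        )
        results = run_burden(m)
        assert len({r.p for r in results}) == 1
        assert all(r.q == results[0].p for r in results)

    def test_q_matches_independent_bh_oracle(self):
        rng = np.random.default_rng(11)
        d = (rng.random((50, 100)) < 0.05).astype(np.uint8)
        m = FlagMatrix(
            genes=tuple(f"g{i:03d}" for i in range(50)),
            samples=tuple(f"s{i:03d}" for i in range(100)),
            d=d,
        )
        results = run_burden(m)
        by_gene = {r.gene: r for r in results}
        genes = list(m.genes)
        pvals = [by_gene[g].p for g in genes]
        expected = bh_oracle(pvals)
        for g, q in zip(genes, expected):
            assert by_gene[g].q == pytest.approx(q, rel=1e-12)
        # invariants: sorted by p with stable gene tie-break, q >= p, exact rates
        assert [(r.p, r.gene) for r in results] == sorted((r.p, r.gene) for r in results)
        for r in results:
            assert r.q >= r.p and r.rate == r.k / r.S

    def test_sample_permutation_changes_nothing(self, small_cohort):
        _, _, truth = small_cohort
        m = truth.flag_matrix
        rng = np.random.default_rng(5)
        perm = rng.permutation(m.n_samples)
        m2 = FlagMatrix(
            genes=m.genes, samples=tuple(m.samples[i] for i in perm), d=m.d[:, perm]
        )
        r1 = {r.gene: (r.k, r.p, r.q) for r in run_burden(m)}
        r2 = {r.gene: (r.k, r.p, r.q) for r in run_burden(m2)}
        assert r1 == r2

    def test_leave_one_out_background_excludes_gene(self):
        d = np.array([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 0, 0]])
        m = FlagMatrix(genes=("a", "b", "c"), samples=("w", "x", "y", "z"), d=d)
        results = {r.gene: r for r in run_burden(m, leave_one_out=True)}
        assert results["a"].background == pytest.approx(1 / 8)  # (5-4)/(2*4)
        assert results["b"].background == pytest.approx(5 / 8)


def test_flag_matrix_invariants():
    with pytest.raises(ValidationError):
        FlagMatrix(genes=("a", "a"), samples=("s",), d=np.zeros((2, 1)))
    with pytest.raises(ValidationError):
        FlagMatrix(genes=("a",), samples=("s",), d=np.array([[2]]))
    with pytest.raises(ValidationError):
        FlagMatrix(genes=("a",), samples=("s", "t"), d=np.zeros((1, 3)))
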