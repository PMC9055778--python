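from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import methbatch as mb
from methbatch.associations import FISHER_MAX_CELLS


def hwe_pairing_oracle(n_aa, n_ab, n_bb):
    """Exact HWE p by counting allele pairings with double factorials.

    The conditional distribution of the heterozygote count given allele
    counts equals that of a uniformly random perfect matching of the
    2n alleles into n pairs; pairings are counted exactly with Fractions.
    """

    def double_fact(m):  # (m-1)!! pairings of m items, m even
        out = 1
        for v in range(m - 1, 0, -2):
            out *= v
        return out

    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n = n_aa + n_ab + n_bb
    total = double_fact(2 * n)

    def ways(h):
        # choose which alleles form the h mixed pairs, match them (h! ways),
        # then pair off the leftovers within each allele class
        a_rem, b_rem = n_a - h, n_b - h
        if a_rem < 0 or b_rem < 0 or a_rem % 2 or b_rem % 2:
            return 0
        return (
            comb(n_a, h)
            * comb(n_b, h)
            * factorial(h)
            * double_fact(a_rem)
            * double_fact(b_rem)
        )

    probs = {}
    for h in range(min(n_a, n_b) + 1):
        w = ways(h)
        if w:
            probs[h] = Fraction(w, total)
    assert abs(sum(probs.values()) - 1) == 0
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs))


class TestFisher:
    def test_diagonal_two_by_two(self):
        p = mb.fisher_cluster_association([0] * 10 + [1] * 10, ["a"] * 10 + ["b"] * 10)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_independent_table(self):
        p = mb.fisher_cluster_association(
            [0] * 5 + [1] * 5 + [0] * 5 + [1] * 5,
            ["a"] * 10 + ["b"] * 10,
        )
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_on_2x2(self, rng):
        for _ in range(40):
            table = rng.integers(1, 12, size=(2, 2))
            a = np.repeat([0, 0, 1, 1], table.flatten())
            f = np.repeat([0, 1, 0, 1], table.flatten())
            ours = mb.fisher_cluster_association(a, f)
            assert ours == pytest.approx(stats.fisher_exact(table).pvalue, rel=1e-9)

    def test_2xc_matches_scipy_monte_carlo(self, rng):
        # scipy's r x c fisher is simulated; exact enumeration should sit
        # within its Monte-Carlo error
        a = np.repeat([0, 1], 20)
        f = rng.integers(0, 3, 40)
        ours = mb.fisher_cluster_association(a, f)
        table = np.zeros((2, 3), int)
        np.add.at(table, (a, f), 1)
        theirs = stats.fisher_exact(table).pvalue
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_large_table_raises(self):
        a = np.tile(np.arange(4), 24)
        f = np.repeat(np.arange(8), 12)
        with pytest.raises(mb.TableTooLargeError):
            mb.fisher_cluster_association(a, f)

    def test_cluster_relabelling_invariant(self, rng):
        a = rng.integers(0, 2, 30)
        f = rng.integers(0, 2, 30)
        assert mb.fisher_cluster_association(a, f) == pytest.approx(
            mb.fisher_cluster_association(1 - a, f)
        )

    def test_null_p_values_approximately_uniform(self, rng):
        a = np.repeat([0, 1], 24)
        ps = []
        for _ in range(1000):
            ps.append(mb.fisher_cluster_association(a, rng.permutation(a)))
        ps = np.sort(ps)
        grid = (np.arange(ps.size) + 1) / ps.size
        # exact tests are super-uniform: ECDF never far above the diagonal
        assert np.max(grid - ps) <= 0.0 + 0.05 or np.max(np.maximum(0, grid - ps)) < 0.05
        assert 0.3 < ps.mean() < 0.7


class TestChisqMonteCarlo:
    def test_strong_dependence_hits_floor(self):
        a = np.repeat(np.arange(4), 18)
        f = np.repeat(np.arange(6), 12)  # aligned blocks: strong dependence
        p = mb.chisq_monte_carlo(a, f, B=1999, seed=0)
        assert p == pytest.approx(1 / 2000)

    def test_independent_factor_rarely_significant(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = np.repeat([0, 1, 2], 20)
            f = r.integers(0, 4, 60)
            if mb.chisq_monte_carlo(a, f, B=999, seed=seed) > 0.05:
                hits += 1
        assert hits >= 90

    def test_seeded_determinism(self, rng):
        a = rng.integers(0, 3, 50)
        f = rng.integers(0, 5, 50)
        p1 = mb.chisq_monte_carlo(a, f, seed=4)
        p2 = mb.chisq_monte_carlo(a, f, seed=4)
        assert p1 == p2

    def test_degenerate_table_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = mb.chisq_monte_carlo(np.zeros(20, int), np.repeat([0, 1], 10))
        assert p == 1.0

    def test_b_floor(self):
        with pytest.raises(ValueError, match="B"):
            mb.chisq_monte_carlo([0, 1], [0, 1], B=10)


class TestContinuousAssociation:
    def test_constant_covariate(self):
        assert mb.continuous_association([0] * 5 + [1] * 5, np.full(10, 0.2)) == 1.0

    def test_separated_cluster_means(self, rng):
        cov = np.concatenate([rng.normal(0.03, 0.02, 48), rng.normal(0.30, 0.02, 48)])
        a = np.repeat([0, 1], 48)
        assert mb.continuous_association(a, cov) < 1e-10

    def test_matches_scipy_f_oneway(self, rng):
        a = rng.integers(0, 3, 45)
        cov = rng.normal(size=45)
        groups = [cov[a == g] for g in range(3)]
        assert mb.continuous_association(a, cov) == pytest.approx(
            stats.f_oneway(*groups).pvalue
        )

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            mb.continuous_association([0, 1, 2], [0.1, 0.2, 0.3])


class TestHweExact:
    def test_most_probable_configuration(self):
        assert mb.hwe_exact([25, 50, 25]) > 0.9

    def test_missing_heterozygotes(self):
        assert mb.hwe_exact([50, 0, 50]) < 1e-20

    def test_rare_allele_two_cluster_mapping(self):
        assert mb.hwe_exact([81, 18]) >= 0.001
        # order of the two clusters must not matter
        assert mb.hwe_exact([18, 81]) == mb.hwe_exact([81, 18])

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_matches_pairing_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert mb.hwe_exact([a, b, c]) == pytest.approx(
            hwe_pairing_oracle(a, b, c), rel=1e-9, abs=1e-300
        )

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            mb.hwe_exact([1, 2, 3, 4])
        with pytest.raises(ValueError):
            mb.hwe_exact([0, 0, 0])


class TestBhFdr:
    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(mb.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(mb.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = mb.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mb.bh_fdr([0.5, 1.5])


class TestAttribution:
    def test_no_modal_probes(self):
        sheet = pd.DataFrame(
            {"sample_id": ["a", "b"], "slide": ["A", "A"], "gender": ["F", "M"],
             "superbatch": ["S", "S"], "cell_fraction": [0.1, 0.2]}
        )
        table, tally = mb.attribute_modal_probes({}, sheet)
        assert table.empty

    def test_default_study_attribution(self, default_run):
        truth, att = default_run.truth, default_run.attribution
        gids = att.index.intersection(truth.probes_of("gender_bimodal"))
        assert att.loc[gids, "sig_gender"].eq(True).mean() >= 0.9
        cids = att.index.intersection(truth.probes_of("cell_gradient"))
        assert att.loc[cids, "sig_cell"].eq(True).mean() >= 0.8
        aids = att.index.intersection(truth.probes_of("asm_trimodal"))
        assert att.loc[aids, "hwe_consistent"].eq(True).mean() >= 0.9

    def test_missing_covariate_skipped_with_warning(self, default_run):
        clusters = {
            pid: m for pid, m in list(default_run.clusters.items())[:5] if m.k > 1
        }
        sheet = pd.DataFrame(
            {
                "sample_id": default_run.pre_beta.sample_ids,
                "slide": ["A"] * 48 + ["B"] * 48,
            }
        )
        with pytest.warns(UserWarning):
            table, _ = mb.attribute_modal_probes(clusters, sheet)
        assert "sig_gender" not in table.columns or table["sig_gender"].isna().all()
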