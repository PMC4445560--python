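import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dloopabc import popgen_stats as ps
from dloopabc.data_model import AlignedSequences, SequenceRecord


def aln(*seqs):
    n = len(seqs[0])
    return AlignedSequences(
        [SequenceRecord(id=f"s{i}", seq=s, anchor_start=1) for i, s in enumerate(seqs)],
        window=(1, n),
    )


class TestHaplotypes:
    def test_exact_identity(self):
        table = ps.call_haplotypes(aln("ACGT", "ACGT", "ACGA"))
        assert table.k == 2 and table.counts.tolist() == [2, 1]

    def test_wildcard_n_matches_any(self):
        assert ps.call_haplotypes(aln("ACGT", "ACNT")).k == 1

    def test_wildcard_transitive_merge(self):
        # a~b via N, b~c via N, but a and c differ: one transitive cluster
        table = ps.call_haplotypes(aln("ACGT", "ANGT", "ATGT"))
        assert table.k == 1

    def test_complete_sites_policy(self):
        # dropping the N-bearing column separates a and c
        table = ps.call_haplotypes(
            aln("ACGT", "ANGT", "ATGA"), missing_policy="complete_sites"
        )
        assert table.k == 2

    def test_monomorphic_group(self, toys):
        table = ps.call_haplotypes(toys["sf_monomorphic"])
        assert table.k == 1 and table.counts.tolist() == [8]

    def test_empty_alignment_error(self):
        with pytest.raises(ValueError):
            ps.call_haplotypes(np.empty((0, 4), dtype=np.int8))


class TestHaplotypeDiversity:
    def test_two_by_two(self):
        h, _ = ps.haplotype_diversity([2, 2])
        assert h == pytest.approx(2 / 3)

    def test_monomorphic_zero(self):
        h, sd = ps.haplotype_diversity([8])
        assert h == 0.0 and sd == 0.0

    def test_requires_two(self):
        with pytest.raises(ValueError):
            ps.haplotype_diversity([1])

    @given(
        counts=st.lists(st.integers(1, 20), min_size=1, max_size=10).filter(
            lambda c: sum(c) >= 2
        )
    )
    def test_bounds_and_zero_iff_single(self, counts):
        h, _ = ps.haplotype_diversity(counts)
        assert 0.0 <= h <= 1.0
        assert (h == 0.0) == (len(counts) == 1)


class TestDiversity:
    def test_single_pair_three_diffs(self):
        pi, _ = ps.mean_pairwise_differences(aln("AAAA", "ATTT"))
        assert pi == 3.0

    def test_identical_zero(self, toys):
        pi, sd = ps.mean_pairwise_differences(toys["sf_monomorphic"])
        assert pi == 0.0 and sd == 0.0

    def test_pairwise_deletion(self):
        # N site is excluded from the comparison of that pair only
        pi, _ = ps.mean_pairwise_differences(aln("ACGT", "NCGA"))
        assert pi == 1.0

    def test_segregating_sites(self):
        assert ps.segregating_sites(aln("AA", "AT", "TT", "TT")) == 2
        assert ps.segregating_sites(aln("ACGT", "ACGT")) == 0

    def test_missing_only_variation_not_segregating(self):
        # column with {A, N, -} has a single non-missing state
        assert ps.segregating_sites(aln("A", "N", "-")) == 0


class TestTajimasD:
    def test_toy_value(self):
        r = ps.tajimas_d(aln("AA", "AT", "TT", "TT"), n_null_sims=0)
        assert r.statistic == pytest.approx(0.5916, abs=1e-4)

    def test_zero_when_pi_equals_watterson(self):
        # numerator pi - S/a1 vanishes by construction
        assert ps.tajimas_d_value(12 / 11, 2, 4) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_undefined(self, toys):
        r = ps.tajimas_d(toys["sf_monomorphic"], n_null_sims=0)
        assert not r.defined and str(r) == "-"

    def test_n2_variance_vanishes(self):
        assert ps.tajimas_d_value(1.0, 1, 2) is None

    def test_p_value_reproducible(self):
        a = aln("AAAA", "ATTT", "TTTT", "TTAT")
        r1 = ps.tajimas_d(a, n_null_sims=200, seed=3)
        r2 = ps.tajimas_d(a, n_null_sims=200, seed=3)
        assert r1.p_value == r2.p_value


def ewens_enumeration_oracle(n: int, theta: float) -> np.ndarray:
    """Pr(K = k) by exhaustive enumeration of set partitions with CRP weights.

    Independent of the Stirling-number recurrence used by the implementation:
    P(partition) = theta^k * prod (|block|-1)! / rising(theta, n).
    """

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
            yield [[first]] + smaller

    rising = math.prod(theta + i for i in range(n))
    pmf = np.zeros(n)
    for part in partitions(list(range(n))):
        k = len(part)
        w = theta**k * math.prod(math.factorial(len(b) - 1) for b in part)
        pmf[k - 1] += w / rising
    return pmf


class TestFusFs:
    @pytest.mark.parametrize("theta", [0.5, 1.0, 5.0])
    @pytest.mark.parametrize("n", range(2, 9))
    def test_matches_ewens_enumeration(self, n, theta):
        oracle = ewens_enumeration_oracle(n, theta)
        mine = np.exp(ps.ewens_log_pmf(n, theta))
        assert np.allclose(mine, oracle, atol=1e-9)
        for k_obs in range(2, n + 1):
            sp = oracle[k_obs - 1 :].sum()
            if sp >= 1.0:
                continue
            expected = math.log(sp / (1 - sp))
            assert ps.fs_value(n, k_obs, theta) == pytest.approx(expected, abs=1e-9)

    def test_example_n4(self):
        # S' = 7/24 for n=4, theta=1, k_obs=3
        assert ps.fs_value(4, 3, 1.0) == pytest.approx(math.log(7 / 17), abs=1e-9)

    def test_single_haplotype_undefined(self):
        assert ps.fs_value(4, 1, 1.0) is None

    def test_monomorphic_undefined(self, toys):
        r = ps.fus_fs(toys["sf_monomorphic"], n_null_sims=0)
        assert not r.defined and str(r) == "-"


def amova_oracle(diffs: np.ndarray, sizes) -> float:
    """Naive two-level AMOVA variance components, written with plain loops."""
    n = diffs.shape[0]
    groups = []
    start = 0
    for s in sizes:
        groups.append(list(range(start, start + s)))
        start += s
    ssd_t = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ssd_t += diffs[i, j]
    ssd_t /= n
    ssd_w = 0.0
    for g in groups:
        acc = 0.0
        for i in g:
            for j in g:
                if j > i:
                    acc += diffs[i, j]
        ssd_w += acc / len(g)
    sigma_w = ssd_w / (n - len(groups))
    ms_a = (ssd_t - ssd_w) / (len(groups) - 1)
    n_prime = (n - sum(s**2 for s in sizes) / n) / (len(groups) - 1)
    sigma_a = (ms_a - sigma_w) / n_prime
    return sigma_a / (sigma_a + sigma_w) if sigma_a + sigma_w else 0.0


class TestFst:
    def test_fixed_difference_is_one(self, toys):
        f, _ = ps.pairwise_fst(toys["fst_fixed_a"], toys["fst_fixed_b"])
        assert f == pytest.approx(1.0)

    def test_identical_composition_nonpositive(self):
        g = aln("AAAA", "ATTT")
        f, _ = ps.pairwise_fst(g, g)
        assert f <= 0.0

    def test_haplotype_freq_fixed_difference(self, toys):
        f, _ = ps.pairwise_fst(
            toys["fst_fixed_a"], toys["fst_fixed_b"], estimator="haplotype_freq"
        )
        assert f == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_phi_st_matches_amova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 4, size=(9, 12)).astype(np.int8)
        sizes = (4, 5)
        diffs = ps.pairwise_diff_matrix(mat)
        expected = amova_oracle(diffs, sizes)
        got = ps._phi_st_from_diffs(diffs, sizes)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_permutation_p_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, size=(5, 20)).astype(np.int8)
        b = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
        f1, p1 = ps.pairwise_fst(a, b, n_perm=200, seed=11)
        # permute rows within each group: statistic and p unchanged
        f2, p2 = ps.pairwise_fst(a[::-1], b[::-1], n_perm=200, seed=11)
        assert f1 == pytest.approx(f2) and p1 == p2

    def test_null_split_mean_near_zero(self):
        # random halves of one panmictic sample: mean Phi_ST ~ 0
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            mat = rng.integers(0, 4, size=(40, 30)).astype(np.int8)
            order = rng.permutation(40)
            f, _ = ps.pairwise_fst(mat[order[:20]], mat[order[20:]])
            vals.append(f)
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 0.01

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            ps.pairwise_fst(aln("ACGT"), aln("ACGT", "ACGA"))


class TestFstMatrix:
    def test_two_groups_consistent(self, toys):
        fst, _ = ps.fst_matrix(
            {"a": toys["fst_fixed_a"], "b": toys["fst_fixed_b"]}
        )
        direct, _ = ps.pairwise_fst(toys["fst_fixed_a"], toys["fst_fixed_b"])
        assert fst.loc["a", "b"] == pytest.approx(direct)
        assert fst.loc["a", "a"] == 0.0
        assert np.allclose(fst.to_numpy(), fst.to_numpy().T)


class TestStatVector:
    def groups_from(self, mats):
        return dict(zip(ps.ABC_GROUP_ORDER, mats))

    def test_length_and_names(self):
        assert len(ps.STAT_VECTOR_NAMES) == 32

    def test_monomorphic_groups(self):
        m = np.zeros((3, 10), dtype=np.int8)
        v = ps.abc_stat_vector(self.groups_from([m, m, m, m]))
        within = v.values[:20].reshape(4, 5)
        assert np.allclose(within, [1, 0, 0, 0, 0])
        between = v.values[20:].reshape(6, 2)
        assert np.allclose(between, 0.0)
        assert v.d_defined == (False, False, False, False)

    def test_composition_matches_individual_calls(self):
        rng = np.random.default_rng(3)
        mats = [rng.integers(0, 4, size=(n, 25)).astype(np.int8) for n in (4, 6, 5, 7)]
        v = ps.abc_stat_vector(self.groups_from(mats))
        for gi, mat in enumerate(mats):
            k = ps.call_haplotypes(mat).k
            h, _ = ps.haplotype_diversity(ps.call_haplotypes(mat).counts)
            pi, _ = ps.mean_pairwise_differences(mat)
            s = ps.segregating_sites(mat)
            d = ps.tajimas_d_value(pi, s, mat.shape[0])
            expected = [k, h, pi, s, d if d is not None else 0.0]
            assert np.allclose(v.values[5 * gi : 5 * gi + 5], expected)
        # first pair block = pairwise fst + between-group mean differences
        f, _ = ps.pairwise_fst(mats[0], mats[1])
        pooled = np.vstack([mats[0], mats[1]])
        diffs = ps.pairwise_diff_matrix(pooled)
        pi_b = diffs[: mats[0].shape[0], mats[0].shape[0] :].mean()
        assert v.values[20] == pytest.approx(f)
        assert v.values[21] == pytest.approx(pi_b)

    def test_missing_group_error(self):
        with pytest.raises(ValueError, match="missing"):
            ps.abc_stat_vector({"ancient_NE": np.zeros((2, 5), dtype=np.int8)})
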