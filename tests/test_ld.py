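"""Pairwise LD, map distances, PLD scores, permutation p-values."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import snpsieve as sv
from snpsieve.ld import (build_ld_profile, default_tag_indices, ld_perm_pvalue,
                         map_distance, pairwise_ld, pld_score)


def _haps_from_counts(ab, aB, Ab, AB):
    """Two haplotype vectors with given joint counts ((0,0),(0,1),(1,0),(1,1))."""
    a = np.r_[np.zeros(ab + aB), np.ones(Ab + AB)].astype(np.int8)
    b = np.r_[np.zeros(ab), np.ones(aB), np.zeros(Ab), np.ones(AB)].astype(np.int8)
    return a, b


@st.composite
def _polymorphic_pair(draw):
    n = draw(st.integers(8, 60))
    a = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)),
                 dtype=np.int8)
    b = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)),
                 dtype=np.int8)
    a[0], a[1], b[2], b[3] = 0, 1, 0, 1  # force both loci polymorphic
    return a, b


class TestPairwiseLd:
    def test_identical_vectors_in_perfect_ld(self):
        a = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        D, dprime, r2 = pairwise_ld(a, a)
        assert dprime == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_counted_example(self):
        # joint haplotype counts AB=40, Ab=10, aB=10, ab=40 out of N=100
        a, b = _haps_from_counts(ab=40, aB=10, Ab=10, AB=40)
        D, dprime, r2 = pairwise_ld(a, b)
        assert D == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)
        assert dprime == pytest.approx(0.6)

    def test_independent_vectors_have_small_r2(self):
        rng = np.random.default_rng(8)
        n = 100
        vals = []
        for _ in range(400):
            a = rng.integers(0, 2, n).astype(np.int8)
            b = rng.integers(0, 2, n).astype(np.int8)
            if 0 < a.sum() < n and 0 < b.sum() < n:
                vals.append(pairwise_ld(a, b)[2])
        # null expectation of the squared correlation is about 1/N
        assert 0.5 / n < np.mean(vals) < 2.0 / n

    def test_monomorphic_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_ld(np.zeros(10, dtype=np.int8),
                        np.array([0, 1] * 5, dtype=np.int8))

    @given(_polymorphic_pair())
    def test_symmetry_range_and_pearson_identity(self, pair):
        a, b = pair
        D1, dp1, r21 = pairwise_ld(a, b)
        D2, dp2, r22 = pairwise_ld(b, a)
        assert dp1 == pytest.approx(dp2)
        assert r21 == pytest.approx(r22)
        assert 0.0 <= dp1 <= 1.0 + 1e-12
        assert 0.0 <= r21 <= 1.0 + 1e-12
        # r^2 equals the squared Pearson correlation of the binary vectors
        assert r21 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-10)


class TestMapDistance:
    def test_basic_cases(self):
        m = np.array([0.0, 0.5, 2.0])
        assert map_distance(m, 0, 0) == 0.0
        assert map_distance(m, 0, 2) == 2.0
        assert map_distance(m, 2, 0) == 2.0

    def test_collinearity_on_monotone_map(self):
        m = np.array([0.0, 0.3, 0.9, 1.4, 2.0])
        for i, k, j in [(0, 2, 4), (1, 2, 3), (0, 1, 3)]:
            assert map_distance(m, i, j) == pytest.approx(
                map_distance(m, i, k) + map_distance(m, k, j))


class TestPldScore:
    @pytest.mark.parametrize("tags, top, expected", [
        ((0.1, 0.5, 0.9, 0.3), 0.4, 0.5),
        ((0.1, 0.5, 0.9, 0.3), 1.0, 0.0),
        ((0.0, 0.0, 0.0), 0.0, 0.0),  # strict inequality
    ])
    def test_examples(self, tags, top, expected):
        assert pld_score(np.array(tags), top) == pytest.approx(expected)

    def test_empty_tag_set_rejected(self):
        with pytest.raises(ValueError):
            pld_score(np.array([]), 0.5)

    def test_monotone_in_top_r2(self):
        rng = np.random.default_rng(0)
        tags = rng.random(30)
        scores = [pld_score(tags, v) for v in np.linspace(0, 1, 21)]
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))


class TestPermPvalue:
    def test_copy_attains_minimal_p(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 80).astype(float)
        p = ld_perm_pvalue(x, x, n_perm=200, seed=9)
        assert p == pytest.approx(1 / 201)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, 50).astype(float)
        z = rng.integers(0, 3, 50).astype(float)
        assert ld_perm_pvalue(x, z, 99, seed=4) == ld_perm_pvalue(x, z, 99, seed=4)

    def test_null_uniformity(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            x = rng.integers(0, 3, 60).astype(float)
            z = rng.integers(0, 3, 60).astype(float)
            if x.std() and z.std():
                ps.append(ld_perm_pvalue(x, z, 99, seed=int(rng.integers(2**31))))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_vector_sentinel(self):
        assert ld_perm_pvalue(np.ones(10), np.arange(10.0) % 3, 99, seed=0) == 1.0


class TestProfile:
    def test_top_hit_self_entries(self, ld_profile):
        t = ld_profile.top_hit_index
        assert ld_profile.r2_to_top[t] == 1.0
        assert ld_profile.dprime_to_top[t] == 1.0
        assert ld_profile.cm_to_top[t] == 0.0
        assert ld_profile.pld[t] == 0.0

    def test_vector_ranges(self, ld_profile):
        assert np.all((ld_profile.r2_to_top >= 0) & (ld_profile.r2_to_top <= 1))
        assert np.all((ld_profile.dprime_to_top >= 0) & (ld_profile.dprime_to_top <= 1))
        assert np.all(ld_profile.cm_to_top >= 0)
        assert np.all((ld_profile.pld >= 0) & (ld_profile.pld <= 1))
        assert np.all((ld_profile.perm_p > 0) & (ld_profile.perm_p <= 1))

    def test_pld_granularity_is_tag_count(self, ld_profile):
        T = ld_profile.n_tags
        scaled = ld_profile.pld * T
        assert np.allclose(scaled, np.round(scaled), atol=1e-9)

    def test_default_tag_count_near_target(self):
        assert 70 <= len(default_tag_indices(2871, target=77)) <= 77
        assert len(default_tag_indices(50, target=77)) == 50

    def test_haplotype_and_dose_fallback_agree(self, cc_dataset, scan_table,
                                               ld_profile):
        dose_only = sv.CaseControlData(
            doses=cc_dataset.doses, phenotype=cc_dataset.phenotype,
            causal_index=cc_dataset.causal_index, snp_ids=cc_dataset.snp_ids,
            positions=cc_dataset.positions, map_cM=cc_dataset.map_cM)
        fallback = build_ld_profile(dose_only, scan_table, n_perm=10, seed=1,
                                    compute_perm=False)
        diff = np.abs(fallback.r2_to_top - ld_profile.r2_to_top)
        assert diff.max() <= 0.05

    def test_monomorphic_snps_get_rank_last_sentinels(self, cc_dataset):
        doses = cc_dataset.doses.copy().astype(float)
        mono = 3 if cc_dataset.causal_index != 3 else 4
        doses[:, mono] = 1.0
        data = sv.CaseControlData(doses=doses, phenotype=cc_dataset.phenotype,
                                  causal_index=cc_dataset.causal_index,
                                  snp_ids=cc_dataset.snp_ids,
                                  positions=cc_dataset.positions,
                                  map_cM=cc_dataset.map_cM)
        table = sv.scan_region(data)
        prof = build_ld_profile(data, table, n_perm=10, seed=2)
        assert prof.r2_to_top[mono] == 0.0
        assert prof.dprime_to_top[mono] == 0.0
        assert np.isinf(prof.cm_to_top[mono])
        assert prof.pld[mono] == 1.0
        assert prof.perm_p[mono] == 1.0
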