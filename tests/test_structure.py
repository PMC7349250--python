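import numpy as np
import pytest

from gbspopgen import (
    PopulationMap,
    SimulationConfig,
    ajk_matrix,
    nei_distance,
    pairwise_fst,
    pca_coords,
    simulate,
)
from gbspopgen.structure import StructureError, wc_fst_components

from conftest import build_matrix


def two_pop_map(n1, n2):
    ids = [f"S{i}" for i in range(n1 + n2)]
    return PopulationMap(
        {s: ("pop1" if i < n1 else "pop2") for i, s in enumerate(ids)}
    )


def longhand_wc_theta(dosage, n1):
    """Independent scalar evaluation of the Weir-Cockerham components."""
    a_sum = b_sum = c_sum = 0.0
    r = 2
    for j in range(dosage.shape[1]):
        groups = [dosage[:n1, j], dosage[n1:, j]]
        ns, ps, hs = [], [], []
        for g in groups:
            g = g[g != -1]
            ns.append(len(g))
            ps.append(g.sum() / (2 * len(g)))
            hs.append((g == 1).sum() / len(g))
        n_bar = sum(ns) / r
        n_c = (sum(ns) - sum(n**2 for n in ns) / sum(ns)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + h_bar / 2
    return a_sum / (a_sum + b_sum + c_sum)


class TestPairwiseFst:
    def test_complete_fixation_is_one(self):
        dosage = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2)]).astype(np.int8)
        gm = build_matrix(dosage)
        fst = pairwise_fst(gm, two_pop_map(4, 4))
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_matches_longhand_component_oracle(self):
        rng = np.random.default_rng(9)
        dosage = rng.choice([0, 1, 2], size=(12, 8))
        gm = build_matrix(dosage)
        fst = pairwise_fst(gm, two_pop_map(7, 5))
        assert fst.values[0, 1] == pytest.approx(longhand_wc_theta(dosage, 7), abs=1e-12)

    def test_invariant_to_sample_order_and_relabeling(self):
        rng = np.random.default_rng(10)
        dosage = rng.choice([0, 1, 2], size=(10, 20))
        gm = build_matrix(dosage)
        pm = two_pop_map(5, 5)
        base = pairwise_fst(gm, pm).values[0, 1]
        # permute samples (keeping labels attached)
        perm = rng.permutation(10)
        gm2 = build_matrix(dosage[perm], sample_ids=[gm.sample_ids[i] for i in perm])
        assert pairwise_fst(gm2, pm).values[0, 1] == pytest.approx(base)
        # flip ref/alt on half the sites
        flipped = dosage.copy()
        flipped[:, ::2] = 2 - flipped[:, ::2]
        gm3 = build_matrix(flipped)
        assert pairwise_fst(gm3, pm).values[0, 1] == pytest.approx(base)

    def test_small_population_fatal(self):
        gm = build_matrix(np.zeros((3, 2)))
        pm = PopulationMap({"S0": "a", "S1": "b", "S2": "b"})
        with pytest.raises(StructureError, match="'a'"):
            pairwise_fst(gm, pm)

    def test_matrix_shape_and_symmetry(self, study_fixture):
        gm, pm, _ = study_fixture
        fst = pairwise_fst(gm, pm)
        assert fst.values.shape == (5, 5)
        assert np.allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        block = np.array([[0, 1, 2, 1]] * 4).T  # same genotypes in both pops
        dosage = np.vstack([block, block]).astype(np.int8)
        gm = build_matrix(dosage)
        d = nei_distance(gm, two_pop_map(4, 4))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_longhand_two_locus_oracle(self):
        # pop1 frequencies p = (0.5, 0.25); pop2 p = (0.25, 0.75)
        pop1 = np.array([[1, 1], [1, 0], [2, 1], [0, 0]])
        pop2 = np.array([[1, 2], [0, 2], [1, 1], [0, 1]])
        gm = build_matrix(np.vstack([pop1, pop2]).astype(np.int8))
        d = nei_distance(gm, two_pop_map(4, 4))
        p1, p2 = np.array([0.5, 0.25]), np.array([0.25, 0.75])
        jx = np.mean(p1**2 + (1 - p1) ** 2)
        jy = np.mean(p2**2 + (1 - p2) ** 2)
        jxy = np.mean(p1 * p2 + (1 - p1) * (1 - p2))
        assert d.values[0, 1] == pytest.approx(-np.log(jxy / np.sqrt(jx * jy)))

    def test_positive_when_frequencies_differ(self, study_fixture):
        gm, pm, _ = study_fixture
        d = nei_distance(gm, pm)
        off = d.values[np.triu_indices(5, 1)]
        assert (off > 0).all()

    def test_nexus_export_contains_labels(self, study_fixture):
        gm, pm, _ = study_fixture
        nex = nei_distance(gm, pm).to_nexus()
        assert nex.startswith("#NEXUS")
        for pop in pm.populations():
            assert pop in nex


class TestAjk:
    def test_centered_heterozygotes_give_zero(self):
        # every individual heterozygous at every site, p = 0.5
        gm = build_matrix(np.ones((4, 6), dtype=np.int8))
        a = ajk_matrix(gm, min_sites=1)
        off = a.values[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.0)

    def test_diagonal_arithmetic(self):
        # two samples [0, 1] at one site -> p = 0.25; diagonal term of the
        # x = 0 sample is (0 - 0 + 2 * 0.0625) / 0.375 = 1/3
        gm = build_matrix(np.array([[0], [1]], dtype=np.int8))
        a = ajk_matrix(gm, min_sites=1)
        assert a.values[0, 0] == pytest.approx(1 / 3)

    def test_symmetric_and_permutation_invariant(self):
        rng = np.random.default_rng(11)
        dosage = rng.choice([0, 1, 2], size=(8, 200))
        gm = build_matrix(dosage)
        a = ajk_matrix(gm)
        assert np.allclose(a.values, a.values.T, equal_nan=True)
        # permuting variant columns changes nothing
        gm2 = build_matrix(dosage[:, rng.permutation(200)])
        assert np.allclose(ajk_matrix(gm2).values, a.values, equal_nan=True)

    def test_min_sites_flags_pairs(self):
        gm = build_matrix(np.array([[0, 1], [1, 0], [2, 1]], dtype=np.int8))
        a = ajk_matrix(gm, min_sites=100)
        assert np.isnan(a.values[0, 1])

    def test_unrelated_panmictic_mean_near_zero(self, study_fixture):
        gm, _, _ = study_fixture
        a = ajk_matrix(gm)
        off = a.off_diagonal()
        se = off.std(ddof=1) / np.sqrt(len(off))
        # samples share one small ancestral pool; mean off-diagonal ~ 0
        assert abs(np.nanmean(off)) < 5 * max(se, 0.005)


class TestPca:
    def test_duplicated_individuals_identical_coords(self):
        rng = np.random.default_rng(12)
        row = rng.choice([0, 1, 2], 30)
        dosage = np.vstack([row, row, rng.choice([0, 1, 2], (4, 30))]).astype(np.int8)
        gm = build_matrix(dosage)
        pca = pca_coords(gm, n_axes=3)
        assert np.allclose(pca.coords[0], pca.coords[1], atol=1e-8)

    def test_planted_clusters_separate_on_axis_one(self):
        rng = np.random.default_rng(13)
        # two groups with shifted allele frequencies
        g1 = (rng.random((15, 300)) < 0.2).astype(np.int8) + (
            rng.random((15, 300)) < 0.2
        ).astype(np.int8)
        g2 = (rng.random((15, 300)) < 0.6).astype(np.int8) + (
            rng.random((15, 300)) < 0.6
        ).astype(np.int8)
        gm = build_matrix(np.vstack([g1, g2]))
        pca = pca_coords(gm, n_axes=2)
        from sklearn.metrics import silhouette_score

        labels = [0] * 15 + [1] * 15
        assert silhouette_score(pca.coords[:, :1], labels) > 0

    def test_variance_fractions_match_dense_eigensolver(self):
        rng = np.random.default_rng(14)
        dosage = rng.choice([0, 1, 2], size=(10, 20))
        gm = build_matrix(dosage)
        pca = pca_coords(gm, n_axes=5)
        x = dosage.astype(float)
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        w = np.linalg.eigvalsh((x.T @ x) / (10 - 1))[::-1]
        expect = w / w.sum()
        assert np.allclose(pca.variance_fractions, expect[:5], atol=1e-8)
        assert pca.variance_fractions.sum() <= 1 + 1e-9
        assert (np.diff(pca.variance_fractions) <= 1e-12).all()

    def test_axes_truncated_with_warning(self):
        rng = np.random.default_rng(15)
        gm = build_matrix(rng.choice([0, 1, 2], size=(4, 10)))
        pca = pca_coords(gm, n_axes=50)
        assert pca.coords.shape[1] <= 4
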