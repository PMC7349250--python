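import numpy as np
import pandas as pd
import pytest

from gbspopgen import MISSING, collect_pairs, decay_summary, pair_r2, phased_r2
from gbspopgen.ld import DEFAULT_BINS, LDError, _pairwise_r2_matrix

from conftest import build_matrix


class TestPairR2:
    def test_self_pair_is_one(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert pair_r2(g, g.copy()) == pytest.approx(1.0)

    def test_complete_association_phased(self):
        # haplotypes AB, ab, AB, ab
        ha = np.array([1, 0, 1, 0])
        hb = np.array([1, 0, 1, 0])
        assert phased_r2(ha, hb) == pytest.approx(1.0)

    def test_phased_quarter_frequencies(self):
        # all four haplotypes equally frequent -> D = 0
        ha = np.array([1, 1, 0, 0])
        hb = np.array([1, 0, 1, 0])
        assert phased_r2(ha, hb) == pytest.approx(0.0)

    def test_composite_equals_phased_when_all_homozygous(self):
        rng = np.random.default_rng(0)
        ha = rng.integers(0, 2, 30)
        hb = (ha + (rng.random(30) < 0.2)) % 2
        dos_a, dos_b = 2 * ha, 2 * hb  # each individual homozygous
        haps_a = np.repeat(ha, 2)
        haps_b = np.repeat(hb, 2)
        assert pair_r2(dos_a, dos_b) == pytest.approx(phased_r2(haps_a, haps_b))

    def test_ref_alt_swap_invariance(self):
        rng = np.random.default_rng(1)
        ga = rng.choice([0, 1, 2], 40)
        gb = rng.choice([0, 1, 2], 40)
        base = pair_r2(ga, gb)
        assert pair_r2(2 - ga, gb) == pytest.approx(base)
        assert pair_r2(ga, 2 - gb) == pytest.approx(base)

    def test_monomorphic_site_undefined(self):
        assert np.isnan(pair_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 1])))

    def test_too_few_complete_cells_undefined(self):
        ga = np.array([0, 2, MISSING, MISSING])
        gb = np.array([0, 2, 1, 1])
        assert np.isnan(pair_r2(ga, gb))

    def test_length_mismatch_fatal(self):
        with pytest.raises(LDError, match="mismatch"):
            pair_r2(np.array([0, 1]), np.array([0, 1, 2]))


class TestPairwiseMatrix:
    def test_matches_per_pair_corrcoef_with_missing(self):
        rng = np.random.default_rng(2)
        dosage = rng.choice([0, 1, 2, MISSING], size=(12, 15), p=[0.4, 0.3, 0.2, 0.1])
        r2 = _pairwise_r2_matrix(dosage)
        for a in range(15):
            for b in range(a + 1, 15):
                expect = pair_r2(dosage[:, a], dosage[:, b])
                got = r2[a, b]
                if np.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-10)


class TestCollectPairs:
    def test_three_snps_three_pairs(self):
        rng = np.random.default_rng(3)
        gm = build_matrix(rng.choice([0, 1, 2], (10, 3)))
        pairs, _ = collect_pairs(gm)
        assert len(pairs) == 3

    def test_distance_cutoff_excludes(self):
        rng = np.random.default_rng(4)
        gm = build_matrix(rng.choice([0, 1, 2], (10, 2)), positions=[1_000, 60_000])
        pairs, _ = collect_pairs(gm, max_distance_bp=40_000)
        assert len(pairs) == 0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        chroms = ["chr1"] * 60 + ["chr2"] * 40
        positions = sorted(rng.choice(10**6, 60, replace=False)) + sorted(
            rng.choice(10**6, 40, replace=False)
        )
        gm = build_matrix(
            rng.choice([0, 1, 2], (8, 100)), chroms=chroms, positions=positions
        )
        max_d = 400_000
        pairs, n_undef = collect_pairs(gm, max_distance_bp=max_d)
        brute = 0
        for c in ("chr1", "chr2"):
            idx = [i for i, v in enumerate(gm.variants) if v.chrom == c]
            for x in range(len(idx)):
                for y in range(x + 1, len(idx)):
                    a, b = idx[x], idx[y]
                    if abs(gm.variants[b].pos - gm.variants[a].pos) <= max_d:
                        brute += 1
        assert len(pairs) + n_undef == brute

    def test_undefined_pairs_counted_not_returned(self):
        dosage = np.array([[0, 1], [0, 0], [0, 2], [0, 1]])  # site 0 monomorphic
        gm = build_matrix(dosage)
        pairs, n_undef = collect_pairs(gm)
        assert len(pairs) == 0 and n_undef == 1


class TestDecaySummary:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["distance_bp", "r2"])

    def test_singleton_bin(self):
        df, _ = decay_summary(self._pairs([(10_000, 0.5)]))
        row = df[df["label"] == "0-40 kb"].iloc[0]
        assert row["n_pairs"] == 1
        assert row["mean_r2"] == 0.5
        assert row["sd_r2"] == 0.0
        assert row["frac_gt_02"] == 1.0

    def test_half_open_boundary(self):
        df, _ = decay_summary(self._pairs([(40_000, 0.1)]))
        assert df[df["label"] == "0-40 kb"].iloc[0]["n_pairs"] == 0
        assert df[df["label"] == "40-60 kb"].iloc[0]["n_pairs"] == 1

    def test_planted_values_recomputed(self):
        rng = np.random.default_rng(6)
        rows = [(int(d), float(r)) for d, r in
                zip(rng.integers(0, 92_000_000, 500), rng.random(500))]
        df, n_unbinned = decay_summary(self._pairs(rows))
        assert n_unbinned == 0
        # independent accumulation
        for _, b in df.iterrows():
            vals = [r for d, r in rows if b["lo_bp"] <= d < b["hi_bp"]]
            assert b["n_pairs"] == len(vals)
            if vals:
                assert b["mean_r2"] == pytest.approx(np.mean(vals))
                assert b["frac_gt_03"] == pytest.approx(np.mean(np.array(vals) > 0.3))
        assert df["n_pairs"].sum() == 500

    def test_unbinned_tally(self):
        df, n_unbinned = decay_summary(self._pairs([(99_000_000, 0.5)]))
        assert n_unbinned == 1 and df["n_pairs"].sum() == 0

    def test_overlapping_bins_rejected(self):
        with pytest.raises(LDError):
            decay_summary(self._pairs([(1, 0.1)]), bins=[(0, 10, "a"), (5, 20, "b")])

    def test_bins_partition_default_scheme(self):
        los = [b[0] for b in DEFAULT_BINS]
        his = [b[1] for b in DEFAULT_BINS]
        assert los[1:] == his[:-1]  # contiguous, non-overlapping


class TestDecayOnSimulatedData:
    def test_mean_r2_nonincreasing_with_distance(self, study_fixture):
        # LD decays with distance; allow one inversion between adjacent bins
        gm, _, _ = study_fixture
        pairs, _ = collect_pairs(gm, max_distance_bp=240_000)
        bins = [(0, 20_000, "a"), (20_000, 60_000, "b"), (60_000, 240_000, "c")]
        df, _ = decay_summary(pairs, bins)
        means = df["mean_r2"].to_numpy()
        inversions = int((np.diff(means) > 0).sum())
        assert inversions <= 1
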