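"""Profile extraction, normalization, orientation, bins, landmarks, trends."""
import numpy as np
import pytest

from sarcotrace import profiles, synthdata
from sarcotrace.stack import VoxelStack
from sarcotrace.trace import CandidateSarcomere
from sarcotrace.zdisc import ZDisc


def _profile(channels, length=2.0, n=100):
    return profiles.SarcomereProfile(
        s_grid=np.linspace(0, 1, n), channels=channels, length=length)


def _division_profile_sets(lengths, **kwargs):
    """Oriented, normalized mean profiles per length from the generator."""
    defaults = dict(n_samples=20, noise_sd=0.02, seed=0)
    defaults.update(kwargs)
    sets = synthdata.make_division_profiles(list(lengths), **defaults)
    out = []
    for ds in sets:
        members = []
        for rep in ds.replicates:
            p = profiles.SarcomereProfile(s_grid=ds.s_grid, channels=rep,
                                          length=ds.length)
            members.append(profiles.orient_profile(profiles.normalize_profile(p)))
        mean = profiles.mean_profile(profiles.LengthBin(0, 99, members))
        out.append((ds, {ch: mu for ch, (mu, _) in mean.items()}))
    return out


class TestExtract:
    def _stack_and_sarcomere(self, fill):
        vol = np.stack([np.full((5, 20, 40), fill)] * 4)
        stack = VoxelStack(vol, (0.1, 0.1, 0.2),
                           ("actin", "sls", "mhc", "obscurin"))
        discs = [ZDisc(0, 0.5, 1.0, 0.4, 3, 1.0), ZDisc(1, 2.5, 1.0, 0.4, 3, 1.0)]
        cand = CandidateSarcomere(id_a=0, id_b=1, length=2.0, axis_angle=0.0)
        return stack, discs, cand

    def test_constant_channel_gives_constant_profile(self):
        stack, discs, cand = self._stack_and_sarcomere(0.7)
        prof = profiles.extract_profile(cand, stack, discs, n_samples=50)
        for ch in stack.channel_names:
            assert np.allclose(prof.channels[ch], 0.7)

    def test_linear_ramp_sampled_exactly(self):
        vol = np.broadcast_to(np.arange(40, dtype=float), (5, 20, 40)).copy()
        stack = VoxelStack(vol[None], (0.1, 0.1, 0.2), ("actin",))
        discs = [ZDisc(0, 0.5, 1.0, 0.4, 3, 1.0), ZDisc(1, 2.5, 1.0, 0.4, 3, 1.0)]
        cand = CandidateSarcomere(id_a=0, id_b=1, length=2.0, axis_angle=0.0)
        prof = profiles.extract_profile(cand, stack, discs, n_samples=21,
                                        channels=("actin",))
        expected = np.linspace(5.0, 25.0, 21)  # voxel index along the segment
        assert np.allclose(prof.channels["actin"], expected, atol=1e-9)

    def test_peak_positions_match_rendered_bands(self, small_stack):
        stack, gt = small_stack
        chain = gt.zdisc_positions[0]
        discs = [ZDisc(0, *chain[1], 3, 1.0), ZDisc(1, *chain[2], 3, 1.0)]
        cand = CandidateSarcomere(id_a=0, id_b=1, length=2.0, axis_angle=0.0)
        prof = profiles.extract_profile(cand, stack, discs, n_samples=100)
        # Obscurin M-band peaks at the sarcomere center
        assert abs(np.argmax(prof.channels["obscurin"]) / 99 - 0.5) <= 0.02


class TestNormalize:
    def test_constant_profile_normalizes_to_one(self):
        p = _profile({"sls": np.full(100, 3.0)})
        out = profiles.normalize_profile(p)
        assert np.allclose(out.channels["sls"], 1.0)

    def test_single_spike_matches_hand_computed_moving_average(self):
        y = np.zeros(100)
        y[50] = 5.0
        out = profiles.normalize_profile(_profile({"sls": y}))
        # window 10 → smoothed max is the spike averaged over 10 samples
        assert out.channels["sls"][50] == pytest.approx(10.0)

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0.1, 2.0, 100)
        a = profiles.normalize_profile(_profile({"sls": y}))
        b = profiles.normalize_profile(_profile({"sls": 7.3 * y}))
        assert np.allclose(a.channels["sls"], b.channels["sls"])
        twice = profiles.normalize_profile(a)
        assert np.allclose(twice.channels["sls"], a.channels["sls"])

    def test_all_zero_channel_flagged_not_divided(self):
        out = profiles.normalize_profile(_profile({"sls": np.zeros(100)}))
        assert np.allclose(out.channels["sls"], 0.0)
        assert any(f.startswith("all_zero") for f in out.flags)


class TestOrient:
    def test_right_heavy_obscurin_is_reversed(self):
        obs = np.zeros(100)
        obs[75] = 1.0
        out = profiles.orient_profile(_profile({"obscurin": obs}))
        assert np.argmax(out.channels["obscurin"]) == 24

    def test_symmetric_profile_kept_as_is(self):
        obs = np.zeros(101)
        obs[50] = 1.0
        marker = np.arange(101, dtype=float)
        out = profiles.orient_profile(
            _profile({"obscurin": obs, "mhc": marker}, n=101))
        assert np.array_equal(out.channels["mhc"], marker)

    def test_left_half_total_always_dominates(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            obs = rng.uniform(0, 1, 100)
            out = profiles.orient_profile(_profile({"obscurin": obs}))
            y = out.channels["obscurin"]
            s = out.s_grid
            assert y[s <= 0.5].sum() >= y[s > 0.5].sum()


class TestBins:
    def test_regular_bin_membership(self):
        bins, _ = profiles.bin_by_length([_profile({}, length=1.9)])
        assert len(bins[0].members) == 1

    def test_half_open_convention_at_edge(self):
        bins, _ = profiles.bin_by_length([_profile({}, length=2.4)])
        by_edge = {(b.low, b.high): len(b.members) for b in bins}
        assert by_edge[(2.4, 2.6)] == 1
        assert by_edge[(2.2, 2.4)] == 0

    def test_counts_match_recount_oracle(self):
        rng = np.random.default_rng(3)
        lengths = rng.uniform(1.5, 3.8, 1000)
        ps = [_profile({}, length=l) for l in lengths]
        bins, excluded = profiles.bin_by_length(ps)
        edges = profiles.DEFAULT_BIN_EDGES
        for b in bins:
            assert len(b.members) == int(np.sum((lengths >= b.low) & (lengths < b.high)))
        assert excluded == int(np.sum((lengths < edges[0]) | (lengths >= edges[-1])))

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValueError):
            profiles.bin_by_length([], edges=(2.0, 1.8))


class TestMeanProfile:
    def test_single_member_mean_is_member_sd_zero(self):
        y = np.linspace(0, 1, 50)
        b = profiles.LengthBin(1.8, 2.2, [_profile({"sls": y}, n=50)])
        mu, sd = profiles.mean_profile(b)["sls"]
        assert np.allclose(mu, y) and np.allclose(sd, 0.0)

    def test_mirror_pair_identical_after_orientation(self):
        obs = np.zeros(100)
        obs[30] = 1.0
        p1 = profiles.orient_profile(_profile({"obscurin": obs}))
        p2 = profiles.orient_profile(_profile({"obscurin": obs[::-1].copy()}))
        _, sd = profiles.mean_profile(profiles.LengthBin(0, 9, [p1, p2]))["obscurin"]
        assert np.allclose(sd, 0.0)

    def test_noise_averages_down_with_sqrt_n(self):
        rng = np.random.default_rng(4)
        clean = np.sin(np.linspace(0, np.pi, 100)) + 1.0
        n = 400
        members = [_profile({"sls": clean + rng.normal(0, 0.1, 100)}) for _ in range(n)]
        mu, _ = profiles.mean_profile(profiles.LengthBin(0, 9, members))["sls"]
        assert np.abs(mu - clean).max() < 5 * 0.1 / np.sqrt(n)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            profiles.mean_profile(profiles.LengthBin(0, 1, []))


class TestLandmarks:
    def test_division_landmarks_recovered_within_one_sample(self):
        for ds, mean in _division_profile_sets([2.6, 3.0]):
            lp = profiles.find_landmark_peaks(mean, ds.length)
            assert lp.flags == []
            for name, true in ds.landmarks_um.items():
                assert abs(lp.positions[name] - true) <= ds.length / 100

    def test_landmark_ordering_invariant(self):
        for ds, mean in _division_profile_sets([2.5, 2.8, 3.2]):
            lp = profiles.find_landmark_peaks(mean, ds.length)
            p = lp.positions
            assert p["Z1"] < p["M1"] <= p["M2"] < p["Z2"]

    def test_regular_profile_flags_single_peak(self):
        s = np.linspace(0, 1, 100)
        channels = {
            "obscurin": np.exp(-0.5 * ((s - 0.5) / 0.04) ** 2),
            "sls": np.exp(-0.5 * (s / 0.04) ** 2) + np.exp(-0.5 * ((s - 1) / 0.04) ** 2),
        }
        lp = profiles.find_landmark_peaks(channels, 2.0)
        assert "single_obscurin_peak" in lp.flags

    def test_mirror_symmetry_gives_equal_block_offsets(self):
        (item,) = _division_profile_sets([3.0], asymmetry=0.5, noise_sd=0.0,
                                         n_samples=1)
        ds, mean = item
        lp = profiles.find_landmark_peaks(mean, ds.length)
        assert lp.distance("Z1-M1") == pytest.approx(lp.distance("M2-Z2"), abs=0.02)


class TestTrends:
    def test_rigid_block_slopes(self):
        peaks = [profiles.find_landmark_peaks(mean, ds.length)
                 for ds, mean in _division_profile_sets([2.5, 2.8, 3.2])]
        slopes = profiles.interpeak_trends(peaks)
        assert slopes["M1-S2"] == pytest.approx(1.0, abs=0.05)
        assert slopes["M2-S1"] == pytest.approx(1.0, abs=0.05)
        assert abs(slopes["Z1-M1"]) <= 0.05
        assert abs(slopes["Z2-M2"]) <= 0.05

    def test_slopes_equal_closed_form_ols(self):
        peaks = [profiles.find_landmark_peaks(mean, ds.length)
                 for ds, mean in _division_profile_sets([2.5, 2.8, 3.2])]
        slopes = profiles.interpeak_trends(peaks, pairs=("M1-S2",))
        x = np.array([p.length for p in peaks])
        y = np.array([p.distance("M1-S2") for p in peaks])
        beta = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert slopes["M1-S2"] == pytest.approx(beta, abs=1e-12)

    def test_fewer_than_three_bins_rejected(self):
        peaks = [profiles.find_landmark_peaks(mean, ds.length)
                 for ds, mean in _division_profile_sets([2.5, 2.8])]
        with pytest.raises(ValueError):
            profiles.interpeak_trends(peaks)


class TestNeighborAmounts:
    def test_identical_sarcomeres_give_unit_ratio(self):
        y = np.full(100, 2.0)
        p = _profile({"mhc": y})
        assert profiles.neighbor_normalized_amount(p, p, p, "mhc") == pytest.approx(1.0)

    def test_doubled_center_gives_ratio_two(self):
        nb = _profile({"mhc": np.full(100, 1.0)})
        center = _profile({"mhc": np.full(100, 2.0)})
        assert profiles.neighbor_normalized_amount(center, nb, nb, "mhc") == pytest.approx(2.0)

    def test_missing_neighbor_excluded(self):
        p = _profile({"mhc": np.ones(100)})
        assert profiles.neighbor_normalized_amount(p, None, p, "mhc") is None

    def test_recruitment_makes_ratio_grow_with_length(self):
        sets = synthdata.make_division_profiles([2.5, 2.8, 3.2], noise_sd=0.0,
                                                recruitment=0.4)
        nb = _profile({"mhc": np.full(100, 0.5)}, length=2.0)
        ratios = []
        for ds in sets:
            center = profiles.SarcomereProfile(s_grid=ds.s_grid,
                                               channels=ds.replicates[0],
                                               length=ds.length)
            ratios.append(profiles.neighbor_normalized_amount(center, nb, nb, "mhc"))
        assert ratios[0] < ratios[1] < ratios[2]
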