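"""Sarcomere candidate generation, scoring, selection, chains, curation."""
import io

import numpy as np
import pandas as pd
import pytest

from sarcotrace import synthdata, trace
from sarcotrace.stack import VoxelStack
from sarcotrace.zdisc import ZDisc


def _discs(positions):
    return [ZDisc(id=i, x=p[0], y=p[1], z=p[2], n_supporting_slices=3,
                  mean_intensity=1.0) for i, p in enumerate(positions)]


AXIS_X = np.array([1.0, 0.0, 0.0])


class TestCandidatePairs:
    def test_pair_within_reach_along_axis(self):
        cands = trace.candidate_pairs(_discs([(0, 0, 0), (2, 0, 0)]), axis=AXIS_X)
        assert len(cands) == 1
        assert cands[0].length == pytest.approx(2.0)

    def test_pair_beyond_search_distance_dropped(self):
        assert trace.candidate_pairs(_discs([(0, 0, 0), (4, 0, 0)]), axis=AXIS_X) == []

    def test_pair_outside_angular_cone_dropped(self):
        # 45° off-axis at half_angle 30° is excluded, 20° off-axis kept
        steep = _discs([(0, 0, 0), (1.0, 1.0, 0)])
        shallow = _discs([(0, 0, 0), (1.0, 0.36, 0)])
        assert trace.candidate_pairs(steep, axis=AXIS_X, half_angle=30) == []
        assert len(trace.candidate_pairs(shallow, axis=AXIS_X, half_angle=30)) == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 6, (15, 3))
        discs = _discs(pos)
        got = {c.key for c in trace.candidate_pairs(discs, axis=AXIS_X, half_angle=40)}
        expected = set()
        cos_min = np.cos(np.deg2rad(40))
        for i in range(15):
            for j in range(i + 1, 15):
                sep = pos[j] - pos[i]
                d = np.linalg.norm(sep)
                if 0 < d <= 3.5 and abs(sep[0] / d) >= cos_min:
                    expected.add((i, j) if sep[0] > 0 else (j, i))
        assert got == expected

    def test_fewer_than_two_discs(self):
        assert trace.candidate_pairs(_discs([(0, 0, 0)])) == []


def _uniform_stack(actin=1.0, obscurin=0.0, shape=(5, 20, 40)):
    vol = np.stack([np.full(shape, actin), np.zeros(shape),
                    np.zeros(shape), np.full(shape, obscurin)])
    return VoxelStack(vol, (0.1, 0.1, 0.2), ("actin", "sls", "mhc", "obscurin"))


class TestScoring:
    def test_constant_one_actin_constant_zero_obscurin(self):
        stack = _uniform_stack(actin=1.0, obscurin=0.0)
        discs = _discs([(0.5, 1.0, 0.4), (2.5, 1.0, 0.4)])
        (cand,) = trace.candidate_pairs(discs, axis=AXIS_X)
        trace.score_candidates([cand], stack, discs, normalize=False)
        assert cand.score == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_raw_score_is_linear_in_intensity(self, c):
        stack = _uniform_stack(actin=c, obscurin=c)
        discs = _discs([(0.5, 1.0, 0.4), (2.5, 1.0, 0.4)])
        (cand,) = trace.candidate_pairs(discs, axis=AXIS_X)
        trace.score_candidates([cand], stack, discs, normalize=False)
        assert cand.score == pytest.approx(2 * c)
        # normalized score is scale-free
        trace.score_candidates([cand], stack, discs, normalize=True)
        assert cand.score == pytest.approx(2.0)

    def test_true_sarcomere_outscores_background_segment(self, small_stack):
        stack, gt = small_stack
        chain = gt.zdisc_positions[0]
        true_discs = _discs([chain[1], chain[2]])
        bg = [(chain[1][0], chain[1][1] + 0.6, chain[1][2]),
              (chain[2][0], chain[2][1] + 0.6, chain[2][2])]
        bg_discs = _discs(bg)
        (true_c,) = trace.candidate_pairs(true_discs, axis=AXIS_X)
        (bg_c,) = trace.candidate_pairs(bg_discs, axis=AXIS_X)
        trace.score_candidates([true_c], stack, true_discs)
        trace.score_candidates([bg_c], stack, bg_discs)
        assert true_c.score > bg_c.score


def _cand(a, b, length, score):
    c = trace.CandidateSarcomere(id_a=a, id_b=b, length=length, axis_angle=0.0)
    c.score = score
    return c


class TestSelection:
    def test_collinear_chain_fully_accepted(self):
        cands = [_cand(0, 1, 2.0, 3.0), _cand(1, 2, 2.0, 2.5)]
        assert {c.key for c in trace.select_sarcomeres(cands)} == {(0, 1), (1, 2)}

    def test_branch_resolved_toward_higher_score(self):
        # two candidates leave A toward the same (positive) side: B wins
        cands = [_cand(0, 1, 2.0, 3.0), _cand(0, 2, 2.0, 2.0)]
        assert [c.key for c in trace.select_sarcomeres(cands)] == [(0, 1)]

    def test_opposite_sides_may_coexist(self):
        cands = [_cand(0, 1, 2.0, 3.0), _cand(2, 0, 2.0, 2.0)]
        assert len(trace.select_sarcomeres(cands)) == 2

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(5)
        cands = [_cand(i, j, rng.uniform(1.5, 3), rng.uniform(0, 2))
                 for i in range(6) for j in range(i + 1, 6)]
        base = [c.key for c in trace.select_sarcomeres(cands)]
        for _ in range(5):
            rng.shuffle(cands)
            assert [c.key for c in trace.select_sarcomeres(cands)] == base

    def test_matches_lexicographic_subset_oracle(self):
        from itertools import combinations

        def feasible(subset):
            slots = set()
            for c in subset:
                new = {(c.id_a, +1), (c.id_b, -1)}
                if new & slots:
                    return False
                slots |= new
            return True

        rng = np.random.default_rng(17)
        for trial in range(8):
            n = 10
            keys = list(combinations(range(n), 2))
            rng.shuffle(keys)
            cands = [_cand(a, b, rng.uniform(1.5, 3.4), round(rng.uniform(0, 3), 6))
                     for a, b in keys[:12]]
            got = {c.key for c in trace.select_sarcomeres(cands)}
            # oracle: over all feasible subsets, the inclusion vector that is
            # lexicographically maximal in descending-score candidate order
            order = sorted(cands, key=lambda c: (-c.score, c.length, c.key))
            best = None
            for r in range(len(order) + 1):
                for subset in combinations(order, r):
                    if feasible(subset):
                        vec = tuple(int(c in subset) for c in order)
                        if best is None or vec > best[0]:
                            best = (vec, subset)
            assert got == {c.key for c in best[1]}


class TestAssembly:
    def test_single_chain(self):
        discs = _discs([(i * 2.0, 0, 0) for i in range(6)])
        cands = [_cand(i, i + 1, 2.0, 1.0) for i in range(5)]
        fibs = trace.assemble_myofibrils(cands, discs, AXIS_X)
        assert len(fibs) == 1
        assert fibs[0].zdisc_ids == [0, 1, 2, 3, 4, 5]

    def test_two_disjoint_chains(self):
        discs = _discs([(i * 2.0, 0, 0) for i in range(4)]
                       + [(i * 2.0, 3, 0) for i in range(3)])
        cands = [_cand(0, 1, 2, 1), _cand(1, 2, 2, 1), _cand(2, 3, 2, 1),
                 _cand(4, 5, 2, 1), _cand(5, 6, 2, 1)]
        fibs = trace.assemble_myofibrils(cands, discs, AXIS_X)
        assert sorted(len(f.sarcomeres) for f in fibs) == [2, 3]

    def test_cycle_rejected(self):
        discs = _discs([(0, 0, 0), (2, 0, 0), (1, 1, 0)])
        cands = [_cand(0, 1, 2, 1), _cand(1, 2, 1.5, 1), _cand(2, 0, 1.5, 1)]
        with pytest.raises(ValueError, match="cycle"):
            trace.assemble_myofibrils(cands, discs, AXIS_X)

    def test_ground_truth_chains_recovered(self, noisy_detection):
        stack, gt, discs, _ = noisy_detection
        axis = trace.fiber_axis(discs)
        cands = trace.candidate_pairs(discs, axis=axis)
        trace.score_candidates(cands, stack, discs)
        accepted = trace.select_sarcomeres(cands)
        fibs = trace.assemble_myofibrils(accepted, discs, axis)
        assert len(fibs) == len(gt.zdisc_positions)
        assert sorted(len(f.sarcomeres) for f in fibs) == sorted(
            len(c) for c in gt.sarcomere_lengths)


class TestCuration:
    def _accepted(self):
        return [_cand(0, 1, 2.0, 1.0), _cand(1, 2, 1.7, 1.0),
                _cand(2, 3, 2.5, 1.0), _cand(3, 4, 2.1, 1.0)]

    def test_no_decisions_applies_length_filter_only(self):
        curated, report = trace.apply_curation(self._accepted())
        assert {c.key for c in curated} == {(0, 1), (2, 3), (3, 4)}
        assert report["n_rejected_short"] == 1

    def test_manual_rejection_bookkeeping(self):
        decisions = pd.DataFrame({"sarcomere_id": ["0-1"], "decision": ["reject"]})
        curated, report = trace.apply_curation(self._accepted(), decisions)
        assert {c.key for c in curated} == {(2, 3), (3, 4)}
        assert report["removed_fraction"] == pytest.approx(0.5)

    def test_reject_all_empties_output(self):
        decisions = pd.DataFrame({
            "sarcomere_id": ["0-1", "1-2", "2-3", "3-4"],
            "decision": ["reject"] * 4})
        curated, _ = trace.apply_curation(self._accepted(), decisions)
        assert curated == []

    def test_unknown_id_rejected_with_line_number(self):
        decisions = pd.DataFrame({"sarcomere_id": ["9-9"], "decision": ["reject"]})
        with pytest.raises(ValueError, match="line 2"):
            trace.apply_curation(self._accepted(), decisions)

    def test_csv_round_trip(self):
        csv = io.StringIO("sarcomere_id,decision\n2-3,reject\n")
        curated, _ = trace.apply_curation(self._accepted(), csv)
        assert {c.key for c in curated} == {(0, 1), (3, 4)}


class TestEndToEndLengths:
    def test_noiseless_lengths_within_tolerance(self, small_stack):
        from sarcotrace import zdisc as zd
        stack, gt = small_stack
        discs = zd.detect_zdiscs(stack)
        axis = trace.fiber_axis(discs)
        cands = trace.candidate_pairs(discs, axis=axis)
        trace.score_candidates(cands, stack, discs)
        accepted = trace.select_sarcomeres(cands)
        got = sorted(s.length for s in accepted)
        want = sorted(gt.all_lengths())
        assert len(got) == len(want)
        assert max(abs(a - b) for a, b in zip(got, want)) < 0.05
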