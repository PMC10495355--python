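"""Link scoring, optimal assignment, and track assembly."""

import itertools

import numpy as np
import pytest

from myxotrack.tracking import (DEFAULT_AHP_MATRIX, ahp_weights,
                                assemble_tracks, consistency_ratio,
                                link_frames, masks_from_labels, score_links,
                                track_label_stack)


def brute_force_best_assignment(candidates, min_score):
    """Enumerate all one-to-one assignments; return the maximal total score."""
    adm = [c for c in candidates if c.score >= min_score]
    ls_t = sorted({c.mask_t.label for c in adm})
    ls_t1 = sorted({c.mask_t1.label for c in adm})
    score = {(c.mask_t.label, c.mask_t1.label): c.score for c in adm}
    best = 0.0
    for k in range(min(len(ls_t), len(ls_t1)) + 1):
        for subset in itertools.combinations(ls_t, k):
            for perm in itertools.permutations(ls_t1, k):
                pairs = list(zip(subset, perm))
                if all(p in score for p in pairs):
                    best = max(best, sum(score[p] for p in pairs))
    return best


def _labels_with_squares(positions, shape=(64, 64), size=6):
    img = np.zeros(shape, np.uint16)
    for lab, (r, c) in positions.items():
        img[r:r + size, c:c + size] = lab
    return img


class TestAHP:
    def test_all_ones_matrix_gives_uniform_weights(self):
        w = ahp_weights(np.ones((3, 3)))
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_default_matrix_is_consistent_and_ranks_overlap_first(self):
        assert consistency_ratio(DEFAULT_AHP_MATRIX) < 0.1
        w = ahp_weights(DEFAULT_AHP_MATRIX)
        assert w[0] > w[1] > w[2]
        assert w.sum() == pytest.approx(1.0)

    def test_non_reciprocal_matrix_rejected(self):
        bad = np.array([[1.0, 2.0, 3.0], [1.0, 1.0, 2.0], [1 / 3, 0.5, 1.0]])
        with pytest.raises(ValueError, match="reciprocal"):
            ahp_weights(bad)
        with pytest.raises(ValueError, match="positive"):
            ahp_weights(np.array([[1.0, -2.0], [-0.5, 1.0]]))


class TestScoreLinks:
    def test_identical_frames_score_one_with_self(self):
        img = _labels_with_squares({1: (10, 10), 2: (40, 40)})
        m_t = masks_from_labels(img, 0)
        m_t1 = masks_from_labels(img, 1)
        cands = score_links(m_t, m_t1)
        for mk in m_t:
            own = [c for c in cands if c.mask_t.label == mk.label
                   and c.mask_t1.label == mk.label]
            assert own and own[0].score == pytest.approx(1.0)
            best = max((c for c in cands if c.mask_t.label == mk.label),
                       key=lambda c: c.score)
            assert best.mask_t1.label == mk.label

    def test_distant_nonoverlapping_masks_yield_no_candidate(self):
        a = masks_from_labels(_labels_with_squares({1: (2, 2)}), 0)
        b = masks_from_labels(_labels_with_squares({1: (50, 50)}), 1)
        assert score_links(a, b, search_radius=30.0) == []


class TestLinkFrames:
    def test_unambiguous_two_versus_two_links_both(self):
        a = masks_from_labels(_labels_with_squares({1: (5, 5), 2: (40, 40)}), 0)
        b = masks_from_labels(_labels_with_squares({1: (7, 5), 2: (42, 40)}), 1)
        links = link_frames(score_links(a, b))
        assert [(p[0], p[1]) for p in links.pairs] == [(1, 1), (2, 2)]

    def test_fusion_links_best_predecessor_and_flags(self):
        # two masks at t, one larger overlapping mask at t+1
        img_t = _labels_with_squares({1: (10, 10), 2: (10, 20)})
        img_t1 = np.zeros((64, 64), np.uint16)
        img_t1[10:16, 10:26] = 1
        a = masks_from_labels(img_t, 0)
        b = masks_from_labels(img_t1, 1)
        cands = score_links(a, b)
        links = link_frames(cands)
        assert len(links.pairs) == 1
        best = max(cands, key=lambda c: c.score)
        assert links.pairs[0][0] == best.mask_t.label
        assert 1 in links.fused_t1

    def test_empty_input_gives_empty_assignment(self):
        links = link_frames([])
        assert links.pairs == [] and links.unmatched_t == []

    def test_assignment_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(2)
        for trial in range(8):
            n = int(rng.integers(2, 6))
            pos_t = {i + 1: (int(rng.integers(2, 50)), int(rng.integers(2, 50)))
                     for i in range(n)}
            pos_t1 = {i + 1: (pos_t[i + 1][0] + int(rng.integers(-4, 5)),
                              pos_t[i + 1][1] + int(rng.integers(-4, 5)))
                      for i in range(n)}
            a = masks_from_labels(_labels_with_squares(pos_t), 0)
            b = masks_from_labels(_labels_with_squares(pos_t1), 1)
            cands = score_links(a, b)
            links = link_frames(cands)
            assert links.total_score == pytest.approx(
                brute_force_best_assignment(cands, 0.1), abs=1e-9)

    def test_translation_invariance_of_assignment(self):
        pos_t = {1: (5, 5), 2: (20, 8), 3: (35, 30)}
        pos_t1 = {1: (7, 6), 2: (22, 9), 3: (36, 32)}
        base = link_frames(score_links(
            masks_from_labels(_labels_with_squares(pos_t), 0),
            masks_from_labels(_labels_with_squares(pos_t1), 1)))
        moved_t = {k: (r + 10, c + 12) for k, (r, c) in pos_t.items()}
        moved_t1 = {k: (r + 10, c + 12) for k, (r, c) in pos_t1.items()}
        moved = link_frames(score_links(
            masks_from_labels(_labels_with_squares(moved_t), 0),
            masks_from_labels(_labels_with_squares(moved_t1), 1)))
        assert [(p[0], p[1]) for p in base.pairs] == \
            [(p[0], p[1]) for p in moved.pairs]


class TestAssembleTracks:
    def _stack_from_positions(self, frames):
        return np.stack([_labels_with_squares(p) for p in frames])

    def test_unbroken_chain_gives_one_track(self):
        stack = self._stack_from_positions(
            [{1: (10 + t, 10)} for t in range(5)])
        tracks = track_label_stack(stack)
        assert len(tracks) == 1 and tracks[0].duration == 5

    def test_broken_chain_gives_two_tracks(self):
        frames = [{1: (10, 10)}, {1: (11, 10)}, {1: (12, 10)},
                  {1: (50, 50)}, {1: (51, 50)}]
        tracks = track_label_stack(self._stack_from_positions(frames))
        assert sorted(t.duration for t in tracks) == [2, 3]

    def test_no_track_holds_two_masks_in_one_frame(self, small_scene):
        _, labels, _, _ = small_scene
        for tr in track_label_stack(labels):
            frames = tr.frames
            assert len(frames) == len(set(frames))
            assert frames == sorted(frames)
            assert all(b - a == 1 for a, b in zip(frames[:-1], frames[1:]))

    def test_separated_cells_recover_99pct_of_truth_links(self, separated_scene):
        cfg, labels, _, truth = separated_scene
        tracks = track_label_stack(labels)
        true_links = {(t, cid + 1) for cid in truth.positions.cell_id.unique()
                      for t in range(cfg.n_frames - 1)}
        found = set()
        for tr in tracks:
            for (f1, l1, _), (f2, l2, _) in zip(tr.items[:-1], tr.items[1:]):
                if l1 == l2:
                    found.add((f1, l1))
        assert len(found & true_links) / len(true_links) >= 0.99
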