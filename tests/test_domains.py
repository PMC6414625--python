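"""Domain calling: window scores, DP optimality, two-step annotation."""

import numpy as np
import pytest

from laminachrom import (
    ContactMap,
    call_domains,
    domain_quality,
    overlap_degree,
    two_step_annotation,
)
from laminachrom.domains import INTER, TAD, DomainAnnotation

from conftest import random_symmetric


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_quality(counts, a, b, gamma):
    """Window quality computed by direct loops (independent of the package)."""
    n = counts.shape[0]
    L = b - a + 1

    def s(x, y):
        tot = 0.0
        for i in range(x, y + 1):
            for j in range(i + 1, y + 1):
                tot += counts[i, j]
        return tot

    scaled = [s(x, x + L - 1) / L**gamma for x in range(n - L + 1)]
    return s(a, b) / L**gamma - float(np.mean(scaled))


def brute_best_partition(counts, gamma):
    """Exhaustive search over all TAD/inter-TAD segmentations (n <= 12)."""
    n = counts.shape[0]
    q = {
        (a, b): brute_quality(counts, a, b, gamma)
        for a in range(n)
        for b in range(a, n - 1 + 1)
    }
    best = {"score": -1.0, "doms": []}

    def rec(pos, score, doms):
        if pos == n:
            if score > best["score"]:
                best["score"] = score
                best["doms"] = list(doms)
            return
        rec(pos + 1, score, doms)  # pos is inter-TAD
        for end in range(pos, n):
            qq = q[(pos, end)]
            if qq > 0:
                doms.append((pos, end + 1))
                rec(end + 1, score + qq, doms)
                doms.pop()

    rec(0, 0.0, [])
    return best["score"], best["doms"]


def dp_score(counts, doms, gamma):
    return sum(
        brute_quality(counts, s, e - 1, gamma) for s, e in doms
    )


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestDomainQuality:
    def test_uniform_matrix_all_zero(self):
        cmap = ContactMap(np.full((8, 8), 2.0), corrected=True)
        for a, b in [(0, 3), (2, 7), (5, 5)]:
            assert domain_quality(cmap, a, b, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_dense_block_has_maximal_quality(self, rng):
        counts = random_symmetric(8, rng, 0.5, 1.0)
        counts[2:6, 2:6] += 5.0
        np.fill_diagonal(counts, 0)
        cmap = ContactMap(counts, corrected=True)
        q_block = domain_quality(cmap, 2, 5, 1.0)
        assert q_block == pytest.approx(brute_quality(counts, 2, 5, 1.0))
        others = [
            domain_quality(cmap, a, b, 1.0)
            for a in range(8)
            for b in range(a, 8)
            if (a, b) != (2, 5)
        ]
        assert q_block > max(others)

    def test_quality_matches_bruteforce_everywhere(self, rng):
        counts = random_symmetric(7, rng)
        np.fill_diagonal(counts, 0)
        cmap = ContactMap(counts, corrected=True)
        for a in range(7):
            for b in range(a, 7):
                assert domain_quality(cmap, a, b, 0.8) == pytest.approx(
                    brute_quality(counts, a, b, 0.8), abs=1e-9
                )


class TestCallDomains:
    def test_two_planted_blocks_found_exactly(self, rng):
        counts = random_symmetric(10, rng, 0.2, 0.6)
        counts[0:5, 0:5] += 4.0
        counts[5:10, 5:10] += 4.0
        np.fill_diagonal(counts, 0)
        cmap = ContactMap(counts, corrected=True)
        ann = call_domains(cmap, 1.0)
        assert ann.tads == [(0, 5), (5, 10)]
        score_bf, _ = brute_best_partition(counts, 1.0)
        assert dp_score(counts, ann.tads, 1.0) == pytest.approx(score_bf)

    def test_uniform_matrix_yields_single_intertad(self):
        cmap = ContactMap(np.full((9, 9), 1.0), corrected=True)
        ann = call_domains(cmap, 1.0)
        assert ann.tads == []
        assert ann.segments == [(0, 9, INTER)]

    @pytest.mark.parametrize("seed", range(25))
    def test_dp_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        counts = random_symmetric(n, rng)
        np.fill_diagonal(counts, 0)
        gamma = float(rng.uniform(0.3, 1.5))
        ann = call_domains(ContactMap(counts, corrected=True), gamma)
        score_bf, _ = brute_best_partition(counts, gamma)
        assert dp_score(counts, ann.tads, gamma) == pytest.approx(
            score_bf, abs=1e-9
        )

    def test_max_domain_length_nonincreasing_in_gamma(self, rng):
        counts = random_symmetric(12, rng, 0.2, 0.8)
        counts[1:7, 1:7] += 3.0
        counts[8:12, 8:12] += 3.0
        np.fill_diagonal(counts, 0)
        cmap = ContactMap(counts, corrected=True)
        prev = np.inf
        for gamma in [0.3, 0.6, 1.0, 1.5, 2.0, 3.0]:
            ann = call_domains(cmap, gamma)
            longest = max((e - s for s, e in ann.tads), default=0)
            assert longest <= prev
            prev = longest


class TestTwoStep:
    def _block_map(self, n, blocks, noise_rng, boost=4.0):
        counts = random_symmetric(n, noise_rng, 0.2, 0.5)
        for s, e in blocks:
            counts[s:e, s:e] += boost
        np.fill_diagonal(counts, 0)
        return ContactMap(counts, corrected=True)

    def test_oversized_tad_is_split_at_double_gamma(self, rng):
        # two 20-bin sub-blocks inside a 40-bin (800 kb) super-domain
        counts = random_symmetric(50, rng, 0.1, 0.3)
        counts[5:45, 5:45] += 3.0
        counts[5:25, 5:25] += 1.5
        counts[25:45, 25:45] += 1.5
        np.fill_diagonal(counts, 0)
        cmap = ContactMap(counts, corrected=True)
        one = call_domains(cmap, 0.2)
        assert any((e - s) * 20_000 > 600_000 for s, e in one.tads)
        two = two_step_annotation(cmap, 0.2)
        assert all((e - s) * 20_000 <= 600_000 for s, e in two.tads)
        assert (5, 25) in two.tads and (25, 45) in two.tads

    def test_exactly_600kb_not_split(self, rng):
        cmap = self._block_map(40, [(5, 35)], rng)  # 30 bins = 600 kb
        two = two_step_annotation(cmap, 0.7)
        assert (5, 35) in two.tads

    def test_small_tads_relabelled_intertad(self, rng):
        # a 3-bin (60 kb) dense block must end up inter-TAD
        cmap = self._block_map(20, [(2, 5), (8, 16)], rng, boost=5.0)
        two = two_step_annotation(cmap, 1.0)
        assert (2, 5) not in two.tads
        assert all((e - s) * 20_000 > 60_000 for s, e in two.tads)

    def test_annotation_tiles_arm(self, rng):
        cmap = self._block_map(30, [(3, 12), (15, 27)], rng)
        ann = two_step_annotation(cmap, 0.8)
        pos = 0
        for s, e, _ in ann.segments:
            assert s == pos
            pos = e
        assert pos == 30


class TestOverlapDegree:
    def _ann(self, n, tads):
        segs = []
        pos = 0
        for s, e in tads:
            if s > pos:
                segs.append((pos, s, INTER))
            segs.append((s, e, TAD))
            pos = e
        if pos < n:
            segs.append((pos, n, INTER))
        return DomainAnnotation(segs, 1.0, n_bins=n)

    def test_identical_annotations_all_one(self):
        a = self._ann(20, [(0, 5), (8, 15)])
        assert overlap_degree(a, a) == [1.0, 1.0]

    def test_half_split(self):
        a = self._ann(20, [(0, 10)])
        b = self._ann(20, [(0, 5), (5, 10)])
        assert overlap_degree(a, b) == [0.5]

    def test_no_overlap_zero(self):
        a = self._ann(20, [(0, 5)])
        b = self._ann(20, [(10, 15)])
        assert overlap_degree(a, b) == [0.0]
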