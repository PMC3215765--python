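"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from domarch.model import Architecture, ArchUnit


def make_arch(pid: str, labels, types=None) -> Architecture:
    """Architecture from a label sequence (Family type unless given)."""
    types = types or ["Family"] * len(labels)
    return Architecture(
        pid, tuple(ArchUnit(lab, lab, tc) for lab, tc in zip(labels, types))
    )


@pytest.fixture
def arch():
    return make_arch


def enumerate_global_alignments(s1, s2, match=0.0, gap=3.0, mismatch=10.0):
    """Brute-force enumeration of every global alignment of two label
    strings; yields (total_cost, match_count) per alignment.

    Independent oracle: no dynamic programming, no pruning — the full
    alignment tree is walked.
    """
    out = []

    def rec(i, j, cost, matches):
        if i == len(s1) and j == len(s2):
            out.append((cost, matches))
            return
        if i < len(s1) and j < len(s2):
            eq = s1[i] == s2[j]
            rec(i + 1, j + 1, cost + (match if eq else mismatch), matches + eq)
        if i < len(s1):
            rec(i + 1, j, cost + gap, matches)
        if j < len(s2):
            rec(i, j + 1, cost + gap, matches)

    rec(0, 0, 0.0, 0)
    return out


def brute_force_optimum(s1, s2, **costs):
    """(min cost, set of match counts achieved at min cost)."""
    alignments = enumerate_global_alignments(s1, s2, **costs)
    best = min(c for c, _ in alignments)
    return best, {m for c, m in alignments if c == best}
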