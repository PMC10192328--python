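"""Shared fixtures: reference sequences and an independent mining oracle."""

from __future__ import annotations

import re

import numpy as np
import pytest

# Mature E. coli CsgA (UniProt P28307, signal peptide 1-20 removed).
# 131 aa: the 22-aa N22 targeting segment followed by five curlin repeats
# with Ser-substituted motif-a anchors.
EC_CSGA_MATURE = (
    "GVVPQYGGGGNHGGGGNNSGPNSELNIYQYGGGNSALALQTDARNSDLTITQHGGGNGADVGQGSDDSS"
    "IDLTQRGFGNSATLDQWNGKNSEMTVKQFGGGNGAAVDQTASNSSVNVTQVGFGNNATAHQY"
)


@pytest.fixture
def ec_csga():
    return EC_CSGA_MATURE


# ---------------------------------------------------------------------------
# Independent repeat-mining oracle.
#
# The package scans sequences with plain index arithmetic; this oracle
# enumerates *all* anchor placements with the ``re`` engine first and
# then replays the declared selection policy (pass precedence, leftmost
# anchor, lookahead boundary preferring N-anchored downstream starts).

_PATTERNS = {
    "kernel": re.compile(r".{6}Q.{10}Q"),
    "n_anchor": re.compile(r"N.{5}Q.G"),
    "degenerate": re.compile(r"..[AIVLSTG].[IVLQTA].Q.G"),
}
_HALF = re.compile(r"N.{5}Q")
_MIN_ROOM = {"kernel": 18, "n_anchor": 22, "degenerate": 18}


def _all_anchors(seq: str, kind: str, lo: int, hi: int) -> list[int]:
    """Exhaustive enumeration of anchor placements inside [lo, hi)."""
    out = []
    for i in range(lo, hi):
        if i + _MIN_ROOM[kind] > hi:
            break
        if _PATTERNS[kind].match(seq, i, hi):
            out.append(i)
    return out


def _oracle_half_at(seq: str, i: int, hi: int) -> bool:
    return hi - i == 7 and _HALF.fullmatch(seq, i, hi) is not None


def _oracle_length(seq: str, i: int, hi: int, kind: str) -> int:
    anchored, bare = [], []
    for d in range(21, 32):
        j = i + d
        if j >= hi:
            break
        here = (j in _all_anchors(seq, kind, j, hi)) or _oracle_half_at(seq, j, hi)
        if not here:
            continue
        (anchored if seq[j] == "N" else bare).append(d)
    if anchored:
        return anchored[0]
    if bare:
        return bare[0]
    return min(22, hi - i)


def oracle_find_repeats(sequence: str) -> list[tuple[int, int, str]]:
    """(start, end, pass) triples under the declared cascade policy."""
    seq = sequence.upper()
    n = len(seq)
    claimed: list[tuple[int, int, str]] = []

    def spans(min_len: int):
        out, cur = [], 0
        for s, e, _ in sorted(claimed):
            if s - cur >= min_len:
                out.append((cur, s))
            cur = max(cur, e)
        if n - cur >= min_len:
            out.append((cur, n))
        return out

    for kind in ("kernel", "n_anchor", "degenerate"):
        for lo, hi in spans(18):
            pos = lo
            while pos + 18 <= hi:
                starts = [i for i in _all_anchors(seq, kind, pos, hi)]
                if not starts:
                    break
                i = starts[0]
                length = _oracle_length(seq, i, hi, kind)
                claimed.append((i, i + length, kind))
                pos = i + length
        claimed.sort()

    if claimed:
        tail = claimed[-1][1]
        for i in range(max(tail, n - 12), n - 6):
            if _oracle_half_at(seq, i, n):
                claimed.append((i, i + 7, "half"))
                break
    return claimed


@pytest.fixture
def mining_oracle():
    return oracle_find_repeats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
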