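"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (nested loops, math.comb)
so they share no code path with the implementations they check.
"""

import itertools
import math

import numpy as np
import pytest

from ribodelta.annotation import TranscriptModel


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orf(seq: str):
    """Enumerate every (ATG, first in-frame stop) span in all three frames;
    return (start, end) of the longest (ties: smallest start) or None."""
    seq = seq.upper()
    n = len(seq)
    candidates = []
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        end = None
        for j in range(i + 3, n - 2, 3):
            if seq[j : j + 3] in STOPS:
                end = j + 3
                break
        if end is None:
            end = i + 3 * ((n - i) // 3)
        if end > i:
            candidates.append((i, end))
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[1] - c[0], -c[0]))


def brute_force_hypergeom(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric mass function."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def brute_force_jackknife_values(groups: dict) -> np.ndarray:
    """All simultaneous leave-one-out ΔTE values by nested enumeration
    (single gene; groups hold 1-D arrays)."""
    tm, tc = np.asarray(groups["trap_mutant"]), np.asarray(groups["trap_control"])
    rm, rc = np.asarray(groups["rna_mutant"]), np.asarray(groups["rna_control"])
    vals = []
    for i, j, k, l in itertools.product(
        range(len(tm)), range(len(tc)), range(len(rm)), range(len(rc))
    ):
        a = np.delete(tm, i).mean()
        b = np.delete(tc, j).mean()
        c = np.delete(rm, k).mean()
        d = np.delete(rc, l).mean()
        vals.append((a - b) - (c - d))
    return np.array(vals)


def brute_force_mwu_exact_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all rank assignments."""
    a, b = list(a), list(b)
    na = len(a)
    combined = sorted(a + b)
    assert len(set(combined)) == len(combined), "oracle requires no ties"

    def u_of(sample_a):
        return sum(1 for x in sample_a for y in combined if y not in sample_a and x > y)

    # enumerate every way the na ranks could have been assigned
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for subset in itertools.combinations(combined, na):
        rest = [v for v in combined if v not in subset]
        us.append(sum(1 for x in subset for y in rest if x > y))
    us = np.array(us)
    n_total = len(us)
    lo = (us <= u_obs).sum()
    hi = (us >= u_obs).sum()
    return min(1.0, 2.0 * min(lo, hi) / n_total)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def two_exon_plus() -> TranscriptModel:
    return TranscriptModel("tx1", "g1", "chr1", "+", ((0, 10), (20, 30)))


@pytest.fixture
def two_exon_minus() -> TranscriptModel:
    return TranscriptModel("tx2", "g1", "chr1", "-", ((20, 30), (0, 10)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
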