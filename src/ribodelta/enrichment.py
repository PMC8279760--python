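"""Hypergeometric gene-set enrichment, list overlap and rank comparisons.

Overlap significance is the exact upper tail of the hypergeometric
distribution: drawing ``n`` genes from a universe of ``N`` of which ``K``
belong to the set, the p-value is P(X ≥ k) for the observed overlap k.
The universe is the set of genes passing the expression filter in the
relevant matrix rather than the whole annotation, to avoid inflating
enrichment with genes that were never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from ._errors import InsufficientDataError, InsufficientPoolError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    """Hypergeometric overlap between a gene list and a gene set."""

    set_name: str
    universe_size: int  # N
    set_in_universe: int  # K
    list_size: int  # n
    overlap: int  # k
    p_upper: float
    n_dropped: int = 0


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X ≥ k).

    ``k`` observed overlap, ``K`` set size in the universe, ``n`` list size,
    ``N`` universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}"
        )
    # P(X >= k) = sf(k - 1)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def list_overlap_test(
    list_a: Iterable[str],
    list_b: Iterable[str],
    universe: Iterable[str],
    set_name: str = "overlap",
) -> EnrichmentResult:
    """Hypergeometric test of the overlap between two gene lists.

    Members outside the universe are dropped (counted and logged), never
    silently kept.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    dropped = len(a - uni) + len(b - uni)
    if dropped:
        logger.warning("%d list members outside the universe were dropped", dropped)
    a &= uni
    b &= uni
    k = len(a & b)
    p = hypergeom_p(k, len(b), len(a), len(uni))
    return EnrichmentResult(set_name, len(uni), len(b), len(a), k, p, dropped)


def enrich_gene_sets(
    gene_list: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> List[EnrichmentResult]:
    """Overlap test of one gene list against several gene sets."""
    return [
        list_overlap_test(gene_list, gs.members, universe, set_name=gs.name)
        for gs in gene_sets
    ]


def expression_matched_sample(
    target_genes: Iterable[str],
    pool: Iterable[str],
    expression: Mapping[str, float],
    n_bins: int = 10,
    seed: int = 0,
) -> List[str]:
    """Draw a control gene set matching the targets' expression distribution.

    The expression range is split into ``n_bins`` quantile bins over the
    targets; each bin contributes as many (seeded, without replacement) pool
    genes as it holds targets.  A bin the pool cannot fill raises
    :class:`InsufficientPoolError` naming the deficient bins — no silent
    fallback.
    """
    targets = sorted(set(target_genes))
    pool = sorted(set(pool) - set(targets))
    if not targets:
        raise InsufficientDataError("no target genes")
    for g in targets + pool:
        v = expression[g]
        if not np.isfinite(v):
            raise ValidationError(f"non-finite expression for {g}")
    t_expr = np.array([expression[g] for g in targets])
    edges = np.quantile(t_expr, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # ties collapse bins
    if len(edges) < 2:  # all target expressions identical: one bin spanning everything
        edges = np.array([-np.inf, np.inf])
    edges[0], edges[-1] = -np.inf, np.inf

    def bin_of(value: float) -> int:
        return int(np.searchsorted(edges, value, side="right") - 1)

    t_bins: Dict[int, int] = {}
    for g in targets:
        t_bins[bin_of(expression[g])] = t_bins.get(bin_of(expression[g]), 0) + 1
    p_bins: Dict[int, List[str]] = {}
    for g in pool:
        p_bins.setdefault(bin_of(expression[g]), []).append(g)
    deficient = [
        (b, need, len(p_bins.get(b, [])))
        for b, need in sorted(t_bins.items())
        if len(p_bins.get(b, [])) < need
    ]
    if deficient:
        raise InsufficientPoolError(deficient)
    rng = np.random.default_rng(seed)
    control: List[str] = []
    for b, need in sorted(t_bins.items()):
        candidates = sorted(p_bins[b])
        control.extend(rng.choice(candidates, size=need, replace=False).tolist())
    return control


def length_comparison(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of two length samples.

    Exact rank enumeration for small samples (combined n ≤ 12 without ties),
    tie-corrected normal approximation otherwise.  Returns (U of sample A,
    two-sided p).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 values per sample")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> List[GeneSet]:
    """Read gene sets from GMT (name, description, members; tab-separated)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            sets.append(GeneSet(name, frozenset(members), desc))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description] + sorted(gs.members)) + "\n")


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("set_name\tN\tK\tn\tk\tp_upper\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.universe_size}\t{r.set_in_universe}\t"
                f"{r.list_size}\t{r.overlap}\t{r.p_upper:.17g}\n"
            )
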