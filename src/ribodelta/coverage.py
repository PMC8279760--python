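"""Per-base spliced coverage, positional bin profiles and region statistics.

The positional analysis rescales every transcript to 100 bins of read
*fractions* so that transcripts of different lengths and depths are
comparable; a systematic dip of the mutant profile toward the 3' bins is
the signature of increased 3'→5' transcript degradation.  Region-level
statistics split the same per-base depth by the 5'UTR/CDS/3'UTR
segmentation and compare genotypes by the difference of mean read
fractions, treating animals (not reads) as the replication unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._errors import (
    DegenerateInputError,
    InsufficientDataError,
    SegmentationMissingError,
    UndefinedProfileError,
)
from .annotation import OrfSegmentation, TranscriptModel

logger = logging.getLogger(__name__)

REGIONS = ("utr5", "cds", "utr3")


@dataclass
class CoverageVector:
    """Per-nucleotide read depth along one transcript's spliced coordinates."""

    transcript_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def total(self) -> float:
        return float(self.depth.sum())


@dataclass
class BinnedProfile:
    """Read-fraction summary of a coverage vector over ``n_bins`` positional bins."""

    transcript_id: str
    sample_id: str
    fractions: np.ndarray
    total_reads: float


@dataclass
class MetageneProfile:
    """Per-genotype positional summary: median across transcripts within each
    animal, then mean and SEM across animals."""

    genotype: str
    mean: np.ndarray
    sem: np.ndarray
    n_animals: int
    sem_defined: bool = True


@dataclass
class RegionDelta:
    """Mutant−control difference of mean region read fractions for one transcript."""

    transcript_id: str
    control_fracs: Dict[str, float]
    mutant_fracs: Dict[str, float]
    delta: Dict[str, float]
    log2fc: Optional[float] = None


def per_base_coverage(
    alignments: Iterable[Sequence[Tuple[int, int]]],
    model: TranscriptModel,
    sample_id: str = "",
) -> CoverageVector:
    """Project genomic alignment blocks onto spliced transcript coordinates.

    Each element of ``alignments`` is the list of genomic (start, end) blocks
    of one read (introns already excised, as from ``pysam`` ``get_blocks``).
    Bases falling outside the transcript's exons are ignored.
    """
    depth = np.zeros(model.spliced_length, dtype=np.int64)
    offsets = []
    off = 0
    for s, e in model.exons:
        offsets.append(off)
        off += e - s
    for blocks in alignments:
        for bs, be in blocks:
            for (es, ee), off in zip(model.exons, offsets):
                s, e = max(bs, es), min(be, ee)
                if s >= e:
                    continue
                if model.strand == "+":
                    depth[off + (s - es) : off + (e - es)] += 1
                else:
                    depth[off + (ee - e) : off + (ee - s)] += 1
    return CoverageVector(model.transcript_id, sample_id, depth)


def coverage_from_sam(
    sam_path: str,
    models: Sequence[TranscriptModel],
    sample_id: str = "",
) -> Dict[str, CoverageVector]:
    """Per-base spliced coverage for several transcripts from one SAM/BAM file.

    Reads are streamed once; each read's aligned blocks (CIGAR N respected)
    are assigned to every transcript they overlap.
    """
    import pysam

    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    reads_by_model: Dict[str, List] = {m.transcript_id: [] for m in models}
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            blocks = read.get_blocks()
            if not blocks:
                continue
            lo, hi = blocks[0][0], blocks[-1][1]
            for m in by_chrom.get(read.reference_name, ()):
                span = m.genomic_span()
                if lo < span[1] and hi > span[0]:
                    reads_by_model[m.transcript_id].append(blocks)
    return {
        m.transcript_id: per_base_coverage(reads_by_model[m.transcript_id], m, sample_id)
        for m in models
    }


def load_bedgraph(bedgraph_path: str) -> Dict[str, List[Tuple[int, int, int]]]:
    """Read a 4-column bedGraph into chrom → [(start, end, depth), ...]."""
    out: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(bedgraph_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.setdefault(chrom, []).append((int(start), int(end), int(float(value))))
    return out


def coverage_from_intervals(
    intervals: Sequence[Tuple[int, int, int]],
    model: TranscriptModel,
    sample_id: str = "",
) -> CoverageVector:
    """Per-base spliced coverage from genomic (start, end, depth) intervals."""
    depth = np.zeros(model.spliced_length, dtype=np.int64)
    offsets = []
    off = 0
    for s, e in model.exons:
        offsets.append(off)
        off += e - s
    for bs, be, v in intervals:
        for (es, ee), off in zip(model.exons, offsets):
            s, e = max(bs, es), min(be, ee)
            if s >= e:
                continue
            if model.strand == "+":
                depth[off + (s - es) : off + (e - es)] += v
            else:
                depth[off + (ee - e) : off + (ee - s)] += v
    return CoverageVector(model.transcript_id, sample_id, depth)


def coverage_from_bedgraph(
    bedgraph_path: str, model: TranscriptModel, sample_id: str = ""
) -> CoverageVector:
    """Per-base spliced coverage from a 4-column bedGraph of genomic depth."""
    by_chrom = load_bedgraph(bedgraph_path)
    return coverage_from_intervals(by_chrom.get(model.chrom, ()), model, sample_id)


def write_bedgraph(cov: CoverageVector, model: TranscriptModel, fh) -> None:
    """Append one transcript's depth to an open bedGraph stream (genomic coords)."""
    # map spliced depth back to genomic per-exon runs
    off = 0
    for s, e in model.exons:
        n = e - s
        seg = cov.depth[off : off + n]
        if model.strand == "-":
            seg = seg[::-1]
        run_start = 0
        for i in range(1, n + 1):
            if i == n or seg[i] != seg[run_start]:
                if seg[run_start] != 0:
                    fh.write(
                        f"{model.chrom}\t{s + run_start}\t{s + i}\t{int(seg[run_start])}\n"
                    )
                run_start = i
        off += n


def passes_expression_filter(cov: CoverageVector, min_mean_depth: float = 1.0) -> bool:
    """True iff mean per-base depth is at least ``min_mean_depth`` (default 1)."""
    if len(cov.depth) == 0:
        raise DegenerateInputError("zero-length coverage vector")
    return float(cov.depth.mean()) >= min_mean_depth


def bin_boundaries(length: int, n_bins: int = 100) -> np.ndarray:
    """Bin edges under the floor rule: bin b covers [⌊bL/n⌋, ⌊(b+1)L/n⌋)."""
    return (np.arange(n_bins + 1, dtype=np.int64) * length) // n_bins


def bin_profile(cov: CoverageVector, n_bins: int = 100) -> BinnedProfile:
    """Collapse per-base depth into ``n_bins`` positional read fractions.

    Fractions are bin depth sums over total depth, so they sum to 1 and are
    invariant to uniform depth scaling.  Bins made empty by short transcripts
    (L < n_bins) receive fraction 0.
    """
    total = cov.total
    if total <= 0:
        raise UndefinedProfileError(
            f"transcript {cov.transcript_id}: zero total depth, profile undefined"
        )
    edges = bin_boundaries(len(cov.depth), n_bins)
    csum = np.concatenate([[0.0], np.cumsum(cov.depth, dtype=np.float64)])
    sums = csum[edges[1:]] - csum[edges[:-1]]
    return BinnedProfile(cov.transcript_id, cov.sample_id, sums / total, total)


def metagene_summary(
    profiles: Iterable[BinnedProfile],
    sample_info: Mapping[str, Tuple[str, str]],
    n_bins: int = 100,
) -> Dict[str, MetageneProfile]:
    """Summarize binned profiles per genotype.

    ``sample_info`` maps sample_id → (animal_id, genotype).  Within each
    animal the per-bin median across transcripts is taken; across animals of
    one genotype, the mean and SEM of those medians.  A genotype with a
    single animal is flagged (SEM undefined).
    """
    by_animal: Dict[Tuple[str, str], List[np.ndarray]] = {}
    for p in profiles:
        animal, genotype = sample_info[p.sample_id]
        by_animal.setdefault((genotype, animal), []).append(p.fractions)
    by_genotype: Dict[str, List[np.ndarray]] = {}
    for (genotype, _animal), fracs in sorted(by_animal.items()):
        if not fracs:
            continue
        med = np.median(np.vstack(fracs), axis=0)
        by_genotype.setdefault(genotype, []).append(med)
    out: Dict[str, MetageneProfile] = {}
    for genotype, medians in by_genotype.items():
        arr = np.vstack(medians)
        n = arr.shape[0]
        mean = arr.mean(axis=0)
        if n >= 2:
            sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
            out[genotype] = MetageneProfile(genotype, mean, sem, n, True)
        else:
            logger.warning("genotype %s has one animal: SEM undefined", genotype)
            out[genotype] = MetageneProfile(
                genotype, mean, np.full(n_bins, np.nan), n, False
            )
    return out


def region_fractions(cov: CoverageVector, seg: OrfSegmentation) -> Dict[str, float]:
    """Read fraction falling in each of 5'UTR, CDS, 3'UTR."""
    if not seg.has_orf:
        raise SegmentationMissingError(
            f"transcript {cov.transcript_id} has no ORF segmentation"
        )
    total = cov.total
    if total <= 0:
        raise UndefinedProfileError(
            f"transcript {cov.transcript_id}: zero total depth"
        )
    out = {}
    for name in REGIONS:
        s, e = seg.region(name)
        out[name] = float(cov.depth[s:e].sum()) / total
    return out


def region_mean_depth(cov: CoverageVector, seg: OrfSegmentation, region: str) -> float:
    """Mean per-base depth over one region (0 for an empty region)."""
    if not seg.has_orf:
        raise SegmentationMissingError(
            f"transcript {cov.transcript_id} has no ORF segmentation"
        )
    s, e = seg.region(region)
    if e <= s:
        return 0.0
    return float(cov.depth[s:e].mean())


def region_delta(
    fractions_by_sample: Mapping[str, Dict[str, float]],
    genotypes: Mapping[str, str],
    transcript_id: str,
    log2fc: Optional[float] = None,
    control_label: str = "control",
    mutant_label: str = "mutant",
) -> Optional[RegionDelta]:
    """Per-region mutant−control difference of mean read fractions.

    ``fractions_by_sample`` maps sample_id → region fractions for one
    transcript; aggregation is the mean of per-sample fractions within each
    genotype (animals are the replication unit).  Returns ``None`` (with a
    log entry) if a genotype has no samples for this transcript.
    """
    groups: Dict[str, List[Dict[str, float]]] = {control_label: [], mutant_label: []}
    for sid, fracs in fractions_by_sample.items():
        g = genotypes[sid]
        if g in groups:
            groups[g].append(fracs)
    if not groups[control_label] or not groups[mutant_label]:
        logger.info(
            "transcript %s absent in one genotype; excluded from region deltas",
            transcript_id,
        )
        return None
    means = {}
    for label, lst in groups.items():
        means[label] = {r: float(np.mean([f[r] for f in lst])) for r in REGIONS}
    delta = {
        r: means[mutant_label][r] - means[control_label][r] for r in REGIONS
    }
    return RegionDelta(
        transcript_id, means[control_label], means[mutant_label], delta, log2fc
    )


@dataclass
class RegionComparison:
    """One-way ANOVA over the three region-delta groups plus Tukey HSD pairs."""

    f_statistic: float
    p_value: float
    tukey_p: Dict[Tuple[str, str], float]
    group_means: Dict[str, float] = field(default_factory=dict)
    direction: Optional[str] = None


def compare_regions(
    deltas: Sequence[RegionDelta], direction: Optional[str] = None
) -> RegionComparison:
    """Test whether coverage change differs between transcript regions.

    One-way ANOVA across the utr5/cds/utr3 delta groups followed by Tukey's
    honest-significant-difference pairwise comparisons.  ``direction`` is
    carried through as metadata describing which DE stratum (up/down) the
    transcripts came from.
    """
    from scipy import stats
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(deltas) < 2:
        raise InsufficientDataError("need at least 2 transcripts for region ANOVA")
    groups = {r: np.array([d.delta[r] for d in deltas]) for r in REGIONS}
    f, p = stats.f_oneway(*(groups[r] for r in REGIONS))
    values = np.concatenate([groups[r] for r in REGIONS])
    labels = np.concatenate([[r] * len(groups[r]) for r in REGIONS])
    tk = pairwise_tukeyhsd(values, labels)
    tukey_p: Dict[Tuple[str, str], float] = {}
    res = tk.summary().data[1:]
    for row in res:
        g1, g2 = str(row[0]), str(row[1])
        tukey_p[(g1, g2)] = float(row[3])
    return RegionComparison(
        float(f),
        float(p),
        tukey_p,
        {r: float(groups[r].mean()) for r in REGIONS},
        direction,
    )


def tukey_pair_p(comparison: RegionComparison, a: str, b: str) -> float:
    """Tukey p-value for an unordered region pair."""
    if (a, b) in comparison.tukey_p:
        return comparison.tukey_p[(a, b)]
    return comparison.tukey_p[(b, a)]


def utr3_log2_change(
    covs_by_sample: Mapping[str, CoverageVector],
    seg: OrfSegmentation,
    genotypes: Mapping[str, str],
    region: str = "utr3",
    control_label: str = "control",
    mutant_label: str = "mutant",
) -> float:
    """Mutant−control change of mean log2(region mean depth + 1).

    The log scale makes the region-level change commensurable with the
    transcript-level log2 fold change from the DE stage.
    """
    vals: Dict[str, List[float]] = {control_label: [], mutant_label: []}
    for sid, cov in covs_by_sample.items():
        g = genotypes[sid]
        if g in vals:
            vals[g].append(np.log2(region_mean_depth(cov, seg, region) + 1.0))
    if not vals[control_label] or not vals[mutant_label]:
        raise InsufficientDataError("need both genotypes for region log2 change")
    return float(np.mean(vals[mutant_label]) - np.mean(vals[control_label]))


def select_3utr_biased(
    down_log2fc: Mapping[str, float],
    utr3_changes: Mapping[str, float],
) -> List[str]:
    """Among downregulated transcripts, keep those whose 3'UTR drops more than
    the transcript as a whole.

    ``down_log2fc`` maps downregulated transcript → overall log2FC (DE stage);
    ``utr3_changes`` maps transcript → 3'UTR log2 change.  Selection requires
    the 3'UTR change to be strictly more negative than the overall change;
    transcripts with no segmentation/region value are skipped with a log entry.
    """
    selected = []
    for tid in down_log2fc:
        if tid not in utr3_changes:
            logger.info("transcript %s lacks a 3'UTR change value; skipped", tid)
            continue
        if utr3_changes[tid] < down_log2fc[tid]:
            selected.append(tid)
    return selected
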