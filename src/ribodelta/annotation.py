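"""Transcript models and sequence-derived UTR/CDS segmentation.

A transcript is represented in a *spliced* coordinate system: exons are
concatenated 5'→3' so that position 0 is always the transcript's 5' end,
regardless of genomic strand.  Coding and untranslated regions are then
assigned by searching the spliced sequence for the longest ATG-initiated
open reading frame — annotated CDS features are deliberately ignored, so
the segmentation works on assembled transcripts that carry no CDS record.

All internal coordinates are 0-based half-open; GTF I/O converts from the
1-based closed convention at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from ._errors import (
    CoordinateError,
    DegenerateInputError,
    LookupError_,
    MalformedAnnotationError,
)

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def reverse_complement(seq: str) -> str:
    """Reverse-complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and spliced coordinate system of one transcript.

    ``exons`` are genomic 0-based half-open intervals ordered 5'→3' in
    *transcript* orientation: ascending genomic position on '+', descending
    on '−'.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_span(self) -> Interval:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


def build_transcript_model(
    exon_records: Iterable[Tuple[str, int, int, str, str, str]],
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel` from (chrom, start, end, strand,
    transcript_id, gene_id) exon records.

    Records must agree on chrom/strand/transcript_id and must not overlap.
    Exons are sorted into transcript (5'→3') order: ascending genomic
    coordinate for '+', descending for '−'.
    """
    records = list(exon_records)
    if not records:
        raise MalformedAnnotationError("no exon records supplied")
    chroms = {r[0] for r in records}
    strands = {r[3] for r in records}
    tids = {r[4] for r in records}
    gids = {r[5] for r in records}
    if len(chroms) != 1 or len(strands) != 1 or len(tids) != 1:
        raise MalformedAnnotationError(
            f"mixed chrom/strand/transcript_id in exon records: "
            f"chrom={sorted(chroms)} strand={sorted(strands)} tid={sorted(tids)}"
        )
    strand = strands.pop()
    if strand not in ("+", "-"):
        raise MalformedAnnotationError(f"strand must be '+' or '-', got {strand!r}")
    ivals = sorted((int(r[1]), int(r[2])) for r in records)
    for (s, e) in ivals:
        if e <= s:
            raise MalformedAnnotationError(f"empty or inverted exon [{s},{e})")
    for (_, e_prev), (s_next, _) in zip(ivals, ivals[1:]):
        if s_next < e_prev:
            raise MalformedAnnotationError("overlapping exons")
    if strand == "-":
        ivals = ivals[::-1]
    return TranscriptModel(
        transcript_id=tids.pop(),
        gene_id=gids.pop(),
        chrom=chroms.pop(),
        strand=strand,
        exons=tuple(ivals),
    )


def spliced_sequence(model: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Extract the spliced transcript sequence, 5'→3'.

    ``genome`` maps chromosome name to a sliceable sequence (a plain string
    or a ``pyfaidx.FastaRecord``).  Minus-strand exons are individually
    reverse-complemented so index 0 of the result is the transcript 5' end.
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise LookupError_(f"chromosome {model.chrom!r} not in genome")
    chrom_len = len(chrom_seq)
    parts = []
    for s, e in model.exons:
        if s < 0 or e > chrom_len:
            raise CoordinateError(
                f"exon [{s},{e}) outside chromosome {model.chrom} (length {chrom_len})"
            )
        piece = str(chrom_seq[s:e]).upper()
        if model.strand == "-":
            piece = reverse_complement(piece)
        parts.append(piece)
    return "".join(parts)


@dataclass(frozen=True)
class OrfSegmentation:
    """5'UTR / CDS / 3'UTR partition of a spliced transcript.

    Intervals are spliced-coordinate half-open; when ``has_orf`` is false
    all three are ``None`` and the transcript is excluded from region-level
    analyses.
    """

    transcript_id: str
    has_orf: bool
    utr5: Optional[Interval]
    cds: Optional[Interval]
    utr3: Optional[Interval]

    def region(self, name: str) -> Interval:
        val = {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}[name]
        if val is None:
            raise ValueError(f"no {name} for transcript without ORF")
        return val


def find_longest_orf(sequence: str, transcript_id: str = "") -> OrfSegmentation:
    """Segment a spliced sequence by its longest ATG-initiated open reading frame.

    All three forward frames are scanned.  An ORF runs from an ATG to the
    first in-frame stop codon (stop included in the CDS); an ATG with no
    in-frame stop yields an ORF running to the last complete codon — common
    for 3'-incomplete assembled transcripts.  The longest ORF wins; length
    ties go to the 5'-most start.  Codons containing N never match ATG or a
    stop.
    """
    if len(sequence) == 0:
        raise DegenerateInputError("cannot search an empty sequence for ORFs")
    seq = sequence.upper()
    n = len(seq)
    best: Optional[Interval] = None  # (start, end), maximizing end-start then min start
    for frame in range(3):
        start: Optional[int] = None
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                best = _better(best, (start, pos + 3))
                start = None
            pos += 3
        if start is not None:
            # open-ended ORF: truncate at the last complete codon in frame
            end = start + 3 * ((n - start) // 3)
            if end > start:
                best = _better(best, (start, end))
    if best is None:
        return OrfSegmentation(transcript_id, False, None, None, None)
    s, e = best
    return OrfSegmentation(transcript_id, True, (0, s), (s, e), (e, n))


def _better(current: Optional[Interval], cand: Interval) -> Interval:
    if current is None:
        return cand
    cur_len = current[1] - current[0]
    cand_len = cand[1] - cand[0]
    if cand_len > cur_len or (cand_len == cur_len and cand[0] < current[0]):
        return cand
    return current


def segment_transcript(model: TranscriptModel, genome: Mapping[str, object]) -> OrfSegmentation:
    """Convenience: spliced sequence extraction followed by ORF segmentation."""
    return find_longest_orf(spliced_sequence(model, genome), model.transcript_id)


# ---------------------------------------------------------------------------
# I/O: GTF exons in, transcript models out; segmentations out as BED
# ---------------------------------------------------------------------------

def read_gtf_models(gtf_path: str) -> "dict[str, TranscriptModel]":
    """Read exon records from a GTF file into transcript models.

    Requires ``transcript_id`` and ``gene_id`` attributes on exon features.
    Coordinates are converted from GTF 1-based closed to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tid: dict[str, list] = {}
    for feat in db.features_of_type("exon"):
        tid = feat["transcript_id"][0]
        gid = feat["gene_id"][0]
        by_tid.setdefault(tid, []).append(
            (feat.seqid, feat.start - 1, feat.end, feat.strand, tid, gid)
        )
    return {tid: build_transcript_model(recs) for tid, recs in sorted(by_tid.items())}


def write_gtf(models: Sequence[TranscriptModel], path: str, source: str = "ribodelta") -> None:
    """Write transcript exon records as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            # emit in ascending genomic order regardless of strand
            for s, e in sorted(m.exons):
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    """Write sequences as uncompressed FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(fasta_path: str) -> Mapping[str, object]:
    """Open an indexed FASTA as a chrom → sliceable-sequence mapping."""
    from pyfaidx import Fasta

    return Fasta(fasta_path, as_raw=False, sequence_always_upper=True)


def write_segmentation_bed(segmentations: Iterable[OrfSegmentation], path: str) -> None:
    """Export segmentations as BED in spliced transcript coordinates.

    Columns: transcript id, start, end, region name.  Empty regions and
    ORF-less transcripts are skipped.
    """
    with open(path, "w") as fh:
        for seg in segmentations:
            if not seg.has_orf:
                continue
            for name in ("utr5", "cds", "utr3"):
                s, e = seg.region(name)
                if e > s:
                    fh.write(f"{seg.transcript_id}\t{s}\t{e}\t{name}\n")
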