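"""Synthetic-data generator for every input the pipeline consumes.

The generator emulates the study design the pipeline was built for: total
RNA from FACS-sorted cells in 4 mutant vs 4 control animals, TRAP
(ribosome-bound) RNA in 3 vs 3, negative-binomial gene counts with a shared
dispersion, and per-base transcript coverage with a tunable 3'-directed
read-survival decay in the mutant.  Planted gene groups carry the
signatures the analysis is meant to detect:

* ``fmrp_like``   — total RNA halved, ribosome binding unchanged (ΔTE = +1)
* ``top_like``    — ribosome binding up 2^0.5, total RNA unchanged
* ``down_both``   — RNA and TRAP both halved (ΔTE = 0)
* ``null``        — no effect

All generators are pure functions of (config, seed): per-stage random
streams are derived from the master seed keyed by stage name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .annotation import (
    STOP_CODONS,
    TranscriptModel,
    build_transcript_model,
    reverse_complement,
)
from .coverage import CoverageVector

GROUPS = ("fmrp_like", "top_like", "down_both", "null")

DEFAULT_PROPORTIONS = {"fmrp_like": 0.08, "top_like": 0.05, "down_both": 0.04, "null": 0.83}
DEFAULT_EFFECTS = {  # log2 fold change (mutant vs control) per (group, assay)
    ("fmrp_like", "RNA"): -1.0,
    ("fmrp_like", "TRAP"): 0.0,
    ("top_like", "RNA"): 0.0,
    ("top_like", "TRAP"): 0.5,
    ("down_both", "RNA"): -1.0,
    ("down_both", "TRAP"): -1.0,
    ("null", "RNA"): 0.0,
    ("null", "TRAP"): 0.0,
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the emulated study: 4v4 RNA and 3v3 TRAP samples,
    NB dispersion 0.1, baseline means log-normal with median 50, and 2,000
    genes — small enough that every stage runs in minutes on one CPU while
    leaving hundreds of genes per planted group.
    """

    seed: int = 0
    n_genes: int = 2000
    n_rna_control: int = 4
    n_rna_mutant: int = 4
    n_trap_control: int = 3
    n_trap_mutant: int = 3
    proportions: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effects: Dict[Tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(50.0))  # natural-log location; median 50
    baseline_log_sigma: float = 1.0
    # transcript architecture (nucleotides / codons)
    utr5_range: Tuple[int, int] = (50, 300)
    cds_codon_range: Tuple[int, int] = (200, 600)
    utr3_range: Tuple[int, int] = (100, 400)
    max_exons: int = 4
    intron_range: Tuple[int, int] = (60, 400)
    # coverage simulation
    read_length: int = 50
    coverage_depth: float = 5.0  # target mean reads per base before decay
    decay_rate: float = 0.0  # mutant-only 3' survival decrement
    n_coverage_transcripts: int = 200

    def validate(self) -> None:
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("group proportions must sum to 1")
        if set(self.proportions) != set(GROUPS):
            raise ValidationError(f"proportions must cover exactly {GROUPS}")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        for n in (self.n_rna_control, self.n_rna_mutant, self.n_trap_control, self.n_trap_mutant):
            if n < 2:
                raise ValidationError("every sample group needs at least 2 samples")
        if not (0.0 <= self.decay_rate < 1.0):
            raise ValidationError("decay_rate must be in [0, 1)")


def stage_rng(config_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream keyed by stage name."""
    return np.random.default_rng([config_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# gene truth and count matrices
# ---------------------------------------------------------------------------

def simulate_gene_truth(config: SimulationConfig) -> pd.DataFrame:
    """Gene-level ground truth: group label, per-assay log2FC, true ΔTE, baseline.

    Group sizes are the largest-remainder rounding of the configured
    proportions; labels are assigned by a seeded permutation so any subset of
    gene ids mixes groups.
    """
    config.validate()
    rng = stage_rng(config.seed, "truth")
    n = config.n_genes
    raw = {g: config.proportions[g] * n for g in GROUPS}
    sizes = {g: int(np.floor(raw[g])) for g in GROUPS}
    rem = n - sum(sizes.values())
    for g in sorted(GROUPS, key=lambda g: raw[g] - sizes[g], reverse=True)[:rem]:
        sizes[g] += 1
    labels = np.concatenate([[g] * sizes[g] for g in GROUPS])
    rng.shuffle(labels)
    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, size=n)
    lfc_rna = np.array([config.effects[(g, "RNA")] for g in labels])
    lfc_trap = np.array([config.effects[(g, "TRAP")] for g in labels])
    truth = pd.DataFrame(
        {
            "group": labels,
            "lfc_rna": lfc_rna,
            "lfc_trap": lfc_trap,
            "delta_te": lfc_trap - lfc_rna,
            "baseline": baseline,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + dispersion·mean²) via the (r, p) parametrization."""
    if (mean <= 0).any():
        raise ValidationError("non-positive NB mean")
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_count_matrices(
    truth: pd.DataFrame, config: SimulationConfig
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the RNA and TRAP count matrices plus their joint sample sheet."""
    config.validate()
    rng = stage_rng(config.seed, "counts")
    baseline = truth["baseline"].to_numpy()
    frames = {}
    sheet_rows = []
    for assay, n_ctl, n_mut in (
        ("RNA", config.n_rna_control, config.n_rna_mutant),
        ("TRAP", config.n_trap_control, config.n_trap_mutant),
    ):
        lfc = truth[f"lfc_{assay.lower()}"].to_numpy()
        cols = {}
        for genotype, n_samples in (("control", n_ctl), ("mutant", n_mut)):
            mean = baseline * (2.0 ** lfc if genotype == "mutant" else 1.0)
            for i in range(n_samples):
                sid = f"{assay}_{genotype}_{i + 1}"
                cols[sid] = _nb_draw(rng, mean, config.dispersion)
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "assay": assay,
                        "animal_id": f"{assay}_animal_{genotype}_{i + 1}",
                    }
                )
        frames[assay] = pd.DataFrame(cols, index=truth.index)
    sheet = pd.DataFrame(sheet_rows)
    return frames["RNA"], frames["TRAP"], sheet


# ---------------------------------------------------------------------------
# transcript architecture and sequences
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _random_utr(rng: np.random.Generator, length: int, forbid_atg: bool) -> str:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    if forbid_atg:
        # an upstream in-frame ATG would extend the planted ORF; scrub them all
        while "ATG" in seq:
            i = seq.index("ATG")
            seq = seq[:i] + "AC" + seq[i + 2 :]
    return seq


def simulate_transcripts(
    config: SimulationConfig,
    n_transcripts: Optional[int] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    """Transcript models with planted ATG…stop ORFs, plus chromosome sequences.

    Each transcript sits on its own synthetic chromosome with 1–4 exons on a
    random strand.  The 5'UTR is generated ATG-free and the planted CDS is
    much longer than either UTR, so the longest-ORF search recovers the
    planted segmentation in effectively all transcripts (rare longer spurious
    ORFs in alternate frames are possible and tolerated downstream).
    """
    config.validate()
    rng = stage_rng(config.seed, "transcripts")
    if n_transcripts is None:
        n_transcripts = config.n_coverage_transcripts
    if gene_ids is None:
        width = len(str(config.n_genes))
        gene_ids = [f"g{i:0{width}d}" for i in range(n_transcripts)]
    models: List[TranscriptModel] = []
    genome: Dict[str, str] = {}
    stops = sorted(STOP_CODONS)
    for idx, gid in enumerate(gene_ids[:n_transcripts]):
        utr5_len = int(rng.integers(*config.utr5_range))
        n_codons = int(rng.integers(*config.cds_codon_range))
        utr3_len = int(rng.integers(*config.utr3_range))
        utr5 = _random_utr(rng, utr5_len, forbid_atg=True)
        body = "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
        cds = "ATG" + body + stops[rng.integers(len(stops))]
        utr3 = _random_utr(rng, utr3_len, forbid_atg=False)
        spliced = utr5 + cds + utr3
        n_exons = int(rng.integers(1, config.max_exons + 1))
        # split spliced sequence into exon chunks of ≥30 nt
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(30, len(spliced) - 30), size=n_exons - 1, replace=False))
            cuts = np.unique(cuts)
        else:
            cuts = np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), len(spliced)]
        chunks = [spliced[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
        chunks = [c for c in chunks if c]
        strand = "+" if rng.random() < 0.5 else "-"
        # lay out on the plus strand, then flip coordinates for minus
        pieces: List[str] = []
        exon_ivals: List[Tuple[int, int]] = []
        pos = int(rng.integers(20, 100))
        pieces.append("".join(rng.choice(list("ACGT"), size=pos)))
        for j, chunk in enumerate(chunks):
            if j > 0:
                ilen = int(rng.integers(*config.intron_range))
                pieces.append("".join(rng.choice(list("ACGT"), size=ilen)))
                pos += ilen
            exon_ivals.append((pos, pos + len(chunk)))
            pieces.append(chunk)
            pos += len(chunk)
        tail = int(rng.integers(20, 100))
        pieces.append("".join(rng.choice(list("ACGT"), size=tail)))
        g_plus = "".join(pieces)
        chrom = f"chr_{gid}"
        if strand == "+":
            genome[chrom] = g_plus
            exons = exon_ivals
        else:
            genome[chrom] = reverse_complement(g_plus)
            L = len(g_plus)
            exons = [(L - e, L - s) for s, e in exon_ivals][::-1]
        records = [(chrom, s, e, strand, gid, gid) for s, e in exons]
        models.append(build_transcript_model(records))
    return models, genome


# ---------------------------------------------------------------------------
# coverage with 3'-directed decay
# ---------------------------------------------------------------------------

def simulate_coverage(
    model: TranscriptModel,
    n_reads: int,
    read_length: int,
    decay_rate: float,
    seed: int = 0,
    sample_id: str = "",
    rng: Optional[np.random.Generator] = None,
) -> CoverageVector:
    """Uniform read starts thinned by a 3'-directed survival decay.

    Each read starts uniformly along the spliced transcript and is retained
    with probability (1 − decay_rate)^(d/100), where d is the distance of the
    read's 3'-most base from the transcript 5' end — reads reaching far into
    the 3' end are progressively lost, emulating 3'→5' degradation.  Decay
    acts on reads, not depth, so coverage stays integer.
    """
    if n_reads < 0:
        raise ValidationError("n_reads must be non-negative")
    if not (0.0 <= decay_rate < 1.0):
        raise ValidationError("decay_rate must be in [0, 1)")
    L = model.spliced_length
    if read_length > L:
        raise ValidationError(f"read_length {read_length} exceeds transcript length {L}")
    if rng is None:
        rng = np.random.default_rng(seed)
    depth = np.zeros(L, dtype=np.int64)
    if n_reads == 0:
        return CoverageVector(model.transcript_id, sample_id, depth)
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    if decay_rate > 0:
        survival = (1.0 - decay_rate) ** ((starts + read_length - 1) / 100.0)
        keep = rng.random(n_reads) < survival
        starts = starts[keep]
    edges = np.zeros(L + 1, dtype=np.int64)
    np.add.at(edges, starts, 1)
    np.add.at(edges, starts + read_length, -1)
    depth = np.cumsum(edges[:-1])
    return CoverageVector(model.transcript_id, sample_id, depth)


def simulate_sample_coverages(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    decayed_transcripts: Optional[set] = None,
    rna_sheet: Optional[pd.DataFrame] = None,
) -> Dict[str, Dict[str, CoverageVector]]:
    """Coverage vectors for every RNA sample × transcript.

    Mutant samples apply ``config.decay_rate`` to transcripts in
    ``decayed_transcripts`` (default: all); control samples are undecayed.
    Returns sample_id → transcript_id → CoverageVector.
    """
    rng = stage_rng(config.seed, "coverage")
    if rna_sheet is None:
        sids = [
            (f"RNA_control_{i + 1}", "control") for i in range(config.n_rna_control)
        ] + [(f"RNA_mutant_{i + 1}", "mutant") for i in range(config.n_rna_mutant)]
    else:
        rna = rna_sheet[rna_sheet["assay"] == "RNA"]
        sids = list(zip(rna["sample_id"], rna["genotype"]))
    out: Dict[str, Dict[str, CoverageVector]] = {}
    for sid, genotype in sids:
        per_tx: Dict[str, CoverageVector] = {}
        for m in models:
            L = m.spliced_length
            n_reads = int(rng.poisson(config.coverage_depth * L / config.read_length))
            decayed = decayed_transcripts is None or m.transcript_id in decayed_transcripts
            rate = config.decay_rate if (genotype == "mutant" and decayed) else 0.0
            per_tx[m.transcript_id] = simulate_coverage(
                m, n_reads, config.read_length, rate, sample_id=sid, rng=rng
            )
        out[sid] = per_tx
    return out


# ---------------------------------------------------------------------------
# full dataset writer
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, outdir: str) -> Dict[str, str]:
    """Write a complete, self-consistent synthetic dataset directory.

    Contents: gene truth table, RNA/TRAP count TSVs, sample sheet, planted
    gene groups as GMT sets, transcript GTF + genome FASTA for the first
    ``n_coverage_transcripts`` genes, and per-RNA-sample bedGraph coverage
    (mutant samples decayed on RNA-downregulated transcripts at
    ``config.decay_rate``).  Returns a path manifest.
    """
    import os

    from .annotation import write_fasta, write_gtf
    from .coverage import write_bedgraph
    from .enrichment import GeneSet, write_gmt
    from .expression import write_counts_tsv

    os.makedirs(outdir, exist_ok=True)
    truth = simulate_gene_truth(config)
    rna, trap, sheet = simulate_count_matrices(truth, config)
    paths = {
        "truth": os.path.join(outdir, "gene_truth.tsv"),
        "rna_counts": os.path.join(outdir, "rna_counts.tsv"),
        "trap_counts": os.path.join(outdir, "trap_counts.tsv"),
        "sample_sheet": os.path.join(outdir, "sample_sheet.tsv"),
        "gene_sets": os.path.join(outdir, "planted_sets.gmt"),
        "gtf": os.path.join(outdir, "transcripts.gtf"),
        "fasta": os.path.join(outdir, "genome.fa"),
        "coverage_dir": os.path.join(outdir, "coverage"),
    }
    truth.to_csv(paths["truth"], sep="\t", float_format="%.17g")
    write_counts_tsv(rna, paths["rna_counts"])
    write_counts_tsv(trap, paths["trap_counts"])
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    sets = [
        GeneSet(g, frozenset(truth.index[truth["group"] == g]), f"planted {g} genes")
        for g in GROUPS
        if (truth["group"] == g).any()
    ]
    write_gmt(sets, paths["gene_sets"])
    models, genome = simulate_transcripts(config, gene_ids=list(truth.index))
    write_gtf(models, paths["gtf"])
    write_fasta(genome, paths["fasta"])
    decayed = set(truth.index[truth["lfc_rna"] < 0])
    covs = simulate_sample_coverages(models, config, decayed_transcripts=decayed, rna_sheet=sheet)
    os.makedirs(paths["coverage_dir"], exist_ok=True)
    by_tid = {m.transcript_id: m for m in models}
    for sid, per_tx in covs.items():
        with open(os.path.join(paths["coverage_dir"], f"{sid}.bedgraph"), "w") as fh:
            for tid in sorted(per_tx):
                write_bedgraph(per_tx[tid], by_tid[tid], fh)
    return paths
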