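"""End-to-end orchestration: annotation → coverage → DE → TE → enrichment.

The pipeline consumes a dataset directory in the layout the simulator
writes (GTF + FASTA, per-sample bedGraph coverage, RNA/TRAP count TSVs,
sample sheet, GMT gene sets) and emits one table per stage plus a JSON
manifest of outputs, row counts and checksums.  Runs are idempotent for a
fixed input and seed; per-stage random streams are derived from the single
configured seed keyed by stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ._errors import RibodeltaError
from . import annotation as ann
from . import coverage as cov
from . import enrichment as enr
from .expression import DifferentialExpression, read_counts_tsv
from .te import TranslationEfficiency, ecdf_table

logger = logging.getLogger(__name__)


class StageError(RibodeltaError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[stage {stage}] {cause}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stage-name keyed, < 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run.

    Threshold defaults follow the analysis the pipeline reimplements:
    fold change > 2 with p < 0.01 for DE, |Z| > 4 for ΔTE, mean coverage ≥ 1
    read/nt to enter the positional analysis, 100 positional bins, and at
    most 100 jackknife resamples per gene.
    """

    outdir: str
    gtf: Optional[str] = None
    fasta: Optional[str] = None
    coverage_dir: Optional[str] = None
    rna_counts: Optional[str] = None
    trap_counts: Optional[str] = None
    sample_sheet: Optional[str] = None
    gene_sets: Optional[str] = None
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    z_threshold: float = 4.0
    coverage_filter: float = 1.0
    n_bins: int = 100
    max_resamples: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @classmethod
    def from_dataset_dir(cls, dataset_dir: str, outdir: str, **kw) -> "PipelineConfig":
        """Point every input at the simulator's dataset-directory layout."""
        j = lambda name: os.path.join(dataset_dir, name)
        return cls(
            outdir=outdir,
            gtf=j("transcripts.gtf"),
            fasta=j("genome.fa"),
            coverage_dir=j("coverage"),
            rna_counts=j("rna_counts.tsv"),
            trap_counts=j("trap_counts.tsv"),
            sample_sheet=j("sample_sheet.tsv"),
            gene_sets=j("planted_sets.gmt"),
            **kw,
        )

    def validate_inputs(self) -> None:
        for name in ("gtf", "fasta", "coverage_dir", "rna_counts", "trap_counts", "sample_sheet"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"missing input {name!r}: {path}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _rows(path: str) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate_inputs()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: Dict = {
        "seed": config.seed,
        "thresholds": {
            "fc": config.fc_threshold,
            "p": config.p_threshold,
            "z": config.z_threshold,
            "coverage_filter": config.coverage_filter,
            "n_bins": config.n_bins,
            "max_resamples": config.max_resamples,
        },
        "outputs": {},
        "status": "incomplete",
    }
    out = lambda name: os.path.join(config.outdir, name)

    def record(key: str, path: str) -> None:
        manifest["outputs"][key] = {
            "path": os.path.basename(path),
            "rows": _rows(path),
            "sha256": _sha256(path),
        }

    def manifest_out() -> None:
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "annotation"
    try:
        t0 = time.time()
        models = ann.read_gtf_models(config.gtf)
        genome = ann.load_genome(config.fasta)
        segs = {
            tid: ann.segment_transcript(m, genome) for tid, m in models.items()
        }
        ann.write_segmentation_bed(segs.values(), out("segmentation.bed"))
        record("segmentation", out("segmentation.bed"))
        logger.info("[%s] %d transcripts in %.1fs", stage, len(models), time.time() - t0)

        stage = "de"
        t0 = time.time()
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        rna = read_counts_tsv(config.rna_counts)
        trap = read_counts_tsv(config.trap_counts)
        de_lists: Dict[str, List[str]] = {}
        de_results = {}
        for assay, counts in (("RNA", rna), ("TRAP", trap)):
            res = DifferentialExpression(counts, sheet, assay=assay).fit()
            up, down = res.classify(config.fc_threshold, config.p_threshold)
            res.to_tsv(out(f"de_{assay.lower()}.tsv"))
            record(f"de_{assay.lower()}", out(f"de_{assay.lower()}.tsv"))
            de_lists[f"{assay}_up"], de_lists[f"{assay}_down"] = up, down
            de_results[assay] = res
        logger.info("[%s] done in %.1fs", stage, time.time() - t0)

        stage = "coverage"
        t0 = time.time()
        rna_sheet = sheet[sheet["assay"] == "RNA"]
        genotypes = dict(zip(rna_sheet["sample_id"], rna_sheet["genotype"]))
        sample_info = {
            r.sample_id: (r.animal_id, r.genotype) for r in rna_sheet.itertuples()
        }
        covs: Dict[str, Dict[str, cov.CoverageVector]] = {}
        for sid in rna_sheet["sample_id"]:
            path = os.path.join(config.coverage_dir, f"{sid}.bedgraph")
            by_chrom = cov.load_bedgraph(path)
            covs[sid] = {
                tid: cov.coverage_from_intervals(by_chrom.get(m.chrom, ()), m, sid)
                for tid, m in models.items()
            }
        # expression filter: a transcript enters if it passes in every sample
        kept = [
            tid
            for tid in models
            if all(
                cov.passes_expression_filter(covs[sid][tid], config.coverage_filter)
                for sid in covs
            )
        ]
        profiles = [
            cov.bin_profile(covs[sid][tid], config.n_bins)
            for sid in covs
            for tid in kept
            if covs[sid][tid].total > 0
        ]
        prof_rows = [
            {"transcript_id": p.transcript_id, "sample_id": p.sample_id,
             **{f"bin_{i:03d}": p.fractions[i] for i in range(config.n_bins)}}
            for p in profiles
        ]
        pd.DataFrame(prof_rows).to_csv(out("bin_profiles.tsv"), sep="\t", index=False,
                                       float_format="%.17g")
        record("bin_profiles", out("bin_profiles.tsv"))
        meta = cov.metagene_summary(profiles, sample_info, config.n_bins)
        meta_rows = []
        for genotype, mp in sorted(meta.items()):
            for i in range(config.n_bins):
                meta_rows.append(
                    {"genotype": genotype, "bin": i, "mean": mp.mean[i], "sem": mp.sem[i]}
                )
        pd.DataFrame(meta_rows).to_csv(out("metagene.tsv"), sep="\t", index=False,
                                       float_format="%.17g")
        record("metagene", out("metagene.tsv"))

        de_rna_frame = de_results["RNA"].frame
        deltas = []
        utr3_changes = {}
        for tid in kept:
            seg = segs[tid]
            if not seg.has_orf:
                continue
            fracs = {
                sid: cov.region_fractions(covs[sid][tid], seg)
                for sid in covs
                if covs[sid][tid].total > 0
            }
            lfc = (
                float(de_rna_frame.loc[tid, "log2FC"]) if tid in de_rna_frame.index else None
            )
            rd = cov.region_delta(fracs, genotypes, tid, log2fc=lfc)
            if rd is not None:
                deltas.append(rd)
            utr3_changes[tid] = cov.utr3_log2_change(
                {sid: covs[sid][tid] for sid in covs}, seg, genotypes
            )
        delta_rows = [
            {
                "transcript_id": d.transcript_id,
                **{f"control_{r}": d.control_fracs[r] for r in cov.REGIONS},
                **{f"mutant_{r}": d.mutant_fracs[r] for r in cov.REGIONS},
                **{f"delta_{r}": d.delta[r] for r in cov.REGIONS},
                "log2FC": d.log2fc if d.log2fc is not None else np.nan,
                "utr3_log2_change": utr3_changes.get(d.transcript_id, np.nan),
            }
            for d in deltas
        ]
        pd.DataFrame(delta_rows).to_csv(out("region_deltas.tsv"), sep="\t", index=False,
                                        float_format="%.17g")
        record("region_deltas", out("region_deltas.tsv"))
        comparison = None
        if len(deltas) >= 2:
            comparison = cov.compare_regions(deltas, direction="down")
            with open(out("region_anova.json"), "w") as fh:
                json.dump(
                    {
                        "f_statistic": comparison.f_statistic,
                        "p_value": comparison.p_value,
                        "tukey_p": {f"{a}|{b}": p for (a, b), p in comparison.tukey_p.items()},
                        "group_means": comparison.group_means,
                    },
                    fh,
                    indent=2,
                )
            record("region_anova", out("region_anova.json"))
        down_lfc = {
            tid: float(de_rna_frame.loc[tid, "log2FC"])
            for tid in de_lists["RNA_down"]
            if tid in utr3_changes
        }
        biased = cov.select_3utr_biased(down_lfc, utr3_changes)
        with open(out("utr3_biased.txt"), "w") as fh:
            fh.writelines(f"{tid}\n" for tid in biased)
        record("utr3_biased", out("utr3_biased.txt"))
        logger.info("[%s] %d kept transcripts in %.1fs", stage, len(kept), time.time() - t0)

        stage = "te"
        t0 = time.time()
        te_model = TranslationEfficiency(rna, trap, sheet)
        te_res = te_model.fit(
            max_resamples=config.max_resamples,
            seed=stage_seed(config.seed, "te"),
            z_threshold=config.z_threshold,
        )
        te_res.to_tsv(out("te_results.tsv"))
        record("te_results", out("te_results.tsv"))
        increased, decreased = te_res.classify()
        ecdf_table(te_res.frame["delta_te"].dropna()).to_csv(
            out("delta_te_ecdf.tsv"), sep="\t", index=False, float_format="%.17g"
        )
        record("delta_te_ecdf", out("delta_te_ecdf.tsv"))
        logger.info("[%s] done in %.1fs", stage, time.time() - t0)

        stage = "enrichment"
        t0 = time.time()
        universe = sorted(
            set(rna.index[rna.mean(axis=1) >= 1.0]) & set(te_res.frame.index)
        )
        results = []
        if config.gene_sets and os.path.exists(config.gene_sets):
            sets = enr.read_gmt(config.gene_sets)
            for list_name, gene_list in (
                ("RNA_down", de_lists["RNA_down"]),
                ("TE_increased", increased),
            ):
                for r in enr.enrich_gene_sets(gene_list, sets, universe):
                    r.set_name = f"{list_name}~{r.set_name}"
                    results.append(r)
        overlap = enr.list_overlap_test(
            biased, increased, universe, set_name="utr3_biased~TE_increased"
        )
        results.append(overlap)
        enr.write_enrichment_tsv(results, out("enrichment.tsv"))
        record("enrichment", out("enrichment.tsv"))
        logger.info("[%s] done in %.1fs", stage, time.time() - t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest_out()
        raise StageError(stage, exc) from exc

    manifest["counts"] = {
        "transcripts": len(models),
        "coverage_kept": len(kept),
        "utr3_biased": len(biased),
        "rna_down": len(de_lists["RNA_down"]),
        "rna_up": len(de_lists["RNA_up"]),
        "te_increased": len(increased),
        "te_decreased": len(decreased),
        "overlap": overlap.overlap,
    }
    manifest["status"] = "complete"
    manifest_out()
    return manifest
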