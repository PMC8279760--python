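# ribodelta

Joint analysis of **total-RNA** and **TRAP** (translating ribosome affinity
purification) sequencing from a mutant-vs-control design: positional
transcript-coverage profiling with 5'UTR/CDS/3'UTR segmentation,
translation-efficiency change (ΔTE) with jackknife Z-scores, moderated
differential expression, and hypergeometric gene-set/overlap enrichment —
all exercisable end-to-end on a built-in synthetic-data generator, so the
whole pipeline is testable without any download.

## The problem

When a cell type (for example, cerebellar Purkinje cells carrying a
conditional *Tsc1* deletion that activates mTOR) shows widespread
transcript downregulation, two distinct mechanisms are confounded in
ordinary RNA-seq: loss of the mRNA itself versus a change in how much of it
is being translated. Two signals separate them:

1. **Positional coverage decay.** Per-nucleotide read depth along each
   spliced transcript is rescaled to 100 positional bins of read
   *fractions*. A genotype-specific dip toward the 3' bins — and a more
   negative coverage change over the 3'UTR than over the CDS or 5'UTR — is
   the signature of increased 3'→5' degradation.

2. **Translation efficiency.** With log₂(count+1) expression x, the
   mutant-vs-control TE change of a gene is the difference of differences

   ```
   ΔTE = (x̄_TRAP,mut − x̄_TRAP,ctl) − (x̄_RNA,mut − x̄_RNA,ctl)
   ```

   so a gene whose total RNA halves while its ribosome binding is
   unchanged scores ΔTE = +1. Per-gene variability is estimated by
   leave-one-out jackknife resampling across the four sample groups
   (≤100 seeded combinations per gene), rescaled to a standard error, and
   summarized as Z = ΔTE / sd; |Z| > 4 (one-sided normal tail ≈ 3.17·10⁻⁵)
   flags significant TE changes.

Differential expression uses a gene-wise two-group linear model on
log₂(CPM+1) with empirical-Bayes variance moderation
(s̃²_g = (d₀s₀² + d s²_g)/(d₀+d), moderated t with d+d₀ df), thresholded at
fold change > 2 and p < 0.01. Overlaps between gene lists (for example,
3'UTR-biased transcripts vs increased-ΔTE genes) are tested with the exact
hypergeometric upper tail; length comparisons use Mann–Whitney U against an
expression-matched control set.

## Worked example

Simulate a study-shaped dataset (2,000 genes, 4v4 RNA and 3v3 TRAP samples,
negative-binomial counts, planted effect groups, mutant-only 3' coverage
decay on downregulated transcripts) and run every stage:

```bash
ribodelta simulate --outdir demo --seed 7 --n-genes 2000 \
    --decay-rate 0.2 --n-coverage-transcripts 200
ribodelta run-all --dataset-dir demo --outdir demo_out --seed 7
```

which prints the stage counts

```json
{
  "transcripts": 200,
  "coverage_kept": 188,
  "utr3_biased": 5,
  "rna_down": 109,
  "rna_up": 7,
  "te_increased": 14,
  "te_decreased": 1,
  "overlap": 0
}
```

— 109 genes pass the DE down threshold (the simulator plants 8%
"RNA down, ribosome binding unchanged" genes and 4% "down in both" genes),
188 of the 200 profiled transcripts pass the ≥1 read/nt coverage filter,
and 14 genes clear |Z| > 4 for increased ΔTE. The same objects are
available as a library:

```python
from ribodelta import DifferentialExpression, TranslationEfficiency

de = DifferentialExpression(rna_counts, sample_sheet, assay="RNA").fit()
print(de.summary())
te = TranslationEfficiency(rna_counts, trap_counts, sample_sheet).fit(seed=7)
print(te.summary())
```

```
Differential expression (moderated two-group t)
  genes: 2000   samples: 4 control vs 4 mutant
  prior df d0: 20.41   prior variance s0^2: 0.2829
  residual df: 6   total df: 26.41
  significant (|FC|>2, p<0.01): 7 up, 109 down

Translation-efficiency change (jackknife ΔTE)
  groups: rna_control=4, rna_mutant=4, trap_control=3, trap_mutant=3
  genes: 2000   resamples/gene: ≤100
  mean ΔTE: 0.02614   median: -0.01595
  |Z| > 4: 14 increased, 1 decreased
  unstable (sd = 0, ΔTE ≠ 0): 0
```

The prior df of ~20 means each gene's 6-df residual variance borrows
roughly 20 genes' worth of information from the variance prior; the ΔTE
distribution is centered near 0 because most genes are null, while the
planted "RNA down, TRAP unchanged" genes average ΔTE ≈ +1.

Each `run-all` stage (`segment`, `coverage`, `de`, `te`, `enrich`) is also
a standalone subcommand over the same files, and the output directory
carries a `manifest.json` with row counts and checksums — reruns with the
same seed are byte-identical.

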