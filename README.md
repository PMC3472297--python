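# cnasim

Synthetic tumour SNP-array genotyping data (per-SNP LRR and BAF signals)
under copy-number alterations, loss of heterozygosity, normal-cell
contamination and intra-tumour subclonality — plus a benchmarking harness
(overlap-based recall and a wrong-copy-number FDR approximation) for
stress-testing CNA/LOH callers on fully synthetic, truth-annotated samples.

## Model

Each sample is a mixture of a diploid normal cell type and one or more
tumour subclones. Per locus, each cell type carries an integer copy number
`x` and B-allele count `z`; the observed signals are

- `LRR_i = Σ_j w_ij · r(x_ij) + l + c_i`, with `r(x) ~ N(μ_x, σ_x)` per
  copy number, a sample-wide baseline shift `l` drawn from the DNA-index
  relationship, and an ARMA-autocorrelated bias `c`;
- `BAF_i = Σ_j w_ij z_ij / Σ_j w_ij x_ij + n_i`, where homozygous loci are
  forced to the exact extreme with probability `π` (default 0.30) and
  otherwise perturbed by a half-Gaussian, and heterozygous loci receive a
  full Gaussian.

Genotypes obey coherence rules: loci homozygous in the normal genome stay
homozygous (same allele) in every subclone, and within a region all
heterozygous loci derive from one haplotype-level event per clone, so the
B-allele count can only flip between `m` and `x − m` across SNPs.

Five pattern presets (`near_diploid`, `near_triploid`, `near_tetraploid`,
`loh_enriched`, `complex`) tile a synthetic genome with 205–280 regions of
10–160 SNPs, hitting characteristic DNA indexes (1.03 / 1.32 / 1.57 / 1.31
/ 1.39) and composition fractions. A scaffold mode builds hybrid samples
from a user-supplied TSV of region lengths, copy numbers, allelic ratios
and germline-LOH flags.

## CLI

```sh
# 5 replicates of the near-triploid pattern at 25% contamination
cnasim generate --pattern near_triploid --contamination 0.25 \
    --replicates 5 --seed 7 --out samples/

# hybrid samples from a scaffold
cnasim generate --scaffold scaffold.tsv --contamination 0.5 --seed 7 --out samples/

# score caller output against a truth annotation
cnasim evaluate --truth samples/near_triploid_c25_r000.truth.bed \
    --calls mycaller.tsv --group-by copy_number,length_bin --out report.tsv
```

`generate` writes, per replicate, an Illumina-style per-SNP signal table
(`Name Chr Position "Log R Ratio" "B Allele Freq"`), a PennCNV-dialect
`.pfb` file, and a BED-like truth annotation (0-based half-open bp). A YAML
config (`--config`) can override the μ/σ tables, BAF noise, ARMA
parameters, shift law, PFB source and grid layout; see
`SampleConfig.from_dict` for the keys.

Caller output for `evaluate` is a TSV `chrom start end copy_number[ loh]`
with `loh ∈ {none, somatic, germline}`; convert your caller's native
segments into this form first. Heterozygous-diploid fragments are excluded
from both truth and calls before scoring; a truth region counts as recalled
when a single call with the same copy number overlaps at least half its
length (`--min-overlap`), optionally also matching LOH presence
(`--require-loh`).

## Python API

```python
from cnasim import build_pattern, SampleConfig, composition

track, truth, grid = build_pattern("near_diploid", contamination=0.25, seed=1)
print(truth.dna_index, len(truth.regions), composition(truth))
```

Lower-level pieces — `sample_normal_genotypes`, `assign_region_genotypes`,
`synthesize_lrr`, `synthesize_baf`, `expected_signals`, `make_pfb`,
`recall_table`, `fdr_matrix`, `estimate_contraction` — are exported from
the package root.
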