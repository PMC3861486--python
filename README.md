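# pedexome

Pedigree-driven discovery of candidate disease variants from family exome
variant calls. The package implements the classic small-family workflow as
reusable, tested components:

1. **Inheritance-model filtering** — for each biallelic site, an exhaustive
   constraint search decides whether *any* full-penetrance genotype
   assignment to the whole pedigree (sequenced members fixed to their
   observed calls, everyone else free) is consistent with Mendelian
   transmission under AD / AR / X-linked dominant / X-linked recessive
   models. Structural rules exclude inapplicable chromosome scopes (Y when
   an affected female exists, MT on proven paternal origin, XLD on
   male-to-male transmission).
2. **Consequence annotation** — minimal transcript models (exons + CDS
   sequence) drive CDS/codon coordinate mapping, synonymous /
   nonsynonymous / stopgain / stoploss / frameshift / splicing calls and
   HGVS-style c./p. names (both `c.695G>T` and the legacy `c.G695T`).
3. **Filter cascade** — the staged exonic/splicing → non-synonymous →
   conserved → non-segdup → not-in-dbSNP → MAF < 0.05 pipeline with
   per-step SNV/indel accounting, followed by a strict novelty filter
   (any reported population frequency marks a variant as known).
4. **Prioritization** — strict consensus deleteriousness over seven
   categorical predictor columns, control-panel screening
   (polymorphism vs family-specific), family cosegregation checking and
   deterministic candidate ranking.
5. **Simulation** — a seeded generator that emits a complete synthetic
   dataset (VCF, PED, transcript models + CDS FASTA, conserved/segdup
   BEDs, frequency/known-variant tables, prediction profiles, validation
   facts) around a 7-member / 5-sequenced family, with one planted causal
   variant, background variants at population frequencies, optional
   genotyping error, missing calls, multi-allelic loci and
   pedigree-consistent false-positive calls — all tied to a truth table.

## Test

```bash
python -m pytest -q tests/
```

The acceptance suite (`tests/test_acceptance.py`) includes an exhaustive
matcher-vs-oracle equivalence check and a 100-seed planted-variant
recovery experiment; the full run takes about a minute.

## CLI

```bash
# generate a synthetic dataset
pedexome simulate --seed 1 --out data/ --n-background 1000

# full pipeline on that dataset
pedexome run --dataset-dir data/ --out results/

# or stage by stage
pedexome inherit  --vcf data/study.vcf --ped data/family.ped --out inherit.tsv
pedexome annotate --vcf data/study.vcf --tx data/transcripts.tsv \
                  --fasta data/cds.fa --out annotated.tsv
pedexome cascade  --vcf data/study.vcf --tx data/transcripts.tsv \
                  --fasta data/cds.fa --conserved data/conserved.bed \
                  --segdup data/segdup.bed --dbsnp data/dbsnp.tsv \
                  --freq-1000g data/freq_1000g.tsv --out candidates.tsv
pedexome prioritize --candidates candidates.tsv \
                    --predictions data/predictions.tsv \
                    --validations data/validations.tsv \
                    --ped data/family.ped --out ranked.tsv
```

`pedexome run` also accepts a YAML config (`--config pipeline.yaml`) whose
keys mirror `PipelineConfig`; command-line flags override the file.

## File formats

* **PED** — 6 standard columns plus an optional 7th `sequenced` flag.
* **VCF v4.x** — unphased GT; `./.` is missing; haploid GT encodes male X.
* **Transcripts** — TSV (gene, transcript_id, chrom, strand,
  `start-end,...` exon list, CDS bounds) + FASTA of spliced CDS sequences.
* **BED** — 0-based half-open, converted to 1-based inclusive internally.
* **Tables** — headered TSVs keyed by (chrom, pos, ref, alt) for
  frequencies, known variants, and validation facts; prediction profiles
  keyed by gene.
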