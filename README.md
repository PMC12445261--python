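# addom

Additive + dominance genomic analysis for small livestock cohorts, built
around a divergent selection/mating design: cohort simulation, variant QC,
genomic and pedigree relationship matrices, AI-REML variance components with
liability-scale conversion for binary traits, BLUP breeding values and their
correlations, joint additive/dominance single-variant association with
Meff-based significance thresholds, and candidate-gene annotation.

## Modules

| module            | purpose |
|-------------------|---------|
| `addom.cohort`    | synthetic selection/mating cohorts: pedigree, gene-dropped genotypes, traits with configurable additive/dominance architecture, binary liability traits |
| `addom.qc`        | call-rate / MAF / exact-HWE variant filters, PCs from a relationship matrix, effective number of independent variants by windowed LD pruning |
| `addom.kinship`   | additive (centred-dosage) and dominance (`-2p², 2pq, -2q²` coding) genomic matrices; pedigree numerator and dominance matrices by the tabular method |
| `addom.varcomp`   | AI-REML with EM fallback, heritability and dominance fractions with delta-method SEs, observed-to-liability-scale transform |
| `addom.blup`      | BLUP breeding values at fixed variance components, EBV Pearson correlation tables with significance stars, descriptive statistics |
| `addom.gwas`      | per-variant GLS scan with simultaneous additive and dominance codings, genomic inflation factor, Bonferroni/suggestive thresholds, Manhattan export |
| `addom.annotate`  | gene annotation by a strand-agnostic ±1 kb proximity rule (GFF3/BED input) |
| `addom.io`        | VCF, PLINK `.bed/.bim/.fam`, TSV and GCTA-style binary relationship matrices |

## CLI

```bash
addom simulate --n-variants 2000 --seed 1 --out sim           # cohort -> VCF/CSV/JSON
addom qc --vcf sim.vcf --out qc                                # filters + Meff
addom kinship --vcf qc.filtered.vcf --make-grm --out grm       # G (or --make-dgrm/-a/-dped)
addom reml --grm grm --pheno sim.traits.csv --trait TL --out r # variance components
addom gwas --vcf qc.filtered.vcf --grm grm --pheno sim.traits.csv \
      --trait TL --meff-from-geno --out scan                   # A+D association scan
addom annotate --assoc scan.assoc.tsv --genes genes.gff3 --out cand
```

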