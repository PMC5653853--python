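# quasipop

Low-frequency ("localised heterogeneity") variant analysis for deep-sequenced
phage populations: simulate quasispecies-like populations with planted
single-nucleotide variants on weighted haplotypes, call variants against the
sample consensus with strict depth/frequency thresholds and a
six-configuration two-standard-deviation consensus filter, measure read-backed
pairwise co-occurrence of variant sites, and localise variants on annotated
gene modules.

## Modules

| module | purpose |
| --- | --- |
| `quasipop.popgen_sim` | haplotype populations with closed-form truth (site frequencies, pairwise co-occurrence); paired-end read simulation (2×300 bp, configurable coverage/insert/error/quality model) incl. two-phage co-infection pools |
| `quasipop.read_qc` | sliding-window quality trimming (mean Q < 20 over 5 bases) and the variant-calling read filter (mean Q ≥ 30, length ≥ 50, pairs dropped together) |
| `quasipop.align_lite` | ungapped substitution-only seed-and-verify read mapper (k-mer index, exhaustive-scored candidates, deterministic tie-breaks) plus text SAM ingest/export via pysam |
| `quasipop.pileup_caller` | strand-aware pileups with mate-overlap resolution, pileup-majority sample consensus, variant calls (> 1% frequency, ≥ 100× depth, minimum alt count), two-SD six-value consensus filter, substitution classification |
| `quasipop.linkage` | fragment-level co-occurrence of variant-site pairs: `100·n_both/(n_both+n_only_i+n_only_j)` with full count output |
| `quasipop.locale_annot` | gene-category assignment (non-structural / structural / adsorption / other / non-coding), per-category summaries, codon consequences (e.g. `E123K`), multi-SNP codons |
| `quasipop.cli_pipeline` | end-to-end orchestration, YAML config, truth comparison (precision/recall/frequency error) |

## CLI

```bash
quasipop simulate --config sim.yaml --outdir out --seed 1
quasipop qc --mode variant-filter --in1 R1.fastq --in2 R2.fastq --out1 q1.fastq --out2 q2.fastq
quasipop align --ref ref.fasta --fastq R1.fastq,R2.fastq --out aln.sam
quasipop call --sam aln.sam --ref ref.fasta --min-freq 0.01 --min-depth 100 --out-vcf calls.vcf
quasipop linkage --sam aln.sam --vcf calls.vcf --ref ref.fasta --max-span 900 --out cooccurrence.tsv
quasipop annotate --vcf calls.vcf --gff genes.gff3 --ref ref.fasta
quasipop run --config pipeline.yaml
quasipop compare --vcf calls.vcf --truth truth_variants.tsv
```

A minimal simulation config:

```yaml
reference: {length: 43000, id: simA}
variants:
  frequencies: [0.0144, 0.0831, 0.40]
reads:
  mean_coverage: 1000
  substitution_error_rate: 0.002
  quality: calibrated   # or a constant Phred score
```

`quasipop call` accepts one SAM (called under the internal six-parameterization
grid: base quality cutoffs {15,20,25} × minimum alt counts {2,4}) or a
comma-separated list of externally produced SAMs, each contributing one value
to the per-site frequency vector before the two-SD consensus.

## File formats

FASTA / FASTQ (Phred+33) / text SAM / GFF3 (gene category in a `category=`
attribute) / VCF 4.2 (INFO `AF, DP, AC, NCONF`; FILTER `PASS`, `sd2_fail`,
`low_freq`, `low_cov`) / TSV truth and result tables. All coordinates are
1-based inclusive.
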