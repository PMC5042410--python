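# phagesieve

Identify assembled metagenomic contigs of bacteriophage origin by
comparing them to a database of phage whole-genome sequences.

Phages are the most abundant biological entities on earth, yet they
contribute only a small share of the DNA in most metagenomes and have no
single universally shared gene. Many phage genomes are also mosaic —
different regions resemble *different* known phages — so classifying a
contig by its single best database hit misses exactly the cases that
matter. `phagesieve` instead pools **all** nucleotide-alignment hits of a
contig against the whole database into one score, the database-wide
average nucleotide identity:

```
          Σᵢ idᵢ · alᵢ
  %ANI = ────────────── · m_cov
            Σᵢ alᵢ
```

where `idᵢ` and `alᵢ` are the percent identity and alignment length of
hit *i* (all hits with e-value ≤ 0.05, to every database genome), and
`m_cov` is the fraction of the contig covered by the union of all hit
intervals after overlaps are merged. A contig is called **phage** when
%ANI > 1.7 — a deliberately low cutoff, because known phage genomes cover
only a small part of phage sequence diversity.

The package also ships the machinery to build and evaluate such a
classifier:

- **blast_io** — read/write the standard 12-column tabular alignment
  format; optionally run `blastn`/`makeblastdb` as external subprocesses
  (every other operation works on precomputed hit files).
- **ani** — interval merging, %ANI scoring, classification.
- **kmer** — k-mer query coverage `q_cov` and the analytic bridge
  `q_cov = (%ANI/100)^k`, which maps a 95% ANI cutoff at k = 16 to a
  q_cov cutoff of 0.44.
- **reduce** — Hobohm-1 homology reduction (alignment- or k-mer-based)
  and size-balanced partitioning for cross-validation.
- **fragment** — artificial contigs: random cuts ≥ 500 bp from positive
  genomes plus length-matched cuts from a negative pool.
- **evaluate** — ROC/AUC with tie grouping, threshold selection at the
  balanced-error point (FPR = 1 − TPR), length-binned AUC, per-dataset
  summary tables, and a pooled cross-validation driver.
- **synthetic** — seeded generators for random genomes, mutated
  relatives, mosaic genomes, and synthetic hit tables, so the whole
  pipeline is testable without external data.

## Worked example

Score two contigs against precomputed tabular hits. `contig_1` (2000 bp)
has two hits: 90% identity over bases 1–1000 and 70% identity over bases
1501–2000; `contig_2` has none.

```bash
phagesieve classify --contigs contigs.fasta --hits hits.tsv
```

```
contig_id	classification	pct_ani	merged_coverage	n_genomes_hit	contig_length
contig_1	phage	62.500	0.750	2	2000
contig_2	negative	0.000	0.000	0	800
```

For `contig_1` the identity term is (90·1000 + 70·500)/1500 = 83.3̅, the
merged coverage is 1500/2000 = 0.75, and %ANI = 83.3̅ × 0.75 = 62.5 —
far above the 1.7 threshold, so the contig is called phage. `contig_2`
has no hits, scores 0, and is called negative. With a database FASTA
instead of a hit file (`--database phages.fasta`), `blastn` is invoked
externally with an e-value cutoff of 0.05.

A full benchmark run — partition genomes by size, cut artificial
contigs, rotate a hold-one-partition-out cross-validation, pool the
predictions — is one command:

```bash
phagesieve crossval --phages phages.fasta --negatives negatives.fasta \
    --n 5 --seed 1 --out-prefix cv_
```

It prints the pooled AUC and the selected balanced-error threshold and
writes the per-query score table to `cv_scores.tsv`.

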