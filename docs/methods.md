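# Methods

## The score

A query contig is aligned with `blastn` against a database of phage
whole-genome sequences and every hit with e-value ≤ 0.05 (inclusive) is
retained, across *all* database genomes. The score is

    %ANI = ( Σᵢ idᵢ·alᵢ / Σᵢ alᵢ ) · m_cov

with `idᵢ` the aligner-reported percent identity, `alᵢ` the reported
alignment length (gaps included, no correction), and `m_cov` the merged
query coverage: hit intervals in query coordinates are pooled over all
subjects, merged, and the covered-base count is divided by the contig
length. Pooling across subjects is the point of the method — mosaic
phage genomes are jointly covered by hits to several different genomes,
while a best-single-hit score sees only a fraction of the evidence.

Conventions fixed here (the underlying quantities do not pin them down):

- **Interval merging** treats closed 1-based intervals; intervals that
  abut ([1,100], [101,200]) merge, since coverage is a per-base property
  and no base between them is uncovered. Merge behaviour beyond the
  covered-base count is irrelevant to the score.
- **No overlap deduplication in the identity term**: Σ id·al runs over
  all retained alignments even when they overlap on the query; only
  `m_cov` merges. Duplicated hits therefore never inflate the score
  above 100 (the identity term is a weighted mean) nor change coverage.
- **Classification is strict**: phage iff %ANI > threshold (default
  1.7). A contig exactly at the threshold is negative, matching the
  ROC convention "positive ⇔ score > cutoff".
- Query coordinates of a nucleotide query are always forward; hits with
  reversed query coordinates are rejected as malformed at parse time.
  Reversed *subject* coordinates (minus-strand hits) are accepted and
  irrelevant, since scoring uses query coordinates only.
- %ANI is printed to 3 decimals; internal computation is full precision.

The 1.7 default is the balanced-error threshold obtained on a large
curated benchmark; it is a parameter everywhere, since it is expected to
drift as phage databases grow.

## K-mer similarity and the q_cov–ANI bridge

For settings where alignment is too slow (homology-reducing thousands of
bacterial genomes), similarity is measured as k-mer query coverage:
the fraction of the query's distinct k-mers found in the template.
K-mers are restricted to those starting with a literal prefix (default
`ATG`, k = 16) to thin the sets; both the sequence and its reverse
complement are scanned, because a literal prefix is strand-specific and
canonicalizing would break it. K-mers containing ambiguous bases are
dropped.

Under uniformly random substitutions at per-base rate m, a k-mer
survives with probability (1−m)^k, giving

    q_cov = (%ANI / 100)^k

so a 95% ANI cutoff maps to q_cov = 0.95¹⁶ ≈ 0.44 at k = 16. When
mutations cluster instead, q_cov tracks %ANI itself, so the relation
gives the *maximal* ANI consistent with an observed q_cov — which is the
conservative direction for exclusion. Both regimes are verified by
simulation in the test suite.

The denominator of q_cov is taken as the query's own distinct
prefix-filtered k-mer count. This is the only reading under which the
bridge formula holds (q_cov is then exactly a k-mer survival
probability); a database-wide denominator would depend on database size
and could not equal (%ANI/100)^k. This resolves a genuine ambiguity in
how the quantity is described in the field.

## Dataset construction

- **Hobohm-1 reduction**: a greedy single pass over the genome list;
  a genome is accepted iff its similarity to every previously accepted
  genome stays at or below the cutoff (exclusion is strict ">"). The
  similarity is asymmetric (%ANI of candidate-as-query against the
  accepted genome). The acceptance order is a parameter; the default
  sorts longest-first, the conventional Hobohm choice that keeps the
  most informative representative. Defaults: 90 %ANI for phage sets,
  q_cov 0.44 (the 95%-ANI image) for large negative sets.
- **Partitioning**: genomes are sorted descending by length and each
  consecutive block of n genomes is dealt randomly across the n
  partitions, one per partition (a trailing partial block goes to
  distinct random partitions). This balances the length — and with it,
  roughly, the taxonomic — distribution across partitions; sizes differ
  by at most one.
- **Artificial contigs**: each positive genome is cut 5 times; cut
  length is uniform on [500 bp, genome length] (the minimum is the
  contract, the uniform law is this package's choice — the sampler is
  pluggable), start uniform over valid positions. Negative cuts match
  the positive cut lengths exactly, drawing the (genome, start) pair
  uniformly over all feasible pairs, so sequence length never separates
  the classes by construction. Fragments inherit their source genome's
  partition and are emitted forward-strand only (alignment scoring is
  strand-agnostic). Fragment ids encode source, start, and length.

## Evaluation

The ROC is computed with ties grouped at one threshold step, which makes
the trapezoidal area identical to the Mann–Whitney pairwise estimator
P(score_pos > score_neg) + ½P(tie); the tests assert this equivalence
exactly on random instances, with scikit-learn's AUC as a second,
independent oracle. Because a positive call requires score > cutoff,
each operating point corresponds to a half-open *interval* of cutoffs
between adjacent distinct scores; the point is represented by the
interval midpoint, so the selected threshold of a perfectly separated
sample is the midpoint of the separating gap, not a data value.

The classification threshold is selected where FPR = 1 − TPR (the
balanced-error point; the intersection of the ROC curve with the
descending diagonal). Along descending cutoffs FPR − (1 − TPR) rises
from −1 to +1, so a crossing always exists; when it falls between two
operating points the cutoff is linearly interpolated between their
representatives. The degenerate all-ties curve returns the single score.

Length-binned AUC uses half-open bins [lo, hi) with user-supplied edges
(no canonical edges exist); bins missing a class report NaN rather than
erroring. Cross-validation evaluates *pooled* predictions from all folds
rather than averaging per-fold figures.

The cross-validation driver builds, for each fold, a database from all
other partitions (asserting on every run that no held-out genome id
leaks into it) and scores the held-out whole genomes, their artificial
contigs, an equal number of whole negative sequences, and length-matched
negative contigs. It shells out to `blastn`; with no aligner on PATH it
raises a capability error, and every scoring path accepts precomputed
hit files instead.

## What the synthetic data does and does not emulate

`synthetic.py` generates i.i.d. random genomes, point-mutated relatives
(independent per-base substitution to a uniformly chosen different
base), mosaic concatenations of donor segments, and synthetic hit tables
that place one hit per mosaic segment with the planted identity plus
truncated Gaussian noise (e-values 10⁻¹⁰, far under the 0.05 filter,
unless a boundary case is requested). All generators take explicit seeds
and are bit-reproducible; there is no hidden global random state.

This emulates the *geometry* the method exploits — segment provenance,
identity levels, coverage fractions, family structure — but not real
phage biology: no gene content, codon structure, indels, rearrangement
within segments, or database-scale diversity. Passing tests therefore
demonstrate that the scoring, reduction, and evaluation machinery is
correct and that the method separates classes whenever held-out queries
share recognizable ancestry with the database; they do not certify the
headline accuracy achievable on real curated phage databases, which
depends on real diversity and database completeness.

The end-to-end cross-validation test runs at desk scale: 4 mutation
families × 5 members of 6 kb at substitution rate 0.04, 20 random 6 kb
negatives, 5 partitions, 5 cuts per genome (≥ 500 bp) — sizes chosen so
the whole rotated benchmark, through real `blastn`, completes in
seconds while still exercising every stage.

## Known limitations

- The method cannot identify truly novel phages: it requires similarity
  to some database genome. Accuracy drops sharply for very short
  contigs (a warning is logged below 500 bp).
- `ani_similarity` is asymmetric and alignment-backed; Hobohm-1 results
  depend on the acceptance order by design.
- The uniform cut-length law and the negative-pool composition of the
  artificial-contig benchmark are package choices, configurable by the
  caller.
- The k-mer routine is a minimal coverage calculator, not a full k-mer
  typing tool (no scoring modes or winner-takes-all).
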