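"""K-mer genome similarity and its analytic link to average nucleotide identity.

The query coverage q_cov of a sequence against a template is the fraction
of the query's distinct k-mers that also occur in the template.  Under
uniformly random substitutions at per-base rate m, a k-mer survives intact
with probability (1 - m)^k, which gives the analytic bridge

    q_cov = (%ANI / 100) ** k

used to translate an ANI cutoff into a k-mer coverage cutoff (e.g. 95% ANI
at k = 16 maps to 0.44).  When mutations instead cluster in one region,
q_cov tracks %ANI itself, so (%ANI/100)^k is the *maximal* ANI consistent
with an observed q_cov.

A literal start prefix (default ``ATG``) thins the k-mer sets the way fast
k-mer lookup tools do.  Because a literal prefix is strand-specific, both
the sequence and its reverse complement are scanned rather than using
canonical k-mers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import reverse_complement

from .genomes import GenomeRecord

DEFAULT_K = 16
DEFAULT_PREFIX = "ATG"

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class KmerProfile:
    """Distinct prefix-filtered k-mers of one source sequence, both strands."""

    source_id: str
    k: int
    prefix: str
    kmers: frozenset[str] = field(repr=False)

    def __post_init__(self) -> None:
        bad = [m for m in self.kmers if len(m) != self.k or not m.startswith(self.prefix)]
        if bad:
            raise ValueError(
                f"profile {self.source_id!r}: {len(bad)} k-mers violate "
                f"length {self.k} / prefix {self.prefix!r}"
            )


def _scan_kmers(sequence: str, k: int, prefix: str) -> set[str]:
    kmers: set[str] = set()
    for strand in (sequence, reverse_complement(sequence)):
        n = len(strand)
        pos = 0
        while True:
            pos = strand.find(prefix, pos)
            if pos < 0 or pos + k > n:
                break
            mer = strand[pos : pos + k]
            if _VALID.issuperset(mer):  # ambiguous bases invalidate a k-mer
                kmers.add(mer)
            pos += 1
    return kmers


def build_profile(
    source: GenomeRecord | str,
    k: int = DEFAULT_K,
    prefix: str = DEFAULT_PREFIX,
    source_id: str | None = None,
) -> KmerProfile:
    """Collect the distinct k-mers of a sequence that start with ``prefix``."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(prefix) > k:
        raise ValueError(f"prefix {prefix!r} longer than k={k}")
    if isinstance(source, GenomeRecord):
        sequence = source.sequence
        source_id = source_id or source.genome_id
    else:
        sequence = source
        source_id = source_id or "<anonymous>"
    return KmerProfile(
        source_id=source_id,
        k=k,
        prefix=prefix.upper(),
        kmers=frozenset(_scan_kmers(sequence.upper(), k, prefix.upper())),
    )


def qcov_threshold(ani_percent: float, k: int) -> float:
    """Map an ANI cutoff (in percent) to the equivalent k-mer coverage cutoff.

    Returns ``(ani_percent / 100) ** k``, the probability that a k-mer is
    untouched when substitutions land uniformly at random at per-base rate
    ``1 - ani_percent/100``.
    """
    if not 0.0 <= ani_percent <= 100.0:
        raise ValueError(f"ani_percent out of [0, 100]: {ani_percent}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return (ani_percent / 100.0) ** k


def kmer_qcov(
    query: GenomeRecord | str,
    profile_db: KmerProfile | Iterable[KmerProfile],
) -> float:
    """Query coverage: shared distinct k-mers over the query's distinct k-mers.

    The denominator is the query's own prefix-filtered k-mer count; this is
    the reading under which q_cov equals the survival probability
    (%ANI/100)^k of a query k-mer.  A query shorter than k (or with no
    prefix-matching k-mers) scores 0 with a warning rather than an error.
    """
    profiles = [profile_db] if isinstance(profile_db, KmerProfile) else list(profile_db)
    if not profiles:
        raise ValueError("empty profile database")
    k = profiles[0].k
    prefix = profiles[0].prefix
    if any(p.k != k or p.prefix != prefix for p in profiles):
        raise ValueError("profiles mix k or prefix settings")
    seq = query.sequence if isinstance(query, GenomeRecord) else query
    if len(seq) < k:
        warnings.warn(
            f"query shorter than k={k}; query coverage reported as 0",
            stacklevel=2,
        )
        return 0.0
    query_kmers = _scan_kmers(seq.upper(), k, prefix)
    if not query_kmers:
        warnings.warn(
            f"query has no k-mers with prefix {prefix!r}; query coverage reported as 0",
            stacklevel=2,
        )
        return 0.0
    db_kmers: set[str] = set()
    for p in profiles:
        db_kmers |= p.kmers
    return len(query_kmers & db_kmers) / len(query_kmers)


def qcov_ani_curve(
    genomes: list[GenomeRecord],
    ani_of_pair,
    k: int = DEFAULT_K,
    prefix: str = DEFAULT_PREFIX,
) -> list[tuple[str, float, float]]:
    """Diagnostic: iteratively grow a database, pairing each new genome's
    best k-mer coverage with its alignment %ANI to the same template.

    ``ani_of_pair(query, template) -> %ANI`` supplies the alignment-based
    score.  Returns (genome_id, q_cov, pct_ani) tuples for each genome
    after the first; useful for checking q_cov <= implied (%ANI/100)^k
    behaviour on synthetic genomes.
    """
    out: list[tuple[str, float, float]] = []
    accepted: list[tuple[GenomeRecord, KmerProfile]] = []
    for g in genomes:
        prof = build_profile(g, k=k, prefix=prefix)
        if accepted:
            covs = [(kmer_qcov(g, p), tmpl) for tmpl, p in accepted]
            best_cov, best_tmpl = max(covs, key=lambda t: t[0])
            out.append((g.genome_id, best_cov, ani_of_pair(g, best_tmpl)))
        accepted.append((g, prof))
    return out
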