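"""Database-wide average nucleotide identity (%ANI) scoring of contigs.

A query contig is compared against an entire phage whole-genome database,
not just its best hit.  All retained alignments (e-value <= 0.05 by
default) are aggregated into one score:

    %ANI = ( sum_i id_i * al_i / sum_i al_i ) * m_cov

where ``id_i`` and ``al_i`` are the aligner-reported percent identity and
alignment length of hit *i*, and ``m_cov`` is the fraction of query bases
covered by the union of all hit intervals after overlaps are merged.
Pooling hits across every database genome is deliberate: many phages have
mosaic genomes whose segments each resemble a *different* known phage, so
no single genome covers the query well even when the query is clearly
phage-derived.

A contig is classified as phage when its %ANI strictly exceeds a fixed
threshold (default 1.7).  The threshold is low because known phage
genomes cover only a small part of phage sequence diversity.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .blast_io import AlignmentHit

#: Default classification threshold in %ANI units.
DEFAULT_ANI_THRESHOLD = 1.7


@dataclass(frozen=True)
class AniResult:
    """Per-contig aggregate score against the whole database.

    ``n_subjects`` counts distinct database genomes hit; ``n_alignments``
    counts individual alignment records (one genome may contribute many).
    """

    query_id: str
    query_length: int
    pct_ani: float
    merged_coverage: float
    n_subjects: int
    n_alignments: int
    is_phage: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_ani <= 100.0:
            raise ValueError(f"pct_ani out of [0, 100]: {self.pct_ani}")
        if not 0.0 <= self.merged_coverage <= 1.0:
            raise ValueError(
                f"merged_coverage out of [0, 1]: {self.merged_coverage}"
            )
        if self.n_alignments < self.n_subjects:
            raise ValueError("n_alignments cannot be below n_subjects")


def merge_query_intervals(
    hits: Sequence[AlignmentHit],
) -> list[tuple[int, int]]:
    """Merge hit intervals on the query into disjoint maximal intervals.

    Intervals are closed and 1-based, pooled across ALL subject genomes.
    Abutting intervals ([1,100] and [101,200]) merge: coverage is a
    per-base property and there is no uncovered base between them.

    Returns sorted, pairwise-disjoint, non-adjacent intervals whose union
    equals the union of ``[q_start, q_end]`` over all hits.

    Raises
    ------
    ValueError
        If the hits do not all share one query_id.
    """
    if not hits:
        return []
    query_ids = {h.query_id for h in hits}
    if len(query_ids) > 1:
        raise ValueError(
            f"hits span multiple queries: {sorted(query_ids)}; merge one query at a time"
        )
    intervals = sorted((h.q_start, h.q_end) for h in hits)
    merged: list[list[int]] = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start <= merged[-1][1] + 1:  # overlap or abut
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def covered_bases(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bases covered by disjoint closed intervals."""
    return sum(e - s + 1 for s, e in intervals)


def compute_ani(
    hits: Sequence[AlignmentHit],
    query_length: int,
    threshold: float = DEFAULT_ANI_THRESHOLD,
    query_id: str | None = None,
) -> AniResult:
    """Aggregate a contig's hits into its database-wide %ANI score.

    The identity term is the alignment-length-weighted mean of the
    reported percent identities over *all* retained alignments — hits are
    not deduplicated or overlap-filtered, only the coverage factor uses
    interval merging.  An empty hit list yields a zero score classified
    as non-phage.

    Parameters
    ----------
    hits
        Alignments of one query, already filtered at the e-value cutoff.
    query_length
        Length of the query contig in base pairs (>= 1).
    threshold
        Classification cutoff in %ANI units (strict ``>``).
    query_id
        Identifier for the result; defaults to the hits' shared query_id.
    """
    if query_length < 1:
        raise ValueError(f"query_length must be >= 1, got {query_length}")
    if not hits:
        return AniResult(
            query_id=query_id or "",
            query_length=query_length,
            pct_ani=0.0,
            merged_coverage=0.0,
            n_subjects=0,
            n_alignments=0,
            is_phage=False,
        )
    if query_id is None:
        query_id = hits[0].query_id
    total_len = sum(h.aln_length for h in hits)
    weighted_id = sum(h.pct_identity * h.aln_length for h in hits)
    m_cov = min(1.0, covered_bases(merge_query_intervals(hits)) / query_length)
    pct_ani = (weighted_id / total_len) * m_cov
    return AniResult(
        query_id=query_id,
        query_length=query_length,
        pct_ani=pct_ani,
        merged_coverage=m_cov,
        n_subjects=len({h.subject_id for h in hits}),
        n_alignments=len(hits),
        is_phage=classify(pct_ani, threshold),
    )


def classify(pct_ani: float, threshold: float = DEFAULT_ANI_THRESHOLD) -> bool:
    """True iff the score strictly exceeds the threshold.

    The boundary convention is strict: a contig sitting exactly at the
    threshold is called non-phage, matching the ROC convention that a
    positive call requires score > cutoff.
    """
    return pct_ani > threshold


RESULT_COLUMNS = (
    "contig_id", "classification", "pct_ani",
    "merged_coverage", "n_genomes_hit", "contig_length",
)


def write_results(
    results: Iterable[AniResult], dest: str | os.PathLike | IO[str]
) -> None:
    """Write per-contig results as a tab-separated table (%ANI to 3 decimals)."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt") as fh:
            write_results(results, fh)
        return
    dest.write("\t".join(RESULT_COLUMNS) + "\n")
    for r in results:
        dest.write(
            f"{r.query_id}\t{'phage' if r.is_phage else 'negative'}\t"
            f"{r.pct_ani:.3f}\t{r.merged_coverage:.3f}\t"
            f"{r.n_subjects}\t{r.query_length}\n"
        )
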