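"""Homology reduction and size-balanced partitioning of genome sets.

Redundancy in a reference database biases both scoring and
cross-validation, so genome sets are reduced with the greedy single-pass
Hobohm-1 scheme: walk the genomes in a chosen order and accept one only
if its similarity to every previously accepted genome stays at or below a
threshold.  Similarity can be alignment-based (%ANI, threshold 90) or, for
large sets where alignment is too slow, k-mer query coverage (threshold
0.44, the k = 16 image of 95% ANI).

Partitioning for cross-validation sorts genomes by length and deals each
consecutive block of ``n_parts`` genomes randomly across the partitions,
one per partition, so all partitions see a comparable length (and hence
taxonomy) distribution.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import blast_io
from .ani import compute_ani
from .genomes import GenomeRecord, read_fasta, write_fasta  # noqa: F401  (re-export)
from .kmer import DEFAULT_K, DEFAULT_PREFIX, build_profile, kmer_qcov

SimilarityFn = Callable[[GenomeRecord, GenomeRecord], float]

DEFAULT_ANI_REDUCE_THRESHOLD = 90.0
DEFAULT_QCOV_REDUCE_THRESHOLD = 0.44


def sort_by_length_desc(genomes: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Longest first; ties broken by id for determinism."""
    return sorted(genomes, key=lambda g: (-g.length, g.genome_id))


def hobohm1_reduce(
    genomes: Sequence[GenomeRecord],
    similarity: SimilarityFn,
    threshold: float,
) -> list[GenomeRecord]:
    """Greedy single-pass redundancy reduction.

    A genome is accepted iff ``similarity(genome, accepted)`` does not
    exceed ``threshold`` for every previously accepted genome (rejection
    is strict ``>``).  The candidate is always the first argument (the
    query side of an asymmetric similarity).  Output preserves input
    order; callers pre-sort by their chosen key (length-descending is the
    conventional choice, see :func:`sort_by_length_desc`).
    """
    accepted: list[GenomeRecord] = []
    for g in genomes:
        keep = True
        for a in accepted:
            try:
                sim = similarity(g, a)
            except Exception as exc:
                exc.add_note(
                    f"while comparing candidate {g.genome_id!r} "
                    f"to accepted {a.genome_id!r}"
                )
                raise
            if sim > threshold:
                keep = False
                break
        if keep:
            accepted.append(g)
    return accepted


def ani_similarity(
    a: GenomeRecord,
    b: GenomeRecord,
    evalue_max: float = blast_io.DEFAULT_EVALUE_MAX,
    workdir: str | os.PathLike | None = None,
) -> float:
    """Pairwise %ANI with ``a`` as query and ``b`` as a one-genome database.

    Runs the external aligner; raises :class:`~phagesieve.errors.CapabilityError`
    when no aligner is on PATH.  Self-comparison returns ~100.
    """
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        qpath = Path(tmp) / "query.fasta"
        spath = Path(tmp) / "subject.fasta"
        write_fasta([a], qpath)
        write_fasta([b], spath)
        grouped = blast_io.align_fastas(qpath, spath, evalue_max, workdir=tmp)
    hits = grouped.get(a.genome_id, [])
    return compute_ani(hits, a.length, query_id=a.genome_id).pct_ani


def kmer_qcov_similarity(
    k: int = DEFAULT_K, prefix: str = DEFAULT_PREFIX
) -> SimilarityFn:
    """Similarity function returning pairwise k-mer query coverage in [0, 1].

    Pair with threshold ``(ani/100)**k`` (0.44 at 95% ANI, k=16) to mimic
    an ANI cutoff without alignment.  Profiles are cached per genome id.
    """
    cache: dict[str, object] = {}

    def sim(a: GenomeRecord, b: GenomeRecord) -> float:
        prof = cache.get(b.genome_id)
        if prof is None:
            prof = build_profile(b, k=k, prefix=prefix)
            cache[b.genome_id] = prof
        return kmer_qcov(a, prof)

    return sim


def partition_by_size(
    genomes: Sequence[GenomeRecord],
    n_parts: int,
    seed: int,
) -> list[list[GenomeRecord]]:
    """Deal size-sorted genomes into ``n_parts`` length-balanced partitions.

    Genomes are sorted descending by length; each consecutive block of
    ``n_parts`` genomes is randomly permuted over the partitions, one
    genome per partition (a trailing partial block goes to distinct
    random partitions).  Partition sizes differ by at most one and the
    assignment is deterministic under ``seed``.
    """
    if n_parts < 2:
        raise ValueError(f"n_parts must be >= 2, got {n_parts}")
    if n_parts > len(genomes):
        raise ValueError(
            f"n_parts={n_parts} exceeds number of genomes ({len(genomes)})"
        )
    rng = np.random.default_rng(seed)
    ordered = sort_by_length_desc(genomes)
    parts: list[list[GenomeRecord]] = [[] for _ in range(n_parts)]
    for i in range(0, len(ordered), n_parts):
        block = ordered[i : i + n_parts]
        slots = rng.permutation(n_parts)[: len(block)]
        for g, p in zip(block, slots):
            parts[int(p)].append(g)
    return parts
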