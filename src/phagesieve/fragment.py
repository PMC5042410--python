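"""Artificial-contig generation: random cuts mimicking assembled metagenomic contigs.

Whole genomes are easy to classify; real metagenomic contigs are short.
To benchmark at realistic contig sizes, each positive genome is cut a
fixed number of times (default 5) at random positions with random lengths
(minimum 500 bp, uniform up to the genome length), and the negative pool
is cut into fragments whose lengths exactly match the positive cuts, so
that length never separates the classes by construction.  Fragments
inherit the cross-validation partition of their source genome.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np

from .genomes import GenomeRecord

log = logging.getLogger(__name__)

DEFAULT_CUTS_PER_GENOME = 5
DEFAULT_MIN_LEN = 500


@dataclass(frozen=True)
class FragmentSpec:
    """One cut taken from a source genome; coordinates are 1-based inclusive."""

    fragment_id: str
    source_id: str
    start: int
    length: int
    label: str  # "phage" | "negative"
    partition: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.length < 1:
            raise ValueError(
                f"fragment {self.fragment_id!r}: start and length must be >= 1"
            )


def _extract(genome: GenomeRecord, start: int, length: int) -> str:
    if start + length - 1 > genome.length:
        raise ValueError(
            f"cut [{start}, {start + length - 1}] exceeds {genome.genome_id!r} "
            f"length {genome.length}"
        )
    return genome.sequence[start - 1 : start + length - 1]


def cut_positive(
    genomes: Sequence[GenomeRecord],
    cuts_per_genome: int = DEFAULT_CUTS_PER_GENOME,
    min_len: int = DEFAULT_MIN_LEN,
    seed: int = 0,
    label: str = "phage",
    partition_of: dict[str, int] | None = None,
) -> list[tuple[FragmentSpec, str]]:
    """Cut each genome ``cuts_per_genome`` times at random length >= ``min_len``.

    Lengths are uniform on [min_len, genome length], starts uniform over
    valid positions; both deterministic under ``seed``.  Genomes shorter
    than ``min_len`` are skipped with a warning.  ``partition_of`` maps a
    source genome id to its partition index, inherited by its fragments.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[FragmentSpec, str]] = []
    for g in genomes:
        if g.length < min_len:
            log.warning(
                "genome %s (%d bp) shorter than min_len=%d; skipped",
                g.genome_id, g.length, min_len,
            )
            continue
        for i in range(cuts_per_genome):
            length = int(rng.integers(min_len, g.length + 1))
            start = int(rng.integers(1, g.length - length + 2))
            spec = FragmentSpec(
                fragment_id=f"{g.genome_id}|c{i}|{start}|{length}",
                source_id=g.genome_id,
                start=start,
                length=length,
                label=label,
                partition=None if partition_of is None else partition_of.get(g.genome_id),
            )
            out.append((spec, _extract(g, start, length)))
    return out


def cut_negative_matched(
    genomes: Sequence[GenomeRecord],
    target_lengths: Sequence[int],
    seed: int = 0,
    label: str = "negative",
    partitions: Sequence[int | None] | None = None,
) -> list[tuple[FragmentSpec, str]]:
    """One negative cut per target length, exactly matching that length.

    For each target, the (source genome, start) pair is drawn uniformly
    over all feasible pairs — i.e. genomes at least as long as the target,
    weighted by their number of valid start positions.  ``partitions``
    optionally assigns each fragment the partition of the positive cut it
    mirrors.  Raises if any target length exceeds every negative genome.
    """
    if partitions is not None and len(partitions) != len(target_lengths):
        raise ValueError("partitions must align with target_lengths")
    lengths = np.array([g.length for g in genomes], dtype=np.int64)
    too_long = [int(t) for t in target_lengths if t > lengths.max(initial=0)]
    if too_long:
        raise ValueError(
            f"no negative genome long enough for target lengths: {sorted(set(too_long))}"
        )
    rng = np.random.default_rng(seed)
    out: list[tuple[FragmentSpec, str]] = []
    for i, target in enumerate(target_lengths):
        feasible = np.flatnonzero(lengths >= target)
        weights = lengths[feasible] - target + 1  # valid starts per genome
        gi = int(rng.choice(feasible, p=weights / weights.sum()))
        g = genomes[gi]
        start = int(rng.integers(1, g.length - target + 2))
        spec = FragmentSpec(
            fragment_id=f"{g.genome_id}|n{i}|{start}|{target}",
            source_id=g.genome_id,
            start=start,
            length=int(target),
            label=label,
            partition=None if partitions is None else partitions[i],
        )
        out.append((spec, _extract(g, start, int(target))))
    return out


MANIFEST_COLUMNS = ("fragment_id", "source_id", "start", "length", "label", "partition")


def write_manifest(
    fragments: Sequence[tuple[FragmentSpec, str]],
    dest: str | os.PathLike | IO[str],
) -> None:
    """Tab-separated manifest of fragment provenance."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt") as fh:
            write_manifest(fragments, fh)
        return
    dest.write("\t".join(MANIFEST_COLUMNS) + "\n")
    for spec, _ in fragments:
        part = "" if spec.partition is None else str(spec.partition)
        dest.write(
            f"{spec.fragment_id}\t{spec.source_id}\t{spec.start}\t"
            f"{spec.length}\t{spec.label}\t{part}\n"
        )


def fragments_to_genomes(
    fragments: Sequence[tuple[FragmentSpec, str]],
) -> list[GenomeRecord]:
    """View fragments as GenomeRecords (e.g. for FASTA output or scoring)."""
    return [GenomeRecord(spec.fragment_id, seq) for spec, seq in fragments]
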