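"""Tabular nucleotide-alignment hits: parsing, writing, optional blastn invocation.

The on-disk format is the standard 12-column tabular alignment output
(``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``), tab-separated, one hit per line, ``#`` comments allowed.
Coordinates are kept 1-based inclusive exactly as the format defines them;
subject coordinates may run backwards for minus-strand hits, query
coordinates of a nucleotide query are always forward.
"""

from __future__ import annotations

import io
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

from .errors import AlignerError, CapabilityError, HitParseError

#: Column order of the standard tabular alignment format.
TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_EVALUE_MAX = 0.05


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular alignment record.

    ``pct_identity`` and ``aln_length`` are the aligner-reported percent
    identity and alignment length (gaps included) that enter the %ANI sum.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if not 1 <= self.q_start <= self.q_end:
            raise ValueError(
                f"query coordinates must satisfy 1 <= q_start <= q_end, "
                f"got [{self.q_start}, {self.q_end}]"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")


def _parse_line(line: str, lineno: int) -> AlignmentHit:
    parts = line.rstrip("\n").split("\t")
    if len(parts) == 1:  # tolerate space-separated tables
        parts = line.split()
    if len(parts) != 12:
        raise HitParseError(
            f"line {lineno}: expected 12 columns, got {len(parts)}"
        )
    try:
        return AlignmentHit(
            query_id=parts[0],
            subject_id=parts[1],
            pct_identity=float(parts[2]),
            aln_length=int(parts[3]),
            mismatches=int(parts[4]),
            gap_opens=int(parts[5]),
            q_start=int(parts[6]),
            q_end=int(parts[7]),
            s_start=int(parts[8]),
            s_end=int(parts[9]),
            evalue=float(parts[10]),
            bit_score=float(parts[11]),
        )
    except ValueError as exc:
        raise HitParseError(f"line {lineno}: {exc}") from exc


def read_hits(
    source: str | os.PathLike | IO[str] | Iterable[str],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> dict[str, list[AlignmentHit]]:
    """Parse tabular hits, keep those with ``evalue <= evalue_max``, group by query.

    The e-value filter is inclusive.  Input order is preserved within each
    query.  ``source`` may be a path, an open text stream, or any iterable
    of lines.

    Raises
    ------
    HitParseError
        On a malformed line (wrong column count or non-numeric field); the
        message names the 1-based line number.
    ValueError
        If ``evalue_max`` is negative.
    """
    if evalue_max < 0:
        raise ValueError(f"evalue_max must be non-negative, got {evalue_max}")
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt") as fh:
            return read_hits(fh, evalue_max)
    grouped: dict[str, list[AlignmentHit]] = {}
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        hit = _parse_line(line, lineno)
        if hit.evalue <= evalue_max:
            grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def write_hits(
    hits: Iterable[AlignmentHit] | Mapping[str, list[AlignmentHit]],
    dest: str | os.PathLike | IO[str],
) -> None:
    """Write hits in the 12-column tabular format (round-trips with read_hits)."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "wt") as fh:
            write_hits(hits, fh)
        return
    if isinstance(hits, Mapping):
        hits = [h for group in hits.values() for h in group]
    for h in hits:
        dest.write(
            "\t".join(
                str(v)
                for v in (
                    h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                    h.mismatches, h.gap_opens, h.q_start, h.q_end,
                    h.s_start, h.s_end, h.evalue, h.bit_score,
                )
            )
            + "\n"
        )


def hits_to_text(hits: Iterable[AlignmentHit]) -> str:
    buf = io.StringIO()
    write_hits(hits, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# optional external aligner plumbing


def _require_executable(name: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise CapabilityError(
            f"external executable {name!r} not found on PATH; supply a "
            f"precomputed hit file instead"
        )
    return path


def make_blast_db(
    fasta: str | os.PathLike,
    out_prefix: str | os.PathLike | None = None,
    executable: str = "makeblastdb",
) -> str:
    """Build a nucleotide BLAST database from a FASTA file; return its prefix."""
    exe = _require_executable(executable)
    if out_prefix is None:
        out_prefix = str(fasta)
    proc = subprocess.run(
        [exe, "-in", str(fasta), "-dbtype", "nucl", "-out", str(out_prefix)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise AlignerError(
            f"{executable} failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    return str(out_prefix)


def run_aligner(
    contigs: str | os.PathLike,
    database: str | os.PathLike,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    executable: str = "blastn",
) -> str:
    """Run the external nucleotide aligner; return its tabular output text.

    ``database`` is an indexed database prefix (see :func:`make_blast_db`).
    Raises :class:`CapabilityError` when the executable is absent so that
    every other operation remains usable on precomputed hit files.
    """
    exe = _require_executable(executable)
    proc = subprocess.run(
        [
            exe,
            "-query", str(contigs),
            "-db", str(database),
            "-evalue", str(evalue_max),
            "-outfmt", "6",
        ],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise AlignerError(
            f"{executable} failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    return proc.stdout


def align_fastas(
    query_fasta: str | os.PathLike,
    subject_fasta: str | os.PathLike,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    workdir: str | os.PathLike | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Convenience: index ``subject_fasta``, align ``query_fasta``, parse hits.

    Requires both ``makeblastdb`` and ``blastn`` on PATH.
    """
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        prefix = make_blast_db(subject_fasta, Path(tmp) / "db")
        text = run_aligner(query_fasta, prefix, evalue_max)
    return read_hits(io.StringIO(text), evalue_max)
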