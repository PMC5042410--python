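"""ROC analysis, threshold selection, length-binned AUC, summary tables,
and a cross-validation driver.

The classifier convention throughout is *positive iff score > cutoff*.
An operating point of the empirical ROC therefore corresponds to an
interval of cutoffs between two adjacent distinct scores; each point is
represented by the midpoint of that interval, so a selected threshold
falls in the middle of a separating gap rather than on a data point.

The classification threshold is chosen where the false positive rate
equals one minus the true positive rate (the balanced-error operating
point, the intersection of the ROC curve with the descending diagonal).
Along descending cutoffs FPR - (1 - TPR) rises from -1 toward +1, so a
crossing always exists; when it falls between two achievable operating
points the cutoff is linearly interpolated.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import blast_io
from .ani import DEFAULT_ANI_THRESHOLD, AniResult, compute_ani
from .fragment import (
    DEFAULT_CUTS_PER_GENOME,
    DEFAULT_MIN_LEN,
    cut_negative_matched,
    cut_positive,
    fragments_to_genomes,
)
from .genomes import GenomeRecord, write_fasta

log = logging.getLogger(__name__)

POSITIVE_LABEL = "phage"


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    return np.array(
        [l is True or l == 1 or str(l).lower() == POSITIVE_LABEL for l in labels],
        dtype=bool,
    )


@dataclass
class RocSummary:
    """Empirical ROC of a labeled score set.

    ``thresholds`` are descending representative cutoffs, one per
    operating point, aligned with ``fpr``/``tpr`` (both start at 0 and
    end at 1).  ``auc`` is the trapezoidal area; ``selected_threshold``
    is the balanced-error cutoff (FPR = 1 - TPR).
    """

    scores: np.ndarray
    labels: np.ndarray
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    selected_threshold: float


def roc_auc(scores: Sequence[float], labels: Sequence) -> RocSummary:
    """Empirical ROC with tie grouping and trapezoidal AUC.

    ``labels`` may be booleans, 0/1, or "phage"/"negative" strings.
    Equal scores are grouped at one threshold step, which makes the
    trapezoidal area identical to the pairwise-comparison (Mann-Whitney)
    estimator P(pos > neg) + P(tie)/2.

    Raises ``ValueError`` when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both classes; got {n_pos} positives, {n_neg} negatives"
        )
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each tie group of equal scores
    group_ends = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    distinct = s_sorted[group_ends]  # descending distinct scores
    tp = np.r_[0, np.cumsum(y_sorted)[group_ends]]
    fp = np.r_[0, np.cumsum(~y_sorted)[group_ends]]
    tpr = tp / n_pos
    fpr = fp / n_neg
    m = len(distinct)
    # operating point k = "scores strictly above cutoff"; its cutoff interval
    # is [distinct[k], distinct[k-1]) -> midpoint representative
    thresholds = np.empty(m + 1)
    thresholds[0] = distinct[0]
    thresholds[1:m] = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds[m] = distinct[-1] - 1.0
    auc = float(np.trapezoid(tpr, fpr))
    summary = RocSummary(
        scores=s, labels=y, thresholds=thresholds,
        fpr=fpr, tpr=tpr, auc=auc, selected_threshold=np.nan,
    )
    summary.selected_threshold = select_threshold(summary)
    return summary


def select_threshold(summary: RocSummary) -> float:
    """Cutoff at which FPR crosses 1 - TPR, interpolating between points.

    The degenerate all-ties curve (a single distinct score) returns that
    score.
    """
    f = summary.fpr + summary.tpr - 1.0  # FPR - (1 - TPR)
    if len(summary.thresholds) == 2:  # single distinct score
        return float(summary.thresholds[0])
    idx = int(np.flatnonzero(f >= 0)[0])  # f[0] = -1, f[-1] = +1
    if f[idx] == 0.0:
        return float(summary.thresholds[idx])
    t0, t1 = summary.thresholds[idx - 1], summary.thresholds[idx]
    w = -f[idx - 1] / (f[idx] - f[idx - 1])
    return float(t0 + w * (t1 - t0))


def auc_by_length(
    scores: Sequence[float],
    labels: Sequence,
    lengths: Sequence[int],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-length-bin AUC table over half-open bins [edge_i, edge_{i+1}).

    A record exactly at an edge falls in the right-hand bin.  Bins missing
    a class get ``auc = NaN`` (undefined, not an error).  Records outside
    all bins are dropped.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be sorted strictly increasing, length >= 2")
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    ln = np.asarray(lengths, dtype=float)
    which = np.digitize(ln, edges, right=False) - 1  # bin index, half-open left-closed
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        n_pos = int(y[mask].sum())
        n_neg = int(mask.sum()) - n_pos
        if n_pos and n_neg:
            auc = roc_auc(s[mask], y[mask]).auc
        else:
            auc = np.nan
        rows.append(
            {
                "bin_lo": edges[b], "bin_hi": edges[b + 1],
                "n_pos": n_pos, "n_neg": n_neg, "auc": auc,
            }
        )
    return pd.DataFrame(rows)


def summarize_dataset(
    results: Sequence[AniResult],
    labels: Sequence,
    threshold: float = DEFAULT_ANI_THRESHOLD,
) -> dict:
    """Summary row: mean/median hits, %ANI, merged coverage, sensitivity/specificity.

    "Hits" counts distinct database genomes matched (``n_subjects``), not
    alignment records.  Sensitivity is computed over positive-labeled
    results, specificity over negative-labeled ones; either is ``None``
    when its class is absent.  Classification is score > ``threshold``.
    """
    if len(results) == 0:
        raise ValueError("empty result list")
    if len(results) != len(labels):
        raise ValueError("labels must align with results")
    y = _as_bool_labels(labels)
    hits = np.array([r.n_subjects for r in results], dtype=float)
    ani = np.array([r.pct_ani for r in results], dtype=float)
    cov = np.array([r.merged_coverage for r in results], dtype=float)
    called = ani > threshold
    sens = float(called[y].mean()) if y.any() else None
    spec = float((~called[~y]).mean()) if (~y).any() else None
    return {
        "n": len(results),
        "mean_n_hits": float(hits.mean()),
        "median_n_hits": float(np.median(hits)),
        "mean_pct_ani": float(ani.mean()),
        "median_pct_ani": float(np.median(ani)),
        "mean_merged_coverage": float(cov.mean()),
        "median_merged_coverage": float(np.median(cov)),
        "sensitivity": sens,
        "specificity": spec,
    }


# ---------------------------------------------------------------------------
# cross-validation driver


@dataclass
class CrossValResult:
    """Pooled scores of a rotated hold-one-partition-out evaluation."""

    scored: pd.DataFrame  # query_id, label, length, score, kind, fold
    summary: RocSummary


def cross_validate(
    phage_partitions: Sequence[Sequence[GenomeRecord]],
    negatives: Sequence[GenomeRecord],
    seed: int = 0,
    evalue_max: float = blast_io.DEFAULT_EVALUE_MAX,
    cuts_per_genome: int = DEFAULT_CUTS_PER_GENOME,
    min_len: int = DEFAULT_MIN_LEN,
    include_whole_genomes: bool = True,
) -> CrossValResult:
    """Score each held-out partition against a database of the others.

    Per fold, the database is built (via the external aligner) from every
    phage partition except the held-out one; queries are the held-out
    whole genomes, their artificial contigs, an equal number of whole
    negative sequences, and negative contigs length-matched to the
    positive cuts.  Predictions from all folds are pooled into a single
    ROC, matching a combined (rather than fold-averaged) evaluation.

    Requires ``blastn``/``makeblastdb`` on PATH.  Deterministic under
    ``seed`` for fixed inputs.
    """
    n_parts = len(phage_partitions)
    if n_parts < 2:
        raise ValueError(f"need at least 2 partitions, got {n_parts}")
    rng = np.random.default_rng(seed)
    neg_pool = list(negatives)
    rows: list[dict] = []
    for fold in range(n_parts):
        held = list(phage_partitions[fold])
        db_genomes = [
            g for p, part in enumerate(phage_partitions) if p != fold for g in part
        ]
        held_ids = {g.genome_id for g in held}
        db_ids = {g.genome_id for g in db_genomes}
        if held_ids & db_ids:  # leakage guard: held-out genomes never enter the db
            raise AssertionError(
                f"fold {fold}: held-out genomes leaked into database: "
                f"{sorted(held_ids & db_ids)}"
            )
        pos_frags = cut_positive(
            held, cuts_per_genome=cuts_per_genome, min_len=min_len,
            seed=int(rng.integers(2**31)), label=POSITIVE_LABEL,
        )
        neg_whole = [
            neg_pool[int(i)]
            for i in rng.choice(len(neg_pool), size=min(len(held), len(neg_pool)),
                                replace=False)
        ]
        neg_frags = cut_negative_matched(
            neg_pool, [spec.length for spec, _ in pos_frags],
            seed=int(rng.integers(2**31)),
        )
        queries: list[tuple[GenomeRecord, str, str]] = []
        if include_whole_genomes:
            queries += [(g, POSITIVE_LABEL, "genome") for g in held]
            queries += [(g, "negative", "genome") for g in neg_whole]
        queries += [
            (g, POSITIVE_LABEL, "contig") for g in fragments_to_genomes(pos_frags)
        ]
        queries += [(g, "negative", "contig") for g in fragments_to_genomes(neg_frags)]

        with tempfile.TemporaryDirectory() as tmp:
            db_fasta = Path(tmp) / "db.fasta"
            q_fasta = Path(tmp) / "queries.fasta"
            write_fasta(db_genomes, db_fasta)
            write_fasta([q for q, _, _ in queries], q_fasta)
            grouped = blast_io.align_fastas(q_fasta, db_fasta, evalue_max, workdir=tmp)
        for g, label, kind in queries:
            res = compute_ani(
                grouped.get(g.genome_id, []), g.length, query_id=g.genome_id
            )
            rows.append(
                {
                    "query_id": g.genome_id, "label": label, "length": g.length,
                    "score": res.pct_ani, "merged_coverage": res.merged_coverage,
                    "n_genomes_hit": res.n_subjects, "kind": kind, "fold": fold,
                }
            )
        log.info("fold %d: %d queries scored against %d genomes",
                 fold, len(queries), len(db_genomes))
    scored = pd.DataFrame(rows)
    summary = roc_auc(scored["score"].to_numpy(), scored["label"].to_list())
    return CrossValResult(scored=scored, summary=summary)
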