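"""Annotation accuracy: sensitivity, specificity and F1.

A prediction set is compared against a reference annotation at three
levels with exact-match semantics throughout:

* CDS level: two CDS agree iff seqname, strand and both coordinates are
  identical; the units are the unique (seqname, strand, start, end)
  tuples within each set, so shared CDS among isoforms count once.
* transcript level: a reference transcript is correctly predicted iff
  some prediction agrees with it on the complete set of CDS intervals;
  identifiers are irrelevant.
* gene level: a predicted gene is correct iff at least one of its
  isoforms exactly matches an isoform of some reference gene; each
  reference gene can be claimed by at most one predicted gene (greedy
  matching in coordinate order).

Sn = TP / #reference * 100, Sp = TP / #prediction * 100, and F1 is
their harmonic mean (0 when Sn + Sp = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import formats
from .scoring import PredictedTranscript

log = logging.getLogger("txselect")

LEVELS = ("CDS", "transcript", "gene")


# ---------------------------------------------------------------------------
# matching predicates
# ---------------------------------------------------------------------------

def cds_match(c1: tuple[str, str, int, int], c2: tuple[str, str, int, int]) -> bool:
    """Two CDS agree iff seqname, strand, start and end are identical."""
    return c1 == c2


def transcript_match(t_pred: PredictedTranscript, t_ref: PredictedTranscript) -> bool:
    """Structure-only comparison: equal CDS sets on the same seqname and
    strand; transcript and gene identifiers play no role."""
    return t_pred.chain_key == t_ref.chain_key


def gene_match(
    g_pred: Sequence[PredictedTranscript], reference: Iterable[PredictedTranscript]
) -> bool:
    """True iff any isoform of the predicted gene exactly matches any
    reference isoform."""
    ref_chains = {t.chain_key for t in reference}
    return any(t.chain_key in ref_chains for t in g_pred)


# ---------------------------------------------------------------------------
# the report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelAccuracy:
    tp: int
    n_pred: int
    n_ref: int
    sn: float  # percent
    sp: float  # percent
    f1: float  # percent


@dataclass(frozen=True)
class AccuracyReport:
    levels: dict[str, LevelAccuracy]

    def __getitem__(self, level: str) -> LevelAccuracy:
        return self.levels[level]

    def to_tsv(self) -> str:
        lines = ["level\tTP\tpred\tref\tSn\tSp\tF1"]
        for level in LEVELS:
            a = self.levels[level]
            lines.append(
                f"{level}\t{a.tp}\t{a.n_pred}\t{a.n_ref}"
                f"\t{a.sn:.2f}\t{a.sp:.2f}\t{a.f1:.2f}"
            )
        return "".join(line + "\n" for line in lines)


def f1_score(sn: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity (all in percent)."""
    if sn + sp == 0:
        return 0.0
    return 2 * sn * sp / (sn + sp)


def _level(tp: int, n_pred: int, n_ref: int) -> LevelAccuracy:
    sn = 100.0 * tp / n_ref if n_ref else 0.0
    sp = 100.0 * tp / n_pred if n_pred else 0.0
    return LevelAccuracy(tp, n_pred, n_ref, sn, sp, f1_score(sn, sp))


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _cds_units(transcripts: Iterable[PredictedTranscript]) -> set:
    return {
        (t.seqname, t.strand, s, e) for t in transcripts for s, e in t.cds
    }


def _genes(transcripts: Iterable[PredictedTranscript]) -> list[tuple[tuple, set]]:
    """Group isoforms by gene_id; return (coordinate key, chain set) per
    gene, sorted by coordinates for the greedy gene matching."""
    by_gene: dict[str, list[PredictedTranscript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid, members in by_gene.items():
        key = (
            members[0].seqname,
            min(t.span[0] for t in members),
            max(t.span[1] for t in members),
            gid,
        )
        genes.append((key, {t.chain_key for t in members}))
    genes.sort(key=lambda g: g[0])
    return genes


def _gene_tp(pred_genes: list[tuple[tuple, set]], ref_genes: list[tuple[tuple, set]]) -> int:
    claimed: set[int] = set()
    tp = 0
    for _, pred_chains in pred_genes:
        for i, (_, ref_chains) in enumerate(ref_genes):
            if i not in claimed and pred_chains & ref_chains:
                claimed.add(i)
                tp += 1
                break
    return tp


def accuracy(
    predictions: Sequence[PredictedTranscript],
    reference: Sequence[PredictedTranscript],
) -> AccuracyReport:
    """Compute Sn/Sp/F1 at CDS, transcript and gene level."""
    if not reference:
        raise ValueError("empty reference annotation: sensitivity is undefined")
    if not predictions:
        log.warning("empty prediction set: specificity reported as 0")

    pred_cds, ref_cds = _cds_units(predictions), _cds_units(reference)
    pred_tx = {t.chain_key for t in predictions}
    ref_tx = {t.chain_key for t in reference}
    pred_genes, ref_genes = _genes(predictions), _genes(reference)

    return AccuracyReport(
        {
            "CDS": _level(len(pred_cds & ref_cds), len(pred_cds), len(ref_cds)),
            "transcript": _level(len(pred_tx & ref_tx), len(pred_tx), len(ref_tx)),
            "gene": _level(_gene_tp(pred_genes, ref_genes), len(pred_genes), len(ref_genes)),
        }
    )


def accuracy_from_files(pred_path: str | Path, ref_path: str | Path) -> AccuracyReport:
    """Parse two GTF files and compare them (prediction vs reference)."""
    preds = formats.parse_predictions(pred_path)
    refs = formats.parse_predictions(ref_path)
    if not refs:
        raise formats.ParseError(f"{ref_path}: reference contains no CDS rows")
    return accuracy(preds, refs)
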