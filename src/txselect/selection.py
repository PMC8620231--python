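"""Evidence-based transcript selection.

The workflow turns the union of several prediction sets into one
combined annotation of higher specificity:

1. take the union of all input transcripts, merging identical ones;
2. compute the four support scores for every transcript;
3. find all pairs of transcripts with overlapping coding regions
   (>= 3 adjacent coding nucleotides shared, same strand, same frame);
4. apply the pairwise comparison rule to every such pair and collect
   the transcripts it marks -- a transcript already marked is still
   compared to all of its overlap partners and may mark others;
5. remove all marked transcripts;
6. remove transcripts with low evidence support;
7. single-linkage cluster the survivors by coding overlap: each cluster
   is one output gene, its members the alternative isoforms.

Marks are accumulated over the original union and applied once, so the
result does not depend on the order in which pairs are evaluated.  A
transcript that is discarded may still have strong support in absolute
terms -- it loses only to an overlapping transcript with even stronger
support.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import formats
from .scoring import (
    HintCollection,
    Hyperparameters,
    PredictedTranscript,
    ScoreVector,
    score_vector,
)

log = logging.getLogger("txselect")

NEITHER, FIRST, SECOND = 0, 1, 2


@dataclass(frozen=True)
class ComparisonOutcome:
    """Result of comparing one pair: which transcript (if any) is marked
    for removal, and the index j of the decisive score."""

    marked: int  # NEITHER, FIRST or SECOND
    decisive: int | None = None  # j in 1..4, or None

    def __post_init__(self) -> None:
        if (self.marked == NEITHER) != (self.decisive is None):
            raise ValueError("a transcript is marked iff a decisive score index exists")


@dataclass
class GeneCluster:
    """One output gene: a single-linkage cluster of surviving transcripts
    connected by chains of pairwise coding overlaps."""

    gene_id: str
    seqname: str
    strand: str
    members: list[PredictedTranscript]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.members),
            max(t.span[1] for t in self.members),
        )


@dataclass
class SelectionResult:
    clusters: list[GeneCluster]
    transcripts: list[PredictedTranscript]  # the merged union, step 1
    scores: dict[str, ScoreVector]
    marked: set[str]
    low_support_removed: set[str]
    merged_away: dict[str, str]  # dropped duplicate id -> kept id

    @property
    def survivors(self) -> list[PredictedTranscript]:
        return [t for c in self.clusters for t in c.members]

    @property
    def n_input(self) -> int:
        return len(self.transcripts) + len(self.merged_away)


# ---------------------------------------------------------------------------
# step 1: merge identical transcripts
# ---------------------------------------------------------------------------

def merge_identical(
    transcripts: Iterable[PredictedTranscript],
) -> tuple[list[PredictedTranscript], dict[str, str]]:
    """Collapse transcripts with identical (seqname, strand, CDS chain).

    The representative is the copy from the lowest file index (ties
    broken by identifier) so the result does not depend on input order.
    Returns the deduplicated list and a map of dropped ids to kept ids.
    """
    by_chain: dict[tuple, PredictedTranscript] = {}
    merged_away: dict[str, str] = {}
    ordered = sorted(
        transcripts,
        key=lambda t: (t.file_index if t.file_index is not None else 0, t.tx_id),
    )
    for tx in ordered:
        kept = by_chain.get(tx.chain_key)
        if kept is None:
            by_chain[tx.chain_key] = tx
        else:
            merged_away[tx.tx_id] = kept.tx_id
    return list(by_chain.values()), merged_away


# ---------------------------------------------------------------------------
# step 3: coding overlap with reading-frame agreement
# ---------------------------------------------------------------------------

def _frame_at(tx: PredictedTranscript, index: int, pos: int) -> int:
    """Codon offset (0..2) of genomic position ``pos`` inside CDS
    interval ``index``, counted from the transcript's own translation
    start (strand-aware cumulative coding length mod 3)."""
    if tx.strand == "+":
        before = sum(e - s + 1 for s, e in tx.cds[:index])
        return (before + pos - tx.cds[index][0]) % 3
    after = sum(e - s + 1 for s, e in tx.cds[index + 1 :])
    return (after + tx.cds[index][1] - pos) % 3


def coding_overlap(t1: PredictedTranscript, t2: PredictedTranscript) -> bool:
    """True iff the transcripts share >= 3 adjacent coding nucleotides on
    the same strand and in the same reading frame.

    Three consecutive genomic positions that are coding in both
    transcripts necessarily lie inside a single CDS interval of each
    (introns are at least 1 nt), and the frame difference is constant
    across one interval intersection, so it suffices to check each pair
    of CDS intervals whose intersection spans >= 3 nt at one position.
    """
    if t1.seqname != t2.seqname or t1.strand != t2.strand:
        return False
    for i, (s1, e1) in enumerate(t1.cds):
        for j, (s2, e2) in enumerate(t2.cds):
            lo, hi = max(s1, s2), min(e1, e2)
            if hi - lo + 1 >= 3 and _frame_at(t1, i, lo) == _frame_at(t2, j, lo):
                return True
    return False


def _candidate_pairs(
    transcripts: Sequence[PredictedTranscript],
) -> Iterator[tuple[PredictedTranscript, PredictedTranscript]]:
    """Unordered pairs whose spans intersect on the same (seqname, strand).

    Same strand and seqname are necessary for coding overlap, so the
    sweep yields a superset of the coding-overlap pairs while avoiding
    the all-pairs quadratic scan; the result is contract-identical.
    """
    groups: dict[tuple[str, str], list[PredictedTranscript]] = defaultdict(list)
    for tx in transcripts:
        groups[(tx.seqname, tx.strand)].append(tx)
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda t: (t.span, t.tx_id))
        active: list[PredictedTranscript] = []
        for tx in group:
            start = tx.span[0]
            active = [u for u in active if u.span[1] >= start]
            for u in active:
                yield u, tx
            active.append(tx)


# ---------------------------------------------------------------------------
# step 4: the pairwise comparison rule
# ---------------------------------------------------------------------------

def compare_pair(
    v1: ScoreVector, v2: ScoreVector, params: Hyperparameters
) -> ComparisonOutcome:
    """Compare two overlapping transcripts by their score vectors.

    The score differences are examined in order s1, s2, s3, s4, each
    against its threshold e_j.  The first time |s_j(1) - s_j(2)| exceeds
    e_j the rule terminates and the transcript with the smaller s_j is
    marked for removal.  Neither is marked when every difference is
    less than or equal to its threshold.
    """
    for j, (a, b, eps) in enumerate(zip(v1, v2, params.epsilons), start=1):
        if abs(a - b) > eps:
            return ComparisonOutcome(FIRST if a < b else SECOND, j)
    return ComparisonOutcome(NEITHER)


# ---------------------------------------------------------------------------
# step 6: low evidence support
# ---------------------------------------------------------------------------

def low_support(v: ScoreVector, params: Hyperparameters) -> bool:
    """True (remove) iff the supported intron fraction AND the supported
    start/stop fraction are both below their thresholds.

    The joint condition keeps transcripts whose introns are well
    supported even when a codon hint is missing, and vice versa.
    """
    return v.s1 < params.intron_support and v.s2 < params.startstop_support


# ---------------------------------------------------------------------------
# steps 1-7: the full workflow
# ---------------------------------------------------------------------------

def _cluster_survivors(
    survivors: list[PredictedTranscript],
    overlap_pairs: list[tuple[str, str]],
) -> list[GeneCluster]:
    parent: dict[str, str] = {t.tx_id: t.tx_id for t in survivors}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    alive = set(parent)
    for a, b in overlap_pairs:
        if a in alive and b in alive:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, list[PredictedTranscript]] = defaultdict(list)
    for tx in survivors:
        groups[find(tx.tx_id)].append(tx)

    clusters = [
        GeneCluster("", members[0].seqname, members[0].strand, members)
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: (c.seqname, c.span[0], c.span[1], c.strand))
    for number, cluster in enumerate(clusters, 1):
        cluster.gene_id = f"g{number}"
        cluster.members.sort(key=lambda t: (t.span, t.tx_id))
    return clusters


def run_selection(
    transcripts: Iterable[PredictedTranscript],
    hints: HintCollection,
    params: Hyperparameters | None = None,
) -> SelectionResult:
    """Run the full selection workflow and cluster survivors into genes.

    All pairs of the merged union are compared before any removal, so a
    marked transcript can still cause the removal of another.  The
    output is invariant under any permutation of the input transcripts
    or of the pair-evaluation order.
    """
    if params is None:
        params = Hyperparameters()
    merged, merged_away = merge_identical(transcripts)
    scores = {t.tx_id: score_vector(t, hints, params) for t in merged}

    overlap_pairs: list[tuple[str, str]] = []
    marked: set[str] = set()
    for a, b in _candidate_pairs(merged):
        if not coding_overlap(a, b):
            continue
        overlap_pairs.append((a.tx_id, b.tx_id))
        outcome = compare_pair(scores[a.tx_id], scores[b.tx_id], params)
        if outcome.marked == FIRST:
            marked.add(a.tx_id)
        elif outcome.marked == SECOND:
            marked.add(b.tx_id)

    low = {
        t.tx_id
        for t in merged
        if t.tx_id not in marked and low_support(scores[t.tx_id], params)
    }
    survivors = [t for t in merged if t.tx_id not in marked and t.tx_id not in low]
    clusters = _cluster_survivors(survivors, overlap_pairs)
    return SelectionResult(
        clusters=clusters,
        transcripts=merged,
        scores=scores,
        marked=marked,
        low_support_removed=low,
        merged_away=merged_away,
    )


def combine_files(
    prediction_paths: Sequence[str | Path],
    hint_paths: Sequence[str | Path],
    params: Hyperparameters | None = None,
) -> SelectionResult:
    """Parse prediction and hint files and run the selection workflow.

    File indices (used to make transcript identifiers unique) are
    assigned by the rank of each path in sorted order, so the result is
    independent of the order in which the files are listed.
    """
    ranked = {p: i for i, p in enumerate(sorted(str(p) for p in prediction_paths), 1)}
    transcripts: list[PredictedTranscript] = []
    for path in prediction_paths:
        parsed = formats.parse_predictions(path, file_index=ranked[str(path)])
        log.info("parsed %d transcripts from %s", len(parsed), path)
        transcripts.extend(parsed)
    hints = formats.parse_hints(hint_paths)
    log.info(
        "parsed %d hints (total multiplicity %d) from %d file(s)",
        len(hints),
        hints.total_multiplicity(),
        len(list(hint_paths)),
    )
    return run_selection(transcripts, hints, params)
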