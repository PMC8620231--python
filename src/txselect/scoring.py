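"""Transcript data model and evidence-support scores.

Gene predictions from multiple annotation pipelines are compared on the
basis of extrinsic evidence: intron intervals inferred from spliced
RNA-seq alignments, and start/stop codon positions inferred from protein
alignments.  Each such piece of evidence is a *hint* carrying a source
label (e.g. ``E`` for an EST/RNA-seq database, ``P`` for a protein
database) and a *multiplicity* -- the number of alignments from that
source supporting it.

The support of a transcript is summarised by four scores:

``s1 = r_i``
    fraction of the transcript's introns matched by at least one hint,
``s2 = r_s``
    fraction of its start/stop codons matched by at least one hint,
``s3 = a_i``
    weighted sum ``w_src(h) * mult(h)`` over hints matching introns,
``s4 = a_s``
    the same weighted sum over hints matching start/stop codons.

A hint supports a transcript feature only on exact identity: sequence
name, start, end, feature type and strand must all match.  All
coordinates are 1-based and fully inclusive (GTF convention); the intron
between consecutive CDS intervals ``[a,b]`` and ``[c,d]`` is
``[b+1, c-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

INTRON = "intron"
START = "start"
STOP = "stop"
FEATURE_TYPES = (INTRON, START, STOP)

#: Default source weights for a standard BRAKER1 + BRAKER2 combination:
#: protein database (P), EST/RNA-seq database (E), combined (C), manual (M).
DEFAULT_WEIGHTS: dict[str, float] = {"P": 0.1, "E": 10.0, "C": 5.0, "M": 1.0}


@dataclass(frozen=True, slots=True)
class FeatureKey:
    """Identity of one transcript feature / hint position.

    Equality of all five fields is the matching predicate for "a hint
    supports a transcript feature".
    """

    seqname: str
    start: int
    end: int
    kind: str  # one of FEATURE_TYPES
    strand: str


class ScoreVector(NamedTuple):
    """The four support scores of one transcript."""

    s1: float  # r_i, fraction of supported introns, in [0, 1]
    s2: float  # r_s, fraction of supported start/stop codons, in [0, 1]
    s3: float  # a_i, weighted intron support, >= 0
    s4: float  # a_s, weighted start/stop support, >= 0


@dataclass
class PredictedTranscript:
    """One transcript's CDS structure from one input prediction set.

    ``cds`` holds 1-based inclusive intervals, sorted by coordinate and
    strictly separated (every intron is at least 1 nt).  ``frames`` are
    the GTF phase column values of the CDS rows, kept for round-trip
    fidelity; when empty they are recomputed from the structure on
    output.  Explicit ``start_codon`` / ``stop_codon`` intervals from the
    input are authoritative; otherwise the codons are derived from the
    CDS chain (strand-aware).
    """

    tx_id: str
    gene_id: str
    seqname: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    frames: tuple[str, ...] = ()
    file_index: int | None = None
    start_codon: tuple[int, int] | None = None
    stop_codon: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.tx_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.cds:
            raise ValueError(f"transcript {self.tx_id!r} has no CDS intervals")
        self.cds = tuple(sorted(tuple(iv) for iv in self.cds))
        for s, e in self.cds:
            if s > e:
                raise ValueError(f"transcript {self.tx_id!r}: CDS start {s} > end {e}")
        for (_, b), (c, _) in zip(self.cds, self.cds[1:]):
            if c <= b + 1:  # overlapping or touching -> no valid intron
                raise ValueError(
                    f"transcript {self.tx_id!r}: CDS intervals overlap or touch"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def chain_key(self) -> tuple:
        """Structural identity: (seqname, strand, CDS coordinate list)."""
        return (self.seqname, self.strand, self.cds)

    # -- derived features -----------------------------------------------

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((b + 1, c - 1) for (_, b), (c, _) in zip(self.cds, self.cds[1:]))

    def start_codon_interval(self) -> tuple[int, int]:
        """First 3 coding nucleotides in translation order (3-nt window)."""
        if self.start_codon is not None:
            return self.start_codon
        if self.strand == "+":
            s = self.cds[0][0]
            return (s, s + 2)
        e = self.cds[-1][1]
        return (e - 2, e)

    def stop_codon_interval(self) -> tuple[int, int]:
        """Last 3 coding nucleotides (explicit stop_codon row wins)."""
        if self.stop_codon is not None:
            return self.stop_codon
        if self.strand == "+":
            e = self.cds[-1][1]
            return (e - 2, e)
        s = self.cds[0][0]
        return (s, s + 2)


def derive_features(
    tx: PredictedTranscript,
) -> tuple[tuple[FeatureKey, ...], tuple[FeatureKey, ...]]:
    """Return ``(F_i, F_s)``: the transcript's intron and codon features.

    A single-CDS transcript has no introns (``F_i`` empty).  Start and
    stop codon are two separate features, so ``|F_s| == 2``.
    """
    f_i = tuple(
        FeatureKey(tx.seqname, s, e, INTRON, tx.strand) for s, e in tx.introns()
    )
    start = tx.start_codon_interval()
    stop = tx.stop_codon_interval()
    f_s = (
        FeatureKey(tx.seqname, start[0], start[1], START, tx.strand),
        FeatureKey(tx.seqname, stop[0], stop[1], STOP, tx.strand),
    )
    return f_i, f_s


def cds_phases(cds: tuple[tuple[int, int], ...], strand: str) -> tuple[str, ...]:
    """GTF frame/phase column for each CDS interval, in coordinate order."""
    n = len(cds)
    order = range(n) if strand == "+" else range(n - 1, -1, -1)
    phases = [""] * n
    cum = 0
    for i in order:
        s, e = cds[i]
        phases[i] = str((3 - cum % 3) % 3)
        cum += e - s + 1
    return tuple(phases)


class HintCollection:
    """All extrinsic evidence, keyed by feature identity and source.

    Hints with identical (position, type, strand, source) are merged by
    summing their multiplicities; multiplicity is the number of
    supporting alignments, so duplicates are additive.
    """

    def __init__(self) -> None:
        self._by_key: dict[FeatureKey, dict[str, int]] = {}
        self.sources: set[str] = set()

    def add(self, key: FeatureKey, src: str, mult: int = 1) -> None:
        if mult < 1:
            raise ValueError(f"hint multiplicity must be >= 1, got {mult}")
        if key.kind not in FEATURE_TYPES:
            raise ValueError(f"unknown hint feature type {key.kind!r}")
        self.sources.add(src)
        self._by_key.setdefault(key, {})
        self._by_key[key][src] = self._by_key[key].get(src, 0) + mult

    def supports(self, key: FeatureKey) -> bool:
        """True iff at least one hint (of any source) matches ``key``."""
        return key in self._by_key

    def support_of(self, key: FeatureKey) -> Mapping[str, int]:
        """Per-source multiplicities of hints matching ``key``."""
        return self._by_key.get(key, {})

    def items(self) -> Iterator[tuple[FeatureKey, str, int]]:
        for key, by_src in self._by_key.items():
            for src, mult in by_src.items():
                yield key, src, mult

    def total_multiplicity(self) -> int:
        return sum(m for _, _, m in self.items())

    def __len__(self) -> int:
        return sum(1 for _ in self.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HintCollection):
            return NotImplemented
        return self._by_key == other._by_key


@dataclass
class Hyperparameters:
    """Source weights, comparison thresholds and low-support thresholds.

    ``e1..e4`` are the score-specific thresholds of the pairwise
    comparison rule (for s1..s4 in order).  ``intron_support`` and
    ``startstop_support`` are the minimum supported fractions below
    which (jointly) a transcript counts as having low evidence support.
    """

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    e1: float = 0.0
    e2: float = 0.5
    e3: float = 25.0
    e4: float = 10.0
    intron_support: float = 0.75
    startstop_support: float = 1.0

    def __post_init__(self) -> None:
        for src, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weight for source {src!r} must be >= 0, got {w}")
        if not (0 <= self.e1 <= 1 and 0 <= self.e2 <= 1):
            raise ValueError("e_1 and e_2 must lie in [0, 1]")
        if self.e3 < 0 or self.e4 < 0:
            raise ValueError("e_3 and e_4 must be >= 0")

    @property
    def epsilons(self) -> tuple[float, float, float, float]:
        return (self.e1, self.e2, self.e3, self.e4)

    def weight_of(self, src: str) -> float:
        try:
            return self.weights[src]
        except KeyError:
            raise ValueError(
                f"no weight configured for evidence source {src!r}"
            ) from None


def relative_support(features: tuple[FeatureKey, ...], hints: HintCollection) -> float:
    """r_f = |F_f ∩ E| / |F_f|: fraction of features with >= 1 matching hint.

    Each feature counts at most once no matter how many sources hit it.
    An empty feature set (a single-CDS transcript has no introns) is
    defined as fully supported (1.0), so intron-less transcripts are not
    automatically low-support.
    """
    if not features:
        return 1.0
    return sum(1 for f in features if hints.supports(f)) / len(features)


def absolute_support(
    features: tuple[FeatureKey, ...],
    hints: HintCollection,
    weights: Mapping[str, float],
) -> float:
    """a_f = sum over matching hints of ``w_src(h) * mult(h)``."""
    total = 0.0
    for f in features:
        for src, mult in hints.support_of(f).items():
            if src not in weights:
                raise ValueError(f"no weight configured for evidence source {src!r}")
            total += weights[src] * mult
    return total


def score_vector(
    tx: PredictedTranscript, hints: HintCollection, params: Hyperparameters
) -> ScoreVector:
    """Assemble (s1, s2, s3, s4) for one transcript.

    Pure function of the transcript's derived features, the evidence and
    the source weights.
    """
    f_i, f_s = derive_features(tx)
    return ScoreVector(
        s1=relative_support(f_i, hints),
        s2=relative_support(f_s, hints),
        s3=absolute_support(f_i, hints, params.weights),
        s4=absolute_support(f_s, hints, params.weights),
    )
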