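"""Deterministic synthetic fixtures and a brute-force selection oracle.

The generator lays out non-overlapping gene loci on artificial contigs
and emits, per locus:

* one or two *true* isoforms (alternative splicing by internal-exon
  skipping or terminal-exon extension, always in multiples of 3 nt so
  isoforms stay frame-compatible),
* optionally a *decoy* transcript that overlaps a true isoform in at
  least 3 in-frame coding nucleotides by construction (the whole chain,
  or a single-CDS variant, shifted by a multiple of 3) but carries only
  sparse hint support,
* optionally a *duplicate* of a true isoform in a second prediction
  file, to exercise the merge step.

Hints are drawn per evidence source from coverage profiles over the
union of true-isoform features (and separately, over decoy features).
All randomness flows through one seeded generator, so a fixed seed
reproduces every file byte for byte.

``oracle_select`` is a literal, unoptimised transcription of the
selection workflow (all pairs, per-nucleotide frame labelling, no
interval index) kept independent of the main implementation so the two
can be tested for equivalence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import formats
from .scoring import (
    INTRON,
    START,
    STOP,
    FeatureKey,
    HintCollection,
    Hyperparameters,
    PredictedTranscript,
    ScoreVector,
)

_LOCI_PER_CONTIG = 25
_LOCUS_GAP = 1500


@dataclass(frozen=True)
class HintProfile:
    """Coverage of one evidence source: the probability that a feature
    receives a hint, and the multiplicity range drawn when it does."""

    source: str
    intron_p: float
    codon_p: float
    mult_min: int = 1
    mult_max: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.intron_p <= 1 and 0 <= self.codon_p <= 1):
            raise ValueError("hint probabilities must lie in [0, 1]")
        if not 1 <= self.mult_min <= self.mult_max:
            raise ValueError("need 1 <= mult_min <= mult_max")


#: Default world: RNA-seq intron hints are abundant and deep (most introns
#: of expressed genes are seen by many spliced reads), protein hints are
#: sparser but also cover start/stop codons, and decoys attract only
#: occasional low-multiplicity protein support.
_DEFAULT_TRUE_PROFILES = (
    HintProfile("E", intron_p=0.9, codon_p=0.0, mult_min=1, mult_max=10),
    HintProfile("P", intron_p=0.4, codon_p=0.8, mult_min=1, mult_max=3),
)
_DEFAULT_DECOY_PROFILES = (HintProfile("P", intron_p=0.15, codon_p=0.1),)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic annotation problem."""

    seed: int = 0
    n_loci: int = 10
    isoform_range: tuple[int, int] = (1, 2)
    cds_range: tuple[int, int] = (1, 4)
    decoy_fraction: float = 0.5
    duplicate_fraction: float = 0.5
    true_profiles: tuple[HintProfile, ...] = _DEFAULT_TRUE_PROFILES
    decoy_profiles: tuple[HintProfile, ...] = _DEFAULT_DECOY_PROFILES

    def __post_init__(self) -> None:
        if self.n_loci < 0:
            raise ValueError("n_loci must be >= 0")
        if not (0 <= self.decoy_fraction <= 1 and 0 <= self.duplicate_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_loci == 0 and self.decoy_fraction > 0:
            raise ValueError("decoy_fraction > 0 is infeasible with zero loci")
        for lo, hi in (self.isoform_range, self.cds_range):
            if not 1 <= lo <= hi:
                raise ValueError("ranges must satisfy 1 <= low <= high")

    @classmethod
    def recovery(cls, seed: int = 0, n_loci: int = 100) -> "FixtureSpec":
        """Best-case world: every true feature hinted once (RNA-seq introns,
        protein codons), decoys entirely unsupported."""
        return cls(
            seed=seed,
            n_loci=n_loci,
            decoy_fraction=0.7,
            true_profiles=(
                HintProfile("E", intron_p=1.0, codon_p=0.0),
                HintProfile("P", intron_p=0.0, codon_p=1.0),
            ),
            decoy_profiles=(),
        )


@dataclass(frozen=True)
class TruthRecord:
    """Planted truth for one generated transcript (ids as the pipeline
    sees them, i.e. with the file-index prefix)."""

    tx_id: str
    role: str  # "true", "decoy" or "duplicate-of:<local id>"
    scores: ScoreVector  # computed by the oracle's naive scorer
    survives: bool  # expected survival, from oracle_select


@dataclass
class Fixture:
    spec: FixtureSpec
    files: list[list[PredictedTranscript]]  # local ids, per prediction file
    hint_rows: list[tuple[FeatureKey, str, int]]  # as written (mults may be split)
    hints: HintCollection
    reference: list[PredictedTranscript]  # the true isoforms only
    roles: dict[str, str]  # prefixed id -> role
    truth: list[TruthRecord] = field(default_factory=list)

    def parsed_union(self) -> list[PredictedTranscript]:
        """The transcripts as parse_predictions would return them: one
        list over all files, ids prefixed with the 1-based file index."""
        out = []
        for index, txs in enumerate(self.files, 1):
            for t in txs:
                out.append(
                    PredictedTranscript(
                        tx_id=f"{index}_{t.tx_id}",
                        gene_id=t.gene_id,
                        seqname=t.seqname,
                        strand=t.strand,
                        cds=t.cds,
                        file_index=index,
                    )
                )
        return out


@dataclass(frozen=True)
class GeneratedFixture:
    fixture: Fixture
    prediction_paths: tuple[Path, ...]
    hint_paths: tuple[Path, ...]
    reference_path: Path
    truth_path: Path


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------

def _base_chain(rng: random.Random, origin: int, n_cds: int) -> tuple[tuple[int, int], ...]:
    cds = []
    pos = origin
    for k in range(n_cds):
        length = 3 * rng.randint(20, 100)
        cds.append((pos, pos + length - 1))
        if k < n_cds - 1:
            pos = cds[-1][1] + 1 + rng.randint(50, 400)
    return tuple(cds)


def _variant_chain(
    rng: random.Random, base: tuple[tuple[int, int], ...], taken: set
) -> tuple[tuple[int, int], ...] | None:
    """An alternative isoform of ``base``: skip one internal exon, or
    extend the rightmost exon by a multiple of 3.  Returns None when no
    unused variant is found."""
    for _ in range(8):
        if len(base) >= 3 and rng.random() < 0.5:
            k = rng.randint(1, len(base) - 2)
            chain = base[:k] + base[k + 1 :]
        else:
            ext = 3 * rng.randint(1, 30)
            last = base[-1]
            chain = base[:-1] + ((last[0], last[1] + ext),)
        if chain not in taken:
            return chain
    return None


def _codon_windows(chain: tuple[tuple[int, int], ...], strand: str) -> tuple:
    if strand == "+":
        return (
            (chain[0][0], chain[0][0] + 2),
            (chain[-1][1] - 2, chain[-1][1]),
        )
    return (
        (chain[-1][1] - 2, chain[-1][1]),
        (chain[0][0], chain[0][0] + 2),
    )


def _decoy_chain(
    rng: random.Random,
    base: tuple[tuple[int, int], ...],
    taken: set,
    true_windows: set,
) -> tuple[tuple[int, int], ...]:
    """A conflicting transcript guaranteed to share >= 3 in-frame coding
    nucleotides with ``base``: the anchor exon is kept but shifted by a
    multiple of 3 (< its length - 3), so frames agree on the retained
    part.  Codon windows are nudged (in steps of 3) until they collide
    with no true isoform's codon window."""
    first_len = base[0][1] - base[0][0] + 1
    last_len = base[-1][1] - base[-1][0] + 1
    max_shift = (min(first_len, last_len) - 3) // 3

    def ok(chain: tuple[tuple[int, int], ...]) -> bool:
        lo_win = (chain[0][0], chain[0][0] + 2)
        hi_win = (chain[-1][1] - 2, chain[-1][1])
        return chain not in taken and lo_win not in true_windows and hi_win not in true_windows

    if len(base) > 1 and rng.random() < 0.5:
        # whole chain shifted right by 3k: first/last exons still overlap in frame
        for k in range(rng.randint(1, max_shift), max_shift + 1):
            chain = tuple((s + 3 * k, e + 3 * k) for s, e in base)
            if ok(chain):
                return chain
    # single-CDS decoy anchored inside the first exon, extended past it
    shift = 3 * rng.randint(1, max(1, (first_len - 3) // 3))
    shift = min(shift, first_len - 3)
    start = base[0][0] + shift
    length = first_len + 3 * rng.randint(1, 30)
    for _ in range(64):
        chain = ((start, start + length - 1),)
        if ok(chain):
            return chain
        if (start, start + 2) in true_windows and start - 3 >= base[0][0] + 3:
            start -= 3  # anchor collided with a true codon window
        else:
            length += 3
    raise AssertionError("could not place a decoy without codon collisions")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _emit_hints(
    rng: random.Random,
    rows: list[tuple[FeatureKey, str, int]],
    features: Iterable[FeatureKey],
    profiles: Sequence[HintProfile],
) -> None:
    for key in features:
        for prof in profiles:
            p = prof.intron_p if key.kind == INTRON else prof.codon_p
            if rng.random() >= p:
                continue
            mult = rng.randint(prof.mult_min, prof.mult_max)
            if mult >= 2 and rng.random() < 0.3:
                # split one hint over two rows: parsers must sum these
                cut = rng.randint(1, mult - 1)
                rows.append((key, prof.source, cut))
                rows.append((key, prof.source, mult - cut))
            else:
                rows.append((key, prof.source, mult))


def _features_of(tx: PredictedTranscript) -> list[FeatureKey]:
    keys = [
        FeatureKey(tx.seqname, b + 1, c - 1, INTRON, tx.strand)
        for (_, b), (c, _) in zip(tx.cds, tx.cds[1:])
    ]
    start, stop = _codon_windows(tx.cds, tx.strand)
    keys.append(FeatureKey(tx.seqname, start[0], start[1], START, tx.strand))
    keys.append(FeatureKey(tx.seqname, stop[0], stop[1], STOP, tx.strand))
    return keys


def build(spec: FixtureSpec, params: Hyperparameters | None = None) -> Fixture:
    """Generate one fixture in memory, including its planted truth.

    Expected survival is computed by ``oracle_select`` under ``params``
    (default hyperparameters when None), never by the main pipeline.
    """
    if params is None:
        params = Hyperparameters()
    rng = random.Random(spec.seed)
    files: list[list[PredictedTranscript]] = [[], []]
    reference: list[PredictedTranscript] = []
    rows: list[tuple[FeatureKey, str, int]] = []
    roles: dict[str, str] = {}
    cursor = 1

    for locus in range(spec.n_loci):
        contig = f"ctg{locus // _LOCI_PER_CONTIG + 1}"
        if locus % _LOCI_PER_CONTIG == 0:
            cursor = 1
        strand = rng.choice("+-")
        gene_id = f"g{locus + 1}"
        origin = cursor + rng.randint(100, 500)
        base = _base_chain(rng, origin, rng.randint(*spec.cds_range))

        chains = [base]
        n_iso = rng.randint(*spec.isoform_range)
        while len(chains) < n_iso:
            variant = _variant_chain(rng, base, set(chains))
            if variant is None:
                break
            chains.append(variant)

        isoforms = [
            PredictedTranscript(f"{gene_id}.t{k + 1}", gene_id, contig, strand, chain)
            for k, chain in enumerate(chains)
        ]
        for iso in isoforms:
            files[0].append(iso)
            reference.append(iso)
            roles[f"1_{iso.tx_id}"] = "true"
            if rng.random() < spec.duplicate_fraction:
                dup = PredictedTranscript(
                    f"{iso.tx_id}.d", gene_id, contig, strand, iso.cds
                )
                files[1].append(dup)
                roles[f"2_{dup.tx_id}"] = f"duplicate-of:{iso.tx_id}"

        true_windows = {w for c in chains for w in _codon_windows(c, strand)}
        true_features: dict[FeatureKey, None] = {}
        for iso in isoforms:
            for key in _features_of(iso):
                true_features.setdefault(key)
        _emit_hints(rng, rows, true_features, spec.true_profiles)

        locus_max = max(c[-1][1] for c in chains)
        if rng.random() < spec.decoy_fraction:
            chain = _decoy_chain(rng, base, set(chains), true_windows)
            which = rng.randint(0, 1)
            decoy = PredictedTranscript(
                f"{gene_id}.d1", f"{gene_id}d", contig, strand, chain
            )
            files[which].append(decoy)
            roles[f"{which + 1}_{decoy.tx_id}"] = "decoy"
            _emit_hints(rng, rows, _features_of(decoy), spec.decoy_profiles)
            locus_max = max(locus_max, chain[-1][1])

        cursor = locus_max + _LOCUS_GAP

    hints = HintCollection()
    for key, src, mult in rows:
        hints.add(key, src, mult)

    fixture = Fixture(
        spec=spec,
        files=files,
        hint_rows=rows,
        hints=hints,
        reference=reference,
        roles=roles,
    )
    union = fixture.parsed_union()
    surviving = oracle_select(union, hints, params)
    hint_list = list(hints.items())
    fixture.truth.extend(
        TruthRecord(
            tx_id=t.tx_id,
            role=fixture.roles[t.tx_id],
            scores=_oracle_scores(t, hint_list, params),
            survives=t.chain_key in surviving,
        )
        for t in union
    )
    return fixture


def generate(spec: FixtureSpec, outdir: str | Path) -> GeneratedFixture:
    """Write the fixture to ``outdir``: two prediction GTFs, one hint GFF
    per evidence source, the reference annotation (true isoforms only)
    and the truth table as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = build(spec)

    pred_paths = []
    for index, txs in enumerate(fixture.files, 1):
        path = outdir / f"preds_{index}.gtf"
        formats.write_predictions(txs, path, source=f"pred{index}")
        pred_paths.append(path)

    by_src: dict[str, list[tuple[FeatureKey, str, int]]] = {}
    for row in fixture.hint_rows:
        by_src.setdefault(row[1], []).append(row)
    hint_paths = []
    for src in sorted(by_src):
        path = outdir / f"hints_{src}.gff"
        sorted_rows = sorted(
            by_src[src], key=lambda r: (r[0].seqname, r[0].start, r[0].end, r[0].kind, r[2])
        )
        formats.write_hints(sorted_rows, path)
        hint_paths.append(path)
    if not hint_paths:  # selection still needs a (possibly empty) evidence file
        path = outdir / "hints_none.gff"
        formats.write_hints([], path)
        hint_paths.append(path)

    reference_path = outdir / "reference.gtf"
    formats.write_predictions(fixture.reference, reference_path, source="reference")

    truth_path = outdir / "truth.tsv"
    lines = ["tx_id\trole\ts1\ts2\ts3\ts4\tsurvives"]
    for rec in sorted(fixture.truth, key=lambda r: r.tx_id):
        s = rec.scores
        lines.append(
            f"{rec.tx_id}\t{rec.role}\t{s.s1:.6g}\t{s.s2:.6g}\t{s.s3:.6g}\t{s.s4:.6g}"
            f"\t{int(rec.survives)}"
        )
    truth_path.write_text("".join(line + "\n" for line in lines))

    return GeneratedFixture(
        fixture=fixture,
        prediction_paths=tuple(pred_paths),
        hint_paths=tuple(hint_paths),
        reference_path=reference_path,
        truth_path=truth_path,
    )


# ---------------------------------------------------------------------------
# the brute-force oracle
# ---------------------------------------------------------------------------

def _position_frames(t: PredictedTranscript) -> dict[int, int]:
    """Label every coding position with its codon offset, walking the CDS
    chain nucleotide by nucleotide in translation order."""
    frames: dict[int, int] = {}
    offset = 0
    if t.strand == "+":
        for s, e in t.cds:
            for p in range(s, e + 1):
                frames[p] = offset % 3
                offset += 1
    else:
        for s, e in reversed(t.cds):
            for p in range(e, s - 1, -1):
                frames[p] = offset % 3
                offset += 1
    return frames


def _oracle_overlap(
    t1: PredictedTranscript,
    t2: PredictedTranscript,
    f1: dict[int, int],
    f2: dict[int, int],
) -> bool:
    if t1.seqname != t2.seqname or t1.strand != t2.strand:
        return False
    common = f1.keys() & f2.keys()
    for p in common:
        if (
            p + 1 in common
            and p + 2 in common
            and all(f1[q] == f2[q] for q in (p, p + 1, p + 2))
        ):
            return True
    return False


def _oracle_scores(
    t: PredictedTranscript,
    hint_list: list[tuple[FeatureKey, str, int]],
    params: Hyperparameters,
) -> ScoreVector:
    introns = [
        FeatureKey(t.seqname, b + 1, c - 1, INTRON, t.strand)
        for (_, b), (c, _) in zip(t.cds, t.cds[1:])
    ]
    start = t.start_codon_interval()
    stop = t.stop_codon_interval()
    codons = [
        FeatureKey(t.seqname, start[0], start[1], START, t.strand),
        FeatureKey(t.seqname, stop[0], stop[1], STOP, t.strand),
    ]

    def rel(feats: list[FeatureKey]) -> float:
        if not feats:
            return 1.0
        hit = sum(1 for f in feats if any(k == f for k, _, _ in hint_list))
        return hit / len(feats)

    def absolute(feats: list[FeatureKey]) -> float:
        return sum(
            params.weight_of(src) * mult
            for key, src, mult in hint_list
            if any(key == f for f in feats)
        )

    return ScoreVector(rel(introns), rel(codons), absolute(introns), absolute(codons))


def oracle_select(
    transcripts: Sequence[PredictedTranscript],
    hints: HintCollection,
    params: Hyperparameters,
) -> frozenset:
    """Literal transcription of the selection workflow for small inputs.

    All unordered pairs are evaluated on the pre-removal union, marks
    are applied afterwards, then the joint low-support filter.  Returns
    the surviving structures as a frozenset of chain keys.
    """
    # step 1: merge identical structures, keeping the lowest file index
    merged: list[PredictedTranscript] = []
    seen: set = set()
    for t in sorted(
        transcripts, key=lambda t: (t.file_index if t.file_index is not None else 0, t.tx_id)
    ):
        if t.chain_key not in seen:
            seen.add(t.chain_key)
            merged.append(t)

    hint_list = list(hints.items())
    scores = [_oracle_scores(t, hint_list, params) for t in merged]
    frames = [_position_frames(t) for t in merged]

    # steps 3-4: all pairs, first threshold exceeded decides
    marked: set[int] = set()
    eps = [params.e1, params.e2, params.e3, params.e4]
    for i in range(len(merged)):
        for j in range(i + 1, len(merged)):
            if not _oracle_overlap(merged[i], merged[j], frames[i], frames[j]):
                continue
            for a, b, e in zip(scores[i], scores[j], eps):
                if abs(a - b) > e:
                    marked.add(i if a < b else j)
                    break

    # steps 5-6
    survivors = []
    for i, t in enumerate(merged):
        if i in marked:
            continue
        if scores[i].s1 < params.intron_support and scores[i].s2 < params.startstop_support:
            continue
        survivors.append(t)
    return frozenset(t.chain_key for t in survivors)
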