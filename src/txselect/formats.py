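"""Reading and writing the interchange formats.

Three file kinds are handled:

* prediction GTF (BRAKER/AUGUSTUS dialect): 9 tab-separated columns,
  ``transcript_id``/``gene_id`` attributes in column 9, one ``CDS`` row
  per coding interval, optionally ``start_codon``/``stop_codon`` rows;
* hint GFF: 9 columns, feature type ``intron``/``start``/``stop`` (the
  ``*_codon`` spellings are accepted), with ``src=`` and ``mult=``
  tokens in column 9;
* a flat ``name value`` configuration file for the hyperparameters.

Coordinates are 1-based and fully inclusive everywhere.  Output is a
pure function of content: rows are sorted, never echoed in input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .scoring import (
    DEFAULT_WEIGHTS,
    FEATURE_TYPES,
    FeatureKey,
    HintCollection,
    Hyperparameters,
    PredictedTranscript,
    cds_phases,
)

if TYPE_CHECKING:  # pragma: no cover
    from .selection import GeneCluster

log = logging.getLogger("txselect")

OUTPUT_HEADER = "# txselect combined gene set"

_HINT_TYPE_ALIASES = {
    "intron": "intron",
    "start": "start",
    "start_codon": "start",
    "stop": "stop",
    "stop_codon": "stop",
}


class ParseError(ValueError):
    """Malformed input data (GTF/GFF row or value)."""


class ConfigError(ValueError):
    """Malformed or unknown configuration entry."""


@dataclass
class GtfRecord:
    """One 9-column GTF row; attributes keep their input order."""

    seqname: str
    source: str
    feature: str
    start: int
    end: int
    score: str
    strand: str
    frame: str
    attributes: list[tuple[str, str]] = field(default_factory=list)

    def attr(self, name: str) -> str | None:
        for key, value in self.attributes:
            if key == name:
                return value
        return None

    def to_line(self) -> str:
        attrs = " ".join(f'{k} "{v}";' for k, v in self.attributes)
        return "\t".join(
            (
                self.seqname,
                self.source,
                self.feature,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.frame,
                attrs,
            )
        )


def _parse_gtf_attributes(text: str) -> list[tuple[str, str]]:
    attrs: list[tuple[str, str]] = []
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        key = parts[0]
        value = parts[1].strip().strip('"') if len(parts) > 1 else ""
        attrs.append((key, value))
    return attrs


def _split_row(line: str, path: str, lineno: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}")
    return fields


def _coords(fields: list[str], path: str, lineno: int) -> tuple[int, int]:
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
    if start > end:
        raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
    return start, end


# ---------------------------------------------------------------------------
# prediction GTF
# ---------------------------------------------------------------------------

def parse_predictions(
    path: str | Path, file_index: int | None = None
) -> list[PredictedTranscript]:
    """Parse one prediction GTF into transcripts.

    One transcript per distinct ``transcript_id``, CDS intervals sorted.
    When ``file_index`` is given, transcript identifiers are prefixed
    ``{file_index}_`` so that identifiers from different input files
    never collide.  Transcripts without any CDS row are skipped with a
    warning.  Rows with CDS on mixed strands or sequences for a single
    transcript are an error.
    """
    path = str(path)
    cds_rows: dict[str, list[GtfRecord]] = {}
    codon_rows: dict[str, dict[str, GtfRecord]] = {}
    gene_of: dict[str, str] = {}
    seen_ids: dict[str, None] = {}  # insertion-ordered

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line, path, lineno)
            feature = fields[2]
            start, end = _coords(fields, path, lineno)
            strand = fields[6]
            attrs = _parse_gtf_attributes(fields[8])
            rec = GtfRecord(
                fields[0], fields[1], feature, start, end, fields[5], strand, fields[7], attrs
            )
            tid = rec.attr("transcript_id")
            if feature not in ("CDS", "start_codon", "stop_codon"):
                # exon/transcript/gene/... rows only register the identifier,
                # so CDS-less transcripts can be reported
                if tid is not None:
                    seen_ids.setdefault(tid)
                    gene_of.setdefault(tid, rec.attr("gene_id") or tid)
                continue
            if feature == "CDS" and strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: CDS row with strand {strand!r}")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: row without transcript_id attribute")
            seen_ids.setdefault(tid)
            gene_of.setdefault(tid, rec.attr("gene_id") or tid)
            if feature == "CDS":
                cds_rows.setdefault(tid, []).append(rec)
            else:
                codon_rows.setdefault(tid, {}).setdefault(feature, rec)

    out: list[PredictedTranscript] = []
    prefix = f"{file_index}_" if file_index is not None else ""
    for tid in seen_ids:
        rows = cds_rows.get(tid)
        if not rows:
            log.warning("%s: transcript %s has no CDS rows; skipped", path, tid)
            continue
        seqnames = {r.seqname for r in rows}
        strands = {r.strand for r in rows}
        if len(seqnames) > 1 or len(strands) > 1:
            raise ParseError(
                f"{path}: transcript {tid} has CDS rows on mixed "
                f"{'sequences' if len(seqnames) > 1 else 'strands'}"
            )
        rows.sort(key=lambda r: (r.start, r.end))
        codons = codon_rows.get(tid, {})

        def _codon(name: str) -> tuple[int, int] | None:
            rec = codons.get(name)
            return (rec.start, rec.end) if rec is not None else None

        try:
            tx = PredictedTranscript(
                tx_id=prefix + tid,
                gene_id=gene_of[tid],
                seqname=rows[0].seqname,
                strand=rows[0].strand,
                cds=tuple((r.start, r.end) for r in rows),
                frames=tuple(r.frame for r in rows),
                file_index=file_index,
                start_codon=_codon("start_codon"),
                stop_codon=_codon("stop_codon"),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
        out.append(tx)
    return out


# ---------------------------------------------------------------------------
# hint GFF
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def parse_hints(paths: Iterable[str | Path]) -> HintCollection:
    """Parse one or more hint GFF files into a single collection.

    Hints are keyed by (seqname, start, end, feature type, strand,
    source); duplicate keys have their multiplicities summed.  An absent
    ``mult=`` token means multiplicity 1.  A missing ``src=`` token is
    an error (the source weight lookup would be undefined); unknown
    feature types are skipped with a warning.
    """
    hints = HintCollection()
    for path in paths:
        path = str(path)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = _split_row(line, path, lineno)
                kind = _HINT_TYPE_ALIASES.get(fields[2])
                if kind is None:
                    log.warning(
                        "%s:%d: unknown hint feature type %r; skipped", path, lineno, fields[2]
                    )
                    continue
                start, end = _coords(fields, path, lineno)
                if kind in ("start", "stop") and end - start != 2:
                    raise ParseError(
                        f"{path}:{lineno}: {kind} codon hint must span 3 nt, "
                        f"got [{start},{end}]"
                    )
                attrs = _parse_gff_attributes(fields[8])
                src = attrs.get("src")
                if not src:
                    raise ParseError(f"{path}:{lineno}: hint without src= attribute")
                mult_text = attrs.get("mult", "1")
                try:
                    mult = int(mult_text)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer mult={mult_text!r}") from None
                if mult < 1:
                    raise ParseError(f"{path}:{lineno}: mult must be >= 1, got {mult}")
                hints.add(FeatureKey(fields[0], start, end, kind, fields[6]), src, mult)
    return hints


def write_hints(
    rows: Iterable[tuple[FeatureKey, str, int]], path: str | Path, source: str = "hint"
) -> None:
    """Write hint rows as 9-column GFF with ``mult=``/``src=`` attributes."""
    lines = []
    for key, src, mult in rows:
        feature = {"start": "start_codon", "stop": "stop_codon"}.get(key.kind, key.kind)
        lines.append(
            "\t".join(
                (
                    key.seqname,
                    source,
                    feature,
                    str(key.start),
                    str(key.end),
                    ".",
                    key.strand,
                    ".",
                    f"mult={mult};src={src};",
                )
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SCALAR_KEYS = {
    "e_1": "e1",
    "e_2": "e2",
    "e_3": "e3",
    "e_4": "e4",
    "intron_support": "intron_support",
    "startstop_support": "startstop_support",
}


def parse_config(path: str | Path) -> Hyperparameters:
    """Parse a flat ``name value`` configuration file.

    Recognised names: ``w_<SRC>`` (weight of evidence source ``SRC``),
    ``e_1`` .. ``e_4`` (comparison-rule thresholds), ``intron_support``
    and ``startstop_support`` (low-support thresholds).  Any name absent
    from the file keeps its default; unknown names and non-numeric
    values are errors.
    """
    path = str(path)
    weights = dict(DEFAULT_WEIGHTS)
    scalars: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConfigError(f"{path}:{lineno}: expected 'name value', got {raw.strip()!r}")
            name, text = parts
            try:
                value = float(text)
            except ValueError:
                raise ConfigError(
                    f"{path}:{lineno}: non-numeric value {text!r} for {name!r}"
                ) from None
            if name.startswith("w_") and len(name) > 2:
                weights[name[2:]] = value
            elif name in _SCALAR_KEYS:
                scalars[_SCALAR_KEYS[name]] = value
            else:
                raise ConfigError(f"{path}:{lineno}: unknown hyperparameter {name!r}")
    try:
        return Hyperparameters(weights=weights, **scalars)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# output GTF
# ---------------------------------------------------------------------------

def _transcript_rows(tx: PredictedTranscript, gene_id: str) -> list[GtfRecord]:
    attrs = [("gene_id", gene_id), ("transcript_id", tx.tx_id)]
    frames = tx.frames if len(tx.frames) == len(tx.cds) else cds_phases(tx.cds, tx.strand)
    rows = [
        GtfRecord(tx.seqname, "txselect", "CDS", s, e, ".", tx.strand, frame, list(attrs))
        for (s, e), frame in zip(tx.cds, frames)
    ]
    for name, iv in (("start_codon", tx.start_codon), ("stop_codon", tx.stop_codon)):
        if iv is not None:
            rows.append(
                GtfRecord(tx.seqname, "txselect", name, iv[0], iv[1], ".", tx.strand, "0", list(attrs))
            )
    rows.sort(key=lambda r: (r.start, r.end, r.feature))
    span = (min(r.start for r in rows), max(r.end for r in rows))
    head = GtfRecord(
        tx.seqname, "txselect", "transcript", span[0], span[1], ".", tx.strand, ".", list(attrs)
    )
    return [head] + rows


def annotation_to_text(clusters: Sequence["GeneCluster"]) -> str:
    """Render gene clusters as GTF text (deterministic; see write_annotation)."""
    ordered = sorted(clusters, key=lambda c: (c.seqname, c.span[0], c.span[1], c.strand))
    lines = [OUTPUT_HEADER]
    for number, cluster in enumerate(ordered, 1):
        gene_id = f"g{number}"
        members = sorted(cluster.members, key=lambda t: (t.span, t.tx_id))
        for tx in members:
            lines.extend(rec.to_line() for rec in _transcript_rows(tx, gene_id))
    return "".join(line + "\n" for line in lines)


def write_annotation(clusters: Sequence["GeneCluster"], path: str | Path) -> None:
    """Write the combined gene set as GTF.

    Genes are sorted by (seqname, leftmost, rightmost coordinate) and
    renumbered ``g1, g2, ...``; every transcript row group carries its
    cluster's gene_id and its own transcript_id; CDS rows preserve the
    original coordinates, strand and frame.  Identical clusters always
    produce byte-identical output.
    """
    Path(path).write_text(annotation_to_text(clusters))


def write_predictions(
    transcripts: Iterable[PredictedTranscript], path: str | Path, source: str = "pred"
) -> None:
    """Write transcripts as a prediction-style GTF (used by the fixture
    generator and for re-emitting parsed sets)."""
    lines: list[str] = []
    for tx in sorted(transcripts, key=lambda t: (t.seqname, t.span, t.tx_id)):
        attrs = [("gene_id", tx.gene_id), ("transcript_id", tx.tx_id)]
        frames = tx.frames if len(tx.frames) == len(tx.cds) else cds_phases(tx.cds, tx.strand)
        rows = [
            GtfRecord(tx.seqname, source, "CDS", s, e, ".", tx.strand, fr, list(attrs))
            for (s, e), fr in zip(tx.cds, frames)
        ]
        for name, iv in (("start_codon", tx.start_codon), ("stop_codon", tx.stop_codon)):
            if iv is not None:
                rows.append(
                    GtfRecord(tx.seqname, source, name, iv[0], iv[1], ".", tx.strand, "0", list(attrs))
                )
        rows.sort(key=lambda r: (r.start, r.end, r.feature))
        lines.extend(r.to_line() for r in rows)
    Path(path).write_text("".join(line + "\n" for line in lines))
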