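"""Typed genome/annotation model and readers/writers.

Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive. Strand-aware "downstream" always means toward the 3' end of the
feature's own strand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal
from urllib.parse import quote, unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chromoforge")

#: Feature kinds the toolkit understands; unknown kinds are kept opaque.
KNOWN_KINDS = frozenset(
    {
        "ORF",
        "intron",
        "tRNA",
        "transposon",
        "telomere",
        "centromere",
        "loxpsym",
        "rox",
        "pcrtag",
        "marker",
        "motif",
    }
)

VALID_BASES = frozenset("ACGT")


class CoordinateError(ValueError):
    """A feature or position lies outside the sequence it annotates."""


class LedgerError(ValueError):
    """An edit ledger violates ordering/overlap/consistency invariants."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(cds: str) -> str:
    """Translate a coding sequence (standard nuclear code), stop as '*'."""
    return str(Seq(cds).translate())


@dataclass
class Feature:
    """A stranded, typed annotation on a chromosome.

    ``interval`` is 0-based half-open.  ``attrs`` carries free-form
    key/value metadata; the design engine reads ``essential`` (yes/no),
    ``orf_class`` (Verified/Uncharacterized/Dubious), ``anticodon`` and
    ``retain_intron`` from here.
    """

    id: str
    kind: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"feature {self.id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GenomeRecord:
    """A chromosome sequence plus its ordered feature annotations."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"non-ACGT bases in {self.id}: {sorted(bad)}")
        self.features.sort(key=lambda f: (f.start, f.end, f.id))
        for f in self.features:
            if f.end > len(self.sequence):
                raise CoordinateError(
                    f"feature {f.id} [{f.start},{f.end}) outside "
                    f"{self.id} of length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        want = set(kinds)
        return [f for f in self.features if f.kind in want]

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def subsequence(self, start: int, end: int) -> str:
        return self.sequence[start:end]

    def feature_sequence(self, feat: Feature) -> str:
        """Feature sequence in its own 5'->3' orientation."""
        s = self.sequence[feat.start : feat.end]
        return revcomp(s) if feat.strand == "-" else s

    def orf_cds(self, orf: Feature) -> str:
        """Coding sequence of an ORF with child introns excised (gene orientation)."""
        introns = [
            f
            for f in self.features
            if f.kind == "intron" and f.attrs.get("Parent") == orf.id
        ]
        parts: list[str] = []
        cursor = orf.start
        for iv in sorted(introns, key=lambda f: f.start):
            if not (orf.start <= iv.start and iv.end <= orf.end):
                raise CoordinateError(f"intron {iv.id} not nested in ORF {orf.id}")
            parts.append(self.sequence[cursor : iv.start])
            cursor = iv.end
        parts.append(self.sequence[cursor : orf.end])
        cds = "".join(parts)
        if orf.strand == "-":
            cds = revcomp(cds)
        if len(cds) % 3:
            raise CoordinateError(f"ORF {orf.id}: CDS length {len(cds)} not divisible by 3")
        return cds


# ---------------------------------------------------------------------------
# FASTA + GFF3 I/O
# ---------------------------------------------------------------------------

def _fmt_attrs(feat: Feature) -> str:
    items = [("ID", feat.id)] + [(k, v) for k, v in feat.attrs.items() if k != "ID"]
    return ";".join(f"{quote(str(k), safe='')}={quote(str(v), safe='')}" for k, v in items)


def _parse_attrs(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for piece in col.split(";"):
        if not piece:
            continue
        key, _, val = piece.partition("=")
        out[unquote(key)] = unquote(val)
    return out


def load_genome(fasta_path: str | Path, gff_path: str | Path) -> GenomeRecord:
    """Load one chromosome from FASTA + GFF3 into a :class:`GenomeRecord`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Features of unknown kind are kept with a warning; features outside the
    sequence raise :class:`CoordinateError`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()

    features: list[Feature] = []
    n_auto = 0
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attr_col = cols
            if seqid != rec.id:
                continue
            attrs = _parse_attrs(attr_col)
            fid = attrs.pop("ID", None)
            if fid is None:
                n_auto += 1
                fid = f"{ftype}_{n_auto}"
            if ftype not in KNOWN_KINDS:
                logger.warning("unknown feature kind %r kept opaque (%s)", ftype, fid)
            strand = strand if strand in ("+", "-") else "+"
            features.append(
                Feature(id=fid, kind=ftype, start=int(start1) - 1, end=int(end1),
                        strand=strand, attrs=attrs)
            )
    return GenomeRecord(id=rec.id, sequence=seq, features=features)


def save_genome(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write FASTA (60-column wrap) and GFF3; round-trips exactly via load_genome."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "chromoforge",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        _fmt_attrs(f),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Edit ledger
# ---------------------------------------------------------------------------

EDIT_OPS = ("insert", "delete", "substitute")
EDIT_RATIONALES = (
    "loxpsym",
    "intron_removal",
    "stop_swap",
    "feature_removal",
    "telomere_cap",
    "pcrtag_recode",
    "marker",
    "junction",
    "repair",
)


@dataclass
class EditRecord:
    """One atomic design edit in native coordinates.

    ``insert`` has a zero-length native interval (payload goes before
    ``start``); ``delete`` has an empty payload; ``substitute`` replaces the
    interval with a payload of possibly different length.
    """

    op: str
    start: int
    end: int
    payload: str = ""
    rationale: str = "repair"
    note: str = ""

    def __post_init__(self) -> None:
        if self.op not in EDIT_OPS:
            raise LedgerError(f"bad op {self.op!r}")
        if self.rationale not in EDIT_RATIONALES:
            raise LedgerError(f"bad rationale {self.rationale!r}")
        if self.start > self.end or self.start < 0:
            raise LedgerError(f"bad interval [{self.start},{self.end})")
        self.payload = self.payload.upper()
        if self.op == "insert":
            if self.start != self.end:
                raise LedgerError("insert must have zero-length native interval")
            if not self.payload:
                raise LedgerError("insert needs a payload")
        elif self.op == "delete":
            if self.payload:
                raise LedgerError("delete must have empty payload")
            if self.start == self.end:
                raise LedgerError("delete needs a non-empty interval")
        else:
            if self.start == self.end:
                raise LedgerError("substitute needs a non-empty interval")

    @property
    def delta(self) -> int:
        return len(self.payload) - (self.end - self.start)


@dataclass
class DesignLedger:
    """Ordered, invertible record of edits mapping a native to a designed sequence."""

    source_id: str
    target_id: str
    edits: list[EditRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edits.sort(key=lambda e: (e.start, e.end))
        prev: EditRecord | None = None
        for e in self.edits:
            if prev is not None:
                if e.start < prev.end or (
                    e.start == prev.start and e.op == "insert" and prev.op == "insert"
                ):
                    raise LedgerError(
                        f"overlapping edits at native {prev.start}-{prev.end} "
                        f"and {e.start}-{e.end}"
                    )
            prev = e

    @property
    def net_delta(self) -> int:
        return sum(e.delta for e in self.edits)

    # -- application ---------------------------------------------------------

    def apply(self, source_sequence: str) -> str:
        return apply_ledger(source_sequence, self)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "source_id": self.source_id,
            "target_id": self.target_id,
            "edits": [
                {
                    "op": e.op,
                    "start": e.start,
                    "end": e.end,
                    "payload": e.payload,
                    "rationale": e.rationale,
                    "note": e.note,
                }
                for e in self.edits
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignLedger":
        obj = json.loads(Path(path).read_text())
        return cls(
            source_id=obj["source_id"],
            target_id=obj["target_id"],
            edits=[EditRecord(**e) for e in obj["edits"]],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("op\tstart\tend\tpayload\trationale\tnote\n")
            for e in self.edits:
                fh.write(f"{e.op}\t{e.start}\t{e.end}\t{e.payload}\t{e.rationale}\t{e.note}\n")


def apply_ledger(source_sequence: str, ledger: DesignLedger) -> str:
    """Apply a ledger to a native sequence, returning the designed sequence.

    Untouched regions are copied verbatim; total length changes by
    ``ledger.net_delta``.
    """
    n = len(source_sequence)
    parts: list[str] = []
    cursor = 0
    for e in ledger.edits:
        if e.end > n:
            raise LedgerError(f"edit [{e.start},{e.end}) outside sequence of length {n}")
        parts.append(source_sequence[cursor : e.start])
        parts.append(e.payload)
        cursor = e.end
    parts.append(source_sequence[cursor:])
    out = "".join(parts)
    assert len(out) == n + ledger.net_delta
    return out


def lift_position(
    ledger: DesignLedger,
    pos: int,
    direction: str = "native_to_design",
) -> int | None:
    """Map a position across the ledger; ``None`` means the base was deleted.

    Positions inside a deleted interval (or beyond a substitute payload's
    extent) have no image.  Substituted positions map positionally while the
    payload covers them, which keeps same-length substitutions transparent.
    The map is monotone non-decreasing where defined.
    """
    if pos < 0:
        raise CoordinateError(f"negative position {pos}")
    if direction == "native_to_design":
        offset = 0
        for e in ledger.edits:
            # an insert at exactly `pos` places its payload before the native
            # base, so its delta counts toward the image of `pos`
            if e.end <= pos:
                offset += e.delta
                continue
            if e.start <= pos < e.end:
                rel = pos - e.start
                if rel < len(e.payload):
                    return e.start + offset + rel
                return None
            break
        return pos + offset
    elif direction == "design_to_native":
        offset = 0  # running (design - native) offset before current edit
        for e in ledger.edits:
            d0 = e.start + offset
            d1 = d0 + len(e.payload)
            if pos < d0:
                return pos - offset
            if pos < d1:
                rel = pos - d0
                if e.op != "insert" and rel < (e.end - e.start):
                    return e.start + rel
                return None  # inserted base has no native image
            offset += e.delta
        return pos - offset
    raise ValueError(f"bad direction {direction!r}")


def lift_interval(ledger: DesignLedger, start: int, end: int) -> tuple[int, int] | None:
    """Lift a native interval to design coordinates; ``None`` if fully deleted."""
    if start >= end:
        raise CoordinateError("empty interval")
    s: int | None = None
    for p in range(start, end):
        s = lift_position(ledger, p)
        if s is not None:
            break
    if s is None:
        return None
    e: int | None = None
    for p in range(end - 1, start - 1, -1):
        e = lift_position(ledger, p)
        if e is not None:
            e += 1
            break
    assert e is not None
    if s >= e:
        return None
    return (s, e)


def payload_design_intervals(ledger: DesignLedger) -> list[tuple[EditRecord, int, int]]:
    """Design-space interval occupied by each edit's payload."""
    out = []
    offset = 0
    for e in ledger.edits:
        d0 = e.start + offset
        out.append((e, d0, d0 + len(e.payload)))
        offset += e.delta
    return out
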