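"""SwapIn build planning: chunk/megachunk tiling of a designed chromosome.

Chunks of ~10 kb are delimited at restriction junctions whose recognition
site occurs exactly once within the union of the two adjacent chunks;
consecutive chunks are grouped 4-5 per megachunk (30-60 kb) labelled
A, B, C, ... with LEU2/URA3 marker cassettes alternating megachunk to
megachunk so each integration can select for the new marker and screen for
loss of the previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_io import EditRecord, GenomeRecord

logger = logging.getLogger("chromoforge")

#: default junction enzymes (rare 8-bp cutters)
DEFAULT_ENZYMES = {
    "NotI": "GCGGCCGC",
    "AscI": "GGCGCGCC",
    "PacI": "TTAATTAA",
    "PmeI": "GTTTAAAC",
    "SbfI": "CCTGCAGG",
    "FseI": "GGCCGGCC",
    "SwaI": "ATTTAAAT",
}

MARKERS = ("LEU2", "URA3")


class PlanningError(ValueError):
    """No feasible junction/grouping exists for an interval."""


@dataclass
class Chunk:
    chunk_id: str
    start: int
    end: int
    junction_enzyme: str | None = None  # enzyme at this chunk's downstream junction
    junction_site_pos: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Megachunk:
    label: str
    chunk_ids: list[str]
    marker: str
    marker_pos: int  # design coordinate where the cassette is inserted
    warning: str = ""


@dataclass
class ChunkPlan:
    chromosome_id: str
    chunks: list[Chunk] = field(default_factory=list)
    megachunks: list[Megachunk] = field(default_factory=list)
    marker_edits: list[EditRecord] = field(default_factory=list)

    def validate(self, length: int) -> None:
        cursor = 0
        for c in self.chunks:
            if c.start != cursor:
                raise PlanningError(f"chunk {c.chunk_id} breaks tiling at {c.start}")
            cursor = c.end
        if cursor != length:
            raise PlanningError(f"chunks end at {cursor}, chromosome is {length}")


@dataclass
class PartitionParams:
    target: int = 10_000
    min_chunk: int = 5_000
    max_chunk: int = 12_000
    slack: int = 2_000
    enzymes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ENZYMES))


def _megachunk_label(i: int) -> str:
    # A..Z then AA, AB, ...
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def _intergenic(designed: GenomeRecord, pos: int) -> bool:
    return not any(f.contains(pos) for f in designed.features if f.kind == "ORF")


def partition_chunks(designed: GenomeRecord, params: PartitionParams | None = None) -> ChunkPlan:
    """Place chunk boundaries at unique restriction junctions near 10-kb marks.

    Greedy scan: around each running target a ±slack window is searched for
    an enzyme site; candidates are ranked by (non-intergenic penalty,
    deviation from target) and accepted if the enzyme's site occurs exactly
    once in the region spanning the previous boundary through the next
    prospective chunk.  A final pass re-checks uniqueness within each
    realized adjacent-chunk union.
    """
    params = params or PartitionParams()
    if not params.enzymes:
        raise PlanningError("enzyme list is empty")
    L = designed.length
    seq = designed.sequence
    if L <= params.max_chunk:
        plan = ChunkPlan(designed.id, [Chunk("c0001", 0, L)])
        return plan

    boundaries: list[tuple[int, str]] = []  # (position, enzyme)
    prev = 0
    while L - prev > params.max_chunk:
        target = prev + params.target
        lo = max(prev + params.min_chunk, target - params.slack)
        hi = min(L, target + params.slack)
        candidates: list[tuple[int, int, int, str]] = []
        for name, site in sorted(params.enzymes.items()):
            k = seq.find(site, lo, hi)
            while k != -1:
                # uniqueness over previous chunk + prospective next chunk
                span_lo, span_hi = prev, min(L, k + params.max_chunk)
                count = seq.count(site, span_lo, span_hi)
                if count == 1:
                    penalty = 0 if _intergenic(designed, k) else 1
                    candidates.append((penalty, abs(k - target), k, name))
                k = seq.find(site, k + 1, hi)
        if not candidates:
            raise PlanningError(
                f"no feasible junction in [{lo},{hi}) of {designed.id}"
            )
        candidates.sort()
        _, _, pos, name = candidates[0]
        boundaries.append((pos, name))
        prev = pos

    chunks: list[Chunk] = []
    cursor = 0
    for i, (pos, name) in enumerate(boundaries):
        chunks.append(Chunk(f"c{i + 1:04d}", cursor, pos, name, pos))
        cursor = pos
    chunks.append(Chunk(f"c{len(boundaries) + 1:04d}", cursor, L))

    for c in chunks[:-1]:
        if not (params.min_chunk <= c.length <= params.max_chunk):
            raise PlanningError(f"chunk {c.chunk_id} length {c.length} out of range")
    last = chunks[-1]
    if not (params.min_chunk <= last.length <= params.max_chunk):
        # terminal remainder; junction sites may not permit an in-range split
        logger.warning("terminal chunk %s length %d outside [%d,%d]",
                       last.chunk_id, last.length, params.min_chunk, params.max_chunk)

    # final adjacent-union uniqueness audit
    for i in range(len(chunks) - 1):
        a, b = chunks[i], chunks[i + 1]
        site = params.enzymes[a.junction_enzyme]
        if seq.count(site, a.start, b.end) != 1:
            raise PlanningError(
                f"junction enzyme {a.junction_enzyme} not unique in union "
                f"[{a.start},{b.end})"
            )
    plan = ChunkPlan(designed.id, chunks)
    plan.validate(L)
    return plan


@dataclass
class GroupingParams:
    chunks_per_megachunk: tuple[int, int] = (4, 5)
    megachunk_range: tuple[int, int] = (30_000, 60_000)
    markers: tuple[str, str] = MARKERS
    marker_cassettes: dict[str, str] = field(
        default_factory=lambda: {"LEU2": "ATG" + "CTG" * 30 + "TAA",
                                 "URA3": "ATG" + "CGT" * 30 + "TAA"}
    )


def group_megachunks(plan: ChunkPlan, params: GroupingParams | None = None) -> ChunkPlan:
    """Group consecutive chunks into labelled megachunks with alternating markers.

    Chunks are renamed megachunk-relative (A1, A2, ... as in the build
    sheets).  A trailing remainder that cannot reach the 4-chunk minimum is
    relaxed to 3 with a warning rather than inflating the final megachunk.
    The marker cassette is recorded as an insert edit at the 3' end of each
    megachunk's final chunk; cassette sequences are opaque placeholders and
    are not spliced into the chunk sequences.
    """
    params = params or GroupingParams()
    kmin, kmax = params.chunks_per_megachunk
    n = len(plan.chunks)
    # group sizes: prefer groups of kmin; a remainder of kmin-1 is kept as a
    # short trailing group (warned); remainders of 1-2 are absorbed by
    # upgrading that many groups to kmax
    q, r = divmod(n, kmin)
    if n < kmin:
        sizes = [n]
    elif r == 0:
        sizes = [kmin] * q
    elif r == kmin - 1:
        sizes = [kmin] * q + [r]
    elif q >= r:
        sizes = [kmin] * (q - r) + [kmax] * r
    else:  # tiny pathological counts (e.g. 6 with 4-5 grouping)
        sizes = [n // 2, n - n // 2]

    new_chunks: list[Chunk] = []
    megachunks: list[Megachunk] = []
    marker_edits: list[EditRecord] = []
    idx = 0
    for gi, size in enumerate(sizes):
        label = _megachunk_label(gi)
        group = plan.chunks[idx : idx + size]
        idx += size
        ids = []
        for j, c in enumerate(group):
            cid = f"{label}{j + 1}"
            new_chunks.append(replace(c, chunk_id=cid))
            ids.append(cid)
        marker = params.markers[gi % 2]
        end = group[-1].end
        warning = ""
        if size < kmin:
            warning = f"remainder megachunk of {size} chunks"
            logger.warning("%s: %s", label, warning)
        span = end - group[0].start
        lo, hi = params.megachunk_range
        if not (lo <= span <= hi) and not warning:
            logger.warning("megachunk %s span %d outside [%d,%d]", label, span, lo, hi)
        megachunks.append(Megachunk(label, ids, marker, end, warning))
        marker_edits.append(
            EditRecord("insert", end, end, params.marker_cassettes[marker], "marker",
                       note=f"{label}:{marker}")
        )
    return ChunkPlan(plan.chromosome_id, new_chunks, megachunks, marker_edits)


def emit_build_plan(
    plan: ChunkPlan, designed: GenomeRecord, out_dir: str | Path,
    enzymes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Write per-chunk FASTA and the plan table.

    Each emitted chunk carries its downstream junction site duplicated at
    its 3' end (the overlap the restriction digest regenerates); collapsing
    each overlap once reconstructs the designed chromosome exactly.
    """
    enzymes = enzymes or DEFAULT_ENZYMES
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunk_to_mega = {cid: m for m in plan.megachunks for cid in m.chunk_ids}
    records = []
    rows = []
    for c in plan.chunks:
        overlap = len(enzymes[c.junction_enzyme]) if c.junction_enzyme else 0
        seq = designed.sequence[c.start : min(designed.length, c.end + overlap)]
        records.append(SeqRecord(Seq(seq), id=c.chunk_id, description=""))
        m = chunk_to_mega.get(c.chunk_id)
        rows.append(
            dict(
                chunk_id=c.chunk_id,
                start=c.start,
                end=c.end,
                enzyme=c.junction_enzyme or "",
                megachunk=m.label if m else "",
                marker=m.marker if m and m.chunk_ids[-1] == c.chunk_id else "",
            )
        )
    with open(out_dir / "chunks.fasta", "w") as fh:
        SeqIO.write(records, fh, "fasta")
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "plan.tsv", sep="\t", index=False)
    return table


def reconstruct_from_chunks(
    table: pd.DataFrame, fasta_path: str | Path, enzymes: dict[str, str] | None = None
) -> str:
    """Collapse per-chunk junction overlaps once and reassemble the chromosome."""
    enzymes = enzymes or DEFAULT_ENZYMES
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    parts: list[str] = []
    for row in table.itertuples():
        s = seqs[row.chunk_id]
        overlap = len(enzymes[row.enzyme]) if row.enzyme else 0
        parts.append(s[: len(s) - overlap] if overlap else s)
    return "".join(parts)
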