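"""Relocated tRNA-array design.

Each relocated tRNA gene receives heterologous 5' (500 bp) and 3' (40 bp)
flanking sequences drawn from a donor pool (e.g. Ashbya gossypii or
Eremothecium cymbalariae loci) assigned preferentially by anticodon, with
unwanted 5'-flank motifs scrubbed, tRNA introns excised, and Dre rox
recombination sites interleaved between cassettes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .genome_io import Feature, GenomeRecord

logger = logging.getLogger("chromoforge")

#: Dre recombinase rox site (32 bp)
DEFAULT_ROX = "TAACTTTAAATAATGCCAATTATTTAAAGTTA"

FIVE_PRIME_LEN = 500
THREE_PRIME_LEN = 40


class PoolExhausted(ValueError):
    """Not enough unused flank entries for the tRNA set."""


@dataclass
class TrnaGene:
    id: str
    anticodon: str  # RNA alphabet, e.g. "UGC"
    sequence: str  # genomic tRNA sequence, 5'->3'
    intron: tuple[int, int] | None = None  # half-open, gene-local

    @property
    def mature(self) -> str:
        if self.intron is None:
            return self.sequence
        s, e = self.intron
        return self.sequence[:s] + self.sequence[e:]


@dataclass
class FlankEntry:
    entry_id: str
    donor_species: str
    source_anticodon: str
    five_prime_seq: str
    three_prime_seq: str
    scrubbed: bool = False

    def __post_init__(self) -> None:
        if len(self.five_prime_seq) != FIVE_PRIME_LEN:
            raise ValueError(f"{self.entry_id}: 5' flank must be {FIVE_PRIME_LEN} bp")
        if len(self.three_prime_seq) != THREE_PRIME_LEN:
            raise ValueError(f"{self.entry_id}: 3' flank must be {THREE_PRIME_LEN} bp")


def _decoded_aa(anticodon: str) -> str:
    """Amino acid decoded by a tRNA anticodon (RNA alphabet)."""
    codon = str(Seq(anticodon.replace("U", "T")).reverse_complement())
    return str(Seq(codon).translate())


def assign_flanks(
    trnas: list[TrnaGene], pool: list[FlankEntry]
) -> dict[str, FlankEntry]:
    """Stable greedy flank assignment, preferentially by anticodon.

    For each tRNA (lexicographic id order): an unused entry with the exact
    anticodon first, else one whose source anticodon decodes the same amino
    acid, else any unused entry.  Within each tier, entries are taken in
    (donor_species, entry_id) order.  Each entry is used at most once.
    """
    if len(pool) < len(trnas):
        raise PoolExhausted(f"pool of {len(pool)} entries for {len(trnas)} tRNAs")
    unused = sorted(pool, key=lambda e: (e.donor_species, e.entry_id))
    assignment: dict[str, FlankEntry] = {}
    for trna in sorted(trnas, key=lambda t: t.id):
        pick = next((e for e in unused if e.source_anticodon == trna.anticodon), None)
        if pick is None:
            aa = _decoded_aa(trna.anticodon)
            pick = next((e for e in unused if _decoded_aa(e.source_anticodon) == aa), None)
        if pick is None:
            pick = unused[0]
        unused.remove(pick)
        assignment[trna.id] = pick
    return assignment


def scrub_flank(five_prime_seq: str, motif_list: list[str]) -> str:
    """Disrupt every motif occurrence with one central-base substitution.

    Length-preserving; iterates until a full scan finds no occurrence of
    any motif (a substitution could in principle create a new one).
    """
    seq = list(five_prime_seq)
    for _ in range(100):
        dirty = False
        s = "".join(seq)
        for motif in motif_list:
            k = s.find(motif)
            if k == -1:
                continue
            dirty = True
            center = k + len(motif) // 2
            original = seq[center]
            # any substitution breaks the match at k; prefer one that does not
            # leave a motif in the local neighbourhood
            fallback = None
            for base in "ACGT":
                if base == original:
                    continue
                trial = seq.copy()
                trial[center] = base
                fallback = fallback or trial
                t = "".join(trial)
                if motif not in t[max(0, k - len(motif)) : k + 2 * len(motif)]:
                    fallback = trial
                    break
            seq = fallback
            break
        if not dirty:
            return "".join(seq)
    raise RuntimeError("scrubbing did not converge")


@dataclass
class ArrayParams:
    rox_seq: str = DEFAULT_ROX
    rox_every_n_genes: int = 1
    scrub_motifs: tuple[str, ...] = ("TATAAA", "TATATA")  # TATA-like gene starts


def build_trna_array(
    trnas: list[TrnaGene],
    assignment: dict[str, FlankEntry],
    params: ArrayParams | None = None,
) -> GenomeRecord:
    """Concatenate rox-delimited cassettes into an annotated array.

    Cassette layout per tRNA (array order = lexicographic tRNA id):
    [rox] + scrubbed 5' flank + intron-less tRNA + 3' flank, with a
    terminal rox after the final cassette.  Features annotate every part.
    """
    params = params or ArrayParams()
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(s: str, fid: str, kind: str, attrs: dict | None = None) -> None:
        nonlocal pos
        parts.append(s)
        if fid:
            features.append(Feature(fid, kind, pos, pos + len(s), "+", attrs or {}))
        pos += len(s)

    ordered = sorted(trnas, key=lambda t: t.id)
    n_rox = 0
    for i, trna in enumerate(ordered):
        if i % params.rox_every_n_genes == 0:
            n_rox += 1
            emit(params.rox_seq, f"rox{n_rox:02d}", "rox")
        entry = assignment[trna.id]
        five = scrub_flank(entry.five_prime_seq, list(params.scrub_motifs))
        entry.scrubbed = True
        emit(five, f"{trna.id}_5p", "motif",
             {"role": "five_prime_flank", "donor": entry.donor_species,
              "source_entry": entry.entry_id})
        emit(trna.mature, trna.id, "tRNA", {"anticodon": trna.anticodon})
        emit(entry.three_prime_seq, f"{trna.id}_3p", "motif",
             {"role": "three_prime_flank", "donor": entry.donor_species})
    n_rox += 1
    emit(params.rox_seq, f"rox{n_rox:02d}", "rox")

    return GenomeRecord(id="trna_array", sequence="".join(parts), features=features)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_trna_table(path: str | Path) -> list[TrnaGene]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        intron = None
        if isinstance(getattr(r, "intron_start", None), (int, float)) and \
                pd.notna(getattr(r, "intron_start", None)):
            intron = (int(r.intron_start), int(r.intron_end))
        out.append(TrnaGene(r.id, r.anticodon, r.sequence.upper(), intron))
    return out


def read_flank_pool(path: str | Path) -> list[FlankEntry]:
    df = pd.read_csv(path, sep="\t")
    return [
        FlankEntry(r.entry_id, r.donor_species, r.source_anticodon,
                   r.five_prime_seq.upper(), r.three_prime_seq.upper())
        for r in df.itertuples()
    ]
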