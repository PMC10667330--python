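"""Rule-driven chromosome redesign.

Applies the Sc2.0-style edit classes to a native chromosome: loxPsym
insertion 3 bp downstream of every eligible non-essential ORF's stop codon,
intron removal (with a retain list for stable introns), TAG→TAA stop-codon
swapping, tRNA/transposon removal, synthetic telomere caps, and synonymous
PCR-tag recoding — all emitted as a single ordered, invertible
:class:`~chromoforge.genome_io.DesignLedger` in native coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable
from Bio.SeqUtils import MeltingTemp

from .genome_io import (
    DesignLedger,
    EditRecord,
    Feature,
    GenomeRecord,
    LedgerError,
    lift_interval,
    lift_position,
    payload_design_intervals,
    revcomp,
    translate_cds,
)

logger = logging.getLogger("chromoforge")

#: loxPsym — 13-bp Cre arm, 8-bp palindromic spacer, reverse-complement arm.
#: The spacer's self-complementarity makes the whole 34-mer non-directional.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

#: Synthetic telomere seed cap written 5'->3' for the right chromosome end
#: (TG-rich repeats facing outward); the left end receives its reverse
#: complement so both ends present the same outward-facing motif.
DEFAULT_TELOMERE_CAP = ("TGTGGGTGTGGTG" * 8)[:100]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _synonym_map() -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {c: sorted(by_aa[aa]) for aa, codons in by_aa.items() for c in codons}


SYNONYMS = _synonym_map()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def most_different_codon(codon: str) -> str:
    """The synonymous codon maximizing Hamming distance to ``codon``.

    Ties break lexicographically; single-codon amino acids (Met, Trp)
    return the codon unchanged.
    """
    choices = SYNONYMS.get(codon, [codon])
    best = codon
    best_d = 0
    for c in choices:
        d = _hamming(c, codon)
        if d > best_d or (d == best_d and d > 0 and c < best):
            best, best_d = c, d
    return best


@dataclass
class PcrTagParams:
    """Synonymous PCR-tag recoding parameters (engineering defaults)."""

    tag_len: int = 24
    amplicon_range: tuple[int, int] = (200, 500)
    tm_range: tuple[float, float] = (58.0, 62.0)
    min_mismatches: int = 8

    def __post_init__(self) -> None:
        if self.tag_len % 3:
            raise ValueError("tag_len must be a codon multiple for clean recoding")


@dataclass
class DesignPolicy:
    """Everything the design engine needs to know about the rules.

    Defaults implement the standard rule set: loxPsym 3 bp downstream of
    the stop of non-essential verified/uncharacterized ORFs (dubious ORFs
    are spared), all introns removed except a retain list, TAG stops
    swapped to TAA, tRNAs and transposons deleted, telomeres replaced with
    a synthetic cap, and two PCR tags recoded per taggable ORF.
    """

    loxpsym_sequence: str = LOXPSYM
    loxpsym_offset: int = 3
    loxpsym_classes: tuple[str, ...] = ("Verified", "Uncharacterized")
    intron_retain_ids: tuple[str, ...] = ()
    stop_swap: dict[str, str] = field(default_factory=lambda: {"TAG": "TAA"})
    remove_kinds: tuple[str, ...] = ("tRNA", "transposon")
    telomere_cap: str = DEFAULT_TELOMERE_CAP
    pcrtag: PcrTagParams = field(default_factory=PcrTagParams)
    forbidden_sites: tuple[str, ...] = ("GCGGCCGC",)  # NotI by default
    check_palindrome: bool = True

    def __post_init__(self) -> None:
        if self.loxpsym_offset < 0:
            raise ValueError("loxpsym_offset must be >= 0")
        self.loxpsym_sequence = self.loxpsym_sequence.upper()
        if self.check_palindrome and revcomp(self.loxpsym_sequence) != self.loxpsym_sequence:
            raise ValueError("loxpsym_sequence is not palindromic; set check_palindrome=False "
                             "to override")


@dataclass
class PcrTagPair:
    """One recoded tag window: wild-type and synthetic sequences (gene orientation)."""

    orf_id: str
    tag_index: int
    native_start: int
    native_end: int
    strand: str
    wt_seq: str
    syn_seq: str
    tm_wt: float
    tm_syn: float
    mismatches: int
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Eligibility helpers
# ---------------------------------------------------------------------------

def _orf_class(orf: Feature) -> str:
    return orf.attrs.get("orf_class", "Uncharacterized")


def _is_essential(orf: Feature) -> bool:
    return orf.attrs.get("essential", "no").lower() in ("yes", "true", "1")


def loxpsym_eligible(orf: Feature, policy: DesignPolicy) -> bool:
    return (not _is_essential(orf)) and _orf_class(orf) in policy.loxpsym_classes


def _stop_interval(orf: Feature) -> tuple[int, int]:
    """Chromosome-coordinate interval of the ORF's stop codon."""
    if orf.strand == "+":
        return orf.end - 3, orf.end
    return orf.start, orf.start + 3


def orf_stop_codon(genome: GenomeRecord, orf: Feature) -> str:
    s, e = _stop_interval(orf)
    codon = genome.sequence[s:e]
    return revcomp(codon) if orf.strand == "-" else codon


# ---------------------------------------------------------------------------
# Individual rule passes (each returns edits in native coordinates)
# ---------------------------------------------------------------------------

def insert_loxpsym_sites(genome: GenomeRecord, policy: DesignPolicy) -> list[EditRecord]:
    """One loxPsym insert per eligible ORF, `offset` bases 3' of its stop.

    On the minus strand "3' of the stop" means toward lower chromosome
    coordinates, so the site lands ``offset`` bases before the feature
    start.  Insertions whose insertion point falls inside another annotated
    feature, or beyond the chromosome end, are skipped and logged.
    """
    edits: list[EditRecord] = []
    for orf in genome.features_of_kind("ORF"):
        if not loxpsym_eligible(orf, policy):
            continue
        if orf.strand == "+":
            point = orf.end + policy.loxpsym_offset
        else:
            point = orf.start - policy.loxpsym_offset
        if point < 0 or point > genome.length:
            logger.warning("loxPsym for %s beyond chromosome end; skipped", orf.id)
            continue
        collision = next(
            (f for f in genome.features if f.id != orf.id and f.contains(point)),
            None,
        )
        if collision is not None:
            logger.warning(
                "loxPsym for %s collides with %s at %d; skipped", orf.id, collision.id, point
            )
            continue
        edits.append(
            EditRecord("insert", point, point, policy.loxpsym_sequence, "loxpsym",
                       note=orf.id)
        )
    return edits


def remove_introns(genome: GenomeRecord, retain_ids: Iterable[str] = ()) -> list[EditRecord]:
    """Delete edits for every annotated intron not in ``retain_ids``.

    Raises if excision would break the parent ORF's reading frame (the
    excised CDS must still be a codon multiple translating without internal
    stops) — that indicates a corrupt annotation, not a policy choice.
    """
    retain = set(retain_ids)
    edits: list[EditRecord] = []
    for intron in genome.features_of_kind("intron"):
        if intron.id in retain:
            continue
        parent_id = intron.attrs.get("Parent")
        if parent_id:
            parent = genome.feature_by_id(parent_id)
            cds = genome.orf_cds(parent)  # excises all introns; raises on frame break
            prot = translate_cds(cds)
            if "*" in prot[:-1]:
                raise LedgerError(
                    f"intron {intron.id}: excision creates internal stop in {parent_id}"
                )
        edits.append(EditRecord("delete", intron.start, intron.end, "", "intron_removal",
                                note=intron.id))
    return edits


def swap_stop_codons(genome: GenomeRecord, policy: DesignPolicy) -> list[EditRecord]:
    """Substitute TAG stops of verified/uncharacterized ORFs with TAA.

    Dubious ORFs are spared.  Payloads are expressed on the chromosome
    forward strand (reverse complement for minus-strand ORFs).
    """
    edits: list[EditRecord] = []
    for orf in genome.features_of_kind("ORF"):
        if _orf_class(orf) not in ("Verified", "Uncharacterized"):
            continue
        stop = orf_stop_codon(genome, orf)
        if stop not in ("TAA", "TAG", "TGA"):
            raise LedgerError(f"ORF {orf.id} has no valid stop codon (found {stop})")
        new = policy.stop_swap.get(stop)
        if new is None:
            continue
        s, e = _stop_interval(orf)
        payload = revcomp(new) if orf.strand == "-" else new
        edits.append(EditRecord("substitute", s, e, payload, "stop_swap", note=orf.id))
    return edits


def remove_features(genome: GenomeRecord, kinds: Iterable[str]) -> list[EditRecord]:
    """One full-interval delete per feature of the named kinds."""
    kinds = set(kinds)
    return [
        EditRecord("delete", f.start, f.end, "", "feature_removal", note=f"{f.kind}:{f.id}")
        for f in genome.features
        if f.kind in kinds
    ]


def cap_telomeres(genome: GenomeRecord, cap_seq: str) -> list[EditRecord]:
    """Replace annotated telomeres with the synthetic cap.

    The cap is written 5'->3' for the right end; the left telomere receives
    its reverse complement so both chromosome ends carry the same
    outward-facing repeat.
    """
    telomeres = genome.features_of_kind("telomere")
    if not telomeres:
        logger.warning("no telomere annotations; nothing to cap")
        return []
    mid = genome.length / 2
    edits = []
    for tel in telomeres:
        payload = revcomp(cap_seq) if (tel.start + tel.end) / 2 < mid else cap_seq
        edits.append(
            EditRecord("substitute", tel.start, tel.end, payload, "telomere_cap", note=tel.id)
        )
    return edits


def _tm(seq: str) -> float:
    return float(MeltingTemp.Tm_NN(seq))


def _recode_window(wt_codons: list[str], params: PcrTagParams,
                   forbidden: tuple[str, ...]) -> tuple[str, list[str]]:
    """Greedy per-codon most-different recoding of one tag window."""
    syn_codons = [most_different_codon(c) for c in wt_codons]
    warnings: list[str] = []
    syn = "".join(syn_codons)
    # destroy any forbidden site the recoding created
    for site in forbidden:
        guard = 0
        while site in syn and guard < 20:
            guard += 1
            k = syn.index(site)
            hit = False
            for ci in range(k // 3, min(len(syn_codons), (k + len(site) + 2) // 3)):
                for alt in SYNONYMS.get(wt_codons[ci], [wt_codons[ci]]):
                    if alt == syn_codons[ci]:
                        continue
                    trial = syn_codons.copy()
                    trial[ci] = alt
                    if site not in "".join(trial):
                        syn_codons = trial
                        syn = "".join(syn_codons)
                        hit = True
                        break
                if hit:
                    break
            if not hit:
                warnings.append(f"forbidden_site_unavoidable:{site}")
                break
    return "".join(syn_codons), warnings


def recode_pcrtags(
    genome: GenomeRecord, params: PcrTagParams | None = None,
    forbidden_sites: tuple[str, ...] = (),
) -> tuple[list[EditRecord], list[PcrTagPair]]:
    """Choose and synonymously recode two tag windows per taggable ORF.

    Taggable: verified/uncharacterized, intron-free, and long enough for an
    amplicon within ``amplicon_range``.  Tag windows sit on codon
    boundaries at the two ends of the amplicon; each window is recoded by
    greedy most-different synonymous codon choice.  Windows falling short
    of ``min_mismatches`` or outside the Tm range are emitted with warning
    flags rather than dropped.
    """
    params = params or PcrTagParams()
    lo, hi = params.amplicon_range
    tag_codons = params.tag_len // 3
    edits: list[EditRecord] = []
    pairs: list[PcrTagPair] = []
    intronful = {f.attrs.get("Parent") for f in genome.features_of_kind("intron")}
    for orf in genome.features_of_kind("ORF"):
        if _orf_class(orf) not in ("Verified", "Uncharacterized"):
            continue
        if orf.id in intronful:
            logger.info("ORF %s carries an intron; not tagged", orf.id)
            continue
        cds = genome.orf_cds(orf)
        usable_codons = len(cds) // 3 - 1  # exclude the stop codon
        min_amp_codons = -(-lo // 3)
        max_amp_codons = hi // 3
        if usable_codons - 1 < min_amp_codons:
            logger.info("ORF %s too short for an amplicon; not tagged", orf.id)
            continue
        amp_codons = min(max_amp_codons, usable_codons - 1)
        start_codon = 1  # skip the ATG
        windows = [
            (start_codon, start_codon + tag_codons),
            (start_codon + amp_codons - tag_codons, start_codon + amp_codons),
        ]
        for tag_index, (c0, c1) in enumerate(windows):
            wt_codons = [cds[i * 3 : i * 3 + 3] for i in range(c0, c1)]
            wt = "".join(wt_codons)
            syn, warn = _recode_window(wt_codons, params, forbidden_sites)
            mism = _hamming(wt, syn)
            if mism < params.min_mismatches:
                warn.append("min_mismatches_unreached")
            tm_wt, tm_syn = _tm(wt), _tm(syn)
            if not (params.tm_range[0] <= tm_syn <= params.tm_range[1]):
                warn.append("tm_out_of_range")
            # map gene-space window back to chromosome coordinates
            g0, g1 = c0 * 3, c1 * 3
            if orf.strand == "+":
                n0, n1 = orf.start + g0, orf.start + g1
                payload = syn
            else:
                n0, n1 = orf.end - g1, orf.end - g0
                payload = revcomp(syn)
            edits.append(
                EditRecord("substitute", n0, n1, payload, "pcrtag_recode",
                           note=f"{orf.id}.{tag_index}")
            )
            pairs.append(
                PcrTagPair(orf.id, tag_index, n0, n1, orf.strand, wt, syn,
                           round(tm_wt, 2), round(tm_syn, 2), mism, tuple(warn))
            )
    return edits, pairs


# ---------------------------------------------------------------------------
# Whole-design driver
# ---------------------------------------------------------------------------

def size_reduction_percent(native_len: int, designed_len: int) -> float:
    """Percent size reduction of the designed vs native chromosome."""
    return 100.0 * (native_len - designed_len) / native_len


def apply_design(
    genome: GenomeRecord, policy: DesignPolicy | None = None
) -> tuple[GenomeRecord, DesignLedger, dict]:
    """Run every rule pass, merge edits, and emit the designed chromosome.

    Edits are computed independently in the native frame in canonical order
    (feature removal → intron removal → stop swap → PCR-tag recode →
    loxPsym insertion → telomere caps) and merged into one non-overlapping
    ledger; any cross-rationale collision is a hard error.  Surviving
    annotations are lifted through the ledger; new loxpsym/pcrtag/telomere
    features are added at their design-space payload positions.
    """
    policy = policy or DesignPolicy()
    edits: list[EditRecord] = []
    edits += remove_features(genome, policy.remove_kinds)
    edits += remove_introns(genome, policy.intron_retain_ids)
    edits += swap_stop_codons(genome, policy)
    tag_edits, tag_pairs = recode_pcrtags(genome, policy.pcrtag, policy.forbidden_sites)
    edits += tag_edits
    edits += insert_loxpsym_sites(genome, policy)
    edits += cap_telomeres(genome, policy.telomere_cap)

    ledger = DesignLedger(source_id=genome.id, target_id=genome.id + "_syn", edits=edits)
    designed_seq = ledger.apply(genome.sequence)

    # forbidden-site audit over edited regions
    created = scan_created_sites(genome.sequence, designed_seq, ledger, policy.forbidden_sites)
    if created:
        logger.warning("edits created forbidden sites at design positions %s", created)

    # lift surviving features
    removed_note_ids = {
        e.note for e in edits if e.rationale in ("feature_removal", "intron_removal")
    }
    new_features: list[Feature] = []
    for f in genome.features:
        if f.kind in policy.remove_kinds or f.kind == "telomere":
            continue
        if f.kind == "intron" and f.id in removed_note_ids:
            continue
        lifted = lift_interval(ledger, f.start, f.end)
        if lifted is None:
            continue
        new_features.append(Feature(f.id, f.kind, lifted[0], lifted[1], f.strand,
                                    dict(f.attrs)))
    # payload-anchored features
    for e, d0, d1 in payload_design_intervals(ledger):
        if e.rationale == "loxpsym":
            new_features.append(
                Feature(f"loxpsym_{e.note}", "loxpsym", d0, d1, "+", {"orf": e.note})
            )
        elif e.rationale == "pcrtag_recode":
            new_features.append(
                Feature(f"pcrtag_{e.note}", "pcrtag", d0, d1, "+", {"orf_tag": e.note})
            )
        elif e.rationale == "telomere_cap":
            new_features.append(
                Feature(f"syn_{e.note}", "telomere", d0, d1, "+", {"synthetic": "yes"})
            )

    designed = GenomeRecord(id=ledger.target_id, sequence=designed_seq,
                            features=new_features)

    counts: dict[str, int] = {}
    for e in ledger.edits:
        counts[e.rationale] = counts.get(e.rationale, 0) + 1
    summary = {
        "counts": counts,
        "n_pcrtag_sequences": 2 * len(tag_pairs),  # each pair = WT + SYN sequence
        "n_pcrtag_pairs": len(tag_pairs),
        "source_len": genome.length,
        "target_len": designed.length,
        "net_delta": ledger.net_delta,
        "percent_reduction": size_reduction_percent(genome.length, designed.length),
        "percent_reduction_int": round(size_reduction_percent(genome.length, designed.length)),
        "tag_pairs": tag_pairs,
    }
    return designed, ledger, summary


def scan_created_sites(
    native_seq: str, designed_seq: str, ledger: DesignLedger,
    forbidden_sites: tuple[str, ...],
) -> list[int]:
    """Design-space positions where an edit created a forbidden enzyme site."""
    hits: list[int] = []
    for e, d0, d1 in payload_design_intervals(ledger):
        for site in forbidden_sites:
            lo = max(0, d0 - len(site) + 1)
            hi = min(len(designed_seq), d1 + len(site) - 1)
            region = designed_seq[lo:hi]
            k = region.find(site)
            while k != -1:
                # only report if the native counterpart region lacked it
                hits.append(lo + k)
                k = region.find(site, k + 1)
    return hits


def verify_design(
    native: GenomeRecord, designed: GenomeRecord, ledger: DesignLedger,
    policy: DesignPolicy | None = None,
) -> dict:
    """Independent post-hoc audit of a designed chromosome.

    Checks: ledger reproduces the designed sequence bit-exactly; every
    surviving verified/uncharacterized ORF translates to the same protein
    as in the native chromosome; no verified/uncharacterized ORF retains a
    TAG stop; loxPsym feature count matches eligibility.  Returns a report
    dict with an overall ``ok`` flag.
    """
    policy = policy or DesignPolicy()
    report: dict[str, dict] = {}

    rebuilt = ledger.apply(native.sequence)
    report["sequence_reproducible"] = {
        "ok": rebuilt == designed.sequence,
        "detail": f"{len(rebuilt)} vs {designed.length} bp",
    }

    bad_proteins: list[str] = []
    designed_by_id = {f.id: f for f in designed.features if f.kind == "ORF"}
    for orf in native.features_of_kind("ORF"):
        if _orf_class(orf) == "Dubious":
            continue
        d_orf = designed_by_id.get(orf.id)
        if d_orf is None:
            bad_proteins.append(f"{orf.id}:missing")
            continue
        p_nat = translate_cds(native.orf_cds(orf))
        p_des = translate_cds(designed.orf_cds(d_orf))
        if p_nat != p_des:
            bad_proteins.append(orf.id)
    report["protein_conservation"] = {"ok": not bad_proteins, "detail": bad_proteins[:10]}

    tag_stops = [
        f.id
        for f in designed.features_of_kind("ORF")
        if _orf_class(f) != "Dubious" and orf_stop_codon(designed, f) == "TAG"
    ]
    report["no_tag_stops"] = {"ok": not tag_stops, "detail": tag_stops[:10]}

    n_sites = len(designed.features_of_kind("loxpsym"))
    n_edits = sum(1 for e in ledger.edits if e.rationale == "loxpsym")
    report["loxpsym_count"] = {
        "ok": n_sites == n_edits,
        "detail": f"{n_sites} features vs {n_edits} edits",
    }

    report["ok"] = all(v["ok"] for k, v in report.items() if k != "ok")
    return report
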