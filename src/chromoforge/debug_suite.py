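"""Sequencing-based debugging of a synthetic chromosome build.

Four stages: (1) localize growth-defect loci from pooled fast/slow-grower
coverage over a hybrid synthetic+wild-type reference, (2) estimate copy
number from relative read depth, (3) classify design-vs-observed sequence
discrepancies into critical and non-critical classes, and (4) plan repairs
with proximity bundling of non-critical discrepancies onto critical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .genome_io import GenomeRecord, revcomp, translate_cds

logger = logging.getLogger("chromoforge")


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, partition: str | None = None) -> pd.DataFrame:
    """Read a 4-column bedGraph into a window table (start, end, depth[, partition]).

    A ``partition`` column may also ride along as a 5th column (SYN_allele /
    WT_allele / other) for hybrid-reference tracks.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 5:
        df.columns = ["contig", "start", "end", "depth", "partition"]
    else:
        df.columns = ["contig", "start", "end", "depth"]
        df["partition"] = partition or "SYN_allele"
    return df[["start", "end", "depth", "partition"]]


def write_bedgraph(track: pd.DataFrame, path: str | Path, contig: str = "chr") -> None:
    out = track.copy()
    out.insert(0, "contig", contig)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Pooled fast/slow defect localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizeParams:
    min_run: int = 3  # consecutive windows
    log2_threshold: float = -1.0
    pseudocount: float = 0.01  # on median-normalized depth, guards log2(0)


@dataclass
class CandidateInterval:
    start: int
    end: int
    n_windows: int
    mean_score: float
    reciprocal_support: bool
    megachunks: tuple[str, ...] = ()


def _runs_below(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def localize_defect(
    fast_track: pd.DataFrame,
    slow_track: pd.DataFrame,
    params: LocalizeParams | None = None,
    megachunk_table: pd.DataFrame | None = None,
) -> list[CandidateInterval]:
    """Find synthetic regions depleted in the fast pool relative to the slow pool.

    Each track is median-normalized over all its windows; the per-window
    score is log2(fast/slow) computed within the SYN_allele partition.
    Maximal runs of >= min_run windows at score <= threshold become
    candidates.  The reciprocal signal — the wild-type allele depleted in
    the slow pool over the same windows — is cross-checked and reported as
    ``reciprocal_support``.
    """
    params = params or LocalizeParams()
    cands: list[CandidateInterval] = []

    def norm(track: pd.DataFrame) -> pd.DataFrame:
        med = float(track["depth"].median())
        if med <= 0:
            raise ValueError("track median depth is zero; cannot normalize")
        t = track.copy()
        t["norm"] = t["depth"] / med
        return t

    fast = norm(fast_track)
    slow = norm(slow_track)

    def scores(partition: str) -> pd.DataFrame:
        f = fast[fast["partition"] == partition].sort_values("start").reset_index(drop=True)
        s = slow[slow["partition"] == partition].sort_values("start").reset_index(drop=True)
        if len(f) != len(s) or not (f["start"].values == s["start"].values).all():
            raise ValueError("fast and slow tracks do not tile the same windows")
        eps = params.pseudocount
        out = f[["start", "end"]].copy()
        out["score"] = np.log2((f["norm"].values + eps) / (s["norm"].values + eps))
        return out

    syn = scores("SYN_allele")
    has_wt = (fast["partition"] == "WT_allele").any()
    wt = scores("WT_allele") if has_wt else None

    mask = syn["score"].values <= params.log2_threshold
    for i, j in _runs_below(mask, params.min_run):
        start = int(syn["start"].iloc[i])
        end = int(syn["end"].iloc[j - 1])
        recip = False
        if wt is not None:
            # reciprocal: WT allele low in slow pool == score >= |threshold| here
            wt_scores = wt["score"].values[i:j]
            recip = bool(np.median(wt_scores) >= -params.log2_threshold)
        megas: tuple[str, ...] = ()
        if megachunk_table is not None:
            hit = megachunk_table[
                (megachunk_table["start"] < end) & (start < megachunk_table["end"])
            ]
            megas = tuple(sorted(set(hit["megachunk"])))
        cands.append(
            CandidateInterval(
                start=start,
                end=end,
                n_windows=j - i,
                mean_score=float(np.mean(syn["score"].values[i:j])),
                reciprocal_support=recip,
                megachunks=megas,
            )
        )
    return cands


# ---------------------------------------------------------------------------
# Read-depth copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberEstimate:
    copies: float
    ci_low: float
    ci_high: float
    n_target_windows: int
    n_baseline_windows: int


def estimate_copy_number(
    track: pd.DataFrame,
    target_interval: tuple[int, int],
    baseline_intervals: list[tuple[int, int]],
    baseline_copies: float = 1.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CopyNumberEstimate:
    """Copy number of a target interval relative to baseline loci.

    copies = baseline_copies * mean(depth in target) / mean(depth in baseline),
    with a percentile bootstrap CI over windows.
    """
    def select(lo: int, hi: int) -> np.ndarray:
        m = (track["start"] < hi) & (track["end"] > lo)
        return track.loc[m, "depth"].values.astype(float)

    tgt = select(*target_interval)
    base = np.concatenate([select(lo, hi) for lo, hi in baseline_intervals]) \
        if baseline_intervals else np.array([])
    if tgt.size == 0 or base.size == 0:
        raise ValueError("empty target or baseline interval")
    if base.mean() <= 0:
        raise ValueError("baseline depth must be positive")
    copies = baseline_copies * tgt.mean() / base.mean()

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        t = rng.choice(tgt, size=tgt.size, replace=True).mean()
        z = rng.choice(base, size=base.size, replace=True).mean()
        boots[b] = baseline_copies * t / z if z > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CopyNumberEstimate(float(copies), float(lo), float(hi), tgt.size, base.size)


# ---------------------------------------------------------------------------
# Discrepancy classification
# ---------------------------------------------------------------------------

SEVERITY = {
    "residual_TAG_stop": "critical",
    "nonsynonymous": "critical",
    "duplication": "critical",
    "missing_loxpsym": "noncritical",
    "missing_pcrtag": "noncritical",
    "missing_restriction_site": "noncritical",
    "synonymous_other": "noncritical",
}


@dataclass
class Variant:
    """Minimal variant in design coordinates (0-based)."""

    pos: int
    ref: str
    alt: str  # literal bases, or symbolic "<DEL>"/"<DUP>"
    end: int | None = None  # for symbolic alleles

    @property
    def is_symbolic(self) -> bool:
        return self.alt in ("<DEL>", "<DUP>")

    @property
    def span(self) -> tuple[int, int]:
        if self.is_symbolic:
            return self.pos, self.end if self.end is not None else self.pos + len(self.ref)
        return self.pos, self.pos + len(self.ref)


@dataclass
class DiscrepancyRecord:
    position: int
    klass: str
    severity: str
    detail: str = ""


def read_minimal_vcf(path: str | Path) -> list[Variant]:
    """Parse the minimal VCF dialect: CHROM POS REF ALT [END=n for symbolic]."""
    variants: list[Variant] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            pos1 = int(cols[1])
            ref, alt = cols[3].upper(), cols[4].upper()
            end = None
            if len(cols) > 7 and "END=" in cols[7]:
                for item in cols[7].split(";"):
                    if item.startswith("END="):
                        end = int(item[4:])  # 1-based inclusive -> half-open below
            v = Variant(pos=pos1 - 1, ref=ref, alt=alt, end=end)
            variants.append(v)
    return variants


def variants_from_observed_fasta(designed_seq: str, observed_seq: str) -> list[Variant]:
    """Derive variant blocks by global alignment of observed vs designed sequence.

    Affine gap penalties keep indels contiguous (a 34-bp loxPsym loss comes
    out as one <DEL> block rather than scattered gaps); mismatch runs inside
    aligned blocks become substitution variants.
    """
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-6,
        extend_gap_score=-0.1,
    )
    aln = aligner.align(designed_seq, observed_seq)[0]
    d_blocks, o_blocks = aln.aligned
    variants: list[Variant] = []
    d_prev = o_prev = 0
    for (d0, d1), (o0, o1) in zip(d_blocks, o_blocks):
        if d0 > d_prev:  # gap in observed -> deletion from design
            variants.append(
                Variant(d_prev, designed_seq[d_prev:d0], "<DEL>", end=d0)
            )
        if o0 > o_prev:  # gap in design -> insertion
            variants.append(Variant(d0, "", observed_seq[o_prev:o0]))
        # mismatch runs inside the aligned block
        i = 0
        n = d1 - d0
        while i < n:
            if designed_seq[d0 + i] != observed_seq[o0 + i]:
                j = i
                while j < n and designed_seq[d0 + j] != observed_seq[o0 + j]:
                    j += 1
                variants.append(
                    Variant(d0 + i, designed_seq[d0 + i : d0 + j],
                            observed_seq[o0 + i : o0 + j])
                )
                i = j
            else:
                i += 1
        d_prev, o_prev = d1, o1
    if len(designed_seq) > d_prev:
        variants.append(
            Variant(d_prev, designed_seq[d_prev:], "<DEL>", end=len(designed_seq))
        )
    if len(observed_seq) > o_prev:
        variants.append(Variant(len(designed_seq), "", observed_seq[o_prev:]))
    return variants


def _patched_window(seq: str, w0: int, w1: int, v: Variant) -> str | None:
    """The designed window [w0,w1) with the variant applied, if length-preserving."""
    s, e = v.span
    if v.is_symbolic or len(v.ref) != len(v.alt):
        return None
    if s < w0 or e > w1:
        return None
    rel = s - w0
    win = seq[w0:w1]
    return win[:rel] + v.alt + win[rel + len(v.alt):]


def classify_discrepancies(
    designed: GenomeRecord,
    variants: list[Variant],
    tag_pairs=None,
    junction_sites: list[tuple[int, str]] | None = None,
    duplication_intervals: list[tuple[int, int]] | None = None,
) -> list[DiscrepancyRecord]:
    """Assign every observed variant exactly one discrepancy class.

    Precedence: duplication (symbolic <DUP> or supplied CN-gain interval) →
    missing_loxpsym (deletion covering a loxPsym feature) →
    residual_TAG_stop (verified-ORF stop reads TAG where design says TAA) →
    missing_pcrtag (substitution inside a tag window reverting toward the
    wild-type tag) → missing_restriction_site (junction recognition
    sequence destroyed) → nonsynonymous / synonymous_other by codon
    comparison inside verified/uncharacterized ORFs; anything else is
    synonymous_other (noncritical).
    """
    seq = designed.sequence
    orfs = designed.features_of_kind("ORF")
    lox = designed.features_of_kind("loxpsym")
    dup_iv = duplication_intervals or []
    tag_windows = []
    if tag_pairs:
        for p in tag_pairs:
            # design-space window: tags keep their recoded (SYN) sequence
            hits = [f for f in designed.features_of_kind("pcrtag")
                    if f.attrs.get("orf_tag") == f"{p.orf_id}.{p.tag_index}"]
            if hits:
                tag_windows.append((hits[0].start, hits[0].end, p))
    records: list[DiscrepancyRecord] = []
    for v in variants:
        s, e = v.span
        if e > designed.length + 1:
            raise ValueError(f"variant at {v.pos} outside chromosome")
        rec = None
        if v.alt == "<DUP>" or any(s < d1 and d0 < e for d0, d1 in dup_iv):
            rec = DiscrepancyRecord(v.pos, "duplication", "critical",
                                    f"span {s}-{e}")
        elif v.alt == "<DEL>" and any(s <= f.start and f.end <= e for f in lox):
            hit = next(f for f in lox if s <= f.start and f.end <= e)
            rec = DiscrepancyRecord(v.pos, "missing_loxpsym", "noncritical", hit.id)
        if rec is None:
            for orf in orfs:
                if not orf.overlaps(s, e):
                    continue
                klass = orf.attrs.get("orf_class", "Uncharacterized")
                stop0, stop1 = (orf.end - 3, orf.end) if orf.strand == "+" else \
                    (orf.start, orf.start + 3)
                patched = _patched_window(seq, stop0, stop1, v)
                if patched is not None and klass == "Verified":
                    obs_stop = revcomp(patched) if orf.strand == "-" else patched
                    des_stop = seq[stop0:stop1]
                    des_stop = revcomp(des_stop) if orf.strand == "-" else des_stop
                    if des_stop == "TAA" and obs_stop == "TAG":
                        rec = DiscrepancyRecord(v.pos, "residual_TAG_stop", "critical",
                                                orf.id)
                        break
                # tag-window reversion?
                for w0, w1, pair in tag_windows:
                    if pair.orf_id != orf.id:
                        continue
                    patched = _patched_window(seq, w0, w1, v)
                    if patched is None:
                        continue
                    win = seq[w0:w1]
                    gene_patched = revcomp(patched) if pair.strand == "-" else patched
                    gene_win = revcomp(win) if pair.strand == "-" else win
                    d_before = sum(a != b for a, b in zip(gene_win, pair.wt_seq))
                    d_after = sum(a != b for a, b in zip(gene_patched, pair.wt_seq))
                    if d_after < d_before:
                        rec = DiscrepancyRecord(v.pos, "missing_pcrtag", "noncritical",
                                                f"{pair.orf_id}.{pair.tag_index}")
                        break
                if rec is not None:
                    break
                if klass in ("Verified", "Uncharacterized") and not v.is_symbolic \
                        and len(v.ref) == len(v.alt):
                    if _protein_changing(designed, orf, v):
                        rec = DiscrepancyRecord(v.pos, "nonsynonymous", "critical", orf.id)
                    else:
                        rec = DiscrepancyRecord(v.pos, "synonymous_other", "noncritical",
                                                orf.id)
                    break
                # indels inside coding sequence shift frame -> protein-changing
                if klass in ("Verified", "Uncharacterized"):
                    rec = DiscrepancyRecord(v.pos, "nonsynonymous", "critical",
                                            f"{orf.id}:indel")
                    break
        if rec is None and junction_sites:
            for jpos, site in junction_sites:
                j0, j1 = jpos, jpos + len(site)
                if s < j1 and j0 < e:
                    patched = _patched_window(seq, j0, j1, v)
                    if patched is None or patched != site:
                        rec = DiscrepancyRecord(v.pos, "missing_restriction_site",
                                                "noncritical", f"junction@{jpos}")
                        break
        if rec is None:
            rec = DiscrepancyRecord(v.pos, "synonymous_other", "noncritical", "intergenic")
        assert SEVERITY[rec.klass] == rec.severity
        records.append(rec)
    return records


def _protein_changing(designed: GenomeRecord, orf, v: Variant) -> bool:
    seq = designed.sequence
    patched = _patched_window(seq, orf.start, orf.end, v)
    if patched is None:
        return True
    before = seq[orf.start : orf.end]
    if orf.strand == "-":
        before, patched = revcomp(before), revcomp(patched)
    # introns inside designed ORFs are rare (retain list); compare direct codons
    n = len(before) - len(before) % 3
    return translate_cds(before[:n]) != translate_cds(patched[:n])


# ---------------------------------------------------------------------------
# Repair planning
# ---------------------------------------------------------------------------

@dataclass
class RepairItem:
    position: int
    critical: DiscrepancyRecord
    bundled: list[DiscrepancyRecord] = field(default_factory=list)


@dataclass
class RepairPlan:
    scheduled: list[RepairItem]
    deferred: list[DiscrepancyRecord]


def plan_repairs(records: list[DiscrepancyRecord], bundle_distance: int = 5_000) -> RepairPlan:
    """Schedule all critical repairs; bundle nearby non-critical ones.

    Every critical record becomes a scheduled repair (ordered by
    coordinate).  Each non-critical record within ``bundle_distance`` of a
    scheduled critical record is attached to the nearest one; the rest are
    deferred.  The result is independent of input order and idempotent.
    """
    criticals = sorted((r for r in records if r.severity == "critical"),
                       key=lambda r: (r.position, r.klass))
    noncrit = sorted((r for r in records if r.severity == "noncritical"),
                     key=lambda r: (r.position, r.klass))
    items = [RepairItem(r.position, r) for r in criticals]
    deferred: list[DiscrepancyRecord] = []
    for r in noncrit:
        best = None
        best_d = bundle_distance + 1
        for it in items:
            d = abs(r.position - it.position)
            if d < best_d:
                best, best_d = it, d
        if best is not None and best_d <= bundle_distance:
            best.bundled.append(r)
        else:
            deferred.append(r)
    return RepairPlan(items, deferred)
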