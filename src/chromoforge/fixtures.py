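"""Seeded synthetic-input generators.

Every generator is a pure function of (spec, seed) and produces inputs that
satisfy the preconditions of the module that consumes them: toy chromosomes
for the design engine and build planner, pooled fast/slow coverage tracks
for the defect localizer, qPCR plates for the genotyping caller, and
propidium-iodide DNA-content histograms for the ploidy classifier.

The toy chromosome emulates the annotation structure of a yeast chromosome
arm-to-arm: telomeres at both ends, one centromere, stranded ORFs (a subset
essential, a subset dubious, a subset intron-bearing), tRNA genes with
anticodons, and transposon blocks, separated by intergenic spacers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import Feature, GenomeRecord, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))

#: sense codons (all 64 minus the three stops)
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: a few real yeast tRNA anticodons to draw from
ANTICODONS = [
    "AGC", "UGC", "GCA", "GUC", "UUC", "GCC", "GUG", "GAU", "UAA", "CAA",
    "UUU", "CAU", "GAA", "UGG", "UGA", "AGU", "AGA", "UAC", "CCA", "GUA",
]


class GenerationError(ValueError):
    """Requested features cannot be packed into the requested length."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int, stop: str) -> str:
    """ATG + random sense codons + stop; translates with no internal stops."""
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + stop


@dataclass
class ToyChromosomeSpec:
    """Parameters of a generated toy chromosome."""

    length: int = 60_000
    n_orfs: int = 20
    fraction_essential: float = 0.15
    fraction_dubious: float = 0.1
    n_introns: int = 2
    n_trnas: int = 3
    n_transposons: int = 2
    telomere_len: int = 500
    intergenic_min: int = 100
    orf_codons: tuple[int, int] = (100, 250)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.fraction_essential, self.fraction_dubious):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.n_introns > self.n_orfs:
            raise GenerationError("more introns than ORFs")


def make_toy_chromosome(spec: ToyChromosomeSpec) -> tuple[GenomeRecord, pd.DataFrame]:
    """Generate a toy chromosome plus a truth table of every planted feature.

    The truth table columns: id, kind, start, end, strand, essential,
    orf_class, stop_codon, has_intron, anticodon, eligible_loxpsym.
    """
    rng = np.random.default_rng(spec.seed)

    # -- draw the blocks -----------------------------------------------------
    blocks: list[dict] = []  # kind, seq, strand, meta
    intron_orfs = set(rng.choice(spec.n_orfs, size=spec.n_introns, replace=False).tolist())
    for i in range(spec.n_orfs):
        n_codons = int(rng.integers(spec.orf_codons[0], spec.orf_codons[1] + 1))
        stop = STOP_CODONS[rng.integers(0, 3)]
        cds = _random_cds(rng, n_codons, stop)
        strand = "+" if rng.random() < 0.5 else "-"
        dubious = rng.random() < spec.fraction_dubious
        essential = (not dubious) and rng.random() < spec.fraction_essential
        orf_class = (
            "Dubious" if dubious else ("Verified" if rng.random() < 0.8 else "Uncharacterized")
        )
        intron = None
        if i in intron_orfs:
            ilen = int(rng.integers(60, 201))
            iseq = "GT" + _random_dna(rng, ilen - 4) + "AG"
            # insert between codons, away from ATG and the stop
            codon_idx = int(rng.integers(2, n_codons - 2))
            intron = (codon_idx * 3, iseq)
        blocks.append(
            dict(
                kind="ORF",
                id=f"ORF{i + 1:03d}",
                cds=cds,
                strand=strand,
                essential=essential,
                orf_class=orf_class,
                stop=stop,
                intron=intron,
            )
        )
    for i in range(spec.n_trnas):
        blocks.append(
            dict(
                kind="tRNA",
                id=f"tRNA{i + 1:02d}",
                seq=_random_dna(rng, 72),
                strand="+",
                anticodon=ANTICODONS[int(rng.integers(0, len(ANTICODONS)))],
            )
        )
    for i in range(spec.n_transposons):
        blocks.append(
            dict(kind="transposon", id=f"TY{i + 1:02d}", seq=_random_dna(rng, 400), strand="+")
        )
    blocks.append(dict(kind="centromere", id="CEN", seq=_random_dna(rng, 120), strand="+"))

    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    def block_len(b: dict) -> int:
        if b["kind"] == "ORF":
            return len(b["cds"]) + (len(b["intron"][1]) if b["intron"] else 0)
        return len(b["seq"])

    need = (
        2 * spec.telomere_len
        + sum(block_len(b) for b in blocks)
        + (len(blocks) + 1) * spec.intergenic_min
    )
    if need > spec.length:
        raise GenerationError(f"need {need} bp but only {spec.length} requested")

    # distribute the slack over the gaps
    slack = spec.length - need
    n_gaps = len(blocks) + 1
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gap_extra = np.diff(np.concatenate([[0], cuts, [slack]]))

    # -- lay the sequence down ----------------------------------------------
    seq_parts: list[str] = []
    features: list[Feature] = []
    truth_rows: list[dict] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        seq_parts.append(s)
        pos += len(s)

    emit(_random_dna(rng, spec.telomere_len))
    features.append(Feature("TEL_L", "telomere", 0, spec.telomere_len, "+"))
    truth_rows.append(dict(id="TEL_L", kind="telomere", start=0, end=spec.telomere_len,
                           strand="+"))

    for gi, b in enumerate(blocks):
        emit(_random_dna(rng, spec.intergenic_min + int(gap_extra[gi])))
        start = pos
        if b["kind"] == "ORF":
            cds, intron = b["cds"], b["intron"]
            if intron:
                off, iseq = intron
                genomic = cds[:off] + iseq + cds[off:]
            else:
                genomic = cds
            if b["strand"] == "-":
                genomic = revcomp(genomic)
            emit(genomic)
            attrs = {
                "essential": "yes" if b["essential"] else "no",
                "orf_class": b["orf_class"],
            }
            features.append(Feature(b["id"], "ORF", start, pos, b["strand"], attrs))
            if intron:
                off, iseq = intron
                if b["strand"] == "+":
                    i0 = start + off
                else:
                    i0 = pos - off - len(iseq)
                features.append(
                    Feature(
                        b["id"] + "_intron",
                        "intron",
                        i0,
                        i0 + len(iseq),
                        b["strand"],
                        {"Parent": b["id"]},
                    )
                )
            truth_rows.append(
                dict(
                    id=b["id"],
                    kind="ORF",
                    start=start,
                    end=pos,
                    strand=b["strand"],
                    essential=b["essential"],
                    orf_class=b["orf_class"],
                    stop_codon=b["stop"],
                    has_intron=bool(intron),
                    eligible_loxpsym=(not b["essential"]) and b["orf_class"] != "Dubious",
                )
            )
        else:
            emit(b["seq"])
            attrs = {}
            if b["kind"] == "tRNA":
                attrs["anticodon"] = b["anticodon"]
            features.append(Feature(b["id"], b["kind"], start, pos, b["strand"], attrs))
            truth_rows.append(
                dict(id=b["id"], kind=b["kind"], start=start, end=pos, strand=b["strand"],
                     anticodon=b.get("anticodon"))
            )

    emit(_random_dna(rng, spec.intergenic_min + int(gap_extra[-1])))
    # right telomere fills the remainder exactly
    tel_start = spec.length - spec.telomere_len
    assert pos == tel_start
    emit(_random_dna(rng, spec.telomere_len))
    features.append(Feature("TEL_R", "telomere", tel_start, spec.length, "+"))
    truth_rows.append(dict(id="TEL_R", kind="telomere", start=tel_start, end=spec.length,
                           strand="+"))

    genome = GenomeRecord(id=f"toychr_{spec.seed}", sequence="".join(seq_parts),
                          features=features)
    truth = pd.DataFrame(truth_rows)
    return genome, truth


def plant_junction_sites(
    genome: GenomeRecord,
    enzymes: dict[str, str],
    spacing: int = 10_000,
    clearance: int = 15_000,
) -> GenomeRecord:
    """Overwrite intergenic bases near every `spacing` mark with enzyme sites.

    Emulates a design whose chunk junctions were incorporated as unique
    restriction sites.  For each junction an enzyme is chosen (cycling
    through the list) whose recognition sequence does not already occur
    within ``clearance`` of the mark; the site is written into intergenic
    sequence as close to the mark as possible.
    """
    seq = list(genome.sequence)
    names = sorted(enzymes)
    # plant up to within one slack window of the chromosome end so the
    # planner always finds a junction wherever one is still required
    targets = list(range(spacing, genome.length - 1_999, spacing))
    for j, target in enumerate(targets, start=1):
        placed = False
        for k in range(len(names)):
            name = names[(j + k) % len(names)]
            site = enzymes[name]
            lo, hi = max(0, target - clearance), min(genome.length, target + clearance)
            region = "".join(seq[lo:hi])
            if site in region:
                # scrub natural occurrences (central-base flip) where they
                # fall in intergenic sequence; skip this enzyme otherwise
                occluded = False
                p = region.find(site)
                while p != -1:
                    a = lo + p
                    if any(f.overlaps(a, a + len(site)) for f in genome.features):
                        occluded = True
                        break
                    c = a + len(site) // 2
                    seq[c] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[c]]
                    p = region.find(site, p + 1)
                if occluded:
                    continue
                region = "".join(seq[lo:hi])
                if site in region:
                    continue
            # find an intergenic spot near the target
            for delta in range(0, 2000, 17):
                for p in (target + delta, target - delta):
                    if p < 0 or p + len(site) > genome.length:
                        continue
                    if any(f.overlaps(p, p + len(site)) for f in genome.features):
                        continue
                    seq[p : p + len(site)] = list(site)
                    placed = True
                    break
                if placed:
                    break
            if placed:
                break
        if not placed:
            raise GenerationError(f"could not plant a junction site near {target}")
    return GenomeRecord(id=genome.id, sequence="".join(seq),
                        features=[Feature(f.id, f.kind, f.start, f.end, f.strand, dict(f.attrs))
                                  for f in genome.features])


# ---------------------------------------------------------------------------
# Pooled fast/slow coverage simulation
# ---------------------------------------------------------------------------

@dataclass
class PoolSimSpec:
    """Bulk-segregant pooled-sequencing simulation parameters.

    ``selection_strength`` is the fraction of fast-pool genomes carrying the
    wild-type allele at the causal locus (1.0 = complete selection);
    ``linkage_decay`` is the distance over which allele skew relaxes
    linearly back to the unlinked expectation.
    """

    window: int = 1_000
    mean_depth: float = 100.0
    causal_interval: tuple[int, int] = (30_000, 33_000)
    selection_strength: float = 0.8
    linkage_decay: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.selection_strength <= 1.0:
            raise ValueError("selection_strength in [0,1]")


def _linkage_weight(centers: np.ndarray, causal: tuple[int, int], decay: float) -> np.ndarray:
    lo, hi = causal
    dist = np.where(centers < lo, lo - centers, np.where(centers >= hi, centers - hi + 1, 0))
    if decay == 0:
        return (dist == 0).astype(float)
    if not np.isfinite(decay):
        return np.ones_like(dist, dtype=float)
    return np.clip(1.0 - dist / decay, 0.0, 1.0)


def simulate_pool_coverage(
    genome: GenomeRecord, spec: PoolSimSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fast-pool and slow-pool depth tracks over a hybrid reference.

    Each returned track is a tiled window table with columns
    (start, end, depth, partition), where partition SYN_allele /WT_allele
    represents reads mapping to the synthetic vs wild-type version of each
    locus.  In the fast pool the synthetic allele is depleted at the causal
    locus (depth ≈ (1-s)·mean) and the wild-type allele enriched; the slow
    pool mirrors this.  Per-window depths are Poisson.
    """
    L = genome.length
    if spec.window > L:
        raise ValueError("window larger than chromosome")
    lo, hi = spec.causal_interval
    if not (0 <= lo < hi <= L):
        raise ValueError("causal interval outside chromosome")
    rng = np.random.default_rng(spec.seed)
    starts = np.arange(0, L, spec.window)
    ends = np.minimum(starts + spec.window, L)
    centers = (starts + ends) / 2.0
    g = _linkage_weight(centers, spec.causal_interval, spec.linkage_decay)
    s = spec.selection_strength

    frac = ends - starts
    scale = frac / spec.window  # short terminal window gets proportional depth

    def track(syn_mult: np.ndarray, wt_mult: np.ndarray) -> pd.DataFrame:
        syn = rng.poisson(np.maximum(spec.mean_depth * syn_mult * scale, 0.0))
        wt = rng.poisson(np.maximum(spec.mean_depth * wt_mult * scale, 0.0))
        return pd.DataFrame(
            {
                "start": np.concatenate([starts, starts]),
                "end": np.concatenate([ends, ends]),
                "depth": np.concatenate([syn, wt]).astype(float),
                "partition": ["SYN_allele"] * len(starts) + ["WT_allele"] * len(starts),
            }
        )

    fast = track(1.0 - s * g, 1.0 + s * g)
    slow = track(1.0 + s * g, 1.0 - s * g)
    return fast, slow


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

@dataclass
class QpcrSimParams:
    """Plate-simulation parameters; absent templates yield an empty Cq."""

    cq_mean: float = 22.0
    cq_sd: float = 0.5
    false_rate: float = 0.0  # probability an absent template still amplifies
    false_cq_mean: float = 30.0
    false_cq_sd: float = 2.0
    melt_sd: float = 0.15
    replicates: int = 1


def make_tag_manifest(n_tags: int, n_megachunks: int, seed: int = 0) -> pd.DataFrame:
    """Expected melt peaks and megachunk mapping for a panel of PCR tags."""
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_megachunks)]
    rows = []
    for i in range(n_tags):
        rows.append(
            dict(
                tag_id=f"tag{i + 1:04d}",
                megachunk=labels[i * n_megachunks // n_tags],
                melt_syn=round(float(rng.uniform(78, 88)), 2),
                melt_wt=round(float(rng.uniform(78, 88)), 2),
            )
        )
    return pd.DataFrame(rows)


def simulate_qpcr_table(
    truth: pd.DataFrame,
    params: QpcrSimParams | None = None,
    seed: int = 0,
    sample: str = "transformant1",
) -> pd.DataFrame:
    """Simulate a qPCR plate from per-tag SYN/WT presence truth.

    ``truth`` columns: tag_id, megachunk, melt_syn, melt_wt, syn_present,
    wt_present.  The plate includes, per tag and allele: replicate sample
    wells, one no-template-control well, and wells for the positive control
    (synthetic chunk DNA: SYN amplifies) and negative control (wild-type
    genomic DNA: WT amplifies).  Control wells are clean; the false-
    amplification rate applies to sample wells with absent template only.
    """
    params = params or QpcrSimParams()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    well = 0

    def add(samp: str, tag: str, allele: str, present: bool, melt_expect: float,
            is_ntc: bool = False, allow_false: bool = False) -> None:
        nonlocal well
        well += 1
        cq = np.nan
        melt = np.nan
        if present:
            cq = rng.normal(params.cq_mean, params.cq_sd)
            melt = melt_expect + rng.normal(0.0, params.melt_sd)
        elif allow_false and rng.random() < params.false_rate:
            cq = rng.normal(params.false_cq_mean, params.false_cq_sd)
            melt = melt_expect + rng.normal(0.0, params.melt_sd)
        rows.append(
            dict(well=f"W{well:04d}", sample=samp, tag_id=tag, allele=allele,
                 Cq=round(float(cq), 3) if np.isfinite(cq) else np.nan,
                 melt_c=round(float(melt), 3) if np.isfinite(melt) else np.nan,
                 is_ntc=is_ntc)
        )

    for r in truth.itertuples():
        for _ in range(params.replicates):
            add(sample, r.tag_id, "SYN", bool(r.syn_present), r.melt_syn, allow_false=True)
            add(sample, r.tag_id, "WT", bool(r.wt_present), r.melt_wt, allow_false=True)
        add("NTC", r.tag_id, "SYN", False, r.melt_syn, is_ntc=True)
        add("NTC", r.tag_id, "WT", False, r.melt_wt, is_ntc=True)
        add("POS_CTRL", r.tag_id, "SYN", True, r.melt_syn)
        add("POS_CTRL", r.tag_id, "WT", False, r.melt_wt)
        add("NEG_CTRL", r.tag_id, "SYN", False, r.melt_syn)
        add("NEG_CTRL", r.tag_id, "WT", True, r.melt_wt)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Propidium-iodide DNA-content histograms
# ---------------------------------------------------------------------------

@dataclass
class PiHistParams:
    """Fluorescence-histogram model: G1 mode position proportional to DNA
    content, G2 at twice G1, lognormal-ish peak widths, G1:G2 mixing."""

    scale: float = 100.0  # fluorescence units per haploid G1 complement
    cv: float = 0.07
    g1_fraction: float = 0.6
    n_cells: int = 20_000
    n_bins: int = 256
    max_fluor: float = 1_000.0


def simulate_pi_histogram(
    ploidy: int, params: PiHistParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate a PI DNA-content histogram (columns: bin_center, count)."""
    if ploidy not in (1, 2, 3, 4):
        raise ValueError("ploidy must be 1..4")
    params = params or PiHistParams()
    rng = np.random.default_rng(seed)
    g1_pos = ploidy * params.scale
    g2_pos = 2.0 * g1_pos
    n_g1 = int(round(params.n_cells * params.g1_fraction))
    n_g2 = params.n_cells - n_g1
    fluor = np.concatenate(
        [
            rng.normal(g1_pos, params.cv * g1_pos, size=n_g1),
            rng.normal(g2_pos, params.cv * g2_pos, size=n_g2),
        ]
    )
    counts, edges = np.histogram(fluor, bins=params.n_bins, range=(0.0, params.max_fluor))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame({"bin_center": centers, "count": counts})
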