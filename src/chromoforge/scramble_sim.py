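"""Cre-loxPsym SCRaMbLE simulation on polyploid synthetic/wild-type hybrids,
plus propidium-iodide DNA-content ploidy classification.

A cell's genome is a multiset of molecules; each molecule is an ordered
list of oriented segments delimited (on synthetic molecules only) by
loxPsym junctions.  Recombination between two junctions on one molecule
deletes or inverts the intervening segments with equal probability
(loxPsym is non-directional); recombination between junctions on two
molecules reciprocally exchanges the distal tails, so non-allelic exchange
between homologues yields one duplication- and one deletion-bearing
molecule.  A cell survives if at least one intact copy of every essential
segment remains anywhere in the cell — wild-type homologues therefore
buffer essential-gene loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from scipy.signal import find_peaks

from .genome_io import GenomeRecord


@dataclass(frozen=True)
class Segment:
    id: int
    essential: bool
    centromere: bool


@dataclass
class Molecule:
    """Ordered oriented segments; only synthetic molecules recombine."""

    segments: list[tuple[int, int]]  # (segment_id, orientation +1/-1)
    recombinable: bool

    @property
    def n_junctions(self) -> int:
        return max(0, len(self.segments) - 1) if self.recombinable else 0


@dataclass
class ScrambleGenome:
    reference: dict[int, Segment]
    molecules: list[Molecule]
    circles: list[list[tuple[int, int]]] = field(default_factory=list)

    def clone(self) -> "ScrambleGenome":
        return ScrambleGenome(
            self.reference,
            [Molecule(list(m.segments), m.recombinable) for m in self.molecules],
            [list(c) for c in self.circles],
        )

    def segment_multiset(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for m in self.molecules:
            for sid, _ in m.segments:
                counts[sid] = counts.get(sid, 0) + 1
        return counts


def build_scramble_genome(
    designed: GenomeRecord, ploidy: int, syn_mask: str
) -> ScrambleGenome:
    """One molecule per mask letter over the designed chromosome's segmentation.

    Synthetic (S) molecules are segmented at every loxpsym feature; wild-
    type (W) molecules carry the same segment ids but no recombinable
    junctions.  A segment is essential iff it contains at least one
    essential ORF; the centromere flag marks the segment containing the
    centromere feature.
    """
    if len(syn_mask) != ploidy:
        raise ValueError(f"mask {syn_mask!r} does not match ploidy {ploidy}")
    if set(syn_mask) - {"S", "W"}:
        raise ValueError("mask letters must be S or W")
    sites = sorted(f.start for f in designed.features_of_kind("loxpsym"))
    bounds = [0] + sites + [designed.length]
    reference: dict[int, Segment] = {}
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        essential = any(
            f.attrs.get("essential", "no").lower() in ("yes", "true", "1")
            and f.start < hi and lo < f.end
            for f in designed.features_of_kind("ORF")
        )
        cen = any(f.start < hi and lo < f.end
                  for f in designed.features_of_kind("centromere"))
        reference[i] = Segment(i, essential, cen)
    molecules = [
        Molecule([(i, +1) for i in range(len(bounds) - 1)], letter == "S")
        for letter in syn_mask
    ]
    return ScrambleGenome(reference, molecules)


@dataclass
class ScrambleParams:
    """Population-simulation parameters; λ is the mean recombination-event
    count per cell per induction (a free parameter, not a measured rate)."""

    event_rate: float = 2.0  # Poisson mean; ignored if fixed_events is set
    n_cells: int = 10_000
    seed: int = 0
    intermolecular_allowed: bool = True
    centromere_rule: str = "off"  # "off" | "strict"
    deletion_prob: float = 0.5  # vs inversion, intramolecular
    fixed_events: int | None = None
    keep_circles: bool = False

    def __post_init__(self) -> None:
        if self.event_rate < 0 or self.n_cells < 1:
            raise ValueError("event_rate >= 0 and n_cells >= 1 required")
        if self.centromere_rule not in ("off", "strict"):
            raise ValueError("centromere_rule must be 'off' or 'strict'")


Site = tuple[int, int]  # (molecule index, junction index 1..len(segments)-1)


def enumerate_sites(genome: ScrambleGenome) -> list[Site]:
    """All recombinable junctions, as (molecule, junction) pairs.

    Junction j of a molecule sits between segments j-1 and j (j >= 1).
    """
    sites: list[Site] = []
    for mi, m in enumerate(genome.molecules):
        if m.recombinable:
            sites.extend((mi, j) for j in range(1, len(m.segments)))
    return sites


def apply_event(
    genome: ScrambleGenome,
    site_a: Site,
    site_b: Site,
    rng: np.random.Generator,
    deletion_prob: float = 0.5,
    keep_circles: bool = False,
) -> ScrambleGenome:
    """Recombine two loxPsym junctions in place and return the genome.

    Same molecule: with probability ``deletion_prob`` the intervening
    segments are excised (as a lost — optionally recorded — circle),
    otherwise they are inverted with flipped orientations.  Different
    molecules: the tails distal to the two junctions are exchanged
    reciprocally.
    """
    (ma, ja), (mb, jb) = site_a, site_b
    mol_a, mol_b = genome.molecules[ma], genome.molecules[mb]
    if not (mol_a.recombinable and mol_b.recombinable):
        raise ValueError("recombination requires junctions on synthetic molecules")
    if ma == mb:
        j1, j2 = sorted((ja, jb))
        if j1 == j2:
            return genome
        segs = mol_a.segments
        if rng.random() < deletion_prob:
            excised = segs[j1:j2]
            mol_a.segments = segs[:j1] + segs[j2:]
            if keep_circles:
                genome.circles.append(excised)
        else:
            inverted = [(sid, -o) for sid, o in reversed(segs[j1:j2])]
            mol_a.segments = segs[:j1] + inverted + segs[j2:]
    else:
        tail_a = mol_a.segments[ja:]
        tail_b = mol_b.segments[jb:]
        mol_a.segments = mol_a.segments[:ja] + tail_b
        mol_b.segments = mol_b.segments[:jb] + tail_a
    return genome


def is_viable(genome: ScrambleGenome, centromere_rule: str = "off") -> bool:
    """Viable iff every essential segment survives with >= 1 copy cell-wide
    (and, under the strict rule, every molecule keeps exactly one centromere)."""
    counts = genome.segment_multiset()
    for seg in genome.reference.values():
        if seg.essential and counts.get(seg.id, 0) < 1:
            return False
    if centromere_rule == "strict":
        for m in genome.molecules:
            n_cen = sum(1 for sid, _ in m.segments if genome.reference[sid].centromere)
            if n_cen != 1:
                return False
    return True


def _wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def simulate_population(
    genome: ScrambleGenome, params: ScrambleParams | None = None
) -> dict:
    """SCRaMbLE a population of cells and score the surviving fraction.

    Per cell: event count ~ Poisson(λ) (or fixed), each event picks a
    uniform unordered pair of currently recombinable junctions
    (intermolecular pairs included when allowed) and applies it.  Returns
    viability fraction with a 95% Wilson CI and per-cell outcomes.
    """
    params = params or ScrambleParams()
    rng = np.random.default_rng(params.seed)
    outcomes = []
    n_viable = 0
    for _ in range(params.n_cells):
        cell = genome.clone()
        n_events = (
            params.fixed_events
            if params.fixed_events is not None
            else int(rng.poisson(params.event_rate))
        )
        applied = 0
        for _ in range(n_events):
            sites = enumerate_sites(cell)
            if params.intermolecular_allowed:
                pairs_exist = len(sites) >= 2
            else:
                pairs_exist = any(
                    sum(1 for s in sites if s[0] == mi) >= 2
                    for mi in range(len(cell.molecules))
                )
            if not pairs_exist:
                break
            while True:
                i, j = rng.integers(0, len(sites)), rng.integers(0, len(sites))
                if i == j:
                    continue
                a, b = sites[i], sites[j]
                if not params.intermolecular_allowed and a[0] != b[0]:
                    continue
                break
            apply_event(cell, a, b, rng, params.deletion_prob, params.keep_circles)
            applied += 1
        viable = is_viable(cell, params.centromere_rule)
        n_viable += viable
        outcomes.append(
            dict(events=applied, viable=viable,
                 n_segments=sum(len(m.segments) for m in cell.molecules))
        )
    frac = n_viable / params.n_cells
    lo, hi = _wilson_ci(n_viable, params.n_cells)
    return {
        "viability": frac,
        "ci_low": lo,
        "ci_high": hi,
        "n_cells": params.n_cells,
        "outcomes": pd.DataFrame(outcomes),
    }


# ---------------------------------------------------------------------------
# PI-histogram ploidy classification
# ---------------------------------------------------------------------------

def _g1_g2_modes(hist: pd.DataFrame) -> tuple[float, float]:
    """Positions of the two major fluorescence modes (G1 first)."""
    counts = hist["count"].values.astype(float)
    # light smoothing stabilizes peak calling on multinomial noise
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts, kernel, mode="same")
    peaks, props = find_peaks(smooth, height=smooth.max() * 0.2, distance=5)
    if len(peaks) < 2:
        raise ValueError("fewer than two discernible peaks in histogram")
    order = np.argsort(props["peak_heights"])[::-1][:2]
    top = np.sort(peaks[order])
    centers = hist["bin_center"].values
    return float(centers[top[0]]), float(centers[top[1]])


def classify_ploidy(
    histogram: pd.DataFrame,
    reference_haploid: pd.DataFrame,
    reference_diploid: pd.DataFrame,
    tolerance: float = 0.10,
) -> int | str:
    """Classify DNA content from a PI histogram against haploid/diploid references.

    The haploid reference's G1 peak estimates a 1n complement and its G2 a
    2n complement; the diploid G2 estimates 4n.  A sample whose G1 peak
    matches the diploid G2 is tetraploid; a G1 strictly between the diploid
    G1 and G2 peaks (outside tolerance of both) is triploid.  Returns 1-4,
    or "indeterminate" when no rule matches.
    """
    h1, _h2 = _g1_g2_modes(reference_haploid)
    d1, d2 = _g1_g2_modes(reference_diploid)
    try:
        g1, _ = _g1_g2_modes(histogram)
    except ValueError:
        return "indeterminate"

    def near(x: float, ref: float) -> bool:
        return abs(x - ref) <= tolerance * ref

    if near(g1, h1):
        return 1
    if near(g1, d1):
        return 2
    if near(g1, d2):
        return 4
    if d1 < g1 < d2:
        return 3
    return "indeterminate"
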