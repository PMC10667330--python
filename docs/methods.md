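# Methods

This note documents the models, parameter choices and numerical details
behind chromoforge, and what the synthetic fixtures do and do not
demonstrate.

## Genome model and edit ledger

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive. "Downstream" is always 3′ in the feature's own orientation.
Input FASTA is uppercased and restricted to A/C/G/T: the design edits are
codon arithmetic, and ambiguity codes would make synonymy undecidable.

The ledger is a sorted, non-overlapping list of insert/delete/substitute
edits in *native* coordinates, each tagged with a rationale. Applying a
ledger is a single left-to-right splice; the designed length is
`source_len + Σ(len(payload) − len(interval))` by construction. Position
liftover is monotone outside edited intervals; bases inside a deletion
(or beyond a substitute payload's extent) map to "deleted", and a native
base at an insert point maps *after* the payload, which makes
native→design→native a partial identity. Same-length substitutions map
positionally, so stop swaps and tag recodings are transparent to feature
liftover.

## Design rules

- **loxPsym.** The default 34-bp site is the standard Cre loxPsym
  (13-bp arms around the self-complementary spacer `ATGTACAT`); the
  constructor checks palindromicity unless overridden. Insertion point:
  `offset` (default 3) bases 3′ of the stop codon in gene orientation —
  on the minus strand that is `feature.start − offset` in chromosome
  coordinates. Eligibility: non-essential and verified/uncharacterized;
  dubious ORFs are spared. Insertions whose point falls inside another
  annotated feature are *skipped and logged*, not shifted: shifting would
  silently violate the 3-bp rule, skipping is auditable.
- **Stop swaps** apply to every verified/uncharacterized ORF ending TAG
  (essential ones included); dubious ORFs are untouched.
- **Telomere caps.** The cap constant is a TG-rich repeat written 5′→3′
  for the right chromosome end; the left end receives its reverse
  complement so both ends present the same outward-facing motif. The cap
  sequence is an overridable configuration default — placement, not
  sequence identity, is what the rules specify.
- **PCR tags.** Defaults: 24-bp tags (8 codons), amplicons of 200–500 bp,
  Tm target 58–62 °C by nearest-neighbor thermodynamics
  (Biopython `Tm_NN`, SantaLucia parameters), ≥ 8 mismatches per tag.
  These are conventional qPCR engineering numbers. Tag windows sit on
  codon boundaries, skip the start codon, exclude the stop (so stop swaps
  and tags can never collide), and are only placed in intron-free ORFs.
  Recoding picks, per codon, the synonymous codon with maximal Hamming
  distance (ties lexicographic); windows that cannot reach the mismatch
  floor (Met/Trp-rich stretches) or the Tm range are emitted with warning
  flags rather than dropped. Forbidden enzyme sites created by recoding
  are destroyed by substituting next-best synonymous codons.
- **Edit merge order.** Feature removal → intron removal → stop swap →
  tag recode → loxPsym insertion → telomere caps, all computed in the
  native frame and merged once; any cross-rationale overlap is a hard
  error, which the construction rules above make unreachable on valid
  annotations. Determinism over resolution cleverness.

`verify_design` re-derives everything it checks: ledger replay equals the
designed sequence; every surviving non-dubious ORF translates identically
pre/post design; no non-dubious designed ORF ends TAG; loxPsym features
equal loxPsym edits.

## Build planning

Chunks target 10 kb (5–12 kb hard range) with a ±2-kb slack window
searched around each running target; candidate junctions are enzyme-site
occurrences ranked by (intergenic preference, deviation from target) and
accepted only if the recognition site occurs exactly once across the
previous chunk plus the prospective next chunk; a final pass re-audits
uniqueness over each realized adjacent-chunk union. The planner finds
existing sites only — it does not recode junctions into existence. A
terminal remainder that no junction can bring into range is emitted short,
with a warning.

Megachunks group 4 chunks by default, upgrading to 5 to absorb remainders
of 1–2; a trailing remainder of 3 is kept short and warned rather than
inflating a megachunk past range. Labels run A, B, …; markers alternate
LEU2, URA3, … starting with LEU2, so each integration selects the new
marker while screening for loss of the previous one. Marker cassettes are
opaque placeholder sequences recorded as insert edits and plan-table
metadata but not spliced into chunk FASTA — emitted chunks carry their
downstream junction site duplicated at the 3′ end (the overlap a digest
regenerates), and collapsing each overlap once reconstructs the designed
chromosome bit-exactly. Keeping cassettes out of the chunk sequences is
what makes that reconstruction identity exact.

## Genotyping

Call thresholds Cq ≤ 35 and melt within 1.0 °C of the tag's expected peak
are conventional defaults (cycling conditions do not fix call thresholds);
both are exposed in `CallThresholds`. Expected melt peaks come from the
tag manifest, not from thermodynamic melt modeling. Replicate wells
aggregate by majority with ties treated as aberrant (conservative).
"Aberrant" is operationalized as: the tag's no-template control amplifies,
or its wrong-template control does (negative control for a synthetic tag,
positive control for a wild-type tag). Acceptance then needs every
informative synthetic tag amplified and no informative wild-type tag
amplified; a megachunk with no informative tags is indeterminate.

Relative expression validates efficiencies into (1, 2] — an efficiency of
exactly 1 would make the ratio degenerate, and > 2 is physically
impossible for PCR.

## Debugging

The pooled localizer compares *coverage*, not allele frequencies, because
pools are mapped against a hybrid synthetic+wild-type reference where each
locus appears twice; depleted synthetic coverage in the fast pool is the
defect signal and the enriched wild-type counterpart in the slow pool is
its reciprocal check. Window 1 kb, run length 3, log₂ threshold −1 are
engineering defaults. Tracks are normalized by their own median (robust to
depth differences between pools); a pseudocount of 0.01 on normalized
depth guards log₂(0), which matters precisely in the full-selection limit
where causal windows have zero reads.

Copy number is a ratio of window means with a percentile bootstrap CI
(1000 resamples). On Poisson fixtures at depth 100 with 50 target windows
the estimator recovers 4.0 ± 0.2 in ≥ 95% of seeds and is unbiased to
< 0.05 copies — the ratio-of-means bias at these depths is negligible.

Discrepancy classification is total by construction: every variant falls
through a precedence chain (duplication → missing loxPsym →
residual-TAG-stop → tag reversion → junction loss → nonsynonymous /
synonymous) and lands in exactly one class with a fixed severity map.
Duplications are critical: observed build practice is to actively repair
them. Coding indels are classified nonsynonymous (frame-breaking).
Observed-assembly input is aligned to the design with Biopython's
`PairwiseAligner` under affine gap penalties so a contiguous 34-bp site
loss surfaces as one deletion block, not scattered gaps. The minimal VCF
dialect is CHROM/POS/REF/ALT plus symbolic `<DEL>`/`<DUP>` with INFO END —
the smallest dialect expressing every discrepancy class.

Repair planning schedules every critical record in coordinate order and
bundles each non-critical record onto the nearest scheduled critical
within 5 kb; everything else is deferred. Sorting internally makes the
plan input-order independent and idempotent.

## tRNA array

Flank assignment is stable greedy matching over lexicographically ordered
tRNA ids: exact anticodon, then same decoded amino acid, then any unused
entry, with entries consumed in (donor, id) order — deterministic and, for
exact-anticodon matches on same-anticodon pools, maximal (verified against
exhaustive matching on small instances). Flanks are fixed at 500 bp (5′)
and 40 bp (3′). Scrubbing disrupts each unwanted 5′-flank motif with a
single central-base substitution, length-preserving, re-scanning until no
motif remains; the default motif list (TATA-like hexamers) stands in for
unpublished artefact lists and is configurable. Cassettes are laid out
rox + 5′ flank + intron-less tRNA + 3′ flank with a terminal rox (n + 1
rox sites for n tRNAs at the default spacing of one per gene); the rox
interval is configurable since the real spacing is not fixed by rule.

## SCRaMbLE simulation

Intramolecular events delete or invert with probability ½ each — loxPsym
is non-directional, so neither outcome is privileged; the split is a
parameter. Site pairs are uniform over unordered recombinable-junction
pairs; distance-dependent contact probability is out of scope. Excised
circles are lost by default (`keep_circles` records them but never
reintegrates). The event count per cell is Poisson(λ) with λ a free
parameter: measured viability percentages depend on biological rates the
simulator does not model, so only orderings (fewer events ⇒ more viable;
more wild-type homologues ⇒ more viable) are asserted, never absolute
percentages. Viability = every essential segment present ≥ once cell-wide;
`centromere_rule="strict"` additionally requires exactly one centromere
per molecule. Simulated viability agrees with an exhaustive
enumeration oracle within 3 binomial σ on genomes with ≤ 4 sites and
≤ 2 events.

Ploidy classification finds the two dominant histogram modes after a
3-bin moving-average smooth (`scipy.signal.find_peaks`, 20% height
floor). The haploid reference G1/G2 estimate 1n/2n and the diploid G2
estimates 4n; a sample G1 within 10% of the diploid G2 is tetraploid, and
one strictly between the diploid G1 and G2 (outside tolerance of both) is
triploid. Histograms that yield fewer than two peaks are indeterminate.

## Synthetic fixtures: what they emulate and what they do not

The toy chromosome packs stranded ORFs (intron-bearing, essential and
dubious subsets), tRNAs with anticodons, transposons, one centromere and
two telomeres into a requested length with ≥ 100-bp intergenic spacers —
enough structure to exercise every design rule, including both-strand
placement arithmetic. It does not model codon usage, overlapping genes,
repeats, or GC structure; passing tests show the *rules and bookkeeping*
are correct, not that the toolkit handles every pathology of a real
chromosome (overlapping ORFs in particular are resolved by skip-and-log,
not redesign). Pool coverage uses per-window Poisson depth with linear
linkage decay of allele skew — no GC or mappability bias, so localizer
recovery rates on fixtures are upper bounds. qPCR plates draw present
templates at Cq ~ N(22, 0.5) with on-target melts, encode "no
amplification" as an empty Cq (not Cq = 40, avoiding threshold
ambiguity), and apply the false-amplification rate only to test-sample
wells so control-driven exclusion and error-rate calibration can be
measured separately. PI histograms are two-Gaussian mixtures (CV 7%,
G1:G2 = 60:40) on a shared fluorescence scale — no sub-G1 debris, doublets
or S-phase plateau.

Test and acceptance problem sizes — 30–110 kb toy chromosomes, 1000
random ledger instances ≤ 10 kb, 100–200 seeded replicates for the
localizer/copy-number/classifier studies, 10⁴ cells for the buffering
comparison — were chosen as the smallest sizes at which the asserted
statistical margins (binomial 3σ, ≥ 95% recovery) are comfortably
separated from their thresholds.

## Known limitations

- The designer only *finds* restriction junctions; it cannot recode one
  into existence where none lies in the slack window.
- Discrepancy calling assumes variants are reported (or alignable) in
  design coordinates; structural rearrangements beyond symbolic
  DEL/DUP are out of scope.
- The SCRaMbLE model is segment-level: partial-segment damage,
  re-integration of excised circles and contact-distance effects are not
  modeled.
- Tag Tm targets are frequently unattainable for arbitrary fixture
  sequence composition; such tags carry warning flags and downstream code
  treats them as usable, which mirrors best-effort primer design but can
  overstate assay quality on extreme-GC windows.
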