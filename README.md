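# chromoforge

A toolkit for the computational side of building a synthetic yeast
chromosome: rule-driven redesign of a native chromosome with a verifiable
edit ledger, SwapIn-style chunk/megachunk build planning, PCR-tag qPCR
genotyping and efficiency-corrected expression analysis, sequencing-based
debugging (pooled fast/slow growth-defect localization, read-depth copy
number, design-vs-observed discrepancy classification and repair planning),
relocated tRNA-array design, and a Cre-loxPsym SCRaMbLE viability simulator
for polyploid synthetic/wild-type hybrids.

It is aimed at synthetic-genomics practitioners who want the design,
bookkeeping and debugging logic of an Sc2.0-style chromosome build as
testable, scriptable components, exercised end-to-end on seeded synthetic
fixtures rather than wet-lab data.

## The core models

**Design rules.** Given a native chromosome (FASTA + GFF3 with
`essential=yes|no` and `orf_class=Verified|Uncharacterized|Dubious`
attributes), the design engine emits an ordered ledger of edits:

- a 34-bp palindromic **loxPsym** site inserted exactly 3 bp downstream
  (3′ in gene orientation) of the stop codon of every non-essential
  verified/uncharacterized ORF (dubious ORFs are spared);
- **introns removed**, except an explicit retain list for stable introns;
- **TAG→TAA stop-codon swaps** on verified/uncharacterized ORFs, freeing
  the TAG codon;
- **tRNA and transposon deletion**, and native telomeres replaced with a
  synthetic cap;
- two **PCR tags** per taggable ORF: 24-bp windows on codon boundaries at
  the ends of a 200–500-bp amplicon, recoded by greedy most-different
  synonymous codon choice (protein invariant), so allele-specific primers
  distinguish synthetic from wild-type DNA.

Every edit is recorded in native coordinates; the designed sequence is
reproducible bit-exactly from native + ledger, and positions lift
monotonically between coordinate frames.

**Genotyping.** A megachunk integration is *accepted* iff every informative
synthetic tag amplifies and no informative wild-type tag does; tags whose
no-template or wrong-template control amplifies are excluded as aberrant.
Relative expression uses the efficiency-corrected ratio

```
ratio = E_t^(Cq_t,cal − Cq_t,test) / E_r^(Cq_r,cal − Cq_r,test)
```

with per-primer-pair efficiencies E ∈ (1, 2] (reducing to 2^−ΔΔCq at
E = 2).

**Debugging.** Pooled fast/slow-grower coverage over a hybrid
synthetic+wild-type reference is median-normalized per track; windows with
log₂(fast/slow) ≤ −1 in runs of ≥ 3 on the synthetic partition mark
candidate defect loci, cross-checked against the reciprocal wild-type
signal. Copy number is `baseline_copies × mean depth(target) / mean
depth(baseline)` with a bootstrap CI. Observed-vs-design variants are
classified as critical (residual TAG stops in verified ORFs, nonsynonymous
changes, duplications) or non-critical (missing loxPsym/PCR-tag/restriction
sites, synonymous changes); repairs schedule all criticals and bundle
non-criticals within 5 kb.

**SCRaMbLE.** A cell is a multiset of molecules of oriented segments
delimited by loxPsym junctions (wild-type molecules carry none).
Intramolecular recombination deletes or inverts the intervening segments
with equal probability; intermolecular recombination exchanges distal
tails. A cell survives iff every essential segment retains ≥ 1 intact copy
cell-wide, which is why wild-type homologues in WS/WSSS hybrids buffer
viability.

## Worked example

```
$ python -c "
from chromoforge.fixtures import ToyChromosomeSpec, make_toy_chromosome
from chromoforge.genome_io import save_genome
g, t = make_toy_chromosome(ToyChromosomeSpec(seed=12))
save_genome(g, 'native.fasta', 'native.gff3')"

$ chromoforge design --fasta native.fasta --gff native.gff3 --out-prefix synchr
designed 58638 bp from 60000 bp (2.27% reduction)
```

The summary (`synchr.summary.tsv`) reports the edit census: 17 loxPsym
insertions (one per eligible non-essential ORF), 2 intron removals, 6
TAG→TAA stop swaps, 5 tRNA/transposon deletions, 34 PCR-tag recodings (17
tag pairs, 68 tag sequences counting wild-type and synthetic alleles), and
2 telomere caps — a 1,362-bp (2.27%) size reduction. `synchr.ledger.json`
replays those edits onto the native sequence to reproduce `synchr.fasta`
bit-exactly.

SCRaMbLE-ing hybrids of this design shows the ploidy buffering effect:

```
$ chromoforge scramble --design-fasta synchr.fasta --design-gff synchr.gff3 \
    --mask S --rate 2.0 --cells 5000 --seed 1 --out outcomes.tsv
viability 0.757 [0.745,0.768] over 5000 cells
$ chromoforge scramble ... --mask WSSS ...
viability 1.000 [0.999,1.000] over 5000 cells
```

A haploid synthetic chromosome loses essential segments in ~24% of cells
at two events per cell, while a tetraploid with one wild-type homologue
survives essentially always — the wild-type copy supplies every essential
segment.

## Layout

- `src/chromoforge/genome_io.py` — genome/feature model, FASTA+GFF3 I/O,
  edit ledger, coordinate liftover
- `src/chromoforge/fixtures.py` — seeded generators for every input
- `src/chromoforge/design_engine.py` — design rules and verification
- `src/chromoforge/assembly_planner.py` — chunk/megachunk build planning
- `src/chromoforge/genotyping_qpcr.py` — tag calling, acceptance, expression
- `src/chromoforge/debug_suite.py` — localization, copy number,
  discrepancies, repairs
- `src/chromoforge/trna_array.py` — relocated tRNA array design
- `src/chromoforge/scramble_sim.py` — SCRaMbLE simulation, ploidy calls
- `src/chromoforge/cli.py` — `chromoforge` command group

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
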