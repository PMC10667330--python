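"""Design rules: loxPsym placement, intron removal, stop swaps, removals,
telomere caps, PCR-tag recoding, and whole-design verification."""

import numpy as np
import pytest

from chromoforge.design_engine import (
    DesignPolicy,
    LOXPSYM,
    apply_design,
    cap_telomeres,
    insert_loxpsym_sites,
    most_different_codon,
    orf_stop_codon,
    recode_pcrtags,
    remove_features,
    remove_introns,
    size_reduction_percent,
    swap_stop_codons,
    verify_design,
)
from chromoforge.genome_io import (
    DesignLedger, Feature, GenomeRecord, revcomp, translate_cds,
)
from chromoforge.fixtures import ToyChromosomeSpec, make_toy_chromosome
from conftest import random_dna


def _orf_genome(cds: str, strand: str = "+", attrs: dict | None = None) -> GenomeRecord:
    rng = np.random.default_rng(0)
    flank = random_dna(rng, 100)
    flank2 = random_dna(rng, 100)
    body = revcomp(cds) if strand == "-" else cds
    attrs = attrs or {"essential": "no", "orf_class": "Verified"}
    return GenomeRecord(
        "c", flank + body + flank2,
        [Feature("orf1", "ORF", 100, 100 + len(cds), strand, attrs)],
    )


def test_loxpsym_is_palindromic():
    assert revcomp(LOXPSYM) == LOXPSYM and len(LOXPSYM) == 34


def test_loxpsym_insertion_point_plus_strand():
    g = _orf_genome("ATG" + "GCT" * 80 + "TAA")
    edits = insert_loxpsym_sites(g, DesignPolicy())
    orf = g.feature_by_id("orf1")
    assert len(edits) == 1
    assert edits[0].op == "insert"
    assert edits[0].start == orf.end + 3


def test_loxpsym_insertion_point_minus_strand():
    g = _orf_genome("ATG" + "GCT" * 80 + "TAA", strand="-")
    edits = insert_loxpsym_sites(g, DesignPolicy())
    orf = g.feature_by_id("orf1")
    assert len(edits) == 1
    assert edits[0].start == orf.start - 3


def test_essential_and_dubious_orfs_get_no_loxpsym():
    for attrs in ({"essential": "yes", "orf_class": "Verified"},
                  {"essential": "no", "orf_class": "Dubious"}):
        g = _orf_genome("ATG" + "GCT" * 80 + "TAA", attrs=attrs)
        assert insert_loxpsym_sites(g, DesignPolicy()) == []


def test_loxpsym_collision_skipped():
    cds = "ATG" + "GCT" * 80 + "TAA"
    g = _orf_genome(cds)
    orf = g.feature_by_id("orf1")
    blocker = Feature("blk", "motif", orf.end + 1, orf.end + 20, "+")
    g = GenomeRecord(g.id, g.sequence, g.features + [blocker])
    assert insert_loxpsym_sites(g, DesignPolicy()) == []


def test_loxpsym_count_matches_truth_table(designed_toy):
    genome, truth, designed, ledger, summary = designed_toy
    expected = int(truth[truth["kind"] == "ORF"]["eligible_loxpsym"].sum())
    assert summary["counts"]["loxpsym"] == expected


def test_intron_retention_and_protein_identity():
    rng = np.random.default_rng(3)
    spec = ToyChromosomeSpec(n_introns=3, seed=3)
    g, truth = make_toy_chromosome(spec)
    introns = g.features_of_kind("intron")
    assert len(introns) == 3
    retained = introns[0].id
    edits = remove_introns(g, retain_ids=[retained])
    assert len(edits) == 2
    assert all(e.note != retained for e in edits)
    # protein identity pre/post excision for the edited parents
    led = DesignLedger(g.id, "x", edits)
    out = led.apply(g.sequence)
    for intron in introns[1:]:
        parent = g.feature_by_id(intron.attrs["Parent"])
        prot_before = translate_cds(g.orf_cds(parent))
        from chromoforge.genome_io import lift_interval
        s, e = lift_interval(led, parent.start, parent.end)
        lifted = GenomeRecord("x", out, [Feature(parent.id, "ORF", s, e, parent.strand,
                                                 dict(parent.attrs))])
        prot_after = translate_cds(lifted.orf_cds(lifted.feature_by_id(parent.id)))
        assert prot_before == prot_after


def test_no_introns_empty_edit_list():
    g = _orf_genome("ATG" + "GCT" * 80 + "TAA")
    assert remove_introns(g) == []


@pytest.mark.parametrize(
    "stop,strand,expect_edit",
    [("TAG", "+", True), ("TAG", "-", True), ("TGA", "+", False), ("TAA", "+", False)],
)
def test_stop_swap_rules(stop, strand, expect_edit):
    g = _orf_genome("ATG" + "GCT" * 80 + stop, strand=strand)
    edits = swap_stop_codons(g, DesignPolicy())
    if not expect_edit:
        assert edits == []
        return
    assert len(edits) == 1
    payload = edits[0].payload
    assert (revcomp(payload) if strand == "-" else payload) == "TAA"
    # applying the edit leaves a TAA stop in gene orientation
    led = DesignLedger("c", "x", edits)
    out = led.apply(g.sequence)
    lifted = GenomeRecord("x", out, [Feature("orf1", "ORF", 100, 100 + 246, strand)])
    assert orf_stop_codon(lifted, lifted.feature_by_id("orf1")) == "TAA"


def test_dubious_orf_stop_untouched():
    g = _orf_genome("ATG" + "GCT" * 80 + "TAG",
                    attrs={"essential": "no", "orf_class": "Dubious"})
    assert swap_stop_codons(g, DesignPolicy()) == []


def test_remove_features_counts_and_net_delta(toy):
    genome, truth = toy
    edits = remove_features(genome, ["tRNA", "transposon"])
    n_expected = len(genome.features_of_kind("tRNA", "transposon"))
    assert len(edits) == n_expected
    total = sum(f.length for f in genome.features_of_kind("tRNA", "transposon"))
    assert sum(e.delta for e in edits) == -total
    only_trna = remove_features(genome, ["tRNA"])
    assert len(only_trna) == len(genome.features_of_kind("tRNA"))


def test_telomere_caps_outward_motifs(toy):
    genome, _ = toy
    cap = "TGTGGGTGTGGTG" * 3
    edits = cap_telomeres(genome, cap)
    assert len(edits) == 2
    led = DesignLedger(genome.id, "x", edits)
    out = led.apply(genome.sequence)
    assert out.startswith(revcomp(cap))
    assert out.endswith(cap)


def test_most_different_codon_properties():
    # synonymy preserved, distance maximal among synonyms
    assert most_different_codon("ATG") == "ATG"  # Met: single codon
    assert most_different_codon("TGG") == "TGG"  # Trp
    alt = most_different_codon("CTG")  # Leu has six codons
    assert alt != "CTG"
    assert translate_cds(alt) == translate_cds("CTG")


def test_pcrtag_synonymy_and_mismatch_floor():
    rng = np.random.default_rng(5)
    codons = [c for c in ("".join(x) for x in zip(*[iter(random_dna(rng, 999))]*3))]
    cds = "ATG" + "".join(c for c in codons if c not in ("TAA", "TAG", "TGA"))[:330 * 3 - 6] + "TAA"
    cds = cds[: (len(cds) // 3) * 3]
    g = _orf_genome(cds)
    edits, pairs = recode_pcrtags(g)
    assert len(pairs) == 2
    for p in pairs:
        assert translate_cds(p.wt_seq) == translate_cds(p.syn_seq)
        assert sum(a != b for a, b in zip(p.wt_seq, p.syn_seq)) == p.mismatches
        assert p.mismatches >= 8 or "min_mismatches_unreached" in p.warnings


def test_pcrtag_minus_strand_payload_orientation():
    cds = "ATG" + "GAA" * 120 + "TAA"
    g = _orf_genome(cds, strand="-")
    edits, pairs = recode_pcrtags(g)
    led = DesignLedger("c", "x", edits)
    out = led.apply(g.sequence)
    for p, e in zip(pairs, edits):
        assert revcomp(e.payload) == p.syn_seq
    # recoded gene still translates identically
    orf = g.feature_by_id("orf1")
    new_cds = revcomp(out[orf.start : orf.end])
    assert translate_cds(new_cds) == translate_cds(cds)


def test_apply_design_empty_policy_is_identity():
    from chromoforge.design_engine import PcrTagParams

    g = _orf_genome("ATG" + "GCT" * 80 + "TAG")
    policy = DesignPolicy(
        loxpsym_classes=(), stop_swap={}, remove_kinds=(),
        pcrtag=PcrTagParams(amplicon_range=(600_000, 600_300)),
    )
    designed, ledger, summary = apply_design(g, policy)
    assert ledger.edits == []
    assert designed.sequence == g.sequence


def test_apply_design_summary_counts_match_truth(designed_toy):
    genome, truth, designed, ledger, summary = designed_toy
    orfs = truth[truth["kind"] == "ORF"]
    assert summary["counts"]["loxpsym"] == int(orfs["eligible_loxpsym"].sum())
    assert summary["counts"]["intron_removal"] == int(orfs["has_intron"].sum())
    n_tag_stops = int(
        ((orfs["stop_codon"] == "TAG") & (orfs["orf_class"] != "Dubious")).sum()
    )
    assert summary["counts"]["stop_swap"] == n_tag_stops
    n_removals = len(truth[truth["kind"].isin(["tRNA", "transposon"])])
    assert summary["counts"]["feature_removal"] == n_removals
    assert summary["net_delta"] == ledger.net_delta
    assert summary["n_pcrtag_sequences"] == 2 * summary["n_pcrtag_pairs"]


def test_size_reduction_percent_basic():
    assert size_reduction_percent(1000, 900) == pytest.approx(10.0)


def test_verify_design_passes_on_engine_output(designed_toy):
    genome, _, designed, ledger, _ = designed_toy
    report = verify_design(genome, designed, ledger)
    assert report["ok"], report


def test_verify_design_detects_flipped_base(designed_toy):
    genome, _, designed, ledger, _ = designed_toy
    orf = next(f for f in designed.features_of_kind("ORF")
               if f.attrs.get("orf_class") == "Verified")
    mid = (orf.start + orf.end) // 2
    mid -= (mid - orf.start) % 3  # hit a first codon position for a sure AA change
    seq = designed.sequence
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[mid]]
    broken = GenomeRecord(designed.id, seq[:mid] + flip + seq[mid + 1 :],
                          [Feature(f.id, f.kind, f.start, f.end, f.strand, dict(f.attrs))
                           for f in designed.features])
    report = verify_design(genome, broken, ledger)
    assert not report["ok"]
    assert not report["sequence_reproducible"]["ok"] or \
        not report["protein_conservation"]["ok"]


def test_protein_conservation_over_random_fixtures():
    for seed in range(8):
        g, truth = make_toy_chromosome(ToyChromosomeSpec(length=40_000, n_orfs=12, seed=seed))
        designed, ledger, _ = apply_design(g)
        report = verify_design(g, designed, ledger)
        assert report["ok"], (seed, report)
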