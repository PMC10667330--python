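"""Defect localization, copy-number estimation, discrepancy classification
and repair planning."""

import numpy as np
import pandas as pd
import pytest

from chromoforge.debug_suite import (
    DiscrepancyRecord,
    LocalizeParams,
    SEVERITY,
    Variant,
    classify_discrepancies,
    estimate_copy_number,
    localize_defect,
    plan_repairs,
    read_bedgraph,
    read_minimal_vcf,
    variants_from_observed_fasta,
    write_bedgraph,
)
from chromoforge.fixtures import PoolSimSpec, simulate_pool_coverage
from chromoforge.genome_io import Feature, GenomeRecord, revcomp
from conftest import random_dna


# ---------------------------------------------------------------------------
# localizer
# ---------------------------------------------------------------------------

def _flat_track(n_windows=60, depth=100.0, window=1000):
    starts = np.arange(0, n_windows * window, window)
    return pd.DataFrame(
        {
            "start": np.concatenate([starts, starts]),
            "end": np.concatenate([starts + window, starts + window]),
            "depth": depth,
            "partition": ["SYN_allele"] * n_windows + ["WT_allele"] * n_windows,
        }
    )


def test_identical_tracks_no_candidates():
    t = _flat_track()
    assert localize_defect(t, t.copy()) == []


def test_full_selection_zero_decay_pinpoints_causal_windows(toy):
    genome, _ = toy
    causal = (30_000, 33_000)
    spec = PoolSimSpec(selection_strength=1.0, linkage_decay=0.0,
                       causal_interval=causal, seed=13)
    fast, slow = simulate_pool_coverage(genome, spec)
    cands = localize_defect(fast, slow)
    assert len(cands) == 1
    assert (cands[0].start, cands[0].end) == causal
    assert cands[0].reciprocal_support


def test_zero_median_track_errors():
    t = _flat_track(depth=0.0)
    with pytest.raises(ValueError):
        localize_defect(t, t.copy())


def test_localizer_reports_megachunk_labels(toy):
    genome, _ = toy
    spec = PoolSimSpec(selection_strength=1.0, linkage_decay=0.0,
                       causal_interval=(30_000, 33_000), seed=14)
    fast, slow = simulate_pool_coverage(genome, spec)
    mega = pd.DataFrame({"megachunk": ["A", "B"], "start": [0, 30_000],
                         "end": [30_000, 60_000]})
    cands = localize_defect(fast, slow, megachunk_table=mega)
    assert cands[0].megachunks == ("B",)


def test_bedgraph_round_trip(tmp_path):
    t = _flat_track(n_windows=10)
    write_bedgraph(t, tmp_path / "t.bedgraph")
    back = read_bedgraph(tmp_path / "t.bedgraph")
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True),
        t[["start", "end", "depth", "partition"]].reset_index(drop=True),
        check_dtype=False,
    )


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def test_copy_number_simple_ratio():
    track = pd.DataFrame({
        "start": np.arange(0, 20_000, 1_000),
        "end": np.arange(1_000, 21_000, 1_000),
        "depth": [200.0] * 10 + [50.0] * 10,
        "partition": "SYN_allele",
    })
    est = estimate_copy_number(track, (0, 10_000), [(10_000, 20_000)])
    assert est.copies == pytest.approx(4.0)


def test_copy_number_target_equals_baseline_is_one():
    track = pd.DataFrame({
        "start": np.arange(0, 10_000, 1_000),
        "end": np.arange(1_000, 11_000, 1_000),
        "depth": 80.0,
        "partition": "SYN_allele",
    })
    est = estimate_copy_number(track, (0, 10_000), [(0, 10_000)])
    assert est.copies == pytest.approx(1.0)
    assert est.ci_low <= 1.0 <= est.ci_high


def test_copy_number_empty_interval_errors():
    track = _flat_track(n_windows=5)
    with pytest.raises(ValueError):
        estimate_copy_number(track, (100_000, 101_000), [(0, 1_000)])


# ---------------------------------------------------------------------------
# discrepancy classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def design_for_classify(designed_toy):
    genome, truth, designed, ledger, summary = designed_toy
    return designed, summary["tag_pairs"]


def _stop_tag_variant(designed):
    """A variant flipping a verified plus-strand ORF's TAA stop back to TAG."""
    for orf in designed.features_of_kind("ORF"):
        if orf.attrs.get("orf_class") != "Verified" or orf.strand != "+":
            continue
        stop = designed.sequence[orf.end - 3 : orf.end]
        if stop == "TAA":
            return Variant(orf.end - 3, "TAA", "TAG"), orf
    raise AssertionError("fixture lacks a usable verified ORF")


def test_residual_tag_stop_is_critical(design_for_classify):
    designed, pairs = design_for_classify
    v, orf = _stop_tag_variant(designed)
    recs = classify_discrepancies(designed, [v], tag_pairs=pairs)
    assert recs[0].klass == "residual_TAG_stop"
    assert recs[0].severity == "critical"


def test_loxpsym_deletion_noncritical(design_for_classify):
    designed, pairs = design_for_classify
    site = designed.features_of_kind("loxpsym")[0]
    v = Variant(site.start, designed.sequence[site.start : site.end], "<DEL>",
                end=site.end)
    recs = classify_discrepancies(designed, [v], tag_pairs=pairs)
    assert recs[0].klass == "missing_loxpsym"
    assert recs[0].severity == "noncritical"


def test_nonsynonymous_vs_synonymous(design_for_classify):
    designed, pairs = design_for_classify
    tag_spans = [(f.start, f.end) for f in designed.features_of_kind("pcrtag")]
    orf = next(f for f in designed.features_of_kind("ORF")
               if f.strand == "+" and f.attrs.get("orf_class") == "Verified")
    # middle codon outside any tag window
    for ci in range(10, orf.length // 3 - 10):
        p = orf.start + ci * 3
        if not any(s <= p < e or s < p + 3 <= e for s, e in tag_spans):
            break
    codon = designed.sequence[p : p + 3]
    # first position flip: near-certain amino-acid change
    ns = Variant(p, codon[0], {"A": "C", "C": "A", "G": "T", "T": "G"}[codon[0]])
    recs = classify_discrepancies(designed, [ns], tag_pairs=pairs)
    assert recs[0].klass in ("nonsynonymous", "synonymous_other")
    assert SEVERITY[recs[0].klass] == recs[0].severity
    # wobble-position synonymous change where possible
    from chromoforge.design_engine import SYNONYMS
    for alt in SYNONYMS.get(codon, []):
        if alt != codon and alt[:2] == codon[:2]:
            syn = Variant(p + 2, codon[2], alt[2])
            recs = classify_discrepancies(designed, [syn], tag_pairs=pairs)
            assert recs[0].klass == "synonymous_other"
            break


def test_pcrtag_reversion_noncritical(design_for_classify):
    designed, pairs = design_for_classify
    pair = next(p for p in pairs if p.mismatches >= 2 and p.strand == "+")
    feat = next(f for f in designed.features_of_kind("pcrtag")
                if f.attrs.get("orf_tag") == f"{pair.orf_id}.{pair.tag_index}")
    win = designed.sequence[feat.start : feat.end]
    k = next(i for i, (a, b) in enumerate(zip(win, pair.wt_seq)) if a != b)
    v = Variant(feat.start + k, win[k], pair.wt_seq[k])
    recs = classify_discrepancies(designed, [v], tag_pairs=pairs)
    assert recs[0].klass == "missing_pcrtag"
    assert recs[0].severity == "noncritical"


def test_duplication_symbolic_and_cn_interval(design_for_classify):
    designed, pairs = design_for_classify
    v = Variant(5_000, "N", "<DUP>", end=9_000)
    recs = classify_discrepancies(designed, [v])
    assert recs[0].klass == "duplication" and recs[0].severity == "critical"
    v2 = Variant(5_500, designed.sequence[5_500], designed.sequence[5_500])
    recs = classify_discrepancies(designed, [v2], duplication_intervals=[(5_000, 9_000)])
    assert recs[0].klass == "duplication"


def test_junction_site_loss(design_for_classify):
    designed, pairs = design_for_classify
    site = "GCGGCCGC"
    seq = designed.sequence[:20_000] + site + designed.sequence[20_000 + 8:]
    with_site = GenomeRecord(designed.id, seq,
                             [Feature(f.id, f.kind, f.start, f.end, f.strand, dict(f.attrs))
                              for f in designed.features
                              if not f.overlaps(20_000, 20_008)])
    v = Variant(20_003, seq[20_003], "A" if seq[20_003] != "A" else "T")
    recs = classify_discrepancies(with_site, [v], junction_sites=[(20_000, site)])
    assert recs[0].klass == "missing_restriction_site"


def test_classification_totality(design_for_classify):
    """Every random variant receives exactly one class with mapped severity."""
    designed, pairs = design_for_classify
    rng = np.random.default_rng(21)
    variants = []
    for _ in range(120):
        p = int(rng.integers(0, designed.length - 3))
        ref = designed.sequence[p]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            alt = revcomp(ref)
        variants.append(Variant(p, ref, alt))
    recs = classify_discrepancies(designed, variants, tag_pairs=pairs)
    assert len(recs) == len(variants)
    for r in recs:
        assert r.klass in SEVERITY
        assert r.severity == SEVERITY[r.klass]


def test_variant_outside_chromosome_errors(design_for_classify):
    designed, _ = design_for_classify
    with pytest.raises(ValueError):
        classify_discrepancies(designed, [Variant(designed.length + 50, "A", "T")])


def test_variants_from_observed_fasta():
    rng = np.random.default_rng(22)
    design = random_dna(rng, 2_000)
    observed = design[:500] + ("G" if design[500] != "G" else "C") + design[501:]
    observed = observed[:1_200] + observed[1_234:]  # 34-base deletion
    variants = variants_from_observed_fasta(design, observed)
    kinds = {(v.pos, v.alt) for v in variants}
    assert any(v.pos == 500 and len(v.ref) == 1 == len(v.alt) for v in variants)
    assert any(v.alt == "<DEL>" and v.span[1] - v.span[0] == 34 for v in variants)


def test_read_minimal_vcf(tmp_path):
    p = tmp_path / "v.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr\t101\t.\tTAA\tTAG\t.\t.\t.\n"
        "chr\t501\t.\tN\t<DEL>\t.\t.\tEND=534\n"
    )
    vs = read_minimal_vcf(p)
    assert vs[0].pos == 100 and vs[0].alt == "TAG"
    assert vs[1].is_symbolic and vs[1].span == (500, 534)


# ---------------------------------------------------------------------------
# repair planning
# ---------------------------------------------------------------------------

def _rec(pos, klass):
    return DiscrepancyRecord(pos, klass, SEVERITY[klass])


def test_bundling_by_proximity():
    crit = _rec(10_000, "residual_TAG_stop")
    near = _rec(12_000, "missing_loxpsym")
    far = _rec(40_000, "missing_pcrtag")
    plan = plan_repairs([near, far, crit], bundle_distance=5_000)
    assert len(plan.scheduled) == 1
    assert plan.scheduled[0].bundled == [near]
    assert plan.deferred == [far]


def test_only_noncritical_all_deferred():
    recs = [_rec(1_000, "missing_loxpsym"), _rec(2_000, "synonymous_other")]
    plan = plan_repairs(recs)
    assert plan.scheduled == []
    assert len(plan.deferred) == 2


def test_bundling_order_independent_and_idempotent():
    rng = np.random.default_rng(23)
    recs = [_rec(int(rng.integers(0, 100_000)),
                 ["residual_TAG_stop", "nonsynonymous", "missing_loxpsym",
                  "missing_pcrtag", "synonymous_other"][int(rng.integers(0, 5))])
            for _ in range(40)]

    def signature(plan):
        return (
            [(it.position, it.critical.klass,
              tuple((b.position, b.klass) for b in it.bundled))
             for it in plan.scheduled],
            [(d.position, d.klass) for d in plan.deferred],
        )

    base = signature(plan_repairs(recs))
    for _ in range(5):
        perm = [recs[i] for i in rng.permutation(len(recs))]
        assert signature(plan_repairs(perm)) == base
    # idempotence: re-planning scheduled + deferred reproduces the plan
    plan = plan_repairs(recs)
    flat = [it.critical for it in plan.scheduled] + \
           [b for it in plan.scheduled for b in it.bundled] + plan.deferred
    assert signature(plan_repairs(flat)) == base
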