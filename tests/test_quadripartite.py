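import numpy as np
import pandas as pd
import pytest

from conftest import SMALL, build_quadripartite_sequence, random_sequence
from plastome_compare.io import GeneFeature, PlastomeRecord, revcomp
from plastome_compare.quadripartite import (
    NoInvertedRepeatError,
    QuadripartitePartition,
    canonicalize,
    detect_inverted_repeat,
    gc_fraction,
    gene_census,
    range_summary,
    region_profiles,
    summarize_panel,
)


def test_detection_recovers_constructed_coordinates():
    rng = np.random.default_rng(11)
    seq = build_quadripartite_sequence(rng, lsc_len=8000, ir_len=2000, ssc_len=1500)
    rec = PlastomeRecord("C1", "constructed", seq)
    part = detect_inverted_repeat(rec, min_ir_len=1000)
    assert (part.lsc_len, part.ir_len, part.ssc_len) == (8000, 2000, 1500)
    assert part.offset == 0
    assert part.genome_length == len(seq)


def test_detection_is_rotation_invariant():
    rng = np.random.default_rng(12)
    seq = build_quadripartite_sequence(rng)
    rec = PlastomeRecord("C1", "constructed", seq)
    base = detect_inverted_repeat(rec)
    n = len(seq)
    for shift in (1, 137, 5000, n - 3):
        rot = rec.rotated(shift)
        part = detect_inverted_repeat(rot)
        assert (part.lsc_len, part.ir_len, part.ssc_len) == (
            base.lsc_len, base.ir_len, base.ssc_len)
        # canonical linearization is identical whatever the input rotation
        canon, _ = canonicalize(rot, part)
        assert canon.sequence == canonicalize(rec, base)[0].sequence


def test_ir_self_consistency_and_tiling(small_panel):
    for rec in small_panel.records:
        part = detect_inverted_repeat(rec)
        canon, cpart = canonicalize(rec, part)
        assert cpart.genome_length == len(rec)
        irb = canon.sequence[slice(*cpart.irb)]
        ira = canon.sequence[slice(*cpart.ira)]
        assert revcomp(irb) == ira


def test_no_inverted_repeat_raises():
    rng = np.random.default_rng(13)
    rec = PlastomeRecord("R1", "random", random_sequence(rng, 10_000))
    with pytest.raises(NoInvertedRepeatError):
        detect_inverted_repeat(rec, min_ir_len=1000)


def test_mismatch_tolerant_extension_recovers_degraded_boundary():
    rng = np.random.default_rng(14)
    seq = build_quadripartite_sequence(rng, lsc_len=6000, ir_len=2000, ssc_len=1200)
    # degrade one base inside the IRb copy near its start: the exact core
    # shrinks, a 1-mismatch search restores the full repeat span
    pos = 6000 + 50
    seq = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
    rec = PlastomeRecord("D1", "degraded", seq)
    exact = detect_inverted_repeat(rec, min_ir_len=1000, max_mismatch=0)
    assert exact.ir_len == 2000 - 51
    relaxed = detect_inverted_repeat(rec, min_ir_len=1000, max_mismatch=1)
    assert relaxed.ir_len == 2000


def test_gc_fraction_counts_and_excludes_ambiguity():
    assert gc_fraction("GCGC") == 1.0
    assert gc_fraction("ATATN") == 0.0
    rng = np.random.default_rng(15)
    seq = "".join(rng.choice(list("ACGTN"), size=1000))
    expected = sum(seq.count(c) for c in "GC") / sum(seq.count(c) for c in "ACGT")
    assert gc_fraction(seq) == pytest.approx(expected)


def test_region_profiles_match_direct_counting(small_panel):
    rec = small_panel.records[0]
    part = detect_inverted_repeat(rec)
    canon, cpart = canonicalize(rec, part)
    profiles = {p.region: p for p in region_profiles(rec, part)}
    assert profiles["LSC"].length == cpart.lsc_len
    for label, bounds in (("LSC", cpart.lsc), ("SSC", cpart.ssc), ("IR", cpart.irb)):
        sub = canon.sequence[slice(*bounds)]
        assert profiles[label].gc == pytest.approx(
            sum(sub.count(c) for c in "GC") / len(sub))
    assert profiles["total"].length == len(rec)


def _toy_record():
    """Genes A,B in LSC; C in SSC; D duplicated in both IRs."""
    rng = np.random.default_rng(16)
    seq = build_quadripartite_sequence(rng, lsc_len=8000, ir_len=2000, ssc_len=1500)
    n = len(seq)
    feats = [
        GeneFeature("psbA", "CDS", 1, [(100, 700)]),
        GeneFeature("rbcL", "CDS", 1, [(1000, 1900)]),
        GeneFeature("ndhF", "CDS", -1, [(10100, 10700)]),
        GeneFeature("rrn16", "rRNA", 1, [(8200, 8800)]),                # IRb copy
        GeneFeature("rrn16", "rRNA", -1, [(n - 800, n - 200)]),        # IRa mirror
    ]
    return PlastomeRecord("TOY1", "toy", seq, features=feats)


def test_gene_census_deduplicates_ir_copies():
    rec = _toy_record()
    part = detect_inverted_repeat(rec)
    census = gene_census(rec, part)
    assert census.n_total == 4
    assert census.n_cds == 3
    assert census.n_rrna == 1
    assert census.n_ir_duplicated == 1
    ira_copy = [f for f in rec.features if f.name == "rrn16" and f.strand == -1]
    assert ira_copy[0].is_duplicate_copy


def test_gene_census_empty_features():
    rng = np.random.default_rng(17)
    rec = PlastomeRecord("E1", "empty", build_quadripartite_sequence(rng))
    part = detect_inverted_repeat(rec)
    census = gene_census(rec, part)
    assert (census.n_total, census.n_cds, census.n_trna, census.n_rrna) == (0, 0, 0, 0)


def test_summarize_panel_matches_simulator_truth(small_panel):
    table = summarize_panel(small_panel.records[:3])
    truth = small_panel.truth.partition
    assert len(table) == 3
    assert list(table.index) == sorted(r.accession for r in small_panel.records[:3])
    assert (table["lsc_len"] == truth.lsc_len).all()
    assert (table["ssc_len"] == truth.ssc_len).all()
    assert (table["ir_len"] == truth.ir_len).all()
    assert (table["genome_size"] == truth.genome_length).all()
    # all four gene classes present with the expected deduplicated counts
    layout_names = {g.name for g in small_panel.truth.layout}
    assert (table["n_cds"] + table["n_trna"] + table["n_rrna"] == len(layout_names)).all()


def test_summarize_panel_single_genome_min_equals_max(small_panel):
    table = summarize_panel(small_panel.records[:1])
    summary = range_summary(table)
    assert (summary["width"] == 0).all()
    assert (summary["min"] == summary["max"]).all()


def test_range_summary_agrees_with_direct_scan():
    rng = np.random.default_rng(18)
    table = pd.DataFrame(
        rng.integers(0, 1_000_000, size=(30, 4)),
        columns=["genome_size", "lsc_len", "ssc_len", "ir_len"],
    )
    out = range_summary(table)
    for col in table.columns:
        vals = sorted(table[col])
        assert out.loc[col, "min"] == vals[0]
        assert out.loc[col, "max"] == vals[-1]
        assert out.loc[col, "width"] == vals[-1] - vals[0]
        assert out.loc[col, "mean"] == pytest.approx(sum(vals) / len(vals))
    with pytest.raises(ValueError):
        range_summary(pd.DataFrame())


def test_partition_regions_tile_and_classify():
    part = QuadripartitePartition(lsc_len=8000, ir_len=2000, ssc_len=1500)
    assert part.genome_length == 13500
    assert part.region_of(0) == "LSC"
    assert part.region_of(8000) == "IRB"
    assert part.region_of(10000) == "SSC"
    assert part.region_of(13499) == "IRA"
    assert part.junctions == {"JLB": 8000, "JSB": 10000, "JSA": 11500, "JLA": 13500}
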