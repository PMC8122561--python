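import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from plastome_compare.diversity import (
    diversity_stats,
    diversity_table,
    identity_profile,
    rank_hotspots,
)
from plastome_compare.loci import LocusAlignment, as_alignment, extract_loci, filter_loci
from plastome_compare.quadripartite import detect_inverted_repeat
from plastome_compare.synthetic_data import GenePlacement, SyntheticPanelSpec, simulate_panel
from _oracles import naive_diversity


def _aln(rows, name="toy", category="coding"):
    labels = [f"T{i}" for i in range(len(rows))]
    return LocusAlignment(name, category, dict(zip(labels, rows)))


def test_hand_computed_example():
    """pairwise diffs of {AAAA, AAAT, AATT} are (1, 2, 1) -> pi = (4/3)/4."""
    stats = diversity_stats(_aln(["AAAA", "AAAT", "AATT"]))
    assert stats.pi == pytest.approx(1 / 3)
    assert stats.s_sites == 2
    assert stats.eta == 2
    assert stats.h == 3
    assert stats.hd == pytest.approx(1.0)
    assert stats.pic == 0
    assert stats.net_length == 4


def test_identical_rows_give_zero_diversity():
    stats = diversity_stats(_aln(["ACGTACGT"] * 5))
    assert stats.pi == 0.0
    assert stats.s_sites == 0
    assert stats.eta == 0
    assert stats.h == 1
    assert stats.hd == 0.0


def test_all_distinct_haplotypes_give_hd_one():
    rows = ["AAAA", "CAAA", "GAAA", "TAAA"]
    stats = diversity_stats(_aln(rows))
    assert stats.h == 4
    assert stats.hd == pytest.approx(1.0)
    assert stats.pic == 0  # singleton alleles are not parsimony informative


def test_multiallelic_column_eta_exceeds_s():
    rows = ["AAAA", "ACAA", "AGAA", "ATAA"]
    stats = diversity_stats(_aln(rows))
    assert stats.s_sites == 1
    assert stats.eta == 3  # k=4 alleles contribute k-1


def test_complete_deletion_removes_gap_and_ambiguity_columns():
    rows = ["A-GTA", "ACGTN", "ACGTA"]
    stats = diversity_stats(_aln(rows))
    assert stats.net_length == 3  # columns 0, 2, 3 survive
    assert stats.s_sites == 0


def test_all_columns_gapped_reports_undefined_not_zero():
    stats = diversity_stats(_aln(["--", "--", "AN"]))
    assert stats.net_length == 0
    assert stats.pi is None and stats.hd is None and stats.s_sites is None


def test_pairwise_deletion_uses_per_pair_columns():
    rows = ["ACGT", "ACGA", "NCGT"]
    c = diversity_stats(_aln(rows), gap_policy="complete_deletion")
    p = diversity_stats(_aln(rows), gap_policy="pairwise_deletion")
    # pairs: (0,1) d=1/4; (0,2) d=0/3; (1,2) d=1/3
    assert p.pi == pytest.approx((1 / 4 + 0 / 3 + 1 / 3) / 3)
    assert c.pi == pytest.approx((1 + 0 + 1) / 3 / 3)


@st.composite
def alignments(draw):
    n = draw(st.integers(2, 8))
    L = draw(st.integers(1, 200))
    alphabet = "ACGT" if draw(st.booleans()) else "ACGT-N"
    rows = draw(
        st.lists(st.text(alphabet=alphabet, min_size=L, max_size=L), min_size=n, max_size=n)
    )
    return rows


@settings(max_examples=120, deadline=None, derandomize=True)
@given(alignments())
def test_statistics_equal_naive_reference(rows):
    stats = diversity_stats(_aln(rows))
    ref = naive_diversity(rows)
    assert stats.net_length == ref["net_length"]
    assert stats.s_sites == ref["S"]
    assert stats.eta == ref["Eta"]
    assert stats.h == ref["h"]
    assert stats.pic == ref["PIC"]
    if ref["Pi"] is None:
        assert stats.pi is None and stats.hd is None
    else:
        assert stats.pi == pytest.approx(ref["Pi"])
        assert stats.hd == pytest.approx(ref["Hd"])


def test_adding_mutated_row_never_decreases_s():
    rng = np.random.default_rng(51)
    rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)]
    s0 = diversity_stats(_aln(rows)).s_sites
    mutated = list(rows[0])
    for pos in rng.choice(60, size=5, replace=False):
        mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
    s1 = diversity_stats(_aln(rows + ["".join(mutated)])).s_sites
    assert s1 >= s0


def test_rank_hotspots_planted_locus_first(small_panel):
    pm = {r.accession: detect_inverted_repeat(r) for r in small_panel.records}
    alns = [as_alignment(l) for l in extract_loci(small_panel.records, pm)]
    table = diversity_table(filter_loci(alns, min_len=100))
    ranking = rank_hotspots(table)
    assert ranking.coding.iloc[0]["name"] == "ndhF"  # simulated at 10x background


def test_rank_hotspots_tie_breaks_lexicographically():
    rows = ["AAAA", "AAAT"]
    alns = [
        _aln(rows, name=n, category="coding") for n in ("zeta", "alpha", "mid")
    ]
    ranking = rank_hotspots([diversity_stats(a) for a in alns])
    assert list(ranking.coding["name"]) == ["alpha", "mid", "zeta"]


def test_rank_hotspots_top_k_and_threshold():
    stats = []
    for i, pi_target in enumerate((0, 1, 2, 3)):
        rows = ["A" * 8, "A" * (8 - pi_target) + "T" * pi_target]
        stats.append(diversity_stats(_aln(rows, name=f"l{i}", category="noncoding")))
    top = rank_hotspots(stats, top_noncoding=2)
    assert len(top.noncoding) == 2
    assert "top" in top.rule
    thr = rank_hotspots(stats, pi_threshold=0.2)
    assert set(thr.noncoding["name"]) == {"l2", "l3"}


def test_identity_profile_identical_and_single_mismatch():
    ref = "A" * 100
    aln = _aln([ref, ref], name="w")
    prof = identity_profile(aln, "T0", window=100, step=25)
    assert (prof.table["T1"] == 100.0).all()
    query = "A" * 50 + "C" + "A" * 49
    prof2 = identity_profile(_aln([ref, query]), "T0", window=100, step=25)
    assert prof2.table["T1"].iloc[0] == pytest.approx(99.0)


def test_identity_profile_ignores_gap_columns_and_requires_reference():
    rows = ["AC-T" * 25, "ACGT" * 25]
    prof = identity_profile(_aln(rows), "T0", window=100, step=100)
    # 25 gap columns excluded: identity is 75/75 matches
    assert prof.table["T1"].iloc[0] == pytest.approx(100.0)
    with pytest.raises(ValueError, match="reference"):
        identity_profile(_aln(rows), "missing")


def test_windows_tile_with_fixed_step():
    rows = ["A" * 260, "A" * 260]
    prof = identity_profile(_aln(rows), "T0", window=100, step=25)
    starts = list(prof.table["start"])
    assert starts == list(range(0, 161, 25))
    assert (prof.table["end"] - prof.table["start"] == 100).all()


def test_pi_rank_tracks_true_mutation_rates():
    """Spearman correlation between per-locus rates and estimated pi is high."""
    rng = np.random.default_rng(61)
    n_loci = 30
    layout = [
        GenePlacement(f"g{i:02d}", "CDS", "LSC", 650 * i + 50, 400)
        for i in range(n_loci)
    ]
    rates = 10 ** rng.uniform(-3, -1.3, size=n_loci)
    spec = SyntheticPanelSpec(
        seed=20240918, n_taxa=20, lsc_len=650 * n_loci + 200, ssc_len=1500,
        ir_len=1200, background_rate=0.002, gene_layout=layout,
        rate_overrides={f"g{i:02d}": float(rates[i]) for i in range(n_loci)},
    )
    panel = simulate_panel(spec)
    pm = {r.accession: detect_inverted_repeat(r) for r in panel.records}
    loci = [l for l in extract_loci(panel.records, pm) if l.category == "coding"]
    table = diversity_table([as_alignment(l) for l in loci]).set_index("name")
    estimated = [table.loc[f"g{i:02d}", "Pi"] for i in range(n_loci)]
    rho = spearmanr(rates, estimated).statistic
    assert rho >= 0.8
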