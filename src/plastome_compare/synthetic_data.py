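"""Seeded synthetic plastome panels with known ground truth.

The generator builds a circular ancestor genome with an exact quadripartite
layout (LSC, IRb, SSC, IRa = revcomp(IRb)), places CDS/tRNA/rRNA genes --
including IR-duplicated copies, junction-spanning genes and intron-bearing
genes -- and derives each taxon by independent per-site substitutions at a
per-locus rate (equal probability over the three alternative bases, as in a
Jukes-Cantor step).  Substitutions in the IR are applied to IRb and
mirrored into IRa so the inverted-repeat identity holds exactly in every
simulated genome.  No indels are introduced, so the true multiple alignment
of every locus is the sequences themselves.

Default dimensions follow the study system (Myrtales-like plastomes):
~86 kb LSC, ~17 kb SSC, ~26.5 kb IRs, and a low background substitution
rate with designated hotspot loci at an elevated rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from plastome_compare.io import GeneFeature, PlastomeRecord, revcomp
from plastome_compare.quadripartite import QuadripartitePartition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenePlacement:
    """One gene in the ancestor layout.

    ``offset`` is relative to the start of ``region`` (LSC/IRB/SSC); genes
    flagged ``ir_duplicated`` are specified on IRb and mirrored into IRa.
    ``spans_junction`` genes may extend past the end of their region.
    ``intron_at`` optionally splits the gene into two exons around an
    intron of ``intron_len`` bp (both measured from the gene start).
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    region: str  # LSC | IRB | SSC
    offset: int
    length: int
    strand: int = 1
    spans_junction: bool = False
    ir_duplicated: bool = False
    intron_at: int | None = None
    intron_len: int = 0


def default_gene_layout(lsc_len: int, ssc_len: int, ir_len: int) -> list[GenePlacement]:
    """A compact, plastome-like gene layout scaled to the region sizes.

    Includes the canonical junction actors (rps19 spanning JLB, ndhF near
    JSB, ycf1 spanning JSA, trnH-GUG near JLA), an IR-duplicated gene pair
    (rpl2, rrn16), an intron-bearing gene (trnL-UAA) and several single-copy
    genes with intergenic spacers between them.
    """
    u = lsc_len // 20
    genes = [
        GenePlacement("trnH-GUG", "tRNA", "LSC", 5, 75),
        GenePlacement("psbA", "CDS", "LSC", u, min(1062, 2 * u), strand=-1),
        GenePlacement("matK", "CDS", "LSC", 4 * u, min(1500, 2 * u)),
        GenePlacement("trnL-UAA", "tRNA", "LSC", 7 * u, 120 + 500,
                      intron_at=35, intron_len=500),
        GenePlacement("rbcL", "CDS", "LSC", 10 * u, min(1428, 2 * u)),
        GenePlacement("accD", "CDS", "LSC", 13 * u, min(1480, 2 * u)),
        GenePlacement("psbK", "CDS", "LSC", 16 * u, 180),
        GenePlacement("psbI", "CDS", "LSC", 16 * u + 600, 110),
        # rps19 spans the LSC/IRb junction (JLB)
        GenePlacement("rps19", "CDS", "LSC", lsc_len - 160, 279, spans_junction=True),
        # IR-duplicated genes, specified on IRb
        GenePlacement("rpl2", "CDS", "IRB", 400, min(990, ir_len // 3),
                      strand=-1, ir_duplicated=True),
        GenePlacement("rrn16", "rRNA", "IRB", ir_len // 2, min(1491, ir_len // 3),
                      ir_duplicated=True),
        # ndhF fully inside the SSC, close to JSB
        GenePlacement("ndhF", "CDS", "SSC", 60, min(2200, ssc_len // 3), strand=-1),
        GenePlacement("rpl32", "CDS", "SSC", ssc_len // 2, 170),
        # ycf1 spans the SSC/IRa junction (JSA)
        GenePlacement("ycf1", "CDS", "SSC", ssc_len - max(900, ssc_len // 8),
                      max(900, ssc_len // 8) + 1000, spans_junction=True),
    ]
    return genes


@dataclass
class SyntheticPanelSpec:
    """Generative parameters of a synthetic panel; the seed is mandatory.

    ``background_rate`` is the per-site, per-taxon substitution probability
    away from the ancestor; ``rate_overrides`` elevates named loci (gene
    names or ``geneA-geneB`` spacer names resolved against the layout).
    ``families`` optionally groups taxa into named clades that first share
    clade-level substitutions (rate ``family_rate``) before individual ones.
    """

    seed: int
    n_taxa: int = 24
    lsc_len: int = 86_000
    ssc_len: int = 17_000
    ir_len: int = 26_500
    background_rate: float = 0.005
    rate_overrides: dict[str, float] = field(default_factory=dict)
    families: dict[str, list[int]] | None = None
    family_rate: float = 0.01
    gene_layout: list[GenePlacement] | None = None
    taxon_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        rates = [self.background_rate, self.family_rate, *self.rate_overrides.values()]
        if any(not 0 <= r <= 0.5 for r in rates):
            raise ValueError("substitution rates must lie in [0, 0.5]")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated panel, for recovery tests."""

    partition: QuadripartitePartition
    layout: list[GenePlacement]
    features: list[GeneFeature]
    locus_rates: dict[str, float]
    clade_map: dict[str, str]  # accession -> family
    ancestor: str


@dataclass
class SyntheticPanel:
    records: list[PlastomeRecord]
    truth: SyntheticTruth


def _layout_to_features(
    layout: list[GenePlacement], part: QuadripartitePartition
) -> list[GeneFeature]:
    region_start = {"LSC": 0, "IRB": part.irb[0], "SSC": part.ssc[0]}
    n = part.genome_length
    feats: list[GeneFeature] = []
    for g in layout:
        start = region_start[g.region] + g.offset
        end = start + g.length
        if end > n:
            raise ValueError(f"gene {g.name} overflows the genome")
        region_end = {"LSC": part.lsc[1], "IRB": part.irb[1], "SSC": part.ssc[1]}[g.region]
        if end > region_end and not g.spans_junction:
            raise ValueError(f"gene {g.name} overflows region {g.region}")
        if g.intron_at is not None:
            cut = start + g.intron_at
            intervals = [(start, cut), (cut + g.intron_len, end)]
        else:
            intervals = [(start, end)]
        feats.append(GeneFeature(g.name, g.kind, g.strand, intervals))
        if g.ir_duplicated:
            if g.region != "IRB":
                raise ValueError(f"{g.name}: ir_duplicated genes are specified on IRb")
            # mirror position within IRa: IRb offset t maps to IRa end - t
            mirrored = []
            for s, e in intervals:
                t0, t1 = s - part.irb[0], e - part.irb[0]
                mirrored.append((part.ira[1] - t1, part.ira[1] - t0))
            feats.append(
                GeneFeature(g.name, g.kind, -g.strand, sorted(mirrored),
                            is_duplicate_copy=True)
            )
    return sorted(feats, key=lambda f: f.span)


def _locus_rate_map(
    layout: list[GenePlacement],
    features: list[GeneFeature],
    part: QuadripartitePartition,
    background: float,
    overrides: dict[str, float],
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-site substitution rates over the mutable half-genome [0, IRa).

    Spacer names ``geneA-geneB`` refer to the gap between the two gene spans
    on the canonical linearization.  Returns (site rates, realized per-locus
    rates including the background entries).
    """
    n_mut = part.ira[0]  # IRa mirrors IRb; never mutated directly
    site_rate = np.full(n_mut, background)
    realized: dict[str, float] = {}
    spans = {}
    for f in features:
        if not f.is_duplicate_copy:
            spans[f.name] = f.span
    for name, rate in overrides.items():
        if name in spans:
            s, e = spans[name]
            site_rate[s:min(e, n_mut)] = rate
        elif "-" in name and all(p in spans for p in _split_spacer(name, spans)):
            g1, g2 = _split_spacer(name, spans)
            s = spans[g1][1]
            e = spans[g2][0]
            if not 0 <= s < e:
                raise ValueError(f"spacer {name}: genes not adjacent in layout")
            site_rate[s:min(e, n_mut)] = rate
        else:
            raise ValueError(f"rate override for unknown locus {name!r}")
        realized[name] = rate
    for f in features:
        if not f.is_duplicate_copy and f.name not in realized:
            realized[f.name] = background
    return site_rate, realized


def _split_spacer(name: str, spans: dict) -> tuple[str, str]:
    # spacer names may contain hyphens inside tRNA symbols (trnH-GUG-psbA)
    for i in range(1, len(name)):
        if name[i] == "-" and name[:i] in spans and name[i + 1 :] in spans:
            return name[:i], name[i + 1 :]
    return ("", "")


def simulate_panel(spec: SyntheticPanelSpec) -> SyntheticPanel:
    """Generate a panel of annotated plastomes plus its ground truth.

    Fully reproducible from ``spec.seed``; identical specs give
    byte-identical panels.
    """
    rng = np.random.default_rng(spec.seed)
    part = QuadripartitePartition(
        lsc_len=spec.lsc_len, ir_len=spec.ir_len, ssc_len=spec.ssc_len
    )
    n = part.genome_length
    layout = spec.gene_layout if spec.gene_layout is not None else default_gene_layout(
        spec.lsc_len, spec.ssc_len, spec.ir_len
    )
    features = _layout_to_features(layout, part)

    n_mut = part.ira[0]
    anc = rng.integers(0, 4, size=n_mut, dtype=np.uint8)  # LSC + IRb + SSC
    guard = _fix_ir_guards(anc, part, rng)

    site_rate, realized = _locus_rate_map(
        layout, features, part, spec.background_rate, spec.rate_overrides
    )
    mutable = np.ones(n_mut, dtype=bool)
    mutable[list(guard)] = False  # junction guards never mutate
    site_rate = site_rate * mutable

    taxa = spec.taxon_names or [f"Taxon_{i+1:02d}" for i in range(spec.n_taxa)]
    if len(taxa) != spec.n_taxa:
        raise ValueError("taxon_names length != n_taxa")
    clade_of: dict[int, str] = {}
    if spec.families:
        for fam, members in spec.families.items():
            for m in members:
                clade_of[m] = fam

    clade_anc: dict[str, np.ndarray] = {}
    if spec.families:
        for fam in sorted(spec.families):
            clade_anc[fam] = _mutate(anc, spec.family_rate * mutable, rng)

    records: list[PlastomeRecord] = []
    clade_map: dict[str, str] = {}
    for i in range(spec.n_taxa):
        fam = clade_of.get(i)
        base = clade_anc[fam] if fam is not None else anc
        derived = _mutate(base, site_rate, rng)
        seq = _assemble(derived, part)
        acc = f"SYN{i+1:03d}"
        records.append(
            PlastomeRecord(
                accession=acc,
                taxon=taxa[i],
                family=fam,
                sequence=seq,
                features=[GeneFeature(f.name, f.kind, f.strand, list(f.intervals),
                                      is_duplicate_copy=f.is_duplicate_copy)
                          for f in features],
            )
        )
        clade_map[acc] = fam if fam is not None else "none"

    truth = SyntheticTruth(
        partition=part,
        layout=layout,
        features=features,
        locus_rates=realized,
        clade_map=clade_map,
        ancestor=_assemble(anc, part),
    )
    return SyntheticPanel(records=records, truth=truth)


def _mutate(base: np.ndarray, site_rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(base.size) < site_rate
    out = base.copy()
    if hit.any():
        # equal probability over the three alternative bases
        shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def _assemble(half: np.ndarray, part: QuadripartitePartition) -> str:
    """Build the full circular sequence: [LSC + IRb + SSC] + revcomp(IRb)."""
    seq = _BASES[half].tobytes().decode("ascii")
    irb = seq[part.irb[0] : part.irb[1]]
    return seq + revcomp(irb)


def _fix_ir_guards(
    anc: np.ndarray, part: QuadripartitePartition, rng: np.random.Generator
) -> set[int]:
    """Break reverse-complementarity just outside the constructed IR.

    Without guards, a chance complementary base adjacent to a junction would
    extend the realized inverted repeat past the constructed boundary.  Two
    base pairs decide this: (last LSC base, first LSC base) and (first SSC
    base, last SSC base).  They are resampled until non-complementary and
    excluded from mutation, so every simulated genome's maximal IR equals
    the constructed one exactly.
    """
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G on 0..3
    pairs = [
        (part.lsc[1] - 1, 0),                 # extension at JLB/JLA side
        (part.ssc[0], part.ssc[1] - 1),       # extension at JSB/JSA side
    ]
    guards: set[int] = set()
    for x, y in pairs:
        while anc[x] == comp[anc[y]]:
            anc[x] = rng.integers(0, 4, dtype=np.uint8)
        guards.update((x, y))
    return guards


def make_fixture_table1(include_outgroups: bool = False) -> pd.DataFrame:
    """The transcribed 92-genome Myrtales plastome characteristics table.

    Lengths in bp, gene counts, and GC as fractions, indexed by accession,
    with taxon and family columns.  ``tiling_consistent`` flags rows whose
    printed lengths satisfy genome = LSC + SSC + 2*IR exactly; the printed
    source table contains internally inconsistent rows, which are retained
    verbatim for range statistics but excluded from identity-based checks.
    With ``include_outgroups`` the three non-Myrtales outgroup genomes are
    appended (95 rows).
    """
    src = resources.files("plastome_compare.data").joinpath("myrtales_panel.tsv")
    with resources.as_file(src) as path:
        table = pd.read_csv(path, sep="\t", index_col="accession")
    for c in ("gc_total", "gc_lsc", "gc_ssc", "gc_ir"):
        table[c] = table[c] / 100.0
    if not include_outgroups:
        table = table[~table["family"].str.contains("outgroup")]
    table["tiling_consistent"] = (
        table["genome_size"] == table["lsc_len"] + table["ssc_len"] + 2 * table["ir_len"]
    )
    return table
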