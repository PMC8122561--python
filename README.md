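# plastome-compare

Comparative analysis of chloroplast genomes (plastomes) for phylogenetics
and molecular-marker discovery. The package targets the standard workflow
used in plant comparative plastomics — e.g. for panels of Myrtales
chloroplast genomes — and makes every stage testable against synthetic
ground truth:

1. **Quadripartite structure** — detect the inverted repeat directly from
   sequence (the longest pair of disjoint, exactly reverse-complementary
   segments on the circle), partition the genome into LSC / IRb / SSC / IRa,
   and summarize region lengths, GC content and the deduplicated gene census
   per genome.
2. **IR/SC junctions** — for each of the four boundaries (JLB, JSB, JSA,
   JLA), report the gene spanning it (with the bp falling on each side) or
   the nearest flanking genes and their distances.
3. **Homologous loci** — extract coding regions, introns and intergenic
   spacers across a panel, match them by name/gene-pair, and apply the
   marker screen: aligned length > 200 bp and ≥ 1 variable site.
4. **Nucleotide diversity** — per-locus S, η, h, Hd, π and
   parsimony-informative sites under complete (or pairwise) deletion;
   hypervariable-region ranking by π within coding and noncoding
   categories; mVISTA-style sliding-window percent identity.
5. **Sanity trees** — p-distance matrices and neighbor-joining trees in
   Newick, to smoke-test locus outputs end to end (likelihood/Bayesian
   inference is intentionally out of scope).
6. **Synthetic panels** — a seeded generator that builds annotated circular
   plastomes with exact IRs, junction-spanning and IR-duplicated genes, and
   per-locus substitution rates, so boundary detection, junction mapping
   and hotspot ranking can all be verified against construction.

The core diversity statistics for an alignment of *n* sequences over the
*L*ₙ columns retained after complete deletion:

- nucleotide diversity  π = 2/(n(n−1)) · Σ_{i<j} d_ij / Lₙ, where d_ij is
  the number of differing retained columns between sequences i and j;
- haplotype diversity  Hd = n/(n−1) · (1 − Σ_k p_k²) over haplotype
  frequencies p_k;
- η counts k−1 mutations for a column with k alleles; S counts polymorphic
  columns; PIC counts columns with ≥ 2 alleles each carried by ≥ 2
  sequences.

## Worked example

A six-taxon synthetic panel at 1/10 plastome scale, with the `ndhF` locus
planted at 10× the background substitution rate:

```python
from plastome_compare import *
from plastome_compare.diversity import diversity_table
from plastome_compare.loci import as_alignment
from plastome_compare.synthetic_data import SyntheticPanelSpec, simulate_panel

spec = SyntheticPanelSpec(seed=42, n_taxa=6, lsc_len=8000, ssc_len=1600,
                          ir_len=2100, background_rate=0.005,
                          rate_overrides={"ndhF": 0.05})
panel = simulate_panel(spec)

rec = panel.records[0]
part = detect_inverted_repeat(rec)
print(f"{rec.accession}: LSC={part.lsc_len} IRb={part.ir_len} "
      f"SSC={part.ssc_len} IRa={part.ir_len}")
for r in junction_report(rec, part):
    print(r.junction, r.gene, r.placement, r.distance,
          r.overlap_left, r.overlap_right, sep="\t")
```

```
SYN001: LSC=8000 IRb=2100 SSC=1600 IRa=2100
JLB	rps19	spans	0	160	119
JSB	rrn16	left_of	350	0	0
JSB	ndhF	right_of	60	0	0
JSA	ycf1	spans	0	900	1000
JLA	rpl2	left_of	400	0	0
JLA	trnH-GUG	right_of	5	0	0
```

The detected partition equals the generator's layout exactly: `rps19`
spans the LSC/IRb junction with 160 bp in the LSC and 119 bp in the IR,
`ycf1` spans SSC/IRa, and `ndhF` sits 60 bp inside the SSC. Continuing to
the diversity screen and hotspot ranking:

```python
pm = {r.accession: detect_inverted_repeat(r) for r in panel.records}
alns = [as_alignment(l) for l in extract_loci(panel.records, pm)]
table = diversity_table(filter_loci(alns, min_len=200))
ranking = rank_hotspots(table, top_coding=2, top_noncoding=2)
print(ranking.coding[["name", "n", "net_length", "S", "Hd", "Pi"]]
      .round(5).to_string(index=False))
```

```
name  n  net_length   S  Hd      Pi
ndhF  6         533 144 1.0 0.10156
matK  6         800  34 1.0 0.01417
```

The planted hotspot `ndhF` ranks first by π (0.102 versus ≈ 0.014 for
background loci, consistent with a 10× rate), exactly how hypervariable
barcode candidates are screened on real panels.

The same stages are available from the shell:

```bash
plastome-compare simulate --seed 42 --n-taxa 6 --out panel/
plastome-compare structure panel/*.gb --out structure.tsv
plastome-compare junctions panel/*.gb --out junctions.tsv
```

A packaged reference table of 92 published Myrtales plastomes
(`make_fixture_table1()`) provides real genome/LSC/SSC/IR lengths, gene
counts and GC content for range statistics and regression tests.

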