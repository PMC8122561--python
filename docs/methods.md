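# Methods

## Scope and data model

The package analyses annotated circular plastomes. Internally every
interval is 0-based half-open on a linearized sequence; human-facing tables
are 1-based/length-based, matching how plastome papers report coordinates.
Gene features carry a case-normalized plastid symbol (`ndhF`, `trnH-GUG`),
a class (CDS/tRNA/rRNA — the three classes counted in plastome gene
censuses; `misc_feature`, `repeat_region` and similar are ignored), a
strand and an ordered interval list, so compound (join) locations and
trans-spliced genes are representable. IUPAC ambiguity codes are kept in
the sequence and handled per statistic (below).

## Inverted-repeat detection and the quadripartite partition

The IR core is defined as the longest pair of disjoint segments of the
circular sequence that are exact reverse complements of each other. It is
found by seed-and-extend: every k-mer (k = 24 by default, clamped to the
minimum IR length) of the sequence is indexed; k-mers of the reverse
complement are looked up and each hit extended maximally in both
directions on the circle. Matches lying on one anti-diagonal are the same
maximal match, which lets already-covered seeds be skipped, so the search
is effectively linear for plastome-sized inputs. Candidates whose two
segments overlap on the circle (palindromic self-matches) are discarded.
Ties on length are broken by the smallest start coordinate and logged.

The two gaps between the IR copies are the single-copy regions; the longer
is the LSC (equal lengths raise an error as biologically implausible — the
length difference is the only disambiguator). The canonical linearization
starts at base 1 of the LSC, giving the region order LSC, IRb, SSC, IRa
and making the four junctions JLB/JSB/JSA/JLA well defined. The partition
records the rotation offset back to the input coordinates; detection is
therefore rotation-invariant, which the tests assert directly.

An optional mismatch-tolerant mode (`max_mismatch > 0`) extends the exact
core greedily across at most that many mismatched base pairs, one junction
side at a time, and trims each boundary back to a matching pair. It is off
by default: the exact-match contract is what the simulator guarantees and
what the recovery tests check to 0 bp.

Region GC content excludes N and other ambiguity codes from both numerator
and denominator. The gene census counts unique gene names, counting a gene
present once in each IR a single time (flagging the IRa copy), counting
trans-spliced `rps12` once, and excluding pseudogenes; more than two
copies of a name is logged and counted once.

## Junction mapping

For each junction, a gene whose outermost annotated extent strictly
contains the boundary is reported as spanning, with the bp on either side;
otherwise the nearest gene on each side within a flanking window (default
1,500 bp) is reported with its distance, 0 when abutting. Distance is
measured to the nearest end of the gene's outermost span — introns and
internal structure do not interrupt the span. Genes tied at the same
distance are all reported, ordered by coordinate. Genes that wrap the
canonical origin (common at JLA after rotation) are unwrapped before the
comparison, so reports are rotation-invariant.

## Locus extraction and the marker screen

Three locus classes are extracted per genome on the canonical
linearization: coding loci (concatenated exons, reverse-complemented for
minus-strand genes), introns (gaps between consecutive exons, numbered in
transcription order; `rps12` is excluded because its parts are
trans-spliced), and intergenic spacers (sequence between consecutive gene
spans, including the wrap-around pair; non-positive spacers from
overlapping genes are skipped). IR-duplicated genes contribute once, via
the IRb copy.

Across genomes, coding loci and introns match by name; spacers match by
the unordered pair of flanking genes, with the display name taken from the
first genome observed and sequences from genomes where the pair occurs in
the opposite linear order reverse-complemented into a common orientation.
This makes extraction invariant under reverse-complementing and rotating a
genome, which is tested. Loci present in fewer than two genomes are
dropped with a log line.

The marker screen keeps a locus when its aligned length is strictly
greater than 200 bp and it has at least one variable column (a column with
two or more distinct unambiguous bases). The length bound is strict and
the variable-site threshold configurable, because the screen is typically
stated loosely in the literature; both knobs are explicit parameters.

Multiple alignment itself is delegated: substitution-only panels (the
generator's output) are already aligned, and real data with indels should
be aligned externally (e.g. MAFFT) and ingested from FASTA. This keeps the
diversity statistics independent of aligner behaviour.

## Diversity statistics

Under the default complete-deletion policy, every column containing a gap
or ambiguous base is removed first; all statistics then share the retained
columns L_net. Per locus:

- S — columns with ≥ 2 alleles; η — Σ (k−1) over columns with k alleles;
- PIC — columns with ≥ 2 alleles each present in ≥ 2 sequences;
- h and Hd = n/(n−1)(1 − Σ p_k²) over haplotypes of the retained columns;
- π = 2/(n(n−1)) Σ_{i<j} d_ij / L_net.

When no column survives, statistics are reported as undefined (None), not
zero. A pairwise-deletion option computes π over per-pair comparable
columns (site and haplotype statistics still use fully unambiguous
columns); it exists because published analyses do not always state the
deletion policy of the tool they used. π is reported to 5 decimals in
tables. The implementation is vectorized (numpy over byte-encoded
matrices) and is checked column-for-column against a naive pure-Python
enumeration on hundreds of random alignments, including gapped ones.

Hotspot ranking sorts by π descending with lexicographic tie-breaks,
separately for coding and noncoding loci. The classic 9 coding + 12
noncoding barcode shortlist is a preset of the top-k parameters, not a
hard-coded rule, since no π threshold generalizes across panels. The
sliding-window identity profile (default window 100, step 25 — chosen as
typical mVISTA-scale resolution) reports matches/(matches+mismatches)×100
per window over columns where neither row is gapped, NaN where no column
is comparable.

## Trees

p-distances are computed over complete-deletion columns; neighbor joining
is delegated to scikit-bio with negative branch lengths clamped at zero
and labels sorted for deterministic tie-breaking. NJ exists to
smoke-test the pipeline (e.g. family monophyly on clade-structured
synthetic panels, exact recovery of additive matrices); it is not a
substitute for ML/Bayesian inference, which is out of scope.

## Synthetic panels

The generator draws a uniform-random ancestor for LSC + IRb + SSC, sets
IRa = revcomp(IRb), and derives each taxon by independent per-site
substitutions: a site at rate μ changes with probability μ to one of the
three other bases uniformly (a single Jukes–Cantor step; two taxa then
differ at a site with probability 2μ(1−μ) + (2/3)μ², ≈ 2μ for small μ,
which the tests verify within 3 binomial standard errors). IR sites are
mutated on IRb and mirrored, so the IR identity holds exactly in every
genome. Optional family clades first derive a shared clade ancestor at a
clade-level rate, producing ground-truth monophyly.

Two base pairs adjacent to the junctions — (last LSC base, first LSC base)
and (first SSC base, last SSC base) — are resampled until
non-complementary and excluded from mutation. Without these guards a
chance complementary base would extend the realized maximal IR a few bp
past the constructed boundary in a sizable fraction of panels, making
"0 bp recovery" the wrong expectation for a correct detector.

The default layout mirrors real plastome architecture: `rps19` spanning
JLB, `ndhF` just inside the SSC, `ycf1` spanning JSA, `trnH-GUG` near JLA,
duplicated `rpl2`/`rrn16` in the IRs, an intron-bearing `trnL-UAA`, and
single-copy LSC genes with spacers. Default dimensions are full plastome
scale (86 kb LSC, 17 kb SSC, 26.5 kb IR, 24 taxa, background rate 0.005
substitutions/site/taxon — diversity of the order seen across confamilial
plastome panels). The test suite and the acceptance script run the same
architecture at ~1/10 linear scale (8 kb LSC, 1.6 kb SSC, 2.1 kb IR) with
2–6 taxa and 10–100 replicates; structure, junction and hotspot recovery
are scale-free properties, so the reduced size changes runtime, not the
contract being tested.

What the generator does **not** emulate: indels and alignment uncertainty,
rate heterogeneity within a locus, base-composition bias (real plastomes
are ~37% GC, the simulator is 50%), gene-sequence realism (no ORFs), IR
expansion/contraction between taxa, and recombination. Passing recovery
tests therefore demonstrate correctness of the algorithms under the stated
model, not robustness to annotation errors or alignment artifacts in real
data.

## Packaged reference table

`make_fixture_table1()` returns a transcription of a published
characteristics table for 92 Myrtales plastomes (plus three outgroups on
request): genome/LSC/SSC/IR lengths, CDS/tRNA/rRNA counts and GC
fractions, indexed by GenBank accession. Twenty of the 92 printed rows do
not satisfy genome = LSC + SSC + 2·IR exactly (printed inconsistencies of
a few bp up to obvious typos); they are kept verbatim for range statistics
and flagged `tiling_consistent=False` so identity-based checks can exclude
them. The table's range summary (e.g. genome sizes 152,214–171,315 bp,
width 19,101 bp; SSC minimum 11,150 bp; panel-mean GC 37%) is recomputed
by `range_summary`, never stored.

## Numerical and degenerate-input choices

- LSC = SSC length ties: error (no biological tie-break exists).
- Equal-length IR candidates: smallest start coordinate, logged.
- Empty alignments/columns: undefined markers rather than zeros.
- NJ on a star-like matrix: a resolved tree with the documented
  deterministic tie order — a contract about determinism, not about
  biological meaning.
- All randomness flows through one `numpy` Generator per simulation,
  seeded from the spec; identical seeds give byte-identical panels,
  and the pipeline rerun with the same config reproduces its outputs
  byte-for-byte.

## Limitations

Annotation quality bounds everything downstream: junction and locus
results are only as good as the gene features in the input GenBank files.
The marker screen and hotspot ranking operate per locus; no multiple-test
correction or phylogenetic correction is applied, matching standard
practice for descriptive hotspot scans. Percent-identity profiles assume a
whole-genome alignment is supplied; the package does not compute one.
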