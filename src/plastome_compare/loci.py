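"""Homologous-locus extraction and filtering across a plastome panel.

Three locus classes are extracted from annotated genomes: coding regions
(concatenated exons per gene), introns (gaps between consecutive exons of
one gene) and intergenic spacers (the sequence between consecutive gene
spans on the canonical linearization).  Loci are matched across genomes by
name; spacers are matched by their unordered gene pair so that genomes with
locally inverted gene order still contribute, with sequences oriented
consistently.  The hotspot screen keeps a locus only when its aligned
length exceeds a minimum (default 200 bp, strict) and it shows at least one
variable column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from plastome_compare.io import PlastomeRecord, revcomp
from plastome_compare.quadripartite import QuadripartitePartition, canonicalize

logger = logging.getLogger(__name__)

UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class LocusSet:
    """One homologous locus across taxa, unaligned.

    ``name`` is a gene symbol, a ``geneA-geneB`` spacer label (plus-strand
    order of the reference linearization) or ``gene-intronN``.
    """

    name: str
    category: str  # coding | noncoding
    sequences: dict[str, str] = field(default_factory=dict)  # accession -> seq

    @property
    def n(self) -> int:
        return len(self.sequences)


@dataclass
class LocusAlignment:
    """An aligned locus: equal-length rows over {A,C,G,T,N,-,IUPAC}."""

    name: str
    category: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.name}: ragged alignment rows {sorted(lengths)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def aligned_length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def _per_genome_loci(record: PlastomeRecord, partition: QuadripartitePartition):
    """Loci of one genome on its canonical linearization.

    Returns (name -> (category, sequence, key)); ``key`` is the identity used
    for cross-genome matching (spacers use a frozenset of the two genes).
    IRa copies of duplicated genes are dropped so each gene contributes once
    (the IRb copy, which precedes IRa on the linearization, wins); spacers
    are computed over all copies and deduplicated the same way.
    """
    rec, part = canonicalize(record, partition)
    feats = sorted(
        (f for f in rec.features if not f.pseudo),
        key=lambda f: f.span,
    )
    out: dict[str, tuple[str, str, object]] = {}

    for f in feats:
        # coding locus: concatenated exons, transcription orientation
        if f.name not in out:
            out[f.name] = ("coding", f.extract(rec.sequence), f.name)
        # introns between consecutive exons
        if len(f.intervals) > 1 and f.name != "rps12":
            gaps = []
            for (s1, e1), (s2, _) in zip(f.intervals, f.intervals[1:]):
                if s2 > e1:
                    gaps.append(rec.sequence[e1:s2])
            if f.strand < 0:
                gaps = [revcomp(g) for g in reversed(gaps)]
            for i, g in enumerate(gaps, start=1):
                iname = f"{f.name}-intron{i}"
                if g and iname not in out:
                    out[iname] = ("noncoding", g, iname)

    # intergenic spacers between consecutive gene spans (incl. the wrap-around
    # pair); overlapping genes give non-positive spacers, which are skipped
    for (f1, f2) in zip(feats, feats[1:] + feats[:1]):
        s1, e1 = f1.span
        s2, _ = f2.span
        if f2 is feats[0]:
            s2 += len(rec)  # wrap-around spacer through the origin
        if s2 <= e1 or f1.name == f2.name:
            continue
        seq = rec.subseq(e1, s2)
        name = f"{f1.name}-{f2.name}"
        key = frozenset((f1.name, f2.name))
        if name not in out and not any(v[2] == key for v in out.values()):
            out[name] = ("noncoding", seq, key)
    return out


def extract_loci(
    records: list[PlastomeRecord],
    partition_map: dict[str, QuadripartitePartition],
    min_genomes: int = 2,
) -> list[LocusSet]:
    """Extract coding, intron and spacer loci shared across a panel.

    Loci present in fewer than ``min_genomes`` genomes are dropped with a
    log line.  Spacer naming follows the first genome in which the pair is
    seen; a genome where the two genes occur in the opposite linear order
    contributes the reverse complement, keeping orientations comparable.
    """
    by_key: dict[object, LocusSet] = {}
    order: list[object] = []
    for rec in records:
        part = partition_map[rec.accession]
        for name, (category, seq, key) in _per_genome_loci(rec, part).items():
            if not seq:
                continue
            ls = by_key.get(key)
            if ls is None:
                ls = LocusSet(name=name, category=category, sequences={})
                by_key[key] = ls
                order.append(key)
            elif isinstance(key, frozenset) and ls.name != name:
                seq = revcomp(seq)  # opposite gene order in this genome
            ls.sequences[rec.accession] = seq
    kept = []
    for key in order:
        ls = by_key[key]
        if ls.n >= min_genomes:
            kept.append(ls)
        else:
            logger.info("locus %s present in %d genome(s) < %d; dropped",
                        ls.name, ls.n, min_genomes)
    return kept


def as_alignment(locus: LocusSet) -> LocusAlignment:
    """Treat an indel-free locus set (all rows equal length) as aligned.

    Substitution-only panels (the synthetic generator) need no aligner; for
    real data with indels, align externally (e.g. MAFFT) and use
    :func:`ingest_alignment`.
    """
    lengths = {len(s) for s in locus.sequences.values()}
    if len(lengths) > 1:
        raise ValueError(
            f"{locus.name}: unequal sequence lengths {sorted(lengths)}; "
            "run an external aligner and ingest_alignment()"
        )
    return LocusAlignment(locus.name, locus.category, dict(locus.sequences))


def ingest_alignment(
    path: str | Path, name: str | None = None, category: str = "noncoding"
) -> LocusAlignment:
    """Read one aligned FASTA (gaps '-') into a LocusAlignment."""
    from Bio import SeqIO

    path = Path(path)
    rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return LocusAlignment(name or path.stem, category, rows)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in aln.rows.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def count_variable_columns(aln: LocusAlignment) -> int:
    """Columns with >= 2 distinct unambiguous bases (gaps/N/IUPAC ignored)."""
    rows = list(aln.rows.values())
    count = 0
    for col in zip(*rows):
        alleles = {c for c in col if c in UNAMBIGUOUS}
        if len(alleles) >= 2:
            count += 1
    return count


def filter_loci(
    alignments: list[LocusAlignment],
    min_len: int = 200,
    min_variable_sites: int = 1,
) -> list[LocusAlignment]:
    """Keep loci with aligned length strictly greater than ``min_len`` and at
    least ``min_variable_sites`` variable columns; input order preserved."""
    kept = []
    for aln in alignments:
        if aln.aligned_length > min_len and count_variable_columns(aln) >= min_variable_sites:
            kept.append(aln)
    return kept
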