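"""Plastome records, GenBank/FASTA input and tabular output.

Coordinate convention: every interval in memory is 0-based half-open on the
linearized sequence; human-facing tables are 1-based inclusive.  Gene names
are case-normalized to conventional plastid symbols (``ndhF``, ``rbcL``,
``trnH-GUG`` with the anticodon suffix kept verbatim) because locus and
junction matching across genomes is name-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GENE_KINDS = ("CDS", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


# Conventional plastid symbols: 3 lowercase letters, optional uppercase
# letter, optional copy number (ndhF, rbcL, ycf1, rpoC2, rps12, rrn16).
_SYMBOL_RE = re.compile(r"([A-Za-z]{3})([A-Za-z]?)(\d*)")


def normalize_gene_symbol(raw: str) -> str:
    """Case-normalize a plastid gene symbol.

    ``NDHF``/``ndhf`` -> ``ndhF``; ``RBCL`` -> ``rbcL``; tRNA anticodon
    suffixes (``trnH-GUG``) are upper-cased and kept.  Symbols that do not
    look like conventional plastid names are returned stripped but
    otherwise untouched.
    """
    name = raw.strip()
    if not name:
        return name
    head, _, tail = name.partition("-")
    m = _SYMBOL_RE.fullmatch(head)
    if m:
        prefix, letter, digits = m.groups()
        head = prefix.lower() + letter.upper() + digits
    if tail:
        return f"{head}-{tail.upper()}" if head.lower().startswith("trn") else f"{head}-{tail}"
    return head


@dataclass
class GeneFeature:
    """One gene copy on the linearized genome.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    pairs; compound (join) locations appear as multiple intervals.
    """

    name: str
    kind: str  # one of GENE_KINDS
    strand: int  # +1 / -1
    intervals: list[tuple[int, int]]
    is_duplicate_copy: bool = False
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for s, e in self.intervals:
            if not 0 <= s < e:
                raise ValueError(f"bad interval [{s}, {e}) in {self.name!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Outermost extent ``(min start, max end)`` across all intervals."""
        return (min(s for s, _ in self.intervals), max(e for _, e in self.intervals))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extract(self, sequence: str) -> str:
        """Feature sequence in transcription orientation (revcomp on minus)."""
        parts = "".join(sequence[s:e] for s, e in self.intervals)
        return revcomp(parts) if self.strand < 0 else parts


@dataclass
class PlastomeRecord:
    """An annotated (usually circular) plastome."""

    accession: str
    taxon: str
    sequence: str
    family: str | None = None
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if e > n:
                    raise ValueError(
                        f"{self.accession}: feature {f.name!r} interval [{s},{e}) "
                        f"outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Subsequence on the circular molecule; ``end`` may exceed length."""
        n = len(self.sequence)
        start %= n
        end = start + (end - start) if end >= start else end
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("interval wraps origin of a linear record")
        return self.sequence[start:] + self.sequence[: end - n]

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Return the record re-linearized to start at ``offset`` (circular).

        Features are shifted accordingly; a feature interval that wraps the
        new origin is split into two intervals.
        """
        n = len(self.sequence)
        offset %= n
        if offset == 0:
            return self
        if not self.circular:
            raise ValueError("cannot rotate a linear record")
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            ivs: list[tuple[int, int]] = []
            for s, e in f.intervals:
                s2, e2 = (s - offset) % n, (e - offset) % n or n
                if s2 < e2:
                    ivs.append((s2, e2))
                else:  # wraps the new origin
                    ivs.append((s2, n))
                    ivs.append((0, e2))
            feats.append(replace(f, intervals=ivs))
        return replace(self, sequence=seq, features=feats)


def _feature_from_seqfeature(sf: SeqFeature) -> GeneFeature | None:
    kind = sf.type
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("product") or quals.get("locus_tag") or [None])[0]
    if name is None:
        logger.warning("skipping %s feature without gene/product name at %s", kind, sf.location)
        return None
    pseudo = "pseudo" in quals or "pseudogene" in quals
    try:
        parts = sf.location.parts
        intervals = [(int(p.start), int(p.end)) for p in parts]
        strand = -1 if (sf.location.strand or 1) < 0 else 1
    except Exception:  # unparseable location
        logger.warning("skipping feature %r: unparseable location", name)
        return None
    intervals.sort()
    return GeneFeature(
        name=normalize_gene_symbol(name),
        kind=kind,
        strand=strand,
        intervals=intervals,
        pseudo=pseudo,
    )


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    Only CDS/tRNA/rRNA features are retained (the census counts those three
    classes); if none are present, bare ``gene`` features are used with the
    kind inferred from the symbol (trn* -> tRNA, rrn* -> rRNA, else CDS).
    """
    seqrec = SeqIO.read(str(path), "genbank")
    if len(seqrec.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no sequence")
    feats: list[GeneFeature] = []
    for sf in seqrec.features:
        if sf.type in GENE_KINDS:
            f = _feature_from_seqfeature(sf)
            if f is not None:
                feats.append(f)
    if not feats:
        for sf in seqrec.features:
            if sf.type != "gene":
                continue
            f = _feature_from_seqfeature(sf)
            if f is None:
                continue
            low = f.name.lower()
            f.kind = "tRNA" if low.startswith("trn") else "rRNA" if low.startswith("rrn") else "CDS"
            feats.append(f)
    taxon = seqrec.annotations.get("organism") or seqrec.description or seqrec.id
    topology = seqrec.annotations.get("topology", "circular")
    return PlastomeRecord(
        accession=seqrec.id,
        taxon=taxon,
        sequence=str(seqrec.seq),
        circular=topology != "linear",
        features=sorted(feats, key=lambda f: f.span),
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Emit a record as a GenBank flat file (round-trips through read_genbank)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=record.taxon,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.taxon,
        },
    )
    for f in record.features:
        locs = [SimpleLocation(s, e, strand=f.strand) for s, e in f.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.pseudo:
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(location, type=f.kind, qualifiers=quals))
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta_panel(path: str | Path) -> list[PlastomeRecord]:
    """Read a multi-FASTA of whole genomes; headers parsed as ``accession taxon``."""
    records: list[PlastomeRecord] = []
    seen: set[str] = set()
    for seqrec in SeqIO.parse(str(path), "fasta"):
        acc = seqrec.id
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        taxon = seqrec.description[len(seqrec.id):].strip() or acc
        records.append(PlastomeRecord(accession=acc, taxon=taxon, sequence=str(seqrec.seq)))
    return records


def write_fasta_panel(records: Iterable[PlastomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.taxon}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


#: Column order of the panel summary table (lengths in bp, GC as fractions).
PANEL_COLUMNS = [
    "taxon",
    "genome_size",
    "lsc_len",
    "ssc_len",
    "ir_len",
    "n_cds",
    "n_trna",
    "n_rrna",
    "gc_total",
    "gc_lsc",
    "gc_ssc",
    "gc_ir",
]

_LEN_COLS = ["genome_size", "lsc_len", "ssc_len", "ir_len", "n_cds", "n_trna", "n_rrna"]
_GC_COLS = ["gc_total", "gc_lsc", "gc_ssc", "gc_ir"]


def check_tiling(table: pd.DataFrame) -> pd.Series:
    """Boolean per row: genome_size == lsc + ssc + 2*ir."""
    return table["genome_size"] == table["lsc_len"] + table["ssc_len"] + 2 * table["ir_len"]


def write_panel_table(
    table: pd.DataFrame, path: str | Path, allow_inconsistent: bool = False
) -> None:
    """Write the per-genome summary table as TSV.

    Columns follow :data:`PANEL_COLUMNS` (accession index first); lengths are
    integers, GC is emitted as percent with 2 decimals.  Rows violating the
    quadripartite tiling identity genome = LSC + SSC + 2*IR are refused
    unless ``allow_inconsistent`` (used for transcribed literature tables
    that contain printed inconsistencies).
    """
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"panel table missing columns: {missing}")
    ok = check_tiling(table)
    if not allow_inconsistent and not ok.all():
        bad = list(table.index[~ok])
        raise ValueError(f"tiling identity violated for rows: {bad}")
    out = table[PANEL_COLUMNS].copy()
    for c in _LEN_COLS:
        out[c] = out[c].astype(int)
    for c in _GC_COLS:
        out[c] = (out[c] * 100).map(lambda v: f"{v:.2f}")
    out.index.name = "accession"
    out.to_csv(path, sep="\t")


def validate_files(paths: Sequence[str | Path]) -> pd.DataFrame:
    """Parse each file (GenBank or FASTA by extension) and report basic facts."""
    rows = []
    for p in paths:
        p = Path(p)
        try:
            if p.suffix.lower() in {".gb", ".gbk", ".genbank"}:
                recs = [read_genbank(p)]
            else:
                recs = read_fasta_panel(p)
            for r in recs:
                rows.append(
                    {"file": str(p), "accession": r.accession, "taxon": r.taxon,
                     "length": len(r), "n_features": len(r.features), "status": "ok"}
                )
        except Exception as exc:  # pragma: no cover - reporting path
            rows.append({"file": str(p), "accession": "", "taxon": "", "length": 0,
                         "n_features": 0, "status": f"error: {exc}"})
    return pd.DataFrame(rows)
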