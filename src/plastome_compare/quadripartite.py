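"""Quadripartite structure: inverted-repeat detection, region statistics, gene census.

A chloroplast genome is modelled as a circle carrying two identical inverted
repeats (IRa, IRb) separated by a large and a small single-copy region
(LSC, SSC).  Detection finds the longest pair of disjoint, exactly
reverse-complementary segments on the circle and normalizes the rotation so
that the canonical linearization reads LSC, IRb, SSC, IRa with the LSC
starting at position 0.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plastome_compare.io import (
    GENE_KINDS,
    PANEL_COLUMNS,
    PlastomeRecord,
    revcomp,
)

logger = logging.getLogger(__name__)


class NoInvertedRepeatError(ValueError):
    """No inverted repeat of the required minimum length was found.

    IR contraction down to complete loss is known in some plant lineages, so
    this is a legitimate biological outcome, not only a data error.
    """


@dataclass(frozen=True)
class QuadripartitePartition:
    """Coordinates of LSC/IRb/SSC/IRa on the canonical linearization.

    ``offset`` maps canonical coordinates back to the input record:
    canonical position 0 corresponds to input position ``offset`` (the first
    base of the LSC as the record was supplied).
    """

    lsc_len: int
    ir_len: int
    ssc_len: int
    offset: int = 0

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    # canonical [start, end) intervals
    @property
    def lsc(self) -> tuple[int, int]:
        return (0, self.lsc_len)

    @property
    def irb(self) -> tuple[int, int]:
        return (self.lsc_len, self.lsc_len + self.ir_len)

    @property
    def ssc(self) -> tuple[int, int]:
        s = self.lsc_len + self.ir_len
        return (s, s + self.ssc_len)

    @property
    def ira(self) -> tuple[int, int]:
        return (self.genome_length - self.ir_len, self.genome_length)

    @property
    def junctions(self) -> dict[str, int]:
        """Canonical coordinates of the four boundaries JLB/JSB/JSA/JLA."""
        return {
            "JLB": self.lsc[1],
            "JSB": self.irb[1],
            "JSA": self.ssc[1],
            "JLA": self.genome_length,  # == 0 on the circle
        }

    def region_of(self, pos: int) -> str:
        pos %= self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(self, name)
            if s <= pos < e:
                return name.upper()
        raise AssertionError("unreachable: regions tile the genome")


def canonicalize(record: PlastomeRecord, partition: QuadripartitePartition):
    """Rotate a record so the LSC starts at base 0; partition offset becomes 0."""
    rec = record.rotated(partition.offset)
    part = QuadripartitePartition(
        lsc_len=partition.lsc_len, ir_len=partition.ir_len,
        ssc_len=partition.ssc_len, offset=0,
    )
    return rec, part


def _maximal_rc_matches(seq: str, min_len: int, k: int) -> list[tuple[int, int, int]]:
    """Maximal reverse-complement self-matches on the circular sequence.

    Returns triples ``(a, b, L)``: ``seq[a:a+L]`` (circular) equals
    revcomp of ``seq[b:b+L]`` (circular), with a <= b after normalization.
    Seed-and-extend over exact k-mers; the anti-diagonal (a + b + L) mod n is
    constant along one match, which lets previously extended seeds be skipped.
    """
    n = len(seq)
    dbl = seq + seq[: k - 1]
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        index[dbl[i : i + k]].append(i)
    rc = revcomp(seq)
    rc_dbl = rc + rc[: k - 1]

    matches: list[tuple[int, int, int]] = []
    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for j in range(n):
        kmer = rc_dbl[j : j + k]
        for i in index.get(kmer, ()):
            d = (i - j) % n
            if any((i - a0) % n < L for a0, L in covered[d]):
                continue
            # extend the exact match in both directions (at most n columns)
            left = 0
            while left < n - k and (
                dbl[(i - left - 1) % n] == rc_dbl[(j - left - 1) % n]
            ):
                left += 1
            right = 0
            while left + k + right < n and (
                dbl[(i + k + right) % n] == rc_dbl[(j + k + right) % n]
            ):
                right += 1
            a0 = (i - left) % n
            L = left + k + right
            covered[d].append((a0, L))
            if L < min_len:
                continue
            # map the rc-coordinate start back to a plain segment of seq
            b0 = (n - (j - left) - L) % n
            a, b = (a0, b0) if a0 <= b0 else (b0, a0)
            matches.append((a, b, L))
    # dedupe (each pair is discovered from both strands)
    return sorted(set(matches))


def _disjoint_on_circle(a: int, b: int, L: int, n: int) -> bool:
    """Do circular segments [a, a+L) and [b, b+L) avoid overlap?"""
    gap1 = (b - (a + L)) % n
    gap2 = (a - (b + L)) % n
    return gap1 + gap2 + 2 * L == n and gap1 >= 0 and gap2 >= 0


def detect_inverted_repeat(
    record: PlastomeRecord,
    min_ir_len: int = 1000,
    max_mismatch: int = 0,
    seed_k: int = 24,
) -> QuadripartitePartition:
    """Find the inverted repeat and partition the genome into LSC/IRb/SSC/IRa.

    The IR core is the longest pair of disjoint, exactly reverse-complementary
    segments on the circular sequence (ties broken by smallest start
    coordinate).  With ``max_mismatch > 0`` the exact core is then extended
    greedily outwards, consuming at most that many mismatched base pairs.

    Raises :class:`NoInvertedRepeatError` when no candidate reaches
    ``min_ir_len``, and ``ValueError`` when LSC and SSC come out equal
    (length is the only disambiguator between them).
    """
    seq = record.sequence
    n = len(seq)
    if n < 2 * min_ir_len:
        raise NoInvertedRepeatError(
            f"{record.accession}: genome of {n} bp cannot hold two IRs >= {min_ir_len} bp"
        )
    k = min(seed_k, min_ir_len)
    candidates = [
        (a, b, L)
        for a, b, L in _maximal_rc_matches(seq, min_ir_len, k)
        if _disjoint_on_circle(a, b, L, n)
    ]
    if not candidates:
        raise NoInvertedRepeatError(
            f"{record.accession}: no inverted repeat of >= {min_ir_len} bp"
        )
    best_len = max(c[2] for c in candidates)
    ties = sorted(c for c in candidates if c[2] == best_len)
    if len(ties) > 1:
        logger.info(
            "%s: %d equal-length IR candidates, keeping smallest start",
            record.accession, len(ties),
        )
    a, b, L = ties[0]

    if max_mismatch > 0:
        a, b, L = _extend_with_mismatches(seq, a, b, L, max_mismatch)

    # gaps between the two repeat copies on the circle
    gap_ab = (b - (a + L)) % n  # from end of A to start of B
    gap_ba = (a - (b + L)) % n  # from end of B to start of A
    if gap_ab == gap_ba:
        raise ValueError(
            f"{record.accession}: single-copy regions have equal length "
            f"({gap_ab} bp); cannot tell LSC from SSC"
        )
    if gap_ab > gap_ba:
        # LSC runs from end of A to start of B; IRb is then copy B
        lsc_len, ssc_len, offset = gap_ab, gap_ba, (a + L) % n
    else:
        lsc_len, ssc_len, offset = gap_ba, gap_ab, (b + L) % n
    part = QuadripartitePartition(lsc_len=lsc_len, ir_len=L, ssc_len=ssc_len, offset=offset)
    assert part.genome_length == n
    return part


def _extend_with_mismatches(seq: str, a: int, b: int, L: int, budget: int):
    """Greedy boundary extension tolerating up to ``budget`` mismatched pairs.

    The exact core A = [a, a+L) pairs with B = [b, b+L) so that
    ``A[t] == comp(B[L-1-t])``.  Each junction side extends independently:
    growing A leftwards grows B rightwards and vice versa.  Boundaries always
    end on a matching pair (trailing mismatches are trimmed back).
    """
    n = len(seq)
    comp = str.maketrans("ACGT", "TGCA")

    def pair_ok(x: int, y: int) -> bool:
        return seq[x % n] == seq[y % n].translate(comp)

    used = 0
    # side 1: A start <-> B end
    gained = 0
    while used <= budget and _disjoint_on_circle((a - gained - 1) % n, b, L + gained + 1, n):
        if not pair_ok(a - gained - 1, b + L + gained):
            used += 1
            if used > budget:
                break
        gained += 1
    while gained and not pair_ok(a - gained, b + L + gained - 1):
        gained -= 1  # trim back to a matching pair
    a = (a - gained) % n
    L += gained
    # side 2: A end <-> B start
    gained = 0
    while used <= budget and _disjoint_on_circle(a, (b - gained - 1) % n, L + gained + 1, n):
        if not pair_ok(a + L + gained, b - gained - 1):
            used += 1
            if used > budget:
                break
        gained += 1
    while gained and not pair_ok(a + L + gained - 1, b - gained):
        gained -= 1
    b = (b - gained) % n
    L += gained
    return a, b, L


def gc_fraction(seq: str) -> float:
    """G+C over unambiguous bases only; N and IUPAC codes are excluded."""
    gc = sum(seq.count(c) for c in "GC")
    at = sum(seq.count(c) for c in "AT")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


@dataclass(frozen=True)
class RegionProfile:
    region: str  # LSC | SSC | IR | total
    length: int
    gc: float


def region_profiles(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> list[RegionProfile]:
    """Length and GC for LSC, SSC, IR (computed on IRb) and the whole genome."""
    rec, part = canonicalize(record, partition)
    out = []
    for label, (s, e) in (("LSC", part.lsc), ("SSC", part.ssc), ("IR", part.irb)):
        sub = rec.sequence[s:e]
        out.append(RegionProfile(label, e - s, gc_fraction(sub)))
    out.append(RegionProfile("total", len(rec), gc_fraction(rec.sequence)))
    return out


@dataclass(frozen=True)
class GeneCensus:
    n_total: int
    n_cds: int
    n_trna: int
    n_rrna: int
    n_ir_duplicated: int


def gene_census(record: PlastomeRecord, partition: QuadripartitePartition) -> GeneCensus:
    """Deduplicated gene counts by class.

    A gene present once in each IR counts once and is flagged IR-duplicated
    (the flag is set on the IRa copy).  The trans-spliced rps12 counts once
    however many parts are annotated.  Pseudogenes are excluded.  Genes with
    more than two copies are counted once with a warning.
    """
    rec, part = canonicalize(record, partition)
    by_name: dict[str, list] = defaultdict(list)
    for f in rec.features:
        if f.pseudo:
            continue
        by_name[f.name].append(f)
    counts = {k: 0 for k in GENE_KINDS}
    n_ir_dup = 0
    for name, copies in sorted(by_name.items()):
        if len(copies) > 2 and name != "rps12":
            logger.warning("%s: gene %s has %d copies; counted once",
                           rec.accession, name, len(copies))
        regions = {part.region_of(sum(f.span) // 2) for f in copies}
        if len(copies) >= 2 and {"IRA", "IRB"} <= regions:
            n_ir_dup += 1
            for f in copies:
                if part.region_of(sum(f.span) // 2) == "IRA":
                    f.is_duplicate_copy = True
        counts[copies[0].kind] += 1
    return GeneCensus(
        n_total=sum(counts.values()),
        n_cds=counts["CDS"],
        n_trna=counts["tRNA"],
        n_rrna=counts["rRNA"],
        n_ir_duplicated=n_ir_dup,
    )


def summarize_panel(
    records: list[PlastomeRecord], min_ir_len: int = 1000
) -> pd.DataFrame:
    """Per-genome structure summary (one row per accession, sorted).

    Runs IR detection, region profiling and the gene census per record;
    records where detection fails are logged and omitted from the table.
    """
    rows = {}
    for rec in records:
        try:
            part = detect_inverted_repeat(rec, min_ir_len=min_ir_len)
        except (NoInvertedRepeatError, ValueError) as exc:
            logger.warning("%s: skipped (%s)", rec.accession, exc)
            continue
        profiles = {p.region: p for p in region_profiles(rec, part)}
        census = gene_census(rec, part)
        rows[rec.accession] = {
            "taxon": rec.taxon,
            "genome_size": len(rec),
            "lsc_len": part.lsc_len,
            "ssc_len": part.ssc_len,
            "ir_len": part.ir_len,
            "n_cds": census.n_cds,
            "n_trna": census.n_trna,
            "n_rrna": census.n_rrna,
            "gc_total": profiles["total"].gc,
            "gc_lsc": profiles["LSC"].gc,
            "gc_ssc": profiles["SSC"].gc,
            "gc_ir": profiles["IR"].gc,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "accession"
    return table.reindex(columns=PANEL_COLUMNS)


def range_summary(table: pd.DataFrame, decimals: int | None = None) -> pd.DataFrame:
    """min / max / width (max - min) / mean per numeric column."""
    if table.empty:
        raise ValueError("empty panel table")
    num = table.select_dtypes(include=[np.number])
    out = pd.DataFrame(
        {
            "min": num.min(),
            "max": num.max(),
            "width": num.max() - num.min(),
            "mean": num.mean(),
        }
    )
    if decimals is not None:
        out["mean"] = out["mean"].round(decimals)
    return out
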