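"""IR/SC junction mapping: which genes span or flank each of the four boundaries.

The four junctions are JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa) and
JLA (IRa/LSC).  For each junction the report lists either the single gene
spanning it (with the number of bases falling on each side) or the nearest
gene on each side within a flanking window, with its distance to the
boundary.  Distances use the gene's outermost annotated extent, so introns
and stop codons inside the annotation count toward the span.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from plastome_compare.io import PlastomeRecord
from plastome_compare.quadripartite import QuadripartitePartition, canonicalize

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class JunctionReport:
    """Placement of one gene relative to one junction.

    ``placement`` is ``spans`` / ``left_of`` / ``right_of`` (left = lower
    canonical coordinate); ``distance`` is bp from the nearest gene end to
    the junction, 0 when the gene abuts or spans it.  ``gene`` is None when
    nothing lies within the flanking window.
    """

    junction: str
    gene: str | None
    placement: str
    distance: int
    overlap_left: int = 0
    overlap_right: int = 0


def _unwrapped_span(feature, n: int) -> tuple[int, int]:
    """Outermost extent in canonical coords, unwrapping an origin-crossing gene.

    A gene whose intervals touch both ends of the linearization (e.g. trnH
    at the IRa/LSC boundary after rotation) is represented with its start
    pushed below zero so that start < end always holds.
    """
    s, e = min(a for a, _ in feature.intervals), max(b for _, b in feature.intervals)
    if e - s > n // 2 and len(feature.intervals) > 1:
        # candidate wrap: intervals hug both ends of the linearization
        head = [iv for iv in feature.intervals if iv[0] < n // 2]
        tail = [iv for iv in feature.intervals if iv[0] >= n // 2]
        if head and tail:
            return (min(a for a, _ in tail) - n, max(b for _, b in head))
    return (s, e)


def junction_report(
    record: PlastomeRecord,
    partition: QuadripartitePartition,
    flank_window: int = 1500,
) -> list[JunctionReport]:
    """Gene placements at the four IR/SC boundaries (one list, JLB->JLA order).

    For each junction: if a gene spans it, that single gene is reported
    (ties on spanning resolved to the gene with the largest overlap into the
    junction, then by name).  Otherwise the nearest gene on each side within
    ``flank_window`` bp is reported; genes tied at the same distance are all
    reported, ordered by coordinate.  Pseudogenes are ignored.
    """
    rec, part = canonicalize(record, partition)
    n = part.genome_length
    spans = []
    for f in rec.features:
        if f.pseudo:
            continue
        spans.append((f, _unwrapped_span(f, n)))

    reports: list[JunctionReport] = []
    for jname in JUNCTION_NAMES:
        p = part.junctions[jname]
        spanning = []
        lefts: list[tuple[int, int, str]] = []  # (distance, start, gene)
        rights: list[tuple[int, int, str]] = []
        for f, (s, e) in spans:
            for q in (p, p - n):  # evaluate junction on both unwrappings
                if s < q < e:
                    spanning.append((min(q - s, e - q), f.name, q - s, e - q, s))
                    break
            else:
                d_left = (p - e) % n   # gene entirely before the junction
                d_right = (s - p) % n  # gene entirely after the junction
                if d_left <= d_right:
                    lefts.append((d_left, s, f.name))
                else:
                    rights.append((d_right, s, f.name))
        if spanning:
            spanning.sort(key=lambda t: (-t[0], t[1]))
            _, name, ol, orr, s = spanning[0]
            reports.append(
                JunctionReport(jname, name, "spans", 0, overlap_left=ol, overlap_right=orr)
            )
            continue
        found = False
        for side, pool in (("left_of", lefts), ("right_of", rights)):
            pool = [t for t in pool if t[0] <= flank_window]
            if not pool:
                continue
            dmin = min(t[0] for t in pool)
            for d, s, name in sorted(t for t in pool if t[0] == dmin):
                reports.append(JunctionReport(jname, name, side, d))
                found = True
        if not found:
            reports.append(JunctionReport(jname, None, "none", 0))
    return reports


def junction_table(
    records_partitions: list[tuple[PlastomeRecord, QuadripartitePartition]],
    flank_window: int = 1500,
) -> pd.DataFrame:
    """Tabular junction report for a panel (one row per accession x entry)."""
    rows = []
    for rec, part in records_partitions:
        for r in junction_report(rec, part, flank_window=flank_window):
            rows.append(
                {
                    "accession": rec.accession,
                    "junction": r.junction,
                    "gene": r.gene if r.gene is not None else ".",
                    "placement": r.placement,
                    "distance": r.distance,
                    "overlap_left": r.overlap_left,
                    "overlap_right": r.overlap_right,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "junction", "gene", "placement",
            "distance", "overlap_left", "overlap_right",
        ],
    )
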