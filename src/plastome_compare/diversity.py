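"""Per-locus nucleotide-diversity statistics, hotspot ranking and windowed identity.

The statistics mirror the classic population-genetics quantities computed by
DnaSP on a multiple alignment:

* S   - segregating (polymorphic) sites
* eta - total number of mutations: a site with k alleles contributes k - 1
* h   - number of distinct haplotypes
* Hd  - haplotype diversity, n/(n-1) * (1 - sum p_k^2)
* pi  - nucleotide diversity per site,
        2/(n(n-1)) * sum_{i<j} d_ij / L_net
* PIC - parsimony-informative columns (>= 2 alleles each in >= 2 sequences)

Under the default complete-deletion gap policy every column containing a
gap or an ambiguous base is removed before anything is counted, so all
statistics share one set of retained columns (L_net).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from plastome_compare.loci import LocusAlignment

_BASES = b"ACGT"


@dataclass(frozen=True)
class DiversityStats:
    """Diversity summary of one locus alignment.

    Statistics are None when no column survives the gap policy (undefined,
    not zero).
    """

    name: str
    category: str
    n: int
    aligned_length: int
    net_length: int
    s_sites: int | None
    eta: int | None
    h: int | None
    hd: float | None
    pi: float | None
    pic: int | None

    def as_row(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "n": self.n,
            "aligned_length": self.aligned_length,
            "net_length": self.net_length,
            "S": self.s_sites,
            "Eta": self.eta,
            "h": self.h,
            "Hd": self.hd,
            "Pi": self.pi,
            "PIC": self.pic,
        }


def _encode(aln: LocusAlignment) -> np.ndarray:
    """Rows as a (n, L) uint8 matrix of ASCII codes, upper-cased."""
    rows = [s.upper().encode("ascii") for s in aln.rows.values()]
    return np.frombuffer(b"".join(rows), dtype=np.uint8).reshape(len(rows), -1)


def diversity_stats(
    aln: LocusAlignment, gap_policy: str = "complete_deletion"
) -> DiversityStats:
    """Compute S, eta, h, Hd, pi and PIC for one locus alignment.

    ``gap_policy='complete_deletion'`` (default) removes every column with a
    gap or ambiguous base first; ``'pairwise_deletion'`` computes pi over
    per-pair comparable columns while the site/haplotype statistics still
    use fully unambiguous columns.
    """
    if aln.n < 2:
        raise ValueError(f"{aln.name}: need >= 2 sequences, have {aln.n}")
    mat = _encode(aln)
    n, L = mat.shape
    unamb = np.isin(mat, np.frombuffer(_BASES, dtype=np.uint8))
    complete = unamb.all(axis=0)
    kept = mat[:, complete]
    L_net = kept.shape[1]
    if L_net == 0:
        return DiversityStats(aln.name, aln.category, n, L, 0,
                              None, None, None, None, None, None)

    # per-column allele counts over the four bases
    counts = np.stack([(kept == b).sum(axis=0) for b in _BASES])  # (4, L_net)
    k_alleles = (counts > 0).sum(axis=0)
    S = int((k_alleles >= 2).sum())
    eta = int((k_alleles - 1).sum())
    pic = int(((counts >= 2).sum(axis=0) >= 2).sum())

    # haplotypes on retained columns
    _, inverse = np.unique(kept, axis=0, return_inverse=True)
    freqs = np.bincount(inverse) / n
    h = int(freqs.size)
    hd = float(n / (n - 1) * (1.0 - np.sum(freqs**2)))

    if gap_policy == "complete_deletion":
        # mean pairwise difference per retained site
        diffs = 0
        for i in range(n - 1):
            diffs += (kept[i] != kept[i + 1 :]).sum()
        pi = float(2.0 * diffs / (n * (n - 1)) / L_net)
    elif gap_policy == "pairwise_deletion":
        num, cnt = 0.0, 0
        for i in range(n - 1):
            both = unamb[i] & unamb[i + 1 :]
            comp_sites = both.sum(axis=1)
            d = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
            ok = comp_sites > 0
            num += (d[ok] / comp_sites[ok]).sum()
            cnt += int(ok.sum())
        pi = float(num / cnt) if cnt else None
    else:
        raise ValueError(f"unknown gap policy {gap_policy!r}")

    return DiversityStats(aln.name, aln.category, n, L, L_net, S, eta, h, hd, pi, pic)


def diversity_table(
    alignments: list[LocusAlignment], gap_policy: str = "complete_deletion"
) -> pd.DataFrame:
    """Diversity statistics for many loci as one DataFrame (input order)."""
    return pd.DataFrame([diversity_stats(a, gap_policy).as_row() for a in alignments])


@dataclass(frozen=True)
class HotspotRanking:
    """Coding and noncoding loci ranked by pi (descending, ties by name)."""

    coding: pd.DataFrame
    noncoding: pd.DataFrame
    rule: str


def rank_hotspots(
    stats: list[DiversityStats] | pd.DataFrame,
    top_coding: int | None = None,
    top_noncoding: int | None = None,
    pi_threshold: float | None = None,
) -> HotspotRanking:
    """Rank loci by nucleotide diversity within each category.

    Selection is either the top-k per category (e.g. the 9 coding + 12
    noncoding barcode candidates) or every locus with pi >= threshold; with
    neither given, full rankings are returned.  Loci with undefined pi are
    excluded.  The applied rule is recorded on the result.
    """
    table = stats if isinstance(stats, pd.DataFrame) else pd.DataFrame(
        [s.as_row() for s in stats]
    )
    table = table.dropna(subset=["Pi"])
    table = table.sort_values(["Pi", "name"], ascending=[False, True], kind="mergesort")
    parts = {}
    for category, top in (("coding", top_coding), ("noncoding", top_noncoding)):
        sub = table[table["category"] == category].reset_index(drop=True)
        if pi_threshold is not None:
            sub = sub[sub["Pi"] >= pi_threshold].reset_index(drop=True)
        elif top is not None:
            sub = sub.head(top)
        parts[category] = sub
    if pi_threshold is not None:
        rule = f"pi >= {pi_threshold}"
    elif top_coding is not None or top_noncoding is not None:
        rule = f"top {top_coding} coding + top {top_noncoding} noncoding by pi"
    else:
        rule = "full ranking by pi"
    return HotspotRanking(parts["coding"], parts["noncoding"], rule)


@dataclass(frozen=True)
class IdentityProfile:
    """Sliding-window percent identity of each row against a reference row."""

    reference: str
    window: int
    step: int
    table: pd.DataFrame  # columns: start, end, <accession>... (percent or NaN)


def identity_profile(
    aln: LocusAlignment,
    reference: str,
    window: int = 100,
    step: int = 25,
) -> IdentityProfile:
    """mVISTA-style windowed identity against a reference genome row.

    Identity per window = matches / (matches + mismatches) * 100 over
    columns where neither the reference nor the query has a gap or
    ambiguity; windows with no comparable column are NaN (undefined).
    """
    if reference not in aln.rows:
        raise ValueError(f"reference {reference!r} not in alignment")
    mat = _encode(aln)
    ids = list(aln.rows.keys())
    ref_i = ids.index(reference)
    unamb = np.isin(mat, np.frombuffer(_BASES, dtype=np.uint8))
    L = mat.shape[1]
    starts = list(range(0, max(L - window, 0) + 1, step))
    if not starts:
        starts = [0]
    rows = []
    for s in starts:
        e = min(s + window, L)
        entry: dict[str, float | int] = {"start": s, "end": e}
        for qi, acc in enumerate(ids):
            if qi == ref_i:
                continue
            both = unamb[ref_i, s:e] & unamb[qi, s:e]
            m = int(both.sum())
            if m == 0:
                entry[acc] = float("nan")
            else:
                matches = int(((mat[ref_i, s:e] == mat[qi, s:e]) & both).sum())
                entry[acc] = 100.0 * matches / m
        rows.append(entry)
    return IdentityProfile(reference, window, step, pd.DataFrame(rows))
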