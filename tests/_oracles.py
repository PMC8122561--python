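"""Naive reference implementations used as independent oracles in tests.

Everything here is deliberately brute force: pure-Python loops over pairs
and columns, no shared code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations

UNAMB = set("ACGT")


def naive_diversity(rows: list[str]) -> dict:
    """S, Eta, h, Hd, Pi, PIC under complete deletion, by direct enumeration."""
    n = len(rows)
    keep = [i for i in range(len(rows[0])) if all(r[i].upper() in UNAMB for r in rows)]
    kept = ["".join(r[i].upper() for i in keep) for r in rows]
    L = len(keep)
    if L == 0:
        return {"S": None, "Eta": None, "h": None, "Hd": None, "Pi": None, "PIC": None,
                "net_length": 0}
    S = eta = pic = 0
    for i in range(L):
        col = [r[i] for r in kept]
        alleles = sorted(set(col))
        if len(alleles) >= 2:
            S += 1
        eta += len(alleles) - 1
        if sum(1 for a in alleles if col.count(a) >= 2) >= 2:
            pic += 1
    haps: dict[str, int] = {}
    for r in kept:
        haps[r] = haps.get(r, 0) + 1
    h = len(haps)
    hd = n / (n - 1) * (1.0 - sum((c / n) ** 2 for c in haps.values()))
    diffs = sum(
        sum(a != b for a, b in zip(kept[i], kept[j]))
        for i, j in combinations(range(n), 2)
    )
    pi = 2.0 * diffs / (n * (n - 1)) / L
    return {"S": S, "Eta": eta, "h": h, "Hd": hd, "Pi": pi, "PIC": pic, "net_length": L}


def naive_p_distance(rows: list[str]) -> list[list[float]]:
    keep = [i for i in range(len(rows[0])) if all(r[i].upper() in UNAMB for r in rows)]
    n = len(rows)
    d = [[0.0] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        diff = sum(rows[i][k].upper() != rows[j][k].upper() for k in keep)
        d[i][j] = d[j][i] = diff / len(keep)
    return d


def naive_filter(alignments, min_len=200, min_variable=1):
    """The hotspot-screen rule applied literally, column by column."""
    kept = []
    for name, rows in alignments:
        L = len(rows[0])
        variable = 0
        for i in range(L):
            alleles = {r[i].upper() for r in rows} & UNAMB
            if len(alleles) >= 2:
                variable += 1
        if L > min_len and variable >= min_variable:
            kept.append(name)
    return kept
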