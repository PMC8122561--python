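"""p-distance matrices and neighbor-joining trees.

Deliberately lightweight phylogenetic plumbing for sanity-checking locus
outputs end-to-end: uncorrected p-distances plus a standard NJ tree.
Likelihood/Bayesian inference is out of scope and should be done with
dedicated tools on exported alignments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from plastome_compare.diversity import _encode
from plastome_compare.loci import LocusAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def p_distance_matrix(aln: LocusAlignment) -> DistanceMatrix:
    """Uncorrected pairwise distances over complete-deletion columns.

    d_ij = differing columns / retained columns, where retained columns are
    those unambiguous in every row.  Labels are sorted so downstream
    tie-breaking is by accession order.
    """
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    ids = sorted(aln.rows)
    ordered = LocusAlignment(aln.name, aln.category, {i: aln.rows[i] for i in ids})
    mat = _encode(ordered)
    keep = np.isin(mat, _BASES).all(axis=0)
    kept = mat[:, keep]
    if kept.shape[1] == 0:
        raise ValueError("no columns retained under complete deletion")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = (kept[i] != kept[i + 1 :]).mean(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(d, ids=ids)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string.

    Negative branch lengths are clamped at zero; input labels are processed
    in sorted order, which fixes tie-breaking deterministically.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ids = sorted(dm.ids)
    dm = dm.filter(ids)
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-style TSV: first line taxon count, then label + row values."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")
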