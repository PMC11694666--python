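"""Dice-distance proteomic trees from summed protein-homology bitscores.

Whole-proteome relatedness between two genomes A and B is summarized as

    distance(A, B) = 1 - 2 * AB / (AA + BB)

where AB is the summed bitscore of all protein matches between A and B and
AA, BB are the summed self-match bitscores.  Identical proteomes give 0;
genomes sharing no homologs give 1, because the self terms remain.  The
distance matrix feeds the Saitou-Nei neighbor-joining algorithm, which is
exact on additive matrices; the tree is serialized as Newick.

Directed bitscore sums (A->B vs B->A searches) are symmetrized by their
mean; pairs never observed are treated as AB = 0, i.e. distance 1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "dice_distance",
    "build_distance_matrix",
    "neighbor_joining",
    "newick_path_distances",
]


def dice_distance(ab: float, aa: float, bb: float) -> float:
    """Dice distance from summed bitscores, clipped into [0, 1].

    Raises on non-positive self scores (every genome matches itself).  Raw
    cross sums occasionally exceed the Dice bound through asymmetric search
    artefacts; such pairs are treated as identical (distance 0).
    """
    if aa <= 0 or bb <= 0:
        raise ValueError(f"self scores must be positive (got AA={aa}, BB={bb})")
    if ab < 0:
        raise ValueError("cross score must be non-negative")
    return max(0.0, 1.0 - 2.0 * ab / (aa + bb))


def build_distance_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Dice distance matrix from a long bitscore table.

    *scores* has columns ``query_genome, subject_genome, summed_bitscore``
    and must contain a self row for every genome; the genome set is taken
    from the self rows.  Directed cross sums are averaged; missing pairs
    count as 0 (distance 1).  The diagonal is 0 by construction.
    """
    s = scores.set_index(["query_genome", "subject_genome"])["summed_bitscore"]
    genomes = sorted({q for q, t in s.index if q == t})
    referenced = {g for pair in s.index for g in pair}
    missing_self = referenced - set(genomes)
    if missing_self:
        raise ValueError(f"genomes without self scores: {sorted(missing_self)[:5]}")
    self_score = {g: float(s[(g, g)]) for g in genomes}
    n = len(genomes)
    d = np.zeros((n, n))
    for i, a in enumerate(genomes):
        for j in range(i + 1, n):
            b = genomes[j]
            ab = (float(s.get((a, b), 0.0)) + float(s.get((b, a), 0.0))) / 2.0
            d[i, j] = d[j, i] = dice_distance(ab, self_score[a], self_score[b])
    return pd.DataFrame(d, index=genomes, columns=genomes)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def neighbor_joining(distance: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining, returned as an unrooted Newick string.

    At each step the pair minimizing the Q criterion
    ``(n - 2) d_ij - r_i - r_j`` is joined; ties are broken by the
    lexicographically smallest (id, id) pair so the output is deterministic.
    A negative branch length is clamped to zero and its deficit moved to the
    sibling branch, preserving the path length through the new node.  The
    last three lineages are joined at an unresolved central node with the
    closed-form three-point lengths.  Exact on additive matrices.
    """
    d = distance.copy().astype(float)
    if not np.allclose(d.to_numpy(), d.to_numpy().T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if len(d) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    newick: dict[str, str] = {t: str(t) for t in d.index}
    active = sorted(d.index)
    k = 0
    while len(active) > 3:
        n = len(active)
        sub = d.loc[active, active]
        r = sub.sum(axis=1)
        best, best_pair = np.inf, None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * sub.at[a, b] - r[a] - r[b]
                if q < best - 1e-12:
                    best, best_pair = q, (a, b)
        a, b = best_pair
        va = sub.at[a, b] / 2 + (r[a] - r[b]) / (2 * (n - 2))
        vb = sub.at[a, b] - va
        if va < 0:
            vb, va = vb + va, 0.0
        if vb < 0:
            va, vb = va + vb, 0.0
        u = f"_nj{k}"
        k += 1
        newick[u] = f"({newick[a]}:{_fmt(va)},{newick[b]}:{_fmt(vb)})"
        new_row = {c: (sub.at[a, c] + sub.at[b, c] - sub.at[a, b]) / 2
                   for c in active if c not in (a, b)}
        d.loc[u, :] = 0.0
        d.loc[:, u] = 0.0
        for c, val in new_row.items():
            d.at[u, c] = d.at[c, u] = val
        active = sorted(c for c in active if c not in (a, b)) + [u]
        active.sort(key=str)
    a, b, c = sorted(active, key=str)
    dab, dac, dbc = d.at[a, b], d.at[a, c], d.at[b, c]
    va = max(0.0, (dab + dac - dbc) / 2)
    vb = max(0.0, (dab + dbc - dac) / 2)
    vc = max(0.0, (dac + dbc - dab) / 2)
    return f"({newick[a]}:{_fmt(va)},{newick[b]}:{_fmt(vb)},{newick[c]}:{_fmt(vc)});"


def newick_path_distances(newick: str, taxa: list[str] | None = None) -> pd.DataFrame:
    """Patristic (path-sum) distances between all leaf pairs of a Newick tree."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(t.label for t in tree.taxon_namespace)
    if taxa is not None:
        leaves = [t for t in taxa if t in leaves]
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    taxon_by_label = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            dist = pdm.patristic_distance(taxon_by_label[a], taxon_by_label[b])
            out.at[a, b] = out.at[b, a] = dist
    return out
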