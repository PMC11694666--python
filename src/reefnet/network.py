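"""Bipartite structure of the virus-host interaction network.

The unique-pair table becomes a hosts x viruses binary incidence matrix, on
which four families of statistics are computed:

* **NODF** (nestedness by overlap and decreasing fill): mean, over all row
  pairs and column pairs with strictly decreasing marginal totals, of the
  fraction of the sparser line's presences shared with the denser line.
  Reported on a 0-1 scale.
* **Nestedness temperature**: the matrix is packed by descending marginal
  totals, a straight isocline ``x + y = c`` is placed so the area above-left
  of it equals the fill, and T is 100 x the squared-distance mass of
  unexpected presences/absences relative to the worst case in which every
  cell is unexpected.  T = 0 is perfectly nested; the nestedness score is
  ``1 - T/100``.
* **SS null model**: size and fill are conserved while the positions of the
  1s are shuffled uniformly over all cells; empirical p-values use the
  standard (1 + exceedances) / (1 + permutations) estimator.
* **Barber bipartite modularity** ``Q = (1/m) sum_ij (A_ij - k_i d_j / m)
  delta(g_i, g_j)`` maximized over joint host/virus module assignments by
  label propagation with single-node refinement and agglomerative module
  merging (LPAwb+ style), best of several seeded restarts.  The normalized
  score divides by the Q of an idealized matrix with the same marginals and
  all edges within modules.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "build_matrix",
    "network_from_link_table",
    "nodf",
    "nestedness_temperature",
    "null_model_ss",
    "barber_modularity",
    "modularity_score",
    "exhaustive_modularity",
    "degree_stats",
    "NetworkMetrics",
    "compute_network_metrics",
]


# --------------------------------------------------------------------------
# matrix construction
# --------------------------------------------------------------------------

def build_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Hosts x viruses binary incidence matrix from a unique-pair table.

    Rows and columns are ordered lexicographically; duplicate pair rows
    collapse to a single 1.  Needs columns ``virus_pop_id`` and
    ``host_species_id`` (or ``virus_id`` / ``host_id``).
    """
    if len(pairs) == 0:
        raise ValueError("cannot build an incidence matrix from zero pairs")
    vcol = "virus_pop_id" if "virus_pop_id" in pairs.columns else "virus_id"
    hcol = "host_species_id" if "host_species_id" in pairs.columns else "host_id"
    hosts = sorted(pairs[hcol].unique())
    viruses = sorted(pairs[vcol].unique())
    mat = pd.DataFrame(0, index=hosts, columns=viruses, dtype=int)
    for _, row in pairs.iterrows():
        mat.at[row[hcol], row[vcol]] = 1
    return mat


def network_from_link_table(path, virus_col: str | None = None,
                            host_col: str | None = None) -> pd.DataFrame:
    """Build the incidence matrix straight from an on-disk link table.

    Accepts a TSV/CSV with one row per link; the virus and host columns are
    auto-detected (first column name containing ``virus``/``vmag`` and
    ``host``/``bmag``, case-insensitive) unless given explicitly.  Use this
    to recompute network statistics from externally published link tables.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    def _find(keys):
        for c in df.columns:
            if any(k in c.lower() for k in keys):
                return c
        raise ValueError(f"no column matching {keys} in {list(df.columns)}")
    vcol = virus_col or _find(("virus", "vmag", "phage"))
    hcol = host_col or _find(("host", "bmag", "bacter"))
    pairs = df[[vcol, hcol]].rename(columns={vcol: "virus_pop_id", hcol: "host_species_id"})
    return build_matrix(pairs.drop_duplicates())


def _as_array(matrix) -> np.ndarray:
    a = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    return (a > 0).astype(float)


# --------------------------------------------------------------------------
# nestedness
# --------------------------------------------------------------------------

def _nodf_lines(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired overlaps over ordered row pairs with decreasing fill."""
    fills = a.sum(axis=1)
    overlap = a @ a.T
    total = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if fills[i] > fills[j] and fills[j] > 0:
                total += overlap[i, j] / fills[j]
    return total, n * (n - 1) // 2


def nodf(matrix) -> float:
    """Nestedness by overlap and decreasing fill, on a 0-1 scale.

    Pairs of lines with equal marginal totals contribute zero; a pair with
    strictly decreasing totals contributes the fraction of the sparser
    line's 1s that also appear in the denser line.  The result averages over
    all row pairs and all column pairs together.
    """
    a = _as_array(matrix)
    if a.size == 0:
        raise ValueError("empty matrix")
    row_sum, row_pairs = _nodf_lines(a)
    col_sum, col_pairs = _nodf_lines(a.T)
    n_pairs = row_pairs + col_pairs
    return (row_sum + col_sum) / n_pairs if n_pairs else 0.0


def _tie_blocks(totals: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Packing order by descending totals; lines index -> block positions.

    Returns for each line the array of packed positions occupied by its
    tie block (lines with equal totals are interchangeable in a packing
    sorted by totals, so each owns the whole block of positions).
    """
    order = np.argsort(-totals, kind="stable")
    positions = np.empty(len(totals), dtype=int)
    positions[order] = np.arange(len(totals))
    blocks: dict[float, np.ndarray] = {
        t: np.sort(positions[totals == t]) for t in np.unique(totals)
    }
    return positions, [blocks[t] for t in totals]


def nestedness_temperature(matrix) -> tuple[float, float]:
    """(temperature in [0, 100], nestedness score = 1 - T/100).

    The matrix is packed by descending marginal totals and each cell placed
    at the center of its unit-square patch; the isocline is the straight
    line ``x + y = c`` with the above-left area equal to the fill, so a
    perfectly nested packed matrix has presences exactly where the isocline
    expects them.  Presences below and absences above the isocline are
    "unexpected"; T is the ratio of their squared distances to the isocline
    over the same sum taken over all cells (the all-unexpected worst case),
    times 100.

    Lines with equal totals have no canonical packing order, so their
    contribution is the expected one over a uniformly random arrangement of
    the tied lines — this makes T exactly invariant to row and column
    permutations of the input.  Degenerate all-ones or all-zeros matrices
    have T = 0 by convention.
    """
    a = _as_array(matrix)
    if a.size == 0:
        raise ValueError("empty matrix")
    m, n = a.shape
    p = a.sum() / a.size
    if p in (0.0, 1.0):
        return 0.0, 1.0
    c = np.sqrt(2 * p) if p <= 0.5 else 2 - np.sqrt(2 * (1 - p))
    x = (np.arange(n) + 0.5) / n
    y = (np.arange(m) + 0.5) / m
    s = y[:, None] + x[None, :] - c       # signed distance along the diagonal
    d2 = s**2
    # per position-block pair: mean unexpectedness of a presence / an absence
    _, row_blocks = _tie_blocks(a.sum(axis=1))
    _, col_blocks = _tie_blocks(a.sum(axis=0))
    cache: dict[tuple[bytes, bytes], tuple[float, float]] = {}
    total = 0.0
    for i in range(m):
        for j in range(n):
            key = (row_blocks[i].tobytes(), col_blocks[j].tobytes())
            if key not in cache:
                sub_s = s[np.ix_(row_blocks[i], col_blocks[j])]
                sub_d2 = d2[np.ix_(row_blocks[i], col_blocks[j])]
                size = sub_s.size
                cache[key] = (
                    float(sub_d2[sub_s > 0].sum() / size),   # unexpected presence
                    float(sub_d2[sub_s <= 0].sum() / size),  # unexpected absence
                )
            pres, absent = cache[key]
            total += pres if a[i, j] else absent
    denom = d2.sum()
    t = 100.0 * total / denom if denom > 0 else 0.0
    return float(t), float(1.0 - t / 100.0)


def null_model_ss(matrix, metric, n_permutations: int = 999, seed: int = 0,
                  alternative: str = "greater") -> float:
    """Permutation p-value under the size-and-fill-conserving (SS) null.

    Each permutation scatters the observed number of 1s uniformly over the
    cells of an equally sized matrix and re-evaluates *metric*.  The p-value
    is ``(1 + #{null >= observed}) / (1 + n_permutations)`` (``<=`` for
    ``alternative="less"``), deterministic given *seed*.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    a = _as_array(matrix)
    rng = np.random.default_rng(seed)
    observed = metric(a)
    n_cells = a.size
    fill = int(a.sum())
    exceed = 0
    for _ in range(n_permutations):
        null = np.zeros(n_cells)
        null[rng.choice(n_cells, size=fill, replace=False)] = 1.0
        value = metric(null.reshape(a.shape))
        if alternative == "greater":
            exceed += value >= observed
        else:
            exceed += value <= observed
    return (1 + exceed) / (1 + n_permutations)


# --------------------------------------------------------------------------
# Barber modularity
# --------------------------------------------------------------------------

def modularity_score(a: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber's bipartite Q for a given joint module assignment."""
    m = a.sum()
    if m == 0:
        return 0.0
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    b = a - np.outer(k, d) / m
    delta = row_labels[:, None] == col_labels[None, :]
    return float((b * delta).sum() / m)


def _qmax(a: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Q of the idealized all-within-module matrix with the same marginals."""
    m = a.sum()
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    total = 0.0
    for mod in np.unique(np.concatenate([row_labels, col_labels])):
        total += k[row_labels == mod].sum() * d[col_labels == mod].sum()
    return float(1.0 - total / m**2)


def _relabel(row_labels: np.ndarray, col_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Renumber modules contiguously from 1, ordered by first appearance."""
    joint = np.concatenate([row_labels, col_labels])
    order = {lab: i + 1 for i, lab in enumerate(dict.fromkeys(joint))}
    rl = np.array([order[l] for l in row_labels])
    cl = np.array([order[l] for l in col_labels])
    return rl, cl, len(order)


def _propagate(b: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray,
               max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Alternating best-label moves for rows and columns until stable."""
    n_rows, n_cols = b.shape
    for _ in range(max_iter):
        moved = False
        for side in (0, 1):
            own, other, scores = (
                (row_labels, col_labels, b) if side == 0 else (col_labels, row_labels, b.T)
            )
            labels = np.unique(other)
            # gain of joining module t = sum of B over the other side's members of t
            gains = np.stack([scores[:, other == t].sum(axis=1) for t in labels], axis=1)
            best = gains.argmax(axis=1)
            for i in range(len(own)):
                g = gains[i, best[i]]
                target = labels[best[i]]
                if g > 0 and target != own[i]:
                    own[i] = target
                    moved = True
                elif g <= 0 and not np.any(other == own[i]):
                    pass  # isolated node keeps its own label
        if not moved:
            break
    return row_labels, col_labels


def _agglomerate(a: np.ndarray, row_labels: np.ndarray, col_labels: np.ndarray) -> None:
    """Greedy module merging while any merge increases Q (in place)."""
    m = a.sum()
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    b = a - np.outer(k, d) / m
    while True:
        labels = list(dict.fromkeys(np.concatenate([row_labels, col_labels])))
        best_gain, best_pair = 0.0, None
        for s, t in itertools.combinations(labels, 2):
            rs, cs = row_labels == s, col_labels == s
            rt, ct = row_labels == t, col_labels == t
            gain = b[np.ix_(rs, ct)].sum() + b[np.ix_(rt, cs)].sum()
            if gain > best_gain + 1e-12:
                best_gain, best_pair = gain, (s, t)
        if best_pair is None:
            break
        s, t = best_pair
        row_labels[row_labels == t] = s
        col_labels[col_labels == t] = s


def _dissolve_single_side_modules(b: np.ndarray, row_labels: np.ndarray,
                                  col_labels: np.ndarray) -> None:
    """Fold modules containing only rows or only columns into neighbours.

    Such modules contribute nothing to Q; their nodes join the mixed module
    with the highest non-negative gain (a zero-gain move keeps Q unchanged
    but avoids spurious module counts on structureless matrices).
    """
    for own, other, scores in ((row_labels, col_labels, b),
                               (col_labels, row_labels, b.T)):
        other_set = set(other)
        labels = np.array(sorted(other_set))
        if labels.size == 0:
            continue
        for i in range(len(own)):
            if own[i] in other_set:
                continue  # mixed module
            gains = np.array([scores[i, other == t].sum() for t in labels])
            if gains.max() >= 0:
                own[i] = labels[int(gains.argmax())]


def barber_modularity(matrix, n_restarts: int = 20, seed: int = 0,
                      max_iter: int = 100) -> dict:
    """Maximize Barber bipartite modularity over joint module assignments.

    Label-propagation with single-node refinement and agglomerative merging,
    best of *n_restarts* randomized initializations (restart 0 is the
    deterministic one-module-per-row start).  Returns a dict with ``q``
    (Barber Q of the best partition), ``q_normalized`` (Q / Q of the
    idealized fully-within-module matrix with the same marginals; defined as
    0 when that ideal Q is 0), ``n_modules`` and ``modules`` mapping
    row/column ids to contiguous module ids starting at 1.
    """
    labels_df = isinstance(matrix, pd.DataFrame)
    a = _as_array(matrix)
    if a.size == 0 or a.sum() == 0:
        raise ValueError("empty matrix")
    n_rows, n_cols = a.shape
    m = a.sum()
    b = a - np.outer(a.sum(axis=1), a.sum(axis=0)) / m
    rng = np.random.default_rng(seed)

    best_q, best = -np.inf, None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            row_labels = np.arange(n_rows)
        else:
            row_labels = rng.integers(0, n_rows, size=n_rows)
        col_labels = np.full(n_cols, -1)
        # seed columns on their best row label
        for j in range(n_cols):
            gains = np.array([b[row_labels == t, j].sum() for t in np.unique(row_labels)])
            col_labels[j] = np.unique(row_labels)[gains.argmax()]
        row_labels, col_labels = _propagate(b, row_labels, col_labels, max_iter)
        _agglomerate(a, row_labels, col_labels)
        row_labels, col_labels = _propagate(b, row_labels, col_labels, max_iter)
        _dissolve_single_side_modules(b, row_labels, col_labels)
        q = modularity_score(a, row_labels, col_labels)
        if q > best_q + 1e-12:
            best_q, best = q, (row_labels.copy(), col_labels.copy())

    row_labels, col_labels, n_modules = _relabel(*best)
    qmax = _qmax(a, row_labels, col_labels)
    # rounding can push the ratio a ulp past 1 on perfectly modular input
    q_norm = min(1.0, max(0.0, best_q / qmax)) if qmax > 1e-12 else 0.0
    if labels_df:
        modules = {**{str(r): int(l) for r, l in zip(matrix.index, row_labels)},
                   **{str(c): int(l) for c, l in zip(matrix.columns, col_labels)}}
    else:
        modules = {**{f"row{i}": int(l) for i, l in enumerate(row_labels)},
                   **{f"col{j}": int(l) for j, l in enumerate(col_labels)}}
    return {"q": float(best_q), "q_normalized": float(q_norm),
            "n_modules": int(n_modules), "modules": modules}


def _set_partitions(n: int):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def exhaustive_modularity(matrix) -> float:
    """Global maximum of Barber Q by brute force over all joint partitions.

    Only feasible for tiny matrices (rows + columns <= ~10); serves as the
    independent oracle for the heuristic optimizer.
    """
    a = _as_array(matrix)
    n_rows, n_cols = a.shape
    best = -np.inf
    for labels in _set_partitions(n_rows + n_cols):
        q = modularity_score(a, labels[:n_rows], labels[n_rows:])
        best = max(best, q)
    return float(best)


# --------------------------------------------------------------------------
# degree statistics
# --------------------------------------------------------------------------

def degree_stats(matrix: pd.DataFrame, host_class: dict[str, str] | None = None) -> dict:
    """Specialist/generalist structure of the virus side of the network.

    A specialist virus interacts with exactly one host.  Returns the
    specialist percentage (one decimal), the generalists with their host
    sets, and — when a host-to-class mapping is given — how many generalists
    span more than one host class.
    """
    a = _as_array(matrix)
    degrees = a.sum(axis=0)
    viruses = list(matrix.columns)
    hosts = np.array(matrix.index)
    generalists = {
        viruses[j]: sorted(hosts[a[:, j] > 0]) for j in range(len(viruses)) if degrees[j] >= 2
    }
    n = len(viruses)
    specialist_percent = round(100.0 * (n - len(generalists)) / n, 1) if n else 0.0
    out = {
        "n_viruses": n,
        "n_hosts": len(hosts),
        "specialist_percent": specialist_percent,
        "n_generalists": len(generalists),
        "generalists": generalists,
        "host_degree_one_percent": round(
            100.0 * (a.sum(axis=1) == 1).sum() / len(hosts), 1) if len(hosts) else 0.0,
    }
    if host_class is not None:
        out["cross_class_generalists"] = sum(
            len({host_class[h] for h in hs}) > 1 for hs in generalists.values()
        )
    return out


# --------------------------------------------------------------------------
# bundled metrics
# --------------------------------------------------------------------------

@dataclass
class NetworkMetrics:
    """All network statistics for one incidence matrix, JSON-serializable."""

    nodf: float
    temperature: float
    nestedness_score: float
    q_barber: float
    q_normalized: float
    n_modules: int
    module_assignment: dict[str, int]
    p_values: dict[str, float]
    n_permutations: int
    n_restarts: int
    seed: int
    degree: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compute_network_metrics(matrix: pd.DataFrame, n_permutations: int = 999,
                            n_restarts: int = 20, seed: int = 0) -> NetworkMetrics:
    """NODF, temperature, modularity and SS-null p-values in one pass."""
    mod = barber_modularity(matrix, n_restarts=n_restarts, seed=seed)
    t, score = nestedness_temperature(matrix)
    p_nodf = null_model_ss(matrix, nodf, n_permutations, seed=seed + 1)
    p_temp = null_model_ss(matrix, lambda a: nestedness_temperature(a)[1],
                           n_permutations, seed=seed + 2)
    return NetworkMetrics(
        nodf=nodf(matrix),
        temperature=t,
        nestedness_score=score,
        q_barber=mod["q"],
        q_normalized=mod["q_normalized"],
        n_modules=mod["n_modules"],
        module_assignment=mod["modules"],
        p_values={"nodf": p_nodf, "nestedness_score": p_temp},
        n_permutations=n_permutations,
        n_restarts=n_restarts,
        seed=seed,
        degree=degree_stats(matrix),
    )
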