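"""VHR quartile categories, group comparisons, and metabolic-module enrichment.

Per-pair median virus-to-host ratios (free and cell-associated fractions)
are split at their lower and upper quartiles, computed by default on a
log10 scale since VHRs span decades.  The quartile lines partition pairs
into four corner categories plus a middle class:

1. low cell-associated VHR, high free VHR (stable particles, slow decay);
2. high VHR in both fractions (productive lytic infections);
3. low VHR in both fractions (low production, prophage-enriched hosts);
4. high cell-associated VHR, low free VHR (fast decay or long latency);

with "high" strictly above Q3 and "low" strictly below Q1 (points on the
lines are middle).  Abundance differences between lifestyle/link groups use
a Shapiro-Wilk normality gate, a Kruskal-Wallis omnibus, and pairwise
two-sided Wilcoxon rank-sum tests summarized as compact letter groupings.
Metabolic-module presence follows the genome-class rules (bacteria: >=50%
of a module's steps or at least three; viruses: any step, zero
contamination) and category enrichment is reported as frequency differences
against the middle-VHR hosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VhrThresholds",
    "vhr_quartiles",
    "classify_pairs",
    "compare_groups",
    "module_presence",
    "category_enrichment",
]

CATEGORIES = ("1", "2", "3", "4", "middle")


@dataclass(frozen=True)
class VhrThresholds:
    """Lower/upper quartiles of per-pair VHRs, one pair per fraction.

    Stored on the scale they were computed on (``log10`` by default).
    """

    q1_free: float
    q3_free: float
    q1_cell: float
    q3_cell: float
    scale: str = "log10"

    def __post_init__(self) -> None:
        if self.q1_free > self.q3_free or self.q1_cell > self.q3_cell:
            raise ValueError("lower quartile exceeds upper quartile")


def _to_scale(values: pd.Series, scale: str) -> pd.Series:
    if scale == "log10":
        if (values <= 0).any():
            raise ValueError("log10 scale requires strictly positive VHRs")
        return np.log10(values)
    if scale == "linear":
        return values
    raise ValueError("scale must be 'log10' or 'linear'")


def vhr_quartiles(pairs: pd.DataFrame, scale: str = "log10") -> VhrThresholds:
    """Q1/Q3 of per-pair median VHRs, pooled across pairs, per fraction.

    *pairs* is the per-pair median table (columns ``vhr_free``,
    ``vhr_cell``); quartiles use linear interpolation between order
    statistics.  Requires at least four pairs with defined VHRs in both
    fractions.
    """
    ok = pairs.dropna(subset=["vhr_free", "vhr_cell"])
    if len(ok) < 4:
        raise ValueError(f"need >= 4 pairs with defined VHRs, have {len(ok)}")
    free = _to_scale(ok["vhr_free"], scale)
    cell = _to_scale(ok["vhr_cell"], scale)
    q1f, q3f = np.percentile(free, [25, 75])
    q1c, q3c = np.percentile(cell, [25, 75])
    return VhrThresholds(float(q1f), float(q3f), float(q1c), float(q3c), scale)


def classify_pairs(pairs: pd.DataFrame, thresholds: VhrThresholds) -> pd.DataFrame:
    """Assign each pair to one of the four VHR corner categories or "middle".

    High means strictly above the upper quartile, low strictly below the
    lower quartile, in the same scale the thresholds were computed on.
    Every pair with defined VHRs in both fractions receives exactly one
    label; pairs with undefined VHRs get ``NaN``.
    """
    out = pairs.copy()
    free = _to_scale(out["vhr_free"].where(out["vhr_free"] > 0), thresholds.scale) \
        if thresholds.scale == "log10" else out["vhr_free"]
    cell = _to_scale(out["vhr_cell"].where(out["vhr_cell"] > 0), thresholds.scale) \
        if thresholds.scale == "log10" else out["vhr_cell"]
    high_f, low_f = free > thresholds.q3_free, free < thresholds.q1_free
    high_c, low_c = cell > thresholds.q3_cell, cell < thresholds.q1_cell
    category = pd.Series("middle", index=out.index)
    category[low_c & high_f] = "1"
    category[high_c & high_f] = "2"
    category[low_c & low_f] = "3"
    category[high_c & low_f] = "4"
    category[free.isna() | cell.isna()] = np.nan
    out["category"] = category
    return out


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def _compact_letters(groups: Sequence[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinct.

    Insert-and-absorb: start with one letter covering everything, then split
    letters that join a significantly different pair.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in sorted(distinct):
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if cand and not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[str, str] = {g: "" for g in groups}
    for letter, members in zip(alphabet, letter_sets):
        for g in sorted(members):
            assignment[g] += letter
    return assignment


def _ranksum_exact_cutoff(n1: int, n2: int) -> bool:
    return n1 <= 25 and n2 <= 25


def compare_groups(values: Mapping[str, Sequence[float]] | pd.DataFrame,
                   value_col: str | None = None, group_col: str | None = None,
                   alpha: float = 0.05, holm: bool = False) -> dict:
    """Nonparametric comparison of two or more groups of abundances or VHRs.

    Runs a Shapiro-Wilk normality check per group (reported, and the reason
    the nonparametric path is taken), a Kruskal-Wallis omnibus test, then
    all pairwise two-sided Wilcoxon rank-sum tests.  The exact null
    distribution is used for groups of <= 25 observations without ties,
    otherwise the normal approximation with continuity correction.  Pairs
    with p < *alpha* (Holm-adjusted when ``holm=True``) are declared
    distinct and summarized as a compact letter display.

    *values* is either a mapping of group label -> observations or a long
    DataFrame with *value_col* and *group_col*.
    """
    if isinstance(values, pd.DataFrame):
        if value_col is None or group_col is None:
            raise ValueError("value_col and group_col required with a DataFrame")
        data = {g: sub[value_col].to_numpy(dtype=float)
                for g, sub in values.groupby(group_col)}
    else:
        data = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    shapiro = {}
    for g, v in data.items():
        if len(v) >= 3 and np.ptp(v) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapiro[g] = float(stats.shapiro(v).pvalue)
        else:
            shapiro[g] = float("nan")

    kw_stat, kw_p = stats.kruskal(*data.values())

    names = sorted(data)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = data[a], data[b]
            ties = len(np.unique(np.concatenate([va, vb]))) < len(va) + len(vb)
            if _ranksum_exact_cutoff(len(va), len(vb)) and not ties:
                method = "exact"
            else:
                method = "asymptotic"
            res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method,
                                     use_continuity=True)
            pairwise[(a, b)] = float(res.pvalue)

    p_adj = dict(pairwise)
    if holm and pairwise:
        order = sorted(pairwise, key=pairwise.get)
        m = len(order)
        running = 0.0
        for rank, key in enumerate(order):
            running = max(running, (m - rank) * pairwise[key])
            p_adj[key] = min(1.0, running)

    distinct = {pair for pair, p in p_adj.items() if p < alpha}
    letters = _compact_letters(names, distinct)
    return {
        "shapiro_p": shapiro,
        "kruskal": {"statistic": float(kw_stat), "p_value": float(kw_p)},
        "wilcoxon_p": {f"{a}|{b}": p for (a, b), p in pairwise.items()},
        "wilcoxon_p_adjusted": {f"{a}|{b}": p for (a, b), p in p_adj.items()},
        "letters": letters,
        "alpha": alpha,
        "holm": holm,
    }


# --------------------------------------------------------------------------
# metabolic modules
# --------------------------------------------------------------------------

def module_presence(step_annotations: Mapping[str, set[str]],
                    module_steps: Mapping[str, Sequence[str]],
                    entity_kind: str,
                    contamination: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Entities x modules boolean presence matrix.

    Bacterial genomes carry a module when they encode at least half of its
    steps or a minimum of three.  Viral genomes carry a module when they
    encode at least one step, and genomes with nonzero estimated
    contamination are excluded entirely (their rows are dropped).  Annotated
    steps not belonging to any module definition are ignored with a warning.
    """
    if entity_kind not in ("bMAG", "vMAG"):
        raise ValueError("entity_kind must be 'bMAG' or 'vMAG'")
    known_steps = {s for steps in module_steps.values() for s in steps}
    entities = sorted(step_annotations)
    if entity_kind == "vMAG" and contamination is not None:
        entities = [e for e in entities if contamination.get(e, 0.0) == 0.0]
    stray = {s for e in entities for s in step_annotations[e]} - known_steps
    if stray:
        warnings.warn(f"ignoring {len(stray)} annotated steps outside all module "
                      f"definitions (e.g. {sorted(stray)[:3]})")
    rows = {}
    for e in entities:
        found = set(step_annotations[e])
        row = {}
        for mod, steps in module_steps.items():
            n_found = len(found & set(steps))
            if entity_kind == "bMAG":
                row[mod] = (n_found / len(steps) >= 0.5) or (n_found >= 3)
            else:
                row[mod] = n_found >= 1
        rows[e] = row
    return pd.DataFrame.from_dict(rows, orient="index", dtype=bool).sort_index()


def category_enrichment(presence: pd.DataFrame,
                        host_categories: Mapping[str, str],
                        virus_presence: pd.DataFrame | None = None,
                        pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Module frequency differences of each VHR category against the middle.

    For each module and each non-middle category, the difference is the
    module frequency among the category's hosts minus its frequency among
    middle-VHR hosts.  When viral presence and the pair table are supplied,
    a ``shared_with_virus`` column flags modules carried by both a linked
    virus and its host anywhere in the network.
    """
    cats = pd.Series(host_categories)
    cats = cats[cats.index.isin(presence.index)]
    middle_hosts = cats.index[cats == "middle"]
    if len(middle_hosts) == 0:
        raise ValueError("middle category is empty; enrichment baseline undefined")
    baseline = presence.loc[middle_hosts].mean(axis=0)
    records = []
    for cat in sorted(set(cats) - {"middle"}):
        hosts = cats.index[cats == cat]
        if len(hosts) == 0:
            continue
        freq = presence.loc[hosts].mean(axis=0)
        for mod in presence.columns:
            records.append((mod, cat, float(freq[mod]), float(baseline[mod]),
                            float(freq[mod] - baseline[mod])))
    out = pd.DataFrame(records, columns=["module_id", "category", "frequency",
                                         "middle_frequency", "difference"])
    if virus_presence is not None and pairs is not None:
        shared = set()
        for _, p in pairs.iterrows():
            v, h = p["virus_pop_id"], p["host_species_id"]
            if v in virus_presence.index and h in presence.index:
                both = presence.columns[
                    presence.loc[h] & virus_presence.loc[v].reindex(presence.columns,
                                                                    fill_value=False)]
                shared.update(both)
        out["shared_with_virus"] = out["module_id"].isin(shared)
    return out
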