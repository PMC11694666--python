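"""Microscopy-scaled abundance estimation and virus-to-host ratios.

Mapped-read counts are converted to genome-length-normalized relative
abundances per sample (an RPKM-proportional estimator: reads/length,
renormalized to sum to one), then multiplied by direct epifluorescence
microscopy counts — VLP/ml for viral entities, cells/ml for bacterial
entities — to give genome copies per ml of seawater.  Per linked pair, the
virus-to-host ratio (VHR) is computed separately in the free (<0.45 um) and
cell-associated (>0.22 um) fractions; the cell-associated VHR serves as the
proxy for ongoing viral production.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_abundance",
    "scale_by_microscopy",
    "compute_vhr",
    "pair_median_vhr",
    "rank_statistics",
    "read_microscopy",
]


def read_microscopy(path) -> pd.DataFrame:
    """Read a microscopy CSV (sample_id, vlp_per_ml, cells_per_ml) and add VMR."""
    micro = pd.read_csv(path).set_index("sample_id")
    if (micro[["vlp_per_ml", "cells_per_ml"]] <= 0).any().any():
        raise ValueError("microscopy counts must be positive")
    micro["vmr"] = micro["vlp_per_ml"] / micro["cells_per_ml"]
    return micro


def relative_abundance(
    counts: pd.DataFrame,
    genome_lengths: Mapping[str, int] | pd.Series,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Length-normalized relative abundance per sample.

    *counts* is long-form (``entity_id``, ``sample_id``, ``reads``).  Within
    each sample, ``weight = reads / genome_length`` and
    ``relative = weight / sum(weights)``; the fraction of raw reads
    (``fractional``) is reported alongside.  *pseudocount* reads can be added
    to every entity before normalization (the zero-count alternative used
    when downstream ratios must stay defined).

    Raises if any entity lacks a length or a sample has no reads at all.
    """
    lengths = pd.Series(genome_lengths, dtype=float)
    missing = set(counts["entity_id"].unique()) - set(lengths.index)
    if missing:
        raise KeyError(f"no genome length for entities: {sorted(missing)[:5]}")
    if (lengths < 1).any():
        raise ValueError("genome lengths must be >= 1")
    df = counts.copy()
    df["reads"] = df["reads"].astype(float) + pseudocount
    totals = df.groupby("sample_id")["reads"].transform("sum")
    dead = df.loc[totals <= 0, "sample_id"].unique()
    if len(dead):
        raise ValueError(f"sample(s) with all-zero read counts: {sorted(dead)}")
    df["weight"] = df["reads"] / df["entity_id"].map(lengths)
    df["relative"] = df["weight"] / df.groupby("sample_id")["weight"].transform("sum")
    df["fractional"] = df["reads"] / totals
    return df[["entity_id", "sample_id", "reads", "relative", "fractional"]]


def scale_by_microscopy(
    relative: pd.DataFrame,
    microscopy: pd.DataFrame,
    entity_kind: str,
) -> pd.DataFrame:
    """Convert relative abundances to genomes per ml via direct counts.

    ``entity_kind="virus"`` scales by ``vlp_per_ml``, ``"host"`` by
    ``cells_per_ml``.  Proportions are preserved exactly, so per sample the
    scaled column sums to the microscopy total times the summed relative
    abundance (equal to the total itself when the table covers the whole
    entity class).
    """
    column = {"virus": "vlp_per_ml", "host": "cells_per_ml"}.get(entity_kind)
    if column is None:
        raise ValueError("entity_kind must be 'virus' or 'host'")
    missing = set(relative["sample_id"].unique()) - set(microscopy.index)
    if missing:
        raise KeyError(f"samples absent from microscopy table: {sorted(missing)}")
    out = relative.copy()
    out["genomes_per_ml"] = out["relative"] * out["sample_id"].map(microscopy[column])
    return out


def _gpm_lookup(gpm: pd.DataFrame) -> pd.Series:
    return gpm.set_index(["entity_id", "sample_id"])["genomes_per_ml"]


def compute_vhr(
    pairs: pd.DataFrame,
    virus_gpm_free: pd.DataFrame,
    virus_gpm_cell: pd.DataFrame,
    host_gpm: pd.DataFrame,
) -> pd.DataFrame:
    """Per-pair, per-sample virus-to-host ratios in both size fractions.

    For every unique pair and every sample where the host has positive
    genomes/ml, ``vhr_free`` and ``vhr_cell`` divide the virus genomes/ml
    (free and cell-associated fractions; the host denominator is always the
    cell fraction) by the host genomes/ml.  A virus absent from a fraction
    in a sample gets VHR 0 there; samples where the host is absent are
    emitted with NaN VHRs and excluded from quartile statistics downstream.
    """
    vfree, vcell, host = (_gpm_lookup(t) for t in (virus_gpm_free, virus_gpm_cell, host_gpm))
    samples = sorted(host.index.get_level_values("sample_id").unique())
    rows = []
    for _, pair in pairs.iterrows():
        v, h = pair["virus_pop_id"], pair["host_species_id"]
        for s in samples:
            denom = host.get((h, s), np.nan)
            if pd.isna(denom) or denom <= 0:
                rows.append((v, h, s, np.nan, np.nan))
                continue
            rows.append((v, h, s,
                         float(vfree.get((v, s), 0.0)) / denom,
                         float(vcell.get((v, s), 0.0)) / denom))
    return pd.DataFrame(rows, columns=["virus_pop_id", "host_species_id", "sample_id",
                                       "vhr_free", "vhr_cell"])


def pair_median_vhr(vhr: pd.DataFrame) -> pd.DataFrame:
    """Median VHR per pair across samples (one point per pair, as plotted)."""
    med = (
        vhr.groupby(["virus_pop_id", "host_species_id"])[["vhr_free", "vhr_cell"]]
        .median()
        .reset_index()
    )
    return med.dropna(subset=["vhr_free", "vhr_cell"]).reset_index(drop=True)


def rank_statistics(gpm: pd.DataFrame) -> pd.DataFrame:
    """Per-entity abundance-rank summaries across samples.

    Within each sample, entities are ranked by genomes/ml with rank 1 = most
    abundant and ties sharing the average rank.  Returns, per entity, the
    median rank, the standard deviation of the rank, and the standard
    deviation of genomes/ml across samples (ddof=1; NaN with fewer than two
    samples).
    """
    df = gpm.copy()
    df["rank"] = df.groupby("sample_id")["genomes_per_ml"].rank(
        ascending=False, method="average")
    out = df.groupby("entity_id").agg(
        median_rank=("rank", "median"),
        rank_sd=("rank", lambda r: r.std(ddof=1)),
        abundance_sd=("genomes_per_ml", lambda a: a.std(ddof=1)),
        n_samples=("sample_id", "nunique"),
    ).reset_index()
    return out


def linked_rank_correlation(
    pairs: pd.DataFrame,
    virus_ranks: pd.DataFrame,
    host_ranks: pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation between linked virus and host median ranks.

    Returns (rho, two-sided p-value) over the unique pairs whose virus and
    host both have a median rank.
    """
    v = virus_ranks.set_index("entity_id")["median_rank"]
    h = host_ranks.set_index("entity_id")["median_rank"]
    x = pairs["virus_pop_id"].map(v)
    y = pairs["host_species_id"].map(h)
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 linked pairs with ranks")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)
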