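"""Virus-host link inference from proximity-ligation, prophage, and CRISPR evidence.

Three independent lines of evidence connect a viral genome (vMAG) to a
bacterial genome (bMAG):

* **Hi-C / proximity ligation** — chimeric read pairs bridging viral and host
  DNA inside intact cells.  Links are filtered on a raw contact count and a
  normalized score.
* **Prophage integration** — a near-complete, high-identity BLASTn alignment
  of a viral contig inside a host contig (default: >=95% identity and >=99%
  coverage of the entire viral contig).
* **CRISPR spacers** — spacers mined from host genomes matching a viral
  genome (default: at most two mismatches+gaps, 100% coverage, and a matched
  length of at least 20 nt).

After filtering, genomes are dereplicated into populations (viruses: 95% ANI
and 80% shared genes; hosts: 95% ANI, i.e. species level) and evidence rows
are collapsed into one row per unique (virus population, host species) pair.

All thresholds are boundary-inclusive, matching the printed conventions
(``>=`` retains, never ``>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "BLAST6_COLUMNS",
    "PopulationMap",
    "read_blast_tabular",
    "filter_prophage_hits",
    "filter_spacer_matches",
    "filter_hic_links",
    "dereplicate",
    "merge_links",
    "classify_lifestyle",
    "count_links_by_evidence",
]

#: Standard 12-column BLAST tabular (outfmt 6) header, extended with the
#: query (viral contig) length needed for coverage computation.
BLAST6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "e_value",
    "bitscore",
]

EVIDENCE_TYPES = ("hic", "prophage", "crispr")


def read_blast_tabular(path, query_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Read a BLAST outfmt-6 table (12 or 13 columns).

    A 13th column, if present, is taken as ``query_length``; otherwise the
    lengths must be supplied via *query_lengths* keyed by ``query_id``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(BLAST6_COLUMNS):
        df.columns = BLAST6_COLUMNS
    elif df.shape[1] == len(BLAST6_COLUMNS) + 1:
        df.columns = BLAST6_COLUMNS + ["query_length"]
    else:
        raise ValueError(
            f"expected 12 or 13 tab-separated columns, found {df.shape[1]} in {path!r}"
        )
    if "query_length" not in df.columns:
        if query_lengths is None:
            raise ValueError("query lengths required: pass query_lengths or a 13-column table")
        df["query_length"] = df["query_id"].map(query_lengths)
    return df


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def filter_prophage_hits(
    hits: pd.DataFrame,
    min_identity: float = 95.0,
    min_query_coverage: float = 99.0,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Retain alignments evidencing an integrated prophage.

    A hit is kept when ``percent_identity >= min_identity`` and the alignment
    covers at least *min_query_coverage* percent of the entire viral contig
    (query side).  Coverage uses 1-based inclusive coordinates,
    ``|query_end - query_start| + 1``, so strand does not matter.

    Returns a link-evidence table with one row per retained
    (virus, host, sample) combination and the number of supporting hits.
    """
    _require_columns(hits, ["query_id", "subject_id", "percent_identity",
                            "query_start", "query_end"], "prophage hit")
    if "query_length" not in hits.columns or hits["query_length"].isna().any():
        bad = hits.index[hits["query_length"].isna()].tolist() if "query_length" in hits.columns else "all"
        raise ValueError(f"query_length missing for prophage hit rows: {bad}")
    span = (hits["query_end"] - hits["query_start"]).abs() + 1
    coverage = 100.0 * span / hits["query_length"]
    keep = (hits["percent_identity"] >= min_identity) & (coverage >= min_query_coverage)
    kept = hits.loc[keep]
    sample = kept["sample_id"] if "sample_id" in kept.columns else sample_id
    out = pd.DataFrame(
        {
            "virus_id": kept["query_id"],
            "host_id": kept["subject_id"],
            "sample_id": sample,
            "evidence_type": "prophage",
        }
    )
    return _collapse_support(out)


def filter_spacer_matches(
    matches: pd.DataFrame,
    max_mm_gaps: int = 2,
    required_coverage: float = 100.0,
    min_length: int = 20,
) -> pd.DataFrame:
    """Retain CRISPR spacer-to-virus matches implying a past infection.

    Keeps rows with ``mismatches_plus_gaps <= max_mm_gaps``,
    ``coverage_percent >= required_coverage`` and
    ``matched_length >= min_length``.  An empty result is legitimate.
    """
    _require_columns(matches, ["virus_id", "host_id", "mismatches_plus_gaps",
                               "coverage_percent", "matched_length"], "spacer match")
    keep = (
        (matches["mismatches_plus_gaps"] <= max_mm_gaps)
        & (matches["coverage_percent"] >= required_coverage)
        & (matches["matched_length"] >= min_length)
    )
    kept = matches.loc[keep]
    out = pd.DataFrame(
        {
            "virus_id": kept["virus_id"],
            "host_id": kept["host_id"],
            "sample_id": kept["sample_id"] if "sample_id" in kept.columns else None,
            "evidence_type": "crispr",
        }
    )
    return _collapse_support(out)


def filter_hic_links(
    links: pd.DataFrame,
    min_contacts: int = 2,
    min_normalized_score: float = 0.0,
) -> pd.DataFrame:
    """Retain proximity-ligation links above contact and score thresholds.

    The published pipeline's confidence model is proprietary; this filter is
    a transparent stand-in with the same interface: keep links with
    ``contact_count >= min_contacts`` and
    ``normalized_score >= min_normalized_score``.
    """
    if min_contacts < 0 or min_normalized_score < 0:
        raise ValueError("Hi-C thresholds must be non-negative")
    _require_columns(links, ["virus_id", "host_id", "contact_count"], "Hi-C link")
    score = links["normalized_score"] if "normalized_score" in links.columns else 0.0
    keep = (links["contact_count"] >= min_contacts) & (score >= min_normalized_score)
    kept = links.loc[keep]
    out = pd.DataFrame(
        {
            "virus_id": kept["virus_id"],
            "host_id": kept["host_id"],
            "sample_id": kept["sample_id"] if "sample_id" in kept.columns else None,
            "evidence_type": "hic",
        }
    )
    return _collapse_support(out)


def _collapse_support(evidence: pd.DataFrame) -> pd.DataFrame:
    """One row per (virus, host, sample, evidence type) with a support count."""
    if evidence.empty:
        return pd.DataFrame(
            columns=["virus_id", "host_id", "sample_id", "evidence_type", "support"]
        )
    grouped = (
        evidence.groupby(["virus_id", "host_id", "sample_id", "evidence_type"], dropna=False)
        .size()
        .reset_index(name="support")
    )
    return grouped.sort_values(["virus_id", "host_id", "sample_id"], ignore_index=True)


@dataclass(frozen=True)
class PopulationMap:
    """Mapping of genome members to cluster representatives.

    Representatives map to themselves and the map is total over the ids it
    was built from.  ``ani_threshold`` / ``shared_gene_threshold`` record the
    clustering parameters (the latter is ``None`` for host, ANI-only
    dereplication).
    """

    mapping: dict[str, str]
    ani_threshold: float
    shared_gene_threshold: float | None = None

    def __post_init__(self) -> None:
        for member, rep in self.mapping.items():
            if rep not in self.mapping or self.mapping[rep] != rep:
                raise ValueError(f"representative {rep!r} of {member!r} does not map to itself")

    def __getitem__(self, member: str) -> str:
        return self.mapping[member]

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def representatives(self) -> list[str]:
        return sorted({r for r in self.mapping.values()})

    def apply(self, ids: pd.Series) -> pd.Series:
        unknown = set(ids.unique()) - set(self.mapping)
        if unknown:
            raise KeyError(f"ids not covered by population map: {sorted(unknown)[:5]}")
        return ids.map(self.mapping)


def dereplicate(
    pairwise: pd.DataFrame,
    member_sizes: Mapping[str, int],
    ani_threshold: float = 95.0,
    shared_threshold: float | None = 80.0,
) -> PopulationMap:
    """Cluster genomes into populations by single linkage over similarity edges.

    An edge joins two genomes when ``ani >= ani_threshold`` and, if
    *shared_threshold* is given, ``shared_gene_fraction >= shared_threshold``
    (viral populations: 95% ANI and 80% shared genes; host species: 95% ANI
    only).  Each connected component becomes one population; the
    representative is the longest member, ties broken by lexicographic id.

    *pairwise* needs columns ``a, b, ani`` and, when *shared_threshold* is
    not None, ``shared_gene_fraction``; it is treated as undirected.
    *member_sizes* must cover every genome (singletons included).
    """
    if not (0 < ani_threshold <= 100):
        raise ValueError("ani_threshold must be in (0, 100]")
    if shared_threshold is not None and not (0 < shared_threshold <= 100):
        raise ValueError("shared_threshold must be in (0, 100] or None")
    g = nx.Graph()
    g.add_nodes_from(member_sizes)
    if len(pairwise):
        _require_columns(pairwise, ["a", "b", "ani"], "pairwise similarity")
        unknown = (set(pairwise["a"]) | set(pairwise["b"])) - set(member_sizes)
        if unknown:
            raise KeyError(f"pairwise table references unknown genomes: {sorted(unknown)[:5]}")
        passing = pairwise["ani"] >= ani_threshold
        if shared_threshold is not None:
            _require_columns(pairwise, ["shared_gene_fraction"], "pairwise similarity")
            passing &= pairwise["shared_gene_fraction"] >= shared_threshold
        g.add_edges_from(pairwise.loc[passing, ["a", "b"]].itertuples(index=False))
    mapping: dict[str, str] = {}
    for component in nx.connected_components(g):
        # longest member wins; ties go to the lexicographically smallest id
        rep = sorted(component, key=lambda m: (-member_sizes[m], m))[0]
        for member in component:
            mapping[member] = rep
    return PopulationMap(mapping, ani_threshold, shared_threshold)


def merge_links(
    evidence: pd.DataFrame | Iterable[pd.DataFrame],
    virus_map: PopulationMap,
    host_map: PopulationMap,
) -> pd.DataFrame:
    """Collapse filtered evidence to unique (virus population, host species) pairs.

    Evidence rows are re-keyed to their representatives and aggregated: one
    output row per unique pair carrying the sorted set of evidence types,
    per-type support sums, the set of samples, and the total support.
    Idempotent: merging the output again changes nothing.
    """
    if not isinstance(evidence, pd.DataFrame):
        frames = [f for f in evidence if len(f)]
        evidence = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["virus_id", "host_id", "sample_id", "evidence_type", "support"])
        )
    if evidence.empty:
        return pd.DataFrame(
            columns=["virus_pop_id", "host_species_id", "evidence_types", "samples",
                     "support_hic", "support_prophage", "support_crispr", "support_total"]
        )
    ev = evidence.copy()
    ev["virus_pop_id"] = virus_map.apply(ev["virus_id"])
    ev["host_species_id"] = host_map.apply(ev["host_id"])
    if "support" not in ev.columns:
        ev["support"] = 1

    def _agg(group: pd.DataFrame) -> pd.Series:
        by_type = group.groupby("evidence_type")["support"].sum()
        samples = sorted({s for s in group["sample_id"] if pd.notna(s)})
        return pd.Series(
            {
                "evidence_types": ",".join(sorted(set(group["evidence_type"]))),
                "samples": ",".join(str(s) for s in samples),
                **{f"support_{t}": int(by_type.get(t, 0)) for t in EVIDENCE_TYPES},
                "support_total": int(group["support"].sum()),
            }
        )

    merged = (
        ev.groupby(["virus_pop_id", "host_species_id"])
        .apply(_agg, include_groups=False)
        .reset_index()
        .sort_values(["virus_pop_id", "host_species_id"], ignore_index=True)
    )
    return merged


def count_links_by_evidence(merged: pd.DataFrame) -> dict[str, int]:
    """Unique pair counts per evidence type and overall, from merged links."""
    counts = {t: 0 for t in EVIDENCE_TYPES}
    for types in merged.get("evidence_types", pd.Series(dtype=str)):
        for t in str(types).split(","):
            if t in counts:
                counts[t] += 1
    counts["total_unique_pairs"] = int(len(merged))
    return counts


def classify_lifestyle(
    virus_pop_id: str,
    has_integrase: bool,
    prophage_pairs: set[tuple[str, str]] | set[str],
) -> str:
    """Assign a replication lifestyle to a virus population.

    Observed integrated (prophage evidence) -> ``temperate_prophage``;
    integrase-encoding but never observed integrated -> ``temperate``;
    otherwise -> ``lytic``.  The coarse label "temperate" covers both
    temperate subclasses when only two classes are needed.
    """
    prophage_viruses = {p[0] if isinstance(p, tuple) else p for p in prophage_pairs}
    if virus_pop_id in prophage_viruses:
        return "temperate_prophage"
    if has_integrase:
        return "temperate"
    return "lytic"
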