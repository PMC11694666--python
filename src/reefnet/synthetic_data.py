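"""Synthetic reef-water communities with known virus-host ground truth.

The generator emulates the observable layers of a size-fractionated
metagenome + proximity-ligation + microscopy study of oligotrophic reef
seawater, at the summary-table level the analysis pipeline consumes (no
sequences are simulated):

* a log-normal host community, optionally with dominant unlinked lineages
  (the cyanobacteria analogue: abundant, but absent from the link network);
* a planted bipartite infection structure that is modular (blocks of hosts
  and viruses) and nested within blocks, with a small generalist fraction
  linking across blocks, and temperate/lytic lifestyle labels;
* Hi-C contact tables (Poisson counts proportional to the co-abundance of
  infected cells), prophage alignments (BLAST-tabular), and CRISPR spacer
  matches, each with controllable noise and decoy rows below the published
  filter thresholds;
* multinomial read-count tables per size fraction (sampling weight =
  abundance x genome length, i.e. reads scale with DNA mass) and
  epifluorescence microscopy totals with multiplicative log-normal noise.

Free and cell-associated viral abundances are constructed from per-virus
virus-to-host ratios (VHR) drawn on a log10 scale with a positive
correlation between fractions, so the free-vs-cell VHR relationship of real
reef data is reproduced and every downstream VHR is known exactly.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
identical arguments and seed give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityTruth",
    "SimulatedEvidence",
    "simulate_community",
    "simulate_evidence",
    "simulate_bitscores",
    "identity_population_map",
    "write_evidence_tables",
]

#: Study-scale defaults: median bacterial density observed by epifluorescence
#: microscopy in reef boundary-layer water, cells per ml.
DEFAULT_CELLS_PER_ML = 9.6e5


@dataclass
class CommunityTruth:
    """Ground-truth community state behind one synthetic study.

    Abundances are genomes per ml, one column per sample.  ``true_links``
    holds (virus_id, host_id) pairs; ``prophage_carriers`` is the subset
    observed integrated (always temperate viruses).
    """

    host_ids: list[str]
    virus_ids: list[str]
    host_abundance: pd.DataFrame          # hosts x samples, genomes/ml
    virus_abundance_free: pd.DataFrame    # viruses x samples, genomes/ml
    virus_abundance_cell: pd.DataFrame    # viruses x samples, genomes/ml
    true_links: set[tuple[str, str]]
    lifestyle: dict[str, str]             # virus -> temperate | lytic
    prophage_carriers: set[tuple[str, str]]
    genome_lengths: dict[str, int]        # bp, hosts and viruses
    module_of: dict[str, int]             # planted module id per node
    seed: int

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        hosts, viruses = set(self.host_ids), set(self.virus_ids)
        for v, h in self.true_links:
            if v not in viruses or h not in hosts:
                raise ValueError(f"link ({v!r}, {h!r}) references unknown ids")
        for table in (self.host_abundance, self.virus_abundance_free, self.virus_abundance_cell):
            if (table.to_numpy() <= 0).any():
                raise ValueError("abundances must be strictly positive")
        for gid, length in self.genome_lengths.items():
            if length < 1000:
                raise ValueError(f"genome {gid!r} shorter than 1000 bp")
        if not self.prophage_carriers <= self.true_links:
            raise ValueError("prophage_carriers must be a subset of true_links")
        for v, _ in self.prophage_carriers:
            if self.lifestyle.get(v) != "temperate":
                raise ValueError(f"prophage carrier {v!r} must be temperate")

    @property
    def samples(self) -> list[str]:
        return list(self.host_abundance.columns)

    @property
    def linked_hosts(self) -> set[str]:
        return {h for _, h in self.true_links}

    def virus_degree(self, virus_id: str) -> int:
        return sum(1 for v, _ in self.true_links if v == virus_id)

    def true_vhr(self, virus_id: str, host_id: str, sample: str) -> tuple[float, float]:
        """(free, cell-associated) VHR of a pair in one sample, from truth."""
        h = self.host_abundance.at[host_id, sample]
        return (
            self.virus_abundance_free.at[virus_id, sample] / h,
            self.virus_abundance_cell.at[virus_id, sample] / h,
        )


def _planted_links(
    host_blocks: list[list[str]],
    virus_blocks: list[list[str]],
    fill: str,
) -> set[tuple[str, str]]:
    """Within-module link sets.

    ``nested``:   virus *i* of a module links to the first ``max(1, m - i)``
                  hosts of the module -- a staircase whose host prefixes are
                  perfectly nested.
    ``specialist``: every virus links to exactly one host (round-robin),
                  mirroring networks dominated by single-host viruses.
    """
    links: set[tuple[str, str]] = set()
    for hosts, viruses in zip(host_blocks, virus_blocks):
        m = len(hosts)
        for i, v in enumerate(viruses):
            if fill == "nested":
                for h in hosts[: max(1, m - i)]:
                    links.add((v, h))
            elif fill == "specialist":
                links.add((v, hosts[i % m]))
            else:
                raise ValueError(f"unknown fill shape {fill!r}")
    return links


def simulate_community(
    n_hosts: int,
    n_viruses: int,
    n_samples: int,
    lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0),
    planted_modules: int = 2,
    generalist_fraction: float = 0.0,
    temperate_fraction: float = 0.3,
    seed: int = 0,
    *,
    fill: str = "nested",
    n_unlinked_hosts: int = 0,
    unlinked_dominance: float = 3.0,
    cells_per_ml: float = DEFAULT_CELLS_PER_ML,
    vhr_free_log10_mu_sigma: tuple[float, float] = (1.0, 0.8),
    vhr_cell_log10_mu_sigma: tuple[float, float] = (0.3, 0.8),
    vhr_fraction_correlation: float = 0.7,
    prophage_carrier_fraction: float = 0.6,
    top_generalist_extra_hosts: int = 1,
) -> CommunityTruth:
    """Draw a community with a planted modular-and-nested infection network.

    Parameters
    ----------
    n_hosts, n_viruses, n_samples
        Community and study sizes (linked hosts only; see *n_unlinked_hosts*).
    lognormal_mu_sigma
        Log-normal parameters of raw per-host abundance weights, renormalized
        per sample so the community totals *cells_per_ml*.
    planted_modules
        Number of bipartite blocks; hosts and viruses are split across blocks
        as evenly as possible.
    generalist_fraction
        ``ceil(generalist_fraction * n_viruses)`` viruses each receive one
        extra host outside their own module; the first of them receives
        *top_generalist_extra_hosts* instead (real networks usually contain
        one stand-out generalist).
    temperate_fraction
        Fraction of viruses labelled temperate; a *prophage_carrier_fraction*
        of those is additionally marked as observed integrated in one of its
        true hosts.
    fill
        Within-module link shape, ``"nested"`` (staircase) or
        ``"specialist"`` (every virus one host).
    n_unlinked_hosts
        Extra hosts carrying no links, whose abundance weights are multiplied
        by *unlinked_dominance* -- the abundant-but-unlinked lineage analogue.
    cells_per_ml
        Per-sample total bacterial density (epifluorescence scale).
    vhr_*_log10_mu_sigma, vhr_fraction_correlation
        Per-virus log10 virus-to-host ratios in the free and cell-associated
        fractions are drawn from a correlated bivariate normal; virus
        abundances are then VHR x (abundance of the virus's primary host), so
        every pair VHR is known analytically.
    """
    if n_hosts < 1 or n_viruses < 1 or n_samples < 1:
        raise ValueError("counts must be positive")
    if not (1 <= planted_modules <= min(n_hosts, n_viruses)):
        raise ValueError("planted_modules must be in [1, min(n_hosts, n_viruses)]")
    for name, frac in (("generalist_fraction", generalist_fraction),
                       ("temperate_fraction", temperate_fraction)):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    n_generalists = math.ceil(generalist_fraction * n_viruses)
    if n_generalists > 0 and planted_modules < 2:
        raise ValueError("generalists need at least 2 planted modules")

    rng = np.random.default_rng(seed)
    host_ids = [f"h{i:03d}" for i in range(n_hosts + n_unlinked_hosts)]
    linked_host_ids = host_ids[:n_hosts]
    virus_ids = [f"v{i:03d}" for i in range(n_viruses)]
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]

    host_blocks = [[str(x) for x in b]
                   for b in np.array_split(np.array(linked_host_ids), planted_modules)]
    virus_blocks = [[str(x) for x in b]
                    for b in np.array_split(np.array(virus_ids), planted_modules)]
    links = _planted_links(host_blocks, virus_blocks, fill)
    module_of: dict[str, int] = {}
    for mod, (hs, vs) in enumerate(zip(host_blocks, virus_blocks), start=1):
        for node in [*hs, *vs]:
            module_of[node] = mod

    if len(links) + n_generalists > n_hosts * n_viruses:
        raise ValueError("generalist_fraction too large: links would exceed matrix size")
    generalists = sorted(str(v) for v in rng.choice(virus_ids, size=n_generalists, replace=False))
    for rank, v in enumerate(generalists):
        n_extra = top_generalist_extra_hosts if rank == 0 else 1
        foreign = [h for h in linked_host_ids if module_of[h] != module_of[v]]
        for h in rng.choice(foreign, size=min(n_extra, len(foreign)), replace=False):
            links.add((v, str(h)))

    mu, sigma = lognormal_mu_sigma
    weights = rng.lognormal(mu, sigma, size=(len(host_ids), n_samples))
    if n_unlinked_hosts:
        weights[n_hosts:, :] *= unlinked_dominance
    host_ab = pd.DataFrame(
        cells_per_ml * weights / weights.sum(axis=0, keepdims=True),
        index=host_ids, columns=samples,
    )

    # correlated per-virus log10 VHRs for the two size fractions
    rho = vhr_fraction_correlation
    z_shared = rng.standard_normal(n_viruses)
    z_free = rho * z_shared + math.sqrt(1 - rho**2) * rng.standard_normal(n_viruses)
    z_cell = rho * z_shared + math.sqrt(1 - rho**2) * rng.standard_normal(n_viruses)
    log_vhr_free = vhr_free_log10_mu_sigma[0] + vhr_free_log10_mu_sigma[1] * z_free
    log_vhr_cell = vhr_cell_log10_mu_sigma[0] + vhr_cell_log10_mu_sigma[1] * z_cell

    primary_host = {}
    for v in virus_ids:
        v_hosts = sorted(h for vv, h in links if vv == v)
        primary_host[v] = v_hosts[0]
    free = np.empty((n_viruses, n_samples))
    cell = np.empty((n_viruses, n_samples))
    for i, v in enumerate(virus_ids):
        base = host_ab.loc[primary_host[v]].to_numpy()
        free[i] = 10.0 ** log_vhr_free[i] * base
        cell[i] = 10.0 ** log_vhr_cell[i] * base
    virus_free = pd.DataFrame(free, index=virus_ids, columns=samples)
    virus_cell = pd.DataFrame(cell, index=virus_ids, columns=samples)

    n_temperate = round(temperate_fraction * n_viruses)
    temperate = {str(v) for v in rng.choice(virus_ids, size=n_temperate, replace=False)}
    lifestyle = {v: ("temperate" if v in temperate else "lytic") for v in virus_ids}
    prophage_carriers: set[tuple[str, str]] = set()
    for v in sorted(temperate):
        if rng.random() < prophage_carrier_fraction:
            prophage_carriers.add((v, primary_host[v]))

    lengths = {h: int(rng.integers(1_500_000, 5_000_000)) for h in host_ids}
    lengths.update({v: int(rng.integers(20_000, 150_000)) for v in virus_ids})

    return CommunityTruth(
        host_ids=host_ids,
        virus_ids=virus_ids,
        host_abundance=host_ab,
        virus_abundance_free=virus_free,
        virus_abundance_cell=virus_cell,
        true_links=links,
        lifestyle=lifestyle,
        prophage_carriers=prophage_carriers,
        genome_lengths=lengths,
        module_of=module_of,
        seed=seed,
    )


@dataclass
class SimulatedEvidence:
    """All pipeline input tables produced from one :class:`CommunityTruth`."""

    hic: pd.DataFrame                # virus_id, host_id, sample_id, contact_count, normalized_score
    prophage_hits: pd.DataFrame      # BLAST outfmt-6 columns + query_length
    spacer_matches: pd.DataFrame     # spacer_id, virus_id, host_id, ...
    counts_cell: pd.DataFrame        # entity_id, sample_id, reads (hosts + cell-assoc. viruses)
    counts_free: pd.DataFrame        # entity_id, sample_id, reads (viruses)
    microscopy: pd.DataFrame         # index sample_id: vlp_per_ml, cells_per_ml
    genome_lengths: pd.Series
    params: dict = field(default_factory=dict)


def _multinomial_counts(
    abundance: pd.DataFrame,
    lengths: pd.Series,
    read_depth: int,
    rng: np.random.Generator,
    exact: bool,
) -> pd.DataFrame:
    """Per-sample read counts; weight = abundance x genome length (DNA mass)."""
    rows = []
    w = abundance.mul(lengths.loc[abundance.index], axis=0)
    for sample in abundance.columns:
        p = (w[sample] / w[sample].sum()).to_numpy()
        reads = read_depth * p if exact else rng.multinomial(read_depth, p)
        rows.append(pd.DataFrame({
            "entity_id": abundance.index,
            "sample_id": sample,
            "reads": reads,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_evidence(
    truth: CommunityTruth,
    read_depth: int = 1_000_000,
    hic_links_per_infection: float = 10.0,
    prophage_noise: float = 0.0,
    crispr_mismatch_rate: float = 0.0,
    seed: int = 0,
    *,
    hic_false_positive_rows: int = 0,
    n_decoy_alignments: int = 0,
    n_decoy_spacers: int = 0,
    crispr_link_fraction: float = 0.05,
    microscopy_noise_sd: float = 0.0,
    exact_reads: bool = False,
) -> SimulatedEvidence:
    """Emit every evidence table the pipeline reads, from known truth.

    Hi-C contact counts for a true link are Poisson with mean proportional
    to the pair's co-abundance (host x cell-associated virus genomes/ml);
    ``hic_links_per_infection`` anchors the sequencing depth as the expected
    contact count of the *rarest* true pair, so abundant infected pairs
    yield proportionally more chimeric reads.  The
    false-positive floor (off by default) adds non-link rows with a single
    contact, below the default contact filter; decoy alignments and decoy
    spacers likewise sit below the published prophage/CRISPR thresholds, so
    with zero noise the filtered evidence equals the planted truth exactly.

    ``exact_reads=True`` replaces multinomial read sampling with expected
    (fractional) counts, making abundance round trips exact.
    """
    for name, value in (("read_depth", read_depth),
                        ("hic_links_per_infection", hic_links_per_infection),
                        ("prophage_noise", prophage_noise),
                        ("crispr_mismatch_rate", crispr_mismatch_rate)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if read_depth < 1000:
        raise ValueError("read_depth below 1000 gives meaningless count tables")
    rng = np.random.default_rng(seed)
    samples = truth.samples
    links = sorted(truth.true_links)

    # --- Hi-C contacts -----------------------------------------------------
    co = np.array([
        [truth.host_abundance.at[h, s] * truth.virus_abundance_cell.at[v, s] for s in samples]
        for v, h in links
    ])
    hic_rows = []
    if links and hic_links_per_infection > 0:
        # contacts stay proportional to co-abundance; the rate sets the
        # expected count of the rarest true pair (sequencing-depth anchor)
        mean = hic_links_per_infection * co / co.min()
        counts = rng.poisson(mean)
        for (v, h), per_sample in zip(links, counts):
            for s, c in zip(samples, per_sample):
                if c >= 1:
                    hic_rows.append((v, h, s, int(c), 1.0))
    non_links = [(v, h) for v in truth.virus_ids for h in truth.host_ids
                 if (v, h) not in truth.true_links]
    if hic_false_positive_rows and non_links:
        idx = rng.choice(len(non_links), size=min(hic_false_positive_rows, len(non_links)),
                         replace=False)
        for i in idx:
            v, h = non_links[i]
            s = str(rng.choice(samples))
            hic_rows.append((v, h, s, 1, float(rng.uniform(0.0, 0.5))))
    hic = pd.DataFrame(hic_rows, columns=["virus_id", "host_id", "sample_id",
                                          "contact_count", "normalized_score"])

    # --- prophage alignments (BLAST tabular + query_length) ----------------
    pro_rows = []
    for v, h in sorted(truth.prophage_carriers):
        length = truth.genome_lengths[v]
        identity = max(0.0, 100.0 - abs(rng.normal(0.0, prophage_noise))) if prophage_noise else 100.0
        pro_rows.append((v, h, identity, length, int(round(length * (100 - identity) / 100)),
                         0, 1, length, 1, length, 0.0, 2.0 * length * identity / 100, length))
    for _ in range(n_decoy_alignments):
        if not non_links:
            break
        v, h = non_links[rng.integers(len(non_links))]
        length = truth.genome_lengths[v]
        identity = float(rng.uniform(70.0, 94.0))      # always below the 95% gate
        span = int(length * rng.uniform(0.3, 0.9))     # and below 99% coverage
        pro_rows.append((v, h, identity, span, int(span * (100 - identity) / 100),
                         1, 1, span, 1, span, 1e-20, 2.0 * span * identity / 100, length))
    prophage_hits = pd.DataFrame(pro_rows, columns=[
        "query_id", "subject_id", "percent_identity", "alignment_length", "mismatches",
        "gap_opens", "query_start", "query_end", "subject_start", "subject_end",
        "e_value", "bitscore", "query_length",
    ])

    # --- CRISPR spacer matches ---------------------------------------------
    spacer_rows = []
    n_crispr = round(crispr_link_fraction * len(links))
    chosen = rng.choice(len(links), size=min(n_crispr, len(links)), replace=False) if links else []
    for k, i in enumerate(sorted(chosen)):
        v, h = links[i]
        slen = int(rng.integers(25, 41))
        mm = int(rng.binomial(slen, crispr_mismatch_rate)) if crispr_mismatch_rate else 0
        spacer_rows.append((f"sp{k:04d}", slen, v, h, mm, 100.0, slen))
    for k in range(n_decoy_spacers):
        if not non_links:
            break
        v, h = non_links[rng.integers(len(non_links))]
        slen = int(rng.integers(25, 41))
        spacer_rows.append((f"spX{k:04d}", slen, v, h, int(rng.integers(3, 7)), 100.0, slen))
    spacer_matches = pd.DataFrame(spacer_rows, columns=[
        "spacer_id", "spacer_length", "virus_id", "host_id",
        "mismatches_plus_gaps", "coverage_percent", "matched_length",
    ])

    # --- read counts per fraction ------------------------------------------
    lengths = pd.Series(truth.genome_lengths)
    cell_ab = pd.concat([truth.host_abundance, truth.virus_abundance_cell])
    counts_cell = _multinomial_counts(cell_ab, lengths, read_depth, rng, exact_reads)
    counts_free = _multinomial_counts(truth.virus_abundance_free, lengths, read_depth,
                                      rng, exact_reads)

    # --- microscopy totals --------------------------------------------------
    vlp_true = truth.virus_abundance_free.sum(axis=0)
    cells_true = truth.host_abundance.sum(axis=0)
    noise = (np.exp(rng.normal(0.0, microscopy_noise_sd, size=(2, len(samples))))
             if microscopy_noise_sd else np.ones((2, len(samples))))
    microscopy = pd.DataFrame({
        "vlp_per_ml": vlp_true.to_numpy() * noise[0],
        "cells_per_ml": cells_true.to_numpy() * noise[1],
    }, index=pd.Index(samples, name="sample_id"))

    params = dict(read_depth=read_depth, hic_links_per_infection=hic_links_per_infection,
                  prophage_noise=prophage_noise, crispr_mismatch_rate=crispr_mismatch_rate,
                  seed=seed, hic_false_positive_rows=hic_false_positive_rows,
                  n_decoy_alignments=n_decoy_alignments, n_decoy_spacers=n_decoy_spacers,
                  crispr_link_fraction=crispr_link_fraction,
                  microscopy_noise_sd=microscopy_noise_sd, exact_reads=exact_reads)
    return SimulatedEvidence(hic, prophage_hits, spacer_matches, counts_cell,
                             counts_free, microscopy, lengths, params)


def simulate_bitscores(truth: CommunityTruth, seed: int = 0,
                       within_module_similarity: tuple[float, float] = (0.3, 0.7),
                       background_similarity: float = 0.02) -> pd.DataFrame:
    """Summed protein-homology bitscores for the viral proteomic tree.

    Self scores scale with genome length (~1 gene per kb, ~60 bits each);
    viruses of the same planted module share a uniform fraction of their
    proteome, others only a small background, giving a tree whose clades
    track the planted modules.  Returns a long table
    (query_genome, subject_genome, summed_bitscore) including self rows.
    """
    rng = np.random.default_rng(seed)
    ids = truth.virus_ids
    self_score = {v: 60.0 * truth.genome_lengths[v] / 1000.0 for v in ids}
    rows = [(v, v, self_score[v]) for v in ids]
    lo, hi = within_module_similarity
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if truth.module_of[a] == truth.module_of[b]:
                s = rng.uniform(lo, hi)
            else:
                s = rng.uniform(0.0, background_similarity)
            ab = s * min(self_score[a], self_score[b])
            rows.append((a, b, ab))
            rows.append((b, a, ab))
    return pd.DataFrame(rows, columns=["query_genome", "subject_genome", "summed_bitscore"])


def identity_population_map(ids, lengths=None):
    """Identity dereplication map for communities simulated pre-dereplicated."""
    from .link_inference import PopulationMap

    return PopulationMap({i: i for i in ids}, ani_threshold=95.0)


def write_evidence_tables(evidence: SimulatedEvidence, outdir, truth: CommunityTruth | None = None) -> dict[str, str]:
    """Write every table in the on-disk formats the pipeline reads.

    BLAST hits go out tab-separated without a header (outfmt-6 convention,
    13th column = query length); other tables are TSV/CSV with headers.  A
    YAML manifest records the generator parameters and, when *truth* is
    given, the planted links and lifestyles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hic": outdir / "hic_links.tsv",
        "prophage": outdir / "prophage_hits.tsv",
        "spacers": outdir / "spacer_matches.tsv",
        "counts_cell": outdir / "counts_cell.tsv",
        "counts_free": outdir / "counts_free.tsv",
        "lengths": outdir / "genome_lengths.tsv",
        "microscopy": outdir / "microscopy.csv",
        "manifest": outdir / "manifest.yaml",
    }
    evidence.hic.to_csv(paths["hic"], sep="\t", index=False)
    evidence.prophage_hits.to_csv(paths["prophage"], sep="\t", index=False, header=False)
    evidence.spacer_matches.to_csv(paths["spacers"], sep="\t", index=False)
    evidence.counts_cell.to_csv(paths["counts_cell"], sep="\t", index=False)
    evidence.counts_free.to_csv(paths["counts_free"], sep="\t", index=False)
    evidence.genome_lengths.rename("genome_length").rename_axis("entity_id").to_csv(
        paths["lengths"], sep="\t")
    evidence.microscopy.to_csv(paths["microscopy"])
    manifest: dict = {"parameters": dict(evidence.params)}
    if truth is not None:
        manifest["truth"] = {
            "seed": truth.seed,
            "n_hosts": len(truth.host_ids),
            "n_viruses": len(truth.virus_ids),
            "true_links": sorted([list(p) for p in truth.true_links]),
            "prophage_carriers": sorted([list(p) for p in truth.prophage_carriers]),
            "lifestyle": dict(sorted(truth.lifestyle.items())),
            "modules": dict(sorted(truth.module_of.items())),
        }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
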