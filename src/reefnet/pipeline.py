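"""End-to-end orchestration: evidence tables in, network + VHR + tree out.

``run_pipeline`` executes link inference -> abundance -> VHR classes ->
network statistics -> proteomic tree on the input tables named in a
:class:`RunConfig`, writing every stage's outputs plus a run manifest
(config hash, seeds, versions) into the output directory.  ``run_demo``
generates a synthetic community first and then runs the same pipeline on
it, so the whole analysis can be exercised without any external data.
Identical config + inputs + seeds give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import link_inference as li
from . import network as net
from . import proteomic_tree as pt
from . import synthetic_data as syn
from . import vhr_classes as vc

__all__ = ["RunConfig", "run_pipeline", "run_demo"]

log = logging.getLogger("reefnet")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Thresholds default to the published values: prophage alignments at
    >=95% identity and >=99% viral-contig coverage; CRISPR matches at <=2
    mismatches+gaps, 100% coverage, >=20 nt; viral dereplication at 95% ANI
    and 80% shared genes; host dereplication at 95% ANI; the Hi-C
    contact/score filter is the transparent stand-in for the proprietary
    confidence model.
    """

    # inputs (demo mode fills these in)
    hic_links: str | None = None
    prophage_hits: str | None = None
    spacer_matches: str | None = None
    counts_cell: str | None = None
    counts_free: str | None = None
    genome_lengths: str | None = None
    microscopy: str | None = None
    virus_pairwise: str | None = None      # a, b, ani, shared_gene_fraction
    host_pairwise: str | None = None       # a, b, ani
    bitscores: str | None = None           # query_genome, subject_genome, summed_bitscore
    integrase_flags: str | None = None     # virus_id, has_integrase

    # thresholds
    prophage_min_identity: float = 95.0
    prophage_min_coverage: float = 99.0
    crispr_max_mm_gaps: int = 2
    crispr_required_coverage: float = 100.0
    crispr_min_length: int = 20
    hic_min_contacts: int = 2
    hic_min_score: float = 0.0
    virus_ani_threshold: float = 95.0
    virus_shared_threshold: float = 80.0
    host_ani_threshold: float = 95.0

    # statistics
    n_permutations: int = 999
    n_restarts: int = 20
    quartile_scale: str = "log10"
    seed: int = 0

    def validate(self) -> None:
        percent_fields = [
            "prophage_min_identity", "prophage_min_coverage", "crispr_required_coverage",
            "virus_ani_threshold", "virus_shared_threshold", "host_ani_threshold",
        ]
        for name in percent_fields:
            value = getattr(self, name)
            if not (0 < value <= 100):
                raise ValueError(f"{name}={value} outside (0, 100]")
        for name in ("crispr_max_mm_gaps", "crispr_min_length", "hic_min_contacts",
                     "n_permutations", "n_restarts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.quartile_scale not in ("log10", "linear"):
            raise ValueError("quartile_scale must be 'log10' or 'linear'")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # re-raise with stage context
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return run
    return wrap


def _read_tsv(path):
    return pd.read_csv(path, sep="\t")


@_stage("links")
def _links_stage(cfg: RunConfig, outdir: Path) -> dict:
    lengths = pd.read_csv(cfg.genome_lengths, sep="\t").set_index("entity_id")["genome_length"]
    evidence = []
    if cfg.hic_links:
        evidence.append(li.filter_hic_links(_read_tsv(cfg.hic_links),
                                            cfg.hic_min_contacts, cfg.hic_min_score))
    if cfg.prophage_hits:
        hits = li.read_blast_tabular(cfg.prophage_hits)
        evidence.append(li.filter_prophage_hits(hits, cfg.prophage_min_identity,
                                                cfg.prophage_min_coverage))
    if cfg.spacer_matches:
        evidence.append(li.filter_spacer_matches(_read_tsv(cfg.spacer_matches),
                                                 cfg.crispr_max_mm_gaps,
                                                 cfg.crispr_required_coverage,
                                                 cfg.crispr_min_length))
    all_ev = pd.concat([e for e in evidence if len(e)], ignore_index=True) \
        if any(len(e) for e in evidence) else pd.DataFrame(
            columns=["virus_id", "host_id", "sample_id", "evidence_type", "support"])
    virus_ids = sorted(set(all_ev["virus_id"]))
    host_ids = sorted(set(all_ev["host_id"]))
    sizes = lengths.to_dict()
    if cfg.virus_pairwise:
        vmap = li.dereplicate(_read_tsv(cfg.virus_pairwise),
                              {v: sizes.get(v, 1000) for v in virus_ids},
                              cfg.virus_ani_threshold, cfg.virus_shared_threshold)
    else:
        vmap = syn.identity_population_map(virus_ids)
    if cfg.host_pairwise:
        hmap = li.dereplicate(_read_tsv(cfg.host_pairwise),
                              {h: sizes.get(h, 1000) for h in host_ids},
                              cfg.host_ani_threshold, shared_threshold=None)
    else:
        hmap = syn.identity_population_map(host_ids)
    merged = li.merge_links(all_ev, vmap, hmap)
    merged.to_csv(outdir / "links.tsv", sep="\t", index=False)
    counts = li.count_links_by_evidence(merged)
    counts["individual_links"] = int(all_ev["support"].sum()) if len(all_ev) else 0
    return {"merged": merged, "counts": counts, "lengths": lengths,
            "prophage_pairs": {
                (r.virus_pop_id, r.host_species_id)
                for r in merged.itertuples() if "prophage" in r.evidence_types}}


@_stage("abundance")
def _abundance_stage(cfg: RunConfig, outdir: Path, lengths: pd.Series) -> dict:
    counts_cell = _read_tsv(cfg.counts_cell)
    counts_free = _read_tsv(cfg.counts_free)
    micro = ab.read_microscopy(cfg.microscopy)
    virus_ids = set(counts_free["entity_id"].unique())
    cell_virus = counts_cell[counts_cell["entity_id"].isin(virus_ids)]
    cell_host = counts_cell[~counts_cell["entity_id"].isin(virus_ids)]
    if cell_host.empty:
        raise ValueError("cell-associated counts contain no host entities")
    rel_host = ab.relative_abundance(cell_host, lengths)
    rel_vcell = ab.relative_abundance(cell_virus, lengths)
    rel_vfree = ab.relative_abundance(counts_free, lengths)
    gpm_host = ab.scale_by_microscopy(rel_host, micro, "host")
    gpm_vcell = ab.scale_by_microscopy(rel_vcell, micro, "virus")
    gpm_vfree = ab.scale_by_microscopy(rel_vfree, micro, "virus")
    tables = {"host_cell": gpm_host, "virus_cell": gpm_vcell, "virus_free": gpm_vfree}
    stacked = pd.concat([t.assign(table=name) for name, t in tables.items()],
                        ignore_index=True)
    stacked.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
    return {"micro": micro, **tables}


@_stage("vhr")
def _vhr_stage(cfg: RunConfig, outdir: Path, merged: pd.DataFrame,
               gpm: dict) -> dict:
    vhr = ab.compute_vhr(merged, gpm["virus_free"], gpm["virus_cell"], gpm["host_cell"])
    vhr.to_csv(outdir / "vhr.tsv", sep="\t", index=False)
    medians = ab.pair_median_vhr(vhr)
    thresholds = vc.vhr_quartiles(medians, scale=cfg.quartile_scale)
    classified = vc.classify_pairs(medians, thresholds)
    classified.to_csv(outdir / "vhr_categories.tsv", sep="\t", index=False)
    return {"vhr": vhr, "medians": medians, "thresholds": thresholds,
            "classified": classified,
            "category_counts": classified["category"].value_counts().to_dict()}


@_stage("network")
def _network_stage(cfg: RunConfig, outdir: Path, merged: pd.DataFrame) -> net.NetworkMetrics:
    matrix = net.build_matrix(merged)
    matrix.to_csv(outdir / "matrix.tsv", sep="\t")
    metrics = net.compute_network_metrics(matrix, cfg.n_permutations,
                                          cfg.n_restarts, cfg.seed)
    metrics.to_json(outdir / "network_metrics.json")
    rows = [(node, "host" if node in matrix.index else "virus", mod)
            for node, mod in sorted(metrics.module_assignment.items())]
    pd.DataFrame(rows, columns=["node", "side", "module"]).to_csv(
        outdir / "modules.tsv", sep="\t", index=False)
    edges = matrix.stack()
    edges[edges > 0].reset_index().iloc[:, :2].set_axis(
        ["host", "virus"], axis=1).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    return metrics


@_stage("tree")
def _tree_stage(cfg: RunConfig, outdir: Path) -> str:
    scores = _read_tsv(cfg.bitscores)
    dist = pt.build_distance_matrix(scores)
    dist.to_csv(outdir / "dice_distances.tsv", sep="\t")
    newick = pt.neighbor_joining(dist)
    (outdir / "proteomic_tree.nwk").write_text(newick + "\n")
    return newick


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and return the result bundle.

    Stages run in order (links -> abundance -> VHR -> network -> tree);
    stages whose inputs are not configured are reported as skipped.  A
    failure aborts the run with the stage name attached.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    links = _links_stage(config, outdir)
    bundle["link_counts"] = links["counts"]
    if config.counts_cell and config.counts_free and config.microscopy:
        gpm = _abundance_stage(config, outdir, links["lengths"])
        if len(links["merged"]):
            vhr = _vhr_stage(config, outdir, links["merged"], gpm)
            bundle["vhr_category_counts"] = vhr["category_counts"]
            bundle["vhr_thresholds"] = asdict(vhr["thresholds"])
    if len(links["merged"]):
        metrics = _network_stage(config, outdir, links["merged"])
        bundle["network"] = {
            "nodf": metrics.nodf, "temperature": metrics.temperature,
            "nestedness_score": metrics.nestedness_score, "q": metrics.q_barber,
            "q_normalized": metrics.q_normalized, "n_modules": metrics.n_modules,
            "p_values": metrics.p_values,
            "specialist_percent": metrics.degree["specialist_percent"],
        }
    if config.bitscores:
        bundle["newick"] = _tree_stage(config, outdir)
    manifest = {
        "config": asdict(config),
        "config_sha256": config.sha256(),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    try:
        from importlib.metadata import version
        manifest["reefnet_version"] = version("reefnet")
    except Exception:
        manifest["reefnet_version"] = "unknown"
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle


def run_demo(outdir, seed: int = 0, scale: str = "paper") -> dict:
    """Generate a synthetic study and run the full pipeline on it.

    ``scale="paper"`` mirrors the published study's network dimensions
    (51 linked hosts, 88 viruses, 29 planted modules, 8 generalists, 6
    samples) plus abundant unlinked hosts; ``scale="small"`` is a quick
    2-module community for smoke tests.
    """
    outdir = Path(outdir)
    datadir = outdir / "synthetic_inputs"
    if scale == "paper":
        truth = syn.simulate_community(
            n_hosts=51, n_viruses=88, n_samples=6, planted_modules=29,
            generalist_fraction=8 / 88, temperate_fraction=0.4, seed=seed,
            fill="specialist", n_unlinked_hosts=10, top_generalist_extra_hosts=2,
        )
    elif scale == "small":
        truth = syn.simulate_community(
            n_hosts=8, n_viruses=16, n_samples=3, planted_modules=2,
            generalist_fraction=0.1, temperate_fraction=0.3, seed=seed,
        )
    else:
        raise ValueError("scale must be 'paper' or 'small'")
    evidence = syn.simulate_evidence(truth, seed=seed + 1,
                                     crispr_link_fraction=0.05,
                                     microscopy_noise_sd=0.1)
    paths = syn.write_evidence_tables(evidence, datadir, truth)
    scores = syn.simulate_bitscores(truth, seed=seed + 2)
    bitscore_path = datadir / "bitscores.tsv"
    scores.to_csv(bitscore_path, sep="\t", index=False)
    cfg = RunConfig(
        hic_links=paths["hic"], prophage_hits=paths["prophage"],
        spacer_matches=paths["spacers"], counts_cell=paths["counts_cell"],
        counts_free=paths["counts_free"], genome_lengths=paths["lengths"],
        microscopy=paths["microscopy"], bitscores=str(bitscore_path),
        n_permutations=199, n_restarts=10, seed=seed,
    )
    bundle = run_pipeline(cfg, outdir)
    bundle["truth_links"] = len(truth.true_links)
    return bundle
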