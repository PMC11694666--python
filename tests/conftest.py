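import pandas as pd
import pytest

import reefnet as rn


@pytest.fixture(scope="session")
def recovery_truth():
    """Two planted modules, dense nested fill, exactly 40 links."""
    truth = rn.simulate_community(
        n_hosts=12, n_viruses=10, n_samples=3, planted_modules=2,
        generalist_fraction=0.0, temperate_fraction=0.3, seed=11,
    )
    assert len(truth.true_links) == 40
    return truth


@pytest.fixture(scope="session")
def noiseless_evidence(recovery_truth):
    return rn.simulate_evidence(
        recovery_truth, read_depth=100_000, hic_links_per_infection=10.0,
        prophage_noise=0.0, crispr_mismatch_rate=0.0, seed=12,
    )


def infer_pairs(truth, evidence):
    """Run the filtering + merging path and return the merged pair table."""
    hic = rn.filter_hic_links(evidence.hic)
    prophage = rn.filter_prophage_hits(evidence.prophage_hits)
    crispr = rn.filter_spacer_matches(evidence.spacer_matches)
    vmap = rn.identity_population_map(truth.virus_ids)
    hmap = rn.identity_population_map(truth.host_ids)
    return rn.merge_links([hic, prophage, crispr], vmap, hmap)


@pytest.fixture(scope="session")
def merged_pairs(recovery_truth, noiseless_evidence):
    return infer_pairs(recovery_truth, noiseless_evidence)


def truth_matrix(truth):
    pairs = pd.DataFrame(
        [{"virus_pop_id": v, "host_species_id": h} for v, h in truth.true_links]
    )
    return rn.build_matrix(pairs)
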