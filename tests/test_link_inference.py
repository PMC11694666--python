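"""Evidence filters, dereplication, and link merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reefnet as rn


def _hit(identity, qstart, qend, qlen, virus="vA", host="hA"):
    return dict(query_id=virus, subject_id=host, percent_identity=identity,
                alignment_length=qend - qstart + 1, mismatches=0, gap_opens=0,
                query_start=qstart, query_end=qend, subject_start=1,
                subject_end=qend - qstart + 1, e_value=0.0, bitscore=100.0,
                query_length=qlen)


class TestProphageFilter:
    @pytest.mark.parametrize(
        "identity,qstart,qend,qlen,kept",
        [
            (95.0, 1, 99, 100, True),    # both thresholds exactly met
            (94.9, 1, 100, 100, False),  # identity just below
            (99.0, 1, 98, 100, False),   # coverage 98% < 99%
            (100.0, 2, 100, 100, True),  # reversed-orientation-safe span
        ],
    )
    def test_boundary_inclusive_identity_and_coverage(self, identity, qstart,
                                                      qend, qlen, kept):
        hits = pd.DataFrame([_hit(identity, qstart, qend, qlen)])
        out = rn.filter_prophage_hits(hits)
        assert (len(out) == 1) is kept

    def test_hand_enumerated_fixture_keeps_exactly_two(self):
        hits = pd.DataFrame([
            _hit(96.0, 1, 100, 100, "v1", "h1"),   # pass
            _hit(95.0, 1, 99, 100, "v2", "h1"),    # pass (both at boundary)
            _hit(94.0, 1, 100, 100, "v3", "h2"),   # identity fail
            _hit(99.0, 1, 90, 100, "v4", "h2"),    # coverage fail
            _hit(90.0, 1, 50, 100, "v5", "h3"),    # both fail
            _hit(95.0, 10, 100, 100, "v6", "h3"),  # coverage 91% fail
        ])
        out = rn.filter_prophage_hits(hits)
        assert len(out) == 2
        assert set(out["virus_id"]) == {"v1", "v2"}

    def test_missing_query_length_is_a_hard_error(self):
        hits = pd.DataFrame([_hit(99.0, 1, 100, 100)])
        hits.loc[0, "query_length"] = np.nan
        with pytest.raises(ValueError, match="query_length"):
            rn.filter_prophage_hits(hits)


class TestSpacerFilter:
    @pytest.mark.parametrize(
        "mm,coverage,length,kept",
        [
            (2, 100.0, 21, True),   # at the mismatch budget
            (3, 100.0, 30, False),  # one mismatch too many
            (0, 100.0, 19, False),  # below minimum matched length
            (0, 99.0, 30, False),   # incomplete coverage
            (0, 100.0, 20, True),   # minimum length exactly
        ],
    )
    def test_published_thresholds(self, mm, coverage, length, kept):
        matches = pd.DataFrame([{
            "spacer_id": "s1", "spacer_length": length, "virus_id": "v",
            "host_id": "h", "mismatches_plus_gaps": mm,
            "coverage_percent": coverage, "matched_length": length,
        }])
        assert (len(rn.filter_spacer_matches(matches)) == 1) is kept

    def test_empty_output_is_allowed(self):
        out = rn.filter_spacer_matches(pd.DataFrame(
            columns=["spacer_id", "spacer_length", "virus_id", "host_id",
                     "mismatches_plus_gaps", "coverage_percent", "matched_length"]))
        assert len(out) == 0


class TestHicFilter:
    def test_contact_and_score_thresholds(self):
        links = pd.DataFrame({
            "virus_id": ["v1", "v2"], "host_id": ["h1", "h2"],
            "sample_id": ["S1", "S1"], "contact_count": [5, 1],
            "normalized_score": [0.9, 0.9],
        })
        out = rn.filter_hic_links(links, min_contacts=2)
        assert list(out["virus_id"]) == ["v1"]

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            rn.filter_hic_links(pd.DataFrame(), min_contacts=-1)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_filters_are_monotone_in_their_thresholds(seed):
    """Relaxing any threshold never removes a previously retained row."""
    rng = np.random.default_rng(seed)
    hits = pd.DataFrame([
        _hit(float(rng.uniform(80, 100)), 1, int(rng.integers(50, 101)), 100,
             f"v{i}", "h")
        for i in range(12)
    ])
    strict = rn.filter_prophage_hits(hits, 97.0, 99.5)
    relaxed = rn.filter_prophage_hits(hits, 95.0, 90.0)
    strict_pairs = set(zip(strict["virus_id"], strict["host_id"]))
    relaxed_pairs = set(zip(relaxed["virus_id"], relaxed["host_id"]))
    assert strict_pairs <= relaxed_pairs


class TestDereplicate:
    def test_single_linkage_with_shared_gene_gate(self):
        pairwise = pd.DataFrame({
            "a": ["A", "B"], "b": ["B", "C"],
            "ani": [96.0, 96.0], "shared_gene_fraction": [85.0, 70.0],
        })
        pops = rn.dereplicate(pairwise, {"A": 30_000, "B": 40_000, "C": 20_000},
                              ani_threshold=95.0, shared_threshold=80.0)
        assert pops["A"] == pops["B"] == "B"  # B is the longest member
        assert pops["C"] == "C"

    def test_empty_table_yields_singletons(self):
        pops = rn.dereplicate(pd.DataFrame(), {"X": 1000, "Y": 2000},
                              shared_threshold=None)
        assert pops["X"] == "X" and pops["Y"] == "Y"

    def test_ani_boundary_is_inclusive_and_ties_break_lexicographically(self):
        pairwise = pd.DataFrame({"a": ["A"], "b": ["B"], "ani": [95.0]})
        pops = rn.dereplicate(pairwise, {"A": 1000, "B": 1000},
                              shared_threshold=None)
        assert pops["A"] == pops["B"] == "A"

    def test_unknown_genome_in_pairwise_table_raises(self):
        pairwise = pd.DataFrame({"a": ["A"], "b": ["Z"], "ani": [99.0]})
        with pytest.raises(KeyError):
            rn.dereplicate(pairwise, {"A": 1000}, shared_threshold=None)


class TestMergeLinks:
    def _maps(self):
        vmap = rn.PopulationMap({"v1": "v1", "v2": "v1"}, 95.0, 80.0)
        hmap = rn.PopulationMap({"h1": "h1", "h2": "h2"}, 95.0)
        return vmap, hmap

    def test_same_population_members_collapse_with_summed_support(self):
        vmap, hmap = self._maps()
        ev = pd.DataFrame({
            "virus_id": ["v1", "v2"], "host_id": ["h1", "h1"],
            "sample_id": ["S1", "S2"], "evidence_type": ["hic", "hic"],
            "support": [1, 1],
        })
        merged = rn.merge_links(ev, vmap, hmap)
        assert len(merged) == 1
        assert merged.loc[0, "support_hic"] == 2
        assert merged.loc[0, "samples"] == "S1,S2"

    def test_multiple_evidence_types_union_into_one_pair(self):
        vmap, hmap = self._maps()
        ev = pd.DataFrame({
            "virus_id": ["v1", "v1"], "host_id": ["h1", "h1"],
            "sample_id": ["S1", "S1"], "evidence_type": ["hic", "prophage"],
            "support": [3, 1],
        })
        merged = rn.merge_links(ev, vmap, hmap)
        assert len(merged) == 1
        assert merged.loc[0, "evidence_types"] == "hic,prophage"
        counts = rn.count_links_by_evidence(merged)
        assert counts == {"hic": 1, "prophage": 1, "crispr": 0,
                          "total_unique_pairs": 1}

    def test_merging_is_a_fixed_point_on_representative_keyed_evidence(self):
        vmap, hmap = self._maps()
        ev = pd.DataFrame({
            "virus_id": ["v1", "v1", "v2"], "host_id": ["h1", "h2", "h1"],
            "sample_id": ["S1"] * 3, "evidence_type": ["hic"] * 3,
            "support": [2, 1, 5],
        })
        once = rn.merge_links(ev, vmap, hmap)
        again = rn.merge_links(
            once.rename(columns={"virus_pop_id": "virus_id",
                                 "host_species_id": "host_id"})
                .assign(evidence_type="hic", sample_id="S1",
                        support=lambda d: d["support_hic"]),
            rn.identity_population_map(once["virus_pop_id"].unique()),
            rn.identity_population_map(once["host_species_id"].unique()),
        )
        assert len(again) == len(once)
        assert list(again["support_hic"]) == list(once["support_hic"])


def test_noiseless_evidence_filters_to_exactly_the_planted_links(
        recovery_truth, merged_pairs):
    inferred = set(zip(merged_pairs["virus_pop_id"],
                       merged_pairs["host_species_id"]))
    assert inferred == recovery_truth.true_links


@pytest.mark.parametrize(
    "integrase,in_prophage,expected",
    [
        (False, True, "temperate_prophage"),
        (True, True, "temperate_prophage"),
        (True, False, "temperate"),
        (False, False, "lytic"),
    ],
)
def test_lifestyle_classification_branches(integrase, in_prophage, expected):
    pairs = {("vX", "hY")} if in_prophage else set()
    assert rn.classify_lifestyle("vX", integrase, pairs) == expected


def test_blast_tabular_reader_accepts_12_columns_with_length_map(tmp_path):
    row = "\t".join(map(str, ["v1", "h1", 99.5, 100, 0, 0, 1, 100, 1, 100,
                              1e-30, 185.0]))
    path = tmp_path / "hits.tsv"
    path.write_text(row + "\n")
    df = rn.read_blast_tabular(path, query_lengths={"v1": 100})
    assert df.loc[0, "query_length"] == 100
    with pytest.raises(ValueError):
        rn.read_blast_tabular(path)
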