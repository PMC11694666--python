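"""VHR quartile categories, group tests, and metabolic-module enrichment."""

import numpy as np
import pandas as pd
import pytest

import reefnet as rn
from reefnet.vhr_classes import VhrThresholds


def _pairs(free, cell):
    n = len(free)
    return pd.DataFrame({
        "virus_pop_id": [f"v{i}" for i in range(n)],
        "host_species_id": [f"h{i}" for i in range(n)],
        "vhr_free": free,
        "vhr_cell": cell,
    })


class TestQuartiles:
    def test_linear_interpolation_on_four_values(self):
        thr = rn.vhr_quartiles(_pairs([1, 2, 3, 4], [1, 2, 3, 4]), scale="linear")
        assert thr.q1_free == pytest.approx(1.75)
        assert thr.q3_free == pytest.approx(3.25)

    def test_constant_values_collapse_quartiles(self):
        thr = rn.vhr_quartiles(_pairs([5] * 6, [5] * 6), scale="linear")
        assert thr.q1_free == thr.q3_free == 5.0

    def test_log10_scale_is_the_default(self):
        thr = rn.vhr_quartiles(_pairs([1, 10, 100, 1000], [1, 10, 100, 1000]))
        assert thr.q1_free == pytest.approx(0.75)
        assert thr.q3_free == pytest.approx(2.25)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            rn.vhr_quartiles(_pairs([1, 2, 3], [1, 2, 3]))

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            VhrThresholds(2.0, 1.0, 0.0, 1.0)


class TestClassify:
    thr = VhrThresholds(q1_free=0.0, q3_free=1.0, q1_cell=0.0, q3_cell=1.0,
                        scale="linear")

    @pytest.mark.parametrize(
        "free,cell,expected",
        [
            (2.0, -1.0, "1"),   # high free, low cell
            (2.0, 2.0, "2"),    # high both
            (-1.0, -1.0, "3"),  # low both
            (-1.0, 2.0, "4"),   # low free, high cell
            (0.5, 0.5, "middle"),
            (1.0, 2.0, "middle"),  # on the line is not beyond it
        ],
    )
    def test_corner_categories_and_strict_inequalities(self, free, cell, expected):
        out = rn.classify_pairs(_pairs([free], [cell]), self.thr)
        assert out.loc[0, "category"] == expected

    def test_planted_category_counts_recovered_exactly(self):
        """10/10/10/10/60 pairs planted beyond/between quartile lines."""
        rng = np.random.default_rng(0)
        free, cell = [], []
        for _ in range(10):  # category 1
            free.append(10 ** rng.uniform(1.5, 2.0)); cell.append(10 ** rng.uniform(-2.0, -1.5))
        for _ in range(10):  # category 2
            free.append(10 ** rng.uniform(1.5, 2.0)); cell.append(10 ** rng.uniform(1.5, 2.0))
        for _ in range(10):  # category 3
            free.append(10 ** rng.uniform(-2.0, -1.5)); cell.append(10 ** rng.uniform(-2.0, -1.5))
        for _ in range(10):  # category 4
            free.append(10 ** rng.uniform(-2.0, -1.5)); cell.append(10 ** rng.uniform(1.5, 2.0))
        for _ in range(60):  # middle band
            free.append(10 ** rng.uniform(-0.5, 0.5)); cell.append(10 ** rng.uniform(-0.5, 0.5))
        pairs = _pairs(free, cell)
        thr = VhrThresholds(-1.0, 1.0, -1.0, 1.0)  # log10 lines between the bands
        counts = rn.classify_pairs(pairs, thr)["category"].value_counts()
        assert counts.to_dict() == {"middle": 60, "1": 10, "2": 10, "3": 10, "4": 10}

    def test_every_pair_receives_exactly_one_label(self):
        rng = np.random.default_rng(3)
        pairs = _pairs(10 ** rng.normal(size=40), 10 ** rng.normal(size=40))
        thr = rn.vhr_quartiles(pairs)
        out = rn.classify_pairs(pairs, thr)
        assert out["category"].notna().all()
        assert out["category"].value_counts().sum() == 40

    def test_raising_upper_quartile_only_demotes_high_categories(self):
        rng = np.random.default_rng(4)
        pairs = _pairs(10 ** rng.normal(size=50), 10 ** rng.normal(size=50))
        low = VhrThresholds(-0.5, 0.5, -0.5, 0.5)
        high = VhrThresholds(-0.5, 1.0, -0.5, 1.0)
        a = rn.classify_pairs(pairs, low)["category"]
        b = rn.classify_pairs(pairs, high)["category"]
        for before, after in zip(a, b):
            if before == "2":
                assert after in {"2", "middle", "1", "4"}
            if before == "middle":
                assert after in {"middle"}  # raising Q3 cannot promote out of middle


class TestCompareGroups:
    def test_identical_groups_are_not_distinct(self):
        report = rn.compare_groups({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        assert report["wilcoxon_p"]["x|y"] == pytest.approx(1.0)
        assert report["letters"]["x"] == report["letters"]["y"]

    def test_fully_separated_triples_hit_the_exact_floor(self):
        # all 20 rank splits enumerable: two-sided exact p = 2/20 = 0.1
        report = rn.compare_groups({"lo": [1, 2, 3], "hi": [101, 102, 103]})
        assert report["wilcoxon_p"]["hi|lo"] == pytest.approx(0.1)

    def test_shifted_group_gets_its_own_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=12)
        report = rn.compare_groups({
            "a": base, "b": rng.normal(0, 1, size=12),
            "c": rng.normal(8, 1, size=12),
        })
        assert report["kruskal"]["p_value"] < 0.05
        assert report["letters"]["c"] not in (report["letters"]["a"],
                                              report["letters"]["b"])
        assert set(report["letters"]["a"]) & set(report["letters"]["b"])

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            rn.compare_groups({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rn.compare_groups({"only": [1.0, 2.0]})

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(loc, 1, size=10)
                  for k, loc in (("a", 0), ("b", 0.5), ("c", 5))}
        plain = rn.compare_groups(groups, holm=False)
        adjusted = rn.compare_groups(groups, holm=True)
        for key, p in plain["wilcoxon_p"].items():
            assert adjusted["wilcoxon_p_adjusted"][key] >= p - 1e-12


class TestModulePresence:
    defs = {"M1": ["s1", "s2", "s3", "s4", "s5", "s6"],
            "M2": [f"t{i}" for i in range(10)]}

    def test_bacterial_half_or_three_step_rule(self):
        annotations = {
            "b1": {"s1", "s2"},                    # 2/6: absent
            "b2": {"t0", "t1", "t2"},              # 3/10: present via min-three
            "b3": {"s1", "s2", "s3"},              # 3/6 = 50%: present
        }
        presence = rn.module_presence(annotations, self.defs, "bMAG")
        assert not presence.loc["b1", "M1"]
        assert presence.loc["b2", "M2"]
        assert presence.loc["b3", "M1"]

    def test_viral_single_step_rule_and_contamination_exclusion(self):
        annotations = {"v1": {"t3"}, "v2": {"t3", "t4"}}
        presence = rn.module_presence(annotations, self.defs, "vMAG",
                                      contamination={"v1": 0.0, "v2": 1.5})
        assert list(presence.index) == ["v1"]
        assert presence.loc["v1", "M2"]

    def test_bacterial_rule_is_monotone_in_annotated_steps(self):
        smaller = rn.module_presence({"b": {"t0", "t1"}}, self.defs, "bMAG")
        larger = rn.module_presence({"b": {"t0", "t1", "t2", "t3"}}, self.defs, "bMAG")
        assert (~smaller.loc["b"] | larger.loc["b"]).all()

    def test_unknown_steps_warn_but_do_not_fail(self):
        with pytest.warns(UserWarning, match="outside"):
            presence = rn.module_presence({"b": {"zzz", "s1", "s2", "s3"}},
                                          self.defs, "bMAG")
        assert presence.loc["b", "M1"]


class TestEnrichment:
    def test_universal_module_has_zero_difference(self):
        presence = pd.DataFrame({"M1": [True] * 6},
                                index=[f"h{i}" for i in range(6)])
        cats = {f"h{i}": c for i, c in enumerate(["1", "2", "3", "middle",
                                                  "middle", "middle"])}
        out = rn.category_enrichment(presence, cats)
        assert (out["difference"] == 0).all()

    def test_frequency_difference_arithmetic(self):
        hosts = [f"h{i}" for i in range(10)]
        presence = pd.DataFrame(
            {"M1": [True] * 5 + [True, True, False, False, False]},
            index=hosts)
        cats = {h: ("2" if i < 5 else "middle") for i, h in enumerate(hosts)}
        out = rn.category_enrichment(presence, cats)
        assert out.loc[0, "difference"] == pytest.approx(1.0 - 0.4)

    def test_empty_middle_category_is_an_error(self):
        presence = pd.DataFrame({"M1": [True]}, index=["h0"])
        with pytest.raises(ValueError, match="middle"):
            rn.category_enrichment(presence, {"h0": "2"})

    def test_shared_virus_host_modules_flagged(self):
        presence = pd.DataFrame({"M1": [True], "M2": [True]}, index=["h0"])
        vpresence = pd.DataFrame({"M1": [True], "M2": [False]}, index=["v0"])
        pairs = pd.DataFrame({"virus_pop_id": ["v0"], "host_species_id": ["h0"]})
        presence2 = pd.DataFrame({"M1": [True, False], "M2": [True, False]},
                                 index=["h0", "h1"])
        out = rn.category_enrichment(presence2, {"h0": "2", "h1": "middle"},
                                     vpresence, pairs)
        flags = out.set_index("module_id")["shared_with_virus"]
        assert flags["M1"] and not flags["M2"]
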