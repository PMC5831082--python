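"""Core-pathway classification: thresholds, filters, levels, enrichment,
essential-gene summary and the co-occurrence screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdyn.coreness import (
    CorenessConfig,
    apply_taxonomic_filters,
    classify_core_levels,
    classify_coreness,
    co_occurrence_screen,
    detect_core_pathways,
    genus_of,
    human_associated_genera,
    human_enriched_flag,
    prevalence_and_coreness_counts,
    select_subject_unique_samples,
    site_enriched_flag,
    taxonomic_range_fraction,
)
from microdyn.io_profiles import AbundanceTable, SampleMetadata

CFG = CorenessConfig()


def _meta(rows):
    return SampleMetadata(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "subject_id",
                "body_site",
                "collection_day",
                "replicate_group",
                "visit_number",
            ],
        )
    )


class TestSubjectUniqueSamples:
    def test_lowest_visit_kept(self):
        meta = _meta(
            [
                ("a", "p1", "stool", 200, "g1", 2),
                ("b", "p1", "stool", 0, "g2", 1),
                ("c", "p1", "stool", 400, "g3", 3),
            ]
        )
        assert select_subject_unique_samples(meta) == ["b"]

    def test_first_replicate_kept_by_stable_order(self):
        meta = _meta(
            [
                ("rep2", "p1", "stool", 0, "g1", 1),
                ("rep1", "p1", "stool", 0, "g1", 1),
            ]
        )
        assert select_subject_unique_samples(meta) == ["rep2"]

    def test_count_equals_subject_site_pairs(self):
        rng = np.random.default_rng(0)
        rows = []
        pairs = set()
        for i in range(10):
            for site in ("stool", "tongue_dorsum"):
                if rng.random() < 0.8:
                    pairs.add((f"p{i}", site))
                    for v in range(1, int(rng.integers(1, 4)) + 1):
                        rows.append(
                            (f"s{i}{site[:2]}{v}", f"p{i}", site, v * 100, f"g{i}{site[:2]}{v}", v)
                        )
        meta = _meta(rows)
        assert len(select_subject_unique_samples(meta)) == len(pairs)


class TestDetectCore:
    def _one_pathway(self, abundances):
        cols = [f"s{i}" for i in range(len(abundances))]
        table = AbundanceTable(pd.DataFrame([abundances], index=["P"], columns=cols))
        meta = _meta(
            [(c, f"p{i}", "stool", 0, f"g{i}", 1) for i, c in enumerate(cols)]
        )
        return detect_core_pathways(table, meta, CFG)

    def test_above_threshold_prevalence(self):
        sets = self._one_pathway([2e-4] * 76 + [0.0] * 24)
        assert sets["stool"] == {"P"}

    def test_exactly_75_percent_is_core(self):
        # "at least 75%" implemented as >= 0.75
        sets = self._one_pathway([2e-4] * 75 + [0.0] * 25)
        assert sets["stool"] == {"P"}
        sets = self._one_pathway([2e-4] * 74 + [0.0] * 26)
        assert sets["stool"] == set()

    def test_detection_is_strictly_above_threshold(self):
        sets = self._one_pathway([1e-4] * 100)
        assert sets["stool"] == set()


class TestHumanGenera:
    def _table(self, rows, ids, subjects):
        cols = [f"s{i}" for i in range(len(subjects))]
        table = AbundanceTable(pd.DataFrame(rows, index=ids, columns=cols))
        meta = _meta(
            [(c, subj, "stool", 0, f"g{i}", 1) for i, (c, subj) in enumerate(zip(cols, subjects))]
        )
        return table, meta

    def test_five_subjects_included_one_subject_excluded(self):
        subjects = [f"p{i}" for i in range(5)] + ["p0"] * 6
        high = [2e-3] * 11
        table, meta = self._table(
            [high, [2e-3] * 6 + [0.0] * 5], ["g__A.s__x", "g__B.s__y"], subjects
        )
        # genus A crosses the bar in 5 subjects; genus B only in p0..p4?  No:
        # B is present in the first 6 samples = subjects p0..p4 and p0 again
        got = human_associated_genera(table, meta, CFG)
        assert "A" in got
        assert got == {"A", "B"}

    def test_repeated_samples_of_one_subject_do_not_count(self):
        subjects = ["p0"] * 6 + ["p1"] * 5
        table, meta = self._table([[2e-3] * 6 + [0.0] * 5], ["g__A.s__x"], subjects)
        assert human_associated_genera(table, meta, CFG) == set()

    def test_planted_set_recovered_exactly(self, community):
        got = human_associated_genera(community.species_table, community.metadata, CFG)
        assert got == community.truth["human_genera"]

    def test_genus_parsing(self):
        assert genus_of("g__Bacteroides.s__dorei") == "Bacteroides"
        assert genus_of("k__B|g__Rothia|s__mucilaginosa") == "Rothia"
        assert genus_of("Prevotella copri") == "Prevotella"


class TestTaxonomicFilters:
    def test_range_and_attribution_rules(self):
        candidates = {"stool": {"P_range", "P_attr_hi", "P_attr_ok", "P_missing"}}
        annotations = {
            "P_range": {"EnvOnly"},
            "P_attr_hi": {"Hum"},
            "P_attr_ok": {"Hum"},
        }
        samples = [f"s{i}" for i in range(10)]
        attribution = pd.DataFrame(
            {
                s: {
                    "P_attr_hi": 0.6 if i < 3 else 0.1,  # 30% of samples > 0.5
                    "P_attr_ok": 0.6 if i < 2 else 0.1,  # 20% of samples > 0.5
                    "P_range": 0.0,
                }
                for i, s in enumerate(samples)
            }
        )
        core, excluded = apply_taxonomic_filters(
            candidates, annotations, attribution, {"Hum"}, CFG
        )
        assert core["stool"] == {"P_attr_ok"}
        assert excluded["stool"] == {
            "P_range": "range",
            "P_attr_hi": "attribution",
            "P_missing": "no annotation",
        }


class TestCoreLevels:
    def test_single_area_is_core_only(self):
        report = classify_core_levels(
            {"tongue_dorsum": {"P"}, "supragingival_plaque": {"P"}}, CFG
        )
        assert report.level["P"] == "core"

    def test_two_areas_multicore(self):
        report = classify_core_levels({"stool": {"P"}, "tongue_dorsum": {"P"}}, CFG)
        assert report.level["P"] == "multicore"

    def test_all_six_supercore_and_nesting(self):
        sets = {s: {"P"} for s in CFG.targeted_sites}
        report = classify_core_levels(sets, CFG)
        assert report.level["P"] == "supercore"
        counts = report.counts()
        assert counts["core_pathways"] >= counts["multicore_pathways"] >= counts[
            "supercore_pathways"
        ] == 1


class TestRangeAndEnrichment:
    def test_fractions(self):
        human = {f"h{i}" for i in range(10)}
        annotations = {"P": {"h0", "h1", "h2", "n0", "n1", "n2", "n3", "n4"}}
        annotations["universe"] = human | {f"n{i}" for i in range(90)}
        hf, nf = taxonomic_range_fraction("P", annotations, human)
        assert hf == pytest.approx(0.3)
        assert nf == pytest.approx(5 / 90)

    def test_all_and_none(self):
        human = {"h"}
        annotations = {"P": {"h", "n"}, "Q": set()}
        assert taxonomic_range_fraction("P", annotations, human) == (1.0, 1.0)
        assert taxonomic_range_fraction("Q", annotations, human) == (0.0, 0.0)

    def test_enriched_flag_strict_boundary(self):
        human = {f"h{i}" for i in range(10)}
        nonhuman = {f"n{i}" for i in range(10)}
        annotations = {"P": {"h0"}, "universe": human | nonhuman}
        pan_h = {f"ph{i}" for i in range(10)}
        pan_n = {f"pn{i}" for i in range(10)}
        pan = {"P": {"ph0"}, "universe": pan_h | pan_n}
        assert human_enriched_flag("P", annotations, pan, human, pan_h, CFG)
        # exactly 10% of non-human genera -> strict < fails
        annotations["P"] = {"h0", "n0"}
        assert not human_enriched_flag("P", annotations, pan, human, pan_h, CFG)


class TestSiteEnriched:
    def _setup(self, focal_vals, other_vals):
        rows = []
        vals = []
        for i, v in enumerate(focal_vals):
            rows.append((f"st{i}", f"p{i}", "stool", 0, f"g{i}", 1))
            vals.append(v)
        for i, v in enumerate(other_vals):
            rows.append((f"td{i}", f"q{i}", "tongue_dorsum", 0, f"h{i}", 1))
            vals.append(v)
        meta = _meta(rows)
        table = AbundanceTable(
            pd.DataFrame([vals], index=["P"], columns=[r[0] for r in rows])
        )
        return table, meta

    def test_clear_separation(self):
        table, meta = self._setup([0.01] * 8, [0.004] * 8)
        assert site_enriched_flag("P", "stool", table, meta, CFG)

    def test_insufficient_ratio(self):
        table, meta = self._setup([0.01] * 8, [0.006] * 8)
        assert not site_enriched_flag("P", "stool", table, meta, CFG)

    def test_oral_sites_not_compared_to_each_other(self):
        rows, vals = [], []
        for i in range(6):
            rows.append((f"td{i}", f"p{i}", "tongue_dorsum", 0, f"g{i}", 1))
            vals.append(0.01)
        for i in range(6):
            rows.append((f"bm{i}", f"q{i}", "buccal_mucosa", 0, f"h{i}", 1))
            vals.append(0.02)  # higher at another oral site: ignored
        for i in range(6):
            rows.append((f"st{i}", f"r{i}", "stool", 0, f"k{i}", 1))
            vals.append(0.001)
        meta = _meta(rows)
        table = AbundanceTable(pd.DataFrame([vals], index=["P"], columns=[r[0] for r in rows]))
        assert site_enriched_flag("P", "tongue_dorsum", table, meta, CFG)


class TestPrevalenceSummary:
    def _planted(self, p_ess, p_non, n_ess=40, n_non=60, n_samples=80, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"E{i}" for i in range(n_ess)] + [f"N{i}" for i in range(n_non)]
        vals = np.zeros((n_ess + n_non, n_samples))
        for i in range(n_ess + n_non):
            p = p_ess if i < n_ess else p_non
            mask = rng.random(n_samples) < p
            vals[i, mask] = 2e-4
        cols = [f"s{j}" for j in range(n_samples)]
        table = AbundanceTable(pd.DataFrame(vals, index=ids, columns=cols))
        meta = _meta([(c, f"p{j}", "stool", 0, f"g{j}", 1) for j, c in enumerate(cols)])
        return table, meta, [f"E{i}" for i in range(n_ess)]

    def test_planted_medians_recovered(self):
        table, meta, ess = self._planted(0.9, 0.2)
        summary = prevalence_and_coreness_counts(table, meta, ess, CFG)
        assert summary.median_prevalence["essential"] == pytest.approx(0.9, abs=0.06)
        assert summary.median_prevalence["non_essential"] == pytest.approx(0.2, abs=0.06)
        assert summary.p_prevalence < 1e-6

    def test_identical_classes_uniform_p(self):
        # p-value calibration: under the null, P(p < 0.3) ~ 0.3
        hits = 0
        sims = 120
        for seed in range(sims):
            table, meta, ess = self._planted(0.5, 0.5, n_ess=25, n_non=25, seed=seed)
            s = prevalence_and_coreness_counts(table, meta, ess, CFG)
            hits += s.p_prevalence < 0.3
        rate = hits / sims
        se = math.sqrt(0.3 * 0.7 / sims)
        assert abs(rate - 0.3) < 3 * se + 0.03

    def test_empty_class_rejected(self):
        table, meta, ess = self._planted(0.9, 0.2)
        with pytest.raises(ValueError):
            prevalence_and_coreness_counts(table, meta, [], CFG)


class TestCoOccurrence:
    def _table(self, rows, ids):
        cols = [f"s{i}" for i in range(len(rows[0]))]
        return AbundanceTable(pd.DataFrame(rows, index=ids, columns=cols))

    @staticmethod
    def _enumerated_two_sided_p(n11, n10, n01, n00):
        """Hypergeometric enumeration: sum the probabilities of all tables
        with the same margins whose probability does not exceed the observed
        table's (the two-sided Fisher rule)."""
        row1, col1, n = n11 + n10, n11 + n01, n11 + n10 + n01 + n00

        def prob(k):
            return (
                math.comb(col1, k)
                * math.comb(n - col1, row1 - k)
                / math.comb(n, row1)
            )

        p_obs = prob(n11)
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)
        return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))

    def test_perfect_cooccurrence_exact_p(self):
        # 20 samples, both present in the same 10: the enumeration puts mass
        # 1/C(20,10) on each extreme overlap (10 and 0), so p = 2/C(20,10)
        a = [5e-3] * 10 + [0.0] * 10
        table = self._table([a, a], ["f1", "f2"])
        res = co_occurrence_screen(table, threshold=1e-3)
        row = res.table.iloc[0]
        expected = self._enumerated_two_sided_p(10, 0, 0, 10)
        assert expected == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)
        assert row["p"] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(1.083e-5, rel=1e-3)
        assert np.isinf(row["odds_ratio"])

    def test_five_five_split_exact_p(self):
        a = [5e-3] * 5 + [0.0] * 5
        b = [0.0] * 5 + [5e-3] * 5
        res = co_occurrence_screen(self._table([a, b], ["f1", "f2"]), threshold=1e-3)
        assert res.table.iloc[0]["p"] == pytest.approx(
            self._enumerated_two_sided_p(0, 5, 5, 0)
        )
        assert res.table.iloc[0]["p"] == pytest.approx(0.00794, abs=5e-5)

    def test_matches_fisher_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        vals = (rng.random((6, 30)) < 0.5) * 5e-3
        table = self._table(list(vals), [f"f{i}" for i in range(6)])
        res = co_occurrence_screen(table, threshold=1e-3)
        for row in res.table.itertuples():
            tab = [[row.n11, row.n10], [row.n01, row.n00]]
            assert row.p == pytest.approx(stats.fisher_exact(tab)[1])
        # BH q-values are monotone in p and >= p
        frame = res.table.sort_values("p")
        assert (frame["q"].to_numpy() >= frame["p"].to_numpy() - 1e-12).all()
        assert (np.diff(frame["q"].to_numpy()) >= -1e-12).all()

    def test_constant_features_skipped(self):
        a = [5e-3] * 10
        b = [5e-3] * 5 + [0.0] * 5
        res = co_occurrence_screen(self._table([a, b], ["always", "varies"]), threshold=1e-3)
        assert len(res.table) == 0
        assert res.skipped and "always" in res.skipped[0][2]

    def test_independent_features_controlled_by_fdr(self):
        rng = np.random.default_rng(7)
        false_pre = []
        false_post = []
        for _ in range(30):
            vals = (rng.random((8, 40)) < 0.5) * 5e-3
            res = co_occurrence_screen(
                self._table(list(vals), [f"f{i}" for i in range(8)]), threshold=1e-3
            )
            false_pre.append((res.table["p"] < 0.1).mean())
            false_post.append((res.table["q"] < 0.1).mean())
        assert np.mean(false_pre) == pytest.approx(0.1, abs=0.05)
        assert np.mean(false_post) <= 0.02


def _brute_force_classification(pathway_table, meta, annotations, human, cfg):
    """Independent full-procedure oracle: plain loops, no shared helpers."""
    frame = meta.frame
    unique = {}
    for _, row in frame.iterrows():
        key = (row["subject_id"], row["body_site"])
        if key not in unique or row["visit_number"] < unique[key][1]:
            unique[key] = (row["sample_id"], row["visit_number"])
    chosen = {v[0] for v in unique.values()}
    site_of = dict(zip(frame["sample_id"], frame["body_site"]))
    data = pathway_table.to_frame()
    core = {}
    for site in sorted(set(site_of.values())):
        ids = [s for s in data.columns if s in chosen and site_of[s] == site]
        if not ids:
            continue
        core[site] = set()
        for p in data.index:
            det = (data.loc[p, ids] > cfg.detection_threshold).mean()
            if det >= cfg.prevalence_threshold:
                if annotations.get(p) and set(annotations[p]) & human:
                    core[site].add(p)
    levels = {}
    for p in data.index:
        sites = [s for s, members in core.items() if p in members]
        areas = {cfg.body_area_map.get(s, s) for s in sites}
        if sites and set(cfg.targeted_sites) <= set(sites):
            levels[p] = "supercore"
        elif len(areas) >= 2:
            levels[p] = "multicore"
        elif sites:
            levels[p] = "core"
    return core, levels


class TestFullProcedureOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sites = CFG.targeted_sites
        rows = []
        for i in range(60):
            site = sites[i % len(sites)]
            rows.append((f"s{i}", f"p{i // 3}", site, (i % 3) * 100, f"g{i}", i % 3 + 1))
        meta = _meta(rows)
        ids = [f"P{k}" for k in range(20)]
        vals = rng.random((20, 60)) * 1e-3 * (rng.random((20, 60)) < 0.8)
        table = AbundanceTable(pd.DataFrame(vals, index=ids, columns=[r[0] for r in rows]))
        human = {"Hum"}
        annotations = {
            p: ({"Hum"} if rng.random() < 0.7 else {"EnvZ"}) for p in ids
        }
        candidates = detect_core_pathways(table, meta, CFG)
        core, _ = apply_taxonomic_filters(candidates, annotations, None, human, CFG)
        report = classify_core_levels(core, CFG)
        oracle_core, oracle_levels = _brute_force_classification(
            table, meta, annotations, human, CFG
        )
        assert {s: set(v) for s, v in core.items() if v} == {
            s: v for s, v in oracle_core.items() if v
        }
        assert {p: l for p, l in report.level.items() if l != "none"} == oracle_levels

    def test_parameter_sweep_runs_everywhere(self, community):
        """Counts respond smoothly (no crashes, monotone in prevalence) over
        a grid of detection and prevalence thresholds."""
        counts = {}
        for prev in (0.6, 0.75, 0.9):
            for det in (1e-5, 1e-4, 1e-3):
                cfg = CorenessConfig(detection_threshold=det, prevalence_threshold=prev)
                report = classify_coreness(
                    community.pathway_table,
                    community.species_table,
                    community.metadata,
                    community.annotations,
                    community.attribution,
                    cfg=cfg,
                )
                counts[(prev, det)] = report.counts()["core_instances"]
        for det in (1e-5, 1e-4, 1e-3):
            assert counts[(0.6, det)] >= counts[(0.75, det)] >= counts[(0.9, det)]


class TestEndToEndPlantedTruth:
    def test_community_classification(self, community):
        report = classify_coreness(
            community.pathway_table,
            community.species_table,
            community.metadata,
            community.annotations,
            community.attribution,
            community.pangenomes,
            community.human_pangenomes,
        )
        truth = community.truth
        for p in truth["supercore"]:
            assert report.level[p] == "supercore"
        for p in truth["multicore"]:
            assert report.level[p] in ("multicore", "supercore")
        for p, site in truth["single_site_core"].items():
            assert report.sites_core_at[p] == [site]
        for p, reason in truth["excluded"].items():
            assert p not in report.level or report.level[p] != "supercore"
            assert any(
                excl.get(p) == reason for excl in report.exclusions.values()
            )
        for p in truth["human_enriched"]:
            assert report.human_enriched[p]
        assert not report.human_enriched.get("PWY_SUPERCORE", False)
        for site, paths in truth["site_enriched"].items():
            for p in paths:
                assert site in report.site_enriched.get(p, [])
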