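import math

import numpy as np
import pandas as pd
import pytest

from modcal.benchmark import (
    DetectionOutcome,
    GridSpec,
    ThresholdSet,
    apply_thresholds,
    candidate_filter,
    classify_known_sites,
    detection_summary,
    grid_search,
    precision_recall,
)
from modcal.io_formats import KnownSite, SiteRecord

from conftest import random_called, random_known, random_sites
from oracles import naive_apply, naive_classify, naive_grid_search, naive_precision_recall

PAPER_LIKE = ThresholdSet(0.1, 0.01, 3.0, 0.05)


def site(mol, pos, et, ec, orr, p, depth=100):
    return SiteRecord(mol, pos, "A", et, ec, orr, p, depth)


class TestApplyThresholds:
    def test_clearly_passing_site_called(self):
        s = site("16S", 1518, 0.61, 0.002, 5.0, 1e-8)
        assert apply_thresholds([s], PAPER_LIKE) == {("16S", 1518)}

    def test_all_four_boundaries_inclusive(self):
        s = site("m", 1, 0.1, 0.01, 3.0, 0.05)
        assert apply_thresholds([s], PAPER_LIKE) == {("m", 1)}

    def test_each_criterion_alone_excludes(self):
        base = dict(et=0.1, ec=0.01, orr=3.0, p=0.05)
        for k, bad in (("et", 0.099), ("ec", 0.011), ("orr", 2.9), ("p", 0.051)):
            v = dict(base, **{k: bad})
            s = site("m", 1, v["et"], v["ec"], v["orr"], v["p"])
            assert apply_thresholds([s], PAPER_LIKE) == set()

    def test_matches_naive_filter_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            sites = random_sites(rng)
            t = ThresholdSet(
                float(rng.choice([0.05, 0.1, 0.3])),
                float(rng.choice([0.005, 0.01, 0.02])),
                float(rng.choice([1.5, 3.0])),
                float(rng.choice([0.01, 0.05])),
            )
            assert apply_thresholds(sites, t) == naive_apply(sites, t)

    def test_empty_input(self):
        assert apply_thresholds([], PAPER_LIKE) == set()


class TestCandidateFilter:
    def frame(self, **cols):
        return pd.DataFrame({"molecule": ["m"], "position": [1], **cols})

    @pytest.mark.parametrize(
        "rule,cols,kept",
        [
            # boundary inclusivity exactly as each tool's authors print it
            ("eligos", dict(odds_ratio=[2.5], p_adj=[1e-5]), True),
            ("eligos", dict(odds_ratio=[2.49], p_adj=[1e-5]), False),
            ("drummer", dict(odds_ratio=[1.5], p_g=[0.04], p_oddr=[0.04]), True),
            ("drummer", dict(odds_ratio=[1.5], p_g=[0.05], p_oddr=[0.04]), False),
            ("nanocompore", dict(p_gmm=[0.01]), True),
            ("nanocompore", dict(p_gmm=[0.011]), False),
            ("cheui_diff", dict(stoich_diff=[0.1], p_adj=[0.05]), True),
            # 0.9995 is not < 0.999: the IVT clause rejects
            ("cheui_solo", dict(prob_wt=[0.99995], prob_ivt=[0.9995]), False),
            ("cheui_solo", dict(prob_wt=[0.9999], prob_ivt=[0.99]), True),
        ],
    )
    def test_rules_as_printed(self, rule, cols, kept):
        result = candidate_filter(self.frame(**cols), rule)
        assert result == ({("m", 1)} if kept else set())

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="unknown candidate rule"):
            candidate_filter(self.frame(p_gmm=[0.01]), "minion")


class TestClassifyKnownSites:
    DEPTH = {"16S": 800, "t1": 40, "low": 10}

    def test_offset_signal_upstream(self):
        # like the 16S m3U signal appearing 5 nt upstream of the known site
        known = [KnownSite("16S", 1498, "δ")]
        out = classify_known_sites({("16S", 1493)}, known, self.DEPTH)
        assert out[0].category == "detected_with_offset"
        assert out[0].offset_nt == -5

    def test_not_detectable_takes_precedence_over_exact_call(self):
        known = [KnownSite("16S", 967, "?", detectable=False)]
        out = classify_known_sites({("16S", 967)}, known, self.DEPTH)
        assert out[0].category == "type_not_detectable"

    def test_depth_precedence_and_plain_outcomes(self):
        known = [
            KnownSite("low", 5, "Ж"),
            KnownSite("t1", 37, "Ж"),
            KnownSite("t1", 55, "P"),
        ]
        out = classify_known_sites({("t1", 37)}, known, self.DEPTH)
        assert [o.category for o in out] == [
            "depth_insufficient", "detected", "not_detected"
        ]

    def test_offset_tie_resolves_upstream(self):
        known = [KnownSite("t1", 50, "Ж")]
        out = classify_known_sites({("t1", 47), ("t1", 53)}, known, self.DEPTH)
        assert out[0].offset_nt == -3

    def test_missing_depth_is_an_error(self):
        with pytest.raises(KeyError, match="depth"):
            classify_known_sites(set(), [KnownSite("ghost", 1, "Ж")], self.DEPTH)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            called = random_called(rng)
            known = random_known(rng, n_sites=10)
            depth = {f"m{i}": int(rng.integers(5, 60)) for i in range(3)}
            got = classify_known_sites(called, known, depth)
            want = naive_classify(called, known, depth)
            assert [(o.known_site, o.category, o.offset_nt) for o in got] == want

    def test_categories_partition_catalogue(self, sim, sim_called):
        out = classify_known_sites(sim_called[0], sim.truth.known_sites,
                                   sim.truth.depth_a)
        assert len(out) == len(sim.truth.known_sites)
        summary = detection_summary(out)
        assert summary["categories"]["count"].sum() == len(sim.truth.known_sites)


class TestPrecisionRecall:
    def test_region_within_tolerance_is_true(self):
        called = {("m", p) for p in (5, 6, 7, 8)}
        pr = precision_recall(called, [KnownSite("m", 12, "Ж")], tolerance=10)
        assert pr.true_regions == 1 and pr.false_regions == 0
        assert pr.precision == 1.0

    def test_paperlike_counts(self):
        # 31 exact hits among 36 known sites, no false regions
        known = [KnownSite("r", 40 * i + 20, "Ж") for i in range(36)]
        called = {(k.molecule_id, k.position) for k in known[:31]}
        pr = precision_recall(called, known)
        assert pr.precision == 1.0
        assert pr.recall == pytest.approx(31 / 36)

    def test_empty_called_flags_precision_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            pr = precision_recall(set(), [KnownSite("m", 5, "Ж")])
        assert math.isnan(pr.precision)
        assert pr.recall == 0.0
        assert "undefined" in caplog.text

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            called = random_called(rng, density=0.2)
            known = random_known(rng)
            tol = int(rng.integers(0, 12))
            pr = precision_recall(called, known, tolerance=tol)
            assert (pr.true_regions, pr.false_regions, pr.known_detected,
                    pr.known_total) == naive_precision_recall(called, known, tol)

    def test_recall_window_widens_matching(self):
        known = [KnownSite("m", 10, "Ж")]
        called = {("m", 13)}
        assert precision_recall(called, known).recall == 0.0
        assert precision_recall(called, known, recall_window=3).recall == 1.0

    def test_detectable_only_switch(self):
        known = [KnownSite("m", 10, "Ж"), KnownSite("m", 30, "?", detectable=False)]
        called = {("m", 10)}
        assert precision_recall(called, known).recall == pytest.approx(0.5)
        assert precision_recall(called, known, detectable_only=True).recall == 1.0


class TestGridSpec:
    def test_default_grid_has_32000_combinations(self):
        grid = GridSpec()
        assert grid.n_combinations == 32000
        assert ThresholdSet(0.05, 0.02, 3.0, 0.05) in grid
        assert ThresholdSet(0.1, 0.01, 3.0, 0.05) in grid  # canonical selected set

    def test_unsorted_lists_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            GridSpec(esb_test_values=(0.2, 0.1))


class TestGridSearch:
    def small_instance(self, seed):
        rng = np.random.default_rng(seed)
        sites = random_sites(rng, n=120, n_molecules=3, max_pos=100)
        known = random_known(rng, n_molecules=3, max_pos=100, n_sites=12)
        grid = GridSpec(
            esb_test_values=(0.05, 0.1, 0.3),
            esb_control_values=(0.005, 0.01, 0.02),
            oddr_values=(1.5, 3.0),
            padj_values=(0.01, 0.05),
        )
        return sites, known, grid

    def test_equals_exhaustive_oracle_on_small_grids(self):
        for seed in range(8):
            sites, known, grid = self.small_instance(seed)
            for floor in (0.3, 0.85):
                best, landscape = grid_search(sites, known, grid,
                                              precision_floor=floor)
                oracle_best, oracle_land = naive_grid_search(
                    sites, known, grid, precision_floor=floor
                )
                got = (None if best is None else
                       (best.esb_test_min, best.esb_control_max,
                        best.oddr_min, best.padj_max))
                assert got == oracle_best
                for p in landscape:
                    c = (p.thresholds.esb_test_min, p.thresholds.esb_control_max,
                         p.thresholds.oddr_min, p.thresholds.padj_max)
                    op, orecall = oracle_land[c]
                    assert p.recall == orecall
                    assert p.precision == op or (
                        math.isnan(p.precision) and math.isnan(op)
                    )

    def test_single_combination_grid(self):
        sites = [site("m", 5, 0.3, 0.005, 8.0, 1e-6)]
        known = [KnownSite("m", 5, "Ж")]
        grid = GridSpec((0.1,), (0.01,), (3.0,), (0.05,))
        best, landscape = grid_search(sites, known, grid)
        assert best == ThresholdSet(0.1, 0.01, 3.0, 0.05)
        assert len(landscape) == 1
        # and returned as infeasible when the floor cannot be met
        best2, _ = grid_search(
            sites, [KnownSite("other", 500, "Ж")], grid, precision_floor=0.85
        )
        assert best2 is None

    def test_recall_monotone_under_tightening(self, sim):
        bench = [s for s in sim.sites_a if s.molecule_id.startswith(("trna", "rrna"))]
        known = sim.truth.known_sites
        t = sim.truth.thresholds
        base = precision_recall(apply_thresholds(bench, t), known, thresholds=t)
        for tighter in (
            ThresholdSet(t.esb_test_min + 0.02, t.esb_control_max, t.oddr_min, t.padj_max),
            ThresholdSet(t.esb_test_min, t.esb_control_max / 2, t.oddr_min, t.padj_max),
            ThresholdSet(t.esb_test_min, t.esb_control_max, t.oddr_min + 2, t.padj_max),
            ThresholdSet(t.esb_test_min, t.esb_control_max, t.oddr_min, t.padj_max / 5),
        ):
            pr = precision_recall(apply_thresholds(bench, tighter), known,
                                  thresholds=tighter)
            assert pr.recall <= base.recall
            assert 0.0 <= pr.recall <= 1.0


class TestDetectionSummary:
    def outcomes(self, detected, offset, not_detectable, low_depth, missed):
        out = []
        pos = 1

        def mk(category, n, **kw):
            nonlocal pos
            for _ in range(n):
                detectable = category != "type_not_detectable"
                out.append(
                    DetectionOutcome(
                        KnownSite("m", pos, "Ж" if detectable else "?",
                                  detectable=detectable),
                        category, **kw,
                    )
                )
                pos += 1

        mk("detected", detected)
        mk("detected_with_offset", offset, offset_nt=-5)
        mk("type_not_detectable", not_detectable)
        mk("depth_insufficient", low_depth)
        mk("not_detected", missed)
        return out

    def test_rrna_style_denominators(self):
        # 36 known: 31 detected (one via offset), 4 of undetectable types,
        # 1 genuinely missed
        summary = detection_summary(self.outcomes(30, 1, 4, 0, 1))
        assert summary["recall"]["overall"]["percent"] == 86.1
        assert summary["recall"]["detectable"]["total"] == 32
        assert summary["recall"]["detectable"]["percent_truncated"] == 96.8
        assert summary["recall"]["detectable"]["percent"] == 96.9  # half-up variant

    def test_all_detected_is_100_everywhere(self):
        summary = detection_summary(self.outcomes(5, 0, 0, 0, 0))
        assert all(v["percent"] == 100.0 for v in summary["recall"].values())

    def test_counts_sum_to_catalogue(self):
        summary = detection_summary(self.outcomes(3, 2, 4, 5, 6))
        assert summary["categories"]["count"].sum() == 20
        assert summary["recall"]["overall"]["detected"] == 5

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            detection_summary([])
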