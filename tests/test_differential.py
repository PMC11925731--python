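import math

import numpy as np
import pytest

from modcal.differential import (
    compare_conditions,
    compute_delta_esb,
    ms_correlation,
)
from modcal.io_formats import KnownSite, MsMeasurement, SiteRecord

from conftest import random_sites


def site(mol, pos, et, ec):
    return SiteRecord(mol, pos, "A", et, ec, max(et / max(ec, 1e-3), 0.0), 1e-6, 100)


class TestComputeDeltaEsb:
    def test_heat_responsive_site_labelled_increased(self):
        # 16S-style site: ESB test 0.4 at 37C vs 0.61 at 45C, equal controls
        a = [site("16S", 1518, 0.40, 0.002)]
        b = [site("16S", 1518, 0.61, 0.002)]
        (rec,) = compute_delta_esb(a, b, {("16S", 1518)}, {("16S", 1518)})
        assert rec.delta_a == pytest.approx(0.398)
        assert rec.delta_b == pytest.approx(0.608)
        assert rec.change == "increased"

    def test_position_missing_from_one_condition_gets_zero(self):
        a = [site("m", 5, 0.3, 0.01)]
        (rec,) = compute_delta_esb(a, [], {("m", 5)}, set())
        assert rec.delta_a == pytest.approx(0.29)
        assert rec.delta_b == 0.0
        assert math.isnan(rec.esb_test_b)
        assert rec.change == "decreased"

    def test_total_over_union_of_called_sets(self):
        rng = np.random.default_rng(12)
        a = random_sites(rng, n=80)
        b = random_sites(rng, n=80)
        called_a = {(s.molecule_id, s.position) for s in a[::2]}
        called_b = {(s.molecule_id, s.position) for s in b[::3]}
        records = compute_delta_esb(a, b, called_a, called_b)
        assert {(r.molecule_id, r.position) for r in records} == called_a | called_b

    def test_rowwise_against_naive_recomputation(self):
        rng = np.random.default_rng(13)
        a = random_sites(rng, n=60)
        b = random_sites(rng, n=60)
        called_a = {(s.molecule_id, s.position) for s in a if s.esb_test > 0.05}
        called_b = {(s.molecule_id, s.position) for s in b if s.esb_test > 0.05}
        ia = {(s.molecule_id, s.position): s for s in a}
        ib = {(s.molecule_id, s.position): s for s in b}
        for r in compute_delta_esb(a, b, called_a, called_b):
            key = (r.molecule_id, r.position)
            want_a = (ia[key].esb_test - ia[key].esb_control
                      if key in called_a and key in ia else 0.0)
            want_b = (ib[key].esb_test - ib[key].esb_control
                      if key in called_b and key in ib else 0.0)
            assert r.delta_a == pytest.approx(want_a)
            assert r.delta_b == pytest.approx(want_b)
            if want_a != 0:
                assert r.ratio == pytest.approx(want_b / want_a)
            else:
                assert math.isnan(r.ratio)

    def test_unchanged_band(self):
        a = [site("m", 1, 0.3, 0.01)]
        b = [site("m", 1, 0.3, 0.01)]
        (rec,) = compute_delta_esb(a, b, {("m", 1)}, {("m", 1)})
        assert rec.change == "unchanged"


class TestCompareConditions:
    DEPTH_A = {"m1": 100, "m2": 100, "m3": 12}
    DEPTH_B = {"m1": 100, "m2": 12, "m3": 100}

    def test_three_way_labels(self):
        called_a = {("m1", 5), ("m2", 7)}
        called_b = {("m1", 5), ("m3", 9)}
        statuses, summary = compare_conditions(called_a, called_b,
                                               self.DEPTH_A, self.DEPTH_B)
        by_key = {(s.molecule_id, s.position): s.status for s in statuses}
        assert by_key[("m1", 5)] == "shared"
        # called only at a; molecule under-covered at b -> RNA itself unique
        assert by_key[("m2", 7)] == "modification_in_unique_rna"
        assert by_key[("m3", 9)] == "modification_in_unique_rna"
        assert summary["counts"]["shared"] == 1

    def test_unique_modification_when_rna_covered(self):
        statuses, _ = compare_conditions({("m1", 5)}, set(),
                                         self.DEPTH_A, self.DEPTH_B)
        assert statuses[0].status == "unique_modification"

    def test_labels_partition_union(self):
        rng = np.random.default_rng(14)
        called_a = {("m1", int(p)) for p in rng.integers(1, 50, 20)}
        called_b = {("m1", int(p)) for p in rng.integers(1, 50, 20)}
        statuses, summary = compare_conditions(called_a, called_b,
                                               {"m1": 50}, {"m1": 50})
        assert len(statuses) == len(called_a | called_b)
        assert sum(summary["counts"].values()) == summary["total"]

    def test_missing_depth_is_an_error(self):
        with pytest.raises(KeyError):
            compare_conditions({("ghost", 1)}, set(), {}, {"ghost": 30})

    def test_planted_truth_matches_bruteforce(self, sim, sim_called):
        called_a, called_b = sim_called
        statuses, _ = compare_conditions(called_a, called_b,
                                         sim.truth.depth_a, sim.truth.depth_b)
        for s in statuses:
            key = (s.molecule_id, s.position)
            if key in called_a and key in called_b:
                want = "shared"
            else:
                other = (sim.truth.depth_b if key in called_a
                         else sim.truth.depth_a)[s.molecule_id]
                want = ("modification_in_unique_rna" if other < 20
                        else "unique_modification")
            assert s.status == want

    def test_cds_increased_fraction_reported(self):
        a = [site("m1", 5, 0.2, 0.0)]
        b = [site("m1", 5, 0.4, 0.0)]
        delta = compute_delta_esb(a, b, {("m1", 5)}, {("m1", 5)})
        _, summary = compare_conditions(
            {("m1", 5)}, {("m1", 5)}, {"m1": 100}, {"m1": 100},
            delta_records=delta, biotype_by_site={("m1", 5): "CDS"},
        )
        assert summary["cds_shared"] == 1
        assert summary["cds_increased_fraction"] == 1.0


def delta_records_for(ratios, sites_per_type=2):
    """Build delta records and a type map realizing the given per-type ratios."""
    records, names = [], {}
    a_tables, b_tables = [], []
    pos = 1
    for name, ratio in ratios.items():
        for _ in range(sites_per_type):
            da = 0.3
            a_tables.append(site("m", pos, da, 0.0))
            b_tables.append(site("m", pos, da * ratio, 0.0))
            names[("m", pos)] = name
            pos += 1
    keys = set(names)
    records = compute_delta_esb(a_tables, b_tables, keys, keys)
    return records, names


def ms_rows(ratios, base=1.0):
    rows = []
    for name, ratio in ratios.items():
        rows.append(MsMeasurement(name, "37C", base))
        rows.append(MsMeasurement(name, "45C", base * ratio))
    return rows


class TestMsCorrelation:
    RATIOS = {"D": 0.95, "Um": 0.72, "m66A": 1.18, "Y": 0.78, "m7G": 1.0}

    def test_identical_ratio_vectors_give_rho_1(self):
        records, names = delta_records_for(self.RATIOS)
        rho, p, paired = ms_correlation(records, ms_rows(self.RATIOS), names)
        assert rho == pytest.approx(1.0)
        assert len(paired) == 5

    def test_anticorrelated_pairs_give_rho_minus_1(self):
        records, names = delta_records_for(self.RATIOS)
        inverted = {n: 2.0 - r for n, r in self.RATIOS.items()}
        rho, _, _ = ms_correlation(records, ms_rows(inverted), names)
        assert rho == pytest.approx(-1.0)

    def test_fewer_than_three_pairs_rejected(self):
        ratios = {"D": 1.0, "Um": 0.8}
        records, names = delta_records_for(ratios)
        with pytest.raises(ValueError, match=">= 3"):
            ms_correlation(records, ms_rows(ratios), names)

    def test_zero_variance_rejected(self):
        ratios = {"D": 1.0, "Um": 1.0, "m7G": 1.0}
        records, names = delta_records_for(ratios)
        with pytest.raises(ValueError, match="zero-variance"):
            ms_correlation(records, ms_rows(ratios), names)

    def test_symmetric_under_condition_swap_on_log_scale(self):
        records, names = delta_records_for(self.RATIOS)
        ms = ms_rows(self.RATIOS)
        rho_fwd, _, _ = ms_correlation(records, ms, names, log_scale=True)
        # swap conditions in both datasets: b/a ratios invert on both axes
        swapped = [
            type(r)(r.molecule_id, r.position, r.esb_test_b, r.esb_control_b,
                    r.esb_test_a, r.esb_control_a, r.delta_b, r.delta_a,
                    r.delta_a / r.delta_b, r.change)
            for r in records
        ]
        rho_rev, _, _ = ms_correlation(swapped, ms, names, condition_a="45C",
                                       condition_b="37C", log_scale=True)
        assert rho_rev == pytest.approx(rho_fwd)

    def test_sites_with_zero_delta_a_excluded(self):
        records, names = delta_records_for(self.RATIOS)
        extra_a = [site("m", 99, 0.1, 0.1)]        # delta 0 -> undefined ratio
        extra = compute_delta_esb(extra_a, [], {("m", 99)}, set())
        names[("m", 99)] = "D"
        rho, _, paired = ms_correlation(records + extra, ms_rows(self.RATIOS), names)
        assert rho == pytest.approx(1.0)
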