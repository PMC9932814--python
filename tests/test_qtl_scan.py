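import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from riqtl import core_io, qtl_scan, synthetic_data as sd
from riqtl.core_io import GenotypeMatrix, MarkerInfo, ValidationError
from riqtl.qtl_scan import (
    ScanRecord,
    ScanResult,
    composite_scan,
    lod_scan,
    permutation_thresholds,
    support_intervals,
)


def closed_form_lod(codes: str, y) -> float:
    """Independent oracle: LOD = -(n/2) log10(1 - r^2), r from Pearson."""
    x = np.array([1.0 if c == "A" else 0.0 for c in codes])
    r = stats.pearsonr(x, np.asarray(y, float)).statistic
    return -(len(y) / 2.0) * math.log10(1.0 - r**2)


class TestLodScan:
    def test_matches_closed_form_worked_example(self, single_marker_genotypes):
        means = dict(zip(single_marker_genotypes.strains, [10, 11, 10, 20, 21, 19]))
        scan = lod_scan(single_marker_genotypes, means)
        rec = scan.records[0]
        assert rec.lod == pytest.approx(5.19, abs=0.01)
        assert rec.lod == pytest.approx(
            closed_form_lod("AAABBB", [10, 11, 10, 20, 21, 19]), abs=1e-12
        )
        assert rec.effect == pytest.approx(-9.67, abs=0.01)

    def test_perfect_separation_is_capped(self, single_marker_genotypes):
        means = dict(zip(single_marker_genotypes.strains, [10, 10, 10, 20, 20, 20]))
        rec = lod_scan(single_marker_genotypes, means).records[0]
        assert rec.lod == pytest.approx(6 / 2 * 12)
        assert "separation" in rec.flags

    def test_constant_phenotype_gives_zero_everywhere(self, toy_genotypes):
        means = {s: 5.0 for s in toy_genotypes.strains}
        assert (lod_scan(toy_genotypes, means).lods == 0).all()

    def test_monomorphic_marker_flagged(self):
        g = GenotypeMatrix(
            ["s1", "s2", "s3"],
            [MarkerInfo("m1", "1", 0.0, 1.0)],
            np.array([["A"], ["A"], ["A"]]),
        )
        rec = lod_scan(g, {"s1": 1.0, "s2": 2.0, "s3": 3.0}).records[0]
        assert rec.lod == 0.0 and "monomorphic" in rec.flags

    def test_missing_calls_dropped_per_marker(self):
        g = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [MarkerInfo("m1", "1", 0.0, 1.0), MarkerInfo("m2", "1", 10.0, 2.0)],
            np.array(
                [["A", "A"], ["A", "B"], ["U", "A"], ["B", "B"], ["B", "A"], ["B", "B"]]
            ),
        )
        y = {f"s{i}": v for i, v in enumerate([10.0, 11, 99, 20, 21, 19])}
        rec = lod_scan(g, y).records[0]
        assert rec.n_used == 5
        assert rec.lod == pytest.approx(
            closed_form_lod("AABBB", [10, 11, 20, 21, 19]), abs=1e-9
        )

    def test_exclude_strains_removes_parentals(self, single_marker_genotypes):
        means = dict(zip(single_marker_genotypes.strains, [10, 11, 10, 20, 21, 19]))
        scan = lod_scan(single_marker_genotypes, means, exclude_strains=["s0"])
        assert scan.records[0].n_used == 5

    def test_weighted_scan_matches_statsmodels_wls(self, toy_genotypes):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        y = rng.normal(50, 10, 6)
        w = rng.uniform(0.5, 2.0, 6)
        means = dict(zip(toy_genotypes.strains, y))
        weights = dict(zip(toy_genotypes.strains, w))
        scan = lod_scan(toy_genotypes, means, weights=weights)
        X = toy_genotypes.indicator()
        for j, rec in enumerate(scan.records):
            null = sm.WLS(y, np.ones(6), weights=w).fit()
            full = sm.WLS(y, np.column_stack([np.ones(6), X[:, j]]), weights=w).fit()
            expected = (6 / 2) * math.log10(null.ssr / full.ssr)
            assert rec.lod == pytest.approx(max(expected, 0.0), abs=1e-9)

    @given(
        scale=st.floats(0.01, 1000.0),
        shift=st.floats(-1e5, 1e5),
    )
    def test_lod_affine_invariant_effect_scales(self, scale, shift):
        g = GenotypeMatrix(
            [f"s{i}" for i in range(6)],
            [MarkerInfo("m1", "1", 0.0, 1.0)],
            np.array([["A"], ["A"], ["A"], ["B"], ["B"], ["B"]]),
        )
        y = np.array([10.0, 11, 10, 20, 21, 19])
        base = lod_scan(g, dict(zip(g.strains, y))).records[0]
        moved = lod_scan(g, dict(zip(g.strains, y * scale + shift))).records[0]
        assert moved.lod == pytest.approx(base.lod, rel=1e-7, abs=1e-9)
        assert moved.effect == pytest.approx(base.effect * scale, rel=1e-7)


class TestCompositeScan:
    def test_empty_controls_reduces_to_simple_scan(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        a = lod_scan(toy_genotypes, means)
        b = composite_scan(toy_genotypes, means, [])
        np.testing.assert_allclose(a.lods, b.lods)

    def test_control_marker_absorbs_its_own_signal(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        scan = composite_scan(toy_genotypes, means, ["m1"])
        j = toy_genotypes.marker_index("m1")
        assert scan.records[j].lod == pytest.approx(0.0, abs=1e-9)

    def test_near_covariate_flagging_same_chromosome_only(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        scan = composite_scan(toy_genotypes, means, ["m1"])
        flags = {r.marker.name: r.flags for r in scan.records}
        assert "near-covariate" in flags["m1"]  # 0 cM away, same chromosome
        assert "near-covariate" not in flags["m3"]  # other chromosome
        assert "near-covariate" not in flags["m2"]  # 20 cM away

    def test_monomorphic_control_rejected(self):
        g = GenotypeMatrix(
            ["s1", "s2", "s3", "s4"],
            [MarkerInfo("m1", "1", 0.0, 1.0), MarkerInfo("m2", "1", 10.0, 2.0)],
            np.array([["A", "A"], ["A", "B"], ["A", "A"], ["A", "B"]]),
        )
        y = {s: float(i) for i, s in enumerate(g.strains)}
        with pytest.raises(ValidationError, match="monomorphic"):
            composite_scan(g, y, ["m1"])

    def test_conditioning_unveils_second_qtl(self):
        """Controlling the larger QTL raises the smaller QTL's LOD."""
        wins = 0
        for rep in range(20):
            cfg = sd.SimConfig(
                qtls=(
                    sd.QtlSpec("19", 11.0, 13585.0, "A"),
                    sd.QtlSpec("9", 26.0, 11139.0, "A"),
                ),
                seed=7000 + rep,
            )
            gt = sd.simulate_ri_genotypes(cfg)
            ph = sd.simulate_phenotypes(gt, cfg)
            simple = lod_scan(gt, ph)
            comp = composite_scan(gt, ph, [simple.peak("19").marker.name])
            j = gt.marker_index(sd.snap_qtls_to_markers(gt, cfg.qtls)[1][1])
            wins += comp.records[j].lod > simple.records[j].lod
        assert wins >= 16


class TestPermutationThresholds:
    def test_constant_phenotype_gives_zero_thresholds(self, toy_genotypes):
        means = {s: 3.0 for s in toy_genotypes.strains}
        res = permutation_thresholds(toy_genotypes, means, n_perm=200, seed=1)
        assert res.suggestive == 0.0 and res.significant == 0.0

    def test_quantile_ordering(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        res = permutation_thresholds(toy_genotypes, means, n_perm=500, seed=2)
        assert res.significant >= res.suggestive
        assert res.significant in res.max_lods  # attained value ("higher" rule)

    def test_reproducible_from_seed(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        a = permutation_thresholds(toy_genotypes, means, n_perm=200, seed=9)
        b = permutation_thresholds(toy_genotypes, means, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.max_lods, b.max_lods)

    def test_small_n_perm_warns(self, toy_genotypes):
        means = dict(zip(toy_genotypes.strains, [10.0, 12, 11, 20, 21, 19]))
        with pytest.warns(UserWarning, match="unstable"):
            permutation_thresholds(toy_genotypes, means, n_perm=50, seed=1)


def trace(positions, lods, chrom="1"):
    records = [
        ScanRecord(MarkerInfo(f"t{i}", chrom, float(i), float(p)), float(l), 0.0, 6)
        for i, (p, l) in enumerate(zip(positions, lods))
    ]
    return ScanResult(records)


class TestSupportIntervals:
    def test_hand_interpolated_crossings(self):
        scan = trace([10, 20, 30, 40, 50, 60], [1.0, 2.0, 4.0, 3.0, 2.4, 1.0])
        (iv,) = support_intervals(scan, "1", drop=1.5)
        assert iv.start_Mb == pytest.approx(22.5)
        assert iv.end_Mb == pytest.approx(48.3333, abs=1e-3)
        assert iv.peak_marker == "t2" and iv.peak_lod == 4.0

    def test_split_locus_merged_across_small_gap(self):
        # two runs above threshold separated by a ~5 Mb dip (the split-locus
        # situation: a recombination event in one strain splits one QTL)
        positions = [30, 33, 36, 37, 39, 42, 45, 48, 50, 55]
        lods = [4.0, 4.2, 4.1, 3.9, 1.0, 3.8, 4.0, 3.9, 3.7, 1.0]
        scan = trace(positions, lods)
        ivs = support_intervals(scan, "1", drop=1.5, merge_gap_Mb=10)
        assert len(ivs) == 1 and ivs[0].merged_from == 2
        assert ivs[0].start_Mb == 30 and ivs[0].end_Mb < 55

    def test_no_merge_when_gap_large(self):
        positions = [10, 20, 30, 60, 70, 80]
        lods = [4.0, 4.0, 0.5, 0.5, 4.0, 4.0]
        ivs = support_intervals(trace(positions, lods), "1", drop=1.5, merge_gap_Mb=5)
        assert len(ivs) == 2 and all(iv.merged_from == 1 for iv in ivs)

    def test_monotone_trace_clamps_to_first_position(self):
        scan = trace([10, 20, 30, 40], [5.0, 4.0, 2.0, 1.0])
        (iv,) = support_intervals(scan, "1", drop=1.5)
        assert iv.start_Mb == 10.0

    def test_sub_threshold_flagging(self):
        scan = trace([10, 20, 30], [1.0, 2.0, 1.0])
        (iv,) = support_intervals(scan, "1", drop=1.5, suggestive=3.0)
        assert "sub-threshold" in iv.flags

    def test_interval_property_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(4, 30))
            positions = np.sort(rng.uniform(0, 100, m))
            positions += np.arange(m) * 1e-6  # ensure strictly increasing
            lods = rng.uniform(0, 6, m)
            ivs = support_intervals(trace(positions, lods), "1", merge_gap_Mb=0.0)
            peak = lods.max()
            for iv in ivs:
                assert iv.start_Mb <= iv.end_Mb
                inside = (positions >= iv.start_Mb - 1e-9) & (positions <= iv.end_Mb + 1e-9)
                assert (lods[inside] >= peak - 1.5 - 1e-9).all()


class TestParameterRecovery:
    def test_peak_location_and_effect_recovery(self):
        """One planted QTL on a 100-strain panel is found and sized."""
        s = 5000.0
        hits, effects = 0, []
        for rep in range(25):
            cfg = sd.SimConfig(
                n_strains=100,
                qtls=(sd.QtlSpec("9", 26.0, s, "A"),),
                between_strain_residual_sd=s * math.sqrt(3) / 2,
                seed=5000 + rep,
            )
            gt = sd.simulate_ri_genotypes(cfg)
            ph = sd.simulate_phenotypes(gt, cfg)
            scan = lod_scan(gt, ph)
            peak = scan.peak()
            true = gt.markers[gt.marker_index(sd.snap_qtls_to_markers(gt, cfg.qtls)[0][1])]
            if (
                peak.marker.chromosome == true.chromosome
                and abs(peak.marker.position_cM - true.position_cM) <= 10
            ):
                hits += 1
            effects.append(scan.records[gt.marker_index(true.name)].effect)
        assert hits >= 20
        assert abs(np.mean(effects) - s) / s < 0.1
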