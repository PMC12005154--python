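"""Mosaic simulator: tile process, signal injection, array design, scenarios."""

import filecmp
import os

import numpy as np
import pytest
from scipy import stats

from surfbat.mosaic_sim import (
    MosaicSpec,
    decimate_sites,
    design_array_sites,
    frequency_window_filter,
    generate_founder_panel,
    inject_allelic_signal,
    inject_local_ancestry_signal,
    scenario,
    simulate_case_cohort,
    simulate_mosaic_haplotype,
    simulate_pool,
)

from conftest import make_panel


@pytest.fixture(scope="module")
def small_panel():
    rng = np.random.default_rng(777)
    return generate_founder_panel(
        {"AFR": 30, "EUR": 30}, n_sites=300, length_cm=50.0, rng=rng
    )


class TestMosaicHaplotype:
    def test_single_group_weights(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=5.0, group_weights={"AFR": 1.0})
        _, track = simulate_mosaic_haplotype(small_panel, spec, rng)
        assert all(t.group == "AFR" for t in track.tiles)

    def test_alleles_equal_source_everywhere(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=5.0, group_weights={"AFR": 0.5, "EUR": 0.5})
        cm = small_panel.cm_positions()
        for _ in range(5):
            alleles, track = simulate_mosaic_haplotype(small_panel, spec, rng)
            src = np.array([track.source_at(c) for c in cm])
            np.testing.assert_array_equal(
                alleles, small_panel.haplotypes[np.arange(small_panel.n_sites), src]
            )

    def test_tiles_tile_the_chromosome(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=8.0, group_weights={"AFR": 0.5, "EUR": 0.5})
        _, track = simulate_mosaic_haplotype(small_panel, spec, rng)
        cm = small_panel.cm_positions()
        assert track.tiles[0].start_cm == pytest.approx(cm[0])
        assert track.tiles[-1].end_cm >= cm[-1]
        for a, b in zip(track.tiles, track.tiles[1:]):
            assert a.end_cm == pytest.approx(b.start_cm)

    def test_tile_count_poisson_expectation(self, rng):
        # over a chromosome of length L the expected tile count is 1 + L/tile
        panel = generate_founder_panel(
            {"A": 10}, n_sites=40, length_cm=40.0, rng=np.random.default_rng(3)
        )
        spec = MosaicSpec(tile_cm=10.0, group_weights={"A": 1.0})
        span = panel.cm_positions()[-1] - panel.cm_positions()[0]
        counts = []
        for _ in range(4000):
            _, track = simulate_mosaic_haplotype(panel, spec, rng)
            counts.append(len(track.tiles))
        expect = 1.0 + span / 10.0
        se = np.sqrt(span / 10.0 / len(counts))
        assert np.mean(counts) == pytest.approx(expect, abs=4 * se + 0.05)

    def test_tile_lengths_exponential(self, rng):
        panel = generate_founder_panel(
            {"A": 10}, n_sites=40, length_cm=200.0, rng=np.random.default_rng(4)
        )
        spec = MosaicSpec(tile_cm=10.0, group_weights={"A": 1.0})
        lengths = []
        while len(lengths) < 10_000:
            _, track = simulate_mosaic_haplotype(panel, spec, rng)
            # include the straddling last tile: every gap is a full exponential
            # draw, and dropping the straddler would length-bias the sample
            lengths.extend(t.end_cm - t.start_cm for t in track.tiles)
        ks = stats.kstest(lengths, "expon", args=(0, 10.0))
        assert ks.pvalue > 0.01

    def test_group_frequency_converges_to_weights(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=2.0, group_weights={"AFR": 0.3, "EUR": 0.7})
        n_afr = n_tot = 0
        for _ in range(300):
            _, track = simulate_mosaic_haplotype(small_panel, spec, rng)
            n_afr += sum(t.group == "AFR" for t in track.tiles)
            n_tot += len(track.tiles)
        phat = n_afr / n_tot
        ci = 2.576 * np.sqrt(0.3 * 0.7 / n_tot)
        assert abs(phat - 0.3) < ci

    def test_missing_group_rejected(self, small_panel, rng):
        spec = MosaicSpec(group_weights={"MARS": 1.0})
        with pytest.raises(ValueError, match="MARS"):
            simulate_mosaic_haplotype(small_panel, spec, rng)


class TestCohortAndInjection:
    def test_cohort_determinism(self, small_panel):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5}, seed=42)
        t1, tr1 = simulate_case_cohort(small_panel, 5, spec)
        t2, tr2 = simulate_case_cohort(small_panel, 5, spec)
        np.testing.assert_array_equal(t1.haplotypes, t2.haplotypes)
        assert [t.tiles for t in tr1] == [t.tiles for t in tr2]

    def test_cohort_group_fraction(self, small_panel):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5}, seed=1)
        _, tracks = simulate_case_cohort(small_panel, 50, spec)
        fracs = [t.group_fraction("AFR") for t in tracks]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_ancestry_injection_composition(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5})
        _, tracks = simulate_pool(small_panel, 400, spec, rng)
        focal = 25.0
        sel = inject_local_ancestry_signal(tracks, focal, 130, 50, "EUR", "AFR", rng)
        assert len(sel) == 180
        assert len(set(sel.tolist())) == 180  # without replacement
        groups = [tracks[i].group_at(focal) for i in sel]
        assert groups.count("EUR") == 130 and groups.count("AFR") == 50

    def test_ancestry_injection_shortfall_named(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 1.0})
        _, tracks = simulate_pool(small_panel, 20, spec, rng)
        with pytest.raises(ValueError, match="EUR"):
            inject_local_ancestry_signal(tracks, 25.0, 5, 5, "EUR", "AFR", rng)

    def test_allelic_injection_exact_counts(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5})
        pool, _ = simulate_pool(small_panel, 300, spec, rng)
        freq = small_panel.alt_frequencies()
        site = int(np.argmin(np.abs(freq - 0.5)))
        sel = inject_allelic_signal(pool, site, 100, 80, rng)
        assert pool[sel, site].sum() == 100
        assert len(sel) == 180

    def test_allelic_injection_noncarriers_only(self, small_panel, rng):
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5})
        pool, _ = simulate_pool(small_panel, 200, spec, rng)
        freq = small_panel.alt_frequencies()
        site = int(np.argmin(np.abs(freq - 0.5)))
        sel = inject_allelic_signal(pool, site, 0, 50, rng)
        assert pool[sel, site].sum() == 0


class TestArrayDesign:
    def test_identical_columns_thinned(self):
        col = np.array([0, 0, 1, 1, 0, 1], dtype=np.uint8)
        haps = np.column_stack([col, col, 1 - col])  # sites x haps? build site-major
        haps = np.array([col, col, 1 - col])  # 3 sites, same column pattern
        panel = make_panel(haps, cm=[0.0, 0.1, 0.2])
        kept = design_array_sites(panel, maf_min=0.1, r2_max=0.8, n_sites=10)
        # site 1 duplicates site 0 (r2=1); site 2 is its complement (also r2=1)
        assert list(kept) == [0]

    def test_moderate_ld_retained(self):
        s1 = np.array([0, 0, 1, 1], dtype=np.uint8)
        s2 = np.array([0, 1, 1, 1], dtype=np.uint8)
        panel = make_panel(np.array([s1, s2]), cm=[0.0, 0.1])
        kept = design_array_sites(panel, maf_min=0.1, r2_max=0.8, n_sites=10)
        assert list(kept) == [0, 1]  # r^2 = 1/3 <= 0.8

    def test_shortfall_returns_all_with_warning(self, small_panel, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="surfbat"):
            kept = design_array_sites(small_panel, n_sites=100_000)
        assert kept.size < 100_000
        assert any("candidates" in r.message for r in caplog.records)

    def test_subsample_is_sorted_and_sized(self, small_panel, rng):
        kept = design_array_sites(small_panel, n_sites=50, rng=rng)
        assert kept.size == 50
        assert np.all(np.diff(kept) > 0)


class TestSiteFilters:
    def test_frequency_window(self, rng):
        haps = np.zeros((3, 100), dtype=np.uint8)
        haps[0, :4] = 1  # freq 0.04 -> dropped
        haps[1, :50] = 1  # freq 0.50 -> kept
        haps[2, :96] = 1  # freq 0.96 -> dropped
        panel = make_panel(haps)
        np.testing.assert_array_equal(
            frequency_window_filter(panel), [False, True, False]
        )

    def test_decimation_counts(self):
        idx = decimate_sites(100, 5)
        assert idx.size == 20
        assert list(idx[:3]) == [0, 5, 10]


class TestScenarios:
    def test_bundle_determinism_byte_identical(self, tmp_path):
        b1 = scenario("null", scale=0.05, seed=7)
        b2 = scenario("null", scale=0.05, seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        b1.write(str(d1))
        b2.write(str(d2))
        for name in sorted(os.listdir(d1)):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_ancestry_signal_truth(self):
        b = scenario("ancestry_signal", scale=0.05, seed=3)
        n_sel = 2 * b.config["n_cases"]
        assert b.truth["n_focal_EUR"] + b.truth["n_focal_AFR"] == n_sel
        assert b.truth["n_focal_EUR"] == round(n_sel * 650 / 900)
        groups = [t.group_at(b.truth["focal_cm"]) for t in b.tracks]
        assert groups.count("EUR") == b.truth["n_focal_EUR"]

    def test_allelic_signal_truth(self):
        b = scenario("allelic_signal", scale=0.05, seed=3)
        j = b.truth["signal_site_index"]
        assert int(b.case_alleles[:, j].sum()) == b.truth["n_carriers"]
        n_sel = 2 * b.config["n_cases"]
        assert b.truth["n_carriers"] == round(n_sel * 500 / 900)

    def test_inflation_scenario_panels(self):
        b = scenario("small_panel_inflation", scale=0.05, seed=3)
        assert b.alt_panel is not None
        assert set(b.panel.group_labels) == {"EUR"}
        assert "AFR" in set(b.alt_panel.group_labels)
        assert b.panel.n_sites == b.alt_panel.n_sites

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("voodoo")

    def test_admixed_null_weights(self):
        b = scenario("admixed_null", scale=0.1, seed=5)
        fr = np.mean([t.group_fraction("ASIA") for t in b.tracks])
        assert fr == pytest.approx(0.5, abs=0.06)
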