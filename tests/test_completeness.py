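"""Rolling-window recovery simulation and completeness/size estimation."""

import math

import numpy as np
import pytest

from sagpipe.core_genome import MarkerCatalog, OrthologMatrix, marker_catalog
from sagpipe.completeness import (
    GenomeLayout,
    RecoveryDistribution,
    build_layout,
    clustered_marker_layout,
    count_markers_in_sag,
    estimate_completeness,
    estimate_genome_size,
    layout_from_dict,
    layout_to_dict,
    simulate_recovery,
    uniform_marker_layout,
    window_marker_counts,
)
from sagpipe.io import Hit, HitTable, SagAssembly
from sagpipe.synthetic import generate_sag


def catalog_one_genome(genome_id, markers):
    """Catalog with one genome; markers: cluster -> (contig, start, end)."""
    return MarkerCatalog(
        clusters=sorted(markers),
        coords={c: {genome_id: (ctg, s, e, "+")} for c, (ctg, s, e) in markers.items()},
    )


class TestBuildLayout:
    def test_single_contig_coordinates_unchanged(self):
        asm = SagAssembly("g", [("c1", "A" * 200)])
        cat = catalog_one_genome("g", {"m1": ("c1", 10, 20)})
        layout = build_layout(asm, cat)
        assert layout.markers["m1"] == (10, 20)
        assert layout.length == 200

    def test_second_contig_offsets(self):
        asm = SagAssembly("g", [("c1", "A" * 100), ("c2", "A" * 100)])
        cat = catalog_one_genome("g", {"m1": ("c2", 10, 20)})
        layout = build_layout(asm, cat)
        assert layout.markers["m1"] == (110, 120)

    def test_permuted_order_full_window_invariant(self):
        asm = SagAssembly("g", [("c1", "A" * 100), ("c2", "A" * 100)])
        cat = catalog_one_genome("g", {"m1": ("c2", 10, 20), "m2": ("c1", 50, 70)})
        for order in (["c1", "c2"], ["c2", "c1"]):
            layout = build_layout(asm, cat, contig_order=order)
            counts = window_marker_counts(layout, layout.length, np.array([0, 37, 150]))
            assert (counts == 2).all()

    def test_missing_marker_names_cluster(self):
        asm = SagAssembly("g", [("c1", "A" * 100)])
        cat = catalog_one_genome("other", {"m1": ("c1", 10, 20)})
        with pytest.raises(ValueError, match="m1"):
            build_layout(asm, cat)


class TestSimulateRecovery:
    def test_full_fraction_recovers_all_markers_at_every_start(self):
        layout = uniform_marker_layout(100_000, 8, marker_length=500)
        dist = simulate_recovery([layout], fraction_grid=np.array([1.0]), n_starts=50)
        assert dist.observed_counts() == [8]
        assert len(dist.samples[8]) == 50

    def test_counts_match_bruteforce_interval_oracle(self):
        layout = GenomeLayout(
            "g", 1000, {"a": (0, 100), "b": (150, 250), "c": (400, 450), "d": (900, 980)}
        )
        starts = np.arange(1000)
        counts = window_marker_counts(layout, 300, starts)
        for s in range(1000):
            expected = 0
            for ms, me in layout.markers.values():
                # brute force on the unrolled circle
                rel = (ms - s) % 1000
                if rel + (me - ms) <= 300:
                    expected += 1
            assert counts[s] == expected

    def test_pooling_two_identical_layouts_doubles_samples(self):
        layout = uniform_marker_layout(50_000, 5, marker_length=200)
        one = simulate_recovery([layout], fraction_grid=np.array([0.3, 0.7]), n_starts=40)
        two = simulate_recovery([layout, layout], fraction_grid=np.array([0.3, 0.7]), n_starts=40)
        for k in one.observed_counts():
            assert len(two.samples[k]) == 2 * len(one.samples[k])
            assert np.allclose(np.sort(two.samples[k]), np.repeat(np.sort(one.samples[k]), 2))

    def test_k_total_support_includes_one(self):
        layout = uniform_marker_layout(50_000, 5, marker_length=200)
        dist = simulate_recovery([layout], n_starts=100)
        assert 1.0 in dist.samples[5]

    def test_empty_grid_rejected(self):
        layout = uniform_marker_layout(50_000, 5)
        with pytest.raises(ValueError, match="non-empty"):
            simulate_recovery([layout], fraction_grid=np.array([]))

    def test_summary_box_statistics(self):
        dist = RecoveryDistribution(
            m=5, samples={2: np.array([0.1, 0.2, 0.3, 0.4, 0.9])}
        )
        row = dist.summary().iloc[0]
        arr = np.array([0.1, 0.2, 0.3, 0.4, 0.9])
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        assert row["median"] == pytest.approx(med)
        assert row["q1"] == pytest.approx(q1)
        assert row["q3"] == pytest.approx(q3)
        assert row["n_outliers"] == int(((arr < q1 - 1.5 * (q3 - q1)) | (arr > q3 + 1.5 * (q3 - q1))).sum())


class TestEstimateCompleteness:
    def test_degenerate_distribution(self):
        dist = RecoveryDistribution(m=71, samples={5: np.full(10, 0.3)})
        fraction, (q1, q3) = estimate_completeness(5, dist)
        assert fraction == 0.3
        assert q1 == q3 == 0.3

    def test_missing_k_advises_denser_grid(self):
        dist = RecoveryDistribution(m=71, samples={5: np.full(10, 0.3)})
        with pytest.raises(ValueError, match="denser"):
            estimate_completeness(6, dist)

    def test_median_non_decreasing_in_k_on_uniform_layout(self):
        layout = uniform_marker_layout(3_000_000, 71)
        dist = simulate_recovery([layout], n_starts=500)
        summary = dist.summary()
        well_sampled = summary[summary["n"] >= 30]
        medians = well_sampled.sort_values("k")["median"].to_numpy()
        assert (np.diff(medians) >= -1e-12).all()

    def test_clustered_markers_exceed_naive_k_over_m(self):
        # with clustered markers a small observed count is compatible with
        # large recovered fractions, so the median estimate is far above k/M
        layout = clustered_marker_layout(3_000_000, 71, cluster_span=0.1)
        dist = simulate_recovery([layout], n_starts=500)
        for k in (2, 3, 5):
            assert dist.median_fraction(k) > k / 71


class TestEstimateGenomeSize:
    def test_complete_assembly(self):
        est = estimate_genome_size(1_000_000, 1.0, (1.0, 1.0))
        assert est.size == 1_000_000
        assert est.uncertainty == 0.0

    def test_size_fraction_product_identity(self):
        est = estimate_genome_size(807_656, 0.5624)
        assert math.isclose(est.size * est.fraction, 807_656, rel_tol=1e-12)

    def test_group3_sag_table_row(self):
        # assembly 1,423,799 bp at printed fraction 0.47
        est = estimate_genome_size(1_423_799, 0.47)
        assert est.size == pytest.approx(3_029_359, abs=1)
        # printed size 3,032,068 agrees within the two-decimal rounding of 0.47
        assert abs(est.size - 3_032_068) / 3_032_068 < 0.01

    def test_group5_sag_table_row(self):
        est = estimate_genome_size(807_656, 0.5624)
        assert est.size == pytest.approx(1_436_088, abs=1)
        assert abs(est.size - 1_436_137) / 1_436_137 < 0.001

    def test_uncertainty_from_quartiles(self):
        est = estimate_genome_size(1_000_000, 0.5, (0.4, 0.6))
        assert est.uncertainty == pytest.approx((1_000_000 / 0.4 - 1_000_000 / 0.6) / 2)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_genome_size(1000, 0.0)


class TestCountMarkersInSag:
    def test_no_hits(self):
        assert count_markers_in_sag(HitTable([])) == 0

    def test_multiple_hits_same_cluster_count_once(self):
        hits = HitTable(
            [
                Hit("g1", "core0001", 90, 100, 200, 1e-30),
                Hit("g2", "core0001", 88, 100, 180, 1e-25),
                Hit("g3", "core0001", 85, 100, 150, 1e-20),
            ]
        )
        assert count_markers_in_sag(hits) == 1

    def test_evalue_filter_matches_hand_count(self):
        hits = HitTable(
            [
                Hit("g1", "c1", 90, 100, 200, 1e-30),
                Hit("g2", "c2", 90, 100, 200, 1e-12),
                Hit("g3", "c3", 90, 100, 200, 1e-9),   # fails 1e-10 cutoff
                Hit("g4", "c4", 90, 100, 200, 1e-10),  # boundary: kept
                Hit("g5", "c5", 90, 100, 200, 1e-2),   # fails
            ]
        )
        assert count_markers_in_sag(hits, evalue_cutoff=1e-10) == 3

    def test_best_cluster_per_gene(self):
        hits = HitTable(
            [
                Hit("g1", "cA", 90, 100, 250, 1e-40),
                Hit("g1", "cB", 80, 100, 150, 1e-20),
            ]
        )
        # only g1's best cluster (cA) is counted
        assert count_markers_in_sag(hits) == 1


class TestEstimatorParameterRecovery:
    def test_single_window_sags_recovered_within_tolerance(self):
        layout = uniform_marker_layout(3_000_000, 71)
        dist = simulate_recovery([layout], n_starts=500)
        for f in (0.1, 0.5, 0.9):
            errors = []
            for rep in range(100):
                sag = generate_sag(layout.length, layout.markers, f, seed=10_000 + rep)
                fraction, _ = estimate_completeness(sag.marker_count, dist)
                errors.append(abs(fraction - f))
            assert np.median(errors) <= 0.05


def test_layout_json_round_trip():
    layout = uniform_marker_layout(50_000, 5, marker_length=200)
    back = layout_from_dict(layout_to_dict(layout))
    assert back.genome_id == layout.genome_id
    assert back.length == layout.length
    assert back.markers == layout.markers
    assert back.circular == layout.circular
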