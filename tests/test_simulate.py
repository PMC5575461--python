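"""Synthetic-data generators: uplift curve, birth-death and GeoSSE
simulators, occurrences, and range reshuffling."""
import math

import numpy as np
import pytest

from andesdiv import simulate
from andesdiv.geosse import GeoSSEParams
from andesdiv.simulate import (
    DegenerateSimulationError,
    OccurrenceSpec,
    UpliftCurveSpec,
    make_uplift_curve,
    reshuffle_ranges,
    simulate_bd_tree,
    simulate_geosse,
    simulate_occurrences,
)
from andesdiv.trees import to_newick, validate_ultrametric


class TestUpliftCurve:
    def test_logistic_midpoint_exact(self):
        spec = UpliftCurveSpec(e_max=4000, t_mid=6, k=1, e_floor=200)
        assert spec.elevation(6.0) == pytest.approx((4000 + 200) / 2)

    def test_deep_past_asymptote(self):
        spec = UpliftCurveSpec()
        assert spec.elevation(1e3) == pytest.approx(spec.e_floor, abs=1e-6)

    def test_present_elevation_near_plateau(self):
        # mimics a ~4000 m maximum mean palaeo-elevation at present
        df = make_uplift_curve(UpliftCurveSpec(e_max=4000.0), t_max=30)
        assert df.elev_m.iloc[0] == pytest.approx(4000.0, rel=0.01)

    def test_monotone_non_increasing_with_age(self):
        df = make_uplift_curve(UpliftCurveSpec(), t_max=30, n=301)
        assert np.all(np.diff(df.elev_m.to_numpy()) <= 1e-9)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            UpliftCurveSpec(e_max=100.0, e_floor=200.0)
        with pytest.raises(ValueError):
            UpliftCurveSpec(k=0.0)
        with pytest.raises(ValueError):
            make_uplift_curve(UpliftCurveSpec(), ages=[-1.0, 2.0])


class TestBirthDeathSimulator:
    def test_zero_rates_give_two_crown_tips(self):
        tree = simulate_bd_tree(0.0, 0.0, 7.0, seed=1)
        assert tree.n_tips == 2
        assert tree.crown_age == pytest.approx(7.0)

    def test_seed_determinism(self):
        a = simulate_bd_tree(0.2, 0.05, 10.0, f=0.8, seed=99)
        b = simulate_bd_tree(0.2, 0.05, 10.0, f=0.8, seed=99)
        assert to_newick(a) == to_newick(b)

    def test_pure_birth_mean_tip_count(self):
        # crown pure birth: E[N(T)] = 2 exp(lambda T)
        lam, T, reps = 0.1, 10.0, 800
        counts = np.array([
            simulate_bd_tree(lam, 0.0, T, seed=i).n_tips for i in range(reps)
        ])
        expected = 2.0 * math.exp(lam * T)
        sem = counts.std(ddof=1) / math.sqrt(reps)
        assert abs(counts.mean() - expected) < 3.0 * sem

    def test_trees_are_ultrametric_with_correct_crown(self):
        for seed in range(5):
            tree = simulate_bd_tree(0.3, 0.1, 8.0, f=0.7, seed=seed)
            assert validate_ultrametric(tree)[0]
            assert tree.crown_age == pytest.approx(8.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_bd_tree(0.1, 0.0, -1.0)
        with pytest.raises(ValueError):
            simulate_bd_tree(lambda t: np.full_like(t, np.inf), 0.0, 5.0)


class TestGeoSSESimulator:
    def test_all_rates_zero_is_degenerate(self):
        with pytest.raises(DegenerateSimulationError):
            simulate_geosse(GeoSSEParams(0, 0), t_max=5.0, seed=0)

    def test_pure_birth_in_region_a(self):
        # sA only, root A: every tip stays in A and the conditional mean
        # tip count matches the Yule expectation E[N | N >= 2]
        lam, t = 0.3, 8.0
        counts = []
        for i in range(300):
            tree, ranges = simulate_geosse(
                GeoSSEParams(sA=lam, sB=0.0), root_state="A", t_max=t, seed=i
            )
            assert set(ranges.values()) == {"A"}
            counts.append(tree.n_tips)
        counts = np.array(counts)
        p1 = math.exp(-lam * t)  # geometric P(N=1)
        expected = (math.exp(lam * t) - p1) / (1.0 - p1)
        sem = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 3.5 * sem

    def test_dispersal_drives_tips_widespread(self):
        # fast dA, no losses: almost all surviving tips end up AB
        tree, ranges = simulate_geosse(
            GeoSSEParams(sA=0.3, sB=0.0, dA=5.0), root_state="A",
            t_max=8.0, seed=4,
        )
        states = list(ranges.values())
        assert states.count("AB") / len(states) > 0.9

    def test_no_dispersal_keeps_single_regions(self):
        tree, ranges = simulate_geosse(
            GeoSSEParams(sA=0.3, sB=0.3, sAB=0.2, xA=0.02, xB=0.02),
            root_state="A", t_max=8.0, seed=5,
        )
        assert "AB" not in set(ranges.values())

    def test_gsa_hits_requested_size(self):
        tree, ranges = simulate_geosse(
            GeoSSEParams(**{"sA": 0.2, "sB": 0.2, "sAB": 0.1, "xA": 0.05,
                            "xB": 0.05, "dA": 0.05, "dB": 0.05}),
            root_state="AB", n_tips=60, seed=8,
        )
        assert tree.n_tips == 60
        assert set(ranges) == set(tree.labels)

    def test_seed_determinism(self):
        p = GeoSSEParams(0.3, 0.2, 0.1, 0.05, 0.05, 0.1, 0.1)
        a = simulate_geosse(p, n_tips=30, seed=7)
        b = simulate_geosse(p, n_tips=30, seed=7)
        assert to_newick(a[0]) == to_newick(b[0]) and a[1] == b[1]


class TestOccurrences:
    def test_record_count_and_containment(self):
        spec = OccurrenceSpec(records_per_species=5.0, scatter_sd=0.1)
        occ = simulate_occurrences({"sp": 0.2}, {"sp": "A"}, spec, seed=0)
        x0, y0, x1, y1 = spec.region_boxes["A"]
        pad = 4 * spec.scatter_sd
        assert occ.lon.between(x0 - pad, x1 + pad).all()
        assert occ.lat.between(y0 - pad, y1 + pad).all()
        assert (occ.elev_m >= 0).all()

    def test_degenerate_scatter_collapses_to_centroid(self):
        spec = OccurrenceSpec(records_per_species=20.0, scatter_sd=1e-9)
        occ = simulate_occurrences({"sp": 0.2}, {"sp": "B"}, spec, seed=1)
        assert occ.lon.std() < 1e-6 and occ.lat.std() < 1e-6

    def test_widespread_species_span_both_boxes(self):
        spec = OccurrenceSpec(records_per_species=200.0, scatter_sd=0.1)
        occ = simulate_occurrences({"sp": 0.2}, {"sp": "AB"}, spec, seed=2)
        in_a = occ.lon < spec.region_boxes["A"][2] + 1
        assert 0 < in_a.sum() < len(occ)

    def test_seed_determinism_byte_identical(self, tmp_path):
        spec = OccurrenceSpec()
        rates = {f"s{i}": 0.1 for i in range(5)}
        regions = {f"s{i}": "A" for i in range(5)}
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simulate_occurrences(rates, regions, spec, seed=5).to_csv(f1, index=False)
        simulate_occurrences(rates, regions, spec, seed=5).to_csv(f2, index=False)
        assert f1.read_bytes() == f2.read_bytes()

    def test_species_without_region_raises(self):
        with pytest.raises(KeyError):
            simulate_occurrences({"sp": 0.2}, {}, OccurrenceSpec(), seed=0)


class TestReshuffle:
    def test_state_multiset_conserved(self):
        ranges = {f"s{i}": st for i, st in enumerate(
            ["A"] * 10 + ["B"] * 5 + ["AB"] * 3)}
        out = reshuffle_ranges(ranges, seed=0)
        assert sorted(out.values()) == sorted(ranges.values())
        assert set(out) == set(ranges)

    def test_single_species_identity(self):
        assert reshuffle_ranges({"x": "A"}, seed=9) == {"x": "A"}

    def test_different_seeds_differ(self):
        ranges = {f"s{i}": ("A" if i % 2 else "B") for i in range(100)}
        assert reshuffle_ranges(ranges, seed=1) != reshuffle_ranges(ranges, seed=2)
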