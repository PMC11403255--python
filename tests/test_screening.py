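"""Maturity calling, DMSO-referenced hit calling and per-target tabulation."""

import math

import numpy as np
import pytest

from spinescreen.errors import (
    ConfigurationError,
    DamagedNeuronError,
    InvalidWellError,
    NoSpinesError,
    ValidationError,
)
from spinescreen.screening import (
    PlateRecord,
    ScreenConfig,
    ScreenResult,
    Treatment,
    WellRecord,
    call_hit,
    call_neuron_maturity,
    confirm_secondary,
    dmso_reference,
    round_half_up,
    run_screen,
    tabulate_by_target,
    well_mature_fraction,
)

from conftest import make_neuron


def make_well(n_mature, n_immature, n_damaged=0, treatment=None, well_id="w0",
              stage="primary"):
    neurons = (
        [make_neuron(n_mushroom=3, n_thin=1, neuron_id=f"m{i}") for i in range(n_mature)]
        + [make_neuron(n_mushroom=1, n_thin=3, neuron_id=f"i{i}") for i in range(n_immature)]
        + [make_neuron(n_mushroom=2, n_thin=2, damaged=True, neuron_id=f"d{i}")
           for i in range(n_damaged)]
    )
    return WellRecord(well_id, treatment or Treatment.vehicle(), neurons, stage)


class TestNeuronMaturity:
    def test_over_half_mushroom_is_mature(self):
        assert call_neuron_maturity(make_neuron(n_mushroom=11, n_thin=9))

    def test_exactly_half_is_immature(self):
        assert not call_neuron_maturity(make_neuron(n_mushroom=10, n_thin=10))

    def test_no_mushroom_is_immature(self):
        assert not call_neuron_maturity(make_neuron(n_thin=5))

    def test_damaged_neuron_refused(self):
        with pytest.raises(DamagedNeuronError):
            call_neuron_maturity(make_neuron(n_mushroom=5, damaged=True))

    def test_zero_spines_rejected(self):
        with pytest.raises(NoSpinesError):
            call_neuron_maturity(make_neuron())


class TestWellMatureFraction:
    def test_arithmetic(self):
        assert well_mature_fraction(make_well(7, 13)) == 35.0

    def test_damaged_excluded_from_both_sides(self):
        # 20 imaged, 4 damaged, 8 of the 16 evaluable mature -> 50%
        well = make_well(8, 8, n_damaged=4)
        assert len(well.neurons) == 20
        assert well_mature_fraction(well) == 50.0
        # brute-force recount
        evaluable = [n for n in well.neurons if not n.damaged]
        mature = sum(call_neuron_maturity(n) for n in evaluable)
        assert well_mature_fraction(well) == 100 * mature / len(evaluable)

    def test_zero_mature(self):
        assert well_mature_fraction(make_well(0, 20)) == 0.0

    def test_too_few_evaluable_flags_invalid(self):
        well = make_well(5, 4, n_damaged=11)
        with pytest.raises(InvalidWellError, match="evaluable"):
            well_mature_fraction(well)

    def test_min_evaluable_configurable(self):
        well = make_well(3, 3)
        assert well_mature_fraction(well, ScreenConfig(min_evaluable=6)) == 50.0

    def test_percentages_are_multiples_of_five_with_20_neurons(self, rng):
        for _ in range(10):
            k = int(rng.integers(0, 21))
            pct = well_mature_fraction(make_well(k, 20 - k))
            assert pct == 5.0 * k

    def test_monotone_in_maturity_upgrades(self):
        base = well_mature_fraction(make_well(6, 14))
        upgraded = well_mature_fraction(make_well(7, 13))
        assert upgraded >= base


class TestDmsoReference:
    def test_mean_of_two_wells(self):
        wells = [make_well(4, 16, well_id="d1"), make_well(6, 14, well_id="d2")]
        assert dmso_reference(wells) == 25.0

    def test_identical_wells(self):
        wells = [make_well(5, 15, well_id="d1"), make_well(5, 15, well_id="d2")]
        assert dmso_reference(wells) == 25.0

    @pytest.mark.parametrize("n_wells", [0, 1, 3])
    def test_requires_exactly_two(self, n_wells):
        wells = [make_well(5, 15, well_id=f"d{i}") for i in range(n_wells)]
        with pytest.raises(ConfigurationError):
            dmso_reference(wells)

    def test_rejects_compound_wells(self):
        wells = [
            make_well(5, 15, well_id="d1"),
            make_well(5, 15, treatment=Treatment("C001", 1.0), well_id="c1"),
        ]
        with pytest.raises(ConfigurationError):
            dmso_reference(wells)

    def test_vehicle_reference_tracks_generator_prevalence(self, btbr):
        """Means of simulated duplicate-DMSO references converge on the
        generator's mature-neuron probability (binomial SE bound)."""
        from spinescreen.synthetic import sample_neurons

        rng = np.random.default_rng(11)
        n_plates = 60
        refs = []
        for p in range(n_plates):
            wells = []
            for d in range(2):
                wells.append(
                    WellRecord(
                        f"p{p}d{d}",
                        Treatment.vehicle(),
                        sample_neurons(btbr, 20, rng),
                    )
                )
            refs.append(dmso_reference(wells))
        target = 100 * btbr.mature_neuron_target
        se = 100 * math.sqrt(
            btbr.mature_neuron_target * (1 - btbr.mature_neuron_target)
            / (n_plates * 40)
        )
        assert abs(np.mean(refs) - target) < 3 * se


class TestCallHit:
    @pytest.mark.parametrize(
        "compound, ref, expected",
        [
            (36.0, 25.0, True),   # margin exceeded
            (35.0, 25.0, False),  # exactly 10 points: strict >
            (20.0, 25.0, False),  # decrease
            (100.0, 0.0, True),
        ],
    )
    def test_margin(self, compound, ref, expected):
        assert call_hit(compound, ref) is expected

    @pytest.mark.parametrize("bad", [-1.0, 101.0, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            call_hit(bad, 25.0)
        with pytest.raises(ValidationError):
            call_hit(25.0, bad)

    def test_monotone_in_compound_pct(self):
        hits = [call_hit(p, 25.0) for p in (30.0, 35.0, 36.0, 50.0)]
        assert hits == sorted(hits)  # once a hit, stays a hit as pct rises


class TestConfirmSecondary:
    def test_passing_subset(self):
        series = [(1.0, 38.0), (0.3, 34.0), (0.1, 28.0)]
        confirmed, passing = confirm_secondary(series, 25.0)
        assert confirmed and passing == [1.0]

    def test_no_effect_not_confirmed(self):
        series = [(1.0, 25.0), (0.3, 25.0)]
        confirmed, passing = confirm_secondary(series, 25.0)
        assert not confirmed and passing == []

    def test_empty_passing_iff_not_confirmed(self, rng):
        for _ in range(20):
            series = [(c, float(rng.integers(0, 101)))
                      for c in (1.0, 0.3, 0.1, 0.03, 0.01)]
            confirmed, passing = confirm_secondary(series, 25.0)
            assert confirmed == (len(passing) >= 1)

    def test_min_passing_tightens(self):
        series = [(1.0, 38.0), (0.3, 34.0)]
        confirmed, _ = confirm_secondary(series, 25.0, min_passing=2)
        assert not confirmed

    def test_off_ladder_concentration_warns(self):
        with pytest.warns(UserWarning, match="ladder"):
            confirm_secondary([(0.7, 40.0)], 25.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            confirm_secondary([], 25.0)


def build_plate(plate_id, compound_wells, dmso=(5, 5)):
    """compound_wells: list of (compound_id, conc, n_mature, n_immature, stage)."""
    wells = [
        make_well(dmso[0], 20 - dmso[0], well_id=f"{plate_id}-d1", stage="vehicle"),
        make_well(dmso[1], 20 - dmso[1], well_id=f"{plate_id}-d2", stage="vehicle"),
    ]
    for cid, conc, n_mat, n_imm, stage in compound_wells:
        wells.append(
            make_well(n_mat, n_imm, treatment=Treatment(cid, conc),
                      well_id=f"{plate_id}-{cid}-{conc}", stage=stage)
        )
    return PlateRecord(plate_id, wells)


class TestRunScreen:
    def test_empty_library(self):
        plate = build_plate("P1", [])
        assert run_screen([plate], {}) == []

    def test_candidate_and_confirmation_flow(self):
        # DMSO ref 25%; C001 primary 40% -> candidate; secondary passes at 1.0
        primary = build_plate(
            "P1",
            [("C001", 1.0, 8, 12, "primary"), ("C002", 1.0, 6, 14, "primary")],
        )
        secondary = build_plate(
            "S1",
            [("C001", 1.0, 9, 11, "secondary"), ("C001", 0.3, 6, 14, "secondary")],
        )
        results = run_screen([primary, secondary], {"C001": "5-HT receptor",
                                                    "C002": "FAAH"})
        by_id = {r.compound_id: r for r in results}
        assert by_id["C001"].candidate and by_id["C001"].confirmed
        assert by_id["C001"].confirmation_concentrations == [1.0]
        assert not by_id["C002"].candidate and not by_id["C002"].confirmed

    def test_plate_without_two_dmso_wells_excluded(self, caplog):
        plate = PlateRecord(
            "P1",
            [make_well(8, 12, treatment=Treatment("C001", 1.0), well_id="c1")],
        )
        results = run_screen([plate], {"C001": "FAAH"})
        assert len(results) == 1 and not results[0].candidate
        assert results[0].primary_pct_mature is None

    def test_confirmed_requires_candidate_invariant(self):
        with pytest.raises(ValidationError):
            ScreenResult("C1", "FAAH", 20.0, 25.0, candidate=False, confirmed=True)

    def test_order_invariance_of_neurons(self, rng):
        well = make_well(7, 13)
        before = well_mature_fraction(well)
        perm = list(rng.permutation(len(well.neurons)))
        well.neurons = [well.neurons[i] for i in perm]
        assert well_mature_fraction(well) == before


class TestTabulateByTarget:
    def test_published_style_rates(self):
        # 38 compounds / 5 hits -> 13.2%; 8 compounds / 2 hits -> 25.0%
        results = []
        for i in range(38):
            results.append(ScreenResult(f"A{i}", "5-HT receptor", 30.0, 25.0,
                                        candidate=i < 14, confirmed=i < 5))
        for i in range(8):
            results.append(ScreenResult(f"B{i}", "nACh receptor", 30.0, 25.0,
                                        candidate=i < 3, confirmed=i < 2))
        rows = {s.target_class: s for s in tabulate_by_target(results)}
        assert rows["5-HT receptor"].hit_rate == 13.2
        assert rows["nACh receptor"].hit_rate == 25.0
        total = rows["Total"]
        assert (total.n_compounds, total.n_candidates, total.n_hits) == (46, 17, 7)

    def test_total_row_sums_columns(self, rng):
        results = []
        for i in range(50):
            cand = bool(rng.integers(0, 2))
            conf = cand and bool(rng.integers(0, 2))
            results.append(
                ScreenResult(f"C{i}", f"T{int(rng.integers(0, 5))}", 30.0, 25.0,
                             candidate=cand, confirmed=conf)
            )
        rows = tabulate_by_target(results)
        total = rows[-1]
        assert total.n_compounds == sum(r.n_compounds for r in rows[:-1]) == 50
        assert total.n_candidates == sum(r.n_candidates for r in rows[:-1])
        assert total.n_hits == sum(r.n_hits for r in rows[:-1])
        for r in rows:
            assert r.n_hits <= r.n_candidates <= r.n_compounds

    def test_unknown_target_grouped_literally(self):
        results = [ScreenResult("C1", "mystery target", 30.0, 25.0, True)]
        rows = tabulate_by_target(results)
        assert rows[0].target_class == "mystery target"

    @pytest.mark.parametrize(
        "value, expected", [(13.15, 13.2), (13.14, 13.1), (8.25, 8.3), (25.0, 25.0)]
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value) == expected
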