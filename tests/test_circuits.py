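"""Mass-action circuit model: builders, integration, conservation laws."""

import numpy as np
import pytest

from dsdpore import circuits as cc


def rk4_reference(system, duration, n_steps):
    """Fixed-step RK4 integrator, independent of the solver under test."""
    terms = cc._rate_terms(system)

    def rhs(y):
        dy = np.zeros_like(y)
        for reactants, stoich, k in terms:
            flux = k
            for i in reactants:
                flux *= max(y[i], 0.0)
            dy += flux * stoich
        return dy

    y = system.initial_state().astype(float)
    h = duration / n_steps
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestBuildSeesaw:
    def test_standard_operating_point_structure(self):
        system = cc.build_seesaw(0.5, 0.2, 2.0)
        assert len(system.reactions) == 2
        assert all(r.reversible for r in system.reactions)
        assert len(system.species) == 7
        assert system.species["gate"].initial_concentration == 0.5
        assert system.species["fuel"].initial_concentration == 2.0

    def test_leak_reaction_added_only_when_requested(self):
        base = cc.build_seesaw(0.5, 0.0, 2.0)
        leaky = cc.build_seesaw(0.5, 0.0, 2.0, leak_rate=1e-3, reporter_conc=3.0)
        assert len(base.reactions) == 2
        assert len(leaky.reactions) == 3
        assert "gate_reporter" in leaky.species

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(gate_conc=-0.1, input_conc=0, fuel_conc=0), "gate_conc"),
            (dict(gate_conc=0.5, input_conc=-1, fuel_conc=0), "input_conc"),
            (dict(gate_conc=0.5, input_conc=0, fuel_conc=0, leak_rate=-1), "leak_rate"),
            (
                dict(gate_conc=0.5, input_conc=0, fuel_conc=0, rates={"k_displace": -2}),
                "k_displace",
            ),
        ],
    )
    def test_negative_inputs_rejected_naming_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            cc.build_seesaw(**kwargs)

    def test_no_input_no_leak_output_stays_zero(self):
        system = cc.build_seesaw(0.5, 0.0, 2.0)
        traj = cc.simulate(system, 3600.0, step=60.0)
        assert np.all(traj.species("output") == 0.0)

    def test_fuel_free_steady_state_matches_analytic_equilibrium(self):
        """Single reversible displacement: K (I0-x)(G0-x) = x^2 solvable in
        closed form; the integrator must land on that root."""
        system = cc.build_seesaw(0.5, 0.2, 0.0)
        kf = system.reactions[0].rate_constant
        kr = system.reactions[0].reverse_rate_constant
        K = kf / kr
        a, b, c = K - 1.0, -K * 0.7, K * 0.1
        x_analytic = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
        traj = cc.simulate(system, 7200.0, step=60.0)
        x_ode = traj.species("output")[-1]
        assert x_ode <= 0.2 + 1e-9  # never exceeds the input supply
        assert abs(x_ode - x_analytic) < 1e-6


class TestBuildLet7:
    def test_diagonal_matrix_triggers_only_cognate_probe(self):
        system = cc.build_let7_system(
            {"a": 0.1, "c": 0.1, "e": 0.1},
            {"a": 0.05},
            np.array([[0.1, 0.0, 0.0]]),
        )
        traj = cc.simulate(system, 3600.0, step=60.0)
        assert traj.species("output_a")[-1] > 0.045
        assert np.all(traj.species("output_c") == 0.0)
        assert np.all(traj.species("output_e") == 0.0)

    def test_zero_matrix_releases_nothing(self):
        system = cc.build_let7_system(
            {"a": 0.1, "c": 0.1}, {"a": 0.05, "c": 0.05}, np.zeros((2, 2))
        )
        traj = cc.simulate(system, 600.0, step=10.0)
        for name in ("output_a", "output_c"):
            assert np.all(traj.species(name) == 0.0)

    def test_crosstalk_entry_gives_small_offtarget_release(self):
        """epsilon-rate e->a crosstalk releases some probe-a output, far less
        than the on-target release; cross-checked against a tight-tolerance
        independent integration."""
        rate = np.array([[0.01, 0.1], [0.1, 0.0]])  # rows: inputs (e, a); cols: probes (a, e)
        system = cc.build_let7_system(
            {"a": 0.1, "e": 0.1}, {"e": 0.05, "a": 0.0}, rate
        )
        traj = cc.simulate(system, 3600.0, step=60.0)
        out_a = traj.species("output_a")[-1]
        out_e = traj.species("output_e")[-1]
        assert 0 < out_a < 0.2 * out_e
        y_ref = rk4_reference(system, 3600.0, 40_000)
        names = system.species_names
        assert abs(y_ref[names.index("output_a")] - out_a) < 1e-6
        assert abs(y_ref[names.index("output_e")] - out_e) < 1e-6

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cc.build_let7_system({"a": 0.1}, {"a": 0.05}, np.zeros((2, 2)))


class TestSimulate:
    def test_catalytic_seesaw_approaches_full_displacement(self):
        traj = cc.simulate(cc.build_seesaw(0.5, 0.2, 2.0), 4 * 3600.0, step=120.0)
        assert traj.species("output")[-1] / 0.5 > 0.98
        assert traj.species("output")[-1] / 0.5 == pytest.approx(1.0, abs=0.02)

    def test_empty_reaction_list_keeps_species_constant(self):
        system = cc.CircuitSystem(
            {"x": cc.Species("x", "input", 1.5, {"x": 1})}, [], label="inert"
        )
        traj = cc.simulate(system, 100.0, step=10.0)
        assert np.all(traj.species("x") == 1.5)

    def test_matches_fixed_step_rk4_reference(self):
        system = cc.build_seesaw(
            0.5, 0.2, 2.0, rates=dict(k_displace=0.01, k_fuel=0.01)
        )
        traj = cc.simulate(system, 600.0, step=600.0)
        y_ref = rk4_reference(system, 600.0, 60_000)
        final = traj.concentrations.iloc[-1].to_numpy()
        scale = np.maximum(np.abs(y_ref), 1e-6)
        assert np.max(np.abs(final - y_ref) / scale) < 1e-6

    def test_strand_conservation_along_trajectory(self):
        system = cc.build_seesaw(0.5, 0.2, 2.0)
        traj = cc.simulate(system, 4 * 3600.0, step=120.0)
        assert traj.conservation_error(system) < 1e-8

    def test_nonnegative_concentrations_everywhere(self):
        traj = cc.simulate(cc.build_seesaw(0.5, 0.2, 2.0), 3600.0, step=30.0)
        assert (traj.concentrations.to_numpy() >= 0).all()

    def test_catalysis_beats_no_fuel(self):
        with_fuel = cc.simulate(cc.build_seesaw(0.5, 0.2, 2.0), 7200.0, step=120.0)
        no_fuel = cc.simulate(cc.build_seesaw(0.5, 0.2, 0.0), 7200.0, step=120.0)
        assert with_fuel.species("output")[-1] > no_fuel.species("output")[-1]

    def test_bad_duration_rejected(self):
        with pytest.raises(ValueError):
            cc.simulate(cc.build_seesaw(0.5, 0.2, 2.0), -1.0)


class TestStructuralValidation:
    def test_reaction_referencing_unknown_species_rejected(self):
        sp = {"a": cc.Species("a", "input", 1.0)}
        rxn = cc.Reaction(("a",), ("ghost",), 0.1)
        with pytest.raises(ValueError, match="undeclared"):
            cc.CircuitSystem(sp, [rxn])

    def test_strand_imbalance_rejected(self):
        sp = {
            "a": cc.Species("a", "input", 1.0, {"x": 1}),
            "b": cc.Species("b", "waste", 0.0, {"y": 1}),
        }
        rxn = cc.Reaction(("a",), ("b",), 0.1)
        with pytest.raises(ValueError, match="conserve"):
            cc.CircuitSystem(sp, [rxn])

    def test_config_round_trip(self, tmp_path):
        system = cc.build_seesaw(0.5, 0.2, 2.0)
        path = tmp_path / "circuit.json"
        cc.dump_circuit(system, path)
        again = cc.load_circuit(path)
        assert again.species_names == system.species_names
        assert len(again.reactions) == len(system.reactions)
        t1 = cc.simulate(system, 600.0, step=60.0)
        t2 = cc.simulate(again, 600.0, step=60.0)
        assert np.array_equal(
            t1.concentrations.to_numpy(), t2.concentrations.to_numpy()
        )
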