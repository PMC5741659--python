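import numpy as np
import pytest

from stoichcorr import kinetics, run_sca
from stoichcorr.kinetics import (
    Reaction,
    ReactionNetwork,
    conserved_moieties,
    default_time_grid,
    expand_enzyme_complexes,
    fixture_tca_mini,
    fixture_toy_cycle,
    mass_action_rates,
    michaelis_menten_rates,
    read_network,
    reversible_to_irreversible,
    sample_ensemble,
    simulate,
    steady_state,
    write_network,
)


class TestMassActionRates:
    def test_bimolecular_arithmetic(self):
        net = ReactionNetwork(
            ["S1", "S2"], [Reaction("r", {"S1": 1, "S2": 1}, {}, params={"k": 2.0})]
        )
        assert mass_action_rates(net, [0.5, 3.0])[0] == pytest.approx(3.0)

    def test_zero_substrate_zero_rate(self):
        net = ReactionNetwork(
            ["S1", "S2"], [Reaction("r", {"S1": 1, "S2": 2}, {}, params={"k": 5.0})]
        )
        assert mass_action_rates(net, [0.0, 1.0])[0] == 0.0

    def test_negative_concentration_rejected(self, toy_cycle):
        with pytest.raises(ValueError, match="negative"):
            mass_action_rates(toy_cycle, [-1.0, 1.0, 1.0, 1.0])

    def test_rates_equal_at_steady_state(self, toy_cycle):
        x = steady_state(toy_cycle, [1.0, 2.0, 3.0, 4.0])
        v = mass_action_rates(toy_cycle, x)
        assert np.ptp(v) < 1e-8


class TestMichaelisMentenRates:
    def _uni(self, vf=2.0, vr=0.0, kms=1.5, kmp=2.5):
        return ReactionNetwork(
            ["S", "P"],
            [
                Reaction(
                    "r",
                    {"S": 1},
                    {"P": 1},
                    "michaelis_menten",
                    {"vf": vf, "vr": vr, "km_S": kms, "km_P": kmp},
                )
            ],
        )

    def test_half_saturation(self):
        net = self._uni(vf=2.0, kms=1.5)
        assert michaelis_menten_rates(net, [1.5, 0.0])[0] == pytest.approx(1.0)

    def test_saturation_asymptote(self):
        net = self._uni(vf=2.0, kms=1.5)
        v = michaelis_menten_rates(net, [1.5e6, 0.0])[0]
        assert v == pytest.approx(2.0, rel=1e-4)

    def test_equilibrium_zero_net_rate(self):
        vf, vr, kms, kmp = 2.0, 0.5, 1.5, 2.5
        net = self._uni(vf, vr, kms, kmp)
        s = 0.8
        p = vf * s * kmp / (kms * vr)  # solves vf s/KmS = vr p/KmP
        assert michaelis_menten_rates(net, [s, p])[0] == pytest.approx(0.0, abs=1e-14)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError, match="km"):
            Reaction(
                "r", {"S": 1}, {"P": 1}, "michaelis_menten",
                {"vf": 1.0, "vr": 0.0, "km_S": 0.0, "km_P": 1.0},
            )


class TestEnzymeExpansion:
    def _base(self):
        return ReactionNetwork(
            ["S", "P"],
            [Reaction("r1", {"S": 1}, {"P": 1}, params={"k": 1.0}, enzyme="E1")],
            {"S": (0.1, 10.0), "P": (0.1, 10.0)},
        )

    def test_structure_counts(self):
        ex = expand_enzyme_complexes(self._base())
        assert ex.n_species == 4  # S, P + enzyme + complex
        assert ex.n_reactions == 3
        assert [r.name for r in ex.reactions] == ["r1_bind", "r1_unbind", "r1_cat"]

    def test_net_stoichiometry_preserved(self):
        base = self._base()
        ex = expand_enzyme_complexes(base)
        # the catalytic route (binding then catalysis) recovers S -> P;
        # unbinding is the exact reverse of binding
        N = ex.stoichiometric_matrix
        names = [r.name for r in ex.reactions]
        net_change = N[:, names.index("r1_bind")] + N[:, names.index("r1_cat")]
        expect = {"S": -1.0, "P": 1.0, "E1": 0.0, "E1_r1": 0.0}
        np.testing.assert_array_equal(
            N[:, names.index("r1_unbind")], -N[:, names.index("r1_bind")]
        )
        for sp, val in zip(ex.species, net_change):
            assert val == expect[sp]

    def test_enzyme_total_conserved(self):
        ex = expand_enzyme_complexes(self._base())
        x0 = {"S": 5.0, "P": 0.1, "E1": 0.2, "E1_r1": 0.05}
        traj = simulate(ex, x0, t_grid=np.linspace(0, 50, 30))
        tot = traj.states["E1"] + traj.states["E1_r1"]
        assert np.ptp(tot.to_numpy()) / tot.iloc[0] < 1e-8

    def test_name_collision_rejected(self):
        net = ReactionNetwork(
            ["S", "P", "E1"],
            [Reaction("r1", {"S": 1}, {"P": 1}, params={"k": 1.0}, enzyme="E1")],
        )
        with pytest.raises(ValueError, match="collision"):
            expand_enzyme_complexes(net)

    def test_qssa_limit_matches_michaelis_menten(self):
        """k_on, k_off >> k_cat and E_tot << S: flux ~ Vmax s / (Km + s)."""
        ex = expand_enzyme_complexes(self._base())
        k_cat, e_tot = 1.0, 0.01
        km = (100.0 + 1.0) / 100.0
        for s in (0.2, 0.5, 1.0, 2.0, 5.0):
            x0 = {"S": s, "P": 0.0, "E1": e_tot, "E1_r1": 0.0}
            traj = simulate(ex, x0, t_grid=np.linspace(0, 0.5, 6))
            end = traj.states.iloc[-1]
            flux = k_cat * end["E1_r1"]
            expected = k_cat * e_tot * end["S"] / (km + end["S"])
            assert flux == pytest.approx(expected, rel=0.02)


class TestReversibleSplit:
    def test_one_becomes_two(self):
        net = ReactionNetwork(
            ["A", "B"],
            [Reaction("r", {"A": 1}, {"B": 1}, params={"kf": 1.0, "kb": 0.5}, reversible=True)],
        )
        out = reversible_to_irreversible(net)
        assert out.n_reactions == 2
        assert out.reactions[0].substrates == {"A": 1}
        assert out.reactions[1].substrates == {"B": 1}

    def test_eleven_reversible_give_twentytwo(self):
        species = [f"X{i}" for i in range(12)]
        rxns = [
            Reaction(
                f"r{i}", {species[i]: 1}, {species[i + 1]: 1},
                params={"kf": 1.0 + 0.1 * i, "kb": 0.4}, reversible=True,
            )
            for i in range(11)
        ]
        out = reversible_to_irreversible(ReactionNetwork(species, rxns))
        assert out.n_reactions == 22

    def test_missing_backward_constant(self):
        with pytest.raises(ValueError, match="kb"):
            Reaction("r", {"A": 1}, {"B": 1}, params={"kf": 1.0}, reversible=True)

    def test_trajectory_equivalence_net_vs_split(self):
        species = ["A", "B", "C"]
        rxns = [
            Reaction("r1", {"A": 1}, {"B": 1}, params={"kf": 1.2, "kb": 0.3}, reversible=True),
            Reaction("r2", {"B": 1}, {"C": 1}, params={"kf": 0.7, "kb": 0.2}, reversible=True),
        ]
        net = ReactionNetwork(species, rxns)
        split = reversible_to_irreversible(net)
        grid = np.linspace(0, 20, 40)
        x0 = [2.0, 0.5, 0.1]
        a = simulate(net, x0, t_grid=grid).states.to_numpy()
        b = simulate(split, x0, t_grid=grid).states.to_numpy()
        assert np.abs(a - b).max() < 1e-6


class TestSimulate:
    def test_steady_start_stays_constant(self, toy_cycle):
        x = steady_state(toy_cycle, [1.0, 1.0, 1.0, 1.0])
        traj = simulate(toy_cycle, x, t_grid=np.linspace(0, 100, 11))
        drift = np.abs(traj.states.to_numpy() - x).max()
        assert drift < 1e-8 * (1 + np.abs(x).max())

    def test_moiety_conservation(self, toy_cycle, rng):
        basis = conserved_moieties(toy_cycle)
        assert basis.shape[0] >= 2
        x0 = rng.uniform(0.5, 5.0, size=4)
        traj = simulate(toy_cycle, x0, t_grid=default_time_grid(200.0))
        for vec in basis:
            m = traj.states.to_numpy() @ vec
            assert np.ptp(m) <= 1e-8 * max(1.0, abs(m[0]))

    def test_rates_equalize_from_random_start(self, toy_cycle, rng):
        x0 = rng.uniform(0.5, 5.0, size=4)
        x = steady_state(toy_cycle, x0)
        v = toy_cycle.rates(x)
        assert np.ptp(v) < 1e-6

    def test_decreasing_grid_rejected(self, toy_cycle):
        with pytest.raises(ValueError):
            simulate(toy_cycle, [1, 1, 1, 1], t_grid=np.array([0.0, 2.0, 1.0]))

    def test_default_grid_shape(self):
        g = default_time_grid()
        assert len(g) == 21 and g[0] == 0.0 and g[1] == 1.0 and g[-1] == 1280.0


class TestSampleEnsemble:
    def test_same_seed_identical(self, toy_cycle):
        a = sample_ensemble(toy_cycle, n_draws=5, seed=3)
        b = sample_ensemble(toy_cycle, n_draws=5, seed=3)
        assert a.values.equals(b.values)

    def test_endpoint_matrix_shape_and_tolerance(self, toy_cycle):
        ens = sample_ensemble(toy_cycle, n_draws=10, seed=2)
        assert ens.values.shape == (10, 4)
        N = toy_cycle.stoichiometric_matrix
        for row in ens.values.to_numpy():
            ddt = np.abs(N @ toy_cycle.rates(row)).max()
            assert ddt <= 1e-9 * (1 + np.abs(row).max())

    def test_rate_ratio_constant_across_ensemble(self, toy_ensemble, toy_cycle):
        # coupled rates: the ratio of any two reaction rates has CV < 1e-6
        v = np.array([toy_cycle.rates(row) for row in toy_ensemble.values.to_numpy()])
        for p in range(3):
            for q in range(p + 1, 3):
                ratio = v[:, p] / v[:, q]
                assert np.std(ratio) / np.mean(ratio) < 1e-6

    def test_ensemble_reproduces_worked_coupling(self, toy_ensemble):
        table = run_sca(toy_ensemble)
        rec = table.records
        row = rec[
            (rec["side_A_members"] == ("S1", "S2")) & (rec["side_B_members"] == ("S4",))
        ].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-6)
        assert row["beta"] == (1, 1) and row["eta"] == (1,)


class TestFixtures:
    def test_toy_cycle_structure(self, toy_cycle):
        N = toy_cycle.stoichiometric_matrix
        assert N.shape == (4, 3)
        # each column balances: substrate loss equals product gain
        np.testing.assert_array_equal(
            N, [[-1, 0, 1], [-1, 0, 1], [1, -1, 0], [0, 1, -1]]
        )

    def test_toy_cycle_rate_coupling_identity(self, toy_cycle):
        k1 = toy_cycle.reactions[0].params["k"]
        k3 = toy_cycle.reactions[2].params["k"]
        x = steady_state(toy_cycle, [2.0, 1.0, 0.5, 3.0])
        assert k1 * x[0] * x[1] == pytest.approx(k3 * x[3], abs=1e-8)

    @pytest.mark.parametrize(
        "variant", ["mass_action", "enzyme_complex", "michaelis_menten"]
    )
    def test_tca_mini_species_set(self, variant):
        net = fixture_tca_mini(variant)
        assert set(kinetics.TCA_MINI_SPECIES) <= set(net.species)
        assert len(kinetics.TCA_MINI_SPECIES) == 11
        if variant != "enzyme_complex":
            assert net.n_species == 11 and net.n_reactions == 10
        n_bisub = sum(
            1
            for r in net.reactions
            if sum(r.substrates.values()) >= 2 and not r.name.endswith(("_unbind", "_cat"))
        )
        assert n_bisub >= 1

    def test_tca_mini_single_loop_conserves_mass(self):
        net = fixture_tca_mini("mass_action")
        x0 = np.linspace(0.5, 5.0, 11)
        traj = simulate(net, x0, t_grid=np.linspace(0, 100, 10))
        # accoa + oaa counted once via cit: total carbon-weighted moiety
        basis = conserved_moieties(net)
        assert basis.shape[0] >= 1
        for vec in basis:
            m = traj.states.to_numpy() @ vec
            assert np.ptp(m) <= 1e-8 * max(1.0, abs(m[0]))


class TestModelFiles:
    def test_roundtrip(self, tmp_path):
        net = fixture_tca_mini("michaelis_menten")
        path = tmp_path / "model.txt"
        write_network(net, path)
        back = read_network(path)
        assert back.species == net.species
        assert back.initial_ranges == net.initial_ranges
        for a, b in zip(back.reactions, net.reactions):
            assert (a.name, a.substrates, a.products, a.law) == (
                b.name,
                b.substrates,
                b.products,
                b.law,
            )
            assert a.params == pytest.approx(b.params)

    def test_parse_example(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "# toy\n"
            "species: A B C\n"
            "range A 0.1 10\n"
            "reaction r1: A + 2 B -> C ; law=mass_action ; k=0.5\n"
            "reaction r2: C <-> A ; law=mass_action ; kf=1 ; kb=0.25\n"
        )
        net = read_network(path)
        assert net.reactions[0].substrates == {"A": 1, "B": 2}
        assert net.reactions[1].reversible

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("species: A B\nreaction r1: A -> B ; law=mass_action\n")
        with pytest.raises(ValueError, match=":2:"):
            read_network(path)
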