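import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from radiocell import nuclide_data as nd


class TestChainStructure:
    def test_ac225_cascade_order_and_terminus(self, ac225):
        assert ac225.names == (
            "Ac-225", "Fr-221", "At-217", "Bi-213",
            "Po-213", "Tl-209", "Pb-209", "Bi-209",
        )
        assert ac225["Bi-209"].stable
        assert ac225["Bi-209"].emissions == ()

    def test_ac225_emits_four_alphas_over_branches(self, ac225):
        assert nd.alpha_transition_count(ac225) == pytest.approx(4.0, abs=1e-9)

    def test_lu177_single_radioactive_step_no_alphas(self, lu177):
        radioactive = [s for s in lu177.steps if not s.stable]
        assert len(radioactive) == 1
        assert nd.charged_energy_per_decay(lu177, {"alpha"}) == 0.0

    def test_bi213_branching_fractions_sum_to_one(self, ac225):
        total = sum(f for _, f in ac225["Bi-213"].daughters)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_unknown_parent_raises(self):
        with pytest.raises(nd.UnsupportedNuclideError):
            nd.load_chain("Ra-223")

    def test_json_round_trip(self, ac225):
        restored = nd.DecayChain.from_json(ac225.to_json())
        assert restored == ac225


class TestBateman:
    def test_initial_condition(self, ac225):
        act = nd.bateman_activities(ac225, 0.0, 5.0)
        assert act["Ac-225"] == pytest.approx(5.0)
        for name in ac225.names[1:]:
            assert act[name] == 0.0

    def test_fr221_ingrowth_ratio_at_30_min(self, ac225):
        # 1 - exp(-lambda_Fr * t) with T1/2 = 4.8 min gives 0.987 at 30 min
        act = nd.bateman_activities(ac225, 30 * 60.0, 1.0)
        assert act["Fr-221"] / act["Ac-225"] == pytest.approx(0.987, abs=1e-3)

    def test_fr221_secular_equilibrium_at_24_h(self, ac225):
        act = nd.bateman_activities(ac225, 24 * 3600.0, 1.0)
        assert act["Fr-221"] / act["Ac-225"] == pytest.approx(1.0, abs=1e-3)

    def test_negative_time_rejected(self, ac225):
        with pytest.raises(ValueError):
            nd.bateman_activities(ac225, -1.0, 1.0)

    def test_daughter_activities_nonnegative_over_time(self, ac225):
        t = np.geomspace(1.0, 10 * 86400.0, 50)
        act = nd.bateman_activities(ac225, t, 1.0)
        for name in ac225.names:
            assert np.all(np.asarray(act[name]) >= 0.0)

    @pytest.mark.parametrize("parent", ["Lu-177", "Ac-225"])
    def test_closed_form_matches_stiff_ode_oracle(
        self, parent, decay_matrix_factory
    ):
        """Bateman solution vs Radau integration, rel err < 1e-6."""
        chain = nd.load_chain(parent)
        names, lam, a = decay_matrix_factory(chain)
        n0 = np.zeros(len(names))
        n0[0] = 1.0 / lam[0]
        t_grid = np.array([600.0, 3600.0, 86400.0, 10 * 86400.0])
        sol = solve_ivp(
            lambda t, y: a @ y, (0.0, t_grid[-1]), n0, t_eval=t_grid,
            method="Radau", rtol=1e-10, atol=1e-20 * n0[0],
        )
        assert sol.success
        for k, t in enumerate(t_grid):
            closed = nd.bateman_atoms(chain, t, n0[0])
            for i, name in enumerate(names):
                oracle = sol.y[i, k]
                if oracle > 1e-12 * n0[0]:
                    assert closed[name] == pytest.approx(oracle, rel=1e-6)

    def test_atom_count_conserved_for_linear_chain(self, lu177):
        # Lu-177 -> Hf-177: total atoms constant
        n0 = 1e6
        atoms = nd.bateman_atoms(lu177, 3 * 86400.0, n0)
        assert atoms["Lu-177"] + atoms["Hf-177"] == pytest.approx(n0, rel=1e-12)

    def test_equilibrium_time_98pct_about_27_min(self, ac225):
        t98 = nd.equilibrium_time(ac225, "Fr-221", level=0.98)
        assert t98 / 60.0 == pytest.approx(27.1, abs=0.5)
        assert t98 / 60.0 <= 30.0


class TestEnergyBookkeeping:
    def test_lu177_electron_energy_per_decay(self, lu177):
        e = nd.charged_energy_per_decay(
            lu177, {"beta_mean", "conversion_auger_electron"}
        )
        assert e == pytest.approx(0.147, rel=0.02)

    def test_ac225_alpha_energy_per_decay(self, ac225):
        e = nd.charged_energy_per_decay(ac225, {"alpha"})
        assert e == pytest.approx(27.6, rel=0.02)

    def test_additive_over_disjoint_classes(self, ac225):
        total = nd.charged_energy_per_decay(
            ac225, {"alpha", "beta_mean", "conversion_auger_electron"}
        )
        parts = (
            nd.charged_energy_per_decay(ac225, {"alpha"})
            + nd.charged_energy_per_decay(ac225, {"beta_mean"})
            + nd.charged_energy_per_decay(ac225, {"conversion_auger_electron"})
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_empty_class_set_rejected(self, ac225):
        with pytest.raises(ValueError):
            nd.charged_energy_per_decay(ac225, set())

    def test_equilibrium_weights_follow_branching(self, ac225):
        w = nd.equilibrium_decay_weights(ac225)
        assert w["Ac-225"] == pytest.approx(1.0)
        assert w["Po-213"] == pytest.approx(0.978)
        assert w["Tl-209"] == pytest.approx(0.022)
        assert w["Pb-209"] == pytest.approx(1.0)
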