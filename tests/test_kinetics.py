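import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignoflux.kinetics import (
    BRANCH_REACTIONS,
    BranchModel,
    BranchReactionKinetics,
    perturbation_response,
    reaction_rate,
    steady_state,
)


def make_model(mode="mm", **overrides) -> BranchModel:
    """Moderately saturated default model; overrides are (vmax, km[, n])."""
    base = {rid: (1.0, 1.0, 1.0) for rid in BRANCH_REACTIONS}
    base.update(overrides)
    kin = {
        rid: BranchReactionKinetics(rid, vmax=t[0], km=t[1],
                                    hill_n=t[2] if len(t) > 2 else 1.0)
        for rid, t in base.items()
    }
    return BranchModel(kin, mode)


class TestRateLaw:
    @pytest.mark.parametrize(
        "vmax, km, n, c, expected",
        [
            (2.0, 1.0, 1.0, 1.0, 1.0),  # half saturation
            (2.0, 1.0, 1.0, 0.0, 0.0),
            (2.0, 1.0, 4.0, 1.0, 1.0),  # Hill at c = km
            (3.0, 0.5, 2.0, 100.0, pytest.approx(3.0, rel=1e-4)),  # saturation
        ],
    )
    def test_reference_values(self, vmax, km, n, c, expected):
        k = BranchReactionKinetics("v14", vmax=vmax, km=km, hill_n=n)
        assert reaction_rate(k, c) == expected

    def test_negative_concentration_rejected(self):
        k = BranchReactionKinetics("v14", vmax=1, km=1)
        with pytest.raises(ValueError):
            reaction_rate(k, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BranchReactionKinetics("v14", vmax=1, km=0)
        with pytest.raises(ValueError):
            BranchReactionKinetics("v14", vmax=1, km=1, hill_n=0.5)


class TestModelStructure:
    def test_mm_mode_has_16_free_parameters(self):
        assert make_model("mm").n_free_parameters == 16

    def test_hill_mode_adds_cooperativity_parameters(self):
        m = make_model("hill", v14=(1.0, 1.0, 2.0))
        assert m.n_free_parameters == 24

    def test_wrong_reaction_set_rejected(self):
        kin = {"v10": BranchReactionKinetics("v10", 1, 1)}
        with pytest.raises(ValueError, match="exactly"):
            BranchModel(kin, "mm")


class TestSteadyState:
    def test_single_step_matches_closed_form(self):
        # all flux forced down one chain: c = km J / (vmax - J) at each step
        J = 0.5
        m = make_model(
            v10=(1e-12, 1.0), v12=(1e-12, 1.0), v16=(1e-12, 1.0), v20=(1e-12, 1.0),
            v11=(1.0, 1.0), v13=(2.0, 0.7), v14=(1.5, 2.0), v15=(1.2, 0.3),
        )
        ss = steady_state(m, J)
        assert ss.converged
        assert ss.concentrations["feruloyl_coa"] == pytest.approx(
            0.7 * J / (2.0 - J), abs=1e-6
        )
        assert ss.concentrations["coniferyl_aldehyde"] == pytest.approx(
            2.0 * J / (1.5 - J), abs=1e-6
        )
        assert ss.g_flux == pytest.approx(J, abs=1e-8)

    def test_influx_beyond_capacity_reported_not_converged(self):
        m = make_model(v10=(0.5, 1.0), v11=(0.5, 1.0))
        ss = steady_state(m, 1.5)  # J > vmax10 + vmax11
        assert not ss.converged
        assert "capacity" in ss.diagnostic or "accumulates" in ss.diagnostic

    def test_symmetric_branches_give_unit_sg_ratio(self):
        m = make_model(v14=(1.0, 1.0), v16=(1.0, 1.0), v20=(1e-12, 1.0),
                       v15=(2.0, 0.5))
        ss = steady_state(m, 0.6)
        assert ss.converged
        assert ss.sg_ratio == pytest.approx(1.0, abs=1e-6)

    def test_flux_conservation_at_steady_state(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            over = {
                rid: (float(np.exp(rng.uniform(np.log(0.1), np.log(10)))),
                      float(np.exp(rng.uniform(np.log(0.1), np.log(10)))))
                for rid in BRANCH_REACTIONS
            }
            ss = steady_state(make_model(**over), 0.5)
            if not ss.converged:
                continue
            assert ss.g_flux + ss.s_flux == pytest.approx(0.5, abs=1e-8)
            checked += 1

    def test_hill_with_unit_exponent_reproduces_mm(self):
        over = dict(v10=(0.8, 2.0), v11=(1.4, 0.6), v12=(1.1, 1.7), v13=(2.2, 0.9),
                    v14=(1.6, 1.2), v15=(1.9, 0.4), v16=(0.7, 3.0), v20=(0.5, 1.1))
        mm = steady_state(make_model("mm", **over), 0.5)
        hill = steady_state(
            make_model("hill", **{k: (*v, 1.0) for k, v in over.items()}), 0.5
        )
        assert mm.converged and hill.converged
        for sp, c in mm.concentrations.items():
            assert hill.concentrations[sp] == pytest.approx(c, abs=1e-12)

    def test_ode_integration_agrees_with_algebraic_solution(self):
        m = make_model(v13=(2.0, 0.7), v16=(0.6, 1.4), v20=(0.4, 0.8))
        alg = steady_state(m, 0.5, method="algebraic")
        ode = steady_state(m, 0.5, method="ode")
        assert alg.converged and ode.converged
        for sp, c in alg.concentrations.items():
            assert ode.concentrations[sp] == pytest.approx(c, abs=1e-6)
        assert ode.sg_ratio == pytest.approx(alg.sg_ratio, abs=1e-6)

    def test_nonpositive_influx_rejected(self):
        with pytest.raises(ValueError):
            steady_state(make_model(), 0.0)


class TestPerturbation:
    def test_unit_factor_changes_nothing(self):
        pr = perturbation_response(make_model(), 0.5, "CCoAOMT", 1.0)
        assert pr.relative_change == pytest.approx(0.0, abs=1e-12)

    def test_conservation_holds_before_and_after(self):
        pr = perturbation_response(make_model(), 0.5, "CCR1", 0.2)
        for ss in (pr.baseline, pr.perturbed):
            if ss.converged:
                assert ss.g_flux + ss.s_flux == pytest.approx(0.5, abs=1e-8)

    def test_linear_regime_knockdown_leaves_sg_unchanged(self):
        # far from saturation the branch split depends only on vmax/km at
        # the branch points, not on how the upstream routes share the load
        m = make_model(
            v10=(1e-12, 1.0), v11=(50.0, 50.0), v13=(60.0, 40.0),
            v12=(50.0, 50.0), v14=(40.0, 60.0), v16=(30.0, 45.0),
            v15=(55.0, 35.0), v20=(25.0, 50.0),
        )
        pr = perturbation_response(m, 0.5, "CCoAOMT", 0.2)
        assert pr.relative_change == pytest.approx(0.0, abs=1e-6)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            perturbation_response(make_model(), 0.5, "CAD", 0.2)

    def test_nonconvergent_perturbation_flagged(self):
        # knocking v13 down to 10% drops its capacity below the route flux
        m = make_model(v10=(1e-12, 1.0), v11=(2.0, 0.1), v13=(1.0, 1.0))
        pr = perturbation_response(m, 0.5, "CCR1", 0.1)
        assert pr.relative_change is None
        assert not pr.perturbed.converged
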