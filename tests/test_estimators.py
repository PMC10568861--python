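"""Estimator families: name parsing, hand oracles, MR reductions."""

import numpy as np
import pytest

from hypothesis import given, settings
from hypothesis import strategies as st

from mrate.estimators import (
    EstimatorSpec,
    ipw_estimate,
    mr_estimate,
    or_estimate,
    parse_estimator_name,
)
from mrate.models import FittedCandidates, assemble_candidates, or_spec, ps_spec
from tests.conftest import make_dataset


def empty_candidates(n):
    return FittedCandidates(
        ps_hat=np.empty((n, 0)),
        m1_hat=np.empty((n, 0)),
        m0_hat=np.empty((n, 0)),
        theta1=np.empty(0),
        theta0=np.empty(0),
        eta1=np.empty(0),
        eta0=np.empty(0),
    )


class TestNameParsing:
    def test_mr_digit_mapping(self):
        spec = parse_estimator_name("MR000010", 3, 3)
        assert spec.family == "mr"
        assert spec.ps_indices == ()
        assert spec.or_indices == (1,)  # fifth digit = second OR model

    def test_mr_all_models(self):
        spec = parse_estimator_name("MR111111", 3, 3)
        assert spec.ps_indices == (0, 1, 2)
        assert spec.or_indices == (0, 1, 2)

    def test_wrong_digit_count(self):
        with pytest.raises(ValueError, match="6 digits"):
            parse_estimator_name("MR0000", 3, 3)

    @pytest.mark.parametrize("name", ["MRabc", "IPW.model9", "XYZ.model1", "OR.model0"])
    def test_malformed_names(self, name):
        with pytest.raises(ValueError):
            parse_estimator_name(name, 3, 3)

    @settings(deadline=None, derandomize=True)
    @given(bits=st.lists(st.booleans(), min_size=1, max_size=12), n_ps=st.integers(0, 6))
    def test_mr_digit_roundtrip(self, bits, n_ps):
        """Any digit string parses back to exactly the selected candidates."""
        n_ps = min(n_ps, len(bits))
        n_or = len(bits) - n_ps
        name = "MR" + "".join("1" if b else "0" for b in bits)
        spec = parse_estimator_name(name, n_ps, n_or)
        assert spec.included_ps + spec.included_or == tuple(bits)
        assert spec.name == name

    def test_single_model_families(self):
        ipw = parse_estimator_name("IPW.model2", 3, 3)
        assert ipw.family == "ipw" and ipw.ps_indices == (1,)
        orr = parse_estimator_name("OR.model1", 3, 3)
        assert orr.family == "or" and orr.or_indices == (0,)


class TestIPW:
    def test_constant_propensity_reduces_to_mean_difference(self, tiny_dataset):
        est = ipw_estimate(tiny_dataset, np.full(4, 0.5)).estimate
        assert est == pytest.approx(3.0 - 2.0)

    def test_hajek_hand_oracle(self, tiny_dataset):
        # Z=(1,1,0,0), Y=(2,4,1,3), pi=(0.5,0.25,0.5,0.25):
        # treated: (2/0.5+4/0.25)/(1/0.5+1/0.25) = 20/6; control: (1/0.5+3/(0.75))/(2+4/3)=1.8
        pi = np.array([0.5, 0.25, 0.5, 0.25])
        est = ipw_estimate(tiny_dataset, pi).estimate
        assert est == pytest.approx(10 / 3 - 1.8)

    def test_horvitz_thompson_variant(self, tiny_dataset):
        pi = np.array([0.5, 0.25, 0.5, 0.25])
        est = ipw_estimate(tiny_dataset, pi, hajek=False).estimate
        expected = (2 / 0.5 + 4 / 0.25 - 1 / 0.5 - 3 / 0.75) / 4
        assert est == pytest.approx(expected)

    def test_empty_arm_rejected(self):
        ds = make_dataset([[0.0], [1.0]], [1, 1], [1.0, 2.0])
        from mrate.data import EmptyArmError

        with pytest.raises(EmptyArmError):
            ipw_estimate(ds, np.array([0.5, 0.5]))


class TestOR:
    def test_equal_counterfactuals_give_zero(self, tiny_dataset):
        m = np.ones(4)
        assert or_estimate(tiny_dataset, m, m).estimate == 0.0

    def test_unit_contrast_gives_one(self, tiny_dataset):
        m0 = np.arange(4.0)
        assert or_estimate(tiny_dataset, m0 + 1.0, m0).estimate == pytest.approx(1.0)


class TestMR:
    def test_empty_mask_reduces_to_arm_mean_difference(self, tiny_dataset):
        spec = EstimatorSpec("MR000000", "mr", (False,) * 0, (False,) * 0)
        est = mr_estimate(tiny_dataset, empty_candidates(4), spec)
        assert est.estimate == pytest.approx(3.0 - 2.0, abs=1e-14)

    def test_constant_model_injection_is_invariant(self, small_sim):
        """A model whose centered constraint column is zero never moves MR."""
        fc0 = empty_candidates(small_sim.n)
        base = mr_estimate(
            small_sim, fc0, EstimatorSpec("MR", "mr", (), ())
        ).estimate
        fc1 = FittedCandidates(
            ps_hat=np.full((small_sim.n, 1), 0.37),
            m1_hat=np.empty((small_sim.n, 0)),
            m0_hat=np.empty((small_sim.n, 0)),
            theta1=np.array([0.37]),
            theta0=np.array([0.63]),
            eta1=np.empty(0),
            eta0=np.empty(0),
        )
        with_const = mr_estimate(
            small_sim, fc1, EstimatorSpec("MR1", "mr", (True,), ())
        ).estimate
        assert with_const == pytest.approx(base, abs=1e-12)

    def test_calibration_transfer(self, small_sim):
        """Reweighted arm means of each included candidate hit its target."""
        ps_specs = [ps_spec([f"X{i}" for i in range(1, 8)])]
        or_specs = [or_spec(["X1", "X2", "X3", "X8", "X9", "X10", "X1^2", "X2^2"])]
        fc = assemble_candidates(small_sim, ps_specs, or_specs, seed=0)
        spec = EstimatorSpec("MR11", "mr", (True,), (True,))
        est = mr_estimate(small_sim, fc, spec)
        from mrate.el import build_constraints, el_weights

        treated = small_sim.Z == 1
        sol = el_weights(build_constraints(fc, small_sim, "treated"))
        assert sol.weights @ fc.m1_hat[treated, 0] == pytest.approx(fc.eta1[0], abs=1e-6)
        assert sol.weights @ fc.ps_hat[treated, 0] == pytest.approx(fc.theta1[0], abs=1e-6)
        assert np.isfinite(est.estimate)
        assert est.diagnostics["treated"]["max_constraint_residual"] <= 1e-6


def test_correct_ps_calibration_is_nearly_unbiased():
    """MR with the exactly-correct logistic PS: small-sample sanity at 100 reps.

    The correctly specified propensity candidate drives the calibrated
    estimate close to the truth; the near-correct OR candidate (its printed
    feature list omits X4) carries a small residual association, so its
    bound is looser.
    """
    from mrate.dgp import DGPConfig, generate_dataset
    from mrate.sim import scenario, run_scenario

    sc = scenario(
        "T1", n=2000, n_reps=100, B=0,
        estimator_names=("MR010000", "MR000010", "MR010010"), base_seed=77,
    )
    out = run_scenario(sc).set_index("estimator")
    assert abs(out.loc["MR010000", "bias_pct"]) < 1.5
    assert abs(out.loc["MR010010", "bias_pct"]) < 1.5
    assert abs(out.loc["MR000010", "bias_pct"]) < 3.0
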