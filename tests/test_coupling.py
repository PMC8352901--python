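"""Coupling terms, network assembly and the ensemble builder."""

import math

import numpy as np
import pytest

from perclock.core_model import VariantSpec
from perclock.coupling import (
    CouplingTerm,
    NetworkError,
    NetworkSpec,
    Oscillator,
    antiphase_coupling_term,
    assemble_network,
    build_ensemble,
    dual_input_term,
    ensemble_readout,
    inphase_coupling_term,
    p2_coupling_term,
    single_oscillator,
)
from perclock.simulate import SolverSettings
from perclock.stimuli import StimulusSpec
from perclock.analysis import run_network, run_single


class TestCouplingTermArithmetic:
    def test_product_decay_values(self):
        assert antiphase_coupling_term(1.0, 2.0, 0.5) == pytest.approx(-1.0)
        assert antiphase_coupling_term(1.0, 0.0, 0.5) == 0.0  # silent source
        assert p2_coupling_term(2.0, 1.0, 0.5) == pytest.approx(-1.0)
        assert p2_coupling_term(2.0, 0.0, 0.5) == 0.0

    def test_gated_decay_limits(self):
        # saturating source switches the decay off
        assert inphase_coupling_term(1.0, 1e6, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)
        # beta=0 degenerates to constant-rate decay
        assert inphase_coupling_term(1.5, 3.0, 0.5, 0.0) == pytest.approx(-0.75)

    def test_gated_decay_monotone_in_source(self):
        sources = np.linspace(0.0, 5.0, 30)
        values = [inphase_coupling_term(1.0, s, 0.5, 2.0) for s in sources]
        assert np.all(np.diff(values) > 0)  # less negative as the source rises

    def test_product_terms_linear_in_source(self):
        for s in (0.0, 0.5, 2.0):
            assert antiphase_coupling_term(1.3, s, 0.7) == pytest.approx(-0.7 * 1.3 * s)

    def test_dual_input_degenerates_without_food(self):
        assert dual_input_term(1.0, 2.0, 0.5, 2.0, 0.0, 0.4) == pytest.approx(
            inphase_coupling_term(1.0, 2.0, 0.5, 2.0)
        )

    def test_dual_input_food_part(self):
        food_part = dual_input_term(1.0, 2.0, 0.5, 2.0, 0.5, 0.4) - dual_input_term(
            1.0, 2.0, 0.5, 2.0, 0.0, 0.4
        )
        assert food_part == pytest.approx(-0.2)


class TestValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            NetworkSpec(oscillators=(Oscillator(id="a"), Oscillator(id="a")))

    def test_dangling_source_rejected_before_integration(self):
        with pytest.raises(NetworkError, match="unknown oscillator"):
            NetworkSpec(
                oscillators=(Oscillator(id="a"),),
                couplings=(
                    CouplingTerm(
                        target=("a", "P0"), form="product_decay", source=("ghost", "P0"), alpha_t=0.5
                    ),
                ),
            )

    def test_unknown_variable_rejected(self):
        with pytest.raises(NetworkError, match="unknown variable"):
            NetworkSpec(
                oscillators=(Oscillator(id="a"),),
                couplings=(
                    CouplingTerm(
                        target=("a", "Q7"), form="product_decay", source=("a", "P0"), alpha_t=0.5
                    ),
                ),
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(form="product_decay", alpha_t=-0.5),
            dict(form="gated_decay", alpha_t=0.5),  # missing beta
            dict(form="dual_input", alpha_t=0.5, beta=2.0, delta=0.4),  # missing food
            dict(form="product_decay", alpha_t=0.5, beta=2.0),  # beta unused
        ],
    )
    def test_coupling_constant_validation(self, kwargs):
        with pytest.raises(NetworkError):
            CouplingTerm(target=("a", "P0"), source=("b", "P0"), **kwargs)


class TestAssembly:
    def test_decoupling_identity(self):
        """With vanishing coupling constants each unit follows its standalone
        trajectory (checked with alpha_t at the smallest admissible value)."""
        settings = SolverSettings(t_end=60.0)
        alone = run_single(settings=settings)
        net = NetworkSpec(
            oscillators=(Oscillator(id="a"), Oscillator(id="b")),
            couplings=(
                CouplingTerm(
                    target=("b", "P0"), form="product_decay", source=("a", "P0"), alpha_t=1e-12
                ),
            ),
        )
        traj = run_network(net, settings)
        np.testing.assert_allclose(traj["a.M"], alone["osc.M"], atol=1e-6)
        np.testing.assert_allclose(traj["b.M"], alone["osc.M"], atol=1e-6)

    def test_declaration_order_does_not_affect_trajectories(self):
        settings = SolverSettings(t_end=60.0)
        central = Oscillator(
            id="c", variant=VariantSpec.fly(1.0), stimulus=StimulusSpec.periodic(phi=math.pi)
        )
        peri = Oscillator(id="p")
        coupling = CouplingTerm(
            target=("p", "P0"), form="product_decay", source=("c", "P0"), alpha_t=0.5
        )
        t1 = run_network(NetworkSpec(oscillators=(central, peri), couplings=(coupling,)), settings)
        t2 = run_network(NetworkSpec(oscillators=(peri, central), couplings=(coupling,)), settings)
        np.testing.assert_allclose(t1["p.M"], t2["p.M"], atol=1e-9)
        np.testing.assert_allclose(t1["c.M"], t2["c.M"], atol=1e-9)

    def test_signal_tap_equals_explicit_coupling_source(self):
        """A signal-tap stimulus through the mrna port reads the source state
        exactly as the same value fed through a time-stimulus would."""
        settings = SolverSettings(t_end=40.0)
        net = NetworkSpec(
            oscillators=(
                Oscillator(id="src"),
                Oscillator(
                    id="dst",
                    variant=VariantSpec.mrna_decay(0.2),
                    stimulus=StimulusSpec.signal_tap("src", "M"),
                ),
            )
        )
        traj = run_network(net, settings)
        # the tapped oscillator is perturbed, the source is not
        alone = run_single(settings=settings)
        np.testing.assert_allclose(traj["src.M"], alone["osc.M"], atol=1e-7)
        assert np.max(np.abs(traj["dst.M"] - alone["osc.M"])) > 0.01

    def test_machinery_variant_conserves_pool_along_trajectory(self):
        from perclock.core_model import MachineryParams

        net = single_oscillator(
            variant=VariantSpec.mammal_machinery(2.0, MachineryParams(rho_m=1.0, xi=0.5, T0=1.0)),
            stimulus=StimulusSpec.periodic(),
        )
        traj = run_network(net, SolverSettings(t_end=60.0))
        total = traj["osc.T"] + traj["osc.Tstar"]
        np.testing.assert_allclose(total, 1.0, atol=1e-8)


class TestEnsemble:
    def test_single_unit_readout_equals_single_oscillator(self):
        settings = SolverSettings(t_end=60.0)
        spec = build_ensemble(n=1, alpha=1.0)
        traj = run_network(spec, settings)
        readout = ensemble_readout(traj, spec)
        alone = run_single(settings=settings)
        np.testing.assert_allclose(readout, alone["osc.M"], atol=1e-7)

    def test_homogeneous_units_stay_phase_identical_through_a_pulse(self):
        spec = build_ensemble(
            n=3, alpha=1.0, spread=0.0,
            stimulus=StimulusSpec.pulse(t_start=30.0, duration=1.0, magnitude=2.0),
        )
        traj = run_network(spec, SolverSettings(t_end=80.0))
        np.testing.assert_allclose(traj["unit0.M"], traj["unit1.M"], atol=1e-8)
        np.testing.assert_allclose(traj["unit0.M"], traj["unit2.M"], atol=1e-8)
        readout = ensemble_readout(traj, spec)
        np.testing.assert_allclose(readout, 3 * traj["unit0.M"], atol=1e-7)

    def test_inhomogeneous_coupling_desynchronizes_after_one_pulse(self):
        """The singularity mechanism: spread coupling constants plus a single
        1 h pulse shrink the macroscopic amplitude."""
        spec = build_ensemble(
            n=5, alpha=1.0, spread=0.5,
            stimulus=StimulusSpec.pulse(t_start=100.0, duration=1.0, magnitude=5.0),
        )
        traj = run_network(spec, SolverSettings(t_end=240.0))
        macro = ensemble_readout(traj, spec)
        t = traj.t
        before = macro[(t >= 52.0) & (t <= 100.0)]
        after = macro[(t >= 192.0) & (t <= 240.0)]
        amp_before = before.max() - before.min()
        amp_after = after.max() - after.min()
        assert amp_after < amp_before

    def test_invalid_ensemble_arguments(self):
        with pytest.raises(ValueError):
            build_ensemble(n=0)
        with pytest.raises(ValueError):
            build_ensemble(n=3, spread=1.5)
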