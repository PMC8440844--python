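"""Accelerometer inverse filtering: forward model, inversion, calibration."""

import numpy as np
import pytest
from dataclasses import replace

from voxphys.ibif import (
    IBIFParams,
    NotchFilterSpec,
    band_rms_error,
    calibrate_pso,
    default_bounds,
    forward_acc,
    ibif_inverse,
    optimize_notch_center,
    ovv_notch_inverse,
    transfer_function,
)
from voxphys.pipeline import glottal_pulse_train

FS = 8192.0
NOMINAL = IBIFParams(skin_mass=2.0, skin_stiffness=1.3e6, skin_damping=600.0,
                     trachea_length=0.115, sensor_depth=0.05)


def pulse_flow(duration=0.4, fo=180.0):
    """Band-limited glottal-flow surrogate in m^3/s."""
    return glottal_pulse_train(fo, FS, duration) * 1e-6


class TestForward:
    def test_zero_in_zero_out(self):
        acc = forward_acc(np.zeros(2048), NOMINAL, FS)
        assert np.max(np.abs(acc)) == 0.0

    def test_linear_in_sensitivity(self):
        ug = pulse_flow()
        a1 = forward_acc(ug, NOMINAL, FS)
        a2 = forward_acc(ug, replace(NOMINAL, sensitivity=2.0), FS)
        assert np.allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_system_resonance_maximizes_response(self):
        """Sinusoidal flow sweep: the output amplitude is maximal at the
        composed-system resonance (oracle: |H| of the LTI model; for the
        nominal geometry the tracheal quarter-wave resonance dominates)."""
        freqs = np.linspace(60.0, 1100.0, 120)
        H = np.abs(transfer_function(NOMINAL, freqs))
        f_peak_tf = freqs[np.argmax(H)]
        # tracheal quarter-wave estimate
        assert f_peak_tf == pytest.approx(NOMINAL.c / (4 * NOMINAL.trachea_length), rel=0.2)
        t = np.arange(int(FS)) / FS
        amps = []
        for f0 in (100.0, f_peak_tf, 1050.0):
            ug = 1e-5 * np.sin(2 * np.pi * f0 * t)
            acc = forward_acc(ug, NOMINAL, FS)
            amps.append(np.sqrt(np.mean(acc[2000:] ** 2)))
        assert amps[1] == max(amps)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            IBIFParams(skin_mass=-1.0, skin_stiffness=1e6, skin_damping=500.0,
                       trachea_length=0.1, sensor_depth=0.05)
        with pytest.raises(ValueError):
            replace(NOMINAL, sensor_depth=0.2)


class TestInverse:
    def test_zero_input_zero_output(self):
        out = ibif_inverse(np.zeros(1024), NOMINAL, FS)
        assert np.max(np.abs(out)) == 0.0

    # the system impulse response spans ~50 ms, so finite-window round trips
    # are compared on the interior (continuous recordings discard edges)
    TRIM = slice(820, -820)

    def test_roundtrip_within_two_percent(self):
        """inverse(forward(Ug)) recovers Ug within 2% RMS in 60-1,100 Hz."""
        ug = pulse_flow()
        acc = forward_acc(ug, NOMINAL, FS)
        est = ibif_inverse(acc, NOMINAL, FS)  # mL/s
        err = band_rms_error(est[self.TRIM], ug[self.TRIM] * 1e6, FS)
        assert err < 0.02

    def test_roundtrip_other_direction(self):
        """forward(inverse(acc)) reproduces acc within 2% RMS in band."""
        acc0 = forward_acc(pulse_flow(), NOMINAL, FS)
        flow = ibif_inverse(acc0, NOMINAL, FS) * 1e-6
        acc1 = forward_acc(flow, NOMINAL, FS)
        assert band_rms_error(acc1[self.TRIM], acc0[self.TRIM], FS) < 0.02

    def test_roundtrip_across_parameter_bounds(self, rng):
        """The 2% round-trip property holds over the documented bounds."""
        bounds = default_bounds(NOMINAL, rel=0.5)
        for _ in range(5):
            draw = {k: rng.uniform(*v) for k, v in bounds.items()}
            draw["sensor_depth"] = min(draw["sensor_depth"], 0.9 * draw["trachea_length"])
            p = replace(NOMINAL, **draw)
            ug = pulse_flow()
            est = ibif_inverse(forward_acc(ug, p, FS), p, FS)
            assert band_rms_error(est[self.TRIM], ug[self.TRIM] * 1e6, FS) < 0.02

    def test_mismatched_parameters_degrade_roundtrip(self):
        ug = pulse_flow()
        acc = forward_acc(ug, NOMINAL, FS)
        good = band_rms_error(ibif_inverse(acc, NOMINAL, FS), ug * 1e6, FS)
        wrong = replace(NOMINAL, trachea_length=0.115 * 1.2)
        bad = band_rms_error(ibif_inverse(acc, wrong, FS), ug * 1e6, FS)
        assert bad > good


class TestPSO:
    def _setup(self):
        truth = replace(NOMINAL, skin_mass=2.3, skin_stiffness=1.1e6,
                        skin_damping=700.0, trachea_length=0.12, sensor_depth=0.055)
        # fo chosen so the harmonic comb samples the skin-resonance region
        ug = pulse_flow(duration=0.3, fo=130.0)
        acc = forward_acc(ug, truth, FS)
        return truth, ug, acc

    def test_parameter_recovery_over_seeds(self):
        """Known-parameter synthetic calibration: every parameter recovered
        within 10% and final cost below 5% RMS, across 5 seeds."""
        truth, ug, acc = self._setup()
        bounds = default_bounds(NOMINAL, rel=0.5)
        for seed in range(5):
            best, cost = calibrate_pso(acc, ug * 1e6, FS, bounds, seed=seed,
                                       swarm_size=24, iters=40, nominal=NOMINAL)
            assert cost < 0.05, f"seed {seed}: cost {cost}"
            for f in bounds:
                rel = abs(getattr(best, f) - getattr(truth, f)) / getattr(truth, f)
                assert rel < 0.10, f"seed {seed}: {f} off by {rel:.2%}"

    def test_degenerate_swarm_returns_initial_particle(self):
        truth, ug, acc = self._setup()
        bounds = default_bounds(NOMINAL, rel=0.5)
        best, cost = calibrate_pso(acc, ug * 1e6, FS, bounds, seed=0,
                                   swarm_size=1, iters=0, nominal=NOMINAL)
        for f in bounds:
            assert getattr(best, f) == pytest.approx(getattr(NOMINAL, f), rel=1e-12)

    def test_seed_determinism(self):
        truth, ug, acc = self._setup()
        bounds = default_bounds(NOMINAL, rel=0.5)
        b1, c1 = calibrate_pso(acc, ug * 1e6, FS, bounds, seed=4, swarm_size=8, iters=5)
        b2, c2 = calibrate_pso(acc, ug * 1e6, FS, bounds, seed=4, swarm_size=8, iters=5)
        assert c1 == c2 and b1 == b2


class TestNotchFilter:
    def test_notch_kills_center_frequency(self):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 700.0 * t)
        y = ovv_notch_inverse(x, FS, NotchFilterSpec(center_hz=700.0))
        assert np.sqrt(np.mean(y[100:] ** 2)) < 0.01

    def test_dc_passes_unchanged(self):
        y = ovv_notch_inverse(np.full(1000, 3.0), FS, NotchFilterSpec(center_hz=700.0))
        assert np.allclose(y[5:], 3.0, atol=1e-9)

    def test_center_frequency_bounds(self):
        with pytest.raises(ValueError):
            NotchFilterSpec(center_hz=50.0)

    def test_optimizer_finds_first_formant(self):
        """Pulse train + F1 resonator: optimizer picks the center within 5%
        of the known resonance (oracle: the resonator's pole frequency)."""
        from scipy import signal as sig

        f1 = 720.0
        r = 0.97
        flow = glottal_pulse_train(170.0, FS, 0.4)
        b, a = [1.0 - r], [1.0, -2 * r * np.cos(2 * np.pi * f1 / FS), r * r]
        ovv = sig.lfilter(b, a, flow - np.mean(flow))
        spec = optimize_notch_center(ovv, FS, band=(400.0, 1100.0))
        assert spec.center_hz == pytest.approx(f1, rel=0.05)
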