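"""Coherence/PLV formulas against naive oracles and closed-form cases."""

import numpy as np
import pytest

from eureka_eeg import connectivity
from eureka_eeg.connectivity import (
    all_pairs,
    baseline_correct,
    coherency,
    plv,
    windowed_connectivity,
)


def naive_coherency(ca, cb):
    """Literal transcription of the coherence formula, one frequency."""
    num = 0.0 + 0.0j
    sum_a = 0.0
    sum_b = 0.0
    for k in range(len(ca)):
        a_k, phi_k = abs(ca[k]), np.angle(ca[k])
        b_k, theta_k = abs(cb[k]), np.angle(cb[k])
        num += a_k * b_k * np.exp(1j * (phi_k - theta_k))
        sum_a += a_k**2
        sum_b += b_k**2
    return num / (np.sqrt(sum_a) * np.sqrt(sum_b))


def naive_plv(ca, cb):
    total = 0.0 + 0.0j
    for k in range(len(ca)):
        total += np.exp(1j * (np.angle(ca[k]) - np.angle(cb[k])))
    return total / len(ca)


class TestFormulaOracles:
    @pytest.mark.parametrize("n_trials", [2, 4, 8])
    def test_vectorized_equals_naive_loop(self, n_trials, rng):
        coeffs = rng.standard_normal((n_trials, 3)) + 1j * rng.standard_normal((n_trials, 3))
        for i in range(3):
            for j in range(3):
                fast_c = coherency(coeffs[:, i], coeffs[:, j])
                fast_p = plv(coeffs[:, i], coeffs[:, j])
                assert abs(fast_c - naive_coherency(coeffs[:, i], coeffs[:, j])) < 1e-12
                assert abs(fast_p - naive_plv(coeffs[:, i], coeffs[:, j])) < 1e-12

    def test_proportional_signals_give_unit_coherence(self, rng):
        a = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        c = coherency(a, 2 * a)
        assert abs(c) == pytest.approx(1.0, abs=1e-12)
        assert c.imag == pytest.approx(0.0, abs=1e-12)

    def test_quarter_cycle_lag_gives_unit_imaginary_coherence(self, rng):
        a = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        c = coherency(a, a * np.exp(-1j * np.pi / 2))
        assert c.imag == pytest.approx(1.0, abs=1e-12)

    def test_constant_phase_lag_gives_unit_plv(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 10)
        p = plv(phases, phases - np.pi / 4)
        assert abs(p) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_phase_differences_cancel(self):
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, np.pi, 0.0, np.pi])
        assert abs(plv(a, b)) == pytest.approx(0.0, abs=1e-12)

    def test_self_connectivity_is_exactly_one(self, rng):
        a = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        assert abs(coherency(a, a)) == pytest.approx(1.0, abs=1e-12)
        assert abs(plv(a, a)) == pytest.approx(1.0, abs=1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            coherency(np.ones(1, complex), np.ones(1, complex))
        with pytest.raises(ValueError):
            plv(np.ones(1), np.ones(1))

    def test_independent_phases_stay_below_null_ceiling(self, rng):
        # N = 200 independent trials: coherence rarely exceeds 0.15
        a = rng.standard_normal((200, 50)) + 1j * rng.standard_normal((200, 50))
        b = rng.standard_normal((200, 50)) + 1j * rng.standard_normal((200, 50))
        c = np.abs(coherency(a, b, axis=0))
        assert np.mean(c < 0.15) > 0.99


class TestWindowedConnectivity:
    def test_plv_invariant_to_per_trial_amplitude_rescaling(self, coupled_epochs, rng):
        cell = coupled_epochs.select(condition="Aha", stage="third")
        scaled = cell.take(range(cell.n_trials))
        scaled.data = scaled.data * rng.uniform(0.5, 5.0, size=(cell.n_trials, 1, 1))
        base = windowed_connectivity(cell, "alpha", (0.1, 0.5), pairs=[("C3", "C4")])
        resc = windowed_connectivity(scaled, "alpha", (0.1, 0.5), pairs=[("C3", "C4")])
        assert np.allclose(base.values("plv"), resc.values("plv"), atol=1e-9)
        # coherence weights amplitudes, so it must move
        assert not np.allclose(
            base.values("coherence"), resc.values("coherence"), atol=1e-6
        )

    def test_magnitudes_bounded_by_one(self, coupled_epochs):
        cell = coupled_epochs.select(condition="Ctrl", stage="third")
        conn = windowed_connectivity(cell, "alpha", (0.0, 0.5))
        for metric in ("coherence", "plv"):
            vals = conn.values(metric)
            assert np.nanmax(vals) <= 1 + 1e-9 and np.nanmin(vals) >= 0
        assert np.nanmax(np.abs(conn.values("icoh"))) <= 1 + 1e-9

    def test_imaginary_bounded_by_magnitude(self, coupled_epochs):
        cell = coupled_epochs.select(condition="Aha", stage="third")
        conn = windowed_connectivity(cell, "alpha", (0.0, 0.5))
        assert np.all(
            np.abs(np.imag(conn.coh)) <= np.abs(conn.coh) + 1e-12
        )

    def test_window_outside_epoch_rejected(self, coupled_epochs):
        cell = coupled_epochs.select(condition="Aha", stage="third")
        with pytest.raises(ValueError):
            windowed_connectivity(cell, "alpha", (0.5, 3.0))

    def test_kappa_sweep_maps_monotonically_to_plv(self):
        from eureka_eeg.synthdata import Oscillation, SynthSpec, generate_epochs

        ch = ("C3", "C4")
        estimates = []
        for kappa in (0.0, 1.0, 3.0, 10.0):
            spec = SynthSpec(
                n_trials_per_cell=60,
                channels=ch,
                fs=250.0,
                coupling=(
                    Oscillation(channels=ch, f_lo=9, f_hi=11, amplitude=8.0,
                                kappa=kappa, window=(0.0, 0.6)),
                ),
                noise_amplitude=1.0,
                seed=11,
            )
            cell = generate_epochs(spec).select(condition="Aha", stage="third")
            conn = windowed_connectivity(cell, "alpha", (0.1, 0.5), pairs=[ch])
            estimates.append(float(np.nanmean(conn.values("plv"))))
        assert estimates == sorted(estimates)


class TestBaselineCorrect:
    def test_identical_stages_cancel(self, coupled_epochs):
        cell = coupled_epochs.select(condition="Aha", stage="third")
        conn = windowed_connectivity(cell, "alpha", (0.0, 0.5), pairs=[("C3", "C4")])
        pv = baseline_correct(conn, conn, "plv")
        # stage-1 enters as its time average, so the corrected course is
        # centered on zero rather than identically zero
        assert abs(np.nanmean(pv.values)) < 1e-9
        assert pv.corrected

    def test_stage3_only_coupling_detected_positively(self):
        from eureka_eeg.synthdata import Oscillation, SynthSpec, generate_epochs

        ch = ("C3", "C4", "P3", "P4")
        spec = SynthSpec(
            n_trials_per_cell=12,
            channels=ch,
            fs=250.0,
            bands=(Oscillation(channels=ch, f_lo=8, f_hi=12, amplitude=2.0),),
            coupling=(
                Oscillation(channels=("C3", "C4"), f_lo=9, f_hi=11, amplitude=6.0,
                            kappa=8.0, window=(0.0, 0.6), stage="third"),
            ),
            noise_amplitude=3.0,
            seed=77,
        )
        epochs = generate_epochs(spec)
        aha3 = epochs.select(condition="Aha", stage="third")
        aha1 = epochs.select(condition="Aha", stage="first")
        c3 = windowed_connectivity(aha3, "alpha", (0.1, 0.5), pairs=[("C3", "C4"), ("P3", "P4")])
        c1 = windowed_connectivity(aha1, "alpha", (0.1, 0.5), pairs=[("C3", "C4"), ("P3", "P4")])
        pv = baseline_correct(c3, c1, "plv")
        coupled = np.nanmean(pv.values[0])
        uncoupled = np.nanmean(pv.values[1])
        assert coupled > 0.3 and coupled > uncoupled + 0.2

    def test_mismatched_pairs_rejected(self, coupled_epochs):
        cell = coupled_epochs.select(condition="Aha", stage="third")
        a = windowed_connectivity(cell, "alpha", (0.0, 0.5), pairs=[("C3", "C4")])
        b = windowed_connectivity(cell, "alpha", (0.0, 0.5), pairs=[("P3", "P4")])
        with pytest.raises(ValueError):
            baseline_correct(a, b, "plv")


def test_all_pairs_count():
    assert len(all_pairs(["a", "b", "c", "d"])) == 6
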