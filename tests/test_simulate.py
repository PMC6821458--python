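"""Generators: spectra, modulation ground truth, and scenario structure."""

import numpy as np
import pytest
from scipy import signal as sg

from glmcfc.decompose import analytic_phase_amplitude
from glmcfc.simulate import (SimulationSpec, local_maxima, pink_noise,
                             simulate, simulate_aac, simulate_amp_confound,
                             simulate_opposed_pac, simulate_pac,
                             simulate_pac_aac, simulate_sparse_pac,
                             simulate_spiking, simulate_stepped_confound,
                             simulate_two_condition)

FS = 1000.0


def test_pink_noise_spectral_slope():
    """Log-log periodogram slope near -1 over 1-100 Hz."""
    f = None
    acc = 0.0
    for seed in range(20):
        f, p = sg.periodogram(pink_noise(20.0, FS, seed), FS)
        acc = acc + p
    keep = (f >= 1.0) & (f <= 100.0)
    slope = np.polyfit(np.log(f[keep]), np.log(acc[keep] / 20), 1)[0]
    assert -1.3 < slope < -0.7


def test_pink_noise_deterministic_zero_mean_unit_sd():
    a = pink_noise(5.0, FS, seed=42)
    b = pink_noise(5.0, FS, seed=42)
    assert np.array_equal(a, b)
    assert abs(a.mean()) < 3.0 / np.sqrt(len(a))
    assert a.std() == pytest.approx(1.0)


def test_pac_zero_intensity_is_identity():
    sim = simulate_pac(i_pac=0.0, seed=1)
    assert np.all(sim.modulation == 1.0)
    assert np.array_equal(sim.v_high_mod, sim.v_high)


def test_pac_modulation_peak_exactly_doubles():
    sim = simulate_pac(i_pac=1.0, seed=2)
    assert sim.modulation.max() == pytest.approx(2.0, abs=1e-12)
    assert sim.modulation.min() >= 1.0
    # the modulation peaks exactly on V_low local maxima
    assert np.all(sim.modulation[sim.peak_times] == pytest.approx(2.0, abs=1e-9))


def test_pac_envelope_contrast_at_peaks():
    sim = simulate_pac(i_pac=1.0, seed=3)
    _, a_high = analytic_phase_amplitude(sim.v_high_mod)
    near = np.zeros(len(a_high), dtype=bool)
    for t in sim.peak_times:
        near[max(0, t - 21):t + 22] = True
    interior = slice(1000, -1000)
    assert a_high[interior][near[interior]].mean() > 1.3 * a_high[interior][~near[interior]].mean()


def test_aac_scaling_formula():
    sim = simulate_aac(i_aac=1.0, seed=4)
    k = np.argmax(sim.a_low)
    assert sim.v_high_mod[k] == pytest.approx(2.0 * sim.v_high[k], rel=1e-12)
    assert np.array_equal(simulate_aac(i_aac=0.0, seed=4).v_high_mod,
                          simulate_aac(i_aac=0.0, seed=4).v_high)


def test_aac_envelope_correlation():
    sim = simulate_aac(i_aac=1.0, seed=5)
    _, a_high = analytic_phase_amplitude(sim.v_high_mod)
    win = np.hanning(501); win /= win.sum()
    sm = np.convolve(a_high, win, mode="same")
    r = np.corrcoef(sim.a_low[1000:-1000], sm[1000:-1000])[0, 1]
    assert r > 0.5


def test_pac_aac_composition(pac_sim):
    sim = simulate_pac_aac(i_pac=1.0, i_aac=1.0, seed=6)
    expected = (sim.modulation * sim.v_high) * (1.0 + sim.a_low / sim.a_low.max())
    assert np.allclose(sim.v_high_mod, expected, rtol=1e-12)
    base = simulate_pac_aac(i_pac=0.0, i_aac=0.0, seed=6)
    assert np.array_equal(base.v_high_mod, base.v_high)


def test_sparse_pac_retains_high_amplitude_peaks():
    sim = simulate_sparse_pac(i_pac=1.0, seed=7)
    n_peaks = len(sim.peak_times)
    n_kept = len(sim.retained_peaks)
    # the surviving events sit in the high-envelope stretches: a modest
    # fraction of cycles, all above the peak-value threshold
    assert 0.05 * n_peaks <= n_kept <= 0.30 * n_peaks
    assert np.all(sim.a_low[sim.retained_peaks] >= sim.threshold)
    # the strict top-5% variant keeps far fewer
    strict = simulate_sparse_pac(i_pac=1.0, seed=7, quantile=0.95)
    assert len(strict.retained_peaks) < n_kept
    # modulation is baseline 1 away from the retained bumps
    far = np.ones(len(sim.v), dtype=bool)
    for t in sim.retained_peaks:
        far[max(0, t - 30):t + 31] = False
    assert np.all(sim.modulation[far] == 1.0)


def test_opposed_pac_modulation_bounds_and_stratification():
    sim = simulate_opposed_pac(i_pac=1.0, seed=8)
    assert sim.modulation.min() >= 0.0
    assert sim.modulation.max() <= 2.0 + 1e-12
    kept = sim.retained_peaks
    dropped = np.setdiff1d(sim.peak_times, kept)
    assert kept.size and dropped.size
    # suppressed bumps silence the modulation entirely
    assert np.all(sim.modulation[dropped] == 0.0)
    assert np.all(sim.modulation[kept] == pytest.approx(2.0, abs=1e-9))


def test_amp_confound_pair():
    sim = simulate_amp_confound(i_pac=1.0, seed=9)
    _, e1 = analytic_phase_amplitude(sim.v_low)
    # the alternate trace carries a doubled low-frequency component
    from glmcfc.decompose import decompose
    d1 = decompose(sim.v, FS).trimmed(1.0)
    d2 = decompose(sim.v_alternate, FS).trimmed(1.0)
    ratio = d2.a_low.mean() / d1.a_low.mean()
    assert 1.8 < ratio < 2.2
    r = np.corrcoef(d1.a_high, d2.a_high)[0, 1]
    assert r > 0.95


def test_stepped_confound_structure():
    sim = simulate_stepped_confound(duration=60.0, seed=10)
    n = len(sim.v)
    _, a = analytic_phase_amplitude(sim.v_low)
    first = a[1000:n // 2 - 1000].mean()
    second = a[n // 2 + 1000:-1000].mean()
    assert 7.0 < second / first < 13.0
    assert sim.modulation is None  # no phase coupling anywhere


def test_two_condition_variants():
    sim = simulate_two_condition("step_pac", seed=11)
    n = len(sim.v)
    assert sim.condition.sum() == n // 2
    assert np.all(sim.retained_peaks >= n // 2)
    null = simulate_two_condition("null", seed=11)
    assert np.all(null.modulation == 1.0)
    amp = simulate_two_condition("amp_double", seed=11)
    assert np.allclose(amp.v_low[n // 2:], 2.0 * null.v_low[n // 2:], rtol=1e-12)
    with pytest.raises(ValueError, match="variant"):
        simulate_two_condition("bogus", seed=0)


def test_spiking_phase_preference_tracks_alow():
    sim = simulate_spiking(duration=40.0, seed=12)
    spikes = sim.spikes.astype(bool)
    lo = spikes & (sim.a_low < 1.2)
    hi = spikes & (sim.a_low > 1.8)
    assert lo.sum() > 10 and hi.sum() > 10
    mean_lo = np.angle(np.mean(np.exp(1j * sim.phi_low[lo])))
    mean_hi = np.abs(np.angle(np.mean(np.exp(1j * (sim.phi_low[hi] + np.pi)))))
    assert abs(mean_lo) < 0.5          # near phase 0 when A_low small
    assert mean_hi < 0.5               # near +/-pi when A_low large
    resid = sim.a_high - sim.spikes
    assert resid.std() == pytest.approx(0.1, rel=0.05)


def test_generators_bit_reproducible():
    for fn in (lambda s: simulate_pac(1.0, seed=s).v,
               lambda s: simulate_opposed_pac(1.0, seed=s).v,
               lambda s: simulate_spiking(seed=s).a_high):
        assert np.array_equal(fn(99), fn(99))


def test_zero_intensity_scenarios_coincide():
    """With all intensities zero, the PAC and AAC constructions consume the
    same random draws and produce the identical trace."""
    assert np.array_equal(simulate_pac(0.0, seed=13).v,
                          simulate_aac(0.0, seed=13).v)


def test_spec_validation_and_dispatch():
    with pytest.raises(ValueError):
        SimulationSpec(scenario="pac", i_pac=-1.0)
    sim = simulate(SimulationSpec(scenario="two_condition", variant="null",
                                  duration=4.0, seed=1))
    assert sim.condition is not None


def test_local_maxima_plateau_first_sample():
    x = np.array([0.0, 1.0, 1.0, 0.5, 2.0, 1.0])
    assert np.array_equal(local_maxima(x), [1, 4])
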