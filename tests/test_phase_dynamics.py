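"""Envelope/modulation decomposition, Hilbert phase shifting, phase
estimation from emitter images, and phase-drift correction."""

import numpy as np
import pandas as pd
import pytest

from fourpi_smlm.config import OpticalConfig
from fourpi_smlm.localization import fit_images
from fourpi_smlm.phase_dynamics import (
    calibrate_phase_to_z,
    correct_phase_drift,
    decompose_psf,
    estimate_phase,
    phase_shift_psf,
    phase_trace,
)
from fourpi_smlm.psf_spline import BeadStack
from fourpi_smlm.simulator import (
    GroundTruthEmitter,
    make_symmetric_4pi_psf,
    simulate_emitter_image,
)


def _emitter_images(psf, cfg, rng, n, photons=8000.0, background=10.0, z_span=100.0):
    return np.stack(
        [
            simulate_emitter_image(
                psf,
                GroundTruthEmitter(
                    x=rng.uniform(-60, 60),
                    y=rng.uniform(-60, 60),
                    z=rng.uniform(-z_span, z_span),
                    photons=photons,
                    background=background,
                ),
                cfg=cfg,
                rng=rng,
            )
            for _ in range(n)
        ]
    )


# ------------------------------------------------------------- decomposition
def test_reconstruction_is_exact(small_dec, small_stack):
    # exact by construction, up to float cancellation in near-zero voxels
    assert np.allclose(
        small_dec.reconstruct(), small_stack.data,
        atol=1e-12 * small_stack.data.max(), rtol=0,
    )


def test_modulation_has_near_zero_z_mean(small_dec):
    colmean = np.abs(small_dec.h_mod.mean(axis=1))
    assert colmean.max() < 0.01 * small_dec.h_env.max()


def test_pure_envelope_has_no_modulation():
    # a band-limited envelope (decayed well before the stack edges, so the
    # periodic Fourier extension sees no discontinuity) must land entirely
    # in h_env
    zero_m = OpticalConfig(
        modulation_depth=1e-9,
        envelope_axial_sigma=350.0,
        defocus_spread_rate=1e-6,
        defocus_asymmetry=0.0,
    )
    stack = make_symmetric_4pi_psf(zero_m, n_xy=17, n_z=281, dz=10.0)
    dec = decompose_psf(stack)
    assert np.abs(dec.h_mod).max() < 1e-3 * stack.data.max()


def test_hilbert_turns_cosine_into_sine():
    z = np.arange(160) * 10.0
    k = 2 * np.pi / 200.0  # integer number of periods in the window
    col = np.cos(k * z)
    data = np.broadcast_to(col[None, :, None, None], (4, 160, 3, 3)).copy()
    dec = decompose_psf(
        BeadStack(data=data, voxel_size=(100.0, 100.0, 10.0)), cutoff_period=500.0
    )
    inner = slice(20, -20)  # Hilbert boundary effects excluded
    assert np.allclose(
        dec.h_mod_90[0, inner, 1, 1], np.sin(k * z)[inner], atol=0.02
    )


def test_decompose_requires_z_extent():
    data = np.ones((4, 10, 3, 3))
    with pytest.raises(ValueError):
        decompose_psf(BeadStack(data=data, voxel_size=(100, 100, 10.0)))


# -------------------------------------------------------------- phase shift
def test_phase_shift_zero_is_identity(small_dec, small_stack):
    stack = phase_shift_psf(small_dec, 0.0, rebuild_spline=False)
    assert np.allclose(stack.data, small_stack.data, atol=1e-12)


def test_phase_shift_two_pi_is_identity(small_dec, small_stack):
    stack = phase_shift_psf(small_dec, 2 * np.pi, rebuild_spline=False)
    inner = np.s_[:, 15:-15]
    assert np.allclose(
        stack.data[inner], small_stack.data[inner],
        atol=1e-3 * small_stack.data.max(),
    )


def test_phase_shifts_compose_additively(small_dec):
    a = phase_shift_psf(small_dec, 0.4, rebuild_spline=False)
    b = phase_shift_psf(decompose_psf(a), 0.9, rebuild_spline=False)
    direct = phase_shift_psf(small_dec, 1.3, rebuild_spline=False)
    inner = np.s_[:, 15:-15]
    assert np.allclose(
        b.data[inner], direct.data[inner], atol=1e-3 * direct.data.max()
    )


def test_phase_shift_matches_simulator_oracle(cfg, small_dec):
    """Numerically shifted PSF equals the scalar model generated with its
    interference phase advanced by the same amount (the validation the
    cavity-length experiment provides for real PSFs)."""
    dphi = 0.7
    shifted = phase_shift_psf(small_dec, dphi, rebuild_spline=False)
    ref = make_symmetric_4pi_psf(cfg, n_xy=17, n_z=101, dz=10.0, phase=dphi)
    inner = np.s_[:, 15:-15]
    err = np.abs(shifted.data[inner] - ref.data[inner]).max()
    assert err < 0.03 * ref.data.max()


def test_phase_shift_records_offset(small_dec):
    _, psf = phase_shift_psf(small_dec, 0.55)
    assert psf.phase_offset == pytest.approx(0.55)


# ---------------------------------------------------------- phase estimation
def test_phase_of_base_model_is_zero(small_psf, cfg, phase_models, rng):
    ims = _emitter_images(small_psf, cfg, rng, 150)
    phi, prec, info = estimate_phase(
        ims, small_psf, cfg.pixel_size_lateral, models=phase_models
    )
    err = min(phi, 2 * np.pi - phi)
    assert err < 3 * max(prec, 0.02)
    assert not info["low_confidence"]


def test_phase_estimate_recovers_known_phase(small_psf, small_dec, cfg, phase_models, rng):
    phi_true = 2.3
    _, psf_true = phase_shift_psf(small_dec, phi_true)
    ims = _emitter_images(psf_true, cfg, rng, 250)
    phi, prec, _ = estimate_phase(
        ims, small_psf, cfg.pixel_size_lateral, models=phase_models
    )
    assert phi == pytest.approx(phi_true, abs=0.1)


def test_dense_scan_agrees_with_sparse_model_minimum(
    small_psf, small_dec, cfg, phase_models, rng
):
    """Brute-force scan with a finer phase grid lands on the same minimum
    as the 12-model procedure."""
    phi_true = 1.7
    _, psf_true = phase_shift_psf(small_dec, phi_true)
    ims = _emitter_images(psf_true, cfg, rng, 120)
    phi12, _, _ = estimate_phase(
        ims, small_psf, cfg.pixel_size_lateral, models=phase_models
    )
    phi24, _, _ = estimate_phase(
        ims, small_psf, cfg.pixel_size_lateral, n_phase_models=24
    )
    d = abs(phi12 - phi24)
    assert min(d, 2 * np.pi - d) < 0.05


def test_phase_trace_recovers_linear_drift(small_psf, cfg, rng):
    n = 750
    tt = np.linspace(0, 300, n)
    phis = 0.6 + 0.5 * tt / 300
    ims = np.stack(
        [
            simulate_emitter_image(
                None,
                GroundTruthEmitter(
                    x=rng.uniform(-50, 50),
                    y=rng.uniform(-50, 50),
                    z=rng.uniform(-100, 100),
                    photons=8000.0,
                    background=10.0,
                ),
                cfg=cfg,
                rng=rng,
                phase=phis[i],
            )
            for i in range(n)
        ]
    )
    trace = phase_trace(ims, tt, small_psf, cfg.pixel_size_lateral, window_size=250)
    assert len(trace.window_phases) == 3
    true_at = np.interp(trace.window_times, tt, phis)
    slope_est = np.polyfit(trace.window_times, trace.window_phases, 1)[0]
    slope_true = 0.5 / 300
    assert slope_est == pytest.approx(
        slope_true, abs=2 * trace.phase_precision.mean() / np.ptp(trace.window_times)
    )
    # windows track the injected phase up to a common estimator offset
    offs = trace.window_phases - true_at
    assert np.ptp(offs) < 0.1


def test_phase_trace_requires_time_order(small_psf, cfg, rng):
    ims = np.zeros((10, 4, 7, 7))
    with pytest.raises(ValueError, match="time-ordered"):
        phase_trace(ims, np.arange(10)[::-1], small_psf, 138.2)


# ------------------------------------------------------------- calibration
def test_phase_to_z_slope_matches_fringe_period(small_psf, cfg):
    cal = calibrate_phase_to_z(small_psf)
    assert not cal.flagged
    assert cal.r_squared > 0.99
    assert abs(cal.slope) == pytest.approx(cfg.fringe_period / (2 * np.pi), rel=0.05)
    # sign convention: advancing the model phase moves the fitted z up
    assert cal.slope > 0


def test_phase_to_z_zero_span_rejected(small_psf):
    with pytest.raises(ValueError, match="degenerate"):
        calibrate_phase_to_z(small_psf, phase_span=0.0)


def test_correct_phase_drift_identity_and_linearity(small_psf):
    from fourpi_smlm.phase_dynamics import PhaseTrace, PhaseZCalibration

    cal = PhaseZCalibration(slope=40.0)
    trace = PhaseTrace(
        window_times=[0.0, 10.0],
        window_phases=[1.0, 1.0],
        phase_precision=[0.02, 0.02],
        n_locs_per_window=[250, 250],
    )
    locs = pd.DataFrame(dict(z_nm=[100.0, -50.0], time_s=[2.0, 8.0]))
    out = correct_phase_drift(locs, trace, cal, reference_phase=1.0)
    assert np.allclose(out["z_nm"], locs["z_nm"])  # flat trace at reference
    step = PhaseTrace(
        window_times=[0.0, 10.0],
        window_phases=[1.0, 1.5],
        phase_precision=[0.02, 0.02],
        n_locs_per_window=[250, 250],
    )
    out2 = correct_phase_drift(locs, step, cal, reference_phase=1.0)
    # linear interpolation of the 0.5 rad step, scaled by the slope
    assert out2["z_nm"][0] == pytest.approx(100.0 + 40.0 * 0.5 * 0.2)


def test_drifting_phase_experiment_detrended(small_psf, small_dec, cfg, rng):
    n = 500
    tt = np.linspace(0, 250, n)
    phis = 0.9 + 0.6 * tt / 250
    zt = rng.uniform(-100, 100, n)
    ims = np.stack(
        [
            simulate_emitter_image(
                None,
                GroundTruthEmitter(x=0, y=0, z=zt[i], photons=8000.0, background=10.0),
                cfg=cfg,
                rng=rng,
                phase=phis[i],
            )
            for i in range(n)
        ]
    )
    trace = phase_trace(ims, tt, small_psf, cfg.pixel_size_lateral, window_size=250)
    cal = calibrate_phase_to_z(small_psf)
    ref = trace.mean_phase
    _, model = phase_shift_psf(small_dec, ref)
    params, _, conv = fit_images(ims, model, cfg.pixel_size_lateral)
    locs = pd.DataFrame(dict(z_nm=params[:, 2], time_s=tt))
    corr = correct_phase_drift(locs, trace, cal, ref)
    # interior region (between window centers, where the trace interpolates)
    inner = (tt >= trace.window_times[0]) & (tt <= trace.window_times[-1]) & conv
    resid_b = locs["z_nm"].to_numpy()[inner] - zt[inner]
    resid_a = corr["z_nm"].to_numpy()[inner] - zt[inner]
    # the drift trend (|corr| ~ 1 before) is removed; a weak residual
    # correlation remains because the per-window estimator bias depends
    # slightly on where the phase falls within the 12-model grid
    assert abs(np.corrcoef(tt[inner], resid_a)[0, 1]) < 0.4
    assert resid_a.std() < 0.5 * resid_b.std()


# ------------------------------------------------- mis-phased model artifacts
def test_misphasing_beyond_sixty_degrees_raises_artifacts(
    wide_psf, cfg, rng
):
    """Fitting with a model mis-phased by 180 deg produces fringe
    misassignment; 60 deg does not (relative to the matched model), the
    safety margin that phase correction must keep."""
    from fourpi_smlm.localization import artifact_fraction
    from fourpi_smlm.phase_dynamics import decompose_psf as dp
    from fourpi_smlm.simulator import simulate_stepped_bead

    dec = dp(wide_psf)
    zs = np.arange(-500, 501, 100.0)
    ims, zt = simulate_stepped_bead(wide_psf, zs, 9200.0, 10.0, 8, rng=rng)
    cal_slope = cfg.fringe_period / (2 * np.pi)
    fracs = {}
    for deg in (0, 60, 180):
        dphi = np.deg2rad(deg)
        model = wide_psf if deg == 0 else phase_shift_psf(dec, dphi)[1]
        params, _, conv = fit_images(ims, model, cfg.pixel_size_lateral)
        # a mis-phased model shifts apparent z by +dphi * slope; artifacts
        # are counted relative to that phase-consistent position
        expected = zt + dphi * cal_slope
        frac, _, _ = artifact_fraction(
            params[conv, 2], expected[conv], cfg.fringe_period
        )
        fracs[deg] = frac
    assert fracs[0] == 0.0
    assert fracs[60] <= fracs[0] + 0.02
    assert fracs[180] > fracs[60] + 0.2
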