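"""Detection, grouping, multi-start fitting, CRLB and artifact counting."""

import numpy as np
import pandas as pd
import pytest

from fourpi_smlm import _kernels
from fourpi_smlm.localization import (
    EmitterImage,
    artifact_fraction,
    compute_crlb,
    default_z_starts,
    detect_candidates,
    fit_images,
    fit_localization,
    group_events,
    _geom,
)
from fourpi_smlm.psf_spline import PSFModelParams
from fourpi_smlm.simulator import (
    GroundTruthEmitter,
    scalar_psf_channels,
    simulate_emitter_image,
    simulate_stepped_bead,
)


def _movie_with_emitters(cfg, rng, emitters, n_frames=4, shape=48, photons=8000.0):
    frames = []
    for _ in range(n_frames):
        img = np.zeros((4, shape, shape))
        for (cx, cy, z) in emitters:
            X, Y = np.meshgrid(
                (np.arange(shape) - cx) * cfg.pixel_size_lateral,
                (np.arange(shape) - cy) * cfg.pixel_size_lateral,
            )
            piece = scalar_psf_channels(cfg, X, Y, np.full_like(X, z))
            img += piece / piece.sum() * photons
        img += 10.0
        frames.append(rng.poisson(img))
    return np.asarray(frames, float)


# ------------------------------------------------------------------ detection
def test_single_emitter_detected_within_one_pixel(cfg, rng):
    frames = _movie_with_emitters(cfg, rng, [(20, 30, 40.0)], n_frames=2)
    cands = detect_candidates(frames)
    assert len(cands) == 2
    assert np.allclose(cands["x_px"], 20, atol=1.0)
    assert np.allclose(cands["y_px"], 30, atol=1.0)


def test_background_only_movie_has_no_candidates(cfg, rng):
    frames = rng.poisson(10.0, size=(4, 4, 48, 48)).astype(float)
    cands = detect_candidates(frames)
    false_positive_rate = len(cands) / 4
    assert false_positive_rate == 0


def test_detection_is_insensitive_to_emitter_z(cfg, rng):
    """The channel-summed image cancels the interference term, so detected
    brightness barely depends on where in the fringe the emitter sits."""
    b = []
    for z in (0.0, cfg.fringe_period / 4, cfg.fringe_period / 2):
        frames = _movie_with_emitters(cfg, rng, [(24, 24, z)], n_frames=3)
        cands = detect_candidates(frames)
        assert len(cands) == 3
        b.append(cands["brightness"].mean())
    assert np.ptp(b) / np.mean(b) < 0.25


# ------------------------------------------------------------------- grouping
def test_three_frame_event_grouped_and_summed(cfg, rng):
    frames = _movie_with_emitters(cfg, rng, [(20, 20, 0.0)], n_frames=3)
    cands = detect_candidates(frames)
    events = group_events(cands, frames)
    assert len(events) == 1
    assert events[0].frame_count == 3
    # photon conservation: grouped ROI equals the sum of per-frame ROIs
    x0, y0 = events[0].roi_origin
    manual = frames[:, :, y0 : y0 + 7, x0 : x0 + 7].sum(axis=0)
    assert np.array_equal(events[0].pixels, manual)


def test_distant_emitters_stay_separate(cfg, rng):
    frames = _movie_with_emitters(cfg, rng, [(15, 15, 0.0), (30, 32, 50.0)])
    events = group_events(detect_candidates(frames), frames)
    assert len(events) == 2


# ------------------------------------------------------------------- fitting
def test_noiseless_self_consistency(small_psf, cfg):
    em = GroundTruthEmitter(x=25.0, y=-40.0, z=110.0, photons=8000.0, background=5.0)
    img = simulate_emitter_image(small_psf, em, cfg=cfg, noiseless=True)
    res = fit_localization(
        EmitterImage(pixels=img), small_psf, cfg.pixel_size_lateral
    )
    assert res.converged
    assert res.x == pytest.approx(25.0, abs=1e-3)
    assert res.y == pytest.approx(-40.0, abs=1e-3)
    assert res.z == pytest.approx(110.0, abs=1e-3)
    assert res.chi2 < 1e-8
    # photon estimate equals the expected in-ROI signal (truncation excluded)
    expected_in_roi = img.sum() - img.size * 5.0
    assert res.photons == pytest.approx(expected_in_roi, rel=1e-3)
    assert res.fringe_index == 0


def test_noisy_precision_in_paper_range(small_psf, cfg, rng):
    ims = np.stack(
        [
            simulate_emitter_image(
                small_psf,
                GroundTruthEmitter(photons=8000.0, background=10.0),
                cfg=cfg,
                rng=rng,
            )
            for _ in range(200)
        ]
    )
    params, chi2, conv = fit_images(ims, small_psf, cfg.pixel_size_lateral)
    assert conv.mean() > 0.98
    assert params[conv, 0].std() <= 5.0
    assert params[conv, 1].std() <= 5.0
    assert params[conv, 2].std() <= 3.0


def test_efficiency_against_crlb(small_psf, cfg, rng):
    """Empirical scatter tracks the Poisson CRLB within 20% on every axis."""
    n = 250
    ims = np.stack(
        [
            simulate_emitter_image(
                small_psf,
                GroundTruthEmitter(photons=8000.0, background=10.0),
                cfg=cfg,
                rng=rng,
            )
            for _ in range(n)
        ]
    )
    params, _, conv = fit_images(ims, small_psf, cfg.pixel_size_lateral)
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    rep = compute_crlb(
        small_psf, PSFModelParams(0, 0, 0, 8000.0, 10.0), pix, pix
    )
    for axis, bound in [(0, rep.crlb_x), (1, rep.crlb_y), (2, rep.crlb_z)]:
        ratio = params[conv, axis].std() / bound
        assert 0.9 < ratio < 1.2


def test_z_estimate_unbiased(small_psf, cfg, rng):
    zs = np.arange(-300, 301, 100.0)
    ims, zt = simulate_stepped_bead(small_psf, zs, 9200.0, 10.0, 40, rng=rng)
    params, _, conv = fit_images(ims, small_psf, cfg.pixel_size_lateral)
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    for z in zs:
        sel = conv & (zt == z) & (np.abs(params[:, 2] - zt) < cfg.fringe_period / 2)
        bias = params[sel, 2].mean() - z
        f = small_psf.evaluate(*np.meshgrid(pix, pix), np.full((7, 7), z))
        rep = compute_crlb(
            small_psf, PSFModelParams(0, 0, z, 9200.0 / f.sum(), 10.0), pix, pix
        )
        # mean of 40 fits: allow CRLB/3 systematic plus the sampling error
        assert abs(bias) < rep.crlb_z / 3 + 3 * rep.crlb_z / np.sqrt(sel.sum())


def test_multistart_finds_global_minimum(wide_psf, cfg, rng):
    """With start spacing below the fringe period, the converged starts
    always contain the global minimum seen by a dense z scan."""
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    n_bad = 0
    for _ in range(25):
        z_true = rng.uniform(-700, 700)
        em = GroundTruthEmitter(
            x=rng.uniform(-60, 60), y=rng.uniform(-60, 60), z=z_true,
            photons=9200.0, background=10.0,
        )
        img = np.ascontiguousarray(
            simulate_emitter_image(wide_psf, em, cfg=cfg, rng=rng)
        )
        zst = default_z_starts(wide_psf, None, cfg.fringe_period)
        best_p, best_chi2, conv, _, start_chi2s, _ = _kernels.fit_multistart(
            *_geom(wide_psf), pix, pix, img, 0.0, 0.0, zst, 50, 1e-6,
            _kernels.MODE_MLE,
        )
        # dense scan: fits pinned to a fine z grid must not beat the winner
        dense = np.linspace(-1050, 1050, 85)
        dense_best = np.inf
        for z0 in dense:
            A0, b0 = _kernels._init_amplitude(
                *_geom(wide_psf), pix, pix, img, 0.0, 0.0, z0
            )
            p, c, cv, _ = _kernels.lm_fit(
                *_geom(wide_psf), pix, pix, img,
                np.array([0.0, 0.0, z0, A0, b0]), 50, 1e-8, _kernels.MODE_MLE,
            )
            if cv:
                dense_best = min(dense_best, c)
        if dense_best < best_chi2 - 1e-6 * abs(best_chi2):
            n_bad += 1
    assert n_bad == 0


def test_wrong_fringe_start_converges_to_higher_local_minimum(small_psf, cfg):
    em = GroundTruthEmitter(x=0, y=0, z=30.0, photons=8000.0, background=10.0)
    img = np.ascontiguousarray(
        simulate_emitter_image(small_psf, em, cfg=cfg, noiseless=True)
    )
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    # single start one fringe away
    z0 = 30.0 + cfg.fringe_period
    A0, b0 = _kernels._init_amplitude(*_geom(small_psf), pix, pix, img, 0, 0, z0)
    p, chi2, conv, _ = _kernels.lm_fit(
        *_geom(small_psf), pix, pix, img, np.array([0, 0, z0, A0, b0]),
        50, 1e-8, _kernels.MODE_MLE,
    )
    res = fit_localization(EmitterImage(pixels=img), small_psf, cfg.pixel_size_lateral)
    assert conv
    assert abs(p[2] - 30.0) > cfg.fringe_period / 2  # stuck in the wrong fringe
    assert chi2 > res.chi2 + 1.0


# ----------------------------------------------------------------------- CRLB
def test_crlb_scales_with_photons(small_psf, cfg):
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    r1 = compute_crlb(small_psf, PSFModelParams(0, 0, 0, 4000.0, 0.0), pix, pix)
    r2 = compute_crlb(small_psf, PSFModelParams(0, 0, 0, 8000.0, 0.0), pix, pix)
    for a, b in [(r1.crlb_x, r2.crlb_x), (r1.crlb_z, r2.crlb_z)]:
        assert b / a == pytest.approx(1 / np.sqrt(2), rel=1e-3)


def test_fisher_matrix_matches_finite_differences(small_psf, cfg):
    pix = (np.arange(7) - 3) * cfg.pixel_size_lateral
    p = PSFModelParams(5.0, -8.0, 70.0, 8000.0, 10.0)
    mu, jac = small_psf.model_gradient(p, pix, pix)
    h = 1e-3
    names = ["x0", "y0", "z0", "A", "b"]
    num_jac = np.empty_like(jac)
    for a, name in enumerate(names):
        hp = h if name not in ("A",) else 1e-2
        pp = PSFModelParams(**{**p.__dict__})
        setattr(pp, name, getattr(p, name) + hp)
        pm = PSFModelParams(**{**p.__dict__})
        setattr(pm, name, getattr(p, name) - hp)
        num_jac[a] = (
            small_psf.model_image(pp, pix, pix)
            - small_psf.model_image(pm, pix, pix)
        ) / (2 * hp)
    mu_c = np.clip(mu, 1e-12, None)
    F_analytic = np.einsum("acpq,bcpq->ab", jac / mu_c, jac)
    F_numeric = np.einsum("acpq,bcpq->ab", num_jac / mu_c, num_jac)
    assert np.allclose(F_analytic, F_numeric, rtol=1e-3)


# ----------------------------------------------------------------- artifacts
def test_artifact_fraction_counts_and_bins():
    z_true = np.array([0.0, 0.0, 500.0, 500.0])
    z_fit = np.array([1.0, 260.0, 499.0, 500.0 - 253.0])
    frac, centers, per_bin = artifact_fraction(
        z_fit, z_true, 252.6, bins=np.array([-100.0, 100.0, 600.0])
    )
    assert frac == pytest.approx(0.5)
    assert per_bin[0] == pytest.approx(0.5)
    assert per_bin[1] == pytest.approx(0.5)


def test_noiseless_fits_have_zero_artifacts(small_psf, cfg):
    zs = np.arange(-400, 401, 100.0)
    ims, zt = simulate_stepped_bead(small_psf, zs, 9200.0, 10.0, 1, noiseless=True)
    params, _, conv = fit_images(ims, small_psf, cfg.pixel_size_lateral)
    frac, _, _ = artifact_fraction(params[conv, 2], zt[conv], cfg.fringe_period)
    assert frac == 0.0
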