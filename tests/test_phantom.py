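"""Phantom generator: analytic truth, reproducibility, parameter validation."""

import numpy as np
import pytest

from onhmorph.morphometry import measure_eye
from onhmorph.phantom import (PhantomParameterError, PhantomParams,
                              analytic_truth, generate_surfaces, mrw_truth_dense,
                              prelamina_volume_quadrature, rolled_params)
from onhmorph.regions import REGIONS, region_angle, trig_interp


def test_trig_interp_reproduces_samples_and_mean(rng):
    vals = rng.uniform(0.1, 0.5, 8)
    th = np.deg2rad(np.arange(8) * 45.0)
    assert np.allclose(trig_interp(vals, th), vals, atol=1e-12)
    dense = trig_interp(vals, np.linspace(0, 2 * np.pi, 4096, endpoint=False))
    assert np.mean(dense) == pytest.approx(np.mean(vals), abs=1e-12)


def test_noise_free_flat_rim_border_nfl_is_exact(flat_phantom):
    """Flat 0.30 mm rim: measured border NFL equals 0.300 in all regions."""
    truth = analytic_truth(flat_phantom)
    meas = measure_eye(generate_surfaces(flat_phantom, seed=0))
    for reg in REGIONS:
        assert truth.bnfl[reg] == pytest.approx(0.300, abs=1e-12)
        assert meas.bnfl[reg] == pytest.approx(0.300, abs=2 * flat_phantom.grid_spacing)
        # flat rim: minimum distance degenerates to the vertical distance
        assert truth.mrw[reg] == pytest.approx(0.300, abs=1e-6)


def test_cylinder_prelamina_volume_closed_form():
    """Flat prelamina at plane level over a flat LC at 0.5 mm: a cylinder."""
    p = PhantomParams(bmo_radius=0.9, cup_depth=0.0, lc_depth=0.5,
                      prelamina_thickness_profile={r: 0.5 for r in REGIONS},
                      grid_spacing=0.01)
    expected = np.pi * 0.9 ** 2 * 0.5
    truth = analytic_truth(p)
    assert truth.plv == pytest.approx(expected, rel=1e-9)
    assert prelamina_volume_quadrature(p, rtol=1e-6) == pytest.approx(expected, rel=1e-5)
    meas = measure_eye(generate_surfaces(p, seed=0))
    assert meas.plv == pytest.approx(expected, rel=0.01)


def test_sloped_cup_volume_matches_voxel_summation():
    """Cosine-cup truth vs brute-force lateral Riemann sum at 2 um."""
    p = PhantomParams(cup_depth=0.25, lc_depth=0.65,
                      prelamina_thickness_profile={r: 0.3 + 0.02 * i
                                                   for i, r in enumerate(REGIONS)})
    truth = analytic_truth(p)
    h = 0.002
    ax = np.arange(-p.bmo_radius, p.bmo_radius + h, h)
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y)
    th = np.arctan2(Y, X)
    inside = r <= p.bmo_radius
    integrand = (p.lc_z(r[inside], th[inside])
                 - np.clip(p.prelamina_z(r[inside]), 0.0, None))
    voxel = float(np.sum(integrand) * h * h)
    assert truth.plv == pytest.approx(voxel, rel=0.005)


def test_thickness_field_is_lc_minus_prelamina_everywhere(rng):
    """Conservation of the defining subtraction of prelamina thickness."""
    p = PhantomParams(cup_depth=0.2, lc_depth=0.55,
                      prelamina_thickness_profile={r: float(v) for r, v in
                                                   zip(REGIONS, rng.uniform(0.2, 0.5, 8))})
    r = rng.uniform(0, p.bmo_radius, 200)
    th = rng.uniform(0, 2 * np.pi, 200)
    np.testing.assert_allclose(p.lc_z(r, th) - p.prelamina_z(r),
                               p.thickness_field(r, th), atol=1e-12)


def test_mrw_truth_against_dense_bruteforce(rng):
    for _ in range(5):
        p = PhantomParams(rim_slope=float(rng.uniform(-0.1, 0.4)),
                          cup_depth=float(rng.uniform(0.05, 0.3)),
                          lc_depth=1.0,
                          rim_height_profile={r: float(v) for r, v in
                                              zip(REGIONS, rng.uniform(0.2, 0.4, 8))})
        truth = analytic_truth(p)
        for reg in ("S", "T", "IN"):
            dense = mrw_truth_dense(p, region_angle(reg), spacing=5e-5)
            assert truth.mrw[reg] == pytest.approx(dense, abs=1e-6)


def test_fixed_seed_bit_reproducible():
    p = PhantomParams(surface_noise_sd=0.01, grid_spacing=0.02)
    a = generate_surfaces(p, seed=42)
    b = generate_surfaces(p, seed=42)
    for name in a.SURFACE_NAMES:
        np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
    c = generate_surfaces(p, seed=43)
    assert not np.array_equal(a.ilm, c.ilm)


def test_noisy_measurements_unbiased_across_seeds():
    """Noise-free means over many seeds agree with truth within 3 SE."""
    p = PhantomParams(surface_noise_sd=0.01, grid_spacing=0.02)
    truth = analytic_truth(p)
    vals = []
    for seed in range(60):
        meas = measure_eye(generate_surfaces(p, seed=seed),
                           volume_n_r=80, volume_n_theta=96)
        vals.append(meas.bnfl["S"])
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - truth.bnfl["S"]) < 3 * se + 1e-4


def test_rolled_profiles_rotate_truth():
    vals = [0.32, 0.30, 0.28, 0.27, 0.31, 0.29, 0.25, 0.33]
    p = PhantomParams(rim_height_profile=dict(zip(REGIONS, vals)))
    t0 = analytic_truth(p)
    t1 = analytic_truth(rolled_params(p, k=1))
    for reg in REGIONS:
        th2 = (region_angle(reg) + np.pi / 4) % (2 * np.pi)
        reg2 = next(r for r in REGIONS
                    if np.isclose(region_angle(r) % (2 * np.pi), th2, atol=1e-9))
        assert t1.bnfl[reg2] == pytest.approx(t0.bnfl[reg], abs=1e-12)
    # the circular mean (hence volume, means) is rotation invariant
    assert t1.plv == pytest.approx(t0.plv, rel=1e-12)


@pytest.mark.parametrize("kwargs", [
    {"bmo_radius": 0.0},
    {"bmo_radius": -1.0},
    {"grid_spacing": 0.0},
    {"cup_depth": -0.1},
    {"cup_depth": 0.6, "lc_depth": 0.5},
    {"surface_noise_sd": -1e-3},
    {"rim_height_profile": {r: -0.1 for r in REGIONS}},
    {"rim_height_profile": {"S": 0.3}},
    {"prelamina_center_thickness": 0.99},
])
def test_invalid_phantom_params_rejected(kwargs):
    with pytest.raises(PhantomParameterError):
        PhantomParams(**kwargs)


def test_generate_surfaces_requires_phantom_params():
    with pytest.raises(PhantomParameterError):
        generate_surfaces("not params", seed=0)
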