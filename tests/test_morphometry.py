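"""Plane fitting, radial reslicing and the six measurement operations."""

import warnings

import numpy as np
import pytest

from onhmorph.morphometry import (CoverageError, FittingError, HalfMeridian,
                                  VolumeCoverageError, border_nfl,
                                  extract_radial_sections, fit_bmo_frame,
                                  measure_eye, mra_region, mrw, mrw_3d,
                                  peripapillary_nfl, prelamina_thickness,
                                  prelamina_volume)
from onhmorph.phantom import (PhantomParams, SurfaceSet, analytic_truth,
                              generate_surfaces, mirror_to_os)
from onhmorph.regions import REGIONS, region_angle

# ---------------------------------------------------------------------------
# BMO frame
# ---------------------------------------------------------------------------


def _circle_points(radius=0.9, z=0.0, n=8):
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    return {f"L{i}": np.array([radius * np.cos(t), radius * np.sin(t), z])
            for i, t in enumerate(th)}


def test_fit_bmo_frame_exact_planar_circle():
    frame = fit_bmo_frame(_circle_points())
    np.testing.assert_allclose(np.abs(frame.normal), [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(frame.centre, [0, 0, 0], atol=1e-12)
    # region axes pairwise at multiples of 45 degrees
    for a, b in [("S", "SN"), ("SN", "N"), ("T", "ST")]:
        cosang = frame.region_directions[a] @ frame.region_directions[b]
        assert cosang == pytest.approx(np.cos(np.pi / 4), abs=1e-9)


def test_fit_bmo_frame_alternating_perturbation_centred():
    pts = _circle_points()
    for i, k in enumerate(pts):
        pts[k] = pts[k] + np.array([0, 0, 0.01 if i % 2 == 0 else -0.01])
    frame = fit_bmo_frame(pts)
    assert np.linalg.norm(frame.centre[:2]) < 0.005
    assert abs(frame.centre[2]) < 0.005
    # least-squares residual property: mean signed distance to plane ~ 0
    d = [(p - frame.centre) @ frame.normal for p in pts.values()]
    assert abs(np.mean(d)) < 1e-9


def test_fit_bmo_frame_degenerate_points_rejected():
    coincident = {f"L{i}": np.array([0.1, 0.2, 0.3]) for i in range(8)}
    with pytest.raises(FittingError):
        fit_bmo_frame(coincident)
    collinear = {f"L{i}": np.array([i * 0.1, 0.0, 0.0]) for i in range(8)}
    with pytest.raises(FittingError):
        fit_bmo_frame(collinear)
    with pytest.raises(FittingError):
        fit_bmo_frame(np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# radial sections
# ---------------------------------------------------------------------------


def test_symmetric_phantom_has_identical_half_meridians(flat_phantom):
    ss = generate_surfaces(flat_phantom, seed=0)
    frame = fit_bmo_frame(ss.bmo_terminations)
    sections = extract_radial_sections(ss, frame)
    halves = {r: hm for sec in sections for r, hm in sec.halves.items()}
    ref = halves["S"]
    for reg in REGIONS:
        hm = halves[reg]
        n = min(len(ref.r), len(hm.r))
        np.testing.assert_allclose(hm.curves["ilm"][:n], ref.curves["ilm"][:n],
                                   atol=2e-4)


def test_superior_rim_asymmetry_localised():
    prof = {r: 0.30 for r in REGIONS}
    prof["S"] = 0.33
    p = PhantomParams(rim_height_profile=prof, grid_spacing=0.01)
    meas = measure_eye(generate_surfaces(p, seed=0))
    assert meas.bnfl["S"] == pytest.approx(0.33, abs=0.02)
    for reg in set(REGIONS) - {"S"}:
        assert meas.bnfl[reg] == pytest.approx(0.30, abs=0.02)


def test_short_grid_raises_coverage_error(flat_phantom):
    ss = generate_surfaces(flat_phantom, seed=0)
    keep = np.abs(ss.x) <= 1.5
    cropped = SurfaceSet(
        x=ss.x[keep], y=ss.y[keep],
        bmo_terminations=ss.bmo_terminations, eye=ss.eye,
        **{name: z[np.ix_(keep, keep)] for name, z in ss.surfaces().items()})
    with pytest.raises(CoverageError):
        extract_radial_sections(cropped, fit_bmo_frame(ss.bmo_terminations))


# ---------------------------------------------------------------------------
# per-half-meridian operations on constructed sections
# ---------------------------------------------------------------------------


def _flat_half_meridian(ilm_level=-0.25, nfl_offset=0.10, term_r=0.9):
    r = np.arange(0.0, 2.0, 0.01)
    curves = {
        "ilm": np.full_like(r, ilm_level),
        "nfl_posterior": np.full_like(r, ilm_level + nfl_offset),
        "bruchs": np.where(r >= term_r, 0.0, np.nan),
        "prelamina_anterior": np.where(r < term_r, 0.1, np.nan),
        "anterior_lc": np.where(r < term_r, 0.45, np.nan),
    }
    return HalfMeridian(region="S", r=r, curves=curves,
                        term_r=term_r, term_depth=0.0)


def test_border_nfl_flat_and_zero_cases():
    assert border_nfl(_flat_half_meridian(-0.25)) == pytest.approx(0.250, abs=1e-9)
    assert border_nfl(_flat_half_meridian(0.0)) == pytest.approx(0.0, abs=1e-9)
    missing = _flat_half_meridian()
    missing.curves["ilm"][:] = np.nan
    assert np.isnan(border_nfl(missing))


def test_peripapillary_nfl_parallel_planes_and_zero():
    hm = _flat_half_meridian(-0.25, nfl_offset=0.10)
    assert peripapillary_nfl(hm) == pytest.approx(0.100, abs=1e-9)
    hm0 = _flat_half_meridian(-0.25, nfl_offset=0.0)
    assert peripapillary_nfl(hm0) == pytest.approx(0.0, abs=1e-12)


def test_mrw_flat_equals_vertical_and_zero_on_contact():
    assert mrw(_flat_half_meridian(-0.25)) == pytest.approx(0.250, abs=1e-9)
    assert mrw(_flat_half_meridian(0.0)) == pytest.approx(0.0, abs=1e-9)


def test_mrw_never_exceeds_border_nfl_on_rough_curves(rng):
    for _ in range(50):
        hm = _flat_half_meridian(-float(rng.uniform(0.1, 0.4)))
        hm.curves["ilm"] = hm.curves["ilm"] + rng.normal(0, 0.02, len(hm.r))
        hm._splines.clear()
        b = border_nfl(hm)
        assert mrw(hm) <= b + 1e-9


def test_mra_full_ring_closed_form():
    # w = 0.25 mm at mid-radius 0.8 mm over 8 regions: 2*pi*0.8*0.25
    total = 8 * mra_region(0.25, 0.8, 0.8)
    assert total == pytest.approx(2 * np.pi * 0.8 * 0.25, rel=1e-12)
    assert np.isnan(mra_region(np.nan, 0.8, 0.8))


def test_prelamina_thickness_parallel_flat_surfaces():
    sections = []

    class FakeSection:
        def __init__(self, halves):
            self.halves = halves

    halves = {}
    for reg in REGIONS:
        halves[reg] = _flat_half_meridian()
    sections = [FakeSection({r: halves[r] for r in pair})
                for pair in (("S", "I"), ("SN", "IT"), ("N", "T"), ("ST", "IN"))]
    out = prelamina_thickness(sections)
    assert set(out) == set(REGIONS) | {"centre"}
    for k, v in out.items():
        assert v == pytest.approx(0.350, abs=1e-9)


def test_prelamina_thickness_clamps_negative_with_warning():
    hm = _flat_half_meridian()
    hm.curves["anterior_lc"] = np.where(hm.r < hm.term_r, 0.05, np.nan)  # above prelamina

    class FakeSection:
        def __init__(self, halves):
            self.halves = halves

    with pytest.warns(UserWarning, match="clamped"):
        out = prelamina_thickness([FakeSection({"S": hm})])
    assert out["S"] == 0.0


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------


def _cylinder_surface_set(radius=0.9, depth=0.5, spacing=0.01):
    p = PhantomParams(bmo_radius=radius, cup_depth=0.0, lc_depth=depth,
                      prelamina_thickness_profile={r: depth for r in REGIONS},
                      grid_spacing=spacing)
    return generate_surfaces(p, seed=0)


def test_prelamina_volume_cylinder():
    ss = _cylinder_surface_set()
    frame = fit_bmo_frame(ss.bmo_terminations)
    v = prelamina_volume(ss, frame)
    assert v == pytest.approx(np.pi * 0.9 ** 2 * 0.5, rel=0.01)


def test_prelamina_volume_zero_when_lc_touches_prelamina():
    ss = _cylinder_surface_set()
    ss.anterior_lc = ss.prelamina_anterior.copy()
    frame = fit_bmo_frame(ss.bmo_terminations)
    assert prelamina_volume(ss, frame) == pytest.approx(0.0, abs=1e-9)


def test_prelamina_volume_hole_handling():
    ss = _cylinder_surface_set()
    frame = fit_bmo_frame(ss.bmo_terminations)
    lc = ss.anterior_lc.copy()
    # small hole: inpainted with a warning
    hole = (np.hypot(*np.meshgrid(ss.x, ss.y)) < 0.08)
    ss.anterior_lc = np.where(hole, np.nan, lc)
    with pytest.warns(UserWarning, match="inpainting"):
        v = prelamina_volume(ss, frame)
    assert v == pytest.approx(np.pi * 0.9 ** 2 * 0.5, rel=0.02)
    # large hole: error
    hole = (np.hypot(*np.meshgrid(ss.x, ss.y)) < 0.45)
    ss.anterior_lc = np.where(hole, np.nan, lc)
    with pytest.raises(VolumeCoverageError):
        prelamina_volume(ss, frame)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_measure_eye_matches_truth_in_all_slots(asymmetric_measurement,
                                                asymmetric_phantom):
    truth, meas = asymmetric_measurement
    tol = 2 * asymmetric_phantom.grid_spacing
    for fam in ("bnfl", "pnfl", "mrw", "plt"):
        for k, tv in getattr(truth, fam).items():
            assert getattr(meas, fam)[k] == pytest.approx(tv, abs=tol), (fam, k)
    for k in REGIONS:
        assert meas.mra[k] == pytest.approx(truth.mra[k], rel=0.01)
    assert meas.plv == pytest.approx(truth.plv, rel=0.01)
    assert meas.bnfl_mean == pytest.approx(truth.bnfl_mean, abs=tol)


def test_measure_eye_missing_ilm_still_yields_volume(flat_phantom):
    ss = generate_surfaces(flat_phantom, seed=0)
    ss.ilm = np.full_like(ss.ilm, np.nan)
    ss.nfl_posterior = np.full_like(ss.nfl_posterior, np.nan)
    meas = measure_eye(ss)
    assert all(np.isnan(v) for v in meas.bnfl.values())
    assert all(np.isnan(v) for v in meas.mrw.values())
    assert np.isnan(meas.bnfl_mean)
    assert meas.plv > 0  # families are independent


def test_symmetric_phantom_mean_equals_regions(flat_phantom):
    meas = measure_eye(generate_surfaces(flat_phantom, seed=0))
    for reg in REGIONS:
        assert meas.bnfl[reg] == pytest.approx(meas.bnfl_mean, abs=1e-3)


def test_left_eye_mirroring_preserves_anatomical_labels(asymmetric_phantom,
                                                        asymmetric_measurement):
    truth, _ = asymmetric_measurement
    ss = mirror_to_os(generate_surfaces(asymmetric_phantom, seed=11))
    meas = measure_eye(ss)
    tol = 2 * asymmetric_phantom.grid_spacing
    for reg in REGIONS:
        assert meas.bnfl[reg] == pytest.approx(truth.bnfl[reg], abs=tol)
        assert meas.pnfl[reg] == pytest.approx(truth.pnfl[reg], abs=tol)


def test_mrw_3d_no_larger_than_section_mrw(flat_phantom):
    ss = generate_surfaces(flat_phantom, seed=0)
    frame = fit_bmo_frame(ss.bmo_terminations)
    sections = extract_radial_sections(ss, frame)
    hm = sections[0].halves["S"]
    w2d = mrw(hm)
    w3d = mrw_3d(ss, frame, "S")
    assert w3d <= w2d + 1e-3
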