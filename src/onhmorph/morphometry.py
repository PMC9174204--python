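"""ONH morphometry from segmented surfaces.

All measurements are referenced to the Bruch's membrane opening (BMO)
plane: a total-least-squares plane through the BMO termination
landmarks.  The volume is resliced radially at 45-degree intervals
around the BMO centre into four sections (eight half-meridians, regions
S, SN, N, IN, I, IT, T, ST), and per region the pipeline measures

* border NFL   – distance from the termination to the ILM along the
  plane normal ("height above the Bruch's membrane termination");
* peripapillary NFL – ILM to NFL-posterior separation, perpendicular to
  the local NFL course, at 1.7 mm in-plane from the BMO centre;
* minimum rim width (MRW) – minimum termination-to-ILM distance within
  the section plane;
* minimum rim area (MRA) – area of the conical frustum strip swept by
  the MRW segment over the region's 45-degree arc,
  ``(pi/4) * d_mid * w``;
* prelamina thickness – anterior-LC depth minus prelamina-surface depth
  (along the plane normal) at the centre and the eight sector midpoints;
* prelamina volume – integral of (LC depth − clamped cup depth) over
  the BMO-projected area.

Depths along the plane normal make every quantity invariant to scan
tilt; sampling a surface "along the normal" is solved by fixed-point
iteration on the height-map interpolant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize_scalar

from .parameters import ONHParameters
from .phantom import SurfaceSet
from .regions import REGIONS, region_angle


class FittingError(ValueError):
    """Degenerate landmark geometry (collinear/coincident points)."""


class CoverageError(ValueError):
    """A surface does not cover the lateral extent a measurement needs."""


#: Section orientations: each pairs two opposite half-meridians.
SECTION_ORIENTATIONS = (("S", "I"), ("SN", "IT"), ("N", "T"), ("ST", "IN"))


@dataclass
class BMOFrame:
    """BMO reference plane, centre and in-plane basis.

    ``normal`` is the unit plane normal pointing posteriorly
    (positive z); ``u``/``v`` span the plane.  ``region_directions``
    maps each region to its unit in-plane direction (the anatomical
    en-face direction projected onto the plane).
    """

    centre: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    eye: str = "OD"
    region_directions: dict[str, np.ndarray] = field(default_factory=dict)

    def inplane_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (a, b, depth): in-plane coordinates and normal depth."""
        d = np.atleast_2d(points) - self.centre
        return d @ self.u, d @ self.v, d @ self.normal


def fit_bmo_frame(terminations: dict[str, np.ndarray] | np.ndarray,
                  eye: str = "OD") -> BMOFrame:
    """Total-least-squares BMO reference plane from termination landmarks.

    The centre is the landmark centroid projected onto the plane.  The
    radial axes are anchored anatomically: each region direction is the
    en-face direction for ``eye`` projected into the plane.
    """
    if isinstance(terminations, dict):
        pts = np.array([np.asarray(p, dtype=float) for p in terminations.values()])
    else:
        pts = np.asarray(terminations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise FittingError("need at least 6 three-dimensional termination points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear or coincident landmarks leave no well-defined plane
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-8:
        raise FittingError("termination landmarks are collinear or coincident")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    frame = BMOFrame(centre=centroid, normal=normal, u=np.zeros(3), v=np.zeros(3), eye=eye)
    # in-plane basis: u along the projected +x axis, v = n x u
    ex = np.array([1.0, 0.0, 0.0])
    u = ex - np.dot(ex, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    frame.u, frame.v = u, v
    for region in REGIONS:
        th = region_angle(region, eye)
        d = np.array([math.cos(th), math.sin(th), 0.0])
        d = d - np.dot(d, normal) * normal
        frame.region_directions[region] = d / np.linalg.norm(d)
    return frame


# ---------------------------------------------------------------------------
# surface sampling along the plane normal
# ---------------------------------------------------------------------------

def _interpolator(ss: SurfaceSet, name: str) -> RegularGridInterpolator:
    return RegularGridInterpolator((ss.y, ss.x), getattr(ss, name),
                                   method="linear", bounds_error=False,
                                   fill_value=np.nan)


def _depth_along_normal(interp, origins: np.ndarray, normal: np.ndarray,
                        n_iter: int = 30, tol: float = 1e-12) -> np.ndarray:
    """Depth s of a height-map surface along lines ``origins + s*normal``.

    Solves z(s) = surf(xy(s)) by fixed-point iteration; with a vertical
    normal a single evaluation is exact.
    """
    nz = normal[2]
    if abs(nz) < 0.5:
        raise ValueError("plane normal too oblique for height-map sampling")
    lateral = math.hypot(normal[0], normal[1])
    iters = 1 if lateral < 1e-12 else n_iter

    def iterate(origins_sub: np.ndarray, s0: np.ndarray) -> np.ndarray:
        s = s0
        for _ in range(iters):
            p = origins_sub + s[:, None] * normal
            z = interp(p[:, [1, 0]])  # interpolator is (y, x) ordered
            s_new = (z - origins_sub[:, 2]) / nz
            if np.allclose(np.nan_to_num(s_new - s), 0.0, atol=tol):
                return s_new
            s = s_new
        return s

    s = iterate(origins, np.zeros(len(origins)))
    # points whose s=0 lateral start falls outside the surface footprint get
    # NaN-trapped even when the normal line does hit the surface; retry those
    # from a few plausible depths before declaring them missing
    stuck = ~np.isfinite(s)
    if stuck.any() and iters > 1:
        starts = [0.2, 0.4, 0.7, 1.0, -0.2]
        if np.isfinite(s).any():
            starts.insert(0, float(np.nanmedian(s)))
        for s0 in starts:
            sub = np.flatnonzero(stuck)
            if sub.size == 0:
                break
            s_try = iterate(origins[sub], np.full(sub.size, s0))
            ok = np.isfinite(s_try)
            s[sub[ok]] = s_try[ok]
            stuck[sub[ok]] = False
    return s


@dataclass
class HalfMeridian:
    """One half-meridian of a radial section, in section coordinates.

    ``r`` is the in-plane distance from the BMO centre along the region
    direction; ``curves[name][i]`` is the surface depth along the plane
    normal at ``r[i]`` (positive posterior, ``nan`` where undefined).
    ``term_r``/``term_depth`` locate the BM termination in the same
    coordinates.
    """

    region: str
    r: np.ndarray
    curves: dict[str, np.ndarray]
    term_r: float
    term_depth: float
    _splines: dict[str, CubicSpline | None] = field(default_factory=dict, repr=False)

    def spline(self, name: str) -> CubicSpline | None:
        if name not in self._splines:
            z = self.curves[name]
            good = np.isfinite(z)
            if good.sum() < 4:
                self._splines[name] = None
            else:
                self._splines[name] = CubicSpline(self.r[good], z[good],
                                                  extrapolate=False)
        return self._splines[name]

    def coverage(self, name: str) -> float:
        z = self.curves[name]
        good = np.isfinite(z)
        return float(self.r[good].max()) if good.any() else 0.0


@dataclass
class RadialSection:
    """A radial slice through the ONH: two opposite half-meridians."""

    orientation: tuple[str, str]
    halves: dict[str, HalfMeridian]


def extract_radial_sections(ss: SurfaceSet, frame: BMOFrame,
                            step: float | None = None,
                            required_radius: float = 1.7) -> list[RadialSection]:
    """Reslice the surfaces into 4 radial sections (8 half-meridians).

    Each surface is sampled along the plane normal at in-plane radii
    ``0, step, 2*step, ...`` in each region direction.  Raises
    :class:`CoverageError` naming the half-meridian if the ILM or NFL
    posterior boundary does not reach ``required_radius``.
    """
    ss.validate()
    if step is None:
        step = float(ss.x[1] - ss.x[0])
    r_max = float(min(ss.x[-1], ss.y[-1])) * 0.999
    if r_max < required_radius:
        raise CoverageError(
            f"lateral grid covers only {r_max:.3f} mm from the centre; "
            f"{required_radius} mm is required")
    r = np.arange(0.0, r_max, step)
    interps = {name: _interpolator(ss, name) for name in SurfaceSet.SURFACE_NAMES}

    halves: dict[str, HalfMeridian] = {}
    for region in REGIONS:
        e = frame.region_directions[region]
        origins = frame.centre + r[:, None] * e
        curves = {name: _depth_along_normal(interps[name], origins, frame.normal)
                  for name in SurfaceSet.SURFACE_NAMES}
        term = ss.bmo_terminations.get(region)
        if term is None:
            raise CoverageError(f"no BMO termination landmark for region {region}")
        a, b, depth = frame.inplane_coords(term)
        term_r = float(np.hypot(a, b)[0])
        hm = HalfMeridian(region=region, r=r, curves=curves,
                          term_r=term_r, term_depth=float(depth[0]))
        for name in ("ilm", "nfl_posterior"):
            cov = hm.coverage(name)
            # a wholly-unsegmented surface yields missing values downstream;
            # a surface that stops short of the pNFL radius is a hard error
            if 0.0 < cov < required_radius:
                raise CoverageError(
                    f"half-meridian {region}: {name} covers only "
                    f"{cov:.3f} mm < {required_radius} mm")
        halves[region] = hm

    return [RadialSection(orientation=pair,
                          halves={reg: halves[reg] for reg in pair})
            for pair in SECTION_ORIENTATIONS]


# ---------------------------------------------------------------------------
# per-half-meridian measurements
# ---------------------------------------------------------------------------

def border_nfl(hm: HalfMeridian) -> float:
    """Border NFL: termination-to-ILM distance along the plane normal (mm)."""
    sp = hm.spline("ilm")
    if sp is None:
        return float("nan")
    z = sp(hm.term_r)
    if not np.isfinite(z):
        return float("nan")
    return float(hm.term_depth - z)


def peripapillary_nfl(hm: HalfMeridian, radius: float = 1.7) -> float:
    """NFL thickness perpendicular to its local course at ``radius`` (mm)."""
    sp_i, sp_n = hm.spline("ilm"), hm.spline("nfl_posterior")
    if sp_i is None or sp_n is None:
        return float("nan")
    zi, zn = sp_i(radius), sp_n(radius)
    if not (np.isfinite(zi) and np.isfinite(zn)):
        return float("nan")
    slope = 0.5 * (float(sp_i(radius, 1)) + float(sp_n(radius, 1)))
    return float((zn - zi) / math.hypot(1.0, slope))


def mrw(hm: HalfMeridian, return_foot: bool = False):
    """Minimum rim width: min termination-to-ILM distance in-section (mm).

    Discrete search over the sampled ILM curve with local continuous
    refinement on the spline.  ``return_foot`` additionally returns the
    in-plane radius of the minimising ILM point (used by MRA).
    """
    sp = hm.spline("ilm")
    if sp is None:
        return (float("nan"), float("nan")) if return_foot else float("nan")
    rr = hm.r[np.isfinite(hm.curves["ilm"])]
    zz = sp(rr)
    d2 = (rr - hm.term_r) ** 2 + (zz - hm.term_depth) ** 2
    i = int(np.argmin(d2))
    best_r, best_d2 = float(rr[i]), float(d2[i])
    # the ILM point directly above the termination is on the curve too;
    # including it keeps mrw <= border NFL by construction
    z_t = sp(hm.term_r)
    if np.isfinite(z_t) and (z_t - hm.term_depth) ** 2 < best_d2:
        best_r, best_d2 = float(hm.term_r), float((z_t - hm.term_depth) ** 2)
    lo = rr[max(i - 1, 0)]
    hi = rr[min(i + 1, len(rr) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda r: (r - hm.term_r) ** 2 + (float(sp(r)) - hm.term_depth) ** 2,
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
        if np.isfinite(res.fun) and res.fun < best_d2:
            best_r, best_d2 = float(res.x), float(res.fun)
    w = math.sqrt(best_d2)
    return (w, best_r) if return_foot else w


def mrw_3d(ss: SurfaceSet, frame: BMOFrame, region: str) -> float:
    """Full 3-D minimum distance from a termination to the ILM surface.

    Available behind a flag; the standard measure is per-section
    (:func:`mrw`).
    """
    term = ss.bmo_terminations[region]
    X, Y = np.meshgrid(ss.x, ss.y)
    Z = ss.ilm
    good = np.isfinite(Z)
    d2 = (X[good] - term[0]) ** 2 + (Y[good] - term[1]) ** 2 + (Z[good] - term[2]) ** 2
    return float(np.sqrt(d2.min()))


def mra_region(w: float, term_r: float, foot_r: float) -> float:
    """Regional minimum rim area: frustum strip swept over a 45-degree arc.

    ``area = (pi/4) * d_mid * w`` with ``d_mid`` the in-plane distance
    from the BMO central axis to the MRW segment midpoint.
    """
    if not (np.isfinite(w) and np.isfinite(foot_r)):
        return float("nan")
    d_mid = 0.5 * (term_r + foot_r)
    return (math.pi / 4.0) * d_mid * w


def prelamina_thickness(sections: list[RadialSection]) -> dict[str, float]:
    """Prelamina thickness at the centre and the 8 sector midpoints (mm).

    Thickness is anterior-LC depth minus prelamina-surface depth, both
    along the plane normal; sector values are taken halfway between the
    BMO centre and each termination.  Negative values (possible under
    segmentation noise) are clamped to 0 with a warning.
    """
    out: dict[str, float] = {}
    centre_vals = []
    for sec in sections:
        for region, hm in sec.halves.items():
            sp_p, sp_l = hm.spline("prelamina_anterior"), hm.spline("anterior_lc")
            if sp_p is None or sp_l is None:
                out[region] = float("nan")
                continue
            r_mid = 0.5 * hm.term_r
            zp, zl = sp_p(r_mid), sp_l(r_mid)
            out[region] = float(zl - zp) if np.isfinite(zp) and np.isfinite(zl) else float("nan")
            zp0, zl0 = sp_p(0.0), sp_l(0.0)
            if np.isfinite(zp0) and np.isfinite(zl0):
                centre_vals.append(float(zl0 - zp0))
    out["centre"] = float(np.mean(centre_vals)) if centre_vals else float("nan")
    clamped = {k for k, v in out.items() if np.isfinite(v) and v < 0}
    if clamped:
        warnings.warn(f"negative prelamina thickness clamped to 0 in {sorted(clamped)}",
                      stacklevel=2)
        for k in clamped:
            out[k] = 0.0
    return out


class VolumeCoverageError(ValueError):
    """More than the tolerated fraction of the LC surface is unsegmented."""


def _opening_radius_interp(frame: BMOFrame, terms: dict[str, np.ndarray]):
    """Periodic interpolant of the opening radius vs in-plane angle."""
    angs, rads = [], []
    for p in terms.values():
        a, b, _ = frame.inplane_coords(np.asarray(p, dtype=float))
        angs.append(math.atan2(float(b[0]), float(a[0])) % (2 * math.pi))
        rads.append(float(np.hypot(a, b)[0]))
    order = np.argsort(angs)
    angs = np.array(angs)[order]
    rads = np.array(rads)[order]
    angs_ext = np.concatenate([angs - 2 * math.pi, angs, angs + 2 * math.pi])
    rads_ext = np.concatenate([rads, rads, rads])

    def rho(theta):
        return np.interp(np.asarray(theta) % (2 * math.pi), angs_ext, rads_ext)

    return rho


def _inpaint_nearest(a: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(a)
    if not bad.any():
        return a
    idx = distance_transform_edt(bad, return_distances=False, return_indices=True)
    return a[tuple(idx)]


def prelamina_volume(ss: SurfaceSet, frame: BMOFrame,
                     n_r: int = 160, n_theta: int = 240,
                     max_hole_fraction: float = 0.05) -> float:
    """Prelamina volume (mm^3) over the BMO-projected area.

    ``V = int depth_LC dA − int max(depth_prelamina, 0) dA`` with depths
    along the plane normal; polar midpoint quadrature over the opening
    (radius per angle interpolated from the terminations).  Holes in LC
    coverage above ``max_hole_fraction`` raise
    :class:`VolumeCoverageError`; smaller holes are inpainted by nearest
    neighbour with a logged warning.
    """
    rho = _opening_radius_interp(frame, ss.bmo_terminations)
    theta = (np.arange(n_theta) + 0.5) * (2 * math.pi / n_theta)
    frac = (np.arange(n_r) + 0.5) / n_r
    TH, FR = np.meshgrid(theta, frac, indexing="ij")
    RHO = rho(theta)[:, None]
    R = FR * RHO
    A = R * np.cos(TH)
    B = R * np.sin(TH)
    origins = (frame.centre[None, :]
               + A.ravel()[:, None] * frame.u
               + B.ravel()[:, None] * frame.v)

    depths = {}
    for name in ("anterior_lc", "prelamina_anterior"):
        d = _depth_along_normal(_interpolator(ss, name), origins, frame.normal)
        depths[name] = d.reshape(TH.shape)

    dA_all = R * (RHO / n_r) * (2 * math.pi / n_theta)
    hole_frac = float(np.sum(dA_all[~np.isfinite(depths["anterior_lc"])])
                      / np.sum(dA_all))
    if hole_frac > max_hole_fraction:
        raise VolumeCoverageError(
            f"{hole_frac:.1%} of the anterior LC surface is unsegmented "
            f"(> {max_hole_fraction:.0%})")
    if hole_frac > 0 or not np.isfinite(depths["prelamina_anterior"]).all():
        warnings.warn(f"inpainting {hole_frac:.2%} LC coverage holes by nearest neighbour",
                      stacklevel=2)
        depths = {k: _inpaint_nearest(v) for k, v in depths.items()}

    integrand = depths["anterior_lc"] - np.clip(depths["prelamina_anterior"], 0.0, None)
    # midpoint rule: dA = r dr dtheta with dr = rho/n_r per angle
    return float(np.sum(integrand * dA_all))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def measure_eye(ss: SurfaceSet, frame: BMOFrame | None = None,
                pnfl_radius: float = 1.7,
                volume_n_r: int = 160, volume_n_theta: int = 240,
                required_radius: float | None = None) -> ONHParameters:
    """All six parameter families for one eye (the full 35-slot vector).

    Missing regional values propagate as ``nan`` (never zero-filled);
    family means are over non-missing regions.  Raises
    :class:`CoverageError` / :class:`VolumeCoverageError` naming the
    failing half-meridian or surface.
    """
    if frame is None:
        frame = fit_bmo_frame(ss.bmo_terminations, eye=ss.eye)
    if required_radius is None:
        required_radius = pnfl_radius
    sections = extract_radial_sections(ss, frame, required_radius=required_radius)

    bnfl, pnfl, mrw_vals, mra_vals = {}, {}, {}, {}
    provenance: dict[str, dict] = {}
    for sec in sections:
        for region, hm in sec.halves.items():
            bnfl[region] = border_nfl(hm)
            pnfl[region] = peripapillary_nfl(hm, radius=pnfl_radius)
            w, foot = mrw(hm, return_foot=True)
            mrw_vals[region] = w
            mra_vals[region] = mra_region(w, hm.term_r, foot)
            provenance[region] = {"term_r_mm": hm.term_r,
                                  "term_depth_mm": hm.term_depth,
                                  "mrw_foot_r_mm": foot}

    plt = prelamina_thickness(sections)
    plv = prelamina_volume(ss, frame, n_r=volume_n_r, n_theta=volume_n_theta)
    return ONHParameters(bnfl=bnfl, pnfl=pnfl, mrw=mrw_vals, mra=mra_vals,
                         plt=plt, plv=plv, provenance=provenance)
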