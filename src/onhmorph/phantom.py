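"""Parametric 3-D optic-nerve-head phantoms with analytic ground truth.

The phantom family is built from smooth, radially parameterised surfaces
so that every regional morphometric target has a closed form:

* The BMO is a circle of radius ``R`` in a (possibly tilted) reference
  plane; the eight terminations sit on it at 45-degree spacing.
* Rim ILM height above each termination follows a band-limited angular
  profile ``h(theta)`` (trigonometric interpolation of the 8 regional
  targets), optionally with a constant radial slope outside the opening.
* Inside the opening the ILM descends into the cup along a cosine blend,
  flat (zero radial slope) at both the termination and the centre.
* The NFL posterior boundary is the ILM offset posteriorly by the
  angular peripapillary-thickness profile ``t(theta)``.
* The prelamina anterior surface is a cosine dome of depth ``cup_depth``;
  the anterior lamina cribrosa lies posterior to it by the thickness
  field ``T(u, theta) = T_c + (T_mid(theta) - T_c) * sin^2(pi u)`` with
  ``u = r/R``, so the centre thickness is ``T_c`` and the thickness at
  the sector midpoints (u = 1/2) equals the regional targets.

Axial convention: z increases posteriorly; depths below the BMO plane
are positive.  The canonical en-face frame is a right eye (+x temporal,
+y superior); plane tilt is an exact rigid rotation about the y axis,
so all plane-referenced measurements are invariant to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import ONHParameters
from .regions import PRELAMINA_REGIONS, REGIONS, profile_to_angle_order, region_angle, trig_interp


class PhantomParameterError(ValueError):
    """Raised when phantom parameters violate an invariant."""


def _uniform_profile(value: float) -> dict[str, float]:
    return {r: float(value) for r in REGIONS}


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of one ONH phantom (all lengths in mm).

    ``rim_height_profile`` sets the target border NFL per 45-degree region;
    ``pnfl_profile`` the target NFL thickness at 1.7 mm; ``cup_depth`` and
    ``lc_depth`` the prelamina-anterior and anterior-LC depths below the
    BMO plane at the centre.  ``rim_slope`` is the radial slope (mm/mm,
    positive = descending posteriorly going outward) of the ILM outside
    the opening; a positive slope makes the minimum rim width strictly
    smaller than the border NFL.
    """

    bmo_radius: float = 0.9
    bmo_plane_tilt: float = 0.0  # degrees, rotation about the y (S-I) axis
    rim_height_profile: dict[str, float] = field(default_factory=lambda: _uniform_profile(0.30))
    pnfl_profile: dict[str, float] = field(default_factory=lambda: _uniform_profile(0.10))
    cup_depth: float = 0.15
    lc_depth: float = 0.55
    prelamina_center_thickness: float | None = None
    prelamina_thickness_profile: dict[str, float] | None = None
    rim_slope: float = 0.0
    surface_noise_sd: float = 0.0
    grid_spacing: float = 0.010
    half_width: float = 1.85

    def __post_init__(self) -> None:
        if self.bmo_radius <= 0:
            raise PhantomParameterError("bmo_radius must be > 0")
        if self.grid_spacing <= 0:
            raise PhantomParameterError("grid_spacing must be > 0")
        if self.cup_depth < 0:
            raise PhantomParameterError("cup_depth must be >= 0")
        if self.lc_depth <= self.cup_depth:
            raise PhantomParameterError(
                "lc_depth must exceed cup_depth (prelamina thickness positive)")
        if self.surface_noise_sd < 0:
            raise PhantomParameterError("surface_noise_sd must be >= 0")
        if abs(self.bmo_plane_tilt) > 15.0:
            raise PhantomParameterError("bmo_plane_tilt limited to +/-15 degrees")
        if self.half_width < 1.75:
            raise PhantomParameterError("half_width must cover the 1.7 mm pNFL radius")
        for name in ("rim_height_profile", "pnfl_profile"):
            prof = getattr(self, name)
            missing = [r for r in REGIONS if r not in prof]
            if missing:
                raise PhantomParameterError(f"{name} missing regions {missing}")
            if any(prof[r] < 0 for r in REGIONS):
                raise PhantomParameterError(f"{name} values must be >= 0")
        tc = self.lc_depth - self.cup_depth
        if self.prelamina_center_thickness is not None:
            if not math.isclose(self.prelamina_center_thickness, tc, rel_tol=1e-9, abs_tol=1e-12):
                raise PhantomParameterError(
                    "prelamina_center_thickness inconsistent with lc_depth - cup_depth")
        object.__setattr__(self, "prelamina_center_thickness", tc)
        if self.prelamina_thickness_profile is None:
            object.__setattr__(self, "prelamina_thickness_profile", _uniform_profile(tc))
        else:
            prof = self.prelamina_thickness_profile
            missing = [r for r in REGIONS if r not in prof]
            if missing:
                raise PhantomParameterError(
                    f"prelamina_thickness_profile missing regions {missing}")
            if any(prof[r] <= 0 for r in REGIONS):
                raise PhantomParameterError(
                    "prelamina_thickness_profile values must be > 0")

    # -- generating functions (canonical, untilted frame) -----------------

    def _h(self, theta):
        """Rim ILM height above the plane at the opening edge."""
        return trig_interp(profile_to_angle_order(self.rim_height_profile), theta)

    def _t(self, theta):
        """Vertical ILM to NFL-posterior separation outside the opening."""
        return trig_interp(profile_to_angle_order(self.pnfl_profile), theta)

    def _tmid(self, theta):
        """Prelamina thickness at the sector midpoints."""
        return trig_interp(profile_to_angle_order(self.prelamina_thickness_profile), theta)

    def ilm_z(self, r, theta):
        """ILM depth (z, positive posterior) as a generating function."""
        r = np.asarray(r, dtype=float)
        h = self._h(theta)
        R = self.bmo_radius
        inside = r < R
        s = (1.0 - np.cos(np.pi * np.clip(r / R, 0.0, 1.0))) / 2.0
        z_in = self.cup_depth + (-h - self.cup_depth) * s
        z_out = -h + self.rim_slope * (r - R)
        return np.where(inside, z_in, z_out)

    def nfl_posterior_z(self, r, theta):
        r = np.asarray(r, dtype=float)
        z = self.ilm_z(r, theta)
        return np.where(r < self.bmo_radius, z, z + self._t(theta))

    def bruchs_z(self, r, theta=None):
        r = np.asarray(r, dtype=float)
        return np.where(r >= self.bmo_radius, 0.0, np.nan)

    def prelamina_z(self, r, theta=None):
        r = np.asarray(r, dtype=float)
        u = r / self.bmo_radius
        dome = (1.0 + np.cos(np.pi * np.clip(u, 0.0, 1.0))) / 2.0
        return np.where(u <= 1.0, self.cup_depth * dome, np.nan)

    def thickness_field(self, r, theta):
        """Prelamina thickness T(u, theta) inside the opening."""
        u = np.asarray(r, dtype=float) / self.bmo_radius
        tc = self.prelamina_center_thickness
        return tc + (self._tmid(theta) - tc) * np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2

    def lc_z(self, r, theta):
        r = np.asarray(r, dtype=float)
        z = self.prelamina_z(r) + self.thickness_field(r, theta)
        return np.where(r / self.bmo_radius <= 1.0, z, np.nan)


@dataclass
class SurfaceSet:
    """Calibrated height-map representation of the five segmented surfaces.

    Height maps are indexed ``[iy, ix]`` over the regular lateral grid
    ``(x, y)`` (mm, origin near the BMO centre); ``nan`` marks undefined
    samples (e.g. inside the Bruch's membrane opening, outside the LC).
    ``bmo_terminations`` are labelled 3-D landmark points on the opening
    boundary.  ``z_positive_posterior`` records the axial convention.
    """

    x: np.ndarray
    y: np.ndarray
    ilm: np.ndarray
    nfl_posterior: np.ndarray
    bruchs: np.ndarray
    prelamina_anterior: np.ndarray
    anterior_lc: np.ndarray
    bmo_terminations: dict[str, np.ndarray]
    eye: str = "OD"
    z_positive_posterior: bool = True

    SURFACE_NAMES = ("ilm", "nfl_posterior", "bruchs", "prelamina_anterior", "anterior_lc")

    def surfaces(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.SURFACE_NAMES}

    def validate(self) -> None:
        ny, nx = len(self.y), len(self.x)
        for name, z in self.surfaces().items():
            if z.shape != (ny, nx):
                raise ValueError(f"surface {name} shape {z.shape} != grid ({ny}, {nx})")
        if len(self.bmo_terminations) < 6:
            raise ValueError("need at least 6 BMO termination landmarks")
        both = ~(np.isnan(self.ilm) | np.isnan(self.nfl_posterior))
        if np.any(self.nfl_posterior[both] < self.ilm[both] - 1e-9):
            raise ValueError("nfl_posterior anterior to ilm")
        both = ~(np.isnan(self.prelamina_anterior) | np.isnan(self.anterior_lc))
        if np.any(self.anterior_lc[both] < self.prelamina_anterior[both] - 1e-9):
            raise ValueError("anterior_lc anterior to prelamina_anterior")


def _tilt_heightmap(f, alpha: float, x: np.ndarray, y: np.ndarray,
                    domain=None, n_iter: int = 60) -> np.ndarray:
    """Exact height map of a surface zeta = f(xi, eta) rotated about y.

    The rotation maps canonical coordinates (xi, eta, zeta) to world
    (x, y, z) via x = xi cos a + zeta sin a, z = -xi sin a + zeta cos a.
    The pre-image xi of each grid column is found by fixed-point
    iteration (a contraction for the small tilts allowed here).

    ``f`` must be total (defined for all r); surfaces with a bounded
    footprint pass ``domain(r) -> bool mask`` and are evaluated on a
    clamped extension, with samples outside the rotated footprint set to
    nan afterwards — this keeps the footprint boundary exact.
    """
    ca, sa = math.cos(alpha), math.sin(alpha)
    X, Y = np.meshgrid(x, y)
    if alpha == 0.0:
        r = np.hypot(X, Y)
        th = np.arctan2(Y, X)
        z = f(r, th)
        if domain is not None:
            z = np.where(domain(r), z, np.nan)
        return z
    xi = X / ca
    for _ in range(n_iter):
        r = np.hypot(xi, Y)
        th = np.arctan2(Y, xi)
        zeta = f(r, th)
        xi_new = (X - zeta * sa) / ca
        if np.max(np.abs(xi_new - xi)) < 1e-11:
            xi = xi_new
            break
        xi = xi_new
    r = np.hypot(xi, Y)
    th = np.arctan2(Y, xi)
    zeta = f(r, th)
    z = -xi * sa + zeta * ca
    if domain is not None:
        z = np.where(domain(r), z, np.nan)
    return z


def generate_surfaces(params: PhantomParams, seed: int) -> SurfaceSet:
    """Sample the phantom's generating functions onto a regular grid.

    Noise (if ``surface_noise_sd > 0``) is an independent Gaussian
    perturbation of each surface height sample; termination landmarks are
    exact.  Output is bit-reproducible for a fixed seed.
    """
    if not isinstance(params, PhantomParams):
        raise PhantomParameterError("params must be a PhantomParams")
    n = int(round(2 * params.half_width / params.grid_spacing)) + 1
    x = np.linspace(-params.half_width, params.half_width, n)
    y = x.copy()
    alpha = math.radians(params.bmo_plane_tilt)

    R = params.bmo_radius

    def prelamina_ext(r, th):
        u = np.clip(np.asarray(r, dtype=float) / R, 0.0, 1.0)
        return params.cup_depth * (1.0 + np.cos(np.pi * u)) / 2.0

    def lc_ext(r, th):
        return prelamina_ext(r, th) + params.thickness_field(np.clip(r, 0.0, R), th)

    maps = {
        "ilm": _tilt_heightmap(params.ilm_z, alpha, x, y),
        "nfl_posterior": _tilt_heightmap(params.nfl_posterior_z, alpha, x, y),
        "bruchs": _tilt_heightmap(lambda r, th: np.zeros_like(r), alpha, x, y,
                                  domain=lambda r: r >= R),
        "prelamina_anterior": _tilt_heightmap(prelamina_ext, alpha, x, y,
                                              domain=lambda r: r <= R),
        "anterior_lc": _tilt_heightmap(lc_ext, alpha, x, y,
                                       domain=lambda r: r <= R),
    }

    rng = np.random.default_rng(seed)
    if params.surface_noise_sd > 0:
        for name in SurfaceSet.SURFACE_NAMES:
            maps[name] = maps[name] + rng.normal(0.0, params.surface_noise_sd,
                                                 size=maps[name].shape)
    # enforce the anatomical ordering invariants where both surfaces are
    # defined: independent height noise can break them anywhere, and the
    # tilt inversion can by a few ulp at the opening-boundary discontinuity
    # of the NFL posterior map (nan footprints must be preserved)
    def _clamp(post: np.ndarray, ant: np.ndarray) -> np.ndarray:
        both = ~(np.isnan(post) | np.isnan(ant))
        out = post.copy()
        out[both] = np.maximum(post[both], ant[both])
        return out

    maps["nfl_posterior"] = _clamp(maps["nfl_posterior"], maps["ilm"])
    maps["anterior_lc"] = _clamp(maps["anterior_lc"], maps["prelamina_anterior"])

    ca, sa = math.cos(alpha), math.sin(alpha)
    terminations: dict[str, np.ndarray] = {}
    R = params.bmo_radius
    for region in REGIONS:
        th = region_angle(region, "OD")
        xi, eta = R * math.cos(th), R * math.sin(th)
        terminations[region] = np.array([xi * ca, eta, -xi * sa])

    ss = SurfaceSet(x=x, y=y, bmo_terminations=terminations, eye="OD", **maps)
    ss.validate()
    return ss


# ---------------------------------------------------------------------------
# Analytic ground truth
# ---------------------------------------------------------------------------

def _mrw_truth(params: PhantomParams, theta: float,
               n_dense: int = 2001) -> tuple[float, float]:
    """Minimum termination-to-ILM distance and its foot radius.

    Computed from the generating function by dense evaluation of the
    squared distance plus parabolic vertex refinement; for
    ``rim_slope = m >= 0`` this reproduces the closed form
    ``h / sqrt(1 + m^2)`` attained at ``r = R + m h / (1 + m^2)``.
    """
    R = params.bmo_radius
    r = np.linspace(0.0, params.half_width, n_dense)
    z = params.ilm_z(r, theta)
    d2 = (r - R) ** 2 + z ** 2
    i = int(np.argmin(d2))
    if 0 < i < n_dense - 1:
        # parabola through the three bracketing samples of the smooth d^2
        y0, y1, y2 = d2[i - 1], d2[i], d2[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            step = r[1] - r[0]
            r_star = r[i] + delta * step
            z_star = float(params.ilm_z(np.array([r_star]), theta)[0])
            d2_star = (r_star - R) ** 2 + z_star ** 2
            if d2_star <= d2[i]:
                return math.sqrt(d2_star), float(r_star)
    return math.sqrt(d2[i]), float(r[i])


def mrw_truth_dense(params: PhantomParams, theta: float,
                    spacing: float = 1e-4) -> float:
    """Brute-force minimum distance at fixed sample ``spacing`` (mm).

    Independent slow oracle for :func:`analytic_truth`'s rim values.
    """
    R = params.bmo_radius
    n = int(params.half_width / spacing) + 1
    r = np.linspace(0.0, params.half_width, n)
    z = params.ilm_z(r, theta)
    return float(np.sqrt(np.min((r - R) ** 2 + z ** 2)))


def analytic_truth(params: PhantomParams) -> ONHParameters:
    """Closed-form regional values for all six parameter families.

    Values are computed from the generating functions, never from sampled
    surfaces.  Plane tilt does not enter: all quantities are defined
    relative to the BMO reference plane and are rotation invariant.
    """
    if not isinstance(params, PhantomParams):
        raise PhantomParameterError("params must be a PhantomParams")
    m = params.rim_slope
    slope_factor = 1.0 / math.sqrt(1.0 + m * m)
    thetas = np.array([region_angle(region, "OD") for region in REGIONS])
    h_arr = params._h(thetas)
    t_arr = params._t(thetas) * slope_factor
    tm_arr = params._tmid(thetas)

    # minimum rim width: dense distance evaluation over all 8 meridians at
    # once, then per-meridian parabolic vertex refinement
    R = params.bmo_radius
    n_dense = 2001
    r = np.linspace(0.0, params.half_width, n_dense)
    z = params.ilm_z(r[None, :], thetas[:, None])
    d2 = (r[None, :] - R) ** 2 + z ** 2
    idx = np.argmin(d2, axis=1)
    w_arr = np.sqrt(d2[np.arange(8), idx])
    foot_arr = r[idx]
    interior = (idx > 0) & (idx < n_dense - 1)
    if interior.any():
        i = idx[interior]
        rows = np.arange(8)[interior]
        y0, y1, y2 = d2[rows, i - 1], d2[rows, i], d2[rows, i + 1]
        denom = y0 - 2.0 * y1 + y2
        ok = denom > 0
        delta = np.where(ok, 0.5 * (y0 - y2) / np.where(ok, denom, 1.0), 0.0)
        r_star = r[i] + delta * (r[1] - r[0])
        z_star = params.ilm_z(r_star, thetas[rows])
        d2_star = (r_star - R) ** 2 + z_star ** 2
        better = d2_star <= d2[rows, i]
        w_arr[rows[better]] = np.sqrt(d2_star[better])
        foot_arr[rows[better]] = r_star[better]

    bnfl, pnfl, mrw, mra, plt = {}, {}, {}, {}, {}
    for k, region in enumerate(REGIONS):
        bnfl[region] = float(h_arr[k])
        pnfl[region] = float(t_arr[k])
        mrw[region] = float(w_arr[k])
        mra[region] = (math.pi / 4.0) * 0.5 * (R + float(foot_arr[k])) * float(w_arr[k])
        plt[region] = float(tm_arr[k])
    plt["centre"] = params.prelamina_center_thickness

    # Prelamina volume: integral of the thickness field over the opening.
    # With T = Tc + (Tmid(theta) - Tc) sin^2(pi u) and int_0^1 u sin^2(pi u) du
    # = 1/4, V = pi R^2 [Tc + (mean_theta(Tmid) - Tc)/2]; the circular mean of
    # the band-limited profile is the arithmetic mean of the 8 targets.
    tc = params.prelamina_center_thickness
    tmid_mean = float(np.mean(profile_to_angle_order(params.prelamina_thickness_profile)))
    plv = math.pi * params.bmo_radius ** 2 * (tc + 0.5 * (tmid_mean - tc))

    return ONHParameters(bnfl=bnfl, pnfl=pnfl, mrw=mrw, mra=mra, plt=plt, plv=plv)


def prelamina_volume_quadrature(params: PhantomParams, rtol: float = 1e-6) -> float:
    """Adaptive-quadrature prelamina volume from the generating functions.

    Independent of :func:`analytic_truth`'s closed form; integrates
    LC depth minus clamped prelamina depth over the opening disc.
    """
    from scipy.integrate import quad

    R = params.bmo_radius

    def radial(theta: float) -> float:
        val, _ = quad(
            lambda r: (float(params.lc_z(np.array([r]), theta)[0])
                       - max(float(params.prelamina_z(np.array([r]))[0]), 0.0)) * r,
            0.0, R, epsrel=rtol, limit=200)
        return val

    val, _ = quad(radial, 0.0, 2.0 * math.pi, epsrel=rtol, limit=200)
    return val


def mirror_to_os(ss: SurfaceSet) -> SurfaceSet:
    """Mirror a right-eye SurfaceSet nasal-temporal into a left eye.

    Anatomical content is unchanged: region-labelled landmarks keep their
    labels, and downstream region labelling uses the OS angle convention.
    """
    if ss.eye != "OD":
        raise ValueError("expected an OD surface set")
    maps = {name: z[:, ::-1].copy() for name, z in ss.surfaces().items()}
    terms = {}
    for region, p in ss.bmo_terminations.items():
        q = p.copy()
        q[0] = -q[0]
        terms[region] = q
    return SurfaceSet(x=ss.x.copy(), y=ss.y.copy(), bmo_terminations=terms,
                      eye="OS", z_positive_posterior=ss.z_positive_posterior, **maps)


def rolled_params(params: PhantomParams, k: int = 1) -> PhantomParams:
    """Phantom with all angular profiles rotated by k*45 degrees.

    Equivalent to a rigid in-plane rotation of the geometry; used by the
    rotation-relabelling invariance checks.
    """
    def roll(profile: dict[str, float]) -> dict[str, float]:
        by_angle = profile_to_angle_order(profile)
        rolled = np.roll(by_angle, k)
        out = {}
        for r in REGIONS:
            from .regions import angle_index
            out[r] = float(rolled[angle_index(r)])
        return out

    return replace(params,
                   rim_height_profile=roll(params.rim_height_profile),
                   pnfl_profile=roll(params.pnfl_profile),
                   prelamina_thickness_profile=roll(params.prelamina_thickness_profile),
                   prelamina_center_thickness=None)
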