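"""Readers/writers for the pipeline's on-disk formats.

All coordinates on disk are in millimetres with the unit tagged in the
column header (``x_mm``/``y_mm``/``z_mm``); micrometre columns
(``x_um`` ...) are accepted and converted on load.  Missing values are
empty cells, never 0 (0 is a legal thickness).  Schema violations
raise :class:`SurfaceIOError` naming the file and row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSpec
from .cohort import CohortSpec
from .phantom import PhantomParams, SurfaceSet

_FLOAT_FMT = "%.10g"


class SurfaceIOError(ValueError):
    """Malformed surface/landmark/cohort file (carries file and row)."""


def _read_xyz_csv(path: Path) -> pd.DataFrame:
    """Read a coordinate CSV with unit-tagged headers into mm columns."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=True,
                         na_values=[""], comment="#")
    except Exception as exc:
        raise SurfaceIOError(f"{path}: unreadable CSV ({exc})") from exc
    rename = {}
    scale = {}
    for axis in ("x", "y", "z"):
        if f"{axis}_mm" in df.columns:
            rename[f"{axis}_mm"] = axis
            scale[axis] = 1.0
        elif f"{axis}_um" in df.columns:
            rename[f"{axis}_um"] = axis
            scale[axis] = 1e-3
        else:
            raise SurfaceIOError(
                f"{path}: missing column {axis}_mm (or {axis}_um)")
    df = df.rename(columns=rename)
    for axis in ("x", "y", "z"):
        raw = df[axis]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SurfaceIOError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{axis}, data row {row + 1}")
        df[axis] = vals * scale[axis]
    return df


def write_surface_set(ss: SurfaceSet, directory: str | Path) -> list[Path]:
    """One long-format CSV per surface plus a landmarks CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    X, Y = np.meshgrid(ss.x, ss.y)
    for name, Z in ss.surfaces().items():
        path = directory / f"{name}.csv"
        pd.DataFrame({"x_mm": X.ravel(), "y_mm": Y.ravel(), "z_mm": Z.ravel()}
                     ).to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
        written.append(path)
    lm = pd.DataFrame(
        [{"label": k, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
         for k, p in ss.bmo_terminations.items()])
    lm_path = directory / "landmarks.csv"
    lm.to_csv(lm_path, index=False, float_format=_FLOAT_FMT)
    written.append(lm_path)
    meta = {"eye": ss.eye, "z_positive_posterior": ss.z_positive_posterior}
    meta_path = directory / "surfaceset.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    written.append(meta_path)
    return written


def read_surface_set(directory: str | Path) -> SurfaceSet:
    """Load a SurfaceSet written by :func:`write_surface_set`."""
    directory = Path(directory)
    meta_path = directory / "surfaceset.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    maps = {}
    x = y = None
    for name in SurfaceSet.SURFACE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SurfaceIOError(f"{path}: missing surface file")
        df = _read_xyz_csv(path)
        xu = np.unique(df["x"].to_numpy())
        yu = np.unique(df["y"].to_numpy())
        if len(xu) * len(yu) != len(df):
            raise SurfaceIOError(f"{path}: samples do not form a regular grid")
        if x is None:
            x, y = xu, yu
        elif not (len(xu) == len(x) and len(yu) == len(y)
                  and np.allclose(xu, x, atol=1e-9)
                  and np.allclose(yu, y, atol=1e-9)):
            raise SurfaceIOError(f"{path}: grid differs from other surfaces")
        z = (df.sort_values(["y", "x"])["z"].to_numpy()
             .reshape(len(yu), len(xu)))
        maps[name] = z
    lm = _read_xyz_csv(directory / "landmarks.csv")
    labels = pd.read_csv(directory / "landmarks.csv", comment="#")["label"]
    terms = {str(lab): np.array([r["x"], r["y"], r["z"]])
             for lab, (_, r) in zip(labels, lm.iterrows())}
    if len(terms) < 6:
        raise SurfaceIOError(
            f"{directory / 'landmarks.csv'}: only {len(terms)} termination "
            "landmarks; the BMO reference plane needs at least 6")
    ss = SurfaceSet(x=x, y=y, bmo_terminations=terms,
                    eye=meta.get("eye", "OD"),
                    z_positive_posterior=meta.get("z_positive_posterior", True),
                    **maps)
    ss.validate()
    return ss


# -- cohort / parameter tables ---------------------------------------------

def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise SurfaceIOError(f"{path}: unreadable cohort CSV ({exc})") from exc


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Full configuration of a simulate -> measure -> analyze run."""

    seed: int = 0
    outdir: str = "onhmorph_out"
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    responses: tuple[str, ...] = ("bnfl_mean", "pnfl_mean", "mrw_mean",
                                  "mra_mean", "plt_centre", "plv")
    measure_surfaces: bool = True
    pnfl_radius_mm: float = 1.7
    alpha: float = 0.05


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (missing keys default)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    if "responses" in raw:
        cfg.responses = tuple(raw["responses"])
    if "measure_surfaces" in raw:
        cfg.measure_surfaces = bool(raw["measure_surfaces"])
    if "pnfl_radius_mm" in raw:
        cfg.pnfl_radius_mm = float(raw["pnfl_radius_mm"])
    if "alpha" in raw:
        cfg.alpha = float(raw["alpha"])
    if "calibration" in raw:
        cfg.calibration = CalibrationSpec(**raw["calibration"])
    if "cohort" in raw:
        c = dict(raw["cohort"])
        if "base_params" in c:
            bp = dict(c.pop("base_params"))
            cfg.cohort = CohortSpec(base_params=PhantomParams(**bp), **c)
        else:
            cfg.cohort = CohortSpec(**c)
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "seed": cfg.seed,
        "outdir": cfg.outdir,
        "responses": list(cfg.responses),
        "measure_surfaces": cfg.measure_surfaces,
        "pnfl_radius_mm": cfg.pnfl_radius_mm,
        "alpha": cfg.alpha,
        "calibration": asdict(cfg.calibration),
        "cohort": {
            "n_per_stage": cfg.cohort.n_per_stage,
            "inter_eye_sd": cfg.cohort.inter_eye_sd,
            "residual_sd": cfg.cohort.residual_sd,
            "missing_eye_prob": cfg.cohort.missing_eye_prob,
            "seed": cfg.cohort.seed,
        },
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


# -- manifest ---------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[Path], out: str | Path,
                   root: str | Path | None = None) -> Path:
    """JSON manifest of output files with content hashes (deterministic)."""
    out = Path(out)
    root = Path(root) if root else out.parent
    entries = {}
    for p in sorted(Path(p) for p in paths):
        key = str(p.relative_to(root)) if p.is_relative_to(root) else str(p)
        entries[key] = sha256_file(p)
    out.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return out


# -- optional voxel export ---------------------------------------------------

def export_voxel_tiff(ss: SurfaceSet, path: str | Path,
                      axial_pitch_mm: float = 0.01) -> Path:
    """Rasterise a SurfaceSet into a labelled multi-page 16-bit TIFF.

    Labels: 1 = NFL (ILM to NFL posterior), 2 = prelamina (prelamina
    anterior to anterior LC), 3 = Bruch's membrane.  A JSON sidecar
    records the voxel pitch.  Demo export only; the measurements act on
    surfaces, not voxels.
    """
    import tifffile

    path = Path(path)
    zs = [z for z in ss.surfaces().values()]
    zmin = np.nanmin([np.nanmin(z) for z in zs]) - 2 * axial_pitch_mm
    zmax = np.nanmax([np.nanmax(z) for z in zs]) + 2 * axial_pitch_mm
    nz = int(np.ceil((zmax - zmin) / axial_pitch_mm)) + 1
    zaxis = zmin + axial_pitch_mm * np.arange(nz)
    vol = np.zeros((nz, len(ss.y), len(ss.x)), dtype=np.uint16)
    Z = zaxis[:, None, None]
    with np.errstate(invalid="ignore"):
        nfl = (Z >= ss.ilm[None]) & (Z <= ss.nfl_posterior[None])
        pre = (Z >= ss.prelamina_anterior[None]) & (Z <= ss.anterior_lc[None])
        bm = np.abs(Z - ss.bruchs[None]) <= axial_pitch_mm / 2
    vol[nfl] = 1
    vol[pre] = 2
    vol[bm] = 3
    tifffile.imwrite(path, vol, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "voxel_pitch_mm": [axial_pitch_mm,
                           float(ss.y[1] - ss.y[0]), float(ss.x[1] - ss.x[0])],
        "z0_mm": float(zmin), "axes": "zyx",
        "labels": {"1": "nfl", "2": "prelamina", "3": "bruchs"},
    }, indent=1))
    return path
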