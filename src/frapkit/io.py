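"""Delimited-text readers/writers, config handling and fixture generation.

All artefacts are plain text.  Recovery curves are CSV with columns
``time_s, fluorescence[, sigma]``; spatial fields are a matrix with a
header row of radii and a first column of times (the observable total
fluorescence ``w``; optional ``.u``/``.v`` companion files carry the
species split).  Config files are flat YAML mappings whose keys name the
fields of the corresponding dataclass exactly; unknown keys are errors.
Every writer prepends ``#`` comment lines carrying the seed and a config
digest so outputs are reproducible from their own headers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .core import PhysicalParams
from .simulate import (ExperimentDesign, RadialGrid, RecoveryCurve,
                       SampleSpec, SpatialField, sample_parameters,
                       simulate_frap, recovery_from_spatial)

__all__ = [
    "read_recovery_curve",
    "write_recovery_curve",
    "read_spatial_field",
    "write_spatial_field",
    "load_params",
    "load_design",
    "load_sample_spec",
    "dump_yaml",
    "config_digest",
    "make_fixtures",
]

PathLike = Union[str, Path]


def config_digest(obj) -> str:
    """Short stable digest of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed=None, meta: Optional[dict] = None):
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    if meta is not None:
        lines.append(f"# config_digest={config_digest(meta)}")
    return lines


# --------------------------------------------------------------------------
# recovery curves
# --------------------------------------------------------------------------

def write_recovery_curve(curve: RecoveryCurve, path: PathLike, seed=None,
                         meta: Optional[dict] = None) -> None:
    path = Path(path)
    cols = ["time_s", "fluorescence"]
    data = [curve.times, curve.values]
    if curve.sigmas is not None:
        cols.append("sigma")
        data.append(curve.sigmas)
    with path.open("w") as fh:
        for line in _header_lines(seed, meta):
            fh.write(line + "\n")
        fh.write(",".join(cols) + "\n")
        for row in zip(*data):
            fh.write(",".join(format(x, ".17g") for x in row) + "\n")


def read_recovery_curve(path: PathLike) -> RecoveryCurve:
    """Parse a recovery-curve CSV, validating monotone times."""
    path = Path(path)
    header = None
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:2] != ["time_s", "fluorescence"] or \
                        header not in (["time_s", "fluorescence"],
                                       ["time_s", "fluorescence", "sigma"]):
                    raise ValueError(
                        f"{path}:{lineno}: expected columns "
                        f"time_s,fluorescence[,sigma], got {header}")
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(header)} cells, got {len(cells)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell "
                                 f"({exc})") from None
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    t = arr[:, 0]
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(f"{path}: times not strictly increasing at data "
                         f"row {bad[0] + 2}")
    sig = arr[:, 2] if len(header) == 3 else None
    return RecoveryCurve(times=t, values=arr[:, 1], sigmas=sig)


# --------------------------------------------------------------------------
# spatial fields
# --------------------------------------------------------------------------

def write_spatial_field(fld: SpatialField, path: PathLike, seed=None,
                        meta: Optional[dict] = None,
                        companions: bool = False) -> None:
    """Write the total-fluorescence matrix; optional .u/.v companions."""
    path = Path(path)

    def _write(matrix, p):
        with Path(p).open("w") as fh:
            for line in _header_lines(seed, meta):
                fh.write(line + "\n")
            fh.write("time_s," + ",".join(
                format(r, ".17g") for r in fld.grid.r) + "\n")
            for t, row in zip(fld.times, matrix):
                fh.write(format(t, ".17g") + "," + ",".join(
                    format(x, ".17g") for x in row) + "\n")

    _write(fld.w, path)
    if companions:
        _write(fld.u, path.with_suffix(path.suffix + ".u"))
        _write(fld.v, path.with_suffix(path.suffix + ".v"))


def _read_matrix(path: Path):
    header = None
    times, rows = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split(",")
            if header is None:
                if cells[0].strip() != "time_s":
                    raise ValueError(f"{path}:{lineno}: header must start "
                                     "with time_s")
                try:
                    header = np.array([float(c) for c in cells[1:]])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric radius") from None
                continue
            if len(cells) != len(header) + 1:
                raise ValueError(f"{path}:{lineno}: ragged row "
                                 f"({len(cells)} cells, expected "
                                 f"{len(header) + 1})")
            try:
                vals = [float(c) for c in cells]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell "
                                 f"({exc})") from None
            times.append(vals[0])
            rows.append(vals[1:])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    return header, np.array(times), np.array(rows)


def read_spatial_field(path: PathLike) -> SpatialField:
    """Read a spatial-field matrix (and species companions if present).

    Without companions the species split is unobservable; ``u`` is set to
    the total fluorescence and ``v`` to zero, which is all the spatial
    objective needs (it compares ``w`` only).
    """
    path = Path(path)
    radii, times, w = _read_matrix(path)
    dr = np.diff(radii)
    if len(radii) < 3 or radii[0] != 0.0 or np.any(
            np.abs(dr - dr[0]) > 1e-9 * max(dr[0], 1e-30)):
        raise ValueError(f"{path}: radial header must be uniform from 0")
    grid = RadialGrid(r=radii, dr=float(dr[0]))
    u_path = path.with_suffix(path.suffix + ".u")
    v_path = path.with_suffix(path.suffix + ".v")
    if u_path.exists() and v_path.exists():
        _, _, u = _read_matrix(u_path)
        _, _, v = _read_matrix(v_path)
    else:
        u, v = w, np.zeros_like(w)
    return SpatialField(times=times, grid=grid, u=u, v=v)


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

def _load_yaml(path: PathLike) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_params(path: PathLike) -> PhysicalParams:
    return PhysicalParams.from_dict(_load_yaml(path))


def load_design(path: PathLike) -> ExperimentDesign:
    return ExperimentDesign.from_dict(_load_yaml(path))


def load_sample_spec(path: PathLike) -> SampleSpec:
    data = _load_yaml(path)
    known = set(SampleSpec.__dataclass_fields__)
    extra = set(data) - known
    if extra:
        raise KeyError(f"unknown sample-spec keys: {sorted(extra)}")
    for key in ("eta_log_range", "kappa_log4_range", "kappa_log10_range",
                "delta_range"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SampleSpec(**data)


def dump_yaml(obj: dict, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

FIXTURE_REGIMES = {
    # regime name -> sampling windows (log10 eta, log10 kappa)
    "RE": {"eta_log_range": (1.7, 3.0)},
    "I": {"eta_log_range": (0.4, 1.7)},
    "SE": {"eta_log_range": (-3.0, -1.0)},
    "U": {"eta_log_range": (1.7, 3.0), "kappa_log10_range": (0.53, 1.5)},
    "V": {"eta_log_range": (1.7, 3.0), "kappa_log10_range": (-2.0, -0.9)},
}


def make_fixtures(seed: int, outdir: PathLike,
                  design: Optional[ExperimentDesign] = None) -> dict:
    """One canonical synthetic dataset per regime, truths recorded.

    For each of RE, I, SE, U and V: draw a parameter set in the regime's
    window, simulate the experiment, and write the recovery curve, the
    spatial field and a YAML truth file.  Deterministic in ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design or ExperimentDesign()
    seeds = np.random.SeedSequence(seed).spawn(len(FIXTURE_REGIMES))
    manifest = {}
    for (name, window), child in zip(FIXTURE_REGIMES.items(), seeds):
        spec = SampleSpec(**window, seed=seed)
        truth = sample_parameters(spec, design.r_n,
                                  rng=np.random.default_rng(child))
        fld = simulate_frap(truth, design)
        curve = recovery_from_spatial(fld, design.r_n)
        meta = {"regime": name, "truth": truth.to_dict(),
                "design": design.to_dict()}
        write_recovery_curve(curve, outdir / f"{name}_curve.csv", seed=seed,
                             meta=meta)
        write_spatial_field(fld, outdir / f"{name}_field.csv", seed=seed,
                            meta=meta)
        dump_yaml(meta, outdir / f"{name}_truth.yaml")
        manifest[name] = meta
    dump_yaml({"seed": seed, "regimes": sorted(FIXTURE_REGIMES)},
              outdir / "manifest.yaml")
    return manifest
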