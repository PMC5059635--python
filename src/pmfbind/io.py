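"""File formats: umbrella metadata, trajectories, PMF tables, reports, config.

Trajectory files are plain text with one reaction-coordinate sample (angstrom)
per line; an optional leading integer index column is auto-detected on read.
The metadata file is the de facto dialect of 1-D WHAM programs: whitespace
separated ``trajectory-path  centre(A)  force-constant(kcal/mol/A^2)`` lines
with ``#`` comments. PMFs travel as TSV with ``#`` header metadata sufficient
to re-run the producing stage.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .umbrella import TimeSeries, WindowSpec
from .wham import PMFProfile

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_metadata", "read_metadata",
    "write_umbrella_dataset", "read_umbrella_dataset",
    "write_pmf_tsv", "read_pmf_tsv",
    "write_binding_report",
    "RunConfig", "file_sha256",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Trajectories and metadata
# ---------------------------------------------------------------------------

def write_trajectory(path: PathLike, series: TimeSeries,
                     with_index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if with_index:
            for i, z in enumerate(series.samples):
                fh.write(f"{i}\t{z:.8f}\n")
        else:
            for z in series.samples:
                fh.write(f"{z:.8f}\n")


def read_trajectory(path: PathLike) -> np.ndarray:
    """Read one z sample per line; a leading index column is auto-detected."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] == 1:
        return data[:, 0]
    return data[:, 1]


def write_metadata(path: PathLike, windows: Sequence[WindowSpec]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# trajectory-path  centre(A)  force-constant(kcal/mol/A^2)\n")
        for w in windows:
            if w.trajectory_path is None:
                raise ValueError(
                    f"window at {w.centre:g} A has no trajectory path to record"
                )
            fh.write(f"{w.trajectory_path}\t{w.centre:.6f}\t{w.force_constant:.6f}\n")


def read_metadata(path: PathLike) -> List[WindowSpec]:
    path = Path(path)
    windows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{ln}: expected 'path centre force-constant', got {raw!r}"
            )
        windows.append(WindowSpec(centre=float(parts[1]),
                                  force_constant=float(parts[2]),
                                  trajectory_path=parts[0]))
    if not windows:
        raise ValueError(f"{path}: no windows found")
    return windows


def write_umbrella_dataset(out_dir: PathLike, series: Sequence[TimeSeries],
                           metadata_name: str = "metadata.txt") -> Path:
    """Write all trajectories plus the metadata file; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = []
    for i, s in enumerate(series):
        name = f"window_{i:03d}.traj"
        write_trajectory(out_dir / name, s)
        windows.append(WindowSpec(centre=s.window.centre,
                                  force_constant=s.window.force_constant,
                                  trajectory_path=name))
    meta = out_dir / metadata_name
    write_metadata(meta, windows)
    return meta


def read_umbrella_dataset(metadata_path: PathLike) -> List[TimeSeries]:
    """Load every window trajectory listed in a metadata file.

    Relative trajectory paths are resolved against the metadata file's
    directory. A missing trajectory is reported with its metadata line.
    """
    metadata_path = Path(metadata_path)
    base = metadata_path.parent
    series = []
    for i, w in enumerate(read_metadata(metadata_path), start=1):
        traj = Path(w.trajectory_path)
        if not traj.is_absolute():
            traj = base / traj
        if not traj.exists():
            raise FileNotFoundError(
                f"trajectory {traj} (metadata entry {i} of {metadata_path}) "
                "does not exist"
            )
        samples = read_trajectory(traj)
        series.append(TimeSeries(samples=samples, window=w, seed=-1))
    return series


# ---------------------------------------------------------------------------
# PMF TSV
# ---------------------------------------------------------------------------

def write_pmf_tsv(path: PathLike, pmf: PMFProfile,
                  extra_header: Optional[Dict[str, str]] = None) -> None:
    path = Path(path)
    header = {
        "temperature_K": f"{pmf.temperature:g}",
        "bin_width_A": f"{pmf.bin_width:g}" if pmf.bin_width else "unknown",
        "offset_convention": pmf.offset,
        "bulk_range_A": (f"{pmf.bulk_range[0]:g},{pmf.bulk_range[1]:g}"
                         if pmf.bulk_range else "none"),
    }
    if extra_header:
        header.update(extra_header)
    with path.open("w") as fh:
        for k, v in header.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# z_A\tw_kcal_per_mol\tstderr_kcal_per_mol\tn\n")
        stderr = pmf.stderr if pmf.stderr is not None else np.full_like(pmf.w, np.nan)
        counts = pmf.counts if pmf.counts is not None else np.zeros_like(pmf.w)
        for z, w, e, n in zip(pmf.z, pmf.w, stderr, counts):
            fh.write(f"{z:.6f}\t{w:.8f}\t{e:.8f}\t{int(n)}\n")


def read_pmf_tsv(path: PathLike) -> PMFProfile:
    path = Path(path)
    header: Dict[str, str] = {}
    rows = []
    for raw in path.read_text().splitlines():
        if raw.startswith("#"):
            if "=" in raw:
                k, v = raw.lstrip("# ").split("=", 1)
                header[k.strip()] = v.strip()
            continue
        if raw.strip():
            rows.append([float(x) for x in raw.split()])
    if not rows:
        raise ValueError(f"{path}: no PMF rows")
    arr = np.asarray(rows)
    stderr = arr[:, 2] if arr.shape[1] > 2 else None
    if stderr is not None and np.all(np.isnan(stderr)):
        stderr = None
    counts = arr[:, 3] if arr.shape[1] > 3 else None
    bulk = None
    if header.get("bulk_range_A", "none") != "none":
        lo, hi = header["bulk_range_A"].split(",")
        bulk = (float(lo), float(hi))
    return PMFProfile(
        z=arr[:, 0], w=arr[:, 1], stderr=stderr, counts=counts,
        temperature=float(header.get("temperature_K", "310.15")),
        offset=header.get("offset_convention", "raw"),
        bulk_range=bulk,
    )


# ---------------------------------------------------------------------------
# Binding report
# ---------------------------------------------------------------------------

def write_binding_report(path: PathLike, result) -> None:
    """TSV key-value binding report plus the human-readable summary."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# effective 1-D binding estimate under a cylindrical restraint\n")
        rows = {
            "label": result.label or "-",
            "kd_M": f"{result.kd:.6e}",
            "kd_display": format_display(result.kd),
            "dg_kcal_per_mol": f"{result.dg:.4f}",
            "stderr_dg_kcal_per_mol": (f"{result.stderr_dg:.4f}"
                                       if result.stderr_dg is not None else "NA"),
            "site_lo_A": f"{result.site_bounds[0]:g}",
            "site_hi_A": f"{result.site_bounds[1]:g}",
            "provenance": result.provenance or "-",
        }
        rows.update({k: f"{v:g}" for k, v in result.params.as_dict().items()})
        for k, v in rows.items():
            fh.write(f"{k}\t{v}\n")
        fh.write("\n")
        for line in result.summary().splitlines():
            fh.write(f"# {line}\n")


def format_display(kd: float) -> str:
    from .binding import format_kd

    return format_kd(kd)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Flat key=value run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: Dict[str, Tuple[type, object]] = {
    # window layout
    "z_min": (float, -49.5),
    "z_max": (float, -7.5),
    "spacing": (float, 0.5),
    "force_constant": (float, 10.0),
    # sampler
    "potential": (str, "open-like"),
    "n_steps": (int, 220_000),
    "dt": (float, 0.01),
    "diffusion": (float, 1.0),
    "scheme": (str, "metropolis"),
    "bias_convention": (str, "half-k"),
    # histogram / WHAM
    "bin_width": (float, 0.1),
    "burn_in_fraction": (float, 2.0 / 22.0),
    "tolerance": (float, 1e-7),
    "max_iter": (int, 100_000),
    "anderson": (bool, True),
    # thermodynamics
    "temperature": (float, 310.15),
    "cylinder_radius": (float, 10.0),
    "site_lo": (float, float("nan")),  # NaN = use the automatic site rule
    "site_hi": (float, float("nan")),
    "bulk_lo": (float, float("nan")),  # NaN = use the potential's bulk range
    "bulk_hi": (float, float("nan")),
    "n_boot": (int, 0),  # 0 = skip bootstrap uncertainties
    # run control
    "seed": (int, 0),
}


class RunConfig:
    """Flat key=value configuration with a fixed schema.

    Unknown keys are rejected by name; every value is typed per the schema.
    The master ``seed`` deterministically derives per-window sampler seeds.
    """

    def __init__(self, **overrides):
        self._values = {k: default for k, (_, default) in _CONFIG_SCHEMA.items()}
        self.update(overrides)

    def update(self, overrides: Dict[str, object]) -> None:
        for key, val in overrides.items():
            if key not in _CONFIG_SCHEMA:
                raise KeyError(f"unknown configuration key {key!r}")
            typ, _ = _CONFIG_SCHEMA[key]
            if typ is bool and isinstance(val, str):
                val = val.strip().lower() in ("1", "true", "yes", "on")
            self._values[key] = typ(val)

    def __getattr__(self, key):
        try:
            return self._values[key]
        except KeyError:
            raise AttributeError(key) from None

    def __getitem__(self, key):
        return self._values[key]

    def as_dict(self) -> Dict[str, object]:
        return dict(self._values)

    @classmethod
    def from_file(cls, path: PathLike, **overrides) -> "RunConfig":
        cfg = cls()
        text_overrides: Dict[str, object] = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            text_overrides[key] = val
        cfg.update(text_overrides)
        cfg.update(overrides)
        return cfg

    def write(self, path: PathLike) -> None:
        with Path(path).open("w") as fh:
            for k, v in self._values.items():
                fh.write(f"{k} = {v}\n")

    def config_hash(self) -> str:
        text = "\n".join(f"{k}={v}" for k, v in sorted(self._values.items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]
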