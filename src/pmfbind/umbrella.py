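"""Umbrella-window layout and biased Brownian-dynamics sampling.

The sampler replaces molecular dynamics for the synthetic pipeline: for each
window i with harmonic bias U_i(z) it generates a Markov chain whose stationary
law is exactly the biased Boltzmann density

    p_i(z) \propto exp(-[u(z) + U_i(z)] / k_B T).

The default scheme is Metropolis-adjusted overdamped Langevin (MALA): an
Euler--Maruyama proposal followed by a Metropolis--Hastings accept/reject,
which removes the O(dt) discretisation bias of plain overdamped Langevin so
that downstream WHAM tests probe WHAM, not the integrator. Plain (uncorrected)
overdamped Langevin is available as ``scheme="overdamped-langevin"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE
from .potentials import TruePotential

__all__ = [
    "WindowSpec",
    "SamplerParams",
    "TimeSeries",
    "bias_energy",
    "make_window_layout",
    "sample_biased_trajectory",
    "sample_umbrella_windows",
    "derive_window_seeds",
]

#: Harmonic-bias conventions: "half-k" is U = (k/2)(z-z0)^2 (MD-engine
#: convention); "full-k" is U = k (z-z0)^2 (the dialect some WHAM tools use).
BIAS_CONVENTIONS = ("half-k", "full-k")


def bias_energy(z, centre: float, force_constant: float,
                convention: str = "half-k"):
    """Harmonic window bias in kcal/mol."""
    z = np.asarray(z, dtype=float)
    if convention == "half-k":
        return 0.5 * force_constant * (z - centre) ** 2
    if convention == "full-k":
        return force_constant * (z - centre) ** 2
    raise ValueError(f"unknown bias convention {convention!r}; use one of {BIAS_CONVENTIONS}")


@dataclass(frozen=True)
class WindowSpec:
    """One umbrella window: harmonic restraint centre and force constant."""

    centre: float  # angstrom
    force_constant: float  # kcal mol^-1 A^-2; 0 means an unbiased window
    trajectory_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")

    def bias(self, z, convention: str = "half-k"):
        return bias_energy(z, self.centre, self.force_constant, convention)


def make_window_layout(z_min: float, z_max: float, spacing: float,
                       force_constant: float = 10.0) -> List[WindowSpec]:
    """Evenly spaced window centres z_min, z_min+spacing, ..., z_max inclusive.

    The span (z_max - z_min) must be an integer multiple of the spacing to
    within 1e-9; otherwise the residual is reported in the error.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if z_max < z_min:
        raise ValueError("z_max must be >= z_min")
    span = z_max - z_min
    n_intervals = round(span / spacing)
    residual = abs(span - n_intervals * spacing)
    if residual > 1e-9:
        raise ValueError(
            f"window range ({z_min}, {z_max}) is not an integer multiple of "
            f"spacing {spacing}: residual {residual:.3g} A"
        )
    centres = z_min + spacing * np.arange(n_intervals + 1)
    return [WindowSpec(centre=float(c), force_constant=force_constant) for c in centres]


@dataclass(frozen=True)
class SamplerParams:
    """Brownian-dynamics sampler settings (reduced time units).

    ``n_steps`` defaults to 220 000 so that, with the default burn-in fraction
    of 2/22 discarded downstream, 200 000 samples per window survive --- the
    synthetic analogue of keeping the last 20 ns of a 22 ns window.
    """

    n_steps: int = 220_000
    dt: float = 0.01  # reduced time per step
    diffusion: float = 1.0  # A^2 per reduced time
    temperature: float = DEFAULT_TEMPERATURE  # K
    scheme: str = "metropolis"  # "metropolis" (MALA) or "overdamped-langevin"
    bias_convention: str = "half-k"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0 or self.diffusion <= 0 or self.temperature <= 0:
            raise ValueError("dt, diffusion and temperature must be > 0")
        if self.scheme not in ("metropolis", "overdamped-langevin"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.bias_convention not in BIAS_CONVENTIONS:
            raise ValueError(f"unknown bias convention {self.bias_convention!r}")

    @property
    def kt(self) -> float:
        return BOLTZMANN_KCAL * self.temperature


@dataclass
class TimeSeries:
    """Ordered samples of the reaction coordinate from one window."""

    samples: np.ndarray  # angstrom
    window: WindowSpec
    seed: int
    sample_interval: float = 1.0  # reduced time between stored samples
    acceptance_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.samples.size


def derive_window_seeds(master_seed: int, n_windows: int) -> List[int]:
    """Deterministically derive one sub-31-bit integer seed per window."""
    state = np.random.SeedSequence(master_seed).generate_state(n_windows, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _biased_start(potential: TruePotential, window: WindowSpec,
                  convention: str) -> float:
    """Deterministic start point: argmin of the biased potential near the
    window centre, located on a fine grid (0.001 A)."""
    lo = max(potential.domain[0], window.centre - 3.0)
    hi = min(potential.domain[1], window.centre + 3.0)
    grid = np.arange(lo, hi + 1e-12, 1e-3)
    e = potential(grid) + window.bias(grid, convention)
    return float(grid[int(np.argmin(e))])


def sample_umbrella_windows(potential: TruePotential,
                            windows: Sequence[WindowSpec],
                            params: SamplerParams,
                            seeds: Sequence[int]) -> List[TimeSeries]:
    """Sample all windows at once (vectorised over windows).

    Each window consumes randomness only from its own seeded generator, so the
    series for a given (window, seed, params) is identical whether the window
    is sampled alone or as part of a batch.
    """
    if len(seeds) != len(windows):
        raise ValueError("need exactly one seed per window")
    dom_lo, dom_hi = potential.domain
    for w in windows:
        if not (dom_lo <= w.centre <= dom_hi):
            raise ValueError(
                f"window centre {w.centre} A outside potential domain "
                f"[{dom_lo}, {dom_hi}] A"
            )
    n_win = len(windows)
    n_steps = params.n_steps
    kt = params.kt
    centres = np.array([w.centre for w in windows], dtype=float)
    ks = np.array([w.force_constant for w in windows], dtype=float)
    conv = params.bias_convention
    kfac = 0.5 if conv == "half-k" else 1.0

    # Per-window random streams, drawn up front (normals then uniforms), so
    # single-window and batched sampling agree bit for bit.
    normals = np.empty((n_steps, n_win))
    uniforms = np.empty((n_steps, n_win)) if params.scheme == "metropolis" else None
    for j, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed))
        normals[:, j] = rng.standard_normal(n_steps)
        if uniforms is not None:
            uniforms[:, j] = rng.random(n_steps)

    mobility = params.diffusion * params.dt / kt  # drift per unit force
    noise_scale = math.sqrt(2.0 * params.diffusion * params.dt)
    inv_4Ddt = 1.0 / (4.0 * params.diffusion * params.dt)

    def total_force(x):
        return potential.force(x) - 2.0 * kfac * ks * (x - centres)

    def total_energy(x):
        return potential(x) + kfac * ks * (x - centres) ** 2

    x = np.array([_biased_start(potential, w, conv) for w in windows])
    e_x = total_energy(x)
    f_x = total_force(x)
    out = np.empty((n_steps, n_win))
    n_accept = np.zeros(n_win)
    lo, hi = potential.domain

    # overflow during a diverging uncorrected-Langevin run is caught by the
    # domain check below, not surfaced as numpy warnings
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_steps):
            mean_fwd = x + mobility * f_x
            prop = mean_fwd + noise_scale * normals[t]
            if params.scheme == "overdamped-langevin":
                x = prop
                f_x = total_force(x)
            else:
                e_p = total_energy(prop)
                f_p = total_force(prop)
                mean_bwd = prop + mobility * f_p
                log_alpha = (
                    -(e_p - e_x) / kt
                    - ((x - mean_bwd) ** 2 - (prop - mean_fwd) ** 2) * inv_4Ddt
                )
                accept = np.log(uniforms[t]) < log_alpha
                x = np.where(accept, prop, x)
                e_x = np.where(accept, e_p, e_x)
                f_x = np.where(accept, f_p, f_x)
                n_accept += accept
            out[t] = x
            if t % 1000 == 0:
                bad_mask = (x < lo - 5.0) | (x > hi + 5.0) | ~np.isfinite(x)
                if np.any(bad_mask):
                    bad = int(np.argmax(bad_mask))
                    raise RuntimeError(
                        f"trajectory for window at {centres[bad]:g} A left the "
                        "potential domain by more than 5 A; reduce the sampler "
                        "step size dt"
                    )
    if np.any((out < lo - 5.0) | (out > hi + 5.0) | ~np.isfinite(out)):
        raise RuntimeError(
            "a trajectory left the potential domain by more than 5 A; "
            "reduce the sampler step size dt"
        )

    series = []
    for j, (w, seed) in enumerate(zip(windows, seeds)):
        acc = float(n_accept[j] / n_steps) if params.scheme == "metropolis" else None
        series.append(TimeSeries(samples=out[:, j].copy(), window=w,
                                 seed=int(seed), sample_interval=params.dt,
                                 acceptance_rate=acc))
    return series


def sample_biased_trajectory(potential: TruePotential, window: WindowSpec,
                             params: SamplerParams, seed: int) -> TimeSeries:
    """Sample a single umbrella window; see :func:`sample_umbrella_windows`."""
    return sample_umbrella_windows(potential, [window], params, [seed])[0]
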