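"""End-to-end synthetic pipeline: potential -> windows -> WHAM -> binding.

One :class:`~pmfbind.io.RunConfig` drives every stage; a single master seed
deterministically derives all per-window sampler seeds, so a full run is
byte-reproducible.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Sequence

from .binding import BindingResult, binding_result_from_pmf
from .constants import ThermoParams
from .io import RunConfig
from .potentials import TruePotential, preset_potential
from .umbrella import (SamplerParams, TimeSeries, derive_window_seeds,
                       make_window_layout, sample_umbrella_windows)
from .wham import (PMFProfile, UmbrellaWHAM, WHAMResults, build_histograms,
                   estimate_uncertainty)

__all__ = ["simulate_windows", "wham_from_series", "bind_from_pmf", "run_pipeline"]


def _potential_from_config(config: RunConfig) -> TruePotential:
    return preset_potential(config.potential)


def simulate_windows(config: RunConfig,
                     potential: Optional[TruePotential] = None) -> List[TimeSeries]:
    """Generate every window's biased trajectory from one config."""
    potential = potential or _potential_from_config(config)
    windows = make_window_layout(config.z_min, config.z_max, config.spacing,
                                 config.force_constant)
    seeds = derive_window_seeds(config.seed, len(windows))
    params = SamplerParams(n_steps=config.n_steps, dt=config.dt,
                           diffusion=config.diffusion,
                           temperature=config.temperature,
                           scheme=config.scheme,
                           bias_convention=config.bias_convention)
    return sample_umbrella_windows(potential, windows, params, seeds)


def _bulk_range(config: RunConfig, potential: Optional[TruePotential]):
    if not (math.isnan(config.bulk_lo) or math.isnan(config.bulk_hi)):
        return (config.bulk_lo, config.bulk_hi)
    if potential is not None and potential.bulk_range is not None:
        # clip the declared bulk plateau to the sampled window range
        lo = max(potential.bulk_range[0], min(config.z_min, config.z_max))
        hi = min(potential.bulk_range[1], max(config.z_min, config.z_max))
        if hi > lo:
            return (lo, hi)
    raise ValueError(
        "no bulk range available: set bulk_lo/bulk_hi in the config or use a "
        "potential with a declared bulk plateau"
    )


def wham_from_series(series: Sequence[TimeSeries], config: RunConfig,
                     potential: Optional[TruePotential] = None,
                     with_uncertainty: Optional[bool] = None) -> PMFProfile:
    """Histogram, solve WHAM, bulk-anchor, and (optionally) attach stderr."""
    hists = build_histograms(series, bin_width=config.bin_width,
                             burn_in_fraction=config.burn_in_fraction)
    model = UmbrellaWHAM(hists, temperature=config.temperature,
                         bias_convention=config.bias_convention)
    solution = model.fit(tolerance=config.tolerance, max_iter=config.max_iter,
                         anderson=config.anderson)
    bulk = _bulk_range(config, potential or _potential_from_config(config))
    if with_uncertainty is None:
        with_uncertainty = config.n_boot > 0
    if with_uncertainty:
        n_boot = config.n_boot if config.n_boot >= 20 else 50
        pmf = estimate_uncertainty(series, hists, solution, n_boot=n_boot,
                                   seed=config.seed, bulk_range=bulk,
                                   burn_in_fraction=config.burn_in_fraction)
    else:
        pmf = solution.pmf(bulk_range=bulk)
    pmf.solution = solution  # type: ignore[attr-defined]  # diagnostics access
    return pmf


def bind_from_pmf(pmf: PMFProfile, config: RunConfig,
                  label: str = "") -> BindingResult:
    params = ThermoParams(temperature=config.temperature,
                          cylinder_radius=config.cylinder_radius)
    site = None
    if not (math.isnan(config.site_lo) or math.isnan(config.site_hi)):
        site = (config.site_lo, config.site_hi)
    return binding_result_from_pmf(pmf, params, site_bounds=site, label=label,
                                   seed=config.seed)


def run_pipeline(config: RunConfig, label: str = ""):
    """All stages in memory: simulate, WHAM, binding.

    Returns ``(result, pmf)`` — the :class:`BindingResult` and the
    bulk-anchored :class:`PMFProfile` it was computed from.
    """
    potential = _potential_from_config(config)
    series = simulate_windows(config, potential)
    pmf = wham_from_series(series, config, potential)
    result = bind_from_pmf(pmf, config, label=label or config.potential)
    return result, pmf
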