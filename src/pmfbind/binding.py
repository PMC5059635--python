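r"""Binding thermodynamics from a bulk-anchored PMF.

With a flat-bottom cylindrical restraint of radius R confining the ligand
laterally, the effective 1-D dissociation constant is

    K_D = [ pi R^2 N_A  \int_site exp(-w(z)/k_B T) dz ]^-1        (mol/L)

with w(z) the PMF offset to zero in bulk, and the standard binding free
energy is

    dG = k_B T ln(K_D / c0),    c0 = 1 mol/L.

These are effective, one-dimensional estimates: the lateral volume enters
only as pi R^2 and no orientational/conformational restraint corrections are
applied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .constants import LITER_PER_CUBIC_ANGSTROM, ThermoParams
from .wham import PMFProfile

__all__ = [
    "BindingResult",
    "kd_from_pmf",
    "dg_from_kd",
    "kd_from_dg",
    "delta_delta_g",
    "protonated_fraction",
    "propagate_dg_error",
    "find_site_bounds",
    "binding_result_from_pmf",
    "format_kd",
]


def dg_from_kd(kd: float, params: ThermoParams = ThermoParams()) -> float:
    """Standard binding free energy dG = kT ln(K_D/c0) in kcal/mol."""
    if kd <= 0:
        raise ValueError("K_D must be > 0")
    return float(params.kt * np.log(kd / params.standard_concentration))


def kd_from_dg(dg: float, params: ThermoParams = ThermoParams()) -> float:
    """Exact inverse of :func:`dg_from_kd` (mol/L)."""
    return params.standard_concentration * float(np.exp(dg / params.kt))


def protonated_fraction(ph: float, pka: float) -> float:
    """Henderson--Hasselbalch protonated fraction of a basic amine.

    f = 1 / (1 + 10^(pH - pKa)); strictly decreasing in pH. The ligand's pKa
    is an explicit argument (no default is shipped).
    """
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def find_site_bounds(pmf: PMFProfile, params: ThermoParams = ThermoParams(),
                     threshold_kt: float = 1.0) -> Tuple[float, float]:
    """Default binding-site bounds for the K_D integral.

    Starting from the cavity-side end of the profile (the end opposite the
    declared bulk range) and moving toward bulk, the site ends where w(z)
    first rises above ``-threshold_kt * kT``. Deep wells dominate the
    Boltzmann integral, so K_D is insensitive to the exact cutoff; the bounds
    are nevertheless always recorded on the result.

    When the profile carries per-bin counts, bins with fewer than 1% of the
    best-sampled bin's counts (minimum 10) are ignored: the nearly empty tail
    bins beyond the outermost window carry spuriously noisy w values that
    would otherwise truncate or inflate the site.
    """
    if pmf.bulk_range is None:
        raise ValueError("PMF has no declared bulk range; pass site bounds explicitly")
    m = pmf.supported
    if pmf.counts is not None and np.nanmax(pmf.counts) > 0:
        min_count = max(10.0, 0.01 * float(np.nanmax(pmf.counts)))
        m = m & (np.nan_to_num(pmf.counts) >= min_count)
    z = pmf.z[m]
    w = pmf.w[m]
    bulk_mid = 0.5 * (pmf.bulk_range[0] + pmf.bulk_range[1])
    cavity_on_right = abs(z[-1] - bulk_mid) > abs(z[0] - bulk_mid)
    if not cavity_on_right:
        z, w = z[::-1], w[::-1]
    # walk from the cavity end toward bulk
    cut = -threshold_kt * params.kt
    idx = len(z) - 1
    for i in range(len(z) - 1, -1, -1):
        if w[i] <= cut:
            idx = i
        elif idx != len(z) - 1:
            # already inside the well and back above the cutoff: stop
            break
    inner, outer = z[idx], z[-1]
    lo, hi = (min(inner, outer), max(inner, outer))
    if lo == hi:
        raise ValueError(
            f"no bins below {-threshold_kt:g} kT; the PMF has no binding site "
            "under the default rule -- pass site bounds explicitly"
        )
    return (float(lo), float(hi))


def _site_integral(pmf: PMFProfile, params: ThermoParams,
                   site_bounds: Tuple[float, float],
                   w: Optional[np.ndarray] = None) -> float:
    """Trapezoid of exp(-w/kT) over site bins (angstrom)."""
    lo, hi = sorted(map(float, site_bounds))
    if w is None:
        w = pmf.w
    mask = (pmf.z >= lo - 1e-12) & (pmf.z <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("site bounds cover fewer than 2 bins")
    if not np.all(np.isfinite(w[mask])):
        bad = pmf.z[mask & ~np.isfinite(w)]
        raise ValueError(
            f"site contains unsupported bins at z = {np.round(bad, 3).tolist()} A"
        )
    return float(np.trapezoid(np.exp(-w[mask] / params.kt), pmf.z[mask]))


def kd_from_pmf(pmf: PMFProfile, params: ThermoParams = ThermoParams(),
                site_bounds: Optional[Tuple[float, float]] = None) -> float:
    """Effective dissociation constant (mol/L) from a bulk-anchored PMF.

    The PMF must carry the bulk-zero offset; a raw profile is refused because
    the integral is only meaningful relative to w = 0 in bulk. The integral
    is a trapezoid over the bin grid; angstrom^3 convert to litres via 1e-27.
    """
    if pmf.offset != "bulk-zero":
        raise ValueError(
            "PMF is not anchored to the bulk (offset convention "
            f"{pmf.offset!r}); apply offset_to_bulk first"
        )
    if site_bounds is None:
        site_bounds = find_site_bounds(pmf, params)
    integral = _site_integral(pmf, params, site_bounds)  # angstrom
    area = np.pi * params.cylinder_radius**2  # angstrom^2
    volume_l_per_mol = area * integral * LITER_PER_CUBIC_ANGSTROM * params.avogadro
    return 1.0 / volume_l_per_mol


@dataclass(frozen=True)
class BindingResult:
    """Effective K_D and dG for one channel-state / ligand-form system.

    ``dg`` and ``kd`` always satisfy dG = kT ln(K_D/c0) exactly because dG is
    derived from kd at construction.
    """

    kd: float  # mol/L
    dg: float  # kcal/mol
    site_bounds: Tuple[float, float]
    params: ThermoParams
    stderr_dg: Optional[float] = None
    label: str = ""
    provenance: str = ""

    def summary(self) -> str:
        err = f" +/- {self.stderr_dg:.2f}" if self.stderr_dg is not None else ""
        return (
            f"Binding result {self.label or '(unlabelled)'}\n"
            f"  K_D         : {self.kd:.4e} M ({format_kd(self.kd)})\n"
            f"  dG          : {self.dg:.2f}{err} kcal/mol\n"
            f"  site bounds : [{self.site_bounds[0]:g}, {self.site_bounds[1]:g}] A\n"
            f"  T           : {self.params.temperature:g} K, "
            f"R = {self.params.cylinder_radius:g} A, "
            f"c0 = {self.params.standard_concentration:g} M\n"
            f"  note        : effective 1-D estimate under a cylindrical restraint\n"
        )


def binding_result_from_pmf(pmf: PMFProfile,
                            params: ThermoParams = ThermoParams(),
                            site_bounds: Optional[Tuple[float, float]] = None,
                            label: str = "", n_boot: int = 200,
                            seed: int = 0) -> BindingResult:
    """Full conversion PMF -> BindingResult, with error propagation when the
    profile carries per-bin standard errors."""
    if site_bounds is None:
        site_bounds = find_site_bounds(pmf, params)
    kd = kd_from_pmf(pmf, params, site_bounds)
    stderr = None
    if pmf.stderr is not None:
        stderr = propagate_dg_error(pmf, params, site_bounds, n_boot=n_boot,
                                    seed=seed)
    prov = hashlib.sha256(
        json.dumps({"params": params.as_dict(), "site": list(site_bounds),
                    "z": np.round(pmf.z, 9).tolist(),
                    "w": np.round(np.nan_to_num(pmf.w, nan=1e30), 9).tolist()},
                   sort_keys=True).encode()
    ).hexdigest()[:16]
    return BindingResult(kd=kd, dg=dg_from_kd(kd, params),
                         site_bounds=tuple(site_bounds), params=params,
                         stderr_dg=stderr, label=label, provenance=prov)


def delta_delta_g(result_a: BindingResult, result_b: BindingResult
                  ) -> Tuple[float, Optional[float]]:
    """ddG = dG_a - dG_b with quadrature uncertainty when both carry errors.

    Both results must share the same thermodynamic parameters.
    """
    if result_a.params != result_b.params:
        raise ValueError("results were computed under different ThermoParams")
    ddg = result_a.dg - result_b.dg
    err = None
    if result_a.stderr_dg is not None and result_b.stderr_dg is not None:
        err = float(np.hypot(result_a.stderr_dg, result_b.stderr_dg))
    return float(ddg), err


def propagate_dg_error(pmf: PMFProfile, params: ThermoParams,
                       site_bounds: Tuple[float, float],
                       n_boot: int = 200, seed: int = 0) -> float:
    """Propagate per-bin PMF standard errors through the K_D integral.

    Seeded parametric bootstrap: each replicate perturbs every site bin by an
    independent Gaussian with that bin's stderr, recomputes dG, and the spread
    of replicates is returned as stderr_dG.
    """
    if pmf.stderr is None:
        raise ValueError("PMF carries no stderr")
    lo, hi = sorted(map(float, site_bounds))
    mask = (pmf.z >= lo - 1e-12) & (pmf.z <= hi + 1e-12)
    if not np.all(np.isfinite(pmf.stderr[mask])):
        raise ValueError("stderr missing on some site bins")
    rng = np.random.default_rng(seed)
    dgs = np.empty(n_boot)
    for b in range(n_boot):
        w = pmf.w.copy()
        w[mask] = w[mask] + rng.standard_normal(mask.sum()) * pmf.stderr[mask]
        integral = _site_integral(pmf, params, site_bounds, w=w)
        area = np.pi * params.cylinder_radius**2
        kd = 1.0 / (area * integral * LITER_PER_CUBIC_ANGSTROM * params.avogadro)
        dgs[b] = dg_from_kd(kd, params)
    return float(np.std(dgs, ddof=1))


def format_kd(kd: float) -> str:
    """Human-readable K_D with the unit prefix the value calls for."""
    if kd <= 0 or not np.isfinite(kd):
        return f"{kd} M"
    for scale, unit in ((1.0, "M"), (1e-3, "mM"), (1e-6, "uM"),
                        (1e-9, "nM"), (1e-12, "pM")):
        if kd >= scale:
            return f"{kd / scale:.3g} {unit}"
    return f"{kd / 1e-12:.3g} pM"
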