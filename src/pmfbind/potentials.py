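"""Analytic one-dimensional ground-truth potentials.

These potentials stand in for the unknown true free-energy profile w(z) along
the drug translocation coordinate z (ligand centre of mass relative to the
selectivity-filter anchor; more negative z is further down the permeation
pathway toward the intracellular bulk). They give the synthetic umbrella
pipeline an exact answer to recover: the biased sampler draws from
exp(-(u + bias)/kT), WHAM reconstructs w(z), and the reconstruction can be
compared bin-by-bin against ``u``.

Every preset is exactly zero in its declared bulk region, so the bulk-offset
convention applied to a reconstructed PMF makes it directly comparable to the
preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

__all__ = ["TruePotential", "preset_potential", "PRESET_NAMES"]


@dataclass
class TruePotential:
    """An analytic 1-D potential u(z) in kcal/mol on a finite domain.

    Attributes
    ----------
    name : str
        Label for reports.
    u : callable
        Vectorised potential energy, kcal/mol, valid on ``domain``.
    domain : (float, float)
        Closed interval [z_lo, z_hi] in angstrom on which u is defined.
    bulk_range : (float, float) or None
        Sub-interval where the potential is flat at zero (the bulk phase).
        None for potentials with no bulk plateau (e.g. a pure harmonic well).
    params : dict
        Named parameters (well depths kcal/mol, centres angstrom, widths
        angstrom, ...) for provenance.
    du : callable or None
        Analytic derivative du/dz (kcal/mol/angstrom). When None a central
        finite difference is used and ``finite_difference`` is flagged.
    """

    name: str
    u: Callable[[np.ndarray], np.ndarray]
    domain: Tuple[float, float]
    bulk_range: Optional[Tuple[float, float]] = None
    params: dict = field(default_factory=dict)
    du: Optional[Callable[[np.ndarray], np.ndarray]] = None
    finite_difference: bool = field(init=False, default=False)
    _fd_step: float = 1e-5

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError("domain must satisfy z_hi > z_lo")
        zs = np.linspace(lo, hi, 257)
        if not np.all(np.isfinite(self.u(zs))):
            raise ValueError(f"potential {self.name!r} is not finite on its domain")
        if self.du is None:
            self.finite_difference = True

    def __call__(self, z):
        return self.u(np.asarray(z, dtype=float))

    def derivative(self, z):
        """du/dz, analytic when available, else central finite difference."""
        z = np.asarray(z, dtype=float)
        if self.du is not None:
            return self.du(z)
        h = self._fd_step
        return (self.u(z + h) - self.u(z - h)) / (2.0 * h)

    def force(self, z):
        """Mechanical force -du/dz in kcal/mol/angstrom."""
        return -self.derivative(z)

    def contains(self, z) -> np.ndarray:
        lo, hi = self.domain
        z = np.asarray(z, dtype=float)
        return (z >= lo) & (z <= hi)


def _gaussian_wells(name, wells, domain, bulk_range, extra=None):
    """Sum of Gaussian wells: u(z) = sum_j depth_j * exp(-(z-c_j)^2 / (2 s_j^2))."""
    wells = [tuple(map(float, w)) for w in wells]

    def u(z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for depth, centre, sigma in wells:
            out = out + depth * np.exp(-((z - centre) ** 2) / (2.0 * sigma**2))
        return out

    def du(z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for depth, centre, sigma in wells:
            out = out + depth * np.exp(-((z - centre) ** 2) / (2.0 * sigma**2)) * (
                -(z - centre) / sigma**2
            )
        return out

    params = {
        f"well{j}_{key}": val
        for j, (depth, centre, sigma) in enumerate(wells, start=1)
        for key, val in (("depth_kcal", depth), ("centre_A", centre), ("width_A", sigma))
    }
    if extra:
        params.update(extra)
    return TruePotential(name=name, u=u, du=du, domain=domain,
                         bulk_range=bulk_range, params=params)


def _make_open_like() -> TruePotential:
    # Two moderate binding wells near the intracavitary site, mimicking the
    # two-site profile seen for the neutral ligand in the open channel.
    return _gaussian_wells(
        "open-like",
        wells=[(-8.0, -16.0, 1.5), (-7.0, -10.0, 1.3)],
        domain=(-55.0, -4.0),
        bulk_range=(-52.0, -44.0),
    )


def _make_inactivated_like() -> TruePotential:
    # One deep (~18 kcal/mol) well plus a shallow outer minimum near the gate,
    # mimicking the lock-in profile of the cationic ligand in the
    # open-inactivated channel.
    return _gaussian_wells(
        "inactivated-like",
        wells=[(-18.0, -10.0, 2.0), (-3.0, -16.0, 1.5)],
        domain=(-45.0, -3.0),
        bulk_range=(-44.0, -36.0),
    )


def _make_flat() -> TruePotential:
    pot = TruePotential(
        name="flat",
        u=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
        du=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
        domain=(-55.0, 5.0),
        bulk_range=(-55.0, 5.0),
        params={},
    )
    return pot


def _make_harmonic(k: float = 1.0, centre: float = 0.0) -> TruePotential:
    return TruePotential(
        name="harmonic",
        u=lambda z: 0.5 * k * (np.asarray(z, dtype=float) - centre) ** 2,
        du=lambda z: k * (np.asarray(z, dtype=float) - centre),
        domain=(centre - 20.0, centre + 20.0),
        bulk_range=None,  # a harmonic well has no flat bulk plateau
        params={"force_constant_kcal_A2": k, "centre_A": centre},
    )


def _make_square_well(depth: float = -5.0, width: float = 1.0,
                      centre: float = -10.0) -> TruePotential:
    half = width / 2.0

    def u(z):
        z = np.asarray(z, dtype=float)
        return np.where(np.abs(z - centre) < half, depth, 0.0)

    return TruePotential(
        name="square-well",
        u=u,
        du=None,  # discontinuous; Metropolis correction handles the jump exactly
        domain=(centre - 10.0, centre + 10.0),
        bulk_range=(centre + 2.0, centre + 10.0),
        params={"depth_kcal": depth, "width_A": width, "centre_A": centre},
    )


_PRESETS = {
    "open-like": _make_open_like,
    "inactivated-like": _make_inactivated_like,
    "flat": _make_flat,
    "harmonic": _make_harmonic,
    "square-well": _make_square_well,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_potential(name: str, **kwargs) -> TruePotential:
    """Return a named preset potential.

    ``open-like`` has two wells of roughly -8 and -7 kcal/mol;
    ``inactivated-like`` has a single -18 kcal/mol well plus a shallow outer
    minimum; ``flat`` is identically zero; ``harmonic`` is a quadratic well
    (accepts ``k`` and ``centre``); ``square-well`` is a flat-bottom well
    (accepts ``depth``, ``width``, ``centre``).
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return factory(**kwargs)
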