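"""Patch-clamp measurement models: generators and least-squares fits.

Three reduced measurement models cover the channel-block experiments:

* Hill concentration--response:  block(c) = 1 / (1 + (IC50/c)^n_H)
* use-dependent block time course:  I(t)/I_0 = A exp(-t/tau) + C
* Boltzmann activation:  g/g_max = 1 / (1 + exp((V1/2 - V)/k_s))

Each model follows the statsmodels pattern: construct from data, ``fit()``
returns a :class:`CurveFitResult` with parameter estimates, standard errors
from the fit covariance, residual sum of squares, and a convergence flag.
Module-level ``fit_*`` helpers accept tidy DataFrames with documented column
names. Matching noisy-data generators make every fit testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CurveFitResult",
    "HillModel",
    "ExponentialDecayModel",
    "BoltzmannModel",
    "fit_hill",
    "fit_exponential",
    "fit_boltzmann",
    "compare_conditions",
    "generate_hill_data",
    "generate_exponential_block",
    "generate_gv_data",
]

_LS_KW = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20_000)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _noisy(clean: np.ndarray, noise_sd: float, seed, clip=None) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = clean.astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(y.shape)
    if clip is not None:
        y = np.clip(y, *clip)
    return y


def generate_hill_data(ic50: float, n_h: float, concentrations: Sequence[float],
                       noise_sd: float = 0.0, seed: Optional[int] = None
                       ) -> pd.DataFrame:
    """Fractional block vs concentration (uM) with additive Gaussian noise,
    clipped to [0, 1]."""
    c = np.asarray(concentrations, dtype=float)
    if ic50 <= 0 or n_h <= 0 or np.any(c <= 0):
        raise ValueError("ic50, n_h and all concentrations must be > 0")
    block = 1.0 / (1.0 + (ic50 / c) ** n_h)
    block = _noisy(block, noise_sd, seed, clip=(0.0, 1.0))
    return pd.DataFrame({"concentration_uM": c, "block_fraction": block})


def generate_exponential_block(tau: float, times: Sequence[float],
                               noise_sd: float = 0.0,
                               seed: Optional[int] = None,
                               amplitude: float = 1.0,
                               offset: float = 0.0) -> pd.DataFrame:
    """Normalised current decay A exp(-t/tau) + C with additive noise."""
    t = np.asarray(times, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be > 0")
    current = amplitude * np.exp(-t / tau) + offset
    current = _noisy(current, noise_sd, seed)
    return pd.DataFrame({"time_s": t, "i_norm": current})


def generate_gv_data(v_half: float, slope: float, voltages: Sequence[float],
                     noise_sd: float = 0.0, seed: Optional[int] = None
                     ) -> pd.DataFrame:
    """Normalised conductance--voltage Boltzmann curve with additive noise."""
    v = np.asarray(voltages, dtype=float)
    if slope == 0:
        raise ValueError("slope must be nonzero")
    with np.errstate(over="ignore"):  # steep-slope limit saturates cleanly
        g = 1.0 / (1.0 + np.exp((v_half - v) / slope))
    g = _noisy(g, noise_sd, seed)
    return pd.DataFrame({"voltage_mV": v, "g_norm": g})


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class CurveFitResult:
    """Parameter estimates and diagnostics from one curve fit."""

    model: str
    params: Dict[str, float]
    stderr: Optional[Dict[str, float]]
    rss: float
    n: int
    converged: bool
    flags: List[str] = field(default_factory=list)
    predict: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def summary(self) -> str:
        lines = [f"{self.model} fit ({self.n} points)",
                 "-" * 40]
        for name, val in self.params.items():
            if self.stderr is not None and name in self.stderr:
                lines.append(f"  {name:<10s} {val:>14.6g} +/- {self.stderr[name]:.3g}")
            else:
                lines.append(f"  {name:<10s} {val:>14.6g}")
        lines.append(f"  RSS        {self.rss:>14.6g}")
        lines.append(f"  converged  {self.converged}")
        for fl in self.flags:
            lines.append(f"  note: {fl}")
        return "\n".join(lines)


def _run_fit(model_name, func, x, y, p0, bounds, param_names, flags=None):
    flags = list(flags or [])
    try:
        popt, pcov = optimize.curve_fit(func, x, y, p0=p0, bounds=bounds,
                                        **_LS_KW)
        converged = True
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        return CurveFitResult(model=model_name,
                              params=dict(zip(param_names, p0)),
                              stderr=None, rss=float("nan"), n=len(x),
                              converged=False,
                              flags=flags + [f"optimizer failure: {exc}"])
    resid = y - func(x, *popt)
    rss = float(np.dot(resid, resid))
    stderr = None
    if len(x) > len(popt) and np.all(np.isfinite(pcov)):
        stderr = dict(zip(param_names, np.sqrt(np.diag(pcov))))
    return CurveFitResult(model=model_name,
                          params=dict(zip(param_names, map(float, popt))),
                          stderr=stderr, rss=rss, n=len(x),
                          converged=converged, flags=flags,
                          predict=lambda xx, p=popt: func(np.asarray(xx, float), *p))


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class HillModel:
    """Hill concentration--response model for fractional block.

    block(c) = 1 / (1 + (IC50/c)^n_H). Parameters: ``ic50`` (uM, > 0) and
    ``n_h`` (> 0). When no start values are given a deterministic multi-start
    grid over the observed concentration range is used, so the fit depends
    only on the data.
    """

    param_names = ("ic50", "n_h")

    def __init__(self, concentration, block):
        c = np.asarray(concentration, dtype=float)
        b = np.asarray(block, dtype=float)
        order = np.argsort(c, kind="stable")
        self.c, self.b = c[order], b[order]
        if np.unique(self.c).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(self.c <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any((b < 0) | (b > 1)):
            raise ValueError("block fractions must lie in [0, 1]")
        if np.ptp(self.b) == 0:
            raise ValueError("degenerate data: all block fractions identical")

    @staticmethod
    def func(c, ic50, n_h):
        return 1.0 / (1.0 + (ic50 / c) ** n_h)

    def fit(self, start: Optional[Tuple[float, float]] = None) -> CurveFitResult:
        bounds = ([1e-12, 1e-3], [1e12, 50.0])
        if start is not None:
            starts = [tuple(start)]
        else:
            ic_grid = np.geomspace(self.c.min() / 10.0, self.c.max() * 10.0, 9)
            starts = [(ic, nh) for ic in ic_grid for nh in (0.5, 1.0, 2.0, 4.0)]
        best = None
        for p0 in starts:
            res = _run_fit("hill", self.func, self.c, self.b, p0, bounds,
                           self.param_names)
            if res.converged and (best is None or res.rss < best.rss):
                best = res
        if best is None:
            return _run_fit("hill", self.func, self.c, self.b, starts[0],
                            bounds, self.param_names)
        return best


class ExponentialDecayModel:
    """Single-exponential decay I(t) = A exp(-t/tau) + C.

    ``tau`` is the use-dependent block time constant. The steady-state offset
    C is included by default and declared on the result; pass
    ``with_offset=False`` to fit the pure two-parameter exponential.
    """

    def __init__(self, time, current, with_offset: bool = True):
        t = np.asarray(time, dtype=float)
        y = np.asarray(current, dtype=float)
        order = np.argsort(t, kind="stable")
        self.t, self.y = t[order], y[order]
        if self.t.size < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(self.y) == 0:
            raise ValueError("degenerate data: constant current")
        self.with_offset = with_offset
        self.param_names = ("amplitude", "tau", "offset") if with_offset \
            else ("amplitude", "tau")

    def func(self, t, *p):
        if self.with_offset:
            a, tau, c = p
        else:
            (a, tau), c = p, 0.0
        return a * np.exp(-t / tau) + c

    def fit(self, start=None) -> CurveFitResult:
        span = self.t[-1] - self.t[0]
        if start is None:
            c0 = float(self.y[-1])
            a0 = float(self.y[0] - c0) or 1.0
            tau0 = span / 3.0 if span > 0 else 1.0
            start = (a0, tau0, c0) if self.with_offset else (a0, tau0)
        lo = [-np.inf, 1e-12] + ([-np.inf] if self.with_offset else [])
        hi = [np.inf, np.inf] + ([np.inf] if self.with_offset else [])
        flags = ["offset term included" if self.with_offset else "no offset term"]
        res = _run_fit("exponential-decay", self.func, self.t, self.y, start,
                       (lo, hi), self.param_names, flags=flags)
        if res.converged and res.params["amplitude"] <= 0:
            res.converged = False
            res.flags.append("non-decaying data: fitted amplitude <= 0")
        return res


class BoltzmannModel:
    """Boltzmann conductance--voltage activation curve.

    g/g_max = 1 / (1 + exp((V1/2 - V)/k_s)); a positive slope factor k_s means
    activation with depolarisation. With ``fit_gmax=True`` an overall scale
    g_max is fitted as a third parameter instead of being fixed at 1.
    """

    def __init__(self, voltage, conductance, fit_gmax: bool = False):
        v = np.asarray(voltage, dtype=float)
        g = np.asarray(conductance, dtype=float)
        order = np.argsort(v, kind="stable")
        self.v, self.g = v[order], g[order]
        if self.v.size < 4:
            raise ValueError("need at least 4 points")
        self.fit_gmax = fit_gmax
        self.param_names = ("v_half", "slope", "g_max") if fit_gmax \
            else ("v_half", "slope")

    def func(self, v, *p):
        if self.fit_gmax:
            vh, ks, gmax = p
        else:
            (vh, ks), gmax = p, 1.0
        return gmax / (1.0 + np.exp((vh - v) / ks))

    def fit(self, start=None) -> CurveFitResult:
        if start is None:
            # midpoint guess: voltage where conductance crosses half its range
            gm = self.g.max() if self.fit_gmax else 1.0
            half = gm / 2.0
            i = int(np.argmin(np.abs(self.g - half)))
            vh0 = float(self.v[i])
            ks0 = max(1.0, float(np.ptp(self.v)) / 8.0)
            start = (vh0, ks0, gm) if self.fit_gmax else (vh0, ks0)
        lo = [-np.inf, 1e-9] + ([1e-12] if self.fit_gmax else [])
        hi = [np.inf, np.inf] + ([np.inf] if self.fit_gmax else [])
        res = _run_fit("boltzmann", self.func, self.v, self.g, start,
                       (lo, hi), self.param_names)
        if res.converged:
            vh = res.params["v_half"]
            if vh <= self.v.min() or vh >= self.v.max():
                res.flags.append(
                    "one-sided data: fitted midpoint outside the sampled "
                    "voltage range; standard errors are unreliable"
                )
        return res


# ---------------------------------------------------------------------------
# DataFrame adapters
# ---------------------------------------------------------------------------

def _col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise KeyError(f"expected column {name!r}; got {list(df.columns)}")
    return df[name].to_numpy(dtype=float)


def fit_hill(data: pd.DataFrame, start=None) -> CurveFitResult:
    """Fit the Hill model to a table with columns concentration_uM, block_fraction."""
    return HillModel(_col(data, "concentration_uM"),
                     _col(data, "block_fraction")).fit(start=start)


def fit_exponential(data: pd.DataFrame, with_offset: bool = True) -> CurveFitResult:
    """Fit the exponential decay to a table with columns time_s, i_norm."""
    return ExponentialDecayModel(_col(data, "time_s"), _col(data, "i_norm"),
                                 with_offset=with_offset).fit()


def fit_boltzmann(data: pd.DataFrame, fit_gmax: bool = False) -> CurveFitResult:
    """Fit the Boltzmann activation curve to a table with columns voltage_mV, g_norm."""
    return BoltzmannModel(_col(data, "voltage_mV"), _col(data, "g_norm"),
                          fit_gmax=fit_gmax).fit()


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def compare_conditions(results_by_condition: Dict[str, Sequence],
                       parameter: str) -> pd.DataFrame:
    """Welch t-test on a fitted parameter between every pair of conditions.

    ``results_by_condition`` maps a condition label (e.g. a pH) to per-cell
    fits (:class:`CurveFitResult`) or plain parameter values. No
    multiple-testing correction is applied (single planned comparisons).
    Returns one row per ordered pair with mean difference, pooled standard
    error, Welch t, degrees of freedom and two-sided p.
    """
    groups = {}
    for label, results in results_by_condition.items():
        vals = [r.params[parameter] if isinstance(r, CurveFitResult) else float(r)
                for r in results]
        if len(vals) < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 fits")
        groups[label] = np.asarray(vals, dtype=float)

    rows = []
    labels = list(groups)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a, b = groups[la], groups[lb]
            diff = float(a.mean() - b.mean())
            se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
            if se == 0.0:
                t_stat, p, df = (0.0, 1.0, float(a.size + b.size - 2))
            else:
                welch = stats.ttest_ind(a, b, equal_var=False)
                t_stat, p = float(welch.statistic), float(welch.pvalue)
                df = float(welch.df)
            rows.append({"condition_a": la, "condition_b": lb,
                         "parameter": parameter, "mean_diff": diff,
                         "stderr": se, "t": t_stat, "df": df, "p_value": p,
                         "n_a": a.size, "n_b": b.size})
    return pd.DataFrame(rows)
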