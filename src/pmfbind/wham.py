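r"""Weighted histogram analysis method (WHAM) for 1-D umbrella sampling.

Given per-window histograms n_i(b) of the reaction coordinate collected under
harmonic biases U_i(z), WHAM solves the self-consistency equations

    rho(b)  \propto  sum_i n_i(b)  /  sum_i N_i exp[(f_i - U_i(z_b)) / k_B T]
    f_i     =  -k_B T ln sum_b rho(b) exp(-U_i(z_b) / k_B T)

for the unbiased density rho and the per-window free-energy constants f_i
(gauge-fixed to f_1 = 0). The PMF is w(z) = -k_B T ln rho(z), conventionally
offset so that it averages to zero over a declared bulk region.

The model/results split mirrors statsmodels: build an :class:`UmbrellaWHAM`
from histograms, call :meth:`~UmbrellaWHAM.fit`, and read the PMF and
diagnostics off the returned :class:`WHAMResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .constants import BOLTZMANN_KCAL, DEFAULT_TEMPERATURE
from .umbrella import TimeSeries, WindowSpec, bias_energy

__all__ = [
    "WindowHistogram",
    "build_histograms",
    "UmbrellaWHAM",
    "WHAMResults",
    "PMFProfile",
    "solve_wham",
    "pmf_from_solution",
    "offset_to_bulk",
    "statistical_inefficiency",
    "estimate_uncertainty",
]

#: Default burn-in: discard the first 2 of every 22 samples (keep the final
#: 20/22 of each window's trajectory).
DEFAULT_BURN_IN = 2.0 / 22.0


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

@dataclass
class WindowHistogram:
    """Histogram of one window's retained samples on the shared bin grid."""

    edges: np.ndarray  # strictly increasing, uniform width
    counts: np.ndarray  # nonnegative ints, len(edges) - 1
    window: WindowSpec
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        widths = np.diff(self.edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bin widths must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        """Retained in-range sample count (== sum of counts)."""
        return int(self.counts.sum())

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_histograms(series: Sequence[TimeSeries], bin_width: float = 0.1,
                     burn_in_fraction: float = DEFAULT_BURN_IN,
                     hist_range: Optional[Tuple[float, float]] = None,
                     ) -> List[WindowHistogram]:
    """Histogram every window's trajectory on one shared uniform grid.

    The first ``ceil(burn_in_fraction * n)`` samples of each series are
    discarded as equilibration. Bins are half-open [left, right) with the last
    bin right-closed (numpy convention), so retained in-range counts are
    conserved exactly. Samples falling outside ``hist_range`` are counted on
    each histogram's ``n_out_of_range`` rather than silently dropped.

    When ``hist_range`` is None the grid spans all retained samples, with
    edges anchored at integer multiples of ``bin_width``.
    """
    if not series:
        raise ValueError("no time series given")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")

    retained = []
    for s in series:
        n_burn = math.ceil(burn_in_fraction * len(s))
        kept = s.samples[n_burn:]
        if kept.size == 0:
            raise ValueError(
                f"window at {s.window.centre:g} A has no samples left after burn-in"
            )
        retained.append(kept)

    if hist_range is None:
        lo = min(float(k.min()) for k in retained)
        hi = max(float(k.max()) for k in retained)
        lo = math.floor(lo / bin_width) * bin_width
        hi = math.ceil(hi / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = map(float, hist_range)
        if hi <= lo:
            raise ValueError("hist_range must be an increasing pair")
    n_bins = max(1, round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)

    out = []
    for s, kept in zip(series, retained):
        counts, _ = np.histogram(kept, bins=edges)
        n_out = int(kept.size - counts.sum())
        out.append(WindowHistogram(edges=edges, counts=counts, window=s.window,
                                   n_out_of_range=n_out))
    return out


# ---------------------------------------------------------------------------
# PMF container
# ---------------------------------------------------------------------------

@dataclass
class PMFProfile:
    """Tabulated potential of mean force w(z) on a uniform bin grid.

    Bins that received no samples are flagged unsupported and carry NaN; they
    are never interpolated to zero. ``offset`` records whether the profile is
    raw (arbitrary additive constant) or anchored to average zero over
    ``bulk_range``.
    """

    z: np.ndarray  # bin centres, angstrom
    w: np.ndarray  # kcal/mol, NaN where unsupported
    temperature: float
    stderr: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None  # pooled samples per bin
    offset: str = "raw"  # "raw" | "bulk-zero"
    bulk_range: Optional[Tuple[float, float]] = None
    bin_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.shape != self.w.shape:
            raise ValueError("z and w must have the same shape")
        if self.bin_width is None and self.z.size > 1:
            self.bin_width = float(np.median(np.diff(self.z)))

    @property
    def supported(self) -> np.ndarray:
        return np.isfinite(self.w)

    def plot(self, ax=None, **kwargs):
        """Quick-look PMF plot with a stderr band when available."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.supported
        ax.plot(self.z[m], self.w[m], **kwargs)
        if self.stderr is not None:
            ax.fill_between(self.z[m], self.w[m] - self.stderr[m],
                            self.w[m] + self.stderr[m], alpha=0.3)
        ax.set_xlabel("z (Å)")
        ax.set_ylabel("w(z) (kcal/mol)")
        return ax


def offset_to_bulk(pmf: PMFProfile, bulk_range: Tuple[float, float]) -> PMFProfile:
    """Anchor the PMF so its mean over ``bulk_range`` is exactly zero.

    At least three supported bins must fall inside the bulk range. The shift
    is a pure gauge change: per-bin uncertainties are untouched.
    """
    lo, hi = sorted(map(float, bulk_range))
    mask = (pmf.z >= lo) & (pmf.z <= hi) & pmf.supported
    if mask.sum() < 3:
        raise ValueError(
            f"bulk range ({lo}, {hi}) A overlaps only {int(mask.sum())} supported "
            "bins; need at least 3"
        )
    shift = float(np.mean(pmf.w[mask]))
    return replace(pmf, w=pmf.w - shift, offset="bulk-zero", bulk_range=(lo, hi))


# ---------------------------------------------------------------------------
# WHAM model / results
# ---------------------------------------------------------------------------

class UmbrellaWHAM:
    """WHAM estimator for a set of umbrella-window histograms.

    Parameters
    ----------
    histograms : list of WindowHistogram
        All histograms must share one bin grid (use :func:`build_histograms`).
    temperature : float
        Simulation temperature in K.
    bias_convention : str
        "half-k" for U = (k/2)(z-z0)^2, "full-k" for U = k (z-z0)^2.
    min_count : int
        Minimum pooled samples for a bin to be part of the solution support,
        and minimum shared samples for two windows to count as overlapping.
    """

    def __init__(self, histograms: Sequence[WindowHistogram],
                 temperature: float = DEFAULT_TEMPERATURE,
                 bias_convention: str = "half-k", min_count: int = 1):
        if not histograms:
            raise ValueError("no histograms given")
        edges = histograms[0].edges
        for h in histograms[1:]:
            if h.edges.shape != edges.shape or not np.allclose(h.edges, edges):
                raise ValueError("all histograms must share one bin grid")
        self.histograms = list(histograms)
        self.temperature = float(temperature)
        self.kt = BOLTZMANN_KCAL * self.temperature
        self.bias_convention = bias_convention
        self.min_count = int(min_count)

        self.edges = edges
        self.centres = 0.5 * (edges[:-1] + edges[1:])
        self.counts = np.array([h.counts for h in histograms])  # (n_win, n_bins)
        self.n_samples = self.counts.sum(axis=1)  # N_i
        self.pooled = self.counts.sum(axis=0)  # M_b
        self.support = self.pooled >= self.min_count
        if not np.any(self.support):
            raise ValueError("no bin has any samples")
        # Log bias Boltzmann factors on supported bins: (n_win, n_sup)
        zc = self.centres[self.support]
        self.log_bias = np.array([
            -bias_energy(zc, h.window.centre, h.window.force_constant,
                         bias_convention) / self.kt
            for h in histograms
        ])
        self._check_overlap()

    def _check_overlap(self) -> None:
        """The windows must form one connected overlap graph: two windows are
        linked when they share >= min_count samples in some bin."""
        n = len(self.histograms)
        if n == 1:
            return
        present = self.counts >= self.min_count  # (n_win, n_bins)
        adj = (present @ present.T) > 0
        # BFS over components
        comp = -np.ones(n, dtype=int)
        c = 0
        for start in range(n):
            if comp[start] >= 0:
                continue
            stack = [start]
            comp[start] = c
            while stack:
                i = stack.pop()
                for j in np.nonzero(adj[i])[0]:
                    if comp[j] < 0:
                        comp[j] = c
                        stack.append(j)
            c += 1
        if c > 1:
            groups = [
                [f"{self.histograms[i].window.centre:g}" for i in np.nonzero(comp == k)[0]]
                for k in range(c)
            ]
            desc = "; ".join("{" + ", ".join(g) + "}" for g in groups)
            raise ValueError(
                f"window overlap graph is disconnected ({c} components, by "
                f"window centre in A): {desc}"
            )

    # -- solver ------------------------------------------------------------

    def _sweep(self, g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """One WHAM fixed-point sweep on reduced constants g_i = f_i / kT.

        Returns (g_new, log_rho) with the gauge g_new[0] = 0.
        """
        log_m = np.log(self.pooled[self.support])
        log_n = np.log(self.n_samples)
        denom = logsumexp(log_n[:, None] + g[:, None] + self.log_bias, axis=0)
        log_rho = log_m - denom
        g_new = -logsumexp(log_rho[None, :] + self.log_bias, axis=1)
        return g_new - g_new[0], log_rho

    def fit(self, tolerance: float = 1e-7, max_iter: int = 100_000,
            anderson: bool = True, anderson_order: int = 5,
            f_init: Optional[np.ndarray] = None) -> "WHAMResults":
        """Iterate the WHAM equations to self-consistency.

        Convergence is declared when the largest change of any window constant
        f_i between sweeps drops to ``tolerance`` (kcal/mol, default 1e-7).
        Direct iteration is optionally wrapped in Anderson acceleration
        (order 5 by default) with a fallback to the plain sweep whenever the
        accelerated step fails to reduce the residual.
        """
        n_win = len(self.histograms)
        g = (np.zeros(n_win) if f_init is None
             else np.asarray(f_init, dtype=float) / self.kt)
        g = g - g[0]
        tol_g = tolerance / self.kt

        # Anderson mixing (type II): x_{k+1} = x_k + r_k - (dX + dR) gamma with
        # gamma the least-squares combination of recent residual differences.
        hist_x: List[np.ndarray] = []
        hist_r: List[np.ndarray] = []
        last_resid = np.inf
        n_worse = 0
        log_rho = None
        resid = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            g_img, log_rho = self._sweep(g)
            r = g_img - g
            resid = float(np.max(np.abs(r)))
            if resid <= tol_g:
                g = g_img
                break
            g_next = g_img
            if anderson:
                hist_x.append(g.copy())
                hist_r.append(r.copy())
                if len(hist_x) > anderson_order + 1:
                    hist_x.pop(0)
                    hist_r.pop(0)
                if len(hist_x) >= 2:
                    d_x = np.diff(np.array(hist_x), axis=0).T
                    d_r = np.diff(np.array(hist_r), axis=0).T
                    try:
                        gamma, *_ = np.linalg.lstsq(d_r, r, rcond=None)
                        cand = g + r - (d_x + d_r) @ gamma
                        cand = cand - cand[0]
                        if np.all(np.isfinite(cand)):
                            g_next = cand
                    except np.linalg.LinAlgError:
                        pass
                # safeguard: a run of growing residuals restarts the history
                if resid > last_resid:
                    n_worse += 1
                    if n_worse >= 5:
                        hist_x.clear()
                        hist_r.clear()
                        n_worse = 0
                        g_next = g_img
                else:
                    n_worse = 0
                last_resid = resid
            g = g_next
        converged = resid <= tol_g
        if log_rho is None:  # pragma: no cover - max_iter >= 1 always iterates
            _, log_rho = self._sweep(g)
        if anderson and converged:
            # the reported density must be the exact image of the final
            # constants, not an extrapolated mixture
            g, log_rho = self._sweep(g)
            g = g - g[0]
        return WHAMResults(model=self, f=g * self.kt, log_density=log_rho,
                           n_iter=it, final_residual=resid * self.kt,
                           converged=converged, tolerance=tolerance)


@dataclass
class WHAMResults:
    """Converged (or flagged unconverged) WHAM solution.

    ``f`` are the per-window free-energy constants in kcal/mol with f_1 = 0;
    ``log_density`` is the unnormalised log of the reconstructed unbiased
    density on the supported bins.
    """

    model: UmbrellaWHAM
    f: np.ndarray
    log_density: np.ndarray
    n_iter: int
    final_residual: float
    converged: bool
    tolerance: float

    def pmf(self, bulk_range: Optional[Tuple[float, float]] = None,
            allow_unconverged: bool = False) -> PMFProfile:
        """PMF w(z) = -kT ln rho(z); bulk-anchored when a range is given."""
        if not self.converged and not allow_unconverged:
            raise RuntimeError(
                f"WHAM did not converge (residual {self.final_residual:.3g} "
                f"kcal/mol after {self.n_iter} sweeps); pass "
                "allow_unconverged=True to extract the PMF anyway"
            )
        m = self.model
        w = np.full(m.centres.size, np.nan)
        w[m.support] = -m.kt * self.log_density
        prof = PMFProfile(z=m.centres.copy(), w=w, temperature=m.temperature,
                          counts=m.pooled.copy(), offset="raw",
                          bin_width=float(m.edges[1] - m.edges[0]))
        if bulk_range is not None:
            prof = offset_to_bulk(prof, bulk_range)
        return prof

    def summary(self) -> str:
        m = self.model
        lines = [
            "WHAM results",
            "============",
            f"windows:            {len(m.histograms)}",
            f"bins (supported):   {m.centres.size} ({int(m.support.sum())})",
            f"bin width:          {m.edges[1] - m.edges[0]:g} A",
            f"temperature:        {m.temperature:g} K",
            f"bias convention:    {m.bias_convention}",
            f"iterations:         {self.n_iter}",
            f"final residual:     {self.final_residual:.3e} kcal/mol",
            f"tolerance:          {self.tolerance:.3e} kcal/mol",
            f"converged:          {self.converged}",
            "",
            "window centre (A)   f_i (kcal/mol)   N_i",
        ]
        for h, fi, ni in zip(m.histograms, self.f, m.n_samples):
            lines.append(f"{h.window.centre:>14.2f} {fi:>16.6f} {ni:>8d}")
        return "\n".join(lines)


def solve_wham(histograms: Sequence[WindowHistogram],
               temperature: float = DEFAULT_TEMPERATURE,
               tolerance: float = 1e-7, max_iter: int = 100_000,
               **kwargs) -> WHAMResults:
    """Functional wrapper: build an :class:`UmbrellaWHAM` and fit it."""
    model_kwargs = {k: kwargs.pop(k) for k in ("bias_convention", "min_count")
                    if k in kwargs}
    model = UmbrellaWHAM(histograms, temperature=temperature, **model_kwargs)
    return model.fit(tolerance=tolerance, max_iter=max_iter, **kwargs)


def pmf_from_solution(solution: WHAMResults,
                      temperature: Optional[float] = None) -> PMFProfile:
    """Raw-offset PMF from a WHAM solution (w = -kT ln rho)."""
    if temperature is not None and not np.isclose(
            temperature, solution.model.temperature):
        raise ValueError("temperature differs from the one WHAM was solved at")
    return solution.pmf()


# ---------------------------------------------------------------------------
# Uncertainty
# ---------------------------------------------------------------------------

def statistical_inefficiency(x: np.ndarray) -> float:
    """Statistical inefficiency g = 1 + 2 * sum_t (1 - t/n) * rho(t).

    The normalised autocorrelation function rho(t) is accumulated until it
    first becomes non-positive (initial-positive-sequence cutoff), the usual
    estimator for the effective sample size n/g of a correlated series.
    Returns 1.0 for constant or length-<2 series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    dx = x - x.mean()
    var = float(np.dot(dx, dx) / n)
    if var == 0.0:
        return 1.0
    # FFT autocovariance
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    fx = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real / n
    rho = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if rho[t] <= 0.0:
            break
        g += 2.0 * (1.0 - t / n) * rho[t]
    return max(1.0, float(g))


def estimate_uncertainty(series: Sequence[TimeSeries],
                         histograms: Sequence[WindowHistogram],
                         solution: WHAMResults,
                         n_boot: int = 50, seed: int = 0,
                         bulk_range: Optional[Tuple[float, float]] = None,
                         burn_in_fraction: float = DEFAULT_BURN_IN,
                         ) -> PMFProfile:
    """Per-bin PMF standard errors by seeded bootstrap over effective samples.

    Each window's statistical inefficiency g is estimated from the integrated
    autocorrelation time of its retained trajectory; the window then
    contributes n_eff = N/g effective samples. Bootstrap replicates redraw
    every window's histogram multinomially with n_eff counts from the observed
    bin frequencies, re-solve WHAM (warm-started from the base solution), and
    apply the bulk offset per replicate; the reported stderr is the bootstrap
    standard deviation of w(z) per bin.

    Returns a copy of the solution's PMF carrying ``stderr`` (bulk-anchored
    when ``bulk_range`` is given). Windows whose series are shorter than 10*g
    are noted on the returned profile's ``short_series_windows`` attribute.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for a usable stderr")
    if len(series) != len(histograms):
        raise ValueError("need one time series per histogram")
    model = solution.model
    rng = np.random.default_rng(seed)

    g_vals = []
    short = []
    for s in series:
        n_burn = math.ceil(burn_in_fraction * len(s))
        kept = s.samples[n_burn:]
        g = statistical_inefficiency(kept)
        g_vals.append(g)
        if kept.size < 10.0 * g:
            short.append(s.window.centre)
    g_vals = np.asarray(g_vals)
    n_eff = np.maximum(1, (model.n_samples / g_vals).astype(int))

    probs = [h.counts / h.n_total for h in histograms]
    replicas = np.empty((n_boot, int(model.support.sum())))
    for b in range(n_boot):
        boot_hists = [
            WindowHistogram(edges=h.edges,
                            counts=rng.multinomial(int(ne), p),
                            window=h.window)
            for h, p, ne in zip(histograms, probs, n_eff)
        ]
        try:
            boot_model = UmbrellaWHAM(boot_hists, temperature=model.temperature,
                                      bias_convention=model.bias_convention,
                                      min_count=model.min_count)
            res = boot_model.fit(tolerance=solution.tolerance,
                                 f_init=solution.f[:len(boot_hists)])
        except ValueError:
            replicas[b] = np.nan
            continue
        w = np.full(model.centres.size, np.nan)
        w[boot_model.support] = -boot_model.kt * res.log_density
        prof = PMFProfile(z=model.centres, w=w, temperature=model.temperature)
        if bulk_range is not None:
            prof = offset_to_bulk(prof, bulk_range)
        replicas[b] = prof.w[model.support]

    import warnings

    with warnings.catch_warnings():
        # bins that almost never receive resampled counts yield < 2 finite
        # replicates; their stderr is legitimately NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        stderr_sup = np.nanstd(replicas, axis=0, ddof=1)
    stderr = np.full(model.centres.size, np.nan)
    stderr[model.support] = stderr_sup

    prof = solution.pmf(bulk_range=bulk_range, allow_unconverged=True)
    prof.stderr = stderr
    prof.short_series_windows = short  # type: ignore[attr-defined]
    prof.inefficiencies = g_vals  # type: ignore[attr-defined]
    return prof
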