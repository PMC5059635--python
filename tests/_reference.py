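"""Independent reference implementation of the WHAM equations.

Deliberately written as plain fixed-point iteration with explicit loops and
no acceleration, log-space tricks, or code shared with the package, so it can
serve as an oracle for the production solver on small instances.
"""

import math


def reference_wham(counts, bin_centres, window_centres, force_constants, kt,
                   tolerance=1e-7, max_iter=2_000_000, half_k=True):
    """Solve WHAM by direct fixed-point iteration.

    Parameters are plain Python lists: ``counts[i][b]`` samples of window i in
    bin b, harmonic biases U_i(z) = (k_i/2)(z - z0_i)^2 (or k_i (z-z0)^2 when
    ``half_k`` is false). Returns (f_list_kcal, rho_list) with f[0] = 0 and
    rho the unnormalised density on bins with nonzero pooled counts (None on
    empty bins).
    """
    n_win = len(counts)
    n_bins = len(bin_centres)
    n_i = [sum(row) for row in counts]
    m_b = [sum(counts[i][b] for i in range(n_win)) for b in range(n_bins)]
    kfac = 0.5 if half_k else 1.0
    boltz = [
        [math.exp(-kfac * force_constants[i]
                  * (bin_centres[b] - window_centres[i]) ** 2 / kt)
         for b in range(n_bins)]
        for i in range(n_win)
    ]

    f = [0.0] * n_win  # in kcal/mol
    for _ in range(max_iter):
        expf = [math.exp(f[i] / kt) for i in range(n_win)]
        rho = []
        for b in range(n_bins):
            if m_b[b] == 0:
                rho.append(None)
                continue
            denom = 0.0
            for i in range(n_win):
                denom += n_i[i] * expf[i] * boltz[i][b]
            rho.append(m_b[b] / denom)
        f_new = []
        for i in range(n_win):
            s = 0.0
            for b in range(n_bins):
                if rho[b] is not None:
                    s += rho[b] * boltz[i][b]
            f_new.append(-kt * math.log(s))
        f_new = [fi - f_new[0] for fi in f_new]
        delta = max(abs(a - b) for a, b in zip(f_new, f))
        f = f_new
        if delta <= tolerance:
            break
    return f, rho
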