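"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, grid searches) and
shares no code with the package's estimators.
"""

import math

import numpy as np


def naive_v_terms(X, h):
    """Triple-loop evaluation of the pairwise-sum V-term formulas.

    Direct transcription: K_k(i, s) = G_{sqrt(2) h_k}(X[i,k] - X[s,k]),
    V_J, V_C, V_M assembled with explicit Python loops.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    h = list(h)

    def G(d, hh):
        return math.exp(-d * d / (2.0 * hh * hh)) / (math.sqrt(2.0 * math.pi) * hh)

    K = [
        [[G(X[i, k] - X[s, k], math.sqrt(2.0) * h[k]) for s in range(n)]
         for i in range(n)]
        for k in range(p)
    ]
    v_j = 0.0
    for i in range(n):
        for s in range(n):
            prod = 1.0
            for k in range(p):
                prod *= K[k][i][s]
            v_j += prod
    v_j /= n * n

    v_c = 0.0
    for i in range(n):
        prod = 1.0
        for k in range(p):
            row = 0.0
            for s in range(n):
                row += K[k][i][s]
            prod *= row / n
        v_c += prod
    v_c /= n

    v_m = 1.0
    for k in range(p):
        tot = 0.0
        for i in range(n):
            for s in range(n):
                tot += K[k][i][s]
        v_m *= tot / (n * n)
    return v_j, v_c, v_m


def naive_eqmi_star(X, h):
    v_j, v_c, v_m = naive_v_terms(X, h)
    return (v_j - 2.0 * v_c + v_m) / (v_j + v_m)


def breslow_loglik_1d(gamma, e, time, event):
    """Breslow log partial likelihood of a single-covariate Cox model."""
    e = np.asarray(e, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    ll = 0.0
    for j in np.where(event == 1)[0]:
        risk = time >= time[j]
        ll += gamma * e[j] - math.log(float(np.sum(np.exp(gamma * e[risk]))))
    return ll


def grid_search_cox_gamma(e, time, event, lo=-20.0, hi=20.0, rounds=6, points=2001):
    """Maximize the Breslow partial likelihood by iterated grid refinement."""
    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = np.array([breslow_loglik_1d(g, e, time, event) for g in grid])
        best = grid[int(np.argmax(vals))]
        span = (hi - lo) / points
        lo, hi = best - 2 * span, best + 2 * span
    return float(best)


def winsorize_then_minmax(values, cap_q):
    """Brute-force winsorize-at-quantile then min-max scale (for one marker)."""
    x = np.asarray(values, dtype=float)
    cap = float(np.quantile(x, cap_q))
    x = np.minimum(x, cap)
    return (x - x.min()) / (x.max() - x.min())
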