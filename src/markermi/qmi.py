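"""Quadratic mutual information between marker intensities.

For a subject with ``p`` markers observed in ``n`` cells, the Euclidean
quadratic mutual information (EQMI) compares the joint density of the
markers with the product of their marginals:

    EQMI = V_J - 2 V_C + V_M

where ``V_J`` is the integral of the squared joint density, ``V_C`` the
cross integral of the joint against the product of marginals and ``V_M``
the integral of the squared product of marginals.  EQMI is zero exactly
at independence.  Because its scale varies between subjects it is
standardized as

    EQMI* = (V_J - 2 V_C + V_M) / (V_J + V_M)  in  [0, 1],

which is the per-subject co-expression statistic used throughout the
package.  The Cauchy-Schwarz variant CSQMI = log(V_J V_M / V_C^2) is
reported alongside.

Plugging Gaussian kernel density estimates into the V integrals and
integrating analytically collapses everything onto pairwise kernel sums:
with a per-marker bandwidth ``h_k``, the kernel convolution identity
``∫ G_h(x-a) G_h(x-b) dx = G_{√2 h}(a-b)`` gives

    V_J = n^-2 Σ_i Σ_s Π_k K_k(i,s)
    V_C = n^-1 Σ_i Π_k [ n^-1 Σ_s K_k(i,s) ]
    V_M = Π_k [ n^-2 Σ_i Σ_s K_k(i,s) ],      K_k(i,s) = G_{√2 h_k}(X_ki - X_ks),

an O(n² p) computation that never touches a p-dimensional grid and is
valid for unequal bandwidths.  A two-dimensional quadrature routine that
evaluates the V integrals by brute-force numerical integration is kept as
an independent cross-check of this algebra.

Bandwidths are selected per subject, either by a univariate two-stage
direct plug-in rule applied marker by marker (the diagonal plug-in
selector; default for p <= 6) or by Silverman's rule of thumb.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CellTable
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DegenerateMarkerError,
    EmptyInputError,
)

_SQRT2PI = math.sqrt(2.0 * math.pi)
#: absolute numerical slack for inequalities that hold exactly in real arithmetic
EPS_NUM = 1e-10
#: lower clip for bandwidths, guards against near-duplicate intensities
MIN_BANDWIDTH = 1e-6
#: above this many markers the plug-in selector switches to Silverman's rule
P_MAX_PLUGIN = 6


@dataclass(frozen=True)
class BandwidthSet:
    """Per-marker Gaussian kernel bandwidths."""

    h: np.ndarray
    method_tag: str = "fixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.atleast_1d(np.asarray(self.h, dtype=float)))
        if self.method_tag not in {"plugin", "silverman", "fixed"}:
            raise ConfigurationError(f"unknown bandwidth tag {self.method_tag!r}")
        if not np.all(np.isfinite(self.h)) or np.any(self.h <= 0):
            raise ConfigurationError("bandwidths must be positive and finite")


@dataclass(frozen=True)
class VTerms:
    """The (V_J, V_C, V_M) triple underlying every QMI statistic."""

    v_j: float
    v_c: float
    v_m: float

    def __post_init__(self) -> None:
        for name in ("v_j", "v_c", "v_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -EPS_NUM:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class QmiResult:
    """All QMI statistics for one subject's cells."""

    eqmi_star: float
    eqmi_raw: float
    csqmi: float
    vterms: VTerms
    bandwidths: BandwidthSet
    n_cells: int


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def gaussian_kernel(d, h: float):
    """Gaussian kernel G_h(d) = (2π)^{-1/2} h^{-1} exp(-d²/(2h²))."""
    if not (np.isfinite(h) and h > 0):
        raise ConfigurationError(f"bandwidth must be positive and finite, got {h}")
    d = np.asarray(d, dtype=float)
    out = np.exp(-(d * d) / (2.0 * h * h)) / (_SQRT2PI * h)
    return float(out) if out.ndim == 0 else out


def pairwise_kernel_matrix(x: np.ndarray, h_k: float) -> np.ndarray:
    """n x n matrix of G_{√2 h_k}(x_i - x_s).

    The √2 inflation is the kernel self-convolution: each entry is the
    exact integral of the product of two bandwidth-``h_k`` kernels
    centred at ``x_i`` and ``x_s``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise EmptyInputError("pairwise_kernel_matrix needs at least one point")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("non-finite values in kernel input")
    return gaussian_kernel(x[:, None] - x[None, :], math.sqrt(2.0) * h_k)


# ---------------------------------------------------------------------------
# V-term estimation
# ---------------------------------------------------------------------------

def estimate_v_terms(subject_data: np.ndarray, bw: BandwidthSet) -> VTerms:
    """Pairwise-sum estimators of (V_J, V_C, V_M) for one subject.

    ``subject_data`` is the ``n x p`` intensity matrix of the subject's
    cells.  Per marker the n x n kernel matrix is formed once; its
    row means and grand mean are combined across markers, so memory stays
    O(n²) regardless of p.
    """
    X = np.atleast_2d(np.asarray(subject_data, dtype=float))
    n, p = X.shape
    if n == 0:
        raise EmptyInputError("subject has no cells")
    if p < 2:
        raise ConfigurationError("need at least 2 markers")
    h = bw.h
    if h.size == 1:
        h = np.full(p, float(h[0]))
    if h.size != p:
        raise ConfigurationError("bandwidth count must match marker count")

    prod_mat = np.ones((n, n), dtype=float)
    prod_row = np.ones(n, dtype=float)
    v_m = 1.0
    for k in range(p):
        K = pairwise_kernel_matrix(X[:, k], h[k])
        prod_mat *= K
        row_mean = K.mean(axis=1)
        prod_row *= row_mean
        v_m *= float(row_mean.mean())
    v_j = float(prod_mat.mean())
    v_c = float(prod_row.mean())
    return VTerms(v_j=v_j, v_c=v_c, v_m=v_m)


def eqmi_raw(v: VTerms) -> float:
    """Unstandardized EQMI = V_J - 2 V_C + V_M (non-negative up to roundoff)."""
    return v.v_j - 2.0 * v.v_c + v.v_m


def eqmi_star(v: VTerms) -> float:
    """Standardized EQMI* = (V_J - 2 V_C + V_M) / (V_J + V_M) in [0, 1]."""
    denom = v.v_j + v.v_m
    if denom <= 0:
        raise DegenerateInputError("V_J + V_M must be positive")
    val = eqmi_raw(v) / denom
    if val < -EPS_NUM or val > 1.0 + EPS_NUM:
        raise ValueError(f"EQMI* outside [0,1] beyond numerical slack: {val}")
    return float(min(max(val, 0.0), 1.0))


def csqmi(v: VTerms) -> float:
    """Cauchy-Schwarz QMI = log(V_J V_M / V_C²); +inf when V_C = 0."""
    if v.v_c <= 0:
        return math.inf
    return math.log(v.v_j * v.v_m / (v.v_c * v.v_c))


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def _column_scales(X: np.ndarray) -> np.ndarray:
    """min(sd, IQR/1.34) per column; errors on constant columns."""
    sd = X.std(axis=0, ddof=1)
    q75, q25 = np.quantile(X, [0.75, 0.25], axis=0)
    iqr = q75 - q25
    scale = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
    for k, s in enumerate(scale):
        if not (np.isfinite(s) and s > 0):
            raise DegenerateMarkerError(f"marker column {k} is constant (sd = 0)")
    return scale


def silverman_bandwidths(subject_data: np.ndarray) -> BandwidthSet:
    """Silverman's rule of thumb, marker by marker.

    h_k = 0.9 · min(sd_k, IQR_k / 1.34) · n^{-1/5}
    """
    X = np.atleast_2d(np.asarray(subject_data, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise DegenerateInputError("Silverman's rule needs n >= 2")
    h = 0.9 * _column_scales(X) * n ** (-0.2)
    return BandwidthSet(h=np.maximum(h, MIN_BANDWIDTH), method_tag="silverman")


def _pairwise_psi(x: np.ndarray, g: float, r: int) -> float:
    """Estimate ψ_r = n^-2 Σ_i Σ_j φ_g^{(r)}(x_i - x_j).

    For even r, φ^{(r)}(u) = He_r(u) φ(u) (probabilist's Hermite) is even,
    so only the condensed i < j distances are evaluated.
    """
    from scipy.spatial.distance import pdist

    n = x.size
    t2 = pdist(x[:, None]) / g
    np.multiply(t2, t2, out=t2)  # t² for i < j
    if r == 4:
        he = (t2 - 6.0) * t2 + 3.0
        he0 = 3.0
    elif r == 6:
        he = ((t2 - 15.0) * t2 + 45.0) * t2 - 15.0
        he0 = -15.0
    else:  # pragma: no cover - only r in {4, 6} is used
        raise ValueError("unsupported derivative order")
    total = 2.0 * float(he @ np.exp(-0.5 * t2)) + n * he0
    return total / (n * n * _SQRT2PI * g ** (r + 1))


def _dpi_bandwidth(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for one marker.

    Normal-scale estimate of ψ8 seeds a kernel estimate of ψ6, which
    seeds ψ4; the AMISE-optimal h = (R(K) / (ψ4 n))^{1/5} follows with
    R(K) = 1/(2√π) and unit kernel variance.  Raises on any
    non-positive intermediate so the caller can fall back to Silverman.
    """
    n = x.size
    sd = x.std(ddof=1)
    if sd <= 0:
        raise DegenerateMarkerError("constant marker (sd = 0)")
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * sd**9)
    # stage 1: ψ6 with pilot g1;  φ⁽⁶⁾(0) = -15/√(2π)
    g1 = (2.0 * 15.0 / (_SQRT2PI * psi8 * n)) ** (1.0 / 9.0)
    psi6 = _pairwise_psi(x, g1, r=6)
    if psi6 >= 0:
        raise ArithmeticError("plug-in stage 1 failed (psi6 >= 0)")
    # stage 2: ψ4 with pilot g2;  φ⁽⁴⁾(0) = 3/√(2π)
    g2 = (-2.0 * 3.0 / (_SQRT2PI * psi6 * n)) ** (1.0 / 7.0)
    psi4 = _pairwise_psi(x, g2, r=4)
    if psi4 <= 0:
        raise ArithmeticError("plug-in stage 2 failed (psi4 <= 0)")
    return (1.0 / (2.0 * math.sqrt(math.pi) * psi4 * n)) ** 0.2


def plugin_bandwidths(subject_data: np.ndarray) -> BandwidthSet:
    """Diagonal multivariate plug-in selector: a univariate two-stage
    direct plug-in bandwidth per marker.

    With more than ``P_MAX_PLUGIN`` markers, or when the plug-in
    equations fail numerically, falls back to Silverman's rule with a
    warning.
    """
    X = np.atleast_2d(np.asarray(subject_data, dtype=float))
    n, p = X.shape
    if n < 4:
        raise DegenerateInputError("plug-in selector needs n >= 4 cells")
    _column_scales(X)  # raise early on constant markers
    if p > P_MAX_PLUGIN:
        warnings.warn(
            f"p = {p} > {P_MAX_PLUGIN}: switching from plug-in to Silverman "
            "bandwidths to avoid computational deadlock",
            stacklevel=2,
        )
        return silverman_bandwidths(X)
    h = np.empty(p, dtype=float)
    for k in range(p):
        try:
            h[k] = _dpi_bandwidth(X[:, k])
        except ArithmeticError:
            warnings.warn(
                f"plug-in equation failed for marker column {k}; "
                "using Silverman's rule for this marker",
                stacklevel=2,
            )
            h[k] = silverman_bandwidths(X).h[k]
    return BandwidthSet(h=np.maximum(h, MIN_BANDWIDTH), method_tag="plugin")


def select_bandwidths(
    subject_data: np.ndarray, method: str, fixed_h: float | Sequence[float] | None = None
) -> BandwidthSet:
    """Dispatch on a bandwidth method tag: plugin | silverman | fixed."""
    if method == "plugin":
        return plugin_bandwidths(subject_data)
    if method == "silverman":
        return silverman_bandwidths(subject_data)
    if method == "fixed":
        if fixed_h is None:
            raise ConfigurationError("fixed bandwidths require an h value")
        p = np.atleast_2d(subject_data).shape[1]
        h = np.atleast_1d(np.asarray(fixed_h, dtype=float))
        if h.size == 1:
            h = np.full(p, float(h[0]))
        return BandwidthSet(h=h, method_tag="fixed")
    raise ConfigurationError(f"unknown bandwidth method {method!r}")


# ---------------------------------------------------------------------------
# quadrature cross-check (p = 2 only)
# ---------------------------------------------------------------------------

def quadrature_oracle(
    subject_data: np.ndarray, bw: BandwidthSet, grid_size: int = 401
) -> VTerms:
    """Brute-force V integrals via gridded kernel density estimates (p = 2).

    Builds the joint product-kernel KDE and both marginal KDEs on a 2-D
    grid extending 4 bandwidths beyond [0, 1] (and beyond the data range,
    if wider) and integrates numerically with the trapezoid rule.  This
    is the computationally naive route the pairwise-sum estimators
    replace; it exists as an independent numerical check of that algebra.
    """
    X = np.atleast_2d(np.asarray(subject_data, dtype=float))
    n, p = X.shape
    if p != 2:
        raise ConfigurationError("quadrature oracle supports exactly 2 markers")
    if n > 2000:
        raise ConfigurationError("quadrature oracle is restricted to n <= 2000")
    if grid_size < 400:
        raise ConfigurationError("grid must have at least 400 points per axis")
    h = bw.h if bw.h.size == 2 else np.full(2, float(bw.h[0]))
    pad = 4.0 * float(h.max())
    lo = min(float(X.min()), 0.0) - pad
    hi = max(float(X.max()), 1.0) + pad
    g = np.linspace(lo, hi, grid_size)

    # columns of A_k: kernel centred at each data point, evaluated on grid
    A1 = gaussian_kernel(g[:, None] - X[None, :, 0], float(h[0]))
    A2 = gaussian_kernel(g[:, None] - X[None, :, 1], float(h[1]))
    f1 = A1.mean(axis=1)
    f2 = A2.mean(axis=1)
    f12 = (A1 @ A2.T) / n  # f12[a, b] = joint KDE at (g[a], g[b])

    def trapz2(Z: np.ndarray) -> float:
        return float(np.trapezoid(np.trapezoid(Z, g, axis=1), g))

    v_j = trapz2(f12 * f12)
    v_c = trapz2(f12 * np.outer(f1, f2))
    v_m = float(np.trapezoid(f1 * f1, g) * np.trapezoid(f2 * f2, g))
    return VTerms(v_j=v_j, v_c=v_c, v_m=v_m)


# ---------------------------------------------------------------------------
# per-subject driver
# ---------------------------------------------------------------------------

def compute_subject_qmi(
    subject_data: np.ndarray,
    bw_method: str = "plugin",
    fixed_h: float | Sequence[float] | None = None,
) -> QmiResult:
    """Bandwidths + V terms + all QMI statistics for one subject."""
    X = np.atleast_2d(np.asarray(subject_data, dtype=float))
    bw = select_bandwidths(X, bw_method, fixed_h)
    v = estimate_v_terms(X, bw)
    return QmiResult(
        eqmi_star=eqmi_star(v),
        eqmi_raw=eqmi_raw(v),
        csqmi=csqmi(v),
        vterms=v,
        bandwidths=bw,
        n_cells=X.shape[0],
    )


def compute_eqmi_all_subjects(
    table: CellTable,
    markers: Sequence[str] | None = None,
    bw_method: str = "plugin",
    fixed_h: float | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-subject QMI statistics for a marker subset.

    Bandwidths are selected per subject from that subject's own cells.
    Subjects that cannot support the estimate (fewer than 2 cells, or a
    marker constant within the subject) are excluded with a warning, not
    silently and not fatally.

    Returns a DataFrame with columns ``subject_id, marker_set,
    eqmi_star, eqmi_raw, csqmi, n_cells, h_1..h_p, bw_method``.
    """
    markers = list(markers) if markers is not None else list(table.marker_names)
    if len(markers) < 2:
        raise ConfigurationError("need at least 2 markers")
    unknown = [m for m in markers if m not in table.marker_names]
    if unknown:
        raise ConfigurationError(f"unknown markers requested: {unknown}")

    rows = []
    marker_set = ";".join(markers)
    for subject in table.subjects:
        X = table.subject_matrix(subject, markers)
        if X.shape[0] < 2:
            warnings.warn(
                f"subject {subject!r} excluded: fewer than 2 cells", stacklevel=2
            )
            continue
        try:
            res = compute_subject_qmi(X, bw_method=bw_method, fixed_h=fixed_h)
        except (DegenerateMarkerError, DegenerateInputError) as err:
            warnings.warn(f"subject {subject!r} excluded: {err}", stacklevel=2)
            continue
        row = {
            "subject_id": subject,
            "marker_set": marker_set,
            "eqmi_star": res.eqmi_star,
            "eqmi_raw": res.eqmi_raw,
            "csqmi": res.csqmi,
            "n_cells": res.n_cells,
        }
        for k, hk in enumerate(res.bandwidths.h, start=1):
            row[f"h_{k}"] = float(hk)
        row["bw_method"] = res.bandwidths.method_tag
        rows.append(row)
    if not rows:
        raise EmptyInputError("no subject supported the QMI estimate")
    return pd.DataFrame(rows)
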