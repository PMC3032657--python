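"""LD decay with distance: Hill-Weir expectation, nls fit, threshold, extent.

The decay curve is the sample-size-adjusted drift-recombination
expectation E[r^2 | C, n] with C = gamma_per_bp * distance; gamma is fit
by non-linear least squares.  The significance threshold is the squared
95th percentile of square-root-transformed r^2 values from unlinked
loci, and the extent of LD is where the fitted curve crosses it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq, least_squares

#: sentinel statuses for the extent of LD
EXTENT_ZERO = "zero"              # curve already below threshold at d -> 0
EXTENT_BEYOND = "beyond_range"    # curve above threshold at d_max
EXTENT_OK = "crossed"

DEFAULT_D_MAX = 1371.0  # longest analyzed fragment, bp


@dataclass
class DecayFit:
    gamma_per_bp: float
    n: int
    sse: float
    threshold_r2: float | None = None
    extent_bp: float | None = None
    extent_status: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def hill_weir_expectation(C, n: int):
    """Sample-size-adjusted expectation of r^2 at scaled distance C = 4Nc.

    E[r^2] = [(10+C)/((2+C)(11+C))] *
             [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C)(13+C))]
    """
    if n < 2:
        raise ValueError("need n >= 2")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    first = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    second = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C) * (13.0 + C))
    out = first * second
    return float(out) if out.ndim == 0 else out


_STARTS = (1e-4, 1e-2, 1.0)  # gamma-per-bp multi-start grid


def fit_gamma(distances, r2, n: int) -> DecayFit:
    """Least-squares fit of gamma_per_bp to an r^2-vs-distance scatter.

    Deterministic multi-start (1e-4, 1e-2, 1 per bp); the lowest-SSE
    solution wins.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(r2, dtype=float)
    if d.size != y.size:
        raise ValueError("distances and r2 must be the same length")
    if d.size < 5:
        raise ValueError("need at least 5 scatter points")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    if np.unique(d).size == 1:
        raise ValueError("degenerate scatter: all points at one distance")

    def residuals(log_gamma):
        return hill_weir_expectation(np.exp(log_gamma[0]) * d, n) - y

    best = None
    for start in _STARTS:
        sol = least_squares(residuals, x0=[math.log(start)],
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[1] - 1e-10:
            best = (float(np.exp(sol.x[0])), sse)
    return DecayFit(gamma_per_bp=best[0], n=n, sse=best[1])


def ld_threshold(unlinked_r2, percentile: float = 95.0) -> float:
    """Squared 95th percentile of sqrt(r^2) from unlinked-locus pairs.

    Percentiles use linear interpolation (type 7).
    """
    v = np.asarray(unlinked_r2, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 20:
        raise ValueError("need at least 20 unlinked r2 values")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("r2 values must lie in [0, 1]")
    return float(np.percentile(np.sqrt(v), percentile) ** 2)


def ld_extent(fit: DecayFit, threshold_r2: float,
              d_max: float = DEFAULT_D_MAX) -> DecayFit:
    """Distance where the fitted decay curve crosses the threshold.

    Returns an updated DecayFit with extent_bp and a status: the curve
    may start below the threshold (extent 0) or stay above it out to
    d_max (beyond range).  Root located by bisection to 0.5 bp.
    """
    gamma = fit.gamma_per_bp

    def curve(d):
        return hill_weir_expectation(gamma * d, fit.n) - threshold_r2

    at_zero = curve(1e-9)
    if at_zero <= 0:
        return DecayFit(gamma, fit.n, fit.sse, threshold_r2, 0.0, EXTENT_ZERO)
    if curve(d_max) > 0:
        return DecayFit(gamma, fit.n, fit.sse, threshold_r2, float(d_max),
                        EXTENT_BEYOND)
    root = brentq(curve, 1e-9, d_max, xtol=0.5)
    return DecayFit(gamma, fit.n, fit.sse, threshold_r2, float(root), EXTENT_OK)


def analytic_extent(gamma_per_bp: float, n: int, threshold_r2: float,
                    d_max: float = DEFAULT_D_MAX) -> float:
    """Extent for a known gamma (no fitting); same crossing rules."""
    fit = DecayFit(gamma_per_bp=gamma_per_bp, n=n, sse=0.0)
    return ld_extent(fit, threshold_r2, d_max).extent_bp
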