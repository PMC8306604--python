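"""Equal-mass aggregation of GEC TMRCA samples into per-region densities.

Every retained clade carries a different number of TMRCA samples (one per
posterior tree it is monophyletic in), so pooling the raw samples would
weight well-supported clades more heavily.  Instead, a Gaussian kernel
density estimate is computed per clade, normalised to unit mass on the age
grid, and the per-clade curves are averaged with equal weight — each clade
contributes exactly 1/(number of clades) of the aggregate mass.  The module
also provides equal-weight percentiles and the clade-size vs TMRCA
ordinary-least-squares regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gec import GEClade

#: Minimum kernel bandwidth in years, guarding degenerate clades.
BANDWIDTH_FLOOR = 100.0

#: Number of evaluation points on the shared age grid.
GRID_SIZE = 512


@dataclass
class DensityCurve:
    """An aggregate TMRCA density on an ascending age grid (yBP)."""

    grid: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    bandwidths: np.ndarray  # per-clade, years
    region: str
    n_clades: int

    def integral(self) -> float:
        return float(np.trapezoid(self.pdf, self.grid))


@dataclass
class SizeAgeRegression:
    """Linear and quadratic OLS fits of median TMRCA on clade size."""

    region: str
    linear: tuple[float, float]            # (intercept, slope)
    quadratic: tuple[float, float, float]  # (intercept, b1, b2)
    rss_linear: float
    rss_quadratic: float


def nrd0_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(SD, IQR/1.34) * n^(-1/5).

    Degenerate inputs (fewer than 3 samples, or zero spread) fall back to
    :data:`BANDWIDTH_FLOOR` so that every clade still contributes a proper
    Gaussian bump.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return BANDWIDTH_FLOOR
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return BANDWIDTH_FLOOR
    return max(0.9 * spread * x.size ** (-0.2), BANDWIDTH_FLOOR)


def _clade_pdf(samples: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[None, :] - samples[:, None]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=0) / (samples.size * bw * np.sqrt(2 * np.pi))
    mass = np.trapezoid(dens, grid)  # renormalise after truncation at age 0
    if mass <= 0:
        raise ValueError("clade density has no mass on the age grid")
    return dens / mass


def aggregate_density(
    gecs: Sequence[GEClade],
    region: str,
    grid: np.ndarray | None = None,
    bandwidth_rule=nrd0_bandwidth,
) -> DensityCurve:
    """Equal-mass aggregate TMRCA density for one region.

    Each clade's Gaussian KDE is evaluated on a shared grid (default: 512
    points from 0 to 1.1x the oldest TMRCA sample), truncated at age 0,
    renormalised to unit mass, and the clade curves averaged with weight
    1/(number of clades).
    """
    clades = [g for g in gecs if g.region == region]
    if not clades:
        raise ValueError(f"no clades for region {region!r}")
    if any(len(g.tmrca_samples) == 0 for g in clades):
        raise ValueError("clade without TMRCA samples")
    if grid is None:
        top = max(max(g.tmrca_samples) for g in clades)
        grid = np.linspace(0.0, 1.1 * max(top, BANDWIDTH_FLOOR), GRID_SIZE)
    bws = np.array([bandwidth_rule(np.asarray(g.tmrca_samples, float)) for g in clades])
    pdf = np.zeros_like(grid)
    for g, bw in zip(clades, bws):
        pdf += _clade_pdf(np.asarray(g.tmrca_samples, float), grid, bw)
    pdf /= len(clades)
    cdf = _cumtrapz(pdf, grid)
    cdf = np.clip(cdf / cdf[-1], 0.0, 1.0)
    return DensityCurve(grid=grid, pdf=pdf, cdf=cdf, bandwidths=bws,
                        region=region, n_clades=len(clades))


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def percentile(curve: DensityCurve, q: float | Sequence[float]) -> float | np.ndarray:
    """Age (yBP) at which the equal-clade-weighted CDF reaches ``q``.

    Linear interpolation on the grid; ``q`` must lie in (0, 1).
    """
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("percentile q must lie in (0, 1)")
    out = np.interp(qs, curve.cdf, curve.grid)
    return float(out[0]) if np.isscalar(q) else out


def size_age_regression(gecs: Sequence[GEClade], region: str) -> SizeAgeRegression:
    """OLS of median TMRCA on clade size, linear and quadratic."""
    clades = [g for g in gecs if g.region == region]
    if len(clades) < 3:
        raise ValueError(f"need >= 3 clades for region {region!r}, have {len(clades)}")
    x = np.array([g.size for g in clades], dtype=float)
    y = np.array([g.median_tmrca for g in clades], dtype=float)
    X1 = np.column_stack([np.ones_like(x), x])
    X2 = np.column_stack([np.ones_like(x), x, x**2])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ b1) ** 2))
    rss2 = float(np.sum((y - X2 @ b2) ** 2))
    return SizeAgeRegression(
        region=region,
        linear=(float(b1[0]), float(b1[1])),
        quadratic=(float(b2[0]), float(b2[1]), float(b2[2])),
        rss_linear=rss1,
        rss_quadratic=rss2,
    )
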