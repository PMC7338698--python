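"""ROC and z-ROC construction and slope estimation.

An ROC plots the hit rate against the false-alarm rate as the decision
criterion sweeps across the five confidence cut-points; the z-ROC is the
same curve after probit transform of both axes.  Under UVSD the z-ROC is
exactly linear with slope sigma_n / sigma_o = 1 / sigma_o, so the
commonly observed slope of ~0.8 corresponds to an old-item SD about 1.25
times the new-item SD.  DPSD and MSD produce curved z-ROCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .data import RatingCounts
from .models import _survival_old

__all__ = ["ROCPoints", "empirical_roc", "zroc_slope", "model_roc", "plot_roc"]


@dataclass(frozen=True)
class ROCPoints:
    """Cumulative (fa, hit) proportions and their probit transforms."""

    fa: np.ndarray
    hit: np.ndarray

    def __post_init__(self):
        fa = np.asarray(self.fa, dtype=float)
        hit = np.asarray(self.hit, dtype=float)
        if fa.shape != hit.shape:
            raise ValueError("fa and hit must have matching shapes")
        if np.any((fa <= 0) | (fa >= 1)) or np.any((hit <= 0) | (hit >= 1)):
            raise ValueError("ROC proportions must lie strictly in (0, 1)")
        object.__setattr__(self, "fa", fa)
        object.__setattr__(self, "hit", hit)

    @property
    def z_fa(self) -> np.ndarray:
        return ndtri(self.fa)

    @property
    def z_hit(self) -> np.ndarray:
        return ndtri(self.hit)


def _adjust_degenerate(p, n):
    """Replace cumulative proportions of exactly 0 or 1 by 1/(2N) and
    1 - 1/(2N) so the probit transform is defined."""
    eps = 1.0 / (2.0 * n)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "degenerate cumulative proportion adjusted by 1/(2N)", stacklevel=3
        )
    return np.clip(p, eps, 1.0 - eps)


def empirical_roc(counts: RatingCounts) -> ROCPoints:
    """Observed ROC: point k = proportion of ratings > k, k = 1..5."""
    if not isinstance(counts, RatingCounts):
        counts = RatingCounts(*counts)
    old, new = counts.as_arrays()
    n_old, n_new = old.sum(), new.sum()
    if n_old == 0 or n_new == 0:
        raise ValueError("ROC undefined with zero old or new trials")
    hit = np.cumsum(old[::-1])[::-1][1:] / n_old  # P(rating > k | old)
    fa = np.cumsum(new[::-1])[::-1][1:] / n_new
    return ROCPoints(_adjust_degenerate(fa, n_new), _adjust_degenerate(hit, n_old))


def zroc_slope(points: ROCPoints):
    """Ordinary least-squares line through (z_fa, z_hit).

    Returns ``(slope, intercept)``.  For exact UVSD probabilities the
    slope equals 1/sigma_o: z_hit = d/sigma_o + z_fa/sigma_o.
    """
    z_fa, z_hit = points.z_fa, points.z_hit
    if len(np.unique(z_fa)) < 2:
        raise ValueError("need at least 2 distinct points for a slope")
    slope, intercept = np.polyfit(z_fa, z_hit, 1)
    return float(slope), float(intercept)


def model_roc(params, grid=None) -> ROCPoints:
    """Model-implied ROC evaluated on a criterion grid.

    Defaults to the parameter set's own criteria.  As fa -> 0 the DPSD
    hit rate approaches the recollection intercept R.
    """
    c = np.asarray(params.criteria if grid is None else grid, dtype=float)
    if c.ndim != 1 or len(c) < 1:
        raise ValueError("grid must be a 1-D array of criteria")
    if np.any(np.diff(c) <= 0):
        raise ValueError("grid must be strictly increasing")
    fa = ndtr(-c)
    hit = _survival_old(params, c)
    return ROCPoints(np.clip(fa, 1e-15, 1 - 1e-15), np.clip(hit, 1e-15, 1 - 1e-15))


def plot_roc(points: ROCPoints, model_points: ROCPoints = None, z: bool = False, ax=None):
    """Plot an empirical ROC (and optionally a model curve).

    Imports matplotlib lazily; returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if z:
        ax.plot(points.z_fa, points.z_hit, "o", label="observed")
        if model_points is not None:
            ax.plot(model_points.z_fa, model_points.z_hit, "-", label="model")
        ax.set_xlabel("z(FA)")
        ax.set_ylabel("z(Hit)")
    else:
        ax.plot(points.fa, points.hit, "o", label="observed")
        if model_points is not None:
            ax.plot(model_points.fa, model_points.hit, "-", label="model")
        ax.plot([0, 1], [0, 1], ":", color="grey", lw=1)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("False-alarm rate")
        ax.set_ylabel("Hit rate")
    ax.legend()
    return ax
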