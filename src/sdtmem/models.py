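"""Signal-detection models of recognition confidence ratings.

Three multinomial signal-detection accounts of the old-item variance
effect, all sharing a standard-normal new-item strength distribution
(mu_n = 0, sigma_n = 1) and five ordered decision criteria c1 < ... < c5
partitioning strength into six confidence categories:

* UVSD (unequal variance): old strengths ~ N(d, sigma_o); the hit
  probability at criterion c is Phi((d - c) / sigma_o).  The z-ROC is
  linear with slope 1/sigma_o.
* DPSD (dual process): with probability R an old item is recollected and
  receives the top confidence rating; otherwise an equal-variance
  familiarity process N(d', 1) drives the response.  Hit probability
  R + (1 - R) Phi(d' - c).
* MSD (mixture): old strengths come from an attended component
  N(d_A, 1) with probability lam, else from N(d_A', 1); here d_A' is
  fixed at 0 so old and new coincide on unattended trials.  Hit
  probability lam Phi(d_A - c) + (1 - lam) Phi(d_A' - c).  The mixture
  old-item variance 1 + lam (1 - lam) d_A^2 is maximal at lam = 0.5.

All three reduce to the equal-variance model (EVSD) when sigma_o = 1,
R = 0 or lam = 1 respectively.

Model classes (:class:`UVSDModel` etc.) wrap a
:class:`~sdtmem.data.RatingCounts` table, statsmodels-style: ``fit()``
returns a :class:`~sdtmem.fitting.FitResult` with estimates, G2
goodness of fit and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr  # high-accuracy normal CDF via erfc

from .data import RatingCounts, aggregate_counts

__all__ = [
    "UVSDParams",
    "DPSDParams",
    "MSDParams",
    "CategoryProbs",
    "PROB_FLOOR",
    "uvsd_hit_prob",
    "fa_prob",
    "dpsd_hit_prob",
    "msd_hit_prob",
    "category_probs",
    "log_likelihood",
    "old_item_variance",
    "params_from_dict",
    "SignalDetectionModel",
    "UVSDModel",
    "DPSDModel",
    "MSDModel",
    "MODEL_CLASSES",
    "evsd_params",
]

#: Predicted cell probabilities are clamped to at least this value and
#: renormalized before logs are taken, so extreme criteria never produce
#: -inf log-likelihoods during optimization.
PROB_FLOOR = 1e-10


def _check_criteria(criteria):
    c = tuple(float(x) for x in criteria)
    if len(c) != 5:
        raise ValueError("exactly 5 criteria are required")
    if not all(a < b for a, b in zip(c, c[1:])):
        raise ValueError("criteria must be strictly increasing")
    return c


@dataclass(frozen=True)
class UVSDParams:
    """Unequal-variance model: old ~ N(d, sigma_o), new ~ N(0, 1)."""

    d: float
    sigma_o: float
    criteria: tuple

    def __post_init__(self):
        if not self.sigma_o > 0:
            raise ValueError("sigma_o must be positive")
        object.__setattr__(self, "d", float(self.d))
        object.__setattr__(self, "sigma_o", float(self.sigma_o))
        object.__setattr__(self, "criteria", _check_criteria(self.criteria))

    def to_dict(self):
        out = {"d": self.d, "sigma_o": self.sigma_o}
        out.update({f"c{i+1}": c for i, c in enumerate(self.criteria)})
        return out


@dataclass(frozen=True)
class DPSDParams:
    """Dual-process model: recollection probability R plus familiarity d'."""

    d_prime: float
    R: float
    criteria: tuple

    def __post_init__(self):
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        object.__setattr__(self, "d_prime", float(self.d_prime))
        object.__setattr__(self, "R", float(self.R))
        object.__setattr__(self, "criteria", _check_criteria(self.criteria))

    def to_dict(self):
        out = {"d_prime": self.d_prime, "R": self.R}
        out.update({f"c{i+1}": c for i, c in enumerate(self.criteria)})
        return out


@dataclass(frozen=True)
class MSDParams:
    """Mixture model: attended N(d_A, 1) w.p. lam, else N(d_A', 1).

    ``d_A_prime`` is fixed at 0 by default (unattended items gain no
    strength), which equates the free-parameter count with UVSD/DPSD.
    Pass a nonzero value explicitly to unfreeze it.
    """

    d_A: float
    lam: float
    criteria: tuple
    d_A_prime: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        object.__setattr__(self, "d_A", float(self.d_A))
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "d_A_prime", float(self.d_A_prime))
        object.__setattr__(self, "criteria", _check_criteria(self.criteria))

    def to_dict(self):
        out = {"d_A": self.d_A, "lam": self.lam}
        if self.d_A_prime != 0.0:
            out["d_A_prime"] = self.d_A_prime
        out.update({f"c{i+1}": c for i, c in enumerate(self.criteria)})
        return out


@dataclass(frozen=True)
class CategoryProbs:
    """Predicted probabilities of each rating 1-6 for old and new items."""

    p_old: np.ndarray
    p_new: np.ndarray

    def __post_init__(self):
        p_old = np.asarray(self.p_old, dtype=float)
        p_new = np.asarray(self.p_new, dtype=float)
        for name, p in (("p_old", p_old), ("p_new", p_new)):
            if p.shape != (6,):
                raise ValueError(f"{name} must have shape (6,)")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        object.__setattr__(self, "p_old", p_old)
        object.__setattr__(self, "p_new", p_new)


def params_from_dict(values: dict):
    """Reconstruct a parameter set from a plain key-value mapping.

    Keys follow the serialized names: ``d``/``sigma_o`` (UVSD),
    ``d_prime``/``R`` (DPSD), ``d_A``/``lam`` (MSD), plus ``c1..c5``.
    """
    criteria = tuple(float(values[f"c{i}"]) for i in range(1, 6))
    if "sigma_o" in values:
        return UVSDParams(values["d"], values["sigma_o"], criteria)
    if "R" in values:
        return DPSDParams(values["d_prime"], values["R"], criteria)
    if "lam" in values:
        return MSDParams(values["d_A"], values["lam"], criteria,
                         values.get("d_A_prime", 0.0))
    raise ValueError("cannot identify model family from keys")


# ---------------------------------------------------------------------------
# cumulative ("old" response) probabilities at a single criterion


def uvsd_hit_prob(params: UVSDParams, criterion: float) -> float:
    """P(rating above criterion | old) under UVSD: Phi((d - c)/sigma_o)."""
    return float(ndtr((params.d - criterion) / params.sigma_o))


def fa_prob(criterion: float) -> float:
    """P(rating above criterion | new) = Phi(-c); model independent."""
    return float(ndtr(-np.asarray(criterion, dtype=float)))


def dpsd_hit_prob(params: DPSDParams, criterion: float) -> float:
    """P(hit) under DPSD: R + (1 - R) Phi(d' - c)."""
    return float(params.R + (1.0 - params.R) * ndtr(params.d_prime - criterion))


def msd_hit_prob(params: MSDParams, criterion: float) -> float:
    """P(hit) under MSD: lam Phi(d_A - c) + (1 - lam) Phi(d_A' - c)."""
    return float(
        params.lam * ndtr(params.d_A - criterion)
        + (1.0 - params.lam) * ndtr(params.d_A_prime - criterion)
    )


# ---------------------------------------------------------------------------
# category probabilities and likelihood

def _survival_old(params, c):
    """P(strength > c | old) vectorized over criteria array ``c``."""
    if isinstance(params, UVSDParams):
        return ndtr((params.d - c) / params.sigma_o)
    if isinstance(params, DPSDParams):
        return params.R + (1.0 - params.R) * ndtr(params.d_prime - c)
    if isinstance(params, MSDParams):
        return params.lam * ndtr(params.d_A - c) + (1.0 - params.lam) * ndtr(
            params.d_A_prime - c
        )
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def category_probs(params) -> CategoryProbs:
    """Rating-category probabilities by differencing cumulative curves.

    With c0 = -inf and c6 = +inf, category j has probability
    S(c_{j-1}) - S(c_j) where S is the survival ("old response") curve
    of the relevant distribution.  For DPSD the recollection mass R
    falls entirely in the top category (recollected items are judged
    old with the highest confidence).
    """
    c = np.asarray(params.criteria, dtype=float)
    s_old = np.concatenate(([1.0], _survival_old(params, c), [0.0]))
    s_new = np.concatenate(([1.0], ndtr(-c), [0.0]))
    p_old = -np.diff(s_old)
    p_new = -np.diff(s_new)
    # guard tiny negative values from floating cancellation
    p_old = np.clip(p_old, 0.0, None)
    p_new = np.clip(p_new, 0.0, None)
    return CategoryProbs(p_old / p_old.sum(), p_new / p_new.sum())


def _floored(p, floor=PROB_FLOOR):
    p = np.clip(p, floor, None)
    return p / p.sum()


def log_likelihood(counts: RatingCounts, params, floor: float = PROB_FLOOR) -> float:
    """Multinomial log-likelihood of a 2 x 6 count table under a model.

    Cell probabilities are floored at ``floor`` and renormalized so the
    result is always finite.  The multinomial coefficient is omitted (it
    does not depend on the parameters).  Zero-trial tables give 0.
    """
    probs = category_probs(params)
    old, new = counts.as_arrays()
    ll = 0.0
    if old.sum() > 0:
        ll += float(old @ np.log(_floored(probs.p_old, floor)))
    if new.sum() > 0:
        ll += float(new @ np.log(_floored(probs.p_new, floor)))
    return ll


def old_item_variance(params) -> float:
    """Variance of the old-item strength distribution.

    UVSD: sigma_o**2.  MSD: mixture variance
    ``lam (1 + d_A^2) + (1 - lam)(1 + d_A'^2) - mean^2`` which for
    d_A' = 0 reduces to ``1 + lam (1 - lam) d_A^2`` — equal to 1 (the
    EVSD case) at lam in {0, 1} and maximal at lam = 0.5.  DPSD is
    rejected: the model leaves the recollection distribution's shape
    unspecified, so its old-item variance is undefined.
    """
    if isinstance(params, UVSDParams):
        return params.sigma_o**2
    if isinstance(params, MSDParams):
        lam, a, b = params.lam, params.d_A, params.d_A_prime
        mean = lam * a + (1.0 - lam) * b
        return lam * (1.0 + a**2) + (1.0 - lam) * (1.0 + b**2) - mean**2
    if isinstance(params, DPSDParams):
        raise ValueError(
            "old-item variance is undefined for DPSD: the recollection "
            "distribution's shape is unspecified"
        )
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def evsd_params(d: float, criteria) -> UVSDParams:
    """Equal-variance special case as a UVSD parameter set (sigma_o = 1)."""
    return UVSDParams(d, 1.0, criteria)


# ---------------------------------------------------------------------------
# Model classes (statsmodels-style)


class SignalDetectionModel:
    """Base class binding a rating-count table to one model family.

    Subclasses set ``model_name`` and ``param_class``.  ``fit`` performs
    seeded multi-start maximum-likelihood estimation (see
    :func:`sdtmem.fitting.fit_model`) and returns a
    :class:`~sdtmem.fitting.FitResult`.
    """

    model_name: str = None
    param_class = None

    def __init__(self, counts: RatingCounts):
        if not isinstance(counts, RatingCounts):
            counts = RatingCounts(*counts)
        if counts.total_old < 1 or counts.total_new < 1:
            raise ValueError("need at least one old and one new trial")
        self.counts = counts

    @classmethod
    def from_trials(cls, trials, participant=None, condition=None):
        """Build the model from a trial table (see :mod:`sdtmem.data`)."""
        return cls(aggregate_counts(trials, participant, condition))

    def loglike(self, params) -> float:
        return log_likelihood(self.counts, params)

    def predict(self, params) -> CategoryProbs:
        return category_probs(params)

    def fit(self, n_starts: int = 20, seed: int = 0, **options):
        from . import fitting

        return fitting.fit_model(
            self.counts, self.model_name, n_starts=n_starts, seed=seed, **options
        )


class UVSDModel(SignalDetectionModel):
    model_name = "UVSD"
    param_class = UVSDParams


class DPSDModel(SignalDetectionModel):
    model_name = "DPSD"
    param_class = DPSDParams


class MSDModel(SignalDetectionModel):
    model_name = "MSD"
    param_class = MSDParams


MODEL_CLASSES = {"UVSD": UVSDModel, "DPSD": DPSDModel, "MSD": MSDModel}
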