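"""Maximum-likelihood fitting of signal-detection models and G2 model
comparison.

Each model (UVSD, DPSD, MSD with d_A' = 0) has 7 free parameters on
6-category data: 5 ordered criteria plus 2 strength/variance parameters.
The multinomial likelihood is maximized over an unconstrained transform:

* criteria as (c1, log-increments) — enforces strict ordering,
* sigma_o as log — enforces positivity,
* R and lam via logit — enforces [0, 1],
* d, d', d_A box-bounded in [-5, 25] (the MSD d_A blow-up degeneracy is
  capped at the bound and reported as a boundary fit).

Multi-start local search (seeded, deterministic) guards against the
multimodality of the DPSD/MSD likelihoods: criteria start from the
probit of the observed new-item cumulative proportions, strength
parameters are jittered across starts.

Goodness of fit uses the likelihood-ratio statistic
``G2 = 2 sum O ln(O/E)`` over the 12 cells, chi-square distributed with
df = 2*(6-1) - 7 = 3 under the fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, ndtr, ndtri
from scipy.stats import chi2

from .data import RatingCounts, aggregate_counts
from .models import (
    PROB_FLOOR,
    CategoryProbs,
    DPSDParams,
    MSDParams,
    UVSDParams,
    category_probs,
    log_likelihood,
)

__all__ = [
    "FitResult",
    "FitError",
    "fit_model",
    "fit_trials",
    "g_squared",
    "saturated_loglik",
    "compare_models",
    "flag_outliers",
    "MODEL_NAMES",
    "DF_FIT",
    "STRENGTH_BOUNDS",
    "SIGMA_BOUNDS",
]

MODEL_NAMES = ("UVSD", "DPSD", "MSD")
#: residual degrees of freedom: 2 classes x (6 - 1) free cells - 7 parameters
DF_FIT = 3
STRENGTH_BOUNDS = (-5.0, 25.0)
SIGMA_BOUNDS = (0.1, 10.0)
_LOGIT_BOUND = 15.0
_MIN_INC, _MAX_INC = 1e-3, 8.0


class FitError(RuntimeError):
    """Raised when no optimization start converges."""


@dataclass(frozen=True)
class FitResult:
    """Fitted model for one rating-count table (results object).

    Attributes
    ----------
    params : UVSDParams | DPSDParams | MSDParams
        Maximum-likelihood estimates.
    loglik : float
        Maximized multinomial log-likelihood (constant omitted).
    g_squared, df, p_value : float, int, float
        Likelihood-ratio goodness of fit against the saturated model.
    boundary : bool
        True if a strength/variance parameter landed on a search bound
        (e.g. the d_A blow-up degeneracy of MSD).
    """

    model_name: str
    params: object
    loglik: float
    g_squared: float
    df: int
    p_value: float
    n_starts: int
    converged: bool
    best_start_seed: int
    boundary: bool
    counts: RatingCounts = field(repr=False, compare=False, default=None)

    @property
    def rejected(self) -> bool:
        """Fit rejected at the conventional p < .05 level."""
        return self.p_value < 0.05

    def expected_counts(self) -> CategoryProbs:
        probs = category_probs(self.params)
        return (
            probs.p_old * self.counts.total_old,
            probs.p_new * self.counts.total_new,
        )

    def predict(self) -> CategoryProbs:
        return category_probs(self.params)

    def summary(self) -> str:
        lines = [
            f"{self.model_name} model fit (multinomial MLE)",
            "=" * 44,
            f"{'log-likelihood':<22}{self.loglik:>12.4f}",
            f"{'G2':<22}{self.g_squared:>12.4f}",
            f"{'df':<22}{self.df:>12d}",
            f"{'p (chi2)':<22}{self.p_value:>12.4f}",
            f"{'n trials (old/new)':<22}"
            f"{self.counts.total_old:>6d}/{self.counts.total_new:<5d}",
            f"{'starts / converged':<22}{self.n_starts:>6d}/{str(self.converged):<5}",
            "-" * 44,
        ]
        for name, value in self.params.to_dict().items():
            lines.append(f"{name:<22}{value:>12.4f}")
        if self.boundary:
            lines.append("warning: parameter at search bound")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# objective over the transformed parameter space


def _criteria_from_x(x):
    return x[0] + np.concatenate(([0.0], np.cumsum(np.exp(x[1:5]))))


def _params_from_x(model_name, x):
    criteria = tuple(_criteria_from_x(x))
    if model_name == "UVSD":
        return UVSDParams(x[5], math.exp(x[6]), criteria)
    if model_name == "DPSD":
        return DPSDParams(x[5], expit(x[6]), criteria)
    if model_name == "MSD":
        return MSDParams(x[5], expit(x[6]), criteria)
    raise ValueError(f"unknown model {model_name!r}")


def _make_objective(model_name, counts: RatingCounts, floor):
    old, new = counts.as_arrays()

    def nll(x):
        c = _criteria_from_x(x)
        s_new = np.empty(7)
        s_new[0], s_new[6] = 1.0, 0.0
        s_new[1:6] = ndtr(-c)
        s_old = np.empty(7)
        s_old[0], s_old[6] = 1.0, 0.0
        if model_name == "UVSD":
            s_old[1:6] = ndtr((x[5] - c) / math.exp(x[6]))
        elif model_name == "DPSD":
            r = expit(x[6])
            s_old[1:6] = r + (1.0 - r) * ndtr(x[5] - c)
        else:  # MSD, d_A' = 0
            lam = expit(x[6])
            s_old[1:6] = lam * ndtr(x[5] - c) + (1.0 - lam) * ndtr(-c)
        p_old = np.clip(-np.diff(s_old), floor, None)
        p_new = np.clip(-np.diff(s_new), floor, None)
        p_old /= p_old.sum()
        p_new /= p_new.sum()
        return -(old @ np.log(p_old) + new @ np.log(p_new))

    return nll


def _start_point(model_name, counts: RatingCounts):
    """Heuristic start: criteria from probit of new-item cumulative
    proportions; strength from the probit difference at the midpoint."""
    old, new = counts.as_arrays()
    n_new, n_old = new.sum(), old.sum()
    eps_new = 1.0 / (2.0 * n_new)
    cum_new = np.clip(np.cumsum(new)[:5] / n_new, eps_new, 1.0 - eps_new)
    z = ndtri(cum_new)
    # enforce strict ordering before taking log-increments
    for i in range(1, 5):
        z[i] = max(z[i], z[i - 1] + 5 * _MIN_INC)
    inc = np.clip(np.diff(z), 5 * _MIN_INC, _MAX_INC - 1e-6)

    eps_old = 1.0 / (2.0 * n_old)
    hit = np.clip(old[3:].sum() / n_old, eps_old, 1.0 - eps_old)
    fa = np.clip(new[3:].sum() / n_new, eps_new, 1.0 - eps_new)
    d0 = float(np.clip(ndtri(hit) - ndtri(fa), 0.1, 5.0))

    x = np.empty(7)
    x[0] = z[0]
    x[1:5] = np.log(inc)
    if model_name == "UVSD":
        x[5], x[6] = d0, math.log(1.25)
    elif model_name == "DPSD":
        x[5], x[6] = 0.7 * d0, logit(0.2)
    else:
        x[5], x[6] = max(d0 / 0.6, 0.5), logit(0.6)
    return x


def _bounds(model_name):
    b = [(-8.0, 8.0)] + [(math.log(_MIN_INC), math.log(_MAX_INC))] * 4
    b.append(STRENGTH_BOUNDS)
    if model_name == "UVSD":
        b.append((math.log(SIGMA_BOUNDS[0]), math.log(SIGMA_BOUNDS[1])))
    else:
        b.append((-_LOGIT_BOUND, _LOGIT_BOUND))
    return b


def fit_model(
    counts: RatingCounts,
    model_name: str,
    n_starts: int = 20,
    seed: int = 0,
    floor: float = PROB_FLOOR,
    tol: float = 1e-8,
    maxiter: int = 2000,
) -> FitResult:
    """Fit one model to one 2 x 6 count table by multi-start MLE.

    Deterministic given ``seed``: the first start is the data-driven
    heuristic, the remaining ``n_starts - 1`` jitter it with seeded
    Gaussian noise.  Raises :class:`FitError` if every start fails.
    """
    model_name = model_name.upper()
    if model_name not in MODEL_NAMES:
        raise ValueError(f"model_name must be one of {MODEL_NAMES}")
    if not isinstance(counts, RatingCounts):
        counts = RatingCounts(*counts)
    if counts.total_old < 1 or counts.total_new < 1:
        raise ValueError("need at least one old and one new trial")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    nll = _make_objective(model_name, counts, floor)
    x0 = _start_point(model_name, counts)
    bounds = _bounds(model_name)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    jitter_scale = np.array([0.25, 0.3, 0.3, 0.3, 0.3, 0.6, 0.8])

    best = None
    best_f = np.inf
    best_start = -1
    any_success = False
    for k in range(n_starts):
        xk = x0 if k == 0 else np.clip(
            x0 + rng.normal(0.0, jitter_scale), lo + 1e-9, hi - 1e-9
        )
        try:
            res = optimize.minimize(
                nll,
                xk,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol * 1e-2, "gtol": 1e-8},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best_f:
            best, best_f, best_start = res, res.fun, k

    if best is None:
        raise FitError(
            f"{model_name}: all {n_starts} starts failed on counts "
            f"{counts.n_old}/{counts.n_new}"
        )

    params = _params_from_x(model_name, best.x)
    loglik = -best_f
    g2, df, p = g_squared(counts, category_probs(params), floor=floor)
    boundary = bool(
        abs(best.x[5] - STRENGTH_BOUNDS[1]) < 1e-6
        or abs(best.x[5] - STRENGTH_BOUNDS[0]) < 1e-6
        or (model_name == "UVSD" and min(abs(best.x[6] - math.log(SIGMA_BOUNDS[0])),
                                         abs(best.x[6] - math.log(SIGMA_BOUNDS[1]))) < 1e-6)
    )
    return FitResult(
        model_name=model_name,
        params=params,
        loglik=loglik,
        g_squared=g2,
        df=df,
        p_value=p,
        n_starts=n_starts,
        converged=bool(best.success or any_success),
        best_start_seed=best_start,
        boundary=boundary,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# goodness of fit


def saturated_loglik(counts: RatingCounts) -> float:
    """Log-likelihood of the saturated model (observed proportions)."""
    ll = 0.0
    for vec in counts.as_arrays():
        n = vec.sum()
        if n > 0:
            nz = vec[vec > 0]
            ll += float(nz @ np.log(nz / n))
    return ll


def g_squared(observed: RatingCounts, expected: CategoryProbs, floor: float = PROB_FLOOR):
    """Likelihood-ratio GOF: ``G2 = 2 sum O ln(O/E)`` over 12 cells.

    ``expected`` holds predicted category probabilities; expected counts
    are probability x class total.  Cells with O = 0 contribute 0.
    Probabilities are floored exactly as in the likelihood, so
    ``G2 == 2 * (loglik_saturated - loglik_model)`` holds identically.
    Returns ``(statistic, df, p)`` with df = 3 and p from chi-square.
    """
    if not isinstance(observed, RatingCounts):
        observed = RatingCounts(*observed)
    if observed.total_old == 0 and observed.total_new == 0:
        raise ValueError("observed totals must be positive")

    def _clamped(p):
        p = np.clip(np.asarray(p, dtype=float), floor, None)
        return p / p.sum()

    g2 = 0.0
    for obs, p in (
        (observed.as_arrays()[0], _clamped(expected.p_old)),
        (observed.as_arrays()[1], _clamped(expected.p_new)),
    ):
        n = obs.sum()
        if n == 0:
            continue
        e = p * n
        nz = obs > 0
        g2 += 2.0 * float(obs[nz] @ np.log(obs[nz] / e[nz]))
    g2 = max(g2, 0.0)
    return g2, DF_FIT, float(chi2.sf(g2, DF_FIT))


# ---------------------------------------------------------------------------
# batch fitting and model comparison


def fit_trials(
    trials: pd.DataFrame,
    models=MODEL_NAMES,
    level: str = "participant",
    n_starts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit models to every participant x condition table of a trial file.

    ``level="aggregate"`` pools counts across participants within each
    condition before fitting.  Returns a tidy DataFrame (one row per
    fit) with parameter columns named as serialized (d, sigma_o,
    d_prime, R, d_A, lam, c1..c5).
    """
    if level not in ("participant", "aggregate"):
        raise ValueError("level must be 'participant' or 'aggregate'")
    rows = []
    conditions = sorted(trials["condition"].unique(), key=str)
    if level == "participant":
        units = [
            (p, c)
            for p in sorted(trials["participant"].unique(), key=str)
            for c in conditions
        ]
    else:
        units = [(None, c) for c in conditions]
    for participant, condition in units:
        counts = aggregate_counts(trials, participant, condition)
        for i, model in enumerate(models):
            fit = fit_model(counts, model, n_starts=n_starts, seed=seed + 7919 * i)
            row = {
                "participant": "aggregate" if participant is None else participant,
                "condition": condition,
                "model": fit.model_name,
                "loglik": fit.loglik,
                "g_squared": fit.g_squared,
                "df": fit.df,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "boundary": fit.boundary,
            }
            row.update(fit.params.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def compare_models(fits, tie_tol: float = 1e-6) -> pd.DataFrame:
    """Participant-level model-comparison table.

    ``fits`` maps participant -> {model_name: FitResult} (every
    participant must carry one fit per model).  Returns a DataFrame
    indexed by model with the summed G2, the percentage of participants
    best fit (lowest G2; ties within ``tie_tol`` split fractionally),
    and the percentage of fits rejected at p < .05.
    """
    participants = list(fits)
    if not participants:
        raise ValueError("no fits supplied")
    missing = {
        p: sorted(set(MODEL_NAMES) - set(fits[p]))
        for p in participants
        if set(MODEL_NAMES) - set(fits[p])
    }
    if missing:
        raise ValueError(f"missing fits for participants: {missing}")

    sum_g2 = {m: 0.0 for m in MODEL_NAMES}
    best = {m: 0.0 for m in MODEL_NAMES}
    rejected = {m: 0 for m in MODEL_NAMES}
    for p in participants:
        g2s = {m: fits[p][m].g_squared for m in MODEL_NAMES}
        lo = min(g2s.values())
        winners = [m for m in MODEL_NAMES if g2s[m] <= lo + tie_tol]
        for m in MODEL_NAMES:
            sum_g2[m] += g2s[m]
            if m in winners:
                best[m] += 1.0 / len(winners)
            if fits[p][m].p_value < 0.05:
                rejected[m] += 1
    n = len(participants)
    return pd.DataFrame(
        {
            "sum_g2": [sum_g2[m] for m in MODEL_NAMES],
            "pct_best": [100.0 * best[m] / n for m in MODEL_NAMES],
            "pct_rejected": [100.0 * rejected[m] / n for m in MODEL_NAMES],
        },
        index=pd.Index(MODEL_NAMES, name="model"),
    )


def flag_outliers(fits, threshold: float = 10.0):
    """Partition MSD fits by the d_A > threshold outlier rule.

    ``fits`` maps participant -> FitResult (MSD).  Fits at the d_A
    search bound count as outliers (the bound stands in for the
    unbounded blow-up).  Returns ``(flagged, retained)`` participant
    lists, supporting listwise exclusion in paired analyses.
    """
    flagged, retained = [], []
    for p, fit in fits.items():
        if fit.model_name != "MSD":
            raise ValueError("flag_outliers applies to MSD fits only")
        if fit.params.d_A > threshold or fit.boundary:
            flagged.append(p)
        else:
            retained.append(p)
    return flagged, retained
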