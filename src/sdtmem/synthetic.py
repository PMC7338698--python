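"""Synthetic recognition experiments with controlled encoding variability.

This module generates trial-level confidence-rating data with the
statistical structure of three within-subject encoding-variability
manipulations:

1. **Study duration** — old items studied for a fixed 3,000 ms vs. for
   durations drawn from a truncated normal N(3000, 1100) on
   [500, 5500] ms whose sum is constrained to the fixed-condition total
   (390 s over 130 trials) and which must pass composite
   Kolmogorov-Smirnov and Anderson-Darling normality checks.
2. **Attention (one-back distractor task)** — auditory digits at fixed
   3,500 ms intervals (synchronised with trials) vs. intervals drawn
   from a truncated normal N(3500, 1100) on [1000, 6000] ms summing to
   the session length (455 s); the digit count per trial (0-3) is the
   attentional covariate.
3. **Word frequency** — Zipf scores of study/test words with low
   variance (mean 3.48, range 3.41-3.59) vs. high variance (mean 3.5,
   SD 1, range 1.17-5.84, truncated-normal shaped).

Under the encoding-variability hypothesis an old item's strength is the
sum of a baseline component B ~ N(mu_B, sigma_B) and an added component
Y ~ N(mu_Y, sigma_Y) with correlation rho, giving old-item variance
``sigma_B^2 + sigma_Y^2 + 2 rho sigma_Y sigma_B``.  Strengths can also
be generated directly from UVSD/DPSD/MSD parameter sets, and cohorts of
participants from population distributions of those parameters.

All samplers are bit-reproducible given their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import kstest, truncnorm
from statsmodels.stats.diagnostic import normal_ad

from .models import DPSDParams, MSDParams, UVSDParams

__all__ = [
    "EncodingSpec",
    "DesignSpec",
    "CohortSpec",
    "ConstraintError",
    "sample_strengths",
    "strengths_to_ratings",
    "sample_constrained_durations",
    "schedule_digits",
    "sample_zipf",
    "zipf_to_per_million",
    "per_million_to_zipf",
    "saturating_link",
    "linear_link",
    "generate_experiment",
    "simulate_experiment",
    "experiment_designs",
    "default_cohort",
    "TABLE_PARAMS",
    "DURATION_LINK_GAIN",
    "ZIPF_LINK_GAIN",
]


class ConstraintError(RuntimeError):
    """Raised when a constrained sampler exhausts its retry budget."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class EncodingSpec:
    """Baseline + added strength construction for old items.

    New-item strengths use the baseline component only.  ``rho`` is the
    correlation between an old item's baseline and added strengths.
    """

    mu_baseline: float = 0.0
    sigma_baseline: float = 1.0
    mu_added: float = 1.0
    sigma_added: float = 0.5
    rho: float = 0.0

    def __post_init__(self):
        if not self.sigma_baseline > 0:
            raise ValueError("sigma_baseline must be positive")
        if self.sigma_added < 0:
            raise ValueError("sigma_added must be nonnegative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def old_variance(self) -> float:
        """sigma_B^2 + sigma_Y^2 + 2 rho sigma_Y sigma_B."""
        return (
            self.sigma_baseline**2
            + self.sigma_added**2
            + 2.0 * self.rho * self.sigma_added * self.sigma_baseline
        )


@dataclass(frozen=True)
class DesignSpec:
    """One condition's trial counts and covariate-sampling scheme.

    ``covariate`` selects the scheme: ``"duration"`` (constrained
    truncated-normal study durations), ``"digits"`` (distractor-digit
    schedule from constrained inter-digit intervals), ``"zipf"``
    (truncated-normal word-frequency scores for old and new items), or
    ``None``.  ``fixed_value`` gives the constant covariate of a fixed
    condition (e.g. 3000 ms durations); when set, no sampling happens.
    ``link`` maps the covariate to a shift in the old-item strength
    mean (callable, centred across the condition's covariate set).
    """

    n_old: int = 130
    n_new: int = 130
    covariate: str = None
    fixed_value: float = None
    duration_mean_ms: float = None
    duration_sd_ms: float = None
    duration_lo_ms: float = None
    duration_hi_ms: float = None
    sum_target_ms: float = None
    trial_len_ms: float = 3500.0
    zipf_mean: float = None
    zipf_sd: float = None
    zipf_lo: float = None
    zipf_hi: float = None
    match_sample_sd: bool = False
    normality_alpha: float = 0.05
    link: object = None

    def __post_init__(self):
        if self.n_old <= 0 or self.n_new <= 0:
            raise ValueError("n_old and n_new must be positive")
        if self.covariate not in (None, "duration", "digits", "zipf"):
            raise ValueError(f"unknown covariate scheme {self.covariate!r}")
        for mean, lo, hi in (
            (self.duration_mean_ms, self.duration_lo_ms, self.duration_hi_ms),
            (self.zipf_mean, self.zipf_lo, self.zipf_hi),
        ):
            if mean is not None and lo is not None and hi is not None:
                if not lo < mean < hi:
                    raise ValueError("bounds must straddle the mean (lo < mean < hi)")


@dataclass(frozen=True)
class CohortSpec:
    """Population distribution of model parameters across participants.

    ``param_means``/``param_sds`` use the serialized parameter names of
    the generating model (e.g. d, sigma_o, c1..c5).  Draws are
    truncated to valid ranges: sigma_o >= 0.1, R and lam in [0, 1],
    criteria re-ordered after the draw.
    """

    n_participants: int = 40
    model: str = "UVSD"
    param_means: dict = None
    param_sds: dict = None

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.param_sds is not None and any(v < 0 for v in self.param_sds.values()):
            raise ValueError("population SDs must be nonnegative")


#: Condition means (SDs) of participant-level fits used as cohort
#: defaults: the fixed/low-variance column of the duration experiment.
TABLE_PARAMS = {
    "UVSD": {
        "means": {"d": 1.27, "sigma_o": 1.47, "c1": -1.21, "c2": -0.12,
                  "c3": 0.54, "c4": 1.08, "c5": 1.92},
        "sds": {"d": 1.06, "sigma_o": 0.41, "c1": 1.04, "c2": 0.65,
                "c3": 0.52, "c4": 0.56, "c5": 1.06},
    },
    "DPSD": {
        "means": {"d_prime": 0.56, "R": 0.26, "c1": -1.14, "c2": -0.12,
                  "c3": 0.50, "c4": 1.03, "c5": 2.59},
        "sds": {"d_prime": 0.49, "R": 0.22, "c1": 0.96, "c2": 0.62,
                "c3": 0.50, "c4": 0.53, "c5": 1.99},
    },
    "MSD": {
        "means": {"d_A": 2.60, "lam": 0.58, "c1": -1.25, "c2": -0.14,
                  "c3": 0.52, "c4": 1.08, "c5": 2.20},
        "sds": {"d_A": 1.99, "lam": 0.30, "c1": 1.27, "c2": 0.64,
                "c3": 0.52, "c4": 0.56, "c5": 1.53},
    },
}


def default_cohort(model: str = "UVSD", n_participants: int = 40) -> CohortSpec:
    entry = TABLE_PARAMS[model.upper()]
    return CohortSpec(
        n_participants=n_participants,
        model=model.upper(),
        param_means=dict(entry["means"]),
        param_sds=dict(entry["sds"]),
    )


# ---------------------------------------------------------------------------
# strength generation


def _as_rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_strengths(model, n_old: int, n_new: int, seed=0, added_shift=None):
    """Draw old/new memory-strength vectors from a model or encoding spec.

    For :class:`EncodingSpec`, old strengths are B + Y with
    Corr(B, Y) = rho (bivariate-normal construction) and new strengths
    are independent baseline draws.  For DPSD the returned old
    strengths are the familiarity component; apply recollection through
    ``strengths_to_ratings(..., dpsd_R=R)``.  ``added_shift`` optionally
    shifts the old-item (added-strength) mean per trial, e.g. from a
    covariate link.  Returns ``(old, new)``.
    """
    rng = _as_rng(seed)
    shift = 0.0 if added_shift is None else np.asarray(added_shift, dtype=float)
    if isinstance(model, EncodingSpec):
        s = model
        b_old = rng.normal(s.mu_baseline, s.sigma_baseline, n_old)
        if s.sigma_added > 0 and abs(s.rho) > 0:
            # added strength conditionally on baseline: Corr(B, Y) = rho
            z = rng.normal(0.0, 1.0, n_old)
            y = s.mu_added + s.rho * s.sigma_added / s.sigma_baseline * (
                b_old - s.mu_baseline
            ) + s.sigma_added * math.sqrt(1.0 - s.rho**2) * z
        else:
            y = rng.normal(s.mu_added, s.sigma_added, n_old) if s.sigma_added > 0 else (
                np.full(n_old, s.mu_added)
            )
        old = b_old + y + shift
        new = rng.normal(s.mu_baseline, s.sigma_baseline, n_new)
        return old, new
    if isinstance(model, UVSDParams):
        old = rng.normal(model.d + shift, model.sigma_o, n_old)
        new = rng.normal(0.0, 1.0, n_new)
        return old, new
    if isinstance(model, DPSDParams):
        old = rng.normal(model.d_prime + shift, 1.0, n_old)
        new = rng.normal(0.0, 1.0, n_new)
        return old, new
    if isinstance(model, MSDParams):
        attended = rng.random(n_old) < model.lam
        means = np.where(attended, model.d_A, model.d_A_prime) + shift
        old = rng.normal(means, 1.0)
        new = rng.normal(0.0, 1.0, n_new)
        return old, new
    raise TypeError(f"unsupported generator {type(model).__name__}")


def strengths_to_ratings(
    old_strengths,
    new_strengths,
    criteria,
    dpsd_R: float = None,
    seed=0,
    participant="s1",
    condition="synthetic",
) -> pd.DataFrame:
    """Map strengths to 1-6 confidence ratings via the ordered criteria.

    Rating j corresponds to strength in (c_{j-1}, c_j] with c0 = -inf,
    c6 = +inf.  With ``dpsd_R`` each old item is independently
    recollected with probability R and rated 6 regardless of strength.
    Returns a validated trial table.
    """
    c = np.asarray(criteria, dtype=float)
    if np.any(np.diff(c) <= 0):
        raise ValueError("criteria must be strictly increasing")
    old = np.asarray(old_strengths, dtype=float)
    new = np.asarray(new_strengths, dtype=float)
    r_old = np.searchsorted(c, old, side="left") + 1
    r_new = np.searchsorted(c, new, side="left") + 1
    if dpsd_R is not None:
        rng = _as_rng(seed)
        recollected = rng.random(len(old)) < dpsd_R
        r_old = np.where(recollected, 6, r_old)
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": condition,
            "status": ["old"] * len(old) + ["new"] * len(new),
            "rating": np.concatenate([r_old, r_new]).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# constrained covariate samplers


def _truncnorm_ab(lo, hi, mean, sd):
    return (lo - mean) / sd, (hi - mean) / sd


def _normality_ok(x, alpha):
    """Composite KS and AD tests against a normal with sample-estimated
    mean/SD; both must be non-significant at ``alpha``."""
    m, s = x.mean(), x.std(ddof=1)
    if s == 0:
        return False
    p_ks = kstest(x, "norm", args=(m, s)).pvalue
    _, p_ad = normal_ad(x)
    return p_ks > alpha and p_ad > alpha


def _enforce_sum(x, target, lo, hi, rtol=1e-9):
    """Spread the sum deficit additively, re-clip, iterate; finish with
    an exact residual correction on interior values."""
    x = x.copy()
    for _ in range(200):
        resid = target - x.sum()
        if abs(resid) <= rtol * max(1.0, abs(target)):
            break
        interior = (x > lo) & (x < hi)
        if not interior.any():
            return None
        x[interior] += resid / interior.sum()
        np.clip(x, lo, hi, out=x)
    resid = target - x.sum()
    if abs(resid) > rtol * max(1.0, abs(target)):
        return None
    # exact correction on the single value with the most slack
    slack = np.where(resid > 0, hi - x, x - lo)
    i = int(np.argmax(slack))
    if slack[i] < abs(resid):
        return None
    x[i] += resid
    return x


def sample_constrained_durations(
    spec: DesignSpec, n: int = None, seed=0, max_attempts: int = 1000
) -> np.ndarray:
    """Sample study durations (or inter-digit intervals) under the three
    design constraints: values within [lo, hi]; the sum exactly equal to
    the fixed-condition total; and no significant deviation from
    normality by composite KS and AD tests.

    Rejection-samples candidate sets from the truncated normal, applies
    an additive sum correction with re-clipping, and re-tests; retries
    with fresh sub-seeds up to ``max_attempts``.
    """
    n = spec.n_old if n is None else int(n)
    mean, sd = spec.duration_mean_ms, spec.duration_sd_ms
    lo, hi = spec.duration_lo_ms, spec.duration_hi_ms
    target = spec.sum_target_ms
    if mean is None or lo is None or hi is None:
        raise ValueError("duration_mean_ms / duration_lo_ms / duration_hi_ms required")
    if sd == 0:
        x = np.full(n, float(mean))
        if target is not None and abs(x.sum() - target) > 1e-9 * max(1.0, abs(target)):
            raise ConstraintError("sd=0 sample cannot meet the sum constraint")
        warnings.warn("sd=0: degenerate sample, normality tests skipped")
        return x
    if target is not None and not lo * n <= target <= hi * n:
        raise ConstraintError("sum target infeasible under the bounds")

    rng = _as_rng(seed)
    a, b = _truncnorm_ab(lo, hi, mean, sd)
    for attempt in range(max_attempts):
        x = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        if target is not None:
            x = _enforce_sum(x, target, lo, hi)
            if x is None:
                continue
        if spec.normality_alpha is not None and not _normality_ok(
            x, spec.normality_alpha
        ):
            continue
        return x
    raise ConstraintError(
        f"no sample satisfying all constraints in {max_attempts} attempts "
        f"(n={n}, mean={mean}, sd={sd}, bounds=[{lo}, {hi}], sum={target})"
    )


def schedule_digits(
    intervals, trial_len_ms: float = 3500.0, n_trials: int = 130
) -> np.ndarray:
    """Assign distractor-digit onsets to their enclosing study trials.

    Digit k occurs at the k-th cumulative interval sum from session
    start.  Trial i spans the half-open window
    (i*trial_len, (i+1)*trial_len], so in the synchronised fixed
    condition (every interval equal to the trial length) each trial
    receives exactly one digit.  Onsets beyond the session end are
    dropped with a warning.  Returns digit counts per trial.
    """
    onsets = np.cumsum(np.asarray(intervals, dtype=float))
    session_end = trial_len_ms * n_trials
    dropped = onsets > session_end + 1e-9
    if dropped.any():
        warnings.warn(f"{int(dropped.sum())} digit onset(s) beyond session end dropped")
        onsets = onsets[~dropped]
    # (start, end] windows: ceil(t / L) - 1, clipped for t == 0
    idx = np.maximum(np.ceil(onsets / trial_len_ms - 1e-12).astype(int) - 1, 0)
    counts = np.bincount(idx, minlength=n_trials)
    return counts[:n_trials]


def _solve_parent_sigma(mean, target_sd, lo, hi):
    """Parent normal SD whose truncation to [lo, hi] has SD target_sd."""

    def f(s):
        a, b = _truncnorm_ab(lo, hi, mean, s)
        return truncnorm.std(a, b, loc=mean, scale=s) - target_sd

    hi_s = target_sd * 5.0
    if f(hi_s) < 0:  # truncation cannot reach the target
        raise ConstraintError("target SD unreachable inside the bounds")
    return optimize.brentq(f, target_sd * 0.2, hi_s, xtol=1e-10)


def sample_zipf(spec: DesignSpec, n: int = None, seed=0, max_attempts: int = 1000):
    """Sample word-frequency Zipf scores from a truncated normal.

    With ``match_sample_sd`` the parent SD is solved so the *truncated*
    distribution's SD equals ``zipf_sd`` (the high-variance sets report
    their realised SD of ~1 inside bounds of about +/-2.3 SD).  The
    normality constraint (composite KS and AD, p > alpha) applies when
    ``normality_alpha`` is set; retries use fresh sub-seeds.
    """
    n = spec.n_old if n is None else int(n)
    mean, sd = spec.zipf_mean, spec.zipf_sd
    lo, hi = spec.zipf_lo, spec.zipf_hi
    if mean is None or sd is None or lo is None or hi is None:
        raise ValueError("zipf_mean/zipf_sd/zipf_lo/zipf_hi required")
    parent_sd = _solve_parent_sigma(mean, sd, lo, hi) if spec.match_sample_sd else sd
    rng = _as_rng(seed)
    a, b = _truncnorm_ab(lo, hi, mean, parent_sd)
    for attempt in range(max_attempts):
        x = truncnorm.rvs(a, b, loc=mean, scale=parent_sd, size=n, random_state=rng)
        if spec.normality_alpha is not None and not _normality_ok(
            x, spec.normality_alpha
        ):
            continue
        return x
    raise ConstraintError(f"no normal-looking Zipf sample in {max_attempts} attempts")


def zipf_to_per_million(zipf) -> float:
    """Occurrences per million words: 10**(zipf - 3)."""
    return float(10.0 ** (np.asarray(zipf, dtype=float) - 3.0))


def per_million_to_zipf(freq_per_million) -> float:
    """Zipf score: log10(occurrences per million) + 3."""
    return float(np.log10(np.asarray(freq_per_million, dtype=float)) + 3.0)


# ---------------------------------------------------------------------------
# covariate links

#: Gain of the default saturating duration link, calibrated by
#: simulation (10 cohorts of 40 participants) so the mean
#: per-participant duration-rating correlation in the variable-duration
#: condition is ~.05 (the observed value).
DURATION_LINK_GAIN = 0.8
#: Slope (per Zipf unit) of the default linear word-frequency link,
#: calibrated likewise so the mean per-participant Zipf-rating
#: correlation in the high-variance condition is ~-.10.
ZIPF_LINK_GAIN = -0.155


def saturating_link(gain: float, tau: float = 1500.0):
    """Negatively accelerated covariate link: gain * (1 - exp(-x/tau)).

    Mirrors the saturating relation between study duration and memory
    accuracy; ``tau`` is the duration scale in ms.
    """

    def link(x):
        return gain * (1.0 - np.exp(-np.asarray(x, dtype=float) / tau))

    return link


def linear_link(slope: float):
    def link(x):
        return slope * np.asarray(x, dtype=float)

    return link


# ---------------------------------------------------------------------------
# experiment presets and cohort generation


def experiment_designs(experiment: int) -> dict:
    """The two within-subject condition designs of each experiment."""
    if experiment == 1:
        return {
            "fixed": DesignSpec(covariate="duration", fixed_value=3000.0,
                                link=saturating_link(DURATION_LINK_GAIN)),
            "variable": DesignSpec(
                covariate="duration",
                duration_mean_ms=3000.0,
                duration_sd_ms=1100.0,
                duration_lo_ms=500.0,
                duration_hi_ms=5500.0,
                sum_target_ms=3000.0 * 130,
                link=saturating_link(DURATION_LINK_GAIN),
            ),
        }
    if experiment == 2:
        return {
            "fixed": DesignSpec(covariate="digits", fixed_value=3500.0,
                                trial_len_ms=3500.0),
            "variable": DesignSpec(
                covariate="digits",
                duration_mean_ms=3500.0,
                duration_sd_ms=1100.0,
                duration_lo_ms=1000.0,
                duration_hi_ms=6000.0,
                sum_target_ms=3500.0 * 130,
                trial_len_ms=3500.0,
            ),
        }
    if experiment == 3:
        return {
            "low_variance": DesignSpec(
                n_old=100, n_new=100, covariate="zipf",
                zipf_mean=3.48, zipf_sd=0.05, zipf_lo=3.41, zipf_hi=3.59,
                normality_alpha=None,
                link=linear_link(ZIPF_LINK_GAIN),
            ),
            "high_variance": DesignSpec(
                n_old=100, n_new=100, covariate="zipf",
                zipf_mean=3.5, zipf_sd=1.0, zipf_lo=1.17, zipf_hi=5.84,
                match_sample_sd=True,
                link=linear_link(ZIPF_LINK_GAIN),
            ),
        }
    raise ValueError("experiment must be 1, 2 or 3")


def _draw_participant_params(cohort: CohortSpec, rng):
    """One truncated population draw of the cohort's generating model."""
    means, sds = cohort.param_means, cohort.param_sds
    draw = {k: rng.normal(means[k], sds.get(k, 0.0)) for k in means}
    c = np.sort([draw[f"c{i}"] for i in range(1, 6)])
    for i in range(1, 5):  # re-impose strict ordering after the draw
        c[i] = max(c[i], c[i - 1] + 1e-3)
    criteria = tuple(c)
    model = cohort.model.upper()
    if model == "UVSD":
        return UVSDParams(float(np.clip(draw["d"], -5, 25)),
                          float(max(draw["sigma_o"], 0.1)), criteria)
    if model == "DPSD":
        return DPSDParams(float(np.clip(draw["d_prime"], -5, 25)),
                          float(np.clip(draw["R"], 0.0, 1.0)), criteria)
    if model == "MSD":
        return MSDParams(float(np.clip(draw["d_A"], -5, 25)),
                         float(np.clip(draw["lam"], 0.0, 1.0)), criteria)
    raise ValueError(f"unknown cohort model {cohort.model!r}")


def _condition_covariates(design: DesignSpec, rng):
    """Frozen covariate set for one condition (shared by participants).

    Returns ``(per_trial_values, column_name)`` for the old items, or
    ``(None, None)`` when the design has no covariate.
    """
    if design.covariate is None:
        return None, None
    if design.covariate == "duration":
        if design.fixed_value is not None:
            return np.full(design.n_old, float(design.fixed_value)), "duration_ms"
        child = np.random.default_rng(rng.integers(2**31))
        return sample_constrained_durations(design, design.n_old, child), "duration_ms"
    if design.covariate == "digits":
        if design.fixed_value is not None:
            intervals = np.full(design.n_old, float(design.fixed_value))
        else:
            child = np.random.default_rng(rng.integers(2**31))
            intervals = sample_constrained_durations(design, design.n_old, child)
        counts = schedule_digits(intervals, design.trial_len_ms, design.n_old)
        return counts.astype(float), "digit_count"
    if design.covariate == "zipf":
        child = np.random.default_rng(rng.integers(2**31))
        return sample_zipf(design, design.n_old, child), "zipf"
    raise ValueError(design.covariate)


def generate_experiment(
    cohort: CohortSpec,
    designs,
    generator=None,
    seed=0,
) -> pd.DataFrame:
    """Generate a full within-subject synthetic experiment.

    ``designs`` maps condition name -> :class:`DesignSpec` (or is a
    single spec, labelled "condition").  ``generator`` overrides the
    per-participant generating process: an :class:`EncodingSpec` (whose
    baseline/added construction replaces the strength model but keeps
    the cohort's criteria), or None to generate from the cohort's
    parameter draws directly.  Each participant's parameters are drawn
    once and reused in every condition (a null cohort); the covariate
    set is frozen per condition and its assignment to trials shuffled
    per participant.  Covariates shift the old-item strength mean
    through the design's (centred) link.  Returns a validated trial
    table.
    """
    from .data import validate_trials

    if isinstance(designs, DesignSpec):
        designs = {"condition": designs}
    rng = np.random.default_rng(seed)
    cond_covariates = {
        name: _condition_covariates(spec, rng) for name, spec in designs.items()
    }
    frames = []
    for p in range(cohort.n_participants):
        params = _draw_participant_params(cohort, rng)
        pid = f"p{p+1:03d}"
        for name, design in designs.items():
            cov, colname = cond_covariates[name]
            if cov is not None:
                cov = rng.permutation(cov)
                shift = None
                if design.link is not None:
                    raw = design.link(cov)
                    shift = raw - raw.mean()
            else:
                shift = None
            gen = generator if generator is not None else params
            old, new = sample_strengths(
                gen, design.n_old, design.n_new, rng, added_shift=shift
            )
            dpsd_R = params.R if isinstance(params, DPSDParams) and generator is None else None
            trials = strengths_to_ratings(
                old, new, params.criteria, dpsd_R=dpsd_R, seed=rng,
                participant=pid, condition=name,
            )
            if cov is not None:
                col = np.full(len(trials), np.nan)
                col[: design.n_old] = cov
                if colname == "zipf":
                    # new items carry a matched frequency distribution
                    child = np.random.default_rng(rng.integers(2**31))
                    col[design.n_old:] = rng.permutation(
                        cond_covariates[name][0]
                    ) if design.n_new == design.n_old else sample_zipf(
                        design, design.n_new, child
                    )
                trials[colname] = col
            frames.append(trials)
    return validate_trials(pd.concat(frames, ignore_index=True))


def simulate_experiment(
    experiment: int = 1,
    generator: str = "uvsd",
    n_participants: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: preset designs + default cohort.

    ``generator`` is one of ``uvsd``/``dpsd``/``msd`` (cohort draws from
    the corresponding population) or ``encoding`` (baseline + added
    construction with the UVSD cohort's criteria).
    """
    designs = experiment_designs(experiment)
    if generator.lower() == "encoding":
        cohort = default_cohort("UVSD", n_participants)
        return generate_experiment(
            cohort, designs, generator=EncodingSpec(mu_added=1.2, sigma_added=1.0),
            seed=seed,
        )
    cohort = default_cohort(generator.upper(), n_participants)
    return generate_experiment(cohort, designs, seed=seed)
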