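"""Trial-level recognition data and rating-count tables.

The unit of analysis is a 2 x 6 table of confidence-rating counts
(:class:`RatingCounts`): for each item class (old / new), the number of
responses at each confidence level 1-6 on the scale
``1 = sure new ... 6 = sure old``.  Trial-level data are kept as plain
pandas DataFrames with a small validated schema (the "trial table"):

========== ========= =======================================================
column     dtype     meaning
========== ========= =======================================================
participant any      participant identifier
condition   any      condition label (e.g. ``fixed`` / ``variable``)
status      str      item class, ``old`` or ``new``
rating      int      confidence rating, integer in [1, 6]
duration_ms float    optional: exposure duration of the studied item (ms)
digit_count int      optional: distractor digits during the study trial
zipf        float    optional: Zipf word-frequency score, roughly [1, 7]
========== ========= =======================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatingCounts",
    "TrialValidationError",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "N_CATEGORIES",
    "validate_trials",
    "read_trials",
    "write_trials",
    "aggregate_counts",
    "counts_to_frame",
    "hit_fa_rates",
]

N_CATEGORIES = 6
REQUIRED_COLUMNS = ("participant", "condition", "status", "rating")
OPTIONAL_COLUMNS = ("duration_ms", "digit_count", "zipf")
_STATUS_VALUES = ("old", "new")


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema invariants."""


@dataclass(frozen=True)
class RatingCounts:
    """Response counts of one participant/condition: old/new x rating 1-6."""

    n_old: tuple
    n_new: tuple

    def __post_init__(self):
        n_old = tuple(int(x) for x in self.n_old)
        n_new = tuple(int(x) for x in self.n_new)
        for name, vec, raw in (("n_old", n_old, self.n_old), ("n_new", n_new, self.n_new)):
            if len(vec) != N_CATEGORIES:
                raise ValueError(f"{name} must have {N_CATEGORIES} entries, got {len(vec)}")
            arr = np.asarray(raw, dtype=float)
            if np.any(arr < 0) or np.any(arr != np.round(arr)):
                raise ValueError(f"{name} must contain nonnegative integers")
        object.__setattr__(self, "n_old", n_old)
        object.__setattr__(self, "n_new", n_new)

    @property
    def total_old(self) -> int:
        return int(sum(self.n_old))

    @property
    def total_new(self) -> int:
        return int(sum(self.n_new))

    @property
    def total(self) -> int:
        return self.total_old + self.total_new

    def as_arrays(self):
        return np.asarray(self.n_old, dtype=float), np.asarray(self.n_new, dtype=float)

    def __add__(self, other: "RatingCounts") -> "RatingCounts":
        return RatingCounts(
            tuple(a + b for a, b in zip(self.n_old, other.n_old)),
            tuple(a + b for a, b in zip(self.n_new, other.n_new)),
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema, returning a clean copy.

    Raises :class:`TrialValidationError` naming offending rows (0-based
    positional row numbers) for out-of-range ratings or unknown status
    values, and for missing mandatory columns.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    out = trials.copy()

    rating = pd.to_numeric(out["rating"], errors="coerce")
    bad = rating.isna() | (rating != np.floor(rating)) | (rating < 1) | (rating > N_CATEGORIES)
    if bad.any():
        rows = [int(i) for i in np.flatnonzero(bad.to_numpy())[:20]]
        raise TrialValidationError(
            f"rating outside 1-{N_CATEGORIES} (or non-integer) at row(s) {rows}"
        )
    out["rating"] = rating.astype(int)

    status = out["status"].astype(str).str.strip().str.lower()
    bad = ~status.isin(_STATUS_VALUES)
    if bad.any():
        rows = [int(i) for i in np.flatnonzero(bad.to_numpy())[:20]]
        raise TrialValidationError(f"status must be one of {_STATUS_VALUES}; bad row(s) {rows}")
    out["status"] = status

    # optional covariates: present for all trials of a condition x item-class
    # group or absent from it (study covariates may exist for old items only)
    for col in OPTIONAL_COLUMNS:
        if col not in out.columns:
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        for key, grp in vals.groupby([out["condition"], out["status"]]):
            if grp.isna().any() and not grp.isna().all():
                raise TrialValidationError(
                    f"covariate {col!r} partially missing within group {key!r}"
                )
        out[col] = vals
    if "zipf" in out.columns:
        z = out["zipf"].dropna()
        if len(z) and ((z < 1) | (z > 7)).any():
            raise TrialValidationError("zipf scores must lie in [1, 7]")
    if "duration_ms" in out.columns:
        d = out["duration_ms"].dropna()
        if len(d) and (d <= 0).any():
            raise TrialValidationError("duration_ms must be positive")
    return out


def read_trials(path, **read_csv_kwargs) -> pd.DataFrame:
    """Read a CSV trial file (header required) and validate it."""
    trials = pd.read_csv(path, **read_csv_kwargs)
    return validate_trials(trials)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a validated trial table to CSV (UTF-8, comma separated)."""
    validate_trials(trials).to_csv(path, index=False)


def _select(trials, participant=None, condition=None):
    mask = pd.Series(True, index=trials.index)
    if participant is not None:
        mask &= trials["participant"] == participant
    if condition is not None:
        mask &= trials["condition"] == condition
    return trials.loc[mask]


def aggregate_counts(trials: pd.DataFrame, participant=None, condition=None) -> RatingCounts:
    """Aggregate (a subset of) a trial table into a 2 x 6 count table.

    ``participant``/``condition`` of ``None`` pool over that dimension,
    so ``aggregate_counts(trials, condition="fixed")`` gives the
    aggregate (pooled-count) table for a condition.
    """
    sel = _select(validate_trials(trials), participant, condition)
    if len(sel) == 0:
        raise ValueError("empty selection: no trials match the requested subset")
    counts = {s: np.zeros(N_CATEGORIES, dtype=int) for s in _STATUS_VALUES}
    grouped = sel.groupby(["status", "rating"]).size()
    for (status, rating), n in grouped.items():
        counts[status][rating - 1] = n
    return RatingCounts(tuple(counts["old"]), tuple(counts["new"]))


def counts_to_frame(counts: RatingCounts) -> pd.DataFrame:
    """One-row DataFrame with columns old1..old6,new1..new6 (CSV export)."""
    row = {f"old{j+1}": counts.n_old[j] for j in range(N_CATEGORIES)}
    row.update({f"new{j+1}": counts.n_new[j] for j in range(N_CATEGORIES)})
    return pd.DataFrame([row])


def hit_fa_rates(counts: RatingCounts, criterion_index: int = 3):
    """Hit and false-alarm rates at a decision criterion.

    The hit rate is the proportion of old items rated strictly above
    ``criterion_index``; the false-alarm rate likewise for new items.
    The default ``criterion_index=3`` implements the conventional "old"
    decision of rating >= 4, the midpoint of the 1-6 scale
    ("4 = guess old").
    """
    if not 1 <= int(criterion_index) <= 5:
        raise ValueError("criterion_index must be in 1..5")
    k = int(criterion_index)
    old, new = counts.as_arrays()
    if old.sum() == 0 or new.sum() == 0:
        raise ValueError("hit/FA rates undefined with zero old or new trials")
    return float(old[k:].sum() / old.sum()), float(new[k:].sum() / new.sum())
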