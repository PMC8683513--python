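"""Canonical data structures, tabular IO and preprocessing rules.

A subject's session consists of preference ratings for single items
(one or two rating phases on a continuous slider, stored normalized to
[0, 1]), two-alternative choice trials between rated items (choice,
reaction time, confidence report), and fixation records from which each
trial's dwell share ``g_upper`` is computed.

Preprocessing rules implemented here:

* dwell shares count only fixations on the two options; "elsewhere"
  fixations are excluded from the denominator;
* trials lacking at least one fixation on each option are excluded;
* a choice is *consistent* when the chosen item's mean rating strictly
  exceeds the other item's; exact ties are flagged and dropped from
  consistency analyses;
* trial regressors: VD = |v_upper - v_lower|, Var = var_upper + var_lower
  (requires two rating phases), TV = v_upper + v_lower.

File formats are plain CSV (see :func:`load_dataset`); reaction times are
stored in seconds, fixation timestamps in milliseconds at IO.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RatingRecord", "FixationRecord", "Trial", "SubjectDataset",
    "SchemaError", "ValidationError",
    "load_dataset", "write_dataset", "compute_gaze_shares",
    "apply_exclusion", "label_consistency", "build_regressors",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["subject", "trial", "item_upper", "item_lower",
                 "rating1_upper", "rating2_upper", "rating1_lower",
                 "rating2_lower", "choice", "rt_s", "confidence"]
FIXATION_COLUMNS = ["subject", "trial", "target", "onset_ms", "offset_ms"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A value violates its documented range, with the offending row named."""


@dataclass(frozen=True)
class RatingRecord:
    item_id: str
    phase: int            # 1 or 2
    rating: float         # slider position, full-scale normalized to [0, 1]

    def __post_init__(self):
        if self.phase not in (1, 2):
            raise ValidationError(f"item {self.item_id}: phase must be 1 or 2")
        if not 0.0 <= self.rating <= 1.0:
            raise ValidationError(
                f"item {self.item_id} phase {self.phase}: rating "
                f"{self.rating} outside [0, 1]")


@dataclass(frozen=True)
class FixationRecord:
    trial_id: int
    target: str           # "upper", "lower" or "elsewhere"
    onset_ms: float
    offset_ms: float

    def __post_init__(self):
        if self.target not in ("upper", "lower", "elsewhere"):
            raise ValidationError(
                f"trial {self.trial_id}: unknown fixation target {self.target!r}")
        if not self.offset_ms > self.onset_ms:
            raise ValidationError(
                f"trial {self.trial_id}: fixation offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class Trial:
    trial_id: int
    item_upper: str
    item_lower: str
    v_upper: float        # mean rating across phases, in [0, 1]
    v_lower: float
    var_upper: float | None   # across-phase rating variance; None if 1 phase
    var_lower: float | None
    choice: str           # "upper" or "lower"
    rt_s: float
    confidence: float
    g_upper: float | None = None
    valid: bool = True

    def __post_init__(self):
        if self.choice not in ("upper", "lower"):
            raise ValidationError(f"trial {self.trial_id}: bad choice {self.choice!r}")
        if not 0.0 < self.rt_s <= 4.0:
            raise ValidationError(
                f"trial {self.trial_id}: rt_s {self.rt_s} outside (0, 4]")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"trial {self.trial_id}: confidence {self.confidence} outside [0, 1]")
        for name in ("v_upper", "v_lower"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"trial {self.trial_id}: {name} {v} outside [0, 1]")
        if self.g_upper is not None and not 0.0 <= self.g_upper <= 1.0:
            raise ValidationError(
                f"trial {self.trial_id}: g_upper {self.g_upper} outside [0, 1]")

    @property
    def g_lower(self) -> float | None:
        return None if self.g_upper is None else 1.0 - self.g_upper

    @property
    def v_chosen(self) -> float:
        return self.v_upper if self.choice == "upper" else self.v_lower

    @property
    def v_other(self) -> float:
        return self.v_lower if self.choice == "upper" else self.v_upper


@dataclass
class SubjectDataset:
    """All ratings, trials and fixations for one participant."""

    subject_id: str
    ratings: list[RatingRecord]
    trials: list[Trial]
    fixations: dict[int, list[FixationRecord]] = field(default_factory=dict)
    scale_meta: dict = field(default_factory=lambda: {"rating": (0.0, 1.0),
                                                      "confidence": (0.0, 1.0)})
    n_excluded: int = 0

    def valid_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.valid]

    @property
    def n_rating_phases(self) -> int:
        return max((r.phase for r in self.ratings), default=1)

    def to_frame(self) -> pd.DataFrame:
        """Valid trials as a DataFrame (one row per trial)."""
        rows = []
        for t in self.valid_trials():
            vd, var, tv = build_regressors(t)
            rows.append({
                "trial": t.trial_id, "v_upper": t.v_upper, "v_lower": t.v_lower,
                "choice": t.choice, "choice_upper": t.choice == "upper",
                "rt_s": t.rt_s, "confidence": t.confidence,
                "g_upper": t.g_upper, "VD": vd, "Var": var, "TV": tv,
                "consistency": label_consistency(t),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preprocessing


def compute_gaze_shares(fixations: list[FixationRecord], trial: Trial) -> Trial:
    """Attach the dwell share g_upper to a trial.

    Only fixations on the two options enter the share; "elsewhere" dwell is
    excluded from the denominator.  A trial with zero option-directed dwell
    cannot form a share and is flagged invalid.
    """
    up = sum(f.duration_ms for f in fixations if f.target == "upper")
    low = sum(f.duration_ms for f in fixations if f.target == "lower")
    total = up + low
    if total <= 0:
        trial.g_upper = None
        trial.valid = False
        return trial
    trial.g_upper = up / total
    return trial


def apply_exclusion(ds: SubjectDataset) -> SubjectDataset:
    """Drop trials lacking at least one fixation on each option.

    Idempotent; the exclusion count is recorded on the returned dataset and
    logged.  An empty result is permitted (with a warning).
    """
    kept, dropped = [], 0
    for t in ds.trials:
        fx = ds.fixations.get(t.trial_id, [])
        has_up = any(f.target == "upper" for f in fx)
        has_low = any(f.target == "lower" for f in fx)
        if has_up and has_low and t.valid:
            kept.append(t)
        else:
            dropped += 1
    if not kept:
        warnings.warn(f"subject {ds.subject_id}: no trials survive exclusion")
    logger.info("subject %s: excluded %d of %d trials",
                ds.subject_id, dropped, len(ds.trials))
    return replace(ds, trials=kept, n_excluded=ds.n_excluded + dropped)


def label_consistency(trial: Trial) -> str:
    """Label a choice consistent/inconsistent/tie by mean ratings.

    Consistent iff the chosen item's mean rating strictly exceeds the
    other's.  Exact ties are flagged "tie" and are dropped from consistency
    analyses downstream.
    """
    if trial.v_chosen > trial.v_other:
        return "consistent"
    if trial.v_chosen < trial.v_other:
        return "inconsistent"
    return "tie"


def build_regressors(trial: Trial):
    """(VD, Var, TV) for one trial; Var is None for single-phase data."""
    vd = abs(trial.v_upper - trial.v_lower)
    tv = trial.v_upper + trial.v_lower
    if trial.var_upper is None or trial.var_lower is None:
        var = None
    else:
        var = trial.var_upper + trial.var_lower
    return vd, var, tv


# ---------------------------------------------------------------------------
# Tabular IO


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_dataset(trials_path, fixations_path=None, subject=None,
                 scale_meta=None, exclude=True) -> SubjectDataset:
    """Load one subject's session from the documented CSV schema.

    ``trials`` columns: subject, trial, item_upper, item_lower,
    rating1_upper, rating2_upper, rating1_lower, rating2_lower, choice,
    rt_s, confidence.  ``rating2_*`` may be empty (single-rating-phase
    datasets), in which case per-item variances are undefined.

    ``fixations`` columns: subject, trial, target, onset_ms, offset_ms with
    target in {upper, lower, elsewhere}.  If a fixation file is given, dwell
    shares are computed and (by default) the fixation-based trial exclusion
    rule is applied.
    """
    df = pd.read_csv(trials_path)
    _require_columns(df, TRIAL_COLUMNS, trials_path)
    if subject is not None:
        df = df[df["subject"].astype(str) == str(subject)]
    elif df["subject"].nunique() > 1:
        raise ValidationError(
            f"{trials_path}: multiple subjects present; pass subject=")
    two_phase = df["rating2_upper"].notna().any()

    ratings: dict[tuple[str, int], RatingRecord] = {}
    trials = []
    for idx, row in df.iterrows():
        for side in ("upper", "lower"):
            item = str(row[f"item_{side}"])
            for phase in (1, 2):
                val = row[f"rating{phase}_{side}"]
                if pd.isna(val):
                    continue
                key = (item, phase)
                if key not in ratings:
                    try:
                        ratings[key] = RatingRecord(item, phase, float(val))
                    except ValidationError as err:
                        raise ValidationError(f"{trials_path} row {idx}: {err}")
        r1u, r2u = row["rating1_upper"], row["rating2_upper"]
        r1l, r2l = row["rating1_lower"], row["rating2_lower"]
        if two_phase and not (pd.isna(r2u) or pd.isna(r2l)):
            v_up = (r1u + r2u) / 2.0
            v_low = (r1l + r2l) / 2.0
            var_up = float(np.var([r1u, r2u], ddof=1))
            var_low = float(np.var([r1l, r2l], ddof=1))
        else:
            v_up, v_low, var_up, var_low = float(r1u), float(r1l), None, None
        try:
            trials.append(Trial(
                trial_id=int(row["trial"]), item_upper=str(row["item_upper"]),
                item_lower=str(row["item_lower"]), v_upper=float(v_up),
                v_lower=float(v_low), var_upper=var_up, var_lower=var_low,
                choice=str(row["choice"]), rt_s=float(row["rt_s"]),
                confidence=float(row["confidence"])))
        except ValidationError as err:
            raise ValidationError(f"{trials_path} row {idx}: {err}")

    sid = str(df["subject"].iloc[0]) if len(df) else str(subject)
    ds = SubjectDataset(subject_id=sid, ratings=list(ratings.values()),
                        trials=trials,
                        scale_meta=scale_meta or {"rating": (0.0, 1.0),
                                                  "confidence": (0.0, 1.0)})
    if fixations_path is not None:
        fdf = pd.read_csv(fixations_path)
        _require_columns(fdf, FIXATION_COLUMNS, fixations_path)
        if subject is not None:
            fdf = fdf[fdf["subject"].astype(str) == str(subject)]
        fx: dict[int, list[FixationRecord]] = {}
        for idx, row in fdf.iterrows():
            try:
                rec = FixationRecord(int(row["trial"]), str(row["target"]),
                                     float(row["onset_ms"]),
                                     float(row["offset_ms"]))
            except ValidationError as err:
                raise ValidationError(f"{fixations_path} row {idx}: {err}")
            fx.setdefault(rec.trial_id, []).append(rec)
        ds.fixations = fx
        for t in ds.trials:
            compute_gaze_shares(fx.get(t.trial_id, []), t)
        if exclude:
            ds = apply_exclusion(ds)
    return ds


def write_dataset(ds: SubjectDataset, trials_path, fixations_path=None,
                  float_format="%.10g"):
    """Write a session back to the CSV schema (inverse of load_dataset)."""
    r1 = {r.item_id: r.rating for r in ds.ratings if r.phase == 1}
    r2 = {r.item_id: r.rating for r in ds.ratings if r.phase == 2}
    rows = []
    for t in ds.trials:
        rows.append({
            "subject": ds.subject_id, "trial": t.trial_id,
            "item_upper": t.item_upper, "item_lower": t.item_lower,
            "rating1_upper": r1.get(t.item_upper),
            "rating2_upper": r2.get(t.item_upper),
            "rating1_lower": r1.get(t.item_lower),
            "rating2_lower": r2.get(t.item_lower),
            "choice": t.choice, "rt_s": t.rt_s, "confidence": t.confidence,
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(
        trials_path, index=False, float_format=float_format)
    if fixations_path is not None:
        frows = []
        for tid, fxs in sorted(ds.fixations.items()):
            for f in fxs:
                frows.append({"subject": ds.subject_id, "trial": tid,
                              "target": f.target, "onset_ms": f.onset_ms,
                              "offset_ms": f.offset_ms})
        pd.DataFrame(frows, columns=FIXATION_COLUMNS).to_csv(
            fixations_path, index=False, float_format=float_format)
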