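"""From raw telemetry to the daily population space-use matrix.

The clustering stage consumes one row per ordinal day (1..365, circular;
leap days folded into day 59) whose columns are population means of movement
metrics (step length, turning angle), continuous landscape covariates at the
used locations, and per-class land-cover occupancy fractions.  This module
applies, in order: the boundary-day exclusion around capture and mortality,
greedy resampling to a target relocation interval, step-metric computation,
nearest-cell covariate extraction, daily pooling across individuals and
years, normalizing transformations, and a pairwise-correlation screen.

Tracks are plain pandas DataFrames with columns ``individual_id``,
``timestamp`` (tz-aware), ``x``, ``y``; annotation adds ``step_length``,
``turning_angle`` and one column per landscape layer.  Undefined step
metrics (the first fix of a track, the first two turning angles, zero-length
segments) are NaN, never zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import OrderingError, OutOfBoundsError
from .landscape import CONTINUOUS_LAYERS, LandscapeStack
from .season_calendar import DAYS_PER_YEAR

MOVEMENT_METRICS = ("step_length", "turning_angle")


def exclude_boundary_days(
    track: pd.DataFrame,
    capture_date,
    end_date,
    buffer_days: int = 7,
) -> pd.DataFrame:
    """Drop fixes within ``buffer_days`` of capture or of the track end.

    Removes capture-related movements and fixes near an uncertain mortality
    date.  Returns an empty track (with a warning) if nothing survives.
    """
    if buffer_days < 0:
        raise ValueError("buffer_days must be >= 0")
    capture_date = pd.Timestamp(capture_date)
    end_date = pd.Timestamp(end_date)
    tz = getattr(track["timestamp"].dt, "tz", None)
    if tz is not None:
        if capture_date.tz is None:
            capture_date = capture_date.tz_localize(tz)
        if end_date.tz is None:
            end_date = end_date.tz_localize(tz)
    if end_date < capture_date:
        raise ValueError("end_date precedes capture_date")
    buf = pd.Timedelta(days=buffer_days)
    ts = track["timestamp"]
    keep = (ts - capture_date >= buf) & (end_date - ts >= buf)
    out = track.loc[keep].reset_index(drop=True)
    if len(out) == 0 and len(track) > 0:
        warnings.warn(
            f"boundary-day exclusion removed every fix "
            f"({track['individual_id'].iloc[0]})",
            stacklevel=2,
        )
    return out


def resample_track(
    track: pd.DataFrame, target_hours: float = 12.0, tol_hours: float = 2.0
) -> pd.DataFrame:
    """Greedy forward resampling to ``target_hours +/- tol_hours`` intervals.

    Keep the first fix; from each kept fix keep the earliest later fix whose
    gap lies in [target - tol, target + tol]; if no such fix exists, restart
    the chain at the earliest fix beyond target + tol.  Idempotent, and
    independent of fixes later than the one under consideration.
    """
    if len(track) <= 1:
        return track.reset_index(drop=True)
    ts = pd.DatetimeIndex(track["timestamp"])
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise OrderingError("timestamps must be strictly increasing")
    hours = (track["timestamp"] - track["timestamp"].iloc[0]) / pd.Timedelta(hours=1)
    hours = hours.to_numpy()
    lo, hi = target_hours - tol_hours, target_hours + tol_hours
    kept = [0]
    i = 0
    n = len(hours)
    while True:
        gaps = hours[i + 1 :] - hours[i]
        in_window = np.flatnonzero((gaps >= lo) & (gaps <= hi))
        if in_window.size:
            i = i + 1 + in_window[0]
        else:
            beyond = np.flatnonzero(gaps > hi)
            if not beyond.size:
                break
            i = i + 1 + beyond[0]
        kept.append(i)
        if i == n - 1:
            break
    return track.iloc[kept].reset_index(drop=True)


def compute_step_metrics(track: pd.DataFrame) -> pd.DataFrame:
    """Fill step_length (m) and signed turning_angle (degrees).

    The step length at a fix is the Euclidean distance from the prior
    retained fix.  The turning angle at a fix is the signed change in
    heading between the two preceding segments (prior-to-previous and
    previous-to-current), counterclockwise positive, in (-180, 180]; it is
    undefined (NaN) for the first two fixes and wherever a segment has zero
    length.
    """
    if len(track) == 0:
        raise ValueError("track must contain at least one fix")
    out = track.copy()
    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    out["step_length"] = np.concatenate([[np.nan], step])

    angle = np.full(len(out), np.nan)
    if len(out) >= 3:
        # heading change between segment (i-2 -> i-1) and (i-1 -> i)
        h = np.arctan2(dy, dx)
        turn = np.degrees(h[1:] - h[:-1])
        turn = (turn + 180.0) % 360.0 - 180.0
        turn[turn == -180.0] = 180.0
        zero_seg = (step[1:] == 0) | (step[:-1] == 0)
        turn[zero_seg] = np.nan
        angle[2:] = turn
    out["turning_angle"] = angle
    return out


def extract_covariates(track: pd.DataFrame, landscape: LandscapeStack) -> pd.DataFrame:
    """Annotate fixes with nearest-cell landscape covariate values.

    Cell membership follows the half-open convention: x in [left, right),
    y in (bottom, top].  Land cover is returned as the class label.
    """
    grid = landscape.grid
    row, col = grid.rowcol(track["x"].to_numpy(), track["y"].to_numpy())
    bad = (row < 0) | (row >= grid.n_rows) | (col < 0) | (col >= grid.n_cols)
    if bad.any():
        raise OutOfBoundsError(
            f"{int(bad.sum())} fixes outside the landscape extent",
            indices=np.flatnonzero(bad),
        )
    out = track.copy()
    codes = landscape.land_cover[row, col]
    out["land_cover"] = np.asarray(landscape.classes, dtype=object)[codes]
    for name in CONTINUOUS_LAYERS:
        out[name] = getattr(landscape, name)[row, col]
    return out


def ordinal_day(timestamps: pd.Series) -> pd.Series:
    """Day-of-year on a fixed 365-day cycle; Feb 29 merges into day 59."""
    ts = pd.to_datetime(timestamps)
    doy = ts.dt.dayofyear
    leap = ts.dt.is_leap_year
    return doy.where(~(leap & (doy >= 60)), doy - 1).astype(int)


@dataclass
class DailySpaceUseMatrix:
    """One row per ordinal day of population-average space-use covariates.

    ``values`` is indexed by ordinal day 1..365; days with no contributing
    fixes carry NaN rows and are listed in ``missing_days``.  ``transforms``
    and ``dropped`` record per-column processing; ``fix_counts`` the number
    of contributing fixes per day.
    """

    values: pd.DataFrame
    fix_counts: pd.Series
    transforms: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def missing_days(self) -> list[int]:
        return [int(d) for d in self.fix_counts.index[self.fix_counts == 0]]

    @property
    def retained(self) -> pd.DataFrame:
        """Retained columns, missing days excluded."""
        cols = [c for c in self.values.columns if c not in self.dropped]
        return self.values.loc[self.fix_counts > 0, cols]

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None):
        self.values.to_csv(csv_path)
        if meta_path is None:
            meta_path = Path(csv_path).with_suffix(".meta.json")
        meta = {
            "transforms": self.transforms,
            "dropped": self.dropped,
            "fix_counts": {str(k): int(v) for k, v in self.fix_counts.items()},
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path, meta_path: str | Path | None = None):
        values = pd.read_csv(csv_path, index_col=0)
        values.index = values.index.astype(int)
        if meta_path is None:
            meta_path = Path(csv_path).with_suffix(".meta.json")
        meta = json.loads(Path(meta_path).read_text())
        counts = pd.Series(
            {int(k): v for k, v in meta["fix_counts"].items()}
        ).sort_index()
        counts.index.name = "ordinal_day"
        return cls(
            values=values,
            fix_counts=counts,
            transforms=meta["transforms"],
            dropped=meta["dropped"],
        )


def daily_population_matrix(
    annotated: list[pd.DataFrame] | pd.DataFrame,
    classes: tuple[str, ...] | None = None,
) -> DailySpaceUseMatrix:
    """Pool annotated fixes of a population into daily averages.

    All individuals and years contribute to the same ordinal day.  Land
    cover expands to per-class occupancy fractions (which sum to 1 on every
    day with fixes); NaN movement metrics are excluded from their means.

    Because the occupancy fractions are compositional (they sum to one),
    one class is linearly redundant in a way the pairwise correlation
    screen cannot detect; the most-used class is therefore marked dropped
    as the compositional reference (its column stays in ``values`` so the
    sum-to-one invariant remains checkable).
    """
    df = (
        pd.concat(annotated, ignore_index=True)
        if isinstance(annotated, list)
        else annotated.copy()
    )
    if len(df) == 0:
        raise ValueError("no fixes supplied")
    if classes is None:
        from .landscape import LAND_COVER_CLASSES

        classes = LAND_COVER_CLASSES
    df = df.copy()
    df["ordinal_day"] = ordinal_day(df["timestamp"])

    cont_cols = [c for c in MOVEMENT_METRICS + CONTINUOUS_LAYERS if c in df.columns]
    agg = df.groupby("ordinal_day")[cont_cols].mean()
    occ = None
    if "land_cover" in df.columns:
        ind = pd.get_dummies(df["land_cover"]).astype(float)
        for cls in classes:
            if cls not in ind.columns:
                ind[cls] = 0.0
        ind = ind[list(classes)]
        ind["ordinal_day"] = df["ordinal_day"].values
        occ = ind.groupby("ordinal_day").mean()
        occ.columns = [f"occ_{c}" for c in occ.columns]

    full_index = pd.RangeIndex(1, DAYS_PER_YEAR + 1, name="ordinal_day")
    values = agg if occ is None else agg.join(occ)
    values = values.reindex(full_index)
    counts = (
        df.groupby("ordinal_day").size().reindex(full_index, fill_value=0).astype(int)
    )
    dropped = {}
    if occ is not None:
        reference = df["land_cover"].value_counts().idxmax()
        dropped[f"occ_{reference}"] = "compositional_reference"
    return DailySpaceUseMatrix(values=values, fix_counts=counts, dropped=dropped)


def transform_columns(
    matrix: DailySpaceUseMatrix, skew_threshold: float = 1.0
) -> DailySpaceUseMatrix:
    """Normalize each retained column and record the transform applied.

    A non-negative column with sample skewness above the threshold gets a
    square root before centering and scaling; every other column is centered
    and scaled only.  This automates the usual quantile-quantile-plot
    judgment deterministically.  Zero-variance columns are dropped.
    Standardization uses the sample SD (ddof = 1).
    """
    present = matrix.values.loc[matrix.fix_counts > 0]
    if len(present) < 30:
        raise ValueError(f"need >= 30 days with fixes, have {len(present)}")
    values = matrix.values.copy()
    transforms = dict(matrix.transforms)
    dropped = dict(matrix.dropped)
    for col in values.columns:
        if col in dropped:
            continue
        x = values[col]
        obs = x.dropna()
        if len(obs) == 0 or float(obs.std(ddof=1)) == 0 or np.isnan(obs.std(ddof=1)):
            dropped[col] = "zero_variance"
            transforms[col] = "none"
            continue
        if (obs >= 0).all() and stats.skew(obs, bias=False) > skew_threshold:
            x = np.sqrt(x)
            transforms[col] = "sqrt"
        else:
            transforms[col] = "zscore"
        obs = x.dropna()
        sd = float(obs.std(ddof=1))
        if sd == 0:
            dropped[col] = "zero_variance"
            transforms[col] = "none"
            continue
        values[col] = (x - obs.mean()) / sd
    return DailySpaceUseMatrix(
        values=values,
        fix_counts=matrix.fix_counts,
        transforms=transforms,
        dropped=dropped,
    )


def collinearity_filter(
    matrix: DailySpaceUseMatrix, threshold: float = 0.70
) -> DailySpaceUseMatrix:
    """Iteratively remove columns until no retained pair has |r| >= threshold.

    While any retained pair is over the threshold, the worst pair is found
    and the member with the larger mean absolute correlation to all other
    retained columns is dropped (ties break toward the later column in
    order).  Dropped columns are recorded with the partner that triggered
    the removal.
    """
    dropped = dict(matrix.dropped)
    cols = [c for c in matrix.values.columns if c not in dropped]
    if len(cols) < 2:
        return matrix
    data = matrix.values.loc[matrix.fix_counts > 0]
    while True:
        corr = data[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if not (corr.values >= threshold).any():
            break
        flat = corr.values
        i, j = np.unravel_index(np.nanargmax(flat), flat.shape)
        a, b = corr.columns[i], corr.columns[j]
        mean_a = corr.loc[a].drop(a).mean()
        mean_b = corr.loc[b].drop(b).mean()
        if mean_a > mean_b:
            victim, partner = a, b
        elif mean_b > mean_a:
            victim, partner = b, a
        else:  # tie: drop the later column in order
            victim = a if cols.index(a) > cols.index(b) else b
            partner = b if victim == a else a
        dropped[victim] = f"collinear_with:{partner}"
        cols.remove(victim)
        if len(cols) < 2:
            break
    return DailySpaceUseMatrix(
        values=matrix.values,
        fix_counts=matrix.fix_counts,
        transforms=dict(matrix.transforms),
        dropped=dropped,
    )


def prepare_daily_matrix(
    tracks: list[pd.DataFrame],
    landscape: LandscapeStack,
    target_hours: float = 12.0,
    tol_hours: float = 2.0,
    corr_threshold: float = 0.70,
) -> DailySpaceUseMatrix:
    """Full preparation chain: resample, annotate, pool, transform, screen."""
    annotated = []
    for tr in tracks:
        tr = resample_track(tr, target_hours, tol_hours)
        tr = compute_step_metrics(tr)
        tr = extract_covariates(tr, landscape)
        annotated.append(tr)
    matrix = daily_population_matrix(annotated, classes=landscape.classes)
    matrix = transform_columns(matrix)
    return collinearity_filter(matrix, threshold=corr_threshold)
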