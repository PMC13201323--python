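"""Seasonal resource selection: segments, utilization distributions, RSFs.

The sample unit is the individual-space-use state: one individual's fixes
within one seasonal state of one year, buffered away from transition dates
and required to hold at least 50 locations.  For each segment a utilization
distribution (UD) is estimated and habitat selection is fit at the core
(50% UD) and home-range (95% UD) levels by contrasting used locations with
available locations sampled inside the isopleth, using a weighted logistic
approximation to an inhomogeneous Poisson point process.  Per-segment
coefficients are pooled to the population level by AICc weights (or
equally), with significance judged by whether the 95% CI excludes zero.

The UD here is a time-weighted plain Gaussian kernel density — each fix is
weighted by the time span it represents (half the gap to each temporal
neighbor) — rather than an autocorrelation-adjusted continuous-time
estimator; the simplification is recorded in every fit's metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .errors import DegenerateUDError
from .landscape import LandscapeStack
from .season_calendar import SeasonCalendar, circular_diff
from .trackprep import ordinal_day, resample_track

logger = logging.getLogger(__name__)

ESTIMATOR_NOTE = (
    "time-span-weighted Gaussian KDE + weighted logistic point-process "
    "approximation (no autocorrelation adjustment)"
)


def resample_for_rsf(
    track: pd.DataFrame, target_hours: float = 4.0, tol_hours: float = 1.0
) -> pd.DataFrame:
    """Resample to 4 +/- 1 h intervals for the selection stage."""
    return resample_track(track, target_hours=target_hours, tol_hours=tol_hours)


@dataclass
class IndividualSeasonSegment:
    """One individual's fixes within one seasonal state of one year."""

    individual_id: str
    state: str
    year: int
    fixes: pd.DataFrame

    @property
    def n_locations(self) -> int:
        return len(self.fixes)


def segment_locations(
    tracks: list[pd.DataFrame],
    calendar: SeasonCalendar,
    min_locs: int = 50,
    buffer_days: int = 14,
) -> list[IndividualSeasonSegment]:
    """Split tracks into individual-space-use-state segments.

    Fixes less than ``buffer_days`` from any transition date (circularly)
    are excluded; groups are individual x state x year with a state that
    spans the year boundary assigned to the year in which it begins;
    segments below ``min_locs`` are dropped (logged).
    """
    trans_days = [t["day"] for t in calendar.transitions()]
    state_by_label = {s.label: s for s in calendar.states}
    segments = []
    for track in tracks:
        if len(track) == 0:
            continue
        df = track.copy()
        doy = ordinal_day(df["timestamp"])
        if trans_days:
            near = np.zeros(len(df), dtype=bool)
            for td in trans_days:
                near |= np.abs([circular_diff(d, td) for d in doy]) < buffer_days
            df = df.loc[~near]
            doy = doy.loc[~near]
        if len(df) == 0:
            continue
        states = doy.map(calendar.state_of)
        year = pd.to_datetime(df["timestamp"]).dt.year.to_numpy().copy()
        for lbl, st in state_by_label.items():
            if st.start_day > st.end_day:  # wraps the year boundary
                in_tail = (states == lbl) & (doy <= st.end_day)
                year[in_tail.to_numpy()] -= 1
        df = df.assign(_state=states.values, _year=year)
        for (lbl, yr), grp in df.groupby(["_state", "_year"], sort=True):
            ind = grp["individual_id"].iloc[0]
            if len(grp) < min_locs:
                logger.info(
                    "dropping segment %s/%s/%s: %d < %d locations",
                    ind, lbl, yr, len(grp), min_locs,
                )
                continue
            segments.append(
                IndividualSeasonSegment(
                    individual_id=str(ind),
                    state=str(lbl),
                    year=int(yr),
                    fixes=grp.drop(columns=["_state", "_year"]).reset_index(drop=True),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# utilization distributions


@dataclass
class UtilizationDistribution:
    """Normalized density mass per grid cell with 50/95% isopleth masks."""

    mass: np.ndarray  # sums to 1
    masks: dict[int, np.ndarray]  # level -> boolean superlevel mask
    bandwidth_factor: float
    landscape: LandscapeStack = field(repr=False)
    estimator: str = ESTIMATOR_NOTE

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def mass_within(self, level: int) -> float:
        return float(self.mass[self.masks[level]].sum())


def time_span_weights(timestamps: pd.Series) -> np.ndarray:
    """Weight per fix proportional to the time span it represents
    (half the gap to each temporal neighbor; one-sided at the ends)."""
    t = pd.to_datetime(timestamps).astype("int64").to_numpy() / 3.6e12  # hours
    n = len(t)
    if n == 1:
        return np.array([1.0])
    w = np.empty(n)
    gaps = np.diff(t)
    w[0] = gaps[0] / 2
    w[-1] = gaps[-1] / 2
    if n > 2:
        w[1:-1] = (gaps[:-1] + gaps[1:]) / 2
    s = w.sum()
    return w / s if s > 0 else np.full(n, 1.0 / n)


def fit_ud(
    segment: IndividualSeasonSegment,
    landscape: LandscapeStack,
    levels: tuple[int, ...] = (50, 95),
) -> UtilizationDistribution:
    """Time-weighted Gaussian KDE on the landscape grid with isopleths.

    The isopleth at level L is the smallest superlevel set of cells holding
    L% of the UD mass (the crossing cell included), so nested levels give
    nested regions by construction.
    """
    x = segment.fixes["x"].to_numpy(float)
    y = segment.fixes["y"].to_numpy(float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateUDError(
            "all fixes identical; specify a minimum bandwidth or more data"
        )
    w = time_span_weights(segment.fixes["timestamp"])
    try:
        kde = sstats.gaussian_kde(np.vstack([x, y]), weights=w)
    except np.linalg.LinAlgError as exc:
        raise DegenerateUDError(
            f"singular fix covariance ({exc}); suggest a minimum bandwidth"
        ) from exc
    xs, ys = landscape.grid.cell_centers()
    XX, YY = np.meshgrid(xs, ys)
    dens = kde(np.vstack([XX.ravel(), YY.ravel()])).reshape(XX.shape)
    mass = dens * landscape.grid.cell_size**2
    total = mass.sum()
    if total <= 0:
        raise DegenerateUDError("zero density mass on the grid")
    mass = mass / total

    order = np.argsort(mass.ravel())[::-1]
    cum = np.cumsum(mass.ravel()[order])
    masks = {}
    for lv in sorted(levels):
        target = lv / 100.0
        n_in = int(np.searchsorted(cum, target) + 1)
        m = np.zeros(mass.size, dtype=bool)
        m[order[:n_in]] = True
        masks[lv] = m.reshape(mass.shape)
    return UtilizationDistribution(
        mass=mass,
        masks=masks,
        bandwidth_factor=float(kde.factor),
        landscape=landscape,
    )


# ---------------------------------------------------------------------------
# RSF fitting


@dataclass
class RsfFit:
    """Per-segment selection coefficients (reference class fixed at 0)."""

    coefficients: pd.Series
    cov: pd.DataFrame
    aicc: float
    n_used: int
    n_available: int
    ud_level: int
    segment_id: str
    inestimable: list[str] = field(default_factory=list)
    ridge_penalty: float | None = None
    estimator: str = ESTIMATOR_NOTE


def _design(
    fixes_like: pd.DataFrame, landscape: LandscapeStack, reference: str
) -> pd.DataFrame:
    """Design matrix at the supplied points: land-cover dummies vs the
    reference class, northness, slope, and distances in km."""
    cov = landscape.covariates_at(
        fixes_like["x"].to_numpy(float), fixes_like["y"].to_numpy(float)
    )
    labels = np.asarray(landscape.classes, dtype=object)[cov["land_cover"]]
    X = pd.DataFrame(index=pd.RangeIndex(len(labels)))
    for cls in landscape.classes:
        if cls == reference:
            continue
        X[cls] = (labels == cls).astype(float)
    X["northness"] = cov["northness"]
    X["slope"] = cov["slope"]
    X["dist_lake_km"] = cov["dist_lake"] / 1000.0
    X["dist_road_km"] = cov["dist_road"] / 1000.0
    return X


def sample_available(
    ud: UtilizationDistribution, level: int, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Uniform spatial sample inside the isopleth region at a level."""
    mask = ud.masks[level]
    grid = ud.landscape.grid
    rows, cols = np.nonzero(mask)
    pick = rng.integers(0, len(rows), size=n)
    cs = grid.cell_size
    x = grid.origin_x + (cols[pick] + rng.uniform(0, 1, n)) * cs
    y = grid.origin_y - (rows[pick] + rng.uniform(0, 1, n)) * cs
    return pd.DataFrame({"x": x, "y": y})


def fit_rsf(
    segment: IndividualSeasonSegment,
    ud: UtilizationDistribution,
    landscape: LandscapeStack,
    level: int = 95,
    availability_ratio: int = 10,
    seed: int = 0,
    reference_class: str = "open_water",
    available_weight: float = 1000.0,
) -> RsfFit:
    """Weighted used-available logistic fit within the UD isopleth.

    Used points are the segment fixes inside the isopleth at ``level``,
    carrying their time-span weights (normalized to mean 1); available
    points are a uniform sample within the isopleth at
    ``availability_ratio`` per used point, carrying a large weight so the
    logistic fit approximates the Poisson point-process likelihood.  A
    land-cover class absent from both point sets is marked inestimable;
    separation or non-convergence falls back to a small ridge penalty.
    """
    rng = np.random.default_rng(seed)
    grid = landscape.grid
    row, col = grid.rowcol(
        segment.fixes["x"].to_numpy(float), segment.fixes["y"].to_numpy(float)
    )
    inside = ud.masks[level][row, col]
    used = segment.fixes.loc[inside].reset_index(drop=True)
    if len(used) < 10:
        raise ValueError(
            f"only {len(used)} used locations inside the {level}% isopleth"
        )
    w_used = time_span_weights(used["timestamp"])
    w_used = w_used / w_used.mean()
    n_avail = availability_ratio * len(used)
    avail = sample_available(ud, level, n_avail, rng)

    X_used = _design(used, landscape, reference_class)
    X_avail = _design(avail, landscape, reference_class)
    X = pd.concat([X_used, X_avail], ignore_index=True)
    y = np.concatenate([np.ones(len(X_used)), np.zeros(len(X_avail))])
    w = np.concatenate([w_used, np.full(len(X_avail), available_weight)])

    inestimable = []
    class_cols = [c for c in X.columns if c in landscape.classes]
    for c in class_cols:
        if X[c].sum() == 0:
            inestimable.append(c)
    X = X.drop(columns=inestimable)
    Xd = sm.add_constant(X, has_constant="add")

    ridge = None
    params = cov = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(y, Xd, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200)
            ok = (
                bool(res.converged)
                and np.isfinite(res.params).all()
                and np.abs(res.params).max() < 50
                and np.isfinite(res.cov_params().to_numpy()).all()
            )
            if ok:
                params = res.params
                cov = res.cov_params()
                llf = float(res.llf)
        except Exception:
            ok = False
    if not ok:
        ridge = 1.0
        params, cov, llf = _ridge_logistic(Xd.to_numpy(), y, w, ridge)
        params = pd.Series(params, index=Xd.columns)
        cov = pd.DataFrame(cov, index=Xd.columns, columns=Xd.columns)

    p = Xd.shape[1]
    n_eff = len(used)
    aic = -2 * llf + 2 * p
    aicc = aic + (2 * p * (p + 1) / (n_eff - p - 1)) if n_eff > p + 1 else np.inf

    coefs = params.drop("const")
    cov_coef = cov.drop(index="const", columns="const")
    # the reference class is fixed at 0 by construction
    coefs[reference_class] = 0.0
    return RsfFit(
        coefficients=coefs,
        cov=cov_coef,
        aicc=float(aicc),
        n_used=len(used),
        n_available=n_avail,
        ud_level=level,
        segment_id=f"{segment.individual_id}/{segment.state}/{segment.year}",
        inestimable=inestimable,
        ridge_penalty=ridge,
    )


def _ridge_logistic(X, y, w, lam):
    """Penalized IRLS logistic fallback for separated fits.

    Returns (params, covariance, log-likelihood); the covariance is the
    inverse penalized Fisher information.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = w * mu * (1 - mu)
        H = X.T @ (X * W[:, None]) + lam * np.eye(p)
        g = X.T @ (w * (y - mu)) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    llf = float(np.sum(w * (y * np.log(mu + 1e-12) + (1 - y) * np.log(1 - mu + 1e-12))))
    Wd = w * mu * (1 - mu)
    H = X.T @ (X * Wd[:, None]) + lam * np.eye(p)
    cov = np.linalg.inv(H)
    return beta, cov, llf


def fits_to_frame(fits: list[RsfFit]) -> pd.DataFrame:
    """Long-format per-segment coefficient table (one row per segment x
    predictor) with SEs, AICc and sample sizes, ready for CSV export."""
    rows = []
    for f in fits:
        for pred, est in f.coefficients.items():
            se = (
                float(np.sqrt(f.cov.loc[pred, pred]))
                if pred in f.cov.index
                else np.nan
            )
            rows.append(
                {
                    "segment_id": f.segment_id,
                    "ud_level": f.ud_level,
                    "predictor": pred,
                    "estimate": float(est),
                    "se": se,
                    "aicc": f.aicc,
                    "n_used": f.n_used,
                    "n_available": f.n_available,
                    "ridge_penalty": f.ridge_penalty,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population pooling


@dataclass
class PopulationRsf:
    """Pooled population-level selection summary."""

    table: pd.DataFrame  # estimate, ci_low, ci_high, significant, n_segments
    weighting: str
    weights: pd.Series  # per segment id
    ud_level: int

    def significant_predictors(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"].fillna(False)])


def pool_population(
    fits: list[RsfFit], weighting: str = "aicc", conf_level: float = 0.95
) -> PopulationRsf:
    """Pool per-segment coefficients to a population mean with 95% CI.

    The pooled estimate per predictor is the weighted arithmetic mean of
    the per-segment coefficients, with weights from relative AICc (Akaike
    weights within the fit set) or equal.  The CI comes from the
    t-distribution on the weighted across-segment variance with the
    effective degrees of freedom implied by the weights
    (``n_eff - 1`` where ``n_eff = 1 / sum(w^2)``): AICc values from
    different segments are not on a common likelihood scale, so their
    relative weights can concentrate on one segment, and the effective-df
    interval then widens honestly instead of collapsing to a zero-width
    CI around that segment.  With equal weights this reduces to the plain
    ``n - 1``-df mean CI.  A predictor is significant when its CI excludes
    zero; predictors estimable in fewer than 2 segments are reported
    without a CI.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs >= 2 fits")
    if weighting == "aicc":
        aiccs = np.array([f.aicc for f in fits], dtype=float)
        finite = np.isfinite(aiccs)
        delta = aiccs - aiccs[finite].min() if finite.any() else np.zeros(len(fits))
        raw = np.where(np.isfinite(delta), np.exp(-delta / 2.0), 0.0)
        if raw.sum() == 0:
            raw = np.ones(len(fits))
    elif weighting == "equal":
        raw = np.ones(len(fits))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    wts = raw / raw.sum()
    weights = pd.Series(wts, index=[f.segment_id for f in fits])

    predictors = sorted({p for f in fits for p in f.coefficients.index})
    rows = {}
    for pred in predictors:
        vals, ws = [], []
        for f, wt in zip(fits, wts):
            if pred in f.coefficients.index and pred not in f.inestimable:
                vals.append(float(f.coefficients[pred]))
                ws.append(wt)
        vals = np.asarray(vals)
        ws = np.asarray(ws)
        if len(vals) == 0:
            continue
        ws = ws / ws.sum()
        est = float(np.sum(ws * vals))
        if len(vals) < 2:
            rows[pred] = dict(
                estimate=est, ci_low=np.nan, ci_high=np.nan,
                significant=np.nan, n_segments=len(vals),
            )
            continue
        n_eff = 1.0 / np.sum(ws**2)
        var_w = float(np.sum(ws * (vals - est) ** 2))
        denom = 1.0 - np.sum(ws**2)
        if denom <= 0:
            # weights collapsed onto a single segment (AICc differences
            # beyond floating-point range): one effective segment, no CI
            rows[pred] = dict(
                estimate=est, ci_low=np.nan, ci_high=np.nan,
                significant=np.nan, n_segments=len(vals),
            )
            continue
        var_unb = var_w / denom
        se = np.sqrt(var_unb / n_eff)
        df = max(n_eff - 1.0, 0.5)
        tcrit = sstats.t.ppf(0.5 + conf_level / 2.0, df=df)
        lo, hi = est - tcrit * se, est + tcrit * se
        rows[pred] = dict(
            estimate=est, ci_low=lo, ci_high=hi,
            significant=bool(lo > 0 or hi < 0), n_segments=len(vals),
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PopulationRsf(
        table=table,
        weighting=weighting,
        weights=weights,
        ud_level=fits[0].ud_level,
    )
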