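"""Delineating seasonal space-use states from the daily matrix.

The clustering observation is an ordinal day of the year, described by the
retained, transformed columns of the daily space-use matrix.  The stage
order is:

1. variable screening — HINoV (heuristic identification of noisy
   variables: rank variables by the summed adjusted Rand agreement of
   their single-variable k-means partitions) followed by a one-way ANOVA
   screen across a provisional partition;
2. choice of the number of clusters k by the elbow (second difference of
   the within-cluster sum of squares) and mean-silhouette criteria;
3. k-means with a bootstrap cluster-stability check: for each of several
   random seeds, B bootstrap resamples of the days are re-clustered and
   each reference cluster is scored by its mean Jaccard similarity to the
   best-matching bootstrap cluster.  If any cluster of any seed falls below
   the stability threshold gamma, cluster formation is judged not possible
   and the pipeline reports "no seasonal states";
4. a 5-day circular moving-window mode smooths the daily assignments;
5. transition dates between states are the circular midpoint of the first
   chronological and last reverse-chronological runs of ``run_length``
   consecutive days in the new/old state, rounded to the nearest day;
6. PCA characterizes how the retained variables separate the states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score
from scipy import stats

from .season_calendar import (
    DAYS_PER_YEAR,
    SeasonCalendar,
    SeasonState,
    circular_day,
)

NO_SEASONAL_STATES = "no seasonal states"


def _kmeans(X, k, seed, n_init=10) -> KMeans:
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)


# ---------------------------------------------------------------------------
# variable screening


@dataclass
class HinovReport:
    """HINoV screening output: pairwise ARI of single-variable partitions."""

    ari_matrix: pd.DataFrame
    topri: pd.Series  # row sums of ARI, self excluded, descending
    flagged_noisy: list[str]  # below the largest gap in sorted topri
    excluded: list[str]  # too few distinct values to partition
    null_topri: float = np.nan  # permutation reference for the max topri
    informative: list[str] = field(default_factory=list)  # above null_topri
    anova_p: pd.Series | None = None
    anova_removed: list[str] = field(default_factory=list)


def _topri(partitions: dict) -> tuple[pd.DataFrame, pd.Series]:
    cols = list(partitions)
    m = len(cols)
    ari = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    for i in range(m):
        for j in range(i + 1, m):
            v = adjusted_rand_score(partitions[cols[i]], partitions[cols[j]])
            ari.iloc[i, j] = ari.iloc[j, i] = v
    topri = (ari.sum(axis=1) - 1.0).sort_values(ascending=False)
    return ari, topri


def hinov_screen(
    data: pd.DataFrame,
    k_probe: int = 2,
    seed: int = 0,
    n_reference: int = 20,
) -> HinovReport:
    """Rank variables by clustering information content.

    Each variable is clustered alone into ``k_probe`` groups; the adjusted
    Rand index (ARI) is computed for every pair of the resulting partitions
    and each variable's "topri" score is its row sum.  Variables below the
    largest gap in the sorted topri sequence are flagged as noisy (flagged,
    not yet removed).  Variables with fewer than ``k_probe`` distinct
    values cannot be partitioned and are excluded from screening.

    The largest-gap rule always splits the ranking somewhere, even when
    every variable is noise, so topri scores are additionally calibrated
    against a reference null: multivariate Gaussian draws with the data's
    own covariance, which carry the same inter-variable correlation but no
    cluster structure (the reference-distribution idea behind the gap
    statistic).  Variables whose topri exceeds the largest reference topri
    are listed as ``informative``; when that list is empty the ranking
    carries no evidence of cluster structure beyond plain covariance and
    downstream removal should not act on it.
    """
    if k_probe < 2:
        raise ValueError("k_probe must be >= 2")
    if data.shape[1] < 3:
        raise ValueError("HINoV screening needs at least 3 variables")
    clean = data.dropna(axis=0)
    partitions = {}
    excluded = []
    for col in data.columns:
        x = clean[col].to_numpy(float)
        if len(np.unique(x)) < k_probe:
            excluded.append(col)
            continue
        partitions[col] = _kmeans(x.reshape(-1, 1), k_probe, seed).labels_
    ari, topri = _topri(partitions)
    m = len(topri)

    flagged = []
    if m >= 2:
        vals = topri.to_numpy()
        gaps = vals[:-1] - vals[1:]
        if gaps.size and gaps.max() > 0:
            cut = int(np.argmax(gaps))
            flagged = list(topri.index[cut + 1 :])

    null_max = np.nan
    informative = list(topri.index)
    if n_reference > 0 and m >= 2:
        rng = np.random.default_rng(seed)
        n = len(clean)
        cols = list(partitions)
        cov = np.cov(clean[cols].to_numpy(float), rowvar=False)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cols)))
        maxes = []
        for rep in range(n_reference):
            ref = rng.standard_normal((n, len(cols))) @ chol.T
            ref_parts = {
                c: _kmeans(ref[:, i].reshape(-1, 1), k_probe, seed).labels_
                for i, c in enumerate(cols)
            }
            _, null_topri = _topri(ref_parts)
            maxes.append(float(null_topri.iloc[0]))
        null_max = float(np.max(maxes))
        informative = [c for c in topri.index if topri[c] > null_max]
    return HinovReport(
        ari_matrix=ari,
        topri=topri,
        flagged_noisy=flagged,
        excluded=excluded,
        null_topri=null_max,
        informative=informative,
    )


def anova_screen(
    data: pd.DataFrame,
    candidate_assignment: np.ndarray,
    alpha: float = 0.05,
    mode: str = "remove_significant",
) -> tuple[list[str], pd.Series]:
    """One-way ANOVA of each variable across a candidate partition.

    Returns (removal list, per-variable p values).  ``mode`` selects which
    side of alpha is listed for removal:

    * ``"remove_significant"`` lists variables whose distributions differ
      across the candidate groups (p < alpha) — this discards the
      informative variables and is almost certainly not what an analyst
      wants, so it logs a prominent warning;
    * ``"remove_nonsignificant"`` lists variables that do not differ
      (p >= alpha), consistent with screening out noise.
    """
    if mode not in ("remove_significant", "remove_nonsignificant"):
        raise ValueError(f"unknown anova_mode {mode!r}")
    groups = np.asarray(candidate_assignment)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("candidate assignment must have >= 2 groups")
    if mode == "remove_significant":
        warnings.warn(
            "anova_mode='remove_significant' removes the variables that "
            "differ between candidate clusters, i.e. the informative ones; "
            "use 'remove_nonsignificant' to screen out noise",
            stacklevel=2,
        )
    pvals = {}
    removal = []
    for col in data.columns:
        x = data[col].to_numpy(float)
        samples = []
        skip = False
        for g in uniq:
            vals = x[groups == g]
            vals = vals[~np.isnan(vals)]
            if len(vals) < 2:
                skip = True
                break
            samples.append(vals)
        if skip:
            pvals[col] = np.nan
            continue
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*samples)
            if np.isnan(p):
                p = 1.0
        pvals[col] = p
        significant = p < alpha
        if (mode == "remove_significant") == significant:
            removal.append(col)
    return removal, pd.Series(pvals)


# ---------------------------------------------------------------------------
# choosing k


@dataclass
class KSelection:
    k_elbow: int
    k_silhouette: int
    wss: dict[int, float]
    silhouette: dict[int, float]

    @property
    def candidates(self) -> list[int]:
        return sorted({self.k_elbow, self.k_silhouette})


def select_k(data: pd.DataFrame, k_min: int = 2, k_max: int = 8, seed: int = 0) -> KSelection:
    """Elbow and silhouette choices of the number of clusters.

    The elbow k maximizes the second difference of the within-cluster
    sum-of-squares curve (the sharpest bend); the silhouette k maximizes
    the mean silhouette width.  Full curves are returned for audit.
    """
    X = data.dropna(axis=0).to_numpy(float)
    n = len(X)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the {n} available days")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    wss = {}
    sil = {}
    for k in range(max(1, k_min - 1), k_max + 2):
        if k > n:
            break
        km = _kmeans(X, k, seed)
        wss[k] = float(km.inertia_)
        if k_min <= k <= k_max and k >= 2:
            sil[k] = float(silhouette_score(X, km.labels_))
    second_diff = {
        k: wss[k - 1] - 2 * wss[k] + wss[k + 1]
        for k in range(k_min, k_max + 1)
        if k - 1 in wss and k + 1 in wss
    }
    k_elbow = max(second_diff, key=second_diff.get)
    k_sil = max(sil, key=sil.get)
    return KSelection(k_elbow=k_elbow, k_silhouette=k_sil, wss=wss, silhouette=sil)


# ---------------------------------------------------------------------------
# bootstrap-stability k-means


def jaccard(a: set, b: set) -> float:
    """Jaccard similarity of two member sets (1 if both empty)."""
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 1.0


@dataclass
class StabilityReport:
    k: int
    B: int
    gamma: float
    mean_jaccard: pd.DataFrame  # rows: seeds, columns: reference clusters
    stable: bool
    assignment: np.ndarray | None  # first seed's labels when stable
    retries: int = 0

    def min_jaccard(self) -> float:
        return float(self.mean_jaccard.to_numpy().min())


def stable_kmeans(
    data: pd.DataFrame,
    k: int,
    B: int = 5000,
    n_seeds: int = 10,
    gamma: float = 0.75,
    base_seed: int = 0,
) -> StabilityReport:
    """Cluster-wise bootstrap stability assessment of k-means.

    For each outer seed a reference k-means partition of the days is fit;
    each of B bootstrap resamples of the days is re-clustered and every
    reference cluster is matched to the bootstrap cluster maximizing
    Jaccard similarity over the days present in the resample.  The verdict
    is unstable as soon as any reference cluster of any seed has a mean
    Jaccard below gamma.  When stable, the first seed's day assignment is
    carried forward.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    X = data.dropna(axis=0).to_numpy(float)
    n = len(X)
    seed_rows = []
    first_assignment = None
    retries_total = 0
    for s in range(n_seeds):
        seed = int(np.random.SeedSequence([base_seed, s]).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(seed)
        ref = _kmeans(X, k, seed)
        ref_labels = ref.labels_
        if s == 0:
            first_assignment = ref_labels.copy()
        ref_sets = [set(np.flatnonzero(ref_labels == c)) for c in range(k)]
        sums = np.zeros(k)
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            present = np.unique(idx)
            scores = None
            for attempt in range(10):
                fit_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    bm = _kmeans(X[idx], k, fit_seed)
                except ValueError:
                    retries_total += 1
                    continue
                boot_labels = bm.predict(X[present])
                boot_sets = [
                    set(present[boot_labels == c]) for c in range(k)
                ]
                pres = set(present)
                scores = [
                    max(jaccard(rs & pres, bs) for bs in boot_sets)
                    for rs in ref_sets
                ]
                break
            if scores is None:  # all retries failed: unmatched clusters score 0
                scores = [0.0] * k
            sums += scores
        seed_rows.append(sums / B)
    mean_j = pd.DataFrame(
        seed_rows,
        index=[f"seed_{s}" for s in range(n_seeds)],
        columns=[f"cluster_{c}" for c in range(k)],
    )
    stable = bool((mean_j.to_numpy() >= gamma).all())
    return StabilityReport(
        k=k,
        B=B,
        gamma=gamma,
        mean_jaccard=mean_j,
        stable=stable,
        assignment=first_assignment if stable else None,
        retries=retries_total,
    )


# ---------------------------------------------------------------------------
# smoothing and transition dating


def smooth_assignments(day_labels, window: int = 5):
    """Circular moving-window mode of daily labels.

    Per day, the mode of the ``window`` days centered on it (wrapping
    across the year boundary).  Ties break in favor of the day's own raw
    label if tied, else the smallest label.  Deterministic.
    """
    labels = np.asarray(day_labels)
    n = len(labels)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive (center undefined)")
    half = window // 2
    out = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        win = labels[(np.arange(i - half, i + half + 1)) % n]
        vals, counts = np.unique(win, return_counts=True)
        top = vals[counts == counts.max()]
        if labels[i] in top:
            out[i] = labels[i]
        else:
            out[i] = np.sort(top)[0]
    return out


def _runs(labels) -> list[tuple[object, int, int]]:
    """Circular run-length encoding: list of (label, start, length).

    The first run starts at the first index whose predecessor (circularly)
    differs; starts are 0-based positions in the input array.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if all(labels[i] == labels[0] for i in range(n)):
        return [(labels[0], 0, n)]
    start = 0
    while labels[start - 1] == labels[start]:
        start -= 1  # walk back across the wrap to the true run start
    start %= n
    runs = []
    i = start
    seen = 0
    while seen < n:
        j = i
        length = 0
        while length < n and labels[j % n] == labels[i % n]:
            length += 1
            j += 1
        runs.append((labels[i % n], i % n, length))
        seen += length
        i = j
    return runs


def merge_short_runs(labels, min_length: int):
    """Merge runs shorter than min_length into their larger neighbor.

    Returns the merged macro label sequence.  Shortest runs are absorbed
    first; ties in neighbor size break toward the preceding neighbor.
    """
    labels = list(np.asarray(labels))
    n = len(labels)
    while True:
        runs = _runs(labels)
        if len(runs) == 1:
            return np.asarray(labels)
        short = [r for r in runs if r[2] < min_length]
        if not short:
            return np.asarray(labels)
        lab, start, length = min(short, key=lambda r: r[2])
        k = runs.index((lab, start, length))
        prev = runs[(k - 1) % len(runs)]
        nxt = runs[(k + 1) % len(runs)]
        absorb = prev if prev[2] >= nxt[2] else nxt
        for off in range(length):
            labels[(start + off) % n] = absorb[0]


def transition_days(smoothed_labels, run_length: int = 8) -> list[dict]:
    """Transition day per boundary between circular label regimes.

    Runs shorter than ``run_length`` are first merged into their larger
    neighbor (no transition satisfying the run rule exists for them).  For
    each remaining boundary from old label ``o`` to new label ``u``:
    scanning forward from the start of the old regime, day A is the first
    day beginning ``run_length`` consecutive days of ``u`` in the original
    sequence; scanning backward from the end of the new regime, day B is
    the day after the last run of ``run_length`` consecutive days of ``o``.
    The transition is the circular midpoint of A and B rounded half-up, and
    is the first day of the new state.

    Days here are 0-based positions; callers mapping to ordinal days add 1.
    """
    labels = np.asarray(smoothed_labels)
    n = len(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 distinct labels to date transitions")
    macro = merge_short_runs(labels, run_length)
    runs = _runs(macro)
    if len(runs) < 2:
        raise ValueError(
            "all regimes shorter than run_length merged into one; "
            "no transition satisfies the run rule"
        )

    def run_of(label, at, length):
        """True if labels[at .. at+length-1] (circular) all equal label."""
        return all(labels[(at + o) % n] == label for o in range(length))

    out = []
    for k, (u_lab, u_start, u_len) in enumerate(runs):
        o_lab, o_start, o_len = runs[(k - 1) % len(runs)]
        # forward: first run_length-run of the new label, scanning from the
        # start of the old regime through the new regime
        a = None
        for off in range(o_len + u_len):
            d = (o_start + off) % n
            if run_of(u_lab, d, run_length):
                a = d
                break
        # backward: last run_length-run of the old label; candidate is the
        # day after its end
        b = None
        for off in range(o_len + u_len - 1, -1, -1):
            d = (o_start + off) % n
            if run_of(o_lab, (d - run_length + 1) % n, run_length):
                b = (d + 1) % n
                break
        if a is None or b is None:  # defensive; macro runs are >= run_length
            a = b = u_start
        day = circular_midpoint_index(b, a, n)
        out.append({"from": o_lab, "to": u_lab, "day": day})
    return out


def circular_midpoint_index(i: int, j: int, n: int) -> int:
    """Midpoint of 0-based circular positions along the shorter arc,
    rounded half-up (toward j)."""
    d = (j - i) % n
    if d > n / 2:
        d -= n
    import math

    return (i + math.floor(d / 2 + 0.5)) % n


def transition_dates(
    smoothed_labels, run_length: int = 8, provenance: dict | None = None
) -> SeasonCalendar:
    """Build a season calendar from smoothed daily labels (365 days)."""
    labels = np.asarray(smoothed_labels)
    if len(labels) != DAYS_PER_YEAR:
        raise ValueError(f"expected {DAYS_PER_YEAR} daily labels, got {len(labels)}")
    trans = transition_days(labels, run_length)
    trans = sorted(trans, key=lambda t: t["day"])
    days = [t["day"] for t in trans]
    if len(set(days)) != len(days):
        raise ValueError("transition dates collide; regimes too short to date")
    states = []
    for t, t_next in zip(trans, trans[1:] + trans[:1]):
        start = circular_day(t["day"] + 1)  # 0-based position -> ordinal day
        end = circular_day(t_next["day"])
        states.append(SeasonState(str(t["to"]), start, end))
    return SeasonCalendar(states=states, provenance=provenance or {})


# ---------------------------------------------------------------------------
# PCA characterization


@dataclass
class PcaSummary:
    loadings: pd.DataFrame  # variables x components (unit-norm columns)
    pct_variance: np.ndarray  # percent variance per component
    scores: pd.DataFrame  # per-day component scores with state labels


def characterize_pca(data: pd.DataFrame, day_states: pd.Series) -> PcaSummary:
    """PCA of the retained daily matrix, scores labeled by state.

    ``day_states`` maps the rows of ``data`` (ordinal days) to state
    labels.  Components 1 and 2 are reported (or a single component for a
    rank-1 problem).
    """
    clean = data.dropna(axis=0)
    if clean.shape[1] < 2:
        raise ValueError("PCA needs at least 2 retained variables")
    n_comp = min(2, clean.shape[1], len(clean))
    pca = PCA(n_components=n_comp, random_state=0)
    sc = pca.fit_transform(clean.to_numpy(float))
    comp_names = [f"component_{i + 1}" for i in range(n_comp)]
    loadings = pd.DataFrame(
        pca.components_.T, index=clean.columns, columns=comp_names
    )
    scores = pd.DataFrame(sc, index=clean.index, columns=comp_names)
    scores["state"] = day_states.reindex(clean.index).to_numpy()
    return PcaSummary(
        loadings=loadings,
        pct_variance=pca.explained_variance_ratio_ * 100.0,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# the full stage


@dataclass
class SeasonConfig:
    """Settings of the seasonality stage (defaults follow the study design;
    tests use the lighter replicates/seeds profile)."""

    k_min: int = 2
    k_max: int = 8
    replicates: int = 5000
    n_seeds: int = 10
    gamma: float = 0.75
    window: int = 5
    run_length: int = 8
    k_probe: int = 2
    anova_alpha: float = 0.05
    anova_mode: str = "remove_nonsignificant"
    seed: int = 0


@dataclass
class SeasonalityResult:
    status: str  # "seasonal" | NO_SEASONAL_STATES
    calendar: SeasonCalendar | None
    hinov: HinovReport
    k_selection: KSelection | None
    stability: dict[int, StabilityReport]
    pca: PcaSummary | None
    retained_variables: list[str]
    day_labels: pd.Series | None = None  # smoothed label per ordinal day


def _fill_missing_days(labels: pd.Series) -> pd.Series:
    """Assign each missing ordinal day the label of the nearest labeled day
    (circular; earlier day wins ties)."""
    full = pd.Series(index=pd.RangeIndex(1, DAYS_PER_YEAR + 1), dtype=object)
    full.loc[labels.index] = labels.values
    if full.isna().any():
        known = labels.index.to_numpy()
        for d in full.index[full.isna()]:
            deltas = np.abs([((d - kd + 182) % 365) - 182 for kd in known])
            full.loc[d] = labels.loc[known[int(np.argmin(deltas))]]
    return full


def run_seasonality(matrix, config: SeasonConfig | None = None) -> SeasonalityResult:
    """Execute the full seasonality stage on a daily space-use matrix.

    ``matrix`` is a :class:`~ecoseasons.trackprep.DailySpaceUseMatrix` (its
    ``retained`` frame is used) or a bare DataFrame of transformed daily
    covariates.  Returns a calendar when a stable clustering exists for at
    least one candidate k, else the "no seasonal states" outcome.
    """
    config = config or SeasonConfig()
    X = matrix.retained if hasattr(matrix, "retained") else matrix.dropna(axis=0)

    hinov = hinov_screen(X, k_probe=config.k_probe, seed=config.seed)
    # removal acts only when the topri ranking beats its permutation null:
    # with no informative variable the largest-gap flags (and any ANOVA
    # against a partition of pure noise) would merely concentrate the
    # matrix on a spurious axis
    if hinov.informative:
        keep = [
            c for c in X.columns if c not in hinov.flagged_noisy + hinov.excluded
        ]
        if len(keep) >= 2:
            X = X[keep]

        provisional = _kmeans(X.to_numpy(float), config.k_probe, config.seed).labels_
        with warnings.catch_warnings():
            if config.anova_mode == "remove_significant":
                warnings.simplefilter("always")
            removed, pvals = anova_screen(
                X, provisional, alpha=config.anova_alpha, mode=config.anova_mode
            )
        hinov.anova_p = pvals
        hinov.anova_removed = removed
        keep = [c for c in X.columns if c not in removed]
        if len(keep) >= 2:
            X = X[keep]

    ksel = select_k(X, config.k_min, config.k_max, seed=config.seed)
    stability: dict[int, StabilityReport] = {}
    chosen = None
    for k in ksel.candidates:  # ascending: prefer the smaller stable k
        rep = stable_kmeans(
            X,
            k,
            B=config.replicates,
            n_seeds=config.n_seeds,
            gamma=config.gamma,
            base_seed=config.seed,
        )
        stability[k] = rep
        if rep.stable:
            chosen = rep
            break

    if chosen is None:
        return SeasonalityResult(
            status=NO_SEASONAL_STATES,
            calendar=None,
            hinov=hinov,
            k_selection=ksel,
            stability=stability,
            pca=None,
            retained_variables=list(X.columns),
        )

    present_days = X.dropna(axis=0).index
    raw = pd.Series(chosen.assignment, index=present_days)
    full = _fill_missing_days(raw)
    smoothed = smooth_assignments(full.to_numpy(), window=config.window)
    try:
        calendar = transition_dates(
            smoothed,
            run_length=config.run_length,
            provenance={
                "k": chosen.k,
                "n_seeds": config.n_seeds,
                "replicates": config.replicates,
                "gamma": config.gamma,
                "window": config.window,
                "run_length": config.run_length,
                "seed": config.seed,
            },
        )
    except ValueError:
        # smoothing/merging collapsed the labels to one regime
        return SeasonalityResult(
            status=NO_SEASONAL_STATES,
            calendar=None,
            hinov=hinov,
            k_selection=ksel,
            stability=stability,
            pca=None,
            retained_variables=list(X.columns),
        )

    day_labels = pd.Series(
        smoothed, index=pd.RangeIndex(1, DAYS_PER_YEAR + 1, name="ordinal_day")
    )
    states_of_days = day_labels.astype(str)
    pca = characterize_pca(X, states_of_days)
    return SeasonalityResult(
        status="seasonal",
        calendar=calendar,
        hinov=hinov,
        k_selection=ksel,
        stability=stability,
        pca=pca,
        retained_variables=list(X.columns),
        day_labels=day_labels,
    )
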