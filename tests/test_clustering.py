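"""Screening, k selection, bootstrap stability, smoothing, transition dating."""

import numpy as np
import pandas as pd
import pytest

from ecoseasons import (
    SeasonConfig,
    anova_screen,
    characterize_pca,
    hinov_screen,
    run_seasonality,
    select_k,
    smooth_assignments,
    stable_kmeans,
    transition_dates,
    transition_days,
)
from ecoseasons.clustering import jaccard, merge_short_runs


# ---------------------------------------------------------------------------
# oracles (independent of the implementation paths they check)


def oracle_window_mode(labels, window, i):
    """Mode of the circular window centered on i; ties prefer labels[i],
    then the smallest label."""
    n = len(labels)
    half = window // 2
    win = [labels[(i + d) % n] for d in range(-half, half + 1)]
    counts = {}
    for v in win:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    tied = sorted(v for v, c in counts.items() if c == best)
    return labels[i] if labels[i] in tied else tied[0]


def oracle_smooth(labels, window=5):
    return [oracle_window_mode(labels, window, i) for i in range(len(labels))]


def oracle_transitions(labels, run_length=8):
    """Exhaustive run-scan transition dating on a circular label sequence.

    Re-derives macro regimes by iterative merging of short runs, then for
    each boundary scans every position of the doubled sequence for the
    first forward run of the new label and the last backward run of the
    old label.
    """
    labels = list(labels)
    n = len(labels)

    def rle(seq):
        # circular run-length encoding starting at a true run boundary
        start = 0
        if all(s == seq[0] for s in seq):
            return [(seq[0], 0, len(seq))]
        while seq[(start - 1) % n] == seq[start]:
            start = (start - 1) % n
        runs = []
        i, seen = start, 0
        while seen < n:
            j, ln = i, 0
            while ln < n and seq[j % n] == seq[i % n]:
                ln += 1
                j += 1
            runs.append((seq[i % n], i % n, ln))
            seen += ln
            i = j
        return runs

    merged = list(labels)
    while True:
        runs = rle(merged)
        if len(runs) == 1:
            return None
        short = [r for r in runs if r[2] < run_length]
        if not short:
            break
        lab, start, ln = min(short, key=lambda r: r[2])
        k = runs.index((lab, start, ln))
        prev, nxt = runs[(k - 1) % len(runs)], runs[(k + 1) % len(runs)]
        absorb = prev if prev[2] >= nxt[2] else nxt
        for off in range(ln):
            merged[(start + off) % n] = absorb[0]

    out = []
    for k, (u_lab, u_start, u_len) in enumerate(runs):
        o_lab, o_start, o_len = runs[(k - 1) % len(runs)]
        a = b = None
        for off in range(o_len + u_len):
            d = (o_start + off) % n
            if all(labels[(d + t) % n] == u_lab for t in range(run_length)):
                a = d
                break
        for off in range(o_len + u_len - 1, -1, -1):
            d = (o_start + off) % n
            s = (d - run_length + 1) % n
            if all(labels[(s + t) % n] == o_lab for t in range(run_length)):
                b = (d + 1) % n
                break
        if a is None or b is None:
            a = b = u_start
        delta = (a - b) % n
        if delta > n / 2:
            delta -= n
        import math

        day = (b + math.floor(delta / 2 + 0.5)) % n
        out.append((o_lab, u_lab, day))
    return out


def random_blocky_labels(rng, n=365, n_labels=2, flip=0.05):
    """Piecewise-constant circular labels with occasional noise flips."""
    labels = []
    while len(labels) < n:
        labels.extend([rng.integers(0, n_labels)] * rng.integers(10, 70))
    labels = np.array(labels[:n])
    noise = rng.uniform(size=n) < flip
    labels[noise] = rng.integers(0, n_labels, size=noise.sum())
    return labels


def blobs(rng, centers, n_per, sd=1.0):
    parts = [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    return pd.DataFrame(np.vstack(parts))


# ---------------------------------------------------------------------------
# HINoV + ANOVA


class TestHinov:
    def test_pure_noise_variable_has_minimum_topri(self):
        rng = np.random.default_rng(21)
        signal = np.concatenate([rng.normal(0, 1, 30), rng.normal(6, 1, 30)])
        df = pd.DataFrame(
            {
                "a": signal + rng.normal(0, 0.3, 60),
                "b": signal + rng.normal(0, 0.3, 60),
                "noise": rng.uniform(size=60),
            }
        )
        rep = hinov_screen(df, k_probe=2, seed=0)
        assert rep.topri.idxmin() == "noise"
        assert rep.topri.index[0] in ("a", "b")
        assert "noise" in rep.flagged_noisy
        assert set(rep.informative) <= {"a", "b"}

    def test_identical_variables_have_equal_topri(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=80)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        rep = hinov_screen(df, k_probe=2, seed=0, n_reference=0)
        assert rep.topri.nunique() == 1
        assert rep.flagged_noisy == []

    def test_topri_invariant_to_cluster_relabeling(self):
        # ARI is label-invariant, so shifting every value (which permutes
        # which k-means cluster gets id 0) must not change topri
        rng = np.random.default_rng(23)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        r1 = hinov_screen(df, seed=0, n_reference=0)
        r2 = hinov_screen(-df, seed=0, n_reference=0)
        pd.testing.assert_series_equal(
            r1.topri.sort_index(), r2.topri.sort_index(), atol=1e-12
        )

    def test_constant_variable_excluded(self):
        rng = np.random.default_rng(24)
        df = pd.DataFrame(
            {"a": rng.normal(size=50), "b": rng.normal(size=50), "c": 1.0}
        )
        rep = hinov_screen(df, seed=0, n_reference=0)
        assert rep.excluded == ["c"]

    def test_noise_ranked_last_across_seeded_replicates(self):
        """An injected pure-noise column receives the minimum topri in at
        least 95% of 40 seeded replicates."""
        wins = 0
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            signal = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
            df = pd.DataFrame(
                {
                    "a": signal + rng.normal(0, 0.5, 60),
                    "b": signal + rng.normal(0, 0.5, 60),
                    "c": signal + rng.normal(0, 0.5, 60),
                    "noise": rng.uniform(-3, 3, size=60),
                }
            )
            rep = hinov_screen(df, k_probe=2, seed=s, n_reference=0)
            wins += rep.topri.idxmin() == "noise"
        assert wins >= 38


class TestAnovaScreen:
    def test_identical_distribution_not_listed(self):
        rng = np.random.default_rng(25)
        df = pd.DataFrame({"flat": rng.normal(size=60)})
        groups = np.repeat([0, 1], 30)
        with pytest.warns(UserWarning):
            removed, p = anova_screen(df, groups, mode="remove_significant")
        assert removed == []
        assert p["flat"] > 0.05

    def test_separated_means_listed(self):
        rng = np.random.default_rng(26)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        df = pd.DataFrame({"sep": x})
        groups = np.repeat([0, 1], 30)
        with pytest.warns(UserWarning):
            removed, p = anova_screen(df, groups, mode="remove_significant")
        assert removed == ["sep"]
        assert p["sep"] < 1e-10

    def test_alpha_zero_never_lists_significant(self):
        rng = np.random.default_rng(27)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        df = pd.DataFrame({"sep": x})
        with pytest.warns(UserWarning):
            removed, _ = anova_screen(
                df, np.repeat([0, 1], 30), alpha=0.0, mode="remove_significant"
            )
        assert removed == []

    def test_nonsignificant_mode_removes_noise(self):
        rng = np.random.default_rng(28)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(10, 1, 30)])
        df = pd.DataFrame({"sep": x, "noise": rng.normal(size=60)})
        removed, _ = anova_screen(
            df, np.repeat([0, 1], 30), mode="remove_nonsignificant"
        )
        assert removed == ["noise"]

    def test_unknown_mode_and_single_group_raise(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            anova_screen(df, np.repeat([0, 1], 5), mode="bogus")
        with pytest.raises(ValueError):
            anova_screen(df, np.zeros(10), mode="remove_nonsignificant")


# ---------------------------------------------------------------------------
# choosing k


class TestSelectK:
    def test_two_blobs_yield_two_by_both_methods(self):
        rng = np.random.default_rng(30)
        df = blobs(rng, [(0, 0), (10, 10)], 60)
        sel = select_k(df, 2, 6, seed=0)
        assert sel.k_elbow == 2
        assert sel.k_silhouette == 2

    def test_three_blobs_yield_three_by_silhouette(self):
        rng = np.random.default_rng(31)
        df = blobs(rng, [(0, 0), (12, 0), (6, 10.4)], 50)
        sel = select_k(df, 2, 6, seed=0)
        assert sel.k_silhouette == 3

    def test_silhouette_values_bounded(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame(rng.normal(size=(80, 3)))
        sel = select_k(df, 2, 6, seed=0)
        assert all(-1 <= v <= 1 for v in sel.silhouette.values())

    def test_k_max_beyond_rows_raises(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            select_k(df, 2, 8, seed=0)


# ---------------------------------------------------------------------------
# bootstrap stability


class TestStability:
    def test_jaccard_identical_and_disjoint(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard({1, 2}, {3, 4}) == 0.0
        assert jaccard(set(), set()) == 1.0

    def test_well_separated_blobs_are_stable(self):
        rng = np.random.default_rng(33)
        df = blobs(rng, [(0, 0), (20, 20)], 100)
        rep = stable_kmeans(df, 2, B=200, n_seeds=3, base_seed=0)
        assert rep.stable
        assert rep.min_jaccard() > 0.95
        assert rep.assignment is not None and len(rep.assignment) == 200

    def test_single_gaussian_forced_split_is_unstable(self):
        """k-means on one spherical Gaussian forced to k=2 is judged
        unstable in at least 9 of 10 outer replications."""
        unstable = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            df = pd.DataFrame(rng.normal(size=(365, 6)))
            rep = stable_kmeans(df, 2, B=200, n_seeds=3, base_seed=s)
            unstable += not rep.stable
        assert unstable >= 9

    def test_jaccard_means_bounded_and_monotone_in_separation(self):
        mins = []
        for sep in (0.0, 4.0, 20.0):
            vals = []
            for s in range(5):
                rng = np.random.default_rng(300 + s)
                df = blobs(rng, [(0, 0), (sep, 0)], 60)
                rep = stable_kmeans(df, 2, B=60, n_seeds=2, base_seed=s)
                m = rep.mean_jaccard.to_numpy()
                assert ((m >= 0) & (m <= 1 + 1e-12)).all()
                vals.append(rep.min_jaccard())
            mins.append(np.mean(vals))
        assert mins[0] <= mins[1] + 0.05 <= mins[2] + 0.10


# ---------------------------------------------------------------------------
# smoothing


class TestSmoothing:
    def test_constant_labels_unchanged(self):
        labels = np.zeros(20, dtype=int)
        assert (smooth_assignments(labels) == labels).all()

    def test_single_blip_removed_on_20_day_circle(self):
        labels = np.zeros(20, dtype=int)
        labels[10] = 1
        out = smooth_assignments(labels, window=5)
        assert (out == 0).all()
        assert out.tolist() == oracle_smooth(labels.tolist())

    def test_two_two_tie_keeps_own_label(self):
        # window [A A B B A]: 5th entry is the center day's own label A;
        # drop it to force an exact 2-2 tie around the boundary
        labels = np.array([0, 0, 0, 1, 1, 0, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        out = smooth_assignments(labels, window=5)
        assert out.tolist() == oracle_smooth(labels.tolist())

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            smooth_assignments(np.zeros(10, dtype=int), window=4)

    def test_matches_oracle_on_random_circles(self):
        rng = np.random.default_rng(34)
        for _ in range(300):
            n = int(rng.integers(5, 31))
            labels = rng.integers(0, 2, size=n)
            out = smooth_assignments(labels, window=5)
            assert out.tolist() == oracle_smooth(labels.tolist()), labels

    def test_matches_oracle_exhaustively_on_short_circles(self):
        for n in (5, 6, 7, 8):
            for code in range(2**n):
                labels = np.array([(code >> i) & 1 for i in range(n)])
                out = smooth_assignments(labels, window=5)
                assert out.tolist() == oracle_smooth(labels.tolist())


# ---------------------------------------------------------------------------
# transition dating


class TestTransitions:
    def test_clean_step_change_dates_exactly(self):
        labels = np.zeros(365, dtype=int)
        labels[99:299] = 1  # positions 99..298 = ordinal days 100..299
        cal = transition_dates(labels)
        assert sorted(t["day"] for t in cal.transitions()) == [100, 300]
        assert sum(s.n_days for s in cal.states) == 365

    def test_isolated_blip_skipped_by_forward_scan(self):
        # ... A A B A B B B B B B ... (the isolated B is skipped; the
        # 8-run of B starts after the isolated A)
        labels = np.zeros(60, dtype=int)
        labels[20] = 1
        labels[22:40] = 1
        got = transition_days(labels, run_length=8)
        expected = oracle_transitions(labels.tolist(), run_length=8)
        assert {(t["from"], t["to"], t["day"]) for t in got} == set(expected)

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(35)
        checked = 0
        while checked < 1000:
            labels = random_blocky_labels(rng, n=120, flip=0.06)
            expected = oracle_transitions(labels.tolist())
            if expected is None:
                continue  # merged to a single regime; no transitions exist
            got = transition_days(labels)
            assert {(t["from"], t["to"], t["day"]) for t in got} == set(expected)
            checked += 1

    def test_collapsing_sequence_raises(self):
        labels = np.zeros(365, dtype=int)
        labels[10:14] = 1  # 4-day regime cannot satisfy an 8-day run
        with pytest.raises(ValueError):
            transition_days(labels)
        with pytest.raises(ValueError):
            transition_days(np.zeros(30, dtype=int))

    def test_two_state_calendar_tiles_for_random_inputs(self):
        rng = np.random.default_rng(36)
        made = 0
        while made < 30:
            labels = random_blocky_labels(rng, n=365, flip=0.03)
            try:
                cal = transition_dates(labels)
            except ValueError:
                continue
            assert sum(s.n_days for s in cal.states) == 365
            # each transition date is the first day of its incoming state
            incoming = cal.states[1:] + cal.states[:1]
            for t, state in zip(cal.transitions(), incoming):
                assert state.label == str(t["to"])
                assert state.start_day == t["day"]
            made += 1

    def test_merge_short_runs_absorbs_into_larger_neighbor(self):
        labels = np.array([0] * 20 + [1] * 3 + [2] * 30)
        merged = merge_short_runs(labels, 8)
        assert (merged == np.array([0] * 20 + [2] * 33)).all()


# ---------------------------------------------------------------------------
# PCA characterization


class TestPca:
    def test_two_variable_matrix_explains_everything(self):
        rng = np.random.default_rng(37)
        df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["u", "v"])
        df -= df.mean()
        states = pd.Series(["a"] * 100, index=df.index)
        summ = characterize_pca(df, states)
        assert summ.pct_variance.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(
            np.linalg.norm(summ.loadings.to_numpy(), axis=0), 1.0, atol=1e-9
        )

    def test_variance_shares_non_increasing(self):
        rng = np.random.default_rng(38)
        df = pd.DataFrame(rng.normal(size=(80, 5)))
        summ = characterize_pca(df, pd.Series(["a"] * 80))
        assert summ.pct_variance[0] >= summ.pct_variance[1]

    def test_isotropic_noise_component_share_within_envelope(self):
        """On isotropic noise the leading share stays inside a
        simulation envelope around 1/6."""
        def comp1_share(seed):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(365, 6)))
            return characterize_pca(df, pd.Series(["a"] * 365)).pct_variance[0]

        envelope = [comp1_share(500 + i) for i in range(30)]
        observed = comp1_share(11)
        assert min(envelope) - 1.5 <= observed <= max(envelope) + 1.5
        assert abs(observed / 100 - 1 / 6) < 0.05


# ---------------------------------------------------------------------------
# the full stage


class TestRunSeasonality:
    def test_deterministic_given_identical_seeds(self, two_regime_matrix):
        cfg = SeasonConfig(replicates=60, n_seeds=2, seed=5)
        r1 = run_seasonality(two_regime_matrix, cfg)
        r2 = run_seasonality(two_regime_matrix, cfg)
        assert r1.status == r2.status
        if r1.calendar is not None:
            assert r1.calendar.to_dict() == r2.calendar.to_dict()
            pd.testing.assert_frame_equal(
                r1.stability[r1.calendar.provenance["k"]].mean_jaccard,
                r2.stability[r2.calendar.provenance["k"]].mean_jaccard,
            )

    def test_two_regime_matrix_yields_two_state_calendar(self, two_regime_matrix):
        cfg = SeasonConfig(replicates=100, n_seeds=2, seed=0)
        res = run_seasonality(two_regime_matrix, cfg)
        assert res.status == "seasonal"
        assert len(res.calendar.states) == 2
        days = sorted(t["day"] for t in res.calendar.transitions())
        assert abs(days[0] - 100) <= 3 and abs(days[1] - 300) <= 3
        assert res.pca is not None
        assert res.day_labels is not None and len(res.day_labels) == 365
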