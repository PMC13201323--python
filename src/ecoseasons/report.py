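"""Derived quantities and serialization around the season pipeline.

Covers the green-up proxy (daily growing-degree-day change, ΔGDD, from mean
daily temperature above a plant-growth base threshold), its association
with snow depth, signed circular offsets between populations' transition
dates, and figure-ready CSV/JSON exports with provenance headers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import UndefinedCorrelationError
from .season_calendar import DAYS_PER_YEAR, SeasonCalendar, circular_diff
from .trackprep import ordinal_day


def gdd_series(weather_table: pd.DataFrame, base_temp: float = 1.0) -> pd.DataFrame:
    """Growing-degree-day series from a daily weather table.

    The daily increment is ``max(0, mean_temp - base_temp)``; the
    accumulation resets every 1 January; ΔGDD (the day-over-day change of
    the accumulation) equals the increment.  The default base of 1 °C is
    the operative plant-growth threshold for the study latitude (the
    latitudinal correction that produces it is applied upstream and is
    exposed here only through ``base_temp``).  Missing days stay missing.
    """
    df = weather_table.copy()
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in weather table")
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    full = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    if getattr(df["date"].dt, "tz", None) is not None:
        full = full.tz_localize(df["date"].dt.tz) if full.tz is None else full
    df = df.set_index("date").reindex(full)
    df.index.name = "date"
    inc = (df["mean_temp"] - base_temp).clip(lower=0)
    accum = inc.groupby(df.index.year).cumsum()
    out = pd.DataFrame(
        {
            "mean_temp": df["mean_temp"],
            "gdd_increment": inc,
            "gdd_accum": accum,
            "delta_gdd": inc,
        }
    )
    out.attrs["base_temp"] = base_temp
    return out.reset_index()


def correlate_gdd_snow(delta_gdd: pd.Series, snow_depth: pd.Series):
    """Pearson correlation of ΔGDD and snow depth with its t statistic.

    Returns (r, t, p) with ``t = r sqrt((n-2) / (1-r^2))`` and a two-sided
    p value.  Input series are aligned on their index; missing pairs drop.
    """
    pair = pd.concat(
        {"gdd": pd.Series(delta_gdd), "snow": pd.Series(snow_depth)}, axis=1
    ).dropna()
    n = len(pair)
    if n < 3:
        raise ValueError(f"need >= 3 aligned pairs, have {n}")
    if pair["gdd"].nunique() == 1 or pair["snow"].nunique() == 1:
        raise UndefinedCorrelationError("zero variance in a series")
    r = float(np.corrcoef(pair["gdd"], pair["snow"])[0, 1])
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        return r, t, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * sstats.t.sf(abs(t), df=n - 2)
    return r, float(t), float(p)


def to_ordinal(date_like) -> int:
    """Ordinal day 1..365 from an int, a date string, or a timestamp."""
    if isinstance(date_like, (int, np.integer)):
        d = int(date_like)
        if not 1 <= d <= DAYS_PER_YEAR:
            raise ValueError(f"ordinal day {d} out of 1..365")
        return d
    return int(ordinal_day(pd.Series([pd.Timestamp(date_like)])).iloc[0])


@dataclass
class OffsetTable:
    """Signed circular day offsets between populations' transitions."""

    table: pd.DataFrame  # population_a, population_b, boundary, offset_days
    notices: list[str]


def _transition_map(calendar_or_dates) -> dict[str, int]:
    if isinstance(calendar_or_dates, SeasonCalendar):
        return {
            f"{t['from']}_to_{t['to']}": int(t["day"])
            for t in calendar_or_dates.transitions()
        }
    return {str(k): to_ordinal(v) for k, v in calendar_or_dates.items()}


def season_offsets(calendars: dict[str, object]) -> OffsetTable:
    """Signed day offsets between populations for shared boundary types.

    ``calendars`` maps population name to either a SeasonCalendar or a
    mapping of boundary type to transition date (ordinal day, date string,
    or timestamp).  For each boundary type and ordered population pair
    (A, B), the offset is the signed shortest-arc difference in days,
    positive when A's transition falls later than B's.  Populations missing
    a boundary are skipped for that boundary with a notice.
    """
    trans = {pop: _transition_map(c) for pop, c in calendars.items()}
    boundaries = sorted({b for t in trans.values() for b in t})
    rows = []
    notices = []
    pops = list(trans)
    for b in boundaries:
        have = [p for p in pops if b in trans[p]]
        miss = [p for p in pops if b not in trans[p]]
        for p in miss:
            notices.append(f"population {p!r} has no boundary {b!r}; row omitted")
        for i, pa in enumerate(have):
            for pb in have:
                if pa == pb:
                    continue
                rows.append(
                    {
                        "population_a": pa,
                        "population_b": pb,
                        "boundary": b,
                        "offset_days": circular_diff(trans[pa][b], trans[pb][b]),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["population_a", "population_b", "boundary", "offset_days"]
    )
    return OffsetTable(table=table, notices=notices)


# ---------------------------------------------------------------------------
# exports


def _provenance_header(provenance: dict) -> str:
    blob = json.dumps(provenance, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    lines = [f"# config_hash: {digest}"]
    for k in sorted(provenance):
        lines.append(f"# {k}: {provenance[k]}")
    return "\n".join(lines) + "\n"


def export_reports(
    out_dir: str | Path,
    calendars: dict[str, SeasonCalendar] | None = None,
    gdd: pd.DataFrame | None = None,
    pca_summaries: dict[str, object] | None = None,
    pooled: list[tuple[str, str, object]] | None = None,
    provenance: dict | None = None,
) -> dict[str, Path]:
    """Write the pipeline's artifact files to ``out_dir``.

    Produces (where inputs are given) a calendar JSON, a per-ordinal-day
    state CSV with the ΔGDD column, a PCA-loadings CSV, and a pooled-RSF
    coefficient CSV.  ``pooled`` entries are (population, state, PopulationRsf).
    Every CSV carries a provenance header (hash of the provenance dict);
    writes are deterministic so re-export is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = dict(provenance or {})
    header = _provenance_header(provenance)
    written: dict[str, Path] = {}

    prov_path = out / "provenance.json"
    prov_path.write_text(
        json.dumps({"provenance": provenance}, indent=2, sort_keys=True, default=str)
    )
    written["provenance"] = prov_path

    if calendars:
        cal_path = out / "calendars.json"
        cal_path.write_text(
            json.dumps(
                {pop: c.to_dict() for pop, c in sorted(calendars.items())},
                indent=2,
                sort_keys=True,
            )
        )
        written["calendars"] = cal_path

        rows = pd.DataFrame(
            {"ordinal_day": np.arange(1, DAYS_PER_YEAR + 1)}
        ).set_index("ordinal_day")
        for pop, cal in sorted(calendars.items()):
            rows[pop] = cal.day_labels()
        if gdd is not None:
            g = gdd.copy()
            g["ordinal_day"] = ordinal_day(g["date"])
            rows["delta_gdd"] = g.groupby("ordinal_day")["delta_gdd"].mean()
        day_path = out / "calendar_by_day.csv"
        with open(day_path, "w") as fh:
            fh.write(header)
            rows.to_csv(fh)
        written["calendar_by_day"] = day_path

    if pca_summaries:
        frames = []
        for pop, summ in sorted(pca_summaries.items()):
            lf = summ.loadings.copy()
            lf.insert(0, "population", pop)
            lf.index.name = "variable"
            for i, pct in enumerate(summ.pct_variance):
                lf[f"pct_variance_{i + 1}"] = pct
            frames.append(lf.reset_index())
        pca_path = out / "pca_loadings.csv"
        with open(pca_path, "w") as fh:
            fh.write(header)
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
        written["pca_loadings"] = pca_path

    if pooled:
        frames = []
        for pop, state, prsf in pooled:
            t = prsf.table.copy()
            t.insert(0, "population", pop)
            t.insert(1, "state", state)
            t.insert(2, "ud_level", prsf.ud_level)
            t.index.name = "predictor"
            frames.append(t.reset_index())
        rsf_path = out / "pooled_rsf.csv"
        with open(rsf_path, "w") as fh:
            fh.write(header)
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
        written["pooled_rsf"] = rsf_path

    return written
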