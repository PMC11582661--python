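"""Descriptive surveillance demography: person-years and rates per 1000.

Event rates (births, deaths, in-/out-migration, household entry and exit,
and net migration) are computed per 1000 person-years of residency, within
strata defined by calendar year, gender, slum area and age group.  Day
offsets are mapped to calendar dates through a configurable epoch (day 0 is
2002-01-01 by default, the baseline census).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import DEATH

logger = logging.getLogger(__name__)

DEFAULT_EPOCH = pd.Timestamp("2002-01-01")
DAYS_PER_YEAR = 365.25

#: States whose occupant is resident in the surveillance area.
RESIDENT_STATES = frozenset({1, 2, 3, 4, 6})

EVENT_TYPES = ("birth", "death", "in_migration", "out_migration",
               "entry", "exit")
_STATE_EVENT = {2: "birth", 3: "exit", 4: "entry", 5: "out_migration",
                6: "in_migration", DEATH: "death"}

AGE_GROUP_LABELS = ("0-14", "15-19", "20-35", "36-50", "51+")
_AGE_BREAKS = (0.0, 15.0, 20.0, 36.0, 51.0, np.inf)


def age_group(age) -> np.ndarray | str:
    """Map ages in years to the five analysis bins (left-closed)."""
    arr = np.asarray(age, float)
    if np.any(arr < 0):
        raise ValueError("age must be non-negative")
    idx = np.searchsorted(_AGE_BREAKS, arr, side="right") - 1
    out = np.asarray(AGE_GROUP_LABELS, object)[idx]
    return out if np.ndim(out) else str(out)


@dataclass(frozen=True)
class ResidencyEpisode:
    """A half-open interval [start, end) of residency, in study days."""

    individual_id: object
    start: float
    end: float
    gender: str
    slum_area: str
    birth_day: float  # day offset of the individual's birth (may be < 0)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("episode must have start < end")


def residency_episodes(history, gender, slum_area, age_at_onset) -> list:
    """Residency episodes of one exact trajectory.

    Residency runs while the current state is one of the resident states;
    an out-migration jump closes the episode, an in-migration reopens it,
    death ends follow-up.
    """
    birth_day = history.onset - float(age_at_onset) * DAYS_PER_YEAR
    episodes = []
    open_start = None
    last_t = history.onset
    for t, s in history.jumps:
        resident = s in RESIDENT_STATES
        if resident and open_start is None:
            open_start = t
        elif not resident and open_start is not None:
            if t > open_start:
                episodes.append(ResidencyEpisode(
                    history.individual_id, open_start, t, gender, slum_area,
                    birth_day))
            open_start = None
        last_t = t
    return episodes, open_start, last_t, birth_day


def episodes_from_histories(histories, roster, horizon: float) -> pd.DataFrame:
    """Tidy episode table for a simulated cohort (censored at ``horizon``)."""
    idx = roster.set_index("individual_id")
    rows = []
    for h in histories:
        rec = idx.loc[h.individual_id]
        onset_age = 0.0 if h.jumps[0][1] == 2 else float(rec["age"])
        eps, open_start, _, birth_day = residency_episodes(
            h, rec["gender"], rec["slum_area"], onset_age)
        for e in eps:
            rows.append((e.individual_id, e.start, e.end, e.gender,
                         e.slum_area, e.birth_day))
        if open_start is not None and horizon > open_start:
            rows.append((h.individual_id, open_start, horizon, rec["gender"],
                         rec["slum_area"], birth_day))
    return pd.DataFrame(rows, columns=[
        "individual_id", "start", "end", "gender", "slum_area", "birth_day"])


def events_from_histories(histories, roster) -> pd.DataFrame:
    """Tidy event table (one row per dated demographic event)."""
    idx = roster.set_index("individual_id")
    rows = []
    for h in histories:
        rec = idx.loc[h.individual_id]
        onset_age = 0.0 if h.jumps[0][1] == 2 else float(rec["age"])
        birth_day = h.onset - onset_age * DAYS_PER_YEAR
        jumps = list(h.jumps)
        # the initial enumeration record is a census, not an event; an
        # in-study birth's first jump IS the birth event
        for t, s in (jumps if jumps[0][1] == 2 else jumps[1:]):
            ev = _STATE_EVENT.get(s)
            if ev is not None:
                rows.append((h.individual_id, t, ev, rec["gender"],
                             rec["slum_area"], birth_day))
    return pd.DataFrame(rows, columns=[
        "individual_id", "day", "event_type", "gender", "slum_area",
        "birth_day"])


def _year_bounds(year: int, epoch: pd.Timestamp) -> tuple[float, float]:
    d0 = (pd.Timestamp(year=year, month=1, day=1) - epoch).days
    d1 = (pd.Timestamp(year=year + 1, month=1, day=1) - epoch).days
    return float(d0), float(d1)


def _midyear_day(year: int, epoch: pd.Timestamp) -> float:
    return float((pd.Timestamp(year=year, month=7, day=1) - epoch).days)


def person_years(episodes: pd.DataFrame, year: int,
                 epoch: pd.Timestamp = DEFAULT_EPOCH, **stratum) -> float:
    """Person-years of residency overlapping one calendar year in a stratum.

    ``stratum`` filters on equality of episode columns, with ``age_group``
    evaluated at mid-year.  An empty overlap yields 0.0.
    """
    if len(episodes) == 0:
        return 0.0
    d0, d1 = _year_bounds(year, epoch)
    ep = episodes
    for key, val in stratum.items():
        if key == "age_group":
            ages = (_midyear_day(year, epoch) - ep["birth_day"]) / DAYS_PER_YEAR
            ep = ep[age_group(np.maximum(ages, 0.0)) == val]
        else:
            ep = ep[ep[key] == val]
    overlap = (np.minimum(ep["end"], d1) - np.maximum(ep["start"], d0)).clip(lower=0)
    return float(overlap.sum() / DAYS_PER_YEAR)


def event_rate(count, person_years: float) -> float:
    """Events per 1000 person-years; the count may be signed (net migration)."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * count / person_years


def rate_series(events: pd.DataFrame, episodes: pd.DataFrame,
                stratifiers=(), epoch: pd.Timestamp = DEFAULT_EPOCH) -> pd.DataFrame:
    """Stratified annual event rates per 1000 person-years.

    One row per year x stratum x event type (including ``net_migration`` =
    in-migration count minus out-migration count over the same denominator).
    Ages are evaluated at mid-year.  Strata with zero person-years are
    omitted with a logged warning.
    """
    allowed = {"gender", "slum_area", "age_group"}
    bad = set(stratifiers) - allowed
    if bad:
        raise ValueError(f"unknown stratifiers: {sorted(bad)} (year is implicit)")
    stratifiers = tuple(stratifiers)

    y_min = int((epoch + pd.Timedelta(days=float(episodes["start"].min()))).year)
    y_max = int((epoch + pd.Timedelta(days=float(episodes["end"].max()) - 1e-9)).year)

    rows = []
    for year in range(y_min, y_max + 1):
        d0, d1 = _year_bounds(year, epoch)
        ev = events[(events["day"] >= d0) & (events["day"] < d1)].copy()
        mid = _midyear_day(year, epoch)

        ep = episodes.copy()
        ep["overlap"] = (np.minimum(ep["end"], d1)
                         - np.maximum(ep["start"], d0)).clip(lower=0)
        ep = ep[ep["overlap"] > 0]
        if "age_group" in stratifiers:
            ep["age_group"] = age_group(
                np.maximum((mid - ep["birth_day"]) / DAYS_PER_YEAR, 0.0))
            ev["age_group"] = age_group(
                np.maximum((mid - ev["birth_day"]) / DAYS_PER_YEAR, 0.0))

        if stratifiers:
            py = ep.groupby(list(stratifiers))["overlap"].sum() / DAYS_PER_YEAR
            strata = list(py.index if len(stratifiers) > 1
                          else [(v,) for v in py.index])
            py_lookup = {tuple(np.atleast_1d(k)): v for k, v in py.items()}
        else:
            strata = [()]
            py_lookup = {(): float(ep["overlap"].sum()) / DAYS_PER_YEAR}

        for key in strata:
            key = tuple(np.atleast_1d(key))
            pys = float(py_lookup[key])
            if pys <= 0:
                logger.warning("stratum %s in %d has zero person-years; "
                               "rows omitted", dict(zip(stratifiers, key)), year)
                continue
            sub = ev
            for name, val in zip(stratifiers, key):
                sub = sub[sub[name] == val]
            counts = sub["event_type"].value_counts()
            stratum = dict(zip(stratifiers, key))
            for etype in EVENT_TYPES:
                c = int(counts.get(etype, 0))
                rows.append({"year": year, **stratum, "event_type": etype,
                             "count": c, "person_years": pys,
                             "rate_per_1000": event_rate(c, pys)})
            net = int(counts.get("in_migration", 0)) - int(
                counts.get("out_migration", 0))
            rows.append({"year": year, **stratum, "event_type": "net_migration",
                         "count": net, "person_years": pys,
                         "rate_per_1000": event_rate(net, pys)})
    return pd.DataFrame(rows)
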