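"""Synthetic surveillance-data generator with known ground truth.

Emulates the residency data of an urban health-and-demographic surveillance
system (HDSS): a roster of individuals with fixed covariates, exact
continuous-time residency trajectories simulated by the Gillespie algorithm
under a specified intensity model, and observation records produced by
~180-day status-update rounds with exactly dated deaths and right-censoring
at the end of follow-up.

Because surveillance systems date every classified event (births, deaths,
migrations, household moves), the default observation stream contains the
event-dated records in addition to the round snapshots (``record_events``);
turn it off to obtain a strict panel design whose observation times are
non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (
    BIRTH_AREA_LEVELS,
    ETHNICITY_LEVELS,
    GENDER_LEVELS,
    SLUM_LEVELS,
    CovariateVector,
)
from .data import split_by_gender
from .states import (
    DEATH,
    ModelParameters,
    default_transition_structure,
    intensity_matrix,
)

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Mean sojourn time (days) per transient state, by gender — the magnitudes
#: reported for the two Nairobi slum surveillance areas.
_SOJOURN_DAYS = {
    "Female": {1: 813.3, 2: 680.3, 3: 8.2, 4: 535.8, 5: 588.7, 6: 566.7},
    "Male": {1: 820.8, 2: 640.2, 3: 8.0, 4: 564.9, 5: 618.1, 6: 604.3},
}

#: Destination split of each transient state's exits (from observed counts).
_DESTINATION_COUNTS = {
    "Female": {
        (1, 3): 10055, (1, 5): 11053, (1, 7): 592,
        (2, 3): 4536, (2, 5): 4780, (2, 7): 635,
        (3, 4): 78842,
        (4, 3): 37156, (4, 5): 26793, (4, 7): 757,
        (5, 6): 16056,
        (6, 3): 27531, (6, 5): 41258, (6, 7): 538,
    },
    "Male": {
        (1, 3): 13882, (1, 5): 15791, (1, 7): 832,
        (2, 3): 4904, (2, 5): 5171, (2, 7): 696,
        (3, 4): 93539,
        (4, 3): 43057, (4, 5): 32752, (4, 7): 1093,
        (5, 6): 18934,
        (6, 3): 32282, (6, 5): 47375, (6, 7): 775,
    },
}

#: Default covariate effects: slum-area and per-year age hazard ratios by
#: gender and transition (the two dominant reported effects); ethnicity and
#: area-of-birth effects default to zero.
_SLUM_HR = {
    "Female": {(1, 3): 1.390, (1, 5): 1.521, (1, 7): 0.766, (2, 3): 0.918,
               (2, 5): 1.123, (2, 7): 0.792, (3, 4): 0.896, (4, 3): 0.901,
               (4, 5): 1.173, (4, 7): 0.858, (5, 6): 1.051, (6, 3): 1.008,
               (6, 5): 1.022, (6, 7): 0.803},
    "Male": {(1, 3): 1.356, (1, 5): 1.656, (1, 7): 0.661, (2, 3): 0.858,
             (2, 5): 1.187, (2, 7): 0.803, (3, 4): 0.851, (4, 3): 0.904,
             (4, 5): 1.163, (4, 7): 0.705, (5, 6): 1.030, (6, 3): 0.930,
             (6, 5): 1.033, (6, 7): 0.600},
}
_AGE_HR = {
    "Female": {(1, 3): 0.993, (1, 5): 0.994, (1, 7): 1.044, (2, 3): 0.994,
               (2, 5): 0.979, (2, 7): 0.988, (3, 4): 1.001, (4, 3): 0.997,
               (4, 5): 0.991, (4, 7): 1.051, (5, 6): 1.003, (6, 3): 0.997,
               (6, 5): 0.998, (6, 7): 1.055},
    "Male": {(1, 3): 0.991, (1, 5): 0.994, (1, 7): 1.039, (2, 3): 0.994,
             (2, 5): 0.988, (2, 7): 0.992, (3, 4): 0.999, (4, 3): 0.993,
             (4, 5): 0.994, (4, 7): 1.039, (5, 6): 1.001, (6, 3): 0.994,
             (6, 5): 0.996, (6, 7): 1.043},
}


def default_true_params(gender: str = "Female",
                        covariate_effects: bool = True) -> ModelParameters:
    """Generating parameters anchored to the reported study magnitudes.

    Baseline per-day intensities are (destination share) / (mean sojourn);
    the optional covariate effects carry the reported slum-area and per-year
    age hazard ratios on every transition.
    """
    structure = default_transition_structure()
    counts = _DESTINATION_COUNTS[gender]
    totals = {}
    for (i, _j), c in counts.items():
        totals[i] = totals.get(i, 0) + c
    baseline = {}
    for pair in structure.allowed:
        share = counts[pair] / totals[pair[0]]
        baseline[pair] = float(np.log(share / _SOJOURN_DAYS[gender][pair[0]]))
    coefs = {}
    if covariate_effects:
        for pair in structure.allowed:
            coefs[(pair, "slum:Viwandani")] = float(np.log(_SLUM_HR[gender][pair]))
            coefs[(pair, "age")] = float(np.log(_AGE_HR[gender][pair]))
    return ModelParameters(structure, baseline, coefs)


#: Covariate marginals of the surveillance population (normalized).
DEFAULT_COVARIATE_PROFILE = {
    "slum_area": {"Korogocho": 0.39, "Viwandani": 0.61},
    "gender": {"Female": 0.453, "Male": 0.547},
    # reported shares 26.8/26.3/16.7/14.9/15.4 sum to 100.1 after rounding;
    # renormalized so the sampling probabilities sum to one
    "ethnicity": {"Kamba": 0.268 / 1.001, "Kikuyu": 0.263 / 1.001,
                  "Luhya": 0.167 / 1.001, "Luo": 0.149 / 1.001,
                  "Other": 0.154 / 1.001},
    "area_of_birth": {"Rural Kenya": 0.689, "Same DSA slum": 0.155,
                      "Nairobi non-slum": 0.090, "Other": 0.066},
    # piecewise-linear quantile curve through the reported age quartiles
    "age_quantiles": ((0.0, 0.0), (0.25, 10.0), (0.5, 22.0),
                      (0.75, 34.0), (1.0, 80.0)),
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the surveillance setting: ~180-day status rounds over a
    14-year horizon, exactly dated deaths, a 2002-style baseline census
    (everyone starts in Enumeration) with a fraction of in-study births, and
    event-dated records in the observation stream.
    """

    n_individuals: int = 1000
    true_params: dict = field(default_factory=lambda: {
        g: default_true_params(g) for g in GENDER_LEVELS
    })
    covariate_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PROFILE))
    panel_interval: float = 180.0
    horizon: float = 5110.0          # 2002-2015, ~14 years in days
    death_exact: bool = True
    record_events: bool = True
    birth_fraction: float = 0.15     # share entering as in-study births
    panel_jitter: float = 0.0        # uniform +-days on round times
    seed: int = 0

    def __post_init__(self):
        for var in ("slum_area", "gender", "ethnicity", "area_of_birth"):
            total = sum(self.covariate_profile[var].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{var} probabilities sum to {total}, not 1")
        if self.panel_interval <= 0:
            raise ValueError("panel_interval must be positive")
        if self.horizon < self.panel_interval:
            raise ValueError("horizon must cover at least one panel interval")


@dataclass
class EventHistory:
    """An exact jump trajectory: ordered (time, state) starting at onset."""

    individual_id: object
    jumps: tuple  # ((time, state), ...)

    def __post_init__(self):
        t = [tt for tt, _ in self.jumps]
        s = [ss for _, ss in self.jumps]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("jump times must strictly increase")
        if any(x == y for x, y in zip(s, s[1:])):
            raise ValueError("successive states must differ")
        if DEATH in s[:-1]:
            raise ValueError("death must be the final jump")

    def state_at(self, t: float) -> int:
        s = self.jumps[0][1]
        for tt, ss in self.jumps:
            if tt <= t:
                s = ss
            else:
                break
        return s

    @property
    def onset(self) -> float:
        return self.jumps[0][0]

    @property
    def death_time(self):
        t, s = self.jumps[-1]
        return t if s == DEATH else None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _sample_age(u: np.ndarray, quantile_curve) -> np.ndarray:
    qs = np.array([q for q, _ in quantile_curve])
    vs = np.array([v for _, v in quantile_curve])
    return np.interp(u, qs, vs)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw the individual roster (covariates + gender) from the profile."""
    rng = np.random.default_rng([config.seed, 999_983])
    n = config.n_individuals
    prof = config.covariate_profile

    def draw(var, levels):
        p = np.array([prof[var][lv] for lv in levels])
        return np.asarray(levels)[rng.choice(len(levels), size=n, p=p)]

    roster = pd.DataFrame({
        "individual_id": [f"id{i:06d}" for i in range(n)],
        "gender": draw("gender", GENDER_LEVELS),
        "slum_area": draw("slum_area", SLUM_LEVELS),
        "ethnicity": draw("ethnicity", ETHNICITY_LEVELS),
        "area_of_birth": draw("area_of_birth", BIRTH_AREA_LEVELS),
        "age": _sample_age(rng.uniform(size=n), prof["age_quantiles"]),
    })
    return roster


def simulate_trajectory(true_params: ModelParameters, z, initial_state: int,
                        horizon: float, rng, t0: float = 0.0,
                        individual_id=None) -> EventHistory:
    """Exact Gillespie realization of the residency chain up to ``horizon``.

    Holding times are exponential with rate ``-q_ii(z)``; the destination is
    drawn with probability ``q_ij / -q_ii``.  The trajectory stops at
    absorption (Death) or at the horizon, whichever comes first.
    """
    q = intensity_matrix(true_params, z).q
    jumps = [(float(t0), int(initial_state))]
    t, s = float(t0), int(initial_state)
    while s != DEATH:
        rates = q[s - 1].copy()
        rates[s - 1] = 0.0
        total = rates.sum()
        if total <= 0.0:
            break
        t = t + rng.exponential(1.0 / total)
        if t > horizon:
            break
        s = int(rng.choice(np.arange(1, 8), p=rates / total))
        jumps.append((t, s))
    return EventHistory(individual_id=individual_id, jumps=tuple(jumps))


def discretize_to_panel(history: EventHistory, panel_interval: float,
                        horizon: float, death_exact: bool = True,
                        record_events: bool = False,
                        round_times=None) -> list:
    """Observation records (time, state) from an exact trajectory.

    The state is sampled at rounds ``0, D, 2D, ... <= horizon`` (only rounds
    at or after the trajectory's onset apply).  A death between rounds is
    recorded at its exact day when ``death_exact``, at the following round
    otherwise; no records are emitted after death.  With ``record_events``,
    every state change is additionally recorded at its exact time, as
    surveillance systems date each classified event; the onset itself (the
    baseline census, or a birth first registered at the following round) is
    not an event record.  Individuals alive at the horizon are
    right-censored at their last record.
    """
    if round_times is None:
        round_times = np.arange(0.0, horizon + 1e-9, panel_interval)
    times = {float(t) for t in round_times if t >= history.onset}
    if record_events:
        times |= {float(t) for t, s in history.jumps[1:] if s != DEATH}
    times = sorted(times)
    dth = history.death_time
    obs = []
    for t in times:
        if dth is not None and t >= dth:
            break
        obs.append((float(t), history.state_at(t)))
    if dth is not None:
        if death_exact:
            obs.append((float(dth), DEATH))
        else:
            nxt = [t for t in round_times if t >= dth]
            if nxt:
                obs.append((float(nxt[0]), DEATH))
    return obs


def generate_dataset(config: SimulationConfig):
    """End-to-end synthetic dataset: per-gender panel data plus the truth.

    Returns ``(datasets, truth, histories)`` where ``datasets`` maps gender
    to a :class:`PanelDataset`, ``truth`` is ``config.true_params`` and
    ``histories`` the exact trajectories (for rate-table denominators and
    oracle checks).  Fully determined by ``(config, config.seed)``: one
    pseudo-random stream per individual keyed by ``(seed, index)``.
    """
    roster = simulate_covariates(config)
    rng_entry = np.random.default_rng([config.seed, 999_979])
    n = config.n_individuals
    is_birth = rng_entry.uniform(size=n) < config.birth_fraction
    onset = np.where(is_birth, rng_entry.uniform(0.0, config.horizon, size=n), 0.0)

    base_rounds = np.arange(0.0, config.horizon + 1e-9, config.panel_interval)

    rows = []
    histories = []
    for i in range(n):
        rec = roster.iloc[i]
        if is_birth[i]:
            # a newborn is first registered at the next survey round; its
            # fixed age covariate is the age at that first observation
            nxt = base_rounds[base_rounds >= onset[i]]
            if len(nxt) == 0:
                continue  # born after the last round: never observed
            age_i = float(nxt[0] - onset[i]) / 365.25
        else:
            age_i = float(rec["age"])
        z = CovariateVector(
            slum_area=rec["slum_area"], ethnicity=rec["ethnicity"],
            area_of_birth=rec["area_of_birth"], age=age_i,
        )
        rng = np.random.default_rng([config.seed, i])
        history = simulate_trajectory(
            config.true_params[rec["gender"]], z,
            initial_state=2 if is_birth[i] else 1,
            horizon=config.horizon, rng=rng, t0=float(onset[i]),
            individual_id=rec["individual_id"],
        )
        histories.append(history)
        round_times = base_rounds
        if config.panel_jitter > 0:
            jit = rng.uniform(-config.panel_jitter, config.panel_jitter,
                              size=len(base_rounds))
            round_times = np.clip(np.sort(base_rounds + jit), 0.0, config.horizon)
        obs = discretize_to_panel(
            history, config.panel_interval, config.horizon,
            death_exact=config.death_exact,
            record_events=config.record_events,
            round_times=round_times,
        )
        for t, s in obs:
            rows.append((rec["individual_id"], t, s, rec["gender"],
                         rec["slum_area"], rec["ethnicity"],
                         rec["area_of_birth"], z.age))
    df = pd.DataFrame(rows, columns=[
        "individual_id", "time_days", "state", "gender", "slum_area",
        "ethnicity", "area_of_birth", "age",
    ])
    datasets = split_by_gender(df)
    return datasets, config.true_params, histories
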