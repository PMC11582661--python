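"""Seven-state residency process: state space, transition structure, generator.

The surveillance residency process distinguishes seven demographic states:
Enumeration (the 2002 baseline census), Birth, Exit and Entry (internal
household moves within the surveillance area), Out-migration, In-migration,
and Death.  Death is the single absorbing state.  Movement between states is
modelled as a time-homogeneous continuous-time Markov chain whose generator
``Q`` has a fixed sparsity pattern of 14 permitted transitions; covariates act
multiplicatively on each permitted intensity (a proportional-intensity model):

    q_ij(z) = exp(alpha_ij + z' beta_ij)

with ``alpha_ij`` the baseline log intensity (per day) and ``beta_ij`` a
transition-specific coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

N_STATES = 7
DEATH = 7

STATE_LABELS = {
    1: "Enumeration",
    2: "Birth",
    3: "Exit",
    4: "Entry",
    5: "Out-migration",
    6: "In-migration",
    7: "Death",
}

#: The 14 permitted ordered transitions of the residency process.
DEFAULT_TRANSITIONS: tuple[tuple[int, int], ...] = (
    (1, 3), (1, 5), (1, 7),
    (2, 3), (2, 5), (2, 7),
    (3, 4),
    (4, 3), (4, 5), (4, 7),
    (5, 6),
    (6, 3), (6, 5), (6, 7),
)


@dataclass(frozen=True)
class StateSpace:
    """The ordered 1-based state codes with labels and the absorbing set."""

    labels: dict = field(default_factory=lambda: dict(STATE_LABELS))
    absorbing: frozenset = frozenset({DEATH})

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.labels))


@dataclass(frozen=True)
class TransitionStructure:
    """An ordered set of permitted (from, to) transitions on 1-based codes.

    The order of ``allowed`` fixes the parameter order everywhere downstream.
    """

    allowed: tuple[tuple[int, int], ...] = DEFAULT_TRANSITIONS

    def __post_init__(self):
        seen = set()
        for i, j in self.allowed:
            if i == j:
                raise ValueError(f"self-transition ({i},{j}) not permitted")
            if not (1 <= i <= N_STATES and 1 <= j <= N_STATES):
                raise ValueError(f"state code out of range in ({i},{j})")
            if i == DEATH:
                raise ValueError("Death is absorbing; no transition may leave state 7")
            if (i, j) in seen:
                raise ValueError(f"duplicate transition ({i},{j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.allowed)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in set(self.allowed)

    def index(self, pair) -> int:
        return self.allowed.index(tuple(pair))

    def successors(self, state: int) -> tuple[int, ...]:
        return tuple(j for i, j in self.allowed if i == state)

    def reachable_from(self, state: int) -> frozenset:
        """Transitive closure: states reachable from ``state`` in >= 1 step."""
        frontier = {state}
        reached: set[int] = set()
        while frontier:
            nxt = {j for i in frontier for j in self.successors(i)} - reached
            reached |= nxt
            frontier = nxt
        return frozenset(reached)

    def to_edge_list(self) -> str:
        """Serialize as plain-text ``from,to`` lines with 1-based codes."""
        return "\n".join(f"{i},{j}" for i, j in self.allowed) + "\n"

    @classmethod
    def from_edge_list(cls, text: str) -> "TransitionStructure":
        pairs = []
        for line in text.strip().splitlines():
            i, j = line.split(",")
            pairs.append((int(i), int(j)))
        return cls(tuple(pairs))


def default_transition_structure() -> TransitionStructure:
    """The 14-transition topology of the residency state diagram."""
    return TransitionStructure(DEFAULT_TRANSITIONS)


@dataclass
class ModelParameters:
    """Baseline log intensities and covariate coefficients per transition.

    Parameters
    ----------
    structure : TransitionStructure
    baseline_log_intensity : dict
        ``(from, to) -> log rate per day``; keys must equal the allowed set.
    coefficients : dict
        ``((from, to), term) -> float``; missing keys mean zero effect.
    """

    structure: TransitionStructure
    baseline_log_intensity: dict
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self):
        allowed = set(self.structure.allowed)
        keys = {tuple(k) for k in self.baseline_log_intensity}
        if keys != allowed:
            raise ValueError(
                "baseline_log_intensity keys must equal the allowed transition set; "
                f"missing {allowed - keys}, extra {keys - allowed}"
            )
        for (pair, _term), v in list(self.coefficients.items()):
            if tuple(pair) not in allowed:
                raise ValueError(f"coefficient on disallowed transition {pair}")
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {pair}")
        for pair, v in self.baseline_log_intensity.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite baseline log intensity for {pair}")

    # -- array views used by the likelihood engine ------------------------
    def alpha(self) -> np.ndarray:
        return np.array(
            [self.baseline_log_intensity[p] for p in self.structure.allowed], float
        )

    def beta(self, terms) -> np.ndarray:
        """Coefficient matrix of shape ``(len(terms), n_transitions)``."""
        B = np.zeros((len(terms), len(self.structure)))
        for c, term in enumerate(terms):
            for k, pair in enumerate(self.structure.allowed):
                B[c, k] = self.coefficients.get((pair, term), 0.0)
        return B

    @classmethod
    def from_arrays(cls, structure, alpha, beta=None, terms=()) -> "ModelParameters":
        base = dict(zip(structure.allowed, np.asarray(alpha, float)))
        coefs = {}
        if beta is not None:
            beta = np.asarray(beta, float)
            for c, term in enumerate(terms):
                for k, pair in enumerate(structure.allowed):
                    if beta[c, k] != 0.0:
                        coefs[(pair, term)] = beta[c, k]
        return cls(structure, base, coefs)


def linear_predictor(params: ModelParameters, z, pair) -> float:
    """``z' beta_ij`` for one transition, dummy coding against reference levels.

    ``z`` is a :class:`~panelmsm.covariates.CovariateVector` (or anything with
    an ``encode()`` returning ``(values, terms)``).  Age enters untransformed
    in years.
    """
    pair = tuple(pair)
    if pair not in params.structure:
        raise ValueError(f"transition {pair} is not in the allowed structure")
    values, terms = z.encode()
    return float(
        sum(v * params.coefficients.get((pair, t), 0.0) for v, t in zip(values, terms))
    )


@dataclass(frozen=True)
class IntensityMatrix:
    """A 7x7 generator matrix (per-day rates) for one covariate context."""

    q: np.ndarray
    covariate_context: object = None

    def __post_init__(self):
        q = np.asarray(self.q, float)
        if q.shape != (N_STATES, N_STATES):
            raise ValueError("intensity matrix must be 7x7")
        object.__setattr__(self, "q", q)


def intensity_matrix(params: ModelParameters, z=None) -> IntensityMatrix:
    """Build ``Q(z)`` with ``q_ij = exp(alpha_ij + z' beta_ij)`` on allowed pairs.

    Disallowed off-diagonal entries are structural zeros; the diagonal closes
    each row to zero; the Death row is identically zero.
    """
    q = np.zeros((N_STATES, N_STATES))
    for pair in params.structure.allowed:
        eta = params.baseline_log_intensity[pair]
        if z is not None:
            eta += linear_predictor(params, z, pair)
        if not np.isfinite(eta):
            raise ValueError(f"non-finite log intensity for transition {pair}")
        q[pair[0] - 1, pair[1] - 1] = np.exp(eta)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return IntensityMatrix(q=q, covariate_context=z)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """``P(t) = expm(t Q)``: row-stochastic transition probabilities."""

    p: np.ndarray
    elapsed: float


def transition_probability_matrix(q: IntensityMatrix, elapsed: float) -> ProbabilityMatrix:
    """Matrix exponential solution of the forward equations over ``elapsed`` days.

    Uses scaling-and-squaring with Pade approximation (scipy's ``expm``),
    which is robust on near-defective generators.
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    p = expm(q.q * float(elapsed))
    # expm of a generator is stochastic up to roundoff; clean tiny negatives
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(p=p, elapsed=float(elapsed))


def matrix_to_csv(m: np.ndarray) -> str:
    """Render a 7x7 matrix as CSV with a header row of state labels."""
    header = "state," + ",".join(STATE_LABELS[c] for c in range(1, N_STATES + 1))
    lines = [header]
    for i in range(N_STATES):
        row = ",".join(repr(float(v)) for v in m[i])
        lines.append(f"{STATE_LABELS[i + 1]},{row}")
    return "\n".join(lines) + "\n"
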