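"""Per-strain life-cycle machinery: transition and fertility matrices.

The life cycle of *Pristionchus pacificus* is modelled as a discrete-time
absorbing Markov chain over ten stages — egg (E), juvenile (J), dauer larva
(D), young adult (YA), five reproducing-adult day classes (RA1..RA5) and old
adult (OA). One time step corresponds to roughly one hour, so a transition
probability of ~0.0415 yields an expected occupancy of ~24 steps (one day)
in a stage.

Transition probabilities depend on the resource state ``epsilon`` (growth on
*E. coli* OP50, growth on *Novosphingobium* sp. L76, or starvation), and all
stages except the stress-resistant dauer larva suffer density-dependent
mortality ``sigma(N_c) = exp(-psi * N_c)`` where ``N_c`` counts feeding
individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "STAGES",
    "STAGE_INDEX",
    "N_STAGES",
    "CONSUMER_STAGES",
    "PREY_STAGES",
    "PREDATOR_STAGES",
    "ResourceState",
    "StageTransitions",
    "MouthFormProbs",
    "StrainParams",
    "survival_probability",
    "build_transition_matrix",
    "build_fertility_matrix",
    "block_projection_matrix",
    "occupancy_times",
    "dominant_growth_rate",
]

# ---------------------------------------------------------------------------
# Stage set
# ---------------------------------------------------------------------------

#: Ordered stage labels. Public I/O is always in terms of these labels; the
#: 0-based array index of a stage is its position here.
STAGES: tuple[str, ...] = (
    "E", "J", "D", "YA", "RA1", "RA2", "RA3", "RA4", "RA5", "OA",
)
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
N_STAGES = len(STAGES)

E, J, D, YA, RA1, RA2, RA3, RA4, RA5, OA = range(N_STAGES)

#: Feeding stages — everything except eggs and the non-feeding dauer.
CONSUMER_STAGES: tuple[int, ...] = (J, YA, RA1, RA2, RA3, RA4, RA5, OA)
#: Stages vulnerable to intraguild predation.
PREY_STAGES: tuple[int, ...] = (J, D)
#: Stages that can carry the predatory mouth form (young and breeding
#: adults; old adults are excluded).
PREDATOR_STAGES: tuple[int, ...] = (YA, RA1, RA2, RA3, RA4, RA5)

#: RA day-advance transitions, in day order (RA1->RA2 ... RA5->OA). The
#: fertility entry for day j uses the j-th of these.
_RA_ADVANCES = ("g65", "g76", "g87", "g98", "g109")


class ResourceState(str, Enum):
    """Resource state ``epsilon`` experienced by a subpopulation.

    ``STARVED`` is never a deme's diet label; it is entered only through the
    starvation rule (available resource below the per-step demand).
    """

    OP50 = "OP50"
    L76 = "L76"
    STARVED = "STARVED"


#: The two assignable diets.
DIETS: tuple[ResourceState, ResourceState] = (ResourceState.OP50, ResourceState.L76)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass(frozen=True)
class StageTransitions:
    """The ten defined transition probabilities for one resource state.

    Attribute names follow the to/from index convention of the transition
    matrix: ``g21`` is E->J, ``g32`` J->D, ``g42`` J->YA, ``g43`` D->YA,
    ``g54`` YA->RA1, ``g65``..``g98`` the reproducing-adult day advances and
    ``g109`` RA5->OA.
    """

    g21: float
    g32: float
    g42: float
    g43: float
    g54: float
    g65: float
    g76: float
    g87: float
    g98: float
    g109: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_prob(name, getattr(self, name))
        if self.g32 + self.g42 > 1.0 + 1e-12:
            raise ValueError(
                "juvenile exits g32 (J->D) and g42 (J->YA) must sum to <= 1, "
                f"got {self.g32} + {self.g42}"
            )


@dataclass(frozen=True)
class MouthFormProbs:
    """Probability ``lambda(epsilon)`` of the predatory (eurystomatous) form.

    ``starved`` is optional: when ``None``, a starved deme keeps the lambda
    of its diet label (mouth forms do not change when food runs out).
    """

    op50: float
    l76: float
    starved: float | None = None

    def __post_init__(self) -> None:
        _check_prob("lambda(OP50)", self.op50)
        _check_prob("lambda(L76)", self.l76)
        if self.starved is not None:
            _check_prob("lambda(STARVED)", self.starved)

    def for_state(self, state: ResourceState, diet: ResourceState) -> float:
        """Lambda at resource state ``state`` for a deme whose diet label is
        ``diet`` (used as the fallback under starvation)."""
        if state is ResourceState.OP50:
            return self.op50
        if state is ResourceState.L76:
            return self.l76
        if self.starved is not None:
            return self.starved
        return self.op50 if diet is ResourceState.OP50 else self.l76


def _zero_fecundity() -> np.ndarray:
    return np.zeros(5)


@dataclass(frozen=True)
class StrainParams:
    """Full parameter set for one strain.

    ``transitions`` maps every resource state to its
    :class:`StageTransitions`; ``fecundity`` maps a resource state to the
    five mean daily egg counts ``z_bar[j]`` of the RA day classes (eggs/day,
    nonnegative). Fecundity under starvation defaults to zero (no egg laying
    while starved) but is configurable.
    """

    name: str
    transitions: Mapping[ResourceState, StageTransitions]
    fecundity: Mapping[ResourceState, np.ndarray]
    mouthform: MouthFormProbs

    def __post_init__(self) -> None:
        trans = dict(self.transitions)
        fec = {k: np.asarray(v, dtype=float) for k, v in self.fecundity.items()}
        for state in ResourceState:
            if state not in trans:
                raise ValueError(f"strain {self.name}: missing transitions for {state.value}")
        fec.setdefault(ResourceState.STARVED, _zero_fecundity())
        for state in (ResourceState.OP50, ResourceState.L76):
            if state not in fec:
                raise ValueError(f"strain {self.name}: missing fecundity for {state.value}")
        for state, z in fec.items():
            if z.shape != (5,):
                raise ValueError(
                    f"strain {self.name}: fecundity for {state.value} must have "
                    f"5 day-class entries, got shape {z.shape}"
                )
            if np.any(z < 0):
                raise ValueError(f"strain {self.name}: negative fecundity for {state.value}")
        object.__setattr__(self, "transitions", trans)
        object.__setattr__(self, "fecundity", fec)

    def gammas(self, state: ResourceState) -> StageTransitions:
        return self.transitions[state]

    def zbar(self, state: ResourceState) -> np.ndarray:
        return self.fecundity[state]


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def survival_probability(n_consumers: float, psi: float) -> float:
    """Density-dependent per-step survival ``sigma(N_c) = exp(-psi * N_c)``.

    Strictly decreasing in the consumer count, equal to 1 at ``N_c = 0`` or
    ``psi = 0``.
    """
    if n_consumers < 0:
        raise ValueError(f"consumer count must be >= 0, got {n_consumers}")
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    return math.exp(-psi * n_consumers)


def _base_transition_matrix(g: StageTransitions) -> np.ndarray:
    """Transition matrix without density-dependent survival (all sigma = 1)."""
    U = np.zeros((N_STAGES, N_STAGES))
    U[E, E] = 1.0 - g.g21
    U[J, E] = g.g21
    U[J, J] = 1.0 - g.g32 - g.g42
    U[D, J] = g.g32
    U[YA, J] = g.g42
    U[D, D] = 1.0 - g.g43
    U[YA, D] = g.g43
    U[YA, YA] = 1.0 - g.g54
    U[RA1, YA] = g.g54
    for day, name in enumerate(_RA_ADVANCES):
        col = RA1 + day
        gamma = getattr(g, name)
        U[col, col] = 1.0 - gamma
        U[col + 1, col] = gamma
    U[OA, OA] = 1.0
    return U


def survival_column_scale(n_consumers: float, psi: float) -> np.ndarray:
    """Per-source-stage survival factors: ``sigma(N_c)`` everywhere except
    the dauer column, where ``sigma_3 = 1`` (dauers are density-immune)."""
    sigma = survival_probability(n_consumers, psi)
    scale = np.full(N_STAGES, sigma)
    scale[D] = 1.0
    return scale


def build_transition_matrix(
    params: StrainParams,
    state: ResourceState,
    n_consumers: float = 0.0,
    psi: float = 0.0,
) -> np.ndarray:
    """Build the 10x10 transition matrix ``U(epsilon)`` for one strain.

    Each source stage's stay/exit terms (its column) carry the survival
    factor ``sigma(N_c)``, except the dauer column which is unscaled. Column
    sums are therefore at most 1 (sub-stochastic).
    """
    U = _base_transition_matrix(params.gammas(state))
    return U * survival_column_scale(n_consumers, psi)[np.newaxis, :]


def build_fertility_matrix(params: StrainParams, state: ResourceState) -> np.ndarray:
    """Build the 10x10 fertility matrix ``F(epsilon)``.

    The only nonzero entries sit in the egg row at the reproducing-adult
    columns: ``phi_j = z_bar[j] * gamma_{j -> j+1}`` couples a day class's
    mean daily egg output with its day-advance probability.
    """
    g = params.gammas(state)
    z = params.zbar(state)
    F = np.zeros((N_STAGES, N_STAGES))
    for day, name in enumerate(_RA_ADVANCES):
        F[E, RA1 + day] = z[day] * getattr(g, name)
    return F


def block_projection_matrix(
    U_p: np.ndarray, F_p: np.ndarray, U_np: np.ndarray, F_np: np.ndarray
) -> np.ndarray:
    """Two-strain block-diagonal projection matrix ``A(epsilon)``.

    The strains never interact through projection — only through predation
    and the shared resource — so the off-diagonal blocks are zero.
    """
    for M in (U_p, F_p, U_np, F_np):
        if np.shape(M) != (N_STAGES, N_STAGES):
            raise ValueError(f"expected {N_STAGES}x{N_STAGES} blocks, got {np.shape(M)}")
    A = np.zeros((2 * N_STAGES, 2 * N_STAGES))
    A[:N_STAGES, :N_STAGES] = U_p + F_p
    A[N_STAGES:, N_STAGES:] = U_np + F_np
    return A


def occupancy_times(U: np.ndarray, start: int = E) -> np.ndarray:
    """Expected steps spent in each stage by a cohort starting in ``start``.

    Uses the fundamental matrix ``N = (I - U)^-1`` of the absorbing chain;
    the returned vector is the column of ``N`` for the starting stage (the
    matrix is column-oriented: ``n_{t+1} = U n_t``). Requires some leakage
    (spectral radius of ``U`` below 1).
    """
    U = np.asarray(U, dtype=float)
    k = U.shape[0]
    if U.shape != (k, k):
        raise ValueError("U must be square")
    eye = np.eye(k)
    try:
        occ = np.linalg.solve(eye - U, np.eye(k)[:, start])
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "I - U is singular: the chain has no leakage (spectral radius 1)"
        ) from exc
    if not np.all(np.isfinite(occ)) or np.any(occ < -1e-9):
        raise ValueError("occupancy times are not finite/nonnegative; chain not absorbing")
    return occ


def dominant_growth_rate(A: np.ndarray) -> float:
    """Modulus of the dominant eigenvalue of a nonnegative projection matrix.

    For a primitive matrix this is the long-run per-step growth ratio of the
    total population under repeated projection.
    """
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))
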