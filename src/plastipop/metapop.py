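"""Lattice metapopulation: layouts, seeding, dauer dispersal and the
three-step update.

The metapopulation is an ``m x m`` grid of demes, ``S[1,1]`` top-left. Each
step applies, in order: (1) per-deme projection with resource consumption,
(2) intraguild predation within each deme, (3) dispersal of a fraction ``r``
of each deme's dauer larvae to every valid von Neumann neighbour (edges are
absorbing — no wraparound). An optional replenishment schedule resets every
deme's resource to ``R0`` at fixed intervals, optionally redrawing diets at
random, emulating boom-bust cycles.

The lattice update is vectorised over demes (grouped by effective resource
state) but computes exactly the arithmetic of the scalar per-deme reference
operations in :mod:`plastipop.deme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .deme import (
    NONPLASTIC,
    PLASTIC,
    Deme,
    GlobalParams,
    consumer_count,
    holling_kills,
)
from .lifecycle import (
    CONSUMER_STAGES,
    D,
    DIETS,
    N_STAGES,
    PREDATOR_STAGES,
    PREY_STAGES,
    STAGE_INDEX,
    ResourceState,
    StrainParams,
    build_fertility_matrix,
    build_transition_matrix,
)

__all__ = [
    "Lattice",
    "LayoutSpec",
    "SeedEntry",
    "SeedingSpec",
    "ReplenishmentSchedule",
    "SummaryStats",
    "initialize_lattice",
    "von_neumann_neighbors",
    "disperse_dauers",
    "step_metapopulation",
    "replenish",
    "summarize",
]

_STATE_ORDER = (ResourceState.OP50, ResourceState.L76, ResourceState.STARVED)
_DIET_CODE = {ResourceState.OP50: 0, ResourceState.L76: 1}
_CODE_DIET = {v: k for k, v in _DIET_CODE.items()}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayoutSpec:
    """Initial resource layout.

    ``homogeneous`` assigns ``diet`` everywhere. ``quadrants`` splits the
    lattice into four ceil(m/2) blocks; pattern "A" gives the main-diagonal
    quadrants (those holding the default plastic seed corners) OP50 and the
    anti-diagonal quadrants L76, pattern "B" the complement. ``random``
    draws each deme's diet independently and uniformly from a generator.
    """

    kind: Literal["homogeneous", "quadrants", "random"] = "homogeneous"
    diet: ResourceState = ResourceState.OP50
    pattern: Literal["A", "B"] = "A"
    r0: float = 500.0

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError("R0 must be >= 0")
        if self.kind == "homogeneous" and self.diet not in DIETS:
            raise ValueError("homogeneous layout diet must be OP50 or L76")

    def diet_map(self, m: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Integer diet codes (0 = OP50, 1 = L76), shape (m, m)."""
        if self.kind == "homogeneous":
            return np.full((m, m), _DIET_CODE[self.diet], dtype=np.int8)
        if self.kind == "quadrants":
            half = (m + 1) // 2
            rows = np.arange(m)[:, None] >= half
            cols = np.arange(m)[None, :] >= half
            anti_diagonal = rows ^ cols
            codes = anti_diagonal.astype(np.int8)  # pattern A: diag OP50, anti L76
            if self.pattern == "B":
                codes = 1 - codes
            return codes
        if rng is None:
            raise ValueError("random layout requires an RNG")
        return rng.integers(0, 2, size=(m, m), dtype=np.int8)


@dataclass(frozen=True)
class SeedEntry:
    x: int  # row, 1-based
    y: int  # column, 1-based
    strain: int  # PLASTIC or NONPLASTIC
    stage: str
    count: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("seed counts must be >= 0")
        if self.stage not in STAGE_INDEX:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.strain not in (PLASTIC, NONPLASTIC):
            raise ValueError("strain must be 0 (plastic) or 1 (non-plastic)")


@dataclass(frozen=True)
class SeedingSpec:
    """Initial placement of individuals on the lattice.

    The default competition seeding puts 50 dauers of the plastic strain at
    the main-diagonal corners S[1,1] and S[m,m] and 50 dauers of the
    non-plastic strain at S[1,m] and S[m,1]. ``randomize_locations`` redraws
    the four corner locations uniformly without replacement.
    """

    entries: tuple[SeedEntry, ...] | None = None
    randomize_locations: bool = False
    dauers_per_site: float = 50.0

    @staticmethod
    def default_corners(m: int, dauers: float = 50.0) -> tuple[SeedEntry, ...]:
        return (
            SeedEntry(1, 1, PLASTIC, "D", dauers),
            SeedEntry(m, m, PLASTIC, "D", dauers),
            SeedEntry(1, m, NONPLASTIC, "D", dauers),
            SeedEntry(m, 1, NONPLASTIC, "D", dauers),
        )

    def resolve(self, m: int, rng: np.random.Generator | None = None) -> tuple[SeedEntry, ...]:
        if self.entries is not None:
            return self.entries
        if self.randomize_locations:
            if rng is None:
                raise ValueError("randomized seeding requires an RNG")
            flat = rng.choice(m * m, size=4, replace=False)
            locs = [(int(f) // m + 1, int(f) % m + 1) for f in flat]
            strains = (PLASTIC, PLASTIC, NONPLASTIC, NONPLASTIC)
            return tuple(
                SeedEntry(x, y, s, "D", self.dauers_per_site)
                for (x, y), s in zip(locs, strains)
            )
        return self.default_corners(m, self.dauers_per_site)


@dataclass(frozen=True)
class ReplenishmentSchedule:
    """Boom-bust schedule: every ``interval`` steps reset each deme's
    resource to ``r0`` and, if ``reassign_diets``, redraw every deme's diet
    uniformly at random."""

    interval: int
    r0: float = 500.0
    reassign_diets: bool = True

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("replenishment interval must be >= 1")
        if self.r0 < 0:
            raise ValueError("R0 must be >= 0")


# ---------------------------------------------------------------------------
# Lattice container
# ---------------------------------------------------------------------------


@dataclass
class Lattice:
    """State of the metapopulation.

    ``counts`` has shape (m, m, 2, 10) — row, column, strain, stage;
    ``resource`` and ``diet_codes`` are (m, m). Rows/columns are 0-based
    internally; the public coordinate convention is 1-based with S[1,1]
    top-left.
    """

    m: int
    counts: np.ndarray
    resource: np.ndarray
    diet_codes: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        assert self.counts.shape == (self.m, self.m, 2, N_STAGES)
        assert self.resource.shape == (self.m, self.m)
        assert self.diet_codes.shape == (self.m, self.m)

    def deme(self, x: int, y: int) -> Deme:
        """The deme at 1-based coordinates (x, y) as a scalar object."""
        i, j = x - 1, y - 1
        return Deme(
            self.counts[i, j].copy(),
            float(self.resource[i, j]),
            _CODE_DIET[int(self.diet_codes[i, j])],
        )

    def set_deme(self, x: int, y: int, deme: Deme) -> None:
        i, j = x - 1, y - 1
        self.counts[i, j] = deme.counts
        self.resource[i, j] = deme.resource
        self.diet_codes[i, j] = _DIET_CODE[deme.diet]

    def copy(self) -> "Lattice":
        return Lattice(
            self.m, self.counts.copy(), self.resource.copy(), self.diet_codes.copy(), self.t
        )

    def strain_totals(self) -> np.ndarray:
        """Lattice-wide totals per strain and stage, shape (2, 10)."""
        return self.counts.sum(axis=(0, 1))


def initialize_lattice(
    m: int,
    layout: LayoutSpec,
    seeding: SeedingSpec,
    layout_rng: np.random.Generator | None = None,
    seeding_rng: np.random.Generator | None = None,
) -> Lattice:
    """Build an ``m x m`` lattice with ``R = R0`` everywhere, diets per the
    layout and the seeded stage counts placed."""
    diet_codes = layout.diet_map(m, layout_rng)
    counts = np.zeros((m, m, 2, N_STAGES))
    resource = np.full((m, m), float(layout.r0))
    for entry in seeding.resolve(m, seeding_rng):
        if not (1 <= entry.x <= m and 1 <= entry.y <= m):
            raise ValueError(f"seed location ({entry.x}, {entry.y}) is off a {m}x{m} lattice")
        counts[entry.x - 1, entry.y - 1, entry.strain, STAGE_INDEX[entry.stage]] += entry.count
    return Lattice(m, counts, resource, diet_codes)


def von_neumann_neighbors(x: int, y: int, m: int) -> list[tuple[int, int]]:
    """On-lattice orthogonal neighbours of 1-based (x, y); 2 at corners,
    3 on edges, 4 in the interior. No wraparound."""
    if not (1 <= x <= m and 1 <= y <= m):
        raise ValueError(f"({x}, {y}) is off a {m}x{m} lattice")
    cand = ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1))
    return [(a, b) for a, b in cand if 1 <= a <= m and 1 <= b <= m]


# ---------------------------------------------------------------------------
# Update steps
# ---------------------------------------------------------------------------


def _effective_state_codes(lattice: Lattice, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-deme consumer counts and effective-state codes (0 OP50, 1 L76,
    2 STARVED)."""
    n_c = lattice.counts[:, :, :, list(CONSUMER_STAGES)].sum(axis=(2, 3))
    starved = lattice.resource < beta * n_c
    codes = np.where(starved, 2, lattice.diet_codes).astype(np.int8)
    return n_c, codes


def _projection_blocks(
    strains: tuple[StrainParams, StrainParams], psi_on: bool = True
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per resource state: base 20x20 U block (no survival) and F block."""
    blocks: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for code, state in enumerate(_STATE_ORDER):
        U = np.zeros((2 * N_STAGES, 2 * N_STAGES))
        F = np.zeros((2 * N_STAGES, 2 * N_STAGES))
        for s, strain in enumerate(strains):
            sl = slice(s * N_STAGES, (s + 1) * N_STAGES)
            U[sl, sl] = build_transition_matrix(strain, state)  # sigma = 1 here
            F[sl, sl] = build_fertility_matrix(strain, state)
        blocks[code] = (U, F)
    return blocks


def _project_lattice(
    lattice: Lattice,
    strains: tuple[StrainParams, StrainParams],
    params: GlobalParams,
    resource_limitation: bool = True,
    blocks: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> None:
    """In-place per-deme projection + resource consumption (step 1)."""
    m = lattice.m
    n_c = lattice.counts[:, :, :, list(CONSUMER_STAGES)].sum(axis=(2, 3))
    if resource_limitation:
        starved = lattice.resource < params.beta * n_c
        codes = np.where(starved, 2, lattice.diet_codes)
    else:
        codes = lattice.diet_codes
    if blocks is None:
        blocks = _projection_blocks(strains)

    flat = lattice.counts.reshape(m * m, 2 * N_STAGES)
    codes_flat = np.asarray(codes).reshape(m * m)
    sigma = np.exp(-params.psi * n_c).reshape(m * m)
    # survival scales the source-stage columns, dauers exempt
    scale = np.repeat(sigma[:, None], 2 * N_STAGES, axis=1)
    scale[:, [D, N_STAGES + D]] = 1.0

    out = np.empty_like(flat)
    for code, (U, F) in blocks.items():
        mask = codes_flat == code
        if not mask.any():
            continue
        n = flat[mask]
        out[mask] = (U @ (scale[mask] * n).T + F @ n.T).T
    out[out < params.extinction_threshold] = 0.0
    lattice.counts = out.reshape(m, m, 2, N_STAGES)
    if resource_limitation:
        lattice.resource = np.maximum(lattice.resource - params.beta * n_c, 0.0)


def _predation_lattice(
    lattice: Lattice, strains: tuple[StrainParams, StrainParams], params: GlobalParams
) -> None:
    """In-place simultaneous intraguild predation in every deme (step 2)."""
    a, h = params.predation.attack_rate, params.predation.handling_time
    if a == 0.0:
        return
    n_c, codes = _effective_state_codes(lattice, params.beta)
    pre = lattice.counts.copy()
    # lambda per deme and strain: effective state, diet label as starved fallback
    lam = np.empty((lattice.m, lattice.m, 2))
    for s, strain in enumerate(strains):
        mf = strain.mouthform
        by_diet = np.where(lattice.diet_codes == 0, mf.op50, mf.l76)
        starved_lam = by_diet if mf.starved is None else mf.starved
        lam[:, :, s] = np.select(
            [codes == 0, codes == 1], [mf.op50, mf.l76], default=starved_lam
        )
    n_pred = lam * pre[:, :, :, list(PREDATOR_STAGES)].sum(axis=3)
    for prey, pred in ((PLASTIC, NONPLASTIC), (NONPLASTIC, PLASTIC)):
        for stage in PREY_STAGES:
            n_prey = pre[:, :, prey, stage]
            kills = a * n_prey / (1.0 + a * h * n_prey) * n_pred[:, :, pred]
            lattice.counts[:, :, prey, stage] -= np.minimum(kills, n_prey)
    lattice.counts[lattice.counts < params.extinction_threshold] = 0.0


def disperse_dauers(lattice: Lattice, r: float) -> Lattice:
    """Synchronous dauer dispersal: every deme exports a fraction ``r`` of
    its dauers to EACH valid neighbour (corners thus export ``2r`` in total,
    interior demes ``4r``) and receives the symmetric imports, all computed
    from the pre-dispersal state. Conserves the lattice-wide dauer total of
    each strain exactly.
    """
    if r < 0 or 4.0 * r > 1.0 + 1e-12:
        raise ValueError(f"dispersal r={r} must satisfy 0 <= 4r <= 1")
    out = lattice.copy()
    if r == 0.0 or lattice.m == 1:
        return out
    dauers = lattice.counts[:, :, :, D]
    m = lattice.m
    n_neighbors = np.full((m, m), 4.0)
    n_neighbors[0, :] -= 1
    n_neighbors[-1, :] -= 1
    n_neighbors[:, 0] -= 1
    n_neighbors[:, -1] -= 1
    inflow = np.zeros_like(dauers)
    inflow[1:, :] += r * dauers[:-1, :]
    inflow[:-1, :] += r * dauers[1:, :]
    inflow[:, 1:] += r * dauers[:, :-1]
    inflow[:, :-1] += r * dauers[:, 1:]
    outflow = r * n_neighbors[:, :, None] * dauers
    out.counts[:, :, :, D] = dauers - outflow + inflow
    return out


def replenish(
    lattice: Lattice, schedule: ReplenishmentSchedule | None, rng: np.random.Generator
) -> Lattice:
    """Apply the boom-bust schedule at the start of a step: when ``t`` is a
    positive multiple of the interval, reset every deme's resource to ``R0``
    and optionally redraw all diets uniformly. Otherwise a no-op."""
    if schedule is None or lattice.t == 0 or lattice.t % schedule.interval != 0:
        return lattice
    out = lattice.copy()
    out.resource[:] = schedule.r0
    if schedule.reassign_diets:
        out.diet_codes = rng.integers(0, 2, size=(lattice.m, lattice.m), dtype=np.int8)
    return out


def step_metapopulation(
    lattice: Lattice,
    strains: tuple[StrainParams, StrainParams],
    params: GlobalParams,
    resource_limitation: bool = True,
    blocks: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
) -> Lattice:
    """One full metapopulation step: projection + resource consumption in
    every deme, then predation, then dauer dispersal; increments ``t``."""
    out = lattice.copy()
    _project_lattice(out, strains, params, resource_limitation, blocks)
    _predation_lattice(out, strains, params)
    out = disperse_dauers(out, params.dispersal)
    out.counts[out.counts < params.extinction_threshold] = 0.0
    out.t = lattice.t + 1
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Lattice summary: per-stage mean counts per deme (2 x 10), the plastic
    dauer fraction per deme (NaN where a deme has no dauers) and
    lattice-wide, plus totals and the resource map."""

    mean_counts: np.ndarray
    fhat_dauer_p: np.ndarray
    fhat_dauer_p_total: float | None
    totals: np.ndarray
    resource: np.ndarray


def summarize(lattice: Lattice) -> SummaryStats:
    """Per-deme and lattice-wide summary statistics.

    ``fhat_dauer_p`` is the plastic strain's share of all dauer larvae; it
    is undefined (NaN per deme, ``None`` lattice-wide) where no dauers
    exist, never coerced to 0.
    """
    totals = lattice.strain_totals()
    mean_counts = totals / (lattice.m**2)
    dauers = lattice.counts[:, :, :, D]
    tot = dauers.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat = np.where(tot > 0, dauers[:, :, PLASTIC] / tot, np.nan)
    grand = float(tot.sum())
    fhat_total = float(dauers[:, :, PLASTIC].sum() / grand) if grand > 0 else None
    return SummaryStats(mean_counts, fhat, fhat_total, totals, lattice.resource.copy())
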