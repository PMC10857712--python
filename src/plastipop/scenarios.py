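"""Config-driven scenario runners: isolation growth, well-mixed
competition, lattice competitions with counterfactual fecundity
manipulations, and boom-bust replenishment runs.

Every experiment — including the "well-mixed" one, modelled as an m=1
lattice — goes through the same lattice engine, so a single code path is
exercised everywhere. Shipped scenario files (one YAML per figure-style
setup) live in the package's ``data/scenarios`` directory and are resolved
by name.

The counterfactual manipulations remove one of the two fitness costs:
``dwE2_zero`` grants the non-plastic strain its (higher) inducing-diet
fecundity on OP50, erasing its cost of phenotypic mismatch; ``dwE1_zero``
grants the plastic strain its (higher) OP50 fecundity on L76, erasing its
cost of plasticity. Only fecundity tables are touched; diet-dependent
developmental speed is left as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .deme import NONPLASTIC, PLASTIC, GlobalParams, PredationParams
from .iohub import ConfigDocument, default_fixture_params, load_config, substream
from .lifecycle import (
    CONSUMER_STAGES,
    D,
    N_STAGES,
    STAGES,
    ResourceState,
    StrainParams,
)
from .metapop import (
    Lattice,
    LayoutSpec,
    SeedEntry,
    SeedingSpec,
    SummaryStats,
    initialize_lattice,
    replenish,
    step_metapopulation,
    summarize,
)
from .metapop import _projection_blocks  # single code path for all runs

__all__ = [
    "CounterfactualTarget",
    "counterfactual_equalize",
    "ScenarioResult",
    "run_isolation_growth",
    "run_well_mixed_competition",
    "run_lattice_scenario",
    "builtin_scenarios",
    "load_scenario",
]

CounterfactualTarget = Literal["none", "dwE1_zero", "dwE2_zero"]

_STRAIN_LABEL = {PLASTIC: "P", NONPLASTIC: "NP"}


def counterfactual_equalize(
    strains: tuple[StrainParams, StrainParams], target: CounterfactualTarget
) -> tuple[StrainParams, StrainParams]:
    """Apply a fecundity-equalising counterfactual; idempotent.

    ``dwE2_zero`` sets the non-plastic strain's OP50 fecundity equal to its
    L76 fecundity; ``dwE1_zero`` sets the plastic strain's L76 fecundity
    equal to its OP50 fecundity. ``none`` is the identity.
    """
    if target == "none":
        return strains
    p, np_ = strains
    if target == "dwE2_zero":
        fec = dict(np_.fecundity)
        fec[ResourceState.OP50] = np.array(fec[ResourceState.L76], copy=True)
        return (p, replace(np_, fecundity=fec))
    if target == "dwE1_zero":
        fec = dict(p.fecundity)
        fec[ResourceState.L76] = np.array(fec[ResourceState.OP50], copy=True)
        return (replace(p, fecundity=fec), np_)
    raise ValueError(f"unknown counterfactual target {target!r}")


# ---------------------------------------------------------------------------
# Result container and engine loop
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Outputs of a scenario run.

    ``trajectory`` is a tidy frame of lattice-wide totals (t, strain, stage,
    count) at the recording cadence plus the lattice resource total;
    ``snapshots`` (optional) holds per-deme tidy rows; ``outcome`` is the
    dominance classification at the horizon (plastic_dominant /
    nonplastic_dominant / coexistence / no_dauers), using the >99% dauer
    share rule for dominance and >1% for each strain under coexistence.
    """

    trajectory: pd.DataFrame
    summary: SummaryStats
    final_lattice: Lattice
    outcome: str
    fhat_dauer_p: float | None
    snapshots: pd.DataFrame | None = None
    exclusion: dict[str, int | None] | None = None


def _classify_outcome(fhat: float | None) -> str:
    if fhat is None:
        return "no_dauers"
    if fhat > 0.99:
        return "plastic_dominant"
    if fhat < 0.01:
        return "nonplastic_dominant"
    return "coexistence"


def _totals_records(lattice: Lattice) -> list[dict]:
    totals = lattice.strain_totals()
    recs = [
        {
            "t": lattice.t,
            "strain": _STRAIN_LABEL[s],
            "stage": STAGES[k],
            "count": float(totals[s, k]),
        }
        for s in (PLASTIC, NONPLASTIC)
        for k in range(N_STAGES)
    ]
    recs.append(
        {"t": lattice.t, "strain": "lattice", "stage": "R", "count": float(lattice.resource.sum())}
    )
    return recs


def _snapshot_records(lattice: Lattice, beta: float) -> list[dict]:
    recs = []
    for i in range(lattice.m):
        for j in range(lattice.m):
            n_c = float(lattice.counts[i, j, :, list(CONSUMER_STAGES)].sum())
            starved = int(lattice.resource[i, j] < beta * n_c)
            diet = "OP50" if lattice.diet_codes[i, j] == 0 else "L76"
            for s in (PLASTIC, NONPLASTIC):
                for k in range(N_STAGES):
                    recs.append(
                        {
                            "t": lattice.t,
                            "x": i + 1,
                            "y": j + 1,
                            "strain": _STRAIN_LABEL[s],
                            "stage": STAGES[k],
                            "count": float(lattice.counts[i, j, s, k]),
                            "R": float(lattice.resource[i, j]),
                            "diet": diet,
                            "starved_flag": starved,
                        }
                    )
    return recs


def run_lattice_scenario(doc: ConfigDocument) -> ScenarioResult:
    """Execute a full scenario from a validated config document.

    Applies the counterfactual to the strain set, resolves toggles
    (predation off => attack rate 0; density mortality off => psi 0;
    resource limitation off => unlimited resource), initialises the lattice
    from the seeded substreams, then repeats the three-step metapopulation
    update (with start-of-step replenishment when scheduled) for the step
    budget, recording lattice totals at the configured cadence.
    """
    sc = doc.scenario
    strains = counterfactual_equalize(doc.strain_params(), sc.counterfactual)
    params = doc.global_params()
    if not sc.toggles.predation:
        params = replace(params, predation=PredationParams(0.0, params.predation.handling_time))
    if not sc.toggles.density_mortality:
        params = replace(params, psi=0.0)
    layout = sc.layout.to_spec(doc.globals.r0)
    lattice = initialize_lattice(
        sc.m,
        layout,
        sc.seeding.to_spec(),
        layout_rng=substream(doc.seed, "layout"),
        seeding_rng=substream(doc.seed, "seeding"),
    )
    schedule = None if sc.replenishment is None else sc.replenishment.to_spec(doc.globals.r0)
    rng_rep = substream(doc.seed, "replenishment")
    blocks = _projection_blocks(strains)

    records = _totals_records(lattice)
    snap_records = _snapshot_records(lattice, params.beta) if doc.output.snapshots else None
    exclusion: dict[str, int | None] = {"P": None, "NP": None}
    consumer_idx = list(CONSUMER_STAGES)

    for _ in range(sc.max_steps):
        lattice = replenish(lattice, schedule, rng_rep)
        lattice = step_metapopulation(
            lattice, strains, params, resource_limitation=sc.toggles.resource_limitation, blocks=blocks
        )
        totals = lattice.strain_totals()
        for s, label in _STRAIN_LABEL.items():
            if exclusion[label] is None and totals[s, consumer_idx].sum() == 0.0:
                exclusion[label] = lattice.t
        if lattice.t % sc.record_every == 0 or lattice.t == sc.max_steps:
            records.extend(_totals_records(lattice))
            if snap_records is not None:
                snap_records.extend(_snapshot_records(lattice, params.beta))
        if sc.stop_when_exhausted and lattice.resource.sum() == 0.0:
            if totals[:, consumer_idx].sum() == 0.0:
                break

    summary = summarize(lattice)
    fhat = summary.fhat_dauer_p_total
    return ScenarioResult(
        trajectory=pd.DataFrame.from_records(records),
        summary=summary,
        final_lattice=lattice,
        outcome=_classify_outcome(fhat),
        fhat_dauer_p=fhat,
        snapshots=None if snap_records is None else pd.DataFrame.from_records(snap_records),
        exclusion=exclusion,
    )


# ---------------------------------------------------------------------------
# Convenience runners
# ---------------------------------------------------------------------------


def run_isolation_growth(
    strain: StrainParams,
    diet: ResourceState,
    steps: int,
    n0: float = 50.0,
    params: GlobalParams | None = None,
) -> pd.DataFrame:
    """Single-strain growth in isolation: one deme, unlimited resource, no
    density mortality, no predation, started with ``n0`` juveniles.

    Returns a per-step frame with stage counts (columns named by stage) and
    stage proportions (``prop_<stage>``).
    """
    if params is None:
        params = default_fixture_params()[1]
    params = replace(params, psi=0.0, predation=PredationParams(0.0, 0.0))
    lattice = initialize_lattice(
        1,
        LayoutSpec(kind="homogeneous", diet=diet, r0=1.0),
        SeedingSpec(entries=(SeedEntry(1, 1, PLASTIC, "J", n0),)),
    )
    strains = (strain, strain)  # slot NP stays empty
    blocks = _projection_blocks(strains)
    rows = []
    for _ in range(steps + 1):
        counts = lattice.counts[0, 0, PLASTIC]
        total = counts.sum()
        row = {"t": lattice.t, "total": float(total)}
        row.update({STAGES[k]: float(counts[k]) for k in range(N_STAGES)})
        row.update(
            {
                f"prop_{STAGES[k]}": float(counts[k] / total) if total > 0 else np.nan
                for k in range(N_STAGES)
            }
        )
        rows.append(row)
        lattice = step_metapopulation(
            lattice, strains, params, resource_limitation=False, blocks=blocks
        )
    return pd.DataFrame(rows)


def run_well_mixed_competition(
    diet: ResourceState,
    predation_on: bool,
    steps: int,
    strains: tuple[StrainParams, StrainParams] | None = None,
    params: GlobalParams | None = None,
    r0: float = 500.0,
    dauers: float = 50.0,
) -> ScenarioResult:
    """Two-strain competition in a well-mixed (m=1) population with finite
    resource and density-dependent mortality, predation per the flag.

    Both strains start with ``dauers`` dauer larvae. ``exclusion`` in the
    result records, per strain, the first step at which all of its consumer
    stages fell below the extinction threshold (``None`` if never).
    """
    if strains is None:
        strains = default_fixture_params()[0]
    if params is None:
        params = default_fixture_params()[1]
    if not predation_on:
        params = replace(params, predation=PredationParams(0.0, params.predation.handling_time))
    lattice = initialize_lattice(
        1,
        LayoutSpec(kind="homogeneous", diet=diet, r0=r0),
        SeedingSpec(
            entries=(
                SeedEntry(1, 1, PLASTIC, "D", dauers),
                SeedEntry(1, 1, NONPLASTIC, "D", dauers),
            )
        ),
    )
    blocks = _projection_blocks(strains)
    consumer_idx = list(CONSUMER_STAGES)
    records = _totals_records(lattice)
    exclusion: dict[str, int | None] = {"P": None, "NP": None}
    for _ in range(steps):
        lattice = step_metapopulation(lattice, strains, params, blocks=blocks)
        totals = lattice.strain_totals()
        for s, label in _STRAIN_LABEL.items():
            if exclusion[label] is None and totals[s, consumer_idx].sum() == 0.0:
                exclusion[label] = lattice.t
        if lattice.t % 10 == 0 or lattice.t == steps:
            records.extend(_totals_records(lattice))
    summary = summarize(lattice)
    return ScenarioResult(
        trajectory=pd.DataFrame.from_records(records),
        summary=summary,
        final_lattice=lattice,
        outcome=_classify_outcome(summary.fhat_dauer_p_total),
        fhat_dauer_p=summary.fhat_dauer_p_total,
        exclusion=exclusion,
    )


# ---------------------------------------------------------------------------
# Shipped scenario files
# ---------------------------------------------------------------------------


def _scenario_dir():
    return resources.files("plastipop").joinpath("data/scenarios")


def builtin_scenarios() -> list[str]:
    """Names of the shipped scenario files."""
    return sorted(p.name[: -len(".yaml")] for p in _scenario_dir().iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path: str | Path) -> ConfigDocument:
    """Load a scenario config by shipped name (e.g. ``fig2c``) or file path."""
    path = Path(name_or_path)
    if path.exists():
        return load_config(path)
    candidate = _scenario_dir().joinpath(f"{name_or_path}.yaml")
    if candidate.is_file():
        with resources.as_file(candidate) as real:
            return load_config(real)
    raise FileNotFoundError(
        f"no scenario file at {name_or_path!r} and no builtin scenario of that "
        f"name; builtins: {builtin_scenarios()}"
    )
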