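"""Configuration schema, parameter fixtures, readers/writers and seed
management.

The config dialect is YAML validated by a pydantic schema: unknown keys are
rejected with location-bearing messages, every default is resolved at load
time, and a loaded document round-trips through :func:`dump_config`. One
master seed deterministically derives all named substreams (layout, seeding,
replenishment, inference) so any run is replayable bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .deme import GlobalParams, PredationParams
from .lifecycle import (
    DIETS,
    MouthFormProbs,
    ResourceState,
    StageTransitions,
    StrainParams,
)
from .metapop import LayoutSpec, ReplenishmentSchedule, SeedEntry, SeedingSpec

__all__ = [
    "ConfigDocument",
    "RunManifest",
    "load_config",
    "dump_config",
    "default_fixture_params",
    "substream",
    "write_trajectory",
    "read_mouthform_counts",
]

SCHEMA_VERSION = 1

#: Stable substream identities derived from the master seed. Adding a new
#: consumer must not perturb existing streams, hence explicit codes.
_SUBSTREAMS = {"layout": 11, "seeding": 23, "replenishment": 37, "inference": 53}


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from the master seed."""
    try:
        code = _SUBSTREAMS[name]
    except KeyError:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_SUBSTREAMS)}") from None
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(code,)))


# ---------------------------------------------------------------------------
# Fixture parameters
# ---------------------------------------------------------------------------

#: One day of the ~1 h time step: exit probability giving ~24-step occupancy.
GAMMA_DAY = 0.0415


def default_fixture_params() -> tuple[tuple[StrainParams, StrainParams], GlobalParams]:
    """Default strain and global parameters.

    Mouth-form induction probabilities are the reported estimates
    (plastic: 0.11 on OP50, 0.83 on L76; non-plastic: 1.0 on both diets).
    Transition magnitudes are time-calibrated so one step is about an hour
    (day-class advances ~0.0415), with the faster young-adult maturation on
    L76 expressed as a larger YA->RA1 probability on that diet. The
    FECUNDITY MEANS ARE SYNTHETIC PLACEHOLDERS: the underlying egg-count
    means are published only graphically, so these values are package
    fixtures that respect the established qualitative orderings — the
    plastic strain out-produces the non-plastic on OP50 (cost of phenotypic
    mismatch for the fixed strain) and vice versa on L76 (cost of
    plasticity). Replace them via the config when measured means are
    available; nothing in the model code hard-codes them.
    """
    diet_common = dict(
        g21=GAMMA_DAY,  # eggs hatch in ~a day
        g32=0.001,  # trickle dauer formation on food
        g43=GAMMA_DAY,  # dauers resume development on food
        g65=GAMMA_DAY,
        g76=GAMMA_DAY,
        g87=GAMMA_DAY,
        g98=GAMMA_DAY,
        g109=GAMMA_DAY,
    )
    starved = StageTransitions(
        g21=GAMMA_DAY,  # hatching continues
        g32=0.25,  # starvation drives juveniles into the dauer stage
        g42=0.0,  # no maturation without food
        g43=0.0,  # dauers wait for favourable conditions
        g54=0.0,
        g65=GAMMA_DAY,  # adults keep ageing
        g76=GAMMA_DAY,
        g87=GAMMA_DAY,
        g98=GAMMA_DAY,
        g109=GAMMA_DAY,
    )
    juvenile_days = 0.017  # ~2.5-day juvenile phase

    plastic = StrainParams(
        name="P",
        transitions={
            ResourceState.OP50: StageTransitions(g42=juvenile_days, g54=GAMMA_DAY, **diet_common),
            ResourceState.L76: StageTransitions(g42=juvenile_days, g54=0.078, **diet_common),
            ResourceState.STARVED: starved,
        },
        fecundity={
            ResourceState.OP50: np.array([40.0, 55.0, 40.0, 20.0, 8.0]),
            ResourceState.L76: np.array([28.0, 40.0, 28.0, 14.0, 6.0]),
        },
        mouthform=MouthFormProbs(op50=0.11, l76=0.83),
    )
    nonplastic = StrainParams(
        name="NP",
        transitions={
            ResourceState.OP50: StageTransitions(g42=juvenile_days, g54=GAMMA_DAY, **diet_common),
            ResourceState.L76: StageTransitions(g42=juvenile_days, g54=0.083, **diet_common),
            ResourceState.STARVED: starved,
        },
        fecundity={
            ResourceState.OP50: np.array([30.0, 42.0, 30.0, 15.0, 6.0]),
            ResourceState.L76: np.array([42.0, 58.0, 44.0, 22.0, 9.0]),
        },
        mouthform=MouthFormProbs(op50=1.0, l76=1.0),
    )
    glob = GlobalParams(
        beta=0.002,
        psi=6e-5,
        predation=PredationParams(attack_rate=0.2, handling_time=0.15),
        dispersal=0.01,
        extinction_threshold=1e-6,
    )
    return (plastic, nonplastic), glob


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


_GAMMA_FIELDS = ("g21", "g32", "g42", "g43", "g54", "g65", "g76", "g87", "g98", "g109")


class TransitionsModel(_Strict):
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


class StrainModel(_Strict):
    name: str
    transitions: dict[Literal["OP50", "L76", "STARVED"], TransitionsModel]
    fecundity: dict[Literal["OP50", "L76", "STARVED"], list[float]]
    mouthform: dict[Literal["OP50", "L76", "STARVED"], float]

    def to_params(self) -> StrainParams:
        return StrainParams(
            name=self.name,
            transitions={
                ResourceState(k): StageTransitions(**v.model_dump())
                for k, v in self.transitions.items()
            },
            fecundity={ResourceState(k): np.array(v) for k, v in self.fecundity.items()},
            mouthform=MouthFormProbs(
                op50=self.mouthform["OP50"],
                l76=self.mouthform["L76"],
                starved=self.mouthform.get("STARVED"),
            ),
        )

    @classmethod
    def from_params(cls, p: StrainParams) -> "StrainModel":
        mf = {"OP50": p.mouthform.op50, "L76": p.mouthform.l76}
        if p.mouthform.starved is not None:
            mf["STARVED"] = p.mouthform.starved
        return cls(
            name=p.name,
            transitions={
                s.value: TransitionsModel(**{f: getattr(g, f) for f in _GAMMA_FIELDS})
                for s, g in p.transitions.items()
            },
            fecundity={s.value: list(map(float, z)) for s, z in p.fecundity.items()},
            mouthform=mf,
        )


class GlobalsModel(_Strict):
    beta: float = 0.002
    psi: float = 6e-5
    attack_rate: float = 0.2
    handling_time: float = 0.15
    dispersal: float = 0.01
    r0: float = 500.0
    extinction_threshold: float = 1e-6

    def to_params(self) -> GlobalParams:
        return GlobalParams(
            beta=self.beta,
            psi=self.psi,
            predation=PredationParams(self.attack_rate, self.handling_time),
            dispersal=self.dispersal,
            extinction_threshold=self.extinction_threshold,
        )


class LayoutModel(_Strict):
    kind: Literal["homogeneous", "quadrants", "random"] = "homogeneous"
    diet: Literal["OP50", "L76"] = "OP50"
    pattern: Literal["A", "B"] = "A"

    def to_spec(self, r0: float) -> LayoutSpec:
        return LayoutSpec(kind=self.kind, diet=ResourceState(self.diet), pattern=self.pattern, r0=r0)


class SeedEntryModel(_Strict):
    x: int
    y: int
    strain: Literal["P", "NP"]
    stage: str = "D"
    count: float = 50.0


class SeedingModel(_Strict):
    kind: Literal["default", "random", "explicit"] = "default"
    dauers_per_site: float = 50.0
    entries: list[SeedEntryModel] = Field(default_factory=list)

    def to_spec(self) -> SeedingSpec:
        if self.kind == "explicit":
            return SeedingSpec(
                entries=tuple(
                    SeedEntry(e.x, e.y, 0 if e.strain == "P" else 1, e.stage, e.count)
                    for e in self.entries
                )
            )
        return SeedingSpec(
            randomize_locations=(self.kind == "random"),
            dauers_per_site=self.dauers_per_site,
        )


class ReplenishmentModel(_Strict):
    interval: int
    reassign_diets: bool = True

    def to_spec(self, r0: float) -> ReplenishmentSchedule:
        return ReplenishmentSchedule(interval=self.interval, r0=r0, reassign_diets=self.reassign_diets)


class TogglesModel(_Strict):
    predation: bool = True
    density_mortality: bool = True
    resource_limitation: bool = True


class ScenarioModel(_Strict):
    id: str = "custom"
    m: int = 20
    layout: LayoutModel = Field(default_factory=LayoutModel)
    seeding: SeedingModel = Field(default_factory=SeedingModel)
    replenishment: Optional[ReplenishmentModel] = None
    toggles: TogglesModel = Field(default_factory=TogglesModel)
    counterfactual: Literal["none", "dwE1_zero", "dwE2_zero"] = "none"
    max_steps: int = 10000
    record_every: int = 100
    stop_when_exhausted: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ScenarioModel":
        if self.m < 1:
            raise ValueError("scenario.m must be >= 1")
        if self.max_steps < 0 or self.record_every < 1:
            raise ValueError("scenario.max_steps must be >= 0 and record_every >= 1")
        return self


class OutputModel(_Strict):
    dir: Optional[str] = None
    snapshots: bool = False


class ConfigDocument(_Strict):
    """Validated, fully-resolved run configuration."""

    version: int = SCHEMA_VERSION
    seed: int = 0
    strains: Literal["default"] | dict[Literal["plastic", "nonplastic"], StrainModel] = "default"
    globals: GlobalsModel = Field(default_factory=GlobalsModel)
    scenario: ScenarioModel = Field(default_factory=ScenarioModel)
    output: OutputModel = Field(default_factory=OutputModel)

    @model_validator(mode="after")
    def _check(self) -> "ConfigDocument":
        if self.version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        self.globals.to_params()  # surfaces invariant violations (e.g. 4r > 1)
        if isinstance(self.strains, dict) and set(self.strains) != {"plastic", "nonplastic"}:
            raise ValueError("strains must define both 'plastic' and 'nonplastic'")
        return self

    def strain_params(self) -> tuple[StrainParams, StrainParams]:
        if self.strains == "default":
            return default_fixture_params()[0]
        return (self.strains["plastic"].to_params(), self.strains["nonplastic"].to_params())

    def global_params(self) -> GlobalParams:
        return self.globals.to_params()


def load_config(path: str | Path) -> ConfigDocument:
    """Load and validate a YAML config; fails loudly naming the offending
    key on schema violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return ConfigDocument.model_validate(raw)


def dump_config(doc: ConfigDocument, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc.model_dump(mode="json"), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = ["t", "x", "y", "strain", "stage", "count", "R", "diet", "starved_flag"]


@dataclass
class RunManifest:
    """Everything needed to replay a run bit-identically."""

    config: dict
    package_version: str
    seed: int
    substreams: dict[str, int]
    outputs: list[str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def write_trajectory(
    snapshots: pd.DataFrame,
    summary: pd.DataFrame,
    out_dir: str | Path,
    doc: ConfigDocument | None = None,
) -> list[Path]:
    """Write tidy per-deme snapshots and the lattice-total summary table as
    CSV (UTF-8, comma, header, '.' decimal), plus a replay manifest."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snap_path = out_dir / "snapshots.csv"
    summ_path = out_dir / "summary.csv"
    for col in TRAJECTORY_COLUMNS:
        if col not in snapshots.columns:
            raise ValueError(f"snapshot table missing column {col!r}")
    snapshots[TRAJECTORY_COLUMNS].to_csv(snap_path, index=False)
    summary.to_csv(summ_path, index=False)
    paths = [snap_path, summ_path]
    if doc is not None:
        manifest = RunManifest(
            config=doc.model_dump(mode="json"),
            package_version=__version__,
            seed=doc.seed,
            substreams=dict(_SUBSTREAMS),
            outputs=[p.name for p in paths],
        )
        man_path = out_dir / "manifest.json"
        manifest.write(man_path)
        paths.append(man_path)
    return paths


def read_mouthform_counts(path: str | Path) -> pd.DataFrame:
    """Read mouth-form count data (CSV with header strain, diet, replicate,
    predatory, scored) and validate the count invariants."""
    df = pd.read_csv(path)
    required = {"strain", "diet", "replicate", "predatory", "scored"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mouth-form CSV missing columns: {sorted(missing)}")
    if (df["scored"] < 1).any():
        raise ValueError("every replicate must score at least one worm")
    if ((df["predatory"] < 0) | (df["predatory"] > df["scored"])).any():
        raise ValueError("predatory counts must satisfy 0 <= predatory <= scored")
    return df
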