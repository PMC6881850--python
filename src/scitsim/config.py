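"""Declarative run configuration: defaults, YAML round-trip, validation.

A :class:`RunConfig` bundles every input of a model run in one human-editable
document: the population source (synthetic generator parameters or a CSV
path), prevalences, within-severity splits, cost tables, SCIT drug costs,
the discount specification, the transition-matrix source, the allocation
interpretation and the calibration settings.  Defaults are the base-case
point values of the analysis; the transition matrices default to the
synthetic placeholders and are tagged as such in the provenance block.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Mapping

import numpy as np
import yaml

from .economics import CostTable, DiscountSpec, ScitCostSchedule
from .markov import validate_matrix
from .population import PrevalenceTable, SeveritySplit
from .states import AgeGroup, AllergyType, Arm, DiseaseState

__all__ = [
    "PopulationSource",
    "TransitionSource",
    "CalibrationSpec",
    "RunConfig",
    "load_config",
    "save_config",
    "matrices_to_yaml",
    "matrices_from_yaml",
]


@dataclass(frozen=True)
class PopulationSource:
    """Where the population projection comes from."""

    kind: Literal["synthetic", "csv"] = "synthetic"
    base_pop_6_65: float = 62_000_000.0
    annual_trend: float = -0.003
    age_profile: str = "youth-declining"
    seed: int = 0
    path: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "csv" and not self.path:
            raise ValueError("population source kind 'csv' requires a path")


@dataclass(frozen=True)
class TransitionSource:
    """Where the transition matrices come from."""

    kind: Literal["synthetic", "file"] = "synthetic"
    effect_size: float = 0.75
    jitter: float = 0.0
    seed: int = 0
    path: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "file" and not self.path:
            raise ValueError("transition source kind 'file' requires a path")


@dataclass(frozen=True)
class CalibrationSpec:
    rel_tol: float = 0.005
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("calibration rel_tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("calibration max_iter must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    population: PopulationSource = field(default_factory=PopulationSource)
    prevalence: PrevalenceTable = field(default_factory=PrevalenceTable)
    split: SeveritySplit = field(default_factory=SeveritySplit)
    costs: CostTable = field(default_factory=CostTable)
    scit_costs: ScitCostSchedule = field(default_factory=ScitCostSchedule)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    transitions: TransitionSource = field(default_factory=TransitionSource)
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    horizon: tuple[int, int] = (2011, 2050)
    allocation: Literal["flow", "stock"] = "flow"

    @property
    def provenance(self) -> dict[str, str]:
        return {
            "population": self.population.kind,
            "transitions": self.transitions.kind if self.transitions.kind == "file"
            else "synthetic",
        }

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "population": {
                "kind": self.population.kind,
                "base_pop_6_65": self.population.base_pop_6_65,
                "annual_trend": self.population.annual_trend,
                "age_profile": self.population.age_profile,
                "seed": self.population.seed,
                "path": self.population.path,
            },
            "prevalence": {
                "ar": {g.value: self.prevalence.ar[g] for g in AgeGroup},
                "aa": {g.value: self.prevalence.aa[g] for g in AgeGroup},
                "seasonal_share": self.prevalence.seasonal_share,
            },
            "split": {
                "ar_mild": self.split.ar_mild,
                "aa_mild": self.split.aa_mild,
                "onset_mild": self.split.onset_mild,
            },
            "costs": {
                g.value: {
                    s.name: self.costs.state_cost[(g, s)]
                    for s in (DiseaseState.A, DiseaseState.B,
                              DiseaseState.C, DiseaseState.D)
                }
                for g in AgeGroup
            },
            "scit_costs": {
                "preseasonal": list(self.scit_costs.preseasonal),
                "perennial": list(self.scit_costs.perennial),
                "mean_mode": self.scit_costs.mean_mode,
            },
            "discount": {
                "annual_rate": self.discount.annual_rate,
                "base_year": self.discount.base_year,
            },
            "transitions": {
                "kind": self.transitions.kind,
                "effect_size": self.transitions.effect_size,
                "jitter": self.transitions.jitter,
                "seed": self.transitions.seed,
                "path": self.transitions.path,
            },
            "calibration": {
                "rel_tol": self.calibration.rel_tol,
                "max_iter": self.calibration.max_iter,
            },
            "horizon": list(self.horizon),
            "allocation": self.allocation,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        def sub(section: str) -> dict:
            v = d.get(section, {})
            if not isinstance(v, Mapping):
                raise ValueError(f"config section {section!r} must be a mapping")
            return dict(v)

        kwargs: dict[str, Any] = {}
        if "population" in d:
            kwargs["population"] = PopulationSource(**sub("population"))
        if "prevalence" in d:
            p = sub("prevalence")
            kwargs["prevalence"] = PrevalenceTable(
                ar={AgeGroup(g): v for g, v in p.get("ar", {}).items()},
                aa={AgeGroup(g): v for g, v in p.get("aa", {}).items()},
                seasonal_share=p.get("seasonal_share", 0.60),
            )
        if "split" in d:
            kwargs["split"] = SeveritySplit(**sub("split"))
        if "costs" in d:
            table = {
                (AgeGroup(g), DiseaseState[s]): float(c)
                for g, states in sub("costs").items()
                for s, c in states.items()
            }
            kwargs["costs"] = CostTable(table)
        if "scit_costs" in d:
            s = sub("scit_costs")
            kwargs["scit_costs"] = ScitCostSchedule(
                preseasonal=tuple(s.get("preseasonal", (262.0, 262.0, 262.0))),
                perennial=tuple(s.get("perennial", (502.0, 480.0, 480.0))),
                mean_mode=bool(s.get("mean_mode", True)),
            )
        if "discount" in d:
            kwargs["discount"] = DiscountSpec(**sub("discount"))
        if "transitions" in d:
            kwargs["transitions"] = TransitionSource(**sub("transitions"))
        if "calibration" in d:
            kwargs["calibration"] = CalibrationSpec(**sub("calibration"))
        if "horizon" in d:
            kwargs["horizon"] = tuple(int(y) for y in d["horizon"])
        if "allocation" in d:
            kwargs["allocation"] = d["allocation"]
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the effective configuration (for run metadata)."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config file must contain a YAML mapping")
    try:
        return RunConfig.from_dict(data)
    except (TypeError, ValueError, KeyError) as exc:
        raise ValueError(f"{path}: invalid configuration: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def matrices_to_yaml(
    matrices: Mapping[tuple[AgeGroup, AllergyType, Arm], np.ndarray], path,
    provenance: str = "synthetic",
) -> None:
    """Write transition matrices keyed ``group/type/arm`` with state-order rows."""
    doc: dict[str, Any] = {
        "state_order": [s.name for s in DiseaseState],
        "provenance": provenance,
        "matrices": {
            f"{g.value}/{t.value}/{a.value}": np.asarray(m, dtype=float).tolist()
            for (g, t, a), m in matrices.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def matrices_from_yaml(path) -> dict[tuple[AgeGroup, AllergyType, Arm], np.ndarray]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("state_order") != [s.name for s in DiseaseState]:
        raise ValueError(f"{path}: state_order must be "
                         f"{[s.name for s in DiseaseState]}")
    out: dict[tuple[AgeGroup, AllergyType, Arm], np.ndarray] = {}
    for key, rows in doc.get("matrices", {}).items():
        try:
            g, t, a = key.split("/")
            full_key = (AgeGroup(g), AllergyType(t), Arm(a))
        except ValueError as exc:
            raise ValueError(f"{path}: bad matrix key {key!r}: {exc}") from exc
        try:
            out[full_key] = validate_matrix(np.asarray(rows, dtype=float))
        except ValueError as exc:
            raise ValueError(f"{path}: matrix {key!r}: {exc}") from exc
    for g in AgeGroup:
        for t in AllergyType:
            for a in (Arm.ST, Arm.SCIT):
                if (g, t, a) not in out:
                    raise ValueError(
                        f"{path}: missing matrix for {g.value}/{t.value}/{a.value}"
                    )
    return out
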