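"""Variable schema for CRASH-style head-injury cohorts.

Thirteen categorical admission predictors plus a binary 6-month outcome.
Category labels follow the trial's published frequency table verbatim;
missing-data codes ("no data", "unable to assess", "scan not done",
"alive, disability unknown") are carried alongside the categories so a
raw cohort can represent exactly what was (not) recorded at admission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "VariableSchema",
    "Schema",
    "crash_schema",
    "PREDICTORS",
    "OUTCOME",
    "POOR_OUTCOME",
    "GOOD_OUTCOME",
    "IMAGING_VARS",
]

NO_DATA = "no data"
UNABLE_TO_ASSESS = "unable to assess"
SCAN_NOT_DONE = "scan not done"
ALIVE_UNKNOWN = "alive, disability unknown"

MISSING_CODES = frozenset({NO_DATA, UNABLE_TO_ASSESS, SCAN_NOT_DONE, ALIVE_UNKNOWN})

OUTCOME = "outcome"
POOR_OUTCOME = "death or severe disability"
GOOD_OUTCOME = "moderate disability or good recovery"

#: the five CT-based variables that share the "scan not done" code
IMAGING_VARS = ("phm", "sah", "oblt", "mdls", "hmt")


@dataclass(frozen=True)
class VariableSchema:
    """One categorical variable: ordered categories plus its missing codes."""

    name: str
    group: str  # epidemiology | assessment | imaging | outcome
    categories: tuple[str, ...]
    missing_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate category labels")
        overlap = set(self.categories) & set(self.missing_codes)
        if overlap:
            raise ValueError(f"{self.name}: categories overlap missing codes: {overlap}")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.categories + self.missing_codes

    @property
    def n_categories(self) -> int:
        return len(self.categories)


class Schema:
    """Ordered collection of variable schemas; predictors first, outcome last."""

    def __init__(self, variables: Iterable[VariableSchema]):
        self.variables: tuple[VariableSchema, ...] = tuple(variables)
        self._by_name: dict[str, VariableSchema] = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise ValueError("duplicate variable names in schema")

    def __getitem__(self, name: str) -> VariableSchema:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.group != "outcome")

    @property
    def outcome(self) -> str | None:
        for v in self.variables:
            if v.group == "outcome":
                return v.name
        return None

    def subset(self, names: Iterable[str]) -> "Schema":
        return Schema(self._by_name[n] for n in names)


PREDICTORS = (
    "sex", "age", "cause", "ec",
    "eye", "motor", "verbal", "pupils",
    "phm", "sah", "oblt", "mdls", "hmt",
)


def crash_schema() -> Schema:
    """The 13-predictor + outcome schema of the head-injury trial cohort."""
    yn = ("yes", "no")
    ct_missing = (SCAN_NOT_DONE, NO_DATA)
    return Schema([
        VariableSchema("sex", "epidemiology", ("male", "female")),
        VariableSchema("age", "epidemiology",
                       ("<20", "20-24", "25-29", "30-34", "35-44", "45-54", ">55")),
        VariableSchema("cause", "epidemiology",
                       ("road traffic accident", "fall >2 meters", "other"),
                       (NO_DATA,)),
        VariableSchema("ec", "epidemiology", yn, (NO_DATA,)),
        VariableSchema("eye", "assessment",
                       ("no response", "to pain", "to verbal stimulus", "spontaneous")),
        VariableSchema("motor", "assessment",
                       ("no response", "extension", "abnormal flexion",
                        "withdrawal", "localises", "follows commands")),
        VariableSchema("verbal", "assessment",
                       ("no response", "incomprehensible sounds", "single words",
                        "confused", "orientated")),
        VariableSchema("pupils", "assessment",
                       ("both reactive", "no response unilateral", "no response"),
                       (UNABLE_TO_ASSESS,)),
        VariableSchema("phm", "imaging", yn, ct_missing),
        VariableSchema("sah", "imaging", yn, ct_missing),
        VariableSchema("oblt", "imaging", yn, ct_missing),
        VariableSchema("mdls", "imaging", yn, ct_missing),
        VariableSchema("hmt", "imaging", yn, ct_missing),
        VariableSchema(OUTCOME, "outcome", (POOR_OUTCOME, GOOD_OUTCOME),
                       (ALIVE_UNKNOWN, NO_DATA)),
    ])


def _canon(label: str) -> str:
    return label.strip().lower().replace("_", " ").replace("–", "-")


def alias_map(schema: Schema) -> Mapping[str, dict[str, str]]:
    """Per variable: canonicalized alias -> exact label, for tolerant CSV input."""
    out: dict[str, dict[str, str]] = {}
    for v in schema:
        out[v.name] = {_canon(lbl): lbl for lbl in v.all_labels}
    return out
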