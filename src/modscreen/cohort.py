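"""Cohort representation and case/control analysis design.

A modifier-gene screen contrasts symptom-positive patients against
symptom-negative controls drawn from the same monogenic-disease cohort.
The positive arm is organised into *subgroups*: all affected members of one
family, or a single unrelated patient.  The negative arm is a flat list of
controls shared by every subgroup of the analysis, subject to three rules:

* a control must be phenotype-negative (an unrecorded phenotype excludes a
  patient from either role in that analysis);
* a control must be at least ``min_control_age`` years old (default 40, the
  age by which nearly all disease manifestations are expected);
* at most one member of any family may serve as a control.

Designs are supplied explicitly (config), never auto-derived from phenotype
flags; :func:`build_design` validates them against these rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Sentinel family identifier for patients unrelated to every other participant.
UNRELATED = "UNRELATED"

#: Tokens in the cohort table's family column that mean "unrelated".
_UNRELATED_TOKENS = {"", "-", "unrelated"}

#: Phenotype cell vocabulary -> internal state.
_PHENOTYPE_STATES = {
    "yes": "positive",
    "no": "negative",
    "n/d": "unknown",
    "n-d": "unknown",
    "nd": "unknown",
}

_META_COLUMNS = ("patient_id", "family_id", "men1_variant", "age", "sex")


class CohortError(ValueError):
    """Malformed cohort table."""


class DesignError(ValueError):
    """An analysis design violating the case/control rules."""


@dataclass(frozen=True)
class Patient:
    """One study participant with per-phenotype status flags."""

    patient_id: str
    family_id: str  # a family label, or UNRELATED
    men1_variant: str
    age_years: int
    sex: str  # "F" or "M"
    phenotypes: Mapping[str, str]  # phenotype -> positive | negative | unknown

    def status(self, phenotype: str) -> str:
        if phenotype not in self.phenotypes:
            raise KeyError(f"patient {self.patient_id}: no phenotype column {phenotype!r}")
        return self.phenotypes[phenotype]


@dataclass(frozen=True)
class Subgroup:
    """The positive arm unit: one family's affected members, or one unrelated patient."""

    subgroup_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise DesignError(f"subgroup {self.subgroup_id!r} has no members")


@dataclass(frozen=True)
class AnalysisDesign:
    """A validated case/control layout for one phenotype analysis."""

    analysis_name: str
    phenotype: str
    positive_subgroups: tuple[Subgroup, ...]
    negative_ids: tuple[str, ...]
    min_control_age: int = 40

    @property
    def positive_ids(self) -> tuple[str, ...]:
        return tuple(pid for sg in self.positive_subgroups for pid in sg.member_ids)

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.positive_ids + self.negative_ids


def _parse_phenotype(cell: str, column: str, patient_id: str) -> str:
    token = str(cell).strip().lower()
    try:
        return _PHENOTYPE_STATES[token]
    except KeyError:
        raise CohortError(
            f"patient {patient_id}: phenotype {column}={cell!r} not in yes/no/n-d"
        ) from None


def load_cohort_table(path: str | Path) -> list[Patient]:
    """Read a cohort table (TSV or CSV) into a list of :class:`Patient`.

    The table must contain ``patient_id, family_id, men1_variant, age, sex``
    followed by one column per phenotype with cells ``yes``/``no``/``n/d``.
    Row order is preserved.  A family cell of ``-`` (or empty) marks the
    patient as unrelated to all other participants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")
    phenotype_cols = [c for c in df.columns if c not in _META_COLUMNS]

    patients: list[Patient] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = row["patient_id"].strip()
        if pid in seen:
            raise CohortError(f"duplicate patient_id {pid!r}")
        seen.add(pid)
        fam = row["family_id"].strip()
        family_id = UNRELATED if fam.lower() in _UNRELATED_TOKENS else fam
        try:
            age = int(row["age"])
        except ValueError:
            raise CohortError(f"patient {pid}: unparseable age {row['age']!r}") from None
        if age < 0:
            raise CohortError(f"patient {pid}: negative age {age}")
        phenotypes = {c: _parse_phenotype(row[c], c, pid) for c in phenotype_cols}
        patients.append(
            Patient(
                patient_id=pid,
                family_id=family_id,
                men1_variant=row["men1_variant"].strip(),
                age_years=age,
                sex=row["sex"].strip().upper(),
                phenotypes=phenotypes,
            )
        )
    return patients


def _index(cohort: Iterable[Patient]) -> dict[str, Patient]:
    return {p.patient_id: p for p in cohort}


def _subgroup_id(members: Sequence[Patient]) -> str:
    """Label a subgroup by its family, or by the patient for unrelated singletons."""
    fam = members[0].family_id
    if fam != UNRELATED:
        return fam
    return members[0].patient_id


def build_design(
    cohort: Sequence[Patient],
    phenotype: str,
    positive_grouping: Sequence[Sequence[str]],
    negative_ids: Sequence[str],
    *,
    analysis_name: str | None = None,
    min_control_age: int = 40,
) -> AnalysisDesign:
    """Assemble and validate an :class:`AnalysisDesign`.

    ``positive_grouping`` is a list of member-id lists, one per subgroup.
    Raises :class:`DesignError` naming the offending patient when any
    case/control rule is violated.
    """
    by_id = _index(cohort)
    name = analysis_name or phenotype

    def resolve(pid: str) -> Patient:
        if pid not in by_id:
            raise DesignError(f"{name}: unknown patient id {pid!r}")
        return by_id[pid]

    subgroups: list[Subgroup] = []
    pos_seen: set[str] = set()
    for group in positive_grouping:
        members = [resolve(pid) for pid in group]
        if not members:
            raise DesignError(f"{name}: empty positive subgroup")
        families = {m.family_id for m in members}
        if len(members) > 1 and (len(families) > 1 or UNRELATED in families):
            ids = [m.patient_id for m in members]
            raise DesignError(f"{name}: subgroup {ids} mixes families")
        for m in members:
            if m.patient_id in pos_seen:
                raise DesignError(f"{name}: {m.patient_id} in two positive subgroups")
            pos_seen.add(m.patient_id)
            if m.status(phenotype) != "positive":
                raise DesignError(
                    f"{name}: positive {m.patient_id} is {m.status(phenotype)} "
                    f"for {phenotype}"
                )
        subgroups.append(
            Subgroup(_subgroup_id(members), tuple(m.patient_id for m in members))
        )

    negatives = [resolve(pid) for pid in negative_ids]
    neg_families: set[str] = set()
    for m in negatives:
        if m.patient_id in pos_seen:
            raise DesignError(f"{name}: {m.patient_id} is both positive and negative")
        if m.status(phenotype) != "negative":
            raise DesignError(
                f"{name}: control {m.patient_id} is {m.status(phenotype)} for {phenotype}"
            )
        if m.age_years < min_control_age:
            raise DesignError(
                f"{name}: control {m.patient_id} aged {m.age_years} "
                f"is below {min_control_age}"
            )
        if m.family_id != UNRELATED:
            if m.family_id in neg_families:
                raise DesignError(
                    f"{name}: two controls from family {m.family_id} "
                    f"(second: {m.patient_id})"
                )
            neg_families.add(m.family_id)

    design = AnalysisDesign(
        analysis_name=name,
        phenotype=phenotype,
        positive_subgroups=tuple(subgroups),
        negative_ids=tuple(n.patient_id for n in negatives),
        min_control_age=min_control_age,
    )
    return design


def validate_design(design: AnalysisDesign, cohort: Sequence[Patient]) -> AnalysisDesign:
    """Re-validate an existing design against a cohort (idempotent, no mutation)."""
    rebuilt = build_design(
        cohort,
        design.phenotype,
        [sg.member_ids for sg in design.positive_subgroups],
        design.negative_ids,
        analysis_name=design.analysis_name,
        min_control_age=design.min_control_age,
    )
    return rebuilt


def load_designs(path: str | Path, cohort: Sequence[Patient]) -> list[AnalysisDesign]:
    """Load analysis designs from a YAML config block and validate each."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    designs = []
    for block in doc["analyses"]:
        designs.append(
            build_design(
                cohort,
                block["phenotype"],
                block["positive_subgroups"],
                block["negatives"],
                analysis_name=block.get("name", block["phenotype"]),
                min_control_age=int(block.get("min_control_age", 40)),
            )
        )
    return designs


def packaged_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(str(resources.files("modscreen").joinpath("data", name)))


def load_packaged_table1() -> list[Patient]:
    """The packaged ten-patient study cohort table."""
    return load_cohort_table(packaged_path("cohort_table1.tsv"))


def load_packaged_designs(cohort: Sequence[Patient] | None = None) -> list[AnalysisDesign]:
    """The packaged pituitary and adrenocortical analysis designs."""
    if cohort is None:
        cohort = load_packaged_table1()
    return load_designs(packaged_path("designs.yaml"), cohort)
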