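"""Miniature drug- and condition-code registry.

Claims rules never operate on raw codes: every medication event is mapped to
a therapeutic class (SABA, single-agent LABA, single-agent ICS, fixed-dose
ICS/LABA combination, LTRA, xanthine, oral corticosteroid, and the exclusion
drugs omalizumab / tiotropium / indacaterol), and every diagnosis or
long-term-condition event to a condition label.  Codes are opaque strings:
ATC-like for the dispensation (French-claims-style) dialect and Read-like for
the prescription (UK-primary-care-style) dialect; the pipeline never parses
code internals.

A small default terminology ships with the package, with at least two codes
per class and dialect so that many-to-one code→class mapping is exercised.
It is deliberately miniature, not a reproduction of any real dictionary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_TERMINOLOGY_RESOURCE = "default_terminology.csv"


class Dialect(str, Enum):
    """Which claims-database dialect a record comes from.

    The prescription dialect models a UK-primary-care-style source: clinician
    prescribing events plus coded diagnoses.  The dispensation dialect models
    a French-claims-style source: pharmacy dispensation events with no
    diagnoses, but long-term-condition flags and hospital-discharge codes.
    """

    PRESCRIPTION_UK_LIKE = "PRESCRIPTION_UK_LIKE"
    DISPENSATION_FR_LIKE = "DISPENSATION_FR_LIKE"


class DrugClass(str, Enum):
    SABA = "SABA"
    LABA_MONO = "LABA_MONO"
    ICS_MONO = "ICS_MONO"
    FDC_ICS_LABA = "FDC_ICS_LABA"
    LTRA = "LTRA"
    XANTHINE = "XANTHINE"
    OCS = "OCS"
    OMALIZUMAB = "OMALIZUMAB"
    TIOTROPIUM = "TIOTROPIUM"
    INDACATEROL = "INDACATEROL"
    OTHER = "OTHER"


#: Classes whose events qualify a patient for cohort entry.
RESPIRATORY_CLASSES = frozenset(
    {
        DrugClass.SABA,
        DrugClass.LABA_MONO,
        DrugClass.ICS_MONO,
        DrugClass.FDC_ICS_LABA,
        DrugClass.LTRA,
        DrugClass.XANTHINE,
    }
)

#: Classes that deliver an inhaled corticosteroid (single agent or combined).
ICS_CONTAINING_CLASSES = frozenset({DrugClass.ICS_MONO, DrugClass.FDC_ICS_LABA})


class ConditionLabel(str, Enum):
    COPD = "COPD"
    CYSTIC_FIBROSIS = "CYSTIC_FIBROSIS"
    LUNG_CANCER = "LUNG_CANCER"
    BRONCHIECTASIS = "BRONCHIECTASIS"
    TUBERCULOSIS = "TUBERCULOSIS"
    SARCOIDOSIS = "SARCOIDOSIS"
    ASTHMA = "ASTHMA"
    OTHER = "OTHER"


#: Conditions that exclude a candidate (asthma is inclusion-side).
EXCLUSION_CONDITIONS = frozenset(
    {
        ConditionLabel.COPD,
        ConditionLabel.CYSTIC_FIBROSIS,
        ConditionLabel.LUNG_CANCER,
        ConditionLabel.BRONCHIECTASIS,
        ConditionLabel.TUBERCULOSIS,
        ConditionLabel.SARCOIDOSIS,
    }
)


class SourceKind(str, Enum):
    DIAGNOSIS = "DIAGNOSIS"
    LTC_FLAG = "LTC_FLAG"
    HOSPITAL_DISCHARGE = "HOSPITAL_DISCHARGE"


def is_respiratory(drug_class: DrugClass) -> bool:
    """True iff the class qualifies an event for cohort entry."""
    return drug_class in RESPIRATORY_CLASSES


class TerminologyError(ValueError):
    """Malformed terminology file (e.g. one code mapped to two classes)."""


_DRUG_LABELS = {c.value for c in DrugClass} - {DrugClass.OTHER.value}
_CONDITION_LABELS = {c.value for c in ConditionLabel} - {ConditionLabel.OTHER.value}


@dataclass
class Terminology:
    """Code → class lookup table for drugs and conditions.

    Codes are globally unique across dialects in the shipped file; the
    dialect column records which synthetic-data dialect emits each code.
    Unmapped codes classify as OTHER and are logged once per code.
    """

    drug_map: dict[str, DrugClass]
    condition_map: dict[str, ConditionLabel]
    dialect_of: dict[str, Dialect]
    human_name: dict[str, str]
    _warned: set[str] = field(default_factory=set, repr=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "Terminology":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.DictReader(fh), source=str(path))

    @classmethod
    def default(cls) -> "Terminology":
        ref = resources.files(__package__) / "data" / DEFAULT_TERMINOLOGY_RESOURCE
        with ref.open(newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.DictReader(fh), source="<default>")

    @classmethod
    def _from_reader(cls, reader: csv.DictReader, source: str) -> "Terminology":
        required = {"code", "dialect", "class_label", "human_name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TerminologyError(
                f"{source}: terminology file must have columns {sorted(required)}"
            )
        drug_map: dict[str, DrugClass] = {}
        condition_map: dict[str, ConditionLabel] = {}
        dialect_of: dict[str, Dialect] = {}
        human_name: dict[str, str] = {}
        for i, row in enumerate(reader, start=2):
            code = row["code"].strip()
            label = row["class_label"].strip()
            if not code:
                raise TerminologyError(f"{source}:{i}: empty code")
            try:
                dialect = Dialect(row["dialect"].strip())
            except ValueError as exc:
                raise TerminologyError(f"{source}:{i}: unknown dialect {row['dialect']!r}") from exc
            if label in _DRUG_LABELS:
                new = DrugClass(label)
                old = drug_map.get(code)
            elif label in _CONDITION_LABELS:
                new = ConditionLabel(label)
                old = condition_map.get(code)
            else:
                raise TerminologyError(f"{source}:{i}: unknown class_label {label!r}")
            if code in drug_map and label in _CONDITION_LABELS or (
                code in condition_map and label in _DRUG_LABELS
            ):
                raise TerminologyError(
                    f"{source}:{i}: code {code!r} listed as both drug and condition"
                )
            if old is not None and old != new:
                raise TerminologyError(
                    f"{source}:{i}: code {code!r} mapped to both {old.value} and {label}"
                )
            if isinstance(new, DrugClass):
                drug_map[code] = new
            else:
                condition_map[code] = new
            dialect_of[code] = dialect
            human_name[code] = row["human_name"].strip()
        return cls(drug_map, condition_map, dialect_of, human_name)

    # -- lookups ----------------------------------------------------------

    def classify_drug(self, code: str) -> DrugClass:
        """Map a drug code to its class; unknown codes are OTHER (logged once)."""
        found = self.drug_map.get(code)
        if found is None:
            if code not in self._warned:
                self._warned.add(code)
                logger.warning("unmapped drug code %r classified as OTHER", code)
            return DrugClass.OTHER
        return found

    def classify_condition(self, code: str) -> ConditionLabel:
        found = self.condition_map.get(code)
        if found is None:
            if code not in self._warned:
                self._warned.add(code)
                logger.warning("unmapped condition code %r classified as OTHER", code)
            return ConditionLabel.OTHER
        return found

    def drug_codes_for(self, dialect: Dialect, drug_class: DrugClass) -> list[str]:
        """Sorted codes of one class in one dialect (used by the simulator)."""
        return sorted(
            c
            for c, k in self.drug_map.items()
            if k == drug_class and self.dialect_of[c] == dialect
        )

    def condition_codes_for(self, dialect: Dialect, label: ConditionLabel) -> list[str]:
        return sorted(
            c
            for c, k in self.condition_map.items()
            if k == label and self.dialect_of[c] == dialect
        )

    # -- round-trip -------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "dialect", "class_label", "human_name"])
            for code in sorted(set(self.drug_map) | set(self.condition_map)):
                label = (
                    self.drug_map[code].value
                    if code in self.drug_map
                    else self.condition_map[code].value
                )
                writer.writerow(
                    [code, self.dialect_of[code].value, label, self.human_name.get(code, "")]
                )
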