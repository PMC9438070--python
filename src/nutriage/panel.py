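"""Biomarker panel definitions.

The default panel holds the 30 serum/blood biomarkers used for the
dysregulation scores, grouped into five physiological systems (oxygen
transport, liver/kidney function, leukopoiesis, micronutrients, lipids);
platelet count belongs to no system and enters the global score only.
Markers flagged ``log`` are log-transformed before standardization to
approach normality.  Population means and SDs ship with each marker and
double as the simulator's baseline values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "Marker",
    "BiomarkerPanel",
    "default_panel",
    "PHENOAGE_MARKERS",
    "KDM_DEFAULT_MARKERS",
    "KDM_DEFAULT_EXCLUSIONS",
]

SYSTEMS = (
    "oxygen_transport",
    "liver_kidney",
    "leukopoiesis",
    "micronutrients",
    "lipids",
)


@dataclass(frozen=True)
class Marker:
    """One biomarker: name, units, system membership, normalizing transform
    and population baseline (mean, SD) on the measurement scale."""

    name: str
    units: str
    system: str  # one of SYSTEMS or "none"
    transform: str  # {"log", "sqrt", "none"}
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.system != "none" and self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r} for marker {self.name!r}")
        if self.transform not in ("log", "sqrt", "none"):
            raise ValueError(f"unknown transform {self.transform!r} for marker {self.name!r}")
        if self.sd <= 0:
            raise ValueError(f"marker {self.name!r} needs SD > 0")


# name, units, system, transform, mean, sd
_DEFAULT_MARKERS = [
    ("mch", "pg", "oxygen_transport", "none", 31.0, 1.6),
    ("mchc", "g/L", "oxygen_transport", "none", 340.0, 8.0),
    ("mcv", "fL", "oxygen_transport", "none", 91.3, 4.3),
    ("rbc", "10^12/L", "oxygen_transport", "none", 4.49, 0.43),
    ("rdw", "proportion", "oxygen_transport", "log", 0.136, 0.010),
    ("hemoglobin", "g/L", "oxygen_transport", "none", 139.0, 13.0),
    ("albumin", "g/L", "liver_kidney", "none", 43.2, 2.4),
    ("creatinine", "umol/L", "liver_kidney", "log", 80.3, 21.1),
    ("albumin_globulin_ratio", "ratio", "liver_kidney", "none", 1.52, 0.22),
    ("bilirubin_total", "umol/L", "liver_kidney", "log", 10.2, 4.3),
    ("alkaline_phosphatase", "U/L", "liver_kidney", "log", 78.3, 24.5),
    ("alt", "U/L", "liver_kidney", "log", 12.5, 22.5),
    ("ast", "U/L", "liver_kidney", "log", 22.9, 22.8),
    ("ggt", "U/L", "liver_kidney", "log", 33.0, 32.5),
    ("ldh", "U/L", "liver_kidney", "log", 158.0, 30.0),
    ("protein_total", "g/L", "liver_kidney", "none", 71.9, 4.1),
    ("uric_acid", "umol/L", "liver_kidney", "none", 342.0, 82.0),
    ("monocytes", "proportion", "leukopoiesis", "none", 0.076, 0.029),
    ("neutrophils", "proportion", "leukopoiesis", "none", 0.616, 0.087),
    ("leukocytes", "10^9/L", "leukopoiesis", "log", 6.36, 1.71),
    ("lymphocytes", "proportion", "leukopoiesis", "none", 0.294, 0.081),
    ("folate", "nmol/L", "micronutrients", "log", 38.3, 12.5),
    ("vitamin_b12", "pmol/L", "micronutrients", "log", 431.0, 183.0),
    ("beta_carotene", "umol/L", "micronutrients", "log", 3.40, 5.55),
    ("alpha_tocopherol", "umol/L", "micronutrients", "log", 28.6, 16.0),
    ("gamma_tocopherol", "umol/L", "micronutrients", "log", 3.36, 2.72),
    ("triglycerides", "mmol/L", "lipids", "log", 1.63, 0.77),
    ("cholesterol_total", "mmol/L", "lipids", "none", 5.12, 1.02),
    ("cholesterol_hdl", "mmol/L", "lipids", "none", 1.44, 0.39),
    ("platelets", "10^9/L", "none", "log", 237.0, 64.0),
]

#: the 9 biomarker inputs of the phenotypic-age mortality score (plus
#: chronological age).  CRP is replaced by a fixed constant under the
#: default policy because it is not assayed in the cohort.
PHENOAGE_MARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_percent",
    "mcv",
    "rdw_percent",
    "alkaline_phosphatase",
    "leukocytes",
)

#: age-correlated markers retained for the Klemera-Doubal biological age in
#: the source cohort (after dropping three with numerous missing values).
KDM_DEFAULT_MARKERS = (
    "hemoglobin",
    "hematocrit",
    "rbc",
    "rdw",
    "monocytes",
    "albumin",
    "folate",
    "creatinine",
    "blood_urea_nitrogen",
    "lymphocyte_percent",
)

#: candidates excluded from the KDM calibration for missingness.
KDM_DEFAULT_EXCLUSIONS = ("cholesterol_non_hdl", "cholesterol_ldl", "egfr")


@dataclass
class BiomarkerPanel:
    """Ordered collection of :class:`Marker` definitions."""

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def systems(self) -> list[str]:
        """Systems with at least one member, in canonical order."""
        present = {m.system for m in self.markers}
        return [s for s in SYSTEMS if s in present]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def system_members(self, system: str) -> list[str]:
        return [m.name for m in self.markers if m.system == system]

    def transform_of(self, name: str) -> str:
        return self[name].transform

    def validate(self) -> None:
        """Check the structural invariants of a dysregulation panel."""
        for s in self.systems:
            if len(self.system_members(s)) < 2:
                raise ValueError(f"system {s!r} needs >= 2 markers")

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = [
            {
                "name": m.name,
                "units": m.units,
                "system": m.system,
                "transform": m.transform,
                "mean": m.mean,
                "sd": m.sd,
            }
            for m in self.markers
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BiomarkerPanel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls([Marker(**row) for row in payload])


def default_panel() -> BiomarkerPanel:
    """The default 30-marker panel with system labels and log flags."""
    panel = BiomarkerPanel([Marker(*row) for row in _DEFAULT_MARKERS])
    panel.validate()
    return panel
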