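"""In-memory containers for a paired-technique patient cohort."""

from __future__ import annotations

from dataclasses import dataclass, field

from .dvh import DVH
from .errors import ValidationError

__all__ = ["Plan", "Patient", "Cohort"]


@dataclass
class Plan:
    """One treatment plan: per-structure DVHs plus plan-level metadata."""

    technique: str
    dvhs: dict[str, DVH]
    prescription_gy: float = 59.4
    fractions: int = 33
    target_volumes_cc: dict[str, float] = field(default_factory=dict)
    ctv95_cc: float | None = None       # CTV volume covered by the 95% isodose
    v95_body_cc: float | None = None    # total patient volume of the 95% isodose


@dataclass
class Patient:
    patient_id: str
    plans: dict[str, Plan]


@dataclass
class Cohort:
    patients: list[Patient]
    meta: dict = field(default_factory=dict)

    @property
    def techniques(self) -> list[str]:
        names: list[str] = []
        for p in self.patients:
            for t in p.plans:
                if t not in names:
                    names.append(t)
        return names

    def require_paired(self) -> None:
        """Every patient must carry every technique (paired design)."""
        techs = self.techniques
        if len(techs) < 2:
            raise ValidationError(
                f"paired analysis needs two techniques, found {techs}"
            )
        for p in self.patients:
            missing = [t for t in techs if t not in p.plans]
            if missing:
                raise ValidationError(
                    f"patient {p.patient_id} is missing plans for {missing}"
                )
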