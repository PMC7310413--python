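"""Target plan-quality indices: homogeneity, conformity, coverage goals.

* Homogeneity index (RTOG): ``HI = (D2% - D98%) / D50%`` over the target
  DVH — 0 for a perfectly uniform target dose, larger for hotter/colder
  spread.
* Conformation number: ``CN = CTV95^2 / (CTV * V95)`` where ``CTV95`` is the
  target volume covered by the 95% reference isodose and ``V95`` the total
  patient volume of that isodose — 1 for perfect conformity, 0 when the
  isodose misses the target entirely.
* Coverage flags: prescription goals of the form "100% of GTV receives
  >= 95% of the dose", ">= 98% of CTV receives >= 95%", and "no CTV volume
  receives >= 107%".
"""

from __future__ import annotations

from dataclasses import dataclass

from .dvh import DVH
from .errors import UndefinedValueError, ValidationError

__all__ = [
    "TargetCoverageGoals",
    "ConformityInputs",
    "homogeneity_index",
    "conformation_number",
    "coverage_flags",
    "CoverageFlag",
]

# volume below this is "0 cc" for the no-hot-spot goal
_HOTSPOT_TOL_CC = 0.01


@dataclass(frozen=True)
class TargetCoverageGoals:
    """Prescription coverage goals as fractions."""

    gtv_d100_min_frac: float = 0.95   # GTV minimum dose >= this x prescription
    ctv_v95_min_frac: float = 0.98    # >= this fraction of CTV inside 95% isodose
    ctv_v107_max_frac: float = 0.0    # fraction of CTV allowed >= 107% dose

    def __post_init__(self) -> None:
        for value in (self.gtv_d100_min_frac, self.ctv_v95_min_frac,
                      self.ctv_v107_max_frac):
            if not 0 <= value <= 1:
                raise ValidationError("coverage goal fractions must be in [0,1]")


@dataclass(frozen=True)
class ConformityInputs:
    """Volumes entering the conformation number.

    ``v_t``: target (CTV) volume, cc; ``v_t95``: target volume covered by
    the 95% isodose, cc; ``v95_total``: total patient volume of the 95%
    isodose, cc.
    """

    v_t: float
    v_t95: float
    v95_total: float

    def __post_init__(self) -> None:
        if self.v_t <= 0 or self.v95_total <= 0:
            raise ValidationError("target and isodose volumes must be > 0")
        if not 0 <= self.v_t95 <= min(self.v_t, self.v95_total) * (1 + 1e-9):
            raise ValidationError(
                f"covered target volume {self.v_t95:g} cc exceeds target "
                f"({self.v_t:g} cc) or isodose ({self.v95_total:g} cc) volume"
            )


def homogeneity_index(target_dvh: DVH) -> float:
    """RTOG homogeneity index (D2% - D98%) / D50% of the target DVH."""
    d2 = target_dvh.dose_at_volume(2.0, unit="percent")
    d98 = target_dvh.dose_at_volume(98.0, unit="percent")
    d50 = target_dvh.dose_at_volume(50.0, unit="percent")
    if d50 <= 0:
        raise UndefinedValueError(
            f"{target_dvh.structure}: D50% is zero, HI undefined")
    return (d2 - d98) / d50


def conformation_number(inputs: ConformityInputs) -> float:
    """CN = CTV95^2 / (CTV x V95), in [0, 1]."""
    return inputs.v_t95 ** 2 / (inputs.v_t * inputs.v95_total)


@dataclass(frozen=True)
class CoverageFlag:
    goal: str
    achieved: float
    required: float
    passed: bool
    note: str = ""


def coverage_flags(gtv_dvh: DVH, ctv_dvh: DVH, prescription: float,
                   goals: TargetCoverageGoals | None = None) -> list[CoverageFlag]:
    """Audit GTV/CTV DVHs against the prescription coverage goals.

    Degenerate DVHs produce failed flags with an explanatory note rather
    than raising.
    """
    if prescription <= 0:
        raise ValidationError("prescription must be > 0")
    goals = goals or TargetCoverageGoals()
    flags: list[CoverageFlag] = []

    d95 = goals.gtv_d100_min_frac * prescription
    try:
        gtv_min = gtv_dvh.dose_at_volume(100.0, unit="percent")
        flags.append(CoverageFlag(
            f"GTV D100% >= {100 * goals.gtv_d100_min_frac:g}% of prescription",
            gtv_min, d95, gtv_min >= d95))
    except (UndefinedValueError, ValidationError) as exc:
        flags.append(CoverageFlag("GTV D100%", float("nan"), d95, False, str(exc)))

    try:
        v95 = ctv_dvh.volume_at_dose(0.95 * prescription, unit="percent")
        req = 100 * goals.ctv_v95_min_frac
        flags.append(CoverageFlag(
            f"CTV V(95% presc) >= {req:g}%", v95, req, v95 >= req))
    except (UndefinedValueError, ValidationError) as exc:
        flags.append(CoverageFlag("CTV V95%", float("nan"),
                                  100 * goals.ctv_v95_min_frac, False, str(exc)))

    try:
        hot_cc = ctv_dvh.volume_at_dose(1.07 * prescription, unit="cc")
        allowed = goals.ctv_v107_max_frac * ctv_dvh.total_volume_cc
        flags.append(CoverageFlag(
            f"CTV volume >= 107% of prescription <= {allowed:g} cc",
            hot_cc, allowed, hot_cc <= allowed + _HOTSPOT_TOL_CC))
    except (UndefinedValueError, ValidationError) as exc:
        flags.append(CoverageFlag("CTV hot spot", float("nan"), 0.0, False,
                                  str(exc)))
    return flags
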