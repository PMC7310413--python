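"""EQD2 conversion, gEUD reduction, and the LKB NTCP model.

The Lyman-Kutcher-Burman (LKB) normal-tissue-complication-probability model
maps a heterogeneous organ dose distribution to a toxicity probability in
three steps:

1. every DVH bin dose is converted to the equivalent dose in 2-Gy fractions
   (EQD2) under the linear-quadratic model,
   ``EQD2(D) = D * (d + a/b) / (2 + a/b)`` with per-fraction dose
   ``d = D / n_fractions`` and tissue ratio ``a/b`` (4 Gy for the upper-GI
   organs modelled here);
2. the DVH is reduced to a generalized equivalent uniform dose,
   ``gEUD = ( sum_i (v_i / V) * D_i**(1/n) )**n`` — the Kutcher-Burman
   histogram reduction with volume-effect exponent ``n`` (``n=1`` is the mean
   dose; ``n -> 0`` approaches the maximum dose, i.e. a serial organ);
3. the probability is the probit dose response
   ``NTCP = Phi( (gEUD - TD50) / (m * TD50) )`` with ``TD50`` the uniform
   whole-organ dose giving 50% complication probability and ``m`` the
   relative slope.

The module ships the six published (TD50, m, n) parameter sets used for
upper-GI toxicity endpoints (Pan et al., Burman et al., Holyoake et al.).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import logsumexp, ndtr

from .dvh import DVH
from .errors import UndefinedValueError, ValidationError

__all__ = [
    "LKBParameters",
    "FractionationScheme",
    "eqd2_transform",
    "geud",
    "lkb_ntcp",
    "ntcp_from_dvh",
    "builtin_parameter_registry",
    "lookup_parameters",
    "save_parameter_registry",
    "load_parameter_registry",
]


@dataclass(frozen=True)
class LKBParameters:
    """One published LKB parameter set.

    ``td50`` is on the EQD2 scale (Gy); ``m`` is the dimensionless slope of
    the dose-response curve; ``n`` the dose-volume (volume-effect) exponent.
    """

    organ: str
    source: str
    td50: float
    m: float
    n: float
    endpoint: str = ""

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValidationError("td50 must be > 0")
        if self.m <= 0:
            raise ValidationError("m must be > 0")
        if not 0 < self.n <= 1:
            raise ValidationError("n must lie in (0, 1]")

    @property
    def key(self) -> str:
        return f"{self.organ}/{self.source}"


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription: total dose, fraction count, LQ alpha/beta ratio.

    ``rbe`` is informational only: doses are Gy(RBE) throughout and are never
    rescaled here.
    """

    total_dose: float = 59.4
    fractions: int = 33
    alpha_beta: float = 4.0
    rbe: float = 1.1

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise ValidationError("total_dose must be > 0")
        if int(self.fractions) < 1:
            raise ValidationError("fractions must be >= 1")
        if self.alpha_beta <= 0:
            raise ValidationError("alpha_beta must be > 0")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.fractions

    def eqd2(self, dose: np.ndarray | float) -> np.ndarray | float:
        """EQD2 of a physical dose delivered over this scheme's fractions."""
        d = np.asarray(dose, dtype=float) / self.fractions
        out = np.asarray(dose, dtype=float) * (d + self.alpha_beta) / (
            2.0 + self.alpha_beta)
        return float(out) if np.isscalar(dose) else out


def eqd2_transform(dvh: DVH, scheme: FractionationScheme) -> DVH:
    """Map every bin dose to its EQD2; volumes are untouched.

    Each bin's dose is assumed delivered over the plan's full fraction count
    (per-fraction bin dose ``D_i / fractions``), the standard DVH-wise LQ
    correction.  The map is strictly increasing in dose, so DVH validity is
    preserved; the output grid is generally non-uniform.
    """
    new_dose = scheme.eqd2(dvh.dose)
    return replace(dvh, dose=np.asarray(new_dose, dtype=float))


def geud(dvh: DVH, n: float) -> float:
    """Generalized equivalent uniform dose with volume-effect exponent n.

    Computed in log space so that small exponents (serial organs,
    ``1/n`` of order 10^3) do not overflow.
    """
    if not 0 < n <= 1:
        raise ValidationError("gEUD exponent n must lie in (0, 1]")
    diff = dvh.to_differential()
    total = diff.total_volume_cc
    if total <= 0:
        raise UndefinedValueError(
            f"{dvh.structure}: gEUD undefined for zero-volume structure")
    frac = diff.volume_cc / total
    pos = (frac > 0) & (diff.dose > 0)
    if not np.any(pos):
        return 0.0
    a = 1.0 / n
    log_mean = logsumexp(np.log(frac[pos]) + a * np.log(diff.dose[pos]))
    return float(np.exp(n * log_mean))


def lkb_ntcp(eud: float, params: LKBParameters) -> float:
    """Probit dose response: NTCP = Phi((EUD - TD50) / (m * TD50))."""
    if eud < 0:
        raise ValidationError("EUD must be >= 0")
    t = (eud - params.td50) / (params.m * params.td50)
    return float(ndtr(t))


def ntcp_from_dvh(dvh: DVH, params: LKBParameters,
                  scheme: FractionationScheme | None = None,
                  apply_eqd2: bool = True) -> float:
    """Full LKB chain: (EQD2 ->) gEUD -> probit.

    ``apply_eqd2=False`` evaluates on the physical-dose axis, for sensitivity
    analysis.
    """
    if apply_eqd2:
        if scheme is None:
            scheme = FractionationScheme()
        dvh = eqd2_transform(dvh, scheme)
    return lkb_ntcp(geud(dvh, params.n), params)


# ---------------------------------------------------------------------------
# published parameter registry

_REGISTRY: tuple[LKBParameters, ...] = (
    LKBParameters("stomach", "pan", 62.0, 0.30, 0.07, "gastric bleed"),
    LKBParameters("stomach", "burman", 65.0, 0.14, 0.15,
                  "ulceration/perforation"),
    LKBParameters("duodenum", "pan", 180.0, 0.49, 0.12, "gastric bleed"),
    LKBParameters("duodenum", "holyoake", 299.1, 0.51, 0.193,
                  "grade >=3 GI toxicity"),
    LKBParameters("small_bowel", "burman", 55.0, 0.16, 0.15,
                  "obstruction/perforation"),
    LKBParameters("stoduo", "pan", 52.5, 0.35, 0.21, "gastric bleed"),
)


def builtin_parameter_registry() -> list[LKBParameters]:
    """The six published upper-GI LKB parameter sets shipped with the
    package, keyed by (organ, source)."""
    return list(_REGISTRY)


def lookup_parameters(organ: str, source: str) -> LKBParameters:
    organ, source = organ.lower(), source.lower()
    for p in _REGISTRY:
        if p.organ == organ and p.source == source:
            return p
    raise KeyError(f"no LKB parameter set for {organ}/{source}")


def save_parameter_registry(params: Sequence[LKBParameters],
                            path: str | Path) -> None:
    """Serialize parameter sets to JSON or YAML (by file extension)."""
    path = Path(path)
    doc = [asdict(p) for p in params]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_parameter_registry(path: str | Path) -> list[LKBParameters]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return [LKBParameters(**rec) for rec in doc]
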