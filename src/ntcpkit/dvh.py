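"""Dose-volume histogram data model and metric extraction.

A dose-volume histogram (DVH) summarises a 3-D dose distribution within one
anatomical structure.  The *cumulative* form gives, for each dose level ``d``,
the structure volume receiving at least ``d``; the *differential* form gives
the volume falling in each dose bin.  The cumulative form in absolute cubic
centimetres is the canonical representation here, since clinical constraints
mix absolute (``V50Gy in cc``, ``D0.1cc``) and relative (``V50Gy in %``)
quantities and cc is the lossless base unit.

All doses are Gy(RBE): proton doses are assumed to have been scaled by the
constant RBE factor (1.1) upstream in the planning system; this module never
rescales dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import RangeError, UndefinedValueError, ValidationError

__all__ = [
    "DVH",
    "MetricSpec",
    "ConstraintSpec",
    "ConstraintResult",
    "evaluate_constraints",
    "worst_case_envelope",
]

_REL_TOL = 1e-6


@dataclass(frozen=True)
class DVH:
    """A single structure's dose-volume histogram.

    Parameters
    ----------
    structure:
        Structure label, e.g. ``"stomach"``.
    mode:
        ``"cumulative"`` (volume receiving at least each dose) or
        ``"differential"`` (volume per dose bin; ``dose`` then holds the
        representative dose of each bin).
    dose:
        Strictly increasing dose grid in Gy(RBE).  Cumulative DVHs must start
        at 0 so that ``volume_cc[0]`` is the whole structure volume.
    volume_cc:
        Non-negative volumes in cc, one per grid point.
    metadata:
        Opaque key/value pairs carried through file round-trips.
    """

    structure: str
    mode: Literal["cumulative", "differential"]
    dose: np.ndarray
    volume_cc: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        vol = np.asarray(self.volume_cc, dtype=float)
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "volume_cc", vol)
        if dose.ndim != 1 or vol.shape != dose.shape or dose.size == 0:
            raise ValidationError(
                f"{self.structure}: dose and volume must be equal-length 1-d arrays"
            )
        if dose.size > 1 and np.any(np.diff(dose) <= 0):
            i = int(np.argmax(np.diff(dose) <= 0))
            raise ValidationError(
                f"{self.structure}: dose grid not strictly increasing at bin {i}"
            )
        if np.any(vol < 0):
            i = int(np.argmax(vol < 0))
            raise ValidationError(
                f"{self.structure}: negative volume {vol[i]:g} cc at bin {i}"
            )
        if self.mode == "cumulative":
            if dose[0] != 0.0:
                raise ValidationError(
                    f"{self.structure}: cumulative DVH must start at dose 0"
                )
            diffs = np.diff(vol)
            tol = _REL_TOL * max(vol[0], 1.0)
            if np.any(diffs > tol):
                i = int(np.argmax(diffs > tol))
                raise ValidationError(
                    f"{self.structure}: cumulative volume increases at bin {i} "
                    f"({vol[i]:g} -> {vol[i + 1]:g} cc)"
                )
            # clip tiny numerical upticks so downstream differences stay >= 0
            object.__setattr__(self, "volume_cc", np.minimum.accumulate(vol))
        elif self.mode != "differential":
            raise ValidationError(f"unknown DVH mode {self.mode!r}")

    # -- basic descriptors -------------------------------------------------

    @property
    def total_volume_cc(self) -> float:
        """Whole-structure volume in cc."""
        if self.mode == "cumulative":
            return float(self.volume_cc[0])
        return float(self.volume_cc.sum())

    @property
    def bin_width(self) -> float | None:
        """Grid spacing in Gy(RBE), or ``None`` if the grid is non-uniform
        (e.g. after an EQD2 transform)."""
        if self.dose.size < 2:
            return None
        steps = np.diff(self.dose)
        if np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            return float(steps[0])
        return None

    @property
    def max_dose(self) -> float:
        """Largest dose received by any (non-zero) part of the structure."""
        if self.mode == "cumulative":
            nz = np.nonzero(self.volume_cc > 0)[0]
        else:
            nz = np.nonzero(self.volume_cc > 0)[0]
        if nz.size == 0:
            return 0.0
        return float(self.dose[nz[-1]])

    # -- representation changes -------------------------------------------

    def to_differential(self) -> "DVH":
        """Successive differences of the cumulative curve.

        Bin ``i`` holds the volume receiving between ``dose[i]`` and
        ``dose[i+1]``, assigned representative dose ``dose[i]``; the last bin
        holds the volume at or above the last grid dose.
        """
        if self.mode == "differential":
            return self
        v = self.volume_cc
        dv = np.empty_like(v)
        dv[:-1] = v[:-1] - v[1:]
        dv[-1] = v[-1]
        return DVH(self.structure, "differential", self.dose.copy(), dv,
                   dict(self.metadata))

    def to_cumulative(self) -> "DVH":
        """Suffix sums of the differential bins (inverse of
        :meth:`to_differential`)."""
        if self.mode == "cumulative":
            return self
        cum = np.cumsum(self.volume_cc[::-1])[::-1]
        dose = self.dose
        vol = cum
        if dose[0] != 0.0:
            dose = np.concatenate(([0.0], dose))
            vol = np.concatenate(([cum[0]], cum))
        return DVH(self.structure, "cumulative", dose, vol, dict(self.metadata))

    # -- metric extraction -------------------------------------------------

    def volume_at_dose(self, dose_gy: float, unit: str = "cc") -> float:
        """V_x: volume receiving at least ``dose_gy``, in cc or percent.

        Linear interpolation between grid points; doses beyond the last grid
        point return 0 (the curve is truncated there).
        """
        if dose_gy < 0:
            raise RangeError("query dose must be >= 0")
        cum = self.to_cumulative()
        if dose_gy > cum.dose[-1]:
            v = 0.0
        else:
            v = float(np.interp(dose_gy, cum.dose, cum.volume_cc))
        if unit == "cc":
            return v
        if unit in ("percent", "%"):
            total = cum.total_volume_cc
            if total <= 0:
                raise UndefinedValueError(
                    f"{self.structure}: percent volume undefined for a "
                    "zero-volume structure"
                )
            return 100.0 * v / total
        raise RangeError(f"unknown volume unit {unit!r}")

    def dose_at_volume(self, volume: float, unit: str = "cc") -> float:
        """D_v: the largest dose such that at least ``volume`` receives it.

        Inverse linear interpolation of the cumulative curve; flat segments
        resolve to their high-dose end.
        """
        cum = self.to_cumulative()
        total = cum.total_volume_cc
        if unit in ("percent", "%"):
            if total <= 0:
                raise UndefinedValueError(
                    f"{self.structure}: percent query undefined for a "
                    "zero-volume structure"
                )
            volume = volume / 100.0 * total
        elif unit != "cc":
            raise RangeError(f"unknown volume unit {unit!r}")
        if volume <= 0:
            raise RangeError("query volume must be > 0")
        if volume > total * (1 + _REL_TOL):
            raise RangeError(
                f"{self.structure}: query volume {volume:g} cc exceeds "
                f"structure volume {total:g} cc"
            )
        v = cum.volume_cc
        d = cum.dose
        # last index with V(d_i) >= volume (flat ties -> max dose)
        ge = np.nonzero(v >= volume - _REL_TOL * max(total, 1.0))[0]
        if ge.size == 0:
            return 0.0
        i = int(ge[-1])
        if i == v.size - 1 or v[i] <= volume:
            return float(d[i])
        # interpolate on the bracketing bin: v[i] > volume > v[i+1]
        frac = (v[i] - volume) / (v[i] - v[i + 1])
        return float(d[i] + frac * (d[i + 1] - d[i]))

    def mean_dose(self) -> float:
        """Volume-weighted mean dose over the differential bins."""
        diff = self.to_differential()
        total = diff.total_volume_cc
        if total <= 0:
            raise UndefinedValueError(
                f"{self.structure}: mean dose undefined for zero-volume structure"
            )
        return float(np.dot(diff.dose, diff.volume_cc) / total)

    # -- convenience -------------------------------------------------------

    @staticmethod
    def uniform(dose_gy: float, total_volume_cc: float, structure: str = "organ",
                bin_width: float = 0.05) -> "DVH":
        """Whole structure uniformly irradiated at ``dose_gy``."""
        if dose_gy < 0 or total_volume_cc < 0:
            raise ValidationError("dose and volume must be non-negative")
        n = max(int(round(dose_gy / bin_width)), 1)
        grid = np.linspace(0.0, dose_gy if dose_gy > 0 else bin_width, n + 1)
        vol = np.full(n + 1, float(total_volume_cc))
        if dose_gy == 0:
            vol[1:] = 0.0
        return DVH(structure, "cumulative", grid, vol)

    def scaled_doses(self, factor: float) -> "DVH":
        """Multiply every grid dose by ``factor`` (dose escalation)."""
        if factor <= 0:
            raise RangeError("scale factor must be positive")
        return replace(self, dose=self.dose * factor)


# ---------------------------------------------------------------------------
# metric and constraint specifications


@dataclass(frozen=True)
class MetricSpec:
    """One DVH-derived scalar: V_x, D_v, or mean dose.

    ``direction`` states which way is clinically worse, used by the
    worst-case scenario envelope: ``"max"`` for organ-at-risk metrics
    (more dose/volume is worse, the default) and ``"min"`` for target
    coverage metrics.
    """

    kind: Literal["volume_at_dose", "dose_at_volume", "mean_dose"]
    threshold: float = 0.0
    output_unit: str = "cc"
    direction: Literal["max", "min"] = "max"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("metric threshold must be >= 0")
        allowed = {
            "volume_at_dose": {"cc", "percent", "%"},
            "dose_at_volume": {"Gy", "Gy(RBE)", "GyE"},
            "mean_dose": {"Gy", "Gy(RBE)", "GyE"},
        }
        if self.kind not in allowed:
            raise ValidationError(f"unknown metric kind {self.kind!r}")
        if self.output_unit not in allowed[self.kind]:
            raise ValidationError(
                f"output unit {self.output_unit!r} inconsistent with {self.kind}"
            )

    def evaluate(self, dvh: DVH) -> float:
        if self.kind == "volume_at_dose":
            return dvh.volume_at_dose(self.threshold, unit=self.output_unit)
        if self.kind == "dose_at_volume":
            return dvh.dose_at_volume(self.threshold, unit="cc")
        return dvh.mean_dose()

    def label(self) -> str:
        if self.kind == "volume_at_dose":
            unit = "%" if self.output_unit in ("percent", "%") else "cc"
            return f"V{self.threshold:g}GyE ({unit})"
        if self.kind == "dose_at_volume":
            return f"D{self.threshold:g}cc (GyE)"
        return "Mean dose (GyE)"


@dataclass(frozen=True)
class ConstraintSpec:
    """A clinical dose-volume limit, e.g. 'stomach: <=16 cc receive 50 GyE'."""

    metric: MetricSpec
    comparator: Literal["<=", "<", ">="]
    limit: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValidationError("constraint limit must be >= 0")
        if self.comparator not in ("<=", "<", ">="):
            raise ValidationError(f"unknown comparator {self.comparator!r}")


@dataclass(frozen=True)
class ConstraintResult:
    label: str
    achieved: float | None
    comparator: str
    limit: float
    passed: bool | None
    error: str | None = None


def evaluate_constraints(dvh: DVH,
                         constraints: Sequence[ConstraintSpec]) -> list[ConstraintResult]:
    """Audit a DVH against a constraint list, preserving input order.

    Metric-level failures (e.g. percent metrics on a zero-volume structure)
    are attached to the offending record instead of aborting the audit.
    """
    report: list[ConstraintResult] = []
    for spec in constraints:
        label = spec.label or spec.metric.label()
        try:
            achieved = spec.metric.evaluate(dvh)
        except (UndefinedValueError, RangeError) as exc:
            report.append(ConstraintResult(label, None, spec.comparator,
                                           spec.limit, None, str(exc)))
            continue
        if spec.comparator == "<=":
            ok = achieved <= spec.limit
        elif spec.comparator == "<":
            ok = achieved < spec.limit
        else:
            ok = achieved >= spec.limit
        report.append(ConstraintResult(label, achieved, spec.comparator,
                                       spec.limit, bool(ok)))
    return report


def worst_case_envelope(scenarios: Sequence[DVH],
                        metric: MetricSpec) -> tuple[float, int]:
    """Worst metric value over perturbation-scenario DVHs of one structure.

    Robustness evaluation recomputes each DVH under setup/range perturbations
    and takes the clinically worst value: the maximum for organ-at-risk
    metrics, the minimum for target-coverage metrics (``metric.direction``).

    Returns ``(worst value, index of worst scenario)``.
    """
    if len(scenarios) == 0:
        raise RangeError("worst-case envelope needs at least one scenario")
    labels = {s.structure for s in scenarios}
    if len(labels) > 1:
        raise ValidationError(
            f"scenarios mix structures: {sorted(labels)}"
        )
    values = [metric.evaluate(s) for s in scenarios]
    pick = max if metric.direction == "max" else min
    idx = pick(range(len(values)), key=values.__getitem__)
    return values[idx], idx
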