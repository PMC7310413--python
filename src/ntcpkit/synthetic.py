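"""Seedable generator of paired photon-like / proton-like patient plans.

No per-patient DVH data are available for the nine-patient pancreatic-head
cohort the defaults emulate — only cohort summary statistics — so this
module generates surrogate cohorts whose summary metrics approximate those
published cohort means, letting every downstream stage (metrics, NTCP,
paired statistics, reports) run end to end without any external data.

Organ DVH surrogate
-------------------
A structure's cumulative relative DVH is modelled as a two-component
survival curve

    S(D) = b * exp(-(D / lambda)^gamma)  +  h * Phi((mu - D) / sigma)

where the Weibull term is the low/intermediate-dose *bath* (fraction ``b``
of the organ, scale ``lambda``, shape ``gamma``) and the probit term is the
*hot region* abutting the target (fraction ``h`` centred near the
prescription at ``mu`` with spread ``sigma``).  The remaining fraction
``1 - b - h`` of the organ is essentially unirradiated.  Target (GTV/CTV)
DVHs are truncated-normal survival curves around the prescription dose.

Pairing
-------
The two techniques share each patient's random anatomy effects (organ
volume, lognormal multipliers on ``lambda`` and the component fractions, a
shared hot-centre shift) and differ through technique-level model
parameters plus a small independent per-arm jitter, so paired differences
are positively correlated across patients — the property that gives the
paired signed-rank test its power.

Randomness
----------
One root seed; per-patient and per-(patient, organ) substreams are derived
from keyed ``SeedSequence`` tuples, so adding organs or patients never
perturbs existing draws and regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .cohort import Cohort, Patient, Plan
from .dvh import DVH
from .errors import ValidationError
from .radiobiology import FractionationScheme

__all__ = ["OrganDvhModel", "TargetModel", "CohortSpec", "default_spec",
           "sample_patient", "generate_cohort"]


@dataclass(frozen=True)
class OrganDvhModel:
    """Parametric surrogate for one organ's cumulative DVH under one
    technique.  Fractions are of the organ volume; doses in Gy(RBE)."""

    organ: str
    bath_fraction: float
    bath_scale: float          # Weibull scale lambda, Gy
    bath_shape: float          # Weibull shape gamma
    hot_fraction: float = 0.0
    hot_center: float = 55.0   # mu, Gy (near prescription)
    hot_spread: float = 2.0    # sigma, Gy
    bath_max: float = 55.0     # truncation of the bath component, Gy
    patient_variability: float = 0.35   # lognormal SD on lambda and fractions
    arm_jitter: float = 0.05            # independent per-arm lognormal SD
    hot_center_sd: float = 1.2          # shared per-patient shift of mu, Gy

    # the bath scale gets a damped share of the patient variability: dose
    # percentiles respond exponentially to lambda, so full-strength lognormal
    # scatter on it would blow up the high-dose metrics' cohort SD
    _SCALE_VAR_DAMP = 0.4

    def __post_init__(self) -> None:
        if self.bath_fraction < 0 or self.hot_fraction < 0:
            raise ValidationError("fractions must be >= 0")
        if self.bath_fraction + self.hot_fraction > 1.0 + 1e-9:
            raise ValidationError("bath_fraction + hot_fraction must be <= 1")
        if self.bath_scale <= 0 or self.bath_shape <= 0 or self.hot_spread <= 0:
            raise ValidationError("scales and spreads must be > 0")


@dataclass(frozen=True)
class TargetModel:
    """Truncated-normal survival around the prescription for GTV/CTV."""

    sigma_ctv: float           # Gy; sets the homogeneity index
    gtv_tighten: float = 0.8   # sigma_gtv = gtv_tighten * sigma_ctv
    trunc_q: float = 0.005     # two-sided truncation quantile


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic paired cohort."""

    n_patients: int = 9
    seed: int = 0
    scheme: FractionationScheme = field(default_factory=FractionationScheme)
    techniques: tuple[str, str] = ("photon", "proton")
    organ_models: dict = field(default_factory=dict)   # technique -> organ -> model
    organ_volume_cc: dict = field(default_factory=dict)
    organ_volume_sd: float = 0.20                      # lognormal SD, shared
    gtv_range_cc: tuple[float, float] = (22.9, 54.3)
    ctv_over_gtv: tuple[float, float] = (1.85, 2.20)
    ptv_over_ctv: tuple[float, float] = (1.65, 1.90)
    target_models: dict = field(default_factory=dict)  # technique -> TargetModel
    v95_multiplier: dict = field(default_factory=dict) # technique -> (mean, sd)
    ctv95_frac: tuple[float, float] = (0.985, 0.995)
    bin_width: float = 0.05
    grid_max: float = 70.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        lo, hi = self.gtv_range_cc
        if not 0 < lo < hi:
            raise ValidationError("gtv_range_cc must be positive and ordered")

    @property
    def organs(self) -> list[str]:
        names = list(self.organ_models[self.techniques[0]])
        if "stomach" in names and "duodenum" in names and "stoduo" not in names:
            names.insert(names.index("duodenum") + 1, "stoduo")
        return names


# calibrated to the published nine-patient cohort means (see docs/methods.md)
_PHOTON_MODELS = {
    "stomach": OrganDvhModel("stomach", 0.55, 21.0, 1.60, 0.031, 55.5, 0.8),
    "duodenum": OrganDvhModel("duodenum", 0.78, 20.0, 1.50, 0.080, 48.0, 6.0),
    "small_bowel": OrganDvhModel("small_bowel", 0.70, 24.0, 2.00, 0.020, 50.0, 3.0),
    "kidneys": OrganDvhModel("kidneys", 0.80, 8.5, 2.00, bath_max=40.0),
    "liver": OrganDvhModel("liver", 0.45, 14.5, 1.00, bath_max=50.0),
    "spinal_cord": OrganDvhModel("spinal_cord", 0.50, 10.5, 2.50, bath_max=30.0),
}
_PROTON_MODELS = {
    "stomach": OrganDvhModel("stomach", 0.30, 15.5, 0.90, 0.020, 55.0, 1.0),
    "duodenum": OrganDvhModel("duodenum", 0.70, 21.5, 1.55, 0.075, 47.5, 6.0),
    "small_bowel": OrganDvhModel("small_bowel", 0.36, 12.0, 1.20, 0.012, 49.0, 3.5),
    "kidneys": OrganDvhModel("kidneys", 0.90, 12.3, 1.90, bath_max=40.0),
    "liver": OrganDvhModel("liver", 0.47, 12.5, 1.15, bath_max=50.0),
    "spinal_cord": OrganDvhModel("spinal_cord", 0.25, 4.0, 2.50, bath_max=30.0),
}
_ORGAN_VOLUMES = {
    "stomach": 300.0, "duodenum": 70.0, "small_bowel": 350.0,
    "kidneys": 300.0, "liver": 1500.0, "spinal_cord": 30.0,
}


def default_spec(n_patients: int = 9, seed: int = 0) -> CohortSpec:
    """The default study conditions: nine patients, 59.4 Gy(RBE) in 33
    fractions, photon-like vs proton-like arms calibrated to the published
    cohort's summary dose metrics."""
    return CohortSpec(
        n_patients=n_patients,
        seed=seed,
        organ_models={"photon": dict(_PHOTON_MODELS),
                      "proton": dict(_PROTON_MODELS)},
        organ_volume_cc=dict(_ORGAN_VOLUMES),
        target_models={"photon": TargetModel(sigma_ctv=0.61),
                       "proton": TargetModel(sigma_ctv=1.06)},
        v95_multiplier={"photon": (2.28, 0.12), "proton": (1.66, 0.12)},
    )


# ---------------------------------------------------------------------------


def _organ_rng(spec: CohortSpec, patient_index: int, organ_index: int):
    return np.random.default_rng(
        np.random.SeedSequence((spec.seed, 101, patient_index, organ_index)))


def _patient_rng(spec: CohortSpec, patient_index: int):
    return np.random.default_rng(
        np.random.SeedSequence((spec.seed, 7, patient_index)))


def _organ_dvh(model: OrganDvhModel, volume_cc: float, shared: dict,
               arm: dict, grid: np.ndarray, structure: str) -> DVH:
    b = model.bath_fraction * shared["z_frac"]
    h = model.hot_fraction * shared["z_hot"] * arm["j_hot"]
    if b + h > 0.99:  # keep a valid DVH without wiping out either component
        scale = 0.99 / (b + h)
        b *= scale
        h *= scale
    lam = model.bath_scale * shared["z_scale"] * arm["j_scale"]
    mu = model.hot_center + shared["z_center"]
    # Weibull bath truncated at bath_max: no bath volume beyond the maximum
    # physically plausible dose (~ the prescription region)
    raw = np.exp(-np.power(grid / lam, model.bath_shape))
    tail = float(np.exp(-np.power(model.bath_max / lam, model.bath_shape)))
    surv = b * np.clip((raw - tail) / (1.0 - tail), 0.0, 1.0)
    if h > 0:
        surv = surv + h * ndtr((mu - grid) / model.hot_spread)
    vol = volume_cc * np.minimum(surv, 1.0)
    vol[0] = volume_cc                      # whole organ receives >= 0 Gy
    vol = np.minimum.accumulate(vol)
    return DVH(structure, "cumulative", grid, vol)


def _target_dvh(sigma: float, mu: float, volume_cc: float, trunc_q: float,
                grid: np.ndarray, structure: str) -> DVH:
    raw = ndtr((mu - grid) / sigma)
    surv = np.clip((raw - trunc_q) / (1.0 - 2.0 * trunc_q), 0.0, 1.0)
    vol = volume_cc * surv
    vol[0] = volume_cc
    vol = np.minimum.accumulate(vol)
    return DVH(structure, "cumulative", grid, vol)


def sample_patient(spec: CohortSpec, patient_index: int) -> Patient:
    """Generate one patient's paired plans (both techniques).

    Deterministic in ``(spec, patient_index)``: the same index always
    reproduces bit-identical DVHs.
    """
    grid = np.round(np.arange(0.0, spec.grid_max + spec.bin_width / 2,
                              spec.bin_width), 10)
    prng = _patient_rng(spec, patient_index)
    gtv = prng.uniform(*spec.gtv_range_cc)
    ctv = gtv * prng.uniform(*spec.ctv_over_gtv)
    ptv = ctv * prng.uniform(*spec.ptv_over_ctv)
    ctv95_frac = prng.uniform(*spec.ctv95_frac)
    presc = spec.scheme.total_dose

    organs = spec.organs
    organ_draws: dict[str, dict] = {}
    for j, organ in enumerate(organs):
        if organ == "stoduo":
            continue
        orng = _organ_rng(spec, patient_index, j)
        base_vol = spec.organ_volume_cc.get(organ, 100.0)
        shared = {
            "volume": base_vol * np.exp(orng.normal(0.0, spec.organ_volume_sd)),
            "z_scale": float(np.exp(orng.normal(
                0.0, OrganDvhModel._SCALE_VAR_DAMP
                * spec.organ_models[spec.techniques[0]][organ]
                .patient_variability))),
            "z_frac": float(np.exp(orng.normal(
                0.0, spec.organ_models[spec.techniques[0]][organ]
                .patient_variability))),
            "z_hot": float(np.exp(orng.normal(
                0.0, spec.organ_models[spec.techniques[0]][organ]
                .patient_variability))),
            "z_center": float(orng.normal(
                0.0, spec.organ_models[spec.techniques[0]][organ]
                .hot_center_sd)),
        }
        arms = {}
        for technique in spec.techniques:
            model = spec.organ_models[technique][organ]
            arms[technique] = {
                "j_scale": float(np.exp(orng.normal(0.0, model.arm_jitter))),
                "j_hot": float(np.exp(orng.normal(0.0, model.arm_jitter))),
            }
        organ_draws[organ] = {"shared": shared, "arms": arms}

    plans: dict[str, Plan] = {}
    for technique in spec.techniques:
        tmodel = spec.target_models[technique]
        mu_t = presc * (1.0 + prng.normal(0.0, 0.0015))
        sigma_ctv = tmodel.sigma_ctv * float(np.exp(prng.normal(0.0, 0.10)))
        dvhs: dict[str, DVH] = {
            "GTV": _target_dvh(sigma_ctv * tmodel.gtv_tighten, mu_t, gtv,
                               tmodel.trunc_q, grid, "GTV"),
            "CTV": _target_dvh(sigma_ctv, mu_t, ctv, tmodel.trunc_q, grid,
                               "CTV"),
        }
        for organ in organs:
            if organ == "stoduo":
                continue
            draw = organ_draws[organ]
            model = spec.organ_models[technique][organ]
            dvhs[organ] = _organ_dvh(model, draw["shared"]["volume"],
                                     draw["shared"], draw["arms"][technique],
                                     grid, organ)
        # composite stomach+duodenum contour: cumulative volumes add
        if "stomach" in dvhs and "duodenum" in dvhs:
            combined = dvhs["stomach"].volume_cc + dvhs["duodenum"].volume_cc
            dvhs["stoduo"] = DVH("stoduo", "cumulative", grid, combined)
        mult_mean, mult_sd = spec.v95_multiplier[technique]
        plans[technique] = Plan(
            technique=technique,
            dvhs=dvhs,
            prescription_gy=presc,
            fractions=spec.scheme.fractions,
            target_volumes_cc={"GTV": gtv, "CTV": ctv, "PTV": ptv},
            ctv95_cc=ctv * ctv95_frac,
            v95_body_cc=ctv * max(float(prng.normal(mult_mean, mult_sd)), 1.0),
        )
    return Patient(f"p{patient_index + 1}", plans)


def generate_cohort(spec: CohortSpec, out_dir=None) -> Cohort:
    """Generate the full paired cohort; optionally write DVH tables and a
    manifest to ``out_dir`` (see :func:`ntcpkit.io.write_cohort`)."""
    patients = [sample_patient(spec, i) for i in range(spec.n_patients)]
    cohort = Cohort(patients, meta={
        "generator": "ntcpkit.synthetic",
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "prescription_gy": spec.scheme.total_dose,
        "fractions": spec.scheme.fractions,
        "alpha_beta": spec.scheme.alpha_beta,
    })
    if out_dir is not None:
        from .io import write_cohort
        write_cohort(cohort, out_dir)
    return cohort
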