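"""Tabular DVH file I/O and cohort manifests.

DVH table dialect
-----------------
UTF-8 text.  Lines starting ``#`` are comments.  A header block of
``key: value`` lines declares at least ``structure`` and ``mode``
(``cumulative`` or ``differential``); optional keys are ``dose_unit``
(default Gy), ``volume_unit`` (``cc``, default, or ``percent``) and
``total_volume_cc`` (mandatory when volumes are in percent).  Unknown header
keys are preserved as opaque metadata.  The header is followed by two
whitespace- or comma-separated columns: dose, volume.  A ``dose,volume``
CSV header row before the data is accepted.  Several DVHs may share a file;
each new ``structure:`` key opens a new block.

Cohort manifest
---------------
One JSON or YAML document listing patients, each with
``technique -> structure -> DVH file path`` plus plan metadata
(``prescription_gy``, ``fractions``, target volumes, ``ctv95_cc``,
``v95_body_cc``).  Paths are resolved relative to the manifest file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .cohort import Cohort, Patient, Plan
from .dvh import DVH
from .errors import ParseError, ValidationError

__all__ = ["read_dvh_table", "write_dvh_table", "load_cohort", "write_cohort"]

_KNOWN_KEYS = {"structure", "mode", "dose_unit", "volume_unit", "total_volume_cc"}


def _finish_block(header: dict, rows: list[tuple[float, float]],
                  path: Path, line_no: int) -> DVH:
    for key in ("structure", "mode"):
        if key not in header:
            raise ParseError(
                f"{path}:{line_no}: DVH block is missing mandatory header {key!r}"
            )
    if not rows:
        raise ParseError(f"{path}:{line_no}: DVH block has no data rows")
    dose = np.array([r[0] for r in rows])
    vol = np.array([r[1] for r in rows])
    volume_unit = header.get("volume_unit", "cc")
    if volume_unit in ("percent", "%"):
        if "total_volume_cc" not in header:
            raise ParseError(
                f"{path}:{line_no}: percent volumes need total_volume_cc"
            )
        vol = vol / 100.0 * float(header["total_volume_cc"])
    elif volume_unit != "cc":
        raise ParseError(f"{path}:{line_no}: unknown volume_unit {volume_unit!r}")
    meta = {k: v for k, v in header.items() if k not in _KNOWN_KEYS}
    try:
        return DVH(str(header["structure"]), header["mode"], dose, vol, meta)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_dvh_table(path: str | Path) -> list[DVH]:
    """Parse every DVH block in a table file."""
    path = Path(path)
    dvhs: list[DVH] = []
    header: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line and not line.split(":", 1)[0].strip().replace(
                    ".", "").replace("-", "").isdigit():
                key, value = (part.strip() for part in line.split(":", 1))
                if key == "structure" and header.get("structure") is not None and rows:
                    dvhs.append(_finish_block(header, rows, path, line_no))
                    header, rows = {}, []
                header[key] = value
                continue
            fields = line.replace(",", " ").split()
            if fields[0].lower() in ("dose", "dose_gy"):
                continue  # CSV column-header row
            if len(fields) < 2:
                raise ParseError(f"{path}:{line_no}: expected two columns")
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: {exc}") from exc
    if header or rows:
        dvhs.append(_finish_block(header, rows, path, line_no if rows else 0))
    if not dvhs:
        raise ParseError(f"{path}: no DVH blocks found")
    return dvhs


def write_dvh_table(dvhs: Sequence[DVH] | DVH, path: str | Path) -> None:
    """Write DVHs in the table dialect; values survive a read bit-for-bit."""
    if isinstance(dvhs, DVH):
        dvhs = [dvhs]
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for k, dvh in enumerate(dvhs):
            if k:
                fh.write("\n")
            fh.write(f"structure: {dvh.structure}\n")
            fh.write(f"mode: {dvh.mode}\n")
            fh.write("dose_unit: Gy\n")
            fh.write("volume_unit: cc\n")
            fh.write(f"total_volume_cc: {dvh.total_volume_cc:.17g}\n")
            for key, value in dvh.metadata.items():
                fh.write(f"{key}: {value}\n")
            for d, v in zip(dvh.dose, dvh.volume_cc):
                fh.write(f"{d:.17g} {v:.17g}\n")


# ---------------------------------------------------------------------------
# cohort manifest


def _plan_from_record(rec: dict, base: Path) -> Plan:
    dvhs: dict[str, DVH] = {}
    for structure, rel in rec.get("dvh_files", {}).items():
        found = read_dvh_table(base / rel)
        match = [d for d in found if d.structure == structure] or found
        dvhs[structure] = match[0]
    return Plan(
        technique=rec["technique"],
        dvhs=dvhs,
        prescription_gy=float(rec.get("prescription_gy", 59.4)),
        fractions=int(rec.get("fractions", 33)),
        target_volumes_cc={k: float(v)
                           for k, v in rec.get("target_volumes_cc", {}).items()},
        ctv95_cc=None if rec.get("ctv95_cc") is None else float(rec["ctv95_cc"]),
        v95_body_cc=(None if rec.get("v95_body_cc") is None
                     else float(rec["v95_body_cc"])),
    )


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Read a JSON/YAML cohort manifest and every DVH file it references."""
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text(encoding="utf-8")
    if manifest_path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "patients" not in doc:
        raise ParseError(f"{manifest_path}: manifest must contain 'patients'")
    base = manifest_path.parent
    patients = []
    for prec in doc["patients"]:
        plans: dict[str, Plan] = {}
        for technique, rec in prec["plans"].items():
            rec = dict(rec)
            rec.setdefault("technique", technique)
            plans[technique] = _plan_from_record(rec, base)
        patients.append(Patient(str(prec["id"]), plans))
    return Cohort(patients, meta=doc.get("meta", {}))


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 manifest_format: str = "json") -> Path:
    """Write one DVH file per patient/technique plus a manifest.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc: dict = {"meta": cohort.meta, "patients": []}
    for patient in cohort.patients:
        prec: dict = {"id": patient.patient_id, "plans": {}}
        for technique, plan in patient.plans.items():
            fname = f"{patient.patient_id}_{technique}.dvh"
            write_dvh_table(list(plan.dvhs.values()), out_dir / fname)
            prec["plans"][technique] = {
                "technique": technique,
                "dvh_files": {s: fname for s in plan.dvhs},
                "prescription_gy": plan.prescription_gy,
                "fractions": plan.fractions,
                "target_volumes_cc": plan.target_volumes_cc,
                "ctv95_cc": plan.ctv95_cc,
                "v95_body_cc": plan.v95_body_cc,
            }
        doc["patients"].append(prec)
    if manifest_format == "json":
        manifest = out_dir / "manifest.json"
        manifest.write_text(json.dumps(doc, indent=2, sort_keys=True),
                            encoding="utf-8")
    else:
        manifest = out_dir / "manifest.yaml"
        manifest.write_text(yaml.safe_dump(doc, sort_keys=True),
                            encoding="utf-8")
    return manifest
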