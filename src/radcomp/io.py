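"""Reading and writing DVHs in a plain-text tabular dialect.

A DVH file is a header block of ``# key: value`` lines followed by a
two-column table (dose, volume).  Comma- and whitespace-delimited
tables are both accepted, with or without a column-name line.
Cumulative volumes may be given as fractions or percentages (the
``volume_unit`` header says which; ``percent`` exports are rescaled on
read).

Example::

    # patient_id: P007
    # structure: left lung
    # organ: lung
    # algorithm: AAA
    # dvh_type: differential
    # dose_unit: Gy
    # volume_unit: relative
    # n_fractions: 25
    # prescription_dose: 50.0
    dose,volume
    0.125,0.52
    0.375,0.11
    ...

For differential DVHs the dose column holds bin centres on a uniform
grid; for cumulative DVHs it holds the curve's sample doses.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dvh import (
    CumulativeDVH,
    DifferentialDVH,
    DVHError,
    FractionationScheme,
    StructureDVH,
)

_HEADER_RE = re.compile(r"^#\s*([A-Za-z_][\w ]*?)\s*:\s*(.*?)\s*$")


@dataclass
class DVHRecord:
    """One parsed DVH file: the structure plus its plan metadata."""

    structure: StructureDVH
    patient_id: str | None = None
    algorithm_tag: str | None = None
    site: str | None = None
    fractionation: FractionationScheme | None = None


def _parse_table(lines: list[str]) -> np.ndarray:
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        try:
            rows.append([float(parts[0]), float(parts[1])])
        except (ValueError, IndexError):
            if rows:
                raise DVHError(f"malformed DVH table line: {line!r}")
            # tolerate a column-name line before the first data row
            continue
    if not rows:
        raise DVHError("no data rows found in DVH table")
    return np.asarray(rows, dtype=float)


def loads(text: str) -> DVHRecord:
    """Parse a DVH record from text."""
    header: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        m = _HEADER_RE.match(line)
        if m and not body:
            header[m.group(1).strip().lower().replace(" ", "_")] = m.group(2)
        else:
            body.append(line)
    table = _parse_table(body)
    dose, vol = table[:, 0], table[:, 1]

    dvh_type = header.get("dvh_type", "cumulative").lower()
    volume_unit = header.get("volume_unit", "relative").lower()
    if volume_unit in {"percent", "%"}:
        vol = vol / 100.0
        volume_unit = "relative"

    abs_volume = None
    if volume_unit in {"cm3", "cc", "cm^3"}:
        abs_volume = float(vol.sum()) if dvh_type == "differential" else float(vol[0])
        vol = vol / (abs_volume if abs_volume > 0 else 1.0)
    elif dvh_type == "cumulative" and vol[0] > 1.5:
        # unlabelled cumulative export in percent
        vol = vol / vol[0]

    if dvh_type == "differential":
        step = float(np.median(np.diff(dose))) if dose.size > 1 else 2 * dose[0]
        edges = np.concatenate((dose - step / 2, [dose[-1] + step / 2]))
        dvh: DifferentialDVH | CumulativeDVH = DifferentialDVH(edges, vol)
    elif dvh_type == "cumulative":
        if dose[0] > 0:
            dose = np.concatenate(([0.0], dose))
            vol = np.concatenate(([vol[0]], vol))
        dvh = CumulativeDVH(dose, vol)
    else:
        raise DVHError(f"unknown dvh_type {dvh_type!r}")

    structure = StructureDVH(
        structure_name=header.get("structure", "structure"),
        organ_label=header.get("organ", header.get("organ_label", "PTV")),
        dvh=dvh,
        absolute_volume=abs_volume,
        volume_convention=header.get("volume_convention"),
    )
    frac = None
    if "n_fractions" in header and "prescription_dose" in header:
        frac = FractionationScheme(
            n_fractions=int(float(header["n_fractions"])),
            prescription_dose=float(header["prescription_dose"]),
        )
    return DVHRecord(
        structure=structure,
        patient_id=header.get("patient_id"),
        algorithm_tag=header.get("algorithm"),
        site=header.get("site"),
        fractionation=frac,
    )


def read_dvh(path: str | Path) -> DVHRecord:
    return loads(Path(path).read_text())


def dumps(record: DVHRecord) -> str:
    """Serialize a DVH record to the text dialect (CSV table)."""
    s = record.structure
    buf = _io.StringIO()
    if record.patient_id:
        buf.write(f"# patient_id: {record.patient_id}\n")
    buf.write(f"# structure: {s.structure_name}\n")
    buf.write(f"# organ: {s.organ_label}\n")
    if record.algorithm_tag:
        buf.write(f"# algorithm: {record.algorithm_tag}\n")
    if record.site:
        buf.write(f"# site: {record.site}\n")
    if record.fractionation is not None:
        buf.write(f"# n_fractions: {record.fractionation.n_fractions}\n")
        buf.write(f"# prescription_dose: {record.fractionation.prescription_dose}\n")
    if s.volume_convention:
        buf.write(f"# volume_convention: {s.volume_convention}\n")
    buf.write("# dose_unit: Gy\n# volume_unit: relative\n")
    if isinstance(s.dvh, DifferentialDVH):
        buf.write("# dvh_type: differential\ndose,volume\n")
        for d, v in zip(s.dvh.bin_centers, s.dvh.volumes):
            buf.write(f"{d:.6f},{v:.10g}\n")
    else:
        buf.write("# dvh_type: cumulative\ndose,volume\n")
        for d, v in zip(s.dvh.doses, s.dvh.volumes):
            buf.write(f"{d:.6f},{v:.10g}\n")
    return buf.getvalue()


def write_dvh(record: DVHRecord, path: str | Path) -> None:
    Path(path).write_text(dumps(record))
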