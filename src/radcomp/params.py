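"""Built-in library of published NTCP model parameter sets.

The library ships as a human-readable YAML file
(``radcomp/data/ntcp_parameters.yaml``) holding, for each published
parameterization: the model (LKB or relative seriality), the organ and
toxicity endpoint, the citation label, the numeric parameters, and any
volume-convention note (e.g. "rectal wall" versus "solid rectum
including filling").  Users can point :func:`load` at their own file
with the same schema to extend the library without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .dvh import ORGAN_LABELS
from .radiobiology import LKBParams, RSParams

_BUILTIN_RESOURCE = "ntcp_parameters.yaml"


@dataclass(frozen=True)
class NTCPParameterSet:
    """One published NTCP model/parameter combination."""

    model: str  # "LKB" or "RS"
    organ: str
    endpoint: str
    source: str
    params: LKBParams | RSParams
    note: str = ""
    variant: str = ""
    dose_engine_basis: str = ""  # EPL / CS where the source states it

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.model, self.organ, self.endpoint, self.source, self.variant)

    @property
    def label(self) -> str:
        v = f" ({self.variant})" if self.variant else ""
        return f"{self.source}{v} [{self.model}]"


def _from_record(rec: dict) -> NTCPParameterSet:
    model = rec["model"].upper()
    raw = rec["params"]
    if model == "LKB":
        params: LKBParams | RSParams = LKBParams(
            n=float(raw["n"]), D50=float(raw["D50"]), m=float(raw["m"])
        )
    elif model == "RS":
        params = RSParams(
            gamma=float(raw["gamma"]), D50=float(raw["D50"]), s=float(raw["s"])
        )
    else:
        raise ValueError(f"unknown NTCP model {rec['model']!r}")
    organ = rec["organ"]
    if organ not in ORGAN_LABELS:
        raise ValueError(f"unknown organ label {organ!r} in parameter file")
    return NTCPParameterSet(
        model=model,
        organ=organ,
        endpoint=rec["endpoint"],
        source=rec["source"],
        params=params,
        note=rec.get("note") or "",
        variant=str(rec.get("variant") or ""),
        dose_engine_basis=rec.get("dose_engine_basis") or "",
    )


def load(path: str | Path) -> list[NTCPParameterSet]:
    """Load a parameter library from a YAML file (documented schema)."""
    data = yaml.safe_load(Path(path).read_text())
    sets = [_from_record(rec) for rec in data["parameter_sets"]]
    keys = [s.key for s in sets]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (model, organ, endpoint, source, variant) keys")
    return sets


def load_builtin() -> list[NTCPParameterSet]:
    """All parameter sets shipped with the package.

    6 heart + 8 lung + 3 parotid + 7 rectum + 1 femoral head = 25 sets.
    """
    ref = resources.files("radcomp.data").joinpath(_BUILTIN_RESOURCE)
    with resources.as_file(ref) as path:
        return load(path)


def query(
    organ: str,
    endpoint: str | None = None,
    model: str | None = None,
    source: str | None = None,
    sets: list[NTCPParameterSet] | None = None,
) -> list[NTCPParameterSet]:
    """Filter parameter sets by organ and, optionally, endpoint/model/source.

    Raises ``KeyError`` for an organ label outside the registry; an
    empty list simply means nothing matched the other filters.
    """
    if organ not in ORGAN_LABELS:
        raise KeyError(f"unknown organ label {organ!r}")
    if sets is None:
        sets = load_builtin()
    out = [s for s in sets if s.organ == organ]
    if endpoint is not None:
        out = [s for s in out if s.endpoint.lower() == endpoint.lower()]
    if model is not None:
        out = [s for s in out if s.model == model.upper()]
    if source is not None:
        out = [s for s in out if s.source.lower() == source.lower()]
    return out


def check_volume_convention(pset: NTCPParameterSet, structure_convention: str | None) -> None:
    """Warn when a structure's volume convention disagrees with the set's note."""
    if not structure_convention or not pset.note:
        return
    if structure_convention.lower() not in pset.note.lower():
        warnings.warn(
            f"volume convention mismatch: parameters {pset.label} expect "
            f"{pset.note!r} but structure is {structure_convention!r}",
            stacklevel=2,
        )
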