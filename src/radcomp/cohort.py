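"""Seeded generator of paired per-patient DVH sets.

Each synthetic patient gets two plans computed from one shared latent
draw: a "PBC-like" plan and an "AAA-like" plan obtained by applying a
deterministic algorithm effect to the same latent patient, so the
paired design has the positive within-pair correlation a paired t-test
assumes.

Structure DVHs come from two shape families:

``target_gaussian``
    A unimodal near-Gaussian dose peak for PTV/CTV-like targets
    (mean dose and spread in Gy).

``oar_shoulder``
    A two-component organ-at-risk histogram: an irradiated fraction of
    the volume near a shoulder dose (the high-dose region abutting the
    target) and the remainder in a low-dose bath.

The algorithm effect moves the AAA-like plan relative to PBC-like:
a target mean-dose shift and spread inflation (broadened penumbra,
reduced near-minimum target dose), a shift of the organ-at-risk
high-dose shoulder, and a change of the irradiated volume fraction.
Positive values denote an AAA-like increase.

The packaged site templates (breast, lung, head_and_neck, prostate)
emulate the direction and rough magnitude of published mean PBC-vs-AAA
differences; they are not patient-level reconstructions of any real
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.special import ndtr

from .dvh import (
    DEFAULT_STEP,
    DifferentialDVH,
    FractionationScheme,
    PlanDVHSet,
    StructureDVH,
    normalize_volumes,
)


@dataclass(frozen=True)
class StructureShape:
    """Parametric DVH shape for one structure."""

    model: str  # "target_gaussian" | "oar_shoulder"
    mean_dose: float = 0.0  # target_gaussian: peak mean in Gy
    spread: float = 0.0  # target_gaussian: peak sd in Gy
    irradiated_fraction: float = 0.0  # oar_shoulder: volume near the shoulder
    shoulder_dose: float = 0.0  # oar_shoulder: high-dose component mean, Gy
    shoulder_width: float = 0.0  # oar_shoulder: high-dose component sd, Gy
    low_dose_bath: float = 0.0  # oar_shoulder: bath component mean, Gy
    bath_width: float = 1.5  # oar_shoulder: bath component sd, Gy

    def __post_init__(self):
        if self.model not in {"target_gaussian", "oar_shoulder"}:
            raise ValueError(f"unknown shape model {self.model!r}")
        for name in ("mean_dose", "spread", "shoulder_dose", "shoulder_width",
                     "low_dose_bath", "bath_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.irradiated_fraction <= 1:
            raise ValueError("irradiated_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AlgorithmEffect:
    """Deterministic AAA-minus-PBC difference applied to a latent patient.

    Sign convention: positive = AAA-like increase.
    """

    target_mean_shift: float = 0.0  # Gy
    target_spread_inflation: float = 1.0  # multiplicative
    oar_hot_tail_shift: float = 0.0  # Gy, applied to the shoulder dose
    oar_mid_volume_shift: float = 0.0  # added to irradiated_fraction

    def is_null(self) -> bool:
        return (
            self.target_mean_shift == 0.0
            and self.target_spread_inflation == 1.0
            and self.oar_hot_tail_shift == 0.0
            and self.oar_mid_volume_shift == 0.0
        )


@dataclass(frozen=True)
class TemplateStructure:
    """One structure of a site template."""

    name: str
    organ_label: str
    shape: StructureShape
    effect: AlgorithmEffect | None = None  # None -> cohort default
    volume_convention: str | None = None


@dataclass
class CohortConfig:
    """Configuration of a paired synthetic cohort."""

    site: str
    n_patients: int
    seed: int
    structures: list[TemplateStructure]
    fractionation: FractionationScheme
    default_effect: AlgorithmEffect = field(default_factory=AlgorithmEffect)
    # relative inter-patient sd per shape-parameter group
    variability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("a paired cohort needs at least 2 patients")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


_DEFAULT_VARIABILITY = {
    "target_mean": 0.02,
    "target_spread": 0.10,
    "oar_fraction": 0.15,
    "oar_shoulder": 0.04,
    "oar_bath": 0.10,
}


def _gauss_bin(mean: float, sd: float, step: float) -> DifferentialDVH:
    """Bin a (clipped) Gaussian dose component onto the canonical grid."""
    mean = max(mean, step)
    if sd < step / 20:
        # degenerate spread: all volume at one dose
        edges = np.array([mean - step / 2, mean + step / 2])
        return DifferentialDVH(edges, np.array([1.0]))
    hi = mean + 6 * sd
    n_bins = int(np.ceil(hi / step)) + 1
    edges = step * np.arange(n_bins + 1)
    z = (edges - mean) / sd
    cdf = ndtr(z)
    vols = np.diff(cdf)
    vols[0] += cdf[0]  # mass below zero dose folded into the first bin
    return DifferentialDVH(edges, vols)


def _mix(components: list[tuple[float, DifferentialDVH]], step: float) -> DifferentialDVH:
    hi = max(c.bin_edges[-1] for _, c in components)
    n_bins = int(round(hi / step))
    edges = step * np.arange(n_bins + 1)
    vols = np.zeros(n_bins)
    for w, c in components:
        k = c.volumes.size
        # component grids share the origin-aligned canonical grid
        if abs(c.bin_edges[0]) < 1e-9:
            vols[:k] += w * c.volumes
        else:  # single-bin degenerate component, not grid aligned
            center = 0.5 * (c.bin_edges[0] + c.bin_edges[1])
            idx = min(int(center / step), n_bins - 1)
            vols[idx] += w
    return normalize_volumes(DifferentialDVH(edges, vols))


def generate_structure_dvh(
    shape: StructureShape, rng: np.random.Generator | None = None,
    step: float = DEFAULT_STEP,
) -> DifferentialDVH:
    """Realize a normalized differential DVH from a structure shape.

    The construction is deterministic given the shape; ``rng`` is
    accepted for interface symmetry and future stochastic families.
    """
    if shape.model == "target_gaussian":
        if shape.spread < step / 20:
            return _gauss_bin(shape.mean_dose, 0.0, step)
        return _mix([(1.0, _gauss_bin(shape.mean_dose, shape.spread, step))], step)
    f = shape.irradiated_fraction
    comps = []
    if f > 0:
        comps.append((f, _gauss_bin(shape.shoulder_dose, shape.shoulder_width, step)))
    if f < 1:
        comps.append((1 - f, _gauss_bin(shape.low_dose_bath, shape.bath_width, step)))
    return _mix(comps, step)


def _perturb(shape: StructureShape, rng: np.random.Generator,
             var: dict[str, float]) -> StructureShape:
    """Draw one latent patient's structure shape around the template."""
    v = {**_DEFAULT_VARIABILITY, **var}

    def rel(x: float, key: str, floor: float = 0.0) -> float:
        if x == 0:
            return 0.0
        z = np.clip(rng.standard_normal(), -3, 3)
        return max(x * (1.0 + v[key] * z), floor)

    if shape.model == "target_gaussian":
        return replace(
            shape,
            mean_dose=rel(shape.mean_dose, "target_mean", 1.0),
            spread=rel(shape.spread, "target_spread"),
        )
    frac = float(np.clip(
        shape.irradiated_fraction
        * (1.0 + v["oar_fraction"] * np.clip(rng.standard_normal(), -3, 3)),
        0.002, 0.98,
    ))
    return replace(
        shape,
        irradiated_fraction=frac,
        shoulder_dose=rel(shape.shoulder_dose, "oar_shoulder", 1.0),
        low_dose_bath=rel(shape.low_dose_bath, "oar_bath"),
    )


def _apply_effect(shape: StructureShape, eff: AlgorithmEffect) -> StructureShape:
    if shape.model == "target_gaussian":
        return replace(
            shape,
            mean_dose=max(shape.mean_dose + eff.target_mean_shift, 1.0),
            spread=shape.spread * eff.target_spread_inflation,
        )
    return replace(
        shape,
        shoulder_dose=max(shape.shoulder_dose + eff.oar_hot_tail_shift, 1.0),
        irradiated_fraction=float(
            np.clip(shape.irradiated_fraction + eff.oar_mid_volume_shift, 0.002, 0.98)
        ),
    )


def generate_paired_cohort(
    cfg: CohortConfig,
) -> list[tuple[PlanDVHSet, PlanDVHSet]]:
    """Generate ``(PBC plan, AAA plan)`` pairs for every patient.

    Per-patient random substreams are derived from the master seed by
    patient counter, so growing the cohort never reshuffles earlier
    patients; the same seed always reproduces the same cohort.
    """
    pairs = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,))
        )
        pid = f"{cfg.site}-{i + 1:03d}"
        pbc_structs, aaa_structs = [], []
        for tmpl in cfg.structures:
            latent = _perturb(tmpl.shape, rng, cfg.variability)
            eff = tmpl.effect if tmpl.effect is not None else cfg.default_effect
            pbc_structs.append(
                StructureDVH(
                    tmpl.name, tmpl.organ_label, generate_structure_dvh(latent),
                    volume_convention=tmpl.volume_convention,
                )
            )
            aaa_structs.append(
                StructureDVH(
                    tmpl.name, tmpl.organ_label,
                    generate_structure_dvh(_apply_effect(latent, eff)),
                    volume_convention=tmpl.volume_convention,
                )
            )
        pairs.append(
            (
                PlanDVHSet(pid, "PBC", pbc_structs, cfg.fractionation, cfg.site),
                PlanDVHSet(pid, "AAA", aaa_structs, cfg.fractionation, cfg.site),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# packaged site templates
# ---------------------------------------------------------------------------


def _breast(n_patients: int, seed: int) -> CohortConfig:
    return CohortConfig(
        site="breast",
        n_patients=n_patients,
        seed=seed,
        fractionation=FractionationScheme(25, 50.0),
        structures=[
            TemplateStructure(
                "PTV", "PTV", StructureShape("target_gaussian", mean_dose=50.4, spread=0.94)
            ),
            TemplateStructure(
                "CTV", "CTV", StructureShape("target_gaussian", mean_dose=50.6, spread=0.75)
            ),
            TemplateStructure(
                "left lung", "lung",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.06, shoulder_dose=46.0,
                    shoulder_width=1.5, low_dose_bath=1.4, bath_width=1.5,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=-3.9, oar_mid_volume_shift=0.05),
            ),
            TemplateStructure(
                "heart", "heart",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.04, shoulder_dose=36.0,
                    shoulder_width=6.0, low_dose_bath=1.2, bath_width=1.0,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=0.2, oar_mid_volume_shift=0.012),
            ),
        ],
        default_effect=AlgorithmEffect(target_mean_shift=-1.2, target_spread_inflation=1.26),
        variability={"target_mean": 0.013, "oar_fraction": 0.25},
    )


def _lung(n_patients: int, seed: int) -> CohortConfig:
    return CohortConfig(
        site="lung",
        n_patients=n_patients,
        seed=seed,
        fractionation=FractionationScheme(30, 60.0),
        structures=[
            TemplateStructure(
                "PTV", "PTV", StructureShape("target_gaussian", mean_dose=60.5, spread=1.47)
            ),
            TemplateStructure(
                "CTV", "CTV", StructureShape("target_gaussian", mean_dose=60.7, spread=1.2)
            ),
            TemplateStructure(
                "lung-CTV", "lung",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.30, shoulder_dose=50.0,
                    shoulder_width=8.0, low_dose_bath=4.0, bath_width=3.0,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=-3.6, oar_mid_volume_shift=-0.005),
            ),
        ],
        default_effect=AlgorithmEffect(target_mean_shift=-1.8, target_spread_inflation=1.19),
        variability={"target_mean": 0.006, "oar_fraction": 0.40},
    )


def _head_and_neck(n_patients: int, seed: int) -> CohortConfig:
    return CohortConfig(
        site="head_and_neck",
        n_patients=n_patients,
        seed=seed,
        # simultaneous-integrated-boost scheme: 2.12 Gy/fraction, so the
        # pipeline's EQD2 correction is exercised
        fractionation=FractionationScheme(33, 69.96),
        structures=[
            TemplateStructure(
                "PTV", "PTV", StructureShape("target_gaussian", mean_dose=64.3, spread=1.04)
            ),
            TemplateStructure(
                "CTV", "CTV", StructureShape("target_gaussian", mean_dose=64.5, spread=0.9)
            ),
            TemplateStructure(
                "parotid glands", "parotid",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.55, shoulder_dose=60.0,
                    shoulder_width=6.0, low_dose_bath=8.0, bath_width=4.0,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=-1.5, oar_mid_volume_shift=-0.005),
            ),
        ],
        default_effect=AlgorithmEffect(target_mean_shift=-2.2, target_spread_inflation=1.13),
        variability={"target_mean": 0.05, "oar_fraction": 0.11},
    )


def _prostate(n_patients: int, seed: int) -> CohortConfig:
    return CohortConfig(
        site="prostate",
        n_patients=n_patients,
        seed=seed,
        fractionation=FractionationScheme(38, 76.0),
        structures=[
            TemplateStructure(
                "PTV", "PTV", StructureShape("target_gaussian", mean_dose=77.4, spread=0.67)
            ),
            TemplateStructure(
                "CTV", "CTV", StructureShape("target_gaussian", mean_dose=77.5, spread=0.6)
            ),
            TemplateStructure(
                "rectum", "rectum",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.35, shoulder_dose=74.0,
                    shoulder_width=3.0, low_dose_bath=28.0, bath_width=12.0,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=-2.7, oar_mid_volume_shift=0.01),
                volume_convention="solid rectum including filling",
            ),
            TemplateStructure(
                "femoral heads", "femoral_head",
                StructureShape(
                    "oar_shoulder", irradiated_fraction=0.65, shoulder_dose=47.0,
                    shoulder_width=5.0, low_dose_bath=18.0, bath_width=6.0,
                ),
                effect=AlgorithmEffect(oar_hot_tail_shift=0.7),
            ),
        ],
        default_effect=AlgorithmEffect(target_mean_shift=-0.9, target_spread_inflation=1.0),
        variability={"target_mean": 0.02, "oar_fraction": 0.15},
    )


SITE_TEMPLATES = {
    "breast": _breast,
    "lung": _lung,
    "head_and_neck": _head_and_neck,
    "prostate": _prostate,
}


def site_template(site: str, n_patients: int = 20, seed: int = 0) -> CohortConfig:
    """Packaged cohort configuration for one of the four treatment sites."""
    try:
        return SITE_TEMPLATES[site](n_patients, seed)
    except KeyError:
        raise KeyError(
            f"unknown site {site!r}; available: {sorted(SITE_TEMPLATES)}"
        ) from None


def iter_all_sites(n_patients: int = 20, seed: int = 0) -> Iterator[CohortConfig]:
    for site in ("breast", "lung", "head_and_neck", "prostate"):
        yield site_template(site, n_patients, seed)
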