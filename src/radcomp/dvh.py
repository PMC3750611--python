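"""Dose-volume histogram data model and dose-volume indices.

Two in-memory forms are used throughout the package:

``DifferentialDVH``
    Uniform-width dose bins (default 0.25 Gy) with the relative volume
    fraction deposited in each bin.  The dose of a bin is its centre.
    This is the canonical input of every radiobiological operation.

``CumulativeDVH``
    A sampled curve of "fraction of the structure receiving at least
    dose d".  Dose-volume indices (D2%, D95%, V20, ...) are read off
    this curve by linear interpolation.

Conversion between the two treats each differential bin's volume as
concentrated at the bin centre: the cumulative curve drops (almost)
vertically at each occupied centre, so a structure irradiated to a
single uniform dose has D2% = D95% = Dmedian and an inhomogeneity
index of zero, as it must.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

#: canonical differential-DVH bin width in Gy
DEFAULT_STEP = 0.25

#: half-width in Gy of the "vertical" drop used when sampling the
#: cumulative staircase of a differential DVH (strictly increasing dose
#: samples are required, so a true step cannot be represented exactly)
_DROP_HALF_WIDTH = 5e-10

_NORM_TOL = 1e-9


class DVHError(ValueError):
    """Raised for invalid DVH data or operations on it."""


@dataclass(frozen=True)
class DifferentialDVH:
    """Binned differential DVH with uniform bin width.

    Parameters
    ----------
    bin_edges : ndarray, shape (n_bins + 1,)
        Strictly increasing dose edges in Gy, uniform spacing.
    volumes : ndarray, shape (n_bins,)
        Non-negative relative volume per bin.  A *normalized* DVH has
        volumes summing to one.
    """

    bin_edges: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "volumes", vols)
        if edges.ndim != 1 or edges.size < 2:
            raise DVHError("bin_edges must be a 1-d array with at least two edges")
        if vols.shape != (edges.size - 1,):
            raise DVHError("volumes must have one entry per bin")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise DVHError("bin_edges must be strictly increasing")
        if np.ptp(widths) > 1e-12:
            raise DVHError("bin width must be uniform within 1e-12 Gy")
        if np.any(vols < 0):
            raise DVHError("bin volumes must be non-negative")
        if edges[0] < -1e-12:
            raise DVHError("dose cannot be negative")

    @property
    def step(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.total_volume - 1.0) <= _NORM_TOL

    def require_normalized(self, op: str) -> None:
        if not self.is_normalized:
            raise DVHError(
                f"{op} requires a normalized DVH (volumes summing to 1); "
                f"total volume is {self.total_volume:.6g}"
            )

    def max_dose(self) -> float:
        """Centre dose of the highest occupied bin (0 if empty)."""
        occ = np.nonzero(self.volumes > 0)[0]
        if occ.size == 0:
            return 0.0
        return float(self.bin_centers[occ[-1]])


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: fraction of volume receiving at least each dose.

    ``doses`` are strictly increasing Gy values starting at 0 and
    ``volumes`` are the corresponding relative volumes (1 at dose 0),
    non-increasing in dose.  Between samples the curve is linear.
    """

    doses: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "volumes", v)
        if d.ndim != 1 or d.shape != v.shape or d.size < 2:
            raise DVHError("doses and volumes must be matching 1-d arrays (n >= 2)")
        if np.any(np.diff(d) <= 0):
            raise DVHError("cumulative doses must be strictly increasing")
        if abs(d[0]) > 1e-12:
            raise DVHError("cumulative DVH must start at dose 0")
        if np.any(np.diff(v) > 1e-12):
            raise DVHError("cumulative volumes must be non-increasing")
        if abs(v[0] - 1.0) > _NORM_TOL:
            raise DVHError("relative cumulative DVH must have volume 1 at dose 0")


@dataclass(frozen=True)
class FractionationScheme:
    """Number of fractions and total prescription dose in Gy."""

    n_fractions: int
    prescription_dose: float

    def __post_init__(self):
        if self.n_fractions < 1 or int(self.n_fractions) != self.n_fractions:
            raise DVHError("n_fractions must be a positive integer")
        if self.prescription_dose <= 0:
            raise DVHError("prescription_dose must be positive")

    @property
    def fraction_dose(self) -> float:
        return self.prescription_dose / self.n_fractions


#: controlled vocabulary shared with the parameter library
ORGAN_LABELS = frozenset(
    {
        "PTV",
        "CTV",
        "lung",
        "lung_left",
        "lung_right",
        "heart",
        "parotid",
        "rectum",
        "femoral_head",
    }
)


@dataclass
class StructureDVH:
    """A named anatomical structure with its DVH."""

    structure_name: str
    organ_label: str
    dvh: DifferentialDVH | CumulativeDVH
    absolute_volume: float | None = None  # cm^3, metadata only
    volume_convention: str | None = None  # e.g. "rectal wall"

    def __post_init__(self):
        if self.organ_label not in ORGAN_LABELS:
            raise DVHError(
                f"unknown organ label {self.organ_label!r}; "
                f"known labels: {sorted(ORGAN_LABELS)}"
            )

    def differential(self) -> DifferentialDVH:
        if isinstance(self.dvh, DifferentialDVH):
            return self.dvh
        return cumulative_to_differential(self.dvh)

    def cumulative(self) -> CumulativeDVH:
        if isinstance(self.dvh, CumulativeDVH):
            return self.dvh
        return differential_to_cumulative(normalize_volumes(self.dvh))


Site = Literal["breast", "lung", "head_and_neck", "prostate"]


@dataclass
class PlanDVHSet:
    """All structure DVHs of one plan (one patient, one dose algorithm)."""

    patient_id: str
    algorithm_tag: str
    structures: list[StructureDVH] = field(default_factory=list)
    fractionation: FractionationScheme | None = None
    site: str | None = None

    def __post_init__(self):
        names = [s.structure_name for s in self.structures]
        if len(names) != len(set(names)):
            raise DVHError("structure names must be unique within a plan")

    def structure(self, name: str) -> StructureDVH:
        for s in self.structures:
            if s.structure_name == name:
                return s
        raise KeyError(name)

    def by_label(self, organ_label: str) -> list[StructureDVH]:
        return [s for s in self.structures if s.organ_label == organ_label]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_volumes(dvh: DifferentialDVH) -> DifferentialDVH:
    """Scale bin volumes to sum to one.

    Raises
    ------
    DVHError
        If the total volume is zero ("empty structure").
    """
    total = dvh.total_volume
    if total <= 0:
        raise DVHError("empty structure: total volume is zero")
    return replace(dvh, volumes=dvh.volumes / total)


def differential_to_cumulative(dvh: DifferentialDVH) -> CumulativeDVH:
    """Sample the cumulative curve of a normalized differential DVH.

    Each bin's volume is treated as concentrated at the bin centre; the
    curve drops near-vertically there.  The cumulative volume at a
    bin's lower edge equals the sum of that bin's volume and all higher
    bins', and the curve is 1 at dose 0 and 0 beyond the last occupied
    centre.
    """
    dvh.require_normalized("differential_to_cumulative")
    occ = np.nonzero(dvh.volumes > 0)[0]
    if occ.size == 0:  # cannot happen for a normalized DVH
        raise DVHError("empty structure")
    centers = dvh.bin_centers[occ]
    vols = dvh.volumes[occ]
    # tail sums: volume at-or-above each occupied centre (incl. its own mass)
    tail_incl = np.cumsum(vols[::-1])[::-1]
    tail_excl = tail_incl - vols
    h = _DROP_HALF_WIDTH
    doses = np.empty(2 * occ.size, dtype=float)
    volumes = np.empty_like(doses)
    doses[0::2] = centers - h
    doses[1::2] = centers + h
    volumes[0::2] = tail_incl
    volumes[1::2] = tail_excl
    if doses[0] > 0:
        doses = np.concatenate(([0.0], doses))
        volumes = np.concatenate(([1.0], volumes))
    else:  # first centre within h of zero: start the curve at 0 directly
        doses[0] = 0.0
        volumes[0] = 1.0
    return CumulativeDVH(doses=doses, volumes=volumes)


def cumulative_to_differential(
    cdvh: CumulativeDVH, step: float = DEFAULT_STEP
) -> DifferentialDVH:
    """Bin the dose distribution implied by a cumulative curve.

    The piecewise-linear cumulative curve implies a dose distribution
    whose mass between two samples equals the drop in cumulative
    volume, spread uniformly over the dose interval.  That mass is
    assigned to uniform bins of width ``step`` (aligned to multiples of
    the step) by overlap proportion, so the round trip with
    :func:`differential_to_cumulative` is exact for grid-aligned DVHs.
    """
    if step <= 0:
        raise DVHError("step must be positive")
    d, v = cdvh.doses, cdvh.volumes
    seg_mass = -np.diff(v)  # >= 0 by the monotonicity invariant
    lo = np.floor(d[0] / step + 1e-12) * step
    n_bins = int(np.ceil((d[-1] - lo) / step - 1e-12))
    n_bins = max(n_bins, 1)
    edges = lo + step * np.arange(n_bins + 1)
    vols = np.zeros(n_bins)
    for a, b, m in zip(d[:-1], d[1:], seg_mass):
        if m <= 0:
            continue
        _deposit_uniform(vols, edges, a, b, m)
    # mass sitting exactly at the terminal sample (curve ends above zero)
    if v[-1] > 0:
        _deposit_uniform(vols, edges, d[-1], d[-1], v[-1])
    return DifferentialDVH(bin_edges=edges, volumes=vols)


def _deposit_uniform(vols: np.ndarray, edges: np.ndarray, a: float, b: float, mass: float) -> None:
    """Spread ``mass`` uniformly over dose interval [a, b] onto bins."""
    n = vols.size
    if b <= a:  # point mass
        k = min(int(np.searchsorted(edges, a, side="right")) - 1, n - 1)
        vols[max(k, 0)] += mass
        return
    width = b - a
    k0 = max(int(np.searchsorted(edges, a, side="right")) - 1, 0)
    k1 = min(int(np.searchsorted(edges, b, side="left")) - 1, n - 1)
    for k in range(k0, k1 + 1):
        overlap = min(b, edges[k + 1]) - max(a, edges[k])
        if overlap > 0:
            vols[k] += mass * overlap / width


def rebin(dvh: DifferentialDVH, step: float) -> DifferentialDVH:
    """Re-grid a differential DVH to a new uniform bin width.

    Mass of each source bin is spread uniformly over the bin and
    assigned to destination bins by overlap proportion; total volume is
    conserved and the mean dose moves by less than half the new width.
    """
    if step <= 0:
        raise DVHError("step must be positive")
    if abs(step - dvh.step) <= 1e-12 and _grid_aligned(dvh.bin_edges[0], step):
        return dvh
    lo = np.floor(dvh.bin_edges[0] / step + 1e-12) * step
    hi = dvh.bin_edges[-1]
    n_bins = max(int(np.ceil((hi - lo) / step - 1e-12)), 1)
    edges = lo + step * np.arange(n_bins + 1)
    vols = np.zeros(n_bins)
    for a, b, m in zip(dvh.bin_edges[:-1], dvh.bin_edges[1:], dvh.volumes):
        if m > 0:
            _deposit_uniform(vols, edges, a, b, m)
    return DifferentialDVH(bin_edges=edges, volumes=vols)


def _grid_aligned(edge0: float, step: float) -> bool:
    r = edge0 / step
    return abs(r - round(r)) < 1e-9


def _crossing_interval(cdvh: CumulativeDVH, level: float) -> tuple[float, float]:
    """Dose interval over which the piecewise-linear curve equals ``level``."""
    d, v = cdvh.doses, cdvh.volumes
    if level >= v[0]:
        return d[0], d[0]
    if level <= v[-1]:
        # curve never descends to this level: clamp to the maximum dose
        return d[-1], d[-1]
    lo = None
    hi = None
    for i in range(d.size - 1):
        v0, v1 = v[i], v[i + 1]
        if v1 <= level <= v0:
            if v0 == v1:  # plateau exactly at the level
                x0, x1 = d[i], d[i + 1]
            else:
                x0 = x1 = d[i] + (v0 - level) / (v0 - v1) * (d[i + 1] - d[i])
            if lo is None:
                lo = x0
            hi = x1
    assert lo is not None
    return lo, hi


def dose_at_volume(cdvh: CumulativeDVH, x_percent: float) -> float:
    """Dose D such that x% of the structure receives at least D (Dx%).

    Linear interpolation between the bracketing cumulative samples; if
    the requested level falls on a plateau of the curve, the midpoint
    of the plateau is returned (so the median of a symmetric two-level
    distribution is the midpoint of the two doses).
    """
    if not 0 < x_percent < 100:
        raise DVHError("x_percent must lie strictly between 0 and 100")
    lo, hi = _crossing_interval(cdvh, x_percent / 100.0)
    return 0.5 * (lo + hi)


def volume_at_dose(cdvh: CumulativeDVH, dose: float) -> float:
    """Percent of the structure receiving at least ``dose`` Gy (VD)."""
    if dose < 0:
        raise DVHError("dose must be non-negative")
    if dose <= cdvh.doses[0]:
        return 100.0
    if dose >= cdvh.doses[-1]:
        return 100.0 * float(cdvh.volumes[-1])
    return 100.0 * float(np.interp(dose, cdvh.doses, cdvh.volumes))


def mean_dose(dvh: DifferentialDVH) -> float:
    """Mean dose of a normalized differential DVH (bin-centre weighted)."""
    dvh.require_normalized("mean_dose")
    return float(np.dot(dvh.volumes, dvh.bin_centers))


def inhomogeneity_index(cdvh: CumulativeDVH) -> float:
    """Target-dose inhomogeneity index II = (D2% - D95%) / Dmedian.

    Zero for a perfectly uniform target dose; invariant under uniform
    dose scaling.
    """
    d2 = dose_at_volume(cdvh, 2.0)
    d95 = dose_at_volume(cdvh, 95.0)
    dmed = dose_at_volume(cdvh, 50.0)
    if dmed == 0:
        raise DVHError("median dose is zero; II undefined")
    return (d2 - d95) / dmed


def uniform_dose_dvh(dose: float, step: float = DEFAULT_STEP) -> DifferentialDVH:
    """Single-bin DVH: the whole structure receives exactly ``dose`` Gy."""
    if dose < step / 2:
        raise DVHError("dose must be at least half a bin width")
    edges = np.array([dose - step / 2, dose + step / 2])
    return DifferentialDVH(bin_edges=edges, volumes=np.array([1.0]))
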