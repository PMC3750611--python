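"""Radiobiological models: EQD2, gEUD, LKB and relative-seriality NTCP,
LQ-Poisson TCP.

All operations act on a *normalized* :class:`~radcomp.dvh.DifferentialDVH`
whose bin centres are physical total doses in Gy.

Model forms
-----------
EQD2 (linear-quadratic fractionation correction), per dose bin::

    EQD2_i = D_i * (d_i + a/b) / (2 + a/b),    d_i = D_i / n_fractions

gEUD (generalized equivalent uniform dose), volume-effect exponent n::

    gEUD = ( sum_i v_i * D_i**(1/n) )**n

LKB NTCP (probit dose response on the gEUD)::

    NTCP = Phi( (gEUD - D50) / (m * D50) )

Relative seriality NTCP (Poisson subvolume responses combined through
the seriality parameter s; s -> 1 serial organ, s -> 0 parallel)::

    P(D)  = 2 ** ( -exp( e * gamma * (1 - D / D50) ) )
    NTCP  = ( 1 - prod_i (1 - P(D_i)**s)**v_i )**(1/s)

LQ-Poisson TCP on the EQD2-corrected target DVH::

    TCP = prod_i P(D_i)**v_i,  with P as above using gamma50 / D50.

Per-bin products are accumulated in log space so many-bin DVHs cannot
underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtr

from .dvh import (
    DEFAULT_STEP,
    DifferentialDVH,
    DVHError,
    FractionationScheme,
)

#: gEUD volume-effect exponents below this are treated as the serial
#: (maximum-dose) limit
GEUD_N_GUARD = 1e-4

#: seriality parameters below this are rejected rather than
#: approximated by a parallel limit (smallest published value: 0.0061)
RS_S_GUARD = 1e-6

#: NTCP values below 0.1% are reported as zero
REPORT_FLOOR = 1e-3

_E = math.e


@dataclass(frozen=True)
class LKBParams:
    """Lyman-Kutcher-Burman parameters: volume exponent n, D50 (Gy), slope m."""

    n: float
    D50: float
    m: float

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("LKB n must be >= 0")
        if self.D50 <= 0 or self.m <= 0:
            raise ValueError("LKB D50 and m must be positive")


@dataclass(frozen=True)
class RSParams:
    """Relative-seriality parameters: slope gamma, D50 (Gy), seriality s."""

    gamma: float
    D50: float
    s: float

    def __post_init__(self):
        if self.gamma <= 0 or self.D50 <= 0:
            raise ValueError("RS gamma and D50 must be positive")
        if self.s <= RS_S_GUARD:
            raise ValueError(f"RS seriality s must exceed {RS_S_GUARD}")


@dataclass(frozen=True)
class AlphaBeta:
    """Linear-quadratic alpha/beta ratio in Gy."""

    ratio: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("alpha/beta ratio must be positive")


@dataclass(frozen=True)
class TCPParams:
    """LQ-Poisson TCP parameters: alpha/beta, D50 (Gy), gamma50."""

    alpha_beta: AlphaBeta
    D50: float
    gamma50: float

    def __post_init__(self):
        if self.D50 <= 0 or self.gamma50 <= 0:
            raise ValueError("TCP D50 and gamma50 must be positive")


# ---------------------------------------------------------------------------
# EQD2
# ---------------------------------------------------------------------------


def eqd2_dose(dose: float | np.ndarray, scheme: FractionationScheme, ab: AlphaBeta):
    """Map a total dose to its equivalent in 2 Gy fractions.

    The per-bin fraction dose is ``dose / n_fractions`` (all fractions
    assumed identical).  The map is the identity at 2 Gy per fraction.
    """
    d_fx = np.asarray(dose, dtype=float) / scheme.n_fractions
    return dose * (d_fx + ab.ratio) / (2.0 + ab.ratio)


def eqd2_transform(
    dvh: DifferentialDVH,
    scheme: FractionationScheme,
    ab: AlphaBeta,
    step: float = DEFAULT_STEP,
) -> DifferentialDVH:
    """EQD2-correct a DVH and re-bin it to the canonical step.

    Each bin's dose (its centre) is mapped through the monotone EQD2
    transform and the bin's volume deposited into the containing bin of
    a uniform grid with the same step phase as the input, so the
    transform is exactly the identity at 2 Gy per fraction.  Dose
    quantization of the output is at most half a step.
    """
    dvh.require_normalized("eqd2_transform")
    if abs(step - dvh.step) > 1e-12:
        from .dvh import rebin as _rebin

        dvh = _rebin(dvh, step)
    occ = dvh.volumes > 0
    centers = np.asarray(eqd2_dose(dvh.bin_centers[occ], scheme, ab))
    vols_in = dvh.volumes[occ]
    offset = dvh.bin_edges[0] - math.floor(dvh.bin_edges[0] / step + 1e-12) * step
    k = np.floor((centers - offset) / step + 1e-9).astype(int)
    k = np.maximum(k, 0)  # keep the grid at non-negative dose
    k_lo = int(k.min())
    n_bins = int(k.max()) - k_lo + 1
    edges = offset + step * (k_lo + np.arange(n_bins + 1))
    vols = np.zeros(n_bins)
    np.add.at(vols, k - k_lo, vols_in)
    return DifferentialDVH(bin_edges=edges, volumes=vols)


# ---------------------------------------------------------------------------
# DVH reduction
# ---------------------------------------------------------------------------


def geud(dvh: DifferentialDVH, n: float) -> float:
    """Generalized equivalent uniform dose ``(sum v_i D_i^(1/n))^n``.

    ``n = 1`` gives the mean dose; ``n`` below the guard threshold the
    maximum occupied bin dose (serial limit).  Evaluated in log space,
    so very small ``n`` (exponents of order 1/n) cannot overflow.
    """
    dvh.require_normalized("geud")
    if n < 0:
        raise ValueError("gEUD exponent n must be >= 0")
    if n < GEUD_N_GUARD:
        return dvh.max_dose()
    occ = dvh.volumes > 0
    d = dvh.bin_centers[occ]
    v = dvh.volumes[occ]
    with np.errstate(divide="ignore"):  # log(0) for a zero-dose bin -> -inf
        log_d = np.log(d, out=np.full_like(d, -np.inf), where=d > 0)
    return float(np.exp(n * logsumexp(np.log(v) + log_d / n)))


def effective_volume_reduction(dvh: DifferentialDVH, n: float) -> tuple[float, float]:
    """Kutcher-Burman reduction to an effective volume at the maximum dose.

    Returns ``(v_eff, D_ref)`` with ``v_eff = sum_i v_i (D_i/D_max)^(1/n)``
    and ``D_ref`` the maximum occupied bin dose.  The one-step DVH
    (fraction ``v_eff`` at ``D_ref``) yields the same LKB NTCP as the
    gEUD route, since ``D_ref * v_eff**n == gEUD``.
    """
    dvh.require_normalized("effective_volume_reduction")
    d_max = dvh.max_dose()
    if d_max <= 0:
        raise DVHError("all dose is zero; no reference dose for reduction")
    if n < GEUD_N_GUARD:
        top = dvh.bin_centers >= d_max - 1e-12
        return float(dvh.volumes[top].sum()), d_max
    occ = dvh.volumes > 0
    d = dvh.bin_centers[occ]
    v = dvh.volumes[occ]
    with np.errstate(divide="ignore"):
        log_ratio = np.where(d > 0, np.log(d / d_max), -np.inf)
    v_eff = float(np.exp(logsumexp(np.log(v) + log_ratio / n)))
    return v_eff, d_max


# ---------------------------------------------------------------------------
# NTCP / TCP
# ---------------------------------------------------------------------------


def lkb_ntcp(dvh: DifferentialDVH, p: LKBParams) -> float:
    """LKB complication probability: Phi((gEUD - D50)/(m D50))."""
    eud = geud(dvh, p.n)
    t = (eud - p.D50) / (p.m * p.D50)
    return float(ndtr(t))


def lkb_ntcp_from_reduction(v_eff: float, d_ref: float, p: LKBParams) -> float:
    """LKB NTCP evaluated through the effective-volume route."""
    if not 0 < v_eff <= 1 + 1e-12:
        raise ValueError("effective volume must lie in (0, 1]")
    eud = d_ref * v_eff**p.n
    t = (eud - p.D50) / (p.m * p.D50)
    return float(ndtr(t))


def _log_poisson_response(dose: np.ndarray, gamma: float, d50: float) -> np.ndarray:
    """log of P(D) = 2^(-exp(e*gamma*(1 - D/D50)))."""
    return -np.exp(_E * gamma * (1.0 - dose / d50)) * math.log(2.0)


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x <= 0, stable at both ends (-inf at x = 0)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x > -math.log(2.0)
    with np.errstate(divide="ignore"):
        out[small] = np.log(-np.expm1(x[small]))
        out[~small] = np.log1p(-np.exp(x[~small]))
    return out


def rs_ntcp(dvh: DifferentialDVH, p: RSParams) -> float:
    """Relative-seriality complication probability.

    Uniform whole-organ irradiation at dose D collapses to the single
    subvolume response P(D) for any seriality.
    """
    dvh.require_normalized("rs_ntcp")
    occ = dvh.volumes > 0
    d = dvh.bin_centers[occ]
    v = dvh.volumes[occ]
    log_p = _log_poisson_response(d, p.gamma, p.D50)
    # log prod_i (1 - P_i^s)^(v_i), accumulated stably
    log_one_minus_ps = _log1mexp(log_p * p.s)
    log_prod = float(np.dot(v, log_one_minus_ps))
    inner = -math.expm1(log_prod)  # 1 - prod
    if inner <= 0:
        return 0.0
    return float(min(inner ** (1.0 / p.s), 1.0))


def poisson_tcp(
    dvh: DifferentialDVH, p: TCPParams, scheme: FractionationScheme
) -> float:
    """LQ-Poisson tumour control probability of an EQD2-corrected DVH."""
    dvh.require_normalized("poisson_tcp")
    corrected = eqd2_transform(dvh, scheme, p.alpha_beta)
    occ = corrected.volumes > 0
    d = corrected.bin_centers[occ]
    v = corrected.volumes[occ]
    log_tcp = float(np.dot(v, _log_poisson_response(d, p.gamma50, p.D50)))
    return float(np.exp(log_tcp))


def report_floor(ntcp: float, floor: float = REPORT_FLOOR) -> float:
    """Reporting rule: probabilities below 0.1% are reported as zero."""
    if not 0 <= ntcp <= 1:
        raise ValueError("probability must lie in [0, 1]")
    return 0.0 if ntcp < floor else ntcp
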