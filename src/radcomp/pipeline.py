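"""Plan evaluation and paired algorithm-vs-algorithm comparison.

``evaluate_plan`` turns one plan's DVH set into a metric table: the
site's dose-volume indices, LQ-Poisson TCP of the target, and NTCP for
every applicable published parameter set (with the 0.1% reporting
floor applied at output).  ``summarize_comparison`` reduces the paired
per-patient metric tables of two algorithms to mean/sd per algorithm
plus a two-tailed paired Student t-test per metric, the cell structure
of a plan-comparison summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import (
    DVHError,
    PlanDVHSet,
    StructureDVH,
    dose_at_volume,
    inhomogeneity_index,
    mean_dose,
    volume_at_dose,
)
from .params import NTCPParameterSet, check_volume_convention, load_builtin
from .radiobiology import (
    AlphaBeta,
    LKBParams,
    TCPParams,
    eqd2_transform,
    lkb_ntcp,
    poisson_tcp,
    report_floor,
    rs_ntcp,
)

#: per-site metric menus: ordered (organ role, metrics) blocks.
#: "NTCP" expands to one row per applicable parameter set; "TCP" to one
#: row per configured alpha/beta.
SITE_MENUS: dict[str, list[tuple[str, list[str]]]] = {
    "breast": [
        ("PTV", ["D2%", "D95%", "Dmean", "II", "TCP"]),
        ("lung", ["D2%", "D15%", "Dmean", "NTCP"]),
        ("heart", ["D2%", "D15%", "NTCP"]),
    ],
    "lung": [
        ("PTV", ["D2%", "D95%", "Dmean", "II", "TCP"]),
        ("lung", ["D2%", "D20%", "D60%", "Dmean", "V20", "NTCP"]),
    ],
    "head_and_neck": [
        ("PTV", ["D2%", "D95%", "Dmean", "II", "TCP"]),
        ("parotid", ["Dmean", "NTCP"]),
    ],
    "prostate": [
        ("PTV", ["D2%", "D95%", "Dmean", "II", "TCP"]),
        ("rectum", ["D2%", "D50%", "D95%", "Dmean", "NTCP"]),
        ("femoral_head", ["D2%", "D50%", "D80%", "NTCP"]),
    ],
}

#: default LQ-Poisson TCP configuration per site.  The alpha/beta
#: ratios are standard (10 Gy for breast/lung/head-and-neck; 1.49 and
#: 10 Gy bracketing the prostate debate); D50/gamma50 are package
#: defaults chosen so uniform irradiation at the site's prescription
#: gives a plausible control probability — they are run configuration,
#: not published constants.
SITE_TCP: dict[str, list[tuple[str, TCPParams]]] = {
    "breast": [("TCP", TCPParams(AlphaBeta(10.0), D50=40.0, gamma50=2.0))],
    "lung": [("TCP", TCPParams(AlphaBeta(10.0), D50=48.0, gamma50=2.0))],
    "head_and_neck": [("TCP", TCPParams(AlphaBeta(10.0), D50=56.0, gamma50=2.0))],
    "prostate": [
        ("TCP[a/b=1.49]", TCPParams(AlphaBeta(1.49), D50=62.0, gamma50=2.0)),
        ("TCP[a/b=10]", TCPParams(AlphaBeta(10.0), D50=51.5, gamma50=2.0)),
    ],
}

#: alpha/beta used for the EQD2 correction of organ-at-risk DVHs
OAR_ALPHA_BETA = AlphaBeta(3.0)

#: fraction-dose deviation from 2 Gy beyond which EQD2 is applied
EQD2_TOLERANCE = 0.01


@dataclass
class PairedSummary:
    """One row of a paired comparison table."""

    metric: str
    structure: str
    mean_AAA: float
    sd_AAA: float
    mean_PBC: float
    sd_PBC: float
    t: float
    p_two_tailed: float
    n: int
    degenerate: bool = False
    model: str = ""
    label: str = ""


def _dose_metric(structure: StructureDVH, metric: str) -> float:
    cdvh = structure.cumulative()
    if metric == "Dmean":
        return mean_dose(structure.differential())
    if metric == "II":
        return inhomogeneity_index(cdvh)
    if metric.startswith("D") and metric.endswith("%"):
        return dose_at_volume(cdvh, float(metric[1:-1]))
    if metric.startswith("V"):
        return volume_at_dose(cdvh, float(metric[1:]))
    raise ValueError(f"unknown dose metric {metric!r}")


def _ntcp_dvh(plan: PlanDVHSet, structure: StructureDVH):
    """Differential DVH for NTCP, EQD2-corrected if fractionation deviates from 2 Gy/fx."""
    dvh = structure.differential()
    scheme = plan.fractionation
    if scheme is not None and abs(scheme.fraction_dose - 2.0) > EQD2_TOLERANCE:
        dvh = eqd2_transform(dvh, scheme, OAR_ALPHA_BETA)
    return dvh


def _ntcp_rows(plan: PlanDVHSet, organ: str, psets: list[NTCPParameterSet]) -> list[dict]:
    rows = []
    applicable = [p for p in psets if p.organ == organ]
    structures = plan.by_label(organ)
    # separate-organ mode for sets annotated as such, when per-lung
    # structures are supplied
    for pset in applicable:
        separate = (
            organ == "lung"
            and "separate" in pset.note
            and plan.by_label("lung_left")
            and plan.by_label("lung_right")
        )
        targets: list[tuple[str, StructureDVH]]
        if separate:
            targets = [
                ("left", plan.by_label("lung_left")[0]),
                ("right", plan.by_label("lung_right")[0]),
            ]
        elif structures:
            targets = [("", structures[0])]
        else:
            rows.append(_row(organ, organ, "NTCP", math.nan, model=pset.model,
                             label=pset.label, status="missing"))
            continue
        for side, structure in targets:
            check_volume_convention(pset, structure.volume_convention)
            dvh = _ntcp_dvh(plan, structure)
            if isinstance(pset.params, LKBParams):
                raw = lkb_ntcp(dvh, pset.params)
            else:
                raw = rs_ntcp(dvh, pset.params)
            label = pset.label if not side else f"{pset.label} ({side})"
            rows.append(
                _row(structure.structure_name, organ, "NTCP", report_floor(raw),
                     model=pset.model, label=label, raw=raw)
            )
    return rows


def _row(structure, organ, metric, value, model="", label="", status="ok", raw=None):
    return {
        "structure": structure,
        "organ": organ,
        "metric": metric,
        "model": model,
        "label": label,
        "value": value,
        "raw": value if raw is None else raw,
        "status": status,
    }


def evaluate_plan(
    plan: PlanDVHSet,
    param_sets: list[NTCPParameterSet] | None = None,
    tcp_configs: list[tuple[str, TCPParams]] | None = None,
    menus: dict[str, list[tuple[str, list[str]]]] | None = None,
) -> pd.DataFrame:
    """Evaluate every metric of the plan's site menu.

    Returns a tidy table with one row per metric (NTCP: one row per
    applicable parameter set; missing structures yield rows flagged
    ``status == "missing"`` rather than raising).
    """
    if plan.site is None:
        raise DVHError("plan has no site; cannot select a metric menu")
    menus = menus if menus is not None else SITE_MENUS
    if plan.site not in menus:
        raise DVHError(f"no metric menu for site {plan.site!r}")
    psets = param_sets if param_sets is not None else load_builtin()
    if tcp_configs is None:
        tcp_configs = SITE_TCP.get(plan.site, [])

    rows: list[dict] = []
    for organ, metrics in menus[plan.site]:
        structures = plan.by_label(organ)
        structure = structures[0] if structures else None
        for metric in metrics:
            if metric == "NTCP":
                rows.extend(_ntcp_rows(plan, organ, psets))
                continue
            if metric == "TCP":
                # TCP from the CTV DVH, falling back to the PTV
                tcp_structs = plan.by_label("CTV") or plan.by_label("PTV")
                for label, tp in tcp_configs:
                    if not tcp_structs or plan.fractionation is None:
                        rows.append(_row(organ, organ, label, math.nan, status="missing"))
                        continue
                    tcp = poisson_tcp(
                        tcp_structs[0].differential(), tp, plan.fractionation
                    )
                    rows.append(_row(tcp_structs[0].structure_name, organ, label, tcp))
                continue
            if structure is None:
                rows.append(_row(organ, organ, metric, math.nan, status="missing"))
                continue
            rows.append(
                _row(structure.structure_name, organ, metric,
                     _dose_metric(structure, metric))
            )
    df = pd.DataFrame(rows)
    df.insert(0, "algorithm", plan.algorithm_tag)
    df.insert(0, "patient_id", plan.patient_id)
    return df


def paired_t_test(x, y) -> tuple[float, float, bool]:
    """Two-tailed paired Student t-test.

    ``t = mean(d) / (sd(d)/sqrt(N))`` on the differences ``d = x - y``
    with sample sd (N-1 denominator); p from the t-distribution with
    N-1 degrees of freedom.  Returns ``(t, p, degenerate)`` where the
    flag marks zero-variance differences (p is 0 for a nonzero mean
    difference, 1 for identical samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired t-test needs two equal-length 1-d samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, d.mean()), 0.0, True
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def evaluate_cohort(pairs, **kwargs) -> pd.DataFrame:
    """Metric tables for every plan of a paired cohort, concatenated."""
    frames = [
        evaluate_plan(plan, **kwargs) for pair in pairs for plan in pair
    ]
    return pd.concat(frames, ignore_index=True)


def summarize_comparison(results: pd.DataFrame) -> pd.DataFrame:
    """Paired AAA-vs-PBC summary of a cohort metric table.

    One row per metric: mean and sample sd per algorithm and the
    two-tailed paired t-test p-value, computed on patients with both
    algorithms present (complete pairs only); row order follows the
    metric-menu order of the input.
    """
    ok = results[results["status"] == "ok"]
    out_rows: list[PairedSummary] = []
    key_cols = ["organ", "structure", "metric", "model", "label"]
    # preserve first-appearance order of metric keys
    keys = ok[key_cols].drop_duplicates().itertuples(index=False)
    for key in keys:
        sel = ok
        for col, val in zip(key_cols, key):
            sel = sel[sel[col] == val]
        pivot = sel.pivot_table(
            index="patient_id", columns="algorithm", values="value", aggfunc="first"
        )
        if not {"AAA", "PBC"}.issubset(pivot.columns):
            continue
        pivot = pivot.dropna(subset=["AAA", "PBC"])
        n = len(pivot)
        if n < 2:
            continue
        aaa = pivot["AAA"].to_numpy()
        pbc = pivot["PBC"].to_numpy()
        t, p, degen = paired_t_test(aaa, pbc)
        out_rows.append(
            PairedSummary(
                metric=key.metric,
                structure=key.structure,
                mean_AAA=float(aaa.mean()),
                sd_AAA=float(aaa.std(ddof=1)),
                mean_PBC=float(pbc.mean()),
                sd_PBC=float(pbc.std(ddof=1)),
                t=t,
                p_two_tailed=p,
                n=n,
                degenerate=degen,
                model=key.model,
                label=key.label,
            )
        )
    return pd.DataFrame([vars(r) for r in out_rows])


def compare_site(
    cfg, param_sets: list[NTCPParameterSet] | None = None
) -> pd.DataFrame:
    """Generate a synthetic paired cohort and summarize it end to end."""
    from .cohort import generate_paired_cohort

    pairs = generate_paired_cohort(cfg)
    results = evaluate_cohort(pairs, param_sets=param_sets)
    summary = summarize_comparison(results)
    summary.insert(0, "site", cfg.site)
    return summary


def format_report(summary: pd.DataFrame) -> str:
    """Human-readable comparison table (one decimal, * marks p < 0.05).

    Probabilities are printed as percentages; machine-readable output
    should use the summary DataFrame itself (full precision).
    """
    lines = [
        f"{'structure':<16}{'metric':<14}{'parameters':<34}"
        f"{'AAA mean':>9}{'sd':>7}{'PBC mean':>9}{'sd':>7}{'p':>9}"
    ]
    for row in summary.itertuples(index=False):
        prob = row.metric == "NTCP" or row.metric.startswith("TCP")
        scale = 100.0 if prob else 1.0
        p_txt = "degen" if row.degenerate else f"{row.p_two_tailed:.3f}"
        mark = "*" if (not row.degenerate and row.p_two_tailed < 0.05) else " "
        lines.append(
            f"{row.structure:<16}{row.metric:<14}{row.label:<34}"
            f"{row.mean_AAA * scale:>9.1f}{row.sd_AAA * scale:>7.1f}"
            f"{row.mean_PBC * scale:>9.1f}{row.sd_PBC * scale:>7.1f}"
            f"{p_txt:>8}{mark}"
        )
    return "\n".join(lines)
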