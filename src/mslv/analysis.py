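"""Cohort analysis: from validated patient records to the shoulder-imbalance
report.

For every patient the pipeline measures the preoperative and 2-year
radiographic parameters, determines the MSLV from the preoperative film and
the actual LIV, classifies the actual UIV against all four recommendation
methods, and classifies 2-year shoulder balance.  Cohort-level outputs are
the per-method 2x2 tables (imbalanced/balanced x unmatched/matched) with
odds ratios, Woolf CIs and Fisher p-values; preoperative-CA-adjusted
logistic fits; M-group vs P-group parameter comparisons; MSLV sensitivity
to one-level LIV shifts; and junctional-complication counts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import levels as lv
from . import selection as sel
from . import stats as st
from .errors import MSLVError, SeparationError, ZeroCellError
from .records import PatientRecord

log = logging.getLogger(__name__)

METHODS = ("MSLV", "Lenke", "Ilharreborde", "Trobisch")


@dataclass(frozen=True)
class AnalysisConfig:
    contact_tol: float = sel.DEFAULT_CONTACT_TOL
    windows: dict = field(default_factory=lambda: dict(geo.DEFAULT_WINDOWS))
    lenke_complement: tuple[str, ...] = sel.LENKE_COMPLEMENT
    conf_level: float = 0.95
    #: when a 2x2 cell is zero, fall back to the +0.5 continuity correction
    #: (flagged in the report) instead of failing the whole analysis
    continuity_on_zero_cell: bool = True


@dataclass
class PatientAnalysis:
    """Per-patient intermediate results feeding the cohort report."""

    id: str
    params_pre: geo.RadiographicParams
    params_2yr: geo.RadiographicParams
    mslv: sel.MSLVResult
    match: dict  # method -> matched|proximal|distal|unmatched
    imbalanced: bool
    sensitivity: tuple[bool | None, bool | None]
    pjk: bool | None
    adding_on: bool | None


@dataclass
class CohortReport:
    n_analyzed: int
    tables: dict  # method -> ContingencyTable2x2
    or_results: dict  # method -> ORResult | {"error": ...}
    fisher_p: dict  # method -> float
    logistic: dict  # method -> LogisticFit | {"error": ...}
    group_comparison: pd.DataFrame
    group_sizes: dict  # M/P/D -> n
    sensitivity: dict  # changed counts and evaluable n per direction
    pjk: dict
    adding_on: dict
    imbalance_prevalence: dict  # method -> {unmatched: %, matched: %}
    exclusions: list
    per_patient: list = field(default_factory=list, repr=False)


# --------------------------------------------------------------------------
# Per-patient stage
# --------------------------------------------------------------------------


def analyze_patient(rec: PatientRecord, cfg: AnalysisConfig) -> PatientAnalysis:
    params_pre = geo.measure_params(rec.preop_coronal, rec.preop_sagittal, cfg.windows)
    params_2yr = geo.measure_params(rec.two_year_coronal, rec.two_year_sagittal, cfg.windows)

    mslv_res = sel.determine_mslv(rec.preop_coronal, rec.actual_liv, cfg.contact_tol)
    recs = {
        "MSLV": sel.mslv_recommendation(mslv_res),
        "Lenke": sel.recommend_lenke(params_pre, cfg.lenke_complement),
        "Ilharreborde": sel.recommend_ilharreborde(
            rec.bending, params_pre.t1_tilt, params_pre.rsh
        ),
        "Trobisch": sel.recommend_trobisch(),
    }
    match = {
        name: sel.classify_match(rec.actual_uiv, r, mslv_res).match_class
        for name, r in recs.items()
    }
    return PatientAnalysis(
        id=rec.id,
        params_pre=params_pre,
        params_2yr=params_2yr,
        mslv=mslv_res,
        match=match,
        imbalanced=st.shoulder_imbalance(params_2yr.rsh),
        sensitivity=sel.mslv_liv_sensitivity(rec.preop_coronal, rec.actual_liv, cfg.contact_tol),
        pjk=geo.pjk_flag(rec.preop_sagittal, rec.two_year_sagittal, rec.actual_uiv),
        adding_on=geo.adding_on_flag(
            rec.first_erect_coronal, rec.two_year_coronal, rec.actual_liv, cfg.windows
        ),
    )


# --------------------------------------------------------------------------
# Cohort stage
# --------------------------------------------------------------------------


def build_method_table(analyses: list[PatientAnalysis], method: str) -> st.ContingencyTable2x2:
    """2x2 counts for one method: rows unmatched/matched, columns
    imbalanced/balanced.  For the MSLV method the proximal and distal groups
    together form the unmatched row."""
    a = b = c = d = 0
    for pa in analyses:
        matched = pa.match[method] == "matched"
        if matched:
            c += int(pa.imbalanced)
            d += int(not pa.imbalanced)
        else:
            a += int(pa.imbalanced)
            b += int(not pa.imbalanced)
    return st.ContingencyTable2x2(a=a, b=b, c=c, d=d)


_CONTINUOUS_FIELDS = (
    "pt_cobb", "mt_cobb", "c7pl_csvl", "ca", "t1_tilt", "rsh", "mt_avt",
    "tk_t5_t12", "ll_t12_s1",
)


def _group_rows(analyses: list[PatientAnalysis]) -> pd.DataFrame:
    """M-group vs P-group comparison of every radiographic parameter
    (preoperative, 2-year, and pre-to-post change), Welch t-test on the
    mean; the UIV/MSLV ordinals get the exact Mann-Whitney U test.  The
    D-group is summarized descriptively only."""
    groups: dict[str, list[PatientAnalysis]] = {"M": [], "P": [], "D": []}
    for pa in analyses:
        cls = pa.match["MSLV"]
        groups["M" if cls == "matched" else ("P" if cls == "proximal" else "D")].append(pa)

    def values(pas, stage, name):
        out = []
        for pa in pas:
            if stage == "delta":
                v2 = getattr(pa.params_2yr, name)
                v0 = getattr(pa.params_pre, name)
                v = None if v2 is None or v0 is None else v2 - v0
            else:
                v = getattr(pa.params_pre if stage == "pre" else pa.params_2yr, name)
            if name == "rsh" and v is not None and stage != "delta":
                v = abs(v)  # the tabulated quantity is |RSH|
            if v is not None:
                out.append(float(v))
        return np.asarray(out)

    rows = []
    for stage in ("pre", "2yr", "delta"):
        for name in _CONTINUOUS_FIELDS:
            m = values(groups["M"], stage, name)
            p = values(groups["P"], stage, name)
            d = values(groups["D"], stage, name)
            if len(m) >= 2 and len(p) >= 2 and (np.var(m) + np.var(p)) > 0:
                _, _, pval = st.welch_t(m, p)
            else:
                pval = math.nan  # descriptive only
            rows.append(
                {
                    "variable": f"{name}_{stage}",
                    "test": "welch_t",
                    "m_n": len(m), "m_mean": _mean(m), "m_sd": _sd(m),
                    "p_n": len(p), "p_mean": _mean(p), "p_sd": _sd(p),
                    "d_n": len(d), "d_mean": _mean(d), "d_sd": _sd(d),
                    "p_value": pval,
                }
            )
    return pd.DataFrame(rows)


def _mean(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else math.nan


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else math.nan


def run_analysis(
    records: list[PatientRecord],
    cfg: AnalysisConfig | None = None,
    exclusions: list | None = None,
) -> CohortReport:
    """Run the full comparative analysis on a validated cohort.

    Deterministic: the same records and configuration always produce an
    identical report."""
    cfg = cfg or AnalysisConfig()
    if not records:
        raise MSLVError("empty cohort")
    analyses = [analyze_patient(r, cfg) for r in records]
    uiv_by_id = {r.id: r.actual_uiv for r in records}

    tables: dict = {}
    or_results: dict = {}
    fisher_p: dict = {}
    logistic: dict = {}
    prevalence: dict = {}
    for method in METHODS:
        t = build_method_table(analyses, method)
        tables[method] = t
        try:
            or_results[method] = st.odds_ratio_woolf(
                t, cfg.conf_level, continuity=cfg.continuity_on_zero_cell
            )
        except ZeroCellError as e:
            or_results[method] = {"error": str(e)}
        fisher_p[method] = st.fisher_exact(t)
        prevalence[method] = {
            "unmatched": 100.0 * t.a / (t.a + t.b) if t.a + t.b else math.nan,
            "matched": 100.0 * t.c / (t.c + t.d) if t.c + t.d else math.nan,
        }
        # adjusted model: imbalance ~ unmatched-with-this-method + preop CA
        y = np.array([float(pa.imbalanced) for pa in analyses])
        unmatched = np.array([float(pa.match[method] != "matched") for pa in analyses])
        ca = np.array([pa.params_pre.ca for pa in analyses])
        X = np.column_stack([np.ones_like(y), unmatched, ca])
        try:
            logistic[method] = st.logistic_fit(
                y, X, names=("intercept", "unmatched", "preop_ca")
            )
        except (SeparationError, MSLVError) as e:
            logistic[method] = {"error": str(e)}

    group_df = _group_rows(analyses)
    # ordinal M-vs-P comparisons (UIV and MSLV as level ranks)
    m_pa = [pa for pa in analyses if pa.match["MSLV"] == "matched"]
    p_pa = [pa for pa in analyses if pa.match["MSLV"] == "proximal"]
    d_pa = [pa for pa in analyses if pa.match["MSLV"] == "distal"]
    ordinal_rows = []
    for name, getter in (
        ("uiv", lambda pa: float(lv.index(uiv_by_id[pa.id]))),
        ("mslv", lambda pa: float(lv.index(pa.mslv.mslv))),
    ):
        m = np.array([getter(pa) for pa in m_pa])
        p = np.array([getter(pa) for pa in p_pa])
        d = np.array([getter(pa) for pa in d_pa])
        if len(m) >= 1 and len(p) >= 1:
            res = st.mann_whitney(m, p)
            pval, test = res.p, f"mann_whitney_{res.mode}"
        else:
            pval, test = math.nan, "mann_whitney"
        ordinal_rows.append(
            {
                "variable": f"{name}_level", "test": test,
                "m_n": len(m), "m_mean": _mean(m), "m_sd": _sd(m),
                "p_n": len(p), "p_mean": _mean(p), "p_sd": _sd(p),
                "d_n": len(d), "d_mean": _mean(d), "d_sd": _sd(d),
                "p_value": pval,
            }
        )
    group_df = pd.concat([group_df, pd.DataFrame(ordinal_rows)], ignore_index=True)

    sens_prox = [pa.sensitivity[0] for pa in analyses]
    sens_dist = [pa.sensitivity[1] for pa in analyses]
    report = CohortReport(
        n_analyzed=len(records),
        tables=tables,
        or_results=or_results,
        fisher_p=fisher_p,
        logistic=logistic,
        group_comparison=group_df,
        group_sizes={"M": len(m_pa), "P": len(p_pa), "D": len(d_pa)},
        sensitivity={
            "proximal_changed": sum(1 for f in sens_prox if f is True),
            "proximal_evaluable": sum(1 for f in sens_prox if f is not None),
            "distal_changed": sum(1 for f in sens_dist if f is True),
            "distal_evaluable": sum(1 for f in sens_dist if f is not None),
        },
        pjk={
            "count": sum(1 for pa in analyses if pa.pjk is True),
            "evaluable": sum(1 for pa in analyses if pa.pjk is not None),
        },
        adding_on={
            "count": sum(1 for pa in analyses if pa.adding_on is True),
            "evaluable": sum(1 for pa in analyses if pa.adding_on is not None),
        },
        imbalance_prevalence=prevalence,
        exclusions=list(exclusions or []),
        per_patient=analyses,
    )
    return report


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def _or_to_json(res) -> dict:
    if isinstance(res, dict):
        return res
    return {
        "or": res.or_point,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "conf_level": res.conf_level,
        "continuity_corrected": res.continuity_corrected,
    }


def _logistic_to_json(fit) -> dict:
    if isinstance(fit, dict):
        return fit
    return {
        "names": list(fit.names),
        "coef": list(fit.coef),
        "wald_se": list(fit.wald_se),
        "or": list(fit.or_point),
        "or_ci_low": list(fit.or_ci_low),
        "or_ci_high": list(fit.or_ci_high),
        "p_values": list(fit.p_values),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }


def report_to_json(report: CohortReport) -> dict:
    """Full-precision machine-readable form of the report."""

    def clean(v):
        return None if isinstance(v, float) and math.isnan(v) else v

    return {
        "n_analyzed": report.n_analyzed,
        "tables": {
            m: {"a": t.a, "b": t.b, "c": t.c, "d": t.d} for m, t in report.tables.items()
        },
        "odds_ratios": {m: _or_to_json(r) for m, r in report.or_results.items()},
        "fisher_p": dict(report.fisher_p),
        "logistic": {m: _logistic_to_json(f) for m, f in report.logistic.items()},
        "imbalance_prevalence_pct": {
            m: {k: clean(v) for k, v in d.items()}
            for m, d in report.imbalance_prevalence.items()
        },
        "group_sizes": dict(report.group_sizes),
        "group_comparison": [
            {k: clean(v) for k, v in row.items()}
            for row in report.group_comparison.to_dict(orient="records")
        ],
        "sensitivity": dict(report.sensitivity),
        "pjk": dict(report.pjk),
        "adding_on": dict(report.adding_on),
        "exclusions": [list(e) for e in report.exclusions],
    }


def write_report(report: CohortReport, out_dir: str | Path) -> list[Path]:
    """Write the report bundle: table4_analogue.csv, group_comparison.csv,
    logistic.json, exclusions.log and the full-precision report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    rows = []
    for method in METHODS:
        t = report.tables[method]
        res = report.or_results[method]
        prev = report.imbalance_prevalence[method]
        row = {
            "method": method,
            "unmatched_imbalanced": t.a,
            "unmatched_balanced": t.b,
            "matched_imbalanced": t.c,
            "matched_balanced": t.d,
            "unmatched_imbalanced_pct": (
                f"{prev['unmatched']:.0f}" if not math.isnan(prev["unmatched"]) else "NA"
            ),
            "matched_imbalanced_pct": (
                f"{prev['matched']:.0f}" if not math.isnan(prev["matched"]) else "NA"
            ),
        }
        if isinstance(res, dict):
            row.update(odds_ratio="NA", ci_95="NA (zero cell)")
        else:
            row.update(
                odds_ratio=st.format_ratio(res.or_point),
                ci_95=f"{st.format_ratio(res.ci_low)}-{st.format_ratio(res.ci_high)}",
            )
        row["fisher_p"] = f"{report.fisher_p[method]:.2f}"
        rows.append(row)
    p = out / "table4_analogue.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)

    p = out / "group_comparison.csv"
    df = report.group_comparison.copy()
    for col in df.columns:
        if df[col].dtype == float:
            df[col] = df[col].round(4)
    df.to_csv(p, index=False)
    paths.append(p)

    p = out / "logistic.json"
    p.write_text(
        json.dumps({m: _logistic_to_json(f) for m, f in report.logistic.items()},
                   indent=2, sort_keys=True)
    )
    paths.append(p)

    p = out / "exclusions.log"
    p.write_text(
        "".join(f"{pid}\t{reason}\n" for pid, reason in report.exclusions)
    )
    paths.append(p)

    p = out / "report.json"
    p.write_text(json.dumps(report_to_json(report), indent=2, sort_keys=True))
    paths.append(p)
    return paths
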