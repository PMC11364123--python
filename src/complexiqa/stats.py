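"""Complexity-QA correlation statistics and report tables.

Implements the analysis stage of pre-treatment-verification studies:

* tie-corrected Spearman rank correlations with two-tailed t-approximation
  p-values and the conventional strength grades (|r| >= 0.7 strong,
  0.5-0.7 moderate, 0.4-0.5 weak, < 0.4 none);
* the calculation-vs-measurement GPR correlation grid (r_calc-meas);
* the per-metric radar table |r_pcm-QA| with the "PCMs% >= 0.5" summary and
  per-system top-10 ranking at the strictest criterion;
* principal-component regression (PCR): z-scored metrics, PCA keeping the
  smallest number of components covering the target explained variance
  (default 90%), ordinary least squares of GPR on the component scores,
  reported as R^2 with an F-test p-value;
* plain CSV/Markdown report bundles mirroring the distribution summaries,
  correlation grids and PCR tables of such studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

CRITERIA_ORDER = ("3%/3mm", "3%/2mm", "2%/2mm", "1%/1mm")
STRICTEST = "1%/1mm"

#: |r| grade boundaries: [0.7, 1] strong, [0.5, 0.7) moderate,
#: [0.4, 0.5) weak, [0, 0.4) none.
GRADE_BOUNDS = ((0.7, "strong"), (0.5, "moderate"), (0.4, "weak"), (0.0, "none"))


class ConstantInputError(ValueError):
    """Correlation of a constant vector is undefined."""


def grade_correlation(r: float) -> str:
    """Strength grade of a correlation coefficient from |r|."""
    a = abs(r)
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| = {a} > 1")
    for bound, name in GRADE_BOUNDS:
        if a >= bound:
            return name
    return "none"


@dataclass(frozen=True)
class CorrelationReport:
    """One Spearman correlation with significance and strength grade."""

    r: float
    p: float
    n: int
    grade: str

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def spearman(x, y) -> CorrelationReport:
    """Tie-corrected Spearman rank correlation with a two-tailed t-test p.

    Requires at least 5 finite pairs; constant inputs raise
    :class:`ConstantInputError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError(f"need >= 5 finite pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("undefined correlation: constant input vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = sps.spearmanr(x, y)
    r = float(r)
    return CorrelationReport(r=r, p=float(p), n=int(x.size),
                             grade=grade_correlation(r))


# ---------------------------------------------------------------------------
# cohort table


@dataclass
class QACohortTable:
    """The paired data behind all statistics of the study.

    gpr:
        Long table (plan_id, system, criterion, gpr %, status).
    pcm:
        Long table (plan_id, metric, value).
    meta:
        Per-plan metadata (plan_id, site, linac, complexity dial when known).
    """

    gpr: pd.DataFrame
    pcm: pd.DataFrame
    meta: pd.DataFrame
    registry: object | None = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        bad_crit = set(self.gpr["criterion"]) - set(CRITERIA_ORDER)
        if bad_crit:
            raise ValueError(f"unknown criteria in GPR table: {sorted(bad_crit)}")
        finite = self.gpr["gpr"].dropna()
        if ((finite < 0) | (finite > 100)).any():
            raise ValueError("GPR values outside [0, 100]")
        gpr_plans = set(self.gpr["plan_id"])
        pcm_counts = self.pcm.groupby("plan_id")["metric"].nunique()
        missing = gpr_plans - set(pcm_counts.index)
        if missing:
            raise ValueError(f"plans without PCM vectors: {sorted(missing)[:5]}")
        if pcm_counts.nunique() > 1:
            raise ValueError("inconsistent PCM vector lengths across plans")

    @property
    def metrics(self) -> list[str]:
        return sorted(self.pcm["metric"].unique())

    @property
    def systems(self) -> list[str]:
        return sorted(self.gpr["system"].unique())

    def pcm_wide(self) -> pd.DataFrame:
        return self.pcm.pivot(index="plan_id", columns="metric", values="value")

    def site_of(self) -> pd.Series:
        return self.meta.set_index("plan_id")["site"]

    def gpr_pivot(self) -> pd.DataFrame:
        return self.gpr.pivot_table(index="plan_id", columns=["system", "criterion"],
                                    values="gpr")

    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.gpr.to_csv(directory / "gpr.csv", index=False)
        self.pcm.to_csv(directory / "pcm.csv", index=False)
        self.meta.to_csv(directory / "meta.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "QACohortTable":
        directory = Path(directory)
        return cls(gpr=pd.read_csv(directory / "gpr.csv"),
                   pcm=pd.read_csv(directory / "pcm.csv"),
                   meta=pd.read_csv(directory / "meta.csv"))


def _cqa_mqa_systems(systems) -> tuple[list[str], list[str]]:
    cqa = [s for s in systems if s.startswith("cqa")]
    mqa = [s for s in systems if s.startswith("mqa")]
    return cqa, mqa


# ---------------------------------------------------------------------------
# correlation grids


def r_calc_meas_matrix(table: QACohortTable,
                       by_site: bool = True) -> pd.DataFrame:
    """Spearman grid between calculation-QA and measurement-QA GPRs.

    One row per (CQA system, MQA system, criterion, site or 'all') over the
    plans present in both systems.  Cells without overlap, or with constant
    GPR columns, are kept with NaN r and an explanatory status — never
    silently dropped.  Grades at or above the weak cut (0.4) carry a
    highlight flag.
    """
    piv = table.gpr_pivot()
    site_of = table.site_of()
    cqa, mqa = _cqa_mqa_systems(table.systems)
    strata = [("all", piv.index)]
    if by_site:
        for site in sorted(site_of.unique()):
            ids = site_of.index[site_of == site]
            strata.append((site, piv.index.intersection(ids)))
    rows = []
    for c_sys in cqa:
        for m_sys in mqa:
            for crit in CRITERIA_ORDER:
                if (c_sys, crit) not in piv.columns or (m_sys, crit) not in piv.columns:
                    continue
                for site, ids in strata:
                    x = piv.loc[ids, (c_sys, crit)]
                    y = piv.loc[ids, (m_sys, crit)]
                    ok = x.notna() & y.notna()
                    row = {"cqa_system": c_sys, "mqa_system": m_sys,
                           "criterion": crit, "site": site,
                           "n": int(ok.sum())}
                    if ok.sum() < 5:
                        row.update(r=np.nan, p=np.nan, grade="empty",
                                   status="no overlap")
                    else:
                        try:
                            rep = spearman(x[ok], y[ok])
                            row.update(r=rep.r, p=rep.p, grade=rep.grade,
                                       status="ok")
                        except ConstantInputError:
                            row.update(r=np.nan, p=np.nan, grade="empty",
                                       status="constant input")
                    row["highlight"] = (row.get("grade") in
                                        ("weak", "moderate", "strong"))
                    rows.append(row)
    return pd.DataFrame(rows)


def r_pcm_qa_radar(table: QACohortTable, by_site: bool = False,
                   r_cut: float = 0.5, top_n: int = 10):
    """Per-metric |r_pcm-QA| radar table plus the PCMs% >= cut summary.

    Returns ``(radar, summary, top)``: the long radar table (metric, system,
    criterion, site, |r|, p, grade), the PCMs%>=cut summary per
    (system, criterion, site), and the per-system top-``top_n`` metric
    ranking at the strictest criterion.
    """
    piv = table.gpr_pivot()
    pcm = table.pcm_wide().reindex(piv.index)
    site_of = table.site_of()
    strata = [("all", piv.index)] if not by_site else [
        (site, piv.index.intersection(site_of.index[site_of == site]))
        for site in sorted(site_of.unique())]
    rows = []
    for system in table.systems:
        for crit in CRITERIA_ORDER:
            if (system, crit) not in piv.columns:
                continue
            for site, ids in strata:
                g = piv.loc[ids, (system, crit)]
                for metric in table.metrics:
                    x = pcm.loc[ids, metric]
                    ok = x.notna() & g.notna()
                    row = {"metric": metric, "system": system,
                           "criterion": crit, "site": site, "n": int(ok.sum())}
                    try:
                        rep = spearman(x[ok], g[ok]) if ok.sum() >= 5 else None
                    except ConstantInputError:
                        rep = None
                    if rep is None:
                        row.update(abs_r=np.nan, p=np.nan, grade="empty")
                    else:
                        row.update(abs_r=abs(rep.r), p=rep.p,
                                   grade=grade_correlation(rep.r))
                    rows.append(row)
    radar = pd.DataFrame(rows)

    def _summ(df):
        n_metrics = df["metric"].nunique()
        n_ge = int((df["abs_r"] >= r_cut).sum())
        return pd.Series({"n_metrics": n_metrics, "n_ge_cut": n_ge,
                          "pcms_pct_ge_cut": 100.0 * n_ge / n_metrics})

    summary = (radar.groupby(["system", "criterion", "site"])
               .apply(_summ, include_groups=False).reset_index())
    strict = radar[radar["criterion"] == STRICTEST]
    top = (strict.sort_values("abs_r", ascending=False)
           .groupby(["system", "site"], group_keys=False)
           .head(top_n).reset_index(drop=True))
    return radar, summary, top


# ---------------------------------------------------------------------------
# principal-component regression


@dataclass(frozen=True)
class PCRResult:
    r2: float
    n_components: int
    explained_variance: float
    coefficients: np.ndarray
    p: float
    n: int
    dropped_metrics: tuple[str, ...] = ()


def pcr_predict(pcm_matrix: pd.DataFrame, gpr_vector,
                variance_target: float = 0.90) -> PCRResult:
    """Principal-component regression of GPR on z-scored complexity metrics.

    Metrics are standardized, PCA on the correlation structure keeps the
    smallest k whose cumulative explained variance reaches
    ``variance_target``, and GPR is regressed on the k component scores by
    ordinary least squares.  Reports R^2 and the overall F-test p-value.
    Zero-variance metric columns are dropped with a warning before PCA.
    """
    from sklearn.decomposition import PCA

    X = pd.DataFrame(pcm_matrix).astype(float)
    y = np.asarray(gpr_vector, float)
    if X.shape[0] != y.size:
        raise ValueError("metric matrix and GPR vector length mismatch")
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X.loc[ok], y[ok]

    sd = X.std(axis=0, ddof=0)
    dropped = tuple(sd.index[sd <= 0])
    if dropped:
        warnings.warn(f"dropping zero-variance metrics: {list(dropped)}")
        X = X.drop(columns=list(dropped))
    n, p_all = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    pca = PCA(n_components=min(n - 1, p_all))
    scores = pca.fit_transform(Z.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target) + 1)
    k = min(k, scores.shape[1])
    if n <= k + 1:
        raise ValueError(f"n = {n} too small for {k} components")
    S = scores[:, :k]

    A = np.column_stack([np.ones(n), S])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        p_val = 0.0
    else:
        f_stat = ((ss_tot - ss_res) / k) / (ss_res / (n - k - 1))
        p_val = float(sps.f.sf(f_stat, k, n - k - 1))
    return PCRResult(r2=float(r2), n_components=k,
                     explained_variance=float(cum[k - 1]),
                     coefficients=beta[1:], p=p_val, n=n,
                     dropped_metrics=dropped)


# ---------------------------------------------------------------------------
# report bundle


def _gpr_summary(table: QACohortTable) -> pd.DataFrame:
    g = table.gpr.dropna(subset=["gpr"])
    out = (g.groupby(["system", "criterion"])["gpr"]
           .agg(["count", "median", "mean", "std", "min", "max"])
           .reset_index())
    return out


def median_gap_table(table: QACohortTable) -> pd.DataFrame:
    """Max difference in median GPR between CQA and MQA systems per criterion."""
    med = (table.gpr.dropna(subset=["gpr"])
           .groupby(["system", "criterion"])["gpr"].median().unstack("criterion"))
    cqa, mqa = _cqa_mqa_systems(med.index)
    rows = []
    for crit in CRITERIA_ORDER:
        if crit not in med.columns:
            continue
        diffs = [med.loc[c, crit] - med.loc[m, crit] for c in cqa for m in mqa]
        rows.append({"criterion": crit,
                     "max_median_gap": float(np.max(diffs)) if diffs else np.nan,
                     "median_cqa": float(med.loc[cqa, crit].median()),
                     "median_mqa": float(med.loc[mqa, crit].median())})
    return pd.DataFrame(rows)


def study_report(table: QACohortTable, out_dir: str | Path,
                 variance_target: float = 0.90,
                 site_strata: bool = True, min_n: int = 30) -> dict:
    """Write the CSV/Markdown report bundle; returns the tables in memory.

    Contents: GPR distribution summaries per system/criterion, the
    CQA-vs-MQA median-gap table, the r_calc-meas grid with grades, the
    |r_pcm-QA| radar with PCMs%>=0.5 and top-10 ranking, and PCR R^2 per
    system/criterion (pooled plans; per-site strata when requested and
    populated).  Deterministic: rerunning on the same table regenerates the
    same files bitwise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = _gpr_summary(table)
    gaps = median_gap_table(table)
    rcm = r_calc_meas_matrix(table, by_site=site_strata)
    radar, pcms_pct, top = r_pcm_qa_radar(table, by_site=site_strata)

    piv = table.gpr_pivot()
    pcm = table.pcm_wide().reindex(piv.index)
    site_of = table.site_of()
    pcr_rows = []
    strata = [("all", piv.index)]
    if site_strata:
        from .rtplan_io import SITES
        for site in SITES:
            ids = piv.index.intersection(site_of.index[site_of == site])
            strata.append((site, ids))
    for system in table.systems:
        for crit in CRITERIA_ORDER:
            if (system, crit) not in piv.columns:
                continue
            for site, ids in strata:
                y = piv.loc[ids, (system, crit)].dropna()
                if y.size < min_n:
                    continue
                X = pcm.loc[y.index]
                try:
                    res = pcr_predict(X, y.values, variance_target)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    pcr_rows.append({"system": system, "criterion": crit,
                                     "site": site, "n": int(y.size),
                                     "r2": np.nan, "k": np.nan, "p": np.nan,
                                     "status": str(exc)})
                    continue
                pcr_rows.append({"system": system, "criterion": crit,
                                 "site": site, "n": res.n, "r2": res.r2,
                                 "k": res.n_components, "p": res.p,
                                 "status": "ok"})
    pcr_df = pd.DataFrame(pcr_rows, columns=["system", "criterion", "site",
                                             "n", "r2", "k", "p", "status"])

    tables = {"gpr_summary": summary, "median_gaps": gaps,
              "r_calc_meas": rcm, "r_pcm_qa": radar,
              "pcms_pct": pcms_pct, "top_metrics": top, "pcr": pcr_df}
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g")

    lines = ["# QA cohort report", ""]
    empty_sites = [s for s, ids in strata if len(ids) == 0]
    for s in empty_sites:
        lines.append(f"*Site stratum '{s}' is empty; its sections are omitted.*")
    lines += ["", "## Median GPR gap (CQA - MQA) per criterion", "",
              gaps.to_markdown(index=False), "",
              "## PCMs% >= 0.5 per system/criterion (site = all)", "",
              pcms_pct[pcms_pct["site"] == "all"].to_markdown(index=False), "",
              "## PCR R^2 per system/criterion (site = all)", "",
              pcr_df[pcr_df["site"] == "all"].to_markdown(index=False), ""]
    (out_dir / "report.md").write_text("\n".join(lines))
    return tables
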