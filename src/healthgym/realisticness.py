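"""Three-stage realisticness validation of a synthetic cohort.

Stage one is visual: kernel-density overlays for numerics and side-by-side
class-share bars for categoricals.  Stage two is a hierarchical statistical
battery per variable: a two-sample Kolmogorov-Smirnov test first; on
failure, numeric variables get a pooled-variance t-test, a variance-ratio
F-test and a three-sigma range test, while categorical variables get an
ANOVA-style class-share F-test and the three-sigma test (on ordered class
codes).  No multiplicity correction is applied.  Stage three compares
Kendall rank-correlation structure: static (pooled over patients and
timesteps) and dynamic, where each patient's series is first linearly
decomposed into a least-squares trend plus residual cycle and correlations
are averaged over patients.

Categorical variables enter rank-based statistics through their declared
class order (clinically ordinal for coma scores and decile codes; for
nominal variables the result is order-dependent, which is documented
behaviour).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .gan import CorrelationMatrix
from .schema import NUMERIC, CohortSchema, LongitudinalDataset, SchemaError

DISTRIBUTION_MATCHED = "distribution_matched"
MOMENT_MATCHED = "moment_matched"
RANGE_PLAUSIBLE = "range_plausible"
FAILED = "failed"


# ---------------------------------------------------------------------------
# component tests
# ---------------------------------------------------------------------------

def ks_test(real_values, syn_values, kind: str = NUMERIC) -> Tuple[float, float]:
    """Two-sample KS test; categorical inputs must already be class codes."""
    real_values = np.asarray(real_values, dtype=float)
    syn_values = np.asarray(syn_values, dtype=float)
    res = stats.ks_2samp(real_values, syn_values, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_test(real_values, syn_values) -> Tuple[float, float]:
    """Two independent-sample Student's t-test with pooled variance."""
    real_values = np.asarray(real_values, dtype=float)
    syn_values = np.asarray(syn_values, dtype=float)
    if len(real_values) < 2 or len(syn_values) < 2:
        raise SchemaError("t-test needs at least 2 values per sample")
    res = stats.ttest_ind(real_values, syn_values, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def f_test(real_values, syn_values) -> Tuple[float, float]:
    """Variance-ratio F-test, two-sided via doubled tail probability."""
    real_values = np.asarray(real_values, dtype=float)
    syn_values = np.asarray(syn_values, dtype=float)
    if len(real_values) < 2 or len(syn_values) < 2:
        raise SchemaError("F-test needs at least 2 values per sample")
    v1 = real_values.var(ddof=1)
    v2 = syn_values.var(ddof=1)
    if v1 == 0 or v2 == 0:
        raise SchemaError("F-test undefined for zero-variance input")
    F = v1 / v2
    df1, df2 = len(real_values) - 1, len(syn_values) - 1
    tail = stats.f.cdf(F, df1, df2)
    p = 2.0 * min(tail, 1.0 - tail)
    return float(F), float(min(p, 1.0))


def anova_f_test(real_values, syn_values, classes) -> Tuple[float, float]:
    """Class-share comparison as a one-way ANOVA over class contrasts.

    For each class c the group holds the synthetic membership indicators
    centred by the real class share; group means are then the per-class
    share differences, so the F statistic is exactly 0 when the shares
    coincide and grows with any displaced class mass.
    """
    real_values = np.asarray(real_values)
    syn_values = np.asarray(syn_values)
    classes = list(classes)
    if len(classes) < 2:
        raise SchemaError("ANOVA F-test needs at least 2 classes")
    groups = []
    for c in classes:
        share_real = float((real_values == c).mean())
        groups.append((syn_values == c).astype(float) - share_real)
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def three_sigma_test(
    real_values, syn_values, kind: str = NUMERIC, threshold: float = 0.997
) -> Tuple[float, bool]:
    """Fraction of synthetic values inside the real mean +- 3 SD band."""
    real_values = np.asarray(real_values, dtype=float)
    syn_values = np.asarray(syn_values, dtype=float)
    m, s = real_values.mean(), real_values.std(ddof=1)
    inside = (syn_values >= m - 3 * s) & (syn_values <= m + 3 * s)
    frac = float(inside.mean())
    return frac, frac >= threshold


def verdict_of(
    ks_pass: bool,
    parametric_passes: Optional[List[bool]],
    three_sigma_pass: Optional[bool],
) -> str:
    """Pure hierarchy: KS pass ends the cascade; otherwise moment tests,
    then the plausible-range fallback."""
    if ks_pass:
        return DISTRIBUTION_MATCHED
    if parametric_passes and all(parametric_passes):
        return MOMENT_MATCHED
    if three_sigma_pass:
        return RANGE_PLAUSIBLE
    return FAILED


@dataclass
class VariableTestResult:
    variable: str
    kind: str
    ks: Tuple[float, float]
    t: Optional[Tuple[float, float]] = None
    f: Optional[Tuple[float, float]] = None
    anova_f: Optional[Tuple[float, float]] = None
    three_sigma: Optional[Tuple[float, bool]] = None
    verdict: str = FAILED


@dataclass
class ValidationReport:
    results: List[VariableTestResult]
    alpha: float
    static_tau_real: Optional[CorrelationMatrix] = None
    static_tau_syn: Optional[CorrelationMatrix] = None
    trend_tau_real: Optional[CorrelationMatrix] = None
    trend_tau_syn: Optional[CorrelationMatrix] = None
    cycle_tau_real: Optional[CorrelationMatrix] = None
    cycle_tau_syn: Optional[CorrelationMatrix] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "variable": r.variable,
                "kind": r.kind,
                "ks_stat": r.ks[0],
                "ks_p": r.ks[1],
                "t_p": r.t[1] if r.t else np.nan,
                "f_p": r.f[1] if r.f else np.nan,
                "anova_f_p": r.anova_f[1] if r.anova_f else np.nan,
                "three_sigma_frac": r.three_sigma[0] if r.three_sigma else np.nan,
                "verdict": r.verdict,
            })
        return pd.DataFrame(rows)

    def n_with_verdict(self, verdict: str) -> int:
        return sum(1 for r in self.results if r.verdict == verdict)

    def summary(self) -> str:
        df = self.to_frame()
        counts = df["verdict"].value_counts().to_dict()
        head = (
            f"Realisticness validation: {len(self.results)} variables, "
            f"alpha={self.alpha} — " +
            ", ".join(f"{k}: {v}" for k, v in counts.items())
        )
        return head + "\n" + df.to_string(index=False)


def hierarchical_validate(
    real: LongitudinalDataset,
    syn: LongitudinalDataset,
    alpha: float = 0.05,
    three_sigma_threshold: float = 0.997,
    include_correlations: bool = True,
) -> ValidationReport:
    """Run the full per-variable test hierarchy (stage two), optionally with
    the stage-three Kendall correlation matrices attached."""
    if real.schema.variable_names != syn.schema.variable_names:
        raise SchemaError("real and synthetic datasets have different schemas")
    results = []
    for v in real.schema.variables:
        rv = real.coded_column(v.name)
        sv = syn.coded_column(v.name)
        ks = ks_test(rv, sv, v.kind)
        res = VariableTestResult(v.name, v.kind, ks)
        if ks[1] >= alpha:
            res.verdict = DISTRIBUTION_MATCHED
        else:
            parametric = []
            if v.kind == NUMERIC:
                res.t = t_test(rv, sv)
                res.f = f_test(rv, sv)
                parametric = [res.t[1] >= alpha, res.f[1] >= alpha]
            else:
                codes = np.arange(len(v.classes), dtype=float)
                res.anova_f = anova_f_test(rv, sv, codes)
                parametric = [res.anova_f[1] >= alpha]
            res.three_sigma = three_sigma_test(
                rv, sv, v.kind, threshold=three_sigma_threshold
            )
            res.verdict = verdict_of(False, parametric, res.three_sigma[1])
        results.append(res)

    report = ValidationReport(results, alpha)
    if include_correlations:
        report.static_tau_real = static_kendall(real)
        report.static_tau_syn = static_kendall(syn)
        report.trend_tau_real, report.cycle_tau_real = dynamic_kendall(real)
        report.trend_tau_syn, report.cycle_tau_syn = dynamic_kendall(syn)
    return report


# ---------------------------------------------------------------------------
# stage three: correlations
# ---------------------------------------------------------------------------

def static_kendall(dataset: LongitudinalDataset) -> CorrelationMatrix:
    """Kendall tau-b over all variable pairs, pooled across patients and
    timesteps (class-coded for categorical variables)."""
    names = dataset.schema.variable_names
    cols = {n: dataset.coded_column(n) for n in names}
    C = len(names)
    r = np.eye(C)
    const = [n for n in names if np.ptp(cols[n]) == 0]
    for i, j in combinations(range(C), 2):
        if names[i] in const or names[j] in const:
            tau = 0.0
        else:
            tau = stats.kendalltau(cols[names[i]], cols[names[j]]).statistic
            tau = 0.0 if not np.isfinite(tau) else float(tau)
        r[i, j] = r[j, i] = tau
    return CorrelationMatrix(r, names, const)


def trend_cycle_decompose(series) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares linear trend and residual cycle; trend + cycle = series."""
    y = np.asarray(series, dtype=float)
    t = np.arange(len(y), dtype=float)
    slope, intercept = np.polyfit(t, y, 1) if len(y) > 1 else (0.0, float(y[0]))
    trend = intercept + slope * t
    return trend, y - trend


def dynamic_kendall(
    dataset: LongitudinalDataset,
) -> Tuple[CorrelationMatrix, CorrelationMatrix]:
    """Per-patient Kendall tau between variable pairs' trends and cycles,
    averaged over patients.

    A patient whose trend or cycle sequence is constant for a variable has
    undefined tau for that pair and is excluded from that pair's mean (the
    exclusion count is recorded on the returned matrices).  For two fitted
    lines, tau is the sign of the slope product, which is used directly.
    """
    names = dataset.schema.variable_names
    n, T = dataset.n_patients, dataset.schema.timesteps_per_patient
    panels = {m: dataset.panel(m) for m in names}
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    slopes = {m: (panels[m] - panels[m].mean(axis=1, keepdims=True)) @ tc / denom
              for m in names}
    cycles = {m: panels[m] - panels[m].mean(axis=1, keepdims=True)
              - slopes[m][:, None] * tc for m in names}

    C = len(names)
    trend_r, cycle_r = np.eye(C), np.eye(C)
    trend_excl, cycle_excl = {}, {}
    for i, j in combinations(range(C), 2):
        si, sj = slopes[names[i]], slopes[names[j]]
        defined = (si != 0) & (sj != 0)
        trend_excl[(names[i], names[j])] = int(n - defined.sum())
        trend_r[i, j] = trend_r[j, i] = (
            float(np.sign(si[defined] * sj[defined]).mean()) if defined.any() else 0.0
        )

        taus = []
        for p in range(n):
            ci, cj = cycles[names[i]][p], cycles[names[j]][p]
            if np.ptp(ci) == 0 or np.ptp(cj) == 0:
                continue
            tau = stats.kendalltau(ci, cj).statistic
            if np.isfinite(tau):
                taus.append(tau)
        cycle_excl[(names[i], names[j])] = n - len(taus)
        cycle_r[i, j] = cycle_r[j, i] = float(np.mean(taus)) if taus else 0.0

    tm = CorrelationMatrix(trend_r, names)
    cm = CorrelationMatrix(cycle_r, names)
    tm.excluded = trend_excl  # type: ignore[attr-defined]
    cm.excluded = cycle_excl  # type: ignore[attr-defined]
    return tm, cm


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_report(
    report: ValidationReport,
    real: LongitudinalDataset,
    syn: LongitudinalDataset,
    out_dir,
    top_k: int = 20,
) -> dict:
    """Write stage-one/-three figures and a machine-readable summary.

    Produces per-variable KDE overlays (real in orange, synthetic in blue)
    or class-share bars, side-by-side correlation heatmaps (red positive,
    blue negative), a strongest-pairs panel, and ``summary.csv`` /
    ``summary.json`` mirroring the hierarchical test table.  Returns a dict
    of written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if not report.results:
        raise SchemaError("empty report: no variables to render")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    # stage one: distributions
    n_vars = len(report.results)
    ncols = 4
    nrows = int(np.ceil(n_vars / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows))
    axes = np.atleast_1d(axes).ravel()
    for ax, res in zip(axes, report.results):
        v = real.schema[res.variable]
        if v.kind == NUMERIC:
            sns.kdeplot(real.column(v.name).astype(float), ax=ax,
                        color="tab:orange", label="real", fill=True, alpha=0.3)
            sns.kdeplot(syn.column(v.name).astype(float), ax=ax,
                        color="tab:blue", label="synthetic", fill=True, alpha=0.3)
        else:
            width = 0.4
            xs = np.arange(len(v.classes))
            rshare = [np.mean(real.column(v.name) == c) * 100 for c in v.classes]
            sshare = [np.mean(syn.column(v.name) == c) * 100 for c in v.classes]
            ax.bar(xs - width / 2, rshare, width, color="tab:orange", label="real")
            ax.bar(xs + width / 2, sshare, width, color="tab:blue", label="synthetic")
            ax.set_xticks(xs)
            ax.set_xticklabels(v.classes, rotation=45, fontsize=6)
        ax.set_title(f"{res.variable} [{res.verdict}]", fontsize=8)
    for ax in axes[n_vars:]:
        ax.axis("off")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    path = out / "distributions.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written["distributions"] = str(path)

    # stage three: correlation heatmaps
    def heatmap_pair(name, mat_real, mat_syn):
        if mat_real is None or mat_syn is None:
            return
        fig, (a, b) = plt.subplots(1, 2, figsize=(14, 6))
        for ax, mat, title in ((a, mat_real, "real"), (b, mat_syn, "synthetic")):
            sns.heatmap(mat.r, ax=ax, cmap="RdBu_r", vmin=-1, vmax=1,
                        xticklabels=mat.labels, yticklabels=mat.labels,
                        cbar=ax is b)
            ax.set_title(f"{name} Kendall tau ({title})", fontsize=10)
            ax.tick_params(labelsize=6)
        fig.tight_layout()
        p = out / f"{name}_correlations.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[f"{name}_correlations"] = str(p)

    heatmap_pair("static", report.static_tau_real, report.static_tau_syn)
    heatmap_pair("trend", report.trend_tau_real, report.trend_tau_syn)
    heatmap_pair("cycle", report.cycle_tau_real, report.cycle_tau_syn)

    if report.static_tau_real is not None:
        pairs = top_pairs(report.static_tau_real, top_k)
        rs = report.static_tau_syn.r
        labels = [f"{a} / {b}" for a, b, _ in pairs]
        rvals = [tau for _, _, tau in pairs]
        idx = {n: i for i, n in enumerate(report.static_tau_real.labels)}
        svals = [rs[idx[a], idx[b]] for a, b, _ in pairs]
        fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(pairs))))
        ys = np.arange(len(pairs))
        ax.barh(ys - 0.2, rvals, 0.4, color="tab:orange", label="real")
        ax.barh(ys + 0.2, svals, 0.4, color="tab:blue", label="synthetic")
        ax.set_yticks(ys)
        ax.set_yticklabels(labels, fontsize=6)
        ax.set_xlabel("Kendall tau")
        ax.legend()
        fig.tight_layout()
        p = out / "top_pairs.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written["top_pairs"] = str(p)

    df = report.to_frame()
    df.to_csv(out / "summary.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(json.loads(df.to_json(orient="records")), fh, indent=2)
    written["summary_csv"] = str(out / "summary.csv")
    written["summary_json"] = str(out / "summary.json")
    return written


def top_pairs(mat: CorrelationMatrix, k: int = 20) -> list:
    """The k strongest off-diagonal pairs by |tau|, strongest first."""
    C = mat.r.shape[0]
    entries = [
        (mat.labels[i], mat.labels[j], float(mat.r[i, j]))
        for i, j in combinations(range(C), 2)
    ]
    entries.sort(key=lambda e: abs(e[2]), reverse=True)
    return entries[:k]
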