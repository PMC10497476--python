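"""Agreement statistics and the framing-protocol comparison report.

Implements the quantitative machinery used to compare parametric results:
ROI means, absolute/relative differences, Bland-Altman limits of
agreement, squared Pearson correlation, paired t-tests, variance F-tests,
and a report generator that tabulates Ki/intercept per protocol against a
reference protocol across replicate phantoms ("subjects").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .idif import auc
from .patlak import PatlakResult

__all__ = [
    "roi_mean",
    "abs_diff",
    "rel_diff",
    "BlandAltman",
    "bland_altman",
    "correlation_r2",
    "paired_t_test",
    "variance_f_test",
    "ComparisonReport",
    "protocol_comparison",
]


def roi_mean(parametric_map: np.ndarray, labels: np.ndarray, label: int) -> float:
    """Unweighted mean of a parametric map over one labeled ROI."""
    m = np.asarray(labels) == label
    if not m.any():
        raise ValueError(f"label {label} selects no voxels")
    return float(np.asarray(parametric_map)[m].mean())


def abs_diff(p1: float, p2: float) -> float:
    """Absolute difference |p1 - p2|."""
    return abs(p1 - p2)


def rel_diff(p1: float, p2: float) -> float:
    """Relative difference (p1 - p2) / p2 (fractional; x100 for percent)."""
    if p2 == 0:
        raise ZeroDivisionError("relative difference undefined for p2 = 0")
    return (p1 - p2) / p2


@dataclass(frozen=True)
class BlandAltman:
    """Per-pair differences with mean bias and 1.96-SD limits of agreement."""

    means: np.ndarray
    diffs: np.ndarray
    bias: float
    loa_low: float
    loa_high: float
    mode: str


def bland_altman(a, b, mode: str = "relative") -> BlandAltman:
    """Bland-Altman agreement between paired measurements.

    ``relative`` mode uses (a - b)/b in percent; ``absolute`` uses a - b.
    The x-axis value is the pairwise mean (a + b)/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if mode == "relative":
        diffs = (a - b) / b * 100.0
    elif mode == "absolute":
        diffs = a - b
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        means=(a + b) / 2.0,
        diffs=diffs,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        mode=mode,
    )


def correlation_r2(a, b) -> float:
    """Squared Pearson correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    Identical samples give (0, 1); zero-variance nonzero differences have
    an undefined t statistic and are reported as (nan, nan).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired test needs equal-length samples of size >= 2")
    d = a - b
    if d.std(ddof=1) == 0:
        return (0.0, 1.0) if np.all(d == 0) else (float("nan"), float("nan"))
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def variance_f_test(a, b) -> tuple[float, float]:
    """Two-sided F-test comparing the variances of two samples.

    F = var(a)/var(b) with (n_a - 1, n_b - 1) degrees of freedom;
    p = 2 * min(P(F' <= F), P(F' >= F)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("F-test needs at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 or va == 0:
        if va == vb:
            return 1.0, 1.0
        raise ValueError("F-test undefined for a zero-variance sample")
    F = float(va / vb)
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(p, 1.0))


def _as_result_list(v) -> list[PatlakResult]:
    if isinstance(v, PatlakResult):
        return [v]
    return list(v)


@dataclass
class ComparisonReport:
    """Protocol-comparison tables (one row per ROI, one column per protocol).

    ``ki_mean``/``ki_sd`` are in uL/min/cm^3 across replicates; the
    ``*_rel_diff_*`` tables are percent differences versus the reference
    protocol, paired by replicate. The reference's own columns are
    exactly zero by construction.
    """

    reference: str
    ki_mean: pd.DataFrame
    ki_sd: pd.DataFrame
    intercept_mean: pd.DataFrame
    intercept_sd: pd.DataFrame
    ki_rel_diff_mean: pd.DataFrame
    ki_rel_diff_sd: pd.DataFrame
    intercept_rel_diff_mean: pd.DataFrame
    intercept_rel_diff_sd: pd.DataFrame
    t_test: pd.DataFrame
    f_test: pd.DataFrame
    auc_rel_err: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def to_csv(self, out_dir) -> list[str]:
        """Write every table as CSV into ``out_dir``; returns the paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in (
            "ki_mean",
            "ki_sd",
            "intercept_mean",
            "intercept_sd",
            "ki_rel_diff_mean",
            "ki_rel_diff_sd",
            "intercept_rel_diff_mean",
            "intercept_rel_diff_sd",
            "t_test",
            "f_test",
            "auc_rel_err",
        ):
            table = getattr(self, name)
            if table is None:
                continue
            path = out / f"{name}.csv"
            table.to_csv(path, float_format="%.10g")
            written.append(str(path))
        return written


def protocol_comparison(
    results: Mapping[str, Mapping[str, PatlakResult | Sequence[PatlakResult]]],
    reference: str,
    idifs: Mapping[str, Sequence] | None = None,
) -> ComparisonReport:
    """Compare per-ROI Patlak scalars across framing protocols.

    Parameters
    ----------
    results : mapping
        ``results[protocol][roi]`` is a PatlakResult or a sequence of them
        (one per replicate phantom / subject); all protocols must share
        the same ROI set and replicate count.
    reference : str
        Protocol against which differences are computed.
    idifs : mapping, optional
        ``idifs[protocol]`` = input function(s) per replicate; enables the
        0-60 min AUC relative-error table.

    The variance F-test on each protocol's pooled relative-difference
    sample uses the first non-reference protocol as its comparison sample
    (the reference's own differences are identically zero, so its variance
    cannot anchor an F-test).
    """
    protocols = list(results)
    if reference not in protocols:
        raise ValueError(f"reference protocol {reference!r} not in results")
    rois = list(results[reference])
    for p in protocols:
        if list(results[p]) != rois:
            raise ValueError(f"protocol {p!r} has a different ROI set")

    ki = {
        p: {r: np.array([res.ki for res in _as_result_list(results[p][r])]) for r in rois}
        for p in protocols
    }
    ic = {
        p: {
            r: np.array([res.intercept for res in _as_result_list(results[p][r])])
            for r in rois
        }
        for p in protocols
    }
    n_rep = ki[reference][rois[0]].size
    for p in protocols:
        for r in rois:
            if ki[p][r].size != n_rep:
                raise ValueError("replicate counts differ across protocols/ROIs")

    def table(values, fn):
        return pd.DataFrame(
            {p: [fn(values[p][r]) for r in rois] for p in protocols}, index=rois
        )

    sd = (lambda v: float(np.std(v, ddof=1))) if n_rep > 1 else (lambda v: 0.0)

    ki_mean = table(ki, lambda v: float(np.mean(v)) * 1000.0)  # uL/min/cm^3
    ki_sd = table(ki, lambda v: sd(v) * 1000.0)
    ic_mean = table(ic, lambda v: float(np.mean(v)))
    ic_sd = table(ic, sd)

    def rel_tables(values):
        mean_t = pd.DataFrame(index=rois, columns=protocols, dtype=float)
        sd_t = pd.DataFrame(index=rois, columns=protocols, dtype=float)
        pooled = {}
        for p in protocols:
            diffs_all = []
            for r in rois:
                if p == reference:
                    d = np.zeros(n_rep)
                else:
                    d = (values[p][r] - values[reference][r]) / values[reference][r] * 100.0
                mean_t.loc[r, p] = float(d.mean())
                sd_t.loc[r, p] = sd(d)
                diffs_all.append(d)
            pooled[p] = np.concatenate(diffs_all)
        return mean_t, sd_t, pooled

    ki_rd_mean, ki_rd_sd, ki_pooled = rel_tables(ki)
    ic_rd_mean, ic_rd_sd, ic_pooled = rel_tables(ic)

    # paired t-test per ROI and protocol on Ki replicates vs the reference
    t_rows = []
    for r in rois:
        row = {}
        for p in protocols:
            if p == reference or n_rep < 2:
                row[p] = np.nan
            else:
                row[p] = paired_t_test(ki[p][r], ki[reference][r])[1]
        t_rows.append(row)
    t_test = pd.DataFrame(t_rows, index=rois)

    # F-test of pooled relative-difference variance vs the first
    # non-reference protocol's sample
    others = [p for p in protocols if p != reference]
    f_rows = {}
    if others:
        base = others[0]
        for p in protocols:
            row = {}
            for tag, pooled in (("ki", ki_pooled), ("intercept", ic_pooled)):
                if p == reference or pooled[p].size < 2 or p == base:
                    row[f"{tag}_F"], row[f"{tag}_p"] = (
                        (1.0, 1.0) if p == base else (np.nan, np.nan)
                    )
                else:
                    F, pv = variance_f_test(pooled[p], pooled[base])
                    row[f"{tag}_F"], row[f"{tag}_p"] = F, pv
            f_rows[p] = row
    f_test = pd.DataFrame(f_rows).T

    auc_table = None
    if idifs is not None:
        missing = [p for p in protocols if p not in idifs]
        if missing:
            raise ValueError(f"idifs missing for protocols: {missing}")
        aucs = {}
        for p in protocols:
            lst = idifs[p] if isinstance(idifs[p], (list, tuple)) else [idifs[p]]
            if len(lst) != n_rep:
                raise ValueError("IDIF replicate count differs from results")
            end_min = min(i.schedule.end_time_s for i in lst) / 60.0
            aucs[p] = np.array([auc(i, 0.0, min(60.0, end_min)) for i in lst])
        err = {
            p: (aucs[p] - aucs[reference]) / aucs[reference] * 100.0
            for p in protocols
        }
        auc_table = pd.DataFrame(
            {
                "auc_rel_err_mean": {p: float(err[p].mean()) for p in protocols},
                "auc_rel_err_sd": {p: sd(err[p]) for p in protocols},
            }
        )

    return ComparisonReport(
        reference=reference,
        ki_mean=ki_mean,
        ki_sd=ki_sd,
        intercept_mean=ic_mean,
        intercept_sd=ic_sd,
        ki_rel_diff_mean=ki_rd_mean,
        ki_rel_diff_sd=ki_rd_sd,
        intercept_rel_diff_mean=ic_rd_mean,
        intercept_rel_diff_sd=ic_rd_sd,
        t_test=t_test,
        f_test=f_test,
        auc_rel_err=auc_table,
        notes={"n_replicates": n_rep, "rois": rois},
    )
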