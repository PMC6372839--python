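"""Time-course significance testing.

Each feature's replicate x time matrix from the oxygen-exposed arm is
subjected to a classical one-within-factor repeated-measures ANOVA with
time as a categorical factor (no functional form of the response is
assumed), giving one p-value per feature; p-values are corrected across
the features of one omic layer with the Benjamini-Hochberg step-up
procedure; features are then filtered with the dual rule
|fold change| > threshold AND FDR < threshold (strict comparisons, as
the thresholds are printed). The anaerobic control arm is not tested —
its sampling is sparser and not statistically comparable.

Unbalanced data are handled by complete-case reduction: a replicate
(subject) missing any time level is dropped for that feature, keeping
the closed-form sum-of-squares decomposition exact. No sphericity
correction is applied; that choice is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from oxshift.data_model import NormalizedSeries, SignificanceThresholds, StudyDesign


@dataclass
class AnovaResult:
    """One-within-factor repeated-measures ANOVA summary for a feature."""

    feature: str
    f_stat: float
    df_time: int
    df_error: int
    p_value: float
    fdr: float | None = None
    n_subjects: int = 0
    n_times: int = 0
    degenerate: bool = False


class InsufficientDataError(ValueError):
    """Fewer than 2 complete subjects or 2 time levels remain."""


def rm_anova(values: np.ndarray, feature: str = "") -> AnovaResult:
    """Repeated-measures ANOVA on a subject x time matrix.

    Partitions total variance into subject, time (categorical), and
    error components:

        SS_subject = t * sum_i (ybar_i. - ybar)^2
        SS_time    = n * sum_j (ybar_.j - ybar)^2
        SS_error   = SS_total - SS_subject - SS_time
        F = [SS_time / (t-1)] / [SS_error / ((t-1)(n-1))]

    Subjects (rows) with any missing value are dropped first. Degenerate
    inputs: no variance at all -> F = 0, p = 1; zero error with nonzero
    time effect -> p = 0 with the ``degenerate`` flag set.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2-D subject x time matrix")
    complete = ~np.isnan(y).any(axis=1)
    y = y[complete]
    n, t = y.shape
    if n < 2 or t < 2:
        raise InsufficientDataError(
            f"insufficient_subjects: {n} complete subject(s), {t} time level(s)"
        )
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_subject = t * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_time
    df_time = t - 1
    df_error = (t - 1) * (n - 1)
    # numerical guard: tiny negative residual from cancellation;
    # thresholds relative to SS_total so the test is scale-free
    ss_error = max(ss_error, 0.0)
    if ss_error <= 1e-12 * ss_total:
        if ss_time <= 1e-12 * ss_total:
            return AnovaResult(feature, 0.0, df_time, df_error, 1.0,
                               n_subjects=n, n_times=t)
        return AnovaResult(feature, float("inf"), df_time, df_error, 0.0,
                           n_subjects=n, n_times=t, degenerate=True)
    f_stat = (ss_time / df_time) / (ss_error / df_error)
    p = float(sps.f.sf(f_stat, df_time, df_error))
    return AnovaResult(feature, float(f_stat), df_time, df_error, p,
                       n_subjects=n, n_times=t)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in the input order.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1. Ties share a value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significance_filter(
    series: NormalizedSeries | dict[int, float],
    result: AnovaResult,
    thr: SignificanceThresholds,
) -> tuple[bool, str]:
    """Dual threshold: FDR < max_fdr AND max |linear fold change| over
    the time course > min_abs_fold_change. Returns (significant, reason);
    ``reason`` names the failed criterion."""
    if isinstance(series, NormalizedSeries):
        max_abs_l2 = series.max_abs_log2fc()
    else:
        vals = [v for v in series.values() if np.isfinite(v)]
        max_abs_l2 = max(abs(v) for v in vals) if vals else float("nan")
    if not np.isfinite(max_abs_l2):
        return False, "no_data"
    if result.fdr is None:
        raise ValueError("AnovaResult lacks an FDR value; run bh_adjust first")
    fdr_ok = result.fdr < thr.max_fdr
    fc_ok = 2.0**max_abs_l2 > thr.min_abs_fold_change
    if fdr_ok and fc_ok:
        return True, "ok"
    if not fdr_ok and not fc_ok:
        return False, "fdr+fold_change"
    return (False, "fdr") if not fdr_ok else (False, "fold_change")


def run_stats(
    matrix: pd.DataFrame,
    design: StudyDesign,
    condition: str = "O2",
    thr: SignificanceThresholds = SignificanceThresholds(),
    assay: str = "metabolomics_intra",
    fold_changes: dict[str, NormalizedSeries | dict[int, float]] | None = None,
) -> pd.DataFrame:
    """Per-feature ANOVA + BH FDR + dual-threshold filter for one layer.

    ``matrix`` is feature x sample (columns are sample ids) on the scale
    the layer is tested on (corrected intensities for metabolites, TPM
    for transcripts, log2 LFQ for proteins). The FDR family is exactly
    the set of features tested in this call. ``fold_changes`` supplies
    the baseline-normalized series used by the fold-change criterion;
    when omitted, log2 fold changes are computed from time-point means
    of the matrix itself (valid for positive-scale layers).

    Returns a DataFrame with columns feature, f_stat, df_time, df_error,
    p_value, fdr, max_abs_fc, significant, reason (skipped features keep
    their row with reason ``insufficient_subjects``).
    """
    samples = [m for m in design.samples(assay) if m.condition == condition]
    times = sorted({m.time_min for m in samples})
    reps = sorted({m.replicate for m in samples})
    sid = {
        (m.time_min, m.replicate): m.sample_id
        for m in samples
        if m.sample_id in matrix.columns
    }

    results: list[AnovaResult] = []
    skipped: list[str] = []
    for feature in matrix.index:
        y = np.full((len(reps), len(times)), np.nan)
        for a, r in enumerate(reps):
            for b, t in enumerate(times):
                key = (t, r)
                if key in sid:
                    y[a, b] = matrix.at[feature, sid[key]]
        try:
            results.append(rm_anova(y, feature))
        except InsufficientDataError:
            skipped.append(feature)

    fdr = bh_adjust([r.p_value for r in results]) if results else np.array([])
    for r, q in zip(results, fdr):
        r.fdr = float(q)

    rows = []
    for r in results:
        if fold_changes is not None and r.feature in fold_changes:
            fc_series = fold_changes[r.feature]
        else:
            sub = np.array(
                [
                    np.nanmean(
                        [
                            matrix.at[r.feature, sid[(t, rep)]]
                            for rep in reps
                            if (t, rep) in sid
                        ]
                    )
                    for t in times
                ]
            )
            base = sub[times.index(0)] if 0 in times else sub[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                fc_series = dict(zip(times, np.log2(sub / base)))
        sig, reason = significance_filter(fc_series, r, thr)
        if isinstance(fc_series, NormalizedSeries):
            max_l2 = fc_series.max_abs_log2fc()
        else:
            finite = [abs(v) for v in fc_series.values() if np.isfinite(v)]
            max_l2 = max(finite) if finite else float("nan")
        rows.append(
            {
                "feature": r.feature,
                "f_stat": r.f_stat,
                "df_time": r.df_time,
                "df_error": r.df_error,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "max_abs_fc": 2.0**max_l2 if np.isfinite(max_l2) else np.nan,
                "significant": sig,
                "reason": reason,
            }
        )
    for feature in skipped:
        rows.append(
            {
                "feature": feature,
                "f_stat": np.nan,
                "df_time": 0,
                "df_error": 0,
                "p_value": np.nan,
                "fdr": np.nan,
                "max_abs_fc": np.nan,
                "significant": False,
                "reason": "insufficient_subjects",
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["sphericity_correction"] = "none"
    out.attrs["condition"] = condition
    return out
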