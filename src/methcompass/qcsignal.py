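"""Array-wide signal QC: medians, failure calls, study fractions, comparisons.

A sample is called failed when it fails at least one BeadArray control, or
when BOTH its log2 median methylated and log2 median unmethylated signals fall
below a threshold (default 11, the conventional low-signal cut). Study-level
failure fractions (f_st) flag studies above 60% failures, with a minimum-size
filter applied to flagging only. Label enrichment among failed samples uses
exact binomial tests with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "summarize_signals",
    "assess_sample_failure",
    "study_failure_fractions",
    "label_enrichment",
    "storage_condition_comparison",
]


def summarize_signals(signals) -> pd.DataFrame:
    """Per-sample log2 median methylated/unmethylated intensity.

    Medians are taken across the full shared probe universe; an even count
    uses the midpoint mean. Nonpositive medians (log undefined) and
    all-missing samples raise.
    """
    meth = signals.meth.to_numpy(dtype=float)
    unmeth = signals.unmeth.to_numpy(dtype=float)
    if meth.shape[0] < 1:
        raise ValueError("need >= 1 probe per sample")
    med_m = np.median(meth, axis=0)
    med_u = np.median(unmeth, axis=0)
    if not (np.isfinite(med_m).all() and np.isfinite(med_u).all()):
        raise ValueError("sample with missing intensities")
    if (med_m <= 0).any() or (med_u <= 0).any():
        raise ValueError("nonpositive median intensity: log2 undefined")
    return pd.DataFrame(
        {
            "log2_median_meth": np.log2(med_m),
            "log2_median_unmeth": np.log2(med_u),
        },
        index=signals.meth.columns,
    )


def assess_sample_failure(
    summaries: pd.DataFrame,
    outcomes: pd.DataFrame,
    signal_threshold: float = 11.0,
) -> pd.DataFrame:
    """Per-sample failure flag with reasons.

    failed iff (i) any BeadArray control failed OR (ii) both log2 medians
    < ``signal_threshold``.
    """
    missing = summaries.index.difference(outcomes.index)
    if len(missing):
        raise KeyError(f"samples missing from outcomes: {list(missing[:5])}")
    out = outcomes.loc[summaries.index]
    control_fail = (out == 0).any(axis=1)
    signal_fail = (summaries["log2_median_meth"] < signal_threshold) & (
        summaries["log2_median_unmeth"] < signal_threshold
    )
    return pd.DataFrame(
        {
            "failed": control_fail | signal_fail,
            "control_failure": control_fail,
            "signal_failure": signal_fail,
        }
    )


def study_failure_fractions(
    flags: pd.DataFrame,
    study_ids: pd.Series,
    fst_cutoff: float = 0.60,
    min_study_size: int = 10,
) -> tuple[pd.DataFrame, list]:
    """Per-study failure fraction f_st with a failure-mode breakdown.

    The table reports every study; the flagged list excludes studies with
    <= ``min_study_size`` samples (the size filter affects flagging only).
    Breakdown: control-only / signal-only / either (both reasons).
    """
    study = study_ids.reindex(flags.index)
    if study.isna().any():
        raise ValueError("every sample needs a study id")
    rows = []
    for sid, grp in flags.groupby(study):
        n = len(grp)
        failed = grp["failed"]
        n_failed = int(failed.sum())
        control_only = int((grp["control_failure"] & ~grp["signal_failure"]).sum())
        signal_only = int((grp["signal_failure"] & ~grp["control_failure"]).sum())
        either = int((grp["control_failure"] & grp["signal_failure"]).sum())
        rows.append(
            {
                "study": sid,
                "n_samples": n,
                "n_failed": n_failed,
                "f_st": n_failed / n,
                "control_only": control_only,
                "signal_only": signal_only,
                "both": either,
            }
        )
    table = pd.DataFrame(rows).set_index("study")
    flagged = table.index[
        (table["f_st"] > fst_cutoff) & (table["n_samples"] > min_study_size)
    ]
    return table, list(flagged)


def label_enrichment(
    flags: pd.Series | pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Label over-representation among failed samples.

    Per label (binary column of ``labels``): exact binomial test of the label
    count among failed samples, success probability = label frequency among
    all samples; BH adjustment across labels; enriched iff adjusted p < alpha
    and observed > expected. Labels present in zero samples are skipped.
    """
    if isinstance(flags, pd.DataFrame):
        flags = flags["failed"]
    failed_idx = flags.index[flags.astype(bool)]
    if len(failed_idx) == 0:
        raise ValueError("no failed samples")
    labels = labels.reindex(flags.index).fillna(False).astype(bool)
    rows = []
    for term in labels.columns:
        freq = labels[term].mean()
        if freq == 0:
            warnings.warn(f"label {term!r} present in zero samples; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        k = int(labels.loc[failed_idx, term].sum())
        n = len(failed_idx)
        p = stats.binomtest(k, n, freq).pvalue
        rows.append(
            {"label": term, "observed": k, "expected": n * freq, "p_value": p}
        )
    table = pd.DataFrame(rows).set_index("label")
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["enriched"] = (table["p_adjusted"] < alpha) & (
            table["observed"] > table["expected"]
        )
    return table


def _confidence_ellipse(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> dict:
    """Bivariate normal confidence-ellipse parameters for a point cloud."""
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    scale = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return {
        "center": (float(np.mean(x)), float(np.mean(y))),
        "width": float(2 * np.sqrt(scale * evals[0])),
        "height": float(2 * np.sqrt(scale * evals[1])),
        "angle_degrees": angle,
    }


def storage_condition_comparison(
    summaries: pd.DataFrame,
    outcomes: pd.DataFrame,
    condition: pd.Series,
) -> dict:
    """Compare FFPE vs fresh-frozen signal variance and control failures.

    Returns per-condition variances of the log2 median signals, per-control
    failure percentages with their FFPE-FF differences, and 95% bivariate
    confidence-ellipse parameters of the (meth, unmeth) summary cloud.
    """
    condition = condition.reindex(summaries.index)
    levels = [lv for lv in ("FFPE", "FF") if (condition == lv).any()]
    if len(levels) < 2:
        raise ValueError("both storage conditions must be non-empty")
    variances, ellipses, fail_pct = {}, {}, {}
    for lv in levels:
        idx = condition.index[condition == lv]
        if len(idx) < 2:
            raise ValueError(f"condition {lv} has a single sample: variance undefined")
        sub = summaries.loc[idx]
        variances[lv] = {
            "meth": float(sub["log2_median_meth"].var(ddof=1)),
            "unmeth": float(sub["log2_median_unmeth"].var(ddof=1)),
        }
        ellipses[lv] = _confidence_ellipse(
            sub["log2_median_meth"].to_numpy(), sub["log2_median_unmeth"].to_numpy()
        )
        fail_pct[lv] = (1 - outcomes.loc[idx]).mean(axis=0) * 100.0
    diff = fail_pct[levels[0]] - fail_pct[levels[1]]
    return {
        "variances": variances,
        "failure_percent": pd.DataFrame(fail_pct),
        "failure_percent_difference": diff,
        "ellipses": ellipses,
    }
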