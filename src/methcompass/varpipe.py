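"""Seven-tissue DNAm variability analysis: filters and probe selection.

Stages, per tissue, on study-adjusted autosomal Beta-values:

1. sample filtering — drop samples failing any BeadArray control or with both
   log2 median signals below their within-study 5th percentile, then drop
   non-representative replicate samples;
2. covariate probe filtering — drop probes whose variance has a substantial
   (percent variance >= 10%) and significant (BH-adjusted p < 0.01)
   contribution from age, sex or cell fractions (per-probe sequential ANOVA);
3. two-step quantile variance selection — the intersection of (i) the extreme
   decile of per-probe variance and (ii) the extreme decile of variance
   within each mean-Beta bin (10 bins of width 0.1);
4. cross-tissue combination — shared low-variance probes pass the low filter
   in every tissue with cross-tissue mean range < 0.01; tissue-specific
   high-variance probes pass the high filter in exactly one tissue (top
   2000 by variance retained);
5. genome-context enrichment of a selection against a background probe set
   (binomial tests, BH-adjusted).

Quantile membership is rank-based: the ceil(q*n) most extreme probes, ties
broken by probe id, which makes selections deterministic and reproduces the
fixed selection sizes of the published workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .predict import detect_replicates

__all__ = [
    "VarianceFilterConfig",
    "TwoStepVarianceSelector",
    "two_step_select",
    "CovariateVarianceFilter",
    "covariate_probe_filter",
    "filter_low_quality_samples",
    "select_low_variance_shared",
    "select_tissue_specific",
    "region_enrichment",
]


@dataclass(frozen=True)
class VarianceFilterConfig:
    quantile: float = 0.10
    n_bins: int = 10
    bin_width: float = 0.1
    low_mean_range_cut: float = 0.01
    covariate_pct_cut: float = 0.10
    covariate_p_cut: float = 0.01
    top_k_per_tissue: int = 2000
    combine: str = "intersection"  # or "union" for sensitivity analysis

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 0.5):
            raise ValueError("quantile must lie in (0, 0.5)")
        if abs(self.n_bins * self.bin_width - 1.0) > 1e-9:
            raise ValueError("n_bins * bin_width must equal 1")
        if self.combine not in ("intersection", "union"):
            raise ValueError("combine must be 'intersection' or 'union'")


def _extreme_rank_mask(values: pd.Series, k: int, largest: bool) -> np.ndarray:
    """Boolean mask of the k most extreme entries, ties broken by index."""
    ids = values.index.to_numpy()
    v = values.to_numpy(dtype=float)
    key = -v if largest else v
    order = np.lexsort((ids, key))
    mask = np.zeros(len(v), dtype=bool)
    mask[order[:k]] = True
    return mask


class TwoStepVarianceSelector(BaseEstimator):
    """Two-step (absolute + binned) quantile variance probe selector.

    X in :meth:`fit` is samples x probes (DataFrame; columns are probe ids).
    ``direction='low'`` targets the least variable decile, ``'high'`` the most
    variable. Fitted attributes: ``variances_``, ``means_``, ``absolute_mask_``,
    ``binned_mask_``, ``support_``.
    """

    def __init__(self, direction: str = "low",
                 config: VarianceFilterConfig = VarianceFilterConfig()):
        self.direction = direction
        self.config = config

    def fit(self, X: pd.DataFrame, y=None):
        if self.direction not in ("low", "high"):
            raise ValueError("direction must be 'low' or 'high'")
        cfg = self.config
        n_probes = X.shape[1]
        if n_probes * cfg.quantile < 1:
            raise ValueError("fewer than 1/quantile probes")
        var = X.var(axis=0, ddof=1)
        mean = X.mean(axis=0)
        largest = self.direction == "high"

        k_abs = ceil(cfg.quantile * n_probes)
        absolute = _extreme_rank_mask(var, k_abs, largest)

        bins = np.minimum(
            (mean.to_numpy() / cfg.bin_width).astype(int), cfg.n_bins - 1
        )
        binned = np.zeros(n_probes, dtype=bool)
        for b in range(cfg.n_bins):
            members = np.nonzero(bins == b)[0]
            if members.size == 0:
                continue  # empty bin: no probes can qualify from it
            k_bin = ceil(cfg.quantile * members.size)
            sub = _extreme_rank_mask(var.iloc[members], k_bin, largest)
            binned[members[sub]] = True

        self.variances_ = var
        self.means_ = mean
        self.bins_ = pd.Series(bins, index=X.columns)
        self.absolute_mask_ = pd.Series(absolute, index=X.columns)
        self.binned_mask_ = pd.Series(binned, index=X.columns)
        if cfg.combine == "intersection":
            self.support_ = self.absolute_mask_ & self.binned_mask_
        else:
            self.support_ = self.absolute_mask_ | self.binned_mask_
        return self

    def get_support(self) -> pd.Series:
        return self.support_


def two_step_select(
    matrix: pd.DataFrame,
    direction: str = "low",
    config: VarianceFilterConfig = VarianceFilterConfig(),
) -> pd.Series:
    """Two-step selection on a probes x samples matrix (thin wrapper)."""
    sel = TwoStepVarianceSelector(direction=direction, config=config).fit(matrix.T)
    return sel.get_support()


class CovariateVarianceFilter(BaseEstimator):
    """Drop probes with substantial, significant covariate-driven variance.

    Per probe, a sequential ANOVA of Beta on the covariate design (age, sex,
    cell fractions, in that order); per covariate the percent variance
    (sequential SS / total SS) and F-test p-value, BH-adjusted across probes
    within the covariate. A probe is dropped iff ANY covariate reaches both
    ``covariate_pct_cut`` and (adjusted) ``covariate_p_cut``. X is
    samples x probes; covariates a samples-indexed DataFrame with columns
    'age', 'sex' and cell-fraction columns (one fraction is dropped
    internally — they sum to 1).
    """

    def __init__(self, config: VarianceFilterConfig = VarianceFilterConfig()):
        self.config = config

    @staticmethod
    def _design_blocks(cov: pd.DataFrame) -> list:
        blocks = []
        if "age" in cov:
            blocks.append(("age", cov[["age"]].to_numpy(dtype=float)))
        if "sex" in cov:
            sex = (cov["sex"].astype(str) == "female").to_numpy(dtype=float)
            blocks.append(("sex", sex[:, None]))
        cell_cols = [c for c in cov.columns if c not in ("age", "sex")]
        if cell_cols:
            # fractions live on the simplex: drop the last column
            blocks.append(("cell", cov[cell_cols[:-1]].to_numpy(dtype=float)))
        return blocks

    def fit(self, X: pd.DataFrame, covariates: pd.DataFrame):
        cfg = self.config
        Y = X.to_numpy(dtype=float)
        n = Y.shape[0]
        if not covariates.index.equals(X.index):
            covariates = covariates.loc[X.index]
        blocks = self._design_blocks(covariates)

        basis = [np.full((n, 1), 1.0 / np.sqrt(n))]
        group_cols: list = []
        kept_blocks = []
        for name, block in blocks:
            cols = []
            for j in range(block.shape[1]):
                v = block[:, j].copy()
                for q in np.hstack(basis).T:
                    v -= (q @ v) * q
                norm = np.linalg.norm(v)
                if norm < 1e-8 * max(1.0, np.linalg.norm(block[:, j])):
                    continue
                basis.append((v / norm)[:, None])
                cols.append(len(basis) - 2)  # index among non-intercept columns
            if not cols:
                warnings.warn(f"covariate {name!r} constant or aliased; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            group_cols.append((name, cols))
            kept_blocks.append(name)

        Q = np.hstack(basis[1:])  # n x q, orthonormal, intercept removed
        C = Q.T @ Y  # per-column projections
        col_ss = C**2
        sst = (Y**2).sum(axis=0) - n * Y.mean(axis=0) ** 2
        sst = np.maximum(sst, 1e-300)
        rss = np.maximum(sst - col_ss.sum(axis=0), 0.0)
        df_res = n - 1 - Q.shape[1]

        pct = {}
        pval = {}
        padj = {}
        for name, cols in group_cols:
            ss = col_ss[cols].sum(axis=0)
            pct[name] = ss / sst
            f = (ss / len(cols)) / np.maximum(rss / df_res, 1e-300)
            p = stats.f.sf(f, len(cols), df_res)
            pval[name] = p
            padj[name] = multipletests(p, method="fdr_bh")[1]

        drop = np.zeros(Y.shape[1], dtype=bool)
        for name in pct:
            drop |= (pct[name] >= cfg.covariate_pct_cut) & (
                padj[name] < cfg.covariate_p_cut
            )
        self.percent_variance_ = pd.DataFrame(pct, index=X.columns)
        self.p_values_ = pd.DataFrame(pval, index=X.columns)
        self.p_adjusted_ = pd.DataFrame(padj, index=X.columns)
        self.dropped_ = pd.Series(drop, index=X.columns)
        self.support_ = ~self.dropped_
        return self

    def get_support(self) -> pd.Series:
        return self.support_


def covariate_probe_filter(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame,
    config: VarianceFilterConfig = VarianceFilterConfig(),
) -> pd.Series:
    """Retained-probe mask for a probes x samples matrix (thin wrapper)."""
    filt = CovariateVarianceFilter(config=config).fit(matrix.T, covariates)
    return filt.get_support()


def filter_low_quality_samples(
    panel,
    summaries: pd.DataFrame,
    outcomes: pd.DataFrame,
    study_quantile: float = 0.05,
    replicate_tau: float = 0.1,
):
    """Remove low-quality and replicate samples from a tissue panel.

    A sample is removed when it fails >= 1 BeadArray control, or when BOTH its
    log2 median signals fall below the within-study ``study_quantile``; then
    non-representative replicate samples (SNP-probe identity) are removed.
    Returns (filtered panel, removal log).
    """
    sm = panel.samples
    missing = sm.index.difference(summaries.index).union(
        sm.index.difference(outcomes.index)
    )
    if len(missing):
        raise KeyError(f"QC inputs missing samples: {list(missing[:5])}")
    summ = summaries.loc[sm.index]
    ctrl_fail = (outcomes.loc[sm.index] == 0).any(axis=1)

    low_both = pd.Series(False, index=sm.index)
    for _, grp in summ.groupby(sm["study"]):
        qm = np.quantile(grp["log2_median_meth"], study_quantile)
        qu = np.quantile(grp["log2_median_unmeth"], study_quantile)
        low_both.loc[grp.index] = (grp["log2_median_meth"] < qm) & (
            grp["log2_median_unmeth"] < qu
        )

    removals = []
    for sample in sm.index:
        if ctrl_fail[sample]:
            removals.append((sample, "failed BeadArray control"))
        elif low_both[sample]:
            removals.append((sample, "both signals below study 5th percentile"))
    removed = {s for s, _ in removals}

    keep = [s for s in sm.index if s not in removed]
    snp_rows = [p for p in panel.betas.index if str(p).startswith("rs")]
    if len(snp_rows) >= 5 and len(keep) >= 2:
        groups = detect_replicates(panel.betas.loc[snp_rows, keep], tau=replicate_tau)
        for sample in keep:
            if groups.loc[sample, "group"] != sample and groups.loc[sample, "group_size"] > 1:
                removals.append((sample, f"replicate of {groups.loc[sample, 'group']}"))
                removed.add(sample)
        keep = [s for s in keep if s not in removed]

    filtered = panel.subset_samples(keep)
    empty = set(panel.samples["tissue"]) - set(filtered.samples["tissue"])
    if empty:
        raise ValueError(f"filtering emptied tissues: {sorted(empty)}")
    log = pd.DataFrame(removals, columns=["sample_id", "reason"])
    return filtered, log


def _per_tissue_flags(per_tissue: dict, direction: str, config: VarianceFilterConfig):
    return {t: two_step_select(m, direction, config) for t, m in per_tissue.items()}


def select_low_variance_shared(
    per_tissue: dict, config: VarianceFilterConfig = VarianceFilterConfig()
) -> pd.DataFrame:
    """Probes passing the low two-step filter in EVERY tissue with
    cross-tissue mean range below the cut.

    ``per_tissue`` maps tissue -> probes x samples matrix (covariate-filtered,
    study-adjusted). Returns a per-probe table of tissue means/variances and
    the final ``selected`` flag for the probes retained in every tissue.
    """
    flags = _per_tissue_flags(per_tissue, "low", config)
    common = None
    for t, m in per_tissue.items():
        common = m.index if common is None else common.intersection(m.index)
    means = pd.DataFrame({t: m.loc[common].mean(axis=1) for t, m in per_tissue.items()})
    variances = pd.DataFrame({t: m.loc[common].var(axis=1, ddof=1) for t, m in per_tissue.items()})
    low_everywhere = pd.Series(True, index=common)
    for t, fl in flags.items():
        low_everywhere &= fl.reindex(common).fillna(False)
    mean_range = means.max(axis=1) - means.min(axis=1)
    selected = low_everywhere & (mean_range < config.low_mean_range_cut)
    out = means.add_prefix("mean_").join(variances.add_prefix("var_"))
    out["mean_range"] = mean_range
    out["low_everywhere"] = low_everywhere
    out["selected"] = selected
    return out


def select_tissue_specific(
    per_tissue: dict, config: VarianceFilterConfig = VarianceFilterConfig()
) -> dict:
    """Per tissue: probes passing the high two-step filter there and nowhere
    else, ranked by descending variance (ties by probe id), top_k retained."""
    flags = _per_tissue_flags(per_tissue, "high", config)
    out = {}
    for t in per_tissue:
        sel = flags[t].copy()
        for u in per_tissue:
            if u == t:
                continue
            other = flags[u].reindex(sel.index).fillna(False)
            sel &= ~other
        qualifying = sel.index[sel]
        var = per_tissue[t].loc[qualifying].var(axis=1, ddof=1)
        order = var.to_frame("var").assign(pid=qualifying).sort_values(
            ["var", "pid"], ascending=[False, True]
        )
        if len(order) < config.top_k_per_tissue:
            warnings.warn(
                f"{t}: only {len(order)} qualifying probes (< top_k="
                f"{config.top_k_per_tissue})",
                RuntimeWarning,
                stacklevel=2,
            )
        chosen = order.index[: config.top_k_per_tissue]
        out[t] = pd.DataFrame(
            {
                "variance": var.loc[chosen],
                "mean": per_tissue[t].loc[chosen].mean(axis=1),
            }
        ).sort_values("variance", ascending=False)
    return out


def region_enrichment(
    selection,
    annotation: pd.DataFrame,
    background,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Genome-context class enrichment of a probe selection vs background.

    Per class of island relation and gene relation: exact binomial test of
    the selection's class count with success probability the background class
    fraction; BH adjustment across classes; direction reported; significant
    at adjusted p < alpha.
    """
    selection = pd.Index(selection)
    background = pd.Index(background)
    if len(selection) == 0:
        raise ValueError("empty selection")
    missing = selection.difference(annotation.index)
    if len(missing):
        raise ValueError(f"annotation missing probes: {list(missing[:5])}")
    rows = []
    for column in ("island_relation", "gene_relation"):
        sel_classes = annotation.loc[selection, column]
        bg_classes = annotation.loc[background, column]
        for cls in sorted(bg_classes.unique()):
            p0 = float((bg_classes == cls).mean())
            k = int((sel_classes == cls).sum())
            n = len(selection)
            if p0 in (0.0, 1.0):
                pval = 1.0
            else:
                pval = stats.binomtest(k, n, p0).pvalue
            rows.append(
                {
                    "feature": column,
                    "class": cls,
                    "observed": k,
                    "expected": n * p0,
                    "selection_fraction": k / n,
                    "background_fraction": p0,
                    "p_value": pval,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["direction"] = np.where(
        table["observed"] > table["expected"], "enriched", "depleted"
    )
    table["significant"] = table["p_adjusted"] < alpha
    return table.set_index(["feature", "class"])
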