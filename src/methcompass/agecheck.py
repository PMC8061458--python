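"""Concordance of mined chronological vs predicted epigenetic age.

Supports the reliability workflow: cohort-level concordance statistics (mean
absolute difference, R-squared, Spearman rho), study-level MAD filtering
(studies whose within-study MAD exceeds a cutoff are ineligible), imputation
of missing chronological ages by the epigenetic age in eligible non-cancer
tissue samples, age-acceleration outlier tables (inclusive +/-15-year bounds)
and a sequential-ANOVA variance attribution of epigenetic age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "concordance_stats",
    "filter_studies_by_mad",
    "impute_age",
    "acceleration_outliers",
    "variance_attribution",
]

_REQUIRED = ("chronological_age", "epigenetic_age", "study")


def _complete(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs.dropna(subset=["chronological_age", "epigenetic_age"])


def concordance_stats(pairs: pd.DataFrame) -> dict:
    """MAD (mean absolute difference), R^2 (squared Pearson), Spearman rho."""
    comp = _complete(pairs)
    if len(comp) < 3:
        raise ValueError("need >= 3 complete age pairs")
    x = comp["chronological_age"].to_numpy(dtype=float)
    y = comp["epigenetic_age"].to_numpy(dtype=float)
    mad = float(np.mean(np.abs(y - x)))
    r = stats.pearsonr(x, y).statistic if np.std(x) > 0 and np.std(y) > 0 else np.nan
    rho = stats.spearmanr(x, y).statistic
    return {"mad": mad, "r_squared": float(r) ** 2, "spearman_rho": float(rho), "n": len(comp)}


def filter_studies_by_mad(
    pairs: pd.DataFrame, mad_cutoff: float = 10.0
) -> tuple[list, pd.DataFrame]:
    """Studies whose within-study MAD (complete, non-cancer tissue pairs only)
    is <= the cutoff.

    Returns (eligible study ids, per-study table with ineligibility reasons).
    Studies with < 3 complete pairs are ineligible rather than trivially
    passing.
    """
    df = pairs.copy()
    if "cancer" in df.columns:
        df = df[~df["cancer"].astype(bool)]
    if "sample_type" in df.columns:
        df = df[df["sample_type"] == "tissue"]
    rows = []
    for study, grp in df.groupby("study"):
        comp = _complete(grp)
        if len(comp) < 3:
            rows.append({"study": study, "mad": np.nan, "n_pairs": len(comp),
                         "eligible": False, "reason": "fewer than 3 complete pairs"})
            continue
        mad = float(
            np.mean(np.abs(comp["epigenetic_age"] - comp["chronological_age"]))
        )
        ok = mad <= mad_cutoff
        rows.append({"study": study, "mad": mad, "n_pairs": len(comp),
                     "eligible": ok, "reason": "" if ok else f"MAD {mad:.2f} > {mad_cutoff}"})
    table = pd.DataFrame(rows).set_index("study")
    return list(table.index[table["eligible"]]), table


def impute_age(pairs: pd.DataFrame, eligible_studies) -> pd.DataFrame:
    """Fill missing chronological ages with the epigenetic age.

    Only samples in eligible studies that are non-cancer tissue are imputed;
    mined ages are never overwritten. Adds an ``age_provenance`` column
    ('mined', 'imputed' or 'missing').
    """
    eligible = set(eligible_studies)
    out = pairs.copy()
    mined = out["chronological_age"].notna()
    imputable = (
        ~mined
        & out["study"].isin(eligible)
        & ~out.get("cancer", pd.Series(False, index=out.index)).astype(bool)
        & (out.get("sample_type", pd.Series("tissue", index=out.index)) == "tissue")
    )
    out.loc[imputable, "chronological_age"] = out.loc[imputable, "epigenetic_age"]
    prov = pd.Series("missing", index=out.index)
    prov[mined] = "mined"
    prov[imputable] = "imputed"
    out["age_provenance"] = prov
    return out


def acceleration_outliers(
    pairs: pd.DataFrame, pos_cut: float = 15.0, neg_cut: float = -15.0
) -> pd.DataFrame:
    """Age-acceleration outliers (epigenetic - chronological), inclusive bounds."""
    comp = _complete(pairs)
    acc = comp["epigenetic_age"] - comp["chronological_age"]
    out = comp.assign(acceleration=acc)
    out["outlier"] = np.select(
        [acc >= pos_cut, acc <= neg_cut], ["positive", "negative"], default=""
    )
    return out[out["outlier"] != ""].sort_values(["study", "acceleration"])


def variance_attribution(
    pairs: pd.DataFrame,
    covariates: tuple = ("chronological_age", "study", "cancer", "sample_type"),
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of epigenetic age on the covariates in order.

    Numeric covariates enter as single columns, categoricals as dummy blocks.
    Returns percent variance and an F-test p-value per term plus the residual
    share; aliased covariates raise with the collinear pair named.
    """
    comp = _complete(pairs)
    y = comp["epigenetic_age"].to_numpy(dtype=float)
    y = y - y.mean()
    sst = float(y @ y)
    if sst == 0:
        raise ValueError("epigenetic age is constant")
    n = len(comp)
    basis = [np.full(n, 1.0 / np.sqrt(n))]
    rows = []
    used_df = 1
    prev_name = None
    for name in covariates:
        col = comp[name]
        if col.dtype.kind in "biufc" and col.nunique() > 2:
            block = col.to_numpy(dtype=float)[:, None]
        else:
            levels = pd.unique(col)
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} has < 2 levels")
            block = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        ss = 0.0
        rank = 0
        for j in range(block.shape[1]):
            v = block[:, j].copy()
            for q in basis:
                v -= (q @ v) * q
            norm = np.linalg.norm(v)
            if norm < 1e-8 * max(1.0, np.linalg.norm(block[:, j])):
                continue
            q = v / norm
            basis.append(q)
            ss += float((q @ y) ** 2)
            rank += 1
        if rank == 0:
            raise ValueError(
                f"covariate {name!r} is aliased with {prev_name or 'the intercept'}"
            )
        rows.append({"term": name, "ss": ss, "df": rank})
        used_df += rank
        prev_name = name
    table = pd.DataFrame(rows).set_index("term")
    rss = sst - table["ss"].sum()
    df_res = n - used_df
    table["percent_variance"] = 100.0 * table["ss"] / sst
    ms_res = rss / df_res if df_res > 0 else np.nan
    table["f_value"] = (table["ss"] / table["df"]) / ms_res
    table["p_value"] = stats.f.sf(table["f_value"], table["df"], df_res)
    table.loc["residual"] = [rss, df_res, 100.0 * rss / sst, np.nan, np.nan]
    return table
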