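"""Model-based sample predictions from DNAm: age, sex, cell fractions, identity.

The machinery matches the published model forms — a sparse penalized-regression
epigenetic clock with the piecewise log-linear age calibration, median X/Y
total-intensity sex calling, reference-based (constrained least squares) blood
cell deconvolution, and SNP-probe genotype concordance for duplicate-sample
detection — while the coefficient tables themselves are pluggable inputs
(published clock and reference files load from TSV; tests use synthetic
models). The replicate detector is a distance-threshold simplification of the
mixture-model genotype-identity approach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClockModel",
    "CellTypeReference",
    "horvath_transform",
    "inverse_horvath_transform",
    "EpigeneticClock",
    "predict_age",
    "predict_sex",
    "CellTypeDeconvolver",
    "deconvolve_cells",
    "detect_replicates",
]


@dataclass(frozen=True)
class ClockModel:
    """Sparse linear epigenetic clock on transformed age."""

    intercept: float
    coefficients: pd.Series  # indexed by probe id
    adult_age: float = 20.0

    @classmethod
    def from_tsv(cls, path, adult_age: float = 20.0) -> "ClockModel":
        """Load (probe_id, coefficient) TSV; the '(Intercept)' row, if any,
        supplies the intercept."""
        tab = pd.read_csv(path, sep="\t")
        tab.columns = ["probe_id", "coefficient"]
        inter = tab[tab["probe_id"] == "(Intercept)"]
        intercept = float(inter["coefficient"].iloc[0]) if len(inter) else 0.0
        coefs = tab[tab["probe_id"] != "(Intercept)"].set_index("probe_id")["coefficient"]
        return cls(intercept=intercept, coefficients=coefs, adult_age=adult_age)


@dataclass(frozen=True)
class CellTypeReference:
    """Reference Beta-profiles (probes x cell types) for deconvolution."""

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.betas.to_numpy()
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("reference betas must lie in [0, 1]")
        if self.betas.shape[1] < 2:
            raise ValueError("need >= 2 cell types")
        if np.linalg.matrix_rank(arr) < self.betas.shape[1]:
            raise ValueError("reference matrix is rank deficient")

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)


def horvath_transform(age, adult_age: float = 20.0):
    """Piecewise log-linear age calibration used by penalized-regression clocks.

    F(age) = log((age+1)/(adult_age+1)) for age <= adult_age, else
    (age - adult_age)/(adult_age + 1); continuous at adult_age with F = 0.
    """
    age_arr = np.asarray(age, dtype=float)
    if (age_arr <= -1).any():
        raise ValueError("age must be > -1")
    out = np.where(
        age_arr <= adult_age,
        np.log((age_arr + 1.0) / (adult_age + 1.0)),
        (age_arr - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_horvath_transform(x, adult_age: float = 20.0):
    """Inverse calibration: exp branch for x <= 0, linear branch for x > 0."""
    x_arr = np.asarray(x, dtype=float)
    out = np.where(
        x_arr <= 0,
        (adult_age + 1.0) * np.exp(x_arr) - 1.0,
        x_arr * (adult_age + 1.0) + adult_age,
    )
    return out if out.ndim else float(out)


class EpigeneticClock(BaseEstimator, RegressorMixin):
    """Predict age in years from Beta-values with a fixed sparse linear model.

    The model is supplied, not trained (published coefficients are pluggable
    inputs); ``fit`` records the probe alignment and the cohort medians used
    to impute missing clock probes. X is samples x probes (DataFrame, columns
    are probe ids).

    Parameters
    ----------
    model : ClockModel
    max_missing : float, default 0.10
        Per-sample error if more than this fraction of clock probes is
        missing; below it, missing values impute at the cohort median beta.
    """

    def __init__(self, model: ClockModel | None = None, max_missing: float = 0.10):
        self.model = model
        self.max_missing = max_missing

    def fit(self, X: pd.DataFrame, y=None):
        if self.model is None:
            raise ValueError("a ClockModel must be supplied")
        probes = self.model.coefficients.index
        present = probes.intersection(X.columns)
        if len(present) < (1 - self.max_missing) * len(probes):
            raise ValueError(
                f"only {len(present)}/{len(probes)} clock probes present"
            )
        self.probes_ = probes
        sub = X.reindex(columns=probes)
        self.cohort_median_ = sub.median(axis=0, skipna=True)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "probes_")
        sub = X.reindex(columns=self.probes_)
        n_missing = sub.isna().sum(axis=1)
        too_many = n_missing > self.max_missing * len(self.probes_)
        sub = sub.fillna(self.cohort_median_)
        score = self.model.intercept + sub.to_numpy() @ self.model.coefficients.to_numpy()
        ages = inverse_horvath_transform(score, self.model.adult_age)
        ages = np.asarray(ages, dtype=float)
        ages[too_many.to_numpy()] = np.nan
        self.n_missing_ = n_missing
        return ages


def predict_age(beta: pd.DataFrame, clock: ClockModel, max_missing: float = 0.10) -> pd.Series:
    """Predict ages from a probes x samples Beta matrix (thin wrapper)."""
    X = beta.T
    est = EpigeneticClock(model=clock, max_missing=max_missing).fit(X)
    return pd.Series(est.predict(X), index=X.index, name="epigenetic_age")


def predict_sex(
    meth: pd.DataFrame,
    unmeth: pd.DataFrame,
    annotation: pd.DataFrame,
    cutoff: float = -2.0,
    dead_zone: float = 0.5,
) -> pd.DataFrame:
    """Call sample sex from median log2 total X vs Y intensity.

    ``annotation`` needs probe_id-indexed 'chrom'. Call is male iff
    (yMed - xMed) >= cutoff + dead_zone/2, female iff <= cutoff - dead_zone/2,
    undetermined inside the dead zone.
    """
    chrom = annotation["chrom"].reindex(meth.index)
    x_probes = meth.index[chrom.isin(["chrX", "X"])]
    y_probes = meth.index[chrom.isin(["chrY", "Y"])]
    if len(x_probes) < 10 or len(y_probes) < 10:
        raise ValueError("need >= 10 probes on each of X and Y")
    total = np.log2(meth + unmeth + 1.0)
    x_med = total.loc[x_probes].median(axis=0)
    y_med = total.loc[y_probes].median(axis=0)
    diff = y_med - x_med
    call = pd.Series("undetermined", index=meth.columns)
    call[diff >= cutoff + dead_zone / 2] = "male"
    call[diff <= cutoff - dead_zone / 2] = "female"
    return pd.DataFrame(
        {"x_median": x_med, "y_median": y_med, "difference": diff, "call": call}
    )


class CellTypeDeconvolver(BaseEstimator, RegressorMixin):
    """Reference-based cell-fraction estimation by constrained least squares.

    Per sample, minimize ||b - R w||^2 subject to w >= 0 and sum(w) <= 1.
    Solved exactly by non-negative least squares on an augmented system: a
    slack component turns the inequality into an equality on the simplex, and
    a large penalty row enforces it.
    """

    def __init__(self, reference: CellTypeReference | None = None):
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None):
        if self.reference is None:
            raise ValueError("a CellTypeReference must be supplied")
        ref = self.reference.betas
        present = ref.index.intersection(X.columns)
        if len(present) < ref.shape[1]:
            raise ValueError("too few reference probes present in the data")
        self.probes_ = present
        self.R_ = ref.loc[present].to_numpy()
        if np.linalg.matrix_rank(self.R_) < self.R_.shape[1]:
            raise ValueError("reference rank deficient on the shared probe subset")
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "R_")
        R = self.R_
        k = R.shape[1]
        # augmented system: [R | 0; penalty * 1^T, penalty] w' = [b; penalty]
        penalty = 100.0 * max(1.0, np.abs(R).max()) * np.sqrt(R.shape[0])
        A = np.zeros((R.shape[0] + 1, k + 1))
        A[:-1, :k] = R
        A[-1, :] = penalty
        frames = []
        for sample in X.index:
            b = X.loc[sample, self.probes_].to_numpy(dtype=float)
            rhs = np.concatenate([b, [penalty]])
            w_aug, _ = nnls(A, rhs)
            w = w_aug[:k]
            resid = float(np.linalg.norm(b - R @ w))
            frames.append(np.concatenate([w, [resid]]))
        cols = list(self.reference.betas.columns) + ["residual"]
        return pd.DataFrame(frames, index=X.index, columns=cols)


def deconvolve_cells(beta: pd.DataFrame, reference: CellTypeReference) -> pd.DataFrame:
    """Estimate cell fractions from a probes x samples Beta matrix."""
    X = beta.T
    est = CellTypeDeconvolver(reference=reference).fit(X)
    return est.predict(X)


def detect_replicates(snp_betas: pd.DataFrame, tau: float = 0.1) -> pd.DataFrame:
    """Group samples by SNP-probe genotype agreement.

    ``snp_betas`` is SNP probes x samples. Pairs with mean absolute
    Beta-difference < tau are linked; connected components form donor groups;
    the lexicographically first sample id in each group is its representative.
    Samples with no observed SNP betas are isolated with a warning.
    """
    if snp_betas.shape[0] < 5:
        raise ValueError("need >= 5 SNP probes")
    samples = list(snp_betas.columns)
    vals = snp_betas.to_numpy(dtype=float)
    observed = np.isfinite(vals)
    empty = ~observed.any(axis=0)
    if empty.any():
        warnings.warn(
            f"samples without SNP betas isolated: {list(np.array(samples)[empty])}",
            RuntimeWarning,
            stacklevel=2,
        )
    n = len(samples)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if empty[i]:
            continue
        for j in range(i + 1, n):
            if empty[j]:
                continue
            both = observed[:, i] & observed[:, j]
            if not both.any():
                continue
            dist = float(np.mean(np.abs(vals[both, i] - vals[both, j])))
            if dist < tau:
                parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(samples[i])
    rows = []
    for members in groups.values():
        members = sorted(members)
        rep = members[0]
        for m in members:
            rows.append((m, rep, len(members)))
    out = pd.DataFrame(rows, columns=["sample_id", "group", "group_size"])
    return out.sort_values("sample_id").set_index("sample_id")
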