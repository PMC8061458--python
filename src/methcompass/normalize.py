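"""Background correction and scale handling for Infinium intensity data.

Implements the normal-exponential out-of-band ("noob") background model: the
observed intensity at a probe is modelled as ``X = S + B`` with signal
``S ~ Exponential(alpha)`` and background ``B ~ Normal(mu, sigma^2)``.
Out-of-band intensities — type-I probes read in the opposite colour channel —
measure the background distribution alone and supply ``mu`` and ``sigma``;
the corrected intensity is the conditional expectation ``E[S | X = x]``.

Also provides Beta/M-value conversions, per-study location adjustment of
M-values (removing batch shifts while preserving each probe's grand mean) and
per-sample median imputation of missing Beta-values. The study adjuster and
imputer are scikit-learn style transformers operating on samples x probes
matrices; the module-level functions accept the field-conventional
probes x samples orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import check_positive

__all__ = [
    "NormexpParams",
    "fit_normexp",
    "normexp_conditional_mean",
    "noob_correct",
    "dye_bias_equalize",
    "to_beta",
    "to_mvalue",
    "from_mvalue",
    "adjust_study",
    "impute_median",
    "StudyBatchAdjuster",
    "SampleMedianImputer",
]


@dataclass(frozen=True)
class NormexpParams:
    """Normal-exponential convolution parameters for one sample/channel.

    mu, sigma: background mean and sd (intensity units); alpha: signal rate,
    so the mean true signal is ``1/alpha``.
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        check_positive(self.sigma, "sigma")
        check_positive(self.alpha, "alpha")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


def fit_normexp(
    oob_pool: np.ndarray,
    observed: np.ndarray,
    *,
    signal_floor: float = 10.0,
) -> NormexpParams:
    """Method-of-moments fit of the normal-exponential model.

    ``mu`` and ``sigma`` come from the out-of-band pool (background-only
    draws); the signal mean ``1/alpha`` from ``mean(observed) - mu``, floored
    at ``signal_floor`` so alpha stays finite when the observed mean falls at
    or below background.
    """
    oob_pool = np.asarray(oob_pool, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if oob_pool.size < 30:
        raise ValueError(f"out-of-band pool too small ({oob_pool.size} < 30)")
    mu = float(np.mean(oob_pool))
    sigma = float(np.std(oob_pool, ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate out-of-band pool: zero variance")
    mean_signal = float(np.mean(observed)) - mu
    if mean_signal < signal_floor:
        warnings.warn(
            "observed mean at or below background; signal mean floored",
            RuntimeWarning,
            stacklevel=2,
        )
        mean_signal = signal_floor
    return NormexpParams(mu=mu, sigma=sigma, alpha=1.0 / mean_signal)


def normexp_conditional_mean(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """E[S | X = x] under the normal-exponential convolution.

    Computed in log space (``log_ndtr``) so extreme arguments neither overflow
    nor underflow; for large x this tends to ``x - mu - sigma^2 * alpha``.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite observed intensity")
    mu_sf = x - params.mu - params.sigma**2 * params.alpha
    z = mu_sf / params.sigma
    # E[S|x] = mu_sf + sigma * phi(z) / Phi(z); the Mills-ratio term is
    # evaluated as exp(logpdf - logcdf) for numerical stability at z << 0.
    out = mu_sf + params.sigma * np.exp(norm.logpdf(z) - log_ndtr(z))
    return np.maximum(out, np.finfo(float).tiny)


def noob_correct(signals, params_by_channel: dict[str, dict[str, NormexpParams]]):
    """Apply the normexp conditional-mean correction to a RawSignalSet.

    ``params_by_channel`` maps sample id -> channel -> NormexpParams (as fit
    from that sample's out-of-band pools). Returns a new signal set; corrected
    intensities are strictly positive and preserve within-sample ordering.
    """
    meth = signals.meth.copy()
    unmeth = signals.unmeth.copy()
    channel = signals.probe_channel
    for sample in meth.columns:
        pars = params_by_channel[sample]
        for chan in ("green", "red"):
            mask = (channel == chan).to_numpy()
            if not mask.any():
                continue
            p = pars[chan]
            meth.loc[mask, sample] = normexp_conditional_mean(
                meth.loc[mask, sample].to_numpy(), p
            )
            unmeth.loc[mask, sample] = normexp_conditional_mean(
                unmeth.loc[mask, sample].to_numpy(), p
            )
    return signals.replace(meth=meth, unmeth=unmeth)


def fit_normexp_per_sample(signals) -> dict[str, dict[str, NormexpParams]]:
    """Fit per-sample, per-channel normexp parameters from a RawSignalSet."""
    out: dict[str, dict[str, NormexpParams]] = {}
    channel = signals.probe_channel
    for sample in signals.meth.columns:
        pars = {}
        for chan, oob in (("green", signals.oob_grn), ("red", signals.oob_red)):
            mask = (channel == chan).to_numpy()
            observed = np.concatenate(
                [
                    signals.meth.loc[mask, sample].to_numpy(),
                    signals.unmeth.loc[mask, sample].to_numpy(),
                ]
            )
            pars[chan] = fit_normexp(oob[sample].to_numpy(), observed)
        out[sample] = pars
    return out


def dye_bias_equalize(signals, control_table: pd.DataFrame):
    """Scale red-channel intensities so channel control means match.

    Uses the normalization-control intensities (here: all control probes in
    the table) to compute per-sample green/red mean ratios; red-channel probe
    intensities are multiplied by that ratio.
    """
    meth = signals.meth.copy()
    unmeth = signals.unmeth.copy()
    red_mask = (signals.probe_channel == "red").to_numpy()
    by = control_table.groupby(["sample_id", "channel"])["intensity"].mean()
    for sample in meth.columns:
        try:
            grn = by[(sample, "green")]
            red = by[(sample, "red")]
        except KeyError as exc:
            raise KeyError(f"no control intensities for sample {sample!r}") from exc
        if red == 0 or grn == 0:
            raise ValueError(f"zero control mean for sample {sample!r}")
        factor = grn / red
        meth.loc[red_mask, sample] *= factor
        unmeth.loc[red_mask, sample] *= factor
    return signals.replace(meth=meth, unmeth=unmeth)


def to_beta(meth, unmeth, offset: float = 100.0):
    """Beta = meth / (meth + unmeth + offset), in [0, 1)."""
    meth_arr = np.asarray(meth, dtype=float)
    unmeth_arr = np.asarray(unmeth, dtype=float)
    if (meth_arr < 0).any() or (unmeth_arr < 0).any():
        raise ValueError("negative intensity passed to to_beta")
    beta = meth_arr / (meth_arr + unmeth_arr + offset)
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(beta, index=meth.index, columns=meth.columns)
    return beta


def to_mvalue(beta, epsilon: float = 1e-6):
    """M = log2(b / (1 - b)) with b clamped to [epsilon, 1 - epsilon]."""
    arr = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def from_mvalue(m):
    """Inverse of :func:`to_mvalue`: b = 2^M / (1 + 2^M), computed stably."""
    arr = np.asarray(m, dtype=float)
    # expit in base 2: stable for large |M|
    b = np.where(arr >= 0, 1.0 / (1.0 + 2.0**(-arr)), 2.0**arr / (1.0 + 2.0**arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


class StudyBatchAdjuster(BaseEstimator, TransformerMixin):
    """Remove per-study location shifts from M-values, probe by probe.

    Equivalent to OLS of each probe's M-value on study indicators: the fitted
    per-study means are subtracted and the probe's grand mean (weighted by
    study size, i.e. the plain mean over samples) restored. X is
    samples x probes; ``y`` in :meth:`fit` is the per-sample study id.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("study ids required (pass as y)")
        study = np.asarray(y)
        if X.shape[0] != study.shape[0]:
            raise ValueError("X and study ids disagree in length")
        levels, codes = np.unique(study, return_inverse=True)
        if len(levels) < 2:
            warnings.warn("single study: adjustment is the identity", RuntimeWarning)
        counts = np.bincount(codes)
        if (counts < 2).any() and len(levels) >= 2:
            small = levels[counts < 2]
            raise ValueError(f"studies with < 2 samples: {list(small)}")
        grand = X.mean(axis=0)
        study_means = np.zeros((len(levels), X.shape[1]))
        for k in range(len(levels)):
            study_means[k] = X[codes == k].mean(axis=0)
        self.studies_ = levels
        self.grand_mean_ = grand
        # centered study effects: study mean minus grand mean
        self.study_effects_ = study_means - grand
        return self

    def transform(self, X, y=None):
        check_is_fitted(self, "study_effects_")
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("study ids required (pass as y)")
        codes = np.searchsorted(self.studies_, np.asarray(y))
        if (self.studies_[codes] != np.asarray(y)).any():
            raise ValueError("unknown study id in transform")
        return X - self.study_effects_[codes]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X, y)


def adjust_study(m: pd.DataFrame, study_ids) -> pd.DataFrame:
    """Study-adjust a probes x samples M-value matrix (thin wrapper)."""
    adj = StudyBatchAdjuster().fit_transform(m.to_numpy().T, np.asarray(study_ids))
    return pd.DataFrame(adj.T, index=m.index, columns=m.columns)


class SampleMedianImputer(BaseEstimator, TransformerMixin):
    """Replace each sample's missing Beta-values by its array-wide median.

    Stateless per sample (the median is recomputed from the transformed
    matrix), so ``fit`` only validates.
    """

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.array(X, dtype=float, copy=True)
        missing = ~np.isfinite(X)
        if missing.all(axis=1).any():
            raise ValueError("sample with no observed values cannot be imputed")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(missing, np.nan, X), axis=1)
        rows, cols = np.nonzero(missing)
        X[rows, cols] = med[rows]
        return X


def impute_median(beta: pd.DataFrame) -> pd.DataFrame:
    """Impute a probes x samples Beta matrix by per-sample medians."""
    out = SampleMedianImputer().fit_transform(beta.to_numpy().T)
    return pd.DataFrame(out.T, index=beta.index, columns=beta.columns)
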