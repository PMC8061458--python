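"""BeadArray control metrics: computation, pass/fail outcomes, dimension.

The 17 BeadArray controls each check one assay step (staining, extension,
hybridization, target removal, bisulfite conversion, specificity,
non-polymorphic, restoration) as a signal ratio with a manufacturer-prescribed
minimum threshold. Conventions, following the published re-implementations of
Illumina's BeadArray Controls Reporter:

* the sample's mean extension-green control intensity serves as background;
* a denominator offset of +1 is applied where the denominator would be 0;
* a sample passes a control iff metric value >= threshold (pass=1, fail=0).

:func:`outcome_intrinsic_dimension` estimates how many controls carry the
quality signal: PCA of the binary outcome matrix followed by a per-component
sequential (type-I) ANOVA of component scores on the 17 outcome columns in
registry order, then a greedy minimal control subset covering a configurable
majority of the retained components' variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BACKGROUND",
    "MetricGroup",
    "ControlMetric",
    "ControlMetricRegistry",
    "load_default_registry",
    "compute_control_metrics",
    "evaluate_outcomes",
    "outcome_intrinsic_dimension",
]

BACKGROUND = "BACKGROUND"
_AGGREGATORS = {"mean": np.mean, "min": np.min, "max": np.max}


@dataclass(frozen=True)
class MetricGroup:
    control_type: str
    channel: str
    aggregate: str

    def __post_init__(self) -> None:
        if self.channel not in ("red", "green"):
            raise ValueError(f"channel must be red/green, got {self.channel!r}")
        if self.aggregate not in _AGGREGATORS:
            raise ValueError(f"aggregate must be one of {sorted(_AGGREGATORS)}")


@dataclass(frozen=True)
class ControlMetric:
    name: str
    numerator: MetricGroup | str  # MetricGroup or BACKGROUND
    denominator: MetricGroup | str
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class ControlMetricRegistry:
    metrics: list[ControlMetric] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.metrics]
        if len(set(names)) != len(names):
            raise ValueError("metric names must be unique")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.metrics]

    def with_threshold(self, name: str, threshold: float) -> "ControlMetricRegistry":
        """Return a copy with one metric's threshold replaced."""
        if name not in self.names:
            raise KeyError(name)
        return ControlMetricRegistry(
            [
                ControlMetric(m.name, m.numerator, m.denominator, threshold)
                if m.name == name
                else m
                for m in self.metrics
            ]
        )

    def control_types(self) -> set[str]:
        out = set()
        for m in self.metrics:
            for grp in (m.numerator, m.denominator):
                if isinstance(grp, MetricGroup):
                    out.add(grp.control_type)
        out.update({"extension_cg", "extension_at"})  # background groups
        return out

    @classmethod
    def from_yaml(cls, path_or_stream) -> "ControlMetricRegistry":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        metrics = []
        for entry in raw["metrics"]:
            num = entry["numerator"]
            den = entry["denominator"]
            metrics.append(
                ControlMetric(
                    name=entry["name"],
                    numerator=num if num == BACKGROUND else MetricGroup(**num),
                    denominator=den if den == BACKGROUND else MetricGroup(**den),
                    threshold=float(entry["threshold"]),
                )
            )
        return cls(metrics)


def load_default_registry() -> ControlMetricRegistry:
    """The shipped 17-metric registry (editable YAML in package data)."""
    ref = resources.files("methcompass.data") / "control_registry.yaml"
    with ref.open() as fh:
        reg = ControlMetricRegistry.from_yaml(fh)
    if len(reg.metrics) != 17:
        raise RuntimeError("default registry must define 17 metrics")
    return reg


def _sample_backgrounds(table: pd.DataFrame) -> pd.Series:
    ext = table[
        table["control_type"].isin(["extension_cg", "extension_at"])
        & (table["channel"] == "green")
    ]
    return ext.groupby("sample_id")["intensity"].mean()


def compute_control_metrics(
    table: pd.DataFrame, registry: ControlMetricRegistry | None = None
) -> pd.DataFrame:
    """Compute the control metrics for every sample in a control-probe table.

    ``table`` columns: sample_id, control_type, address, channel, intensity.
    Returns a tidy frame (sample_id, metric, value, background, available);
    a missing control group yields an unavailable metric (value NaN) rather
    than a silent pass.
    """
    registry = registry or load_default_registry()
    if (table["intensity"] < 0).any() or not np.isfinite(table["intensity"]).all():
        raise ValueError("control intensities must be finite and >= 0")
    background = _sample_backgrounds(table)
    samples = table["sample_id"].unique()
    missing_bg = set(samples) - set(background.index)
    if missing_bg:
        raise ValueError(f"no extension-green probes for samples {sorted(missing_bg)}")

    grouped = table.groupby(["sample_id", "control_type", "channel"])["intensity"]
    aggregates = {
        "mean": grouped.mean(),
        "min": grouped.min(),
        "max": grouped.max(),
    }

    def resolve(group, sample: str) -> float | None:
        if group == BACKGROUND:
            return float(background[sample])
        key = (sample, group.control_type, group.channel)
        series = aggregates[group.aggregate]
        return float(series[key]) if key in series.index else None

    rows = []
    for sample in samples:
        bg = float(background[sample])
        for metric in registry.metrics:
            num = resolve(metric.numerator, sample)
            den = resolve(metric.denominator, sample)
            if num is None or den is None:
                warnings.warn(
                    f"sample {sample!r}: missing control data for {metric.name!r}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rows.append((sample, metric.name, np.nan, bg, False))
                continue
            if den == 0:
                den = den + 1.0  # documented +1 offset for zero denominators
            rows.append((sample, metric.name, num / den, bg, True))
    return pd.DataFrame(
        rows, columns=["sample_id", "metric", "value", "background", "available"]
    )


def evaluate_outcomes(
    results: pd.DataFrame, registry: ControlMetricRegistry | None = None
) -> pd.DataFrame:
    """Binary outcome matrix (samples x 17; pass=1, fail=0).

    Unavailable metrics fail conservatively (with a warning emitted at
    computation time). Column order matches the registry. The returned frame
    carries per-sample summaries in ``.attrs``: ``n_failed`` and
    ``any_failure``.
    """
    registry = registry or load_default_registry()
    thresholds = {m.name: m.threshold for m in registry.metrics}
    wide = results.pivot(index="sample_id", columns="metric", values="value")
    missing_cols = set(thresholds) - set(wide.columns)
    if missing_cols:
        raise ValueError(f"results missing metrics: {sorted(missing_cols)}")
    wide = wide[registry.names]
    outcome = pd.DataFrame(0, index=wide.index, columns=wide.columns, dtype=int)
    for name, thr in thresholds.items():
        vals = wide[name]
        outcome[name] = ((vals >= thr) & vals.notna()).astype(int)
    n_failed = (1 - outcome).sum(axis=1)
    outcome.attrs["n_failed"] = n_failed
    outcome.attrs["any_failure"] = n_failed > 0
    return outcome


def _sequential_anova_fractions(scores: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Sequential (type-I) sums of squares of ``scores`` on X's columns.

    Columns enter in order; each column's SS is the drop in residual sum of
    squares when it is added, as a fraction of the total (centered) SS.
    Implemented by Gram-Schmidt against previously entered columns, so
    constant or aliased columns contribute exactly 0.
    """
    n = len(scores)
    y = scores - scores.mean()
    sst = float(y @ y)
    if sst == 0:
        return np.zeros(X.shape[1])
    basis = [np.full(n, 1.0 / np.sqrt(n))]
    fracs = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        for q in basis:
            v = v - (q @ v) * q
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            continue
        q = v / norm
        fracs[j] = float((q @ y) ** 2) / sst
        basis.append(q)
    return fracs


def outcome_intrinsic_dimension(
    outcomes: pd.DataFrame,
    *,
    n_components: int = 5,
    majority: float = 0.95,
) -> dict:
    """PCA + per-component ANOVA of the binary outcome matrix.

    Returns the per-component variance fractions, the per-control variance
    fractions within each retained component (sequential SS, registry order),
    each control's overall contribution (component-variance-weighted), and
    the minimal control subset covering ``majority`` of the retained
    components' variance.
    """
    X = outcomes.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant outcome matrix: no variation to analyze")
    # PCA via SVD of the centered matrix
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    var_frac = var / var.sum()
    k = min(n_components, int((S > 1e-10).sum()))
    scores = U[:, :k] * S[:k]

    per_component = []
    contributions = np.zeros(X.shape[1])
    retained_weight = var_frac[:k].sum()
    for comp in range(k):
        fr = _sequential_anova_fractions(scores[:, comp], Xc)
        per_component.append(fr)
        contributions += var_frac[comp] * fr
    contrib_frac = contributions / retained_weight if retained_weight > 0 else contributions

    order = np.argsort(-contrib_frac, kind="stable")
    subset, covered = [], 0.0
    for idx in order:
        if covered >= majority:
            break
        if contrib_frac[idx] <= 0:
            break
        subset.append(outcomes.columns[idx])
        covered += contrib_frac[idx]
    return {
        "component_variance_fractions": var_frac[:k],
        "per_component_control_fractions": pd.DataFrame(
            per_component, columns=outcomes.columns, index=[f"PC{i+1}" for i in range(k)]
        ),
        "control_contributions": pd.Series(contrib_frac, index=outcomes.columns),
        "majority_subset": subset,
        "majority_covered": covered,
    }
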