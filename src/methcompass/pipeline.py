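"""Orchestration of the two headline workflows on a synthetic cohort.

``run_qc_report`` chains control metrics -> outcome evaluation -> signal
summaries -> per-sample and per-study failure calls -> storage comparison ->
label enrichment -> control intrinsic dimension. ``run_variance_analysis``
chains sample filtering -> study adjustment -> model-based predictions ->
age reliability/imputation -> covariate probe filtering -> two-step variance
selections -> genome-context enrichment -> hashed PCA. Every output file
embeds the config hash and seed, so equal configs give byte-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agecheck, dimred, metaharmon, predict, qcsignal, varpipe
from .controls import (
    compute_control_metrics,
    evaluate_outcomes,
    load_default_registry,
    outcome_intrinsic_dimension,
)
from .normalize import adjust_study, from_mvalue, to_mvalue
from .synthdata import (
    SimScenario,
    generate_control_signals,
    generate_metadata_records,
    generate_models,
    generate_raw_signals,
    generate_tissue_beta_panel,
)

__all__ = ["RunConfig", "run_qc_report", "run_variance_analysis"]


@dataclass
class RunConfig:
    """All thresholds of the pipeline, plus the simulation scenario."""

    seed: int = 0
    signal_threshold: float = 11.0
    fst_cutoff: float = 0.60
    min_study_size: int = 10
    mad_cutoff: float = 10.0
    pos_acceleration_cut: float = 15.0
    neg_acceleration_cut: float = -15.0
    enrichment_alpha: float = 1e-3
    hash_d: int = 1000
    n_components: int = 2
    variance: varpipe.VarianceFilterConfig = field(
        default_factory=varpipe.VarianceFilterConfig
    )
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.fst_cutoff <= 1):
            raise ValueError("fst_cutoff must lie in (0, 1]")
        if self.signal_threshold <= 0 or self.mad_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if self.pos_acceleration_cut <= 0 or self.neg_acceleration_cut >= 0:
            raise ValueError("acceleration cuts must bracket 0")

    def scenario(self) -> SimScenario:
        return SimScenario(seed=self.seed, **self.scenario_overrides)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "variance" in raw:
            raw["variance"] = varpipe.VarianceFilterConfig(**raw["variance"])
        return cls(**raw)


def _write(frame: pd.DataFrame, path: Path, config: RunConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        frame.to_csv(fh, sep="\t", lineterminator="\n", **kwargs)


def _manifest(outdir: Path, config: RunConfig, files: list) -> None:
    man = pd.DataFrame({"file": [f.name for f in files]})
    _write(man, outdir / "MANIFEST.tsv", config, index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"config_hash": config.config_hash(), **config.to_dict()},
            fh,
            sort_keys=True,
        )


def run_qc_report(config: RunConfig, outdir) -> dict:
    """Quality-control workflow: control metrics, failure calls, reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario()
    registry = load_default_registry()

    controls_table, gt = generate_control_signals(scenario)
    metrics = compute_control_metrics(controls_table, registry)
    outcomes = evaluate_outcomes(metrics, registry)
    signals, _ = generate_raw_signals(scenario)
    summaries = qcsignal.summarize_signals(signals)
    flags = qcsignal.assess_sample_failure(
        summaries, outcomes, signal_threshold=config.signal_threshold
    )
    study_table, flagged = qcsignal.study_failure_fractions(
        flags,
        gt.samples["study"],
        fst_cutoff=config.fst_cutoff,
        min_study_size=config.min_study_size,
    )

    records, gt_meta = generate_metadata_records(scenario)
    labels = [
        metaharmon.apply_vocabulary(metaharmon.parse_soft_block(r)) for r in records
    ]
    tissue_terms = sorted({t for lab in labels for t in lab.terms.get("tissue", ())})
    label_matrix = pd.DataFrame(
        {
            term: [term in lab.terms.get("tissue", ()) for lab in labels]
            for term in tissue_terms
        },
        index=[lab.sample_id for lab in labels],
    )
    enrichment = (
        qcsignal.label_enrichment(flags, label_matrix, alpha=config.enrichment_alpha)
        if flags["failed"].any()
        else pd.DataFrame()
    )

    qc_table = metrics.pivot(index="sample_id", columns="metric", values="value")
    qc_table = qc_table[registry.names].join(summaries)  # 19 quality metrics

    try:
        dimension = outcome_intrinsic_dimension(outcomes)
        contributions = dimension["control_contributions"].to_frame("contribution")
    except ValueError:
        dimension = None
        contributions = pd.DataFrame()

    storage = None
    cond = gt.samples["storage"]
    if cond.nunique() > 1 and cond.value_counts().min() >= 2:
        storage = qcsignal.storage_condition_comparison(summaries, outcomes, cond)

    files = []
    for name, frame, kwargs in (
        ("per_sample_qc.tsv", qc_table, {}),
        ("outcomes.tsv", outcomes, {}),
        ("study_failures.tsv", study_table, {}),
        ("label_enrichment.tsv", enrichment, {}),
        ("control_contributions.tsv", contributions, {}),
    ):
        _write(frame, outdir / name, config, **kwargs)
        files.append(outdir / name)
    _manifest(outdir, config, files)
    return {
        "qc_table": qc_table,
        "outcomes": outcomes,
        "flags": flags,
        "study_table": study_table,
        "flagged_studies": flagged,
        "enrichment": enrichment,
        "intrinsic_dimension": dimension,
        "storage_comparison": storage,
        "ground_truth": gt,
    }


def run_variance_analysis(config: RunConfig, outdir) -> dict:
    """Seven-tissue variability workflow on the configured scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = config.scenario()
    if not scenario.tissues:
        raise ValueError("empty tissue list")

    panel, gt = generate_tissue_beta_panel(scenario)
    clock, reference, annotation = generate_models(scenario)
    controls_table, _ = generate_control_signals(scenario)
    outcomes = evaluate_outcomes(compute_control_metrics(controls_table))
    signals, _ = generate_raw_signals(scenario)
    summaries = qcsignal.summarize_signals(signals)

    filtered, removal_log = varpipe.filter_low_quality_samples(
        panel, summaries, outcomes
    )

    # model-based sample predictions
    sex_calls = predict.predict_sex(
        signals.meth[filtered.samples.index],
        signals.unmeth[filtered.samples.index],
        annotation,
    )
    ages = predict.predict_age(filtered.betas, clock)
    cells = predict.deconvolve_cells(filtered.betas, reference)

    # mined ages from the metadata corpus
    records, _ = generate_metadata_records(scenario)
    mined_age = {}
    for rec_text in records:
        rec = metaharmon.parse_soft_block(rec_text)
        lab = metaharmon.apply_vocabulary(rec)
        if lab.age_years is not None:
            mined_age[rec.sample_id] = lab.age_years
    pairs = pd.DataFrame(
        {
            "chronological_age": pd.Series(mined_age).reindex(filtered.samples.index),
            "epigenetic_age": ages,
            "study": filtered.samples["study"],
            "cancer": False,
            "sample_type": "tissue",
        }
    )
    eligible, mad_table = agecheck.filter_studies_by_mad(
        pairs, mad_cutoff=config.mad_cutoff
    )
    completed = agecheck.impute_age(pairs, eligible)
    outliers = agecheck.acceleration_outliers(
        pairs, config.pos_acceleration_cut, config.neg_acceleration_cut
    )

    # autosomal cg probes only
    autosomal = annotation.index[
        (annotation["probe_type"] == "cg")
        & ~annotation["chrom"].isin(["chrX", "chrY"])
    ]
    betas = filtered.betas.loc[autosomal]

    # per-tissue study adjustment and covariate probe filtering
    cell_cols = list(reference.betas.columns)
    covars = pd.DataFrame(
        {
            "age": completed["chronological_age"],
            "sex": sex_calls["call"],
            **{c: cells[c] for c in cell_cols},
        }
    )
    per_tissue: dict = {}
    drop_counts = {}
    for tissue in scenario.tissues:
        ids = filtered.tissue_samples(tissue)
        mat = betas[ids]
        adj = from_mvalue(adjust_study(to_mvalue(mat), filtered.samples.loc[ids, "study"]))
        cov = covars.loc[ids].dropna()
        retained = varpipe.covariate_probe_filter(
            adj[cov.index], cov, config.variance
        )
        drop_counts[tissue] = int((~retained).sum())
        per_tissue[tissue] = adj.loc[retained[retained].index]

    shared_low = varpipe.select_low_variance_shared(per_tissue, config.variance)
    tissue_specific = varpipe.select_tissue_specific(per_tissue, config.variance)

    low_ids = shared_low.index[shared_low["selected"]]
    enrich_low = varpipe.region_enrichment(
        low_ids, annotation, autosomal, alpha=config.enrichment_alpha
    )
    ts_all = pd.Index(
        sorted(set().union(*[set(t.index) for t in tissue_specific.values()]))
    )
    enrich_ts = varpipe.region_enrichment(
        ts_all, annotation, autosomal, alpha=config.enrichment_alpha
    )

    hashed = dimred.hash_project(
        betas, dimred.HashedProjection(d=config.hash_d, seed=config.seed)
    )
    scores, var_fracs = dimred.pca_embed(hashed, k=config.n_components)

    # planted-truth recovery metrics (simulation mode)
    def _pr(selected: set, planted: set) -> tuple[float, float]:
        if not selected or not planted:
            return float("nan"), 0.0
        tp = len(selected & planted)
        return tp / len(selected), tp / len(planted)

    prec_low, rec_low = _pr(set(low_ids), set(gt.planted_low_var_probes))
    ts_prec, ts_rec = [], []
    for tissue in scenario.tissues:
        p, r = _pr(
            set(tissue_specific[tissue].index),
            set(gt.planted_tissue_specific_probes[tissue]),
        )
        ts_prec.append(p)
        ts_rec.append(r)
    recovery = {
        "shared_low_precision": prec_low,
        "shared_low_recall": rec_low,
        "tissue_specific_precision": float(np.nanmean(ts_prec)),
        "tissue_specific_recall": float(np.nanmean(ts_rec)),
    }

    files = []
    selections = pd.concat(
        [
            frame.assign(tissue=tissue, kind="tissue-specific high-variance")
            for tissue, frame in tissue_specific.items()
        ]
    )
    for name, frame, kwargs in (
        ("removal_log.tsv", removal_log, {"index": False}),
        ("shared_low_variance.tsv", shared_low[shared_low["selected"]], {}),
        ("tissue_specific.tsv", selections, {}),
        ("enrichment_shared_low.tsv", enrich_low, {}),
        ("enrichment_tissue_specific.tsv", enrich_ts, {}),
        ("age_concordance.tsv", mad_table, {}),
        ("acceleration_outliers.tsv", outliers, {}),
        ("pca_scores.tsv", scores, {}),
        (
            "recovery.tsv",
            pd.Series(recovery, name="value").to_frame(),
            {},
        ),
    ):
        _write(frame, outdir / name, config, **kwargs)
        files.append(outdir / name)
    _manifest(outdir, config, files)
    return {
        "panel": filtered,
        "removal_log": removal_log,
        "per_tissue": per_tissue,
        "drop_counts": drop_counts,
        "shared_low": shared_low,
        "tissue_specific": tissue_specific,
        "enrichment_shared_low": enrich_low,
        "enrichment_tissue_specific": enrich_ts,
        "age_pairs": completed,
        "eligible_studies": eligible,
        "mad_table": mad_table,
        "acceleration_outliers": outliers,
        "pca_scores": scores,
        "pca_variance_fractions": var_fracs,
        "recovery": recovery,
        "ground_truth": gt,
    }
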