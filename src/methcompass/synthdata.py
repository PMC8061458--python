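"""Synthetic Infinium-style data with planted ground truth.

Every input the pipeline consumes can be generated here: control-probe
intensities with planted quality failures, raw methylated/unmethylated
intensities under the normal-exponential convolution with background-only
out-of-band pools, a multi-tissue Beta panel with planted low-variance,
tissue-specific, globally-variable and covariate-driven probes plus
study batch effects on the M-value scale, free-text SOFT-style metadata
records with configurable token coverage, and matching model inputs
(synthetic clock, cell-type reference, probe annotation).

One global seed fans out to named sub-streams (see ``_utils.STREAMS``) so
each product can be regenerated independently and reproducibly. Probe
"architecture" (baselines, variances, effect sizes, genotypes, annotation
classes) is drawn from the shared ``effects`` stream so the Beta panel, the
raw signals and the model files agree about the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import check_fraction, check_positive, substream
from .containers import RawSignalSet, TissueBetaPanel
from .controls import load_default_registry
from .normalize import NormexpParams, from_mvalue, to_mvalue
from .predict import CellTypeReference, ClockModel, horvath_transform

__all__ = [
    "SimScenario",
    "GroundTruth",
    "generate_ground_truth",
    "generate_control_signals",
    "generate_raw_signals",
    "generate_tissue_beta_panel",
    "generate_metadata_records",
    "generate_models",
    "simulate_normexp_draws",
]

DEFAULT_TISSUES = ("adipose", "blood", "brain", "buccal", "liver", "nasal", "sperm")
CELL_TYPES = ("neutrophil", "lymphocyte", "monocyte")
_CLOCK_LOADING = 0.08  # per-probe loading of transformed age on clock probes
_AGE_CENTER = 45.5


def _default_normexp() -> dict:
    return {
        "green": NormexpParams(mu=400.0, sigma=80.0, alpha=1.0 / 8000.0),
        "red": NormexpParams(mu=500.0, sigma=100.0, alpha=1.0 / 8000.0),
    }


@dataclass
class SimScenario:
    """Study conditions for the synthetic cohort.

    Defaults emulate the seven-tissue variability scenario: 7 tissues x 3
    studies x 40-60 samples (~150 samples/tissue across >= 2 studies), 20 000
    probes with planted shared low-variance, tissue-specific high-variance,
    globally variable, and covariate-driven probe sets; modest study batch
    shifts on the M-value scale.
    """

    seed: int = 0
    tissues: tuple = DEFAULT_TISSUES
    n_studies: int = 3  # per tissue
    samples_per_study: tuple = (40, 60)
    n_probes: int = 20000
    n_control_probes_per_type: int = 5
    normexp_params: Mapping[str, NormexpParams] = field(default_factory=_default_normexp)
    study_effect_sd: float = 0.2  # M-value units
    tissue_offset_sd: float = 0.4  # M-value units, background probes
    fail_fraction: float | Mapping[str, float] = 0.0
    low_signal_fraction: float = 0.0
    replicate_fraction: float = 0.03
    ffpe_fraction: float = 0.3
    token_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "tissue": 0.76,
            "age": 0.80,
            "sex": 0.90,
            "storage": 0.70,
            "disease": 0.80,
        }
    )
    # planted probe-set sizes (ids are assigned deterministically)
    n_clock_probes: int = 24
    n_low_var_probes: int = 200
    n_tissue_specific_per_tissue: int = 300
    n_shared_high_probes: int = 1900
    n_age_probes: int = 1200
    n_sex_probes: int = 600
    n_cell_probes: int = 600
    n_x_probes: int = 300
    n_y_probes: int = 100
    n_snp_probes: int = 60
    n_reference_probes: int = 100

    # derived probe-id sets (filled in __post_init__)
    planted_low_var_probes: frozenset = field(default=None, repr=False)
    planted_tissue_specific_probes: dict = field(default=None, repr=False)
    covariate_probe_map: dict = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for name in (
            "n_studies",
            "n_probes",
            "n_control_probes_per_type",
            "n_clock_probes",
            "n_snp_probes",
        ):
            check_positive(getattr(self, name), name)
        lo, hi = self.samples_per_study
        if not (0 < lo <= hi):
            raise ValueError("samples_per_study must be a positive (lo, hi) range")
        for frac in self._fail_fractions().values():
            check_fraction(frac, "fail_fraction")
        check_fraction(self.low_signal_fraction, "low_signal_fraction")
        check_fraction(self.replicate_fraction, "replicate_fraction")
        check_positive(self.study_effect_sd + 1e-300, "study_effect_sd")
        for par in self.normexp_params.values():
            check_positive(par.sigma, "sigma")
            check_positive(par.alpha, "alpha")

        self._partition_probes()
        sets = [self.planted_low_var_probes, *self.planted_tissue_specific_probes.values(),
                *self.covariate_probe_map.values()]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("planted probe sets must be disjoint")

    # -- probe partition ---------------------------------------------------
    def _partition_probes(self) -> None:
        need = (
            self.n_clock_probes
            + self.n_low_var_probes
            + self.n_tissue_specific_per_tissue * len(self.tissues)
            + self.n_shared_high_probes
            + self.n_age_probes
            + self.n_sex_probes
            + self.n_cell_probes
            + self.n_x_probes
            + self.n_y_probes
        )
        if need > self.n_probes:
            raise ValueError(
                f"planted sets need {need} probes but n_probes={self.n_probes}"
            )
        ids = [f"cg{i:08d}" for i in range(self.n_probes)]
        cursor = 0

        def take(n: int) -> tuple:
            nonlocal cursor
            out = tuple(ids[cursor : cursor + n])
            cursor += n
            return out

        self.clock_probes = take(self.n_clock_probes)
        low = take(self.n_low_var_probes)
        ts = {t: frozenset(take(self.n_tissue_specific_per_tissue)) for t in self.tissues}
        self.shared_high_probes = frozenset(take(self.n_shared_high_probes))
        age = take(self.n_age_probes)
        sex = take(self.n_sex_probes)
        cell = take(self.n_cell_probes)
        self.x_probes = frozenset(take(self.n_x_probes))
        self.y_probes = frozenset(take(self.n_y_probes))
        self.background_probes = tuple(ids[cursor:])
        self.snp_probes = tuple(f"rs{i:07d}" for i in range(self.n_snp_probes))
        self.cg_probes = tuple(ids)
        self.all_probes = tuple(ids) + self.snp_probes
        if self.planted_low_var_probes is None:
            self.planted_low_var_probes = frozenset(low)
        if self.planted_tissue_specific_probes is None:
            self.planted_tissue_specific_probes = ts
        if self.covariate_probe_map is None:
            self.covariate_probe_map = {
                "age": frozenset(age),
                "sex": frozenset(sex),
                "cell": frozenset(cell),
            }

    def _fail_fractions(self) -> dict:
        names = load_default_registry().names
        if isinstance(self.fail_fraction, Mapping):
            return {n: float(self.fail_fraction.get(n, 0.0)) for n in names}
        return {n: float(self.fail_fraction) for n in names}


@dataclass
class GroundTruth:
    """Planted truth: per-sample labels and the planted probe sets."""

    samples: pd.DataFrame
    planted_low_var_probes: frozenset
    planted_tissue_specific_probes: dict
    covariate_probe_map: dict
    shared_high_probes: frozenset
    clock_probes: tuple
    planted_control_failures: pd.DataFrame | None = None
    planted_restoration_low: pd.Series | None = None
    metadata_tokens: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        fr = self.samples[list(CELL_TYPES)].to_numpy()
        if (fr < 0).any() or not np.allclose(fr.sum(axis=1), 1.0):
            raise ValueError("cell fractions must be nonnegative and sum to 1")
        if (self.samples["age"] < 0).any():
            raise ValueError("ages must be >= 0")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_ground_truth(scenario: SimScenario) -> GroundTruth:
    """Deterministic cohort table (tissue, study, sex, age, cells, ...)."""
    rng = substream(scenario.seed, "samples")
    lo, hi = scenario.samples_per_study
    rows = []
    gsm = 1000001
    gse = 10001
    donor = 1
    for tissue in scenario.tissues:
        for _ in range(scenario.n_studies):
            study = f"GSE{gse:05d}"
            gse += 1
            storage = "FFPE" if rng.random() < scenario.ffpe_fraction else "FF"
            n = int(rng.integers(lo, hi + 1))
            study_rows = []
            for _ in range(n):
                sex = "male" if tissue == "sperm" else ("female" if rng.random() < 0.5 else "male")
                age = float(rng.uniform(18, 60)) if tissue == "sperm" else float(rng.uniform(1, 90))
                cells = rng.dirichlet((6.0, 3.0, 1.0))
                study_rows.append(
                    {
                        "sample_id": f"GSM{gsm:07d}",
                        "study": study,
                        "tissue": tissue,
                        "sex": sex,
                        "age": round(age, 1),
                        **dict(zip(CELL_TYPES, cells)),
                        "replicate_group": f"D{donor:06d}",
                        "storage": storage,
                        "low_signal": bool(rng.random() < scenario.low_signal_fraction),
                    }
                )
                gsm += 1
                donor += 1
            # replicates: later samples copy an earlier donor within the study
            n_rep = int(round(scenario.replicate_fraction * n))
            if n_rep and n >= 2:
                targets = rng.choice(n, size=n_rep, replace=False)
                for idx in targets:
                    src = int(rng.integers(0, n))
                    if src == idx:
                        src = (src + 1) % n
                    for key in ("replicate_group", "sex", "age", *CELL_TYPES):
                        study_rows[idx][key] = study_rows[src][key]
            rows.extend(study_rows)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return GroundTruth(
        samples=samples,
        planted_low_var_probes=scenario.planted_low_var_probes,
        planted_tissue_specific_probes=scenario.planted_tissue_specific_probes,
        covariate_probe_map=scenario.covariate_probe_map,
        shared_high_probes=scenario.shared_high_probes,
        clock_probes=scenario.clock_probes,
    )


# ---------------------------------------------------------------------------
# probe architecture (shared 'effects' stream)
# ---------------------------------------------------------------------------

class _Architecture:
    """Per-probe structural parameters shared by every generator."""

    def __init__(self, scenario: SimScenario, gt: GroundTruth):
        rng = substream(scenario.seed, "effects")
        sc = scenario
        n = sc.n_probes
        tissues = list(sc.tissues)
        nt = len(tissues)
        ids = pd.Index(sc.cg_probes)
        self.probe_index = ids
        pos = {p: i for i, p in enumerate(ids)}

        # bimodal background baselines (typical methylome shape)
        comp = rng.choice(3, size=n, p=(0.35, 0.45, 0.20))
        base = np.empty(n)
        base[comp == 0] = rng.beta(1.5, 10.0, size=(comp == 0).sum())
        base[comp == 1] = rng.beta(10.0, 1.5, size=(comp == 1).sum())
        base[comp == 2] = rng.uniform(0.0, 1.0, size=(comp == 2).sum())
        base = np.clip(base, 1e-3, 1 - 1e-3)

        offsets = rng.normal(0.0, sc.tissue_offset_sd, size=(n, nt))
        sd = rng.uniform(0.015, 0.06, size=n)

        def idx(probes) -> np.ndarray:
            return np.fromiter((pos[p] for p in probes), dtype=int)

        low = idx(sorted(sc.planted_low_var_probes))
        base[low] = rng.uniform(0.005, 0.03, size=low.size)
        offsets[low] = 0.0
        sd[low] = rng.uniform(0.001, 0.003, size=low.size)

        high = idx(sorted(sc.shared_high_probes))
        base[high] = rng.uniform(0.2, 0.8, size=high.size)
        offsets[high] = rng.normal(0.0, 0.1, size=(high.size, nt))
        # heterogeneous, tissue-constant spread so global variability is a
        # per-probe property rather than a knife-edge shared rank
        sd[high] = rng.uniform(0.10, 0.22, size=high.size)

        base_matrix = from_mvalue(
            to_mvalue(np.repeat(base[:, None], nt, axis=1)) + offsets
        )
        sd_matrix = np.repeat(sd[:, None], nt, axis=1)

        for t_i, tissue in enumerate(tissues):
            ts = idx(sorted(sc.planted_tissue_specific_probes[tissue]))
            base_matrix[ts, :] = from_mvalue(
                to_mvalue(np.clip(rng.uniform(0.1, 0.9, size=ts.size), 1e-3, 1 - 1e-3))
            )[:, None] * np.ones((1, nt))
            base_matrix[ts, t_i] = rng.uniform(0.3, 0.7, size=ts.size)
            sd_matrix[ts, :] = rng.uniform(0.015, 0.05, size=(ts.size, nt))
            sd_matrix[ts, t_i] = 0.25

        age = idx(sorted(sc.covariate_probe_map["age"]))
        base_matrix[age] = np.clip(base_matrix[age], 0.2, 0.7)
        sd_matrix[age] = 0.025
        self.age_idx = age
        self.age_slope = rng.uniform(0.0008, 0.0016, size=age.size) * rng.choice(
            (-1.0, 1.0), size=age.size
        )

        sex = idx(sorted(sc.covariate_probe_map["sex"]))
        base_matrix[sex] = np.clip(base_matrix[sex], 0.2, 0.7)
        sd_matrix[sex] = 0.025
        self.sex_idx = sex
        self.sex_effect = rng.uniform(0.03, 0.06, size=sex.size) * rng.choice(
            (-1.0, 1.0), size=sex.size
        )

        cell = idx(sorted(sc.covariate_probe_map["cell"]))
        sd_matrix[cell] = 0.025
        self.cell_idx = cell
        self.cell_reference = rng.uniform(0.1, 0.9, size=(cell.size, len(CELL_TYPES)))

        clock = idx(sc.clock_probes)
        sd_matrix[clock] = 0.01
        self.clock_idx = clock

        self.base_matrix = base_matrix
        self.sd_matrix = sd_matrix

        # study batch effects on M scale
        studies = list(pd.unique(gt.samples["study"]))
        self.studies = studies
        self.study_effects = rng.normal(0.0, sc.study_effect_sd, size=(n, len(studies)))

        # SNP genotype betas per donor
        donors = list(pd.unique(gt.samples["replicate_group"]))
        self.donors = donors
        self.snp_genotypes = rng.choice(
            (0.05, 0.5, 0.95), size=(sc.n_snp_probes, len(donors)), p=(0.25, 0.5, 0.25)
        )

        # probe colour channel
        self.channel = pd.Series(
            rng.choice(("green", "red"), size=len(sc.all_probes)),
            index=pd.Index(sc.all_probes),
        )

        # annotation classes with planted genome-context enrichments
        island_levels = np.array(["island", "shore", "shelf", "open sea"])
        gene_levels = np.array(["promoter", "body", "intergenic"])
        island = rng.choice(island_levels, size=n, p=(0.30, 0.23, 0.10, 0.37))
        gene = rng.choice(gene_levels, size=n, p=(0.30, 0.40, 0.30))
        island[low] = rng.choice(island_levels, size=low.size, p=(0.90, 0.06, 0.02, 0.02))
        gene[low] = rng.choice(gene_levels, size=low.size, p=(0.55, 0.35, 0.10))
        all_ts = idx(sorted(frozenset().union(*sc.planted_tissue_specific_probes.values())))
        island[all_ts] = rng.choice(island_levels, size=all_ts.size, p=(0.05, 0.15, 0.15, 0.65))
        gene[all_ts] = rng.choice(gene_levels, size=all_ts.size, p=(0.10, 0.60, 0.30))
        chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object)
        chrom[idx(sorted(sc.x_probes))] = "chrX"
        chrom[idx(sorted(sc.y_probes))] = "chrY"
        self.island = island
        self.gene = gene
        self.chrom = chrom


def _architecture(scenario: SimScenario, gt: GroundTruth) -> _Architecture:
    return _Architecture(scenario, gt)


def _true_betas(
    scenario: SimScenario, gt: GroundTruth, arch: _Architecture, rng: np.random.Generator
) -> pd.DataFrame:
    """Planted Beta matrix (cg + SNP probes x samples), before study effects."""
    sm = gt.samples
    tissues = list(scenario.tissues)
    tcode = sm["tissue"].map({t: i for i, t in enumerate(tissues)}).to_numpy()
    n_s = len(sm)

    beta = arch.base_matrix[:, tcode]
    beta = beta + rng.standard_normal(beta.shape) * arch.sd_matrix[:, tcode]

    ages = sm["age"].to_numpy(dtype=float)
    beta[arch.age_idx] += arch.age_slope[:, None] * (ages - _AGE_CENTER)[None, :]
    female = (sm["sex"] == "female").to_numpy(dtype=float)
    beta[arch.sex_idx] += arch.sex_effect[:, None] * (female - 0.5)[None, :]
    fr = sm[list(CELL_TYPES)].to_numpy(dtype=float)
    beta[arch.cell_idx] = (
        arch.cell_reference @ fr.T
        + rng.standard_normal((arch.cell_idx.size, n_s)) * 0.025
    )
    beta[arch.clock_idx] = (
        0.5
        + _CLOCK_LOADING * horvath_transform(ages)[None, :]
        + rng.standard_normal((arch.clock_idx.size, n_s)) * 0.01
    )
    beta = np.clip(beta, 0.0, 1.0)

    dcode = sm["replicate_group"].map(
        {d: i for i, d in enumerate(arch.donors)}
    ).to_numpy()
    snp = np.clip(
        arch.snp_genotypes[:, dcode]
        + rng.standard_normal((scenario.n_snp_probes, n_s)) * 0.01,
        0.0,
        1.0,
    )
    full = np.vstack([beta, snp])
    return pd.DataFrame(full, index=pd.Index(scenario.all_probes), columns=sm.index)


# ---------------------------------------------------------------------------
# control signals
# ---------------------------------------------------------------------------

def generate_control_signals(scenario: SimScenario):
    """Control-probe intensities with planted metric failures.

    Pass-mode draws place each metric's ratio well above its threshold
    (1.5-3x), fail-mode draws well below (0.2-0.8x, relative to
    max(threshold, 1) so the restoration metric — threshold 0 — lands in
    [0, 1), failing only the documented raised-threshold variant).
    """
    gt = generate_ground_truth(scenario)
    rng = substream(scenario.seed, "controls")
    registry = load_default_registry()
    fails = scenario._fail_fractions()
    samples = gt.samples.index
    n = len(samples)
    m = scenario.n_control_probes_per_type

    planted = pd.DataFrame(False, index=samples, columns=registry.names)
    for name in registry.names:
        planted[name] = rng.random(n) < fails[name]

    intens: dict[tuple, np.ndarray] = {}

    def jitter(shape):
        return rng.uniform(0.99, 1.01, size=shape)

    # extension probes (both channels); extension metric failures planted here
    ext_fail_g = planted["extension green"].to_numpy()
    ext_fail_r = planted["extension red"].to_numpy()
    cg_g = rng.normal(3000.0, 150.0, size=(n, m))
    cg_g[ext_fail_g] = rng.normal(350.0, 15.0, size=(int(ext_fail_g.sum()), m))
    at_g = rng.normal(90.0, 8.0, size=(n, m))
    at_r = rng.normal(3000.0, 150.0, size=(n, m))
    at_r[ext_fail_r] = rng.normal(350.0, 15.0, size=(int(ext_fail_r.sum()), m))
    cg_r = rng.normal(90.0, 8.0, size=(n, m))
    intens[("extension_cg", "green")] = np.abs(cg_g)
    intens[("extension_at", "green")] = np.abs(at_g)
    intens[("extension_at", "red")] = np.abs(at_r)
    intens[("extension_cg", "red")] = np.abs(cg_r)
    background = np.concatenate(
        [intens[("extension_cg", "green")], intens[("extension_at", "green")]], axis=1
    ).mean(axis=1)

    def target_ratios(name: str) -> np.ndarray:
        thr = max({mt.name: mt.threshold for mt in registry.metrics}[name], 1.0)
        fail = planted[name].to_numpy()
        r = thr * rng.uniform(1.5, 3.0, size=n)
        r[fail] = thr * rng.uniform(0.2, 0.8, size=int(fail.sum()))
        return r

    den_base = {"hybridization_low": 400.0}
    for metric in registry.metrics:
        if metric.name.startswith("extension"):
            continue
        r = target_ratios(metric.name)
        num, den = metric.numerator, metric.denominator
        if den == "BACKGROUND":
            key = (num.control_type, num.channel)
            intens[key] = (r * background)[:, None] * jitter((n, m))
            continue
        if num == "BACKGROUND":
            key = (den.control_type, den.channel)
            intens[key] = (background / r)[:, None] * jitter((n, m))
            continue
        dkey = (den.control_type, den.channel)
        if dkey not in intens:
            base = den_base.get(den.control_type, 800.0)
            intens[dkey] = base * rng.uniform(0.98, 1.02, size=(n, m))
        agg = {"mean": np.mean, "min": np.min, "max": np.max}[den.aggregate]
        den_val = agg(intens[dkey], axis=1)
        intens[(num.control_type, num.channel)] = (r * den_val)[:, None] * jitter((n, m))

    frames = []
    for (ctype, channel), arr in intens.items():
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(samples.to_numpy(), m),
                    "control_type": ctype,
                    "address": np.tile(np.arange(m), n),
                    "channel": channel,
                    "intensity": arr.ravel(),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)

    default_fail = planted.copy()
    default_fail["restoration"] = False  # a nonneg ratio never fails threshold 0
    gt.planted_control_failures = default_fail
    gt.planted_restoration_low = planted["restoration"].copy()
    return table, gt


# ---------------------------------------------------------------------------
# raw signals
# ---------------------------------------------------------------------------

def simulate_normexp_draws(
    params: NormexpParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(observed, background-only) draws from the normal-exponential model."""
    signal = rng.exponential(1.0 / params.alpha, size=n)
    bg = np.clip(rng.normal(params.mu, params.sigma, size=n), 0.0, None)
    oob = np.clip(rng.normal(params.mu, params.sigma, size=n), 0.0, None)
    return signal + bg, oob


def generate_raw_signals(scenario: SimScenario, oob_pool_size: int = 600):
    """Raw methylated/unmethylated intensities plus out-of-band pools."""
    gt = generate_ground_truth(scenario)
    arch = _architecture(scenario, gt)
    rng = substream(scenario.seed, "signals")
    beta = _true_betas(scenario, gt, arch, rng).to_numpy()
    sm = gt.samples
    n_p, n_s = beta.shape

    chan = arch.channel.to_numpy()
    mean_signal = np.where(
        chan == "green",
        1.0 / scenario.normexp_params["green"].alpha,
        1.0 / scenario.normexp_params["red"].alpha,
    )
    scale = np.where(sm["low_signal"].to_numpy(), 0.15, 1.0)
    total = rng.exponential(1.0, size=(n_p, n_s)) * mean_signal[:, None] * scale[None, :]

    probe_ids = pd.Index(scenario.all_probes)
    female = (sm["sex"] == "female").to_numpy()
    y_rows = probe_ids.isin(scenario.y_probes)
    x_rows = probe_ids.isin(scenario.x_probes)
    total[np.ix_(y_rows, female)] *= 0.02
    total[np.ix_(x_rows, ~female)] *= 0.55

    mus = np.where(chan == "green", scenario.normexp_params["green"].mu,
                   scenario.normexp_params["red"].mu)[:, None]
    sigmas = np.where(chan == "green", scenario.normexp_params["green"].sigma,
                      scenario.normexp_params["red"].sigma)[:, None]
    meth = beta * total + np.clip(rng.normal(mus, sigmas, size=(n_p, n_s)), 0.0, None)
    unmeth = (1.0 - beta) * total + np.clip(
        rng.normal(mus, sigmas, size=(n_p, n_s)), 0.0, None
    )

    g = scenario.normexp_params["green"]
    r = scenario.normexp_params["red"]
    oob_grn = np.clip(rng.normal(g.mu, g.sigma, size=(oob_pool_size, n_s)), 0.0, None)
    oob_red = np.clip(rng.normal(r.mu, r.sigma, size=(oob_pool_size, n_s)), 0.0, None)

    signals = RawSignalSet(
        meth=pd.DataFrame(meth, index=probe_ids, columns=sm.index),
        unmeth=pd.DataFrame(unmeth, index=probe_ids, columns=sm.index),
        oob_grn=pd.DataFrame(oob_grn, columns=sm.index),
        oob_red=pd.DataFrame(oob_red, columns=sm.index),
        probe_channel=arch.channel,
    )
    return signals, gt


# ---------------------------------------------------------------------------
# tissue beta panel
# ---------------------------------------------------------------------------

def generate_tissue_beta_panel(scenario: SimScenario):
    """Probes x samples Beta panel with planted structure and study effects."""
    if scenario.n_studies < 2:
        raise ValueError("tissue eligibility requires >= 2 studies per tissue")
    gt = generate_ground_truth(scenario)
    arch = _architecture(scenario, gt)
    rng = substream(scenario.seed, "panel")
    beta = _true_betas(scenario, gt, arch, rng)

    scode = gt.samples["study"].map(
        {s: i for i, s in enumerate(arch.studies)}
    ).to_numpy()
    effects = np.vstack(
        [arch.study_effects, np.zeros((scenario.n_snp_probes, len(arch.studies)))]
    )
    adjusted = from_mvalue(to_mvalue(beta.to_numpy()) + effects[:, scode])
    betas = pd.DataFrame(adjusted, index=beta.index, columns=beta.columns)
    panel = TissueBetaPanel(betas=betas, samples=gt.samples.copy())
    return panel, gt


# ---------------------------------------------------------------------------
# metadata records
# ---------------------------------------------------------------------------

_TISSUE_FORMS = {
    "blood": ("Whole Blood", "peripheral blood", "blood"),
    "brain": ("brain", "Brain tissue (prefrontal cortex)"),
    "buccal": ("buccal", "buccal swab"),
    "nasal": ("nasal epithelium", "nasal"),
    "adipose": ("adipose", "adipose tissue"),
    "liver": ("Liver", "liver biopsy"),
    "sperm": ("sperm", "semen sample"),
}
_DISEASE_FORMS = {
    # surface form -> expected controlled-vocabulary terms
    "healthy control": frozenset({"healthy", "control"}),
    "control subject": frozenset({"control"}),
    "severely obese patient": frozenset({"obese"}),
    "Parkinson's disease": frozenset({"parkinson's disease"}),
    "rheumatoid arthritis": frozenset({"arthritis"}),
}
_STUDY_CONDITIONS = (
    "healthy control",
    "control subject",
    "severely obese patient",
    "Parkinson's disease",
    "rheumatoid arthritis",
)


def generate_metadata_records(scenario: SimScenario):
    """SOFT-style text blocks, one per sample, with token bookkeeping."""
    gt = generate_ground_truth(scenario)
    rng = substream(scenario.seed, "metadata")
    tf = scenario.token_fractions
    study_condition = {
        s: _STUDY_CONDITIONS[int(rng.integers(0, len(_STUDY_CONDITIONS)))]
        for s in pd.unique(gt.samples["study"])
    }
    records, token_rows = [], []
    for sample_id, row in gt.samples.iterrows():
        lines = [
            f"^SAMPLE = {sample_id}",
            f"!Sample_geo_accession = {sample_id}",
            f"!Sample_series_id = {row['study']}",
            "!Sample_platform_id = GPL13534",
        ]
        toks = {"sample_id": sample_id}

        toks["tissue_token"] = rng.random() < tf.get("tissue", 1.0)
        if toks["tissue_token"]:
            forms = _TISSUE_FORMS.get(row["tissue"], (row["tissue"],))
            surface = forms[int(rng.integers(0, len(forms)))]
            style = int(rng.integers(0, 3))
            if style == 0:
                lines.append(f"!Sample_characteristics_ch1 = tissue: {surface}")
            elif style == 1:
                lines.append(f"!Sample_characteristics_ch1 = Tissue type: {surface}")
            else:
                lines.append(f"!Sample_source_name_ch1 = {surface}")
            lines.insert(1, f"!Sample_title = {surface} sample")
        else:
            lines.insert(1, "!Sample_title = sample")

        toks["age_token"] = rng.random() < tf.get("age", 1.0)
        toks["age_value"] = np.nan
        if toks["age_token"]:
            age = float(row["age"])
            if age < 2.0 and rng.random() < 0.5:
                months = int(round(age * 12))
                lines.append(f"!Sample_characteristics_ch1 = age: {months} months")
                toks["age_value"] = months / 12.0
            else:
                years = int(round(age))
                phr = (
                    f"age: {years} years",
                    f"age (yrs): {years}",
                    f"Age: {years}",
                    f"age: {years} y",
                )[int(rng.integers(0, 4))]
                lines.append(f"!Sample_characteristics_ch1 = {phr}")
                toks["age_value"] = float(years)

        toks["sex_token"] = rng.random() < tf.get("sex", 1.0)
        if toks["sex_token"]:
            if row["sex"] == "female":
                phr = ("Sex: F", "Sex: Female", "gender: female")[int(rng.integers(0, 3))]
            else:
                phr = ("Sex: M", "Sex: Male", "gender: male")[int(rng.integers(0, 3))]
            lines.append(f"!Sample_characteristics_ch1 = {phr}")

        toks["storage_token"] = rng.random() < tf.get("storage", 1.0)
        if toks["storage_token"]:
            if row["storage"] == "FFPE":
                phr = ("ffpe", "FFPE", "formalin-fixed paraffin embedded")[
                    int(rng.integers(0, 3))
                ]
            else:
                phr = ("fresh frozen", "FF", "frozen")[int(rng.integers(0, 3))]
            lines.append(f"!Sample_characteristics_ch1 = storage: {phr}")

        toks["disease_token"] = rng.random() < tf.get("disease", 1.0)
        condition = study_condition[row["study"]]
        toks["disease_terms"] = (
            _DISEASE_FORMS[condition] if toks["disease_token"] else frozenset()
        )
        if toks["disease_token"]:
            lines.append(f"!Sample_characteristics_ch1 = disease state: {condition}")

        records.append("\n".join(lines) + "\n")
        token_rows.append(toks)

    gt.metadata_tokens = pd.DataFrame(token_rows).set_index("sample_id")
    return records, gt


# ---------------------------------------------------------------------------
# models and annotation
# ---------------------------------------------------------------------------

def generate_models(scenario: SimScenario):
    """Synthetic clock, cell-type reference and probe annotation table.

    The clock is exact on noise-free planted betas: each clock probe carries
    beta = 0.5 + a*F(age), and with coefficient 1/(K*a) per probe and
    intercept -0.5/a the linear score recovers F(age) identically.
    """
    gt = generate_ground_truth(scenario)
    arch = _architecture(scenario, gt)
    a = _CLOCK_LOADING
    k = scenario.n_clock_probes
    coefs = pd.Series(1.0 / (k * a), index=pd.Index(scenario.clock_probes))
    clock = ClockModel(intercept=-0.5 / a, coefficients=coefs, adult_age=20.0)

    ref_idx = arch.cell_idx[: scenario.n_reference_probes]
    ref_ids = arch.probe_index[ref_idx]
    reference = CellTypeReference(
        betas=pd.DataFrame(
            arch.cell_reference[: scenario.n_reference_probes],
            index=ref_ids,
            columns=list(CELL_TYPES),
        )
    )

    rng = substream(scenario.seed, "models")
    snp_chrom = np.array(
        [f"chr{c}" for c in rng.integers(1, 23, size=scenario.n_snp_probes)],
        dtype=object,
    )
    annotation = pd.DataFrame(
        {
            "chrom": np.concatenate([arch.chrom, snp_chrom]),
            "island_relation": np.concatenate(
                [arch.island, np.full(scenario.n_snp_probes, "open sea", dtype=object)]
            ),
            "gene_relation": np.concatenate(
                [arch.gene, np.full(scenario.n_snp_probes, "intergenic", dtype=object)]
            ),
            "probe_type": ["cg"] * scenario.n_probes + ["rs"] * scenario.n_snp_probes,
        },
        index=pd.Index(scenario.all_probes, name="probe_id"),
    )
    return clock, reference, annotation
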