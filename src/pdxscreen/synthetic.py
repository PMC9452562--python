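"""Seedable generators for every input table the pipeline consumes.

Each generator emulates the statistical structure the corresponding analysis
assumes: exponential tumor growth with arm- and class-specific rates plus
multiplicative caliper noise; ordinal IHC panels whose composite-rule call
disagrees with the true response class at a configurable label-noise rate;
per-patient Bernoulli alteration flags whose double-hit x exposure interaction
equals a configured log odds ratio; spheroid-area changes with class-separated
means; four-parameter-logistic dose plates; and Ct matrices with stable and
unstable reference genes.

Every generator is a pure function of its config (master seed included): each
draws from its own RNG stream derived from the master seed by a stable label,
so adding a generator never shifts another's output, and regeneration is
byte-identical. Truth keys are returned as separate tables, never embedded in
analysis inputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .exvivo import DosePlate

__all__ = [
    "SyntheticConfig",
    "GrowthConfig",
    "BiomarkerConfig",
    "GenomicConfig",
    "SpheroidConfig",
    "DosePlateConfig",
    "QpcrConfig",
    "gen_growth_cohort",
    "gen_biomarker_cohort",
    "gen_genomic_cohort",
    "gen_spheroid_cohort",
    "gen_dose_plate",
    "gen_qpcr",
]


def _rng(seed: int, label: str) -> np.random.Generator:
    """Generator-specific RNG stream: master seed + CRC32 of a stable label."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass
class GrowthConfig:
    """Study-scale growth screen: ~21 evaluable models, 2-8 tumors each,
    vehicle + treated arms, caliper days 0-35 twice weekly.

    ``class_counts`` fixes how many models belong to each true response class;
    ``class_day35_pct`` is the noise-free percent volume change each class
    reaches at day 35 (rates are back-solved from it), placed well inside the
    corresponding response band. Vehicle arms always grow.
    """

    class_counts: dict = field(
        default_factory=lambda: {"CR": 1, "PR": 2, "SD": 2, "PD": 16}
    )
    class_day35_pct: dict = field(
        default_factory=lambda: {"CR": -97.5, "PR": -60.0, "SD": -5.0, "PD": 300.0}
    )
    vehicle_day35_pct: float = 300.0
    tumors_per_model: tuple = (2, 8)
    days: tuple = (0, 4, 7, 11, 14, 18, 21, 25, 28, 32, 35)
    baseline_volume_range: tuple = (100.0, 300.0)  # mm^3, randomization window
    noise_sd: float = 0.10  # SD of lognormal multiplicative volume noise
    aspect_ratio: float = 1.5  # length/width used to back-solve caliper dims
    max_volume: float = 1500.0  # welfare truncation: series stops beyond this


@dataclass
class BiomarkerConfig:
    """IHC panel generator: score patterns realize the intended composite
    call; the observed call disagrees with the true class at rate
    ``label_noise``."""

    n_samples: int = 200
    resistant_prevalence: float = 0.65
    label_noise: float = 0.15


@dataclass
class GenomicConfig:
    """Exposure cohort with a tunable double-hit x exposure log odds ratio.

    Marginal alteration prevalences are set so the smallest interaction cell
    keeps roughly >= 10 expected events at the default cohort size, keeping
    Wald inference in its asymptotic regime (see docs/methods.md).
    """

    n_patients: int = 582
    exposure_prevalence: float = 71.0 / 582.0
    p_mutation: float = 0.30
    p_deletion: float = 0.45
    double_hit_log_or: float = 0.0
    gene: str = "RB1"


@dataclass
class SpheroidConfig:
    """Spheroid-area readouts with class-conditional change distributions
    (percent of vehicle - 100): sensitive N(-50, 10), resistant N(0, 10)."""

    n_models: int = 37
    sensitive_fraction: float = 0.4
    sensitive_mean: float = -50.0
    resistant_mean: float = 0.0
    change_sd: float = 10.0
    n_replicates: int = 3
    replicate_cv: float = 0.05
    vehicle_area: float = 1.0e4


@dataclass
class DosePlateConfig:
    """4PL dose plate: 8 log-spaced doses plus vehicle wells, day0/day6
    growth values with multiplicative noise."""

    ic50: float = 1.0  # micromolar
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    n_doses: int = 8
    dose_min: float = 1e-3
    dose_max: float = 1e2
    n_replicates: int = 3
    vehicle_growth: float = 5.0  # day6/day0 fold growth of vehicle wells
    day0_value: float = 100.0
    noise_sd: float = 0.0  # SD of lognormal noise on well values


@dataclass
class QpcrConfig:
    """Ct matrix with shared per-sample offsets (so ratio-stable reference
    genes exist), unstable candidates, and a group effect on some targets."""

    n_samples: int = 12
    stable_genes: tuple = ("GAPDH", "ACTB")
    unstable_genes: tuple = ("RPL13A",)
    target_genes: tuple = ("CCND1", "CCNE1", "RB1", "CDKN2A", "CCNB2", "BID")
    sample_offset_sd: float = 1.0
    stable_noise_sd: float = 0.05
    unstable_noise_sd: float = 1.0
    target_noise_sd: float = 0.3
    affected_genes: tuple = ("CCNE1",)
    group_effect_ct: float = -2.0  # Ct shift in the "treated" group
    base_ct_range: tuple = (18.0, 30.0)


@dataclass
class SyntheticConfig:
    """Master config: one seed, one sub-config per generator."""

    seed: int
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    biomarker: BiomarkerConfig = field(default_factory=BiomarkerConfig)
    genomic: GenomicConfig = field(default_factory=GenomicConfig)
    spheroid: SpheroidConfig = field(default_factory=SpheroidConfig)
    dose_plate: DosePlateConfig = field(default_factory=DosePlateConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name, rate in [
            ("biomarker.resistant_prevalence", self.biomarker.resistant_prevalence),
            ("biomarker.label_noise", self.biomarker.label_noise),
            ("genomic.exposure_prevalence", self.genomic.exposure_prevalence),
            ("genomic.p_mutation", self.genomic.p_mutation),
            ("genomic.p_deletion", self.genomic.p_deletion),
            ("spheroid.sensitive_fraction", self.spheroid.sensitive_fraction),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name}={rate} outside [0, 1]")
        if self.growth.noise_sd < 0 or self.dose_plate.noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")

    def to_dict(self) -> dict:
        """Serializable echo of the full configuration."""
        return asdict(self)


def _dims_from_volume(volume: float, aspect_ratio: float) -> tuple[float, float]:
    """Back-solve caliper length/width from an ellipsoid volume with a fixed
    aspect ratio L = ar * W: V = ar * W^3 * pi/6."""
    width = (6.0 * volume / (math.pi * aspect_ratio)) ** (1.0 / 3.0)
    return aspect_ratio * width, width


def gen_growth_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Caliper measurement table plus the true-class key.

    V(t) = V0 * exp(r t) with the class rate r solved from the day-35 target;
    measured volumes carry lognormal noise and are converted back to
    length/width at a fixed aspect ratio. Vehicle arms grow for every model.
    Measurements stop once the noise-free volume passes the welfare cap.
    """
    g = config.growth
    rng = _rng(config.seed, "growth")
    horizon = float(max(g.days))
    rows, truth = [], []
    model_idx = 0
    for cls in ("CR", "PR", "SD", "PD"):
        n_models = int(g.class_counts.get(cls, 0))
        rate = math.log1p(g.class_day35_pct[cls] / 100.0) / horizon
        vehicle_rate = math.log1p(g.vehicle_day35_pct / 100.0) / horizon
        for _ in range(n_models):
            model_idx += 1
            model_id = f"SIM{model_idx:03d}"
            truth.append({"model_id": model_id, "true_class": cls, "rate": rate})
            n_tumors = int(rng.integers(g.tumors_per_model[0], g.tumors_per_model[1] + 1))
            for arm, r in (("treated", rate), ("vehicle", vehicle_rate)):
                for t in range(n_tumors):
                    v0 = rng.uniform(*g.baseline_volume_range)
                    for day in g.days:
                        v_true = v0 * math.exp(r * day)
                        if v_true > g.max_volume:
                            break
                        v_obs = v_true * math.exp(rng.normal(0.0, g.noise_sd))
                        length, width = _dims_from_volume(v_obs, g.aspect_ratio)
                        rows.append(
                            {
                                "model_id": model_id,
                                "animal_id": f"{model_id}-{arm[0]}{t + 1}",
                                "arm": arm,
                                "day": day,
                                "length_mm": length,
                                "width_mm": width,
                            }
                        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


_LUMINAL = ("LumA", "LumB")
_RESISTANT_RULES = ("basal_subtype", "p16_high", "prb_low", "cyclin_e1", "cyclin_d1")


def _sensitive_scores(rng: np.random.Generator) -> dict:
    """Score pattern that fires no composite rule."""
    return {
        "p16": int(rng.integers(0, 2)),  # < 2
        "prb": int(rng.integers(3, 5)),  # > 2
        "cyclin_e1": int(rng.integers(0, 5)),  # <= 4
        "cyclin_d1": int(rng.integers(0, 7)),  # <= 6
        "subtype": str(rng.choice(_LUMINAL)),
    }


def gen_biomarker_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IHC panel table plus the true response key.

    Each sample draws a true class (resistant with the configured prevalence);
    with probability ``label_noise`` the panel realizes the opposite composite
    call. Resistant-call panels fire one uniformly chosen rule; sensitive-call
    panels keep every score below threshold. Measured composite accuracy
    against the truth is therefore 1 - label_noise in expectation.
    """
    b = config.biomarker
    rng = _rng(config.seed, "biomarker")
    rows, truth = [], []
    for i in range(b.n_samples):
        sid = f"S{i + 1:04d}"
        true_resistant = rng.random() < b.resistant_prevalence
        flip = rng.random() < b.label_noise
        call_resistant = true_resistant ^ flip
        scores = _sensitive_scores(rng)
        if call_resistant:
            rule = str(rng.choice(_RESISTANT_RULES))
            if rule == "basal_subtype":
                scores["subtype"] = "Basal"
            elif rule == "p16_high":
                scores["p16"] = int(rng.integers(2, 5))
            elif rule == "prb_low":
                scores["prb"] = int(rng.integers(0, 3))
            elif rule == "cyclin_e1":
                scores["cyclin_e1"] = int(rng.integers(5, 9))
            else:
                scores["cyclin_d1"] = int(rng.integers(7, 9))
        rows.append({"sample_id": sid, **scores})
        truth.append(
            {
                "sample_id": sid,
                "true_response": "resistant" if true_resistant else "sensitive",
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def _exposed_cell_probs(g: GenomicConfig) -> np.ndarray:
    """Joint (mutation, deletion) cell probabilities among exposed patients.

    Unexposed cells are independent Bernoulli products; exposed cells tilt the
    (1,1) cell by exp(theta). The cross-product ratio of exposure odds across
    the four cells then equals exp(theta) exactly, so the logistic interaction
    coefficient targets theta.
    """
    pm, pd_ = g.p_mutation, g.p_deletion
    base = np.array(
        [
            (1 - pm) * (1 - pd_),  # (0,0)
            pm * (1 - pd_),  # (1,0)
            (1 - pm) * pd_,  # (0,1)
            pm * pd_ * math.exp(g.double_hit_log_or),  # (1,1)
        ]
    )
    return base / base.sum()


def gen_genomic_cohort(
    config: SyntheticConfig, realize_tables: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Exposure cohort (patient_id, exposed, mutation, deletion) and —
    optionally — variant/copy-number tables realizing the flags.

    Returns ``(cohort, variants, copy_numbers)``; the latter two are None
    unless ``realize_tables``. Realized mutations draw a protein-change string
    whose parsed consequence qualifies under the coding rule set; realized
    deletions carry allele copy numbers (minor < 0.01, major ~ 1).
    """
    g = config.genomic
    rng = _rng(config.seed, "genomic")
    pm, pd_ = g.p_mutation, g.p_deletion
    unexposed = np.array(
        [(1 - pm) * (1 - pd_), pm * (1 - pd_), (1 - pm) * pd_, pm * pd_]
    )
    exposed = _exposed_cell_probs(g)
    cells = np.array([(0, 0), (1, 0), (0, 1), (1, 1)])

    n = g.n_patients
    exp_flags = rng.random(n) < g.exposure_prevalence
    rows = []
    for i in range(n):
        probs = exposed if exp_flags[i] else unexposed
        m, d = cells[rng.choice(4, p=probs)]
        rows.append(
            {
                "patient_id": f"P{i + 1:04d}",
                "exposed": int(exp_flags[i]),
                "mutation": int(m),
                "deletion": int(d),
            }
        )
    cohort = pd.DataFrame(rows)
    if not realize_tables:
        return cohort, None, None

    styles = ("frameshift", "stop", "splice", "missense")
    var_rows, cn_rows = [], []
    for r in cohort.itertuples():
        if r.mutation:
            style = styles[int(rng.integers(0, len(styles)))]
            pos = int(rng.integers(50, 900))
            if style == "frameshift":
                pc = f"p.M{pos}Nfs*{int(rng.integers(2, 40))}"
            elif style == "stop":
                pc = f"p.K{pos}*"
            elif style == "splice":
                pc = f"p.X{pos}_splice"
            else:
                pc = f"p.H{pos}R"
            var_rows.append(
                {"sample_id": r.patient_id, "gene": g.gene, "protein_change": pc}
            )
        minor = 0.0 if r.deletion else float(rng.uniform(0.8, 1.2))
        major = float(rng.uniform(0.8, 1.2))
        cn_rows.append(
            {
                "sample_id": r.patient_id,
                "gene": g.gene,
                "minor_cn": min(minor, major),
                "major_cn": max(minor, major),
            }
        )
    variants = pd.DataFrame(var_rows, columns=["sample_id", "gene", "protein_change"])
    copy_numbers = pd.DataFrame(cn_rows)
    return cohort, variants, copy_numbers


def gen_spheroid_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format spheroid-area table (model_id, condition, replicate, area)
    plus the true class key with each model's noise-free area change."""
    s = config.spheroid
    rng = _rng(config.seed, "spheroid")
    rows, truth = [], []
    for i in range(s.n_models):
        model_id = f"PDC{i + 1:03d}"
        sensitive = rng.random() < s.sensitive_fraction
        mean = s.sensitive_mean if sensitive else s.resistant_mean
        change = float(rng.normal(mean, s.change_sd))
        treated_mean = s.vehicle_area * max(1.0 + change / 100.0, 1e-3)
        for rep in range(s.n_replicates):
            rows.append(
                {
                    "model_id": model_id,
                    "condition": "vehicle",
                    "replicate": rep + 1,
                    "area": s.vehicle_area
                    * math.exp(rng.normal(0.0, s.replicate_cv)),
                }
            )
            rows.append(
                {
                    "model_id": model_id,
                    "condition": "treated",
                    "replicate": rep + 1,
                    "area": treated_mean * math.exp(rng.normal(0.0, s.replicate_cv)),
                }
            )
        truth.append(
            {
                "model_id": model_id,
                "true_response": "sensitive" if sensitive else "resistant",
                "true_change_pct": change,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def gen_dose_plate(config: SyntheticConfig) -> DosePlate:
    """One dose-response plate from known 4PL parameters.

    Vehicle wells grow ``vehicle_growth``-fold between day 0 and day 6;
    treated wells scale that growth by the 4PL percent response, and every
    well value carries lognormal noise. With ``noise_sd = 0`` the normalized
    responses reproduce the 4PL exactly.
    """
    p = config.dose_plate
    rng = _rng(config.seed, "dose_plate")
    doses = np.concatenate(
        [[0.0], np.geomspace(p.dose_min, p.dose_max, p.n_doses)]
    )
    frac = np.empty_like(doses)
    frac[0] = 1.0
    d = doses[1:]
    pct = p.bottom + (p.top - p.bottom) / (1.0 + (d / p.ic50) ** p.hill)
    frac[1:] = pct / 100.0
    shape = (doses.size, p.n_replicates)
    day0 = p.day0_value * np.exp(rng.normal(0.0, p.noise_sd, shape))
    day6 = (
        p.day0_value
        * p.vehicle_growth
        * frac[:, None]
        * np.exp(rng.normal(0.0, p.noise_sd, shape))
    )
    return DosePlate(doses=doses, day0=day0, day6=day6)


def gen_qpcr(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Ct matrix (genes x samples), sample group labels, and the truth table.

    Stable reference genes share the per-sample offset exactly (plus tiny
    noise), so their pairwise ratios are near-constant; unstable candidates
    add large gene-specific noise. Affected target genes shift by
    ``group_effect_ct`` cycles in the "treated" group.
    """
    q = config.qpcr
    rng = _rng(config.seed, "qpcr")
    samples = [f"T{i + 1:02d}" for i in range(q.n_samples)]
    half = q.n_samples // 2
    groups = pd.Series(
        ["vehicle"] * half + ["treated"] * (q.n_samples - half),
        index=samples,
        name="group",
    )
    offsets = rng.normal(0.0, q.sample_offset_sd, q.n_samples)
    genes = list(q.stable_genes) + list(q.unstable_genes) + list(q.target_genes)
    base = {g: float(rng.uniform(*q.base_ct_range)) for g in genes}
    data = {}
    for gname in genes:
        if gname in q.stable_genes:
            noise = rng.normal(0.0, q.stable_noise_sd, q.n_samples)
        elif gname in q.unstable_genes:
            noise = rng.normal(0.0, q.unstable_noise_sd, q.n_samples)
        else:
            noise = rng.normal(0.0, q.target_noise_sd, q.n_samples)
        ct = base[gname] + offsets + noise
        if gname in q.affected_genes:
            ct = ct + np.where(groups.to_numpy() == "treated", q.group_effect_ct, 0.0)
        data[gname] = ct
    ct_matrix = pd.DataFrame(data, index=samples).T
    truth = pd.DataFrame(
        {
            "gene": genes,
            "role": [
                "stable_reference"
                if g in q.stable_genes
                else "unstable_reference"
                if g in q.unstable_genes
                else "target"
                for g in genes
            ],
            "group_affected": [g in q.affected_genes for g in genes],
        }
    )
    return ct_matrix, groups, truth
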