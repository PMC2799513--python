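"""Synthetic-cohort generation with known planted truth.

Every downstream stage of the pipeline (lesion quantification, differential
expression, gene-set scoring, pattern extraction, clinical correlation) is
exercised against cohorts generated here, so each generator returns both the
data and a :class:`PlantedTruth` record of exactly what was planted.

The generators emulate a two-cohort blood study design:

* **Expression** — genes x samples log2 ratios versus a universal reference.
  Differentially expressed genes receive a fixed mean shift between cases and
  controls (half up, half down); co-expression pattern members are linear
  functions of a per-sample clinical covariate plus independent noise, with
  the noise scaled to hit a target within-pattern correlation.  Measurement
  noise is additive Gaussian on the log2 scale.
* **QPCR** — per-sample amplification signals follow the Poisson zero class:
  ``signal = copy_factor * exp(-lambda) * noise_factor`` where ``lambda`` is
  the planted lesion density times amplicon length.  The copy factor is
  log-normal and shared across all amplicons of a genome within a sample
  (mitochondrial copy number varies between blood draws); measurement noise is
  an independent log-normal factor per well.  Short amplicons get the same
  model — their lambda is tiny simply because they are short.
* **Gene sets** — GMT-style catalogs with selected genes planted into an exact
  number of sets, remaining slots filled uniformly from the universe.
* **Clinical** — a frataxin ddCt drawn from a two-component Gaussian mixture
  (the bimodal expression distribution seen in patient cohorts) plus age of
  onset, ICARS disability score, and GAA repeat length constructed to achieve
  target squared correlations with ddCt in expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr_damage import (
    AmpliconSpec,
    ConfigurationError,
    DEFAULT_AMPLICONS,
    validate_amplicons,
)


@dataclass(frozen=True)
class PatternSpec:
    """A planted co-expression pattern tied to one clinical covariate.

    ``covariate_group_shift`` adds a case-vs-control mean difference to the
    covariate itself, giving the planted pattern a between-group contrast
    (high SNR); at 0 the pattern is orthogonal to the group structure.
    """

    n_member_genes: int
    covariate_name: str
    loading: float  # log2 units per covariate unit
    within_pattern_corr_target: float = 0.9
    covariate_group_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_member_genes < 2:
            raise ConfigurationError("a pattern needs at least 2 member genes")
        if not 0 < self.within_pattern_corr_target <= 1:
            raise ConfigurationError("within_pattern_corr_target must be in (0, 1]")


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_cases: int
    n_controls: int
    n_genes: int
    n_de_genes: int
    de_log2_shift: float
    noise_sd: float
    patterns: tuple[PatternSpec, ...] = ()
    #: Anticorrelate the latent (non-group) parts of the pattern covariates at
    #: pairwise correlation -1/(k-1).  With a single case/control axis, same-sign
    #: group shifts induce positive cross-pattern correlation; anticorrelated
    #: latents cancel part of it so distinct planted patterns stay separable.
    anticorrelate_pattern_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_de_genes < 0:
            raise ConfigurationError("n_de_genes must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        n_pattern = sum(p.n_member_genes for p in self.patterns)
        if self.n_de_genes + n_pattern > self.n_genes:
            raise ConfigurationError(
                f"{self.n_de_genes} DE + {n_pattern} pattern genes exceed n_genes={self.n_genes}"
            )


@dataclass(frozen=True)
class QpcrSimConfig:
    n_cases: int
    n_controls: int
    lesions_per_10kb_cases: Mapping[str, float]
    lesions_per_10kb_controls: Mapping[str, float]
    amplicons: tuple[AmpliconSpec, ...] = DEFAULT_AMPLICONS
    copy_number_cv: float = 0.0
    measurement_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("group sizes must be > 0")
        if self.copy_number_cv < 0 or self.measurement_cv < 0:
            raise ConfigurationError("coefficients of variation must be >= 0")
        by_name = validate_amplicons(self.amplicons)
        target_genomes = {a.genome for a in by_name.values() if a.role == "damage_target"}
        for rates in (self.lesions_per_10kb_cases, self.lesions_per_10kb_controls):
            for genome, rate in rates.items():
                if rate < 0:
                    raise ConfigurationError(f"negative lesion rate for {genome}: {rate}")
                if genome not in target_genomes:
                    raise ConfigurationError(
                        f"lesion rate given for {genome!r} but no damage-target amplicon exists"
                    )


@dataclass
class PlantedTruth:
    """What a simulation planted, keyed so tests can look everything up."""

    de_gene_ids: dict[str, str] = field(default_factory=dict)  # gene -> "up" | "down"
    pattern_memberships: dict[str, list[str]] = field(default_factory=dict)
    true_lesions_per_10kb: dict[str, float] = field(default_factory=dict)  # "group/genome"
    covariate_values: dict[str, list[float]] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Generate a genes x samples log2-ratio matrix with planted DE genes and patterns.

    Returns ``(matrix, labels, truth)`` where ``matrix`` is indexed by gene id
    with sample-id columns, ``labels`` maps sample id to ``case``/``control``,
    and ``truth`` records the planted DE directions, pattern memberships, and
    covariate values.  Identical config (including seed) gives bitwise-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"case_{i+1}" for i in range(config.n_cases)] + [
        f"ctrl_{i+1}" for i in range(config.n_controls)
    ]
    gene_ids = [f"g{i+1:05d}" for i in range(config.n_genes)]
    labels = pd.Series(
        ["case"] * config.n_cases + ["control"] * config.n_controls,
        index=sample_ids, name="group",
    )
    case_mask = np.arange(n) < config.n_cases

    mat = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n)) if config.noise_sd > 0 \
        else np.zeros((config.n_genes, n))

    truth = PlantedTruth(sample_ids=sample_ids)

    # DE genes occupy the first rows: half shifted up in cases, half down.
    n_up = config.n_de_genes // 2 + config.n_de_genes % 2
    for i in range(config.n_de_genes):
        direction = "up" if i < n_up else "down"
        shift = config.de_log2_shift if direction == "up" else -config.de_log2_shift
        mat[i, case_mask] += shift
        truth.de_gene_ids[gene_ids[i]] = direction

    # Pattern members follow loading * covariate + noise; the noise variance is
    # set from the target within-pattern correlation r: two members share the
    # covariate term, so r = var_signal / (var_signal + var_noise).
    latents: dict[str, np.ndarray] = {}
    fresh_names = [p.covariate_name for p in config.patterns]
    fresh_names = list(dict.fromkeys(fresh_names))
    if config.anticorrelate_pattern_covariates and len(fresh_names) > 1:
        k = len(fresh_names)
        g = rng.normal(0.0, 1.0, size=(k, n))
        z = (g - g.mean(axis=0)) / math.sqrt((k - 1) / k)  # pairwise corr -1/(k-1)
        latents = dict(zip(fresh_names, z))
    row = config.n_de_genes
    for k, spec in enumerate(config.patterns, start=1):
        if spec.covariate_name in truth.covariate_values:
            cov = np.asarray(truth.covariate_values[spec.covariate_name])
        else:
            cov = latents.get(spec.covariate_name)
            if cov is None:
                cov = rng.normal(0.0, 1.0, size=n)
            else:
                cov = cov.copy()
            cov[case_mask] += spec.covariate_group_shift
            truth.covariate_values[spec.covariate_name] = cov.tolist()
        r = spec.within_pattern_corr_target
        sig_sd = abs(spec.loading) * float(np.std(cov)) or 1.0
        noise_sd = 0.0 if r == 1.0 else sig_sd * math.sqrt((1 - r) / r)
        pat_id = f"pattern_{k}"
        members = []
        for _ in range(spec.n_member_genes):
            mat[row] = spec.loading * cov + (
                rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
            )
            members.append(gene_ids[row])
            row += 1
        truth.pattern_memberships[pat_id] = members

    matrix = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# QPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(config: QpcrSimConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a long-amplicon QPCR amplification table from planted lesion densities.

    Per sample and amplicon: ``signal = copy_factor * exp(-lambda) * noise``
    with ``lambda = lesions_per_10kb * length_kb / 10``.  The copy factor is
    shared by all amplicons of the same genome within a sample, which is what
    the short-fragment normalization removes.
    """
    rng = np.random.default_rng(config.seed)
    by_name = validate_amplicons(config.amplicons)
    samples = [("case", f"case_{i+1}") for i in range(config.n_cases)] + [
        ("control", f"ctrl_{i+1}") for i in range(config.n_controls)
    ]
    genomes = sorted({a.genome for a in by_name.values()})

    rows = []
    truth = PlantedTruth(sample_ids=[sid for _, sid in samples])
    for group, rates in (("case", config.lesions_per_10kb_cases),
                         ("control", config.lesions_per_10kb_controls)):
        for genome, rate in rates.items():
            truth.true_lesions_per_10kb[f"{group}/{genome}"] = float(rate)

    for group, sid in samples:
        rates = (config.lesions_per_10kb_cases if group == "case"
                 else config.lesions_per_10kb_controls)
        copy_factors = {
            g: float(_lognormal_factors(rng, config.copy_number_cv, None)) for g in genomes
        }
        for amp in by_name.values():
            rate = rates.get(amp.genome, 0.0)
            lam = rate * amp.length_kb / 10.0
            noise = float(_lognormal_factors(rng, config.measurement_cv, None))
            rows.append({
                "sample_id": sid,
                "group": group,
                "target": amp.name,
                "signal": copy_factors[amp.genome] * math.exp(-lam) * noise,
            })
    return pd.DataFrame(rows), truth


def poisson_zero_fraction_mc(
    lesions_per_10kb: float, length_kb: float, n_templates: int, seed: int
) -> float:
    """Monte-Carlo zero-class fraction: place Poisson lesions on templates, count clean ones.

    Independent cross-check of the closed form ``exp(-lambda)``: each template
    receives ``Poisson(lambda)`` lesions and only lesion-free templates amplify.
    """
    rng = np.random.default_rng(seed)
    lam = lesions_per_10kb * length_kb / 10.0
    lesions = rng.poisson(lam, size=n_templates)
    return float(np.mean(lesions == 0))


# ---------------------------------------------------------------------------
# Reference study scenarios
# ---------------------------------------------------------------------------

def study_qpcr_config(seed: int, copy_number_cv: float = 0.05,
                      measurement_cv: float = 0.05) -> QpcrSimConfig:
    """The blood-cohort damage scenario: 47 cases vs 15 controls with planted
    excesses of 0.81 (mitochondrial) and 0.53 (nuclear) lesions/10 kb and 5%
    multiplicative noise on copy number and measurement."""
    return QpcrSimConfig(
        n_cases=47, n_controls=15,
        lesions_per_10kb_cases={"mitochondrial": 0.81, "nuclear": 0.53},
        lesions_per_10kb_controls={"mitochondrial": 0.0, "nuclear": 0.0},
        copy_number_cv=copy_number_cv, measurement_cv=measurement_cv, seed=seed,
    )


def de_recovery_config(seed: int) -> ExpressionSimConfig:
    """The differential-expression recovery scenario: 50 of 1000 genes shifted
    by 5 noise standard deviations, 10 cases vs 10 controls."""
    return ExpressionSimConfig(
        n_cases=10, n_controls=10, n_genes=1000, n_de_genes=50,
        de_log2_shift=5.0, noise_sd=1.0, seed=seed,
    )


def pattern_recovery_config(seed: int, n_noise_genes: int = 250) -> ExpressionSimConfig:
    """The co-expression recovery scenario: three 50-gene patterns at
    within-correlation 0.9 over a 20v20 cohort.

    Each pattern's covariate carries an alternating-sign case/control mean
    shift of 2.7 (planted SNR ~1.9) on top of latents anticorrelated at
    -1/(k-1), which keeps same-sign cross-pattern correlation (~0.47) safely
    below typical clustering thresholds: with a single disease axis, three
    mutually orthogonal group-shifted patterns are impossible, so this is the
    closest realizable configuration to independent high-SNR patterns.
    """
    shifts = (2.7, -2.7, 2.7)
    specs = tuple(
        PatternSpec(50, f"cov{k}", loading=1.0, within_pattern_corr_target=0.9,
                    covariate_group_shift=shifts[k])
        for k in range(3)
    )
    return ExpressionSimConfig(
        n_cases=20, n_controls=20, n_genes=150 + n_noise_genes, n_de_genes=0,
        de_log2_shift=0.0, noise_sd=0.3, patterns=specs,
        anticorrelate_pattern_covariates=True, seed=seed,
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    n_sets: int,
    set_sizes: Sequence[int],
    planted: Mapping[str, int],
    universe: Sequence[str],
    seed: int,
) -> dict[str, list[str]]:
    """Generate a gene-set catalog with exact planted membership counts.

    Each gene in ``planted`` appears in exactly its requested number of sets
    (which sets is random); remaining slots are filled uniformly at random from
    the universe without replacement within a set.  Returns an ordered mapping
    of set name to member gene list.
    """
    if len(set_sizes) != n_sets:
        raise ConfigurationError(f"need {n_sets} set sizes, got {len(set_sizes)}")
    universe = list(universe)
    for size in set_sizes:
        if size > len(universe):
            raise ConfigurationError(f"set size {size} exceeds universe of {len(universe)}")
    for gene, count in planted.items():
        if count > n_sets:
            raise ConfigurationError(f"gene {gene!r} planted in {count} > {n_sets} sets")
        if gene not in set(universe):
            raise ConfigurationError(f"planted gene {gene!r} not in universe")

    rng = np.random.default_rng(seed)
    members: list[set[str]] = [set() for _ in range(n_sets)]
    # Plant the fixed-membership genes first so their counts are exact.
    for gene in sorted(planted):
        chosen = rng.choice(n_sets, size=planted[gene], replace=False)
        for j in chosen:
            members[j].add(gene)
    planted_set = set(planted)
    for j, size in enumerate(set_sizes):
        if len(members[j]) > size:
            raise ConfigurationError(
                f"set {j} has {len(members[j])} planted genes but size {size}"
            )
        pool = [g for g in universe if g not in members[j] and g not in planted_set]
        extra = rng.choice(len(pool), size=size - len(members[j]), replace=False)
        members[j].update(pool[i] for i in extra)
    return {f"set_{j+1:03d}": sorted(members[j]) for j in range(n_sets)}


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def _correlated_covariate(
    rng: np.random.Generator,
    anchor_z: np.ndarray,
    r2: float,
    mean: float,
    sd: float,
    sign: int,
) -> np.ndarray:
    """A covariate with squared Pearson correlation ``r2`` to the anchor in expectation."""
    n = anchor_z.size
    eps = rng.normal(0.0, 1.0, size=n) if r2 < 1.0 else np.zeros(n)
    z = sign * math.sqrt(r2) * anchor_z + math.sqrt(max(0.0, 1.0 - r2)) * eps
    return mean + sd * z


def simulate_clinical(
    n: int,
    ddct_modes: Sequence[tuple[float, float, float]] = ((0.0, 0.3, 0.22), (-3.5, 0.6, 0.78)),
    onset_r2: float = 0.305,
    seed: int = 0,
    icars_r2: float | None = None,
    gaa_r2: float | None = None,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a patient clinical table anchored on a bimodal frataxin ddCt.

    ``ddct_modes`` are two ``(mean, sd, weight)`` Gaussian mixture components —
    the defaults put ~22% of patients in a high-expression mode near 0 and the
    rest in a low-expression mode near -3.5 ddCt.  Age of onset is built to
    correlate positively with ddCt at squared correlation ``onset_r2`` in
    expectation (higher frataxin, later onset); ICARS and the long GAA repeat
    correlate negatively at ``icars_r2``/``gaa_r2`` (default: same strength).

    Returns the clinical table (sample_id, group, ddct, age, age_of_onset,
    age_of_diagnosis, icars, gaa_short, gaa_long) and the planted truth with
    the covariate vectors.
    """
    if len(ddct_modes) != 2:
        raise ConfigurationError("ddct_modes must have exactly two components")
    weights = [w for _, _, w in ddct_modes]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigurationError(f"mixture weights must sum to 1, got {sum(weights)}")
    for r2, name in ((onset_r2, "onset_r2"), (icars_r2, "icars_r2"), (gaa_r2, "gaa_r2")):
        if r2 is not None and not 0.0 <= r2 <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {r2}")
    icars_r2 = onset_r2 if icars_r2 is None else icars_r2
    gaa_r2 = onset_r2 if gaa_r2 is None else gaa_r2

    rng = np.random.default_rng(seed)
    comp = rng.choice(2, size=n, p=weights)
    means = np.array([ddct_modes[0][0], ddct_modes[1][0]])
    sds = np.array([ddct_modes[0][1], ddct_modes[1][1]])
    noise = rng.normal(0.0, 1.0, size=n) if np.any(sds > 0) else np.zeros(n)
    ddct = means[comp] + sds[comp] * noise

    sd_ddct = float(np.std(ddct))
    z = (ddct - ddct.mean()) / sd_ddct if sd_ddct > 0 else np.zeros(n)

    onset = _correlated_covariate(rng, z, onset_r2, mean=10.0, sd=4.0, sign=+1)
    icars = _correlated_covariate(rng, z, icars_r2, mean=45.0, sd=15.0, sign=-1)
    gaa_long = _correlated_covariate(rng, z, gaa_r2, mean=800.0, sd=200.0, sign=-1)
    gaa_short = _correlated_covariate(rng, z, gaa_r2, mean=600.0, sd=180.0, sign=-1)

    onset = np.clip(onset, 0.0, None)
    icars = np.clip(icars, 0.0, 100.0)
    gaa_long = np.clip(np.round(gaa_long), 66, None)
    gaa_short = np.clip(np.round(gaa_short), 66, None)
    diagnosis = onset + np.abs(rng.normal(1.5, 1.0, size=n))
    age = diagnosis + np.abs(rng.normal(3.0, 2.0, size=n))

    sample_ids = [f"pt_{i+1}" for i in range(n)]
    table = pd.DataFrame({
        "sample_id": sample_ids,
        "group": "case",
        "ddct": ddct,
        "age": age,
        "age_of_onset": onset,
        "age_of_diagnosis": diagnosis,
        "icars": icars,
        "gaa_short": gaa_short,
        "gaa_long": gaa_long,
    })
    truth = PlantedTruth(
        sample_ids=sample_ids,
        covariate_values={
            "ddct": ddct.tolist(),
            "age_of_onset": onset.tolist(),
            "icars": icars.tolist(),
            "gaa_long": gaa_long.tolist(),
            "gaa_short": gaa_short.tolist(),
        },
    )
    return table, truth
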