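"""Mitochondrial and nuclear DNA lesion quantification from long-amplicon QPCR.

Long-range QPCR measures polymerase-blocking DNA lesions: any oxidative lesion
(strand break, abasic site, blocking base damage) on a template halts the
polymerase, so only lesion-free templates amplify fully.  Under a random
(Poisson) distribution of lesions along the genome, the fraction of templates
with zero lesions on an amplicon is ``exp(-lambda)`` where ``lambda`` is the
mean number of lesions per amplicon.  The relative amplification of a sample
versus an undamaged control group therefore inverts to a lesion frequency

    lambda = -ln(A_sample / A_control)

which is rescaled by amplicon length to excess lesions per 10 kb.

The assay uses a large mitochondrial amplicon (8.9 kb), a large nuclear
amplicon (12.2 kb), and a short (~0.2 kb) mitochondrial amplicon that is too
small to carry a lesion at physiological damage levels and so reports
mitochondrial copy number; the long mitochondrial signal is divided by the
short one before any ratio is formed.  The nuclear amplicon is used
unnormalized: nuclear copy number is taken as constant across blood samples
(two copies per cell), so there is nothing for a short-fragment reference to
remove.

Group comparisons are non-parametric (the lesion distributions are skewed):
Mann-Whitney U between cases and controls, Spearman rank correlation between
the mitochondrial and nuclear lesion loads of the same samples, and a
dichotomization of samples into "high"/"low" damage at 0.85 lesions/10 kb.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration."""


Genome = Literal["mitochondrial", "nuclear"]
AmpliconRole = Literal["damage_target", "copy_number_reference"]


@dataclass(frozen=True)
class AmpliconSpec:
    """A QPCR amplicon: name, source genome, length, and its role in the assay."""

    name: str
    genome: Genome
    length_kb: float
    role: AmpliconRole = "damage_target"

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ConfigurationError(
                f"amplicon {self.name!r}: length_kb must be > 0, got {self.length_kb}"
            )
        if self.genome not in ("mitochondrial", "nuclear"):
            raise ConfigurationError(f"amplicon {self.name!r}: unknown genome {self.genome!r}")
        if self.role not in ("damage_target", "copy_number_reference"):
            raise ConfigurationError(f"amplicon {self.name!r}: unknown role {self.role!r}")


#: The assay's amplicon panel: 8.9 kb mitochondrial and 12.2 kb nuclear damage
#: targets, plus a ~200 bp mitochondrial copy-number reference.
DEFAULT_AMPLICONS: tuple[AmpliconSpec, ...] = (
    AmpliconSpec("mt_long", "mitochondrial", 8.9, "damage_target"),
    AmpliconSpec("nuc_long", "nuclear", 12.2, "damage_target"),
    AmpliconSpec("mt_short", "mitochondrial", 0.2, "copy_number_reference"),
)

#: Lesions/10 kb above which a sample is classified as "high damage".
DAMAGE_THRESHOLD_PER_10KB = 0.85


def validate_amplicons(amplicons: Sequence[AmpliconSpec]) -> dict[str, AmpliconSpec]:
    """Check the panel: unique names, at most one copy-number reference per genome."""
    by_name: dict[str, AmpliconSpec] = {}
    refs_per_genome: dict[str, int] = {}
    for amp in amplicons:
        if amp.name in by_name:
            raise ConfigurationError(f"duplicate amplicon name {amp.name!r}")
        by_name[amp.name] = amp
        if amp.role == "copy_number_reference":
            refs_per_genome[amp.genome] = refs_per_genome.get(amp.genome, 0) + 1
    for genome, n in refs_per_genome.items():
        if n > 1:
            raise ConfigurationError(f"{genome} genome has {n} copy-number references; at most 1")
    return by_name


# ---------------------------------------------------------------------------
# Elementary operations of the Poisson zero-class inversion
# ---------------------------------------------------------------------------

def normalize_mito(long_signal: float, short_signal: float, sample_id: str = "?") -> float:
    """Divide the long mitochondrial signal by the short-fragment signal.

    The short amplicon is effectively lesion-free, so its signal tracks
    mitochondrial copy number only; the quotient removes per-sample copy-number
    variation from the damage readout.
    """
    if long_signal <= 0 or short_signal <= 0:
        raise DataError(
            f"sample {sample_id!r}: non-positive amplification signal "
            f"(long={long_signal}, short={short_signal})"
        )
    return long_signal / short_signal


def control_reference(control_values: Sequence[float]) -> float:
    """Arithmetic mean of the control group's (normalized) amplification values."""
    vals = np.asarray(control_values, dtype=float)
    if vals.size == 0:
        raise DataError("control group is empty; cannot form an amplification reference")
    return float(vals.mean())


def relative_amplification(sample_value: float, control_ref: float, sample_id: str = "?") -> float:
    """Amplification of a sample relative to the control-group mean."""
    if sample_value <= 0:
        raise DataError(f"sample {sample_id!r}: non-positive amplification {sample_value}")
    if control_ref <= 0:
        raise DataError(f"non-positive control reference {control_ref}")
    return sample_value / control_ref


def lesion_frequency(ratio: float) -> float:
    """Invert the Poisson zero class: lambda = -ln(ratio) lesions per amplicon.

    Negative values (a sample amplifying better than the control mean) are
    legitimate sampling outcomes and are returned as-is; clamping them to zero
    would bias group means upward.
    """
    if ratio <= 0:
        raise DataError(f"relative amplification must be > 0, got {ratio}")
    return -math.log(ratio)


def per_10kb(lam: float, length_kb: float) -> float:
    """Rescale lesions/amplicon to lesions/10 kb."""
    if length_kb <= 0:
        raise ConfigurationError(f"amplicon length must be > 0 kb, got {length_kb}")
    return lam / length_kb * 10.0


def classify_damage(lesions_per_10kb: float, threshold: float = DAMAGE_THRESHOLD_PER_10KB) -> str:
    """Dichotomize a lesion load at the threshold; equality goes to "low"."""
    if not math.isfinite(lesions_per_10kb):
        raise DataError(f"non-finite lesion value {lesions_per_10kb}")
    return "high" if lesions_per_10kb > threshold else "low"


# ---------------------------------------------------------------------------
# Table-level estimation
# ---------------------------------------------------------------------------

@dataclass
class LesionResult:
    """Per-sample lesion estimate for one genome."""

    sample_id: str
    group: str
    genome: str
    relative_amplification: float
    lambda_per_amplicon: float
    lesions_per_10kb: float


def estimate_lesions(
    table: pd.DataFrame,
    amplicons: Sequence[AmpliconSpec] = DEFAULT_AMPLICONS,
) -> pd.DataFrame:
    """Estimate per-sample lesion frequencies for every genome with a damage target.

    ``table`` holds one row per (sample, amplicon) with columns
    ``sample_id, group, target, signal``; ``group`` is ``case`` or ``control``.
    For each genome: the damage-target signal is normalized by that genome's
    copy-number reference when one exists, each sample's normalized value is
    divided by the mean normalized value of the controls, and the ratio is
    inverted through the Poisson zero class and rescaled per 10 kb.

    Returns a DataFrame with one row per (sample, genome):
    ``sample_id, group, genome, relative_amplification, lambda_per_amplicon,
    lesions_per_10kb``.
    """
    required = {"sample_id", "group", "target", "signal"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"amplification table lacks columns: {sorted(missing)}")
    if table.duplicated(["sample_id", "target"]).any():
        dup = table[table.duplicated(["sample_id", "target"])].iloc[0]
        raise DataError(
            f"duplicate (sample, target) pair: ({dup['sample_id']!r}, {dup['target']!r})"
        )
    bad = table[table["signal"] <= 0]
    if len(bad):
        raise DataError(f"non-positive signal for sample {bad.iloc[0]['sample_id']!r}")
    unknown_groups = set(table["group"]) - {"case", "control"}
    if unknown_groups:
        raise DataError(f"unknown group labels: {sorted(unknown_groups)}")

    by_name = validate_amplicons(amplicons)
    unknown_targets = set(table["target"]) - set(by_name)
    if unknown_targets:
        raise DataError(f"table references unspecified amplicons: {sorted(unknown_targets)}")

    wide = table.pivot(index="sample_id", columns="target", values="signal")
    groups = table.drop_duplicates("sample_id").set_index("sample_id")["group"]
    groups = groups.loc[wide.index]

    results: list[LesionResult] = []
    for genome in ("mitochondrial", "nuclear"):
        targets = [a for a in by_name.values() if a.genome == genome and a.role == "damage_target"]
        if not targets:
            continue
        if len(targets) > 1:
            raise ConfigurationError(f"{genome} genome has multiple damage targets")
        target = targets[0]
        refs = [a for a in by_name.values()
                if a.genome == genome and a.role == "copy_number_reference"]
        ref = refs[0] if refs else None

        if target.name not in wide.columns:
            raise DataError(f"no signals for damage target {target.name!r}")
        sig = wide[target.name]
        if sig.isna().any():
            missing_samples = sig[sig.isna()].index.tolist()
            raise DataError(f"missing {target.name!r} signal for samples {missing_samples}")
        if ref is not None:
            if ref.name not in wide.columns:
                raise DataError(f"no signals for copy-number reference {ref.name!r}")
            normalized = np.array([
                normalize_mito(long_s, short_s, sample_id=sid)
                for sid, long_s, short_s in zip(wide.index, sig, wide[ref.name])
            ])
        else:
            normalized = sig.to_numpy(dtype=float)

        ctrl_mask = (groups == "control").to_numpy()
        ref_value = control_reference(normalized[ctrl_mask])
        for sid, grp, val in zip(wide.index, groups, normalized):
            ratio = relative_amplification(val, ref_value, sample_id=sid)
            lam = lesion_frequency(ratio)
            results.append(LesionResult(
                sample_id=sid,
                group=grp,
                genome=genome,
                relative_amplification=ratio,
                lambda_per_amplicon=lam,
                lesions_per_10kb=per_10kb(lam, target.length_kb),
            ))

    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def compare_damage(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U comparison of two lesion-load groups; returns (U, two-sided p).

    The p-value is exact (full enumeration of labelings) when the combined
    sample size is at most 12 and the data are tie-free; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty for the Mann-Whitney test")
    combined = np.concatenate([x, y])
    tie_free = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided Spearman p by full enumeration of rank permutations (n <= 7)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    denom_x = np.sqrt(((rx - rx.mean()) ** 2).sum())
    count = 0
    total = 0
    ryc = ry - ry.mean()
    denom_y = np.sqrt((ryc ** 2).sum())
    rxc = rx - rx.mean()
    for perm in itertools.permutations(range(n)):
        rho = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_damage(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation of paired lesion loads; returns (rho, p).

    Ties receive average ranks.  The p-value is exact by enumeration for
    n <= 7 and uses the t-approximation otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise DataError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise DataError("need at least 3 paired values for a rank correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DataError("rank correlation undefined for a constant input")
    rho, p_t = stats.spearmanr(xa, ya)
    if xa.size <= 7:
        return float(rho), _spearman_exact_p(xa, ya, float(rho))
    return float(rho), float(p_t)


def damage_group_stats(lesions: pd.DataFrame) -> dict:
    """Summary statistics of an `estimate_lesions` result.

    Per genome: case-group mean excess lesions/10 kb with its SEM and the
    Mann-Whitney case-vs-control comparison.  Across genomes: the Spearman
    correlation of mitochondrial vs nuclear lesion loads over all samples.
    """
    out: dict = {"per_genome": {}}
    for genome, sub in lesions.groupby("genome"):
        cases = sub.loc[sub["group"] == "case", "lesions_per_10kb"].to_numpy()
        controls = sub.loc[sub["group"] == "control", "lesions_per_10kb"].to_numpy()
        u, p = compare_damage(cases, controls)
        out["per_genome"][genome] = {
            "mean_excess_per_10kb": float(cases.mean()),
            "sem": float(cases.std(ddof=1) / math.sqrt(len(cases))) if len(cases) > 1 else float("nan"),
            "U": u,
            "p_mannwhitney": p,
            "n_cases": int(len(cases)),
            "n_controls": int(len(controls)),
        }
    genomes = sorted(lesions["genome"].unique())
    if len(genomes) == 2:
        wide = lesions.pivot(index="sample_id", columns="genome", values="lesions_per_10kb")
        wide = wide.dropna()
        rho, p = correlate_damage(wide[genomes[0]], wide[genomes[1]])
        out["cross_genome"] = {
            "genomes": genomes,
            "rho_spearman": rho,
            "p_spearman": p,
            "n": int(len(wide)),
        }
    return out
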