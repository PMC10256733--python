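"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator follows the linear instrumental-variable model underlying
two-sample MR.  For instrument j:

    gamma_j      true exposure effect, |N(0, gamma_sd)| (effects are coded
                 on the exposure-increasing allele, so directional
                 pleiotropy has a well-defined sign),
    alpha_j      direct (pleiotropic) effect on the outcome,
    Gamma_j      = beta_true * gamma_j + alpha_j,
    gamma_hat_j  ~ N(gamma_j, se_gamma)   (exposure study),
    Gamma_hat_j  ~ N(Gamma_j, se_Gamma)   (outcome study, independent noise
                 draws: the two samples do not overlap).

Pleiotropy modes: "none" (alpha = 0), "balanced" (alpha ~ N(0, alpha_sd)),
"directional" (alpha ~ N(alpha_mean, alpha_sd), optionally touching only a
fraction of instruments), and "inside_violating"
(alpha = kappa * gamma + noise, correlating instrument strength with the
direct effect).  Injected outliers shift Gamma_hat by
``outlier_shift * se_Gamma``.

Unless weak-instrument mode is on, true gamma_j are resampled until
|gamma_j| / se_gamma exceeds the genome-wide-significance z, so the
emitted exposure rows pass the p < 5e-8 instrument filter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .summary_data import HarmonizedSet, COMPLEMENT

#: z threshold matching two-sided p = 5e-8
GENOME_WIDE_Z = float(stats.norm.isf(2.5e-8))

_MIN_P = 1e-320

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("G", "A"), ("G", "T"),
    ("C", "A"), ("C", "T"), ("T", "G"), ("T", "C"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def case_control_se(n_cases: int, n_controls: int, eaf: float) -> float:
    """Log-odds SE scale for a case-control GWAS,
    sqrt((1/n_cases + 1/n_controls) / (2 eaf (1 - eaf))).

    With 132 cases / 784 controls and eaf 0.3 this gives ~0.15, the scale
    of a small outcome study.
    """
    return float(np.sqrt((1.0 / n_cases + 1.0 / n_controls) / (2.0 * eaf * (1.0 - eaf))))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters for one simulated exposure/outcome pair."""

    beta_true: float = 0.0
    J: int = 50
    gamma_sd: float = 0.1
    se_gamma: float = 0.005
    se_Gamma: float = 0.05
    pleiotropy_mode: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    kappa: float = 0.3
    n_outliers: int = 0
    outlier_shift: float = 0.0
    palindromic_fraction: float = 0.0
    weak_instruments: bool = False
    scramble_outcome_alleles: bool = True
    n_exposure: int = 300_000
    n_outcome: int = 916
    seed: int = 20230609

    def __post_init__(self):
        if self.J < 2:
            raise ConfigurationError("J must be >= 2")
        if self.se_gamma < 0 or self.se_Gamma < 0 or self.gamma_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigurationError("pleiotropy_fraction must be in [0, 1]")
        if self.outlier_shift < 0 or self.n_outliers < 0:
            raise ConfigurationError("outlier settings must be non-negative")
        if self.n_outliers > self.J:
            raise ConfigurationError("more outliers than instruments")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must be in [0, 1]")
        if not self.weak_instruments and self.se_gamma > 0:
            # significance guarantee must be reachable by rejection sampling
            if GENOME_WIDE_Z * self.se_gamma > 4.0 * self.gamma_sd:
                raise ConfigurationError(
                    "gamma_sd too small relative to se_gamma to guarantee "
                    "genome-wide significance; enable weak_instruments or raise gamma_sd"
                )


@dataclass(frozen=True)
class SimulatedEffects:
    """True and observed effects for one replicate (arrays of length J)."""

    gamma: np.ndarray
    alpha: np.ndarray
    Gamma: np.ndarray
    gamma_hat: np.ndarray
    Gamma_hat: np.ndarray
    se_gamma: np.ndarray
    se_Gamma: np.ndarray
    outlier_idx: np.ndarray


def simulate_effects(truth: SimulationTruth, rng: np.random.Generator | None = None) -> SimulatedEffects:
    """Draw one replicate of true and observed effects (no table I/O).

    Accepts zero SEs to support exact noiseless-limit checks; the table
    writer (:func:`simulate_pair`) requires strictly positive SEs because
    the record format does.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    j = truth.J

    gamma = np.abs(rng.normal(0.0, truth.gamma_sd, j))
    if not truth.weak_instruments and truth.se_gamma > 0:
        threshold = GENOME_WIDE_Z * truth.se_gamma
        for _ in range(1000):
            weak = gamma <= threshold
            if not weak.any():
                break
            gamma[weak] = np.abs(rng.normal(0.0, truth.gamma_sd, int(weak.sum())))
        else:  # pragma: no cover - guarded by __post_init__
            raise ConfigurationError("could not satisfy the significance guarantee")

    alpha = np.zeros(j)
    if truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.alpha_sd, j)
    elif truth.pleiotropy_mode == "directional":
        alpha = rng.normal(truth.alpha_mean, truth.alpha_sd, j)
    elif truth.pleiotropy_mode == "inside_violating":
        alpha = truth.kappa * gamma + rng.normal(0.0, truth.alpha_sd, j)
    if truth.pleiotropy_fraction < 1.0 and truth.pleiotropy_mode != "none":
        n_pleio = int(round(truth.pleiotropy_fraction * j))
        valid = rng.choice(j, size=j - n_pleio, replace=False)
        alpha[valid] = 0.0

    Gamma = truth.beta_true * gamma + alpha
    gamma_hat = gamma + rng.normal(0.0, 1.0, j) * truth.se_gamma
    Gamma_hat = Gamma + rng.normal(0.0, 1.0, j) * truth.se_Gamma

    outlier_idx = np.array([], dtype=int)
    if truth.n_outliers:
        outlier_idx = np.sort(rng.choice(j, size=truth.n_outliers, replace=False))
        Gamma_hat = Gamma_hat.copy()
        Gamma_hat[outlier_idx] += truth.outlier_shift * truth.se_Gamma

    return SimulatedEffects(
        gamma=gamma,
        alpha=alpha,
        Gamma=Gamma,
        gamma_hat=gamma_hat,
        Gamma_hat=Gamma_hat,
        se_gamma=np.full(j, float(truth.se_gamma)),
        se_Gamma=np.full(j, float(truth.se_Gamma)),
        outlier_idx=outlier_idx,
    )


def simulate_harmonized(
    truth: SimulationTruth, rng: np.random.Generator | None = None
) -> tuple[HarmonizedSet, SimulatedEffects]:
    """One replicate already in harmonized form (fast path for
    simulation studies that bypass table round-trips)."""
    effects = simulate_effects(truth, rng)
    hset = HarmonizedSet.from_arrays(
        effects.gamma_hat,
        effects.se_gamma,
        effects.Gamma_hat,
        effects.se_Gamma,
        exposure_name="simulated_exposure",
        outcome_name="simulated_outcome",
    )
    return hset, effects


def _variant_metadata(j: int, palindromic_fraction: float, rng: np.random.Generator):
    ids = [f"rs{1000000 + k}" for k in range(j)]
    chroms = [str(k % 22 + 1) for k in range(j)]
    positions = [1_000_000 + 50_000_000 * (k // 22) for k in range(j)]
    n_palindromic = int(round(palindromic_fraction * j))
    palindromic = np.zeros(j, dtype=bool)
    if n_palindromic:
        palindromic[rng.choice(j, size=n_palindromic, replace=False)] = True
    alleles = []
    for k in range(j):
        pool = _PALINDROMIC_PAIRS if palindromic[k] else _NON_PALINDROMIC_PAIRS
        alleles.append(pool[rng.integers(len(pool))])
    return ids, chroms, positions, alleles, palindromic


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), _MIN_P)


def simulate_pair(
    truth: SimulationTruth, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit an (exposure table, outcome table, truth manifest) triple.

    Tables use the standard summary-statistics dialect (variant_id,
    chromosome, position, effect_allele, other_allele, eaf, beta, se,
    pvalue, n).  Instruments are placed far apart on alternating
    chromosomes, so they are independent by construction.  When
    ``scramble_outcome_alleles`` is set, the outcome rows are re-expressed
    with randomly swapped or strand-complemented alleles (the semantics
    are unchanged; it exercises harmonization downstream).
    """
    if truth.se_gamma <= 0 or truth.se_Gamma <= 0:
        raise ConfigurationError("simulate_pair requires strictly positive SEs")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    effects = simulate_effects(truth, rng)
    j = truth.J
    ids, chroms, positions, alleles, _ = _variant_metadata(j, truth.palindromic_fraction, rng)

    eaf_exp = rng.uniform(0.05, 0.95, j)
    eaf_out = np.clip(eaf_exp + rng.normal(0.0, 0.01, j), 0.001, 0.999)

    exposure = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position": positions,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf_exp,
            "beta": effects.gamma_hat,
            "se": effects.se_gamma,
            "pvalue": _two_sided_p(effects.gamma_hat / effects.se_gamma),
            "n": truth.n_exposure,
        }
    )

    out_effect, out_other, out_beta, out_eaf = [], [], [], []
    for k in range(j):
        ea, oa = alleles[k]
        beta_k, eaf_k = float(effects.Gamma_hat[k]), float(eaf_out[k])
        if truth.scramble_outcome_alleles:
            mode = rng.integers(4)  # 0 keep, 1 swap, 2 complement, 3 complement+swap
            if mode in (1, 3):
                ea, oa = oa, ea
                beta_k, eaf_k = -beta_k, 1.0 - eaf_k
            if mode in (2, 3):
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        out_effect.append(ea)
        out_other.append(oa)
        out_beta.append(beta_k)
        out_eaf.append(eaf_k)

    outcome = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position": positions,
            "effect_allele": out_effect,
            "other_allele": out_other,
            "eaf": out_eaf,
            "beta": out_beta,
            "se": effects.se_Gamma,
            "pvalue": _two_sided_p(np.asarray(out_beta) / effects.se_Gamma),
            "n": truth.n_outcome,
        }
    )

    manifest = {
        "truth": dataclasses.asdict(truth),
        "outlier_variants": [ids[k] for k in effects.outlier_idx],
        "genome_wide_z": GENOME_WIDE_Z,
    }
    return exposure, outcome, manifest


def write_pair(truth: SimulationTruth, out_dir) -> dict:
    """Write exposure.tsv, outcome.tsv and truth.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposure, outcome, manifest = simulate_pair(truth)
    exposure.to_csv(out / "exposure.tsv", sep="\t", index=False)
    outcome.to_csv(out / "outcome.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def scenario_suite() -> dict[str, SimulationTruth]:
    """Named presets covering the study's qualitative regimes.

    Instrument counts for the flagship scenarios (41 and 23) match the
    two headline exposures; noise scales represent a well-powered
    exposure GWAS paired with a small outcome study (see docs/methods.md).
    """
    return {
        "null": SimulationTruth(beta_true=0.0, J=50),
        "causal_protective": SimulationTruth(beta_true=-0.5, J=41),
        "directional_pleiotropy": SimulationTruth(
            beta_true=-0.5,
            J=41,
            pleiotropy_mode="directional",
            alpha_mean=0.05,
            alpha_sd=0.01,
        ),
        "heterogeneous": SimulationTruth(
            beta_true=-0.5,
            J=23,
            pleiotropy_mode="balanced",
            alpha_sd=0.1,
        ),
        "single_outlier": SimulationTruth(
            beta_true=0.0,
            J=20,
            n_outliers=1,
            outlier_shift=10.0,
        ),
        "weak_instruments": SimulationTruth(
            beta_true=-0.5,
            J=50,
            gamma_sd=0.03,
            se_gamma=0.01,
            weak_instruments=True,
        ),
    }
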