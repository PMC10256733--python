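"""Causal-effect estimators: Wald ratios, IVW, MR-Egger, weighted median.

Notation follows the two-sample MR literature: instrument j has exposure
association gamma_j (SE sigma_gamma_j) and outcome association Gamma_j
(SE sigma_Gamma_j).  The per-instrument Wald ratio is
beta_j = Gamma_j / gamma_j with first-order SE s_j = sigma_Gamma_j / |gamma_j|,
and the IVW weight is w_j = 1 / s_j^2 = gamma_j^2 / sigma_Gamma_j^2.

Conventions (documented, since the source studies rarely state them):

* IVW p-values come from the standard normal; MR-Egger p-values from a
  t distribution with J - 2 degrees of freedom.
* The multiplicative random-effects IVW inflates the fixed-effect SE by
  max(1, sqrt(Q / (J - 1))) — never deflated under underdispersion.
* Odds-ratio confidence intervals are exp(beta +/- 1.96 * se).
* The weighted-median SE is a parametric bootstrap (default 1000 draws,
  fixed seed) so runs are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientInstrumentsError, InvalidInstrumentError, ValidationError
from .summary_data import HarmonizedSet

Z95 = 1.96
_MIN_P = 1e-320

DEFAULT_N_BOOT = 1000
DEFAULT_BOOTSTRAP_SEED = 20230609


def _two_sided_normal_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), _MIN_P))


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)


@dataclass(frozen=True)
class RatioSet:
    """Per-instrument Wald ratios plus the source effects they came from
    (kept so bootstrap resampling can perturb gamma and Gamma directly)."""

    variant_ids: tuple[str, ...]
    gamma: np.ndarray
    sigma_gamma: np.ndarray
    Gamma: np.ndarray
    sigma_Gamma: np.ndarray

    def __len__(self) -> int:
        return self.gamma.size

    @property
    def beta(self) -> np.ndarray:
        return self.Gamma / self.gamma

    @property
    def se(self) -> np.ndarray:
        return self.sigma_Gamma / np.abs(self.gamma)

    @property
    def weight(self) -> np.ndarray:
        return self.gamma**2 / self.sigma_Gamma**2

    @classmethod
    def from_instruments(cls, instruments: HarmonizedSet) -> "RatioSet":
        g, sg, G, sG = instruments.arrays()
        return cls(tuple(instruments.variant_ids), g, sg, G, sG)

    @classmethod
    def from_ratios(
        cls, beta, se, variant_ids: Sequence[str] | None = None
    ) -> "RatioSet":
        """Build directly from ratio estimates and their SEs.

        Encoded as gamma = 1 exactly (sigma_gamma = 0), so bootstrap
        perturbation reduces to beta* ~ N(beta_j, s_j).
        """
        beta = np.asarray(beta, dtype=float)
        se = np.asarray(se, dtype=float)
        if variant_ids is None:
            variant_ids = [f"rs{1000000 + j}" for j in range(beta.size)]
        ones = np.ones_like(beta)
        return cls(tuple(str(v) for v in variant_ids), ones, 0.0 * ones, beta, se)


def wald_ratios(instruments: HarmonizedSet) -> RatioSet:
    """Per-SNP Wald ratios beta_j = Gamma_j / gamma_j.

    Zero exposure effects should have been removed by the significance
    filter upstream; they are rejected here with the offending variant
    named.
    """
    ratios = RatioSet.from_instruments(instruments)
    zero = np.flatnonzero(ratios.gamma == 0.0)
    if zero.size:
        names = ", ".join(ratios.variant_ids[j] for j in zero)
        raise InvalidInstrumentError(f"zero exposure effect (gamma = 0) for: {names}")
    return ratios


def _ivw_core(beta: np.ndarray, weight: np.ndarray) -> tuple[float, float, float]:
    """(weighted-mean estimate, sum of weights, Cochran's Q)."""
    sw = float(weight.sum())
    bhat = float((weight * beta).sum() / sw)
    q = float((weight * (beta - bhat) ** 2).sum())
    return bhat, sw, q


def ivw(ratios: RatioSet, mode: str = "fixed") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    ``mode="fixed"`` uses SE = (sum w_j)^(-1/2); ``mode="mre"``
    (multiplicative random effects) inflates it by
    max(1, sqrt(Q / (J - 1))).
    """
    if mode not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    j = len(ratios)
    if j < 2:
        raise InsufficientInstrumentsError(
            "IVW requires >= 2 instruments; report the single Wald ratio instead"
        )
    bhat, sw, q = _ivw_core(ratios.beta, ratios.weight)
    se = sw**-0.5
    if mode == "mre":
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return MrEstimate(
        method="IVW_fixed" if mode == "fixed" else "IVW_mre",
        beta=bhat,
        se=se,
        pvalue=_two_sided_normal_p(bhat / se),
        n_snp=j,
    )


def wald_ratio_estimate(ratios: RatioSet) -> MrEstimate:
    """Single-instrument fallback: the lone Wald ratio, normal-theory p."""
    if len(ratios) != 1:
        raise InsufficientInstrumentsError("wald_ratio_estimate expects exactly 1 instrument")
    b = float(ratios.beta[0])
    s = float(ratios.se[0])
    return MrEstimate("WaldRatio", b, s, _two_sided_normal_p(b / s), 1)


@dataclass(frozen=True)
class EggerFit:
    slope: MrEstimate
    intercept: MrEstimate
    rss: float
    dof: int


def egger(instruments: HarmonizedSet) -> EggerFit:
    """MR-Egger: weighted regression of Gamma on gamma with an intercept.

    Instruments are first oriented so gamma_j >= 0 (negating gamma and
    Gamma together, which leaves every Wald ratio unchanged).  Weights are
    1 / sigma_Gamma^2; coefficient covariance uses a residual-variance
    inflation factor max(1, RSS / (J - 2)) and p-values come from
    t(J - 2).  The intercept estimates the average directional
    pleiotropy; the slope is the pleiotropy-adjusted causal estimate.
    """
    j = len(instruments)
    if j < 3:
        raise InsufficientInstrumentsError("Egger requires >=3 instruments")
    g, _, G, sG = instruments.arrays()
    flip = g < 0
    g = np.where(flip, -g, g)
    G = np.where(flip, -G, G)
    w = 1.0 / sG**2

    design = sm.add_constant(g)
    fit = sm.WLS(G, design, weights=w).fit()
    intercept_hat, slope_hat = (float(v) for v in fit.params)

    resid = G - design @ fit.params
    rss = float((w * resid**2).sum())
    dof = j - 2
    phi = max(1.0, rss / dof)
    xtwx = design.T @ (design * w[:, None])
    cov = phi * np.linalg.inv(xtwx)
    se_intercept, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    def t_p(b: float, s: float) -> float:
        return float(max(2.0 * stats.t.sf(abs(b / s), dof), _MIN_P))

    return EggerFit(
        slope=MrEstimate("Egger_slope", slope_hat, se_slope, t_p(slope_hat, se_slope), j),
        intercept=MrEstimate(
            "Egger_intercept", intercept_hat, se_intercept, t_p(intercept_hat, se_intercept), j
        ),
        rss=rss,
        dof=dof,
    )


def weighted_median_point(beta: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median by linear interpolation of standardized cumulative
    weights p_k = (sum_{i<=k} w_i - w_k / 2) / sum w_i at probability 0.5."""
    order = np.argsort(beta, kind="stable")
    b = np.asarray(beta, dtype=float)[order]
    w = np.asarray(weight, dtype=float)[order]
    cw = np.cumsum(w)
    p = (cw - 0.5 * w) / cw[-1]
    return float(np.interp(0.5, p, b))


def weighted_median(
    ratios: RatioSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> MrEstimate:
    """Weighted-median causal estimate, consistent when instruments
    carrying at least half of the weight are valid.

    The SE is a parametric bootstrap: resample gamma* ~ N(gamma, sigma_gamma)
    and Gamma* ~ N(Gamma, sigma_Gamma), recompute the weighted median
    ``n_boot`` times, and take the standard deviation of the replicates.
    """
    j = len(ratios)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires >=3 instruments")
    if not np.isfinite(ratios.beta).all():
        raise ValidationError("non-finite Wald ratios passed to weighted_median")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is below 100; bootstrap SE will be unstable", stacklevel=2
        )

    estimate = weighted_median_point(ratios.beta, ratios.weight)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(ratios.gamma, ratios.sigma_gamma, size=(n_boot, j))
    G_star = rng.normal(ratios.Gamma, ratios.sigma_Gamma, size=(n_boot, j))
    with np.errstate(divide="ignore", invalid="ignore"):
        b_star = G_star / g_star
        w_star = g_star**2 / ratios.sigma_Gamma**2
    bad = ~np.isfinite(b_star)
    b_star[bad] = 0.0
    w_star[bad] = 0.0

    replicates = np.empty(n_boot)
    for i in range(n_boot):
        replicates[i] = weighted_median_point(b_star[i], w_star[i])
    se = float(max(replicates.std(ddof=1), 1e-300))
    return MrEstimate("WeightedMedian", estimate, se, _two_sided_normal_p(estimate / se), j)
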