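"""Heterogeneity, pleiotropy, outlier, and sensitivity diagnostics.

* Cochran's Q over the per-instrument Wald ratios (chi-square, J - 1 df).
* The MR-Egger intercept test (computed in :mod:`mrdiet.estimators`).
* MR-PRESSO: a parametric-simulation residual-sum-of-squares global test
  with per-SNP outlier flags.
* Leave-one-out IVW estimates for influence analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import (
    Z95,
    EggerFit,
    MrEstimate,
    RatioSet,
    _ivw_core,
    egger,
    ivw,
    wald_ratios,
)
from .summary_data import HarmonizedSet

logger = logging.getLogger(__name__)


def cochran_q(ratios: RatioSet, beta_ivw: float | None = None) -> tuple[float, float]:
    """Cochran's Q = sum_j w_j (beta_j - beta_IVW)^2 and its upper-tail
    chi-square p-value on J - 1 degrees of freedom.

    ``beta_ivw`` defaults to the fixed-effect IVW estimate of ``ratios``.
    """
    j = len(ratios)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >=2 instruments")
    if beta_ivw is None:
        beta_ivw, _, _ = _ivw_core(ratios.beta, ratios.weight)
    q = float((ratios.weight * (ratios.beta - beta_ivw) ** 2).sum())
    return q, float(stats.chi2.sf(q, j - 1))


@dataclass(frozen=True)
class PressoConfig:
    n_sim: int = 1000
    seed: int = 20230609
    outlier_alpha: float = 0.05

    def __post_init__(self):
        if self.n_sim < 100:
            raise ConfigurationError("MR-PRESSO needs n_sim >= 100")
        if not (0.0 < self.outlier_alpha < 1.0):
            raise ConfigurationError("outlier_alpha must be in (0, 1)")


@dataclass(frozen=True)
class PressoResult:
    global_p: float
    outlier_ids: tuple[str, ...]
    per_snp_p: np.ndarray
    corrected_p: np.ndarray
    rss_obs: float
    n_sim: int


def _loo_ivw_terms(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, computed from totals."""
    w = g**2 / sG**2
    wb = g * G / sG**2  # w_j * beta_j without forming the ratio
    return (wb.sum() - wb) / (w.sum() - w)


def mr_presso(instruments: HarmonizedSet, config: PressoConfig | None = None) -> PressoResult:
    """MR-PRESSO residual-sum-of-squares outlier test.

    Observed RSS sums, over instruments j, the leave-one-out residual
    (Gamma_j - beta_(-j) * gamma_j)^2 / sigma_Gamma_j^2.  The null
    distribution is built by parametric simulation: draw
    Gamma* ~ N(beta_(-j) gamma_j, sigma_Gamma_j) and
    gamma* ~ N(gamma_j, sigma_gamma_j) and recompute the RSS.  The global
    p uses the add-one correction (1 + #{RSS* >= RSS_obs}) / (n_sim + 1);
    per-SNP outlier p-values compare each instrument's observed
    contribution with its simulated contributions and are
    Bonferroni-corrected by J.
    """
    cfg = config or PressoConfig()
    j = len(instruments)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >=4 instruments")
    g, sg, G, sG = instruments.arrays()

    beta_loo = _loo_ivw_terms(g, G, sG)
    d_obs = (G - beta_loo * g) ** 2 / sG**2
    rss_obs = float(d_obs.sum())

    rng = np.random.default_rng(cfg.seed)
    G_star = rng.normal(beta_loo * g, sG, size=(cfg.n_sim, j))
    g_star = rng.normal(g, sg, size=(cfg.n_sim, j))

    w_star = g_star**2 / sG**2
    wb_star = g_star * G_star / sG**2
    sw = w_star.sum(axis=1, keepdims=True)
    swb = wb_star.sum(axis=1, keepdims=True)
    beta_loo_star = (swb - wb_star) / (sw - w_star)
    d_star = (G_star - beta_loo_star * g_star) ** 2 / sG**2
    rss_star = d_star.sum(axis=1)

    global_p = float((1 + (rss_star >= rss_obs).sum()) / (cfg.n_sim + 1))
    per_snp_p = (1 + (d_star >= d_obs).sum(axis=0)) / (cfg.n_sim + 1)
    corrected = np.minimum(1.0, per_snp_p * j)
    ids = np.array(instruments.variant_ids)
    outliers = tuple(str(v) for v in ids[corrected < cfg.outlier_alpha])
    return PressoResult(
        global_p=global_p,
        outlier_ids=outliers,
        per_snp_p=per_snp_p,
        corrected_p=corrected,
        rss_obs=rss_obs,
        n_sim=cfg.n_sim,
    )


@dataclass(frozen=True)
class LooResult:
    """Per-excluded-variant IVW estimates plus a sign-stability flag."""

    table: pd.DataFrame
    no_single_driver: bool
    full: MrEstimate


def leave_one_out(instruments: HarmonizedSet) -> LooResult:
    """Fixed-effect IVW re-estimated J times, each excluding one variant.

    The "no single instrument drives the result" flag is set when every
    leave-one-out estimate keeps the sign of the full estimate and their
    confidence intervals mutually overlap.
    """
    ratios = wald_ratios(instruments)
    j = len(ratios)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >=3 instruments")
    w = ratios.weight
    b = ratios.beta
    sw = w.sum()
    swb = (w * b).sum()
    beta_loo = (swb - w * b) / (sw - w)
    se_loo = (sw - w) ** -0.5
    table = pd.DataFrame(
        {
            "excluded_variant": list(ratios.variant_ids),
            "beta": beta_loo,
            "se": se_loo,
            "ci_low": beta_loo - Z95 * se_loo,
            "ci_high": beta_loo + Z95 * se_loo,
        }
    )
    full = ivw(ratios, mode="fixed")
    same_sign = bool(np.all(np.sign(beta_loo) == np.sign(full.beta)))
    overlap = bool(table["ci_low"].max() <= table["ci_high"].min())
    return LooResult(table=table, no_single_driver=same_sign and overlap, full=full)


@dataclass
class DiagnosticsBundle:
    """Everything the decision rules and the report need in one place."""

    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: tuple[str, ...] = ()
    loo: LooResult | None = None


def compute_diagnostics(
    instruments: HarmonizedSet,
    presso_config: PressoConfig | None = None,
    egger_fit: EggerFit | None = None,
) -> DiagnosticsBundle:
    """Run every diagnostic the instrument count allows.

    Q needs >= 2 instruments, the Egger intercept >= 3, MR-PRESSO >= 4;
    anything below its threshold stays ``None`` in the bundle.
    """
    j = len(instruments)
    bundle = DiagnosticsBundle()
    if j >= 2:
        ratios = wald_ratios(instruments)
        bundle.q, bundle.q_p = cochran_q(ratios)
        bundle.q_df = j - 1
    if j >= 3:
        fit = egger_fit or egger(instruments)
        bundle.egger_intercept = fit.intercept.beta
        bundle.egger_intercept_p = fit.intercept.pvalue
        bundle.loo = leave_one_out(instruments)
    if j >= 4:
        presso = mr_presso(instruments, presso_config)
        bundle.presso_global_p = presso.global_p
        bundle.presso_outliers = presso.outlier_ids
    return bundle
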