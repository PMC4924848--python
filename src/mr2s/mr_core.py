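"""Causal estimators for two-sample summary-data MR.

Given k harmonized instruments with exposure effects gamma_j (SE
sigma_gamma_j) and outcome effects Gamma_j (SE sigma_Gamma_j), the per-SNP
causal estimate is the Wald ratio beta_j = Gamma_j / gamma_j with
first-order (delta-method) SE sigma_Gamma_j / |gamma_j| — exposure-side
uncertainty is ignored (the NOME approximation standard for strong,
genome-wide-significant instruments).

Three pooled estimators are provided:

* fixed-effects inverse-variance weighting (IVW), the primary estimate,
  with Cochran-Q / I-squared heterogeneity;
* MR-Egger regression — weighted least squares of Gamma on gamma *with a
  free intercept*; a nonzero intercept is evidence of directional
  pleiotropy and the slope is a pleiotropy-adjusted effect (consistent
  under the InSIDE condition that pleiotropic effects are independent of
  instrument strength);
* the weighted median of the Wald ratios, consistent whenever more than
  half the total inverse-variance weight comes from valid instruments,
  with a parametric-bootstrap SE.

All SEs are treated as known (no residual-variance rescaling), so CIs and
p-values are normal-theory throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

from mr2s.errors import ConfigError, DomainError
from mr2s.harmonize import Z975, HarmonizedInstrument

#: Default parametric-bootstrap settings for the weighted-median SE.
DEFAULT_N_BOOT = 5000
DEFAULT_SEED = 42


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio: causal effect per unit exposure, in outcome units."""

    snp_id: str
    ratio: float
    se_ratio: float

    def __post_init__(self) -> None:
        if self.se_ratio <= 0 or not math.isfinite(self.se_ratio):
            raise DomainError(f"{self.snp_id}: ratio SE must be positive and finite")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass
class HeterogeneityBlock:
    """Cochran's Q and the I-squared statistic with a test-based CI."""

    Q: float
    df: int
    i2: float
    i2_ci_low: float
    i2_ci_high: float


@dataclass
class MRResult:
    """A pooled causal estimate on the log scale, with normal-theory CI."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    het: Optional[HeterogeneityBlock] = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z975 * self.se

    @property
    def or_(self) -> float:
        """Point estimate on the odds-ratio scale (binary outcomes)."""
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self, or_scale: bool = True) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
        }
        if or_scale:
            d.update(or_=self.or_, or_ci_low=self.or_ci_low, or_ci_high=self.or_ci_high)
        if self.het is not None:
            d["heterogeneity"] = {
                "Q": self.het.Q,
                "df": self.het.df,
                "i2": self.het.i2,
                "i2_ci_low": self.het.i2_ci_low,
                "i2_ci_high": self.het.i2_ci_high,
            }
        return d


def p_two_sided(z: float) -> float:
    """Two-sided normal p-value, floored at the smallest positive normal
    double so downstream logs never see an exact zero."""
    if not math.isfinite(z):
        raise DomainError(f"non-finite z-score {z}")
    p = 2.0 * stats.norm.sf(abs(z))
    return max(float(p), float(np.finfo(float).tiny))


def wald_ratio(inst: HarmonizedInstrument) -> RatioEstimate:
    """Per-SNP causal estimate Gamma/gamma with delta-method SE.

    The SE is first-order, ``se_Gamma / |gamma|``: exposure-side noise is
    neglected, which is accurate when instruments are strong (|gamma| many
    SEs from zero, as genome-wide-significant hits are).
    """
    if inst.gamma == 0:
        raise DomainError(f"{inst.snp_id}: zero exposure effect, Wald ratio undefined")
    return RatioEstimate(
        snp_id=inst.snp_id,
        ratio=inst.Gamma / inst.gamma,
        se_ratio=inst.se_Gamma / abs(inst.gamma),
    )


def _as_ratios(items: Sequence[Union[HarmonizedInstrument, RatioEstimate]]) -> list[RatioEstimate]:
    return [r if isinstance(r, RatioEstimate) else wald_ratio(r) for r in items]


def ivw_fixed(
    ratios: Sequence[Union[HarmonizedInstrument, RatioEstimate]],
) -> MRResult:
    """Fixed-effects inverse-variance-weighted pooling of Wald ratios.

    beta = sum(w_j b_j) / sum(w_j), se = sum(w_j)^(-1/2), w_j = 1/se_j^2.
    A heterogeneity block is attached when at least two ratios are pooled.
    """
    ratios = _as_ratios(ratios)
    if not ratios:
        raise DomainError("IVW requires at least one ratio estimate")
    w = np.array([r.weight for r in ratios])
    b = np.array([r.ratio for r in ratios])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    het = heterogeneity(ratios, beta) if len(ratios) >= 2 else None
    return MRResult(
        method="IVW_fixed",
        beta=beta,
        se=se,
        pvalue=p_two_sided(beta / se),
        n_snps=len(ratios),
        het=het,
    )


def heterogeneity(
    ratios: Sequence[Union[HarmonizedInstrument, RatioEstimate]],
    beta_pooled: float,
) -> HeterogeneityBlock:
    """Cochran's Q of the ratios around the pooled estimate, with
    I2 = max(0, 100 (Q - df) / Q) and a test-based CI.

    The CI follows the ln-H construction: H = sqrt(Q/df), with
    SE(ln H) = (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1))) when
    Q > df and sqrt(1/(2(df-1)) (1 - 1/(3 (df-2)^2))) otherwise; the
    normal-theory interval for H is back-transformed to the I2 scale and
    truncated to [0, 100].
    """
    ratios = _as_ratios(ratios)
    if len(ratios) < 2:
        raise DomainError("heterogeneity needs at least 2 ratios")
    w = np.array([r.weight for r in ratios])
    b = np.array([r.ratio for r in ratios])
    Q = float(np.sum(w * (b - beta_pooled) ** 2))
    df = len(ratios) - 1
    i2 = max(0.0, 100.0 * (Q - df) / Q) if Q > 0 else 0.0

    ln_h = 0.5 * math.log(Q / df) if Q > df else 0.0
    if Q > df:
        se_ln_h = 0.5 * (math.log(Q) - math.log(df)) / (math.sqrt(2 * Q) - math.sqrt(2 * df - 1))
    elif df > 2:
        se_ln_h = math.sqrt(1.0 / (2 * (df - 1)) * (1.0 - 1.0 / (3 * (df - 2) ** 2)))
    else:
        se_ln_h = 0.0

    def _h_to_i2(h: float) -> float:
        if h <= 1.0:
            return 0.0
        return min(100.0, 100.0 * (h * h - 1.0) / (h * h))

    lo = _h_to_i2(math.exp(ln_h - Z975 * se_ln_h))
    hi = _h_to_i2(math.exp(ln_h + Z975 * se_ln_h))
    return HeterogeneityBlock(Q=Q, df=df, i2=i2, i2_ci_low=lo, i2_ci_high=hi)


def _oriented_arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gamma, Gamma, se_Gamma) with every gamma flipped non-negative.

    Jointly flipping the sign of (gamma, Gamma) re-expresses the SNP on its
    other allele and leaves the Wald ratio unchanged; Egger regression
    requires this consistent orientation to make the intercept meaningful.
    """
    g = np.array([i.gamma for i in instruments], dtype=float)
    G = np.array([i.Gamma for i in instruments], dtype=float)
    seG = np.array([i.se_Gamma for i in instruments], dtype=float)
    sign = np.where(g < 0, -1.0, 1.0)
    return g * sign, G * sign, seG


def egger(instruments: Sequence[HarmonizedInstrument]) -> tuple[MRResult, MRResult]:
    """MR-Egger regression: WLS of Gamma on gamma with a free intercept.

    Weights are 1/se_Gamma^2 and parameter SEs come from the unscaled
    (known-variance) covariance (X' W X)^{-1}.  Returns
    ``(intercept_result, slope_result)``; the intercept estimates the
    average directional pleiotropic effect and the slope the
    pleiotropy-adjusted causal effect.
    """
    if len(instruments) < 3:
        raise DomainError("MR-Egger needs at least 3 instruments")
    g, G, seG = _oriented_arrays(instruments)
    if np.ptp(g) == 0.0:
        raise DomainError("zero spread in exposure effects: Egger design is singular")
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=1.0 / seG**2).fit()
    beta0, beta1 = (float(v) for v in fit.params)
    # normalized_cov_params is (X'WX)^{-1}: the known-variance covariance
    cov = np.asarray(fit.normalized_cov_params)
    se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    intercept = MRResult(
        method="Egger_intercept",
        beta=beta0,
        se=se0,
        pvalue=p_two_sided(beta0 / se0),
        n_snps=len(instruments),
    )
    slope = MRResult(
        method="Egger_slope",
        beta=beta1,
        se=se1,
        pvalue=p_two_sided(beta1 / se1),
        n_snps=len(instruments),
    )
    return intercept, slope


def weighted_median_point(
    ratios: Sequence[Union[HarmonizedInstrument, RatioEstimate]],
    interpolate: bool = True,
) -> float:
    """Weighted median of the Wald ratios with inverse-variance weights.

    With ratios sorted ascending and weights normalized to sum 1, the
    cumulative midpoint of ratio j is p_j = S_j - w_j/2.  The default
    (``interpolate=True``) linearly interpolates the ratio at p = 1/2 —
    the estimator of the published weighted-median method.  With
    ``interpolate=False`` the step-CDF convention is used instead (the
    smallest ratio whose cumulative weight reaches 1/2), which is exactly
    the minimizer of sum_j w_j |x - b_j|.  The two conventions differ by
    at most the spacing between adjacent ratios.
    """
    ratios = _as_ratios(ratios)
    if len(ratios) < 1:
        raise DomainError("weighted median needs at least one ratio")
    b = np.array([r.ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    return _weighted_median_values(b, w, interpolate)


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    interpolate: bool = True,
) -> MRResult:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Each bootstrap replicate redraws every (gamma_j, Gamma_j) from normal
    distributions centred on the observed effects with their reported SEs,
    recomputes Wald ratios and weights, and re-evaluates the weighted
    median; the SE is the standard deviation over replicates
    (seed-deterministic).
    """
    if len(instruments) < 3:
        raise DomainError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise ConfigError(f"n_boot must be >= 1, got {n_boot}")
    point = weighted_median_point([wald_ratio(i) for i in instruments], interpolate=interpolate)

    g = np.array([i.gamma for i in instruments])
    seg = np.array([i.se_gamma for i in instruments])
    G = np.array([i.Gamma for i in instruments])
    seG = np.array([i.se_Gamma for i in instruments])
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for r in range(n_boot):
        gb = rng.normal(g, seg)
        Gb = rng.normal(G, seG)
        gb = np.where(gb == 0.0, np.finfo(float).tiny, gb)
        ratios = Gb / gb
        weights = (gb / seG) ** 2
        reps[r] = _weighted_median_values(ratios, weights, interpolate)
    se = float(np.std(reps, ddof=1)) if n_boot > 1 else float("nan")
    if not se > 0:
        raise DomainError("degenerate bootstrap: zero spread in replicates")
    return MRResult(
        method="WeightedMedian",
        beta=point,
        se=se,
        pvalue=p_two_sided(point / se),
        n_snps=len(instruments),
    )


def _weighted_median_values(b: np.ndarray, w: np.ndarray, interpolate: bool = True) -> float:
    order = np.argsort(b, kind="stable")
    b = b[order]
    w = w[order]
    w = w / w.sum()
    cum = np.cumsum(w)
    if interpolate:
        return float(np.interp(0.5, cum - w / 2.0, b))
    idx = int(np.searchsorted(cum, 0.5))
    return float(b[min(idx, len(b) - 1)])
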