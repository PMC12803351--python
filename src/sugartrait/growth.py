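"""Growth statistics: OD600 curve AUC, Spearman gene-count/growth
association, predictor prevalence filtering, and the random-intercept
linear mixed model for CFU outcomes.

The mixed model regresses a CFU outcome at one (timepoint, sugar
concentration) stratum on binary gene-presence indicators with a random
intercept per biological repeat:

    y = X beta + u_group + eps,   u ~ N(0, s_u^2),  eps ~ N(0, s_e^2)

fitted by maximum likelihood.  The default outcome scale is
log10(CFU + 1); CFU counts span orders of magnitude and residual
normality is untenable on the raw scale, but a raw mode is available.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GrowthCurve:
    strain: str
    condition: str
    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)
        if len(t) != len(od) or len(t) < 2:
            raise ValueError("need >= 2 matching (time, OD) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD600 must be non-negative")


def curve_auc(curve: GrowthCurve, baseline_subtract: bool = False) -> float:
    """Area under an OD600 growth curve (OD*hours), trapezoidal rule.

    With ``baseline_subtract`` the initial OD is subtracted first
    (negative areas are possible then); by default the raw curve is
    integrated.
    """
    od = curve.od600 - (curve.od600[0] if baseline_subtract else 0.0)
    return float(np.trapezoid(od, curve.times))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_assoc(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= ``exact_max_n`` the p-value is
    an exact permutation tail probability (all n! orderings of y);
    beyond that the usual t approximation is used.  Constant input makes
    rho undefined and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman association")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # exact two-sided permutation p over all orderings of y's ranks
        rx_c = rx - rx.mean()
        denom = math.sqrt(np.sum(rx_c**2))
        obs = abs(rho)
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        sy = math.sqrt(np.sum(ry_c**2))
        for perm in itertools.permutations(range(n)):
            r = float(np.dot(rx_c, ry_c[list(perm)])) / (denom * sy)
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    # t approximation
    t = rho * math.sqrt((n - 2) / (1 - rho**2)) if abs(rho) < 1 else math.inf
    p = 2 * stats.t.sf(abs(t), df=n - 2) if math.isfinite(t) else 0.0
    return rho, float(min(p, 1.0))


def prevalence_gene_filter(
    presence: pd.DataFrame, lower: float = 0.25, upper: float = 0.75
) -> list[str]:
    """Retain genes informative for regression: present in more than
    ``lower`` but fewer than ``upper`` of species (both bounds strict).

    ``presence`` is a species x gene binary matrix.
    """
    if len(presence) < 1:
        raise ValueError("need at least one species")
    prev = presence.mean(axis=0)
    return [g for g in presence.columns if lower < prev[g] < upper]


@dataclass
class MixedModelDesign:
    """CFU outcome and gene-presence predictors at one stratum."""

    outcome: np.ndarray
    predictors: pd.DataFrame  # binary indicator columns
    group: np.ndarray  # biological-repeat index per row
    log10_transform: bool = True

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome, dtype=float)
        g = np.asarray(self.group)
        if not (len(y) == len(self.predictors) == len(g)):
            raise ValueError("outcome, predictors and group must align row-wise")
        if not self.predictors.isin([0, 1]).all().all():
            raise ValueError("predictors must be binary indicators")
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "group", g)

    @property
    def y(self) -> np.ndarray:
        return np.log10(self.outcome + 1.0) if self.log10_transform else self.outcome


@dataclass
class MixedModelFit:
    params: pd.Series  # fixed effects incl. intercept
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma_u2: float
    sigma_e2: float
    loglik: float
    dropped: list[str] = field(default_factory=list)


def fit_random_intercept_lmm(design: MixedModelDesign) -> MixedModelFit:
    """ML fit of the random-intercept model for one stratum.

    Constant predictor columns are dropped with a warning; remaining
    rank deficiency raises with the aliased columns named.  Wald z tests
    per fixed effect are reported.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = design.predictors.copy()
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    groups = pd.Series(design.group)
    if groups.nunique() < 2:
        raise ValueError("need >= 2 biological-repeat groups")
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    names = ["const", *X.columns]
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # name aliased columns for the error message
        aliased = []
        for j in range(1, exog.shape[1]):
            others = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(exog):
                aliased.append(names[j])
        raise ValueError(f"design is rank deficient; aliased predictors: {aliased}")
    model = MixedLM(design.y, exog, groups=groups.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)
    params = pd.Series(np.asarray(fit.fe_params), index=names)
    bse = pd.Series(np.asarray(fit.bse_fe), index=names)
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    sigma_u2 = float(np.asarray(fit.cov_re)[0, 0])
    return MixedModelFit(
        params=params,
        bse=bse,
        zvalues=z,
        pvalues=pd.Series(p, index=names),
        sigma_u2=sigma_u2,
        sigma_e2=float(fit.scale),
        loglik=float(fit.llf),
        dropped=dropped,
    )
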