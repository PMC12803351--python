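"""Bayesian sugar-genus association models and the second-stage
transporter-count regression.

Each genus gets an independent univariate linear model of its
standardized CLR abundance on standardized lagged sugar exposure:

    y_i ~ Normal(mu_i, sigma),  mu_i = alpha + beta * x_i
    alpha ~ Normal(0, 1),  beta ~ Normal(0, 1),  sigma ~ Exponential(1)

Posteriors are drawn with an adaptive random-walk Metropolis sampler on
(alpha, beta, log sigma) — the model is three-dimensional, so a
gradient-based sampler buys nothing — with covariance adaptation during
warmup only, 4 chains x 1000 retained draws (4000 total) by default.
Summaries report the beta mean, 66% and 95% equal-tail credible
intervals, and the 95% highest-posterior-density (HPD) interval; a
genus "responds" to sugar when the HPD excludes zero.

The second stage regresses the per-genus beta means on the genus-mean
transporter count of one family, normalized by its maximum, using the
same priors and sampler.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_LOG_2PI = math.log(2.0 * math.pi)
RHAT_WARN = 1.01


@dataclass
class GenusModel:
    """Data and sufficient statistics for one univariate genus model."""

    y: np.ndarray
    x: np.ndarray
    genus: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("y and x must be equal-length vectors")
        if not (np.isfinite(y).all() and np.isfinite(x).all()):
            raise ValueError("non-finite data")
        self.y, self.x = y, x
        # sufficient statistics make each likelihood evaluation O(1)
        self._n = len(y)
        self._sx = float(x.sum())
        self._sy = float(y.sum())
        self._sxx = float(x @ x)
        self._syy = float(y @ y)
        self._sxy = float(x @ y)

    @property
    def n(self) -> int:
        return self._n

    def _ssr(self, alpha: float, beta: float) -> float:
        return (
            self._syy
            - 2 * alpha * self._sy
            - 2 * beta * self._sxy
            + 2 * alpha * beta * self._sx
            + self._n * alpha * alpha
            + beta * beta * self._sxx
        )


def log_posterior(
    model: GenusModel, alpha: float, beta: float, sigma: float
) -> float:
    """Joint log density of data and parameters (no terms dropped).

    Returns -inf for sigma <= 0 (rejected state).
    """
    if sigma <= 0:
        return -math.inf
    n = model.n
    ll = 0.0
    if n:
        ll = -n * math.log(sigma) - model._ssr(alpha, beta) / (
            2.0 * sigma * sigma
        ) - 0.5 * n * _LOG_2PI
    lp = (
        -0.5 * alpha * alpha
        - 0.5 * beta * beta
        - _LOG_2PI  # the two standard-normal prior constants
        - sigma  # Exponential(1) log pdf, support already checked
    )
    return ll + lp


@dataclass
class PosteriorDraws:
    """Post-warmup draws (chains x draws) with convergence diagnostics."""

    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    accept_rate: float = float("nan")

    @property
    def n_total(self) -> int:
        return self.alpha.size

    def flat(self, name: str) -> np.ndarray:
        return getattr(self, name).reshape(-1)


def split_rhat(chains: np.ndarray) -> float:
    """Split R-hat over a (chains, draws) array."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    k, h = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = h * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (h - 1) / h * w + b / h
    return float(math.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk ESS via per-chain autocorrelation (Geyer initial positive
    sequence), averaged across chains."""
    m, n = chains.shape
    if n < 4:
        return float("nan")
    acov = np.zeros(n)
    for c in range(m):
        x = chains[c] - chains[c].mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n].real / n
        acov += ac
    acov /= m
    if acov[0] == 0:
        return float(m * n)
    rho = acov / acov[0]
    # sum paired autocorrelations until a pair goes non-positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2 * pair
        t += 2
    return float(m * n / tau)


def _run_chain(
    model: GenusModel,
    rng: np.random.Generator,
    draws: int,
    warmup: int,
    fixed_sigma: Optional[float],
    thin: int = 4,
) -> tuple[np.ndarray, float]:
    """One adaptive RWM chain on (alpha, beta[, log sigma]).

    ``thin`` post-warmup steps are taken per retained draw to cut
    autocorrelation.  Returns (draws x 3 array, acceptance rate).
    """
    d = 2 if fixed_sigma is not None else 3

    def target(state: np.ndarray) -> float:
        a, b = state[0], state[1]
        if fixed_sigma is not None:
            return log_posterior(model, a, b, fixed_sigma)
        ls = state[2]
        # change of variables sigma = exp(ls): add the log-Jacobian ls
        return log_posterior(model, a, b, math.exp(ls)) + ls

    state = np.zeros(d)
    lp = target(state)
    tries = 0
    while not math.isfinite(lp):
        tries += 1
        if tries > 10:
            raise RuntimeError("could not find a finite starting point")
        state = rng.normal(scale=0.5, size=d)
        lp = target(state)

    log_scale = math.log(0.5)
    chol = np.eye(d)
    hist = np.empty((warmup, d))
    out = np.empty((draws, 3))
    accepted = 0
    kept = warmup + draws * thin
    total = kept
    half = warmup // 2
    for t in range(total):
        adapting = t < warmup
        step = math.exp(log_scale)
        prop = state + step * (chol @ rng.standard_normal(d))
        lp_prop = target(prop)
        log_u = math.log(rng.random())
        acc = lp_prop - lp
        if log_u < acc:
            state, lp = prop, lp_prop
            if not adapting:
                accepted += 1
        if adapting:
            hist[t] = state
            # Robbins-Monro step-size tuning toward ~30% acceptance
            prob = 1.0 if acc >= 0 else (math.exp(acc) if acc > -50 else 0.0)
            log_scale += (prob - 0.3) / (t + 1) ** 0.6
            if half >= 10 and t >= half and (t - half) % 200 == 0:
                # adapt the proposal shape to the warmup covariance
                cov = np.cov(hist[t // 2 : t + 1].T) + 1e-8 * np.eye(d)
                chol = np.linalg.cholesky((2.38**2 / d) * cov)
                if t == half:
                    log_scale = 0.0
        elif (t - warmup) % thin == thin - 1:
            i = (t - warmup) // thin
            if d == 3:
                out[i] = (state[0], state[1], math.exp(state[2]))
            else:
                out[i] = (state[0], state[1], fixed_sigma)
    return out, accepted / max(draws * thin, 1)


def sample_posterior(
    model: GenusModel,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    fixed_sigma: Optional[float] = None,
    thin: int = 4,
) -> PosteriorDraws:
    """Draw from the posterior of one genus model.

    ``fixed_sigma`` conditions on a known residual scale (then only
    alpha and beta are sampled), which is useful for validating against
    the conjugate Gaussian closed form.  ``thin`` controls post-warmup
    thinning (retained draws stay chains x draws).  Identical seeds
    give identical draws.
    """
    seeds = np.random.SeedSequence(seed).spawn(chains)
    a = np.empty((chains, draws))
    b = np.empty((chains, draws))
    s = np.empty((chains, draws))
    acc = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        samples, rate = _run_chain(model, rng, draws, warmup, fixed_sigma, thin=thin)
        a[c], b[c], s[c] = samples[:, 0], samples[:, 1], samples[:, 2]
        acc.append(rate)
    rhat = {
        "alpha": split_rhat(a),
        "beta": split_rhat(b),
        "sigma": split_rhat(s) if fixed_sigma is None else 1.0,
    }
    ess = {
        "alpha": effective_sample_size(a),
        "beta": effective_sample_size(b),
        "sigma": effective_sample_size(s) if fixed_sigma is None else float("nan"),
    }
    worst = max(v for v in rhat.values() if math.isfinite(v))
    if worst > RHAT_WARN:
        warnings.warn(
            f"split R-hat {worst:.3f} > {RHAT_WARN} for model {model.genus!r}; "
            "chains may not have converged",
            stacklevel=2,
        )
    return PosteriorDraws(
        alpha=a, beta=b, sigma=s, rhat=rhat, ess=ess, accept_rate=float(np.mean(acc))
    )


def conjugate_posterior(
    model: GenusModel, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Gaussian posterior of (alpha, beta) given sigma.

    With standard-normal priors this is ridge regression:
    cov = (I + X'X / sigma^2)^-1, mean = cov X'y / sigma^2.
    """
    X = np.column_stack([np.ones(model.n), model.x])
    prec = np.eye(2) + X.T @ X / sigma**2
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ model.y) / sigma**2
    return mean, cov


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = int(math.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


@dataclass(frozen=True)
class PosteriorSummary:
    genus: str
    beta_mean: float
    ci66: tuple[float, float]
    ci95: tuple[float, float]
    hpd95: tuple[float, float]
    excludes_zero: bool
    rhat_beta: float = float("nan")
    ess_beta: float = float("nan")


def summarize_posterior(draws: PosteriorDraws, genus: str = "") -> PosteriorSummary:
    """Summarize the sugar coefficient: mean, 66%/95% equal-tail
    intervals, 95% HPD, and whether the HPD excludes zero."""
    beta = draws.flat("beta")
    if len(beta) < 100:
        raise ValueError("need >= 100 draws to summarize")
    ci66 = tuple(np.quantile(beta, [0.17, 0.83]))
    ci95 = tuple(np.quantile(beta, [0.025, 0.975]))
    hpd = hpd_interval(beta, 0.95)
    return PosteriorSummary(
        genus=genus,
        beta_mean=float(beta.mean()),
        ci66=(float(ci66[0]), float(ci66[1])),
        ci95=(float(ci95[0]), float(ci95[1])),
        hpd95=hpd,
        excludes_zero=not (hpd[0] <= 0.0 <= hpd[1]),
        rhat_beta=draws.rhat.get("beta", float("nan")),
        ess_beta=draws.ess.get("beta", float("nan")),
    )


def fit_all_genera(
    clr: pd.DataFrame,
    exposures: pd.DataFrame,
    seed: int = 0,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
) -> pd.DataFrame:
    """Fit one sugar-association model per genus.

    ``clr`` is a sample x genus CLR matrix indexed by sample_id;
    ``exposures`` carries sample_id and sugar_exposure.  Samples with an
    undefined exposure are excluded; the exposure is standardized once
    over the retained samples, and each genus column is standardized
    independently.  Genera with zero variance are reported with status
    ``zero_variance`` and NaN estimates.  Per-genus seeds derive
    deterministically from ``seed``.
    """
    from .compositional import standardize

    exp = exposures.dropna(subset=["sugar_exposure"]).set_index("sample_id")
    common = [s for s in clr.index if s in exp.index]
    if len(common) < 3:
        raise ValueError("need >= 3 samples with defined exposure")
    x = standardize(exp.loc[common, "sugar_exposure"].to_numpy(dtype=float))
    sub = clr.loc[common]
    genus_seeds = np.random.SeedSequence(seed).spawn(len(sub.columns))
    rows = []
    for gi, genus in enumerate(sub.columns):
        yraw = sub[genus].to_numpy(dtype=float)
        if np.std(yraw, ddof=1) == 0:
            rows.append({"genus": genus, "status": "zero_variance"})
            continue
        model = GenusModel(y=standardize(yraw), x=x, genus=str(genus))
        dr = sample_posterior(
            model,
            chains=chains,
            draws=draws,
            warmup=warmup,
            seed=int(genus_seeds[gi].generate_state(1)[0] % (2**31)),
        )
        summ = summarize_posterior(dr, genus=str(genus))
        rows.append(
            {
                "genus": genus,
                "status": "ok",
                "beta_mean": summ.beta_mean,
                "ci66_lo": summ.ci66[0],
                "ci66_hi": summ.ci66[1],
                "ci95_lo": summ.ci95[0],
                "ci95_hi": summ.ci95[1],
                "hpd95_lo": summ.hpd95[0],
                "hpd95_hi": summ.hpd95[1],
                "excludes_zero": summ.excludes_zero,
                "rhat_beta": summ.rhat_beta,
                "ess_beta": summ.ess_beta,
            }
        )
    cols = [
        "genus",
        "status",
        "beta_mean",
        "ci66_lo",
        "ci66_hi",
        "ci95_lo",
        "ci95_hi",
        "hpd95_lo",
        "hpd95_hi",
        "excludes_zero",
        "rhat_beta",
        "ess_beta",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


@dataclass
class TraitRegression:
    """Second-stage regression of genus sugar coefficients on a
    transporter-family mean count (normalized by its maximum)."""

    transporter_type: str
    covariate: np.ndarray  # normalized to [0, 1]
    outcome: np.ndarray  # per-genus beta means (z scale)
    genera: list[str]
    summary: Optional[PosteriorSummary]
    draws: Optional[PosteriorDraws]
    grid: Optional[np.ndarray]
    mean_curve: Optional[np.ndarray]
    band_lo: Optional[np.ndarray]
    band_hi: Optional[np.ndarray]
    spearman_rho: float
    spearman_p: float


_TYPE_COLS = {"abc": "abc", "pts": "pts", "mfs": "mfs", "total": "total"}


def _merge_stage2(
    summaries: pd.DataFrame, census: pd.DataFrame, transporter_type: str
) -> pd.DataFrame:
    col = _TYPE_COLS.get(transporter_type.lower())
    if col is None:
        raise ValueError(f"unknown transporter type {transporter_type!r}")
    fitted = summaries[summaries.get("status", "ok") == "ok"]
    merged = fitted.merge(census[["genus", col]], on="genus", how="inner")
    merged = merged.dropna(subset=["beta_mean", col])
    return merged.rename(columns={col: "count"})


def trait_regression(
    summaries: pd.DataFrame,
    census: pd.DataFrame,
    transporter_type: str = "abc",
    seed: int = 0,
    chains: int = 4,
    draws: int = 1000,
    warmup: int = 1000,
    grid_points: int = 50,
) -> TraitRegression:
    """Bayesian regression of beta means on normalized mean counts.

    ``summaries`` is a :func:`fit_all_genera` table; ``census`` a genus
    census table with columns genus/abc/pts/mfs/total.  The covariate
    is divided by its maximum before sampling (the outcome is already
    on the z scale).  The fitted mean over the covariate range is
    simulated from the posterior draws with a 95% band.  An all-zero
    covariate skips the regression but still reports the (undefined)
    Spearman statistics.
    """
    from .growth import spearman_assoc

    merged = _merge_stage2(summaries, census, transporter_type)
    if len(merged) < 3:
        raise ValueError("need >= 3 genera with both a count and a beta mean")
    counts = merged["count"].to_numpy(dtype=float)
    y = merged["beta_mean"].to_numpy(dtype=float)
    genera = merged["genus"].astype(str).tolist()
    if counts.max() <= 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearman_assoc(counts, y) if np.ptp(counts) else (np.nan, np.nan)
        return TraitRegression(
            transporter_type=transporter_type,
            covariate=counts,
            outcome=y,
            genera=genera,
            summary=None,
            draws=None,
            grid=None,
            mean_curve=None,
            band_lo=None,
            band_hi=None,
            spearman_rho=rho,
            spearman_p=p,
        )
    xnorm = counts / counts.max()
    model = GenusModel(y=y, x=xnorm, genus=f"stage2_{transporter_type}")
    dr = sample_posterior(
        model, chains=chains, draws=draws, warmup=warmup, seed=seed
    )
    summ = summarize_posterior(dr, genus=model.genus)
    grid = np.linspace(xnorm.min(), xnorm.max(), grid_points)
    mu = dr.flat("alpha")[:, None] + dr.flat("beta")[:, None] * grid[None, :]
    rho, p = spearman_assoc(counts, y)
    return TraitRegression(
        transporter_type=transporter_type,
        covariate=xnorm,
        outcome=y,
        genera=genera,
        summary=summ,
        draws=dr,
        grid=grid,
        mean_curve=mu.mean(axis=0),
        band_lo=np.quantile(mu, 0.025, axis=0),
        band_hi=np.quantile(mu, 0.975, axis=0),
        spearman_rho=rho,
        spearman_p=p,
    )


def trait_spearman(
    summaries: pd.DataFrame, census: pd.DataFrame, transporter_type: str = "abc"
) -> tuple[float, float]:
    """Spearman correlation between genus mean transporter counts and
    the per-genus sugar coefficients."""
    from .growth import spearman_assoc

    merged = _merge_stage2(summaries, census, transporter_type)
    if len(merged) < 3:
        raise ValueError("need >= 3 genera with both a count and a beta mean")
    counts = merged["count"].to_numpy(dtype=float)
    y = merged["beta_mean"].to_numpy(dtype=float)
    if np.ptp(counts) == 0:
        warnings.warn("constant covariate: Spearman undefined", stacklevel=2)
        return float("nan"), float("nan")
    return spearman_assoc(counts, y)
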