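"""Bayesian estimation of between-line differences by Gibbs sampling.

Each selected metabolite's (alr-transformed) abundance is modelled as a
Gaussian linear model y = Xb + e with fixed effects for line and sex and
i.i.d. residuals, e ~ N(0, I sigma2_e). With flat priors on the fixed
effects and the residual variance the full conditionals are conjugate:

    b | sigma2, y  ~  N( b_ols, sigma2 (X'X)^-1 )
    sigma2 | b, y  ~  SSR(b) / chi2_n   (scaled inverse chi-square, df = n)

Lines are coded +1/2 (H) and -1/2 (L), so the line coefficient is
directly the phenotypic H-minus-L difference D_HL. Posterior draws are
summarized by the median of D_HL, the shortest 95% highest-posterior-
density interval, the probability P0 that the difference shares the sign
of its median, and the difference expressed in units of the metabolite's
pooled within-line SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LinearModelSpec:
    """Response vector and fixed-effect incidence matrix for one trait."""

    y: np.ndarray
    design: np.ndarray  # (n, p) incidence matrix; full column rank required
    effect_names: tuple = ("intercept", "line", "sex")

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.design = np.asarray(self.design, dtype=float)
        n, p = self.design.shape
        if self.y.shape[0] != n:
            raise ValueError("response and design row counts differ")
        if n <= p:
            raise ValueError("need more observations than fixed effects")
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("rank-deficient design matrix")


@dataclass
class PosteriorSummary:
    """Posterior summary of one metabolite's line difference."""

    d_hl_median: float
    hpd95: tuple[float, float]
    p0: float
    d_sd_units: float
    n_draws: int
    burn_in: int

    def __post_init__(self) -> None:
        lo, hi = self.hpd95
        if not lo <= self.d_hl_median <= hi:
            raise ValueError("median must lie inside the HPD interval")
        if not 0.5 - 1e-12 <= self.p0 <= 1.0 + 1e-12:
            raise ValueError("P0 must lie in [0.5, 1]")


def make_line_sex_design(samples: pd.DataFrame) -> np.ndarray:
    """Incidence matrix with intercept, line (H=+1/2, L=-1/2) and sex
    (M=+1/2, F=-1/2) columns, so each coefficient is directly a contrast."""
    line = (samples["line"] == "H").to_numpy(float) - 0.5
    sex = (samples["sex"] == "M").to_numpy(float) - 0.5
    return np.column_stack([np.ones(len(samples)), line, sex])


def gibbs_sample(
    spec: LinearModelSpec,
    n_draws: int = 50_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Gibbs sampler for the flat-prior Gaussian linear model.

    Alternates the conjugate full conditionals of b and sigma2_e; returns
    the post-burn-in draws. A Geweke mean-comparison on the first fixed
    effect after the intercept flags (but does not fail on) poor mixing.
    """
    if not n_draws > burn_in >= 0:
        raise ValueError("need n_draws > burn_in >= 0")
    X, y = spec.design, spec.y
    n, p = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    chol = np.linalg.cholesky(xtx_inv)
    b_ols = xtx_inv @ (X.T @ y)
    yty = y @ y
    xty = X.T @ y

    rng = np.random.default_rng(seed)
    b = b_ols.copy()
    ssr = yty - 2 * b @ xty + b @ xtx @ b
    sigma2 = max(ssr / n, 1e-12)

    b_draws = np.empty((n_draws - burn_in, p))
    s2_draws = np.empty(n_draws - burn_in)
    for it in range(n_draws):
        b = b_ols + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
        ssr = yty - 2 * b @ xty + b @ xtx @ b
        sigma2 = max(ssr, 1e-300) / rng.chisquare(n)
        if it >= burn_in:
            b_draws[it - burn_in] = b
            s2_draws[it - burn_in] = sigma2

    _geweke_check(b_draws[:, min(1, p - 1)])
    return {"b": b_draws, "sigma2": s2_draws}


def _geweke_check(chain: np.ndarray, z_limit: float = 3.0) -> float:
    """Geweke convergence diagnostic: compare the first 10% of the chain
    with the last 50%; warn when |z| exceeds ``z_limit``."""
    n = chain.size
    a = chain[: max(n // 10, 2)]
    c = chain[n // 2 :]
    denom = np.sqrt(a.var(ddof=1) / a.size + c.var(ddof=1) / c.size)
    z = 0.0 if denom == 0 else float((a.mean() - c.mean()) / denom)
    if abs(z) > z_limit:
        warnings.warn(
            f"Geweke z = {z:.2f} suggests the chain has not converged",
            RuntimeWarning,
            stacklevel=3,
        )
    return z


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n == 0:
        raise ValueError("no draws")
    k = max(int(np.ceil(mass * n)), 1)
    if k >= n:
        return float(draws[0]), float(draws[-1])
    widths = draws[k:] - draws[: n - k]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k])


def summarize_difference(
    draws: np.ndarray,
    metabolite_sd: float,
    n_draws: int | None = None,
    burn_in: int = 0,
) -> PosteriorSummary:
    """Summarize posterior draws of the line contrast.

    P0 is the posterior probability that the difference is positive when
    its median is positive, negative when negative — by construction at
    least 0.5 (draws equal to zero count half to each side).
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("no draws")
    if metabolite_sd <= 0:
        raise ValueError("metabolite SD must be positive")
    median = float(np.median(draws))
    sign = 1.0 if median >= 0 else -1.0
    p0 = float(np.mean(sign * draws > 0) + 0.5 * np.mean(draws == 0))
    p0 = max(p0, 0.5)
    lo, hi = hpd_interval(draws, 0.95)
    lo, hi = min(lo, median), max(hi, median)
    return PosteriorSummary(
        d_hl_median=median,
        hpd95=(lo, hi),
        p0=p0,
        d_sd_units=median / metabolite_sd,
        n_draws=n_draws if n_draws is not None else draws.size,
        burn_in=burn_in,
    )


def pooled_line_sd(values: pd.Series, line: pd.Series) -> float:
    """Pooled across-line sample SD of one trait."""
    groups = [values[line == ln].to_numpy(dtype=float) for ln in ("H", "L")]
    num = sum((g.size - 1) * g.var(ddof=1) for g in groups if g.size > 1)
    den = sum(g.size - 1 for g in groups if g.size > 1)
    if den <= 0:
        raise ValueError("need at least two samples in a line")
    return float(np.sqrt(num / den))


def fit_all_selected(
    data: pd.DataFrame,
    samples: pd.DataFrame,
    selected,
    n_draws: int = 50_000,
    burn_in: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the line+sex model to every selected metabolite.

    ``data`` holds the alr-transformed (un-standardized) traits so that
    D_HL and its SD standardization are on the interpretable log-ratio
    scale. One independent seed per metabolite is spawned from ``seed``,
    making the whole table reproducible and each trait re-runnable alone.
    """
    selected = pd.Index(selected)
    if selected.empty:
        raise ValueError("empty selection")
    missing = selected.difference(data.columns)
    if len(missing):
        raise KeyError(f"selected metabolites absent from data: {list(missing)}")

    design = make_line_sex_design(samples)
    children = np.random.SeedSequence(seed).spawn(len(selected))
    rows = []
    for met, child in zip(selected, children):
        spec = LinearModelSpec(y=data[met].to_numpy(), design=design)
        draws = gibbs_sample(
            spec, n_draws=n_draws, burn_in=burn_in,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        contrast = draws["b"][:, 1]  # line column
        sd = pooled_line_sd(data[met], samples["line"])
        summ = summarize_difference(contrast, sd, n_draws=n_draws, burn_in=burn_in)
        rows.append(
            {
                "metabolite_id": met,
                "d_hl_median": summ.d_hl_median,
                "hpd95_low": summ.hpd95[0],
                "hpd95_high": summ.hpd95[1],
                "p0": summ.p0,
                "sd": sd,
                "d_sd_units": summ.d_sd_units,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite_id")
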