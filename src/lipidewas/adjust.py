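"""Empirical-null recalibration of z-scores and multiplicity control.

Sequencing EWAS test statistics are typically biased and inflated —
from unmodelled overdispersion of read counts, batch structure, or
residual confounding — so the raw z-scores are recalibrated against an
estimated empirical null.  The statistic vector is modelled as a
three-component Gaussian mixture w0 N(mu0, sigma0^2) + w1 N(mu1,
sigma1^2) + w2 N(mu2, sigma2^2) with mu1 < mu0 < mu2 and the null
component dominant; the null bias mu0 and inflation sigma0 are estimated
by a constrained EM and the corrected statistic is z' = (z - mu0) /
sigma0.  Multiplicity is controlled per trait with Storey q-values
(pi0 estimated on a lambda grid with a cubic smoother) and the classical
per-trait Bonferroni cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmpiricalNull",
    "estimate_empirical_null",
    "correct_statistics",
    "genomic_inflation_lambda",
    "storey_qvalues",
    "bonferroni_threshold",
    "adjust_associations",
]

CHI2_1_MEDIAN = 0.45493642311957184  # median of chi-square with 1 df


@dataclass
class EmpiricalNull:
    """Fitted null component of the z-score mixture."""

    mu0: float
    sigma0: float
    w0: float
    means: np.ndarray  # (low, null, high)
    sigmas: np.ndarray
    weights: np.ndarray
    converged: bool
    fallback: bool
    n_iter: int
    loglik: float


def _em_mixture(
    z: np.ndarray, max_iter: int, tol: float, separation: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int, float]:
    """Constrained 3-component Gaussian mixture EM.

    The two signal components are kept at least ``separation`` null-SDs
    away from the null mean (identifiability: the null must not leak
    into the tails it is supposed to own).
    """
    med = float(np.median(z))
    mad_sd = float(stats.median_abs_deviation(z, scale="normal"))
    if mad_sd <= 0:
        mad_sd = max(float(np.std(z)), 1e-6)
    means = np.array([med - 4.0 * mad_sd, med, med + 4.0 * mad_sd])
    sigmas = np.array([mad_sd, mad_sd, mad_sd])
    weights = np.array([0.05, 0.90, 0.05])

    loglik_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space
        logdens = np.stack(
            [stats.norm.logpdf(z, means[c], max(sigmas[c], 1e-6)) for c in range(3)]
        ) + np.log(np.maximum(weights, 1e-300))[:, None]
        m = logdens.max(axis=0)
        lse = m + np.log(np.exp(logdens - m).sum(axis=0))
        resp = np.exp(logdens - lse)
        loglik = float(lse.sum())

        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / len(z)
        means = (resp @ z) / nk
        sigmas = np.sqrt(
            np.maximum((resp @ (z**2)) / nk - means**2, 1e-12)
        )
        # constraints: ordered means with minimum separation from the null
        sep = separation * sigmas[1]
        means[0] = min(means[0], means[1] - sep)
        means[2] = max(means[2], means[1] + sep)
        # null dominance
        if weights[1] < max(weights[0], weights[2]):
            top = max(weights[0], weights[2])
            weights[1] = top
            weights = weights / weights.sum()

        if abs(loglik - loglik_prev) < tol * (abs(loglik) + 1.0):
            converged = True
            break
        loglik_prev = loglik
    return means, sigmas, weights, converged, it, loglik


def estimate_empirical_null(
    z: np.ndarray | pd.Series,
    max_iter: int = 500,
    tol: float = 1e-10,
    separation: float = 3.0,
) -> EmpiricalNull:
    """Estimate null bias and inflation from a vector of z-scores.

    Requires at least 500 finite statistics.  Falls back to the
    median/MAD estimate (flagged) if the EM does not converge.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 500:
        raise ValueError(f"need at least 500 finite z-scores, got {len(z)}")
    means, sigmas, weights, converged, n_iter, loglik = _em_mixture(
        z, max_iter=max_iter, tol=tol, separation=separation
    )
    if not converged:
        import warnings

        warnings.warn("empirical-null EM did not converge; falling back to median/MAD")
        mu0 = float(np.median(z))
        sigma0 = float(stats.median_abs_deviation(z, scale="normal"))
        return EmpiricalNull(
            mu0=mu0, sigma0=max(sigma0, 1e-6), w0=1.0,
            means=np.array([np.nan, mu0, np.nan]),
            sigmas=np.array([np.nan, sigma0, np.nan]),
            weights=np.array([0.0, 1.0, 0.0]),
            converged=False, fallback=True, n_iter=n_iter, loglik=loglik,
        )
    return EmpiricalNull(
        mu0=float(means[1]), sigma0=float(sigmas[1]), w0=float(weights[1]),
        means=means, sigmas=sigmas, weights=weights,
        converged=True, fallback=False, n_iter=n_iter, loglik=loglik,
    )


def correct_statistics(
    z: np.ndarray | pd.Series, null: EmpiricalNull
) -> tuple[np.ndarray, np.ndarray]:
    """Recentre/rescale z by the fitted null; two-sided normal p-values."""
    if null.sigma0 <= 0:
        raise ValueError("null inflation sigma0 must be positive")
    z = np.asarray(z, dtype=float)
    z_corr = (z - null.mu0) / null.sigma0
    p_corr = 2.0 * stats.norm.sf(np.abs(z_corr))
    return z_corr, p_corr


def genomic_inflation_lambda(z: np.ndarray | pd.Series) -> float:
    """lambda = median(z^2) / median of chi-square(1)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) == 0:
        raise ValueError("empty statistic vector")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def storey_qvalues(
    p: np.ndarray | pd.Series, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoothed lambda-grid pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    grid 0.05..0.95 and a cubic smoother is read off at lambda = 0.95;
    estimates above 1 (or fewer than 100 p-values) fall back to pi0 = 1,
    which reduces q-values to Benjamini-Hochberg.  Returns (q, pi0).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            grid = np.arange(0.05, 0.951, 0.05)
            pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
            coeffs = np.polyfit(grid, pi0_grid, deg=3)
            pi0 = float(np.polyval(coeffs, 0.95))
            if pi0 > 1.0 or pi0 <= 0.0:
                pi0 = 1.0
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-trait Bonferroni significance cutoff alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def adjust_associations(
    records: pd.DataFrame,
    fdr_levels: tuple[float, ...] = (0.05, 0.10),
) -> tuple[pd.DataFrame, dict]:
    """Empirical-null correction and per-trait q-values for an EWAS table.

    Adds z_corrected, p_corrected and q columns (flagged records keep
    NaN and are excluded from the multiplicity denominator).  Returns
    the augmented table and a per-trait summary: null parameters, lambda
    before/after, and the corrected-p cutoffs realizing each FDR level.
    """
    out = records.copy()
    out["z_corrected"] = np.nan
    out["p_corrected"] = np.nan
    out["q"] = np.nan
    summary: dict[str, dict] = {}
    for trait, idx in out.groupby("trait").groups.items():
        sub = out.loc[idx]
        ok = sub["z"].notna()
        z = sub.loc[ok, "z"].to_numpy()
        if len(z) == 0:
            continue
        null = estimate_empirical_null(z)
        z_corr, p_corr = correct_statistics(z, null)
        q, pi0 = storey_qvalues(np.maximum(p_corr, np.nextafter(0, 1)))
        out.loc[sub.index[ok], "z_corrected"] = z_corr
        out.loc[sub.index[ok], "p_corrected"] = p_corr
        out.loc[sub.index[ok], "q"] = q
        cutoffs = {}
        for level in fdr_levels:
            sig = p_corr[q <= level]
            cutoffs[level] = float(sig.max()) if len(sig) else 0.0
        summary[str(trait)] = {
            "mu0": null.mu0,
            "sigma0": null.sigma0,
            "w0": null.w0,
            "fallback": null.fallback,
            "pi0": pi0,
            "lambda_raw": genomic_inflation_lambda(z),
            "lambda_corrected": genomic_inflation_lambda(z_corr),
            "n_tests": int(len(z)),
            "n_flagged": int((~ok).sum()),
            "bonferroni": bonferroni_threshold(len(z)),
            "fdr_cutoffs": cutoffs,
        }
    return out, summary
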