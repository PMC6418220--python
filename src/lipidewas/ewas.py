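"""Trait preparation and coverage-weighted binomial regression per CpG.

The association model is a binomial GLM with logit link on the
methylation proportion m of each CpG, weighted by the read coverage T of
the site in each sample — equivalent to modelling the methylated read
count out of T reads — with the standardized lipid trait and the cohort
covariates (age, sex, BMI, capture-panel batch, optionally cell
proportions) in the linear predictor.  The trait coefficient is tested
with a two-sided Wald z.

Fitting is batched Newton/IRLS across all CpGs simultaneously: missing
entries enter with zero weight, so CpG-specific coverage patterns need
no per-CpG design rebuilds.  Convergence is declared when the largest
absolute score-equation component falls below ``tol`` (default 1e-8,
at most 50 iterations); non-converged or separated fits are flagged,
never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from lipidewas.qc import MethylationMatrix

__all__ = ["TraitVector", "prepare_trait", "build_design", "fit_weighted_binomial", "run_ewas"]


@dataclass
class TraitVector:
    """A prepared trait: transformed, outlier-trimmed once, standardized.

    ``values`` holds the standardized trait with NaN at trimmed or
    missing samples; ``mask`` marks samples entering fits.
    """

    values: pd.Series
    mask: pd.Series
    transform: str
    n_trimmed: int


def prepare_trait(raw: pd.Series, transform: str = "identity") -> TraitVector:
    """Transform, trim outliers at mean +/- 3 SD (single pass), standardize.

    The log transform (for right-skewed traits such as TG) is applied
    first; the trim threshold is computed once on the transformed
    pre-trim distribution and not re-applied to the trimmed set.
    """
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    values = raw.astype(float)
    present = values.notna()
    if present.sum() < 10:
        raise ValueError("need at least 10 non-missing trait values")
    if transform == "log":
        bad = present & (values <= 0)
        if bad.any():
            raise ValueError(
                "log transform undefined for non-positive values at samples: "
                + ", ".join(map(str, values.index[bad]))
            )
        values = values.where(~present, np.log(values))
    mean = values[present].mean()
    sd = values[present].std(ddof=1)
    keep = present & (values >= mean - 3 * sd) & (values <= mean + 3 * sd)
    n_trimmed = int(present.sum() - keep.sum())
    kept = values[keep]
    standardized = (values - kept.mean()) / kept.std(ddof=1)
    standardized[~keep] = np.nan
    return TraitVector(values=standardized, mask=keep, transform=transform, n_trimmed=n_trimmed)


def build_design(
    covariates: pd.DataFrame,
    cell_prefix: str = "cell_",
) -> pd.DataFrame:
    """Numeric design columns from the covariate table (no intercept).

    Continuous covariates are standardized, the batch factor is dummy
    coded, and one cell-proportion column is dropped to break the
    simplex collinearity.
    """
    cols = {}
    for name in ("age", "bmi"):
        if name in covariates:
            x = covariates[name].astype(float)
            cols[name] = (x - x.mean()) / x.std(ddof=0)
    if "sex" in covariates:
        cols["sex"] = covariates["sex"].astype(float)
    if "batch" in covariates:
        levels = sorted(covariates["batch"].unique())
        for level in levels[1:]:
            cols[f"batch_{level}"] = (covariates["batch"] == level).astype(float)
    cells = sorted(c for c in covariates.columns if c.startswith(cell_prefix))
    for c in cells[1:]:  # drop the first: proportions sum to one
        cols[c] = covariates[c].astype(float)
    design = pd.DataFrame(cols, index=covariates.index)
    if design.isna().any().any():
        raise ValueError("missing values in covariates entering the design")
    return design


def _batched_irls(
    M: np.ndarray,
    W0: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS for k weighted-binomial GLMs sharing one design.

    M: (k, n) proportions (NaN allowed where weight 0), W0: (k, n)
    coverage weights, X: (n, p).  Returns (beta (k, p), cov (k, p, p),
    converged (k,)).
    """
    k, n = M.shape
    p = X.shape[1]
    M = np.where(W0 > 0, M, 0.0)
    beta = np.zeros((k, p))
    tw = W0.sum(axis=1)
    pooled = np.clip(
        np.divide((W0 * M).sum(axis=1), np.maximum(tw, 1e-12)), 1e-6, 1 - 1e-6
    )
    beta[:, 0] = logit(pooled)
    converged = np.zeros(k, dtype=bool)
    eye = np.eye(p)

    for _ in range(maxiter):
        eta = np.clip(beta @ X.T, -30.0, 30.0)
        mu = expit(eta)
        resid = W0 * (M - mu)
        grad = resid @ X  # (k, p) score equations
        gmax = np.abs(grad).max(axis=1)
        newly = gmax < tol
        converged |= newly
        active = ~converged
        if not active.any():
            break
        w = (W0 * mu * (1.0 - mu))[active]
        A = np.einsum("kn,np,nq->kpq", w, X, X)
        # tiny ridge keeps near-separated fits solvable; flagged below anyway
        A += 1e-10 * eye
        try:
            step = np.linalg.solve(A, grad[active][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(a, g, rcond=None)[0] for a, g in zip(A, grad[active])]
            )
        beta[active] += step

    eta = np.clip(beta @ X.T, -30.0, 30.0)
    mu = expit(eta)
    w = W0 * mu * (1.0 - mu)
    A = np.einsum("kn,np,nq->kpq", w, X, X) + 1e-10 * eye
    cov = np.linalg.pinv(A)
    # runaway coefficients mean separation: report as non-converged
    converged &= np.abs(beta).max(axis=1) < 1e3
    return beta, cov, converged


def fit_weighted_binomial(
    m: np.ndarray,
    T: np.ndarray,
    X: np.ndarray,
    test_col: int = 1,
    tol: float = 1e-8,
    maxiter: int = 50,
    min_n: int | None = None,
) -> dict:
    """Fit one coverage-weighted binomial GLM; Wald test on ``test_col``.

    Returns a record dict (beta, se, z, p_raw, n_used, flag).  Flags:
    'ok', 'degenerate' (methylation constant at 0 or 1), 'low_n',
    'constant_trait', 'not_converged'.  Never raises for data problems.
    ``min_n`` overrides the default sample floor rank(X) + 5 — e.g. for
    saturated fits on pooled count rows, where the coefficient has a
    closed form regardless of row count.
    """
    m = np.asarray(m, dtype=float)
    T = np.asarray(T, dtype=float)
    X = np.asarray(X, dtype=float)
    used = (T > 0) & np.isfinite(m) & np.isfinite(X).all(axis=1)
    record = {
        "beta": np.nan, "se": np.nan, "z": np.nan, "p_raw": np.nan,
        "n_used": int(used.sum()), "flag": "ok",
    }
    p = X.shape[1]
    floor = p + 5 if min_n is None else min_n
    if used.sum() < max(floor, p):
        record["flag"] = "low_n"
        return record
    if X.shape[1] > 1 and np.ptp(X[used, test_col]) == 0:
        record["flag"] = "constant_trait"
        return record
    mm = m[used]
    if np.all(mm == 0) or np.all(mm == 1):
        record["flag"] = "degenerate"
        return record
    W0 = np.where(used, T, 0.0)[None, :]
    beta, cov, conv = _batched_irls(m[None, :], W0, X, tol=tol, maxiter=maxiter)
    se = float(np.sqrt(max(cov[0, test_col, test_col], 0.0)))
    record["beta"] = float(beta[0, test_col])
    record["se"] = se
    record["intercept"] = float(beta[0, 0])
    record["coef"] = beta[0]
    if not conv[0]:
        record["flag"] = "not_converged"
        return record
    if se > 0:
        record["z"] = record["beta"] / se
        record["p_raw"] = float(2.0 * stats.norm.sf(abs(record["z"])))
    return record


def run_ewas(
    mat: MethylationMatrix,
    traits: dict[str, TraitVector],
    covariates: pd.DataFrame,
    min_samples: int = 20,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> pd.DataFrame:
    """Coverage-weighted binomial EWAS of every kept CpG against each trait.

    One record per (CpG x trait), deterministically ordered by
    (chrom, pos, trait).  Per-CpG sample sets are restricted to covered
    samples with a non-trimmed trait value; CpGs with fewer than
    ``min_samples`` usable samples, constant methylation, or
    non-converged fits are flagged with missing z rather than fitted.
    """
    if len(mat.cpg_ids) == 0:
        import warnings

        warnings.warn("no CpGs passed QC; EWAS result is empty")
        return pd.DataFrame(
            columns=["cpg_id", "chrom", "pos", "trait", "beta", "se", "z",
                     "p_raw", "n_used", "direction", "flag"]
        )
    design_cov = build_design(covariates).to_numpy()
    samples = mat.sample_ids
    M = mat.meth.to_numpy(dtype=float)
    T = mat.cov.to_numpy(dtype=float)
    k = M.shape[0]
    p = 2 + design_cov.shape[1]
    min_needed = max(min_samples, p + 5)

    all_records = []
    for trait_name in sorted(traits):
        tv = traits[trait_name]
        t = tv.values.reindex(samples).to_numpy(dtype=float)
        ok_sample = np.isfinite(t)
        X = np.column_stack([np.ones(len(samples)), np.where(ok_sample, t, 0.0), design_cov])
        W0 = T * ok_sample[None, :]
        Mz = np.where(W0 > 0, M, 0.0)

        covered = W0 > 0
        n_used = covered.sum(axis=1)
        all0 = ~(covered & (Mz > 0)).any(axis=1)
        all1 = ~(covered & (Mz < 1)).any(axis=1)
        degenerate = (all0 | all1) & (n_used > 0)
        tcol = X[:, 1]
        tmax = np.where(covered, tcol[None, :], -np.inf).max(axis=1)
        tmin = np.where(covered, tcol[None, :], np.inf).min(axis=1)
        tvar = np.where(n_used > 1, tmax - tmin, 0.0)
        fit_ok = (n_used >= min_needed) & ~degenerate & (tvar > 0)

        beta = np.full(k, np.nan)
        se = np.full(k, np.nan)
        conv = np.zeros(k, dtype=bool)
        if fit_ok.any():
            b, c, cv = _batched_irls(Mz[fit_ok], W0[fit_ok], X, tol=tol, maxiter=maxiter)
            beta[fit_ok] = b[:, 1]
            se[fit_ok] = np.sqrt(np.maximum(c[:, 1, 1], 0.0))
            conv[fit_ok] = cv

        flag = np.full(k, "ok", dtype=object)
        flag[n_used < min_needed] = "low_n"
        flag[(n_used >= min_needed) & degenerate] = "degenerate"
        flag[(n_used >= min_needed) & ~degenerate & (tvar == 0)] = "constant_trait"
        flag[fit_ok & ~conv] = "not_converged"

        z = np.where((se > 0) & conv, beta / np.where(se > 0, se, 1.0), np.nan)
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
        records = pd.DataFrame(
            {
                "cpg_id": mat.cpg_ids,
                "chrom": mat.positions["chrom"].to_numpy(),
                "pos": mat.positions["pos"].to_numpy(),
                "trait": trait_name,
                "beta": beta,
                "se": se,
                "z": z,
                "p_raw": p_raw,
                "n_used": n_used,
                "direction": np.sign(beta),
                "flag": flag,
            }
        )
        all_records.append(records)
    out = pd.concat(all_records, ignore_index=True)
    return out.sort_values(["chrom", "pos", "trait"], ignore_index=True)
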