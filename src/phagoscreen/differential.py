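"""Per-sgRNA negative-binomial differential abundance between sorted fractions.

This is step 1 of the two-step screen analysis. Counts are normalized with
median-of-ratios size factors, per-guide NB dispersions are estimated by a
method-of-moments estimator shrunk toward a mean-dispersion trend, and each
guide gets a Wald test on the log2 fold change from a two-condition NB GLM
with log link:

    mu_ij = s_j * q_i * 2**(beta_i * x_j),   Var = mu + alpha_i * mu**2

where s_j is the sample size factor, q_i the baseline abundance, x_j the
indicator of the contrast condition, and alpha_i the guide's dispersion. The
(q_i, beta_i) likelihood is maximized per guide by damped Newton iteration;
the standard error of beta comes from the observed Fisher information, the
p-value from the two-sided normal tail of beta/se, and multiple testing is
controlled by Benjamini-Hochberg across all tested guides in the contrast.

By design this is a deterministic, documented NB Wald pipeline: no Cox-Reid
adjustment, no empirical-Bayes dispersion prior, no LFC shrinkage, no
independent filtering or outlier refitting. Guides with all-zero counts in
both contrast conditions are the only exclusion (p = NA, out of the BH m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from phagoscreen.library import CountMatrix

LN2 = float(np.log(2.0))

#: Lower bound on the NB dispersion; below this the model is effectively Poisson.
DISPERSION_FLOOR = 1e-8


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each guide with positive counts in every sample, the ratio of its
    count to its across-sample geometric mean is formed; a sample's factor is
    the median of these ratios. Only all-positive guides enter (the geometric
    mean of a row containing zero is zero).
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no guide has positive counts in all samples; consider a "
            "pseudo-reference fallback on a filtered guide set"
        )
    sub = arr[positive]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    matrix: CountMatrix,
    norm: pd.Series,
    conditions: pd.Series | None = None,
    shrinkage_weight: float | str = "adaptive",
) -> pd.DataFrame:
    """Per-guide NB dispersions: within-condition MoM, trend fit, shrinkage.

    For each condition with >=2 replicates the method-of-moments dispersion
    ``(var - xi*mean)/mean**2`` is computed on normalized counts (``xi`` is
    the mean reciprocal size factor, the Poisson-noise term on the normalized
    scale; xi = 1 when all factors are 1) and pooled across conditions with
    degrees-of-freedom weights. A mean-dispersion trend a1/mu + a0 is fitted
    by least squares over guides with positive raw estimates, and the final
    dispersion interpolates between raw estimate and trend on the log scale
    with weight ``w`` on the trend, floored at :data:`DISPERSION_FLOOR`.

    By default ``w`` is estimated empirically as the fraction of the observed
    log-dispersion spread attributable to sampling noise: with ``d`` pooled
    residual degrees of freedom the raw estimate behaves roughly like
    ``alpha * chi2_d / d``, whose log has variance ``trigamma(d/2)``; the
    excess of the observed spread around the trend over that noise estimates
    the true guide-to-guide dispersion variation, and ``w = noise / (noise +
    excess)``. At typical screen replication (2-4 replicates) the raw
    estimates are so noisy that this pushes most of the weight onto the
    trend, which is what keeps the Wald test calibrated; pass a float in
    [0, 1] to fix the weight instead.

    Returns a DataFrame indexed by guide id with columns ``base_mean``,
    ``alpha_mom``, ``alpha_trend``, ``alpha`` and the weight used in
    ``.attrs["shrinkage_weight"]``.
    """
    if isinstance(shrinkage_weight, str):
        if shrinkage_weight != "adaptive":
            raise ValueError("shrinkage_weight must be a float in [0,1] or 'adaptive'")
    elif not 0.0 <= shrinkage_weight <= 1.0:
        raise ValueError("shrinkage_weight must be in [0, 1]")
    if conditions is None:
        conditions = matrix.samples.set_index("sample_id")["condition"]
    counts = matrix.counts
    norm = norm.reindex(counts.columns)
    normed = counts.to_numpy(dtype=float) / norm.to_numpy()[None, :]
    base_mean = normed.mean(axis=1)

    cond_labels = conditions.reindex(counts.columns).to_numpy()
    alpha_num = np.zeros(len(counts))
    alpha_den = np.zeros(len(counts))
    any_replicated = False
    for cond in pd.unique(cond_labels):
        cols = cond_labels == cond
        n_rep = int(cols.sum())
        if n_rep < 2:
            continue
        any_replicated = True
        sub = normed[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / norm.to_numpy()[cols]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - xi * mu) / np.square(mu), 0.0)
        w = float(n_rep - 1)
        alpha_num += w * np.nan_to_num(a)
        alpha_den += np.where(mu > 0, w, 0.0)
    if not any_replicated:
        raise ValueError("dispersion estimation needs >=2 replicates in some condition")
    with np.errstate(invalid="ignore"):
        alpha_mom = np.where(alpha_den > 0, alpha_num / np.maximum(alpha_den, 1.0), 0.0)
    alpha_mom = np.maximum(alpha_mom, 0.0)

    alpha_trend = _fit_trend(base_mean, alpha_mom)
    log_trend = np.log(np.maximum(alpha_trend, DISPERSION_FLOOR))
    log_raw = np.log(np.maximum(alpha_mom, DISPERSION_FLOOR))
    if shrinkage_weight == "adaptive":
        dof = float(alpha_den.max())  # pooled residual d.f. of the MoM estimate
        weight = _adaptive_weight(log_raw, log_trend, alpha_mom > 0, dof)
    else:
        weight = float(shrinkage_weight)
    # Raw estimate 0 carries no dispersion signal: fall back to the trend.
    w = np.where(alpha_mom > 0, weight, 1.0)
    alpha = np.exp((1.0 - w) * log_raw + w * log_trend)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "alpha_mom": alpha_mom,
            "alpha_trend": np.maximum(alpha_trend, DISPERSION_FLOOR),
            "alpha": alpha,
        },
        index=counts.index,
    )
    out.attrs["shrinkage_weight"] = weight
    return out


def _adaptive_weight(
    log_raw: np.ndarray, log_trend: np.ndarray, positive: np.ndarray, dof: float
) -> float:
    """Trend weight = sampling noise / (sampling noise + excess spread)."""
    from scipy.special import polygamma

    noise = float(polygamma(1, max(dof, 1.0) / 2.0))
    if positive.sum() < 2:
        return 1.0
    observed = float(np.var(log_raw[positive] - log_trend[positive]))
    excess = max(observed - noise, 0.0)
    return noise / (noise + excess)


def _fit_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a1/mu + a0 over positive raw estimates."""
    ok = (alpha_mom > 0) & (base_mean > 0)
    if ok.sum() < 2:
        # Degenerate screen (almost no replicate variance): flat fallback at
        # the mean positive estimate, or the floor if there is none.
        level = float(alpha_mom[ok].mean()) if ok.any() else DISPERSION_FLOOR
        return np.full_like(base_mean, max(level, DISPERSION_FLOOR))
    X = np.column_stack([1.0 / base_mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    a1, a0 = coef
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a1 / base_mean + a0, a0)
    return trend


@dataclass
class WaldOptions:
    max_iter: int = 100
    score_tol: float = 1e-8
    max_halvings: int = 30


def wald_test(
    matrix: CountMatrix,
    norm: pd.Series,
    dispersions: pd.DataFrame | pd.Series,
    contrast: tuple[str, str],
    options: WaldOptions | None = None,
) -> pd.DataFrame:
    """NB Wald test of condition ``contrast[0]`` versus reference ``contrast[1]``.

    Returns one row per guide with columns guide_id (index), gene, base_mean,
    log2fc, se, wald, p, padj, dispersion. Guides with zero counts in all
    samples of both conditions get NA statistics and do not count toward the
    BH denominator; guides whose likelihood maximization does not converge
    within the iteration budget are likewise flagged NA rather than crashing.
    """
    options = options or WaldOptions()
    cond_a, cond_b = contrast
    samples_a = matrix.condition_samples(cond_a)
    samples_b = matrix.condition_samples(cond_b)
    for cond, smp in ((cond_a, samples_a), (cond_b, samples_b)):
        if len(smp) < 2:
            raise ValueError(f"condition {cond!r} has {len(smp)} replicate(s); need >=2")
    cols = samples_a + samples_b
    k = matrix.counts[cols].to_numpy(dtype=float)
    s = norm.reindex(cols).to_numpy(dtype=float)
    x = np.array([1.0] * len(samples_a) + [0.0] * len(samples_b))
    alpha = (
        dispersions["alpha"] if isinstance(dispersions, pd.DataFrame) else dispersions
    )
    alpha = np.maximum(alpha.reindex(matrix.counts.index).to_numpy(dtype=float), DISPERSION_FLOOR)

    beta, se, converged = _fit_nb_glm(k, s, x, alpha, options)

    tested = k.sum(axis=1) > 0
    valid = tested & converged
    wald = np.where(valid, beta / se, np.nan)
    p = np.full(len(beta), np.nan)
    p[valid] = 2.0 * stats.norm.sf(np.abs(wald[valid]))
    padj = adjust_bh(p)

    base_mean = (k / s[None, :]).mean(axis=1)
    genes = (
        pd.Series(matrix.guide_to_gene).reindex(matrix.counts.index)
        if matrix.guide_to_gene
        else pd.Series("", index=matrix.counts.index)
    )
    out = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base_mean,
            "log2fc": np.where(valid, beta, np.nan),
            "se": np.where(valid, se, np.nan),
            "wald": wald,
            "p": p,
            "padj": padj,
            "dispersion": alpha,
        },
        index=matrix.counts.index,
    )
    out.index.name = "guide_id"
    return out


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Mu-dependent part of the NB log-likelihood, summed over samples."""
    amu = alpha[:, None] * mu
    return np.sum(
        k * np.log(np.maximum(mu, 1e-300)) - (k + 1.0 / alpha[:, None]) * np.log1p(amu),
        axis=1,
    )


def _fit_nb_glm(
    k: np.ndarray,
    s: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    options: WaldOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized damped-Newton fit of (log q, beta) for every guide at once.

    The linear predictor is log mu = log s + theta + beta*ln2*x. The Newton
    direction uses the observed Hessian; steps are halved until the
    log-likelihood does not decrease. Guides whose score norm never falls
    below tolerance, or whose Hessian degenerates (e.g., one condition all
    zero, pushing beta to infinity), are reported unconverged.
    """
    G = k.shape[0]
    logs = np.log(s)
    in_a = x == 1.0
    eps = 1e-8

    mean_b = (k[:, ~in_a] / s[~in_a]).mean(axis=1)
    mean_a = (k[:, in_a] / s[in_a]).mean(axis=1)
    theta = np.log(np.maximum(mean_b, eps))
    beta = np.log2(np.maximum(mean_a, eps) / np.maximum(mean_b, eps))

    def predictors(th: np.ndarray, be: np.ndarray) -> np.ndarray:
        eta = logs[None, :] + th[:, None] + LN2 * be[:, None] * x[None, :]
        return np.exp(np.clip(eta, -50.0, 50.0))

    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    # relative score tolerance: the score scales with the counts, so an
    # absolute cutoff would be unreachable in float64 for deep samples
    tol = options.score_tol * np.maximum(1.0, k.sum(axis=1))
    ll = _nb_loglik(k, predictors(theta, beta), alpha)
    for _ in range(options.max_iter):
        if not active.any():
            break
        mu = predictors(theta, beta)
        amu = alpha[:, None] * mu
        w_score = k - mu * (k * alpha[:, None] + 1.0) / (1.0 + amu)
        h = (k * alpha[:, None] + 1.0) * mu / np.square(1.0 + amu)
        u_t = w_score.sum(axis=1)
        u_b = LN2 * w_score[:, in_a].sum(axis=1)
        h_tt = h.sum(axis=1)
        h_ab = h[:, in_a].sum(axis=1)
        h_tb = LN2 * h_ab
        h_bb = LN2 * LN2 * h_ab

        score_norm = np.maximum(np.abs(u_t), np.abs(u_b))
        newly = active & (score_norm < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

        det = h_tt * h_bb - h_tb * h_tb
        degenerate = active & (det < 1e-12)
        active &= ~degenerate  # unrecoverable: boundary MLE (beta -> +/-inf)
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            d_theta = (h_bb * u_t - h_tb * u_b) / det
            d_beta = (h_tt * u_b - h_tb * u_t) / det
        step = np.clip(np.column_stack([d_theta, d_beta]), -10.0, 10.0)

        t = np.where(active, 1.0, 0.0)
        for _ in range(options.max_halvings):
            cand_ll = _nb_loglik(
                k, predictors(theta + t * step[:, 0], beta + t * step[:, 1]), alpha
            )
            worse = active & (cand_ll < ll - 1e-12)
            if not worse.any():
                break
            t = np.where(worse, t / 2.0, t)
        theta = theta + t * step[:, 0]
        beta = beta + t * step[:, 1]
        ll = _nb_loglik(k, predictors(theta, beta), alpha)

    # Standard error from the observed information at the optimum.
    mu = predictors(theta, beta)
    amu = alpha[:, None] * mu
    h = (k * alpha[:, None] + 1.0) * mu / np.square(1.0 + amu)
    h_tt = h.sum(axis=1)
    h_ab = h[:, in_a].sum(axis=1)
    det = h_tt * (LN2 * LN2 * h_ab) - np.square(LN2 * h_ab)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_beta = h_tt / np.maximum(det, 1e-300)
    se = np.sqrt(np.maximum(var_beta, 0.0))
    bad = det < 1e-12
    converged &= ~bad
    return beta, se, converged


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NA entries are excluded from m.

    Returns adjusted p-values aligned with the input (NA stays NA), capped at
    1 and monotone non-decreasing in the raw p ranking.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    vals = p[ok]
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    out[ok] = adjusted
    return out


def write_sgrna_stats(stats: pd.DataFrame, path: str, contrast: tuple[str, str]) -> None:
    """Write the per-guide statistics TSV; the contrast goes in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# contrast: {contrast[0]} vs {contrast[1]}\n")
        stats.to_csv(fh, sep="\t")
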