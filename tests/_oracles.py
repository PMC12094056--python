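"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: relationships come
from Monte-Carlo gene dropping, group-size edits from a naive full-rescan
fixed point, and variance components from ANOVA moment estimators or
closed-form least squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def gene_drop_A(
    sire: np.ndarray,
    dam: np.ndarray,
    n_reps: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the additive relationship matrix and its SE.

    Founders receive unique alleles; alleles are dropped through the
    pedigree (parents precede offspring, -1 = unknown; unknown parents
    contribute fresh unique alleles). The relationship estimate per
    replicate is half the number of IBD matches among the four cross-animal
    allele comparisons; its mean over replicates estimates A and the SE is
    the replicate standard deviation / sqrt(n_reps).
    """
    rng = np.random.default_rng(seed)
    n = len(sire)
    alleles = np.empty((n, 2, n_reps), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        for g, parent in enumerate((sire[i], dam[i])):
            if parent < 0:
                alleles[i, g, :] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, n_reps)
                alleles[i, g, :] = alleles[parent, pick, np.arange(n_reps)]

    A_est = np.zeros((n, n))
    A_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                # self: A_ii = 1 + P(the two alleles IBD)
                x = 1.0 + (alleles[i, 0] == alleles[i, 1]).astype(float)
            else:
                x = 0.5 * (
                    (alleles[i, 0] == alleles[j, 0]).astype(float)
                    + (alleles[i, 0] == alleles[j, 1])
                    + (alleles[i, 1] == alleles[j, 0])
                    + (alleles[i, 1] == alleles[j, 1])
                )
            A_est[i, j] = A_est[j, i] = x.mean()
            A_se[i, j] = A_se[j, i] = x.std(ddof=1) / np.sqrt(n_reps)
    return A_est, A_se


def brute_force_edits(
    df: pd.DataFrame, min_group: int, max_sweeps: int = 1000
) -> pd.DataFrame:
    """Fixed point of the group-minimum edits by repeated full rescans.

    ``df`` needs columns cow_id, hys, hpm. Each sweep recomputes, from
    scratch, distinct-cow counts per HPM group (dropping offending records)
    and per HYS group (dropping offending cows entirely), until stable.
    """
    cur = df.copy()
    for _ in range(max_sweeps):
        before = len(cur)
        counts = cur.groupby("hpm")["cow_id"].nunique()
        ok_hpm = set(counts[counts >= min_group].index)
        cur = cur[cur["hpm"].isin(ok_hpm)]
        if len(cur):
            counts = cur.groupby("hys")["cow_id"].nunique()
            ok_hys = set(counts[counts >= min_group].index)
            cur = cur[cur["hys"].isin(ok_hys)]
        if len(cur) == before:
            return cur
    raise RuntimeError("edits oracle did not reach a fixed point")


def anova_one_way(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (group variance, residual variance) for balanced data."""
    df = pd.DataFrame({"y": y, "g": groups})
    means = df.groupby("g")["y"].mean()
    counts = df.groupby("g")["y"].count()
    assert counts.nunique() == 1, "oracle expects balanced groups"
    n_per = int(counts.iloc[0])
    k = len(means)
    grand = df["y"].mean()
    ms_between = n_per * ((means - grand) ** 2).sum() / (k - 1)
    sse = ((df["y"] - df["g"].map(means)) ** 2).sum()
    ms_within = sse / (k * (n_per - 1))
    return (ms_between - ms_within) / n_per, ms_within


def grid_posterior_repeated(
    y: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    W: np.ndarray,
    prior_a: tuple[float, float],
    prior_pe: tuple[float, float],
    prior_e: tuple[float, float],
    grid: np.ndarray,
) -> dict:
    """Numerical posterior for y = mu + Z a + W pe + e (tiny systems).

    Same construction as :func:`grid_posterior_trio` but with a permanent
    environmental term, integrated over a 3-D variance grid.
    """
    n = len(y)
    X = np.ones((n, 1))
    ZAZ = Z @ A @ Z.T
    WW = W @ W.T
    eye = np.eye(n)

    def logprior(nu, s2, v):
        return -(nu / 2 + 1) * np.log(v) - nu * s2 / (2 * v)

    dg = np.gradient(grid)
    g = len(grid)
    log_w = np.full((g, g, g), -np.inf)
    cond_a = np.zeros((g, g, g, A.shape[0]))
    for ia, sa in enumerate(grid):
        for ip, sp in enumerate(grid):
            for ie, se in enumerate(grid):
                V = sa * ZAZ + sp * WW + se * eye
                Vi = np.linalg.inv(V)
                XtViX = X.T @ Vi @ X
                P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
                _, ldv = np.linalg.slogdet(V)
                _, ldx = np.linalg.slogdet(XtViX)
                log_w[ia, ip, ie] = (
                    -0.5 * (ldv + ldx + y @ P @ y)
                    + logprior(*prior_a, sa)
                    + logprior(*prior_pe, sp)
                    + logprior(*prior_e, se)
                )
                cond_a[ia, ip, ie] = sa * (A @ Z.T) @ P @ y
    log_w -= log_w.max()
    w = np.exp(log_w) * (dg[:, None, None] * dg[None, :, None] * dg[None, None, :])
    w /= w.sum()
    return {
        "sigma2_a": float((w.sum(axis=(1, 2)) * grid).sum()),
        "sigma2_pe": float((w.sum(axis=(0, 2)) * grid).sum()),
        "sigma2_e": float((w.sum(axis=(0, 1)) * grid).sum()),
        "a": (w[..., None] * cond_a).sum(axis=(0, 1, 2)),
    }


def grid_posterior_trio(
    y: np.ndarray,
    Z: np.ndarray,
    A: np.ndarray,
    prior_a: tuple[float, float],
    prior_e: tuple[float, float],
    grid: np.ndarray,
) -> dict:
    """Numerical posterior for y = mu + Z a + e on a tiny pedigree.

    Flat prior on mu, scaled-inverse-chi-square (nu, S2) priors on the two
    variances. Location effects are integrated analytically per grid cell
    (Gaussian algebra); the 2-D variance grid is integrated numerically.
    Returns posterior means of both variances and of each additive effect.
    """
    n = len(y)
    X = np.ones((n, 1))
    nu_a, s2_a = prior_a
    nu_e, s2_e = prior_e

    log_w = np.full((len(grid), len(grid)), -np.inf)
    cond_a = np.zeros((len(grid), len(grid), A.shape[0]))
    for ia, sa in enumerate(grid):
        for ie, se in enumerate(grid):
            V = sa * (Z @ A @ Z.T) + se * np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
            # log marginal of y after integrating mu (flat) and a
            _, logdet_v = np.linalg.slogdet(V)
            _, logdet_x = np.linalg.slogdet(XtViX)
            ll = -0.5 * (logdet_v + logdet_x + y @ P @ y)
            lp = (
                -(nu_a / 2 + 1) * np.log(sa)
                - nu_a * s2_a / (2 * sa)
                - (nu_e / 2 + 1) * np.log(se)
                - nu_e * s2_e / (2 * se)
            )
            log_w[ia, ie] = ll + lp
            cond_a[ia, ie] = sa * (A @ Z.T) @ P @ y

    log_w -= log_w.max()
    w = np.exp(log_w)
    # integration measure: cell widths for the (possibly log-spaced) grid
    dg = np.gradient(grid)
    w *= dg[:, None] * dg[None, :]
    w /= w.sum()
    sa_mean = float((w.sum(axis=1) * grid).sum())
    se_mean = float((w.sum(axis=0) * grid).sum())
    a_mean = (w[:, :, None] * cond_a).sum(axis=(0, 1))
    return {"sigma2_a": sa_mean, "sigma2_e": se_mean, "a": a_mean}
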