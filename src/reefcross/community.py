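"""Community statistics for the symbiont OTU table.

Median-of-ratios size factors and a shifted-log variance-stabilizing
transform, per-OTU negative-binomial Wald tests of differential abundance
between mortality classes with Benjamini-Hochberg adjustment, Chao1 richness,
Bray-Curtis dissimilarities, non-metric multidimensional scaling (SMACOF with
isotonic regression on dissimilarity ranks, Kruskal stress-1) and one-way
PERMANOVA with a permutation p value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.optimize import isotonic_regression
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "size_factors_median_ratio",
    "shifted_log",
    "nb_wald_da",
    "chao1",
    "bray_curtis",
    "nmds",
    "permanova",
    "OrdinationResult",
    "PermanovaResult",
]

LN2 = float(np.log(2.0))


def _counts_matrix(counts) -> np.ndarray:
    if isinstance(counts, CountTable):
        return counts.counts.astype(float)
    return np.asarray(counts, dtype=float)


def size_factors_median_ratio(counts) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    The pseudo-reference is the per-OTU geometric mean across samples,
    computed over OTUs with all-positive counts; each sample's factor is the
    median ratio of its counts to the reference over those OTUs, rescaled so
    the factors have geometric mean one.  When no OTU is positive everywhere
    a modified geometric mean over positive entries is used, with a warning.
    """
    mat = _counts_matrix(counts)  # OTUs x samples
    if np.any(mat.sum(axis=0) == 0):
        raise ValueError("every sample needs at least one nonzero count")
    all_pos = np.all(mat > 0, axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        warnings.warn(
            "no OTU detected in every sample; using modified geometric mean "
            "over positive entries",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logs = np.where(mat > 0, np.log(mat), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(mat > 0, mat / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def shifted_log(counts, size_factors, shift: float = 1.0) -> np.ndarray:
    """log2(count / size_factor + shift); the default shift is one count."""
    if shift <= 0:
        raise ValueError("shift must be positive")
    mat = _counts_matrix(counts)
    sf = np.asarray(size_factors, dtype=float)
    return np.log2(mat / sf[None, :] + shift)


def _mom_alpha(y, mu) -> float:
    """Method-of-moments NB2 alpha (variance = mu + alpha mu^2), floored."""
    resid = np.sum((y - mu) ** 2 / mu) - len(y)
    denom = np.sum(mu)
    return float(max(resid / denom, 1e-6)) if denom > 0 else 1e-6


def nb_wald_da(
    counts,
    condition,
    contrast: tuple[str, str] = ("high", "low"),
    size_factors=None,
    min_nonzero: int = 2,
) -> pd.DataFrame:
    """Per-OTU negative-binomial Wald tests between two condition levels.

    Each OTU is modelled as NB with a log link on the two-level condition,
    log size factors as offsets, and a per-OTU dispersion estimated by
    maximum likelihood (method-of-moments fallback, flagged in the
    ``dispersion_converged`` column).  The Wald statistic uses a
    small-sample correction: the dispersion is degrees-of-freedom adjusted
    (times n/(n-2)) and the p value is referred to a t distribution on
    n-2 degrees of freedom.  The log2 fold change is reported for
    ``contrast[0]`` relative to ``contrast[1]``; p values are BH-adjusted
    across the tested OTUs.  OTUs detected in fewer than ``min_nonzero``
    samples are excluded (``tested`` False, all statistics NaN).
    """
    table = counts if isinstance(counts, CountTable) else None
    mat = _counts_matrix(counts)
    otu_ids = table.otu_ids if table is not None else [f"OTU{i+1}" for i in range(mat.shape[0])]
    condition = np.asarray(condition, dtype=object)
    if mat.shape[1] != len(condition):
        raise ValueError("condition length must match the number of samples")
    lv_a, lv_b = contrast
    keep_samples = np.isin(condition, [lv_a, lv_b])
    mat = mat[:, keep_samples]
    condition = condition[keep_samples]
    for lv in (lv_a, lv_b):
        if np.sum(condition == lv) < 2:
            raise ValueError(f"need >= 2 samples in level {lv!r}")
    if size_factors is None:
        size_factors = size_factors_median_ratio(mat)
    else:
        size_factors = np.asarray(size_factors, dtype=float)[keep_samples]
    offset = np.log(size_factors)
    x = (condition == lv_a).astype(float)
    X = sm.add_constant(x)

    rows = []
    for i, otu in enumerate(otu_ids):
        y = mat[i]
        tested = int(np.count_nonzero(y)) >= min_nonzero
        if not tested:
            rows.append(
                {"otu_id": otu, "tested": False, "log2_fold_change": np.nan,
                 "standard_error": np.nan, "wald_p": np.nan,
                 "dispersion": np.nan, "dispersion_converged": False}
            )
            continue
        alpha = np.nan
        ml_ok = False
        n_s = len(y)
        df_resid = n_s - 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                ml = sm.NegativeBinomial(y, X, offset=offset).fit(
                    disp=0, maxiter=200, method="bfgs", gtol=1e-6
                )
                if ml.mle_retvals.get("converged", False) and np.all(
                    np.isfinite(ml.bse[:2])
                ):
                    alpha = float(ml.params[-1])  # statsmodels stores alpha itself
                    ml_ok = alpha > 0 and np.isfinite(alpha)
            except Exception:
                ml_ok = False
            if not ml_ok:
                # moment dispersion from a Poisson fit as fallback
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                alpha = _mom_alpha(y, pois.mu)
            # small-sample Wald: degrees-of-freedom correction of the ML
            # dispersion, SE from the fixed-dispersion GLM, t reference
            alpha_adj = max(alpha * n_s / df_resid, 1e-6)
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha_adj),
                offset=offset,
            ).fit()
            coef, se = float(glm.params[1]), float(glm.bse[1])
        z = coef / se if se > 0 else np.nan
        from scipy import stats as sps

        p = 2.0 * sps.t.sf(abs(z), df_resid) if np.isfinite(z) else np.nan
        rows.append(
            {"otu_id": otu, "tested": True, "log2_fold_change": coef / LN2,
             "standard_error": se / LN2, "wald_p": p,
             "dispersion": alpha, "dispersion_converged": ml_ok}
        )
    res = pd.DataFrame(rows)
    res["p_adj"] = np.nan
    tested_mask = res["tested"] & res["wald_p"].notna()
    if tested_mask.any():
        res.loc[tested_mask, "p_adj"] = multipletests(
            res.loc[tested_mask, "wald_p"].to_numpy(), method="fdr_bh"
        )[1]
    if table is not None and table.otu_annotation:
        res["clade"] = res["otu_id"].map(table.otu_annotation)
    return res


def chao1(sample_counts) -> float:
    """Chao1 richness from one sample's OTU counts.

    ``S_obs + f1^2 / (2 f2)`` with singleton/doubleton counts f1/f2; the
    bias-corrected form ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))`` is used when
    there are no doubletons.  An empty sample has richness zero.
    """
    y = np.asarray(sample_counts)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    s_obs = int(np.count_nonzero(y))
    if s_obs == 0:
        return 0.0
    f1 = int(np.sum(y == 1))
    f2 = int(np.sum(y == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def bray_curtis(values) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix for a samples x OTUs matrix."""
    mat = np.asarray(values, dtype=float)
    if np.any(mat < 0):
        raise ValueError("Bray-Curtis needs non-negative values")
    zero_rows = np.where(mat.sum(axis=1) == 0)[0]
    if len(zero_rows) > 1:
        warnings.warn(
            "all-zero samples present; their mutual distance is defined as 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(mat, metric="braycurtis"))
    d[np.isnan(d)] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    stress_history: list[float] = None


def _stress1(dhat, dconf) -> float:
    denom = np.sum(dconf**2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((dhat - dconf) ** 2) / denom))


def nmds(
    dist,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Iterative majorization (SMACOF) alternates a Guttman update of the
    configuration with monotone (isotonic) regression of the configuration
    distances on the rank order of the observed dissimilarities; the best of
    ``n_starts`` random starts is kept, centred and rotated to principal
    axes.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("need a square symmetric distance matrix")
    if n < k + 2:
        raise ValueError("too few samples for the requested dimension")
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    best = None
    best_stress = np.inf
    best_converged = False
    best_history: list[float] = []
    for _ in range(n_starts):
        Xc = rng.normal(size=(n, k)) * np.max(delta)
        prev = np.inf
        prev_X = Xc
        converged = False
        history: list[float] = []
        for _ in range(max_iter):
            dconf = squareform(pdist(Xc))[iu]
            # monotone regression of configuration distances on rank of delta;
            # disparities rescaled to the configuration's sum of squares so the
            # Guttman step cannot shrink the configuration toward collapse
            dhat = np.empty_like(dconf)
            dhat[order] = isotonic_regression(dconf[order]).x
            ss = np.sum(dhat**2)
            if ss > 0:
                dhat *= np.sqrt(np.sum(dconf**2) / ss)
            stress = _stress1(dhat, dconf)
            if stress > prev:  # keep the best iterate
                Xc, stress = prev_X, prev
                converged = True
                break
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev, prev_X = stress, Xc
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dconf > 0, dhat / dconf, 0.0)
            B = np.zeros((n, n))
            B[iu] = -ratio
            B = B + B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            Xc = (B @ Xc) / n
        if stress < best_stress:
            best_stress = stress
            best = Xc.copy()
            best_converged = converged
            best_history = history
    best = best - best.mean(axis=0)
    # principal-axis rotation for a reproducible orientation
    _, _, vt = np.linalg.svd(best, full_matrices=False)
    best = best @ vt.T
    if not best_converged:
        warnings.warn("NMDS best start did not converge", stacklevel=2)
    if best_stress < 1e-3:
        warnings.warn(
            "nearly zero stress: groups may be perfectly separable, making "
            "the non-metric configuration degenerate",
            stacklevel=2,
        )
    return OrdinationResult(coordinates=best, stress=best_stress,
                            converged=best_converged,
                            stress_history=best_history)


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    df: tuple[int, int]
    n_permutations: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, levels) -> float:
    ss = 0.0
    for lv in levels:
        idx = np.where(labels == lv)[0]
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def permanova(
    dist, grouping, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the sum of squared distances between and within groups; the
    pseudo-F is compared against random relabelings and
    ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(grouping, dtype=object)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix and grouping sizes differ")
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2 or n < 3:
        raise ValueError("need >= 2 groups and >= 3 samples")
    if (counts == 1).any():
        warnings.warn("groups with a single sample present", stacklevel=2)
    d2 = D**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = _ss_within(d2, labels, levels)
    ss_between = ss_total - ss_within
    df_b, df_w = len(levels) - 1, n - len(levels)
    f_obs = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssw = _ss_within(d2, labels[perm], levels)
        ssb = ss_total - ssw
        f_perm = (ssb / df_b) / (ssw / df_w) if ssw > 0 else np.inf
        if f_perm >= f_obs - 1e-12:
            count_ge += 1
    p = (1.0 + count_ge) / (n_perm + 1.0)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        r2=float(r2), pseudo_f=float(f_obs), p=float(p),
        df=(df_b, df_w), n_permutations=n_perm,
    )
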