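"""Variance partitioning of settlement and juvenile survival, and the
cross-stage maternal-contribution propagation.

The settlement model is a log-link Poisson GLMM with crossed random
intercepts for dam, sire and their interaction plus an observation-level
random effect for overdispersion.  The survival model is a negative-binomial
GLMM with settlement count as a fixed covariate and parental identity as
random effects; when sire and interaction variances collapse to zero the
model is refitted without them and the refits are compared by AICc.

Latent-scale variance shares follow an ICC-style decomposition: the total is
the variance of the fitted fixed-effect predictor (when a covariate is
present) plus the random-intercept variances plus a distribution-level
residual — ``ln(1 + 1/exp(mean eta))`` for Poisson and
``ln(1 + 1/mean_mu + 1/theta)`` for NB2, the usual log-normal
approximations to count noise on the log scale.

Maternal contribution to juvenile survival combines the direct dam share of
survival variability with the carry-on share transmitted through settlement
(the dam share of settlement times the settlement share of survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breeding import round_percent
from .mixedglm import MixedModelFit, RandomTerm, fit_mixed_glm, indicator_matrix

__all__ = [
    "VarianceDecomposition",
    "MaternalContribution",
    "fit_settlement_model",
    "fit_survival_model",
    "partition_variance",
    "propagate_maternal",
    "deviation_contrasts",
]


@dataclass
class VarianceDecomposition:
    """Percent-of-total latent variance per component.

    ``component_shares`` covers every random term (including the
    observation-level effect); ``random_within`` re-expresses each random
    component as a percent of the combined random share.
    """

    component_shares: dict[str, float]
    combined_random_share: float
    residual_share: float
    fixed_share: float | None = None
    random_within: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "component_shares": self.component_shares,
            "combined_random_share": self.combined_random_share,
            "residual_share": self.residual_share,
            "fixed_share": self.fixed_share,
            "random_within": self.random_within,
        }
        return out


@dataclass
class MaternalContribution:
    direct_percent: float
    indirect_percent: float
    total_percent: float


def _design_terms(data: pd.DataFrame, which=("dam", "sire", "dam_x_sire")):
    terms = []
    if "dam" in which:
        Z, _ = indicator_matrix(data["dam_id"])
        terms.append(RandomTerm("dam", Z))
    if "sire" in which:
        Z, _ = indicator_matrix(data["sire_id"])
        terms.append(RandomTerm("sire", Z))
    if "dam_x_sire" in which:
        Z, _ = indicator_matrix(data["family_id"])
        terms.append(RandomTerm("dam_x_sire", Z))
    return terms


def fit_settlement_model(life: pd.DataFrame, design=None) -> MixedModelFit:
    """Poisson-OLRE GLMM of settlement counts on dam, sire and interaction.

    ``life`` needs columns family_id, dam_id, sire_id, settled (one row per
    culture replicate); rows whose culture died are excluded when a
    culture_alive column is present.
    """
    data = life.copy()
    if "culture_alive" in data.columns:
        data = data[data["culture_alive"].astype(int) == 1]
    if data["dam_id"].nunique() < 2 or data["sire_id"].nunique() < 2:
        raise ValueError("need at least two dams and two sires")
    y = data["settled"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    terms = _design_terms(data)
    return fit_mixed_glm(
        y, X, terms, family="poisson", olre=True,
        fixed_names=["intercept"], compute_beta_cov=False,
    )


def fit_survival_model(
    life: pd.DataFrame,
    design=None,
    drop_null_terms: bool = True,
    null_var: float = 1e-4,
) -> MixedModelFit:
    """NB GLMM of juvenile survivors on settlement plus parental identity.

    ``life`` is aggregated to one row per family (survivors and settlers
    summed over replicates); families with no settlers are excluded.  With
    ``drop_null_terms`` the model is refitted without sire and interaction
    when their variance estimates collapse to (approximately) zero, and the
    refit is kept when AICc does not disfavour it.
    """
    fam = life.groupby("family_id", sort=False).agg(
        dam_id=("dam_id", "first"),
        sire_id=("sire_id", "first"),
        settled=("settled", "sum"),
        survived=("survived", "sum"),
    ).reset_index()
    fam = fam[fam["settled"] > 0].reset_index(drop=True)
    y = fam["survived"].to_numpy(dtype=float)
    settled = fam["settled"].to_numpy(dtype=float)
    # standardize the covariate internally for numerical stability
    s_mean, s_sd = settled.mean(), settled.std()
    s_sd = s_sd if s_sd > 0 else 1.0
    X = np.column_stack([np.ones(len(y)), (settled - s_mean) / s_sd])

    def _fit(which):
        terms = _design_terms(fam, which)
        return fit_mixed_glm(
            y, X, terms, family="negative_binomial",
            fixed_names=["intercept", "settled_std"],
        )

    fit = _fit(("dam", "sire", "dam_x_sire"))
    if drop_null_terms:
        null_terms = [
            nm for nm in ("sire", "dam_x_sire")
            if fit.random_variances.get(nm, 0.0) < null_var
        ]
        if null_terms:
            keep = tuple(
                nm for nm in ("dam", "sire", "dam_x_sire") if nm not in null_terms
            )
            refit = _fit(keep)
            if refit.aicc <= fit.aicc + 2.0:
                fit = refit
    # rescale the slope back to the raw settlement scale
    est, se = fit.fixed_effects["settled_std"]
    fit.fixed_effects["settled"] = (est / s_sd, se / s_sd)
    return fit


def _residual_latent_variance(fit: MixedModelFit) -> float:
    if fit.family.startswith("poisson"):
        return float(np.log1p(1.0 / np.exp(fit.mean_linear_predictor)))
    return float(np.log1p(1.0 / fit.mean_mu + 1.0 / fit.nb_dispersion))


def partition_variance(fit: MixedModelFit) -> VarianceDecomposition:
    """Percent-of-total latent variance for every model component."""
    if not fit.converged:
        raise ValueError("refusing to partition a non-converged fit")
    random_vars = dict(fit.random_variances)
    resid = _residual_latent_variance(fit)
    fixed = fit.fixed_predictor_variance if len(fit.fixed_names) > 1 else None
    total = sum(random_vars.values()) + resid + (fixed or 0.0)
    if total <= 1e-12:
        raise ValueError("total latent variance is zero; shares undefined")
    shares = {k: 100.0 * v / total for k, v in random_vars.items()}
    combined = sum(shares.values())
    within = (
        {k: 100.0 * s / combined for k, s in shares.items()} if combined > 0 else {}
    )
    return VarianceDecomposition(
        component_shares=shares,
        combined_random_share=combined,
        residual_share=100.0 * resid / total,
        fixed_share=(100.0 * fixed / total) if fixed is not None else None,
        random_within=within,
    )


def propagate_maternal(
    direct_percent: float,
    upstream_stage_share: float,
    upstream_maternal_share: float,
    indirect_percent: float | None = None,
) -> MaternalContribution:
    """Total maternal contribution to survival: direct plus carry-on.

    The carry-on (indirect) component is the maternal share of the upstream
    stage times the share of survival variability that the upstream stage
    explains, both in percent.  ``indirect_percent`` overrides the product
    when an unrounded upstream value was used to compute it elsewhere.
    Components are rounded to one decimal before summing, matching how such
    percentages are reported.
    """
    for v in (direct_percent, upstream_stage_share, upstream_maternal_share):
        if not (0.0 <= v <= 100.0):
            raise ValueError("percent inputs must lie in [0, 100]")
    if indirect_percent is None:
        indirect_percent = upstream_maternal_share * upstream_stage_share / 100.0
    direct = round_percent(direct_percent)
    indirect = round_percent(indirect_percent)
    return MaternalContribution(
        direct_percent=direct,
        indirect_percent=indirect,
        total_percent=round_percent(direct + indirect),
    )


def _deviation_code(labels) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k-1 columns, last level = -1 row."""
    labels = np.asarray(labels)
    levels = sorted(dict.fromkeys(labels.tolist()))
    k = len(levels)
    X = np.zeros((len(labels), k - 1))
    index = {lv: j for j, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        j = index[lab]
        if j < k - 1:
            X[i, j] = 1.0
        else:
            X[i, :] = -1.0
    return X, levels


def deviation_contrasts(
    life: pd.DataFrame,
    focal_factor: str = "dam",
    response: str = "settled",
) -> pd.DataFrame:
    """Per-level deviations of the focal parent from the grand mean.

    Refits the settlement model with the focal factor fixed and
    deviation-coded (each level contrasted against the grand mean), keeping
    the other parent, the interaction and the observation-level effect
    random.  Returns one row per level with the log-scale estimate, its
    standard error and a Wald p value; the estimates sum to zero across
    levels by construction of the coding.
    """
    if focal_factor not in ("dam", "sire"):
        raise ValueError("focal_factor must be 'dam' or 'sire'")
    data = life.copy()
    if "culture_alive" in data.columns:
        data = data[data["culture_alive"].astype(int) == 1]
    col = f"{focal_factor}_id"
    labels = data[col]
    if labels.nunique() < 3:
        raise ValueError("focal factor needs at least three levels")
    singles = labels.value_counts()
    if (singles == 1).any():
        import warnings

        warnings.warn(
            "focal levels with a single observation yield wide intervals",
            stacklevel=2,
        )
    Xdev, levels = _deviation_code(labels)
    X = np.column_stack([np.ones(len(data)), Xdev])
    other = "sire" if focal_factor == "dam" else "dam"
    terms = _design_terms(data, (other, "dam_x_sire"))
    y = data[response].to_numpy(dtype=float)
    fit = fit_mixed_glm(
        y, X, terms, family="poisson", olre=True,
        fixed_names=["intercept"] + [f"dev_{lv}" for lv in levels[:-1]],
        compute_beta_cov=True,
    )
    beta = fit.beta
    cov = fit.beta_cov
    from scipy import stats

    rows = []
    k = len(levels)
    for j, lv in enumerate(levels):
        if j < k - 1:
            est = beta[1 + j]
            var = cov[1 + j, 1 + j] if cov is not None else np.nan
        else:  # last level is minus the sum of the others
            c = np.zeros(len(beta))
            c[1:] = -1.0
            est = float(c @ beta)
            var = float(c @ cov @ c) if cov is not None else np.nan
        se = np.sqrt(var) if var == var and var >= 0 else np.nan
        z = est / se if se and se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if z == z else np.nan
        rows.append({"level": lv, "estimate": float(est), "se": float(se), "p": float(p)})
    return pd.DataFrame(rows)
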