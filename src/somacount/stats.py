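"""Genotype statistics on regional cell counts and volumes.

The central comparison is a per-composite-region negative-binomial GLM of
cell counts on genotype (log link, wild type as reference).  Exponentiated
coefficients are rate ratios — the multiplicative change in expected count
relative to the reference; p-values are Benjamini–Hochberg adjusted across
regions within a contrast family and reported as log worth,
``-log10(FDR p)``, for volcano plots.  Supporting analyses: a mixed model on
log10 major-region mean cell volumes (random intercept per animal), two-way
Ward clustering of the animal x region count matrix, and co-labeling
efficiency summaries with Tukey box-whisker statistics and a four-bin
classification.

The NB parameterization throughout is NB2 with dispersion theta:
``variance = mu + mu^2 / theta`` (theta -> inf recovers Poisson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

ALPHA_DEFAULT = 0.01
#: theta above this cap is reported as the Poisson limit.
THETA_POISSON_CAP = 1e7


# ---------------------------------------------------------------------------
# Negative-binomial GLM
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    """Maximum-likelihood NB2 regression fit with a log link.

    ``coefficients`` are on the log scale: intercept (log reference mean)
    followed by one contrast per non-reference genotype, in ``group_order``.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    theta: float
    wald_p: np.ndarray
    log_likelihood: float
    converged: bool
    group_order: list[str]
    reference: str
    df_resid: int = 0
    flags: list[str] = field(default_factory=list)  # 'separated', 'poisson_limit'

    def rate_ratio(self, genotype: str) -> float:
        i = self.group_order.index(genotype)
        return float(np.exp(self.coefficients[i + 1]))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood; the Poisson limit is used above the theta cap."""
    if theta >= THETA_POISSON_CAP:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _irls_beta(
    y: np.ndarray, X: np.ndarray, theta: float, beta: np.ndarray,
    tol: float = 1e-10, max_iter: int = 100,
) -> np.ndarray:
    """IRLS for beta at fixed theta (log link, NB2 working weights mu/(1+mu/theta))."""
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def fit_nb_glm(
    counts: Sequence[int],
    genotype: Sequence[str],
    reference: str = "WT",
) -> NBFit:
    """Fit counts ~ genotype by NB2 maximum likelihood, reference-coded.

    Alternates IRLS for the coefficients at fixed theta with a profile
    maximization of theta (golden-section on log theta) until the joint
    log-likelihood change falls below 1e-8 (at most 100 outer iterations).
    For this group-indicator design the fitted group means equal the sample
    group means whatever theta is, so convergence is fast and exact.

    Inference is Wald with a small-sample t reference distribution
    (``df = n - p`` residual degrees of freedom) rather than the asymptotic
    normal: with the few animals per genotype these studies run, plug-in
    estimation of theta makes normal-quantile tail p-values anticonservative,
    which inflates false discoveries after FDR adjustment.

    A genotype group whose counts are all zero makes its contrast diverge;
    the fit is flagged ``separated`` with a ``-inf`` sentinel coefficient and
    should be excluded from downstream volcano tables.  theta estimates above
    ``THETA_POISSON_CAP`` are flagged ``poisson_limit`` and inference uses
    Poisson weights.
    """
    y = np.asarray(counts, dtype=float)
    geno = np.asarray(genotype, dtype=object)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    groups = [reference] + sorted(g for g in pd.unique(geno) if g != reference)
    if reference not in geno:
        raise ValueError(f"reference genotype {reference!r} absent from data")
    if len(groups) < 2:
        raise ValueError("need at least two genotype groups")
    contrast_order = groups[1:]
    X = np.ones((len(y), len(groups)))
    for j, g in enumerate(contrast_order, start=1):
        X[:, j] = (geno == g).astype(float)

    group_sums = {g: y[geno == g].sum() for g in groups}
    separated = [g for g in groups if group_sums[g] == 0]
    flags: list[str] = []
    if separated:
        flags.append("separated")
        coef = np.full(len(groups), np.nan)
        se = np.full(len(groups), np.nan)
        means = {g: y[geno == g].mean() for g in groups}
        coef[0] = math.log(means[reference]) if means[reference] > 0 else -math.inf
        for j, g in enumerate(contrast_order, start=1):
            if means[g] == 0 or means[reference] == 0:
                coef[j] = -math.inf if means[g] == 0 else math.inf
            else:
                coef[j] = math.log(means[g] / means[reference])
        return NBFit(
            coefficients=coef, standard_errors=se, theta=math.nan,
            wald_p=np.full(len(groups), np.nan), log_likelihood=-math.inf,
            converged=False, group_order=contrast_order, reference=reference,
            flags=flags,
        )

    # initialize at Poisson MLE (= log group means for the indicator design)
    means0 = np.maximum(y.mean(), 0.5) * np.ones(len(y))
    beta = np.zeros(len(groups))
    beta[0] = math.log(means0[0])
    theta = 10.0
    ll_old = -np.inf
    converged = False
    for _ in range(100):
        beta = _irls_beta(y, X, theta, beta)
        mu = np.exp(X @ beta)

        def neg_ll(log_theta: float) -> float:
            return -_nb_loglik(y, mu, math.exp(log_theta))

        res = optimize.minimize_scalar(neg_ll, bounds=(-7.0, 18.0), method="bounded",
                                       options={"xatol": 1e-10})
        theta = math.exp(res.x)
        ll = _nb_loglik(y, mu, theta)
        if abs(ll - ll_old) < 1e-8:
            converged = True
            break
        ll_old = ll

    if theta > THETA_POISSON_CAP * math.exp(-1):  # hit the profile upper bound
        flags.append("poisson_limit")
        theta = math.inf
        w = np.exp(X @ beta)
    else:
        mu = np.exp(X @ beta)
        w = mu / (1.0 + mu / theta)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    df_resid = len(y) - X.shape[1]
    if df_resid > 0:
        wald_p = 2.0 * sps.t.sf(np.abs(zvals), df_resid)
    else:
        wald_p = 2.0 * sps.norm.sf(np.abs(zvals))
    mu = np.exp(X @ beta)
    ll = _nb_loglik(y, mu, theta if math.isfinite(theta) else THETA_POISSON_CAP)
    return NBFit(
        coefficients=beta, standard_errors=se, theta=theta, wald_p=wald_p,
        log_likelihood=ll, converged=converged, group_order=contrast_order,
        reference=reference, df_resid=df_resid, flags=flags,
    )


# ---------------------------------------------------------------------------
# FDR, rate-ratio and volcano tables
# ---------------------------------------------------------------------------

def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (with monotonicity)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def rate_ratio_table(
    fits: Mapping[int, NBFit],
    alpha: float = ALPHA_DEFAULT,
    ci_level: float = 0.95,
    major_of: Mapping[int, int] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Rate ratios with Wald CIs, one BH family per genotype contrast.

    Returns ``(table, exclusions)``: one row per (region, contrast) with
    ``rate_ratio, ci_low, ci_high, p, fdr_p, log_worth, significant``;
    separated fits are excluded from the family and listed in ``exclusions``.
    FDR adjustment runs across regions separately for each contrast genotype.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    exclusions = []
    for region, fit in fits.items():
        if "separated" in fit.flags:
            exclusions.append({"region_id": region, "reason": "separated"})
            continue
        if fit.df_resid > 0:
            zcrit = sps.t.ppf(0.5 + ci_level / 2.0, fit.df_resid)
        else:
            zcrit = sps.norm.ppf(0.5 + ci_level / 2.0)
        for j, g in enumerate(fit.group_order, start=1):
            beta, se = fit.coefficients[j], fit.standard_errors[j]
            rows.append(
                {
                    "region_id": region,
                    "contrast": g,
                    "rate_ratio": math.exp(beta),
                    "ci_low": math.exp(beta - zcrit * se),
                    "ci_high": math.exp(beta + zcrit * se),
                    "p": fit.wald_p[j],
                    "theta": fit.theta,
                }
            )
    table = pd.DataFrame(
        rows, columns=["region_id", "contrast", "rate_ratio", "ci_low", "ci_high", "p", "theta"]
    )
    if not table.empty:
        table["fdr_p"] = np.nan
        for g in table["contrast"].unique():
            mask = table["contrast"] == g
            table.loc[mask, "fdr_p"] = bh_fdr(table.loc[mask, "p"].to_numpy())
        with np.errstate(divide="ignore"):
            table["log_worth"] = -np.log10(table["fdr_p"])
        table["significant"] = table["fdr_p"] <= alpha
    else:
        for col in ("fdr_p", "log_worth", "significant"):
            table[col] = pd.Series(dtype=float if col != "significant" else bool)
    if major_of is not None and not table.empty:
        table["major_region"] = table["region_id"].map(lambda r: major_of.get(int(r), -1))
    return table.reset_index(drop=True), exclusions


def volcano_table(results: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> tuple[pd.DataFrame, dict]:
    """Volcano-plot table plus reference-line metadata.

    Points are (rate_ratio, log_worth) per composite region, colourable by
    major region; the metadata carries the dashed reference lines at rate
    ratio 1 (no change) and log worth ``-log10(alpha)`` (significance).
    """
    cols = ["region_id", "major_region", "contrast", "rate_ratio", "log_worth", "significant"]
    if results.empty:
        return pd.DataFrame(columns=cols), {
            "rate_ratio_line": 1.0, "log_worth_line": -math.log10(alpha)
        }
    out = results.copy()
    if "major_region" not in out.columns:
        out["major_region"] = -1
    meta = {"rate_ratio_line": 1.0, "log_worth_line": -math.log10(alpha)}
    return out[cols].reset_index(drop=True), meta


# ---------------------------------------------------------------------------
# Mixed model on log10 volumes
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    fixed_effects: pd.Series
    random_intercept_var: float
    residual_var: float
    interaction_lrt: float
    interaction_df: int
    interaction_p: float
    converged: bool


def fit_volume_mixed_model(table: pd.DataFrame) -> MixedModelResult:
    """Mixed model on per-animal major-region mean log10 cell volumes.

    ``table`` needs columns ``animal_id, genotype, region_id,
    mean_log10_volume``.  Fixed effects: genotype, major region and their
    interaction; random intercept per animal absorbs within-animal
    correlation across regions.  The interaction (does the genotype effect on
    soma volume differ by region?) is tested by a likelihood-ratio test of ML
    fits with vs without the interaction term.
    """
    import statsmodels.formula.api as smf

    required = {"animal_id", "genotype", "region_id", "mean_log10_volume"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = table.copy()
    df["genotype"] = df["genotype"].astype(str)
    df["region"] = df["region_id"].astype(str)
    if df["genotype"].nunique() < 2 or df["region"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 major regions")
    counts = df.groupby("region")["mean_log10_volume"].count()
    if (counts < 2).any():
        raise ValueError("singular design: a region with fewer than 2 observations")

    import warnings

    def _fit(formula: str):
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return smf.mixedlm(formula, df, groups=df["animal_id"]).fit(
                        reml=False, method=method, maxiter=500, disp=False
                    )
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        raise RuntimeError(f"mixed-model fit failed for {formula!r}") from last_exc

    full = _fit("mean_log10_volume ~ genotype * region")

    # Degenerate zero-residual designs break the likelihood comparison (llf
    # diverges); fall back on exact OLS residuals to decide the interaction.
    ols_red = smf.ols("mean_log10_volume ~ genotype + region", df).fit()
    ols_full = smf.ols("mean_log10_volume ~ genotype * region", df).fit()
    tot = max(float(ols_red.centered_tss), 1e-12)
    if ols_red.ssr <= 1e-12 * tot:
        lrt = 0.0  # additive model already perfect: no interaction evidence
    elif ols_full.ssr <= 1e-12 * tot:
        lrt = math.inf  # interaction fits exactly where the additive cannot
    else:
        reduced = _fit("mean_log10_volume ~ genotype + region")
        lrt = 2.0 * (full.llf - reduced.llf)
        if not math.isfinite(lrt):
            lrt = 0.0
    lrt = max(lrt, 0.0)
    dof = (df["genotype"].nunique() - 1) * (df["region"].nunique() - 1)
    # F-calibrated reference: the chi2(dof) approximation is anticonservative
    # at the animal counts these studies run; the monotone F transform of the
    # ML likelihood ratio (exact for fixed-variance linear models) restores
    # null uniformity of the p-value.
    n_obs = len(df)
    p_full = len(full.fe_params)
    with np.errstate(over="ignore"):
        f_stat = (np.exp(lrt / n_obs) - 1.0) * (n_obs - p_full) / dof
    p = float(sps.f.sf(f_stat, dof, n_obs - p_full))
    return MixedModelResult(
        fixed_effects=full.fe_params,
        random_intercept_var=float(np.asarray(full.cov_re).ravel()[0]),
        residual_var=float(full.scale),
        interaction_lrt=float(lrt),
        interaction_df=int(dof),
        interaction_p=p,
        converged=bool(full.converged and reduced.converged),
    )


# ---------------------------------------------------------------------------
# Two-way Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[int]
    col_order: list[int]


def ward_two_way(matrix: np.ndarray, transform: str = "none") -> ClusterResult:
    """Cluster rows (animals) and columns (regions) independently, Ward linkage.

    ``transform='log1p'`` applies log(1+x) first — counts span orders of
    magnitude across regions, and the clustering scale is a config choice.
    Merge heights are non-decreasing (Ward is monotone); leaf orders are the
    scipy dendrogram orders and deterministic.
    """
    M = np.asarray(matrix, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(M).all():
        raise ValueError("matrix contains NaN/inf")
    if transform == "log1p":
        M = np.log1p(M)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    def _link(data: np.ndarray) -> tuple[np.ndarray, list[int]]:
        if data.shape[0] == 1:
            return np.empty((0, 4)), [0]
        Z = hierarchy.linkage(data, method="ward")
        order = hierarchy.leaves_list(Z).tolist()
        return Z, order

    row_Z, row_order = _link(M)
    col_Z, col_order = _link(M.T)
    return ClusterResult(row_Z, col_Z, row_order, col_order)


# ---------------------------------------------------------------------------
# Labeling efficiency
# ---------------------------------------------------------------------------

EFFICIENCY_BINS = ("<10%", "10-50%", "50-75%", "75-100%")


def classify_efficiency(mean_ratio: float) -> str:
    """Four-bin labeling-efficiency class, left-closed bins on [0, 1]."""
    if not 0.0 <= mean_ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {mean_ratio}")
    if mean_ratio < 0.10:
        return EFFICIENCY_BINS[0]
    if mean_ratio < 0.50:
        return EFFICIENCY_BINS[1]
    if mean_ratio < 0.75:
        return EFFICIENCY_BINS[2]
    return EFFICIENCY_BINS[3]


def tukey_box_stats(values: Sequence[float]) -> dict:
    """Tukey box-whisker statistics with 1.5 x IQR fences.

    Quartiles use linear interpolation of order statistics; whiskers are the
    extreme *data values* inside the fences; outliers are the points outside.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise ValueError("need >= 1 finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": outliers.tolist(),
    }


def labeling_efficiency(records: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Co-labeling efficiency summary per region.

    ``records`` columns: ``region, animal_id, slice_id, co_positive, total``
    — counts of reporter+marker double-positive cells and of all
    marker-positive cells in one slice.  Per-record ratios are averaged over
    slices within each animal, then summarized across animals per region
    (mean, Tukey box stats, four-bin class).  Slices with ``total = 0`` carry
    no information and are excluded (returned in the log).
    """
    required = {"region", "animal_id", "slice_id", "co_positive", "total"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = records[records["co_positive"] > records["total"]]
    if not bad.empty:
        raise ValueError("co_positive exceeds total in some records")
    dropped = [
        {"region": r.region, "animal_id": r.animal_id, "slice_id": r.slice_id,
         "reason": "total=0"}
        for r in records[records["total"] == 0].itertuples()
    ]
    usable = records[records["total"] > 0].copy()
    usable["ratio"] = usable["co_positive"] / usable["total"]
    per_animal = (
        usable.groupby(["region", "animal_id"], as_index=False)["ratio"].mean()
    )
    rows = []
    for region, grp in per_animal.groupby("region"):
        ratios = grp["ratio"].to_numpy()
        box = tukey_box_stats(ratios)
        mean_ratio = float(ratios.mean())
        rows.append(
            {
                "region": region,
                "mean_ratio": mean_ratio,
                "n": len(ratios),
                "bin": classify_efficiency(mean_ratio),
                **box,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["region", "mean_ratio", "n", "bin", "q1", "median", "q3",
                 "whisker_low", "whisker_high", "outliers"],
    )
    return summary, dropped
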