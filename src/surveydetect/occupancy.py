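"""Single-season occupancy model with detection covariates.

The model of MacKenzie et al.: a site is occupied with probability psi;
given occupancy, each survey occasion yields a detection with
probability p, modelled on the logit scale from site-level covariates
(survey method, habitat, their interaction).  The likelihood for site i
with observed cells h_ij (missing occasions skipped) is

    L_i = psi * prod_j p_ij^h_ij (1 - p_ij)^(1 - h_ij)
          + (1 - psi) * I[all h_ij = 0]

When the species is known to use every site (here: confirmed presence at
all sampling locations) psi is fixed at 1 and only detection is modelled;
the likelihood then reduces to a Bernoulli product over non-missing
cells.

Model comparison uses AICc (small-sample corrected AIC with n = number
of sites); goodness of fit uses the MacKenzie–Bailey parametric
bootstrap of a chi-square statistic over cohorts of sites sharing
covariates and missingness patterns.  The minimum survey effort to
detect an occupying species with confidence 1 - alpha is

    N_min = log(alpha) / log(1 - p)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .detection_data import DetectionHistory, ValidationError

__all__ = [
    "OccupancyModelSpec",
    "OccupancyFit",
    "GOFResult",
    "design_matrix",
    "negloglik",
    "fit",
    "aicc",
    "rank_models",
    "predict_p",
    "gof_parboot",
    "n_min",
]

REFERENCE_LEVELS = {"method": "PT", "habitat": "forest"}


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Which detection covariates enter the model, and how psi is treated.

    ``p_covariates`` is a subset of {"method", "habitat"}; set
    ``interaction=True`` for the full method x habitat model (requires
    both mains).  ``psi_mode`` is ``"fixed_one"`` (psi = 1) or
    ``"free"`` (scalar psi estimated on the logit scale).
    """

    name: str
    p_covariates: tuple[str, ...] = ()
    interaction: bool = False
    psi_mode: str = "fixed_one"
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self):
        unknown = set(self.p_covariates) - {"method", "habitat"}
        if unknown:
            raise ValidationError(f"unknown detection covariate(s): {sorted(unknown)}")
        if self.interaction and set(self.p_covariates) != {"method", "habitat"}:
            raise ValidationError("interaction requires both main effects")
        if self.psi_mode not in ("fixed_one", "free"):
            raise ValidationError("psi_mode must be 'fixed_one' or 'free'")


#: the four candidate models of the standard comparison
def standard_model_set(psi_mode: str = "fixed_one") -> list[OccupancyModelSpec]:
    return [
        OccupancyModelSpec("null", (), psi_mode=psi_mode),
        OccupancyModelSpec("method", ("method",), psi_mode=psi_mode),
        OccupancyModelSpec("habitat", ("habitat",), psi_mode=psi_mode),
        OccupancyModelSpec(
            "method_x_habitat", ("method", "habitat"), interaction=True, psi_mode=psi_mode
        ),
    ]


def _levels(series: pd.Series, reference: str) -> list[str]:
    seen = list(pd.unique(series))
    if reference not in seen:
        raise ValidationError(f"reference level {reference!r} absent from the data")
    return [reference] + sorted(l for l in seen if l != reference)


def design_matrix(
    covariates: pd.DataFrame,
    spec: OccupancyModelSpec,
    levels: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded (dummy) design matrix for the detection submodel.

    The first level of each factor is the reference (method: PT,
    habitat: forest) and is absorbed into the intercept.  Returns the
    design and the level ordering used, so that prediction can reuse it;
    a category unseen at training raises.
    """
    if levels is None:
        levels = {
            cov: _levels(covariates[cov], spec.reference_levels[cov])
            for cov in spec.p_covariates
        }
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(covariates))}
    for cov in spec.p_covariates:
        vals = covariates[cov]
        unseen = set(vals) - set(levels[cov])
        if unseen:
            raise ValidationError(
                f"unseen {cov} level(s) {sorted(unseen)}; seen levels: {levels[cov]}"
            )
        for lev in levels[cov][1:]:
            cols[f"{cov}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
    if spec.interaction:
        for ml in levels["method"][1:]:
            for hl in levels["habitat"][1:]:
                cols[f"method[{ml}]:habitat[{hl}]"] = (
                    cols[f"method[{ml}]"] * cols[f"habitat[{hl}]"]
                )
    X = pd.DataFrame(cols, index=covariates.index)
    return X, levels


def negloglik(
    beta: np.ndarray,
    history_matrix: np.ndarray,
    X: np.ndarray,
    psi_mode: str = "fixed_one",
    psi_logit: float | None = None,
) -> float:
    """Negative log-likelihood of the single-season occupancy model.

    ``history_matrix`` is sites x occasions with NaN for missing cells;
    detection probability is constant across occasions within a site
    (site-level covariates only).  With ``psi_mode="free"``,
    ``psi_logit`` is the logit of the occupancy probability.
    """
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    p = expit(eta)
    obs = ~np.isnan(history_matrix)
    d = np.nansum(history_matrix, axis=1)          # detections per site
    m = obs.sum(axis=1)                            # non-missing occasions
    # log p^d (1-p)^(m-d), numerically via logs of expit
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    cond = d * log_p + (m - d) * log_q
    if psi_mode == "fixed_one":
        ll = cond
    else:
        psi = expit(psi_logit)
        zero = d == 0
        contrib = psi * np.exp(cond)
        contrib = np.where(zero, contrib + (1.0 - psi), contrib)
        with np.errstate(divide="ignore"):
            ll = np.log(contrib)
    return float(-np.sum(ll))


@dataclass
class OccupancyFit:
    """A fitted occupancy model.

    ``beta`` are logit-scale detection coefficients; ``psi`` is the
    occupancy probability (1.0 when fixed); ``vcov`` is the inverse
    observed information over all estimated parameters (detection
    coefficients first, then logit-psi when free).
    """

    spec: OccupancyModelSpec
    beta: pd.Series
    psi: float
    vcov: pd.DataFrame
    loglik: float
    n_params: int
    n_sites: int
    aic: float
    aicc: float
    converged: bool
    levels: dict[str, list[str]]
    history: DetectionHistory

    @property
    def name(self) -> str:
        return self.spec.name

    def coef_table(self) -> pd.DataFrame:
        """Estimate / SE / z / p for the detection coefficients (Wald)."""
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.vcov.to_numpy())[: len(self.beta)])
        z = self.beta.to_numpy() / se
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "z": z,
                "p_value": 2 * norm.sf(np.abs(z)),
            }
        )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit(
    history: DetectionHistory,
    spec: OccupancyModelSpec,
    gtol: float = 1e-8,
) -> OccupancyFit:
    """Maximum-likelihood fit by quasi-Newton (BFGS) from a zero start.

    Sites whose rows are entirely missing are excluded with a warning
    (the history container normally forbids them).  The covariance is
    the inverse observed information from a numeric Hessian.  Complete
    separation (a covariate level with all-1 or all-0 cells) yields
    divergent coefficients; a warning is emitted and ``converged`` may
    still be True if the gradient norm criterion is met.
    """
    Y = history.matrix.to_numpy(dtype=float)
    keep = ~np.isnan(Y).all(axis=1)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} all-missing site row(s)", stacklevel=2)
        Y = Y[keep]
    covs = history.covariates.loc[history.matrix.index[keep]]
    Xdf, levels = design_matrix(covs, spec)
    X = Xdf.to_numpy(dtype=float)
    n_sites, k_det = X.shape
    free_psi = spec.psi_mode == "free"
    n_par = k_det + (1 if free_psi else 0)

    # separation diagnostics: any design-distinct cohort with all-0 or all-1 cells
    for _, idx in Xdf.groupby(list(Xdf.columns)).groups.items():
        cells = Y[Xdf.index.get_indexer(idx)]
        vals = cells[~np.isnan(cells)]
        if vals.size and (vals.min() == 1.0 or vals.max() == 0.0):
            warnings.warn(
                "a covariate cohort has all-detected or never-detected cells; "
                "its coefficient is not finite (complete separation)",
                stacklevel=2,
            )
            break

    def objective(theta: np.ndarray) -> float:
        if free_psi:
            return negloglik(theta[:k_det], Y, X, "free", theta[k_det])
        return negloglik(theta, Y, X, "fixed_one")

    x0 = np.zeros(n_par)
    res = minimize(objective, x0, method="BFGS", options={"gtol": gtol, "maxiter": 500})
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gnorm < 1e-4)

    names = list(Xdf.columns) + (["logit(psi)"] if free_psi else [])
    H = _numeric_hessian(objective, res.x)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((n_par, n_par), np.nan)
        converged = False

    beta = pd.Series(res.x[:k_det], index=list(Xdf.columns), name="beta")
    psi = float(expit(res.x[k_det])) if free_psi else 1.0
    ll = -float(res.fun)
    return OccupancyFit(
        spec=spec,
        beta=beta,
        psi=psi,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=ll,
        n_params=n_par,
        n_sites=n_sites,
        aic=-2 * ll + 2 * n_par,
        aicc=aicc(ll, n_par, n_sites),
        converged=converged,
        levels=levels,
        history=history,
    )


def aicc(loglik: float, K: int, n: int) -> float:
    """AICc = AIC + 2K(K+1)/(n - K - 1), with n = number of sites."""
    if n <= K + 1:
        raise ValidationError(f"AICc undefined for n={n} <= K+1={K + 1}")
    aic = -2.0 * loglik + 2.0 * K
    return aic + 2.0 * K * (K + 1) / (n - K - 1)


def rank_models(fits: Sequence[OccupancyFit], delta_threshold: float = 7.0) -> pd.DataFrame:
    """AICc model table: delta to the top model, Akaike weights, flags.

    ``parsimonious`` flags models with delta below the threshold; the
    conventional check that the null model (when present) is *not*
    among them is reported in ``null_excluded``.
    """
    site_sets = {frozenset(f.history.matrix.index) for f in fits}
    if len(site_sets) > 1:
        raise ValidationError("all models must be fitted to the same site set")
    rows = pd.DataFrame(
        {
            "model": [f.name for f in fits],
            "n_params": [f.n_params for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    ).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    rows["delta"] = rows["aicc"] - rows["aicc"].iloc[0]
    w = np.exp(-rows["delta"] / 2.0)
    rows["weight"] = w / w.sum()
    rows["cumulative_weight"] = rows["weight"].cumsum()
    rows["parsimonious"] = rows["delta"] < delta_threshold
    null_rows = rows.loc[rows["model"] == "null"]
    rows.attrs["null_excluded"] = (
        bool((null_rows["delta"] > delta_threshold).all()) if len(null_rows) else None
    )
    return rows


def predict_p(fit_result: OccupancyFit, newdata: pd.DataFrame) -> pd.DataFrame:
    """Back-transformed detection probability with delta-method SE.

    ``newdata`` has one row per prediction with the model's covariate
    columns; p = logit^-1(x'beta), SE_p = p(1-p) * sqrt(x'Vx).
    Levels not seen at training raise.
    """
    Xdf, _ = design_matrix(newdata, fit_result.spec, levels=fit_result.levels)
    X = Xdf.to_numpy(dtype=float)
    beta = fit_result.beta.to_numpy()
    V = fit_result.vcov.to_numpy()[: beta.size, : beta.size]
    eta = X @ beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, V, X))
    p = expit(eta)
    out = newdata.copy()
    out["p"] = p
    out["se"] = p * (1.0 - p) * se_eta
    out["eta"] = eta
    out["se_eta"] = se_eta
    return out


# ---------------------------------------------------------------------------
# Goodness of fit (MacKenzie–Bailey parametric bootstrap)
# ---------------------------------------------------------------------------

@dataclass
class GOFResult:
    chisq_obs: float
    boot_stats: np.ndarray
    p_value: float
    n_boot: int
    n_failed: int
    seed: int


def _chisq_stat(Y: np.ndarray, p_site: np.ndarray, psi: float) -> float:
    """Chi-square over unique histories within covariate x NA-pattern cohorts.

    Within each cohort (sites sharing the same fitted p and missingness
    pattern) every possible history over the observed occasions gets an
    expected count n_cohort * P(history); expected cells below 2 are
    pooled into one.
    """
    obs_mask = ~np.isnan(Y)
    cohort_key = [
        (round(float(p), 12), tuple(row)) for p, row in zip(p_site, obs_mask)
    ]
    total = 0.0
    df_cohorts = pd.DataFrame({"key": pd.Series(cohort_key, dtype=object)})
    for key, idx in df_cohorts.groupby("key").groups.items():
        p, mask = key
        mask = np.array(mask)
        J = int(mask.sum())
        sub = Y[np.asarray(idx)][:, mask].astype(int)
        n_c = sub.shape[0]
        # observed counts per unique history
        obs_counts: dict[tuple, int] = {}
        for row in sub:
            t = tuple(row)
            obs_counts[t] = obs_counts.get(t, 0) + 1
        # expected counts for the observed histories; the mass of the
        # never-observed histories enters as a remainder term with O = 0,
        # whose contribution (0 - E)^2 / E collapses to E itself
        cells = []
        e_observed = 0.0
        for h, o in obs_counts.items():
            d = sum(h)
            prob = psi * (p ** d) * ((1 - p) ** (J - d))
            if d == 0:
                prob += 1.0 - psi
            e = n_c * prob
            e_observed += e
            cells.append((o, e))
        # pool observed cells with expected count below 2
        big = [(o, e) for o, e in cells if e >= 2.0]
        small = [(o, e) for o, e in cells if e < 2.0]
        if small:
            big.append((sum(o for o, _ in small), sum(e for _, e in small)))
        for o, e in big:
            if e > 0:
                total += (o - e) ** 2 / e
        total += max(n_c - e_observed, 0.0)
    return total


def _simulate_history(
    rng: np.random.Generator, p_site: np.ndarray, psi: float, obs_mask: np.ndarray
) -> np.ndarray:
    n, J = obs_mask.shape
    z = rng.random(n) < psi
    Y = np.where(
        obs_mask,
        (rng.random((n, J)) < p_site[:, None]) & z[:, None],
        np.nan,
    ).astype(float)
    Y[~obs_mask] = np.nan
    return Y


def gof_parboot(
    fit_result: OccupancyFit,
    n_boot: int = 1000,
    seed: int | None = None,
) -> GOFResult:
    """Parametric-bootstrap chi-square goodness-of-fit test.

    Simulates ``n_boot`` datasets from the fitted model (same design
    and missingness pattern), refits, and recomputes the statistic; the
    p-value is the proportion of bootstrap statistics at least as large
    as the observed one.  Deterministic under a fixed seed (mandatory).
    Replicates whose refit fails are dropped and counted.
    """
    if seed is None:
        raise ValidationError("gof_parboot requires an explicit seed")
    if not fit_result.converged:
        raise ValidationError("goodness of fit requires a converged fit")

    history = fit_result.history
    Y = history.matrix.to_numpy(dtype=float)
    covs = history.covariates
    Xdf, _ = design_matrix(covs, fit_result.spec, levels=fit_result.levels)
    p_site = expit(Xdf.to_numpy(dtype=float) @ fit_result.beta.to_numpy())
    obs_mask = ~np.isnan(Y)

    chisq_obs = _chisq_stat(Y, p_site, fit_result.psi)

    rng = np.random.default_rng(seed)
    stats, n_failed = [], 0
    for _ in range(n_boot):
        Yb = _simulate_history(rng, p_site, fit_result.psi, obs_mask)
        hb = DetectionHistory(
            matrix=pd.DataFrame(Yb, index=history.matrix.index,
                                columns=history.matrix.columns),
            covariates=covs,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fb = fit(hb, fit_result.spec)
            pb = expit(Xdf.to_numpy(dtype=float) @ fb.beta.to_numpy())
            stats.append(_chisq_stat(Yb, pb, fb.psi))
        except (ValidationError, np.linalg.LinAlgError):
            n_failed += 1
    boot = np.asarray(stats)
    p_value = float(np.mean(boot >= chisq_obs)) if boot.size else np.nan
    return GOFResult(
        chisq_obs=float(chisq_obs),
        boot_stats=boot,
        p_value=p_value,
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )


def n_min(p: float, alpha: float = 0.05) -> float:
    """Minimum survey occasions to detect an occupying species.

    ``N_min = log(alpha) / log(1 - p)`` — the number of occasions at
    detection probability p after which the chance of never detecting
    the species falls to alpha.  Returned unrounded.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"n_min requires 0 < p < 1, got p={p}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"n_min requires 0 < alpha < 1, got alpha={alpha}")
    return float(np.log(alpha) / np.log1p(-p))
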