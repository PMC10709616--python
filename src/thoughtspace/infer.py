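"""Inferential layer: mixed models, bootstrap, and RT regressions.

All models follow one set of conventions, chosen so that results are
comparable with the R mixed-model stack (lme4 + lmerTest + emmeans) that
dominates this literature:

* restricted maximum likelihood (REML) estimation,
* sum-to-zero factor coding (the intercept is the grand mean; a 2-level
  factor's coefficient is half the difference between its levels),
* type-3 F tests with Satterthwaite denominator degrees of freedom,
* estimated marginal means evaluated at covariate means,
* nonparametric cluster bootstrap (participants resampled whole) for
  robustness: percentile 95% CIs and a sign-flip bootstrap P value.

The engine covers the random-intercept case (one grouping factor), which is
the only random structure these analyses use; richer structures are out of
scope.  OLS regressions (response-time models) share the same design and
type-3 machinery with exact residual degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedEffectsModel",
    "MixedModelResult",
    "fit_lmm",
    "bootstrap_params",
    "rt_regression",
    "state_by_network_lmm",
    "prevalence_by_context",
    "bonferroni_alpha",
    "RT_OUTLIER_Z",
]

#: z-scored response times beyond this are outliers; their z is set to 0.
RT_OUTLIER_Z = 2.5


class ModelError(ValueError):
    pass


@dataclasses.dataclass
class ModelSpec:
    """Specification of one (mixed) linear model.

    ``fixed_factors`` are sum-coded categorical predictors; ``covariates``
    may mix continuous columns (standardized before entry when
    ``standardize_covariates``) and categorical ones (detected by dtype,
    sum-coded -- e.g. gender).  ``interactions`` are pairs of fixed
    factors.  ``random_intercept`` names the grouping column; ``None``
    yields plain OLS.
    """

    outcome: str
    fixed_factors: Sequence[str] = ()
    covariates: Sequence[str] = ()
    interactions: Sequence[tuple[str, str]] = ()
    random_intercept: str | None = "participant"
    standardize_covariates: bool = True

    @property
    def formula(self) -> str:
        terms = list(self.fixed_factors)
        terms += [f"{a}:{b}" for a, b in self.interactions]
        terms += list(self.covariates)
        rhs = " + ".join(terms) if terms else "1"
        if self.random_intercept:
            rhs += f" + (1|{self.random_intercept})"
        return f"{self.outcome} ~ {rhs}"


def _sum_code(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding: L levels -> L-1 columns (last level coded -1)."""
    levels = sorted(pd.unique(values.dropna()).tolist(), key=str)
    if len(levels) < 2:
        raise ModelError(f"factor {values.name!r} needs >= 2 levels")
    X = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        X[arr == lev, j] = 1.0
    X[arr == levels[-1], :] = -1.0
    return X, levels


class _Design:
    """Sum-coded fixed-effects design with term bookkeeping."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        cols: list[np.ndarray] = [np.ones((len(data), 1))]
        names = ["(Intercept)"]
        self.term_slices: dict[str, list[int]] = {}
        self.factor_codes: dict[str, tuple[np.ndarray, list]] = {}
        self.covariate_means: dict[str, float] = {}
        pos = 1

        factor_like = list(spec.fixed_factors) + [
            c for c in spec.covariates
            if not pd.api.types.is_numeric_dtype(data[c])
        ]
        for f in factor_like:
            X, levels = _sum_code(data[f])
            self.factor_codes[f] = (X, levels)
            cols.append(X)
            names += [f"{f}[{lev}]" for lev in levels[:-1]]
            self.term_slices[f] = list(range(pos, pos + X.shape[1]))
            pos += X.shape[1]
        for a, b in spec.interactions:
            Xa, _ = self.factor_codes[a]
            Xb, _ = self.factor_codes[b]
            inter = np.einsum("ni,nj->nij", Xa, Xb).reshape(len(data), -1)
            cols.append(inter)
            names += [f"{a}:{b}[{i},{j}]" for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
            self.term_slices[f"{a}:{b}"] = list(range(pos, pos + inter.shape[1]))
            pos += inter.shape[1]
        for c in spec.covariates:
            if not pd.api.types.is_numeric_dtype(data[c]):
                continue  # handled as a factor above
            v = data[c].to_numpy(float)
            self.covariate_means[c] = float(v.mean())
            if spec.standardize_covariates:
                sd = v.std(ddof=1)
                v = (v - v.mean()) / (sd if sd > 0 else 1.0)
            cols.append(v[:, None])
            names.append(c)
            self.term_slices[c] = [pos]
            pos += 1

        self.X = np.hstack(cols)
        self.names = names
        self.spec = spec
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ModelError("design matrix is rank deficient (empty cells or collinearity)")

    def emm_row(self, at: Mapping[str, object]) -> np.ndarray:
        """Design row for an estimated marginal mean.

        Factors named in ``at`` are set to the given level; unnamed factors
        average out (their sum codes average to zero across levels);
        continuous covariates sit at their training means (zero when
        standardized).
        """
        row = np.zeros(self.X.shape[1])
        row[0] = 1.0
        codes: dict[str, np.ndarray] = {}
        for f, (Xf, levels) in self.factor_codes.items():
            q = Xf.shape[1]
            if f in at:
                lev = at[f]
                if lev not in levels:
                    raise KeyError(f"unknown level {lev!r} of factor {f!r}; have {levels}")
                i = levels.index(lev)
                code = -np.ones(q) if i == q else np.eye(q)[i]
            else:
                code = np.zeros(q)
            codes[f] = code
            row[self.term_slices[f]] = code
        for a, b in self.spec.interactions:
            row[self.term_slices[f"{a}:{b}"]] = np.outer(codes[a], codes[b]).ravel()
        # covariates: zero when standardized; otherwise their mean
        for c, idx in self.term_slices.items():
            if c in self.covariate_means and not self.spec.standardize_covariates:
                row[idx] = self.covariate_means[c]
        return row


@dataclasses.dataclass
class MixedModelResult:
    """Fitted-model summary: coefficients, type-3 F tests, marginal means."""

    formula: str
    params: pd.DataFrame  # estimate, se per coefficient
    anova: pd.DataFrame  # F, df1, df2, p per term
    emmeans: dict[str, pd.DataFrame]
    tau2: float
    sigma2: float
    singular: bool
    n_obs: int
    n_groups: int
    bootstrap: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None


class MixedEffectsModel:
    """Random-intercept linear mixed model, REML, sum coding.

    sklearn-style estimator: ``fit(data)`` populates ``beta_``,
    ``cov_beta_``, ``tau2_`` (random-intercept variance), ``sigma2_``
    (residual variance); ``anova_()``, ``emmeans_(factor)`` and
    ``pairwise_(factor, by=...)`` derive the inferential quantities.

    The covariance between-group/within-group is estimated by profiling the
    residual variance out of the REML criterion and optimizing the variance
    ratio on a bounded interval; a ratio on the zero boundary is flagged as
    a singular fit (results are still returned).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    # -- core REML machinery -------------------------------------------------

    def _group_stats(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        """Per-group sufficient statistics, stacked for vectorized assembly."""
        codes, _ = pd.factorize(groups, sort=False)
        n_g = np.bincount(codes).astype(float)
        xs = np.zeros((len(n_g), X.shape[1]))
        ys = np.zeros(len(n_g))
        np.add.at(xs, codes, X)
        np.add.at(ys, codes, y)
        return {
            "XtX": X.T @ X,
            "Xty": X.T @ y,
            "yty": float(y @ y),
            "xs": xs,
            "ys": ys,
            "n": n_g,
        }

    def _assemble(self, phi: float):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y at sigma2=1 for variance ratio phi."""
        s = self._stats
        c = phi / (1.0 + s["n"] * phi)
        A = s["XtX"] - (s["xs"] * c[:, None]).T @ s["xs"]
        b = s["Xty"] - s["xs"].T @ (c * s["ys"])
        q = s["yty"] - float(c @ s["ys"] ** 2)
        logdet_ratio = float(np.log1p(s["n"] * phi).sum())
        return A, b, q, logdet_ratio

    def _profiled_neg2reml(self, phi: float) -> float:
        A, b, q, logdet_ratio = self._assemble(phi)
        sign, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, b)
        rss = q - b @ beta
        dfe = self._n - self._p
        sigma2 = max(rss / dfe, 1e-300)
        return dfe * (np.log(sigma2) + 1 + np.log(2 * np.pi)) + logdet_ratio + logdetA

    def _neg2reml(self, tau2: float, sigma2: float) -> float:
        phi = max(tau2, 0.0) / sigma2
        A, b, q, logdet_ratio = self._assemble(phi)
        sign, logdetA = np.linalg.slogdet(A)
        beta = np.linalg.solve(A, b)
        rss = q - b @ beta
        n, p = self._n, self._p
        return (
            (n - p) * np.log(sigma2)
            + logdet_ratio
            + logdetA
            + rss / sigma2
            + (n - p) * np.log(2 * np.pi)
        )

    def _beta_cov(self, tau2: float, sigma2: float):
        A, b, _, _ = self._assemble(max(tau2, 0.0) / sigma2)
        Ainv = np.linalg.inv(A)
        return Ainv @ b, sigma2 * Ainv

    # -- fitting -------------------------------------------------------------

    def fit(self, data: pd.DataFrame) -> "MixedEffectsModel":
        spec = self.spec
        needed = [spec.outcome, *spec.fixed_factors, *spec.covariates]
        if spec.random_intercept:
            needed.append(spec.random_intercept)
        n0 = len(data)
        data = data.dropna(subset=needed).reset_index(drop=True)
        if n0 - len(data):
            logger.info("dropped %d rows with missing model columns", n0 - len(data))
        if spec.random_intercept and data[spec.random_intercept].nunique() < 2:
            raise ModelError("random intercept grouping needs >= 2 groups")

        design = _Design(data, spec)
        X, y = design.X, data[spec.outcome].to_numpy(float)
        self.design_ = design
        self._n, self._p = X.shape
        groups = (
            data[spec.random_intercept].to_numpy()
            if spec.random_intercept
            else np.arange(len(data))
        )
        self._stats = self._group_stats(X, y, groups)
        self.n_groups_ = len(self._stats["n"])

        if spec.random_intercept:
            res = optimize.minimize_scalar(
                self._profiled_neg2reml, bounds=(0.0, 1e4), method="bounded",
                options={"xatol": 1e-10},
            )
            phi = float(res.x)
            A, b, q, _ = self._assemble(phi)
            beta = np.linalg.solve(A, b)
            sigma2 = (q - b @ beta) / (self._n - self._p)
            tau2 = phi * sigma2
            self.singular_ = phi < 1e-6
            if self.singular_:
                warnings.warn("singular fit: random-intercept variance is ~0", stacklevel=2)
        else:
            phi, tau2 = 0.0, 0.0
            A, b, q, _ = self._assemble(0.0)
            beta = np.linalg.solve(A, b)
            sigma2 = (q - b @ beta) / (self._n - self._p)
            self.singular_ = False

        self.tau2_, self.sigma2_ = float(tau2), float(sigma2)
        self.beta_, self.cov_beta_ = self._beta_cov(tau2, sigma2)
        self._vtheta = self._theta_cov() if spec.random_intercept else None
        return self

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of (tau2, sigma2) from the REML information."""
        th = np.array([max(self.tau2_, 0.0), self.sigma2_])
        # step ~ eps^(1/4): optimal for second-order central differences
        h = np.maximum(1e-4 * (th + 1e-2), 1e-8)
        # central differences where possible, forward at the tau2 >= 0 boundary
        H = np.zeros((2, 2))

        def f(t):
            return 0.5 * self._neg2reml(max(t[0], 0.0), max(t[1], 1e-12))

        for i in range(2):
            for j in range(i, 2):
                ei, ej = np.eye(2)[i] * h[i], np.eye(2)[j] * h[j]
                base = th.copy()
                if base[0] - (ei + ej)[0] < 0:
                    base = base + ei + ej  # shift away from the boundary
                H[i, j] = H[j, i] = (
                    f(base + ei + ej) - f(base + ei - ej) - f(base - ei + ej) + f(base - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)

    # -- inference -----------------------------------------------------------

    def _contrast_df(self, l: np.ndarray) -> float:
        """Satterthwaite denominator df for a single contrast l'beta."""
        if self.spec.random_intercept is None or self.singular_ or self._vtheta is None:
            return float(self._n - self._p)
        th = np.array([self.tau2_, self.sigma2_])
        h = np.maximum(1e-5 * (th + 1e-2), 1e-9)

        def g(t):
            _, C = self._beta_cov(max(t[0], 0.0), max(t[1], 1e-12))
            return float(l @ C @ l)

        grad = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            lo = th - e
            if lo[0] < 0:
                grad[i] = (g(th + e) - g(th)) / h[i]
            else:
                grad[i] = (g(th + e) - g(lo)) / (2 * h[i])
        var_f = float(grad @ self._vtheta @ grad)
        fval = g(th)
        if var_f <= 0 or not np.isfinite(var_f):
            return float(self._n - self._p)
        return float(2 * fval**2 / var_f)

    def term_F(self, term: str) -> tuple[float, int, float, float]:
        """Type-3 F, numerator df, Satterthwaite denominator df, P."""
        idx = self.design_.term_slices[term]
        L = np.zeros((len(idx), self._p))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        q = len(idx)
        M = L @ self.cov_beta_ @ L.T
        vals, vecs = np.linalg.eigh(M)
        keep = vals > 1e-12 * vals.max()
        vals, vecs = vals[keep], vecs[:, keep]
        Lb = L @ self.beta_
        F = float(sum((vecs[:, i] @ Lb) ** 2 / vals[i] for i in range(len(vals))) / q)
        nus = [self._contrast_df(L.T @ vecs[:, i]) for i in range(len(vals))]
        finite = [nu for nu in nus if nu > 2]
        if len(finite) == len(nus) and nus:
            E = sum(nu / (nu - 2) for nu in nus)
            df2 = 2 * E / (E - q) if E > q else float(self._n - self._p)
        else:
            df2 = float(self._n - self._p)
        p = float(stats.f.sf(F, q, df2)) if np.isfinite(df2) else np.nan
        return F, q, df2, p

    def anova_(self) -> pd.DataFrame:
        rows = []
        for term in self.design_.term_slices:
            F, df1, df2, p = self.term_F(term)
            rows.append({"term": term, "F": F, "df1": df1, "df2": df2, "p": p})
        return pd.DataFrame(rows).set_index("term")

    def params_(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta_))
        dfs = [self._contrast_df(np.eye(self._p)[i]) for i in range(self._p)]
        t = self.beta_ / se
        p = 2 * stats.t.sf(np.abs(t), dfs)
        return pd.DataFrame(
            {"estimate": self.beta_, "se": se, "df": dfs, "t": t, "p": p},
            index=self.design_.names,
        )

    def _cell(self, at: Mapping[str, object]) -> dict:
        row = self.design_.emm_row(at)
        est = float(row @ self.beta_)
        se = float(np.sqrt(row @ self.cov_beta_ @ row))
        df = self._contrast_df(row)
        tcrit = stats.t.ppf(0.975, df)
        return {
            "estimate": est,
            "se": se,
            "df": df,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
        }

    def emmeans_(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means per level, at covariate means."""
        _, levels = self.design_.factor_codes[factor]
        return pd.DataFrame(
            {lev: self._cell({factor: lev}) for lev in levels}
        ).T.rename_axis(factor)

    def pairwise_(
        self, factor: str, by: str | None = None, n_comparisons: int | None = None
    ) -> pd.DataFrame:
        """Pairwise level differences, optionally within each level of ``by``.

        P values are Bonferroni-adjusted for ``n_comparisons`` (default: the
        number of contrasts computed).
        """
        _, levels = self.design_.factor_codes[factor]
        by_levels = self.design_.factor_codes[by][1] if by else [None]
        rows = []
        for w in by_levels:
            for i, a in enumerate(levels):
                for b in levels[i + 1 :]:
                    at_a = {factor: a} | ({by: w} if by else {})
                    at_b = {factor: b} | ({by: w} if by else {})
                    l = self.design_.emm_row(at_a) - self.design_.emm_row(at_b)
                    est = float(l @ self.beta_)
                    se = float(np.sqrt(l @ self.cov_beta_ @ l))
                    df = self._contrast_df(l)
                    t = est / se if se > 0 else 0.0
                    p = 2 * float(stats.t.sf(abs(t), df))
                    row = {"contrast": f"{a} - {b}", "estimate": est, "se": se,
                           "df": df, "t": t, "p": p}
                    if by:
                        row[by] = w
                    rows.append(row)
        out = pd.DataFrame(rows)
        m = n_comparisons or len(out)
        out["p_adj"] = np.minimum(out["p"] * m, 1.0)
        return out


# ---------------------------------------------------------------------------
# public operations


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    emmeans_factors: Sequence[str] | None = None,
    bootstrap_iter: int = 0,
    seed: int = 0,
) -> MixedModelResult:
    """Fit a model per the package conventions and summarize it.

    Returns coefficients, type-3 Satterthwaite F tests, marginal means for
    the requested factors (default: all fixed factors), and optionally
    cluster-bootstrap CIs/P values.
    """
    model = MixedEffectsModel(spec).fit(data)
    factors = list(emmeans_factors if emmeans_factors is not None else spec.fixed_factors)
    boot = None
    if bootstrap_iter:
        boot = bootstrap_params(data, spec, n_iter=bootstrap_iter, seed=seed)
    logger.info("fitted %s", spec.formula)
    return MixedModelResult(
        formula=spec.formula,
        params=model.params_(),
        anova=model.anova_(),
        emmeans={f: model.emmeans_(f) for f in factors},
        tau2=model.tau2_,
        sigma2=model.sigma2_,
        singular=model.singular_,
        n_obs=model._n,
        n_groups=model.n_groups_,
        bootstrap=boot,
    )


def bootstrap_params(
    data: pd.DataFrame, spec: ModelSpec, n_iter: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Cluster bootstrap of the fixed effects.

    Participants (clusters) are resampled whole, with replacement, keeping
    the number of clusters; each resample is refit and the coefficient
    draws summarized as percentile 95% CIs and a two-sided sign-share P
    value floored at 2/n_iter.  Degenerate resamples (a single distinct
    cluster, or a lost factor level making the design singular) are redrawn
    and counted.
    """
    if n_iter < 100:
        raise ModelError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)
    group_col = spec.random_intercept or "participant"
    clusters = [g for _, g in data.groupby(group_col, sort=False)]
    n_cl = len(clusters)
    draws = []
    redraws = 0
    while len(draws) < n_iter:
        idx = rng.integers(0, n_cl, n_cl)
        if len(set(idx)) < 2:
            redraws += 1
            continue
        parts = []
        for new_id, i in enumerate(idx):
            g = clusters[i].copy()
            g[group_col] = f"bs{new_id}"
            parts.append(g)
        sample = pd.concat(parts, ignore_index=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = MixedEffectsModel(spec).fit(sample)
        except (ModelError, np.linalg.LinAlgError):
            redraws += 1
            if redraws > 10 * n_iter:
                raise ModelError("bootstrap cannot find non-degenerate resamples")
            continue
        draws.append(m.beta_)
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    B = np.vstack(draws)
    lo, hi = np.percentile(B, [2.5, 97.5], axis=0)
    p = 2 * np.minimum((B <= 0).mean(axis=0), (B >= 0).mean(axis=0))
    p = np.maximum(p, 2.0 / n_iter)
    names = _Design(data, spec).names
    return pd.DataFrame(
        {"estimate": B.mean(axis=0), "ci_low": lo, "ci_high": hi, "p_boot": p},
        index=names,
    )


def rt_regression(
    rt: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "rt_z",
    covariates: Sequence[str] = ("age", "gender", "mean_movement"),
    bootstrap_iter: int = 0,
    seed: int = 0,
) -> MixedModelResult:
    """OLS regression of z-scored response time on state-space predictors.

    The outlier rule is applied first: rows with |z| above 2.5 have their z
    set to zero (count logged).  Sum coding, type-3 F per predictor with
    exact residual df, age/gender/mean-movement covariates, optional
    row-resampling bootstrap (one row per participant, so cluster and case
    resampling coincide).
    """
    rt = rt.copy()
    if "participant" in rt.columns and rt["participant"].duplicated().any():
        raise ModelError("rt table must have one row per participant")
    n_out = int((rt[outcome].abs() > RT_OUTLIER_Z).sum())
    if n_out:
        logger.info("set %d RT outliers (|z| > %.1f) to zero", n_out, RT_OUTLIER_Z)
    rt.loc[rt[outcome].abs() > RT_OUTLIER_Z, outcome] = 0.0
    covs = [c for c in covariates if c in rt.columns]
    spec = ModelSpec(
        outcome=outcome,
        fixed_factors=(),
        covariates=list(predictors) + covs,
        random_intercept=None,
    )
    n_params = 1 + len(predictors) + len(covs)
    if n_params > len(rt) - 2:
        raise ModelError(
            f"{n_params} parameters for {len(rt)} participants: overparameterized"
        )
    model = MixedEffectsModel(spec).fit(rt)
    boot = None
    if bootstrap_iter:
        boot_spec = dataclasses.replace(spec, random_intercept="participant")
        boot = bootstrap_params(rt, boot_spec, n_iter=bootstrap_iter, seed=seed)
    result = MixedModelResult(
        formula=spec.formula,
        params=model.params_(),
        anova=model.anova_(),
        emmeans={},
        tau2=0.0,
        sigma2=model.sigma2_,
        singular=False,
        n_obs=model._n,
        n_groups=model._n,
        bootstrap=boot,
    )
    result.params.attrs["n_outliers"] = n_out
    return result


def state_by_network_lmm(
    network_means: pd.DataFrame,
    value_col: str = "value",
    bootstrap_iter: int = 0,
    seed: int = 0,
) -> MixedModelResult:
    """State x network interaction model on per-subject network averages.

    ``network_means`` is tidy: participant, state, network, value.  Fits
    value ~ state * network + (1 | participant) and reports the type-3
    interaction F plus pairwise state contrasts within each network,
    Bonferroni-corrected for the 7 networks.
    """
    counts = network_means.groupby(["participant", "network"])["state"].nunique()
    if (counts < 2).any():
        missing = counts[counts < 2].index.tolist()[:5]
        raise ModelError(f"missing state/network cells for {missing}")
    spec = ModelSpec(
        outcome=value_col,
        fixed_factors=("state", "network"),
        interactions=(("state", "network"),),
        covariates=(),
        random_intercept="participant",
    )
    model = MixedEffectsModel(spec).fit(network_means)
    n_networks = network_means["network"].nunique()
    pairwise = model.pairwise_("state", by="network", n_comparisons=n_networks)
    boot = None
    if bootstrap_iter:
        boot = bootstrap_params(network_means, spec, n_iter=bootstrap_iter, seed=seed)
    return MixedModelResult(
        formula=spec.formula,
        params=model.params_(),
        anova=model.anova_(),
        emmeans={"state": model.emmeans_("state"), "network": model.emmeans_("network")},
        tau2=model.tau2_,
        sigma2=model.sigma2_,
        singular=model.singular_,
        n_obs=model._n,
        n_groups=model.n_groups_,
        bootstrap=boot,
        pairwise=pairwise,
    )


def prevalence_by_context(
    scores: pd.DataFrame,
    context_col: str = "context",
    covariates: Sequence[str] = ("probe_order", "day", "order"),
    components: Sequence[str] | None = None,
) -> dict[str, MixedModelResult]:
    """Per-component mixed models of projected scores across task contexts.

    One model per component score: score ~ context + nuisance covariates +
    (1 | participant); marginal means per context come back for radar or
    word-cloud style summaries.  Contexts observed fewer than twice are
    flagged.
    """
    counts = scores[context_col].value_counts()
    thin = counts[counts < 2].index.tolist()
    if thin:
        raise ModelError(f"contexts with < 2 observations: {thin}")
    comps = list(components or [c for c in scores.columns if c.startswith("score_")])
    out = {}
    for comp in comps:
        spec = ModelSpec(
            outcome=comp,
            fixed_factors=(context_col,),
            covariates=[c for c in covariates if c in scores.columns],
            random_intercept="participant",
        )
        out[comp] = fit_lmm(scores, spec, emmeans_factors=[context_col])
    return out


def bonferroni_alpha(n_models: int) -> float:
    """Family alpha 0.05 split across a set of models."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return 0.05 / n_models
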