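"""Covariate-adjusted linear models with nonparametric bootstrap inference.

The estimation strategy mirrors a common epidemiological workflow: point
estimates come from ordinary least squares on the full analysis sample, while
standard errors, 95% confidence intervals and p-values come from case
resampling of individuals (percentile intervals; p-values from the
bootstrap-z statistic against the standard normal).  On top of the linear
model sit:

* a depression-type x score interaction test (joint Wald test on the product
  terms using the bootstrap covariance),
* covariate-adjusted group means and pairwise contrasts via marginal
  standardization (g-computation over the observed covariate distribution),
* per-stratum simple slopes of the score,
* a bootstrap multinomial logistic model reporting sample-averaged predicted
  subtype probabilities per score category, and
* Bonferroni adjustment over the family of quality-of-life outcomes.

Models follow the statsmodels idiom: construct from a DataFrame, call
``fit()``, and work with the returned Results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats as st

__all__ = [
    "DEFAULT_COVARIATES",
    "AnalysisPlan",
    "BootstrapGLM",
    "BootstrapGLMResults",
    "InteractionModel",
    "InteractionResults",
    "MultinomialSubtypeModel",
    "MultinomialResults",
    "adjust_bonferroni",
    "fit_glm_bootstrap",
    "test_interaction",
    "estimate_adjusted_means",
]

# default adjustment set: age, sex, stratification PCs, lifestyle, SES,
# comorbidities, BMI and physical activity
DEFAULT_COVARIATES = [
    "age",
    "sex",
    "pc1",
    "pc2",
    "pc3",
    "smoking",
    "alcohol",
    "ses",
    "comorbidity_class",
    "bmi",
    "ltpa_met_h_wk",
]

_REFERENCES = {"subtype": "none", "eprs_cat": "low"}


@dataclass
class AnalysisPlan:
    """Declarative description of one regression analysis."""

    outcome: str
    exposure: str | None = None  # e.g. 3-level depression type
    modifier: str | None = None  # ePRS z-score or category
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    n_boot: int = 10_000
    seed: int | None = None
    alpha: float = 0.05


def _term(data: pd.DataFrame, name: str) -> str:
    """Formula term for a column: categoricals get treatment coding, with the
    conventional reference level where one is defined."""
    if pd.api.types.is_numeric_dtype(data[name]):
        return name
    ref = _REFERENCES.get(name)
    if ref is None and isinstance(data[name].dtype, pd.CategoricalDtype):
        ref = data[name].cat.categories[0]
    if ref is not None:
        return f'C({name}, Treatment("{ref}"))'
    return f"C({name})"


def _bootstrap_betas(
    X: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Case-resampled OLS coefficients, solved in batches of normal equations."""
    n, p = X.shape
    out = np.empty((n_boot, p))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(b, n))
        Xi = X[idx]
        yi = y[idx]
        XtX = Xi.transpose(0, 2, 1) @ Xi
        Xty = (Xi.transpose(0, 2, 1) @ yi[..., None])[..., 0]
        try:
            out[start : start + b] = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            out[start : start + b] = (np.linalg.pinv(XtX) @ Xty[..., None])[..., 0]
    return out


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is collinear; aliased terms: {aliased}")


class BootstrapGLM:
    """Linear model with bootstrap inference, built from a DataFrame.

    Parameters
    ----------
    data
        Analysis table; rows with missing values in any model variable are
        dropped (complete-case) and the count is recorded on the results.
    formula
        Patsy formula for the mean model.
    """

    def __init__(self, data: pd.DataFrame, formula: str):
        self.formula = formula
        used = [c for c in data.columns if c in formula]
        frame = data.dropna(subset=used) if used else data
        self.n_dropped = len(data) - len(frame)
        self.frame = frame.reset_index(drop=True)
        y, X = patsy.dmatrices(formula, self.frame, return_type="dataframe")
        self.design_info = X.design_info
        self.exog_names = list(X.columns)
        self.endog_name = y.columns[0]
        self.X = X.to_numpy(dtype=float)
        self.y = y.to_numpy(dtype=float).ravel()
        if self.X.shape[0] == 0:
            raise ValueError("no complete cases to fit")
        _check_full_rank(self.X, self.exog_names)

    @classmethod
    def from_plan(cls, data: pd.DataFrame, plan: AnalysisPlan) -> "BootstrapGLM":
        rhs = []
        if plan.exposure:
            rhs.append(_term(data, plan.exposure))
        if plan.modifier:
            rhs.append(_term(data, plan.modifier))
        rhs += [_term(data, c) for c in plan.covariates]
        formula = f"{plan.outcome} ~ " + (" + ".join(rhs) if rhs else "1")
        return cls(data, formula)

    def fit(
        self, n_boot: int = 10_000, seed: int | None = None
    ) -> "BootstrapGLMResults":
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        rng = np.random.default_rng(seed)
        boot = _bootstrap_betas(self.X, self.y, n_boot, rng)
        return BootstrapGLMResults(self, beta, boot, n_boot=n_boot, seed=seed)


def _boot_pvalue(est: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Two-sided p from the bootstrap-z statistic; degenerate SE -> p = 1."""
    est = np.atleast_1d(np.asarray(est, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    return 2.0 * st.norm.sf(np.abs(z))


class BootstrapGLMResults:
    """OLS point estimates with bootstrap uncertainty.

    Attributes mirror statsmodels results: ``params``, ``bse``, ``pvalues``,
    ``conf_int()``, ``nobs``, plus the raw ``boot_params`` draws.
    """

    def __init__(self, model: BootstrapGLM, beta, boot, n_boot: int, seed):
        self.model = model
        self.params = pd.Series(beta, index=model.exog_names)
        self.boot_params = boot  # (n_boot, p)
        self.n_boot = n_boot
        self.seed = seed
        self.nobs = len(model.y)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.boot_params.std(axis=0, ddof=1), index=self.params.index)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            _boot_pvalue(self.params.to_numpy(), self.bse.to_numpy()),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo, hi = np.percentile(
            self.boot_params, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.params.index)

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "coef": self.params,
                "boot_se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "pvalue": self.pvalues,
            }
        )

    def summary(self, alpha: float = 0.05) -> str:
        head = (
            f"Bootstrap GLM: {self.model.endog_name}"
            f"  (n={self.nobs}, dropped={self.model.n_dropped},"
            f" n_boot={self.n_boot}, seed={self.seed})\n"
        )
        return head + self.summary_frame(alpha).to_string(float_format="%.4f")

    # -- linear functionals of the coefficients ------------------------------

    def linear_combination(self, c: np.ndarray, alpha: float = 0.05) -> dict:
        """Estimate, percentile CI and bootstrap-z p of c'beta."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        draws = self.boot_params @ c
        lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        se = float(draws.std(ddof=1))
        return {
            "estimate": est,
            "se": se,
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "pvalue": float(_boot_pvalue(est, se)[0]),
        }

    def wald_joint(self, terms: Sequence[str]) -> dict:
        """Joint chi-square test of several coefficients being zero, using the
        bootstrap covariance of the coefficient vector."""
        idx = [self.params.index.get_loc(t) for t in terms]
        b = self.params.to_numpy()[idx]
        V = np.cov(self.boot_params[:, idx], rowvar=False)
        V = np.atleast_2d(V)
        stat = float(b @ np.linalg.pinv(V) @ b)
        df = len(idx)
        return {"statistic": stat, "df": df, "pvalue": float(st.chi2.sf(stat, df))}

    # -- marginal standardization --------------------------------------------

    def _counterfactual_row(self, assignments: dict) -> np.ndarray:
        """Mean design row after setting columns of the model frame."""
        frame = self.model.frame.copy()
        for col, val in assignments.items():
            frame[col] = _like_column(frame[col], val)
        (X,) = patsy.build_design_matrices([self.model.design_info], frame)
        return np.asarray(X).mean(axis=0)

    def adjusted_means(
        self, group: str, levels: Sequence | None = None, alpha: float = 0.05
    ) -> pd.DataFrame:
        """Predicted outcome per group level, averaged over the observed
        covariate distribution (continuous covariates at their means,
        categorical at observed proportions)."""
        if levels is None:
            levels = _levels(self.model.frame[group])
        rows = {}
        for lev in levels:
            c = self._counterfactual_row({group: lev})
            rows[lev] = self.linear_combination(c, alpha=alpha)
        out = pd.DataFrame(rows).T
        out.index.name = group
        return out

    def contrasts(
        self, group: str, levels: Sequence | None = None, alpha: float = 0.05,
        extra: dict | None = None,
    ) -> pd.DataFrame:
        """Pairwise differences of adjusted means with bootstrap CIs."""
        if levels is None:
            levels = _levels(self.model.frame[group])
        if any(lev not in set(_levels(self.model.frame[group])) for lev in levels):
            raise ValueError(f"level absent from model frame column {group!r}")
        crows = {
            lev: self._counterfactual_row({group: lev, **(extra or {})})
            for lev in levels
        }
        rows = {}
        for a, b in combinations(levels, 2):
            rows[f"{a} - {b}"] = self.linear_combination(
                crows[a] - crows[b], alpha=alpha
            )
        out = pd.DataFrame(rows).T
        out.index.name = f"contrast({group})"
        return out

    def slope(
        self, variable: str, at: dict | None = None, alpha: float = 0.05
    ) -> dict:
        """Simple slope of a continuous variable (optionally within a stratum
        fixed by ``at``), by unit-increment counterfactual contrast."""
        base = dict(at or {})
        x0 = self.model.frame[variable].mean()
        r0 = self._counterfactual_row({**base, variable: x0})
        r1 = self._counterfactual_row({**base, variable: x0 + 1.0})
        return self.linear_combination(r1 - r0, alpha=alpha)


def _levels(col: pd.Series) -> list:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return [lev for lev in col.cat.categories if (col == lev).any()]
    return sorted(col.dropna().unique())


def _like_column(col: pd.Series, val):
    if isinstance(col.dtype, pd.CategoricalDtype):
        return pd.Categorical([val] * len(col), categories=col.cat.categories)
    return val


class InteractionModel:
    """Adjusted model with depression-type x modifier product terms.

    ``modifier`` may be the continuous standardized score or the three-level
    category; the exposure is the three-level depression type.  ``fit``
    reports a joint bootstrap Wald test of all interaction terms plus the
    per-stratum quantities (simple slopes of a continuous modifier, or
    adjusted means and group contrasts per category).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        exposure: str = "subtype",
        modifier: str = "eprs_z",
        covariates: Sequence[str] | None = None,
    ):
        self.outcome = outcome
        self.exposure = exposure
        self.modifier = modifier
        self.covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
        self.modifier_is_categorical = not pd.api.types.is_numeric_dtype(data[modifier])

        if len(_levels(data[exposure].dropna())) < 2:
            raise ValueError("exposure must have at least two levels")
        if self.modifier_is_categorical:
            levels = _levels(data[modifier].dropna())
            if len(levels) < 2:
                raise ValueError("modifier has a single level; no interaction estimable")
            cells = pd.crosstab(data[exposure], data[modifier])
            empty = [
                (str(r), str(c))
                for r in cells.index
                for c in cells.columns
                if cells.at[r, c] == 0
            ]
            if empty:
                raise ValueError(f"empty exposure x modifier cells: {empty}")
        elif data[modifier].nunique() < 2:
            raise ValueError("modifier has a single level; no interaction estimable")

        e_term = _term(data, exposure)
        m_term = _term(data, modifier)
        rhs = [f"{e_term} * {m_term}"] + [_term(data, c) for c in self.covariates]
        self.glm = BootstrapGLM(data, f"{outcome} ~ " + " + ".join(rhs))

    def fit(
        self, n_boot: int = 10_000, seed: int | None = None
    ) -> "InteractionResults":
        res = self.glm.fit(n_boot=n_boot, seed=seed)
        inter_terms = [name for name in res.params.index if ":" in name]
        joint = res.wald_joint(inter_terms)
        return InteractionResults(self, res, joint)


class InteractionResults:
    """Joint interaction test plus stratum-level summaries."""

    def __init__(self, model: InteractionModel, glm_results, joint: dict):
        self.model = model
        self.glm_results = glm_results
        self.interaction_test = joint

    @property
    def interaction_pvalue(self) -> float:
        return self.interaction_test["pvalue"]

    def stratum_slopes(self, alpha: float = 0.05) -> pd.DataFrame:
        """Slope of the continuous modifier within each depression type."""
        if self.model.modifier_is_categorical:
            raise ValueError("slopes require a continuous modifier")
        res = self.glm_results
        rows = {
            lev: res.slope(self.model.modifier, at={self.model.exposure: lev}, alpha=alpha)
            for lev in _levels(res.model.frame[self.model.exposure])
        }
        out = pd.DataFrame(rows).T
        out.index.name = self.model.exposure
        return out

    def adjusted_cell_means(self, alpha: float = 0.05) -> pd.DataFrame:
        """Adjusted outcome mean per exposure x modifier-category cell."""
        if not self.model.modifier_is_categorical:
            raise ValueError("cell means require a categorical modifier")
        res = self.glm_results
        frame = res.model.frame
        rows = []
        for m_lev in _levels(frame[self.model.modifier]):
            for e_lev in _levels(frame[self.model.exposure]):
                c = res._counterfactual_row(
                    {self.model.exposure: e_lev, self.model.modifier: m_lev}
                )
                d = res.linear_combination(c, alpha=alpha)
                rows.append({self.model.modifier: m_lev, self.model.exposure: e_lev, **d})
        return pd.DataFrame(rows)

    def stratum_contrasts(self, alpha: float = 0.05) -> pd.DataFrame:
        """Pairwise depression-type contrasts within each modifier category."""
        if not self.model.modifier_is_categorical:
            raise ValueError("stratum contrasts require a categorical modifier")
        res = self.glm_results
        frames = []
        for m_lev in _levels(res.model.frame[self.model.modifier]):
            ct = res.contrasts(
                self.model.exposure, alpha=alpha, extra={self.model.modifier: m_lev}
            )
            ct = ct.reset_index()
            ct.insert(0, self.model.modifier, m_lev)
            frames.append(ct)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        jt = self.interaction_test
        head = (
            f"Interaction model: {self.model.outcome} ~ {self.model.exposure}"
            f" x {self.model.modifier}\n"
            f"Joint interaction Wald chi2={jt['statistic']:.3f}"
            f" (df={jt['df']}), p={jt['pvalue']:.4g}\n"
        )
        return head + self.glm_results.summary()

    def plot_stratum_slopes(self, ax=None):
        """Fitted modifier-vs-outcome lines per depression type."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.glm_results
        frame = res.model.frame
        if self.model.modifier_is_categorical:
            cells = self.adjusted_cell_means()
            for e_lev, grp in cells.groupby(self.model.exposure, observed=True):
                ax.errorbar(
                    grp[self.model.modifier].astype(str),
                    grp["estimate"],
                    yerr=[
                        grp["estimate"] - grp["ci_lower"],
                        grp["ci_upper"] - grp["estimate"],
                    ],
                    marker="o",
                    capsize=3,
                    label=str(e_lev),
                )
        else:
            xs = np.linspace(frame[self.model.modifier].min(),
                             frame[self.model.modifier].max(), 25)
            for lev in _levels(frame[self.model.exposure]):
                ys = []
                for x in xs:
                    c = res._counterfactual_row(
                        {self.model.exposure: lev, self.model.modifier: x}
                    )
                    ys.append(float(c @ res.params.to_numpy()))
                ax.plot(xs, ys, label=str(lev))
        ax.set_xlabel(self.model.modifier)
        ax.set_ylabel(self.model.outcome)
        ax.legend(title=self.model.exposure)
        return ax


class MultinomialSubtypeModel:
    """Multinomial logit of depression subtype with bootstrap inference.

    Reports per-modifier-category sample-averaged predicted probabilities of
    each subtype (with bootstrap SEs) and pairwise category differences.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        subtype: str = "subtype",
        modifier: str = "eprs_cat",
        covariates: Sequence[str] | None = None,
    ):
        import statsmodels.api as sm  # deferred: heavy import

        self._sm = sm
        self.subtype = subtype
        self.modifier = modifier
        self.covariates = list(DEFAULT_COVARIATES if covariates is None else covariates)
        used = [subtype, modifier] + self.covariates
        frame = data.dropna(subset=[c for c in used if c in data.columns])
        self.frame = frame.reset_index(drop=True)
        self.subtype_levels = _levels(self.frame[subtype])
        if len(self.subtype_levels) < 2:
            raise ValueError("subtype outcome needs at least two populated levels")
        counts = self.frame[subtype].value_counts()
        empty = [str(v) for v in self.subtype_levels if counts.get(v, 0) == 0]
        if empty:
            raise ValueError(f"empty subtype levels: {empty}")
        rhs = [_term(self.frame, modifier)] + [
            _term(self.frame, c) for c in self.covariates
        ]
        self.formula_rhs = " + ".join(rhs) if rhs else "1"
        X = patsy.dmatrix(self.formula_rhs, self.frame, return_type="dataframe")
        self.design_info = X.design_info
        self.X = X.to_numpy(dtype=float)
        self.exog_names = list(X.columns)
        _check_full_rank(self.X, self.exog_names)
        codes = pd.Categorical(
            self.frame[subtype], categories=self.subtype_levels
        ).codes
        self.y = np.asarray(codes, dtype=int)

    def _fit_probs(self, X: np.ndarray, y: np.ndarray, X_eval_by_cat, start=None):
        mn = self._sm.MNLogit(y, X)
        fitres = mn.fit(method="newton", disp=0, start_params=start, maxiter=100)
        probs = {
            cat: fitres.predict(Xc).mean(axis=0) for cat, Xc in X_eval_by_cat.items()
        }
        return fitres.params, probs

    def fit(self, n_boot: int = 1500, seed: int | None = None) -> "MultinomialResults":
        rng = np.random.default_rng(seed)
        cats = _levels(self.frame[self.modifier])
        X_eval = {}
        for cat in cats:
            frame = self.frame.copy()
            frame[self.modifier] = _like_column(frame[self.modifier], cat)
            (Xc,) = patsy.build_design_matrices([self.design_info], frame)
            X_eval[cat] = np.asarray(Xc)
        params, probs = self._fit_probs(self.X, self.y, X_eval)
        boot_probs = {cat: np.empty((n_boot, len(self.subtype_levels))) for cat in cats}
        n = len(self.y)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            # evaluation design stays the full-sample one: only coefficient
            # uncertainty is propagated
            try:
                _, pb = self._fit_probs(self.X[idx], self.y[idx], X_eval, start=params)
            except Exception:
                pb = probs  # non-converged resample: fall back to point fit
            for cat in cats:
                boot_probs[cat][b] = pb[cat]
        return MultinomialResults(
            self, cats, probs, boot_probs, params, n_boot=n_boot, seed=seed
        )


class MultinomialResults:
    def __init__(self, model, categories, probs, boot_probs, params, n_boot, seed):
        self.model = model
        self.categories = categories
        self._probs = probs
        self._boot = boot_probs
        self.params = params
        self.n_boot = n_boot
        self.seed = seed

    def predicted_probabilities(self) -> pd.DataFrame:
        """Sample-averaged predicted probability (bootstrap SE) per cell."""
        rows = []
        for cat in self.categories:
            se = self._boot[cat].std(axis=0, ddof=1)
            for j, lev in enumerate(self.model.subtype_levels):
                rows.append(
                    {
                        self.model.modifier: cat,
                        self.model.subtype: lev,
                        "probability": float(self._probs[cat][j]),
                        "se": float(se[j]),
                    }
                )
        return pd.DataFrame(rows)

    def category_differences(self) -> pd.DataFrame:
        """Pairwise modifier-category differences in each subtype probability."""
        rows = []
        for a, b in combinations(self.categories, 2):
            diff = self._probs[b] - self._probs[a]
            draws = self._boot[b] - self._boot[a]
            se = draws.std(axis=0, ddof=1)
            p = _boot_pvalue(diff, se)
            for j, lev in enumerate(self.model.subtype_levels):
                rows.append(
                    {
                        "comparison": f"{b} vs {a}",
                        self.model.subtype: lev,
                        "difference": float(diff[j]),
                        "se": float(se[j]),
                        "pvalue": float(p[j]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            f"Multinomial subtype model (n={len(self.model.y)},"
            f" n_boot={self.n_boot}, seed={self.seed})\n"
        )
        return head + self.predicted_probabilities().to_string(
            index=False, float_format="%.4f"
        )


def adjust_bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, m * p); m defaults to the family size."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    adj = np.minimum(1.0, m * p)
    if np.isscalar(p_values) or np.ndim(p_values) == 0:
        return float(adj[0])
    return adj


# -- plan-level convenience wrappers -----------------------------------------


def fit_glm_bootstrap(data: pd.DataFrame, plan: AnalysisPlan) -> BootstrapGLMResults:
    """Fit the plan's adjusted linear model with bootstrap inference."""
    model = BootstrapGLM.from_plan(data, plan)
    return model.fit(n_boot=plan.n_boot, seed=plan.seed)


def test_interaction(data: pd.DataFrame, plan: AnalysisPlan) -> InteractionResults:
    """Fit the exposure x modifier interaction model from an analysis plan."""
    model = InteractionModel(
        data,
        outcome=plan.outcome,
        exposure=plan.exposure or "subtype",
        modifier=plan.modifier or "eprs_z",
        covariates=plan.covariates,
    )
    return model.fit(n_boot=plan.n_boot, seed=plan.seed)


def fit_multinomial_probs(
    data: pd.DataFrame,
    subtype: str = "subtype",
    modifier_category: str = "eprs_cat",
    covariates: Sequence[str] | None = None,
    n_boot: int = 1500,
    seed: int | None = None,
) -> MultinomialResults:
    """Bootstrap multinomial logit: mean predicted subtype probabilities per
    modifier category, with bootstrap SEs and pairwise category differences."""
    model = MultinomialSubtypeModel(
        data, subtype=subtype, modifier=modifier_category, covariates=covariates
    )
    return model.fit(n_boot=n_boot, seed=seed)


def estimate_adjusted_means(
    results: BootstrapGLMResults, group: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted group means and pairwise contrasts from a fitted model."""
    return results.adjusted_means(group, alpha=alpha), results.contrasts(
        group, alpha=alpha
    )
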