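"""Inference layer: pattern permutation test, mixed models, ANOVA, LRT.

Three families of tests operate on the pipeline outputs:

* a label-permutation test on cross-day spatial-pattern correlations
  (are the feedback-day patterns less similar to the rest?),
* linear mixed-effects models on run-level ERDd scores (REML fits with
  Satterthwaite-approximated, generally fractional, degrees of freedom,
  and a parametric-bootstrap "simulated" likelihood-ratio test), and
* fixed-effects factorial ANOVA on cross-validated classifier
  accuracies.

The mixed models themselves are fitted with statsmodels ``MixedLM``;
the Satterthwaite machinery (REML criterion on natural-scale variance
parameters, numerical Hessian, delta method on Var(c'beta)) and the
bootstrap loop are implemented here, since no installed package exposes
them for Python mixed models.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from .synthetic import FAMILIAR_TYPES

# ---------------------------------------------------------------------------
# permutation test on cross-day pattern correlations


@dataclass
class PermutationResult:
    observed_statistic: float
    null_sample: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def _feedback_statistic(R: np.ndarray, fb_mask: np.ndarray) -> float:
    """mean rho(feedback, non-feedback) - mean rho(non-feedback pairs)."""
    nf = ~fb_mask
    cross = R[np.ix_(fb_mask, nf)].mean()
    sub = R[np.ix_(nf, nf)]
    off = sub[~np.eye(sub.shape[0], dtype=bool)]
    return float(cross - off.mean())


def feedback_pattern_permutation(
    patterns_by_day: np.ndarray,
    feedback_days: tuple[int, int] = (1, 6),
    n_permutations: int = 100_000,
    seed: int = 0,
) -> PermutationResult:
    """Left-tailed permutation test of feedback-related pattern change.

    ``patterns_by_day`` holds one mean forward model per day (rows) for
    a single source; the statistic is the mean correlation between
    feedback-day and non-feedback-day patterns minus the mean
    correlation among non-feedback patterns, so a *small* value means
    the feedback-day patterns stand apart.  The null reassigns the two
    pseudo-feedback days uniformly over the non-identity day pairs;
    the add-one rule represents the identity assignment exactly once,
    keeping the p-value valid (P(p <= a) <= a under the null).
    """
    P = np.asarray(patterns_by_day, float)
    n_days = P.shape[0]
    if P.ndim != 2 or n_days < 3:
        raise ValueError("need one pattern per day for at least 3 days")
    if np.any(P.std(axis=1) == 0):
        raise ValueError("zero-variance (constant) pattern")
    # pairwise sign alignment: forward-model polarity is arbitrary, so the
    # similarity of two patterns is |rho|; unlike aligning everything to a
    # reference day this keeps the days exchangeable under the null
    R = np.abs(np.corrcoef(P))
    np.fill_diagonal(R, 1.0)
    days = np.arange(1, n_days + 1)
    true_pair = frozenset(feedback_days)
    if not true_pair <= set(days) or len(true_pair) != 2:
        raise ValueError(f"feedback_days must be 2 distinct days in 1..{n_days}")
    observed = _feedback_statistic(R, np.isin(days, list(true_pair)))
    others = [pair for pair in itertools.combinations(days, 2)
              if frozenset(pair) != true_pair]
    values = np.array([
        _feedback_statistic(R, np.isin(days, pair)) for pair in others])
    rng = np.random.default_rng(seed)
    null = values[rng.integers(0, len(values), n_permutations)]
    p = (np.sum(null <= observed + 1e-12) + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_statistic=observed,
        null_sample=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# linear mixed-effects models on run-level ERDd

def _familiar(df):
    return df[df["imageryType"].isin(FAMILIAR_TYPES)]


def _familiar_mid_days(df):
    return _familiar(df)[lambda d: d["day"].between(2, 5)]


def _thumb(df):
    return df[df["imageryType"].isin(("TR", "TRv"))]


#: the model catalogue: fixed formula, random-effects formula, row filter
MODEL_SPECS = {
    # does ERD strength drift over the no-feedback days 2-5?
    "4a": ("ERDd ~ 1 + day * imageryType", "~1 + day", _familiar_mid_days),
    "4b": ("ERDd ~ 1 + imageryType", "~1", _familiar_mid_days),
    # per-subject feedback effect, familiar imageries, all days
    "5": ("ERDd ~ 1 + isFeedbacked * subject", "~1 + imageryType", _familiar),
    # novel thumb imagery: feedback vs static cue vs video guidance
    "6": ("ERDd ~ 1 + videoORfeed", "~1", _thumb),
}


@dataclass
class LMEFit:
    """A fitted mixed model plus the pieces inference needs."""

    formula: str
    re_formula: str
    method: str
    result: object                  # statsmodels MixedLMResults
    data: pd.DataFrame
    converged: bool
    tag: str | None = None
    _mach: object = field(default=None, repr=False)

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    def machinery(self) -> "_REMLMachinery":
        if self._mach is None:
            self._mach = _REMLMachinery(self.result)
        return self._mach

    def fixed_effects_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Estimate / SE / 95 % CI / t / Satterthwaite df / p per coefficient."""
        mach = self.machinery()
        rows = []
        names = list(self.result.model.exog_names)
        for i, name in enumerate(names):
            c = np.zeros(len(names))
            c[i] = 1.0
            rows.append(self._contrast_row(name, c, mach, alpha))
        return pd.DataFrame(rows).set_index("term")

    def _contrast_row(self, name, c, mach, alpha=0.05):
        est = float(c @ self.fe_params.to_numpy())
        var, df = mach.satterthwaite(c)
        se = np.sqrt(var)
        t = est / se if se > 0 else np.nan
        tq = sps.t.ppf(1 - alpha / 2, df)
        return {
            "term": name, "estimate": est, "se": se,
            "ci_lower": est - tq * se, "ci_upper": est + tq * se,
            "t": t, "df": df,
            "p": float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else np.nan,
        }

    def contrast(self, c: np.ndarray, name: str = "contrast") -> dict:
        """t-test of a single linear combination of the fixed effects."""
        return self._contrast_row(name, np.asarray(c, float), self.machinery())

    def feedback_effects_by_subject(self) -> pd.DataFrame:
        """Per-subject feedback effect (main + interaction contrast)."""
        names = list(self.result.model.exog_names)
        if "isFeedbacked" not in names:
            raise ValueError("model has no isFeedbacked term")
        subjects = sorted(self.data["subject"].unique())
        rows = []
        for s in subjects:
            c = np.zeros(len(names))
            c[names.index("isFeedbacked")] = 1.0
            inter = f"isFeedbacked:subject[T.{s}]"
            if inter in names:
                c[names.index(inter)] = 1.0
            rows.append(self.contrast(c, name=s))
        return pd.DataFrame(rows).set_index("term").rename_axis("subject")


def prepare_erdd_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate/coerce the run-level ERDd schema for model fitting."""
    required = {"subject", "day", "imageryType", "isFeedbacked", "ERDd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ERDd table lacks columns {sorted(missing)}")
    out = table.copy()
    out["isFeedbacked"] = out["isFeedbacked"].astype(int)
    out["day"] = out["day"].astype(float)
    return out


def fit_lme(
    table: pd.DataFrame,
    formula: str = "5",
    method: str = "REML",
) -> LMEFit:
    """Fit one of the catalogue models (or a custom pair of formulas).

    ``formula`` is a tag from :data:`MODEL_SPECS` or a tuple
    ``(fixed_formula, re_formula)`` applied to the table as-is.
    ``method`` is REML (parameter inference) or ML (model comparison).
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    tag = None
    if isinstance(formula, str) and formula in MODEL_SPECS:
        tag = formula
        fixed, re_form, row_filter = MODEL_SPECS[formula]
        data = row_filter(prepare_erdd_table(table)).reset_index(drop=True)
    elif isinstance(formula, (tuple, list)) and len(formula) == 2:
        fixed, re_form = formula
        data = prepare_erdd_table(table)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if data.empty:
        raise ValueError(f"no rows left for model {formula!r}")
    model = smf.mixedlm(fixed, data, groups=data["subject"],
                        re_formula=re_form)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for optimizer in ("bfgs", "powell", "lbfgs", "cg"):
            try:
                candidate = model.fit(reml=(method == "REML"),
                                      method=optimizer, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
            if not np.isfinite(candidate.llf):
                continue
            # prefer converged fits; break ties by likelihood
            if (result is None
                    or (candidate.converged and not result.converged)
                    or (candidate.converged == result.converged
                        and candidate.llf > result.llf)):
                result = candidate
            if result.converged:
                break
    if result is None:  # every optimizer diverged
        raise ValueError(f"mixed model {formula!r} could not be fitted")
    converged = bool(getattr(result, "converged", True))
    if not converged:
        warnings.warn(f"mixed model {formula!r} did not converge",
                      UserWarning, stacklevel=2)
    return LMEFit(formula=fixed, re_formula=re_form, method=method,
                  result=result, data=data, converged=converged, tag=tag)


class _REMLMachinery:
    """Satterthwaite df from an explicit REML criterion.

    Works on the natural scale: phi = (vech of the random-effect
    covariance G, residual variance s2).  Variance components whose
    fitted diagonal is numerically zero sit on the boundary and are
    held fixed (excluded from the uncertainty propagation).
    """

    def __init__(self, result, drop_tol: float = 1e-8):
        model = result.model
        self.X = np.asarray(model.exog, float)
        self.y = np.asarray(model.endog, float)
        Zfull = np.asarray(model.exog_re, float)
        if Zfull.ndim == 1:
            Zfull = Zfull[:, None]
        self.groups = [np.asarray(idx, int)
                       for idx in model.row_indices.values()]
        self.G = np.atleast_2d(np.asarray(result.cov_re, float))
        self.s2 = float(result.scale)
        self.k_re = self.G.shape[0]
        self.Z = Zfull
        # active (off-boundary) random-effect components
        self.active = np.flatnonzero(np.diag(self.G) > drop_tol * self.s2)
        ii, jj = np.tril_indices(len(self.active))
        self._tri = (self.active[ii], self.active[jj])
        self.phi_hat = np.concatenate([
            self.G[self._tri], [self.s2]])
        self._cache = {}

    # -- phi packing --------------------------------------------------
    def _unpack(self, phi):
        G = np.zeros_like(self.G)
        vals = phi[:-1]
        G[self._tri] = vals
        G[(self._tri[1], self._tri[0])] = vals
        return G, float(phi[-1])

    def _per_group(self, phi):
        """Return (XtViX, XtViy, logdetV, quad at beta-hat)."""
        G, s2 = self._unpack(phi)
        p = self.X.shape[1]
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        logdet = 0.0
        ytViy = 0.0
        per = []
        for idx in self.groups:
            Xg, yg, Zg = self.X[idx], self.y[idx], self.Z[idx]
            V = Zg @ G @ Zg.T + s2 * np.eye(len(idx))
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                # boundary fits can leave V semidefinite; nudge the ridge
                V = V + (1e-8 * max(s2, np.trace(V) / len(idx))
                         + 1e-12) * np.eye(len(idx))
                cf = cho_factor(V, lower=True)
            logdet += 2.0 * np.sum(np.log(np.diag(cf[0])))
            ViX = cho_solve(cf, Xg)
            Viy = cho_solve(cf, yg)
            XtViX += Xg.T @ ViX
            XtViy += Xg.T @ Viy
            ytViy += yg @ Viy
            per.append((Xg, yg, cf))
        return XtViX, XtViy, logdet, ytViy, per

    def reml_loglike(self, phi) -> float:
        """REML criterion up to an additive constant."""
        try:
            XtViX, XtViy, logdet, ytViy, _ = self._per_group(phi)
            beta = np.linalg.solve(XtViX, XtViy)
            quad = ytViy - XtViy @ beta
            sign, logdet_X = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return -np.inf
            return -0.5 * (logdet + logdet_X + quad)
        except np.linalg.LinAlgError:
            return -np.inf

    def fe_cov(self, phi=None) -> np.ndarray:
        """GLS covariance of the fixed effects, (X' V^-1 X)^-1."""
        phi = self.phi_hat if phi is None else phi
        XtViX, *_ = self._per_group(phi)
        try:
            return np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(XtViX, hermitian=True)

    # -- Satterthwaite ------------------------------------------------
    def _steps(self):
        return 1e-3 * (np.abs(self.phi_hat) + 1e-2 * self.s2)

    def vcov_phi(self) -> np.ndarray:
        if "vcov_phi" in self._cache:
            return self._cache["vcov_phi"]
        k = len(self.phi_hat)
        h = self._steps()
        H = np.zeros((k, k))
        f0 = self.reml_loglike(self.phi_hat)
        for i in range(k):
            for j in range(i, k):
                pp = self.phi_hat.copy()
                if i == j:
                    pp[i] += h[i]
                    fp = self.reml_loglike(pp)
                    pp[i] -= 2 * h[i]
                    fm = self.reml_loglike(pp)
                    H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
                else:
                    vals = []
                    for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                        pp = self.phi_hat.copy()
                        pp[i] += si * h[i]
                        pp[j] += sj * h[j]
                        vals.append(self.reml_loglike(pp))
                    H[i, j] = H[j, i] = (
                        vals[0] - vals[1] - vals[2] + vals[3]
                    ) / (4 * h[i] * h[j])
        cov = np.linalg.pinv(-H, hermitian=True)
        # clip to PSD in case the numerical Hessian is slightly indefinite
        evals, evecs = np.linalg.eigh(cov)
        cov = (evecs * np.clip(evals, 0, None)) @ evecs.T
        self._cache["vcov_phi"] = cov
        return cov

    def satterthwaite(self, c: np.ndarray) -> tuple[float, float]:
        """(Var(c'beta), denominator df) for a 1-df contrast."""
        c = np.asarray(c, float)
        f0 = float(c @ self.fe_cov() @ c)
        h = self._steps()
        grad = np.zeros(len(self.phi_hat))
        for i in range(len(self.phi_hat)):
            pp = self.phi_hat.copy()
            pp[i] += h[i]
            fp = float(c @ self.fe_cov(pp) @ c)
            pp[i] -= 2 * h[i]
            fm = float(c @ self.fe_cov(pp) @ c)
            grad[i] = (fp - fm) / (2 * h[i])
        denom = float(grad @ self.vcov_phi() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return f0, np.inf
        return f0, 2.0 * f0**2 / denom

    def satterthwaite_F(self, L: np.ndarray, beta: np.ndarray):
        """(F, num df, den df) for a multi-row contrast, per lmerTest.

        The contrast covariance L C L' is eigendecomposed; each
        eigen-direction gets a 1-df Satterthwaite df and the dfs are
        combined through E = sum nu/(nu-2) into ddf = 2E/(E-q).
        """
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        C = self.fe_cov()
        M = L @ C @ L.T
        evals, P = np.linalg.eigh(M)
        evals = np.maximum(evals, 1e-300)
        Lb = L @ beta
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
        nus = []
        for k in range(q):
            ck = (P[:, k] @ L) / np.sqrt(evals[k])
            _, nu = self.satterthwaite(ck)
            nus.append(nu)
        nus = np.asarray(nus)
        finite = nus[np.isfinite(nus) & (nus > 2)]
        if len(finite) < q:
            return F, q, np.inf
        E = float(np.sum(finite / (finite - 2)))
        ddf = 2 * E / (E - q) if E > q else np.inf
        return F, q, ddf


def lme_anova(fit: LMEFit) -> pd.DataFrame:
    """Marginal F-tests per fixed-effect term, Satterthwaite denominators."""
    if not fit.converged:
        raise ValueError("refusing to run ANOVA on an unconverged fit")
    design = fit.result.model.data.design_info
    mach = fit.machinery()
    beta = fit.fe_params.to_numpy()
    p = len(beta)
    rows = []
    for term, sl in design.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(p)[sl]
        L = np.zeros((len(idx), p))
        L[np.arange(len(idx)), idx] = 1.0
        F, dfn, dfd = mach.satterthwaite_F(L, beta)
        rows.append({
            "term": term, "F": F, "df_num": dfn, "df_den": dfd,
            "p": float(sps.f.sf(F, dfn, dfd)) if np.isfinite(dfd)
            else float(sps.chi2.sf(F * dfn, dfn)),
        })
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# simulated (parametric bootstrap) likelihood-ratio test


@dataclass
class SimulatedLRTResult:
    statistic: float
    p_value: float
    p_ci: tuple[float, float]
    null_sample: np.ndarray
    n_simulations: int
    df_difference: int
    n_failures: int = 0


def _simulate_response(fit: LMEFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from the fitted (reduced) model."""
    model = fit.result.model
    mach = fit.machinery()
    y = model.exog @ fit.fe_params.to_numpy()
    y = np.array(y, float)
    G = np.atleast_2d(np.asarray(fit.result.cov_re, float))
    s2 = float(fit.result.scale)
    # PSD square root of G (fits on the boundary have singular G)
    evals, evecs = np.linalg.eigh(G)
    Ghalf = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    for idx in mach.groups:
        b = Ghalf @ rng.standard_normal(G.shape[0])
        y[idx] += mach.Z[idx] @ b
    y += np.sqrt(s2) * rng.standard_normal(len(y))
    return y


def _check_nested(full: LMEFit, reduced: LMEFit):
    fe_full = set(full.result.model.exog_names)
    fe_red = set(reduced.result.model.exog_names)
    if not fe_red <= fe_full:
        raise ValueError(
            f"models are not nested: {sorted(fe_red - fe_full)} only in "
            "the reduced model")


def simulated_lrt(
    table: pd.DataFrame,
    full: str = "4a",
    reduced: str = "4b",
    n_sim: int = 1000,
    seed: int = 0,
) -> SimulatedLRTResult:
    """Parametric-bootstrap likelihood-ratio test of nested ML fits.

    The observed statistic is 2(l_full - l_reduced) from ML fits; the
    null distribution is built by simulating responses from the reduced
    ML fit and refitting both models.  The p-value uses the add-one
    rule with a Clopper-Pearson 95 % interval.
    """
    fit_full = fit_lme(table, full, method="ML")
    fit_red = fit_lme(table, reduced, method="ML")
    _check_nested(fit_full, fit_red)
    observed = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
    df_diff = (len(fit_full.result.model.exog_names)
               - len(fit_red.result.model.exog_names))

    rng = np.random.default_rng(seed)
    base = fit_red.data
    null, failures = [], 0
    for _ in range(n_sim):
        sim_table = base.copy()
        sim_table["ERDd"] = _simulate_response(fit_red, rng)
        try:
            f = fit_lme(sim_table, (fit_full.formula, fit_full.re_formula),
                        method="ML")
            r = fit_lme(sim_table, (fit_red.formula, fit_red.re_formula),
                        method="ML")
            null.append(max(0.0, 2.0 * (f.llf - r.llf)))
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
    null = np.asarray(null)
    n_eff = len(null)
    k = int(np.sum(null >= observed - 1e-10))
    p = (k + 1) / (n_eff + 1)
    lo = sps.beta.ppf(0.025, k, n_eff - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(0.975, k + 1, n_eff - k)
    return SimulatedLRTResult(
        statistic=observed, p_value=float(p),
        p_ci=(float(lo), float(hi)),
        null_sample=null, n_simulations=n_eff,
        df_difference=df_diff, n_failures=failures,
    )


# ---------------------------------------------------------------------------
# factorial ANOVA on classifier accuracies


def accuracy_anova(
    accuracies: pd.DataFrame,
    factors: tuple[str, ...] = ("subject", "feedback"),
    response: str = "accuracy",
    interactions: bool = False,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA (type-II sums of squares).

    The study's two-way (subject x feedback) and three-way (adding
    cv-scheme) analyses are additive; pass ``interactions=True`` for a
    full factorial.  Empty factor-level cells are flagged with a
    warning (type-II SS remain well defined for additive models).
    """
    for f in factors:
        if f not in accuracies.columns:
            raise ValueError(f"missing factor column {f!r}")
        if accuracies[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if len(factors) >= 2:
        counts = accuracies.groupby(list(factors), observed=True).size()
        full = np.prod([accuracies[f].nunique() for f in factors])
        if len(counts) < full:
            warnings.warn("empty cells in the factorial design",
                          UserWarning, stacklevel=2)
    op = " * " if interactions else " + "
    formula = f"{response} ~ " + op.join(f"C(Q('{f}'))" for f in factors)
    resp = accuracies[response].to_numpy(float)
    degenerate = np.var(resp) < 1e-18 * max(1.0, np.mean(resp) ** 2)
    fit = smf.ols(formula, data=accuracies).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = anova_lm(fit, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    out = []
    for term in table.index:
        if term == "Residual":
            continue
        name = term
        for f in factors:
            name = name.replace(f"C(Q('{f}'))", f)
        F = table.loc[term, "F"]
        if degenerate or not np.isfinite(F):  # 0/0 on a flat response
            F = 0.0
        out.append({
            "term": name, "F": float(F),
            "df_num": float(table.loc[term, "df"]), "df_den": resid_df,
            "p": float(sps.f.sf(F, table.loc[term, "df"], resid_df)),
        })
    return pd.DataFrame(out).set_index("term")
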