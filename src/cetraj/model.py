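"""Piecewise linear mixed models around an aligned time origin.

The fixed-effect design splits centred time ``t`` into ``pre_time =
min(t, 0)`` and ``post_time = max(t, 0)`` so the two pieces join at the
origin, and crosses both with the exposure-group indicator and with
age-at-origin (aget0, centred at the analysis-sample mean).  Optional
higher-order time terms (quadratic/cubic, each with its group and aget0
interactions), a step-change ("discontinuity") indicator at t >= 0, and a
practice-effect assessment-round index can be added.  Time-updating
covariates vary before the origin and are carried forward (frozen at
their value at or last before t = 0) afterwards, so post-exposure
mediators are not adjusted away.

Random structure: per-participant random intercept, random pre-slope and
random post-slope with an unstructured 3x3 covariance, estimated by
maximum likelihood via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
No clustering beyond the participant level is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import TIME_UPDATING_COVARIATES, EDUCATION_LEVELS, LABOUR_FORCE_LEVELS, HEARING_LEVELS
from .errors import CohortIntegrityError, ConvergenceError, SpecificationError

#: Supported higher-order time terms, by (piece, degree).
HIGHER_ORDER_TERMS = {"pre2": ("pre", 2), "pre3": ("pre", 3), "post2": ("post", 2), "post3": ("post", 3)}

RE_LABELS = ["intercept", "pre_slope", "post_slope"]


def carry_forward_covariates(
    data: pd.DataFrame, columns=tuple(TIME_UPDATING_COVARIATES), baseline_fallback: bool = False
) -> pd.DataFrame:
    """Freeze time-updating covariates at their value at (or last before) t = 0.

    Rows with ``t < 0`` keep their observed values (missing cells filled by
    last observation carried forward within the pre-origin window); every
    row with ``t >= 0`` takes the participant's value at the last
    observation with ``t <= 0``.  A participant with no observation at or
    before the origin raises :class:`CohortIntegrityError`, unless
    ``baseline_fallback`` is set, in which case their earliest observed
    value is used (useful for controls whose assigned origin precedes
    their first interview).
    """
    cols = [c for c in columns if c in data.columns]
    out = data.sort_values(["participant_id", "t"], kind="mergesort").copy()
    gid = out["participant_id"]
    is_pre = out["t"] <= 0

    no_pre = ~is_pre.groupby(gid.values).transform("max")
    if no_pre.any() and not baseline_fallback:
        bad = out.loc[no_pre, "participant_id"].unique().tolist()
        raise CohortIntegrityError(
            f"participants with no observation at or before t=0: {bad[:10]} "
            "(pass baseline_fallback=True to freeze at their earliest observation)"
        )

    for col in cols:
        pre_vals = out[col].where(is_pre)
        locf = pre_vals.groupby(gid.values).ffill()
        frozen = locf.groupby(gid.values).transform("last")
        if baseline_fallback:
            first = out[col].groupby(gid.values).transform("first")
            frozen = frozen.where(~no_pre, first)
        out[col] = locf.where(is_pre, frozen)
        # pre-window gaps before the first observed value: nothing to carry
        out[col] = out[col].where(is_pre | frozen.notna() | out[col].notna(), np.nan)
    return out


def _covariate_block(data: pd.DataFrame) -> pd.DataFrame:
    """Adjustment-covariate columns (dummy-coded, deterministic order)."""
    X = pd.DataFrame(index=data.index)
    # birth-cohort proxy from wave timing and age (constant per participant
    # when interviews are exactly biennial)
    proxy = 2.0 * (data["wave"] - 1) - data["age"]
    X["birth_cohort"] = proxy - proxy.mean()
    X["female"] = (data["sex"] == "female").astype(float)
    for lev in EDUCATION_LEVELS[1:]:
        X[f"edu_{lev}"] = (data["education_level"] == lev).astype(float)
    for lev in LABOUR_FORCE_LEVELS[1:]:
        X[f"lf_{lev}"] = (data["labour_force"] == lev).astype(float)
    X["wealth_z"] = pd.to_numeric(data["wealth_z"], errors="coerce")
    X["smoker"] = pd.to_numeric(data["smoker"], errors="coerce")
    X["alcohol"] = pd.to_numeric(data["alcohol"], errors="coerce")
    X["mvpa_weekly"] = pd.to_numeric(data["mvpa_weekly"], errors="coerce")
    for lev in HEARING_LEVELS[1:]:
        X[f"hearing_{lev}"] = (data["hearing"] == lev).astype(float)
    X["cesd"] = pd.to_numeric(data["cesd"], errors="coerce")
    for cond in ("hypertension", "heart_disease", "stroke", "cancer", "diabetes", "psychiatric"):
        X[cond] = pd.to_numeric(data[cond], errors="coerce")
    return X


def time_columns(t, group, aget0_c, terms=(), discontinuity=False):
    """Fixed-effect time/group columns for time ``t`` and group ``group``.

    ``t`` and ``group`` may be scalars or arrays; ``aget0_c`` is the
    centred age-at-origin (scalar or array).  Returns an ordered dict of
    column name -> values satisfying pre + post = t and pre * post = 0.
    """
    t = np.asarray(t, dtype=float)
    group = np.asarray(group, dtype=float)
    aget0_c = np.asarray(aget0_c, dtype=float)
    pre = np.minimum(t, 0.0)
    post = np.maximum(t, 0.0)
    cols = {
        "pre_time": pre,
        "post_time": post,
        "group": group * np.ones_like(t),
        "group_pre": group * pre,
        "group_post": group * post,
        "aget0": aget0_c * np.ones_like(t),
        "aget0_pre": aget0_c * pre,
        "aget0_post": aget0_c * post,
    }
    for name in sorted(terms, key=lambda n: (HIGHER_ORDER_TERMS[n][0], HIGHER_ORDER_TERMS[n][1])):
        piece, deg = HIGHER_ORDER_TERMS[name]
        base = (pre if piece == "pre" else post) ** deg
        cols[name] = base
        cols[f"group_{name}"] = group * base
        cols[f"aget0_{name}"] = aget0_c * base
    if discontinuity:
        D = (t >= 0.0).astype(float)
        cols["disc"] = D
        cols["group_disc"] = group * D
    return cols


def build_design(
    data: pd.DataFrame,
    outcome: str = "memory_z",
    terms=(),
    discontinuity: bool = False,
    practice_effect: bool = False,
    age_t0_center: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Construct the full fixed-effect design from a matched long table.

    ``data`` must carry ``participant_id``, ``t``, ``group``, ``age_t0``,
    ``wave``, the outcome column and the adjustment covariates (after
    carry-forward).  Rows with a missing outcome are dropped (the mixed
    model uses all remaining observations).  Returns ``(design, meta)``
    where ``design`` holds ``participant_id``, the outcome and the fixed
    columns, and ``meta`` records the column list and aget0 centre.
    """
    bad = [n for n in terms if n not in HIGHER_ORDER_TERMS]
    if bad:
        raise SpecificationError(f"unknown higher-order terms: {bad}")

    d = data[data[outcome].notna()].reset_index(drop=True)
    center = float(d["age_t0"].mean()) if age_t0_center is None else float(age_t0_center)
    aget0_c = d["age_t0"].to_numpy(dtype=float) - center

    X = pd.DataFrame({"const": np.ones(len(d))})
    for name, vals in time_columns(
        d["t"].to_numpy(dtype=float), d["group"].to_numpy(dtype=float), aget0_c, terms, discontinuity
    ).items():
        X[name] = vals
    if practice_effect:
        X["assessment_round"] = d["assessment_round"].to_numpy(dtype=float) - 1.0
    X = pd.concat([X, _covariate_block(d)], axis=1)

    bad_rows = ~np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if bad_rows.any():
        idx = np.flatnonzero(bad_rows)[:10].tolist()
        raise CohortIntegrityError(f"non-finite covariate values after carry-forward at rows {idx}")

    design = pd.concat([d[["participant_id", outcome]], X], axis=1)
    meta = {
        "outcome": outcome,
        "terms": sorted(terms, key=lambda n: HIGHER_ORDER_TERMS[n]),
        "discontinuity": discontinuity,
        "practice_effect": practice_effect,
        "age_t0_center": center,
        "columns": list(X.columns),
    }
    return design, meta


def _drop_aliased_columns(X: pd.DataFrame, tol: float = 1e-9) -> tuple[pd.DataFrame, list]:
    """Remove constant (non-intercept) and linearly dependent columns.

    A greedy left-to-right sweep, so earlier columns (the structural
    time/group block) always take precedence over later adjustment
    columns when a dependency must be broken.
    """
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    basis = np.empty((len(X), 0))
    final = []
    for c in keep:
        v = X[c].to_numpy(dtype=float)
        nv = np.linalg.norm(v)
        if basis.shape[1]:
            coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
            resid = v - basis @ coef
        else:
            resid = v
        if np.linalg.norm(resid) > max(tol, 1e-7 * nv):
            final.append(c)
            basis = np.column_stack([basis, v / (nv if nv else 1.0)])
        else:
            dropped.append(c)
    return X[final], dropped


@dataclass
class PiecewiseFit:
    """Estimates from a piecewise linear mixed model."""

    params: pd.Series
    cov_params: pd.DataFrame
    re_cov: pd.DataFrame  # 3x3: intercept, pre_slope, post_slope
    resid_var: float
    llf: float
    n_obs: int
    n_participants: int
    outcome: str
    terms: list = field(default_factory=list)
    discontinuity: bool = False
    age_t0_center: float = 0.0
    converged: bool = True
    method: str = "ml"

    @property
    def rho(self) -> pd.DataFrame:
        """Pairwise correlations of the random effects, G_ij / sqrt(G_ii G_jj)."""
        g = self.re_cov.to_numpy(dtype=float)
        sd = np.sqrt(np.clip(np.diag(g), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = g / np.outer(sd, sd)
        return pd.DataFrame(r, index=RE_LABELS, columns=RE_LABELS)

    def wald_block(self, names) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the named coefficients are all zero."""
        names = [n for n in names if n in self.params.index]
        if not names:
            raise SpecificationError("no requested coefficients present in the fit")
        b = self.params[names].to_numpy()
        V = self.cov_params.loc[names, names].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(names)
        return stat, df, float(stats.chi2.sf(stat, df))

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "params": self.params.to_dict(),
            "bse": np.sqrt(np.diag(self.cov_params)).tolist(),
            "re_cov": self.re_cov.to_numpy().tolist(),
            "rho": self.rho.to_numpy().tolist(),
            "resid_var": self.resid_var,
            "llf": self.llf,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "terms": list(self.terms),
            "discontinuity": self.discontinuity,
            "age_t0_center": self.age_t0_center,
            "converged": self.converged,
            "method": self.method,
        }


class PiecewiseLinearMixedModel(BaseEstimator):
    """Piecewise linear mixed model with random intercept and two random slopes.

    Parameters
    ----------
    outcome : str
        Outcome column in the matched long table (``memory_z`` or
        ``fluency_z``).
    terms : sequence of {"pre2", "pre3", "post2", "post3"}
        Higher-order time terms; each enters together with its group and
        aget0 interactions.
    discontinuity : bool
        Add a step indicator for t >= 0 and its group interaction.
    practice_effect : bool
        Add a (0-based) assessment-round index.
    variance_components : (G, sigma2), optional
        If given, the 3x3 random-effects covariance and residual variance
        are taken as known and the fixed effects are the exact
        generalised-least-squares solution (no iterative estimation).
        This also handles noise-free data, where maximum likelihood is
        degenerate.
    maxiter : int
        Optimizer iteration cap for maximum likelihood.

    Fitted attributes: ``fit_`` (a :class:`PiecewiseFit`), ``X_`` (the
    fixed-effect design), ``design_meta_``, ``result_`` (the statsmodels
    results object when ML was used).
    """

    def __init__(
        self,
        outcome: str = "memory_z",
        terms=(),
        discontinuity: bool = False,
        practice_effect: bool = False,
        age_t0_center: float | None = None,
        variance_components=None,
        maxiter: int = 200,
        start_params=None,
    ):
        self.outcome = outcome
        self.terms = terms
        self.discontinuity = discontinuity
        self.practice_effect = practice_effect
        self.age_t0_center = age_t0_center
        self.variance_components = variance_components
        self.maxiter = maxiter
        self.start_params = start_params

    # -- fitting -----------------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        if self.discontinuity and not (data["t"] >= 0).any():
            raise SpecificationError("discontinuity model requires observations with t >= 0")
        design, meta = build_design(
            data,
            outcome=self.outcome,
            terms=tuple(self.terms),
            discontinuity=self.discontinuity,
            practice_effect=self.practice_effect,
            age_t0_center=self.age_t0_center,
        )
        ycol = design[self.outcome].to_numpy(dtype=float)
        X = design[meta["columns"]]
        groups = design["participant_id"].to_numpy()
        if len(design) < 2 or (self.variance_components is None and np.std(ycol) == 0):
            raise SpecificationError("outcome is degenerate (fewer than 2 rows or zero variance)")

        # drop empty or aliased adjustment columns (e.g. a covariate level
        # absent from a small matched sample), as any sane LS software does;
        # structural time/group columns are never dropped
        X, dropped = _drop_aliased_columns(X)
        meta = dict(meta, columns=list(X.columns), dropped_columns=dropped)

        if self.variance_components is not None:
            fitres = self._fit_gls(ycol, X, groups, design, meta)
        else:
            fitres = self._fit_ml(ycol, X, groups, design, meta)
        self.X_ = X
        self.design_meta_ = meta
        self.design_ = design
        self.fit_ = fitres
        return self

    def _zmat(self, X: pd.DataFrame) -> np.ndarray:
        return X[["const", "pre_time", "post_time"]].to_numpy(dtype=float)

    def _fit_ml(self, y, X, groups, design, meta) -> PiecewiseFit:
        # random slopes are parameterised per decade internally: the slope
        # variances are then within ~an order of magnitude of the intercept
        # variance, which keeps the optimizer off the boundary; estimates
        # are rescaled back to per-year units below
        Zs = X[["const", "pre_time", "post_time"]].copy()
        Zs["pre_time"] = Zs["pre_time"] / 10.0
        Zs["post_time"] = Zs["post_time"] / 10.0
        model = sm.MixedLM(y, X, groups=groups, exog_re=Zs)
        start = self.start_params
        if start is not None and len(np.asarray(start)) != X.shape[1] + 6:
            start = None  # stale warm start from a differently shaped design
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            attempts = [(m, start) for m in ("lbfgs", "bfgs")]
            if start is not None:
                attempts += [("lbfgs", None), ("bfgs", None)]
            attempts += [("cg", None), ("powell", None)]
            k_fe = X.shape[1]
            for method, sp in attempts:
                try:
                    cand = model.fit(reml=False, method=method, maxiter=self.maxiter, start_params=sp)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                # a usable fit needs a valid fixed-effect covariance, not just
                # an optimizer success flag (near-boundary Hessians can be
                # indefinite)
                d = np.diag(np.asarray(cand.cov_params())[:k_fe, :k_fe])
                if cand.converged and np.all(np.isfinite(d)) and np.all(d > 0):
                    res = cand
                    break
                res = res or cand
        if res is not None:
            d = np.diag(np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]])
            if not (np.all(np.isfinite(d)) and np.all(d > 0)):
                res = None
        if res is None or not res.converged:
            raise ConvergenceError(
                f"mixed model did not converge for outcome {self.outcome!r} "
                f"(n_obs={len(y)}, n_participants={len(np.unique(groups))})"
            )
        self.result_ = res
        k = X.shape[1]
        cov_fe = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns)
        scale_back = np.diag([1.0, 0.1, 0.1])
        re_cov = pd.DataFrame(
            scale_back @ np.asarray(res.cov_re) @ scale_back, index=RE_LABELS, columns=RE_LABELS
        )
        return PiecewiseFit(
            params=pd.Series(res.fe_params.to_numpy(), index=X.columns),
            cov_params=cov_fe,
            re_cov=re_cov,
            resid_var=float(res.scale),
            llf=float(res.llf),
            n_obs=len(y),
            n_participants=len(np.unique(groups)),
            outcome=self.outcome,
            terms=list(meta["terms"]),
            discontinuity=self.discontinuity,
            age_t0_center=meta["age_t0_center"],
            converged=True,
            method="ml",
        )

    def _fit_gls(self, y, X, groups, design, meta) -> PiecewiseFit:
        """Exact GLS fixed effects at known variance components."""
        G, sigma2 = self.variance_components
        G = np.asarray(G, dtype=float)
        Xa = X.to_numpy(dtype=float)
        Z = self._zmat(X)
        p = Xa.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        llf = 0.0
        uniq, inv = np.unique(groups, return_inverse=True)
        order = np.argsort(inv, kind="mergesort")
        bounds = np.searchsorted(inv[order], np.arange(len(uniq) + 1))
        for gi in range(len(uniq)):
            sel = order[bounds[gi] : bounds[gi + 1]]
            Xi, Zi, yi = Xa[sel], Z[sel], y[sel]
            Vi = Zi @ G @ Zi.T + sigma2 * np.eye(len(sel))
            Li = np.linalg.cholesky(Vi)
            Xw = np.linalg.solve(Li, Xi)
            yw = np.linalg.solve(Li, yi)
            XtVX += Xw.T @ Xw
            XtVy += Xw.T @ yw
            llf -= np.log(np.diag(Li)).sum()
        beta = np.linalg.solve(XtVX, XtVy)
        cov = np.linalg.inv(XtVX)
        resid = y - Xa @ beta
        # quadratic form of residuals for the Gaussian log-likelihood
        quad = 0.0
        for gi in range(len(uniq)):
            sel = order[bounds[gi] : bounds[gi + 1]]
            Zi = Z[sel]
            Vi = Zi @ G @ Zi.T + sigma2 * np.eye(len(sel))
            ri = resid[sel]
            quad += float(ri @ np.linalg.solve(Vi, ri))
        llf += -0.5 * quad - 0.5 * len(y) * np.log(2 * np.pi)
        return PiecewiseFit(
            params=pd.Series(beta, index=X.columns),
            cov_params=pd.DataFrame(cov, index=X.columns, columns=X.columns),
            re_cov=pd.DataFrame(G, index=RE_LABELS, columns=RE_LABELS),
            resid_var=float(sigma2),
            llf=float(llf),
            n_obs=len(y),
            n_participants=len(uniq),
            outcome=self.outcome,
            terms=list(meta["terms"]),
            discontinuity=self.discontinuity,
            age_t0_center=meta["age_t0_center"],
            converged=True,
            method="gls",
        )

    # -- prediction --------------------------------------------------------
    def marginal_design(self, t: float, group: int, at_aget0: float | None = None) -> np.ndarray:
        """Design matrix at time ``t`` for group ``group``, covariates as observed.

        Every analysis row keeps its own covariate vector and aget0; only
        the time, group and their interaction columns are overridden.
        ``at_aget0`` (uncentred years) fixes aget0 for every row instead,
        for contrasts at a chosen age at exposure.
        """
        X = self.X_.copy()
        if at_aget0 is None:
            aget0_c = X["aget0"].to_numpy()
        else:
            aget0_c = np.full(len(X), float(at_aget0) - self.design_meta_["age_t0_center"])
            X["aget0"] = aget0_c
        cols = time_columns(
            np.full(len(X), float(t)),
            float(group),
            aget0_c,
            self.design_meta_["terms"],
            self.design_meta_["discontinuity"],
        )
        for name, vals in cols.items():
            X[name] = vals
        return X.to_numpy(dtype=float)


def fit_piecewise_lmm(data: pd.DataFrame, outcome: str = "memory_z", **kwargs) -> PiecewiseLinearMixedModel:
    """Fit the piecewise linear mixed model; functional wrapper over the estimator."""
    return PiecewiseLinearMixedModel(outcome=outcome, **kwargs).fit(data)


def _block_names(term: str) -> list:
    return [term, f"group_{term}", f"aget0_{term}"]


def backward_select(
    data: pd.DataFrame,
    outcome: str = "memory_z",
    candidates=("post2",),
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[PiecewiseLinearMixedModel, list]:
    """Backward selection of higher-order time terms by joint Wald tests.

    Each candidate block (the term plus its group and aget0 interactions)
    is tested in the model containing all currently retained terms.
    Cubic blocks are tested before quadratic ones, and a quadratic block
    is only eligible for testing/removal once no cubic on the same time
    piece remains.  The highest-order non-significant block (p >= alpha)
    is dropped and the model refitted until every remaining candidate is
    significant.  Returns the final fitted model and the test trail.
    """
    current = sorted(set(candidates), key=lambda n: HIGHER_ORDER_TERMS[n])
    trail = []
    while True:
        model = PiecewiseLinearMixedModel(outcome=outcome, terms=tuple(current), **fit_kwargs).fit(data)
        if not current:
            return model, trail
        testable = [
            n
            for n in current
            if n in candidates
            and not any(
                HIGHER_ORDER_TERMS[m][0] == HIGHER_ORDER_TERMS[n][0]
                and HIGHER_ORDER_TERMS[m][1] > HIGHER_ORDER_TERMS[n][1]
                for m in current
            )
        ]
        tested = []
        for name in sorted(testable, key=lambda n: -HIGHER_ORDER_TERMS[n][1]):
            stat, df, p = model.fit_.wald_block(_block_names(name))
            tested.append((name, stat, df, p))
        drop = None
        for name, stat, df, p in sorted(tested, key=lambda r: (-HIGHER_ORDER_TERMS[r[0]][1], -r[3])):
            if p >= alpha:
                drop = (name, stat, df, p)
                break
        for name, stat, df, p in tested:
            trail.append(
                {"term": name, "wald": stat, "df": df, "p": p, "action": "drop" if drop and drop[0] == name else "keep"}
            )
        if drop is None:
            return model, trail
        current = [n for n in current if n != drop[0]]


def fit_discontinuity_variant(
    data: pd.DataFrame, outcome: str = "memory_z", terms=(), **fit_kwargs
) -> PiecewiseLinearMixedModel:
    """Variant allowing a step change in level at the origin.

    Adds the t >= 0 indicator and its group interaction; the per-group
    step is the ``disc`` coefficient (controls) and ``disc + group_disc``
    (exposed).
    """
    return PiecewiseLinearMixedModel(
        outcome=outcome, terms=tuple(terms), discontinuity=True, **fit_kwargs
    ).fit(data)
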