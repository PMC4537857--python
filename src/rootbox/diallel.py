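"""Fixed-effects generation-block diallel model.

Implements the modified Eberhart–Gardner model for a trial containing three
entry classes — parental inbreds, their unordered F1 crosses, and commercial
check hybrids — grown in a replicated multi-environment design:

    Y = μ + e_i + r_ij + b_k + β(a_l + a_m) + γ(g_l + g_m) + δ·s_lm
          + eb_ik + rb_ijk + d_ilm + c_n + ec_in + ε

with design coefficients β = 1 for a parent on its own additive effect,
β = ½ for each parent of a cross, and γ = δ = 1 only for crosses. With this
generation structure the line-heterosis and specific-heterosis effects of
the classical model coincide with general (GCA) and specific (SCA)
combining ability. All genetic parameters are fixed effects: the parents
are a selected set, not a sample from a population.

Estimability comes from the usual sum-to-zero restrictions on every effect
family. Each family is represented by its full per-level coefficient matrix
multiplied by an orthonormal basis of the null space of its constraint
matrix, which yields exactly the familiar free-parameter counts (p−1
additive, p−1 GCA, p(p−3)/2 SCA columns for p parents). Type III tests are
full-versus-reduced model comparisons under this coding; significance is
adjusted with an adaptive false-discovery-rate step-up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

__all__ = [
    "DiallelSpec",
    "DesignMatrix",
    "ModelFit",
    "build_design",
    "fit_ols",
    "type3_anova",
    "estimate_contrasts",
    "adjust_fdr",
    "significance_stars",
    "repeatability",
]

CLASSES = ("parent", "F1", "check")


@dataclass(frozen=True)
class DiallelSpec:
    """The mating/trial design: parents, all unordered crosses, checks,
    environments and replications."""

    parent_ids: tuple[str, ...]
    check_ids: tuple[str, ...]
    env_ids: tuple[str, ...]
    reps_per_env: int

    def __post_init__(self):
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValueError("duplicate parent ids")
        if len(self.parent_ids) < 3:
            raise ValueError("need at least 3 parents for a diallel")
        if self.reps_per_env < 1:
            raise ValueError("reps_per_env must be >= 1")

    @property
    def crosses(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.parent_ids, 2))

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)


@dataclass
class _Term:
    """One effect family: full-level coefficient matrix and the sum-to-zero
    basis that maps its reduced columns back onto named levels."""

    name: str
    levels: list
    coef_full: np.ndarray  # n_rows x n_levels, Eq-coefficients (1, 0.5, ...)
    basis: np.ndarray      # n_levels x n_free, null space of the constraints

    @property
    def n_free(self) -> int:
        return self.basis.shape[1]

    @property
    def columns(self) -> np.ndarray:
        return self.coef_full @ self.basis


@dataclass
class DesignMatrix:
    """Reduced (estimable) design matrix plus the term bookkeeping needed to
    recover full per-level effect estimates."""

    X: np.ndarray
    terms: dict[str, _Term]
    term_slices: dict[str, slice]
    row_index: pd.Index

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelFit:
    design: DesignMatrix
    beta: np.ndarray
    cov_beta: np.ndarray         # sigma^2 * (X'X)^-
    sigma2: float
    df_resid: int
    rank: int
    fitted: np.ndarray
    residuals: np.ndarray
    row_mask: np.ndarray         # rows of the original table actually used

    def effects(self, term: str) -> pd.Series:
        """Full per-level estimates of one effect family (sum-to-zero)."""
        t = self.design.terms[term]
        sl = self.design.term_slices[term]
        return pd.Series(t.basis @ self.beta[sl], index=_level_index(t.levels), name=term)

    def effect_ses(self, term: str) -> pd.Series:
        t = self.design.terms[term]
        sl = self.design.term_slices[term]
        cov = t.basis @ self.cov_beta[sl, sl] @ t.basis.T
        return pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)),
                         index=_level_index(t.levels), name=f"{term}_se")


def _level_index(levels: list) -> pd.Index:
    if levels and isinstance(levels[0], tuple):
        return pd.Index([" x ".join(map(str, lv)) for lv in levels])
    return pd.Index([str(lv) for lv in levels])


def _sum_to_zero_basis(constraints: np.ndarray) -> np.ndarray:
    b = null_space(constraints)
    if b.size == 0:
        raise ValueError("constraints leave no free parameters")
    return b


def _main_effect(name, levels, row_level, n_rows, coef=None) -> _Term:
    """A plain categorical family with one overall sum-to-zero constraint."""
    L = len(levels)
    pos = {lv: i for i, lv in enumerate(levels)}
    cf = np.zeros((n_rows, L))
    for r, lv in enumerate(row_level):
        if lv is None or (isinstance(lv, float) and np.isnan(lv)):
            continue
        c = 1.0 if coef is None else coef[r]
        if c:
            cf[r, pos[lv]] += c
    return _Term(name, list(levels), cf, _sum_to_zero_basis(np.ones((1, L))))


def build_design(spec: DiallelSpec, data: pd.DataFrame) -> DesignMatrix:
    """Build the sum-to-zero reduced design matrix for a plot table.

    ``data`` needs columns env, rep, entry_class, parent1, parent2,
    check_id. Coefficients follow the design exactly: a parent row puts 1.0
    on its own additive column; a cross row puts 0.5 on each parent's
    additive column, 1.0 on each parent's GCA column and 1.0 on its SCA
    column; a check row carries only its check column. The additive × env
    interaction inherits the β weights.
    """
    req = {"env", "rep", "entry_class", "parent1", "parent2", "check_id"}
    missing = req - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    n = len(data)
    parents = list(spec.parent_ids)
    ppos = {p: i for i, p in enumerate(parents)}
    envs = list(spec.env_ids)
    reps = list(range(1, spec.reps_per_env + 1))
    checks = list(spec.check_ids)
    crosses = spec.crosses
    xpos = {frozenset(c): i for i, c in enumerate(crosses)}

    env_col = data["env"].tolist()
    rep_col = data["rep"].tolist()
    cls_col = data["entry_class"].tolist()
    p1_col = data["parent1"].tolist()
    p2_col = data["parent2"].tolist()
    ck_col = data["check_id"].tolist()

    def _isna(v):
        return v is None or (isinstance(v, float) and np.isnan(v))

    for r in range(n):
        k = cls_col[r]
        if k not in CLASSES:
            raise ValueError(f"row {r}: unknown entry_class {k!r}")
        if k == "parent":
            if p1_col[r] not in ppos:
                raise ValueError(f"row {r}: unknown parent {p1_col[r]!r}")
        elif k == "F1":
            if p1_col[r] not in ppos or p2_col[r] not in ppos:
                raise ValueError(f"row {r}: unknown parent in cross")
            if p1_col[r] == p2_col[r]:
                raise ValueError(f"row {r}: selfed cross not allowed")
            if frozenset((p1_col[r], p2_col[r])) not in xpos:
                raise ValueError(f"row {r}: cross not in design")
        else:
            if _isna(ck_col[r]) or ck_col[r] not in checks:
                raise ValueError(f"row {r}: unknown check id {ck_col[r]!r}")
        if env_col[r] not in envs:
            raise ValueError(f"row {r}: unknown env {env_col[r]!r}")

    p = len(parents)
    terms: dict[str, _Term] = {}

    # μ
    terms["intercept"] = _Term("intercept", ["mu"], np.ones((n, 1)), np.ones((1, 1)))
    # e_i
    terms["env"] = _main_effect("env", envs, env_col, n)
    # r_ij: reps nested in env, sum to zero within each env
    rep_levels = [(e, j) for e in envs for j in reps]
    cf = np.zeros((n, len(rep_levels)))
    rpos = {lv: i for i, lv in enumerate(rep_levels)}
    for r in range(n):
        cf[r, rpos[(env_col[r], rep_col[r])]] = 1.0
    C = np.zeros((len(envs), len(rep_levels)))
    for i, e in enumerate(envs):
        for j in reps:
            C[i, rpos[(e, j)]] = 1.0
    terms["rep"] = _Term("rep", rep_levels, cf, _sum_to_zero_basis(C))
    # b_k
    terms["entry_class"] = _main_effect("entry_class", list(CLASSES), cls_col, n)

    # a_l with β weights
    cf = np.zeros((n, p))
    for r in range(n):
        if cls_col[r] == "parent":
            cf[r, ppos[p1_col[r]]] = 1.0
        elif cls_col[r] == "F1":
            cf[r, ppos[p1_col[r]]] = 0.5
            cf[r, ppos[p2_col[r]]] = 0.5
    terms["additive"] = _Term("additive", parents, cf, _sum_to_zero_basis(np.ones((1, p))))

    # g_l with γ weights (crosses only)
    cf = np.zeros((n, p))
    for r in range(n):
        if cls_col[r] == "F1":
            cf[r, ppos[p1_col[r]]] = 1.0
            cf[r, ppos[p2_col[r]]] = 1.0
    terms["gca"] = _Term("gca", parents, cf, _sum_to_zero_basis(np.ones((1, p))))

    # s_lm with δ weights; constraints: for each l, sum_m s_lm = 0
    cf = np.zeros((n, len(crosses)))
    for r in range(n):
        if cls_col[r] == "F1":
            cf[r, xpos[frozenset((p1_col[r], p2_col[r]))]] = 1.0
    C = np.zeros((p, len(crosses)))
    for i, l in enumerate(parents):
        for c, (a, b) in enumerate(crosses):
            if l in (a, b):
                C[i, c] = 1.0
    terms["sca"] = _Term("sca", crosses, cf, _sum_to_zero_basis(C))

    # eb_ik: env × entry class, doubly centered
    lv = [(e, k) for e in envs for k in CLASSES]
    lpos = {x: i for i, x in enumerate(lv)}
    cf = np.zeros((n, len(lv)))
    for r in range(n):
        cf[r, lpos[(env_col[r], cls_col[r])]] = 1.0
    C = _cross_constraints(envs, list(CLASSES), lpos)
    terms["env_class"] = _Term("env_class", lv, cf, _sum_to_zero_basis(C))

    # rb_ijk: rep(env) × class; sum over reps within (env,class) and over
    # classes within (env,rep)
    lv = [(e, j, k) for e in envs for j in reps for k in CLASSES]
    lpos = {x: i for i, x in enumerate(lv)}
    cf = np.zeros((n, len(lv)))
    for r in range(n):
        cf[r, lpos[(env_col[r], rep_col[r], cls_col[r])]] = 1.0
    rows = []
    for e in envs:
        for k in CLASSES:
            c = np.zeros(len(lv));
            for j in reps:
                c[lpos[(e, j, k)]] = 1.0
            rows.append(c)
        for j in reps:
            c = np.zeros(len(lv))
            for k in CLASSES:
                c[lpos[(e, j, k)]] = 1.0
            rows.append(c)
    terms["rep_class"] = _Term("rep_class", lv, cf, _sum_to_zero_basis(np.array(rows)))

    # d_ilm: env × additive, β-weighted, doubly centered
    lv = [(e, l) for e in envs for l in parents]
    lpos = {x: i for i, x in enumerate(lv)}
    cf = np.zeros((n, len(lv)))
    for r in range(n):
        if cls_col[r] == "parent":
            cf[r, lpos[(env_col[r], p1_col[r])]] = 1.0
        elif cls_col[r] == "F1":
            cf[r, lpos[(env_col[r], p1_col[r])]] = 0.5
            cf[r, lpos[(env_col[r], p2_col[r])]] = 0.5
    C = _cross_constraints(envs, parents, lpos)
    terms["env_additive"] = _Term("env_additive", lv, cf, _sum_to_zero_basis(C))

    # c_n
    terms["checks"] = _main_effect("checks", checks, ck_col, n,
                                   coef=[1.0 if k == "check" else 0.0 for k in cls_col])
    # ec_in
    lv = [(e, c) for e in envs for c in checks]
    lpos = {x: i for i, x in enumerate(lv)}
    cf = np.zeros((n, len(lv)))
    for r in range(n):
        if cls_col[r] == "check":
            cf[r, lpos[(env_col[r], ck_col[r])]] = 1.0
    C = _cross_constraints(envs, checks, lpos)
    terms["env_check"] = _Term("env_check", lv, cf, _sum_to_zero_basis(C))

    cols = []
    slices = {}
    start = 0
    for name, t in terms.items():
        block = t.columns
        slices[name] = slice(start, start + block.shape[1])
        start += block.shape[1]
        cols.append(block)
    X = np.hstack(cols)
    return DesignMatrix(X=X, terms=terms, term_slices=slices, row_index=data.index)


def _cross_constraints(levels_a, levels_b, lpos) -> np.ndarray:
    """Row/column centering constraints of an a × b interaction family."""
    rows = []
    for a in levels_a:
        c = np.zeros(len(lpos))
        for b in levels_b:
            c[lpos[(a, b)]] = 1.0
        rows.append(c)
    for b in levels_b:
        c = np.zeros(len(lpos))
        for a in levels_a:
            c[lpos[(a, b)]] = 1.0
        rows.append(c)
    return np.array(rows)


def fit_ols(data: pd.DataFrame, design: DesignMatrix, trait: str) -> ModelFit:
    """Ordinary least squares under the sum-to-zero coding.

    Rows with a missing trait value are dropped for that trait (the
    unbalanced-design convention). A Moore–Penrose pseudoinverse handles
    rank deficiency; coefficients in a deficient direction are the
    minimum-norm solution and their covariance reflects the generalized
    inverse.
    """
    if trait not in data.columns:
        raise ValueError(f"trait column {trait!r} not in data")
    y_all = pd.to_numeric(data[trait], errors="coerce").to_numpy(dtype=float)
    mask = np.isfinite(y_all)
    if mask.sum() == 0:
        raise ValueError(f"trait {trait!r} is entirely missing")
    X = design.X[mask]
    y = y_all[mask]
    xtx = X.T @ X
    xtx_pinv = np.linalg.pinv(xtx, rcond=1e-10)
    beta = xtx_pinv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rank = int(np.linalg.matrix_rank(X, tol=1e-8))
    df_resid = int(mask.sum()) - rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    return ModelFit(
        design=design,
        beta=beta,
        cov_beta=sigma2 * xtx_pinv,
        sigma2=sigma2,
        df_resid=df_resid,
        rank=rank,
        fitted=fitted,
        residuals=resid,
        row_mask=mask,
    )


def type3_anova(
    fit: ModelFit, data: pd.DataFrame, trait: str, fdr: bool = True
) -> pd.DataFrame:
    """Type III F tests by full-vs-reduced comparison per term.

    For each effect family the reduced model drops that family's columns
    while keeping every other term; the numerator df is the rank difference.
    Under sum-to-zero coding this matches the classical Type III convention
    for this design. q-values from the adaptive FDR step-up are appended
    over the term p-values.
    """
    design = fit.design
    y = pd.to_numeric(data[trait], errors="coerce").to_numpy(dtype=float)[fit.row_mask]
    X = design.X[fit.row_mask]
    sse_full = float(fit.residuals @ fit.residuals)
    rank_full = fit.rank
    rows = []
    from scipy import stats

    for name in design.terms:
        if name == "intercept":
            continue
        sl = design.term_slices[name]
        keep = np.ones(X.shape[1], dtype=bool)
        keep[sl] = False
        Xr = X[:, keep]
        beta_r = np.linalg.pinv(Xr.T @ Xr, rcond=1e-10) @ (Xr.T @ y)
        resid_r = y - Xr @ beta_r
        sse_r = float(resid_r @ resid_r)
        df_num = rank_full - int(np.linalg.matrix_rank(Xr, tol=1e-8))
        if df_num <= 0:
            rows.append({"term": name, "df": 0, "F": np.nan, "p": np.nan})
            continue
        F = ((sse_r - sse_full) / df_num) / (sse_full / fit.df_resid)
        pval = float(stats.f.sf(F, df_num, fit.df_resid))
        rows.append({"term": name, "df": df_num, "F": float(F), "p": pval})
    out = pd.DataFrame(rows).set_index("term")
    if fdr:
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = adjust_fdr(out.loc[ok, "p"].to_numpy())
        out["q"] = q
        out["stars"] = [significance_stars(v) if np.isfinite(v) else "" for v in q]
    return out


def estimate_contrasts(fit: ModelFit, fdr: bool = True) -> pd.DataFrame:
    """Entry-class contrasts on the fitted model.

    * heterosis — F1 class mean minus parent class mean (mid-parent
      heterosis of the generation blocks),
    * F1_vs_checks — F1 class mean minus check class mean,
    * env_difference — first minus second environment effect.

    With sum-to-zero effects the class least-square means are μ + b_k, so
    each contrast is a linear function of the reduced coefficients; its SE
    comes from the fit's coefficient covariance.
    """
    design = fit.design
    out = []
    from scipy import stats

    def _family_contrast(term: str, w_full: np.ndarray) -> tuple[float, float]:
        t = design.terms[term]
        sl = design.term_slices[term]
        w_red = t.basis.T @ w_full            # contrast in reduced coords
        est = float(w_red @ fit.beta[sl])
        var = float(w_red @ fit.cov_beta[sl, sl] @ w_red)
        return est, np.sqrt(max(var, 0.0))

    cls = design.terms["entry_class"].levels
    w = np.zeros(len(cls)); w[cls.index("F1")] = 1.0; w[cls.index("parent")] = -1.0
    est, se = _family_contrast("entry_class", w)
    out.append({"name": "heterosis", "estimate": est, "se": se})

    w = np.zeros(len(cls)); w[cls.index("F1")] = 1.0; w[cls.index("check")] = -1.0
    est, se = _family_contrast("entry_class", w)
    out.append({"name": "F1_vs_checks", "estimate": est, "se": se})

    envs = design.terms["env"].levels
    if len(envs) >= 2:
        w = np.zeros(len(envs)); w[0] = 1.0; w[1] = -1.0
        est, se = _family_contrast("env", w)
        out.append({"name": "env_difference", "estimate": est, "se": se})

    df = pd.DataFrame(out).set_index("name")
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = df["estimate"] / df["se"]
    df["t"] = tval
    df["p"] = 2.0 * stats.t.sf(np.abs(tval), fit.df_resid)
    if fdr:
        df["q"] = adjust_fdr(df["p"].to_numpy())
        df["stars"] = [significance_stars(v) for v in df["q"]]
    return df


def class_lsmeans(fit: ModelFit) -> pd.Series:
    """Least-square means of the entry classes: μ + b_k under sum-to-zero."""
    mu = float(fit.beta[fit.design.term_slices["intercept"]][0])
    b = fit.effects("entry_class")
    return mu + b


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Adaptive linear step-up q-values.

    The number of true nulls m0 is estimated with the lowest-slope rule
    (walk the ordered p-values until the slope estimate stops decreasing),
    then the Benjamini–Hochberg step-up is applied with m0 in place of m.
    Degenerates to plain BH when m0 = m; returns q monotone in p, in [0, 1];
    a single p-value maps to itself.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    # lowest-slope m0 estimator
    prev = np.inf
    m0 = m
    for i in range(m):
        denom = 1.0 - ps[i]
        s = (m + 1 - (i + 1)) / denom if denom > 0 else np.inf
        if s > prev:
            m0 = min(m, int(np.floor(prev)) + 1)
            break
        prev = s
    else:
        m0 = min(m, int(np.floor(prev)) + 1) if np.isfinite(prev) else m
    m0 = max(1, m0)
    q = ps * m0 / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def significance_stars(q: float) -> str:
    """Render significance at q ≤ 0.001 / 0.01 / 0.05 / 0.1 as ***, **, *, +."""
    if q <= 0.001:
        return "***"
    if q <= 0.01:
        return "**"
    if q <= 0.05:
        return "*"
    if q <= 0.1:
        return "+"
    return ""


def genetic_effect_table(fit: ModelFit, fdr: bool = True) -> pd.DataFrame:
    """Per-line additive and GCA effects and per-cross SCA effects with SEs
    and adaptive-FDR q-values (each family adjusted over its own tests)."""
    from scipy import stats

    frames = []
    for term in ("additive", "gca", "sca"):
        est = fit.effects(term)
        t = fit.design.terms[term]
        sl = fit.design.term_slices[term]
        cov = t.basis @ fit.cov_beta[sl, sl] @ t.basis.T
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        df = pd.DataFrame({"term": term, "level": est.index, "estimate": est.to_numpy(),
                           "se": se})
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = df["estimate"] / df["se"]
        df["p"] = 2.0 * stats.t.sf(np.abs(tv), fit.df_resid)
        if fdr:
            df["q"] = adjust_fdr(df["p"].to_numpy())
            df["stars"] = [significance_stars(v) for v in df["q"]]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def repeatability(
    data: pd.DataFrame, trait: str, entry_class: str, genotype_cols=("parent1", "parent2")
) -> float:
    """Broad-sense repeatability of entry means within one entry class.

    Variance components (genotype, genotype × environment, residual) are
    extracted from the expected mean squares of the two-way genotype × env
    ANOVA with replications, then plugged into the entry-mean formula

        R = σ²_G / (σ²_G + σ²_GE / nE + σ²_ε / (nE · nR)).

    Negative component estimates are truncated at zero. This plug-in is an
    artifact convention — reported as repeatability, not heritability,
    because the genotypes are a selected set.
    """
    sub = data[data["entry_class"] == entry_class].copy()
    if sub.empty:
        raise ValueError(f"no rows for entry class {entry_class!r}")
    envs = sub["env"].unique()
    if len(envs) < 2:
        raise ValueError("repeatability needs at least 2 environments")
    geno = sub[list(genotype_cols)].astype(str).agg("|".join, axis=1)
    sub = sub.assign(_g=geno, _y=pd.to_numeric(sub[trait], errors="coerce")).dropna(
        subset=["_y"]
    )
    n_env = sub["env"].nunique()
    n_rep = int(round(len(sub) / (sub["_g"].nunique() * n_env)))
    n_rep = max(1, n_rep)
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols("_y ~ C(_g) + C(env) + C(_g):C(env)", data=sub).fit()
    tab = anova_lm(model, typ=2)
    ms = tab["sum_sq"] / tab["df"]
    ms_g = float(ms["C(_g)"])
    ms_ge = float(ms["C(_g):C(env)"])
    ms_e = float(ms["Residual"]) if tab.loc["Residual", "df"] > 0 else 0.0
    var_ge = max(0.0, (ms_ge - ms_e) / n_rep)
    var_g = max(0.0, (ms_g - ms_ge) / (n_rep * n_env))
    var_e = max(0.0, ms_e)
    denom = var_g + var_ge / n_env + var_e / (n_env * n_rep)
    if denom == 0:
        return 0.0
    return float(np.clip(var_g / denom, 0.0, 1.0))
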