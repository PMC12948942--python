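"""Trio polygenic-score regressions (the trait-based stage).

For each focal family member and trait, repeated mental-distress scores
are regressed on the polygenic scores of all three trio members at once,
so each member's coefficient is adjusted for the other two: the focal
person's own coefficient is the direct genetic effect, the others are
consistent with indirect genetic effects.  Models adjust for time since
lockdown, focal age and child sex, carry a random intercept per focal
person (repeated measures) and, for adolescent outcomes, a maternal-ID
intercept to account for siblings.  Estimation is restricted maximum
likelihood on all available outcome rows.  Benjamini-Hochberg FDR is
applied within each declared 5-trait family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .simulate import ROLES

__all__ = ["LMMResult", "fit_trio_pgs", "fit_trio_pgs_time_interaction", "fdr_adjust",
           "fit_pgs_grid"]

PGS_TERMS = {"offspring": "pgs_offspring", "mother": "pgs_mother", "father": "pgs_father"}


@dataclass
class LMMResult:
    focal_role: str
    trait: str
    table: pd.DataFrame  # term, role, effect_type, beta, se, ci_low, ci_high, p
    random_effects: dict[str, float]
    residual_var: float
    n_obs: int
    n_groups: int
    converged: bool
    singular_refit: bool = False
    interactions: bool = False
    metadata: dict = field(default_factory=dict)


def _prepare(pheno: pd.DataFrame, pgs: pd.DataFrame, focal_role: str, trait: str,
             covariates: tuple[str, ...]):
    wide = (
        pgs[pgs["trait"] == trait]
        .pivot(index="family_id", columns="role", values="score")
        .rename(columns={r: PGS_TERMS[r] for r in ROLES})
        .reset_index()
    )
    wide = wide.dropna(subset=list(PGS_TERMS.values()))
    sub = pheno[pheno["role"] == focal_role].copy()
    time_col = "days" if "days" in sub.columns else "date_offset_days"
    sub["time"] = sub[time_col].astype(float)
    sub = sub.dropna(subset=["transformed_score"] + list(covariates))
    df = sub.merge(wide, on="family_id", how="inner")
    return df


def _fit_mixed(df: pd.DataFrame, formula: str, use_cluster: bool):
    """REML mixed model; person intercept, optional maternal-cluster level.

    Optimizers are tried in a fixed cascade because boundary fits can make
    individual methods fail with singular working matrices (bfgs first: the
    box-constrained method is the one that tends to blow up here).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_cluster:
            md = smf.mixedlm(
                formula,
                df,
                groups=df["maternal_cluster_id"],
                re_formula="1",
                vc_formula={"person": "0 + C(person_id)"},
            )
        else:
            # all-numeric single-level design: build arrays directly,
            # skipping the formula machinery (same model, same names)
            rhs = [t.strip() for t in formula.split("~")[1].split("+")]
            exog = pd.DataFrame({"Intercept": np.ones(len(df))})
            for term in rhs:
                if ":" in term:
                    a, b = term.split(":")
                    exog[term] = df[a].to_numpy(float) * df[b].to_numpy(float)
                else:
                    exog[term] = df[term].to_numpy(float)
            md = sm.MixedLM(
                df["transformed_score"].to_numpy(float), exog, groups=df["person_id"].to_numpy()
            )
        last = None
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                return md.fit(reml=True, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
        raise last


def _is_singular(res) -> bool:
    try:
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        vcomp = np.asarray(res.vcomp, dtype=float)
    except Exception:
        return True
    scale = max(res.scale, 1e-12)
    small_re = cov_re.size > 0 and np.any(np.diag(cov_re) < 1e-6 * scale)
    small_vc = vcomp.size > 0 and np.any(vcomp < 1e-6 * scale)
    return bool(small_re or small_vc) or not res.converged


def fit_trio_pgs(
    pheno: pd.DataFrame,
    pgs: pd.DataFrame,
    focal_role: str,
    trait: str,
    *,
    covariates: tuple[str, ...] = ("sex", "age"),
    interactions: bool = False,
    include_sibling_cluster: bool | None = None,
) -> LMMResult:
    """One trio-PGS multilevel regression.

    The outcome is the transformed distress score over waves; exposures are
    the standardized PGS of all three family members plus time and
    covariates.  Families lacking any member's PGS are excluded; rows with
    a missing outcome are dropped (all available rows are retained, the
    likelihood-based analogue of full-information estimation).  A singular
    random-effects fit is refit without the offending intercept and
    flagged.
    """
    df = _prepare(pheno, pgs, focal_role, trait, covariates)
    if df.empty:
        raise ValueError("no analyzable rows after merging phenotypes and scores")
    n_waves = df["wave"].nunique()
    if interactions and n_waves < 2:
        raise ValueError("PGS x time interactions need at least two waves")

    terms = [PGS_TERMS[focal_role]] + [PGS_TERMS[r] for r in ROLES if r != focal_role]
    rhs = terms + ["time"] + list(covariates)
    if interactions:
        df["time_c"] = df["time"] - df["time"].mean()  # centered before products
        inter = [f"{t}:time_c" for t in terms]
        rhs = rhs + inter
    formula = "transformed_score ~ " + " + ".join(rhs)

    use_cluster = (
        include_sibling_cluster
        if include_sibling_cluster is not None
        else focal_role == "offspring"
    )
    if use_cluster and df["maternal_cluster_id"].nunique() == df["person_id"].nunique():
        # no sibling structure: the extra level is vacuous, skip it
        use_cluster = False

    singular_refit = False
    res = _fit_mixed(df, formula, use_cluster)
    if use_cluster and _is_singular(res):
        res = _fit_mixed(df, formula, False)
        singular_refit = True
    if (not use_cluster or singular_refit) and _is_singular(res):
        # person intercept itself degenerate: plain OLS with flagged refit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, df).fit()
        singular_refit = True

    rows = []
    params = res.params
    bse = res.bse
    pvals = res.pvalues
    role_of_term = {v: k for k, v in PGS_TERMS.items()}
    for name in params.index:
        if name in ("Group Var", "person Var") or name.endswith(" Var"):
            continue
        base = name.split(":")[0]
        role = role_of_term.get(base)
        effect = (
            ("direct" if role == focal_role else "indirect") if role is not None else "covariate"
        )
        if ":" in name:
            effect += "_x_time"
        beta = float(params[name])
        se = float(bse[name])
        rows.append(
            {
                "term": name,
                "role": role,
                "effect_type": effect,
                "beta": beta,
                "se": se,
                "ci_low": beta - 1.96 * se,
                "ci_high": beta + 1.96 * se,
                "p": float(pvals[name]),
            }
        )
    table = pd.DataFrame(rows)
    ranef = {}
    resid = float(res.scale) if hasattr(res, "scale") else float(np.var(res.resid))
    if hasattr(res, "cov_re"):
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        if cov_re.size:
            ranef["group_intercept_var"] = float(cov_re[0, 0])
        vcomp = np.asarray(res.vcomp, dtype=float)
        if vcomp.size:
            ranef["person_intercept_var"] = float(vcomp[0])
    return LMMResult(
        focal_role=focal_role,
        trait=trait,
        table=table,
        random_effects=ranef,
        residual_var=resid,
        n_obs=int(res.nobs),
        n_groups=int(df["person_id"].nunique()),
        converged=bool(getattr(res, "converged", True)),
        singular_refit=singular_refit,
        interactions=interactions,
        metadata={"estimation": "REML" if hasattr(res, "cov_re") else "OLS-fallback",
                  "formula": formula},
    )


def fit_trio_pgs_time_interaction(pheno, pgs, focal_role, trait, **kwargs) -> LMMResult:
    """Trio-PGS model with PGS x time interactions for all three scores."""
    return fit_trio_pgs(pheno, pgs, focal_role, trait, interactions=True, **kwargs)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fit_pgs_grid(
    pheno: pd.DataFrame,
    pgs: pd.DataFrame,
    focal_roles,
    traits,
    *,
    interactions: bool = False,
    covariates: tuple[str, ...] = ("sex", "age"),
) -> pd.DataFrame:
    """The (focal role x trait) grid of trio-PGS models as one tidy table.

    q-values are computed within each (focal role, term) family across the
    listed traits -- the declared multiple-testing family of five PGS.
    """
    frames = []
    for focal_role in focal_roles:
        for trait in traits:
            fit = fit_trio_pgs(
                pheno, pgs, focal_role, trait,
                interactions=interactions, covariates=covariates,
            )
            t = fit.table.copy()
            t.insert(0, "trait", trait)
            t.insert(0, "focal_role", focal_role)
            t["n_obs"] = fit.n_obs
            t["n_groups"] = fit.n_groups
            t["singular_refit"] = fit.singular_refit
            frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out["q"] = np.nan
    mask = out["role"].notna()
    for (_, _), idx in out[mask].groupby(["focal_role", "term"]).groups.items():
        out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return out
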