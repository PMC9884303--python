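"""Statistical battery for glucose-group fat analyses.

Given a subject table (see :mod:`epifat.cohort` for the column dictionary),
this module reproduces the analysis stages of a cross-sectional
cardiometabolic study:

* descriptive group summaries — median (IQR) per glucose group, the
  difference of medians versus the NGT reference, pairwise two-sample
  Kruskal-Wallis tests (group vs. NGT) for continuous variables and a
  Pearson chi-square across groups for categorical ones;
* an ordinal trend test — Kendall's tau-b between a measure and the glucose
  groups coded NGT=0, IFG/IGT=1, CGI=2, T2D=3, with a seeded bootstrap CI;
* confounder qualification — a candidate qualifies when it is associated
  with EATV independently of VAT area (p < 0.10) in the NGT group;
* staged linear models — Model 1 regresses the outcome on the exposure
  alone (glucose-group indicators with NGT reference, or HOMA-IR); Models
  2-4 add one anthropometric at a time (BMI, waist, VAT area,
  non-cumulative); Model 5 adds the qualified confounders on top of the VAT
  adjustment; Model 6 (attenuation outcome only) additionally adjusts for
  EATV, asking whether an attenuation association is independent of depot
  size;
* the three pairwise attenuation/volume regressions (EATA on EATV, VAT
  attenuation on EATV, EATA on VAT attenuation).

All models are ordinary least squares with analytic 95 % confidence
intervals, fitted on complete cases (rows with any missing model variable
drop out; nothing is imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, ParameterError, UndefinedStatisticError

DEFAULT_CONTINUOUS = ("homa_ir", "bmi", "waist_cm", "vat_cm2", "eatv_ml", "eata_hu")
DEFAULT_CATEGORICAL = (
    "sex", "smoking", "education", "physical_activity", "alcohol", "season", "lipid_med",
)
DEFAULT_CONFOUNDER_CANDIDATES = (
    "sex", "age", "physical_activity", "lipid_med", "smoking", "alcohol", "education", "season",
)


def homa_ir(insulin, glucose):
    """HOMA-IR = insulin [uU/mL] x fasting glucose [mmol/L] / 22.5.

    Vectorised; negative inputs are a domain error.
    """
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(insulin < 0) or np.any(glucose < 0):
        raise ParameterError("insulin and glucose must be non-negative")
    out = insulin * glucose / 22.5
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Descriptive summary of a cohort table.

    ``continuous`` has one row per (variable, group) with the group's n,
    median, IQR, difference of medians vs. the reference group and the
    two-sample Kruskal-Wallis p-value vs. the reference.  ``categorical``
    has one row per (variable, level) with per-group rates;
    ``categorical_p`` holds the across-group chi-square p per variable.
    """

    continuous: pd.DataFrame
    categorical: pd.DataFrame
    categorical_p: pd.Series
    reference: str


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def summarize_groups(
    table: pd.DataFrame,
    continuous=DEFAULT_CONTINUOUS,
    categorical=DEFAULT_CATEGORICAL,
    group_col: str = "glucose_group",
    reference: str = "NGT",
) -> GroupSummary:
    """Median (IQR) per group with differences and tests vs. the reference."""
    if group_col not in table:
        raise ParameterError(f"missing group column {group_col!r}")
    groups = [g for g in _group_levels(table[group_col]) if (table[group_col] == g).any()]
    if reference not in groups:
        raise ParameterError(f"reference group {reference!r} not present")

    rows = []
    for var in continuous:
        if var not in table:
            continue
        ref_vals = table.loc[table[group_col] == reference, var].dropna().to_numpy()
        ref_med = float(np.median(ref_vals)) if ref_vals.size else np.nan
        for g in groups:
            vals = table.loc[table[group_col] == g, var].dropna().to_numpy()
            if vals.size == 0:
                rows.append((var, g, 0, np.nan, np.nan, np.nan, np.nan))
                continue
            med = float(np.median(vals))
            diff = np.nan if g == reference else med - ref_med
            if g == reference or vals.size == 0 or ref_vals.size == 0:
                p = np.nan
            else:
                p = float(sps.kruskal(ref_vals, vals).pvalue)
            rows.append((var, g, int(vals.size), med, _iqr(vals), diff, p))
    cont = pd.DataFrame(
        rows, columns=["variable", "group", "n", "median", "iqr", "diff_vs_ref", "p_vs_ref"]
    ).set_index(["variable", "group"])

    cat_rows = []
    cat_p = {}
    for var in categorical:
        if var not in table:
            continue
        ct = pd.crosstab(table[var], table[group_col])
        ct = ct.loc[:, [g for g in groups if g in ct.columns]]
        ct = ct.loc[(ct.sum(axis=1) > 0)]
        if ct.shape[0] >= 2 and ct.shape[1] >= 2:
            cat_p[var] = float(sps.chi2_contingency(ct.to_numpy()).pvalue)
        else:
            cat_p[var] = np.nan
        rates = ct / ct.sum(axis=0)
        for level, row in rates.iterrows():
            for g in rates.columns:
                cat_rows.append((var, level, g, float(row[g])))
    cat = pd.DataFrame(cat_rows, columns=["variable", "level", "group", "rate"]).set_index(
        ["variable", "level", "group"]
    )
    return GroupSummary(
        continuous=cont,
        categorical=cat,
        categorical_p=pd.Series(cat_p, name="chi2_p"),
        reference=reference,
    )


def _group_levels(col: pd.Series):
    if isinstance(col.dtype, pd.CategoricalDtype):
        return list(col.cat.categories)
    return list(pd.unique(col))


# ---------------------------------------------------------------------------
# ordinal trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    tau: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    ci_method: str


def kendall_trend(
    table: pd.DataFrame,
    value_col: str,
    ordinal_col: str = "glucose_group_ord",
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> TrendResult:
    """Kendall tau-b between a measure and the ordered glucose groups.

    The p-value uses the tie-corrected normal approximation.  The CI is a
    seeded percentile bootstrap by default; ``ci_method='asymptotic'`` uses
    the large-sample normal interval instead (flagged in the result).
    """
    sub = table[[ordinal_col, value_col]].dropna()
    x = sub[ordinal_col].to_numpy(dtype=float)
    y = sub[value_col].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise UndefinedStatisticError("need at least two distinct ordinal levels")
    if np.unique(y).size < 2:
        raise UndefinedStatisticError("tau is undefined for a constant measure")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    tau, p = float(res.statistic), float(res.pvalue)
    n = x.size
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        taus = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            taus[b] = sps.kendalltau(x[idx], y[idx], variant="b", method="asymptotic").statistic
        lo, hi = np.nanpercentile(taus, [2.5, 97.5])
    elif ci_method == "asymptotic":
        se = np.sqrt(2.0 * (2.0 * n + 5.0) / (9.0 * n * (n - 1.0)))
        lo, hi = tau - 1.959963984540054 * se, tau + 1.959963984540054 * se
    else:
        raise ParameterError(f"unknown ci_method {ci_method!r}")
    return TrendResult(tau=tau, ci_low=float(lo), ci_high=float(hi), p=p, n=n, ci_method=ci_method)


def kendall_tau_b_exhaustive(x, y) -> float:
    """O(n^2) all-pairs tau-b; the brute-force reference implementation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    if denom == 0:
        raise UndefinedStatisticError("tau-b undefined: a variable is constant")
    return float((conc - disc) / denom)


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """One fitted OLS model: coefficients, 95 % CIs, p-values, bookkeeping."""

    outcome: str
    model_id: int
    exposure: str
    formula: str
    n: int
    r_squared: float
    params: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, p
    exposure_terms: list[str] = field(default_factory=list)
    f_p: float = float("nan")  # overall regression F-test p-value

    @property
    def exposure_params(self) -> pd.DataFrame:
        return self.params.loc[self.exposure_terms]


def _term_for(table: pd.DataFrame, name: str) -> str:
    """Wrap non-numeric columns in C() so patsy dummy-codes them."""
    if name in table and not pd.api.types.is_numeric_dtype(table[name]):
        return f"C({name})"
    return name


def _fit_ols(table: pd.DataFrame, formula: str) -> tuple:
    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, _, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        null = vt[rank:]
        bad = X.columns[np.any(np.abs(null) > 1e-8, axis=0)]
        raise CollinearityError(bad)
    res = sm.OLS(y.to_numpy().ravel(), X).fit()
    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci.iloc[:, 0],
            "ci_high": ci.iloc[:, 1],
            "p": res.pvalues,
        }
    )
    return res, params, int(res.nobs)


def qualify_confounders(
    table: pd.DataFrame,
    candidates=DEFAULT_CONFOUNDER_CANDIDATES,
    outcome: str = "eatv_ml",
    adjust_for: str = "vat_cm2",
    group: str | None = "NGT",
    group_col: str = "glucose_group",
    alpha: float = 0.10,
) -> list[str]:
    """Candidates associated with the outcome independently of VAT area.

    Each candidate is tested in ``outcome ~ candidate + adjust_for`` on the
    reference-group rows; multi-level candidates use a joint Wald F-test over
    their indicator columns.  Candidates with p < ``alpha`` qualify.
    """
    sub = table if group is None else table[table[group_col] == group]
    if len(sub) == 0:
        raise ParameterError("no rows in the reference group")
    qualified = []
    for cand in candidates:
        if cand not in sub:
            continue
        term = _term_for(sub, cand)
        formula = f"{outcome} ~ {term} + {adjust_for}"
        res, params, _ = _fit_ols(sub, formula)
        cand_cols = [c for c in params.index if c == cand or c.startswith(f"C({cand})")]
        if not cand_cols:
            continue
        if len(cand_cols) == 1:
            p = float(params.loc[cand_cols[0], "p"])
        else:
            sel = np.zeros((len(cand_cols), len(params)))
            for i, c in enumerate(cand_cols):
                sel[i, list(params.index).index(c)] = 1.0
            p = float(res.f_test(sel).pvalue)
        if p < alpha:
            qualified.append(cand)
    return qualified


_MODEL_COVARIATES = {1: (), 2: ("bmi",), 3: ("waist_cm",), 4: ("vat_cm2",)}


def fit_staged_models(
    table: pd.DataFrame,
    outcome: str = "eatv_ml",
    exposure: str = "groups",
    confounders: list[str] | None = None,
    model5_anthropometric: str = "vat_cm2",
    reference: str = "NGT",
    models=None,
) -> list[ModelFit]:
    """Fit the staged regression battery for one outcome and exposure.

    ``exposure='groups'`` uses the four non-reference glucose-group
    indicators; ``exposure='homa_ir'`` (or any numeric column name) enters
    the column directly.  Model 5 combines the exposure, one anthropometric
    (VAT area by default) and the qualified confounders; Model 6, fitted for
    the attenuation outcome only, adds EATV on top of Model 5.

    ``confounders=None`` runs the qualification rule on the reference-group
    rows of ``table`` first.
    """
    if exposure == "groups":
        exp_term = f"C(glucose_group, Treatment('{reference}'))"
    else:
        exp_term = exposure
    if confounders is None:
        confounders = qualify_confounders(table, group=reference)
    conf_terms = [_term_for(table, c) for c in confounders]

    if models is None:
        models = (1, 2, 3, 4, 5, 6) if outcome == "eata_hu" else (1, 2, 3, 4, 5)
    fits = []
    for mid in models:
        if mid in _MODEL_COVARIATES:
            covs = [c for c in _MODEL_COVARIATES[mid] if c != outcome]
        elif mid == 5:
            covs = [model5_anthropometric] + conf_terms
        elif mid == 6:
            if outcome != "eata_hu":
                raise ParameterError("model 6 is defined for the attenuation outcome only")
            covs = [model5_anthropometric] + conf_terms + ["eatv_ml"]
        else:
            raise ParameterError(f"unknown model id {mid}")
        rhs = " + ".join([exp_term] + covs)
        formula = f"{outcome} ~ {rhs}"
        res, params, n = _fit_ols(table, formula)
        exp_cols = [
            c for c in params.index
            if c.startswith("C(glucose_group") or c == exposure
        ] if exposure == "groups" else [c for c in params.index if c == exposure]
        fits.append(
            ModelFit(
                outcome=outcome,
                model_id=mid,
                exposure=exposure,
                formula=formula,
                n=n,
                r_squared=float(res.rsquared),
                params=params,
                exposure_terms=exp_cols,
                f_p=float(res.f_pvalue),
            )
        )
    return fits


@dataclass(frozen=True)
class PairwiseFit:
    """Simple regression of y on x: slope B with CI, plus Pearson R."""

    y: str
    x: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p: float
    r: float
    n: int


def pairwise_regressions(table: pd.DataFrame) -> dict[str, PairwiseFit]:
    """The three attenuation/volume regressions.

    Returns fits keyed ``eata_on_eatv``, ``vat_hu_on_eatv`` and
    ``eata_on_vat_hu``; each is a simple OLS on complete cases with the
    Pearson correlation alongside.
    """
    pairs = {
        "eata_on_eatv": ("eata_hu", "eatv_ml"),
        "vat_hu_on_eatv": ("vat_hu", "eatv_ml"),
        "eata_on_vat_hu": ("eata_hu", "vat_hu"),
    }
    out = {}
    for key, (yv, xv) in pairs.items():
        sub = table[[yv, xv]].dropna()
        res, params, n = _fit_ols(sub, f"{yv} ~ {xv}")
        r = float(np.corrcoef(sub[xv], sub[yv])[0, 1])
        out[key] = PairwiseFit(
            y=yv, x=xv,
            slope=float(params.loc[xv, "coef"]),
            intercept=float(params.loc["Intercept", "coef"]),
            ci_low=float(params.loc[xv, "ci_low"]),
            ci_high=float(params.loc[xv, "ci_high"]),
            p=float(params.loc[xv, "p"]),
            r=r, n=n,
        )
    return out


def model_fits_to_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Long-format coefficient table (forest-plot ready) for a list of fits."""
    rows = []
    for f in fits:
        for term, row in f.params.iterrows():
            rows.append(
                {
                    "outcome": f.outcome,
                    "model": f.model_id,
                    "exposure": f.exposure,
                    "term": term,
                    "is_exposure_term": term in f.exposure_terms,
                    "coef": row["coef"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "n": f.n,
                }
            )
    return pd.DataFrame(rows)
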