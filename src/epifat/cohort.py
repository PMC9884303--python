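"""Synthetic five-group cardiometabolic cohort generator.

The statistical pipeline in this package analyses subject tables with a
five-level glucose-tolerance grouping — NGT (normal), IFG (impaired fasting
glucose), IGT (impaired glucose tolerance), CGI (their combination) and
newly diagnosed T2D — together with CT fat measures (EATV, EATA, abdominal
VAT area and VAT/SAT attenuation), anthropometrics (BMI, waist) and
insulin resistance (HOMA-IR).  Since the study cohort itself is not
deposited, this module generates tables whose *marginal* group distributions
(median, IQR, categorical rates) and *cross-variable* dependence emulate the
published cohort characteristics, so that parameter-recovery tests can
exercise the full statistical battery end to end.

Generation model, per glucose group:

* EATV, VAT area and HOMA-IR are log-normal; BMI, waist and glucose are
  normal.  Each margin is solved from its (median, IQR) pair.  Dependence
  between the five core margins (EATV, VAT, BMI, waist, HOMA-IR) comes from
  a Gaussian copula with a target Spearman rank-correlation matrix
  (default targets sit in the published 0.30-0.74 range; the full joint
  matrix beyond the published pairs is an explicit, editable assumption).
* EATA is tied structurally to EATV,
  ``eata = median_eata + b * (eatv - median_eatv) + noise`` with
  ``b = -0.082`` (larger hearts carry more, lipid-richer, hence lower-HU
  fat); the residual SD is solved per group so the EATA IQR stays
  calibrated.  VAT attenuation is tied the same way with slope ``-0.129``;
  SAT attenuation is an independent normal margin.
* Age is uniform on a 14-year window inside 50-64 centred near the group
  median.  Sex, smoking, physical activity, lipid-lowering medication,
  education, alcohol use and CT season are drawn independently at the group
  rates.
* EATV additionally carries small built-in confounder effects (age, male
  sex, smoking, physical activity), mean-centred per group and compensated
  in the log-normal base scale so medians and IQRs stay calibrated.  These
  give the confounder-qualification rule something real to find.
* HOMA-IR is drawn, fasting glucose is drawn, and insulin is back-solved so
  the identity ``homa_ir = insulin * glucose / 22.5`` holds row-wise.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .errors import ParameterError

GROUP_ORDER = ("NGT", "IGT", "IFG", "CGI", "T2D")

#: Ordinal trend coding: IFG and IGT share one rank (the ordering
#: NGT - IFG/IGT - CGI - T2D does not separate them).
ORDINAL_CODING = {"NGT": 0, "IFG": 1, "IGT": 1, "CGI": 2, "T2D": 3}

#: Margins drawn through the Gaussian copula, in matrix order.
COPULA_VARS = ("eatv_ml", "vat_cm2", "bmi", "waist_cm", "homa_ir")

LOGNORMAL_VARS = {"eatv_ml", "vat_cm2", "homa_ir"}

#: Target Spearman rank correlations between the copula margins.  The
#: EATV-VAT and EATV-BMI entries are the published NGT-group extremes
#: (0.739 and 0.581); the remainder interpolate plausibly.
DEFAULT_RANK_CORR = np.array(
    [
        [1.00, 0.739, 0.581, 0.65, 0.30],
        [0.739, 1.00, 0.70, 0.80, 0.35],
        [0.581, 0.70, 1.00, 0.85, 0.32],
        [0.65, 0.80, 0.85, 1.00, 0.35],
        [0.30, 0.35, 0.32, 0.35, 1.00],
    ]
)

#: Built-in regression slopes tying attenuation to EATV.
EATA_ON_EATV_SLOPE = -0.082
VATHU_ON_EATV_SLOPE = -0.129

#: Built-in confounder effects on EATV (ml per unit), mean-centred per group.
DEFAULT_CONFOUNDER_EFFECTS = {
    "age": 1.0,  # ml per year
    "sex": 15.0,  # male vs female
    "smoking": 12.0,
    "physical_activity": -15.0,
}

_Z75 = float(ndtri(0.75))  # 0.6745, the 75th-percentile standard-normal quantile


@dataclass
class GroupSpec:
    """Marginal targets for one glucose group.

    ``continuous`` maps variable name to ``(median, iqr)``; ``binary_rates``
    maps 0/1 variables to the probability of 1; ``categorical_rates`` maps a
    variable to a level->rate dict (normalised at draw time).
    """

    name: str
    n: int
    age_median: float
    continuous: dict[str, tuple[float, float]]
    binary_rates: dict[str, float]
    categorical_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError("group size must be >= 0")
        for var, (_, iqr) in self.continuous.items():
            if iqr <= 0:
                raise ParameterError(f"{self.name}/{var}: IQR must be > 0")
        for var, p in self.binary_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{self.name}/{var}: rate must be in [0, 1]")


def default_group_specs() -> list[GroupSpec]:
    """The five published group specifications (n = 1948 in total).

    Group medians/IQRs and categorical rates follow the published cohort
    characteristics table; the VAT/SAT attenuation margins are published for
    NGT and IGT only and interpolated for the other groups; fasting glucose
    margins are invented at physiologically sensible levels per group.
    """
    edu = ("Elementary", "High-school", "University")
    alc = ("Low", "Low-moderate", "Moderate", "Moderate-high", "High")
    sea = ("Winter", "Spring", "Summer", "Fall")

    def g(name, n, age, male, smoke, pa, lipid, edu_r, alc_r, sea_r, cont):
        return GroupSpec(
            name=name,
            n=n,
            age_median=age,
            continuous=cont,
            binary_rates={
                "sex": male,
                "smoking": smoke,
                "physical_activity": pa,
                "lipid_med": lipid,
            },
            categorical_rates={
                "education": dict(zip(edu, edu_r)),
                "alcohol": dict(zip(alc, alc_r)),
                "season": dict(zip(sea, sea_r)),
            },
        )

    return [
        g("NGT", 1012, 57.5, 0.617, 0.083, 0.047, 0.076,
          (0.070, 0.458, 0.472), (0.042, 0.136, 0.420, 0.351, 0.051),
          (0.262, 0.303, 0.124, 0.310),
          {"eatv_ml": (104.9, 53.4), "eata_hu": (-69.0, 8.0),
           "vat_cm2": (137.9, 102.0), "bmi": (26.8, 5.7), "waist_cm": (96.0, 16.0),
           "homa_ir": (1.33, 1.0), "vat_hu": (-88.0, 13.0), "sat_hu": (-106.0, 5.0),
           "glucose": (5.0, 0.8)}),
        g("IGT", 321, 60.5, 0.564, 0.078, 0.043, 0.121,
          (0.131, 0.523, 0.346), (0.075, 0.121, 0.355, 0.358, 0.090),
          (0.231, 0.299, 0.153, 0.318),
          {"eatv_ml": (112.2, 62.8), "eata_hu": (-71.0, 6.0),
           "vat_cm2": (166.7, 110.0), "bmi": (26.9, 6.1), "waist_cm": (97.0, 20.0),
           "homa_ir": (1.48, 1.4), "vat_hu": (-92.0, 12.0), "sat_hu": (-107.0, 4.0),
           "glucose": (5.2, 0.8)}),
        g("IFG", 414, 58.4, 0.430, 0.092, 0.049, 0.068,
          (0.061, 0.522, 0.417), (0.029, 0.118, 0.394, 0.394, 0.065),
          (0.263, 0.292, 0.109, 0.336),
          {"eatv_ml": (114.7, 56.0), "eata_hu": (-69.0, 6.0),
           "vat_cm2": (165.2, 119.0), "bmi": (27.1, 5.1), "waist_cm": (98.0, 15.0),
           "homa_ir": (1.73, 1.3), "vat_hu": (-90.0, 12.0), "sat_hu": (-106.0, 5.0),
           "glucose": (6.3, 0.7)}),
        g("CGI", 128, 60.4, 0.430, 0.102, 0.039, 0.094,
          (0.109, 0.469, 0.422), (0.039, 0.205, 0.402, 0.276, 0.079),
          (0.250, 0.328, 0.094, 0.328),
          {"eatv_ml": (134.6, 65.3), "eata_hu": (-71.0, 6.0),
           "vat_cm2": (219.8, 113.0), "bmi": (29.9, 6.5), "waist_cm": (105.0, 16.0),
           "homa_ir": (2.70, 2.5), "vat_hu": (-93.0, 12.0), "sat_hu": (-107.0, 5.0),
           "glucose": (6.6, 0.9)}),
        g("T2D", 73, 60.0, 0.370, 0.123, 0.039, 0.260,
          (0.137, 0.521, 0.342), (0.068, 0.192, 0.466, 0.178, 0.096),
          (0.260, 0.438, 0.082, 0.219),
          {"eatv_ml": (146.6, 63.0), "eata_hu": (-72.0, 7.5),
           "vat_cm2": (247.2, 179.0), "bmi": (30.6, 7.8), "waist_cm": (107.0, 19.0),
           "homa_ir": (3.22, 2.2), "vat_hu": (-94.0, 13.0), "sat_hu": (-107.0, 5.0),
           "glucose": (7.8, 1.5)}),
    ]


# ---------------------------------------------------------------------------
# margin solving
# ---------------------------------------------------------------------------

def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    With q75/q25 = exp(+-sigma*z75) around the median m, the quartile span is
    m*(t - 1/t) with t = exp(sigma*z75); solving the quadratic in t gives a
    closed form.
    """
    if median <= 0:
        raise ParameterError("log-normal margin needs a positive median")
    t = (iqr + np.sqrt(iqr**2 + 4.0 * median**2)) / (2.0 * median)
    return float(np.log(median)), float(np.log(t) / _Z75)


def _normal_params(median: float, iqr: float) -> tuple[float, float]:
    return float(median), float(iqr / (2.0 * _Z75))


def _margin_ppf(var: str, u: np.ndarray, median: float, iqr: float) -> np.ndarray:
    z = ndtri(np.clip(u, 1e-12, 1.0 - 1e-12))
    if var in LOGNORMAL_VARS:
        mu, sigma = _lognormal_params(median, iqr)
        return np.exp(mu + sigma * z)
    m, sd = _normal_params(median, iqr)
    return m + sd * z


def spearman_to_pearson_latent(rho: np.ndarray) -> np.ndarray:
    """Latent normal correlation reproducing a Spearman target."""
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _age_window(age_median: float, half_width: float = 7.0) -> tuple[float, float]:
    lo = max(50.0, age_median - half_width)
    hi = min(64.0, lo + 2.0 * half_width)
    lo = max(50.0, hi - 2.0 * half_width)
    return lo, hi


def generate_cohort(
    specs: list[GroupSpec] | None = None,
    copula_corr: np.ndarray | None = None,
    seed: int = 0,
    confounder_effects: dict[str, float] | None = None,
    eata_slope: float = EATA_ON_EATV_SLOPE,
    vat_hu_slope: float = VATHU_ON_EATV_SLOPE,
) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Parameters
    ----------
    specs:
        Per-group marginal targets; defaults to the published five groups.
    copula_corr:
        Target Spearman matrix over :data:`COPULA_VARS`; must be positive
        semi-definite.
    seed:
        Seeds every random draw; identical seeds give identical tables.
    confounder_effects:
        Additive, per-group-centred effects on EATV, keyed by
        ``age``/``sex``/``smoking``/``physical_activity``.
    """
    specs = specs if specs is not None else default_group_specs()
    corr = DEFAULT_RANK_CORR if copula_corr is None else np.asarray(copula_corr, float)
    if corr.shape != (len(COPULA_VARS), len(COPULA_VARS)):
        raise ParameterError(f"copula_corr must be {len(COPULA_VARS)}x{len(COPULA_VARS)}")
    if not np.allclose(corr, corr.T):
        raise ParameterError("copula_corr must be symmetric")
    latent = spearman_to_pearson_latent(corr)
    np.fill_diagonal(latent, 1.0)
    eig = np.linalg.eigvalsh(latent)
    if eig.min() < -1e-8:
        raise ParameterError("copula correlation matrix is not positive semi-definite")
    chol = np.linalg.cholesky(latent + 1e-10 * np.eye(len(COPULA_VARS)))
    effects = (
        DEFAULT_CONFOUNDER_EFFECTS if confounder_effects is None else confounder_effects
    )

    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for spec in specs:
        n = spec.n
        if n == 0:
            continue
        z = rng.standard_normal((n, len(COPULA_VARS))) @ chol.T
        u = ndtr(z)

        cols: dict[str, np.ndarray] = {}

        # categoricals / demographics first (they feed the EATV effects)
        lo, hi = _age_window(spec.age_median)
        age = rng.uniform(lo, hi, size=n)
        cols["age"] = age
        for var, p in spec.binary_rates.items():
            cols[var] = (rng.random(n) < p).astype(int)
        for var, rates in spec.categorical_rates.items():
            levels = list(rates)
            pvec = np.asarray([rates[k] for k in levels], float)
            pvec = pvec / pvec.sum()
            cols[var] = rng.choice(levels, p=pvec, size=n)

        # EATV: copula margin with effect-variance compensation
        med_v, iqr_v = spec.continuous["eatv_ml"]
        var_eff = (
            effects.get("age", 0.0) ** 2 * (hi - lo) ** 2 / 12.0
            + sum(
                effects.get(k, 0.0) ** 2
                * spec.binary_rates[k]
                * (1.0 - spec.binary_rates[k])
                for k in ("sex", "smoking", "physical_activity")
            )
        )
        iqr_base = float(
            np.sqrt(max((iqr_v**2) - (2.0 * _Z75) ** 2 * var_eff, (0.3 * iqr_v) ** 2))
        )
        eatv = _margin_ppf("eatv_ml", u[:, 0], med_v, iqr_base)
        eatv = eatv + effects.get("age", 0.0) * (age - (lo + hi) / 2.0)
        for k in ("sex", "smoking", "physical_activity"):
            p = spec.binary_rates[k]
            eatv = eatv + effects.get(k, 0.0) * (cols[k] - p)
        cols["eatv_ml"] = np.maximum(eatv, 1.0)

        for j, var in enumerate(COPULA_VARS[1:], start=1):
            med, iqr = spec.continuous[var]
            cols[var] = _margin_ppf(var, u[:, j], med, iqr)

        # attenuations tied to EATV; residual SD keeps the IQR calibrated
        var_v = float(np.var(cols["eatv_ml"]))
        for var, slope in (("eata_hu", eata_slope), ("vat_hu", vat_hu_slope)):
            med, iqr = spec.continuous[var]
            sd_target = iqr / (2.0 * _Z75)
            sd_resid = float(
                np.sqrt(max(sd_target**2 - slope**2 * var_v, (0.25 * sd_target) ** 2))
            )
            cols[var] = (
                med + slope * (cols["eatv_ml"] - med_v) + rng.normal(0.0, sd_resid, n)
            )
        med, iqr = spec.continuous["sat_hu"]
        m, sd = _normal_params(med, iqr)
        cols["sat_hu"] = rng.normal(m, sd, n)

        # glucose and insulin, honouring the HOMA-IR identity
        med, iqr = spec.continuous["glucose"]
        m, sd = _normal_params(med, iqr)
        cols["glucose"] = np.maximum(rng.normal(m, sd, n), 3.0)
        cols["insulin"] = cols["homa_ir"] * 22.5 / cols["glucose"]

        frame = pd.DataFrame(cols)
        frame.insert(0, "subject_id", np.arange(offset, offset + n))
        frame.insert(1, "glucose_group", spec.name)
        frame.insert(2, "glucose_group_ord", ORDINAL_CODING.get(spec.name, np.nan))
        frames.append(frame)
        offset += n

    if not frames:
        cols = ["subject_id", "glucose_group", "glucose_group_ord", "age"]
        return pd.DataFrame(columns=cols)
    table = pd.concat(frames, ignore_index=True)
    table["glucose_group"] = pd.Categorical(
        table["glucose_group"],
        categories=[s.name for s in specs if s.n > 0],
    )
    return table


def inject_missingness(
    table: pd.DataFrame,
    rates: dict[str, float] | None = None,
    seed: int = 0,
    counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Missing-completely-at-random masking; returns a copy.

    ``rates`` masks each cell of a column independently with the given
    probability; ``counts`` masks an exact number of rows per column
    (sampled without replacement).  Downstream analyses are complete-case,
    so masked rows simply drop out of any model using the column.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    for col, rate in (rates or {}).items():
        if not 0.0 <= rate <= 1.0:
            raise ParameterError(f"missingness rate for {col} must be in [0, 1]")
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    for col, k in (counts or {}).items():
        if not 0 <= k <= len(out):
            raise ParameterError(f"missingness count for {col} must be in [0, n]")
        idx = rng.choice(len(out), size=k, replace=False)
        out.iloc[idx, out.columns.get_loc(col)] = np.nan
    return out


# ---------------------------------------------------------------------------
# YAML round-trip for group specs
# ---------------------------------------------------------------------------

def specs_to_yaml(specs: list[GroupSpec], path) -> None:
    doc = [
        {
            "name": s.name,
            "n": s.n,
            "age_median": s.age_median,
            "continuous": {k: list(v) for k, v in s.continuous.items()},
            "binary_rates": dict(s.binary_rates),
            "categorical_rates": {k: dict(v) for k, v in s.categorical_rates.items()},
        }
        for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def specs_from_yaml(path) -> list[GroupSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        GroupSpec(
            name=d["name"],
            n=int(d["n"]),
            age_median=float(d["age_median"]),
            continuous={k: tuple(v) for k, v in d["continuous"].items()},
            binary_rates=d["binary_rates"],
            categorical_rates=d.get("categorical_rates", {}),
        )
        for d in doc
    ]
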