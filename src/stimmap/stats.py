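"""Group inference: hierarchical linear models, likelihood-ratio model
comparison, FDR correction and cohort summaries.

Connectivity data are nested — connections within recording/stimulation
sites, within brain regions, within subjects — so hypothesis tests compare a
null mixed model against an alternative that adds exactly the tested fixed
effect, both fitted by maximum likelihood (REML likelihoods are not
comparable across fixed-effect structures).  Significance comes from the
likelihood-ratio test; AIC/BIC for both fits are reported alongside.  When
the requested random structure cannot be estimated the deepest level is
dropped first (site -> region -> subject), deterministically, and the
downgrade is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = ["HlmSpec", "TestResult", "fit_and_compare", "fdr_correct",
           "cohort_summary", "load_demo_participants"]


@dataclass
class HlmSpec:
    """Specification of one mixed-model comparison.

    ``fixed`` are the alternative model's covariate columns; ``test`` names
    the single covariate whose effect is under test (the null model is
    ``fixed`` without it).  ``nested_random`` is the ordered grouping ladder,
    outermost first, e.g. ``("subject", "region", "site")``.
    """

    response: str
    fixed: tuple
    test: str
    nested_random: tuple = ("subject", "region", "site")

    def __post_init__(self) -> None:
        if self.test not in self.fixed:
            raise ValueError("tested effect must be part of the alternative model")


@dataclass
class TestResult:
    estimate: float
    tvalue: float
    p_raw: float
    p_fdr: float | None
    aic: float
    bic: float
    aic_null: float
    bic_null: float
    n_connections: int
    n_subjects: int
    random_structure: tuple = ()
    downgraded: bool = False
    message: str = ""


def _fit_mixed(data: pd.DataFrame, response: str, fixed, groups: str,
               vc_levels):
    """ML fit of response ~ fixed with a random intercept per ``groups`` and
    variance components for the nested levels.  Returns the statsmodels
    results object."""
    import statsmodels.formula.api as smf

    rhs = " + ".join(fixed) if fixed else "1"
    vc = {}
    for lvl in vc_levels:
        data = data.copy()
        key = f"_{lvl}_in_{groups}"
        data[key] = data[groups].astype(str) + ":" + data[lvl].astype(str)
        vc[lvl] = f"0 + C({key})"
    model = smf.mixedlm(f"{response} ~ {rhs}", data=data, groups=data[groups],
                        vc_formula=vc or None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
    if not np.isfinite(res.llf):
        raise ValueError("non-finite likelihood")
    return res


def _n_params(res) -> int:
    # fixed effects + variance parameters (random intercept, vcs, residual)
    return len(res.fe_params) + len(res.cov_re) + len(getattr(res, "vcomp", [])) + 1


def _information(res, n: int):
    k = _n_params(res)
    return 2 * k - 2 * res.llf, np.log(n) * k - 2 * res.llf


def fit_and_compare(data: pd.DataFrame, spec: HlmSpec) -> TestResult:
    """Fit null and alternative mixed models by ML and compare by LRT.

    The effect estimate and its t (z) statistic come from the alternative
    fit; AIC/BIC for both models are recorded.  Singular or non-convergent
    fits trigger the deterministic downgrade ladder on the random structure
    (drop site, then region; the subject intercept is kept; the last resort
    is ordinary least squares, flagged).
    """
    for col in (spec.response, *spec.fixed, *spec.nested_random):
        if col not in data:
            raise ValueError(f"missing column {col!r}")
    groups = spec.nested_random[0]
    if data[groups].nunique() < 2:
        raise ValueError("outermost grouping factor needs >= 2 levels")
    null_fixed = tuple(f for f in spec.fixed if f != spec.test)
    n = len(data)

    ladders = [tuple(spec.nested_random[1:k]) for k in
               range(len(spec.nested_random), 0, -1)]
    last_err = ""
    for vc_levels in ladders:
        try:
            res_a = _fit_mixed(data, spec.response, spec.fixed, groups, vc_levels)
            res_0 = _fit_mixed(data, spec.response, null_fixed, groups, vc_levels)
        except Exception as err:  # noqa: BLE001 - downgrade on any fit failure
            last_err = str(err)
            continue
        lr = 2.0 * (res_a.llf - res_0.llf)
        df = len(res_a.fe_params) - len(res_0.fe_params)
        p = float(sp_stats.chi2.sf(max(lr, 0.0), df))
        term = next(t for t in res_a.fe_params.index if spec.test in t)
        aic_a, bic_a = _information(res_a, n)
        aic_0, bic_0 = _information(res_0, n)
        downgraded = vc_levels != tuple(spec.nested_random[1:])
        return TestResult(
            estimate=float(res_a.fe_params[term]),
            tvalue=float(res_a.tvalues[term]),
            p_raw=p, p_fdr=None, aic=float(aic_a), bic=float(bic_a),
            aic_null=float(aic_0), bic_null=float(bic_0),
            n_connections=n, n_subjects=int(data[groups].nunique()),
            random_structure=(groups, *vc_levels), downgraded=downgraded,
            message="" if not downgraded else f"random structure downgraded ({last_err})",
        )
    # last resort: ordinary least squares with an LRT on the same df
    import statsmodels.formula.api as smf
    res_a = smf.ols(f"{spec.response} ~ {' + '.join(spec.fixed)}", data).fit()
    rhs0 = " + ".join(null_fixed) if null_fixed else "1"
    res_0 = smf.ols(f"{spec.response} ~ {rhs0}", data).fit()
    lr = 2.0 * (res_a.llf - res_0.llf)
    df = res_a.df_model - res_0.df_model
    term = next(t for t in res_a.params.index if spec.test in t)
    return TestResult(
        estimate=float(res_a.params[term]), tvalue=float(res_a.tvalues[term]),
        p_raw=float(sp_stats.chi2.sf(max(lr, 0.0), df)), p_fdr=None,
        aic=float(res_a.aic), bic=float(res_a.bic),
        aic_null=float(res_0.aic), bic_null=float(res_0.bic),
        n_connections=n, n_subjects=int(data[groups].nunique()),
        random_structure=(), downgraded=True,
        message=f"fell back to OLS ({last_err})",
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D array of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- summaries


def _round_half_away(x: float, ndigits: int) -> float:
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def cohort_summary(participants: pd.DataFrame) -> dict:
    """Cohort demographics: total electrode sites, mean/SD electrodes per
    participant, mean/SD age, percent female.

    SDs are sample SDs (n-1); printed values are rounded half away from
    zero to the conventional precision (electrodes to integers, age to one
    decimal, percent to one decimal).
    """
    for col in ("Age", "Gender", "Number of electrodes"):
        if col not in participants:
            raise ValueError(f"missing column {col!r}")
    n = len(participants)
    elec = participants["Number of electrodes"].astype(float)
    age = participants["Age"].astype(float)
    pct_female = 100.0 * (participants["Gender"].astype(str).str.upper() == "F").mean()
    sd = lambda x: float(x.std(ddof=1)) if n > 1 else 0.0  # noqa: E731
    return {
        "n_participants": n,
        "total_sites": int(elec.sum()),
        "mean_electrodes": _round_half_away(float(elec.mean()), 0),
        "sd_electrodes": _round_half_away(sd(elec), 0),
        "mean_age": _round_half_away(float(age.mean()), 1),
        "sd_age": _round_half_away(sd(age), 1),
        "percent_female": _round_half_away(pct_female, 1),
    }


def load_demo_participants() -> pd.DataFrame:
    """The bundled 27-participant demographics table (age, gender, hemisphere
    coverage, electrode counts) used by the worked examples."""
    from importlib.resources import files

    path = files("stimmap").joinpath("data/participants.tsv")
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t")
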