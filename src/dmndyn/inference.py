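"""Inferential machinery for band-power tables.

Nested linear mixed-effects models (random intercepts for subject and for
electrode within subject), sequential likelihood-ratio model comparison,
z-approximation post hocs with Bonferroni correction, and an
electrode-averaged repeated-measures ANOVA cross-check.

Model-comparison fits use maximum likelihood (not REML): REML log-likelihoods
of models with different fixed effects are not comparable, so every fit that
feeds a likelihood-ratio test is ML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class LMMFit:
    """A fitted mixed model plus the bookkeeping LRTs need."""

    result: object
    fixed: str
    response: str
    ml: bool
    converged: bool
    subject_only_fallback: bool = False

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def n_fixed(self) -> int:
        return len(self.result.fe_params)

    @property
    def fixed_names(self) -> list[str]:
        return list(self.result.fe_params.index)


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


@dataclass
class ContrastResult:
    name: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adj: float


def fit_lmm(df: pd.DataFrame, fixed: str, response: str = "pct_change",
            subject: str = "subject", electrode: str = "electrode",
            reml: bool = False) -> LMMFit:
    """Fit ``response ~ fixed`` with subject intercepts and electrode-within-
    subject intercepts (variance component).

    A singular or non-converged nested fit falls back to a subject-only
    random intercept, recorded on the returned object.
    """
    if df[subject].nunique() < 2:
        raise ValidationError("need at least 2 subjects for a mixed model")
    y = df[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("response contains non-finite values")
    formula = f"{response} ~ {fixed}"
    vc = {electrode: f"0 + C({electrode})"}

    def _fit(vc_formula, method):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(formula, df, groups=df[subject], re_formula="1",
                                vc_formula=vc_formula)
            res = model.fit(reml=reml, method=method, maxiter=200)
            ok = bool(res.converged) and np.isfinite(res.fe_params.to_numpy()).all() \
                and np.isfinite(_fe_bse(res)).all() and np.isfinite(res.llf)
            return res, ok

    attempts = [(vc, "lbfgs", False), (None, "lbfgs", True), (None, "powell", True)]
    res, fallback = None, False
    for vc_formula, method, is_fallback in attempts:
        try:
            res, ok = _fit(vc_formula, method)
        except (np.linalg.LinAlgError, ValueError):
            ok = False
        if ok:
            fallback = is_fallback
            break
    else:
        if res is None:
            raise ValidationError("mixed-model fit failed for every fallback")
        fallback = True
    if fallback:
        logger.warning("nested random-effects fit singular or non-converged; "
                       "using subject-only intercepts")
    return LMMFit(result=res, fixed=fixed, response=response, ml=not reml,
                  converged=bool(res.converged), subject_only_fallback=fallback)


def _fe_bse(res) -> np.ndarray:
    k = len(res.fe_params)
    return np.asarray(res.bse[:k], dtype=float)


def _fe_cov(res) -> np.ndarray:
    k = len(res.fe_params)
    return np.asarray(res.cov_params())[:k, :k]


def lrt_compare(small: LMMFit, large: LMMFit) -> LRTResult:
    """Chi-square difference test between two nested ML fits.

    The statistic is clipped at zero; the degrees of freedom equal the
    difference in fixed-effect parameter counts.
    """
    if not (small.ml and large.ml):
        raise ValidationError("likelihood-ratio comparison requires ML fits, not REML")
    if small.response != large.response:
        raise ValidationError("models fit different responses")
    if not set(small.fixed_names) <= set(large.fixed_names):
        raise ValidationError("models are not nested (small's terms must be a "
                              "subset of large's)")
    df = large.n_fixed - small.n_fixed
    chi2 = max(0.0, 2.0 * (large.llf - small.llf))
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p)


def sequential_model_comparison(df: pd.DataFrame, terms: list[str],
                                response: str = "pct_change", base: str = "1",
                                **fit_kwargs) -> list[tuple[str, LRTResult, LMMFit]]:
    """Fit an increasing ladder of fixed-effect structures and LRT each step.

    ``terms`` are added cumulatively to ``base`` (e.g. task -> +stage ->
    +task:stage -> +bin ...), mirroring sequential evaluation of each effect
    with an identical random structure throughout.
    """
    current = base
    prev = fit_lmm(df, current, response=response, **fit_kwargs)
    ladder = []
    for term in terms:
        current = f"{current} + {term}"
        fit = fit_lmm(df, current, response=response, **fit_kwargs)
        ladder.append((term, lrt_compare(prev, fit), fit))
        prev = fit
    return ladder


def posthoc_contrasts(fit: LMMFit, contrasts: dict[str, np.ndarray],
                      family_size: int | None = None) -> list[ContrastResult]:
    """Linear contrasts of fixed coefficients with z-approximation p-values.

    Two-sided p from the standard normal; Bonferroni correction over
    ``family_size`` (defaults to the number of contrasts supplied).
    """
    m = family_size or len(contrasts)
    k = fit.n_fixed
    beta = fit.result.fe_params.to_numpy()
    cov = _fe_cov(fit.result)
    out = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.shape != (k,):
            raise ValidationError(
                f"contrast '{name}' has length {c.shape}, model has {k} fixed coefficients")
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(ContrastResult(name=name, estimate=est, se=se, z=z,
                                  p_raw=p_raw, p_adj=min(1.0, m * p_raw)))
    return out


def cell_contrast(fit: LMMFit, cell_a: dict, cell_b: dict,
                  average_over: dict[str, list] | None = None) -> np.ndarray:
    """Design-row difference between two cells of the fixed-effect structure.

    Each cell fixes factor levels (e.g. {"network": "default", "stage":
    "response"}); factors in ``average_over`` are marginalized by averaging
    design rows over their listed levels.
    """
    di = fit.result.model.data.design_info

    def mean_row(cell: dict) -> np.ndarray:
        if average_over:
            grids = [dict(cell)]
            for factor, levels in average_over.items():
                grids = [dict(g, **{factor: lev}) for g in grids for lev in levels]
        else:
            grids = [dict(cell)]
        X = patsy.dmatrix(di, pd.DataFrame(grids))
        return np.asarray(X).mean(axis=0)

    return mean_row(cell_a) - mean_row(cell_b)


def rm_anova_check(df: pd.DataFrame, dv: str = "pct_change",
                   factors: tuple[str, str] = ("network", "stage"),
                   subject: str = "subject") -> pd.DataFrame:
    """Simplified cross-check: average across electrodes (and bins) per
    subject x cell, then a within-subject factorial ANOVA.

    Subjects missing any factor cell are removed listwise with a warning.
    Returns the ANOVA table (F, num/den df, p per effect).
    """
    agg = (df.groupby([subject, *factors], observed=True)[dv]
             .mean().reset_index())
    n_cells = int(np.prod([agg[f].nunique() for f in factors]))
    counts = agg.groupby(subject, observed=True).size()
    complete = counts[counts == n_cells].index
    dropped = sorted(set(agg[subject]) - set(complete))
    if dropped:
        warnings.warn(f"subjects dropped from RM-ANOVA (incomplete cells): {dropped}",
                      stacklevel=2)
        agg = agg[agg[subject].isin(complete)]
    if agg[subject].nunique() < 2:
        raise ValidationError("need at least 2 complete subjects for RM-ANOVA")
    # degenerate input: no within-subject variation across cells at all ->
    # every effect and error sum of squares is zero; report F = 0, p = 1
    if agg.groupby(subject, observed=True)[dv].var().max() < 1e-24:
        effects = [factors[0], factors[1], f"{factors[0]}:{factors[1]}"]
        n = agg[subject].nunique()
        return pd.DataFrame({"F Value": 0.0, "Num DF": 1.0,
                             "Den DF": float(n - 1), "Pr > F": 1.0},
                            index=pd.Index(effects))
    res = AnovaRM(agg, depvar=dv, subject=subject, within=list(factors)).fit()
    return res.anova_table
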