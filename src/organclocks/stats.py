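"""Downstream association statistics for age gaps.

Covers the inference layer: ordinary least squares "age gap ~ trait +
age + sex" with Benjamini-Hochberg FDR control per analysis family,
inverse-variance fixed-effect meta-analysis across cohorts, Cox
proportional-hazards models "event ~ age gap + age + sex" (gap entered as
a z-score, so hazard ratios are per SD), and logistic e-ageotype/disease
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    model_name: str
    trait: str
    effect: float
    se: float
    ci95: tuple[float, float]
    p: float
    q: float | None
    n: int
    covariates: tuple[str, ...]

    def effect_in_years(self, raw_gap_sd: float) -> float:
        """Convert a z-gap-scale effect to years of additional aging."""
        return self.effect * raw_gap_sd


@dataclass
class MetaResult:
    effects: np.ndarray
    ses: np.ndarray
    weights: np.ndarray
    effect: float
    se: float
    z: float
    p: float


@dataclass
class SurvivalResult:
    model_name: str
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    coefficient: float
    se: float
    n_events: int
    n_subjects: int


def linear_association(
    zgap: np.ndarray,
    trait: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    model_name: str = "",
    trait_name: str = "trait",
) -> AssociationResult:
    """OLS fit of z_gap ~ trait + age + sex; returns the trait coefficient.

    Subjects with any missing value are dropped listwise. For a binary
    trait the effect is the adjusted mean z-gap difference between groups;
    for a continuous trait it is the per-unit slope.
    """
    df = pd.DataFrame({"zgap": zgap, "trait": trait, "age": age, "sex": sex}).astype(float)
    before = len(df)
    df = df.dropna()
    if len(df) < before:
        logger.info("listwise deletion dropped %d subjects", before - len(df))
    X = sm.add_constant(df[["trait", "age", "sex"]], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack().sort_values(ascending=False)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); most collinear "
            f"columns: {pairs.index[0]}"
        )
    fit = sm.OLS(df["zgap"], X).fit()
    eff, se = float(fit.params["trait"]), float(fit.bse["trait"])
    return AssociationResult(
        model_name=model_name,
        trait=trait_name,
        effect=eff,
        se=se,
        ci95=(eff - 1.96 * se, eff + 1.96 * se),
        p=float(fit.pvalues["trait"]),
        q=None,
        n=len(df),
        covariates=("age", "sex"),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fixed_effect_meta(effects, ses) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooling of study estimates."""
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if effects.size == 0:
        raise ValueError("no studies to pool")
    if (ses <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses ** 2
    combined = float((w * effects).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    z = combined / se
    p = 2 * sps.norm.sf(abs(z))
    return MetaResult(effects, ses, w / w.sum(), combined, se, float(z), float(p))


def cox_ph_association(
    zgap: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    model_name: str = "",
    ties: str = "breslow",
) -> SurvivalResult:
    """Cox PH model event ~ z-gap + age + sex, Breslow tie handling.

    The gap enters as a z-score, so the hazard ratio is per one SD of age
    gap. Wald confidence interval and p-value.
    """
    if ties != "breslow":
        raise NotImplementedError("only Breslow tie handling is available")
    df = pd.DataFrame(
        {"zgap": zgap, "T": time, "E": event, "age": age, "sex": sex}
    ).astype(float).dropna()
    if (df["T"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    n_events = int(df["E"].sum())
    if n_events == 0:
        raise ValueError("no events observed: Cox model undefined")
    covars = ["zgap"] + [c for c in ("age", "sex") if df[c].std() > 0]
    cph = CoxPHFitter()
    try:
        cph.fit(df[covars + ["T", "E"]], duration_col="T", event_col="E")
    except Exception as exc:  # surface convergence/separation diagnostics
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    coef = float(cph.params_["zgap"])
    se = float(cph.standard_errors_["zgap"])
    hr = float(np.exp(coef))
    return SurvivalResult(
        model_name=model_name,
        hazard_ratio=hr,
        ci95=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
        p=float(cph.summary.loc["zgap", "p"]),
        coefficient=coef,
        se=se,
        n_events=n_events,
        n_subjects=len(df),
    )


def ageotype_logistic(
    trait: np.ndarray,
    membership: np.ndarray,
    trait_name: str = "trait",
    ageotype_name: str = "",
) -> AssociationResult:
    """Logistic regression trait ~ e-ageotype membership (both binary).

    Returns the log-odds coefficient of membership. Perfect separation and
    empty levels raise with a diagnostic.
    """
    trait = np.asarray(trait, dtype=float)
    membership = np.asarray(membership, dtype=float)
    for name, v in (("trait", trait), ("membership", membership)):
        levels = np.unique(v[~np.isnan(v)])
        if not np.isin(levels, [0.0, 1.0]).all():
            raise ValueError(f"{name} must be binary 0/1")
        if len(levels) < 2:
            raise ValueError(f"{name} has a single level: degenerate input")
    keep = ~(np.isnan(trait) | np.isnan(membership))
    X = sm.add_constant(membership[keep])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(trait[keep], X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError(f"perfect separation between trait and ageotype: {exc}") from exc
    eff, se = float(fit.params[1]), float(fit.bse[1])
    return AssociationResult(
        model_name=ageotype_name,
        trait=trait_name,
        effect=eff,
        se=se,
        ci95=(eff - 1.96 * se, eff + 1.96 * se),
        p=float(fit.pvalues[1]),
        q=None,
        n=int(keep.sum()),
        covariates=(),
    )


def adjust_family(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust a family of association results in place (fills q)."""
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
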