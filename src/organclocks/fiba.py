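"""Feature importance for biological aging (FIBA) and chronological PFI.

PFI is classic permutation feature importance for the clock's target:
the drop in Pearson correlation between ensemble-mean predicted and
chronological age when one probe's column is shuffled across subjects
(mean over 5 shuffles).

FIBA instead asks how much a probe supports the clock's *biological*
signal: per bootstrap instance, the age gap is recomputed with the probe
shuffled (predictions, LOWESS calibration, z-scoring and the linear model
z_gap ~ trait + age + sex are all redone), and the FIBA score is the drop
in the sign-oriented trait association. Probes with a zero coefficient in
an instance cannot change that instance's predictions, so their score is
exactly zero by construction (no permutation is run). A probe is FIBA+
when fewer than 5% of its per-instance scores are negative, provided it
carries a nonzero coefficient in enough instances (100 of 500) to be
considered at all. FIBA+ organ proteins define the second-generation,
trait-optimized ("Cognition*") clocks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agegap import GapConfig, fit_lowess_calibration
from .clocks import ClockConfig, ClockModel, CohortData, standardize_features, train_bagged_clock

logger = logging.getLogger(__name__)


@dataclass
class FibaConfig:
    n_permutations: int = 5
    #: sign (+1/-1) of the trait's expected association with the age gap
    expected_direction: int = 1
    negative_fraction_threshold: float = 0.05
    #: nonzero-coefficient instances required for a probe to be considered,
    #: on the reference 500-bootstrap scale (rescaled pro rata for other B)
    min_nonzero_bootstraps: int = 100
    reference_bootstraps: int = 500
    seed: int = 0
    #: refit the LOWESS calibration on permuted predictions (default), or
    #: reuse the instance's unpermuted calibration curve
    recalibrate_after_permutation: bool = True
    #: re-estimate the z-score mean/SD on each permuted gap vector instead of
    #: reusing the instance's baseline standardization. Off by default:
    #: permutation inflates the gap SD, so re-estimating the scale shrinks
    #: the standardized trait coefficient for *every* variance-carrying
    #: probe and biases FIBA scores positive even for trait-inert probes
    restandardize_after_permutation: bool = False
    #: evaluate each ensemble instance on its own bootstrap resample of the
    #: evaluation cohort (default) rather than on the full cohort. With a
    #: single shared cohort an inert probe's finite-sample correlation with
    #: the trait is identical in every instance, so the fraction-negative
    #: rule cannot average it away; per-instance resampling restores
    #: sampling variability and makes the empirical one-tailed p-value
    #: meaningful
    resample_per_instance: bool = True
    #: association statistic: trait "coefficient" or its "t" statistic
    association_statistic: str = "coefficient"
    #: LOWESS settings for instance-level gap calibration; the small
    #: interpolation delta keeps the ~B*p*5 refits tractable and is applied
    #: identically to baseline and permuted gaps
    gap_config: GapConfig = field(
        default_factory=lambda: GapConfig(delta_frac=0.01)
    )

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.negative_fraction_threshold < 1:
            raise ValueError("negative_fraction_threshold must be in (0, 1)")
        if self.expected_direction not in (-1, 1):
            raise ValueError("expected_direction must be +1 or -1")

    def effective_min_nonzero(self, n_bootstraps: int) -> int:
        if n_bootstraps == self.reference_bootstraps:
            return self.min_nonzero_bootstraps
        return math.ceil(self.min_nonzero_bootstraps * n_bootstraps / self.reference_bootstraps)


@dataclass
class FibaResult:
    """Per-probe FIBA/PFI summary plus the instance-level score matrix."""

    table: pd.DataFrame  # probe, pfi, mean_fiba, fraction_negative, n_nonzero, considered, fiba_plus
    instance_scores: pd.DataFrame  # B x probes
    model_name: str
    trait: str

    def fiba_plus_probes(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["fiba_plus"], "probe"])


class _GapAssociation:
    """Oriented trait association of LOWESS-calibrated, z-scored gaps.

    The design matrix (intercept, trait, age, sex, minus any degenerate
    column) is fixed across permutations, so its pseudoinverse is
    precomputed; only the response (the z-scored gap) changes.
    """

    def __init__(
        self,
        age: np.ndarray,
        sex: np.ndarray,
        trait: np.ndarray,
        cohorts: np.ndarray,
        config: FibaConfig,
    ):
        self.age = age
        self.config = config
        if np.std(trait) == 0:
            raise ValueError("trait is constant: no association to measure")
        cols = [np.ones_like(age), trait]
        self.names = ["const", "trait"]
        for name, c in (("age", age), ("sex", sex)):
            if np.std(c) == 0:
                logger.warning("covariate %r is constant; dropped from the FIBA model", name)
            else:
                cols.append(c)
                self.names.append(name)
        self.D = np.column_stack(cols)
        self.pinv = np.linalg.pinv(self.D)
        self.trait_idx = 1
        self.groups = [np.flatnonzero(cohorts == c) for c in pd.unique(cohorts)]
        self.ddof = config.gap_config.zscore_ddof

    def _zgaps(self, pred: np.ndarray, calibrations=None, zparams=None):
        """Calibrated, standardized gaps; returns (z, zparams used)."""
        z = np.empty_like(pred)
        params = []
        for k, idx in enumerate(self.groups):
            if calibrations is None:
                cal = fit_lowess_calibration(self.age[idx], pred[idx], self.config.gap_config)
            else:
                cal = calibrations[k]
            raw = pred[idx] - cal(self.age[idx])
            if zparams is None:
                m, s = raw.mean(), raw.std(ddof=self.ddof)
            else:
                m, s = zparams[k]
            params.append((m, s))
            z[idx] = (raw - m) / s
        return z, params

    def calibrations(self, pred: np.ndarray) -> list:
        return [
            fit_lowess_calibration(self.age[idx], pred[idx], self.config.gap_config)
            for idx in self.groups
        ]

    def baseline(self, pred: np.ndarray, calibrations=None):
        """Baseline association plus the z-standardization parameters."""
        z, params = self._zgaps(pred, calibrations)
        return self._stat(z), params

    def __call__(self, pred: np.ndarray, calibrations=None, zparams=None) -> float:
        z, _ = self._zgaps(pred, calibrations, zparams)
        return self._stat(z)

    def _stat(self, z: np.ndarray) -> float:
        beta = self.pinv @ z
        if self.config.association_statistic == "t":
            resid = z - self.D @ beta
            dof = len(z) - self.D.shape[1]
            sigma2 = (resid @ resid) / dof
            cov = sigma2 * np.linalg.inv(self.D.T @ self.D)
            stat = beta[self.trait_idx] / np.sqrt(cov[self.trait_idx, self.trait_idx])
        else:
            stat = beta[self.trait_idx]
        return self.config.expected_direction * float(stat)



def compute_pfi(
    model: ClockModel,
    cohort: CohortData,
    probe: str,
    config: FibaConfig | None = None,
) -> float:
    """Chronological permutation feature importance for one probe.

    Score = r_original - mean over permutations of r_permuted, on
    ensemble-mean predictions. Exactly zero (no permutation run) when the
    probe's coefficient is zero in every instance.
    """
    config = config or FibaConfig()
    if probe not in model.probes:
        raise ValueError(f"probe {probe!r} not in model feature set")
    j = model.probes.index(probe)
    mean_coefs = model.coefs.mean(axis=0)
    if (model.coefs[:, j] == 0).all():
        return 0.0
    X, _, _ = standardize_features(cohort, model.probes, model.feature_means, model.feature_sds)
    y = cohort.age
    base_pred = X @ mean_coefs + model.intercepts.mean()
    r_orig = np.corrcoef(base_pred, y)[0, 1]
    n = len(y)
    rs = []
    for rep in range(config.n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0, j, rep]))
        permuted = X[:, j][rng.permutation(n)]
        pred = base_pred + mean_coefs[j] * (permuted - X[:, j])
        rs.append(np.corrcoef(pred, y)[0, 1])
    return float(r_orig - np.mean(rs))


def compute_fiba(
    model: ClockModel,
    cohort: CohortData,
    trait: str,
    config: FibaConfig | None = None,
) -> FibaResult:
    """Per-probe, per-bootstrap-instance FIBA scores on an evaluation cohort.

    Permutation seeds are derived per (instance, probe, replicate) from the
    master seed, so evaluation order cannot change results.
    """
    config = config or FibaConfig()
    if trait not in cohort.meta.columns:
        raise ValueError(f"trait column {trait!r} missing from cohort metadata")
    trait_vals = cohort.meta[trait].to_numpy(dtype=float)
    cohorts = (
        cohort.meta["cohort"].to_numpy()
        if "cohort" in cohort.meta.columns
        else np.zeros(len(trait_vals), dtype=int)
    )
    age, sex = cohort.age, cohort.sex
    full_assoc = _GapAssociation(age, sex, trait_vals, cohorts, config)
    X, _, _ = standardize_features(cohort, model.probes, model.feature_means, model.feature_sds)
    n = X.shape[0]
    B = model.n_instances
    p = len(model.probes)
    scores = np.zeros((B, p))

    for b in range(B):
        beta = model.coefs[b]
        if not beta[:p].any():
            continue  # no probe can change this instance: all scores stay 0
        if config.resample_per_instance:
            rrng = np.random.default_rng(
                np.random.SeedSequence([config.seed, b, 1_000_003])
            )
            idx = rrng.integers(0, n, size=n)
            Xb = X[idx]
            assoc = _GapAssociation(
                age[idx], sex[idx], trait_vals[idx], cohorts[idx], config
            )
        else:
            Xb = X
            assoc = full_assoc
        pred_b = Xb @ beta + model.intercepts[b]
        if config.recalibrate_after_permutation:
            base_cals = None
            fit_cals = assoc.calibrations(pred_b)
        else:
            base_cals = fit_cals = assoc.calibrations(pred_b)
        a_b, zparams = assoc.baseline(pred_b, fit_cals)
        if config.restandardize_after_permutation:
            zparams = None
        for j in np.flatnonzero(beta[:p] != 0):
            col = Xb[:, j]
            a_perm = np.empty(config.n_permutations)
            for rep in range(config.n_permutations):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, b, j, rep])
                )
                pred = pred_b + beta[j] * (col[rng.permutation(n)] - col)
                a_perm[rep] = assoc(pred, base_cals, zparams)
            scores[b, j] = a_b - a_perm.mean()

    nonzero = (model.coefs[:, :p] != 0).sum(axis=0)
    min_nz = config.effective_min_nonzero(B)
    considered = nonzero >= min_nz
    frac_neg = (scores < 0).sum(axis=0) / B  # denominator: all instances
    fiba_plus = considered & (frac_neg < config.negative_fraction_threshold)
    pfi = np.array([compute_pfi(model, cohort, pr, config) for pr in model.probes])
    table = pd.DataFrame(
        {
            "probe": model.probes,
            "pfi": pfi,
            "mean_fiba": scores.mean(axis=0),
            "fraction_negative": frac_neg,
            "n_nonzero": nonzero,
            "considered": considered,
            "fiba_plus": fiba_plus,
        }
    )
    return FibaResult(
        table=table,
        instance_scores=pd.DataFrame(scores, columns=model.probes),
        model_name=model.model_name,
        trait=trait,
    )


def select_fiba_plus(result: FibaResult, config: FibaConfig | None = None) -> frozenset[str]:
    """FIBA+ probes: considered and with < threshold fraction of negative
    per-instance scores (strict inequality)."""
    config = config or FibaConfig()
    t = result.table
    mask = t["considered"] & (t["fraction_negative"] < config.negative_fraction_threshold)
    return frozenset(t.loc[mask, "probe"])


def train_cognition_model(
    train: CohortData,
    fiba_plus: frozenset[str],
    clock_config: ClockConfig,
    base_name: str = "brain",
) -> ClockModel:
    """Retrain a clock on the FIBA+ subset (second-generation model).

    The caller restricts ``train`` to cognitively unimpaired subjects.
    """
    if not fiba_plus:
        raise ValueError("empty FIBA+ set: nothing to retrain on")
    name = "Cognition" + base_name[:1].upper() + base_name[1:]
    return train_bagged_clock(train, fiba_plus, clock_config, model_name=name)
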