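"""Association analyses: Spearman correlations and linear mixed-effects models.

Two model classes follow the statsmodels Model/Results convention:

* :class:`BaselineRafhModel` — cross-sectional model of baseline RAFH on one
  or more covariates with a random intercept per participant to absorb
  inter-eye correlation.
* :class:`LongitudinalRafhModel` — RAFH over time with fixed effects of time
  (plus treatment arm and the time x arm interaction when the treatment
  question is asked), a crossed random intercept for participant, a random
  intercept for eye nested in participant, and a random slope for eye over
  time.

Both are REML fits through statsmodels MixedLM; inference on fixed effects
is Wald z (CI = estimate +/- 1.96 SE).  The longitudinal model carries an
explicit convergence fallback ladder (drop the eye slope, then the eye
intercept), each step logged, never silent.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

Z95 = 1.96

#: Baseline covariates screened one-by-one in the univariate models.
DEFAULT_BASELINE_COVARIATES = [
    "lesion_number",
    "sqrt_area",
    "perimeter",
    "bmi",
    "age",
    "sex_male",
    "cvd_yes",
    "smoking_yes",
    "faf_pattern_2",
    "foveal_yes",
    "multifocal",
]


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    defined: bool = True


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (<= 10), ties via average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = len(rx)
    count = 0
    total = 0
    batch: list[np.ndarray] = []

    def flush(batch_arr: list[np.ndarray]) -> int:
        perms = np.array(batch_arr)
        perms = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
        rhos = perms @ rx / n
        return int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))

    for perm in itertools.permutations(ry):
        batch.append(np.asarray(perm))
        total += 1
        if len(batch) == 50000:
            count += flush(batch)
            batch = []
    if batch:
        count += flush(batch)
    return count / total


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p via the t approximation for n > 10 and the exact permutation
    distribution for n <= 10.  Constant input leaves rho undefined (NaN,
    ``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, defined=False)
    rho, p_t = stats.spearmanr(x, y)
    if n <= 10:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(p_t)
    return SpearmanResult(float(rho), p, n)


def tertile_correlation_panel(
    growth_list: Sequence, baseline_rafh: Sequence[float]
) -> pd.DataFrame:
    """Spearman(baseline RAFH, growth rate) for each metric, overall and per tertile.

    ``growth_list`` holds GrowthRates with tertiles already assigned;
    ``baseline_rafh`` is aligned with it.  Returns a tidy frame with columns
    metric, subset, rho, p_value, n.
    """
    rafh = np.asarray(baseline_rafh, dtype=float)
    if len(rafh) != len(growth_list):
        raise ValueError("baseline_rafh must align with growth_list")
    if any(g.tertile is None for g in growth_list):
        raise ValueError("tertiles must be assigned before building the panel")
    tert = np.array([g.tertile for g in growth_list])
    metrics = {
        "area_rate": np.array([g.area_rate for g in growth_list]),
        "sqrt_rate": np.array([g.sqrt_rate for g in growth_list]),
        "perim_adj_rate": np.array([g.perim_adj_rate for g in growth_list]),
    }
    rows = []
    subsets = [("all", np.ones(len(rafh), dtype=bool))] + [
        (f"T{t}", tert == t) for t in (1, 2, 3)
    ]
    for name, values in metrics.items():
        for subset, sel in subsets:
            if sel.sum() < 3:
                raise ValueError(f"subset {subset} has fewer than 3 eyes")
            res = spearman_assoc(rafh[sel], values[sel])
            rows.append(
                {"metric": name, "subset": subset, "rho": res.rho, "p_value": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-model results container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelFit:
    """Results of a mixed-model fit: Wald-z fixed effects plus variance components."""

    fixed_effects: list[FixedEffect]
    random_variances: dict[str, float]
    n_obs: int
    n_eyes: int
    n_participants: int
    converged: bool
    description: str = ""
    fallback: str | None = None

    def fixed(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(f"no fixed effect named {name!r}; have {[f.name for f in self.fixed_effects]}")

    @property
    def params(self) -> dict[str, float]:
        return {fe.name: fe.estimate for fe in self.fixed_effects}

    def summary(self) -> str:
        lines = [self.description or "Mixed-effects model",
                 f"n_obs={self.n_obs}  n_eyes={self.n_eyes}  n_participants={self.n_participants}  "
                 f"converged={self.converged}" + (f"  fallback={self.fallback}" if self.fallback else "")]
        lines.append(f"{'term':<28}{'est':>10}{'SE':>10}{'95% CI':>24}{'p':>10}")
        for fe in self.fixed_effects:
            ci = f"({fe.ci_low:+.4f}, {fe.ci_high:+.4f})"
            lines.append(f"{fe.name:<28}{fe.estimate:>+10.4f}{fe.se:>10.4f}{ci:>24}{fe.p:>10.4g}")
        lines.append("random-effect variances: " + ", ".join(
            f"{k}={v:.5g}" for k, v in self.random_variances.items()))
        return "\n".join(lines)


def _wald_effects(result) -> list[FixedEffect]:
    fe = []
    params = result.fe_params
    ses = result.bse_fe
    for name in params.index:
        est = float(params[name])
        se = float(ses[name])
        z = est / se if se > 0 else float("inf")
        p = 2.0 * stats.norm.sf(abs(z))
        fe.append(FixedEffect(name, est, se, est - Z95 * se, est + Z95 * se, float(p)))
    return fe


def _counts(data: pd.DataFrame) -> tuple[int, int, int]:
    n_obs = len(data)
    if "eye" in data.columns:
        n_eyes = data.groupby(["participant_id", "eye"]).ngroups
    else:
        n_eyes = data["participant_id"].nunique()
    n_part = data["participant_id"].nunique()
    return n_obs, n_eyes, n_part


# ---------------------------------------------------------------------------
# Baseline cross-sectional model
# ---------------------------------------------------------------------------


class BaselineRafhModel:
    """Baseline RAFH ~ covariates + random intercept(participant), REML.

    ``data`` holds one row per eye at baseline with a ``rafh`` response,
    a ``participant_id`` grouping column, and numeric covariate columns
    (binary factors coded 0/1).
    """

    def __init__(self, data: pd.DataFrame, covariates: Sequence[str], response: str = "rafh"):
        if len(covariates) == 0:
            raise ValueError("at least one covariate is required")
        cols = [response, "participant_id", *covariates]
        self.data = data.dropna(subset=list(cols)).copy()
        self.covariates = list(covariates)
        self.response = response

    @classmethod
    def from_cohort(cls, series_list, covariate: str) -> "BaselineRafhModel":
        return cls(baseline_frame(series_list), [covariate])

    def fit(self) -> ModelFit:
        formula = f"{self.response} ~ " + " + ".join(self.covariates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(formula, self.data, groups=self.data["participant_id"])
            result = model.fit(reml=True)
        n_obs, n_eyes, n_part = _counts(self.data)
        return ModelFit(
            fixed_effects=_wald_effects(result),
            random_variances={
                "participant_intercept": float(np.asarray(result.cov_re)[0, 0]),
                "residual": float(result.scale),
            },
            n_obs=n_obs,
            n_eyes=n_eyes,
            n_participants=n_part,
            converged=bool(result.converged),
            description=f"Baseline mixed model: {formula}",
        )


def baseline_frame(series_list) -> pd.DataFrame:
    """One row per eye at baseline with the modelling covariates.

    RAFH is the grader mean at the first visit; categorical covariates are
    coded as 0/1 indicators (reference levels: female, no smoking, no CVD,
    FAF pattern group 1, no foveal involvement, unifocal).
    """
    rows = []
    for s in series_list:
        v = s.visits.iloc[0]
        rows.append(
            {
                "participant_id": s.participant_id,
                "eye": s.eye,
                "rafh": 0.5 * (float(v["rafh_g1"]) + float(v["rafh_g2"])),
                "sqrt_area": math.sqrt(float(v["ga_area_mm2"])),
                "perimeter": float(v["ga_perimeter_mm"]),
                "lesion_number": float(v["focus_count"]),
                "multifocal": float(float(v["focus_count"]) > 1),
                "age": float(v["age"]),
                "bmi": float(v["bmi"]),
                "sex_male": float(str(v["sex"]).lower().startswith("m")),
                "smoking_yes": float(str(v["smoking"]).lower().startswith("y")),
                "cvd_yes": float(str(v["cvd"]).lower().startswith("y")),
                "faf_pattern_2": float(int(v["faf_pattern_group"]) == 2),
                "foveal_yes": float(str(v["foveal_involvement"]).lower().startswith("y")),
            }
        )
    return pd.DataFrame(rows)


def fit_univariate_baseline(data: pd.DataFrame, covariate: str) -> ModelFit:
    """Screen a single baseline covariate against RAFH."""
    return BaselineRafhModel(data, [covariate]).fit()


def fit_multivariate_baseline(
    data: pd.DataFrame, univariate_fits: dict[str, ModelFit], alpha: float = 0.05
) -> ModelFit | None:
    """Joint model of every covariate with univariate p < alpha.

    Returns None (logged) when no covariate passes the screen — the explicit
    "no multivariate model" outcome, not an error.
    """
    selected = [
        cov for cov, fit in univariate_fits.items() if fit.converged and fit.fixed(cov).p < alpha
    ]
    if not selected:
        logger.info("no covariate passed the univariate screen at p < %.2f", alpha)
        return None
    return BaselineRafhModel(data, selected).fit()


# ---------------------------------------------------------------------------
# Longitudinal model
# ---------------------------------------------------------------------------


class LongitudinalRafhModel:
    """RAFH over time with participant/eye random structure.

    Fixed effects: time (+ arm and time x arm when ``with_arm``).  Random
    effects: participant intercept (grouping factor), eye intercept nested
    in participant, and an eye-specific random slope on time, the latter two
    as uncorrelated variance components.  When the full structure fails to
    converge the model refits on an explicit fallback ladder: first without
    the eye slope, then without the eye intercept; every step is logged.

    ``window_years`` limits follow-up: 1.5 years for the treatment question
    (drug stopped at 18 months), 2.0 years for the pooled drift.  Setting
    ``adherence_min_pct`` excludes all eyes of participants whose recorded
    adherence falls below the threshold (missing adherence passes).
    """

    TREATMENT_WINDOW_YEARS = 1.5
    DRIFT_WINDOW_YEARS = 2.0

    def __init__(
        self,
        data: pd.DataFrame,
        window_years: float | None = None,
        with_arm: bool = True,
        adherence_min_pct: float | None = None,
    ):
        if window_years is None:
            window_years = self.TREATMENT_WINDOW_YEARS if with_arm else self.DRIFT_WINDOW_YEARS
        self.window_years = float(window_years)
        self.with_arm = bool(with_arm)
        self.adherence_min_pct = adherence_min_pct
        df = data.copy()
        if "rafh" not in df.columns:
            df["rafh"] = 0.5 * (df["rafh_g1"] + df["rafh_g2"])
        df = df[df["time_years"] <= self.window_years + 1e-9]
        if adherence_min_pct is not None:
            adh = df.groupby("participant_id")["adherence_pct"].min()
            drop = adh.index[adh.notna() & (adh < float(adherence_min_pct))]
            if len(drop):
                logger.info("adherence filter (<%s%%) excludes participants: %s",
                            adherence_min_pct, sorted(drop.tolist()))
            df = df[~df["participant_id"].isin(set(drop))]
        df["arm_metformin"] = (df["arm"].astype(str) == "metformin").astype(float)
        self.data = df.reset_index(drop=True)

    def _formula(self) -> str:
        f = "rafh ~ time_years"
        if self.with_arm:
            f += " + arm_metformin + time_years:arm_metformin"
        return f

    _LADDER = (
        ("full", {"eye": "0 + C(eye)", "eye_slope": "0 + C(eye):time_years"}),
        ("no_eye_slope", {"eye": "0 + C(eye)"}),
        ("no_eye_intercept", None),
    )

    def fit(self) -> ModelFit:
        df = self.data
        formula = self._formula()
        n_obs, n_eyes, n_part = _counts(df)
        last_err: Exception | None = None
        for level, vcf in self._LADDER:
            result = None
            for method in ("lbfgs", "powell"):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        warnings.simplefilter("ignore", RuntimeWarning)
                        warnings.simplefilter("ignore", UserWarning)
                        model = smf.mixedlm(
                            formula,
                            df,
                            groups=df["participant_id"],
                            re_formula="1",
                            vc_formula=vcf,
                        )
                        candidate = model.fit(reml=True, maxiter=500, method=method)
                    if candidate.converged:
                        result = candidate
                        break
                    last_err = RuntimeError(f"non-convergence at level {level!r} ({method})")
                except Exception as err:  # noqa: BLE001 - ladder is the recovery path
                    last_err = err
            if result is None:
                logger.warning(
                    "longitudinal fit failed at level %r (%s); descending ladder", level, last_err
                )
                continue
            variances = {"participant_intercept": float(np.asarray(result.cov_re)[0, 0])}
            if vcf is not None:
                vcomp = dict(zip(model.exog_vc.names, np.asarray(result.vcomp, dtype=float)))
                if "eye" in vcomp:
                    variances["eye_intercept"] = float(vcomp["eye"])
                if "eye_slope" in vcomp:
                    variances["eye_slope"] = float(vcomp["eye_slope"])
            variances["residual"] = float(result.scale)
            if level != "full":
                logger.warning("longitudinal model reported from fallback level %r", level)
            return ModelFit(
                fixed_effects=_wald_effects(result),
                random_variances=variances,
                n_obs=n_obs,
                n_eyes=n_eyes,
                n_participants=n_part,
                converged=True,
                description=f"Longitudinal mixed model: {formula} "
                f"(window <= {self.window_years} yr)",
                fallback=None if level == "full" else level,
            )
        raise RuntimeError(f"longitudinal model failed at every ladder level: {last_err}")


def fit_longitudinal_rafh(
    data: pd.DataFrame,
    window_years: float | None = None,
    with_arm: bool = True,
    adherence_min_pct: float | None = None,
) -> ModelFit:
    """Functional wrapper over :class:`LongitudinalRafhModel`."""
    return LongitudinalRafhModel(
        data, window_years=window_years, with_arm=with_arm, adherence_min_pct=adherence_min_pct
    ).fit()
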