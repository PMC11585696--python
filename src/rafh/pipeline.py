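"""End-to-end cohort analysis: agreement -> consensus -> growth -> models.

``run_pipeline`` is a pure function of (inputs, config, seed): the same
cohort and configuration produce the same report.  Each stage failure is
re-raised as a :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import growth as gr
from . import models as mdl
from .io import EyeSeries, read_cohort_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis configuration; defaults are the analysis' standard settings."""

    cohort_csv: str | None = None
    out_dir: str | None = None
    scale_um_per_px: float | None = None
    threshold_offset: int = 40
    rim_width_um: float = 450.0
    window_um: float = 500.0
    background_mode: str = "local"
    treatment_window_years: float = 1.5
    drift_window_years: float = 2.0
    adherence_min_pct: float = 75.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""

    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


def _fit_to_dict(fit: mdl.ModelFit | None) -> dict | None:
    if fit is None:
        return None
    return {
        "fixed_effects": [dataclasses.asdict(fe) for fe in fit.fixed_effects],
        "random_variances": fit.random_variances,
        "n_obs": fit.n_obs,
        "n_eyes": fit.n_eyes,
        "n_participants": fit.n_participants,
        "converged": fit.converged,
        "fallback": fit.fallback,
        "description": fit.description,
    }


def _versions() -> dict:
    import scipy
    import skimage
    import statsmodels

    from . import __version__

    return {
        "rafh": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-image": skimage.__version__,
    }


def run_pipeline(
    config: RunConfig, cohort: list[EyeSeries] | pd.DataFrame | None = None
) -> dict:
    """Run the cohort analysis and return a JSON-serializable report.

    Stages: load -> agreement (Bland-Altman + ICC, single consensus round)
    -> grader averaging -> growth rates + tertiles -> correlation panel ->
    baseline covariate screen and multivariate model -> longitudinal drift,
    treatment, and adherence-sensitivity models.
    """
    report: dict = {"config": config.to_dict(), "versions": _versions(), "stages": []}

    # --- load ---
    try:
        if cohort is None:
            if config.cohort_csv is None:
                raise ValueError("no cohort given: set cohort_csv or pass a table")
            series_list = read_cohort_table(config.cohort_csv)
        elif isinstance(cohort, pd.DataFrame):
            series_list = _frame_to_series(cohort)
        else:
            series_list = list(cohort)
        flat = pd.concat([s.visits for s in series_list], ignore_index=True)
    except Exception as err:
        raise PipelineStageError("load", err) from err
    report["stages"].append("load")

    # --- agreement & consensus ---
    try:
        for col in ("rafh_g1", "rafh_g2"):
            if col not in flat.columns or flat[col].isna().all():
                raise ValueError(f"column {col!r} missing or empty")
        ids = list(zip(flat["participant_id"], flat["eye"], flat["time_years"]))
        pairs = agr.GraderPairSet(ids, flat["rafh_g1"].to_numpy(), flat["rafh_g2"].to_numpy())
        summary, resolved = agr.grade_agreement(pairs)
        report["agreement"] = {
            "n_images": summary.n,
            "mean_diff": summary.mean_diff,
            "sd_diff": summary.sd_diff,
            "loa_low": summary.loa_low,
            "loa_high": summary.loa_high,
            "icc": summary.icc,
            "icc_ci": [summary.icc_ci_low, summary.icc_ci_high],
            "n_flagged": summary.n_flagged,
            "pct_flagged": 100.0 * summary.n_flagged / summary.n,
        }
    except Exception as err:
        raise PipelineStageError("agreement", err) from err
    report["stages"].append("agreement")

    # --- grader averaging ---
    flat = flat.copy()
    flat["rafh"] = agr.mean_grader_rafh(resolved)
    report["stages"].append("average_graders")

    # --- growth + tertiles ---
    try:
        eligible = [s for s in series_list if s.growth_eligible]
        rates = [gr.growth_rates(s) for s in eligible]
        gr.assign_tertiles(rates)
        baseline_rafh = np.array(
            [0.5 * (s.visits.iloc[0]["rafh_g1"] + s.visits.iloc[0]["rafh_g2"]) for s in eligible]
        )
        report["growth"] = {
            "n_eyes": len(rates),
            "mean_area_rate_mm2_per_yr": float(np.mean([g.area_rate for g in rates])),
            "mean_sqrt_rate_mm_per_yr": float(np.mean([g.sqrt_rate for g in rates])),
            "mean_perim_adj_rate_mm_per_yr": float(np.mean([g.perim_adj_rate for g in rates])),
            "tertile_sizes": [sum(g.tertile == t for g in rates) for t in (1, 2, 3)],
        }
    except Exception as err:
        raise PipelineStageError("growth", err) from err
    report["stages"].append("growth")

    # --- correlation panel ---
    try:
        panel = mdl.tertile_correlation_panel(rates, baseline_rafh)
        report["correlations"] = panel.to_dict(orient="records")
    except Exception as err:
        raise PipelineStageError("correlations", err) from err
    report["stages"].append("correlations")

    # --- baseline models ---
    try:
        base = mdl.baseline_frame(series_list)
        univariate = {}
        for cov in mdl.DEFAULT_BASELINE_COVARIATES:
            if cov in base.columns and base[cov].notna().any():
                univariate[cov] = mdl.fit_univariate_baseline(base, cov)
        multivariate = mdl.fit_multivariate_baseline(base, univariate)
        report["baseline_models"] = {
            "univariate": {cov: _fit_to_dict(f) for cov, f in univariate.items()},
            "multivariate": _fit_to_dict(multivariate),
            "selected": [c for c, f in univariate.items() if f.converged and f.fixed(c).p < 0.05],
        }
    except Exception as err:
        raise PipelineStageError("baseline_models", err) from err
    report["stages"].append("baseline_models")

    # --- longitudinal models ---
    try:
        drift = mdl.fit_longitudinal_rafh(
            flat, window_years=config.drift_window_years, with_arm=False
        )
        treatment = mdl.fit_longitudinal_rafh(
            flat, window_years=config.treatment_window_years, with_arm=True
        )
        sensitivity = mdl.fit_longitudinal_rafh(
            flat,
            window_years=config.treatment_window_years,
            with_arm=True,
            adherence_min_pct=config.adherence_min_pct,
        )
        report["longitudinal"] = {
            "drift": _fit_to_dict(drift),
            "treatment": _fit_to_dict(treatment),
            "adherence_sensitivity": _fit_to_dict(sensitivity),
            "rafh_slope_per_year": drift.fixed("time_years").estimate,
            "interaction_p": treatment.fixed("time_years:arm_metformin").p,
        }
    except Exception as err:
        raise PipelineStageError("longitudinal", err) from err
    report["stages"].append("longitudinal")

    return report


def _frame_to_series(df: pd.DataFrame) -> list[EyeSeries]:
    out = []
    for (pid, eye), grp in df.groupby(["participant_id", "eye"], sort=True):
        out.append(EyeSeries(str(pid), str(eye), grp.sort_values("time_years").reset_index(drop=True)))
    return out
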