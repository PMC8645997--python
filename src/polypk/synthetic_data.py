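"""Study-like synthetic cohorts.

The raw clinical data behind the obese-cohort polymyxin B model are not
deposited, so this module is the stand-in: it draws covariates matching the
published cohort summaries (26 obese adults, TBW 75–125 kg with median
≈ 90, BMI 30.04–40.35), assigns empirical loading + q12h maintenance
regimens, simulates steady-state day-4 concentrations from the population
model at either a rich 7-point or sparse 2-point schedule, and censors at
the assay lower limit.

What it deliberately does not emulate: real assay error structure beyond a
proportional CV, dose adjustments during therapy, irregular clinical
sampling times, or infection-site covariates (carried as labels only in the
published cohort and never used in modeling here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body_metrics import append_derived_columns
from .datasets import StudyDataset
from .pk_core import DosingRegimen, PKParameters, concentration
from .population_model import PopulationModel

__all__ = ["StudyDesign", "generate_cohort", "censor_lloq"]

RICH_TIMES = (0.0, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0)
SPARSE_TIMES = (0.0, 2.0)


@dataclass(frozen=True)
class StudyDesign:
    """The sampling and covariate design of the emulated study.

    Times are hours post the morning dose of ``sampling_day``; the trough
    sample (0 h) is drawn immediately before that dose.  ``rich_count_range``
    optionally subsamples the rich schedule to a per-subject count (the
    published rich arm had 4–7 samples per patient); ``None`` keeps all
    seven rich times.
    """

    n_subjects: int = 26
    fraction_rich: float = 10 / 26
    rich_times: tuple[float, ...] = RICH_TIMES
    sparse_times: tuple[float, ...] = SPARSE_TIMES
    sampling_day: int = 4
    lloq: float = 0.25  # mg/L; summed B1 (0.2) + B2 (0.05) assay lower limits
    loading_choices: tuple[float, ...] = (100.0, 150.0, 200.0)
    maintenance_choices: tuple[float, ...] = (50.0, 75.0, 100.0)
    infusion_duration: float = 1.0  # h, per the observed-care protocol
    tau: float = 12.0
    rich_count_range: tuple[int, int] | None = None
    male_fraction: float = 17 / 26
    tbw_range: tuple[float, float] = (75.0, 125.0)
    tbw_beta: tuple[float, float] = (2.0, 38.0 / 9.0)  # median ≈ 90 kg on the range
    bmi_range: tuple[float, float] = (30.04, 40.35)
    age_range: tuple[int, int] = (18, 83)
    scr_median: float = 76.0  # µmol/L
    scr_log_sd: float = 0.63
    scr_range: tuple[float, float] = (34.0, 368.0)
    sofa_range: tuple[int, int] = (5, 17)
    gfr_median: float = 80.9
    gfr_log_sd: float = 0.55
    gfr_range: tuple[float, float] = (11.26, 149.57)
    height_range: tuple[float, float] = (152.4, 220.0)
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_rich <= 1.0):
            raise ValueError("fraction_rich must be in [0, 1]")
        if any(t < 0 or t >= self.tau for t in self.rich_times + self.sparse_times):
            raise ValueError("sampling times must lie within one dosing interval")
        if self.lloq < 0:
            raise ValueError("lloq must be non-negative")


def _truncated_lognormal(
    rng: np.random.Generator, median: float, log_sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = median * np.exp(rng.normal(0.0, log_sd))
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(median, lo, hi))


def _draw_covariates(design: StudyDesign, rng: np.random.Generator) -> dict:
    lo, hi = design.tbw_range
    a, b = design.tbw_beta
    for _ in range(design.max_redraws):
        tbw = lo + (hi - lo) * rng.beta(a, b)
        bmi = rng.uniform(*design.bmi_range)
        height = 100.0 * np.sqrt(tbw / bmi)
        if design.height_range[0] <= height <= design.height_range[1]:
            break
    else:
        raise RuntimeError("could not draw a feasible TBW/BMI/height combination")
    return {
        "SEX": 0 if rng.random() < design.male_fraction else 1,
        "AGE": int(rng.integers(design.age_range[0], design.age_range[1] + 1)),
        "HT": round(float(height), 1),
        "TBW": round(float(tbw), 1),
        "SCR": round(
            _truncated_lognormal(rng, design.scr_median, design.scr_log_sd, *design.scr_range), 1
        ),
        "SOFA": int(rng.integers(design.sofa_range[0], design.sofa_range[1] + 1)),
        "GFR": round(
            _truncated_lognormal(rng, design.gfr_median, design.gfr_log_sd, *design.gfr_range), 2
        ),
    }


def generate_cohort(
    design: StudyDesign,
    model: PopulationModel,
    rng: np.random.Generator | int,
) -> StudyDataset:
    """Generate one cohort as a long-format :class:`StudyDataset`.

    The first ``round(n·fraction_rich)`` subjects are rich-sampled, the rest
    sparse.  Each subject receives a loading dose at t = 0 and maintenance
    q12h through the sampling day; observations are individual predictions
    with proportional residual error, flagged (not removed) when below the
    LLOQ.  Fully deterministic under a fixed seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_rich = int(round(design.n_subjects * design.fraction_rich))
    dose_anchor = 24.0 * (design.sampling_day - 1)  # morning dose of the sampling day
    horizon = dose_anchor + design.tau
    rows: list[dict] = []

    for i in range(design.n_subjects):
        sid = i + 1
        cov = _draw_covariates(design, rng)
        loading = float(rng.choice(design.loading_choices))
        maintenance = float(rng.choice(design.maintenance_choices))
        regimen = DosingRegimen.loading_plus_q12h(
            loading_mg=loading,
            maintenance_mg=maintenance,
            infusion_rate=loading / design.infusion_duration,
            maintenance_rate=maintenance / design.infusion_duration,
            tau=design.tau,
            horizon=horizon + 1e-9,  # include the sampling-day morning dose
        )
        params = _draw_params(model, rng)

        if i < n_rich:
            times = list(design.rich_times)
            if design.rich_count_range is not None:
                k = int(rng.integers(design.rich_count_range[0], design.rich_count_range[1] + 1))
                k = min(k, len(times))
                # trough always kept; remaining times subsampled without replacement
                rest = rng.choice(len(times) - 1, size=k - 1, replace=False)
                times = [times[0]] + [times[1 + j] for j in sorted(rest)]
        else:
            times = list(design.sparse_times)

        for ev in regimen.events:
            rows.append(
                {"ID": sid, "TIME": ev.start_time, "AMT": ev.amount, "RATE": ev.rate,
                 "EVID": 1, "DV": np.nan, "MDV": 1, "BLQ": 0, **cov}
            )
        abs_times = np.array([dose_anchor + t for t in times])
        pred = np.asarray(concentration(params, regimen, abs_times), dtype=float)
        eps = rng.normal(0.0, model.sigma, size=pred.shape)
        if model.residual_model == "proportional":
            obs = np.maximum(pred * (1.0 + eps), 0.0)
        else:
            obs = np.maximum(pred + eps, 0.0)
        for t_abs, dv in zip(abs_times, obs):
            rows.append(
                {"ID": sid, "TIME": float(t_abs), "AMT": np.nan, "RATE": np.nan,
                 "EVID": 0, "DV": float(dv), "MDV": 0, "BLQ": 0, **cov}
            )

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    cov_tab = append_derived_columns(df[["SEX", "AGE", "HT", "TBW", "SCR"]])
    for col in ("BMI", "IBW", "ABW", "CRCL_TBW", "CRCL_ABW", "CRCL_IBW"):
        df[col] = cov_tab[col].round(2)
    dataset = StudyDataset(df)
    return censor_lloq(dataset, design.lloq)


def _draw_params(model: PopulationModel, rng: np.random.Generator) -> PKParameters:
    def one(name: str, tv: float) -> float:
        w2 = model.omega2.get(name, 0.0)
        return tv if w2 == 0.0 else tv * float(np.exp(rng.normal(0.0, np.sqrt(w2))))

    # fixed draw order keeps cohorts reproducible under a seed
    CL = one("CL", float(np.asarray(model.theta.CL)))
    V2 = one("V2", float(np.asarray(model.theta.V2)))
    Q = one("Q", float(np.asarray(model.theta.Q)))
    V = one("V", float(np.asarray(model.theta.V)))
    return PKParameters(V=V, V2=V2, CL=CL, Q=Q)


def censor_lloq(dataset: StudyDataset, lloq: float) -> StudyDataset:
    """Flag observation rows with DV below ``lloq``.

    Flagged rows stay in the dataset (the file records them) but are
    excluded from estimation input via :meth:`StudyDataset.without_blq`,
    mirroring the study's exclusion criterion.  The flag count is available
    as ``dataset.n_blq``.
    """
    if lloq < 0:
        raise ValueError("lloq must be non-negative")
    df = dataset.df.copy()
    obs = df["EVID"] == 0
    df.loc[obs, "BLQ"] = 0  # flags are recomputed, not accumulated
    df.loc[obs & (df["DV"] < lloq), "BLQ"] = 1
    return StudyDataset(df)
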