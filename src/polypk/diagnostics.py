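"""Goodness-of-fit residuals and the prediction-corrected visual
predictive check (pc-VPC).

CWRES decorrelates each subject's residual vector by the FOCE-linearized
covariance at the conditional eta mode; on a well-specified model they are
approximately standard normal.  The pc-VPC normalizes every observed and
simulated concentration by its population prediction (rescaled to the bin
median) so that subjects on different doses can share percentile bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import StudyDataset
from .estimation import FitResult, FitSettings, ModelSpec, _Encoded, _FOCEProblem
from .population_model import PopulationModel

__all__ = ["cwres", "VPCResult", "pc_vpc", "gof_panels", "vpc_plot"]

_PCTL = (5.0, 50.0, 95.0)


def _problem_for_model(dataset: StudyDataset, model: PopulationModel) -> _FOCEProblem:
    spec = ModelSpec(
        random_effects=tuple(k for k in ("CL", "V2", "Q", "V") if k in model.omega2),
        residual_model=model.residual_model,
    )
    return _FOCEProblem(_Encoded(dataset), spec, FitSettings(compute_se=False))


def _theta_dict(model: PopulationModel) -> dict[str, float]:
    return {k: float(np.asarray(getattr(model.theta, k))) for k in ("V", "V2", "CL", "Q")}


def cwres(dataset: StudyDataset, fit_result: FitResult | PopulationModel) -> pd.DataFrame:
    """Conditional weighted residuals with PRED and IPRED per observation.

    Accepts a converged :class:`FitResult` or a bare population model.
    Residuals use r = y − f(η̂) + Gη̂ and V = GΩG' + Σ(η̂); a singular
    subject covariance falls back to plain weighted residuals with a
    warning.
    """
    model = fit_result.to_population_model() if isinstance(fit_result, FitResult) else fit_result
    prob = _problem_for_model(dataset, model)
    enc = prob.enc
    theta = _theta_dict(model)
    omega2 = np.array([model.omega2[k] for k in prob.spec.random_effects], dtype=float)
    coefs = np.zeros(0)
    eta = prob.optimize_etas(theta, coefs, omega2, model.sigma,
                             eta0=np.zeros((enc.n_subjects, prob.K)))
    pred = prob.predict(theta, coefs, np.zeros_like(eta))
    ipred, G = prob._f_and_jac(theta, coefs, eta)
    var = prob._variance(ipred, model.sigma)
    Om = np.diag(omega2)
    res = np.empty(enc.n_obs)
    for i in range(enc.n_subjects):
        sl = slice(enc.offsets[i], enc.offsets[i + 1])
        Gi = G[sl]
        ri = enc.y[sl] - ipred[sl] + Gi @ eta[i]
        Vi = Gi @ Om @ Gi.T + np.diag(var[sl])
        try:
            L = np.linalg.cholesky(Vi)
            res[sl] = np.linalg.solve(L, ri)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular covariance for subject {enc.subject_ids[i]}; "
                          "using weighted residuals")
            res[sl] = ri / np.sqrt(np.maximum(np.diag(Vi), 1e-12))
    return pd.DataFrame({
        "ID": np.asarray(enc.subject_ids)[enc.sub],
        "TIME": enc.t,
        "DV": enc.y,
        "PRED": pred,
        "IPRED": ipred,
        "CWRES": res,
    })


# ---------------------------------------------------------------------------
# pc-VPC
# ---------------------------------------------------------------------------

@dataclass
class VPCResult:
    """Per-bin observed percentiles and simulated 90% confidence bands."""

    table: pd.DataFrame
    n_replicates: int
    bin_edges: np.ndarray

    def observed_within_band(self, percentile: int = 50) -> np.ndarray:
        lo = self.table[f"sim_p{percentile}_lo"].to_numpy()
        hi = self.table[f"sim_p{percentile}_hi"].to_numpy()
        ob = self.table[f"obs_p{percentile}"].to_numpy()
        return (ob >= lo) & (ob <= hi)


def _time_after_dose(enc: _Encoded) -> np.ndarray:
    """Time since the most recent dose start at or before each observation."""
    starts = enc.ev_start
    mask = (starts <= enc.t[:, None]) & (enc.ev_rate > 0)
    last = np.where(mask, starts, -np.inf).max(axis=1)
    return enc.t - np.where(np.isfinite(last), last, 0.0)


def pc_vpc(
    dataset: StudyDataset,
    model: PopulationModel,
    n_replicates: int = 1000,
    bins: tuple[float, ...] | None = None,
    rng: np.random.Generator | int = 0,
) -> VPCResult:
    """Prediction-corrected VPC of the model against the cohort.

    Observations are binned by nominal time after dose (defaults to the
    protocol times 0, 1, 1.5, 2, 4, 6, 8 h); each observed and simulated
    value is multiplied by bin-median PRED / own PRED; the 5th/50th/95th
    percentiles (Hazen interpolation) of corrected observations are
    compared with the 90% band of the same percentiles across replicates.
    Bins with fewer than 2 observations are merged into their left
    neighbor with a warning.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    prob = _problem_for_model(dataset, model)
    enc = prob.enc
    theta = _theta_dict(model)
    omega2 = np.array([model.omega2[k] for k in prob.spec.random_effects], dtype=float)
    coefs = np.zeros(0)
    pred = prob.predict(theta, coefs, np.zeros((enc.n_subjects, prob.K)))
    tad = _time_after_dose(enc)

    centers = np.asarray(bins if bins is not None else (0.0, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0))
    centers = np.sort(centers)
    assign = np.argmin(np.abs(tad[:, None] - centers[None, :]), axis=1)
    # merge underpopulated (single-observation) bins into a neighbor
    for b in range(len(centers) - 1, -1, -1):
        if np.sum(assign == b) == 1:
            target = b - 1 if b > 0 else b + 1
            warnings.warn(f"bin at {centers[b]} h has <2 observations; merged")
            assign[assign == b] = target
    used = np.unique(assign)

    bin_med_pred = np.empty(enc.n_obs)
    for b in used:
        bin_med_pred[assign == b] = np.median(pred[assign == b])
    correction = bin_med_pred / np.maximum(pred, 1e-12)
    pc_obs = enc.y * correction

    def percentiles_by_bin(values: np.ndarray) -> np.ndarray:
        out = np.empty((len(used), len(_PCTL)))
        for j, b in enumerate(used):
            out[j] = np.percentile(values[assign == b], _PCTL, method="hazen")
        return out

    obs_p = percentiles_by_bin(pc_obs)

    sim_p = np.empty((n_replicates, len(used), len(_PCTL)))
    for r in range(n_replicates):
        eta = rng.normal(0.0, np.sqrt(omega2), size=(enc.n_subjects, prob.K))
        f = prob.predict(theta, coefs, eta)
        eps = rng.normal(0.0, model.sigma, size=enc.n_obs)
        if model.residual_model == "proportional":
            ysim = np.maximum(f * (1.0 + eps), 0.0)
        else:
            ysim = np.maximum(f + eps, 0.0)
        sim_p[r] = percentiles_by_bin(ysim * correction)

    band_lo = np.percentile(sim_p, 5.0, axis=0, method="hazen")
    band_hi = np.percentile(sim_p, 95.0, axis=0, method="hazen")

    rows = []
    for j, b in enumerate(used):
        row = {
            "bin_time": centers[b],
            "n_obs": int(np.sum(assign == b)),
        }
        for k, p in enumerate((5, 50, 95)):
            row[f"obs_p{p}"] = obs_p[j, k]
            row[f"sim_p{p}_lo"] = band_lo[j, k]
            row[f"sim_p{p}_hi"] = band_hi[j, k]
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_replicates=n_replicates,
                     bin_edges=centers[used])


# ---------------------------------------------------------------------------
# plotting (thin layer; tests only assert file creation)
# ---------------------------------------------------------------------------

def gof_panels(residuals: pd.DataFrame, path: str) -> None:
    """Four-panel goodness-of-fit figure: CWRES vs time / PRED, DV vs IPRED / PRED."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    axes[0, 0].scatter(residuals["TIME"], residuals["CWRES"], s=12)
    axes[0, 0].axhline(0, color="k", lw=0.8)
    axes[0, 0].set(xlabel="Time (h)", ylabel="CWRES")
    axes[0, 1].scatter(residuals["PRED"], residuals["CWRES"], s=12)
    axes[0, 1].axhline(0, color="k", lw=0.8)
    axes[0, 1].set(xlabel="PRED (mg/L)", ylabel="CWRES")
    for ax, col in ((axes[1, 0], "IPRED"), (axes[1, 1], "PRED")):
        ax.scatter(residuals[col], residuals["DV"], s=12)
        lim = max(residuals["DV"].max(), residuals[col].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
        ax.set(xlabel=f"{col} (mg/L)", ylabel="DV (mg/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(result: VPCResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table["bin_time"]
    fig, ax = plt.subplots(figsize=(7, 5))
    for p, color in ((5, "tab:blue"), (50, "tab:red"), (95, "tab:blue")):
        ax.fill_between(t, result.table[f"sim_p{p}_lo"], result.table[f"sim_p{p}_hi"],
                        alpha=0.25, color=color)
        ax.plot(t, result.table[f"obs_p{p}"], "-o", color=color, ms=4,
                label=f"observed P{p}")
    ax.set(xlabel="Time after dose (h)", ylabel="Prediction-corrected concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
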