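"""NONMEM-style rectangular datasets: the interchange format of the pipeline.

One row per dose event (EVID=1, AMT/RATE set, DV empty) or observation
(EVID=0, DV in mg/L), long format, with per-subject covariate columns
repeated on every row.  Files are plain CSV with optional ``#``-prefixed
provenance header lines (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_core import DoseEvent, DosingRegimen

__all__ = ["StudyDataset", "read_dataset", "write_dataset", "provenance_header"]

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV", "BLQ"]
COVARIATE_COLUMNS = [
    "SEX", "AGE", "HT", "TBW", "SCR", "SOFA", "GFR",
    "BMI", "IBW", "ABW", "CRCL_TBW", "CRCL_ABW", "CRCL_IBW",
]


class DatasetValidationError(ValueError):
    """Raised when a dataset violates the long-format schema."""


@dataclass
class StudyDataset:
    """A validated cohort in long format.

    ``df`` holds dose and observation rows; covariates, if present, are
    constant within subject.  BLQ observation rows are retained with the
    flag set — exclusion from estimation happens downstream.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- schema ------------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise DatasetValidationError(f"missing mandatory column {col!r}")
        obs = df[df["EVID"] == 0]
        bad_dv = obs[(obs["DV"].isna()) & (obs["BLQ"] == 0)]
        if len(bad_dv):
            raise DatasetValidationError(
                f"observation rows missing DV without BLQ flag at index {list(bad_dv.index)[:5]}"
            )
        doses = df[df["EVID"] == 1]
        if np.any(doses["AMT"].fillna(0).to_numpy() <= 0):
            raise DatasetValidationError("dose rows must have AMT > 0")
        if np.any(df["TIME"].to_numpy() < 0):
            raise DatasetValidationError("TIME must be non-negative")
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                row = int(grp.index[np.argmax(np.diff(t) < 0) + 1])
                raise DatasetValidationError(
                    f"TIME not non-decreasing within subject {sid} at row {row}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.df["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def observations(self, include_blq: bool = True) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if not include_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def regimen_for(self, subject_id, horizon: float | None = None) -> DosingRegimen:
        rows = self.df[(self.df["ID"] == subject_id) & (self.df["EVID"] == 1)]
        if rows.empty:
            raise KeyError(f"subject {subject_id!r} has no dose rows")
        events = tuple(
            DoseEvent(float(r.TIME), float(r.AMT), float(r.RATE)) for r in rows.itertuples()
        )
        hz = horizon if horizon is not None else float(self.df[self.df["ID"] == subject_id]["TIME"].max()) + 24.0
        return DosingRegimen(events=events, horizon=hz)

    def covariates(self) -> pd.DataFrame:
        """One row per subject with whatever covariate columns are present."""
        cols = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        return self.df.groupby("ID", sort=False)[cols].first().reset_index()

    # -- transforms --------------------------------------------------------
    def without_blq(self) -> "StudyDataset":
        """Copy with BLQ observation rows dropped (the estimation input)."""
        keep = ~((self.df["EVID"] == 0) & (self.df["BLQ"] == 1))
        return StudyDataset(self.df[keep].reset_index(drop=True))

    @property
    def n_blq(self) -> int:
        return int(((self.df["EVID"] == 0) & (self.df["BLQ"] == 1)).sum())

    def subset(self, subject_ids, relabel: bool = False) -> "StudyDataset":
        """Rows of the given subjects, in the given order (duplicates allowed).

        With ``relabel`` each selected subject gets a fresh sequential ID,
        which is what a bootstrap resample needs.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            if relabel:
                block["ID"] = new_id
            parts.append(block)
        return StudyDataset(pd.concat(parts, ignore_index=True))


def provenance_header(seed: int | None = None, config: dict | None = None) -> list[str]:
    from . import __version__

    lines = [f"# polypk {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        lines.append(f"# config-sha256: {digest}")
    return lines


def write_dataset(
    dataset: StudyDataset,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write the cohort CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        dataset.df.to_csv(fh, index=False)


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and validate a cohort CSV (``#`` comment lines are skipped)."""
    df = pd.read_csv(path, comment="#")
    return StudyDataset(df)
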