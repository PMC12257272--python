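"""Long-format dataset container and CSV reader/writer.

The canonical dataset is a tidy CSV with one row per event and
NONMEM-style EVID semantics (evid 1 = dose, evid 0 = observation):

======== =========================================================
column   meaning
======== =========================================================
subject  subject identifier (one physical or pseudo animal)
trial    trial identifier
route    IV | FEED_TLS | FEED_OTHERS | SOL_DW | SOL_TUBING
bw       body weight, kg
time     hours since the subject's first dose
evid     1 for dose events, 0 for observations
amount   dose, mg/kg doxycycline base (dose rows only)
conc     plasma concentration, ug/mL (observation rows only)
lloq     lower limit of quantification of the assay, ug/mL
======== =========================================================

An optional ``health`` column (healthy/sick) carries the health-status
label used as a candidate categorical covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from doxypk.params import DoseEvent, Route

__all__ = ["Dataset", "SubjectData", "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = ("subject", "trial", "route", "bw", "time", "evid", "amount", "conc", "lloq")


@dataclass(frozen=True)
class SubjectData:
    """Per-subject view used by simulation and estimation."""

    subject_id: str
    trial: str
    route: Route
    bw: float
    lloq: float
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    obs_conc: np.ndarray
    health: str | None = None

    @cached_property
    def doses(self) -> list[DoseEvent]:
        return [
            DoseEvent(time=float(t), amount=float(a), route=self.route)
            for t, a in zip(self.dose_times, self.dose_amounts)
        ]


class Dataset:
    """Validated long-format dosing/observation table."""

    def __init__(self, df: pd.DataFrame):
        self.df = self._validate(df.copy())

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing required column(s): {', '.join(missing)}")
        problems: list[str] = []
        for col in ("bw", "time", "evid", "amount", "conc", "lloq"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad_route = ~df["route"].isin([r.value for r in Route])
        if bad_route.any():
            problems.append(f"unknown route in rows {list(df.index[bad_route])[:10]}")
        neg_time = df["time"] < 0
        if neg_time.any():
            problems.append(f"negative time in rows {list(df.index[neg_time])[:10]}")
        bad_bw = ~(df["bw"] > 0)
        if bad_bw.any():
            problems.append(f"missing/non-positive bw in rows {list(df.index[bad_bw])[:10]}")
        doses = df["evid"] == 1
        bad_amt = doses & ~(df["amount"] > 0)
        if bad_amt.any():
            problems.append(f"dose rows without positive amount: {list(df.index[bad_amt])[:10]}")
        obs = df["evid"] == 0
        bad_conc = obs & df["conc"].isna()
        if bad_conc.any():
            problems.append(f"observation rows without conc: {list(df.index[bad_conc])[:10]}")
        # every subject must receive a dose no later than its first observation
        for sid, grp in df.groupby("subject", sort=False):
            dt = grp.loc[grp["evid"] == 1, "time"]
            ot = grp.loc[grp["evid"] == 0, "time"]
            if len(ot) and (not len(dt) or dt.min() > ot.min()):
                problems.append(f"subject {sid!r} has an observation before any dose")
        if problems:
            raise ValueError("invalid dataset:\n  " + "\n  ".join(problems))
        return df.sort_values(["subject", "time", "evid"], ascending=[True, True, False]).reset_index(
            drop=True
        )

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject"].unique())

    @property
    def n_subjects(self) -> int:
        return self.df["subject"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["evid"] == 0).sum())

    def routes(self) -> list[Route]:
        return [Route(r) for r in self.df["route"].unique()]

    def filter_routes(self, routes) -> "Dataset":
        routes = {Route(r).value for r in routes}
        return Dataset(self.df[self.df["route"].isin(routes)])

    def filter_subjects(self, subject_ids) -> "Dataset":
        return Dataset(self.df[self.df["subject"].isin(list(subject_ids))])

    def subject(self, subject_id) -> SubjectData:
        grp = self.df[self.df["subject"] == subject_id]
        if grp.empty:
            raise KeyError(f"no such subject: {subject_id!r}")
        doses = grp[grp["evid"] == 1]
        obs = grp[grp["evid"] == 0]
        health = None
        if "health" in grp.columns:
            vals = grp["health"].dropna().unique()
            if len(vals):
                health = str(vals[0])
        return SubjectData(
            subject_id=subject_id,
            trial=str(grp["trial"].iloc[0]),
            route=Route(grp["route"].iloc[0]),
            bw=float(grp["bw"].iloc[0]),
            lloq=float(grp["lloq"].iloc[0]),
            dose_times=doses["time"].to_numpy(dtype=float),
            dose_amounts=doses["amount"].to_numpy(dtype=float),
            obs_times=obs["time"].to_numpy(dtype=float),
            obs_conc=obs["conc"].to_numpy(dtype=float),
            health=health,
        )

    def subjects(self) -> list[SubjectData]:
        return [self.subject(sid) for sid in self.subject_ids]

    # -- io ----------------------------------------------------------------
    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records) -> "Dataset":
        return cls(pd.DataFrame.from_records(records))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"Dataset({self.n_subjects} subjects, {self.n_observations} observations, "
            f"routes={[r.value for r in self.routes()]})"
        )


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a canonical long-format CSV dataset."""
    return Dataset.read_csv(path)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset to the canonical CSV layout."""
    dataset.write_csv(path)


def read_supplementary_excel(path: str | Path, sheet: str | int = 0) -> Dataset:
    """Best-effort importer mapping a wide supplementary-table Excel layout
    onto the canonical schema.  Columns are matched case-insensitively on
    the canonical names; unmapped columns are ignored."""
    df = pd.read_excel(path, sheet_name=sheet)
    rename = {}
    lower = {c.lower().strip(): c for c in df.columns}
    for want in REQUIRED_COLUMNS:
        for alias in (want, {"subject": "id", "conc": "dv", "amount": "amt"}.get(want, want)):
            if alias in lower:
                rename[lower[alias]] = want
                break
    df = df.rename(columns=rename)
    return Dataset(df)
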