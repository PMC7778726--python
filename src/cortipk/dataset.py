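"""Event-level dataset I/O and schema validation.

The one dataset dialect is a comma-separated file with a header row,
UTF-8, and ``.`` as the missing marker, using rectangular dose/observation
records in the NONMEM column convention:

    ID, TIME, EVID, AMT, CMT, DV, MDV, BLQ, LLOQ, DRUG, TRT, SEQ, PERIOD, WT

Dose rows (EVID=1) carry AMT (mg) and the depot code in CMT; observation
rows (EVID=0) carry either a quantified DV (ng/mL) or BLQ=1, never both.
TIME is hours since the subject's first dose.  Round-trips through
read/write are lossless.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import SubjectData
from .model import Depot

__all__ = ["COLUMNS", "DatasetError", "read_dataset", "write_dataset",
           "validate_dataset", "subjects_from_dataset"]

COLUMNS = ("ID", "TIME", "EVID", "AMT", "CMT", "DV", "MDV", "BLQ",
           "LLOQ", "DRUG", "TRT", "SEQ", "PERIOD", "WT")

_DEPOTS = {d.value for d in Depot}


class DatasetError(ValueError):
    """Schema violation, with the offending data row in the message."""


def validate_dataset(df: pd.DataFrame, *, max_errors: int = 10) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing columns: {', '.join(missing)}")
    errors: list[str] = []

    def err(i, msg):
        # +2: one for the header line, one for 0-based indexing
        errors.append(f"row {i + 2}: {msg}")

    evid = df["EVID"].to_numpy()
    if not np.isin(evid, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(evid, (0, 1)))[0])
        err(bad, f"EVID must be 0 or 1, got {evid[bad]!r}")
    for i, row in df.iterrows():
        if len(errors) >= max_errors:
            break
        if row["TIME"] < 0 or not np.isfinite(row["TIME"]):
            err(i, f"TIME must be finite and >= 0, got {row['TIME']!r}")
        if row["EVID"] == 1:
            if not (row["AMT"] > 0):
                err(i, "dose row requires AMT > 0")
            if np.isfinite(row["DV"]):
                err(i, "dose row must not carry a DV")
            if row["CMT"] not in _DEPOTS:
                err(i, f"unknown depot code {row['CMT']!r}")
        else:
            has_dv = np.isfinite(row["DV"])
            blq = int(row["BLQ"]) if np.isfinite(row["BLQ"]) else -1
            if blq not in (0, 1):
                err(i, f"BLQ must be 0 or 1, got {row['BLQ']!r}")
            elif has_dv == bool(blq):
                err(i, "observation row requires DV xor BLQ=1")
            elif has_dv and not row["DV"] > 0:
                err(i, "quantified DV must be positive")
            if not (row["LLOQ"] > 0):
                err(i, "observation row requires LLOQ > 0")
        if row["DRUG"] not in ("DEX", "BET"):
            err(i, f"DRUG must be DEX or BET, got {row['DRUG']!r}")
    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = grp.index[int(np.flatnonzero(np.diff(t) < 0)[0]) + 1]
            err(bad, f"TIME not non-decreasing within subject {sid}")
    if errors:
        raise DatasetError("; ".join(errors[:max_errors]))


def write_dataset(dataset: pd.DataFrame, path, *,
                  header_comments: list[str] | None = None) -> None:
    """Write the standard CSV; hidden (underscore) columns are dropped."""
    df = dataset[[c for c in COLUMNS if c in dataset.columns]]
    validate_dataset(df)
    buf = io.StringIO()
    for line in header_comments or []:
        buf.write(f"# {line}\n")
    # repr gives the shortest exactly-round-tripping decimal form
    df.to_csv(buf, index=False, na_rep=".",
              float_format=lambda v: repr(float(v)))
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["."], comment="#",
                     float_precision="round_trip",
                     dtype={"CMT": "object", "DRUG": "object",
                            "TRT": "object", "SEQ": "object"})
    validate_dataset(df)
    return df


def subjects_from_dataset(df: pd.DataFrame, drug: str, *,
                          with_index: bool = False):
    """Per-subject event histories for one drug, in engine-ready form.

    Observation order inside a subject follows the dataset row order
    (time-sorted by schema); with ``with_index`` the concatenated original
    row labels are returned too, aligning flattened engine observations
    back to dataset rows.
    """
    drug = drug.upper()
    sub = df[df["DRUG"] == drug]
    subjects: list[SubjectData] = []
    index_parts = []
    for sid, grp in sub.groupby("ID", sort=True):
        doses = grp[grp["EVID"] == 1]
        obs = grp[grp["EVID"] == 0]
        if obs.empty or doses.empty:
            continue
        first_dose = float(doses["TIME"].min())
        wt = grp["WT"].iloc[0] if "WT" in grp else None
        subjects.append(SubjectData(
            id=sid,
            dose_times=doses["TIME"].to_numpy(float) - first_dose,
            dose_amounts=doses["AMT"].to_numpy(float),
            dose_depots=[Depot(c) for c in doses["CMT"]],
            obs_times=obs["TIME"].to_numpy(float) - first_dose,
            dv=obs["DV"].to_numpy(float),
            blq=obs["BLQ"].to_numpy(float) > 0,
            lloq=float(obs["LLOQ"].iloc[0]),
            sequence=str(grp["SEQ"].iloc[0]) if "SEQ" in grp else None,
            weight=float(wt) if wt is not None and np.isfinite(wt) else None,
        ))
        index_parts.append(obs.index.to_numpy())
    if with_index:
        idx = (np.concatenate(index_parts) if index_parts
               else np.array([], dtype=int))
        return subjects, idx
    return subjects
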