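"""Shared in-memory containers for the analysis pipeline.

The pipeline moves five kinds of data between stages: parcellated BOLD time
series, per-subject entropy profiles, a parcellation table, per-subject
structural property tables, and cognitive factor scores with family IDs.
Containers are thin dataclasses over numpy arrays / pandas DataFrames with
alignment checks; file formats are plain TSV plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: resting-state network labels (coarse functional parcels)
NETWORKS = ("VIS", "SM", "ATT", "SAL", "LIM", "FP", "DMN")

#: structural property names handled by the structure analyses
MORPHOMETRY = ("thickness", "myelin", "curv", "sulc")
CONNECTIVITY_PROPERTIES = ("strength", "degree")
PROPERTIES = MORPHOMETRY + CONNECTIVITY_PROPERTIES


class DataError(ValueError):
    """Raised on malformed or misaligned inputs."""


@dataclass
class RoiTimeSeries:
    """Subjects x sessions x runs x ROIs x time array of BOLD-like signals.

    ``data`` has shape ``(n_subjects, n_sessions, n_runs, n_rois,
    n_timepoints)``.  Sessions correspond to scan days (REST1/REST2), runs to
    the phase-encoding repeats within a day.
    """

    data: np.ndarray
    subject_ids: list[str]
    roi_ids: list[str]
    session_labels: tuple[str, ...] = ("REST1", "REST2")
    tr: float = 0.72

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise DataError(
                f"time-series array must be 5-D (subjects, sessions, runs, "
                f"rois, time); got shape {self.data.shape}"
            )
        n_sub, n_ses, _, n_roi, _ = self.data.shape
        if n_sub != len(self.subject_ids):
            raise DataError("subject_ids length does not match data")
        if n_roi != len(self.roi_ids):
            raise DataError(
                f"ROI-count mismatch: data has {n_roi} ROIs, "
                f"roi_ids lists {len(self.roi_ids)}"
            )
        if n_ses != len(self.session_labels):
            raise DataError("session_labels length does not match data")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[3]

    def session_index(self, session: str | int) -> int:
        if isinstance(session, (int, np.integer)):
            if not 0 <= session < len(self.session_labels):
                raise DataError(f"no session index {session}")
            return int(session)
        try:
            return self.session_labels.index(session)
        except ValueError:
            raise DataError(
                f"unknown session {session!r}; have {self.session_labels}"
            ) from None


@dataclass
class EntropyProfiles:
    """Subjects x ROIs matrix of dispersion entropies (nats) for one session
    (or a session average)."""

    values: np.ndarray
    subject_ids: list[str]
    roi_ids: list[str]
    session: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise DataError(
                f"profile matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.roi_ids)} ROIs"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def select_rois(self, roi_mask: np.ndarray) -> "EntropyProfiles":
        roi_mask = np.asarray(roi_mask)
        if roi_mask.dtype == bool:
            idx = np.flatnonzero(roi_mask)
        else:
            idx = roi_mask
        return EntropyProfiles(
            self.values[:, idx],
            list(self.subject_ids),
            [self.roi_ids[i] for i in idx],
            self.session,
        )

    def averaged_with(self, other: "EntropyProfiles") -> "EntropyProfiles":
        """Element-wise mean of two session matrices (the two-day average)."""
        check_aligned(self, other)
        return EntropyProfiles(
            (self.values + other.values) / 2.0,
            list(self.subject_ids),
            list(self.roi_ids),
            f"{self.session}+{other.session}" if self.session else "mean",
        )

    def to_frame(self, parcellation: pd.DataFrame | None = None) -> pd.DataFrame:
        """Long-format TSV-ready table: subject_id, roi_id, [network,]
        session, entropy_nats."""
        n_sub, n_roi = self.values.shape
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, n_roi),
                "roi_id": np.tile(self.roi_ids, n_sub),
                "session": self.session,
                "entropy_nats": self.values.ravel(),
            }
        )
        if parcellation is not None:
            net = parcellation.set_index("roi_id")["network"]
            df.insert(2, "network", net.loc[df["roi_id"]].to_numpy())
        return df


def profiles_from_frame(df: pd.DataFrame, session: str = "") -> EntropyProfiles:
    """Inverse of :meth:`EntropyProfiles.to_frame` (subject/ROI order is the
    order of first appearance)."""
    wide = df.pivot(index="subject_id", columns="roi_id", values="entropy_nats")
    sub_order = list(dict.fromkeys(df["subject_id"]))
    roi_order = list(dict.fromkeys(df["roi_id"]))
    wide = wide.loc[sub_order, roi_order]
    if wide.isna().any().any():
        raise DataError("missing entries in entropy profile table")
    return EntropyProfiles(wide.to_numpy(), sub_order, roi_order, session)


def check_aligned(a: EntropyProfiles, b: EntropyProfiles) -> None:
    if list(a.subject_ids) != list(b.subject_ids):
        raise DataError("subject sets/order differ between profile matrices")
    if list(a.roi_ids) != list(b.roi_ids):
        raise DataError("ROI sets/order differ between profile matrices")


@dataclass
class StructuralProfiles:
    """Per-subject, per-ROI structural property tables.

    ``values`` maps property name -> (n_subjects, n_rois) array.  Units:
    thickness mm, myelin T1w/T2w ratio, curv 1/mm, sulc mm, strength
    (probability sum), degree (suprathreshold link count).
    """

    values: dict[str, np.ndarray]
    subject_ids: list[str]
    roi_ids: list[str]

    def __post_init__(self) -> None:
        shape = (len(self.subject_ids), len(self.roi_ids))
        for prop, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise DataError(
                    f"property {prop!r} has shape {arr.shape}, expected {shape}"
                )
            self.values[prop] = arr

    @property
    def properties(self) -> list[str]:
        return list(self.values)

    def select_rois(self, roi_mask: np.ndarray) -> "StructuralProfiles":
        roi_mask = np.asarray(roi_mask)
        idx = np.flatnonzero(roi_mask) if roi_mask.dtype == bool else roi_mask
        return StructuralProfiles(
            {p: v[:, idx] for p, v in self.values.items()},
            list(self.subject_ids),
            [self.roi_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prop, arr in self.values.items():
            n_sub, n_roi = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": np.repeat(self.subject_ids, n_roi),
                        "roi_id": np.tile(self.roi_ids, n_sub),
                        "property": prop,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def structural_profiles_from_frame(df: pd.DataFrame) -> StructuralProfiles:
    sub_order = list(dict.fromkeys(df["subject_id"]))
    roi_order = list(dict.fromkeys(df["roi_id"]))
    values = {}
    for prop, grp in df.groupby("property", sort=False):
        wide = grp.pivot(index="subject_id", columns="roi_id", values="value")
        values[prop] = wide.loc[sub_order, roi_order].to_numpy()
    return StructuralProfiles(values, sub_order, roi_order)


# ---------------------------------------------------------------------------
# TSV / JSON I/O helpers


def read_tsv_matrix(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise DataError(f"cannot parse matrix file {path}: {exc}") from exc


def write_tsv_matrix(path: Path, arr: np.ndarray, fmt: str = "%.17g") -> None:
    np.savetxt(path, np.asarray(arr), delimiter="\t", fmt=fmt)


def read_manifest(path: Path) -> dict:
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise DataError(f"invalid JSON manifest {path}: {exc}") from exc


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Check a cognitive-score table: subject_id, family_id, outcome columns."""
    required = {"subject_id", "family_id"}
    missing = required - set(scores.columns)
    if missing:
        raise DataError(f"score table missing columns: {sorted(missing)}")
    outcome_cols = [c for c in scores.columns if c not in required]
    if not outcome_cols:
        raise DataError("score table has no outcome columns")
    vals = scores[outcome_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("non-finite cognitive scores")
    return scores
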