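"""Participant-level feature construction from parcel data.

Two modalities are supported. *Connectivity* features are the strict upper
triangle of the parcel-by-parcel Pearson correlation matrix computed from
per-parcel time series (for P parcels this yields P(P-1)/2 edge features;
with the common 100-region cortical parcellation, 4,950 edges). *Thickness*
features are per-parcel mean morphometric values, one feature per parcel.

Edges are flattened row-major over pairs (i, j) with i < j; the flattening
order is fixed and round-trips through :func:`edge_labels` /
:func:`edge_index`. No Fisher z-transform is applied to correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "build_features",
    "edge_labels",
    "edge_index",
    "read_timeseries",
    "read_feature_table",
    "write_feature_table",
]


def edge_labels(n_parcels: int) -> list[tuple[int, int]]:
    """Ordered (i, j) labels, i < j, row-major, for the upper triangle."""
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    return [(i, j) for i in range(n_parcels) for j in range(i + 1, n_parcels)]


def edge_index(i: int, j: int, n_parcels: int) -> int:
    """Flat feature index of edge (i, j) under row-major upper-triangle order."""
    if not (0 <= i < j < n_parcels):
        raise ValueError(f"invalid edge ({i}, {j}) for {n_parcels} parcels")
    # edges before row i: sum_{k<i} (P-1-k); offset within row: j - i - 1
    return i * (2 * n_parcels - i - 1) // 2 + (j - i - 1)


@dataclass
class FeatureMatrix:
    """N x F participant feature matrix with per-feature provenance.

    ``feature_labels`` holds an edge tuple ``(i, j)`` per feature for
    connectivity, or a parcel index for thickness. Row order matches
    ``participant_ids``.
    """

    participant_ids: list
    values: np.ndarray
    feature_labels: list = field(repr=False)
    modality: str = "connectivity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-dimensional")
        if len(self.participant_ids) != self.values.shape[0]:
            raise ValueError("participant_ids do not match number of rows")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels do not match number of columns")
        if self.modality not in ("connectivity", "thickness"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"edge_{lbl[0]}_{lbl[1]}" if isinstance(lbl, tuple) else f"parcel_{lbl}"
            for lbl in self.feature_labels
        ]
        return pd.DataFrame(self.values, index=self.participant_ids, columns=cols)


def _connectivity_row(ts: np.ndarray, participant) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError(
            f"participant {participant!r}: connectivity needs a T x P time-series "
            "array with T >= 3"
        )
    if not np.isfinite(ts).all():
        raise ValueError(f"participant {participant!r}: non-finite time-series values")
    sd = ts.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"participant {participant!r}: zero-variance time series in parcel(s) "
            f"{flat.tolist()}; correlation undefined"
        )
    corr = np.corrcoef(ts, rowvar=False)
    iu = np.triu_indices(ts.shape[1], k=1)
    return corr[iu]


def build_features(
    per_participant_parcel_data: Mapping | Sequence[tuple],
    modality: str = "connectivity",
) -> FeatureMatrix:
    """Build the participant x feature matrix from parcel-level data.

    Parameters
    ----------
    per_participant_parcel_data
        Mapping (or sequence of pairs) from participant id to either a
        T x P time-series array (connectivity) or a length-P vector of
        per-parcel values (thickness). All participants must share P.
    modality
        ``"connectivity"`` or ``"thickness"``.
    """
    items = (
        list(per_participant_parcel_data.items())
        if isinstance(per_participant_parcel_data, Mapping)
        else list(per_participant_parcel_data)
    )
    if not items:
        raise ValueError("no participants supplied")

    ids, rows = [], []
    n_parcels = None
    for pid, data in items:
        arr = np.asarray(data, dtype=float)
        if modality == "connectivity":
            p = arr.shape[1] if arr.ndim == 2 else -1
        elif modality == "thickness":
            arr = arr.ravel()
            p = arr.shape[0]
        else:
            raise ValueError(f"unknown modality {modality!r}")
        if n_parcels is None:
            n_parcels = p
        elif p != n_parcels:
            raise ValueError(
                f"participant {pid!r} has {p} parcels, expected {n_parcels}"
            )
        if modality == "connectivity":
            rows.append(_connectivity_row(arr, pid))
        else:
            if not np.isfinite(arr).all():
                raise ValueError(f"participant {pid!r}: non-finite parcel values")
            rows.append(arr)
        ids.append(pid)

    if n_parcels is None or n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    labels = (
        edge_labels(n_parcels) if modality == "connectivity" else list(range(n_parcels))
    )
    return FeatureMatrix(ids, np.vstack(rows), labels, modality)


# ---------------------------------------------------------------------------
# delimited-text IO


def read_timeseries(path: str | Path, sep: str | None = None) -> np.ndarray:
    """Read one participant's T x P time-series table (header optional)."""
    df = pd.read_csv(path, sep=sep, engine="python", header=None)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].astype(float)
    return df.to_numpy(dtype=float)


def read_feature_table(path: str | Path, sep: str = ",") -> FeatureMatrix:
    """Read an N x F feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    labels: list = []
    modality = "thickness"
    for col in df.columns:
        if col.startswith("edge_"):
            _, i, j = col.split("_")
            labels.append((int(i), int(j)))
            modality = "connectivity"
        elif col.startswith("parcel_"):
            labels.append(int(col.split("_")[1]))
        else:
            labels.append(col)
    return FeatureMatrix(df.index.tolist(), df.to_numpy(dtype=float), labels, modality)


def write_feature_table(fm: FeatureMatrix, path: str | Path, sep: str = ",") -> None:
    fm.to_frame().to_csv(path, sep=sep, index_label="participant_id")
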