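"""ROI-to-ROI functional connectivity predictors.

Resting-state BOLD time series are summarized per subject as Fisher
z-transformed Pearson correlations between pairs of regions of interest.
A configured connection list (by default the 58 DIVA/GODIVA speech-network
pairs) selects which ROI pairs enter the regression design matrix, together
with a binary scanner-site covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .behavioral import BehavioralRecord, DisfluencyRates

__all__ = [
    "ROITimeSeries",
    "ConnectionList",
    "ConnectivityTable",
    "DesignMatrix",
    "pearson_correlation",
    "fisher_z",
    "build_connectivity_table",
    "assemble_design",
    "read_timeseries_csv",
    "read_connectivity_csv",
    "write_connectivity_csv",
    "load_connection_list",
    "default_connection_list",
]

#: correlations at or beyond 1 - CLIP_EPS in magnitude are clipped before arctanh
CLIP_EPS = 1e-7

OUTCOMES = ("repetition", "prolongation", "block")


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's ROI-averaged BOLD series: time x ROI."""

    subject_id: str
    roi_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.roi_names):
            raise ValueError("values must be time x ROI, matching roi_names")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"subject {self.subject_id}: non-finite BOLD values")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")

    def column(self, roi: str) -> np.ndarray:
        try:
            j = self.roi_names.index(roi)
        except ValueError:
            raise KeyError(
                f"subject {self.subject_id}: ROI {roi!r} not in time series"
            ) from None
        return self.values[:, j]


@dataclass(frozen=True)
class ConnectionList:
    """Ordered ROI-pair predictor list; pairs unique under unordered comparison."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-connection {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate connection {a}~{b}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> list[str]:
        return [f"{a}~{b}" for a, b in self.pairs]


@dataclass(frozen=True)
class ConnectivityTable:
    """Subject x connection matrix of Fisher-z correlation coefficients."""

    subject_ids: tuple[str, ...]
    connection_labels: tuple[str, ...]
    z_values: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        object.__setattr__(self, "z_values", z)
        if z.shape != (len(self.subject_ids), len(self.connection_labels)):
            raise ValueError("z_values shape mismatch with ids/labels")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity table contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z_values, index=list(self.subject_ids),
            columns=list(self.connection_labels),
        ).rename_axis("subject_id")


@dataclass(frozen=True)
class DesignMatrix:
    """Predictor matrix (connections + site column) with one outcome vector."""

    X: np.ndarray
    y: np.ndarray
    column_labels: tuple[str, ...]
    site_column_index: int
    subject_ids: tuple[str, ...]
    outcome: str = "block"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if X.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length mismatch")
        site = X[:, self.site_column_index]
        if not np.all(np.isin(site, (0.0, 1.0))):
            raise ValueError("site column must be binary 0/1")


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length series (n >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 time points")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("zero-variance series has no defined correlation")
    r = float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))
    return min(1.0, max(-1.0, r))


def fisher_z(r: float) -> float:
    """Fisher z-transform arctanh(r); |r| >= 1-1e-7 is clipped with a warning."""
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    bound = 1.0 - CLIP_EPS
    if abs(r) >= bound:
        warnings.warn(
            f"correlation {r:.9f} at/beyond clipping bound; clipped to +/-{bound}"
        )
        r = bound if r > 0 else -bound
    return float(np.arctanh(r))


def build_connectivity_table(
    ts: Sequence[ROITimeSeries], conns: ConnectionList
) -> ConnectivityTable:
    """Fisher-z ROI-pair correlations for every subject, in connection order."""
    if not ts:
        raise ValueError("no subjects")
    z = np.empty((len(ts), len(conns)))
    for i, subj in enumerate(ts):
        for k, (a, b) in enumerate(conns.pairs):
            z[i, k] = fisher_z(pearson_correlation(subj.column(a), subj.column(b)))
    return ConnectivityTable(
        subject_ids=tuple(s.subject_id for s in ts),
        connection_labels=tuple(conns.labels),
        z_values=z,
    )


def assemble_design(
    ct: ConnectivityTable,
    rates: Sequence[DisfluencyRates],
    records: Sequence[BehavioralRecord],
    outcome: str,
) -> DesignMatrix:
    """Align connectivity, rates and site codes into one regression design.

    Rows are ordered by sorted subject id; columns are the connections in
    list order followed by the binary site column (MGH=1, BU=0).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    if len(ct.connection_labels) == 0:
        raise ValueError("empty connection list")
    ct_ids = set(ct.subject_ids)
    rate_ids = {r.participant_id for r in rates}
    rec_ids = {r.participant_id for r in records}
    if not (ct_ids == rate_ids == rec_ids):
        bad = sorted(ct_ids ^ rate_ids | ct_ids ^ rec_ids)
        raise ValueError(f"subject id mismatch across inputs: {bad}")

    order = sorted(ct_ids)
    zf = ct.to_frame().loc[order]
    rate_by = {r.participant_id: r for r in rates}
    rec_by = {r.participant_id: r for r in records}
    site = np.array([float(rec_by[s].site_code) for s in order])
    y = np.array([rate_by[s].get(outcome) for s in order])
    X = np.column_stack([zf.to_numpy(), site])
    return DesignMatrix(
        X=X, y=y,
        column_labels=tuple(list(ct.connection_labels) + ["site"]),
        site_column_index=X.shape[1] - 1,
        subject_ids=tuple(order),
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# I/O

def read_timeseries_csv(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    """Per-subject time-series CSV/TSV: header = ROI labels, rows = volumes."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        roi_names=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
    )


def write_connectivity_csv(ct: ConnectivityTable, path: str | Path) -> None:
    ct.to_frame().to_csv(path)


def read_connectivity_csv(path: str | Path) -> ConnectivityTable:
    """Wide CSV: first column subject_id, remaining columns connection labels."""
    df = pd.read_csv(path, index_col=0)
    return ConnectivityTable(
        subject_ids=tuple(str(s) for s in df.index),
        connection_labels=tuple(str(c) for c in df.columns),
        z_values=df.to_numpy(dtype=float),
    )


def load_connection_list(path: str | Path) -> ConnectionList:
    """YAML/JSON list of two-element ROI label arrays."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not all(len(p) == 2 for p in raw):
        raise ValueError("connection list must be a list of [roi_a, roi_b] pairs")
    return ConnectionList(pairs=tuple((str(a), str(b)) for a, b in raw))


def default_connection_list() -> ConnectionList:
    """The packaged 58-pair DIVA/GODIVA reconstruction."""
    ref = resources.files("stutterconn.data") / "diva_godiva_connections.yaml"
    with resources.as_file(ref) as p:
        return load_connection_list(p)
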