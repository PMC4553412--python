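"""Temporal preprocessing of ROI time series.

Desk-scale analogue of the temporal half of a resting-state fMRI
preprocessing stream, applied to region-of-interest (ROI) time courses
that have already been extracted from volumes: discarding of initial
volumes (scanner stabilization), band-pass filtering, and removal of the
linear trend together with nuisance regressors.

Spatial steps (slice timing, realignment, normalization, smoothing) are
out of scope — they happen upstream, before ROI extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RoiTimeSeriesPanel",
    "ConfoundSet",
    "discard_initial",
    "regress_nuisance",
    "bandpass",
    "preprocess",
    "read_panel_tsv",
    "write_panel_tsv",
]


@dataclass(frozen=True)
class RoiTimeSeriesPanel:
    """Per-subject ROI time-series matrices sharing one node order.

    Parameters
    ----------
    subject_ids:
        Ordered subject identifiers.
    data:
        One ``(timepoints, n_nodes)`` float array per subject.  Subjects may
        differ in timepoint count (e.g. before/after volume discarding) but
        never in node count or order.
    node_ids:
        Ordered node labels, shared by every subject.
    tr_seconds:
        Sampling interval (repetition time) in seconds.
    """

    subject_ids: tuple[str, ...]
    data: tuple[np.ndarray, ...]
    node_ids: tuple[str, ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.subject_ids) != len(self.data):
            raise ValueError("one matrix per subject required")
        n_nodes = len(self.node_ids)
        for sid, mat in zip(self.subject_ids, self.data):
            if mat.ndim != 2 or mat.shape[1] != n_nodes:
                raise ValueError(
                    f"subject {sid}: expected (timepoints, {n_nodes}) matrix, "
                    f"got {mat.shape}"
                )
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"subject {sid}: non-finite values in time series")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def matrix(self, subject_id: str) -> np.ndarray:
        return self.data[self.subject_ids.index(subject_id)]

    def with_data(self, new_data: Sequence[np.ndarray]) -> "RoiTimeSeriesPanel":
        return replace(self, data=tuple(np.asarray(m, dtype=float) for m in new_data))


@dataclass(frozen=True)
class ConfoundSet:
    """Per-subject nuisance-regressor matrices (timepoints x k).

    Covers e.g. head-motion parameter expansions and tissue-mean signals.
    An intercept and a linear trend are always appended at regression time
    and never need to be supplied here.
    """

    subject_ids: tuple[str, ...]
    regressors: tuple[np.ndarray, ...]

    def for_subject(self, subject_id: str) -> np.ndarray:
        return self.regressors[self.subject_ids.index(subject_id)]


def discard_initial(panel: RoiTimeSeriesPanel, n_discard: int = 5) -> RoiTimeSeriesPanel:
    """Drop the first ``n_discard`` timepoints of every subject.

    The conventional guard against scanner non-equilibrium: with 180
    acquired volumes and the default of 5, 175 timepoints remain.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    for sid, mat in zip(panel.subject_ids, panel.data):
        if n_discard >= mat.shape[0]:
            raise ValueError(
                f"subject {sid}: cannot discard {n_discard} of {mat.shape[0]} timepoints"
            )
    return panel.with_data([m[n_discard:] for m in panel.data])


def _design_matrix(n_t: int, confounds: np.ndarray | None) -> np.ndarray:
    """Intercept + linear trend, plus any supplied confound columns."""
    cols = [np.ones(n_t), np.linspace(-1.0, 1.0, n_t)]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_t:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, series has {n_t}"
            )
        cols.extend(confounds.T)
    X = np.column_stack(cols)
    # Drop linearly dependent confound columns (rank-revealing QR via pivoted
    # least squares is overkill here; incremental rank check is enough).
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - len(keep)} linearly dependent confound column(s)",
            stacklevel=3,
        )
    return X[:, keep]


def regress_nuisance(
    panel: RoiTimeSeriesPanel, confounds: ConfoundSet | None = None
) -> RoiTimeSeriesPanel:
    """Residualize every node's series against nuisance regressors.

    An intercept and a linear trend are always included, so the output is
    mean-centered and detrended even with no explicit confounds.  Residuals
    are exactly orthogonal to the (full-rank subset of the) confound column
    space.
    """
    out = []
    for sid, mat in zip(panel.subject_ids, panel.data):
        conf = confounds.for_subject(sid) if confounds is not None else None
        X = _design_matrix(mat.shape[0], conf)
        beta, *_ = np.linalg.lstsq(X, mat, rcond=None)
        out.append(mat - X @ beta)
    return panel.with_data(out)


def bandpass(
    panel: RoiTimeSeriesPanel,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    order: int = 4,
) -> RoiTimeSeriesPanel:
    """Zero-phase Butterworth band-pass over the panel.

    ``f_lo = 0`` degrades to a low-pass; ``f_hi`` at the Nyquist frequency
    degrades to a high-pass (and both together to the identity).  Applied
    forward-backward (``sosfiltfilt``) so correlations are not distorted by
    filter lag.
    """
    nyq = 1.0 / (2.0 * panel.tr_seconds)
    if not 0 <= f_lo < f_hi <= nyq:
        raise ValueError(
            f"need 0 <= f_lo < f_hi <= Nyquist ({nyq:.4g} Hz); got [{f_lo}, {f_hi}]"
        )
    lo_open = f_lo <= 0
    hi_open = f_hi >= nyq * (1 - 1e-12)
    if lo_open and hi_open:
        return panel
    if lo_open:
        sos = signal.butter(order, f_hi / nyq, btype="lowpass", output="sos")
    elif hi_open:
        sos = signal.butter(order, f_lo / nyq, btype="highpass", output="sos")
    else:
        sos = signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")
    return panel.with_data([signal.sosfiltfilt(sos, m, axis=0) for m in panel.data])


def preprocess(
    panel: RoiTimeSeriesPanel,
    n_discard: int = 5,
    apply_bandpass: bool = True,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    confounds: ConfoundSet | None = None,
) -> RoiTimeSeriesPanel:
    """Fixed-order preprocessing: discard -> band-pass -> detrend + nuisance.

    The band-pass stage is optional: its default 0.01-0.1 Hz band excludes
    the highest wavelet scales, so analyses of those scales should disable
    it (see docs/methods.md for the trade-off).
    """
    panel = discard_initial(panel, n_discard)
    if apply_bandpass:
        panel = bandpass(panel, f_lo, f_hi)
    return regress_nuisance(panel, confounds)


def write_panel_tsv(panel: RoiTimeSeriesPanel, directory: str | Path) -> list[Path]:
    """One TSV per subject (rows = timepoints, columns = node ids)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, mat in zip(panel.subject_ids, panel.data):
        path = directory / f"{sid}_timeseries.tsv"
        pd.DataFrame(mat, columns=list(panel.node_ids)).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
        paths.append(path)
    return paths


def read_panel_tsv(
    paths: Sequence[str | Path], tr_seconds: float, subject_ids: Sequence[str] | None = None
) -> RoiTimeSeriesPanel:
    """Assemble a panel from per-subject TSV files written by `write_panel_tsv`."""
    frames = [pd.read_csv(p, sep="\t") for p in paths]
    node_ids = tuple(frames[0].columns)
    for p, f in zip(paths, frames):
        if tuple(f.columns) != node_ids:
            raise ValueError(f"{p}: node columns differ from first subject")
    if subject_ids is None:
        subject_ids = [Path(p).stem.removesuffix("_timeseries") for p in paths]
    return RoiTimeSeriesPanel(
        subject_ids=tuple(subject_ids),
        data=tuple(f.to_numpy(dtype=float) for f in frames),
        node_ids=node_ids,
        tr_seconds=tr_seconds,
    )
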