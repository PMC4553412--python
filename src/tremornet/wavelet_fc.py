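"""Wavelet-based functional connectivity.

Functional networks are built by decomposing each ROI time course with
the maximal-overlap discrete wavelet transform (MODWT) and correlating,
between every pair of ROIs, the detail coefficients of one scale.  Scale
j isolates the frequency band [1/2^(j+1), 1/2^j] cycles per sample, so
at TR = 2 s the four default scales map to 0.125-0.250, 0.063-0.125,
0.031-0.063 and 0.016-0.031 Hz.

The MODWT is the non-decimated, shift-equivariant variant of the DWT:
each level keeps the original series length and, with the rescaled
filters used here, the decomposition is exactly energy preserving under
periodic boundary handling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import pywt

from .timeseries_prep import RoiTimeSeriesPanel

__all__ = [
    "WaveletScaleSet",
    "ConnectivityMatrix",
    "modwt",
    "modwt_decompose",
    "scale_band",
    "wavelet_correlation",
    "write_connectivity_tsv",
    "read_connectivity_tsv",
]

Boundary = Literal["periodic", "reflection"]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node-by-node edge-weight matrix for one subject.

    ``weights`` is square and symmetric; the diagonal carries no meaning and
    is never consumed downstream.  Nodes excluded upstream (zero variance)
    appear as NaN rows/columns.  ``modality`` is ``"functional"`` or
    ``"morphological"``; ``scale`` is the wavelet scale for functional
    matrices and ``None`` for morphological ones.
    """

    subject_id: str
    weights: np.ndarray
    node_ids: tuple[str, ...]
    modality: str
    scale: int | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != len(self.node_ids):
            raise ValueError("weights must be square and match node_ids")
        finite = np.isfinite(w)
        if not np.array_equal(finite, finite.T) or np.nanmax(np.abs(w - w.T), initial=0.0) > 0:
            raise ValueError("weights must be symmetric (NaN pattern included)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class WaveletScaleSet:
    """MODWT detail coefficients per subject and scale.

    ``details[s][j-1]`` is the (timepoints, n_nodes) scale-j detail array of
    subject index ``s``; ``smooth[s]`` is the level-J scaling (smooth)
    array.  Node order follows the source panel.
    """

    subject_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    details: tuple[tuple[np.ndarray, ...], ...]
    smooth: tuple[np.ndarray, ...]
    wavelet_name: str
    boundary: Boundary
    levels: int
    tr_seconds: float


def _modwt_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet_name)
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)  # scaling
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)  # wavelet
    return h, g


def max_feasible_level(n_timepoints: int, wavelet_name: str = "sym4") -> int:
    """Largest level whose equivalent filter still fits in the series."""
    L = len(pywt.Wavelet(wavelet_name).dec_lo)
    j = 0
    while (2 ** (j + 1) - 1) * (L - 1) + 1 <= n_timepoints:
        j += 1
    return j


def modwt(
    x: np.ndarray,
    wavelet_name: str = "sym4",
    levels: int = 4,
    boundary: Boundary = "periodic",
) -> tuple[list[np.ndarray], np.ndarray]:
    """MODWT of one or many series (time along axis 0).

    Returns ``(details, smooth)`` where ``details[j-1]`` has the same shape
    as ``x`` for each level j.  The pyramid filters the running smooth with
    the wavelet/scaling filters upsampled by 2^(j-1), circularly.  With
    ``boundary="reflection"`` the series is symmetrically extended to twice
    its length first and the leading half of the coefficients is returned,
    trading exact energy preservation for reduced wrap-around artefacts.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    h, g = _modwt_filters(wavelet_name)
    L = len(h)
    support = (2**levels - 1) * (L - 1) + 1
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if support > n:
        raise ValueError(
            f"series of length {n} too short for level {levels} with {wavelet_name} "
            f"(equivalent filter support {support}); max feasible level is "
            f"{max_feasible_level(n, wavelet_name)}"
        )
    if boundary == "reflection":
        v = np.concatenate([x, x[::-1]], axis=0)
    elif boundary == "periodic":
        v = x
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    m = v.shape[0]
    details: list[np.ndarray] = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        idx = (np.arange(m)[:, None] - step * np.arange(L)[None, :]) % m
        w_j = np.einsum("l,tlk->tk", h, v[idx])
        v = np.einsum("l,tlk->tk", g, v[idx])
        details.append(w_j[:n] if boundary == "reflection" else w_j)
    smooth = v[:n] if boundary == "reflection" else v
    if squeeze:
        details = [d[:, 0] for d in details]
        smooth = smooth[:, 0]
    return details, smooth


def modwt_decompose(
    panel: RoiTimeSeriesPanel,
    wavelet_name: str = "sym4",
    levels: int = 4,
    boundary: Boundary = "periodic",
) -> WaveletScaleSet:
    """Decompose every subject of a panel into MODWT detail coefficients."""
    all_details = []
    all_smooth = []
    for mat in panel.data:
        d, s = modwt(mat, wavelet_name, levels, boundary)
        all_details.append(tuple(d))
        all_smooth.append(s)
    return WaveletScaleSet(
        subject_ids=panel.subject_ids,
        node_ids=panel.node_ids,
        details=tuple(all_details),
        smooth=tuple(all_smooth),
        wavelet_name=wavelet_name,
        boundary=boundary,
        levels=levels,
        tr_seconds=panel.tr_seconds,
    )


def scale_band(j: int, tr_seconds: float) -> tuple[float, float]:
    """Frequency band (Hz) isolated by MODWT scale ``j`` at sampling interval TR.

    ``[1 / (2^(j+1) dt), 1 / (2^j dt)]`` — at TR = 2 s, scale 2 gives
    (0.0625, 0.125) Hz.
    """
    if j < 1:
        raise ValueError("scale index must be >= 1")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return 1.0 / (2 ** (j + 1) * tr_seconds), 1.0 / (2**j * tr_seconds)


def wavelet_correlation(scale_set: WaveletScaleSet, j: int) -> list[ConnectivityMatrix]:
    """Pearson correlation of scale-j detail coefficients for every node pair.

    Zero-variance nodes (no signal at this scale) get NaN rows/columns and a
    warning naming them; the morphological-style exclusion report is not
    needed here because downstream thresholding treats NaN as never-selected.
    """
    if not 1 <= j <= scale_set.levels:
        raise ValueError(f"scale {j} not in decomposition (levels={scale_set.levels})")
    out = []
    for sid, det in zip(scale_set.subject_ids, scale_set.details):
        coeffs = det[j - 1]
        sd = coeffs.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(coeffs, rowvar=False)
        if dead.size:
            warnings.warn(
                f"subject {sid}, scale {j}: zero-variance nodes "
                f"{[scale_set.node_ids[i] for i in dead]} set to NaN"
            )
            r[dead, :] = np.nan
            r[:, dead] = np.nan
        r = np.clip(r, -1.0, 1.0)
        r = (r + r.T) / 2.0  # enforce exact symmetry against float round-off
        out.append(
            ConnectivityMatrix(
                subject_id=sid,
                weights=r,
                node_ids=scale_set.node_ids,
                modality="functional",
                scale=j,
            )
        )
    return out


def write_connectivity_tsv(cm: ConnectivityMatrix, path: str | Path) -> Path:
    """Square TSV with node-id headers plus a JSON sidecar of provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cm.weights, index=list(cm.node_ids), columns=list(cm.node_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
    sidecar = {
        "subject_id": cm.subject_id,
        "modality": cm.modality,
        "scale": cm.scale,
        "n_nodes": cm.n_nodes,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_connectivity_tsv(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ConnectivityMatrix(
        subject_id=meta["subject_id"],
        weights=df.to_numpy(dtype=float),
        node_ids=tuple(str(c) for c in df.columns),
        modality=meta["modality"],
        scale=meta["scale"],
    )
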