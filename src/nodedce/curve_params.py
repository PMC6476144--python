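"""Semiquantitative parameters of enhancement curves.

Three descriptors summarize a (cluster-averaged) NDE curve:

* **AUC** — trapezoidal area under the curve over the post-injection window
  (last baseline frame through the final frame), time in minutes. Not
  normalized.
* **wash-in rate** — the maximum slope between two consecutive time points
  between the last baseline point and the point of maximal enhancement,
  divided by the node's maximal enhancement.
* **wash-out rate** — the least-squares slope over the last 40 time points
  (scans 31-70 of a 70-scan series), divided by the node's maximal
  enhancement; negative when contrast clears.

The normalizer (maximal enhancement of the node-mean NDE curve) is shared
by both clusters of a node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from nodedce.clustering import ClusterResult

#: wash-out fit window for the canonical 70-scan protocol
DEFAULT_WASHOUT_FRAMES = 40


class FitError(ValueError):
    """Raised when a slope fit has too few points."""


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one curve: AUC (a.u.), normalized wash-in and wash-out
    rates (a.u./min), and the node-level normalizer used (a.u.)."""

    auc: float
    wash_in: float
    wash_out: float
    max_enhancement_node: float


def auc(curve: np.ndarray, frame_interval: float, n_baseline: int = 3) -> float:
    """Trapezoidal area under the curve from the last baseline frame to the end.

    Time is in minutes, so the result is in a.u.*min (reported as a.u.).
    """
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    window = curve[n_baseline - 1 :]
    return float(np.trapezoid(window, dx=frame_interval))


def wash_in(
    curve: np.ndarray,
    n_baseline: int,
    frame_interval: float,
    normalizer: float = 1.0,
) -> float:
    """Normalized maximum uptake slope (a.u./min).

    The maximum is taken over consecutive-frame slopes between the last
    baseline frame and the frame of maximal enhancement. A curve whose
    maximum sits at the last baseline frame has no rise; 0 is returned with
    a warning.
    """
    curve = np.asarray(curve, dtype=float)
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    last_base = n_baseline - 1  # 0-based index of the last baseline frame
    peak = int(np.argmax(curve))
    if peak <= last_base:
        warnings.warn("curve does not rise after baseline; wash-in set to 0", stacklevel=2)
        return 0.0
    slopes = np.diff(curve[last_base : peak + 1]) / frame_interval
    return float(slopes.max() / normalizer)


def washout_window(n_frames: int, washout_frames: int | None = None) -> int:
    """Number of final frames used for the wash-out fit.

    Defaults to the last ``max(40, n_frames - 30)`` frames, generalizing the
    scans-31-70 convention of the 70-scan protocol.
    """
    if washout_frames is None:
        washout_frames = max(DEFAULT_WASHOUT_FRAMES, n_frames - 30)
    if washout_frames < 2:
        raise FitError("wash-out window must contain at least 2 frames")
    if washout_frames > n_frames:
        raise FitError(
            f"wash-out window of {washout_frames} frames exceeds the {n_frames}-frame series"
        )
    return washout_frames


def wash_out(
    curve: np.ndarray,
    frame_interval: float,
    normalizer: float = 1.0,
    washout_frames: int | None = None,
) -> float:
    """Normalized late slope (a.u./min): OLS fit over the final frames."""
    curve = np.asarray(curve, dtype=float)
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    w = washout_window(curve.size, washout_frames)
    tail = curve[-w:]
    t = np.arange(w) * frame_interval
    slope = np.polyfit(t, tail, 1)[0]
    return float(slope / normalizer)


def curve_parameters(
    curve: np.ndarray,
    n_baseline: int,
    frame_interval: float,
    normalizer: float,
    washout_frames: int | None = None,
) -> CurveParams:
    """All three descriptors of one curve with a shared node normalizer."""
    return CurveParams(
        auc=auc(curve, frame_interval, n_baseline),
        wash_in=wash_in(curve, n_baseline, frame_interval, normalizer),
        wash_out=wash_out(curve, frame_interval, normalizer, washout_frames),
        max_enhancement_node=normalizer,
    )


def extract_all(
    result: "ClusterResult",
    node_mean_curve: np.ndarray,
    frame_interval: float,
    n_baseline: int,
    washout_frames: int | None = None,
    node_id: int | str = 1,
    agent: str = "Gd-DTPA",
) -> pd.DataFrame:
    """Parameter rows (one per cluster) in the node-table schema.

    The normalizer is the maximum of the node-mean NDE curve, shared by both
    clusters. Requires cluster roles to be assigned.
    """
    if set(result.cluster_curves) != {"inner", "outer"}:
        raise ValueError("cluster roles must be assigned before parameter extraction")
    node_mean_curve = np.asarray(node_mean_curve, dtype=float)
    normalizer = float(node_mean_curve.max())
    if normalizer <= 0:
        raise ValueError("node-mean curve never enhances; normalizer not positive")
    rows = []
    for role in ("inner", "outer"):
        p = curve_parameters(
            result.cluster_curves[role], n_baseline, frame_interval, normalizer, washout_frames
        )
        rows.append(
            {
                "node": node_id,
                "agent": agent,
                "cluster": role,
                "auc": p.auc,
                "wash_in": p.wash_in,
                "wash_out": p.wash_out,
                "volume_pct": result.volume_pct[role],
            }
        )
    return pd.DataFrame(rows)
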