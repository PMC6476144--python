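"""Per-pixel normalized differential enhancement (NDE).

For each node pixel,

    NDE(t) = (SI(t) - SI_pre) / DEmax_muscle

where ``SI_pre`` is the pixel's mean pre-contrast signal and
``DEmax_muscle`` is the maximal differential enhancement of the mean signal
in a muscle ROI. Dividing by the muscle enhancement compensates, at least
partially, for differences in the effectively delivered contrast dose, and
makes NDE invariant to any global intensity rescaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from nodedce.image_io import DynamicSeries, RoiMask


class NormalizerError(ValueError):
    """Muscle ROI never enhances: the NDE normalizer is not positive."""


@dataclass
class NDECurveSet:
    """NDE curves for every pixel of a node mask.

    curves : (n_pixels, n_frames) NDE values
    coords : (n_pixels, 2) row/col of each pixel
    si_pre_map : per-pixel pre-contrast signal (a.u.), on the node pixels
    de_max_muscle : the scalar muscle normalizer (a.u.)
    """

    curves: np.ndarray
    coords: np.ndarray
    si_pre_map: np.ndarray
    de_max_muscle: float
    frame_interval: float
    n_baseline: int

    @property
    def n_pixels(self) -> int:
        return self.curves.shape[0]

    @property
    def n_frames(self) -> int:
        return self.curves.shape[1]

    def mean_curve(self) -> np.ndarray:
        """ROI-mean NDE curve over all node pixels."""
        return self.curves.mean(axis=0)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (pixel, row, col, frame, nde) table."""
        n_px, n_fr = self.curves.shape
        return pd.DataFrame(
            {
                "pixel": np.repeat(np.arange(n_px), n_fr),
                "row": np.repeat(self.coords[:, 0], n_fr),
                "col": np.repeat(self.coords[:, 1], n_fr),
                "frame": np.tile(np.arange(1, n_fr + 1), n_px),
                "nde": self.curves.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def compute_si_pre(series: DynamicSeries, pixel: tuple[int, int]) -> float:
    """Mean pre-contrast signal of one pixel (its first ``n_baseline`` frames)."""
    r, c = pixel
    return float(series.data[r, c, : series.n_baseline].mean())


def compute_muscle_demax(series: DynamicSeries, muscle: RoiMask) -> float:
    """Maximal differential enhancement of the ROI-mean muscle curve.

    The ROI mean is used rather than a per-pixel maximum because the latter
    is biased upward by noise. Raises :class:`NormalizerError` when the
    muscle never enhances above its own baseline.
    """
    muscle.check_grid(series)
    m = series.data[muscle.mask].mean(axis=0)  # mean muscle signal per frame
    m_pre = m[: series.n_baseline].mean()
    de_max = float((m[series.n_baseline :] - m_pre).max())
    if de_max <= 0:
        raise NormalizerError(
            f"muscle differential enhancement is {de_max:.4g} <= 0; cannot normalize"
        )
    return de_max


def compute_nde(series: DynamicSeries, node: RoiMask, muscle: RoiMask) -> NDECurveSet:
    """NDE curves for every pixel of the node mask (series must be registered)."""
    node.check_grid(series)
    de_max = compute_muscle_demax(series, muscle)
    coords = np.argwhere(node.mask)
    signals = series.data[node.mask]  # (n_pixels, n_frames)
    si_pre = signals[:, : series.n_baseline].mean(axis=1)
    curves = (signals - si_pre[:, None]) / de_max
    return NDECurveSet(
        curves=curves,
        coords=coords,
        si_pre_map=si_pre,
        de_max_muscle=de_max,
        frame_interval=series.frame_interval,
        n_baseline=series.n_baseline,
    )
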