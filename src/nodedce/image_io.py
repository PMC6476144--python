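"""Reading and writing the imaging and tabular artifacts of the pipeline.

Images travel as NIfTI (2D+time stacks, binary ROI masks); per-node
semiquantitative parameters travel as CSV. Frame numbering is 1-based in all
user-facing interfaces (scan 1 is the first acquisition) and 0-based in
array indexing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: contrast agents the node table may contain
AGENTS = ("Gd-DTPA", "Gd-BOPTA")
#: cluster role labels
CLUSTERS = ("inner", "outer")

#: default temporal sampling: 70 scans over ~46 minutes
DEFAULT_FRAME_INTERVAL = 46.0 / 70.0
DEFAULT_N_BASELINE = 3


class FormatError(ValueError):
    """Raised for files whose layout does not match the expected format."""


class IntegrityError(ValueError):
    """Raised when a parameter table violates its structural contract."""


@dataclass
class DynamicSeries:
    """A 2D+time signal-intensity stack for one slice of interest.

    Parameters
    ----------
    data : ndarray, shape (height, width, n_frames)
        Signal intensities in arbitrary units.
    frame_interval : float
        Minutes between consecutive frames.
    n_baseline : int
        Number of pre-contrast frames; the bolus arrives between frames
        ``n_baseline`` and ``n_baseline + 1`` (1-based).
    """

    data: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    n_baseline: int = DEFAULT_N_BASELINE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"series must be height x width x time, got ndim={self.data.ndim}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.n_frames < self.n_baseline + 2:
            raise FormatError(
                f"series too short: {self.n_frames} frames with n_baseline={self.n_baseline} "
                f"(need at least {self.n_baseline + 2})"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def injection_between(self) -> tuple[int, int]:
        """1-based frame pair bracketing the bolus injection."""
        return (self.n_baseline, self.n_baseline + 1)

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes, frame 1 at t=0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class RoiMask:
    """A binary region-of-interest mask on the series grid."""

    mask: np.ndarray
    label: str = "node"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be a 2D image")
        if not self.mask.any():
            raise ValueError(f"{self.label} mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_grid(self, series: DynamicSeries) -> None:
        if self.mask.shape != series.grid:
            raise FormatError(
                f"{self.label} mask grid {self.mask.shape} does not match series grid {series.grid}"
            )


def _squeeze_to_3d(arr: np.ndarray, path: Path) -> np.ndarray:
    """Normalize a loaded volume to height x width x time."""
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2D+time volume, got shape {arr.shape} after squeeze")
    return arr


def load_series(
    path: str | Path,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    n_baseline: int = DEFAULT_N_BASELINE,
) -> DynamicSeries:
    """Read a dynamic series from a NIfTI file.

    Singleton axes (e.g. a 4D file holding a single slice) are squeezed so
    the result is always height x width x time.
    """
    path = Path(path)
    img = nib.load(str(path))
    arr = _squeeze_to_3d(np.asanyarray(img.dataobj, dtype=float), path)
    return DynamicSeries(arr, frame_interval=frame_interval, n_baseline=n_baseline)


def save_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a dynamic series as a 3D (2D+time) NIfTI file."""
    img = nib.Nifti1Image(series.data.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, series.frame_interval))
    nib.save(img, str(path))


def load_mask(path: str | Path, label: str = "node") -> RoiMask:
    """Read a binary ROI mask from NIfTI (any nonzero voxel is inside)."""
    img = nib.load(str(path))
    arr = np.squeeze(np.asanyarray(img.dataobj))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2D mask, got shape {arr.shape}")
    return RoiMask(arr != 0, label=label)


def save_mask(mask: RoiMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine=np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# parameter table

#: required columns of a node parameter table
PARAM_COLUMNS = ["node", "agent", "cluster", "auc", "wash_in", "wash_out", "volume_pct"]
#: optional standard-deviation annotation columns (carried through, unused by stats)
SD_COLUMNS = ["auc_sd", "wash_in_sd", "wash_out_sd"]


def load_param_table(path: str | Path) -> pd.DataFrame:
    """Load a node x cluster semiquantitative parameter table from CSV.

    Contract: one row per (node, cluster) with both clusters present for
    every node, a single agent per node, and inner/outer volume percentages
    summing to 100 +- 0.5.
    """
    df = pd.read_csv(path)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"parameter table missing columns: {missing}")
    return validate_param_table(df)


def validate_param_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_agents = set(df["agent"]) - set(AGENTS)
    if bad_agents:
        raise IntegrityError(f"unknown agents {sorted(bad_agents)}; expected {AGENTS}")
    bad_clusters = set(df["cluster"]) - set(CLUSTERS)
    if bad_clusters:
        raise IntegrityError(f"unknown clusters {sorted(bad_clusters)}; expected {CLUSTERS}")
    for node, grp in df.groupby("node"):
        if sorted(grp["cluster"]) != sorted(CLUSTERS):
            raise IntegrityError(f"node {node}: needs exactly one inner and one outer row")
        if grp["agent"].nunique() != 1:
            raise IntegrityError(f"node {node}: rows disagree on agent")
        vsum = grp["volume_pct"].sum()
        if abs(vsum - 100.0) > 0.5:
            raise IntegrityError(f"node {node}: cluster volumes sum to {vsum}, not 100")
    return df.reset_index(drop=True)


def packaged_node_table() -> pd.DataFrame:
    """The packaged transcription of the published per-node parameter table.

    15 normal mouse lymph nodes (9 Gd-DTPA, 6 Gd-BOPTA), two clusters each:
    AUC (a.u.), wash-in and wash-out rates (a.u./min, washout negative) and
    cluster volume (% of node pixels). ``*_sd`` columns are the printed
    standard-deviation annotations.
    """
    ref = importlib.resources.files("nodedce").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as p:
        return load_param_table(p)
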