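"""Digital phantom: synthetic dynamic series with ground truth.

The phantom emulates the acquisition the pipeline targets: 70 T1-weighted
scans over ~46 minutes with 3 pre-contrast baselines and bolus arrival
between scans 3 and 4. It contains an elliptical lymph node split into two
concentric compartments with distinct kinetics (inner: higher, faster uptake
and steeper washout) and a muscle strip used as the enhancement normalizer.

Enhancement curves use a product of mono-exponential uptake and washout,

    E(t) = A * (1 - exp(-k_in * dt)) * exp(-k_out * dt),  dt = time since onset,

a smooth uptake-then-washout shape whose rate parameters make recovery
checks analytic. Pixel signal is ``baseline_signal * (1 + E(t))`` plus
additive Gaussian noise (optionally Rician, as magnitude MRI noise is).
Optional per-frame rigid shifts simulate breathing/peristalsis motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from nodedce.image_io import (
    DEFAULT_FRAME_INTERVAL,
    DEFAULT_N_BASELINE,
    DynamicSeries,
    RoiMask,
    save_mask,
    save_series,
)


class GeometryError(ValueError):
    """Raised when phantom regions overlap or leave the grid."""


@dataclass(frozen=True)
class KineticParams:
    """Enhancement kinetics of one tissue compartment.

    amplitude : peak-scale enhancement relative to baseline signal (a.u.)
    k_in : uptake rate (1/min)
    k_out : washout rate (1/min)
    onset_index : first post-injection frame, 1-based
    """

    amplitude: float
    k_in: float
    k_out: float
    onset_index: int = DEFAULT_N_BASELINE + 1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.k_in <= 0:
            raise ValueError("k_in must be > 0")
        if self.k_out < 0:
            raise ValueError("k_out must be >= 0")
        if self.onset_index < 1:
            raise ValueError("onset_index must be >= 1 (1-based frame)")


# defaults chosen as a plausible normal-node scenario: the inner compartment
# enhances about twice as strongly as the outer one, with faster uptake and
# a clearly steeper washout; muscle enhances weakly and slowly.
DEFAULT_INNER = KineticParams(amplitude=2.5, k_in=1.2, k_out=0.05)
DEFAULT_OUTER = KineticParams(amplitude=1.0, k_in=0.5, k_out=0.02)
DEFAULT_MUSCLE = KineticParams(amplitude=0.4, k_in=0.8, k_out=0.03)


@dataclass
class PhantomSpec:
    """Full description of one synthetic dynamic acquisition."""

    grid: tuple[int, int] = (64, 64)
    node_center: tuple[float, float] = (30.0, 26.0)
    node_axes: tuple[float, float] = (10.0, 7.0)
    inner_fraction: float = 0.3
    muscle_region: tuple[int, int, int, int] = (4, 48, 60, 58)  # (row0, col0, row1, col1), half-open
    kinetics_inner: KineticParams = field(default_factory=lambda: DEFAULT_INNER)
    kinetics_outer: KineticParams = field(default_factory=lambda: DEFAULT_OUTER)
    kinetics_muscle: KineticParams = field(default_factory=lambda: DEFAULT_MUSCLE)
    baseline_signal: float = 100.0
    texture_amp: float = 40.0  # static anatomical background structure (a.u.)
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"  # or "rician"
    n_frames: int = 70
    n_baseline: int = DEFAULT_N_BASELINE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    motion_schedule: np.ndarray | None = None  # (n_frames, 2) row/col shifts in pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline >= self.n_frames:
            raise ValueError("n_baseline must be < n_frames")
        if not 0.0 < self.inner_fraction < 1.0:
            raise ValueError("inner_fraction must be strictly between 0 and 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.motion_schedule is not None:
            sched = np.asarray(self.motion_schedule, dtype=float)
            if sched.shape != (self.n_frames, 2):
                raise ValueError(f"motion_schedule must have shape ({self.n_frames}, 2)")
            object.__setattr__(self, "motion_schedule", sched)
        r0, c0, r1, c1 = self.muscle_region
        h, w = self.grid
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise GeometryError("muscle_region outside grid or empty")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["motion_schedule"] is not None:
            d["motion_schedule"] = np.asarray(d["motion_schedule"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("kinetics_inner", "kinetics_outer", "kinetics_muscle"):
            if key in d and isinstance(d[key], dict):
                d[key] = KineticParams(**d[key])
        for key in ("grid", "node_center", "node_axes", "muscle_region"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("motion_schedule") is not None:
            d["motion_schedule"] = np.asarray(d["motion_schedule"], dtype=float)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom series."""

    inner_mask: np.ndarray
    outer_mask: np.ndarray
    node_mask: np.ndarray
    muscle_mask: np.ndarray
    true_curves: dict[str, np.ndarray]  # noiseless relative-enhancement curve per compartment
    applied_shifts: np.ndarray  # (n_frames, 2), zeros when no motion


def enhancement_curve(k: KineticParams, n_frames: int, frame_interval: float) -> np.ndarray:
    """Noiseless relative enhancement per frame for one compartment.

    Frames before the onset frame are exactly zero; from the onset on the
    curve follows ``amplitude * (1 - exp(-k_in*dt)) * exp(-k_out*dt)`` with
    ``dt`` in minutes since onset.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    frames = np.arange(1, n_frames + 1)  # 1-based
    dt = (frames - k.onset_index) * frame_interval
    curve = np.where(
        frames < k.onset_index,
        0.0,
        k.amplitude * (1.0 - np.exp(-k.k_in * np.maximum(dt, 0.0))) * np.exp(-k.k_out * np.maximum(dt, 0.0)),
    )
    return curve


def _ellipse_mask(grid: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : grid[0], 0 : grid[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _compartment_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Node/inner/outer/muscle masks; inner is the concentric ellipse scaled
    so that its area is ``inner_fraction`` of the node area."""
    node = _ellipse_mask(spec.grid, spec.node_center, spec.node_axes)
    scale = float(np.sqrt(spec.inner_fraction))
    inner = _ellipse_mask(spec.grid, spec.node_center, (spec.node_axes[0] * scale, spec.node_axes[1] * scale))
    inner &= node
    outer = node & ~inner
    r0, c0, r1, c1 = spec.muscle_region
    muscle = np.zeros(spec.grid, dtype=bool)
    muscle[r0:r1, c0:c1] = True
    if not node.any() or not inner.any() or not outer.any():
        raise GeometryError("node geometry degenerate: a compartment has no pixels")
    if (node & muscle).any():
        raise GeometryError("node and muscle regions overlap")
    rr = np.where(node.any(axis=1))[0]
    cc = np.where(node.any(axis=0))[0]
    h, w = spec.grid
    if rr[0] == 0 or rr[-1] == h - 1 or cc[0] == 0 or cc[-1] == w - 1:
        raise GeometryError("node touches the grid border")
    return node, inner, outer, muscle


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, PhantomTruth]:
    """Synthesize a dynamic series plus its ground truth.

    Pixel signal is ``baseline_signal * (1 + compartment curve)``; if a
    motion schedule is present each noise-free frame is resampled by its
    shift before noise is added. Identical spec and seed give bit-identical
    output.
    """
    node, inner, outer, muscle = _compartment_masks(spec)
    curves = {
        "inner": enhancement_curve(spec.kinetics_inner, spec.n_frames, spec.frame_interval),
        "outer": enhancement_curve(spec.kinetics_outer, spec.n_frames, spec.frame_interval),
        "muscle": enhancement_curve(spec.kinetics_muscle, spec.n_frames, spec.frame_interval),
    }

    h, w = spec.grid
    rng = np.random.default_rng(spec.seed)
    clean = np.empty((h, w, spec.n_frames), dtype=float)
    base = np.full((h, w), spec.baseline_signal, dtype=float)
    if spec.texture_amp > 0:
        # static anatomical structure with fine and coarse detail: it cancels
        # out of NDE (it is part of SI_pre per pixel) but anchors the
        # registration in every frame, including the pre-contrast baselines
        fine = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.0)
        coarse = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
        tex = fine / fine.std() + coarse / coarse.std()
        base = base + spec.texture_amp * tex / tex.std()
    for t in range(spec.n_frames):
        frame = base.copy()
        frame[inner] += spec.baseline_signal * curves["inner"][t]
        frame[outer] += spec.baseline_signal * curves["outer"][t]
        frame[muscle] += spec.baseline_signal * curves["muscle"][t]
        clean[:, :, t] = frame

    shifts = np.zeros((spec.n_frames, 2), dtype=float)
    if spec.motion_schedule is not None:
        shifts = np.asarray(spec.motion_schedule, dtype=float)
        for t in range(spec.n_frames):
            if np.any(shifts[t] != 0):
                # sinc (Fourier) translation: exact for the band-limited
                # phantom, so applied shifts are exactly recoverable
                clean[:, :, t] = np.fft.ifft2(
                    ndimage.fourier_shift(np.fft.fft2(clean[:, :, t]), shifts[t])
                ).real

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            data = clean + rng.normal(0.0, spec.noise_sigma, clean.shape)
        else:  # rician magnitude: |signal + n1 + i*n2|
            n1 = rng.normal(0.0, spec.noise_sigma, clean.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, clean.shape)
            data = np.hypot(clean + n1, n2)
    else:
        data = clean

    series = DynamicSeries(data, frame_interval=spec.frame_interval, n_baseline=spec.n_baseline)
    truth = PhantomTruth(
        inner_mask=inner,
        outer_mask=outer,
        node_mask=node,
        muscle_mask=muscle,
        true_curves=curves,
        applied_shifts=shifts,
    )
    return series, truth


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a phantom and write series, masks, truth curves and spec.

    Returns a name -> path mapping of everything written.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = generate_phantom(spec)
    paths = {
        "series": out / "series.nii.gz",
        "node_mask": out / "node_mask.nii.gz",
        "muscle_mask": out / "muscle_mask.nii.gz",
        "inner_mask": out / "inner_mask.nii.gz",
        "outer_mask": out / "outer_mask.nii.gz",
        "true_curves": out / "true_curves.csv",
        "spec": out / "phantom_spec.yaml",
    }
    save_series(series, paths["series"])
    save_mask(RoiMask(truth.node_mask, "node"), paths["node_mask"])
    save_mask(RoiMask(truth.muscle_mask, "muscle"), paths["muscle_mask"])
    save_mask(RoiMask(truth.inner_mask, "node"), paths["inner_mask"])
    save_mask(RoiMask(truth.outer_mask, "node"), paths["outer_mask"])
    pd.DataFrame(
        {"frame": np.arange(1, spec.n_frames + 1), **truth.true_curves}
    ).to_csv(paths["true_curves"], index=False)
    spec.to_yaml(paths["spec"])
    return paths
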