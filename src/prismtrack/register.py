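"""Spatial->spectral field-of-view registration and lateral drift correction.

The two detection paths view the same focal plane through different optics
(different magnification, rotation, prism distortion), so spatial-channel
coordinates must be mapped into the spectral channel before localizations
can be paired.  The mapping is a full two-dimensional 3rd-order polynomial
with 10 coefficients per output coordinate:

    x' = a1 x^3 + a2 y^3 + a3 x^2 y + a4 x y^2 + a5 x^2 + a6 y^2
         + a7 x y + a8 x + a9 y + a10

(and likewise for y').  It is calibrated on a raster-scanned fiducial grid
and is wavelength dependent: it is centered at the emission wavelength of
the fiducial used, which becomes the spectral reference lambda0.

Lateral drift on either path changes pair distances over time and is
compensated per channel from fiducial trajectories; session-to-session
field shifts only move the zero-order coefficients (a10) of the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from prismtrack.io import SPECTRAL_PIXEL_NM, LocalizationTable

__all__ = [
    "FieldTransform",
    "RegistrationQC",
    "DriftTrace",
    "polynomial_terms",
    "fit_field_transform",
    "apply_field_transform",
    "registration_residuals",
    "update_transform_offset",
    "estimate_drift",
    "apply_drift_correction",
    "save_field_transform",
    "load_field_transform",
]

N_COEFFS = 10  # per output coordinate, fixed by the 3rd-order model


def polynomial_terms(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Design-matrix columns [x^3, y^3, x^2 y, x y^2, x^2, y^2, x y, x, y, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.stack(
        [x**3, y**3, x**2 * y, x * y**2, x**2, y**2, x * y, x, y, np.ones_like(x)],
        axis=-1,
    )


@dataclass
class FieldTransform:
    """3rd-order polynomial mapping spatial-channel -> spectral-channel pixels.

    ``ax`` and ``ay`` hold the 10 coefficients of each output coordinate in
    the term order of :func:`polynomial_terms`; ``ax[7] = 1, ay[8] = 1`` with
    all else zero is the identity.  ``reference_wavelength_nm`` records the
    emission wavelength of the calibration fiducial: the transform (and hence
    pair distance zero) is centered at that wavelength.
    """

    ax: np.ndarray
    ay: np.ndarray
    reference_wavelength_nm: float = 683.0

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        if self.ax.shape != (N_COEFFS,) or self.ay.shape != (N_COEFFS,):
            raise ValueError(f"expected exactly {N_COEFFS} coefficients per output coordinate")
        if not (np.isfinite(self.ax).all() and np.isfinite(self.ay).all()):
            raise ValueError("transform coefficients must be finite")

    @classmethod
    def identity(cls, reference_wavelength_nm: float = 683.0) -> "FieldTransform":
        ax = np.zeros(N_COEFFS)
        ay = np.zeros(N_COEFFS)
        ax[7] = 1.0
        ay[8] = 1.0
        return cls(ax=ax, ay=ay, reference_wavelength_nm=reference_wavelength_nm)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_field_transform(self, points)


@dataclass
class RegistrationQC:
    """Per-point residual distances (nm) of a fitted field transform."""

    residuals_nm: np.ndarray
    median_nm: float
    max_nm: float

    def __post_init__(self) -> None:
        self.residuals_nm = np.asarray(self.residuals_nm, dtype=float)
        if (self.residuals_nm < 0).any():
            raise ValueError("residuals must be non-negative")
        if self.median_nm > self.max_nm + 1e-12:
            raise ValueError("median residual cannot exceed max residual")


@dataclass
class DriftTrace:
    """Per-frame lateral offsets (dx, dy) in pixels of one channel.

    Offsets are relative to frame 0 (offset (0, 0) by construction).
    """

    dx: np.ndarray
    dy: np.ndarray
    smoothing_window: int = 50

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return len(self.dx)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"frame": np.arange(self.n_frames), "dx": self.dx, "dy": self.dy}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, smoothing_window: int = 50) -> "DriftTrace":
        df = pd.read_csv(path)
        return cls(df["dx"].to_numpy(float), df["dy"].to_numpy(float), smoothing_window)


# ---------------------------------------------------------------------------
# transform fitting / application
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[-1] != 2:
        raise ValueError("points must have shape (n, 2) as (x, y)")
    return pts


def fit_field_transform(
    pairs: list[tuple],
    reference_wavelength_nm: float = 683.0,
    spectral_pixel_nm: float = SPECTRAL_PIXEL_NM,
) -> tuple[FieldTransform, RegistrationQC]:
    """Fit the 3rd-order polynomial transform to paired fiducial positions.

    ``pairs`` is a sequence of ``((x, y), (x', y'))`` with the spatial-channel
    point first.  The model is linear in its coefficients, so the
    least-squares optimum is computed in closed form by SVD-based linear
    least squares; an iterative Levenberg-Marquardt minimization of the same
    residual converges to the identical optimum.  Returns the transform and
    QC residuals on the training pairs.
    """
    if len(pairs) < N_COEFFS:
        raise ValueError(f"need >= {N_COEFFS} pairs to constrain the transform, got {len(pairs)}")
    src = _as_points([p[0] for p in pairs])
    dst = _as_points([p[1] for p in pairs])
    design = polynomial_terms(src[:, 0], src[:, 1])
    rank = np.linalg.matrix_rank(design)
    if rank < N_COEFFS:
        raise ValueError(
            f"degenerate fiducial geometry: design matrix rank {rank} < {N_COEFFS} "
            "(points may be collinear or on a low-order curve)"
        )
    ax, *_ = np.linalg.lstsq(design, dst[:, 0], rcond=None)
    ay, *_ = np.linalg.lstsq(design, dst[:, 1], rcond=None)
    t = FieldTransform(ax=ax, ay=ay, reference_wavelength_nm=reference_wavelength_nm)
    qc = registration_residuals(t, pairs, spectral_pixel_nm=spectral_pixel_nm)
    return t, qc


def apply_field_transform(t: FieldTransform, points) -> np.ndarray:
    """Map (x, y) spatial-channel points to (x', y') spectral-channel points."""
    pts = _as_points(points)
    design = polynomial_terms(pts[:, 0], pts[:, 1])
    return np.stack([design @ t.ax, design @ t.ay], axis=-1)


def registration_residuals(
    t: FieldTransform,
    pairs: list[tuple],
    spectral_pixel_nm: float = SPECTRAL_PIXEL_NM,
) -> RegistrationQC:
    """Euclidean distances (nm) between transformed spatial and spectral points."""
    if len(pairs) == 0:
        raise ValueError("cannot compute residuals of an empty pair list")
    src = _as_points([p[0] for p in pairs])
    dst = _as_points([p[1] for p in pairs])
    delta = apply_field_transform(t, src) - dst
    res_nm = np.hypot(delta[:, 0], delta[:, 1]) * spectral_pixel_nm
    return RegistrationQC(
        residuals_nm=res_nm, median_nm=float(np.median(res_nm)), max_nm=float(res_nm.max())
    )


def update_transform_offset(
    t: FieldTransform,
    fiducial_spatial: tuple[float, float],
    fiducial_spectral: tuple[float, float],
    expected_distance_px: float = 0.0,
    dispersion_axis: str = "y",
) -> FieldTransform:
    """Re-zero the transform on a fiducial imaged in a new session.

    Lateral shifts accumulated between acquisitions on one coverslip move the
    whole field rigidly, so only the zero-order coefficients (a_x,10, a_y,10)
    need updating: they are shifted so the transformed fiducial lands at
    ``expected_distance_px`` from its spectral localization along the
    dispersion axis (0 when the fiducial emits at the reference wavelength)
    and at zero offset perpendicular to it.
    """
    mapped = apply_field_transform(t, fiducial_spatial)[0]
    target = np.asarray(fiducial_spectral, dtype=float).copy()
    axis = 1 if dispersion_axis == "y" else 0
    target[axis] -= expected_distance_px
    delta = target - mapped
    ax = t.ax.copy()
    ay = t.ay.copy()
    ax[9] += delta[0]
    ay[9] += delta[1]
    return FieldTransform(ax=ax, ay=ay, reference_wavelength_nm=t.reference_wavelength_nm)


# ---------------------------------------------------------------------------
# drift estimation / correction
# ---------------------------------------------------------------------------

def _rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    return pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()


def estimate_drift(
    fiducial_table: LocalizationTable,
    smoothing_window: int = 50,
    n_frames: int | None = None,
    cluster_radius_px: float = 5.0,
    min_coverage: float = 0.8,
) -> DriftTrace:
    """Estimate a per-frame drift trace from fiducial localizations.

    Localizations are clustered into individual fiducials by proximity
    (radius ``cluster_radius_px``).  Each fiducial must be localized in at
    least ``min_coverage`` of the frames; gaps are linearly interpolated.
    Per-fiducial offsets relative to their own first frame are averaged over
    fiducials, smoothed with a centered rolling mean, and re-referenced so
    frame 0 has offset (0, 0).
    """
    df = fiducial_table.df
    if len(df) == 0:
        raise ValueError("no fiducial localizations to estimate drift from")
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1

    # greedy proximity clustering into individual fiducials
    clusters: list[dict] = []
    for row in df.itertuples(index=False):
        pos = np.array([row.x, row.y])
        best = None
        best_d = cluster_radius_px
        for cl in clusters:
            d = np.hypot(*(pos - cl["pos"]))
            if d < best_d:
                best, best_d = cl, d
        if best is None:
            clusters.append({"pos": pos, "frames": [int(row.frame)], "xy": [pos]})
        else:
            best["frames"].append(int(row.frame))
            best["xy"].append(pos)
            best["pos"] = pos  # follow the drifting fiducial

    frames_axis = np.arange(n_frames)
    traces = []
    for cl in clusters:
        fr = np.asarray(cl["frames"])
        xy = np.asarray(cl["xy"])
        uniq, idx = np.unique(fr, return_index=True)
        if len(uniq) < min_coverage * n_frames:
            continue
        x = np.interp(frames_axis, uniq, xy[idx, 0])
        y = np.interp(frames_axis, uniq, xy[idx, 1])
        traces.append(np.stack([x - x[0], y - y[0]], axis=1))
    if not traces:
        raise ValueError(
            f"no fiducial covers >= {min_coverage:.0%} of frames; cannot estimate drift"
        )
    mean_trace = np.mean(traces, axis=0)
    dx = _rolling_mean(mean_trace[:, 0], smoothing_window)
    dy = _rolling_mean(mean_trace[:, 1], smoothing_window)
    return DriftTrace(dx=dx - dx[0], dy=dy - dy[0], smoothing_window=smoothing_window)


def apply_drift_correction(table: LocalizationTable, drift: DriftTrace) -> LocalizationTable:
    """Subtract the per-frame drift offset from every record's coordinates.

    Only x and y change; all other fields are untouched.  A record whose
    frame is outside the trace raises.
    """
    df = table.df.copy()
    if len(df):
        frames = df["frame"].to_numpy()
        if frames.max() >= drift.n_frames or frames.min() < 0:
            raise ValueError(
                f"drift trace covers frames [0, {drift.n_frames - 1}] but table has "
                f"frames [{frames.min()}, {frames.max()}]"
            )
        df["x"] = df["x"].to_numpy() - drift.dx[frames]
        df["y"] = df["y"].to_numpy() - drift.dy[frames]
    return LocalizationTable(df, channel_label=table.channel_label, metadata=dict(table.metadata))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_field_transform(t: FieldTransform, path: str | Path) -> None:
    """Serialize as a 21-value text file: ax (10), ay (10), reference lambda."""
    values = np.concatenate([t.ax, t.ay, [t.reference_wavelength_nm]])
    np.savetxt(path, values, fmt="%.17g")


def load_field_transform(path: str | Path) -> FieldTransform:
    values = np.loadtxt(path)
    if values.shape != (2 * N_COEFFS + 1,):
        raise ValueError(f"expected {2 * N_COEFFS + 1} values in transform file, got {values.shape}")
    return FieldTransform(
        ax=values[:N_COEFFS], ay=values[N_COEFFS : 2 * N_COEFFS], reference_wavelength_nm=float(values[-1])
    )
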