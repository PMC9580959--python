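"""Spectrally displaced localization: pairing, dispersion calibration, wavelength.

A low-dispersion prism in the spectral detection path shifts each emitter's
localization along one camera axis (here +y) in proportion to its mean
emission wavelength.  After the field transform maps a spatial-channel
localization into spectral-channel coordinates, the displacement to its
paired spectral localization,

    d = y_spectral - y'_spatial   (spectral-channel pixels),

is a proxy for the emission spectrum's mean, and the wavelength follows the
linear dispersion law

    lambda = lambda0 + alpha * d,

where lambda0 is the reference wavelength (the calibration fiducial's
emission peak, at which d = 0) and alpha the dispersion coefficient in
nm per pixel.  The process adds the spectral dimension at no photon cost
and never alters the spatial coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from prismtrack.io import LocalizationRecord, LocalizationTable
from prismtrack.register import FieldTransform, apply_field_transform

__all__ = [
    "SpectralCalibration",
    "PairSearchZone",
    "PairedLocalization",
    "calibrate_dispersion",
    "pair_localizations",
    "pairs_to_table",
    "assign_wavelength",
    "classify_species",
    "default_zone_from_calibration",
]

#: Physically plausible emission range (nm) for visible-range fluorophores.
PHYSICAL_RANGE_NM = (400.0, 800.0)


@dataclass
class SpectralCalibration:
    """Linear dispersion law of the prism arm: lambda = lambda0 + alpha d."""

    lambda0_nm: float
    alpha_nm_per_px: float
    dispersion_axis: str = "y"
    uncertainty_nm_per_px: float = 0.0
    intercept_nm: float | None = None  # fitted intercept, reported for QC

    def __post_init__(self) -> None:
        if self.alpha_nm_per_px == 0:
            raise ValueError("dispersion coefficient alpha must be nonzero")
        if not (PHYSICAL_RANGE_NM[0] <= self.lambda0_nm <= PHYSICAL_RANGE_NM[1]):
            raise ValueError(f"lambda0 = {self.lambda0_nm} nm outside physical range {PHYSICAL_RANGE_NM}")
        if self.dispersion_axis not in ("x", "y"):
            raise ValueError("dispersion_axis must be 'x' or 'y'")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"lambda0_nm {self.lambda0_nm:.17g}\n")
            fh.write(f"alpha_nm_per_px {self.alpha_nm_per_px:.17g}\n")
            fh.write(f"uncertainty_nm_per_px {self.uncertainty_nm_per_px:.17g}\n")
            fh.write(f"dispersion_axis {self.dispersion_axis}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SpectralCalibration":
        fields: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                key, value = line.split(maxsplit=1)
                fields[key] = value
        return cls(
            lambda0_nm=float(fields["lambda0_nm"]),
            alpha_nm_per_px=float(fields["alpha_nm_per_px"]),
            uncertainty_nm_per_px=float(fields.get("uncertainty_nm_per_px", 0.0)),
            dispersion_axis=fields.get("dispersion_axis", "y"),
        )


@dataclass
class PairSearchZone:
    """Rectangular search zone for a spatial localization's spectral partner.

    ``dx_px`` is the half-width perpendicular to the dispersion axis;
    ``dmin_px``/``dmax_px`` bound the displacement d along the dispersion
    axis.  The zone's size caps the density of simultaneously emitting
    molecules that can be paired without ambiguity.
    """

    dx_px: float = 2.0
    dmin_px: float = -15.0
    dmax_px: float = 35.0

    def __post_init__(self) -> None:
        if self.dx_px <= 0:
            raise ValueError("dx_px must be positive")
        if self.dmin_px >= self.dmax_px:
            raise ValueError("dmin_px must be smaller than dmax_px")

    def contains(self, dperp: float, d: float) -> bool:
        return abs(dperp) <= self.dx_px and self.dmin_px <= d <= self.dmax_px


@dataclass
class PairedLocalization:
    """A spatial localization matched to its spectral-channel counterpart."""

    spatial: LocalizationRecord
    spectral: LocalizationRecord
    pair_distance_px: float
    wavelength_nm: float | None = None


def default_zone_from_calibration(
    calib: SpectralCalibration,
    lambda_range_nm: tuple[float, float] = PHYSICAL_RANGE_NM,
    dx_px: float = 2.0,
) -> PairSearchZone:
    """Displacement window implied by the physically expected wavelength range."""
    d1 = (lambda_range_nm[0] - calib.lambda0_nm) / calib.alpha_nm_per_px
    d2 = (lambda_range_nm[1] - calib.lambda0_nm) / calib.alpha_nm_per_px
    return PairSearchZone(dx_px=dx_px, dmin_px=min(d1, d2), dmax_px=max(d1, d2))


# ---------------------------------------------------------------------------
# dispersion calibration
# ---------------------------------------------------------------------------

def calibrate_dispersion(
    peaks: list[tuple[float, float]],
    lambda0_nm: float,
    dispersion_axis: str = "y",
) -> SpectralCalibration:
    """Fit the dispersion coefficient from (displacement_px, wavelength_nm) peaks.

    Multicolor calibration beads (several emission peaks of known wavelength,
    e.g. 514 / 607 / 683 nm) give one displacement per peak; an unweighted
    least-squares regression of wavelength on displacement yields the slope
    alpha and its standard error.  Slope and intercept are both fitted; the
    intercept is kept for QC (it should be close to lambda0).
    """
    if len(peaks) < 2:
        raise ValueError("need at least two calibration peaks")
    d = np.asarray([p[0] for p in peaks], dtype=float)
    lam = np.asarray([p[1] for p in peaks], dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("calibration peaks have identical displacements; slope undefined")
    if len(peaks) == 2:
        slope = (lam[1] - lam[0]) / (d[1] - d[0])
        intercept = lam[0] - slope * d[0]
        stderr = 0.0
    else:
        fit = stats.linregress(d, lam)
        slope, intercept, stderr = float(fit.slope), float(fit.intercept), float(fit.stderr)
    return SpectralCalibration(
        lambda0_nm=lambda0_nm,
        alpha_nm_per_px=float(slope),
        dispersion_axis=dispersion_axis,
        uncertainty_nm_per_px=float(stderr),
        intercept_nm=float(intercept),
    )


def assign_wavelength(
    d_px: float,
    calib: SpectralCalibration,
    physical_range_nm: tuple[float, float] = PHYSICAL_RANGE_NM,
) -> tuple[float, bool]:
    """Wavelength for a pair displacement: lambda = lambda0 + alpha d.

    Returns ``(wavelength_nm, in_range)``; ``in_range`` flags whether the
    value lies inside the configured physical emission range.
    """
    lam = calib.lambda0_nm + calib.alpha_nm_per_px * d_px
    return float(lam), bool(physical_range_nm[0] <= lam <= physical_range_nm[1])


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _axes(dispersion_axis: str) -> tuple[int, int]:
    """(along, perpendicular) coordinate index for the dispersion axis."""
    return (1, 0) if dispersion_axis == "y" else (0, 1)


def pair_localizations(
    spatial_table: LocalizationTable,
    spectral_table: LocalizationTable,
    t: FieldTransform,
    zone: PairSearchZone,
    calib: SpectralCalibration | None = None,
    expected_d_px: float | None = None,
    displacement_weight: float = 0.0,
    greedy_above: int = 200,
) -> list[PairedLocalization]:
    """Pair spatial and spectral localizations frame by frame.

    Spatial coordinates are mapped through the field transform; spectral
    candidates within the search zone (|perpendicular offset| <= dx_px and
    displacement d in [dmin, dmax]) form links.  Conflicts are resolved per
    frame by a minimum-cost one-to-one assignment with cost
    ``perp_offset^2 + displacement_weight * (d - expected_d)^2`` (weight 0
    without a species prior; a greedy fallback handles frames with more than
    ``greedy_above`` candidate links).  Unmatched spatial records are kept
    without a wavelength; spatial coordinates are never modified.
    """
    along, perp = _axes(calib.dispersion_axis if calib else "y")
    sp_df = spatial_table.df
    sc_df = spectral_table.df
    pairs: list[PairedLocalization] = []
    sc_by_frame = dict(tuple(sc_df.groupby("frame"))) if len(sc_df) else {}

    spatial_records = spatial_table.records
    # group spatial record indices per frame preserving order
    by_frame: dict[int, list[int]] = {}
    for i, rec in enumerate(spatial_records):
        by_frame.setdefault(rec.frame, []).append(i)

    for frame, idxs in by_frame.items():
        frame_records = [spatial_records[i] for i in idxs]
        pts = np.array([[r.x, r.y] for r in frame_records])
        mapped = apply_field_transform(t, pts)
        sc_frame = sc_by_frame.get(frame)
        if sc_frame is None or len(sc_frame) == 0:
            pairs.extend(PairedLocalization(r, None, np.nan) for r in frame_records)
            continue
        sc_xy = sc_frame[["x", "y"]].to_numpy(float)
        # candidate links inside the zone
        dperp = sc_xy[None, :, perp] - mapped[:, None, perp]
        dalong = sc_xy[None, :, along] - mapped[:, None, along]
        in_zone = (np.abs(dperp) <= zone.dx_px) & (dalong >= zone.dmin_px) & (dalong <= zone.dmax_px)
        cost = dperp**2
        if displacement_weight > 0 and expected_d_px is not None:
            cost = cost + displacement_weight * (dalong - expected_d_px) ** 2
        n_links = int(in_zone.sum())
        match = _one_to_one(cost, in_zone, greedy=n_links > greedy_above)
        spectral_records = LocalizationTable(
            sc_frame, channel_label=spectral_table.channel_label
        ).records
        for i, rec in enumerate(frame_records):
            j = match.get(i)
            if j is None:
                pairs.append(PairedLocalization(rec, None, np.nan))
            else:
                d = float(dalong[i, j])
                lam = None
                if calib is not None:
                    lam, _ = assign_wavelength(d, calib)
                pairs.append(PairedLocalization(rec, spectral_records[j], d, lam))
    return pairs


def _one_to_one(cost: np.ndarray, feasible: np.ndarray, greedy: bool = False) -> dict[int, int]:
    """Minimum-cost one-to-one matching restricted to feasible links."""
    n, m = cost.shape
    match: dict[int, int] = {}
    if not feasible.any():
        return match
    if greedy:
        order = np.argsort(np.where(feasible, cost, np.inf), axis=None)
        used_i: set[int] = set()
        used_j: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), m)
            if not feasible[i, j]:
                break
            if i in used_i or j in used_j:
                continue
            match[i] = j
            used_i.add(i)
            used_j.add(j)
        return match
    big = 1e12
    padded = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(padded)
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            match[int(i)] = int(j)
    return match


def pairs_to_table(
    pairs: list[PairedLocalization],
    channel_label: str = "spatial",
    metadata: dict | None = None,
) -> LocalizationTable:
    """Flatten pairing results into a localization table.

    Each output row is the *spatial* record (coordinates untouched) with
    ``pair_distance`` and ``wavelength`` filled in where a spectral partner
    was found.
    """
    records = []
    for p in pairs:
        rec = LocalizationRecord(**{**p.spatial.__dict__})
        if p.spectral is not None:
            rec.pair_distance = float(p.pair_distance_px)
            rec.wavelength = p.wavelength_nm
        records.append(rec)
    return LocalizationTable(records, channel_label=channel_label, metadata=metadata)


# ---------------------------------------------------------------------------
# species classification
# ---------------------------------------------------------------------------

def classify_species(
    table: LocalizationTable,
    windows: list[tuple[str, float, float]],
) -> LocalizationTable:
    """Label records by non-overlapping wavelength windows.

    ``windows`` is a list of ``(label, lambda_min, lambda_max)``.  Records
    whose wavelength falls in no window (or is unset) are labeled
    ``"unassigned"``.
    """
    ordered = sorted(windows, key=lambda w: w[1])
    for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(ordered, ordered[1:]):
        if hi_a > lo_b:
            raise ValueError(f"species windows '{la}' and '{lb}' overlap")
    df = table.df.copy()
    labels = np.full(len(df), "unassigned", dtype=object)
    lam = df["wavelength"].to_numpy(float)
    for label, lo, hi in windows:
        inside = (lam >= lo) & (lam <= hi)
        labels[inside] = label
    df["species"] = labels
    return LocalizationTable(df, channel_label=table.channel_label, metadata=dict(table.metadata))
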