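"""Spectrally-informed single/double Gaussian fitting.

Two emitters closer than ~200 nm merge into one spot on the spatial
channel, where a systematic single-emitter fit under-counts and a
systematic two-emitter fit over-counts (it happily splits a lone PSF in
two).  If the emitters differ in wavelength, however, the prism separates
them on the spectral channel.  The spectral channel therefore supplies:

1. the number of emitters hiding under each spatial spot (one or two),
   counted from the spectral localizations falling in the spot's pair
   search zone; and
2. an initialization for the coordinates perpendicular to the dispersion
   axis, taken from the spectral localizations and mapped back through the
   inverse field transform.

Only then is a two-component fit attempted, which removes the over-counting
pathology while keeping the resolving power of multi-emitter fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, linear_sum_assignment

from prismtrack.detect import (
    AstigmatismCalibration,
    DetectionParams,
    assign_z,
    detect_spots,
    fit_single,
    wavelet_filter,
    wavelet_noise_scale,
)
from prismtrack.io import LocalizationRecord, LocalizationTable
from prismtrack.register import FieldTransform, apply_field_transform
from prismtrack.spectral import PairSearchZone, SpectralCalibration, assign_wavelength

__all__ = [
    "MultiFitDecision",
    "count_candidates",
    "fit_two_emitters",
    "fit_two_systematic",
    "informed_localize_frame",
    "invert_transform",
]

#: Spectral candidates closer than this along the dispersion axis cannot be
#: resolved and are merged (keeping the brighter one).
MIN_SPECTRAL_SEPARATION_PX = 2.0

#: A second candidate dimmer than this fraction of the primary is treated as
#: a spurious detection, not a hidden emitter.
MIN_RELATIVE_PHOTONS = 0.3


@dataclass
class MultiFitDecision:
    """How many emitters to fit under one spatial seed, and where to start.

    ``n_emitters`` is the number of spectral localizations found in the
    seed's pair search zone, capped at 2.  ``init_positions`` are the
    corresponding spatial-channel coordinates perpendicular to the
    dispersion axis (x when dispersion is along y), obtained by mapping the
    spectral candidates back through the inverse field transform.
    """

    n_emitters: int
    spectral_candidates: list[LocalizationRecord] = field(default_factory=list)
    init_positions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.n_emitters <= 2):
            raise ValueError("n_emitters must be 0, 1 or 2")


def invert_transform(
    t: FieldTransform,
    point_spectral: tuple[float, float],
    guess_spatial: tuple[float, float],
    n_iter: int = 5,
) -> np.ndarray:
    """Invert the cubic field transform locally by Newton iteration.

    The polynomial warp is near-affine over a PSF-sized neighbourhood, so a
    handful of Newton steps from a good guess (the spatial seed) converge to
    machine precision.
    """
    q = np.asarray(point_spectral, dtype=float)
    p = np.asarray(guess_spatial, dtype=float)
    eps = 1e-4
    for _ in range(n_iter):
        f = apply_field_transform(t, p)[0] - q
        jx = (apply_field_transform(t, p + [eps, 0])[0] - apply_field_transform(t, p - [eps, 0])[0]) / (2 * eps)
        jy = (apply_field_transform(t, p + [0, eps])[0] - apply_field_transform(t, p - [0, eps])[0]) / (2 * eps)
        jac = np.column_stack([jx, jy])
        try:
            p = p - np.linalg.solve(jac, f)
        except np.linalg.LinAlgError:
            break
    return p


def count_candidates(
    spatial_seed: tuple[float, float],
    spectral_records: list[LocalizationRecord],
    t: FieldTransform,
    zone: PairSearchZone,
    dispersion_axis: str = "y",
    min_relative_photons: float = MIN_RELATIVE_PHOTONS,
) -> MultiFitDecision:
    """Count spectral localizations in the pair search zone of a spatial seed.

    Candidates closer than :data:`MIN_SPECTRAL_SEPARATION_PX` along the
    dispersion axis are merged to the brighter one (they cannot be resolved
    spectrally), and a secondary candidate below ``min_relative_photons`` of
    the brightest is discarded as spurious.  The decision caps n at 2; with
    three or more surviving candidates the two brightest are used.
    """
    seed_xy = np.asarray(spatial_seed, dtype=float)
    mapped = apply_field_transform(t, seed_xy)[0]
    along, perp = (1, 0) if dispersion_axis == "y" else (0, 1)

    in_zone = []
    for rec in spectral_records:
        sxy = np.array([rec.x, rec.y])
        dperp = sxy[perp] - mapped[perp]
        dalong = sxy[along] - mapped[along]
        if zone.contains(dperp, dalong):
            in_zone.append(rec)
    in_zone.sort(key=lambda r: r.photons, reverse=True)

    merged: list[LocalizationRecord] = []
    for rec in in_zone:
        r_along = rec.y if dispersion_axis == "y" else rec.x
        close = any(
            abs(r_along - (m.y if dispersion_axis == "y" else m.x)) < MIN_SPECTRAL_SEPARATION_PX
            for m in merged
        )
        if not close:
            merged.append(rec)
    if len(merged) >= 2 and merged[1].photons < min_relative_photons * merged[0].photons:
        merged = merged[:1]

    chosen = merged[:2]
    init_positions = []
    for rec in chosen:
        back = invert_transform(t, (rec.x, rec.y), tuple(seed_xy))
        init_positions.append(float(back[perp]))
    return MultiFitDecision(
        n_emitters=len(chosen), spectral_candidates=chosen, init_positions=init_positions
    )


# ---------------------------------------------------------------------------
# two-component fitting
# ---------------------------------------------------------------------------

def _two_gaussian_model(p: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    a1, x1, y1, sx1, sy1, a2, x2, y2, sx2, sy2, b = p
    g1 = a1 * np.exp(-((xg - x1) ** 2) / (2 * sx1**2) - ((yg - y1) ** 2) / (2 * sy1**2))
    g2 = a2 * np.exp(-((xg - x2) ** 2) / (2 * sx2**2) - ((yg - y2) ** 2) / (2 * sy2**2))
    return g1 + g2 + b


def _two_gaussian_jac(p: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    jac = np.empty((xg.size, 11))
    for k in (0, 5):
        a, x0, y0, sx, sy = p[k : k + 5]
        dx, dy = xg - x0, yg - y0
        e = np.exp(-(dx**2) / (2 * sx**2) - (dy**2) / (2 * sy**2))
        jac[:, k + 0] = e.ravel()
        jac[:, k + 1] = (a * e * dx / sx**2).ravel()
        jac[:, k + 2] = (a * e * dy / sy**2).ravel()
        jac[:, k + 3] = (a * e * dx**2 / sx**3).ravel()
        jac[:, k + 4] = (a * e * dy**2 / sy**3).ravel()
    jac[:, 10] = 1.0
    return jac


def _fit_two(
    image: np.ndarray,
    seed: tuple[float, float],
    init_xy: list[tuple[float, float]],
    init_amplitudes: tuple[float, float],
    params: DetectionParams,
    frame: int,
    gain: float,
) -> tuple[list[LocalizationRecord], bool]:
    """Shared sum-of-two-Gaussians least-squares core.

    ``seed`` and ``init_xy`` are (x, y).  The ROI is centered between the
    two initial positions and enlarged over the single-emitter window so
    both components lie well inside it.  Returns the two records (order =
    init order) and a convergence flag.
    """
    image = np.asarray(image, dtype=float)
    spread = float(
        max(abs(init_xy[0][0] - init_xy[1][0]), abs(init_xy[0][1] - init_xy[1][1]))
    )
    r = params.roi_radius_px + 2 + int(np.ceil(spread / 2.0))
    r = min(r, (min(image.shape) - 3) // 2)
    center_x = 0.5 * (init_xy[0][0] + init_xy[1][0])
    center_y = 0.5 * (init_xy[0][1] + init_xy[1][1])
    row, col = int(round(center_y)), int(round(center_x))
    row = min(max(row, r), image.shape[0] - r - 1)
    col = min(max(col, r), image.shape[1] - r - 1)
    roi = image[row - r : row + r + 1, col - r : col + r + 1]
    yg, xg = np.mgrid[row - r : row + r + 1, col - r : col + r + 1].astype(float)

    b0 = float(roi.min())
    s0 = params.psf_sigma_px
    p0 = np.array(
        [
            init_amplitudes[0], init_xy[0][0], init_xy[0][1], s0, s0,
            init_amplitudes[1], init_xy[1][0], init_xy[1][1], s0, s0,
            b0,
        ]
    )
    lb = [0, col - r - 1, row - r - 1, 0.3, 0.3, 0, col - r - 1, row - r - 1, 0.3, 0.3, -np.inf]
    ub = [np.inf, col + r + 1, row + r + 1, 3.0 * r, 3.0 * r,
          np.inf, col + r + 1, row + r + 1, 3.0 * r, 3.0 * r, np.inf]
    p0 = np.clip(p0, lb, ub)
    try:
        res = least_squares(
            lambda p: (_two_gaussian_model(p, xg, yg) - roi).ravel(),
            p0,
            jac=lambda p: _two_gaussian_jac(p, xg, yg),
            bounds=(lb, ub),
            xtol=1e-6,
            max_nfev=100 * 12,
        )
    except Exception:
        return [], False
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((roi - roi.mean()) ** 2))
    goodness = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)) if ss_tot > 0 else 0.0
    records = []
    for k in (0, 5):
        a, x0, y0, sx, sy = res.x[k : k + 5]
        records.append(
            LocalizationRecord(
                frame=frame,
                x=float(x0),
                y=float(y0),
                sigma_x=float(max(sx, 1e-6)),
                sigma_y=float(max(sy, 1e-6)),
                photons=float(2.0 * np.pi * a * sx * sy / gain),
                background=float(res.x[10]),
                goodness=goodness,
                valid=bool(res.success) or res.status > 0,
            )
        )
    converged = (bool(res.success) or res.status > 0) and np.isfinite(res.x).all()
    return records, converged


def _fit_two_constrained(
    image: np.ndarray,
    init_xy: list[tuple[float, float]],
    init_amplitudes: tuple[float, float],
    sigma_xy: tuple[float, float],
    perp: int,
    params: DetectionParams,
    frame: int,
    gain: float,
    perp_halfwidth_px: float = 1.0,
    along_halfwidth_px: float = 1.5,
) -> tuple[list[LocalizationRecord], bool]:
    """Spectrally-constrained sum-of-two-Gaussians fit.

    Both components share fixed widths ``sigma_xy`` taken from the PSF
    model: two sub-diffraction emitters are images of the same optical PSF
    at (nearly) the same defocus, and freeing four width parameters on an
    unresolved pair is statistically degenerate.  The coordinate
    perpendicular to the dispersion axis is bounded within
    ``perp_halfwidth_px`` of its spectral-channel initialization (a
    several-sigma allowance given spectral localization precision); the
    along-axis coordinate stays within ``along_halfwidth_px`` of the seed,
    since the two-component fit only triggers for emitters overlapping
    inside one diffraction-limited spot.
    Free parameters: two amplitudes, two positions, common offset.
    """
    image = np.asarray(image, dtype=float)
    sx, sy = float(sigma_xy[0]), float(sigma_xy[1])
    spread = float(max(abs(init_xy[0][0] - init_xy[1][0]), abs(init_xy[0][1] - init_xy[1][1])))
    r = params.roi_radius_px + 2 + int(np.ceil(spread / 2.0))
    r = min(r, (min(image.shape) - 3) // 2)
    row = int(round(0.5 * (init_xy[0][1] + init_xy[1][1])))
    col = int(round(0.5 * (init_xy[0][0] + init_xy[1][0])))
    row = min(max(row, r), image.shape[0] - r - 1)
    col = min(max(col, r), image.shape[1] - r - 1)
    roi = image[row - r : row + r + 1, col - r : col + r + 1]
    yg, xg = np.mgrid[row - r : row + r + 1, col - r : col + r + 1].astype(float)

    b0 = float(roi.min())

    def model(p: np.ndarray) -> np.ndarray:
        a1, x1, y1, a2, x2, y2, b = p
        g1 = a1 * np.exp(-((xg - x1) ** 2) / (2 * sx**2) - ((yg - y1) ** 2) / (2 * sy**2))
        g2 = a2 * np.exp(-((xg - x2) ** 2) / (2 * sx**2) - ((yg - y2) ** 2) / (2 * sy**2))
        return (g1 + g2 + b - roi).ravel()

    half = [perp_halfwidth_px, perp_halfwidth_px]
    half[1 - perp] = along_halfwidth_px  # index 0 = x, 1 = y in (x, y) order
    p0 = np.array(
        [
            init_amplitudes[0], init_xy[0][0], init_xy[0][1],
            init_amplitudes[1], init_xy[1][0], init_xy[1][1],
            b0,
        ]
    )
    lb = [0, init_xy[0][0] - half[0], init_xy[0][1] - half[1],
          0, init_xy[1][0] - half[0], init_xy[1][1] - half[1], -np.inf]
    ub = [np.inf, init_xy[0][0] + half[0], init_xy[0][1] + half[1],
          np.inf, init_xy[1][0] + half[0], init_xy[1][1] + half[1], np.inf]
    p0 = np.clip(p0, lb, ub)
    try:
        res = least_squares(model, p0, bounds=(lb, ub), xtol=1e-6, max_nfev=100 * 8)
    except Exception:
        return [], False
    ss_res = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((roi - roi.mean()) ** 2))
    goodness = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0)) if ss_tot > 0 else 0.0
    records = []
    for k in (0, 3):
        a, x0, y0 = res.x[k : k + 3]
        records.append(
            LocalizationRecord(
                frame=frame,
                x=float(x0),
                y=float(y0),
                sigma_x=sx,
                sigma_y=sy,
                photons=float(2.0 * np.pi * a * sx * sy / gain),
                background=float(res.x[6]),
                goodness=goodness,
                valid=bool(res.success) or res.status > 0,
            )
        )
    converged = (bool(res.success) or res.status > 0) and np.isfinite(res.x).all()
    return records, converged


def fit_two_emitters(
    image: np.ndarray,
    seed: tuple[float, float],
    decision: MultiFitDecision,
    params: DetectionParams,
    frame: int = 0,
    gain: float = 1.0,
    sigma_xy: tuple[float, float] | None = None,
    dispersion_axis: str = "y",
) -> list[LocalizationRecord]:
    """Fit two emitters under one spot, guided by spectral candidates.

    The coordinates perpendicular to the dispersion axis are initialized
    from ``decision.init_positions`` (and bounded near them); along the axis
    both components start at the seed.  Widths are fixed to the PSF model
    (``sigma_xy``, defaulting to the detection PSF width) and amplitudes
    split proportionally to the spectral candidates' photons.  On
    non-convergence both records come back flagged invalid so the caller
    can fall back to a single fit.  Record order follows the candidate order
    in ``decision`` so each fitted emitter is paired to its spectral
    candidate for wavelength assignment.
    """
    if decision.n_emitters != 2:
        raise ValueError("fit_two_emitters requires a two-candidate decision")
    if sigma_xy is None:
        sigma_xy = (params.psf_sigma_px, params.psf_sigma_px)
    perp = 0 if dispersion_axis == "y" else 1
    ph = np.array([c.photons for c in decision.spectral_candidates[:2]], dtype=float)
    frac = ph / ph.sum() if ph.sum() > 0 else np.array([0.5, 0.5])
    image_f = np.asarray(image, dtype=float)
    peak = float(image_f[int(round(seed[1])), int(round(seed[0]))])
    base = float(np.median(image_f))
    amp = max(peak - base, 1.0)
    init_xy = []
    for k in range(2):
        p = [0.0, 0.0]
        p[perp] = decision.init_positions[k]
        p[1 - perp] = seed[1 - perp]
        init_xy.append((p[0], p[1]))
    records, converged = _fit_two_constrained(
        image, init_xy, (2 * amp * frac[0], 2 * amp * frac[1]), sigma_xy, perp, params, frame, gain
    )
    if not converged:
        for rec in records:
            rec.valid = False
    return records


def fit_two_systematic(
    image: np.ndarray,
    seed: tuple[float, float],
    params: DetectionParams,
    frame: int = 0,
    gain: float = 1.0,
) -> list[LocalizationRecord]:
    """Unconditional two-component fit with no spectral information.

    Used as the benchmark baseline: a single Gaussian is fitted first, and
    the second component is initialized at the maximum of the fit residual —
    the standard blind multi-emitter strategy, which over-counts whenever a
    lone PSF is split in two.
    """
    single = fit_single(image, (int(round(seed[1])), int(round(seed[0]))), params, frame=frame, gain=gain)
    image_f = np.asarray(image, dtype=float)
    r = params.roi_radius_px + 2
    row, col = int(round(seed[1])), int(round(seed[0]))
    row = min(max(row, r), image_f.shape[0] - r - 1)
    col = min(max(col, r), image_f.shape[1] - r - 1)
    roi = image_f[row - r : row + r + 1, col - r : col + r + 1]
    yg, xg = np.mgrid[row - r : row + r + 1, col - r : col + r + 1].astype(float)
    if single.valid:
        amp1 = single.photons * gain / (2 * np.pi * single.sigma_x * single.sigma_y)
        model = amp1 * np.exp(
            -((xg - single.x) ** 2) / (2 * single.sigma_x**2)
            - ((yg - single.y) ** 2) / (2 * single.sigma_y**2)
        ) + single.background
        residual = roi - model
        first_xy = (single.x, single.y)
    else:
        residual = roi - np.median(roi)
        first_xy = (float(col), float(row))
        amp1 = float(roi.max() - np.median(roi))
    ir, ic = np.unravel_index(int(np.argmax(residual)), residual.shape)
    second_xy = (float(xg[ir, ic]), float(yg[ir, ic]))
    amp2 = max(float(residual[ir, ic]), 0.25 * amp1)
    records, _ = _fit_two(image, seed, [first_xy, second_xy], (amp1, amp2), params, frame, gain)
    return records


# ---------------------------------------------------------------------------
# per-frame pipeline
# ---------------------------------------------------------------------------

def informed_localize_frame(
    spatial_image: np.ndarray,
    spectral_image: np.ndarray,
    t: FieldTransform,
    zone: PairSearchZone,
    calib: SpectralCalibration,
    params: DetectionParams | None = None,
    astig_calib: AstigmatismCalibration | None = None,
    frame: int = 0,
    gain: float = 1.0,
    mode: str = "informed",
) -> list[LocalizationRecord]:
    """Full per-frame pipeline: detect on both channels, decide, fit, assign.

    In ``"informed"`` mode each spatial seed is first paired one-to-one with
    spectral localizations (so two partially split seeds of the same pair do
    not both claim two candidates); a seed with an additional unclaimed
    candidate in its zone triggers the two-component fit, otherwise a single
    fit is used and the paired candidate supplies the wavelength.  Modes
    ``"single"`` and ``"systematic"`` run unconditional single- and
    two-component fitting (no spectral information) for benchmarking.
    """
    params = params or DetectionParams()
    along, perp = (1, 0) if calib.dispersion_axis == "y" else (0, 1)

    plane = wavelet_filter(spatial_image, params.wavelet_scale)
    seeds_rc = detect_spots(plane, params, noise_scale=wavelet_noise_scale(spatial_image))
    out: list[LocalizationRecord] = []

    if mode == "single":
        for row, col in seeds_rc:
            rec = fit_single(spatial_image, (row, col), params, frame=frame, gain=gain)
            if rec.valid:
                out.append(rec)
        return _with_z(out, astig_calib)
    if mode == "systematic":
        # the blind policy emits two localizations per spot unconditionally;
        # poorly converged components are kept (that is its failure mode)
        for row, col in seeds_rc:
            recs = fit_two_systematic(spatial_image, (col, row), params, frame=frame, gain=gain)
            out.extend(r for r in recs if np.isfinite(r.x) and np.isfinite(r.y))
        return _with_z(out, astig_calib)
    if mode != "informed":
        raise ValueError(f"unknown mode {mode!r}")

    # spectral-channel localizations (always single emitters: the prism
    # separates species along the dispersion axis)
    spec_plane = wavelet_filter(spectral_image, params.wavelet_scale)
    spec_params = DetectionParams(
        wavelet_scale=params.wavelet_scale,
        threshold_k=params.threshold_k,
        roi_radius_px=params.roi_radius_px,
        min_separation_px=min(params.min_separation_px, MIN_SPECTRAL_SEPARATION_PX),
        psf_sigma_px=params.psf_sigma_px,
    )
    spec_records = [
        r
        for r in (
            fit_single(spectral_image, s, spec_params, frame=frame, gain=gain)
            for s in detect_spots(
                spec_plane, spec_params, noise_scale=wavelet_noise_scale(spectral_image)
            )
        )
        if r.valid
    ]

    # one-to-one pre-pairing of seeds to spectral candidates (perpendicular cost)
    seeds_xy = [(float(c), float(r)) for r, c in seeds_rc]
    mapped = (
        apply_field_transform(t, np.array(seeds_xy)) if seeds_xy else np.zeros((0, 2))
    )
    n_s, n_c = len(seeds_xy), len(spec_records)
    feasible = np.zeros((n_s, n_c), dtype=bool)
    cost = np.zeros((n_s, n_c))
    for i in range(n_s):
        for j, rec in enumerate(spec_records):
            sxy = np.array([rec.x, rec.y])
            dperp = sxy[perp] - mapped[i, perp]
            dalong = sxy[along] - mapped[i, along]
            feasible[i, j] = zone.contains(dperp, dalong)
            cost[i, j] = dperp**2
    primary: dict[int, int] = {}
    if feasible.any():
        ri, ci = linear_sum_assignment(np.where(feasible, cost, 1e12))
        primary = {int(i): int(j) for i, j in zip(ri, ci) if feasible[i, j]}
    claimed = set(primary.values())

    # group spatial seeds whose fitting windows overlap: near-neighbour seeds
    # are fitted jointly so a bright neighbour's tail cannot bias a single fit
    group_radius = 2.0 * params.roi_radius_px + 1.0
    parent = list(range(n_s))

    def _find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n_s):
        for j in range(i + 1, n_s):
            if (
                np.hypot(seeds_xy[i][0] - seeds_xy[j][0], seeds_xy[i][1] - seeds_xy[j][1])
                <= group_radius
            ):
                parent[_find(i)] = _find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n_s):
        groups.setdefault(_find(i), []).append(i)

    for members in groups.values():
        # candidate pool: members' primaries first, then unclaimed feasible extras
        pool: list[int] = []
        for i in members:
            if i in primary and primary[i] not in pool:
                pool.append(primary[i])
        extras = sorted(
            {j for i in members for j in range(n_c) if feasible[i, j] and j not in claimed},
            key=lambda j: -spec_records[j].photons,
        )
        pool.extend(extras)
        group_center = tuple(np.mean([seeds_xy[i] for i in members], axis=0))
        decision = _decide(group_center, [spec_records[j] for j in pool], t, calib.dispersion_axis)

        if decision.n_emitters == 2 and len(members) <= 2:
            claimed.update(j for j in extras if spec_records[j] in decision.spectral_candidates)
            # widths fixed to the PSF model; with astigmatism, the in-focus
            # widths (z refinement of unresolved pairs is not attempted)
            if astig_calib is not None:
                wx, wy = astig_calib.widths_at(0.0)
                sigma_xy = (float(wx), float(wy))
            else:
                sigma_xy = (params.psf_sigma_px, params.psf_sigma_px)
            recs = _fit_group_two(
                spatial_image, members, seeds_xy, decision, params, perp, along, frame, gain, sigma_xy
            )
            if recs and all(r.valid for r in recs):
                for rec, cand in zip(recs, decision.spectral_candidates):
                    _assign_lambda(rec, cand, t, calib, along)
                out.extend(recs)
                continue
        # nominal case (n <= 1) or fallback: one single fit per member seed
        for i in members:
            row, col = seeds_rc[i]
            rec = fit_single(spatial_image, (row, col), params, frame=frame, gain=gain)
            if not rec.valid:
                continue
            if i in primary:
                _assign_lambda(rec, spec_records[primary[i]], t, calib, along)
            out.append(rec)
    return _with_z(out, astig_calib)


def _fit_group_two(
    image: np.ndarray,
    members: list[int],
    seeds_xy: list[tuple[float, float]],
    decision: MultiFitDecision,
    params: DetectionParams,
    perp: int,
    along: int,
    frame: int,
    gain: float,
    sigma_xy: tuple[float, float],
) -> list[LocalizationRecord]:
    """Joint constrained two-component fit for one or two adjacent seeds.

    Each component's perpendicular coordinate starts at the spectral
    candidate's back-mapped position; the coordinate along the dispersion
    axis starts at the nearest member seed (the sole seed when the two
    emitters merged into one spot).  Widths are fixed to the PSF model.
    """
    seed_perp = [s[perp] for s in (seeds_xy[i] for i in members)]
    seed_along = [seeds_xy[i][along] for i in members]
    init_xy = []
    for k in range(2):
        p = [0.0, 0.0]
        p[perp] = decision.init_positions[k]
        nearest = int(np.argmin([abs(decision.init_positions[k] - sp) for sp in seed_perp]))
        p[along] = seed_along[nearest]
        init_xy.append((p[0], p[1]))

    image_f = np.asarray(image, dtype=float)
    peak = max(float(image_f[int(round(s[1])), int(round(s[0]))]) for s in (seeds_xy[i] for i in members))
    base = float(np.median(image_f))
    amp = max(peak - base, 1.0)
    ph = np.array([c.photons for c in decision.spectral_candidates[:2]], dtype=float)
    frac = ph / ph.sum() if ph.sum() > 0 else np.array([0.5, 0.5])
    records, converged = _fit_two_constrained(
        image, init_xy, (2 * amp * frac[0], 2 * amp * frac[1]), sigma_xy, perp, params, frame, gain
    )
    if not converged:
        for rec in records:
            rec.valid = False
    return records


def _decide(
    seed_xy: tuple[float, float],
    candidates: list[LocalizationRecord],
    t: FieldTransform,
    dispersion_axis: str,
) -> MultiFitDecision:
    """Build a MultiFitDecision from pre-screened candidates (merge + intensity filter)."""
    merged: list[LocalizationRecord] = []
    for rec in sorted(candidates, key=lambda r: -r.photons):
        r_along = rec.y if dispersion_axis == "y" else rec.x
        if not any(
            abs(r_along - (m.y if dispersion_axis == "y" else m.x)) < MIN_SPECTRAL_SEPARATION_PX
            for m in merged
        ):
            merged.append(rec)
    if len(merged) >= 2 and merged[1].photons < MIN_RELATIVE_PHOTONS * merged[0].photons:
        merged = merged[:1]
    chosen = merged[:2]
    perp = 0 if dispersion_axis == "y" else 1
    init_positions = [
        float(invert_transform(t, (c.x, c.y), seed_xy)[perp]) for c in chosen
    ]
    return MultiFitDecision(n_emitters=len(chosen), spectral_candidates=chosen, init_positions=init_positions)


def _assign_lambda(
    rec: LocalizationRecord,
    candidate: LocalizationRecord,
    t: FieldTransform,
    calib: SpectralCalibration,
    along: int,
) -> None:
    mapped = apply_field_transform(t, (rec.x, rec.y))[0]
    cand_along = candidate.y if along == 1 else candidate.x
    d = float(cand_along - mapped[along])
    lam, _ = assign_wavelength(d, calib)
    rec.pair_distance = d
    rec.wavelength = lam


def _with_z(
    records: list[LocalizationRecord], astig_calib: AstigmatismCalibration | None
) -> list[LocalizationRecord]:
    if astig_calib is None:
        return records
    return [assign_z(r, astig_calib) for r in records]
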