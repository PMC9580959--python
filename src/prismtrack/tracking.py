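"""Trajectory linking, MSD curves and diffusion coefficients.

Localizations are linked frame to frame by a minimum-cost one-to-one
assignment on squared displacement, subject to a maximum per-link
displacement; tracks may bridge short dark gaps (quantum-dot blinking).
The exact assignment optimum is the default solver; a simulated-annealing
solver with geometric cooling is available as an alternative and converges
to the same optimum on small instances.

For each track, the time-averaged mean squared displacement

    MSD(k dt) = < || r(t + k dt) - r(t) ||^2 >_t        (um^2)

is computed over all pair lags, in 2-D or 3-D depending on z availability.
For free Brownian motion MSD(tau) = 2 * dim * D * tau, so the diffusion
coefficient D follows from an unweighted linear fit through the first MSD
points: D = slope / (2 * dim).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from prismtrack.io import LocalizationTable

__all__ = [
    "Track",
    "DiffusionResult",
    "link_tracks",
    "compute_msd",
    "fit_diffusion",
    "species_split_diffusion",
    "tracks_to_table",
]


@dataclass
class Track:
    """One linked trajectory: frames (strictly increasing), positions, species."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None  # nm, None when 2-D
    species: str | None = None
    record_indices: np.ndarray | None = None  # rows of the source table

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if (np.diff(self.frames) <= 0).any():
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DiffusionResult:
    """MSD curve and (optionally) the diffusion coefficient fitted from it."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    dimensionality: int = 2
    D_um2_per_s: float | None = None
    fit_points: int | None = None
    clamped: bool = False  # negative MSD slope clamped to D = 0
    track_id: int | None = None


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_tracks(
    table: LocalizationTable,
    max_disp_px: float = 5.0,
    max_gap: int = 2,
    seed: int = 0,
    solver: str = "exact",
) -> list[Track]:
    """Link localizations into trajectories.

    Frame to frame, active track ends are matched one-to-one to the next
    frame's detections by minimum total squared displacement; links longer
    than ``max_disp_px`` (scaled by the gap length when bridging up to
    ``max_gap`` missing frames) are forbidden.  Unmatched detections start
    new tracks.  ``solver="anneal"`` replaces the exact per-frame assignment
    with simulated annealing (geometric cooling, fixed ``seed``); both reach
    the same optimum on small instances.
    """
    df = table.df
    has_z = len(df) > 0 and df["z"].notna().all()
    tracks: list[dict] = []  # each: indices, frames, positions
    active: list[int] = []

    frames_sorted = np.sort(df["frame"].unique()) if len(df) else []
    rng = np.random.default_rng(seed)

    for frame in frames_sorted:
        rows = df.index[df["frame"] == frame].to_numpy()
        det_xy = df.loc[rows, ["x", "y"]].to_numpy(float)

        # candidate links: active tracks within max_gap, per-link cap scaled by gap
        cand_tracks = [ti for ti in active if frame - tracks[ti]["frames"][-1] <= max_gap + 1]
        n_t, n_d = len(cand_tracks), len(rows)
        assigned_d: set[int] = set()
        if n_t and n_d:
            cost = np.full((n_t, n_d), np.inf)
            for a, ti in enumerate(cand_tracks):
                tr = tracks[ti]
                gap = frame - tr["frames"][-1]
                last = np.array([tr["x"][-1], tr["y"][-1]])
                d2 = np.sum((det_xy - last) ** 2, axis=1)
                limit = (max_disp_px * gap) ** 2
                cost[a, d2 <= limit] = d2[d2 <= limit]
            pairs = _solve_assignment(cost, solver, rng)
            for a, b in pairs:
                ti = cand_tracks[a]
                tracks[ti]["frames"].append(int(frame))
                tracks[ti]["x"].append(float(det_xy[b, 0]))
                tracks[ti]["y"].append(float(det_xy[b, 1]))
                tracks[ti]["rows"].append(int(rows[b]))
                assigned_d.add(b)
        for b in range(n_d):
            if b not in assigned_d:
                tracks.append(
                    {
                        "frames": [int(frame)],
                        "x": [float(det_xy[b, 0])],
                        "y": [float(det_xy[b, 1])],
                        "rows": [int(rows[b])],
                    }
                )
        active = [ti for ti in range(len(tracks)) if frame - tracks[ti]["frames"][-1] <= max_gap]

    out = []
    for tid, tr in enumerate(tracks):
        rows = np.asarray(tr["rows"])
        z = df.loc[rows, "z"].to_numpy(float) if has_z else None
        species = _majority_species(df.loc[rows, "species"]) if "species" in df else None
        out.append(
            Track(
                track_id=tid,
                frames=np.asarray(tr["frames"]),
                x=np.asarray(tr["x"]),
                y=np.asarray(tr["y"]),
                z=z,
                species=species,
                record_indices=rows,
            )
        )
    return out


def _majority_species(series: pd.Series) -> str | None:
    vals = series.dropna()
    vals = vals[vals != ""]
    if len(vals) == 0:
        return None
    return str(vals.mode().iloc[0])


def _solve_assignment(cost: np.ndarray, solver: str, rng: np.random.Generator) -> list[tuple[int, int]]:
    """One-to-one assignment minimizing total cost; inf marks forbidden links."""
    feasible = np.isfinite(cost)
    if not feasible.any():
        return []
    if solver == "exact":
        padded = np.where(feasible, cost, 1e12)
        ri, ci = linear_sum_assignment(padded)
        return [(int(i), int(j)) for i, j in zip(ri, ci) if feasible[i, j]]
    if solver != "anneal":
        raise ValueError(f"unknown solver {solver!r}")
    return _anneal_assignment(cost, rng)


def _anneal_assignment(
    cost: np.ndarray, rng: np.random.Generator, n_proposals: int = 10_000, cooling: float = 0.95
) -> list[tuple[int, int]]:
    """Simulated-annealing assignment with geometric cooling.

    State: a partial matching.  Moves swap the detections of two random
    tracks or toggle one link.  T0 = mean feasible cost; temperature decays
    by ``cooling`` every 100 proposals.
    """
    feasible = np.isfinite(cost)
    n_t, n_d = cost.shape
    # greedy initial state
    state: dict[int, int] = {}
    used_d: set[int] = set()
    order = np.argsort(np.where(feasible, cost, np.inf), axis=None)
    for flat in order:
        i, j = divmod(int(flat), n_d)
        if not feasible[i, j]:
            break
        if i in state or j in used_d:
            continue
        state[i] = j
        used_d.add(j)

    def total(s: dict[int, int]) -> float:
        # unlinked feasible tracks pay the maximum feasible cost as penalty,
        # pushing the matching toward completeness like the exact solver
        penalty = cost[feasible].max() if feasible.any() else 0.0
        linked = sum(cost[i, j] for i, j in s.items())
        n_possible = min(feasible.any(axis=1).sum(), feasible.any(axis=0).sum())
        return linked + penalty * (n_possible - len(s))

    energy = total(state)
    temp = float(cost[feasible].mean()) if feasible.any() else 1.0
    best, best_e = dict(state), energy
    for it in range(n_proposals):
        prop = dict(state)
        i = int(rng.integers(n_t))
        js = np.where(feasible[i])[0]
        if len(js) == 0:
            continue
        j = int(rng.choice(js))
        owner = next((k for k, v in prop.items() if v == j), None)
        if owner is not None and owner != i:
            if i in prop:
                prop[owner], prop[i] = prop[i], j
            else:
                del prop[owner]
                prop[i] = j
        elif prop.get(i) == j:
            del prop[i]
        else:
            prop[i] = j
        e = total(prop)
        if e <= energy or rng.random() < np.exp(-(e - energy) / max(temp, 1e-12)):
            state, energy = prop, e
            if e < best_e:
                best, best_e = dict(state), e
        if (it + 1) % 100 == 0:
            temp *= cooling
    return sorted(best.items())


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def compute_msd(
    track: Track,
    pixel_size_nm: float,
    frame_interval_s: float,
    min_length: int = 4,
) -> DiffusionResult | None:
    """Time-averaged MSD of one track, in um^2 versus lag seconds.

    Uses all position pairs separated by k frames for each lag k; includes z
    (3-D) when the track carries axial positions.  Tracks shorter than
    ``min_length`` are excluded (returns None).
    """
    n = len(track)
    if n < min_length:
        return None
    xy_um = np.stack([track.x, track.y], axis=1) * pixel_size_nm / 1000.0
    dim = 2
    if track.z is not None and np.isfinite(track.z).all():
        xy_um = np.hstack([xy_um, track.z[:, None] / 1000.0])
        dim = 3
    # time-average over all pairs at each lag; gaps (missing frames) are
    # handled by spreading positions on a dense frame grid with NaN holes
    frames = track.frames
    span = int(frames[-1] - frames[0]) + 1
    dense = np.full((span, xy_um.shape[1]), np.nan)
    dense[frames - frames[0]] = xy_um
    lags = []
    msd = []
    for k in range(1, span):
        d = dense[k:] - dense[:-k]
        valid = ~np.isnan(d).any(axis=1)
        if valid.any():
            lags.append(k * frame_interval_s)
            msd.append(float(np.mean(np.sum(d[valid] ** 2, axis=1))))
    return DiffusionResult(
        lag_s=np.asarray(lags),
        msd_um2=np.asarray(msd),
        dimensionality=dim,
        track_id=track.track_id,
    )


def fit_diffusion(result: DiffusionResult, n_points: int = 4) -> DiffusionResult:
    """Fit D from the first ``n_points`` MSD points (unweighted line, free origin).

    D = slope / (2 * dimensionality); a negative slope is clamped to D = 0
    and flagged.
    """
    if len(result.msd_um2) < n_points:
        raise ValueError(f"MSD has {len(result.msd_um2)} points, need >= {n_points}")
    tau = result.lag_s[:n_points]
    msd = result.msd_um2[:n_points]
    slope, _ = np.polyfit(tau, msd, 1)
    clamped = slope < 0
    D = 0.0 if clamped else float(slope / (2.0 * result.dimensionality))
    return DiffusionResult(
        lag_s=result.lag_s,
        msd_um2=result.msd_um2,
        dimensionality=result.dimensionality,
        D_um2_per_s=D,
        fit_points=n_points,
        clamped=bool(clamped),
        track_id=result.track_id,
    )


def species_split_diffusion(
    tracks: list[Track],
    pixel_size_nm: float,
    frame_interval_s: float,
    n_points: int = 4,
    min_length: int = 5,
) -> pd.DataFrame:
    """Per-species summary of diffusion coefficients.

    Returns one row per species label with the number of tracks, the median
    D and the interquartile range.  Tracks without a species label are
    summarized under "unassigned".
    """
    rows: dict[str, list[float]] = {}
    for tr in tracks:
        res = compute_msd(tr, pixel_size_nm, frame_interval_s, min_length=min_length)
        if res is None or len(res.msd_um2) < n_points:
            continue
        res = fit_diffusion(res, n_points=n_points)
        label = tr.species if tr.species else "unassigned"
        rows.setdefault(label, []).append(res.D_um2_per_s)
    out = []
    for label, ds in sorted(rows.items()):
        arr = np.asarray(ds)
        out.append(
            {
                "species": label,
                "n_tracks": len(arr),
                "D_median_um2_per_s": float(np.median(arr)),
                "D_iqr_um2_per_s": float(np.percentile(arr, 75) - np.percentile(arr, 25)),
            }
        )
    return pd.DataFrame(out, columns=["species", "n_tracks", "D_median_um2_per_s", "D_iqr_um2_per_s"])


def tracks_to_table(table: LocalizationTable, tracks: list[Track]) -> LocalizationTable:
    """Return a copy of the table with track_id filled in from the linking result."""
    df = table.df.copy()
    for tr in tracks:
        if tr.record_indices is not None:
            df.loc[tr.record_indices, "track_id"] = tr.track_id
    return LocalizationTable(df, channel_label=table.channel_label, metadata=dict(table.metadata))
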