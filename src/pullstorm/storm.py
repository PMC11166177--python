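"""dSTORM localization post-processing and super-resolved morphometry.

The processing chain is fixed in this order:

    trim initial frames -> localize (if starting from raw frames)
    -> drift estimation and correction (mean-shift modal displacement)
    -> localization merge (blinking events) -> density filter
    -> binary rendering -> connected-component morphometry

All coordinates are physical nanometres measured from the top-left corner of
the field of view; render bins are half-open ``[k·px, (k+1)·px)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .counting import detect_spots
from .synthetic import LOC_COLUMNS, FrameStack

__all__ = [
    "DriftTrack",
    "AggregateMorphology",
    "localize",
    "trim_initial_frames",
    "estimate_drift",
    "apply_drift",
    "merge_blinks",
    "filter_density",
    "render",
    "regularize_mask",
    "segment_and_measure",
    "process_table",
]

logger = logging.getLogger(__name__)

#: frames discarded at the start of every dSTORM acquisition (focus settling)
TRIM_FRAMES = 200


@dataclass
class DriftTrack:
    """Per-frame stage displacement relative to frame 0 (nm)."""

    dx: np.ndarray                     # nm, indexed by frame
    dy: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_modes: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if len(self.dx) and (abs(self.dx[0]) > 1e-9 or abs(self.dy[0]) > 1e-9):
            raise ValueError("drift track must be anchored at (0, 0) for frame 0")

    @property
    def n_frames(self) -> int:
        return len(self.dx)


@dataclass
class AggregateMorphology:
    """One segmented super-resolved aggregate."""

    label: int
    area: float            # µm²
    perimeter: float       # µm (Crofton 4-direction estimate)
    circularity: float     # 4π·area/perimeter², clamped to 1
    n_localizations: int
    centroid: tuple[float, float]   # nm


# ---------------------------------------------------------------------------
# localization from raw frames
# ---------------------------------------------------------------------------

def _gauss2d(params, xx, yy):
    a, x0, y0, sig, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig**2)) + b


def localize(stack: FrameStack, fit_window: int = 7, gain: float = 250.0) -> pd.DataFrame:
    """Sub-pixel localization of blinking emitters in every frame.

    Candidates are detected per frame with the wavelet filter and hybrid
    threshold used for diffraction-limited counting, then refined by a
    least-squares 2-D Gaussian fit in a ``fit_window``×``fit_window`` pixel
    window. The localization precision column follows the Thompson scaling
    ``sigma/sqrt(photons)`` with the background-corrected photon count.
    Diverged fits and fits leaving the window are dropped.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    px = stack.pixel_size
    half = fit_window // 2
    rows = []
    for f in range(stack.n_frames):
        frame = np.asarray(stack.data[f], dtype=float)
        cand = detect_spots(frame[None]).spots
        for _, c in cand.iterrows():
            cx, cy = int(c["x"]), int(c["y"])
            if (cx - half < 0 or cy - half < 0
                    or cx + half + 1 > frame.shape[1] or cy + half + 1 > frame.shape[0]):
                continue
            win = frame[cy - half: cy + half + 1, cx - half: cx + half + 1]
            yy, xx = np.mgrid[cy - half: cy + half + 1, cx - half: cx + half + 1]
            b0 = float(win.min())
            a0 = float(win.max() - b0)
            p0 = [a0, float(cx), float(cy), 1.3, b0]
            try:
                res = optimize.least_squares(
                    lambda p: (_gauss2d(p, xx, yy) - win).ravel(), p0,
                    bounds=([0, cx - half, cy - half, 0.3, -np.inf],
                            [np.inf, cx + half, cy + half, half, np.inf]),
                    max_nfev=200,
                )
            except Exception:
                logger.debug("fit failed at frame %d (%d, %d)", f, cx, cy)
                continue
            a, x0, y0, sig, b = res.x
            if not res.success and res.status <= 0:
                continue
            if a <= 0:
                continue
            photons = max(2 * math.pi * a * sig**2 / gain, 1.0)
            sigma_nm = sig * px
            # Thompson precision with background correction: the shot-noise
            # term plus the local-background term, in photon units
            sa2 = sigma_nm**2 + px**2 / 12.0
            bg_var = max(b, 0.0) / gain  # Poisson background variance, photons/px
            unc2 = sa2 / photons + 8 * math.pi * sa2**2 * bg_var / (px**2 * photons**2)
            rows.append(
                {
                    "frame": f,
                    "x": (x0 + 0.5) * px,
                    "y": (y0 + 0.5) * px,
                    "sigma": sigma_nm,
                    "intensity": photons,
                    "uncertainty": math.sqrt(unc2),
                }
            )
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


# ---------------------------------------------------------------------------
# table-level chain
# ---------------------------------------------------------------------------

def trim_initial_frames(table: pd.DataFrame, n: int = TRIM_FRAMES) -> pd.DataFrame:
    """Drop all localizations from frames < n (microscope focus settling)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0 or table.empty:
        return table.copy()
    return table[table["frame"] >= n].reset_index(drop=True)


def _mean_shift_mode(points: np.ndarray, bandwidth: float,
                     start: np.ndarray | None = None, tol: float = 1e-3,
                     max_iter: int = 500) -> np.ndarray:
    """Gaussian-kernel mean-shift mode of a 2-D point cloud.

    Starts from the median (or the given start) and anneals the bandwidth from
    3× down to the stated value, which makes the climb robust to the lumpy
    sampling structure of pairwise-displacement populations.
    """
    m = np.median(points, axis=0) if start is None else np.asarray(start, dtype=float)
    for h in (3 * bandwidth, bandwidth):
        for _ in range(max_iter):
            w = np.exp(-np.sum((points - m) ** 2, axis=1) / (2 * h**2))
            if w.sum() <= 0:
                break
            new = (points * w[:, None]).sum(axis=0) / w.sum()
            if np.hypot(*(new - m)) < tol:
                m = new
                break
            m = new
    return m


#: cap on pairwise displacement vectors fed to one mean-shift climb; above it
#: the population is subsampled (deterministically) — mode noise stays ~1 nm
MAX_PAIRS = 20000


def _pair_mode(pts: np.ndarray, ref_tree: cKDTree, ref: np.ndarray,
               shift: np.ndarray, radius: float, bandwidth: float) -> np.ndarray | None:
    """Modal displacement from ref to pts, pairing within a window centred on
    the expected shift (recentring avoids truncation bias under large drift)."""
    neigh = ref_tree.query_ball_point(pts - shift, radius)
    counts = np.fromiter((len(js) for js in neigh), dtype=int, count=len(neigh))
    if counts.sum() < 10:
        return None
    i_idx = np.repeat(np.arange(len(pts)), counts)
    j_idx = np.concatenate([js for js in neigh if js]).astype(int)
    disp = pts[i_idx] - ref[j_idx]
    if len(disp) > MAX_PAIRS:
        sel = np.random.default_rng(0).choice(len(disp), MAX_PAIRS, replace=False)
        disp = disp[sel]
    return _mean_shift_mode(disp, bandwidth, start=shift)


def estimate_drift(
    table: pd.DataFrame,
    n_frames: int,
    n_bins: int = 10,
    bandwidth: float = 20.0,
    search_radius: float = 200.0,
    min_per_bin: int = 50,
) -> DriftTrack:
    """Estimate stage drift by redundant modal inter-block displacements.

    Frames are split into ``n_bins`` equal intervals. A first sequential pass
    finds the modal displacement between consecutive bins by Gaussian-kernel
    mean-shift (bandwidth in nm) over pairwise displacement vectors within
    ``search_radius``. A second pass measures the modal displacement of every
    bin pair (pairing windows recentred on the first-pass estimate) and the
    per-bin drift is solved by least squares over all pair measurements —
    redundancy averages down the single-pair mode noise. Per-frame drift is
    linearly interpolated between bin midpoints (extrapolated with the edge
    segments) and anchored to (0, 0) at frame 0.
    """
    edges = np.linspace(0, n_frames, n_bins + 1)
    bins = [table[(table["frame"] >= lo) & (table["frame"] < hi)]
            for lo, hi in zip(edges[:-1], edges[1:])]
    for k, b in enumerate(bins):
        if len(b) < min_per_bin:
            raise ValueError(
                f"temporal bin {k} has only {len(b)} localizations "
                f"(need >= {min_per_bin}) — insufficient for drift correction")
    pts = [b[["x", "y"]].to_numpy() for b in bins]
    trees = [cKDTree(p) for p in pts]

    # sequential pass: consecutive-bin modes, accumulated
    rough = np.zeros((n_bins, 2))
    for k in range(1, n_bins):
        step = _pair_mode(pts[k], trees[k - 1], pts[k - 1], np.zeros(2),
                          search_radius, bandwidth)
        if step is None:
            raise ValueError(f"no displacement pairs within search radius for bin {k}")
        rough[k] = rough[k - 1] + step

    # redundant pass: all bin pairs, windows recentred on the rough estimate
    rows, rhs = [], []
    for k in range(n_bins):
        for l in range(k + 1, n_bins):
            m = _pair_mode(pts[l], trees[k], pts[k], rough[l] - rough[k],
                           search_radius, bandwidth)
            if m is None:
                continue
            row = np.zeros(n_bins)
            row[l], row[k] = 1.0, -1.0
            rows.append(row)
            rhs.append(m)
    A = np.asarray(rows)[:, 1:]  # drift of bin 0 pinned to 0
    rhs = np.asarray(rhs)
    sol_x, *_ = np.linalg.lstsq(A, rhs[:, 0], rcond=None)
    sol_y, *_ = np.linalg.lstsq(A, rhs[:, 1], rcond=None)
    modes = np.column_stack([np.concatenate([[0.0], sol_x]),
                             np.concatenate([[0.0], sol_y])])

    frames = np.arange(n_frames, dtype=float)
    midpoints = (edges[:-1] + edges[1:]) / 2
    dx = _interp_extrap(frames, midpoints, modes[:, 0])
    dy = _interp_extrap(frames, midpoints, modes[:, 1])
    dx -= dx[0]
    dy -= dy[0]
    return DriftTrack(dx, dy, bin_edges=edges, bin_modes=modes)


def _interp_extrap(x, xp, fp):
    """np.interp with linear extrapolation beyond the end points."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[lo] = fp[0] + slope_lo * (x[lo] - xp[0])
        y[hi] = fp[-1] + slope_hi * (x[hi] - xp[-1])
    return y


def apply_drift(table: pd.DataFrame, track: DriftTrack) -> pd.DataFrame:
    """Translate every localization by minus the drift of its frame."""
    if table.empty:
        return table.copy()
    frames = table["frame"].to_numpy().astype(int)
    if frames.max() >= track.n_frames:
        raise ValueError("drift track does not cover all frames in the table")
    out = table.copy()
    out["x"] = out["x"].to_numpy() - track.dx[frames]
    out["y"] = out["y"].to_numpy() - track.dy[frames]
    return out


def merge_blinks(table: pd.DataFrame, radius: float = 50.0, max_gap: int = 3) -> pd.DataFrame:
    """Collapse consecutive-frame localizations of one blinking event.

    Localizations within ``radius`` nm in consecutive frames (frame gaps up to
    ``max_gap`` allowed) are merged into a single row at their photon-weighted
    mean position; photons are summed and the merged row keeps the first frame
    of the chain.
    """
    if table.empty:
        return table.copy()
    tab = table.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = tab["frame"].to_numpy()
    xy = tab[["x", "y"]].to_numpy()

    chain_id = np.full(len(tab), -1, dtype=int)
    next_id = 0
    # active chains: id -> (last_frame, last_xy)
    active: dict[int, tuple[int, np.ndarray]] = {}
    for start in _frame_group_slices(frames):
        idx = start
        f = frames[idx[0]]
        # retire stale chains; gap = missing frames between chain members,
        # so a chain survives while f - last_frame <= max_gap + 1
        active = {cid: v for cid, v in active.items() if f - v[0] <= max_gap + 1}
        if active:
            ids = list(active)
            pos = np.array([active[c][1] for c in ids])
            tree = cKDTree(pos)
            for i in idx:
                d, j = tree.query(xy[i])
                if d <= radius:
                    chain_id[i] = ids[j]
                else:
                    chain_id[i] = next_id
                    next_id += 1
        else:
            for i in idx:
                chain_id[i] = next_id
                next_id += 1
        for i in idx:
            active[chain_id[i]] = (f, xy[i])

    tab["_chain"] = chain_id
    w = tab["intensity"].to_numpy()
    g = tab.groupby("_chain", sort=True)
    merged = pd.DataFrame(
        {
            "frame": g["frame"].min(),
            "x": g.apply(lambda d: np.average(d["x"], weights=d["intensity"]),
                         include_groups=False),
            "y": g.apply(lambda d: np.average(d["y"], weights=d["intensity"]),
                         include_groups=False),
            "sigma": g["sigma"].mean(),
            "intensity": g["intensity"].sum(),
            "uncertainty": g["uncertainty"].mean(),
        }
    ).reset_index(drop=True)
    return merged.sort_values("frame", kind="stable").reset_index(drop=True)[LOC_COLUMNS]


def _frame_group_slices(frames: np.ndarray):
    """Yield index arrays of equal-frame runs of a sorted frame vector."""
    start = 0
    for i in range(1, len(frames) + 1):
        if i == len(frames) or frames[i] != frames[start]:
            yield np.arange(start, i)
            start = i


def filter_density(table: pd.DataFrame, radius: float = 50.0, min_neighbors: int = 5) -> pd.DataFrame:
    """Remove localizations with fewer than ``min_neighbors`` spatial
    neighbours within ``radius`` nm (all frames pooled) — isolated points are
    treated as false-positive signals."""
    if table.empty:
        return table.copy()
    xy = table[["x", "y"]].to_numpy()
    tree = cKDTree(xy)
    counts = np.array([len(n) - 1 for n in tree.query_ball_point(xy, radius)])
    return table[counts >= min_neighbors].reset_index(drop=True)


def render(table: pd.DataFrame, render_px: float = 10.0,
           fov_side_nm: float | None = None) -> np.ndarray:
    """Binarized 2-D localization histogram at ``render_px`` nm bins.

    Bins are half-open with origin at the FoV top-left corner; a pixel is set
    when at least one localization falls in it.
    """
    if render_px <= 0:
        raise ValueError("render_px must be positive")
    if fov_side_nm is None:
        fov_side_nm = float(max(table["x"].max(), table["y"].max())) + render_px if len(table) else render_px
    n = int(math.ceil(fov_side_nm / render_px))
    raster = np.zeros((n, n), dtype=bool)
    if len(table):
        cols = np.floor(table["x"].to_numpy() / render_px).astype(int)
        rows = np.floor(table["y"].to_numpy() / render_px).astype(int)
        ok = (cols >= 0) & (cols < n) & (rows >= 0) & (rows < n)
        raster[rows[ok], cols[ok]] = True
    return raster


def regularize_mask(raster: np.ndarray, close_px: int = 3, erode_px: int = 2) -> np.ndarray:
    """Morphological closing then erosion of the binarized rendering.

    A binarized localization histogram of a finitely sampled structure is a
    dotted, ragged mask whose Crofton perimeter grossly over-estimates the
    true boundary length, collapsing the circularity of genuinely round
    objects. Closing with a disc of ``close_px`` rendering pixels bridges the
    gaps between localizations; the subsequent erosion by ``erode_px`` removes
    most of the dilation bias so that areas stay close to the sampled support.
    Set both to 0 to measure the raw mask.
    """
    out = np.asarray(raster, dtype=bool)
    if close_px > 0:
        out = morphology.closing(out, morphology.disk(close_px))
    if erode_px > 0:
        out = morphology.erosion(out, morphology.disk(erode_px))
    return out


def segment_and_measure(
    raster: np.ndarray,
    table: pd.DataFrame,
    render_px: float = 10.0,
    min_locs: int = 10,
) -> list[AggregateMorphology]:
    """Morphometry of 8-connected components of the binary super-resolved image.

    Area is pixel count × render_px² (reported in µm²); perimeter uses the
    Crofton 4-direction estimate; circularity = 4π·area/perimeter² clamped to
    1. Components with fewer than ``min_locs`` assigned localizations are
    discarded as under-sampled.
    """
    labels = measure.label(raster, connectivity=2)
    if len(table):
        cols = np.floor(table["x"].to_numpy() / render_px).astype(int)
        rows = np.floor(table["y"].to_numpy() / render_px).astype(int)
        ok = (cols >= 0) & (cols < labels.shape[1]) & (rows >= 0) & (rows < labels.shape[0])
        loc_labels = np.zeros(len(table), dtype=int)
        loc_labels[ok] = labels[rows[ok], cols[ok]]
        loc_counts = np.bincount(loc_labels, minlength=labels.max() + 1)
    else:
        loc_counts = np.zeros(labels.max() + 1, dtype=int)

    out = []
    for rp in measure.regionprops(labels):
        n_locs = int(loc_counts[rp.label]) if rp.label < len(loc_counts) else 0
        if n_locs < min_locs:
            continue
        area_um2 = rp.area * render_px**2 / 1e6
        perim_um = rp.perimeter_crofton * render_px / 1e3
        circ = 4 * math.pi * area_um2 / perim_um**2 if perim_um > 0 else 1.0
        cy, cx = rp.centroid
        out.append(
            AggregateMorphology(
                label=int(rp.label),
                area=area_um2,
                perimeter=perim_um,
                circularity=min(circ, 1.0),
                n_localizations=n_locs,
                centroid=((cx + 0.5) * render_px, (cy + 0.5) * render_px),
            )
        )
    return out


def process_table(
    table: pd.DataFrame,
    n_frames: int,
    fov_side_nm: float,
    trim: int = TRIM_FRAMES,
    drift_bins: int = 10,
    drift_bandwidth: float = 20.0,
    merge_radius: float = 50.0,
    merge_max_gap: int = 3,
    density_radius: float = 50.0,
    density_min_neighbors: int = 5,
    render_px: float = 10.0,
    min_locs: int = 10,
    close_px: int = 3,
    erode_px: int = 2,
    correct_drift: bool = True,
) -> tuple[list[AggregateMorphology], pd.DataFrame]:
    """Full table-level chain: trim → drift → merge → density filter →
    render → mask regularization → measure. Returns the morphologies and the
    processed table."""
    tab = trim_initial_frames(table, trim)
    if correct_drift:
        track = estimate_drift(tab, n_frames, n_bins=drift_bins, bandwidth=drift_bandwidth)
        tab = apply_drift(tab, track)
    tab = merge_blinks(tab, radius=merge_radius, max_gap=merge_max_gap)
    tab = filter_density(tab, radius=density_radius, min_neighbors=density_min_neighbors)
    raster = render(tab, render_px, fov_side_nm)
    raster = regularize_mask(raster, close_px=close_px, erode_px=erode_px)
    morphs = segment_and_measure(raster, tab, render_px, min_locs)
    return morphs, tab
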