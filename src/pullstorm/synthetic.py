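"""Ground-truthed synthetic data for the SiMPull / dSTORM analysis chain.

Every downstream stage of the package (diffraction-limited spot counting,
localization post-processing, morphometry, cohort statistics) is exercised
against data produced here, with known truth: immobilized fluorescent spots
over camera noise, blinking emitters decorating round or fibrillar aggregate
footprints with finite localization precision and slow stage drift, and
two-group cohorts with a prescribed contrast in the alpha-synuclein/amyloid-beta
count ratio and in the weight of the large/fibrillar amyloid-beta
subpopulation.

All randomness flows through an explicit ``numpy.random.Generator`` derived
from an integer seed; identical seeds reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "AggregateTruth",
    "BlinkParams",
    "CohortSpec",
    "FrameStack",
    "make_disc",
    "make_fibril",
    "render_spots",
    "simulate_dl_stack",
    "simulate_storm_table",
    "simulate_cohort",
    "simulate_cohort_summaries",
]

#: column order of every localization table in the package (all lengths in nm)
LOC_COLUMNS = ["frame", "x", "y", "sigma", "intensity", "uncertainty"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging and camera parameters of the TIRF setup being emulated.

    Defaults follow the acquisition protocol: 103.5 nm pixels, ~2500 µm²
    fields of view, 50-frame diffraction-limited stacks (16 FoVs per target)
    and 8000-frame dSTORM stacks (4 FoVs per target), an EMCCD-style linear
    camera with 250 ADU/photon gain.
    """

    pixel_size: float = 103.5       # nm / pixel
    fov_side: int = 483             # pixels; 483 * 103.5 nm = 49.99 µm -> 2499 µm²
    n_frames_dl: int = 50
    n_frames_storm: int = 8000
    n_fov_dl: int = 16
    n_fov_storm: int = 4
    psf_sigma: float = 130.0        # nm
    camera_gain: float = 250.0      # ADU / photon
    camera_offset: float = 100.0    # ADU baseline
    read_noise: float = 50.0        # ADU rms

    def __post_init__(self) -> None:
        for name in ("fov_side", "n_frames_dl", "n_frames_storm", "n_fov_dl", "n_fov_storm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.read_noise < 0 or self.camera_gain <= 0:
            raise ValueError("invalid camera model parameters")

    @property
    def fov_side_nm(self) -> float:
        return self.fov_side * self.pixel_size

    @property
    def fov_area_um2(self) -> float:
        return (self.fov_side_nm / 1000.0) ** 2


@dataclass
class AggregateTruth:
    """One simulated aggregate: footprint class, geometry and emitter decoration.

    ``true_circularity`` is the analytic 4πA/P² of the footprint; fibrillar
    footprints are constructed with circularity < 0.4 and round ones >= 0.4,
    matching the morphology threshold the analysis applies downstream.
    """

    shape_kind: Literal["round", "fibrillar"]
    centroid: tuple[float, float]          # (x, y) nm from FoV top-left corner
    true_area: float                       # µm²
    true_circularity: float
    emitter_positions: np.ndarray          # (n, 2) array of (x, y) nm
    brightness: float = 80.0               # peak photons/frame in DL imaging

    def __post_init__(self) -> None:
        self.emitter_positions = np.atleast_2d(np.asarray(self.emitter_positions, dtype=float))
        if not (0 < self.true_circularity <= 1):
            raise ValueError("true_circularity must lie in (0, 1]")
        if self.shape_kind == "fibrillar" and self.true_circularity >= 0.4:
            raise ValueError("fibrillar aggregates must have circularity < 0.4")
        if self.shape_kind == "round" and self.true_circularity < 0.4:
            raise ValueError("round aggregates must have circularity >= 0.4")


@dataclass(frozen=True)
class BlinkParams:
    """Two-state blinking model for dSTORM emitters.

    Each emitter fires ``~Poisson(mean_bursts)`` bursts at uniform times; a
    burst stays on for ``1 + Geometric`` frames (mean ``mean_on_frames``),
    producing one localization per on-frame, jittered by an isotropic Gaussian
    localization error (default 20 nm, the spatial resolution of the assay).
    False localizations appear uniformly at ``background_per_um2_frame``.
    """

    mean_bursts: float = 3.0
    mean_on_frames: float = 2.0
    loc_error_nm: float = 20.0
    mean_photons: float = 500.0
    background_per_um2_frame: float = 1e-4

    def __post_init__(self) -> None:
        if self.loc_error_nm < 0:
            raise ValueError("localization error sd must be non-negative")
        if self.background_per_um2_frame < 0:
            raise ValueError("background density must be non-negative")
        if self.mean_bursts < 0 or self.mean_on_frames < 1:
            raise ValueError("invalid blinking parameters")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort generative model (Parkinson's disease vs control).

    ``ratio_location`` sets the group-level median of the per-participant
    αS/Aβ count ratio (default 2.2-fold PD/control contrast); ``ratio_dispersion``
    is the log-scale sd of the participant ratios (0.7 corresponds to a
    ratio-alone ROC AUC of ≈0.79 between the groups). ``fibril_weight`` is the
    group-level mean fraction of large/fibrillar Aβ aggregates, with
    participant weights Beta-distributed at concentration ``weight_concentration``
    (30 yields a simulated morphology-alone ROC AUC of ≈0.76 once binomial
    per-aggregate counting noise is included).
    """

    n_per_group: int = 10
    ratio_location: dict = field(default_factory=lambda: {"PD": 1.056, "control": 0.48})
    ratio_dispersion: float = 0.7
    fibril_weight: dict = field(default_factory=lambda: {"PD": 0.12, "control": 0.06})
    weight_concentration: float = 30.0
    counts_rate: float = 12.0            # mean Aβ aggregates per DL FoV
    storm_aggregates_per_fov: float = 30.0
    participant_log_sd: float = 0.3      # log-normal participant abundance factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g, w in self.fibril_weight.items():
            if not 0 <= w <= 1:
                raise ValueError(f"fibril_weight[{g}] must lie in [0, 1]")
        if self.counts_rate < 0 or self.storm_aggregates_per_fov < 0:
            raise ValueError("rates must be non-negative")
        if self.ratio_dispersion < 0 or self.participant_log_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.weight_concentration <= 0:
            raise ValueError("weight_concentration must be positive")


@dataclass
class FrameStack:
    """Time-ordered stack of 2-D camera frames with physical pixel size."""

    data: np.ndarray         # (n_frames, h, w)
    pixel_size: float        # nm / pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be (frames, h, w)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


# ---------------------------------------------------------------------------
# aggregate footprints
# ---------------------------------------------------------------------------

#: emitters per nm² of aggregate footprint (≈1 fluorophore per 14 nm grid)
EMITTER_DENSITY = 1.0 / 200.0


def _sample_emitters(n: int, inside, bbox, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly inside a footprint."""
    (x0, x1), (y0, y1) = bbox
    out = []
    need = n
    while need > 0:
        cand = np.column_stack([
            rng.uniform(x0, x1, size=4 * need),
            rng.uniform(y0, y1, size=4 * need),
        ])
        keep = cand[inside(cand)]
        out.append(keep[:need])
        need -= len(keep[:need])
    return np.concatenate(out) if out else np.empty((0, 2))


def make_disc(
    centroid: tuple[float, float],
    area_um2: float,
    rng: np.random.Generator,
    emitter_density: float = EMITTER_DENSITY,
    brightness: float = 80.0,
) -> AggregateTruth:
    """Round aggregate: a disc of the requested area, circularity 1."""
    area_nm2 = area_um2 * 1e6
    radius = math.sqrt(area_nm2 / math.pi)
    n = max(4, int(rng.poisson(area_nm2 * emitter_density)))
    cx, cy = centroid

    def inside(p):
        return (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2 <= radius**2

    emitters = _sample_emitters(n, inside, ((cx - radius, cx + radius), (cy - radius, cy + radius)), rng)
    return AggregateTruth("round", centroid, area_um2, 1.0, emitters, brightness)


def make_fibril(
    centroid: tuple[float, float],
    area_um2: float,
    rng: np.random.Generator,
    aspect: float | None = None,
    emitter_density: float = EMITTER_DENSITY,
    brightness: float = 80.0,
) -> AggregateTruth:
    """Fibrillar aggregate: a randomly oriented rectangle with aspect >= 6.

    For a w×l rectangle circularity is π·(l/w)/(1+l/w)², below 0.4 for any
    aspect ratio above ≈5.6; aspect ratios are drawn in [6, 12].
    """
    if aspect is None:
        aspect = rng.uniform(6.0, 12.0)
    if aspect < 6.0:
        raise ValueError("fibril aspect ratio must be >= 6 to keep circularity < 0.4")
    area_nm2 = area_um2 * 1e6
    width = math.sqrt(area_nm2 / aspect)
    length = width * aspect
    circ = 4 * math.pi * area_nm2 / (2 * (width + length)) ** 2
    theta = rng.uniform(0, math.pi)
    c, s = math.cos(theta), math.sin(theta)
    cx, cy = centroid

    def inside(p):
        dx, dy = p[:, 0] - cx, p[:, 1] - cy
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)

    half = length / 2
    n = max(4, int(rng.poisson(area_nm2 * emitter_density)))
    emitters = _sample_emitters(n, inside, ((cx - half, cx + half), (cy - half, cy + half)), rng)
    return AggregateTruth("fibrillar", centroid, area_um2, circ, emitters, brightness)


# ---------------------------------------------------------------------------
# diffraction-limited stacks
# ---------------------------------------------------------------------------

def render_spots(truth: Sequence[AggregateTruth], acq: AcquisitionParams) -> np.ndarray:
    """Noise-free expected photon image of immobile diffraction-limited spots.

    Each aggregate contributes one 2-D Gaussian of width ``psf_sigma`` centred
    on its centroid with peak value ``brightness`` (photons); pixel (r, c) is
    sampled at its centre ((c+0.5)·px, (r+0.5)·px) nm.
    """
    side = acq.fov_side
    px = acq.pixel_size
    img = np.zeros((side, side), dtype=float)
    sig_px = acq.psf_sigma / px
    win = int(math.ceil(6 * sig_px))
    for agg in truth:
        x_nm, y_nm = agg.centroid
        cx, cy = x_nm / px - 0.5, y_nm / px - 0.5  # pixel-centre coordinates
        c0, c1 = max(0, int(cx) - win), min(side, int(cx) + win + 2)
        r0, r1 = max(0, int(cy) - win), min(side, int(cy) + win + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        gx = np.exp(-((cols - cx) ** 2) / (2 * sig_px**2))
        gy = np.exp(-((rows - cy) ** 2) / (2 * sig_px**2))
        img[r0:r1, c0:c1] += agg.brightness * np.outer(gy, gx)
    return img


def simulate_dl_stack(
    truth: Sequence[AggregateTruth],
    acq: AcquisitionParams,
    seed: int,
    camera_noise: bool = True,
    background_photons: float = 0.0,
) -> tuple[FrameStack, pd.DataFrame]:
    """Diffraction-limited 50-frame stack of immobilized aggregates.

    Per-pixel counts follow the linear camera model
    ``Poisson(photons)·gain + offset + N(0, read_noise)``. Returns the stack
    and a ground-truth spot table; centroid pairs closer than one pixel are
    flagged unresolvable.

    With ``camera_noise=False`` the frames are the noise-free photon image
    (identical on every frame, no gain or offset applied).
    """
    rng = np.random.default_rng(seed)
    for agg in truth:
        x, y = agg.centroid
        if not (0 <= x <= acq.fov_side_nm and 0 <= y <= acq.fov_side_nm):
            raise ValueError("aggregate centroid outside the field of view")
    photons = render_spots(truth, acq) + background_photons
    frames = np.empty((acq.n_frames_dl, acq.fov_side, acq.fov_side), dtype=float)
    if camera_noise:
        for f in range(acq.n_frames_dl):
            shot = rng.poisson(photons).astype(float)
            frame = shot * acq.camera_gain + acq.camera_offset
            if acq.read_noise > 0:
                frame = frame + rng.normal(0.0, acq.read_noise, size=frame.shape)
            frames[f] = np.clip(frame, 0, None)
    else:
        frames[:] = photons

    px = acq.pixel_size
    xs = np.array([a.centroid[0] for a in truth])
    ys = np.array([a.centroid[1] for a in truth])
    resolvable = np.ones(len(truth), dtype=bool)
    for i in range(len(truth)):
        for j in range(i + 1, len(truth)):
            if math.hypot(xs[i] - xs[j], ys[i] - ys[j]) < px:
                resolvable[i] = resolvable[j] = False
    spots = pd.DataFrame(
        {
            "x_nm": xs,
            "y_nm": ys,
            "x_px": xs / px - 0.5,
            "y_px": ys / px - 0.5,
            "brightness": [a.brightness for a in truth],
            "shape_kind": [a.shape_kind for a in truth],
            "resolvable": resolvable,
        }
    )
    return FrameStack(frames, px), spots


# ---------------------------------------------------------------------------
# dSTORM localization streams
# ---------------------------------------------------------------------------

def simulate_storm_table(
    truth: Sequence[AggregateTruth],
    acq: AcquisitionParams,
    drift: tuple[float, float] = (0.0, 0.0),
    blink: BlinkParams | None = None,
    seed: int = 0,
    random_walk_sd: float = 0.0,
) -> tuple[pd.DataFrame, list[AggregateTruth]]:
    """Blinking-emitter localization stream over a drifting stage.

    ``drift`` is the linear stage drift in nm per frame; an optional random
    walk (per-frame step sd ``random_walk_sd``) is added on top. Every
    localization of an emitter active at frame f is the emitter position,
    translated by the cumulative drift at f and jittered by the localization
    error. Uniform false localizations are appended at the configured
    background density. The returned table is sorted by frame.
    """
    blink = blink or BlinkParams()
    rng = np.random.default_rng(seed)
    nf = acq.n_frames_storm

    drift_x = np.arange(nf) * drift[0]
    drift_y = np.arange(nf) * drift[1]
    if random_walk_sd > 0:
        drift_x = drift_x + np.concatenate([[0], np.cumsum(rng.normal(0, random_walk_sd, nf - 1))])
        drift_y = drift_y + np.concatenate([[0], np.cumsum(rng.normal(0, random_walk_sd, nf - 1))])

    frames, xs, ys, photons = [], [], [], []
    for agg in truth:
        for ex, ey in agg.emitter_positions:
            n_bursts = rng.poisson(blink.mean_bursts)
            for _ in range(n_bursts):
                start = rng.integers(0, nf)
                length = int(rng.geometric(1.0 / blink.mean_on_frames))
                for f in range(start, min(start + length, nf)):
                    frames.append(f)
                    xs.append(ex + drift_x[f])
                    ys.append(ey + drift_y[f])
                    photons.append(rng.gamma(2.0, blink.mean_photons / 2.0))

    # uniform false localizations over the whole acquisition
    n_bg = rng.poisson(blink.background_per_um2_frame * acq.fov_area_um2 * nf)
    if n_bg:
        frames.extend(rng.integers(0, nf, n_bg).tolist())
        xs.extend(rng.uniform(0, acq.fov_side_nm, n_bg).tolist())
        ys.extend(rng.uniform(0, acq.fov_side_nm, n_bg).tolist())
        photons.extend(rng.gamma(2.0, blink.mean_photons / 2.0, n_bg).tolist())

    frames = np.asarray(frames, dtype=int)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    photons = np.asarray(photons, dtype=float)
    if blink.loc_error_nm > 0 and len(xs):
        xs = xs + rng.normal(0, blink.loc_error_nm, len(xs))
        ys = ys + rng.normal(0, blink.loc_error_nm, len(ys))

    table = pd.DataFrame(
        {
            "frame": frames,
            "x": xs,
            "y": ys,
            "sigma": np.full(len(xs), acq.psf_sigma),
            "intensity": photons,
            "uncertainty": np.full(len(xs), max(blink.loc_error_nm, 1.0)),
        }
    )
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)
    return table, list(truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: marginal size distributions of the two morphology classes (log-normal,
#: medians matching the observed medians: round ≈ 0.005 µm², fibrillar ≈ 0.05 µm²)
ROUND_AREA_MEDIAN_UM2 = 0.005
ROUND_AREA_LOG_SD = 0.8
FIBRIL_AREA_MEDIAN_UM2 = 0.05
FIBRIL_AREA_LOG_SD = 0.5


def _draw_participant_params(spec: CohortSpec, group: str, rng: np.random.Generator):
    abundance = rng.lognormal(0.0, spec.participant_log_sd)
    ratio = rng.lognormal(math.log(spec.ratio_location[group]), spec.ratio_dispersion)
    w = spec.fibril_weight[group]
    k = spec.weight_concentration
    fibril_p = rng.beta(w * k, (1 - w) * k)
    return abundance, ratio, fibril_p


def _draw_morphologies(n: int, fibril_p: float, rng: np.random.Generator) -> pd.DataFrame:
    """Per-aggregate (shape class, area, circularity) draws for one participant."""
    is_fib = rng.random(n) < fibril_p
    area = np.where(
        is_fib,
        rng.lognormal(math.log(FIBRIL_AREA_MEDIAN_UM2), FIBRIL_AREA_LOG_SD, n),
        rng.lognormal(math.log(ROUND_AREA_MEDIAN_UM2), ROUND_AREA_LOG_SD, n),
    )
    aspect = rng.uniform(6.0, 12.0, n)
    circ_fib = np.pi * aspect / (1 + aspect) ** 2
    circ_round = np.clip(rng.normal(0.85, 0.12, n), 0.4, 1.0)
    circ = np.where(is_fib, circ_fib, circ_round)
    return pd.DataFrame({"shape_kind": np.where(is_fib, "fibrillar", "round"),
                         "area_um2": area, "circularity": circ})


def simulate_cohort_summaries(spec: CohortSpec) -> pd.DataFrame:
    """Fast participant-level cohort draw (no images, no localization streams).

    Returns one row per participant with observed counts per target, the
    count ratio, per-aggregate-derived thresholded proportions (area > 0.03 µm²,
    circularity < 0.4, both) and the combined discriminator. The generative
    model is identical to the one the raw-data generator uses; this surface is
    meant for statistical calibration experiments that need hundreds of
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    acq = AcquisitionParams()
    for group in ("PD", "control"):
        for i in range(spec.n_per_group):
            abundance, ratio, fibril_p = _draw_participant_params(spec, group, rng)
            lam_ab = spec.counts_rate * abundance * acq.n_fov_dl
            count_ab = rng.poisson(lam_ab)
            count_as = rng.poisson(lam_ab * ratio)
            n_agg = rng.poisson(spec.storm_aggregates_per_fov * acq.n_fov_storm)
            morph = _draw_morphologies(max(n_agg, 1), fibril_p, rng)
            big = morph["area_um2"] > 0.03
            fib = morph["circularity"] < 0.4
            rows.append(
                {
                    "participant_id": f"{group}-{i:02d}",
                    "group": group,
                    "count_asyn": count_as,
                    "count_abeta": count_ab,
                    "ratio": count_as / count_ab if count_ab else np.nan,
                    "prop_area": big.mean(),
                    "prop_circ": fib.mean(),
                    "prop_both": (big & fib).mean(),
                    "true_ratio": ratio,
                    "true_fibril_weight": fibril_p,
                }
            )
    df = pd.DataFrame(rows, columns=[
        "participant_id", "group", "count_asyn", "count_abeta", "ratio",
        "prop_area", "prop_circ", "prop_both", "true_ratio", "true_fibril_weight",
    ])
    df["discriminator"] = df["ratio"] * df["prop_both"]
    return df


@dataclass
class ParticipantData:
    """Raw simulated data bundle for one participant."""

    participant_id: str
    group: str
    dl_stacks: dict          # target -> list[FrameStack]
    dl_truth: dict           # target -> list[pd.DataFrame]
    storm_tables: dict       # target -> list[pd.DataFrame]
    storm_truth: dict        # target -> list[list[AggregateTruth]]
    summary_truth: dict      # generative parameters used for this participant


def _place_aggregates(n: int, fibril_p: float, acq: AcquisitionParams,
                      rng: np.random.Generator) -> list[AggregateTruth]:
    margin = 2000.0  # nm, keep shapes inside the FoV
    aggs = []
    morph = _draw_morphologies(max(n, 0), fibril_p, rng) if n else None
    for k in range(n):
        centroid = tuple(rng.uniform(margin, acq.fov_side_nm - margin, 2))
        if morph.iloc[k]["shape_kind"] == "fibrillar":
            aggs.append(make_fibril(centroid, float(morph.iloc[k]["area_um2"]), rng))
        else:
            aggs.append(make_disc(centroid, float(morph.iloc[k]["area_um2"]), rng))
    return aggs


def simulate_cohort(
    spec: CohortSpec,
    acq: AcquisitionParams | None = None,
    blink: BlinkParams | None = None,
    drift_per_frame: tuple[float, float] = (0.0125, 0.0),
    targets: Sequence[str] = ("asyn", "abeta"),
) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Full raw-data cohort: DL stacks and dSTORM streams per participant.

    Per participant and target, ``acq.n_fov_dl`` diffraction-limited stacks
    with Poisson spot counts (rate ``counts_rate`` for Aβ, scaled by the
    participant ratio for αS and by a log-normal participant abundance factor
    for both) and ``acq.n_fov_storm`` dSTORM fields whose aggregate shapes are
    drawn from the group's round/fibrillar mixture. Returns the bundles and
    the ground-truth participant summary table.
    """
    acq = acq or AcquisitionParams()
    blink = blink or BlinkParams()
    rng = np.random.default_rng(spec.seed)
    participants, rows = [], []
    for group in ("PD", "control"):
        for i in range(spec.n_per_group):
            pid = f"{group}-{i:02d}"
            abundance, ratio, fibril_p = _draw_participant_params(spec, group, rng)
            dl_stacks, dl_truth, storm_tables, storm_truth = {}, {}, {}, {}
            true_counts = {}
            for target in targets:
                rate = spec.counts_rate * abundance
                if target == "asyn":
                    rate *= ratio
                stacks, truths = [], []
                total = 0
                for _ in range(acq.n_fov_dl):
                    n_spots = rng.poisson(rate)
                    total += n_spots
                    margin = 5 * acq.psf_sigma
                    spots = [
                        make_disc(tuple(rng.uniform(margin, acq.fov_side_nm - margin, 2)),
                                  ROUND_AREA_MEDIAN_UM2, rng)
                        for _ in range(n_spots)
                    ]
                    st, tr = simulate_dl_stack(spots, acq, seed=int(rng.integers(2**31)))
                    stacks.append(st)
                    truths.append(tr)
                dl_stacks[target] = stacks
                dl_truth[target] = truths
                true_counts[target] = total

                tabs, ttruths = [], []
                # the fibrillar subpopulation contrast is an Aβ phenomenon
                p_fib = fibril_p if target == "abeta" else spec.fibril_weight["control"]
                for _ in range(acq.n_fov_storm):
                    n_agg = rng.poisson(spec.storm_aggregates_per_fov)
                    aggs = _place_aggregates(n_agg, p_fib, acq, rng)
                    tab, tru = simulate_storm_table(
                        aggs, acq, drift=drift_per_frame, blink=blink,
                        seed=int(rng.integers(2**31)))
                    tabs.append(tab)
                    ttruths.append(tru)
                storm_tables[target] = tabs
                storm_truth[target] = ttruths

            summary = {
                "participant_id": pid,
                "group": group,
                "true_ratio": ratio,
                "true_fibril_weight": fibril_p,
                "count_asyn": true_counts.get("asyn", 0),
                "count_abeta": true_counts.get("abeta", 0),
            }
            rows.append(summary)
            participants.append(ParticipantData(pid, group, dl_stacks, dl_truth,
                                                storm_tables, storm_truth, summary))
    return participants, pd.DataFrame(rows)
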