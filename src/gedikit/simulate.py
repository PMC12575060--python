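"""Synthetic-data generator with known ground truth.

Emulates the four experimental inputs the quantification pipelines consume:

* ratiometric live/dead biosensor time-lapse stacks (red morphology marker,
  green calcium reporter) with dose- and sEV-dose-dependent exponential
  death hazards, a step-like green surge at death, and detachment after a
  configurable delay;
* DNA-damage foci images (live 53BP1-style red-channel puncta or fixed
  γ-H2AX-style green puncta over DAPI nuclei) with Poisson focus counts
  following an induction-plus-exponential-repair rate law;
* flow-cytometry event tables with lognormal stained/unstained populations;
* clonogenic colony images whose areas grow exponentially frame to frame.

Every stochastic draw comes from a single seeded generator in a fixed,
documented order, so outputs are bit-identical for a fixed config.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stack import ImageStack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlacementError",
    "simulate_timelapse",
    "simulate_foci_images",
    "simulate_flow_events",
    "simulate_colony_series",
]

#: reference radiation dose (Gy) at which ``base_hazard_per_h`` applies
REFERENCE_DOSE_GY = 8.0

#: sEV dose levels used in the protection experiments (vesicles per cell)
SEV_DOSE_LEVELS = (2500, 5000, 15000)


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails within the retry bound."""


@dataclass
class SimulationConfig:
    """Parameters of a simulated experiment.

    The defaults describe the live-cell death assay: cells imaged at 0, 6,
    12 and 18 h post-irradiation after an 8 Gy dose, with a baseline death
    hazard of 0.1/h at the 8 Gy reference and live/dead GEDI-ratio medians
    of 0.5 and 2.0 (geometric mean 1, the operating classification
    threshold).  ``protection_factor`` multiplies the radiation-driven
    hazard; values below 1 model sEV-mediated protection.
    """

    seed: int = 0
    fov_shape: tuple[int, int] = (512, 512)
    n_cells: int = 100
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    group: str = "control"

    # death model
    radiation_dose_Gy: float = 8.0
    sev_dose_per_cell: int = 0
    base_hazard_per_h: float = 0.1
    spontaneous_hazard_per_h: float = 0.002
    protection_factor: float = 1.0
    detach_delay_h: float = 4.0

    # ratiometric reporter
    live_ratio_median: float = 0.5
    dead_ratio_median: float = 2.0
    ratio_sigma_log: float = 0.25

    # rendering
    cell_radius_px: float = 8.0
    red_amplitude: float = 200.0
    amplitude_sigma_log: float = 0.2
    motion_sd_px: float = 2.0
    background_offset: float = 10.0
    noise_gaussian_sd: float = 2.0
    noise_poisson_scale: float = 0.5

    # DNA-damage foci model
    puncta_baseline_rate: float = 1.0
    puncta_induction_per_Gy: float = 3.0
    puncta_repair_halflife_h: float = 4.0
    puncta_amplitude_fold: float = 12.0

    # colony model
    n_colonies: int = 12
    colony_radius_px: float = 10.0
    colony_radius_sigma_log: float = 0.15
    colony_growth_per_frame: float = 0.35

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp.size == 0:
            raise ValueError("at least one timepoint is required")
        if tp.size > 1 and not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints_h must be strictly increasing")
        for name in (
            "radiation_dose_Gy",
            "base_hazard_per_h",
            "spontaneous_hazard_per_h",
            "detach_delay_h",
            "ratio_sigma_log",
            "motion_sd_px",
            "noise_gaussian_sd",
            "noise_poisson_scale",
            "puncta_baseline_rate",
            "puncta_induction_per_Gy",
            "colony_growth_per_frame",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.protection_factor <= 1:
            raise ValueError("protection_factor must be in (0, 1]")
        if self.dead_ratio_median <= self.live_ratio_median:
            raise ValueError("dead_ratio_median must exceed live_ratio_median")
        if self.cell_radius_px <= 0 or self.colony_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.puncta_repair_halflife_h <= 0:
            raise ValueError("puncta_repair_halflife_h must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_h)

    def effective_hazard_per_h(self) -> float:
        """Death hazard: radiation term linear in dose relative to 8 Gy,
        scaled by the protection factor, plus a spontaneous rate."""
        radiation = (
            self.base_hazard_per_h
            * self.protection_factor
            * self.radiation_dose_Gy
            / REFERENCE_DOSE_GY
        )
        return radiation + self.spontaneous_hazard_per_h

    def puncta_rate(self, t_h: float) -> float:
        """Mean foci per cell at ``t_h`` hours post-irradiation.

        ``baseline + induction * dose * 2^(-t / repair half-life)`` for
        t > 0.  The frame at t = 0 is imaged at irradiation, before any
        focus has had time to assemble, so it carries the baseline rate
        only — counts then peak at the first post-irradiation frame and
        decay back to baseline as breaks are repaired.
        """
        if t_h <= 0:
            return self.puncta_baseline_rate
        induced = (
            self.puncta_induction_per_Gy
            * self.radiation_dose_Gy
            * 2.0 ** (-t_h / self.puncta_repair_halflife_h)
        )
        return self.puncta_baseline_rate + induced

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["fov_shape"] = list(self.fov_shape)
        d["timepoints_h"] = [float(t) for t in self.timepoints_h]
        return d


@dataclass
class GroundTruth:
    """Simulator oracle: true per-cell fates, positions, foci counts,
    flow-event classes and colony areas, depending on the experiment.

    ``cells`` has one row per cell (``cell_id, group, true_death_time_h,
    true_detach_time_h``; times are ``inf`` for cells that never die).
    ``per_timepoint`` has one row per cell per timepoint (true centroid,
    presence, and — for foci experiments — the true rendered puncta count).
    """

    cells: pd.DataFrame | None = None
    per_timepoint: pd.DataFrame | None = None
    flow: pd.DataFrame | None = None
    colonies: pd.DataFrame | None = None
    config: SimulationConfig | None = None

    def to_csv(self, directory: str | Path, prefix: str = "truth") -> list[Path]:
        """Write each populated table as ``<prefix>_<table>.csv``; returns paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("cells", "per_timepoint", "flow", "colonies"):
            df = getattr(self, name)
            if df is not None:
                p = directory / f"{prefix}_{name}.csv"
                df.to_csv(p, index=False)
                written.append(p)
        return written


# ---------------------------------------------------------------------------
# placement and rendering helpers
# ---------------------------------------------------------------------------


def _place_points(
    rng: np.random.Generator,
    n: int,
    fov_shape: tuple[int, int],
    margin: float,
    min_separation: float,
    max_attempts_per_point: int = 1000,
) -> np.ndarray:
    """Reject-sample ``n`` centres at pairwise distance >= min_separation,
    at least ``margin`` px from the border.  Raises PlacementError when the
    retry bound is exhausted."""
    h, w = fov_shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("field of view too small for the requested margin")
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(max_attempts_per_point):
            cand = np.array(
                [
                    rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin),
                ]
            )
            if all(np.hypot(*(cand - p)) >= min_separation for p in placed):
                placed.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {n} objects at separation "
                f"{min_separation:.1f}px in a {h}x{w} field"
            )
    return np.array(placed).reshape(n, 2)


def _add_gaussian_blob(
    image: np.ndarray, row: float, col: float, amplitude: float, sigma: float
) -> None:
    """Accumulate a truncated (4-sigma) 2-D Gaussian into ``image`` in place."""
    h, w = image.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -(rr**2 + cc**2) / (2.0 * sigma**2)
    )


def _add_disk(
    image: np.ndarray, row: float, col: float, radius: float, amplitude: float
) -> int:
    """Accumulate a flat disk; returns the number of pixels covered."""
    h, w = image.shape
    r0, r1 = max(0, int(row - radius) - 1), min(h, int(row + radius) + 2)
    c0, c1 = max(0, int(col - radius) - 1), min(w, int(col + radius) + 2)
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    inside = rr**2 + cc**2 <= radius**2
    image[r0:r1, c0:c1][inside] += amplitude
    return int(inside.sum())


def _apply_noise(image: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise (gain ``noise_poisson_scale``) then Gaussian read
    noise, clipped at zero."""
    out = image
    if cfg.noise_poisson_scale > 0:
        out = rng.poisson(out / cfg.noise_poisson_scale) * cfg.noise_poisson_scale
    if cfg.noise_gaussian_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# time-lapse death assay
# ---------------------------------------------------------------------------


def simulate_timelapse(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate the ratiometric live/dead biosensor time-lapse.

    Each cell is a 2-D Gaussian blob of constant red amplitude; its green
    amplitude is set so the green/red ratio has the configured live median.
    Death times are exponential with the config's effective hazard; at
    death the green amplitude steps up to the dead-ratio level, and after
    ``detach_delay_h`` the cell disappears from the field.  Cells perform a
    small Gaussian random walk between frames.

    Draw order (one generator seeded from ``config.seed``): placement,
    per-cell red amplitudes, live ratios, dead ratios, death times, the
    random walk (per frame, all cells), then per-frame noise.

    Returns the stack (channels ``red``, ``green``) and the ground truth.
    """
    cfg = config
    if cfg.n_timepoints == 0:  # pragma: no cover - config already forbids
        raise ValueError("zero timepoints")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    times = np.asarray(cfg.timepoints_h, dtype=float)
    sigma = cfg.cell_radius_px / 2.0

    if n > 0:
        margin = cfg.cell_radius_px + 2.0
        min_sep = 2.0 * cfg.cell_radius_px + 4.0 * cfg.motion_sd_px
        centres = _place_points(rng, n, cfg.fov_shape, margin, min_sep)
        red_amp = cfg.red_amplitude * np.exp(
            rng.normal(0.0, cfg.amplitude_sigma_log, n)
        )
        live_ratio = cfg.live_ratio_median * np.exp(
            rng.normal(0.0, cfg.ratio_sigma_log, n)
        )
        dead_ratio = cfg.dead_ratio_median * np.exp(
            rng.normal(0.0, cfg.ratio_sigma_log, n)
        )
        lam = cfg.effective_hazard_per_h()
        if lam > 0:
            death_t = rng.exponential(1.0 / lam, n)
        else:
            death_t = np.full(n, np.inf)
        # random walk: positions per frame
        paths = np.empty((len(times), n, 2))
        paths[0] = centres
        for i in range(1, len(times)):
            paths[i] = paths[i - 1] + rng.normal(
                0.0, cfg.motion_sd_px, size=(n, 2)
            )
    else:
        centres = np.empty((0, 2))
        red_amp = live_ratio = dead_ratio = death_t = np.empty(0)
        paths = np.empty((len(times), 0, 2))

    detach_t = death_t + cfg.detach_delay_h
    h, w = cfg.fov_shape
    pixels = np.empty((len(times), 2, h, w))
    rows = []
    for ti, t in enumerate(times):
        red = np.full((h, w), cfg.background_offset, dtype=float)
        green = np.full((h, w), cfg.background_offset, dtype=float)
        for i in range(n):
            present = t < detach_t[i]
            dead = t >= death_t[i]
            r, c = paths[ti, i]
            if present:
                ratio = dead_ratio[i] if dead else live_ratio[i]
                _add_gaussian_blob(red, r, c, red_amp[i], sigma)
                _add_gaussian_blob(green, r, c, ratio * red_amp[i], sigma)
            rows.append(
                {
                    "cell_id": i,
                    "group": cfg.group,
                    "timepoint_h": t,
                    "row": r,
                    "col": c,
                    "present": present,
                    "dead": dead,
                }
            )
        pixels[ti, 0] = _apply_noise(red, cfg, rng)
        pixels[ti, 1] = _apply_noise(green, cfg, rng)

    stack = ImageStack(
        pixels=pixels, channel_names=["red", "green"], timepoints_h=list(times)
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "group": cfg.group,
            "true_death_time_h": death_t,
            "true_detach_time_h": detach_t,
            "live_ratio": live_ratio,
            "dead_ratio": dead_ratio,
        }
    )
    per_tp = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "group", "timepoint_h", "row", "col", "present", "dead",
        ],
    )
    truth = GroundTruth(cells=cells, per_timepoint=per_tp, config=cfg)
    return stack, truth


# ---------------------------------------------------------------------------
# DNA-damage foci images
# ---------------------------------------------------------------------------


def _place_puncta_in_disk(
    rng: np.random.Generator, count: int, radius: float, min_sep: float
) -> np.ndarray:
    """Place ``count`` puncta offsets within a disk, preferring pairwise
    separation >= min_sep; relaxes the separation when the disk is too
    crowded rather than dropping puncta."""
    offsets: list[np.ndarray] = []
    sep = min_sep
    for _ in range(count):
        placed = False
        while not placed:
            for _attempt in range(400):
                ang = rng.uniform(0, 2 * np.pi)
                rad = radius * np.sqrt(rng.uniform())
                cand = np.array([rad * np.cos(ang), rad * np.sin(ang)])
                if all(np.hypot(*(cand - p)) >= sep for p in offsets):
                    offsets.append(cand)
                    placed = True
                    break
            else:
                sep *= 0.8  # crowded cell: relax separation and retry
    return np.array(offsets).reshape(count, 2)


def simulate_foci_images(
    config: SimulationConfig, marker: str = "red"
) -> tuple[ImageStack, GroundTruth]:
    """Simulate DNA-damage focus images with Poisson ground-truth counts.

    Per cell and timepoint ``t`` the true count is drawn from
    ``Poisson(baseline + induction_per_Gy * dose * 2^(-t/halflife))``.
    Cells render as flat disks; each focus is a narrow Gaussian peak whose
    added height is ``(puncta_amplitude_fold - 1) x`` the cell's own
    background, so the peak sits at ``puncta_amplitude_fold x`` background.

    ``marker="red"`` emulates the live 53BP1 reporter (single red channel,
    foci in the same channel as the cell body); ``marker="dapi"`` emulates
    fixed-cell γ-H2AX staining (DAPI nuclei plus a green channel carrying a
    dim nuclear background and the foci).
    """
    cfg = config
    if cfg.puncta_amplitude_fold <= 1:
        raise ValueError(
            "puncta_amplitude_fold must exceed 1 (foci must rise above background)"
        )
    if marker not in ("red", "dapi"):
        raise ValueError("marker must be 'red' or 'dapi'")
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.timepoints_h, dtype=float)
    n = cfg.n_cells
    h, w = cfg.fov_shape
    radius = cfg.cell_radius_px

    if n > 0:
        margin = radius + 2.0
        centres = _place_points(rng, n, cfg.fov_shape, margin, 2 * radius + 4.0)
    else:
        centres = np.empty((0, 2))
    body_amp = 100.0 * np.exp(rng.normal(0.0, 0.1, n)) if n else np.empty(0)

    marker_amp = body_amp if marker == "red" else 150.0 * np.ones(n)
    green_base = body_amp if marker == "red" else 20.0 * np.ones(n)

    n_ch = 1 if marker == "red" else 2
    channel_names = ["red"] if marker == "red" else ["dapi", "green"]
    pixels = np.empty((len(times), n_ch, h, w))
    rows = []
    for ti, t in enumerate(times):
        rate = cfg.puncta_rate(t)
        marker_img = np.full((h, w), cfg.background_offset, dtype=float)
        foci_img = (
            marker_img
            if marker == "red"
            else np.full((h, w), cfg.background_offset, dtype=float)
        )
        for i in range(n):
            r, c = centres[i]
            _add_disk(marker_img, r, c, radius, marker_amp[i])
            if marker == "dapi":
                _add_disk(foci_img, r, c, radius, green_base[i])
            count = int(rng.poisson(rate))
            # foci are diffraction-limited: narrow (sigma 0.8 px) and well
            # separated (5 px Euclidean clears a 3 px Chebyshev NMS window)
            offsets = _place_puncta_in_disk(
                rng, count, max(radius - 4.0, 1.0), min_sep=5.0
            )
            peak = (cfg.puncta_amplitude_fold - 1.0) * (
                green_base[i] + cfg.background_offset
            )
            sigma_p = 0.8
            for dr, dc in offsets:
                pr, pc = r + dr, c + dc
                # normalize so the brightest rendered PIXEL (not the
                # continuous peak) sits at the configured fold: scale by the
                # Gaussian falloff at the nearest pixel centre
                d2 = (pr - round(pr)) ** 2 + (pc - round(pc)) ** 2
                amp = peak / math.exp(-d2 / (2 * sigma_p**2))
                _add_gaussian_blob(foci_img, pr, pc, amp, sigma_p)
            rows.append(
                {
                    "cell_id": i,
                    "group": cfg.group,
                    "timepoint_h": t,
                    "row": r,
                    "col": c,
                    "puncta_count": count,
                }
            )
        if marker == "red":
            pixels[ti, 0] = _apply_noise(marker_img, cfg, rng)
        else:
            pixels[ti, 0] = _apply_noise(marker_img, cfg, rng)
            pixels[ti, 1] = _apply_noise(foci_img, cfg, rng)

    stack = ImageStack(
        pixels=pixels, channel_names=channel_names, timepoints_h=list(times)
    )
    cells = pd.DataFrame({"cell_id": np.arange(n), "group": cfg.group})
    per_tp = pd.DataFrame(
        rows,
        columns=["cell_id", "group", "timepoint_h", "row", "col", "puncta_count"],
    )
    return stack, GroundTruth(cells=cells, per_timepoint=per_tp, config=cfg)


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------


def simulate_flow_events(
    n_events: int,
    positive_fraction: float,
    neg_mu: float = 100.0,
    pos_mu: float = 1000.0,
    sigma_log: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a stained flow-cytometry acquisition.

    ``positive_fraction`` of events are truly labelled; fluorescence is
    lognormal with median ``pos_mu`` for positives and ``neg_mu`` for
    negatives (common ``sigma_log``).  Forward/side scatter are filler
    lognormals and every event is flagged a singlet (no doublet model).

    Returns the event table (columns ``event_id, fl_bb515, fsc, ssc,
    is_singlet``) and ground truth with per-event true classes.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if pos_mu <= neg_mu:
        raise ValueError("pos_mu must exceed neg_mu")
    rng = np.random.default_rng(seed)
    is_pos = rng.uniform(size=n_events) < positive_fraction
    mu = np.where(is_pos, math.log(pos_mu), math.log(neg_mu))
    fl = np.exp(rng.normal(mu, sigma_log))
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "fl_bb515": fl,
            "fsc": np.exp(rng.normal(math.log(5e4), 0.2, n_events)),
            "ssc": np.exp(rng.normal(math.log(3e4), 0.25, n_events)),
            "is_singlet": True,
        }
    )
    flow = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "true_class": np.where(is_pos, "positive", "negative"),
        }
    )
    return events, GroundTruth(flow=flow)


# ---------------------------------------------------------------------------
# colony growth series
# ---------------------------------------------------------------------------


def simulate_colony_series(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate a clonogenic imaging series of exponentially growing colonies.

    Colonies are flat disks; the true area of colony ``j`` at frame ``f``
    is ``pi * r0_j^2 * exp(growth * f)`` (log-area grows linearly with
    frame index).  Frames reuse ``timepoints_h`` as imaging days.  Raises
    when a colony's final extent would overflow the field of view.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.timepoints_h, dtype=float)
    n_frames = len(times)
    n = cfg.n_colonies
    h, w = cfg.fov_shape

    growth_factor = math.exp(cfg.colony_growth_per_frame * (n_frames - 1) / 2.0)
    r0 = cfg.colony_radius_px * np.exp(
        rng.normal(0.0, cfg.colony_radius_sigma_log, n)
    )
    r_final = r0 * growth_factor
    if np.any(2 * r_final.max() + 4 > min(h, w)):
        raise ValueError("colonies would overflow the field of view")
    margin = float(r_final.max()) + 2.0
    if 2 * margin >= min(h, w):
        raise ValueError("colonies would overflow the field of view")
    centres = _place_points(
        rng, n, cfg.fov_shape, margin, min_separation=2.2 * float(r_final.max())
    )

    pixels = np.empty((n_frames, 1, h, w))
    rows = []
    for f in range(n_frames):
        img = np.full((h, w), cfg.background_offset, dtype=float)
        radii = r0 * math.exp(cfg.colony_growth_per_frame * f / 2.0)
        for j in range(n):
            _add_disk(img, centres[j, 0], centres[j, 1], radii[j], 100.0)
            rows.append(
                {
                    "colony_id": j,
                    "frame": f,
                    "day": times[f],
                    "row": centres[j, 0],
                    "col": centres[j, 1],
                    "true_area_px": math.pi * radii[j] ** 2,
                }
            )
        pixels[f, 0] = _apply_noise(img, cfg, rng)

    stack = ImageStack(
        pixels=pixels, channel_names=["brightfield"], timepoints_h=list(times)
    )
    colonies = pd.DataFrame(
        rows, columns=["colony_id", "frame", "day", "row", "col", "true_area_px"]
    )
    return stack, GroundTruth(colonies=colonies, config=cfg)
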