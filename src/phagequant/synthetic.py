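"""Seeded synthetic microscopy scenes with known ground truth.

This module emulates the imaging experiments the quantification pipeline is
built for: rod-shaped *M. smegmatis* cells on an agarose pad or in a
microfluidic chamber, stained with a fluorogenic cell-wall probe (green
channel, enriched at poles and septa because mycobacteria build new wall
there), exposed to nucleic-acid-stained phage particles that appear as
diffraction-limited red puncta on the cell surface, and — in time lapse —
carrying an mCherry reporter that turns on when an infecting phage expresses
its genes, followed by lysis or, for resistant cells, outgrowth.

Every scene is generated from a :class:`SceneConfig` and a seed, and carries
complete ground-truth tables (cells, phage anchor positions and classes,
infection event frames), so downstream stages can be validated by parameter
recovery rather than by eye.

Optics are modelled as an isotropic Gaussian PSF (truncated at 4 sigma) with
per-pixel Poisson shot noise and Gaussian read noise, the standard sCMOS
model; both noise terms can be switched off independently for oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as _draw_polygon

from .geometry import Capsule

__all__ = [
    "SceneConfig",
    "CellTruth",
    "PhageTruth",
    "SyntheticScene",
    "binding_capacity",
    "place_phages",
    "render_membrane_green",
    "simulate_scene",
    "simulate_timelapse",
    "rasterize_labels",
    "write_scene",
]

FATES = ("susceptible_lyse", "resistant_outgrow", "uninfected")


@dataclass
class SceneConfig:
    """Parameters of a synthetic imaging field.

    Geometry is in micrometres where stated; everything else is in pixels or
    camera intensity units.  Defaults emulate the study system: ~0.5 um wide,
    2.5–5 um long *M. smegmatis* rods imaged at 100x on an sCMOS camera
    (0.065 um/px), phage dosing of a few particles per cell, frames every
    12 minutes in time lapse, and a 1:1000 dilution of pre-infected seeder
    cells into uninfected ones.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.065          # um per pixel
    n_cells: int = 30
    cell_length_range: tuple[float, float] = (2.5, 5.0)  # um, pole to pole
    cell_width: float = 0.5            # um
    septum_prob: float = 0.3
    polar_green_ratio: float = 2.0     # old-pole / new-pole label density, >= 1
    lateral_green_level: float = 0.2   # lateral density as fraction of new-pole
    phage_rate: float = 3.0            # mean phage particles per cell (Poisson)
    polar_bias: float = 0.8            # P(anchor drawn in pole/septum arcs)
    psf_sigma: float = 1.5             # px
    background_level: float = 100.0    # intensity units (fluorescence channels)
    gaussian_read_sd: float = 2.0      # intensity units; 0 disables
    poisson_scale: float = 1.0         # photons per intensity unit; 0 disables
    n_operator_sites: int = 7
    protomers_per_site: int = 2
    n_frames: int = 1
    frame_interval: float = 12.0       # minutes
    resistant_fraction: float = 0.5    # P(infected cell follows outgrowth fate)
    infected_dilution: float = 1e-3    # seeder : uninfected ratio
    seed: int = 0

    # secondary knobs (not part of the experimental design, but exposed)
    phage_photons: float = 400.0       # integrated intensity per phage punctum
    green_density: float = 50.0        # green photons per px of pole-arc length
    phase_background: float = 1000.0   # phase channel background level
    phase_cell_level: float = 0.4      # cell interior as fraction of background
    mcherry_amplitude: float = 150.0   # plateau of the reporter sigmoid
    focus_photons_per_interaction: float = 30.0
    doubling_time: float = 180.0       # minutes, exponential elongation
    old_pole_fraction: float = 0.7     # share of elongation at the old pole
    placement_clearance: float = 2.0   # px between neighbouring cells

    def validate(self) -> None:
        if not (0.0 <= self.polar_bias <= 1.0):
            raise ValueError("polar_bias must be in [0, 1]")
        if self.polar_green_ratio < 1.0:
            raise ValueError("polar_green_ratio must be >= 1")
        if self.phage_rate < 0 or self.background_level < 0 or self.poisson_scale < 0:
            raise ValueError("rates and levels must be >= 0")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.cell_length_range[0] < self.cell_width:
            raise ValueError("cells must be at least as long as wide")
        if not (0.0 <= self.resistant_fraction <= 1.0):
            raise ValueError("resistant_fraction must be in [0, 1]")

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: int
    capsule: Capsule                   # midline endpoints + half-width, px
    length: float                      # um, pole to pole
    width: float                       # um
    orientation: float                 # radians
    old_pole_end: int = 0              # 0 -> capsule.p0 is the old pole
    septum_arclength: float | None = None  # mid-plane arc position, px
    fate: str = "uninfected"
    infection_frame: int | None = None
    mcherry_onset_frame: int | None = None
    lysis_frame: int | None = None

    @property
    def has_septum(self) -> bool:
        return self.septum_arclength is not None

    @property
    def boundary(self) -> np.ndarray:
        return self.capsule.boundary_polyline(max_step=0.5)

    def site_class(self, arclength: float) -> str:
        old = "p0" if self.old_pole_end == 0 else "p1"
        return self.capsule.classify_arclength(arclength, septum=self.has_septum,
                                               old_pole=old)


@dataclass
class PhageTruth:
    """Ground truth for one phage particle bound to a cell surface."""

    phage_id: int
    cell_id: int
    anchor_arclength: float
    site_class: str                    # old_pole / new_pole / septum / lateral
    photon_intensity: float

    def anchor_xy(self, cell: CellTruth) -> np.ndarray:
        return cell.capsule.point_at(self.anchor_arclength)


@dataclass
class SyntheticScene:
    """A rendered multi-channel field plus its ground truth."""

    channels: dict[str, np.ndarray]
    cells: list[CellTruth]
    phages: list[PhageTruth]
    config: SceneConfig
    frame: int = 0

    def labels(self) -> np.ndarray:
        """Ground-truth integer label mask (cell_id per pixel)."""
        return rasterize_labels(self.cells, self.config.image_shape)

    def cells_table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append({
                "cell_id": c.cell_id,
                "x0": c.capsule.p0[0], "y0": c.capsule.p0[1],
                "x1": c.capsule.p1[0], "y1": c.capsule.p1[1],
                "length_um": c.length, "width_um": c.width,
                "orientation": c.orientation, "old_pole_end": c.old_pole_end,
                "septum_arclength": c.septum_arclength,
                "fate": c.fate,
                "infection_frame": c.infection_frame,
                "mcherry_onset_frame": c.mcherry_onset_frame,
                "lysis_frame": c.lysis_frame,
            })
        return pd.DataFrame(rows)

    def phages_table(self) -> pd.DataFrame:
        rows = []
        for p in self.phages:
            cell = next(c for c in self.cells if c.cell_id == p.cell_id)
            x, y = p.anchor_xy(cell)
            rows.append({
                "phage_id": p.phage_id, "cell_id": p.cell_id,
                "anchor_arclength": p.anchor_arclength,
                "anchor_x": x, "anchor_y": y,
                "site_class": p.site_class,
                "photon_intensity": p.photon_intensity,
            })
        return pd.DataFrame(rows, columns=["phage_id", "cell_id", "anchor_arclength",
                                           "anchor_x", "anchor_y", "site_class",
                                           "photon_intensity"])


def binding_capacity(n_sites: int, protomers_per_site: int) -> int:
    """Number of fluorescent protein–operator interactions per phage genome.

    An operator-array reporter phage carries ``n_sites`` operator sites, each
    accommodating ``protomers_per_site`` protomers of the fluorescently tagged
    transcription factor; the per-genome focus brightness scales with the
    product.  With the study's design of seven operator sites binding two
    protomers each, this is 14.
    """
    n_sites = int(n_sites)
    protomers_per_site = int(protomers_per_site)
    if n_sites < 0 or protomers_per_site < 0:
        raise ValueError("counts must be non-negative")
    return n_sites * protomers_per_site


# ---------------------------------------------------------------------------
# phage placement

def place_phages(cell: CellTruth, rate: float, polar_bias: float,
                 rng: np.random.Generator, photon_intensity: float = 400.0,
                 start_id: int = 0) -> list[PhageTruth]:
    """Draw a Poisson number of surface-bound phages for one cell.

    Each particle anchors, with probability ``polar_bias``, uniformly within
    the union of the two pole-cap arcs (plus the septum arc when the cell has
    a septum) — mimicking preferential attachment at sites of new cell-wall
    synthesis — and otherwise uniformly over the whole boundary.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not (0.0 <= polar_bias <= 1.0):
        raise ValueError("polar_bias must be in [0, 1]")
    n = int(rng.poisson(rate))
    if n == 0:
        return []
    cap = cell.capsule
    arcs = list(cap.cap_arcs().values())
    if cell.has_septum:
        arcs.extend(cap.septum_arcs())
    arc_lens = np.array([b - a for a, b in arcs])
    arc_cum = np.cumsum(arc_lens)
    total_arc = arc_cum[-1]
    out = []
    for i in range(n):
        if rng.random() < polar_bias:
            u = rng.random() * total_arc
            j = int(np.searchsorted(arc_cum, u, side="right"))
            s = arcs[j][0] + (u - (arc_cum[j] - arc_lens[j]))
        else:
            s = rng.random() * cap.circumference
        out.append(PhageTruth(
            phage_id=start_id + i, cell_id=cell.cell_id,
            anchor_arclength=float(s % cap.circumference),
            site_class=cell.site_class(s),
            photon_intensity=float(photon_intensity),
        ))
    return out


# ---------------------------------------------------------------------------
# rendering primitives

def _splat(image: np.ndarray, points: np.ndarray, amounts: np.ndarray) -> None:
    """Deposit amounts at continuous (x, y) points by bilinear splatting."""
    h, w = image.shape
    pts = np.atleast_2d(points)
    amounts = np.broadcast_to(np.atleast_1d(amounts), (pts.shape[0],))
    x, y = pts[:, 0], pts[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dy in (0, 1):
        for dx in (0, 1):
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xi, yi = x0 + dx, y0 + dy
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            np.add.at(image, (yi[ok], xi[ok]), amounts[ok] * wgt[ok])


def render_membrane_green(cell: CellTruth, polar_ratio: float,
                          lateral_level: float, shape: tuple[int, int],
                          density: float = 50.0, ds: float = 0.25) -> np.ndarray:
    """Render the membrane label of one cell, before PSF convolution.

    Intensity is deposited along the boundary with per-arclength density 1
    (in units of ``density``) on the new-pole cap, ``polar_ratio`` on the old
    pole cap and the septum band, and ``lateral_level`` elsewhere, so the
    integrated old-pole intensity is ``polar_ratio`` times the new-pole one.
    """
    if polar_ratio < 1.0:
        raise ValueError("polar_ratio must be >= 1")
    img = np.zeros(shape, dtype=float)
    cap = cell.capsule
    C = cap.circumference
    n = max(int(np.ceil(C / ds)), 16)
    s = (np.arange(n) + 0.5) * (C / n)
    pts = cap.point_at(s)
    dens = np.empty(n)
    for i, si in enumerate(s):
        cls = cell.site_class(si)
        if cls == "old_pole":
            dens[i] = polar_ratio
        elif cls in ("new_pole", "septum"):
            dens[i] = polar_ratio if cls == "septum" else 1.0
        else:
            dens[i] = lateral_level
    _splat(img, pts, dens * density * (C / n))
    return img


def rasterize_labels(cells: list[CellTruth], shape: tuple[int, int]) -> np.ndarray:
    """Integer label mask with each cell's id painted over its silhouette."""
    mask = np.zeros(shape, dtype=np.int32)
    for c in cells:
        poly = c.boundary
        rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
        mask[rr, cc] = c.cell_id
    return mask


def _apply_noise(img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * cfg.poisson_scale) / cfg.poisson_scale
    if cfg.gaussian_read_sd > 0:
        out = out + rng.normal(0.0, cfg.gaussian_read_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# cell placement

def _place_cells(cfg: SceneConfig, rng: np.random.Generator,
                 max_attempts_per_cell: int = 200,
                 growth_factor: float = 1.0) -> list[CellTruth]:
    """Rejection-sample non-overlapping capsules.

    ``growth_factor`` reserves room for elongation: the overlap test and
    field margins use the cell's final length so that a time lapse stays
    collision-free as cells grow.
    """
    h, w = cfg.image_shape
    r_px = (cfg.cell_width / 2.0) / cfg.pixel_size
    pad = 4.0 * cfg.psf_sigma + r_px + 2.0
    cells: list[CellTruth] = []
    final_caps: list[Capsule] = []
    attempts = 0
    budget = max_attempts_per_cell * max(cfg.n_cells, 1)
    while len(cells) < cfg.n_cells:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping cells in a "
                f"{cfg.image_shape} field after {budget} attempts; reduce "
                "n_cells or enlarge the field")
        attempts += 1
        L_um = rng.uniform(*cfg.cell_length_range)
        L_px = L_um / cfg.pixel_size
        ell = max(L_px - 2 * r_px, 1.0)      # midline length
        ell_final = max(L_px * growth_factor - 2 * r_px, ell)
        theta = rng.uniform(0, 2 * np.pi)
        half = ell / 2.0
        arm_final = ell / 2.0 + 0.75 * (ell_final - ell)   # covers 70/30 split
        margin = pad + arm_final
        if 2 * margin >= min(h, w):
            raise RuntimeError("cells too long for the field")
        cx = rng.uniform(margin, w - 1 - margin)
        cy = rng.uniform(margin, h - 1 - margin)
        u = np.array([np.cos(theta), np.sin(theta)])
        p0 = np.array([cx, cy]) - u * half
        p1 = np.array([cx, cy]) + u * half
        cand = Capsule(tuple(p0), tuple(p1), r_px)
        # final-size envelope, asymmetric growth bounded by the longer arm
        cand_final = Capsule(tuple(np.array([cx, cy]) - u * arm_final),
                             tuple(np.array([cx, cy]) + u * arm_final), r_px)
        if any(cand_final.distance_to(other) < 2 * r_px + cfg.placement_clearance
               for other in final_caps):
            continue
        cell = CellTruth(
            cell_id=len(cells) + 1, capsule=cand,
            length=cand.length * cfg.pixel_size,
            width=cfg.cell_width, orientation=theta,
            old_pole_end=int(rng.integers(0, 2)),
        )
        if rng.random() < cfg.septum_prob:
            # place the septum marker at the mid-plane arc on side A
            cell.septum_arclength = cand.midline_length / 2.0
        cells.append(cell)
        final_caps.append(cand_final)
    return cells


# ---------------------------------------------------------------------------
# scene assembly

def _render_channels(cells, phages, cfg, rng, channels, mcherry_levels=None,
                     focus_cells=None):
    h, w = cfg.image_shape
    out: dict[str, np.ndarray] = {}
    trunc = 4.0
    if "phase" in channels:
        img = np.full((h, w), cfg.phase_background, float)
        lab = rasterize_labels(cells, (h, w))
        img[lab > 0] = cfg.phase_background * cfg.phase_cell_level
        img = gaussian_filter(img, 1.0, truncate=trunc)
        out["phase"] = _apply_noise(img, cfg, rng)
    if "green" in channels:
        img = np.zeros((h, w))
        for c in cells:
            img += render_membrane_green(c, cfg.polar_green_ratio,
                                         cfg.lateral_green_level, (h, w),
                                         density=cfg.green_density)
        img = gaussian_filter(img, cfg.psf_sigma, truncate=trunc)
        img += cfg.background_level
        out["green"] = _apply_noise(img, cfg, rng)
    if "red" in channels:
        img = np.zeros((h, w))
        if phages:
            by_cell = {c.cell_id: c for c in cells}
            pts = np.array([p.anchor_xy(by_cell[p.cell_id]) for p in phages])
            amts = np.array([p.photon_intensity for p in phages])
            _splat(img, pts, amts)
        img = gaussian_filter(img, cfg.psf_sigma, truncate=trunc)
        img += cfg.background_level
        out["red"] = _apply_noise(img, cfg, rng)
    if "mcherry" in channels:
        img = np.zeros((h, w))
        levels = mcherry_levels or {}
        for c in cells:
            lvl = levels.get(c.cell_id, 0.0)
            if lvl > 0:
                poly = c.boundary
                rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
                img[rr, cc] += lvl
        img = gaussian_filter(img, 1.0, truncate=trunc)
        img += cfg.background_level
        out["mcherry"] = _apply_noise(img, cfg, rng)
    if "focus" in channels:
        img = np.zeros((h, w))
        brightness = (binding_capacity(cfg.n_operator_sites, cfg.protomers_per_site)
                      * cfg.focus_photons_per_interaction)
        for c in (focus_cells or []):
            t = rng.uniform(0.2, 0.8)
            p0 = np.asarray(c.capsule.p0, float)
            pos = p0 + c.capsule.axis * (t * c.capsule.midline_length)
            _splat(img, pos[None, :], np.array([brightness]))
        img = gaussian_filter(img, cfg.psf_sigma, truncate=trunc)
        img += cfg.background_level
        out["focus"] = _apply_noise(img, cfg, rng)
    return out


def simulate_scene(config: SceneConfig,
                   channels: tuple[str, ...] = ("phase", "green", "red"),
                   ) -> SyntheticScene:
    """Generate one static multi-channel field with ground truth.

    Deterministic given ``(config, config.seed)``.  The phase channel shows
    dark cells on a bright background; the green channel is membrane label
    with polar/septal enrichment; the red channel is the sum of PSF-convolved
    phage puncta plus background and noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = _place_cells(config, rng)
    phages: list[PhageTruth] = []
    for c in cells:
        phages.extend(place_phages(c, config.phage_rate, config.polar_bias, rng,
                                   photon_intensity=config.phage_photons,
                                   start_id=len(phages)))
    rendered = _render_channels(cells, phages, config, rng, channels)
    return SyntheticScene(channels=rendered, cells=cells, phages=phages,
                          config=config)


# ---------------------------------------------------------------------------
# time lapse

def _grow_capsule(cell: CellTruth, new_length_px: float) -> Capsule:
    """Elongated copy of a cell's capsule; poles move apart along the axis."""
    cap = cell.capsule
    new_ell = max(new_length_px - cap.width, 1.0)
    delta = new_ell - cap.midline_length
    u = cap.axis
    old_frac = cell._old_frac  # set by simulate_timelapse
    p0 = np.asarray(cap.p0, float)
    p1 = np.asarray(cap.p1, float)
    if cell.old_pole_end == 0:
        p0 = p0 - u * delta * old_frac
        p1 = p1 + u * delta * (1 - old_frac)
    else:
        p1 = p1 + u * delta * old_frac
        p0 = p0 - u * delta * (1 - old_frac)
    return Capsule(tuple(p0), tuple(p1), cap.radius)


def simulate_timelapse(config: SceneConfig,
                       channels: tuple[str, ...] = ("phase", "mcherry"),
                       ) -> list[SyntheticScene]:
    """Generate a seeded time lapse of growing, infected and lysing cells.

    Cells elongate exponentially (length doubling over ``doubling_time``)
    with an old-pole-biased split of the added length.  A fraction
    ``infected_dilution / (1 + infected_dilution)`` of cells start infected
    at frame 0; of these, ``resistant_fraction`` follow the outgrowth fate
    (never express the reporter, keep growing) and the rest turn on mCherry
    sigmoidally from a drawn onset frame and disappear at their lysis frame.
    All event frames are recorded in the ground truth.
    """
    config.validate()
    if config.n_frames < 2:
        raise ValueError("a time lapse needs n_frames >= 2")
    rng = np.random.default_rng(config.seed)
    total_min = (config.n_frames - 1) * config.frame_interval
    growth_total = 2.0 ** (total_min / config.doubling_time)
    cells = _place_cells(config, rng, growth_factor=growth_total)
    p_inf = config.infected_dilution / (1.0 + config.infected_dilution)
    max_onset = max(config.n_frames - 10, 2)
    for c in cells:
        c._old_frac = config.old_pole_fraction
        if rng.random() < p_inf:
            c.infection_frame = 0
            if rng.random() < config.resistant_fraction:
                c.fate = "resistant_outgrow"
            else:
                c.fate = "susceptible_lyse"
                onset = int(rng.integers(3, max(4, min(7, max_onset + 1))))
                lag = int(rng.integers(4, 9))
                c.mcherry_onset_frame = onset
                c.lysis_frame = min(onset + lag, config.n_frames - 1)
        else:
            c.fate = "uninfected"

    frames: list[SyntheticScene] = []
    interval = config.frame_interval
    for f in range(config.n_frames):
        t = f * interval
        growth = 2.0 ** (t / config.doubling_time)
        alive: list[CellTruth] = []
        levels: dict[int, float] = {}
        for c in cells:
            if c.lysis_frame is not None and f >= c.lysis_frame:
                continue
            L0_px = c.length / config.pixel_size
            cap_f = _grow_capsule(c, L0_px * growth)
            cf = dataclasses.replace(c, capsule=cap_f,
                                     length=cap_f.length * config.pixel_size)
            cf._old_frac = config.old_pole_fraction
            alive.append(cf)
            if c.mcherry_onset_frame is not None and f >= c.mcherry_onset_frame:
                x = (f - c.mcherry_onset_frame - 1.5) / 0.75
                levels[c.cell_id] = config.mcherry_amplitude / (1.0 + np.exp(-x))
        rendered = _render_channels(alive, [], config, rng, channels,
                                    mcherry_levels=levels,
                                    focus_cells=[c for c in alive
                                                 if c.infection_frame is not None])
        frames.append(SyntheticScene(channels=rendered, cells=alive, phages=[],
                                     config=config, frame=f))
    return frames


# ---------------------------------------------------------------------------
# disk IO

def write_scene(scene: SyntheticScene, out_dir: str | Path) -> None:
    """Write one scene as 16-bit TIFFs per channel plus ground-truth CSVs.

    Layout: ``<channel>_f<frame>.tif``, ``cells.csv``, ``phages.csv`` and a
    flat ``config.txt`` with every config field including the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, img in scene.channels.items():
        arr = np.clip(img, 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / f"{name}_f{scene.frame:03d}.tif", arr)
    scene.cells_table().to_csv(out / "cells.csv", index=False)
    scene.phages_table().to_csv(out / "phages.csv", index=False)
    with open(out / "config.txt", "w") as fh:
        for f_ in dataclasses.fields(scene.config):
            fh.write(f"{f_.name}={getattr(scene.config, f_.name)}\n")


def write_timelapse(frames: list[SyntheticScene], out_dir: str | Path) -> None:
    """Write a time lapse: per-frame channel TIFFs plus an events table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scene in frames:
        for name, img in scene.channels.items():
            arr = np.clip(img, 0, 65535).astype(np.uint16)
            tifffile.imwrite(out / f"{name}_f{scene.frame:03d}.tif", arr)
    frames[0].cells_table().to_csv(out / "cells.csv", index=False)
    ev = frames[0].cells_table()[["cell_id", "fate", "infection_frame",
                                  "mcherry_onset_frame", "lysis_frame"]]
    ev.to_csv(out / "events.csv", index=False)
    with open(out / "config.txt", "w") as fh:
        for f_ in dataclasses.fields(frames[0].config):
            fh.write(f"{f_.name}={getattr(frames[0].config, f_.name)}\n")
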