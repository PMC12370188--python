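"""Gabor contour-path displays.

Synthesizes the matched contour-present / contour-absent displays used in
the contour-integration experiments: a jittered 16x16 grid of Gabor
elements on a 512x512 canvas, 12 of which are aligned along a smooth path
whose global curvature is controlled by the angle beta between successive
path segments. Also provides the element masks, the alignment-jitter
manipulation, and the dataset / behavioral-set manifest builders.

Conventions
-----------
* Images are float rasters in [0, 1], quantized to 8-bit levels (k/255),
  origin top-left, ``x`` = column, ``y`` = row.
* Angles are degrees. A direction angle ``theta`` maps to the unit vector
  ``(cos theta, sin theta)`` in (x, y). A Gabor's orientation is the
  direction of its stripes and is only defined modulo 180 degrees; the
  renderer canonicalizes it accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GaborParams",
    "GridSpec",
    "PathParams",
    "ElementPlacement",
    "DisplayPair",
    "MaskSet",
    "PathGenerationError",
    "render_gabor",
    "gaussian_envelope",
    "generate_path",
    "assemble_display_pair",
    "render_pair",
    "make_masks",
    "apply_alignment_jitter",
    "build_manifest",
    "build_dataset",
    "build_behavioral_set",
    "rotate90",
    "save_image",
    "DESK_GABOR",
    "DESK_GRID",
    "DESK_PATH",
]


class PathGenerationError(RuntimeError):
    """A path could not be completed (escaped the canvas or ran out of
    collision retries); the caller should retry with fresh randomness."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaborParams:
    """Local element parameters: an odd-symmetric grating under a Gaussian
    envelope, mid-gray background."""
    wavelength: float = 8.0
    sigma: float = 4.0
    phase: float = -90.0
    patch_size: int = 28
    amplitude: float = 0.5
    background_level: float = 0.5

    def __post_init__(self):
        if self.wavelength <= 0 or self.sigma <= 0:
            raise ValueError("wavelength and sigma must be positive")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")
        if not (0 <= self.background_level <= 1):
            raise ValueError("background_level must be in [0, 1]")
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")


@dataclass(frozen=True)
class GridSpec:
    image_size: int = 512
    grid_n: int = 16

    def __post_init__(self):
        if self.image_size % self.grid_n != 0:
            raise ValueError("image_size must be a multiple of grid_n")

    @property
    def cell_size(self) -> int:
        return self.image_size // self.grid_n


@dataclass(frozen=True)
class PathParams:
    """Contour path geometry.

    ``beta`` is the magnitude of the turn between successive segments (sign
    drawn per segment); ``delta_beta_range`` bounds the uniform integer
    perturbation added to each turn after the first; anchors are spaced
    ``inter_anchor_distance`` apart, stretched by ``distance_increment``
    whenever the target grid cell is already occupied.
    """
    beta: float = 0.0
    delta_beta_range: int = 10
    inter_anchor_distance: float = 32.0
    distance_increment: float = 8.0
    n_anchors: int = 13
    start_radius: float = 64.0
    alpha: float = 0.0

    def __post_init__(self):
        if self.n_anchors < 2:
            raise ValueError("need at least 2 anchors")
        if self.inter_anchor_distance <= 0:
            raise ValueError("inter_anchor_distance must be positive")


@dataclass(frozen=True)
class ElementPlacement:
    center_x: float
    center_y: float
    orientation: float
    role: str  # "contour" | "background"
    cell_index: tuple[int, int]  # (row, col)


@dataclass
class DisplayPair:
    present_image: np.ndarray
    absent_image: np.ndarray
    placements_present: list[ElementPlacement]
    placements_absent: list[ElementPlacement]
    path_params: PathParams
    seed: int
    grid: GridSpec = field(default_factory=GridSpec)
    gabor: GaborParams = field(default_factory=GaborParams)


@dataclass
class MaskSet:
    contour_mask: np.ndarray
    background_mask: np.ndarray
    threshold: float


# desk-scale preset: same construction at a quarter of the linear scale,
# used for experiments that train networks on CPU
DESK_GABOR = GaborParams(wavelength=4.0, sigma=2.0, patch_size=14)
DESK_GRID = GridSpec(image_size=128, grid_n=8)
DESK_PATH = PathParams(inter_anchor_distance=16.0, distance_increment=4.0,
                       n_anchors=7, start_radius=32.0)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _offsets(patch_size: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.arange(patch_size) - patch_size // 2
    return np.meshgrid(c, c)  # dx (varies along columns), dy (along rows)


def render_gabor(params: GaborParams, orientation: float) -> np.ndarray:
    """Render one Gabor patch at the given stripe orientation (degrees).

    value = bg + A * exp(-(dx^2+dy^2)/(2 sigma^2)) * cos(2 pi u / lambda + phase)
    with ``u`` the coordinate perpendicular to the stripes. Orientation is
    reduced modulo 180 first (a grating orientation is only defined mod 180).
    """
    theta = math.radians(orientation % 180.0)
    dx, dy = _offsets(params.patch_size)
    u = -dx * math.sin(theta) + dy * math.cos(theta)
    envelope = np.exp(-(dx ** 2 + dy ** 2) / (2.0 * params.sigma ** 2))
    carrier = np.cos(2.0 * math.pi * u / params.wavelength
                     + math.radians(params.phase))
    patch = params.background_level + params.amplitude * envelope * carrier
    return np.clip(patch, 0.0, 1.0)


def gaussian_envelope(params: GaborParams) -> np.ndarray:
    """The element's Gaussian envelope scaled to 0-255 (mask construction)."""
    dx, dy = _offsets(params.patch_size)
    return 255.0 * np.exp(-(dx ** 2 + dy ** 2) / (2.0 * params.sigma ** 2))


# ---------------------------------------------------------------------------
# path generation
# ---------------------------------------------------------------------------

_MAX_DISTANCE_INCREMENTS = 20
_MAX_RESTARTS = 50


def _cell_of(x: float, y: float, grid: GridSpec) -> tuple[int, int]:
    return (int(y // grid.cell_size), int(x // grid.cell_size))


def generate_path(path_params: PathParams, grid: GridSpec,
                  rng: np.random.Generator, margin: float | None = None,
                  ) -> tuple[np.ndarray, list[ElementPlacement]]:
    """Lay out the contour path: ``n_anchors`` anchor points with one element
    at each segment midpoint, oriented along the segment.

    The first anchor sits ``start_radius`` px from the image center at a
    random polar angle; the first segment heads toward the center turned by
    a random-signed beta; each later segment turns by signed beta plus a
    uniform integer perturbation. When a segment's midpoint lands in an
    occupied cell the segment is stretched by the distance increment and
    retried. Raises :class:`PathGenerationError` when the path leaves the
    canvas or retries run out.
    """
    p, g = path_params, grid
    if margin is None:
        margin = 14.0
    center = g.image_size / 2.0
    if p.start_radius >= center:
        raise ValueError("start_radius must be inside the canvas")

    phi0 = rng.uniform(0.0, 360.0)
    cur = np.array([center + p.start_radius * math.cos(math.radians(phi0)),
                    center + p.start_radius * math.sin(math.radians(phi0))])
    direction = phi0 + 180.0  # toward the center
    anchors = [cur.copy()]
    occupied: set[tuple[int, int]] = set()
    placements: list[ElementPlacement] = []

    for k in range(p.n_anchors - 1):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        turn = sign * p.beta
        if k > 0 and p.delta_beta_range > 0:
            turn += int(rng.integers(-p.delta_beta_range, p.delta_beta_range + 1))
        direction += turn
        step = np.array([math.cos(math.radians(direction)),
                         math.sin(math.radians(direction))])
        dist = p.inter_anchor_distance
        for _ in range(_MAX_DISTANCE_INCREMENTS + 1):
            nxt = cur + dist * step
            mid = (cur + nxt) / 2.0
            inside = (margin <= mid[0] <= g.image_size - margin
                      and margin <= mid[1] <= g.image_size - margin)
            cell = _cell_of(mid[0], mid[1], g) if inside else None
            if inside and cell not in occupied:
                break
            dist += p.distance_increment
        else:
            raise PathGenerationError("no free cell within retry budget")
        occupied.add(cell)
        placements.append(ElementPlacement(
            center_x=float(mid[0]), center_y=float(mid[1]),
            orientation=(direction + p.alpha) % 360.0,
            role="contour", cell_index=cell))
        anchors.append(nxt.copy())
        cur = nxt

    return np.array(anchors), placements


# ---------------------------------------------------------------------------
# display assembly
# ---------------------------------------------------------------------------

def _paste(canvas: np.ndarray, patch: np.ndarray, cx: float, cy: float,
           background_level: float) -> None:
    """Add the patch's deviation from background into the canvas (linear
    superposition; clipping happens once at the end)."""
    p = patch.shape[0]
    x0 = int(round(cx)) - p // 2
    y0 = int(round(cy)) - p // 2
    h, w = canvas.shape
    sx0, sy0 = max(0, -x0), max(0, -y0)
    sx1, sy1 = min(p, w - x0), min(p, h - y0)
    if sx0 >= sx1 or sy0 >= sy1:
        raise PathGenerationError("element footprint fully outside canvas")
    canvas[y0 + sy0:y0 + sy1, x0 + sx0:x0 + sx1] += \
        patch[sy0:sy1, sx0:sx1] - background_level


def _compose(placements: list[ElementPlacement], gabor: GaborParams,
             grid: GridSpec) -> np.ndarray:
    canvas = np.zeros((grid.image_size, grid.image_size))
    for pl in placements:
        patch = render_gabor(gabor, pl.orientation)
        _paste(canvas, patch, pl.center_x, pl.center_y, gabor.background_level)
    img = np.clip(gabor.background_level + canvas, 0.0, 1.0)
    return np.round(img * 255.0) / 255.0


def assemble_display_pair(path_output: tuple[np.ndarray, list[ElementPlacement]],
                          gabor: GaborParams, grid: GridSpec,
                          rng: np.random.Generator, bg_jitter: int = 9,
                          path_params: PathParams | None = None,
                          seed: int = 0) -> DisplayPair:
    """Build the matched pair: aligned contour elements in the present image,
    independently re-oriented contour elements at identical positions in the
    absent image, and one identically-jittered random background Gabor in
    every unoccupied cell of both."""
    _, contour = path_output
    occupied = {pl.cell_index for pl in contour}

    absent_contour = [replace(pl, orientation=float(rng.uniform(0.0, 360.0)))
                      for pl in contour]

    background: list[ElementPlacement] = []
    for row in range(grid.grid_n):
        for col in range(grid.grid_n):
            if (row, col) in occupied:
                continue
            jx = int(rng.integers(-bg_jitter, bg_jitter + 1))
            jy = int(rng.integers(-bg_jitter, bg_jitter + 1))
            cx = col * grid.cell_size + grid.cell_size // 2 + jx
            cy = row * grid.cell_size + grid.cell_size // 2 + jy
            background.append(ElementPlacement(
                center_x=float(cx), center_y=float(cy),
                orientation=float(rng.uniform(0.0, 360.0)),
                role="background", cell_index=(row, col)))

    present = _compose(contour + background, gabor, grid)
    absent = _compose(absent_contour + background, gabor, grid)
    return DisplayPair(
        present_image=present, absent_image=absent,
        placements_present=contour + background,
        placements_absent=absent_contour + background,
        path_params=path_params or PathParams(), seed=seed,
        grid=grid, gabor=gabor)


def render_pair(beta: float, seed: int, gabor: GaborParams = GaborParams(),
                grid: GridSpec = GridSpec(), path_params: PathParams | None = None,
                bg_jitter: int | None = None) -> DisplayPair:
    """Generate one display pair for a curvature level, restarting path
    generation with fresh randomness when it dead-ends."""
    base = path_params or PathParams()
    params = replace(base, beta=beta)
    if bg_jitter is None:
        bg_jitter = 9 if grid.cell_size >= 32 else max(1, grid.cell_size // 4)
    rng = np.random.default_rng(seed)
    margin = gabor.patch_size / 2.0
    for _ in range(_MAX_RESTARTS):
        try:
            path = generate_path(params, grid, rng, margin=margin)
            return assemble_display_pair(path, gabor, grid, rng,
                                         bg_jitter=bg_jitter,
                                         path_params=params, seed=seed)
        except PathGenerationError:
            continue
    raise PathGenerationError(f"no valid path after {_MAX_RESTARTS} restarts")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def make_masks(placements: list[ElementPlacement], gabor: GaborParams,
               threshold: float = 140.0) -> MaskSet:
    """Binary contour / background masks: per role, the per-element Gaussian
    envelopes (0-255) are combined by maximum and thresholded."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must be in [0, 255]")
    env_patch = gaussian_envelope(gabor)
    size = None
    masks = {}
    for role in ("contour", "background"):
        canvas = None
        for pl in placements:
            if pl.role != role:
                continue
            if canvas is None:
                if size is None:
                    # infer canvas size from the placements' grid footprint
                    size = _canvas_size_from(placements, gabor)
                canvas = np.zeros((size, size))
            p = env_patch.shape[0]
            x0 = int(round(pl.center_x)) - p // 2
            y0 = int(round(pl.center_y)) - p // 2
            sx0, sy0 = max(0, -x0), max(0, -y0)
            sx1, sy1 = min(p, size - x0), min(p, size - y0)
            region = canvas[y0 + sy0:y0 + sy1, x0 + sx0:x0 + sx1]
            np.maximum(region, env_patch[sy0:sy1, sx0:sx1], out=region)
        if canvas is None:
            canvas = np.zeros((size or 512, size or 512))
        masks[role] = canvas > threshold
    return MaskSet(contour_mask=masks["contour"],
                   background_mask=masks["background"], threshold=threshold)


def _canvas_size_from(placements: list[ElementPlacement], gabor: GaborParams) -> int:
    extent = max(max(pl.center_x, pl.center_y) for pl in placements)
    for size in (128, 256, 512, 1024):
        if extent + gabor.patch_size / 2 <= size:
            return size
    return int(2 ** math.ceil(math.log2(extent + gabor.patch_size)))


def make_masks_for_pair(pair: DisplayPair, threshold: float = 140.0) -> MaskSet:
    ms = make_masks(pair.placements_present, pair.gabor, threshold)
    n = pair.grid.image_size
    return MaskSet(ms.contour_mask[:n, :n], ms.background_mask[:n, :n],
                   threshold)


# ---------------------------------------------------------------------------
# alignment jitter
# ---------------------------------------------------------------------------

def apply_alignment_jitter(pair: DisplayPair, jitter: float,
                           rng: np.random.Generator) -> DisplayPair:
    """Displace each contour element by +/- ``jitter`` px perpendicular to its
    local path segment (sign random per element, identical across the two
    images of the pair); orientations and background untouched."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    new_present: list[ElementPlacement] = []
    new_absent: list[ElementPlacement] = []
    size = pair.grid.image_size
    half = pair.gabor.patch_size / 2.0
    for pl_p, pl_a in zip(pair.placements_present, pair.placements_absent):
        if pl_p.role != "contour":
            new_present.append(pl_p)
            new_absent.append(pl_a)
            continue
        theta = math.radians(pl_p.orientation)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        dx = sign * jitter * (-math.sin(theta))
        dy = sign * jitter * math.cos(theta)
        nx, ny = pl_p.center_x + dx, pl_p.center_y + dy
        if not (half <= nx <= size - half and half <= ny <= size - half):
            raise PathGenerationError("jittered element leaves canvas")
        new_present.append(replace(pl_p, center_x=nx, center_y=ny))
        new_absent.append(replace(pl_a, center_x=nx, center_y=ny))
    present = _compose(new_present, pair.gabor, pair.grid)
    absent = _compose(new_absent, pair.gabor, pair.grid)
    return DisplayPair(present_image=present, absent_image=absent,
                       placements_present=new_present,
                       placements_absent=new_absent,
                       path_params=pair.path_params, seed=pair.seed,
                       grid=pair.grid, gabor=pair.gabor)


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------

def _pair_seed(seed: int, beta: float, index: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(round(beta * 10)), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_manifest(betas, pairs_per_beta: int, seed: int,
                   split: str = "train") -> pd.DataFrame:
    """One row per image (two per pair). Deterministic per-pair seeds."""
    rows = []
    for beta in betas:
        for i in range(pairs_per_beta):
            pid = f"b{beta:g}_p{i:05d}"
            ps = _pair_seed(seed, beta, i)
            for label in ("present", "absent"):
                rows.append({
                    "image_path": f"{split}/{pid}_{label}.png",
                    "pair_id": pid, "label": label, "beta_deg": float(beta),
                    "split": split, "rotation_deg": 0, "seed": ps,
                })
    df = pd.DataFrame(rows)
    if df["pair_id"].nunique() * 2 != len(df):
        raise ValueError("duplicate pair ids in manifest")
    return df


def build_dataset(betas, pairs_per_beta: int, seed: int, out_dir=None,
                  render: bool = False, gabor: GaborParams = GaborParams(),
                  grid: GridSpec = GridSpec(),
                  path_params: PathParams | None = None,
                  split: str = "train") -> pd.DataFrame:
    """Build the manifest and optionally rasterize every image to PNG under
    ``out_dir``. Full-scale manifests (hundreds of thousands of rows) are
    normally built with ``render=False``."""
    df = build_manifest(betas, pairs_per_beta, seed, split=split)
    if render:
        if out_dir is None:
            raise ValueError("render=True needs an out_dir")
        import os
        for pid, sub in df.groupby("pair_id", sort=False):
            beta = float(sub["beta_deg"].iloc[0])
            pseed = int(sub["seed"].iloc[0])
            pair = render_pair(beta, pseed, gabor=gabor, grid=grid,
                               path_params=path_params)
            for _, row in sub.iterrows():
                img = (pair.present_image if row["label"] == "present"
                       else pair.absent_image)
                path = os.path.join(out_dir, row["image_path"])
                os.makedirs(os.path.dirname(path), exist_ok=True)
                save_image(img, path)
        df.to_csv(os.path.join(out_dir, f"{split}_manifest.csv"), index=False)
    return df


def build_behavioral_set(seed: int, betas=(15, 30, 45, 60, 75),
                         pairs_per_beta: int = 200, n_splits: int = 5
                         ) -> pd.DataFrame:
    """The behavioral stimulus set: ``pairs_per_beta`` pairs per curvature,
    partitioned into ``n_splits`` disjoint splits balanced over beta, with
    the two interval displays of every trial given rotations that differ by
    90, 180 or 270 degrees."""
    if pairs_per_beta % n_splits != 0:
        raise ValueError("pairs_per_beta must be divisible by n_splits")
    rng = np.random.default_rng(seed)
    per_split = pairs_per_beta // n_splits
    rows = []
    for beta in betas:
        order = rng.permutation(pairs_per_beta)
        for rank, i in enumerate(order):
            split = rank // per_split
            r1 = int(rng.choice([0, 90, 180, 270]))
            r2 = (r1 + int(rng.choice([90, 180, 270]))) % 360
            rows.append({
                "pair_id": f"b{beta:g}_p{int(i):05d}",
                "beta_deg": float(beta), "split": int(split),
                "rotation_1": r1, "rotation_2": r2,
                "seed": _pair_seed(seed, beta, int(i)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raster utilities
# ---------------------------------------------------------------------------

def rotate90(image: np.ndarray, degrees: int) -> np.ndarray:
    """Lossless rotation by a multiple of 90 degrees (counterclockwise)."""
    if degrees % 90 != 0:
        raise ValueError("rotation must be a multiple of 90 degrees")
    return np.rot90(image, k=(degrees // 90) % 4)


def save_image(image: np.ndarray, path: str) -> None:
    from PIL import Image
    arr = np.round(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask(mask: np.ndarray, path: str) -> None:
    from PIL import Image
    Image.fromarray(mask.astype(bool)).save(path)
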