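"""Vernier/flanker displays and the uncrowding train/test protocol.

A vernier target is two near-collinear vertical segments whose lateral
offset direction (left/right) the network must judge. Crowding is probed by
surrounding the vernier with rows of identical outline shapes: training
displays are *non-overlapping* (vernier and flanker group at spatially
separate locations), test displays are *overlapping* (vernier centered
within the flanker row), so above-chance test accuracy requires
generalizing the vernier judgment into a crowded configuration. Uncrowding is the recovery
of accuracy as identical flankers are added; the protocol's minimal
signature at small scale is the crowding drop from the unflanked to the
one-flanker condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter, polygon_perimeter

from . import nn, probe

__all__ = [
    "VernierSpec",
    "FlankerConfigSpec",
    "UncrowdingDisplay",
    "UncrowdingConfig",
    "render_vernier",
    "render_flanker",
    "compose_display",
    "build_uncrowding_sets",
    "render_manifest",
    "run_protocol",
    "SHAPES",
]

SHAPES = ("square", "circle", "hexagon", "octagon", "diamond")


@dataclass(frozen=True)
class VernierSpec:
    line_length: int = 20
    line_width: int = 2
    vertical_gap: int = 2
    horizontal_offset: int = 2
    offset_direction: str = "left"

    def __post_init__(self):
        if self.offset_direction not in ("left", "right"):
            raise ValueError("offset_direction must be 'left' or 'right'")
        if self.horizontal_offset == 0:
            raise ValueError("zero offset with a direction label is degenerate")

    @property
    def height(self) -> int:
        return 2 * self.line_length + self.vertical_gap

    @property
    def width(self) -> int:
        return self.line_width + self.horizontal_offset


@dataclass(frozen=True)
class FlankerConfigSpec:
    shape: str = "square"
    size: int = 19
    count: int = 1
    spacing: int = 25

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.count != 0 and self.count % 2 == 0:
            raise ValueError("flanker count must be odd or zero")

    @property
    def row_width(self) -> int:
        if self.count == 0:
            return 0
        return (self.count - 1) * self.spacing + self.size


@dataclass
class UncrowdingDisplay:
    canvas: np.ndarray
    layout: str  # non_overlapping | overlapping | unflanked
    label: str  # left | right
    noise_level: float
    vernier_center: tuple[float, float]
    flanker_centers: list[tuple[float, float]]


def render_vernier(spec: VernierSpec) -> tuple[np.ndarray, str]:
    """Two bright vertical bars with a vertical gap; the lower bar is
    shifted toward the labeled side relative to the upper bar."""
    patch = np.zeros((spec.height, spec.width))
    if spec.offset_direction == "left":
        upper_x, lower_x = spec.horizontal_offset, 0
    else:
        upper_x, lower_x = 0, spec.horizontal_offset
    patch[:spec.line_length, upper_x:upper_x + spec.line_width] = 1.0
    patch[spec.line_length + spec.vertical_gap:,
          lower_x:lower_x + spec.line_width] = 1.0
    return patch, spec.offset_direction


def render_flanker(shape: str, size: int = 19) -> np.ndarray:
    """One outline flanker (1-px stroke) in a size x size patch."""
    patch = np.zeros((size, size))
    r = (size - 1) // 2
    c = r
    if shape == "circle":
        rr, cc = circle_perimeter(c, c, r)
    else:
        n = {"square": 4, "diamond": 4, "hexagon": 6, "octagon": 8}[shape]
        # square axis-aligned; diamond is the square rotated 45 degrees
        phase = {"square": math.pi / 4, "diamond": 0.0,
                 "hexagon": math.pi / 2, "octagon": math.pi / 8}[shape]
        ang = phase + 2 * math.pi * np.arange(n) / n
        rad = r / max(abs(math.cos(phase)), abs(math.sin(phase))) \
            if shape == "square" else r
        rows = np.clip(np.round(c + rad * np.sin(ang)), 0, size - 1)
        cols = np.clip(np.round(c + rad * np.cos(ang)), 0, size - 1)
        rr, cc = polygon_perimeter(rows, cols, shape=patch.shape)
    patch[rr, cc] = 1.0
    return patch


def _paste(canvas: np.ndarray, patch: np.ndarray, cy: int, cx: int) -> tuple[int, int, int, int]:
    h, w = patch.shape
    y0, x0 = cy - h // 2, cx - w // 2
    if y0 < 0 or x0 < 0 or y0 + h > canvas.shape[0] or x0 + w > canvas.shape[1]:
        raise ValueError("requested geometry does not fit the canvas")
    np.maximum(canvas[y0:y0 + h, x0:x0 + w], patch,
               out=canvas[y0:y0 + h, x0:x0 + w])
    return y0, x0, y0 + h, x0 + w


def compose_display(vernier: VernierSpec, flankers: FlankerConfigSpec,
                    layout: str, noise_level: float,
                    rng: np.random.Generator,
                    canvas_size: int = 227,
                    background: float = 0.0) -> UncrowdingDisplay:
    """Place the vernier and the flanker row on the canvas.

    The canvas is dark with bright (1.0) strokes; additive zero-mean
    Gaussian noise (SD ``noise_level``) is applied last and the result is
    clipped to [0, 1], which on the dark background shaves the negative
    noise tail (pass ``background=0.5`` for unclipped noise).
    ``overlapping``: the flanker row's bounding box is centered on the
    vernier at the canvas center. ``non_overlapping``: vernier and flanker
    row are placed at free random positions whose bounding boxes are at
    least 10 px apart (rejection sampling).
    """
    canvas = np.full((canvas_size, canvas_size), background)
    vpatch, label = render_vernier(vernier)
    fpatch = render_flanker(flankers.shape, flankers.size) \
        if flankers.count else None
    centers: list[tuple[float, float]] = []

    def flanker_xs(cx: int) -> list[int]:
        w = flankers.row_width
        start = cx - w // 2 + flankers.size // 2
        return [start + i * flankers.spacing for i in range(flankers.count)]

    mid = canvas_size // 2
    if flankers.count == 0 or layout == "unflanked":
        cy = cx = mid
        _paste(canvas, vpatch, cy, cx)
        vc = (cy, cx)
        layout = "unflanked"
    elif layout == "overlapping":
        cy = cx = mid
        for fx in flanker_xs(cx):
            _paste(canvas, fpatch, cy, fx)
            centers.append((cy, fx))
        _paste(canvas, vpatch, cy, cx)
        vc = (cy, cx)
    elif layout == "non_overlapping":
        gap = 10  # minimum separation between the two bounding boxes

        def sample_center(h, w):
            y0, y1 = h // 2 + 1, canvas_size - (h - h // 2) - 1
            x0, x1 = w // 2 + 1, canvas_size - (w - w // 2) - 1
            if y1 < y0 or x1 < x0:
                raise ValueError("requested geometry does not fit the canvas")
            return (int(rng.integers(y0, y1 + 1)), int(rng.integers(x0, x1 + 1)))

        def boxes_apart(c1, h1, w1, c2, h2, w2):
            dy = abs(c1[0] - c2[0]) - (h1 + h2) / 2
            dx = abs(c1[1] - c2[1]) - (w1 + w2) / 2
            return max(dy, dx) >= gap

        for _ in range(200):
            vc = sample_center(vernier.height, vernier.width)
            fc = sample_center(flankers.size, flankers.row_width)
            if boxes_apart(vc, vernier.height, vernier.width,
                           fc, flankers.size, flankers.row_width):
                break
        else:
            raise ValueError("requested geometry does not fit the canvas")
        _paste(canvas, vpatch, *vc)
        for fx in flanker_xs(fc[1]):
            _paste(canvas, fpatch, fc[0], fx)
            centers.append((fc[0], fx))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if noise_level > 0:
        canvas = canvas + rng.normal(0.0, noise_level, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    return UncrowdingDisplay(canvas=canvas, layout=layout, label=label,
                             noise_level=noise_level, vernier_center=vc,
                             flanker_centers=centers)


# ---------------------------------------------------------------------------
# datasets and protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncrowdingConfig:
    canvas_size: int = 227
    counts: tuple[int, ...] = (1, 3, 5, 7)
    shapes: tuple[str, ...] = SHAPES
    offset: int = 2
    noise_level: float = 0.1
    spacing: int = 25
    n_train: int = 2000
    n_test_per_condition: int = 400
    seed: int = 0


def build_uncrowding_sets(cfg: UncrowdingConfig
                          ) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Training manifest (all non-overlapping) and one overlapping test
    manifest per flanker count (count 0 = unflanked), labels exactly
    balanced left/right in every manifest."""
    rng = np.random.default_rng(cfg.seed)

    def manifest(n, layout, count):
        if n % 2:
            raise ValueError("counts must be even for exact label balance")
        rows = []
        for i in range(n):
            rows.append({
                "index": i, "layout": layout,
                "shape": cfg.shapes[int(rng.integers(len(cfg.shapes)))],
                "count": count if count is not None
                else int(rng.choice([1, 3, 5, 7])),
                "label": "left" if i < n // 2 else "right",
                "seed": int(rng.integers(2 ** 31)),
            })
        df = pd.DataFrame(rows)
        return df.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))) \
                 .reset_index(drop=True)

    train = manifest(cfg.n_train, "non_overlapping", None)
    train["count"] = train["count"].where(
        train["count"].isin(cfg.counts),
        cfg.counts[0])
    tests = {}
    for count in (0,) + tuple(cfg.counts):
        layout = "unflanked" if count == 0 else "overlapping"
        tests[count] = manifest(cfg.n_test_per_condition, layout, count)
    return train, tests


def render_manifest(manifest: pd.DataFrame, cfg: UncrowdingConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a manifest; labels are 0 = left, 1 = right."""
    images, labels = [], []
    for row in manifest.itertuples():
        rng = np.random.default_rng(row.seed)
        vern = VernierSpec(horizontal_offset=cfg.offset,
                           offset_direction=row.label)
        flank = FlankerConfigSpec(shape=row.shape, count=int(row.count),
                                  spacing=cfg.spacing)
        disp = compose_display(vern, flank, row.layout, cfg.noise_level,
                               rng, canvas_size=cfg.canvas_size)
        images.append(disp.canvas)
        labels.append(0 if row.label == "left" else 1)
    return np.array(images), np.array(labels)


def run_protocol(model: nn.Sequential, layer: str, cfg: UncrowdingConfig,
                 probe_cfg: probe.ProbeConfig) -> pd.DataFrame:
    """Train the two-way vernier readout on non-overlapping stimuli and
    evaluate per overlapping condition. Returns one row per condition
    (count 0 = unflanked) plus a ``train`` row with training-set accuracy."""
    train_m, test_ms = build_uncrowding_sets(cfg)
    imgs, labels = render_manifest(train_m, cfg)
    train_ds = probe.ContourDataset(
        images=imgs, labels=labels,
        pair_ids=np.array([f"tr{i}" for i in range(len(labels))]),
        betas=train_m["count"].to_numpy(dtype=float))
    head = probe.train_readout(model, train_ds, probe_cfg)

    rows = []
    rep = probe.evaluate(head, model, layer, train_ds)
    rows.append({"condition": "train", "count": -1,
                 "accuracy": rep.accuracy, "ci95_low": rep.ci95_low,
                 "ci95_high": rep.ci95_high, "n": rep.n})
    for count, man in test_ms.items():
        imgs, labels = render_manifest(man, cfg)
        ds = probe.ContourDataset(
            images=imgs, labels=labels,
            pair_ids=np.array([f"te{count}_{i}" for i in range(len(labels))]),
            betas=np.full(len(labels), float(count)))
        rep = probe.evaluate(head, model, layer, ds)
        name = "unflanked" if count == 0 else f"{count}_flankers"
        rows.append({"condition": name, "count": count,
                     "accuracy": rep.accuracy, "ci95_low": rep.ci95_low,
                     "ci95_high": rep.ci95_high, "n": rep.n})
    return pd.DataFrame(rows)
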