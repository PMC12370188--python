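"""Guided-backpropagation saliency and mask-conditioned sensitivity scores.

The saliency map for an image is the input gradient of the contour-present
output node, computed with the guided rule (each rectifier passes only
positive gradients during the backward pass), taken in magnitude and
min-max normalized to [0, 1]. Sensitivity to the contour is summarized by
splitting the map's pixels with the contour / background element masks and
comparing the two value distributions: the difference of means (bounded in
[-1, 1] on the normalized map) and A', the probability that a random
contour pixel outranks a random background pixel (area under the empirical
ROC; ties count one half).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import nn
from .stimuli import MaskSet

__all__ = [
    "SaliencyMap",
    "SensitivityScores",
    "AlignmentSensitivity",
    "guided_backprop",
    "split_by_masks",
    "mean_difference",
    "a_prime",
    "score_image",
    "alignment_sensitivity",
]


@dataclass
class SaliencyMap:
    relevance: np.ndarray  # (H, W) in [0, 1]
    target: str = "contour_present"


@dataclass
class SensitivityScores:
    mean_diff: float
    a_prime: float
    n_contour_px: int
    n_background_px: int
    n_overlap_px: int = 0


@dataclass
class AlignmentSensitivity:
    deltas: np.ndarray  # aligned score - misaligned score, per pair
    mean_delta: float
    ci95_low: float
    ci95_high: float


def guided_backprop(model: nn.Sequential, head: nn.Linear, layer: str,
                    image: np.ndarray) -> SaliencyMap:
    """Saliency map of the contour-present decision for one image.

    Forward through the backbone to the probe point and the linear head,
    then backpropagate the contour-present node (output index 1) with the
    guided rectifier rule. The raw input gradient is taken in absolute
    value and min-max normalized; an identically-zero gradient returns an
    all-zero map.
    """
    x = image[None, None, :, :] if image.ndim == 2 else image[None]
    has_relu = any(isinstance(l, nn.ReLU) for l in model.layers)
    if not has_relu:
        warnings.warn("model has no rectifier; guided backprop reduces to "
                      "the plain gradient", stacklevel=2)
    a = model.forward(x, upto=layer)
    z = head.forward(a.reshape(1, -1))
    dz = np.zeros_like(z)
    dz[0, 1] = 1.0
    dfeat = head.backward(dz)
    dx = model.backward(dfeat.reshape(a.shape), guided=True)
    rel = np.abs(dx[0]).sum(axis=0)
    lo, hi = rel.min(), rel.max()
    if hi - lo <= 0:
        return SaliencyMap(np.zeros_like(rel))
    return SaliencyMap((rel - lo) / (hi - lo))


def split_by_masks(smap: SaliencyMap, masks: MaskSet
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Relevance values under the contour mask and under the background
    mask; pixels under both masks go to the contour distribution, pixels
    under neither are ignored."""
    if smap.relevance.shape != masks.contour_mask.shape:
        raise ValueError("mask/image shape mismatch")
    contour = masks.contour_mask
    background = masks.background_mask & ~contour
    return smap.relevance[contour], smap.relevance[background]


def mean_difference(contour_values: np.ndarray,
                    background_values: np.ndarray) -> float:
    """mean(contour) - mean(background); in [-1, 1] on a normalized map."""
    if len(contour_values) == 0 or len(background_values) == 0:
        raise ValueError("mean_difference undefined for an empty distribution")
    return float(np.mean(contour_values) - np.mean(background_values))


def a_prime(contour_values: np.ndarray, background_values: np.ndarray) -> float:
    """P(random contour value > random background value) with ties at 1/2,
    i.e. the Mann-Whitney U statistic over n1*n2 (empirical ROC area)."""
    n1, n2 = len(contour_values), len(background_values)
    if n1 == 0 or n2 == 0:
        raise ValueError("a_prime undefined for an empty distribution")
    ranks = rankdata(np.concatenate([contour_values, background_values]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def score_image(model: nn.Sequential, head: nn.Linear, layer: str,
                image: np.ndarray, masks: MaskSet) -> SensitivityScores:
    smap = guided_backprop(model, head, layer, image)
    cvals, bvals = split_by_masks(smap, masks)
    overlap = int((masks.contour_mask & masks.background_mask).sum())
    return SensitivityScores(
        mean_diff=mean_difference(cvals, bvals),
        a_prime=a_prime(cvals, bvals),
        n_contour_px=len(cvals), n_background_px=len(bvals),
        n_overlap_px=overlap)


def alignment_sensitivity(aligned_scores, misaligned_scores
                          ) -> AlignmentSensitivity:
    """Per-pair difference between the sensitivity score for the aligned
    (contour-present) and misaligned (contour-absent) member of each
    position-matched pair, with a normal-approximation 95% CI on the mean."""
    aligned = np.asarray(aligned_scores, dtype=float)
    misaligned = np.asarray(misaligned_scores, dtype=float)
    if aligned.shape != misaligned.shape:
        raise ValueError("aligned/misaligned inputs must be paired")
    deltas = aligned - misaligned
    n = len(deltas)
    mean = float(deltas.mean())
    se = float(deltas.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return AlignmentSensitivity(deltas=deltas, mean_delta=mean,
                                ci95_low=mean - 1.96 * se,
                                ci95_high=mean + 1.96 * se)
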