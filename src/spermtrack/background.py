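"""Adaptive per-pixel Gaussian-mixture background model.

Each pixel keeps ``K`` weighted Gaussians over intensity. Components are
ranked by weight / sigma; the top-ranked components whose cumulative weight
stays below the background ratio ``bg_t`` are deemed background. A pixel
whose intensity is explained (within ``match_lambda`` standard deviations)
by one of those background components is background; everything else —
a match to a transient component, or no match at all — is foreground and
marks a moving object, since static structure (dish, immotile cells,
debris) is absorbed into the high-weight components within a few tens of
frames.

``bg_t`` is the one parameter that is sample-dependent. The automatic
protocol in :func:`optimize_background_threshold` sweeps it over a coarse
grid and keeps the value that maximizes the number of valid detections on
a single evaluation frame, on the premise that the acquisition conditions
are constant within a recording.

The whole model is deterministic: no randomness anywhere, so identical
input produces bit-identical masks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .video_io import FrameSequence

__all__ = [
    "BackgroundParams",
    "MixtureState",
    "DEFAULT_BG_GRID",
    "gaussian_density",
    "init_mixture",
    "update_and_classify",
    "optimize_background_threshold",
]

logger = logging.getLogger(__name__)

#: The background-ratio grid swept by the optimizer: 10% to 100% in steps of 10%.
DEFAULT_BG_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


def gaussian_density(x: float, mu: float, sigma2: float) -> float:
    """Univariate normal density at intensity ``x``.

    The general multivariate form specializes to one dimension here because
    intensities are scalar grayscale values.
    """
    if sigma2 <= 0:
        raise ValueError("variance must be positive")
    return math.exp(-0.5 * (x - mu) ** 2 / sigma2) / math.sqrt(2.0 * math.pi * sigma2)


@dataclass(frozen=True)
class BackgroundParams:
    """Parameters of the mixture model and its background split.

    ``bg_t=None`` requests the automatic per-sample optimization.
    """

    bg_t: float | None = None
    n_components: int = 3
    learning_rate: float = 0.05
    match_lambda: float = 2.5
    initial_variance: float = 225.0
    variance_floor: float = 4.0
    weight_floor: float = 0.05
    burn_in_frames: int = 30

    def __post_init__(self) -> None:
        if self.bg_t is not None and not 0.0 < self.bg_t <= 1.0:
            raise ValueError("bg_t must lie in (0, 1]")
        if self.n_components < 2:
            raise ValueError("need at least 2 mixture components per pixel")
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning_rate must lie in (0, 1)")
        if self.variance_floor <= 0 or self.initial_variance < self.variance_floor:
            raise ValueError("require 0 < variance_floor <= initial_variance")
        if self.burn_in_frames < 0:
            raise ValueError("burn_in_frames must be >= 0")


@dataclass
class MixtureState:
    """Per-pixel mixture arrays, each of shape ``(K, height, width)``."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    frame_count: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[1:]


def init_mixture(first_frame: np.ndarray, params: BackgroundParams) -> MixtureState:
    """Seed the mixture from the first frame.

    One full-weight component per pixel centred on the observed intensity,
    plus zero-weight placeholders that later observations can claim.
    """
    frame = np.asarray(first_frame, dtype=np.float32)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("first_frame must be a non-empty 2-D raster")
    k = params.n_components
    h, w = frame.shape
    weights = np.zeros((k, h, w), dtype=np.float32)
    weights[0] = 1.0
    means = np.zeros((k, h, w), dtype=np.float32)
    means[0] = frame
    variances = np.full((k, h, w), params.initial_variance, dtype=np.float32)
    return MixtureState(weights, means, variances, frame_count=0)


def update_and_classify(
    state: MixtureState, frame: np.ndarray, params: BackgroundParams
) -> tuple[MixtureState, np.ndarray]:
    """Advance the mixture by one frame and return the foreground mask.

    Per pixel: components are ranked by weight/sigma, the background prefix
    is cut at cumulative weight ``bg_t``, the observation is matched to the
    first component within ``match_lambda`` sigma, weights decay with the
    matched one reinforced, and the matched component's mean and variance
    move toward the observation with rate ``alpha * exp(-d^2 / 2*sigma^2)``
    (the match density scaled to peak at ``alpha``). An unmatched
    observation replaces the weakest component. The mask is 1 exactly where
    no background component explains the pixel.
    """
    if params.bg_t is None:
        raise ValueError("bg_t is unset; run optimize_background_threshold first")
    x = np.asarray(frame, dtype=np.float32)
    if x.shape != state.shape:
        raise ValueError(f"frame shape {x.shape} != model shape {state.shape}")
    alpha = np.float32(params.learning_rate)

    # Rank components by weight/sigma (descending), per pixel.
    fitness = state.weights / np.sqrt(state.variances)
    order = np.argsort(-fitness, axis=0, kind="stable")
    w = np.take_along_axis(state.weights, order, axis=0)
    mu = np.take_along_axis(state.means, order, axis=0)
    var = np.take_along_axis(state.variances, order, axis=0)

    # Background prefix: components whose preceding cumulative weight is
    # still below bg_t.
    cum_before = np.cumsum(w, axis=0) - w
    is_background = cum_before < np.float32(params.bg_t)

    # First matching component in rank order; placeholders never match.
    delta = x[None] - mu
    matched = (np.abs(delta) <= params.match_lambda * np.sqrt(var)) & (w > 0)
    any_match = matched.any(axis=0)
    first = np.argmax(matched, axis=0)[None]  # (1, H, W)

    fg_mask = ~(any_match & np.take_along_axis(is_background, first, axis=0)[0])

    # Weight update where a match occurred: decay all, reinforce the match.
    hit = np.zeros_like(matched)
    np.put_along_axis(hit, first, any_match[None], axis=0)
    w = np.where(any_match[None], (1 - alpha) * w + alpha * hit, w)

    # Mean/variance update of the matched component.
    d = np.take_along_axis(delta, first, axis=0)
    v = np.take_along_axis(var, first, axis=0)
    rho = alpha * np.exp(-0.5 * d * d / v)
    rho = np.where(any_match[None], rho, 0.0)
    new_mu = np.take_along_axis(mu, first, axis=0) + rho * d
    new_var = v + rho * (d * d - v)
    np.put_along_axis(mu, first, new_mu, axis=0)
    np.put_along_axis(var, first, new_var, axis=0)

    # Unmatched pixels: the weakest (last-ranked) component is replaced by
    # a fresh one centred on the observation.
    miss = ~any_match
    w[-1][miss] = params.weight_floor
    mu[-1][miss] = x[miss]
    var[-1][miss] = params.initial_variance

    np.maximum(var, np.float32(params.variance_floor), out=var)
    w /= w.sum(axis=0, keepdims=True)

    new_state = MixtureState(w, mu, var, frame_count=state.frame_count + 1)
    return new_state, fg_mask.astype(np.uint8)


def _count_detections(mask: np.ndarray, morph_params, min_area: float, frame_index: int) -> int:
    # Local import: detection depends on this module's mask type, not vice versa.
    from .detection import clean_mask, filter_detections, label_regions

    cleaned = clean_mask(mask, morph_params)
    return len(filter_detections(label_regions(cleaned), min_area, frame_index))


def optimize_background_threshold(
    frames: FrameSequence,
    params_base: BackgroundParams,
    morph_params=None,
    min_area: float = 150.0,
    grid: tuple[float, ...] = DEFAULT_BG_GRID,
) -> BackgroundParams:
    """Choose the background ratio that maximizes valid detections.

    For each grid value a fresh mixture is trained over the burn-in prefix
    and the first post-burn-in frame is segmented, cleaned and counted with
    the standard minimum-area rule. The grid value with the highest count
    wins; ties go to the smallest ratio (the strictest foreground split).
    One evaluation frame suffices because the recording conditions are
    constant within a sample.
    """
    from .detection import MorphologyParams

    if morph_params is None:
        morph_params = MorphologyParams()
    n_train = params_base.burn_in_frames
    if len(frames) < n_train + 1:
        raise ValueError(
            f"need at least burn_in_frames+1={n_train + 1} frames, got {len(frames)}"
        )
    if not grid:
        raise ValueError("empty bg_t grid")

    best_bg_t, best_count = None, -1
    for bg_t in grid:
        params = replace(params_base, bg_t=float(bg_t))
        state = init_mixture(frames[0], params)
        for i in range(n_train):
            state, _ = update_and_classify(state, frames[i], params)
        _, mask = update_and_classify(state, frames[n_train], params)
        count = _count_detections(mask, morph_params, min_area, n_train)
        logger.info("bg_t=%.2f -> %d detections", bg_t, count)
        if count > best_count:
            best_bg_t, best_count = float(bg_t), count
    return replace(params_base, bg_t=best_bg_t)
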