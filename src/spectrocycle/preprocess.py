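"""Image preparation: defective pixels, flat field, background, shot noise.

The four artefact classes treated before feature extraction are dead or
saturated pixels (neighbour-median repair), illumination curvature
(low-order polynomial flat-field), background fluorescence (per-channel
percentile pedestal subtraction) and Poisson shot noise (Anscombe-domain
Gaussian smoothing).  Every operation is channel-separable, mask-agnostic
and deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack import MultispectralStack

__all__ = [
    "PrepConfig",
    "PrepReport",
    "repair_defective_pixels",
    "subtract_background",
    "flatten_illumination",
    "stabilize_poisson",
    "prepare",
]


@dataclass
class PrepReport:
    """Bookkeeping of what preparation did, per channel."""

    dead_repaired: list[int] = field(default_factory=list)
    saturated_repaired: list[int] = field(default_factory=list)
    background_level: list[float] = field(default_factory=list)
    vignette_coeffs: list[list[float]] = field(default_factory=list)
    steps: list[str] = field(default_factory=list)

    def merge(self, other: "PrepReport") -> None:
        for name in ("dead_repaired", "saturated_repaired",
                     "background_level", "vignette_coeffs"):
            vals = getattr(other, name)
            if vals:
                setattr(self, name, vals)
        self.steps.extend(other.steps)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


_NEIGHBOUR_OFFSETS = [(dr, dc)
                      for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                      if (dr, dc) != (0, 0)]


def _repair_channel(img: np.ndarray, flagged: np.ndarray,
                    max_passes: int = 5) -> tuple[np.ndarray, int]:
    """Replace flagged pixels by the median of their valid 8-neighbours."""
    if flagged.all():
        raise ValueError("channel entirely defective; cannot repair")
    out = img.astype(float)
    n_repaired = int(flagged.sum())
    todo = flagged.copy()
    for _ in range(max_passes):
        if not todo.any():
            break
        valid = ~todo
        padded = np.pad(out, 1, mode="constant")
        pvalid = np.pad(valid, 1, mode="constant", constant_values=False)
        h, w = img.shape
        neigh = np.empty((8, h, w))
        nval = np.empty((8, h, w), dtype=bool)
        for k, (dr, dc) in enumerate(_NEIGHBOUR_OFFSETS):
            neigh[k] = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
            nval[k] = pvalid[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        rows, cols = np.nonzero(todo)
        vals = np.where(nval[:, rows, cols], neigh[:, rows, cols], np.nan)
        with np.errstate(all="ignore"):
            med = np.nanmedian(vals, axis=0)
        fixable = ~np.isnan(med)
        out[rows[fixable], cols[fixable]] = med[fixable]
        still = todo.copy()
        still[rows[fixable], cols[fixable]] = False
        todo = still
    return out, n_repaired


def repair_defective_pixels(
    stack: MultispectralStack,
    dead_value: float = 0,
    sat_fraction: float = 1.0,
) -> tuple[MultispectralStack, PrepReport]:
    """Repair dead (== ``dead_value``) and saturated pixels per channel.

    A pixel at or above ``sat_fraction * (2**bit_depth - 1)`` counts as
    saturated.  Flagged pixels are replaced by the median of their valid
    8-neighbours, iterated for up to 5 passes; all others are untouched.
    """
    px = stack.pixels.astype(float)
    sat_threshold = sat_fraction * stack.max_value
    report = PrepReport(steps=["repair_defective_pixels"])
    out = np.empty_like(px)
    for c in range(stack.n_channels):
        img = px[:, :, c]
        dead = img == dead_value
        sat = img >= sat_threshold
        repaired, _ = _repair_channel(img, dead | sat)
        out[:, :, c] = repaired
        report.dead_repaired.append(int(dead.sum()))
        report.saturated_repaired.append(int(sat.sum()))
    new = stack.copy()
    new.pixels = out
    return new, report


def subtract_background(
    stack: MultispectralStack, percentile: float = 5.0
) -> tuple[MultispectralStack, PrepReport]:
    """Subtract the per-channel low-percentile pedestal, clamping at zero."""
    px = stack.pixels.astype(float)
    levels = np.percentile(px.reshape(-1, stack.n_channels), percentile, axis=0)
    out = np.clip(px - levels[None, None, :], 0, None)
    report = PrepReport(
        background_level=[float(v) for v in levels],
        steps=["subtract_background"],
    )
    new = stack.copy()
    new.pixels = out
    return new, report


def _poly_basis(rows: np.ndarray, cols: np.ndarray, shape, order: int):
    u = 2.0 * cols / max(shape[1] - 1, 1) - 1.0
    v = 2.0 * rows / max(shape[0] - 1, 1) - 1.0
    return np.stack(
        [u**i * v**j
         for i, j in itertools.product(range(order + 1), repeat=2)
         if i + j <= order],
        axis=1,
    )


def flatten_illumination(
    stack: MultispectralStack,
    order: int = 2,
    background: np.ndarray | None = None,
) -> tuple[MultispectralStack, PrepReport]:
    """Divide each channel by a fitted unit-mean polynomial illumination field.

    The polynomial (order 1-3) is least-squares fitted to background pixels
    (``background`` boolean mask; all pixels when omitted), normalised to
    unit mean over the image, clipped away from zero, and divided out.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    h, w, n_chan = stack.shape
    if background is None:
        rows, cols = np.nonzero(np.ones((h, w), dtype=bool))
    else:
        rows, cols = np.nonzero(background)
    n_terms = (order + 1) * (order + 2) // 2
    if len(rows) < 10 * n_terms:
        raise ValueError("too few background pixels for flat-field fit")
    # subsample for the fit; the field itself is evaluated everywhere
    if len(rows) > 50_000:
        step = len(rows) // 50_000 + 1
        rows, cols = rows[::step], cols[::step]
    basis_fit = _poly_basis(rows, cols, (h, w), order)
    rr, cc = np.nonzero(np.ones((h, w), dtype=bool))
    basis_all = _poly_basis(rr, cc, (h, w), order)

    px = stack.pixels.astype(float)
    out = np.empty_like(px)
    report = PrepReport(steps=["flatten_illumination"])
    for c in range(n_chan):
        coef, *_ = np.linalg.lstsq(basis_fit, px[rows, cols, c], rcond=None)
        field_ = (basis_all @ coef).reshape(h, w)
        mean = field_.mean()
        if abs(mean) < 1e-12:
            raise ValueError("degenerate flat-field fit")
        field_ = np.clip(field_ / mean, 0.05, None)
        out[:, :, c] = px[:, :, c] / field_
        report.vignette_coeffs.append([float(v) for v in coef])
    new = stack.copy()
    new.pixels = out
    return new, report


def stabilize_poisson(
    stack: MultispectralStack, smooth_sigma: float = 1.0
) -> MultispectralStack:
    """Anscombe transform, Gaussian smoothing, algebraic inverse.

    ``y = 2 sqrt(x + 3/8)`` approximately unit-variance-stabilises Poisson
    counts; smoothing in the stabilised domain then suppresses shot noise
    uniformly.  With ``smooth_sigma=0`` the transform round-trips exactly.
    """
    px = np.clip(stack.pixels.astype(float), 0, None)
    y = 2.0 * np.sqrt(px + 0.375)
    if smooth_sigma > 0:
        y = gaussian_filter(y, sigma=(smooth_sigma, smooth_sigma, 0))
    out = np.clip((y / 2.0) ** 2 - 0.375, 0, None)
    new = stack.copy()
    new.pixels = out
    return new


@dataclass(frozen=True)
class PrepConfig:
    repair: bool = True
    dead_value: float = 0
    sat_fraction: float = 1.0
    flatten: bool = True
    flatten_order: int = 2
    background_subtract: bool = True
    background_percentile: float = 5.0
    stabilize: bool = True
    smooth_sigma: float = 1.0


def prepare(
    stack: MultispectralStack,
    config: PrepConfig | None = None,
    background: np.ndarray | None = None,
) -> tuple[MultispectralStack, PrepReport]:
    """Full preparation chain, each step switchable.

    Fixed order: defect repair, then the flat-field fit (which must see the
    background pedestal to recover the illumination shape), then pedestal
    subtraction, then variance stabilisation.  With all steps disabled the
    stack is returned unchanged (as float).
    """
    config = config or PrepConfig()
    report = PrepReport()
    out = stack.astype_float()
    if config.repair:
        out, r = repair_defective_pixels(
            out, config.dead_value, config.sat_fraction)
        report.merge(r)
    if config.flatten:
        out, r = flatten_illumination(out, config.flatten_order, background)
        report.merge(r)
    if config.background_subtract:
        out, r = subtract_background(out, config.background_percentile)
        report.merge(r)
    if config.stabilize:
        out = stabilize_poisson(out, config.smooth_sigma)
        report.steps.append("stabilize_poisson")
    return out, report
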