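"""Ratiometric roGFP2 analysis: corrected 405/488 excitation ratios and
compartment classification.

roGFP2 excites more efficiently at 405 nm in an oxidising environment (ER
lumen) and at 488 nm in a reducing one (cytosol), so the background- and
bleed-through-corrected pixelwise I405/I488 ratio reports which side of the
ER membrane the probe occupies.  Reference ratios default to the cytosolic
(0.45) and ER-lumenal (1.34) control means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REDUCING_REF = 0.45
OXIDISING_REF = 1.34


def correct_channels(I405, I488, Iauto=None, bg405: float = 0.0,
                     bg488: float = 0.0, bg_auto: float = 0.0,
                     bleed_coeff: float = 0.0):
    """Background subtraction and autofluorescence bleed-through correction.

    C405 = max(I405 - bg405 - bleed_coeff * (Iauto - bg_auto), 0)
    C488 = max(I488 - bg488, 0)

    Returns (C405, C488, saturated) where ``saturated`` marks pixels at the
    dtype maximum of any integer input channel (excluded from ratios).
    """
    if min(bg405, bg488, bg_auto) < 0:
        raise ValueError("backgrounds must be non-negative")
    if bleed_coeff < 0:
        raise ValueError("bleed_coeff must be >= 0")
    I405 = np.asarray(I405)
    I488 = np.asarray(I488)
    if I405.shape != I488.shape:
        raise ValueError("channel shapes differ")
    saturated = np.zeros(I405.shape, dtype=bool)
    for ch in (I405, I488, Iauto):
        if ch is not None and np.issubdtype(np.asarray(ch).dtype, np.integer):
            saturated |= np.asarray(ch) == np.iinfo(np.asarray(ch).dtype).max
    C405 = I405.astype(float) - bg405
    if bleed_coeff > 0:
        if Iauto is None:
            raise ValueError("bleed correction requires the "
                             "autofluorescence channel")
        if np.asarray(Iauto).shape != I405.shape:
            raise ValueError("channel shapes differ")
        C405 = C405 - bleed_coeff * (np.asarray(Iauto, dtype=float) - bg_auto)
    C405 = np.maximum(C405, 0.0)
    C488 = np.maximum(I488.astype(float) - bg488, 0.0)
    return C405, C488, saturated


def estimate_bleed_coeff(I405, Iauto, region_mask) -> float:
    """Bleed-through coefficient from an autofluorescence-only region:
    least-squares slope of I405 on Iauto through the origin."""
    x = np.asarray(Iauto, dtype=float)[region_mask]
    y = np.asarray(I405, dtype=float)[region_mask]
    denom = (x * x).sum()
    if denom == 0:
        raise ValueError("autofluorescence region has no signal")
    return float((x * y).sum() / denom)


def auto_signal_floor(background_pixels) -> float:
    """Default signal floor: background mean + 3 * background SD."""
    bg = np.asarray(background_pixels, dtype=float)
    return float(bg.mean() + 3.0 * bg.std())


def ratio_map(C405, C488, signal_floor: float, exclude=None):
    """Pixelwise C405/C488 where the 488 channel clears the signal floor.

    Returns (ratio, valid) where ``ratio`` is NaN outside ``valid``.
    Raises when no pixel qualifies.
    """
    C405 = np.asarray(C405, dtype=float)
    C488 = np.asarray(C488, dtype=float)
    valid = (C488 >= signal_floor) & (C405 > 0)
    if exclude is not None:
        valid &= ~np.asarray(exclude, dtype=bool)
    if not valid.any():
        raise ValueError("no signal pixels above the floor")
    ratio = np.full(C405.shape, np.nan)
    ratio[valid] = C405[valid] / C488[valid]
    return ratio, valid


def classify_environment(cell_mean: float, reducing_ref: float = REDUCING_REF,
                         oxidising_ref: float = OXIDISING_REF,
                         margin: float = 0.10) -> str:
    """Classify a cell-mean ratio against the two control references.

    The boundary is the geometric midpoint of the reducing and oxidising
    reference ratios; means within ``margin`` of the midpoint are
    ``ambiguous``.
    """
    if reducing_ref <= 0 or oxidising_ref <= 0 or reducing_ref >= oxidising_ref:
        raise ValueError("need 0 < reducing_ref < oxidising_ref")
    mid = float(np.sqrt(reducing_ref * oxidising_ref))
    if cell_mean < mid * (1.0 - margin):
        return "reducing"
    if cell_mean > mid * (1.0 + margin):
        return "oxidising"
    return "ambiguous"


@dataclass
class RatioResult:
    ratio_map: np.ndarray
    valid: np.ndarray
    cell_mean: float
    cell_sd: float
    n_pixels: int
    classification: str
    correction: dict = field(default_factory=dict)


def analyze_cell(I405, I488, Iauto=None, bg405: float = 0.0,
                 bg488: float = 0.0, bg_auto: float = 0.0,
                 bleed_coeff: float = 0.0, signal_floor: float = 0.0,
                 reducing_ref: float = REDUCING_REF,
                 oxidising_ref: float = OXIDISING_REF,
                 margin: float = 0.10) -> RatioResult:
    """Full per-cell pipeline: correct, ratio, summarise, classify."""
    C405, C488, saturated = correct_channels(
        I405, I488, Iauto, bg405, bg488, bg_auto, bleed_coeff)
    rmap, valid = ratio_map(C405, C488, signal_floor, exclude=saturated)
    vals = rmap[valid]
    mean = float(vals.mean())
    return RatioResult(
        ratio_map=rmap, valid=valid, cell_mean=mean,
        cell_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_pixels=int(valid.sum()),
        classification=classify_environment(mean, reducing_ref,
                                            oxidising_ref, margin),
        correction={"bg405": bg405, "bg488": bg488, "bg_auto": bg_auto,
                    "bleed_coeff": bleed_coeff,
                    "signal_floor": signal_floor})
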