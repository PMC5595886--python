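"""ROI summarisation of parametric maps and simulated repeat measurement.

Per tumor, measurements are taken on the center slice (the slice with the
largest in-mask area; ties break to the lower index), averaging each
parametric map over in-mask voxels whose kurtosis fit converged.  To
emulate the reading study — two observers, two measurements each — the
ROI mask is perturbed (random erosion and in-plane translation, always
intersected back with the true tumor extent) once per observer x repeat,
and the per-tumor consensus value is the arithmetic mean of the four
measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fitting import ParamMap

__all__ = [
    "JitterSpec",
    "RoiMeasurement",
    "center_slice",
    "consensus_means",
    "extract_roi",
    "measurements_to_frame",
    "simulate_observers",
]

log = logging.getLogger(__name__)

ROI_PIXEL_RANGE = (57, 214)


@dataclass(frozen=True)
class RoiMeasurement:
    tumor_id: str
    group: str
    observer: int
    repeat: int
    adc_mean: float
    diffusivity_mean: float
    kurtosis_mean: float
    n_pixels: int


@dataclass(frozen=True)
class JitterSpec:
    """Observer-variability model: each ROI variant is the true mask
    eroded by a random radius in {0..radius} and translated in-plane by
    up to ``translate`` voxels, then clipped to the true extent."""

    radius: int = 1
    translate: int = 1

    def __post_init__(self) -> None:
        if self.radius < 0 or self.translate < 0:
            raise ValueError("jitter amounts must be >= 0")


def center_slice(mask: np.ndarray) -> int:
    """Slice index with maximal in-mask area (ties -> lower index)."""
    mask = np.asarray(mask, dtype=bool)
    areas = mask.sum(axis=(0, 1))
    if areas.max() == 0:
        raise ValueError("mask is empty")
    return int(np.argmax(areas))


def extract_roi(
    pmap: ParamMap,
    mask: np.ndarray,
    tumor_id: str = "",
    group: str = "",
    observer: int = 1,
    repeat: int = 1,
    slice_index: int | None = None,
) -> RoiMeasurement:
    """Mean ADC/diffusivity/kurtosis over converged in-mask voxels on the
    center slice (or an explicit ``slice_index``)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.shape:
        raise ValueError("mask and map grids differ")
    z = center_slice(mask) if slice_index is None else slice_index
    roi = mask[:, :, z]
    n_pixels = int(roi.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI on the chosen slice")
    lo, hi = ROI_PIXEL_RANGE
    if not lo <= n_pixels <= hi:
        log.warning("ROI size %d outside the expected %d-%d range", n_pixels, lo, hi)
    use = roi & pmap.converged[:, :, z]
    if use.sum() == 0:
        raise ValueError("no converged voxels in the ROI")
    return RoiMeasurement(
        tumor_id=tumor_id,
        group=group,
        observer=observer,
        repeat=repeat,
        adc_mean=float(np.mean(pmap.adc[:, :, z][use])),
        diffusivity_mean=float(np.mean(pmap.diffusivity[:, :, z][use])),
        kurtosis_mean=float(np.mean(pmap.kurtosis[:, :, z][use])),
        n_pixels=n_pixels,
    )


def _perturb_mask(
    mask: np.ndarray, jitter: JitterSpec, rng: np.random.Generator
) -> np.ndarray:
    out = mask.copy()
    r = int(rng.integers(0, jitter.radius + 1))
    if r > 0:
        structure = ndimage.generate_binary_structure(2, 1)
        for z in range(out.shape[2]):
            out[:, :, z] = ndimage.binary_erosion(
                out[:, :, z], structure=structure, iterations=r
            )
    if jitter.translate > 0:
        dx = int(rng.integers(-jitter.translate, jitter.translate + 1))
        dy = int(rng.integers(-jitter.translate, jitter.translate + 1))
        out = np.roll(np.roll(out, dx, axis=0), dy, axis=1)
    return out & mask  # variants never leave the true tumor extent


def simulate_observers(
    pmap: ParamMap,
    mask: np.ndarray,
    jitter: JitterSpec = JitterSpec(),
    seed: int | np.random.SeedSequence = 0,
    tumor_id: str = "",
    group: str = "",
    n_observers: int = 2,
    n_repeats: int = 2,
) -> list[RoiMeasurement]:
    """One ROI measurement per observer x repeat, each on a seeded random
    perturbation of the true mask.  Zero jitter makes all four identical."""
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    out = []
    for obs in range(1, n_observers + 1):
        for rep in range(1, n_repeats + 1):
            for _ in range(50):
                variant = _perturb_mask(mask, jitter, rng)
                if variant[:, :, center_slice(mask)].sum() > 0:
                    break
            else:
                raise ValueError("jitter produced an empty ROI")
            out.append(
                extract_roi(
                    pmap,
                    variant,
                    tumor_id=tumor_id,
                    group=group,
                    observer=obs,
                    repeat=rep,
                    slice_index=center_slice(mask),
                )
            )
    return out


def measurements_to_frame(measurements: list[RoiMeasurement]) -> pd.DataFrame:
    """Long-format measurement table (one row per tumor x observer x
    repeat)."""
    return pd.DataFrame(
        [
            {
                "tumor_id": m.tumor_id,
                "group": m.group,
                "observer": m.observer,
                "repeat": m.repeat,
                "adc": m.adc_mean,
                "diffusivity": m.diffusivity_mean,
                "kurtosis": m.kurtosis_mean,
                "n_pixels": m.n_pixels,
            }
            for m in measurements
        ]
    )


def consensus_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor consensus: the arithmetic mean of the observer x repeat
    measurements (invariant to their order)."""
    return (
        table.groupby(["tumor_id", "group"], as_index=False)[
            ["adc", "diffusivity", "kurtosis"]
        ]
        .mean()
        .sort_values("tumor_id")
        .reset_index(drop=True)
    )
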