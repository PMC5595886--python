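"""Synthetic two-group DKI xenograft cohorts.

This module generates everything the downstream analysis consumes without
any real acquisition: 4D multi-b-value magnitude DWI volumes for two groups
of implanted tumors (an epithelial control line and an EMT-induced line),
binary tumor ROI masks, ground-truth parameter maps, and tumor-level
histology covariates (cellularity, Ki-67, E-cadherin) with a prescribed
correlation structure against the diffusion parameters.

The signal model is the trace-weighted diffusion-kurtosis representation

    S(b) = S0 * exp(-b*D + b^2 * D^2 * K / 6)

with diffusivity D in mm2/s and unitless excess kurtosis K (K = 0 is
perfectly Gaussian diffusion).  Tumor-level (D, K, histology) tuples are
drawn from a Gaussian copula over Gaussian marginals so that the cohort
reproduces both the group means/SDs and the pairwise parameter-histology
correlations; voxel-level parameters then scatter around the tumor means
with a configurable coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import AcquisitionProtocol, NoiseModel

__all__ = [
    "COVARIATE_NAMES",
    "GroupSpec",
    "TumorSample",
    "VoxelParams",
    "add_noise",
    "control_spec",
    "emt_spec",
    "gaussian_copula_sample",
    "make_cohort",
    "make_tumor",
    "nearest_positive_definite",
    "sample_tumor_covariates",
    "simulate_signal",
    "tumor_volume",
]

# Variable order of the tumor-level correlation matrix.
COVARIATE_NAMES = ("d", "k", "cellularity", "ki67", "ecadherin")

# Default latent correlation targets among (D, K, cellularity, Ki-67,
# E-cadherin).  The parameter-histology entries are the reported pooled
# associations of kurtosis metrics with histology in this tumor model; the
# remaining entries (D-K, and among the histology covariates) are chosen
# for plausibility and positive-definiteness and are configuration-exposed.
DEFAULT_HISTOLOGY_CORR = np.array(
    [
        #  d      k     cell   ki67   ecad
        [1.00, -0.60, -0.56, -0.59, 0.51],
        [-0.60, 1.00, 0.74, 0.73, -0.59],
        [-0.56, 0.74, 1.00, 0.60, -0.50],
        [-0.59, 0.73, 0.60, 1.00, -0.50],
        [0.51, -0.59, -0.50, -0.50, 1.00],
    ]
)

# Physical truncation box for voxel/tumor parameter draws.  The observed
# group ranges (D ~ 0.4-0.6e-3 mm2/s, K ~ 1.2-1.5) sit far inside, so the
# truncation bias is negligible.
D_MIN = 1e-5
K_MIN = 0.0
K_MAX = 3.0


@dataclass(frozen=True)
class VoxelParams:
    """Ground-truth signal parameters of one voxel."""

    s0: float
    d: float  # mm2/s
    k: float  # unitless

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Tumor-level distribution of one experimental group.

    Diffusivity moments are in mm2/s (e.g. 0.54e-3); kurtosis is unitless;
    cellularity is cells per high-power field; Ki-67 and E-cadherin are
    percent-type scores truncated to [0, 100].  ``voxel_cv`` is the
    within-tumor coefficient of variation applied to both D and K.
    ``histology_corr`` is the 5x5 latent correlation matrix over
    ``COVARIATE_NAMES``.
    """

    label: str
    n_tumors: int = 10
    d_mean: float = 0.54e-3
    d_sd: float = 0.06e-3
    k_mean: float = 1.22
    k_sd: float = 0.14
    cell_mean: float = 488.0
    cell_sd: float = 42.0
    ki67_mean: float = 30.0
    ki67_sd: float = 8.0
    ecad_mean: float = 70.0
    ecad_sd: float = 10.0
    vol_mean: float = 485.64
    vol_sd: float = 74.05
    s0: float = 1000.0
    voxel_cv: float = 0.05
    histology_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_HISTOLOGY_CORR.copy()
    )

    def __post_init__(self) -> None:
        if self.d_mean <= 0:
            raise ValueError("d_mean must be > 0")
        if self.k_mean < 0:
            raise ValueError("k_mean must be >= 0")
        for name in ("d_sd", "k_sd", "cell_sd", "ki67_sd", "ecad_sd", "vol_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tumors < 2:
            raise ValueError("n_tumors must be >= 2")
        if self.voxel_cv < 0:
            raise ValueError("voxel_cv must be >= 0")
        corr = np.asarray(self.histology_corr, dtype=float)
        if corr.shape != (5, 5):
            raise ValueError("histology_corr must be 5x5")
        if not np.allclose(corr, corr.T):
            raise ValueError("histology_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("histology_corr must have unit diagonal")
        off = corr[~np.eye(5, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal correlations must satisfy |r| < 1")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("histology_corr must be positive definite")
        object.__setattr__(self, "histology_corr", corr)


def control_spec(**overrides) -> GroupSpec:
    """Default spec of the epithelial control group."""
    return GroupSpec(label="control", **overrides)


def emt_spec(**overrides) -> GroupSpec:
    """Default spec of the EMT-induced group: lower diffusivity, higher
    kurtosis and cellularity, higher Ki-67, lower E-cadherin."""
    defaults = dict(
        d_mean=0.46e-3,
        d_sd=0.02e-3,
        k_mean=1.53,
        k_sd=0.13,
        cell_mean=700.0,
        cell_sd=43.0,
        ki67_mean=55.0,
        ki67_sd=10.0,
        ecad_mean=40.0,
        ecad_sd=10.0,
        vol_mean=469.59,
        vol_sd=44.29,
    )
    defaults.update(overrides)
    return GroupSpec(label="emt", **defaults)


@dataclass
class TumorSample:
    """One simulated xenograft tumor."""

    tumor_id: str
    group: str
    signal: np.ndarray  # (x, y, z, b) magnitude signal
    mask: np.ndarray  # (x, y, z) boolean ROI
    truth_d: np.ndarray  # (x, y, z) ground-truth diffusivity, NaN outside mask
    truth_k: np.ndarray
    truth_s0: np.ndarray
    d_mean: float  # tumor-level means the voxels scatter around
    k_mean: float
    cellularity: float
    ki67: float
    ecadherin: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.signal.shape[:3] != self.mask.shape:
            raise ValueError("signal and mask grids differ")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be >= 0")
        if not np.all(np.isfinite(self.truth_d[self.mask])):
            raise ValueError("truth must be defined wherever mask is set")


def simulate_signal(params: VoxelParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noiseless kurtosis-model signal, one value per b.

    S(b) = s0 * exp(-b*d + b^2*d^2*k/6); S(0) = s0 exactly.
    """
    b = np.asarray(protocol.b_values, dtype=float)
    return params.s0 * np.exp(-b * params.d + b**2 * params.d**2 * params.k / 6.0)


def add_noise(
    signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Apply magnitude (Rician) noise to a noiseless signal array.

    Deterministic for a fixed ``noise.seed`` (or an explicitly passed
    generator, which takes precedence).  ``kind='none'`` returns the input
    unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be >= 0")
    if noise.kind == "none":
        return signal
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    e1 = rng.normal(0.0, noise.sigma, signal.shape)
    e2 = rng.normal(0.0, noise.sigma, signal.shape)
    return np.hypot(signal + e1, e2)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume: length * width^2 / 2 (mm3)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be > 0")
    return length * width * width / 2.0


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive-definite
    correlation matrix (eigenvalue clipping + unit-diagonal rescale)."""
    corr = np.asarray(corr, dtype=float)
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() > eps:
        return sym
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    dinv = 1.0 / np.sqrt(np.diag(fixed))
    fixed = fixed * np.outer(dinv, dinv)
    return (fixed + fixed.T) / 2.0


def gaussian_copula_sample(
    corr: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n rows from a Gaussian copula with Gaussian marginals.

    With Gaussian marginals the copula reduces to a multivariate normal, so
    the latent correlation equals the Pearson correlation of the output.
    The matrix is projected to the nearest positive-definite correlation
    matrix if numerically indefinite.
    """
    corr = nearest_positive_definite(np.asarray(corr, dtype=float))
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, corr.shape[0])) @ chol.T
    return np.asarray(means) + z * np.asarray(sds)


def sample_tumor_covariates(
    spec: GroupSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Tumor-level (D, K, cellularity, Ki-67, E-cadherin) draws for a group.

    Values are truncated to their physical ranges after sampling; the group
    means sit several SDs inside every bound, so the truncation bias is
    far below Monte-Carlo resolution at the tested sizes.
    """
    means = np.array(
        [spec.d_mean, spec.k_mean, spec.cell_mean, spec.ki67_mean, spec.ecad_mean]
    )
    sds = np.array(
        [spec.d_sd, spec.k_sd, spec.cell_sd, spec.ki67_sd, spec.ecad_sd]
    )
    draws = gaussian_copula_sample(spec.histology_corr, means, sds, n, rng)
    df = pd.DataFrame(draws, columns=list(COVARIATE_NAMES))
    df["d"] = df["d"].clip(lower=D_MIN)
    df["k"] = df["k"].clip(lower=K_MIN, upper=K_MAX)
    df["cellularity"] = df["cellularity"].clip(lower=0.0)
    df["ki67"] = df["ki67"].clip(lower=0.0, upper=100.0)
    df["ecadherin"] = df["ecadherin"].clip(lower=0.0, upper=100.0)
    return df


def _ellipsoid_mask(
    shape: tuple[int, int, int], rx: float, ry: float, rz: float
) -> np.ndarray:
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.ogrid[:nx, :ny, :nz]
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _draw_mask(
    protocol: AcquisitionProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Axis-aligned ellipsoid mask whose center slice has 57-214 in-plane
    voxels, matching the ROI sizes the analysis assumes."""
    rz = protocol.n_slices / 2.0 + 0.5
    for _ in range(100):
        rx = rng.uniform(4.6, 8.0)
        ry = rng.uniform(4.6, 8.0)
        mask = _ellipsoid_mask(protocol.shape, rx, ry, rz)
        center_area = mask.sum(axis=(0, 1)).max()
        if 57 <= center_area <= 214:
            return mask
    raise RuntimeError("could not draw a mask within the ROI size range")


def _monotone_k_limit(d: np.ndarray, b_max: float) -> np.ndarray:
    """Largest K for which the signal stays strictly decreasing on [0, b_max].

    d/db of the log-signal is -D + b*D^2*K/3, negative on the whole b range
    iff K < 3 / (b_max * D).
    """
    return 3.0 / (b_max * np.asarray(d))


def make_tumor(
    spec: GroupSpec,
    protocol: AcquisitionProtocol,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence,
    tumor_id: str | None = None,
    covariates: pd.Series | None = None,
) -> TumorSample:
    """Simulate one tumor: covariate draw, mask, voxel parameters, signal.

    ``covariates`` lets the caller supply a pre-drawn tumor-level row (used
    by :func:`make_cohort` so that the cohort-level joint distribution is
    drawn in one block); otherwise one row is drawn here.
    """
    rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = sample_tumor_covariates(spec, 1, rng).iloc[0]
    d_tumor = float(covariates["d"])
    k_tumor = float(covariates["k"])

    mask = _draw_mask(protocol, rng)
    shape = protocol.shape
    truth_d = np.full(shape, np.nan)
    truth_k = np.full(shape, np.nan)
    truth_s0 = np.full(shape, np.nan)

    n_vox = int(mask.sum())
    d_vox = d_tumor * (1.0 + spec.voxel_cv * rng.standard_normal(n_vox))
    k_vox = k_tumor * (1.0 + spec.voxel_cv * rng.standard_normal(n_vox))
    d_vox = np.clip(d_vox, D_MIN, None)
    k_vox = np.clip(k_vox, K_MIN, K_MAX)
    # keep the signal strictly decreasing over the acquired b range
    k_cap = 0.999 * _monotone_k_limit(d_vox, protocol.b_max)
    bad = k_vox >= k_cap
    for _ in range(20):
        if not bad.any():
            break
        k_vox[bad] = np.clip(
            k_tumor * (1.0 + spec.voxel_cv * rng.standard_normal(bad.sum())),
            K_MIN,
            K_MAX,
        )
        bad = k_vox >= k_cap
    k_vox = np.minimum(k_vox, k_cap)

    truth_d[mask] = d_vox
    truth_k[mask] = k_vox
    truth_s0[mask] = spec.s0

    b = np.asarray(protocol.b_values)
    signal = np.zeros(shape + (len(b),))
    # vectorised kurtosis signal over in-mask voxels
    exponent = -np.outer(d_vox, b) + np.outer(d_vox**2 * k_vox, b**2) / 6.0
    signal[mask] = spec.s0 * np.exp(exponent)
    signal = add_noise(signal, noise, rng=rng)
    signal[~mask] = 0.0  # background zeroed; noise applies inside the ROI

    target_vol = max(float(rng.normal(spec.vol_mean, spec.vol_sd)), 1.0)
    width = (2.0 * target_vol / 1.2) ** (1.0 / 3.0)
    volume = tumor_volume(1.2 * width, width)

    return TumorSample(
        tumor_id=tumor_id or f"{spec.label}-{rng.integers(1 << 30)}",
        group=spec.label,
        signal=signal,
        mask=mask,
        truth_d=truth_d,
        truth_k=truth_k,
        truth_s0=truth_s0,
        d_mean=d_tumor,
        k_mean=k_tumor,
        cellularity=float(covariates["cellularity"]),
        ki67=float(covariates["ki67"]),
        ecadherin=float(covariates["ecadherin"]),
        volume_mm3=volume,
    )


def make_cohort(
    control: GroupSpec,
    emt: GroupSpec,
    protocol: AcquisitionProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[TumorSample]:
    """Simulate the full two-group cohort.

    The master seed is split into independent per-tumor streams with
    ``SeedSequence.spawn`` so that changing one group's size never
    reshuffles the other tumors.
    """
    protocol = protocol or AcquisitionProtocol()
    noise = noise if noise is not None else NoiseModel()
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    cov_ss, tumor_root = root.spawn(2)
    cov_rng = np.random.default_rng(cov_ss)

    samples: list[TumorSample] = []
    streams = tumor_root.spawn(control.n_tumors + emt.n_tumors)
    i = 0
    for spec in (control, emt):
        covs = sample_tumor_covariates(spec, spec.n_tumors, cov_rng)
        for j in range(spec.n_tumors):
            samples.append(
                make_tumor(
                    spec,
                    protocol,
                    noise,
                    streams[i],
                    tumor_id=f"{spec.label}-{j + 1:02d}",
                    covariates=covs.iloc[j],
                )
            )
            i += 1
    return samples
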