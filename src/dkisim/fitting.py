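"""Voxel-wise diffusion model fitting.

Two signal representations are fitted per voxel:

* monoexponential:  S(b) = S0 * exp(-b * ADC)
* kurtosis:         S(b) = S0 * exp(-b * D + b^2 * D^2 * K / 6)

The ADC fit is an ordinary least-squares line on ln(S) vs b by default
(slope = -ADC), with an optional nonlinear signal-domain alternative.  The
kurtosis fit minimises the residual sum of squares in the signal domain
with the Levenberg-Marquardt algorithm (MINPACK via lmfit, with bound
transforms), initialised from a quadratic cumulant fit of ln(S) on
(b, b^2).  D is constrained to (1e-6, 1e-2) mm2/s and K to [0, k_max]
(default 3): negative excess kurtosis is non-physical for restricted
diffusion in tissue, and the cap stops runaway fits at high noise.

Goodness of fit (R^2) is always reported against the observed signal, not
the log-signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "DirectionalKurtosis",
    "FitOptions",
    "FitResult",
    "ParamMap",
    "fit_adc",
    "fit_dki",
    "fit_dki_directional",
    "fit_maps",
    "kurtosis_signal",
]

D_LOWER = 1e-6
D_UPPER = 1e-2


def kurtosis_signal(
    b: np.ndarray, s0: float, d: float, k: float
) -> np.ndarray:
    """Kurtosis-model signal at the given b-values."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * d + b**2 * d**2 * k / 6.0)


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting knobs.

    ``xtol`` is the relative parameter-change convergence criterion of the
    LM iteration; ``max_iter`` caps function evaluations; ``k_max`` is the
    upper kurtosis bound.  ``adc_method`` selects the ADC estimator
    ('loglinear' OLS or 'nls' signal-domain).  ``adc_b_subset`` optionally
    restricts the ADC fit to the listed b-values (all acquired b by
    default).
    """

    xtol: float = 1e-8
    max_iter: int = 500
    k_max: float = 3.0
    adc_method: str = "loglinear"
    adc_b_subset: tuple[float, ...] | None = None


DEFAULT_OPTIONS = FitOptions()


@dataclass(frozen=True)
class FitResult:
    """Per-voxel fit outcome.  ``adc_hat`` is set by the monoexponential
    fit, ``d_hat``/``k_hat`` by the kurtosis fit."""

    s0_hat: float
    r2: float
    converged: bool
    n_iter: int
    adc_hat: float | None = None
    d_hat: float | None = None
    k_hat: float | None = None


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        # flat observed signal: perfect fit up to numerical noise
        return 1.0 if ss_res <= 1e-18 * np.sum(observed**2) else -np.inf
    return 1.0 - ss_res / ss_tot


def _validate(signal, b_values, min_distinct: int):
    signal = np.asarray(signal, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if signal.shape != b.shape:
        raise ValueError("signal and b_values must have the same length")
    if len(np.unique(b)) < min_distinct:
        raise ValueError(f"need at least {min_distinct} distinct b-values")
    if np.any(signal <= 0):
        raise ValueError("signals must be > 0")
    return signal, b


def fit_adc(
    signal: np.ndarray,
    b_values: np.ndarray,
    options: FitOptions = DEFAULT_OPTIONS,
) -> FitResult:
    """Monoexponential (S0, ADC) estimate for one voxel."""
    signal, b = _validate(signal, b_values, 2)
    if options.adc_b_subset is not None:
        keep = np.isin(b, np.asarray(options.adc_b_subset, dtype=float))
        if keep.sum() < 2:
            raise ValueError("adc_b_subset leaves fewer than 2 points")
        signal, b = signal[keep], b[keep]

    slope, intercept = np.polyfit(b, np.log(signal), 1)
    adc = max(-slope, 0.0)
    s0 = float(np.exp(intercept))
    n_iter = 0

    if options.adc_method == "nls":
        params = lmfit.Parameters()
        params.add("s0", value=s0, min=1e-12)
        params.add("adc", value=max(adc, D_LOWER), min=0.0, max=D_UPPER)
        out = lmfit.minimize(
            lambda p: p["s0"] * np.exp(-b * p["adc"]) - signal,
            params,
            method="leastsq",
            xtol=options.xtol,
            max_nfev=options.max_iter * 3,
        )
        s0 = float(out.params["s0"].value)
        adc = float(out.params["adc"].value)
        n_iter = int(out.nfev)
    elif options.adc_method != "loglinear":
        raise ValueError(f"unknown adc_method {options.adc_method!r}")

    r2 = _r2(signal, s0 * np.exp(-b * adc))
    return FitResult(
        s0_hat=s0, adc_hat=float(adc), r2=r2, converged=True, n_iter=n_iter
    )


def _cumulant_init(signal: np.ndarray, b: np.ndarray, k_max: float):
    """Quadratic OLS of ln(S) on (b, b^2): the cumulant expansion gives
    ln S = ln S0 - b D + b^2 D^2 K / 6, read off as starting values."""
    c2, c1, c0 = np.polyfit(b, np.log(signal), 2)
    d0 = float(np.clip(-c1, D_LOWER * 1.01, D_UPPER * 0.99))
    k0 = float(np.clip(6.0 * c2 / d0**2, 0.0, k_max))
    s0 = float(np.exp(c0))
    return s0, d0, k0


def fit_dki(
    signal: np.ndarray,
    b_values: np.ndarray,
    options: FitOptions = DEFAULT_OPTIONS,
) -> FitResult:
    """Kurtosis-model (S0, D, K) estimate for one voxel.

    Signal-domain Levenberg-Marquardt from a cumulant initialisation; the
    returned parameters never have a larger residual sum of squares than
    the initialisation (the initialisation is kept on the rare occasion the
    bounded iteration ends higher).  Non-convergence is flagged on the
    result, never silent.
    """
    signal, b = _validate(signal, b_values, 3)
    s0_init, d_init, k_init = _cumulant_init(signal, b, options.k_max)

    params = lmfit.Parameters()
    params.add("s0", value=max(s0_init, 1e-12), min=1e-12)
    params.add("d", value=d_init, min=D_LOWER, max=D_UPPER)
    params.add("k", value=k_init, min=0.0, max=options.k_max)

    def residual(p):
        return kurtosis_signal(b, p["s0"].value, p["d"].value, p["k"].value) - signal

    out = lmfit.minimize(
        residual,
        params,
        method="leastsq",
        xtol=options.xtol,
        ftol=options.xtol,
        max_nfev=options.max_iter * 4,
    )
    s0, d, k = (float(out.params[n].value) for n in ("s0", "d", "k"))

    sse_fit = float(np.sum((kurtosis_signal(b, s0, d, k) - signal) ** 2))
    sse_init = float(
        np.sum((kurtosis_signal(b, s0_init, d_init, k_init) - signal) ** 2)
    )
    if sse_fit > sse_init:
        s0, d, k = s0_init, d_init, k_init

    r2 = _r2(signal, kurtosis_signal(b, s0, d, k))
    return FitResult(
        s0_hat=s0,
        d_hat=d,
        k_hat=k,
        r2=r2,
        converged=bool(out.success),
        n_iter=int(out.nfev),
    )


@dataclass
class ParamMap:
    """Grid-shaped parametric maps; NaN marks out-of-mask (or excluded)
    voxels.  ``converged`` is False outside the mask."""

    adc: np.ndarray
    diffusivity: np.ndarray
    kurtosis: np.ndarray
    r2: np.ndarray  # kurtosis-fit R^2
    r2_adc: np.ndarray
    converged: np.ndarray
    convergence_fraction: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.adc.shape

    @classmethod
    def from_truth(cls, truth_d, truth_k, mask) -> "ParamMap":
        """Wrap ground-truth maps in the ParamMap container (no fitting);
        ADC is set to the diffusivity as a Gaussian-limit placeholder."""
        mask = np.asarray(mask, dtype=bool)
        r2 = np.where(mask, 1.0, np.nan)
        return cls(
            adc=np.array(truth_d, dtype=float),
            diffusivity=np.array(truth_d, dtype=float),
            kurtosis=np.array(truth_k, dtype=float),
            r2=r2,
            r2_adc=r2.copy(),
            converged=mask.copy(),
            convergence_fraction=1.0,
        )


def fit_maps(
    volume: np.ndarray,
    mask: np.ndarray,
    b_values: np.ndarray,
    options: FitOptions = DEFAULT_OPTIONS,
) -> ParamMap:
    """Voxel-by-voxel ADC and kurtosis fits over an ROI.

    ``volume`` is (x, y, z, b); ``mask`` is (x, y, z).  Out-of-mask voxels
    carry NaN.  Voxels whose kurtosis fit does not converge keep their
    estimates but are flagged, so ROI summaries can exclude them.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape[:3] != mask.shape:
        raise ValueError("volume and mask grids differ")
    if mask.sum() == 0:
        raise ValueError("mask is empty")

    shape = mask.shape
    adc = np.full(shape, np.nan)
    diff = np.full(shape, np.nan)
    kurt = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    r2_adc = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    coords = np.argwhere(mask)
    n_ok = 0
    for x, y, z in coords:
        s = volume[x, y, z]
        res_a = fit_adc(s, b_values, options)
        res_k = fit_dki(s, b_values, options)
        adc[x, y, z] = res_a.adc_hat
        r2_adc[x, y, z] = res_a.r2
        diff[x, y, z] = res_k.d_hat
        kurt[x, y, z] = res_k.k_hat
        r2[x, y, z] = res_k.r2
        converged[x, y, z] = res_k.converged
        n_ok += res_k.converged

    return ParamMap(
        adc=adc,
        diffusivity=diff,
        kurtosis=kurt,
        r2=r2,
        r2_adc=r2_adc,
        converged=converged,
        convergence_fraction=n_ok / len(coords),
    )


@dataclass(frozen=True)
class DirectionalKurtosis:
    """Comparison of two trace-weighted kurtosis estimators."""

    k_per_direction: tuple[float, ...]
    k_avg_of_fits: float  # fit each direction, then average K
    k_fit_of_average: float  # geometric-mean the signals, then fit once
    difference: float  # fit-of-average minus average-of-fits

    @property
    def relative_error(self) -> float:
        return abs(self.difference) / abs(self.k_avg_of_fits)


def fit_dki_directional(
    per_direction_signals: np.ndarray,
    b_values: np.ndarray,
    options: FitOptions = DEFAULT_OPTIONS,
) -> DirectionalKurtosis:
    """Contrast per-direction kurtosis fitting with trace-weighted fitting.

    Fitting the geometric mean of the three orthogonal-direction signals
    (the trace-weighted image) is not equivalent to averaging the three
    per-direction kurtosis estimates when diffusion is anisotropic; this
    returns both estimators and their discrepancy.
    """
    signals = np.asarray(per_direction_signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] != 3:
        raise ValueError("expected three direction-wise signal vectors")
    ks = tuple(float(fit_dki(s, b_values, options).k_hat) for s in signals)
    k_avg = float(np.mean(ks))
    geo = np.exp(np.mean(np.log(signals), axis=0))
    k_trace = float(fit_dki(geo, b_values, options).k_hat)
    return DirectionalKurtosis(
        k_per_direction=ks,
        k_avg_of_fits=k_avg,
        k_fit_of_average=k_trace,
        difference=k_trace - k_avg,
    )
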