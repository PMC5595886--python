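"""Acquisition protocol and noise-model descriptions.

The acquisition emulated throughout the package is a small-animal
multi-b-value trace-weighted DWI protocol: five diffusion weightings
(b = 0, 500, 1000, 1500, 2000 s/mm2) on a 64x64 in-plane matrix with a
handful of slices.  The protocol object carries everything the simulator
and the fitters need to agree on: the b-value table and the image grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_B_VALUES = (0.0, 500.0, 1000.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Diffusion-weighting table and image-grid geometry.

    Parameters
    ----------
    b_values
        Diffusion weightings in s/mm2, sorted ascending, starting at 0.
    matrix_x, matrix_y
        In-plane grid size in voxels.
    n_slices
        Number of slices.
    voxel_size
        Voxel dimensions in mm (metadata only; carried into NIfTI affines).
    """

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    matrix_x: int = 64
    matrix_y: int = 64
    n_slices: int = 4
    voxel_size: tuple[float, float, float] = (0.78, 0.78, 2.0)

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        object.__setattr__(self, "b_values", b)
        if len(b) < 2:
            raise ValueError("need at least two b-values")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if any(x < 0 for x in b):
            raise ValueError("b-values must be non-negative")
        if list(b) != sorted(b):
            raise ValueError("b-values must be sorted ascending")
        if self.matrix_x < 8 or self.matrix_y < 8:
            raise ValueError("matrix dimensions must be >= 8")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix_x, self.matrix_y, self.n_slices)

    @property
    def b_max(self) -> float:
        return self.b_values[-1]


@dataclass(frozen=True)
class NoiseModel:
    """Magnitude-noise description for the simulated signal.

    ``rician`` replaces each signal s by sqrt((s+e1)^2 + e2^2) with e1, e2
    independent zero-mean Gaussians of standard deviation ``sigma`` —
    the magnitude-reconstruction noise of a single-coil MR image.
    ``none`` is the identity (exact-recovery tests).
    """

    kind: str = "rician"
    sigma: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


NOISELESS = NoiseModel(kind="none", sigma=0.0)
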