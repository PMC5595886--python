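"""Reading and writing the on-disk study layout.

Volumes travel as NIfTI-1 (4D signal with axis order x, y, z, b; 3D masks
and parametric maps on the same affine), b-value tables as FSL-style
whitespace-separated ``.bval`` text files, and tabular data (ground truth,
histology, ROI measurements) as CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import ParamMap
from .phantom import TumorSample
from .protocol import AcquisitionProtocol

__all__ = [
    "affine_for",
    "load_maps",
    "load_nifti",
    "read_bval",
    "save_cohort",
    "save_maps",
    "save_nifti",
    "truth_table",
    "write_bval",
]


def affine_for(protocol: AcquisitionProtocol) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = protocol.voxel_size
    return aff


def save_nifti(data: np.ndarray, path: Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64),
                          np.eye(4) if affine is None else affine)
    img.to_filename(str(path))


def load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_bval(path: Path, b_values) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def read_bval(path: Path) -> np.ndarray:
    return np.array([float(x) for x in Path(path).read_text().split()])


def truth_table(samples: list[TumorSample]) -> pd.DataFrame:
    """One row per tumor: identifiers, tumor-level ground truth and
    histology covariates."""
    return pd.DataFrame(
        [
            {
                "tumor_id": s.tumor_id,
                "group": s.group,
                "d_mean": s.d_mean,
                "k_mean": s.k_mean,
                "cellularity": s.cellularity,
                "ki67": s.ki67,
                "ecadherin": s.ecadherin,
                "volume_mm3": s.volume_mm3,
            }
            for s in samples
        ]
    )


def save_cohort(
    samples: list[TumorSample],
    out_dir: Path,
    protocol: AcquisitionProtocol,
) -> None:
    """Write the simulated cohort: per-tumor DWI + mask NIfTIs, one shared
    ``.bval`` file and the ground-truth/histology CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = affine_for(protocol)
    for s in samples:
        save_nifti(s.signal, out_dir / f"{s.tumor_id}_dwi.nii.gz", aff)
        save_nifti(s.mask.astype(np.float64), out_dir / f"{s.tumor_id}_mask.nii.gz", aff)
    write_bval(out_dir / "protocol.bval", protocol.b_values)
    truth_table(samples).to_csv(out_dir / "truth.csv", index=False)


_MAP_NAMES = ("adc", "diffusivity", "kurtosis", "r2", "r2_adc")


def save_maps(pmap: ParamMap, out_dir: Path, prefix: str,
              affine: np.ndarray | None = None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in _MAP_NAMES:
        save_nifti(getattr(pmap, name), out_dir / f"{prefix}_{name}.nii.gz", affine)
    save_nifti(pmap.converged.astype(np.float64),
               out_dir / f"{prefix}_converged.nii.gz", affine)


def load_maps(out_dir: Path, prefix: str) -> ParamMap:
    out_dir = Path(out_dir)
    arrays = {n: load_nifti(out_dir / f"{prefix}_{n}.nii.gz") for n in _MAP_NAMES}
    converged = load_nifti(out_dir / f"{prefix}_converged.nii.gz") > 0.5
    return ParamMap(
        converged=converged,
        convergence_fraction=float(converged.sum())
        / max(int(np.isfinite(arrays["r2"]).sum()), 1),
        **arrays,
    )
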