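"""Reading, validation and overlap metrics for 4D binary segmentation series.

A series is a stack of per-cardiac-phase 3D binary masks sharing one voxel
grid.  Masks come from any segmentation source (for the aorta typically a
trained network's output); this module only handles label volumes, never
grey-value images.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    """Raised for invalid segmentation input."""


@dataclass
class SegmentationSeries:
    """A 4D binary mask stack with voxel geometry.

    Parameters
    ----------
    data
        Binary array indexed ``(phase, x, y, z)`` (uint8, values 0/1).
    affine
        4x4 voxel-index -> world-mm transform (RAS+ convention, voxel
        centers).  World coordinates of index ``(i, j, k)`` are
        ``affine @ (i, j, k, 1)``.
    phase_duration_ms
        Optional temporal resolution per cardiac phase.
    """

    data: np.ndarray
    affine: np.ndarray
    phase_duration_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise MaskError(f"expected 4D (phase, x, y, z) data, got {self.data.ndim}D")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise MaskError(f"mask values must be 0/1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        if self.affine.shape != (4, 4):
            raise MaskError("affine must be 4x4")
        if self.n_phases < 2:
            raise MaskError("a series needs at least 2 cardiac phases")
        counts = self.data.reshape(self.n_phases, -1).sum(axis=1)
        if (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            raise MaskError(f"empty phase: phase {empty} has no foreground voxels")
        if (self.spacing <= 0).any():
            raise MaskError("voxel spacing must be positive")

    @property
    def n_phases(self) -> int:
        return int(self.data.shape[0])

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def phase(self, t: int) -> np.ndarray:
        """3D mask of cardiac phase ``t``."""
        return self.data[t]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm (voxel centers)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def _binarize(arr: np.ndarray) -> np.ndarray:
    # Fractional values (resampled probabilities) threshold at 0.5.
    return (np.asarray(arr) > 0.5).astype(np.uint8)


def _check_anisotropy(spacing: np.ndarray) -> None:
    if spacing.max() > 1.1 * spacing.min():
        warnings.warn(
            f"anisotropic voxels: spacing {np.round(spacing, 4)} mm differs by "
            ">10% between axes",
            stacklevel=3,
        )


def read_mask_series(
    path: str | Path | Sequence[str | Path],
    phase_duration_ms: float | None = None,
) -> SegmentationSeries:
    """Read a segmentation series from one 4D NIfTI or an ordered list of 3D NIfTIs.

    A single path must name a 4D volume (phase on the last NIfTI axis).  A
    sequence of paths is taken as per-phase 3D volumes; they are sorted
    lexicographically with zero-padding of any embedded phase index, so
    ``mask_2.nii`` orders before ``mask_10.nii``.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 4:
            raise MaskError(
                f"{p} is {arr.ndim}D; a single file must be 4D "
                "(pass a list of 3D files for per-phase masks)"
            )
        data = np.moveaxis(_binarize(arr), 3, 0)
        affine = np.asarray(img.affine, dtype=float)
    else:
        paths = sorted((Path(q) for q in path), key=_phase_sort_key)
        if not paths:
            raise MaskError("empty file list")
        vols, affine = [], None
        for q in paths:
            if not q.exists():
                raise FileNotFoundError(q)
            img = nib.load(str(q))
            arr = np.asanyarray(img.dataobj)
            if arr.ndim != 3:
                raise MaskError(f"{q} is {arr.ndim}D; per-phase files must be 3D")
            if affine is None:
                affine = np.asarray(img.affine, dtype=float)
            elif not np.allclose(img.affine, affine, atol=1e-6):
                raise MaskError(f"{q}: affine differs from first phase")
            vols.append(_binarize(arr))
        data = np.stack(vols, axis=0)

    series = SegmentationSeries(data, affine, phase_duration_ms=phase_duration_ms)
    _check_anisotropy(series.spacing)
    return series


def _phase_sort_key(p: Path) -> str:
    # zero-pad every digit run so phase 10 sorts after phase 2
    return re.sub(r"\d+", lambda m: m.group(0).zfill(8), p.name)


def write_mask_series(series: SegmentationSeries, path: str | Path) -> Path:
    """Write the series as one 4D NIfTI, preserving the affine."""
    path = Path(path)
    arr = np.moveaxis(series.data, 0, 3).astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, series.affine), str(path))
    return path


@dataclass
class ValidationReport:
    """Per-phase foreground counts, connected components, and warnings."""

    voxel_counts: list[int]
    component_counts: list[int]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "voxel_counts": self.voxel_counts,
                "component_counts": self.component_counts,
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def validate_series(series: SegmentationSeries) -> ValidationReport:
    """Report per-phase statistics and flag suspicious masks.

    Warnings (never errors): more than one connected component in a phase,
    and a phase-to-phase foreground-volume jump above 30%.
    """
    counts, comps, warns = [], [], []
    for t in range(series.n_phases):
        mask = series.phase(t)
        counts.append(int(mask.sum()))
        _, n_comp = ndimage.label(mask)
        comps.append(int(n_comp))
        if n_comp > 1:
            warns.append(f"phase {t}: multiple components ({n_comp})")
    for t in range(1, series.n_phases):
        prev, cur = counts[t - 1], counts[t]
        if prev > 0 and abs(cur - prev) / prev > 0.30:
            warns.append(
                f"phase {t}: volume jump {100 * (cur - prev) / prev:+.0f}% "
                f"({prev} -> {cur} voxels)"
            )
    return ValidationReport(counts, comps, warns)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) between binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise MaskError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise MaskError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / (na + nb)
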