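"""Volumetric map container shared by all pipeline stages.

A :class:`VolumeMap` is a named 3D scalar array on a subject's voxel grid.
Invalid voxels are encoded as NaN and are excluded from all downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Registered map roles. Writing a map with an unknown role is an error so
#: that manifests stay self-describing.
KNOWN_ROLES = frozenset(
    {
        "MWF_NNLS",
        "MWF_SPIJN",
        "MWF",
        "ihMTR",
        "MTsat",
        "R1",
        "A_app",
        "PD",
        "MTV",
        "MVF",
        "AVF",
        "NMVF",
        "g",
        "v_ic",
        "v_iso",
        "truth",
        "mask",
        "other",
    }
)


@dataclass
class VolumeMap:
    """A named 3D scalar map with a spatial affine.

    Parameters
    ----------
    values
        3D float array; NaN marks invalid voxels.
    affine
        4x4 voxel-to-world transform (must be invertible).
    role
        One of :data:`KNOWN_ROLES`.
    units
        Free-form unit string ("%", "1/s", "" for fractions).
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    role: str = "other"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeMap requires a 3D array, got ndim={self.values.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.role not in KNOWN_ROLES:
            raise ValueError(f"unknown map role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of finite (valid) voxels."""
        return np.isfinite(self.values)

    def copy(self, role: str | None = None, units: str | None = None) -> "VolumeMap":
        return VolumeMap(
            values=self.values.copy(),
            affine=self.affine.copy(),
            role=self.role if role is None else role,
            units=self.units if units is None else units,
        )

    def like(self, values: np.ndarray, role: str, units: str = "") -> "VolumeMap":
        """New map on this map's grid."""
        return VolumeMap(values=np.asarray(values, float), affine=self.affine.copy(), role=role, units=units)


def check_same_grid(*maps: VolumeMap) -> None:
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"maps are on different grids: {sorted(shapes)}")
    ref = maps[0].affine
    for m in maps[1:]:
        if not np.allclose(m.affine, ref, atol=1e-6):
            raise ValueError("maps have mismatched affines")
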