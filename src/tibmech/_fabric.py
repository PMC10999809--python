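"""Fabric tensor estimation by the mean intercept length (MIL) method.

For a set of quasi-uniform test directions, parallel line probes are cast
through a domain (a sphere around an element centroid, or a whole mask) and
the mean intercept length MIL(d) = total probe length in bone / number of
bone intercepts is accumulated. An ellipsoid d^T A d = 1/MIL(d)^2 is fitted
by least squares; the fabric tensor is M = A^(-1/2) with eigenvalues
normalized to mean 1 (m1 <= m2 <= m3, DA = m3/m1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FabricTensor", "mil_directions", "mil_fabric", "fabric_tensor"]


@dataclass
class FabricTensor:
    """Symmetric positive-definite fabric tensor, eigenvalues mean-1."""

    M: np.ndarray  # 3x3, global (x, y, z) frame
    eigenvalues: np.ndarray  # ascending, sum = 3
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    isotropic_fallback: bool = False

    @property
    def degree_of_anisotropy(self) -> float:
        return float(self.eigenvalues[-1] / self.eigenvalues[0])

    @classmethod
    def isotropic(cls, fallback: bool = True) -> "FabricTensor":
        return cls(np.eye(3), np.ones(3), np.eye(3), isotropic_fallback=fallback)

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "FabricTensor":
        M = 0.5 * (M + M.T)
        w, V = np.linalg.eigh(M)
        w = np.clip(w, 1e-9, None)
        w = 3.0 * w / w.sum()
        return cls(V @ np.diag(w) @ V.T, w, V)


def mil_directions(n: int = 49) -> np.ndarray:
    """Quasi-uniform unit directions on the hemisphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = i / n  # upper hemisphere suffices: MIL is even in d
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)  # (x, y, z)


_BUNDLE_CACHE: dict = {}


def _bundles(n_directions: int, radius_vox: float, step: float, line_spacing: float):
    """Cached (directions, line-bundle offsets) for repeated per-element calls."""
    key = (n_directions, round(float(radius_vox), 6), step, line_spacing)
    if key not in _BUNDLE_CACHE:
        dirs = mil_directions(n_directions)
        _BUNDLE_CACHE[key] = (dirs, [_line_bundle(d, radius_vox, step, line_spacing) for d in dirs])
        if len(_BUNDLE_CACHE) > 32:
            _BUNDLE_CACHE.pop(next(iter(_BUNDLE_CACHE)))
    return _BUNDLE_CACHE[key]


def _line_bundle(direction: np.ndarray, radius_vox: float, step: float, line_spacing: float):
    """Sample points of a parallel line bundle covering a sphere of given radius.

    Returns offsets of shape (n_lines, n_steps, 3) in voxel units, centred on
    the origin, components ordered (x, y, z).
    """
    d = direction / np.linalg.norm(direction)
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    off = np.arange(-radius_vox, radius_vox + line_spacing / 2, line_spacing)
    t = np.arange(-radius_vox, radius_vox + step / 2, step)
    A, B = np.meshgrid(off, off, indexing="ij")
    keep = A**2 + B**2 <= radius_vox**2
    starts = A[keep][:, None] * e1 + B[keep][:, None] * e2  # (L, 3)
    return starts[:, None, :] + t[None, :, None] * d[None, None, :]


def mil_fabric(
    bone_mask: np.ndarray,
    spacing: float,
    center_vox: np.ndarray | None = None,
    radius_vox: float | None = None,
    domain_mask: np.ndarray | None = None,
    n_directions: int = 49,
    step: float = 0.7,
    line_spacing: float = 2.0,
) -> FabricTensor:
    """MIL fabric of the bone phase within a spherical (or masked) domain.

    ``bone_mask`` is a boolean (z, y, x) array; the domain is the sphere of
    ``radius_vox`` around ``center_vox`` ((x, y, z) voxel coordinates),
    optionally intersected with ``domain_mask``. Falls back to the identity
    (flagged) when no bone or no bone/marrow interface is found.
    """
    nz, ny, nx = bone_mask.shape
    if center_vox is None:
        center_vox = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    if radius_vox is None:
        radius_vox = min(nx, ny, nz) / 2.0 - 1.0
    center_vox = np.asarray(center_vox, dtype=float)

    dirs, bundles = _bundles(n_directions, radius_vox, step, line_spacing)
    inv_mil_sq = np.full(len(dirs), np.nan)
    for k, d in enumerate(dirs):
        pts = bundles[k] + center_vox  # (L, T, 3) x,y,z
        ix = np.rint(pts[..., 0]).astype(np.int64)
        iy = np.rint(pts[..., 1]).astype(np.int64)
        iz = np.rint(pts[..., 2]).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
        ixc, iyc, izc = (np.clip(a, 0, m - 1) for a, m in ((ix, nx), (iy, ny), (iz, nz)))
        valid = inside
        if domain_mask is not None:
            valid = valid & domain_mask[izc, iyc, ixc]
        bone = bone_mask[izc, iyc, ixc] & valid
        n_bone = int(bone.sum())
        # intercepts: bone/marrow interface crossings (0 -> 1 transitions
        # between consecutive in-domain samples, so domain entry does not
        # count); zero for solid or empty content -> isotropic fallback
        entries = int((valid[:, 1:] & valid[:, :-1] & bone[:, 1:] & ~bone[:, :-1]).sum())
        if n_bone == 0 or entries == 0:
            continue
        mil = n_bone * step * spacing / entries
        inv_mil_sq[k] = 1.0 / mil**2

    ok = np.isfinite(inv_mil_sq)
    if ok.sum() < 6:
        return FabricTensor.isotropic()
    D = dirs[ok]
    G = np.column_stack(
        [D[:, 0] ** 2, D[:, 1] ** 2, D[:, 2] ** 2,
         2 * D[:, 0] * D[:, 1], 2 * D[:, 0] * D[:, 2], 2 * D[:, 1] * D[:, 2]]
    )
    coef, *_ = np.linalg.lstsq(G, inv_mil_sq[ok], rcond=None)
    A = np.array(
        [[coef[0], coef[3], coef[4]], [coef[3], coef[1], coef[5]], [coef[4], coef[5], coef[2]]]
    )
    w, V = np.linalg.eigh(A)
    if not np.all(np.isfinite(w)) or w.max() <= 0:
        return FabricTensor.isotropic()
    # near-degenerate structures (ideal plates/rods) give a rank-deficient
    # quadric; floor the eigenvalues at 1 % of the largest (caps DA at 10)
    w = np.clip(w, 1e-2 * w.max(), None)
    m = 1.0 / np.sqrt(w)
    m = 3.0 * m / m.sum()
    order = np.argsort(m)
    m, V = m[order], V[:, order]
    M = V @ np.diag(m) @ V.T
    return FabricTensor(M, m, V)


def fabric_tensor(
    labels_or_mask,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    n_directions: int = 49,
    spacing: float | None = None,
) -> FabricTensor:
    """MIL fabric within a sphere of ``radius_mm`` at ``center_mm`` (x, y, z).

    Accepts a LabelVolume (bone = labels > 0) or a boolean mask plus
    ``spacing``. The sphere must intersect the volume; with no bone or no
    interface the isotropic fallback is returned, flagged.
    """
    if hasattr(labels_or_mask, "labels"):
        bone = labels_or_mask.labels > 0
        spacing = labels_or_mask.spacing
    else:
        bone = np.asarray(labels_or_mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing required when passing a raw mask")
    center_vox = np.asarray(center_mm, dtype=float) / spacing
    nz, ny, nx = bone.shape
    if not (
        -radius_mm / spacing <= center_vox[0] <= nx + radius_mm / spacing
        and -radius_mm / spacing <= center_vox[1] <= ny + radius_mm / spacing
        and -radius_mm / spacing <= center_vox[2] <= nz + radius_mm / spacing
    ):
        raise ValueError("sphere does not intersect the volume")
    return mil_fabric(bone, spacing, center_vox=center_vox, radius_vox=radius_mm / spacing,
                      n_directions=n_directions)
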