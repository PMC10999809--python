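"""Density/fabric-based orthotropic bone material (Zysset-Curnier form).

In the fabric eigenframe the engineering constants follow power laws of the
bone volume fraction rho and the (mean-1 normalized) fabric eigenvalues m_i:

    E_i    = E0  * rho^k * m_i^(2l)
    nu_ij  = nu0 * (m_i / m_j)^l
    G_ij   = mu0 * rho^k * (m_i m_j)^l

assembled as the standard orthotropic compliance and rotated to the global
frame. The yield surface is an ellipsoid in Mandel stress space, diagonal in
the fabric eigenframe, with radii

    sigma_y,i = sigma0 * rho^p * m_i^(2q),   tau_y,ij = tau0 * rho^p * (m_i m_j)^q

Perfect plasticity: the surface neither hardens nor softens. The global
stiffness and yield-quadric matrices are scaled by the calibration factors
0.942 (stiffness) and 0.78 (strength, applied to the stress radii).

All 6-vector/6x6 algebra uses Mandel notation (sqrt(2) on shear components)
so 6-vectors carry the tensor inner product and rotations are orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fabric import FabricTensor

__all__ = [
    "MaterialParams",
    "ElementMaterial",
    "mandel_rotation",
    "stiffness_matrix",
    "yield_quadric",
    "make_material",
]

_SQ2 = np.sqrt(2.0)


@dataclass
class MaterialParams:
    """Constitutive constants (MPa where dimensional) with literature-family defaults."""

    E0: float = 9759.0  # MPa
    nu0: float = 0.2278
    mu0: float = 3117.0  # MPa
    k: float = 1.91  # density exponent, stiffness
    l: float = 1.1  # fabric exponent
    sigma0: float = 57.0  # MPa, uniaxial yield stress at rho = 1, m = 1
    tau0: float = 29.0  # MPa, shear yield stress at rho = 1, m = 1
    p: float = 1.82  # density exponent, strength
    q: float = 1.1  # fabric exponent, strength
    stiffness_scale: float = 0.942
    strength_scale: float = 0.78
    rho_min: float = 0.01


@dataclass
class ElementMaterial:
    """Per-element homogenized material state."""

    rho: float  # bone volume fraction in (0, 1]
    fabric: FabricTensor
    C: np.ndarray  # 6x6 Mandel stiffness, global frame, MPa
    Q: np.ndarray  # 6x6 Mandel yield quadric, global frame, 1/MPa^2
    flags: list = field(default_factory=list)


_MANDEL_BASIS = None


def _mandel_basis() -> np.ndarray:
    """Orthonormal Mandel basis tensors, order 11, 22, 33, 23, 13, 12."""
    global _MANDEL_BASIS
    if _MANDEL_BASIS is None:
        idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
        B = np.zeros((6, 3, 3))
        for a, (i, j) in enumerate(idx):
            if i == j:
                B[a, i, j] = 1.0
            else:
                B[a, i, j] = B[a, j, i] = 1.0 / _SQ2
        _MANDEL_BASIS = B
    return _MANDEL_BASIS


def mandel_rotation(R: np.ndarray) -> np.ndarray:
    """6x6 Mandel-basis rotation for a 3x3 rotation R: T_ab = B_a : R B_b R^T.

    Orthogonal, so rotating stiffness/quadric matrices is T @ X @ T.T.
    """
    B = _mandel_basis()
    RB = np.einsum("ik,bkl,jl->bij", R, B, R)
    return np.einsum("aij,bij->ab", B, RB)


def _compliance_eigenframe(rho: float, m: np.ndarray, par: MaterialParams) -> np.ndarray:
    E = par.E0 * rho**par.k * m ** (2 * par.l)
    S = np.zeros((6, 6))
    for i in range(3):
        S[i, i] = 1.0 / E[i]
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        nu_ij = par.nu0 * (m[i] / m[j]) ** par.l
        S[i, j] = S[j, i] = -nu_ij / E[i]
    shear_pairs = [(1, 2), (0, 2), (0, 1)]  # rows 4, 5, 6
    for a, (i, j) in enumerate(shear_pairs):
        G = par.mu0 * rho**par.k * (m[i] * m[j]) ** par.l
        S[3 + a, 3 + a] = 1.0 / (2.0 * G)  # Mandel shear compliance
    return S


def stiffness_matrix(rho: float, fabric: FabricTensor, par: MaterialParams) -> np.ndarray:
    """Global-frame 6x6 Mandel stiffness, scaled by the stiffness factor."""
    rho = float(np.clip(rho, par.rho_min, 1.0))
    S = _compliance_eigenframe(rho, fabric.eigenvalues, par)
    C = np.linalg.inv(S)
    R6 = mandel_rotation(fabric.eigenvectors)  # eigenframe -> global
    return par.stiffness_scale * (R6 @ C @ R6.T)


def yield_quadric(rho: float, fabric: FabricTensor, par: MaterialParams) -> np.ndarray:
    """Global-frame yield quadric Q: yield surface is sigma^T Q sigma = 1."""
    rho = float(np.clip(rho, par.rho_min, 1.0))
    m = fabric.eigenvalues
    sy = par.strength_scale * par.sigma0 * rho**par.p * m ** (2 * par.q)
    shear_pairs = [(1, 2), (0, 2), (0, 1)]
    ty = np.array(
        [par.strength_scale * par.tau0 * rho**par.p * (m[i] * m[j]) ** par.q for i, j in shear_pairs]
    )
    Qd = np.diag(np.concatenate([1.0 / sy**2, 1.0 / (2.0 * ty**2)]))
    R6 = mandel_rotation(fabric.eigenvectors)
    return R6 @ Qd @ R6.T


def make_material(
    rho: float, fabric: FabricTensor, par: MaterialParams | None = None
) -> ElementMaterial:
    par = par or MaterialParams()
    flags = []
    if rho < par.rho_min:
        flags.append("rho_floored")
    if rho > 1.0:
        rho = 1.0
    rho_eff = float(np.clip(rho, par.rho_min, 1.0))
    return ElementMaterial(
        rho_eff,
        fabric,
        stiffness_matrix(rho_eff, fabric, par),
        yield_quadric(rho_eff, fabric, par),
        flags,
    )


def strain_to_mandel(eps: np.ndarray) -> np.ndarray:
    """3x3 symmetric strain tensor(s) (..., 3, 3) to Mandel 6-vector(s)."""
    return np.stack(
        [
            eps[..., 0, 0], eps[..., 1, 1], eps[..., 2, 2],
            _SQ2 * eps[..., 1, 2], _SQ2 * eps[..., 0, 2], _SQ2 * eps[..., 0, 1],
        ],
        axis=-1,
    )


def mandel_to_tensor(v: np.ndarray) -> np.ndarray:
    """Mandel 6-vector(s) back to symmetric 3x3 tensor(s)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 0] = v[..., 0]
    out[..., 1, 1] = v[..., 1]
    out[..., 2, 2] = v[..., 2]
    out[..., 1, 2] = out[..., 2, 1] = v[..., 3] / _SQ2
    out[..., 0, 2] = out[..., 2, 0] = v[..., 4] / _SQ2
    out[..., 0, 1] = out[..., 1, 0] = v[..., 5] / _SQ2
    return out
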