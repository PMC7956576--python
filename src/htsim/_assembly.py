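"""Sparse assembly of 7-point finite-volume diffusion operators.

Shared by the electro-quasistatic and bioheat solvers.  Face conductances are
supplied per axis (already multiplied by face area / center distance); the
builder emits the symmetric operator over the unknown voxels, folding
Dirichlet neighbors into the right-hand side.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Series (harmonic) mean of two face-side coefficients; 0 if either is 0."""
    s = a + b
    out = np.zeros_like(s)
    nz = s != 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def face_slices(ax: int) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[ax] = slice(0, -1)
    hi[ax] = slice(1, None)
    return tuple(lo), tuple(hi)


def build_diffusion_system(
    face_coefs: list[np.ndarray],
    unknown: np.ndarray,
    dirichlet: np.ndarray,
    dirichlet_values: np.ndarray,
    dtype=np.float64,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble ``A x = b`` over ``unknown`` voxels.

    ``face_coefs[ax]`` has the grid shape reduced by one along ``ax`` and
    holds the conductance of the face between the two adjacent voxels.
    Faces touching voxels that are neither unknown nor Dirichlet must carry
    zero coefficient (the caller enforces the insulating/excluded regions).

    Returns ``(A, b, idx)`` where ``idx`` maps grid voxels to row indices
    (-1 outside the unknown set).
    """
    shape = unknown.shape
    idx = np.full(shape, -1, dtype=np.int64)
    n = int(unknown.sum())
    idx[unknown] = np.arange(n)

    diag = np.zeros(n, dtype=dtype)
    b = np.zeros(n, dtype=dtype)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    for ax, C in enumerate(face_coefs):
        lo, hi = face_slices(ax)
        p = idx[lo].ravel()
        q = idx[hi].ravel()
        c = np.asarray(C, dtype=dtype).ravel()
        u1 = unknown[lo].ravel()
        u2 = unknown[hi].ravel()
        d1 = dirichlet[lo].ravel()
        d2 = dirichlet[hi].ravel()
        t1 = dirichlet_values[lo].ravel()
        t2 = dirichlet_values[hi].ravel()

        act = c != 0
        both = u1 & u2 & act
        rows += [p[both], q[both]]
        cols += [q[both], p[both]]
        vals += [-c[both], -c[both]]
        np.add.at(diag, p[both], c[both])
        np.add.at(diag, q[both], c[both])

        pd = u1 & d2 & act
        np.add.at(diag, p[pd], c[pd])
        np.add.at(b, p[pd], c[pd] * t2[pd])
        qd = u2 & d1 & act
        np.add.at(diag, q[qd], c[qd])
        np.add.at(b, q[qd], c[qd] * t1[qd])

    i = np.concatenate(rows + [np.arange(n)]) if rows else np.arange(n)
    j = np.concatenate(cols + [np.arange(n)]) if cols else np.arange(n)
    v = np.concatenate(vals + [diag]) if vals else diag
    A = sp.coo_matrix((v, (i, j)), shape=(n, n), dtype=dtype).tocsr()
    return A, b, idx
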