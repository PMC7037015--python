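"""Brute-force density-matrix oracle for the chunked pure-shift acquisition.

Independent of the closed-form synthesis: builds the weak-coupling two-spin
Hamiltonian, propagates the density matrix in small time steps, applies the
decoupling element (hard pi on both spins followed by a slice-selective pi
on the active spin) at every chunk boundary, and records Tr[(Ix + i Iy) s].
"""

import numpy as np
from scipy.linalg import expm

_E = np.eye(2)
_sx = np.array([[0, 0.5], [0.5, 0]])
_sy = np.array([[0, -0.5j], [0.5j, 0]])
_sz = np.diag([0.5, -0.5])
IX, IY, IZ = (np.kron(m, _E) for m in (_sx, _sy, _sz))
SX, SY, SZ = (np.kron(_E, m) for m in (_sx, _sy, _sz))


def oracle_zs_fid(
    nu_i: float,
    nu_s: float,
    j_hz: float,
    n_chunks: int,
    chunk_s: float,
    spectral_width_hz: float,
    dt_max_s: float = 10e-6,
) -> np.ndarray:
    """Pure-shift FID of the active I spin in an AX pair, unit amplitude.

    Ideal instantaneous pulses, no relaxation; the signal is normalized so
    the t=0 point is 1.
    """
    H = 2 * np.pi * (nu_i * IZ + nu_s * SZ + j_hz * (IZ @ SZ))
    dwell = 1.0 / spectral_width_hz
    nsub = int(np.ceil(dwell / dt_max_s))
    U = expm(-1j * H * (dwell / nsub))
    Ud = U.conj().T
    # hard pi_x on both spins, then selective pi_x on the active spin:
    # I returns to itself, S is inverted -> J refocused at chunk midpoints
    R = expm(-1j * np.pi * IX) @ expm(-1j * np.pi * (IX + SX))
    Rd = R.conj().T
    sigma = IX + SX
    detect = IX + 1j * IY
    npts = int(round(n_chunks * chunk_s * spectral_width_hz))
    boundaries = {
        int(round((k - 0.5) * chunk_s * spectral_width_hz)) for k in range(1, n_chunks + 1)
    }
    sig = np.empty(npts, complex)
    for idx in range(npts):
        if idx in boundaries:
            sigma = R @ sigma @ Rd
        sig[idx] = np.trace(detect @ sigma)
        for _ in range(nsub):
            sigma = U @ sigma @ Ud
    return sig / sig[0]
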