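"""First-order Born forward model for differential multiport scattering.

The differential scattering problem is linear in the dielectric contrast:
``dS = L_e . deltaO`` where ``dS`` stacks the 55 independent channels of a
reciprocal 10x10 S-matrix and ``L_e`` is assembled from the background field
of each antenna at each voxel.  The full-wave fields a simulator would export
are replaced here by the analytic scalar point-source field in the lossy
homogeneous background, ``G(R) = exp(-j k_b R) / (4 pi R)``; the assembly
entry point also accepts user-supplied field maps (one complex value per
antenna per voxel) so externally simulated fields can be dropped in.

Channel ordering is the upper triangle in row-major order with 1-based
antenna indices: (1,1), (1,2), ..., (1,10), (2,2), ..., (10,10).  This string
is serialized with every dataset and operator.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
from scipy.constants import c as C_LIGHT

from .scenario import (
    AntennaArray,
    ContrastMap,
    ImagingGrid,
    Medium,
    complex_permittivity,
)

logger = logging.getLogger(__name__)

N_PORTS = 10
N_CHANNELS = N_PORTS * (N_PORTS + 1) // 2  # 55

#: serialized tag of the canonical channel ordering
CHANNEL_ORDERING = "upper-triangle-row-major-1based-v1"

_MM = 1.0e-3  # mm -> m


def channel_pairs(n_ports: int = N_PORTS) -> list[tuple[int, int]]:
    """0-based (m, n) port pairs, m <= n, row-major upper triangle."""
    return [(m, n) for m in range(n_ports) for n in range(m, n_ports)]


def pack_channels(S: np.ndarray) -> np.ndarray:
    """Extract the independent upper-triangle channels of a square matrix."""
    S = np.asarray(S)
    n = S.shape[0]
    iu = np.triu_indices(n)
    return S[iu]


def unpack_channels(v: np.ndarray, n_ports: int = N_PORTS) -> np.ndarray:
    """Inverse of :func:`pack_channels`: symmetric (reciprocal) square matrix."""
    v = np.asarray(v)
    if v.size != n_ports * (n_ports + 1) // 2:
        raise ValueError(f"expected {n_ports*(n_ports+1)//2} channels, got {v.size}")
    S = np.zeros((n_ports, n_ports), dtype=v.dtype)
    iu = np.triu_indices(n_ports)
    S[iu] = v
    S[(iu[1], iu[0])] = v
    return S


@dataclass(frozen=True)
class SMatrix:
    """Complex reciprocal n-port scattering matrix at a single frequency."""

    entries: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        S = np.asarray(self.entries, dtype=complex)
        object.__setattr__(self, "entries", S)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("entries must be a square matrix")

    @property
    def n_ports(self) -> int:
        return self.entries.shape[0]

    def check_reciprocity(self, tol: float = 1e-8) -> None:
        err = np.max(np.abs(self.entries - self.entries.T))
        if err > tol:
            raise ValueError(f"S-matrix not reciprocal: max |S - S^T| = {err:.3g}")


def default_background_smatrix(frequency: float = 1.0e9) -> SMatrix:
    """Fixed reference (stroke-free) S-matrix.

    A documented placeholder: -0.2 on the diagonal (a well-matched antenna
    reflection) and 0.01 off-diagonal (weak transmission through the lossy
    medium).  Only differences from this reference enter the imaging path, so
    the choice is immaterial there; for classification it is a constant offset
    removed by feature centering.
    """
    S = np.full((N_PORTS, N_PORTS), 0.01 + 0j)
    np.fill_diagonal(S, -0.2 + 0j)
    return SMatrix(S, frequency)


def background_wavenumber(background: Medium, frequency: float) -> complex:
    """Complex background wavenumber ``k_b = (2 pi f / c) sqrt(eps_c)`` (rad/m).

    Branch chosen with ``Re(k_b) > 0`` and ``Im(k_b) <= 0`` so forward waves
    decay under the ``exp(+j w t)`` convention.
    """
    ec = complex_permittivity(background, frequency)
    k = 2.0 * np.pi * frequency / C_LIGHT * np.sqrt(ec)
    if k.real < 0:
        k = -k
    return complex(k)


def greens_function(src_mm, obs_mm, k_b: complex):
    """Scalar lossy-medium point-source field ``exp(-j k_b R)/(4 pi R)``.

    Positions in mm (R converted to metres).  Broadcasts over trailing point
    arrays; coincident points raise.
    """
    src = np.asarray(src_mm, float)
    obs = np.asarray(obs_mm, float)
    R = np.linalg.norm(obs - src, axis=-1) * _MM
    if np.any(R == 0.0):
        raise ValueError("source and observation points coincide (R = 0)")
    return np.exp(-1j * k_b * R) / (4.0 * np.pi * R)


@dataclass(frozen=True)
class BornOperator:
    """Linear map from voxel contrast to the differential channel vector.

    ``matrix`` has one row per channel (m <= n, row-major) and one column per
    masked grid voxel.  Reciprocity holds by construction: the row for (m, n)
    is computed from the symmetric field product E_m * E_n.
    """

    matrix: np.ndarray
    grid: ImagingGrid
    k_b: complex
    c0: float = 1.0
    channel_ordering: str = CHANNEL_ORDERING

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", M)
        if M.shape[1] != self.grid.n_voxels:
            raise ValueError("operator columns must match grid voxels")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def assemble_operator(
    array: AntennaArray,
    grid: ImagingGrid,
    background: Medium,
    c0: float = 1.0,
    field_maps: np.ndarray | None = None,
) -> BornOperator:
    """Assemble the Born operator on a masked grid.

    Entry for channel (m, n) and voxel v:
    ``L[(m,n), v] = c0 * k_b^2 * E_m(v) * E_n(v) * dV`` with dV the voxel
    volume in m^3.  ``E`` defaults to the analytic point-source field; pass
    ``field_maps`` (n_antennas x n_voxels complex) to use exported fields
    instead.  ``c0`` is the overall calibration constant (default 1:
    reconstructions are in relative-contrast units).

    A voxel coincident with an antenna is excluded (zeroed column) with a
    logged warning, preserving grid/operator column alignment.
    """
    k_b = background_wavenumber(background, array.frequency)
    pos = array.positions
    n_ant = pos.shape[0]
    centers = grid.centers

    if field_maps is not None:
        E = np.asarray(field_maps, dtype=complex)
        if E.shape != (n_ant, grid.n_voxels):
            raise ValueError(
                f"field_maps must be ({n_ant}, {grid.n_voxels}), got {E.shape}"
            )
    else:
        R = np.linalg.norm(centers[None, :, :] - pos[:, None, :], axis=-1) * _MM
        coincident = np.any(R == 0.0, axis=0)
        if np.any(coincident):
            logger.warning(
                "%d voxel(s) coincide with an antenna; excluded from operator",
                int(coincident.sum()),
            )
            R[:, coincident] = np.inf
        E = np.exp(-1j * k_b * R) / (4.0 * np.pi * R)
        E[:, coincident] = 0.0

    dV = grid.voxel_volume_mm3 * _MM**3
    pairs = channel_pairs(n_ant)
    L = np.empty((len(pairs), grid.n_voxels), dtype=complex)
    for row, (m, n) in enumerate(pairs):
        L[row] = E[m] * E[n]
    L *= c0 * k_b**2 * dV
    return BornOperator(L, grid, k_b, c0)


def forward_dS(operator: BornOperator, contrast: ContrastMap) -> np.ndarray:
    """Differential channel vector ``L . deltaO`` (length 55 for 10 ports)."""
    if not operator.grid.same_geometry(contrast.grid):
        raise ValueError("contrast map is not defined on the operator's grid")
    return operator.matrix @ contrast.values


def synthesize_smatrix(
    background_S: SMatrix,
    dS: np.ndarray,
    noise_std: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SMatrix:
    """Reciprocal S-matrix ``S = S_bg + unpack(dS) + noise``.

    ``noise_std`` is the per-entry standard deviation of the complex noise,
    ``sqrt(E|n|^2)`` (real and imaginary parts i.i.d. N(0, noise_std^2/2)).
    The dataset layer sets it to ``noise_level * RMS(|dS|)`` over the
    reference dataset, emulating receiver noise relative to the differential
    signal.  Noise is drawn per independent channel and symmetrized, so
    reciprocity holds exactly.  Seeded and reproducible.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be >= 0")
    n = background_S.n_ports
    S = background_S.entries + unpack_channels(np.asarray(dS, complex), n)
    if noise_std > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        n_ch = n * (n + 1) // 2
        noise = gen.normal(scale=noise_std / np.sqrt(2.0), size=(n_ch, 2))
        S = S + unpack_channels(noise[:, 0] + 1j * noise[:, 1], n)
    return SMatrix(S, background_S.frequency)
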