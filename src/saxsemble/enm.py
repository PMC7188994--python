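"""Anisotropic network model (ANM) normal modes and directional motion scores.

Cα nodes within a distance cutoff are connected by identical Hookean
springs.  The 3M×3M Hessian has off-diagonal 3×3 blocks

    H_jk = −(γ / r_jk²) · (r_jk ⊗ r_jk)     for contacts j–k

and diagonal blocks equal to minus the sum of the node's off-diagonal
blocks.  A connected, non-collinear network has exactly six zero
eigenvalues (rigid translations and rotations); the first internal motion
is therefore the seventh mode, counting from the lowest frequency — the
standard mode-7 convention.  Nodes are unit-mass (usual for Cα networks)
and the Hessian is diagonalised densely, which is exact at the sizes
treated here (up to a couple of thousand nodes).

The directional score asks whether a chosen node's displacement in a given
mode points toward a target point (e.g. catalytic residue toward the
substrate).  Because an eigenvector's sign is arbitrary, the mode is
oriented so the node's projection onto the node→target direction is
non-negative, and both the oriented cosine and |cosine| are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import ConnectivityError, DegenerateGeometryError
from .structures import AtomSelector, CA_SELECTOR, Structure

__all__ = [
    "ENMModel",
    "ENMModes",
    "MotionScore",
    "build_enm",
    "compute_modes",
    "directional_motion_score",
    "animate_mode",
]


@dataclass(frozen=True)
class ENMModel:
    node_coords: np.ndarray
    cutoff: float
    gamma: float
    contact_pairs: tuple[tuple[int, int], ...]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def is_connected(self) -> bool:
        n = self.n_nodes
        if not self.contact_pairs:
            return n == 1
        rows = [p[0] for p in self.contact_pairs]
        cols = [p[1] for p in self.contact_pairs]
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


@dataclass(frozen=True)
class ENMModes:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (3M, n_modes), columns orthonormal
    n_zero_modes: int

    def mode(self, rank: int) -> tuple[float, np.ndarray]:
        """1-based mode by ascending frequency (rigid-body modes included)."""
        if not 1 <= rank <= self.eigenvalues.size:
            raise ValueError(f"mode rank {rank} out of range")
        return float(self.eigenvalues[rank - 1]), self.eigenvectors[:, rank - 1]

    def node_displacements(self, rank: int) -> np.ndarray:
        _, vec = self.mode(rank)
        return vec.reshape(-1, 3)


@dataclass(frozen=True)
class MotionScore:
    node_index: int
    target_point: np.ndarray
    cosine: float  # under the oriented-"toward" sign convention
    raw_cosine: float  # under the eigendecomposition's arbitrary sign
    abs_cosine: float
    amplitude: float
    mode_rank: int


def build_enm(
    structure: Structure | np.ndarray,
    selector: AtomSelector = CA_SELECTOR,
    cutoff: float = 12.0,
    gamma: float = 1.0,
) -> ENMModel:
    """Cα elastic network: springs between nodes within *cutoff* Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(structure, Structure):
        sub = structure.select(selector)
        if sub is None:
            raise DegenerateGeometryError("selector matched no nodes")
        coords = sub.coords
    else:
        coords = np.asarray(structure, dtype=float)
    m = coords.shape[0]
    if m < 2:
        raise DegenerateGeometryError("need at least 2 nodes")
    if m >= 3:
        centered = coords - coords.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError("nodes are (nearly) collinear")
    d = squareform(pdist(coords))
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    pairs = tuple(zip(ii.tolist(), jj.tolist()))
    return ENMModel(
        node_coords=coords, cutoff=float(cutoff), gamma=float(gamma),
        contact_pairs=pairs,
    )


def anm_hessian(model: ENMModel) -> np.ndarray:
    """Dense 3M×3M ANM Hessian."""
    m = model.n_nodes
    h = np.zeros((3 * m, 3 * m))
    coords = model.node_coords
    for j, k in model.contact_pairs:
        rvec = coords[k] - coords[j]
        r2 = float(rvec @ rvec)
        block = -(model.gamma / r2) * np.outer(rvec, rvec)
        h[3 * j : 3 * j + 3, 3 * k : 3 * k + 3] = block
        h[3 * k : 3 * k + 3, 3 * j : 3 * j + 3] = block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
        h[3 * k : 3 * k + 3, 3 * k : 3 * k + 3] -= block
    return h


def compute_modes(model: ENMModel, n_modes: int | None = None) -> ENMModes:
    """Lowest-frequency ANM modes (rigid-body zero modes included).

    *n_modes* counts internal (nonzero) modes to keep beyond the zero
    modes; None keeps the full spectrum.  A disconnected network raises
    ConnectivityError, since it carries extra zero modes.
    """
    if not model.is_connected():
        raise ConnectivityError("elastic network is disconnected")
    h = anm_hessian(model)
    evals, evecs = eigh(h)
    evals = np.clip(evals, 0.0, None)  # roundoff can leave tiny negatives
    tol = 1e-8 * max(float(evals[-1]), 1.0)
    n_zero = int(np.sum(evals <= tol))
    n_rigid_expected = 5 if model.n_nodes == 2 else 6
    if n_zero > n_rigid_expected:
        raise ConnectivityError(
            f"{n_zero} zero modes found ({n_rigid_expected} expected); "
            "the network is effectively disconnected"
        )
    if n_modes is not None:
        keep = min(evals.size, n_zero + int(n_modes))
        evals, evecs = evals[:keep], evecs[:, :keep]
    return ENMModes(eigenvalues=evals, eigenvectors=evecs, n_zero_modes=n_zero)


def directional_motion_score(
    modes: ENMModes,
    model: ENMModel,
    node_index: int,
    target_point: np.ndarray,
    mode_rank: int = 7,
) -> MotionScore:
    """Cosine between a node's mode displacement and the node→target direction.

    The eigenvector sign is oriented so the node's displacement projects
    non-negatively onto node→target ("toward" convention); the oriented
    cosine, |cosine| and displacement amplitude are returned.
    """
    if not 0 <= node_index < model.n_nodes:
        raise ValueError(f"node index {node_index} out of range")
    if mode_rank <= modes.n_zero_modes:
        raise ValueError(
            f"mode rank {mode_rank} lies within the {modes.n_zero_modes} "
            "rigid-body modes"
        )
    disp = modes.node_displacements(mode_rank)[node_index]
    amplitude = float(np.linalg.norm(disp))
    target_point = np.asarray(target_point, dtype=float)
    to_target = target_point - model.node_coords[node_index]
    norm = float(np.linalg.norm(to_target))
    if norm == 0 or amplitude == 0:
        raw = 0.0
    else:
        raw = float(disp @ to_target / (amplitude * norm))
    cosine = abs(raw)  # orient the (sign-arbitrary) mode "toward" the target
    return MotionScore(
        node_index=int(node_index),
        target_point=target_point,
        cosine=cosine,
        raw_cosine=raw,
        abs_cosine=abs(raw),
        amplitude=amplitude,
        mode_rank=int(mode_rank),
    )


def animate_mode(
    structure: Structure,
    modes: ENMModes,
    mode_rank: int,
    selector: AtomSelector = CA_SELECTOR,
    amplitude: float = 3.0,
    n_frames: int = 11,
):
    """Multi-frame Cα-trace animation interpolating ±amplitude along a mode.

    Returns an Ensemble of the selected node structure displaced linearly
    from −amplitude to +amplitude (Å at the largest node displacement);
    write it with :func:`saxsemble.write_ensemble` for viewing.
    """
    from .structures import Ensemble

    sub = structure.select(selector)
    if sub is None:
        raise DegenerateGeometryError("selector matched no nodes")
    disp = modes.node_displacements(mode_rank)
    if disp.shape[0] != len(sub):
        raise ValueError("mode dimension does not match the selected nodes")
    disp = disp / np.abs(np.linalg.norm(disp, axis=1)).max()
    frames = []
    for k, a in enumerate(np.linspace(-amplitude, amplitude, n_frames)):
        frame = sub.with_coords(sub.coords + a * disp)
        frame.model_id = k + 1
        frames.append(frame)
    return Ensemble(frames)
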