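"""Scattering curves, the Debye profile calculator, and the reduced χ².

The theoretical profile of a rigid structure is the orientationally
averaged Debye sum

    I(q) = Σ_j Σ_k f_j f_k · sin(q·r_jk) / (q·r_jk)

with the j = k terms contributing f_j².  Two scatterer representations are
provided: ``residue-bead`` places one bead per residue at the Cα (ligand
residues at their heavy-atom centroid) with f equal to the residue's
heavy-atom count, and ``all-atom-constant-f`` uses every atom with f equal
to its atomic number.  Both are deliberately simple, q-independent form
factors without a hydration layer: absolute χ² values against real
experiments are not comparable to hydrated-atom calculators such as CRYSOL,
but all relative behaviour (cluster averaging, mixture weights, model
ranking) is preserved.

The goodness of fit is the σ-weighted reduced χ² over the L points of the
common grid, normalised by L − 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .clustering import ClusterResult
from .errors import (
    CurveFormatError,
    EmptyRangeError,
    MissingSigmaError,
    SelectionError,
)
from .structures import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringCurve",
    "ClusterProfiles",
    "debye_profile",
    "read_saxs_curve",
    "write_saxs_curve",
    "trim_curve",
    "average_cluster_profiles",
    "chi_square",
    "RESIDUE_HEAVY_ATOMS",
]

# heavy (non-H) atom counts of the standard amino acids, backbone included
RESIDUE_HEAVY_ATOMS: dict[str, int] = {
    "GLY": 4, "ALA": 5, "SER": 6, "CYS": 6, "THR": 7, "VAL": 7, "PRO": 7,
    "LEU": 8, "ILE": 8, "ASN": 8, "ASP": 8, "MET": 8, "GLN": 9, "GLU": 9,
    "LYS": 9, "HIS": 10, "ARG": 11, "PHE": 11, "TYR": 12, "TRP": 14,
}
_DEFAULT_RESIDUE_F = 8  # unknown residue: typical side chain

_ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "FE": 26,
    "ZN": 30, "MG": 12, "NA": 11, "CL": 17, "K": 19, "CA": 20, "MN": 25,
}


@dataclass(frozen=True)
class ScatteringCurve:
    """I(q) on a strictly increasing positive q grid, optional per-point σ."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.sigma is not None:
            object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a nonempty 1-D array")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if self.intensity.shape != self.q.shape or not np.all(
            np.isfinite(self.intensity)
        ):
            raise ValueError("intensity must be finite and match q")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive and match q")

    def __len__(self) -> int:
        return self.q.size

    def resample_to(self, q_grid: np.ndarray) -> "ScatteringCurve":
        """Linear interpolation onto another grid (σ interpolated alike)."""
        q_grid = np.asarray(q_grid, dtype=float)
        i = np.interp(q_grid, self.q, self.intensity)
        s = None if self.sigma is None else np.interp(q_grid, self.q, self.sigma)
        return ScatteringCurve(q=q_grid, intensity=i, sigma=s)


@dataclass(frozen=True)
class ClusterProfiles:
    """Per-cluster average model profiles on one common q grid."""

    profiles: tuple[ScatteringCurve, ...]
    cluster_populations: np.ndarray

    def __post_init__(self):
        q0 = self.profiles[0].q
        for p in self.profiles[1:]:
            if not np.array_equal(p.q, q0):
                raise ValueError("all cluster profiles must share one q grid")

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q

    @property
    def n_clusters(self) -> int:
        return len(self.profiles)

    def intensity_matrix(self) -> np.ndarray:
        """(n_clusters, L) stacked intensities."""
        return np.stack([p.intensity for p in self.profiles])

    def mixture(self, weights: Sequence[float]) -> ScatteringCurve:
        w = np.asarray(weights, dtype=float)
        if w.size != self.n_clusters:
            raise ValueError("one weight per cluster required")
        return ScatteringCurve(
            q=self.q, intensity=w @ self.intensity_matrix()
        )


def _residue_beads(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Bead positions and form factors for the residue-bead representation."""
    keys = list(
        zip(
            structure.chain_id.tolist(),
            structure.residue_number.tolist(),
            structure.icode.tolist(),
            structure.is_hetero.tolist(),
        )
    )
    positions, factors = [], []
    seen: dict[tuple, None] = {}
    arr_names = structure.atom_name
    heavy = ~np.isin(np.char.upper(structure.element), ["H", "D"])
    for key in keys:
        if key in seen:
            continue
        seen[key] = None
        mask = (
            (structure.chain_id == key[0])
            & (structure.residue_number == key[1])
            & (structure.icode == key[2])
            & (structure.is_hetero == key[3])
        )
        res_name = str(structure.residue_name[mask][0])
        if not key[3] and res_name in RESIDUE_HEAVY_ATOMS:
            ca = mask & (arr_names == "CA")
            pos = (
                structure.coords[ca][0]
                if ca.any()
                else structure.coords[mask & heavy].mean(axis=0)
            )
            f = RESIDUE_HEAVY_ATOMS[res_name]
        else:
            hm = mask & heavy
            if not hm.any():
                continue
            pos = structure.coords[hm].mean(axis=0)
            f = int(hm.sum())
        positions.append(pos)
        factors.append(float(f))
    if not positions:
        raise SelectionError("structure yields no scattering beads")
    return np.asarray(positions), np.asarray(factors)


def _atom_scatterers(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    elements = np.char.upper(structure.element)
    f = np.array([_ATOMIC_NUMBER.get(e, 6) for e in elements], dtype=float)
    keep = ~np.isin(elements, ["H", "D"])
    if not keep.any():
        raise SelectionError("structure has no heavy atoms")
    return structure.coords[keep], f[keep]


def debye_profile(
    structure: Structure,
    q_grid: np.ndarray,
    representation: Literal["residue-bead", "all-atom-constant-f"] = "residue-bead",
) -> ScatteringCurve:
    """Debye-equation profile of one conformer on *q_grid* (Å⁻¹)."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q values must be positive")
    if representation == "residue-bead":
        pos, f = _residue_beads(structure)
    elif representation == "all-atom-constant-f":
        pos, f = _atom_scatterers(structure)
    else:
        raise ValueError(f"unknown representation {representation!r}")

    self_term = float(np.sum(f**2))
    if pos.shape[0] == 1:
        return ScatteringCurve(q=q, intensity=np.full(q.shape, self_term))
    r = pdist(pos)
    # pair weights f_j * f_k for j < k, matching pdist ordering
    n = f.size
    iu = np.triu_indices(n, k=1)
    w = f[iu[0]] * f[iu[1]]
    intensity = np.empty_like(q)
    for s, qs in enumerate(q):
        x = qs * r
        intensity[s] = self_term + 2.0 * np.sum(w * np.sinc(x / np.pi))
    return ScatteringCurve(q=q, intensity=intensity)


def read_saxs_curve(path: str | Path) -> ScatteringCurve:
    """Read a whitespace-delimited q/I(/σ) text curve (ATSAS .dat dialect).

    Header/comment lines and rows with non-numeric content are skipped
    (counted in the log); a file without at least two numeric columns and
    one usable row raises CurveFormatError.
    """
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    skipped = 0
    ncols: int | None = None
    try:
        text = path.read_text().splitlines()
    except OSError as exc:
        raise CurveFormatError(f"cannot read {path}: {exc}") from exc
    for line in text:
        parts = line.split()
        if len(parts) < 2:
            skipped += 1
            continue
        try:
            vals = tuple(float(p) for p in parts[:3])
        except ValueError:
            skipped += 1
            continue
        if ncols is None:
            ncols = len(vals)
        rows.append(vals[: ncols or 3])
    if skipped:
        logger.info("read_saxs_curve(%s): skipped %d non-data lines", path, skipped)
    if not rows:
        raise CurveFormatError(f"{path}: no numeric data rows")
    data = np.array([r[: min(len(r) for r in rows)] for r in rows])
    q, i = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    order = np.argsort(q)
    try:
        return ScatteringCurve(
            q=q[order], intensity=i[order],
            sigma=None if sigma is None else sigma[order],
        )
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def write_saxs_curve(curve: ScatteringCurve, path: str | Path,
                     header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for k in range(len(curve)):
            if curve.sigma is None:
                fh.write(f"{curve.q[k]:.6e} {curve.intensity[k]:.6e}\n")
            else:
                fh.write(
                    f"{curve.q[k]:.6e} {curve.intensity[k]:.6e} "
                    f"{curve.sigma[k]:.6e}\n"
                )


def trim_curve(curve: ScatteringCurve, q_min: float, q_max: float) -> ScatteringCurve:
    """Restrict to q_min ≤ q ≤ q_max (inclusive); empty result is an error."""
    if q_min >= q_max:
        raise ValueError("q_min must be below q_max")
    mask = (curve.q >= q_min) & (curve.q <= q_max)
    if not mask.any():
        raise EmptyRangeError(f"no points in q range [{q_min}, {q_max}]")
    return ScatteringCurve(
        q=curve.q[mask],
        intensity=curve.intensity[mask],
        sigma=None if curve.sigma is None else curve.sigma[mask],
    )


def average_cluster_profiles(
    ensemble: Ensemble,
    clusters: ClusterResult,
    q_grid: np.ndarray,
    representation: Literal["residue-bead", "all-atom-constant-f"] = "residue-bead",
) -> ClusterProfiles:
    """Unweighted per-cluster mean of single-frame Debye profiles."""
    if clusters.labels.shape[0] != len(ensemble):
        raise ValueError("cluster labels do not match the ensemble")
    q = np.asarray(q_grid, dtype=float)
    sums = np.zeros((clusters.n_clusters, q.size))
    counts = np.zeros(clusters.n_clusters, dtype=int)
    for frame, label in zip(ensemble, clusters.labels):
        sums[label] += debye_profile(frame, q, representation).intensity
        counts[label] += 1
    profiles = tuple(
        ScatteringCurve(q=q, intensity=sums[c] / counts[c])
        for c in range(clusters.n_clusters)
    )
    return ClusterProfiles(
        profiles=profiles, cluster_populations=clusters.populations
    )


def chi_square(model: ScatteringCurve, experiment: ScatteringCurve) -> float:
    """Reduced χ² = (1/(L−1)) Σ_s (I_model − I_exp)² / σ², on a shared grid."""
    if experiment.sigma is None:
        raise MissingSigmaError("experimental curve has no per-point σ")
    if len(model) != len(experiment) or not np.allclose(
        model.q, experiment.q, rtol=0, atol=1e-12
    ):
        raise ValueError("model and experiment must share the q grid; resample first")
    L = len(experiment)
    if L < 2:
        raise ValueError("χ² needs at least 2 points")
    resid = (model.intensity - experiment.intensity) / experiment.sigma
    return float(np.sum(resid**2) / (L - 1))
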