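"""Synthetic structures, ensembles and SAXS experiments with planted truth.

The generator emulates the statistical structure the pipeline assumes:

* a two-lobe "hinge" protein — two rigid helical Cα traces joined at a
  vertex, with HETATM marker pseudo-atoms (residue names ``CAT`` and
  ``SUB``) standing in for a catalytic residue and a substrate site on
  opposite lobes, so closing the hinge draws them together;
* ensembles drawn from a small set of discrete conformational states with
  isotropic Gaussian coordinate jitter and known state populations;
* experimental-style scattering curves built as a known population-weighted
  mixture of per-state profiles plus Gaussian noise with per-point σ.

Every stochastic output is reproducible from its seed, and the exact
planted labels/weights are returned in a :class:`SyntheticTruth` sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EnsembleConsistencyError
from .saxs import ClusterProfiles, ScatteringCurve
from .structures import AtomRecord, Ensemble, Structure

__all__ = [
    "SyntheticTruth",
    "default_q_grid",
    "make_hinge_protein",
    "make_hinge_trajectory",
    "make_state_ensemble",
    "simulate_saxs_experiment",
]

# helix geometry chosen so consecutive Calpha atoms sit exactly 3.8 A apart
_RISE = 1.5
_TURN = np.deg2rad(100.0)
_CA_CA = 3.8
_RADIUS = np.sqrt(_CA_CA**2 - _RISE**2) / (2.0 * np.sin(_TURN / 2.0))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth accompanying a generated object."""

    seed: int | None = None
    state_populations: np.ndarray | None = None
    frame_labels: np.ndarray | None = None
    mixture_weights: np.ndarray | None = None
    noise_sigma_fraction: float | None = None
    state_structures: tuple[Structure, ...] | None = None

    def to_json_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return {
            "seed": self.seed,
            "state_populations": conv(self.state_populations),
            "frame_labels": conv(self.frame_labels),
            "mixture_weights": conv(self.mixture_weights),
            "noise_sigma_fraction": self.noise_sigma_fraction,
        }


def default_q_grid(n_points: int = 100) -> np.ndarray:
    """The usable experimental momentum-transfer range, 0.01–0.20 Å⁻¹."""
    return np.linspace(0.01, 0.20, n_points)


def _helix_points(n: int, axis: np.ndarray, origin: np.ndarray,
                  phase: float = 0.0) -> np.ndarray:
    """Cα trace of an ideal helix of *n* residues along *axis* from *origin*."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    k = np.arange(n)
    ang = phase + k * _TURN
    return (
        origin[None, :]
        + np.outer(k * _RISE, axis)
        + _RADIUS * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    )


def make_hinge_protein(
    n_residues_per_lobe: int = 40, hinge_angle: float = 120.0
) -> Structure:
    """Two rigid helical lobes meeting at a hinge with the given angle (deg).

    Residues 1..n form lobe A and n+1..2n lobe B; consecutive Cα atoms in a
    lobe are exactly 3.8 Å apart.  Two HETATM markers (``CAT`` on the tip
    of lobe A, ``SUB`` on the tip of lobe B, atom name SG) close in on each
    other monotonically as the hinge angle decreases.  Deterministic.
    """
    n = int(n_residues_per_lobe)
    if n < 3:
        raise ValueError("need at least 3 residues per lobe")
    if not 0.0 < hinge_angle <= 180.0:
        raise ValueError("hinge angle must lie in (0, 180] degrees")
    half = np.deg2rad(hinge_angle) / 2.0
    axis_a = np.array([np.cos(half), np.sin(half), 0.0])
    axis_b = np.array([np.cos(half), -np.sin(half), 0.0])
    origin = np.zeros(3)
    lobe_a = _helix_points(n, axis_a, origin)
    lobe_b = _helix_points(n, axis_b, origin + axis_b * _RISE, phase=np.pi / 3)
    coords = np.vstack([lobe_a, lobe_b])

    atoms: list[AtomRecord] = []
    for i, xyz in enumerate(coords):
        atoms.append(
            AtomRecord(
                serial=i + 1, name="CA", element="C", residue_name="ALA",
                residue_number=i + 1, icode="", chain_id="A",
                coords=np.asarray(xyz, dtype=float),
                occupancy=1.0, b_factor=0.0, is_hetero=False,
            )
        )
    # markers sit on the lobe axes just beyond each tip, so their separation
    # is exactly 2·L·sin(angle/2) — strictly monotone in the hinge angle
    arm = (n - 1) * _RISE + 1.9
    markers = [
        ("CAT", origin + arm * axis_a),
        ("SUB", origin + arm * axis_b),
    ]
    for k, (resname, xyz) in enumerate(markers):
        atoms.append(
            AtomRecord(
                serial=2 * n + k + 1, name="SG", element="S",
                residue_name=resname, residue_number=1001 + k, icode="",
                chain_id="A", coords=np.asarray(xyz, dtype=float),
                occupancy=1.0, b_factor=0.0, is_hetero=True,
            )
        )
    return Structure.from_atoms(atoms, metadata={"hinge_angle": float(hinge_angle)})


def make_hinge_trajectory(
    n_residues_per_lobe: int = 40,
    angle_start: float = 150.0,
    angle_stop: float = 60.0,
    n_frames: int = 20,
) -> Ensemble:
    """Noise-free hinge-closing trajectory (marker separation monotone)."""
    angles = np.linspace(angle_start, angle_stop, n_frames)
    return Ensemble(
        [make_hinge_protein(n_residues_per_lobe, a) for a in angles]
    )


def make_state_ensemble(
    states: Sequence[Structure],
    populations: Sequence[float],
    n_frames: int,
    jitter_sigma: float = 0.1,
    seed: int = 0,
) -> tuple[Ensemble, SyntheticTruth]:
    """Ensemble drawn from discrete states with Gaussian coordinate jitter.

    Frame k copies state s (probability ``populations[s]``) and perturbs
    every coordinate with isotropic N(0, jitter_sigma²) noise.  The exact
    per-frame state labels are recorded in the returned truth sidecar.
    """
    pops = np.asarray(populations, dtype=float)
    if len(states) != pops.size:
        raise ValueError("one population per state required")
    if abs(pops.sum() - 1.0) > 1e-9 or np.any(pops < 0):
        raise ValueError("populations must be nonnegative and sum to 1")
    ident = states[0].atom_identity()
    for s in states[1:]:
        if s.atom_identity() != ident:
            raise EnsembleConsistencyError("states must share the atom ordering")
    rng = np.random.default_rng(seed)
    labels = rng.choice(pops.size, size=int(n_frames), p=pops)
    frames = []
    for k, lab in enumerate(labels):
        base = states[lab]
        noise = rng.normal(0.0, jitter_sigma, size=base.coords.shape) \
            if jitter_sigma > 0 else 0.0
        frame = base.with_coords(base.coords + noise)
        frame.model_id = k + 1
        frames.append(frame)
    truth = SyntheticTruth(
        seed=seed,
        state_populations=pops,
        frame_labels=labels,
        state_structures=tuple(states),
    )
    return Ensemble(frames), truth


def simulate_saxs_experiment(
    profiles: ClusterProfiles | Sequence[ScatteringCurve],
    weights: Sequence[float],
    noise_sigma_fraction: float = 0.01,
    seed: int = 0,
) -> tuple[ScatteringCurve, SyntheticTruth]:
    """Experimental-style curve: weighted mixture of profiles plus noise.

    I_exp(q) = Σ P_i·I_i(q) + ε(q) with ε ~ N(0, σ(q)²) and
    σ(q) = noise_sigma_fraction × Σ P_i·I_i(q).  With zero noise fraction a
    nominal σ floor of 0.1% of the mixture stands in for an effectively
    noiseless measurement, keeping the σ-weighted χ² defined while leaving
    the intensities exact.
    """
    if isinstance(profiles, ClusterProfiles):
        curves = profiles.profiles
    else:
        curves = tuple(profiles)
    w = np.asarray(weights, dtype=float)
    if w.size != len(curves):
        raise ValueError("one weight per profile required")
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be nonnegative and sum to 1")
    q = curves[0].q
    for c in curves[1:]:
        if not np.array_equal(c.q, q):
            raise ValueError("profiles must share one q grid")
    mixture = w @ np.stack([c.intensity for c in curves])
    if noise_sigma_fraction < 0:
        raise ValueError("noise fraction must be nonnegative")
    if noise_sigma_fraction > 0:
        sigma = noise_sigma_fraction * mixture
        rng = np.random.default_rng(seed)
        intensity = mixture + rng.normal(0.0, sigma)
    else:
        sigma = 1e-3 * mixture
        intensity = mixture
    curve = ScatteringCurve(q=q, intensity=intensity, sigma=sigma)
    truth = SyntheticTruth(
        seed=seed,
        mixture_weights=w,
        noise_sigma_fraction=float(noise_sigma_fraction),
    )
    return curve, truth
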