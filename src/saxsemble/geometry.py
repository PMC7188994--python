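"""Superposition, RMSD with iterative outlier rejection, and distance observables.

The superposition is the classic least-squares fit (SVD-based, reflection
excluded).  ``iterative_align`` mirrors the behaviour of common "align"
commands: superpose, drop atom pairs deviating more than a multiple of the
current RMSD, repeat — which is how aligned-subset counts such as "236
aligned Cα atoms" arise.  Distance observables support the conventions used
for active-site geometry: a named atom pair (e.g. the catalytic residue's
terminal side-chain atom versus the substrate Sγ), the closest heavy-atom
contact, and centroid separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    AmbiguityError,
    DegenerateGeometryError,
    RejectionCollapseError,
    SelectionError,
)
from .structures import AtomSelector, Ensemble, Structure

__all__ = [
    "AlignmentResult",
    "DistanceObservable",
    "DistanceSeries",
    "kabsch_superpose",
    "iterative_align",
    "measure_distance",
    "distance_trajectory",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Least-squares superposition of A onto B: x ↦ rotation·x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_aligned: int
    n_initial: int
    n_cycles: int = 1

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> AlignmentResult:
    """Optimal proper-rotation superposition of *coords_a* onto *coords_b*.

    Returns the rotation/translation minimising the RMSD of A mapped onto B,
    with the minimised RMSD.  Reflections are excluded (det = +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or a.shape != b.shape:
        raise ValueError("inputs must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv_a = np.linalg.svd(a0, compute_uv=False)
    if sv_a[1] <= 1e-8 * max(sv_a[0], 1.0):
        raise DegenerateGeometryError("reference points are (nearly) collinear")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return AlignmentResult(
        rotation=rot, translation=trans, rmsd=rmsd, n_aligned=n, n_initial=n
    )


def _ca_table(structure: Structure, chain: str | None) -> dict[tuple, int]:
    sel = AtomSelector(atom_names="CA", hetero=False, chain=chain)
    sub_mask = sel.mask(structure)
    idx = np.nonzero(sub_mask)[0]
    table: dict[tuple, int] = {}
    for i in idx:
        key = (
            str(structure.chain_id[i]) if chain is None else "*",
            int(structure.residue_number[i]),
            str(structure.icode[i]),
        )
        # first CA wins on duplicates (altlocs already resolved at read time)
        table.setdefault(key, int(i))
    return table


def iterative_align(
    struct_a: Structure,
    struct_b: Structure,
    *,
    pairing: Literal["resid"] | Mapping[int, int] = "resid",
    chain_a: str | None = None,
    chain_b: str | None = None,
    reject_multiplier: float = 2.0,
    max_cycles: int = 5,
) -> AlignmentResult:
    """Cα superposition with cyclic rejection of outlier pairs.

    ``pairing="resid"`` pairs Cα atoms sharing (chain, residue number,
    insertion code); a mapping ``{residue_number_a: residue_number_b}``
    supplies an explicit cross-protein correspondence (chains then taken
    from *chain_a*/*chain_b*).  Each cycle drops pairs deviating more than
    ``reject_multiplier`` × current RMSD and re-superposes, until the
    aligned set is unchanged or *max_cycles* is reached.
    """
    if reject_multiplier <= 0:
        raise ValueError("reject_multiplier must be positive")
    if isinstance(pairing, Mapping):
        # explicit residue-number correspondence; chains collapsed, so either
        # filter to one chain or use single-chain structures
        ta = {k[1]: v for k, v in _ca_table(struct_a, chain_a).items()}
        tb = {k[1]: v for k, v in _ca_table(struct_b, chain_b).items()}
        pairs = [
            (ta[ra], tb[rb]) for ra, rb in sorted(pairing.items())
            if ra in ta and rb in tb
        ]
    else:
        ta = _ca_table(struct_a, chain_a)
        tb = _ca_table(struct_b, chain_b)
        common = sorted(set(ta) & set(tb))
        pairs = [(ta[k], tb[k]) for k in common]
    if len(pairs) < 3:
        raise SelectionError(f"only {len(pairs)} Cα pairs under the pairing rule")

    idx_a = np.array([p[0] for p in pairs])
    idx_b = np.array([p[1] for p in pairs])
    keep = np.arange(len(pairs))
    n_initial = len(pairs)
    result = None
    cycles = 0
    for _ in range(max(1, max_cycles)):
        cycles += 1
        result = kabsch_superpose(
            struct_a.coords[idx_a[keep]], struct_b.coords[idx_b[keep]]
        )
        dev = np.linalg.norm(
            result.transform(struct_a.coords[idx_a[keep]])
            - struct_b.coords[idx_b[keep]],
            axis=1,
        )
        if result.rmsd < 1e-8:  # already an essentially exact fit
            break
        new_keep = keep[dev <= reject_multiplier * result.rmsd]
        if new_keep.size < 3:
            raise RejectionCollapseError(
                "outlier rejection left fewer than 3 Cα pairs"
            )
        if new_keep.size == keep.size:
            break
        keep = new_keep
    assert result is not None
    return AlignmentResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_aligned=int(keep.size),
        n_initial=n_initial,
        n_cycles=cycles,
    )


@dataclass(frozen=True)
class DistanceObservable:
    """A labelled distance between two atom selections.

    convention:
      * ``named-atom-pair`` — both selectors must resolve to exactly one atom
      * ``closest-heavy-atom`` — minimum over heavy-atom (non-H) pairs
      * ``centroid`` — distance between heavy-atom geometric centroids
    """

    label: str
    selector_a: AtomSelector
    selector_b: AtomSelector
    convention: Literal["named-atom-pair", "closest-heavy-atom", "centroid"] = (
        "named-atom-pair"
    )


@dataclass(frozen=True)
class DistanceSeries:
    observable: DistanceObservable
    values: np.ndarray
    frame_times: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def final(self) -> float:
        return float(self.values[-1])


def _heavy(structure: Structure) -> Structure:
    mask = ~np.isin(np.char.upper(structure.element), ["H", "D", ""])
    if not mask.any():
        raise SelectionError("selection contains no heavy atoms")
    return structure._subset(mask)


def measure_distance(structure: Structure, observable: DistanceObservable) -> float:
    """Evaluate one distance observable on one conformer, in Å."""
    sub_a = structure.select(observable.selector_a)
    sub_b = structure.select(observable.selector_b)
    if sub_a is None or sub_b is None:
        raise SelectionError(
            f"observable {observable.label!r}: a selector matched no atoms"
        )
    if observable.convention == "named-atom-pair":
        if len(sub_a) != 1 or len(sub_b) != 1:
            raise AmbiguityError(
                f"observable {observable.label!r}: named-atom-pair needs exactly "
                f"one atom per side, got {len(sub_a)} and {len(sub_b)}"
            )
        return float(np.linalg.norm(sub_a.coords[0] - sub_b.coords[0]))
    if observable.convention == "closest-heavy-atom":
        ha, hb = _heavy(sub_a), _heavy(sub_b)
        return float(cdist(ha.coords, hb.coords).min())
    if observable.convention == "centroid":
        ha, hb = _heavy(sub_a), _heavy(sub_b)
        return float(
            np.linalg.norm(ha.coords.mean(axis=0) - hb.coords.mean(axis=0))
        )
    raise ValueError(f"unknown convention {observable.convention!r}")


def distance_trajectory(
    ensemble: Ensemble,
    observable: DistanceObservable,
    frame_times: Sequence[float] | None = None,
) -> DistanceSeries:
    """Per-frame evaluation of a distance observable over an ensemble."""
    values = np.array([measure_distance(f, observable) for f in ensemble])
    times = None if frame_times is None else np.asarray(frame_times, dtype=float)
    if times is not None and times.shape[0] != values.shape[0]:
        raise ValueError("frame_times length must equal the frame count")
    return DistanceSeries(observable=observable, values=values, frame_times=times)
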