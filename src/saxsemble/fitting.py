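"""Metropolis Monte-Carlo fitting of cluster population weights.

The model intensity is the population-weighted mixture Σ_i P_i·I_i(q) of
the per-cluster average profiles; the energy being minimised is the reduced
χ² against the experimental curve.  Moves perturb a single weight with a
Gaussian step, clip at zero and renormalise onto the simplex; proposals are
accepted with probability min(1, exp(−Δχ²/T)) at unit temperature (an
optional geometric cooling schedule is available).  The reported weights
are the best ever visited, which makes the result robust to the sampling
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MissingSigmaError
from .saxs import ClusterProfiles, ScatteringCurve, chi_square

__all__ = ["PopulationWeights", "fit_populations", "compare_models"]


@dataclass(frozen=True)
class PopulationWeights:
    weights: np.ndarray
    chi_square: float
    n_steps: int
    seed: int
    acceptance_rate: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if self.chi_square < 0:
            raise ValueError("chi_square must be nonnegative")


def _reduced_chi2(model_i: np.ndarray, exp_i: np.ndarray, sigma: np.ndarray) -> float:
    L = exp_i.size
    return float(np.sum(((model_i - exp_i) / sigma) ** 2) / (L - 1))


def fit_populations(
    profiles: ClusterProfiles,
    experiment: ScatteringCurve,
    n_steps: int = 20000,
    seed: int = 0,
    proposal_scale: float = 0.05,
    *,
    cooling: float | None = None,
) -> PopulationWeights:
    """Fit simplex weights P_i minimising the reduced χ² of the mixture.

    Starts from uniform weights and runs *n_steps* Metropolis steps; with a
    single cluster the exact answer is returned without sampling.  The same
    seed reproduces the identical weight trajectory.  ``cooling`` (e.g.
    0.999) geometrically lowers the temperature each step.
    """
    if experiment.sigma is None:
        raise MissingSigmaError("population fitting requires experimental σ")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    basis = profiles.intensity_matrix()
    exp_on_grid = experiment
    if basis.shape[1] != len(experiment) or not np.allclose(
        profiles.q, experiment.q, rtol=0, atol=1e-12
    ):
        # resample model basis onto the (trimmed) experimental grid
        basis = np.stack(
            [p.resample_to(experiment.q).intensity for p in profiles.profiles]
        )
    n_clusters = basis.shape[0]
    exp_i, sigma = exp_on_grid.intensity, exp_on_grid.sigma

    if n_clusters == 1:
        w = np.array([1.0])
        return PopulationWeights(
            weights=w,
            chi_square=_reduced_chi2(basis[0], exp_i, sigma),
            n_steps=0,
            seed=seed,
            acceptance_rate=1.0,
        )

    rng = np.random.default_rng(seed)
    w = np.full(n_clusters, 1.0 / n_clusters)
    energy = _reduced_chi2(w @ basis, exp_i, sigma)
    best_w, best_e = w.copy(), energy
    temperature = 1.0
    accepted = 0
    for _ in range(n_steps):
        prop = w.copy()
        k = rng.integers(n_clusters)
        prop[k] = max(0.0, prop[k] + rng.normal(0.0, proposal_scale))
        total = prop.sum()
        if total <= 0:
            continue
        prop /= total
        e = _reduced_chi2(prop @ basis, exp_i, sigma)
        if e <= energy or rng.random() < np.exp(-(e - energy) / temperature):
            w, energy = prop, e
            accepted += 1
            if e < best_e:
                best_w, best_e = prop.copy(), e
        if cooling is not None:
            temperature *= cooling
    # exact renormalisation guards against accumulated floating-point drift
    best_w = best_w / best_w.sum()
    return PopulationWeights(
        weights=best_w,
        chi_square=best_e,
        n_steps=n_steps,
        seed=seed,
        acceptance_rate=accepted / n_steps,
    )


def compare_models(
    candidates: Sequence[tuple[str, ScatteringCurve | ClusterProfiles]],
    experiment: ScatteringCurve,
    *,
    n_steps: int = 20000,
    seed: int = 0,
) -> list[dict]:
    """Rank candidate models by χ² against one experimental curve.

    Single-structure candidates are scored directly; multi-cluster
    candidates are scored at their fitted weights.  Returns one record per
    candidate, ascending in χ².
    """
    if not candidates:
        raise ValueError("at least one candidate is required")
    report = []
    for label, model in candidates:
        if isinstance(model, ClusterProfiles):
            fit = fit_populations(model, experiment, n_steps=n_steps, seed=seed)
            report.append(
                {
                    "label": label,
                    "chi_square": fit.chi_square,
                    "weights": fit.weights.tolist(),
                }
            )
        else:
            resampled = model.resample_to(experiment.q)
            report.append(
                {
                    "label": label,
                    "chi_square": chi_square(resampled, experiment),
                    "weights": None,
                }
            )
    report.sort(key=lambda r: r["chi_square"])
    for rank, rec in enumerate(report, start=1):
        rec["rank"] = rank
    return report
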