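"""Residue geometry: barycenters, ensemble-averaged distances, neighbor graphs,
and the sigmoidal distance kernel used for inference and homogenization.

Distances between residues are Euclidean distances between the unweighted
barycenters of their heavy atoms, averaged over the models of the ensemble so
that conformational heterogeneity widens effective neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import Residue, ResidueKey, StructureEnsemble


def residue_barycenter(residue: Residue, heavy_only: bool = True) -> np.ndarray:
    """Unweighted mean position of a residue's atoms (heavy atoms by default).

    Hydrogens are excluded by default because they are absent from most X-ray
    structures; including them would make barycenters depend on the refinement
    protocol rather than the fold.
    """
    atoms = [a for a in residue.atoms if not (heavy_only and a.is_hydrogen)]
    if not atoms:  # hydrogen-only residue: fall back to all atoms
        atoms = residue.atoms
    return np.mean([a.coords for a in atoms], axis=0)


class DistanceMatrix:
    """Symmetric residue-residue distance matrix in Å, averaged over models."""

    def __init__(self, keys: list[ResidueKey], dist: np.ndarray):
        dist = np.asarray(dist, dtype=float)
        if dist.shape != (len(keys), len(keys)):
            raise ValueError("distance matrix shape does not match key count")
        if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0) or np.any(dist < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.keys = list(keys)
        self.dist = dist
        self._index = {k: i for i, k in enumerate(keys)}

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    def index(self, key: ResidueKey) -> int:
        return self._index[key]

    def distance(self, i: ResidueKey, j: ResidueKey) -> float:
        return float(self.dist[self._index[i], self._index[j]])

    def neighbors(self, i: ResidueKey, cutoff: float) -> list[ResidueKey]:
        """All residues j != i with d_ij <= cutoff (closed boundary), any chain."""
        if i not in self._index:
            raise KeyError(f"unknown residue {i}")
        row = self.dist[self._index[i]]
        return [self.keys[j] for j in np.nonzero(row <= cutoff)[0] if self.keys[j] != i]


def ensemble_distances(ens: StructureEnsemble, heavy_only: bool = True) -> DistanceMatrix:
    """Pairwise barycenter distances averaged over all models of the ensemble."""
    n = ens.n_residues
    acc = np.zeros((n, n))
    for model in ens.models:
        bary = np.array([residue_barycenter(r, heavy_only) for r in model])
        acc += cdist(bary, bary)
    return DistanceMatrix(ens.keys, acc / ens.n_models)


@dataclass(frozen=True)
class SigmoidKernel:
    """Logistic distance kernel phi(d) = 1 / (1 + alpha_eps * exp(lambda_c * d)).

    With alpha_eps = eps/(1-eps) and lambda_c = (2/c) * ln((1-eps)/eps) the
    kernel satisfies phi(0) = 1-eps, phi(c/2) = 1/2 and phi(c) = eps exactly:
    a neighbor at zero distance carries full weight, one at the cutoff almost
    none, with a smooth crossover at half the cutoff.
    """

    c: float
    eps: float = 1e-3
    alpha_eps: float = field(init=False)
    lambda_c: float = field(init=False)

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.eps < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        object.__setattr__(self, "alpha_eps", self.eps / (1 - self.eps))
        object.__setattr__(self, "lambda_c", (2.0 / self.c) * np.log((1 - self.eps) / self.eps))

    def phi(self, d):
        """Kernel weight for distance d (Å); scalar or array; strictly decreasing."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distance must be non-negative")
        out = 1.0 / (1.0 + self.alpha_eps * np.exp(self.lambda_c * d))
        return float(out) if out.ndim == 0 else out

    def weight_matrix(self, dm: DistanceMatrix) -> np.ndarray:
        """phi(d_ij) for neighbor pairs (0 < d_ij <= c), zero elsewhere.

        The zero diagonal and the hard cutoff encode the neighbor definition:
        a residue is never its own neighbor and pairs beyond c carry no weight.
        """
        w = self.phi(dm.dist)
        w[dm.dist > self.c] = 0.0
        np.fill_diagonal(w, 0.0)
        return w


def phi(d, kernel: SigmoidKernel):
    """Module-level convenience wrapper around :meth:`SigmoidKernel.phi`."""
    return kernel.phi(d)


def neighbors(i: ResidueKey, dm: DistanceMatrix, cutoff: float) -> list[ResidueKey]:
    """Residues within ``cutoff`` Å of residue ``i`` (closed boundary, any chain)."""
    return dm.neighbors(i, cutoff)
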