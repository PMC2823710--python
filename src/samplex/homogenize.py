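"""Iterative spatial smoothing of confidences (Step 3).

Each residue's confidence is repeatedly re-expressed as a weighted average of
its own *starting* confidence (weight 1) and its neighbors' current
confidences (weight phi(d_ij)):

    rho_i(t+1) = ( rho_i(0) + sum_j phi(d_ij) rho_j(t) ) / ( 1 + sum_j phi(d_ij) )

updated synchronously over all non-excluded residues until the RMSD between
consecutive iterates drops below the tolerance.  Anchoring to the starting
value keeps the iteration a strict contraction (the neighbor weights sum to
less than the denominator), so it converges to the unique solution of the
linear system (I - W) rho = b, and produces spatially coherent blocks rather
than collapsing to a single global consensus.
"""

from __future__ import annotations

import numpy as np

from .core import ConfidenceVector, Status
from .geometry import DistanceMatrix, SigmoidKernel


class ConvergenceError(RuntimeError):
    """Smoothing failed to reach the tolerance within the iteration cap."""


def homogenize(
    conf: ConfidenceVector,
    dm: DistanceMatrix,
    kernel: SigmoidKernel,
    tol: float = 1e-5,
    max_iter: int = 100_000,
    trace: list[tuple[int, float]] | None = None,
) -> ConfidenceVector:
    """Smooth confidences over the residue contact graph until convergence.

    Residues with no neighbor inside the cutoff keep their starting value
    exactly.  Excluded residues take no part, neither as targets nor as
    neighbors.  Pass a list as ``trace`` to collect (iteration, rmsd) pairs.
    """
    keys = [k for k in dm.keys if conf.status.get(k) in (Status.MEASURED, Status.INFERRED)]
    if not keys:
        return conf.copy()
    idx = np.array([dm.index(k) for k in keys])
    w = kernel.weight_matrix(dm)[np.ix_(idx, idx)]
    denom = 1.0 + w.sum(axis=1)
    rho0 = np.array([conf.rho[k] for k in keys])

    rho = rho0.copy()
    for it in range(1, max_iter + 1):
        rho_new = (rho0 + w @ rho) / denom
        rmsd = float(np.sqrt(np.mean((rho_new - rho) ** 2)))
        if trace is not None:
            trace.append((it, rmsd))
        rho = rho_new
        if rmsd < tol:
            break
    else:
        raise ConvergenceError(
            f"homogenization did not converge in {max_iter} iterations (last RMSD {rmsd:g})"
        )

    out = conf.copy()
    # contraction mapping keeps iterates within [-max|rho0|, max|rho0|]; clip
    # only shields against rounding at the boundary
    for k, r in zip(keys, np.clip(rho, -1.0, 1.0)):
        out.rho[k] = float(r)
    return out
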