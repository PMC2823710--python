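"""Inference of confidences for residues without data (Step 2).

A residue with no measurement can still be placed in its structural context:
its confidence is interpolated from measured neighbors by inverse distance
weighting with the sigmoidal kernel,

    rho_i = sum_j phi(d_ij) * rho_j / sum_j phi(d_ij)

over neighbors j within the cutoff that carry measured data.  Fewer than two
such neighbors leave the interpolation unsupported: the residue is excluded
from all further computation and ends with no decision.
"""

from __future__ import annotations

from .core import ConfidenceVector, PerResidueData, Status
from .geometry import DistanceMatrix, SigmoidKernel


def infer_missing(
    conf: ConfidenceVector,
    data: PerResidueData,
    dm: DistanceMatrix,
    kernel: SigmoidKernel,
) -> ConfidenceVector:
    """Assign inferred confidences to missing residues; exclude unsupported ones.

    Only measured residues contribute (single pass): inferred values never
    seed other inferences, so the result does not depend on the order in
    which missing residues are visited.  Measured confidences are untouched.
    """
    out = conf.copy()
    for key in sorted(data.missing):
        if key not in dm:
            out.status[key] = Status.EXCLUDED
            continue
        measured = [
            j for j in dm.neighbors(key, kernel.c) if conf.status.get(j) == Status.MEASURED
        ]
        if len(measured) < 2:
            out.status[key] = Status.EXCLUDED
            out.rho.pop(key, None)
            continue
        weights = [kernel.phi(dm.distance(key, j)) for j in measured]
        total = sum(weights)
        out.rho[key] = sum(w * conf.rho[j] for w, j in zip(weights, measured)) / total
        out.status[key] = Status.INFERRED
    return out
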