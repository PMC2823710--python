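"""The full classification pipeline: data + structure -> per-residue labels.

Order of stages is fixed: guard (relative SD) -> calibration -> confidence
attribution -> inference of missing residues -> homogenization -> decision.
Every source of randomness flows from the single seed in SamplexParams, so a
repeated run is bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .confidence import attribute_confidences, calibrate_extremes
from .core import (
    ClassificationResult,
    PerResidueData,
    SamplexParams,
    StructureEnsemble,
)
from .decision import classify, guard_result, relative_sd
from .geometry import SigmoidKernel, ensemble_distances
from .homogenize import homogenize
from .inference import infer_missing
from . import io as sio

logger = logging.getLogger("samplex")


def _align_data(
    ens: StructureEnsemble, data: PerResidueData, strict: bool
) -> PerResidueData:
    """Reconcile the data table with the structure's residue index.

    Structure residues absent from the table are treated as missing (to be
    inferred); table keys absent from the structure are an error under
    ``strict`` and a warning otherwise.
    """
    structure_keys = set(ens.keys)
    extra = (set(data.values) | data.missing) - structure_keys
    if extra:
        msg = f"{len(extra)} data key(s) not in the structure: {sorted(str(k) for k in extra)[:5]}"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    unlisted = structure_keys - set(data.values) - data.missing
    return PerResidueData(values=dict(data.values), missing=data.missing | unlisted)


def classify_perturbations(
    ens: StructureEnsemble,
    data: PerResidueData,
    params: SamplexParams | None = None,
    force: bool = False,
    strict: bool = False,
) -> ClassificationResult:
    """Run the whole pipeline in memory and return the classification.

    When the relative-SD guard fires (flat data: the protein looks globally
    unperturbed) no classification is attempted unless ``force`` is set.
    """
    params = params or SamplexParams()
    data = _align_data(ens, data, strict)

    report = relative_sd(data, params.sigma_r_guard)
    logger.info("sigma_R = %.1f%% (guard at %.0f%%)", 100 * report.sigma_r, 100 * params.sigma_r_guard)
    if report.triggered and not force:
        logger.warning("relative SD below guard: data look unperturbed, no classification made")
        return guard_result(data, report)

    rng = np.random.default_rng(params.seed)
    calib = calibrate_extremes(data, params, rng)
    logger.info("calibrated k_high = %.4f, k_low = %.4f", calib.k_high, calib.k_low)
    conf = attribute_confidences(data, calib, params, rng)

    dm = ensemble_distances(ens)
    kernel = SigmoidKernel(c=params.neighbor_cutoff, eps=params.epsilon)
    conf_start = infer_missing(conf, data, dm, kernel)

    trace: list[tuple[int, float]] = []
    conf_final = homogenize(
        conf_start, dm, kernel, tol=params.homog_tol, max_iter=params.max_homog_iter, trace=trace
    )
    logger.info("homogenization converged in %d iterations", len(trace))

    result = classify(conf_final, params.decision_threshold, data, report.sigma_r)
    result.rho_start = conf_start
    counts = {lab.value: 0 for lab in set(result.labels.values())}
    for lab in result.labels.values():
        counts[lab.value] += 1
    logger.info("labels: %s", counts)
    return result


def run_samplex(
    structure_path: str | Path,
    data_path: str | Path | None = None,
    free_shifts: str | Path | None = None,
    bound_shifts: str | Path | None = None,
    output_path: str | Path | None = None,
    params: SamplexParams | None = None,
    force: bool = False,
    strict: bool = False,
    pdb_out: str | Path | None = None,
    model_policy: str = "all",
) -> ClassificationResult:
    """File-level entry point: read inputs, classify, write results.

    Provide either ``data_path`` (per-residue value table) or both shift
    tables, from which CSPs are computed.  ``pdb_out`` additionally writes a
    copy of the structure with the final confidence in the B-factor column.
    """
    from .csp import compute_csp, read_shift_table

    ens = sio.read_structure(structure_path, model_policy=model_policy)
    if data_path is not None:
        data = sio.read_data_table(data_path)
    elif free_shifts is not None and bound_shifts is not None:
        data = compute_csp(read_shift_table(free_shifts), read_shift_table(bound_shifts))
    else:
        raise ValueError("provide data_path, or both free_shifts and bound_shifts")

    result = classify_perturbations(ens, data, params=params, force=force, strict=strict)
    if output_path is not None:
        sio.write_results(result, output_path)
    if pdb_out is not None and not result.guard_triggered:
        sio.write_pdb(ens, pdb_out, bfactors=result.rho_final.rho)
    return result
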