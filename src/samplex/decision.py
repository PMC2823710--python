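"""Final three-way decision and the unperturbed-protein guard (Step 4).

Residues with a homogenized confidence above +threshold are called perturbed,
below -threshold unperturbed, and in between ambiguous (possibly adjacent to
or indirectly affected by a perturbed region).  Before any of that, the
relative standard deviation sigma_R = sigma/mu of the measured data decides
whether there is a signal at all: flat data (sigma_R below the guard, default
25%) indicate an unperturbed protein and no classification is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ClassificationResult,
    ConfidenceVector,
    Label,
    PerResidueData,
    SamplexParams,
    Status,
)


@dataclass(frozen=True)
class GuardReport:
    """Relative SD of the measured data and whether the guard fired."""

    sigma_r: float  # sigma/mu, population convention; NaN when mu == 0
    triggered: bool


def relative_sd(data: PerResidueData, guard: float = 0.25) -> GuardReport:
    """sigma/mu of the measured values; triggered when below the guard floor.

    All-zero data have no scale to compare against: the guard fires with
    sigma_r flagged as NaN.
    """
    vals = np.fromiter(data.values.values(), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two measured values")
    mu = float(vals.mean())
    if mu == 0.0:
        return GuardReport(sigma_r=float("nan"), triggered=True)
    sigma_r = float(vals.std()) / mu
    return GuardReport(sigma_r=sigma_r, triggered=sigma_r < guard)


def classify(
    conf: ConfidenceVector,
    threshold: float = 0.05,
    data: PerResidueData | None = None,
    sigma_r: float = float("nan"),
) -> ClassificationResult:
    """Label every residue from its homogenized confidence.

    The boundaries +/-threshold belong to the ambiguous class; only strictly
    larger (smaller) confidences are called perturbed (unperturbed).  Excluded
    residues receive no-decision.
    """
    labels: dict = {}
    for key, status in conf.status.items():
        if status == Status.EXCLUDED:
            labels[key] = Label.NO_DECISION
        else:
            r = conf.rho[key]
            if r > threshold:
                labels[key] = Label.PERTURBED
            elif r < -threshold:
                labels[key] = Label.UNPERTURBED
            else:
                labels[key] = Label.AMBIGUOUS
    return ClassificationResult(
        labels=labels,
        rho_start=conf,
        rho_final=conf,
        sigma_r=sigma_r,
        guard_triggered=False,
        input_values=dict(data.values) if data is not None else {},
    )


def guard_result(
    data: PerResidueData, report: GuardReport, conf: ConfidenceVector | None = None
) -> ClassificationResult:
    """All-no-decision result for a guard-triggered (flat) dataset."""
    empty = ConfidenceVector({}, {}) if conf is None else conf
    keys = data.all_keys if conf is None else list(conf.status)
    return ClassificationResult(
        labels={k: Label.NO_DECISION for k in keys},
        rho_start=empty,
        rho_final=empty,
        sigma_r=report.sigma_r,
        guard_triggered=True,
        input_values=dict(data.values),
    )
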