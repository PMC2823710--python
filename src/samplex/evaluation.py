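"""Benchmarking: reference interfaces, Matthews correlation, threshold baselines.

The reference interface of a complex is defined geometrically: a residue of
one subunit belongs to the interface when at least one of its backbone atoms
(N, CA, C, O) lies within the cutoff (default 5 Å) of any heavy atom of the
other subunit, in at least one model of the ensemble.  Predictions are scored
against such a reference with the Matthews correlation coefficient, and
compared with the two classical CSP-threshold selections (single and
iterated mu + n*sigma cuts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import ClassificationResult, Label, PerResidueData, ResidueKey, StructureEnsemble


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; degenerate denominator yields 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator degenerate (a margin is empty); returning 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def interface_residues(
    complex_ens: StructureEnsemble,
    subunit_a: set[str],
    subunit_b: set[str],
    cutoff: float = 5.0,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Interface residue sets of two subunits of a complex.

    A residue of subunit A is at the interface when any of its backbone atoms
    is within ``cutoff`` of any non-hydrogen atom of subunit B in at least one
    model; and symmetrically for B.
    """
    chains = complex_ens.chains()
    for side in (subunit_a, subunit_b):
        if not side:
            raise ValueError("subunit chain sets must be non-empty")
        unknown = set(side) - chains
        if unknown:
            raise KeyError(f"unknown chain(s) {sorted(unknown)}; structure has {sorted(chains)}")
    if subunit_a & subunit_b:
        raise ValueError("subunit chain sets must be disjoint")

    iface_a: set[ResidueKey] = set()
    iface_b: set[ResidueKey] = set()
    for model in complex_ens.models:
        for own, other, out in ((subunit_a, subunit_b, iface_a), (subunit_b, subunit_a, iface_b)):
            heavy = [
                a.coords
                for res in model
                if res.key.chain in other
                for a in res.atoms
                if not a.is_hydrogen
            ]
            if not heavy:
                continue
            tree = cKDTree(np.asarray(heavy))
            for res in model:
                if res.key.chain not in own or res.key in out:
                    continue
                bb = [a.coords for a in res.atoms if a.is_backbone]
                if bb and (tree.query(np.asarray(bb), k=1)[0] <= cutoff).any():
                    out.add(res.key)
    return iface_a, iface_b


def method_a(data: PerResidueData, n_sigma: int = 1) -> set[ResidueKey]:
    """Single-pass threshold baseline: residues with value > mu + n_sigma*sigma.

    mu and sigma (population) are computed once over all measured values.
    """
    vals = np.fromiter(data.values.values(), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two measured values")
    cut = vals.mean() + n_sigma * vals.std()
    return {k for k, v in data.values.items() if v > cut}


def method_b(data: PerResidueData, n_sigma: int = 1) -> set[ResidueKey]:
    """Iterated threshold baseline: reject above mu + n_sigma*sigma of the
    remaining values, recompute, repeat until no rejection; return all rejected."""
    if data.n_measured < 2:
        raise ValueError("need at least two measured values")
    remaining = dict(data.values)
    rejected: set[ResidueKey] = set()
    while len(remaining) >= 2:
        vals = np.fromiter(remaining.values(), dtype=float)
        cut = vals.mean() + n_sigma * vals.std()
        out = {k for k, v in remaining.items() if v > cut}
        if not out:
            break
        rejected |= out
        for k in out:
            del remaining[k]
    return rejected


def score_prediction(
    result: ClassificationResult,
    truth: set[ResidueKey],
    ambiguous_policy: str = "negative",
) -> ConfusionCounts:
    """Confusion counts of a classification against a reference perturbed set.

    Perturbed counts as a positive prediction, unperturbed as negative;
    ambiguous residues follow ``ambiguous_policy`` ("negative", "positive" or
    "drop"); no-decision residues are dropped from the counts.
    """
    if not truth:
        raise ValueError("reference perturbed set is empty; MCC would be undefined")
    if ambiguous_policy not in ("negative", "positive", "drop"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    tp = fp = tn = fn = 0
    for key, label in result.labels.items():
        if label == Label.NO_DECISION:
            continue
        if label == Label.AMBIGUOUS:
            if ambiguous_policy == "drop":
                continue
            positive = ambiguous_policy == "positive"
        else:
            positive = label == Label.PERTURBED
        if positive:
            tp, fp = (tp + 1, fp) if key in truth else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if key in truth else (fn, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def score_selection(
    selected: set[ResidueKey], universe: list[ResidueKey], truth: set[ResidueKey]
) -> ConfusionCounts:
    """Confusion counts for a plain selected-residue set over a residue universe.

    Residues outside ``selected`` count as negative predictions — including
    residues without data, which the threshold baselines can never select.
    """
    if not truth:
        raise ValueError("reference perturbed set is empty; MCC would be undefined")
    tp = fp = tn = fn = 0
    for key in universe:
        if key in selected:
            tp, fp = (tp + 1, fp) if key in truth else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if key in truth else (fn, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
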