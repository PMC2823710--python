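"""Core domain types shared by every stage of the pipeline.

The unit of classification is the residue, identified by chain and author
residue number (plus insertion code when present).  Structures may be NMR-style
ensembles of models; per-residue data carry explicit missing markers so that
absence of a measurement is never conflated with a value of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple


class ResidueKey(NamedTuple):
    """Identity of a residue: chain id, author residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"

    @classmethod
    def parse(cls, chain: str, resi: str | int) -> "ResidueKey":
        """Build a key from a chain label and a residue field like ``12`` or ``12A``."""
        if isinstance(resi, int):
            return cls(str(chain), resi)
        s = str(resi).strip()
        i = len(s)
        while i > 0 and not s[i - 1].isdigit():
            i -= 1
        if i == 0:
            raise ValueError(f"residue field {resi!r} has no numeric part")
        return cls(str(chain).strip(), int(s[:i]), s[i:])

    @property
    def label(self) -> str:
        """Residue number with insertion code, as written in data tables."""
        return f"{self.number}{self.icode}"


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.name}: non-finite coordinates {self.coords}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    """A residue within one model: identity, 3-letter name, and its atoms."""

    key: ResidueKey
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")


class StructureEnsemble:
    """One or more coordinate models sharing a common residue index.

    Every model contains exactly the same set of residue keys, in the same
    order; residues present in only a subset of models must be dropped by the
    reader before construction.
    """

    def __init__(self, models: list[list[Residue]]):
        if not models:
            raise ValueError("ensemble needs at least one model")
        keys0 = [r.key for r in models[0]]
        if len(set(keys0)) != len(keys0):
            raise ValueError("duplicate residue keys within a model")
        for m, model in enumerate(models[1:], start=2):
            if [r.key for r in model] != keys0:
                raise ValueError(f"model {m} has a different residue set/order")
        self.models = models
        self.keys: list[ResidueKey] = keys0
        self._index = {k: i for i, k in enumerate(keys0)}

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_residues(self) -> int:
        return len(self.keys)

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    def residue(self, key: ResidueKey, model: int = 0) -> Residue:
        return self.models[model][self._index[key]]

    def chains(self) -> set[str]:
        return {k.chain for k in self.keys}


@dataclass
class PerResidueData:
    """Per-residue scalar perturbation values with explicit missing markers.

    ``values`` maps residue keys to non-negative scalars (CSPs or any other
    per-residue magnitude); ``missing`` lists residues the user supplied but
    for which no measurement exists (unassigned peaks, prolines, overlap...).
    """

    values: dict[ResidueKey, float]
    missing: set[ResidueKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.values) & self.missing
        if overlap:
            raise ValueError(f"residues both measured and missing: {sorted(overlap)}")
        for k, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"residue {k}: value {v} must be finite and >= 0")

    @property
    def measured_keys(self) -> list[ResidueKey]:
        return list(self.values)

    @property
    def all_keys(self) -> list[ResidueKey]:
        return list(self.values) + sorted(self.missing)

    @property
    def n_measured(self) -> int:
        return len(self.values)


class Status(str, Enum):
    """Provenance of a residue's confidence."""

    MEASURED = "measured"
    INFERRED = "inferred"
    EXCLUDED = "excluded"


@dataclass
class ConfidenceVector:
    """Per-residue confidence rho in [-1, 1] with provenance status.

    +1 means certainly perturbed, -1 certainly unperturbed.  Excluded residues
    (too few informative neighbors) carry no rho at all.
    """

    rho: dict[ResidueKey, float]
    status: dict[ResidueKey, Status]

    def __post_init__(self) -> None:
        for k, r in self.rho.items():
            if self.status.get(k) == Status.EXCLUDED:
                raise ValueError(f"excluded residue {k} must not carry a confidence")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"residue {k}: rho {r} outside [-1, 1]")

    def active_keys(self) -> list[ResidueKey]:
        """Residues that carry a confidence (measured or inferred)."""
        return [k for k, s in self.status.items() if s != Status.EXCLUDED]

    def copy(self) -> "ConfidenceVector":
        return ConfidenceVector(dict(self.rho), dict(self.status))


class Label(str, Enum):
    """Final four-way decision for a residue."""

    PERTURBED = "perturbed"
    UNPERTURBED = "unperturbed"
    AMBIGUOUS = "ambiguous"
    NO_DECISION = "no-decision"


@dataclass
class ClassificationResult:
    """Final labels plus the confidence vectors before and after homogenization."""

    labels: dict[ResidueKey, Label]
    rho_start: ConfidenceVector
    rho_final: ConfidenceVector
    sigma_r: float
    guard_triggered: bool = False
    input_values: dict[ResidueKey, float] = field(default_factory=dict)

    def residues_with(self, label: Label) -> set[ResidueKey]:
        return {k for k, lab in self.labels.items() if lab == label}


@dataclass
class SamplexParams:
    """All tunables of the classification pipeline.

    subset_fraction
        Fraction of the available data drawn into each resampled sub-ensemble
        (0.15: each subset holds 15% of the measured values).
    calib_multiplier, trial_multiplier
        Calibration runs and per-residue trials, each expressed per measured
        datum (1000·N calibration runs, 100·N trials).
    neighbor_cutoff
        Å cutoff defining structural neighbors on barycenter distances (7.5 Å).
    epsilon
        Floor of the sigmoidal distance kernel (1e-3): phi(0) = 1 - epsilon,
        phi(cutoff) = epsilon.
    homog_tol
        RMSD between consecutive smoothing iterations below which the
        homogenization stops (1e-5).
    decision_threshold
        Half-width of the ambiguous dead zone on the final confidence (0.05).
    sigma_r_guard
        Relative-standard-deviation floor (0.25): data with sigma/mu below it
        are deemed unperturbed overall and no classification is made.
    """

    subset_fraction: float = 0.15
    calib_multiplier: int = 1000
    trial_multiplier: int = 100
    neighbor_cutoff: float = 7.5
    epsilon: float = 1e-3
    homog_tol: float = 1e-5
    decision_threshold: float = 0.05
    sigma_r_guard: float = 0.25
    seed: int = 0
    min_subset_size: int = 3
    max_homog_iter: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction < 1:
            raise ValueError("subset_fraction must lie in (0, 1)")
        if self.neighbor_cutoff <= 0:
            raise ValueError("neighbor_cutoff must be positive")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.homog_tol <= 0 or self.decision_threshold <= 0 or self.sigma_r_guard <= 0:
            raise ValueError("tolerances and thresholds must be positive")
        if self.min_subset_size < 3:
            raise ValueError("min_subset_size must be >= 3")

    def subset_size(self, n_measured: int) -> int:
        """Size of each resampled sub-ensemble for N measured values."""
        return max(self.min_subset_size, round(self.subset_fraction * n_measured))
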