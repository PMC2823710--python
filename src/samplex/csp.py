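"""Chemical shift perturbations from free/bound backbone shift tables.

The CSP of a residue combines the shift differences of its backbone nuclei
into a single non-negative magnitude:

    CSP_i = sqrt( dHN^2 + (dN/SW_N)^2 + (dCA/SW_CA)^2 + (dCO/SW_CO)^2 )

where dX is the free-bound shift difference of nucleus X (ppm) and the SW
ratios rescale the heteronuclear terms onto the amide-proton scale.  Nuclei
absent for a residue simply contribute nothing, so HN-only data reduce to
|dHN|.  The SW ratios are acquisition-dependent; the defaults below are
typical values and should be overridden to match the actual spectral widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import PerResidueData, ResidueKey

NUCLEI = ("HN", "N", "CA", "CO")


@dataclass(frozen=True)
class CspWeights:
    """Spectral-width ratios normalizing N, CA and CO shifts to the HN scale."""

    sw_n: float = 6.5
    sw_ca: float = 10.0
    sw_co: float = 10.0

    def __post_init__(self) -> None:
        if min(self.sw_n, self.sw_ca, self.sw_co) <= 0:
            raise ValueError("spectral width ratios must be positive")

    def divisor(self, nucleus: str) -> float:
        return {"HN": 1.0, "N": self.sw_n, "CA": self.sw_ca, "CO": self.sw_co}[nucleus]


@dataclass
class ShiftTable:
    """Backbone chemical shifts: (residue key, nucleus) -> ppm."""

    shifts: dict[tuple[ResidueKey, str], float]

    def __post_init__(self) -> None:
        for (key, nuc), ppm in self.shifts.items():
            if nuc not in NUCLEI:
                raise ValueError(f"unknown nucleus {nuc!r} for residue {key}")
            if not math.isfinite(ppm):
                raise ValueError(f"non-finite shift for {key}/{nuc}")

    def residues(self) -> set[ResidueKey]:
        return {key for key, _ in self.shifts}

    def nuclei_for(self, key: ResidueKey) -> set[str]:
        return {nuc for k, nuc in self.shifts if k == key}


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a shift table TSV/CSV with columns chain, resi, nucleus, ppm."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    cols = [c.lower().strip() for c in df.columns]
    df.columns = cols
    shifts: dict[tuple[ResidueKey, str], float] = {}
    for _, row in df.iterrows():
        key = ResidueKey.parse(row["chain"], row[[c for c in cols if c.startswith("res")][0]])
        nuc = str(row["nucleus"]).strip().upper()
        entry = (key, nuc)
        if entry in shifts:
            raise ValueError(f"{path}: duplicate shift for {key}/{nuc}")
        shifts[entry] = float(row["ppm"])
    return ShiftTable(shifts)


def compute_csp(
    free: ShiftTable, bound: ShiftTable, weights: CspWeights = CspWeights()
) -> PerResidueData:
    """Per-residue CSPs from two shift tables (symmetric in state order).

    A residue contributes a value when it appears in both tables with at least
    one common nucleus; residues seen in only one table, or with no common
    nucleus, are recorded as missing so the pipeline can infer them later.
    """
    common = free.residues() & bound.residues()
    union = free.residues() | bound.residues()
    values: dict[ResidueKey, float] = {}
    missing: set[ResidueKey] = set()
    for key in union:
        nuclei = free.nuclei_for(key) & bound.nuclei_for(key) if key in common else set()
        if not nuclei:
            missing.add(key)
            continue
        sq = 0.0
        for nuc in nuclei:
            delta = free.shifts[(key, nuc)] - bound.shifts[(key, nuc)]
            sq += (delta / weights.divisor(nuc)) ** 2
        values[key] = math.sqrt(sq)
    if not values:
        raise ValueError("no residue has shifts for a common nucleus in both states")
    return PerResidueData(values=values, missing=missing)
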