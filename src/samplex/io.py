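"""Readers and writers: PDB structures, per-residue data tables, result tables.

PDB parsing is delegated to Bio.PDB; this module only adapts parsed structures
into the ensemble container used by the pipeline and enforces the shared
residue index across models.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import pandas as pd
from Bio.PDB import PDBParser

from .core import (
    Atom,
    ClassificationResult,
    ConfidenceVector,
    Label,
    PerResidueData,
    Residue,
    ResidueKey,
    Status,
    StructureEnsemble,
)


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no protein residues."""


def _convert_residue(bio_res) -> Residue:
    het, seq, icode = bio_res.id
    key = ResidueKey(bio_res.get_parent().id.strip() or " ", seq, icode.strip())
    atoms = []
    for a in bio_res.get_atoms():
        # Bio.PDB's disordered-atom wrapper proxies to the highest-occupancy
        # altloc (ties resolved to the first listed), which is the convention
        # we want, so plain iteration suffices.
        x, y, z = (float(c) for c in a.coord)
        atoms.append(
            Atom(
                name=a.get_name().strip(),
                element=(a.element or "").strip(),
                coords=(x, y, z),
                occupancy=float(a.get_occupancy() or 1.0),
            )
        )
    return Residue(key=key, name=bio_res.get_resname(), atoms=atoms)


def read_structure(
    path: str | Path,
    model_policy: str = "all",
    het_whitelist: frozenset[str] = frozenset(),
) -> StructureEnsemble:
    """Parse a PDB file into a structure ensemble with a shared residue index.

    MODEL/ENDMDL blocks become models.  HETATM residues (waters included) are
    dropped unless their residue name is in ``het_whitelist``.  Residues absent
    from some models are removed from all models, with a warning, so that every
    model indexes the identical residue set.

    Parameters
    ----------
    path : file path to a PDB file
    model_policy : "all" to keep every model, "first" to keep only the first
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise IOError(f"cannot parse PDB file {path}: {exc}") from exc

    raw_models: list[dict[ResidueKey, Residue]] = []
    for bio_model in structure:
        model: dict[ResidueKey, Residue] = {}
        for bio_res in bio_model.get_residues():
            het = bio_res.id[0]
            if het != " " and bio_res.get_resname() not in het_whitelist:
                continue
            res = _convert_residue(bio_res)
            model[res.key] = res
        if model:
            raw_models.append(model)
        if model_policy == "first" and raw_models:
            break

    if not raw_models:
        raise EmptyStructureError(f"{path}: no protein residues found")

    shared = set(raw_models[0])
    for m in raw_models[1:]:
        shared &= set(m)
    order = [k for k in raw_models[0] if k in shared]
    if not order:
        raise EmptyStructureError(f"{path}: models share no residues")
    if any(len(m) != len(order) for m in raw_models):
        dropped = {k for m in raw_models for k in m} - shared
        warnings.warn(
            f"{len(dropped)} residue(s) absent from some models were dropped: "
            f"{sorted(str(k) for k in dropped)[:5]}...",
            stacklevel=2,
        )
    return StructureEnsemble([[m[k] for k in order] for m in raw_models])


_RESI_NAMES = ("resi", "residue", "seq_num", "resnum", "number", "res")


def read_data_table(path: str | Path) -> PerResidueData:
    """Read a per-residue data table (TSV/CSV: chain, residue number, value).

    Empty or NA-like value fields mark the residue as missing (supplied but
    unmeasured).  Negative values and duplicated residue keys are errors.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        chain_col = cols["chain"]
        resi_col = next(cols[n] for n in _RESI_NAMES if n in cols)
        value_col = cols["value"]
    except (KeyError, StopIteration):
        if len(df.columns) < 3:
            raise ValueError(f"{path}: need columns chain, residue number, value")
        chain_col, resi_col, value_col = df.columns[:3]

    values: dict[ResidueKey, float] = {}
    missing: set[ResidueKey] = set()
    for _, row in df.iterrows():
        key = ResidueKey.parse(row[chain_col], row[resi_col])
        if key in values or key in missing:
            raise ValueError(f"{path}: duplicate residue key {key}")
        raw = row[value_col]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip().upper() in ("", "NA", "NAN", "N/A", "."):
            missing.add(key)
        else:
            v = float(raw)
            if v < 0:
                raise ValueError(f"{path}: residue {key} has negative value {v}")
            values[key] = v
    return PerResidueData(values=values, missing=missing)


def write_results(result: ClassificationResult, path: str | Path) -> None:
    """Write the classification as a TSV: one row per residue.

    Columns: chain, resi, input_value, rho_start, rho_final, status, label.
    The relative standard deviation and guard flag go into header comments.
    """
    path = Path(path)
    lines = [
        f"# sigma_r\t{result.sigma_r:.6f}",
        f"# guard_triggered\t{str(result.guard_triggered).lower()}",
        "chain\tresi\tinput_value\trho_start\trho_final\tstatus\tlabel",
    ]
    for key in sorted(result.labels, key=lambda k: (k.chain, k.number, k.icode)):
        status = result.rho_final.status.get(key, Status.EXCLUDED)
        val = result.input_values.get(key)
        rs = result.rho_start.rho.get(key)
        rf = result.rho_final.rho.get(key)
        lines.append(
            "\t".join(
                [
                    key.chain,
                    key.label,
                    "" if val is None else f"{val:.6f}",
                    "" if rs is None else f"{rs:.6f}",
                    "" if rf is None else f"{rf:.6f}",
                    status.value,
                    result.labels[key].value,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> ClassificationResult:
    """Re-read a results TSV written by :func:`write_results`."""
    path = Path(path)
    sigma_r, guard = 0.0, False
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("# sigma_r"):
            sigma_r = float(line.split("\t")[1])
        elif line.startswith("# guard_triggered"):
            guard = line.split("\t")[1] == "true"
        elif line.startswith("#") or line.startswith("chain\t"):
            continue
        else:
            rows.append(line.split("\t"))
    labels, rho_s, rho_f, status, inputs = {}, {}, {}, {}, {}
    for chain, resi, val, rs, rf, st, lab in rows:
        key = ResidueKey.parse(chain, resi)
        labels[key] = Label(lab)
        status[key] = Status(st)
        if val:
            inputs[key] = float(val)
        if st != Status.EXCLUDED.value:
            if rs:
                rho_s[key] = float(rs)
            if rf:
                rho_f[key] = float(rf)
    start = ConfidenceVector(rho_s, {k: s for k, s in status.items() if k in rho_s or s == Status.EXCLUDED})
    final = ConfidenceVector(rho_f, dict(status))
    return ClassificationResult(
        labels=labels,
        rho_start=start,
        rho_final=final,
        sigma_r=sigma_r,
        guard_triggered=guard,
        input_values=inputs,
    )


def _format_atom_line(serial: int, atom: Atom, res: Residue, bfactor: float) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    return (
        f"ATOM  {serial:>5d} {name:<4s} {res.name:<3s} {res.key.chain:1s}"
        f"{res.key.number:>4d}{res.key.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(
    ens: StructureEnsemble,
    path: str | Path,
    bfactors: dict[ResidueKey, float] | None = None,
) -> None:
    """Write the ensemble as a PDB file, optionally with per-residue B-factors.

    Used to export structures for visualization with the final confidence in
    the B-factor column (e.g. to color a structure by rho in PyMOL).
    """
    lines = []
    multi = ens.n_models > 1
    for m, model in enumerate(ens.models, start=1):
        if multi:
            lines.append(f"MODEL     {m:>4d}")
        serial = 1
        for res in model:
            b = 0.0 if bfactors is None else bfactors.get(res.key, 0.0)
            for atom in res.atoms:
                lines.append(_format_atom_line(serial, atom, res, b))
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
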