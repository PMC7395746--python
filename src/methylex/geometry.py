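"""Geometry observables of the active/inactive transition on coordinates.

Operates on PDB coordinate files -- single structures or multi-model
ensembles (e.g. trajectory frames exported as MODEL/ENDMDL blocks) -- and
computes, per model,

* the distance between the mass-weighted centres of mass of two helix
  selections (heavy atoms only),
* the inter-helix orientation angle, with each helix axis taken as the
  first principal component of its C-alpha coordinates oriented N->C, and
* named atom--atom distances (e.g. K33 CA to F152 CA, or any atom to the
  catalytic zinc, the conventional active-site marker).

Parsing is done with gemmi; alternate locations are resolved to a single
conformer (highest occupancy, ties broken by altloc letter) before any
measurement.  Helix residue ranges are configuration data: they may be
given explicitly or pulled from the HELIX records of the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "HelixSelection",
    "ObservableSummary",
    "load_structure",
    "com_distance",
    "interhelix_angle",
    "atom_distance",
    "zinc_distance",
    "helix_ranges_from_records",
]


@dataclass(frozen=True)
class HelixSelection:
    """Inclusive residue range defining one helix."""

    chain: str
    first: int
    last: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.last < self.first + 3:
            raise ValueError(
                f"helix {self.label or self.chain} needs >= 4 residues "
                f"(got {self.first}..{self.last})"
            )


@dataclass
class ObservableSummary:
    """Per-model values of one observable plus distribution summary."""

    name: str
    values: np.ndarray  # one entry per model

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=0))

    def histogram(self, bins: int = 20):
        return np.histogram(self.values, bins=bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model": np.arange(1, len(self.values) + 1), self.name: self.values})


class StructureModel:
    """Coordinate ensemble (>= 1 model) with altlocs already resolved."""

    def __init__(self, structure: gemmi.Structure):
        _resolve_altlocs(structure)
        structure.setup_entities()
        self.structure = structure

    @property
    def n_models(self) -> int:
        return len(self.structure)

    @property
    def entry_id(self) -> str:
        return self.structure.name

    def models(self):
        return iter(self.structure)

    def write_pdb(self, path: str | Path) -> None:
        self.structure.write_pdb(str(path))


def load_structure(path: str | Path) -> StructureModel:
    """Read a (possibly multi-model) PDB file."""
    st = gemmi.read_structure(str(path))
    return StructureModel(st)


def _resolve_altlocs(st: gemmi.Structure) -> None:
    """Keep one conformer per atom: highest occupancy, tie -> altloc 'A'."""
    for model in st:
        for chain in model:
            for residue in chain:
                best: dict[str, tuple[float, str]] = {}
                for atom in residue:
                    alt = atom.altloc if atom.altloc != "\0" else "A"
                    key = (atom.occ, -ord(alt))  # highest occ, tie -> 'A'
                    if atom.name not in best or key > best[atom.name][0]:
                        best[atom.name] = (key, atom.altloc)
                for i in reversed(range(len(residue))):
                    atom = residue[i]
                    if atom.altloc != best[atom.name][1]:
                        del residue[i]
                for atom in residue:
                    atom.altloc = "\0"


def _select_atoms(model: gemmi.Model, sel: HelixSelection, ca_only=False):
    coords, masses = [], []
    for chain in model:
        if chain.name != sel.chain:
            continue
        for residue in chain:
            num = residue.seqid.num
            if not sel.first <= num <= sel.last:
                continue
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                if ca_only and atom.name != "CA":
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                masses.append(atom.element.weight)
    return np.asarray(coords), np.asarray(masses)


def com_distance(
    s: StructureModel, a: HelixSelection, b: HelixSelection
) -> ObservableSummary:
    """Distance between the heavy-atom centres of mass of two selections (A).

    Mass-weighted over all heavy atoms of each selection, one value per
    model.  Empty selections are an error.
    """
    values = []
    for model in s.models():
        out = []
        for sel in (a, b):
            coords, masses = _select_atoms(model, sel)
            if len(coords) == 0:
                raise ValueError(
                    f"selection {sel.label or sel.chain}:{sel.first}-{sel.last} "
                    f"matches no atoms in model {model.num}"
                )
            out.append(masses @ coords / masses.sum())
        values.append(float(np.linalg.norm(out[0] - out[1])))
    label = f"com_dist_{a.label or 'a'}_{b.label or 'b'}_A"
    return ObservableSummary(label, np.asarray(values))


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """First principal component of C-alpha coordinates, oriented N->C.

    For selections of >= 6 residues the coordinates are first smoothed with
    a 4-residue moving average (roughly one helical turn), which collapses
    the helical wheel onto the axis and removes the tilt that raw PCA picks
    up when the selection does not span an integer number of turns.
    """
    if len(coords) >= 6:
        kernel = np.full(4, 0.25)
        coords = np.column_stack(
            [np.convolve(coords[:, k], kernel, mode="valid") for k in range(3)]
        )
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def interhelix_angle(
    s: StructureModel, a: HelixSelection, b: HelixSelection
) -> ObservableSummary:
    """Angle between the N->C axes of two helices, degrees in [0, 180]."""
    values = []
    for model in s.models():
        axes = []
        for sel in (a, b):
            coords, _ = _select_atoms(model, sel, ca_only=True)
            if len(coords) < 4:
                raise ValueError(
                    f"selection {sel.label or sel.chain}:{sel.first}-{sel.last} "
                    f"has fewer than 4 C-alpha atoms"
                )
            axes.append(_helix_axis(coords))
        cosang = float(np.clip(axes[0] @ axes[1], -1.0, 1.0))
        values.append(float(np.degrees(np.arccos(cosang))))
    label = f"angle_{a.label or 'a'}_{b.label or 'b'}_deg"
    return ObservableSummary(label, np.asarray(values))


def _find_atom(model: gemmi.Model, chain: str, resid: int, atom_name: str):
    candidates = []
    for ch in model:
        if ch.name != chain:
            continue
        for residue in ch:
            if residue.seqid.num != resid:
                continue
            for atom in residue:
                if atom.name == atom_name:
                    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                candidates.append(f"{residue.name}{resid}:{atom.name}")
    raise KeyError(
        f"atom {chain}/{resid}/{atom_name} not found"
        + (f"; atoms present in that residue: {sorted(set(candidates))}" if candidates else "")
    )


def atom_distance(
    s: StructureModel,
    sel1: tuple[str, int, str],
    sel2: tuple[str, int, str],
) -> ObservableSummary:
    """Distance between two named atoms (chain, residue number, atom name)."""
    values = []
    for model in s.models():
        p1 = _find_atom(model, *sel1)
        p2 = _find_atom(model, *sel2)
        values.append(float(np.linalg.norm(p1 - p2)))
    label = f"dist_{sel1[0]}{sel1[1]}{sel1[2]}_{sel2[0]}{sel2[1]}{sel2[2]}_A"
    return ObservableSummary(label, np.asarray(values))


def zinc_distance(
    s: StructureModel, sel: tuple[str, int, str]
) -> ObservableSummary:
    """Distance from a named atom to the (first) catalytic zinc ion.

    The active site is marked by the HETATM zinc; the nearest ZN to the
    query atom is used in each model.
    """
    values = []
    for model in s.models():
        p = _find_atom(model, *sel)
        zns = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.element.name == "Zn":
                        zns.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if not zns:
            raise KeyError("no zinc ion found in model")
        d = np.linalg.norm(np.asarray(zns) - p, axis=1)
        values.append(float(d.min()))
    return ObservableSummary(f"dist_Zn_{sel[0]}{sel[1]}{sel[2]}_A", np.asarray(values))


def helix_ranges_from_records(s: StructureModel) -> list[HelixSelection]:
    """Helix selections from the file's HELIX records, in file order."""
    out = []
    for i, hx in enumerate(s.structure.helices, start=1):
        out.append(
            HelixSelection(
                chain=hx.start.chain_name,
                first=hx.start.res_id.seqid.num,
                last=hx.end.res_id.seqid.num,
                label=f"H{i}",
            )
        )
    return out
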