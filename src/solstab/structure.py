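"""Protein structure handling: PDB I/O, chain identity, exposure, contacts.

The structural layer is deliberately small.  A :class:`ProteinStructure`
keeps, per chain, both the construct sequence (SEQRES, when present) and
the sequence actually resolved in the coordinates, because the two may
differ where electron density is missing and the solubility machinery
works on the full construct sequence while exposure and contacts only
exist for resolved residues.

Solvent exposure is computed with a deterministic Shrake-Rupley style
sphere sampling (golden-spiral point set) over heavy atoms and expressed
relative to the theoretical maximum accessibility of the residue type in
an extended Gly-X-Gly tripeptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .data import (
    DEFAULT_VDW_RADIUS,
    MAX_ASA_GXG,
    MEAN_MAX_ASA,
    ONE_TO_THREE,
    THREE_TO_ONE,
    VDW_RADIUS,
)

# Residue key: (chain id, author residue number, insertion code or None)
ResidueKey = tuple[str, int, Optional[str]]


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,)

    @property
    def radius(self) -> float:
        return VDW_RADIUS.get(self.element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    number: int
    icode: Optional[str]
    aa: str  # one-letter code, 'X' for non-standard
    atoms: list[Atom] = field(default_factory=list)

    def key(self, chain_id: str) -> ResidueKey:
        return (chain_id, self.number, self.icode)


@dataclass
class Chain:
    id: str
    seqres_sequence: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atom_sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def comparison_sequence(self) -> str:
        """SEQRES sequence when present, else the coordinate sequence."""
        return self.seqres_sequence or self.atom_sequence

    def seq_index_map(self) -> dict[ResidueKey, int]:
        """Map each resolved residue to its index in the comparison sequence.

        When SEQRES and coordinate sequences coincide (or the coordinate
        sequence is a contiguous window of SEQRES) the mapping is exact;
        otherwise residues are mapped by order with a warning.
        """
        seq = self.comparison_sequence
        atom_seq = self.atom_sequence
        offset = 0
        if seq != atom_seq:
            pos = seq.find(atom_seq)
            if pos >= 0:
                offset = pos
            else:
                warnings.warn(
                    f"chain {self.id}: coordinate sequence does not align to "
                    "SEQRES; mapping residues by order"
                )
        return {
            r.key(self.id): min(i + offset, len(seq) - 1)
            for i, r in enumerate(self.residues)
        }


@dataclass
class ProteinStructure:
    chains: list[Chain]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def residue(self, key: ResidueKey) -> Residue:
        chain = self.chain(key[0])
        for r in chain.residues:
            if (r.number, r.icode) == (key[1], key[2]):
                return r
        raise KeyError(f"no residue {key} in structure")

    def heavy_atoms(self) -> tuple[list[ResidueKey], np.ndarray, np.ndarray]:
        """All heavy atoms as (residue key per atom, coords, radii)."""
        keys: list[ResidueKey] = []
        coords: list[np.ndarray] = []
        radii: list[float] = []
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if atom.element.upper() == "H":
                        continue
                    keys.append(res.key(chain.id))
                    coords.append(atom.coord)
                    radii.append(atom.radius)
        if not coords:
            return keys, np.empty((0, 3)), np.empty(0)
        return keys, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def _parse_seqres(path: Path) -> dict[str, str]:
    sequences: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("SEQRES"):
                continue
            chain_id = line[11].strip() or " "
            for resname in line[19:].split():
                sequences.setdefault(chain_id, []).append(
                    THREE_TO_ONE.get(resname, "X")
                )
    return {cid: "".join(seq) for cid, seq in sequences.items()}


def read_structure(path: str | Path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Waters and non-polymer heteroatoms are excluded.  Per chain the
    SEQRES sequence is taken from the header when present, otherwise it
    is set equal to the coordinate-derived sequence.  Non-standard
    polymer residues are kept and mapped to ``'X'``.
    """
    path = Path(path)
    seqres = _parse_seqres(path)
    parser = PDBParser(QUIET=True)
    try:
        model = parser.get_structure("s", str(path))[0]
    except Exception as exc:  # pragma: no cover - biopython error paths
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        seen: set[tuple[int, Optional[str]]] = set()
        for bio_res in bio_chain:
            hetflag, number, icode = bio_res.id
            if hetflag != " ":
                continue  # waters and ligands
            icode = icode.strip() or None
            if (number, icode) in seen:
                continue
            seen.add((number, icode))
            aa = THREE_TO_ONE.get(bio_res.get_resname().strip(), "X")
            atoms = [
                Atom(a.get_name(), (a.element or a.get_name()[0]).strip(),
                     np.asarray(a.get_coord(), dtype=float))
                for a in bio_res
            ]
            residues.append(Residue(number, icode, aa, atoms))
        if not residues:
            if bio_chain.id.strip():
                warnings.warn(
                    f"chain {bio_chain.id}: no standard polymer residues; skipped"
                )
            continue
        cid = bio_chain.id if bio_chain.id.strip() else "A"
        chains.append(Chain(cid, seqres.get(cid, ""), residues))

    if not chains:
        raise ValueError(f"no polymer chains with standard residues in {path}")
    for chain in chains:
        if not chain.seqres_sequence:
            chain.seqres_sequence = chain.atom_sequence
    return ProteinStructure(chains)


def write_pdb(structure: ProteinStructure, path: str | Path | None = None) -> str:
    """Serialise a structure to standards-conformant PDB text."""
    lines: list[str] = []
    for chain in structure.chains:
        seq = chain.seqres_sequence
        three = [ONE_TO_THREE.get(aa, "UNK") for aa in seq]
        for i in range(0, len(three), 13):
            block = three[i:i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:>3} {chain.id} {len(three):>4}  "
                + " ".join(f"{r:<3}" for r in block)
            )
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                name = atom.name
                padded = f" {name:<3}" if len(name) < 4 else name
                icode = res.icode or ""
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:>5} {padded:<4} {resname:>3} {chain.id}"
                    f"{res.number:>4}{icode:<1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element.upper():>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def identity_groups(
    structure: ProteinStructure,
    manual: Optional[Iterable[Iterable[str]]] = None,
) -> list[tuple[str, ...]]:
    """Partition chain ids into groups of identical chains.

    Without a manual specification chains are grouped by exact equality
    of their comparison sequences.  A manual specification overrides the
    grouping; chains it does not mention become singletons.
    """
    ids = structure.chain_ids
    if manual is not None:
        groups: list[tuple[str, ...]] = []
        mentioned: set[str] = set()
        for spec in manual:
            group = tuple(spec)
            for cid in group:
                if cid not in ids:
                    raise ValueError(f"identity group names unknown chain {cid!r}")
                if cid in mentioned:
                    raise ValueError(f"chain {cid!r} mentioned twice in identity spec")
                mentioned.add(cid)
            lengths = {len(structure.chain(c).comparison_sequence) for c in group}
            if len(lengths) > 1:
                warnings.warn(
                    f"manual identity group {group} mixes chains of unequal "
                    "sequence length; accepted as given"
                )
            groups.append(group)
        groups.extend((cid,) for cid in ids if cid not in mentioned)
        groups.sort(key=lambda g: ids.index(g[0]))
        return groups

    by_seq: dict[str, list[str]] = {}
    for cid in ids:
        by_seq.setdefault(structure.chain(cid).comparison_sequence, []).append(cid)
    groups = [tuple(members) for members in by_seq.values()]
    groups.sort(key=lambda g: ids.index(g[0]))
    return groups


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    sphere_points: int = 256,
) -> np.ndarray:
    """Accessible surface area per atom (Shrake-Rupley, deterministic points)."""
    n = len(coords)
    if n == 0:
        return np.empty(0)
    unit = golden_spiral_points(sphere_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_reach = expanded.max()
    for i in range(n):
        neighbours = tree.query_ball_point(coords[i], expanded[i] + max_reach)
        neighbours = [j for j in neighbours if j != i]
        pts = coords[i] + expanded[i] * unit
        if neighbours:
            diff = pts[:, None, :] - coords[neighbours][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            blocked = (d2 <= expanded[neighbours][None, :] ** 2).any(axis=1)
            frac = 1.0 - blocked.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def relative_exposure(
    structure: ProteinStructure,
    probe: float = 1.4,
    sphere_points: int = 256,
) -> dict[ResidueKey, float]:
    """Per-residue relative solvent exposure in [0, 1].

    Heavy-atom accessible areas are summed per residue and divided by
    the tabulated Gly-X-Gly reference area of the residue type.
    """
    keys, coords, radii = structure.heavy_atoms()
    areas = atom_sasa(coords, radii, probe=probe, sphere_points=sphere_points)
    per_residue: dict[ResidueKey, float] = {}
    for key, area in zip(keys, areas):
        per_residue[key] = per_residue.get(key, 0.0) + float(area)

    exposure: dict[ResidueKey, float] = {}
    for chain in structure.chains:
        for res in chain.residues:
            key = res.key(chain.id)
            if key not in per_residue:
                warnings.warn(f"residue {key} has no heavy atoms; exposure undefined")
                continue
            ref = MAX_ASA_GXG.get(res.aa)
            if ref is None:
                warnings.warn(
                    f"residue {key} has unknown type {res.aa!r}; "
                    "using mean reference area"
                )
                ref = MEAN_MAX_ASA
            exposure[key] = float(np.clip(per_residue[key] / ref, 0.0, 1.0))
    return exposure


class ContactMap:
    """Symmetric, irreflexive residue contact relation.

    Two residues are in contact when their minimum heavy-atom distance
    does not exceed ``cutoff``.
    """

    def __init__(self, pairs: Iterable[tuple[ResidueKey, ResidueKey]], cutoff: float):
        self.cutoff = float(cutoff)
        self._adj: dict[ResidueKey, set[ResidueKey]] = {}
        for a, b in pairs:
            if a == b:
                continue
            self._adj.setdefault(a, set()).add(b)
            self._adj.setdefault(b, set()).add(a)

    def neighbours(self, key: ResidueKey) -> set[ResidueKey]:
        return set(self._adj.get(key, set()))

    def in_contact(self, a: ResidueKey, b: ResidueKey) -> bool:
        return b in self._adj.get(a, set())

    @property
    def pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs}

    def __len__(self) -> int:
        return len(self.pairs)


def contact_map(structure: ProteinStructure, cutoff: float = 8.0) -> ContactMap:
    """Residue contact map at a minimum heavy-atom distance cutoff."""
    keys, coords, _ = structure.heavy_atoms()
    if len(coords) == 0:
        warnings.warn("structure has no heavy atoms; contact map is empty")
        return ContactMap([], cutoff)
    tree = cKDTree(coords)
    pairs = []
    for i, j in tree.query_pairs(cutoff):
        if keys[i] != keys[j]:
            pairs.append((keys[i], keys[j]))
    return ContactMap(pairs, cutoff)
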