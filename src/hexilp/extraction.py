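"""Extract binding-site examples from PDB structures.

The binding-site center of a positive example is the centroid of the hexose
pyranose ring (C1–C5 + O5 of the bound ligand); negative examples use the
ligand centroid or the centroid of listed cavity-center atom serials.  The
site itself is every protein heavy atom within a 10 Å sphere of that center;
everything else (hydrogens, waters, ligand and other hetero atoms,
non-standard residues) is discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .bk import (
    AMINO_ACIDS,
    AtomRecord,
    Point3,
    ResidueRecord,
    SiteExample,
    euclid,
    _is_hydrogen,
)

PYRANOSE_RING_ATOMS = ("C1", "C2", "C3", "C4", "C5", "O5")

_THREE_TO_LOWER = {code.upper(): code for code in AMINO_ACIDS}


@dataclass(frozen=True)
class StructureAtom:
    """A single atom read from a structure file, before filtering."""

    serial: int
    atom_name: str
    residue_name: str      # PDB 3-letter code, uppercase
    residue_seq: int
    chain: str
    coords: Point3
    element: str = ""
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0


@dataclass(frozen=True)
class CenterSpec:
    """How to locate the binding-site center within a structure.

    mode 'pyranose_ring': centroid of the six ring atoms of ``ligand_id``
    (``RES-SEQ``, e.g. ``GLC-501``); 'ligand_centroid': centroid of all atoms
    of ``ligand_id``; 'atom_serials': centroid of the atoms with the listed
    serial numbers (the cavity-center convention for non-binding pockets).
    """

    mode: str
    ligand_id: str | None = None
    serials: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("pyranose_ring", "ligand_centroid", "atom_serials"):
            raise ValueError(f"unknown center mode: {self.mode!r}")
        if self.mode == "atom_serials" and not self.serials:
            raise ValueError("atom_serials mode requires at least one serial")
        if self.mode != "atom_serials" and not self.ligand_id:
            raise ValueError(f"{self.mode} mode requires a ligand_id")


@dataclass(frozen=True)
class ExtractionConfig:
    radius: float = 10.0
    exclude_hydrogens: bool = True
    exclude_ligand_atoms: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def centroid(points: Sequence[Point3]) -> Point3:
    """Arithmetic mean of a non-empty collection of points."""
    pts = list(points)
    if not pts:
        raise ValueError("centroid of empty collection")
    n = len(pts)
    return Point3(
        sum(p.x for p in pts) / n,
        sum(p.y for p in pts) / n,
        sum(p.z for p in pts) / n,
    )


def read_pdb_atoms(path: str) -> list[StructureAtom]:
    """Read ATOM/HETATM records of a PDB file (first model) via gemmi."""
    import gemmi

    st = gemmi.read_structure(path)
    atoms: list[StructureAtom] = []
    if len(st) == 0:
        return atoms
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                atoms.append(
                    StructureAtom(
                        serial=atom.serial,
                        atom_name=atom.name,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        chain=chain.name,
                        coords=Point3(atom.pos.x, atom.pos.y, atom.pos.z),
                        element=atom.element.name,
                        is_hetero=het,
                        altloc=atom.altloc or "",
                        occupancy=atom.occ,
                    )
                )
    return atoms


def _ligand_atoms(atoms: Iterable[StructureAtom], ligand_id: str) -> list[StructureAtom]:
    name, _, seq = ligand_id.partition("-")
    seq_num = int(seq)
    hits = [a for a in atoms if a.residue_name == name.upper() and a.residue_seq == seq_num]
    if not hits:
        raise ValueError(f"ligand {ligand_id} not found in structure")
    return hits


def resolve_center(atoms: Sequence[StructureAtom], spec: CenterSpec) -> Point3:
    """Compute the binding-site center an extraction will use."""
    if spec.mode == "atom_serials":
        by_serial = {a.serial: a for a in atoms}
        missing = [s for s in spec.serials if s not in by_serial]
        if missing:
            raise ValueError(f"atom serials not found: {missing}")
        return centroid([by_serial[s].coords for s in spec.serials])
    lig = _ligand_atoms(atoms, spec.ligand_id)  # type: ignore[arg-type]
    if spec.mode == "pyranose_ring":
        by_name = {a.atom_name: a for a in lig}
        missing = [n for n in PYRANOSE_RING_ATOMS if n not in by_name]
        if missing:
            raise ValueError(f"pyranose ring atoms missing from {spec.ligand_id}: {missing}")
        return centroid([by_name[n].coords for n in PYRANOSE_RING_ATOMS])
    return centroid([a.coords for a in lig])


def _dedupe_altloc(atoms: list[StructureAtom]) -> list[StructureAtom]:
    """Keep the highest-occupancy conformer per (chain, seq, resname, atom)."""
    best: dict[tuple, StructureAtom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.residue_seq, a.residue_name, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [best[k] for k in order]


def extract_site(
    atoms: Sequence[StructureAtom],
    center: Point3,
    cfg: ExtractionConfig = ExtractionConfig(),
    label: str = "positive",
    site_id: str = "psite",
) -> SiteExample:
    """Build a :class:`SiteExample` from structure atoms around ``center``.

    Retains protein (non-hetero, standard amino acid) heavy atoms with
    ``euclid(atom, center) <= radius`` — the sphere boundary is inclusive.
    Residues left with zero atoms are dropped; order is primary sequence.
    """
    kept: list[StructureAtom] = []
    for a in _dedupe_altloc(list(atoms)):
        if cfg.exclude_ligand_atoms and a.is_hetero:
            continue
        if a.residue_name not in _THREE_TO_LOWER:
            continue  # waters, cofactors, modified residues
        if cfg.exclude_hydrogens and (a.element.upper() in ("H", "D") or _is_hydrogen(a.atom_name)):
            continue
        if euclid(a.coords, center) <= cfg.radius:
            kept.append(a)

    if not kept:
        warnings.warn(f"no protein atoms within {cfg.radius} Å of center for {site_id}")

    residues: list[ResidueRecord] = []
    current_key: tuple | None = None
    bucket: list[StructureAtom] = []

    def flush() -> None:
        if not bucket:
            return
        first = bucket[0]
        rid = f"a{first.residue_seq}" if first.chain in ("", "A") else f"a{first.chain}{first.residue_seq}"
        rname = _THREE_TO_LOWER[first.residue_name]
        residues.append(
            ResidueRecord(rid, rname, tuple(AtomRecord(a.atom_name, rid, a.coords) for a in bucket))
        )

    for a in kept:
        key = (a.chain, a.residue_seq, a.residue_name)
        if key != current_key:
            flush()
            bucket = []
            current_key = key
        bucket.append(a)
    flush()

    return SiteExample(site_id, label, center, tuple(residues))
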