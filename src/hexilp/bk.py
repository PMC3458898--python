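"""Binding-site background knowledge: domain types and the Prolog fact dialect.

A binding site is represented relationally as ground Prolog facts over five
predicates::

    center_coords(pSITE, p(X,Y,Z)).
    has_aminoacid(pSITE, aNNN, res).
    has_atom(pSITE, aNNN, 'NAME', p(X,Y,Z)).

(``dist``, ``atom_to_center_dist``, ``atom_to_atom_dist`` and
``diff_aminoacid`` are derived at query time, never serialized.)

The order of residues and atoms in the fact file is semantically meaningful:
recall-bounded saturation only considers the first *recall* solutions of a
predicate, so the three ordering schemes (primary sequence, randomized,
domain-dependent) are implemented here as permutations of a site.
"""

from __future__ import annotations

import math
import re
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal as TLiteral

#: the 20 standard amino-acid three-letter codes, lowercase
AMINO_ACIDS = frozenset(
    "ala arg asn asp cys gln glu gly his ile leu lys met phe pro ser thr trp tyr val".split()
)

ORDERING_SCHEMES = ("primary_sequence", "randomized", "domain_dependent")
OrderingScheme = TLiteral["primary_sequence", "randomized", "domain_dependent"]

DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class Point3:
    """A 3-D coordinate in Ångström."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate: {v!r}")

    def close_to(self, other: "Point3", eps: float = DEFAULT_EPS) -> bool:
        return (
            abs(self.x - other.x) <= eps
            and abs(self.y - other.y) <= eps
            and abs(self.z - other.z) <= eps
        )

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y
        yield self.z


def euclid(p: Point3, q: Point3) -> float:
    """Euclidean distance between two points, in Å."""
    return math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))


@dataclass(frozen=True)
class AtomRecord:
    """A heavy atom of a binding-site residue.

    ``atom_name`` is the PDB atom name (``'CA'``, ``'OD2'``, ...);
    ``residue_ref`` identifies the owning residue within the site.
    """

    atom_name: str
    residue_ref: str
    coords: Point3

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("empty atom name")
        if _is_hydrogen(self.atom_name):
            raise ValueError(f"hydrogen atom not allowed: {self.atom_name!r}")


def _is_hydrogen(atom_name: str) -> bool:
    # PDB heavy-atom names never start with H except backbone amide 'H*'
    # variants; hexose-site files carry no hydrogens at all, so a leading H
    # (or digit-prefixed H, e.g. '1HB') marks a hydrogen.
    name = atom_name.lstrip("0123456789")
    return name.startswith(("H", "D"))


@dataclass(frozen=True)
class ResidueRecord:
    """A residue and its (ordered) atoms."""

    residue_id: str
    residue_name: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if self.residue_name not in AMINO_ACIDS:
            raise ValueError(f"unknown residue name: {self.residue_name!r}")
        names = [a.atom_name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate atom name in residue {self.residue_id}")
        for a in self.atoms:
            if a.residue_ref != self.residue_id:
                raise ValueError(
                    f"atom {a.atom_name} claims residue {a.residue_ref}, "
                    f"not {self.residue_id}"
                )


@dataclass(frozen=True)
class SiteExample:
    """One labelled binding site: a center plus the residues/atoms around it.

    ``site_id`` follows the ``pPDBID`` convention with a ``_2`` suffix for a
    protein's second site (e.g. ``p1HSJ_2``).  ``label`` is ``'positive'``
    (hexose-binding) or ``'negative'``.  Residue/atom order is exactly the
    order recall-bounded enumeration will use.
    """

    site_id: str
    label: str
    center: Point3
    residues: tuple[ResidueRecord, ...]
    ordering_scheme: OrderingScheme = "primary_sequence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive|negative, got {self.label!r}")
        ids = [r.residue_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate residue_id in site")

    def atoms(self) -> Iterator[AtomRecord]:
        """All atoms in site order."""
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def residue(self, residue_id: str) -> ResidueRecord:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        raise KeyError(residue_id)

    def check_radius(self, radius: float = 10.0) -> None:
        """Raise if any atom lies outside ``radius`` Å of the center."""
        for a in self.atoms():
            d = euclid(a.coords, self.center)
            if d > radius + 1e-6:
                raise ValueError(
                    f"atom {a.residue_ref}/{a.atom_name} at {d:.2f} Å "
                    f"exceeds extraction radius {radius} Å"
                )


# ---------------------------------------------------------------------------
# Fact dialect parsing / writing
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?"
_POINT = rf"p\(\s*({_NUM})\s*,\s*({_NUM})\s*,\s*({_NUM})\s*\)"
_RE_CENTER = re.compile(rf"^center_coords\(\s*(\w+)\s*,\s*{_POINT}\s*\)\.$")
_RE_AA = re.compile(r"^has_aminoacid\(\s*(\w+)\s*,\s*(\w+)\s*,\s*([a-z]{3})\s*\)\.$")
_RE_ATOM = re.compile(
    rf"^has_atom\(\s*(\w+)\s*,\s*(\w+)\s*,\s*['’‘]([\w'\*]+?)['’‘]\s*,\s*{_POINT}\s*\)\.$"
)


class FactParseError(ValueError):
    """Malformed or inconsistent fact-dialect text."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def parse_facts(
    text: str, label: str = "positive", ordering_scheme: OrderingScheme = "primary_sequence"
) -> SiteExample:
    """Parse fact-dialect text into a :class:`SiteExample`.

    The text must contain exactly one ``center_coords`` fact; every
    ``has_atom`` must reference a previously declared ``has_aminoacid``.
    Fact order is preserved.  ``%`` comments and blank lines are ignored.
    """
    site_id: str | None = None
    center: Point3 | None = None
    res_order: list[str] = []
    res_names: dict[str, str] = {}
    res_atoms: dict[str, list[AtomRecord]] = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        if m := _RE_CENTER.match(line):
            if center is not None:
                raise FactParseError("duplicate center_coords fact", line_no)
            site_id = m.group(1)
            center = Point3(*(float(m.group(i)) for i in (2, 3, 4)))
        elif m := _RE_AA.match(line):
            sid, rid, rname = m.groups()
            site_id = site_id or sid
            if rid in res_names:
                raise FactParseError(f"duplicate has_aminoacid for {rid}", line_no)
            if rname not in AMINO_ACIDS:
                raise FactParseError(f"unknown residue name {rname!r}", line_no)
            res_order.append(rid)
            res_names[rid] = rname
            res_atoms[rid] = []
        elif m := _RE_ATOM.match(line):
            sid, rid, aname = m.group(1), m.group(2), m.group(3)
            if rid not in res_names:
                raise FactParseError(f"dangling atom fact: residue {rid} undeclared", line_no)
            pt = Point3(*(float(m.group(i)) for i in (4, 5, 6)))
            res_atoms[rid].append(AtomRecord(aname, rid, pt))
        else:
            raise FactParseError(f"malformed term: {line!r}", line_no)

    if center is None:
        raise FactParseError("no center: missing center_coords fact")
    assert site_id is not None
    residues = tuple(
        ResidueRecord(rid, res_names[rid], tuple(res_atoms[rid])) for rid in res_order
    )
    return SiteExample(site_id, label, center, residues, ordering_scheme)


def write_facts(site: SiteExample) -> str:
    """Serialize a site back to fact-dialect text (coordinates at one decimal).

    Inverse of :func:`parse_facts` up to whitespace and quote style.
    """
    def pt(p: Point3) -> str:
        return f"p({p.x:.1f},{p.y:.1f},{p.z:.1f})"

    lines = [f"center_coords({site.site_id}, {pt(site.center)})."]
    for res in site.residues:
        lines.append(f"has_aminoacid({site.site_id}, {res.residue_id}, {res.residue_name}).")
        for a in res.atoms:
            lines.append(
                f"has_atom({site.site_id}, {a.residue_ref}, '{a.atom_name}', {pt(a.coords)})."
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Ordering schemes
# ---------------------------------------------------------------------------

def site_rng_seed(global_seed: int, site_id: str) -> int:
    """Per-site RNG seed: global seed XOR a stable hash of the site id."""
    return (int(global_seed) ^ zlib.crc32(site_id.encode())) & 0x7FFFFFFF


def order_site(site: SiteExample, scheme: OrderingScheme, seed: int = 0) -> SiteExample:
    """Reorder residues and atoms according to a recall-ordering scheme.

    primary_sequence
        the order of the source file — returned unchanged.
    randomized
        a seeded uniform permutation of the residues and of the atoms within
        each residue; the per-site seed is ``seed XOR crc32(site_id)`` so the
        permutation does not depend on dataset order.
    domain_dependent
        atoms sorted ascending by distance to the site center; residues
        sorted by their closest atom.  Sorts are stable, ties broken by
        source order.
    """
    if scheme not in ORDERING_SCHEMES:
        raise ValueError(f"unknown ordering scheme: {scheme!r}")
    if scheme == "primary_sequence":
        return replace(site, ordering_scheme=scheme)

    if scheme == "randomized":
        import numpy as np

        rng = np.random.default_rng(site_rng_seed(seed, site.site_id))
        res_perm = rng.permutation(len(site.residues))
        residues = []
        for i in res_perm:
            res = site.residues[i]
            atom_perm = rng.permutation(len(res.atoms))
            residues.append(replace(res, atoms=tuple(res.atoms[j] for j in atom_perm)))
        return replace(site, residues=tuple(residues), ordering_scheme=scheme, seed=seed)

    # domain_dependent
    def atom_key(a: AtomRecord) -> float:
        return euclid(a.coords, site.center)

    residues = [
        replace(res, atoms=tuple(sorted(res.atoms, key=atom_key)))
        for res in site.residues
    ]
    residues.sort(key=lambda r: min((atom_key(a) for a in r.atoms), default=math.inf))
    return replace(site, residues=tuple(residues), ordering_scheme=scheme)
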