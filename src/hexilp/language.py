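"""Hypothesis language: mode declarations, clauses, saturation, rendering.

Two binding-site representations are supported.

*atom-only* — the site is a bag of atoms in space::

    center_coords/2, has_atom/4, dist/4

where ``dist`` relates two previously introduced points (atom or center), so
expressing one distance costs three literals (two ``has_atom`` + one
``dist``).

*amino acid* — the site is a bag of residues that own atoms::

    has_aminoacid/3, atom_to_center_dist/4, atom_to_atom_dist/6,
    diff_aminoacid/2

with the structural bias that atoms may not appear "dangling": a residue must
be introduced by ``has_aminoacid`` before any distance literal may touch its
atoms.

Saturation builds the bottom clause of an example — the most specific clause
entailing it — under a *recall* bound: only the first ``recall`` solutions of
a non-determinate predicate, in site order, enter the bottom clause.  Distance
constants are rounded to 0.1 Å and carry a matching tolerance (default
0.5 Å).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .bk import SiteExample, euclid

DEFAULT_RECALL = 7
DEFAULT_TOLERANCE = 0.5

REPRESENTATIONS = ("atom_only", "amino_acid")

#: semantic types of clause variables / constants
#: (site, residue, point, residue-name, atom-name, distance)

@dataclass(frozen=True)
class Var:
    """A logical variable (rendered as an uppercase letter)."""

    name: str

    def __repr__(self) -> str:
        return f"Var({self.name})"


Term = object  # Var | str | float


@dataclass(frozen=True)
class ModeDecl:
    """Signature of a body predicate: per-argument role and type.

    Roles: ``in`` (input variable, must be bound), ``out`` (output variable,
    gets bound), ``const`` (ground constant from the observed vocabulary).
    ``recall`` caps how many solutions enter a bottom clause.
    """

    predicate: str
    roles: tuple[tuple[str, str], ...]  # (role, semantic type)
    recall: int = DEFAULT_RECALL

    def __post_init__(self) -> None:
        if self.recall < 1:
            raise ValueError("recall must be >= 1")
        for role, _ in self.roles:
            if role not in ("in", "out", "const"):
                raise ValueError(f"bad role {role!r}")

    @property
    def arity(self) -> int:
        return len(self.roles)

    @property
    def key(self) -> str:
        return f"{self.predicate}/{self.arity}"


def modes_for(representation: str, recall: int = DEFAULT_RECALL) -> tuple[ModeDecl, ...]:
    """The mode set of a representation (all recalls defaulting to 7)."""
    if representation == "atom_only":
        return (
            ModeDecl("center_coords", (("in", "site"), ("out", "point")), recall),
            ModeDecl(
                "has_atom",
                (("in", "site"), ("out", "residue"), ("const", "atom-name"), ("out", "point")),
                recall,
            ),
            ModeDecl(
                "dist",
                (("in", "point"), ("in", "point"), ("const", "distance"), ("const", "tolerance")),
                recall,
            ),
        )
    if representation == "amino_acid":
        return (
            ModeDecl(
                "has_aminoacid",
                (("in", "site"), ("out", "residue"), ("const", "residue-name")),
                recall,
            ),
            ModeDecl(
                "atom_to_center_dist",
                (("in", "residue"), ("const", "atom-name"), ("const", "distance"), ("const", "tolerance")),
                recall,
            ),
            ModeDecl(
                "atom_to_atom_dist",
                (
                    ("in", "residue"),
                    ("in", "residue"),
                    ("const", "atom-name"),
                    ("const", "atom-name"),
                    ("const", "distance"),
                    ("const", "tolerance"),
                ),
                recall,
            ),
            ModeDecl("diff_aminoacid", (("in", "residue"), ("in", "residue")), recall),
        )
    raise ValueError(f"unknown representation: {representation!r}")


DISTANCE_PREDICATES = ("dist", "atom_to_center_dist", "atom_to_atom_dist")


@dataclass(frozen=True)
class Literal:
    """One body literal; for distance predicates the last two arguments are
    the stored distance (Å, one decimal) and the matching tolerance (Å)."""

    predicate: str
    args: tuple[Term, ...]

    @property
    def is_distance(self) -> bool:
        return self.predicate in DISTANCE_PREDICATES

    @property
    def value(self) -> float:
        if not self.is_distance:
            raise AttributeError(f"{self.predicate} carries no distance value")
        return float(self.args[-2])  # type: ignore[arg-type]

    @property
    def tolerance(self) -> float:
        if not self.is_distance:
            raise AttributeError(f"{self.predicate} carries no tolerance")
        return float(self.args[-1])  # type: ignore[arg-type]

    def variables(self) -> tuple[Var, ...]:
        return tuple(a for a in self.args if isinstance(a, Var))


@dataclass(frozen=True)
class Clause:
    """``bind(A) :- body`` over one of the two representations."""

    body: tuple[Literal, ...]
    representation: str = "amino_acid"
    head_var: Var = Var("A")

    @property
    def length(self) -> int:
        """Clause length: head plus body literals."""
        return 1 + len(self.body)

    def variables(self) -> tuple[Var, ...]:
        seen: dict[Var, None] = {self.head_var: None}
        for lit in self.body:
            for v in lit.variables():
                seen.setdefault(v, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_MODE_INDEX: dict[str, dict[str, ModeDecl]] = {
    rep: {m.predicate: m for m in modes_for(rep)} for rep in REPRESENTATIONS
}


@dataclass(frozen=True)
class Violation:
    literal_index: int  # -1 for clause-level problems
    message: str


def validate_clause(clause: Clause) -> list[Violation]:
    """Check connectivity and the no-dangling-atom bias; empty list if ok."""
    if clause.representation not in _MODE_INDEX:
        return [Violation(-1, f"unknown representation {clause.representation!r}")]
    modes = _MODE_INDEX[clause.representation]
    violations: list[Violation] = []
    bound: dict[Var, str] = {clause.head_var: "site"}  # var -> semantic type
    residue_vars: set[Var] = set()

    for i, lit in enumerate(clause.body):
        mode = modes.get(lit.predicate)
        if mode is None:
            violations.append(Violation(i, f"predicate {lit.predicate!r} not in representation"))
            continue
        if len(lit.args) != mode.arity:
            violations.append(Violation(i, f"{lit.predicate} arity {len(lit.args)} != {mode.arity}"))
            continue
        ok = True
        for arg, (role, typ) in zip(lit.args, mode.roles):
            if role == "const":
                if isinstance(arg, Var):
                    violations.append(Violation(i, f"variable in constant position of {lit.predicate}"))
                    ok = False
                elif typ == "tolerance" and float(arg) < 0:  # type: ignore[arg-type]
                    violations.append(Violation(i, "negative distance tolerance"))
                    ok = False
            elif role == "in":
                if not isinstance(arg, Var):
                    continue  # ground input is legal, if unusual
                if arg not in bound:
                    if typ == "residue":
                        violations.append(
                            Violation(i, f"dangling residue variable {arg.name} in {lit.predicate}")
                        )
                    else:
                        violations.append(
                            Violation(i, f"unbound input variable {arg.name} in {lit.predicate}")
                        )
                    ok = False
                elif bound[arg] != typ:
                    violations.append(
                        Violation(i, f"variable {arg.name} used as {typ}, bound as {bound[arg]}")
                    )
                    ok = False
                elif typ == "residue" and lit.predicate in (
                    "atom_to_center_dist",
                    "atom_to_atom_dist",
                    "diff_aminoacid",
                ) and arg not in residue_vars:
                    violations.append(
                        Violation(i, f"residue variable {arg.name} not introduced by has_aminoacid")
                    )
                    ok = False
        if ok:
            for arg, (role, typ) in zip(lit.args, mode.roles):
                if role == "out" and isinstance(arg, Var):
                    bound[arg] = typ
                    if typ == "residue" and lit.predicate in ("has_aminoacid", "has_atom"):
                        if lit.predicate == "has_aminoacid":
                            residue_vars.add(arg)
    return violations


def is_valid(clause: Clause) -> bool:
    return not validate_clause(clause)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

def _var_stream(skip: Iterable[str] = ("A",)):
    """B, C, ..., Z, V26, V27, ... skipping reserved names."""
    skipped = set(skip)
    i = 0
    while True:
        name = chr(ord("A") + i) if i < 26 else f"V{i}"
        i += 1
        if name in skipped:
            continue
        yield Var(name)


def saturate(
    site: SiteExample,
    representation: str = "amino_acid",
    recall: int = DEFAULT_RECALL,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Clause:
    """Bottom clause of an example: the conjunction of all admissible features,
    with at most ``recall`` solutions per non-determinate predicate, taken in
    site order.

    amino_acid: the first ``recall`` residues are introduced; per residue the
    first ``recall`` atoms get an ``atom_to_center_dist`` literal, and each
    such atom gets ``atom_to_atom_dist`` literals to the first ``recall``
    previously enumerated atoms (of already-introduced residues, intra-residue
    pairs included).  ``diff_aminoacid`` is emitted for every pair of
    introduced same-named residues.

    atom_only: ``center_coords`` introduces the center point, the first
    ``recall`` atoms are introduced by ``has_atom``, and each point gets
    ``dist`` literals to the first ``recall`` previously introduced points
    (center included).
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation: {representation!r}")
    A = Var("A")
    vars_ = _var_stream()
    body: list[Literal] = []

    def d1(x: float) -> float:
        return round(x, 1)

    if representation == "amino_acid":
        res_vars: list[Var] = []
        introduced: list[tuple[int, Var, str, object]] = []  # (res idx, var, atom name, coords)
        residues = site.residues[:recall]
        for i, res in enumerate(residues):
            rv = next(vars_)
            res_vars.append(rv)
            body.append(Literal("has_aminoacid", (A, rv, res.residue_name)))
            for j, earlier in enumerate(residues[:i]):
                if earlier.residue_name == res.residue_name:
                    body.append(Literal("diff_aminoacid", (res_vars[j], rv)))
            for atom in res.atoms[:recall]:
                dc = d1(euclid(atom.coords, site.center))
                body.append(Literal("atom_to_center_dist", (rv, atom.atom_name, dc, tolerance)))
                targets = introduced[-recall:] if recall else []
                for (_, tv, tname, tcoords) in targets:
                    da = d1(euclid(tcoords, atom.coords))  # type: ignore[arg-type]
                    body.append(
                        Literal("atom_to_atom_dist", (tv, rv, tname, atom.atom_name, da, tolerance))
                    )
                introduced.append((i, rv, atom.atom_name, atom.coords))
        return Clause(tuple(body), "amino_acid")

    # atom_only
    center_var = next(vars_)
    body.append(Literal("center_coords", (A, center_var)))
    points: list[tuple[Var, object]] = [(center_var, site.center)]
    atoms = list(site.atoms())[:recall]
    for atom in atoms:
        rv = next(vars_)
        pv = next(vars_)
        body.append(Literal("has_atom", (A, rv, atom.atom_name, pv)))
        for (qv, qc) in points[-recall:]:
            body.append(Literal("dist", (qv, pv, d1(euclid(qc, atom.coords)), tolerance)))  # type: ignore[arg-type]
        points.append((pv, atom.coords))
    return Clause(tuple(body), "atom_only")


# ---------------------------------------------------------------------------
# Rendering and parsing
# ---------------------------------------------------------------------------

def _fmt_term(t: Term, typ: str) -> str:
    if isinstance(t, Var):
        return t.name
    if typ == "atom-name":
        return f"'{t}'"
    if typ in ("distance", "tolerance"):
        return f"{float(t):.1f}"  # type: ignore[arg-type]
    return str(t)


def render_prolog(clause: Clause) -> str:
    """Serialize as a Prolog clause (re-parses to an equal clause)."""
    if not clause.body:
        return f"bind({clause.head_var.name}):- true."
    modes = _MODE_INDEX[clause.representation]
    lines = [f"bind({clause.head_var.name}):-"]
    for i, lit in enumerate(clause.body):
        mode = modes[lit.predicate]
        args = ",".join(_fmt_term(a, typ) for a, (_, typ) in zip(lit.args, mode.roles))
        sep = "." if i == len(clause.body) - 1 else ","
        lines.append(f"   {lit.predicate}({args}){sep}")
    return "\n".join(lines)


_RE_LITERAL = re.compile(r"(\w+)\(([^()]*)\)")


def parse_prolog(text: str, representation: str = "amino_acid") -> Clause:
    """Parse a clause in the dialect emitted by :func:`render_prolog`."""
    stripped = "\n".join(line.split("%", 1)[0] for line in text.splitlines())
    flat = " ".join(stripped.split())
    if not flat:
        raise ValueError("empty clause text")
    head, sep, body_text = flat.partition(":-")
    m = re.match(r"^bind\(\s*(\w+)\s*\)\s*$", head.strip())
    if m is None:
        raise ValueError(f"malformed clause head: {head!r}")
    head_var = Var(m.group(1))
    body_text = body_text.strip().rstrip(".")
    if not sep or body_text in ("", "true"):
        return Clause((), representation, head_var)
    modes = _MODE_INDEX[representation]
    body: list[Literal] = []
    for pm in _RE_LITERAL.finditer(body_text):
        pred, argtext = pm.group(1), pm.group(2)
        mode = modes.get(pred)
        if mode is None:
            raise ValueError(f"unknown predicate {pred!r} for {representation}")
        raw = [a.strip() for a in argtext.split(",")]
        if len(raw) != mode.arity:
            raise ValueError(f"{pred}: expected {mode.arity} args, got {len(raw)}")
        args: list[Term] = []
        for tok, (role, typ) in zip(raw, mode.roles):
            if re.fullmatch(r"['’‘].*['’‘]", tok):
                args.append(tok[1:-1])
            elif re.fullmatch(r"[-+]?\d+(\.\d+)?", tok):
                args.append(float(tok))
            elif tok[:1].isupper():
                args.append(Var(tok))
            else:
                args.append(tok)
        body.append(Literal(pred, tuple(args)))
    return Clause(tuple(body), representation, head_var)


def _article(word: str) -> str:
    return "an" if word[:1] in "aeiou" else "a"


def render_english(clause: Clause) -> str:
    """Translate a clause into the field's rule-description English, e.g.
    "It contains two different asn residues and an asp residue whose cg atom
    is 5.4±0.5 Å away from the binding center."
    """
    if not clause.body:
        return "It imposes no constraints (covers every site)."
    if clause.representation != "amino_acid":
        # atom_only clauses read off points, not residues; keep it literal.
        parts = []
        for lit in clause.body:
            if lit.predicate == "has_atom":
                parts.append(f"{_article(str(lit.args[2]).lower())} {str(lit.args[2]).lower()} atom")
            elif lit.predicate == "dist":
                parts.append(f"two of its points {lit.value:g}±{lit.tolerance:g} Å apart")
        return "It contains " + _join_english(parts) + "." if parts else "It names the binding center only."

    names: dict[Var, str] = {}
    constraints: dict[Var, list[str]] = {}
    diff_pairs: list[tuple[Var, Var]] = []
    cross: list[str] = []
    for lit in clause.body:
        if lit.predicate == "has_aminoacid":
            rv = lit.args[1]
            names[rv] = str(lit.args[2])  # type: ignore[index]
            constraints.setdefault(rv, [])  # type: ignore[arg-type]
        elif lit.predicate == "diff_aminoacid":
            diff_pairs.append((lit.args[0], lit.args[1]))  # type: ignore[arg-type]
        elif lit.predicate == "atom_to_center_dist":
            rv = lit.args[0]
            atom = str(lit.args[1]).lower()
            constraints.setdefault(rv, []).append(  # type: ignore[arg-type]
                f"whose {atom} atom is {lit.value:g}±{lit.tolerance:g} Å away from the binding center"
            )
        elif lit.predicate == "atom_to_atom_dist":
            b, c = lit.args[0], lit.args[1]
            a1, a2 = str(lit.args[2]).lower(), str(lit.args[3]).lower()
            if b == c:
                constraints.setdefault(b, []).append(  # type: ignore[arg-type]
                    f"whose {a1} and {a2} atoms are {lit.value:g}±{lit.tolerance:g} Å apart"
                )
            else:
                nb = names.get(b, "residue")  # type: ignore[arg-type]
                nc = names.get(c, "residue")  # type: ignore[arg-type]
                cross.append(
                    f"the {nb}'s {a1} atom is {lit.value:g}±{lit.tolerance:g} Å "
                    f"from the {nc}'s {a2} atom"
                )

    # pair same-named unconstrained residues joined by diff_aminoacid
    paired: set[Var] = set()
    parts: list[str] = []
    for b, c in diff_pairs:
        if (
            names.get(b) == names.get(c)
            and not constraints.get(b)
            and not constraints.get(c)
            and b not in paired
            and c not in paired
        ):
            parts.append(f"two different {names[b]} residues")
            paired.update((b, c))
    for rv, name in names.items():
        if rv in paired:
            continue
        desc = f"{_article(name)} {name} residue"
        if constraints.get(rv):
            desc += " " + " and ".join(constraints[rv])
        parts.append(desc)
    sentence = "It contains " + _join_english(parts)
    if cross:
        sentence += ", and " + _join_english(cross)
    return sentence + "."


def _join_english(parts: Sequence[str]) -> str:
    if len(parts) <= 1:
        return "".join(parts)
    return ", ".join(parts[:-1]) + " and " + parts[-1]
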