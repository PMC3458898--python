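"""Clause coverage: θ-subsumption against a site's ground facts.

A clause covers a site iff its variables can be bound to the site's constants
so that every body literal holds.  Distance literals carry a stored value
``d`` and tolerance ``t`` and match an actual distance ``a`` iff
``|a − d| <= t``.

Two complete evaluation strategies are provided — left-to-right SLD-style
backtracking and a fail-first "smallest variable domain" strategy that at
each step resolves the admissible literal with the fewest candidate
solutions — plus a brute-force enumerator used as an oracle in tests.  All
three agree on coverage; they differ only in the order the search space is
explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

from .bk import Point3, SiteExample, euclid
from .language import Clause, Literal, Var

Value = object  # residue id (str) | point key (tuple) | site id (str)
Binding = dict[Var, Value]

CENTER_KEY = ("center",)


class SiteFacts:
    """Indexed ground facts of one site, with memoized distances."""

    def __init__(self, site: SiteExample):
        self.site = site
        self.residue_name: dict[str, str] = {}
        self.residue_ids: list[str] = []
        self.atom_coords: dict[tuple[str, str], Point3] = {}
        self.atoms_by_name: dict[str, list[tuple[str, str]]] = {}
        for res in site.residues:
            self.residue_ids.append(res.residue_id)
            self.residue_name[res.residue_id] = res.residue_name
            for a in res.atoms:
                key = (res.residue_id, a.atom_name)
                self.atom_coords[key] = a.coords
                self.atoms_by_name.setdefault(a.atom_name, []).append(key)
        self._dist_cache: dict[tuple, float] = {}

    def point(self, key: tuple) -> Point3:
        return self.site.center if key == CENTER_KEY else self.atom_coords[key]

    def distance(self, k1: tuple, k2: tuple) -> float:
        if k2 < k1:
            k1, k2 = k2, k1
        cached = self._dist_cache.get((k1, k2))
        if cached is None:
            cached = euclid(self.point(k1), self.point(k2))
            self._dist_cache[(k1, k2)] = cached
        return cached

    def center_distance(self, residue_id: str, atom_name: str) -> float | None:
        key = (residue_id, atom_name)
        if key not in self.atom_coords:
            return None
        return self.distance(CENTER_KEY, key)


@dataclass
class CoverageResult:
    covered: bool
    binding: Binding | None = None
    stats: dict[str, int] = field(default_factory=dict)


def literal_matches(literal: Literal, facts: SiteFacts, partial: Binding) -> list[Binding]:
    """All one-step extensions of ``partial`` that satisfy ``literal``.

    Input variables of the literal must already be bound in ``partial``
    (contract violation otherwise); output variables are bound in the
    returned extensions, which enumerate candidates in site order.
    """
    p = literal.predicate
    args = literal.args

    def need(v: Term) -> Value:  # type: ignore[name-defined]
        if isinstance(v, Var):
            if v not in partial:
                raise ValueError(f"unbound input variable {v.name} in {p}")
            return partial[v]
        return v

    if p == "has_aminoacid":
        _, rv, rname = args
        out: list[Binding] = []
        for rid in facts.residue_ids:
            if facts.residue_name[rid] != rname:
                continue
            if isinstance(rv, Var) and rv in partial:
                if partial[rv] == rid:
                    out.append(dict(partial))
            elif isinstance(rv, Var):
                ext = dict(partial)
                ext[rv] = rid
                out.append(ext)
            elif rv == rid:
                out.append(dict(partial))
        return out

    if p == "diff_aminoacid":
        b, c = (need(args[0]), need(args[1]))
        return [dict(partial)] if b != c else []

    if p == "atom_to_center_dist":
        rid = need(args[0])
        atom_name, d, t = args[1], float(args[2]), float(args[3])  # type: ignore[arg-type]
        actual = facts.center_distance(rid, atom_name)  # type: ignore[arg-type]
        return [dict(partial)] if actual is not None and abs(actual - d) <= t else []

    if p == "atom_to_atom_dist":
        rid1, rid2 = need(args[0]), need(args[1])
        a1, a2, d, t = args[2], args[3], float(args[4]), float(args[5])  # type: ignore[arg-type]
        k1, k2 = (rid1, a1), (rid2, a2)
        if k1 not in facts.atom_coords or k2 not in facts.atom_coords or k1 == k2:
            return []
        return [dict(partial)] if abs(facts.distance(k1, k2) - d) <= t else []

    if p == "center_coords":
        pv = args[1]
        if isinstance(pv, Var) and pv not in partial:
            ext = dict(partial)
            ext[pv] = CENTER_KEY
            return [ext]
        return [dict(partial)] if need(pv) == CENTER_KEY else []

    if p == "has_atom":
        _, rv, atom_name, pv = args
        out = []
        for key in facts.atoms_by_name.get(atom_name, []):  # type: ignore[arg-type]
            rid = key[0]
            ext = dict(partial)
            if isinstance(rv, Var):
                if rv in partial and partial[rv] != rid:
                    continue
                ext[rv] = rid
            elif rv != rid:
                continue
            if isinstance(pv, Var):
                if pv in partial and partial[pv] != key:
                    continue
                ext[pv] = key
            elif pv != key:
                continue
            out.append(ext)
        return out

    if p == "dist":
        k1, k2 = need(args[0]), need(args[1])
        d, t = float(args[2]), float(args[3])  # type: ignore[arg-type]
        if k1 == k2:
            return []
        return [dict(partial)] if abs(facts.distance(k1, k2) - d) <= t else []  # type: ignore[arg-type]

    raise ValueError(f"unknown predicate {p!r}")


def _inputs_bound(literal: Literal, binding: Binding) -> bool:
    """True if the literal can be evaluated now (all join variables bound).

    Output positions may stay unbound; for our mode language the only
    variables that must be pre-bound are those a distance or diff literal
    consumes, plus the site variable which the head always binds.
    """
    from .language import _MODE_INDEX

    for rep_modes in _MODE_INDEX.values():
        mode = rep_modes.get(literal.predicate)
        if mode is not None:
            break
    else:  # pragma: no cover
        raise ValueError(literal.predicate)
    for arg, (role, _) in zip(literal.args, mode.roles):
        if role == "in" and isinstance(arg, Var) and arg not in binding:
            return False
    return True


def _solve_sld(body: Sequence[Literal], facts: SiteFacts, binding: Binding) -> Iterator[Binding]:
    """Depth-first left-to-right backtracking; yields every solution."""
    if not body:
        yield dict(binding)
        return
    head, rest = body[0], body[1:]
    for ext in literal_matches(head, facts, binding):
        yield from _solve_sld(rest, facts, ext)


def _solve_smallest_domain(
    remaining: list[Literal], facts: SiteFacts, binding: Binding
) -> Iterator[Binding]:
    """Fail-first search: resolve the admissible literal with the fewest
    candidate extensions, propagating bindings after each choice."""
    if not remaining:
        yield dict(binding)
        return
    best_i, best_ext = None, None
    for i, lit in enumerate(remaining):
        if not _inputs_bound(lit, binding):
            continue
        ext = literal_matches(lit, facts, binding)
        if best_ext is None or len(ext) < len(best_ext):
            best_i, best_ext = i, ext
        if not ext:
            break
    if best_i is None:
        # no admissible literal: clause is disconnected; fall back to order
        best_i, best_ext = 0, literal_matches(remaining[0], facts, binding)
    rest = remaining[:best_i] + remaining[best_i + 1 :]
    for ext in best_ext or []:
        yield from _solve_smallest_domain(rest, facts, ext)


def covers(
    clause: Clause, site: SiteExample | SiteFacts, strategy: str = "sld"
) -> CoverageResult:
    """Does the clause cover the site?  First solution short-circuits."""
    facts = site if isinstance(site, SiteFacts) else SiteFacts(site)
    binding: Binding = {clause.head_var: facts.site.site_id}
    if strategy == "sld":
        it = _solve_sld(clause.body, facts, binding)
    elif strategy == "smallest_domain":
        it = _solve_smallest_domain(list(clause.body), facts, binding)
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")
    for sol in it:
        return CoverageResult(True, sol)
    return CoverageResult(False, None)


def instantiate(clause: Clause, site: SiteExample | SiteFacts) -> list[dict]:
    """Every satisfying binding, with the realized distance per distance
    literal — the reverse-engineering report behind rule visualization."""
    facts = site if isinstance(site, SiteFacts) else SiteFacts(site)
    out = []
    seen: set[tuple] = set()
    for sol in _solve_sld(clause.body, facts, {clause.head_var: facts.site.site_id}):
        key = tuple(sorted((v.name, repr(sol[v])) for v in sol))
        if key in seen:
            continue
        seen.add(key)
        realized = []
        for i, lit in enumerate(clause.body):
            if not lit.is_distance:
                continue
            if lit.predicate == "atom_to_center_dist":
                rid = sol[lit.args[0]] if isinstance(lit.args[0], Var) else lit.args[0]
                actual = facts.center_distance(rid, lit.args[1])  # type: ignore[arg-type]
            elif lit.predicate == "atom_to_atom_dist":
                r1 = sol[lit.args[0]] if isinstance(lit.args[0], Var) else lit.args[0]
                r2 = sol[lit.args[1]] if isinstance(lit.args[1], Var) else lit.args[1]
                actual = facts.distance((r1, lit.args[2]), (r2, lit.args[3]))  # type: ignore[arg-type]
            else:  # dist
                k1 = sol[lit.args[0]] if isinstance(lit.args[0], Var) else lit.args[0]
                k2 = sol[lit.args[1]] if isinstance(lit.args[1], Var) else lit.args[1]
                actual = facts.distance(k1, k2)  # type: ignore[arg-type]
            realized.append(
                {"literal_index": i, "predicate": lit.predicate,
                 "stored": lit.value, "tolerance": lit.tolerance, "realized": actual}
            )
        out.append({"binding": {v.name: sol[v] for v in sol}, "distances": realized})
    return out


def brute_force_covers(clause: Clause, site: SiteExample | SiteFacts, guard: int = 60) -> bool:
    """Oracle: exhaustively enumerate all variable assignments.

    Residue variables range over every residue id, point variables over the
    center plus every atom.  Refuses sites with more than ``guard`` atoms.
    """
    facts = site if isinstance(site, SiteFacts) else SiteFacts(site)
    if facts.site.n_atoms > guard:
        raise ValueError(f"brute-force guard exceeded: {facts.site.n_atoms} atoms > {guard}")
    from .language import _MODE_INDEX

    modes = _MODE_INDEX[clause.representation]
    var_type: dict[Var, str] = {}
    for lit in clause.body:
        mode = modes[lit.predicate]
        for arg, (_, typ) in zip(lit.args, mode.roles):
            if isinstance(arg, Var) and arg != clause.head_var:
                var_type[arg] = typ
    domains = {
        "residue": list(facts.residue_ids),
        "point": [CENTER_KEY] + list(facts.atom_coords),
        "site": [facts.site.site_id],
    }
    variables = list(var_type)

    def ground_ok(binding: Binding) -> bool:
        for lit in clause.body:
            try:
                if not literal_matches(lit, facts, binding):
                    return False
            except ValueError:
                return False
        return True

    def rec(i: int, binding: Binding) -> bool:
        if i == len(variables):
            return ground_ok(binding)
        v = variables[i]
        for val in domains[var_type[v]]:
            binding[v] = val
            if rec(i + 1, binding):
                return True
        binding.pop(v, None)
        return False

    return rec(0, {clause.head_var: facts.site.site_id})


def coverage(
    clause: Clause, dataset: Sequence[SiteExample | SiteFacts], strategy: str = "smallest_domain"
) -> tuple[int, int, list[str], list[str]]:
    """Count covered positives and negatives over a labelled dataset.

    Returns ``(P, N, covered_positive_ids, covered_negative_ids)`` with the
    id lists sorted.
    """
    pos_ids: list[str] = []
    neg_ids: list[str] = []
    for site in dataset:
        facts = site if isinstance(site, SiteFacts) else SiteFacts(site)
        if covers(clause, facts, strategy).covered:
            (pos_ids if facts.site.label == "positive" else neg_ids).append(facts.site.site_id)
    return len(pos_ids), len(neg_ids), sorted(pos_ids), sorted(neg_ids)
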