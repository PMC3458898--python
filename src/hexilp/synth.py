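"""Synthetic binding-site generator with planted distance patterns.

Sites are generated inside the standard 10 Å extraction sphere.  A *planted
rule* — e.g. "two different asn residues plus an asp whose CG atom is
5.4±0.5 Å from the center" — is embedded in *carrier* sites with realized
distances safely inside the matching tolerance, while *non-carrier* sites are
rejection-sampled until the rule's clause provably does not cover them.  The
generator therefore produces datasets with exactly known ground truth,
which is what the learner-recovery and coverage tests rely on.

Decoy residues draw from the 20 standard amino acids with their canonical
heavy-atom names; only the names, not realistic internal geometry, are
guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bk import AtomRecord, Point3, ResidueRecord, SiteExample, euclid, write_facts
from .coverage import SiteFacts, covers
from .language import Clause, Literal, Var, _var_stream

#: canonical heavy-atom names per residue (backbone + side chain)
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    "ala": ("N", "CA", "C", "O", "CB"),
    "arg": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "asn": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "asp": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "cys": ("N", "CA", "C", "O", "CB", "SG"),
    "gln": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "glu": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "gly": ("N", "CA", "C", "O"),
    "his": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ile": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "leu": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "lys": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "met": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "phe": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "pro": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "ser": ("N", "CA", "C", "O", "CB", "OG"),
    "thr": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "trp": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "tyr": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "val": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}


class InfeasibleGeometry(ValueError):
    """Planted constraints cannot be realized inside the sphere."""


@dataclass(frozen=True)
class ResidueRequirement:
    """One residue a planted rule demands: a name plus distance constraints
    on its atoms.  ``center_dists`` are (atom, d, t) to the site center;
    ``intra_dists`` are (atom1, atom2, d, t) within the residue."""

    name: str
    center_dists: tuple[tuple[str, float, float], ...] = ()
    intra_dists: tuple[tuple[str, str, float, float], ...] = ()


@dataclass(frozen=True)
class PlantedRule:
    """A relational pattern expressible as an amino-acid-representation
    clause: required residues, their distance constraints, and which residue
    pairs must be distinct."""

    residues: tuple[ResidueRequirement, ...]
    distinct_pairs: tuple[tuple[int, int], ...] = ()
    cross_dists: tuple[tuple[int, int, str, str, float, float], ...] = ()

    def to_clause(self) -> Clause:
        """The pattern as a valid amino_acid clause."""
        A = Var("A")
        stream = _var_stream()
        rvars = [next(stream) for _ in self.residues]
        body: list[Literal] = []
        for i, req in enumerate(self.residues):
            body.append(Literal("has_aminoacid", (A, rvars[i], req.name)))
            for j, i2 in self.distinct_pairs:
                if i2 == i:
                    body.append(Literal("diff_aminoacid", (rvars[j], rvars[i])))
            for atom, d, t in req.center_dists:
                body.append(Literal("atom_to_center_dist", (rvars[i], atom, round(d, 1), t)))
            for a1, a2, d, t in req.intra_dists:
                body.append(
                    Literal("atom_to_atom_dist", (rvars[i], rvars[i], a1, a2, round(d, 1), t))
                )
            for i1, i2, a1, a2, d, t in self.cross_dists:
                if i2 == i:
                    body.append(
                        Literal("atom_to_atom_dist", (rvars[i1], rvars[i], a1, a2, round(d, 1), t))
                    )
        return Clause(tuple(body), "amino_acid")


def asn_pair_asp_rule(tolerance: float = 0.5) -> PlantedRule:
    """Two different asn residues plus an asp whose CG atom sits 5.4 Å from
    the binding center — the canonical planar-polar hexose pattern."""
    return PlantedRule(
        residues=(
            ResidueRequirement("asn"),
            ResidueRequirement("asn"),
            ResidueRequirement("asp", center_dists=(("CG", 5.4, tolerance),)),
        ),
        distinct_pairs=((0, 1),),
    )


def asn_glu_rule(tolerance: float = 0.5) -> PlantedRule:
    """An asn whose N and C atoms are 2.4 Å apart plus a glu whose CB and CG
    atoms are 8.0 and 6.9 Å from the binding center."""
    return PlantedRule(
        residues=(
            ResidueRequirement("asn", intra_dists=(("N", "C", 2.4, tolerance),)),
            ResidueRequirement(
                "glu", center_dists=(("CB", 8.0, tolerance), ("CG", 6.9, tolerance))
            ),
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 20
    n_neg: int = 20
    pattern_frequency_pos: float = 1.0
    pattern_frequency_neg: float = 0.0
    decoy_residues: tuple[int, int] = (3, 6)     # inclusive range per site
    decoy_atoms: tuple[int, int] = (3, 5)        # atoms per decoy residue
    jitter: float = 0.2                          # Å, carrier realization slack
    radius: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.pattern_frequency_pos, self.pattern_frequency_neg):
            if not 0.0 <= f <= 1.0:
                raise ValueError("pattern frequencies must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _uniform_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    return _unit(rng) * radius * rng.random() ** (1 / 3)


def _on_sphere_pair(
    rng: np.random.Generator, anchor: np.ndarray, r_center: float | None,
    d_pair: float, radius: float,
) -> np.ndarray:
    """A point at distance ``d_pair`` from ``anchor`` and, if requested,
    ``r_center`` from the origin (random point on the intersection circle)."""
    if r_center is None:
        for _ in range(64):
            p = anchor + _unit(rng) * d_pair
            if np.linalg.norm(p) <= radius:
                return p
        raise InfeasibleGeometry(f"pair distance {d_pair} leaves the sphere")
    a = float(np.linalg.norm(anchor))
    if a == 0.0:
        return _unit(rng) * r_center
    if not abs(r_center - a) <= d_pair <= r_center + a:
        raise InfeasibleGeometry(
            f"no point at {r_center} Å from center and {d_pair} Å from anchor at {a} Å"
        )
    # circle: intersection of sphere(0, r_center) and sphere(anchor, d_pair)
    n = anchor / a
    x = (a * a + r_center * r_center - d_pair * d_pair) / (2 * a)
    rho = math.sqrt(max(r_center * r_center - x * x, 0.0))
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    phi = rng.random() * 2 * math.pi
    return n * x + rho * (math.cos(phi) * e1 + math.sin(phi) * e2)


# --------------------------------------------------------------------------
# site generation
# --------------------------------------------------------------------------

def _carrier_residue(
    req: ResidueRequirement, rng: np.random.Generator, cfg: GeneratorConfig,
    residue_id: str,
) -> ResidueRecord:
    coords: dict[str, np.ndarray] = {}
    for atom, d, t in req.center_dists:
        margin = min(cfg.jitter, max(t - 0.15, 0.0))
        r = d + rng.uniform(-margin, margin)
        if r > cfg.radius:
            raise InfeasibleGeometry(f"center distance {d} exceeds sphere radius")
        coords[atom] = _unit(rng) * r
    for a1, a2, d, t in req.intra_dists:
        margin = min(cfg.jitter, max(t - 0.15, 0.0))
        dp = d + rng.uniform(-margin, margin)
        if a1 not in coords and a2 not in coords:
            coords[a1] = _uniform_ball(rng, max(cfg.radius - dp, 0.1))
        first, second = (a1, a2) if a1 in coords else (a2, a1)
        if second in coords:  # both already placed by center constraints
            if abs(float(np.linalg.norm(coords[a1] - coords[a2])) - d) > t:
                raise InfeasibleGeometry("conflicting center and pair constraints")
            continue
        r_center = None
        coords[second] = _on_sphere_pair(rng, coords[first], r_center, dp, cfg.radius)
    # pad with a couple of unconstrained atoms of the residue's repertoire
    pool = [a for a in RESIDUE_ATOMS[req.name] if a not in coords]
    for a in rng.permutation(pool)[:2]:
        coords[str(a)] = _uniform_ball(rng, cfg.radius)
    # preserve canonical atom order
    names = [a for a in RESIDUE_ATOMS[req.name] if a in coords]
    return ResidueRecord(
        residue_id,
        req.name,
        tuple(
            AtomRecord(n, residue_id, Point3(*map(float, coords[n]))) for n in names
        ),
    )


def _decoy_residue(
    rng: np.random.Generator, cfg: GeneratorConfig, residue_id: str,
    exclude_names: tuple[str, ...] = (),
) -> ResidueRecord:
    names = sorted(set(RESIDUE_ATOMS) - set(exclude_names))
    rname = str(rng.choice(names))
    k = int(rng.integers(cfg.decoy_atoms[0], cfg.decoy_atoms[1] + 1))
    pool = RESIDUE_ATOMS[rname]
    chosen_idx = sorted(rng.choice(len(pool), size=min(k, len(pool)), replace=False))
    atoms = tuple(
        AtomRecord(pool[i], residue_id, Point3(*map(float, _uniform_ball(rng, cfg.radius))))
        for i in chosen_idx
    )
    return ResidueRecord(residue_id, rname, atoms)


def _generate_site(
    site_id: str, label: str, carrier: bool, rule: PlantedRule,
    clause: Clause, rng: np.random.Generator, cfg: GeneratorConfig,
) -> SiteExample:
    for _ in range(200):
        residues: list[ResidueRecord] = []
        next_seq = 1
        if carrier:
            for req in rule.residues:
                residues.append(_carrier_residue(req, rng, cfg, f"a{next_seq}"))
                next_seq += 1
        n_decoys = int(rng.integers(cfg.decoy_residues[0], cfg.decoy_residues[1] + 1))
        for _ in range(n_decoys):
            residues.append(_decoy_residue(rng, cfg, f"a{next_seq}"))
            next_seq += 1
        order = rng.permutation(len(residues))
        residues = [residues[i] for i in order]
        # residue ids must stay unique; relabel in the shuffled order
        relabeled = []
        for seq, res in enumerate(residues, start=1):
            rid = f"a{seq}"
            relabeled.append(
                ResidueRecord(
                    rid, res.residue_name,
                    tuple(AtomRecord(a.atom_name, rid, a.coords) for a in res.atoms),
                )
            )
        site = SiteExample(site_id, label, Point3(0.0, 0.0, 0.0), tuple(relabeled))
        is_covered = covers(clause, site, "smallest_domain").covered
        if is_covered == carrier:
            return site
        # carriers must be covered and non-carriers must not be; resample
    raise InfeasibleGeometry(f"could not realize carrier={carrier} for {site_id}")


def generate_dataset(
    rule: PlantedRule, cfg: GeneratorConfig = GeneratorConfig()
) -> tuple[list[SiteExample], pd.DataFrame]:
    """Generate a labelled dataset plus its carrier truth table.

    Positives carry the pattern with probability ``pattern_frequency_pos``,
    negatives with ``pattern_frequency_neg``.  Every carrier is verified
    covered by ``rule.to_clause()`` and every non-carrier verified uncovered,
    so the truth table is exact.  Byte-identical output for equal seeds.
    """
    clause = rule.to_clause()
    rng = np.random.default_rng(cfg.seed)
    sites: list[SiteExample] = []
    truth = []
    for label, n, freq in (
        ("positive", cfg.n_pos, cfg.pattern_frequency_pos),
        ("negative", cfg.n_neg, cfg.pattern_frequency_neg),
    ):
        for i in range(1, n + 1):
            site_id = f"p{'POS' if label == 'positive' else 'NEG'}{i:03d}"
            carrier = bool(rng.random() < freq)
            site = _generate_site(site_id, label, carrier, rule, clause, rng, cfg)
            sites.append(site)
            truth.append((site_id, label, carrier))
    table = pd.DataFrame(truth, columns=["site_id", "label", "carrier"])
    return sites, table


def write_dataset(
    sites: list[SiteExample], truth: pd.DataFrame, out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Emit one fact-dialect file per site plus a TSV manifest (and a seed
    sidecar when given).  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for site in sites:
        (out / f"{site.site_id}.pl").write_text(write_facts(site))
    manifest = out / "manifest.tsv"
    truth.assign(path=[f"{s.site_id}.pl" for s in sites]).to_csv(
        manifest, sep="\t", index=False
    )
    if seed is not None:
        (out / "seed.txt").write_text(f"{seed}\n")
    return manifest
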