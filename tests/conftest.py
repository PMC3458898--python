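import numpy as np
import pytest

from hexilp.bk import AtomRecord, Point3, ResidueRecord, SiteExample
from hexilp.fixtures import fixture_1bdg
from hexilp.synth import RESIDUE_ATOMS


@pytest.fixture
def site_1bdg() -> SiteExample:
    return fixture_1bdg()


def make_site(
    site_id: str,
    residues: list[tuple[str, str, list[tuple[str, tuple[float, float, float]]]]],
    label: str = "positive",
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SiteExample:
    """Hand-build a site from (residue_id, name, [(atom, xyz), ...]) triples."""
    recs = tuple(
        ResidueRecord(rid, name, tuple(AtomRecord(a, rid, Point3(*xyz)) for a, xyz in atoms))
        for rid, name, atoms in residues
    )
    return SiteExample(site_id, label, Point3(*center), recs)


def random_small_site(rng: np.random.Generator, site_id: str = "pRND", label: str = "positive") -> SiteExample:
    """A small random site (2-4 residues, 2-3 atoms each) inside the 10 Å ball."""
    names = sorted(RESIDUE_ATOMS)
    residues = []
    for i in range(int(rng.integers(2, 5))):
        name = names[int(rng.integers(len(names)))]
        pool = RESIDUE_ATOMS[name]
        k = int(rng.integers(2, 4))
        idx = sorted(rng.choice(len(pool), size=min(k, len(pool)), replace=False))
        atoms = []
        for j in idx:
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * 10.0 * rng.random() ** (1 / 3)
            atoms.append((pool[j], tuple(float(x) for x in v)))
        residues.append((f"a{i + 1}", name, atoms))
    return make_site(site_id, residues, label=label)
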