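"""Bundled reference data for the hexose binding-site benchmark.

* the 160-site benchmark manifest (80 hexose-binding positives: 33 galactose,
  35 glucose, 12 mannose; 80 negatives: 22 hexose-like-ligand, 27
  other-ligand, 31 non-binding surface pockets), with each site's
  binding-center convention (hexose pyranose-ring centroid for positives,
  ligand or cavity-serial centroid for negatives);
* the published background-knowledge excerpt for the glucose site of
  1BDG (glucokinase), used as a worked example throughout;
* the published 10-fold cross-validation accuracy columns for the benchmark
  (three recall-ordering schemes; top-down vs bottom-up ILP and an SVM in
  both representations), used by the statistics fixtures;
* the per-rule coverage id lists of the six published rules (documentation
  fixture; reproducing them needs the real structures).

Site ids follow the ``pPDBID`` convention with a ``_2`` suffix for a
protein's second binding site.
"""

from __future__ import annotations

from functools import lru_cache

import pandas as pd

from .bk import SiteExample, parse_facts

# --------------------------------------------------------------------------
# 1BDG background-knowledge excerpt (glucose bound to glucokinase)
# --------------------------------------------------------------------------

FACTS_1BDG = """\
center_coords(p1BDG, p(27.0,22.1,64.9)).
has_aminoacid(p1BDG, a64, phe).
has_aminoacid(p1BDG, a85, leu).
has_aminoacid(p1BDG, a86, gly).
has_aminoacid(p1BDG, a87, gly).
has_atom(p1BDG, a64, 'CD2', p(22.4,13.3,65.5)).
has_atom(p1BDG, a64, 'CE2', p(21.6,14.0,66.4)).
has_atom(p1BDG, a85, 'C', p(24.6,25.9,57.4)).
has_atom(p1BDG, a85, 'O', p(24.6,24.8,57.8)).
has_atom(p1BDG, a86, 'N', p(24.8,27.0,58.3)).
has_atom(p1BDG, a86, 'CA', p(24.9,26.8,59.7)).
"""


def fixture_1bdg() -> SiteExample:
    """The 1BDG excerpt as a parsed site (4 residues, 6 atoms)."""
    return parse_facts(FACTS_1BDG, label="positive")


# --------------------------------------------------------------------------
# Benchmark manifest
# --------------------------------------------------------------------------

_POSITIVES = {
    "glucose": [
        ("1BDG", "GLC-501"), ("1ISY", "GLC-1471"), ("1EX1", "GLC-617"),
        ("1J0Y", "GLC-1601"), ("1GJW", "GLC-701"), ("1JG9", "GLC-2000"),
        ("1GWW", "GLC-1371"), ("1K1W", "GLC-653"), ("1H5U", "GLC-998"),
        ("1KME", "GLC-501"), ("1HIZ", "GLC-1381"), ("1MMU", "GLC-1"),
        ("1HIZ", "GLC-1382"), ("1NF5", "GLC-125"), ("1HKC", "GLC-915"),
        ("1NSZ", "GLC-1400"), ("1HSJ", "GLC-671"), ("1PWB", "GLC-405"),
        ("1HSJ", "GLC-672"), ("1Q33", "GLC-400"), ("1I8A", "GLC-189"),
        ("1RYD", "GLC-601"), ("1ISY", "GLC-1461"), ("1S5M", "AGC-1001"),
        ("1SZ2", "BGC-1001"), ("1SZ2", "BGC-2001"), ("1U2S", "GLC-1"),
        ("1UA4", "GLC-1457"), ("1V2B", "AGC-1203"), ("1WOQ", "GLC-290"),
        ("1Z8D", "GLC-901"), ("2BQP", "GLC-337"), ("2BVW", "GLC-602"),
        ("2BVW", "GLC-603"), ("2F2E", "AGC-401"),
    ],
    "galactose": [
        ("1AXZ", "GLA-401"), ("1MUQ", "GAL-301"), ("1DIW", "GAL-1400"),
        ("1NS0", "GAL-1400"), ("1DJR", "GAL-1104"), ("1NS2", "GAL-1400"),
        ("1DZQ", "GAL-502"), ("1NS8", "GAL-1400"), ("1EUU", "GAL-2"),
        ("1NSM", "GAL-1400"), ("1ISZ", "GAL-461"), ("1NSU", "GAL-1400"),
        ("1ISZ", "GAL-471"), ("1NSX", "GAL-1400"), ("1JZ7", "GAL-2001"),
        ("1OKO", "GLB-901"), ("1KWK", "GAL-701"), ("1OQL", "GAL-265"),
        ("1L7K", "GAL-500"), ("1OQL", "GAL-267"), ("1LTI", "GAL-104"),
        ("1PIE", "GAL-1"), ("1R47", "GAL-1101"), ("1S5D", "GAL-704"),
        ("1S5E", "GAL-751"), ("1S5F", "GAL-104"), ("1SO0", "GAL-500"),
        ("1TLG", "GAL-1"), ("1UAS", "GAL-1501"), ("1UGW", "GAL-200"),
        ("1XC6", "GAL-9011"), ("1ZHJ", "GAL-1"), ("2GAL", "GAL-998"),
    ],
    "mannose": [
        ("1BQP", "MAN-402"), ("1KZB", "MAN-1501"), ("1KLF", "MAN-1500"),
        ("1KZC", "MAN-1001"), ("1KX1", "MAN-20"), ("1KZE", "MAN-1001"),
        ("1KZA", "MAN-1001"), ("1OP3", "MAN-503"), ("1OUR", "MAN-301"),
        ("1QMO", "MAN-302"), ("1U4J", "MAN-1008"), ("1U4J", "MAN-1009"),
    ],
}

# negatives: (pdb_id, cavity_center, ligand_or_None)
_HEXOSE_LIKE = [
    ("1A8U", "4320, 4323", "BEZ-1"), ("1AI7", "6074, 6077", "IPH-1"),
    ("1AWB", "4175, 4178", "IPD-2"), ("1DBN", "pyranose ring", "GAL-102"),
    ("1EOB", "3532, 3536", "DHB-999"), ("1F9G", "5792, 5785, 5786", "ASC-950"),
    ("1G0H", "4045, 4048", "IPD-292"), ("1JU4", "4356, 4359", "BEZ-1"),
    ("1LBX", "3941, 3944", "IPD-295"), ("1LBY", "3944, 3939, 3941", "F6P-295"),
    ("1LIU", "15441, 15436, 15438", "FBP-580"), ("1MOR", "pyranose ring", "G6P-609"),
    ("1NCW", "3406, 3409", "BEZ-601"), ("1P5D", "pyranose ring", "G1P-658"),
    ("1T10", "4366, 4361, 4363", "F6P-1001"), ("1U0F", "pyranose ring", "G6P-900"),
    ("1UKB", "2144, 2147", "BEZ-1300"), ("1X9I", "pyranose ring", "G6Q-600"),
    ("1Y9G", "4124, 4116, 4117", "FRU-801"), ("2B0C", "pyranose ring", "G1P-496"),
    ("2B32", "3941, 3944", "IPH-401"), ("4PBG", "pyranose ring", "BGP-469"),
]
_OTHER_LIGAND = [
    ("11AS", "5132", "ASN-1"), ("11GS", "1672, 1675", "MES-3"),
    ("1A0J", "6985", "BEN-246"), ("1A42", "2054, 2055", "BZO-555"),
    ("1A50", "4939, 4940", "FIP-270"), ("1A53", "2016, 2017", "IGP-300"),
    ("1AA1", "4472, 4474", "3PG-477"), ("1AJN", "6074, 6079", "AAN-1"),
    ("1AJS", "3276, 3281", "PLA-415"), ("1AL8", "2652", "FMN-360"),
    ("1B8A", "7224", "ATP-500"), ("1BO5", "7811", "GOL-601"),
    ("1BOB", "2566", "ACO-400"), ("1D09", "7246", "PAL-1311"),
    ("1EQY", "3831", "ATP-380"), ("1IOL", "2674, 2675", "EST-400"),
    ("1JTV", "2136, 2137", "TES-500"), ("1KF6", "16674, 16675", "OAA-702"),
    ("1RTK", "3787, 3784", "GBS-300"), ("1TJ4", "1947", "SUC-1"),
    ("1TVO", "2857", "FRZ-1001"), ("1UK6", "2142", "PPI-1300"),
    ("1W8N", "4573, 4585", "DAN-1649"), ("1ZYU", "1284, 1286", "SKM-401"),
    ("2D7S", "3787", "GLU-1008"), ("2GAM", "11955", "NGA-502"),
    ("3PCB", "3421, 3424", "3HB-550"),
]
_NON_BINDING = [
    ("1A04", "1424, 2671"), ("1A0I", "1689, 799"), ("1A22", "2927"),
    ("1AA7", "579"), ("1AF7", "631, 1492"), ("1AM2", "1277"),
    ("1ARO", "154, 1663"), ("1ATG", "1751"), ("1C3G", "630, 888"),
    ("1C3P", "1089, 1576"), ("1DXJ", "867, 1498"), ("1EVT", "2149, 2229"),
    ("1FI2", "1493"), ("1KLM", "4373, 4113"), ("1KWP", "1212"),
    ("1QZ7", "3592, 2509"), ("1YQZ", "4458, 4269"), ("1YVB", "1546, 1814"),
    ("1ZT9", "1056, 1188"), ("2A1K", "2758, 3345"), ("2AUP", "2246"),
    ("2BG9", "14076, 8076"), ("2C9Q", "777"), ("2CL3", "123, 948"),
    ("2DN2", "749, 1006"), ("2F1K", "316, 642"), ("2G50", "26265, 31672"),
    ("2G69", "248, 378"), ("2GRK", "369, 380"), ("2GSE", "337, 10618"),
    ("2GSH", "6260"),
]


@lru_cache(maxsize=1)
def fixture_manifest() -> pd.DataFrame:
    """The 160-site benchmark manifest.

    Columns: ``site_id`` (pPDBID, ``_2`` for second sites), ``pdb_id``,
    ``label``, ``category`` (galactose | glucose | mannose | hexose_like |
    other_ligand | non_binding), ``ligand`` (``RES-SEQ`` or ``None``) and
    ``center_source`` ("pyranose ring" or the cavity-center atom serials).
    """
    rows = []
    seen: dict[str, int] = {}

    def site_id(pdb: str) -> str:
        seen[pdb] = seen.get(pdb, 0) + 1
        return f"p{pdb}" if seen[pdb] == 1 else f"p{pdb}_{seen[pdb]}"

    for category, entries in _POSITIVES.items():
        for pdb, ligand in entries:
            rows.append((site_id(pdb), pdb, "positive", category, ligand, "pyranose ring"))
    for pdb, center, ligand in _HEXOSE_LIKE:
        rows.append((site_id(pdb), pdb, "negative", "hexose_like", ligand, center))
    for pdb, center, ligand in _OTHER_LIGAND:
        rows.append((site_id(pdb), pdb, "negative", "other_ligand", ligand, center))
    for pdb, center in _NON_BINDING:
        rows.append((site_id(pdb), pdb, "negative", "non_binding", None, center))
    return pd.DataFrame(
        rows, columns=["site_id", "pdb_id", "label", "category", "ligand", "center_source"]
    )


# --------------------------------------------------------------------------
# Published 10-fold cross-validation accuracy columns (percent, fold 1..10)
# --------------------------------------------------------------------------

#: atom-only bottom-up ILP under the three recall-ordering schemes
RECALL_ORDERING_ACCURACIES: dict[str, tuple[float, ...]] = {
    "primary_sequence": (43.8, 62.5, 81.3, 56.3, 68.8, 37.5, 56.3, 68.8, 62.5, 56.3),
    "randomized": (56.3, 93.8, 87.5, 50.0, 68.8, 56.3, 62.5, 68.8, 81.3, 62.5),
    "domain_dependent": (87.5, 78.5, 87.5, 43.8, 81.3, 81.3, 75.0, 81.3, 62.5, 68.8),
}

#: learner comparison; suffix 1 = atom-only, 2 = amino-acid representation
LEARNER_ACCURACIES: dict[str, tuple[float, ...]] = {
    "aleph_1": (50.0, 68.8, 62.5, 50.0, 75.0, 68.8, 75.0, 93.8, 68.8, 56.3),
    "progolem_1": (75.0, 81.3, 68.8, 56.3, 81.3, 87.5, 81.3, 81.3, 75.0, 56.3),
    "aleph_2": (56.3, 68.8, 68.8, 68.8, 56.3, 81.3, 75.0, 75.0, 75.0, 87.5),
    "progolem_2": (75.0, 81.3, 93.8, 75.0, 81.3, 87.5, 81.3, 93.8, 81.3, 81.3),
    "svm": (81.3, 87.5, 87.5, 75.0, 75.0, 87.5, 93.8, 87.5, 75.0, 62.5),
}


def reference_cv_accuracies() -> pd.DataFrame:
    """All published fold-accuracy columns as one DataFrame (fold 1..10)."""
    cols = {**RECALL_ORDERING_ACCURACIES, **LEARNER_ACCURACIES}
    return pd.DataFrame(cols, index=pd.RangeIndex(1, 11, name="fold"))


# --------------------------------------------------------------------------
# Per-rule coverage of the six published rules (documentation fixture)
# --------------------------------------------------------------------------

RULE_COVERAGE: dict[int, dict[str, tuple[str, ...]]] = {
    1: {
        "positives": (
            "1BDG", "1BQP", "1DZQ", "1HKC", "1HSJ_2", "1ISY", "1ISZ", "1ISZ_2",
            "1J0Y", "1JG9", "1JZ7", "1KLF", "1MMU", "1MUQ", "1NSU", "1NSX",
            "1NSZ", "1OKO", "1OP3", "1OQL", "1OQL_2", "1OUR", "1PIE", "1Q33",
            "1S5M", "1SZ2", "1SZ2_2", "1TLG", "1U2S", "1U4J", "1U4J_2", "1UA4",
            "1UAS", "1WOQ", "2BQP", "2BVW", "2BVW_2",
        ),
        "negatives": ("1AWB", "1W8N", "2B0C", "2B32"),
    },
    2: {
        "positives": (
            "1DJR", "1EUU", "1HIZ", "1HSJ", "1HSJ_2", "1KWK", "1KX1", "1KZA",
            "1KZB", "1KZC", "1KZE", "1L7K", "1MUQ", "1NS8", "1NSM", "1NSU",
            "1NSX", "1NSZ", "1PWB", "1S5D", "1S5E", "1SO0", "1TLG", "1XC6",
        ),
        "negatives": (),
    },
    3: {
        "positives": (
            "1DIW", "1DJR", "1EUU", "1HIZ", "1ISZ", "1KX1", "1KZA", "1KZB",
            "1KZC", "1KZE", "1L7K", "1LTI", "1NS0", "1NS2", "1NS8", "1NSM",
            "1NSU", "1NSX", "1NSZ", "1OKO", "1OQL_2", "1OUR", "1PWB", "1QMO",
            "1S5D", "1S5E", "1S5F", "1SO0", "1U2S", "2GAL",
        ),
        "negatives": (),
    },
    4: {
        "positives": ("1HSJ", "1HSJ_2", "1KME", "1RYD", "1S5M", "1TLG", "1UGW"),
        "negatives": (),
    },
    5: {
        "positives": ("1HIZ_2", "1KWK", "1QMO", "1U4J", "1U4J_2", "1XC6"),
        "negatives": (),
    },
    6: {
        "positives": (
            "1ISY", "1ISY_2", "1ISZ", "1ISZ_2", "1NF5", "1OKO", "1OQL", "1PIE",
            "1R47", "1SO0", "1SZ2", "1SZ2_2", "1TLG", "1U4J", "1U4J_2", "1UAS",
            "2BVW", "2BVW_2",
        ),
        "negatives": (),
    },
}
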