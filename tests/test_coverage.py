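"""θ-subsumption coverage: strategies, oracle agreement, explanations."""

import numpy as np
import pytest

from hexilp.bk import order_site
from hexilp.coverage import (
    SiteFacts,
    brute_force_covers,
    coverage,
    covers,
    instantiate,
    literal_matches,
)
from hexilp.language import Clause, Literal, Var, saturate
from hexilp.learner import armg
from hexilp.synth import (
    GeneratorConfig,
    asn_glu_rule,
    asn_pair_asp_rule,
    generate_dataset,
)

from conftest import make_site, random_small_site

A, B, C = Var("A"), Var("B"), Var("C")


class TestLiteralMatches:
    def test_distance_within_tolerance(self):
        site = make_site("pX", [("a1", "asp", [("CG", (5.04, 0, 0))])])
        facts = SiteFacts(site)
        lit = Literal("atom_to_center_dist", (B, "CG", 5.4, 0.5))
        assert literal_matches(lit, facts, {B: "a1"}) == [{B: "a1"}]

    def test_distance_outside_tolerance(self):
        site = make_site("pX", [("a1", "asp", [("CG", (6.0, 0, 0))])])
        lit = Literal("atom_to_center_dist", (B, "CG", 5.4, 0.5))
        assert literal_matches(lit, SiteFacts(site), {B: "a1"}) == []

    def test_no_matching_residue_name(self, site_1bdg):
        lit = Literal("has_aminoacid", (A, B, "asp"))
        assert literal_matches(lit, SiteFacts(site_1bdg), {A: "p1BDG"}) == []

    def test_unbound_input_is_contract_violation(self):
        site = make_site("pX", [("a1", "asp", [("CG", (5.0, 0, 0))])])
        lit = Literal("atom_to_center_dist", (B, "CG", 5.4, 0.5))
        with pytest.raises(ValueError, match="unbound input"):
            literal_matches(lit, SiteFacts(site), {})


class TestCovers:
    def test_head_only_covers_everything(self, site_1bdg):
        head_only = Clause((), "amino_acid")
        for strategy in ("sld", "smallest_domain"):
            assert covers(head_only, site_1bdg, strategy).covered
        assert brute_force_covers(head_only, site_1bdg)

    def test_planted_pattern_covered(self):
        rule = asn_pair_asp_rule()
        sites, truth = generate_dataset(rule, GeneratorConfig(n_pos=3, n_neg=3, seed=4))
        clause = rule.to_clause()
        for site, carrier in zip(sites, truth.carrier):
            assert covers(clause, site, "sld").covered == carrier
            assert covers(clause, site, "smallest_domain").covered == carrier

    def test_diff_aminoacid_requires_distinct_ids(self):
        clause = Clause(
            (
                Literal("has_aminoacid", (A, B, "asn")),
                Literal("has_aminoacid", (A, C, "asn")),
                Literal("diff_aminoacid", (B, C)),
            ),
            "amino_acid",
        )
        one_asn = make_site("pX", [("a1", "asn", [("CA", (1, 0, 0))])])
        two_asn = make_site(
            "pY", [("a1", "asn", [("CA", (1, 0, 0))]), ("a2", "asn", [("CA", (2, 0, 0))])]
        )
        assert not covers(clause, one_asn).covered
        assert covers(clause, two_asn).covered

    def test_unknown_strategy(self, site_1bdg):
        with pytest.raises(ValueError):
            covers(Clause((), "amino_acid"), site_1bdg, "breadth_first")


class TestStrategyEquivalence:
    @pytest.mark.parametrize("rep", ["amino_acid", "atom_only"])
    def test_agreement_on_random_pairs(self, rep):
        """sld, smallest_domain and brute force agree on random clause/site pairs."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            gen_site = order_site(random_small_site(rng, "pGEN"), "domain_dependent")
            red_site = order_site(random_small_site(rng, "pRED"), "domain_dependent")
            test_site = random_small_site(rng, "pTST")
            clause = armg(saturate(gen_site, rep, recall=2), red_site)
            sld = covers(clause, test_site, "sld").covered
            sdo = covers(clause, test_site, "smallest_domain").covered
            brute = brute_force_covers(clause, test_site)
            assert sld == sdo == brute
            checked += 1


class TestCoverageCounts:
    def test_head_only_counts_all(self):
        sites, _ = generate_dataset(asn_pair_asp_rule(), GeneratorConfig(n_pos=5, n_neg=5, seed=9))
        P, N, pids, nids = coverage(Clause((), "amino_acid"), sites)
        assert (P, N) == (5, 5)
        assert P + N == len(pids) + len(nids)
        assert pids == sorted(pids) and nids == sorted(nids)

    def test_planted_rule_matches_generator_truth(self):
        rule = asn_pair_asp_rule()
        sites, truth = generate_dataset(rule, GeneratorConfig(seed=11))
        P, N, pids, _ = coverage(rule.to_clause(), sites)
        carriers = set(truth.loc[truth.carrier, "site_id"])
        assert (P, N) == (20, 0)
        assert set(pids) == carriers

    def test_reparse_preserves_coverage(self):
        from hexilp.language import parse_prolog, render_prolog

        rule = asn_pair_asp_rule()
        sites, _ = generate_dataset(rule, GeneratorConfig(n_pos=6, n_neg=6, seed=2))
        clause = rule.to_clause()
        again = parse_prolog(render_prolog(clause))
        assert coverage(clause, sites)[:2] == coverage(again, sites)[:2]


class TestMonotonicityProperties:
    def _planted(self, seed=13, n=8):
        rule = asn_pair_asp_rule()
        sites, _ = generate_dataset(rule, GeneratorConfig(n_pos=n, n_neg=n, seed=seed))
        return rule.to_clause(), sites

    def test_appending_literal_never_increases_coverage(self):
        clause, sites = self._planted()
        extended = Clause(
            clause.body + (Literal("atom_to_center_dist", (Var("D"), "OD1", 4.0, 0.5)),),
            "amino_acid",
        )
        for before, after in zip(coverage(clause, sites)[:2], coverage(extended, sites)[:2]):
            assert after <= before

    def test_removing_literal_never_decreases_coverage(self):
        clause, sites = self._planted()
        for drop in range(len(clause.body)):
            body = clause.body[:drop] + clause.body[drop + 1 :]
            from hexilp.language import is_valid

            pruned = Clause(body, "amino_acid")
            if not is_valid(pruned):
                continue
            for before, after in zip(coverage(clause, sites)[:2], coverage(pruned, sites)[:2]):
                assert after >= before

    def test_coverage_nondecreasing_in_tolerance(self):
        _, sites = self._planted()
        counts = []
        for t in (0.1, 0.5, 1.5):
            clause = asn_pair_asp_rule(tolerance=t).to_clause()
            counts.append(coverage(clause, sites)[0])
        assert counts == sorted(counts)


class TestInstantiate:
    def test_two_matching_residues_two_bindings(self):
        clause = Clause((Literal("has_aminoacid", (A, B, "asn")),), "amino_acid")
        site = make_site(
            "pX", [("a1", "asn", [("CA", (1, 0, 0))]), ("a2", "asn", [("CA", (2, 0, 0))])]
        )
        bindings = instantiate(clause, site)
        assert len(bindings) == 2
        assert len({tuple(sorted(b["binding"].items())) for b in bindings}) == 2

    def test_realized_distances_of_planted_pattern(self):
        rule = asn_glu_rule()
        sites, truth = generate_dataset(rule, GeneratorConfig(n_pos=3, n_neg=0, seed=6))
        clause = rule.to_clause()
        carrier = sites[int(truth.carrier.idxmax())]
        bindings = instantiate(clause, carrier)
        assert bindings
        center = {8.0: False, 6.9: False}
        for b in bindings:
            for d in b["distances"]:
                if d["predicate"] == "atom_to_center_dist":
                    assert abs(d["realized"] - d["stored"]) <= 0.5
                    for target in center:
                        if d["stored"] == target:
                            center[target] = True
        assert all(center.values())

    def test_not_covered_gives_empty(self, site_1bdg):
        clause = Clause((Literal("has_aminoacid", (A, B, "asp")),), "amino_acid")
        assert instantiate(clause, site_1bdg) == []
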