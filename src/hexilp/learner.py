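"""Specific-to-general rule learner.

The search starts from a bottom clause (the most specific clause entailing a
seed positive) and generalizes by *asymmetric relative minimal
generalization* (ARMG): to also cover another positive example, drop the
minimal set of body literals blocking it.  Candidates are scored by
compression

    compression = P − N − L

(positives covered − negatives covered − clause length), capped at ``noise_cap``
covered negatives, and the final theory is built globally: after all
candidates are generated, clauses are added greedily while they strictly
improve the union-coverage theory score.  A site is predicted positive if any
theory clause covers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bk import SiteExample, order_site
from .coverage import SiteFacts, covers, coverage, literal_matches
from .language import Clause, Literal, Var, is_valid, render_prolog, saturate

DEFAULT_NOISE_CAP = 5


def compression(P: int, N: int, L: int) -> int:
    """Clause score: positives covered − negatives covered − clause length."""
    if P < 0 or N < 0:
        raise ValueError("coverage counts must be non-negative")
    if L < 1:
        raise ValueError("clause length includes the head, so L >= 1")
    return P - N - L


@dataclass(frozen=True)
class ScoredClause:
    clause: Clause
    P: int
    N: int

    @property
    def L(self) -> int:
        return self.clause.length

    @property
    def compression(self) -> int:
        return compression(self.P, self.N, self.L)


@dataclass(frozen=True)
class LearnerConfig:
    """Search settings.  Defaults are the study settings: recall bound 7,
    at most 5 covered negatives per accepted clause, 0.5 Å distance
    tolerance, domain-dependent background ordering."""

    representation: str = "amino_acid"
    recall: int = 7
    noise_cap: int = DEFAULT_NOISE_CAP
    seeds_per_iteration: int = 5
    beam_width: int = 3
    ordering_scheme: str = "domain_dependent"
    tolerance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cap < 0:
            raise ValueError("noise_cap must be >= 0")
        for name in ("recall", "seeds_per_iteration", "beam_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Theory:
    """Accepted clauses plus any-of prediction semantics."""

    clauses: list[ScoredClause]
    config: LearnerConfig
    training_summary: dict = field(default_factory=dict)

    def predict(self, site: SiteExample | SiteFacts) -> str:
        return "positive" if any(
            covers(sc.clause, site, "smallest_domain").covered for sc in self.clauses
        ) else "negative"


def predict(theory: Theory, site: SiteExample | SiteFacts) -> str:
    return theory.predict(site)


# ---------------------------------------------------------------------------
# ARMG
# ---------------------------------------------------------------------------

def armg(clause: Clause, site: SiteExample | SiteFacts) -> Clause:
    """Generalize ``clause`` to also cover ``site`` by dropping the minimal
    set of body literals, scanning left to right.

    A literal is kept iff (a) its input variables are still introduced by the
    kept prefix, and (b) the kept prefix extended with the literal still
    admits a binding on ``site``.  Dropping a ``has_aminoacid`` therefore
    drops its dependent distance literals automatically (no dangling atoms).
    The result covers ``site`` and, being a connected subset of the original
    body, still covers every site the original clause covered.
    """
    facts = site if isinstance(site, SiteFacts) else SiteFacts(site)
    kept: list[Literal] = []
    # partial solutions of the kept prefix on `site`
    solutions: list[dict] = [{clause.head_var: facts.site.site_id}]
    introduced: set[Var] = {clause.head_var}
    from .language import _MODE_INDEX

    modes = _MODE_INDEX[clause.representation]
    for lit in clause.body:
        mode = modes[lit.predicate]
        inputs_ok = all(
            (not isinstance(a, Var)) or a in introduced
            for a, (role, _) in zip(lit.args, mode.roles)
            if role == "in"
        )
        if not inputs_ok:
            continue
        new_solutions: list[dict] = []
        for sol in solutions:
            new_solutions.extend(literal_matches(lit, facts, sol))
        if not new_solutions:
            continue
        kept.append(lit)
        # cap the frontier: any single surviving solution witnesses coverage
        solutions = new_solutions[:256]
        for a, (role, _) in zip(lit.args, mode.roles):
            if role == "out" and isinstance(a, Var):
                introduced.add(a)
    return replace(clause, body=tuple(kept))


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def _score(clause: Clause, facts_list: Sequence[SiteFacts]) -> ScoredClause:
    P, N, _, _ = coverage(clause, facts_list)
    return ScoredClause(clause, P, N)


def learn_candidates(
    dataset: Sequence[SiteExample], cfg: LearnerConfig = LearnerConfig()
) -> list[ScoredClause]:
    """Generate scored candidate clauses by saturation + iterated ARMG.

    For each sampled seed positive: saturate it into a bottom clause, then
    repeatedly generalize the current beam against sampled not-yet-covered
    positives, keeping the ``beam_width`` highest-compression clauses, until
    no extension strictly improves compression.  Survivors with
    ``N <= noise_cap`` are collected.  Deterministic given ``cfg.seed``.
    """
    ordered = [order_site(s, cfg.ordering_scheme, cfg.seed) for s in dataset]
    facts_list = [SiteFacts(s) for s in ordered]
    positives = [f for f in facts_list if f.site.label == "positive"]
    if not positives:
        raise ValueError("dataset has no positive examples")
    rng = np.random.default_rng(cfg.seed)

    n_seeds = min(cfg.seeds_per_iteration, len(positives))
    seed_idx = rng.choice(len(positives), size=n_seeds, replace=False)
    out: dict[str, ScoredClause] = {}

    for si in seed_idx:
        seed_facts = positives[si]
        bottom = saturate(seed_facts.site, cfg.representation, cfg.recall, cfg.tolerance)
        beam = [_score(bottom, facts_list)]
        best = beam[0].compression
        while True:
            uncovered = [
                p for p in positives
                if not any(covers(sc.clause, p, "smallest_domain").covered for sc in beam)
            ]
            if not uncovered:
                break
            k = min(cfg.seeds_per_iteration, len(uncovered))
            pick = rng.choice(len(uncovered), size=k, replace=False)
            extensions: dict[str, ScoredClause] = {}
            for sc in beam:
                for pi in pick:
                    g = armg(sc.clause, uncovered[pi])
                    key = render_prolog(g)
                    if key not in extensions and is_valid(g):
                        extensions[key] = _score(g, facts_list)
            pool = list(extensions.values()) + beam
            pool.sort(key=lambda sc: (-sc.compression, -sc.P, sc.L, render_prolog(sc.clause)))
            beam = pool[: cfg.beam_width]
            if beam[0].compression <= best:
                break
            best = beam[0].compression
        for sc in beam:
            if sc.N <= cfg.noise_cap:
                out.setdefault(render_prolog(sc.clause), sc)
    return sorted(out.values(), key=lambda sc: (-sc.compression, -sc.P, sc.L, render_prolog(sc.clause)))


# ---------------------------------------------------------------------------
# Global theory construction
# ---------------------------------------------------------------------------

def theory_compression(
    selected: Sequence[ScoredClause], facts_list: Sequence[SiteFacts]
) -> int:
    """Union-coverage theory score: |pos covered| − |neg covered| − Σ lengths."""
    pos: set[str] = set()
    neg: set[str] = set()
    total_len = 0
    for sc in selected:
        _, _, p_ids, n_ids = coverage(sc.clause, facts_list)
        pos.update(p_ids)
        neg.update(n_ids)
        total_len += sc.L
    return len(pos) - len(neg) - total_len


def build_global_theory(
    candidates: Sequence[ScoredClause],
    dataset: Sequence[SiteExample],
    cfg: LearnerConfig = LearnerConfig(),
) -> Theory:
    """Greedy global construction: repeatedly add the candidate that most
    improves the union-coverage theory score; stop when nothing strictly
    improves.  Ties break toward higher P, shorter clause, then clause text.
    """
    ordered = [order_site(s, cfg.ordering_scheme, cfg.seed) for s in dataset]
    facts_list = [SiteFacts(s) for s in ordered]
    # precompute per-candidate covered-id sets
    cov: list[tuple[ScoredClause, frozenset[str], frozenset[str]]] = []
    seen_text: set[str] = set()
    for sc in candidates:
        text = render_prolog(sc.clause)
        if text in seen_text:
            continue
        seen_text.add(text)
        _, _, p_ids, n_ids = coverage(sc.clause, facts_list)
        cov.append((sc, frozenset(p_ids), frozenset(n_ids)))

    selected: list[tuple[ScoredClause, frozenset[str], frozenset[str]]] = []
    pos_cov: set[str] = set()
    neg_cov: set[str] = set()
    total_len = 0
    score = 0  # empty theory

    while True:
        best = None
        for sc, p_ids, n_ids in cov:
            if any(render_prolog(sc.clause) == render_prolog(s.clause) for s, _, _ in selected):
                continue
            new_score = (
                len(pos_cov | p_ids) - len(neg_cov | n_ids) - (total_len + sc.L)
            )
            key = (new_score, sc.P, -sc.L, render_prolog(sc.clause))
            if new_score > score and (
                best is None
                or key[:3] > best[0][:3]
                or (key[:3] == best[0][:3] and key[3] < best[0][3])
            ):
                best = (key, sc, p_ids, n_ids)
        if best is None:
            break
        _, sc, p_ids, n_ids = best
        selected.append((sc, p_ids, n_ids))
        pos_cov |= p_ids
        neg_cov |= n_ids
        total_len += sc.L
        score = len(pos_cov) - len(neg_cov) - total_len

    theory = Theory([sc for sc, _, _ in selected], cfg)
    n_pos = sum(1 for f in facts_list if f.site.label == "positive")
    n_neg = len(facts_list) - n_pos
    correct = sum(
        1 for f in facts_list
        if theory.predict(f) == f.site.label
    )
    theory.training_summary = {
        "n_pos": n_pos,
        "n_neg": n_neg,
        "positives_covered": len(pos_cov),
        "negatives_covered": len(neg_cov),
        "theory_compression": score,
        "training_accuracy": 100.0 * correct / len(facts_list) if facts_list else float("nan"),
    }
    return theory


def learn(dataset: Sequence[SiteExample], cfg: LearnerConfig = LearnerConfig()) -> Theory:
    """saturate → ARMG search → global theory construction, in one call."""
    return build_global_theory(learn_candidates(dataset, cfg), dataset, cfg)
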