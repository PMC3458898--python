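"""Cross-validation and the statistical comparisons between learners.

The benchmark protocol is a fixed-assignment 10-fold cross-validation over
160 sites (8 positives + 8 negatives per fold): train on 9 folds, predict the
held-out fold, and compare methods fold-by-fold with a two-tailed paired
t-test.  Fold accuracies are percentages; the summary reports the arithmetic
mean and the sample (n−1) standard deviation at one decimal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bk import SiteExample
from .learner import LearnerConfig, Theory, learn


@dataclass(frozen=True)
class FoldSpec:
    """Assignment of every site id to a fold index (1-based)."""

    assignments: Mapping[str, int]

    @property
    def n_folds(self) -> int:
        return max(self.assignments.values()) if self.assignments else 0

    def fold_of(self, site_id: str) -> int:
        return self.assignments[site_id]

    @classmethod
    def round_robin(cls, dataset: Sequence[SiteExample], k: int = 10) -> "FoldSpec":
        """Deterministic balanced assignment: positives and negatives are
        dealt into folds in site order, independently, so each fold gets an
        equal share of each label."""
        assignments: dict[str, int] = {}
        counters = {"positive": 0, "negative": 0}
        for site in dataset:
            i = counters[site.label]
            assignments[site.site_id] = (i % k) + 1
            counters[site.label] += 1
        return cls(assignments)

    def check_balance(self, dataset: Sequence[SiteExample]) -> None:
        per_fold: Counter = Counter()
        for site in dataset:
            per_fold[(self.fold_of(site.site_id), site.label)] += 1
        sizes = {
            f: (per_fold.get((f, "positive"), 0), per_fold.get((f, "negative"), 0))
            for f in range(1, self.n_folds + 1)
        }
        if len(set(sizes.values())) > 1:
            warnings.warn(f"unbalanced folds: {sizes}")


@dataclass
class CVResult:
    fold_accuracies: list[float]  # percent, fold order
    theories: list[Theory]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def summarize(accuracies: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n−1) standard deviation, each rounded to one decimal."""
    if len(accuracies) < 2:
        raise ValueError("need at least two folds for a standard deviation")
    a = np.asarray(accuracies, dtype=float)
    return round(float(a.mean()), 1), round(float(a.std(ddof=1)), 1)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed paired Student t-test on per-fold accuracies.

    Identical columns (zero-mean, zero-variance differences) return
    ``t=0, p=1`` by convention.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least two folds")
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    df = len(diff) - 1
    if np.allclose(diff, 0.0):
        return TTestResult(0.0, df, 1.0)
    res = stats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def run_cv(
    dataset: Sequence[SiteExample],
    folds: FoldSpec,
    cfg: LearnerConfig = LearnerConfig(),
) -> CVResult:
    """Train on k−1 folds, test on the held-out fold, for every fold.

    Accuracy per fold is ``100 × correct / |fold|``.  Deterministic given
    ``cfg.seed`` (the learner's RNG is reseeded per fold from it).
    """
    missing = [s.site_id for s in dataset if s.site_id not in folds.assignments]
    if missing:
        raise ValueError(f"fold spec does not cover sites: {missing[:5]}")
    folds.check_balance(dataset)
    accuracies: list[float] = []
    theories: list[Theory] = []
    from dataclasses import replace as _replace

    for f in range(1, folds.n_folds + 1):
        train = [s for s in dataset if folds.fold_of(s.site_id) != f]
        test = [s for s in dataset if folds.fold_of(s.site_id) == f]
        if not test:
            continue
        fold_cfg = _replace(cfg, seed=(cfg.seed * 1000 + f) & 0x7FFFFFFF)
        theory = learn(train, fold_cfg)
        correct = sum(1 for s in test if theory.predict(s) == s.label)
        accuracies.append(100.0 * correct / len(test))
        theories.append(theory)
    return CVResult(accuracies, theories)
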