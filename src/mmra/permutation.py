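"""Genome-wide significance by max-statistic permutation.

Phenotypes are shuffled against the fixed genotype and pedigree data;
each permuted dataset is rescanned (variance components held at their
observed-data estimates) and only the largest Wald statistic is kept.
The (1 - alpha) quantile of those maxima is the genome-wide threshold,
which controls the family-wise error rate at alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .scan import ScanEngine, ScanResult

__all__ = ["PermutationNull", "permute_phenotypes", "max_statistic_null",
           "empirical_threshold", "declare_significant"]


def permute_phenotypes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly permute phenotype values among the phenotyped individuals."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty phenotype vector")
    return y[rng.permutation(y.size)]


@dataclass(frozen=True)
class PermutationNull:
    """Per-permutation maxima of the Wald statistic under the shuffled null."""

    max_wald: np.ndarray
    seed: int

    @property
    def n_perm(self) -> int:
        return len(self.max_wald)

    def empirical_pvalue(self, observed_max: float) -> float:
        """(1 + #{maxima >= observed}) / (n_perm + 1); never below 1/(n_perm+1)."""
        return (1.0 + np.sum(self.max_wald >= observed_max)) / (self.n_perm + 1.0)


def _perm_rng(seed: int, index: int) -> np.random.Generator:
    # stream depends only on (seed, index) so results are worker-count invariant
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


def _max_for_indices(engine: ScanEngine, y: np.ndarray, seed: int,
                     indices: range) -> np.ndarray:
    out = np.empty(len(indices))
    for k, i in enumerate(indices):
        y_perm = permute_phenotypes(y, _perm_rng(seed, i))
        out[k] = engine.max_wald(engine.rotate(y_perm))
    return out


def max_statistic_null(engine: ScanEngine, y: np.ndarray, n_perm: int,
                       seed: int, workers: int = 1) -> PermutationNull:
    """Largest Wald statistic from each of `n_perm` permuted rescans.

    The permutation stream for index i depends only on (seed, i), so the
    result is bit-identical for any `workers` count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    if workers <= 1:
        maxima = _max_for_indices(engine, y, seed, range(n_perm))
    else:
        bounds = np.linspace(0, n_perm, workers + 1).astype(int)
        chunks = [range(bounds[j], bounds[j + 1]) for j in range(workers)
                  if bounds[j] < bounds[j + 1]]
        parts = Parallel(n_jobs=workers)(
            delayed(_max_for_indices)(engine, y, seed, c) for c in chunks)
        maxima = np.concatenate(parts)
    return PermutationNull(max_wald=maxima, seed=seed)


def empirical_threshold(null: PermutationNull, alpha: float = 0.05) -> float:
    """The ceil((1 - alpha) * n_perm)-th smallest max-Wald value.

    A SNP is declared significant when its observed Wald statistic
    strictly exceeds this threshold.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = null.n_perm
    if n * alpha < 1.0:
        raise ValueError(
            f"n_perm = {n} is too small to estimate the {alpha} tail "
            f"(need n_perm * alpha >= 1)")
    k = math.ceil((1.0 - alpha) * n)
    return float(np.sort(null.max_wald)[k - 1])


def declare_significant(result: ScanResult, threshold: float
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """SNPs whose Wald statistic strictly exceeds the threshold, plus a
    per-chromosome tally."""
    rec = result.records
    sig = rec[rec["tested"] & (rec["wald"] > threshold)].copy()
    tally = sig.groupby("chromosome").size()
    tally.name = "n_significant"
    return sig, tally
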