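"""Permutation test for overlap between a candidate-gene list and an
independent gene set (e.g. differentially expressed genes from a separate
study), under the null that every gene in the shared universe had an equal
chance of entering the candidate list.

Each permutation draws `n` genes uniformly without replacement from the
universe of `N` and counts how many fall in the special set of `K`; the
add-one P-value is the fraction of draws whose overlap reaches the
observed `x`.  The closed-form counterpart is the hypergeometric upper
tail P(X >= x), available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = ["OverlapTest", "overlap_permutation", "hypergeom_tail", "overlap_from_lists"]


@dataclass
class OverlapTest:
    universe_size: int
    special_count: int
    candidate_count: int
    observed_overlap: int
    n_perm: int
    p_perm: float


def _validate(N: int, K: int, n: int, x: int) -> None:
    if not (0 < K <= N and 0 < n <= N):
        raise ValueError("need 0 < K <= N and 0 < n <= N")
    if not 0 <= x <= min(n, K):
        raise ValueError(f"observed overlap {x} exceeds min(n, K) = {min(n, K)}")


def overlap_permutation(
    N: int, K: int, n: int, x: int, n_perm: int = 10_000, seed: int = 0
) -> OverlapTest:
    """Permutation P for seeing >= x of n candidates inside the K-gene set."""
    _validate(N, K, n, x)
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(N, size=n, replace=False)
        if int((draw < K).sum()) >= x:
            hits += 1
    return OverlapTest(
        universe_size=N,
        special_count=K,
        candidate_count=n,
        observed_overlap=x,
        n_perm=n_perm,
        p_perm=(1 + hits) / (n_perm + 1),
    )


def hypergeom_tail(N: int, K: int, n: int, x: int) -> float:
    """Exact hypergeometric upper tail P(X >= x)."""
    _validate(N, K, n, x)
    return float(hypergeom.sf(x - 1, N, K, n))


def overlap_from_lists(
    universe: list[str], special: list[str], candidates: list[str],
    n_perm: int = 10_000, seed: int = 0,
) -> OverlapTest:
    """Run the permutation test from explicit gene lists.

    Genes outside the universe are dropped from the special and candidate
    lists before counting.
    """
    uni = set(universe)
    spec = uni & set(special)
    cand = uni & set(candidates)
    return overlap_permutation(
        N=len(uni), K=len(spec), n=len(cand), x=len(spec & cand),
        n_perm=n_perm, seed=seed,
    )
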