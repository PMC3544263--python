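"""Adjacent-locus clustering permutation test along a linkage map.

Genetic hitchhiking should make extreme per-locus statistics (theta, or
|lnRH|) cluster among neighbouring markers, whereas false positives from
single-locus outlier tests land randomly in the genome.  The test computes
the mean statistic of every pair of map-adjacent markers and compares it to
a null built by shuffling the per-locus values across all mapped positions
genome-wide (the map stays fixed, the values are exchanged), pooling the
permuted pair means into one null distribution whose 95th percentile is
the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MarkerMap

__all__ = ["PermutationNull", "build_adjacent_pairs", "permutation_scan", "cluster_report"]


@dataclass
class PermutationNull:
    """Pooled null distribution of adjacent-pair means."""

    statistic_kind: str
    n_perm: int
    null_pair_means: np.ndarray = field(repr=False)
    threshold_95: float
    degenerate: bool = False


def build_adjacent_pairs(marker_map: MarkerMap, loci: list[str]) -> pd.DataFrame:
    """Consecutive locus pairs within each linkage group, female-map order.

    Only loci in `loci` (mapped, with a statistic value) are paired; ties in
    cM keep map input order; linkage groups with a single locus contribute
    no pair.
    """
    ordered = marker_map.ordered_loci(loci)
    rows = []
    for lg, sub in ordered.groupby("linkage_group", sort=False):
        locs = sub["locus"].tolist()
        pos = sub["position_female_cM"].tolist()
        for i in range(len(locs) - 1):
            rows.append(
                {
                    "locus_a": locs[i],
                    "locus_b": locs[i + 1],
                    "linkage_group": lg,
                    "pos_a_cM": pos[i],
                    "pos_b_cM": pos[i + 1],
                    "distance_cM": pos[i + 1] - pos[i],
                }
            )
    if not rows:
        raise ValueError("no linkage group holds >= 2 of the supplied loci")
    return pd.DataFrame(rows)


def permutation_scan(
    pairs: pd.DataFrame,
    values: pd.Series,
    n_perm: int = 5000,
    seed: int = 0,
    statistic_kind: str = "statistic",
) -> tuple[PermutationNull, pd.DataFrame]:
    """Permutation test of adjacent-pair means against a genome-wide null.

    `values` maps locus label -> per-locus statistic (theta or |lnRH|);
    every paired locus must have a finite value.  Each of the `n_perm`
    permutations shuffles the values over all locus positions, recomputes
    all pair means, and pools them; per-pair
    ``p_perm = (1 + #{null >= observed}) / (len(null) + 1)`` and
    ``significant`` flags pairs whose observed mean exceeds the pooled 95th
    percentile.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    loci = pd.unique(pd.concat([pairs["locus_a"], pairs["locus_b"]]))
    missing = [l for l in loci if l not in values.index or not np.isfinite(values[l])]
    if missing:
        raise ValueError(f"no statistic value for paired loci: {missing[:5]}")
    # permute over every locus that carries a value (the full mapped panel),
    # not only the paired ones, so singleton-LG loci still feed the null
    all_loci = values.index[np.isfinite(values.values)]
    vals = values[all_loci].to_numpy(dtype=float)
    pos = {l: i for i, l in enumerate(all_loci)}
    ia = pairs["locus_a"].map(pos).to_numpy()
    ib = pairs["locus_b"].map(pos).to_numpy()

    observed = (vals[ia] + vals[ib]) / 2.0
    degenerate = np.ptp(vals) == 0

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(ia)))
    work = vals.copy()
    for t in range(n_perm):
        rng.shuffle(work)
        null[t] = (work[ia] + work[ib]) / 2.0
    null = null.ravel()
    null.sort()
    threshold = float(np.quantile(null, 0.95))

    # #{null >= obs} via the sorted null; small tolerance so floating-point
    # noise in the pair-mean sums cannot split exact ties
    ge = null.size - np.searchsorted(null, observed - 1e-9, side="left")
    p_perm = (1 + ge) / (null.size + 1)

    out = pairs.copy()
    out["pair_mean"] = observed
    out["p_perm"] = p_perm
    out["significant"] = (observed > threshold) & ~degenerate
    return (
        PermutationNull(
            statistic_kind=statistic_kind,
            n_perm=n_perm,
            null_pair_means=null,
            threshold_95=threshold,
            degenerate=bool(degenerate),
        ),
        out,
    )


def _pair_note(va: float, vb: float, hi: float, med: float) -> str:
    both_hi = va >= hi and vb >= hi
    single = (va >= hi and vb <= med) or (vb >= hi and va <= med)
    if both_hi:
        return "both elevated"
    if single:
        return "single-marker driven"
    return ""


def cluster_report(
    fst_scan: pd.DataFrame,
    lnrh_scan: pd.DataFrame,
    fst_values: pd.Series,
    lnrh_values: pd.Series,
) -> pd.DataFrame:
    """Merge the theta and |lnRH| clustering scans into one pair table.

    Adds, per statistic, a note on whether a significant pair mean is
    carried by both markers (both in the top 2.5% of single-locus values)
    or driven by a single marker (one above the 97.5% empirical quantile,
    the other below the median).
    """
    key = ["locus_a", "locus_b", "linkage_group", "pos_a_cM", "pos_b_cM", "distance_cM"]
    merged = fst_scan[key + ["pair_mean", "p_perm", "significant"]].merge(
        lnrh_scan[key + ["pair_mean", "p_perm", "significant"]],
        on=key,
        suffixes=("_fst", "_lnrh"),
        validate="one_to_one",
    )
    for tag, values in (("fst", fst_values), ("lnrh", lnrh_values)):
        finite = values[np.isfinite(values.values)]
        hi = float(finite.quantile(0.975))
        med = float(finite.median())
        merged[f"note_{tag}"] = [
            _pair_note(values.get(a, np.nan), values.get(b, np.nan), hi, med)
            for a, b in zip(merged["locus_a"], merged["locus_b"])
        ]
    return merged
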