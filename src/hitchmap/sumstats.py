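"""Diversity indices, Hardy-Weinberg exact tests, and Weir-Cockerham F_ST.

Gene diversity is Nei's unbiased estimator H = n/(n-1) (1 - sum p_i^2) with
n counted in gene copies (the FSTAT convention).  Differentiation between a
wild/reared pair is Weir & Cockerham's theta, computed from the variance
components a (between populations), b (among individuals within
populations) and c (within individuals); the multilocus estimate is the
ratio of summed components, not the mean of per-locus ratios.  Hardy-
Weinberg equilibrium is tested with the exact conditional test: full
enumeration of heterozygote counts for biallelic loci, a seeded Monte-Carlo
table-shuffling version for multiallelic loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, AlleleFreqs, GenotypeMatrix, allele_frequencies, classify_loci

__all__ = [
    "LocusFst",
    "gene_diversity",
    "allele_number",
    "hwe_exact_biallelic",
    "hwe_exact_test",
    "wc_components_pair",
    "wc_theta_locus",
    "multilocus_theta",
    "fst_permutation_test",
    "diversity_table",
]


def gene_diversity(freqs: AlleleFreqs | np.ndarray, n: int | None = None) -> float:
    """Nei's unbiased gene diversity H = n/(n-1) * (1 - sum p^2).

    `freqs` may be an :class:`AlleleFreqs` or a frequency vector with `n`
    gene copies given separately.  Raises for n < 2 (undefined).
    """
    if isinstance(freqs, AlleleFreqs):
        p, n = freqs.freqs, freqs.n
    else:
        p = np.asarray(freqs, dtype=float)
        if n is None:
            raise ValueError("n (gene copies) required with a raw frequency vector")
    if n < 2:
        raise ValueError("gene diversity undefined for fewer than 2 gene copies")
    h = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    return float(min(max(h, 0.0), 1.0))


def allele_number(freqs: AlleleFreqs) -> int:
    return int(freqs.n_alleles)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests
# ---------------------------------------------------------------------------


def hwe_exact_biallelic(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional HWE P-value for a biallelic locus.

    Enumerates every heterozygote count compatible with the observed allele
    counts (Levene/Haldane conditional distribution) and sums the
    probabilities of all outcomes no more probable than the observed one.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n1 = 2 * n_hom1 + n_het  # copies of allele 1
    n2 = 2 * n_hom2 + n_het
    if n1 == 0 or n2 == 0:
        return 1.0  # monomorphic: single possible table
    rare = min(n1, n2)
    # conditional log-probability of h heterozygotes given allele counts
    def logp(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_c + 1)
            + h * math.log(2.0)
            + math.lgamma(n1 + 1)
            + math.lgamma(n2 + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = [h for h in range(rare % 2, rare + 1, 2)]
    lps = np.array([logp(h) for h in hs])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = hs.index(n_het)
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def _genotype_counts(col: np.ndarray) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for a, b in col:
        if a == MISSING or b == MISSING:
            continue
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def hwe_exact_test(
    sample: GenotypeMatrix,
    locus: str,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> tuple[float, bool]:
    """Exact HWE test at one locus; returns ``(p, testable)``.

    Biallelic loci are tested by full enumeration; loci with more than two
    alleles by a seeded Monte-Carlo shuffle of the gene-copy pool (add-one
    P-value).  A monomorphic locus returns ``(1.0, False)``.
    """
    j = sample.locus_index(locus)
    col = sample.calls[:, j, :]
    col = col[(col != MISSING).all(axis=1)]
    if col.shape[0] == 0:
        raise ValueError(f"all calls missing at {locus!r}")
    alleles = np.unique(col)
    if len(alleles) < 2:
        return 1.0, False
    if len(alleles) == 2:
        het = int((col[:, 0] != col[:, 1]).sum())
        hom1 = int(((col[:, 0] == alleles[0]) & (col[:, 1] == alleles[0])).sum())
        hom2 = int(((col[:, 0] == alleles[1]) & (col[:, 1] == alleles[1])).sum())
        return hwe_exact_biallelic(het, hom1, hom2), True

    # multiallelic: Monte-Carlo permutation of gene copies among individuals.
    # Under the null every pairing of the 2n copies is equally likely; the
    # orderable statistic is the conditional table probability, of which only
    # the terms  h*log2 - sum log(genotype count!)  vary across shuffles.
    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    # relabel alleles to 0..k-1 so genotype codes stay small
    ranks = np.searchsorted(alleles, col)
    k = len(alleles)

    def batch_stat(pairs: np.ndarray) -> np.ndarray:
        # pairs: (B, n, 2) allele ranks
        lo = pairs.min(axis=2)
        hi = pairs.max(axis=2)
        het = (lo != hi).sum(axis=1)
        codes = lo * k + hi  # (B, n), values < k*k
        B = codes.shape[0]
        flat = (codes + (np.arange(B)[:, None] * k * k)).ravel()
        cnt = np.bincount(flat, minlength=B * k * k).reshape(B, k * k)
        return het * math.log(2.0) - gammaln(cnt + 1).sum(axis=1)

    obs = float(batch_stat(ranks[None, :, :])[0])
    n_ind = ranks.shape[0]
    copies = np.tile(ranks.ravel(), (n_shuffles, 1))
    copies = rng.permuted(copies, axis=1).reshape(n_shuffles, n_ind, 2)
    stats = batch_stat(copies)
    more_extreme = int((stats <= obs + 1e-9).sum())
    return (1 + more_extreme) / (n_shuffles + 1), True


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta for a pair of population samples
# ---------------------------------------------------------------------------


@dataclass
class LocusFst:
    """Variance components of one locus for one wild/reared pair."""

    locus: str
    pair: tuple[str, str]
    a: float
    b: float
    c: float
    het_total: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0 or not np.isfinite(denom):
            return float("nan")
        return self.a / denom

    @property
    def informative(self) -> bool:
        return np.isfinite(self.a) and (self.a + self.b + self.c) != 0


def _counts_and_hets(calls: np.ndarray, n_codes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus allele counts, heterozygote-carrier counts, and typed-individual
    counts for one sample.  ``calls`` is (n_ind, L, 2)."""
    n_ind, L, _ = calls.shape
    missing = (calls == MISSING).any(axis=2)  # (n_ind, L)
    n_typed = (~missing).sum(axis=0)  # (L,)
    locus_idx = np.broadcast_to(np.arange(L), (n_ind, L))

    counts = np.zeros((L, n_codes), dtype=np.int64)
    for k in (0, 1):
        a = calls[:, :, k]
        valid = ~missing
        np.add.at(counts, (locus_idx[valid], a[valid]), 1)

    het = (calls[:, :, 0] != calls[:, :, 1]) & ~missing
    hets = np.zeros((L, n_codes), dtype=np.int64)
    for k in (0, 1):
        a = calls[:, :, k]
        np.add.at(hets, (locus_idx[het], a[het]), 1)
    return counts, hets, n_typed


def wc_components_pair(
    calls1: np.ndarray, calls2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components (a, b, c) per locus for two samples.

    Vectorised over loci and alleles (components are summed over alleles).
    Returns ``(a, b, c, het_total)`` arrays of length L; loci monomorphic
    across both samples, or untyped in either sample, get NaN components.
    """
    n_codes = int(max(calls1.max(initial=0), calls2.max(initial=0))) + 1
    c1, h1, n1 = _counts_and_hets(calls1, n_codes)
    c2, h2, n2 = _counts_and_hets(calls2, n_codes)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = c1 / (2 * n1[:, None])
        p2 = c2 / (2 * n2[:, None])
        hb1 = h1 / n1[:, None]  # frequency of heterozygote carriers of each allele
        hb2 = h2 / n2[:, None]

        nbar = (n1 + n2) / 2.0
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        pbar = (n1[:, None] * p1 + n2[:, None] * p2) / (2 * nbar[:, None])
        s2 = (
            n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2
        ) / nbar[:, None]
        hbar = (n1[:, None] * hb1 + n2[:, None] * hb2) / (2 * nbar[:, None])

        inner = pbar * (1 - pbar) - s2 / 2.0
        a = (nbar / nc)[:, None] * (s2 - (inner - hbar / 4.0) / (nbar - 1)[:, None])
        b = (nbar / (nbar - 1))[:, None] * (
            inner - ((2 * nbar - 1) / (4 * nbar))[:, None] * hbar
        )
        c = hbar / 2.0

    present = (c1 + c2) > 0
    a = np.where(present, a, 0.0).sum(axis=1)
    b = np.where(present, b, 0.0).sum(axis=1)
    c = np.where(present, c, 0.0).sum(axis=1)
    het_total = np.where(present, hbar, 0.0).sum(axis=1)

    polymorphic = present.sum(axis=1) > 1
    usable = polymorphic & (n1 > 0) & (n2 > 0) & (nbar > 1)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c, het_total


def wc_theta_locus(wild: GenotypeMatrix, reared: GenotypeMatrix, locus: str) -> LocusFst:
    """Per-locus theta for one wild/reared pair (complete-case per locus)."""
    j = wild.locus_index(locus)
    k = reared.locus_index(locus)
    a, b, c, h = wc_components_pair(wild.calls[:, [j], :], reared.calls[:, [k], :])
    return LocusFst(
        locus=locus,
        pair=(wild.name, reared.name),
        a=float(a[0]),
        b=float(b[0]),
        c=float(c[0]),
        het_total=float(h[0]),
    )


def pair_fst_table(wild: GenotypeMatrix, reared: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus variance components and theta for every shared locus."""
    if wild.loci != reared.loci:
        raise ValueError("samples do not share a locus list")
    a, b, c, h = wc_components_pair(wild.calls, reared.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return pd.DataFrame(
        {
            "locus": wild.loci,
            "a": a,
            "b": b,
            "c": c,
            "het_total": h,
            "theta": theta,
            "informative": np.isfinite(theta),
        }
    )


def multilocus_theta(
    wild: GenotypeMatrix,
    reared: GenotypeMatrix,
    loci: list[str] | None = None,
    by_class: bool = False,
) -> float | tuple[float, dict[str, float]]:
    """Multilocus theta = sum(a) / sum(a+b+c) over informative loci.

    With ``by_class=True`` also returns the per-marker-class ratios
    (biallelic SNPs vs multiallelic microsatellites) as a dict.
    """
    tab = pair_fst_table(wild, reared)
    if loci is not None:
        tab = tab[tab["locus"].isin(set(loci))]
    tab = tab[tab["informative"]]
    if tab.empty:
        raise ValueError("no informative loci for multilocus theta")
    overall = float(tab["a"].sum() / (tab["a"] + tab["b"] + tab["c"]).sum())
    if not by_class:
        return overall
    kinds = classify_loci([wild, reared])
    out: dict[str, float] = {}
    for kind, sub in tab.groupby(tab["locus"].map(kinds)):
        denom = (sub["a"] + sub["b"] + sub["c"]).sum()
        if denom != 0:
            out[str(kind)] = float(sub["a"].sum() / denom)
    return overall, out


def fst_permutation_test(
    wild: GenotypeMatrix,
    reared: GenotypeMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation significance of the pairwise multilocus theta.

    Whole multilocus genotypes (individuals) are shuffled between the two
    samples, preserving sample sizes; P = (1 + #{theta* >= theta}) /
    (n_perm + 1).  Returns ``(theta_observed, p)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = multilocus_theta(wild, reared)
    pool = np.concatenate([wild.calls, reared.calls], axis=0)
    n1 = wild.n_individuals
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(pool.shape[0])
        a1, a2 = pool[idx[:n1]], pool[idx[n1:]]
        aa, bb, cc, _ = wc_components_pair(a1, a2)
        ok = np.isfinite(aa)
        denom = (aa[ok] + bb[ok] + cc[ok]).sum()
        theta_p = aa[ok].sum() / denom if denom != 0 else 0.0
        if theta_p >= observed:
            hits += 1
    return observed, (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Diversity summary (per sample x marker class)
# ---------------------------------------------------------------------------


def diversity_table(
    samples: list[GenotypeMatrix], kinds: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-sample, per-marker-class mean gene diversity and allele number,
    with observed ranges — the classic diversity-index summary layout."""
    if kinds is None:
        kinds = classify_loci(samples)
    rows = []
    for s in samples:
        per_locus = []
        for locus in s.loci:
            fr = allele_frequencies(s, locus)
            if fr.n < 2:
                continue
            per_locus.append((kinds[locus], gene_diversity(fr), fr.n_alleles))
        df = pd.DataFrame(per_locus, columns=["kind", "H", "k"])
        for kind, sub in df.groupby("kind"):
            rows.append(
                {
                    "sample": s.name,
                    "marker_class": kind,
                    "mean_gene_diversity": sub["H"].mean(),
                    "min_gene_diversity": sub["H"].min(),
                    "max_gene_diversity": sub["H"].max(),
                    "mean_allele_number": sub["k"].mean(),
                    "min_allele_number": sub["k"].min(),
                    "max_allele_number": sub["k"].max(),
                    "n_loci": len(sub),
                }
            )
        rows.append(
            {
                "sample": s.name,
                "marker_class": "all",
                "mean_gene_diversity": df["H"].mean(),
                "min_gene_diversity": df["H"].min(),
                "max_gene_diversity": df["H"].max(),
                "mean_allele_number": df["k"].mean(),
                "min_allele_number": df["k"].min(),
                "max_allele_number": df["k"].max(),
                "n_loci": len(df),
            }
        )
    return pd.DataFrame(rows)
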