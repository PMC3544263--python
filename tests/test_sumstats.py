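"""Diversity, HWE exact tests, and Weir-Cockerham theta."""

import itertools
import math

import numpy as np
import pytest

from hitchmap.genodata import allele_frequencies
from hitchmap.simulator import SimConfig, run_split_experiment
from hitchmap.sumstats import (
    diversity_table,
    fst_permutation_test,
    gene_diversity,
    hwe_exact_biallelic,
    hwe_exact_test,
    multilocus_theta,
    pair_fst_table,
    wc_theta_locus,
)
from conftest import make_sample, random_dataset


class TestGeneDiversity:
    def test_monomorphic_is_zero(self):
        assert gene_diversity(np.array([1.0]), 20) == 0.0

    def test_half_half_n32(self):
        assert gene_diversity(np.array([0.5, 0.5]), 32) == pytest.approx(0.516129, abs=1e-6)

    def test_relabeling_invariance(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            f = rng.dirichlet(np.ones(k))
            n = int(rng.integers(4, 60)) * 2
            assert gene_diversity(f, n) == pytest.approx(
                gene_diversity(f[rng.permutation(k)], n)
            )

    def test_tends_to_zero_as_one_allele_dominates(self):
        hs = [gene_diversity(np.array([p, 1 - p]), 1000) for p in (0.5, 0.8, 0.95, 0.999)]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_too_few_copies_raises(self):
        with pytest.raises(ValueError):
            gene_diversity(np.array([1.0]), 1)


# --- independent enumeration oracle for the exact conditional HWE test ----


def _hwe_oracle(genotype_counts: dict[tuple[int, int], int]) -> float:
    """Full enumeration of genotype tables conditional on allele counts."""
    alleles = sorted({a for g in genotype_counts for a in g})
    a_counts = {a: 0 for a in alleles}
    n = sum(genotype_counts.values())
    for (i, j), c in genotype_counts.items():
        a_counts[i] += c
        a_counts[j] += c
    pairs = [(i, j) for idx, i in enumerate(alleles) for j in alleles[idx:]]

    def log_prob(table: dict) -> float:
        het = sum(c for (i, j), c in table.items() if i != j)
        lp = math.lgamma(n + 1) + het * math.log(2.0) - math.lgamma(2 * n + 1)
        for a in alleles:
            lp += math.lgamma(a_counts[a] + 1)
        for c in table.values():
            lp -= math.lgamma(c + 1)
        return lp

    tables = []

    def recurse(idx: int, remaining: dict, table: dict) -> None:
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                tables.append(dict(table))
            return
        i, j = pairs[idx]
        cap = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for c in range(cap + 1):
            remaining[i] -= 2 * c if i == j else c
            if i != j:
                remaining[j] -= c
            table[(i, j)] = c
            recurse(idx + 1, remaining, table)
            remaining[i] += 2 * c if i == j else c
            if i != j:
                remaining[j] += c
        del table[(i, j)]

    recurse(0, dict(a_counts), {})
    lps = np.array([log_prob(t) for t in tables])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = np.exp(log_prob(genotype_counts) - lps.max())
    obs /= np.exp(lps - lps.max()).sum()
    return float(probs[probs <= obs * (1 + 1e-9)].sum())


def _calls_from_counts(counts: dict[tuple[int, int], int]) -> np.ndarray:
    rows = []
    for (i, j), c in counts.items():
        rows += [[i, j]] * c
    return np.array(rows).reshape(-1, 1, 2)


class TestHWEExact:
    @pytest.mark.parametrize(
        "het,hom1,hom2",
        [(8, 4, 4), (0, 8, 8), (16, 0, 0), (3, 5, 1), (1, 0, 9)],
    )
    def test_biallelic_matches_enumeration_oracle(self, het, hom1, hom2):
        expected = _hwe_oracle({(1, 1): hom1, (1, 2): het, (2, 2): hom2})
        assert hwe_exact_biallelic(het, hom1, hom2) == pytest.approx(expected, abs=1e-10)

    def test_monomorphic_untestable(self):
        s = make_sample("p", np.full((10, 1, 2), 1))
        p, testable = hwe_exact_test(s, "L1")
        assert p == 1.0 and not testable

    def test_dispatch_biallelic(self):
        counts = {(1, 1): 4, (1, 2): 8, (2, 2): 4}
        s = make_sample("p", _calls_from_counts(counts))
        p, testable = hwe_exact_test(s, "L1")
        assert testable
        assert p == pytest.approx(_hwe_oracle(counts), abs=1e-10)

    @pytest.mark.parametrize(
        "counts",
        [
            {(1, 1): 2, (1, 2): 1, (2, 3): 2, (3, 3): 1},
            {(1, 2): 3, (1, 3): 2, (2, 3): 2, (1, 1): 1},
        ],
    )
    def test_monte_carlo_converges_to_enumeration(self, counts):
        """Multiallelic Monte-Carlo P within 3 MC standard errors of exact."""
        exact = _hwe_oracle(counts)
        s = make_sample("p", _calls_from_counts(counts))
        n_sh = 20_000
        p, _ = hwe_exact_test(s, "L1", n_shuffles=n_sh, seed=5)
        se = math.sqrt(exact * (1 - exact) / n_sh)
        assert abs(p - exact) <= 3 * se + 2 / n_sh

    def test_all_missing_raises(self):
        s = make_sample("p", np.zeros((4, 1, 2), dtype=int))
        with pytest.raises(ValueError):
            hwe_exact_test(s, "L1")


# --- independent scalar oracle for Weir-Cockerham variance components -----


def _wc_oracle_theta(calls1, calls2, j):
    """Scalar per-allele evaluation of the 1984 variance-component formulas."""
    comps = []
    cols = []
    for calls in (calls1, calls2):
        col = calls[:, j, :]
        cols.append(col[(col != 0).all(axis=1)])
    n1, n2 = len(cols[0]), len(cols[1])
    alleles = sorted(set(cols[0].ravel()) | set(cols[1].ravel()))
    if len(alleles) < 2:
        return float("nan")
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for al in alleles:
        p1 = (cols[0] == al).sum() / (2 * n1)
        p2 = (cols[1] == al).sum() / (2 * n2)
        h1 = np.mean((cols[0] == al).sum(axis=1) == 1)
        h2 = np.mean((cols[1] == al).sum(axis=1) == 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        A, B, C = A + a, B + b, C + hbar / 2
    return A / (A + B + C)


class TestWeirCockerhamTheta:
    def test_fixed_difference_is_one(self):
        w = make_sample("w", np.full((16, 1, 2), 1))
        r = make_sample("r", np.full((16, 1, 2), 2))
        assert wc_theta_locus(w, r, "L1").theta == pytest.approx(1.0)

    def test_identical_samples_nonpositive(self, rng):
        calls = rng.integers(1, 3, (16, 6, 2))
        w = make_sample("w", calls)
        r = make_sample("r", calls.copy())
        assert multilocus_theta(w, r) <= 0

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_scalar_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        w, r = random_dataset(rng, n_ind=8, n_loci=4, max_allele=3, missing_rate=0.1)
        for j, locus in enumerate(w.loci):
            expected = _wc_oracle_theta(w.calls, r.calls, j)
            got = wc_theta_locus(w, r, locus).theta
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_locus_flagged_uninformative(self):
        w = make_sample("w", np.full((6, 1, 2), 1))
        r = make_sample("r", np.full((6, 1, 2), 1))
        rec = wc_theta_locus(w, r, "L1")
        assert not rec.informative and np.isnan(rec.theta)

    def test_multilocus_equals_single_locus_when_alone(self, rng):
        w, r = random_dataset(rng, n_ind=10, n_loci=1, missing_rate=0)
        assert multilocus_theta(w, r) == pytest.approx(wc_theta_locus(w, r, "L1").theta)

    def test_multilocus_is_ratio_of_sums(self, rng):
        w, r = random_dataset(rng, n_ind=12, n_loci=8, missing_rate=0)
        tab = pair_fst_table(w, r)
        tab = tab[tab["informative"]]
        expected = tab["a"].sum() / (tab["a"] + tab["b"] + tab["c"]).sum()
        assert multilocus_theta(w, r) == pytest.approx(expected)
        # and generally NOT the mean of per-locus ratios
        assert multilocus_theta(w, r) != pytest.approx(tab["theta"].mean(), abs=1e-12)

    def test_by_class_means_returned(self, rng):
        calls_w = rng.integers(1, 3, (10, 2, 2))
        calls_w[:, 1, :] = rng.integers(1, 6, (10, 2))
        calls_r = rng.integers(1, 3, (10, 2, 2))
        calls_r[:, 1, :] = rng.integers(1, 6, (10, 2))
        w, r = make_sample("w", calls_w), make_sample("r", calls_r)
        overall, per_class = multilocus_theta(w, r, by_class=True)
        assert set(per_class) <= {"biallelic_snp", "multiallelic_msat"}
        assert np.isfinite(overall)


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self, rng):
        w = make_sample("w", np.full((8, 4, 2), 1))
        r = make_sample("r", np.full((8, 4, 2), 2))
        _, p = fst_permutation_test(w, r, n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_seeded_reproducibility(self, rng):
        w, r = random_dataset(rng, n_ind=10, n_loci=6)
        r1 = fst_permutation_test(w, r, n_perm=150, seed=42)
        r2 = fst_permutation_test(w, r, n_perm=150, seed=42)
        assert r1 == r2

    def test_null_p_roughly_uniform(self):
        """Panmictic pool split in two: P should not pile up near 0."""
        ps = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pool = rng.integers(1, 3, (20, 10, 2)).astype(np.int32)
            w = make_sample("w", pool[:10])
            r = make_sample("r", pool[10:])
            ps.append(fst_permutation_test(w, r, n_perm=100, seed=seed)[1])
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) < 0.5 < max(ps)

    def test_n_perm_floor(self, rng):
        w, r = random_dataset(rng)
        with pytest.raises(ValueError):
            fst_permutation_test(w, r, n_perm=10)


class TestDriftRecovery:
    @pytest.mark.parametrize("ne,t", [(65, 5), (238, 5), (330, 8)])
    def test_mean_theta_matches_drift_expectation(self, ne, t):
        """Replicate-mean multilocus theta within 15% of 1-(1-1/(2Ne))^t."""
        rng = np.random.default_rng(ne * 1000 + t)
        L = 50
        mafs = rng.uniform(0.05, 0.5, L)
        cfg = SimConfig(
            ne=ne, t_split=t,
            loci=[f"L{j}" for j in range(L)],
            positions_cM=np.zeros(L), linkage_groups=np.arange(L),
            burnin=0, sample_size=16, n_replicates=200, seed=int(rng.integers(2**31)),
        )
        reps = run_split_experiment(cfg, ancestral_freqs=[np.array([1 - m, m]) for m in mafs])
        mean_theta = np.nanmean([r.multilocus_theta for r in reps])
        expected = 1 - (1 - 1 / (2 * ne)) ** t
        assert abs(mean_theta - expected) <= 0.15 * expected


class TestDiversityTable:
    def test_layout_and_values(self, rng):
        w, r = random_dataset(rng, n_ind=16, n_loci=6, missing_rate=0)
        tab = diversity_table([w, r])
        assert set(tab["sample"]) == {"pop1", "pop2"}
        assert (tab["mean_gene_diversity"] <= 1).all()
        all_row = tab[(tab["sample"] == "pop1") & (tab["marker_class"] == "all")]
        assert int(all_row["n_loci"].iloc[0]) == 6

    def test_mean_matches_per_locus_recomputation(self, rng):
        (pop,) = random_dataset(rng, n_pops=1, n_ind=16, n_loci=5, missing_rate=0)
        tab = diversity_table([pop])
        hs = [gene_diversity(allele_frequencies(pop, l)) for l in pop.loci]
        all_row = tab[tab["marker_class"] == "all"].iloc[0]
        assert all_row["mean_gene_diversity"] == pytest.approx(np.mean(hs))
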