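"""Forward-time diploid Wright-Fisher simulation of directional selection
on standing variation along a mapped chromosome.

The model mirrors a domestication/captive-breeding experiment: an
ancestral population of Ne diploids is founded from an observed wild
sample ("multiplication" of existing genotypes followed by a few
generations of random mating), then split into a wild and a captive deme
of Ne diploids each, which evolve in complete isolation for t
generations.  In the captive deme one locus is under directional
viability selection with genotype fitnesses

    w(AA, Aa, aa) = (1, 1-h*s, 1-s)

where A is the favoured allele (by default the MINOR allele of the
selected locus in the ancestral pool, i.e. selection from standing
variation); the wild deme is strictly neutral.  Gametes recombine along
the female linkage map through Haldane's map function with no
interference; mutation is off on the 5-8 generation timescale modelled.
Each replicate ends by sampling 16 diploids per deme and computing
per-locus and multilocus Weir-Cockerham theta, the same estimator applied
to the empirical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING
from .sumstats import wc_components_pair

__all__ = [
    "SimConfig",
    "SimReplicate",
    "fitness_vector",
    "derive_ne",
    "haldane_r",
    "rec_fractions",
    "population_from_freqs",
    "founder_sample_linked",
    "found_ancestral",
    "evolve",
    "run_split_experiment",
    "replicate_boxplot_stats",
]


def fitness_vector(s: float, h: float) -> tuple[float, float, float]:
    """Genotype fitnesses (w_AA, w_Aa, w_aa) = (1, 1-h*s, 1-s) for the
    favoured allele A."""
    if not (0.0 <= s <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("need s, h in [0, 1]")
    return (1.0, 1.0 - h * s, 1.0 - s)


def derive_ne(t: int, fst: float) -> int:
    """Effective size implied by drift-only divergence: Ne = t / (2 F_ST),
    rounded to the nearest diploid count."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if fst <= 0:
        raise ValueError("drift-only divergence requires F_ST > 0")
    return int(round(t / (2.0 * fst)))


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: r = (1 - exp(-2d))/2 with d in Morgans."""
    d = np.asarray(d_cM, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if np.isscalar(d_cM) else r


def rec_fractions(
    positions_cM: np.ndarray, linkage_groups: np.ndarray | None = None
) -> np.ndarray:
    """Per-interval recombination fractions between consecutive loci.

    Loci must already be in map order.  Intervals crossing a linkage-group
    boundary get r = 0.5 (free recombination between chromosomes).
    """
    pos = np.asarray(positions_cM, dtype=float)
    if pos.size < 2:
        return np.empty(0)
    d = np.diff(pos)
    if linkage_groups is None:
        if (d < 0).any():
            raise ValueError("positions must be nondecreasing within one linkage group")
        return np.asarray(haldane_r(d))
    lg = np.asarray(linkage_groups)
    same = lg[:-1] == lg[1:]
    if (d[same] < 0).any():
        raise ValueError("positions must be nondecreasing within each linkage group")
    r = np.where(same, haldane_r(np.abs(d)), 0.5)
    return r


# ---------------------------------------------------------------------------
# Population state: integer allele-code array (N, L, 2), no missing data
# ---------------------------------------------------------------------------


def population_from_freqs(
    freqs: list[np.ndarray], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw `n` diploids in Hardy-Weinberg and linkage equilibrium at the
    given per-locus allele-frequency vectors (allele codes 1..k per locus)."""
    L = len(freqs)
    calls = np.empty((n, L, 2), dtype=np.int32)
    for j, f in enumerate(freqs):
        f = np.asarray(f, dtype=float)
        calls[:, j, :] = rng.choice(len(f), size=(n, 2), p=f / f.sum()) + 1
    return calls


def founder_sample_linked(
    mafs: np.ndarray,
    n: int,
    sel_idx: int,
    copy_probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Biallelic founder sample with LD between the selected locus and its
    neighbours.

    Each of the 2n founder haplotypes draws its selected-locus allele with
    the given minor-allele frequency; at every other locus j the haplotype
    copies the selected locus's minor/major state with probability
    ``copy_probs[j]`` (1 = complete association, as for markers a fraction
    of a centimorgan apart in a real population) and otherwise draws
    independently at ``mafs[j]``.  Allele codes: 1 = major, 2 = minor.
    """
    mafs = np.asarray(mafs, dtype=float)
    copy_probs = np.asarray(copy_probs, dtype=float)
    L = mafs.size
    haps = (rng.random((2 * n, L)) < mafs).astype(np.int32)  # 1 = minor state
    sel_state = rng.random(2 * n) < mafs[sel_idx]
    haps[:, sel_idx] = sel_state
    copy = rng.random((2 * n, L)) < copy_probs
    copy[:, sel_idx] = False
    haps[copy] = np.broadcast_to(sel_state[:, None], (2 * n, L))[copy]
    return (haps + 1).reshape(n, 2, L).transpose(0, 2, 1).astype(np.int32)


def _gametes(
    calls: np.ndarray, parents: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per parent index; crossovers are independent
    per interval (Haldane, no interference)."""
    G = parents.size
    L = calls.shape[1]
    hap = np.empty((G, L), dtype=np.int64)
    hap[:, 0] = rng.integers(0, 2, size=G)
    if L > 1:
        switch = rng.random((G, L - 1)) < r
        hap[:, 1:] = switch
        np.bitwise_xor.accumulate(hap, axis=1, out=hap)
    return calls[parents[:, None], np.arange(L)[None, :], hap]


def _reproduce(
    calls: np.ndarray,
    r: np.ndarray,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    n_offspring: int | None = None,
) -> np.ndarray:
    """One Wright-Fisher generation: each offspring draws two parents
    (with replacement, probability proportional to fitness) who each
    transmit one recombinant gamete.  Offspring count defaults to the
    parental population size."""
    N = calls.shape[0]
    n_off = N if n_offspring is None else n_offspring
    p = None
    if weights is not None:
        total = weights.sum()
        if total <= 0:
            raise ValueError("all parental fitnesses are zero")
        p = weights / total
    mothers = rng.choice(N, size=n_off, replace=True, p=p)
    fathers = rng.choice(N, size=n_off, replace=True, p=p)
    g1 = _gametes(calls, mothers, r, rng)
    g2 = _gametes(calls, fathers, r, rng)
    return np.stack([g1, g2], axis=2)


def _fitness_weights(
    calls: np.ndarray, selected_idx: int, favored: int, s: float, h: float
) -> np.ndarray:
    w = np.array(fitness_vector(s, h))  # (w_AA, w_Aa, w_aa)
    copies = (calls[:, selected_idx, :] == favored).sum(axis=1)
    return w[2 - copies]


def found_ancestral(
    source_calls: np.ndarray,
    ne: int,
    burnin: int,
    r: np.ndarray,
    rng: np.random.Generator,
    systematic: bool = False,
) -> np.ndarray:
    """Found an ancestral population of `ne` diploids from observed genotypes.

    Individuals are multiplied up to `ne` — sampled with replacement, or
    tiled k-fold when ``systematic`` and ne is a multiple of the source
    size (which preserves allele counts exactly) — then randomly mated for
    `burnin` generations.  Missing calls are imputed from the source allele
    frequencies before expansion.
    """
    src = np.asarray(source_calls, dtype=np.int32)
    if src.shape[0] == 0:
        raise ValueError("empty source sample")
    src = src.copy()
    for j in range(src.shape[1]):
        col = src[:, j, :]
        miss = (col == MISSING).any(axis=1)
        good = col[~miss].ravel()
        if miss.any():
            if good.size == 0:
                raise ValueError(f"locus index {j} entirely missing in source")
            alleles, counts = np.unique(good, return_counts=True)
            col[miss] = rng.choice(alleles, size=(int(miss.sum()), 2), p=counts / counts.sum())
    if systematic:
        if ne % src.shape[0] != 0:
            raise ValueError("systematic expansion requires ne to be a multiple of the source size")
        pop = np.tile(src, (ne // src.shape[0], 1, 1))
    else:
        pop = src[rng.choice(src.shape[0], size=ne, replace=True)]
    for _ in range(burnin):
        pop = _reproduce(pop, r, rng)
    return pop


def evolve(
    calls: np.ndarray,
    generations: int,
    r: np.ndarray,
    rng: np.random.Generator,
    selected_idx: int | None = None,
    favored: int | None = None,
    s: float = 0.0,
    h: float = 0.5,
    track_idx: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve a deme for `generations` discrete Wright-Fisher generations.

    With ``selected_idx`` set and s > 0, parents are drawn with probability
    proportional to their viability at the selected locus.  Returns the
    final population and the tracked-locus favoured-allele frequency
    trajectory of length ``generations + 1`` (entry 0 = starting state).
    """
    if track_idx is None:
        track_idx = selected_idx
    traj = np.full(generations + 1, np.nan)

    def freq(pop: np.ndarray) -> float:
        if track_idx is None or favored is None:
            return float("nan")
        return float((pop[:, track_idx, :] == favored).mean())

    traj[0] = freq(calls)
    for g in range(generations):
        weights = None
        if selected_idx is not None and s > 0:
            if favored is None:
                raise ValueError("favoured allele required under selection")
            weights = _fitness_weights(calls, selected_idx, favored, s, h)
        calls = _reproduce(calls, r, rng, weights=weights)
        traj[g + 1] = freq(calls)
    return calls, traj


# ---------------------------------------------------------------------------
# The split experiment
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of one split-model simulation experiment.

    `loci`, `positions_cM` and optional `linkage_groups` describe the
    simulated marker panel in map order; `selected_locus` (None for the
    pure-drift validation mode) names the locus under selection in the
    captive deme, with fitnesses (1, 1-h*s, 1-s) favouring its ancestral
    minor allele.
    """

    ne: int
    t_split: int
    loci: list[str]
    positions_cM: np.ndarray
    linkage_groups: np.ndarray | None = None
    selected_locus: str | None = None
    s: float = 0.6
    h: float = 0.5
    burnin: int = 3
    sample_size: int = 16
    n_replicates: int = 25
    seed: int = 0
    keep_samples: bool = False

    def __post_init__(self) -> None:
        self.positions_cM = np.asarray(self.positions_cM, dtype=float)
        if len(self.loci) != self.positions_cM.size:
            raise ValueError("loci and positions_cM lengths differ")
        if self.ne < 2 or self.t_split < 1 or self.sample_size < 2:
            raise ValueError("invalid population sizes or split time")
        if self.sample_size > self.ne:
            raise ValueError("cannot sample more diploids than the deme holds")
        if self.selected_locus is not None and self.selected_locus not in self.loci:
            raise ValueError(f"selected locus {self.selected_locus!r} not in panel")

    @property
    def rec(self) -> np.ndarray:
        return rec_fractions(self.positions_cM, self.linkage_groups)

    @property
    def selected_idx(self) -> int | None:
        if self.selected_locus is None:
            return None
        return self.loci.index(self.selected_locus)


@dataclass
class SimReplicate:
    """Per-locus theta readout and selected-allele trajectories of one
    replicate (wild vs captive, `sample_size` diploids sampled per deme)."""

    replicate_id: int
    per_locus_theta: pd.Series = field(repr=False)
    multilocus_theta: float
    traj_wild: np.ndarray = field(repr=False)
    traj_captive: np.ndarray = field(repr=False)
    favored_allele: int | None = None
    sample_wild: np.ndarray | None = field(default=None, repr=False)
    sample_captive: np.ndarray | None = field(default=None, repr=False)


def _minor_allele(pop: np.ndarray, idx: int) -> int:
    alleles, counts = np.unique(pop[:, idx, :], return_counts=True)
    if len(alleles) < 2:
        raise ValueError("selected locus is monomorphic: no standing variation to select")
    return int(alleles[np.argmin(counts)])


def run_split_experiment(
    config: SimConfig,
    source_calls: np.ndarray | None = None,
    ancestral_freqs: list[np.ndarray] | None = None,
) -> list[SimReplicate]:
    """Run the full split experiment for ``config.n_replicates`` replicates.

    The ancestral deme is founded either from observed genotypes
    (`source_calls`, expanded and random-mated for `burnin` generations) or
    directly from per-locus allele frequencies (`ancestral_freqs`, drawn in
    Hardy-Weinberg proportions at size Ne).  Each replicate splits the
    ancestral population into a neutral wild deme and a captive deme (with
    selection at the configured locus), evolves both for ``t_split``
    generations in isolation, samples ``sample_size`` diploids per deme and
    records Weir-Cockerham theta per locus.
    """
    if (source_calls is None) == (ancestral_freqs is None):
        raise ValueError("provide exactly one of source_calls or ancestral_freqs")
    rng = np.random.default_rng(config.seed)
    r = config.rec
    reps: list[SimReplicate] = []
    for rep in range(config.n_replicates):
        if source_calls is not None:
            ancestral = found_ancestral(source_calls, config.ne, config.burnin, r, rng)
        else:
            ancestral = population_from_freqs(ancestral_freqs, config.ne, rng)
        sel = config.selected_idx
        favored = None
        if sel is not None:
            favored = _minor_allele(ancestral, sel)

        wild, traj_w = evolve(
            ancestral, config.t_split, r, rng,
            selected_idx=None, favored=favored, track_idx=sel,
        )
        captive, traj_c = evolve(
            ancestral, config.t_split, r, rng,
            selected_idx=sel, favored=favored, s=config.s, h=config.h,
        )

        # sample each deme as an offspring cohort: 16 diploids whose gametes
        # are i.i.d. draws from the deme's gene pool, matching the sampling
        # model the theta estimator corrects for (a field sample of n
        # individuals from a much larger population)
        sw = _reproduce(wild, r, rng, n_offspring=config.sample_size)
        sc = _reproduce(captive, r, rng, n_offspring=config.sample_size)
        a, b, c, _ = wc_components_pair(sw, sc)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = a / (a + b + c)
        ok = np.isfinite(a)
        denom = (a[ok] + b[ok] + c[ok]).sum()
        multi = float(a[ok].sum() / denom) if denom != 0 else float("nan")
        reps.append(
            SimReplicate(
                replicate_id=rep,
                per_locus_theta=pd.Series(theta, index=config.loci),
                multilocus_theta=multi,
                traj_wild=traj_w,
                traj_captive=traj_c,
                favored_allele=favored,
                sample_wild=sw if config.keep_samples else None,
                sample_captive=sc if config.keep_samples else None,
            )
        )
    return reps


def replicate_boxplot_stats(values: np.ndarray) -> dict[str, object]:
    """Five-number box-plot summary with Tukey 1.5*IQR whiskers and the
    flagged outliers, matching a standard box-plot rendering."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("need >= 5 replicate values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": np.sort(v[(v < lo_fence) | (v > hi_fence)]),
    }
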