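"""Synthetic wild/reared genotype datasets with the statistical structure
the scan assumes, including planted selected regions with known truth.

The generative model is the same split model the simulator implements:
per population pair, an ancestral population is drawn at configured
allele-frequency spectra, split into a neutral wild deme and a captive
deme (optionally with directional selection at a planted locus), evolved
for t generations at effective size Ne, and sampled at 16 diploids per
deme.  Defaults emulate a panel of 261 biallelic SNPs and 70 multiallelic
microsatellites spread over a ~2000 cM female linkage map, with three
wild/reared pairs whose (Ne, t) and SNP frequency spectra bracket the
diversity and differentiation levels typical of recently domesticated
Atlantic salmon strains (multilocus theta roughly 0.01-0.04; mean SNP
gene diversity roughly 0.12-0.32 per pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, MarkerMap, write_genepop, write_marker_map
from .simulator import SimConfig, run_split_experiment

__all__ = [
    "PairSpec",
    "SynthConfig",
    "TruthRecord",
    "gen_marker_panel",
    "gen_ancestral_freqs",
    "gen_pair_dataset",
    "write_pair_dataset",
    "scan_recovery_experiment",
]


@dataclass
class PairSpec:
    """One wild/reared pair: drift parameters, SNP frequency spectrum, and
    the number of planted selected loci (0 = fully neutral)."""

    name: str
    ne: int
    t: int
    snp_maf_beta: tuple[float, float]
    n_selected: int = 0
    s: float = 0.6
    h: float = 0.5


#: three pair profiles spanning the empirical range: a large-Ne long-split
#: pair with common SNP variants, a small-Ne pair with intermediate
#: spectra, and a large-Ne pair with rare-shifted (low-diversity) spectra
DEFAULT_PAIRS = [
    PairSpec("pair_irl", ne=330, t=8, snp_maf_beta=(1.6, 2.0)),
    PairSpec("pair_swe", ne=65, t=5, snp_maf_beta=(1.0, 2.5)),
    PairSpec("pair_can", ne=238, t=5, snp_maf_beta=(0.6, 3.5)),
]


@dataclass
class SynthConfig:
    n_snp: int = 261
    n_msat: int = 70
    n_linkage_groups: int = 31
    total_map_cM: float = 2000.0
    snp_maf_min: float = 0.01
    msat_allele_range: tuple[int, int] = (2, 20)
    msat_dirichlet_alpha: float = 0.35
    pairs: list[PairSpec] = field(default_factory=lambda: list(DEFAULT_PAIRS))
    sample_size: int = 16
    seed: int = 0

    @property
    def n_loci(self) -> int:
        return self.n_snp + self.n_msat


@dataclass
class TruthRecord:
    """Ground truth of one generated dataset, for recovery experiments."""

    dataset_id: str
    selected: list[dict]  # locus, s, h, ancestral minor-allele frequency
    ancestral_freqs: dict[str, list[float]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def gen_marker_panel(config: SynthConfig, seed: int | None = None) -> tuple[MarkerMap, dict[str, str]]:
    """Generate the marker panel: loci placed uniformly on equal-length
    linkage groups summing to ``total_map_cM``; returns the map and each
    locus's marker class."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_loci
    if n < 2 * config.n_linkage_groups:
        raise ValueError("fewer than 2 loci per linkage group on average")
    names = [f"snp{i + 1:04d}" for i in range(config.n_snp)] + [
        f"msat{i + 1:03d}" for i in range(config.n_msat)
    ]
    kinds = {
        nm: ("biallelic_snp" if nm.startswith("snp") else "multiallelic_msat")
        for nm in names
    }
    lg_len = config.total_map_cM / config.n_linkage_groups
    lg = rng.integers(0, config.n_linkage_groups, size=n)
    # guarantee every linkage group holds at least 2 loci
    for g in range(config.n_linkage_groups):
        while (lg == g).sum() < 2:
            lg[rng.integers(0, n)] = g
    # uniform placement, rescaled so each linkage group spans its full
    # length and the spans sum to total_map_cM (up to 0.1 cM rounding)
    pos = np.empty(n)
    for g in range(config.n_linkage_groups):
        idx = np.where(lg == g)[0]
        u = rng.uniform(0, 1, size=idx.size)
        u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
        pos[idx] = np.round(u * lg_len, 1)
    table = pd.DataFrame(
        {
            "locus": names,
            "linkage_group": [f"LG{g + 1:02d}" for g in lg],
            "position_female_cM": pos,
        }
    )
    return MarkerMap(table), kinds


def gen_ancestral_freqs(
    config: SynthConfig, pair: PairSpec, marker_map: MarkerMap, seed: int
) -> tuple[list[str], list[np.ndarray]]:
    """Ancestral allele-frequency spectra for one pair, in map order.

    SNP minor-allele frequencies are 0.5 x Beta(a, b) (truncated below at
    ``snp_maf_min``); microsatellites draw k ~ Uniform{2..20} alleles with
    broken-stick Dirichlet(alpha) frequencies.
    """
    rng = np.random.default_rng(seed)
    ordered = marker_map.ordered_loci()
    loci = ordered["locus"].tolist()
    a, b = pair.snp_maf_beta
    lo, hi = config.msat_allele_range
    freqs: list[np.ndarray] = []
    for locus in loci:
        if locus.startswith("snp"):
            maf = float(np.clip(0.5 * rng.beta(a, b), config.snp_maf_min, 0.5))
            freqs.append(np.array([1.0 - maf, maf]))
        else:
            k = int(rng.integers(lo, hi + 1))
            f = rng.dirichlet(np.full(k, config.msat_dirichlet_alpha))
            # avoid effectively-absent alleles that would break 2-digit codes
            f = np.maximum(f, 1e-4)
            freqs.append(f / f.sum())
    return loci, freqs


def _pick_selected(
    loci: list[str],
    freqs: list[np.ndarray],
    ordered: pd.DataFrame,
    n_selected: int,
    rng: np.random.Generator,
) -> list[int]:
    """Planted loci are SNPs with common standing variation (MAF >= 0.1),
    preferring candidates with a close mapped neighbour so the hitchhiking
    footprint spans an adjacent-locus pair."""
    pos = ordered["position_female_cM"].to_numpy()
    lg = ordered["linkage_group"].to_numpy()
    candidates = [
        i
        for i, (l, f) in enumerate(zip(loci, freqs))
        if l.startswith("snp") and f.min() >= 0.1
    ]
    if len(candidates) < n_selected:
        raise ValueError("not enough common SNPs to plant selected loci")

    def neighbour_distance(i: int) -> float:
        same = (lg == lg[i]) & (np.arange(len(loci)) != i)
        if not same.any():
            return np.inf
        return float(np.abs(pos[same] - pos[i]).min())

    ranked = sorted(candidates, key=lambda i: (neighbour_distance(i), rng.random()))
    return sorted(ranked[:n_selected])


def _draw_source_sample(
    loci: list[str],
    freqs: list[np.ndarray],
    ordered: pd.DataFrame,
    sel_idx: list[int],
    n: int,
    rng: np.random.Generator,
    ld_decay_cM: float = 1.0,
) -> np.ndarray:
    """Draw the wild source sample (n diploids) at the ancestral spectra.

    Loci are drawn independently except around each planted locus, where
    biallelic neighbours on the same linkage group copy the planted locus's
    minor/major haplotype state with probability exp(-d / ld_decay_cM) —
    tightly linked markers in a real population are in strong LD, and the
    hitchhiking footprint only exists if the founders carry it.
    """
    n_hap = 2 * n
    haps = np.empty((n_hap, len(loci)), dtype=np.int32)
    for j, f in enumerate(freqs):
        haps[:, j] = rng.choice(len(f), size=n_hap, p=f) + 1
    pos = ordered["position_female_cM"].to_numpy()
    lg = ordered["linkage_group"].to_numpy()
    for i in sel_idx:
        minor_i = int(np.argmin(freqs[i])) + 1
        state = haps[:, i] == minor_i
        for j in range(len(loci)):
            if j == i or lg[j] != lg[i] or len(freqs[j]) != 2:
                continue
            w = np.exp(-abs(pos[j] - pos[i]) / ld_decay_cM)
            if w < 0.01:
                continue
            minor_j = int(np.argmin(freqs[j])) + 1
            major_j = 3 - minor_j
            copy = rng.random(n_hap) < w
            haps[copy, j] = np.where(state[copy], minor_j, major_j)
    return haps.reshape(n, 2, len(loci)).transpose(0, 2, 1).astype(np.int32)


def gen_pair_dataset(
    config: SynthConfig,
    pair: PairSpec,
    marker_map: MarkerMap,
    seed: int,
) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthRecord]:
    """Generate one wild/reared dataset for `pair` by running the split
    model, returning the two 16-diploid samples and the ground truth."""
    rng = np.random.default_rng(seed)
    loci, freqs = gen_ancestral_freqs(config, pair, marker_map, int(rng.integers(2**31)))
    ordered = marker_map.ordered_loci()
    sel_idx = _pick_selected(loci, freqs, ordered, pair.n_selected, rng) if pair.n_selected else []
    # one selected locus per simulated pair (single candidate region)
    selected_locus = loci[sel_idx[0]] if sel_idx else None
    # founding mirrors the field design: a small wild sample "multiplied"
    # up to Ne and random-mated, which preserves founder LD
    for _ in range(50):
        source = _draw_source_sample(loci, freqs, ordered, sel_idx, config.sample_size, rng)
        if selected_locus is None:
            break
        if len(np.unique(source[:, sel_idx[0], :])) > 1:
            break
    else:
        raise ValueError("planted locus persistently monomorphic in the source sample")
    sim = SimConfig(
        ne=pair.ne,
        t_split=pair.t,
        loci=loci,
        positions_cM=ordered["position_female_cM"].to_numpy(),
        linkage_groups=ordered["linkage_group"].to_numpy(),
        selected_locus=selected_locus,
        s=pair.s,
        h=pair.h,
        burnin=3,
        sample_size=config.sample_size,
        n_replicates=1,
        seed=int(rng.integers(2**31)),
        keep_samples=True,
    )
    rep = run_split_experiment(sim, source_calls=source)[0]
    wild = GenotypeMatrix(
        name=f"{pair.name}_wild",
        individuals=[f"{pair.name}_w{i + 1:02d}" for i in range(config.sample_size)],
        loci=loci,
        calls=rep.sample_wild,
    )
    reared = GenotypeMatrix(
        name=f"{pair.name}_reared",
        individuals=[f"{pair.name}_r{i + 1:02d}" for i in range(config.sample_size)],
        loci=loci,
        calls=rep.sample_captive,
    )
    truth = TruthRecord(
        dataset_id=f"{pair.name}_seed{seed}",
        selected=[
            {
                "locus": loci[i],
                "s": pair.s,
                "h": pair.h,
                "ancestral_maf": float(np.min(freqs[i])),
            }
            for i in sel_idx
        ],
        ancestral_freqs={l: [float(x) for x in f] for l, f in zip(loci, freqs)},
    )
    return wild, reared, truth


def write_pair_dataset(
    outdir: str | Path,
    config: SynthConfig,
    pair: PairSpec,
    marker_map: MarkerMap,
    seed: int,
) -> dict[str, Path]:
    """Generate and write one dataset: Genepop genotypes, map TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wild, reared, truth = gen_pair_dataset(config, pair, marker_map, seed)
    paths = {
        "genotypes": outdir / f"{pair.name}.gen",
        "map": outdir / f"{pair.name}.map.tsv",
        "truth": outdir / f"{pair.name}.truth.json",
    }
    write_genepop([wild, reared], paths["genotypes"], digits=2,
                  title=f"synthetic wild/reared dataset {truth.dataset_id}")
    write_marker_map(marker_map, paths["map"])
    truth.to_json(paths["truth"])
    return paths


def scan_recovery_experiment(
    config: SynthConfig,
    seed: int = 0,
    n_datasets: int = 20,
    pair: PairSpec | None = None,
    n_perm_cluster: int = 1000,
    flag_window_cM: float = 5.0,
) -> dict[str, float]:
    """Generate `n_datasets` datasets and measure planted-signal recovery.

    For each dataset the full scan (theta, lnRH, both clustering tests) is
    run; sensitivity is the fraction of datasets where the planted locus —
    or a mapped neighbour within ``flag_window_cM`` on the same linkage
    group — is flagged by at least one test, and the false-positive rate is
    the mean per-test fraction of flagged loci far from any planted locus.
    """
    from .pipeline import scan_pair

    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    if pair is None:
        pair = PairSpec("recovery", ne=238, t=5, snp_maf_beta=(1.0, 2.5), n_selected=1)
    from .pipeline import EVIDENCE_COLUMNS

    rng = np.random.default_rng(seed)
    marker_map, _ = gen_marker_panel(config, seed=int(rng.integers(2**31)))
    hits = 0
    fp_rates: list[float] = []
    per_test_rates: dict[str, list[float]] = {c: [] for c in EVIDENCE_COLUMNS}
    cluster_sig_fracs: list[float] = []
    for d in range(n_datasets):
        ds_seed = int(rng.integers(2**31))
        wild, reared, truth = gen_pair_dataset(config, pair, marker_map, ds_seed)
        res = scan_pair(
            wild, reared, marker_map,
            n_perm_cluster=n_perm_cluster, n_perm_fst=0, run_hwe=False,
            seed=int(rng.integers(2**31)),
        )
        flagged = res.candidate_loci(min_evidence=1)
        sel = {t["locus"] for t in truth.selected}
        near = set()
        for s_locus in sel:
            lg = marker_map.linkage_group(s_locus)
            p0 = marker_map.position(s_locus)
            near |= {
                l
                for l in wild.loci
                if marker_map.is_mapped(l)
                and marker_map.linkage_group(l) == lg
                and abs(marker_map.position(l) - p0) <= flag_window_cM
            }
        if sel and (flagged & near):
            hits += 1
        informative_far = [l for l in flagged if l not in near]
        n_far_total = max(len(wild.loci) - len(near), 1)
        fp_rates.append(len(informative_far) / n_far_total)
        far = res.evidence[~res.evidence["locus"].isin(near)]
        for col in EVIDENCE_COLUMNS:
            per_test_rates[col].append(float(far[col].mean()))
        ct = res.cluster_table
        both = pd.concat([ct["significant_fst"], ct["significant_lnrh"]])
        cluster_sig_fracs.append(float(both.mean()))
    report: dict[str, float] = {
        "n_datasets": n_datasets,
        "sensitivity": hits / n_datasets if pair.n_selected else float("nan"),
        "false_positive_rate": float(np.mean(fp_rates)),
        "cluster_pair_significant_rate": float(np.mean(cluster_sig_fracs)),
    }
    for col in EVIDENCE_COLUMNS:
        report[f"rate_{col}"] = float(np.mean(per_test_rates[col]))
    return report
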