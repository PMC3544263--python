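"""End-to-end selection scan for one wild/reared pair.

Runs the full battery on a genotype dataset plus marker map: diversity
indices, optional Hardy-Weinberg screen, per-locus and multilocus
Weir-Cockerham theta, lnRH with standardisation, the two adjacent-locus
clustering permutation tests, q-value FDR per test, and an
evidence-merging step that calls a locus a candidate when flagged by at
least two of the four tests (single-locus theta in the empirical top
2.5%, |z_lnRH| > 1.96, membership in a significant theta pair, membership
in a significant |lnRH| pair).  Externally computed outlier flags (e.g.
from coalescent-simulation tests) can be merged as extra evidence
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, multitest, sumstats
from .genodata import GenotypeMatrix, MarkerMap
from .lnrh import lnrh_pvalues, pair_lnrh_table, standardize

__all__ = ["PairScanResult", "scan_pair"]

EVIDENCE_COLUMNS = ["ev_fst_outlier", "ev_lnrh_outlier", "ev_fst_cluster", "ev_lnrh_cluster"]


@dataclass
class PairScanResult:
    """All tables produced by one pair scan."""

    pair: tuple[str, str]
    diversity: pd.DataFrame = field(repr=False)
    fst_table: pd.DataFrame = field(repr=False)
    multilocus_theta: float = float("nan")
    fst_perm_p: float = float("nan")
    lnrh_table: pd.DataFrame = field(repr=False, default=None)
    hwe_table: pd.DataFrame | None = field(repr=False, default=None)
    cluster_table: pd.DataFrame | None = field(repr=False, default=None)
    qvalue_tables: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    evidence: pd.DataFrame = field(repr=False, default=None)

    def candidate_loci(self, min_evidence: int = 2) -> set[str]:
        ev = self.evidence
        return set(ev.loc[ev["n_evidence"] >= min_evidence, "locus"])

    def candidate_regions(self, min_evidence: int = 2, marker_map: MarkerMap | None = None) -> pd.DataFrame:
        """Contiguous runs of flagged loci as cM spans per linkage group."""
        ev = self.evidence
        flagged = ev[ev["n_evidence"] >= min_evidence]
        rows = []
        for lg, sub in flagged.dropna(subset=["linkage_group"]).groupby("linkage_group"):
            sub = sub.sort_values("position_cM")
            start = prev = None
            run: list[str] = []
            all_lg = ev[ev["linkage_group"] == lg].sort_values("position_cM")["locus"].tolist()
            flags = set(sub["locus"])
            for locus in all_lg:
                if locus in flags:
                    run.append(locus)
                else:
                    if run:
                        rows.append(_region_row(lg, run, ev))
                    run = []
            if run:
                rows.append(_region_row(lg, run, ev))
        return pd.DataFrame(
            rows, columns=["linkage_group", "start_cM", "end_cM", "span_cM", "loci", "max_evidence"]
        )


def _region_row(lg: str, run: list[str], ev: pd.DataFrame) -> dict:
    sub = ev[ev["locus"].isin(run)]
    return {
        "linkage_group": lg,
        "start_cM": float(sub["position_cM"].min()),
        "end_cM": float(sub["position_cM"].max()),
        "span_cM": float(sub["position_cM"].max() - sub["position_cM"].min()),
        "loci": ",".join(run),
        "max_evidence": int(sub["n_evidence"].max()),
    }


def scan_pair(
    wild: GenotypeMatrix,
    reared: GenotypeMatrix,
    marker_map: MarkerMap,
    n_perm_cluster: int = 5000,
    n_perm_fst: int = 1000,
    run_hwe: bool = True,
    hwe_shuffles: int = 10_000,
    fst_outlier_quantile: float = 0.975,
    seed: int = 0,
    external_flags: pd.Series | None = None,
) -> PairScanResult:
    """Run the full scan on one wild/reared pair.

    ``n_perm_fst=0`` skips the global multilocus-theta permutation test;
    ``run_hwe=False`` skips the Hardy-Weinberg screen (both are
    conveniences for bulk synthetic runs).  `external_flags` is an
    optional locus-indexed boolean series of outlier calls from an
    external single-locus test, merged as an extra evidence column.
    """
    rng = np.random.default_rng(seed)
    result = PairScanResult(
        pair=(wild.name, reared.name),
        diversity=sumstats.diversity_table([wild, reared]),
        fst_table=sumstats.pair_fst_table(wild, reared),
    )
    result.multilocus_theta = sumstats.multilocus_theta(wild, reared)
    if n_perm_fst:
        _, result.fst_perm_p = sumstats.fst_permutation_test(
            wild, reared, n_perm=n_perm_fst, seed=int(rng.integers(2**31))
        )

    if run_hwe:
        rows = []
        for sample in (wild, reared):
            for locus in sample.loci:
                try:
                    p, testable = sumstats.hwe_exact_test(
                        sample, locus, n_shuffles=hwe_shuffles, seed=int(rng.integers(2**31))
                    )
                except ValueError:
                    p, testable = float("nan"), False
                rows.append(
                    {"sample": sample.name, "locus": locus, "p_hwe": p,
                     "testable": testable, "sig_1pct": testable and p < 0.01}
                )
        result.hwe_table = pd.DataFrame(rows)

    lt = lnrh_pvalues(standardize(pair_lnrh_table(wild, reared)))
    result.lnrh_table = lt

    # clustering on mapped loci informative for both statistics
    ft = result.fst_table
    theta_vals = pd.Series(ft["theta"].to_numpy(), index=ft["locus"])
    lnrh_vals = pd.Series(lt["abs_lnrh"].to_numpy(), index=lt["locus"])
    usable = [
        l
        for l in wild.loci
        if marker_map.is_mapped(l)
        and np.isfinite(theta_vals.get(l, np.nan))
        and np.isfinite(lnrh_vals.get(l, np.nan))
    ]
    pairs = clustering.build_adjacent_pairs(marker_map, usable)
    _, fscan = clustering.permutation_scan(
        pairs, theta_vals[usable], n_perm=n_perm_cluster,
        seed=int(rng.integers(2**31)), statistic_kind="fst",
    )
    _, lscan = clustering.permutation_scan(
        pairs, lnrh_vals[usable], n_perm=n_perm_cluster,
        seed=int(rng.integers(2**31)), statistic_kind="abs_lnrh",
    )
    result.cluster_table = clustering.cluster_report(fscan, lscan, theta_vals, lnrh_vals)

    # q-values per test (lnRH normal-theory P; clustering permutation P)
    for name, pvals in (
        ("lnrh", lt.loc[lt["informative"], "p"].to_numpy()),
        ("fst_cluster", fscan["p_perm"].to_numpy()),
        ("lnrh_cluster", lscan["p_perm"].to_numpy()),
    ):
        if len(pvals) >= 20:
            qr = multitest.qvalue_pipeline(pvals, seed=int(rng.integers(2**31)))
            result.qvalue_tables[name] = pd.DataFrame(
                {"p": qr.pvalues, "q": qr.qvalues, "pi0": qr.pi0}
            )

    # evidence merge
    finite_theta = theta_vals[np.isfinite(theta_vals.values)]
    theta_cut = float(finite_theta.quantile(fst_outlier_quantile))
    in_sig_fst_pair: set[str] = set()
    in_sig_lnrh_pair: set[str] = set()
    for _, row in result.cluster_table.iterrows():
        if row["significant_fst"]:
            in_sig_fst_pair |= {row["locus_a"], row["locus_b"]}
        if row["significant_lnrh"]:
            in_sig_lnrh_pair |= {row["locus_a"], row["locus_b"]}
    lnrh_out = dict(zip(lt["locus"], lt["outlier"]))
    rows = []
    for locus in wild.loci:
        th = theta_vals.get(locus, np.nan)
        flags = {
            "ev_fst_outlier": bool(np.isfinite(th) and th >= theta_cut),
            "ev_lnrh_outlier": bool(lnrh_out.get(locus, False)),
            "ev_fst_cluster": locus in in_sig_fst_pair,
            "ev_lnrh_cluster": locus in in_sig_lnrh_pair,
        }
        if external_flags is not None:
            flags["ev_external"] = bool(external_flags.get(locus, False))
        rows.append(
            {
                "locus": locus,
                "linkage_group": marker_map.linkage_group(locus) if marker_map.is_mapped(locus) else None,
                "position_cM": marker_map.position(locus) if marker_map.is_mapped(locus) else np.nan,
                "theta": th,
                **flags,
                "n_evidence": sum(flags.values()),
            }
        )
    result.evidence = pd.DataFrame(rows)
    return result
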