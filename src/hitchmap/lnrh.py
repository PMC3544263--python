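"""The lnRH heterozygosity-ratio statistic for paired population scans.

For a locus typed in two populations with expected heterozygosities H1 and
H2, the statistic is

    lnRH = ln( [(1/(1-H1))^2 - 1] / [(1/(1-H2))^2 - 1] )

which is approximately normally distributed across neutral loci, so that
after standardisation within a population pair, |z| > 1.96 flags the 5%
most extreme loci.  Because short-term directional selection can either
inflate or deplete diversity at a hitchhiking locus depending on the
starting frequency of the favoured allele, the absolute value |lnRH| is
used downstream as the clustering statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genodata import GenotypeMatrix, allele_frequencies
from .sumstats import gene_diversity

__all__ = ["LNRH_Z_CRIT", "lnrh", "pair_lnrh_table", "standardize", "lnrh_pvalues"]

#: two-sided 5% standard-normal critical value used for the outlier flag
LNRH_Z_CRIT = 1.96


def _transform(h: float) -> float:
    if not 0.0 <= h < 1.0:
        raise ValueError(f"heterozygosity {h} outside [0, 1)")
    return (1.0 / (1.0 - h)) ** 2 - 1.0


def lnrh(h1: float, h2: float) -> float:
    """lnRH for heterozygosities ``h1``, ``h2`` in [0, 1).

    Positive when population 1 is the more diverse; antisymmetric under
    swapping the populations.  Zero diversity in either population makes
    the ratio degenerate — apply the monomorphic-locus correction first.
    """
    t1, t2 = _transform(h1), _transform(h2)
    if t1 == 0.0 or t2 == 0.0:
        raise ValueError("lnRH undefined at zero heterozygosity; correct H upstream")
    return float(np.log(t1 / t2))


def _corrected_diversity(sample: GenotypeMatrix, locus: str) -> tuple[float, int]:
    """Unbiased gene diversity with the single-novel-allele correction.

    A locus monomorphic in this sample (H = 0) gets one copy of a novel
    allele added to its gene-copy pool before recomputing H, which yields
    H = 2/(n+1) and keeps lnRH finite.  Returns ``(H, n_copies)``.
    """
    fr = allele_frequencies(sample, locus)
    if fr.n < 2:
        return float("nan"), fr.n
    if fr.n_alleles >= 2:
        return gene_diversity(fr), fr.n
    counts = np.append(fr.counts, 1)
    n = fr.n + 1
    return gene_diversity(counts / n, n), fr.n


def pair_lnrh_table(wild: GenotypeMatrix, reared: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus lnRH records for one wild/reared pair.

    Loci monomorphic in exactly one sample get the novel-allele correction
    in that sample; loci monomorphic in both (or untyped in either) are
    marked uninformative and excluded from standardisation.
    """
    if wild.loci != reared.loci:
        raise ValueError("samples do not share a locus list")
    rows = []
    for locus in wild.loci:
        fw = allele_frequencies(wild, locus)
        fr = allele_frequencies(reared, locus)
        mono_w = fw.n_alleles <= 1
        mono_r = fr.n_alleles <= 1
        informative = fw.n >= 2 and fr.n >= 2 and not (mono_w and mono_r)
        if informative:
            hw, _ = _corrected_diversity(wild, locus)
            hr, _ = _corrected_diversity(reared, locus)
            val = lnrh(hw, hr)
        else:
            hw = hr = val = float("nan")
        rows.append(
            {
                "locus": locus,
                "H_wild": hw,
                "H_reared": hr,
                "lnrh": val,
                "abs_lnrh": abs(val) if informative else float("nan"),
                "informative": informative,
            }
        )
    return pd.DataFrame(rows)


def standardize(records: pd.DataFrame) -> pd.DataFrame:
    """Add standardised lnRH (column ``z``) and the |z| > 1.96 outlier flag.

    Standardisation pools all informative loci of the pair (SNPs and
    microsatellites on one axis).  Requires >= 10 informative loci and a
    nonzero spread.
    """
    out = records.copy()
    vals = out.loc[out["informative"], "lnrh"]
    if len(vals) < 10:
        raise ValueError(f"only {len(vals)} informative loci; need >= 10 to standardise")
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("lnRH spread is zero; cannot standardise")
    out["z"] = (out["lnrh"] - vals.mean()) / sd
    out["outlier"] = out["z"].abs() > LNRH_Z_CRIT
    out.loc[~out["informative"], "outlier"] = False
    return out


def lnrh_pvalues(records: pd.DataFrame) -> pd.DataFrame:
    """Two-sided normal-theory P-values, p = 2 * Phi(-|z|)."""
    if "z" not in records.columns:
        raise ValueError("records must be standardised first")
    out = records.copy()
    out["p"] = 2.0 * norm.sf(out["z"].abs())
    return out
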