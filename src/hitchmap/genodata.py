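"""Genotype and marker-map data model with Genepop-format I/O.

Diploid multilocus genotypes for named population samples are held as
integer allele-code arrays; a marker map assigns loci to linkage groups
with centimorgan positions on the female map.  Genepop text files (the
lingua franca of microsatellite/SNP population genetics) are the on-disk
genotype format; the marker map is a tab-separated table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "MarkerMap",
    "AlleleFreqs",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_marker_map",
    "write_marker_map",
    "allele_frequencies",
    "classify_loci",
]

#: allele code reserved for missing data (Genepop "00"/"000" convention)
MISSING = 0


class GenepopParseError(ValueError):
    """Raised when a Genepop file violates the dialect this parser accepts."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes of one population sample.

    Parameters
    ----------
    name
        Population sample label.
    individuals
        Identifiers, one per row of ``calls``.
    loci
        Locus labels, one per column of ``calls``.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele
        codes are positive integers, and a call containing the code 0 is
        wholly missing (both gene copies dropped).
    """

    name: str
    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci x 2"
            )
        if len(self.individuals) < 1:
            raise ValueError("a population sample needs at least one individual")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be nonnegative (0 = missing)")
        # a half-missing call is not representable in Genepop: zero both copies
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in sample {self.name!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)`` mask, True where the call is missing."""
        return (self.calls == MISSING).any(axis=2)

    def subset_individuals(self, rows: np.ndarray, name: str | None = None) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            name=name or self.name,
            individuals=[self.individuals[i] for i in rows],
            loci=list(self.loci),
            calls=self.calls[rows].copy(),
        )


@dataclass
class AlleleFreqs:
    """Allele counts and frequencies at one locus in one sample.

    ``n`` is the number of non-missing gene copies (2 x typed individuals);
    frequencies sum to 1 whenever ``n > 0``.
    """

    alleles: np.ndarray
    counts: np.ndarray
    n: int

    @property
    def freqs(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"allele": self.alleles, "count": self.counts, "frequency": self.freqs}
        )


def allele_frequencies(sample: GenotypeMatrix, locus: str) -> AlleleFreqs:
    """Tally allele codes at `locus`, excluding missing calls."""
    j = sample.locus_index(locus)
    col = sample.calls[:, j, :]
    copies = col[(col != MISSING).all(axis=1)].ravel()
    if copies.size == 0:
        return AlleleFreqs(alleles=np.array([], dtype=int), counts=np.array([], dtype=int), n=0)
    alleles, counts = np.unique(copies, return_counts=True)
    return AlleleFreqs(alleles=alleles, counts=counts, n=int(copies.size))


def classify_loci(samples: list[GenotypeMatrix]) -> dict[str, str]:
    """Classify each locus as ``biallelic_snp`` (<= 2 alleles dataset-wide)
    or ``multiallelic_msat`` from the pooled observed allele codes."""
    if not samples:
        return {}
    loci = samples[0].loci
    kinds: dict[str, str] = {}
    stacked = np.concatenate([s.calls for s in samples], axis=0)
    for j, locus in enumerate(loci):
        col = stacked[:, j, :]
        copies = col[(col != MISSING).all(axis=1)].ravel()
        n_all = len(np.unique(copies)) if copies.size else 0
        kinds[locus] = "biallelic_snp" if n_all <= 2 else "multiallelic_msat"
    return kinds


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path) -> list[GenotypeMatrix]:
    """Parse a Genepop text file into one :class:`GenotypeMatrix` per population.

    Accepts 2- or 3-digit per-allele codes, auto-detected from the width of
    the first genotype field; ``00``/``000`` codes mark missing calls.  Locus
    names may be one per line or comma-separated on a single line.
    Populations are returned in file order, named ``pop1`` .. ``popN``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError(f"{path}: too short to be a Genepop file")

    # line 0 is the title; locus names run until the first POP separator
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError(f"{path}: no POP separator found")
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first POP")

    digits: int | None = None
    pops: list[GenotypeMatrix] = []
    cur_ids: list[str] = []
    cur_rows: list[np.ndarray] = []

    def flush() -> None:
        nonlocal cur_ids, cur_rows
        if not cur_ids:
            raise GenepopParseError(f"{path}: empty population block")
        calls = np.stack(cur_rows, axis=0)
        pops.append(
            GenotypeMatrix(
                name=f"pop{len(pops) + 1}",
                individuals=cur_ids,
                loci=list(loci),
                calls=calls,
            )
        )
        cur_ids, cur_rows = [], []

    started = False
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            if started:
                flush()
            started = True
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenepopParseError(
                f"{path}:{lineno + 1}: individual line lacks the ',' separator"
            )
        ident, _, geno = line.partition(",")
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"{path}:{lineno + 1}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        row = np.empty((len(loci), 2), dtype=np.int32)
        for j, f in enumerate(fields):
            if digits is None:
                if len(f) == 4:
                    digits = 2
                elif len(f) == 6:
                    digits = 3
                else:
                    raise GenepopParseError(
                        f"{path}:{lineno + 1}: genotype field {f!r} is neither "
                        "4 (2-digit) nor 6 (3-digit) characters wide"
                    )
            if len(f) != 2 * digits or not f.isdigit():
                raise GenepopParseError(
                    f"{path}:{lineno + 1}: malformed genotype field {f!r} "
                    f"(expected {2 * digits} digits)"
                )
            row[j, 0] = int(f[:digits])
            row[j, 1] = int(f[digits:])
        cur_ids.append(ident.strip())
        cur_rows.append(row)
    if started:
        flush()
    if not pops:
        raise GenepopParseError(f"{path}: no populations parsed")
    return pops


def write_genepop(
    dataset: list[GenotypeMatrix],
    path: str | Path,
    digits: int = 2,
    title: str = "hitchmap dataset",
) -> None:
    """Write population samples to a Genepop file re-readable by
    :func:`read_genepop`; byte-identical on repeated writes."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if not dataset:
        raise ValueError("empty dataset")
    loci = dataset[0].loci
    for s in dataset:
        if s.loci != loci:
            raise ValueError("all samples must share one locus list")
        if s.calls.max(initial=0) >= 10**digits:
            raise ValueError(
                f"allele code {s.calls.max()} does not fit in {digits} digits"
            )
    out: list[str] = [title]
    out.extend(loci)
    for s in dataset:
        out.append("POP")
        for i, ident in enumerate(s.individuals):
            geno = " ".join(
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in s.calls[i]
            )
            out.append(f"{ident} , {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-locus linkage-group assignment and map positions (cM).

    The female-map position is the canonical coordinate; male positions and
    chromosome labels are stored when present but unused by default.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("locus", "linkage_group", "position_female_cM", "position_male_cM", "chromosome")

    def __post_init__(self) -> None:
        t = self.table
        for col in ("locus", "linkage_group", "position_female_cM"):
            if col not in t.columns:
                raise ValueError(f"marker map missing column {col!r}")
        if "position_male_cM" not in t.columns:
            t["position_male_cM"] = np.nan
        if "chromosome" not in t.columns:
            t["chromosome"] = None
        if t["locus"].duplicated().any():
            dup = t.loc[t["locus"].duplicated(), "locus"].iloc[0]
            raise ValueError(f"duplicate locus in marker map: {dup!r}")
        if (t["position_female_cM"] < 0).any():
            raise ValueError("negative map position")
        self.table = t.reset_index(drop=True)
        self._pos = dict(zip(t["locus"], t["position_female_cM"]))
        self._lg = dict(zip(t["locus"], t["linkage_group"]))

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, locus: str) -> bool:
        return locus in self._pos

    def is_mapped(self, locus: str) -> bool:
        return locus in self._pos

    def position(self, locus: str) -> float:
        return float(self._pos[locus])

    def linkage_group(self, locus: str) -> str:
        return self._lg[locus]

    def unmapped(self, loci: list[str]) -> list[str]:
        """Loci present in a genotype dataset but absent from the map
        (retained for single-locus tests, excluded from clustering and
        simulation)."""
        return [l for l in loci if l not in self._pos]

    def ordered_loci(self, loci: list[str] | None = None) -> pd.DataFrame:
        """Mapped loci sorted by (linkage group, female cM); ties keep map
        input order.  Restricted to `loci` if given."""
        t = self.table
        if loci is not None:
            keep = set(loci)
            t = t[t["locus"].isin(keep)]
        t = t.reset_index(drop=True)
        # mergesort = stable: equal-cM markers keep their input order
        return t.sort_values(
            ["linkage_group", "position_female_cM"], kind="mergesort"
        ).reset_index(drop=True)


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a tab-separated marker map.

    Columns (header optional): locus, linkage_group, position_female_cM
    [, position_male_cM [, chromosome]].
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].split("\t")
    has_header = False
    if len(first) >= 3:
        try:
            float(first[2])
        except ValueError:
            has_header = True
    raw = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype=str)
    if not has_header:
        names = list(MarkerMap.COLUMNS[: raw.shape[1]])
        raw.columns = names
    raw.columns = [str(c) for c in raw.columns]
    t = pd.DataFrame(
        {
            "locus": raw["locus"].astype(str),
            "linkage_group": raw["linkage_group"].astype(str),
            "position_female_cM": pd.to_numeric(raw["position_female_cM"]),
        }
    )
    if "position_male_cM" in raw.columns:
        t["position_male_cM"] = pd.to_numeric(raw["position_male_cM"], errors="coerce")
    if "chromosome" in raw.columns:
        t["chromosome"] = raw["chromosome"]
    return MarkerMap(t)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    cols = ["locus", "linkage_group", "position_female_cM", "position_male_cM", "chromosome"]
    marker_map.table[cols].to_csv(path, sep="\t", index=False)
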