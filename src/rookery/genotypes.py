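"""Core containers for microhaplotype genotype and read-depth data.

A microhaplotype locus is a short amplicon treated as a single multiallelic
marker whose alleles are phased haplotype strings.  Genotypes are unordered
diploid calls; internally every call is a pair of allele *indices* into the
locus's allele list, sorted so that ``codes[..., 0] <= codes[..., 1]``.
Missing calls are encoded as ``(-1, -1)``.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
MISSING_TOKEN = "./."


def _as_sorted_codes(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int16)
    if codes.ndim != 3 or codes.shape[2] != 2:
        raise ValueError("codes must have shape (n_individuals, n_loci, 2)")
    codes = np.sort(codes, axis=2)
    # half-missing calls are treated as fully missing
    half = (codes[..., 0] == MISSING) & (codes[..., 1] != MISSING)
    codes[half] = MISSING
    return codes


class GenotypeTable:
    """Individual x locus table of unordered diploid microhaplotype calls."""

    def __init__(
        self,
        codes: np.ndarray,
        individuals: Sequence[str],
        loci: Sequence[str],
        alleles: Mapping[str, Sequence[str]],
    ):
        self.codes = _as_sorted_codes(codes)
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.alleles = {l: list(alleles[l]) for l in self.loci}
        if self.codes.shape[0] != len(self.individuals):
            raise ValueError("codes rows do not match individuals")
        if self.codes.shape[1] != len(self.loci):
            raise ValueError("codes columns do not match loci")
        for j, locus in enumerate(self.loci):
            top = self.codes[:, j, 1].max(initial=MISSING)
            if top >= len(self.alleles[locus]):
                raise ValueError(f"allele index out of range at locus {locus}")
        self._ind_index = {s: i for i, s in enumerate(self.individuals)}
        self._locus_index = {s: j for j, s in enumerate(self.loci)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def ind_idx(self, name: str) -> int:
        return self._ind_index[name]

    def locus_idx(self, name: str) -> int:
        return self._locus_index[name]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return self.codes[..., 0] == MISSING

    def het_mask(self) -> np.ndarray:
        ok = ~self.missing_mask()
        return ok & (self.codes[..., 0] != self.codes[..., 1])

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.codes.copy(), self.individuals, self.loci, self.alleles)

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.alleles == other.alleles
            and np.array_equal(self.codes, other.codes)
        )

    # -- subsetting ----------------------------------------------------------
    def subset(
        self,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeTable":
        inds = self.individuals if individuals is None else list(individuals)
        locs = self.loci if loci is None else list(loci)
        rows = [self._ind_index[s] for s in inds]
        cols = [self._locus_index[s] for s in locs]
        codes = self.codes[np.ix_(rows, cols)]
        return GenotypeTable(codes, inds, locs, {l: self.alleles[l] for l in locs})

    # -- summaries -----------------------------------------------------------
    def allele_freqs(self, individuals: Iterable[str] | None = None) -> dict[str, np.ndarray]:
        """Sample allele frequencies per locus from non-missing calls.

        Loci with no non-missing calls get a uniform vector (flagged use
        upstream should avoid them).
        """
        if individuals is None:
            codes = self.codes
        else:
            rows = [self._ind_index[s] for s in individuals]
            codes = self.codes[rows]
        out: dict[str, np.ndarray] = {}
        for j, locus in enumerate(self.loci):
            k = len(self.alleles[locus])
            calls = codes[:, j, :].ravel()
            calls = calls[calls >= 0]
            if calls.size == 0:
                out[locus] = np.full(k, 1.0 / k)
            else:
                out[locus] = np.bincount(calls, minlength=k) / calls.size
        return out

    def missingness_by_locus(self) -> pd.Series:
        return pd.Series(self.missing_mask().mean(axis=0), index=self.loci)

    def missingness_by_individual(self) -> pd.Series:
        return pd.Series(self.missing_mask().mean(axis=1), index=self.individuals)

    # -- text I/O ------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for j, locus in enumerate(self.loci):
            labels = self.alleles[locus]
            col = []
            for i in range(self.n_individuals):
                a, b = self.codes[i, j]
                col.append(MISSING_TOKEN if a == MISSING else f"{labels[a]}/{labels[b]}")
            data[locus] = col
        return pd.DataFrame(data, index=pd.Index(self.individuals, name="individual"))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, alleles: Mapping[str, Sequence[str]] | None = None
    ) -> "GenotypeTable":
        loci = list(df.columns)
        individuals = [str(s) for s in df.index]
        if alleles is None:
            alleles = {}
            for locus in loci:
                seen: set[str] = set()
                for v in df[locus]:
                    if isinstance(v, str) and v != MISSING_TOKEN and "/" in v:
                        seen.update(v.split("/"))
                alleles[locus] = sorted(seen)
        codes = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int16)
        for j, locus in enumerate(loci):
            lookup = {lab: idx for idx, lab in enumerate(alleles[locus])}
            for i, v in enumerate(df[locus]):
                if not isinstance(v, str) or v == MISSING_TOKEN or "/" not in v:
                    continue
                a, b = v.split("/")
                codes[i, j] = (lookup[a], lookup[b])
        return cls(codes, individuals, loci, alleles)

    @classmethod
    def read_tsv(cls, path, alleles: Mapping[str, Sequence[str]] | None = None) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls.from_dataframe(df, alleles)


class DepthTable:
    """Per (individual, locus, allele) read counts for an amplicon panel.

    Stored densely as an int32 array of shape (n_individuals, n_loci, max_k)
    where ``max_k`` is the largest allele count in the panel; slots beyond a
    locus's allele count are zero by construction.
    """

    def __init__(
        self,
        counts: np.ndarray,
        individuals: Sequence[str],
        loci: Sequence[str],
        alleles: Mapping[str, Sequence[str]],
    ):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 3:
            raise ValueError("counts must have shape (n_individuals, n_loci, max_alleles)")
        if (counts < 0).any():
            raise ValueError("read counts must be non-negative")
        self.counts = counts
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.alleles = {l: list(alleles[l]) for l in self.loci}
        self._ind_index = {s: i for i, s in enumerate(self.individuals)}
        self._locus_index = {s: j for j, s in enumerate(self.loci)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def total_per_individual(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=(1, 2)), index=self.individuals)

    def subset_individuals(self, individuals: Iterable[str]) -> "DepthTable":
        inds = list(individuals)
        rows = [self._ind_index[s] for s in inds]
        return DepthTable(self.counts[rows], inds, self.loci, self.alleles)

    def to_long(self) -> pd.DataFrame:
        recs = []
        for j, locus in enumerate(self.loci):
            labels = self.alleles[locus]
            sub = self.counts[:, j, : len(labels)]
            ii, aa = np.nonzero(sub)
            for i, a in zip(ii, aa):
                recs.append((self.individuals[i], locus, labels[a], int(sub[i, a])))
        return pd.DataFrame(recs, columns=["individual", "locus", "allele", "count"])

    def write_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
        alleles: Mapping[str, Sequence[str]] | None = None,
    ) -> "DepthTable":
        if individuals is None:
            individuals = list(pd.unique(df["individual"]))
        if loci is None:
            loci = list(pd.unique(df["locus"]))
        if alleles is None:
            alleles = {
                locus: sorted(df.loc[df["locus"] == locus, "allele"].unique())
                for locus in loci
            }
        max_k = max((len(v) for v in alleles.values()), default=1)
        counts = np.zeros((len(individuals), len(loci), max_k), dtype=np.int64)
        ind_idx = {s: i for i, s in enumerate(individuals)}
        loc_idx = {s: j for j, s in enumerate(loci)}
        al_idx = {l: {a: k for k, a in enumerate(alleles[l])} for l in loci}
        for row in df.itertuples(index=False):
            counts[ind_idx[row.individual], loc_idx[row.locus], al_idx[row.locus][row.allele]] += int(
                row.count
            )
        return cls(counts, individuals, loci, alleles)

    @classmethod
    def read_csv(cls, path, **kw) -> "DepthTable":
        return cls.from_long(pd.read_csv(path), **kw)
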