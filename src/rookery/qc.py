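"""Microhaplotype genotype quality control.

Implements the amplicon QC cascade for multi-caller microhaplotype data:
per-sample read-depth screening, replicate-mismatch and caller-consensus
locus filters, minor-allele-frequency and iterative missingness filters,
depth-ratio genotype calling with ambiguity and contamination handling,
and a final replicate-consistency filter.  Boundary conventions follow
the source thresholds exactly: loci are *removed* when the replicate
mismatch rate exceeds 7% or the caller mismatch rate exceeds 5.5%
(strictly greater), when all minor alleles sit strictly below MAF 0.01,
and *retained* at a replicate consistency of at least 93%; samples with
at least 10 000 reads are retained.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, DepthTable, GenotypeTable

logger = logging.getLogger(__name__)


class FilterReport:
    """Ordered record of (rule, threshold, removed, retained) per stage."""

    def __init__(self):
        self.rows: list[dict] = []

    def add(self, rule: str, threshold, n_in: int, n_removed: int, axis: str = "loci"):
        if n_removed < 0 or n_removed > n_in:
            raise ValueError("removed count out of range")
        self.rows.append(
            {
                "rule": rule,
                "axis": axis,
                "threshold": threshold,
                "input": n_in,
                "removed": n_removed,
                "retained": n_in - n_removed,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample-level depth screen
# ---------------------------------------------------------------------------

def sample_depth_filter(
    depths: DepthTable, min_total: int = 10_000, report: FilterReport | None = None
) -> list[str]:
    """Retain individuals whose summed read count is at least ``min_total``."""
    totals = depths.total_per_individual()
    if totals.empty:
        logger.warning("sample_depth_filter: empty depth table")
        retained: list[str] = []
    else:
        retained = list(totals.index[totals >= min_total])
    if report is not None:
        report.add("sample_depth", min_total, len(totals), len(totals) - len(retained), "individuals")
    return retained


# ---------------------------------------------------------------------------
# replicate-based locus filters
# ---------------------------------------------------------------------------

def replicate_mismatch_rates(
    calls: GenotypeTable, replicate_pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-locus replicate mismatch rate.

    A mismatch is an unordered genotype inequality between the two members
    of a replicate pair; pairs with any missing call at a locus do not
    enter the denominator.  Loci with zero informative pairs are flagged
    ``untested``.
    """
    if not replicate_pairs:
        raise ValueError("need at least one replicate pair")
    rows_a = [calls.ind_idx(a) for a, _ in replicate_pairs]
    rows_b = [calls.ind_idx(b) for _, b in replicate_pairs]
    ga, gb = calls.codes[rows_a], calls.codes[rows_b]
    informative = (ga[..., 0] >= 0) & (gb[..., 0] >= 0)
    mismatch = informative & ~np.all(ga == gb, axis=-1)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore"):
        rate = np.where(n_inf > 0, mismatch.sum(axis=0) / np.maximum(n_inf, 1), 0.0)
    return pd.DataFrame(
        {"locus": calls.loci, "mismatch_rate": rate, "n_pairs": n_inf, "untested": n_inf == 0}
    ).set_index("locus")


def replicate_mismatch_filter(
    calls: GenotypeTable,
    replicate_pairs: Sequence[tuple[str, str]],
    max_rate: float = 0.07,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop loci whose replicate mismatch rate strictly exceeds ``max_rate``."""
    rates = replicate_mismatch_rates(calls, replicate_pairs)
    keep = rates.index[(rates["mismatch_rate"] <= max_rate + 1e-12) | rates["untested"]]
    if report is not None:
        report.add("replicate_mismatch", max_rate, calls.n_loci, calls.n_loci - len(keep))
    return list(keep), rates


def final_consistency_filter(
    calls: GenotypeTable,
    replicate_pairs: Sequence[tuple[str, str]],
    min_consistency: float = 0.93,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Retain loci whose replicate agreement is at least ``min_consistency``."""
    if not replicate_pairs:
        logger.warning("final_consistency_filter: no replicates; all loci retained")
        if report is not None:
            report.add("final_consistency", min_consistency, calls.n_loci, 0)
        return list(calls.loci), pd.DataFrame()
    rates = replicate_mismatch_rates(calls, replicate_pairs)
    consistency = 1.0 - rates["mismatch_rate"]
    keep = rates.index[(consistency >= min_consistency - 1e-12) | rates["untested"]]
    if report is not None:
        report.add("final_consistency", min_consistency, calls.n_loci, calls.n_loci - len(keep))
    return list(keep), rates.assign(consistency=consistency)


# ---------------------------------------------------------------------------
# multi-caller consensus
# ---------------------------------------------------------------------------

def caller_consensus(
    callsets: Sequence[GenotypeTable],
    min_callers: int = 2,
    max_caller_mismatch: float = 0.055,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Locus retention by multi-caller agreement.

    A locus is retained iff called by at least ``min_callers`` callers and
    its allele-call mismatch fraction, pooled over caller pairs and over
    individuals with non-missing calls in both members, does not exceed
    ``max_caller_mismatch``.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    universe = set(callsets[0].individuals)
    for cs in callsets[1:]:
        if not universe & set(cs.individuals):
            raise ValueError("callsets have disjoint individuals")
    all_loci = sorted({l for cs in callsets for l in cs.loci}, key=lambda l: min(
        cs.loci.index(l) for cs in callsets if l in cs.loci
    ))
    rows = []
    for locus in all_loci:
        present = [cs for cs in callsets if locus in cs.loci]
        mism = comp = 0
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                shared = [s for s in a.individuals if s in b._ind_index]
                ra = [a.ind_idx(s) for s in shared]
                rb = [b.ind_idx(s) for s in shared]
                ga = a.codes[ra, a.locus_idx(locus)]
                gb = b.codes[rb, b.locus_idx(locus)]
                ok = (ga[:, 0] >= 0) & (gb[:, 0] >= 0)
                comp += int(ok.sum())
                mism += int((ok & ~np.all(ga == gb, axis=-1)).sum())
        rate = mism / comp if comp else 0.0
        rows.append(
            {
                "locus": locus,
                "n_callers": len(present),
                "mismatch_rate": rate,
                "retained": len(present) >= min_callers and rate <= max_caller_mismatch + 1e-12,
            }
        )
    df = pd.DataFrame(rows).set_index("locus")
    keep = list(df.index[df["retained"]])
    if report is not None:
        report.add("caller_consensus", (min_callers, max_caller_mismatch), len(df), len(df) - len(keep))
    return keep, df


# ---------------------------------------------------------------------------
# frequency and missingness filters
# ---------------------------------------------------------------------------

def maf_filter(
    table: GenotypeTable,
    min_maf: float = 0.01,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop loci whose minor alleles all fall strictly below ``min_maf``.

    Frequencies come from non-missing calls.  Monomorphic loci are removed
    with reason ``monomorphic``; a locus with its strongest minor allele at
    exactly ``min_maf`` is retained (the rule is "less than").
    """
    freqs = table.allele_freqs()
    rows = []
    for locus in table.loci:
        p = freqs[locus]
        minor = np.sort(p)[:-1]  # all but the major allele
        if minor.size == 0 or minor.max() == 0.0:
            rows.append({"locus": locus, "max_minor_freq": 0.0, "retained": False, "reason": "monomorphic"})
        elif minor.max() < min_maf - 1e-12:
            rows.append({"locus": locus, "max_minor_freq": minor.max(), "retained": False, "reason": "maf"})
        else:
            rows.append({"locus": locus, "max_minor_freq": minor.max(), "retained": True, "reason": ""})
    df = pd.DataFrame(rows).set_index("locus")
    keep = list(df.index[df["retained"]])
    if report is not None:
        report.add("maf", min_maf, table.n_loci, table.n_loci - len(keep))
    return keep, df


class TableEmptiedError(RuntimeError):
    def __init__(self, level: float):
        super().__init__(f"missingness filter emptied the table at allowance {level:.2f}")
        self.level = level


def iterative_missingness_filter(
    table: GenotypeTable,
    start: float = 0.80,
    end: float = 0.30,
    step: float = 0.10,
    report: FilterReport | None = None,
) -> GenotypeTable:
    """Tighten missingness allowances from ``start`` down to ``end``.

    At each allowance level, loci exceeding the level are dropped first,
    then individuals, before the level tightens by ``step``.  The final
    table satisfies the ``end`` allowance on both axes.
    """
    if start < end:
        raise ValueError("start must be >= end")
    levels = list(np.arange(start, end - 1e-9, -step))
    if not levels or abs(levels[-1] - end) > 1e-9:
        levels.append(end)
    out = table
    for level in levels:
        for _ in range(2):  # second pass at the same level reaches a fixed point
            keep_loci = [l for l, frac in out.missingness_by_locus().items() if frac <= level + 1e-12]
            if not keep_loci:
                raise TableEmptiedError(level)
            if keep_loci != out.loci:
                out = out.subset(loci=keep_loci)
            keep_ind = [
                s for s, frac in out.missingness_by_individual().items() if frac <= level + 1e-12
            ]
            if not keep_ind:
                raise TableEmptiedError(level)
            if keep_ind != out.individuals:
                out = out.subset(individuals=keep_ind)
    if report is not None:
        report.add("missingness_loci", (start, end), table.n_loci, table.n_loci - out.n_loci)
        report.add(
            "missingness_individuals",
            (start, end),
            table.n_individuals,
            table.n_individuals - out.n_individuals,
            "individuals",
        )
    return out


# ---------------------------------------------------------------------------
# depth-ratio genotype calling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CallFlags:
    ambiguous: np.ndarray  # (n, m) ratio between hom_max and het_min
    contaminated: np.ndarray  # (n, m) third allele above the het_min relative floor
    low_depth: np.ndarray  # (n, m) total below min_depth


def call_from_depths(
    depths: DepthTable,
    min_depth: int = 12,
    hom_max: float = 0.09,
    het_min: float = 0.20,
    ratio_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[GenotypeTable, CallFlags]:
    """Genotypes from per-allele read depths.

    Per (individual, locus) alleles are ranked by depth and the allelic
    ratio is second/first.  Calls with total depth below ``min_depth`` are
    missing; ratio >= ``het_min`` is a heterozygote of the top two alleles;
    ratio <= ``hom_max`` a homozygote of the top; anything between is
    ambiguous and set missing (flagged).  A third allele reaching
    ``het_min`` times the top depth raises the contamination flag.
    Per-locus (hom_max, het_min) overrides refine the global defaults.
    """
    counts = depths.counts
    n, m, _ = counts.shape
    order = np.argsort(counts, axis=2)
    top_i = order[..., -1]
    second_i = order[..., -2]
    third_i = order[..., -3] if counts.shape[2] >= 3 else None
    take = np.take_along_axis
    top = take(counts, top_i[..., None], axis=2)[..., 0]
    second = take(counts, second_i[..., None], axis=2)[..., 0]
    third = take(counts, third_i[..., None], axis=2)[..., 0] if third_i is not None else np.zeros_like(top)
    total = counts.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(top > 0, second / np.maximum(top, 1), 0.0)
        third_ratio = np.where(top > 0, third / np.maximum(top, 1), 0.0)

    hom_max_v = np.full(m, hom_max)
    het_min_v = np.full(m, het_min)
    for locus, (h, t) in (ratio_overrides or {}).items():
        j = depths._locus_index[locus]
        hom_max_v[j], het_min_v[j] = h, t

    low = total < min_depth
    is_het = (~low) & (ratio >= het_min_v[None, :])
    is_hom = (~low) & (ratio <= hom_max_v[None, :])
    ambiguous = (~low) & ~is_het & ~is_hom
    contaminated = (~low) & (third_ratio >= het_min_v[None, :])

    codes = np.full((n, m, 2), MISSING, dtype=np.int16)
    ii, jj = np.nonzero(is_hom)
    codes[ii, jj, 0] = top_i[ii, jj]
    codes[ii, jj, 1] = top_i[ii, jj]
    ii, jj = np.nonzero(is_het)
    codes[ii, jj, 0] = top_i[ii, jj]
    codes[ii, jj, 1] = second_i[ii, jj]
    table = GenotypeTable(codes, depths.individuals, depths.loci, depths.alleles)
    return table, CallFlags(ambiguous, contaminated, low)


def locus_ratio_acceptability(
    flags: CallFlags,
    loci: Sequence[str],
    min_fraction: float = 0.7,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.Series]:
    """Retain loci where the fraction of depth-adequate calls with an
    acceptable allelic ratio is at least ``min_fraction``."""
    assessed = ~flags.low_depth
    acceptable = assessed & ~flags.ambiguous
    with np.errstate(invalid="ignore"):
        frac = np.where(assessed.sum(0) > 0, acceptable.sum(0) / np.maximum(assessed.sum(0), 1), 1.0)
    frac = pd.Series(frac, index=list(loci))
    keep = list(frac.index[frac >= min_fraction - 1e-12])
    if report is not None:
        report.add("ratio_acceptability", min_fraction, len(loci), len(loci) - len(keep))
    return keep, frac


def contamination_rule(
    depths: DepthTable,
    calls: GenotypeTable,
    flags: CallFlags,
    relative_floor: float = 0.20,
    locus_removal_fraction: float = 0.05,
    report: FilterReport | None = None,
) -> tuple[GenotypeTable, list[str]]:
    """Apply the >2-haplotype contamination policy.

    Calls whose extra alleles all sit below ``relative_floor`` times the
    top depth keep their top-two genotype (the noise alleles are masked,
    which the ranking call already achieves); calls with a third allele at
    or above the floor are set missing.  Loci where more than
    ``locus_removal_fraction`` of individuals are affected are removed.
    """
    counts = depths.counts
    if counts.shape[2] >= 3:
        ranked = np.sort(counts, axis=2)
        top = ranked[..., -1]
        third = ranked[..., -3]
        with np.errstate(invalid="ignore"):
            affected = (top > 0) & (third / np.maximum(top, 1) >= relative_floor) & ~flags.low_depth
    else:
        affected = np.zeros(flags.low_depth.shape, dtype=bool)
    codes = calls.codes.copy()
    codes[affected] = MISSING
    cleaned = GenotypeTable(codes, calls.individuals, calls.loci, calls.alleles)
    frac = affected.mean(axis=0)
    keep = [l for l, f in zip(calls.loci, frac) if f <= locus_removal_fraction]
    if report is not None:
        report.add("contamination", (relative_floor, locus_removal_fraction), calls.n_loci, calls.n_loci - len(keep))
    return cleaned.subset(loci=keep), keep


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QCResult:
    table: GenotypeTable
    report: FilterReport
    replicate_rates: pd.DataFrame | None = None
    caller_rates: pd.DataFrame | None = None


def run_qc(
    depths: DepthTable,
    caller_views: Sequence[GenotypeTable],
    replicate_pairs: Sequence[tuple[str, str]],
    min_total_reads: int = 10_000,
    min_depth: int = 12,
    hom_max: float = 0.09,
    het_min: float = 0.20,
    min_ratio_fraction: float = 0.7,
    min_callers: int = 2,
    max_caller_mismatch: float = 0.055,
    max_replicate_mismatch: float = 0.07,
    min_maf: float = 0.01,
    missing_start: float = 0.80,
    missing_end: float = 0.30,
    min_consistency: float = 0.93,
    contamination_floor: float = 0.20,
    contamination_locus_fraction: float = 0.05,
) -> QCResult:
    """The full QC cascade, each stage shrinking (never growing) the data."""
    report = FilterReport()
    keep_ind = sample_depth_filter(depths, min_total_reads, report)
    depths = depths.subset_individuals(keep_ind)

    calls, flags = call_from_depths(depths, min_depth, hom_max, het_min)
    calls, keep = contamination_rule(
        depths, calls, flags, contamination_floor, contamination_locus_fraction, report
    )
    col_keep = [depths.loci.index(l) for l in keep]
    sub_flags = CallFlags(
        flags.ambiguous[:, col_keep], flags.contaminated[:, col_keep], flags.low_depth[:, col_keep]
    )
    keep, _ = locus_ratio_acceptability(sub_flags, calls.loci, min_ratio_fraction, report)
    calls = calls.subset(loci=keep)

    views = [cs.subset(individuals=[s for s in cs.individuals if s in set(calls.individuals)])
             for cs in caller_views]
    keep, caller_rates = caller_consensus(views, min_callers, max_caller_mismatch, report)
    calls = calls.subset(loci=[l for l in calls.loci if l in set(keep)])

    pairs = [(a, b) for a, b in replicate_pairs
             if a in calls._ind_index and b in calls._ind_index]
    rep_rates = None
    if pairs:
        keep, rep_rates = replicate_mismatch_filter(calls, pairs, max_replicate_mismatch, report)
        calls = calls.subset(loci=keep)

    keep, _ = maf_filter(calls, min_maf, report)
    calls = calls.subset(loci=keep)
    calls = iterative_missingness_filter(calls, missing_start, missing_end, report=report)

    if pairs:
        pairs = [(a, b) for a, b in pairs if a in calls._ind_index and b in calls._ind_index]
    if pairs:
        keep, rep_rates = final_consistency_filter(calls, pairs, min_consistency, report)
        calls = calls.subset(loci=keep)
    return QCResult(calls, report, rep_rates, caller_rates)
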