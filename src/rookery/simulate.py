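"""Synthetic rookery generator.

Produces marker panels, pedigrees, genotypes, read depths, multi-caller
views and replicate samples with *known truth*, emulating the statistical
structure of a small sea-turtle nesting population: ~135 microhaplotype
loci with 2-7 alleles (mean about 2.61), a few tens of breeding adults in
a handful of nesting complexes with weak east-west differentiation,
roughly a thousand sampled offspring, allelic dropout a few percent,
amplicon depths of a few hundred reads, and ~12% replicated samples.

Every function is deterministic given its seed.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, DepthTable, GenotypeTable

# Allele-count spectrum over 2..7 alleles: mean 2.61, max 7, and about
# 12 of 135 loci with four or more alleles, matching the study panel.
DEFAULT_ALLELE_SPECTRUM = (0.546, 0.365, 0.05, 0.02, 0.01, 0.009)

# A final panel's alleles have, by construction, survived the MAF < 0.01
# removal, so simulated base frequencies are conditioned on this floor.
DEFAULT_MIN_FREQ = 0.01

BASE_GROUP = "base"


def _hap_labels(k: int) -> list[str]:
    """Haplotype labels as distinct 3-mer DNA strings (VCF-exportable)."""
    alphabet = "ACGT"
    labels = ["".join(t) for t in itertools.product(alphabet, repeat=3)]
    return labels[:k]


@dataclasses.dataclass
class MarkerPanel:
    """A microhaplotype marker panel with per-group allele frequencies."""

    loci: list[str]
    alleles: dict[str, list[str]]
    freqs: dict[str, dict[str, np.ndarray]]  # group -> locus -> frequency vector

    def __post_init__(self):
        for group, by_locus in self.freqs.items():
            for locus in self.loci:
                p = np.asarray(by_locus[locus], dtype=float)
                if abs(p.sum() - 1.0) > 1e-9:
                    raise ValueError(f"frequencies at {locus} ({group}) do not sum to 1")
                if not 2 <= len(self.alleles[locus]) <= 7:
                    raise ValueError(f"allele count at {locus} outside [2, 7]")
                by_locus[locus] = p

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def n_alleles(self, locus: str) -> int:
        return len(self.alleles[locus])

    def mean_allele_count(self) -> float:
        return float(np.mean([len(self.alleles[l]) for l in self.loci]))

    def group_freqs(self, group: str = BASE_GROUP) -> dict[str, np.ndarray]:
        if group not in self.freqs:
            raise ValueError(f"unknown frequency group: {group!r}")
        return self.freqs[group]

    def freq_frame(self) -> pd.DataFrame:
        recs = []
        for group, by_locus in self.freqs.items():
            for locus in self.loci:
                for lab, p in zip(self.alleles[locus], by_locus[locus]):
                    recs.append((group, locus, lab, p))
        return pd.DataFrame(recs, columns=["group", "locus", "allele", "freq"])

    def write_tsv(self, path) -> None:
        self.freq_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_freq_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        loci = list(pd.unique(df["locus"]))
        alleles = {
            l: list(df.loc[(df["locus"] == l) & (df["group"] == df["group"].iloc[0]), "allele"])
            for l in loci
        }
        freqs: dict[str, dict[str, np.ndarray]] = {}
        for group, sub in df.groupby("group", sort=False):
            freqs[group] = {
                l: sub.loc[sub["locus"] == l, "freq"].to_numpy(dtype=float) for l in loci
            }
        return cls(loci, alleles, freqs)


@dataclasses.dataclass
class ErrorModel:
    """Genotyping error process applied call-by-call to truth genotypes.

    dropout_rate
        Probability that a heterozygous call loses one allele and appears
        homozygous (classic allelic dropout).
    other_error_rate
        Probability that one allele of a call is replaced by a random
        panel allele.
    missing_rate
        Probability that a call is missing outright.
    per_locus_error
        Scalar ``e`` consumed by the likelihood models downstream; not
        applied here.
    """

    dropout_rate: float = 0.035
    other_error_rate: float = 0.004
    missing_rate: float = 0.005
    per_locus_error: float = 0.02

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1]")


@dataclasses.dataclass
class PedigreeTruth:
    """Known pedigree of a simulated rookery."""

    females: pd.DataFrame  # id, complex, beach, lon, lat
    males: pd.DataFrame  # id, complex
    matings: dict[str, str]  # female -> male
    nests: pd.DataFrame  # nest_id, beach, complex, mother_id, clutch_size
    offspring: pd.DataFrame  # id, mother, father, nest

    def __post_init__(self):
        parents = set(self.females["id"]) | set(self.males["id"])
        if not set(self.offspring["mother"]).issubset(set(self.females["id"])):
            raise ValueError("offspring reference unknown mothers")
        if not set(self.offspring["father"]).issubset(set(self.males["id"])):
            raise ValueError("offspring reference unknown fathers")
        nests_per_female = self.nests.groupby("mother_id").size()
        if ((nests_per_female < 1) | (nests_per_female > 5)).any():
            raise ValueError("nests per female outside [1, 5]")
        del parents

    @property
    def adult_ids(self) -> list[str]:
        return list(self.females["id"]) + list(self.males["id"])

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.offspring["id"])

    def complex_of(self) -> dict[str, str]:
        out = dict(zip(self.females["id"], self.females["complex"]))
        out.update(zip(self.males["id"], self.males["complex"]))
        nest_complex = dict(zip(self.nests["nest_id"], self.nests["complex"]))
        for row in self.offspring.itertuples(index=False):
            out[row.id] = nest_complex[row.nest]
        return out

    def write(self, prefix) -> None:
        self.females.to_csv(f"{prefix}.females.tsv", sep="\t", index=False)
        self.males.to_csv(f"{prefix}.males.tsv", sep="\t", index=False)
        self.nests.to_csv(f"{prefix}.nests.tsv", sep="\t", index=False)
        self.offspring.to_csv(f"{prefix}.offspring.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(
    n_loci: int = 135,
    allele_count_distribution: Sequence[float] = DEFAULT_ALLELE_SPECTRUM,
    seed: int | None = None,
    dirichlet_alpha: float = 1.0,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> MarkerPanel:
    """Draw a marker panel with allele counts in 2..7 and Dirichlet frequencies.

    ``allele_count_distribution`` is a probability vector over allele counts
    2, 3, ..., 7.  Base frequencies are drawn per locus from a symmetric
    Dirichlet with concentration ``dirichlet_alpha``, conditioned (by
    rejection) on every allele reaching ``min_freq``: a panel's alleles are
    the ones that survived the minor-allele-frequency filter, so frequencies
    below that floor cannot occur among counted alleles.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    dist = np.asarray(allele_count_distribution, dtype=float)
    if len(dist) != 6 or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("allele_count_distribution must be a probability vector over 2..7")
    if not 0.0 <= min_freq < 1.0 / 7:
        raise ValueError("min_freq must be in [0, 1/7)")
    rng = np.random.default_rng(seed)
    counts = rng.choice(np.arange(2, 8), size=n_loci, p=dist)
    width = len(str(max(n_loci, 1)))
    loci = [f"mh{str(i + 1).zfill(width)}" for i in range(n_loci)]
    alleles = {l: _hap_labels(int(k)) for l, k in zip(loci, counts)}
    base = {}
    for l in loci:
        alpha = np.full(len(alleles[l]), dirichlet_alpha)
        v = rng.dirichlet(alpha)
        while v.min() < min_freq:
            v = rng.dirichlet(alpha)
        base[l] = v
    return MarkerPanel(loci, alleles, {BASE_GROUP: base})


def diverge_complex_freqs(
    panel: MarkerPanel,
    complexes: Sequence[str],
    fst: float,
    seed: int | None = None,
) -> MarkerPanel:
    """Add per-complex frequencies via the Balding-Nichols construction.

    Each complex's frequency vector at a locus is drawn from a Dirichlet
    with concentration ``p * (1 - fst) / fst`` (each allele marginally Beta),
    centred on the base frequencies.  ``fst = 0`` copies the base exactly.
    """
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if len(set(complexes)) != len(complexes):
        raise ValueError("complex labels must be unique")
    rng = np.random.default_rng(seed)
    freqs = {BASE_GROUP: dict(panel.freqs[BASE_GROUP])}
    for cx in complexes:
        by_locus: dict[str, np.ndarray] = {}
        for locus in panel.loci:
            p = panel.freqs[BASE_GROUP][locus]
            if fst == 0.0:
                by_locus[locus] = p.copy()
            else:
                conc = np.maximum(p * (1.0 - fst) / fst, 1e-8)
                q = rng.gamma(conc)
                total = q.sum()
                if total < 1e-250:
                    # fst -> 1 limit: fixation on one allele drawn with prob p
                    q = np.zeros_like(p)
                    q[rng.choice(len(p), p=p)] = 1.0
                    total = 1.0
                by_locus[locus] = q / total
        freqs[cx] = by_locus
    return MarkerPanel(panel.loci, panel.alleles, freqs)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RookeryDesign:
    """Demographic design of a simulated nesting season.

    Defaults mirror the study system: 13 nesting females and 12 breeding
    males spread over three nesting complexes on a short stretch of coast,
    one polygynous male, 1-5 nests per female and clutches sized so that
    the season yields on the order of a thousand sampled offspring.
    """

    n_females: int = 13
    n_males: int = 12
    complexes: tuple[str, ...] = ("Apua", "Pohue", "Kamehame")
    females_per_complex: tuple[int, ...] = (5, 7, 1)
    males_per_complex: tuple[int, ...] = (5, 6, 1)
    assortative_by_complex: bool = True
    polygyny_pairs: int = 1
    nests_per_female_range: tuple[int, int] = (1, 5)
    clutch_size_range: tuple[int, int] = (10, 40)
    coast_origin_lon: float = -155.90
    coast_gap: float = 0.15
    coast_lat: float = 19.10


def simulate_pedigree(design: RookeryDesign | None = None, seed: int | None = None) -> PedigreeTruth:
    """Draw a mating/nesting pedigree for one season.

    Each female mates exactly one male (no polyandry); ``polygyny_pairs``
    males receive a second mate.  Under assortative mating, matings never
    cross nesting complexes.
    """
    design = design or RookeryDesign()
    if design.n_males < 1:
        raise ValueError("need at least one male")
    if design.polygyny_pairs > design.n_females - min(design.n_males, design.n_females):
        if design.polygyny_pairs > design.n_females - design.n_males:
            raise ValueError("polygyny_pairs exceeds n_females - n_males")
    if sum(design.females_per_complex) != design.n_females:
        raise ValueError("females_per_complex must sum to n_females")
    if sum(design.males_per_complex) != design.n_males:
        raise ValueError("males_per_complex must sum to n_males")
    if design.assortative_by_complex:
        for fc, mc in zip(design.females_per_complex, design.males_per_complex):
            if fc > 0 and mc < 1:
                raise ValueError("assortative mating requires >=1 male per occupied complex")

    rng = np.random.default_rng(seed)
    females, males = [], []
    fem_cx, male_cx = [], []
    i_f = i_m = 0
    for cx, nf, nm in zip(design.complexes, design.females_per_complex, design.males_per_complex):
        for _ in range(nf):
            i_f += 1
            females.append(f"F{i_f:02d}")
            fem_cx.append(cx)
        for _ in range(nm):
            i_m += 1
            males.append(f"M{i_m:02d}")
            male_cx.append(cx)

    # beach coordinates: one beach per complex on a 1-D coastline with gaps
    cx_lon = {
        cx: design.coast_origin_lon + i * design.coast_gap
        for i, cx in enumerate(design.complexes)
    }
    beach_of_cx = {cx: f"{cx}-beach" for cx in design.complexes}

    # matings: each female mates exactly one male (no polyandry); exactly
    # polygyny_pairs males receive a second mate.  Allocation works per
    # mating unit (a complex when assortative, the whole rookery otherwise):
    # choose how many distinct sires each unit uses, then hand the extra
    # females to distinct already-mated males.
    if design.assortative_by_complex:
        units = [
            (
                [f for f, c in zip(females, fem_cx) if c == cx],
                [m for m, c in zip(males, male_cx) if c == cx],
            )
            for cx in design.complexes
        ]
    else:
        units = [(list(females), list(males))]
    d = [min(len(fs), len(ms)) for fs, ms in units]  # distinct sires per unit
    target = design.n_females - design.polygyny_pairs
    guard = 0
    while sum(d) > target:
        room = [
            k
            for k in range(len(units))
            if d[k] >= 2 and (len(units[k][0]) - (d[k] - 1)) <= (d[k] - 1)
        ]
        if not room:
            raise ValueError("polygyny_pairs infeasible under this complex layout")
        d[room[guard % len(room)]] -= 1
        guard += 1
    if sum(d) < target:
        raise ValueError("not enough males to honour polygyny_pairs")
    matings: dict[str, str] = {}
    for (fs, ms), dk in zip(units, d):
        if fs and not ms:
            raise ValueError("a mating unit has females but no males")
        sires = list(rng.permutation(ms))[:dk]
        fem_order = list(rng.permutation(fs))
        for i, fem in enumerate(fem_order):
            if i < dk:
                matings[fem] = sires[i]
            else:
                matings[fem] = sires[i - dk]  # each extra female a distinct sire

    # nests and clutches
    lo_n, hi_n = design.nests_per_female_range
    lo_c, hi_c = design.clutch_size_range
    nest_rows, off_rows = [], []
    nest_counter: dict[str, int] = {cx: 0 for cx in design.complexes}
    off_i = 0
    for fem, cx in zip(females, fem_cx):
        n_nests = int(rng.integers(lo_n, hi_n + 1))
        for _ in range(n_nests):
            nest_counter[cx] += 1
            nest_id = f"{cx}-{nest_counter[cx]:02d}"
            clutch = int(rng.integers(lo_c, hi_c + 1))
            nest_rows.append((nest_id, beach_of_cx[cx], cx, fem, clutch))
            for _ in range(clutch):
                off_i += 1
                off_rows.append((f"O{off_i:04d}", fem, matings[fem], nest_id))

    females_df = pd.DataFrame(
        {
            "id": females,
            "complex": fem_cx,
            "beach": [beach_of_cx[c] for c in fem_cx],
            "lon": [cx_lon[c] + rng.uniform(-1e-4, 1e-4) for c in fem_cx],
            "lat": [design.coast_lat + rng.uniform(-1e-4, 1e-4) for _ in fem_cx],
        }
    )
    males_df = pd.DataFrame({"id": males, "complex": male_cx})
    nests_df = pd.DataFrame(
        nest_rows, columns=["nest_id", "beach", "complex", "mother_id", "clutch_size"]
    )
    offspring_df = pd.DataFrame(off_rows, columns=["id", "mother", "father", "nest"])
    return PedigreeTruth(females_df, males_df, matings, nests_df, offspring_df)


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def _draw_parent_codes(rng, panel: MarkerPanel, groups: Sequence[str]) -> np.ndarray:
    """HW draws per individual from that individual's complex frequencies."""
    n, m = len(groups), panel.n_loci
    codes = np.empty((n, m, 2), dtype=np.int16)
    for j, locus in enumerate(panel.loci):
        for i, g in enumerate(groups):
            gf = panel.freqs.get(g, panel.freqs[BASE_GROUP])
            p = gf[locus]
            codes[i, j] = rng.choice(len(p), size=2, p=p)
    return np.sort(codes, axis=2)


def simulate_genotypes(
    pedigree: PedigreeTruth,
    panel: MarkerPanel,
    error: ErrorModel | None = None,
    seed: int | None = None,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Draw truth and observed genotype tables for all rookery members.

    Parents are HW draws from their complex's frequencies (falling back to
    the base frequencies when the panel carries no per-complex vectors);
    offspring receive one uniformly chosen allele from each parent.  The
    observed table applies dropout, random-allele errors and missingness
    independently per call.
    """
    error = error or ErrorModel()
    rng = np.random.default_rng(seed)
    cx_of = pedigree.complex_of()
    adults = pedigree.adult_ids
    adult_codes = _draw_parent_codes(rng, panel, [cx_of[a] for a in adults])
    adult_row = {a: i for i, a in enumerate(adults)}

    off = pedigree.offspring
    n_off, m = len(off), panel.n_loci
    mo_rows = np.array([adult_row[x] for x in off["mother"]])
    fa_rows = np.array([adult_row[x] for x in off["father"]])
    pick_m = rng.integers(0, 2, size=(n_off, m))
    pick_f = rng.integers(0, 2, size=(n_off, m))
    off_codes = np.empty((n_off, m, 2), dtype=np.int16)
    off_codes[..., 0] = adult_codes[mo_rows][np.arange(n_off)[:, None], np.arange(m)[None, :], pick_m]
    off_codes[..., 1] = adult_codes[fa_rows][np.arange(n_off)[:, None], np.arange(m)[None, :], pick_f]

    individuals = adults + list(off["id"])
    codes = np.concatenate([adult_codes, off_codes], axis=0)
    truth = GenotypeTable(codes, individuals, panel.loci, panel.alleles)
    observed = apply_errors(truth, panel, error, rng)
    return truth, observed


def apply_errors(
    truth: GenotypeTable,
    panel: MarkerPanel,
    error: ErrorModel,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Independent per-call corruption: dropout, random allele swap, missing."""
    codes = truth.codes.copy()
    n, m, _ = codes.shape
    het = truth.het_mask()
    drop = het & (rng.random((n, m)) < error.dropout_rate)
    keep = rng.integers(0, 2, size=(n, m))
    ii, jj = np.nonzero(drop)
    codes[ii, jj, 0] = truth.codes[ii, jj, keep[ii, jj]]
    codes[ii, jj, 1] = codes[ii, jj, 0]

    swap = rng.random((n, m)) < error.other_error_rate
    which = rng.integers(0, 2, size=(n, m))
    u = rng.random((n, m))
    ii, jj = np.nonzero(swap & (codes[..., 0] >= 0))
    for i, j in zip(ii, jj):
        k = len(panel.alleles[truth.loci[j]])
        codes[i, j, which[i, j]] = np.int16(min(int(u[i, j] * k), k - 1))
    codes = np.sort(codes, axis=2)

    miss = rng.random((n, m)) < error.missing_rate
    codes[miss] = MISSING
    return GenotypeTable(codes, truth.individuals, truth.loci, truth.alleles)


# ---------------------------------------------------------------------------
# depths, caller views, replicates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SequencingBundle:
    depths: DepthTable
    caller_views: list[GenotypeTable]
    replicate_pairs: list[tuple[str, str]]
    observed: GenotypeTable  # observed table including replicate rows


def simulate_depths_and_views(
    truth: GenotypeTable,
    observed: GenotypeTable,
    panel: MarkerPanel,
    error: ErrorModel | None = None,
    depth_mean_range: tuple[float, float] = (300.0, 500.0),
    depth_dispersion: float = 8.0,
    n_callers: int = 3,
    view_noise: float = 0.02,
    replicate_fraction: float = 0.12,
    het_depth_bias: float = 0.0,
    noise_alleles: bool = True,
    seed: int | None = None,
) -> SequencingBundle:
    """Simulate per-allele read depths, caller views and replicate samples.

    Per (individual, locus) the total depth is negative-binomial around a
    per-locus mean drawn uniformly from ``depth_mean_range``; heterozygote
    depth splits are Binomial(total, 0.5 + het_depth_bias); every
    non-carried panel allele receives Poisson(1) noise reads when
    ``noise_alleles`` is on.  Caller views are independent corruptions of
    the observed table: each call is re-drawn from HW with probability
    ``view_noise``.  Replicate individuals are *re-genotyped* from truth
    with fresh error draws, never copied.
    """
    if not 0.0 <= replicate_fraction <= 1.0:
        raise ValueError("replicate_fraction must be in [0, 1]")
    error = error or ErrorModel()
    rng = np.random.default_rng(seed)

    # replicates: fresh error draws from truth
    n_rep = int(round(replicate_fraction * truth.n_individuals))
    rep_rows = rng.choice(truth.n_individuals, size=n_rep, replace=False) if n_rep else np.array([], int)
    rep_ids = [f"{truth.individuals[i]}__rep1" for i in rep_rows]
    rep_truth = GenotypeTable(
        truth.codes[rep_rows], rep_ids, truth.loci, truth.alleles
    )
    rep_obs = apply_errors(rep_truth, panel, error, rng)
    full_obs = GenotypeTable(
        np.concatenate([observed.codes, rep_obs.codes], axis=0),
        observed.individuals + rep_ids,
        observed.loci,
        observed.alleles,
    )
    replicate_pairs = [(truth.individuals[i], r) for i, r in zip(rep_rows, rep_ids)]

    # depths
    n, m = full_obs.n_individuals, full_obs.n_loci
    max_k = max(len(panel.alleles[l]) for l in panel.loci)
    locus_means = rng.uniform(*depth_mean_range, size=m)
    r = depth_dispersion
    totals = rng.negative_binomial(r, r / (r + locus_means[None, :]), size=(n, m))
    counts = np.zeros((n, m, max_k), dtype=np.int64)
    a0 = full_obs.codes[..., 0].astype(int)
    a1 = full_obs.codes[..., 1].astype(int)
    het = (a0 != a1) & (a0 >= 0)
    hom = (a0 == a1) & (a0 >= 0)
    split = rng.binomial(totals, 0.5 + het_depth_bias)
    ii, jj = np.nonzero(het)
    counts[ii, jj, a0[ii, jj]] += split[ii, jj]
    counts[ii, jj, a1[ii, jj]] += totals[ii, jj] - split[ii, jj]
    ii, jj = np.nonzero(hom)
    counts[ii, jj, a0[ii, jj]] += totals[ii, jj]
    if noise_alleles:
        noise = rng.poisson(1.0, size=(n, m, max_k))
        for j, locus in enumerate(full_obs.loci):
            noise[:, j, len(panel.alleles[locus]):] = 0
        carried = np.zeros((n, m, max_k), dtype=bool)
        valid = a0 >= 0
        ii, jj = np.nonzero(valid)
        carried[ii, jj, a0[ii, jj]] = True
        carried[ii, jj, a1[ii, jj]] = True
        counts += np.where(carried, 0, noise)
    depths = DepthTable(counts, full_obs.individuals, full_obs.loci, panel.alleles)

    # caller views: independent HW re-draws at rate view_noise
    views = []
    for _ in range(n_callers):
        v = full_obs.codes.copy()
        bad = rng.random((n, m)) < view_noise
        ii, jj = np.nonzero(bad & (v[..., 0] >= 0))
        for i, j in zip(ii, jj):
            p = panel.freqs[BASE_GROUP][full_obs.loci[j]]
            v[i, j] = np.sort(rng.choice(len(p), size=2, p=p))
        views.append(GenotypeTable(v, full_obs.individuals, full_obs.loci, full_obs.alleles))

    return SequencingBundle(depths, views, replicate_pairs, full_obs)


# ---------------------------------------------------------------------------
# convenience: one call that builds a whole rookery
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Rookery:
    panel: MarkerPanel
    pedigree: PedigreeTruth
    truth: GenotypeTable
    observed: GenotypeTable
    bundle: SequencingBundle


def simulate_rookery(
    design: RookeryDesign | None = None,
    n_loci: int = 135,
    fst: float = 0.04,
    error: ErrorModel | None = None,
    seed: int | None = None,
    **seq_kw,
) -> Rookery:
    """Full forward simulation: panel -> complex divergence -> pedigree ->
    genotypes -> depths/views/replicates, with one master seed."""
    design = design or RookeryDesign()
    error = error or ErrorModel()
    ss = np.random.SeedSequence(seed)
    s_panel, s_div, s_ped, s_gen, s_seq = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    panel = simulate_panel(n_loci=n_loci, seed=s_panel)
    panel = diverge_complex_freqs(panel, list(design.complexes), fst, seed=s_div)
    pedigree = simulate_pedigree(design, seed=s_ped)
    truth, observed = simulate_genotypes(pedigree, panel, error, seed=s_gen)
    bundle = simulate_depths_and_views(truth, observed, panel, error, seed=s_seq, **seq_kw)
    return Rookery(panel, pedigree, truth, observed, bundle)
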