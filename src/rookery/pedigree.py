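"""Rookery-level pedigree inference.

Builds on the pairwise kin likelihood machinery: maternity assignment for
orphan nests (with off-year negative controls), full-sib verification
within and between nests, maximum-likelihood reconstruction of unsampled
paternal genotypes from mother-offspring data, polygyny detection by
merging reconstructed sires, a sibship-frequency effective-size estimate,
and plain nesting summaries.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotypes import MISSING, GenotypeTable
from .kinlik import pairwise_llr

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class NestRecord:
    nest_id: str
    beach: str
    complex: str
    offspring: list[str]
    observed_mother: str | None = None

    def __post_init__(self):
        if not self.offspring:
            raise ValueError("a nest needs at least one offspring")


@dataclasses.dataclass
class MaternityAssignment:
    nest_id: str
    inferred_mother: str  # candidate id or "unsampled"
    probability: float
    supported: bool
    low_confidence: bool = False
    candidate_probs: dict[str, float] = dataclasses.field(default_factory=dict)


def assign_mothers(
    orphan_nests: Sequence[NestRecord],
    candidates: Sequence[str],
    table: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    e: float = 0.02,
    support_threshold: float = 0.95,
) -> list[MaternityAssignment]:
    """Assign each orphan nest a mother from the candidate set.

    Per nest the parent-offspring vs unrelated log-likelihood ratio is
    summed over the nest's genotyped offspring for every candidate
    (negative controls included); an "unsampled mother" alternative scores
    zero by construction (offspring are then plain Hardy-Weinberg draws).
    Probabilities are the normalized likelihoods over candidates plus the
    unsampled alternative, under a uniform prior.
    """
    out = []
    for nest in orphan_nests:
        offspring = [o for o in nest.offspring if o in table._ind_index]
        low_conf = len(offspring) < 3
        scores = {"unsampled": 0.0}
        for cand in candidates:
            lam = pairwise_llr(table, freqs, [(cand, o) for o in offspring], "PO", "U", e=e)
            scores[cand] = float(lam.sum())
        names = list(scores)
        vals = np.array([scores[n] for n in names])
        probs = np.exp(vals - logsumexp(vals))
        best = names[int(np.argmax(probs))]
        p_best = float(probs.max())
        out.append(
            MaternityAssignment(
                nest.nest_id,
                best,
                p_best,
                supported=p_best >= support_threshold,
                low_confidence=low_conf,
                candidate_probs=dict(zip(names, probs.tolist())),
            )
        )
    return out


# ---------------------------------------------------------------------------
# sib structure
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SibStructure:
    within: pd.DataFrame  # nest_id, pair ids, class in {FS, HS, U}
    cross: pd.DataFrame  # nest_i, nest_j, n_pairs, frac_hs_or_fs, hs_link


def _classify_pairs(table, freqs, pairs, e):
    lam_fs_u = pairwise_llr(table, freqs, pairs, "FS", "U", e=e)
    lam_fs_hs = pairwise_llr(table, freqs, pairs, "FS", "HS", e=e)
    lam_hs_u = pairwise_llr(table, freqs, pairs, "HS", "U", e=e)
    cls = np.where(
        (lam_fs_u > 0) & (lam_fs_hs > 0),
        "FS",
        np.where((lam_hs_u > 0), "HS", "U"),
    )
    return cls, lam_fs_u, lam_fs_hs, lam_hs_u


def confirm_sib_structure(
    nests: Sequence[NestRecord],
    table: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    e: float = 0.02,
    max_pairs_within: int = 50,
    max_pairs_cross: int = 30,
    seed: int | None = None,
) -> SibStructure:
    """Classify nest-mate pairs and cross-nest pairs as FS / HS / U.

    Within-nest full sibships confirm single paternity; cross-nest
    half-sib links between nests of *different* mothers are the genetic
    signature of polygyny.  Pair counts per nest (pair) are capped and
    sampled deterministically under ``seed`` to bound cost on big nests.
    """
    rng = np.random.default_rng(seed)
    win_rows = []
    for nest in nests:
        offs = [o for o in nest.offspring if o in table._ind_index]
        if len(offs) < 2:
            win_rows.append(
                {"nest_id": nest.nest_id, "id_x": offs[0] if offs else "", "id_y": "", "class": "vacuous"}
            )
            continue
        pairs = list(itertools.combinations(offs, 2))
        if len(pairs) > max_pairs_within:
            idx = rng.choice(len(pairs), size=max_pairs_within, replace=False)
            pairs = [pairs[i] for i in idx]
        cls, *_ = _classify_pairs(table, freqs, pairs, e)
        for (a, b), c in zip(pairs, cls):
            win_rows.append({"nest_id": nest.nest_id, "id_x": a, "id_y": b, "class": str(c)})

    cross_rows = []
    for na, nb in itertools.combinations(nests, 2):
        offs_a = [o for o in na.offspring if o in table._ind_index]
        offs_b = [o for o in nb.offspring if o in table._ind_index]
        if not offs_a or not offs_b:
            continue
        pairs = list(itertools.product(offs_a, offs_b))
        if len(pairs) > max_pairs_cross:
            idx = rng.choice(len(pairs), size=max_pairs_cross, replace=False)
            pairs = [pairs[i] for i in idx]
        if not pairs:
            continue
        cls, *_ = _classify_pairs(table, freqs, pairs, e)
        frac_fs = float(np.mean(cls == "FS"))
        frac_hs = float(np.mean(cls == "HS"))
        cross_rows.append(
            {
                "nest_i": na.nest_id,
                "nest_j": nb.nest_id,
                "n_pairs": len(pairs),
                "frac_fs": frac_fs,
                "frac_hs": frac_hs,
                "hs_link": frac_hs > 0.5,
                "fs_link": frac_fs > 0.5,
            }
        )
    return SibStructure(pd.DataFrame(win_rows), pd.DataFrame(cross_rows))


# ---------------------------------------------------------------------------
# paternal genotype reconstruction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PaternalGenotype:
    father_id: str
    codes: np.ndarray  # (n_loci, 2), MISSING where ambiguity-masked
    loci: list[str]
    alleles: dict[str, list[str]]
    supporting_nests: list[str] = dataclasses.field(default_factory=list)
    mother_id: str | None = None
    excluded_offspring: list[str] = dataclasses.field(default_factory=list)

    def masked_fraction(self) -> float:
        return float(np.mean(self.codes[:, 0] == MISSING))


def _child_prob_given_parents(gc, gm, gf, p):
    """P(child gc | mother gm, father gf) by explicit gamete enumeration.

    gm may be None (unsampled mother -> maternal allele from population).
    All genotypes are (a, b) index tuples; p the locus frequency vector.
    """
    c1, c2 = gc
    total = 0.0
    for fa in gf:
        if gm is None:
            if c1 == c2:
                total += 0.5 * (fa == c1) * p[c1]
            else:
                total += 0.5 * ((fa == c1) * p[c2] + (fa == c2) * p[c1])
        else:
            for ma in gm:
                total += 0.25 * (tuple(sorted((ma, fa))) == (c1, c2))
    return total


def reconstruct_father(
    mother_genotype: np.ndarray | None,
    offspring_genotypes: np.ndarray,
    loci: Sequence[str],
    alleles: Mapping[str, Sequence[str]],
    freqs: Mapping[str, np.ndarray],
    e: float = 0.02,
    father_id: str = "P??",
    max_incompatible_fraction: float = 0.10,
    tie_tol: float = 1e-9,
) -> PaternalGenotype:
    """Maximum-likelihood unordered paternal genotype per locus.

    For every candidate genotype the likelihood multiplies, over
    offspring, the error-mixed Mendelian probability of the offspring call
    given the mother (or a population draw where the mother is missing or
    unsampled).  Loci whose ML genotype is not unique are ambiguity-masked.
    Offspring incompatible with the mother at more than
    ``max_incompatible_fraction`` of co-typed loci are excluded first.
    """
    loci = list(loci)
    m = len(loci)
    off = np.asarray(offspring_genotypes)
    n_off = off.shape[0]

    # maternal-incompatibility screen (opposite homozygotes / no shared allele)
    excluded = []
    use = np.ones(n_off, dtype=bool)
    if mother_genotype is not None:
        for i in range(n_off):
            bad = tot = 0
            for j in range(m):
                gm, gc = mother_genotype[j], off[i, j]
                if gm[0] == MISSING or gc[0] == MISSING:
                    continue
                tot += 1
                if not (gc[0] in (gm[0], gm[1]) or gc[1] in (gm[0], gm[1])):
                    bad += 1
            if tot and bad / tot > max_incompatible_fraction:
                use[i] = False
                excluded.append(i)

    codes = np.full((m, 2), MISSING, dtype=np.int16)
    for j, locus in enumerate(loci):
        p = np.asarray(freqs[locus], dtype=float)
        k = len(p)
        gm = None
        if mother_genotype is not None and mother_genotype[j][0] != MISSING:
            gm = (int(mother_genotype[j][0]), int(mother_genotype[j][1]))
        cands = [(a, b) for a in range(k) for b in range(a, k)]
        best_ll, best = -np.inf, []
        for gf in cands:
            ll = 0.0
            for i in range(n_off):
                if not use[i] or off[i, j][0] == MISSING:
                    continue
                gc = (int(off[i, j][0]), int(off[i, j][1]))
                pm = _child_prob_given_parents(gc, gm, gf, p)
                phw = 2 * p[gc[0]] * p[gc[1]] if gc[0] != gc[1] else p[gc[0]] ** 2
                pobs = (1 - e) * pm + e * phw
                ll += np.log(pobs) if pobs > 0 else -1e30
            if ll > best_ll + tie_tol:
                best_ll, best = ll, [gf]
            elif ll >= best_ll - tie_tol:
                best.append(gf)
        n_informative = sum(
            1 for i in range(n_off) if use[i] and off[i, j][0] != MISSING
        )
        if len(best) == 1 and n_informative >= 2:
            codes[j] = best[0]
        elif n_informative == 1:
            # one offspring exposes at most one paternal gamete: resolve a
            # single allele when it is unambiguous, mask the second slot
            i = next(i for i in range(n_off) if use[i] and off[i, j][0] != MISSING)
            gc = {int(off[i, j][0]), int(off[i, j][1])}
            if gm is not None:
                non_maternal = gc - set(gm)
                if len(non_maternal) == 1:
                    codes[j, 0] = non_maternal.pop()
    return PaternalGenotype(
        father_id,
        codes,
        loci,
        {l: list(alleles[l]) for l in loci},
        excluded_offspring=[str(i) for i in excluded],
    )


def reconstruct_fathers_by_mother(
    table: GenotypeTable,
    nests: Sequence[NestRecord],
    mother_of_nest: Mapping[str, str],
    freqs: Mapping[str, np.ndarray],
    e: float = 0.02,
    max_offspring: int = 25,
    seed: int | None = None,
) -> list[PaternalGenotype]:
    """One reconstructed sire per mother, pooling that mother's nests."""
    rng = np.random.default_rng(seed)
    by_mother: dict[str, list[NestRecord]] = {}
    for nest in nests:
        mom = mother_of_nest.get(nest.nest_id)
        if mom is None:
            continue
        by_mother.setdefault(mom, []).append(nest)
    fathers = []
    for i, (mom, mom_nests) in enumerate(sorted(by_mother.items()), start=1):
        offs = [o for nest in mom_nests for o in nest.offspring if o in table._ind_index]
        if len(offs) > max_offspring:
            offs = [offs[k] for k in sorted(rng.choice(len(offs), size=max_offspring, replace=False))]
        if not offs:
            continue
        gm = table.codes[table.ind_idx(mom)] if mom in table._ind_index else None
        go = table.codes[[table.ind_idx(o) for o in offs]]
        pg = reconstruct_father(
            gm, go, table.loci, table.alleles, freqs, e=e, father_id=f"P{i:02d}"
        )
        pg.mother_id = mom
        pg.supporting_nests = [nest.nest_id for nest in mom_nests]
        fathers.append(pg)
    return fathers


# ---------------------------------------------------------------------------
# polygyny detection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MatingMap:
    father_to_mothers: dict[str, list[str]]
    n_males: int
    n_females: int
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def sex_ratio(self) -> tuple[int, int]:
        return (self.n_males, self.n_females)


def detect_polygyny(
    fathers: Sequence[PaternalGenotype],
    cross_links: pd.DataFrame,
    match_threshold: float = 0.90,
    min_shared_loci: int = 50,
) -> MatingMap:
    """Merge per-mother reconstructed sires that are the same male.

    Two sires merge when their genotypes agree at >= ``match_threshold``
    of >= ``min_shared_loci`` jointly unmasked loci AND at least one
    cross-nest half-sib-majority link connects their nest sets.  Genotype
    identity without sib support is reported unmerged with a warning.
    """
    n = len(fathers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    hs_pairs = set()
    if len(cross_links):
        nest_owner = {}
        for i, f in enumerate(fathers):
            for nest in f.supporting_nests:
                nest_owner[nest] = i
        for row in cross_links.itertuples(index=False):
            if getattr(row, "hs_link", False):
                a, b = nest_owner.get(row.nest_i), nest_owner.get(row.nest_j)
                if a is not None and b is not None and a != b:
                    hs_pairs.add(tuple(sorted((a, b))))

    warnings = []
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = fathers[i].codes, fathers[j].codes
            both = (ci[:, 0] != MISSING) & (cj[:, 0] != MISSING)
            if both.sum() < min_shared_loci:
                continue
            agree = np.all(ci[both] == cj[both], axis=1).mean()
            if agree >= match_threshold:
                if (i, j) in hs_pairs:
                    parent[find(i)] = find(j)
                else:
                    warnings.append(
                        f"{fathers[i].father_id} and {fathers[j].father_id} match at "
                        f"{agree:.3f} but lack cross-nest half-sib support; left unmerged"
                    )

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    father_to_mothers = {}
    for members in groups.values():
        lead = fathers[members[0]].father_id
        father_to_mothers[lead] = sorted(
            m for k in members for m in ([fathers[k].mother_id] if fathers[k].mother_id else [])
        )
    n_females = sum(len(v) for v in father_to_mothers.values())
    return MatingMap(father_to_mothers, len(father_to_mothers), n_females, warnings)


# ---------------------------------------------------------------------------
# sibship-frequency effective size
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NeEstimate:
    point: float
    ci_low: float
    ci_high: float
    mating_model: str
    q_fs: float = float("nan")
    q_hs: float = float("nan")

    def __post_init__(self):
        if not (self.ci_low <= self.point <= self.ci_high):
            # degenerate bootstrap can invert; clamp rather than lie
            self.ci_low = min(self.ci_low, self.point)
            self.ci_high = max(self.ci_high, self.point)


def _ne_from_q(q_fs: float, q_hs: float, model: str) -> float:
    """Sibship-frequency Ne.

    Random mating: 1/Ne = (2 Q_FS + Q_HS) / 4, the coancestry identity
    that reduces to Wright's 1/Ne = (1/Nm + 1/Nf)/4 when sharing a father
    and sharing a mother are independent.  Non-random mating inflates the
    one-generation coalescence rate by (1 + alpha), where alpha is the
    correlation between paternal and maternal sharing (alpha = 1 under
    strict monogamy, halving Ne; alpha = 0 recovers the random model).
    """
    denom = 2 * q_fs + q_hs
    if denom <= 0:
        return float("inf")
    ne = 4.0 / denom
    if model == "nonrandom":
        q_parent = q_fs + q_hs / 2.0
        var = q_parent * (1 - q_parent)
        alpha = 0.0 if var <= 0 else (q_fs - q_parent**2) / var
        alpha = float(np.clip(alpha, 0.0, 1.0))
        ne = 4.0 / (denom * (1.0 + alpha))
    return ne


def sibship_ne(
    offspring: Sequence[str],
    table: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    e: float = 0.02,
    max_pairs: int = 2000,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> list[NeEstimate]:
    """Effective breeding size from sib frequencies among offspring pairs.

    Random offspring pairs are classified FS / HS / U by log-likelihood
    ratio; the observed sib-dyad frequencies feed the random-mating and
    non-random-mating estimators.  CIs bootstrap over offspring.
    """
    rng = np.random.default_rng(seed)
    offs = [o for o in offspring if o in table._ind_index]
    pairs = list(itertools.combinations(range(len(offs)), 2))
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    named = [(offs[i], offs[j]) for i, j in pairs]
    cls, *_ = _classify_pairs(table, freqs, named, e)
    classes = {pq: c for pq, c in zip(pairs, cls)}

    def q_from(selected):
        arr = np.array([classes[pq] for pq in selected])
        if arr.size == 0:
            return 0.0, 0.0
        return float(np.mean(arr == "FS")), float(np.mean(arr == "HS"))

    q_fs, q_hs = q_from(pairs)
    if q_fs == 0.0 and q_hs == 0.0:
        logger.warning("sibship_ne: no sib pairs observed; estimate is infinite")
    pair_lookup: dict[int, list[tuple[int, int]]] = {}
    for i, j in pairs:
        pair_lookup.setdefault(i, []).append((i, j))
        pair_lookup.setdefault(j, []).append((i, j))
    boot = {"random": [], "nonrandom": []}
    for _ in range(n_boot):
        take = rng.integers(0, len(offs), size=len(offs))
        chosen = set(take.tolist())
        selected = [pq for pq in pairs if pq[0] in chosen and pq[1] in chosen]
        bq_fs, bq_hs = q_from(selected)
        for model in boot:
            boot[model].append(_ne_from_q(bq_fs, bq_hs, model))
    alpha = (1 - level) / 2
    out = []
    for model in ("random", "nonrandom"):
        point = _ne_from_q(q_fs, q_hs, model)
        finite = [b for b in boot[model] if np.isfinite(b)]
        if finite:
            lo, hi = float(np.quantile(finite, alpha)), float(np.quantile(finite, 1 - alpha))
        else:
            lo = hi = float("inf")
        out.append(NeEstimate(point, lo, hi, model, q_fs, q_hs))
    return out


# ---------------------------------------------------------------------------
# nesting summary
# ---------------------------------------------------------------------------

def summarize_nesting(
    nests: pd.DataFrame,
    assignments: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-female nesting table: beaches used, nest count, offspring totals,
    mean offspring per nest (1 decimal).

    ``nests`` needs columns nest_id, beach, mother_id (or an ``assignments``
    map nest_id -> mother overriding/na-filling mother_id) and a clutch or
    offspring count column named clutch_size or n_offspring.
    """
    if nests.empty:
        return pd.DataFrame(
            columns=["mother", "beaches", "n_nests", "n_offspring", "mean_per_nest"]
        )
    df = nests.copy()
    count_col = "clutch_size" if "clutch_size" in df.columns else "n_offspring"
    if assignments:
        df["mother_id"] = [
            assignments.get(n, m) for n, m in zip(df["nest_id"], df.get("mother_id", [None] * len(df)))
        ]
    rows = []
    for mom, sub in df.groupby("mother_id", sort=True):
        total = int(sub[count_col].sum())
        n_nests = len(sub)
        rows.append(
            {
                "mother": mom,
                "beaches": ";".join(sorted(set(sub["beach"]))),
                "n_nests": n_nests,
                "n_offspring": total,
                "mean_per_nest": round(total / n_nests, 1),
            }
        )
    return pd.DataFrame(rows)
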