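"""Diversity, differentiation, inbreeding and multivariate structure.

Per-locus statistics use the Nei & Chesser small-sample corrections:
with k groups of (locus-wise) sizes n_i, harmonic mean n~, group allele
frequencies p_i and observed heterozygosities Ho_i,

    Ho = mean_i Ho_i
    Hs = n~/(n~-1) * (1 - mean_i sum_a p_ia^2 - Ho/(2 n~))
    Ht = 1 - sum_a pbar_a^2 + Hs/(n~ k) - Ho/(2 n~ k)

from which G_ST = (Ht-Hs)/Ht, Hedrick's standardized G'_ST, the
small-k-corrected G''_ST, Jost's D, and the within-group inbreeding
coefficient G_IS = 1 - Ho/Hs.  Significance is by permutation of
individuals across groups; HWE uses a Monte-Carlo exact test and LD a
permutation G-test, both with Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# heterozygosity and differentiation
# ---------------------------------------------------------------------------

def _locus_group_stats(table: GenotypeTable, group_rows: Sequence[np.ndarray], j: int):
    """Per-group allele freqs, sizes and observed het at locus j."""
    k_alleles = len(table.alleles[table.loci[j]])
    freqs, sizes, hos = [], [], []
    for rows in group_rows:
        calls = table.codes[rows, j, :]
        ok = calls[:, 0] >= 0
        n_i = int(ok.sum())
        sizes.append(n_i)
        if n_i == 0:
            freqs.append(np.zeros(k_alleles))
            hos.append(0.0)
            continue
        flat = calls[ok].ravel()
        freqs.append(np.bincount(flat, minlength=k_alleles) / (2 * n_i))
        hos.append(float(np.mean(calls[ok, 0] != calls[ok, 1])))
    return np.array(freqs), np.array(sizes), np.array(hos)


def het_stats(table: GenotypeTable, groups: Mapping[str, str]) -> pd.DataFrame:
    """Per-locus Ho, Hs (unbiased), Ht across the given grouping."""
    labels = sorted(set(groups.values()))
    group_rows = [
        np.array([table.ind_idx(s) for s, g in groups.items() if g == lab and s in table._ind_index])
        for lab in labels
    ]
    if any(len(r) < 2 for r in group_rows):
        raise ValueError("every group needs at least two individuals")
    rows = []
    for j, locus in enumerate(table.loci):
        p, n, ho = _locus_group_stats(table, group_rows, j)
        used = n > 0
        p, n, ho = p[used], n[used], ho[used]
        k = len(n)
        n_h = k / np.sum(1.0 / n)
        ho_bar = float(np.mean(ho))
        hs_raw = float(np.mean(1.0 - (p**2).sum(axis=1)))
        hs = n_h / (n_h - 1.0) * (hs_raw - ho_bar / (2 * n_h)) if n_h > 1 else hs_raw
        pbar = p.mean(axis=0)
        ht = 1.0 - float((pbar**2).sum()) + hs / (n_h * k) - ho_bar / (2 * n_h * k)
        hs, ht = max(hs, 0.0), max(ht, 0.0)
        rows.append({"locus": locus, "Ho": ho_bar, "Hs": hs, "Ht": ht, "k": k})
    return pd.DataFrame(rows).set_index("locus")


def _diff_from_hs_ht(hs: float, ht: float, k: int) -> dict[str, float]:
    # unbiased estimators can dip below zero when groups are identical;
    # differentiation is reported clipped at zero
    if ht <= 0 or ht <= hs:
        return {"Gst": 0.0, "Gst_prime": 0.0, "Gst_dprime": 0.0, "D": 0.0}
    gst = (ht - hs) / ht
    if hs >= 1.0 or k < 2:
        return {"Gst": gst, "Gst_prime": 0.0, "Gst_dprime": 0.0, "D": 0.0}
    gst_prime = gst * (k - 1 + hs) / ((k - 1) * (1 - hs))
    gst_dprime = k * (ht - hs) / ((k * ht - hs) * (1 - hs))
    d = (k / (k - 1)) * (ht - hs) / (1 - hs)
    return {"Gst": gst, "Gst_prime": gst_prime, "Gst_dprime": gst_dprime, "D": d}


@dataclasses.dataclass
class DifferentiationStats:
    per_locus: pd.DataFrame
    overall: dict[str, float]
    p_values: dict[str, float]
    n_perm: int


def differentiation(
    table: GenotypeTable,
    groups: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> DifferentiationStats:
    """G-statistics and Jost's D with permutation p-values.

    Overall statistics use across-locus means of Hs and Ht (polymorphic
    loci only); p-values are the (b+1)/(m+1) proportion of label-permuted
    replicates with statistic >= observed.
    """
    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    hs_df = het_stats(table, groups)
    k = len(labels)
    per_rows = []
    for locus, row in hs_df.iterrows():
        per_rows.append({"locus": locus, **row.to_dict(), **_diff_from_hs_ht(row["Hs"], row["Ht"], k)})
    per_locus = pd.DataFrame(per_rows).set_index("locus")

    def overall_from(df):
        poly = df[df["Ht"] > 0]
        if poly.empty:
            return {"Gst": 0.0, "Gst_prime": 0.0, "Gst_dprime": 0.0, "D": 0.0}
        return _diff_from_hs_ht(float(poly["Hs"].mean()), float(poly["Ht"].mean()), k)

    overall = overall_from(hs_df)
    rng = np.random.default_rng(seed)
    inds = [s for s in table.individuals if s in groups]
    lab_arr = [groups[s] for s in inds]
    exceed = {key: 0 for key in overall}
    for _ in range(n_perm):
        perm = rng.permutation(lab_arr)
        stats = overall_from(het_stats(table, dict(zip(inds, perm))))
        for key in exceed:
            if stats[key] >= overall[key]:
                exceed[key] += 1
    p_values = {key: (exceed[key] + 1) / (n_perm + 1) for key in exceed}
    return DifferentiationStats(per_locus, overall, p_values, n_perm)


@dataclasses.dataclass
class InbreedingStats:
    group: str
    per_locus: pd.Series  # G_IS per polymorphic locus
    mean: float
    ci_low: float
    ci_high: float
    excluded_loci: list[str]


def gis(
    table: GenotypeTable,
    groups: Mapping[str, str],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> list[InbreedingStats]:
    """Within-group inbreeding coefficient G_IS = 1 - Ho/Hs per group.

    Monomorphic loci (Hs = 0) are excluded from the mean and flagged.
    The CI of the mean is a percentile bootstrap over loci.
    """
    rng = np.random.default_rng(seed)
    out = []
    for lab in sorted(set(groups.values())):
        members = {s: lab for s, g in groups.items() if g == lab}
        stats = het_stats(table, members)
        usable = stats[stats["Hs"] > 0]
        excluded = [l for l in stats.index if l not in usable.index]
        g = 1.0 - usable["Ho"] / usable["Hs"]
        g = g.clip(-1.0, 1.0)
        if g.empty:
            out.append(InbreedingStats(lab, g, float("nan"), float("nan"), float("nan"), excluded))
            continue
        boots = [
            g.iloc[rng.integers(0, len(g), size=len(g))].mean() for _ in range(n_boot)
        ]
        alpha = (1 - level) / 2
        out.append(
            InbreedingStats(
                lab,
                g,
                float(g.mean()),
                float(np.quantile(boots, alpha)),
                float(np.quantile(boots, 1 - alpha)),
                excluded,
            )
        )
    return out


# ---------------------------------------------------------------------------
# HWE and LD testing
# ---------------------------------------------------------------------------

def _log_table_prob(genotype_counts: np.ndarray, allele_counts: np.ndarray, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts
    (the Levene / Guo-Thompson exact-test statistic)."""
    n_het = 0
    log_gf = 0.0
    k = genotype_counts.shape[0]
    for a in range(k):
        for b in range(a, k):
            c = genotype_counts[a, b]
            log_gf += gammaln(c + 1)
            if a != b:
                n_het += int(c)
    return (
        gammaln(n + 1)
        - log_gf
        + n_het * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )


def _hwe_mc_pvalue(calls: np.ndarray, k: int, n_mc: int, rng) -> float:
    ok = calls[:, 0] >= 0
    calls = calls[ok]
    n = calls.shape[0]
    if n < 5:
        return float("nan")
    counts = np.zeros((k, k), dtype=int)
    for a, b in calls:
        counts[a, b] += 1
    alleles = np.bincount(calls.ravel(), minlength=k)
    obs = _log_table_prob(counts, alleles, n)
    pool = calls.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        ga = np.sort(pool.reshape(n, 2), axis=1)
        c2 = np.zeros((k, k), dtype=int)
        for a, b in ga:
            c2[a, b] += 1
        if _log_table_prob(c2, alleles, n) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def hwe_tests(
    table: GenotypeTable,
    groups: Mapping[str, str] | None = None,
    n_mc: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo exact Hardy-Weinberg tests per locus (and group).

    Returns locus, group, p and Benjamini-Hochberg q (step-up over loci
    within each group).  Loci with fewer than five genotyped individuals
    in a group are flagged untested.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        grouping = {s: "all" for s in table.individuals}
    else:
        grouping = dict(groups)
    rows = []
    for lab in sorted(set(grouping.values())):
        rows_idx = [table.ind_idx(s) for s, g in grouping.items() if g == lab and s in table._ind_index]
        for j, locus in enumerate(table.loci):
            k = len(table.alleles[locus])
            p = _hwe_mc_pvalue(table.codes[rows_idx, j, :], k, n_mc, rng)
            rows.append({"locus": locus, "group": lab, "p": p, "untested": not np.isfinite(p)})
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for lab, sub in df.groupby("group"):
        ok = sub["p"].notna()
        if ok.any():
            df.loc[sub.index[ok], "q"] = multipletests(sub.loc[ok, "p"], method="fdr_bh")[1]
    df["significant"] = df["q"] < alpha
    return df


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G-test statistic on the contingency table of two code vectors."""
    xi, xv = pd.factorize(x)
    yi, yv = pd.factorize(y)
    obs = np.zeros((len(xv), len(yv)))
    np.add.at(obs, (xi, yi), 1)
    n = obs.sum()
    exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2 * terms.sum())


def ld_tests(
    table: GenotypeTable,
    n_perm: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    loci: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Permutation G-tests of genotypic association for locus pairs.

    For each pair, genotypes are cross-tabulated over individuals typed at
    both loci; one locus's genotype column is permuted to build the null.
    Significant pairs (BH q < alpha) produce a pruning set: the member
    with more missing data is pruned (ties broken lexicographically,
    keeping the smaller locus id).
    """
    rng = np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(table.loci)
    miss = table.missingness_by_locus()
    # genotype category codes per locus: a*8+b fits k<=7
    geno = table.codes[..., 0].astype(int) * 8 + table.codes[..., 1].astype(int)
    rows = []
    for a_i in range(len(loci)):
        for b_i in range(a_i + 1, len(loci)):
            la, lb = loci[a_i], loci[b_i]
            ja, jb = table.locus_idx(la), table.locus_idx(lb)
            ga, gb = geno[:, ja], geno[:, jb]
            ok = (table.codes[:, ja, 0] >= 0) & (table.codes[:, jb, 0] >= 0)
            ga, gb = ga[ok], gb[ok]
            if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2:
                continue
            g_obs = _g_statistic(ga, gb)
            hits = 0
            for _ in range(n_perm):
                if _g_statistic(ga, rng.permutation(gb)) >= g_obs - 1e-12:
                    hits += 1
            rows.append({"locus_a": la, "locus_b": lb, "G": g_obs, "p": (hits + 1) / (n_perm + 1)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df, []
    df["q"] = bh_adjust(df["p"])
    df["significant"] = df["q"] < alpha
    prune: set[str] = set()
    for row in df[df["significant"]].itertuples(index=False):
        a, b = row.locus_a, row.locus_b
        if a in prune or b in prune:
            continue
        ma, mb = miss[a], miss[b]
        if ma > mb:
            prune.add(a)
        elif mb > ma:
            prune.add(b)
        else:
            prune.add(max(a, b))
    return df, sorted(prune)


# ---------------------------------------------------------------------------
# multivariate: K-means + DAPC
# ---------------------------------------------------------------------------

def one_hot_dosage(table: GenotypeTable, center: bool = True) -> tuple[np.ndarray, list[str]]:
    """Allele-dosage one-hot encoding, one column per (locus, allele).

    Missing calls are imputed at the column mean (so they carry no signal
    after centering).
    """
    cols, names = [], []
    for j, locus in enumerate(table.loci):
        k = len(table.alleles[locus])
        calls = table.codes[:, j, :]
        ok = calls[:, 0] >= 0
        dos = np.zeros((table.n_individuals, k))
        for a in range(k):
            dos[:, a] = (calls[:, 0] == a).astype(float) + (calls[:, 1] == a)
        if ok.any():
            dos[~ok] = dos[ok].mean(axis=0)
        cols.append(dos)
        names.extend(f"{locus}:{lab}" for lab in table.alleles[locus])
    X = np.concatenate(cols, axis=1)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    return X, names


@dataclasses.dataclass
class DapcResult:
    labels: pd.Series
    k: int
    bic: pd.Series  # BIC per candidate k
    pc_scores: np.ndarray
    discriminant_scores: np.ndarray | None


def kmeans_dapc(
    table: GenotypeTable,
    n_pc: int = 20,
    k_range: Sequence[int] = range(1, 7),
    seed: int | None = None,
) -> DapcResult:
    """K-means clustering on retained PCs with BIC model choice, then a
    discriminant analysis of principal components (DAPC) ordination.

    BIC(k) = n log(WSS/n) + k log(n) over the retained PC scores, the
    usual criterion for K-means cluster choice in genotype ordinations.
    """
    X, _ = one_hot_dosage(table)
    n = X.shape[0]
    n_pc_eff = min(n_pc, n - 1, X.shape[1])
    if n_pc_eff < n_pc:
        logger.warning("n_pc reduced from %d to %d", n_pc, n_pc_eff)
    pcs = PCA(n_components=n_pc_eff, random_state=seed).fit_transform(X)
    bic = {}
    fits = {}
    for k in k_range:
        if k > n:
            continue
        if k == 1:
            wss = float(((pcs - pcs.mean(0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
            wss = float(km.inertia_)
            labels = km.labels_
        bic[k] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        fits[k] = labels
    best_k = min(bic, key=bic.get)
    labels = fits[best_k]
    disc = None
    if best_k >= 2:
        lda = LinearDiscriminantAnalysis(n_components=min(best_k - 1, pcs.shape[1]))
        disc = lda.fit_transform(pcs, labels)
    return DapcResult(
        pd.Series(labels, index=table.individuals),
        best_k,
        pd.Series(bic),
        pcs,
        disc,
    )
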