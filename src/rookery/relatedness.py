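"""Method-of-moments pairwise relatedness.

The workhorse is the Lynch & Ritland (1999) regression estimator.  With
reference individual x carrying unordered genotype (a, b) and partner y
carrying (c, d), the locus-level estimate and weight are

    r_x = [p_a(d_bc + d_bd) + p_b(d_ac + d_ad) - 4 p_a p_b]
          / [(1 + d_ab)(p_a + p_b) - 4 p_a p_b]
    w_x = [(1 + d_ab)(p_a + p_b) - 4 p_a p_b] / (2 p_a p_b)

with d the Kronecker delta and p the reference allele frequencies.  The
multilocus estimate is the w-weighted average over loci, and the reported
value is symmetrized by averaging the x-reference and y-reference forms.
Expected values are 0.5 for parent-offspring and full siblings, 0.25 for
half siblings and 0 for unrelated pairs; individual estimates may be
negative.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .simulate import BASE_GROUP, MarkerPanel

_EPS = 1e-12
RELATIONSHIP_TRUTH = {"PO": 0.5, "FS": 0.5, "HS": 0.25, "U": 0.0}
MIN_COTYPED_LOCI = 20


@dataclasses.dataclass
class RelatednessEstimate:
    id_x: str
    id_y: str
    r: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_loci: int = 0
    flagged: bool = False


@dataclasses.dataclass
class ReferenceFreqs:
    """Allele-frequency reference with provenance.

    ``n_samples`` records how many individuals contributed; self-referenced
    estimates of pairwise relatedness are biased downward on the order of
    1/n_samples.
    """

    freqs: dict[str, np.ndarray]
    provenance: str = "unspecified"
    n_samples: int = 0

    def __post_init__(self):
        for locus, p in self.freqs.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(f"frequencies at {locus} do not sum to 1")
            self.freqs[locus] = p

    @classmethod
    def from_table(cls, table: GenotypeTable, individuals=None, provenance="sample") -> "ReferenceFreqs":
        inds = table.individuals if individuals is None else list(individuals)
        return cls(table.allele_freqs(inds), provenance, len(inds))

    @classmethod
    def from_panel(cls, panel: MarkerPanel, group: str = BASE_GROUP) -> "ReferenceFreqs":
        return cls(dict(panel.group_freqs(group)), f"panel:{group}", 0)


def lr_locus(gx: tuple[int, int], gy: tuple[int, int], p: np.ndarray) -> tuple[float, float]:
    """Locus-level Lynch-Ritland components with x as reference.

    Returns ``(r_x, w_x)``.  Raises ValueError when a carried allele has
    zero reference frequency (callers skip and log such loci).
    """
    a, b = gx
    c, d = gy
    pa, pb = float(p[a]), float(p[b])
    if pa <= 0 or pb <= 0 or float(p[c]) <= 0 or float(p[d]) <= 0:
        raise ValueError("zero reference frequency for a carried allele")
    dab = 1.0 if a == b else 0.0
    num = pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d)) - 4 * pa * pb
    den = (1.0 + dab) * (pa + pb) - 4 * pa * pb
    if abs(den) < _EPS:
        raise ValueError("degenerate locus (denominator zero)")
    return num / den, den / (2 * pa * pb)


def _freq_matrix(loci: Sequence[str], alleles: Mapping[str, Sequence[str]], freqs: Mapping[str, np.ndarray]):
    max_k = max(len(alleles[l]) for l in loci)
    P = np.zeros((len(loci), max_k))
    for j, l in enumerate(loci):
        P[j, : len(freqs[l])] = freqs[l]
    return P


def _lr_components(ax, bx, ay, by, pa, pb):
    """Vectorized numerator/denominator of the x-reference estimator,
    both scaled by 1/(2 pa pb) so that sums give the weighted average."""
    dab = (ax == bx).astype(float)
    num = (
        pa * ((bx == ay).astype(float) + (bx == by))
        + pb * ((ax == ay).astype(float) + (ax == by))
        - 4 * pa * pb
    )
    den = (1.0 + dab) * (pa + pb) - 4 * pa * pb
    scale = 2 * pa * pb
    ok = scale > _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(ok, num / scale, 0.0), np.where(ok, den / scale, 0.0), ok


def _pair_locus_terms(table: GenotypeTable, freqs: Mapping[str, np.ndarray], rows_x, rows_y):
    """Per-locus scaled components for many pairs at once.

    Returns arrays of shape (n_pairs, n_loci): numerator and denominator
    sums for the x- and y-reference forms plus a validity mask.
    """
    P = _freq_matrix(table.loci, table.alleles, freqs)
    ax = table.codes[rows_x, :, 0].astype(int)
    bx = table.codes[rows_x, :, 1].astype(int)
    ay = table.codes[rows_y, :, 0].astype(int)
    by = table.codes[rows_y, :, 1].astype(int)
    valid = (ax >= 0) & (ay >= 0)
    axs, bxs, ays, bys = [np.where(valid, z, 0) for z in (ax, bx, ay, by)]
    cols = np.arange(table.n_loci)[None, :]
    pax, pbx = P[cols, axs], P[cols, bxs]
    pay, pby = P[cols, ays], P[cols, bys]
    carried_ok = (pax > 0) & (pbx > 0) & (pay > 0) & (pby > 0)
    nx, dx, okx = _lr_components(axs, bxs, ays, bys, pax, pbx)
    ny, dy, oky = _lr_components(ays, bys, axs, bxs, pay, pby)
    ok = valid & carried_ok & okx & oky
    return nx, dx, ny, dy, ok


def pairwise_r(
    table: GenotypeTable,
    ref: ReferenceFreqs,
    pairs: Sequence[tuple[str, str]],
    min_loci: int = MIN_COTYPED_LOCI,
) -> pd.DataFrame:
    """Symmetrized multilocus Lynch-Ritland r for a list of pairs."""
    rows_x = np.array([table.ind_idx(a) for a, _ in pairs])
    rows_y = np.array([table.ind_idx(b) for _, b in pairs])
    nx, dx, ny, dy, ok = _pair_locus_terms(table, ref.freqs, rows_x, rows_y)
    n_ok = ok.sum(axis=1)
    sx = np.where(ok, nx, 0.0).sum(axis=1) / np.maximum(np.where(ok, dx, 0.0).sum(axis=1), _EPS)
    sy = np.where(ok, ny, 0.0).sum(axis=1) / np.maximum(np.where(ok, dy, 0.0).sum(axis=1), _EPS)
    r = 0.5 * (sx + sy)
    flagged = n_ok < min_loci
    r = np.where(flagged, np.nan, r)
    return pd.DataFrame(
        {
            "id_x": [a for a, _ in pairs],
            "id_y": [b for _, b in pairs],
            "r": r,
            "n_loci": n_ok,
            "flagged": flagged,
        }
    )


def multilocus_r(
    x: str,
    y: str,
    table: GenotypeTable,
    ref: ReferenceFreqs,
    min_loci: int = MIN_COTYPED_LOCI,
) -> RelatednessEstimate:
    row = pairwise_r(table, ref, [(x, y)], min_loci=min_loci).iloc[0]
    return RelatednessEstimate(x, y, float(row["r"]), n_loci=int(row["n_loci"]), flagged=bool(row["flagged"]))


def bootstrap_ci(
    x: str,
    y: str,
    table: GenotypeTable,
    ref: ReferenceFreqs,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    min_loci: int = MIN_COTYPED_LOCI,
) -> RelatednessEstimate:
    """Percentile bootstrap CI, resampling loci with replacement."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rows_x = np.array([table.ind_idx(x)])
    rows_y = np.array([table.ind_idx(y)])
    nx, dx, ny, dy, ok = _pair_locus_terms(table, ref.freqs, rows_x, rows_y)
    keep = np.nonzero(ok[0])[0]
    est = multilocus_r(x, y, table, ref, min_loci=min_loci)
    if keep.size < min_loci:
        return est
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, keep.size, size=(n_boot, keep.size))
    cols = keep[idx]
    rb = 0.5 * (
        nx[0][cols].sum(axis=1) / np.maximum(dx[0][cols].sum(axis=1), _EPS)
        + ny[0][cols].sum(axis=1) / np.maximum(dy[0][cols].sum(axis=1), _EPS)
    )
    alpha = (1.0 - level) / 2.0
    est.ci_low = float(np.quantile(rb, alpha))
    est.ci_high = float(np.quantile(rb, 1.0 - alpha))
    return est


# ---------------------------------------------------------------------------
# simulated relationship pairs
# ---------------------------------------------------------------------------

def _hw_draw(rng, P, kvec, n):
    """n HW genotype draws per locus given the padded frequency matrix."""
    cum = np.cumsum(P, axis=1)
    u = rng.random((n, P.shape[0], 2))
    codes = (u[..., None] >= cum[None, :, None, :]).sum(axis=-1)
    codes = np.minimum(codes, (kvec - 1)[None, :, None])
    return np.sort(codes, axis=2).astype(np.int16)


def simulate_relationship_pairs(
    ref: ReferenceFreqs | MarkerPanel,
    relationship: str,
    n: int = 100,
    seed: int | None = None,
    group: str = BASE_GROUP,
    loci: Sequence[str] | None = None,
    alleles: Mapping[str, Sequence[str]] | None = None,
) -> tuple[GenotypeTable, GenotypeTable]:
    """Draw ``n`` genotype pairs of a given relationship class.

    Pairs are built by explicit gamete sharing: PO children receive one
    parental allele; FS pairs share both parents; HS pairs share one; U
    pairs are independent HW draws.  Returns two aligned tables.
    """
    if relationship not in RELATIONSHIP_TRUTH:
        raise ValueError(f"relationship must be one of {sorted(RELATIONSHIP_TRUTH)}")
    if isinstance(ref, MarkerPanel):
        freqs = ref.group_freqs(group)
        loci = ref.loci
        alleles = ref.alleles
    else:
        freqs = ref.freqs
        if loci is None:
            loci = list(freqs)
        if alleles is None:
            alleles = {l: [f"a{i}" for i in range(len(freqs[l]))] for l in loci}
    kvec = np.array([len(freqs[l]) for l in loci])
    P = _freq_matrix(loci, alleles, freqs)
    rng = np.random.default_rng(seed)
    m = len(loci)

    def hw(count):
        return _hw_draw(rng, P, kvec, count)

    def child(pa, pb):
        out = np.empty((n, m, 2), dtype=np.int16)
        pick_a = rng.integers(0, 2, size=(n, m))
        pick_b = rng.integers(0, 2, size=(n, m))
        rows = np.arange(n)[:, None]
        colsm = np.arange(m)[None, :]
        out[..., 0] = pa[rows, colsm, pick_a]
        out[..., 1] = pb[rows, colsm, pick_b]
        return out

    if relationship == "U":
        gx, gy = hw(n), hw(n)
    elif relationship == "PO":
        gx = hw(n)  # the parent
        pop = hw(n)
        gy = child(gx, pop)
    elif relationship == "FS":
        mo, fa = hw(n), hw(n)
        gx, gy = child(mo, fa), child(mo, fa)
    else:  # HS: shared father, independent mothers
        fa = hw(n)
        mo1, mo2 = hw(n), hw(n)
        gx, gy = child(mo1, fa), child(mo2, fa)

    ids_x = [f"{relationship}_x{i:05d}" for i in range(n)]
    ids_y = [f"{relationship}_y{i:05d}" for i in range(n)]
    tx = GenotypeTable(gx, ids_x, list(loci), alleles)
    ty = GenotypeTable(gy, ids_y, list(loci), alleles)
    return tx, ty


def _paired_r(estimator, tx: GenotypeTable, ty: GenotypeTable, ref: ReferenceFreqs) -> np.ndarray:
    merged = GenotypeTable(
        np.concatenate([tx.codes, ty.codes], axis=0),
        tx.individuals + ty.individuals,
        tx.loci,
        tx.alleles,
    )
    pairs = list(zip(tx.individuals, ty.individuals))
    return estimator(merged, ref, pairs)


def lynch_ritland(table, ref, pairs) -> np.ndarray:
    return pairwise_r(table, ref, pairs)["r"].to_numpy()


def queller_goodnight(table, ref, pairs) -> np.ndarray:
    """Symmetrized Queller-Goodnight estimator (optional alternative)."""
    rows_x = np.array([table.ind_idx(a) for a, _ in pairs])
    rows_y = np.array([table.ind_idx(b) for _, b in pairs])
    P = _freq_matrix(table.loci, table.alleles, ref.freqs)
    cols = np.arange(table.n_loci)[None, :]

    def one_direction(rx, ry):
        ax, bx = table.codes[rx, :, 0].astype(int), table.codes[rx, :, 1].astype(int)
        ay, by = table.codes[ry, :, 0].astype(int), table.codes[ry, :, 1].astype(int)
        valid = (ax >= 0) & (ay >= 0)
        axs, bxs, ays, bys = [np.where(valid, z, 0) for z in (ax, bx, ay, by)]
        pa, pb = P[cols, axs], P[cols, bxs]
        num = (
            0.5
            * (
                (axs == ays).astype(float)
                + (axs == bys)
                + (bxs == ays)
                + (bxs == bys)
            )
            - pa
            - pb
        )
        den = 1.0 + (axs == bxs).astype(float) - pa - pb
        ok = valid & (np.abs(den) > _EPS)
        return np.where(ok, num, 0.0).sum(1), np.where(ok, den, 0.0).sum(1)

    nx, dx = one_direction(rows_x, rows_y)
    ny, dy = one_direction(rows_y, rows_x)
    return 0.5 * (nx / np.maximum(dx, _EPS) + ny / np.maximum(dy, _EPS))


ESTIMATORS: dict[str, Callable] = {
    "lynch_ritland": lynch_ritland,
    "queller_goodnight": queller_goodnight,
}


def evaluate_estimators(
    ref: ReferenceFreqs | MarkerPanel,
    estimators: Mapping[str, Callable] | None = None,
    n_per_class: int = 100,
    seed: int | None = None,
    group: str = BASE_GROUP,
) -> tuple[pd.DataFrame, str]:
    """Correlate each estimator with the truth over simulated pairs.

    Simulates ``n_per_class`` pairs of each of PO/FS/HS/U, estimates r,
    and reports the Pearson correlation with the class truth values
    {0.5, 0.5, 0.25, 0}; the best-correlated estimator is selected.
    """
    estimators = dict(estimators or ESTIMATORS)
    ss = np.random.SeedSequence(seed).spawn(4)
    if isinstance(ref, MarkerPanel):
        freq_ref = ReferenceFreqs.from_panel(ref, group)
    else:
        freq_ref = ref
    truths, sims = [], []
    for cls_seed, cls in zip(ss, ["PO", "FS", "HS", "U"]):
        tx, ty = simulate_relationship_pairs(
            ref, cls, n=n_per_class, seed=int(cls_seed.generate_state(1)[0] % 2**31), group=group
        )
        sims.append((tx, ty))
        truths.append(np.full(n_per_class, RELATIONSHIP_TRUTH[cls]))
    truth = np.concatenate(truths)
    if len({t for t in truth}) < 2:
        raise ValueError("need at least two relationship classes")
    rows = []
    for name, fn in estimators.items():
        est = np.concatenate([_paired_r(fn, tx, ty, freq_ref) for tx, ty in sims])
        ok = np.isfinite(est)
        corr = float(np.corrcoef(truth[ok], est[ok])[0, 1])
        rows.append((name, corr))
    table = pd.DataFrame(rows, columns=["estimator", "correlation"]).sort_values(
        "correlation", ascending=False, ignore_index=True
    )
    return table, str(table.loc[0, "estimator"])


# ---------------------------------------------------------------------------
# reference-frequency bias experiments
# ---------------------------------------------------------------------------

def reference_bias_experiment(
    n_ref: int,
    panel: MarkerPanel,
    n_focal: int = 25,
    seed: int | None = None,
    group: str = BASE_GROUP,
    family_structure: bool = False,
) -> float:
    """Mean Lynch-Ritland r among unrelated individuals under a
    self-estimated allele-frequency reference.

    ``n_ref`` individuals (including the ``n_focal`` focal adults) supply
    the sample allele frequencies; the mean pairwise r among the focal
    adults is returned.  Under the 1/N rule the expectation is about
    -1/n_ref.  With ``family_structure`` the non-focal reference members
    are offspring of the focal adults instead of independent draws, which
    concentrates the reference on the breeders' alleles and drags the bias
    back toward -1/n_focal.
    """
    if n_ref < 3:
        raise ValueError("n_ref must be >= 3")
    n_focal = min(n_focal, n_ref)
    rng = np.random.default_rng(seed)
    freqs = panel.group_freqs(group)
    kvec = np.array([len(freqs[l]) for l in panel.loci])
    P = _freq_matrix(panel.loci, panel.alleles, freqs)
    adults = _hw_draw(rng, P, kvec, n_focal)
    extra = n_ref - n_focal
    blocks = [adults]
    if extra > 0:
        if family_structure:
            rows_m = rng.integers(0, n_focal, size=extra)
            rows_f = rng.integers(0, n_focal, size=extra)
            m = panel.n_loci
            pick_m = rng.integers(0, 2, size=(extra, m))
            pick_f = rng.integers(0, 2, size=(extra, m))
            kids = np.empty((extra, m, 2), dtype=np.int16)
            r_idx = np.arange(extra)[:, None]
            c_idx = np.arange(m)[None, :]
            kids[..., 0] = adults[rows_m][r_idx, c_idx, pick_m]
            kids[..., 1] = adults[rows_f][r_idx, c_idx, pick_f]
            blocks.append(kids)
        else:
            blocks.append(_hw_draw(rng, P, kvec, extra))
    codes = np.concatenate(blocks, axis=0)
    ids = [f"I{i:05d}" for i in range(n_ref)]
    table = GenotypeTable(codes, ids, panel.loci, panel.alleles)
    ref = ReferenceFreqs.from_table(table, provenance=f"self:{n_ref}")
    focal = ids[:n_focal]
    pairs = [(focal[i], focal[j]) for i in range(n_focal) for j in range(i + 1, n_focal)]
    r = pairwise_r(table, ref, pairs)["r"].to_numpy()
    return float(np.nanmean(r))


def estimator_correlation_experiment(
    seed: int | None = None,
    n_replicates: int = 12,
    n_loci: int = 135,
    n_per_class: int = 100,
) -> float:
    """Mean Lynch-Ritland truth-correlation over independent replicates.

    Each replicate draws a fresh default-condition panel (135 loci, mean
    ~2.61 alleles), simulates ``n_per_class`` pairs of each relatedness
    class, and correlates the estimates with {0.5, 0.5, 0.25, 0} under
    true frequencies.
    """
    from .simulate import simulate_panel

    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    cors = []
    for rep in ss:
        s1, s2 = [int(x.generate_state(1)[0] % 2**31) for x in rep.spawn(2)]
        panel = simulate_panel(n_loci, seed=s1)
        table, _ = evaluate_estimators(
            panel, {"lynch_ritland": lynch_ritland}, n_per_class=n_per_class, seed=s2
        )
        cors.append(float(table.loc[0, "correlation"]))
    return float(np.mean(cors))


def reference_bias_magnitude(
    n_ref: int,
    seed: int | None = None,
    n_replicates: int = 20,
    n_loci: int = 135,
    n_focal: int = 25,
    family_structure: bool = False,
) -> float:
    """|mean pairwise r| among self-referenced unrelated adults, averaged
    over replicate simulations (the 1/N reference-bias experiment)."""
    from .simulate import simulate_panel

    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    vals = []
    for rep in ss:
        s1, s2 = [int(x.generate_state(1)[0] % 2**31) for x in rep.spawn(2)]
        panel = simulate_panel(n_loci, seed=s1)
        vals.append(
            reference_bias_experiment(
                n_ref, panel, n_focal=n_focal, seed=s2, family_structure=family_structure
            )
        )
    return float(abs(np.mean(vals)))


def relatedness_edge_list(pairs_df: pd.DataFrame) -> pd.DataFrame:
    """Edge list for network rendering: weight 1 - r, edges with r <= 0 omitted."""
    keep = pairs_df[pairs_df["r"] > 0].copy()
    keep["weight"] = 1.0 - keep["r"]
    return keep[["id_x", "id_y", "r", "weight"]].reset_index(drop=True)
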