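"""Pseudo-likelihood kin classification.

Relationship hypotheses are IBD-coefficient triples (k0, k1, k2): the
probabilities that a pair shares 0, 1 or 2 alleles identical by descent
(parent-offspring (0,1,0), full siblings (1/4,1/2,1/4), half siblings
(1/2,1/2,0), unrelated (1,0,0)).  Conditional on one member's genotype,

    P(gy | gx, k) = k0 P_HW(gy) + k1 P_1(gy | gx) + k2 [gy == gx]

where P_1 places one uniformly chosen allele of gx in gy and draws the
other from the population.  Genotyping error is folded in per locus by
mixing toward Hardy-Weinberg: P_obs = (1 - e) P + e P_HW.  Log-likelihood
ratios sum over co-typed loci; Monte-Carlo calibration reports type-I and
type-II error rates of the threshold-zero decision rule.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .relatedness import _freq_matrix, simulate_relationship_pairs
from .simulate import BASE_GROUP, MarkerPanel

NEG_INF_SENTINEL = -1e30


@dataclasses.dataclass(frozen=True)
class RelationshipModel:
    label: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self):
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k0 + k1 + k2 must equal 1")


MODELS: dict[str, RelationshipModel] = {
    "PO": RelationshipModel("PO", 0.0, 1.0, 0.0),
    "FS": RelationshipModel("FS", 0.25, 0.5, 0.25),
    "HS": RelationshipModel("HS", 0.5, 0.5, 0.0),
    "U": RelationshipModel("U", 1.0, 0.0, 0.0),
}

STANDARD_TESTS: tuple[tuple[str, str], ...] = (("PO", "U"), ("FS", "U"), ("HS", "U"), ("FS", "HS"))


@dataclasses.dataclass
class KinLLR:
    id_x: str
    id_y: str
    h1: str
    h2: str
    llr: float
    flagged: bool = False


def _pair_probs(ax, bx, ay, by, pa_y, pb_y, p_of, model: RelationshipModel):
    """Vectorized P(gy | gx, model) before error mixing.

    ``p_of(u, side)`` is not used; frequencies are passed as arrays:
    pa_y, pb_y are the frequencies of y's two alleles.
    """
    het_y = ay != by
    p_hw = np.where(het_y, 2 * pa_y * pb_y, pa_y * pa_y)

    def given_ibd(u):
        # P(gy | one IBD allele u, other from population)
        hom = (~het_y) & (u == ay)
        het = het_y & ((u == ay) | (u == by))
        other = np.where(u == ay, pb_y, pa_y)
        return np.where(hom, pa_y, np.where(het, other, 0.0))

    p1 = 0.5 * (given_ibd(ax) + given_ibd(bx))
    p2 = ((ax == ay) & (bx == by)).astype(float)
    return model.k0 * p_hw + model.k1 * p1 + model.k2 * p2, p_hw


def genotype_log_likelihoods(
    table_x: GenotypeTable,
    table_y: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    models: Sequence[RelationshipModel],
    e: float = 0.02,
) -> dict[str, np.ndarray]:
    """Multilocus log-likelihood per aligned pair, per model.

    Rows of the two tables are aligned pairs over identical loci.  Returns
    ``{model.label: array(n_pairs)}``; zero-probability genotypes with
    ``e = 0`` yield the large negative sentinel.
    """
    if table_x.loci != table_y.loci:
        raise ValueError("tables must share loci")
    P = _freq_matrix(table_x.loci, table_x.alleles, freqs)
    cols = np.arange(table_x.n_loci)[None, :]
    ax, bx = table_x.codes[..., 0].astype(int), table_x.codes[..., 1].astype(int)
    ay, by = table_y.codes[..., 0].astype(int), table_y.codes[..., 1].astype(int)
    valid = (ax >= 0) & (ay >= 0)
    axs, bxs, ays, bys = [np.where(valid, z, 0) for z in (ax, bx, ay, by)]
    pa_y, pb_y = P[cols, ays], P[cols, bys]
    out = {}
    for model in models:
        p, p_hw = _pair_probs(axs, bxs, ays, bys, pa_y, pb_y, None, model)
        p_obs = (1.0 - e) * p + e * p_hw
        with np.errstate(divide="ignore"):
            ll = np.where(valid, np.log(np.maximum(p_obs, 0.0)), 0.0)
        ll = np.where(valid & (p_obs <= 0.0), NEG_INF_SENTINEL, ll)
        out[model.label] = ll.sum(axis=1)
    return out


def pair_loglik(
    gx: GenotypeTable | tuple,
    gy,
    freqs: Mapping[str, np.ndarray],
    model: RelationshipModel,
    e: float = 0.02,
    loci: Sequence[str] | None = None,
) -> float:
    """Multilocus log P(gy | gx, model) for a single pair.

    ``gx``/``gy`` may be single-row GenotypeTables, or (with ``loci``)
    plain code arrays of shape (n_loci, 2).
    """
    if isinstance(gx, GenotypeTable):
        tx, ty = gx, gy
    else:
        if loci is None:
            raise ValueError("loci required with raw code arrays")
        alleles = {l: [f"a{i}" for i in range(len(freqs[l]))] for l in loci}
        tx = GenotypeTable(np.asarray(gx)[None, :, :], ["x"], list(loci), alleles)
        ty = GenotypeTable(np.asarray(gy)[None, :, :], ["y"], list(loci), alleles)
    return float(genotype_log_likelihoods(tx, ty, freqs, [model], e=e)[model.label][0])


def llr(
    pair: tuple[str, str],
    table: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    h1: str,
    h2: str,
    e: float = 0.02,
) -> KinLLR:
    """Log-likelihood ratio Lambda = loglik(H1) - loglik(H2) for one pair."""
    x, y = pair
    tx = table.subset(individuals=[x])
    ty = table.subset(individuals=[y])
    ll = genotype_log_likelihoods(tx, ty, freqs, [MODELS[h1], MODELS[h2]], e=e)
    l1, l2 = float(ll[h1][0]), float(ll[h2][0])
    flagged = l1 <= NEG_INF_SENTINEL / 2 or l2 <= NEG_INF_SENTINEL / 2
    return KinLLR(x, y, h1, h2, l1 - l2, flagged)


def pairwise_llr(
    table: GenotypeTable,
    freqs: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    h1: str,
    h2: str,
    e: float = 0.02,
) -> np.ndarray:
    rows_x = [table.ind_idx(a) for a, _ in pairs]
    rows_y = [table.ind_idx(b) for _, b in pairs]
    tx = GenotypeTable(table.codes[rows_x], [f"x{i}" for i in range(len(pairs))], table.loci, table.alleles)
    ty = GenotypeTable(table.codes[rows_y], [f"y{i}" for i in range(len(pairs))], table.loci, table.alleles)
    ll = genotype_log_likelihoods(tx, ty, freqs, [MODELS[h1], MODELS[h2]], e=e)
    return ll[h1] - ll[h2]


@dataclasses.dataclass
class CalibrationResult:
    summary: pd.DataFrame  # test, type_I, type_II, and Lambda quantiles
    distributions: dict[tuple[str, str], dict[str, np.ndarray]]  # (h1,h2) -> class -> Lambda


def mc_calibrate(
    ref: MarkerPanel | Mapping[str, np.ndarray],
    tests: Sequence[tuple[str, str]] = STANDARD_TESTS,
    n: int = 10000,
    e: float = 0.02,
    seed: int | None = None,
    group: str = BASE_GROUP,
    threshold: float = 0.0,
) -> CalibrationResult:
    """Monte-Carlo calibration of the Lambda > threshold decision rule.

    For each test (H1 vs H2), ``n`` pairs are simulated under each true
    class; the type-I error is the fraction of H2-true pairs exceeding the
    threshold, the type-II error the fraction of H1-true pairs at or below
    it.  The empirical Lambda distributions are kept for density plots.
    """
    if isinstance(ref, MarkerPanel):
        freqs = ref.group_freqs(group)
    else:
        freqs = dict(ref)
    classes = sorted({h for t in tests for h in t})
    ss = np.random.SeedSequence(seed).spawn(len(classes))
    sims = {}
    for cls, cseed in zip(classes, ss):
        sims[cls] = simulate_relationship_pairs(
            _RefShim(freqs), cls, n=n, seed=int(cseed.generate_state(1)[0] % 2**31)
        )
    rows, dists = [], {}
    for h1, h2 in tests:
        models = [MODELS[h1], MODELS[h2]]
        lam = {}
        for cls in (h1, h2):
            tx, ty = sims[cls]
            ll = genotype_log_likelihoods(tx, ty, freqs, models, e=e)
            lam[cls] = ll[h1] - ll[h2]
        type1 = float(np.mean(lam[h2] > threshold))
        type2 = float(np.mean(lam[h1] <= threshold))
        rows.append(
            {
                "test": f"{h1}-{h2}",
                "type_I": type1,
                "type_II": type2,
                "lambda_h1_median": float(np.median(lam[h1])),
                "lambda_h2_median": float(np.median(lam[h2])),
            }
        )
        dists[(h1, h2)] = lam
    return CalibrationResult(pd.DataFrame(rows), dists)


class _RefShim:
    """Adapter so mc_calibrate can reuse simulate_relationship_pairs with bare freqs."""

    def __init__(self, freqs):
        self.freqs = dict(freqs)
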