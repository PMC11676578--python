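"""Weir-Cockerham F_ST with a locus bootstrap, and cross-dataset genotype concordance.

theta follows Weir & Cockerham (1984): per biallelic locus the three
variance components are estimated from the per-population sample sizes,
allele frequencies, and observed heterozygote frequencies —

    a  among populations,
    b  among individuals within populations,
    c  within individuals,

and the multi-locus estimate is the ratio of sums
theta = sum_l a_l / sum_l (a_l + b_l + c_l), the combination Weir &
Cockerham recommend (and what hierfstat reports). Negative estimates are
reported as computed, never clipped: clipping would bias the bootstrap
null check. Confidence intervals come from a percentile bootstrap that
resamples loci with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genio import MISSING, PopulationMap, SnpGenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Multi-locus theta for one population pair, optionally with a bootstrap CI."""

    pop1: str
    pop2: str
    theta: float
    per_locus_components: np.ndarray  # (n_loci, 3) columns a, b, c
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    ci_level: Optional[float] = None

    @property
    def significant(self) -> Optional[bool]:
        """CI excludes zero (None when no CI was computed)."""
        if self.ci_low is None or self.ci_high is None:
            return None
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass
class ConcordanceResult:
    """Per cross-dataset sample pair: shared-call counts and match rate."""

    rates: pd.DataFrame  # sample_a, sample_b, n_compared, n_matched, rate
    best_matches: pd.DataFrame  # per sample_a: best sample_b, rate, matched flag
    threshold: float


def _wc_components(
    genotypes_by_pop: Sequence[np.ndarray],
) -> np.ndarray:
    """Weir-Cockerham (1984) per-locus variance components (a, b, c).

    ``genotypes_by_pop[k]`` is the (n_k, L) dosage matrix for population k
    (values 0/1/2; MISSING allowed and excluded per locus). Loci where no
    population has two called individuals, or with zero total variance,
    contribute (0, 0, 0).
    """
    r = len(genotypes_by_pop)
    L = genotypes_by_pop[0].shape[1]
    n = np.zeros((r, L))  # called individuals per pop per locus
    p = np.zeros((r, L))  # alt-allele frequency
    h = np.zeros((r, L))  # observed heterozygote frequency
    for k, g in enumerate(genotypes_by_pop):
        called = g != MISSING
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, g, 0).sum(axis=0) / (2 * n[k])
            h[k] = np.where(called, g == 1, False).sum(axis=0) / n[k]

    valid = (n >= 2).all(axis=0)
    components = np.zeros((L, 3))
    if not valid.any():
        return components

    n_v = n[:, valid]
    p_v = p[:, valid]
    h_v = h[:, valid]
    n_bar = n_v.mean(axis=0)
    n_c = (r * n_bar - (n_v**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_v * p_v).sum(axis=0) / (r * n_bar)
    s2 = (n_v * (p_v - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_v * h_v).sum(axis=0) / (r * n_bar)

    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (pq - (r - 1) / r * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0

    # Monomorphic loci (no variance anywhere) contribute nothing.
    poly = (pq > 0) | (h_bar > 0)
    out = np.zeros((valid.sum(), 3))
    out[poly] = np.column_stack([a, b, c])[poly]
    components[valid] = out
    return components


def _theta_from_components(components: np.ndarray) -> float:
    total = components.sum(axis=0)
    denom = total.sum()
    if denom == 0.0:
        return float("nan")
    return float(total[0] / denom)


def wc_fst(
    matrix: SnpGenotypeMatrix,
    popmap: PopulationMap,
    pop1: str,
    pop2: str,
) -> FstResult:
    """Multi-locus Weir-Cockerham theta between two populations (no CI)."""
    groups = []
    for pop in (pop1, pop2):
        ids = popmap.samples(pop)
        ids = [s for s in ids if s in matrix.sample_ids]
        if len(ids) < 2:
            raise ParameterError(
                f"population {pop!r} has {len(ids)} genotyped samples; need >= 2"
            )
        idx = [matrix.sample_index(s) for s in ids]
        groups.append(matrix.genotypes[idx].astype(np.float64))
    components = _wc_components(groups)
    return FstResult(pop1, pop2, _theta_from_components(components), components)


def bootstrap_fst(
    matrix: SnpGenotypeMatrix,
    popmap: PopulationMap,
    pop1: str,
    pop2: str,
    n_boot: int = 1000,
    ci_level: float = 0.99,
    seed: int = 0,
) -> FstResult:
    """theta plus a percentile bootstrap CI from resampling loci with replacement."""
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if not 0.0 < ci_level < 1.0:
        raise ParameterError("ci_level must be in (0, 1)")
    result = wc_fst(matrix, popmap, pop1, pop2)
    comp = result.per_locus_components
    L = comp.shape[0]
    rng = np.random.default_rng(seed)
    thetas = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, L, L)
        thetas[i] = _theta_from_components(comp[idx])
    tail = (1.0 - ci_level) / 2.0
    result.ci_low = float(np.nanquantile(thetas, tail))
    result.ci_high = float(np.nanquantile(thetas, 1.0 - tail))
    result.n_boot = n_boot
    result.ci_level = ci_level
    return result


def pairwise_fst_matrix(
    matrix: SnpGenotypeMatrix,
    popmap: PopulationMap,
    populations: Optional[Sequence[str]] = None,
    n_boot: int = 1000,
    ci_level: float = 0.99,
    seed: int = 0,
) -> dict[tuple[str, str], FstResult]:
    """bootstrap_fst for every unordered population pair.

    Each pair gets an independent bootstrap stream spawned from ``seed``,
    so the result does not depend on pair evaluation order.
    """
    if populations is None:
        populations = popmap.populations
    if len(populations) < 2:
        raise ParameterError("need at least two populations")
    seeds = np.random.SeedSequence(seed).spawn(
        len(list(combinations(populations, 2)))
    )
    results: dict[tuple[str, str], FstResult] = {}
    for (p1, p2), ss in zip(combinations(populations, 2), seeds):
        pair_seed = int(ss.generate_state(1)[0] % (2**31))
        results[(p1, p2)] = bootstrap_fst(
            matrix, popmap, p1, p2, n_boot=n_boot, ci_level=ci_level, seed=pair_seed
        )
    return results


def fst_matrix_dataframe(
    results: dict[tuple[str, str], FstResult]
) -> pd.DataFrame:
    rows = [
        {
            "pop1": r.pop1, "pop2": r.pop2, "theta": r.theta,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "n_boot": r.n_boot, "ci_level": r.ci_level,
            "significant": r.significant,
        }
        for r in results.values()
    ]
    return pd.DataFrame(rows)


def genotype_concordance(
    a: SnpGenotypeMatrix,
    b: SnpGenotypeMatrix,
    threshold: float = 0.96,
) -> ConcordanceResult:
    """Genotype match rates for every cross-dataset sample pair.

    Loci are intersected on (chromosome, position) with ref/alt
    reconciliation as in the merge; a pair's rate is the fraction of
    matching dosages over loci where both calls are non-missing (strictly
    greater than ``threshold`` flags a match). Pairs with nothing to
    compare get a NaN rate and are never flagged.
    """
    b_index = {(l.chrom, l.pos): j for j, l in enumerate(b.loci)}
    cols_a: list[int] = []
    cols_b: list[int] = []
    flip_b: list[bool] = []
    for i, la in enumerate(a.loci):
        j = b_index.get((la.chrom, la.pos))
        if j is None:
            continue
        lb = b.loci[j]
        if (la.ref, la.alt) == (lb.ref, lb.alt):
            flip = False
        elif (la.ref, la.alt) == (lb.alt, lb.ref):
            flip = True
        else:
            continue
        cols_a.append(i)
        cols_b.append(j)
        flip_b.append(flip)
    if not cols_a:
        raise ParameterError("datasets share no reconcilable loci")
    ga = a.genotypes[:, cols_a].astype(np.int16)
    gb = b.genotypes[:, cols_b].astype(np.int16).copy()
    flip_arr = np.array(flip_b)
    if flip_arr.any():
        missing = gb[:, flip_arr] == MISSING
        flipped = 2 - gb[:, flip_arr]
        flipped[missing] = MISSING
        gb[:, flip_arr] = flipped

    rows = []
    for i, sa in enumerate(a.sample_ids):
        for j, sb in enumerate(b.sample_ids):
            both = (ga[i] != MISSING) & (gb[j] != MISSING)
            n_compared = int(both.sum())
            n_matched = int((ga[i][both] == gb[j][both]).sum())
            rate = n_matched / n_compared if n_compared else float("nan")
            rows.append((sa, sb, n_compared, n_matched, rate))
    rates = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_compared", "n_matched", "rate"]
    )
    best_rows = []
    for sa, grp in rates.groupby("sample_a", sort=False):
        evaluable = grp.dropna(subset=["rate"])
        if evaluable.empty:
            best_rows.append((sa, None, float("nan"), False, False))
            continue
        best = evaluable.loc[evaluable["rate"].idxmax()]
        best_rows.append(
            (sa, best["sample_b"], float(best["rate"]),
             bool(best["rate"] > threshold), True)
        )
    best_matches = pd.DataFrame(
        best_rows,
        columns=["sample_a", "best_match", "rate", "matched", "evaluable"],
    )
    return ConcordanceResult(rates, best_matches, threshold)
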