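"""Per-pair excess-derived-allele counts and cross-population replicate summaries.

For each cross-population pair of individuals, every polarized locus is
classified by the orientation of its two derived dosages. Six orientations
are informative with an excess on one side — (0,1), (1,2), (0,2) credit the
second individual with one, one, and two excess derived alleles, and their
mirrors (1,0), (2,1), (2,0) credit the first. (1,1) passes the
informativeness filter but carries equal derived counts on both sides and
contributes nothing. Each individual's derived-allele proportion within a
pair is its share of the pair's total excess; under neutrality and a
symmetric demography it is expected to be 0.5, and a population whose
germline accumulates mutations faster shows a mean proportion above 0.5.

A replicate runs all n x n cross-population pairs (the study design uses
n = 5 per population, hence 25 pairs) and reports per-population mean
proportions and the standard deviation of the proportions over pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MissingDataError, ParameterError
from .genio import MISSING, PopulationMap, SnpGenotypeMatrix
from .polarize import PolarizedDataset, polarize

log = logging.getLogger(__name__)

#: The six informative orientations (dosage_a, dosage_b), in the
#: conventional listing order 0/0:0/1, 0/1:1/1, 0/0:1/1, 0/1:0/0,
#: 1/1:0/1, 1/1:0/0.
ORIENTATIONS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 2), (0, 2), (1, 0), (2, 1), (2, 0),
)


def count_excess_derived(g_a: int, g_b: int) -> tuple[int, int]:
    """Excess derived alleles credited to each side of an informative pair.

    (2, 0) counts two excess derived alleles for the first individual;
    (0, 1), (1, 2) and mirrors count one; (1, 1) counts zero for both.
    Requires an informative pair (0 < g_a + g_b < 4).
    """
    from .polarize import pair_informative

    if not pair_informative(g_a, g_b):
        raise ParameterError(
            f"pair ({g_a},{g_b}) is uninformative; no excess defined"
        )
    diff = g_a - g_b
    return (max(diff, 0), max(-diff, 0))


@dataclass
class PairDerivedResult:
    """Orientation counts and excess-derived totals for one pair."""

    sample_a: str
    sample_b: str
    orientation_counts: dict[tuple[int, int], int]
    d_a: int
    d_b: int
    prop_a: Optional[float]  # None when d_a + d_b == 0
    prop_b: Optional[float]
    n_informative: int

    @property
    def defined(self) -> bool:
        return self.prop_a is not None


@dataclass
class ReplicateSummary:
    """All pair results of one replicate plus the population-level summary."""

    pairs: list[PairDerivedResult]
    mean_prop_a: float
    mean_prop_b: float
    sd: float
    n_excluded: int
    replicate_label: str = ""
    outgroup_label: str = ""
    attrition: dict = field(default_factory=dict)

    def pairs_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            row = {"sample_a": p.sample_a, "sample_b": p.sample_b}
            for (ga, gb), count in p.orientation_counts.items():
                row[f"n_{ga}{gb}"] = count
            row.update(
                d_a=p.d_a, d_b=p.d_b, prop_a=p.prop_a, prop_b=p.prop_b,
                n_informative=p.n_informative,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicate": self.replicate_label,
                    "outgroup": self.outgroup_label,
                    "n_pairs": len(self.pairs),
                    "n_excluded": self.n_excluded,
                    "mean_prop_a": self.mean_prop_a,
                    "mean_prop_b": self.mean_prop_b,
                    # sd of the per-pair proportions (identical for the two
                    # populations since proportions within a pair sum to 1)
                    "sd": self.sd,
                }
            ]
        )


def pair_summary(
    dataset: PolarizedDataset, sample_a: str, sample_b: str
) -> PairDerivedResult:
    """Scan all loci of one pair, accumulating orientation counts and excess."""
    ga = dataset.genotypes[dataset.sample_index(sample_a)].astype(np.int64)
    gb = dataset.genotypes[dataset.sample_index(sample_b)].astype(np.int64)
    total = ga + gb
    informative = (total > 0) & (total < 4)
    counts = {
        (x, y): int(((ga == x) & (gb == y)).sum()) for (x, y) in ORIENTATIONS
    }
    diff = ga - gb
    d_a = int(np.clip(diff, 0, None).sum())  # uninformative pairs have diff 0
    d_b = int(np.clip(-diff, 0, None).sum())
    if d_a + d_b > 0:
        prop_a: Optional[float] = d_a / (d_a + d_b)
        prop_b: Optional[float] = d_b / (d_a + d_b)
    else:
        prop_a = prop_b = None
    return PairDerivedResult(
        sample_a, sample_b, counts, d_a, d_b, prop_a, prop_b,
        int(informative.sum()),
    )


def replicate_analysis(
    dataset: PolarizedDataset,
    pop_a_ids: Sequence[str],
    pop_b_ids: Sequence[str],
    replicate_label: str = "",
    outgroup_label: str = "",
) -> ReplicateSummary:
    """All cross-population pairs (|A| x |B|), then per-population means.

    Pairs whose excess total is zero have no defined proportion; they are
    excluded from the means (with a logged warning) rather than scored 0.5.
    The reported sd is the sample standard deviation of the per-pair
    proportions; because each pair's two proportions sum to 1, it is the
    same number for both populations.
    """
    overlap = set(pop_a_ids) & set(pop_b_ids)
    if overlap:
        raise ParameterError(f"population id lists overlap: {sorted(overlap)}")
    pairs = [
        pair_summary(dataset, a, b) for a, b in product(pop_a_ids, pop_b_ids)
    ]
    defined = [p for p in pairs if p.defined]
    n_excluded = len(pairs) - len(defined)
    if n_excluded:
        log.warning(
            "replicate %s: %d pair(s) had zero excess-derived total and were "
            "excluded from the means", replicate_label or "<unnamed>", n_excluded,
        )
    if not defined:
        mean_a = mean_b = sd = float("nan")
    else:
        props_a = np.array([p.prop_a for p in defined])
        mean_a = float(props_a.mean())
        mean_b = float(1.0 - props_a.mean())
        sd = float(props_a.std(ddof=1)) if len(defined) > 1 else 0.0
    return ReplicateSummary(
        pairs, mean_a, mean_b, sd, n_excluded, replicate_label, outgroup_label,
    )


def run_derived_workflow(
    matrix: SnpGenotypeMatrix,
    outgroup_ids: Sequence[str],
    pop_a_ids: Sequence[str],
    pop_b_ids: Sequence[str],
    n_per_pop: int = 5,
    seed: Optional[int] = None,
    replicate_label: str = "",
    outgroup_label: str = "",
) -> ReplicateSummary:
    """Missingness filter -> polarization -> all-pairs replicate analysis.

    When an id list is larger than ``n_per_pop``, a seeded random subsample
    of ``n_per_pop`` ids is drawn (the study design samples unrelated
    individuals; relatedness screening is the caller's responsibility).
    Locus attrition at each stage is logged and recorded on the returned
    summary's ``attrition`` dict.
    """
    pop_a_ids = list(pop_a_ids)
    pop_b_ids = list(pop_b_ids)
    if len(pop_a_ids) < n_per_pop or len(pop_b_ids) < n_per_pop:
        raise ParameterError(
            f"need at least n_per_pop={n_per_pop} ids per population"
        )
    if len(pop_a_ids) > n_per_pop or len(pop_b_ids) > n_per_pop:
        if seed is None:
            raise ParameterError(
                "subsampling requires an explicit seed for reproducibility"
            )
        rng = np.random.default_rng(seed)
        pop_a_ids = sorted(rng.choice(pop_a_ids, n_per_pop, replace=False).tolist())
        pop_b_ids = sorted(rng.choice(pop_b_ids, n_per_pop, replace=False).tolist())

    used = list(outgroup_ids) + pop_a_ids + pop_b_ids
    sub = matrix.subset_samples(used)
    complete = (sub.genotypes != MISSING).all(axis=0)
    n_in = sub.n_loci
    sub = sub.subset_loci(complete)
    log.info("missingness filter: %d -> %d loci", n_in, sub.n_loci)

    polarized = polarize(sub, list(outgroup_ids), pop_a_ids + pop_b_ids)
    log.info("outgroup-homozygosity filter: %d -> %d loci", sub.n_loci, polarized.n_loci)

    summary = replicate_analysis(
        polarized, pop_a_ids, pop_b_ids, replicate_label, outgroup_label
    )
    summary.attrition = {
        "loci_input": n_in,
        "loci_complete": int(complete.sum()),
        "loci_polarized": polarized.n_loci,
        "pop_a_ids": pop_a_ids,
        "pop_b_ids": pop_b_ids,
    }
    return summary


def ids_by_population(
    popmap: PopulationMap, population: str
) -> list[str]:
    """Convenience: the samples assigned to one population label."""
    ids = popmap.samples(population)
    if not ids:
        raise ParameterError(f"no samples assigned to population {population!r}")
    return ids
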