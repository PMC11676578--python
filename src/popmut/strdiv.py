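"""STR locus quality filtering and per-locus diversity statistics.

Implements the usual codominant-marker diversity panel per (population,
locus): number of alleles Na, effective number of alleles Ne = 1/sum(p^2),
Shannon's information index I = -sum(p ln p), observed and expected
heterozygosity Ho and He = 1 - sum(p^2) (uncorrected, GenAlEx-style; an
(2n/(2n-1)) small-sample correction is available behind a flag), the
fixation index F_IS = (He - Ho)/He, private-allele counts against the
union of all other populations' allele supports, and the Botstein (1980)
polymorphic information content
PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.

Population comparisons use per-metric paired two-sided t-tests across the
shared loci, and genetic differentiation from allele frequencies uses the
Nei-style F_ST = (Ht - Hs)/Ht, combined over loci by summing Ht and Hs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .genio import PopulationMap, StrGenotypeTable

log = logging.getLogger(__name__)

#: Metrics summarize_diversity() tests between populations.
DIVERSITY_METRICS = ("n_typed", "Na", "Ne", "I", "Ho", "He", "Fis",
                     "private_alleles", "PIC")


@dataclass
class AlleleFrequencySpectrum:
    """Per (population, locus) allele relative frequencies.

    ``freqs[(population, locus_id)]`` maps allele (integer repeat count) to
    its relative frequency among the 2 * n_typed called alleles;
    ``n_typed[(population, locus_id)]`` is the count of individuals with a
    complete genotype there.
    """

    freqs: dict[tuple[str, str], dict[int, float]]
    n_typed: dict[tuple[str, str], int]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.freqs:
            seen.setdefault(pop)
        return list(seen)

    @property
    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, locus in self.freqs:
            seen.setdefault(locus)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (population, locus, allele, frequency) for plotting."""
        rows = [
            (pop, locus, allele, freq, self.n_typed[(pop, locus)])
            for (pop, locus), spectrum in self.freqs.items()
            for allele, freq in sorted(spectrum.items())
        ]
        return pd.DataFrame(
            rows, columns=["population", "locus_id", "allele", "frequency", "n_typed"]
        )


def filter_loci_by_likelihood(
    table: StrGenotypeTable,
    threshold: float = -25.0,
    fraction: float = 0.5,
    comparator: str = "le",
) -> tuple[StrGenotypeTable, list[str]]:
    """Drop loci whose call likelihood fails for more than ``fraction`` of individuals.

    A call fails when its log-likelihood is <= ``threshold`` (``comparator``
    = "le", the default, treating the threshold as the caller's floor
    value) or exactly == ``threshold`` ("eq"). A locus is removed iff the
    number of failing calls is *strictly* greater than
    ``fraction * n_individuals``; a locus failing for exactly half of the
    individuals is retained.
    """
    if comparator not in ("le", "eq"):
        raise ParameterError(f"comparator must be 'le' or 'eq', got {comparator!r}")
    df = table.df
    if df.empty:
        log.warning("filter_loci_by_likelihood: empty table")
        return table, []
    n_individuals = df["sample"].nunique()
    failing = (
        df["likelihood"] <= threshold
        if comparator == "le"
        else df["likelihood"] == threshold
    )
    n_fail = df.loc[failing].groupby("locus_id").size()
    removed = sorted(
        locus for locus, n in n_fail.items() if n > fraction * n_individuals
    )
    if removed:
        log.info(
            "filter_loci_by_likelihood: removed %d of %d loci",
            len(removed), df["locus_id"].nunique(),
        )
    kept = StrGenotypeTable(df[~df["locus_id"].isin(removed)].reset_index(drop=True))
    return kept, removed


def allele_frequencies(
    table: StrGenotypeTable, popmap: PopulationMap
) -> AlleleFrequencySpectrum:
    """Allele relative frequencies per (population, locus) from called genotypes."""
    df = table.df
    unmapped = set(df["sample"]) - set(popmap.assignments)
    if unmapped:
        raise ParameterError(f"samples missing from population map: {sorted(unmapped)}")
    called = df.dropna(subset=["allele1_repeats", "allele2_repeats"]).copy()
    called["population"] = called["sample"].map(popmap.assignments)
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    for (pop, locus), grp in called.groupby(["population", "locus_id"], sort=False):
        alleles = pd.concat([grp["allele1_repeats"], grp["allele2_repeats"]])
        counts = alleles.value_counts()
        total = counts.sum()
        freqs[(pop, locus)] = {int(a): c / total for a, c in counts.items()}
        n_typed[(pop, locus)] = len(grp)
    return AlleleFrequencySpectrum(freqs, n_typed)


def _pic(p: np.ndarray) -> float:
    """Botstein et al. (1980) polymorphic information content."""
    sum_p2 = float(np.sum(p**2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - sum_p2 - cross


def locus_diversity(
    spectrum: AlleleFrequencySpectrum,
    table: StrGenotypeTable,
    popmap: PopulationMap,
    bias_corrected_he: bool = False,
) -> pd.DataFrame:
    """Per-(population, locus) diversity panel as a tidy DataFrame.

    Fis is NaN (flagged, not zero) at monomorphic loci where He = 0.
    ``bias_corrected_he`` multiplies He by 2n/(2n-1) (and propagates into
    Fis), the small-sample-unbiased variant; off by default.
    """
    df = table.df
    called = df.dropna(subset=["allele1_repeats", "allele2_repeats"]).copy()
    called["population"] = called["sample"].map(popmap.assignments)
    het = {
        key: int((grp["allele1_repeats"] != grp["allele2_repeats"]).sum())
        for key, grp in called.groupby(["population", "locus_id"], sort=False)
    }
    # Allele support per locus per population, for private-allele counts.
    support: dict[tuple[str, str], set[int]] = {
        key: set(spec) for key, spec in spectrum.freqs.items()
    }
    populations = spectrum.populations
    rows = []
    for (pop, locus), spec in spectrum.freqs.items():
        p = np.array(sorted(spec.values(), reverse=True))
        n = spectrum.n_typed[(pop, locus)]
        sum_p2 = float(np.sum(p**2))
        na = len(p)
        ne = 1.0 / sum_p2
        shannon = float(-np.sum(p * np.log(p)))
        ho = het.get((pop, locus), 0) / n if n else float("nan")
        he = 1.0 - sum_p2
        if bias_corrected_he and n:
            he *= (2 * n) / (2 * n - 1)
        fis = (he - ho) / he if he > 0 else float("nan")
        others: set[int] = set()
        for other in populations:
            if other != pop:
                others |= support.get((other, locus), set())
        private = len(set(spec) - others)
        rows.append(
            (pop, locus, n, na, ne, shannon, ho, he, fis, private, _pic(p))
        )
    out = pd.DataFrame(
        rows,
        columns=["population", "locus_id", "n_typed", "Na", "Ne", "I", "Ho",
                 "He", "Fis", "private_alleles", "PIC"],
    )
    return out


def summarize_diversity(
    diversity: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population means/SEs per metric, plus paired t-tests across loci.

    Returns ``(summary, tests)``. ``summary`` has one row per
    (population, metric) with the mean over loci and SE = sd/sqrt(L).
    ``tests`` pairs the populations' per-locus values on their shared loci
    and runs a two-sided paired t-test per metric, flagging significance at
    ``alpha``; with fewer than two shared loci (or a zero-variance
    difference) the test is skipped with NaN statistics.
    """
    populations = diversity["population"].unique().tolist()
    summary_rows = []
    for pop, grp in diversity.groupby("population", sort=False):
        for metric in DIVERSITY_METRICS:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            mean = float(vals.mean()) if len(vals) else float("nan")
            se = (
                float(vals.std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1
                else 0.0 if len(vals) == 1 else float("nan")
            )
            summary_rows.append((pop, metric, len(vals), mean, se))
    summary = pd.DataFrame(
        summary_rows, columns=["population", "metric", "n_loci", "mean", "se"]
    )

    test_rows = []
    if len(populations) == 2:
        a, b = populations
        wide = diversity.pivot(index="locus_id", columns="population")
        for metric in DIVERSITY_METRICS:
            pair = wide[metric][[a, b]].dropna()
            if len(pair) < 2:
                test_rows.append((metric, len(pair), float("nan"), float("nan"), False))
                continue
            x, y = pair[a].to_numpy(), pair[b].to_numpy()
            if np.allclose(x - y, (x - y)[0]) and np.isclose((x - y).std(), 0):
                if np.isclose((x - y)[0], 0):
                    t_stat, p_val = 0.0, 1.0  # identical values: null by definition
                else:
                    t_stat, p_val = float("inf"), 0.0  # exact constant offset
            else:
                t_stat, p_val = stats.ttest_rel(x, y)
            test_rows.append(
                (metric, len(pair), float(t_stat), float(p_val), bool(p_val < alpha))
            )
    tests = pd.DataFrame(
        test_rows, columns=["metric", "n_loci", "t", "p", "significant"]
    )
    return summary, tests


def str_fst(
    spectrum: AlleleFrequencySpectrum,
    pop_a: Optional[str] = None,
    pop_b: Optional[str] = None,
) -> float:
    """Nei-style F_ST = (Ht - Hs)/Ht from allele frequencies, summed over loci.

    Per locus, Hs is the unweighted mean within-population expected
    heterozygosity and Ht the expected heterozygosity of the unweighted
    mean allele frequencies; the multi-locus value sums Ht and Hs over loci
    before taking the ratio. Defaults to the spectrum's (exactly two)
    populations when none are named.
    """
    pops = spectrum.populations
    if pop_a is None and pop_b is None:
        if len(pops) != 2:
            raise ParameterError(
                f"spectrum has {len(pops)} populations; name the two to compare"
            )
        pop_a, pop_b = pops
    if pop_a == pop_b:
        raise ParameterError("need two distinct populations")
    sum_ht = 0.0
    sum_hs = 0.0
    for locus in spectrum.locus_ids:
        spec_a = spectrum.freqs.get((pop_a, locus))
        spec_b = spectrum.freqs.get((pop_b, locus))
        if spec_a is None or spec_b is None:
            continue
        alleles = sorted(set(spec_a) | set(spec_b))
        pa = np.array([spec_a.get(al, 0.0) for al in alleles])
        pb = np.array([spec_b.get(al, 0.0) for al in alleles])
        hs = 0.5 * ((1 - np.sum(pa**2)) + (1 - np.sum(pb**2)))
        pbar = 0.5 * (pa + pb)
        ht = 1 - float(np.sum(pbar**2))
        sum_hs += hs
        sum_ht += ht
    if sum_ht == 0.0:
        raise ParameterError("total heterozygosity is zero; F_ST undefined")
    return (sum_ht - sum_hs) / sum_ht
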