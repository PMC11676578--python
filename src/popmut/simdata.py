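"""Synthetic SNP and STR datasets with the structure the pipeline assumes.

The SNP generator emulates two populations that diverged from a shared
ancestor, plus an outgroup fixed for the ancestral allele at every site.
Standing variation gets an ancestral derived-allele frequency drawn from a
Beta distribution and then drifts independently in each population
(beta-binomial-style frequency perturbation — enough to create F_ST without
simulating Wright-Fisher generations). On top of that, each locus can
receive a *novel* derived allele private to one population, at a
per-population injection rate: this is the elevated-germline-mutation knob,
and injected alleles enter at singleton/doubleton frequency like de novo
mutations would. A truth record of ancestral alleles and injection origins
accompanies every dataset so parameter-recovery tests never re-simulate.

The STR generator draws multiallelic repeat-count genotypes under a
stepwise mutation model around a base repeat count, and plants a chosen
number of loci whose calls carry a failing log-likelihood for more than
half of the individuals — the pattern the locus-quality filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genio import (
    MISSING,
    Locus,
    PopulationMap,
    SnpGenotypeMatrix,
    StrGenotypeTable,
    StrPanel,
)

OUTGROUP = "outgroup"
POP_A = "pop_a"
POP_B = "pop_b"

_BASES = np.array(list("ACGT"))


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


def _check_count(name: str, value: int, minimum: int = 1) -> None:
    if value < minimum:
        raise ParameterError(f"{name} must be >= {minimum}, got {value}")


@dataclass(frozen=True)
class SnpSimParams:
    """Knobs for the two-population SNP scenario.

    ``ancestral_freq_alpha/beta`` shape the ancestral derived-allele
    frequency spectrum (the default Beta(0.5, 2) is skewed toward rare
    derived alleles, as a neutral frequency spectrum is). ``drift_a/b`` in
    [0, 1) set how far each population's frequencies wander from the
    ancestor (0 = none). ``inject_rate_a/b`` are the per-locus
    probabilities that a locus is instead monomorphic-ancestral everywhere
    except for a novel low-frequency derived allele private to that
    population. Missing calls are off by default; the downstream pipeline
    removes incomplete loci, so a nonzero rate exists to exercise that
    filter, not to model a platform.
    """

    n_loci: int = 10_000
    n_outgroup: int = 3
    n_pop_a: int = 5
    n_pop_b: int = 5
    ancestral_freq_alpha: float = 0.5
    ancestral_freq_beta: float = 2.0
    drift_a: float = 0.02
    drift_b: float = 0.02
    inject_rate_a: float = 0.0
    inject_rate_b: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_count("n_loci", self.n_loci)
        _check_count("n_outgroup", self.n_outgroup)
        _check_count("n_pop_a", self.n_pop_a)
        _check_count("n_pop_b", self.n_pop_b)
        for name in ("drift_a", "drift_b", "inject_rate_a", "inject_rate_b",
                     "missing_rate"):
            _check_rate(name, getattr(self, name))
        if self.ancestral_freq_alpha <= 0 or self.ancestral_freq_beta <= 0:
            raise ParameterError("ancestral frequency shape parameters must be > 0")
        if self.inject_rate_a + self.inject_rate_b > 1.0:
            raise ParameterError("inject_rate_a + inject_rate_b must not exceed 1")
        if not (0.0 <= self.drift_a < 1.0 and 0.0 <= self.drift_b < 1.0):
            raise ParameterError("drift intensities must be in [0, 1)")


def _drift(rng: np.random.Generator, q: np.ndarray, intensity: float) -> np.ndarray:
    """Perturb frequencies q by a beta draw with mean q and variance F*q*(1-q)."""
    if intensity == 0.0:
        return q.copy()
    k = (1.0 - intensity) / intensity
    out = q.copy()
    interior = (q > 0) & (q < 1)
    qi = q[interior]
    out[interior] = rng.beta(qi * k, (1.0 - qi) * k)
    return out


def simulate_snp_dataset(
    params: SnpSimParams,
) -> tuple[SnpGenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Simulate the outgroup + two-population SNP scenario.

    Returns the genotype matrix (VCF allele coding randomized, so the
    derived allele is REF at roughly half the loci and polarization has to
    recode), the population map, and the truth record: one row per locus
    with the true ancestral/derived alleles and the injection origin
    (``standing``, ``inject_a`` or ``inject_b``).
    """
    rng = np.random.default_rng(params.seed)
    L = params.n_loci
    n_out, n_a, n_b = params.n_outgroup, params.n_pop_a, params.n_pop_b

    # Per-locus scenario: injected into A, injected into B, or standing.
    u = rng.random(L)
    inject_a = u < params.inject_rate_a
    inject_b = (~inject_a) & (u < params.inject_rate_a + params.inject_rate_b)
    standing = ~(inject_a | inject_b)

    # Standing variation: shared ancestral frequency, then independent drift.
    q_anc = rng.beta(params.ancestral_freq_alpha, params.ancestral_freq_beta, L)
    q_a = _drift(rng, q_anc, params.drift_a)
    q_b = _drift(rng, q_anc, params.drift_b)
    q_a[~standing] = 0.0
    q_b[~standing] = 0.0

    g_out = np.zeros((n_out, L), dtype=np.int8)  # outgroup fixed ancestral
    g_a = rng.binomial(2, q_a, size=(n_a, L)).astype(np.int8)
    g_b = rng.binomial(2, q_b, size=(n_b, L)).astype(np.int8)

    # Injected loci: a de novo derived allele at singleton/doubleton
    # frequency in the receiving population, absent everywhere else.
    for mask, g_pop, n_pop in ((inject_a, g_a, n_a), (inject_b, g_b, n_b)):
        for j in np.flatnonzero(mask):
            copies = int(rng.integers(1, 3))
            if copies >= 2 and n_pop >= 2:
                carriers = rng.choice(n_pop, size=2, replace=False)
                g_pop[carriers, j] = 1
            elif copies >= 2:
                g_pop[0, j] = 2
            else:
                g_pop[int(rng.integers(n_pop)), j] = 1

    derived_dosage = np.vstack([g_out, g_a, g_b])

    # Alleles and VCF coding: ancestral base per locus, derived base
    # distinct from it; REF is the derived allele at ~half the loci so the
    # polarization recode path is exercised.
    anc_idx = rng.integers(0, 4, L)
    der_idx = (anc_idx + rng.integers(1, 4, L)) % 4
    anc = _BASES[anc_idx]
    der = _BASES[der_idx]
    flip = rng.random(L) < 0.5
    alt_dosage = derived_dosage.copy()
    alt_dosage[:, flip] = 2 - alt_dosage[:, flip]

    if params.missing_rate > 0.0:
        miss = rng.random(alt_dosage.shape) < params.missing_rate
        alt_dosage[miss] = MISSING

    ref = np.where(flip, der, anc)
    alt = np.where(flip, anc, der)
    loci = [Locus("1", 1000 + 10 * j, ref[j], alt[j]) for j in range(L)]

    sample_ids = (
        [f"OUT{i+1:02d}" for i in range(n_out)]
        + [f"A{i+1:03d}" for i in range(n_a)]
        + [f"B{i+1:03d}" for i in range(n_b)]
    )
    matrix = SnpGenotypeMatrix(sample_ids, loci, alt_dosage)
    popmap = PopulationMap(
        {s: OUTGROUP for s in sample_ids[:n_out]}
        | {s: POP_A for s in sample_ids[n_out : n_out + n_a]}
        | {s: POP_B for s in sample_ids[n_out + n_a :]}
    )
    origin = np.where(inject_a, "inject_a", np.where(inject_b, "inject_b", "standing"))
    truth = pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "ancestral_allele": anc,
            "derived_allele": der,
            "origin": origin,
        }
    )
    return matrix, popmap, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# STRs


@dataclass(frozen=True)
class StrSimParams:
    """Knobs for the multiallelic STR scenario.

    Alleles are integer repeat counts within ``smm_steps`` of
    ``base_repeat_count``, weighted toward small deviations as a stepwise
    mutation model produces. ``allele_count_target`` is the mean number of
    distinct alleles per locus (the default 6.7 matches a diverse
    multi-panel set of canine STRs). ``n_bad_loci`` loci receive the
    failing log-likelihood ``bad_likelihood`` for strictly more than half
    of the individuals; all other calls get likelihoods well above it.
    """

    n_loci: int = 54
    n_individuals_per_pop: int = 47
    smm_steps: int = 5
    base_repeat_count: int = 12
    allele_count_target: float = 6.7
    n_bad_loci: int = 10
    bad_likelihood: float = -25.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_count("n_loci", self.n_loci)
        _check_count("n_individuals_per_pop", self.n_individuals_per_pop)
        _check_count("smm_steps", self.smm_steps, minimum=0)
        _check_count("base_repeat_count", self.base_repeat_count)
        _check_count("n_bad_loci", self.n_bad_loci, minimum=0)
        if self.n_bad_loci > self.n_loci:
            raise ParameterError(
                f"n_bad_loci ({self.n_bad_loci}) exceeds n_loci ({self.n_loci})"
            )
        if self.allele_count_target < 1:
            raise ParameterError("allele_count_target must be >= 1")
        if self.base_repeat_count - self.smm_steps < 1:
            raise ParameterError(
                "smm_steps would allow repeat counts below 1; "
                "need base_repeat_count - smm_steps >= 1"
            )


def default_str_panel(n_loci: int, seed: int = 0) -> StrPanel:
    """A deterministic synthetic panel of ``n_loci`` dinucleotide STRs."""
    rng = np.random.default_rng(seed)
    chroms = (1 + rng.integers(0, 38, n_loci)).astype(str)
    starts = 10_000 + 5_000 * np.arange(n_loci)
    motifs = rng.choice(["AC", "AG", "AT", "GT"], n_loci)
    df = pd.DataFrame(
        {
            "locus_id": [f"STR{j+1:03d}" for j in range(n_loci)],
            "chrom": chroms,
            "start": starts,
            "end": starts + 2 * 20 - 1,
            "motif_length": 2,
            "motif": motifs,
            "source_panel": "synthetic",
        }
    )
    return StrPanel(df)


def str_population_map(params: StrSimParams) -> PopulationMap:
    """Sample->population map matching :func:`simulate_str_dataset`'s ids."""
    n = params.n_individuals_per_pop
    return PopulationMap(
        {f"A{i+1:03d}": POP_A for i in range(n)}
        | {f"B{i+1:03d}": POP_B for i in range(n)}
    )


def simulate_str_dataset(panel: StrPanel, params: StrSimParams) -> StrGenotypeTable:
    """Simulate repeat-count genotypes for every (sample, panel locus).

    Exactly ``params.n_bad_loci`` loci end up with
    ``likelihood == bad_likelihood`` for strictly more than half of the
    individuals; every other call's likelihood stays far above the failing
    value, so the likelihood filter removes exactly the planted loci.
    """
    if len(panel) == 0:
        raise ParameterError("panel is empty")
    if params.n_loci != len(panel):
        raise ParameterError(
            f"params.n_loci ({params.n_loci}) != panel size ({len(panel)})"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n_individuals_per_pop
    samples = [f"A{i+1:03d}" for i in range(n)] + [f"B{i+1:03d}" for i in range(n)]
    n_total = len(samples)

    deltas = np.arange(-params.smm_steps, params.smm_steps + 1)
    smm_weights = 0.6 ** np.abs(deltas)
    smm_weights /= smm_weights.sum()

    bad_loci = set(
        rng.choice(len(panel), size=params.n_bad_loci, replace=False).tolist()
    )
    rows = []
    for j, locus_id in enumerate(panel.locus_ids):
        k_max = len(deltas)
        k = int(np.clip(round(rng.normal(params.allele_count_target, 1.0)), 1, k_max))
        support = rng.choice(deltas, size=k, replace=False, p=smm_weights)
        base_freq = rng.dirichlet(np.ones(k))
        # Per-population perturbation of the shared spectrum (mild
        # differentiation, as between recently separated populations).
        likelihoods = rng.uniform(-8.0, -0.5, n_total)
        if j in bad_loci:
            m = int(rng.integers(n_total // 2 + 1, n_total + 1))
            fail_idx = rng.choice(n_total, size=m, replace=False)
            likelihoods[fail_idx] = params.bad_likelihood
        for pop_slice in (slice(0, n), slice(n, n_total)):
            freqs = rng.dirichlet(base_freq * 50.0 + 0.02) if k > 1 else base_freq
            alleles = params.base_repeat_count + rng.choice(
                support, size=(n, 2), p=freqs
            )
            for i, sample in enumerate(samples[pop_slice]):
                a1, a2 = sorted(alleles[i])
                rows.append(
                    (sample, locus_id, int(a1), int(a2),
                     float(likelihoods[pop_slice][i]))
                )
    df = pd.DataFrame(
        rows,
        columns=["sample", "locus_id", "allele1_repeats", "allele2_repeats", "likelihood"],
    )
    df["allele1_repeats"] = df["allele1_repeats"].astype("Int64")
    df["allele2_repeats"] = df["allele2_repeats"].astype("Int64")
    return StrGenotypeTable(df)
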