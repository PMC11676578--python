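"""Independent brute-force reference implementations used only by tests.

Everything here enumerates alleles, loci and individuals explicitly with
plain Python loops and Counters — deliberately naive, sharing no code with
the package — so the vectorized implementations can be checked against a
second derivation of the same statistics.
"""

from collections import Counter
from math import log


# --- derived-allele counting -------------------------------------------------

def brute_pair_counts(g_a, g_b):
    """Orientation counts and excess totals by per-locus case analysis."""
    counts = Counter()
    d_a = d_b = n_informative = 0
    for x, y in zip(g_a, g_b):
        total = x + y
        if total == 0 or total == 4:
            continue
        n_informative += 1
        if (x, y) == (1, 1):
            continue
        counts[(x, y)] += 1
        if x > y:
            d_a += x - y
        else:
            d_b += y - x
    return dict(counts), d_a, d_b, n_informative


# --- STR diversity ------------------------------------------------------------

def brute_locus_stats(genotypes, other_pop_alleles=()):
    """Diversity panel for one (population, locus) from explicit allele lists.

    ``genotypes`` is a list of (allele1, allele2) tuples for the typed
    individuals; ``other_pop_alleles`` the set of alleles seen in any other
    population at this locus (for the private-allele count).
    """
    alleles = [a for g in genotypes for a in g]
    counts = Counter(alleles)
    n_alleles = len(alleles)
    p = {a: c / n_alleles for a, c in counts.items()}
    sum_p2 = sum(q * q for q in p.values())
    na = len(p)
    ne = 1.0 / sum_p2
    shannon = -sum(q * log(q) for q in p.values())
    ho = sum(1 for a, b in genotypes if a != b) / len(genotypes)
    he = 1.0 - sum_p2
    fis = (he - ho) / he if he > 0 else float("nan")
    support = sorted(p)
    pic = 1.0 - sum_p2
    for i in range(len(support)):
        for j in range(i + 1, len(support)):
            pic -= 2.0 * p[support[i]] ** 2 * p[support[j]] ** 2
    private = sum(1 for a in p if a not in set(other_pop_alleles))
    return {
        "n_typed": len(genotypes), "Na": na, "Ne": ne, "I": shannon,
        "Ho": ho, "He": he, "Fis": fis, "private_alleles": private, "PIC": pic,
    }


def brute_nei_fst(freqs_a, freqs_b):
    """(Ht - Hs)/Ht summed over loci from two lists of allele->freq dicts."""
    sum_ht = sum_hs = 0.0
    for fa, fb in zip(freqs_a, freqs_b):
        alleles = set(fa) | set(fb)
        hs = 0.5 * ((1 - sum(fa.get(a, 0) ** 2 for a in alleles))
                    + (1 - sum(fb.get(a, 0) ** 2 for a in alleles)))
        ht = 1 - sum((0.5 * (fa.get(a, 0) + fb.get(a, 0))) ** 2 for a in alleles)
        sum_hs += hs
        sum_ht += ht
    return (sum_ht - sum_hs) / sum_ht


# --- Weir-Cockerham theta ------------------------------------------------------

def _wc_locus(pop_genotypes):
    """Variance components (a, b, c) for one locus.

    ``pop_genotypes[k]`` is the list of dosages (0/1/2) called in
    population k at this locus. Returns None for loci with no variance.
    """
    r = len(pop_genotypes)
    n = [len(g) for g in pop_genotypes]
    p = [sum(g) / (2 * len(g)) for g in pop_genotypes]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pop_genotypes]
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    pq = p_bar * (1 - p_bar)
    if pq == 0 and h_bar == 0:
        return None
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def brute_wc_theta(pop_genotypes_by_locus):
    """Ratio-of-sums theta; input is a list over loci of per-pop dosage lists."""
    sum_a = sum_abc = 0.0
    for pops in pop_genotypes_by_locus:
        comp = _wc_locus(pops)
        if comp is None:
            continue
        a, b, c = comp
        sum_a += a
        sum_abc += a + b + c
    if sum_abc == 0:
        return float("nan")
    return sum_a / sum_abc
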