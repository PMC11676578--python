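"""STR filtering, diversity closed forms, oracle equivalence, and population tests."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_locus_stats, brute_nei_fst
from popmut import (
    AlleleFrequencySpectrum,
    ParameterError,
    PopulationMap,
    StrGenotypeTable,
    allele_frequencies,
    filter_loci_by_likelihood,
    locus_diversity,
    str_fst,
    summarize_diversity,
)


def make_table(rows):
    """rows: (sample, locus, a1, a2, likelihood)."""
    df = pd.DataFrame(
        rows,
        columns=["sample", "locus_id", "allele1_repeats", "allele2_repeats",
                 "likelihood"],
    )
    df["allele1_repeats"] = df["allele1_repeats"].astype("Int64")
    df["allele2_repeats"] = df["allele2_repeats"].astype("Int64")
    return StrGenotypeTable(df)


def spectrum_from(freqs):
    """freqs: {(pop, locus): {allele: p}}; n_typed fixed at 10."""
    return AlleleFrequencySpectrum(freqs, {k: 10 for k in freqs})


class TestLikelihoodFilter:
    def test_exactly_half_failing_is_retained(self):
        rows = [(f"S{i}", "L1", 12, 12, -25.0 if i < 2 else -3.0) for i in range(4)]
        kept, removed = filter_loci_by_likelihood(make_table(rows))
        assert removed == []
        assert kept.locus_ids == ["L1"]

    def test_strict_majority_failing_is_removed(self):
        rows = [(f"S{i}", "L1", 12, 12, -25.0 if i < 3 else -3.0) for i in range(4)]
        kept, removed = filter_loci_by_likelihood(make_table(rows))
        assert removed == ["L1"]
        assert kept.locus_ids == []

    def test_le_comparator_catches_values_below_threshold(self):
        rows = [(f"S{i}", "L1", 12, 12, -30.0) for i in range(4)]
        _, removed = filter_loci_by_likelihood(make_table(rows))
        assert removed == ["L1"]
        _, removed_eq = filter_loci_by_likelihood(make_table(rows), comparator="eq")
        assert removed_eq == []

    def test_infinitely_low_threshold_removes_nothing(self):
        rows = [(f"S{i}", "L1", 12, 12, -25.0) for i in range(4)]
        _, removed = filter_loci_by_likelihood(make_table(rows), threshold=-math.inf)
        assert removed == []

    def test_empty_table_warns_and_returns_empty(self, caplog):
        empty = make_table([])
        kept, removed = filter_loci_by_likelihood(empty)
        assert removed == [] and kept.df.empty


class TestAlleleFrequencies:
    def test_single_homozygote(self):
        table = make_table([("S1", "L1", 12, 12, -3.0)])
        spec = allele_frequencies(table, PopulationMap({"S1": "p1"}))
        assert spec.freqs[("p1", "L1")] == {12: 1.0}
        assert spec.n_typed[("p1", "L1")] == 1

    def test_het_and_hom_mix(self):
        table = make_table([("S1", "L1", 12, 14, -3.0), ("S2", "L1", 12, 12, -3.0)])
        spec = allele_frequencies(table, PopulationMap({"S1": "p1", "S2": "p1"}))
        assert spec.freqs[("p1", "L1")] == {12: 0.75, 14: 0.25}

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        rows = []
        popmap = {}
        for i in range(12):
            s = f"S{i}"
            popmap[s] = "p1" if i < 6 else "p2"
            for locus in ("L1", "L2", "L3"):
                a1, a2 = rng.integers(8, 15, 2)
                rows.append((s, locus, int(a1), int(a2), -3.0))
        spec = allele_frequencies(make_table(rows), PopulationMap(popmap))
        for spectrum in spec.freqs.values():
            assert sum(spectrum.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(p > 0 for p in spectrum.values())

    def test_unmapped_sample_rejected(self):
        table = make_table([("S1", "L1", 12, 12, -3.0)])
        with pytest.raises(ParameterError):
            allele_frequencies(table, PopulationMap({"other": "p1"}))

    def test_no_calls_reduce_n_typed_not_drop_locus(self):
        table = make_table(
            [("S1", "L1", 12, 12, -3.0), ("S2", "L1", None, None, -25.0)]
        )
        spec = allele_frequencies(table, PopulationMap({"S1": "p1", "S2": "p1"}))
        assert spec.n_typed[("p1", "L1")] == 1


class TestLocusDiversity:
    def test_closed_forms_biallelic_even(self):
        # p = (0.5, 0.5): Ne = 2, He = 0.5, I = ln 2, PIC = 0.375
        table = make_table(
            [("S1", "L1", 12, 14, -3.0), ("S2", "L1", 14, 12, -3.0)]
        )
        popmap = PopulationMap({"S1": "p1", "S2": "p1"})
        spec = allele_frequencies(table, popmap)
        div = locus_diversity(spec, table, popmap).iloc[0]
        assert div["Ne"] == pytest.approx(2.0)
        assert div["He"] == pytest.approx(0.5)
        assert div["I"] == pytest.approx(math.log(2))
        assert div["PIC"] == pytest.approx(0.375)
        assert div["Ho"] == pytest.approx(1.0)
        assert div["Fis"] == pytest.approx((0.5 - 1.0) / 0.5)

    def test_uniform_k_alleles(self):
        # four equally frequent alleles: Ne = 4, I = ln 4
        table = make_table(
            [("S1", "L1", 10, 11, -3.0), ("S2", "L1", 12, 13, -3.0)]
        )
        popmap = PopulationMap({"S1": "p1", "S2": "p1"})
        spec = allele_frequencies(table, popmap)
        div = locus_diversity(spec, table, popmap).iloc[0]
        assert div["Na"] == 4
        assert div["Ne"] == pytest.approx(4.0)
        assert div["I"] == pytest.approx(math.log(4))

    def test_monomorphic_locus_fis_flagged(self):
        table = make_table([("S1", "L1", 12, 12, -3.0), ("S2", "L1", 12, 12, -3.0)])
        popmap = PopulationMap({"S1": "p1", "S2": "p1"})
        spec = allele_frequencies(table, popmap)
        div = locus_diversity(spec, table, popmap).iloc[0]
        assert math.isnan(div["Fis"])
        assert div["He"] == 0.0 and div["Na"] == 1

    def test_private_alleles_counted_against_other_population(self):
        table = make_table(
            [("S1", "L1", 12, 14, -3.0), ("S2", "L1", 12, 12, -3.0)]
        )
        popmap = PopulationMap({"S1": "p1", "S2": "p2"})
        spec = allele_frequencies(table, popmap)
        div = locus_diversity(spec, table, popmap).set_index("population")
        assert div.loc["p1", "private_alleles"] == 1  # allele 14
        assert div.loc["p2", "private_alleles"] == 0

    def test_invariant_identities_on_random_records(self):
        rng = np.random.default_rng(7)
        rows = []
        popmap = {}
        for i in range(10):
            s = f"S{i}"
            popmap[s] = "p1" if i < 5 else "p2"
            for locus in ("L1", "L2", "L3", "L4"):
                a1, a2 = rng.integers(8, 16, 2)
                rows.append((s, locus, int(a1), int(a2), -3.0))
        table = make_table(rows)
        popmap = PopulationMap(popmap)
        spec = allele_frequencies(table, popmap)
        div = locus_diversity(spec, table, popmap)
        assert ((1 <= div["Ne"]) & (div["Ne"] <= div["Na"] + 1e-12)).all()
        assert ((0 - 1e-12 <= div["I"]) & (div["I"] <= np.log(div["Na"]) + 1e-12)).all()
        assert div[["Ho", "He"]].ge(0).all().all()
        assert div[["Ho", "He"]].le(1).all().all()
        assert (div["PIC"] <= div["He"] + 1e-12).all()
        # private alleles: an allele is private to at most one population
        for locus in ("L1", "L2", "L3", "L4"):
            sub = div[div["locus_id"] == locus]
            total_alleles = len(
                set(spec.freqs[("p1", locus)]) | set(spec.freqs[("p2", locus)])
            )
            assert sub["private_alleles"].sum() <= total_alleles

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n_loci = int(rng.integers(1, 6))
            n_per_pop = int(rng.integers(1, 4))  # <= 6 individuals total
            rows = []
            popmap = {}
            for i in range(2 * n_per_pop):
                s = f"S{i}"
                popmap[s] = "p1" if i < n_per_pop else "p2"
                for j in range(n_loci):
                    a1, a2 = rng.integers(8, 13, 2)
                    rows.append((s, f"L{j}", int(a1), int(a2), -3.0))
            table = make_table(rows)
            pm = PopulationMap(popmap)
            spec = allele_frequencies(table, pm)
            div = locus_diversity(spec, table, pm).set_index(["population", "locus_id"])
            for (pop, locus), spectrum in spec.freqs.items():
                other = "p2" if pop == "p1" else "p1"
                genotypes = [
                    (int(r[2]), int(r[3])) for r in rows
                    if popmap[r[0]] == pop and r[1] == locus
                ]
                expected = brute_locus_stats(
                    genotypes, spec.freqs.get((other, locus), {}).keys()
                )
                got = div.loc[(pop, locus)]
                for key, val in expected.items():
                    if isinstance(val, float) and math.isnan(val):
                        assert math.isnan(got[key])
                    else:
                        assert got[key] == pytest.approx(val), (pop, locus, key)

    def test_bias_corrected_he_flag(self):
        table = make_table([("S1", "L1", 12, 14, -3.0), ("S2", "L1", 12, 12, -3.0)])
        popmap = PopulationMap({"S1": "p1", "S2": "p1"})
        spec = allele_frequencies(table, popmap)
        plain = locus_diversity(spec, table, popmap).iloc[0]["He"]
        corrected = locus_diversity(spec, table, popmap, bias_corrected_he=True)
        assert corrected.iloc[0]["He"] == pytest.approx(plain * 4 / 3)


class TestSummarize:
    def _diversity_frame(self, offset=0.0):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.3, 0.8, 8)
        rows = []
        for j, locus in enumerate([f"L{j}" for j in range(8)]):
            for pop, delta in (("p1", 0.0), ("p2", offset)):
                v = base[j] + delta + (rng.normal(0, 0.01) if offset else 0.0)
                rows.append(
                    {"population": pop, "locus_id": locus, "n_typed": 10,
                     "Na": 4, "Ne": 1 + v, "I": v, "Ho": v, "He": v,
                     "Fis": 0.1, "private_alleles": 1, "PIC": v}
                )
        return pd.DataFrame(rows)

    def test_identical_populations_null(self):
        summary, tests = summarize_diversity(self._diversity_frame(0.0))
        he = tests.set_index("metric").loc["He"]
        assert he["t"] == 0.0 and he["p"] == 1.0 and not he["significant"]

    def test_constant_offset_detected(self):
        _, tests = summarize_diversity(self._diversity_frame(0.1))
        assert tests.set_index("metric").loc["He", "significant"]

    def test_constant_metric_mean_and_zero_se(self):
        summary, _ = summarize_diversity(self._diversity_frame(0.0))
        na = summary.set_index(["population", "metric"]).loc[("p1", "Na")]
        assert na["mean"] == 4.0 and na["se"] == 0.0

    def test_single_locus_no_test(self):
        df = self._diversity_frame(0.0)
        df = df[df["locus_id"] == "L0"]
        _, tests = summarize_diversity(df)
        assert not tests["significant"].any()
        assert tests["t"].isna().all()


class TestStrFst:
    def test_identical_spectra_zero(self):
        f = {
            ("p1", "L1"): {12: 0.5, 14: 0.5},
            ("p2", "L1"): {12: 0.5, 14: 0.5},
        }
        assert str_fst(spectrum_from(f)) == pytest.approx(0.0)

    def test_fixed_for_different_alleles_is_one(self):
        f = {("p1", "L1"): {12: 1.0}, ("p2", "L1"): {14: 1.0}}
        assert str_fst(spectrum_from(f)) == pytest.approx(1.0)

    def test_two_locus_hand_computation(self):
        f = {
            ("p1", "L1"): {12: 0.8, 14: 0.2}, ("p2", "L1"): {12: 0.2, 14: 0.8},
            ("p1", "L2"): {10: 0.5, 11: 0.5}, ("p2", "L2"): {10: 0.5, 11: 0.5},
        }
        spec = spectrum_from(f)
        expected = brute_nei_fst(
            [f[("p1", "L1")], f[("p1", "L2")]],
            [f[("p2", "L1")], f[("p2", "L2")]],
        )
        assert str_fst(spec) == pytest.approx(expected)
        # sanity: locus 1 alone gives Hs = 0.32, Ht = 0.5
        only1 = spectrum_from({k: v for k, v in f.items() if k[1] == "L1"})
        assert str_fst(only1) == pytest.approx((0.5 - 0.32) / 0.5)

    def test_all_monomorphic_undefined(self):
        f = {("p1", "L1"): {12: 1.0}, ("p2", "L1"): {12: 1.0}}
        with pytest.raises(ParameterError):
            str_fst(spectrum_from(f))
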