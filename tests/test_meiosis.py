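"""Meiosis, packaging and tally tests, including the exhaustive
chromatid-assortment oracle the octet simulator must agree with."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from octadkit import (
    CrossError,
    CrossParams,
    get_preset,
    nucleus,
    package_ascospores,
    score_ascus,
    simulate_cross_tally,
    simulate_meiosis_octet,
)
from conftest import cross_parents, forced


# ---------------------------------------------------------------------------
# Independent oracle: enumerate every chromatid assortment of a
# translocation-heterozygous meiosis (4 chromatids per chromosome, at most
# one interstitial crossover per region) and collect the possible octet
# genotype compositions.
# ---------------------------------------------------------------------------

_GENO = {
    ("Td", "Tr"): "T",
    ("Nd", "Nr"): "N",
    ("Nd", "Tr"): "Dp",
    ("Td", "Nr"): "Df",
}


def enumerate_octet_compositions(segregation, donor_co, recip_co):
    """All octet genotype compositions reachable for one configuration."""
    donor_opts = list(product(range(2), repeat=2)) if donor_co else [None]
    recip_opts = list(product(range(2), repeat=2)) if recip_co else [None]
    results = set()
    for dch, rch in product(donor_opts, recip_opts):
        dT, dN = ["Td", "Td"], ["Nd", "Nd"]
        if dch is not None:
            i, j = dch
            dT[i], dN[j] = dN[j], dT[i]
        rT, rN = ["Tr", "Tr"], ["Nr", "Nr"]
        if rch is not None:
            i, j = rch
            rT[i], rN[j] = rN[j], rT[i]
        if segregation == "alternate":
            poles = [(dT, rT), (dN, rN)]
        else:  # adjacent-1
            poles = [(dT, rN), (dN, rT)]
        # meiosis II: two donor/recipient chromatid pairings per pole
        for p1, p2 in product(range(2), repeat=2):
            comp = Counter()
            for (dh, rh), p in zip(poles, (p1, p2)):
                for k in range(2):
                    comp[_GENO[(dh[k], rh[(k + p) % 2])]] += 2
            results.add(frozenset(comp.items()))
    return results


class TestOctet:
    def test_alternate_gives_parental_octet(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        octet = simulate_meiosis_octet(p1, p2, [eb4], forced(1.0), rng)
        assert octet.genotype_counts(eb4) == Counter({"T": 4, "N": 4})

    def test_adjacent1_gives_dp_df_octet(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        octet = simulate_meiosis_octet(p1, p2, [eb4], forced(0.0), rng)
        assert octet.genotype_counts(eb4) == Counter({"Dp": 4, "Df": 4})

    def test_isosequential_cross_is_invariant(self, eb4, rng):
        p1, p2 = cross_parents(eb4, "N", "N")
        for p_alt in (0.0, 0.5, 1.0):
            octet = simulate_meiosis_octet(
                p1, p2, [eb4], CrossParams(p_alt=p_alt), rng
            )
            assert octet.genotype_counts(eb4) == Counter({"N": 8})

    def test_single_donor_crossover_gives_tetratype_octet(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = CrossParams(p_alt=1.0, c_donor=1.0, c_recipient=0.0)
        octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
        assert octet.genotype_counts(eb4) == Counter(
            {"T": 2, "N": 2, "Dp": 2, "Df": 2}
        )

    def test_same_mating_type_cross_refused(self, eb4, rng):
        a = nucleus(eb4, "T", "A")
        b = nucleus(eb4, "N", "A")
        with pytest.raises(CrossError):
            simulate_meiosis_octet(a, b, [eb4], CrossParams(), rng)

    def test_mating_type_balance_and_pole_structure(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        for _ in range(50):
            octet = simulate_meiosis_octet(
                p1, p2, [eb4], CrossParams(c_donor=0.3, c_recipient=0.3), rng
            )
            assert octet.mat_counts() == Counter({"A": 4, "a": 4})
            # mat shows first-division segregation: constant within a pole
            mats = [n.mat for n in octet.nuclei]
            assert len(set(mats[:4])) == 1 and len(set(mats[4:])) == 1

    @pytest.mark.parametrize("segregation,p_alt", [("alternate", 1.0),
                                                   ("adjacent-1", 0.0)])
    @pytest.mark.parametrize("donor_co,recip_co", list(product([0, 1], repeat=2)))
    def test_composition_matches_exhaustive_enumeration(
        self, eb4, segregation, p_alt, donor_co, recip_co
    ):
        """Simulated octets realise exactly the brute-force assortment set."""
        rng = np.random.default_rng(7)
        expected = enumerate_octet_compositions(segregation, donor_co, recip_co)
        p1, p2 = cross_parents(eb4)
        params = CrossParams(
            p_alt=p_alt, c_donor=float(donor_co), c_recipient=float(recip_co)
        )
        observed = set()
        for _ in range(120):
            octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
            comp = frozenset(octet.genotype_counts(eb4).items())
            assert comp in expected
            observed.add(comp)
        assert observed == expected


class TestPackaging:
    def test_crassa_packaging_preserves_order(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        octet = simulate_meiosis_octet(p1, p2, [eb4], forced(1.0), rng)
        ascus = package_ascospores(octet, forced(1.0), rng)
        assert [len(s.nuclei) for s in ascus.spores] == [1] * 8
        assert [s.nuclei[0] for s in ascus.spores] == octet.nuclei

    def test_tetrasperma_binucleate_nonsister_pairs(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = forced(0.5, species="tetrasperma")
        for _ in range(25):
            octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
            ascus = package_ascospores(octet, params, rng)
            assert len(ascus.spores) == 4
            for spore in ascus.spores:
                assert sorted(n.mat for n in spore.nuclei) == ["A", "a"]
            assert ascus.n_nuclei == 8

    def test_full_replacement_gives_eight_homokaryotic_spores(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = forced(1.0, species="tetrasperma", replacement_prob=1.0)
        octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
        ascus = package_ascospores(octet, params, rng)
        assert len(ascus.spores) == 8
        assert all(len(s.nuclei) == 1 for s in ascus.spores)

    def test_nucleus_conservation_under_replacement_and_anomaly(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = forced(
            0.5, species="tetrasperma", replacement_prob=0.4, anomaly_prob=0.5
        )
        for _ in range(100):
            octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
            ascus = package_ascospores(octet, params, rng)
            assert ascus.n_nuclei == 8

    def test_random_pairing_still_balances_mating_type(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = forced(0.5, species="tetrasperma", random_pairing=True)
        for _ in range(25):
            octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
            ascus = package_ascospores(octet, params, rng)
            for spore in ascus.spores:
                assert sorted(n.mat for n in spore.nuclei) == ["A", "a"]


class TestScoring:
    @pytest.mark.parametrize("p_alt,expected", [(1.0, (8, 0, "8:0")),
                                                (0.0, (4, 4, "4:4"))])
    def test_it_cross_classes(self, eb4, rng, p_alt, expected):
        p1, p2 = cross_parents(eb4)
        params = forced(p_alt)
        octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
        assert score_ascus(package_ascospores(octet, params, rng)) == expected

    @pytest.mark.parametrize("p_alt,expected", [(1.0, (8, 0, "8:0")),
                                                (0.0, (0, 8, "0:8"))])
    def test_rt_cross_classes(self, rt, rng, p_alt, expected):
        # an RT x N cross signals itself by 8B:0W = 0B:8W
        p1, p2 = cross_parents(rt)
        params = forced(p_alt)
        octet = simulate_meiosis_octet(p1, p2, [rt], params, rng)
        assert score_ascus(package_ascospores(octet, params, rng)) == expected

    def test_tetrasperma_tally_class_is_spore_count(self, eb4, rng):
        p1, p2 = cross_parents(eb4)
        params = forced(1.0, species="tetrasperma")
        octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
        assert package_ascospores(octet, params, rng).tally_class == "4"


class TestTally:
    def test_only_parental_classes_without_crossover(self, eb4):
        p1, p2 = cross_parents(eb4)
        params = CrossParams(c_donor=0.0, c_recipient=0.0, rng_seed=11)
        df = simulate_cross_tally(p1, p2, [eb4], 2000, params)
        present = set(df.loc[df["count"] > 0, "class"])
        assert present == {"8:0", "4:4"}
        # equal segregation likelihood: the 8:0 / 4:4 ratio is 1 within
        # three binomial standard errors
        n80 = int(df.loc[df["class"] == "8:0", "count"].iloc[0])
        n = 2000
        se = np.sqrt(n * 0.25)
        assert abs(n80 - n / 2) < 3 * se

    def test_isosequential_cross_all_eight_black(self, eb4):
        p1, p2 = cross_parents(eb4, "N", "N")
        df = simulate_cross_tally(
            p1, p2, [eb4], 300, CrossParams(rng_seed=5)
        )
        assert int(df.loc[df["class"] == "8:0", "count"].iloc[0]) == 300

    def test_donor_crossover_produces_six_two_class(self, eb4):
        p1, p2 = cross_parents(eb4)
        params = CrossParams(c_donor=0.4, c_recipient=0.0, rng_seed=3)
        df = simulate_cross_tally(p1, p2, [eb4], 1000, params)
        assert int(df.loc[df["class"] == "6:2", "count"].iloc[0]) > 0

    def test_tally_reproducible_under_fixed_seed(self, eb4):
        p1, p2 = cross_parents(eb4)
        params = CrossParams(rng_seed=42, species="tetrasperma",
                             replacement_prob=0.15)
        df1 = simulate_cross_tally(p1, p2, [eb4], 300, params)
        df2 = simulate_cross_tally(p1, p2, [eb4], 300, params)
        assert df1.equals(df2)

    def test_black_fraction_converges_to_three_quarters(self, eb4):
        """IT x N with p_alt = 0.5, no crossover: E[black]/8 = 0.75."""
        p1, p2 = cross_parents(eb4)
        params = CrossParams(c_donor=0.0, c_recipient=0.0, rng_seed=9)
        rng = np.random.default_rng(9)
        fracs = []
        for _ in range(2000):
            octet = simulate_meiosis_octet(p1, p2, [eb4], params, rng)
            ascus = package_ascospores(octet, params, rng)
            fracs.append(ascus.n_black / 8)
        se = np.sqrt(0.0625 / len(fracs))
        assert abs(np.mean(fracs) - 0.75) < 4 * se

    def test_p_alt_recovery_from_tally(self, eb4):
        """p̂_alt = f(8:0) / (f(8:0) + f(4:4)) recovers the generator."""
        p1, p2 = cross_parents(eb4)
        for p_alt in (0.3, 0.7):
            params = CrossParams(
                p_alt=p_alt, c_donor=0.0, c_recipient=0.0, rng_seed=17
            )
            df = simulate_cross_tally(p1, p2, [eb4], 2000, params)
            counts = dict(zip(df["class"], df["count"]))
            n = counts["8:0"] + counts["4:4"]
            p_hat = counts["8:0"] / n
            se = np.sqrt(p_alt * (1 - p_alt) / n)
            assert abs(p_hat - p_alt) < 3 * se
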