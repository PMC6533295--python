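"""AMOVA Phi-statistics against a from-first-principles oracle, plus the
artifact exclusion filter and permutation machinery."""

import numpy as np
import pytest

from ystrkit import (
    DistanceKind,
    DistanceModel,
    PairwiseAmova,
    PopulationSample,
    Profile,
    YFILER_PLUS_PANEL,
    amova_two_group,
    filter_for_distance,
    pairwise_matrix,
    profile_distance,
)
from ystrkit.amova import IntermediatePolicy
from ystrkit.profiles import AlleleCall
from ystrkit.simulate import SimulationConfig, simulate_populations

TWO_LOCI = YFILER_PLUS_PANEL.restrict(["DYS19", "DYS390"])


def make_profile(pid, pop, alleles, panel=TWO_LOCI):
    calls = {}
    for locus, vals in zip(panel.loci, alleles):
        if not isinstance(vals, (tuple, list)):
            vals = (vals,)
        calls[locus] = AlleleCall(tuple(int(round(a * 10)) for a in vals))
    return Profile(pid, pop, calls, panel)


def make_pop(name, haplotypes, panel=TWO_LOCI):
    profiles = tuple(
        make_profile(f"{name}{i}", name, h, panel) for i, h in enumerate(haplotypes)
    )
    return PopulationSample(name, profiles)


# ---------------------------------------------------------------------------
# independent oracle: plain-Python AMOVA from the textbook definitions
# ---------------------------------------------------------------------------

def oracle_phi(pop_a, pop_b, kind):
    """Two-level AMOVA Phi-st computed with explicit loops and its own
    inter-profile distance, independent of the package's code paths."""
    profs = list(pop_a.profiles) + list(pop_b.profiles)
    groups = [0] * pop_a.N + [1] * pop_b.N
    loci = profs[0].panel.loci

    def dist(x, y):
        if kind == "IDENTITY":
            gx = tuple(sorted(x.calls[l].values) for l in loci)
            gy = tuple(sorted(y.calls[l].values) for l in loci)
            return 0.0 if gx == gy else 1.0
        total = 0.0
        for l in loci:
            if profs[0].panel.is_multicopy(l):
                continue
            total += (x.calls[l].values[0] / 10 - y.calls[l].values[0] / 10) ** 2
        return total

    n = len(profs)
    k = 2
    ssd_t = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ssd_t += dist(profs[i], profs[j])
    ssd_t /= n
    ssd_w = 0.0
    for g, size in ((0, pop_a.N), (1, pop_b.N)):
        idx = [i for i in range(n) if groups[i] == g]
        acc = 0.0
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                acc += dist(profs[i], profs[j])
        ssd_w += acc / size
    msd_a = (ssd_t - ssd_w) / (k - 1)
    msd_w = ssd_w / (n - k)
    n_prime = (n - (pop_a.N**2 + pop_b.N**2) / n) / (k - 1)
    s2_a = (msd_a - msd_w) / n_prime
    s2_w = msd_w
    if s2_a + s2_w == 0:
        return 0.0
    return s2_a / (s2_a + s2_w)


def random_pops(rng, n_a, n_b):
    haps_a = [(rng.integers(10, 14), rng.integers(20, 24)) for _ in range(n_a)]
    haps_b = [(rng.integers(11, 15), rng.integers(21, 25)) for _ in range(n_b)]
    return make_pop("A", haps_a), make_pop("B", haps_b)


class TestProfileDistance:
    def test_identical_profiles_distance_zero(self):
        a = make_profile("a", "P", [(15,), (24,)])
        b = make_profile("b", "P", [(15,), (24,)])
        for model in (DistanceModel.rst(), DistanceModel.fst()):
            assert profile_distance(a, b, model) == 0.0

    def test_one_repeat_step_squared_distance_one(self):
        a = make_profile("a", "P", [(15,), (24,)])
        b = make_profile("b", "P", [(16,), (24,)])
        assert profile_distance(a, b, DistanceModel.rst()) == 1.0
        assert profile_distance(a, b, DistanceModel.fst()) == 1.0

    def test_fractional_microvariant_difference(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS627"])
        a = make_profile("a", "P", [(19.2,)], panel)
        b = make_profile("b", "P", [(19,)], panel)
        model = DistanceModel.rst(intermediate_policy=IntermediatePolicy.FRACTIONAL)
        assert profile_distance(a, b, model) == pytest.approx(0.04, abs=1e-12)

    def test_exclude_locus_policy_drops_microvariant_locus(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS627", "DYS19"])
        a = make_profile("a", "P", [(15,), (19.2,)], panel)  # DYS19, DYS627
        b = make_profile("b", "P", [(17,), (19,)], panel)
        model = DistanceModel.rst(
            intermediate_policy=IntermediatePolicy.EXCLUDE_LOCUS
        )
        assert profile_distance(a, b, model) == pytest.approx(4.0)

    def test_multicopy_excluded_from_repeat_metric(self):
        # restricted panel keeps original order: DYS19 before DYS385
        panel = YFILER_PLUS_PANEL.restrict(["DYS385", "DYS19"])
        a = make_profile("a", "P", [(15,), (13, 18)], panel)
        b = make_profile("b", "P", [(15,), (13, 20)], panel)
        assert profile_distance(a, b, DistanceModel.rst()) == 0.0
        # but multicopy combinations still distinguish haplotypes under identity
        assert profile_distance(a, b, DistanceModel.fst()) == 1.0

    def test_dys389_adjustment(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS389I", "DYS389II"])
        a = make_profile("a", "P", [(13,), (29,)], panel)
        b = make_profile("b", "P", [(14,), (30,)], panel)
        plain = DistanceModel.rst()
        adj = DistanceModel.rst(dys389_adjust=True)
        assert profile_distance(a, b, plain) == pytest.approx(2.0)
        # adjusted DYS389II is 16 in both -> only DYS389I differs
        assert profile_distance(a, b, adj) == pytest.approx(1.0)


class TestFilter:
    def test_flagged_profiles_removed_and_logged(self, example_samples):
        filtered, log = filter_for_distance(example_samples)
        removed = {e["sample_id"]: e["reasons"] for e in log}
        assert removed == {
            "A1": ["DUPLICATED_SINGLE_COPY"],
            "A3": ["NULL_ALLELE"],
        }
        assert filtered[0].N == 2 and filtered[1].N == 3

    def test_clean_input_is_identity(self, simulated_pair):
        samples, _ = simulated_pair
        filtered, log = filter_for_distance(samples)
        assert log == []
        assert [s.N for s in filtered] == [s.N for s in samples]

    def test_population_emptied_by_filter_errors(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS19"])
        p = Profile("x", "P", {"DYS19": AlleleCall(())}, panel)
        with pytest.raises(ValueError, match="P"):
            filter_for_distance([PopulationSample("P", (p,))])


class TestAmovaTwoGroup:
    def test_identical_populations_phi_clamps_to_zero(self):
        """Same haplotype multiset in both populations: the unbiased raw
        estimate is <= 0, so the reported (clamped) distance is zero."""
        haps = [(13, 22), (13, 22), (14, 23), (15, 21)]
        a, b = make_pop("A", haps), make_pop("B", haps)
        for model in (DistanceModel.fst(), DistanceModel.rst()):
            comp = amova_two_group(a, b, model)
            assert comp.phi_st <= 1e-12
            assert max(comp.phi_st, 0.0) == 0.0

    def test_fixed_populations_one_step_apart_phi_one(self):
        a = make_pop("A", [(13, 22)] * 5)
        b = make_pop("B", [(14, 22)] * 5)
        comp = amova_two_group(a, b, DistanceModel.rst())
        assert comp.phi_st == pytest.approx(1.0)

    def test_phi_one_regardless_of_allele_gap(self):
        for gap in (1, 4, 9):
            a = make_pop("A", [(13, 22)] * 4)
            b = make_pop("B", [(13 + gap, 22)] * 4)
            comp = amova_two_group(a, b, DistanceModel.rst())
            assert comp.phi_st == pytest.approx(1.0)

    def test_degenerate_all_zero_distances(self):
        a = make_pop("A", [(13, 22)] * 3)
        b = make_pop("B", [(13, 22)] * 3)
        comp = amova_two_group(a, b, DistanceModel.rst())
        assert comp.phi_st == 0.0

    @pytest.mark.parametrize("kind", ["IDENTITY", "SQUARED_REPEAT"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_first_principles_oracle(self, kind, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 7))
        n_b = int(rng.integers(2, min(7, 13 - n_a)))
        a, b = random_pops(rng, n_a, n_b)
        model = DistanceModel(kind=DistanceKind(kind))
        comp = amova_two_group(a, b, model)
        assert comp.phi_st == pytest.approx(oracle_phi(a, b, kind), abs=1e-10)

    def test_replication_consistency(self):
        """Duplicating every profile k times barely moves the Phi estimate."""

        def haps(pop):
            return [
                tuple(p.calls[l].values[0] / 10 for l in TWO_LOCI.loci)
                for p in pop.profiles
            ]

        rng = np.random.default_rng(42)
        a, b = random_pops(rng, 5, 6)
        base = amova_two_group(a, b, DistanceModel.rst()).phi_st
        for k in (2, 3):
            ak = make_pop("A", [h for h in haps(a) for _ in range(k)])
            bk = make_pop("B", [h for h in haps(b) for _ in range(k)])
            rep = amova_two_group(ak, bk, DistanceModel.rst()).phi_st
            assert rep == pytest.approx(base, abs=0.12)

    def test_small_populations_rejected(self):
        a = make_pop("A", [(13, 22)])
        b = make_pop("B", [(14, 22), (14, 23)])
        with pytest.raises(ValueError):
            amova_two_group(a, b, DistanceModel.rst())


class TestPairwiseMatrix:
    def test_determinism_under_seed(self, simulated_pair):
        samples, _ = simulated_pair
        r1 = pairwise_matrix(samples, DistanceModel.rst(), permutations=49, seed=9)
        r2 = pairwise_matrix(samples, DistanceModel.rst(), permutations=49, seed=9)
        assert r1.phi_raw.equals(r2.phi_raw)
        assert r1.pvalues.equals(r2.pvalues)

    def test_matrix_shape_and_symmetry(self, simulated_pair):
        samples, _ = simulated_pair
        res = pairwise_matrix(samples, DistanceModel.rst(), permutations=49, seed=1)
        phi = res.phi
        assert (phi.values == phi.values.T).all()
        assert (np.diag(phi.values) == 0).all()
        p = res.pvalues.iloc[0, 1]
        assert 0 < p <= 1

    def test_diverged_pair_significant_and_negative_phi_clamped(self, simulated_pair):
        samples, _ = simulated_pair
        res = pairwise_matrix(samples, DistanceModel.rst(), permutations=199, seed=3)
        assert res.phi_raw.iloc[0, 1] > 0.1
        assert res.pvalues.iloc[0, 1] <= 0.01
        assert (res.phi.values >= 0).all()

    def test_summary_mentions_metric_and_pair(self, simulated_pair):
        samples, _ = simulated_pair
        res = PairwiseAmova(samples).fit(permutations=19, seed=0)
        text = res.summary()
        assert "Rst" in text and "POP1 vs POP2" in text

    def test_needs_two_populations(self, simulated_pair):
        samples, _ = simulated_pair
        with pytest.raises(ValueError):
            PairwiseAmova(samples[:1])


class TestMonotoneDivergence:
    def test_median_rst_increases_with_divergence(self):
        """Deeper splits under the stepwise mutation model give larger Rst."""
        medians = []
        for gens in (0, 50, 200, 800):
            phis = []
            for rep in range(3):
                cfg = SimulationConfig(
                    n_samples=(20, 20),
                    divergence_generations=(0, gens),
                    within_generations=100,
                    seed=1000 + 10 * gens + rep,
                )
                samples, _ = simulate_populations(cfg)
                res = pairwise_matrix(
                    samples, DistanceModel.rst(), permutations=0
                )
                phis.append(res.phi_raw.iloc[0, 1])
            medians.append(float(np.median(phis)))
        assert all(x < y for x, y in zip(medians, medians[1:]))


class TestMulticopyInclusion:
    def test_multicopy_compared_copywise_when_included(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS19", "DYS385"])
        a = make_profile("a", "P", [(15,), (13, 18)], panel)
        b = make_profile("b", "P", [(15,), (13, 20)], panel)
        model = DistanceModel.rst(include_multicopy=True)
        assert profile_distance(a, b, model) == pytest.approx(4.0)

    def test_copy_number_mismatch_rejected(self):
        panel = YFILER_PLUS_PANEL.restrict(["DYS385"])
        a = make_profile("a", "P", [(13, 18)], panel)
        b = make_profile("b", "P", [(13,)], panel)
        model = DistanceModel.rst(include_multicopy=True)
        with pytest.raises(ValueError, match="copy-number"):
            profile_distance(a, b, model)
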