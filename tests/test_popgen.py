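"""Haplotype table, Weir-Cockerham theta, network, admixture and delta-K."""

import numpy as np
import pytest

import boarmark as bm
from boarmark.popgen import (HAPLOTYPE_CLASSES, HaplotypeTable,
                             MonomorphicLocusError, class_distance,
                             diplotypes_to_site_coding, network_to_frame)


def table_of(**pops):
    return HaplotypeTable(classes=HAPLOTYPE_CLASSES,
                          counts={p: dict(c) for p, c in pops.items()})


def anova_theta(counts_a, counts_b):
    """Independent oracle: one-way ANOVA on per-chromosome 0/1 indicators.

    For each allele, chromosomes are scored 1 if they carry it; mean
    squares among and within populations come straight from the sums of
    squares, and theta follows Weir & Cockerham's haploid estimator
    (MSP - MSG) / (MSP + (nc - 1) MSG) with components summed over
    alleles.
    """
    alleles = sorted(set(counts_a) | set(counts_b))
    groups = []
    for counts in (counts_a, counts_b):
        n = sum(counts.values())
        mat = np.zeros((n, len(alleles)))
        row = 0
        for j, al in enumerate(alleles):
            for _ in range(counts.get(al, 0)):
                mat[row, j] = 1.0
                row += 1
        groups.append(mat)
    n1, n2 = len(groups[0]), len(groups[1])
    n_t = n1 + n2
    nc = (n_t - (n1 ** 2 + n2 ** 2) / n_t)
    num = den = 0.0
    for j in range(len(alleles)):
        y1, y2 = groups[0][:, j], groups[1][:, j]
        grand = np.concatenate([y1, y2]).mean()
        ss_among = n1 * (y1.mean() - grand) ** 2 + n2 * (y2.mean() - grand) ** 2
        ss_within = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
        msp = ss_among / 1
        msg = ss_within / (n_t - 2)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num / den


DOMESTIC = {"E+": 2, "e": 31, "ED": 90, "EP3": 11}
WILD = {"E+": 46, "ED": 2}


class TestHaplotypeTable:
    def test_counts_from_cohort_diplotypes(self, cohort_diplotypes):
        table = bm.build_haplotype_table(cohort_diplotypes)
        assert table.counts["wild_boar"] == WILD
        assert table.counts["domestic"] == DOMESTIC
        assert table.n_chromosomes("domestic") == 134
        assert table.n_chromosomes("wild_boar") == 48
        # hybrids are not part of the two-population comparison
        assert set(table.counts) == {"wild_boar", "domestic"}

    def test_exactly_four_classes(self, cohort_diplotypes):
        table = bm.build_haplotype_table(cohort_diplotypes)
        assert table.observed_classes() == ("e", "E+", "ED", "EP3")

    def test_single_homozygote(self):
        d = type("D", (), {"sample_id": "x", "breed_label": "D",
                           "pair": ("e", "e")})()
        table = bm.build_haplotype_table([d])
        assert table.counts == {"domestic": {"e": 2}}


class TestFst:
    def test_identical_frequencies_give_near_zero(self):
        t = table_of(a={"e": 500, "E+": 500}, b={"e": 500, "E+": 500})
        assert abs(bm.fst_weir_cockerham(t, "a", "b").theta) < 0.005

    def test_fixed_difference_gives_one(self):
        t = table_of(a={"e": 40}, b={"E+": 60})
        assert bm.fst_weir_cockerham(t, "a", "b").theta == pytest.approx(1.0)

    def test_monomorphic_is_undefined_not_zero(self):
        t = table_of(a={"ED": 40}, b={"ED": 60})
        with pytest.raises(MonomorphicLocusError):
            bm.fst_weir_cockerham(t, "a", "b")

    def test_agrees_with_anova_oracle_on_default_table(self):
        t = table_of(domestic=DOMESTIC, wild_boar=WILD)
        res = bm.fst_weir_cockerham(t, "domestic", "wild_boar")
        assert res.theta == pytest.approx(anova_theta(DOMESTIC, WILD),
                                          abs=1e-12)

    def test_agrees_with_anova_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = {c: int(n) for c, n in
                 zip(HAPLOTYPE_CLASSES, rng.integers(1, 60, 4))}
            b = {c: int(n) for c, n in
                 zip(HAPLOTYPE_CLASSES, rng.integers(1, 60, 4))}
            t = table_of(a=a, b=b)
            assert bm.fst_weir_cockerham(t, "a", "b").theta == \
                pytest.approx(anova_theta(a, b), abs=1e-12)

    def test_invariant_to_relabeling_and_swap(self):
        t = table_of(a=DOMESTIC, b=WILD)
        base = bm.fst_weir_cockerham(t, "a", "b").theta
        assert bm.fst_weir_cockerham(t, "b", "a").theta == pytest.approx(base)
        relabeled = table_of(
            a={"ED": 2, "EP3": 31, "e": 90, "E+": 11},
            b={"ED": 46, "e": 2})
        assert bm.fst_weir_cockerham(relabeled, "a", "b").theta == \
            pytest.approx(base)

    def test_downsampling_stability(self):
        t = table_of(domestic=DOMESTIC, wild_boar=WILD)
        full = bm.fst_weir_cockerham(t, "domestic", "wild_boar").theta
        half = table_of(
            domestic={c: n // 2 for c, n in DOMESTIC.items()},
            wild_boar={c: max(n // 2, 1) for c, n in WILD.items()})
        sub = bm.fst_weir_cockerham(half, "domestic", "wild_boar").theta
        assert abs(sub - full) < 0.1

    def test_gst_estimator_available(self):
        t = table_of(domestic=DOMESTIC, wild_boar=WILD)
        res = bm.fst_weir_cockerham(t, "domestic", "wild_boar",
                                    estimator="nei-gst")
        assert 0 < res.theta < 1 and res.estimator == "nei-gst"


class TestNetwork:
    @pytest.mark.parametrize("a, b, d", [
        ("E+", "ED", 1), ("E+", "e", 2), ("e", "ED", 3)])
    def test_hamming_distances(self, a, b, d):
        dist, defined = class_distance(a, b)
        assert dist == d and defined

    def test_ep3_edges_flagged_undefined(self):
        g = bm.haplotype_network({"E+": 46, "ED": 90, "EP3": 11, "e": 31})
        assert g.edges["ED", "EP3"]["distance_defined"] is False
        assert g.edges["E+", "ED"]["distance_defined"] is True
        df = network_to_frame(g)
        assert set(df.columns) == {"from", "to", "distance",
                                   "distance_defined", "mst"}
        assert df["mst"].sum() == 3          # spanning tree on 4 nodes


class TestAdmixture:
    def test_k1_em_equals_closed_form_multinomial(self, cohort_diplotypes):
        x = diplotypes_to_site_coding(cohort_diplotypes)
        fit = bm.admixture_fit(x, K=1, seed=3, method="em")
        assert np.allclose(fit.Q, 1.0)
        ll = 0.0
        for l in range(x.shape[1]):
            c = np.bincount(x[:, l, :].reshape(-1))
            p = c / c.sum()
            ll += (c[c > 0] * np.log(p[p > 0])).sum()
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6)

    def test_em_log_likelihood_is_monotone(self, cohort_diplotypes):
        x = diplotypes_to_site_coding(cohort_diplotypes)
        for seed in (0, 1, 2):
            fit = bm.admixture_fit(x, K=3, seed=seed, method="em")
            assert (np.diff(fit.ll_trace) >= -1e-9).all()

    def test_gibbs_recovers_two_fixed_populations(self):
        for seed in range(5):
            g, labels = bm.generate_structured_pops(
                2, 50, [[1.0, 0.0], [0.0, 1.0]], seed=seed)
            fit = bm.admixture_fit(g, K=2, seed=100 + seed,
                                   burn_in=500, n_reps=1500)
            own = fit.Q.argmax(1)
            # each population maps onto one cluster, confidently
            assert (own[labels == 0] == own[labels == 0][0]).all()
            assert (own[labels == 1] == own[labels == 1][0]).all()
            assert own[labels == 0][0] != own[labels == 1][0]
            assert fit.Q.max(1).min() >= 0.95

    def test_q_rows_sum_to_one(self, cohort_diplotypes):
        x = diplotypes_to_site_coding(cohort_diplotypes)
        fit = bm.admixture_fit(x, K=3, seed=9, burn_in=200, n_reps=400)
        assert np.allclose(fit.Q.sum(1), 1.0, atol=1e-9)

    def test_deterministic_given_seed(self, cohort_diplotypes):
        x = diplotypes_to_site_coding(cohort_diplotypes)
        a = bm.admixture_fit(x, K=2, seed=7, burn_in=100, n_reps=200)
        b = bm.admixture_fit(x, K=2, seed=7, burn_in=100, n_reps=200)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.Q, b.Q)

    def test_excessive_k_warns_but_runs(self):
        g, _ = bm.generate_structured_pops(2, 3, [[1, 0], [0, 1]], seed=0)
        with pytest.warns(UserWarning, match="distinct"):
            bm.admixture_fit(g, K=5, seed=1, burn_in=50, n_reps=100)


class TestEvanno:
    def test_hand_computed_four_point_series(self):
        # second differences: |{-49} - 2{-50} + {-100}| = 49 at K=2,
        # |{-48.5} - 2{-49} + {-50}| = 0.5 at K=3; sd == 1 at every K
        lls = {1: [-99.0, -101.0], 2: [-49.0, -51.0],
               3: [-48.0, -50.0], 4: [-47.5, -49.5]}
        res = bm.evanno_delta_k(lls)
        assert res.optimal_k == 2
        dk = dict(zip(res.table["K"], res.table["delta_K"]))
        sd = np.std([-99.0, -101.0], ddof=1)
        assert dk[2] == pytest.approx(49.0 / sd)
        assert dk[3] == pytest.approx(0.5 / sd)

    def test_constant_likelihood_has_no_optimum(self):
        lls = {k: [-10.0, -10.0] for k in (1, 2, 3, 4)}
        with pytest.warns(UserWarning):
            res = bm.evanno_delta_k(lls)
        assert res.optimal_k is None

    def test_zero_sd_k_excluded_with_warning(self):
        lls = {1: [-100.0, -100.0], 2: [-50.0, -50.0],
               3: [-48.0, -49.0], 4: [-47.0, -48.0]}
        with pytest.warns(UserWarning, match="K=2"):
            res = bm.evanno_delta_k(lls)
        assert res.optimal_k == 3

    def test_requires_consecutive_ks_and_replicates(self):
        with pytest.raises(ValueError):
            bm.evanno_delta_k({1: [-1, -2], 3: [-1, -2], 4: [-1, -2]})
        with pytest.raises(ValueError):
            bm.evanno_delta_k({1: [-1], 2: [-1], 3: [-1]})


class TestStructuredPops:
    def test_fixed_populations_have_zero_within_variance(self):
        g, labels = bm.generate_structured_pops(2, 10, [[1, 0], [0, 1]],
                                                seed=0)
        assert (g[labels == 0] == 0).all() and (g[labels == 1] == 1).all()

    def test_law_of_large_numbers(self):
        freqs = np.array([[2, 31, 90, 11]]) / 134.0
        g, _ = bm.generate_structured_pops(1, 10_000, freqs, seed=1)
        emp = np.bincount(g.reshape(-1), minlength=4) / (2 * 10_000)
        assert np.abs(emp - freqs[0]).max() < 0.02

    def test_deterministic_given_seed(self):
        a, _ = bm.generate_structured_pops(2, 30, [[0.5, 0.5], [0.1, 0.9]],
                                           seed=5)
        b, _ = bm.generate_structured_pops(2, 30, [[0.5, 0.5], [0.1, 0.9]],
                                           seed=5)
        assert np.array_equal(a, b)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            bm.generate_structured_pops(1, 5, [[0.5, 0.4]], seed=0)
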