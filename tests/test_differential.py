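"""Paired-site extraction, sharing filter, the paired Wald test and DMC calling."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cryomethyl.differential import (
    PairedSiteTable,
    build_paired_table,
    call_dmcs,
    classify_dmc,
    extract_paired,
    overlap_counts,
    paired_dm_test,
    select_shared_sites,
    sharing_distribution,
    run_paired_tests,
)
from cryomethyl.types import CytosineRecord, SampleMethylome


def _sample(keys, male=1, cond="fresh", counts=(2, 1)):
    s = SampleMethylome(male_id=male, condition=cond)
    for chrom, pos, strand in keys:
        s.add(CytosineRecord(chrom, pos, strand, *counts))
    return s


K = lambda p: ("chr1", p, "+")  # noqa: E731


class TestExtractPaired:
    def test_intersection(self):
        fresh = _sample([K(1), K(2), K(3)])
        treated = _sample([K(2), K(3), K(4)], cond="DMSO")
        assert set(extract_paired(fresh, treated)) == {K(2), K(3)}

    def test_disjoint_empty(self):
        assert extract_paired(_sample([K(1)]), _sample([K(2)], cond="DMSO")) == {}

    def test_male_mismatch_errors(self):
        with pytest.raises(ValueError, match="male"):
            extract_paired(_sample([K(1)], male=1), _sample([K(1)], male=2, cond="DMSO"))

    def test_counts_preserved_both_sides(self):
        fresh = _sample([K(1)], counts=(5, 0))
        treated = _sample([K(1)], cond="DMSO", counts=(1, 4))
        assert extract_paired(fresh, treated)[K(1)] == (5, 0, 1, 4)

    def test_matches_brute_force_on_fixture(self, small_study):
        fresh = small_study.samples[(1, "fresh")]
        treated = small_study.samples[(1, "MeOH")]
        got = set(extract_paired(fresh, treated))
        assert got == set(fresh.records) & set(treated.records)


class TestSharing:
    def test_small_example(self):
        fresh = {1: _sample([K(1), K(2)], male=1),
                 2: _sample([K(2), K(3)], male=2)}
        treated = {m: _sample(list(fresh[m].records), male=m, cond="DMSO")
                   for m in fresh}
        table = build_paired_table(fresh, treated, "DMSO")
        df = sharing_distribution(table, n_males=2)
        assert df.loc[df.n_males == 1, "n_sites"].item() == 2
        assert df.loc[df.n_males == 2, "n_sites"].item() == 1

    def test_all_males_identical(self):
        keys = [K(i) for i in range(5)]
        fresh = {m: _sample(keys, male=m) for m in range(1, 13)}
        treated = {m: _sample(keys, male=m, cond="DMSO") for m in range(1, 13)}
        table = build_paired_table(fresh, treated, "DMSO")
        df = sharing_distribution(table, n_males=12)
        assert df.loc[df.n_males == 12, "n_sites"].item() == 5
        assert df.n_sites.sum() == 5

    def test_conservation_and_oracle_on_fixture(self, small_study):
        fresh = {m: small_study.samples[(m, "fresh")] for m in range(1, 13)}
        treated = {m: small_study.samples[(m, "DMSO")] for m in range(1, 13)}
        table = build_paired_table(fresh, treated, "DMSO")
        df = sharing_distribution(table, n_males=12)
        # brute-force dictionary count oracle
        counts = {}
        for m in range(1, 13):
            for key in set(fresh[m].records) & set(treated[m].records):
                counts[key] = counts.get(key, 0) + 1
        assert df.n_sites.sum() == len(counts)
        for n in range(1, 13):
            assert df.loc[df.n_males == n, "n_sites"].item() \
                == sum(1 for v in counts.values() if v == n)
        cum = 100.0 * sum(1 for v in counts.values() if v >= 6) / len(counts)
        assert df.attrs["cum_pct_min_males"] == pytest.approx(cum)

    def test_select_shared_boundary(self):
        table = PairedSiteTable("DMSO")
        table.sites[K(1)] = {m: (1, 0, 1, 0) for m in range(1, 7)}   # 6 males
        table.sites[K(2)] = {m: (1, 0, 1, 0) for m in range(1, 6)}   # 5 males
        assert select_shared_sites(table, min_males=6) == {K(1)}
        with pytest.raises(ValueError):
            select_shared_sites(table, min_males=13, n_males=12)


class TestPairedTest:
    def test_identical_counts_null(self):
        pairs = {m: (3, 2, 3, 2) for m in range(1, 7)}
        z, p = paired_dm_test(pairs)
        assert z == 0.0 and p == 1.0

    def test_single_male_closed_form(self):
        # fresh 10/10 methylated, treated 0/10: frozen closed-form oracle
        z, p = paired_dm_test({1: (10, 0, 0, 10)})
        yf = math.asin(math.sqrt(10.5 / 11))
        yt = math.asin(math.sqrt(0.5 / 11))
        expect_z = (yt - yf) / math.sqrt(2 / 44)
        assert z == pytest.approx(expect_z)
        assert z == pytest.approx(-5.35221776, abs=1e-6)
        assert p == pytest.approx(8.6883e-08, rel=1e-3)

    def test_vectorized_agrees_with_scalar(self, power_study):
        fresh = {m: power_study.samples[(m, "fresh")] for m in range(1, 13)}
        treated = {m: power_study.samples[(m, "glycerol")] for m in range(1, 13)}
        table = build_paired_table(fresh, treated, "glycerol")
        results = run_paired_tests(table)
        for r in results[:50]:
            z, p = paired_dm_test(table.sites[r.site])
            assert r.statistic == pytest.approx(z)
            assert r.p_value == pytest.approx(p)

    def test_type_I_error_at_alpha_001(self):
        """Null calibration at depths 10-40, 12 males, intermediate ratios."""
        rng = np.random.default_rng(202)
        n_sites, n_males = 10_000, 12
        r = rng.uniform(0.2, 0.8, size=(n_sites, 1))
        nf = rng.integers(10, 41, size=(n_sites, n_males))
        nt = rng.integers(10, 41, size=(n_sites, n_males))
        kf = rng.binomial(nf, r)
        kt = rng.binomial(nt, r)
        table = PairedSiteTable("null")
        for i in range(n_sites):
            table.sites[K(i + 1)] = {
                m + 1: (int(kf[i, m]), int(nf[i, m] - kf[i, m]),
                        int(kt[i, m]), int(nt[i, m] - kt[i, m]))
                for m in range(n_males)}
        results = run_paired_tests(table)
        frac = np.mean([res.p_value < 0.001 for res in results])
        # binomial 99% band around 0.001 at n = 10^4
        sd = math.sqrt(0.001 * 0.999 / n_sites)
        assert abs(frac - 0.001) <= 2.58 * sd

    def test_agrees_with_sign_flip_permutation(self):
        """P-value ranks track an exact sign-flip permutation test (6 males)."""
        rng = np.random.default_rng(77)
        n_sites, n_males = 200, 6
        wald_p, perm_p = [], []
        flips = np.array(list(itertools.product([1.0, -1.0], repeat=n_males)))
        for _ in range(n_sites):
            r0 = rng.uniform(0.1, 0.9)
            shift = rng.normal(0, 0.1)
            nf = np.full(n_males, 30)
            nt = np.full(n_males, 30)
            kf = rng.binomial(nf, r0)
            kt = rng.binomial(nt, np.clip(r0 + shift, 0, 1))
            pairs = {m + 1: (int(kf[m]), int(nf[m] - kf[m]),
                             int(kt[m]), int(nt[m] - kt[m]))
                     for m in range(n_males)}
            z, p = paired_dm_test(pairs)
            wald_p.append(p)
            # oracle: exact sign-flip distribution of the weighted mean difference
            y_f = np.arcsin(np.sqrt((kf + 0.5) / (nf + 1)))
            y_t = np.arcsin(np.sqrt((kt + 0.5) / (nt + 1)))
            d = y_t - y_f
            w = 1.0 / (1 / (4 * (nt + 1)) + 1 / (4 * (nf + 1)))
            obs = abs(np.sum(d * w))
            null = np.abs((flips * d * w).sum(axis=1))
            perm_p.append(np.mean(null >= obs - 1e-12))
        rho = stats.spearmanr(wald_p, perm_p).statistic
        assert rho > 0.9

    def test_injected_dmc_recovery(self, power_study):
        """>=80% of injected DMCs (effect 0.5, depth ~30, concordance 0.75) recover."""
        fresh = {m: power_study.samples[(m, "fresh")] for m in range(1, 13)}
        for cp in ("DMSO", "MeOH", "glycerol"):
            treated = {m: power_study.samples[(m, cp)] for m in range(1, 13)}
            table = build_paired_table(fresh, treated, cp)
            dmcs = call_dmcs(run_paired_tests(table))
            injected = {d.site: d.direction
                        for d in power_study.truth.injected_for(cp)}
            recovered = [r for r in dmcs if r.site in injected]
            assert len(recovered) >= 0.8 * len(injected)
            # direction recovery among recovered sites
            match = sum(1 for r in recovered if r.trend_class == injected[r.site])
            assert match >= 0.9 * len(recovered)


class TestCallAndClassify:
    def test_empty(self):
        assert call_dmcs([]) == []

    def test_p_equal_alpha_excluded(self):
        from cryomethyl.differential import DMCResult
        r = DMCResult(K(1), 0.0, 0.001, {1: 0.1}, "hyper", 1)
        assert call_dmcs([r], alpha=0.001) == []
        assert call_dmcs([r], alpha=0.0011) == [r]

    @pytest.mark.parametrize("deltas,expected", [
        ({m: -0.1 for m in range(1, 9)} | {m: 0.1 for m in range(9, 13)}, "hypo"),
        ({m: 0.1 for m in range(1, 7)} | {m: -0.1 for m in range(7, 13)}, "unclassified"),
        ({1: 0.1, 2: 0.1, 3: 0.1, 4: 0.1, 5: -0.1, 6: -0.1, 7: -0.1}, "hyper"),
        ({1: 0.0, 2: 0.0, 3: 0.1}, "unclassified"),  # zeros count toward neither
    ])
    def test_majority_rule(self, deltas, expected):
        assert classify_dmc(deltas) == expected

    def test_class_partition_conservation(self, power_study):
        fresh = {m: power_study.samples[(m, "fresh")] for m in range(1, 13)}
        treated = {m: power_study.samples[(m, "DMSO")] for m in range(1, 13)}
        dmcs = call_dmcs(run_paired_tests(build_paired_table(fresh, treated, "DMSO")))
        n_by_class = {c: sum(r.trend_class == c for r in dmcs)
                      for c in ("hyper", "hypo", "unclassified")}
        assert sum(n_by_class.values()) == len(dmcs)


class TestVenn:
    def test_disjoint(self):
        sets = {"A": {K(i) for i in range(3)},
                "B": {K(i) for i in range(10, 14)},
                "C": {K(i) for i in range(20, 25)}}
        part = overlap_counts(sets)
        assert part[("A",)] == 3 and part[("B",)] == 4 and part[("C",)] == 5
        assert part[("A", "B", "C")] == 0

    def test_identical(self):
        s = {K(i) for i in range(7)}
        part = overlap_counts({"A": set(s), "B": set(s), "C": set(s)})
        assert part[("A", "B", "C")] == 7
        assert sum(v for k, v in part.items() if len(k) < 3) == 0

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(5)
        universe = [K(i) for i in range(60)]
        sets = {name: {k for k in universe if rng.random() < 0.4}
                for name in ("DMSO", "MeOH", "glycerol")}
        part = overlap_counts(sets)
        # oracle: per-site membership enumeration
        assert sum(part.values()) == len(set().union(*sets.values()))
        for site in set().union(*sets.values()):
            key = tuple(sorted(n for n in sets if site in sets[n]))
            assert part[key] >= 1
        brute = {}
        for site in set().union(*sets.values()):
            key = tuple(sorted(n for n in sets if site in sets[n]))
            brute[key] = brute.get(key, 0) + 1
        for k, v in brute.items():
            assert part[k] == v
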