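"""Generator correctness: digestion, truth mixture, count model, determinism."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from cryomethyl import io as mio
from cryomethyl.simulate import (
    InjectedDMC,
    SimulationConfig,
    TruthTable,
    assign_truth,
    build_toy_genome,
    digest_mspi,
    simulate_counts,
    simulate_study,
    solve_p_methylated,
    substream,
    write_fixture_set,
)


class TestToyGenome:
    def test_cpg_convention_both_strands(self):
        # "AACCGGTT": CG dinucleotide at 1-based (4,5) -> cytosines (+,4), (-,5)
        seqs = {"chr1": "AACCGGTT"}
        arr = seqs["chr1"]
        cg0 = [i for i in range(len(arr) - 1) if arr[i : i + 2] == "CG"]
        assert cg0 == [3]
        cfg = SimulationConfig(seed=0, n_chrom=1, chrom_length=1000)
        _, cytosines = build_toy_genome(cfg)
        # invariant on the generated genome itself: 2 cytosines per CG dinucleotide
        seq = build_toy_genome(cfg)[0]["chr1"]
        n_cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert len(cytosines) == 2 * n_cg
        plus = [(c, p) for c, p, s in cytosines if s == "+"]
        minus = [(c, p) for c, p, s in cytosines if s == "-"]
        assert all((c, p + 1) in minus for c, p in plus)

    def test_ccgg_count_in_poisson_band(self):
        # density 5/kb over 100 kb -> ~Poisson(500); 99% band ~ 500 +/- 2.58*sqrt(500)
        cfg = SimulationConfig(seed=5, n_chrom=1, chrom_length=100_000, mspi_density=5.0)
        seqs, _ = build_toy_genome(cfg)
        n = seqs["chr1"].count("CCGG")
        lo = 500 - 2.58 * np.sqrt(500) - 15  # small allowance for plant collisions
        hi = 500 + 2.58 * np.sqrt(500)
        assert lo <= n <= hi


class TestDigestion:
    def test_cut_site_definition(self):
        seq = "AAACCGGAAACCGGAAA"
        frags, _ = digest_mspi({"c": seq}, 1, 100)
        spans = [(s, e) for _, s, e in frags]
        assert spans == [(1, 4), (5, 11), (12, 17)]
        middle = seq[spans[1][0] - 1 : spans[1][1]]
        assert middle == "CGGAAAC" and len(middle) == 7

    def test_no_ccgg_single_fragment(self):
        frags, _ = digest_mspi({"c": "ATATATAT"}, 1, 100)
        assert len(frags) == 1

    def test_fragment_count_equals_cut_count_plus_one(self):
        cfg = SimulationConfig(seed=9, n_chrom=2, chrom_length=50_000)
        seqs, _ = build_toy_genome(cfg)
        frags, _ = digest_mspi(seqs, 1, 10**9)
        for chrom, seq in seqs.items():
            # brute-force scan oracle
            n_ccgg = sum(1 for i in range(len(seq) - 3) if seq[i : i + 4] == "CCGG")
            n_frags = sum(1 for c, _, _ in frags if c == chrom)
            assert n_frags == n_ccgg + 1

    def test_size_selection_bounds(self):
        cfg = SimulationConfig(seed=9, n_chrom=1, chrom_length=50_000)
        seqs, _ = build_toy_genome(cfg)
        _, kept = digest_mspi(seqs, 40, 220)
        assert kept and all(40 <= e - s + 1 <= 220 for _, s, e in kept)


class TestTruth:
    def test_null_effect_gives_identical_conditions(self):
        cfg = SimulationConfig(seed=2, n_chrom=1, chrom_length=30_000,
                               n_dmc_true=10, dmc_effect=0.0)
        study = simulate_study(cfg)
        for d in study.truth.injected:
            assert d.effect == 0.0
        site = study.truth.sites[0]
        vals = {c: study.truth.true_ratio(site, c, 1) for c in cfg.conditions}
        assert len(set(vals.values())) == 1

    def test_full_concordance_hits_all_males(self):
        cfg = SimulationConfig(seed=2, n_chrom=1, chrom_length=30_000,
                               n_dmc_true=10, dmc_concordance=1.0)
        study = simulate_study(cfg)
        assert all(len(d.males) == cfg.n_males for d in study.truth.injected)

    def test_mixture_frequencies_within_binomial_bands(self):
        cfg = SimulationConfig(seed=4)
        sites = [("chr1", 2 * i + 1, "+") for i in range(100_000)]
        truth = assign_truth(cfg, sites, propensity=np.ones(len(sites)),
                             rng=substream(4, "truth"))
        n = len(truth.baseline)
        for p_true, observed in [
            (cfg.p_methylated_site, np.sum(truth.baseline == 1.0)),
            (cfg.p_unmethylated_site, np.sum(truth.baseline == 0.0)),
        ]:
            sd = np.sqrt(n * p_true * (1 - p_true))
            assert abs(observed - n * p_true) <= 3 * sd

    def test_injection_exceeding_sites_errors(self):
        cfg = SimulationConfig(seed=2, n_dmc_true=10**7)
        sites = [("chr1", 2 * i + 1, "+") for i in range(100)]
        with pytest.raises(ValueError, match="n_dmc_true"):
            assign_truth(cfg, sites, propensity=np.ones(100))

    def test_solve_p_methylated_inverts_analytic_mean(self):
        p_m = solve_p_methylated(0.8634)
        cfg = SimulationConfig(p_methylated_site=p_m)
        assert cfg.analytic_mean == pytest.approx(0.8634, abs=1e-12)


class TestCounts:
    def _one_site_truth(self, ratio):
        sites = [("chr1", 2 * i + 1, "+") for i in range(2000)]
        return TruthTable(sites=sites, baseline=np.full(len(sites), ratio))

    def test_perfect_conversion_unmethylated(self):
        cfg = SimulationConfig(seed=6, n_males=1, conditions=("fresh",),
                               conversion_rate=1.0)
        truth = self._one_site_truth(0.0)
        samples = simulate_counts(truth, cfg, propensity=np.ones(len(truth.sites)))
        recs = list(samples[(1, "fresh")])
        assert recs and all(r.n_meth == 0 for r in recs)

    def test_fully_methylated_unaffected_by_conversion(self):
        cfg = SimulationConfig(seed=6, n_males=1, conditions=("fresh",),
                               conversion_rate=0.95)
        truth = self._one_site_truth(1.0)
        samples = simulate_counts(truth, cfg, propensity=np.ones(len(truth.sites)))
        assert all(r.n_unmeth == 0 for r in samples[(1, "fresh")])

    def test_conversion_failure_rate_recovered(self):
        # r=0, conversion 0.996 -> methylated fraction ~0.004 of ~6e4 reads
        cfg = SimulationConfig(seed=8, n_males=1, conditions=("fresh",))
        truth = self._one_site_truth(0.0)
        samples = simulate_counts(truth, cfg, propensity=np.ones(len(truth.sites)))
        n_meth = sum(r.n_meth for r in samples[(1, "fresh")])
        n_total = sum(r.depth for r in samples[(1, "fresh")])
        expect = 0.004 * n_total
        sd = np.sqrt(n_total * 0.004 * 0.996)
        assert abs(n_meth - expect) <= 3 * sd


class TestFixtureSet:
    def test_same_seed_byte_identical(self, tmp_path, small_config):
        a, b = tmp_path / "a", tmp_path / "b"
        write_fixture_set(small_config, a)
        write_fixture_set(small_config, b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert not mismatch and not errors

    def test_default_design_yields_48_samples(self, tmp_path, small_config):
        out = tmp_path / "fix"
        write_fixture_set(small_config, out)
        cx = list(out.glob("male*_*.CX_report.txt"))
        assert len(cx) == 12 * 4

    def test_glycerol_fertilization_all_zero(self, small_study):
        q = small_study.quality
        gly = q[q.condition == "glycerol"]
        assert (gly.fert_norm == 0).all()
        assert (gly.motility == 0).all()

    def test_quality_orderings(self, small_study):
        means = small_study.quality.groupby("condition").mean(numeric_only=True)
        assert means.loc["DMSO", "membrane"] >= means.loc["glycerol", "membrane"] \
            >= means.loc["MeOH", "membrane"]
        assert means.loc["DMSO", "motility"] > means.loc["MeOH", "motility"] \
            > means.loc["glycerol", "motility"]

    def test_truth_conservation_in_files(self, tmp_path, small_config):
        out = tmp_path / "fix"
        write_fixture_set(small_config, out)
        lines = (out / "truth_dmcs.tsv").read_text().strip().split("\n")[1:]
        assert len(lines) == small_config.n_dmc_true * 3
        for line in lines:
            fields = line.split("\t")
            assert fields[4] in ("hyper", "hypo")
            n_males = len(fields[6].split(","))
            assert n_males == int(np.ceil(small_config.dmc_concordance
                                          * small_config.n_males))


def test_global_mean_tracks_analytic_mean(power_study):
    """Fixture-wide mean methylation stays within 0.5 points of the mixture mean."""
    from cryomethyl.globalmeth import global_mean_methylation
    cfg = power_study.config
    means = [global_mean_methylation(power_study.samples[(m, "fresh")], min_depth=1)
             for m in range(1, cfg.n_males + 1)]
    assert abs(float(np.mean(means)) - 100 * cfg.analytic_mean) < 0.5
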