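import numpy as np
import pytest
from scipy.stats import ks_2samp

from hapsweep.haplodata import HaplotypeMatrix, read_ms
from hapsweep.sweepsim import (
    Demography,
    SweepModel,
    SweepSample,
    count_origins,
    footprint_length,
    simulate,
    write_ms,
)

# small, fast study system for forward-machinery unit tests: N' = 100
FAST = dict(
    demography=Demography(ne=2e5),
    rescale_q=2000.0,
    locus_length=20_000,
    sample_size=50,
)


class TestFootprint:
    def test_reference_point(self):
        # s = 0.05%, N_e = 1e6, rho = 5e-9 crossovers/bp: ~16.1 kb, over the
        # 10-kb analysis scale
        bp = footprint_length(5e-4, 1e6, 5e-9)
        assert bp == pytest.approx(1.61e4, rel=0.01)
        assert bp >= 10_000

    def test_monotone_and_sublinear_in_s(self):
        # the width grows with s but slower than linearly: the log in the
        # denominator grows too
        one = footprint_length(5e-4, 1e6, 5e-9)
        two = footprint_length(1e-3, 1e6, 5e-9)
        assert one < two < 2 * one

    def test_domain_edges(self):
        with pytest.raises(ValueError):
            footprint_length(1e-6, 1e6, 5e-9)
        with pytest.raises(ValueError):
            footprint_length(0.01, 1e6, 0.0)


class TestCountOrigins:
    def _sample(self, labels, mode="de_novo"):
        m = HaplotypeMatrix("c", [10], np.zeros((len(labels), 1), dtype=np.int8))
        m.alleles[0, 0] = 1
        return SweepSample(
            matrix=m,
            mode=mode,
            adaptive_col=None,
            origin_labels=np.array(labels),
            final_frequency=0.5,
            locus_length=100,
        )

    def test_single_and_multiple_labels(self):
        assert count_origins(self._sample([0, 0, 0, -1])) == 1
        assert count_origins(self._sample([0, 0, 1, -1])) == 2

    def test_neutral_errors(self):
        with pytest.raises(ValueError):
            count_origins(self._sample([-1, -1], mode="neutral"))


class TestNeutralMode:
    def test_watterson_segregating_sites(self):
        # theta = 4 * 1000 * 1e-7 * 1e5 = 40; E[S] = theta * H(n-1)
        model = SweepModel(
            demography=Demography(ne=1000),
            mu=1e-7,
            rho_cm_per_bp=1e-7,
            locus_length=100_000,
            sample_size=20,
            mode="neutral",
        )
        s_vals = [simulate(model, seed=i).matrix.n_snps for i in range(200)]
        expected = 40 * np.sum(1 / np.arange(1, 20))
        se = np.std(s_vals, ddof=1) / np.sqrt(len(s_vals))
        assert abs(np.mean(s_vals) - expected) < 3 * se

    def test_pairwise_diversity_matches_theta(self):
        model = SweepModel(
            demography=Demography(ne=1000),
            mu=1e-7,
            rho_cm_per_bp=1e-7,
            locus_length=50_000,
            sample_size=20,
            mode="neutral",
        )
        theta_site = 4 * 1000 * 1e-7
        pis = []
        for i in range(200):
            m = simulate(model, seed=1000 + i).matrix
            n = m.n_haplotypes
            p = m.alleles.mean(axis=0)
            pi = np.sum(2 * p * (1 - p) * n / (n - 1)) / model.locus_length
            pis.append(pi)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta_site) < 3 * se

    def test_bottleneck_and_admixture_demographies_run(self):
        for dem in (
            Demography(model="bottleneck", ne=5000, nb=0.01, tb=0.01, nf=1.0, tf=0.005),
            Demography(model="admixture", ne=5000, n1=1.0, n2=0.5, prop=0.7),
        ):
            model = SweepModel(
                demography=dem,
                mu=1e-7,
                rho_cm_per_bp=1e-7,
                locus_length=10_000,
                sample_size=10,
                mode="neutral",
            )
            m = simulate(model, seed=5).matrix
            assert m.n_haplotypes == 10


class TestSweepModes:
    def test_stopping_rule_partial_frequency(self):
        model = SweepModel(mode="de_novo", theta_a=1.0, s=0.01, pf=0.5, **FAST)
        for seed in (1, 2, 3):
            sample = simulate(model, seed=seed)
            n_prime = model.n_prime
            assert 0.5 <= sample.final_frequency <= 0.5 + 1 / (2 * n_prime)

    def test_complete_sweep_allowed(self):
        model = SweepModel(mode="de_novo", theta_a=0.1, s=0.05, pf=1.0, **FAST)
        sample = simulate(model, seed=7)
        assert sample.final_frequency == 1.0

    def test_hard_regime_single_origin(self):
        model = SweepModel(mode="de_novo", theta_a=0.01, s=0.01, pf=0.5, **FAST)
        origins = [count_origins(simulate(model, seed=s)) for s in range(15)]
        assert np.mean([o == 1 for o in origins]) >= 0.9

    def test_sgv_single_copy_start_is_single_origin(self):
        model = SweepModel(mode="sgv", f0=1e-6, s=0.05, pf=0.5, **FAST)
        sample = simulate(model, seed=11)
        assert count_origins(sample) == 1
        assert sample.n_carriers > 0

    def test_sgv_standing_variant_multiple_backgrounds(self):
        # f0 = 0.05 -> 10 copies at onset; several backgrounds usually sampled
        model = SweepModel(mode="sgv", f0=0.05, s=0.05, pf=0.5, **FAST)
        origins = [count_origins(simulate(model, seed=s)) for s in range(5)]
        assert max(origins) > 1

    def test_adaptive_column_centered(self):
        model = SweepModel(mode="de_novo", theta_a=1.0, s=0.05, pf=0.5, **FAST)
        sample = simulate(model, seed=3)
        if sample.adaptive_col is not None:
            pos = sample.matrix.positions[sample.adaptive_col]
            assert abs(pos - model.locus_length / 2) <= 1

    def test_sweep_requires_positive_s(self):
        model = SweepModel(mode="de_novo", theta_a=1.0, s=0.0, pf=0.5, **FAST)
        with pytest.raises(ValueError, match="s > 0"):
            simulate(model, seed=1)

    def test_sample_larger_than_population_errors(self):
        model = SweepModel(
            mode="de_novo", theta_a=1.0, s=0.05, pf=0.5,
            demography=Demography(ne=2e5), rescale_q=2000.0,
            locus_length=20_000, sample_size=500,
        )
        with pytest.raises(ValueError, match="sample size"):
            simulate(model, seed=1)

    def test_rescaling_invariance_of_diversity(self):
        # same population-scaled parameters at two rescaling factors: the
        # segregating-sites distributions should agree (KS at alpha = 0.01).
        # s is kept small enough that the rescaled coefficient s' = sQ stays
        # below ~0.25, the regime where generation-by-generation rescaling is
        # faithful.
        base = dict(
            mode="de_novo", theta_a=1.0, s=2.5e-5, pf=0.5,
            demography=Demography(ne=1e6), locus_length=20_000, sample_size=50,
        )
        s_a = [
            simulate(SweepModel(rescale_q=5_000.0, **base), seed=i).matrix.n_snps
            for i in range(80)
        ]
        s_b = [
            simulate(SweepModel(rescale_q=2_500.0, **base), seed=1_000 + i).matrix.n_snps
            for i in range(80)
        ]
        assert ks_2samp(s_a, s_b).pvalue > 0.01


class TestMsRoundTrip:
    def test_write_then_read_identity(self, tmp_path):
        model = SweepModel(mode="de_novo", theta_a=1.0, s=0.05, pf=0.5, **FAST)
        samples = [simulate(model, seed=s) for s in (1, 2, 3)]
        path = str(tmp_path / "sweeps.ms")
        write_ms(samples, path)
        text = open(path).read()
        assert text.count("//") == 3
        back = read_ms(path, model.locus_length, model.sample_size)
        assert len(back) == 3
        for orig, rt in zip(samples, back):
            assert np.array_equal(orig.matrix.positions, rt.positions)
            assert np.array_equal(orig.matrix.alleles, rt.alleles)

    def test_zero_segsite_block(self, tmp_path):
        m = HaplotypeMatrix(
            "c", np.empty(0, dtype=np.int64), np.empty((4, 0), dtype=np.int8)
        )
        sample = SweepSample(
            matrix=m, mode="neutral", adaptive_col=None,
            origin_labels=np.full(4, -1), final_frequency=0.0, locus_length=100,
        )
        path = str(tmp_path / "empty.ms")
        write_ms([sample], path)
        assert "segsites: 0" in open(path).read()
        (rep,) = read_ms(path, 100, 4)
        assert rep.n_snps == 0
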