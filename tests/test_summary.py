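"""Descriptive statistics, distribution fits, sampling precision."""

import math

import numpy as np
import pandas as pd
import pytest

import digiprot as dp
from digiprot import reference as ref


def _df(rows):
    return pd.DataFrame(
        rows, columns=["species", "group", "n_exons", "exon_lengths", "cds_nt", "protein_aa"]
    )


def _row(exon_lengths, species="S p"):
    nt = sum(exon_lengths)
    return [species, "G", len(exon_lengths), list(exon_lengths), nt, nt // 3 - 1]


class TestSpeciesSummary:
    def test_worked_single_gene(self):
        ss = dp.species_summary(_df([_row([415, 363, 176])]))
        assert ss.n_proteins == 1
        assert ss.mean_en == 3
        assert ss.mean_el_pooled == pytest.approx(318.0)
        assert ss.mean_pl == pytest.approx(317.0)

    def test_two_single_exon_genes(self):
        ss = dp.species_summary(_df([_row([300]), _row([300])]))
        assert ss.mean_en == 1
        assert ss.mean_el_pooled == 300
        assert ss.mean_pl == pytest.approx(99.0)

    def test_gene_first_vs_pooled_coincide(self):
        ss = dp.species_summary(_df([_row([100, 300]), _row([200])]))
        assert ss.mean_el_genefirst == pytest.approx(200.0)
        assert ss.mean_el_pooled == pytest.approx(200.0)

    def test_gene_first_vs_pooled_differ(self):
        ss = dp.species_summary(_df([_row([100, 300]), _row([500])]))
        assert ss.mean_el_genefirst == pytest.approx(350.0)
        assert ss.mean_el_pooled == pytest.approx(300.0)

    def test_zero_records_error(self):
        with pytest.raises(dp.summary.UndefinedSummaryError):
            dp.species_summary(_df([]))

    def test_structural_identity(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(200):
            k = int(rng.integers(1, 9))
            nt = 3 * (int(rng.integers(50, 900)) + 1)
            cuts = np.sort(rng.choice(nt - 1, size=k - 1, replace=False) + 1)
            parts = np.diff(np.concatenate(([0], cuts, [nt]))).tolist()
            rows.append(_row(parts))
        ss = dp.species_summary(_df(rows))
        assert ss.mean_en * ss.mean_el_pooled == pytest.approx(
            3 * (ss.mean_pl + 1), rel=1e-12
        )


class TestGroupSummary:
    def test_species_means_unweighted(self):
        s1 = dp.species_summary(_df([_row([1203], species="A a")]))  # 400 aa
        s2 = dp.species_summary(_df([_row([1503], species="B b")]))  # 500 aa
        gs = dp.group_summary([s1, s2], level="species_means")
        assert gs.mean_pl == pytest.approx(450.0)
        assert gs.n_species == 2

    def test_pooled_weighted_toward_larger_species(self):
        rows = [_row([300], species="A a") for _ in range(100)] + [
            _row([3000], species="B b") for _ in range(300)
        ]
        df = _df(rows)
        s1 = dp.species_summary(df[df.species == "A a"])
        s2 = dp.species_summary(df[df.species == "B b"])
        gs = dp.group_summary([s1, s2], level="pooled_proteins", records=df)
        unweighted = (s1.mean_pl + s2.mean_pl) / 2
        assert gs.mean_pl > unweighted
        assert gs.n_proteins_total == 400

    def test_single_species_identity(self):
        df = _df([_row([300]), _row([600])])
        s = dp.species_summary(df)
        gs = dp.group_summary([s], level="species_means")
        assert gs.mean_pl == pytest.approx(s.mean_pl)
        assert gs.median_el == pytest.approx(s.median_el)

    def test_aggregations_coincide_for_equal_n(self):
        rows = [_row([300], species="A a"), _row([900], species="A a"),
                _row([600], species="B b"), _row([1200], species="B b")]
        df = _df(rows)
        ss = [dp.species_summary(df[df.species == s]) for s in ("A a", "B b")]
        g1 = dp.group_summary(ss, level="species_means")
        g2 = dp.group_summary(ss, level="pooled_proteins", records=df)
        assert g1.mean_pl == pytest.approx(g2.mean_pl)

    def test_mixed_group_error(self):
        df = _df([_row([300], species="A a"), _row([300], species="B b")])
        s1 = dp.species_summary(df[df.species == "A a"])
        s2 = dp.species_summary(df[df.species == "B b"])
        s2.group = "Other"
        with pytest.raises(ValueError, match="mixed"):
            dp.group_summary([s1, s2])

    def test_table2_identity_within_4_percent(self):
        """(EN x EL)/3 reproduces the printed group mean protein lengths."""
        worst = 0.0
        for _, r in ref.GROUP_ARCHITECTURE.iterrows():
            implied = r.mean_en * r.mean_el / 3.0 - 1.0
            worst = max(worst, abs(implied - r.mean_pl) / r.mean_pl)
        assert worst < 0.04


class TestPercentile:
    def test_linear_interpolation(self):
        assert dp.percentile(range(1, 101), 90) == pytest.approx(90.1)

    def test_q50_is_median(self):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        assert dp.percentile(vals, 50) == pytest.approx(np.median(vals))

    def test_constant_sample(self):
        assert dp.percentile([7.0] * 5, 32.5) == 7.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            dp.percentile([], 50)


class TestDistributionFit:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(12)
        sample = rng.lognormal(6.0, 0.5, 10_000)
        fit = dp.fit_distribution(sample, "lognormal")
        assert fit.params["mu"] == pytest.approx(6.0, abs=0.02)
        assert fit.params["sigma"] == pytest.approx(0.5, abs=0.02)

    def test_lognormal_beats_gamma_on_lognormal_data(self):
        wins = 0
        for seed in range(20):
            sample = np.random.default_rng(seed).lognormal(6.0, 0.5, 2000)
            ln = dp.fit_distribution(sample, "lognormal")
            ga = dp.fit_distribution(sample, "gamma")
            wins += dp.best_model([ln, ga]).model == "lognormal"
        assert wins >= 19

    def test_constant_sample(self):
        fit = dp.fit_distribution([42.0] * 10, "lognormal")
        assert fit.params["mu"] == pytest.approx(math.log(42.0))
        assert fit.params["sigma"] == 0.0

    def test_exponential_gives_gamma_shape_one(self):
        sample = np.random.default_rng(5).exponential(100.0, 20_000)
        fit = dp.fit_distribution(sample, "gamma")
        assert fit.params["shape"] == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dp.fit_distribution([1.0, -2.0], "lognormal")

    def test_fitted_mean_at_least_median(self):
        sample = np.random.default_rng(9).lognormal(5.5, 0.7, 500)
        fit = dp.fit_distribution(sample, "lognormal")
        mu, sigma = fit.params["mu"], fit.params["sigma"]
        assert math.exp(mu + sigma**2 / 2) >= math.exp(mu)


class TestSamplingPrecision:
    def _fit(self, sigma):
        return dp.DistributionFit("lognormal", {"mu": 6.0, "sigma": sigma}, 0.0, 0.0, 1)

    def test_zero_sigma(self):
        assert dp.sampling_precision(self._fit(0.0), 100) == 0.0

    def test_minimum_sample_size_rule(self):
        """At sigma = 0.8 and n = 500 the relative SE stays below 4.5%."""
        value = dp.sampling_precision(self._fit(0.8), 500)
        assert value == pytest.approx(
            math.sqrt(math.exp(0.64) - 1) / math.sqrt(500), rel=1e-12
        )
        assert value <= 0.045

    def test_inverse_sqrt_n_scaling(self):
        fit = self._fit(0.7)
        assert dp.sampling_precision(fit, 400) == pytest.approx(
            dp.sampling_precision(fit, 100) / 2
        )
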