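"""Sloan NCM: predicted curve, fitting, partition, group comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import amfassembly as A
from amfassembly.community_io import OtuTable


class TestOccurrenceFrequency:
    def test_trivial_frequencies(self):
        counts = np.array([[5.0, 0.0], [3.0, 0.0], [2.0, 5.0]])
        t = OtuTable(["a", "b", "c"], ["x", "y"], counts)
        df = A.occurrence_frequency(t)
        assert df.set_index("otu_id").observed_freq["x"] == 1.0

    def test_hand_arithmetic(self):
        # OTU with counts (0,0,5) over equal-depth samples of 100 reads
        counts = np.zeros((3, 2))
        counts[:, 0] = [100, 100, 95]
        counts[2, 1] = 5
        t = OtuTable(["a", "b", "c"], ["x", "y"], counts)
        df = A.occurrence_frequency(t).set_index("otu_id")
        assert df.observed_freq["y"] == pytest.approx(1 / 3)
        assert df.p["y"] == pytest.approx(np.mean([0, 0, 5 / 100]))

    def test_p_sums_to_one_when_nothing_dropped(self, neutral_table_small):
        df = A.occurrence_frequency(neutral_table_small)
        if len(df) == neutral_table_small.n_otus:
            assert df.p.sum() == pytest.approx(1.0)


class TestPredictedFrequency:
    def test_beta_median_symmetry(self):
        # p = 0.5 makes the Beta symmetric; its median is 0.5
        assert A.predicted_frequency(0.5, 40.0, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_p(self):
        p = np.linspace(0.001, 0.999, 200)
        f = A.predicted_frequency(p, 30.0, 0.002)
        assert np.all(np.diff(f) >= -1e-12)

    def test_quadrature_oracle(self):
        nm, p, dbar = 50.0, 0.01, 0.001
        a, b = nm * p, nm * (1 - p)
        ln_beta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)

        def dens(x):
            return math.exp((a - 1) * math.log(x) + (b - 1) * math.log1p(-x) - ln_beta)

        val, err = quad(dens, dbar, 1.0, limit=200)
        assert A.predicted_frequency(p, nm, dbar) == pytest.approx(val, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            A.predicted_frequency(0.0, 10.0, 0.01)
        with pytest.raises(ValueError):
            A.predicted_frequency(0.5, -1.0, 0.01)
        with pytest.raises(ValueError):
            A.predicted_frequency(0.5, 10.0, 1.5)


class TestFit:
    def test_self_consistency_exact_curve(self):
        p = np.logspace(-4, -0.7, 120)
        dbar = 1e-3
        freq = A.predicted_frequency(p, 50.0, dbar)
        nm, r2 = A.fit_frequency_curve(p, freq, dbar)
        assert abs(nm - 50.0) / 50.0 < 1e-6
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_recovery_on_matched_simulation(self):
        spec = A.NeutralSimSpec(n_samples=60, n_otus=300, reads_per_sample=1000,
                                migration_rate=0.05, seed=40)
        fit = A.fit_ncm(A.simulate_neutral_table(spec).drop_empty())
        assert 0.05 * 0.75 < fit.m < 0.05 * 1.25
        assert fit.n_reads == pytest.approx(1000.0, rel=0.01)

    def test_r_squared_reported_negative_when_fit_is_poor(self):
        p = np.linspace(0.001, 0.2, 50)
        freq = np.linspace(0.9, 0.1, 50)  # opposite of any neutral curve
        _, r2 = A.fit_frequency_curve(p, freq, dbar=0.001)
        assert r2 < 0

    def test_predicted_curve_monotone_and_partition_consistent(self):
        spec = A.NeutralSimSpec(n_samples=40, n_otus=150, seed=41)
        fit = A.fit_ncm(A.simulate_neutral_table(spec).drop_empty())
        df = fit.per_otu.sort_values("p")
        assert np.all(np.diff(df.predicted_freq) >= -1e-12)
        above = df.partition == "above"
        below = df.partition == "below"
        assert np.all(df.observed_freq[above] > df.upper95[above])
        assert np.all(df.observed_freq[below] < df.lower95[below])
        assert fit.neutral_fraction == pytest.approx((df.partition == "neutral").mean())

    def test_wilson_band_coverage_near_nominal(self):
        # matched neutral simulations: observed frequencies should fall
        # inside the 95% bands at a rate close to nominal
        cov = []
        for s in range(3):
            spec = A.NeutralSimSpec(n_samples=60, n_otus=300, reads_per_sample=1000,
                                    migration_rate=0.05, seed=300 + s)
            fit = A.fit_ncm(A.simulate_neutral_table(spec).drop_empty())
            cov.append(fit.neutral_fraction)
        assert np.mean(cov) >= 0.85

    def test_bias_shrinks_with_study_size(self):
        # parameter recovery at two sizes: the larger study is less biased
        errs = []
        for n_samples, n_otus in ((15, 60), (60, 300)):
            rel = []
            for s in range(4):
                spec = A.NeutralSimSpec(n_samples=n_samples, n_otus=n_otus,
                                        reads_per_sample=1000,
                                        migration_rate=0.05, seed=500 + s)
                fit = A.fit_ncm(A.simulate_neutral_table(spec).drop_empty())
                rel.append(abs(fit.m - 0.05) / 0.05)
            errs.append(np.median(rel))
        assert errs[1] <= errs[0] + 0.05

    def test_selection_degrades_fit(self):
        # paired seeds: strong selection should lower R^2 vs matched neutral
        diffs = []
        for s in range(10):
            common = dict(n_samples=30, n_otus=120, reads_per_sample=1000,
                          migration_rate=0.5,
                          metacommunity_distribution="lognormal",
                          lognormal_sigma=0.5, seed=700 + s)
            neutral = A.simulate_neutral_table(A.NeutralSimSpec(**common)).drop_empty()
            sel, _ = A.simulate_selected_table(
                A.SelectionSimSpec(**common, selection_strength=1.5, niche_breadth=0.4)
            )
            diffs.append(A.fit_ncm(neutral).r_squared - A.fit_ncm(sel.drop_empty()).r_squared)
        assert np.mean(diffs) > 0

    def test_too_few_otus_rejected(self):
        t = OtuTable(["a", "b"], [f"o{i}" for i in range(3)], np.ones((2, 3)))
        with pytest.raises(ValueError):
            A.fit_ncm(t)


class TestGroupComparison:
    def _fake_fit(self, m, frac):
        per_otu = pd.DataFrame({"otu_id": ["x"], "p": [0.1], "observed_freq": [0.5]})
        return A.NcmFit(m * 1000, m, 1000.0, 0.5, 1, 0.001, 10, per_otu, frac)

    def test_sorted_by_m_descending(self):
        rep = A.compare_group_fits(
            {"g1": self._fake_fit(0.1, 0.7), "g2": self._fake_fit(0.2, 0.6)}
        )
        assert list(rep.m) == [0.2, 0.1]
        assert list(rep.group) == ["g2", "g1"]

    def test_neutral_fraction_echoed(self):
        rep = A.compare_group_fits(
            {"a": self._fake_fit(0.3, 0.61), "b": self._fake_fit(0.1, 0.74)}
        )
        assert rep.set_index("group").neutral_fraction.to_dict() == {"a": 0.61, "b": 0.74}

    def test_groupwise_fits_from_niche_labels(self):
        # integration: classifier labels -> three group fits
        spec = A.NeutralSimSpec(n_samples=40, n_otus=150, reads_per_sample=1000, seed=50)
        base = A.simulate_sampling_table(spec).drop_empty()
        table, _ = A.plant_generalists_specialists(base, 15, 15, seed=51)
        labels = A.classify_otus(table, n_perm=200, seed=52)
        lab = {r.otu_id: r.label for r in labels}
        groups = {"all": table}
        for grp, want in (("generalists", "generalist"), ("specialists", "specialist")):
            ids = [o for o in table.otu_ids if lab[o] == want]
            if len(ids) >= 10:
                sub = table.subset_otus(ids)
                keep = [s for s, t in zip(sub.sample_ids, sub.sample_totals()) if t > 0]
                groups[grp] = sub.subset_samples(keep)
        fits = {}
        for g, t in groups.items():
            try:
                fits[g] = A.fit_ncm(t)
            except A.FitError:
                # planted uniform generalists occupy every sample: no
                # occupancy variation, migration rate unidentifiable
                assert g == "generalists"
        rep = A.compare_group_fits(fits)
        assert len(rep) >= 2
        assert {"all", "specialists"} <= set(rep.group)
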