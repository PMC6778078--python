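"""Generator determinism, tail behaviour and ground-truth recovery."""

import numpy as np
import pytest

from paleowear.cementochronology import Season, analyze_series
from paleowear.data_model import DietMain, Taxon
from paleowear.microwear import classify_diet_lsr, compute_lsr, summarize_microwear
from paleowear.synthetic_data import (
    AssemblageSpec,
    CementumParams,
    SyntheticConfig,
    generate_cementum_series,
    generate_microwear_assemblage,
    generate_site_dataset,
)


def cfg(seed=1234, **kw):
    return SyntheticConfig(seed=seed, **kw)


class TestMicrowearGenerator:
    def test_grazer_single_event_has_near_zero_lsr(self):
        teeth, _, _ = generate_microwear_assemblage(cfg(), 30, diet="grazer")
        lsr = compute_lsr([t.ns for t in teeth])
        assert lsr <= 10.0  # normal tail beyond 17 at mean 21.6, sd 2.4
        assert classify_diet_lsr(lsr).main is DietMain.grazer

    def test_browser_single_event_classifies_as_browser(self):
        teeth, _, _ = generate_microwear_assemblage(cfg(seed=77), 30, diet="browser")
        lsr = compute_lsr([t.ns for t in teeth])
        assert lsr >= 85.0
        assert classify_diet_lsr(lsr).main is DietMain.browser

    def test_nonconsecutive_event_inflates_cv_and_sd(self):
        """Mixture of seasons two shifts apart lifts mean (CV*, SD) above
        the single-event values (brute-force over seeded replicates)."""
        singles, mixtures = [], []
        for seed in range(40):
            t1, _, _ = generate_microwear_assemblage(cfg(seed=seed), 15, diet="mixed")
            t2, _, _ = generate_microwear_assemblage(
                cfg(seed=1000 + seed), 15, diet="mixed", event_structure="two_nonconsecutive"
            )
            singles.append(summarize_microwear(t1))
            mixtures.append(summarize_microwear(t2))
        assert np.mean([s.ns_sd for s in mixtures]) > np.mean([s.ns_sd for s in singles])
        assert np.mean([s.ns_cv_star for s in mixtures]) > np.mean([s.ns_cv_star for s in singles])

    def test_parameter_recovery_improves_with_n(self):
        errs = {}
        for n in (30, 300):
            teeth, _, truth = generate_microwear_assemblage(cfg(seed=5), n, diet="mixed")
            s = summarize_microwear(teeth)
            errs[n] = abs(s.ns_mean - truth.params.ns_mean)
        assert errs[300] < 1.0 and errs[30] < 2.5

    def test_same_seed_reproduces_assemblage(self):
        a, _, _ = generate_microwear_assemblage(cfg(seed=9), 10, diet="mixed")
        b, _, _ = generate_microwear_assemblage(cfg(seed=9), 10, diet="mixed")
        assert a == b

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_microwear_assemblage(cfg(), 1, diet="mixed")
        with pytest.raises(ValueError):
            generate_microwear_assemblage(cfg(), 5, diet="frugivore")


class TestCementumGenerator:
    def test_noise_free_half_year_death_recovers_50_exactly(self):
        config = cfg(
            cementum=CementumParams(tb_sd=0.0, ob_sd=0.0, noise_frac=0.0)
        )
        series, truth = generate_cementum_series(config, 4, good_season_fraction=0.5)
        res = analyze_series(series)
        assert res.pct_dev == pytest.approx(50.0)
        assert res.season is Season.good_middle is truth.true_season
        assert res.n_pairs == 4 and res.trailing_incomplete_tb

    def test_bad_season_death_leaves_complete_ob(self):
        series, truth = generate_cementum_series(cfg(), 5, death_in_good_season=False)
        res = analyze_series(series)
        assert truth.true_season is Season.bad
        assert res.season is Season.bad and not res.trailing_incomplete_tb
        assert res.n_pairs == 5

    def test_season_recovery_rate_under_measurement_noise(self):
        """>= 95% category recovery at 10% thickness noise when the death
        fraction stays >= 5 points away from the category boundaries."""
        rng = np.random.default_rng(2024)
        config = cfg(cementum=CementumParams(noise_frac=0.10))
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            while True:
                f = rng.uniform(0.05, 0.95)
                if min(abs(100 * f - 33.35), abs(100 * f - 66.65)) >= 5.0:
                    break
            series, truth = generate_cementum_series(
                config, int(rng.integers(4, 10)), good_season_fraction=f, rng=rng
            )
            hits += analyze_series(series).season is truth.true_season
        assert hits / n_rep >= 0.95


class TestSiteBundles:
    SITE = [
        AssemblageSpec(
            taxon=Taxon.cervus,
            level="8",
            diet="mixed",
            n_teeth=15,
            cementum_deaths=[(False, None), (True, 0.2), (True, 0.9), (True, 0.15)],
        ),
        AssemblageSpec(taxon=Taxon.equus, level="8", diet="grazer", n_teeth=15),
    ]

    def test_same_seed_yields_byte_identical_bundle(self, tmp_path):
        generate_site_dataset(self.SITE, cfg(seed=31), tmp_path / "a")
        generate_site_dataset(self.SITE, cfg(seed=31), tmp_path / "b")
        for name in ("specimens.csv", "mesowear_obs.csv", "microwear_obs.csv",
                     "cementum_series.csv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes(), name

    def test_sidecar_scores_season_recovery_without_generator_access(self, tmp_path):
        import json

        from paleowear.data_model import read_specimen_table
        from paleowear.pipeline import analyze_cementum_tables
        from paleowear.cementochronology import SEASON_LABELS

        out = tmp_path / "site"
        generate_site_dataset(self.SITE, cfg(seed=31), out)
        truth = json.loads((out / "ground_truth.json").read_text())
        rows = analyze_cementum_tables(
            read_specimen_table(out / "cementum_series.csv", "cementum_series"),
            read_specimen_table(out / "specimens.csv", "specimens"),
        )
        by_id = {r.specimen_id: r for r in rows}
        truths = [c for a in truth["assemblages"] for c in a["cementum"]]
        assert truths
        for c in truths:
            got = by_id[c["specimen_id"]].season
            want = SEASON_LABELS[Season(c["true_season"])]
            assert got == want
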