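import numpy as np
import pytest
from dataclasses import replace

import serapept as sp
from serapept.simcohort import (NO_NOISE, CohortConfig, NoiseModel,
                                default_signal_panel)


def flat_panel(effects=None, n=5, base=10.0):
    panel = [sp.SignalSpec(1420.77, 100.0, role="internal_standard")]
    for k in range(n):
        panel.append(sp.SignalSpec(900.0 + 50 * k, base,
                                   group_effects=dict(effects or {})))
    return panel


class TestConfigValidation:
    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError, match="group_sizes"):
            CohortConfig(group_sizes={"control": 0})

    def test_unordered_mz_range_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            CohortConfig(mz_range=(3000, 800))

    def test_signal_outside_range_rejected(self):
        panel = flat_panel() + [sp.SignalSpec(5000.0, 1.0)]
        with pytest.raises(ValueError, match="outside"):
            CohortConfig(signal_panel=panel)

    def test_exactly_one_internal_standard_required(self):
        panel = [sp.SignalSpec(900.0, 1.0)]
        with pytest.raises(ValueError, match="internal standard"):
            CohortConfig(signal_panel=panel)


def test_default_panel_contains_fpa_masses_and_standard():
    mzs = {round(s.mz, 2) for s in default_signal_panel()}
    for expected in (905.46, 1077.53, 1350.6, 1465.63, 1420.77):
        assert round(expected, 2) in mzs
    roles = [s.role for s in default_signal_panel()]
    assert roles.count("internal_standard") == 1
    assert roles.count("contaminant") == 1


def test_seed_reproducibility_byte_stable(tmp_path):
    cfg = CohortConfig(group_sizes={"control": 3, "metastatic": 3}, seed=9,
                       signal_panel=flat_panel())
    s1, m1 = sp.generate_cohort(cfg)
    s2, m2 = sp.generate_cohort(cfg)
    assert m1.equals(m2)
    for a, b in zip(s1, s2):
        assert a.age == b.age and a.degradation == b.degradation
        for ra, rb in zip(a.replicates, b.replicates):
            np.testing.assert_array_equal(ra.mz, rb.mz)
            np.testing.assert_array_equal(ra.abundance, rb.abundance)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    sp.write_cohort(s1, m1, d1)
    sp.write_cohort(s2, m2, d2)
    for f in sorted(d1.iterdir()):
        assert f.read_bytes() == (d2 / f.name).read_bytes()


def test_zero_noise_unit_effects_recover_base_abundances():
    cfg = CohortConfig(group_sizes={"control": 4, "metastatic": 4},
                       signal_panel=flat_panel(), noise=NO_NOISE,
                       degradation_range=(0, 0), seed=1)
    samples, manifest = sp.generate_cohort(cfg, peak_lists=False)
    table = sp.cohort_to_table(samples, manifest, normalize=False)
    for group in ("control", "metastatic"):
        cols = manifest.loc[manifest.group == group, "sample_id"]
        means = table.abundance[list(cols)].mean(axis=1)
        for spec in cfg.signal_panel:
            assert means.loc[round(spec.mz, 4)] == pytest.approx(spec.base_abundance)


def test_planted_fold_recovered_across_seeds():
    """Ratio of group means converges to the planted fold (2.9) over seeds."""
    ratios = []
    for seed in range(20):
        cfg = CohortConfig(group_sizes={"control": 19, "metastatic": 92},
                           signal_panel=flat_panel({"metastatic": 2.9}, n=3),
                           covariates={"control": sp.simcohort.DEFAULT_COVARIATES["control"],
                                       "metastatic": sp.simcohort.DEFAULT_COVARIATES["metastatic"]},
                           seed=seed)
        samples, manifest = sp.generate_cohort(cfg, peak_lists=False)
        table = sp.cohort_to_table(samples, manifest, normalize=False)
        cols_c = manifest.loc[manifest.group == "control", "sample_id"]
        cols_m = manifest.loc[manifest.group == "metastatic", "sample_id"]
        row = table.abundance.loc[round(900.0, 4)]
        ratios.append(row[list(cols_m)].mean() / row[list(cols_c)].mean())
    assert np.mean(ratios) == pytest.approx(2.9, rel=0.12)


def test_degradation_strictly_decreases_high_low_ratio():
    ratios = []
    for deg in (0.0, 0.2, 0.5, 0.8):
        cfg = CohortConfig(group_sizes={"control": 1}, noise=NO_NOISE,
                           degradation_range=(deg, deg), seed=3)
        samples, _ = sp.generate_cohort(cfg, peak_lists=False)
        t = samples[0].truth
        high = t[1350.6] + t[1465.63]
        low = t[905.46] + t[1077.53]
        ratios.append(high / low)
    assert all(a > b for a, b in zip(ratios, ratios[1:]))


def test_sporadic_rate_drops_replicates(rng):
    panel = flat_panel()
    panel.append(sp.SignalSpec(2000.0, 10.0, sporadic_rate=0.5))
    cfg = CohortConfig(group_sizes={"control": 30}, signal_panel=panel, seed=4)
    samples, _ = sp.generate_cohort(cfg)
    present = sum(np.any(np.abs(r.mz - 2000.0) < 0.3)
                  for s in samples for r in s.replicates)
    total = sum(len(s.replicates) for s in samples)
    assert 0.35 < present / total < 0.65


class TestRenderProfile:
    def test_empty_panel_flat_baseline(self):
        panel = [sp.SignalSpec(1420.77, 0.0, role="internal_standard")]
        cfg = CohortConfig(group_sizes={"control": 1}, signal_panel=panel,
                           noise=NO_NOISE, seed=0)
        samples, _ = sp.generate_cohort(cfg)
        prof = sp.render_profile(samples[0], mz_range=(800, 900))
        assert np.allclose(prof[0][0].intensity, 0.0)

    def test_apex_at_nearest_grid_point(self):
        panel = [sp.SignalSpec(1420.77, 1.0, role="internal_standard"),
                 sp.SignalSpec(1561.72, 10.0)]
        cfg = CohortConfig(group_sizes={"control": 1}, signal_panel=panel,
                           noise=NO_NOISE, seed=0)
        samples, _ = sp.generate_cohort(cfg)
        prof = sp.render_profile(samples[0], peak_width=0.2, grid_step=0.05,
                                 mz_range=(1500, 1600), scans=1)
        scan = prof[0][0]
        apex = scan.mz[np.argmax(scan.intensity)]
        assert abs(apex - 1561.72) <= 0.05 / 2 + 1e-9

    def test_integral_proportional_to_abundance(self):
        panel = [sp.SignalSpec(1420.77, 1.0, role="internal_standard"),
                 sp.SignalSpec(1000.0, 4.0), sp.SignalSpec(1200.0, 8.0)]
        cfg = CohortConfig(group_sizes={"control": 1}, signal_panel=panel,
                           noise=NO_NOISE, seed=0)
        samples, _ = sp.generate_cohort(cfg)
        prof = sp.render_profile(samples[0], peak_width=0.1, grid_step=0.01,
                                 mz_range=(900, 1300), scans=1)
        scan = prof[0][0]
        near_a = np.abs(scan.mz - 1000.0) < 2
        near_b = np.abs(scan.mz - 1200.0) < 2
        ratio = scan.intensity[near_b].sum() / scan.intensity[near_a].sum()
        assert ratio == pytest.approx(2.0, rel=1e-3)

    def test_coarse_grid_warns(self):
        panel = [sp.SignalSpec(1420.77, 1.0, role="internal_standard")]
        cfg = CohortConfig(group_sizes={"control": 1}, signal_panel=panel,
                           noise=NO_NOISE, seed=0)
        samples, _ = sp.generate_cohort(cfg)
        with pytest.warns(UserWarning, match="coarser"):
            sp.render_profile(samples[0], peak_width=0.05, grid_step=0.5,
                              mz_range=(800, 900))


def test_covariates_match_group_models():
    cfg = CohortConfig(seed=6)
    _, manifest = sp.generate_cohort(cfg, peak_lists=False)
    by_group = manifest.groupby("group")["age"].mean()
    assert by_group["control"] == pytest.approx(54, abs=6)
    assert by_group["metastatic"] == pytest.approx(71, abs=5)
    ages = manifest.groupby("group")["age"]
    assert ages.min()["control"] >= 40 and ages.max()["control"] <= 67
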