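import numpy as np
import pandas as pd
import pytest

import serapept as sp
from serapept.preprocess_align import (CONTAMINANT_MZ, MissingStandardError,
                                       PreprocessConfig, fpa_fpb_exclusion_masses)


def pl(pairs, sample_id="s", replicate=None):
    pairs = sorted(pairs)
    mz, ab = zip(*pairs)
    return sp.PeakList(np.array(mz, float), np.array(ab, float),
                       sample_id=sample_id, replicate=replicate)


STD = 1420.77


class TestNormalize:
    def test_standard_becomes_one(self):
        out = sp.normalize(pl([(900.0, 5.0), (STD, 50.0)]))
        i = int(np.argmin(np.abs(out.mz - STD)))
        assert out.abundance[i] == pytest.approx(1.0)
        assert out.abundance[1 - i] == pytest.approx(0.1)

    def test_constant_mz_shift(self):
        # standard observed at 1420.80 -> every m/z shifted by -0.03
        out = sp.normalize(pl([(900.10, 5.0), (1420.80, 50.0)]))
        np.testing.assert_allclose(out.mz, [900.07, STD], atol=1e-9)

    def test_idempotence(self):
        once = sp.normalize(pl([(900.0, 5.0), (1420.9, 50.0)]))
        twice = sp.normalize(once)
        np.testing.assert_allclose(twice.mz, once.mz)
        np.testing.assert_allclose(twice.abundance, once.abundance)

    def test_missing_standard_flagged(self):
        with pytest.raises(MissingStandardError, match="not found"):
            sp.normalize(pl([(900.0, 5.0)]))


class TestSumIsotopes:
    def test_isolated_peak_unchanged(self):
        out = sp.sum_isotopes(pl([(1000.0, 7.0)]))
        np.testing.assert_allclose(out.mz, [1000.0])
        np.testing.assert_allclose(out.abundance, [7.0])

    def test_envelope_collapses_to_monoisotopic_sum(self):
        out = sp.sum_isotopes(pl([(1561.72, 100.0), (1562.72, 80.0), (1563.73, 40.0)]))
        assert len(out) == 1
        assert out.mz[0] == pytest.approx(1561.72)
        assert out.abundance[0] == pytest.approx(220.0)

    def test_total_abundance_conserved(self, rng):
        peaks = [(800 + 10 * k + j * 1.00335, rng.uniform(1, 10))
                 for k in range(20) for j in range(3)]
        inp = pl(peaks)
        out = sp.sum_isotopes(inp)
        assert out.abundance.sum() == pytest.approx(inp.abundance.sum())

    def test_interleaved_envelopes_resolve_separately(self):
        # two chains offset by 0.5 Da: spacing within each chain matches,
        # cross-chain spacing is off by 0.5 >> tolerance
        a = [(1000.0 + k * 1.00335, 10.0) for k in range(3)]
        b = [(1000.5 + k * 1.00335, 6.0) for k in range(3)]
        out = sp.sum_isotopes(pl(a + b))
        assert len(out) == 2
        np.testing.assert_allclose(out.mz, [1000.0, 1000.5])
        np.testing.assert_allclose(out.abundance, [30.0, 18.0])

    def test_chain_capped_at_max_isotopes(self):
        cfg = PreprocessConfig(max_isotopes=2)
        out = sp.sum_isotopes(pl([(1000.0 + k * 1.00335, 5.0) for k in range(4)]), cfg)
        assert len(out) == 2


class TestAverageReplicates:
    def make_reps(self, present_in, n_reps=4, mz=1000.0):
        reps = []
        for r in range(n_reps):
            peaks = [(STD, 10.0)]
            if r in present_in:
                peaks.append((mz, float(r + 1)))
            reps.append(pl(peaks, replicate=r))
        return reps

    def test_signal_in_two_of_four_dropped(self):
        out = sp.average_replicates(self.make_reps({0, 1}))
        assert not np.any(np.abs(out.mz - 1000.0) < 0.5)

    def test_signal_in_three_of_four_kept(self):
        out = sp.average_replicates(self.make_reps({0, 1, 2}))
        assert np.any(np.abs(out.mz - 1000.0) < 0.5)

    def test_abundance_is_mean_over_present(self):
        out = sp.average_replicates(self.make_reps({0, 1, 2, 3}))
        i = int(np.argmin(np.abs(out.mz - 1000.0)))
        assert out.abundance[i] == pytest.approx(2.5)  # mean of 1,2,3,4

    def test_jittered_mz_matched_within_tolerance(self, rng):
        reps = [pl([(STD, 10.0), (1000.0 + rng.uniform(-0.05, 0.05), 2.0)],
                   replicate=r) for r in range(4)]
        out = sp.average_replicates(reps)
        hits = np.abs(out.mz - 1000.0) < 0.2
        assert hits.sum() == 1


class TestAlignSamples:
    def reps_for(self, n_samples, jitter, rng, extra_for=()):
        reps = {}
        for k in range(n_samples):
            peaks = [(STD, 1.0), (900.0 + rng.normal(0, jitter), 2.0)]
            if k in extra_for:
                peaks.append((1500.0 + rng.normal(0, jitter), 3.0))
            reps[f"s{k}"] = pl(peaks, sample_id=f"s{k}")
        return reps

    def test_identical_lists_dense_table(self, rng):
        reps = {f"s{k}": pl([(STD, 1.0), (900.0, 2.0)]) for k in range(6)}
        table = sp.align_samples(reps)
        assert (table.abundance.to_numpy() > 0).all()

    def test_signal_in_four_samples_excluded_at_threshold_five(self, rng):
        reps = self.reps_for(8, 0.01, rng, extra_for={0, 1, 2, 3})
        table = sp.align_samples(reps)
        assert not np.any(np.abs(table.signals - 1500.0) < 1.0)

    def test_signal_in_five_samples_included(self, rng):
        reps = self.reps_for(8, 0.01, rng, extra_for={0, 1, 2, 3, 4})
        table = sp.align_samples(reps)
        assert np.any(np.abs(table.signals - 1500.0) < 1.0)

    def test_cluster_assignment_matches_brute_force(self, rng):
        """Oracle: single-linkage by all-pairs chaining on pooled m/z."""
        mzs = np.concatenate([1000 + rng.normal(0, 0.02, 7),
                              1001.5 + rng.normal(0, 0.02, 7)])
        reps = {}
        for k in range(7):
            reps[f"s{k}"] = pl([(STD, 1.0), (mzs[k], 1.0), (mzs[7 + k], 1.0)])
        table = sp.align_samples(reps)
        # brute force: sort pooled, chain while gap <= tol
        pooled = np.sort(np.concatenate([reps[s].mz for s in reps]))
        clusters, cur = [], [pooled[0]]
        for v in pooled[1:]:
            if v - cur[-1] <= 0.3:
                cur.append(v)
            else:
                clusters.append(cur)
                cur = [v]
        clusters.append(cur)
        expected_labels = sorted(round(float(np.mean(c)), 4) for c in clusters
                                 if len(c) >= 5)
        assert sorted(np.round(table.signals, 4)) == expected_labels

    def test_duplicate_peak_from_one_sample_keeps_nearest(self, rng):
        reps = {f"s{k}": pl([(STD, 1.0), (900.0, 2.0)]) for k in range(5)}
        reps["s0"] = pl([(STD, 1.0), (899.95, 2.0), (900.1, 9.0)])
        with pytest.warns(UserWarning, match="two peaks"):
            table = sp.align_samples(reps)
        row = np.argmin(np.abs(table.signals - 900.0))
        assert table.abundance.iloc[row]["s0"] == pytest.approx(2.0)


class TestExcludeSignals:
    def make_table(self, signals):
        ab = pd.DataFrame(np.ones((len(signals), 6)),
                          index=pd.Index(signals, name="mz"),
                          columns=[f"s{k}" for k in range(6)])
        ann = pd.DataFrame({"group": ["a"] * 6}, index=ab.columns)
        return sp.AlignedTable(ab, ann)

    def test_fixture_122_signals_reduces_to_103(self):
        """19 fibrinopeptide-related columns among 122 leave 103 signals."""
        ladder = sorted(fpa_fpb_exclusion_masses())[:19]
        others = list(800.0 + np.arange(103) * 18.7)
        table = self.make_table(sorted(ladder + others))
        assert table.abundance.shape[0] == 122
        out = sp.exclude_signals(table, {m: "fpA/fpB" for m in ladder}, 0.3)
        assert out.abundance.shape[0] == 103
        assert len(out.provenance["excluded_signals"]) == 19

    def test_empty_exclusion_list_is_identity(self):
        table = self.make_table([900.0, 1000.0])
        out = sp.exclude_signals(table, {}, 0.3)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_contaminant_removed_with_reason(self):
        table = self.make_table([900.0, CONTAMINANT_MZ])
        out = sp.exclude_signals(table)
        assert out.abundance.shape[0] == 1
        reasons = out.provenance["excluded_signals"]
        assert reasons[CONTAMINANT_MZ] == "contaminant"


def test_preprocess_sample_end_to_end_presence(small_cohort):
    """Non-sporadic planted signals survive replicate averaging; heavily
    sporadic ones do not."""
    cfg, samples, manifest = small_cohort
    reps = {s.sample_id: sp.preprocess_sample(s.replicates) for s in samples}
    table = sp.align_samples(reps, manifest)
    planted = [s.mz for s in cfg.signal_panel]
    for mz in planted:  # default panel is non-sporadic
        assert np.any(np.abs(table.signals - mz) < 0.3), mz


def test_sporadic_signals_below_threshold_dropped():
    panel = [sp.SignalSpec(1420.77, 100.0, role="internal_standard"),
             sp.SignalSpec(1000.0, 10.0),
             sp.SignalSpec(1600.0, 10.0, sporadic_rate=0.9)]
    cfg = sp.CohortConfig(group_sizes={"control": 8}, signal_panel=panel, seed=2)
    samples, manifest = sp.generate_cohort(cfg)
    reps = {s.sample_id: sp.preprocess_sample(s.replicates) for s in samples}
    table = sp.align_samples(reps, manifest)
    assert np.any(np.abs(table.signals - 1000.0) < 0.3)
    assert not np.any(np.abs(table.signals - 1600.0) < 0.3)
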