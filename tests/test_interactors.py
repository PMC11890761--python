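import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rdeep import interactors as ip, synthetic
from rdeep.compare import ScreenTable
from rdeep.gaussfit import GaussPeak, GaussianModel
from rdeep.shifts import ShiftCall

from conftest import bh_adjust_oracle


def make_table(values: dict, n_reps=3):
    """values: protein -> {condition: [per-replicate log2 intensities]}"""
    columns = pd.MultiIndex.from_product(
        [ip.CONDITIONS, range(1, n_reps + 1)], names=["condition", "replicate"]
    )
    rows = {}
    for pid, conds in values.items():
        rows[pid] = np.concatenate([np.asarray(conds[c], float) for c in ip.CONDITIONS])
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).rename_axis(
        "protein_id"
    )


class TestFilterDetection:
    @pytest.mark.parametrize(
        "n_present,kept", [(9, True), (7, True), (6, False)],
    )
    def test_seventy_percent_rule_over_nine_samples(self, n_present, kept):
        row = [25.0] * n_present + [np.nan] * (9 - n_present)
        table = make_table({"P": {
            "igg": row[:3], "bait": row[3:6], "bait_rnase": row[6:9]}})
        out = ip.filter_detection(table)
        assert ("P" in out.index) == kept


class TestImpute:
    def _table_with_missing(self, rng, n=40, missing_frac=0.3):
        base = rng.normal(25, 2, size=(n, 9))
        mask = rng.uniform(size=base.shape) < missing_frac
        base[mask] = np.nan
        columns = pd.MultiIndex.from_product(
            [ip.CONDITIONS, range(1, 4)], names=["condition", "replicate"]
        )
        return pd.DataFrame(base, index=[f"P{i}" for i in range(n)], columns=columns)

    def test_complete_table_unchanged(self, rng):
        table = self._table_with_missing(rng, missing_frac=0.0)
        out = ip.impute(table, seed=1)
        pd.testing.assert_frame_equal(out, table)

    def test_seeded_determinism(self, rng):
        table = self._table_with_missing(rng)
        a = ip.impute(table, seed=7)
        b = ip.impute(table, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = ip.impute(table, seed=8)
        assert not a.equals(c)

    def test_imputed_values_track_sample_median(self, rng):
        table = self._table_with_missing(rng, n=300, missing_frac=0.3)
        out = ip.impute(table, seed=3)
        for col in table.columns:
            observed = table[col].dropna()
            imputed = out.loc[table[col].isna(), col]
            assert abs(imputed.median() - observed.median()) < 0.2 * observed.std()

    def test_clip_strategy_caps_at_sample_mean(self, rng):
        table = self._table_with_missing(rng, n=200, missing_frac=0.3)
        out = ip.impute(table, seed=3, outlier_strategy="clip")
        for col in table.columns:
            imputed = out.loc[table[col].isna(), col]
            assert (imputed <= table[col].mean() + 1e-12).all()

    def test_too_few_observed_refused(self):
        table = make_table({
            "P1": {"igg": [25, np.nan, np.nan], "bait": [25] * 3, "bait_rnase": [25] * 3},
            "P2": {"igg": [np.nan, 24, np.nan], "bait": [25] * 3, "bait_rnase": [25] * 3},
        })
        with pytest.raises(ip.ImputationError, match="observed"):
            ip.impute(table, seed=1)

    def test_unknown_strategy_rejected(self, rng):
        table = self._table_with_missing(rng)
        with pytest.raises(ValueError, match="strategy"):
            ip.impute(table, seed=1, outlier_strategy="bogus")


class TestCallInteractors:
    def test_flat_table_no_interactors(self):
        table = make_table({f"P{i}": {
            "igg": [25.0, 25.1, 24.9],
            "bait": [25.0, 25.1, 24.9],
            "bait_rnase": [25.0, 25.1, 24.9]} for i in range(5)})
        calls = ip.call_interactors(table)
        assert not any(c.is_interactor for c in calls)

    def test_planted_fourfold_recovered(self):
        rows = {}
        rng = np.random.default_rng(0)
        for i in range(30):  # background population for BH
            base = rng.normal(25, 0.1, 9)
            rows[f"bg{i}"] = {"igg": base[:3], "bait": base[3:6],
                              "bait_rnase": base[6:]}
        rows["hit"] = {"igg": [23.0, 23.1, 22.9],
                       "bait": [25.0, 25.1, 24.9],
                       "bait_rnase": [22.95, 23.08, 22.88]}
        calls = {c.protein_id: c for c in ip.call_interactors(make_table(rows))}
        assert calls["hit"].is_interactor
        assert calls["hit"].is_rnase_sensitive
        assert calls["hit"].log2fc_enrichment == pytest.approx(2.0, abs=0.2)

    def test_fold_gate_blocks_sub_twofold(self):
        """An enrichment below two-fold is rejected regardless of how small
        its p-value is."""
        rows = {"weak": {"igg": [25.0, 25.0, 25.0],
                         "bait": [25.93, 25.92, 25.94],  # ~1.9-fold
                         "bait_rnase": [25.93, 25.92, 25.94]}}
        calls = ip.call_interactors(make_table(rows))
        assert calls[0].p_enrichment < 0.001
        assert not calls[0].is_interactor

    def test_sensitivity_requires_interactor(self):
        rows = {"odd": {"igg": [25.0, 25.1, 24.9],
                        "bait": [25.0, 25.1, 24.9],
                        "bait_rnase": [22.0, 22.1, 21.9]}}
        calls = ip.call_interactors(make_table(rows))
        assert not calls[0].is_rnase_sensitive

    def test_missing_values_rejected(self):
        table = make_table({"P": {"igg": [25, np.nan, 25], "bait": [25] * 3,
                                  "bait_rnase": [25] * 3}})
        with pytest.raises(ValueError, match="impute"):
            ip.call_interactors(table)

    def test_recovery_of_strong_sensitive_interactors(self):
        """Fixed-seed screen of 500 proteins: the pipeline recovers the
        clearly enriched (>=4x) and clearly sensitive (>=4x) proteins at the
        rate measured for these generator conditions."""
        specs = synthetic.random_interactor_specs(500, seed=3)
        table = synthetic.generate_ip_table(specs, 3, seed=3)
        complete = ip.impute(ip.filter_detection(table), seed=103)
        calls = {c.protein_id: c for c in ip.call_interactors(complete)}
        strong = [s for s in specs
                  if s.true_enrichment_bait_over_igg >= 4
                  and s.true_rnase_sensitivity >= 4]
        recovered = sum(
            1 for s in strong
            if s.protein_id in calls and calls[s.protein_id].is_rnase_sensitive
        )
        assert recovered / len(strong) >= 0.60
        nulls = [s for s in specs if s.true_enrichment_bait_over_igg == 1.0]
        false_pos = sum(
            1 for s in nulls
            if s.protein_id in calls and calls[s.protein_id].is_interactor
        )
        assert false_pos / len(nulls) <= 0.05


class TestBHAdjustment:
    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=60))
    def test_matches_brute_force(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, bh_adjust_oracle(pvals), rtol=1e-9)


class TestIntersectComigrating:
    def _screen(self, entries):
        """entries: pid -> (peak centers, shifted?)"""
        calls = {}
        for pid, (centers, shifted) in entries.items():
            peaks = tuple(GaussPeak(float(c), 10.0, 1.5) for c in centers)
            ctrl = GaussianModel(pid, "control", peaks, 0.0, len(peaks))
            calls[pid] = ShiftCall(
                pid, [], [], "left" if shifted else "no_shift",
                1.0 if shifted else 0.0,
                "complete" if shifted else "independent",
                shifted, control_model=ctrl,
            )
        return ScreenTable("s", calls, {})

    def test_comigration_at_bait_fraction(self):
        screen = self._screen({
            "kifc1_like": ([17, 21], True),   # co-migrates via second peak
            "far": ([10], True),              # shifted but elsewhere
            "still": ([21], False),           # co-migrates but not shifted
            "other": ([21], True),
        })
        out = ip.intersect_comigrating(
            {"kifc1_like", "far", "still", "other"}, screen, at_fraction=21
        )
        assert out == {"kifc1_like", "other"}

    def test_tolerance_widens_window(self):
        screen = self._screen({"near": ([20], True)})
        assert not ip.intersect_comigrating({"near"}, screen, 21, tolerance=0)
        assert ip.intersect_comigrating({"near"}, screen, 21, tolerance=1) == {"near"}

    def test_planted_complex_members_recovered(self):
        """A synthetic complex co-peaking at the bait fraction is returned
        exactly."""
        members = {f"cplx{i}": ([21.2], True) for i in range(5)}
        members.update({f"bgd{i}": ([float(5 + i)], True) for i in range(5)})
        screen = self._screen(members)
        sensitive = set(members)
        out = ip.intersect_comigrating(sensitive, screen, at_fraction=21)
        assert out == {f"cplx{i}" for i in range(5)}


class TestIO:
    def test_round_trip_and_exclusion(self, tmp_path):
        specs = synthetic.random_interactor_specs(20, seed=1)
        table = synthetic.generate_ip_table(specs, 3, seed=1)
        path = tmp_path / "ip.tsv"
        ip.write_ip_table(table, path)
        back = ip.read_ip_table(path)
        pd.testing.assert_frame_equal(back, table, check_names=False)
        trimmed = ip.read_ip_table(path, excluded_replicates=[("bait", 3)])
        assert ("bait", 3) not in trimmed.columns
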