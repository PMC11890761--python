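import numpy as np
import pandas as pd
import pytest

from rdeep import synthetic
from rdeep.synthetic import InteractorSpec, ProfileSpec, SiteSpec, SpecError


def spec(pid="P1", control=((21.0, 10.0, 1.5),), rnase=((5.0, 10.0, 1.5),), **kw):
    return ProfileSpec(pid, tuple(control), tuple(rnase), **kw)


class TestProfileSpec:
    def test_invalid_center_names_field(self):
        with pytest.raises(SpecError, match="peaks_control.*center"):
            spec(control=((30.0, 10.0, 1.5),))

    def test_invalid_width_names_field(self):
        with pytest.raises(SpecError, match="peaks_rnase.*width"):
            spec(rnase=((5.0, 10.0, 0.1),))

    def test_invalid_amplitude_and_replicates(self):
        with pytest.raises(SpecError, match="amplitude"):
            spec(control=((21.0, -1.0, 1.5),))
        with pytest.raises(SpecError, match="n_replicates"):
            spec(n_replicates=1)

    def test_identical_peaks_truth_no_shift(self):
        s = spec(rnase=((21.0, 10.0, 1.5),))
        assert s.category_true == "no_shift"
        assert s.shifting_coefficient_true == 0.0

    def test_full_left_shift_truth(self):
        s = spec()  # 21 -> 5
        assert s.category_true == "left"
        assert s.shifting_coefficient_true == pytest.approx(1.0)
        assert s.max_abs_distance_true == pytest.approx(16.0)

    def test_precipitation_truth(self):
        s = spec(rnase=((24.5, 10.0, 1.5),))
        assert s.category_true == "precipitated"

    def test_coefficient_equals_analytic_area_ratio(self):
        """Two control peaks, only the second moves: the true coefficient is
        exactly the moved peak's share of the summed Gaussian areas."""
        control = ((5.0, 10.0, 1.0), (17.0, 4.0, 2.0))
        rnase = ((5.0, 10.0, 1.0), (22.0, 4.0, 2.0))
        s = spec(control=control, rnase=rnase)
        areas = [a * w * np.sqrt(2 * np.pi) for _, a, w in control]
        expected = areas[1] / sum(areas)
        assert s.shifting_coefficient_true == pytest.approx(expected, rel=1e-12)


class TestGenerateScreen:
    def test_noiseless_argmax_positions(self):
        """Control peak at 21 and RNase peak at 5 generate profiles whose
        raw maxima sit exactly at those fractions."""
        profiles, truth = synthetic.generate_screen(
            [spec(noise_cv=0.0)], seed=1
        )
        by_cond = {}
        for p in profiles:
            by_cond.setdefault(p.condition, p)
        assert int(np.argmax(by_cond["control"].values)) + 1 == 21
        assert int(np.argmax(by_cond["rnase"].values)) + 1 == 5
        assert truth.loc["P1", "category_true"] == "left"

    def test_seeded_determinism(self):
        specs = synthetic.random_screen_specs(200, seed=7)
        a, _ = synthetic.generate_screen(specs, seed=7)
        b, _ = synthetic.generate_screen(specs, seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.values, pb.values)

    def test_different_seed_differs(self):
        specs = synthetic.random_screen_specs(5, seed=7)
        a, _ = synthetic.generate_screen(specs, seed=7)
        b, _ = synthetic.generate_screen(specs, seed=8)
        assert any(
            not np.array_equal(pa.values, pb.values) for pa, pb in zip(a, b)
        )

    def test_replicate_and_condition_counts(self):
        profiles, _ = synthetic.generate_screen([spec(n_replicates=3)], seed=1)
        assert len(profiles) == 6  # 2 conditions x 3 replicates
        assert {p.replicate for p in profiles} == {1, 2, 3}

    def test_phase_scales_total_amount(self):
        s = spec(total_amount_mitosis=500.0, total_amount_interphase=2000.0,
                 noise_cv=0.0)
        mito, _ = synthetic.generate_screen([s], seed=1, phase="mitosis")
        inter, _ = synthetic.generate_screen([s], seed=1, phase="interphase")
        assert mito[0].total == pytest.approx(500.0)
        assert inter[0].total == pytest.approx(2000.0)

    def test_noise_cv_matches_target(self):
        s = spec(noise_cv=0.1, n_replicates=200)
        profiles, _ = synthetic.generate_screen([s], seed=3)
        ctrl = np.vstack([p.values for p in profiles if p.condition == "control"])
        peak_col = ctrl[:, 20]  # fraction 21
        assert peak_col.std() / peak_col.mean() == pytest.approx(0.1, rel=0.25)

    def test_empty_specs_rejected(self):
        with pytest.raises(SpecError, match="non-empty"):
            synthetic.generate_screen([], seed=1)

    def test_write_screen_layout(self, tmp_path):
        specs = synthetic.random_screen_specs(4, seed=1)
        profiles, truth = synthetic.generate_screen(specs, seed=1)
        written = synthetic.write_screen(profiles, truth, tmp_path)
        names = {p.name for p in written}
        assert "control_rep1.tsv" in names and "rnase_rep3.tsv" in names
        assert "ground_truth.tsv" in names
        header = (tmp_path / "control_rep1.tsv").read_text().splitlines()[0]
        assert header.split("\t")[:2] == ["protein_id", "F01"]


class TestRandomScreenSpecs:
    def test_category_mix_respected(self):
        specs = synthetic.random_screen_specs(500, seed=1)
        cats = pd.Series([s.category_true for s in specs]).value_counts(normalize=True)
        assert cats["no_shift"] == pytest.approx(0.60, abs=0.08)
        assert cats["left"] == pytest.approx(0.20, abs=0.07)

    def test_generated_specs_valid_and_deterministic(self):
        a = synthetic.random_screen_specs(50, seed=9)
        b = synthetic.random_screen_specs(50, seed=9)
        assert a == b


class TestGenerateIpTable:
    def test_neutral_spec_zero_ratios(self):
        specs = [InteractorSpec(f"P{i}", 1.0, 1.0) for i in range(200)]
        table = synthetic.generate_ip_table(specs, 3, seed=1)
        ratios = table["bait"].to_numpy() - table["igg"].to_numpy()
        assert abs(ratios.mean()) < 0.05

    def test_folds_show_up_in_log2_ratios(self):
        specs = [InteractorSpec(f"P{i}", 8.0, 4.0) for i in range(200)]
        table = synthetic.generate_ip_table(specs, 3, seed=1)
        enr = (table["bait"].to_numpy() - table["igg"].to_numpy()).mean()
        sen = (table["bait"].to_numpy() - table["bait_rnase"].to_numpy()).mean()
        assert enr == pytest.approx(3.0, abs=0.1)
        assert sen == pytest.approx(2.0, abs=0.1)

    def test_always_missing_protein_absent_everywhere(self):
        specs = [InteractorSpec("gone", missing_prob_per_sample=1.0)]
        table = synthetic.generate_ip_table(specs, 3, seed=1)
        assert table.loc["gone"].isna().all()

    def test_determinism_and_validation(self):
        specs = [InteractorSpec("P", 2.0, 2.0, missing_prob_per_sample=0.3)]
        a = synthetic.generate_ip_table(specs, 3, seed=5)
        b = synthetic.generate_ip_table(specs, 3, seed=5)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(SpecError):
            InteractorSpec("bad", true_enrichment_bait_over_igg=0.0)
        with pytest.raises(SpecError):
            InteractorSpec("bad", missing_prob_per_sample=1.5)
        with pytest.raises(SpecError, match="n_replicates"):
            synthetic.generate_ip_table(specs, 1, seed=1)


class TestGenerateSites:
    def test_pure_gene_type_mix(self):
        s = SiteSpec(n_sites=100, gene_type_mix={"protein_coding": 1.0})
        sites, _, _ = synthetic.generate_sites(s, seed=1)
        assert (sites["gene_type"] == "protein_coding").all()

    def test_sequences_have_length_seven(self):
        sites, _, _ = synthetic.generate_sites(SiteSpec(n_sites=50), seed=1)
        assert sites["sequence"].str.len().eq(7).all()
        assert sites["sequence"].str.fullmatch("[ACGU]{7}").all()

    def test_seeded_determinism(self):
        s = SiteSpec(n_sites=1000)
        a, _, _ = synthetic.generate_sites(s, seed=11)
        b, _, _ = synthetic.generate_sites(s, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_no_bias_tails_indistinguishable_by_permutation(self):
        """Without the uridine bias, the U-pentamer frequency difference
        between score tails is within the permutation null distribution."""
        sites, _, _ = synthetic.generate_sites(SiteSpec(n_sites=2000), seed=13)
        from rdeep.clipstats import pentamer_contrast

        obs = pentamer_contrast(sites)
        obs_diff = abs(obs["freq_weak"] - obs["freq_strong"]).loc["UUUUU"]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            shuffled = sites.copy()
            shuffled["score"] = rng.permutation(sites["score"].to_numpy())
            perm = pentamer_contrast(shuffled)
            null.append(abs(perm["freq_weak"] - perm["freq_strong"]).loc["UUUUU"])
        assert obs_diff <= np.quantile(null, 0.99)

    def test_invalid_mix_rejected(self):
        with pytest.raises(SpecError, match="sum to 1"):
            SiteSpec(n_sites=10, gene_type_mix={"a": 0.5, "b": 0.2})
        with pytest.raises(SpecError, match="length"):
            SiteSpec(n_sites=10, region_length_table={"CDS": 0.0})


def test_annotation_generator_produces_mixed_evidence(rng):
    records = synthetic.generate_annotations(
        [f"P{i}" for i in range(100)], [f"P{i}" for i in range(30)], seed=4
    )
    in_universe = [r for r in records if r.go_terms & {"GO:mitotic_cell_cycle"}]
    priors = [r for r in in_universe if r.rna_linked_prior]
    assert len(in_universe) > 50
    assert priors
    assert any(not r.has_known_rbd for r in priors)
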