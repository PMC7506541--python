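"""Stutter model calibration, contribution matrices and deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiedit import (
    AlleleDistribution,
    CmsLocus,
    PeakProfile,
    SimulationConfig,
    StutterModel,
    build_contribution_matrix,
    call_mutation_status,
    classify_frames,
    classify_msi_status,
    deconvolve,
    fit_stutter_model,
    frame_of,
    read_peak_profiles,
    simulate_control_profiles,
    simulate_loci,
)


def write_peaks(tmp_path, rows):
    path = tmp_path / "peaks.tsv"
    lines = ["sample_id\tlocus_id\tfragment_length\theight"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPeakProfiles:
    def test_offset_arithmetic(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [("S1", "TGFBR2", 120, 1000)])
        (prof,) = read_peak_profiles(path, {"TGFBR2": toy_locus})
        assert prof.heights[4] == 1000 and prof.heights.sum() == 1000

    def test_multiple_lengths_map_to_offsets(self, tmp_path, toy_locus):
        path = write_peaks(
            tmp_path,
            [("S1", "TGFBR2", 118, 10), ("S1", "TGFBR2", 119, 20), ("S1", "TGFBR2", 120, 70)],
        )
        (prof,) = read_peak_profiles(path, {"TGFBR2": toy_locus})
        assert list(prof.heights[[2, 3, 4]]) == [10, 20, 70]

    def test_out_of_window_band_dropped_with_warning(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [("S1", "TGFBR2", 110, 5), ("S1", "TGFBR2", 120, 100)])
        with pytest.warns(UserWarning, match="outside"):
            (prof,) = read_peak_profiles(path, {"TGFBR2": toy_locus})
        assert prof.total == 100

    def test_noise_floor_zeroes_small_bands(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [("S1", "TGFBR2", 119, 5), ("S1", "TGFBR2", 120, 1000)])
        (prof,) = read_peak_profiles(path, {"TGFBR2": toy_locus}, noise_floor=0.01)
        assert prof.heights[3] == 0.0

    def test_unknown_locus_error(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [("S1", "NOPE", 120, 10)])
        with pytest.raises(KeyError, match="NOPE"):
            read_peak_profiles(path, {"TGFBR2": toy_locus})

    def test_negative_height_error(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [("S1", "TGFBR2", 120, -3)])
        with pytest.raises(ValueError, match="negative"):
            read_peak_profiles(path, {"TGFBR2": toy_locus})

    def test_empty_file_error(self, tmp_path, toy_locus):
        path = write_peaks(tmp_path, [])
        with pytest.raises(ValueError, match="empty"):
            read_peak_profiles(path, {"TGFBR2": toy_locus})


class TestFitStutterModel:
    def test_parameter_recovery_from_known_logistic(self):
        config = SimulationConfig(
            seed=7, n_loci=18, min_repeat_length=10, max_repeat_length=27,
            stutter_slope=0.35, stutter_midpoint=18.0, noise_cv=0.02,
        )
        loci = simulate_loci(config)
        controls = simulate_control_profiles(loci, config, n_controls=20)
        model = fit_stutter_model(controls, {l.locus_id: l for l in loci})
        assert model.slope == pytest.approx(0.35, rel=0.10)
        assert model.midpoint == pytest.approx(18.0, rel=0.10)

    def test_stutter_free_controls_give_pure_reference(self, toy_locus):
        heights = np.zeros(9)
        heights[4] = 500.0
        controls = [PeakProfile(f"C{i}", "TGFBR2", heights) for i in range(3)]
        other = CmsLocus("OTHER", "OTHER", "A", 15, 130)
        controls += [PeakProfile("C0", "OTHER", heights)]
        model = fit_stutter_model(controls, {"TGFBR2": toy_locus, "OTHER": other})
        ref = model.p_ref("TGFBR2")
        assert ref[4] == 1.0 and np.all(ref[np.arange(9) != 4] == 0.0)

    def test_main_fraction_decreases_with_length(self, sim_panel):
        config, loci, _, _ = sim_panel
        controls = simulate_control_profiles(loci, config, n_controls=20)
        model = fit_stutter_model(controls, {l.locus_id: l for l in loci})
        assert model.main_fraction(25) < model.main_fraction(10)

    def test_single_length_error(self, toy_locus):
        heights = np.zeros(9)
        heights[4] = 1.0
        with pytest.raises(ValueError, match="logistic"):
            fit_stutter_model([PeakProfile("C", "TGFBR2", heights)], {"TGFBR2": toy_locus})

    def test_zero_signal_control_error(self, toy_locus):
        with pytest.raises(ValueError, match="zero"):
            fit_stutter_model([PeakProfile("C", "TGFBR2", np.zeros(9))], {"TGFBR2": toy_locus})


class TestContributionMatrix:
    def test_no_stutter_degenerates_to_identity(self, toy_locus):
        ref = np.zeros(9)
        ref[4] = 1.0
        model = StutterModel(slope=0.35, midpoint=18.0, reference_stutter={"TGFBR2": ref})
        C = build_contribution_matrix(toy_locus, model).entries
        assert np.array_equal(C, np.eye(9))

    def test_hand_evaluated_column(self, toy_locus, toy_model):
        # at the effective length, p_effective(0) equals the control main
        # fraction 0.7, so the wild-type column reproduces the control shape
        C = build_contribution_matrix(toy_locus, toy_model).entries
        np.testing.assert_allclose(C[[2, 3, 4], 4], [0.1, 0.2, 0.7], atol=1e-12)
        assert np.all(C[5:, 4] == 0.0)

    def test_columns_sum_to_one(self, sim_panel):
        _, _, _, matrices = sim_panel
        for mat in matrices.values():
            np.testing.assert_allclose(mat.entries.sum(axis=0), 1.0, atol=1e-12)

    def test_longer_alleles_stutter_more(self, toy_locus, toy_model):
        C = build_contribution_matrix(toy_locus, toy_model).entries
        off_diag = lambda j: 1.0 - C[j, j]
        assert off_diag(6) > off_diag(2)  # Δ=+2 vs Δ=-2

    def test_distant_offsets_zero(self, toy_locus, toy_model):
        C = build_contribution_matrix(toy_locus, toy_model).entries
        for i in range(9):
            for j in range(9):
                if abs(i - j) >= 5:
                    assert C[i, j] == 0.0


class TestDeconvolve:
    def test_identity_matrix_passthrough(self, toy_locus):
        ref = np.zeros(9)
        ref[4] = 1.0
        model = StutterModel(slope=0.35, midpoint=18.0, reference_stutter={"TGFBR2": ref})
        mat = build_contribution_matrix(toy_locus, model)
        heights = np.zeros(9)
        heights[4] = heights[3] = 0.5
        dist = deconvolve(PeakProfile("S", "TGFBR2", heights), mat)
        np.testing.assert_allclose(dist.fractions, heights, atol=1e-12)

    def test_forward_convolution_roundtrip(self, toy_matrix):
        truth = np.zeros(9)
        truth[4], truth[3] = 0.6, 0.4
        obs = PeakProfile("S", "TGFBR2", toy_matrix.forward(truth) * 1e4)
        dist = deconvolve(obs, toy_matrix)
        np.testing.assert_allclose(dist.fractions, truth, atol=1e-6)

    def test_pure_control_profile_is_wild_type(self, sim_panel):
        _, loci, _, matrices = sim_panel
        wt = np.zeros(9)
        wt[4] = 1.0
        for locus in loci:
            mat = matrices[locus.locus_id]
            dist = deconvolve(PeakProfile("N", locus.locus_id, mat.forward(wt)), mat)
            assert dist.mutant_fraction < 0.01

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_simplex(self, sim_panel, seed):
        """Noiseless deconvolution inverts the forward model exactly."""
        _, loci, _, matrices = sim_panel
        rng = np.random.default_rng(seed)
        locus = loci[seed % len(loci)]
        truth = rng.dirichlet(np.full(9, 0.8))
        mat = matrices[locus.locus_id]
        dist = deconvolve(PeakProfile("S", locus.locus_id, mat.forward(truth)), mat)
        assert np.abs(dist.fractions - truth).max() <= 1e-6

    def test_zero_signal_error(self, toy_matrix):
        with pytest.raises(ValueError, match="zero total signal"):
            deconvolve(PeakProfile("S", "TGFBR2", np.zeros(9)), toy_matrix)

    def test_locus_mismatch_error(self, toy_matrix):
        heights = np.zeros(9)
        heights[4] = 1.0
        with pytest.raises(ValueError, match="mismatch"):
            deconvolve(PeakProfile("S", "OTHER", heights), toy_matrix)


class TestFramesAndCalls:
    def test_frame_mapping_exhaustive(self):
        expected = {-4: "M1", -3: "M0", -2: "M2", -1: "M1", 0: "M0", 1: "M2", 2: "M1", 3: "M0", 4: "M2"}
        assert {d: frame_of(d) for d in range(-4, 5)} == expected

    @pytest.mark.parametrize(
        "mass,checks",
        [
            ({-1: 0.3, 2: 0.1, 0: 0.6}, {"m1_fraction": 0.4}),
            ({-2: 0.2, 1: 0.1, 0: 0.7}, {"m2_fraction": 0.3}),
            ({-3: 0.5, 0: 0.5}, {"m0_fraction": 1.0, "m1_fraction": 0.0, "m2_fraction": 0.0}),
        ],
    )
    def test_frame_pooling(self, mass, checks):
        frac = np.zeros(9)
        for d, v in mass.items():
            frac[d + 4] = v
        fs = classify_frames(AlleleDistribution("S", "L", frac))
        for attr, val in checks.items():
            assert getattr(fs, attr) == pytest.approx(val)
        assert fs.total == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "wt,status", [(0.90, "wildtype"), (0.60, "mutant"), (0.45, "biallelic"), (0.85, "mutant")]
    )
    def test_mutation_cutoffs(self, wt, status):
        frac = np.zeros(9)
        frac[4], frac[3] = wt, 1 - wt
        call = call_mutation_status(AlleleDistribution("S", "L", frac))
        assert call.status == status

    def test_dominant_frame_and_tie_break(self):
        frac = np.zeros(9)
        frac[4], frac[3], frac[2] = 0.6, 0.2, 0.2  # m1 (M1) vs m2 (M2) tied
        call = call_mutation_status(AlleleDistribution("S", "L", frac))
        assert call.dominant_frame == "M1"
        call = call_mutation_status(AlleleDistribution("S", "L", frac), tie_break="M2")
        assert call.dominant_frame == "M2"

    def test_invalid_cutoff_error(self):
        frac = np.zeros(9)
        frac[4] = 1.0
        with pytest.raises(ValueError, match="cutoff"):
            call_mutation_status(AlleleDistribution("S", "L", frac), mutation_cutoff=1.5)


class TestMsiStatus:
    @pytest.mark.parametrize(
        "n_unstable,n_total,expected",
        [(3, 7, "MSI"), (2, 7, "MSS"), (3, 10, "MSS"), (4, 10, "MSI")],
    )
    def test_thirty_percent_rule_is_strict(self, n_unstable, n_total, expected):
        markers = {f"M{i}": "unstable" if i < n_unstable else "stable" for i in range(n_total)}
        assert classify_msi_status(markers) == expected

    def test_no_markers_error(self):
        with pytest.raises(ValueError, match="markers"):
            classify_msi_status({})
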