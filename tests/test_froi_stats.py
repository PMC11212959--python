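import math

import numpy as np
import pytest

from parsability.froi_stats import (
    CodingError,
    EmptyMaskError,
    FroiResponse,
    ModelSpec,
    UndefinedIndexError,
    VoxelMap,
    build_model_table,
    count_significant_voxels,
    extract_condition_responses,
    fit_fixed_effects,
    froi_size,
    lateralization_index,
    select_froi,
)


def make_map(stats, responses=None, ids=None):
    n = len(stats)
    return VoxelMap(
        voxel_ids=np.array(ids if ids is not None else range(n)),
        localizer_stat=np.array(stats, float),
        condition_responses=responses or {"Sentence": np.zeros(n)},
        mask_label="toy",
    )


class TestSelectFroi:
    def test_top_5_of_50(self):
        stats = np.arange(50, dtype=float)
        m = make_map(stats)
        sel = select_froi(m, 0.10)
        assert len(sel) == 5
        assert sorted(stats[sel]) == [45, 46, 47, 48, 49]

    def test_rounding_rule_exhaustive(self):
        for n in range(1, 1001):
            assert froi_size(n, 0.10) == math.ceil(0.10 * n)

    def test_all_equal_statistics_tie_broken_by_voxel_id(self):
        m = make_map([1.0] * 10, ids=list(range(9, -1, -1)))
        sel = select_froi(m, 0.30)
        assert sorted(m.voxel_ids[sel]) == [0, 1, 2]

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            make_map([])

    def test_signal_enrichment_on_synthetic_map(self, world):
        """With 10% true-signal voxels, the selected set must be enriched
        for signal well above the 10% chance rate."""
        maps = world.simulate_voxel_data(n_voxels=500, noise_sd=1.0)
        m = maps[0]
        sel = select_froi(m, 0.10)
        # signal voxels are those with a planted localizer effect; recover
        # them from the map by their statistic's bimodality midpoint
        signal = m.localizer_stat > 2.0
        enrichment = signal[sel].mean()
        assert enrichment > 0.6


class TestExtractResponses:
    def test_constant_responses(self):
        m = make_map([1, 2, 3], {"A": np.full(3, 0.7), "B": np.full(3, -0.2)})
        r = extract_condition_responses(m, np.array([0, 1, 2]))
        assert r.condition_means == {"A": pytest.approx(0.7), "B": pytest.approx(-0.2)}

    def test_single_voxel_selection(self):
        m = make_map([1, 2], {"A": np.array([0.1, 0.9])})
        r = extract_condition_responses(m, np.array([1]))
        assert r.condition_means["A"] == pytest.approx(0.9)
        assert r.n_voxels_selected == 1

    def test_planted_contrast_recovered(self, world):
        maps = world.simulate_voxel_data(n_voxels=400, noise_sd=0.5)
        m = maps[0]
        r = extract_condition_responses(m, select_froi(m, 0.10))
        diff = r.condition_means["Sentence"] - r.condition_means["Backward"]
        assert diff == pytest.approx(1.5 - 0.9, abs=0.4)

    def test_empty_selection_rejected(self):
        m = make_map([1.0])
        with pytest.raises(ValueError):
            extract_condition_responses(m, np.array([], dtype=int))

    def test_noise_free_generation_exact(self, world):
        maps = world.simulate_voxel_data(n_voxels=100, noise_sd=0.0, signal_fraction=1.0)
        r = extract_condition_responses(maps[0], select_froi(maps[0], 0.10))
        for cond, eff in world.voxel_effects.items():
            assert r.condition_means[cond] == pytest.approx(eff)


class TestLateralization:
    def test_balanced_counts(self):
        idx, right = lateralization_index(100, 100)
        assert idx == 0 and not right

    def test_all_right(self):
        idx, right = lateralization_index(0, 50)
        assert idx == -1 and right

    def test_observed_value_classified_right_lateralized(self):
        # counts chosen so (LH-RH)/(LH+RH) lands near -0.67
        idx, right = lateralization_index(33, 167)
        assert idx == pytest.approx(-0.67)
        assert right

    def test_cutoff_boundary(self):
        idx, right = lateralization_index(3, 5)
        assert idx == -0.25 and right
        idx2, right2 = lateralization_index(39, 61)
        assert idx2 > -0.25 and not right2

    def test_antisymmetric(self):
        for a, b in [(10, 3), (7, 7), (0, 5), (120, 44)]:
            assert lateralization_index(a, b)[0] == -lateralization_index(b, a)[0]

    def test_undefined_for_zero_counts(self):
        with pytest.raises(UndefinedIndexError):
            lateralization_index(0, 0)

    def test_significant_voxel_count_thresholding(self):
        stats = np.array([0.5, 3.2, 4.0, 1.0])
        assert count_significant_voxels(stats, 3.09) == 2


class TestModelTable:
    def _responses(self, conds, n_participants=3):
        out = []
        for p in range(n_participants):
            out.append(
                FroiResponse(
                    participant=f"p{p}",
                    roi_label="roi",
                    condition_means={c: float(i) for i, c in enumerate(conds)},
                    n_voxels_selected=5,
                )
            )
        return out

    def test_two_conditions_one_dummy_reference_codes_zero(self):
        spec = ModelSpec(reference="Sentence")
        table, coding = build_model_table(self._responses(["Sentence", "Backward"]), spec)
        assert list(coding.columns) == ["cond_Backward"]
        ref_rows = table[table.condition == "Sentence"]
        assert (ref_rows["cond_Backward"] == 0).all()

    def test_six_conditions_five_dummies(self):
        conds = ["Sentence", "Backward", "Nonsense", "Jabberwocky", "WordList", "NonwordList"]
        table, coding = build_model_table(self._responses(conds), ModelSpec(reference="Sentence"))
        assert coding.shape[1] == 5

    def test_missing_reference_rejected(self):
        with pytest.raises(CodingError):
            build_model_table(self._responses(["A", "B"]), ModelSpec(reference="Sentence"))

    def test_ols_recovers_generating_effects(self, world):
        """Fixed-effect estimates on the dummy-coded table recover the
        planted condition effects within a noise-scaled tolerance."""
        maps = world.simulate_voxel_data(n_voxels=300, noise_sd=0.5, n_participants=12)
        responses = [
            extract_condition_responses(m, select_froi(m, 0.10), participant=f"p{i}")
            for i, m in enumerate(maps)
        ]
        spec = ModelSpec(reference="Sentence")
        table, _ = build_model_table(responses, spec)
        est = fit_fixed_effects(table, spec)
        effects = world.voxel_effects
        assert est["intercept"] == pytest.approx(effects["Sentence"], abs=0.3)
        for cond in ("Backward", "NonwordList", "Nonsense"):
            assert est[cond] == pytest.approx(effects[cond] - effects["Sentence"], abs=0.3)

    def test_generating_condition_ordering_recovered(self, world):
        maps = world.simulate_voxel_data(n_voxels=400, noise_sd=0.5, n_participants=10)
        responses = [
            extract_condition_responses(m, select_froi(m, 0.10), participant=f"p{i}")
            for i, m in enumerate(maps)
        ]
        means = {
            cond: float(np.mean([r.condition_means[cond] for r in responses]))
            for cond in world.voxel_effects
        }
        assert means["Sentence"] == pytest.approx(means["Nonsense"], abs=0.25)
        assert means["WordList"] == pytest.approx(means["Jabberwocky"], abs=0.25)
        assert means["Sentence"] > means["Backward"] > means["WordList"] > means["NonwordList"]


class TestVoxelMapIO:
    def test_tsv_roundtrip(self, world, tmp_path):
        m = world.simulate_voxel_data(n_voxels=50)[0]
        p = tmp_path / "vox.tsv"
        m.to_tsv(p)
        back = VoxelMap.from_tsv(p, mask_label=m.mask_label)
        np.testing.assert_allclose(back.localizer_stat, m.localizer_stat)
        for cond in m.condition_responses:
            np.testing.assert_allclose(
                back.condition_responses[cond], m.condition_responses[cond]
            )

    def test_nifti_ingestion(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        shape = (4, 4, 3)
        rng = np.random.default_rng(0)
        stat = rng.normal(size=shape)
        mask = np.zeros(shape)
        mask[1:3, 1:3, 1] = 1
        resp = rng.normal(size=shape)
        aff = np.eye(4)
        paths = {}
        for name, arr in [("stat", stat), ("mask", mask), ("resp", resp)]:
            p = tmp_path / f"{name}.nii"
            nib.Nifti1Image(arr, aff).to_filename(str(p))
            paths[name] = p
        m = VoxelMap.from_nifti(paths["stat"], paths["mask"], {"Sentence": paths["resp"]})
        assert m.n_voxels == 4
        np.testing.assert_allclose(
            np.sort(m.localizer_stat), np.sort(stat[mask > 0]), rtol=1e-6
        )
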