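"""Statistical structure and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from nanoladder import ChannelConfig, assign_codebook
from nanoladder.quantify import fold_change_ddct
from nanoladder.simulate import (
    GeneModel,
    SimulationConfig,
    render_image_stack,
    simulate_ground_truth,
    simulate_qpcr,
    simulate_spot_intensities,
)


@pytest.fixture
def ladder_codebook():
    return assign_codebook([f"b{i}" for i in range(1, 11)], ChannelConfig(1, 10))


def noiseless(config: SimulationConfig) -> SimulationConfig:
    cfg = config.model_copy(update={"h_dfp": 1.0, "h_rfp": 1.0})
    cfg.optics.shot_noise = False
    cfg.optics.read_noise_sigma = 0.0
    return cfg


class TestGroundTruth:
    def test_no_cells_gives_empty_tables(self, nineplex_codebook):
        cfg = SimulationConfig(seed=0, n_cells=0)
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        assert gt.cells.empty and gt.copies.empty and gt.amplicons.empty

    def test_nb_sample_mean_within_3_se(self, nineplex_codebook):
        mean, disp, n = 20.0, 5.0, 500
        cfg = SimulationConfig(
            seed=11, n_cells=n,
            genes={g: GeneModel(mean=mean, dispersion=disp) for g in nineplex_codebook.genes},
        )
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        copies = gt.copies[gt.copies.gene_id == "GAPDH"].true_copies
        se = np.sqrt((mean + mean**2 / disp) / n)
        assert abs(copies.mean() - mean) < 3 * se

    def test_detection_thinning_in_binomial_ci(self, nineplex_codebook):
        cfg = SimulationConfig(seed=2, n_cells=300)
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        total = gt.copies.true_copies.sum()
        detected = gt.copies.detected_amplicons.sum()
        assert total > 10_000
        p = 0.30
        se = np.sqrt(p * (1 - p) / total)
        assert abs(detected / total - p) < 1.96 * se

    @pytest.mark.parametrize("mode,rate", [("rna_primed", 0.2), ("primer_assisted", 16.0)])
    def test_nonspecific_mode_rates(self, nineplex_codebook, mode, rate):
        # parameter echo: mean background spots per cell follow the mode
        cfg = SimulationConfig(seed=4, n_cells=200)
        cfg.nonspecific.mode = mode
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        per_cell = (
            gt.amplicons[gt.amplicons.is_nonspecific].groupby("cell_id").size()
            .reindex(gt.cells.cell_id, fill_value=0)
        )
        se = np.sqrt(rate / len(per_cell))
        assert abs(per_cell.mean() - rate) < 4 * se

    def test_nonspecific_spots_carry_no_gene(self, nineplex_codebook):
        cfg = SimulationConfig(seed=4, n_cells=30)
        cfg.nonspecific.mode = "primer_assisted"
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        ns = gt.amplicons[gt.amplicons.is_nonspecific]
        assert len(ns) and ns.gene_id.isna().all()
        # exactly one lit detection channel
        lit = (ns[["level_1", "level_2"]] > 0).sum(axis=1)
        assert (lit == 1).all()

    def test_determinism_byte_identical(self, nineplex_codebook, small_sim_config):
        a = simulate_ground_truth(small_sim_config, nineplex_codebook)
        b = simulate_ground_truth(small_sim_config, nineplex_codebook)
        for x, y in [(a.cells, b.cells), (a.copies, b.copies), (a.amplicons, b.amplicons)]:
            assert x.to_csv() == y.to_csv()


class TestPhotometry:
    def test_zero_noise_ratio_equals_level_for_every_k(self, nineplex_codebook, small_sim_config):
        cfg = noiseless(small_sim_config)
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        ph = simulate_spot_intensities(gt.amplicons, cfg)
        spec = ph[~ph.is_nonspecific]
        assert len(spec) > 50 and spec.K.nunique() > 10
        for c in (1, 2):
            ratio = spec[f"I_De{c}"] / spec["I_Re"]
            assert np.array_equal(ratio.to_numpy(), spec[f"level_{c}"].to_numpy(dtype=float))

    def test_ratio_cv_below_raw_intensity_cv(self, ladder_codebook):
        cfg = SimulationConfig(
            seed=3, n_cells=100,
            genes={g: GeneModel(mean=10.0) for g in ladder_codebook.genes},
        )
        gt = simulate_ground_truth(cfg, ladder_codebook)
        ph = simulate_spot_intensities(gt.amplicons, cfg)
        spec = ph[~ph.is_nonspecific & (ph.I_Re > 0)]
        cv = lambda x: np.std(x) / np.mean(x)
        for gene in ladder_codebook.genes:
            sub = spec[spec.gene_id == gene]
            assert cv(sub.I_De1 / sub.I_Re) < cv(sub.I_De1)

    def test_ladder_mean_intensity_increases_with_level(self, ladder_codebook):
        cfg = SimulationConfig(
            seed=6, n_cells=200,
            genes={g: GeneModel(mean=10.0) for g in ladder_codebook.genes},
        )
        gt = simulate_ground_truth(cfg, ladder_codebook)
        ph = simulate_spot_intensities(gt.amplicons, cfg)
        spec = ph[~ph.is_nonspecific]
        means = spec.groupby("level_1")["I_De1"].mean()
        assert list(means.index) == list(range(1, 11))
        assert means.is_monotonic_increasing

    def test_photometry_determinism(self, nineplex_codebook, small_sim_config):
        gt = simulate_ground_truth(small_sim_config, nineplex_codebook)
        a = simulate_spot_intensities(gt.amplicons, small_sim_config)
        b = simulate_spot_intensities(gt.amplicons, small_sim_config)
        assert a.to_csv() == b.to_csv()


class TestRendering:
    def test_zero_spots_zero_noise_is_constant_background(self, nineplex_codebook):
        cfg = noiseless(SimulationConfig(seed=0, n_cells=1))
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        empty = gt.amplicons.iloc[0:0]
        ph = simulate_spot_intensities(empty, cfg)
        stack, cells_mask, _ = render_image_stack(ph, gt.cells, cfg)
        # all channels except the nuclear stain are flat background
        for plane in stack.data[:-1]:
            assert np.all(plane == int(cfg.optics.background))

    def test_single_spot_centroid_within_half_pixel(self, nineplex_codebook):
        cfg = noiseless(SimulationConfig(seed=1, n_cells=1))
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        truth = pd.DataFrame(
            {"x": [50.3], "y": [61.7], "z": [2.0], "I_Re": [5000.0], "I_De1": [0.0], "I_De2": [0.0]}
        )
        stack, _, _ = render_image_stack(truth, gt.cells, cfg)
        plane = stack.data[0, 2].astype(float) - cfg.optics.background
        ys, xs = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
        cy = (ys * plane).sum() / plane.sum()
        cx = (xs * plane).sum() / plane.sum()
        assert abs(cx - 50.3) < 0.5 and abs(cy - 61.7) < 0.5

    def test_z_spacing_metadata_is_500_nm(self, nineplex_codebook, small_sim_config):
        gt = simulate_ground_truth(small_sim_config, nineplex_codebook)
        ph = simulate_spot_intensities(gt.amplicons, small_sim_config)
        stack, _, _ = render_image_stack(ph, gt.cells, small_sim_config)
        assert stack.z_step_um == 0.5

    def test_stack_io_roundtrip(self, nineplex_codebook, small_sim_config, tmp_path):
        gt = simulate_ground_truth(small_sim_config, nineplex_codebook)
        ph = simulate_spot_intensities(gt.amplicons, small_sim_config)
        stack, _, _ = render_image_stack(ph, gt.cells, small_sim_config)
        path = tmp_path / "field.tif"
        stack.save(path)
        back = stack.load(path)
        assert np.array_equal(back.data, stack.data)
        assert back.channel_names == stack.channel_names
        assert back.z_step_um == stack.z_step_um

    def test_out_of_field_spot_warns_and_clips(self, nineplex_codebook):
        cfg = noiseless(SimulationConfig(seed=1, n_cells=1))
        gt = simulate_ground_truth(cfg, nineplex_codebook)
        truth = pd.DataFrame(
            {"x": [1e4], "y": [5.0], "z": [0.0], "I_Re": [100.0], "I_De1": [0.0], "I_De2": [0.0]}
        )
        with pytest.warns(UserWarning, match="clipped"):
            render_image_stack(truth, gt.cells, cfg)


class TestQpcr:
    @staticmethod
    def copies_frame(means, n=50):
        rows = []
        for gene, mean in means.items():
            rows += [{"gene_id": gene, "true_copies": mean}] * n
        return pd.DataFrame(rows)

    def test_equal_expression_gives_unit_fold_change(self):
        cfg = SimulationConfig()
        samples = {
            "test": self.copies_frame({"T": 10, "GAPDH": 50}),
            "cal": self.copies_frame({"T": 10, "GAPDH": 50}),
        }
        ct = simulate_qpcr(samples, cfg)
        assert fold_change_ddct(ct, "T", "GAPDH", "test", "cal") == pytest.approx(1.0)

    def test_fourfold_difference_recovered_exactly_at_zero_noise(self):
        cfg = SimulationConfig()
        samples = {
            "test": self.copies_frame({"T": 40, "GAPDH": 50}),
            "cal": self.copies_frame({"T": 10, "GAPDH": 50}),
        }
        ct = simulate_qpcr(samples, cfg)
        assert fold_change_ddct(ct, "T", "GAPDH", "test", "cal") == pytest.approx(4.0)

    def test_noisy_replicates_recover_fold_within_5_percent(self):
        cfg = SimulationConfig(seed=9)
        cfg.qpcr.noise_sd = 0.1
        cfg.qpcr.n_replicates = 100
        samples = {
            "test": self.copies_frame({"T": 40, "GAPDH": 50}),
            "cal": self.copies_frame({"T": 10, "GAPDH": 50}),
        }
        ct = simulate_qpcr(samples, cfg)
        fold = fold_change_ddct(ct, "T", "GAPDH", "test", "cal")
        assert abs(fold - 4.0) / 4.0 < 0.05
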