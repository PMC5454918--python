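"""Ground-truth fidelity and reproducibility of the synthetic generators."""

import numpy as np
import pytest

from comboloc.localizer import Frame, localize_stack
from comboloc.probe_design import ALU_PROBE, scan_kmer
from comboloc.synthgen import (
    DEFAULT_DOSES_GY, DOSE_COEFF_A, DOSE_COEFF_B, DOSE_COEFF_C,
    EmitterModel, NucleusModel, RepeatGenomeModel, generate_dose_series,
    generate_genome, generate_nucleus, generate_stack,
)


class TestStackGenerator:
    def test_always_on_single_emitter(self):
        model = EmitterModel(positions_nm=[(1550.0, 1550.0)], blink_prob=1.0,
                             background_mean=0.0, frames=20, seed=1)
        stack, truth = generate_stack(model, frame_shape=(32, 32))
        assert len(truth) == 20
        peaks = [np.unravel_index(np.argmax(f), f.shape) for f in stack]
        # blob stays put: brightest pixel within 1 px of the emitter pixel
        assert all(max(abs(r - 15), abs(c - 15)) <= 1 for r, c in peaks)

    def test_on_event_rate_binomial(self):
        model = EmitterModel(positions_nm=[(1600.0, 1600.0)], blink_prob=0.1,
                             frames=2000, seed=2)
        _, truth = generate_stack(model, frame_shape=(32, 32))
        expect = 2000 * 0.1
        assert abs(len(truth) - expect) <= 4 * np.sqrt(2000 * 0.1 * 0.9)

    def test_default_frame_count(self):
        assert EmitterModel(positions_nm=[(0.0, 0.0)]).frames == 2000

    def test_reproducible(self):
        model = EmitterModel(positions_nm=[(1000.0, 1000.0)], frames=10, seed=9)
        a, ta = generate_stack(model, (16, 16))
        b, tb = generate_stack(model, (16, 16))
        assert np.array_equal(a, b) and ta.equals(tb)

    def test_emitter_outside_field_rejected(self):
        model = EmitterModel(positions_nm=[(1e6, 1e6)])
        with pytest.raises(ValueError):
            generate_stack(model, (16, 16))

    def test_localize_roundtrip_recovers_on_events(self):
        """Detected spot count tracks planted ON events at SNR >= 4."""
        model = EmitterModel(positions_nm=[(1200.0, 1200.0), (4800.0, 4800.0)],
                             blink_prob=0.05, frames=400, seed=4)
        stack, truth = generate_stack(model, (64, 64))
        frames = [Frame(stack[i].astype(float), 100.0, i)
                  for i in range(stack.shape[0])]
        locs = localize_stack(frames)
        assert len(locs) >= 0.9 * len(truth)
        assert len(locs) <= 1.1 * len(truth) + 1


class TestNucleusGenerator:
    def test_truth_lists_planted_centers(self):
        points, truth = generate_nucleus(NucleusModel(n_clusters=30,
                                                      nucleus_radius_nm=3000.0,
                                                      seed=2))
        assert truth["centers"].shape == (30, 2)
        assert (truth["alu_labels"] >= -1).all()

    def test_default_plants_200_clusters(self):
        assert NucleusModel().n_clusters == 200

    def test_noise_fraction(self):
        _, truth = generate_nucleus(NucleusModel(n_clusters=40,
                                                 nucleus_radius_nm=4000.0,
                                                 alu_noise_fraction=0.2, seed=3))
        labels = truth["alu_labels"]
        frac = np.mean(labels == -1)
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_degenerate_tight_cluster(self):
        model = NucleusModel(n_clusters=1, points_per_cluster_mean=10.0,
                             points_per_cluster_min=10, cluster_sigma_nm=1e-6,
                             alu_noise_fraction=0.0, localization_jitter_nm=0.0,
                             seed=5)
        points, truth = generate_nucleus(model)
        xy = points.select("alu").coords()
        assert len(xy) >= 10
        assert np.ptp(xy, axis=0).max() < 1e-3

    def test_annulus_ratio_measured(self):
        """The het intensity around true centers matches the configured ratio."""
        model = NucleusModel(n_clusters=30, nucleus_radius_nm=6000.0,
                             min_separation_nm=1300.0,
                             het_background_per_nm2=1e-4, seed=6)
        points, truth = generate_nucleus(model)
        from comboloc.pointcloud import mean_shell_profile
        p = mean_shell_profile([tuple(c) for c in truth["centers"]],
                               points.select("het"), 20.0, 600.0)
        inner, outer, ratio = model.het_annulus
        mid = p.radii - 10.0
        band = p.densities[(mid > inner + 30) & (mid < outer - 30)].mean()
        base = p.densities[mid > outer + 100].mean()
        assert band / base == pytest.approx(ratio, rel=0.2)

    def test_infeasible_model_rejected(self):
        with pytest.raises(ValueError):
            NucleusModel(het_annulus=(300.0, 100.0, 3.0))
        with pytest.raises(ValueError):
            NucleusModel(het_suppression=-0.1)

    def test_reproducible(self):
        a, _ = generate_nucleus(NucleusModel(n_clusters=10,
                                             nucleus_radius_nm=2000.0, seed=8))
        b, _ = generate_nucleus(NucleusModel(n_clusters=10,
                                             nucleus_radius_nm=2000.0, seed=8))
        assert a.df.equals(b.df)


class TestGenomeGenerator:
    def test_zero_substitution_exact_recovery(self):
        genome, bed = generate_genome(RepeatGenomeModel(n_copies=25, seed=1))
        hits = scan_kmer(genome, ALU_PROBE, strand_policy="forward")
        assert len(hits) == 25

    def test_no_copies_background_only(self):
        genome, bed = generate_genome(RepeatGenomeModel(n_copies=0, seed=1))
        assert bed == []
        assert len(scan_kmer(genome, ALU_PROBE)) == 0

    def test_copies_non_overlapping(self):
        _, bed = generate_genome(RepeatGenomeModel(n_copies=50,
                                                   chrom_lengths={"chr1": 100_000},
                                                   seed=2))
        spans = sorted((s, e) for _, s, e, _ in bed)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_substitution_thins_hits_as_expected(self):
        """P(probe survives) = (1-rate)^k per copy, binomial across copies."""
        rate, k, n = 0.1, len(ALU_PROBE), 300
        model = RepeatGenomeModel(n_copies=n, substitution_rate=rate,
                                  chrom_lengths={"chr1": 600_000}, seed=3)
        genome, _ = generate_genome(model)
        hits = scan_kmer(genome, ALU_PROBE, strand_policy="forward")
        p = (1 - rate) ** k
        assert abs(len(hits) - n * p) <= 4 * np.sqrt(n * p * (1 - p))
        assert len(hits) < n

    def test_copies_must_fit(self):
        with pytest.raises(ValueError):
            RepeatGenomeModel(n_copies=100, chrom_lengths={"chr1": 5000})


class TestDoseSeries:
    def test_noiseless_counts_deterministic(self):
        df = generate_dose_series(noise_sigma=0.0, n_cells_per_dose=5, seed=0)
        for d, g in df.groupby("dose_gy"):
            expect = round(DOSE_COEFF_A * d ** 2 + DOSE_COEFF_B * d + DOSE_COEFF_C)
            assert (g["count"] == expect).all()

    def test_sample_means_near_model(self):
        df = generate_dose_series(noise_sigma=500.0, n_cells_per_dose=200, seed=1)
        for d, g in df.groupby("dose_gy"):
            mean = DOSE_COEFF_A * d ** 2 + DOSE_COEFF_B * d + DOSE_COEFF_C
            assert abs(g["count"].mean() - mean) <= 3 * 500 / np.sqrt(200)

    def test_defaults_are_reference_conditions(self):
        df = generate_dose_series(seed=0)
        assert sorted(df["dose_gy"].unique()) == list(DEFAULT_DOSES_GY)
        assert (df.groupby("dose_gy").size() == 35).all()

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_series(a=0.0, b=-100.0, c=10.0, doses=[0, 1, 2],
                                 n_cells_per_dose=3, noise_sigma=0.0)
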