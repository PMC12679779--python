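"""Marker QC: filters, heterozygote masking, kNN imputation, pipeline order."""

import numpy as np
import pytest

from wheatgs.genoqc import (QCConfig, QCReport, filter_maf, filter_missing,
                            knn_impute, remove_heterozygotes, run_qc)
from wheatgs.simdata import SimConfig, simulate_genotypes

from conftest import make_matrix


class TestFilterMaf:
    def test_monomorphic_marker_removed_at_any_threshold(self):
        g = make_matrix(np.column_stack([np.zeros(20), np.repeat([0.0, 2.0], 10)]))
        for thr in (0.01, 0.2, 0.49):
            out = filter_maf(g, thr)
            assert out.marker_ids == ["M1"]

    def test_maf_just_below_threshold_removed(self):
        # 100 lines, 4 carrying dosage 2 -> MAF = 8/200 = 0.04 < 0.05
        col = np.zeros(100)
        col[:4] = 2.0
        keepcol = np.repeat([0.0, 2.0], 50)
        g = make_matrix(np.column_stack([col, keepcol]))
        out = filter_maf(g, 0.05)
        assert out.marker_ids == ["M1"]

    def test_no_removal_when_simulated_above_threshold(self):
        cfg = SimConfig(n_lines=200, n_markers=300, maf_range=(0.10, 0.5),
                        missing_rate=0.0, het_rate=0.0, seed=21)
        g = simulate_genotypes(cfg)
        out = filter_maf(g, 0.05)
        assert out.n_markers == g.n_markers

    def test_bad_threshold_rejected(self):
        g = make_matrix(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            filter_maf(g, 0.6)


class TestFilterMissing:
    def test_boundary_strictly_more_than(self):
        base = np.tile(np.repeat([0.0, 2.0], 50), (3, 1)).T  # 100 x 3
        base[:31, 0] = np.nan   # 31% -> removed
        base[:30, 1] = np.nan   # exactly 30% -> retained
        g = make_matrix(base)
        out = filter_missing(g, 0.30)
        assert out.marker_ids == ["M1", "M2"]

    def test_complete_matrix_is_identity(self):
        g = make_matrix(np.repeat([[0.0, 2.0]], 10, axis=0))
        out = filter_missing(g, 0.3)
        np.testing.assert_array_equal(out.dosages, g.dosages)
        assert out.marker_ids == g.marker_ids


class TestRemoveHeterozygotes:
    def test_no_hets_is_identity(self):
        g = make_matrix(np.repeat([[0.0, 2.0]], 10, axis=0))
        out = remove_heterozygotes(g)
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_single_het_becomes_one_missing_cell(self):
        d = np.repeat([[0.0, 2.0]], 10, axis=0)
        d[3, 1] = 1.0
        rep = QCReport()
        out = remove_heterozygotes(make_matrix(d), report=rep)
        assert rep.n_het_calls_removed == 1
        assert np.isnan(out.dosages[3, 1])
        assert out.missing_mask.sum() == 1

    def test_het_count_matches_binomial_rate(self):
        cfg = SimConfig(n_lines=100, n_markers=500, missing_rate=0.0,
                        het_rate=0.05, seed=22)
        g = simulate_genotypes(cfg)
        rep = QCReport()
        remove_heterozygotes(g, report=rep)
        calls = g.dosages.size
        sd = np.sqrt(calls * 0.05 * 0.95)
        assert abs(rep.n_het_calls_removed - 0.05 * calls) < 3 * sd

    def test_drop_mode_removes_whole_columns(self):
        d = np.repeat([[0.0, 2.0, 0.0]], 10, axis=0)
        d[0, 2] = 1.0
        rep = QCReport()
        out = remove_heterozygotes(make_matrix(d), mode="drop", report=rep)
        assert out.marker_ids == ["M0", "M1"]
        assert rep.n_het_markers_dropped == 1


class TestKnnImpute:
    def test_complete_matrix_is_identity(self):
        g = make_matrix(np.repeat([[0.0, 2.0]], 10, axis=0))
        out = knn_impute(g, 5)
        np.testing.assert_array_equal(out.dosages, g.dosages)

    def test_twin_line_restores_masked_cell(self):
        rng = np.random.default_rng(3)
        base = rng.choice([0.0, 2.0], size=(8, 30))
        d = np.vstack([base, base[0]])      # line 8 duplicates line 0
        d[8, 5] = np.nan
        out = knn_impute(make_matrix(d), k=1)
        assert out.dosages[8, 5] == base[0, 5]

    def test_observed_cells_bit_exact(self):
        cfg = SimConfig(n_lines=60, n_markers=200, missing_rate=0.1,
                        het_rate=0.0, seed=23)
        g = simulate_genotypes(cfg)
        out = knn_impute(g, 5)
        obs = ~g.missing_mask
        np.testing.assert_array_equal(out.dosages[obs], g.dosages[obs])
        assert not out.missing_mask.any()
        assert set(np.unique(out.dosages)) <= {0.0, 2.0}

    def test_beats_mode_baseline_under_block_ld(self):
        cfg = SimConfig(n_lines=150, n_markers=400, missing_rate=0.0,
                        het_rate=0.0, ld_block_size=20, ld_rho=0.95,
                        maf_range=(0.2, 0.5), seed=24)
        truth = simulate_genotypes(cfg).truth
        rng = np.random.default_rng(1)
        mask = rng.random(truth.dosages.shape) < 0.10
        masked = truth.copy()
        masked.dosages[mask] = np.nan

        imputed = knn_impute(masked, 5)
        acc_knn = np.mean(imputed.dosages[mask] == truth.dosages[mask])

        # marker-mode baseline on the same masked cells
        mode_fill = np.where(np.nanmean(masked.dosages, axis=0) >= 1.0, 2.0, 0.0)
        mode_matrix = np.broadcast_to(mode_fill, truth.dosages.shape)
        acc_mode = np.mean(mode_matrix[mask] == truth.dosages[mask])
        assert acc_knn > acc_mode


class TestRunQc:
    def test_clean_matrix_unchanged_with_zero_counts(self):
        cfg = SimConfig(n_lines=50, n_markers=100, missing_rate=0.0,
                        het_rate=0.0, maf_range=(0.2, 0.5), seed=25)
        g = simulate_genotypes(cfg)
        out, rep = run_qc(g)
        np.testing.assert_array_equal(out.dosages, g.dosages)
        assert rep.n_removed_maf == rep.n_removed_missing == 0
        assert rep.n_het_calls_removed == rep.n_imputed_cells == 0
        assert rep.n_output_markers == rep.n_input_markers

    def test_stage_isolation_fixtures(self):
        """Three planted violations, each caught by exactly one stage."""
        rng = np.random.default_rng(5)
        good = rng.choice([0.0, 2.0], size=(100, 3), p=[0.5, 0.5])
        low_maf = np.zeros(100); low_maf[:2] = 2.0          # MAF 0.02
        high_missing = np.repeat([0.0, 2.0], 50).astype(float)
        high_missing[:40] = np.nan                           # 40% missing
        het_only = np.repeat([0.0, 2.0], 50).astype(float)
        het_only[10] = 1.0                                   # one het call
        d = np.column_stack([good, low_maf, high_missing, het_only])
        g = make_matrix(d)
        out, rep = run_qc(g)
        assert rep.n_input_markers == 6
        assert rep.n_removed_maf == 1
        assert rep.n_removed_missing == 1
        assert rep.n_het_calls_removed == 1
        assert rep.n_output_markers == 4
        assert "M5" in out.marker_ids  # het-masked marker survives, imputed
        assert rep.n_output_markers == (rep.n_input_markers - rep.n_removed_maf
                                        - rep.n_removed_missing)

    def test_idempotence(self):
        cfg = SimConfig(n_lines=60, n_markers=200, missing_rate=0.05,
                        het_rate=0.02, maf_range=(0.15, 0.5), seed=26)
        g = simulate_genotypes(cfg)
        once, _ = run_qc(g)
        twice, rep2 = run_qc(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert rep2.n_removed_maf == rep2.n_removed_missing == 0
        assert rep2.n_het_calls_removed == rep2.n_imputed_cells == 0

    def test_het_masking_counts_toward_missingness(self):
        """Ordering matters: hets masked first can push a marker over the
        missingness threshold even though raw missingness is below it."""
        col = np.repeat([0.0, 2.0], 50).astype(float)
        col[:20] = np.nan  # 20% missing
        col[20:35] = 1.0   # +15% hets -> 35% after masking
        good = np.repeat([[0.0, 2.0]], 50, axis=0).reshape(100, 1)
        g = make_matrix(np.column_stack([col, good]))
        out, rep = run_qc(g)
        assert rep.n_removed_missing == 1
        assert out.marker_ids == ["M1"]
        # the reversed order would have kept it: raw missingness 20% <= 30%
        kept = filter_missing(g, 0.30)
        assert kept.n_markers == 2
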