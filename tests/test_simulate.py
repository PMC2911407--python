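"""Defect sampling, chain growth, ensembles and Monte Carlo moves."""

import math

import numpy as np
import pytest

import e2afiber as ef
from e2afiber.fiber import LH_SKIP, NUC_SKIP, REGULAR, DefectMask
from e2afiber.params import Fixed, Normal
from e2afiber.simulate import equilibration_diagnostic


class TestDrawDefects:
    def test_zero_rates_all_regular(self, params_regular, rng):
        m = ef.draw_defects(params_regular, 500, rng)
        assert m.n_regular == 500

    def test_rates_within_binomial_error(self, params_depleted):
        """Empirical skip rates at n=10^6 within 3 SE of the binomial."""
        rng = np.random.default_rng(42)
        n = 1_000_000
        m = ef.draw_defects(params_depleted, n, rng)
        for rate, count in [(0.08, m.n_nuc_skip), (0.06, m.n_lh_skip)]:
            se = math.sqrt(rate * (1 - rate) * n)
            assert abs(count - rate * n) < 3 * se

    def test_skips_mutually_exclusive(self, params_depleted, rng):
        m = ef.draw_defects(params_depleted, 10_000, rng)
        assert m.n_regular + m.n_lh_skip + m.n_nuc_skip == 10_000

    def test_run_detection_and_naked_stretch_length(self, params_depleted):
        codes = np.array([0, 2, 2, 0, 1, 2, 0], dtype=np.int8)
        m = DefectMask(codes)
        assert m.nuc_skip_runs() == [(1, 2), (5, 1)]
        # a run of k skips leaves k*NRL + linker bp of naked DNA
        assert m.naked_stretch_bp(2, params_depleted) == 2 * 196 + 49

    def test_invalid_rates_rejected(self, params_regular, rng):
        from dataclasses import replace as dc_replace

        bad = dc_replace(params_regular, p_nuc_skip=1.5)  # bypass validate()
        with pytest.raises(ValueError):
            ef.draw_defects(bad, 10, rng)


class TestGrowFiber:
    def test_single_nrl_gives_one_nucleosome_at_origin(self, params_regular, rng):
        cfg = ef.SimulationConfig(params=params_regular, fiber_length_bp=196,
                                  n_fibers=1, rng_seed=0)
        f = ef.grow_fiber(cfg, rng)
        assert f.n_nucleosomes == 1
        assert np.allclose(f.centers[0], 0.0)

    def test_constant_angles_identical_across_seeds(self, params_regular):
        p = params_regular.replace(
            alpha_dist=Fixed(0.69), beta_dist=Fixed(2.24), linker_sd_nm=0.0
        )
        cfg = ef.SimulationConfig(params=p, fiber_length_bp=10_000, n_fibers=1)
        f1 = ef.grow_fiber(cfg, np.random.default_rng(1))
        f2 = ef.grow_fiber(cfg, np.random.default_rng(999))
        assert np.allclose(f1.centers, f2.centers, atol=1e-12)
        spacing = np.linalg.norm(np.diff(f1.centers, axis=0), axis=1)
        assert spacing.std() < 1e-9

    def test_expected_nucleosome_count_160kbp(self, params_regular):
        cfg = ef.SimulationConfig(params=params_regular, fiber_length_bp=160_000,
                                  n_fibers=1, rng_seed=5)
        f = ef.grow_fiber(cfg, np.random.default_rng(5))
        assert f.n_nucleosomes == 160_000 // 196  # 816

    def test_grown_fiber_satisfies_invariants(self, small_depleted_ensemble):
        for f in small_depleted_ensemble.fibers[:3]:
            f.validate()

    def test_index_gaps_match_skip_runs(self, small_depleted_ensemble):
        f = small_depleted_ensemble.fibers[0]
        present = np.flatnonzero(f.defect_mask.codes != NUC_SKIP)
        assert np.array_equal(present, f.genomic_index)

    def test_naked_dna_segment_lengths_exact(self, params_depleted):
        """Naked-DNA polyline segments are rise_nm_per_bp * bp long."""
        n_rep = 60
        codes = np.full(n_rep, REGULAR, dtype=np.int8)
        codes[20:23] = NUC_SKIP
        cfg = ef.SimulationConfig(params=params_depleted,
                                  fiber_length_bp=n_rep * 196, n_fibers=1)
        f = ef.grow_fiber(cfg, np.random.default_rng(3), mask=DefectMask(codes))
        segs = [s for s in f.linker_segments() if s[3] < 1.0]  # B-DNA rise segs
        assert segs, "expected naked-DNA segments"
        for p0, p1, span_bp, rise in segs:
            assert math.isclose(rise, 0.34, rel_tol=1e-9)

    def test_naked_dna_recovers_wlc_persistence_length(self, params_depleted):
        """Long skip run: the naked path is a 50 nm WLC within 10%."""
        n_rep = 160
        codes = np.full(n_rep, REGULAR, dtype=np.int8)
        codes[2:-2] = NUC_SKIP  # one ~30 kbp naked stretch
        cfg = ef.SimulationConfig(params=params_depleted,
                                  fiber_length_bp=n_rep * 196, n_fibers=1)
        lps = []
        for seed in range(12):
            f = ef.grow_fiber(cfg, np.random.default_rng(seed),
                              mask=DefectMask(codes))
            lps.append(ef.wlc_persistence_length(f.dna_points))
        assert abs(np.mean(lps) - 50.0) / 50.0 < 0.10

    def test_unsatisfiable_excluded_volume_raises(self, params_regular):
        p = params_regular.replace(
            linker_nm=6.0, linker_sd_nm=0.0,
            alpha_dist=Fixed(math.pi / 2), beta_dist=Fixed(0.0), pitch_d_nm=0.0,
        )
        cfg = ef.SimulationConfig(params=p, fiber_length_bp=5000, n_fibers=1,
                                  growth_max_retries=10, max_restarts=2)
        with pytest.raises(ef.GrowthError) as exc:
            ef.grow_fiber(cfg, np.random.default_rng(0))
        assert exc.value.partial_length_bp >= 0


class TestEnsembles:
    def test_seed_determinism_bit_identical(self, params_regular):
        cfg = ef.SimulationConfig(params=params_regular, fiber_length_bp=20_000,
                                  n_fibers=3, rng_seed=77)
        e1 = ef.simulate_ensemble(cfg)
        e2 = ef.simulate_ensemble(cfg)
        for a, b in zip(e1.fibers, e2.fibers):
            assert np.array_equal(a.centers, b.centers)
            assert np.array_equal(a.dna_points, b.dna_points)
            assert np.array_equal(a.genomic_index, b.genomic_index)

    def test_different_seeds_differ(self, params_regular):
        cfg1 = ef.SimulationConfig(params=params_regular, fiber_length_bp=20_000,
                                   n_fibers=1, rng_seed=1)
        cfg2 = ef.SimulationConfig(params=params_regular, fiber_length_bp=20_000,
                                   n_fibers=1, rng_seed=2)
        a = ef.simulate_ensemble(cfg1).fibers[0]
        b = ef.simulate_ensemble(cfg2).fibers[0]
        assert not np.allclose(a.centers, b.centers)

    def test_min_center_distance_respects_excluded_volume(
        self, small_regular_ensemble, small_depleted_ensemble
    ):
        from scipy.spatial.distance import pdist

        for ens in (small_regular_ensemble, small_depleted_ensemble):
            for f in ens.fibers:
                d = pdist(f.centers)
                bp = f.nucleosome_bp
                # non-bonded pairs only
                i, j = np.triu_indices(len(bp), k=1)
                nonbond = np.abs(bp[j] - bp[i]) >= f.params.nrl_bp
                assert d[nonbond].min() >= f.params.contact_distance_nm - 1e-9

    def test_depletion_reduces_extension(self, params_regular, params_depleted):
        """Matched seeds: skip rates (8%, 6%) shrink the mean squared
        end-to-end distance relative to regular fibers."""
        kw = dict(fiber_length_bp=80_000, n_fibers=10, rng_seed=31)
        reg = ef.simulate_ensemble(ef.SimulationConfig(params=params_regular, **kw))
        dep = ef.simulate_ensemble(ef.SimulationConfig(params=params_depleted, **kw))
        r2_reg = np.mean([f.end_to_end_nm() ** 2 for f in reg.fibers])
        r2_dep = np.mean([f.end_to_end_nm() ** 2 for f in dep.fibers])
        assert r2_dep < r2_reg

    def test_equilibration_diagnostic_on_iid_ensemble(self, small_regular_ensemble):
        d = equilibration_diagnostic(small_regular_ensemble)
        assert "equilibrated" in d and d["drift_se"] >= 0


class TestMonteCarlo:
    def test_zero_moves_is_identity(self, params_regular):
        cfg = ef.SimulationConfig(params=params_regular, fiber_length_bp=10_000,
                                  n_fibers=1)
        f = ef.grow_fiber(cfg, np.random.default_rng(4))
        g = ef.mc_equilibrate(f, cfg, np.random.default_rng(0), n_moves=0)
        assert np.array_equal(f.centers, g.centers)

    def test_rigid_constant_angle_chain_invariant_under_moves(self, params_regular):
        p = params_regular.replace(alpha_dist=Fixed(0.69), beta_dist=Fixed(2.24),
                                   linker_sd_nm=0.0)
        cfg = ef.SimulationConfig(params=p, fiber_length_bp=6_000, n_fibers=1)
        f = ef.grow_fiber(cfg, np.random.default_rng(4))
        g = ef.mc_equilibrate(f, cfg, np.random.default_rng(1), n_moves=60)
        assert math.isclose(f.end_to_end_nm(), g.end_to_end_nm(), rel_tol=1e-9)

    def test_mc_agrees_with_regrowth_ensemble(self, params_regular):
        """Independence-pivot MC sampling must match independent
        regrowth on <R_ee^2> (same target distribution)."""
        cfg = ef.SimulationConfig(params=params_regular, fiber_length_bp=6_000,
                                  n_fibers=1)
        rng = np.random.default_rng(8)
        # regrowth oracle
        regrow = np.array(
            [ef.grow_fiber(cfg, np.random.default_rng(1000 + k)).end_to_end_nm() ** 2
             for k in range(150)]
        )
        f = ef.grow_fiber(cfg, rng)
        samples = []
        for _ in range(150):
            f = ef.mc_equilibrate(f, cfg, rng, n_moves=30)
            samples.append(f.end_to_end_nm() ** 2)
        samples = np.asarray(samples)
        se = math.sqrt(regrow.var(ddof=1) / len(regrow) + samples.var(ddof=1) / len(samples))
        assert abs(samples.mean() - regrow.mean()) < 3 * se


def test_rebuild_from_variates_is_bit_identical(params_depleted):
    """The MC rebuild path reproduces the grown chain exactly."""
    from e2afiber.simulate import _assemble

    cfg = ef.SimulationConfig(params=params_depleted, fiber_length_bp=30_000,
                              n_fibers=1)
    f = ef.grow_fiber(cfg, np.random.default_rng(12))
    g, clash = _assemble(cfg, f.defect_mask, f._variates)
    assert clash is None
    assert np.array_equal(f.centers, g.centers)
    assert np.array_equal(f.dna_points, g.dna_points)
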