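import numpy as np
import pytest

from grnsim.kinetics import GeneKinetics, RegulationEdge
from grnsim.population import (
    SSA,
    TAU_LEAPING,
    CellState,
    DivisionModel,
    GeneExpressionModel,
    SimulationConfig,
    advance_reactions,
    divide,
    grow,
    propensities,
    simulate_population,
    write_ground_truth,
)
from grnsim.topology import ACTIVATION, ADDITIVE, INHIBITION, Edge, GRNTopology

TINY = 1e-12


def one_gene_model(k1=1.0, k2=TINY, dm=0.1, dp=TINY):
    topo = GRNTopology(1, ())
    return GeneExpressionModel(topo, [GeneKinetics(k1, k2, dm, dp)], [])


def regulated_model(combination_mode, K=100.0, n=2.0):
    """Gene 2 regulated by an activator (gene 0) and an inhibitor (gene 1)."""
    topo = GRNTopology(
        3, (Edge(0, 2, ACTIVATION), Edge(1, 2, INHIBITION)), combination_mode
    )
    gks = [GeneKinetics(10, 1, 1, 1)] * 3
    regs = [RegulationEdge(n, K, ACTIVATION), RegulationEdge(n, K, INHIBITION)]
    return GeneExpressionModel(topo, gks, regs)


def cell(volume=1.0, mrna=(0,), protein=(0,), mu=np.log(2) / 50):
    return CellState(
        volume=volume,
        growth_rate=mu,
        birth_volume=1.0,
        division_target=2.0,
        mrna=np.array(mrna),
        protein=np.array(protein),
    )


class TestPropensities:
    def test_unregulated_transcription_scales_with_volume(self):
        model = one_gene_model(k1=10.0)
        a = propensities(cell(volume=2.0), model)
        assert a[0, 0] == pytest.approx(20.0)

    def test_half_saturation_multiplicative(self):
        model = regulated_model("multiplicative")
        c = cell(mrna=(100, 100, 0), protein=(0, 0, 0))
        a = propensities(c, model)
        assert a[0, 2] == pytest.approx(10 * 0.5 * 0.5)

    def test_half_saturation_additive(self):
        model = regulated_model(ADDITIVE)
        c = cell(mrna=(100, 100, 0), protein=(0, 0, 0))
        a = propensities(c, model)
        assert a[0, 2] == pytest.approx(10 * (0.5 + 0.5))

    def test_decay_and_translation_channels(self):
        model = one_gene_model(k1=1, k2=0.5, dm=2.0, dp=0.25)
        a = propensities(cell(mrna=(8,), protein=(4,)), model)
        assert a[1, 0] == pytest.approx(0.5 * 8)  # translation
        assert a[2, 0] == pytest.approx(2.0 * 8)  # mRNA decay
        assert a[3, 0] == pytest.approx(0.25 * 4)  # protein decay

    def test_absent_regulator_extremes(self):
        # activator absent silences, inhibitor absent leaves full rate
        model = regulated_model("multiplicative")
        c = cell(mrna=(0, 0, 0))
        a = propensities(c, model)
        assert a[0, 2] == pytest.approx(10 * 0.0 * 1.0)


class TestAdvanceReactions:
    @pytest.mark.parametrize("method", [SSA, TAU_LEAPING])
    def test_pure_decay_closed_form(self, method, rng):
        """m(0)=1000, dm=1/h, one 0.1 h window.

        SSA is exact: mean remaining 1000·e^(-0.1). A single tau-leap
        window freezes the rate at the window start, so its mean is the
        first-order value 1000·(1 - dm·τ); the discrepancy vanishes as
        τ → 0 (the operating regime has dm·τ ~ 0.01).
        """
        model = one_gene_model(k1=TINY, dm=1.0)
        n_rep = 2_000 if method == SSA else 10_000
        remaining = np.array(
            [
                advance_reactions(cell(mrna=(1000,)), model, 0.1, method, rng).mrna[0]
                for _ in range(n_rep)
            ]
        )
        expected = 1000 * (np.exp(-0.1) if method == SSA else (1 - 0.1))
        se = remaining.std() / np.sqrt(n_rep)
        assert abs(remaining.mean() - expected) < 3 * se + 1e-9

    def test_rejects_bad_arguments(self, rng):
        model = one_gene_model()
        with pytest.raises(ValueError):
            advance_reactions(cell(), model, -1.0, SSA, rng)
        with pytest.raises(ValueError):
            advance_reactions(cell(), model, 0.1, "leapfrog", rng)

    def test_integer_state_out(self, rng):
        model = one_gene_model(k1=5.0, k2=1.0, dm=0.5, dp=0.1)
        c = cell(mrna=(10,), protein=(100,))
        for method in (SSA, TAU_LEAPING):
            out = advance_reactions(c, model, 0.5, method, rng)
            assert out.mrna.dtype == np.int64 and out.protein.dtype == np.int64
            assert (out.mrna >= 0).all() and (out.protein >= 0).all()


class TestGrow:
    def test_doubles_over_one_doubling_time(self):
        c = cell(volume=1.0)
        assert grow(c, 50.0).volume == pytest.approx(2.0, rel=1e-12)

    def test_zero_step_is_identity(self):
        assert grow(cell(volume=1.3), 0.0).volume == 1.3

    def test_small_steps_compose_exactly(self):
        c = cell(volume=1.0)
        for _ in range(500):
            c = grow(c, 0.1)
        assert c.volume == pytest.approx(2.0, rel=1e-12)


class TestDivide:
    def test_conservation_and_symmetric_volumes(self, rng):
        model = DivisionModel(eta2_sd=0.0)
        parent = cell(volume=2.0, mrna=(100, 40), protein=(7, 0))
        d1, d2 = divide(parent, model, rng)
        assert d1.volume == pytest.approx(1.0) and d2.volume == pytest.approx(1.0)
        np.testing.assert_array_equal(d1.mrna + d2.mrna, parent.mrna)
        np.testing.assert_array_equal(d1.protein + d2.protein, parent.protein)
        assert d1.division_target == pytest.approx(2.0)  # adder: V_F = V_I + 1

    def test_below_target_is_precondition_violation(self, rng):
        with pytest.raises(ValueError):
            divide(cell(volume=1.5), DivisionModel(), rng)

    def test_molecule_fraction_tracks_eta2(self, rng):
        """Binomial partitioning: E[daughter-1 share | η2] = η2 (slope 1)."""
        model = DivisionModel(eta2_sd=0.05)
        etas, fracs = [], []
        for _ in range(4_000):
            parent = cell(volume=2.0, mrna=(20_000,))
            d1, d2 = divide(parent, model, rng)
            etas.append(d1.volume / parent.volume)
            fracs.append(d1.mrna[0] / parent.mrna[0])
        slope = np.polyfit(etas, fracs, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_eta2_clamped_inside_unit_interval(self, rng):
        model = DivisionModel(eta2_sd=5.0)  # absurd noise to force clamping
        for _ in range(50):
            d1, d2 = divide(cell(volume=2.0, mrna=(10,)), model, rng)
            assert 0.05 * 2.0 <= d1.volume <= 0.95 * 2.0
            assert d1.volume + d2.volume == pytest.approx(2.0)


class TestSimulatePopulation:
    def test_population_size_and_shapes_constant(self):
        model = one_gene_model(k1=5.0, k2=0.5, dm=0.2, dp=0.1)
        cfg = SimulationConfig(n_cells=30, t_end=60.0, seed=4)
        gt, _ = simulate_population(model, cfg)
        assert gt.mrna.shape == (1, 30)
        assert gt.protein.shape == (1, 30)
        assert (gt.mrna >= 0).all() and (gt.protein >= 0).all()
        assert (gt.volumes > 0).all() and gt.volumes.max() < 2.6

    def test_unregulated_mrna_concentration_matches_steady_state(self):
        """Pooled final-snapshot mRNA/V has mean k1/(dm+µ).

        Exponential growth dilutes concentration at rate µ on top of
        degradation, so the stationary concentration is k1/(dm+µ); with a
        50 h doubling time µ ≈ 0.014/h, a ~3% correction to k1/dm.
        """
        model = one_gene_model(k1=30.0, dm=0.5)
        cfg = SimulationConfig(n_cells=400, t_end=60.0, seed=5)
        gt, _ = simulate_population(model, cfg)
        conc = gt.mrna[0] / gt.volumes
        se = conc.std() / np.sqrt(len(conc))
        mu = cfg.growth_rate
        assert abs(conc.mean() - 30.0 / (0.5 + mu)) < 3 * se

    def test_fixed_seed_bit_identical(self):
        model = one_gene_model(k1=5.0, k2=0.5, dm=0.2, dp=0.1)
        cfg = SimulationConfig(n_cells=20, t_end=30.0, seed=11)
        a, _ = simulate_population(model, cfg)
        b, _ = simulate_population(model, cfg)
        np.testing.assert_array_equal(a.mrna, b.mrna)
        np.testing.assert_array_equal(a.protein, b.protein)
        np.testing.assert_array_equal(a.volumes, b.volumes)

    def test_trajectory_recording(self):
        model = one_gene_model()
        cfg = SimulationConfig(n_cells=5, t_end=2.0, seed=0)
        _, traj = simulate_population(model, cfg, track_cells=(0, 3), record_every=5)
        assert set(traj.columns) == {"time", "cell", "gene", "mrna", "protein", "volume"}
        assert set(traj["cell"]) == {0, 3}
        assert traj["time"].max() == pytest.approx(2.0)

    def test_ssa_population_runs(self):
        model = one_gene_model(k1=2.0, dm=0.5)
        cfg = SimulationConfig(n_cells=10, t_end=5.0, method=SSA, seed=2)
        gt, _ = simulate_population(model, cfg)
        assert gt.mrna.shape == (1, 10)


def test_ground_truth_writer(tmp_path, toy5_small):
    gt = toy5_small["ground_truth"]
    write_ground_truth(gt, tmp_path)
    import pandas as pd
    from scipy import io as spio

    csv = pd.read_csv(tmp_path / "gt_mrna.csv", index_col=0)
    assert csv.shape == (gt.n_genes, gt.n_cells)
    np.testing.assert_array_equal(csv.to_numpy(), gt.mrna)
    mtx = spio.mmread(str(tmp_path / "gt_mrna.mtx")).toarray()
    np.testing.assert_array_equal(mtx, gt.mrna)
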