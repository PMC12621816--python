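"""Gene dynamics, force readouts, and the coupled genetic-mechanical run."""

import numpy as np
import pytest

from gastrosim.grn import (
    Gate,
    GRNSpec,
    ReadoutRule,
    RegulatoryEdge,
    apply_readouts,
    default_network,
    gene_update,
    run_grn_simulation,
)
from gastrosim.mechanics import IntegratorParams, LongRangeParams, ShortRangeParams
from gastrosim.population import CellPopulation, init_spherical_aggregate
from gastrosim.metrics import largest_aggregate, morphological_asymmetry


def _single_cell(genes):
    g = np.atleast_2d(np.asarray(genes, float))
    return CellPopulation(
        positions=np.zeros((1, 3)),
        radii=np.ones(1),
        types=np.array(["u"]),
        genes=g,
    )


def _spec(n_genes=1, edges=(), amplitude=0.5, h=4.0, k=0.5, leak=0.0,
          delta=0.2, noise=0.0, readout=None):
    return GRNSpec(
        n_genes=n_genes,
        edges=list(edges),
        amplitude=np.full(n_genes, amplitude),
        hill_h=np.full(n_genes, h),
        hill_k=np.full(n_genes, k),
        leak=np.full(n_genes, leak),
        degradation=np.full(n_genes, delta),
        gene_noise_sigma=noise,
        readout=readout or ReadoutRule(class_gene=0),
    )


class TestGeneUpdate:
    def test_pure_degradation_recurrence(self):
        """No edges, no leak: G follows (1 - dt*delta)^k exactly, clipped."""
        spec = _spec(delta=0.3)
        pop = _single_cell([1.0])
        rng = np.random.default_rng(0)
        g = 1.0
        for k in range(40):
            pop.genes = gene_update(pop, spec, dt=0.2, rng=rng)
            g = max(g * (1 - 0.2 * 0.3), 0.0)
            assert pop.genes[0, 0] == pytest.approx(g, abs=1e-12)

    def test_no_input_means_no_production(self):
        # H(0) = 0: with zero degradation and leak the state is frozen
        spec = _spec(delta=0.0)
        pop = _single_cell([0.4])
        out = gene_update(pop, spec, dt=0.2, rng=np.random.default_rng(0))
        assert out[0, 0] == pytest.approx(0.4)

    def test_inhibitory_input_gives_no_production(self):
        spec = _spec(
            n_genes=2,
            edges=[RegulatoryEdge(source=0, target=1, weight=-1.0)],
            delta=0.0,
        )
        pop = CellPopulation(
            positions=np.zeros((1, 3)), radii=np.ones(1),
            types=np.array(["u"]), genes=np.array([[1.0, 0.5]]),
        )
        out = gene_update(pop, spec, dt=0.2, rng=np.random.default_rng(0))
        assert out[0, 1] == pytest.approx(0.5)  # u < 0 -> H = 0

    def test_timer_matches_scalar_recurrence_oracle(self):
        """Self-activating timer: the (N=1) update reproduces the scalar
        recurrence, decays monotonically and crosses 0.5."""
        amp, delta, k, h, dt = 0.142, 0.15, 0.7, 8.0, 0.2
        spec = _spec(amplitude=amp, delta=delta, k=k, h=h,
                     edges=[RegulatoryEdge(source=0, target=0, weight=1.0)])
        pop = _single_cell([1.0])
        rng = np.random.default_rng(0)
        # independent scalar oracle
        g_oracle = [1.0]
        for _ in range(750):
            g = g_oracle[-1]
            hill = g**h / (k**h + g**h) if g > 0 else 0.0
            g_oracle.append(min(max(g + dt * (amp * hill - delta * g), 0), 1))
        g_impl = [1.0]
        for _ in range(750):
            pop.genes = gene_update(pop, spec, dt=dt, rng=rng)
            g_impl.append(pop.genes[0, 0])
        np.testing.assert_allclose(g_impl, g_oracle, atol=1e-12)
        diffs = np.diff(g_impl)
        assert np.all(diffs <= 1e-12)  # monotone non-increasing
        assert min(g_impl) < 0.5  # crosses the stage threshold

    def test_intercellular_cue_decays_with_distance(self):
        spec = _spec(
            n_genes=2,
            edges=[RegulatoryEdge(source=0, target=1, weight=1.0, lam=2.0)],
            delta=0.0, amplitude=1.0,
        )
        for d, expected in [(2.0, np.exp(-1.0)), (4.0, np.exp(-2.0))]:
            pop = CellPopulation(
                positions=np.array([[0.0, 0, 0], [d, 0, 0]]),
                radii=np.ones(2), types=np.array(["u", "u"]),
                genes=np.array([[1.0, 0.0], [0.0, 0.0]]),
            )
            out = gene_update(pop, spec, dt=1.0, rng=np.random.default_rng(0))
            u = expected  # signal received by cell 1
            hill = u**4 / (0.5**4 + u**4)
            assert out[1, 1] == pytest.approx(hill, abs=1e-12)

    def test_gates_control_edges_per_cell(self):
        gate = Gate(gene=0, op="above", theta=0.5)
        spec = _spec(
            n_genes=2,
            edges=[RegulatoryEdge(source=1, target=1, weight=1.0, gate=gate)],
            delta=0.0, amplitude=1.0,
        )
        pop = CellPopulation(
            positions=np.zeros((2, 3)), radii=np.ones(2),
            types=np.array(["u", "u"]),
            genes=np.array([[0.9, 1.0], [0.1, 1.0]]),
        )
        out = gene_update(pop, spec, dt=0.1, rng=np.random.default_rng(0))
        assert out[0, 1] > 1.0 - 1e-9  # gated edge active -> production
        assert out[1, 1] == pytest.approx(1.0)  # gate closed -> frozen

    def test_output_always_within_bounds(self):
        rng = np.random.default_rng(5)
        spec = _spec(
            n_genes=3,
            edges=[RegulatoryEdge(source=i, target=j, weight=w)
                   for i, j, w in [(0, 1, 5.0), (1, 2, -5.0), (2, 0, 3.0)]],
            amplitude=2.0, noise=0.3,
        )
        pop = CellPopulation(
            positions=rng.uniform(0, 3, (10, 3)), radii=np.ones(10),
            types=np.full(10, "u"), genes=rng.random((10, 3)),
        )
        for _ in range(50):
            pop.genes = gene_update(pop, spec, dt=0.2, rng=rng)
            assert np.all(pop.genes >= 0.0) and np.all(pop.genes <= 1.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            _spec(edges=[RegulatoryEdge(source=0, target=3, weight=1.0)])
        with pytest.raises(ValueError):
            _spec(edges=[RegulatoryEdge(source=0, target=0, weight=1.0,
                                        gate=Gate(gene=5, op="above",
                                                  theta=0.5))])
        with pytest.raises(ValueError):
            _spec(edges=[RegulatoryEdge(source=0, target=0, weight=1.0,
                                        lam=-1.0)])
        with pytest.raises(ValueError):
            _spec(k=1.5)


class TestApplyReadouts:
    def _rule(self):
        return ReadoutRule(
            timer_gene=0, timer_threshold=0.5,
            class_gene=1, class_threshold=0.5,
            alpha_hom=0.80,
            alpha_table=ShortRangeParams.from_triple(0.72, 0.79, 0.88),
            beta_table=LongRangeParams.single_channel("o", "o", 0.5),
        )

    def _pop(self, timer, klass):
        n = len(timer)
        genes = np.column_stack([timer, klass])
        return CellPopulation(
            positions=np.zeros((n, 3)), radii=np.ones(n),
            types=np.full(n, "u"), genes=genes,
        )

    def test_establishment_stage_is_homogeneous(self):
        pop = self._pop([1.0, 1.0, 1.0], [0.1, 0.9, 0.5])
        states, alpha3, beta3 = apply_readouts(pop, self._rule())
        assert np.all(states == 2)  # all undifferentiated
        # any pair involving an establishment-stage cell: baseline, no beta
        assert alpha3[2, 2] == 0.80
        assert np.all(beta3[2, :] == 0.0) and np.all(beta3[:, 2] == 0.0)

    def test_maintenance_stage_applies_two_type_tables(self):
        pop = self._pop([0.0, 0.0, 0.0], [0.05, 0.95, 0.05])
        states, alpha3, beta3 = apply_readouts(pop, self._rule())
        assert list(states) == [0, 1, 0]  # o, i, o
        assert alpha3[0, 0] == 0.79  # o-o
        assert alpha3[1, 1] == 0.72  # i-i
        assert alpha3[0, 1] == alpha3[1, 0] == 0.88
        assert beta3[0, 0] == 0.5  # o->o only
        assert beta3[1, 1] == beta3[0, 1] == beta3[1, 0] == 0.0

    def test_mixed_stage_pair_uses_baseline(self):
        pop = self._pop([0.9, 0.1], [0.05, 0.05])
        states, alpha3, beta3 = apply_readouts(pop, self._rule())
        assert list(states) == [2, 0]
        assert alpha3[states[0], states[1]] == 0.80
        assert beta3[states[0], states[1]] == 0.0

    def test_class_tie_resolves_inner(self):
        pop = self._pop([0.0], [0.5])
        states, _, _ = apply_readouts(pop, self._rule())
        assert states[0] == 1  # exactly at threshold -> inner


class TestRunGRNSimulation:
    def test_zeroed_regulation_stays_homogeneous(self):
        spec = default_network()
        for e in list(spec.edges):
            pass
        zeroed = GRNSpec(
            n_genes=3,
            edges=[],
            amplitude=spec.amplitude,
            hill_h=spec.hill_h,
            hill_k=spec.hill_k,
            leak=np.zeros(3),
            degradation=np.zeros(3),
            gene_noise_sigma=0.0,
            readout=spec.readout,
        )
        traj = run_grn_simulation(
            zeroed, n_cells=80,
            integ=IntegratorParams(t_total=10.0, seed=0),
        )
        final = traj.final
        assert np.all(final.genes == 1.0)  # nothing moves the genes
        # all cells stay one class: asymmetry remains zero throughout
        assert np.all(traj.asymmetry == 0.0)

    def test_records_gene_history(self):
        spec = default_network()
        traj = run_grn_simulation(
            spec, n_cells=40, integ=IntegratorParams(t_total=5.0, seed=1),
            record_every=10, metric_every=10,
        )
        assert traj.snapshots[0].genes.min() == 1.0
        assert len(traj.snapshots) == len(traj.steps)
        table = traj.gene_table()
        assert table.shape[1] == 4


class TestDefaultNetworkBehavior:
    """Behavioral suite on the shared full-length 400-cell run."""

    def test_timer_high_then_low(self, grn_run):
        _, traj = grn_run
        g1 = np.array([s.genes[:, 0].mean() for s in traj.snapshots])
        n = len(g1)
        assert g1[: max(1, n // 10)].mean() > 0.8
        assert g1[-max(1, n // 10):].mean() < 0.2

    def test_class_gene_bimodal(self, grn_run):
        _, traj = grn_run
        g2 = traj.final.genes[:, 1]
        mid = ((g2 > 0.35) & (g2 < 0.65)).mean()
        assert mid < 0.05  # valley around the class threshold
        assert (g2 < 0.5).mean() > 0.05  # both modes populated
        assert (g2 >= 0.5).mean() > 0.05

    def test_inner_cells_express_more_class_gene(self, grn_run):
        _, traj = grn_run
        init, final = traj.initial, traj.final
        r0 = np.linalg.norm(init.positions - init.positions.mean(0), axis=1)
        g2 = final.genes[:, 1]
        assert np.corrcoef(r0, g2)[0, 1] < -0.1

    def test_bistable_pair_anticorrelated(self, grn_run):
        _, traj = grn_run
        g2, g3 = traj.final.genes[:, 1], traj.final.genes[:, 2]
        assert np.corrcoef(g2, g3)[0, 1] < -0.5
        # states near the (1, low) / (low, 1) corners
        inner = g2 >= 0.5
        assert g2[inner].mean() > 0.8 and g3[inner].mean() < 0.3
        assert g2[~inner].mean() < 0.3 and g3[~inner].mean() > 0.7

    def test_asymmetry_grows_on_average(self, grn_run):
        _, traj = grn_run
        a = traj.asymmetry
        q = len(a) // 4
        assert a[-q:].mean() > a[:q].mean()
        assert a[-1] > 0.5  # clear symmetry breaking at the end

    def test_gene_bounds_maintained(self, grn_run):
        _, traj = grn_run
        for snap in traj.snapshots:
            assert np.all(snap.genes >= 0) and np.all(snap.genes <= 1)

    def test_classes_lock_in_under_doubled_noise(self):
        """After the maintenance gate engages, doubling gene noise does not
        change any cell's class for the rest of the run."""
        spec = default_network()
        phase1 = run_grn_simulation(
            spec, n_cells=400, integ=IntegratorParams(t_total=80.0, seed=1)
        )
        pop = phase1.final
        assert (pop.genes[:, 0] < 0.5).mean() > 0.99  # gate engaged
        classes_before = pop.genes[:, 1] < 0.5
        noisy = default_network(gene_noise_sigma=2 * spec.gene_noise_sigma)
        phase2 = run_grn_simulation(
            noisy, population=pop,
            integ=IntegratorParams(t_total=70.0, seed=1001),
        )
        classes_after = phase2.final.genes[:, 1] < 0.5
        np.testing.assert_array_equal(classes_before, classes_after)
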