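"""Spatial RDME engine: diffusion physics, SSA equivalence, bias partition."""

import math

import numpy as np
import pytest
from scipy import stats

from splicesim import constants as C
from splicesim import rdme
from splicesim.geometry import (
    LatticeSpec,
    SiteLattice,
    SiteType,
    Sphere,
    stencil_primitive,
)
from splicesim.network import (
    N,
    Reaction,
    ReactionNetwork,
    Species,
    TransitionBias,
)
from splicesim.rdme import RunConfig, _Placement, run
from splicesim.ssa import single_compartment_model, ssa_run

NS = frozenset({SiteType.NUCLEOPLASM, SiteType.SPECKLE})


def uniform_lattice(edge, spacing=0.064, st=SiteType.NUCLEOPLASM):
    lat = SiteLattice.empty(LatticeSpec(edge, spacing))
    lat.sites[:] = int(st)
    return lat


class TestDiffusion:
    def test_diffusion_conserves_every_species(self):
        lat = uniform_lattice(1.28)
        sp = [
            Species("A", N, 1.0, initial=200,
                    initial_compartment=SiteType.NUCLEOPLASM),
            Species("B", N, 0.2, initial=77,
                    initial_compartment=SiteType.NUCLEOPLASM),
        ]
        net = ReactionNetwork(sp, [])
        tr = run(lat, net, RunConfig(duration=1.0, record_interval=0.1, seed=2))
        assert np.all(tr.series("A") == 200)
        assert np.all(tr.series("B") == 77)

    def test_mean_squared_displacement_matches_einstein(self):
        # 2000 molecules from the box center; MSD(t) = 6 D t within 5%
        lam = 0.064
        lat = uniform_lattice(6.4, lam)
        n_half = lat.spec.n_sites_per_dim // 2
        start = np.array([[n_half, n_half, n_half]] * 2000)
        sp = [Species("A", N, 1.0, initial=2000,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        t = 0.5
        tr = run(lat, net, RunConfig(duration=t, seed=9),
                 placements=[_Placement("A", start)])
        pos = tr.metadata["final_positions"]
        n = lat.spec.n_sites_per_dim
        xyz = np.stack(
            [pos // (n * n), (pos // n) % n, pos % n], axis=1
        ).astype(float)
        disp = (xyz - start[0]) * lam
        msd = (disp**2).sum(axis=1).mean()
        assert msd == pytest.approx(6.0 * 1.0 * t, rel=0.05)

    def test_disallowed_region_is_never_entered(self):
        lat = uniform_lattice(1.28)
        # forbidden spherical inclusion in the middle
        stencil_primitive(lat, Sphere((0.64, 0.64, 0.64), 0.3), SiteType.CAJAL)
        sp = [Species("A", N, 1.0, initial=300,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        tr = run(lat, net, RunConfig(duration=0.5, record_interval=0.05, seed=4))
        assert np.all(tr.series("A", "cajal") == 0)
        assert np.all(tr.series("A", "nucleoplasm") == 300)

    def test_tau_above_stability_bound_rejected(self):
        lat = uniform_lattice(1.28)
        sp = [Species("A", N, 1.0, initial=5,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        with pytest.raises(ValueError, match="tau"):
            run(lat, net, RunConfig(duration=0.1, tau=1.0, seed=1))


@pytest.fixture(scope="module")
def speckle_box():
    """Nucleoplasm box with one central speckle sphere."""
    lat = uniform_lattice(1.92, 0.064)
    stencil_primitive(lat, Sphere((0.96, 0.96, 0.96), 0.3), SiteType.SPECKLE)
    return lat


class TestSpeckleBias:
    @pytest.mark.parametrize("rho", [1.0, 3.0, 10.0, 100.0])
    def test_partition_matches_detailed_balance(self, speckle_box, rho):
        lat = speckle_box
        v_s = lat.volume_of(SiteType.SPECKLE)
        v_n = lat.volume_of(SiteType.NUCLEOPLASM)
        expected = rho * v_s / (rho * v_s + v_n)
        sp = [Species("U", NS, 1.0, initial=300,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [],
                              TransitionBias({"U": (1.0, 1.0 / rho)}))
        fracs = []
        for rep in range(5):
            tr = run(lat, net, RunConfig(duration=6.0, record_interval=0.06,
                                         seed=17, replicate_id=rep))
            f = tr.series("U", "speckle")[40:] / 300.0
            fracs.append(f.mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 3 * se + 0.01


class TestReactions:
    def one_site_lattice(self):
        return uniform_lattice(0.064, 0.064)

    def test_zero_propensity_leaves_state_unchanged(self):
        lat = self.one_site_lattice()
        sp = [Species("A", N, 0.0, initial=10,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [Reaction("decay", ("A",), (), 0.0, "s-1", N)])
        tr = run(lat, net, RunConfig(duration=1.0, tau=0.01, seed=1))
        assert tr.final("A") == 10

    def test_first_order_decay_mean(self):
        lat = self.one_site_lattice()
        n0, k, t = 60, 0.5, 1.0
        sp = [Species("A", N, 0.0, initial=n0,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [Reaction("decay", ("A",), (), k, "s-1", N)])
        vals = np.array([
            run(lat, net, RunConfig(duration=t, tau=0.01, seed=5,
                                    replicate_id=i)).final("A")
            for i in range(200)
        ])
        p = math.exp(-k * t)
        se = math.sqrt(n0 * p * (1 - p) / 200)
        assert abs(vals.mean() - n0 * p) < 3 * se

    def test_single_subvolume_reproduces_wellmixed_ssa(self):
        # A+B <-> C in one subvolume vs the SSA oracle at the same volume
        lat = self.one_site_lattice()
        vol = lat.spec.site_volume
        a0, b0 = 15, 10
        sp = [
            Species("A", N, 0.0, initial=a0,
                    initial_compartment=SiteType.NUCLEOPLASM),
            Species("B", N, 0.0, initial=b0,
                    initial_compartment=SiteType.NUCLEOPLASM),
            Species("AB", N, 0.0),
        ]
        rx = [
            Reaction("on", ("A", "B"), ("AB",), C.KON_G, "M-1s-1", N),
            Reaction("off", ("AB",), ("A", "B"), C.KOFF_G, "s-1", N),
        ]
        t = 0.3
        rdme_vals = np.array([
            run(lat, ReactionNetwork(sp, rx),
                RunConfig(duration=t, tau=0.005, seed=7, replicate_id=i)
                ).final("AB")
            for i in range(200)
        ])
        model = single_compartment_model(
            ReactionNetwork(sp, rx), vol, SiteType.NUCLEOPLASM
        )
        ssa_vals = np.array([ssa_run(model, t, seed=50_000 + i).final("AB")
                             for i in range(200)])
        assert stats.ks_2samp(rdme_vals, ssa_vals).pvalue > 0.01

    def test_pore_transport_scales_with_pore_sites(self):
        # a diffusing molecule converts at pore sites; twice the pores ->
        # about twice the early-time conversions
        def flux(n_pores, rep):
            lat = uniform_lattice(0.64, 0.064, SiteType.NUCLEOPLASM)
            lat.sites[0, :n_pores, :1] = int(SiteType.NPC)
            sp = [
                Species("A", frozenset({SiteType.NUCLEOPLASM, SiteType.NPC}),
                        1.0, initial=150,
                        initial_compartment=SiteType.NUCLEOPLASM),
                Species("Aexp", frozenset({SiteType.NUCLEOPLASM, SiteType.NPC}),
                        1.0),
            ]
            rx = [Reaction("export", ("A",), ("Aexp",), 50.0, "s-1",
                           frozenset({SiteType.NPC}))]
            tr = run(lat, ReactionNetwork(sp, rx),
                     RunConfig(duration=0.5, seed=21, replicate_id=rep))
            return tr.final("Aexp")

        f1 = np.array([flux(2, i) for i in range(20)], dtype=float)
        f2 = np.array([flux(4, i) for i in range(20)], dtype=float)
        ratio = f2.mean() / f1.mean()
        se = ratio * math.sqrt(
            (f2.std(ddof=1) / f2.mean()) ** 2 + (f1.std(ddof=1) / f1.mean()) ** 2
        ) / math.sqrt(20)
        assert abs(ratio - 2.0) < 3 * se + 0.2

    def test_zero_pores_zero_transport(self):
        lat = uniform_lattice(0.64, 0.064)
        sp = [
            Species("A", frozenset({SiteType.NUCLEOPLASM, SiteType.NPC}), 1.0,
                    initial=50, initial_compartment=SiteType.NUCLEOPLASM),
            Species("Aexp", frozenset({SiteType.NUCLEOPLASM, SiteType.NPC}), 1.0),
        ]
        rx = [Reaction("export", ("A",), ("Aexp",), 50.0, "s-1",
                       frozenset({SiteType.NPC}))]
        tr = run(lat, ReactionNetwork(sp, rx), RunConfig(duration=0.5, seed=3))
        assert tr.final("Aexp") == 0


class TestRunSemantics:
    def test_zero_duration_returns_initial_state(self, speckle_box):
        sp = [Species("A", NS, 1.0, initial=40,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        tr = run(speckle_box, net, RunConfig(duration=0.0, seed=1))
        assert len(tr.times) == 1 and tr.final("A") == 40

    def test_same_seed_identical_different_replicate_not(self, speckle_box):
        sp = [Species("A", NS, 1.0, initial=60,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        a = run(speckle_box, net, RunConfig(duration=0.5, record_interval=0.05,
                                            seed=5, replicate_id=0))
        b = run(speckle_box, net, RunConfig(duration=0.5, record_interval=0.05,
                                            seed=5, replicate_id=0))
        c = run(speckle_box, net, RunConfig(duration=0.5, record_interval=0.05,
                                            seed=5, replicate_id=1))
        assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_halving_tau_leaves_endpoint_mean_stable(self):
        # operator-splitting convergence: tau and tau/2 agree within noise
        lat = uniform_lattice(0.32, 0.064)
        sp = [
            Species("A", N, 1.0, initial=40,
                    initial_compartment=SiteType.NUCLEOPLASM),
            Species("B", N, 1.0, initial=30,
                    initial_compartment=SiteType.NUCLEOPLASM),
            Species("AB", N, 1.0),
        ]
        rx = [
            Reaction("on", ("A", "B"), ("AB",), 5e7, "M-1s-1", N),
            Reaction("off", ("AB",), ("A", "B"), 1.0, "s-1", N),
        ]
        net = ReactionNetwork(sp, rx)

        def means(tau, base):
            vals = [
                run(lat, net, RunConfig(duration=1.0, tau=tau, seed=base,
                                        replicate_id=i)).final("AB")
                for i in range(40)
            ]
            return np.mean(vals), np.std(vals, ddof=1) / math.sqrt(40)

        m1, se1 = means(6.8e-4, 1)
        m2, se2 = means(3.4e-4, 2)
        assert abs(m1 - m2) < 3 * math.hypot(se1, se2)

    def test_compartment_closure_every_frame(self, speckle_box):
        # a species excluded from speckles never appears there
        sp = [Species("A", N, 1.0, initial=100,
                      initial_compartment=SiteType.NUCLEOPLASM)]
        net = ReactionNetwork(sp, [])
        tr = run(speckle_box, net,
                 RunConfig(duration=1.0, record_interval=0.05, seed=6))
        assert np.all(tr.series("A", "speckle") == 0)
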