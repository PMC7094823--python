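"""Exact Gillespie SSA over well-mixed compartments with exchange.

The direct-method sampler runs a ``ReactionNetwork`` in one or more
well-mixed compartments, each standing in for a lattice site-type region
(nucleoplasm, speckles, cytoplasm, ...), coupled by first-order exchange
reactions.  It is the verification oracle for the spatial engine and the
fast surrogate for the long speckle experiments: speckle partitioning
with bias (P_n, P_s) coarse-grains to exchange constants

    k_in  = P_n * D * A / (lambda * V_n)      (nucleoplasm -> speckle)
    k_out = P_s * D * A / (lambda * V_s)      (speckle -> nucleoplasm)

which reproduce the equilibrium concentration ratio c_s/c_n = P_n/P_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as C
from .geometry import SiteType
from .network import ReactionNetwork
from .traj import Trajectory


@dataclass(frozen=True)
class Compartment:
    name: str
    volume_um3: float
    site_type: SiteType

    def __post_init__(self):
        if self.volume_um3 <= 0:
            raise ValueError(f"compartment {self.name}: volume must be positive")


@dataclass(frozen=True)
class Exchange:
    """First-order transfer of one species between two compartments."""

    species: str
    src: str
    dst: str
    rate: float  # s^-1

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("negative exchange rate")


@dataclass
class CompartmentModel:
    compartments: list[Compartment]
    network: ReactionNetwork
    exchanges: list[Exchange] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        for e in self.exchanges:
            if e.src not in names or e.dst not in names:
                raise ValueError(f"exchange {e} references unknown compartment")


def derive_exchange_rates(
    v_nucleoplasm_um3: float,
    v_speckle_um3: float,
    interface_area_um2: float,
    diffusion: float,
    p_n: float = 1.0,
    p_s: float = 1.0,
    spacing_um: float = 0.064,
) -> tuple[float, float]:
    """(k_in, k_out) coarse-graining biased boundary crossings.

    Detailed balance gives the equilibrium count ratio
    N_s/N_n = k_in/k_out = (P_n/P_s) * (V_s/V_n), i.e. a concentration
    ratio of exactly P_n/P_s.
    """
    if v_nucleoplasm_um3 <= 0 or v_speckle_um3 <= 0:
        raise ValueError("volumes must be positive")
    base = diffusion * interface_area_um2 / spacing_um
    return p_n * base / v_nucleoplasm_um3, p_s * base / v_speckle_um3


def rho_for_localization(target_fraction: float, v_n: float, v_s: float) -> float:
    """P_n/P_s so the equilibrium speckle count fraction equals target."""
    if not 0 < target_fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    rho = target_fraction * v_n / ((1.0 - target_fraction) * v_s)
    return max(rho, 1.0)


def speckle_partition_fraction(rho: float, v_s: float, v_n: float) -> float:
    """Equilibrium fraction of a biased species inside speckles."""
    return rho * v_s / (rho * v_s + v_n)


def build_exchanges(
    network: ReactionNetwork,
    v_n: float,
    v_s: float,
    area: float,
    spacing_um: float = 0.064,
    nucleoplasm: str = "nucleoplasm",
    speckle: str = "speckle",
) -> list[Exchange]:
    """Nucleoplasm<->speckle exchange for every mobile species, using each
    species' diffusion coefficient and its (P_n, P_s) bias."""
    out = []
    for s in network.species:
        if s.diffusion <= 0:
            continue
        if SiteType.SPECKLE not in s.allowed or SiteType.NUCLEOPLASM not in s.allowed:
            continue
        pn, ps = network.bias.get(s.name)
        k_in, k_out = derive_exchange_rates(
            v_n, v_s, area, s.diffusion, pn, ps, spacing_um
        )
        out.append(Exchange(s.name, nucleoplasm, speckle, k_in))
        out.append(Exchange(s.name, speckle, nucleoplasm, k_out))
    return out


# --------------------------------------------------------------------------
# compilation + kernel
# --------------------------------------------------------------------------


@njit(cache=False)
def _ssa_kernel(
    x, kind, i1, i2, rate, s_idx, s_val, s_n, duration, rec_times, seed
):  # pragma: no cover - executed via numba
    np.random.seed(seed)
    n_ch = kind.shape[0]
    n_rec = rec_times.shape[0]
    rec = np.zeros((n_rec, x.shape[0]), dtype=np.int64)
    tallies = np.zeros(n_ch, dtype=np.int64)
    a = np.zeros(n_ch)
    t = 0.0
    irec = 0
    while True:
        a0 = 0.0
        for c in range(n_ch):
            if kind[c] == 0:
                ac = rate[c] * x[i1[c]]
            elif kind[c] == 1:
                ac = rate[c] * x[i1[c]] * x[i2[c]]
            else:
                ac = rate[c] * x[i1[c]] * (x[i1[c]] - 1) * 0.5
            a[c] = ac
            a0 += ac
        if a0 <= 0.0:
            t_next = duration + 1.0
        else:
            t_next = t - np.log(np.random.random()) / a0
        while irec < n_rec and rec_times[irec] <= min(t_next, duration) + 1e-12:
            rec[irec] = x
            irec += 1
        if t_next > duration:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        chosen = n_ch - 1
        for c in range(n_ch):
            acc += a[c]
            if u <= acc:
                chosen = c
                break
        for k in range(s_n[chosen]):
            x[s_idx[chosen, k]] += s_val[chosen, k]
        tallies[chosen] += 1
    while irec < n_rec:
        rec[irec] = x
        irec += 1
    return rec, tallies


def _compile(model: CompartmentModel):
    net = model.network
    sp_index = net.species_index()
    n_sp = len(net.species)
    n_comp = len(model.compartments)
    comp_index = {c.name: i for i, c in enumerate(model.compartments)}

    def flat(ci, si):
        return ci * n_sp + si

    kind, i1, i2, rate, stoich, names = [], [], [], [], [], []
    for rx in net.reactions:
        for ci, comp in enumerate(model.compartments):
            if comp.site_type not in rx.compartments:
                continue
            delta: dict[int, int] = {}
            for nm in rx.reactants:
                delta[flat(ci, sp_index[nm])] = delta.get(flat(ci, sp_index[nm]), 0) - 1
            for nm in rx.products:
                delta[flat(ci, sp_index[nm])] = delta.get(flat(ci, sp_index[nm]), 0) + 1
            if len(rx.reactants) == 0:
                raise ValueError(f"{rx.name}: source reactions need a reactant")
            if rx.units == "s-1":
                kind.append(0)
                i1.append(flat(ci, sp_index[rx.reactants[0]]))
                i2.append(0)
                rate.append(rx.rate)
            else:
                a, b = rx.reactants
                k_eff = rx.rate / (C.AVOGADRO * comp.volume_um3 * 1e-15)
                if a == b:
                    kind.append(2)
                    i1.append(flat(ci, sp_index[a]))
                    i2.append(0)
                    rate.append(2.0 * k_eff)  # propensity k * n(n-1)/2 * 2/2
                else:
                    kind.append(1)
                    i1.append(flat(ci, sp_index[a]))
                    i2.append(flat(ci, sp_index[b]))
                    rate.append(k_eff)
            stoich.append(delta)
            names.append(f"{rx.name}@{comp.name}")
    for ex in model.exchanges:
        si = sp_index[ex.species]
        src, dst = comp_index[ex.src], comp_index[ex.dst]
        kind.append(0)
        i1.append(flat(src, si))
        i2.append(0)
        rate.append(ex.rate)
        stoich.append({flat(src, si): -1, flat(dst, si): +1})
        names.append(f"exchange_{ex.species}_{ex.src}->{ex.dst}")

    n_ch = len(kind)
    max_d = max((len(d) for d in stoich), default=1)
    s_idx = np.zeros((n_ch, max_d), dtype=np.int64)
    s_val = np.zeros((n_ch, max_d), dtype=np.int64)
    s_n = np.zeros(n_ch, dtype=np.int64)
    for c, d in enumerate(stoich):
        for k, (ix, v) in enumerate(d.items()):
            s_idx[c, k] = ix
            s_val[c, k] = v
        s_n[c] = len(d)
    return (
        np.asarray(kind, dtype=np.int8),
        np.asarray(i1, dtype=np.int64),
        np.asarray(i2, dtype=np.int64),
        np.asarray(rate, dtype=np.float64),
        s_idx,
        s_val,
        s_n,
        names,
        comp_index,
        sp_index,
    )


def initial_state(model: CompartmentModel) -> np.ndarray:
    """Place each species' initial count in the compartment matching its
    initial site type (falling back to the first allowed compartment)."""
    n_sp = len(model.network.species)
    x = np.zeros(len(model.compartments) * n_sp, dtype=np.int64)
    st_of = {c.site_type: i for i, c in enumerate(model.compartments)}
    for si, s in enumerate(model.network.species):
        if s.initial == 0:
            continue
        ci = st_of.get(s.initial_compartment)
        if ci is None:
            for st in s.allowed:
                if st in st_of:
                    ci = st_of[st]
                    break
        if ci is None:
            raise ValueError(f"no compartment can host species {s.name}")
        x[ci * n_sp + si] = s.initial
    return x


def ssa_run(
    model: CompartmentModel,
    duration: float,
    seed: int,
    record_interval: float | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Exact direct-method SSA; reproducible from the seed."""
    if duration < 0:
        raise ValueError("negative duration")
    kind, i1, i2, rate, s_idx, s_val, s_n, names, comp_index, sp_index = _compile(model)
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite channel propensity coefficient")
    x = (initial_state(model) if x0 is None else x0.astype(np.int64)).copy()
    if record_interval is None:
        record_interval = duration if duration > 0 else 1.0
    n_rec = int(np.floor(duration / record_interval + 1e-9)) + 1
    rec_times = np.arange(n_rec) * record_interval
    kseed = int(np.random.SeedSequence([seed]).generate_state(1)[0] & 0x7FFFFFFF)
    rec, tallies = _ssa_kernel(
        x, kind, i1, i2, rate, s_idx, s_val, s_n, float(duration), rec_times, kseed
    )
    n_sp = len(model.network.species)
    counts = rec.reshape(n_rec, len(model.compartments), n_sp)
    return Trajectory(
        times=rec_times,
        counts=counts,
        compartment_names=[c.name for c in model.compartments],
        species_names=[s.name for s in model.network.species],
        tallies=tallies,
        channel_names=names,
        metadata={"engine": "ssa", "seed": seed, "duration": duration},
    )


def single_compartment_model(
    network: ReactionNetwork, volume_um3: float, site_type: SiteType
) -> CompartmentModel:
    """One well-mixed compartment standing in for the whole allowed region."""
    return CompartmentModel(
        [Compartment(site_type.name.lower(), volume_um3, site_type)], network
    )


def nucleus_speckle_model(
    network: ReactionNetwork,
    v_nucleoplasm_um3: float,
    v_speckle_um3: float,
    interface_area_um2: float,
    spacing_um: float = 0.064,
) -> CompartmentModel:
    """Two-compartment surrogate of the nucleus: nucleoplasm + pooled
    speckles, with exchange constants derived from the network's bias."""
    comps = [
        Compartment("nucleoplasm", v_nucleoplasm_um3, SiteType.NUCLEOPLASM),
        Compartment("speckle", v_speckle_um3, SiteType.SPECKLE),
    ]
    ex = build_exchanges(
        network, v_nucleoplasm_um3, v_speckle_um3, interface_area_um2, spacing_um
    )
    return CompartmentModel(comps, network, ex)
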