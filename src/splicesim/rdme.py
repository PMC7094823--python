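"""Lattice reaction-diffusion master equation engine.

Operator-split fixed-timestep sampler: each step of length tau performs
(1) independent diffusion jumps of every tracked molecule to one of its
six lattice neighbors with per-direction probability D*tau/lambda^2,
rejecting jumps into site types the species may not occupy and applying
the speckle boundary-crossing bias (P_n inward, P_s outward); then
(2) an exact Gillespie sub-loop over the interval [t, t+tau) inside each
occupied subvolume, with compartment restrictions enforced by site type.
In the tau -> 0 limit the scheme samples the same master equation as an
exact next-subvolume method, and with a single subvolume it reduces to
the well-mixed SSA (tested against it).

Molecules are tracked individually (position + species); multiple
occupancy per site is allowed.  Species flagged ``reservoir`` (very
abundant pools whose spatial fluctuations are irrelevant) are held as
global well-mixed counts: reactions consume them via pseudo-first-order
propensities using the current pool concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as C
from .geometry import SiteLattice, SiteType
from .network import ReactionNetwork, bimolecular_stochastic_rate, compute_timestep
from .traj import Trajectory

_NUCLEO = int(SiteType.NUCLEOPLASM)
_SPECKLE = int(SiteType.SPECKLE)
_N_ST = len(SiteType)


@dataclass
class RunConfig:
    duration: float
    tau: float | None = None
    record_interval: float | None = None
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("negative duration")


@njit(cache=False)
def _recompute_h(h_tot, ch_kind, ch_r1, ch_rate, ch_allowed, res_of, res_count,
                 res_inv_navol):  # pragma: no cover
    h_tot[:, :] = 0.0
    n_ch = ch_kind.shape[0]
    for c in range(n_ch):
        if ch_kind[c] == 0:
            k_eff = ch_rate[c]
        elif ch_kind[c] == 2:
            r = res_of[ch_r1[c, 1]]
            k_eff = ch_rate[c] * res_count[r] * res_inv_navol[r]
        else:
            continue
        s = ch_r1[c, 0]
        for st in range(h_tot.shape[1]):
            if ch_allowed[c, st]:
                h_tot[s, st] += k_eff


@njit(cache=False)
def _rdme_kernel(
    sites,          # uint8 flat
    n0, n1, n2,     # lattice dims
    pos, spc, n_mol,
    jump_p,         # (n_sp, n_st) per-direction jump prob
    allowed,        # (n_sp, n_st) bool
    pn, ps,         # (n_sp,)
    ch_kind,        # (n_ch,) 0 uni, 1 bi, 2 pseudo(reservoir partner)
    ch_r1,          # (n_ch, 2) [species, partner species (bi/pseudo) or -1]
    ch_prod,        # (n_ch, 3) product species or -1
    ch_rate,        # (n_ch,) uni: k ; bi: k/(NA lam^3); pseudo: k (M-1 s-1)
    ch_allowed,     # (n_ch, n_st) bool
    is_res,         # (n_sp,) bool
    res_of,         # (n_sp,) reservoir index or -1
    res_count,      # (n_res,) int64
    res_inv_navol,  # (n_res,) 1/(NA * V_liters)
    tau, n_steps, rec_every, seed,
):  # pragma: no cover - executed via numba
    np.random.seed(seed)
    n_sp = allowed.shape[0]
    n_ch = ch_kind.shape[0]
    plane = n1 * n2
    cap = max(n_mol * 4 + 1024, 4096)
    P = np.empty(cap, dtype=np.int64)
    Sp = np.empty(cap, dtype=np.int16)
    X = np.empty(cap, dtype=np.int32)
    Y = np.empty(cap, dtype=np.int32)
    Z = np.empty(cap, dtype=np.int32)
    for i in range(n_mol):
        P[i] = pos[i]
        Sp[i] = spc[i]
        X[i] = np.int32(pos[i] // plane)
        Y[i] = np.int32((pos[i] // n2) % n1)
        Z[i] = np.int32(pos[i] % n2)
    nm = n_mol

    n_rec = n_steps // rec_every + 1
    rec = np.zeros((n_rec, _N_ST, n_sp), dtype=np.int64)
    rec_res = np.zeros((n_rec, res_count.shape[0]), dtype=np.int64)
    tallies = np.zeros(n_ch, dtype=np.int64)

    h_tot = np.zeros((n_sp, _N_ST))
    _recompute_h(h_tot, ch_kind, ch_r1, ch_rate, ch_allowed, res_of, res_count,
                 res_inv_navol)
    res_dirty = False

    cnt = np.zeros(n_sp, dtype=np.int64)
    cnt0 = np.zeros(n_sp, dtype=np.int64)
    ach = np.zeros(n_ch)
    # linked-list bucketing of molecules by subvolume (built during the
    # diffusion pass, consumed by the reaction pass; O(n) per step)
    head = np.full(sites.shape[0], -1, dtype=np.int32)
    nxt = np.empty(cap, dtype=np.int32)
    gbuf = np.empty(cap, dtype=np.int64)

    for i in range(nm):
        if Sp[i] >= 0:
            rec[0, sites[P[i]], Sp[i]] += 1
    for r in range(res_count.shape[0]):
        rec_res[0, r] = res_count[r]

    for step in range(1, n_steps + 1):
        if res_dirty:
            _recompute_h(h_tot, ch_kind, ch_r1, ch_rate, ch_allowed, res_of,
                         res_count, res_inv_navol)
            res_dirty = False
        # ---- diffusion (and site-bucket insertion) ---------------------
        for i in range(nm):
            s = Sp[i]
            if s < 0:
                continue
            p0 = P[i]
            st = sites[p0]
            pj = jump_p[s, st]
            if pj > 0.0:
                u = np.random.random()
                if u < 6.0 * pj:
                    d = int(u / pj)
                    if d > 5:
                        d = 5
                    npos = np.int64(-1)
                    if d == 0:
                        if X[i] > 0:
                            npos = p0 - plane
                    elif d == 1:
                        if X[i] < n0 - 1:
                            npos = p0 + plane
                    elif d == 2:
                        if Y[i] > 0:
                            npos = p0 - n2
                    elif d == 3:
                        if Y[i] < n1 - 1:
                            npos = p0 + n2
                    elif d == 4:
                        if Z[i] > 0:
                            npos = p0 - 1
                    else:
                        if Z[i] < n2 - 1:
                            npos = p0 + 1
                    if npos >= 0:
                        nst = sites[npos]
                        if allowed[s, nst]:
                            if st == _NUCLEO and nst == _SPECKLE:
                                acc = pn[s]
                            elif st == _SPECKLE and nst == _NUCLEO:
                                acc = ps[s]
                            else:
                                acc = 1.0
                            if acc >= 1.0 or np.random.random() < acc:
                                P[i] = npos
                                if d == 0:
                                    X[i] -= 1
                                elif d == 1:
                                    X[i] += 1
                                elif d == 2:
                                    Y[i] -= 1
                                elif d == 3:
                                    Y[i] += 1
                                elif d == 4:
                                    Z[i] -= 1
                                else:
                                    Z[i] += 1
            nxt[i] = head[P[i]]
            head[P[i]] = np.int32(i)

        # ---- reactions -------------------------------------------------
        nmo = nm  # appends during this phase react from the next step on
        for i0 in range(nmo):
            site = P[i0]
            j = head[site]
            if j < 0:
                continue
            head[site] = -1  # consume this subvolume's chain
            group = 0
            while j >= 0:
                gbuf[group] = j
                group += 1
                j = nxt[j]
            st = sites[site]
            if res_dirty:
                _recompute_h(h_tot, ch_kind, ch_r1, ch_rate, ch_allowed,
                             res_of, res_count, res_inv_navol)
                res_dirty = False
            if group == 1:
                # single molecule: only first-order-type channels
                ia = gbuf[0]
                s = Sp[ia]
                h = h_tot[s, st]
                tloc = 0.0
                while h > 0.0:
                    tloc -= np.log(np.random.random()) / h
                    if tloc >= tau:
                        break
                    # pick channel
                    u = np.random.random() * h
                    acc = 0.0
                    chosen = -1
                    for c in range(n_ch):
                        if not ch_allowed[c, st] or ch_r1[c, 0] != s:
                            continue
                        if ch_kind[c] == 0:
                            acc += ch_rate[c]
                        elif ch_kind[c] == 2:
                            r = res_of[ch_r1[c, 1]]
                            acc += ch_rate[c] * res_count[r] * res_inv_navol[r]
                        else:
                            continue
                        if u <= acc:
                            chosen = c
                            break
                    if chosen < 0:
                        break
                    if ch_kind[chosen] == 2:
                        r = res_of[ch_r1[chosen, 1]]
                        res_count[r] -= 1
                        res_dirty = True
                    tallies[chosen] += 1
                    # apply products; molecule becomes first tracked product
                    newsp = np.int16(-1)
                    for k in range(3):
                        pr = ch_prod[chosen, k]
                        if pr < 0:
                            continue
                        if is_res[pr]:
                            res_count[res_of[pr]] += 1
                            res_dirty = True
                        elif newsp < 0:
                            newsp = np.int16(pr)
                        else:
                            if nm >= cap:
                                cap2 = cap * 2
                                P2 = np.empty(cap2, dtype=np.int64)
                                S2 = np.empty(cap2, dtype=np.int16)
                                X2 = np.empty(cap2, dtype=np.int32)
                                Y2 = np.empty(cap2, dtype=np.int32)
                                Z2 = np.empty(cap2, dtype=np.int32)
                                N2 = np.empty(cap2, dtype=np.int32)
                                G2 = np.empty(cap2, dtype=np.int64)
                                P2[:nm] = P[:nm]
                                S2[:nm] = Sp[:nm]
                                X2[:nm] = X[:nm]
                                Y2[:nm] = Y[:nm]
                                Z2[:nm] = Z[:nm]
                                N2[:nm] = nxt[:nm]
                                G2[:group] = gbuf[:group]
                                P, Sp, X, Y, Z = P2, S2, X2, Y2, Z2
                                nxt, gbuf, cap = N2, G2, cap2
                            P[nm] = site
                            Sp[nm] = np.int16(pr)
                            X[nm] = X[ia]
                            Y[nm] = Y[ia]
                            Z[nm] = Z[ia]
                            nm += 1
                    Sp[ia] = newsp
                    s = newsp
                    if s < 0:
                        break
                    if res_dirty:
                        _recompute_h(h_tot, ch_kind, ch_r1, ch_rate,
                                     ch_allowed, res_of, res_count,
                                     res_inv_navol)
                        res_dirty = False
                    h = h_tot[s, st]
            else:
                # several molecules share the subvolume: local SSA
                for q in range(n_sp):
                    cnt[q] = 0
                for q in range(group):
                    cnt[Sp[gbuf[q]]] += 1
                for q in range(n_sp):
                    cnt0[q] = cnt[q]
                tloc = 0.0
                while True:
                    a0 = 0.0
                    for c in range(n_ch):
                        if not ch_allowed[c, st]:
                            ach[c] = 0.0
                            continue
                        s1 = ch_r1[c, 0]
                        if ch_kind[c] == 0:
                            av = ch_rate[c] * cnt[s1]
                        elif ch_kind[c] == 1:
                            s2 = ch_r1[c, 1]
                            if s1 == s2:
                                av = ch_rate[c] * cnt[s1] * (cnt[s1] - 1) * 0.5
                            else:
                                av = ch_rate[c] * cnt[s1] * cnt[s2]
                        else:
                            r = res_of[ch_r1[c, 1]]
                            av = (ch_rate[c] * res_count[r]
                                  * res_inv_navol[r] * cnt[s1])
                        ach[c] = av
                        a0 += av
                    if a0 <= 0.0:
                        break
                    tloc -= np.log(np.random.random()) / a0
                    if tloc >= tau:
                        break
                    u = np.random.random() * a0
                    acc = 0.0
                    chosen = n_ch - 1
                    for c in range(n_ch):
                        acc += ach[c]
                        if u <= acc:
                            chosen = c
                            break
                    tallies[chosen] += 1
                    cnt[ch_r1[chosen, 0]] -= 1
                    if ch_kind[chosen] == 1:
                        cnt[ch_r1[chosen, 1]] -= 1
                    elif ch_kind[chosen] == 2:
                        res_count[res_of[ch_r1[chosen, 1]]] -= 1
                        res_dirty = True
                    for k in range(3):
                        pr = ch_prod[chosen, k]
                        if pr < 0:
                            continue
                        if is_res[pr]:
                            res_count[res_of[pr]] += 1
                            res_dirty = True
                        else:
                            cnt[pr] += 1
                # reconcile group molecules with final counts
                i_ref = gbuf[0]
                for q in range(n_sp):
                    diff = cnt[q] - cnt0[q]
                    if diff < 0:
                        removed = 0
                        for w in range(group):
                            iw = gbuf[w]
                            if Sp[iw] == q:
                                Sp[iw] = -1
                                removed += 1
                                if removed == -diff:
                                    break
                    elif diff > 0:
                        for _ in range(diff):
                            if nm >= cap:
                                cap2 = cap * 2
                                P2 = np.empty(cap2, dtype=np.int64)
                                S2 = np.empty(cap2, dtype=np.int16)
                                X2 = np.empty(cap2, dtype=np.int32)
                                Y2 = np.empty(cap2, dtype=np.int32)
                                Z2 = np.empty(cap2, dtype=np.int32)
                                N2 = np.empty(cap2, dtype=np.int32)
                                G2 = np.empty(cap2, dtype=np.int64)
                                P2[:nm] = P[:nm]
                                S2[:nm] = Sp[:nm]
                                X2[:nm] = X[:nm]
                                Y2[:nm] = Y[:nm]
                                Z2[:nm] = Z[:nm]
                                N2[:nm] = nxt[:nm]
                                G2[:group] = gbuf[:group]
                                P, Sp, X, Y, Z = P2, S2, X2, Y2, Z2
                                nxt, gbuf, cap = N2, G2, cap2
                            P[nm] = site
                            Sp[nm] = np.int16(q)
                            X[nm] = X[i_ref]
                            Y[nm] = Y[i_ref]
                            Z[nm] = Z[i_ref]
                            nm += 1

        # periodically drop dead molecules and sort by position so
        # neighboring molecules stay close in memory (cache locality)
        if nm > 0 and (step & 63) == 0:
            w = 0
            for i in range(nm):
                if Sp[i] >= 0:
                    P[w] = P[i]
                    Sp[w] = Sp[i]
                    X[w] = X[i]
                    Y[w] = Y[i]
                    Z[w] = Z[i]
                    w += 1
            nm = w
            if nm > 1:
                srt = np.argsort(P[:nm])
                P[:nm] = P[:nm][srt]
                Sp[:nm] = Sp[:nm][srt]
                X[:nm] = X[:nm][srt]
                Y[:nm] = Y[:nm][srt]
                Z[:nm] = Z[:nm][srt]

        if step % rec_every == 0:
            k = step // rec_every
            for i in range(nm):
                if Sp[i] >= 0:
                    rec[k, sites[P[i]], Sp[i]] += 1
            for r in range(res_count.shape[0]):
                rec_res[k, r] = res_count[r]

    # final molecule snapshot (positions + species) for diagnostics
    w = 0
    for i in range(nm):
        if Sp[i] >= 0:
            P[w] = P[i]
            Sp[w] = Sp[i]
            w += 1
    return rec, rec_res, tallies, P[:w].copy(), Sp[:w].copy()


# --------------------------------------------------------------------------
# python-side compilation and driver
# --------------------------------------------------------------------------


def _compile_network(network: ReactionNetwork, spacing_um: float):
    sp_index = network.species_index()
    n_sp = len(network.species)
    allowed = np.zeros((n_sp, _N_ST), dtype=np.bool_)
    jump_d = np.zeros((n_sp, _N_ST))
    pn = np.ones(n_sp)
    ps = np.ones(n_sp)
    is_res = np.zeros(n_sp, dtype=np.bool_)
    res_of = np.full(n_sp, -1, dtype=np.int64)
    res_names = []
    for i, s in enumerate(network.species):
        for st in s.allowed:
            allowed[i, int(st)] = True
            jump_d[i, int(st)] = s.d_at(st)
        pn[i], ps[i] = network.bias.get(s.name)
        if s.reservoir:
            res_of[i] = len(res_names)
            is_res[i] = True
            res_names.append(s.name)

    n_ch = len(network.reactions)
    ch_kind = np.zeros(n_ch, dtype=np.int8)
    ch_r1 = np.full((n_ch, 2), -1, dtype=np.int64)
    ch_prod = np.full((n_ch, 3), -1, dtype=np.int64)
    ch_rate = np.zeros(n_ch)
    ch_allowed = np.zeros((n_ch, _N_ST), dtype=np.bool_)
    for c, rx in enumerate(network.reactions):
        for st in rx.compartments:
            ch_allowed[c, int(st)] = True
        prods = [sp_index[p] for p in rx.products]
        for k, p in enumerate(prods):
            ch_prod[c, k] = p
        if rx.units == "s-1":
            ch_kind[c] = 0
            ch_r1[c, 0] = sp_index[rx.reactants[0]]
            ch_rate[c] = rx.rate
        else:
            a, b = (sp_index[rx.reactants[0]], sp_index[rx.reactants[1]])
            # put the tracked species first; a reservoir partner makes the
            # channel pseudo-first-order in the tracked reactant
            if is_res[a] and not is_res[b]:
                a, b = b, a
            if is_res[b]:
                ch_kind[c] = 2
                ch_rate[c] = rx.rate  # multiplied by pool concentration
            else:
                ch_kind[c] = 1
                ch_rate[c] = bimolecular_stochastic_rate(rx.rate, spacing_um)
            ch_r1[c, 0] = a
            ch_r1[c, 1] = b
    return (sp_index, allowed, jump_d, pn, ps, is_res, res_of, res_names,
            ch_kind, ch_r1, ch_prod, ch_rate, ch_allowed)


def max_diffusion(network: ReactionNetwork) -> float:
    d = 0.0
    for s in network.species:
        if s.reservoir:
            continue
        d = max(d, s.diffusion)
        for dv in s.diffusion_overrides.values():
            d = max(d, dv)
    return d


@dataclass
class _Placement:
    """Optional override of where a species' initial molecules go."""

    species: str
    positions: np.ndarray  # (n, 3) lattice indices


def initial_molecules(
    lattice: SiteLattice,
    network: ReactionNetwork,
    rng: np.random.Generator,
    placements: list[_Placement] | None = None,
):
    """Uniform random placement of each species' initial count over the
    sites of its initial compartment; gene species go to the lattice's
    recorded gene positions when available."""
    n = lattice.spec.n_sites_per_dim
    flat = lattice.sites.reshape(-1)
    pos_list, sp_list = [], []
    sp_index = network.species_index()
    over = {p.species: p.positions for p in (placements or [])}
    gene_pos = lattice.gene_positions
    for s in network.species:
        if s.reservoir or s.initial <= 0:
            continue
        si = sp_index[s.name]
        if s.name in over:
            idx3 = over[s.name]
            fl = idx3[:, 0] * n * n + idx3[:, 1] * n + idx3[:, 2]
            if fl.shape[0] != s.initial:
                fl = fl[rng.integers(0, fl.shape[0], size=s.initial)]
        elif s.name == "geneD" and gene_pos.shape[0] > 0:
            fl = (gene_pos[:, 0] * n * n + gene_pos[:, 1] * n + gene_pos[:, 2])
            fl = fl[np.arange(s.initial) % fl.shape[0]]
        else:
            st = s.initial_compartment
            cand = np.flatnonzero(flat == int(st))
            if cand.size == 0:
                raise ValueError(
                    f"no {st.name} sites to host initial {s.name}"
                )
            fl = cand[rng.integers(0, cand.size, size=s.initial)]
        pos_list.append(fl.astype(np.int64))
        sp_list.append(np.full(fl.shape[0], si, dtype=np.int16))
    if pos_list:
        return np.concatenate(pos_list), np.concatenate(sp_list)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int16)


def run(
    lattice: SiteLattice,
    network: ReactionNetwork,
    config: RunConfig,
    placements: list[_Placement] | None = None,
    reservoir_volumes: dict | None = None,
) -> Trajectory:
    """Advance the RDME and record per-site-type counts.

    ``reservoir_volumes`` maps reservoir species name -> compartment
    volume in um^3 (defaults to the lattice volume of the species'
    initial site type).
    """
    lam = lattice.spec.spacing
    (sp_index, allowed, jump_d, pn, ps, is_res, res_of, res_names,
     ch_kind, ch_r1, ch_prod, ch_rate, ch_allowed) = _compile_network(network, lam)

    d_max = max_diffusion(network)
    tau = config.tau if config.tau is not None else compute_timestep(lam, d_max)
    if d_max > 0 and tau > compute_timestep(lam, d_max) * (1 + 1e-9):
        raise ValueError(
            f"tau={tau} exceeds lambda^2/(6 D_max)={compute_timestep(lam, d_max):.3g}"
        )
    jump_p = jump_d * tau / lam**2

    duration = config.duration
    n_steps = max(int(round(duration / tau)), 0)
    rec_dt = config.record_interval or (duration if duration > 0 else tau)
    rec_every = max(int(round(rec_dt / tau)), 1)
    if n_steps > 0:
        n_steps = (n_steps // rec_every) * rec_every

    ss = np.random.SeedSequence([config.seed, config.replicate_id])
    rng = np.random.default_rng(ss)
    kseed = int(ss.generate_state(2)[1] & 0x7FFFFFFF)

    pos, spc = initial_molecules(lattice, network, rng, placements)

    res_count = np.zeros(len(res_names), dtype=np.int64)
    res_inv = np.zeros(len(res_names))
    for s in network.species:
        if not s.reservoir:
            continue
        r = res_of[sp_index[s.name]]
        res_count[r] = s.initial
        if reservoir_volumes and s.name in reservoir_volumes:
            vol = reservoir_volumes[s.name]
        else:
            vol = lattice.volume_of(s.initial_compartment)
        res_inv[r] = 1.0 / (C.AVOGADRO * vol * 1e-15)

    sites_flat = np.ascontiguousarray(lattice.sites.reshape(-1))
    n = lattice.spec.n_sites_per_dim
    if n_steps == 0:
        rec = np.zeros((1, _N_ST, len(network.species)), dtype=np.int64)
        for p, s in zip(pos, spc):
            rec[0, sites_flat[p], s] += 1
        rec_res = res_count[None, :].copy()
        tallies = np.zeros(len(ch_kind), dtype=np.int64)
        final_pos, final_spc = pos, spc
        times = np.array([0.0])
    else:
        rec, rec_res, tallies, final_pos, final_spc = _rdme_kernel(
            sites_flat, n, n, n, pos, spc, pos.shape[0],
            jump_p, allowed, pn, ps,
            ch_kind, ch_r1, ch_prod, ch_rate, ch_allowed,
            is_res, res_of, res_count, res_inv,
            float(tau), n_steps, rec_every, kseed,
        )
        times = np.arange(rec.shape[0]) * rec_every * tau

    # fold reservoir pools into their home compartment's records
    counts = rec.copy()
    for s in network.species:
        if s.reservoir:
            r = res_of[sp_index[s.name]]
            counts[:, int(s.initial_compartment), sp_index[s.name]] = rec_res[:, r]

    return Trajectory(
        times=times,
        counts=counts,
        compartment_names=[st.name.lower() for st in SiteType],
        species_names=[s.name for s in network.species],
        tallies=tallies,
        channel_names=[r.name for r in network.reactions],
        metadata={
            "engine": "rdme",
            "tau": tau,
            "spacing_um": lam,
            "seed": config.seed,
            "replicate_id": config.replicate_id,
            "duration": duration,
            "final_positions": final_pos,
            "final_species": final_spc,
            "species_index": sp_index,
        },
    )
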