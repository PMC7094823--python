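"""Voxelized whole-cell geometry builder.

A HeLa-scale cell is assembled on a cubic lattice of site types by
stenciling geometric primitives in depth order ("painter's algorithm":
later shapes overwrite earlier ones).  Each lattice site carries exactly
one of 11 site-type codes which later control species permeability and
where reactions may fire.

Site centers sit at ``(i + 0.5) * spacing`` so a site belongs to a shape
iff its center does.  The default lattice is an 18.432 um box at 64 nm
spacing (288 sites per dimension); a 3000 um^3 cell (radius 8.9 um) with
a nucleus of radius 3.7-5.3 um fits inside with room to spare.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage


class SiteType(IntEnum):
    """The 11 site-type codes; every lattice site carries exactly one."""

    EXTRACELLULAR = 0
    PLASMA_MEMBRANE = 1
    CYTOPLASM = 2
    NUCLEAR_MEMBRANE = 3
    NUCLEOPLASM = 4
    CAJAL = 5
    SPECKLE = 6
    NPC = 7
    MITOCHONDRIA = 8
    GOLGI = 9
    ER = 10


N_SITE_TYPES = len(SiteType)

#: site types that make up the nuclear interior
NUCLEAR_TYPES = (SiteType.NUCLEOPLASM, SiteType.CAJAL, SiteType.SPECKLE)
#: site types organelles may be painted over
_CYTO = SiteType.CYTOPLASM


@dataclass(frozen=True)
class LatticeSpec:
    """Cubic lattice dimensions: box edge length and site spacing (um)."""

    edge_length: float = 18.432
    spacing: float = 0.064

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.edge_length <= 0:
            raise ValueError("edge_length and spacing must be positive")

    @property
    def n_sites_per_dim(self) -> int:
        return int(round(self.edge_length / self.spacing))

    @property
    def site_volume(self) -> float:
        """Volume of one subvolume in um^3."""
        return self.spacing**3


@dataclass
class GeometryConfig:
    """All knobs of the cell builder (lengths in um)."""

    edge_length: float = 18.432
    spacing: float = 0.064
    cell_radius: float = 8.9
    nuclear_radius: float = 4.2
    membrane_thickness: float = 0.128
    npc_density: float = 7.0          # pores per um^2 of nuclear envelope
    npc_radius: float = 0.08
    n_speckles: int = 20
    speckle_radius: float = 0.35
    speckle_total_fraction: float | None = None  # of nuclear volume; overrides radius
    n_cajal: int = 4
    cajal_radius: float = 0.5
    n_mitochondria: int = 2000
    mito_length: float = 0.9          # total spherocylinder length
    mito_diameter: float = 0.5
    mito_mode: str = "discrete"       # "discrete" | "network"
    mito_network_rod_length: float = 2.95
    er_fraction: float = 0.045        # of total intracellular volume
    golgi_sheets: int = 5
    golgi_sheet_thickness: float = 0.128
    n_genes: int = 20
    gene_distance: float = 0.0        # distance d from speckle surface
    gene_shell_width: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nuclear_radius >= self.cell_radius:
            raise ValueError("nucleus must fit inside the cell")
        if self.cell_radius * 2 > self.edge_length:
            raise ValueError("cell does not fit in the simulation box")
        if min(self.cell_radius, self.nuclear_radius, self.membrane_thickness) <= 0:
            raise ValueError("radii and thicknesses must be positive")
        if self.er_fraction < 0 or self.npc_density < 0:
            raise ValueError("fractions and densities must be non-negative")

    @property
    def speckle_radius_effective(self) -> float:
        if self.speckle_total_fraction is None:
            return self.speckle_radius
        return speckle_radius_for_fraction(
            self.n_speckles, self.speckle_total_fraction, self.nuclear_radius
        )


def speckle_radius_for_fraction(n: int, fraction: float, nuclear_radius: float) -> float:
    """Per-speckle radius so n equal spheres fill ``fraction`` of the nucleus."""
    if n <= 0 or fraction <= 0:
        raise ValueError("need n > 0 and fraction > 0")
    v_nuc = 4.0 / 3.0 * math.pi * nuclear_radius**3
    return (3.0 * fraction * v_nuc / (4.0 * math.pi * n)) ** (1.0 / 3.0)


# --------------------------------------------------------------------------
# geometric primitives
# --------------------------------------------------------------------------


class Primitive:
    """A solid region; subclasses implement a vectorized inclusion test."""

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:  # (lo, hi) in um
        raise NotImplementedError

    def contains(self, x, y, z):
        raise NotImplementedError


@dataclass(frozen=True)
class Sphere(Primitive):
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("negative sphere radius")

    def bounds(self):
        c = np.asarray(self.center)
        return c - self.radius, c + self.radius

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2


@dataclass(frozen=True)
class SphericalShell(Primitive):
    """Closed shell: inner_radius < |r| <= outer_radius."""

    center: tuple[float, float, float]
    inner_radius: float
    outer_radius: float

    def __post_init__(self):
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")

    def bounds(self):
        c = np.asarray(self.center)
        return c - self.outer_radius, c + self.outer_radius

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return (r2 > self.inner_radius**2) & (r2 <= self.outer_radius**2)


@dataclass(frozen=True)
class Spherocylinder(Primitive):
    """Capsule: all points within ``radius`` of the segment p1-p2."""

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("non-positive capsule radius")

    def bounds(self):
        a, b = np.asarray(self.p1), np.asarray(self.p2)
        return np.minimum(a, b) - self.radius, np.maximum(a, b) + self.radius

    def contains(self, x, y, z):
        a = np.asarray(self.p1)
        d = np.asarray(self.p2) - a
        L2 = float(d @ d)
        px, py, pz = x - a[0], y - a[1], z - a[2]
        if L2 == 0.0:
            dist2 = px**2 + py**2 + pz**2
        else:
            t = (px * d[0] + py * d[1] + pz * d[2]) / L2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
        return dist2 <= self.radius**2


@dataclass(frozen=True)
class ConeShell(Primitive):
    """Intersection of an infinite cone (apex, axis, half-angle) with a shell."""

    apex: tuple[float, float, float]
    axis: tuple[float, float, float]
    half_angle: float  # radians
    inner_radius: float
    outer_radius: float

    def __post_init__(self):
        if not 0 < self.half_angle < math.pi / 2:
            raise ValueError("half_angle must be in (0, pi/2)")
        if not 0 <= self.inner_radius < self.outer_radius:
            raise ValueError("need 0 <= inner_radius < outer_radius")

    def bounds(self):
        c = np.asarray(self.apex)
        return c - self.outer_radius, c + self.outer_radius

    def contains(self, x, y, z):
        a = np.asarray(self.apex)
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        px, py, pz = x - a[0], y - a[1], z - a[2]
        r2 = px**2 + py**2 + pz**2
        proj = px * u[0] + py * u[1] + pz * u[2]
        in_shell = (r2 > self.inner_radius**2) & (r2 <= self.outer_radius**2)
        # cos(angle) >= cos(half_angle)  <=>  proj >= |r| cos(half_angle)
        return in_shell & (proj >= np.sqrt(r2) * math.cos(self.half_angle))


# --------------------------------------------------------------------------
# the lattice
# --------------------------------------------------------------------------


@dataclass
class SiteLattice:
    """3-D grid of site-type codes plus bookkeeping of what was placed."""

    spec: LatticeSpec
    sites: np.ndarray  # uint8, shape (n, n, n)
    placed_objects: list = field(default_factory=list)
    gene_positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.int64)
    )
    #: continuous gene coordinates (um), one per gene_positions row
    gene_coords: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=float)
    )
    seed: int = 0
    config: GeometryConfig | None = None
    npc_count: int = 0

    @classmethod
    def empty(cls, spec: LatticeSpec | None = None, seed: int = 0) -> "SiteLattice":
        spec = spec or LatticeSpec()
        n = spec.n_sites_per_dim
        return cls(spec=spec, sites=np.zeros((n, n, n), dtype=np.uint8), seed=seed)

    @property
    def center(self) -> np.ndarray:
        return np.full(3, self.spec.edge_length / 2.0)

    def site_centers_axis(self) -> np.ndarray:
        n = self.spec.n_sites_per_dim
        return (np.arange(n) + 0.5) * self.spec.spacing

    def index_of(self, point) -> tuple[int, int, int]:
        idx = np.floor(np.asarray(point) / self.spec.spacing).astype(int)
        n = self.spec.n_sites_per_dim
        if np.any(idx < 0) or np.any(idx >= n):
            raise ValueError(f"point {point} outside the box")
        return tuple(idx)

    def count(self, site_type: SiteType) -> int:
        return int(np.count_nonzero(self.sites == int(site_type)))

    def volume_of(self, site_type: SiteType) -> float:
        return self.count(site_type) * self.spec.site_volume


def stencil_primitive(
    lattice: SiteLattice,
    shape: Primitive,
    site_type: SiteType,
    only_replace: tuple[SiteType, ...] | None = None,
) -> SiteLattice:
    """Paint ``shape`` onto the lattice (in place); later calls win.

    A site is painted iff its center lies inside the shape.  With
    ``only_replace`` the overwrite is restricted to the listed codes.
    Returns the lattice for chaining; also records the placed object.
    """
    lam = lattice.spec.spacing
    n = lattice.spec.n_sites_per_dim
    lo, hi = shape.bounds()
    i0 = np.maximum(np.floor(lo / lam - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / lam - 0.5).astype(int) + 1, n)
    if np.any(i0 >= i1):
        lattice.placed_objects.append((type(shape).__name__, shape, site_type))
        return lattice
    ax = (np.arange(i0[0], i1[0]) + 0.5) * lam
    ay = (np.arange(i0[1], i1[1]) + 0.5) * lam
    az = (np.arange(i0[2], i1[2]) + 0.5) * lam
    mask = shape.contains(
        ax[:, None, None], ay[None, :, None], az[None, None, :]
    )
    sub = lattice.sites[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
    if only_replace is not None:
        repl = np.isin(sub, [int(t) for t in only_replace])
        mask = mask & repl
    sub[mask] = int(site_type)
    lattice.placed_objects.append((type(shape).__name__, shape, site_type))
    return lattice


def volume_fraction(lattice: SiteLattice, site_type: SiteType) -> float:
    """Fraction of the intracellular volume (everything inside and
    including the plasma membrane) occupied by ``site_type``."""
    site_type = SiteType(site_type)  # raises on unknown code
    intracellular = int(np.count_nonzero(lattice.sites != int(SiteType.EXTRACELLULAR)))
    if intracellular == 0:
        raise ValueError("lattice has no intracellular sites")
    return lattice.count(site_type) / intracellular


# --------------------------------------------------------------------------
# builder operations
# --------------------------------------------------------------------------


def build_membranes(
    lattice: SiteLattice,
    cell_radius: float,
    nuclear_radius: float,
    thickness: float,
) -> SiteLattice:
    """Cell body plus closed plasma / nuclear membrane shells.

    Paints the cytoplasm sphere, a plasma-membrane shell occupying the
    outermost ``thickness`` of the cell, the nuclear-membrane shell
    (outer radius = nuclear_radius) and the nucleoplasm interior.
    Closure under 6-adjacency is guaranteed for thickness >= spacing:
    a single lattice step of length ``spacing`` cannot jump across a
    shell at least that thick.
    """
    lam = lattice.spec.spacing
    if thickness < lam:
        raise ValueError(
            f"membrane thickness {thickness} um < lattice spacing {lam} um: "
            "the shell would leak"
        )
    c = tuple(lattice.center)
    stencil_primitive(lattice, Sphere(c, cell_radius), SiteType.CYTOPLASM)
    stencil_primitive(
        lattice,
        SphericalShell(c, cell_radius - thickness, cell_radius),
        SiteType.PLASMA_MEMBRANE,
    )
    stencil_primitive(
        lattice,
        SphericalShell(c, nuclear_radius - thickness, nuclear_radius),
        SiteType.NUCLEAR_MEMBRANE,
    )
    stencil_primitive(
        lattice, Sphere(c, nuclear_radius - thickness), SiteType.NUCLEOPLASM
    )
    return lattice


_SIX_NEIGHBOR = ndimage.generate_binary_structure(3, 1)


def leak_adjacencies(lattice: SiteLattice) -> tuple[int, int]:
    """(plasma leaks, nuclear leaks): 6-adjacent site pairs that breach a
    membrane -- cytoplasm|extracellular, and nucleoplasm-interior|cytoplasm
    not mediated by an NPC site."""
    s = lattice.sites
    extra = s == int(SiteType.EXTRACELLULAR)
    inside = ~extra & (s != int(SiteType.PLASMA_MEMBRANE))
    plasma_leaks = int(
        np.count_nonzero(ndimage.binary_dilation(extra, _SIX_NEIGHBOR) & inside)
    )
    nuclear_interior = np.isin(s, [int(t) for t in NUCLEAR_TYPES])
    cyto_side = np.isin(
        s,
        [
            int(SiteType.CYTOPLASM),
            int(SiteType.MITOCHONDRIA),
            int(SiteType.GOLGI),
            int(SiteType.ER),
        ],
    )
    nuclear_leaks = int(
        np.count_nonzero(
            ndimage.binary_dilation(nuclear_interior, _SIX_NEIGHBOR) & cyto_side
        )
    )
    return plasma_leaks, nuclear_leaks


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral layout)."""
    if n <= 0:
        return np.empty((0, 3))
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def place_npcs(
    lattice: SiteLattice,
    density: float,
    npc_radius: float = 0.08,
    nuclear_radius: float | None = None,
    layout: str = "fibonacci",
    rng: np.random.Generator | None = None,
) -> tuple[SiteLattice, int]:
    """Embed nuclear-pore spheres in the nuclear envelope.

    The pore count is ``round(density * 4 pi r_n^2)``; centers sit at
    mid-membrane on a Fibonacci-sphere layout (near-uniform coverage
    without clustering) or uniformly at random with ``layout='random'``.
    Pore spheres only replace nuclear-membrane sites, punching channels
    that connect nucleoplasm to cytoplasm.
    """
    if density < 0:
        raise ValueError("negative NPC density")
    if nuclear_radius is None:
        if lattice.config is None:
            raise ValueError("nuclear_radius required when lattice has no config")
        nuclear_radius = lattice.config.nuclear_radius
    count = int(round(density * 4.0 * math.pi * nuclear_radius**2))
    if count == 0:
        lattice.npc_count = 0
        return lattice, 0
    # center of the membrane slab
    thickness = lattice.config.membrane_thickness if lattice.config else 0.128
    r_mid = nuclear_radius - thickness / 2.0
    min_sep = 2.0 * npc_radius
    if layout == "fibonacci":
        dirs = fibonacci_sphere(count)
        approx_sep = math.sqrt(4.0 * math.pi * r_mid**2 / count)
        if approx_sep < min_sep:
            warnings.warn("NPC spheres forced to overlap; merging", stacklevel=2)
    else:
        rng = rng or np.random.default_rng(lattice.seed)
        dirs = rng.normal(size=(count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = lattice.center[None, :] + r_mid * dirs
    for ctr in centers:
        stencil_primitive(
            lattice,
            Sphere(tuple(ctr), npc_radius),
            SiteType.NPC,
            only_replace=(SiteType.NUCLEAR_MEMBRANE,),
        )
    lattice.npc_count = count
    return lattice, count


def grow_er(
    lattice: SiteLattice,
    target_fraction: float,
    seed: int | None = None,
    n_seeds: int | None = None,
    accept_p0: float = 0.6,
    accept_floor: float = 0.15,
) -> SiteLattice:
    """Stochastic cellular-automaton growth of the endoplasmic reticulum.

    Nucleation sites on the cytoplasmic face of the nuclear envelope are
    dilated iteratively into cytoplasm-only sites; each frontier site is
    converted with a probability that decays with distance from the
    envelope, producing irregular sheets that span outward toward the
    plasma membrane.  Growth stops when the ER occupies the target
    fraction of the intracellular volume (trimmed exactly on the final
    iteration, so the realized fraction is within one site of target).
    Deterministic given the seed.
    """
    if target_fraction < 0:
        raise ValueError("negative ER target fraction")
    if target_fraction == 0:
        return lattice
    rng = np.random.default_rng(lattice.seed if seed is None else seed)
    s = lattice.sites
    intracellular = int(np.count_nonzero(s != int(SiteType.EXTRACELLULAR)))
    target_count = int(round(target_fraction * intracellular))
    cyto = s == int(SiteType.CYTOPLASM)
    available = int(np.count_nonzero(cyto))
    if target_count > available:
        raise ValueError(
            f"ER target fraction {target_fraction} unreachable: only "
            f"{available / intracellular:.4f} of the cell is free cytoplasm"
        )
    if target_count == 0:
        return lattice

    # distance-from-envelope field (um) for the decaying growth probability
    cfg = lattice.config
    r_n = cfg.nuclear_radius if cfg else 4.2
    r_c = cfg.cell_radius if cfg else 8.9
    ax = lattice.site_centers_axis() - lattice.center[0]
    r_grid = np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )
    decay_len = max((r_c - r_n) / 1.5, 1e-6)
    p_accept = np.clip(
        accept_p0 * np.exp(-np.clip(r_grid - r_n, 0.0, None) / decay_len),
        accept_floor,
        accept_p0,
    )

    # Nucleation starts one site off the envelope: the first cytoplasmic
    # layer (the perinuclear cleft and the pore exit sites) stays clear so
    # the ER cannot seal the nuclear pores.  The seed count is a physical
    # quantity (ER exit-site patches per envelope area, ~0.9/um^2),
    # independent of the lattice resolution, so the grown morphology is
    # comparable across spacings.
    envelope = s == int(SiteType.NUCLEAR_MEMBRANE)
    cleft = ndimage.binary_dilation(envelope, _SIX_NEIGHBOR) & cyto
    cyto = cyto & ~cleft
    frontier0 = ndimage.binary_dilation(cleft, _SIX_NEIGHBOR) & cyto
    cand_idx = np.flatnonzero(frontier0.ravel())
    if n_seeds is None:
        n_seeds = max(8, int(round(0.9 * 4.0 * math.pi * r_n**2)))
    n_seeds = min(n_seeds, cand_idx.size, target_count)
    if n_seeds == 0:
        raise ValueError("no cytoplasm adjacent to the nuclear envelope to seed ER")
    er = np.zeros_like(cyto)
    seeds = rng.choice(cand_idx, size=n_seeds, replace=False)
    er.ravel()[seeds] = True
    grown = n_seeds

    while grown < target_count:
        frontier = ndimage.binary_dilation(er, _SIX_NEIGHBOR) & cyto & ~er
        fi = np.flatnonzero(frontier.ravel())
        if fi.size == 0:
            raise ValueError(
                f"ER growth stalled at fraction {grown / intracellular:.4f}"
            )
        accept = rng.random(fi.size) < p_accept.ravel()[fi]
        chosen = fi[accept]
        if chosen.size == 0:
            continue
        if grown + chosen.size > target_count:
            chosen = rng.choice(chosen, size=target_count - grown, replace=False)
        er.ravel()[chosen] = True
        grown += chosen.size

    s[er] = int(SiteType.ER)
    lattice.placed_objects.append(("ERAutomaton", target_fraction, SiteType.ER))
    return lattice


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def place_mitochondria(
    lattice: SiteLattice,
    n: int,
    length: float = 0.9,
    diameter: float = 0.5,
    mode: str = "discrete",
    network_rod_length: float = 2.95,
    seed: int | None = None,
    max_retries: int = 400,
) -> SiteLattice:
    """Place mitochondria in the cytoplasm.

    ``discrete``: n non-overlapping spherocylinders of total length
    ``length`` and diameter ``diameter`` at uniform random positions and
    orientations.  ``network``: long rods (default 2.95 um) that may
    cross each other, added until the total mitochondrial volume matches
    the discrete-mode total within 2%.
    """
    if mode not in ("discrete", "network"):
        raise ValueError(f"unknown mitochondria mode {mode!r}")
    if n <= 0:
        return lattice
    rng = np.random.default_rng(lattice.seed + 17 if seed is None else seed)
    cfg = lattice.config
    r_n = cfg.nuclear_radius if cfg else 4.2
    r_c = cfg.cell_radius if cfg else 8.9
    thick = cfg.membrane_thickness if cfg else 0.128
    radius = diameter / 2.0
    vol_each = (
        math.pi * radius**2 * (length - diameter) + 4.0 / 3.0 * math.pi * radius**3
    )
    target_voxels = int(round(n * vol_each / lattice.spec.site_volume))
    center = lattice.center

    def sample_capsule(seg_len: float) -> Spherocylinder:
        # uniform position in the cytoplasmic annulus, uniform orientation
        while True:
            p = rng.uniform(-r_c, r_c, size=3)
            r = np.linalg.norm(p)
            if r_n + radius < r < r_c - thick - radius:
                break
        u = _random_unit(rng)
        half = (seg_len - diameter) / 2.0
        a = center + p - half * u
        b = center + p + half * u
        return Spherocylinder(tuple(a), tuple(b), radius)

    def paint_if_fits(shape: Spherocylinder, allow_overlap: bool) -> int:
        lam = lattice.spec.spacing
        nn = lattice.spec.n_sites_per_dim
        lo, hi = shape.bounds()
        i0 = np.maximum(np.floor(lo / lam - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / lam - 0.5).astype(int) + 1, nn)
        axx = (np.arange(i0[0], i1[0]) + 0.5) * lam
        ayy = (np.arange(i0[1], i1[1]) + 0.5) * lam
        azz = (np.arange(i0[2], i1[2]) + 0.5) * lam
        mask = shape.contains(
            axx[:, None, None], ayy[None, :, None], azz[None, None, :]
        )
        sub = lattice.sites[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
        if allow_overlap:
            ok = mask & (
                (sub == int(SiteType.CYTOPLASM)) | (sub == int(SiteType.MITOCHONDRIA))
            )
            if not np.array_equal(ok, mask):
                return -1  # clipped by a membrane / another organelle
            newly = mask & (sub == int(SiteType.CYTOPLASM))
            sub[mask] = int(SiteType.MITOCHONDRIA)
            return int(np.count_nonzero(newly))
        if not np.all(sub[mask] == int(SiteType.CYTOPLASM)):
            return -1
        sub[mask] = int(SiteType.MITOCHONDRIA)
        return int(np.count_nonzero(mask))

    if mode == "discrete":
        placed = 0
        for _ in range(n):
            for attempt in range(max_retries):
                if paint_if_fits(sample_capsule(length), allow_overlap=False) >= 0:
                    placed += 1
                    break
            else:
                raise ValueError(
                    f"could not place mitochondrion {placed + 1}/{n} "
                    f"without overlap after {max_retries} retries"
                )
        lattice.placed_objects.append(("MitochondriaDiscrete", n, SiteType.MITOCHONDRIA))
    else:
        total = 0
        rods = 0
        attempts = 0
        while total < target_voxels:
            got = paint_if_fits(sample_capsule(network_rod_length), allow_overlap=True)
            attempts += 1
            if got >= 0:
                total += got
                rods += 1
            if attempts > max_retries * max(n, 1):
                raise ValueError("mitochondrial network placement stalled")
        lattice.placed_objects.append(
            ("MitochondriaNetwork", rods, SiteType.MITOCHONDRIA)
        )
    return lattice


def _place_nuclear_spheres(
    lattice: SiteLattice,
    n: int,
    radius: float,
    site_type: SiteType,
    rng: np.random.Generator,
    existing: list[tuple[np.ndarray, float]],
    max_retries: int = 2000,
) -> list[tuple[np.ndarray, float]]:
    cfg = lattice.config
    r_n = cfg.nuclear_radius if cfg else 4.2
    thick = cfg.membrane_thickness if cfg else 0.128
    r_max = r_n - thick - radius - lattice.spec.spacing
    if r_max <= 0:
        raise ValueError(f"{site_type.name} spheres of radius {radius} do not fit")
    placed: list[tuple[np.ndarray, float]] = []
    gap = lattice.spec.spacing
    for _ in range(n):
        for attempt in range(max_retries):
            p = rng.uniform(-r_max, r_max, size=3)
            if np.linalg.norm(p) > r_max:
                continue
            ctr = lattice.center + p
            if all(
                np.linalg.norm(ctr - c0) >= radius + r0 + gap
                for c0, r0 in existing + placed
            ):
                placed.append((ctr, radius))
                break
        else:
            raise ValueError(
                f"could not pack {n} {site_type.name} spheres of radius "
                f"{radius} in the nucleus (placed {len(placed)})"
            )
    for ctr, r in placed:
        stencil_primitive(lattice, Sphere(tuple(ctr), r), site_type)
    return placed


def place_speckles(
    lattice: SiteLattice,
    n: int,
    radius: float | None = None,
    total_fraction: float | None = None,
    seed: int | None = None,
) -> SiteLattice:
    """n non-overlapping speckle spheres uniformly placed in the nucleus.

    If ``total_fraction`` is given the per-speckle radius is
    ``(3 f V_nucleus / (4 pi n))^(1/3)`` so the summed speckle volume is
    a fixed fraction of the nuclear volume regardless of n.
    """
    if n <= 0:
        return lattice
    cfg = lattice.config
    r_nuc = cfg.nuclear_radius if cfg else 4.2
    if total_fraction is not None:
        radius = speckle_radius_for_fraction(n, total_fraction, r_nuc)
    if radius is None:
        raise ValueError("need radius or total_fraction")
    rng = np.random.default_rng(lattice.seed + 29 if seed is None else seed)
    existing = [
        (np.asarray(obj.center), obj.radius)
        for kind, obj, st in lattice.placed_objects
        if kind == "Sphere" and st == SiteType.CAJAL
    ]
    _place_nuclear_spheres(lattice, n, radius, SiteType.SPECKLE, rng, existing)
    return lattice


def place_genes(
    lattice: SiteLattice,
    n_genes: int,
    distance: float = 0.0,
    shell_width: float = 0.02,
    seed: int | None = None,
    max_retries: int = 5000,
) -> SiteLattice:
    """Pin active-gene sites in a thin shell around the speckle surfaces.

    Each gene is assigned round-robin to a speckle and placed at a
    continuous distance in [d, d + shell_width] from that speckle's
    surface; its lattice site must be nucleoplasm.  d=0 with the default
    0.02 um shell reproduces the canonical "genes hug the speckle
    periphery" arrangement.
    """
    if n_genes <= 0:
        return lattice
    if distance < 0:
        raise ValueError("negative gene distance")
    speckles = [
        (np.asarray(obj.center), obj.radius)
        for kind, obj, st in lattice.placed_objects
        if kind == "Sphere" and st == SiteType.SPECKLE
    ]
    if not speckles:
        raise ValueError("place speckles before genes")
    rng = np.random.default_rng(lattice.seed + 41 if seed is None else seed)
    lam = lattice.spec.spacing
    positions = []
    coords = []
    for g in range(n_genes):
        ctr, r_s = speckles[g % len(speckles)]
        for attempt in range(max_retries):
            u = _random_unit(rng)
            rr = r_s + distance + rng.uniform(0.0, shell_width)
            p = ctr + rr * u
            try:
                idx = lattice.index_of(p)
            except ValueError:
                continue
            if lattice.sites[idx] != int(SiteType.NUCLEOPLASM):
                continue
            # realized distance to the nearest speckle surface
            d_min = min(np.linalg.norm(p - c0) - r0 for c0, r0 in speckles)
            if d_min < distance - 1e-9 or d_min > distance + shell_width + lam:
                continue
            positions.append(idx)
            coords.append(p)
            break
        else:
            raise ValueError(
                f"no nucleoplasm site at distance {distance}-"
                f"{distance + shell_width} um from speckle {g % len(speckles)}"
            )
    lattice.gene_positions = np.asarray(positions, dtype=np.int64)
    lattice.gene_coords = np.asarray(coords, dtype=float)
    return lattice


def build_golgi(
    lattice: SiteLattice,
    n_sheets: int,
    sheet_thickness: float,
    half_angle: float = 0.5,
    seed: int | None = None,
) -> SiteLattice:
    """Golgi stack: a cone from the cell center intersected with
    concentric shells starting at the nuclear envelope (sheets separated
    by one sheet thickness), only replacing cytoplasm."""
    if n_sheets <= 0:
        return lattice
    cfg = lattice.config
    r_n = cfg.nuclear_radius if cfg else 4.2
    rng = np.random.default_rng(lattice.seed + 7 if seed is None else seed)
    axis = tuple(_random_unit(rng))
    for k in range(n_sheets):
        r_in = r_n + k * 2.0 * sheet_thickness
        stencil_primitive(
            lattice,
            ConeShell(tuple(lattice.center), axis, half_angle, r_in, r_in + sheet_thickness),
            SiteType.GOLGI,
            only_replace=(SiteType.CYTOPLASM,),
        )
    return lattice


def build_cell(config: GeometryConfig) -> SiteLattice:
    """Compose the full cell in depth order and return the lattice.

    Order: box (extracellular) -> cell sphere -> membranes -> nucleus
    interior -> Golgi -> mitochondria -> ER -> Cajal bodies -> speckles
    -> NPCs -> genes.  Deterministic given ``config.seed``.
    """
    spec = LatticeSpec(config.edge_length, config.spacing)
    lattice = SiteLattice.empty(spec, seed=config.seed)
    lattice.config = config
    rng = np.random.default_rng(config.seed)
    build_membranes(
        lattice, config.cell_radius, config.nuclear_radius, config.membrane_thickness
    )
    if config.golgi_sheets > 0:
        build_golgi(lattice, config.golgi_sheets, config.golgi_sheet_thickness)
    if config.n_mitochondria > 0:
        place_mitochondria(
            lattice,
            config.n_mitochondria,
            config.mito_length,
            config.mito_diameter,
            mode=config.mito_mode,
            network_rod_length=config.mito_network_rod_length,
        )
    if config.er_fraction > 0:
        grow_er(lattice, config.er_fraction)
    if config.n_cajal > 0:
        _place_nuclear_spheres(
            lattice,
            config.n_cajal,
            config.cajal_radius,
            SiteType.CAJAL,
            np.random.default_rng(config.seed + 23),
            existing=[],
        )
    if config.n_speckles > 0:
        place_speckles(
            lattice,
            config.n_speckles,
            radius=config.speckle_radius_effective,
        )
    place_npcs(lattice, config.npc_density, config.npc_radius)
    if config.n_genes > 0 and config.n_speckles > 0:
        place_genes(
            lattice, config.n_genes, config.gene_distance, config.gene_shell_width
        )
    return lattice


def construction_report(lattice: SiteLattice) -> list[dict]:
    """Per-site-type counts, volumes (um^3) and intracellular fractions."""
    rows = []
    intracellular = int(np.count_nonzero(lattice.sites != int(SiteType.EXTRACELLULAR)))
    for st in SiteType:
        cnt = lattice.count(st)
        rows.append(
            {
                "site_type": st.name.lower(),
                "site_count": cnt,
                "volume_um3": cnt * lattice.spec.site_volume,
                "fraction": (
                    cnt / intracellular if st != SiteType.EXTRACELLULAR else float("nan")
                ),
            }
        )
    return rows
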