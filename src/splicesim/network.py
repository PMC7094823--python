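"""Reaction networks for splicing-particle formation and splicing.

Species carry their permitted site types and diffusion coefficients;
reactions carry mass-action rate constants with declared units and the
site types (compartments) where they may fire.  Three network builders
cover the biology:

* ``build_particle_formation_network`` -- U1/U2 snRNP biogenesis across
  nucleus, NPCs, cytoplasm and Cajal bodies (20 reactions).
* ``build_misassembly_variant`` -- the same chemistry confined to the
  nucleus, plus irreversible misassembly channels in which the
  particle-specific proteins bind the snRNA.Sm5 intermediate before the
  Sm ring is complete.
* ``build_splicing_network`` -- step-wise spliceosome assembly
  (E -> A -> B -> B*) and intron excision in nucleoplasm and speckles,
  optionally as a co-transcriptional 8-intron chain.

Speckle partitioning is expressed as a per-species ``TransitionBias``:
boundary crossings nucleoplasm -> speckle are accepted with probability
P_n and the reverse with P_s <= P_n, which yields an equilibrium
concentration ratio c_s / c_n = P_n / P_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from . import constants as C
from .geometry import SiteType

# compartment shorthands used by the published reaction tables
N = frozenset({SiteType.NUCLEOPLASM})
P = frozenset({SiteType.NPC})
J = frozenset({SiteType.CAJAL})
S = frozenset({SiteType.SPECKLE})
CYT = frozenset({SiteType.CYTOPLASM})
JN = J | N
SN = S | N


def concentration_to_count(concentration: float, compartment_volume_um3: float) -> int:
    """Molecule count for a molar concentration in a volume given in um^3."""
    if concentration < 0 or compartment_volume_um3 < 0:
        raise ValueError("concentration and volume must be non-negative")
    return int(round(concentration * C.AVOGADRO * compartment_volume_um3 * 1e-15))


def bimolecular_stochastic_rate(k: float, spacing_um: float) -> float:
    """Per-pair propensity (s^-1) in one subvolume for a bimolecular k.

    Divides the macroscopic constant (M^-1 s^-1) by N_A * lambda^3 with
    the subvolume expressed in liters; the RDME propensity of A+B in a
    subvolume is then ``rate * n_A * n_B``.
    """
    if k < 0:
        raise ValueError("negative rate constant")
    if spacing_um <= 0:
        raise ValueError("non-positive lattice spacing")
    return k / (C.AVOGADRO * spacing_um**3 * 1e-15)


def compute_timestep(spacing_um: float, d_max: float) -> float:
    """Fixed RDME time step tau = lambda^2 / (6 D_max).

    Caps the per-direction jump probability D tau / lambda^2 at 1/6 for
    the fastest species.  Reproduces the published steps: 7.3e-5 s for
    D_max = 9.35 um^2/s and 3.3e-3 s for D_max = 0.207 um^2/s at 64 nm.
    """
    if d_max <= 0:
        raise ValueError("D_max must be positive")
    return spacing_um**2 / (6.0 * d_max)


@dataclass(frozen=True)
class Species:
    """A chemical species with permeability and mobility metadata."""

    name: str
    allowed: frozenset[SiteType]
    diffusion: float  # um^2/s (uniform over allowed site types)
    initial: int = 0
    initial_compartment: SiteType | None = None
    diffusion_overrides: dict = field(default_factory=dict)  # SiteType -> D
    reservoir: bool = False  # high-abundance pool treated as well mixed

    def d_at(self, site_type: SiteType) -> float:
        return self.diffusion_overrides.get(site_type, self.diffusion)


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction restricted to a set of site types."""

    name: str
    reactants: tuple[str, ...]  # 0, 1 or 2 species names
    products: tuple[str, ...]   # up to 3 species names
    rate: float
    units: str                  # "s-1" or "M-1s-1"
    compartments: frozenset[SiteType]

    def __post_init__(self):
        if self.units not in ("s-1", "M-1s-1"):
            raise ValueError(f"undeclared rate units {self.units!r}")
        if len(self.reactants) > 2 or len(self.products) > 3:
            raise ValueError("at most 2 reactants and 3 products")
        if (self.units == "M-1s-1") != (len(self.reactants) == 2):
            raise ValueError(
                f"{self.name}: bimolecular units require exactly two reactants"
            )
        if self.rate < 0:
            raise ValueError("negative rate")


@dataclass(frozen=True)
class TransitionBias:
    """Per-species speckle boundary-crossing acceptance probabilities.

    ``table`` maps species name -> (P_n, P_s); unbiased species default
    to (1, 1).  The invariant 0 <= P_s <= P_n <= 1 makes speckles
    attractors with equilibrium enrichment rho = P_n / P_s.
    """

    table: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (pn, ps) in self.table.items():
            if not (0.0 <= ps <= pn <= 1.0):
                raise ValueError(
                    f"{name}: need 0 <= P_s <= P_n <= 1, got P_n={pn}, P_s={ps}"
                )

    def get(self, name: str) -> tuple[float, float]:
        return self.table.get(name, (1.0, 1.0))

    @staticmethod
    def for_ratio(species_names, rho: float, p_n: float = 1.0) -> "TransitionBias":
        """Bias with P_n fixed and P_s = P_n / rho for the named species."""
        if rho < 1.0:
            raise ValueError("rho = P_n/P_s must be >= 1")
        return TransitionBias({s: (p_n, p_n / rho) for s in species_names})


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    bias: TransitionBias = field(default_factory=TransitionBias)

    def __post_init__(self):
        names = {s.name for s in self.species}
        if len(names) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for nm in (*r.reactants, *r.products):
                if nm not in names:
                    raise ValueError(f"reaction {r.name} references unknown {nm!r}")

    def species_index(self) -> dict:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_rate(self, reaction_name: str, rate: float) -> "ReactionNetwork":
        new = [
            replace(r, rate=rate) if r.name == reaction_name else r
            for r in self.reactions
        ]
        if all(r.name != reaction_name for r in self.reactions):
            raise KeyError(reaction_name)
        return ReactionNetwork(self.species, new, self.bias)


@dataclass
class FormationParams:
    """Inputs of the particle-formation network builders."""

    cytoplasm_volume_um3: float
    nucleoplasm_volume_um3: float
    n_genes_per_species: int = C.N_SNRNA_GENES_HAPLOID * C.PLOIDY
    conc_g5: float = C.CONC_G5
    conc_sm5: float = C.CONC_SM5
    conc_sm2: float = C.CONC_SM2
    conc_u1prot: float = C.CONC_U1PROT
    conc_u2prot: float = C.CONC_U2PROT
    knpc: float = C.KNPC
    k_misassembly: float = C.K_MISASSEMBLY
    reservoir_proteins: bool = False


def _protein(name, allowed, conc, vol, d=C.D_PROTEIN, reservoir=False):
    return Species(
        name,
        allowed,
        d,
        initial=concentration_to_count(conc, vol),
        initial_compartment=next(iter(allowed & {SiteType.CYTOPLASM, SiteType.NUCLEOPLASM})),
        reservoir=reservoir,
    )


def build_particle_formation_network(params: FormationParams) -> ReactionNetwork:
    """The 20-reaction multi-compartment U1/U2 snRNP formation network.

    Per snRNA species: nuclear transcription, NPC export, Gemin-5
    binding/release, RNP exchange onto the Sm pentamer, late Sm-protein
    addition/loss, NPC import, and particle-specific protein binding in
    Cajal bodies or nucleoplasm.
    """
    vc, vn = params.cytoplasm_volume_um3, params.nucleoplasm_volume_um3
    if vc <= 0 or vn <= 0:
        raise ValueError("compartment volumes must be positive")
    res = params.reservoir_proteins
    species = [
        Species("geneU1", N, 0.0, initial=params.n_genes_per_species,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("geneU2", N, 0.0, initial=params.n_genes_per_species,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("U1snRNA_nuc", N | J | P, C.D_SNRNA),
        Species("U2snRNA_nuc", N | J | P, C.D_SNRNA),
        Species("U1snRNA_cyt", CYT | P, C.D_SNRNA),
        Species("U2snRNA_cyt", CYT | P, C.D_SNRNA),
        Species("U1G5", CYT, C.D_SNRNA),
        Species("U2G5", CYT, C.D_SNRNA),
        Species("U1Sm5", CYT, C.D_SNRNA),
        Species("U2Sm5", CYT, C.D_SNRNA),
        Species("U1Sm7", CYT | P, C.D_SNRNA),
        Species("U2Sm7", CYT | P, C.D_SNRNA),
        Species("U1Sm7_nuc", N | J | P, C.D_SNRNA),
        Species("U2Sm7_nuc", N | J | P, C.D_SNRNA),
        Species("U1snRNP", N | J, C.D_SNRNP),
        Species("U2snRNP", N | J, C.D_SNRNP),
        _protein("G5", CYT, params.conc_g5, vc, reservoir=res),
        _protein("Sm5", CYT, params.conc_sm5, vc, reservoir=res),
        _protein("Sm2", CYT, params.conc_sm2, vc, reservoir=res),
        _protein("U1prot", N | J, params.conc_u1prot, vn, reservoir=res),
        _protein("U2prot", N | J, params.conc_u2prot, vn, reservoir=res),
    ]
    rx = []

    def r(name, reactants, products, rate, units, comp):
        rx.append(Reaction(name, tuple(reactants), tuple(products), rate, units, comp))

    for u, ktr, ks, konu, koffu in (
        ("U1", C.KTRANS_U1, C.KS1, C.KON_U1PROT, C.KOFF_U1PROT),
        ("U2", C.KTRANS_U2, C.KS2, C.KON_U2PROT, C.KOFF_U2PROT),
    ):
        r(f"transcribe_{u}", [f"gene{u}"], [f"gene{u}", f"{u}snRNA_nuc"], ktr, "s-1", N)
        r(f"export_{u}", [f"{u}snRNA_nuc"], [f"{u}snRNA_cyt"], params.knpc, "s-1", P)
        r(f"bindG5_{u}", [f"{u}snRNA_cyt", "G5"], [f"{u}G5"], C.KON_G, "M-1s-1", CYT)
        r(f"releaseG5_{u}", [f"{u}G5"], [f"{u}snRNA_cyt", "G5"], C.KOFF_G, "s-1", CYT)
        r(f"rnp_exchange_{u}", [f"{u}G5", "Sm5"], [f"{u}Sm5", "G5"], ks, "M-1s-1", CYT)
        r(f"addSm2_{u}", [f"{u}Sm5", "Sm2"], [f"{u}Sm7"], C.KON_SM2, "M-1s-1", CYT)
        r(f"loseSm2_{u}", [f"{u}Sm7"], [f"{u}Sm5", "Sm2"], C.KOFF_SM2, "s-1", CYT)
        r(f"import_{u}", [f"{u}Sm7"], [f"{u}Sm7_nuc"], params.knpc, "s-1", P)
        r(f"mature_{u}", [f"{u}Sm7_nuc", f"{u}prot"], [f"{u}snRNP"], konu, "M-1s-1", JN)
        r(f"unmature_{u}", [f"{u}snRNP"], [f"{u}Sm7_nuc", f"{u}prot"], koffu, "s-1", JN)
    return ReactionNetwork(species, rx)


def build_misassembly_variant(params: FormationParams) -> ReactionNetwork:
    """Nucleus-only assembly with irreversible misassembly channels.

    Every compartment restriction collapses to the nucleoplasm (no NPC
    transport, the nuc/cyt forms merge) and the particle-specific
    proteins can bind the snRNA.Sm5 intermediate prematurely:
    ``U snRNA.Sm5 + U_prot -> misassembled_U`` (terminal).  Protein
    concentrations are applied to the nuclear volume.
    """
    vn = params.nucleoplasm_volume_um3
    if vn <= 0:
        raise ValueError("nucleoplasm volume must be positive")
    species = [
        Species("geneU1", N, 0.0, initial=params.n_genes_per_species,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("geneU2", N, 0.0, initial=params.n_genes_per_species,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("U1snRNA", N, C.D_SNRNA),
        Species("U2snRNA", N, C.D_SNRNA),
        Species("U1G5", N, C.D_SNRNA),
        Species("U2G5", N, C.D_SNRNA),
        Species("U1Sm5", N, C.D_SNRNA),
        Species("U2Sm5", N, C.D_SNRNA),
        Species("U1Sm7", N, C.D_SNRNA),
        Species("U2Sm7", N, C.D_SNRNA),
        Species("U1snRNP", N, C.D_SNRNP),
        Species("U2snRNP", N, C.D_SNRNP),
        Species("misassembled_U1", N, C.D_SNRNP),
        Species("misassembled_U2", N, C.D_SNRNP),
        _protein("G5", N, params.conc_g5, vn),
        _protein("Sm5", N, params.conc_sm5, vn),
        _protein("Sm2", N, params.conc_sm2, vn),
        _protein("U1prot", N, params.conc_u1prot, vn),
        _protein("U2prot", N, params.conc_u2prot, vn),
    ]
    rx = []

    def r(name, reactants, products, rate, units):
        rx.append(Reaction(name, tuple(reactants), tuple(products), rate, units, N))

    for u, ktr, ks, konu, koffu in (
        ("U1", C.KTRANS_U1, C.KS1, C.KON_U1PROT, C.KOFF_U1PROT),
        ("U2", C.KTRANS_U2, C.KS2, C.KON_U2PROT, C.KOFF_U2PROT),
    ):
        r(f"transcribe_{u}", [f"gene{u}"], [f"gene{u}", f"{u}snRNA"], ktr, "s-1")
        r(f"bindG5_{u}", [f"{u}snRNA", "G5"], [f"{u}G5"], C.KON_G, "M-1s-1")
        r(f"releaseG5_{u}", [f"{u}G5"], [f"{u}snRNA", "G5"], C.KOFF_G, "s-1")
        r(f"rnp_exchange_{u}", [f"{u}G5", "Sm5"], [f"{u}Sm5", "G5"], ks, "M-1s-1")
        r(f"addSm2_{u}", [f"{u}Sm5", "Sm2"], [f"{u}Sm7"], C.KON_SM2, "M-1s-1")
        r(f"loseSm2_{u}", [f"{u}Sm7"], [f"{u}Sm5", "Sm2"], C.KOFF_SM2, "s-1")
        r(f"mature_{u}", [f"{u}Sm7", f"{u}prot"], [f"{u}snRNP"], konu, "M-1s-1")
        r(f"unmature_{u}", [f"{u}snRNP"], [f"{u}Sm7", f"{u}prot"], koffu, "s-1")
        r(
            f"misassemble_{u}",
            [f"{u}Sm5", f"{u}prot"],
            [f"misassembled_{u}"],
            params.k_misassembly,
            "M-1s-1",
        )
    return ReactionNetwork(species, rx)


# --------------------------------------------------------------------------
# spliceosome assembly / splicing
# --------------------------------------------------------------------------

#: gene architecture of the average transcribed gene
N_INTRONS = 8
INTRON_LENGTH_B = 3400
EXON_LENGTH_B = 137


def total_gene_length_bases(
    n_introns: int = N_INTRONS,
    intron_length: int = INTRON_LENGTH_B,
    exon_length: int = EXON_LENGTH_B,
) -> int:
    """8 introns x 3.4 kb flanked by 9 exons of 137 b -> about 28 kb."""
    return n_introns * intron_length + (n_introns + 1) * exon_length


@dataclass
class SplicingParams:
    """Inputs of the splicing network builders."""

    nucleoplasm_volume_um3: float
    n_genes: int = 20
    u1_count: int | None = None
    u2_count: int | None = None
    triu_count: int | None = None
    concentration: float | None = 1e-9  # M; used when counts not given
    ktrans: float = C.KTRANS_GENE
    kact: float = C.KACT_FIRST_ORDER
    mrna_export: bool = True
    knpc: float = C.KNPC

    def counts(self) -> tuple[int, int, int]:
        if self.u1_count is not None:
            u1 = self.u1_count
        else:
            u1 = concentration_to_count(self.concentration, self.nucleoplasm_volume_um3)
        u2 = self.u2_count if self.u2_count is not None else u1
        # tri.U is pre-formed; defaults to the free U1 pool size
        triu = self.triu_count if self.triu_count is not None else u1
        return u1, u2, triu


def _splicing_core_species(params: SplicingParams) -> list[Species]:
    u1, u2, triu = params.counts()
    if params.n_genes == 0 and (u1 or u2):
        import warnings

        warnings.warn("no genes: the splicing network will produce no mRNA",
                      stacklevel=3)
    sp = [
        Species("geneD", N, 0.0, initial=params.n_genes,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("U1", SN, C.D_SNRNP, initial=u1,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("U2", SN, C.D_SNRNP, initial=u2,
                initial_compartment=SiteType.NUCLEOPLASM),
        Species("triU", SN, C.D_SNRNP, initial=triu,
                initial_compartment=SiteType.NUCLEOPLASM),
    ]
    mrna_allowed = SN | P | CYT if params.mrna_export else SN
    sp.append(Species("mRNA", mrna_allowed, C.D_MRNP))
    if params.mrna_export:
        sp.append(Species("mRNA_cyt", CYT | P, C.D_MRNP))
    return sp


def build_splicing_network(
    params: SplicingParams, cotranscriptional: bool = False
) -> ReactionNetwork:
    """Spliceosome assembly and splicing restricted to speckle+nucleoplasm.

    Plain mode: each pre-mRNA carries one splice site and goes through a
    single E -> A -> B -> B* -> spliced cycle.  Co-transcriptional mode:
    a transcript is a chain of ``N_INTRONS`` intron units, each
    transcribed at per-unit rate ``N_INTRONS * ktrans`` and spliced
    through a full cycle before the next unit appears; mature mRNA is
    released after the last unit.  U1 returns to the free pool at
    activation; U2 and tri.U on splicing.
    """
    species = _splicing_core_species(params)
    rx: list[Reaction] = []

    def r(name, reactants, products, rate, units, comp=SN):
        rx.append(Reaction(name, tuple(reactants), tuple(products), rate, units, comp))

    def cycle(tag: str, pre: str, out_products: tuple[str, ...]):
        """One E/A/B/B* assembly-and-splice cycle acting on ``pre``."""
        for nm in (f"E{tag}", f"A{tag}", f"B{tag}", f"Bs{tag}"):
            species.append(Species(nm, SN, C.D_MRNP))
        r(f"formE{tag}", [pre, "U1"], [f"E{tag}"], C.KON_E, "M-1s-1")
        r(f"dropE{tag}", [f"E{tag}"], [pre, "U1"], C.KOFF_E, "s-1")
        r(f"formA{tag}", [f"E{tag}", "U2"], [f"A{tag}"], C.KON_A, "M-1s-1")
        r(f"dropA{tag}", [f"A{tag}"], [f"E{tag}", "U2"], C.KOFF_A, "s-1")
        r(f"formB{tag}", [f"A{tag}", "triU"], [f"B{tag}"], C.KON_B, "M-1s-1")
        r(f"dropB{tag}", [f"B{tag}"], [f"A{tag}", "triU"], C.KOFF_B, "s-1")
        r(f"activate{tag}", [f"B{tag}"], [f"Bs{tag}", "U1"], params.kact, "s-1")
        r(f"splice{tag}", [f"Bs{tag}"], list(out_products) + ["triU", "U2"],
          C.KSPL, "s-1")

    if not cotranscriptional:
        species.append(Species("premRNA", SN, C.D_MRNP))
        r("transcribe", ["geneD"], ["geneD", "premRNA"], params.ktrans, "s-1", SN)
        cycle("", "premRNA", ("mRNA",))
    else:
        # unit i: T_i = elongating (next intron unit being transcribed),
        # P_i = unit i displayed and awaiting spliceosome assembly
        r("initiate", ["geneD"], ["geneD", "T1"], params.ktrans, "s-1", SN)
        per_unit = N_INTRONS * params.ktrans
        for i in range(1, N_INTRONS + 1):
            species.append(Species(f"T{i}", SN, C.D_MRNP))
            species.append(Species(f"P{i}", SN, C.D_MRNP))
            r(f"elongate{i}", [f"T{i}"], [f"P{i}"], per_unit, "s-1")
            nxt = ("mRNA",) if i == N_INTRONS else (f"T{i + 1}",)
            cycle(str(i), f"P{i}", nxt)
    if params.mrna_export:
        rx.append(
            Reaction("export_mRNA", ("mRNA",), ("mRNA_cyt",), params.knpc, "s-1", P)
        )
    return ReactionNetwork(species, rx)


#: names of the species subject to speckle partitioning in splicing runs
#: (the splicing particles and the transcript lineage; spliced mRNA is not
#: retained so it can reach the pores)
def splicing_biased_species(network: ReactionNetwork) -> list[str]:
    import re

    pat = re.compile(r"^(U1|U2|triU|premRNA|[EAB]\d*|Bs\d*|[PT]\d+)$")
    return [s.name for s in network.species if pat.match(s.name)]


NETWORK_PRESETS = {
    "formation": build_particle_formation_network,
    "formation_nucleus_only": build_misassembly_variant,
    "splicing": lambda p: build_splicing_network(p, cotranscriptional=False),
    "splicing_cotx": lambda p: build_splicing_network(p, cotranscriptional=True),
}


def snrna_mass_balance(counts: dict, u: str = "U1") -> tuple[int, int]:
    """(transcribed, accounted-for) totals for one snRNA species.

    In the formation network every transcribed snRNA is in exactly one
    of: free nuclear/cytoplasmic snRNA, a G5/Sm5/Sm7 intermediate, the
    imported Sm7, or the mature particle.  Works for both the
    multi-compartment and nucleus-only variants.
    """
    forms = [
        f"{u}snRNA_nuc", f"{u}snRNA_cyt", f"{u}snRNA",
        f"{u}G5", f"{u}Sm5", f"{u}Sm7", f"{u}Sm7_nuc",
        f"{u}snRNP", f"misassembled_{u}",
    ]
    accounted = sum(int(counts.get(f, 0)) for f in forms)
    transcribed = int(counts.get(f"transcribed_{u}", accounted))
    return transcribed, accounted
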