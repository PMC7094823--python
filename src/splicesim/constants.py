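"""Physical constants and published kinetic parameters.

Rate constants are the literature / model values for the two reaction
networks simulated by this package: formation of the U1 and U2 snRNP
splicing particles (multi-compartment: nucleus -> NPC -> cytoplasm ->
NPC -> Cajal bodies / nucleus), and step-wise spliceosome assembly with
intron excision (nucleoplasm and nuclear speckles).
"""

AVOGADRO = 6.022e23  # 1/mol

# --- snRNP particle-formation network -----------------------------------
# transcription of the U snRNA genes (per gene copy)
KTRANS_U1 = 0.285  # s^-1
KTRANS_U2 = 0.224  # s^-1
# first-order translocation while sitting on a nuclear-pore site
KNPC = 2.0e4  # s^-1
# Gemin-5 binding / release (cytoplasm)
KON_G = 1.02e8  # M^-1 s^-1, diffusion limited
KOFF_G = 3.05  # s^-1
# RNP exchange: Sm5 ring displaces Gemin 5
KS1 = 5.9e7   # M^-1 s^-1 (U1)
KS2 = 1.18e7  # M^-1 s^-1 (U2)
# addition / loss of the two late Sm proteins
KON_SM2 = 1.39e8  # M^-1 s^-1
KOFF_SM2 = 2.78   # s^-1
# particle-specific protein binding in Cajal bodies / nucleus
KON_U1PROT = 1.22e7   # M^-1 s^-1
KOFF_U1PROT = 4.8e-4  # s^-1
KON_U2PROT = 0.24e7   # M^-1 s^-1
KOFF_U2PROT = 4.8e-4  # s^-1

# --- spliceosome assembly / splicing network ----------------------------
KTRANS_GENE = 4.7e-3  # s^-1, pre-mRNA production per active gene
KON_E = 4.66e7   # M^-1 s^-1, U1 + pre-mRNA -> complex E
KOFF_E = 1.57    # s^-1
KON_A = 8.8e7    # M^-1 s^-1, E + U2 -> complex A
KOFF_A = 0.062   # s^-1
KON_B = 4.66e7   # M^-1 s^-1, A + tri.U -> complex B
KOFF_B = 1.55    # s^-1
# B -> B* activation releasing U1.  Published as 6e4 with bimolecular
# units for a unimolecular conversion; implemented as a fast first-order
# step (the intent: B* forms quickly after B).  Configurable.
KACT_FIRST_ORDER = 380.0  # s^-1
KSPL = 0.067  # s^-1, B* -> mRNA + tri.U + U2

# --- initial abundances --------------------------------------------------
CONC_G5 = 0.61e-6   # M, cytoplasmic Gemin 5
CONC_SM5 = 0.61e-6  # M, pre-assembled Sm pentamer ring
CONC_SM2 = 0.61e-6  # M, late Sm proteins
CONC_U1PROT = 0.89e-6  # M, nuclear U1-specific proteins
CONC_U2PROT = 0.56e-6  # M, nuclear U2-specific proteins
# active U snRNA gene copies: 30 per species per haploid genome
N_SNRNA_GENES_HAPLOID = 30
PLOIDY = 2

# --- default diffusion coefficients (um^2/s) -----------------------------
# Overridable per species/site-type; chosen so that the fastest species
# reproduce the fixed time steps 7.3e-5 s (formation runs) and 3.3e-3 s
# (splicing runs) at lambda = 64 nm.
D_PROTEIN = 9.35      # free proteins and small protein complexes
D_SNRNA = 1.0         # snRNA and cytoplasmic assembly intermediates
D_SNRNP = 0.207       # assembled snRNP particles (U1, U2, tri.U)
D_MRNP = 0.1          # pre-mRNA, spliceosomal complexes, mRNA (mRNP-scale)

# misassembly channel (nucleus-only variant): premature binding of the
# particle-specific proteins to the snRNA.Sm5 intermediate, modeled as
# diffusion-limited with the same constant as the competing Sm2 addition.
K_MISASSEMBLY = KON_SM2
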