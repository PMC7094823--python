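"""Nuclear speckles concentrate the splicing machinery.

Sweeps the degree of splicing-particle localization in speckles (set by
the boundary-crossing bias P_n/P_s) with the two-compartment surrogate:
20 genes, 1 nM free U1, 15 minutes of biological time.  Co-localizing
particles and transcripts in the small speckle volume accelerates every
bimolecular assembly step, so spliced-mRNA output rises with
localization until it saturates at the transcription supply, while the
pool of free (unspliced, unbound) transcripts is drained.
"""

from splicesim.experiments import fold_enhancement, run_speckle_sweep

targets = (0.0, 0.1, 0.25, 0.5, 0.85)
sweep = run_speckle_sweep(localization_targets=targets, n_reps=10, seed=2)

print("localization   mRNA (mean+-sd)   free pre-mRNA    CV")
for t in targets:
    m = sweep[(1e-9, t)]["mRNA"]
    f = sweep[(1e-9, t)]["free_premRNA"]
    cv = m.cv
    print(f"   {t:4.0%}       {m.mean:6.1f} +- {m.sd:4.1f}   "
          f"{f.mean:10.1f}    {cv if cv is None else round(cv, 3)}")
print(f"fold change at 10% localization vs no speckles: "
      f"{fold_enhancement(sweep, 1e-9, 0.1):.1f}x")
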