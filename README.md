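# splicesim

Spatial stochastic simulation of spliceosomal-particle biogenesis and
pre-mRNA splicing in a voxelized model of a human (HeLa-scale) cell.

Splicing depends on machinery that is built across compartments: U snRNA
is transcribed in the nucleus, exported through nuclear pore complexes,
assembled with Sm proteins in the cytoplasm, re-imported and matured in
Cajal bodies — and the finished U1/U2 snRNP particles concentrate in
nuclear speckles, membrane-less droplets where spliceosomes assemble on
nascent transcripts.  `splicesim` is for quantitative cell biologists and
modelers who want to ask how this spatial organization — pore counts,
organelle crowding, speckle number/size, gene placement — shapes particle
yield, splicing output and its cell-to-cell noise.

The package provides:

* **A geometry builder** (`splicesim.geometry`): constructive solid
  geometry stenciled in depth order onto a cubic lattice of 11 site
  types (plasma/nuclear membranes, cytoplasm, nucleoplasm, ER,
  mitochondria, Golgi, Cajal bodies, speckles, nuclear pores,
  extracellular), with a stochastic cellular-automaton ER and
  Fibonacci-layout pores.
* **Reaction networks** (`splicesim.network`): the 20-reaction U1/U2
  particle-formation pipeline, its nucleus-only misassembly variant, and
  the spliceosome-assembly/splicing cycle (E → A → B → B\* → spliced),
  optionally co-transcriptional (8 introns × 3.4 kb ≈ 28 kb gene), all
  with published mass-action constants.
* **Two engines**: a lattice reaction–diffusion master equation (RDME)
  sampler — per-direction jump probability `D·τ/λ²` with `τ = λ²/(6·D_max)`,
  exact Gillespie sub-loops inside subvolumes, site-type permeability,
  and speckle partitioning as boundary-crossing probabilities `P_n`
  (in) and `P_s` (out) giving an equilibrium enrichment `c_s/c_n = P_n/P_s` —
  plus an exact well-mixed SSA over coupled compartments that serves as
  the RDME's verification oracle and as a fast surrogate.
* **Scripted experiments** (`splicesim.experiments`) reproducing the
  compartmentalization, speckle-enhancement, speckle-anatomy and
  gene-distance studies at documented reduced scales.

## Worked example

Why does particle assembly span two compartments?  Confine every step to
the nucleus and count what comes out after 30 s:

```python
from splicesim.experiments import run_misassembly_experiment

res = run_misassembly_experiment(n_reps=10, duration=30.0, seed=1)
print(res["misassembled"])
print(res["mature"])
```

```
ReplicateSummary(n=10, mean=624, sd=18, cv=0.0289, condition={'duration_s': 30.0, 'nuclear_radius_um': 4.2, 'observable': 'misassembled'})
ReplicateSummary(n=10, mean=290, sd=9.05, cv=0.0311, condition={'duration_s': 30.0, 'nuclear_radius_um': 4.2, 'observable': 'mature'})
```

With all steps in one compartment, the particle-specific proteins reach
the incomplete snRNA·Sm⁵ intermediate and ~68% of the RNA output is
diverted into terminal misassembled particles — the quantitative case
for exporting assembly to the cytoplasm, where that premature encounter
cannot happen.

More narrative examples live in `examples/` (one script per
capability: geometry building, misassembly, speckle enhancement,
spatial formation runs); a thin CLI mirrors them:

```bash
splicesim build --out cell.h5 --seed 1 --report report.tsv
splicesim run --lattice cell.h5 --network formation --duration 30 --seed 1 --out traj.tsv
splicesim experiment misassembly --seed 7 --out-dir results/
```

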