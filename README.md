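# pmfkit

Free-energy machinery for QM/MM-style enzyme mechanism studies: 2D
umbrella-sampling WHAM, free-energy-surface stationary-point and
minimum-free-energy-path analysis, low-level→high-level energy-correction
bookkeeping, and exact per-residue electrostatic interaction-energy
decomposition.

## The problem

Mechanistic studies of serine hydrolases (the motivating system is a
PET-degrading esterase with a Ser/His catalytic pair) map each chemical step
on a two-dimensional free-energy surface spanned by distance-based reaction
coordinates — a bond-forming distance and an antisymmetric proton-transfer
combination d(donor–H) − d(acceptor–H).  The surface is sampled with
harmonically restrained umbrella windows and reconstructed by the weighted
histogram analysis method (WHAM):

```
p_l = M_l / Σ_i N_i exp(β(f_i − b_i(l)))        f_i = −kT ln Σ_l exp(−β b_i(l)) p_l
```

iterated to self-consistency, with `G_l = −kT ln p_l`.  Transition states
are saddle points of the resulting surface; the effective barrier is the
maximum of the minimax (widest) path between basins.  Multi-step profiles
report two barrier conventions side by side — every state relative to the
reactant state (RS), and each TS relative to its preceding intermediate —
because the rate-limiting step can differ between them.  Cheap-potential
free energies are corrected per state by ΔG → ΔG + (E_high − E_low) of the
reactive region, and the QM-region/environment interaction energy is
decomposed exactly over environment residues under a fixed-charge model:

```
E_int = Σ_{i∈QM} Σ_{j∈MM} k_e q_i q_j / r_ij ,   k_e = 332.0637 kcal·Å·mol⁻¹·e⁻²
```

Because the real inputs require quantum-chemistry and MD engines, the
package ships a synthetic-data module: analytic 2D surfaces (harmonic well,
double well with exact barrier, scaled Müller–Brown), a seeded Metropolis
walker standing in for restrained MD, and toy charge complexes with known
per-residue energies — so every algorithm is testable against ground truth.

## Worked example

```python
import pmfkit as pk

surface = pk.make_surface("double_well_2d", barrier=13.8)        # kcal/mol
windows = pk.gen_window_grid((-2.0, 2.0), (1.0, 3.0), 40, 40, 50.0, 50.0)
series  = pk.sample_windows(surface, windows, pk.SamplerConfig(seed=2024))
grid    = pk.GridSpec(range1=(-2.0, 2.0), range2=(1.0, 3.0), bins1=60, bins2=60)
fes     = pk.solve_wham(windows, series, grid, temperature=300.0)
prof    = pk.profile_from_fes(fes, labels=("RS", "TS1", "TI1"))
print(pk.barriers(prof).to_string(index=False))
print(f"recovered barrier: {pk.grid_barrier(fes):.2f} kcal/mol (true: 13.8)")
```

prints

```
label kind branch    energy  dG_rel_RS  dG_rel_prev
   RS  min   None -0.043133   0.000000          NaN
  TS1   ts   None 13.707672  13.750805    13.750805
  TI1  min   None  0.008218   0.051352          NaN
recovered barrier: 13.71 kcal/mol (true: 13.8)
```

1600 umbrella windows (force constant 50 kcal·mol⁻¹·Å⁻², 300 K, 20 000
production steps each) are sampled in one vectorized pass, WHAM converges to
its 10⁻⁷ kcal/mol tolerance, and the reconstructed barrier lands within a
tenth of a kcal/mol of the surface's exact 13.8.  `dG_rel_RS` and
`dG_rel_prev` are the two barrier conventions described above.

The same flow is available from the shell:

```bash
pmfkit synth   --config config.json --out-dir data/
pmfkit wham2d  --metadata data/windows.meta --out fes.txt
pmfkit analyze --fes fes.txt --out analysis.json
pmfkit correct --profile profile.json --table corrections.json --out corrected.json
pmfkit decompose --pdb state.pdb --charges state.tsv --out residues.tsv
```

Every run writes a `.run.json` record (resolved parameters, seeds, input
digests) and identical configs + seeds give byte-identical numeric outputs.

## Layout

- `pmfkit.synthetic` — analytic surfaces, window grids, Metropolis sampler, toy complexes
- `pmfkit.wham` — 2D WHAM solver and window-overlap diagnostics
- `pmfkit.analysis` — minima/saddles, minimax MFEP, profiles and barrier tables
- `pmfkit.corrections` — state and path energy corrections
- `pmfkit.decomposition` — per-residue Coulomb decomposition
- `pmfkit.coords` — distance / antisymmetric-difference reaction coordinates
- `pmfkit.umbrella_io` — plain-text formats (window metadata, series, FES grids, PDB + charge tables, JSON tables)
- `pmfkit.cli` — the `pmfkit` console entry point

See `docs/methods.md` for the model details, numerical choices, and known
limitations.
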