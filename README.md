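# riboforma

Hybrid top-down / native mass-spectrometry toolkit for dissecting ribosomal
particles and other large ribonucleoprotein assemblies.

Ribosomes carry features that standard structural methods overlook: processed
termini (e.g. cleaved chloroplast transit peptides), post-translational
modifications such as cysteine methylation, and substoichiometric or variable
subunit composition. Two MS tiers expose them. **Top-down LC-MS/MS** measures
intact proteoform masses and sequences them by HCD fragmentation; **native MS**
weighs the intact complexes, so that accurate masses reveal subunit
stoichiometry, missing proteins, and ligand binding. `riboforma` implements the
computational side of both tiers on plain peak lists, with a synthetic-data
generator that provides ground-truth inputs for every stage.

## What it computes

**Charge-envelope deconvolution** (`riboforma.deconvolution`). An electrospray
envelope of a species of neutral mass *M* places peaks at
*m/z = (M + z·m_H)/z* for consecutive charges *z*. For isotopically unresolved
spectra the charge is inferred by scanning all consecutive-charge assignments
and minimizing the RMS *relative* deviation of the per-peak implied masses
*M_i = z_i (m/z_i − m_H)* from their mean; the fitted mass is the
intensity-weighted mean, reported as *M ± sd*. `deconvolute_scan` applies the
same idea greedily to whole medium-resolution full scans (seed on the most
intense unassigned peak, grow a consecutive-charge series, accept when long
and self-consistent), emulating on-the-fly deconvolution that drives
data-dependent precursor selection with proteoform-level dynamic exclusion.

**Top-down identification** (`riboforma.topdown`). Theoretical b/y ladders
(b_i = Σ first *i* residues + proton; y_j = Σ last *j* residues + water +
proton) are matched at 10 ppm; candidates are scored by matched-fragment
count. The absolute-mass search widens the precursor window up to 5 kDa so a
terminally processed protein is still found from its intact terminus;
`infer_terminal_processing` then enumerates (start, end) spans (± one terminal
modification) that explain the precursor mass and re-scores fragments.
`localize_unit_shifts` walks both ladders counting how many unit masses
(e.g. +14.01565 Da methyl) each fragment carries, localizing modification
sites where the count increments. `decoy_fdr` estimates the identification
FDR by target–decoy competition against shuffled sequences.

**Native composition** (`riboforma.composition`). Bounded integer enumeration
of subunit stoichiometries matching a measured complex mass, missing-subunit
(deficit) assignment between co-occurring subpopulations, and
binding-shift/ligand matching with n:1 stoichiometry checks.

**Synthetic data** (`riboforma.simulate`). Seeded generators for envelopes
(charges 5–100, 5 kDa–2.5 MDa, adducts, m/z jitter, noise peaks), fragment
spectra with partial coverage, superposed complex populations, and fixture
databases with planted truncations, ragged N-termini and modifications —
every artifact ships machine-readable ground truth.

## Worked example

Fit a released stalk-complex envelope, solve its stoichiometry, and assign a
subpopulation deficit:

```python
from riboforma import *

s, _ = simulate_envelope(103_400.0, SimulationConfig(seed=7, mz_jitter_ppm=20),
                         charges=range(24, 31))
fit = fit_envelope(s, range(len(s)), (5, 100), rms_ceiling=1e-3)
print(f"fitted mass: {fit.neutral_mass:.1f} +/- {fit.mass_sd:.1f} Da")

inv = ComponentInventory([("L10", 17_700.0, 1, 1), ("L12", 14_300.0, 0, 8)])
for sol in solve_stoichiometry(fit.neutral_mass, inv, tol=500.0):
    print(f"stoichiometry: {sol.counts}  residual {sol.residual:+.1f} Da")

a = assign_subpopulation_deficit(1_215_347, 1_196_399,
                                 [("S10", 18_900.0), ("S25", 13_600.0)])
print(f"deficit: {format_kda(a.deficit)} kDa -> missing {a.best}")
```

prints

```
fitted mass: 103399.1 +/- 0.9 Da
stoichiometry: {'L10': 1, 'L12': 6}  residual -100.9 Da
deficit: 18.9 kDa -> missing S10
```

i.e. the ~103.4 kDa complex is a heptamer — one L10 carrying six copies
(three dimers) of L12 — and a 1.215 MDa small-subunit particle co-occurring
with a species 18.9 kDa lighter is missing one copy of S10.

The same operations are exposed on the command line:

```sh
riboforma simulate envelope --mass 103400 --charge 24:30 --seed 7 --out run/
riboforma deconvolve --in run/envelope.tsv --mode native --out run/masses.tsv
riboforma compose --measured 103400 --inventory stalk.tsv --tol 500
riboforma identify --db db.fasta --spec frag.tsv --window 5000 --out prsms.tsv
```

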