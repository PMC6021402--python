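# Methods

## Mass bookkeeping

All masses are in daltons. The proton mass is fixed at 1.007276 Da and water
at 18.010565 Da (monoisotopic) / 18.0153 Da (average); every module draws
these from `riboforma.chem` so the electrospray relation
m/z = (M + z·m_H)/z and its inverse are exact inverses of each other.
Two mass scales are carried end to end: monoisotopic for isotopically
resolved data, average for masses obtained from unresolved envelopes. The
monoisotopic residue table is the standard Unimod/IUPAC table; the average
table uses 2013 IUPAC atomic weights. Both are embedded in the package so no
network access is ever needed. The test suite cross-checks proteoform and
fragment masses against pyteomics as an independent oracle; pyteomics is not
used by the implementation.

RNA masses are computed as a linear polymer of nucleotide-monophosphate
residues with 5'-OH termini by default; a flag adds a 5'-monophosphate
(+79.96633 Da). In-vitro transcripts vary in their 5' state, so neither
convention is assumed — this also applies to "theoretical" rRNA-containing
particle masses, which are therefore parameters, not derived quantities,
wherever they are used.

The modification registry ships methylation (+14.01565), dimethylation
(+28.03130), trimethylation (+42.04695), acetylation (+42.01057),
phosphorylation (+79.96633), disulfide (−2.01565) and initiator-Met loss
(−131.04049), all monoisotopic Da, with residue/terminus target lists; users
can merge a JSON file of additional entries. Average-scale deltas default to
the monoisotopic value when no curated number exists.

## Envelope fitting and scan deconvolution

`fit_envelope` scores every assignment of consecutive charges (the
highest-m/z peak taking z in the configured range, charges descending with
increasing m/z) by the RMS *relative* deviation of per-peak implied masses
from their mean. A relative — not absolute — error functional keeps 10 kDa
and 1 MDa envelopes comparable. The fitted mass is the intensity-weighted
mean of implied masses and is reported together with their standard
deviation ("M ± sd"). Ties within 1e-12 in RMS resolve to the lower charge
(higher mass) for determinism. Assignments whose best RMS exceeds a ceiling
(default 2e-4, appropriate for medium-resolution data; configurable) return
a "no consistent envelope" result rather than raising.

Charge discrimination has a physical limit: a misassignment by Δz bends the
implied-mass series by roughly span·Δz/z² in relative terms, so once z is
large and the jitter comparable, adjacent assignments become statistically
indistinguishable. At the charge states large native particles actually
exhibit (tens of charges, envelopes near m/z 20,000–25,000, ~10+ resolved
states) discrimination is robust up to ~0.1 % m/z noise; pushing the same
noise to z ≳ 60 with few peaks is genuinely ambiguous, which is why the
synthetic envelopes for megadalton species default to charge centers around
fifty.

`deconvolute_scan` is deliberately greedy and on-line: seed on the most
intense unassigned peak above an abundance threshold (default 10 % of the
scan base peak — interpreted as a per-scan base-peak fraction), try every
seed charge, grow a consecutive-charge series at predicted m/z positions
within a ppm tolerance (default 20 ppm), and accept the longest
self-consistent series of at least `min_series_length` (default 3) members.
There is no joint global fit. Accepted series are removed and the process
repeats, so total intensity is conserved between assigned series and
leftover peaks. Adducts are not modeled during fitting; a fitted mass is to
be read as molecular mass plus mean adduct load (metal ions, incomplete
desolvation).

Precursor selection mimics data-dependent acquisition: for each of the top-n
(default 3) proteoform masses not on the exclusion list, the single most
intense charge state is isolated and the m/z windows of its sibling charge
states join a dynamic-exclusion list with a scan-count expiry, removing the
redundancy of fragmenting several charge states of one proteoform.

## Top-down identification

Only b/y ions are generated (HCD chemistry); fragment lists are assumed
singly/low-charged and centroided. Matching takes the nearest peak within
10 ppm; one peak satisfying several ions is allowed but flagged ambiguous.
Matched intensities are z-scored with the sample (n−1) standard deviation;
degenerate populations (single match, zero spread) score 0.

The PrSM score is the matched-fragment count, with ties broken by smaller
|precursor residual| then smaller summed |ppm error| — the minimal auditable
choice. The acceptance threshold is `min_matched` (default 5).

The absolute-mass search admits every database entry whose intact mass lies
within the precursor window (default 500 Da, up to 5 kDa). One-sided
fragment support plus a nonzero mass delta is the signature of terminal
processing; `infer_terminal_processing` then enumerates retained spans
(N-terminal trim ≤ 120 residues, C-terminal ≤ 60 by default — transit
peptides and C-tails fall well inside, and the search is quadratic if
unbounded), optionally adding one terminal modification (N-terminal
acetylation by default), keeps spans matching the precursor within 2.2 Da
(covers a mono/average scale mismatch at ~30 kDa plus deconvolution error),
and re-ranks by matched count then |residual|.

Unit-shift localization probes each cleavage site at theoretical + k·unit
(k = 0..n_units) on both ladders; the best-matching k is the cumulative
count of modifications N-terminal of that cleavage (y-ladder counts are
converted through the precursor total). Count increments between observed
cleavages bound the modification sites; intervals are intersected with a
candidate-residue set, and intervals holding more candidates than increments
are reported as ambiguity sets. Non-monotone counts along the sequence
produce a conflict report, never a partial assignment.

Decoy FDR uses within-protein residue shuffling (length and composition
preserved, seed recorded) and per-spectrum target–decoy competition: each
spectrum contributes at most one accepted PrSM, the better-scoring of the
two search winners, and FDR = decoy wins / all wins. Competition matters
here: a shuffled decoy keeps the protein's residue composition, and exact
subset-sum coincidences (Gly+Gly = Asn, Ala+Gly = Gln) reliably hand decoys
a few fragment matches on dense spectra; counting every candidate above a
small fixed threshold would therefore overstate the FDR of an otherwise
clean search.

## Native composition

Stoichiometry solving is exhaustive bounded enumeration over the count
lattice with branch-and-bound pruning on reachable mass, capped at 1e7
combinations. Solutions within tolerance are sorted by |residual|, then
fewer total subunits (Occam), then lexicographic counts. The recommended
tolerance is ~3× the stated measurement spread; residuals are reported in Da
and ppm. Deficit assignment picks the candidate mass nearest the
subpopulation mass difference and reports the runner-up margin (infinite
sentinel for a single candidate). Binding shifts are matched to ligands at a
relative tolerance (default 5 %) assuming 1:1 binding, with integer n:1
alternatives reported independently. Masses print in kDa with one decimal,
half-up — the convention needed to reproduce figures like "5.7 kDa" from
5,745 Da.

One documented inconsistency: with a 1,215,347 Da measured particle, a
1,209,602 Da theoretical mass and a 3,456.35 Da orphan protein, the
remaining deviation is 2,288.65 Da; a "~1.7 kDa" figure sometimes quoted for
this arithmetic is not recoverable from those inputs, so it is not asserted
anywhere.

## Synthetic data

The generator emulates: truncated discrete Gaussian charge profiles (center
0.08·√M by default — native-like charging, saturating around fifty for MDa
ribonucleoprotein particles — width 2 charges); per-peak nonnegative
Gaussian adduct loads; relative Gaussian m/z jitter; log-normal fragment
intensities (σ = 0.5, a generic positive heavy tail); uniform-m/z noise
peaks with intensities below the 20th percentile of signal; uniform random
fragment subsets at a configured coverage; and precursor masses perturbed
within 10 ppm. All randomness flows from one named generator per run, and
identical (config, seed) yields byte-identical output files.

What it does *not* emulate — profile-mode peak shapes, isotope structure,
chromatographic co-elution, charge-state-dependent adduct loads, correlated
noise — bounds what green tests mean: they validate the inference machinery
under the stated noise model, not instrument-specific artifacts.

## Problem sizes and defaults used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
fixtures chosen for desk-scale runtimes: envelope sweeps over 10 masses
between 5 kDa and 2.5 MDa with 13 charge states; 50 terminal-processing
fixtures of 60–90 residues with trims inside (30, 15) bounds; 15
localization fixtures with up to 5 planted methyls; 20-protein databases for
FDR; ≤4-component inventories for solver/oracle comparison. These sizes are
the package's own reproducibility choices; every routine accepts larger
inputs.
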