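# Methods

This note records the model behind `pirprm`, the defaults and why they were
chosen, the numerical conventions, and what the synthetic fixtures do and
do not demonstrate.

## Mass model

Monoisotopic element and residue masses come from the NIST table shipped
with pyteomics; the proton mass is 1.007276466 Da, so that m/z values are
reproducible to the 4 decimals customary in high-resolution work. I and L
are distinct letters with identical mass; ambiguity codes (B/Z/X) are
rejected, because inputs are identified peptide sequences, not database
entries. Carbamidomethylation of Cys (+57.021464 Da, +C2H3NO) is applied as
a fixed modification by default — the standard consequence of iodoacetamide
alkylation during sample preparation — and can be disabled or replaced
through the modification registry.

A peptide's elemental composition is the sum of residue compositions plus
one water plus modification compositions. Mass-only modifications (no
formula) are accepted for m/z arithmetic but refused, with the offending
modification named, when a composition is required (isotope work): guessing
a formula would silently distort isotope distributions.

## PIR linker chemistry

Three empirical constants describe the default linker (BDP): the stump
residual 197.032 Da left on a linked Lys when both labile bonds cleave, the
long-arm residual 948.444 Da after a single cleavage, and the reporter ion
at 752.412 m/z. These three numbers are mutually inconsistent by ~0.007 Da
(948.444 − 197.032 = 751.412 ≠ 752.412 − 1.00728), so they are treated as
independent configurable constants and never derived from one another. The
intact linker's added mass defaults to stump + long-arm = 1145.476 Da and
is user-overridable.

Transition enumeration emits, per pair: released intact peptides (+stump),
long-arm ions (+long-arm residual), and the complete b/y series of both
peptides with the stump attached to whichever fragment spans the link site
(both labile bonds assumed cleaved). All product ions default to charge 1 —
the charge state at which these fragments are characteristically observed —
configurable per kind. b1 ions are emitted; downstream users may filter.
The reporter ion is excluded by default because it is produced by every PIR
species in the run and is therefore non-specific; a flag includes it.
Transitions whose m/z collides with an earlier one within 1e-4 are kept but
flagged, since collapsing them would silently change totals.

Fragment m/z values are monoisotopic. Only the precursor offers an
isotope-distribution option, because the isolation decision — not the
product-ion readout — is what the most-abundant-peak choice affects.

## Isotope distributions

The distribution of a composition is computed by aggregated isotopologue
convolution: per-element single-atom patterns (indexed by neutron offset)
are raised to their atom counts by repeated squaring and combined across
elements, pruning aggregate peaks below 1e-10 raw abundance. Each retained
peak carries the abundance-weighted centroid mass of the isotopologues on
that nominal position, which is what a high-resolution centroided spectrum
reports; the difference from the mono + k × 1.00335 convention is below
5 ppm at these masses, and it means peak-to-peak spacing can dip slightly
below 1.0025 Da when ³⁴S or ¹⁸O (two neutrons for +1.9958/+1.9988 Da)
contribute. Correctness is checked against exhaustive isotopologue
enumeration for small molecules; pruning limits centroid agreement to
~1e-4 Da, well inside any instrument's calibration.

The linker's elemental formula is generally unknown to users; when absent,
an averagine-model composition scaled to the intact added mass stands in
(rounding balanced with hydrogens, monoisotopic mass within 0.5 Da of the
request). This biases the pair's most-abundant-peak m/z by at most ~0.13
m/z at 4+, far inside the 3 m/z isolation window the method uses; supplying
the exact formula in the configuration removes even that.

## SILAC

The heavy channel is ¹³C₆¹⁵N₂-Lys (+8.014199 Da) and ¹³C₆-Arg
(+6.020129 Da); compositions swap the corresponding ¹²C→¹³C and ¹⁴N→¹⁵N
atoms so heavy isotope distributions stay exact. The stump-bearing Lys is
still a Lys and is labeled. Light and heavy partners are independently
targeted precursors, matched downstream by pair identity.

## Quantification

A scan contributes to a pair iff its isolation-window target lies within
half the isolation window of the pair's targeted precursor m/z. The default
window is 3 m/z, with a documented 1 m/z narrow preset; overlapping windows
share scans, which is reported, not corrected. Within a matched scan a
transition's intensity is the summed intensity of centroid peaks within
max(10 ppm, 0.005 m/z) of the product m/z; scans with no matching peak
contribute zero so all of a pair's traces share one RT grid.

Peak areas are trapezoidal (intensity × minutes). Automatic integration
bounds extend from the apex until intensity drops below 1% of apex height
or past a local minimum below 5%, including the stopping point so the
trapezoid reaches baseline; this rule is a declared stand-in for whatever
boundary algorithm an interactive review would apply, and explicit bounds
are supported for exact control. Each pair is integrated over a single
shared window derived from its top-3 most intense transitions' summed
trace, and the pair total is the sum over all transitions — summing rather
than picking a best transition follows how total PRM peak areas are used
for these species. No smoothing is applied by default; an optional 5-point
moving average sits behind a flag.

Response curves are ordinary least squares of mean normalized area against
level, with R² the squared Pearson correlation of the level means; a flat
response is reported as slope 0 with R² = 0 rather than NaN. SILAC ratios
are log2(light total / heavy total); subtracting the control run's ratio
normalizes the control to zero by construction. Zero or missing channel
totals make the ratio undefined (flagged, never imputed).

## mzML

No installed package both writes and reads mzML here, so `mzml_io`
implements a minimal mzML 1.1 writer (centroided MS2 spectra, scan start
time, isolation target, uncompressed 64-bit float arrays, standard PSI-MS
accessions) and a namespace-tolerant reader accepting 32/64-bit, zlib or
uncompressed arrays and minute- or second-valued retention times. The
format is validated in tests by round-trip and by cross-reading with
Bioconductor's mzR as an independent conformance oracle.

## Synthetic fixtures

The simulator emulates a *scheduled* PRM acquisition: per precursor, scans
on a regular RT grid covering apex ± 5σ. Transition intensities follow
abundance × weight × Gaussian(RT; apex, σ) × lognormal noise (σ from the
programmed CV), plus a few random low-level baseline peaks per scan.
Released-peptide ions receive the largest weights (α highest), mirroring
their observed dominance; b/y weights are drawn uniformly in [0.02, 0.25]
deterministically from the seed. Replicates share the design and differ
only in the noise stream.

Two study designs are bundled:

* **Label-free dilution**: a deterministic synthetic 600-residue,
  Lys-rich carrier protein (a stand-in sequence, not a real protein) is
  digested in silico (trypsin, one missed cleavage; a linkable Lys must be
  internal or protein-C-terminal); 25 unique residue–residue linkages are
  targeted as 30 pairs (five re-targeted at an extra charge state, as real
  target lists do), at 4 levels (100/200/500/1000 relative amounts) × 3
  replicates, CV 5%, elution apexes staggered 0.25 min apart with
  σ = 0.06 min at 0.015 min scan intervals. These sizes keep the full
  simulate–extract–integrate–fit cycle around ten seconds while giving
  every pair ~40 points per peak.
* **SILAC titration**: 12 light/heavy pair partners co-eluting across 5
  conditions (a no-drug control plus 4 inhibitor levels), with programmed
  control-normalized log2(L/H) trends cycling through constant
  (0 throughout), increasing (0…+2) and decreasing (0…−2); the heavy
  channel is constant and the light channel realizes the ratio.

Passing the end-to-end tests on these fixtures demonstrates that the
pipeline recovers programmed abundances, linearity and ratio trends under
multiplicative noise. It does not demonstrate robustness to features the
simulator omits: co-eluting interference, chimeric isolation windows,
retention-time drift between runs, detector saturation, or realistic
fragmentation intensity patterns.

## Known limitations

* Only two-labile-bond PIR chemistry; DSSO/DSBU doublet logic, loop-links
  and mono-links are out of scope.
* No MS1 quantification, cross-run RT alignment, or identification FDR.
* The isolation-list dialect targets the Q-Exactive inclusion-list CSV
  only.
* Interference via shared scans across overlapping windows is surfaced but
  not corrected.
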