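# pirprm

Targeted quantitative cross-linking mass spectrometry for Protein
Interaction Reporter (PIR) cross-linked peptide pairs: PRM transition
generation, Skyline-compatible exports, and quantification from mzML.

## The problem

Chemical cross-linking MS (XL-MS) identifies pairs of proximal lysines in
proteins and complexes, turning mass spectra into distance restraints on
structure and interactions. Once a cross-linked peptide pair has been
identified, *quantifying* it across conditions — drug titrations, dilution
series, SILAC comparisons — requires targeted acquisition: parallel
reaction monitoring (PRM), where the instrument repeatedly isolates the
pair's precursor and records all of its fragment ions at high resolution.

PIR cross-linkers carry two MS-labile aspartyl–prolyl bonds. On
fragmentation a cross-linked pair of peptides α and β produces a
characteristic ion set:

* **released peptides** `rp_α`, `rp_β` — the intact peptides, each with a
  small residual "stump" mass (197.032 Da) on the linked Lys after both
  labile bonds cleave; typically the most abundant and most diagnostic
  signals;
* **long-arm ions** `la_α`, `la_β` — a peptide retaining most of the linker
  (+948.444 Da) after a single cleavage;
* **b/y backbone fragments** of both peptides, singly charged, carrying the
  stump whenever their span covers the link site;
* a **reporter ion** at 752.412 m/z, common to all PIR species and therefore
  excluded from transitions by default.

`pirprm` computes all of these from sequence, exports the 7-column Skyline
small-molecule transition list and the Q-Exactive scheduled-PRM isolation
list, and quantifies pairs from PRM mzML runs: per-transition extracted ion
chromatograms, shared-window trapezoidal peak areas, dilution-series
response curves (R² of mean normalized area vs. level), and SILAC
light/heavy log2 ratios normalized to a control condition.

For the precursor, the default target is the m/z of the **most abundant
isotope peak** of the pair (computed by polynomial convolution of elemental
isotope patterns), since cross-linked pairs at 3–4 kDa have their intensity
maximum above the monoisotopic peak; monoisotopic and experimentally
observed m/z modes are also available.

A synthetic-data module simulates scheduled PRM acquisitions with
programmed abundances, so the entire pipeline is testable at desk scale
without instrument data.

## Worked example

The BSA pair linking K235–K28 (`ALK(3)AWSVAR` × `DTHK(4)SEIAHR`, 4+):

```python
from pirprm import make_pair, enumerate_transitions, precursor_mz

pair = make_pair("ALKAWSVAR", 3, "DTHKSEIAHR", 4, charge=4)
mz = {t.product_name: t.product_mz for t in enumerate_transitions(pair)}
print(f"transitions: {len(mz)}")
print(f"released alpha: {mz['rp_alpha']:.4f}")
print(f"released beta:  {mz['rp_beta']:.4f}")
print(f"long-arm alpha: {mz['la_alpha']:.4f}")
print(f"precursor (monoisotopic): {precursor_mz(pair, 'monoisotopic'):.4f}")
```

prints

```
transitions: 38
released alpha: 1198.6211
released beta:  1390.6342
long-arm alpha: 1950.0331
precursor (monoisotopic): 835.6704
```

38 transitions = 2 released + 2 long-arm + 16 b/y for the 9-residue α +
18 b/y for the 10-residue β. The released-α ion at 1198.6211 is the
unmodified peptide [M+H]⁺ (1001.5891) plus the 197.032 Da stump; the
long-arm ion differs from it by exactly 948.444 − 197.032 = 751.412 Da.

From the shell, the same pair table drives the full workflow:

```sh
pirprm transitions pairs.tsv -o out/            # Skyline transition list
pirprm isolation-list pairs.tsv -o out/         # instrument inclusion list
pirprm simulate --preset bsa-like -o sim/       # synthetic dilution series
pirprm quantify sim/run_*.mzML --pair-table sim/pair_table.tsv -o quant/
```

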