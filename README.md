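# pamrm

An LC-MRM-EPI lipidomics toolkit for phosphatidic acid (PA):

* **`pamrm.chem`** — elemental-composition arithmetic and monoisotopic m/z
  computation for glycerophospholipid species, lyso forms, acyl carboxylate
  fragments, nine common adducts, and deuterium labels. Printed m/z values
  use the two-decimal *truncation* convention of unit-resolution triple
  quadrupoles.
* **`pamrm.database`** — MS1 species/adduct tables, MS/MS fragment tables,
  chain-pair decomposition of sum compositions (e.g. PA 34:2 →
  14:2/20:0, 16:0/18:2, 16:1/18:1, 16:2/18:0 under the default curated
  chain space), and MRM transition-list design with a 75-transition cap.
* **`pamrm.spectra`** — chromatogram / EPI-spectrum containers, mzML and
  plain-CSV readers and writers, and peak integration (apex detection,
  MAD-based window selection, linear local baseline, trapezoidal area).
* **`pamrm.isomers`** — sn-1/sn-2 positional isomer assignment: fragment
  matching within an m/z tolerance, pair acceptance (both chains present),
  sn ordering by fragment intensity (sn-1 is the more intense carboxylate
  anion), and confirmation by MRM co-elution.
* **`pamrm.quant`** — internal-standard ratio quantitation (default standard
  PA(17:0/14:1)) normalized to total lipid phosphate, with linear-range
  flags (1 fmol – 12 pmol).
* **`pamrm.stats`** — per-species unpaired two-tailed t tests and
  restored-to-wild-type / elevated-over-mutant classification.
* **`pamrm.simulate`** — ground-truth PA mixtures with Gaussian MRM XICs and
  biased EPI fragment spectra, so the entire pipeline is testable offline.
* **`pamrm.pipeline`** — glue from raw runs to identified, quantified species.

## CLI

Four entry points are installed:

```sh
# MS1 database: formula, neutral mass, nine adduct m/z per sum composition
padb ms1 --class PA --carbons 24:44 --db 0:8 -o ms1.csv

# fragment masses diagnostic of one acyl chain
padb msms --chain 18:1 -o msms.csv

# MRM transition panel (fails loudly above --max without a priority list)
padb transitions --species-file panel.csv --max 75 -o mrm.csv

# positional-isomer identification from EPI spectra (+ optional XICs)
paid identify --spectra run.mzML --species PA:34:2 --mz-tol 0.3 \
    --rt-tol 0.1 -o assignments.csv

# simulate a rescue-design experiment (CSV or mzML output)
pasim --n-species 39 --seed 7 --cv 0.01 -o runs/

# restoration / elevation calls from a long-format quantitation table
pastats compare --quant quant.csv --groups WT,mutant,rescue -o calls.csv
```

Output tables can be written as `.csv`, `.tsv` or `.xlsx` (by extension).

## Conventions worth knowing

* Ion m/z values include electron-mass bookkeeping (anions gain an electron
  mass); this is required to reproduce the printed transition masses under
  truncation.
* Default fragment-matching tolerance is 0.3 Da (unit-resolution Q3);
  fragment absence means no peak at ≥ 1% of the base peak; sn order is
  called ambiguous when the two anion intensities differ by ≤ 20%.
* The default transition-design chain space is a curated list of common
  acyl chains, not a full carbon × double-bond grid; pass a `ChainSpace`
  with grid bounds (or your own chain list) to override.
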