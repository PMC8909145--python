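# neosrm

Targeted SRM assay design and absolute quantification for HLA class I
neoantigen peptides.

Tumor cells present mutation-bearing peptides (neoantigens) on HLA class I
molecules at a handful of copies per cell. Detecting and counting them
without binding-affinity prediction requires a targeted mass-spectrometry
pipeline: enumerate every 8–12-mer spanning a missense site, build and
optimize selected-reaction-monitoring (SRM) assays for each candidate on a
triple quadrupole, protect the scarce analytes from nonspecific surface
losses with carrier peptides, and convert light/heavy peak-area ratios into
copies per tumor cell using a heavy-isotope standard spiked at a known
amount. `neosrm` implements those computational stages as a library plus a
thin CLI, with a bundled acquisition simulator so the whole pipeline is
testable without an instrument.

## What it computes

* **Candidate enumeration** — for a missense mutation `GENE_RefPosAlt`
  (e.g. `KRAS_G12V`), every window of length 8–12 on the mutated protein
  that covers the altered residue: at most 8+9+10+11+12 = 50 candidates per
  site, fewer near a terminus. No HLA-binding prediction is involved.
* **Peptide chemistry** — monoisotopic masses, precursor and b/y product
  m/z, Kyte–Doolittle GRAVY, heavy-label bookkeeping, and the
  size-exclusion gate that keeps peptides strictly between the 800 and
  2000 Da ladder peaks.
* **Two-stage collision-energy (CE) optimization** — stage 1 screens all
  b/y transitions of each precursor charge at the theoretical CE ± 5 eV
  (3 points) and advances ≥ 20 transitions per charge; stage 2 refines each
  survivor on a 9-point grid (± 8 eV in 2 eV steps); transitions with
  blank-matrix interference (blank ≥ 5 % of signal, configurable) are
  curated away; the 8–10 most intense survivors form the signature panel.
* **Carrier (MaxRec) peptide design** — near-copies of each target
  (Hamming distance ≤ 2, |ΔGRAVY| ≤ 0.5) that saturate nonspecific binding
  but are provably invisible to every monitored transition: the precursor
  clears all Q1 settings by ≥ 2 Th, or every b/y product clears the
  clashing Q3 settings by ≥ 1 Th.
* **Quantification** — per replicate, detected ratio
  R = Σ light areas / Σ heavy areas over the signature transitions; then
  abundance (amol) = R̄ × spike, and

  ```
  copies/cell = amol × 10⁻¹⁸ mol × N_A / N_cells      (N_A = 6.02214076 × 10²³)
  ```

  with replicate mean ± sd, CV%, site-level summaries, and the per-target
  fold gain of running with the carrier cocktail.

## Worked example

```python
>>> import neosrm
>>> fx = neosrm.fixtures()                       # bundled 11-target benchmark set
>>> m = neosrm.parse_mutation("KRAS_G12V", fx.contexts)
>>> cs = neosrm.enumerate_candidates(m)
>>> len(cs)
50
>>> neosrm.candidates_table(cs).head(3)
gene  mutation  start  length sequence  monoisotopic_mass  in_sec_window
KRAS KRAS_G12V      5       8 KLVVVGAV          783.52183          False
KRAS KRAS_G12V      6       8 LVVVGAVG          712.44833          False
KRAS KRAS_G12V      7       8 VVVGAVGV          698.43268          False
```

The G12V site sits 11 residues from the KRAS N terminus, so all 50 windows
exist; the short 8-mers fall below the 800 Da SEC gate (`in_sec_window`
False) and would be discarded before assay design.

```python
>>> run = neosrm.design_target("KRAS_G12V_10mer",
...                            neosrm.fixture_heavy_peptide("VVVGAVGVGK"), seed=7)
>>> len(run.panel.entries)
10
>>> e = run.panel.entries[0]; t = e.transition
>>> print(f"{t.key}  Q1 {t.precursor_mz:.5f}  Q3 {t.product.mz:.5f}  CE {e.optimal_ce:.1f} eV")
z2/b1^1  Q1 446.78893  Q3 100.07569  CE 14.9 eV
```

`design_target` runs the full two-stage optimization against the bundled
acquisition simulator and returns a 10-transition signature panel with a
per-transition optimized collision energy.

```python
>>> neosrm.quantify(fx.quant_areas("with_carrier"), fx.spike_amol, fx.cell_count).head(4)
 target_id  ratio_mean  ratio_sd  abundance_amol  copies_per_cell
 KRAS_Q61H       1.045     0.058           522.5              6.3
 KRAS_Q61L       0.729     0.037           364.5              4.4
 KRAS_Q61R       1.495     0.156           747.5              9.0
IDH2_R140Q       1.019     0.057           509.5              6.1
```

Reading the first row: over three replicates the endogenous KRAS Q61H
peptide gave 1.045 ± 0.058 times the signal of the 500 amol heavy standard,
i.e. 522.5 amol recovered, which at 5 × 10⁷ tumor cells is 6.3 copies of
the neoantigen per cell.

The same stages are available from the shell:

```
neosrm enumerate --mutation KRAS_G12V --fasta contexts.fa --lengths 8-12 --out candidates.tsv
neosrm design schedule --target-id KRAS_G12V_10mer --sequence VVVGAVGVGK --stage 1 --out stage1.csv
neosrm maxrec --targets panel.csv --k 3 --out maxrec.csv
neosrm quantify --areas areas.csv --spike-amol 500 --cells 5e7 --out table.tsv
```

## Layout

| module | contents |
| --- | --- |
| `neosrm.chem` | masses, m/z, GRAVY, labels, SEC gate |
| `neosrm.mutations` | mutation parsing, candidate enumeration |
| `neosrm.srm` | CE grids, transition ranking, curation, panels, transition lists |
| `neosrm.carrier` | carrier (MaxRec) peptide design and blindness verification |
| `neosrm.quant` | ratios, attomoles, copies/cell, CV, fold gains |
| `neosrm.simulate` | acquisition/area simulators, benchmark fixtures |
| `neosrm.pipeline` | end-to-end orchestration |
| `neosrm.cli` | `neosrm` command-line entry point |

See `docs/methods.md` for the model assumptions, defaults, and known
limitations.
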