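# foldens

Ensemble analysis for partially folded protein states: the toolchain used to
characterise a thermal folding intermediate from conformational ensembles and
low-resolution experimental observables.

What it does:

- **Structures & descriptors** (`foldens.structures`, `foldens.io`) —
  multi-model PDB / multi-frame XYZ reading and writing, Kabsch
  superposition, RMSD, TM-score, radius of gyration, B-factor profiles,
  residue contact maps, Shrake–Rupley solvent-accessible surface (including
  the summed Trp side-chain SAS used as a UV-exposure proxy).
- **Essential dynamics** (`foldens.ed`) — Cartesian covariance of aligned
  ensembles, essential-space extraction, Hess subspace similarity γ,
  noise-corrected relative similarity κ (split-ensemble self-similarity
  normalisation), inter-state transition vectors and their overlap Ov with
  the top deformation modes, plus a random-subspace Monte-Carlo null for γ.
- **φ-values** (`foldens.phi`) — per-residue fraction of retained native
  contacts (φᵢ = Nᵢ/Nᵢⁿᵃᵗ) and the signed/absolute accumulated error against
  an experimental φ profile, with residue exclusion masks.
- **SAXS** (`foldens.saxs`) — vacuum Debye scattering curves from
  coordinates, iterative Guinier fits (I(0), Rg with the s < 1.3/Rg range
  enforced self-consistently), error-weighted χ fitting with the 7% uniform
  error convention for deconvoluted curves, PCA rank estimation and MCR-ALS
  (non-negativity + closure, purest-row or SVD initialisation) for
  temperature-stacked datasets.
- **Three-state spectra** (`foldens.spectra`) — sequential N↔I↔U populations
  from ΔG₁/ΔG₂ (tabulated or Gibbs–Helmholtz), and per-wavelength
  least-squares deconvolution of temperature series into pure state spectra.
- **Clustering** (`foldens.clustering`) — RMSD-radius leader clustering with
  optional nearest-centroid refinement and centroid-nearest representatives.
- **Intermediate annotation** (`foldens.annotate`) — per-frame evaluation of
  the three experimental criteria (Trp-SAS window, SAXS χ threshold,
  accumulated φ error threshold; presets `loose` = 100–300 Å²/χ<1.5/Φ<2 and
  `strict` = 100–300 Å²/χ<1.0/Φ<1.0) and a config-driven pipeline.
- **Synthetic data** (`foldens.synthetic`) — deterministic generators with
  planted ground truth for every input: Cα-bead toy proteins (rigid helical
  cores + loop arcs), correlated-Gaussian ensembles with planted modes,
  loop-disordered ensembles with recorded contact retention, three-component
  SAXS mixtures and three-state spectra series.

All structural fixtures are Cα-bead toys; the SAXS forward model is vacuum
Debye scattering with effective per-bead factors (no hydration shell or
excluded-volume terms) — sufficient for χ-based ranking and decomposition
logic, not for absolute intensity realism.

## CLI

```bash
foldens simulate --outdir fixtures --seed 1        # synthetic input bundle
foldens descriptors fixtures/intermediate.pdb
foldens cluster fixtures/intermediate.pdb --radius 3.0
foldens ed-compare fixtures/native.pdb fixtures/intermediate.pdb --n-modes 5
foldens phi fixtures/intermediate.pdb fixtures/reference.pdb
foldens saxs-fit fixtures/reference.pdb fixtures/saxs_intermediate.dat
foldens mcr fixtures/saxs_series --n-components 3
foldens annotate fixtures/intermediate.pdb fixtures/reference.pdb \
    fixtures/saxs_intermediate.dat fixtures/phi_exp.tsv --criteria loose
foldens pipeline config.yaml --outdir out
```

A pipeline config names the input files and stage parameters:

```yaml
seed: 1
ensembles: {native: native.pdb, intermediate: intermediate.pdb}
reference: reference.pdb
experimental: {saxs_intermediate: saxs_intermediate.dat, phi: phi_exp.tsv}
contacts: {cutoff: 5.5, min_seq_sep: 2, mode: heavy_atom}
criteria: loose            # or strict, or an explicit threshold mapping
ed: {n_modes: 10}
cluster: {radius: 3.0}
annotate_ensemble: intermediate
phi_exclude_residues: []   # e.g. an unreliable helix
```

Outputs (TSV/JSON) are byte-identical across reruns at a fixed seed.

## File formats

- Structures/ensembles: PDB (multi-model for ensembles) or XYZ.
- SAXS curves: whitespace-delimited 2–3 columns (s [Å⁻¹], I, σ);
  datasets as a curve directory plus `temperatures.tsv` manifest.
- φ profiles: TSV (`residue_index`, `phi`[, `n_native`]).
- Spectra series: CSV matrix, rows = wavelengths (nm), columns =
  temperatures (K).
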