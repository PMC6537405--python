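# cellfate3d

Batch quantification of single-cell viability and proliferation in 3D
cultures from multi-channel fluorescence z-stacks.

High-content drug screens in 3D collagen read out cell fate with simple
stains — Hoechst 33342 for all nuclei, ethidium homodimer (EtHd) for
membrane-compromised dead cells, Apopxin for apoptotic cells, EdU click
labeling for S-phase cells, and optionally a constitutive H2B-eGFP tag
marking one lineage in a co-culture.  Rather than segmenting and counting
individual cells (fragile in thick, scattering samples), the assay reduces
each channel to its total foreground **pixel area** per image and scores
treatments with pixel ratios.  `cellfate3d` is a batch pipeline that takes
directories of single-plane TIFFs (one file per z-slice per channel, channel
identified by a filename token), applies per-slice illumination correction
and per-stack automatic thresholding, and emits per-image and per-treatment
score tables — plus a fully ground-truthed synthetic-stack generator so the
whole pipeline is testable without a microscope.

## Method

For each (well, position, channel) z-stack:

1. **Illumination correction** — each slice is corrected as
   `I' = max(I − G_σ ∗ I, 0)` where `G_σ` is a Gaussian with a large scale
   (σ = 50 px by default, well above the nucleus radius), removing the
   center-bright illumination bias; negatives are physically impossible and
   are clamped to zero.
2. **Yen thresholding from central slices** — a 256-bin histogram pooled
   over the central 20% of slices is cut at the threshold `t*` maximizing
   Yen's maximum-correlation criterion

   `TC(t) = −ln[ (Σ_{i≤t} p_i²)(Σ_{i>t} p_i²) / (P(t)²(1−P(t))²) ]`,

   ties broken toward the lower cut.  Estimating from the stack center only
   keeps the threshold anchored to in-focus nuclei instead of the
   out-of-focus halos that accumulate in the extreme slices; the single
   threshold is applied to every slice.
3. **Signal-absence rule** — if `t* < 10 ×` the mean sub-threshold
   intensity, the stack is declared devoid of biological signal and
   contributes zero foreground (blank wells otherwise hallucinate area from
   noise).
4. **Pixel areas** — per-channel foreground pixels are summed over slices;
   pairwise mask intersections are computed slice-wise in 2D.  Cells marked
   by both death markers are counted once:
   `dead = |EtHd| + |Apopxin| − |EtHd ∩ Apopxin|`.
   In co-culture mode the GFP lineage is deconvolved out by subtracting the
   GFP intersections from the nuclear and EtHd areas.
5. **Scores** — each image yields `ln(px_num / px_den + 1)`
   (nuclear / dead for viability, EdU / nuclear for proliferation; a 1-px
   pseudocount guards empty denominators).  Per-treatment means are divided
   by the vehicle (DMSO) control mean, so the control scores exactly 1.
6. **Statistics** — row-wise Welch t tests (no pooled SD across rows) with
   Holm-Šidák step-down correction at α = 0.05; stars `*`/`**`/`***` at
   adjusted p < 0.05 / 0.005 / 0.0005.

## Worked example

Simulate a four-dose plate (vehicle + three doses, two imaging positions
per well, 120 cells per 12 × 160 × 160 stack) and analyze it:

```bash
cellfate3d simulate --out demo --doses 0,10,100,1000 \
    --n-positions 2 --n-cells 120 --shape 12,160,160 --seed 7
cellfate3d analyze --config demo/layout.yaml --input demo \
    --out demo_results --illum-sigma 25
cat demo_results/scores.csv
```

```
treatment,metric,score,sem,n_images,n_positions
DMSO,proliferation,1,0.03181077469,2,2
DMSO,viability,1,0.1406994558,2,2
dose_10,proliferation,0.9070153401,0.02733154298,2,2
dose_10,viability,0.7232011799,0.1013696558,2,2
dose_100,proliferation,0.4667593556,0.0988009175,2,2
dose_100,viability,0.4154081688,0.001990614871,2,2
dose_1000,proliferation,0.2122008578,0.01292460329,2,2
dose_1000,viability,0.3205436116,0.00186467101,2,2
```

Both scores are 1 for the vehicle control by construction and fall
monotonically with dose: at the top dose viability has dropped to 0.32 of
control and proliferation to 0.21, tracking the planted kill and S-phase
fractions of the simulated drug response.  `demo_results/` also contains
`areas.csv` (per-image pixel areas and intersections — every score is
recomputable from it), `thresholds.json` (the threshold, background mean,
fold-over-background and central slices used for every stack), a config
snapshot, and the run log.

The same `analyze` command runs on real microscope exports: point `channels:`
in the YAML config at your filename tokens, list the well → treatment map
under `wells:`, and name the `control:` treatment.

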