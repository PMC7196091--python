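# Methods

This note documents the models, rules and numerical choices behind
`lipidflow`, module by module, including the places where the design was
genuinely open and what the synthetic-data tests do and do not show.

## Mass arithmetic (`chem`)

Monoisotopic atomic masses (H 1.00782503, C 12 exactly, N 14.00307400,
O 15.99491462, P 30.97376163, Na 22.98976928) and the electron mass
(5.4858×10⁻⁴ Da) are hard constants. A lipid species written
`Class(c:d)` maps to a neutral formula `base(Class) + C_c H_{2c−2d}`,
where the per-class base was derived by subtracting the acyl
contribution from a reference standard of known formula (POPC, POPE,
POPS, POPG, POPI, POPA, SM(d34:1), LPC(16:0), LPE(16:0), CE(18:1),
tripalmitin, DG(34:1)). Ether (O-) lipids replace one ester oxygen by an
ether linkage (−O +H₂ relative to the diacyl base); plasmalogens (P-)
additionally carry the vinyl-ether double bond (−O), which is not
counted in `d`. Two structural identities fall out of this construction
and are asserted over grids in the tests:

* diacyl PC(c:d) ≡ PE(c+3:d) (same formula, hence the 772.5851 isobar);
* PS(c+3:d+1) − H ≡ PC(c:d) + HCOO as negative ions (the 824.5-type
  ambiguity), which the synthetic cohorts reproduce.

Adduct m/z = (neutral mass + delta)/|charge| with electron-corrected
deltas; charge is fixed at ±1 (the instrument scan window 150–1200 is
specified for singly charged species; multiply charged cardiolipins are
out of scope). Fatty-acid fragments are carboxylate anions
[C_cH_{2c−2d−1}O₂]⁻. ppm deviation is 1e6·(observed−theoretical)/theoretical;
m/z is reported to 4 decimals.

Default adducts are {+H, +Na, +NH₄} in positive mode (TGs are seen as
sodium/ammonium adducts) and {−H, +HCOO, +CH₃COO} in negative mode;
both sets are configurable because instrument buffers differ.

## Acquisition handling (`msio`)

One spray produces a 1 Hz scan series that walks through
positive → negative → negative-CID with windows of 72/66/66 s after a
20 s start delay; these are the segmentation defaults. Scans whose own
polarity/CID metadata contradicts their time window are dropped (and
counted) rather than reassigned — a mislabelled scan is more likely a
switching artefact than a timing error. Windows with no scans yield an
empty, flagged spectrum so a plate with failed sprays still processes.

Scans within a window are averaged into one consensus spectrum: peaks
within 5 ppm (default, configurable) across scans merge with
intensity-weighted mean m/z and mean intensity *counting absences as
zero*, so a peak present in half the scans keeps half its intensity.
Mean-with-full-windows was chosen over summing because it keeps
intensities on a per-scan scale regardless of window length.

Inputs are open formats only: mzML, or a strictly specified peak-table
TSV (UTF-8, tab-separated, header `time polarity cid mz intensity`, dot
decimal separator). mzML is read through pyteomics when its CV machinery
is available, with an internal lxml reader covering the same subset
(centroided MS1, 32/64-bit optionally zlib-compressed arrays) otherwise;
profile-mode spectra are rejected loudly. A minimal mzML writer exists
for fixtures and the `simulate` CLI; it is not a general-purpose writer.

## Extraction (`extraction`)

The deviation cut-off is 5 ppm for cohorts of <100 samples and 9 ppm for
>500 — long batches drift — with linear interpolation (rounded to 0.1)
between 100 and 500 samples. The interpolation is a package decision for
continuity; the cut-off is always overridable, and internal-standard
deviation reports (per standard, per mode, mean ± sd across samples)
are the diagnostic for choosing it. Some IS lipids behave well in only
one mode, so per-mode reliability is part of the IS definition, not
hard-coded.

Matching selects, for each search entry, the **most intense** peak
within ±tol ppm (tie → smallest |deviation|, then lowest m/z). Most
intense was preferred over nearest-m/z because DI-MS consensus spectra
are sparse and the dominant peak in a window is almost always the
analyte. One peak may satisfy several entries — exact isobars share a
signal by construction. Unmatched entries are missing, not zero; the
distinction matters for the presence filter and is only collapsed where
medians require it.

## Filtering and normalisation (`qc`)

Stage order: deviation (applied at match time) → QC concentration
correlation → SNR vs blanks → group presence. Survivor counts are
reported per stage and are non-increasing by construction.

* QC correlation: Pearson r of log intensity vs log concentration over
  the dilution series; pass iff r ≥ 0.75 with ≥3 QC observations. The
  0.75 and the log scale are package defaults (configurable); a design
  with <2 distinct levels marks every variable "not evaluable" rather
  than silently passing.
* SNR: median study intensity / median blank intensity > 3, medians for
  robustness, missing counted as zero signal; a variable absent from all
  blanks passes (infinite SNR).
* Presence: the 25% rule is read as *exclude only when the non-missing
  fraction is below 25% in every group* (per tissue), so a variable
  genuinely confined to one phenotype — e.g. a lipid present only in one
  group's kidneys — survives. Exactly 25% retains ("fewer than"
  excludes). The strict all-groups reading is available via config.
* Normalisation divides by the per-sample total *within each ionisation
  mode*, because cross-mode ionisation efficiencies are not comparable;
  retained-variable fractions then sum to 1 per sample per mode.
  Filtering runs before normalisation so junk signal does not sit in the
  denominators; samples with zero total are flagged, not fatal.

## Annotation (`annotation`)

Isobar disambiguation is lexicographic: candidates whose class-specific
negative-mode ion is observed (formate/acetate adduct for
quaternary-amine classes PC/SM/LPC and their ether variants;
[M−H]⁻ for everything else) outrank candidates without such evidence;
within a tier, head-group prior weight decides, then |deviation|.
Direct spectral evidence therefore always beats the prior — the serum
prior encodes PE ≈ 100× below PC (from ³¹P NMR), but a clear [M−H]⁻ at
M−1.0073 still flips the call to PE. Rationale codes record which
evidence fired. Priors for tissues without an NMR table default to
uniform.

Isoform assignment enumerates all unordered chain pairs consistent with
the precursor's totals and scores each pair by the **minimum** of its
two FA-anion intensities — both chains must be evidenced, and the weaker
fragment caps the support. No published rule exists for apportioning
fragment intensity among pairs sharing a chain; min-intensity is the
package's choice and proportions are normalised scores over supported
pairs. Equal fragmentation response across FAs is assumed (a per-FA
response-factor table is a config hook). sn-position is *not* inferred:
pairs are unordered even when written with a slash.

## Statistics (`stats`)

Two-group comparisons use Welch's t (unequal variances) for unpaired
designs and a paired t matched on subject id for within-subject designs
(e.g. fasting vs 2 h). The multiple-testing threshold is the
dependent-variable Bonferroni rule α/√n — lipidomics variables are
strongly correlated, and α/n is far too severe — giving 0.0022 at
α = 0.05, n = 500. The conventional α/n is available but non-default.
Note the rule's arithmetic consequence, demonstrated by the null
simulations below: at n variables the expected number of false
t-positives per cohort is n·α/√n = α√n ≈ 1 for n ≈ 450, i.e. the rule
*trades* strict family-wise control for power by design.

The sPLS-DA is a NIPALS PLS1 against a ±1 class code on centred,
unit-variance data. Per component, the weight vector w ∝ Xᵀy is
soft-thresholded to exactly `keepX` nonzero entries (threshold at the
(keepX+1)-th largest magnitude, ties broken by stable order), normalised,
scores t = Xw extracted, and X and y deflated by regression loadings.
Defaults ncomp = 2, keepX = 10 per component. The algorithm is
closed-form per component and hence exactly reproducible; the seed is
recorded for provenance. Constant variables are dropped with a warning
and re-embedded with zero loadings. In the dense limit keepX = p the
weights coincide with standard PLS (cross-checked against
scikit-learn's NIPALS implementation in the tests, which is never used
as the fitting path).

A candidate biomarker must have a nonzero loading on *any* component
**and** pass the adjusted t threshold. Intersection (rather than
side-by-side reporting) is the package's reading of combining the two
analyses; "any component" because no convention says which components
define discrimination.

Enzyme-ratio markers ship as a built-in table — elongase
(FA(18:0)/FA(16:0); PC(36:4)/PC(34:2)), SCD (CE(16:1)/CE(16:0);
CE(18:3)/CE(18:2); PC(32:1)/PC(32:0)), FADS1 (PC(38:4)/PC(38:3);
TG(54:4)/TG(54:3)), FADS2 (PC(36:3)/PC(36:2); TG(50:3)/TG(50:2)) —
computed per sample on normalised intensities, with species observed via
several adducts contributing their summed fraction; zero denominators
yield missing ratios. Abundance summaries report group means, sds and
log2 fold changes per variable or aggregated per class (class
aggregation sums member fractions per sample first, which is how the
total PE:PC ratio is formed). PCA is offered only as a thin projection
for score plots.

## ³¹P NMR cross-check (`nmr`)

Input is an integral table (shift, integral); FID processing,
deconvolution and 2D acquisition are upstream and out of scope.
Integrals below 0.01% of the total signal are discarded as noise.
Default shift windows are ±0.03 ppm around the assigned centres — PE at
0.55/0.30/0.15 ppm (multi-resonance behaviour of PE in this solvent
family), plasmalogen PC at ~0.05 ppm, PC at 0.0 ppm — plus approximate,
fully overridable windows for PA, PG, PS, SM, LPC, PI and ether PC;
shift positions are solvent-dependent, so the table is configuration,
not fact. Multi-window classes are summed; unassigned shifts are pooled
as "unknown" and excluded from the mole-fraction normalisation. PC is a
single window by default although a second PC resonance may exist.

Ionisation-efficiency factors are (MS signal fraction)/(NMR mole
fraction) normalised to PC = 1; classes absent from either side are
flagged not-cross-checkable. One NMR table represents a pooled phenotype
group — ³¹P needs far more material than MS — so factors attach to
groups, not samples.

## Synthetic data (`simulate`)

The generator emulates a two-phenotype, placenta-scale biomarker study:

* ~460 species over class grids (PC 30–40:0–6, PE 32–42:0–6, PS, PI,
  PG, SM, LPC, TG, DG, CE, ether PC), each quantified via one canonical
  adduct per mode — PC positively as +H and negatively as +HCOO; PE/PS/
  PI/PG as [M−H]⁻; TG/DG/CE as +NH₄. The grids deliberately contain the
  PC(35:2)/PE(38:2) proton isobar and the PS⁻ᴴ/PC⁺ᴴᶜᴼᴼ negative-mode
  coincidences.
* Baseline composition: one lognormal (σ = 1) draw per cohort,
  normalised to fractions. Per-sample biological variation: lognormal
  with CV 0.30; technical intensity noise: lognormal with CV 0.20
  (mean-corrected so recovery is exact in expectation); mass jitter:
  Gaussian, sd 2 ppm. Sample size 40/group. These are the study
  conditions all recovery results refer to.
* Spikes multiply group-B fractions before renormalisation; the default
  six-spike panel covers fold changes 1.5–2.5 on phospholipids across
  both modes. Paired designs reuse each subject's biological draw.
* QCs scale the pooled mean composition linearly over a 5-level dilution
  series (0.2–1.0, 5% noise); blanks carry only the three internal
  standards (spiked species outside the study grids) plus an optional
  contamination floor shared with the study samples ("junk" variables)
  to exercise the SNR filter.
* Negative-CID spectra sum chain contributions of phospholipid species
  using their (randomly assigned, totals-consistent) chain splits.
* NMR tables map pooled phospholipid class fractions to integrals at
  the default shift centres, PE split 50/30/20 over its three
  resonances (an arbitrary fixed split — any positive split summing to
  one behaves identically downstream) with Gaussian integral noise.
* Response factors default to 1 (equal ionisation) so composition
  recovery is exact in expectation; the NMR efficiency cross-check is
  exercised with skewed inputs in its own tests.

All randomness flows from the single config seed; equal seeds give
byte-identical studies.

**What passing tests show — and don't.** Recovery, sensitivity and
false-selection results demonstrate that the *data processing* is
correct and calibrated under the stated noise model. Real spectra add
isotope envelopes, response-factor heterogeneity, drift, and chemical
noise that the generator deliberately omits, so these numbers are upper
bounds on real-data performance, not predictions of it.

## Problem sizes and known behaviours

* The full-pipeline acceptance checks run 100 seeded replicates of
  simulate → extract → filter → normalise → discover at 40 samples/group
  and ~460 variables (~0.7 s per replicate); the acceptance script uses
  40 replicates per condition. Selections are scored at the
  distinct-signal level (exact isobars collapsed) and at species
  granularity.
* Under the α/√n threshold with ~500 variables, null cohorts produce on
  average about one false t-positive each, and because component-1
  sPLS-DA weights are monotone in the per-variable t statistic, the
  loading filter removes only some of them. Measured over 100 null
  cohorts: ~0.6 false selections per run, zero-selection rate ~0.4.
  A workflow needing strict null control should use the standard α/n
  correction (provided) or raise keepX selectivity; the default
  reproduces the adjusted-threshold behaviour described above.
* Negative-mode PC quantification is degraded where a PS species is
  exactly isobaric with the PC formate adduct; positive mode carries PC
  quantification in practice, and the annotation module reports the
  ambiguity.

## Limitations

No isotopologue correction or isotope-envelope modelling; no
multiply-charged species; no retention-time alignment (LC data enter
through the same peak-table interface, with fragment–precursor grouping
abstracted); no batch/drift correction or imputation; no MS² library
matching, double-bond positions, or sphingoid-base decomposition; no
cross-validated component selection or >2-class discrimination.
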