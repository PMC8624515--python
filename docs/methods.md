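# Methods

This note records the models, numerical choices, and design decisions
behind `cyanoprio`, and what the synthetic-data tests do and do not show
about real data.

## Exact-mass calculus

Monoisotopic masses use CODATA/IUPAC most-abundant-isotope values to ≥ 6
decimal places (C 12 exact, H 1.00782503, N 14.00307400, O 15.99491462,
Na 22.98976928, K 38.96370668, Cl 34.96885268, Br 78.91833710, plus P and
S). Charged adduct offsets are electron-corrected (proton 1.00727647 Da),
which is what makes calculated [M+H]⁺ values agree with high-resolution
observations at the sub-ppm level; with nuclide masses alone the error
would be ≈ 0.5 mDa (0.3–1 ppm at these masses), larger than the reported
Δppm values themselves.

Δppm is reported relative to the *calculated* m/z and rounded half away
from zero to 2 decimals, so an observed ion below the calculated value has
a negative Δ. Supported adduct forms ([M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+2H]²⁺,
[2M+H]⁺, [2M+Na]⁺) live in an editable YAML resource; the m/z of each form
is `(n·M + offset)/z`, strictly increasing in M and exactly invertible,
which the tests assert as a round-trip property.

The transformation-delta library (CSV resource) carries the common
single-step biotransformations: CH₂ 14.01565 (methylation state), O
15.99491, H₂ 2.01565, H₂O, NH₃, CO, CO₂, and the Cl↔Br substitution
43.94948. The default matching tolerance is 0.01 Da — deltas are compared
between two *measured* neutral masses, so the tolerance is deliberately
looser than the 5-ppm database tolerance. The CH₂ entry is named
"methylation state" advisedly: a nominal +14.01 Da shift between related
metabolites is a CH₂ compositional change regardless of whether one calls
it a methylated parent or a demethylated derivative.

## Isotope envelopes and halogen scoring

Envelopes are computed on nominal-mass bins (A, A+1, A+2, …) by convolving
per-element isotope distributions (exponentiation-by-squaring over the
convolution monoid), truncating to `max_peaks` bins and renormalizing.
Fine structure within a bin is ignored — the downstream reasoning is in
M+2 terms, where ³⁷Cl (+1.99705) and ⁸¹Br (+1.99795) are not resolved from
each other at the feature level. A brute-force enumeration oracle over all
per-atom isotope assignments validates the convolution on small formulas.

Halogen counts are scored by cosine similarity between the observed
envelope and simulated Clₙ Brₘ envelopes **restricted to the even offsets**
(A, A+2, A+4, …). Using even bins only is the package's own choice: it
isolates the halogen signature from the ¹³C-dominated A+1 ladder, so a
halogen-free molecule with a large carbon count still ranks (0, 0) first,
while comparing on the full envelope (or on A alone) would bias the null
candidate. Ties rank fewer total halogens first. With 2 % multiplicative
bin noise the (nCl, nBr) grid {0..3}² is recovered in ≥ 95 % of seeded
trials.

In feature tables, M+2k isotopologue partners are accepted at spacings of
2k ± 0.01 Da around 1.997 per step, co-eluting within 0.1 min, and the
observed envelope is assembled from the partner features' intensities.

## Screening statistics

Viability is the ratio of mean sample to mean solvent-control absorbance
(×100); replicate SDs are computed on per-replicate viabilities (ddof 1).
Assay quality uses the Zhang Z′-factor, 1 − 3(σ_pos+σ_solv)/|μ_pos−μ_solv|,
flagged below 0.5. The hit threshold is μ + kσ of the positive-control
fraction (default k = 3), and hits are *strictly below* threshold with the
positive control excluded from its own hit list. Group partitioning is a
two-gate rule: a 3D-spheroid hit with 2D HCT 116 viability < 40 % is
group A, any other 3D hit is group B, non-hits are C/inactive. The 40 %
discriminator is a configuration parameter; its default sits in the wide
gap between the bundled reference screen's group A (max 2D viability
27.08 %) and group B (min 50.11 %) fractions. The non-carcinogenic
hCMEC/D3 model never participates in hit selection; it is carried through
for selectivity reporting only. Retention times map to fraction letters
through half-open [start, end) collection windows.

Note that recomputing μ + 3σ from a *rounded* summary can differ in the
last digit from a threshold derived from raw plate data (e.g. 9.13 +
3×2.64 = 17.05); the package always reports the value recomputed from its
inputs.

## Fold change and prioritization

The fold-change statistic is the ratio of unpaired arithmetic group means
on raw peak areas, after replacing every missing (absent or zero) cell
with the constant 1 and applying no filtering or normalization — the
literal preprocessing used for unpaired metabolomics fold-change analysis
of this design. An active-only feature at area ~10⁸ therefore shows
log₂(FC) ≈ 26, which is why the "top" tier default sits at log₂(FC) ≥ 20:
it selects features essentially absent from the control group. The
network tier default is log₂(FC) ≥ 2. Rankings break ties by ascending
m/z for reproducibility. Scale invariance, group-exchange antisymmetry
(FC → 1/FC), and imputation idempotence are asserted as properties.

## Molecular networking

The modified cosine matches fragment pairs either directly or shifted by
the precursor mass difference (default fragment tolerance 0.02 Da,
appropriate for ~17.5k-FWHM MS2), square-root-transforms intensities, and
assigns pairs one-to-one greedily by descending intensity product. Greedy
assignment is a documented approximation: the tests check it never exceeds
the exhaustive optimal assignment and equals it in ≥ 95 % of random small
spectra, and cross-check the score against an independent implementation
(matchms, fed pre-√ intensities since it scores raw intensities).

Network topology uses the classic defaults: edge if cosine ≥ 0.7 and ≥ 6
matched peaks, edge kept only if within the top 10 for both endpoints,
components over 100 nodes pruned weakest-edge-first. Construction is
deterministic and permutation-invariant (ties by cosine then lexicographic
ids). Class propagation is a local majority vote per connected component
over a user-supplied class map (ties → "ambiguous", unlabelled →
"no matches"), with class shares reported over a caller-chosen node subset
— a deliberate, self-contained replacement for web-service annotation
stacks.

## Dereplication

Related-ion grouping is greedy in ascending m/z: each unexplained feature
is hypothesized as [M+H]⁺ and co-eluting features (0.1 min) that
reconstruct as other adducts/multimers of the same neutral within 10 ppm
are absorbed; singletons keep the [M+H]⁺ assumption flagged "unconfirmed".
The grouping tolerance (10 ppm) is looser than database matching (5 ppm)
because it compares two measured values. Database matching computes every
(compound, adduct) m/z and keeps |Δppm| ≤ 5, sorted by |Δppm|; compounds
without an established formula may carry a literature ion m/z instead and
are matched on that value directly. Derivative annotation runs only on
groups with no direct hit and considers exactly one transformation step
(±one library delta, 0.01 Da), bounding the false-annotation surface.

## Synthetic data

The generators emulate the study conditions: a 64-extract × 8-fraction
(512-well) screen in triplicate with solvent controls at 100 % viability,
a positive-control fraction at 68.32 ± 4.60 % (3D) / 9.13 ± 2.64 % (2D),
5 + 6 designated active fractions, and an 18-sample (6 active vs 12
control) feature-table design. LC-MS intensities are log-normal
(multiplicative σ = 0.2, the standard peak-area noise model); within-scan
isotopologue ratios get a much tighter σ = 0.02, as isotope ratios are far
more stable than absolute areas. m/z error is uniform within ±2.5 ppm
(5 ppm peak-to-peak, a calibrated-Orbitrap regime); intensities below a
10⁴ LOD are written as 0 and so exercise the imputation rule. Spiked
compounds appear as [M+H]⁺ plus probabilistic [M+Na]⁺/[2M+H]⁺/[2M+Na]⁺
series at a shared retention time; Cl/Br formulas emit isotopologue
features above a 5 % relative-abundance floor; decoy features appear in
both groups at comparable abundance. MS2 spectra use seeded per-scaffold
fragment sets (not in-silico fragmentation) — enough to make analogs
cluster, not to predict real fragmentation chemistry.

What passing the closure test shows: on data with exactly the assumed
structure, the pipeline recovers ≥ 95 % of spiked actives as top-tier,
correctly dereplicated, correctly halogen-called features. What it does
not show: robustness to retention-time drift, chimeric MS2, in-source
fragmentation (beyond listed reference ions), matrix effects, or
real fragmentation similarity — the real screen's network statistics
(node counts, class shares, log₂FC ranges) and plate viabilities depend on
unreleased raw data and are represented here only by these structural
properties.

## Problem sizes and degenerate inputs

Default test problem sizes — 512-fraction screens, ~60-feature tables,
≤ 40-spectrum networks, 80-trial halogen grids — were chosen as the
smallest sizes at which the statistical assertions (95 % recovery rates)
are meaningful. Degenerate inputs fail loudly: zero-mean solvent controls,
equal control means in Z′, missing 3D viabilities, empty spectra, empty
databases, overlapping collection windows, and non-positive imputation
constants all raise with specific messages rather than propagating NaNs.
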