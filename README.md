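# cyanoprio

Bioactivity-guided prioritization of cyanobacterial natural-product
fractions by untargeted metabolomics.

Drug-discovery programs built on microbial culture collections screen
libraries of chromatographic fractions for cytotoxicity, then have to work
out *which* mass features in an active fraction plausibly carry the
activity. `cyanoprio` implements that prioritization pipeline end to end
for a library of HPLC fractions screened against 2D/3D colon-carcinoma
(HCT 116) and non-carcinogenic (hCMEC/D3) cell models:

1. **Screening statistics** (`cyanoprio.screening`) — viability
   normalization to the solvent control
   (%viability = 100·x̄(A_sample)/x̄(A_control)), assay-window QC by the
   Z′-factor Z′ = 1 − 3(σ_p+σ_n)/|μ_p−μ_n|, hit calling against a
   positive-control-anchored threshold μ + kσ (default k = 3), and
   partitioning of hits into a broadly cytotoxic group A versus a
   spheroid-selective group B.
2. **Fold-change ranking** (`cyanoprio.features`) — MZmine-style
   quantification tables, literal missing-value imputation (absent/zero →
   1, no normalization), FC = mean(active)/mean(control) per feature, and
   selection tiers on log₂(FC) (≥ 2 network tier, ≥ 20 top tier).
3. **Molecular networking** (`cyanoprio.networking`) — modified-cosine
   similarity on √-transformed MS2 intensities with precursor-shifted
   fragment matching, network topology constraints (cosine ≥ 0.7, ≥ 6
   matched peaks, mutual top-10 edges, components ≤ 100 nodes), and
   majority-vote chemical-class propagation over components.
4. **Dereplication** (`cyanoprio.dereplication`) — collapsing co-eluting
   [M+H]⁺/[M+Na]⁺/[M+K]⁺/[M+2H]²⁺/[2M+H]⁺/[2M+Na]⁺ series to neutral
   masses, exact-mass matching against a local compound database with a
   ppm tolerance, Cl/Br detection from M+2 isotopologue features, and
   single-step derivative annotation (±CH₂, ±O, Cl↔Br, …).
5. **Mass calculus** (`cyanoprio.chem_mass`) — formula parsing,
   monoisotopic masses, adduct m/z arithmetic,
   Δppm = (m/z_obs − m/z_calc)/m/z_calc·10⁶, nominal-mass isotope-envelope
   simulation, and halogen-count scoring.
6. **Synthetic data** (`cyanoprio.synthetic_data`) — seeded generators for
   plate screens and LC-MS feature tables/MS2 spectra with full ground
   truth, so the whole pipeline is testable without instrument data.

## Worked example

```python
from cyanoprio.chem_mass import (adduct_mz, get_adduct, monoisotopic_mass,
                                 ppm_error, round_half_away)
from cyanoprio.screening import (assign_groups, call_hits, hit_threshold,
                                 load_reference_screen)

# exact-mass annotation of a cyclic-peptide candidate
M = monoisotopic_mass("C74H109N13O22")
calc = adduct_mz(M, get_adduct("[M+H]+"))
print(round(M, 4), round_half_away(ppm_error(1532.7887, calc), 2))

# hit calling on the bundled fraction-screen summary
viab = load_reference_screen()
pos = next(v for v in viab
           if v.role == "positive_control" and v.cell_model == "3D_HCT116")
thr = hit_threshold(pos)                  # mu + 3 sigma
hits = call_hits(viab, thr, "3D_HCT116")
groups = assign_groups(viab)
print(thr, len(hits),
      sum(g.group == "A" for g in groups), sum(g.group == "B" for g in groups))
```

prints

```
1531.7810 0.27
82.12 11 6 6
```

i.e. the neutral monoisotopic mass of C₇₄H₁₀₉N₁₃O₂₂ is 1531.7810 Da, the
observed [M+H]⁺ ion deviates by +0.27 ppm from the calculated value (a
confident match), the spheroid hit threshold is 82.12 % viability, 11 of
the 23 test fractions are hits, and the hits split into 6 group A and 6
group B fractions (the positive control partitions into group A).

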