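# Methods

## Mass arithmetic

All masses are monoisotopic. Atomic masses come from the standard table
shipped with pyteomics (≥6 decimal places); the proton mass is fixed at
1.007276 Da. Residue masses are derived from elemental compositions
(pyteomics' standard residue table) and validated against those
compositions to 1 µDa at table construction. β-alanine is a first-class
residue code `bA` (C₃H₅NO, 71.03711 Da) — mass-identical to alanine, which
is precisely why the carnosine-TAT1 isomers cannot be separated by mass and
position-sensitive methods are needed. Sequence strings accept hyphen- or
bracket-delimited multi-character tokens (`GRKKRRQRRRPS-bA-H`,
`GRKKRRQ[bA]HRRRPS`), resolved greedily longest-code-first.

Fragment conventions: bᵢ counts i residues from the N-terminus, yⱼ counts j
from the C-terminus, 1-based. A b-type neutral mass is the residue sum;
y-type and precursor add one water. Ion m/z is
`(neutral − Σ losses + z·m_p)/z`; a neutral loss shifts a z-charged ion by
exactly `−mass/z`, which halves loss masses on the ubiquitous 2+ precursor
and makes the 0.5 Th spacing between −H₂O and −NH₃ products a charge-state
signature.

The neutral-loss catalogue (ammonia 17.0265, water 18.0105, carbodiimide
42.0218, guanidine 59.0483 Da) stores the values as commonly printed in the
CID literature; each is cross-checked against its formula within 1e-3 Da
(actual deviations ≤ 6.5e-5 Da). The widely quoted peptide mass 1788.0654 Da
differs from the formula-derived value (1788.0680 Da) by ≈2.6 mDa; the
package computes from formulas and treats the printed value as correct to
±5 mDa. Average masses, isotope patterns, and non-proton adducts are out of
scope.

## Fragment enumeration

`build_catalogue` unions three families and deduplicates by
(kind, residue composition, charge, loss multiset), sorting by m/z:

* **Conventional**: all bᵢ (including the full-length, water-deficient bₙ,
  which is the water-loss species of the intact precursor and is routinely
  observed for these peptides) and yⱼ at charges 1..max (default 2), plus
  the intact precursor as a loss-series base.
* **Loss series**: every loss multiset of size 1..4 (default), capped at
  4×NH₃ and 2×H₂O per ion, and at the ion's arginine count for carbodiimide
  and guanidine — those two molecules originate from arginine side-chain
  termini, so an ion cannot shed more of them than it has arginines.
  Combinations exceeding a cap or the fragment mass are silently excluded.
* **Scrambling**: modelled purely combinatorially. The full-length b ion
  cyclises head-to-tail; reopening at any amide bond yields a b-type ion
  for every contiguous substring of the cyclic sequence (every start, every
  length ≥ 2 by default). Full-length rotations are `scrambled_b` (one
  composition, one m/z — rotations survive only in provenance); shorter
  spans are `internal_b`, a superset of classical internal ions. No
  energetics are attached: the model must merely contain every pathway an
  experiment can realise. a/c/x/z and immonium ions are excluded (never
  needed for these spectra) but the enumeration is trivially extensible.

## Mass degeneracies and annotation

Annotation assigns each peak the candidate minimising |Δm/z| within a
tolerance (default 0.02 Th absolute; ppm mode available). Exact ties are
real, not numerical accidents: guanidine is elementally CH₂N₂+NH₃, so
{−CH₅N₃} ≡ {−CH₂N₂, −NH₃}; the precursor−H₂O ≡ b₁₄; and for T-Car-T the
scrambling-route ion bβ²⁺−H₂O (internal `RRRPSGRKKRRQ` − H₂O) is
elementally identical to the conventional b₁₂²⁺−CH₂N₂
(P+S+CH₂N₂ = bA+H+H₂O = C₉H₁₄N₄O₃). Ties are resolved toward the least
exotic explanation — fewest losses, then conventional > internal >
scrambled kind, then lower charge — and judged with a 1e-4 Th equidistance
margin so that the printed-vs-formula loss-mass differences cannot break a
physically meaningless tie. Consequence: the T-Car-T diagnostic at m/z
772.98 is reported as [b12−CH2N2]2+ even though the consecutive-loss series
it anchors argues for the scrambling route; m/z alone genuinely cannot
decide, and the catalogue keeps both candidates (exhaustive mode returns
all matches).

## Spectra and preprocessing

Formats: MGF (scan per voltage, metadata as `key=value` TITLE tokens, via
pyteomics), mzML (voltage from the standard collision-energy cvParam; read
with a compact lxml-based parser covering centroid/profile float arrays
with optional zlib compression), and two-column CSV peak lists with a
per-directory `metadata.tsv` sidecar. Missing voltage/precursor metadata is
an error, never a default.

Profile spectra are smoothed with a Savitzky–Golay filter (5-point window,
order 2 — the standard order for that window) and centroided: each local
maximum above a base-peak-relative threshold claims its contiguous
above-threshold region up to the neighbouring minima; peak m/z is the
region's intensity-weighted centroid (unbiased on symmetric peaks to well
under a tenth of the profile spacing). Alignment across spectra is
single-linkage clustering in 1-D — split the sorted peak list at gaps
larger than the tolerance (default 0.02 Th, matching >15,000 resolution
below m/z 900) — with consensus m/z the intensity-weighted cluster mean.
Intensities are arbitrary units; TIC normalisation divides by the summed
intensity.

## Energy-resolved curves

Survival Yield at one voltage is the precursor window's share of TIC;
target intensity is the sum of centroids within ±0.05 Th (default) of the
target m/z, so isotope peaks beyond the window deliberately count as
fragments — an explicit, configurable policy. Absent peaks contribute 0
(absence of a diagnostic ion in the other isomers is evidence, not missing
data). Replicates at a voltage are averaged after TIC normalisation so
unequal ion currents do not weight them; SY itself is scale-invariant. No
CE₅₀ interpolation enters the analysis; a logistic-fit utility
(`fit_sigmoid`) is provided for summaries.

## NIPALS PCA and diagnostic ranking

Columns are mean-centred only — no variance scaling. This is load-bearing:
with unscaled columns, loading magnitude tracks a variable's intensity
variation and hence fragment abundance, which is what makes the loading
plot readable as an abundance-ordered list of markers. NIPALS extracts one
component at a time (seed score = highest-variance column; alternate
p = Xᵗt/tᵗt, normalise, t = Xp; converge when the relative score change
drops below 1e-9; deflate X ← X − tpᵗ; at most 500 iterations by default,
raisable for near-degenerate eigenvalue pairs where power iteration is
slow). Explained variance per component is ‖t‖²/total SS × 100. Signs are
fixed by making each loading vector's largest-magnitude element positive.
Components requested beyond the matrix rank return zero vectors and are
flagged, not errored. A centred 3-sample matrix has rank ≤ 2, so two
components always explain exactly 100% — the expected signature when one
spectrum per analyte enters the PCA.

Diagnostic ranking uses known group labels (the analyst knows which
peptide produced which spectrum): each group's direction is its normalised
mean score vector; a variable's specificity is the cosine between its
loading-plane vector and that direction; the ranking score is
specificity × loading magnitude, so abundant *and* group-aligned variables
rank first, with deterministic m/z tie-breaks. The pairwise cosine matrix
of loading vectors exposes consecutive-fragmentation series as near-unity
blocks. Range restriction (e.g. to m/z 600–800, excluding the non-specific
loss region) drops variables without re-normalising rows: TIC refers to
the full acquired spectrum, which is normalised before any windowing.

## Synthetic data generator

The generator emulates the study conditions: three isomeric 2+ precursors
at m/z ≈ 895.04, voltages 20–42 V in 2 V steps, 3 replicates. Precursor
depletion is logistic, SY(V) = 1/(1+exp((V−V₅₀)/w)) with V₅₀ = 32 V and
w = 2.9 V, chosen so the noiseless SY at 36 V is ≈ 0.20 — the regime
described as informative for diagnostic-ion discovery. Depleted intensity
is split over primary channels in proportion to weight × logistic gate;
each consecutive channel drains weight × gate of its parent's current
intensity through a later onset, which guarantees the child's breakdown
curve peaks lower and rises later (total child drain is capped at 95%).
Kinetics are phenomenological logistics, not RRKM theory.

Channel m/z values are looked up in the fragment catalogues, never typed
in: the four shared channels are the precursor losses −NH₃, −CH₂N₂, −CH₅N₃,
and the consecutive −CH₅N₃−NH₃ (886.53/874.03/865.52/857.00); the specific
channels are the y₁₂−H₂O−NH₃ series for Car-TAT1 (773.47 →
764.96/752.46/743.95), the scrambling-route bβ−H₂O series for T-Car-T
(772.98 → 764.47/751.97/743.46), and b₁₀/b₁₁ with losses for TAT1-Car
(689.95→668.93, 738.47→729.96). Scrambled ions are enumerated only in the
T-Car-T catalogue, the one isomer whose diagnostics require them. Specific
channels carry ~1–2% of TIC at 36 V (weights fixed a priori from the
"low-intensity diagnostic" premise, graded within each series so abundance
ordering is testable). Noise is multiplicative log-normal (σ = 0.05),
additive uniform baseline (0.1% of base peak), and Gaussian m/z jitter
(0.003 Th), all seeded; identical seeds give bit-identical spectra. Spectra
are emitted as centroid peak lists (profile synthesis exists only to test
the centroider).

What the simulator does *not* emulate: isotope envelopes, charge-state
mixtures, chemical background, detector saturation, peak-shape effects, or
genuinely unknown fragmentation channels. Passing the end-to-end recovery
tests therefore shows the pipeline is correct and sensitive under the
assumed structure, not that any real instrument will show these exact
intensities or variance splits.

## Numerical choices and degenerate inputs

Single-row matrices cannot be centred (error); all-zero matrices have no
variance (error); empty spectra cannot yield SY (error); macrocycles need
≥3 residues (error); cyclic channel graphs are rejected. Non-physical
loss combinations (loss mass ≥ fragment mass) are excluded from catalogues
and rejected by `ion_mz`. Comparisons against 2-decimal literature m/z
round half-to-even with ±0.01 Th tolerance. Conservation identities
(SY + Σ breakdown fractions = 1) hold to 1e-9 on noiseless data (floating-
point summation, not model error).

## Problem sizes

Default test/demo sizes: 14-residue peptides, catalogues of ~2.8k ions
(conventional+losses) to ~18k (with scrambling); 9 spectra × ~12 variables
in the PCA window; 20-seed recovery studies; oracle comparisons on random
matrices up to 10×50 against dense SVD. These sizes exercise every code
path while keeping the whole suite under a minute of compute.
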