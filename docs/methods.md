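# Methods

This note documents the models, conventions and numerical choices behind
`dimerqa`, and what its synthetic benchmark does and does not demonstrate.

## Data model and parsing

Structures are reduced to protein heavy atoms: hydrogens, waters and
non-amino-acid groups are dropped (with a warning), alternate locations
collapse to the highest-occupancy atom (ties broken by file order), and each
residue's B-factor is the mean over its kept heavy atoms. All confidence
matrices are indexed by the 0-based concatenated residue index in chain
order; author chain IDs and residue numbers are retained for reporting only,
because predictors renumber from 1.

Per-residue pLDDT is always taken from the confidence record, never from the
coordinate file's B-factor column, so ColabFold (PDB + scores JSON) and
AlphaFold3 (mmCIF + confidence JSON) inputs behave identically downstream.
AlphaFold3 atom-level pLDDT is aggregated to residues by an unweighted mean
over heavy atoms — a symmetric, assumption-free rule; the upstream tools do
not document theirs. Token-level PAE rows are mapped to residues through the
record's chain/residue token identifiers; non-protein tokens are dropped
with a warning. The PAE diagonal keeps the file's values and the matrix is
not symmetrized. Reference structures may lack pLDDT; scores that need it
fail at computation time, not at parse time, so references remain usable for
DockQ.

## Interface definition

A residue pair is an inter-chain contact iff the minimum distance between
any heavy atom of one and any heavy atom of the other is strictly below the
cutoff (default 5 Å). The strict `<` mirrors the "less than 5 Å" convention;
DockQ-style tools often use `≤`, which matters only for atom pairs at the
exact boundary. Contact search uses a k-d tree with an explicit strict-
inequality re-check, so it is exactly equivalent to the brute-force all-pairs
scan (asserted in tests). Contact sets are nested across cutoffs, which is
why the 5–9 Å distance sweep changes ipLDDT/iPAE only marginally on
smooth-confidence inputs.

Two filters define a usable heterodimer: at least 3 interface residues on
each chain, and at least 50 residues in every chain (both boundaries
inclusive). Interface "flexibility" is the residue-level mean of per-residue
B-factors over the interface residues (mean of means, not atom-pooled) — the
finer-grained choice is not determined by convention, so it is stated here.

Contact clustering into distinct interface patches uses single linkage over
representative points (midpoint of each contact's closest heavy-atom pair)
with a user-set linkage cutoff. This criterion is a configurable stand-in:
interface-delimiting tools differ here, and no canonical rule exists.

## Score panel

- ipLDDT: mean pLDDT over the union of interface residues of both chains.
- iPAE: mean of `pae[i, j]` and `pae[j, i]` over contact pairs, both matrix
  orientations equally weighted. This is the stricter contact-level reading
  of "interface PAE"; a cross-product mode over all interface residue pairs
  is provided for sensitivity checks, since both readings are in circulation.
- model confidence = 0.8·ipTM + 0.2·pTM, the AlphaFold-Multimer ranking
  convention. It is computed the same way for AlphaFold3 inputs (rather than
  adopting AF3's own ranking score) so all three method regimes are scored
  on one panel.
- pTM/ipTM are never recomputed from the PAE matrix; they are pass-through.
- pDockQ2 uses the published constants (L = 1.31, x₀ = 84.733, k = 0.075,
  b = 0.005, PAE damping scale d₀ = 10 Å); the implementation is checked
  against a separate straight-line transcription of the formula. Its values
  on realistic inputs are low compared to its nominal 0–1.3 range — a known
  property of the score, visible in its unexpectedly low optimal cutoffs.
- VoroIF is accepted as an input number only; re-implementing a GNN is out
  of scope and the published tool is the source of truth for it.

## Combined scores and classification

ipLDDT is divided by 100 and iPAE mapped to 1 − min(iPAE, iPAE_max)/iPAE_max
with iPAE_max defaulting to 31.75 Å, the PAE ceiling of the prediction
records; dataset-specific maxima can be supplied via the profile. The
unweighted combination is the mean of the available normalized scores; the
C2Qscore is the affine form `Σ w·ŝ + β` and is deliberately not clamped —
fitted combinations legitimately leave [0, 1]. If VoroIF carries weight but
is missing, the remaining weights are renormalized to preserve proportions
and the result is tagged `C2Qscore(noVoroIF)`; silently substituting 0 would
shift the score by the full VoroIF weight.

Classification against cutoffs is inclusive (`≥` for higher-is-better
scores, `≤` for the PAE family); the sources are silent on boundary
handling, so the inclusive reading is fixed here and tested explicitly.
The shipped profile carries the published per-method thresholds (ipTM
0.65/0.65/0.70; C2Qscore 0.55/0.48/0.52; gray zone 0.6–0.8). The shipped
regression weights are *not* published values: the published supplementary
weights are not available in this repository, so the profile ships weights
fitted once on the synthetic benchmark (seed 20250926) purely so the tool is
runnable out of the box. No numerical equivalence to the externally
published combined score is claimed; users calibrating on real predictions
should regenerate the profile with `dimerqa calibrate`.

## DockQ

DockQ = (fnat + 1/(1+(iRMS/d₁)²) + 1/(1+(LRMS/d₂)²))/3 with d₁ = 1.5 Å,
d₂ = 8.5 Å, fnat contacts at 5 Å heavy-atom distance, the iRMS interface at
10 Å, and backbone = N, CA, C, O. Class boundaries 0.23/0.49/0.80 are
inclusive on the lower edge (0.23 → acceptable, 0.80 → high); the prose
convention "DockQ > 0.8 / < 0.23" leaves the boundary itself ambiguous, so
the inclusive-upward choice is fixed and boundary-tested. Superposition is
the closed-form least-squares rigid fit (SVD with the determinant
correction; reflections forbidden). Receptor = the longer reference chain,
ties to the first mapped pair.

Chain mapping maximizes summed global-alignment sequence identity over both
permutations of the dimer (match 1, mismatch 0, small gap penalties);
identity below 30% on either chain requires an explicit proceed flag, and
exact ties (homodimer-like) fall back to the first permutation and are
flagged ambiguous. Residue correspondence comes from the alignment, not
author numbering. A conformance note: this is an independent implementation
of the DockQ definitions, not a wrapper around the published executable;
agreement with it has been verified only against this package's own oracles,
and users comparing against the published tool should expect differences at
exact-boundary contacts (strict `<` here) and in chain-mapping options.

The multi-configuration mode evaluates a model against every candidate chain
pair of a larger assembly and reports per-configuration DockQ plus the best,
because a dimer whose partner has homologous copies in the assembly may
legitimately match an alternative placement while scoring near zero against
the nominal target pair.

## Calibration

Labels are binary: correct ⇔ DockQ ≥ 0.23. ROC cutoff candidates advance on
a per-family grid (pLDDT-type 5; PAE-type 1 Å; unit-interval scores 0.05)
anchored at the score's theoretical minimum (0); scores that can go negative
(fitted combinations) anchor at the grid point at or below their observed
minimum. Grid anchoring can move the chosen cutoff by up to one step, which
is why it is pinned down here. PAE-family scores are negated internally so a
single higher-is-better code path serves every score, and chosen cutoffs are
mapped back to the original scale. The selected cutoff maximizes TPR − FPR
(the max-distance-from-diagonal criterion up to a √2 factor); ties go to the
most permissive cutoff. AUC is computed threshold-free (trapezoidal over all
distinct score values) rather than on the grid: a grid-quantized AUC would
not be invariant under monotone rescaling of a score, which is a property
the package asserts. Tables whose AUC ≤ 0.6 are flagged unreliable.

Weight fitting is ordinary least squares on the normalized scores (rank
deficiency raises, naming the collinear features); the Lasso variant takes a
fixed user-supplied penalty (default, with the α = 0 limit delegating to
OLS) — automatic penalty selection is intentionally not performed by
default. The end-to-end pipeline compares the fitted and unweighted
combinations with a two-sided Wilcoxon signed-rank test paired on per-model
absolute deviation from DockQ; fewer than 6 informative pairs raises, and
all-zero differences report p = 1 with a degenerate flag. The equal-weight
subset search enumerates all 2⁵ − 1 subsets and ranks them by Pearson
correlation with DockQ.

## Synthetic benchmark: what it emulates, and what it does not

The generator produces idealized strand-like dimers (N/CA/C/O/CB at fixed
local offsets, CB pointing across the interface, small seeded jitter) with a
contiguous contact patch of exactly the requested width; residue identities
are random so sequence-based chain mapping behaves as on heterodimers.
Decoys are rigid-body perturbations of the second chain about the interface
centroid. The benchmark draws a latent quality q ~ U(0, 1) per model, maps
it to an in-plane rotation (up to 60°) plus register slide (up to 5 Å) so
chains stay in contact while the interface degrades, and generates
confidence records whose statistics track q: pLDDT ~ N(40 + 55q, (100·σ)²)
clipped to [0, 100]; inter-chain PAE ~ N(28(1−q) + 2, (30·σ)²) clipped at
the 31.75 Å ceiling; intra-chain PAE low; ipTM = q plus noise; pTM sharing
ipTM's noise component (ρ ≈ 0.8); a synthetic VoroIF tracking q. The noise
dial σ defaults to 0.05 — enough to make classification non-trivial near the
decision boundary without breaking score–quality correlation. Default
problem sizes (chains of 55–70 residues, patches of 6–10, 200 models per
benchmark half) keep the full pipeline in the seconds range while leaving
every statistic well-populated; they are stated here because all reported
synthetic results are conditional on them.

What passing tests show: the geometry, score definitions, DockQ components
and calibration machinery are internally consistent, agree with independent
brute-force oracles, and recover planted structure. What they do not show:
performance on real predictor output. Real AlphaFold failure modes (domain
swaps, fold errors, compositional confidence biases) are absent from
rigid-body decoys, the synthetic score-noise model is Gaussian and
independent across scores given q, and the shipped weights therefore carry
no claim about real-data accuracy.

## Known limitations

- Heterodimers only; larger assemblies are handled solely via pairwise
  extraction, and no multi-interface aggregation is attempted.
- No buried-surface-area or energetic interface definitions.
- Cutoff calibration is binary (correct vs incorrect); no multi-class or
  probability calibration of the combined score.
- The clustering criterion for interface patches is a documented stand-in.
- DockQ conformance against the published executable is untested here
  (no network access to references); the constants and conventions above
  define this implementation's behavior.
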