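# dimerqa

Quality assessment for predicted protein **heterodimer** complexes.

AlphaFold2/ColabFold and AlphaFold3 routinely produce dimer models whose
global confidence looks reasonable while the inter-chain interface is wrong —
and the widely used ipTM "gray zone" (0.6–0.8) leaves exactly those cases
undecided. `dimerqa` is aimed at structural biologists who need to triage
such predictions: it computes the full panel of interface-aware confidence
scores from the predictor's own output, combines them into a single
calibrated score with per-method correct/incorrect cutoffs, and — when a
reference structure exists — evaluates models with DockQ so the cutoffs can
be recalibrated on your own data.

## What it computes

**Reference-free scores** (from the model + its confidence record):

- pLDDT and PAE global means; **ipLDDT** and **iPAE**, their restrictions to
  the inter-chain interface (residues with any heavy-atom pair < 5 Å);
- pTM and ipTM (pass-through from the predictor), and *model confidence*
  = 0.8·ipTM + 0.2·pTM;
- **pDockQ2** = L / (1 + e^(−k(x − x₀))) + b with
  x = ⟨pLDDT⟩₍iface₎ · ⟨1/(1 + (PAEᵢⱼ/d₀)²)⟩₍contacts₎
  (L = 1.31, x₀ = 84.733, k = 0.075, b = 0.005, d₀ = 10 Å);
- an externally supplied VoroIF-GNN interface score, if available;
- the combined **C2Qscore** = Σ wₛ·ŝ + β over the normalized scores
  ŝ ∈ {ipLDDT/100, 1 − iPAE/iPAE_max, pTM, ipTM, VoroIF}, with weights from a
  linear regression against DockQ, plus the plain unweighted mean.

**Reference-based ground truth**:

DockQ = (fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3, with CAPRI
classes incorrect < 0.23 ≤ acceptable < 0.49 ≤ medium < 0.80 ≤ high, chain
mapping by global sequence alignment, and a multi-configuration mode for
dimers extracted from larger assemblies.

**Calibration**: Pearson correlations, stepped ROC curves with
maximum-distance-from-diagonal cutoff selection (grid steps 5 for pLDDT-type,
1 Å for PAE-type, 0.05 otherwise), AUC, confusion metrics, Wilcoxon
signed-rank comparisons, exhaustive equal-weight subset search, and OLS/Lasso
fitting of the combined score.

The shipped profile carries the published per-method decision thresholds
(ipTM: 0.65 / 0.65 / 0.70 and C2Qscore: 0.55 / 0.48 / 0.52 for
ColabFold+templates / ColabFold−templates / AlphaFold3); the regression
weights in it were fitted on this package's synthetic benchmark and are meant
to be replaced by weights calibrated on real predictions (`dimerqa calibrate`).

## Worked example

The package ships a synthetic generator, so the whole workflow runs without
any downloads. Generate two ColabFold-dialect models with graded decoy
quality, score them, and compare one against its reference:

```sh
$ dimerqa fixtures --n-models 2 --seed 7 --out demo
$ dimerqa score --method cf-t --dialect colabfold \
    demo/model_000_*.pdb demo/model_000_*_scores.json \
    demo/model_001_*.pdb demo/model_001_*_scores.json
model_id	method	plddt	pae	iplddt	ipae	ptm	iptm	model_confidence	pdockq2	voroif	unweighted	c2qscore	classification	grayzone
model_000_s2029167940	CF-T	89.007	3.35418	88.4558	4.97826	0.878464	0.92254	0.913725	0.341665		0.882192	0.624341	correct	high_conf
model_001_s1342382291	CF-T	82.3285	5.23169	80.4289	7.926	0.878959	0.869721	0.871569	0.0937516		0.825833	0.489029	incorrect	high_conf
```

Model 000 has a tight interface (iPAE ≈ 5.0 Å, ipLDDT ≈ 88) and a C2Qscore
of 0.62, above the CF-T cutoff 0.55 → classified *correct*. Model 001 looks
almost as confident globally (ipTM 0.87) but its interface is weaker
(iPAE ≈ 7.9 Å) and its C2Qscore 0.49 falls below the cutoff → *incorrect*.
The `grayzone` column is the AlphaFold-server ipTM guidance; both models sit
above 0.8 there, which is exactly why an interface-aware combined score is
useful. The reference-based check agrees:

```sh
$ dimerqa compare --model demo/model_000_*.pdb --reference demo/target_000_*_ref.pdb
pair	fnat	irms	lrms	dockq	capri_class	best
A-B	1	0.784047	9.15448	0.749465	medium	True
```

All native contacts are reproduced (fnat = 1) but the ligand chain is
displaced (LRMS 9.2 Å), giving DockQ 0.75 — a *medium*-quality model.

Recalibrating cutoffs and weights from a scored table with a `dockq` column:

```sh
$ dimerqa calibrate --table scores.tsv --method cf-t --profile-out my_profile.toml
$ dimerqa score --config my_profile.toml ...
```

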