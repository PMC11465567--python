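# Methods

This note documents the statistical model behind `trypstat`, the synthetic
study generator's assumptions and calibration, the numerical choices made
where the design was genuinely open, and the limits of what the tests show.

## Peptide chemistry

All masses are monoisotopic, in daltons, built from IUPAC/CODATA atomic
masses (H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196,
S 31.97207100). The peptide mass convention is MH — the singly protonated
mass, i.e. residue masses + H2O + one hydrogen atom. Modification deltas
are computed from elemental compositions (negative counts express losses,
e.g. deamidation = +O −N −H = +0.984016 Da); carbamidomethylation of
cysteine (CAM) is +57.021464 Da, oxidation +15.994915 Da. The computed
C-terminal hydroxyl delta is 17.002740 Da; a commonly printed value,
17.002735, differs in the sixth decimal and is treated as a rounding
artifact — the computed value is used.

Digestion is fully tryptic, `[RK]|[X]`: cleavage after every K or R with no
proline exception by default (a `no_cleave_before_proline` switch exists
for interoperability with engines that apply the proline rule). Peptides
with 0..`max_missed` missed cleavages are enumerated; a peptide's missed
cleavage count equals its number of internal K/R residues.

Precursor delta masses (observed − theoretical MH) are classified to the
nearest integer isotope class at a spacing of 1.00335 Da; a delta is
in-band when its residual from the class is <= 0.5 Da and the class lies in
[−2, +4]. Out-of-band deltas are flagged, never dropped.

## The synthetic study generator

The generator emulates the *statistical shape* of a three-treatment plasma
digestion study, not its physics. Defaults (all in `SimParams`) are the
study conditions; the run layout (`TreatmentDesign`) is 4 + 15 + 3×24 = 91
runs per treatment, 273 runs total, 29 blank runs, at 2,000 spectra per
run — a reduced scale (546,000 spectra vs millions) that keeps a full run
around half a minute on one CPU. All scales are configurable; a single
global seed fans out to fixed per-component child streams so any stage is
reproducible in isolation.

**Database.** 2,000 proteins: one albumin analog (585 aa, 17 disulfides,
50% of sample mass), ~1,959 "normal" proteins with lognormal lengths
(median 360 aa, σ 0.35) and power-law mass shares (rank^−0.7, renormalized
so albumin keeps its 50%), and 40 giant proteins of 24,000 aa at
effectively zero abundance. The giants are the random-match sink (see
below). Residue frequencies approximate the human proteome; a small set of
duplicate "historical" accessions shares gene symbols to exercise symbol
collapse.

**Digestion and competition.** Each disulfide contributes a shielded span;
the albumin analog is ~98% shielded, normal proteins ~8% per disulfide
(Poisson mean 1). A peptide inside shielded spans carries its weight times
the treatment's reduction-release fraction: T 0.15, DT 0.90, DAT 1.00.
Within a protein, peptide weights are flyability (lognormal, σ 1.5) ×
missed-cleavage penalty (1, 0.25, 0.04) × a mass-detectability factor
(log-Gaussian around 1,700 Da with a hard 700–4,500 Da window, standing in
for the instrument's m/z transmission optimum), normalized by the protein's
fully released flux so that a fully released protein's total weight equals
its abundance fraction. Spectra are then allocated multinomially over the
pooled weights — this renormalization *is* the ionization/cycle-time
competition mechanism, and it is the minimal one: the study being emulated
states the phenomenon, not a quantitative model.

*Albumin release calibration.* With albumin fully shielded, the T:DAT
albumin spectral-count ratio has the closed form 2x/(x+y), where
x = release_T and y is the mean released fraction of the other proteins
(~0.93 at these defaults). A release_T of 0.25 bounds the ratio below at
~0.40; reproducing the reference ratio of ~0.30 requires release_T ≈ 0.15
with ~98% albumin shielding, which is what the defaults use. Ten seeds at
defaults give ratios 0.29–0.32.

**Spectra.** Charge is Bernoulli: 56% 2+, else 3+. ln-intensity is
N(5.5, 0.75) — spanning roughly e4–e7 counts. Isotope classes are drawn
with probabilities 0.60/0.25/0.10 on 0/+1/+2 and 5% spread over −2, −1,
+3, +4, plus N(0, 0.03) jitter clipped at ±0.1 Da. CAM is applied to
cysteine peptides as a deterministic weight split at the treatment's CAM
rate (T 0.08, DT 0.08, DAT 0.90) rather than by sampling, and only the
first cysteine is annotated.

**Matches and engines.** 90% of spectra are true matches; 5% are spurious
matches drawn from a decoy distribution proportional to the parent
protein's tryptic fragment count (the length proxy that concentrates random
matches in giant proteins); 5% are contaminant spectra from a 500-peptide
noise pool shared with the blank runs. Both engines score every spectrum:
each assigns the correct peptide with probability 0.92 (GOF) / 0.85
(XCORR), otherwise a decoy. True-match GOF p-values are Beta(0.3, 8)
(skewed to 0) and false ones Uniform(0, 1]; true XCorr is N(3.2, 0.8)
truncated at 0 and false N(1.2, 0.5) truncated at 0 — chosen so the
acceptance thresholds (p <= 0.1, XCorr >= 2) sit in the discriminative
region, since the emulated engines publish thresholds, not score
distributions. 30% of spectra emit worse-scoring rank-2 candidates so the
consolidation step has real work. Contaminant spectra are genuine matches
to noise peptides and receive true-model scores; only the blank filter can
remove them, which is the point.

**Controls.** Blank runs draw from the noise pool (plus an optional 2%
carryover of genuine sample peptides) at 400 spectra per run. The random
null assigns `n_random_spectra` to peptides by the decoy distribution; the
default is 150,000. This size is a power choice: one control count is
worth total_exp/n_random expected experimental counts, and at 30,000 random
spectra that quantum (~18 counts) is comparable to a low-abundance
protein's entire spectral count, so Poisson noise in the control would
randomly discard ~10% of true tail proteins. At 150,000 the quantum is
~3.6 counts and the loss is negligible.

## Frequency correction

Both filters are one-degree-of-freedom chi-square tests of the observed
experimental count against the count expected under the control's rate,

    E = max(total_exp · count_ctrl / total_ctrl, pseudocount),
    chi2 = (count_exp − E)² / E,

with retention iff chi2 >= 9 (p <= 0.0027 <= 0.01) **and** the experimental
normalized frequency exceeds the control's raw frequency. Normalization
totals are total MS/MS per source (per-run and per-peptide-sum bases exist
as alternatives in principle; counts-per-spectra is the default and the
only one wired in).

The pseudocount (0.5) is a *floor on the expected count*, not an additive
smoothing of the control rate. The additive form
E = total_exp·(c+0.5)/(T+0.5) makes the floor scale as total_exp/total_ctrl
— about 23 expected counts when 546,000 experimental spectra are judged
against an ~12,000-spectrum blank pool — which would discard essentially
every low-count true peptide and reduce a never-seen-in-control peptide to
a significance test against an imaginary rate. With the floor form, a key
the control never saw needs only 3 observations to resolve (chi2 =
2.5²/0.5 = 12.5 >= 9), while keys the control did see are judged against
the control's actual rate.

**Key levels.** The blank filter runs at the peptide-sequence level
(contaminants are specific sequences). The random filter runs at the
gene-symbol level: random matches are a property of a protein's length, and
pooling a symbol's peptides is the only construction with power to remove
a random-match-inflated giant at reduced control scale — at the peptide
level, individual giant peptides with a lucky zero control count slip
through and re-assemble the symbol. A peptide survives the symbol-level
filter if any of its symbols is resolved. Both levels are configurable;
the hard discard-on-any-overlap blank mode is available as an option.
Filter order is blank first, then random, matching the accounting column
order; both filters are idempotent and conserve counts
(retained + discarded = input).

## Consolidation, inference, agreement

BFPS keeps the best-scoring candidate per spectrum key (minimal p for GOF,
maximal score for XCORR) with a fully deterministic tie chain: score, then
smallest |observed − theoretical MH|, then lexicographically smallest
peptide, then smallest rank. The selected set is invariant to input row
order and the operation is idempotent. No specific keyed store is mandated;
pandas group-wise selection satisfies the uniqueness contract.

Rollup maps each peptide to every accession whose digest contains it and
collapses accessions to gene symbols; shared peptides count toward every
symbol (documented consequence: summed spectral counts can exceed the PSM
count). Unmappable peptides go to an orphan report. The protein p-value is
Fisher's method over the best (minimum) p per distinct supporting peptide —
the emulated study says "cumulative" without printing a formula, and
Fisher's is the canonical reading; it is exact for k = 1 and ignores
p = 1 contributions by construction. q-values are Benjamini–Hochberg
step-up, computed per engine over that engine's full corrected symbol list,
and verified against both a brute-force step-up and statsmodels.

The log–log engine regression is OLS of ln(count_B) on ln(count_A) over
shared symbols with count_A >= 3 and count_B >= 1 (natural log, zero-count
symbols excluded — a log–log scatter has no zeros). Both model and residual
df are reported because an "F on N df" statement is ambiguous between them.
A constant response makes R² undefined (NaN propagates from the fit); the
treatment contrast is a (k−1)-df chi-square per symbol against expectations
proportional to treatment totals, BH-adjusted over symbols, symmetric under
relabeling.

## What passing tests do and do not show

On the simulator's ground truth at defaults, the pipeline recovers >= 90%
(measured ~97%) of truly present proteins with >= 3 sampled peptides at
q <= 0.01, admits <= 5% (measured 0%) false symbols, removes >= 95%
(measured ~98%) of noise-pool-only peptides via the blank filter, and
removes all 40 giant decoys via the Monte Carlo filter. This validates the
*counting machinery* — consolidation, the two null corrections, FDR
inference — under a generative model whose assumptions are stated above.
It does not validate search-engine scoring (engines are simulated, not
implemented), fragment-level identification, retention-time structure,
shared-peptide ambiguity at real-proteome homology levels (random sequences
share few peptides), or the simulator's simplified competition model. The
simulated engines also agree far more strongly (R² ≈ 0.98) than two real
engines with different scoring principles would, because both observe the
same simulated spectra with high assignment accuracy; the cross-engine
regression here checks the statistic, not realistic inter-engine variance.

Headline full-scale quantities (e.g. 5,410,083 MS/MS, 171,446 matched
distinct spectra, 2.6%/7.7% acceptance, the ~30% albumin T:DAT ratio) enter
only as shipped reference-count tables: the accounting code reproduces
their internal arithmetic exactly, and the simulator is calibrated to the
albumin ratio, but proteome-scale counts are not reproducible from a
reduced-scale simulation and are not claimed.

## Degenerate inputs and numerical conventions

Empty protein sequences digest to empty lists; empty pools threshold and
roll up to empty tables; the tier report of an empty rollup is all zeros.
Chi-square filters require positive totals and reject unknown modes/levels.
GOF scores are clamped to (0, 1] at generation (floor 1e-16); truncated
normals use scipy's truncnorm rather than clipping, to avoid atoms at 0.
Sorts are mergesort (stable) wherever order feeds a deterministic
selection; manifests exclude timings from any determinism comparison.
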