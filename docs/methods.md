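# Methods

This note documents the models implemented in `hdxpipe`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Peptide-level uptake quantification

An HDX-MS experiment measures, for each peptic peptide, the mass increase
(deuterium uptake, in daltons ~ deuterons) after exposure to D2O buffer for
a set of labeling times. The package aggregates replicate measurements into
per-(peptide, state, time) means and sample standard deviations (n − 1
denominator); cells with a single replicate carry no SD and are never
imputed.

**Exchangeable amides.** A peptide of length L has at most L − 1 backbone
amide hydrogens; prolines carry none. HDX software disagrees on how many
N-terminal residues to discount for fast back-exchange, so two conventions
are exposed: the default `skip_first` (N = L − 1 − prolines at positions
2..L) and `skip_first_two` (N = L − 2 − prolines at positions 3..L). The
convention is a config key; results tables record N.

**Back-exchange.** Each peptide's maximally labeled control gives

    BE% = (1 − (m_max − m0) / (N · D_frac)) · 100,

with m_max the control's centroid neutral mass, m0 the undeuterated mass
and D_frac the deuterium fraction of the labeling buffer (default 0.85).
BE is a QC quantity: values outside [0, 100] % are reported with a warning
rather than clipped, because a negative BE diagnoses an inconsistent
control or m0. Uptake is *not* BE-corrected by default; an explicitly
labeled corrected view (uptake / (1 − BE)) exists for diagnostics.

**Normalized uptake and butterfly plots.** Normalized HDX is the plain
ratio uptake / control-uptake; values above 1 are flagged, not clamped.
The butterfly comparison arranges two states' normalized uptake per peptide
in N→C order with the second state negated, giving a mirror image whose
asymmetry localizes differences.

Mass constants: deuterium−hydrogen difference 1.00628 Da; proton
1.00728 Da for m/z conversion. Undeuterated peptide masses are computed
with pyteomics when not supplied.

## Differential significance framework

One threshold is computed per state-vs-state comparison, not per peptide.
All available per-peptide, per-time replicate SDs from both states are
pooled into their arithmetic mean σ̄; the accumulated SD is
σ_ave = √n · σ̄ and the zero-centered two-tailed threshold

    CI = t_{1−α/2, n−1} · σ_ave / √n = t · σ̄,

with n the nominal replicate count (default 3, giving t = 4.303 at 95 %).
The two forms are algebraically identical and both are asserted in tests.

A peptide is called significant when any of three branches fires, evaluated
in fixed priority order:

1. **consecutive_CI** — |ΔD| > CI at ≥ 2 consecutive time points, where
   ΔD(t) = mean uptake(reference) − mean uptake(test);
2. **t_test** — a two-tailed, two-sample, pooled-variance Student t-test on
   the replicate uptake values rejects at α (default 0.01) at ≥ 2
   consecutive time points where both states have ≥ 2 replicates. The
   consecutiveness requirement is applied to this branch as well, keeping
   the two branches parallel and conservative;
3. **last_point_2xCI** — |ΔD| at the final time point alone is ≥ 2 · CI,
   catching differences still expanding at the end of the time course.

Direction: positive ΔD means decreased HDX (stabilization) in the test
state. The verdict takes the sign of the triggering ΔD values; if the
triggering points disagree in sign, the larger |ΔD| decides and the call is
flagged `direction_unstable`. Peptides with no replicated time points still
participate through branches 1 and 3 using the comparison-wide CI. No
multiple-testing correction beyond this rule is applied.

**Residue consolidation.** Peptide verdicts are painted onto residues:
unanimous significant coverage gives that verdict, disagreement gives
`mixed`, coverage by only non-significant peptides gives `none`, and
uncovered residues are `no_coverage`. Significant verdicts take precedence
over `none` from overlapping peptides. Coverage percentage is the union of
peptide intervals over the construct length (denominator configurable).

## EX1 detection by bimodal deconvolution

Under EX2 kinetics (fast H-bond reformation) a peptide's isotope envelope
migrates as one distribution; under EX1 (slow cooperative opening) two
populations — already-exchanged and yet-to-exchange — coexist and resolve
in m/z. The envelope intensity is modeled on the deuteration axis
d = (z·(m/z) − z·m_proton − m0)/1.00628 as a two-component Gaussian mixture
with shared width,

    y(d) = A · [w · G(d; c_hi, s) + (1 − w) · G(d; c_lo, s)],

with the amplitude A profiled out analytically. A Gaussian shape (rather
than exact binomial mixtures) was chosen for robustness to the unknown
natural-isotope convolution in real spectra; the generator produces
binomial-shaped populations precisely so the tests exercise this mismatch.
Initialization is a coarse grid over (c_lo, c_hi, w) at 0.25 D resolution,
scanned over several candidate widths (a single width derived from the
unimodal fit misranks configurations when the populations have visibly
different spreads), followed by bounded least-squares refinement of all
four parameters from the best grid points. The one-population model is fit
alongside; re-refining from the degenerate c_lo = c_hi start guarantees the
nested-model inequality SSR_bimodal ≤ SSR_unimodal. Ties between
equivalent labelings are broken by requiring c_hi ≥ c_lo.

A peptide is called EX1 when, at ≥ 2 consecutive time points, all of:
separation ≥ 2.0 D, both population fractions ≥ 0.15, and
SSR_unimodal / SSR_bimodal ≥ 3.0. These numeric criteria are package
defaults exposed in config — the literature describes bimodality
qualitatively, so thresholds are necessarily a design choice. When EX1 is
called, the opening rate is estimated by least squares of
−ln(1 − fraction_high) against time through the origin over the qualifying
points.

Degenerate inputs: an all-zero envelope has no centroid (error); fit
non-convergence yields a flagged result, never an exception; envelopes are
normalized to base peak 1 on ingest and need ≥ 5 points.

## Ligand occupancy and saturation binding

Labeling a receptor at ~0.3 µM with ligands of nanomolar-to-micromolar
affinity depletes the free ligand, so occupancy is computed from the
mass-action quadratic in total concentrations:

    B = [(L + R + Kd) − sqrt((L + R + Kd)² − 4LR)] / 2,  occupancy = B/R,

implemented in the conjugate form 2LR/(s + √disc) to avoid cancellation
when the bound fraction is small. The physical root satisfies
0 ≤ B ≤ min(L, R). Depletion-corrected occupancy is the default — the
high-affinity design points in this problem domain are only explicable
with depletion — and the free-ligand approximation L/(L + Kd) is exposed
for comparison. The design inverse is exact:
L = occ·R + Kd·occ/(1 − occ). Occupancy functions work in µM; the binding
fit in nM; converters are asserted in tests.

The activity assay fit subtracts a paired nonspecific series (interpolated
linearly in concentration when grids differ) and fits
specific = Bmax·L/(Kd + L) by nonlinear least squares (Kd₀ = concentration
nearest half-max signal, Bmax₀ = 1.2 × max), reporting estimates,
asymptotic standard errors and a convergence flag.

## Synthetic-data generator

The generator forward-simulates the statistical structure of a two-state
peptide-level HDX study of a 12-TM transporter, so that every analysis
stage can be verified against known ground truth:

- **Construct**: a deterministic pseudo-random 648-residue sequence
  (630-residue transporter plus a C-terminal protease site and His tag);
  62 peptides whose interval union covers 448 residues (69.1 %), with
  coverage starting at residue 70, a gap at 96–98, and an 11-residue
  segment at 99–109 reserved for EX1 kinetics. The sequence and map are
  synthetic stand-ins designed to the published study dimensions, not the
  real peptide table (which is not publicly deposited).
- **Kinetics**: Linderstrøm-Lang EX2 per amide, k_obs = k_int/pf with a
  single configurable intrinsic rate (default 100 min⁻¹ — fast relative to
  the 0.25-min first time point at pH 8, 25 °C; a per-amide table can be
  supplied). Protection factors are the free lever: log-uniform over
  10–10⁶ so observed timescales straddle the 0.25–480 min grid.
- **Design**: D_frac 0.85; time grid 0.25, 1, 10, 60, 480 min; triplicates
  at 0.25, 10 and 60 min and single measurements elsewhere; additive
  Gaussian replicate noise, default SD 0.079 D; uniform 25 % per-peptide
  back-exchange (no published per-peptide values exist, so this default is
  a free choice, flagged in config); max-label controls at
  N·D_frac·(1 − BE) plus the same noise.
- **Designed differences** are additive offsets on the observed-uptake
  scale applied to the test state, clipped at the physical ceiling
  N·D_frac·(1 − BE). Peptides in designed regions draw protection factors
  from the slower 10³–10⁶ band so the offset is not clipped at early/mid
  time points — a real destabilization acts on protected amides. At the
  latest time point clipping can shrink (never flip) the designed
  difference.
- **EX1 segment**: in the test state, the 99–109 peptide is a
  two-population mixture with opening rate 0.03 min⁻¹ and seven correlated
  amides, giving an expected population separation of 7 · 0.85 ≈ 5.95 D —
  which rounds to the six-deuteron separation the design emulates (six
  amides at 85 % D would give 5.1 D and round to 5). Envelopes are exact
  Poisson-binomial stick spectra (iterative Bernoulli convolution),
  optionally convolved with a natural-isotope distribution, with 1 %
  intensity noise; back-exchange thins per-amide probabilities
  independently. Envelopes are emitted only for designated peptides to
  keep outputs small.
- **Binding assay**: total = Bmax·L/(Kd+L) + ns·L and a paired
  nonspecific series ns·L, each under unit-mean lognormal noise of given
  CV; defaults are triplicates over 1–48 nM with 5 % CV.
- **Determinism**: one top-level seed; all draws flow from it via seed
  sequences; the same seed reproduces byte-identical files, and the seed
  is written into output headers.

A note on the noise default: the mean *sample* SD of n = 3 Gaussian
replicates underestimates the true σ (E[s] = c₄σ ≈ 0.886σ), so with
σ = 0.079 D the realized pooled threshold on simulated data is ≈ 0.30 D
rather than the asymptotic 4.303 · 0.079 ≈ 0.34 D. This does not affect
any of the package's checks, which either use the algebraic identity
directly or leave generous margins.

What the generator does *not* emulate: chromatographic and ionization
artifacts, overlapping-peptide interference, deuterium scrambling,
sequence-dependent intrinsic rates, charge-state effects beyond a single
chosen z, and correlated (batch) replicate error. Passing tests therefore
demonstrate correctness of the statistical machinery under idealized
peptide-level noise, not robustness to raw-spectrum pathologies.

## Problem sizes used in the shipped checks

The end-to-end checks simulate 50 studies for designed-region recall, 200
studies for the null false-positive rate, 50 noisy envelopes for EX1
separation recovery and 200 binding assays for Kd recovery; these sizes
give stable pass/fail behavior while keeping a full run of the suite in
the low minutes on one CPU.

## Known limitations

- The pooled-SD threshold assumes exchangeable replicate noise across
  peptides and times; heteroscedastic data would call for per-peptide
  thresholds, which are deliberately out of scope.
- The bimodal model's shared width biases the fitted separation by a few
  tenths of a deuteron when the two populations differ strongly in width
  (quantified in the tests); separations are reported as fitted, without
  correction.
- EX1 centroid uptake enters difference profiles unchanged (the overall
  mixture centroid), flagged in the EX1 report.
- Competition/IC50 analysis and kinetic (on/off-rate) binding models are
  not implemented.
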