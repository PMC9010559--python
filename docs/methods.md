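# Methods

## 1. The autoregulation model

The simulator's core is a deterministic ODE model of the tubulin
autoregulation loop. Per isoform *i* it tracks pre-mRNA `P_i` and mature
mRNA `M_i`; two aggregate protein pools, free dimer `F` and polymerized
tubulin `G`, are shared across isoforms:

    dP_i/dt = k_tx,i − k_sp,i · P_i
    dM_i/dt = k_sp,i · P_i − k_deg0,i · (1 + α_i · h(F)) · M_i
    dF/dt   = Σ_i k_tl,i · M_i − k_on · F + k_off · G − k_pdeg · F
    dG/dt   = k_on · F − k_off · G

with the saturating feedback response `h(F) = Fⁿ / (Fⁿ + F0ⁿ)`. The
qualitative biology being encoded is: excess free tubulin accelerates the
decay of the *mature* mRNA only; the pre-mRNA is blind to the protein
state. A Hill form was chosen because the underlying mechanism (free
dimer engaging a ribosome-associated RNase) must saturate; unbounded
linear acceleration would let degradation diverge. `α = 0` switches the
feedback off and yields a linear system with closed-form equilibrium
`P* = k_tx/k_sp`, `M* = k_tx/k_deg0`.

Model assumptions worth stating explicitly:

* **Pool-level feedback.** `F` and `G` aggregate all isoforms; per-isoform
  protein pools would be unidentifiable from the data this pipeline
  consumes, and the feedback argument is a pool-level one. Isoform
  specificity enters only through per-isoform gains `α_i`.
* **Polymer-protected turnover.** Protein decay acts on the free pool
  only (`k_pdeg · F`), consistent with increased tubulin lifetime when
  the network is stabilized.
* **Structural invariances.** The `P` equations never reference `F` or
  `G`, so perturbations of polymer exchange cannot move the pre-mRNA —
  this is the model-level counterpart of "introns report transcription".
  At steady state `k_on F = k_off G` cancels identically in `dF/dt`, so
  the equilibrium free pool is independent of the exchange rates: drug
  effects on mRNA are *transients*, which is why drug readouts are taken
  at a finite horizon (default 6 h, matching the cell experiments) rather
  than at equilibrium.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `k_tx` | 60–140 per isoform | molecules/h | heterogeneous panel expression (~2.3× spread) |
| `k_sp` | 4 | 1/h | ~10 min pre-mRNA half-life (fast splicing) |
| `k_deg0` | 0.35 | 1/h | ~2 h basal mRNA half-life |
| `α` | 5 | — | strong feedback: 6-h drug transients of 0.6–1 log2 units, the size the motivating experiments show |
| `F0` | 600 | a.u. | places baseline F* (~430 a.u.) just below half-saturation, so the loop can move in both directions |
| `n_hill` | 2 | — | mild cooperativity |
| `k_tl` | 0.01 | a.u./mRNA/h | sets the free-pool scale |
| `k_on`, `k_off` | 1, 0.1 | 1/h | ≈91% of tubulin polymerized at baseline; pool re-equilibration within ~1 h |
| `k_pdeg` | 0.02 | 1/h | ~35 h free-protein half-life; recovery from drug transients takes days, so 6-h readouts are far from re-equilibrated |

Perturbations are pure parameter maps: colchicine multiplies `k_off` by a
factor > 1, taxol by a factor < 1, adrenergic stimulation multiplies the
`k_tx` of targeted isoforms. With the defaults, colchicine 10× at 6 h
lowers the exon-probe signal ~42% with the intron signal unchanged;
taxol 0.1× roughly doubles it.

### Numerics

Equilibria are found by reducing the fixed point to one scalar equation
in `F` (translation input balancing free-pool decay; polymer exchange
cancels) and solving with bracketed Brent iteration on `[0, F_max]`,
where `F_max` is the feedback-free bound padded by a relative 1e-9 so the
bracket is strict even at `α = 0`. The returned state's residual is
checked against `1e-9 ×` the state scale and a failure is raised rather
than returning a non-equilibrium. Degenerate inputs fail loudly:
`k_pdeg = 0` with nonzero translation flux, or `k_off = 0` with
`k_on > 0`, have no steady state. Trajectories use LSODA (stiff-capable,
adaptive) at rtol 1e-8 / atol 1e-9 by default; invariance tests tighten
to 1e-12 where they assert 1e-10-level statements.

## 2. The synthetic-data generator

`simulate_study` layers the platform's noise structure on top of the
model, per replicate:

1. **Biological variation** — each replicate's `k_tx,i` is multiplied by
   an independent mean-one lognormal draw (CV 0.10 by default, the study
   condition used throughout the benchmarks);
2. **Lane scaling** — a per-sample lognormal factor (σ = 0.10) multiplies
   every hybridization-derived probe mean;
3. **Counting noise** — counts are negative binomial with
   `var = μ + φ μ²` (φ = 0.005, ≈7% technical CV at these depths, typical
   of the platform; φ = 0 gives Poisson), plus an additive background
   (mean 4 counts) on every probe.

Probe means: exon probes see `M + w_pre·P` (exonic sequence exists in the
pre-mRNA too; `w_pre` defaults to 1 and is exposed because the real
probes' cross-detection is unknown — with the defaults `P ≪ M`, so "exon
≈ mature mRNA" holds either way); intron probes see `P` only; the
six-point positive ladder (ratio 4, lowest point "F") and three
housekeeping genes (Gapdh, Rpl4, Tbp) scale with the lane factor;
negatives carry background only. Probe efficiencies (exon 6, intron 20
counts per a.u.) put endogenous counts in the hundreds-to-low-thousands,
as on the real instrument.

The scenario catalogue (`null`, `colchicine-6h`, `taxol-6h`,
`pe-transcriptional`, `transcriptional-down`, `pe-4day`) pins each of the
canonical regimes; ground-truth modes are derived from which effective
parameters actually differ between group models, never from the realized
data. Densitometry tables (blot gain × amount × loading-equivalents ×
lognormal noise, technical duplicates, GAPDH constant per sample) and
peptide tables (shared peptides sum parent abundances; optional fixed
per-peptide ionization efficiencies; missing completely at random) are
generated from the same cell states.

**What the generator does not emulate:** probe-specific sequence biases
and cross-hybridization, batch/cartridge structure beyond a single lane
factor, non-MCAR missingness in proteomics (real intensity-dependent
censoring is left-truncated, not random), stochastic gene expression
(no SSA mode), and any spatial microtubule structure. Passing benchmarks
on these data therefore demonstrate correctness of the *inference
machinery* under the declared noise model, not robustness to every
artefact of real panels.

## 3. Normalization chain

1. **Background threshold** — geometric mean of pooled negative-control
   counts after removing, largest first in a single pass, any value
   greater than 3× the geometric mean of the remaining ones. Zeros are
   replaced by 1 (the smallest observable count) before any geometric
   mean. The threshold is reported, never subtracted, and endogenous
   values are not floored or filtered. Pooling negatives across lanes is
   the default; a per-lane switch exists.
2. **Lane factors** — per-sample factor = (arithmetic mean over samples
   of the per-sample geometric mean of positive controls) / (that
   sample's geometric mean), after dropping the lowest ladder point
   panel-wide when its mean count is below 2× the background threshold
   (the multiplier is configurable).
3. **Content factors** — the same construction on the housekeeping genes,
   computed on the lane-normalized values.

Lane factors apply to every probe; content factors apply only to
biological content (endogenous + housekeeping). This makes the chain an
exact projection: control-probe geometric means are identical across
lanes in the output, and re-running the normalizer on its own output
returns factors identically 1. Exact invariance to arbitrary per-lane
scalings is impossible for any scheme whose reference is the mean of the
lanes' own geometric means (a common rescaling of all lanes must move the
output scale); per-lane *differences* are removed exactly, i.e. scaled
and unscaled inputs yield outputs equal up to one global constant, and
that is what the tests assert.

## 4. Testing conventions

Effect sizes are per-sample log2 fold-changes against the matched control
group; hypothesis tests run on raw-scale values. The two-sample test is
adaptive: Shapiro–Wilk at the 0.05 level in *each* group gates between
Welch's t (both pass) and the two-sample Kolmogorov–Smirnov test with the
exact small-sample null distribution for n ≤ 10 (any rejection, or a
constant-valued group where Shapiro–Wilk is undefined). Per-group gating
is the conservative reading of "normality of the data" and is the
default. Multiplicity is Bonferroni with an explicit family size `m`
(`adj_p = min(1, m·p)`); `m = 2` for the usual two treatment contrasts
gives the per-comparison cut-off 0.025 at family level 0.05. Family sizes
are never inferred from the data shape. Null calibration of the full
adaptive procedure at n = 6 is 0.045–0.048 over 10,000 simulations —
slightly conservative because the exact KS branch has a discrete null.

Zero counts are guarded by a pseudocount (0.5 for counts, 0 for
continuous intensities); the value is a convention, not an estimate.

## 5. The decomposition

Per isoform, multiple probes of one region are combined per sample as the
arithmetic mean of log2 values (`mean-of-logs`, default; `log-of-sums`
available). Within the decomposition the control reference for
fold-changes is the *geometric* control mean (mean of logs). This choice
is load-bearing: it makes the per-sample index
`A_j = ΔE_j − ΔI_j ≡ log2(E_j/I_j) − mean_ctrl log2(E_k/I_k)` exactly
additive with the fold-change of the exon/intron ratio and exactly
invariant to per-sample lane factors (which multiply both probes of a
lane together) — with an arithmetic control mean the control lanes'
factors would not cancel. The arithmetic convention (used for western
blots, where it is the field's habit) remains available as
`reference="arithmetic"`.

`p_I` comes from the adaptive test on intron signals (treated vs
control), `p_A` from the adaptive test on the per-sample `A_j` — a
location test, not a correlation, because the paired-in-lane probe design
makes `A_j` a well-defined per-sample quantity in both groups. Both are
Bonferroni-adjusted with the declared family size; the decision table in
the README then assigns the mode. "Transcriptional" requires only the
intron test; the exon/intron concordance ratio is reported but not
enforced, because translation-lag regimes genuinely violate strict
`y = x`. The cut-off defaults to 0.025.

Operating characteristics under the declared study conditions (n = 6 per
group, biological CV 10%, transcriptional effects 1.5–2×, drug scenarios
at their defaults): 97–98% of per-isoform mode calls match ground truth
over 200 seeded studies (~1,600 calls), with errors dominated by
underpowered 1.5× transcriptional effects (called "unchanged") and the
irreducible ~2.5% false-positive rate of the null regime at the 0.025
cut-off.

## 6. Proteomics

Digestion follows standard specificities (trypsin: after K/R not before
P; chymotrypsin: after F/W/Y not before P; Glu-C: after E), up to 2
missed cleavages by default, optional length bounds. Uniqueness is exact
string identity of a peptide across the digests of all isoforms — I/L
are distinct residues by default (this is an intensity-based workflow,
not spectral matching); a collapse switch is not provided because none of
the shipped analyses needs it. Both the digest and the parent map are
verified against an independent brute-force span enumerator.

Roll-up: missing values imputed per peptide as half its minimum observed
intensity; per-sample median scaling; isoform abundance = mean of its
unique peptides' intensities. Mean (not sum) because unique-peptide
counts per isoform are very unequal (1–13 in the motivating data) and a
sum would conflate coverage with abundance. Isoforms with zero unique
peptides are reported as not-quantifiable rather than silently dropped.
The imputation/scaling pair is one conventional choice among several; no
attempt is made at bit-compatibility with any vendor pipeline.

Concordance is plain OLS of protein log2FC on mRNA log2FC with the
two-sided slope p-value; in the benchmark regime (20 isoforms, true slope
0.2, residual σ 0.3, x-spread σ ≈ 1.2) the recovered slope averages
0.20 ± 0.003 over 500 seeds with mean R² ≈ 0.40.

## 7. Densitometry

Relative quantification forms the target/loading-control ratio per lane
first, averages technical duplicates second (lanes share a blot gain, so
ratio-then-average is the order under which the gain cancels per lane),
and finally divides by the mean over control samples *on the same blot* —
per-blot gain therefore cancels exactly and cross-blot values are
comparable. A blot with no control sample is an error, not a warning.
Quantifying a modification against GAPDH ("absolute") or against
α-tubulin ("relative") agree identically whenever α-tubulin/GAPDH is
constant across samples. The free:poly ratio corrects intensities to
mg-tissue equivalents via an explicit `LoadingConfig` (default: 5 µL
polymer fraction vs 10 µL free fraction at 2× extra dilution, i.e. equal
equivalents, so the corrections cancel); the bookkeeping is parameterized
rather than hard-coded because loading schemes vary. An optional
intensity ceiling can drop saturated bands.

## 8. Problem sizes and determinism

The shipped benchmarks use: 50 random parameter sets for the closed-form
check; 10,000 null simulations for calibration; 200 studies × 8 isoforms
for mode recovery; 100 random toy proteomes (≤ 5 sequences × ≤ 60
residues) for the digestion oracle; 500 seeds × 20 isoforms for
concordance recovery. Every stochastic operation takes an explicit seed
or `numpy.random.Generator`; identical seeds give bit-identical bundles
and pipeline artifacts. `run_pipeline` writes outputs atomically (a
temporary directory replaces the target only on success) and echoes its
full configuration, so a run is reproducible from `config_echo.yaml`
alone.

## 9. Known limitations

* The feedback's kinetic form (Hill exponent, gain) is a modelling
  convenience; only its sign structure and saturation are biologically
  constrained. No attempt is made to *estimate* the gain from data — the
  inference is deliberately categorical.
* The decision table inherits the discreteness of its two tests: near the
  cut-off, calls flip with single samples. The per-sample tables are
  retained so users can inspect marginal calls.
* The adaptive test's KS branch is conservative at small n; with n = 6
  its discrete null cannot reject below p ≈ 0.002, which bounds the
  achievable significance for heavily non-normal groups.
* `truth_labels` equates "polymer-exchange perturbation with α > 0" with
  an autoregulation mode; for a hypothetical drug applied to a model
  where the feedback is saturated (h ≈ 1 already) the realized effect
  would be negligible and the label optimistic. The shipped scenarios
  keep baselines near half-saturation, where the label is faithful.
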