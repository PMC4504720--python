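# Methods

## The crossover model behind the simulator

Crossovers (COs) are placed on **genetic distance** along one bivalent
— a pair of homologous chromosomes, i.e. four chromatids — as a
**stationary gamma renewal process**: inter-event distances are
i.i.d. Gamma(shape ν, mean 1/rate), the standard counting-model
description of crossover interference. ν = 1 recovers a homogeneous
Poisson process (no interference); larger ν makes spacings more
regular, under-dispersing event counts and suppressing nearby double
crossovers. The process runs at rate **2 events per Morgan at the
bivalent level**: each event recombines two of the four chromatids, so
the expected recombinant fraction per gamete per Morgan is 1% per cM,
which is what genetic distance means. Stationarity is enforced by
drawing the first event from the equilibrium forward-recurrence
distribution (a uniform fraction of a length-biased Gamma(ν+1)
interval) rather than anchoring a renewal at the left end; event counts
in a window therefore do not depend on where the window sits, and a
marker span can be simulated in isolation.

Two pathways are superposed, mirroring the Class I / Class II division
in *Arabidopsis* where roughly 85% of crossovers are
interference-sensitive:

- an interfering stream — gamma renewal with shape ν at rate
  2(1 − `class2_fraction`) per Morgan;
- a non-interfering stream — homogeneous Poisson at rate
  2·`class2_fraction` per Morgan (`class2_fraction` defaults to 0.15).

Each event is then assigned one of the four non-sister chromatid
pairings **uniformly and independently** (no chromatid interference —
the conventional assumption; two-, three- and four-strand double
crossovers therefore arise 1:2:1).

### From events to tetrads

The three FTL markers are hemizygous **in coupling**: one homolog
carries all fluorophore transgenes. Crossover designations live on the
intact parental chromatids; the four grains are the product molecules
obtained by following each strand left to right and switching to the
partner chromatid at every junction it participates in. Each junction
exchanges one fluorophore-carrying product against one non-carrying
product, so 2:2 segregation per marker is automatic, and a product's
presence call flips at each of its own crossovers — which is what makes
the 16-pairing enumeration of one-CO-per-interval double crossovers
split TT×TT overlap 2:1:0 as 4:8:4. Both properties are tested against
an independent brute-force enumeration.

### Whole-genome chiasma counts

Per-cell chiasma counts sum five per-bivalent event counts from the
same two-pathway process. Default bivalent genetic lengths are
(120, 85, 95, 90, 90) cM — proportioned roughly like the five
*Arabidopsis* chromosomes and summing to 480 cM so the expected count
at rate 2/Morgan is 9.6 per cell, the wild-type mean. With
`obligate_co` (the default for chiasma simulation) each zero-event
bivalent is resampled until it has at least one crossover; this
rejection conditioning raises the marginal rate slightly (the simulated
wild-type-like mean is ~10 rather than 9.6), which we accept as the
price of the obligate-crossover rule. Without it, every crossover-less
bivalent contributes one univalent pair (2 univalents).

### Intensity datasets

Each simulated cell yields paired synapsed/unsynapsed ROI mean
intensities; the synapsed true level is (1 − reduction) times the
unsynapsed one. Cells are grouped ~6 per slide; each slide has a
lognormal acquisition gain (σ = 0.3) applied to ROI and bead values
alike, so bead normalization cancels it exactly — with measurement
noise off, the estimated reduction equals the true one to machine
precision regardless of gains. ROI measurement error is multiplicative
lognormal (`noise` is its σ, default 0.1); beads, being averages over
many microspheres, are modelled noise-free.

## The analysis statistics

**Perkins map distance.** cM = 100(TT/2 + 3·NPD)/n. The per-tetrad
contribution is 0, ½ or 3, so the standard error is the delta-method
(equivalently, sample-mean) SE of that score,
se = 100·sqrt[((TT/4 + 9·NPD)/n − (cM/100)²)/n]. The estimator is
exact through double crossovers; under a Poisson process it carries a
small third-order downward bias (expected 6.08 cM at a true 6.1 cM,
19.4 at 20), negligible against sampling error at the interval lengths
used here. Reports print one decimal place; full precision is kept
internally.

**Interference ratio.** The test interval's Perkins distance among
tetrads with a crossover (TT or NPD) in the conditioning interval,
over the same among PD tetrads. The significance test is a
delta-method Z on the *difference* of the two conditional distances,
z = (d_without − d_with)/sqrt(se²_with + se²_without), two-sided
normal p. The original method's web tool publishes no formula; this Z
is validated by null calibration (at ν = 1 the IR is 0.9–1.1 at
n = 20,000 and the test rejects at the nominal rate) rather than by
matching that tool.

**Coefficient of coincidence.** Default *tetrad-level* definition:
f_i = (TT_i + NPD_i)/n, observed = fraction of tetrads non-PD in both
intervals, CoC = observed/(f₁f₂). A *gamete-level* variant is
selectable: f_i = (TT_i/2 + NPD_i)/n (the recombinant-gamete
fraction) with the observed double-recombinant grain fraction resolved
through the TT×TT overlap subtypes. Both are unbiased at the
no-interference null; results state which definition was used.

**Poisson goodness-of-fit.** Poisson mean = sample mean. Three modes:
`conventional` — unit bins 0–10 plus a ≥11 tail (12 categories), df = 11,
the conventional presentation for *Arabidopsis* chiasma counts (no df
charged for the estimated mean), kept for comparability; `pooled` (the
default) — adjacent bins merged until each expects ≥ 5, df = k − 2,
the statistically defensible version (type-I error 0.048–0.052 at
α = 0.05 in 1,000-replicate calibration); `bootstrap` — the pooled
statistic calibrated by seeded parametric bootstrap.

**Univalent frequency.** Defined as univalent *pairs* per bivalent
opportunity: (Σ univalents/2)/(5 · n_cells). The alternative —
fraction of cells with ≥ 1 univalent — is available behind a flag and
labelled in output.

**Rank-based count comparison.** Unpaired Wilcoxon rank-sum
(Mann–Whitney U, two-sided, tie-corrected) by default, since genotype
samples are independent; the paired signed-rank variant is available by
flag. Output records which test ran. Degenerate all-tied input returns
p = 1 with a warning.

**Paired intensity reduction.** Percent reduction is defined on means
of bead-normalized values, 100(1 − mean(syn)/mean(unsyn)); the mean of
per-cell ratios is reported alongside (the two differ only under noise,
and by well under a point at the default noise level). Significance is
a two-tailed paired t-test on the per-cell normalized pairs; cells
missing either region are dropped with a warning.

## Numerical and design choices

- All randomness flows through one explicitly passed
  `numpy.random.Generator`; no global state. Identical config + seed
  gives byte-identical outputs, and the pipeline embeds a provenance
  block (version, seed, hash of the scientific configuration — the
  output path is excluded from the hash).
- Renewal sampling is blocked: enough gamma increments are drawn at
  once that crossing the bivalent end is near-certain, with exact
  block-append extension on the rare miss.
- Tetrads with an odd number of recombinant grains in either interval
  (a mis-scored grain) are excluded and logged, never guessed at;
  tallies report exclusion counts and reasons.
- Letter labels A–K ship as a fixed table mapping the 11 canonical
  joint patterns (8 non-TT×TT joints + 3 TT×TT overlap subtypes) to
  letters for report continuity with the field's group nomenclature,
  which names 12 groups; three-colour presence data distinguish only
  these 11, so anything else reports as OTHER. No computation depends
  on the letters.
- The obligate-crossover flag defaults by context: off for FTL marker
  spans (conditioning a short span on ≥ 1 CO would grossly inflate its
  apparent map length), on for whole-genome chiasma simulation.
- The viability caveat of tetrad scoring (only balanced tetrads are
  scored) is modelled by an `unbalanced_fraction` knob plus a filter
  that drops flagged tetrads and logs the count; default off.

## Study scenarios and problem sizes

The analysis drivers simulate a strongly interfering scenario (ν = 2,
obligate crossover, 480 cM genome; IR ≈ 0.5 and CoC ≈ 0.5 on adjacent
~6 cM intervals, chiasma mean ~10) and a weakly interfering one
(ν = 1.2, no obligate crossover, 345 cM genome; chiasma mean ~6.9,
IR ≈ 0.75). Calibration studies use 100 replicates of 5,000 tetrads
(map recovery), 20,000 tetrads per interference run with 20
strong-interference replicates, 1,000 null and 200 power replicates of
50-cell goodness-of-fit, and 500 replicates per intensity arm — sizes
at which Monte-Carlo error is small against every band being checked
while the full set runs in a few minutes on one CPU.

## What the simulator does and does not capture

It reproduces the statistical structure the analyses assume: renewal
interference on genetic distance, two-pathway superposition, uniform
chromatid choice, the obligate crossover, 2:2 marker segregation, and
gain-calibrated paired intensities. It does not model the crossover
mechanism (no DSB designation, beam-film mechanics, or synaptonemal
complex dynamics), physical distance or recombination landscapes,
chromatid interference, or scoring error beyond balanced/unbalanced
filtering. One visible consequence: with obligate crossover off, the
univalent frequency is tied to the zero-class of the renewal process,
so a genome scaled to a chiasma mean of ~6.9 yields ~25% univalent
pairs — real mutants with partial crossover control keep this nearer
10%, a regime between the simulator's obligate and non-obligate
extremes. Passing tests therefore demonstrate correctness of the
estimators and their operating characteristics under this generative
model, not agreement with any particular cytological dataset.
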