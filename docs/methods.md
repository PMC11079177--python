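# Methods

## Scope and model

`ptcquant` covers the computational core of a targeted AP-MS/MS experiment
that asks: *which amino acids are inserted at a premature termination codon
(PTC) during drug-induced stop-codon readthrough of a full-length protein,
and in what proportions?*  The pipeline has five analytic stages.

### 1. Near-cognate enumeration

A near-cognate tRNA pairs with a stop codon with exactly one anticodon
mismatch.  The candidate insertion set for a stop codon is therefore the set
of amino acids encoded by the nine single-nucleotide variants of that codon
(stop codons excluded), computed over the standard genetic code:

* UGA → {R, G, S, L, C, W}
* UAG → {K, Q, E, L, S, W, Y}
* UAA → {K, Q, E, L, S, Y}

For UGA a narrower, experimentally validated set {R, C, W} is exposed as a
second enumeration mode; it is the default for quantification because those
are the insertions recurrently observed for UGA suppression in mammalian
cells.  Only the standard code is supported (cytosolic translation in
human/hamster cells); residue indexing is 1-based everywhere to match
missense nomenclature (G542X, R1162C).

### 2. In-silico proteolysis

Fully specific digestion under position-independent rules:

* trypsin — cleave C-terminal to K/R, suppressed before P (the conventional
  search-engine rule; a strict no-exception variant is available);
* chymotrypsin — cleave C-terminal to {F, W, Y, L, M}, suppressed before P
  (low-specificity rule; a {F, W, Y} high-specificity variant is available).

Peptides carry 1-based inclusive coordinates and a missed-cleavage count;
0-missed peptides tile the parent exactly, and the peptide set is monotone
in `max_missed`.  Semi-specific and nonspecific cleavage are not modeled.
Only *site-spanning* peptides — those whose span covers the PTC residue —
carry variant information downstream.

### 3. Inclusion-list design and the detectability audit

Targets are precursor (m/z, charge) pairs for every site-spanning peptide of
every variant, expanded over modification states (fixed Cys
carbamidomethylation +57.021464 Da; variable Met oxidation +15.994915 Da,
0–2 sites) and charges (default {2, 3}).  Masses are monoisotopic
throughout — the intended acquisition context is a high-resolution Orbitrap
survey scan.  Each row is checked against the instrument constraints
(defaults: survey window m/z 300–1400; peak-list mass window 500–6000 Da;
charges ≤ 5) and *retained with flags* when it violates them: the list is
non-exclusive, and a flagged row is exactly the evidence a design review
needs.  No minimum-length heuristic is applied — the mass floor is the
operative constraint.

The audit asks, per protease, whether *any* site-spanning
peptide/charge/modification combination is flag-free.  It defaults to
**complete digestion** (`max_missed = 0`), deliberately stricter than the
inclusion list's default of one missed cleavage: missed-cleavage forms are
substoichiometric byproducts whose yield the designer does not control, so a
design should not rely on them for detectability.  This choice is what makes
the audit reproduce the Arg blind spot mechanically: in a context where the
nearest upstream K/R sits four residues before the PTC, Arg incorporation
restores a tryptic site and the fully cleaved spanning peptide (SVSR,
447.24 Da) falls below the 500 Da peak-list floor — the variant is invisible
to a tryptic experiment, while Cys/Trp incorporation abolishes the terminal
cleavage and extends the peptide past the floor.  Switching to chymotrypsin
extends the Arg peptide instead and restores detectability.  With
`max_missed ≥ 1` the audit would credit the upstream-extended missed-cleavage
form (≥ 603 Da) and miss the blind spot; users who want that optimistic
reading can pass `max_missed=1` explicitly.

### 4. Spectral-count quantification

The estimator is the spectral-counting ratio

    fraction(a) = SC(site-spanning peptides carrying a) / Σ_b SC(b),

with the sum over the enumeration set in force (default {R, C, W}).  PSMs
are assigned by exact sequence match (mod annotations stripped; I/L not
equated) against the theoretical site-spanning digest; non-spanning and
unmatched PSMs are excluded and tallied.  Fractions are computed per
replicate, then averaged (mean ± s.e.m. across independent experiments);
pooled-count estimation is provided as an option because the per-replicate
vs pooled choice is not canonical — the default is per-replicate averaging.

Counts are **uncorrected** for per-peptide detectability.  When true
detection efficiencies differ between variants the estimator is biased
toward the better-detected variant; the synthetic generator exposes
detectability weights precisely so this bias can be demonstrated, and every
abundance output is stamped "spectral counts uncorrected for per-peptide
detectability".

**Uncertainty.**  Replicates are resampled with replacement and the 2.5/97.5
percentiles of the resampled means form the 95% CI.  With only 3–4
replicates the plain percentile interval is systematically narrow (measured
coverage ≈ 80% at n = 4 in our simulations — a known small-n property of the
percentile method).  When the raw count table is available,
`aggregate_replicates` therefore uses a two-stage (hierarchical) bootstrap:
each drawn replicate's counts are additionally resampled multinomially at
its observed depth, propagating counting noise into the interval.  Measured
coverage at the default study conditions is ≈ 96–98%, i.e. mildly
conservative.  With fractions only, the plain percentile method is used (and
is degenerate, correctly, for identical replicates).  Default 2000 bootstrap
draws; the seed is mandatory in pipeline configurations.

### 5. tRNA microarray conversion and model comparison

Comparative two-channel signals are converted to absolute per-codon
fractions in four steps: (i) per-replicate spike-in normalization — each
probe's channel ratio is divided by the *median* spike-in channel ratio
(median rather than mean for robustness to one bad probe; ≥ 3 usable
spike-ins required; non-positive signals are dropped with a logged count,
never imputed); (ii) anchoring to a reference absolute-abundance table
(ratio × reference fraction), renormalized to 100%; (iii) apportioning each
isoacceptor's fraction across the codons it reads proportionally to
codon-usage weights, summing codons read by several isoacceptors, and
renormalizing to 100% (splitting conserves each isoacceptor's total
exactly, before the final renormalization); (iv) two-model comparison by
Welch's t-test on replicate-level codon fractions — uncorrected when an
a-priori codon subset is supplied (the focused Arg/Cys/Trp-decoder
comparison), Bonferroni-corrected when all codons are tested; the policy is
recorded in the output.  Wobble rules are never inferred; codon pairing
comes entirely from the user's decoding map.

## Synthetic data: what it emulates, what it does not

* **PSM tables** — per-replicate totals are Poisson(`depth_mean`), split
  multinomially with probabilities ∝ θ(a)·w(a), restricted to variants the
  audit passes (an undetectable variant gets zero counts regardless of θ —
  the blind spot made mechanical).  An optional Dirichlet concentration
  parameter adds between-replicate overdispersion.  All counts land on the
  variant's best spanning peptide; real data spread counts over charge and
  modification states and contain misassigned spectra.  Parameter-recovery
  results therefore validate estimator correctness, not robustness to
  search-engine artifacts.
* **Array signals** — the requested codon table is inverted to isoacceptor
  fractions by non-negative least squares (an inconsistent table is
  rejected), then channel signals are gain × fraction with log-normal
  multiplicative noise of unit mean at the stated CV; spike-ins share a
  common concentration across channels.  Gridding artifacts, saturation and
  cross-hybridization are not modeled.
* **Blind-spot context** — `R1162X_CONTEXT` ("FAGQRSVS_NVTDAEKAF") embeds
  the Arg–Ser–Val–Ser–[PTC] tryptic context with chymotryptic anchor
  residues (F) on both flanks; the residues outside the printed local
  context are synthetic, chosen only to give both proteases well-defined
  spanning peptides.

Generator defaults are the package's study conditions: θ = (C 0.65, R 0.25,
W 0.10) — midpoints of the incorporation ranges reported for UGA readthrough
of full-length constructs — 4 replicates, mean depth 40 site-spanning
counts/replicate, array CV 10% with 3 replicates and 4 spike-ins.

## Numerical choices

* Monoisotopic residue masses from the standard table; water 18.0105646863,
  proton 1.00727646688 Da.  m/z = (M + z·mH)/z.  Additivity and round-trip
  hold to 1e−6 Da; inclusion rows round-trip m/z↔mass to 1e−4.
* Applying the same fixed modification twice raises (no silent
  double-counting); variable-mod application beyond the available target
  residues raises.
* Per-replicate fractions sum to 1 within 1e−9 by construction; codon tables
  to 100% within 1e−6 after each renormalization.
* NNLS inversion accepts residuals up to 1e−6 of the target norm.
* Divisors ≤ 1e−12 raise in all normalization operations.
* Zero-total replicates are dropped with a warning; an all-zero experiment
  is an error.
* Degenerate variance in Welch's test (all replicate values identical on
  both sides) is reported as p = 1 for zero difference, p = 0 otherwise.

## Problem sizes used by tests and the acceptance script

Digestion oracle equivalence: 500 random sequences (length ≤ 60) × 2
proteases × missed ∈ {0,1,2}.  Estimator study: 200 simulated experiments at
the default study conditions; bootstrap 500 draws per experiment within the
study (2000 in ordinary use).  Null false-positive rate of the codon
comparison: 500 simulated table pairs (n = 3, CV 10%).  These sizes give
stable Monte-Carlo estimates (s.e. of the coverage estimate ≈ 1.4 points at
200 experiments) at interactive runtimes.

## Known limitations

* No retention-time scheduling, fragment-ion lists, isotope envelopes or
  spectrum-level rescoring — the package designs precursor targets and
  quantifies already-identified PSMs.
* The spectral-count estimator inherits the biases of spectral counting;
  no detectability correction is attempted (by design, matching practice).
* Digestion is fully specific; chymotryptic specificity in vivo is broader
  than either provided rule.
* The decoding map and reference tRNA abundances are user inputs; shipped
  fixtures are small synthetic examples, not published tRNAome tables.
* mRNA-level and functional normalizations operate on already-reduced
  per-construct values; raw trace processing is out of scope.
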