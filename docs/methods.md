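# Methods

## Scope and model

`flrkit` estimates the global false localization rate (FLR) of PTM site
assignments over a ranked list of scored sites. The ingestion boundary is
a tab-separated interchange table (one row per PSM with 1-based modified
positions and per-site localization probabilities); native search-engine
formats (pepXML, mzIdentML, vendor files) are out of scope by design —
exporting to the interchange TSV is the caller's responsibility. All
probabilities are stored as probability-correct; the local error (PEP) is
derived as 1 − p where needed, never stored.

The pipeline mirrors standard phosphoproteomics practice: PSMs are
filtered at a global target-decoy FDR (default 1%, estimated as
cumulative decoys over cumulative targets with q-value monotonization),
expanded to one row per scored site, ranked by the combined probability
(PSM probability × localization probability — justified when the two
probabilities are nearly independent), and the global FLR is
estimated at every row. A `ptm_only` ranking mode supports small search
databases where PSM probabilities are unreliable.

### Estimators

* **Model FLR**: running mean of (1 − combined probability). Exactly the
  expected FLR if the probabilities are calibrated.
* **Decoy FLR**: `2 · (T_c/X_c) · pX_c(n) / n`, capped at 1. `T_c`/`X_c`
  count target/decoy residues with per-PSM multiplicity over the peptides
  of all PSMs contributing at least one site to the ranked list (a
  unique-peptide variant is available). Decoy-residue rows stay in the
  denominator *n*; when the cap binds before a requested threshold is
  reached, the yield is reported as "n/a".
* **Answer-key FLR**: running fraction of sites not matching a known
  truth map. Before use, PSMs are filtered to full-length key peptides
  with the expected modification count and no other variable
  modifications (removals are returned with reasons).

q-values are the running minimum of the raw estimate taken from the
bottom of the list; thresholding returns all rows down to the last row
with q ≤ α and the count of target-residue sites among them.

### Rationale for the decoy factor 2

If wrong sites land on residue classes in proportion to their counts, the
observed decoy hits `pX_c` imply `(T_c/X_c)·pX_c` unseen wrong hits on
targets; the total wrong count is the sum, `(1 + T_c/X_c)·pX_c`. The
estimator instead uses `2·(T_c/X_c)·pX_c`, which equals the exact form at
parity (`T_c = X_c`) and exceeds it for a rarer decoy — a deliberate
conservative choice: the estimator equals the truth times
`2·T_c/(T_c+X_c)` under the proportional-split model.

## Tie-breaking and numerical choices

* Ranking ties (equal ordering key): decoy entries sort above targets —
  decoy PSMs in the FDR stage, decoy-residue sites in the site stage —
  then stable input order. Conservative for every downstream estimator.
* FDR numerator is D (not D+1); the +1 variant is a flag. Rows before the
  first target get FDR 1.
* Collapsing bins the per-site maximum probability by flooring to two
  decimals (order-preserving at bin edges), ranks by bin then
  supporting-PSM count, breaking ties by unbinned probability then first
  appearance. Collapse keys: protein site (default) or peptidoform.
  Probabilities are never combined across PSMs — the observations are not
  independent, and the model-FLR assumptions do not survive collapse.
* Score calibration uses equal-width histogram bins (default 100) over
  the observed range; per-bin PEP = min(1, D/T); zero-target bins inherit
  the nearest populated bin; bin probabilities are made monotone in score
  by isotonic regression weighted by bin occupancy. PSM and site score
  streams are calibrated independently.
* Profiling resolves site coordinates in protein context when a FASTA and
  protein positions (or a unique peptide match) are available, falling
  back to peptide context with a warning. Nearest-residue search uses a
  ±10 window by default; equidistant ties resolve to the N-terminal
  (negative) offset. The proximal-probability profile uses a 0.68
  combined-probability cutoff for "assumed correct" sites, the average
  minimum combined probability at a 5% decoy-FLR cut observed across
  searches.
* de Bruijn decoys are random Eulerian paths (randomized Hierholzer) over
  the (k−1)-mer graph, k = 2 by default; length, composition and the
  overlapping k-mer multiset are preserved exactly. The path starts at
  the sequence's first (k−1)-mer, so first/last residues follow from the
  graph endpoints; enzymatic termini are not specially preserved.
  Sequences shorter than k pass through with a warning. The seed is
  recorded in each decoy entry's description.

## The simulator

The simulator is the package's test harness: site-level search output
with known per-row truth. It emulates the statistical structure the
estimators assume, not spectra.

* **Proteins and peptides**: i.i.d. residues from a configurable
  frequency table (default uniform over the 20 amino acids), tryptic
  digestion (cut after K/R, not before P) with up to 2 missed cleavages,
  peptide length 7–30. Each unique eligible peptide receives one true
  phosphosite, drawn uniformly over its S/T/Y positions; eligibility
  requires ≥2 target residues by default so localization is genuinely
  ambiguous and the mislocalization model is well defined for every row.
* **Rows**: peptides are sampled with replacement into PSMs; per row a
  PSM-correctness probability (Beta(18,1), emulating post-1%-FDR PSM
  probabilities) and a localization-correctness probability (Beta(8,1),
  right-skewed toward confident localizations) are drawn. The site is
  reported at the true position with probability equal to their product,
  else mislocalized. Reported probabilities equal the generative ones
  (calibrated mode) or are logit-shifted (miscalibrated mode). Each row
  draws its randomness from a per-row seed, so paired runs differing in
  one model term share all untouched rows.
* **Mislocalization** (`uniform`): the wrong site lands on the decoy
  class with probability x/(t+x) — the peptide's candidate-residue
  counts, the true site's residue included in t — then uniformly within
  the class excluding the true position. This is the generative model
  under which wrong hits split between targets and decoy in proportion to
  residue counts, the assumption the decoy estimator normalizes by. A
  naive uniform draw over candidate positions minus the true site
  under-weights the target class by one residue per peptide and biases
  the decoy estimator upward by roughly c/(c−1) for c candidates per
  peptide. A `nearest` mode instead moves the site to the closest
  candidate residue (ties N-terminal), and a `motif_bias` term snaps
  wrong sites onto a decoy residue immediately N-terminal of the true
  site — reproducing the effect that makes residues frequently preceding
  true sites (the glycine-before-phosphoserine situation) poor decoys.
* **What it does not model**: spectra and fragmentation, search-engine
  score correlations, real motif biology, non-tryptic backgrounds,
  protein inference. Passing tests show the estimators recover truth
  under their own generative assumptions, not that any particular
  pipeline's probabilities are calibrated on real data.

### Study conditions and a known structural subtlety

Validation runs use 20,000 PSMs over 300 proteins — large enough that
Monte-Carlo standard errors at the 5% FLR threshold are a few tenths of a
percentage point, small enough that a full estimator comparison runs in
seconds.

The decoy estimator's proportional-split assumption refers to *pooled*
residue counts, while mislocalization is necessarily per-peptide. Because
eligible peptides are conditioned to carry ≥2 targets, the per-row decoy
share among wrong sites sits slightly below the pooled X_c/(T_c+X_c)
(measured 0.47 vs 0.51 at parity), making the estimator a few percent
lower (relative) than the pooled-count identity predicts. This is a
property of the method itself on composition-conditioned peptide sets,
not of the implementation; at the study sizes used it is well inside
Monte-Carlo noise. For the same reason, frequency tables that target a
pooled-count condition are calibrated against the eligible library: the
parity table (T_c ≈ X_c) uses a decoy frequency of 0.19 against a
combined raw S/T/Y frequency of 0.15, and the rare-decoy table
(T_c/X_c ≈ 3) uses 0.062.

## Known limitations

* The decoy method estimates global FLR only; it has no per-site (local)
  resolution.
* Decoy-FLR counters are kept from the uncollapsed PSM set when
  re-estimating on collapsed tables.
* The interchange reader rejects tables mixing native and missing PSM
  probabilities rather than imputing; calibrate first, then estimate.
* `answer_key_filter`'s "partial peptide" test is substring containment
  against key peptides, which is what synthetic-library comparisons need
  but is not a general subsequence/homology check.
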