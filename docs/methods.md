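# Methods

This note records the models, conventions and numerical choices behind
`tauscan`, and what the synthetic-data tests do and do not demonstrate.

## Scan procedure

A region (a window centered on a splice junction, or a UTR sequence) is cut
into windows starting at 1, 1+step, 1+2·step, …; trailing fragments shorter
than the window are dropped.  Per window:

1. `ΔG°₃₇(native)` — MFE folding free energy of the window.
2. A null of `n_shuffles` randomized windows (default 50), each refolded.
   `z = (ΔG°native − mean) / SD` with the **sample** SD (n−1 denominator).
   `p` is the fraction of shuffles folding **strictly** more stably than
   the native window, so `p ∈ {k/n_shuffles}`.
3. Ensemble diversity of the native window from its partition function.

Shuffle modes: `mononucleotide` (default; exact composition preserved) and
`dinucleotide` (Euler-path shuffle; the full 16-entry dinucleotide count
vector, and hence both end bases, preserved exactly).  Folding energies are
stacking- and therefore dinucleotide-sensitive, so the dinucleotide null is
the stricter one; outputs name the mode used.  Each window's RNG stream is
derived from `(seed, window start)`, making scan tables bit-reproducible
and independent of evaluation order.

Selection: a window is a z-outlier iff `z < mean_z − selection_sd · sd_z`
(default `selection_sd = 1`), with mean/SD taken over **that scan's own
windows** — each scan is its own null population; pooling across scans or
stages is deliberately not done.  ED-outliers are computed analogously and
reported separately.  A degenerate null (all shuffles identical, e.g. a
homopolymer window) reports `z = 0` with a flag rather than NaN, and a
zero-variance scan selects nothing.  Overlapping or book-ended selected
windows are merged into maximal intervals and each merged interval is
refolded as a single sequence.

Presets: junction stage 1 = 500 nt centered window, 30 nt windows, 10 nt
step (long-range context); junction stage 2 = 250 nt centered, 70 nt
windows, 1 nt step (small junction-proximal motifs); UTR = 150 nt windows,
10 nt step.  Windows centered on near-terminal junctions that run off the
gene are truncated and flagged, not dropped, so every junction is
scannable.

No multiple-testing correction is applied across windows: selection is
relative (≈16% of windows are z-flagged under a Gaussian-like null), and
candidates are meant to be ranked and inspected, not declared significant.

## Ensemble quantities

`ED = Σ_{i<j} 2·p_ij·(1−p_ij)` — the expected base-pair distance between
two independent draws from the Boltzmann ensemble.  The centroid is the
set of pairs with `p_ij > 0.5` (a well-defined, reproducible convention;
such pairs can never conflict).  Both match the ViennaRNA definitions, so
the two backends agree on the meaning of every reported number.  Loop
probabilities are estimated by stochastic backtracking: the frequency of
the loop (all closing pairs present, listed interior positions unpaired)
in `n` sampled structures, reported with a binomial standard error.  This
is a sampling estimator, not an exact conditional-probability computation.

## Folding backends

**vienna** — adapter to ViennaRNA (Turner-2004 parameters, 37 °C, default
model settings, lonely pairs permitted).  This is the quantitative backend:
printed kcal/mol values from the literature are only comparable through a
full parameter set, and even then energy-parameter revisions move window
energies by ~0.1–0.5 kcal/mol, so comparisons against published values are
made at ±0.5 kcal/mol rather than bit-equality.

**reference** — a self-contained engine over a reduced nearest-neighbor
model, so that correctness (as opposed to parameter fidelity) can be proven
against an independent oracle.  The model: tabulated 6×6 stacking energies
over all canonical pairs (Watson–Crick values on the published
nearest-neighbor scale, rounded representative values for wobble stacks,
completed under duplex-reading symmetry), affine penalties for hairpins
(5.4 + 0.25·(u−3) kcal/mol), bulges (3.8 + 0.3·(u−1)), internal loops
(4.0 + 0.3·(u−2)) and multibranch loops (3.4 + 0.4 per helix including the
closing one + 0.4 per unpaired nt); exterior bases are free, so the open
chain is exactly 0.0 kcal/mol.  Hairpin loops need ≥3 unpaired nt;
bulge/internal loops are capped at 30 unpaired nt (infinite energy beyond —
the cap is part of the model definition, so the enumeration oracle and the
dynamic program agree exactly); helices must contain ≥2 stacked pairs
(lone pairs excluded) by default, with `allow_lone_pairs` available.
`RT = 0.6163` kcal/mol (37 °C).

MFE, partition function, base-pair probabilities (inside–outside) and
stochastic backtracking all share one unambiguous helix-based grammar, so
minimization, Boltzmann summation and sampling cannot drift apart.  MFE
ties are broken by a fixed traceback order (unpaired first, then 5′-most
alternatives), making dot-bracket output deterministic.  The partition
function uses unscaled Boltzmann weights and is therefore capped at 300 nt
(float64 overflow guard); the Vienna backend handles long sequences.

Verification: on ~200 random sequences of 8–18 nt, reference-engine MFE,
every base-pair probability, and ED equal exhaustive enumeration of all
nested structures scored by an independent loop-decomposition scorer
(≤1e-9); sampled structure frequencies match enumerated Boltzmann
probabilities within 3 standard errors.

## Conservation scoring

The consensus structure is the query's predicted structure mapped onto
alignment columns — not an alignment-folding recomputation.  This keeps the
bookkeeping (per-pair canonical percentages over rows) exact and cheap; the
cost is that compensatory structures realized at shifted positions in other
species are invisible.  Conventions, chosen where the procedure is
underdetermined:

* Hits of **exactly** 80% of the query length are kept; only strictly
  shorter fragments are dropped (duplicates are collapsed first-wins).
* A gap in either paired column counts as non-canonical.
* The headline "average conservation" is the mean over pairs of per-pair
  percentages; the mean over row×pair cells is also reported
  (`average_pct_cells`) since the two differ when pairs vary in support.
* APSI: mean over row pairs of identical residue columns divided by
  columns where at least one of the two rows has a residue (double-gap
  columns excluded from the denominator).
* Covariation is a **counter**, not a statistic: a pair covaries when ≥2
  non-query rows differ from the query at one or both paired columns while
  still forming a canonical pair.  No covariation score, G-test or E-value
  is computed, and no phylogenetic weighting is applied.

Running BLASTn/MAFFT is out of scope: alignments are ingested (aligned
FASTA/Stockholm).  The built-in pairwise aligner (match +1 / mismatch −1 /
gap −2, stacked onto query coordinates) exists so the test suite needs no
external tool; it is not a substitute for a proper MSA on real data.

## Mutation reports

The analysis window for a mutant is the same region as the wild-type
report row, since that is the window published junction tables describe.
`ΔΔG = ΔG_mut − ΔG_wt` (positive = destabilizing) and `ΔED = ED_mut −
ED_wt`; both are antisymmetric under swapping alleles, and an identity
control is exactly zero.  Splice-site notation (`C(+14)T`, `G(-10)T`) is
parsed directly; protein-style names carry no nucleotide position and are
accepted only with an explicit `(position, ref, alt)` definition.  ED
changes are reported for the window's ensemble; a "centroid ED" is not a
separate quantity in this framework.

## Synthetic data: what it emulates, what it does not

The generator produces (i) i.i.d. background of configurable composition
(uniform default; a GC≈0.55 preset mirrors the GC-rich junction context of
tau), (ii) designed stem-loops overwritten into the background at given
positions — GC-fraction-controlled stems whose intended pairs are recorded
as ground truth, (iii) multi-exon genes with hairpins straddling chosen 5′
splice sites, and (iv) gapless homolog families evolved per consensus pair
(compensatory substitution with probability `compensatory_rate`, uniform
over the 5 alternative canonical pairs) and per unpaired position
(`neutral_rate`).

Real pre-mRNA is not i.i.d.: repeats, composition gradients and real
splice-site motifs produce heavier-tailed window statistics than the
synthetic null, and real homolog families have phylogenetic structure and
indels that the gapless independent-species model lacks.  Passing tests
therefore demonstrate *calibration and recovery under the stated model* —
an unbiased z under a true null, near-certain recovery of thermodynamically
planted motifs, exact closed-form behavior of conservation counters — not
field performance on genomic sequence.

## Problem sizes used in the checks

Null calibration uses 200 non-overlapping 30 nt windows (50 shuffles each);
motif recovery uses 20 replicates of a 12-bp planted hairpin in 150 nt of
background; the enumeration-oracle fixture is ~200 sequences of 8–18 nt;
family recovery uses 10 species over a 20-pair stem at rates 0.2/0.1.
These sizes give 3-SE Monte-Carlo tolerances that are tight relative to the
assertions while keeping the default test run quick.

## Known limitations

* No pseudoknots anywhere; no SHAPE-directed folding (experimental
  structures can be supplied for comparison but are not computed).
* The reduced reference model is for correctness work, not kcal/mol
  fidelity; quantitative claims always go through the Vienna backend.
* Reproducing published tau junction values requires the NCBI RefSeqGene
  record (`NG_007398.1`) as input; species counts from homolog searches
  depend on database state and are not asserted.
* Merged regions include every nucleotide of every flagged window, so they
  typically over-cover a planted motif by up to one window length on each
  side; recall is the designed guarantee, precision is not.
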