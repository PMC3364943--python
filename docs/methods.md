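# Methods

This note documents the models, conventions and numerical choices behind
`structage`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Residue features

RSA is the DSSP accessibility (ACC, Å²) divided by the residue's maximum
accessibility in an extended Gly-X-Gly tripeptide; the reference table
(Miller et al. 1987 values) ships in `structage/data/miller_asa.tsv`.
Distorted conformations can yield RSA > 1; these are clamped to 1.
Exposure uses the 25% threshold; RSA exactly 0.25 is classified
**exposed**, keeping "buried" strictly below the threshold. The 20 RSA
bins are half-open [lo, hi) of width 0.05, except bin 20 = [0.95, 1.0]
closed, so clamped RSA = 1 lands in a bin. DSSP classes map to four
categories: H → helix, E → sheet, S/T → turn, everything else
(B, G, I, blank/'.') → coil. When the DSSP amino acid disagrees with the
coordinate file the position is dropped, so only positions with a
consistent identity enter the analysis.

Chain-level filters reject structures shorter than 50 residues, with a
gap in residue numbering, or with any incomplete N/CA/C/O backbone; the
reason string names the first failed rule. Multi-model (NMR) files
contribute only model 1. DSSP chain-break records would appear here as
numbering gaps and are rejected by the same rule.

## Age assignment

Homolog presence/absence is read from BLAST tabular hit files; hits with
e-value above 10⁻⁴ are ignored and the age class is the oldest species
group with a surviving hit. The default grouping is 14 species in four
clades (mammals; non-mammalian vertebrates; other metazoans; other
eukaryotes); any species → group mapping can be supplied. Mammalia
assignments are returned but flagged excluded, since that class is too
small for meaningful comparisons in the motivating setting. The separate
structure-mapping filter keeps hits with ≥ 99% identity and resolves
overlaps by highest identity, ties by longer alignment, then lower
e-value ("closest to the query" is ambiguous; this reading is a package
choice, recorded here rather than attributed to anyone).

## Rate estimation

dN/dS uses Nei–Gojobori (1986) counting with the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p), in place of a maximum-likelihood codon model.
For the closely related pairs the filters admit (dS ≤ 2) the counting
estimator is adequate, self-contained and deterministic; absolute values
can differ from ML estimates, so cross-study comparisons should be made
on the same estimator. Conventions fixed here because NG86 leaves them
open: single-nucleotide changes producing a stop codon count as
nonsynonymous in site counting; mutational pathways through intermediate
stop codons are excluded from the pathway average (all pathways are used
if every one is blocked); sites are averaged over the two sequences.
pN or pS ≥ 3/4 raises a saturation signal instead of returning a number;
dS = 0 leaves ω undefined (None). Only the universal genetic code is
wired in, behind a single table that could be swapped.

Concatenation builds one codon alignment per structural category, RSA
bin, or (category, age) pair, taking each residue's source codon column;
source pairs below 50% protein identity (exact matches over aligned
non-gap columns) contribute nothing. Post-estimation filters discard
alignments shorter than 60 aa, with dN > 0.5, or dS > 2; thresholds are
exclusive (dN = 0.5 and dS = 2 are retained).

## Four-body potential

Each chain is reduced to Cα points (side-chain centers would be a config
option but are not emitted by the generator) and Delaunay-tessellated;
tetrahedra with any edge above the 8.5 Å cutoff are discarded as
artifactual surface-spanning simplices. Training counts unordered
amino-acid quadruplet compositions q over the corpus and scores

    score(q) = ln( (n_q + 1) / (N + 8855) ) − ln p_q ,

where p_q is the multinomial expectation from corpus amino-acid
frequencies with the multiset coefficient 4!/(k₁!…k_m!) and the add-one
pseudocount keeps all 8,855 = C(23,4) entries finite. Note the
pseudocount does **not** make unobserved compositions uniformly negative:
a composition whose expectation p_q is below the smoothed frequency
scores positive; only absence of *expected* compositions is penalized.
ΔG = −Σ score over retained simplices, so lower ΔG means greater
sequence–structure compatibility. ΔG is reported unnormalized by length;
cross-group ΔG comparisons must go through the length-binned pairing
(below). Exactly coplanar point sets are a degenerate-input error;
near-degenerate sets that fail the tessellation get one retry after a
deterministic 10⁻⁶ Å jitter seeded from the structure id.

## Mutational robustness

Mutants substitute k = max(1, ⌊L/denominator⌋) distinct positions
(denominator 50 or 10, i.e. 2% or 10% of residues), each to a uniformly
chosen different amino acid, and are scored on the fixed native
conformation — no relaxation, as the statistical potential assumes.
Z = (ΔG_native − mean)/sd with the n−1 sd; rank = 1 + #(mutants strictly
below native), so mutants tying the native count as less stable
(deterministic, conservative toward robustness). sd = 0 yields NaN
rather than a Z. Per-site scans mutate every position once (never to the
native residue) and record |ΔΔG| via incremental rescoring of only the
simplices containing the position.

## Statistics

Regressions are ordinary least squares on the 20 binned points, matching
how binned rate–RSA relationships are usually plotted; weighting by
per-bin codon count is available but off by default, and residue-level
fits are a deliberate non-default alternative. The interaction model
dN ~ RSA + age + RSA:age is fit per age pair with age as a 0/1 factor.
Per-bin dN standard errors come from a 200-resample codon bootstrap.
Wilcoxon comparisons use exact enumeration when the smaller sample has
≤ 25 observations and the data are tie-free, otherwise the normal
approximation with continuity and tie corrections. Raw p-values are
reported; Benjamini–Hochberg adjustment exists as an opt-in helper. ΔG
comparisons across age groups first bin structures by length (width 25
residues) and down-sample every group, seeded, to equal counts per bin;
groups sharing no length bin with the others are excluded and reported —
the pairing can legitimately come back empty.

## Synthetic data: what it emulates

The generator exists so every downstream stage is testable without
external data. Its parts:

* **Structures** — a collapsed self-avoiding walk (Cα steps 3.8 ± 0.1 Å,
  clipped to [3.65, 3.95]; centripetal bias toward a target radius
  ∝ L^{1/3}) gives a compact globule with realistic contact density.
  Residues are ranked by burial (contact count within 8.5 Å, ties by
  centroid distance); the `core_fraction` most buried get hydrophobic
  amino acids (AVLIMFWC) and low planted RSA, the rest polar residues
  and higher RSA, via a piecewise-linear quantile map anchored so that
  RSA < 0.25 holds for ≈ core_fraction of residues (Gaussian noise,
  sd 0.02). N/C/O backbone atoms are placed by idealized geometry purely
  so backbone-completeness checks and PDB emission work. DSSP-style
  records (ACC, SS letter) are emitted directly by the generator in
  genuine DSSP column layout — DSSP itself is never run. Secondary
  structure letters are random plausible segments, uncorrelated with
  geometry.
* **Ortholog pairs** — sequence A back-translates the chain exactly
  (uniform codon choice); sequence B substitutes each codon with
  probability min(1, base_rate + rsa_slope·RSA), a single-nucleotide
  change, nonsynonymous with probability 0.75 (≈ the random
  single-nucleotide expectation; configurable). No indels, so
  concatenated alignments are gap-free.
* **Age presets** (the study conditions, fixed once): rsa_slope
  0.0025 / 0.003 / 0.006 for eukarya / metazoa / vertebrata — the
  younger, the steeper; base_rate 0.02 / 0.03 / 0.05 — the younger, the
  faster; core_fraction 0.45 / 0.40 / 0.34 — the younger, the more
  exposed. Mammalia (0.007 / 0.06 / 0.30) exists for completeness but is
  excluded from comparisons. Slope and rate are planted at the per-codon
  substitution scale, so fitted dN-scale slopes are smaller by roughly
  the nonsynonymous fraction over nonsynonymous sites per codon (≈ 0.34)
  while ratios and orderings are preserved.
* **Homolog profiles** — hits in the target group and every younger
  group, none older, all e ≤ 10⁻⁴, so age assignment inverts generation
  exactly.
* **Decoys** — sequence shuffles (exact composition preservation on
  fixed coordinates) or bounded coordinate perturbations (sequence
  fixed).

What passing tests on this generator do **not** show: physical folding
realism, side-chain packing, secondary-structure–geometry coupling,
indel processes, low-complexity/disorder biases, or the empirical
magnitudes of real interspecies divergence. The generator plants the
qualitative regularities (linear RSA–rate relation, age-dependent slope
and rate, age-dependent exposure) and the tests verify the pipeline
recovers exactly what was planted.

## Problem sizes and power

Recovering a dN slope of 0.0025 per unit RSA demands many codons per
bin: with per-bin sampling error ≈ √(dN/N-sites), ~5·10⁵ codons per bin
give binned Pearson r ≥ 0.9 for the shallowest (eukarya) slope, and
1.5·10⁵ per bin give essentially full power for the eukarya-vs-vertebrata
interaction at p < 0.01. The test suite and the acceptance script use
these sizes (and 100–200 structures for corpus training, 50–150
replicate structures for group comparisons), which keep the full run in
the minutes range on one CPU; they are package defaults chosen for
statistical adequacy, not empirical claims.

## Known limitations

* The counting dN/dS estimator saturates (pS ≥ 3/4) on deeply diverged
  pairs; that is signalled, not silently truncated.
* ΔG has no physical units; only comparisons under the same trained
  model are meaningful, and cross-group comparisons must be
  length-paired.
* The four-body table trained on synthetic globules is not transferable
  to real proteins; retrain on a real non-redundant corpus before any
  application beyond the synthetic benchmark.
* Exact Wilcoxon enumeration is skipped in the presence of ties; with
  heavily discrete inputs (identical codon counts) the approximation is
  mildly conservative.
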