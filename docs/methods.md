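# Methods

This note documents the models, parameter defaults, numerical choices
and known limitations of `solstab`. Everything stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Structure layer

Structures are read with Biopython's PDB parser. Waters and non-polymer
heteroatoms are discarded; non-standard polymer residues are kept as
`'X'` and never proposed for mutation. Per chain both the SEQRES
(construct) sequence and the coordinate-derived sequence are kept: the
solubility machinery works on the construct sequence (regions of
missing density still contribute to solution behaviour), while exposure
and contacts exist only for resolved residues. When SEQRES is absent
the coordinate sequence stands in. Residues are keyed by
`(chain, author number, insertion code)`.

**Solvent exposure.** Accessible surface area uses Shrake–Rupley sphere
sampling with a deterministic golden-spiral point set (default 256
points per atom; the acceptance tests cross-check against 1024), probe
radius 1.4 Å, heavy atoms only, and a fixed element-radius table
(C 1.70, N 1.55, O 1.52, S 1.80 Å, default 1.80). Relative exposure
divides the per-residue area by the theoretical maximum accessibility
of that residue type in an extended Gly-X-Gly tripeptide (Tien et al.
2013 theoretical values), clipped to [0, 1]. A residue counts as
solvent-exposed at relative exposure ≥ 0.10 (inclusive boundary).

**Contacts.** Two residues are in contact when their minimum heavy-atom
distance is ≤ 8.0 Å (configurable; the underlying tools that inspired
this pipeline do not expose their cutoff, so the value is a declared
default). The map is symmetric and irreflexive, built with a k-d tree
and verified against an O(n²) scan in the tests.

**Identity groups.** Chains are grouped by exact comparison-sequence
equality; a manual specification overrides this (accepted with a
warning even for unequal lengths, to accommodate non-canonical PDB
files). Mutations are designed on the first designable chain of each
group and mirrored to the rest; single-chain ΔΔG values are multiplied
by the group size.

## Phylogenetic layer

Alignments are read from aligned FASTA or A3M (lowercase insert states
removed; columns where the master row carries a gap are dropped so
positions index the master). PSSM construction per column: gap-excluded
counts plus a background-proportional pseudocount of total weight 1.0,
`f_a = (c_a + τ q_a) / (n + τ)`, uniform background by default. With
≥ 50 sequences the matrix stores `ln(f_a / q_a)`; below that, raw
smoothed frequencies (PWM), whose "permitted" threshold is f ≥ 0.05 —
chosen to mirror the PWM wild-type-rarity threshold (f < 0.05), the one
PWM constant the design rules fix. Columns with ≥ 50 % gaps are flagged
low-confidence but used.

The conservation index is the normalised-entropy complement
`CI_j = 1 − H_j / ln 20` computed from the *unsmoothed* column
frequencies, so an invariant column is exactly 1 and a uniform column
exactly 0. This particular functional form is a declared, configurable
choice; other monotone concentration measures would serve.

Permitted substitutions at a position: `ll_pos` keeps amino acids with
positive log-likelihood (PWM: f ≥ 0.05); `ll_and_delta` (the default)
additionally requires a positive Δlog-likelihood over the wild type
(PWM: higher frequency). The wild type is never returned; excluded
target residues are removed downstream so the scan can log them as
attempted-and-rejected.

## Solubility surrogate

The bundled solubility model follows the architecture of profile-based
aggregation predictors but with transparent, unfitted coefficients —
the pipeline contract only needs a deterministic, monotone solubility
functional behind a stable interface, and external per-residue/global
scores can be imported from CSV as a drop-in replacement.

Raw residue score: `r = w_h(−ĥ) + w_q|q| + w_b(−β̂)` with ĥ the z-scored
Kyte–Doolittle hydropathy, q the net charge at pH 7 (D,E −1; K,R +1;
H +0.1), β̂ the z-scored Chou–Fasman β-sheet propensity, and weights
1.0 / 0.5 / 0.5. Unknown residues score 0. The intrinsic profile is the
7-residue window mean (truncated at termini). The global score over one
or more chains pools the per-chain profiles and subtracts a penalty for
poorly soluble residues:

    G = mean(p) − (1/L) Σ max(0, −1 − p_i).

Chains are profiled independently before pooling, so chain boundaries
do not create window artefacts; as a consequence a two-chain complex is
only equivalent to the concatenated single sequence when no averaging
window would span the junction.

The structurally corrected profile averages each residue's intrinsic
value with its contact neighbours and weights by exposure,
`p̃_i = e_i · Σ_{j∈{i}∪N(i)} p_j / (1+|N(i)|)`: buried residues score
exactly zero, low-scoring exposed patches mark aggregation hotspots.
The true structural-correction functional of fitted predictors
(including its exposure-weight exponent) is more elaborate; this linear
form is a declared stand-in with the same qualitative behaviour.

## Stability surrogate

ΔΔG (kcal/mol, negative = stabilising) from burial b = 1 − exposure:

    ΔΔG = 0.8·b·(ĥ_wt − ĥ_mut) + 1.0·b·max(0, V_mut − V_wt)/100
        + 1.0·[mut = Pro] + 0.5·[wt = Gly] + Σ pair terms,

with V the Zamyatnin residue volume (Å³). Burying more hydrophobic,
not-larger residues stabilises; over-packing, proline introduction and
glycine removal destabilise. The model is exactly additive over
mutation sets unless explicit pairwise terms are supplied
(`pair_terms`, applied only when the partner mutation is in context and
the sites are in structural contact) — this is deliberate plumbing so
the sequential interaction check can be exercised with scripted
non-additive scenarios. The predictor is deterministic, so replicate
statistics (default n = 3, mirroring common replicate reporting for
stochastic energy functions) have sd = 0. A CSV adapter
(`mutation_name, ddg[, run]`) injects externally computed values with
population-sd replicate aggregation; no claim of equivalence to any
licensed energy function is made, the contract is "signed kcal/mol,
negative stabilising".

A consequence of the surrogate's form worth knowing: a substitution is
stabilising only if it increases hydropathy, so mutations that are both
solubilising and stabilising are largely those replacing one
hydrophilic residue by a slightly more hydropathy-favourable one
(Arg→Lys, Arg→Glu, His→Lys, Trp/Tyr→Ser/Thr/Gly). The synthetic demo
fixture was composed around this interplay: it places arginines with
lysine-enriched homolog columns (which survive the full filter chain)
next to a hydrophobic patch whose solubilising substitutions fail the
stability filter (populating the drop-reason audit trail), plus one
conserved position with a rare wild type. Passing tests on these
fixtures demonstrate the pipeline's filter logic, bookkeeping and
determinism; they say nothing about predictive accuracy on real
proteins, which is entirely inherited from the plugged-in predictors.

## Design pipeline

Thresholds (all configurable): intrinsic-profile hotspot θ_seq = −1
(sites additionally require exposure ≥ 0.10); corrected-profile hotspot
θ_str = −0.5 (the profile thresholds are declared values — the
qualitative convention is that negative profile regions are
aggregation-prone); conservation sites need CI > 0.25 and a rare wild
type, with no exposure requirement; exposed-solubility sites are
suppressed when CI > 0.7 and the wild type is the consensus. The site
cap (default 100 logical sites) never truncates the first three
classes; when they already reach the cap the exposed-solubility class
is discarded wholesale, otherwise its sites are admitted in decreasing
order of best achievable solubility gain until the cap. Excluded
targets default to {C, M} (oxidation/dimerisation liabilities).

Scan filters, in order: excluded target; solubility loss (waived at
conservation sites below the exposure threshold — near-surface
liabilities are worth stabilising even at a small solubility cost);
propagated ΔΔG ≥ 0. The full attempts table with drop reasons is kept
for audit; every retained record re-satisfies its filters by
construction, which the acceptance tests re-verify exhaustively.

Δlog-likelihood values are normalised by the standard deviation of all
entries of the record's chain PSSM (degenerate sd ≤ 1e-12 → 0), making
phylogenetic gains comparable across chains.

Combination: singles with negative Mutation Score are discarded. Pairs
enumerate all site-disjoint combinations of survivors; from triples
onward only the top substitution per site is used. Groups are built by
exact enumeration while the combinatorial count stays below
`max_group_designs` (default 20 000); beyond that a deterministic beam
extension of the previous group (width 500) takes over — a guard that
never triggers at fixture scale. Ties in every ranking are broken by
(lower ΔΔG sum, higher ΔSol, lexicographic names), making all outputs
order-deterministic.

**Knee rule.** With M(n) the top score of group n and
g(n) = M(n) − M(n−1): an interior n is selected when
g(n+1) < mean(g(2..n)); if none qualifies the largest group is the best
trade-off; the largest group is additionally included when its own gain
still exceeds the mean of the earlier gains. The shortlist takes three
designs per selected group and one per other group, so every mutation
count is represented.

**Interaction check.** For flagged shortlisted designs, mutations are
applied sequentially in descending single-score order (the order is a
declared choice), each scored in the context of those already applied.
A mutation whose in-context propagated ΔΔG is ≥ 0 is replaced by the
best of up to three ranked alternatives at its site; failing that the
site is dropped and the design competes in the group of its new size.
Scores are recomputed from in-context ΔΔG values; the group is
re-ranked and the check repeated on a new leader at most three times;
the best checked-or-unflagged design represents the group. For an
additive predictor the check provably changes nothing, which the tests
assert.

Antigen-contact flags (any WT heavy atom within 4.5 Å of an antigen
chain) are advisory only and never alter scores.

Instead of modelled mutant structures the pipeline emits mutant
sequences as FASTA plus mutation lists; side-chain modelling is out of
scope.

## FDR benchmark

Records carry experimental and predicted ΔΔG canonicalised to
negative-stabilising (an explicit sign-convention switch handles tables
with the opposite convention). ΔΔG exactly 0 counts as non-stabilising
on both axes (the sign quadrants leave the axis unassigned; this is the
declared tie-break). FDR = FP/(FP+TP), defined as 0 when no positives
remain; an empty filtered set is an error, not a silent 0.

The resampling p-value draws `n_resample` uniform subsets (without
replacement) of the full record set at the filtered subset's size and
uses the add-one estimator `p = (1 + #{FDR ≤ observed})/(n_resample+1)`
(never exactly zero; one-sided by declaration). Subsets with no
predicted positives count FDR 0. The estimator is vectorised; 10 000
resamples on 2 000 records take about a second.

## Synthetic study conditions

The fixture generators define the conditions under which the package
tests and acceptance numbers are computed:

* **Helix PDBs**: ideal α-helix backbone (φ −57°, ψ −47°, Engh–Huber
  style bond geometry) plus Cβ at tetrahedral geometry; no further
  side-chain atoms, so exposure and contacts operate on backbone+Cβ.
  Chains are rigidly offset (default 30 Å, i.e. non-contacting).
* **MSAs**: per-column categorical sampling with a consensus fraction
  (default 0.85 in the demo) and explicit distributions for enriched
  columns; depth 80 (log-likelihood regime) unless a PWM is wanted.
* **Benchmark tables**: 2 000 records split equally into a
  positive-Δlog-likelihood stratum with FDR 0.15 among predicted
  stabilisers and a complement stratum with FDR 0.45, giving an overall
  expected FDR of 0.30; half the complement keeps a positive mutant
  log-likelihood so the two filters are strictly nested. Magnitudes are
  |N(1, 0.5)| + 0.05 kcal/mol. All generators are pure functions of
  their arguments.

These sizes keep the full test suite under a minute on one core while
leaving the statistical checks (99 % binomial intervals at n = 2000,
exhaustive enumeration at n = 8, KS uniformity over 200 replications)
well-powered.

## Limitations

* Both surrogates are transparent stand-ins: they reproduce the
  *shape* of the design problem (profile-based solubility,
  burial-weighted stability, their partial conflict), not validated
  predictions. Real use should inject external predictor outputs
  through the CSV interfaces.
* No mutant structure modelling; the interaction check relies on the
  pluggable predictor's context terms, not on remodelled coordinates.
* mmCIF, .hhm profiles, hydrogen handling, and pH/ionic-strength
  dependence of solubility are out of scope.
* Sequence/structure index mapping assumes the coordinate sequence is a
  contiguous window of SEQRES; anything else falls back to order-based
  mapping with a warning.
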