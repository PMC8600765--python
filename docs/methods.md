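# Methods

This note records the models, defaults and design decisions behind
`plexdesign`, and what the synthetic test scenarios do and do not show.

## Nearest-neighbour thermodynamics

Duplex ΔH/ΔS are summed from the unified Watson–Crick nearest-neighbour
parameters with the standard initiation and terminal-A·T terms; single
internal mismatches use the published mismatch stack tables (G·T, A·C, G·A,
C·T and the like-with-like pairs). The table ships as
`data/nn_parameters.tsv` (kind, key, ΔH kcal/mol, ΔS cal/mol·K; key
convention `XY/WZ` = top 5′-XY-3′ over bottom 3′-WZ-5′) so it is auditable
and swappable.

* Tm: ΔH·1000 / (ΔS′ + R ln k) − 273.15 with k = C_T/4 for
  non-self-complementary duplexes (C_T the total strand concentration),
  ΔS′ = ΔS + 0.368·(N−1)·ln[Na⁺]_eq, and
  [Na⁺]_eq = monovalent + 120·√(Mg²⁺ − dNTP) (mM). DMSO subtracts
  0.6 °C per percent.
* ΔG is reported at a configurable temperature (default 37 °C) as
  ΔH − T·ΔS′, without the bimolecular concentration term.
* Mismatch scoring: an isolated internal mismatch contributes its two
  tabulated mismatch stacks. Runs of ≥ 2 adjacent mismatches, terminal
  mismatches, and untabulated contexts contribute nothing. This
  *overestimates* binding (a free, open region costs nothing), which is the
  conservative direction for a specificity screen: a site is never missed
  because its penalty was guessed too harsh.
* Hairpins: exhaustive enumeration over all stem placements and extensions,
  minimum stem 3 bp, minimum loop 3 nt; loop penalties from the unified
  loop table (ΔH_loop = 0) with Jacobson–Stockmayer extrapolation beyond
  30 nt; unimolecular Tm = ΔH/ΔS′. Exhaustive search is exact and cheap at
  tag+primer scale (≤ ~60 nt, O(n²) stems).
* Heterodimers: every maximal contiguous complementary run (≥ 3 bp) in
  every ungapped register, scored as a bimolecular duplex; symmetric in its
  arguments by construction.

Buffer defaults — 50 mM monovalent, 1.5 mM Mg²⁺, 0.6 mM dNTP, 0 % DMSO,
50 nM oligo — are the common defaults of thermodynamic screening tools; the
method's source does not print its formulation, so these are this package's
declared choice and every value is configurable.

## Candidate design

All substrings within the length (18/20/25), Tm (57/60/63 °C) and GC
(30–70 %) bounds are enumerated on each flank — forward entirely 5′ of the
target, reverse entirely 3′, so the amplicon always contains the whole
target interval (the targets are variants to be sequenced through, so
overlap is not enough). Tm over all substrings uses prefix sums of the
stack contributions, then an exact per-candidate evaluation. Pairs are
ranked by

    w_tm·(|Tm_F − Tm_opt| + |Tm_R − Tm_opt|) + w_len·(|len_F − len_opt| + |len_R − len_opt|)

(weights 1.0), ties broken by smaller product, leftmost forward start, then
lexicographic sequence, so output order is total and reproducible. The
ranking formula is this package's own definition; the method's source
delegates candidate generation to an external library and never states one.
Up to 20 pairs per target are kept (the original service's per-target
limit). Each side is pruned to its best 400 candidates before pairing, with
a full-set fallback when the pruned sets admit no size-compatible pair; if
the full sets still admit none, the failure reason is "product size" with
both side counts recorded — the signature of a target longer than the
product maximum.

5′ tags (defaults: the two Illumina two-step-PCR tags, 34 and 33 nt) are
prepended for all secondary-structure checks; genome alignment uses the
untagged primer, since only the primer portion anneals to template.

## Binding-site discovery

The four annealing conditions (aligned length ≥ 13 bp, ≤ 8 mismatches, ≤ 2
mismatches in the 3′-terminal 3 bases, ΔG ≤ −10 kcal/mol) are the filter;
no alignment statistic is computed. Alignments are ungapped and full-length
(indel binding is treated as non-binding). The boundary semantics
("longer than 12 bp" → ≥ 13, "smaller than 9" → ≤ 8, "smaller than 3" → ≤ 2)
are fixed in `DesignParameters` and pinned by tests. The ΔG rule flags
*strong* binding (ΔG at or below the threshold): binding stronger than
−10 kcal/mol is what amplifies.

Two discovery modes share the condition evaluation:

* **exhaustive** (default for references up to 2 Mb, which covers every
  desk-scale design): a vectorised every-offset mismatch prefilter on both
  strands, then the remaining conditions. The reported set is exactly the
  set passing the four conditions — this is what the oracle-equivalence
  tests pin.
* **seeded** (large references): a k-mer index (default k = 12, configurable
  8–16) provides anchors from every k-mer of the primer; every register of
  both strands within a primer length of an anchor is scored, which also
  catches near-palindromic opposite-strand sites co-located with a seeded
  region. Guarantee: any site within a primer length of an exact k-mer
  match of the primer is found. Sites whose mismatches break every k-mer in
  their whole neighbourhood are unseedable; among sites that also pass the
  ΔG condition these are vanishingly rare, so the seeded mode is a sound
  genome-scale approximation — but it is an approximation, which is why it
  is not the desk-scale default.

Amplicons: two sites on one chromosome, 3′ ends convergent, span measured
5′-outermost to 5′-outermost ≤ 500 bp (the template-fragmentation design
makes longer products unamplifiable). FR, FF and RR pairings are all
considered. An amplicon is on-target when both sites are the pair's
intended ones and the product contains one of the pair's targets; a product
containing no run target at all is a false amplicon.

## Filters and attribution

The four per-pair filters are pure predicates, so the surviving set is
independent of filter order (a property test permutes the order). The fixed
order hairpin → dimer → masked area → masked site → specificity only
determines *stage attribution*: each dropped pair is charged to its first
failing stage, so per-stage counts partition the failures the way a
single-reason failure report expects. Thresholds are strict: Tm exactly
45.0 / 40.0 °C passes. Whether masks are checked before structure is not
stated by the method's source; the order here is fixed and documented, and
the kept set does not depend on it.

## Clustering

Unity uses the pair-mean of the two primer Tm values (the source does not
say which Tm; product Tm would also be defensible) with strict < 150 bp
and < 5 °C comparisons. Cross-incompatibility evaluates all four tagged
primer combinations for dimers and counts cross false amplicons from the
cached binding sites of both pairs.

The greedy pass seeds the remaining pair with the fewest nonspecific sites
(ties: lower penalty, then pair id), deletes incompatible pairs of other
targets at budget 0 and the seeded target's other candidates, and stops
when the pool is empty — giving a pairwise-compatible, maximal (not
necessarily optimal) cluster. Relaxation is a separate post-pass: uncovered
targets re-enter if their *total* cross false amplicons against all current
members fit the budget (0–4), admitted fewest-first; members are never
evicted, so coverage is monotone in the budget. Overlap collapse then
removes members whose target lies wholly inside another member's amplicon
(most-covering amplicon first, ties by pair id, one pass to a fixed point)
and records the assignment, so panels can cover more targets than they have
pairs.

The brute-force reference enumerates one-pair-per-target selections
(guarded to m ≤ 8, n ≤ 3) and counts nonspecific-site × nonspecific-site
comparisons over the four primer combinations of every cross-target
candidate pair; on uniform-k instances this equals C(m,2)·4·(nk)², e.g.
192 for m = 3, n = 2, k = 2. Greedy output is validated against it for
validity, maximality and dominance — optimality is explicitly not the
contract.

## Synthetic scenarios

The fixture generator plants every behaviour by construction. Loci are
"designable islands": engineered ~20-mers with Tm within 0.4 °C of the
optimum embedded in an AT-rich background (GC 0.12) in which essentially no
substring reaches the candidate Tm window, so the designed pairs are known.
Scenario construction then *reverse-engineers*: it runs the real candidate
designer, takes the rank-1 pair, and plants decoys from those exact
sequences — verbatim amplicon copies (specificity traps), 5′-mutated copies
(mutations never in the 3′-terminal 8 bases: the 3′-intact near-copy is
both the PCR-relevant off-target class and the one with a guaranteed
detection path), mask entries at exact 3′ offsets, convergent cross-pair
motifs at stated spacings, and tags that fold the tagged primer into a
12 bp stem. Construction verifies its own invariants — the designed pair
stays on the island, survives the structure filters, and the planted
specificity verdicts and cross-amplicon counts hold exactly — and retries
with fresh deterministic draws otherwise, so a given (name, seed) always
yields the same genome and truth table.

What passing these scenarios shows: every rule of the engine fires exactly
where planted, at its stated boundary. What it does not show: behaviour on
real genomes with repeat families, homopolymers, CpG islands and ambiguous
bases; the background here is i.i.d. and the islands are clean by design.
The separate random-instance clustering tests exercise unity/dimer/amplicon
interactions the planted scenarios hold fixed.

Problem sizes used by the default test run and the acceptance script — 100
primers × 5 kb genomes for oracle equivalence, 200 oligos for the
thermodynamic comparison, a 20-target panel, a 9-target relaxation ladder,
50 random clustering instances (m ≤ 7, n ≤ 3) — were chosen so the whole
surface runs in well under a minute each while every rule is still
exercised at its boundary.

## Known limitations

* No gapped alignment: a binding site with an indel is treated as
  non-binding.
* No partition-function structure prediction; hairpin/dimer evaluation is
  optimal-stem under the two-state model.
* Terminal mismatches contribute no stacking term (conservative).
* Single-tube panels only: targets incompatible with the cluster are
  reported, not split into a second pool.
* The seeded discovery mode can miss heavily mismatched sites (documented
  guarantee above); exhaustive mode is exact but quadratic in reference
  size, hence the 2 Mb auto threshold.
* Primer concentration balancing and anything downstream of sequence
  design (library construction, read analysis) are out of scope.
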