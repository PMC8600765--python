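# plexdesign

Multiplex PCR primer panel design for targeted sequencing.

Genotyping panels read out tens to hundreds of genomic variants in a single
PCR tube. At high plexity the design problem is dominated not by designing
each primer pair in isolation but by what the pairs do *to each other* and
to the rest of the genome: hairpins and primer dimers kill amplification,
primers landing on SNPs or repeats mis-prime, and any two convergent binding
sites anywhere in the genome within amplifiable distance create a spurious
product that steals reads. `plexdesign` takes a reference genome (FASTA) and
a target list (BED4 with a target-ID column), designs candidate primer pairs
per target, screens them individually, and assembles one mutually compatible
panel — reporting, for every target, either its primers or the precise
reason it failed.

It is a library plus a small CLI, intended for people building amplicon
panels (variant hotspot assays, GT-seq-style genotyping) on any species with
a reference sequence.

## Method

**Thermodynamics.** Duplex stability is computed with the unified
nearest-neighbour model: ΔH and ΔS are sums of stacked-dinucleotide terms
plus initiation, Tm = ΔH / (ΔS + R ln C_T/4) with the entropy salt-corrected
by 0.368·(N−1)·ln[Na⁺]_eq, and ΔG(T) = ΔH − T·ΔS. Single internal
mismatches are scored from the published mismatch stack tables; longer
mismatch runs are treated as unstacked. Hairpins are found by exhaustive
stem enumeration (minimum 3 bp stem / 3 nt loop), heterodimers by scoring
every complementary run in every ungapped register. The parameter table
ships as a plain-text file (`src/plexdesign/data/nn_parameters.tsv`).

**Per-pair screening.** Candidate pairs (length/Tm/GC bounded, amplicon
containing the whole target, penalty-ranked) are dropped if: a tagged primer
hairpins with Tm > 45 °C; the tagged forward/reverse heterodimer has
Tm > 40 °C; the 3′-terminal 7 bases of a primer touch a masked site (SNP) or
area (repeat); or the pair can form any off-target amplicon genome-wide.

**Binding sites and off-target amplicons.** A genome location is a binding
site when the alignment is longer than 12 bp, has fewer than 9 mismatches,
fewer than 3 mismatches in the 3′-terminal bases, and annealing
ΔG ≤ −10 kcal/mol. Any two convergent sites (forward–reverse,
forward–forward or reverse–reverse) within 500 bp form a predicted amplicon;
amplicons containing no target are false positives.

**Panel assembly.** Pairs sharing a tube must satisfy *unity* (product
lengths within 150 bp, pair-mean Tm within 5 °C) and show no cross dimer and
no more cross false amplicons than an allowed budget. Testing all pairs
against all pairs costs C(m,2)·4·(nk)² site comparisons for m targets, n
candidates per target and k nonspecific sites per primer; instead, a greedy
*seed pair* strategy repeatedly promotes the remaining pair with the fewest
nonspecific binding sites and deletes whatever is incompatible with it.
Uncovered targets can be re-admitted by relaxing the cross-false-amplicon
budget (0–4) without evicting members, and targets whose interval falls
inside another member's amplicon are collapsed onto that amplicon, so the
final panel can cover more targets than it has primer pairs. A brute-force
optimal search doubles as a correctness oracle on small instances.

## Worked example

Scenarios with known ground truth can be emitted as ordinary input files.
Here a target (`t_dup`) whose amplicon is duplicated verbatim 2 kb away is
designed next to a clean target (`t_weak`):

```bash
plexdesign fixture --name decoy_duplicate --out demo/fixture
plexdesign design \
    --genome demo/fixture/genome.fasta --targets demo/fixture/targets.bed \
    --out demo/out \
    --product-max 340 --tm-min 58 --tm-max 62.5 --n-candidates-per-target 1
```

prints

```
plexdesign 0.1.0 design summary
targets: 2
  design failed:      0
  filtered out:       1
  clustered:          1
  covered by overlap: 0
  uncovered:          0
panel: 1 primer pairs covering 1 targets (budget 0)
filtration stages (targets): specificity=1
```

`t_dup` was filtered at the specificity stage — its failure-ledger row
records the off-target product (`chr1:5489-5746`, orientation FR) that the
duplicated locus would amplify — while `t_weak`'s pair
(`ACTGTTCAAAGAGCCGCACT` / `GAGTACCAAGCTGGCCTGTT`, Tm 60.1/59.9 °C, 289 bp
product) enters the panel. `demo/out/` holds the panel TSV, amplicon BED,
failure ledger TSV, cluster JSON and the config echo.

Other subcommands: `plexdesign sites` (genome-wide binding-site scan for a
primer list), `plexdesign check` (compatibility matrix for an existing
panel TSV).

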