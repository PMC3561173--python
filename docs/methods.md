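# Methods

This note documents the models and procedures implemented in levigene,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Coordinates and translation

All coordinates are 1-based and fully inclusive on the plus strand (the
convention levivirus annotations are printed in: a gene "between
nucleotides 2991–3104" spans 3104 − 2991 + 1 = 114 nt). GFF3 output uses
the same convention, so no shift is applied. Translation uses the
bacterial code (NCBI table 11); the non-AUG initiators GUG and UUG are
decoded as formyl-Met and reported as M, which is the only reading under
which a UUG-initiated 114-nt ORF yields a 37-residue product. Input DNA
is silently transcribed to RNA; mixed case is accepted.

## ORF enumeration and architecture assignment

`find_orfs` reports every maximal stop-terminated ORF over a configurable
start-codon set (default {AUG, GUG, UUG} — levivirus lysis genes are
known to initiate at UUG). Nested starts sharing a stop are all reported,
the 5′-most flagged primary; choosing among them properly needs
initiation-context evidence, which is the lysis screen's job, not the
scanner's. Defaults: 30 aa minimum for core-gene scanning, 17 aa for
alternate-frame probing (so a short negative-control ORF in a shifted
frame is still reportable).

Architecture assignment searches ordered, non-nested primary-ORF triples
and maximizes total coding length plus a soft size-band bonus
(maturation 390–450 aa, coat 120–140 aa, replicase 530–590 aa; linear
decay with scale 100 aa outside a band, weight 300 nt). The bands encode
typical *Leviviridae* proportions and are configurable; they bias, never
veto, so an atypical genome still gets its best-scoring ordered triple.
Consecutive genes may overlap by ≤ 45 nt (small junction overlaps occur
in real genomes). If no valid triple exists the error carries the best
partial assignment.

## Reduced nearest-neighbor folding

The folder minimizes free energy over nested structures with
Watson–Crick and G·U pairs, minimum hairpin loop 3 nt. The energy model
(shipped as TSV fixtures under `structure/params/`) contains:

- helix stacking energies for all ordered pairs of the six pair types,
  Turner-1999-derived, rounded to 0.1 kcal/mol, satisfying
  stack(p, q) = stack(rev q, rev p);
- hairpin/bulge/internal loop initiation penalties for tabulated sizes,
  extended by the Jacobson–Stockmayer form ΔG(n) = ΔG(n_max) +
  1.08·ln(n/n_max);
- a flat multiloop closing penalty (3.4 kcal/mol) plus 0.4 per branch,
  unpaired multiloop bases free.

Deliberately omitted: dangles, coaxial stacking, terminal-AU penalties,
loop-sequence bonuses, asymmetry penalties, and any ensemble/partition
computation. The purpose is local stem-loop detection, and the reduction
keeps the DP exactly testable: the recursion mirrors the loop
decomposition of the independent structure evaluator, so on short windows
the DP optimum equals exhaustive enumeration (asserted over hundreds of
random windows in the tests). Energies are integers in 0.1 kcal/mol
internally, so no comparison ever hinges on float rounding.

Numerical choices: interior loops are capped at 30 unpaired nt (standard
practice; larger interior loops are never competitive at the window sizes
used); windows are capped at 400 nt because the pipeline folds only local
contexts (start-codon windows of 30 nt, operator windows of ~48 nt, the
3′ domain of ≤ ~160 nt); co-optimal structures are resolved by maximizing
the pair count (exactly, via lexicographic DP on (energy, −pairs)) and
then by a fixed traceback order that prefers 5′-most pairing — fully
deterministic, though not a certified lexicographic minimum over
dot-bracket strings. When no structure is negative the open chain is
returned, so energy 0 always means "no pairs".

## Element detectors

- **5′ hairpin**: fold the first 40 nt; report the 5′-most hairpin if its
  isolated ΔG ≤ −8 kcal/mol and stem GC fraction ≥ 0.6. The thresholds
  render "stable GC-rich hairpin" operational and are configurable.
- **Operator**: fold −30..+15 around the replicase start; return the
  hairpin containing the start codon with two diagnostics of a
  coat-protein-binding operator: an adenine in the loop exactly 4 nt
  upstream of the start codon, and ≥ 1 bulged purine in the stem (the arm
  is walked outward through bulges of ≤ 3 nt).
- **3′ domain**: fold the 3′ UTR plus ≤ 60 nt of replicase tail. The
  outermost duplex whose 3′ arm reaches within 5 nt of the terminus, with
  ≥ 4 bp, is ld IX. Hairpins inside the UTR are labeled U1, U2, …
  counting from the 3′ end (replicase-tail hairpins R1, R2, …); the
  unpaired stretch between the two 3′-terminal hairpins — where several
  plasmid-specific phages carry a linker instead of the adenine-rich
  hairpin V — is reported when fully unpaired.
- **Pseudoknot partner search**: pure antiparallel complementarity
  scanning (no pseudoknot folding), default band 1000–1400 nt upstream,
  ≥ 5 contiguous pairs to the loop, Watson–Crick only with a G·U switch.
  Distance convention, stated in every report: loop 5′ start minus
  partner 3′ end, so a partner ending 1215 nt before the loop scores
  distance 1215. Candidates are maximal windows ranked by pair count,
  then proximity to the band center.

## The lysis screen

Criteria and defaults as in the README. Points that were genuinely open:

- The TM criterion replaces an HMM-server probability with the
  Kyte–Doolittle window criterion (w = 19, mean ≥ 1.6 — the published
  surface/buried threshold); an HMM posterior is not reproducible without
  that server, a hydropathy rule is, and for single-TM lysis peptides the
  two agree in practice.
- SD spacing counts nucleotides strictly between the motif 3′ end and
  the start codon's first nt; the accepted window 4–14 nt brackets
  canonical bacterial spacings. Ties between equal-length motifs resolve
  toward spacing 9, the arrangement observed in this family.
- Composite weights (0.4/0.3/0.2/0.1) are this package's own ranking
  convention for four qualitative criteria; they are config-exposed and
  echoed into every report. Length contributes via a soft band: full
  credit 34–120 aa, decaying above (known lysis proteins are short).
- Core genes and their in-frame truncations (same stop, same frame) are
  excluded from the candidate pool; alternative starts of a cistron are
  not separate genes. Candidates overlapping the maturation gene are not
  penalized — nothing rules out that location, and one known phage uses
  the region 5′ of maturation.
- An empty candidate list is a reported result, not an error: the
  canonical-location probes (coat/replicase junction frames,
  replicase-internal frames, 5′ of maturation) state where candidates
  were and were not found, reproducing the elimination logic used when a
  lysis gene is *not* at the usual place.

## Comparative stage

Global alignment is Gotoh's affine-gap Needleman–Wunsch (gap of length L
costs open + (L−1)·extend; BLOSUM62 with −11/−1 for proteins, +2/−1 with
−5/−2 for RNA), with a deterministic diagonal > up > left traceback.
Percent identity divides identical columns by all alignment columns
(switchable to the shorter-sequence convention; the choice is logged in
reports because printed identity values in the literature rarely state
their denominator). UPGMA uses cluster-size-weighted arithmetic-mean
linkage, node height = merge distance / 2; output is ultrametric by
construction and recovers ultrametric inputs exactly. Bootstrap supports
resample alignment columns with replacement (500 replicates by default,
the field's standard protocol); replicate r draws from an RNG substream
derived from (seed, r), so supports are reproducible and invariant to
taxon order. Distances for trees are p-distances with pairwise deletion
of gapped columns. The multiple aligner is an in-repo progressive
aligner (identity-distance UPGMA guide tree, profile–profile merge with
mean-column scoring): deterministic and adequate for the
closely-controlled synthetic families used in validation; it is not a
general-purpose MSA tool.

## Synthetic genomes: what they emulate, and what they do not

`generate_genome` emits a 3405-nt genome with maturation (62–1270), coat
(1280–1669) and replicase (1703–3304) in order, terminal UTRs carrying
the planted structural elements, and a 37-codon lysis ORF in one of three
layouts: inside replicase in a shifted frame at 2991–3104 (the default,
mirroring the smallest known genome of the family), overlapping the
coat/replicase junction, or 5′ of maturation. The planted lysis gene
satisfies all four screen criteria by construction: UUG start, GAGG at
spacing 9, a 19-codon hydrophobic block, AU-rich codons around the start
verified to fold weaker than −5 kcal/mol. One layout note: a replicase
ending at 3305 (a 100-nt 3′ UTR) would put a 2991-start ORF in the
*same* frame as replicase, which contradicts a frame-shifted overlap;
the generator therefore ends replicase at 3304, giving a 101-nt 3′ UTR —
the consistent rendering of "about 100 nt".

Generation is codon-level. Planted elements are written and locked
first; gene codons are sampled from synonymous sets of random proteins
subject to the locked positions, with overlap segments constructed under
a local host-frame constraint (every host codon the segment completes
must be sense, except the host's own stop where the layouts demand it,
and no start codons may arise in the frame of the next gene downstream).
Scrub passes then remove generation artifacts by synonymous codon swaps:
spurious screen-length ORFs get an in-frame stop; competing
complementarity windows in the pseudoknot search band are broken so the
planted partner is the unique hit; and the replicase tail is repaired —
first by string matching, then against an actual fold — so it cannot
out-pair ld IX at the terminus or invade the planted UTR structure.
Everything is deterministic per (config, seed).

What the generator does **not** emulate: real codon usage and
base-composition biases, mutational spectra, overlapping functional
constraints beyond the planted ones, recombination, or
secondary-structure-constrained evolution. Recovery rates measured on
these genomes show that the detectors find what the screen's assumptions
describe when it is present; they do not bound false-negative rates on
real genomes whose lysis genes may violate those assumptions (e.g.
weaker SD motifs or marginal hydropathy).

`evolve_family` simulates substitutions down a fixed ultrametric tree
(heights in expected substitutions/site per lineage): per branch each
site receives Poisson(t) events, each replacing the letter uniformly with
another — the Jukes–Cantor process, so two leaves under a root at height
h have expected p-distance 3/4·(1 − e^(−8h/3)), which the tests check in
closed form. Indels (single-site, disabled by default to keep the
p-distance oracle exact) exist only to stress the aligner. The fixed
6-taxon family used in bootstrap-recovery checks (((A,B),(C,D)),(E,F))
with cherry heights 0.03/0.03/0.05 on a 600-nt root, root seed 42,
evolution seed 7) is a named study condition: all true clades reach ≥ 95%
support at 500 replicates for any resampling seed.

## Problem sizes used in validation

The test suite and the acceptance script size their computations as
follows, as the package's own validation protocol: folding-oracle
equivalence over 500 (tests) / 300 (script) random windows of 4–12 nt;
planted-truth recovery over 100 genomes with lysis layouts cycling
through all three modes; bootstrap behavior at the protocol's 500
replicates; alignment oracles on sequences ≤ 30 residues where exhaustive
path enumeration is feasible.

## Known limitations

- The folding model is intentionally reduced; absolute ΔG values differ
  from full Turner-2004 implementations, and hairpin counts in long
  windows can merge or split relative to a full model. Thresholded
  detectors inherit this (their thresholds are calibrated to this model,
  not to any external folder). An external folding engine can be used as
  a cross-check, never as a dependency.
- The TM criterion is a hydropathy rule, not an HMM; it reports a window
  mean, not a probability.
- UPGMA assumes rate constancy (ultrametricity); like any UPGMA-based
  protocol it can misplace taxa under strong rate variation. No
  model-based distances (JTT, GTR) are provided.
- The progressive aligner has no iterative refinement and should not be
  used for distant homologs.
- The pseudoknot stage searches complementarity only; it does not fold
  pseudoknots or score their stability.
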