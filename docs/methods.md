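# Methods

This note documents the models, conventions and parameter choices
behind `studlines`, the reasoning where the design was genuinely open,
and what the synthetic fixtures do and do not establish about real
data.

## Coordinate frame and alignment

All positions are 1-based inclusive nucleotide positions ("np") on the
reference mitogenome numbering used in the equine mtDNA literature; no
0-based coordinates are ever exposed. The D-loop control region spans
np 15445–16660 and is tiled exactly by the UP segment (15445–16153)
and the DOWN segment (16154–16660). The 8-bp repeat array, whose copy
number varies through length heteroplasmy and is not reproducible
between sequencing runs, is masked from variant calling and haplotype
identity; its default bounds are np 16129–16153 and are configurable.

Queries are aligned as an infix of the reference (semi-global: free
end gaps on the reference, the whole query consumed) using edlib's
edit-distance alignment. Published analyses of this kind use generic
multiple aligners without reporting parameters, so the package fixes a
transparent contract instead: a placement is accepted if it needs at
most `max_distance_fraction` (default 0.25) edits per query base,
otherwise the sequence is rejected as unalignable; an accepted
placement must cover at least `min_overlap` (default 200) D-loop
positions. Indels are left-aligned against the reference. IUPAC
ambiguity codes are treated as non-calls: the corresponding reference
position is dropped from the coverage mask and never produces a
variant. This is deliberately conservative — an ambiguous base can
neither create nor veto a haplotype match.

## Haplotype identity under partial coverage

A haplotype is a named set of variants plus a coverage mask; positions
outside the mask ("nd") assert nothing. Two profiles match iff their
variant sets agree on the *intersection* of their coverages.
Consequences, all intended:

- a truncated sample consistent with exactly one catalogued haplotype
  is merged into it (coverage gaps never mint new haplotypes);
- a sample whose covered positions cannot discriminate between several
  catalogued haplotypes is reported as an ambiguity set;
- a sample sharing no covered position with any catalogued haplotype is
  an error ("uninformative sample"), not a new haplotype.

De novo clustering is the same operation run against an initially
empty catalogue; new profiles mint sequential names with a
configurable stud suffix.

Polymorphic-site counting defaults to the among-haplotypes definition
(a position counts iff ≥ 2 distinct states are observed among the
haplotypes covering it, skipping positions covered by fewer than two);
a vs-reference mode is available because variant tables are usually
printed reference-relative. Insertions occupy no reference position
and never contribute a site. Pairwise haplotype distances are plain
per-site mismatch counts over shared coverage — a deliberate
replacement for tree and network inference, which is out of scope.

Haplogroup classification is a pure rule engine: the highest-priority
rule whose full diagnostic motif is present and covered wins. The
package ships only a synthetic example rule set for its synthetic
catalogue; real analyses must supply real nomenclature motifs, which
are not redistributable here.

## Family assignment

The assignment procedure formalises the stepwise narrative a stud
manager follows. A haplotype's support is the set of families where it
was observed that no other haplotype has claimed yet.

1. **Rule A** (to exhaustion): a haplotype with singleton support
   claims that family — labelled `unique-support` if the support was a
   singleton in the raw table, `exclusion` if it shrank to one.
2. **Rule B**: among open haplotypes whose most-frequent family is
   unique, the one with the largest such count claims it (`majority`);
   ties in selection break by margin over the second-best family, then
   by name. Control returns to rule A.
3. Only when no open haplotype has a unique argmax does the tie rule
   fire: the top haplotype takes all its tied families as a shared
   assignment, and a tied family is withdrawn from the open pool only
   if every open haplotype observed in it retains an alternative.

Restricting rule B to unique-argmax candidates is the substantive
choice: a haplotype torn equally between two families (as the shared
Europa/Theodorosta haplotype is) should not pre-empt a haplotype with a
clear majority, because the clear majority may later resolve the tie by
exclusion. On the packaged census this ordering reproduces the
historically taken decisions exactly, and the exhaustive oracle
confirms the outcome is retention-optimal.

The oracle enumerates every family→haplotype map drawn from observed
support, subject to: every haplotype used, and at most one haplotype
shared between families, allowed only when those families have no
alternative. At the package's intended scale (≤ ~12×12) this is a few
hundred candidates. On error-injected data a full cover can be
legitimately infeasible; the oracle then reports the uncoverable
labels rather than guessing.

Frequencies are percentages of the grand total rounded half-to-even to
one decimal.

## MSY typing

One diagnostic position per locus, states `reference | variant |
missing` (missing = diagnostic position not covered by the alignment).
The rule table is configuration; the default maps a YE17 np-1277
variant to HT02 and a YXX variant to HT3, with all-observed-reference
genotypes called HT01. Which third locus defines HT3 is not settled by
the package's sources, hence the hard default plus the requirement
that analyses of real data set the table explicitly. Genotypes with
every locus missing are uncallable and are excluded from frequency
denominators (reported separately) to avoid silent bias.

## Pedigree statistics

*Reference population.* Defaults to individuals with no recorded
progeny — the current tip generation — and can be overridden with an
explicit id list.

*Inbreeding.* F_i is the Malécot kinship of i's parents, computed by
the standard recursive coancestry with memoisation; unknown parents
contribute no identity by descent. The test suite holds this
implementation equal (to 1e-12) to an independent Wright
path-counting oracle on random pedigrees.

*Founder contributions.* Expected genome proportions are propagated
down the pedigree by recursive halving. An individual with exactly one
known parent routes the unknown side to a phantom founder unique to
that slot, keeping Σq = 1; founders proper are individuals with both
parents unknown. The reported founder total counts both, since both
carry unexplained genome.

*Effective ancestors.* Greedy marginal-contribution selection: each
round scores every not-yet-selected individual by its expected
contribution to the reference gene pool counting only descent paths
that avoid previously selected ancestors (implemented by severing the
selected ancestors' parent links in the upward accumulation), then
selects the maximum; ties break lexicographically for determinism.
Selection stops when the best marginal contribution falls below
`epsilon` (default 1e-6) or the pool is fully explained. Reference
individuals themselves are eligible — a tip with unexplained genome
explains itself — which makes the founders-are-the-reference edge case
come out as f_a = f_e exactly.

*Founder genome equivalents.* Gene dropping: founders and phantoms
carry two uniquely labelled alleles; each replicate transmits alleles
Mendelian-randomly down the pedigree (vectorised across replicates);
N_g = 1/(2·mean(Σ p_a²)) over the reference pool, with a delta-method
Monte-Carlo standard error always reported. Default 10⁴ replicates;
the seed is mandatory and runs are bit-for-bit reproducible.

On every valid pedigree N_g ≤ f_a ≤ f_e ≤ founder total, up to
Monte-Carlo noise on N_g; the suite asserts this on simulated studs.

## Synthetic data: what it emulates, what it does not

The generator produces a closed stud: founder mares split into the
classical maternal families, founder stallions without family labels,
and within-stud mating generation by generation (Poisson offspring per
mare, sires drawn uniformly from the previous generation's males).
mtDNA haplotypes follow the dam line without mutation — haplotypes are
fixed per matriline, exactly the assumption the analysis itself makes.
Recording errors swap only the recorded family label, never the
transmitted haplotype, because discordance is to be interpreted as a
pedigree error rather than a biological event; each swap is logged so
detection can be scored exactly. Demographic defaults — 11 families,
4 foundress mares per family, 6 founder stallions, mean 3 offspring
per mare per generation, 5 generations — were chosen once as a
realistic, demographically viable closed nucleus (supercritical
matrilines; extinction triggers a bounded, logged retry).

The packaged ten-haplotype motif catalogue is synthetic: substitution
motifs on a synthetic reference frame, shaped to the summary structure
of the real stud's haplotypes — 55 distinct polymorphic sites in UP
and 8 in DOWN, per-haplotype private sites, shared blocks mirroring
the reported haplotype clusters (one five-haplotype group, one
three-haplotype group, DOWN-identical subgroups). The census fixture
(93 mares, 11 families, 10 haplotypes) is transcribed count-for-count
and expanded into deterministic per-mare records.

What passing tests therefore establish: the calling, clustering,
assignment, retention and gene-origin machinery is correct on data
with the assumed structure, including under 10% label noise and
truncated coverage. What they do not establish: robustness to real
sequencing artefacts (chimeric reads, heteroplasmy, alignment around
long indel runs), to mutation arising *within* a matriline, or to
haplotype catalogues whose motifs differ in kind from substitution
motifs. The repeat-array masking also means genuine variation inside
the repeat region is invisible by design.

## Numerical and degenerate-input conventions

- Deterministic everywhere: all stochastic stages take an explicit
  seed; the synthetic reference frame uses a fixed internal constant so
  the coordinate frame never varies between runs.
- Equal-cost alignment interpretations (substitution vs indel at equal
  edit distance) follow edlib's canonical path; indels are then
  left-normalised, so planted-substitution round trips are exact.
- Percentages: round-half-to-even, one decimal. Per-class rounding can
  make frequency columns sum to 100 ± 0.1 per class.
- Empty inputs fail loudly and early (no-data errors at contingency
  building, empty reference population, uncallable genotypes) rather
  than propagating empty frames.
- Pedigree cycles are hard errors naming the cycle; sex conflicts,
  dangling parent ids and birth-year inversions are reported as issues
  and only fatal in strict mode.

## Known limitations

- Tree/network phylogenetics and haplogroup motif discovery are out of
  scope; the pairwise difference matrix is the only divergence summary.
- The exhaustive matching oracle is exponential in table size and
  intended for tables up to roughly 12×12.
- The effective-ancestor algorithm is the standard greedy procedure;
  like all such implementations it is order-greedy, not provably
  optimal, and its exact p values depend on the severing convention
  documented above.
- Gene dropping stores one integer pair per individual per replicate;
  very large pedigrees with 10⁵ replicates may need the replicate count
  reduced.
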