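# Methods

`hydroscreen` implements, as a reusable and fully tested pipeline, the
"prioritize functional recognition, then sort" strategy for recovering
anaerobic hydrogen-producing microorganisms from metagenome-assembled
genomes (MAGs): screen annotation tables for the three fermentative
hydrogen-production marker enzymes, build draft digital cell models,
simulate growth across a carbon panel with flux balance analysis (FBA),
and compress the per-MAG requirements into a small set of selective
enrichment media.  Because the original sequencing data, annotation
databases and wet-lab outcomes are not reproducible at desk scale, the
package ships a synthetic-data generator with planted ground truth; all
claims about correctness are made against that truth.

## Screening model

A MAG enters the analysis as an identifier, taxonomy (domain…genus),
CheckM-style completeness and contamination percentages, and the set of
EC numbers annotated on its genome.

**Quality gates.** A MAG passes when completeness > 70% *and*
contamination < 10%, with strict inequalities: a MAG sitting exactly on
a threshold fails, making boundary behaviour deterministic.  Passing
MAGs are additionally tiered *high-quality* when completeness > 90% and
contamination < 5% (the stricter >95% variant is a config switch,
`hq_min_completeness: 95`).

**Candidacy.** The three marker enzymes are formate dehydrogenase
(FDH, EC 1.17.1.9; formate cleavage), acetate kinase (AK, EC 2.7.2.1;
acetate-type fermentation) and butyrate kinase (BK, EC 2.7.2.7;
butyrate-type fermentation).  EC matching is exact-string on fully
specified four-field ECs; partial ECs (`2.7.2.-`) never match, trading
recall for zero silent over-calling.  The default candidacy rule is
**any** of the three markers: a strict three-way intersection would make
the commonly reported high candidate fractions (roughly three quarters
of a screened cohort) impossible, whereas the union reproduces them; the
rule is a config switch (`triad_rule: all`).  The eight-region Venn
partition over the three markers is reported alongside, so any other
rule can be audited from the counts.  Archaeal MAGs are flagged (they
carry the markers but typically consume H₂ towards methane) without
being removed — exclusion is a reporting decision left to the user.

## Digital cell models

Draft models are reconstructed template-style: a universal model holds
one exchange and one transport per medium compound, EC-tagged catabolic
routes from every panel carbon, EC-tagged biosynthesis routes for every
trace supplement, and one biomass reaction; a genome keeps exactly the
EC-tagged reactions whose annotation it carries, plus all EC-free
(exchange/transport) reactions and biomass.  Reconstruction is therefore
monotone in the EC set.  Compartments are limited to internal/external;
bounds follow the standard convention (irreversible 0…1000, reversible
−1000…1000 mmol/gDW/h, exchanges closed to uptake until a medium opens
them).

The template's central design choice is the **two-pool biomass split**:
biomass requires two precursor pools A and B, and every carbon has two
independently EC-tagged catabolic reactions, one into each pool.  A
genome with both ECs of a carbon grows on it alone; a genome with only
the pool-A EC of one carbon and the pool-B EC of another needs both
carbons jointly.  This makes multi-carbon dependence expressible purely
in the EC set, so the same reconstruction code serves the real
annotation-driven path and the synthetic planted path, and planted
phenotypes are provable by construction.  Supplement biosynthesis draws
on pool A; a missing biosynthesis EC makes the supplement essential
because biomass consumes every supplement species unconditionally.
Synthetic pathway ECs live in the reserved fake namespace `9.9.x.y`,
which cannot collide with real EC annotations — the screening axis
(triad markers) and the growth axis are therefore independent by
construction.

## Flux balance analysis

Growth is the optimum of the linear program

maximize v_biomass  subject to  S·v = 0,  lb ≤ v ≤ ub,

solved with HiGHS (`scipy.optimize.linprog`).  Exchange reactions are
written `external metabolite →`, so uptake is negative flux; applying a
medium sets each exchange lower bound to −rate (default 10 mmol/gDW/h
per compound, a conventional figure) and closes everything else; under
anaerobiosis (default) the oxygen exchange is forced shut.  A model
"grows" when the optimum exceeds 10⁻⁶ strictly — small enough to be far
above solver noise at the default feasibility tolerance (10⁻⁹) and far
below any real optimum of these networks (order 1–10).  Optimal
witnesses are audited at 10⁻⁶ (‖S·v‖∞ and bound violations); solver-
grade and test-grade tolerances are deliberately distinct.  Only the
objective value is contractually deterministic: flux vectors are
witnesses of possibly degenerate optima and are never compared across
runs.  Numerically failed solves raise with solver diagnostics rather
than reporting zero growth.

## Utilization spectra and requirements

Each candidate model is screened on the base minimal medium plus one
panel carbon at a time (the packaged panel holds 53 compounds: sugars,
organic acids, sugar alcohols and amino acids; the base medium — NH₄⁺,
phosphate, sulfate, Mg²⁺, Fe²⁺, water, protons — ships as a versioned
TSV because published studies rarely enumerate theirs).  Carbon
screening runs with all trace supplements present so auxotrophies cannot
mask carbon requirements; the two axes are probed independently, which
matches how the ground truth is planted.

MAGs failing every single carbon get a combination search in increasing
size (2…max_k, default 3) and panel order; the first hit is re-verified
minimal by testing all proper subsets, and an assertion fires if a
subset grows (that would indicate a search-order bug).  The cap of 3
reflects that reported multi-carbon requirements are "two or more" and
that exhaustive search beyond triples over a 53-carbon panel buys
nothing at desk scale.  Trace-supplement essentiality is leave-one-out
deletion from a growth-supporting medium; the generator plants only
independent auxotrophies, so single deletions are exact — synthetically
redundant routes (where only a pair of deletions kills growth) are
excluded by design and would require deeper deletion sets.

## Media design

Every distinct observed requirement pattern (minimal carbon set or
single usable carbon, plus required supplements) becomes one candidate
medium; its covered set is computed by subsumption (a composition covers
a single-carbon MAG when it intersects the MAG's usable carbons, a
multi-carbon MAG when it contains the whole combo, and in both cases
must include the required supplements).  The final panel is classic
greedy set cover — repeatedly take the candidate covering the most
uncovered MAGs, ties broken by fewer composition components then
lexicographic composition — giving the standard H(d)·OPT guarantee and
full determinism.  Selectivity (fraction of candidates a medium covers)
is reported, not optimized.  Every claimed (medium, MAG) pair is
re-certified by an independent FBA growth check, so a bug in the
subsumption shortcut cannot produce an uncertified design.  Note the
pattern-based enumeration rule favours specificity: auxotrophy patterns
split media that a human designer might merge, so the designed panel is
typically larger than a hand-crafted one; merging patterns under a
selectivity budget is future work.

## Synthetic cohorts: what they emulate, and what not

`SyntheticConfig` defaults define the study-shaped conditions: 281 MAGs
whose quality metrics fall inside the screened ranges (the emulated
cohort is post-filter, like a published one), marker prevalences
(FDH 0.30, AK 0.50, BK 0.33, independent) chosen so ≈76% of MAGs carry
at least one marker, a 53-carbon panel, 93% single-carbon growers among
all MAGs, ≈2% archaea, and 25% supplement auxotrophs (one supplement,
or two with probability 0.3).  Carbon-usability breadth per MAG is not
reported in the literature at this granularity; the default draws
1 + Binomial(7, 0.3) usable carbons per single-carbon grower, a
configurable choice not claimed to match any particular dataset.
Multi-carbon MAGs are planted with exactly one pair (a consequence of
the two-pool design); the search still probes triples.  Randomness uses
one root seed with a child stream per MAG, so cohort prefixes are stable
as `n_mags` grows.

What passing tests show: screening logic, LP solving, combinatorial
search and cover selection are correct against exact planted truth and
independent oracles (brute-force vertex enumeration for the LP,
exhaustive subset search for combos, brute-force optima for set cover,
an independently coded solver route for cross-checks).  What they do not
show: anything about real annotation quality — fragmented MAGs with
missed or spurious EC calls, pathway databases' coverage, or real
metabolic network structure (the template is a transparent stand-in, not
a reconstruction-tool replica).  On real data the screening and design
machinery applies unchanged, but recovery guarantees do not transfer.

## Numerical and determinism choices

* LP: HiGHS, primal/dual feasibility 10⁻⁹; growth threshold 10⁻⁶
  strict; audits at 10⁻⁶.
* All tie-breaks are deterministic: panel order for combination search,
  component count then lexicographic composition for cover ties.
* TSV outputs format floats explicitly (quality metrics at 4 decimals,
  model files via `repr`), making repeat runs byte-identical; the run
  manifest contains no timestamps for the same reason.
* Acceptance-scale runs use the full 281-MAG default cohort
  (~15,000 LPs, about a minute on one core); unit tests use a 5-carbon,
  2-supplement panel where exhaustive oracles stay trivially cheap.

## Known limitations

* Single-deletion essentiality misses redundant auxotrophies (not
  planted, documented above).
* The combination search is exact only up to `max_k`; a MAG needing four
  carbons would be classified `no_growth`.
* No gap-filling, flux variability, parsimonious or dynamic FBA, no
  hydrogen-yield objective (the screen targets growth, not H₂ flux),
  no inter-strain competition within a medium.
* SBML import maps species/reactions/bounds/objective and reports
  (rather than silently dropping) unsupported constructs; models using
  features outside that subset are rejected or flagged.
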