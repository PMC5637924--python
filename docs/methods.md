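# Methods

This note documents the models, algorithms and defaults behind `lgphylo`,
and what the synthetic-data experiments do and do not establish.

## Synthetic decaploid families

The generator produces, per homeologous chromosome group:

* **Progenitor sequences.** Sequences evolve on a user-supplied newick
  species tree under GTR (default equal rates and frequencies), branch
  lengths in expected substitutions per site. The default tree places the
  Av lineage with four diploid relatives, Bi with one diploid, the
  anchorless sisters B1 and B2 (tip-to-tip distance 0.032), a cryptic
  lineage U sister to the B group, and three distant taxa on the outgroup
  side. No divergence times are known for these subgenome lineages; the
  defaults are configuration, not biological estimates.
* **Parents.** Copy counts per lineage (even; 10 copies = 5 disomic pairs
  for a decaploid) define the scenario: contemporary origin H1 gives
  {Av:4, Bi:2, B1:2, B2:2}; the ancient-hybrid scenarios H2.A-C double Bi,
  B1 or B2 instead; H3 introduces two U copies. Both parents share each
  pair's founder haplotype (pair-private divergence 3e-3). Parent-private
  heterozygous sites become testcross markers (default 1.5e-3 per copy,
  i.e. ~15 markers per homolog copy on 20 kb — ordinary outcrosser
  heterozygosity) and shared heterozygous sites become biparental markers
  (4e-4). Marker sites are placed on a jittered grid (capture targets tile
  a region roughly evenly) at positions where all copies carry the
  reference base, so a single-dose site has alternate-allele dose exactly
  1/ploidy.
* **Meiosis.** Strict disomy: one recombinant copy per pair per parent per
  progeny. Crossovers are Poisson (no interference) by default; a
  gamma-renewal chiasma process (shape 2.63, thinned by 1/2) approximating
  the Kosambi map function is available for strict recovery tests. The
  genetic map is linear in bp; default length 90 cM per pair, inside the
  range observed for real per-LG map lengths.
* **Observations.** Per site and individual, total depth ~ Poisson (progeny
  40x; parents 80x — parents of a cross are routinely sequenced deeper, and
  the >= 40x parental filter then retains ~98% of sites); read error 0.5%,
  uniform over the three other bases; reads showing neither ref nor alt are
  dropped as a biallelic caller would. Read *segments* (800 bp windows,
  three passes, same error rate) tile every homolog copy; they carry no
  source label, so consensus building must assign them by the marker
  alleles they contain, as with real reads.
* **Trait.** A dominant male-sterility allele on one maternal copy;
  phenotype follows inheritance exactly (heterozygote ab = sterile,
  homozygote aa = fertile), segregating 1:1.

What this does *not* emulate: capture efficiency variation, indels and
structural variants, paralogy/mismapping, reference assembly errors, and
polysomic inheritance. Passing tests therefore demonstrate correctness of
the inference chain under its own assumptions, not robustness to those
artefacts.

## Genotype calling

A parent is single-dose heterozygous when its alternate fraction lies in
[0.5/ploidy, 2/ploidy] at depth >= 40 (both bands configurable), homozygous
below 2%. Progeny are ab at >= 2 alternate reads, aa at zero alternate
reads and depth >= 10, otherwise missing. At 40x and dose 1/10 the dominant
error is heterozygote dropout (no alternate read sampled, ~1.5-2%), which
inflates every two-point rf estimate; the mapping stage corrects it.

## Linkage mapping

Two-point rf is the folded mismatch fraction over jointly scored progeny;
LOD = R log10(rf) + (N-R) log10(1-rf) + N log10 2. Map construction:

1. **Grouping** — single linkage over pairs with LOD >= 5, requiring each
   edge to share a common above-threshold neighbour (an isolated spurious
   link is otherwise enough to fuse two groups).
2. **Error cleaning** — within each provisional group, phases are aligned
   along a provisional order and calls contradicted by two agreeing
   flanking markers are replaced (missing calls imputed the same way);
   apparent double recombinants at testcross marker spacing are
   overwhelmingly dropout errors. Two passes, then rf/LOD recomputed.
3. **Touchdown** — fragments reattach to groups when at least two
   independent marker pairs link them at LOD >= 4; stranded single markers
   insert at their best position if they reach LOD >= 4.
4. **Ordering** — greedy chain and principal-coordinate starts, scored by a
   lookahead objective (adjacent rf plus damped 2nd-4th neighbour terms;
   plain adjacent-rf minimisation overfits noise at n = 45), refined by
   window permutations, single-marker relocation and segment reversals.
   Groups containing internally strong blocks joined by weak evidence are
   ordered block-by-block; block order and orientation are chosen by an
   all-cross-pairs vote, falling back to reference coordinates when the
   family is crossover-poor and the cross-block rf carries no distance
   signal (the real protocol likewise curates against the reference
   assembly).
5. **Spacing and refinement** — Kosambi cM from adjacent rf; splits at
   gaps >= 35 cM; fragments under 5 SNPs dropped; oversplit fragments
   rejoin when their consensus sequences sit at the cross-parent consensus
   noise floor (estimated from each maternal LG's nearest paternal LG) —
   the sequence analogue of rejoining by placement in a preliminary
   phylogeny.
6. **Homolog pairing** — biparental (ab x ab) markers link a maternal and a
   paternal LG; the likelihood treats the other parent as transmitting its
   alternate allele with probability 1/2. Combinations are ranked by the
   count of markers reaching LOD >= 4 on both sides, then by summed LOD
   above a floor of 2; LGs still unpaired match by consensus similarity.

Measured at the design point (45 progeny, 15 markers per homolog copy, 40x,
0.5% error, 90 cM), the pipeline recovers 5 maternal + 5 paternal LGs in
16/16 replicate families with mean Kendall order concordance 0.959
(replicate sd ~0.011); with perfect genotypes the same ordering code reaches
0.993, so the residual gap is genotyping noise, not search failure.

## Phylogenetics

Consensus: a read segment is assigned to a linkage group when it shows the
alternate base at one of the group's marker positions; per-position majority
with ties and uncovered positions as N. The supermatrix keeps columns
covered in at least one LG taxon and in all diploids; parsimony-informative
sites require two states each in two taxa.

Likelihood: Felsenstein pruning over unique site patterns with per-pattern
rescaling; GTR via symmetrised eigendecomposition; gamma rate heterogeneity
with four equal-weight categories at median-of-quantile rates normalised to
mean 1; N/gaps fully ambiguous. Base frequencies are empirical; the gamma
shape and exchangeabilities are estimated by Nelder-Mead on the
neighbour-joining start tree (GT fixed at 1), then held during the search.

Search: NJ start (JC distances, pairwise deletion); NNI hill climbing where
all three arrangements around an edge are scored from cached directional
partials (their outside terms cancel, so score differences are exact
log-likelihood differences at fixed branch lengths, with the focal branch
re-optimised by bounded Brent); a full branch-length sweep follows each
accepted move, so the trace is monotone. Constrained searches start from a
constraint-compatible tree (the unconstrained ML tree when compatible,
otherwise average-linkage resolution within clades) and skip NNIs on edges
realising a required clade. An exhaustive-topology oracle covers up to 8
taxa. Bootstrap resamples pattern counts multinomially with a full search
per replicate; supports are bipartition frequencies and are rendered at
>= 50%.

## Hypothesis testing

A hypothesis assigns counts of focal LG taxa to the clades Av, Bi, B1, B2
(anchored by the available diploids; B1/B2 have no extant diploid and are
anonymous) plus an optional free clade; the B clades are jointly
constrained monophyletic. Homologous LG pairs are assignment units; LGs
without a partner are assigned singly. Exhaustive enumeration yields every
admissible assignment (five fully paired LGs under the contemporary-origin
counts give 5!/2! = 60); the default `minimal` mode ranks assignments by a
clustering cost on the unconstrained ML tree (pairwise path distances
within each proposed clade plus distances to the clade anchors) and keeps
the best six. Delta logL is computed against the best tree in the pooled
candidate set, so it is non-negative by construction.

SH test: RELL resampling of per-site log-likelihoods, replicate sums
centred per tree, one-sided comparison of max-centred differences to the
observed deficits. AU test: bootstrap proportions at ten scales 0.5-1.4
(configurable), z = Phi^-1(1-BP) fitted to d*sqrt(r) + c/sqrt(r) by
weighted least squares, p = 1 - Phi(d - c); BP clamped at 1/(2B), and
candidates clamped at every scale short-circuit to p = 0 or 1 with a flag.
Resampling draws sites uniformly (bincounted uniform indices). Candidates
are the pooled-best tree plus each hypothesis's best constrained tree;
candidates sharing a topology share one per-site vector, and the
tie-breaking tolerance is relative to the replicate sum's magnitude —
independently re-optimised copies of the same tree would otherwise create
hair-thin artificial dominance in the resampling.

Because B1 and B2 are anonymous, scenarios differing only by which B
lineage doubled (H2.B vs H2.C) are structurally indistinguishable: both fit
equally and the tests retain both, mirroring the ambiguity the real study
reports within its ancient-hybrid family.

## Trait mapping and introgression screen

Male function is coded sterile = ab, fertile = aa and tested against 1:1 by
chi-square with Yates' continuity correction (the correction is what the
published statistics use: 20:23 gives 0.093, 11:17 gives 0.893). The trait
joins the map as a pseudo-marker: two-point LOD picks the linkage group and
anchor marker (threshold 3); the within-group position comes from the
recombinant-count profile over insertion slots, and the support interval is
all slots within 4 recombinants of the minimum — about two standard
deviations of the between-slot count noise at n = 45, calibrated on
simulations to give roughly nominal 95% coverage (measured 19-20/20).
LOD-drop intervals were tried first and under-covered badly at this marker
density (1-LOD ~50%). The interval is open past the group's ends.

The introgression screen scores a focal LG consensus at discriminating
sites — columns where every named reference group is internally monomorphic
and the groups differ pairwise — reporting the share matching each group
plus an unassigned remainder (sums to 1). This is a re-specification of the
published post hoc test, whose exact internals are not public; output
carries that caveat.

## Problem sizes and determinism

Experiments run one 20 kb homeologous group with 18 taxa (10 LGs + 8
diploids), 45 progeny, RELL 2000 with five AU scales — sizes chosen so a
full origin-test replicate completes in tens of seconds while the
supermatrix retains thousands of informative sites. Every random draw
traces to an integer seed through `numpy.random.SeedSequence`; identical
seeds give identical outputs byte-for-byte.

## Known limitations

* Two-point ordering at n = 45 cannot resolve markers closer than ~1 cM;
  the Kendall concordance ceiling is set by meiosis, not the algorithm.
* The AU test is approximate for candidates that are exact duplicates;
  ties are randomised rather than collapsed, giving p near 0.5 for each
  duplicate, which is conservative for non-rejection decisions.
* Constraint enumeration caps the searched assignments (default 6) in
  `minimal` mode; `exhaustive` mode is the oracle but grows
  multinomially.
* The simulator's uniform bp-to-cM map and error model are idealisations;
  see the generator section for the real-data features not emulated.
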