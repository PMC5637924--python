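# lgphylo

Subgenome-origin inference for high-order polyploids from an F1 mapping
population: single-dose SNP genotyping, testcross linkage mapping,
linkage-group-as-taxon phylogenetics, and statistical tests of origin
hypotheses expressed as constraint topologies.

## The problem

A decaploid (2n = 10x) wild strawberry, *Fragaria cascadensis*, grows in
sympatry with an octoploid and a diploid, suggesting it arose by recent
8x-2x hybridisation. Competing explanations are an ancient hybrid origin
(the extra subgenome contributed by *F. iinumae* or an extinct
*iinumae*-like diploid) or a previously unrecognised cryptic subgenome.
Because each of the ten homologous chromosome copies per homeologous group
descends from one progenitor lineage, the question is answerable from the
phylogenetic placement of the polyploid's chromosomes.

The pipeline implements that inference chain:

1. **Genotyping** (`lgphylo.genotyping`) — in a decaploid, a single-dose SNP
   shows an alternate-allele read fraction near 1/10 in one parent; sites
   are classified maternal (ab x aa), paternal (aa x ab) or biparental
   (ab x ab) from parental depths (>= 40x), and progeny are scored aa/ab.
2. **Linkage mapping** (`lgphylo.linkmap`) — two-point rf/LOD with phase
   folding; single-linkage grouping at LOD 5 with touchdown to 4; seriation
   ordering; Kosambi distances d = 25 ln((1+2r)/(1-2r)) cM; splitting at
   gaps >= 35 cM; >= 5 SNPs per group; homologous maternal/paternal groups
   paired through biparental markers and consensus similarity.
3. **Phylogenetics** (`lgphylo.phylo`) — each linkage group becomes a taxon:
   reads carrying its diagnostic alleles are collapsed into a majority
   consensus, stacked with diploid reference taxa into a reference-projected
   supermatrix, and analysed by GTR+Gamma maximum likelihood (Felsenstein
   pruning, NNI search, nonparametric bootstrap), rooted with the outgroup.
4. **Hypothesis tests** (`lgphylo.hypotest`) — an origin hypothesis fixes
   how many focal LGs sit in each subgenome clade, e.g. contemporary origin
   H1 = (4,Av),((2,Bi),(2,B1),(2,B2)); ancient hybrid origin H2.C =
   (2,Av),((2,Bi),(2,B1),(4,B2)). Homologous LG pairs move between clades
   together; the best constrained ML tree per hypothesis is compared to the
   unconstrained ML tree with the Shimodaira-Hasegawa test (RELL) and the
   approximately unbiased test (multiscale bootstrap).
5. **Trait mapping** (`lgphylo.posthoc`) — dominant male sterility
   (sterile = ab, fertile = aa) is tested against 1:1 segregation
   (continuity-corrected chi-square) and placed on the map as a
   pseudo-marker with a recombinant-count support interval; a site-share
   diagnostic screens anomalously placed LGs for introgression.
6. **Synthetic data** (`lgphylo.simulate`) — a fully labelled generator
   (progenitor lineages on a species tree, disomic decaploid parents, F1
   cross, allele depths, read segments, sterility locus) stands in for raw
   capture reads, so every stage is testable against known truth.

## Worked example

The numbered drivers under `analysis/` run the full chain on one simulated
20 kb homeologous group (45 progeny, ~40x depth, 0.5% read error) generated
under the ancient-hybrid scenario H2.C:

```bash
cd analysis
python 01_simulate_decaploid.py
python 02_call_genotypes.py
python 03_build_linkage_maps.py
python 04_subgenome_phylogeny.py
python 05_test_origin_hypotheses.py
python 06_map_male_sterility.py
```

Outputs land in `results/`. The run prints, among other things:

```
305 informative markers from 328 sites
maternal LGs: 5 (true homolog pairs: 5)
paternal LGs: 5
pairings consistent with simulation truth: 5/5
supermatrix: 18 taxa x 20000 characters, 3824 parsimony-informative sites

hypothesis   delta_lnL     AU_p  SH_p SH_stars  not_rejected
        H1 1078.119359 0.000000   0.0       **         False
      H2.A  335.367832 0.000000   0.0       **         False
      H2.B    0.000000 0.455553   1.0                   True
      H2.C    0.000000 0.539836   1.0                   True
        H3  336.294092 0.000000   0.0       **         False

male sterile : fertile = 18 : 27; chi2 = 1.422; P = 0.233
trait placed on Fcas-I-m-4 at 50.1 cM (best marker I:14136, LOD 13.2)
```

Reading the table: delta_lnL is the log-likelihood cost of forcing each
hypothesis's constraint onto the data; the AU p-value (and SH stars,
* P < 0.05, ** P < 0.01) say whether that cost is statistically significant.
The generating scenario H2.C is retained, and so is H2.B — the B1 and B2
subgenomes have no extant diploid representative, so the two ancient-hybrid
scenarios that differ only by which anonymous B lineage doubled are
genuinely indistinguishable, exactly the ambiguity the real study reports
within its H2 family. The contemporary-origin and cryptic-subgenome
hypotheses are firmly rejected. The sterility locus maps back to its true
linkage group (the B1-subgenome pair) with the support interval covering
the simulated position.

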