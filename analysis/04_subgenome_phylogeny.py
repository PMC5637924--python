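"""Linkage groups as taxa: supermatrix, ML tree and bootstrap supports.

Builds each LG's consensus sequence from the read segments carrying its
diagnostic alleles, stacks them with the diploid reference taxa into a
reference-projected supermatrix, and infers the GTR+Gamma ML tree rooted
with the outgroup (bootstrap supports from column resampling).
"""

from common import CONFIG, SEED, outdir

from lgphylo.orchestrate import analyze_chromosome, simulate_chromosome
from lgphylo.phylo.search import bootstrap_support, search_ml_tree
from lgphylo.simulate import DEFAULT_OUTGROUP

out = outdir()
data = simulate_chromosome(CONFIG, 0, SEED, with_trait=True)
analysis = analyze_chromosome(data, CONFIG)
aln = analysis.aln
aln.to_fasta(out / "supermatrix.fasta")
print(f"supermatrix: {aln.n_taxa} taxa x {aln.n_columns} characters, "
      f"{aln.pis_count()} parsimony-informative sites")

result = search_ml_tree(aln, seed=SEED)
result = bootstrap_support(aln, n_reps=CONFIG.bootstrap_reps, seed=SEED,
                           result=result)
rooted = result.tree.root_with_outgroup(DEFAULT_OUTGROUP)
with open(out / "ml_tree.nwk", "w") as fh:
    fh.write(rooted.to_newick(supports=True, min_support=50.0))

print(f"ML log-likelihood: {result.loglik:.1f}")
print("rooted ML tree (supports >= 50% shown):")
print(rooted.to_newick(lengths=False, supports=True, min_support=50.0))
print("truth: LG -> homolog pair:", analysis.lg_truth_pairs)
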