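"""Constraint-topology tests of the five origin hypotheses.

Each hypothesis fixes how many decaploid LG taxa belong to each subgenome
clade (contemporary sympatric origin H1; ancient hybrid origin H2.A-C by
which lineage contributed the doubled subgenome; cryptic-subgenome H3).
For every hypothesis the best constrained ML tree is compared with the
unconstrained ML tree by the SH and AU tests.  The data were generated under
H2.C, so H2.C should be retained and H1 rejected.
"""

from common import CONFIG, SEED, outdir

from lgphylo.hypotest import run_hypothesis_suite
from lgphylo.orchestrate import analyze_chromosome, simulate_chromosome

out = outdir()
data = simulate_chromosome(CONFIG, 0, SEED, with_trait=True)
analysis = analyze_chromosome(data, CONFIG)

table, details = run_hypothesis_suite(
    analysis.aln, analysis.lg_units, seed=SEED,
    n_rell_sh=CONFIG.n_rell_sh, n_rell_au=CONFIG.n_rell_au,
    au_scales=CONFIG.au_scales,
)
table.to_csv(out / "hypothesis_tests.tsv", sep="\t", index=False)

print(f"generating scenario: {CONFIG.scenario}")
print(table[["hypothesis", "delta_lnL", "AU_p", "SH_p", "SH_stars",
             "not_rejected"]].to_string(index=False))
retained = sorted(table[table.not_rejected].hypothesis)
print("hypotheses not rejected:", retained or "none")
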