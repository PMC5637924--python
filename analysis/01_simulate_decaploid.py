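"""Simulate one homeologous group of a decaploid F1 mapping family.

Generates progenitor sequences on the default species tree, assembles the
two decaploid parents under the ancient-hybrid-origin scenario (four B2
copies), runs the 45-progeny cross with a dominant sterility locus, and
emits the allele-depth table plus read segments.  Writes the observable
inputs of the downstream analyses (and the truth tables, for reference)
under results/.
"""

import json

from common import CONFIG, SEED, outdir

from lgphylo import simulate
from lgphylo.orchestrate import simulate_chromosome

out = outdir()
data = simulate_chromosome(CONFIG, 0, SEED, with_trait=True)

data.depth.to_csv(out / "site_depth.tsv", sep="\t", index=False)
simulate.sequences_to_fasta(
    {k: v for k, v in data.progenitors.items()}, out / "progenitors.fasta")
data.truth.markers.to_csv(out / "truth_markers.tsv", sep="\t", index=False)
with open(out / "truth_summary.json", "w") as fh:
    json.dump(
        {
            "scenario": CONFIG.scenario,
            "pair_lineages": data.truth.pair_lineages,
            "n_progeny": len(data.population.progeny),
            "trait_locus": {
                "pair": data.truth.trait.pair_id,
                "pos_bp": data.truth.trait.pos,
            },
            "phenotypes": {
                "sterile": sum(p.phenotype == "sterile" for p in data.population.progeny),
                "fertile": sum(p.phenotype == "fertile" for p in data.population.progeny),
            },
        },
        fh, indent=2,
    )

mk = data.truth.markers
print(f"simulated {data.truth.seq_length} bp homeologous group {data.chrom} "
      f"under scenario {CONFIG.scenario}")
print("homolog pairs:", data.truth.pair_lineages)
print("marker classes:", mk.seg_class.value_counts().to_dict())
print("depth table:", out / "site_depth.tsv")
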