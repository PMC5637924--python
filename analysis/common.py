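"""Shared configuration for the analysis drivers.

One homeologous group at the study's design point (decaploid, 45 progeny,
~40x depth, 0.5% read error) under the ancient-hybrid-origin scenario with
four B2-subgenome copies.  Every driver reads/writes under results/.
"""

from pathlib import Path

from lgphylo.orchestrate import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11

CONFIG = RunConfig(
    seed=SEED,
    n_chromosomes=1,
    scenario="H2.C",
    n_rell_sh=2000,
    n_rell_au=2000,
    au_scales=(0.6, 0.8, 1.0, 1.2, 1.4),
    bootstrap_reps=20,
)


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
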