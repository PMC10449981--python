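"""Shared study setup for the analysis drivers.

All drivers analyse one deterministic synthetic two-trait study: a
"brain" trait and a "glycemic" trait simulated over a 100-region panel
(M = 20,000 SNPs) with heritabilities 0.4, genetic correlation 0.5 and
50,000 samples each, plus a gene map of two genes per region.  Regenerating
the study from its fixed seed keeps every driver independent of execution
order while guaranteeing they all see identical data.
"""

from pathlib import Path

from xtrait import ldsc, simulate
from xtrait.sumstats import harmonize_pair

STUDY_SEED = 20_240_101
RESULTS = Path(__file__).resolve().parent.parent / "results"

H2_BRAIN = 0.4
H2_GLYC = 0.4
RG_TRUE = 0.5
N_BRAIN = 50_000
N_GLYC = 50_000


def load_study():
    panel = simulate.make_panel(n_blocks=100, block_size=200, seed=1)
    brain, glyc, truth = simulate.simulate_pair(
        panel, H2_BRAIN, H2_GLYC, RG_TRUE, n1=N_BRAIN, n2=N_GLYC,
        seed=STUDY_SEED)
    brain.trait_name, glyc.trait_name = "brain_trait", "glycemic_trait"
    brain, glyc = harmonize_pair(brain, glyc)
    gene_map = simulate.make_gene_map(panel, genes_per_block=2,
                                      gene_length=50_000)
    ld = ldsc.compute_ld_scores(panel)
    return panel, brain, glyc, truth, gene_map, ld


def table_dir():
    d = RESULTS / "tables"
    d.mkdir(parents=True, exist_ok=True)
    return d
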