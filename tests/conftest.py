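import logging

import pytest

from scclone.genome import build_genome, default_genome
from scclone.pipeline import PipelineConfig, analyse_tumour
from scclone.simulate import (
    SimulationParams,
    simulate_cells,
    three_clone_archetype,
    validate_clone_truth,
)

logging.getLogger("scclone").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def grid():
    return default_genome()


@pytest.fixture(scope="session")
def one_chrom_grid():
    """Single 10 Mb chromosome (200 bins at 50 kb), centromere at 4 Mb."""
    return build_genome({"chr1": 10_000_000}, {"chr1": 4_000_000})


@pytest.fixture(scope="session")
def three_clone_battery(grid):
    """The 20-seed three-clone recovery study (50/30/20% clones, 40 cells
    per region x 2 regions, default noise), analysed end-to-end once and
    shared by every statistical assertion over it."""
    from sklearn.metrics import adjusted_rand_score

    truth = validate_clone_truth(three_clone_archetype(purity=0.9), grid)
    root_chroms = {e.chrom for c in truth if c.parent is None for e in c.own_events}
    priv_chroms = {e.chrom for c in truth if c.parent is not None for e in c.own_events}
    outcomes = []
    for seed in range(20):
        counts, meta, _, gt = simulate_cells(
            grid, truth, SimulationParams(seed=seed), tumour_id="T1"
        )
        rep = analyse_tumour(counts, meta, grid, config=PipelineConfig(seed=seed))
        truth_lab = [gt.cell_clone[c] for c in rep.cell_clusters]
        ari = adjusted_rand_score(truth_lab, list(rep.cell_clusters.values()))
        informative = [
            a for a in rep.events if a.event.chrom in root_chroms | priv_chroms
        ]
        clonality_ok = bool(informative) and all(
            (a.clonality == "clonal") == (a.event.chrom in root_chroms)
            for a in informative
        )
        outcomes.append(
            {
                "seed": seed,
                "n_tumour_clones": rep.n_tumour_clones,
                "ari": ari,
                "purity_err": abs(rep.purity - gt.purity["all"]),
                "clonality_ok": clonality_ok,
                "category": rep.category,
                "mode": rep.evolution.mode,
            }
        )
    return outcomes


@pytest.fixture(scope="session")
def three_clone_run(grid):
    """One simulated + fully analysed three-clone tumour, shared read-only."""
    truth = validate_clone_truth(three_clone_archetype(purity=0.9), grid)
    counts, meta, geno, gt = simulate_cells(
        grid, truth, SimulationParams(seed=11), tumour_id="T1"
    )
    report = analyse_tumour(
        counts, meta, grid, genotypes=geno, config=PipelineConfig(seed=11)
    )
    return {"counts": counts, "meta": meta, "geno": geno, "gt": gt,
            "report": report, "truth": truth}
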