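#!/usr/bin/env python
"""Stage 1 — simulate the study cohort and write its data files.

Builds the synthetic study design: a 384-amplicon panel (300-600 bp,
20 bp primers), 333 SNP sites genotyped across two trios of six HapMap-
style samples, individual libraries at 500x mean depth with 0.5%
substitution error. Writes the panel (BED), the truth genotype table,
the pedigree, and per-sample pileups under results/data/.

Later stages re-derive read placements from the same fixed seed instead
of storing them (they are large and fully reproducible).
"""

from pathlib import Path

from tseq_eval.io_formats import write_genotype_table, write_pedigree, write_pileup, write_target_panel
from tseq_eval.pool_analysis import PoolSpec
from tseq_eval.synthetic_data import SimConfig, make_panel, make_truth, simulate_pool_pileup, simulate_sample_pileup

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 0

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, mean_depth=500.0)
    panel = make_panel(cfg)
    truth = make_truth(panel, cfg)
    write_target_panel(panel, OUT / "panel.bed")
    write_genotype_table(truth.reference_genotypes(), OUT / "genotypes.tsv")
    write_pedigree(truth.trios, OUT / "trios.ped")
    for sample in truth.samples:
        pileup, _ = simulate_sample_pileup(truth, panel, cfg, sample)
        write_pileup(pileup, OUT / f"{sample}.pileup.tsv")
    pool_cfg = SimConfig(seed=SEED, mean_depth=2400.0, per_base_error=0.01)
    spec = PoolSpec(tuple(truth.samples))
    for rep in range(2):
        pileup = simulate_pool_pileup(truth, spec, panel, pool_cfg, replicate=rep)
        write_pileup(pileup, OUT / f"pool_rep{rep + 1}.pileup.tsv")
    print(f"panel: {len(panel)} amplicons, {panel.total_analyzable_bases} analyzable bases")
    print(f"truth: {len(truth.sites)} SNP sites x {len(truth.samples)} samples, "
          f"{len(truth.trios)} trios")
    print(f"wrote data files to {OUT}")

if __name__ == "__main__":
    main()
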