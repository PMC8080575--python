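#!/usr/bin/env python
"""Generate the synthetic study data every later step consumes.

Simulates (1) an ascites cell mixture — four patient-specific tumor clones
with planted copy-number segments, macrophages carrying the CCL3/CCR1,
IL1B->IL1R2 and IL10/IL10RA programs, and a small mesothelial population —
and (2) the two-donor M1/M2 reference macrophage experiment. Matrices go to
scratch/data/ (regenerated on demand by later steps if absent); a small
summary lands in results/.
"""

import json
import sys
from pathlib import Path

from asceco import io_qc, synthetic

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    data = ROOT / "scratch" / "data"
    data.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    sim = synthetic.simulate_ascites(synthetic.AscitesConfig(seed=SEED))
    io_qc.write_expression_mtx(sim.counts, data, name="ascites_counts")
    sim.cell_meta.to_csv(data / "ascites_cells_meta.tsv", sep="\t")
    sim.annotation.to_csv(data / "gene_annotation.tsv", sep="\t")
    db = synthetic.default_pair_database(sim)
    db.pairs.to_csv(data / "lr_pairs.tsv", sep="\t", index=False)

    ref = synthetic.simulate_reference_macrophages(synthetic.ReferenceConfig(seed=SEED))
    io_qc.write_expression_mtx(ref.counts, data, name="reference_counts")
    ref.cell_meta.to_csv(data / "reference_cells_meta.tsv", sep="\t")
    (data / "reference_truth.json").write_text(json.dumps(ref.truth, indent=2))

    summary = {
        "seed": SEED,
        "ascites": {
            "n_genes": int(sim.counts.shape[0]),
            "n_cells": int(sim.counts.shape[1]),
            "cells_per_group": sim.cell_meta["group"].value_counts().to_dict(),
            "n_cnv_segments": len(sim.truth["segments"]),
            "n_lr_pairs": len(db),
        },
        "reference": {
            "n_genes": int(ref.counts.shape[0]),
            "cells_per_donor_and_type": ref.cell_meta.value_counts().to_dict().__str__(),
            "planted_m1_up": len(ref.truth["m1_up"]),
            "planted_m2_up": len(ref.truth["m2_up"]),
        },
    }
    (results / "simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"ascites: {sim.counts.shape[0]} genes x {sim.counts.shape[1]} cells "
          f"({sim.cell_meta['group'].nunique()} groups, {len(sim.truth['segments'])} CNV segments)")
    print(f"reference: {ref.counts.shape[1]} cells over 2 donors, "
          f"{len(ref.truth['m1_up'])}/{len(ref.truth['m2_up'])} planted M1/M2-up genes")
    print(f"wrote matrices to {data} and summary to {results/'simulation_summary.json'}")


if __name__ == "__main__":
    main()
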