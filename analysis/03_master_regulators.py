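#!/usr/bin/env python
"""Nominate master-regulator TFs from regulon/DEG overlap.

Fisher's exact test plus a 10,000-draw whole-genome permutation null
for every regulon; TFs passing both at P < 0.05 are the key master
regulators.  The top two selected TFs are then compared by a Venn
partition of their DEG-overlapping targets — the shared-versus-unique
target breakdown used to contrast co-selected regulators.
"""

import json
from pathlib import Path

from resistomics import io, mra
from resistomics._rng import substream
from resistomics.config import AnalysisConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main(seed: int = 0) -> None:
    bundle = OUT / "bundle"
    if not bundle.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    regulons = io.read_gmt(bundle / "regulons.gmt")
    deg_table = io.read_table(bundle / "deg_table.tsv", io.DEG_SCHEMA)
    config = AnalysisConfig(seed=seed)  # 10,000 permutations
    result = mra.run_mra(regulons, deg_table, config,
                         rng=substream(seed, "regulon_mra"))
    io.write_table(result, OUT / "mra_results.tsv")

    selected = result.loc[result["selected"]]
    truth = json.loads((bundle / "truth.json").read_text())
    print(f"{len(selected)} of {len(result)} TFs selected by the dual "
          f"criterion (Fisher P < {config.alpha_fisher} and permutation "
          f"P < {config.alpha_perm})")
    print("selected:", ", ".join(selected["tf"]))
    print("planted: ", ", ".join(truth["planted_tfs"]))

    if len(selected) >= 2:
        tf_a, tf_b = selected["tf"].iloc[0], selected["tf"].iloc[1]
        deg_set = mra.deg_set_from_table(
            deg_table, config.deg_padj_cutoff, config.deg_lfc_cutoff)
        ua, shared, ub = mra.venn_partition(
            regulons[tf_a], regulons[tf_b], deg_set)
        print(f"of {ua + shared + ub} DEGs hit by {tf_a} or {tf_b}: "
              f"{ua} unique to {tf_a}, {shared} shared, {ub} unique to {tf_b}")


if __name__ == "__main__":
    main()
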