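"""Generate the synthetic study inputs and summarise what was planted.

Writes the parcel table, ground-truth fields and gene sets under
results/fixtures/, and prints the planted conditions (cohort composition,
effect sizes, gene-set structure).
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import numpy as np

from gliotopo import fixtures


def main() -> None:
    args = common.parse_args(__doc__)
    config, parc, truth = common.study(args.seed)
    cfg = config.synthetic
    out = args.out / "fixtures"
    out.mkdir(parents=True, exist_ok=True)

    cohort = fixtures.make_lesion_cohort(cfg, parc, truth["frequency"])
    atlas, sets, planted = fixtures.make_expression_atlas(cfg, parc, truth["frequency"])

    parc.table.to_csv(out / "parcels.tsv", sep="\t", index_label="parcel_id")
    for name, vec in truth.items():
        vec.save(out / f"truth_{name}.tsv")
    for name, gs in sets.items():
        gs.save(out / f"{name}.txt")

    n_lgg = sum(g == "LGG" for _, g in cohort)
    print(f"parcellation: {parc.n_parcels} parcels "
          f"({len(parc.ids('left'))} left, "
          f"{int((~parc.table['is_cortical']).sum()) // 2} subcortical per hemisphere)")
    print(f"cohort: {len(cohort)} patients, {n_lgg} LGG "
          f"({100 * n_lgg / len(cohort):.1f}%)")
    print(f"expression atlas: {atlas.expression.shape[0]} samples x "
          f"{atlas.expression.shape[1]} genes; "
          f"marker set {len(sets['opc_markers'])}, driver set "
          f"{len(sets['glioma_drivers'])} (of which "
          f"{len(planted['driver_decoys'])} planted decoys)")
    print(f"planted effect sizes: {cfg.effect_sizes}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
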