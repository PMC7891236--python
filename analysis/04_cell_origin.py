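"""Test glioma localisation to stem/progenitor-cell territories.

Two analyses: mean tumour frequency in the NSC niche parcels (hippocampus +
caudate stand-ins) against random parcel pairs, and the OPC marker score
map (co-expression-validated, filtered, median-enriched per cortical
parcel) spin-tested against tumour frequency.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import json

from gliotopo import cellorigin, fixtures, lesionmap, spatialnull
from gliotopo.workbench import (
    _stream_seed, _STREAM_SPINS, _STREAM_NSC, _STREAM_COEXPR,
)


def main() -> None:
    args = common.parse_args(__doc__)
    config, parc, truth = common.study(args.seed)
    out = args.out / "cellorigin"
    out.mkdir(parents=True, exist_ok=True)

    cohort = fixtures.make_lesion_cohort(config.synthetic, parc, truth["frequency"])
    _, _, freq = lesionmap.frequency_pipeline([m for m, _ in cohort], parc)
    atlas, sets, _ = fixtures.make_expression_atlas(
        config.synthetic, parc, truth["frequency"])

    nsc_mean, nsc_p = cellorigin.nsc_niche_test(
        freq, parc=parc, n_null=config.n_null_pairs,
        seed=_stream_seed(args.seed, _STREAM_NSC))

    opc = cellorigin.marker_score_map(
        sets["opc_markers"], atlas, parc,
        n_null=config.n_null_coexpression,
        seed=_stream_seed(args.seed, _STREAM_COEXPR))
    opc.score_map.save(out / "opc_score_map.tsv")
    ens = spatialnull.build_spin_ensemble(
        parc, n_spins=config.n_spins,
        seed=_stream_seed(args.seed, _STREAM_SPINS), scope="left",
        include_subcortex=False)
    opc_spin = spatialnull.spin_correlation_test(opc.score_map, freq, ens)
    (out / "cellorigin.json").write_text(json.dumps({
        "nsc": {"mean_frequency": nsc_mean, "p": nsc_p},
        "opc": {"coexpression_p": opc.coexpression_p,
                "removed_genes": opc.removed_genes,
                **opc_spin.to_dict()}}, indent=2))

    print(f"NSC niche: mean frequency {nsc_mean:.2f}% vs random pairs, "
          f"P = {nsc_p:.4f}")
    print(f"OPC markers: co-expression P = {opc.coexpression_p:.4f}; "
          f"filter removed {opc.removed_genes or 'no genes'}")
    print(f"OPC map vs frequency: rho = {opc_spin.rho_observed:+.3f}, "
          f"P_spin = {opc_spin.p_spin:.4f}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
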