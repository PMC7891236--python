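"""Relate spatial gene expression to glioma frequency with PLS regression.

Aligns expression samples to the (smoothed, mirrored) frequency map with a
square-root response, fits two PLS components, tests model significance by
permutation, ranks genes by bootstrap Z, tests proto-oncogene median-rank
enrichment, and maps per-sample loadings onto parcels.
"""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import json

from gliotopo import cellorigin, fixtures, lesionmap, plstx
from gliotopo.workbench import (
    _stream_seed, _STREAM_PERM, _STREAM_BOOT, _STREAM_RANK,
)


def main() -> None:
    args = common.parse_args(__doc__)
    config, parc, truth = common.study(args.seed)
    out = args.out / "plstx"
    out.mkdir(parents=True, exist_ok=True)

    cohort = fixtures.make_lesion_cohort(config.synthetic, parc, truth["frequency"])
    raw, _, _ = lesionmap.frequency_pipeline([m for m, _ in cohort], parc)
    atlas, sets, _ = fixtures.make_expression_atlas(
        config.synthetic, parc, truth["frequency"])

    aligned = plstx.align_samples_to_frequency(atlas, raw, parc,
                                               fwhm_mm=config.fwhm_mm)
    fit = plstx.fit_pls(aligned, n_components=2)
    perm_p = plstx.permute_pls_significance(
        aligned, fit, n_perm=config.n_perm,
        seed=_stream_seed(args.seed, _STREAM_PERM))
    ranking = plstx.bootstrap_gene_z(
        aligned, n_boot=config.n_boot,
        seed=_stream_seed(args.seed, _STREAM_BOOT))
    ranking.table().to_csv(out / "gene_ranking.tsv", sep="\t")

    drivers = cellorigin.filter_gene_set(sets["glioma_drivers"], atlas)
    rank_seed = _stream_seed(args.seed, _STREAM_RANK)
    med1, p1 = plstx.rank_enrichment_test(ranking, drivers, component=1,
                                          n_null=config.n_null_rank, seed=rank_seed)
    med2, p2 = plstx.rank_enrichment_test(ranking, drivers, component=2,
                                          n_null=config.n_null_rank, seed=rank_seed)
    maps, summary = plstx.map_loadings_to_parcels(fit, aligned, parc)
    for name, vec in maps.items():
        vec.save(out / f"{name}_loadings.tsv")
    summary.to_csv(out / "sample_parcel_summary.tsv", sep="\t")
    (out / "pls_fit.json").write_text(json.dumps({
        "variance_explained_y": list(map(float, fit.variance_explained_y)),
        "perm_p": perm_p,
        "driver_median_rank": {"pls1": med1, "pls2": med2},
        "driver_enrichment_p": {"pls1": p1, "pls2": p2}}, indent=2))

    v = fit.variance_explained_y
    print(f"PLS1/PLS2 explain {100 * v[0]:.1f}% / {100 * v[1]:.1f}% of "
          f"frequency variance (scree of later components: "
          f"{', '.join(f'{100 * x:.1f}%' for x in v[2:])})")
    print(f"model significance (label permutation): P = {perm_p:.4f}")
    print(f"driver set after co-expression filter: {len(drivers)} genes; "
          f"median rank PLS1 {med1:.0f} (P = {p1:.4f}), "
          f"PLS2 {med2:.0f} (P = {p2:.4f})")
    print(summary)
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
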