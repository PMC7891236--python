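"""End-to-end orchestration: config, staging, logging and run manifests.

``run_pipeline`` executes fixtures -> lesion mapping -> spatial nulls ->
hub graph -> cellular -> transcriptomic -> integrative regression on one
seeded configuration, writes every artefact under the output directory and
records a manifest (config snapshot, seeds, output checksums, headline
numbers) sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellorigin, fixtures, hubgraph, lesionmap, multifactor, plstx, spatialnull
from .containers import ParcelVector

logger = logging.getLogger(__name__)

# analysis rng streams, disjoint from the fixture streams
_STREAM_SPINS = 11
_STREAM_SPLIT = 12
_STREAM_NSC = 13
_STREAM_COEXPR = 14
_STREAM_PERM = 15
_STREAM_BOOT = 16
_STREAM_RANK = 17
_STREAM_MORAN = 18


def _stream_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """One config block per stage, pre-filled with the study defaults:
    2 mm FWHM smoothing, 4 mm white-matter extension, rho > 0.95 metric
    screening, 1000 permutations/bootstraps, 10 000 spins and null pairs.
    """

    synthetic: fixtures.SyntheticConfig = field(default_factory=fixtures.SyntheticConfig)
    fwhm_mm: float = 2.0
    wm_extension_mm: float = 4.0
    mirror_to: str = "left"
    n_split_repeats: int = 100
    lgg_ratio_multiplier: float = 1.5
    n_spins: int = 10000
    screen_rho: float = 0.95
    n_null_pairs: int = 10000
    n_null_coexpression: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    n_null_rank: int = 10000
    sidedness: str = "one"
    include_transcriptomics: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = fixtures.SyntheticConfig(**{
            **raw.pop("synthetic", {}),
        })
        if "grid_shape" in asdict(syn):
            syn.grid_shape = tuple(syn.grid_shape)
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict  # relative path -> sha256
    results: dict
    stages: list
    package_version: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Writer:
    def __init__(self, outdir: Path):
        self.outdir = Path(outdir)
        self.outputs: dict[str, str] = {}

    def record(self, path: Path) -> None:
        rel = str(path.relative_to(self.outdir))
        self.outputs[rel] = _sha256(path)

    def path(self, *parts: str) -> Path:
        p = self.outdir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def json(self, obj: dict, *parts: str) -> None:
        p = self.path(*parts)
        p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
        self.record(p)

    def tsv(self, df: pd.DataFrame, *parts: str, **kw) -> None:
        p = self.path(*parts)
        df.to_csv(p, sep="\t", float_format="%.12g", **kw)
        self.record(p)

    def vector(self, vec: ParcelVector, *parts: str) -> None:
        p = self.path(*parts)
        vec.save(p)
        self.record(p)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 write_volumes: bool = True) -> RunManifest:
    """Run every stage on one seeded synthetic configuration.

    Stage errors abort the run with the stage name attached.  When
    ``include_transcriptomics`` is false the transcriptomic and integrative
    stages are skipped and marked as such in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wr = _Writer(outdir)
    cfg = config.synthetic
    seed = int(cfg.seed)
    stages: list[dict] = []
    results: dict = {}
    stage_t0 = time.time()

    def _done(name: str, status: str = "completed") -> None:
        # timings are logged but never recorded: manifests must be bit-identical
        nonlocal stage_t0
        stages.append({"stage": name, "status": status})
        logger.info("stage %s: %s (%.1fs)", name, status, time.time() - stage_t0)
        stage_t0 = time.time()

    try:
        name = "fixtures"
        parc = fixtures.make_parcellation(cfg)
        truth = fixtures.make_ground_truth_fields(cfg, parc)
        cohort = fixtures.make_lesion_cohort(cfg, parc, truth["frequency"])
        loadings = fixtures.make_connectome_source(cfg, parc, truth["hub"])
        atlas, gene_sets, _planted = fixtures.make_expression_atlas(
            cfg, parc, truth["frequency"])
        if write_volumes:
            parc.save(wr.path("fixtures", "parcellation.nii"),
                      wr.path("fixtures", "parcels.tsv"))
            wr.record(wr.path("fixtures", "parcellation.nii"))
            wr.record(wr.path("fixtures", "parcels.tsv"))
        for nm, vec in truth.items():
            wr.vector(vec, "fixtures", f"truth_{nm}.tsv")
        wr.tsv(loadings, "fixtures", "connectome_loadings.tsv")
        atlas.save(wr.path("fixtures", "expression.tsv"),
                   wr.path("fixtures", "sample_coords.tsv"))
        wr.record(wr.path("fixtures", "expression.tsv"))
        wr.record(wr.path("fixtures", "sample_coords.tsv"))
        for nm, gs in gene_sets.items():
            wr.record(gs.save(wr.path("fixtures", f"{nm}.txt")))
        wr.json({"grades": [g for _, g in cohort]}, "fixtures", "cohort_grades.json")
        _done(name)

        name = "lesionmap"
        ext_labels = lesionmap.extend_labels(parc, config.wm_extension_mm)
        raw, processed, freq_vec = lesionmap.frequency_pipeline(
            [m for m, _ in cohort], parc,
            fwhm_mm=config.fwhm_mm, mirror_to=config.mirror_to,
            wm_extension_mm=config.wm_extension_mm, extended_labels=ext_labels,
        )
        if write_volumes:
            wr.record(raw.save(wr.path("lesionmap", "frequency_raw.nii")))
            wr.record(processed.save(wr.path("lesionmap", "frequency_processed.nii")))
        wr.vector(freq_vec, "lesionmap", "frequency_parcels.tsv")
        net_table, _net_dists = lesionmap.network_summaries(processed, parc)
        wr.tsv(net_table, "lesionmap", "network_summary.tsv")
        split = lesionmap.split_half_replicability(
            cohort, parc, n_repeats=config.n_split_repeats,
            lgg_ratio_multiplier=config.lgg_ratio_multiplier,
            fwhm_mm=config.fwhm_mm, wm_extension_mm=config.wm_extension_mm,
            seed=_stream_seed(seed, _STREAM_SPLIT),
        )
        wr.json({"r": split.r_point, "ci": list(split.ci),
                 "lgg_fractions": list(split.lgg_fractions),
                 "n_repeats": config.n_split_repeats}, "lesionmap", "split_half.json")
        results["split_half_r"] = split.r_point
        results["split_half_ci"] = list(split.ci)
        results["network_means"] = net_table["mean_frequency"].to_dict()
        _done(name)

        name = "spatialnull"
        spin_seed = _stream_seed(seed, _STREAM_SPINS)
        ens_left = spatialnull.build_spin_ensemble(
            parc, n_spins=config.n_spins, seed=spin_seed, scope="left")
        ens_cort = spatialnull.build_spin_ensemble(
            parc, n_spins=config.n_spins, seed=spin_seed, scope="left",
            include_subcortex=False)
        moran_i, moran_p = spatialnull.morans_i(
            freq_vec, parc, seed=_stream_seed(seed, _STREAM_MORAN))
        wr.json({"morans_i": moran_i, "p": moran_p}, "spatialnull", "morans_i.json")
        results["frequency_morans_i"] = moran_i
        results["frequency_morans_p"] = moran_p
        _done(name)

        name = "hubgraph"
        conn = hubgraph.build_parcel_connectome(loadings, parc)
        hubs = hubgraph.hub_metrics(conn)
        hubs_left = hubgraph.homotopic_average(hubs, parc)
        hubs_kept = hubgraph.screen_redundant_metrics(hubs_left, threshold=config.screen_rho)
        assoc = hubgraph.hub_frequency_association(
            hubs_kept, freq_vec, ens_left, sidedness=config.sidedness)
        wr.tsv(conn.weights_frame() if hasattr(conn, "weights_frame")
               else pd.DataFrame(conn.weights, index=conn.parcel_ids,
                                 columns=conn.parcel_ids),
               "hubgraph", "connectome.tsv", index_label="parcel_id")
        wr.tsv(hubs_kept.values, "hubgraph", "hub_metrics.tsv")
        wr.json({m: r.to_dict() for m, r in assoc.items()},
                "hubgraph", "hub_frequency_spin.json")
        wr.json({"screened_out": hubs_kept.screened_out}, "hubgraph", "screening.json")
        results["hub_association"] = {m: r.to_dict() for m, r in assoc.items()}
        results["screened_out"] = hubs_kept.screened_out
        _done(name)

        name = "cellorigin"
        nsc_mean, nsc_p = cellorigin.nsc_niche_test(
            freq_vec, parc=parc, n_null=config.n_null_pairs,
            seed=_stream_seed(seed, _STREAM_NSC))
        opc = cellorigin.marker_score_map(
            gene_sets["opc_markers"], atlas, parc,
            n_null=config.n_null_coexpression,
            seed=_stream_seed(seed, _STREAM_COEXPR))
        opc_spin = spatialnull.spin_correlation_test(
            opc.score_map, freq_vec, ens_cort, sidedness=config.sidedness)
        wr.vector(opc.score_map, "cellorigin", "opc_score_map.tsv")
        wr.json({"nsc_mean_frequency": nsc_mean, "nsc_p": nsc_p,
                 "opc_coexpression_p": opc.coexpression_p,
                 "opc_removed_genes": opc.removed_genes,
                 "opc_spin": opc_spin.to_dict()}, "cellorigin", "cellorigin.json")
        results["nsc_niche"] = {"mean_frequency": nsc_mean, "p": nsc_p}
        results["opc"] = {"coexpression_p": opc.coexpression_p,
                          "rho": opc_spin.rho_observed, "p_spin": opc_spin.p_spin}
        _done(name)

        if not config.include_transcriptomics:
            stages.append({"stage": "plstx", "status": "skipped"})
            stages.append({"stage": "multifactor", "status": "skipped"})
        else:
            name = "plstx"
            aligned = plstx.align_samples_to_frequency(
                atlas, raw, parc, fwhm_mm=config.fwhm_mm)
            fit = plstx.fit_pls(aligned, n_components=2)
            perm_p = plstx.permute_pls_significance(
                aligned, fit, n_perm=config.n_perm,
                seed=_stream_seed(seed, _STREAM_PERM))
            ranking = plstx.bootstrap_gene_z(
                aligned, n_boot=config.n_boot,
                seed=_stream_seed(seed, _STREAM_BOOT))
            drivers = cellorigin.filter_gene_set(gene_sets["glioma_drivers"], atlas)
            rank_seed = _stream_seed(seed, _STREAM_RANK)
            med1, enr_p1 = plstx.rank_enrichment_test(
                ranking, drivers, component=1, n_null=config.n_null_rank, seed=rank_seed)
            med2, enr_p2 = plstx.rank_enrichment_test(
                ranking, drivers, component=2, n_null=config.n_null_rank, seed=rank_seed)
            load_maps, sample_summary = plstx.map_loadings_to_parcels(fit, aligned, parc)
            wr.tsv(ranking.table(), "plstx", "gene_ranking.tsv")
            wr.tsv(sample_summary, "plstx", "sample_parcel_summary.tsv")
            for nm, vec in load_maps.items():
                wr.vector(vec, "plstx", f"{nm}_loadings.tsv")
            wr.json({
                "variance_explained_y": fit.variance_explained_y,
                "n_components": fit.n_components,
                "algorithm": fit.algorithm,
                "perm_p": perm_p, "n_perm": config.n_perm,
                "n_boot": config.n_boot,
                "driver_set_after_filter": drivers.genes,
                "driver_median_rank": {"pls1": med1, "pls2": med2},
                "driver_enrichment_p": {"pls1": enr_p1, "pls2": enr_p2},
            }, "plstx", "pls_fit.json")
            results["pls"] = {
                "var_explained_pls1": float(fit.variance_explained_y[0]),
                "var_explained_pls2": float(fit.variance_explained_y[1]),
                "perm_p": perm_p,
                "driver_enrichment_p_pls1": enr_p1,
                "driver_enrichment_p_pls2": enr_p2,
            }
            _done(name)

            name = "multifactor"
            design = multifactor.assemble_design(
                freq_vec, hubs_kept.metric("strength"), opc.score_map,
                load_maps["pls1"], load_maps["pls2"])
            inter_fit = multifactor.fit_glioma_model(design, interactions=True)
            sig_inter = multifactor.significant_interactions(inter_fit)
            main_fit = multifactor.fit_glioma_model(design, interactions=False)
            main_fit.spin_p = multifactor.predictor_spin_pvalues(design, ens_left)
            main_fit.spin_correction = "bonferroni(4)"
            wr.tsv(main_fit.table(), "multifactor", "model_table.tsv")
            wr.json({
                "interaction_model": {
                    "adj_r2": inter_fit.adj_r_squared,
                    "significant_interactions": sig_inter,
                },
                "main_model": {
                    "adj_r2": main_fit.adj_r_squared,
                    "r2": main_fit.r_squared,
                    "F": main_fit.f_statistic,
                    "df": [main_fit.df_model, main_fit.df_resid],
                    "betas": main_fit.params.to_dict(),
                    "partial_r2_pct": (100 * main_fit.partial_r2).to_dict(),
                    "spin_p_corrected": main_fit.spin_p.to_dict(),
                },
                "zero_filled": {c: int(design.missing[c].sum())
                                for c in design.missing.columns},
            }, "multifactor", "model.json")
            results["multifactor"] = {
                "adj_r2": main_fit.adj_r_squared,
                "F": main_fit.f_statistic,
                "betas": {k: float(v) for k, v in main_fit.params.items()},
                "partial_r2_pct": {k: float(100 * v)
                                   for k, v in main_fit.partial_r2.items()},
                "spin_p_corrected": {k: float(v) for k, v in main_fit.spin_p.items()},
                "significant_interactions": sig_inter,
            }
            _done(name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    from importlib.metadata import version
    try:
        pkg_version = version("gliotopo")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(
        config=config.to_dict(), seed=seed, outputs=wr.outputs,
        results=results, stages=stages, package_version=pkg_version,
    )
    manifest.save(outdir / "manifest.json")
    return manifest
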