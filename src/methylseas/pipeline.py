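"""End-to-end orchestration: annotate -> filter -> beta -> test -> select ->
tabulate -> enrich, from a structured config file.

Every intermediate table is written to the output directory, and a
machine-readable run report records input hashes, thresholds, the seed,
per-stage row counts, and output paths.  Identical configs (including the
seed) give byte-identical outputs; the report deliberately contains no
timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, diffmeth, enrichment, preprocessing, simulate, tabulate

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and permutation settings for one pipeline run.

    Betas may be supplied directly (``tumor_betas``/``normal_betas``) or as
    methylated/unmethylated intensity matrices plus a pairing map, from which
    beta values are computed with the configured offset.
    """

    genome: str
    manifest: str
    gene_models: str
    outdir: str
    tumor_betas: str | None = None
    normal_betas: str | None = None
    meth_intensities: str | None = None
    unmeth_intensities: str | None = None
    pairing: str | None = None
    pathways: str | None = None
    target_map: str | None = None
    truth: str | None = None
    alpha: float = 0.05
    min_abs_fc: float = 2.0
    offset: float = 100.0
    pseudo: float = 0.01
    n_perm: int = 1000
    seed: int | None = None
    use_maxt: bool = False
    subset: str = "all"
    normalize: bool = False

    def validate(self) -> None:
        if self.seed is None:
            raise StageError("config", "seed is mandatory (permutation reproducibility)")
        have_betas = self.tumor_betas and self.normal_betas
        have_intensities = (self.meth_intensities and self.unmeth_intensities
                            and self.pairing)
        if not have_betas and not have_intensities:
            missing = "pairing" if (self.meth_intensities and self.unmeth_intensities) \
                else "tumor_betas/normal_betas or meth/unmeth intensities"
            raise StageError("config", f"missing required field(s): {missing}")
        for name in ("genome", "manifest", "gene_models", "tumor_betas",
                     "normal_betas", "meth_intensities", "unmeth_intensities",
                     "pairing", "pathways", "target_map", "truth"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise StageError("config", f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_betas(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.tumor_betas and config.normal_betas:
        tumor = preprocessing.read_matrix(config.tumor_betas)
        normal = preprocessing.read_matrix(config.normal_betas)
        return tumor, normal
    meth = preprocessing.read_matrix(config.meth_intensities)
    unmeth = preprocessing.read_matrix(config.unmeth_intensities)
    if config.normalize:
        meth = preprocessing.median_scale_normalize(meth)
        unmeth = preprocessing.median_scale_normalize(unmeth)
    betas = preprocessing.compute_beta(meth, unmeth, offset=config.offset)
    pairing = preprocessing.read_pairing(config.pairing)
    missing = [s for s in pd.concat([pairing["tumor_id"], pairing["normal_id"]])
               if s not in betas.columns]
    if missing:
        raise StageError("beta", f"pairing references unknown samples: {missing[:5]}")
    return betas[list(pairing["tumor_id"])], betas[list(pairing["normal_id"])]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "inputs": {}, "params": {
            "alpha": config.alpha, "min_abs_fc": config.min_abs_fc,
            "offset": config.offset, "pseudo": config.pseudo,
            "n_perm": config.n_perm, "seed": config.seed,
            "use_maxt": config.use_maxt, "subset": config.subset,
        },
        "stages": {}, "outputs": {},
    }
    for name in ("genome", "manifest", "gene_models", "tumor_betas", "normal_betas",
                 "meth_intensities", "unmeth_intensities", "pairing", "pathways",
                 "target_map", "truth"):
        p = getattr(config, name)
        if p:
            report["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def _write(key: str, frame: pd.DataFrame, fname: str, **kw) -> None:
        path = outdir / fname
        frame.to_csv(path, sep="\t", index=kw.pop("index", False))
        report["outputs"][key] = fname

    # --- annotate -----------------------------------------------------------
    try:
        genome = annotation.read_fasta(config.genome)
        islands: dict[str, list] = {
            chrom: annotation.detect_cpg_islands(seq, chrom)
            for chrom, seq in genome.items()
        }
        manifest = simulate.read_manifest(config.manifest)
        gene_models = annotation.read_gene_models(config.gene_models)
        ann, ann_rejects = annotation.annotate_probes(manifest, islands, gene_models)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
        raise StageError("annotate", str(exc)) from exc
    all_islands = [i for chrom in sorted(islands) for i in islands[chrom]]
    annotation.write_islands_bed(all_islands, outdir / "islands.bed")
    report["outputs"]["islands"] = "islands.bed"
    _write("annotations", ann, "annotations.tsv")
    _write("annotation_rejects", ann_rejects, "annotation_rejects.tsv")
    report["stages"]["annotate"] = {
        "islands": len(all_islands), "probes": len(manifest),
        "annotated": len(ann), "rejected": len(ann_rejects),
    }

    # --- filter -------------------------------------------------------------
    try:
        kept, filt = preprocessing.filter_probes(manifest)
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc
    _write("filter_report", filt.to_frame(), "filter_report.tsv")
    report["stages"]["filter"] = {
        "kept": filt.kept, "sex_chromosome": filt.sex_chromosome,
        "snp_within_5bp": filt.snp_within_5bp,
        "non_unique_mapping": filt.non_unique_mapping,
    }

    # --- beta ---------------------------------------------------------------
    try:
        tumor, normal = _load_betas(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("beta", str(exc)) from exc
    analysed = [p for p in tumor.index if p in set(kept) and p in set(ann["probe_id"])]
    tumor, normal = tumor.loc[analysed], normal.loc[analysed]
    report["stages"]["beta"] = {"probes_analysed": len(analysed),
                                "pairs": tumor.shape[1]}

    # --- test ---------------------------------------------------------------
    try:
        results = diffmeth.call_sites(
            tumor, normal, alpha=config.alpha, use_maxt=config.use_maxt,
            n_perm=config.n_perm, seed=config.seed, pseudo=config.pseudo)
    except Exception as exc:
        raise StageError("test", str(exc)) from exc
    _write("site_results", results, "site_results.tsv")
    n_sig = int((results["direction"] != "none").sum())
    report["stages"]["test"] = {
        "sites": len(results), "significant": n_sig,
        "hyper": int((results["direction"] == "hyper").sum()),
        "hypo": int((results["direction"] == "hypo").sum()),
    }

    # --- select -------------------------------------------------------------
    candidates = diffmeth.select_fold_candidates(results, min_abs_fc=config.min_abs_fc)
    _write("candidates", candidates, "candidates.tsv")
    report["stages"]["select"] = {"candidates": len(candidates)}

    # --- tabulate -----------------------------------------------------------
    try:
        ct_all = tabulate.crosstab_region(results, ann, subset="all")
        ct_mir = tabulate.crosstab_region(results, ann, subset="mir_only")
        features = tabulate.crosstab_features(results, ann)
        pct = tabulate.summarize_percentages(ct_all) if ct_all.grand_total else {}
    except Exception as exc:
        raise StageError("tabulate", str(exc)) from exc
    _write("crosstab_all", ct_all.to_frame(), "crosstab_all.tsv")
    _write("crosstab_mir", ct_mir.to_frame(), "crosstab_mir.tsv")
    _write("feature_tab", features, "feature_tab.tsv", index=True)
    mir_candidates = candidates.merge(ann[["probe_id", "is_mir"]], on="probe_id")
    mir_candidates = mir_candidates[mir_candidates["is_mir"].astype(bool)]
    heat = tabulate.export_heatmap_matrix(
        mir_candidates.drop(columns="is_mir"), ann, outdir / "heatmap_matrix.tsv")
    report["outputs"]["heatmap_matrix"] = "heatmap_matrix.tsv"
    report["stages"]["tabulate"] = {
        "crosstab_total": ct_all.grand_total,
        "crosstab_mir_total": ct_mir.grand_total,
        "crosstab_rejects": len(ct_all.rejects),
        "heatmap_rows": len(heat),
        "percentages": pct,
    }

    # --- enrich -------------------------------------------------------------
    if config.pathways and config.target_map:
        try:
            collection = enrichment.read_gmt(config.pathways)
            tmap = pd.read_csv(config.target_map, sep="\t")
            mir_genes = sorted({
                g for spec in mir_candidates.merge(
                    ann[["probe_id", "gene_ids"]], on="probe_id")["gene_ids"]
                for g in str(spec).split(",") if g
            })
            per_mir = {}
            frames = []
            for mir in mir_genes:
                targets = tmap.loc[tmap["mir_id"] == mir, "target_gene"]
                if targets.empty:
                    continue
                res = enrichment.hypergeom_ora(set(targets), collection)
                per_mir[mir] = res
                frames.append(res.assign(mir_id=mir))
            ora = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["mir_id", *enrichment.RESULT_COLUMNS]))
            per_mir_counts, per_pathway_counts = enrichment.pathway_mir_counts(
                per_mir, alpha=config.alpha)
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc
        _write("enrichment", ora, "enrichment.tsv")
        _write("pathways_per_mir",
               per_mir_counts.rename("n_pathways").rename_axis("mir_id").reset_index(),
               "pathways_per_mir.tsv")
        _write("mirs_per_pathway",
               per_pathway_counts.rename("n_mirs").rename_axis("pathway").reset_index(),
               "mirs_per_pathway.tsv")
        report["stages"]["enrich"] = {
            "mirs_tested": len(per_mir),
            "pathways": len(collection.sets),
            "significant_pairs": int((ora["p_value"] < config.alpha).sum()) if len(ora) else 0,
        }

    # --- truth comparison (simulated runs) -----------------------------------
    if config.truth:
        truth = simulate.read_truth(config.truth)
        merged = results.merge(truth, on="probe_id", how="inner")
        planted = merged[merged["true_direction"] != "null"]
        called = merged[merged["direction"] != "none"]
        tp = int((planted["direction"] == planted["true_direction"]).sum())
        recall = tp / len(planted) if len(planted) else float("nan")
        precision = (int((called["direction"] == called["true_direction"]).sum())
                     / len(called)) if len(called) else float("nan")
        report["stages"]["truth"] = {
            "planted": len(planted), "recalled": tp,
            "recall": recall, "precision": precision,
        }

    # output paths are recorded relative to outdir so identical configs give
    # byte-identical reports regardless of where the run directory lives
    report_path = outdir / "run_report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"]["run_report"] = "run_report.json"
    report["outdir"] = str(outdir)
    return report


# ---------------------------------------------------------------------------
# simulation -> input files
# ---------------------------------------------------------------------------

def simulate_inputs(sim: simulate.SimConfig, outdir) -> dict[str, str]:
    """Generate a complete, self-consistent input set for ``run_pipeline``.

    Writes genome FASTA, gene models, manifest, paired beta matrices, truth
    table, pairing map, miR target map, and pathway GMT; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequence, islands, gene_models = simulate.generate_genome(sim)
    manifest = simulate.generate_manifest(sim, islands, gene_models)
    tumor, normal, truth = simulate.generate_paired_betas(manifest, sim)
    tmap = simulate.generate_target_map(gene_models, sim)
    pathways = simulate.generate_pathways(tmap, sim)

    paths = {
        "genome": str(outdir / "genome.fa"),
        "gene_models": str(outdir / "gene_models.tsv"),
        "manifest": str(outdir / "manifest.tsv"),
        "tumor_betas": str(outdir / "tumor_betas.tsv"),
        "normal_betas": str(outdir / "normal_betas.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "pairing": str(outdir / "pairing.tsv"),
        "target_map": str(outdir / "target_map.tsv"),
        "pathways": str(outdir / "pathways.gmt"),
    }
    simulate.write_fasta(sequence, paths["genome"])
    simulate.write_gene_models(gene_models, paths["gene_models"])
    simulate.write_manifest(manifest, paths["manifest"])
    preprocessing.write_matrix(tumor, paths["tumor_betas"])
    preprocessing.write_matrix(normal, paths["normal_betas"])
    simulate.write_truth(truth, paths["truth"])
    preprocessing.write_pairing(simulate.pairing_map(tumor, normal), paths["pairing"])
    tmap.to_csv(paths["target_map"], sep="\t", index=False)
    enrichment.write_gmt(pathways, paths["pathways"])
    return paths
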