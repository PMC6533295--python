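"""End-to-end analysis pipeline with a machine-readable run manifest.

Stages: validate -> forensic report per marker subset -> artifact filter
-> pairwise AMOVA distances with permutation p-values -> classical MDS
(+ neighbor-joining tree when three or more populations are present,
+ optional genotype PCA). Every output path, the config snapshot, the
seed and the input checksum go into ``manifest.json``; re-running the
same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .amova import DistanceModel, PairwiseAmova
from .forensic import forensic_report
from .io import read_genotype_table, validation_summary, write_genotype_table
from .ordination import classical_mds, nj_tree, one_hot_encode, pca, write_newick
from .panels import SUBSET_NAMES, YFILER_PLUS_PANEL
from .simulate import SimulationConfig, simulate_populations

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("ystrkit.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: str | Path | dict, outdir: str | Path) -> dict:
    """Execute the full analysis described by a YAML config; return the manifest.

    Config keys: ``input`` (genotype TSV) or ``simulate`` (a
    :class:`~ystrkit.simulate.SimulationConfig` mapping), ``subsets``
    (marker subsets for the forensic report), ``distance`` with
    ``method`` (``rst``/``fst``), ``subset`` and ``permutations``,
    ``pca`` (bool) and ``seed``.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seed": seed,
        "outputs": {},
        "inputs": {},
        "filter_log": [],
    }
    stage = "load"
    try:
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs.setdefault("seed", seed)
            for key in ("n_samples", "divergence_generations", "artifact_loci"):
                if key in sim_kwargs and sim_kwargs[key] is not None:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_cfg = SimulationConfig(**sim_kwargs)
            samples, truth = simulate_populations(sim_cfg)
            sim_path = outdir / "simulated.tsv"
            write_genotype_table(samples, sim_path)
            (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
            manifest["outputs"]["simulated"] = str(sim_path)
            manifest["outputs"]["truth"] = str(outdir / "truth.json")
            manifest["inputs"]["simulated"] = _sha256(sim_path)
        else:
            in_path = Path(cfg["input"])
            samples = read_genotype_table(in_path, YFILER_PLUS_PANEL)
            manifest["inputs"][str(in_path)] = _sha256(in_path)
        logger.info("loaded %d populations: %s", len(samples),
                    [s.name for s in samples])

        stage = "validate"
        qc = validation_summary(samples)
        qc_path = outdir / "qc.json"
        qc_path.write_text(json.dumps(qc, indent=2))
        manifest["outputs"]["qc"] = str(qc_path)

        stage = "forensic_report"
        subsets = [s.upper() for s in cfg.get("subsets", SUBSET_NAMES)]
        report = forensic_report(samples, subsets)
        report_path = outdir / "report.csv"
        report.to_csv(report_path, index=False)
        manifest["outputs"]["report"] = str(report_path)
        logger.info("forensic report: %d rows", len(report))

        stage = "pairwise_distance"
        dist_cfg = cfg.get("distance", {})
        method = str(dist_cfg.get("method", "rst")).lower()
        model = DistanceModel.rst() if method == "rst" else DistanceModel.fst()
        subset = dist_cfg.get("subset")
        subset_loci = (
            samples[0].panel.subset_loci(subset) if subset else None
        )
        permutations = int(dist_cfg.get("permutations", 999))
        amova = PairwiseAmova(samples, model, subset_loci)
        manifest["filter_log"] = amova.filter_log
        result = amova.fit(permutations=permutations, seed=seed)
        dist_path = outdir / f"dist_{method}.csv"
        pval_path = outdir / "pvals.csv"
        result.phi.to_csv(dist_path)
        result.pvalues.to_csv(pval_path)
        manifest["outputs"][f"dist_{method}"] = str(dist_path)
        manifest["outputs"]["pvals"] = str(pval_path)
        logger.info("pairwise %s done (%d permutations, %d profiles removed)",
                    method, permutations, len(amova.filter_log))

        stage = "mds"
        mds = classical_mds(result.phi, k=min(2, len(samples) - 1))
        mds_df = mds.to_frame(include_variance=True)
        mds_path = outdir / "mds.csv"
        mds_df.to_csv(mds_path)
        manifest["outputs"]["mds"] = str(mds_path)

        if len(samples) >= 3:
            stage = "nj_tree"
            tree = nj_tree(result.phi)
            tree_path = outdir / "tree.nwk"
            write_newick(tree, tree_path)
            manifest["outputs"]["tree"] = str(tree_path)
        else:
            logger.info("skipping NJ tree: fewer than 3 populations")

        if cfg.get("pca"):
            stage = "pca"
            _, centered = one_hot_encode(amova.samples, subset_loci)
            labels = [p.sample_id for s in amova.samples for p in s.profiles]
            res = pca(centered, labels=labels, n_components=3)
            pca_df = res.to_frame()
            pca_df["population"] = [
                p.population for s in amova.samples for p in s.profiles
            ]
            pca_df.loc["variance_explained"] = [
                *res.variance_explained, ""
            ]
            pca_path = outdir / "pca.csv"
            pca_df.to_csv(pca_path)
            manifest["outputs"]["pca"] = str(pca_path)
            manifest["pca_variance_explained"] = [
                float(v) for v in res.variance_explained
            ]
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, manifest, exc) from exc

    for name, path in list(manifest["outputs"].items()):
        manifest["outputs"][name] = {
            "path": path, "sha256": _sha256(Path(path)),
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    logger.removeHandler(handler)
    handler.close()
    return manifest
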