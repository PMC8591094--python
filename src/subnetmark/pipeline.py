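"""End-to-end orchestration: simulate/load -> de -> network -> cluster ->
score -> classify -> survive -> enrich.

Each stage writes its artifact into the run directory and appends a manifest
entry (parameters, input hashes, output hashes). Stage outputs are pure
functions of (inputs, config, rng_seed): re-running with an identical config
reproduces byte-identical files. A single ``rng_seed`` fans out to per-stage
seeds by hashing the stage name, so changing one stage's stochastic draw
never perturbs another's.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from subnetmark import data_io
from subnetmark.classify import evaluate, pca_project, train_svm
from subnetmark.data_io import AnnotationSets, ValidationError
from subnetmark.diffexpr import differential_expression, intersect_seeds, select_degs
from subnetmark.enrichment import enrich, enrichment_table
from subnetmark.mcl import MCLParams, filter_subnetworks, mcl_cluster
from subnetmark.network import expand_network, graph_stats
from subnetmark.scoring import activity_scores, assign_directions, zscore
from subnetmark.survival import (
    build_risk_model,
    cox_fit,
    external_validation,
    km_logrank,
    risk_score,
    stratify_median,
)
from subnetmark.synthetic import SyntheticSpec, gen_expression, gen_ppi, gen_survival

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "network", "cluster", "score", "classify", "survive", "enrich")


class StageError(RuntimeError):
    """A stage failed; carries the stage name. Partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated parameters for a full run.

    Either ``inputs`` names the five input files (expression, classes,
    edges, cna, clinical and optional validation_* counterparts) or the
    ``synthetic`` block parameterizes the generators. Unknown keys anywhere
    are rejected up front.
    """

    rng_seed: int = 0
    fc_cut: float = 2.0
    q_cut: float = 0.05
    hops: int = 1
    min_nodes: int = 3
    svm_c: float = 1.0
    n_survival: int = 300
    n_external: int = 150
    mcl: MCLParams = field(default_factory=MCLParams)
    synthetic: SyntheticSpec | None = None
    inputs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            self.synthetic = SyntheticSpec(rng_seed=self.rng_seed)
        if self.synthetic is not None and self.inputs is not None:
            raise ValidationError("give either synthetic parameters or input paths")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        payload = dict(raw)
        if "mcl" in payload and isinstance(payload["mcl"], dict):
            _check_keys(payload["mcl"], MCLParams, "mcl")
            payload["mcl"] = MCLParams(**payload["mcl"])
        if "synthetic" in payload and isinstance(payload["synthetic"], dict):
            _check_keys(payload["synthetic"], SyntheticSpec, "synthetic")
            payload["synthetic"] = SyntheticSpec(**payload["synthetic"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _check_keys(raw: dict, klass, label: str) -> None:
    known = {f.name for f in fields(klass)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown {label} keys: {sorted(unknown)}")


def stage_seed(rng_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (rng_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))


class _Manifest:
    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.path = run_dir / "manifest.json"
        self.entries: dict = {"config": config.to_dict(), "stages": {}}

    def record(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]):
        self.entries["stages"][stage] = {
            "parameters": params,
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        _write_json(self.entries, self.path)


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute every stage in order; return a summary of headline numbers.

    A stage failure raises :class:`StageError` naming the stage; artifacts
    written so far stay in ``run_dir``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, config)
    summary: dict = {}
    state: dict = {}
    for stage in STAGES:
        runner = globals()[f"_stage_{stage}"]
        try:
            runner(config, run_dir, manifest, state, summary)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
    _write_json(summary, run_dir / "summary.json")
    logger.info("pipeline complete: %s", run_dir)
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config, run_dir: Path, manifest, state, summary):
    """Generate (or load) every input cohort."""
    out = run_dir / "inputs"
    out.mkdir(exist_ok=True)
    if config.inputs is not None:
        _load_inputs(config, state)
        paths = [Path(p) for p in config.inputs.values()]
        manifest.record("simulate", {"mode": "files"}, paths, [])
        return
    spec = replace(config.synthetic, rng_seed=stage_seed(config.rng_seed, "simulate"))
    train, truth = gen_expression(spec, sample_prefix="tr_")
    edges, blocks, cna = gen_ppi(spec, truth)
    valid, _ = gen_expression(
        replace(spec, rng_seed=spec.rng_seed + 11), sample_prefix="va_", truth=truth
    )
    state.update(
        train=train, truth=truth, edges=edges, blocks=blocks, cna=cna,
        validation=valid, spec=spec,
    )
    data_io.write_expression(train, out / "expression_train.tsv")
    data_io.write_class_labels(train.class_labels, out / "classes_train.tsv")
    data_io.write_expression(valid, out / "expression_validation.tsv")
    data_io.write_class_labels(valid.class_labels, out / "classes_validation.tsv")
    data_io.write_edge_list(edges, out / "interactions.sif")
    data_io.write_gene_list(cna, out / "cna_genes.txt")
    manifest.record(
        "simulate",
        {"synthetic": asdict(spec)},
        [],
        sorted(out.iterdir()),
    )


def _load_inputs(config, state):
    paths = config.inputs
    for key in ("expression", "classes", "edges", "cna"):
        if key not in paths:
            raise FileNotFoundError(f"missing required input {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])
    state["train"] = data_io.read_expression(paths["expression"], paths["classes"])
    dialect = "sif" if str(paths["edges"]).endswith(".sif") else "tsv2"
    state["edges"] = data_io.read_edge_list(paths["edges"], dialect=dialect)
    state["cna"] = data_io.read_gene_list(paths["cna"], source_tag="CNA")
    if "validation_expression" in paths:
        state["validation"] = data_io.read_expression(
            paths["validation_expression"], paths.get("validation_classes")
        )
    if "clinical" in paths:
        state["clinical"] = data_io.read_clinical(paths["clinical"])
    if "annotations" in paths:
        state["annotations"] = data_io.read_gmt(paths["annotations"])


def _stage_de(config, run_dir: Path, manifest, state, summary):
    """Differential expression, DEG selection and seed intersection."""
    de = differential_expression(state["train"])
    degs = select_degs(de, fc_cut=config.fc_cut, q_cut=config.q_cut)
    seeds = intersect_seeds(degs, state["cna"])
    if not seeds.symbols:
        raise ValidationError("empty seed set: DEG and CNA lists do not overlap")
    state["de"], state["degs"], state["seeds"] = de, degs, seeds
    de.to_tsv(run_dir / "differential_expression.tsv", config.fc_cut, config.q_cut)
    data_io.write_gene_list(sorted(seeds.symbols), run_dir / "seed_genes.txt")
    manifest.record(
        "de",
        {"fc_cut": config.fc_cut, "q_cut": config.q_cut},
        [],
        [run_dir / "differential_expression.tsv", run_dir / "seed_genes.txt"],
    )
    summary["n_degs"] = len(degs)
    summary["n_seed_genes"] = len(seeds)


def _stage_network(config, run_dir: Path, manifest, state, summary):
    graph = expand_network(state["seeds"], state["edges"], hops=config.hops)
    stats = graph_stats(graph)
    state["graph"] = graph
    data_io.write_edge_list(
        sorted(tuple(sorted(e)) for e in graph.edges), run_dir / "network.sif"
    )
    with open(run_dir / "network_nodes.tsv", "w") as fh:
        fh.write("node\tis_seed\tdegree\n")
        for node in sorted(graph.nodes):
            fh.write(
                f"{node}\t{int(graph.is_seed(node))}\t{graph.graph.degree(node)}\n"
            )
    manifest.record(
        "network", {"hops": config.hops},
        [], [run_dir / "network.sif", run_dir / "network_nodes.tsv"],
    )
    summary["n_network_nodes"] = stats["n_nodes"]
    summary["n_network_edges"] = stats["n_edges"]


def _stage_cluster(config, run_dir: Path, manifest, state, summary):
    result = mcl_cluster(state["graph"], config.mcl)
    subnets = filter_subnetworks(result.clusters, state["seeds"], config.min_nodes)
    state["mcl_result"], state["subnetworks"] = result, subnets
    with open(run_dir / "clusters.tsv", "w") as fh:
        fh.write("node\tcluster_id\tis_seed\n")
        for cid, cluster in enumerate(result.clusters, start=1):
            for node in sorted(cluster):
                fh.write(f"{node}\t{cid}\t{int(state['graph'].is_seed(node))}\n")
    manifest.record(
        "cluster",
        {"mcl": asdict(config.mcl), "min_nodes": config.min_nodes,
         "converged": result.converged, "iterations": result.n_iterations},
        [], [run_dir / "clusters.tsv"],
    )
    summary["n_clusters"] = len(result.clusters)
    summary["n_subnetworks"] = len(subnets)


def _stage_score(config, run_dir: Path, manifest, state, summary):
    ztrain = zscore(state["train"])
    subnets = [
        assign_directions(sn, state["de"], state["train"])
        for sn in state["subnetworks"]
    ]
    state["subnetworks"] = subnets
    scores_train = activity_scores(subnets, ztrain)
    state["scores_train"] = scores_train
    data_io.write_subnetworks(subnets, run_dir / "subnetworks.gmt")
    scores_train.to_tsv(run_dir / "scores_train.tsv")
    outputs = [run_dir / "subnetworks.gmt", run_dir / "scores_train.tsv"]
    if "validation" in state:
        zvalid = zscore(state["validation"])
        scores_valid = activity_scores(subnets, zvalid)
        state["scores_validation"] = scores_valid
        scores_valid.to_tsv(run_dir / "scores_validation.tsv")
        outputs.append(run_dir / "scores_validation.tsv")
    manifest.record("score", {}, [], outputs)


def _stage_classify(config, run_dir: Path, manifest, state, summary):
    model = train_svm(
        state["scores_train"], state["train"].class_labels, c=config.svm_c
    )
    train_eval = evaluate(model, state["scores_train"], state["train"].class_labels)
    metrics = {"train": train_eval.to_dict()}
    if "scores_validation" in state:
        valid_eval = evaluate(
            model, state["scores_validation"], state["validation"].class_labels
        )
        metrics["validation"] = valid_eval.to_dict()
        summary["accuracy"] = valid_eval.accuracy
        summary["sensitivity"] = valid_eval.sensitivity
        summary["specificity"] = valid_eval.specificity
        summary["auc"] = valid_eval.auc
    _write_json(metrics, run_dir / "classification_metrics.json")
    coords, var = pca_project(state["scores_train"])
    coords.to_csv(run_dir / "pca_train.tsv", sep="\t")
    manifest.record(
        "classify", {"svm_c": config.svm_c},
        [], [run_dir / "classification_metrics.json", run_dir / "pca_train.tsv"],
    )
    state["svm"] = model


def _stage_survive(config, run_dir: Path, manifest, state, summary):
    """Cox risk model on a survival cohort; KM + log-rank; external check."""
    if config.inputs is not None:
        if "clinical" not in state:
            manifest.record("survive", {"skipped": "no clinical input"}, [], [])
            return
        scores, clinical = state["scores_train"], state["clinical"]
        scores_ext = clinical_ext = None
    else:
        spec, truth = state["spec"], state["truth"]
        seed = stage_seed(config.rng_seed, "survive")
        scores, clinical = _synthetic_cohort(
            config, spec, truth, state, seed, config.n_survival, "sv_"
        )
        scores_ext, clinical_ext = _synthetic_cohort(
            config, spec, truth, state, seed + 17, config.n_external, "ex_"
        )

    model, fits = build_risk_model(scores, clinical)
    clin_fits = []
    try:
        clin_fits = cox_fit(clinical, mode="univariate")
    except ValidationError:
        pass  # clinical covariates may be absent or degenerate
    risk = risk_score(scores, model)
    groups, threshold = stratify_median(risk)
    km = km_logrank(clinical, groups)

    with open(run_dir / "cox_table.tsv", "w") as fh:
        fh.write("covariate\tmodel\tbeta\thr\tci_low\tci_high\tp\n")
        for f in fits + clin_fits:
            fh.write(
                f"{f.covariate}\t{f.model_tag}\t{f.beta:.6g}\t{f.hr:.6g}\t"
                f"{f.ci95[0]:.6g}\t{f.ci95[1]:.6g}\t{f.p_value:.6g}\n"
            )
    risk.to_csv(run_dir / "risk_scores.tsv", sep="\t", header=True)
    with open(run_dir / "risk_groups.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s in risk.index:
            fh.write(f"{s}\t{groups[s]}\n")
    _km_to_tsv(km, run_dir / "km_curves.tsv")
    logrank = {
        "chi_square": km.chi_square, "df": km.df, "p_value": km.p_value,
        "median_threshold": threshold,
    }
    outputs = [
        run_dir / "cox_table.tsv", run_dir / "risk_scores.tsv",
        run_dir / "risk_groups.tsv", run_dir / "km_curves.tsv",
    ]
    summary["logrank_p"] = km.p_value
    if scores_ext is not None:
        km_ext = external_validation(scores_ext, model, clinical_ext)
        _km_to_tsv(km_ext, run_dir / "km_curves_external.tsv")
        logrank["external_p_value"] = km_ext.p_value
        outputs.append(run_dir / "km_curves_external.tsv")
        summary["external_logrank_p"] = km_ext.p_value
    _write_json(logrank, run_dir / "logrank.json")
    outputs.append(run_dir / "logrank.json")
    manifest.record("survive", {"n_survival": config.n_survival}, [], outputs)
    state["risk_model"] = model


def _synthetic_cohort(config, spec, truth, state, seed, n, prefix):
    """Tumor-only cohort: expression -> frozen-direction scores -> survival."""
    cohort_spec = replace(spec, rng_seed=seed, n_case=n, n_control=0)
    expr, _ = gen_expression(cohort_spec, sample_prefix=prefix, truth=truth)
    scores = activity_scores(state["subnetworks"], zscore(expr))
    # the generative risk axis: mean marker activity per sample
    risk_axis = scores.scores.mean(axis=0)
    clinical = gen_survival(risk_axis, cohort_spec)
    return scores, clinical


def _km_to_tsv(km, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\ttime\tat_risk\tsurvival\n")
        for name in sorted(km.curves):
            for _, row in km.curves[name].iterrows():
                fh.write(
                    f"{name}\t{row['time']:.6g}\t{int(row['at_risk'])}\t"
                    f"{row['survival']:.6g}\n"
                )


def _stage_enrich(config, run_dir: Path, manifest, state, summary):
    """Over-representation of subnetwork members in annotation sets."""
    if "annotations" in state:
        sets = state["annotations"]
    elif "blocks" in state:
        all_genes = set(state["truth"])
        sets = AnnotationSets(
            {f"BLOCK{i:02d}": blk for i, blk in enumerate(state["blocks"], start=1)},
            background=all_genes,
        )
    else:
        manifest.record("enrich", {"skipped": "no annotation sets"}, [], [])
        return
    query = set().union(*(sn.members for sn in state["subnetworks"]))
    results = enrich(query & sets.effective_background(), sets)
    enrichment_table(results).to_csv(run_dir / "enrichment.tsv", sep="\t")
    manifest.record("enrich", {}, [], [run_dir / "enrichment.tsv"])
    summary["top_enrichment_fe"] = results[0].fold_enrichment if results else None
    summary["top_enrichment_p"] = results[0].p_value if results else None
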