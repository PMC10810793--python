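"""Configuration-driven orchestration of the analysis stages.

A run is described by a YAML (or dict) config listing stages to execute in
order, a seed, permutation counts, and the threshold set (pre-filled with
the protocol defaults; any override is echoed into the run manifest).  The
manifest records the config hash, seed, stage list and a SHA-256 checksum of
every output file, so identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import response as rsp
from .pca import pc_distance, run_pca
from .preprocess import preprocess_bulk
from .separability import compare_sources, separability_table
from .simulate import (
    BulkSimConfig,
    ScSimConfig,
    generate_bulk_dataset,
    generate_bulk_response_counts,
    generate_singlecell_dataset,
    write_bulk_dataset,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "similarity", "separability", "de", "deconvolute", "report")

#: protocol threshold defaults, by name, so any deviation is explicit
DEFAULT_THRESHOLDS = {
    "min_total_reads": 10_000_000,
    "min_alignment_rate": 0.60,
    "max_duplicate_fraction": 0.50,
    "log_pseudo_tpm": 0.01,
    "min_median_tpm": 1.0,
    "cell_min_genes_detected": 1500,
    "cell_max_reads": 100_000,
    "cell_max_mito_fraction": 0.20,
    "gene_min_cells_detected": 3,
    "marker_adj_p": 0.01,
    "marker_min_pct": 40.0,
    "lfc_cutoff": 0.6,
    "deg_adj_p": 0.05,
    "deg_min_pct": 10.0,
    "bulk_min_max_tpm": 1.0,
}


@dataclass
class RunConfig:
    """Validated pipeline run configuration."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    n_perm: int = 100
    n_null: int = 1000
    reference_source: str = "source_1"
    on_no_signal: str = "top2"
    thresholds: dict = field(default_factory=dict)
    simulate_bulk: dict = field(default_factory=dict)
    simulate_singlecell: dict = field(default_factory=dict)
    bulk_matrix: Path | None = None
    bulk_meta: Path | None = None
    threshold_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        stages = list(raw.get("stages", []))
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid stages: {list(STAGES)}")
        if not stages:
            raise ValueError("config must list at least one stage")
        thresholds = dict(DEFAULT_THRESHOLDS)
        overrides = dict(raw.get("thresholds", {}))
        bad = set(overrides) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise ValueError(f"unknown threshold name(s): {sorted(bad)}")
        thresholds.update(overrides)
        return cls(
            stages=stages,
            out_dir=Path(raw.get("out_dir", "mglkit_run")),
            seed=int(raw.get("seed", 0)),
            n_perm=int(raw.get("n_perm", 100)),
            n_null=int(raw.get("n_null", 1000)),
            reference_source=str(raw.get("reference_source", "source_1")),
            on_no_signal=str(raw.get("on_no_signal", "top2")),
            thresholds=thresholds,
            simulate_bulk=dict(raw.get("simulate", {}).get("bulk", {})),
            simulate_singlecell=dict(raw.get("simulate", {}).get("singlecell", {})),
            bulk_matrix=Path(raw["bulk_matrix"]) if raw.get("bulk_matrix") else None,
            bulk_meta=Path(raw["bulk_meta"]) if raw.get("bulk_meta") else None,
            threshold_overrides=overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> str:
        payload = {
            "stages": self.stages,
            "seed": self.seed,
            "n_perm": self.n_perm,
            "n_null": self.n_null,
            "reference_source": self.reference_source,
            "on_no_signal": self.on_no_signal,
            "thresholds": self.thresholds,
            "simulate_bulk": self.simulate_bulk,
            "simulate_singlecell": self.simulate_singlecell,
        }
        return json.dumps(payload, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    root = logging.getLogger("mglkit")
    root.setLevel(logging.INFO)
    for old in [h for h in root.handlers if getattr(h, "_mglkit_run", False)]:
        root.removeHandler(old)
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")):
        handler.setFormatter(fmt)
        handler._mglkit_run = True
        root.addHandler(handler)


def run_pipeline(config: RunConfig | dict | str | Path) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = config.out_dir
    _setup_logging(out)
    state: dict = {}
    t0 = time.time()
    for stage in config.stages:
        logger.info("stage %s: start", stage)
        _STAGE_FUNCS[stage](config, state)
        logger.info("stage %s: done (%.1fs elapsed)", stage, time.time() - t0)

    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
                     and p.name != "run.log")
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "stages": config.stages,
        "threshold_overrides": config.threshold_overrides,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    mio.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, state: dict) -> None:
    bulk_cfg = BulkSimConfig(**{"seed": cfg.seed, **cfg.simulate_bulk})
    matrix, meta, truth = generate_bulk_dataset(bulk_cfg)
    write_bulk_dataset(matrix, meta, truth, cfg.out_dir / "simulate")
    state.update(bulk_tpm=matrix, bulk_meta=meta, bulk_truth=truth)

    sc_cfg = ScSimConfig(**{"seed": cfg.seed, **cfg.simulate_singlecell})
    control, treated, sc_truth = generate_singlecell_dataset(sc_cfg)
    counts, cpm, conditions, bulk_resp_truth = generate_bulk_response_counts(sc_cfg)
    state.update(
        sc_control=control, sc_treated=treated, sc_truth=sc_truth,
        bulk_resp_counts=counts, bulk_resp_cpm=cpm, bulk_resp_conditions=conditions,
        bulk_resp_truth=bulk_resp_truth, sc_cfg=sc_cfg,
    )


def _require(state: dict, key: str, stage: str, hint: str):
    if key not in state:
        raise RuntimeError(f"stage {stage!r} needs {hint}; run the providing stage first")
    return state[key]


def _stage_preprocess(cfg: RunConfig, state: dict) -> None:
    if "bulk_tpm" not in state:
        if cfg.bulk_matrix is None or cfg.bulk_meta is None:
            raise RuntimeError(
                "stage 'preprocess': no simulated data in this run and no "
                "bulk_matrix/bulk_meta input paths configured"
            )
        for p in (cfg.bulk_matrix, cfg.bulk_meta):
            if not Path(p).exists():
                raise FileNotFoundError(f"stage 'preprocess': missing input {p}")
        state["bulk_tpm"] = mio.read_expression_tsv(cfg.bulk_matrix)
        state["bulk_meta"] = mio.read_sample_table(cfg.bulk_meta)
    result = preprocess_bulk(state["bulk_tpm"], state["bulk_meta"])
    state["preprocessed"] = result
    stage_dir = cfg.out_dir / "preprocess"
    stage_dir.mkdir(parents=True, exist_ok=True)
    mio.write_expression_tsv(result["log2"], stage_dir / "log2_matrix.tsv")
    mio.write_sample_table(result["meta"], stage_dir / "samples_kept.tsv")
    result["removal_log"].to_csv(stage_dir / "removal_log.tsv", sep="\t", index=False)


def _stage_similarity(cfg: RunConfig, state: dict) -> None:
    pre = _require(state, "preprocessed", "similarity", "preprocessed bulk data")
    pca = run_pca(pre["scaled"])
    stage_dir = cfg.out_dir / "similarity"
    stage_dir.mkdir(parents=True, exist_ok=True)
    pca.scores.to_csv(stage_dir / "pc_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame({"pc": pca.scores.columns, "varexp": pca.varexp}).to_csv(
        stage_dir / "varexp.tsv", sep="\t", index=False
    )
    meta = pre["meta"]
    rows = []
    ref = cfg.reference_source
    for other in sorted(meta["source"].unique()):
        if other == ref:
            continue
        for d in pc_distance(pca, meta, ref, other):
            rows.append({"reference": ref, "other": other, "distance": d})
    dist = pd.DataFrame(rows, columns=["reference", "other", "distance"])
    dist.to_csv(stage_dir / "pc_distances.tsv", sep="\t", index=False)
    state["pca"] = pca
    state["pc_distances"] = dist


def _stage_separability(cfg: RunConfig, state: dict) -> None:
    pre = _require(state, "preprocessed", "separability", "preprocessed bulk data")
    meta = pre["meta"]
    sources = sorted(meta["source"].unique())
    pairs = [(a, b) for i, a in enumerate(sources) for b in sources[i + 1:]]
    results = compare_sources(
        pre["log2"], meta, pairs, n_perm=cfg.n_perm, rng=cfg.seed,
        n_null=cfg.n_null, on_no_signal=cfg.on_no_signal,
    )
    table = separability_table(results)
    stage_dir = cfg.out_dir / "separability"
    stage_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(stage_dir / "separability.tsv", sep="\t", index=False)
    mio.write_json([r.to_dict() for r in results], stage_dir / "separability.json")
    state["separability"] = table


def _stage_de(cfg: RunConfig, state: dict) -> None:
    import anndata as ad

    control = _require(state, "sc_control", "de", "simulated single-cell data")
    treated = state["sc_treated"]
    combined = ad.concat([control, treated])
    combined, removal_log = rsp.filter_cells_qc(combined)
    combined = rsp.filter_genes_detection(combined)
    norm = rsp.normalize_cells(combined)
    treated_name = treated.obs["condition"].iloc[0]
    control_name = control.obs["condition"].iloc[0]
    th = cfg.thresholds
    sc_de = rsp.cluster_contrast_de(norm, treated_name, control_name)
    sc_degs = rsp.call_cluster_degs(
        sc_de, adj_p=th["deg_adj_p"], min_abs_lfc=th["lfc_cutoff"], min_pct=th["deg_min_pct"]
    )
    counts = state["bulk_resp_counts"]
    conditions = state["bulk_resp_conditions"]
    bulk_de = rsp.bulk_contrast_de(counts, conditions, treated_name, control_name)
    bulk_degs = rsp.call_bulk_degs(
        bulk_de, state["bulk_resp_cpm"],
        adj_p=th["deg_adj_p"], min_abs_lfc=th["lfc_cutoff"], min_max_tpm=th["bulk_min_max_tpm"],
    )
    stage_dir = cfg.out_dir / "de"
    stage_dir.mkdir(parents=True, exist_ok=True)
    removal_log.to_csv(stage_dir / "cell_removal_log.tsv", sep="\t", index=False)
    sc_degs.to_csv(stage_dir / "sc_degs.tsv", sep="\t", index=False)
    bulk_degs.to_csv(stage_dir / "bulk_degs.tsv", sep="\t", index=False)
    state.update(sc_de=sc_de, sc_degs=sc_degs, bulk_de=bulk_de, bulk_degs=bulk_degs)


def _stage_deconvolute(cfg: RunConfig, state: dict) -> None:
    bulk_degs = _require(state, "bulk_degs", "deconvolute", "bulk DEG table from the 'de' stage")
    mapping = rsp.deconvolute_bulk_degs(bulk_degs, state["sc_degs"])
    stage_dir = cfg.out_dir / "deconvolute"
    stage_dir.mkdir(parents=True, exist_ok=True)
    out = mapping.copy()
    out["clusters"] = out["clusters"].map(lambda c: ",".join(c))
    out["discordant_clusters"] = out["discordant_clusters"].map(lambda c: ",".join(c))
    out.to_csv(stage_dir / "bulk_deg_clusters.tsv", sep="\t", index=False)
    state["deconvolution"] = mapping


def _stage_report(cfg: RunConfig, state: dict) -> None:
    write_report(cfg, state)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "similarity": _stage_similarity,
    "separability": _stage_separability,
    "de": _stage_de,
    "deconvolute": _stage_deconvolute,
    "report": _stage_report,
}


def write_report(cfg: RunConfig, state: dict) -> dict:
    """Assemble summary tables from whatever stage outputs are present.

    One TSV per summary plus a JSON index describing each file; empty
    summaries produce zero-row files, not missing files.
    """
    stage_dir = cfg.out_dir / "report"
    stage_dir.mkdir(parents=True, exist_ok=True)
    index: dict = {"summaries": []}

    def emit(name: str, df: pd.DataFrame, description: str) -> None:
        path = stage_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        index["summaries"].append(
            {"name": name, "path": path.name, "n_rows": int(len(df)), "description": description}
        )

    if not state:
        raise RuntimeError("report stage requires at least one prior stage output")
    if "pc_distances" in state:
        emit("pc_distances", state["pc_distances"], "cross-source Euclidean distances on PC1/PC2")
    if "separability" in state:
        emit("separability", state["separability"], "per-pair separability scores and empirical p-values")
    if "sc_degs" in state:
        counts = (
            state["sc_degs"].groupby(["contrast", "cluster", "direction"], observed=True)
            .size().reset_index(name="n_degs")
            if len(state["sc_degs"])
            else pd.DataFrame(columns=["contrast", "cluster", "direction", "n_degs"])
        )
        emit("deg_counts", counts, "DEG counts per contrast, cluster and direction")
    if "deconvolution" in state:
        m = state["deconvolution"]
        summary = pd.DataFrame(
            {
                "category": ["mapped", "bulk_only", "discordant"],
                "n_genes": [
                    int((~m["bulk_only"]).sum()) if len(m) else 0,
                    int(m["bulk_only"].sum()) if len(m) else 0,
                    int((m["discordant_clusters"].map(len) > 0).sum()) if len(m) else 0,
                ],
            }
        )
        emit("deconvolution_summary", summary, "bulk DEGs mapped to single-cell clusters")
    mio.write_json(index, stage_dir / "index.json")
    validate_report_index(index)
    return index


def validate_report_index(index: dict) -> None:
    """Check a report index against the shipped JSON-schema-style document."""
    from importlib import resources

    schema = json.loads(
        resources.files("mglkit").joinpath("schemas/report_index.schema.json").read_text()
    )
    if not isinstance(index, dict) or "summaries" not in index:
        raise ValueError("report index must be an object with a 'summaries' array")
    required = set(schema["properties"]["summaries"]["items"]["required"])
    for entry in index["summaries"]:
        missing = required - set(entry)
        if missing:
            raise ValueError(f"report index entry missing fields: {sorted(missing)}")
        if not isinstance(entry["n_rows"], int) or entry["n_rows"] < 0:
            raise ValueError("n_rows must be a non-negative integer")
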