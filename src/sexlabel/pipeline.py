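"""End-to-end pipeline driver: configuration, seeding, logging, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias, entities, meta_labels, mislabel, preprocess, sexinfer, synthgen

log = logging.getLogger("sexlabel")

STAGES = ("simulate", "preprocess", "meta_labels", "train", "predict",
          "mislabel", "entities", "bias")


@dataclass
class PipelineConfig:
    """Pipeline-wide configuration; unknown keys are rejected on load."""

    out_dir: str = "run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    category: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    threshold_high: float = 0.7
    alpha_grid: list[float] | None = None
    n_folds: int = 6
    n_lambda: int = 20
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold_high < 1.0:
            raise ValueError(f"threshold_high must be in (0.5, 1), got {self.threshold_high}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # location does not change run semantics
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (logged, collision-free)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _write(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write a run manifest."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    def record(stage: str, t0: float, **counts) -> None:
        elapsed = time.monotonic() - t0
        manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3), **counts}
        log.info("stage=%s elapsed=%.2fs %s", stage, elapsed, counts)

    state: dict = {}
    try:
        if "simulate" in config.stages:
            t0 = time.monotonic()
            sim_cfg = dict(config.sim)
            sim_cfg.setdefault("seed", stage_seed(config.seed, "simulate"))
            cfg = synthgen.config_from_dict(sim_cfg)
            corpus = synthgen.generate_corpus(cfg)
            synthgen.write_corpus(corpus, outdir / "corpus")
            state["corpus"] = corpus
            record("simulate", t0, n_samples=len(corpus.expression),
                   n_studies=cfg.n_studies)

        corpus = state["corpus"]

        if "preprocess" in config.stages:
            t0 = time.monotonic()
            fcfg = preprocess.FilterConfig(
                data_type=corpus.config.data_type, **config.filter)
            expr, _ = preprocess.preprocess(corpus.expression, fcfg)
            state["expr"] = expr
            record("preprocess", t0, rows_in=len(corpus.expression), rows_out=len(expr))
        else:
            state["expr"] = corpus.expression

        if "meta_labels" in config.stages:
            t0 = time.monotonic()
            ccfg = meta_labels.CategoryConfig(**config.category)
            samples, studies = meta_labels.label_metadata(corpus.meta, ccfg)
            _write(samples, outdir / "sample_sex.tsv", chash)
            _write(studies, outdir / "study_categories.tsv", chash)
            state["samples"], state["studies"] = samples, studies
            record("meta_labels", t0, n_samples=len(samples), n_studies=len(studies))

        if "train" in config.stages:
            t0 = time.monotonic()
            samples = state["samples"]
            labeled = samples[samples["metadata_sex"].isin(["female", "male"])]
            labeled = labeled.rename(columns={"metadata_sex": "sex"})
            groups = sexinfer.build_study_groups(
                corpus.meta[["sample_id", "study_id"]].drop_duplicates())
            train, test = sexinfer.construct_train_test(
                labeled, groups, seed=stage_seed(config.seed, "split"))
            X = state["expr"].loc[train["sample_id"]]
            y = (train["sex"] == "male").to_numpy(int)
            kwargs = {}
            if config.alpha_grid:
                kwargs["alpha_grid"] = tuple(config.alpha_grid)
            model = sexinfer.nested_cv_fit(
                X, y, train["group"].to_numpy(), feature_table=corpus.genes,
                n_folds=config.n_folds, n_lambda=config.n_lambda,
                seed=stage_seed(config.seed, "train"),
                threshold_high=config.threshold_high, **kwargs)
            model.to_json(outdir / "model.json")
            state["model"], state["test"] = model, test
            record("train", t0, n_train=len(train), n_test=len(test),
                   alpha=model.alpha, n_nonzero=int((model.coef != 0).sum()))

        if "predict" in config.stages:
            t0 = time.monotonic()
            scores = sexinfer.predict_scores(state["model"], state["expr"])
            scores = scores.merge(state["samples"], on="sample_id")
            platform = corpus.meta[["sample_id", "platform"]].drop_duplicates()
            scores = scores.merge(platform, on="sample_id", how="left")
            _write(scores[["sample_id", "score", "label"]], outdir / "scores.tsv", chash)
            qc, excluded = sexinfer.platform_qc(scores)
            _write(qc, outdir / "platforms.tsv", chash)
            scores = scores[~scores["platform"].isin(excluded)]
            state["scores"] = scores
            record("predict", t0, n_scored=len(scores), n_platforms_excluded=len(excluded))

        if "mislabel" in config.stages:
            t0 = time.monotonic()
            kcfg = mislabel.ClusterConfig(**config.cluster)
            flags, fits = mislabel.flag_all_studies(
                state["scores"][["sample_id", "study_id", "score", "metadata_sex"]], kcfg)
            _write(flags, outdir / "flags.tsv", chash)
            _write(fits, outdir / "cluster_fits.tsv", chash)
            state["flags"] = flags
            record("mislabel", t0, n_flagged=int((flags["flag"] == "mismatch").sum()),
                   n_studies=len(fits))

        if "entities" in config.stages:
            t0 = time.monotonic()
            cells, drugs, controls = synthgen.generate_lexicon_fixtures(
                stage_seed(config.seed, "lexicon"))
            cl = entities.build_cell_line_lexicon(cells)
            dl = entities.build_drug_lexicon(drugs, controls)
            cellmap = entities.map_metadata_to_cell_lines(corpus.meta, cl)
            _write(cellmap, outdir / "cellmap.tsv", chash)
            state["cellmap"], state["drug_lexicon"] = cellmap, dl
            record("entities", t0, n_mapped=int((cellmap["accessions"] != "").sum()))

        if "bias" in config.stages:
            t0 = time.monotonic()
            breakdown = bias.sex_breakdown(state["scores"][["label"]])
            _write(breakdown, outdir / "breakdown.tsv", chash)
            cat_breakdown = bias.study_category_breakdown(state["studies"])
            _write(cat_breakdown, outdir / "study_breakdown.tsv", chash)
            record("bias", t0, n_rows=len(breakdown))
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        done = set(manifest["stages"])
        pending = [s for s in config.stages if s not in done]
        stage = pending[0] if pending else "unknown"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["completed"] = [s for s in config.stages if s in manifest["stages"]]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
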