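"""End-to-end orchestration of the mining pipeline.

Stage order: corpus (synthetic or loaded) → marketing-account filter →
keyword/ontology union selection → background skip-gram training →
relevance classification → theme coding (stratified sample,
distribution, simulated raters, kappa) → per-theme SF-SAI primitive
extraction → semantic maps with distance statistics and closeness
verdicts.  The background embedding is trained before classification
because the default post vectorizer is the mean of token embeddings.

A single :class:`PipelineConfig` (YAML-serializable) drives the run;
every random stage derives its seed from the one top-level seed.  The
run writes all artifacts to ``out_dir`` plus a JSON report with
per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import atlas as atlas_mod
from . import classify as classify_mod
from .corpus import PostPool, filter_marketing_accounts, read_posts, write_posts
from .embedding import train_skipgram
from .ontology import default_groups, union_select
from .primitives import extract_primitives, primitives_to_frame
from .synth import SyntheticConfig, generate_corpus, simulate_raters, write_ground_truth
from .themes import stratified_sample, theme_distribution, verify_codebook

log = logging.getLogger("inferatlas.pipeline")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the reference study settings."""

    out_dir: str = "pipeline_out"
    corpus_path: Optional[str] = None  # load instead of generating
    synthetic: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(n_posts=6000, n_accounts=600)
    )
    follower_threshold: int = 5000
    # embedding
    dim: int = 400
    window: int = 10
    min_count: int = 5
    epochs: int = 5
    # classifier
    n_val_per_class: int = 200
    vectorizer: str = "embedding_mean"
    # theme coding
    per_year: int = 200
    n_check: int = 140
    # primitives / maps
    k_primitives: int = 30
    perplexity: float = 5.0
    min_theme_posts: int = 30
    render_figures: bool = False
    seed: int = 0

    def stage_seed(self, stage: int) -> int:
        return int((self.seed * 1_000_003 + stage) % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self)), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            syn = data["synthetic"]
            for key in ("tokens_per_post", "years"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            if "theme_weights" in syn:
                syn["theme_weights"] = dict(syn["theme_weights"])
            data["synthetic"] = SyntheticConfig(**syn)
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-ready run report."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}

    # -- stage 0: corpus -----------------------------------------------------
    truth = None
    if cfg.corpus_path:
        pool = read_posts(cfg.corpus_path)
    else:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.stage_seed(0))
        pool, truth = generate_corpus(syn)
        write_posts(pool, out / "corpus.jsonl")
        write_ground_truth(truth, out / "ground_truth.csv")
    report["stages"]["corpus"] = {"n_posts": len(pool)}
    log.info("corpus: %d posts", len(pool))

    # -- stage 1: marketing-account filter ----------------------------------
    filtered = filter_marketing_accounts(pool, threshold=cfg.follower_threshold)
    report["stages"]["marketing_filter"] = {
        "n_posts": len(filtered),
        "removed": len(pool) - len(filtered),
    }
    log.info("marketing filter: %d -> %d posts", len(pool), len(filtered))

    # -- stage 2: union keyword/ontology selection ---------------------------
    groups = default_groups(ascii_tokens=cfg.synthetic.ascii_tokens)
    head = cfg.synthetic.head_keyword
    selected = union_select(filtered, groups, head_keyword=head)
    stage: dict = {"n_posts": len(selected)}
    if truth is not None:
        planted = (truth.keyword_ids | truth.eq1_ids) & set(filtered.ids)
        got = set(selected.ids)
        tp = len(got & planted)
        stage["precision"] = tp / len(got) if got else 1.0
        stage["recall"] = tp / len(planted) if planted else 1.0
    report["stages"]["union_selection"] = stage
    log.info("union selection: %d -> %d posts", len(filtered), len(selected))

    # -- stage 3: background skip-gram embedding -----------------------------
    model = train_skipgram(
        filtered,
        dim=cfg.dim,
        window=cfg.window,
        min_count=cfg.min_count,
        epochs=cfg.epochs,
        seed=cfg.stage_seed(3),
    )
    model.save_word2vec(out / "embedding.w2v")
    report["stages"]["embedding"] = {"vocab_size": len(model), "dim": cfg.dim}
    log.info("embedding: vocabulary of %d tokens", len(model))

    # -- stage 4: relevance classification -----------------------------------
    labeled = [p for p in filtered if p.relevance_label is not None]
    labeled_pool = PostPool(list(labeled), filtered.provenance + " | labeled subset")
    feats = classify_mod.vectorize_posts(labeled_pool, model, method=cfg.vectorizer)
    labels = np.array([p.relevance_label for p in labeled_pool])
    rng = np.random.default_rng(cfg.stage_seed(4))
    val_idx: list[int] = []
    for cls_label in classify_mod.LABELS:
        cls_rows = np.flatnonzero(labels == cls_label)
        n_val = min(cfg.n_val_per_class, max(1, len(cls_rows) // 5))
        val_idx.extend(rng.choice(cls_rows, size=n_val, replace=False))
    val_mask = np.zeros(len(labels), dtype=bool)
    val_mask[val_idx] = True
    train_feats = classify_mod.FeatureMatrix(
        [i for i, m in zip(feats.post_ids, val_mask) if not m],
        feats.vectors[~val_mask],
        feats.method,
    )
    val_feats = classify_mod.FeatureMatrix(
        [i for i, m in zip(feats.post_ids, val_mask) if m],
        feats.vectors[val_mask],
        feats.method,
    )
    clf = classify_mod.train_classifier(
        train_feats, labels[~val_mask], seed=cfg.stage_seed(4)
    )
    val_report = classify_mod.evaluate(clf, val_feats, labels[val_mask])
    val_report.to_json(out / "classifier_report.json")
    classify_mod.save_classifier(clf, out / "classifier.joblib",
                                 meta={"vectorizer": cfg.vectorizer})

    pred = clf.predict(
        classify_mod.vectorize_posts(selected, model, method=cfg.vectorizer).vectors
    )
    wpp = selected.subset(
        [pid for pid, y in zip(selected.ids, pred) if y == "target"],
        note="relevance classifier (predicted target)",
    )
    report["stages"]["classification"] = {
        "accuracy": val_report.accuracy,
        "n_eval": val_report.n_eval,
        "n_posts": len(wpp),
    }
    log.info(
        "classifier: accuracy %.4f on %d held-out posts; WPP has %d posts",
        val_report.accuracy, val_report.n_eval, len(wpp),
    )

    # -- stage 5: theme coding ------------------------------------------------
    themed_pool = PostPool(
        [p for p in wpp if p.theme_code is not None],
        wpp.provenance + " | themed posts",
    )
    sample = stratified_sample(
        themed_pool, per_year=cfg.per_year, seed=cfg.stage_seed(5)
    )
    dist = theme_distribution({p.id: p.theme_code for p in sample})
    kappa_stage: dict = {}
    if truth is not None:
        raters = simulate_raters(
            truth, cfg.synthetic.rater_error_rate, seed=cfg.stage_seed(6)
        )
        in_sample = raters[raters.post_id.isin(set(sample.ids))]
        r1 = dict(zip(in_sample.post_id, in_sample.rater1))
        r2 = dict(zip(in_sample.post_id, in_sample.rater2))
        kappas = verify_codebook(r1, r2, n_check=cfg.n_check, seed=cfg.stage_seed(7))
        kappa_stage = {
            "overall_kappa": kappas["overall"].kappa,
            "per_code_kappa": {
                c: (None if np.isnan(k.kappa) else k.kappa)
                for c, k in kappas.items()
                if c != "overall"
            },
        }
        in_sample.to_csv(out / "rater_labels.csv", index=False)
    report["stages"]["theme_coding"] = {
        "n_sampled": len(sample),
        "counts": dist.counts,
        "percentages": dist.percentages,
        **kappa_stage,
    }
    (out / "theme_distribution.json").write_text(
        json.dumps({"counts": dist.counts, "percentages": dist.percentages,
                    "total": dist.total}, indent=2),
        encoding="utf-8",
    )
    log.info("theme coding: sampled %d posts across %d themes",
             len(sample), len(dist.counts))

    # -- stage 6: per-theme primitives and semantic maps ----------------------
    theme_reports: dict = {}
    prim_frames = []
    for code in sorted({p.theme_code for p in themed_pool}):
        field_posts = [p for p in themed_pool if p.theme_code == code]
        if len(field_posts) < cfg.min_theme_posts:
            continue
        field_pool = PostPool(field_posts, f"theme {code} field corpus")
        prims = extract_primitives(
            field_pool, model, k=cfg.k_primitives, allowed_pos={"n"}
        )
        prim_frames.append(primitives_to_frame(prims, theme=code))
        entry: dict = {"n_posts": len(field_posts), "n_primitives": len(prims)}
        if len(prims) >= 4:
            smap = atlas_mod.build_map(
                prims,
                perplexity=min(cfg.perplexity, len(prims) - 1),
                seed=cfg.stage_seed(8),
            )
            verdicts = atlas_mod.close_pairs(smap)
            entry["distance_stats"] = dataclasses.asdict(smap.stats)
            entry["n_close_pairs"] = sum(v.close for v in verdicts)
            atlas_mod.stats_to_json(smap.stats, out / f"map_stats_{code}.json")
            atlas_mod.distances_to_tsv(smap, out / f"distances_{code}.tsv")
            if cfg.render_figures:
                atlas_mod.render_atlas(smap, out / f"atlas_{code}.png")
                atlas_mod.render_atlas(smap, out / f"atlas_{code}.svg")
        theme_reports[code] = entry
        log.info("theme %s: %d posts, %d primitives", code, len(field_posts),
                 entry["n_primitives"])
    if prim_frames:
        import pandas as pd

        pd.concat(prim_frames, ignore_index=True).to_csv(
            out / "primitives.csv", index=False
        )
    report["stages"]["semantic_maps"] = theme_reports

    def _jsonable(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    report = json.loads(json.dumps(report, default=_jsonable))
    (out / "report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
    return report
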