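"""End-to-end orchestration: simulate/load -> preprocess -> fit -> evaluate
-> select -> refit -> project -> report.

The held-out progressive (SPMS) group never participates in filter
computation, TMM reference choice, model fitting or Lasso cross-validation;
its samples are pushed through the frozen preprocessing and projected onto
the fitted latent space afterwards.  Every run writes a JSON report plus TSV
intermediates and a manifest with the configuration hash and seeds, and is
byte-identical under fixed seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference
from .blocks import OmicsBlock, read_matrix
from .evaluate import evaluate_components, rank_sum_test
from .model import MCIA
from .preprocess import PreprocessResult, preprocess_block
from .select import SelectionResult, compare_ranks, reduce_and_refit, select_features
from .synthetic import DEFAULT_BLOCKS, SyntheticConfig, generate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Flat run configuration; defaults follow the published analysis where
    it states a value (min_total 100, coverage 2/3, RCV 1, K 10, 5 folds)."""

    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    input_dir: str | None = None          # read TSV blocks instead of simulating
    min_total: int = 100
    coverage_fraction: float = 2 / 3
    coverage_mode: str = "both"
    rcv_threshold: float = 1.0
    m_trim: float = 0.30
    a_trim: float = 0.05
    log_transform: bool = True
    inertia: str = "root"
    n_components: int = 10
    folds: int = 5
    cv_seed: int = 0
    lambda_rule: str = "min"
    post_sd_filter: bool = False
    positive_labels: tuple[str, ...] = ("RRMS", "CIS", "RIS")
    held_out_labels: tuple[str, ...] = ("SPMS",)
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
            for key in ("features_per_block", "block_loading_strength"):
                d["synthetic"][key] = dict(d["synthetic"][key])
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # analysis-relevant settings only
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "synthetic"})
        if syn is not None:
            cfg = replace(cfg, synthetic=SyntheticConfig(**syn))
        elif cfg.input_dir is None:
            cfg = replace(cfg, synthetic=SyntheticConfig())
        else:
            cfg = replace(cfg, synthetic=None)
        for key in ("positive_labels", "held_out_labels"):
            cfg = replace(cfg, **{key: tuple(getattr(cfg, key))})
        return cfg


@dataclass
class RunReport:
    """Structured run outcome; serializes deterministically to JSON."""

    sections: dict

    def to_json(self) -> str:
        return json.dumps(self.sections, sort_keys=True, indent=1)

    def __getitem__(self, key):
        return self.sections[key]


def load_cohort(input_dir) -> tuple[dict[str, OmicsBlock], pd.DataFrame]:
    """Read every ``<block>.tsv`` named in the default layout plus metadata."""
    input_dir = Path(input_dir)
    metadata = pd.read_csv(input_dir / "metadata.tsv", sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    blocks = {}
    for name, (assay, source, _) in DEFAULT_BLOCKS.items():
        path = input_dir / f"{name}.tsv"
        if path.exists():
            blocks[name] = read_matrix(path, assay=assay, source=source, name=name)
    if not blocks:
        raise FileNotFoundError(f"no block TSVs found under {input_dir}")
    return blocks, metadata


def summarize_selection(
    selection: SelectionResult,
    block_info: Mapping[str, tuple[str, str]],
    biotypes: Mapping[str, str] | None = None,
) -> dict:
    """Cross-tab selected features by pipeline and source (and biotype).

    ``block_info`` maps block name to (assay, source).  Percentages are the
    count ratio x 100, rounded half-up to one decimal, within each pipeline.
    """
    by_assay: dict[str, dict[str, int]] = {}
    by_biotype: dict[str, dict[str, int]] = {}
    for block, coefs in selection.selected.items():
        assay, source = block_info[block]
        by_assay.setdefault(assay, {})
        by_assay[assay][source] = by_assay[assay].get(source, 0) + len(coefs)
        if biotypes is not None:
            for f in coefs.index:
                bt = biotypes.get(str(f), "unknown")
                by_biotype.setdefault(source, {})
                by_biotype[source][bt] = by_biotype[source].get(bt, 0) + 1
    out: dict = {"n_selected": selection.n_selected, "by_pipeline": {}}
    for assay, counts in sorted(by_assay.items()):
        total = sum(counts.values())
        out["by_pipeline"][assay] = {
            "total": total,
            "sources": {
                src: {"count": c, "percent": reference.percentage(c, total)}
                for src, c in sorted(counts.items())
            },
        }
    if biotypes is not None:
        out["by_biotype"] = by_biotype
    return out


def _group_test(scores: pd.Series, a_ids, b_ids) -> dict:
    a = scores.reindex(a_ids).dropna()
    b = scores.reindex(b_ids).dropna()
    if len(a) == 0 or len(b) == 0:
        return {"n_a": int(len(a)), "n_b": int(len(b)), "u": None, "p": None}
    u, p = rank_sum_test(a.to_numpy(), b.to_numpy())
    return {"n_a": int(len(a)), "n_b": int(len(b)), "u": u, "p": p}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and assemble the run report."""
    # --- stage: cohort ------------------------------------------------------
    try:
        if config.input_dir is not None:
            blocks, metadata = load_cohort(config.input_dir)
        else:
            blocks, metadata, _truth = generate_cohort(config.synthetic)
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    groups = metadata["group"].astype(str)
    held_mask = groups.isin(config.held_out_labels)
    fit_ids = list(groups.index[~held_mask])
    held_ids = list(groups.index[held_mask])
    pos_mask = groups.loc[fit_ids].isin(config.positive_labels)
    binary = pd.Series(np.where(pos_mask, "positive", "control"), index=fit_ids)

    # --- stage: preprocess (fitting samples only) ---------------------------
    prep: dict[str, PreprocessResult] = {}
    proc: dict[str, OmicsBlock] = {}
    filter_section: dict = {}
    empty_blocks: list[str] = []
    for name, block in blocks.items():
        try:
            res = preprocess_block(
                block.subset_samples(fit_ids), binary,
                min_total=config.min_total,
                coverage_fraction=config.coverage_fraction,
                coverage_mode=config.coverage_mode,
                rcv_threshold=config.rcv_threshold,
                m_trim=config.m_trim, a_trim=config.a_trim,
                log_transform=config.log_transform,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'preprocess' failed on block {name!r}: {exc}") from exc
        filter_section[name] = {
            "n_input": block.n_features,
            "n_retained": res.block.n_features,
            "chain": [{"rule": r.rule, "n_before": r.n_before, "n_after": r.n_after}
                      for r in res.reports],
        }
        if res.block.n_features == 0:
            empty_blocks.append(name)
            continue
        prep[name] = res
        proc[name] = res.block
    if not proc:
        raise RuntimeError("stage 'preprocess' failed: every block lost all features")

    # --- stage: fit ---------------------------------------------------------
    n_fit = len(fit_ids)
    p_total = sum(b.n_features for b in proc.values())
    k = min(config.n_components, n_fit - 1, p_total)
    try:
        results = MCIA(proc, k, inertia=config.inertia, labels=groups.loc[fit_ids]).fit()
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    # --- stage: evaluate ----------------------------------------------------
    comp_table = evaluate_components(results, positive_labels=set(config.positive_labels))
    fractions = results.contribution_fractions

    # --- stage: select + refit ----------------------------------------------
    try:
        selection = select_features(
            results, folds=config.folds, seed=config.cv_seed, labels=binary,
            lambda_rule=config.lambda_rule, post_sd_filter=config.post_sd_filter,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'select' failed: {exc}") from exc
    block_info = {name: (blocks[name].assay, blocks[name].source) for name in blocks}
    selection_summary = summarize_selection(selection, block_info)
    selection_summary["lambda_chosen"] = selection.lambda_chosen
    selection_summary["dropped_blocks"] = sorted(selection.dropped_blocks + empty_blocks)

    reduced_section: dict = {"fitted": False}
    rank_section: dict = {}
    if selection.n_selected > 0:
        try:
            reduced = reduce_and_refit(proc, selection, config.n_components,
                                       labels=groups.loc[fit_ids], inertia=config.inertia)
        except Exception as exc:
            raise RuntimeError(f"stage 'refit' failed: {exc}") from exc
        red_table = evaluate_components(reduced, positive_labels=set(config.positive_labels))
        best_red = red_table.loc[red_table["best"]].iloc[0]
        reduced_section = {
            "fitted": True,
            "n_components": int(reduced.n_components),
            "component_table": red_table.drop(columns="best").to_dict("records"),
            "auc_L1": float(red_table.loc[red_table["component"] == 1, "auc"].iloc[0]),
            "split_join_L1": int(
                red_table.loc[red_table["component"] == 1, "split_join"].iloc[0]),
            "best_component": int(best_red["component"]),
        }
        try:
            _rank_table, rho = compare_ranks(results, reduced)
            rank_section = {"spearman_rho": rho, "n_shared": int(len(_rank_table))}
        except ValueError as exc:  # < 3 shared features: rho undefined, flagged
            rank_section = {"spearman_rho": None, "flagged": str(exc)}
    else:
        reduced = None

    # --- stage: project held-out samples ------------------------------------
    projection_section: dict = {"n_projected": 0}
    l1_all = results.global_scores["L1"].copy()
    if held_ids and all(name in prep for name in proc):
        new_blocks = {name: prep[name].apply_to_new(blocks[name].subset_samples(held_ids))
                      for name in proc}
        projected = results.project(new_blocks)
        proj_l1 = projected.scores["L1"]
        l1_all = pd.concat([l1_all, proj_l1])
        pos_ids = [s for s in fit_ids if groups[s] in config.positive_labels]
        ctl_ids = [s for s in fit_ids if groups[s] not in config.positive_labels]
        projection_section = {
            "n_projected": len(held_ids),
            "scores_L1": {str(s): float(v) for s, v in proj_l1.items()},
            "tests": {
                "positive_vs_control": _group_test(l1_all, pos_ids, ctl_ids),
                "held_out_vs_positive": _group_test(l1_all, held_ids, pos_ids),
                "held_out_vs_control": _group_test(l1_all, held_ids, ctl_ids),
            },
        }
        phase = metadata.get("phase")
        if phase is not None:
            rel = [s for s in fit_ids if groups[s] == "RRMS" and phase[s] == "relapse"]
            rem = [s for s in fit_ids if groups[s] == "RRMS" and phase[s] == "remission"]
            nindc = [s for s in fit_ids if groups[s] == "NINDC"]
            indc = [s for s in fit_ids if groups[s] == "INDC"]
            projection_section["tests"]["relapse_vs_remission"] = _group_test(l1_all, rel, rem)
            projection_section["tests"]["nindc_vs_indc"] = _group_test(l1_all, nindc, indc)

    # --- report -------------------------------------------------------------
    best = comp_table.loc[comp_table["best"]].iloc[0]
    sections = {
        "manifest": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seeds": {
                "generator": (config.synthetic.seed if config.synthetic else None),
                "cv": config.cv_seed,
            },
            "n_fit_samples": n_fit,
            "n_held_out": len(held_ids),
        },
        "filters": filter_section,
        "total_features": {
            "before": int(sum(b.n_features for b in blocks.values())),
            "after": int(p_total),
        },
        "components": {
            "table": comp_table.drop(columns="best").to_dict("records"),
            "best_component": int(best["component"]),
            "auc_L1": float(comp_table.loc[comp_table["component"] == 1, "auc"].iloc[0]),
            "split_join_L1": int(
                comp_table.loc[comp_table["component"] == 1, "split_join"].iloc[0]),
        },
        "contributions": {
            block: {comp: float(fractions.loc[block, comp]) for comp in fractions.columns}
            for block in fractions.index
        },
        "selection": selection_summary,
        "reduced": reduced_section,
        "rank_comparison": rank_section,
        "projection": projection_section,
    }
    report = RunReport(sections=sections)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        comp_table.to_csv(out / "component_table.tsv", sep="\t", index=False)
        results.global_scores.to_csv(out / "global_scores.tsv", sep="\t")
        fractions.to_csv(out / "contribution_fractions.tsv", sep="\t")
        (out / "selection.json").write_text(
            json.dumps(selection.to_dict(), sort_keys=True, indent=1))
        (out / "filter_reports.json").write_text(json.dumps(
            {name: [r.to_dict() for r in prep[name].reports] for name in prep},
            sort_keys=True, indent=1))
        results.save(out / "model_full")
        if reduced is not None:
            reduced.save(out / "model_reduced")
        if projection_section.get("n_projected"):
            pd.Series(projection_section["scores_L1"]).rename("L1").to_csv(
                out / "projected_scores_L1.tsv", sep="\t")
    return report
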