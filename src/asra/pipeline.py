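"""End-to-end orchestration of the discovery / classification / uniqueness runs.

The three ``run_*`` functions wire the pipeline stages together exactly as
the command-line interface exposes them, and each returns plain Python
objects so they are equally usable from scripts and notebooks.  Every run
assembles a reproducibility block (seeds, parameters, input digests) that is
written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .bga import (
    BGAModel,
    bga_fit,
    classify,
    merge_symmetric_labels,
    project,
    separation_pvalue,
)
from .data_model import ExpressionMatrix, GeneSet, ValidationError, match_genes
from .rankprod import call_differential
from .signature import SignatureTable, build_signature, summarize
from .uniqueness import (
    enrichment_vs_chance,
    evaluate_subsets,
    percentile_rank,
    relative_separation,
    sample_subsets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs shared across the pipeline stages."""

    pfp_cutoff: float = 0.05
    permutations: int = 100
    null_scheme: str = "within-array"
    n_draws: int = 10000
    subset_size: int = 85
    seed: int = 0
    asym_label: str = "ASYM"
    sym_label: str = "SYM"
    p53sym_label: str = "p53SYM"
    reference: str = "SYM"

    def __post_init__(self) -> None:
        if not 0 <= self.pfp_cutoff:
            raise ValidationError("pfp cutoff must be nonnegative")
        if self.permutations < 1 or self.n_draws < 1 or self.subset_size < 2:
            raise ValidationError("permutations, draws and subset size out of range")

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(x: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x.values.to_numpy()).tobytes())
    h.update("\t".join(x.gene_ids[:100]).encode())
    h.update("\t".join(x.sample_ids).encode())
    return h.hexdigest()[:16]


def _repro_block(cfg: PipelineConfig, stage: str, inputs: dict) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "input_digests": inputs,
    }


def run_discovery(
    x: ExpressionMatrix, cfg: PipelineConfig | None = None
) -> tuple[SignatureTable, dict, dict]:
    """Rank-products A and B comparisons + intersection classification.

    Returns the signature table, a summary dict (category counts, the
    exclusive/absent totals and the reproducibility block) and the two
    per-comparison differential results (``{"A": ..., "B": ...}``).  When the
    matrix has no detection calls the discovery still completes with the
    exclusive flags reported as unavailable.
    """
    cfg = cfg or PipelineConfig()
    if cfg.pfp_cutoff == 0:
        logger.warning("pfp cutoff 0: no gene can be called significant")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2)
    diff_a = call_differential(
        x, cfg.asym_label, cfg.sym_label,
        cutoff=cfg.pfp_cutoff, B=cfg.permutations, seed=int(seeds[0]), null=cfg.null_scheme,
    )
    diff_b = call_differential(
        x, cfg.asym_label, cfg.p53sym_label,
        cutoff=cfg.pfp_cutoff, B=cfg.permutations, seed=int(seeds[1]), null=cfg.null_scheme,
    )
    table = build_signature(
        diff_a, diff_b, x,
        asym_label=cfg.asym_label, sym_label=cfg.sym_label, p53sym_label=cfg.p53sym_label,
    )
    summary = summarize(table)
    summary["reproducibility"] = _repro_block(cfg, "discovery", {"training": _digest(x)})
    return table, summary, {"A": diff_a, "B": diff_b}


def discovery_outputs(table: SignatureTable, summary: dict, diffs=None, outdir=None) -> None:
    """Write the discovery tables + summary JSON into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.write_tsv(outdir / "signature.tsv")
    table.write_tsv(outdir / "categories_full.tsv", include_none=True)
    for name, diff in (diffs or {}).items():
        diff.write_tsv(outdir / f"rankprod_{name}.tsv")
    with open(outdir / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)


def run_classification(
    x_train: ExpressionMatrix,
    signature: GeneSet,
    test_sets: dict[str, ExpressionMatrix] | None = None,
    cfg: PipelineConfig | None = None,
    model: BGAModel | None = None,
) -> tuple[BGAModel, pd.DataFrame, dict]:
    """Fit (or reuse) the signature BGA model and classify test sets.

    The training contrast is ASYM vs the merged SYM/p53SYM group.  Returns
    the model, a long table (dataset, sample_id, coordinate, label) covering
    the training samples and every test set, and per-dataset two-group
    p-values where a test set carries exactly two condition labels.
    """
    cfg = cfg or PipelineConfig()
    test_sets = test_sets or {}
    groups = merge_symmetric_labels(
        x_train.conditions, symmetric=(cfg.sym_label, cfg.p53sym_label), merged=cfg.reference
    )
    if model is None:
        x_sig, _, dropped = match_genes(x_train, signature)
        if dropped:
            logger.info("%d signature genes absent from the training matrix", len(dropped))
        model = bga_fit(x_sig, groups=groups, reference=cfg.reference)

    rows = []
    pvalues = {}
    train_sub = x_train.subset_genes(model.gene_ids)
    coords = project(model, train_sub)
    labels = classify(model, coords)
    for s in x_train.sample_ids:
        rows.append(
            {"dataset": "train", "sample_id": s, "condition": str(x_train.conditions[s]),
             "coordinate": coords[s], "label": labels[s]}
        )
    a = coords[groups[groups != cfg.reference].index]
    b = coords[groups[groups == cfg.reference].index]
    pvalues["train"] = separation_pvalue(a, b)[1]

    for name, ts in test_sets.items():
        coords_t = project(model, ts)
        labels_t = classify(model, coords_t)
        conds = ts.conditions if ts.conditions is not None else pd.Series("", index=ts.sample_ids)
        for s in ts.sample_ids:
            rows.append(
                {"dataset": name, "sample_id": s, "condition": str(conds[s]),
                 "coordinate": coords_t[s], "label": labels_t[s]}
            )
        levels = sorted(set(conds))
        if len(levels) == 2:
            pvalues[name] = separation_pvalue(
                coords_t[conds == levels[0]], coords_t[conds == levels[1]]
            )[1]
    return model, pd.DataFrame(rows), pvalues


def run_uniqueness(
    x_train: ExpressionMatrix,
    signature: GeneSet,
    cfg: PipelineConfig | None = None,
    test_a: ExpressionMatrix | None = None,
    test_b: ExpressionMatrix | None = None,
) -> dict:
    """Random-subset uniqueness evaluation (JSON-ready summary).

    Draws ``cfg.n_draws`` subsets of ``cfg.subset_size`` genes from the
    training universe, evaluates the discrimination p of each, and reports
    the signature's percentile, the enrichment table, and — when both test
    sets are given — the relative-separation summary.
    """
    cfg = cfg or PipelineConfig()
    universe = GeneSet("universe", frozenset(x_train.gene_ids))
    groups = merge_symmetric_labels(
        x_train.conditions, symmetric=(cfg.sym_label, cfg.p53sym_label), merged=cfg.reference
    )
    subsets = sample_subsets(universe, cfg.subset_size, cfg.n_draws, seed=cfg.seed)
    dist = evaluate_subsets(
        x_train, groups, subsets, signature=signature, reference=cfg.reference, seed=cfg.seed
    )
    count_better, percentile = percentile_rank(dist)
    enrich = enrichment_vs_chance(dist, signature, universe)
    out = {
        "n_draws": cfg.n_draws,
        "subset_size": cfg.subset_size,
        "seed": cfg.seed,
        "signature_p": dist.signature_p,
        "count_better": count_better,
        "percentile": percentile,
        "null_p_median": float(np.median(dist.pvalues)),
        "enrichment": [
            {"k": int(k), "observed": int(r["observed"]), "expected": float(r["expected"])}
            for k, r in enrich.iterrows()
        ],
        "reproducibility": _repro_block(cfg, "uniqueness", {"training": _digest(x_train)}),
    }
    if test_a is not None and test_b is not None:
        rel, rel_summary = relative_separation(
            x_train, groups, test_a, test_b, subsets, reference=cfg.reference
        )
        hist_edges = [-np.inf, 0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, np.inf]
        counts, _ = np.histogram(rel.to_numpy(), bins=hist_edges)
        rel_summary["histogram"] = {
            "edges": ["<0", "0-0.25", "0.25-0.5", "0.5-0.75", "0.75-1", "1-1.5", "1.5-2", ">2"],
            "counts": [int(c) for c in counts],
        }
        out["relative_separation"] = rel_summary
    return out
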