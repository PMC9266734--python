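"""End-to-end orchestration: simulate/load -> quantify -> comparability ->
differential expression -> pair screen -> survival screen, with a JSON
reproducibility manifest.

The pipeline is a pure function of (inputs, config, seed): identical
inputs produce byte-identical result files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import json

from .datatypes import AnalysisConfig, CtTable, SampleAnnotation
from . import io as pio
from . import quant, de, pairs as pairs_mod, surv
from .errors import StageError
from .simulate import (
    MIRNA_REFERENCES,
    SimulationConfig,
    paper_shape_config,
    simulate_cohort,
)

logger = logging.getLogger("penmark")

__all__ = ["run_pipeline"]


def _stage(name, timings, fn, *args, **kwargs):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        out = fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(name, str(exc)) from exc
    timings[name] = time.perf_counter() - t0
    logger.info("stage %s: done (%.2fs)", name, timings[name])
    return out


def quantify(
    ct: CtTable,
    ann: SampleAnnotation,
    config: AnalysisConfig,
    refs: list[str] | None = None,
):
    """Quantification stage shared by the CLI and the pipeline.

    Aggregates replicates, applies the detection filter to the mRNA
    panel, selects mRNA references by stability (unless ``refs`` given),
    uses the fixed endogenous miRNA assays on the miRNA side, and returns
    (mrna_expr, mirna_expr, stability, refs_used).
    """
    agg = quant.aggregate_replicates(ct)
    filt = quant.apply_ct_filter(
        agg, threshold=config.ct_filter_threshold, scope={"mrna_target"}
    )
    candidates = filt.assays_of_class("endogenous_candidate")
    stability = None
    if refs is None:
        stability = quant.normfinder_stability(filt, candidates, ann)
        refs = quant.select_reference_genes(stability, k=2)
    mirna_refs = filt.assays_of_class("endogenous_fixed") or list(MIRNA_REFERENCES)

    mrna_rows = filt.data["assay_class"].isin(["mrna_target", "endogenous_candidate"])
    mirna_rows = filt.data["assay_class"].isin(["mirna_target", "endogenous_fixed"])
    mrna_ct = CtTable(filt.data[mrna_rows].copy(), aggregated=True)
    mirna_ct = CtTable(filt.data[mirna_rows].copy(), aggregated=True)
    mrna_expr = quant.compute_neg_delta_ct(mrna_ct, refs)
    mirna_expr = quant.compute_neg_delta_ct(mirna_ct, mirna_refs)
    # the non-selected endogenous candidates are normalisation controls,
    # not biomarker targets
    drop = [c for c in mrna_expr.targets if c in set(candidates)]
    if drop:
        mrna_expr.values = mrna_expr.values.drop(columns=drop)
    return mrna_expr, mirna_expr, stability, refs


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    ct_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    preset: str | None = None,
    sim_config: SimulationConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run every stage and write result tables plus a manifest.

    Inputs are either file paths (``ct_path`` + ``annotation_path``) or a
    simulation (``preset="paper-shape"`` or an explicit ``sim_config``).
    Returns the manifest dict; any stage failure raises
    :class:`StageError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig(seed=seed)
    timings: dict[str, float] = {}
    inputs: list = []

    if ct_path is not None:
        ct, ann = _stage("load", timings, pio.load_dataset, ct_path, annotation_path)
        inputs = [ct_path, annotation_path]
        truth = None
    else:
        if sim_config is None:
            if preset not in (None, "paper-shape"):
                raise StageError("simulate", f"unknown preset {preset!r}")
            sim_config = paper_shape_config(seed=seed)
        ct, ann, truth = _stage("simulate", timings, simulate_cohort, sim_config)
        pio.save_ct_table(ct, out_dir / "ct.tsv")
        pio.save_annotation(ann, out_dir / "annotation.tsv")
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth.to_jsonable(), indent=2, sort_keys=True, default=str)
            + "\n"
        )

    mrna_expr, mirna_expr, stability, refs = _stage(
        "quant", timings, quantify, ct, ann, config
    )
    pio.write_results(mrna_expr.values.reset_index(), out_dir / "expr_mrna.tsv")
    pio.write_results(mirna_expr.values.reset_index(), out_dir / "expr_mirna.tsv")

    def _table1():
        variables = [
            de.VariableSpec(c, "binary")
            for c in ann.covariates
            if set(ann.data[c].dropna().unique()) <= {0, 1}
        ]
        split = ann.group
        return de.cohort_comparability(ann, split, variables)

    table1 = _stage("table1", timings, _table1)
    pio.write_results(table1, out_dir / "table1.tsv")

    def _de():
        frames = []
        for label, expr in (("mrna", mrna_expr), ("mirna", mirna_expr)):
            d = de.differential_expression(
                expr, ann, alpha=config.de_alpha, variant=config.t_test_variant
            )
            d.insert(0, "panel", label)
            frames.append(d)
        import pandas as pd

        return pd.concat(frames, ignore_index=True)

    de_table = _stage("de", timings, _de)
    pio.write_results(de_table, out_dir / "de.tsv")

    def _auc():
        import pandas as pd

        frames = []
        for label, expr in (("mrna", mrna_expr), ("mirna", mirna_expr)):
            a = de.marker_auc_table(expr, ann)
            a.insert(0, "panel", label)
            frames.append(a)
        return pd.concat(frames, ignore_index=True)

    auc_table = _stage("marker_auc", timings, _auc)
    pio.write_results(auc_table, out_dir / "marker_auc.tsv")

    pair_table = _stage(
        "pairs",
        timings,
        pairs_mod.screen_pairs,
        mrna_expr,
        mirna_expr,
        ann,
        config.pair_screen_alpha,
        config.pair_auc_cutoff,
        config.correlation_class_alpha,
        config.pair_score_mode,
    )
    pio.write_results(pair_table, out_dir / "pairs.tsv")

    def _survival():
        import pandas as pd

        frames = []
        for endpoint in ("css", "os"):
            res = surv.survival_marker_screen(mrna_expr, ann, endpoint=endpoint)
            res += surv.survival_marker_screen(mirna_expr, ann, endpoint=endpoint)
            frames.append(surv.survival_results_table(res))
        return pd.concat(frames, ignore_index=True)

    surv_table = _stage("survival", timings, _survival)
    pio.write_results(surv_table, out_dir / "surv.tsv")

    outputs = [
        out_dir / p
        for p in (
            "expr_mrna.tsv", "expr_mirna.tsv", "table1.tsv", "de.tsv",
            "marker_auc.tsv", "pairs.tsv", "surv.tsv",
        )
    ]
    cfg_snapshot = asdict(config)
    if sim_config is not None:
        cfg_snapshot["simulation"] = {
            k: v for k, v in asdict(sim_config).items()
        }
    cfg_snapshot["normalization_refs_mrna"] = list(refs)
    manifest = pio.write_manifest(
        out_dir / "manifest.json",
        cfg_snapshot,
        seed,
        inputs,
        outputs,
        timings,
    )
    return manifest
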