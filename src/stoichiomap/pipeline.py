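"""End-to-end orchestration: simulate/ingest -> preprocess -> discriminant
analysis -> correspondence -> network -> structure comparison -> annotations.

``run_pipeline`` takes one flat configuration mapping, executes every stage
in order with per-stage seeds, optionally writes each intermediate artifact
as TSV/JSON, and returns a machine-readable report containing the
cross-validation errors and permutation p-value, SCG sizes, centrality and
generality summaries, csLE eigenvalues, the Theta closeness score and null
percentile, and the annotation tests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations as ann
from . import comparison as cmp
from .correspondence import loocv
from .datasets import GeneratorConfig, make_annotations, make_conditions, make_proteome, make_spectra
from .lda import ConditionLDA, condition_means, growth_rate_correlation
from .network import CosineLaplacianEmbedding, cosine_matrix, extract_scgs, generality
from .preprocess import SpectraPreprocessor, SpectraSet

__all__ = ["run_pipeline", "validate_inputs", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1
logger = logging.getLogger("stoichiomap")

DEFAULT_CONFIG: dict = {
    "n_axes": 4,
    "threshold": 0.995,
    "n_permutations": 1000,
    "null_draws": 1000,
    "enrichment_strength": 0.5,
    "sg_window": 11,
    "sg_polyorder": 3,
    "band": (700.0, 1800.0),
    "seed": 0,
    "generator": {},
    "inputs": {},  # optional paths: proteome, spectra, conditions, annotations
    "outdir": None,
}


def validate_inputs(
    proteome: pd.DataFrame | None = None,
    spectra: SpectraSet | None = None,
    conditions: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Shape/consistency checks; returns {'fatal': [...], 'warnings': [...]}."""
    fatal, warnings_ = [], []
    if proteome is not None:
        X = proteome.to_numpy(dtype=float)
        neg = np.argwhere(X < 0)
        if neg.size:
            i, j = neg[0]
            fatal.append(
                f"negative abundance at row {proteome.index[i]!r}, "
                f"column {proteome.columns[j]!r}"
            )
        zero = np.flatnonzero((X != 0).sum(axis=1) == 0)
        if zero.size:
            warnings_.append(
                f"{zero.size} all-zero protein rows (first: {proteome.index[zero[0]]!r}); "
                "they are inadmissible for cosine analysis"
            )
        if not np.all(np.isfinite(X)):
            fatal.append("proteome contains non-finite values")
    if conditions is not None:
        if conditions["condition_id"].duplicated().any():
            fatal.append("duplicate condition ids")
        if (conditions["growth_rate"] < 0).any() or not np.all(
            np.isfinite(conditions["growth_rate"])
        ):
            fatal.append("growth rates must be finite and non-negative")
        if proteome is not None and list(proteome.columns) != list(
            conditions["condition_id"]
        ):
            fatal.append("proteome columns do not match the condition table order")
    if spectra is not None and conditions is not None:
        missing = set(np.unique(spectra.condition)) - set(conditions["condition_id"])
        if missing:
            fatal.append(f"spectra conditions not in the condition table: {sorted(missing)}")
    if annotations is not None and proteome is not None:
        unmatched = annotations.index.difference(proteome.index)
        if len(unmatched):
            warnings_.append(
                f"{len(unmatched)} annotation ids do not join to the proteome "
                f"({len(annotations)} total)"
            )
    return {"fatal": fatal, "warnings": warnings_}


def _load_or_simulate(config: dict):
    inputs = config.get("inputs") or {}
    if inputs:
        for key in ("proteome", "spectra", "conditions"):
            if key not in inputs:
                raise ValueError(f"inputs requires a {key!r} path")
            if not Path(inputs[key]).exists():
                raise FileNotFoundError(f"{key} path does not exist: {inputs[key]}")
        proteome = pd.read_csv(inputs["proteome"], sep="\t", index_col=0)
        conditions = pd.read_csv(inputs["conditions"], sep="\t")
        spectra = SpectraSet.from_tsv(inputs["spectra"])
        annotations = (
            pd.read_csv(inputs["annotations"], sep="\t", index_col=0)
            if "annotations" in inputs
            else None
        )
        truth = None
    else:
        gen = dict(config.get("generator") or {})
        gen.setdefault("seed", config["seed"])
        cfg = GeneratorConfig(**gen)
        conditions = make_conditions(
            cfg.m_conditions, cfg.growth_rate_range, cfg.seed, cfg.replicates
        )
        proteome, truth = make_proteome(cfg, conditions)
        spectra = make_spectra(proteome, truth, cfg)
        annotations = make_annotations(
            truth, config["enrichment_strength"], seed=cfg.seed + 2
        )
    return proteome, spectra, conditions, annotations, truth


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full analysis under one configuration; return the report."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(cfg["outdir"]) if cfg["outdir"] else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage=load/simulate")
    proteome, spectra, conditions, annotations, truth = _load_or_simulate(cfg)
    issues = validate_inputs(proteome, spectra, conditions, annotations)
    if issues["fatal"]:
        raise ValueError(f"stage=validate failed: {issues['fatal']}")

    logger.info("stage=preprocess shapes=%s", spectra.intensities.shape)
    pre = SpectraPreprocessor(
        sg_window=cfg["sg_window"], sg_polyorder=cfg["sg_polyorder"], band=tuple(cfg["band"])
    )
    processed = pre.transform(spectra)

    logger.info("stage=lda cells=%d channels=%d", *processed.intensities.shape)
    lda = ConditionLDA().fit(processed.intensities, processed.condition)
    scores = lda.transform(processed.intensities)
    cond_order = conditions["condition_id"].to_numpy()
    R_hat = condition_means(scores, processed.condition, cond_order)
    corr = growth_rate_correlation(R_hat[:, 0], conditions["growth_rate"].to_numpy())

    logger.info("stage=correspondence K=%d", cfg["n_axes"])
    P_hat = proteome.to_numpy(dtype=float).T
    report_loocv = loocv(
        P_hat,
        R_hat,
        n_axes=cfg["n_axes"],
        metrics=("euclidean_sq",),
        n_permutations=cfg["n_permutations"],
        seed=cfg["seed"] + 10,
    )

    logger.info("stage=network threshold=%s", cfg["threshold"])
    graph = cosine_matrix(proteome)
    scgs = extract_scgs(graph, cfg["threshold"])
    g = generality(proteome)
    emb = CosineLaplacianEmbedding().fit(proteome)

    logger.info("stage=comparison")
    theta = cmp.theta_from_dataset(proteome, scores, processed.condition, cond_order)
    theta_rep = cmp.theta_report(theta, n_null=cfg["null_draws"], seed=cfg["seed"] + 20)
    mu = conditions.set_index("condition_id")["growth_rate"]
    argmax_cond = proteome.idxmax(axis=1)
    prop = cmp.d_g_proportionality(
        graph.degree, g.to_numpy(), proteome.shape[1], mu.loc[argmax_cond].to_numpy()
    )

    annotation_report = {}
    if annotations is not None:
        joined = annotations.reindex(proteome.index).dropna()
        d_joined = pd.Series(graph.degree, index=proteome.index).loc[joined.index]
        curve = ann.binned_fraction_curve(
            d_joined.to_numpy(), joined["essential"].to_numpy(dtype=bool)
        )
        qc = ann.quartile_comparison(
            d_joined.to_numpy(), joined["ortholog_count"].to_numpy(dtype=float)
        )
        annotation_report = {
            "essential_fraction_by_bin": curve["fraction"].tolist(),
            "ortholog_quartile_tests": {
                k: {"statistic": v.statistic, "pvalue": v.pvalue, "estimate": v.estimate}
                for k, v in qc.items()
            },
        }

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg["seed"],
        "n_proteins": int(proteome.shape[0]),
        "n_conditions": int(proteome.shape[1]),
        "n_cells": int(processed.n_cells),
        "lda": {
            "n_axes": int(lda.n_axes_),
            "eigenvalues": lda.eigenvalues_.tolist(),
            "growth_rate_correlation": {"r": corr.r, "abs_r": corr.abs_r, "p": corr.pvalue},
        },
        "loocv": {
            "n_axes": report_loocv.n_axes,
            "overall_error": report_loocv.overall,
            "permutation_p": report_loocv.permutation_p,
            "n_permutations": report_loocv.n_permutations,
        },
        "scg_sizes": [int(len(c)) for c in scgs],
        "centrality": {
            "min": float(graph.degree.min()),
            "median": float(np.median(graph.degree)),
            "max": float(graph.degree.max()),
        },
        "generality": {
            "min": float(g.min()),
            "median": float(g.median()),
            "max": float(g.max()),
        },
        "csle_eigenvalues": emb.eigenvalues_.tolist(),
        "theta": {
            "closeness": theta_rep.closeness,
            "null_percentile": theta_rep.percentile,
            "n_null": int(theta_rep.null_scores.size),
        },
        "d_g": {
            "slope": prop.slope,
            "residual_spearman_r": prop.spearman_r,
            "residual_spearman_p": prop.spearman_p,
        },
        "annotations": annotation_report,
        "validation_warnings": issues["warnings"],
    }

    if outdir:
        proteome.to_csv(outdir / "proteome.tsv", sep="\t")
        conditions.to_csv(outdir / "conditions.tsv", sep="\t", index=False)
        processed.to_tsv(outdir / "spectra_preprocessed.tsv")
        pd.DataFrame(
            scores, columns=[f"LDA{k + 1}" for k in range(scores.shape[1])]
        ).assign(condition=processed.condition).to_csv(
            outdir / "lda_scores.tsv", sep="\t", index=False
        )
        per_protein = pd.DataFrame(
            {
                "centrality": graph.degree,
                "generality": g.to_numpy(),
                "scg_rank": _scg_rank(proteome.index, scgs),
            },
            index=proteome.index,
        )
        per_protein = pd.concat(
            [
                per_protein,
                pd.DataFrame(
                    emb.embedding_,
                    index=proteome.index,
                    columns=[f"csLE{k + 1}" for k in range(emb.embedding_.shape[1])],
                ),
            ],
            axis=1,
        )
        per_protein.to_csv(outdir / "protein_scores.tsv", sep="\t")
        if truth is not None:
            truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        if annotations is not None:
            annotations.to_csv(outdir / "annotations.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _scg_rank(index: pd.Index, scgs) -> np.ndarray:
    rank = np.zeros(len(index), dtype=int)  # 0 = not in any SCG
    pos = {pid: i for i, pid in enumerate(index)}
    for r, members in enumerate(scgs, start=1):
        for pid in members:
            rank[pos[pid]] = r
    return rank
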