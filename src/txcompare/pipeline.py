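"""End-to-end orchestration: bootstrap -> DE -> non-DEG/DEG -> DTU -> non-DEG^DTU- -> coverage -> QC.

One comparison is run per (model_label, time_point) of the test samples
against the full control group, matching a design where each in vitro model
and time point is compared individually to the reference. All stage outputs
are written as TSV files plus a JSON run log echoing the configuration;
the run is deterministic given identical inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coverage import coverage_matrix
from .data_model import (
    GeneCountMatrix,
    IsoformTable,
    SampleTable,
    read_gene_counts,
    read_gene_sets,
    read_isoform_quant,
    read_sample_table,
)
from .de import run_de
from .dtu import derive_nondeg_dtu_minus, run_dtu
from .nondeg import bootstrap_select_replicates, make_call_set
from .qc import spearman_matrix, variation_coefficient

logger = logging.getLogger("txcompare")

__all__ = ["PipelineConfig", "ComparisonResult", "run_comparison"]

DEFAULT_THRESHOLDS = {
    "alpha_de": 0.05,
    "basemean_min": 10.0,
    "lfc_flag": 1.0,
    "cpm_floor": 1.0,
    "delta_pct": 10.0,
    "max_missing_frac": 0.2,
    "small_n": 5,
    "alpha_dtu": 0.01,
    "k_replicates": 3,
    "coverage_mode": "gene",
    "strip_id_version": False,
    "allow_fewer_replicates": False,
    "bootstrap": True,
}


@dataclass
class PipelineConfig:
    sample_sheet: str
    gene_counts: str | list
    isoform_counts: str | list | None = None
    gene_sets: str | None = None
    node_map: str | None = None
    counts_dialect: str = "matrix"
    isoform_dialect: str = "matrix_pair"
    isoform_pct: str | None = None
    out_dir: str = "txcompare_out"
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "sample_sheet": self.sample_sheet,
            "gene_counts": self.gene_counts,
            "isoform_counts": self.isoform_counts,
            "gene_sets": self.gene_sets,
            "node_map": self.node_map,
            "counts_dialect": self.counts_dialect,
            "isoform_dialect": self.isoform_dialect,
            "isoform_pct": self.isoform_pct,
            "out_dir": self.out_dir,
            "thresholds": self.thresholds,
        }


@dataclass
class ComparisonResult:
    comparison_id: str
    selected_replicates: tuple
    n_non_degs: int
    n_degs: int
    n_dtu: int
    n_non_deg_dtu_minus: int
    out_dir: Path


def _comparison_sheet(samples: SampleTable, test_ids: list) -> SampleTable:
    keep = samples.frame[
        (samples.frame["group"] == "control") | samples.frame["sample_id"].isin(test_ids)
    ]
    return SampleTable(keep.copy())


def run_comparison(config: PipelineConfig | str | Path) -> list:
    """Run the full pipeline for every (model, time point) in the sample sheet."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    t = config.thresholds

    # fail before any computation when inputs are missing
    input_paths = [config.sample_sheet]
    for entry in (config.gene_counts, config.isoform_counts):
        if entry is None:
            continue
        input_paths.extend(entry if isinstance(entry, list) else [entry])
    for entry in (config.gene_sets, config.node_map, config.isoform_pct):
        if entry is not None:
            input_paths.append(entry)
    missing = [p for p in input_paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    samples = read_sample_table(config.sample_sheet)
    matrix = read_gene_counts(
        config.gene_counts,
        dialect=config.counts_dialect,
        sample_table=samples,
        strip_id_version=t["strip_id_version"],
    )
    iso = None
    if config.isoform_counts is not None:
        iso = read_isoform_quant(
            config.isoform_counts,
            dialect=config.isoform_dialect,
            pct_path=config.isoform_pct,
            strip_id_version=t["strip_id_version"],
        )
    gene_sets = None
    if config.gene_sets is not None:
        gene_sets = read_gene_sets(config.gene_sets, node_map=config.node_map)

    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    control_ids = samples.control_ids
    tests = samples.frame[samples.frame["group"] == "test"]
    comparisons = sorted(set(zip(tests["model_label"], tests["time_point_h"])))

    results: list[ComparisonResult] = []
    nondeg_lists: dict = {}
    dtu_minus_lists: dict = {}

    for model_label, time_point in comparisons:
        comp_id = f"{model_label}_{time_point:03d}h"
        comp_dir = out_root / comp_id
        comp_dir.mkdir(parents=True, exist_ok=True)
        replicate_ids = tests.loc[
            (tests["model_label"] == model_label) & (tests["time_point_h"] == time_point),
            "sample_id",
        ].tolist()

        if t["bootstrap"] and len(replicate_ids) > t["k_replicates"]:
            boot = bootstrap_select_replicates(
                matrix,
                control_ids,
                replicate_ids,
                k=t["k_replicates"],
                allow_fewer=t["allow_fewer_replicates"],
                alpha=t["alpha_de"],
                basemean_min=t["basemean_min"],
                model_label=model_label,
                time_point_h=time_point,
            )
            boot.write(comp_dir / "bootstrap.tsv")
            selected = boot.selected
        else:
            if len(replicate_ids) < t["k_replicates"] and not (
                t["allow_fewer_replicates"] and len(replicate_ids) == t["k_replicates"] - 1
            ):
                raise ValueError(
                    f"{comp_id}: {len(replicate_ids)} replicates but k={t['k_replicates']}"
                )
            selected = tuple(sorted(replicate_ids))

        comp_samples = _comparison_sheet(samples, list(selected))
        logger.info("%s: selected replicates %s", comp_id, selected)

        de_result = run_de(matrix, comp_samples)
        de_result.write(comp_dir / "de_results.tsv")
        calls = make_call_set(
            de_result, comp_id, t["alpha_de"], t["basemean_min"], t["lfc_flag"]
        )
        _write_gene_list(de_result, calls.non_degs, comp_dir / "non_degs.tsv")
        _write_gene_list(de_result, calls.degs, comp_dir / "degs.tsv", calls.directions)

        n_dtu = 0
        dtu_minus = calls.non_degs
        if iso is not None:
            dtu_calls, trace = run_dtu(
                iso,
                comp_samples,
                cpm_floor=t["cpm_floor"],
                delta_pct=t["delta_pct"],
                max_missing_frac=t["max_missing_frac"],
                small_n=t["small_n"],
                alpha=t["alpha_dtu"],
            )
            dtu_calls.write(comp_dir / "dtu_genes.tsv")
            trace.write(comp_dir / "filter_trace.tsv")
            dtu_minus = derive_nondeg_dtu_minus(calls.non_degs, dtu_calls)
            n_dtu = len(dtu_calls.dtu_genes)
            assert dtu_minus <= calls.non_degs
        _write_gene_list(de_result, dtu_minus, comp_dir / "non_degs_dtu_minus.tsv")

        nondeg_lists[comp_id] = calls.non_degs
        dtu_minus_lists[comp_id] = dtu_minus
        results.append(
            ComparisonResult(
                comp_id,
                tuple(selected),
                len(calls.non_degs),
                len(calls.degs),
                n_dtu,
                len(dtu_minus),
                comp_dir,
            )
        )

    if gene_sets is not None and nondeg_lists:
        coverage_matrix(nondeg_lists, gene_sets, t["coverage_mode"]).to_csv(
            out_root / "coverage_non_degs.tsv", sep="\t"
        )
        coverage_matrix(dtu_minus_lists, gene_sets, t["coverage_mode"]).to_csv(
            out_root / "coverage_non_degs_dtu_minus.tsv", sep="\t"
        )

    corr = spearman_matrix(matrix)
    corr.to_csv(out_root / "spearman.tsv", sep="\t")
    cv_rows = []
    for model_label in sorted(set(tests["model_label"])):
        cv = variation_coefficient(corr, samples, model_label)
        cv_rows.append({"model_label": model_label, "variation_coefficient_pct": cv})
    pd.DataFrame(cv_rows).to_csv(out_root / "variation_coefficients.tsv", sep="\t", index=False)

    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True, default=str)
    run_log = {
        "version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "comparisons": [
            {
                "comparison_id": r.comparison_id,
                "selected_replicates": list(r.selected_replicates),
                "n_non_degs": r.n_non_degs,
                "n_degs": r.n_degs,
                "n_dtu": r.n_dtu,
                "n_non_deg_dtu_minus": r.n_non_deg_dtu_minus,
            }
            for r in results
        ],
    }
    with open(out_root / "run_log.json", "w", encoding="utf-8") as handle:
        json.dump(run_log, handle, indent=2, default=str)
    return results


def _write_gene_list(de_result, genes: set, path: Path, directions: dict | None = None) -> None:
    frame = de_result.frame.loc[sorted(genes), ["padj", "baseMean", "log2FoldChange"]].copy()
    if directions is not None:
        frame["direction"] = [directions.get(g, "") for g in frame.index]
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")
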