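"""End-to-end pipeline: expression -> enrichment -> class-wise tests ->
joint fold-change report, driven by a flat key-value YAML config.

Config keys::

    annotation            gene annotation (GTF or BED6/BED12)
    counts                TSV count table (gene_id, length, sample columns)
    samples               TSV sample sheet (sample_id, genotype)
    genotype_ref          reference genotype label (e.g. XY)
    genotype_test         test genotype label
    reads_<mark>_<chip|input>_<genotype>   BED read libraries
    de_threshold          fold-change cut for the DE lists (default 1.5)
    test_threshold        fold-change cut defining the tested classes (3.0)
    fc_pseudocount        FPKM pseudocount for fold change (0.1)
    rpm_pseudocount       read pseudocount for RPM (0.5)
    flank                 promoter flank in bp (2000)
    profile_window        metagene window in bp (2000)
    profile_bins          metagene bin count (100)
    gene_subset           optional comma-separated gene ids for the joint table
    seed                  recorded in the manifest

All outputs are TSV with fixed column order and ``%.10g`` floats, so a rerun
with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    enrichment_fold_change_table,
    gene_enrichment_table,
    metagene_profile,
    profile_frame,
)
from .expression import ExpressionTable, read_count_table, read_sample_sheet
from .genome import MARKS, read_alignments_bed, read_gene_annotation
from .integrate import joint_fold_change, mark_vs_expression_test

__all__ = ["load_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"
_FRACTIONS = ("chip", "input")

_DEFAULTS: dict[str, object] = {
    "de_threshold": 1.5,
    "test_threshold": 3.0,
    "fc_pseudocount": 0.1,
    "rpm_pseudocount": 0.5,
    "flank": 2000,
    "profile_window": 2000,
    "profile_bins": 100,
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A pipeline input is missing or inconsistent."""


def load_config(source) -> dict:
    """Load a flat YAML config from a path or mapping."""
    if isinstance(source, Mapping):
        config = dict(source)
    else:
        with open(source, "rt") as fh:
            config = yaml.safe_load(fh)
        if not isinstance(config, dict):
            raise PipelineError(f"{source}: config must be a flat mapping")
    for key, value in _DEFAULTS.items():
        config.setdefault(key, value)
    return config


def _library_keys(config: Mapping) -> list[tuple[str, str, str, str]]:
    keys = []
    for mark in MARKS:
        for fraction in _FRACTIONS:
            for genotype in (config["genotype_ref"], config["genotype_test"]):
                keys.append((f"reads_{mark}_{fraction}_{genotype}", mark, fraction, genotype))
    return keys


def _check_inputs(config: Mapping) -> None:
    required = ["annotation", "counts", "samples", "genotype_ref", "genotype_test"]
    missing_keys = [k for k in required if k not in config]
    if missing_keys:
        raise PipelineError(f"config missing required keys: {missing_keys}")
    paths = [("annotation", config["annotation"]), ("counts", config["counts"]),
             ("samples", config["samples"])]
    lib_keys = [k for k, *_ in _library_keys(config)]
    absent = [k for k in lib_keys if k not in config]
    if absent:
        raise PipelineError(f"config missing read libraries: {absent}")
    paths += [(k, config[k]) for k in lib_keys]
    missing = [f"{key}={path}" for key, path in paths if not Path(str(path)).exists()]
    if missing:
        raise PipelineError(f"input files not found: {missing}")


def _config_hash(config: Mapping) -> str:
    canon = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config, outdir) -> dict:
    """Run every stage and write the report bundle to ``outdir``.

    Returns a dict with the in-memory results: ``expression`` (fold-change
    table), ``enrichment`` per (mark, genotype), ``tests`` per mark,
    ``joint`` table, and ``profiles``.  All inputs are validated before any
    computation starts; a count table whose gene set differs from the
    annotation is rejected.
    """
    config = load_config(config)
    _check_inputs(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genotype_ref = str(config["genotype_ref"])
    genotype_test = str(config["genotype_test"])
    de_threshold = float(config["de_threshold"])
    test_threshold = float(config["test_threshold"])

    genes = read_gene_annotation(config["annotation"])
    counts, lengths = read_count_table(config["counts"])
    sample_genotypes = read_sample_sheet(config["samples"])

    annotated = {g.gene_id for g in genes}
    if annotated != set(counts.index):
        raise PipelineError(
            f"gene universe mismatch between {config['annotation']} and "
            f"{config['counts']}: {len(annotated)} annotated vs "
            f"{len(counts.index)} counted genes"
        )

    # expression stage
    table = ExpressionTable(counts, lengths, sample_genotypes)
    fc = table.fold_changes(
        genotype_test,
        genotype_ref,
        pseudocount=float(config["fc_pseudocount"]),
        threshold=de_threshold,
    )
    fc_test = table.fold_changes(
        genotype_test,
        genotype_ref,
        pseudocount=float(config["fc_pseudocount"]),
        threshold=test_threshold,
    )
    expr_out = pd.DataFrame(
        {
            f"fpkm_{genotype_ref}": table.genotype_fpkm(genotype_ref),
            f"fpkm_{genotype_test}": table.genotype_fpkm(genotype_test),
            "fc": fc.fc,
            "log2fc": fc.log2fc,
            "de_class": fc.de_class,
        }
    )
    expr_out.index.name = "gene_id"
    _write_tsv(expr_out, outdir / "expression.tsv")
    for cls in ("up", "down"):
        pd.Series(fc.de_genes(cls), name="gene_id").to_csv(
            outdir / f"de_{cls}_{de_threshold:g}x.tsv", sep="\t", index=False
        )
        pd.Series(fc_test.de_genes(cls), name="gene_id").to_csv(
            outdir / f"de_{cls}_{test_threshold:g}x.tsv", sep="\t", index=False
        )

    # enrichment stage
    flank = int(config["flank"])
    rpm_pc = float(config["rpm_pseudocount"])
    enrich: dict[tuple[str, str], pd.DataFrame] = {}
    profiles: dict[tuple[str, str], pd.DataFrame] = {}
    for mark in MARKS:
        for genotype in (genotype_ref, genotype_test):
            chip = read_alignments_bed(
                config[f"reads_{mark}_chip_{genotype}"], unique_only=True
            )
            inp = read_alignments_bed(
                config[f"reads_{mark}_input_{genotype}"], unique_only=True
            )
            tab = gene_enrichment_table(
                genes, chip, inp, mark, genotype, flank=flank, pseudocount=rpm_pc
            )
            enrich[(mark, genotype)] = tab
            _write_tsv(tab, outdir / f"enrichment_{mark}_{genotype}.tsv")
            prof = metagene_profile(
                chip,
                genes,
                mode="tss_centered" if mark == MARKS[0] else "scaled_body",
                window=int(config["profile_window"]),
                n_bins=int(config["profile_bins"]),
            )
            pf = profile_frame(prof)
            profiles[(mark, genotype)] = pf
            _write_tsv(pf, outdir / f"profile_{mark}_{genotype}.tsv", index=False)

    # integration stage: Welch tests within classes at the test threshold
    tests: dict[str, dict] = {}
    test_rows = []
    for mark in MARKS:
        res = mark_vs_expression_test(
            enrich[(mark, genotype_ref)]["enrichment"],
            enrich[(mark, genotype_test)]["enrichment"],
            fc_test.de_class,
        )
        tests[mark] = res
        for cls, r in res.items():
            test_rows.append(
                {
                    "mark": mark,
                    "de_class": cls,
                    "t": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "n_ref": r.n1,
                    "n_test": r.n2,
                    "mean_log2_ref": r.mean_a,
                    "mean_log2_test": r.mean_b,
                }
            )
    _write_tsv(pd.DataFrame(test_rows), outdir / "mark_tests.tsv", index=False)

    # joint fold-change table
    k4_fc = enrichment_fold_change_table(
        enrich[(MARKS[0], genotype_test)], enrich[(MARKS[0], genotype_ref)]
    )
    k27_fc = enrichment_fold_change_table(
        enrich[(MARKS[1], genotype_test)], enrich[(MARKS[1], genotype_ref)]
    )
    subset = config.get("gene_subset")
    if isinstance(subset, str):
        subset = [s for s in subset.split(",") if s]
    joint = joint_fold_change(fc, k4_fc, k27_fc, gene_subset=subset)
    _write_tsv(joint, outdir / "joint_fold_change.tsv")

    # run manifest
    versions = {
        "markgene": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(outdir / "manifest.txt", "wt") as fh:
        for k, v in versions.items():
            fh.write(f"version_{k}\t{v}\n")
        fh.write(f"config_hash\t{_config_hash(config)}\n")
        fh.write(f"seed\t{config['seed']}\n")
        fh.write(f"n_genes\t{len(genes)}\n")
        fh.write(f"de_threshold\t{de_threshold:g}\n")
        fh.write(f"test_threshold\t{test_threshold:g}\n")

    return {
        "config": config,
        "expression": fc,
        "expression_test_threshold": fc_test,
        "enrichment": enrich,
        "tests": tests,
        "joint": joint,
        "profiles": profiles,
    }
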