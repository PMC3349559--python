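"""End-to-end orchestration: simulate/load -> clean -> map -> test -> enrich.

All outputs are deterministic text tables; a JSON manifest records the
package version, the seed and every effective parameter.  Randomness flows
exclusively from the single config seed, so rerunning a config reproduces
every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import dge, enrich, refmap, simdata, tagproc

logger = logging.getLogger("tagdge")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_DEFAULT_PARAMS = {
    "max_mismatch": 1,
    "min_copy": 2,
    "fdr_threshold": 0.001,
    "log2_threshold": 1.0,
    "extreme_threshold": 10.0,
    "cluster_k": 4,
    "alpha": 0.05,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``design`` (synthetic mode: libraries are simulated) or
    ``reference`` + ``libraries`` (paths to FASTA and per-library FASTQ/TSV)
    must be provided.  ``annotation`` may be a TSV path, or ``"synthetic"`` in
    synthetic mode to generate one.
    """

    seed: int = 0
    design: "simdata.SyntheticDesign | None" = None
    reference: "str | None" = None
    libraries: dict[str, str] = field(default_factory=dict)
    annotation: "str | None" = None
    comparisons: "list[tuple[str, str]] | None" = None
    params: dict = field(default_factory=lambda: dict(_DEFAULT_PARAMS))

    def __post_init__(self) -> None:
        if self.design is None and not (self.reference and self.libraries):
            raise ConfigError("config needs either a synthetic design or "
                              "reference + libraries paths")
        unknown = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        merged = dict(_DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key in ("fdr_threshold", "extreme_threshold", "cluster_k", "alpha"):
            if merged[key] <= 0:
                raise ConfigError(f"parameter {key} must be positive")
        if merged["log2_threshold"] < 0:
            raise ConfigError("parameter log2_threshold must be >= 0")
        names = self.library_names
        if len(set(names)) != len(names):
            raise ConfigError("library labels must be unique")
        if self.comparisons is not None:
            for pair in self.comparisons:
                for lib in pair:
                    if lib not in names:
                        raise ConfigError(
                            f"comparison references undeclared library {lib!r}")

    @property
    def library_names(self) -> list[str]:
        if self.design is not None:
            return list(self.design.library_names)
        return list(self.libraries)

    @property
    def comparison_design(self) -> dge.ComparisonDesign:
        if self.comparisons is not None:
            return dge.ComparisonDesign.from_pairs(self.comparisons)
        return dge.ComparisonDesign.default(self.library_names)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        design = raw.pop("design", None)
        if design is not None:
            design = dict(design)
            design.setdefault("seed", seed)
            try:
                design = simdata.SyntheticDesign.from_dict(design)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid design: {exc}") from exc
        comparisons = raw.pop("comparisons", None)
        if comparisons is not None:
            comparisons = [tuple(p) for p in comparisons]
        cfg = cls(seed=seed,
                  design=design,
                  reference=raw.pop("reference", None),
                  libraries=dict(raw.pop("libraries", {}) or {}),
                  annotation=raw.pop("annotation", None),
                  comparisons=comparisons,
                  params=dict(raw.pop("parameters", {}) or {}))
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params

    reference_path, lib_reads, truth = _stage("simulate")(_obtain_inputs)(config, out)
    tables = _stage("clean")(_clean_all)(lib_reads, p, out)
    matrix, ledgers = _stage("map")(_map_all)(reference_path, tables, p, out)
    de_results = _stage("diffexp")(_diffexp)(config, matrix, p, out)
    enrichment = _stage("enrich")(_enrich)(config, truth, de_results, p, out)

    manifest = {
        "tagdge_version": __version__,
        "seed": config.seed,
        "parameters": p,
        "libraries": config.library_names,
        "comparisons": [list(c) for c in
                        ((config.comparisons) or
                         simdata.default_comparisons(config.library_names))],
        "synthetic": config.design is not None,
        "outputs": sorted({f.name for f in out.iterdir() if f.is_file()}
                          | {"manifest.json"}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _obtain_inputs(config: PipelineConfig, out: Path):
    if config.design is not None:
        design = config.design
        records, truth = simdata.make_reference(design)
        reference_path = out / "reference.fasta"
        simdata.write_reference_fasta(records, reference_path)
        simdata.write_truth(truth, out / "truth.tsv")
        with open(out / "design.yaml", "w") as fh:
            yaml.safe_dump(design.to_dict(), fh, sort_keys=True)
        lib_reads: dict[str, list[str]] = {}
        for i, lib in enumerate(design.library_names):
            sim = simdata.simulate_library(truth, i, design)
            simdata.write_fastq(sim.reads, lib, out / f"{lib}.fastq")
            simdata.write_tag_counts(sim.reads, out / f"{lib}.tags.tsv")
            lib_reads[lib] = sim.reads
        return reference_path, lib_reads, truth
    lib_reads = {}
    for lib, path in config.libraries.items():
        path = str(path)
        if path.endswith((".fastq", ".fq")):
            lib_reads[lib] = tagproc.read_fastq_sequences(path)
        else:
            lib_reads[lib] = tagproc.read_tag_counts(path)
    return config.reference, lib_reads, None


def _clean_all(lib_reads, p, out: Path) -> dict[str, tagproc.CleanTagTable]:
    tables = {}
    reports = []
    for lib, reads in lib_reads.items():
        table = tagproc.filter_raw_tags(
            reads, adaptors=(simdata.ADAPTOR_1,),
            min_copy=p["min_copy"], library=lib)
        tagproc.write_clean_table(table, out / f"{lib}.clean.tsv",
                                  out / f"{lib}.ledger.json")
        reports.append(tagproc.report_raw_components(table))
        tables[lib] = table
    pd.concat(reports, ignore_index=True).to_csv(
        out / "raw_components.tsv", sep="\t", index=False)
    return tables


def _map_all(reference_path, tables, p, out: Path):
    index = refmap.build_index(reference_path)
    mappings = {}
    ledger_rows = []
    cov_hists = {}
    for lib, table in tables.items():
        res = refmap.map_tags(table, index, max_mismatch=p["max_mismatch"])
        mappings[lib] = res
        row = {"library": lib, **res.ledger.as_dict()}
        total = max(res.ledger.total_clean, 1)
        for key in ("total_mapped", "perfect_match", "mismatch_match",
                    "unique_match", "multi_position", "unmapped"):
            row[f"{key}_pct"] = round(100.0 * row[key] / total, 2)
        ledger_rows.append(row)
        cov, hist = refmap.coverage_profile(res.placements, index.gene_lengths)
        cov_hists[lib] = hist
    pd.DataFrame(ledger_rows).to_csv(out / "mapping_ledgers.tsv",
                                     sep="\t", index=False)
    pd.DataFrame(cov_hists).rename_axis("coverage_bin").to_csv(
        out / "coverage_hist.tsv", sep="\t")
    clean_totals = {lib: t.total_clean for lib, t in tables.items()}
    matrix = refmap.ExpressionMatrix.from_mappings(
        mappings, clean_totals, index.gene_lengths)
    matrix.to_tsv(out / "counts.tsv")
    matrix.tpm().rename_axis("gene").to_csv(out / "tpm.tsv", sep="\t",
                                            float_format="%.6g")
    return matrix, ledger_rows


def _diffexp(config: PipelineConfig, matrix, p, out: Path):
    design = config.comparison_design
    results = dge.call_de(matrix, design,
                          fdr_threshold=p["fdr_threshold"],
                          log2_threshold=p["log2_threshold"])
    for label, df in results.items():
        df.to_csv(out / f"de_{label}.tsv", sep="\t", float_format="%.6g")
    dge.up_down_summary(results).to_csv(out / "up_down_summary.tsv", sep="\t")
    common = dge.intersect_comparisons(dge.significant_sets(results))
    (out / "intersection.txt").write_text(
        "".join(f"{g}\n" for g in sorted(common)))
    profiles = dge.trend_profiles(results, common)
    up, down = dge.screen_extremes(profiles, threshold=p["extreme_threshold"])
    (out / "extremes_up.txt").write_text("".join(f"{g}\n" for g in sorted(up)))
    (out / "extremes_down.txt").write_text("".join(f"{g}\n" for g in sorted(down)))
    if len(profiles) >= p["cluster_k"]:
        labels, _ = dge.cluster_trends(profiles, k=p["cluster_k"])
        pd.concat([profiles, labels], axis=1).rename_axis("gene").to_csv(
            out / "clusters.tsv", sep="\t", float_format="%.6g")
    return results


def _enrich(config: PipelineConfig, truth, de_results, p, out: Path):
    if config.annotation is None:
        return None
    if config.annotation == "synthetic":
        if truth is None:
            raise ConfigError("synthetic annotation requires synthetic mode")
        annotation = simdata.make_annotation(truth, seed=config.seed)
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    else:
        annotation = pd.read_csv(config.annotation, sep="\t")
    screened = dge.intersect_comparisons(dge.significant_sets(de_results))
    result = enrich.enrich_terms(screened, annotation, alpha=p["alpha"])
    result.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
    return result
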