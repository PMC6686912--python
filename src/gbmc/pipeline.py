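"""End-to-end orchestration: classify -> groups -> compare with a manifest.

A run is described by a :class:`RunConfig` (usually loaded from YAML).
Stages execute in order, each writing TSV outputs into the run's output
directory; a ``manifest.json`` records inputs, parameters, seeds and
SHA-256 checksums of every output so a re-run with the same config can
be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression_stats as es
from . import gbm_classifier as gc
from . import methylome_io as mio
from . import ortholog_groups as og

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "classify_sample"]

log = logging.getLogger("gbmc")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    output_dir: str
    annotation: str
    samples_a: dict[str, str]  # sample name -> allc path
    samples_b: dict[str, str]
    counts_a: str  # counts TSV (gene_id + sample columns)
    counts_b: str
    lengths_a: str  # two-column TSV: gene_id, length
    lengths_b: str
    pairs: str | None = None  # two-column TSV gene_a, gene_b
    blast_ab: str | None = None  # alternative to pairs
    blast_ba: str | None = None
    annotation_format: str = "gff3"
    dialect: str = "allc"
    group_mode: str = "cross"
    classifier: dict = field(default_factory=dict)
    statistics: tuple[str, ...] = ("bootstrap", "wilcoxon", "cohend", "classes")
    compare_groups: tuple[str, ...] = ("Group1", "Group2")
    n_reps: int = 1000
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {"annotation": self.annotation, "counts_a": self.counts_a,
                 "counts_b": self.counts_b, "lengths_a": self.lengths_a,
                 "lengths_b": self.lengths_b}
        for name, p in {**self.samples_a, **self.samples_b}.items():
            paths[f"allc:{name}"] = p
        if self.pairs:
            paths["pairs"] = self.pairs
        else:
            if not (self.blast_ab and self.blast_ba):
                raise PipelineError(
                    "config: need either 'pairs' or both 'blast_ab'/'blast_ba'"
                )
            paths["blast_ab"] = self.blast_ab
            paths["blast_ba"] = self.blast_ba
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def classify_sample(
    allc_path: str | Path,
    genes: list[mio.GeneModel],
    config: gc.ClassifierConfig,
    dialect: str = "allc",
) -> pd.DataFrame:
    """Classify one sample's methylome; returns summary + status columns."""
    sites = mio.site_calls_to_frame(mio.read_site_calls(allc_path, dialect))
    summaries = mio.summarize_gene_methylation(
        sites, genes, min_reads=config.min_reads_per_site
    )
    status = gc.classify_methylome(summaries, config)
    return pd.concat([status, summaries], axis=1)


def _read_counts(counts_path: str, lengths_path: str) -> es.CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return es.CountMatrix(counts, lengths)


def _compare_group(
    group: str,
    table: pd.DataFrame,
    logexpr_a: pd.Series,
    logexpr_b: pd.Series,
    fpkm_a: pd.Series,
    fpkm_b: pd.Series,
    statistics: tuple[str, ...],
    n_reps: int,
    seed: int,
) -> list[dict]:
    sub = table[table["group"] == group]
    sub = sub[
        sub["gene_a"].isin(logexpr_a.index) & sub["gene_b"].isin(logexpr_b.index)
    ]
    if sub.empty:
        log.info("compare: group %s empty after expression filter; skipped", group)
        return []
    xa = logexpr_a.loc[sub["gene_a"]].to_numpy()
    xb = logexpr_b.loc[sub["gene_b"]].to_numpy()
    rows = []

    def add(res: es.ComparisonResult):
        rows.append(
            {
                "group": group,
                "statistic": res.statistic,
                "observed": res.observed,
                "p_value": res.p_value,
                "n": res.n if res.n is not None else len(sub),
                "effect_size_d": res.effect_size_d,
                "effect_category": res.effect_category,
                "direction": res.direction,
            }
        )

    # differences are reported as set B relative to set A
    if "bootstrap" in statistics:
        add(es.bootstrap_mean_diff(xb, xa, n_reps=n_reps, seed=seed))
    if "wilcoxon" in statistics:
        add(es.wilcoxon_signed_rank(xb - xa))
    if "cohend" in statistics:
        add(es.cohens_d(xb, xa))
    if "classes" in statistics:
        cls = es.discrete_diff_classes(
            fpkm_b.loc[sub["gene_b"]].to_numpy(),
            fpkm_a.loc[sub["gene_a"]].to_numpy(),
        )
        rows.append(
            {
                "group": group,
                "statistic": "discrete_diff_classes",
                "observed": float("nan"),
                "p_value": float("nan"),
                "n": len(sub),
                "effect_size_d": None,
                "effect_category": None,
                "direction": 0,
                "n_up": cls.n_up,
                "n_down": cls.n_down,
                "n_unchanged": cls.n_unchanged,
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute classify -> groups -> compare; returns the manifest dict."""
    missing = [
        f"{name} ({p})"
        for name, p in config.input_paths().items()
        if not Path(p).exists()
    ]
    if missing:
        raise PipelineError(f"missing input files: {', '.join(missing)}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    clf = gc.ClassifierConfig(**config.classifier)

    # ---- stage 1: classify ------------------------------------------------
    stage = "classify"
    try:
        log.info(
            "classify: min_reads=%d min_sites=%d q<=%.3g dialect=%s",
            clf.min_reads_per_site, clf.min_sites, clf.q_threshold,
            config.dialect,
        )
        genes = mio.read_gene_models(
            config.annotation, format=config.annotation_format
        )
        statuses_a, statuses_b = [], []
        for name, path in {**config.samples_a, **config.samples_b}.items():
            table = classify_sample(path, genes, clf, config.dialect)
            dest = out / f"status_{name}.tsv"
            table.to_csv(dest, sep="\t")
            outputs[f"status_{name}"] = dest
            status_map = table["status"].to_dict()
            (statuses_a if name in config.samples_a else statuses_b).append(
                status_map
            )
            log.info("classify: %s -> %s", name, dest.name)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 2: groups --------------------------------------------------
    stage = "groups"
    try:
        if config.pairs:
            pairs_df = pd.read_csv(
                config.pairs, sep="\t", header=None, names=["gene_a", "gene_b"]
            )
            pairs = list(pairs_df.itertuples(index=False, name=None))
        else:
            pairs = og.reciprocal_best_hits(
                og.read_blast_table(config.blast_ab),
                og.read_blast_table(config.blast_ba),
            )
        table = og.assign_groups(
            pairs, statuses_a, statuses_b, mode=config.group_mode
        )
        dest = out / "ortholog_groups.tsv"
        table.to_csv(dest, sep="\t", index=False)
        outputs["ortholog_groups"] = dest
        log.info(
            "groups: %d pairs -> %s", len(table),
            dict(table["group"].value_counts()) if len(table) else {},
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # ---- stage 3: compare -------------------------------------------------
    stage = "compare"
    try:
        cm_a = _read_counts(config.counts_a, config.lengths_a)
        cm_b = _read_counts(config.counts_b, config.lengths_b)
        fpkm_a = es.fpkm_from_counts(cm_a)
        fpkm_b = es.fpkm_from_counts(cm_b)
        log_a = es.log_transform(fpkm_a).values.mean(axis=1)
        log_b = es.log_transform(fpkm_b).values.mean(axis=1)
        mean_fpkm_a = fpkm_a.values.mean(axis=1)
        mean_fpkm_b = fpkm_b.values.mean(axis=1)
        rows = []
        for group in config.compare_groups:
            rows += _compare_group(
                group, table, log_a, log_b, mean_fpkm_a, mean_fpkm_b,
                config.statistics, config.n_reps, config.seed,
            )
        results = pd.DataFrame(rows)
        dest = out / "comparison_results.tsv"
        results.to_csv(dest, sep="\t", index=False)
        outputs["comparison_results"] = dest
        log.info("compare: %d statistic rows -> %s", len(results), dest.name)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    manifest = {
        "inputs": {k: str(v) for k, v in config.input_paths().items()},
        "parameters": {
            "classifier": {
                "min_reads_per_site": clf.min_reads_per_site,
                "min_sites": clf.min_sites,
                "q_threshold": clf.q_threshold,
            },
            "dialect": config.dialect,
            "group_mode": config.group_mode,
            "statistics": list(config.statistics),
            "compare_groups": list(config.compare_groups),
            "n_reps": config.n_reps,
        },
        "seeds": {"seed": config.seed},
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
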