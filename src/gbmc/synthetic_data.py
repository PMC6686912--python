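"""Synthetic methylomes, ortholog tables and expression matrices.

Generators that emulate the statistical structure of a multi-accession
WGBS + RNA-seq comparison, so the whole classify -> group -> compare
pipeline runs and can be validated against known truth without any
external data:

* methylomes — genes of three classes (gbM with CG levels drawn
  uniformly from 30-60% and only bisulfite non-conversion error
  elsewhere; UM at the error rate in all contexts; teM-like elevated in
  all contexts), Poisson site counts and coverage, binomial read-level
  methylation, emitted as allc-dialect tables plus a GFF3 annotation
  and a truth table;
* expression — per-gene latent log10(FPKM+1) with group-level means, a
  between-set shift per group, per-sample offsets, realized as
  overdispersed (gamma-Poisson) counts with log-normal gene lengths;
* ortholog BLAST tables — reciprocal-best-hit structure with a
  controllable fraction of non-reciprocal decoys.

Every generator is deterministic given its spec and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_stats import CountMatrix
from .methylome_io import CONTEXTS, GeneModel

__all__ = [
    "MethylomeSimSpec",
    "ExpressionSimSpec",
    "SimulatedMethylome",
    "SimulatedExpression",
    "simulate_methylome",
    "simulate_expression",
    "simulate_ortholog_tables",
    "write_allc",
    "write_gff3",
]

_TRINUC = {"CG": "CGG", "CHG": "CAG", "CHH": "CAT"}


@dataclass(frozen=True)
class MethylomeSimSpec:
    """Conditions for a simulated multi-sample methylome.

    Defaults describe an A. thaliana-like gene complement: a quarter of
    genes gene-body methylated with CG levels spanning 30-60%, most
    genes unmethylated at the bisulfite non-conversion floor, and a
    minority with transposon-like methylation in all contexts.
    """

    n_genes: int = 1000
    class_proportions: tuple[tuple[str, float], ...] = (
        ("gbM", 0.25), ("UM", 0.65), ("teM_like", 0.10),
    )
    gbm_cg_range: tuple[float, float] = (0.30, 0.60)
    # generator conventions for transposon-like methylation, per context
    tem_rates: tuple[tuple[str, float], ...] = (
        ("CG", 0.8), ("CHG", 0.6), ("CHH", 0.1),
    )
    sites_per_gene_mean: float = 30.0  # per context, Poisson
    mean_depth: float = 20.0  # per site, Poisson
    nonconversion_error: float = 0.005
    cds_exon_length: int = 750  # two exons per gene
    seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.class_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ValueError("class proportions must be non-negative")
        if not (0 <= self.nonconversion_error < 1):
            raise ValueError("nonconversion_error must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Conditions for simulated two-set ortholog expression.

    Latent per-gene expression is log10(FPKM+1) drawn per group; set B
    genes carry the group's between-set shift delta (log10 units) —
    the Group 1 default mirrors a moderate expression decrease
    accompanying gene body methylation loss.  Sample-level offsets model
    accession effects; counts are gamma-Poisson overdispersed.
    """

    n_pairs: tuple[tuple[str, int], ...] = (
        ("Group1", 1328), ("Group2", 2000),
    )
    baseline_mean: tuple[tuple[str, float], ...] = (
        ("Group1", 1.0), ("Group2", 0.6), ("Group3", 1.0),
    )
    baseline_sd: tuple[tuple[str, float], ...] = (
        ("Group1", 0.35), ("Group2", 0.55), ("Group3", 0.35),
    )
    delta: tuple[tuple[str, float], ...] = (
        ("Group1", -0.138), ("Group2", 0.0), ("Group3", 0.0),
    )
    n_samples_a: int = 7
    n_samples_b: int = 2
    sample_offset_sd: float = 0.05
    residual_sd: float = 0.05
    dispersion: float = 0.05
    lib_size_mean: float = 2e7
    lib_size_jitter: float = 0.2  # uniform +/- fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.n_pairs):
            raise ValueError("n_pairs must be non-negative")
        if any(s < 0 for _, s in self.baseline_sd):
            raise ValueError("baseline SDs must be non-negative")
        if self.n_samples_a < 1 or self.n_samples_b < 1:
            raise ValueError("need at least one sample per set")


@dataclass
class SimulatedMethylome:
    genes: list[GeneModel]
    truth: pd.DataFrame  # gene_id, status, cg_rate
    samples: dict[str, pd.DataFrame]  # sample -> site-call frame


@dataclass
class SimulatedExpression:
    counts_a: CountMatrix
    counts_b: CountMatrix
    truth: pd.DataFrame  # gene_a, gene_b, group, delta


# ---------------------------------------------------------------------------
# methylome

def simulate_methylome(
    spec: MethylomeSimSpec, n_samples: int = 1, out_dir: str | Path | None = None
) -> SimulatedMethylome:
    """Simulate per-cytosine call tables for ``n_samples`` methylomes.

    Gene classes, per-gene gbM CG rates and cytosine positions are fixed
    across samples (they are genomic); read sampling is independent per
    sample.  With ``out_dir`` set, writes ``sample_<i>.allc.tsv``,
    ``genes.gff3`` and ``truth.tsv``.
    """
    rng = np.random.default_rng(spec.seed)
    props = dict(spec.class_proportions)
    tem = dict(spec.tem_rates)
    err = spec.nonconversion_error

    classes = rng.choice(
        list(props), size=spec.n_genes, p=list(props.values())
    )
    gbm_rates = rng.uniform(*spec.gbm_cg_range, size=spec.n_genes)

    # per-gene per-context true methylation rates (before conversion error)
    rate = {c: np.full(spec.n_genes, 0.0) for c in CONTEXTS}
    for c in CONTEXTS:
        rate[c][classes == "teM_like"] = tem[c]
    rate["CG"][classes == "gbM"] = gbm_rates[classes == "gbM"]
    # apparent rate after bisulfite non-conversion error
    eff = {c: rate[c] + (1 - rate[c]) * err for c in CONTEXTS}

    genes: list[GeneModel] = []
    site_rows = []  # (gene_idx, chrom, pos, strand, context)
    exon = spec.cds_exon_length
    pitch = 4 * exon
    for gi in range(spec.n_genes):
        start = gi * pitch + 1
        ivs = [(start, start + exon - 1), (start + 2 * exon, start + 3 * exon - 1)]
        gid = f"g{gi + 1:05d}"
        genes.append(GeneModel(gid, "chr1", "+", ivs))
        cds_pos = np.concatenate(
            [np.arange(s, e + 1) for s, e in ivs]
        )
        for c in CONTEXTS:
            k = min(rng.poisson(spec.sites_per_gene_mean), cds_pos.size)
            if k == 0:
                continue
            pos = np.sort(rng.choice(cds_pos, size=k, replace=False))
            strands = rng.choice(["+", "-"], size=k)
            for p, s in zip(pos, strands):
                site_rows.append((gi, "chr1", int(p), s, c))

    sites = pd.DataFrame(
        site_rows, columns=["gene_idx", "chrom", "pos", "strand", "context"]
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "status": classes,
            "cg_rate": np.where(
                classes == "gbM", gbm_rates,
                np.where(classes == "teM_like", tem["CG"], 0.0),
            ),
        }
    )

    samples = {}
    site_rates = np.empty(len(sites))
    for c in CONTEXTS:
        mask = (sites["context"] == c).to_numpy()
        site_rates[mask] = eff[c][sites.loc[mask, "gene_idx"].to_numpy()]
    for si in range(n_samples):
        total = rng.poisson(spec.mean_depth, size=len(sites))
        meth = rng.binomial(total, site_rates)
        frame = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "strand": sites["strand"],
                "context": sites["context"],
                "meth_reads": meth,
                "total_reads": total,
            }
        )
        samples[f"sample_{si + 1}"] = frame

    sim = SimulatedMethylome(genes=genes, truth=truth, samples=samples)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gff3(genes, out / "genes.gff3")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        for name, frame in samples.items():
            write_allc(frame, out / f"{name}.allc.tsv")
    return sim


def write_allc(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a site-call frame as an allc-dialect TSV."""
    out = pd.DataFrame(
        {
            "chrom": frame["chrom"],
            "pos": frame["pos"],
            "strand": frame["strand"],
            "context": frame["context"].map(_TRINUC),
            "mc": frame["meth_reads"],
            "cov": frame["total_reads"],
            "methylated": (frame["meth_reads"] > 0).astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models (gene + mRNA + CDS features) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = g.cds_intervals[0][0]
            end = g.cds_intervals[-1][1]
            fh.write(
                f"{g.chrom}\tgbmc_sim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tgbmc_sim\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tgbmc_sim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# expression

def simulate_expression(spec: ExpressionSimSpec) -> SimulatedExpression:
    """Simulate paired two-set count matrices with known per-group shifts.

    Per gene pair: latent log10(FPKM+1) ~ Normal(group mean, group SD);
    the set-B copy adds the group's delta.  Per sample: an accession
    offset plus residual noise, then FPKM -> expected counts via gene
    length and library size, realized as gamma-Poisson counts.
    """
    rng = np.random.default_rng(spec.seed)
    means = dict(spec.baseline_mean)
    sds = dict(spec.baseline_sd)
    deltas = dict(spec.delta)

    gene_a, gene_b, groups, delta_col, latent = [], [], [], [], []
    for group, n in spec.n_pairs:
        if n == 0:
            continue
        mu = rng.normal(means[group], sds[group], size=n).clip(min=0.0)
        for i in range(n):
            gene_a.append(f"atha_{group}_{i + 1:05d}")
            gene_b.append(f"esal_{group}_{i + 1:05d}")
        groups += [group] * n
        delta_col += [deltas[group]] * n
        latent.append(mu)
    if not latent:
        raise ValueError("no gene pairs requested")
    mu = np.concatenate(latent)
    delta_arr = np.asarray(delta_col)
    n_genes = mu.size

    lengths = np.round(
        10 ** rng.normal(3.2, 0.25, size=n_genes)
    ).clip(300, 20000)

    def one_set(latent_means: np.ndarray, n_samples: int, prefix: str):
        jit = spec.lib_size_jitter
        lib = spec.lib_size_mean * rng.uniform(1 - jit, 1 + jit, n_samples)
        offsets = rng.normal(0.0, spec.sample_offset_sd, n_samples)
        cols = {}
        for s in range(n_samples):
            lat = latent_means + offsets[s] + rng.normal(
                0.0, spec.residual_sd, n_genes
            )
            fpkm = np.maximum(10.0 ** lat - 1.0, 0.0)
            mean_counts = fpkm * lengths * lib[s] / 1e9
            if spec.dispersion > 0:
                shape = 1.0 / spec.dispersion
                lam = rng.gamma(shape, mean_counts * spec.dispersion)
            else:
                lam = mean_counts
            cols[f"{prefix}{s + 1}"] = rng.poisson(lam)
        return cols, lib

    idx_a = pd.Index(gene_a, name="gene_id")
    idx_b = pd.Index(gene_b, name="gene_id")
    cols_a, lib_a = one_set(mu, spec.n_samples_a, "accA_")
    cols_b, lib_b = one_set(
        (mu + delta_arr).clip(min=0.0), spec.n_samples_b, "accB_"
    )
    counts_a = CountMatrix(
        pd.DataFrame(cols_a, index=idx_a),
        pd.Series(lengths, index=idx_a, name="length"),
        pd.Series(lib_a, index=list(cols_a), name="lib_size"),
    )
    counts_b = CountMatrix(
        pd.DataFrame(cols_b, index=idx_b),
        pd.Series(lengths, index=idx_b, name="length"),
        pd.Series(lib_b, index=list(cols_b), name="lib_size"),
    )
    truth = pd.DataFrame(
        {"gene_a": gene_a, "gene_b": gene_b, "group": groups, "delta": delta_arr}
    )
    return SimulatedExpression(counts_a, counts_b, truth)


# ---------------------------------------------------------------------------
# ortholog BLAST tables

def simulate_ortholog_tables(
    n: int, noise: float = 0.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Paired BLAST outfmt-6-style tables with known reciprocal structure.

    Pair i is a_i <-> b_i.  A ``noise`` fraction of pairs get their
    reciprocity broken: b_i's best reverse hit is redirected to a
    different gene.  Returns (A->B table, B->A table, true RBH pairs).
    """
    if not (0 <= noise < 1):
        raise ValueError("noise must be in [0, 1)")
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    a_ids = [f"atha_g{i + 1:04d}" for i in range(n)]
    b_ids = [f"esal_g{i + 1:04d}" for i in range(n)]
    n_noise = int(round(noise * n))
    noisy = set(rng.choice(n, size=n_noise, replace=False).tolist())

    def row(q, s, bitscore):
        return (
            q, s, 90.0, 400, 10, 2, 1, 400, 1, 400,
            10.0 ** -min(bitscore / 5.0, 180.0), float(bitscore),
        )

    ab_rows, ba_rows = [], []
    for i in range(n):
        top = 500.0 + rng.uniform(0, 50)
        ab_rows.append(row(a_ids[i], b_ids[i], top))
        if i in noisy and n > 1:
            j = int(rng.integers(0, n - 1))
            j = j if j < i else j + 1
            ba_rows.append(row(b_ids[i], a_ids[j], top + 10))
            ba_rows.append(row(b_ids[i], a_ids[i], top))
        else:
            ba_rows.append(row(b_ids[i], a_ids[i], top))
        # low-scoring decoy hits
        for _ in range(int(rng.integers(0, 3))):
            k = int(rng.integers(0, n))
            ab_rows.append(row(a_ids[i], b_ids[k], rng.uniform(50, 200)))

    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    blast_ab = pd.DataFrame(ab_rows, columns=cols)
    blast_ba = pd.DataFrame(ba_rows, columns=cols)
    truth = sorted(
        (a_ids[i], b_ids[i]) for i in range(n) if i not in noisy or n == 1
    )
    return blast_ab, blast_ba, truth


def spec_to_dict(spec) -> dict:
    """Flatten a sim spec dataclass for manifests and config echoes."""
    d = dataclasses.asdict(spec)
    return {
        k: (dict(v) if isinstance(v, tuple) and v and isinstance(v[0], tuple)
            else v)
        for k, v in d.items()
    }
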