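"""Readers for per-cytosine bisulfite call tables and gene annotations.

Per-cytosine calls come from bisulfite pipelines in one of two common
tabular dialects:

* ``allc`` — methylpy-style: chrom, 1-based position, strand,
  trinucleotide context, methylated read count, total read count,
  binomial-call flag (ignored here).
* ``cx_report`` — Bismark CX-report-style: chrom, 1-based position,
  strand, methylated count, unmethylated count, context class,
  trinucleotide.

All coordinates are held internally as 1-based inclusive (the allc
convention); BED input is converted on read.  Sites are intersected
with coding-sequence (CDS) intervals and aggregated into per-gene,
per-context summaries whose weighted methylation level is the summed
methylated read count divided by the summed total read count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

CONTEXTS = ("CG", "CHG", "CHH")

__all__ = [
    "CONTEXTS",
    "SiteCall",
    "GeneModel",
    "MethylomeParseError",
    "read_site_calls",
    "read_gene_models",
    "write_gene_models_bed12",
    "site_calls_to_frame",
    "summarize_gene_methylation",
    "nonconversion_rate",
]


class MethylomeParseError(ValueError):
    """Raised for malformed call-table or annotation rows."""


@dataclass(frozen=True)
class SiteCall:
    """One cytosine's strand-resolved read counts in a sequence context."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    context: str  # 'CG', 'CHG' or 'CHH'
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MethylomeParseError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise MethylomeParseError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise MethylomeParseError(f"bad context {self.context!r}")
        if self.meth_reads < 0 or self.total_reads < 0:
            raise MethylomeParseError("read counts must be non-negative")
        if self.meth_reads > self.total_reads:
            raise MethylomeParseError(
                f"meth_reads {self.meth_reads} > total_reads {self.total_reads}"
            )


@dataclass
class GeneModel:
    """A gene's merged coding-sequence intervals, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds_intervals = merge_intervals(self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or book-ended 1-based inclusive intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise MethylomeParseError(f"interval start {s} > end {e}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def collapse_context(tri: str) -> str:
    """Collapse a trinucleotide (e.g. CGG, CAG, CTT) to its CG/CHG/CHH class.

    Already-collapsed class symbols pass through unchanged.  'N' in the
    second position is ambiguous and rejected.
    """
    tri = tri.upper()
    if tri in CONTEXTS:
        return tri
    if len(tri) != 3 or not tri.startswith("C"):
        raise MethylomeParseError(f"unknown context symbol {tri!r}")
    if tri[1] == "G":
        return "CG"
    if tri[1] in "ACT":
        if tri[2] == "G":
            return "CHG"
        if tri[2] in "ACTN":
            # CHN: methylpy reports trailing N for truncated contexts; class
            # is determined by the second base alone only when third is G/H.
            return "CHH" if tri[2] != "N" else "CHH"
    raise MethylomeParseError(f"unknown context symbol {tri!r}")


def read_site_calls(path, dialect: str = "allc") -> Iterator[SiteCall]:
    """Stream cytosine calls from a TSV in the given dialect.

    Rows with zero total reads are retained: they count as unobserved
    sites in coverage bookkeeping.
    """
    if dialect not in ("allc", "cx_report"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "allc":
                    chrom, pos, strand, ctx, mc, cov = fields[:6]
                    meth, total = int(mc), int(cov)
                else:
                    chrom, pos, strand, mc, umc, ctx = fields[:6]
                    meth = int(mc)
                    total = meth + int(umc)
                yield SiteCall(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    context=collapse_context(ctx),
                    meth_reads=meth,
                    total_reads=total,
                )
            except (MethylomeParseError, ValueError, IndexError) as exc:
                raise MethylomeParseError(
                    f"{path}: malformed {dialect} row at line {lineno}: {exc}"
                ) from exc


def read_gene_models(path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models with CDS intervals from GFF3 or BED12.

    GFF3 CDS features are grouped by their ``Parent`` (transcript) and
    walked up to the enclosing gene where a gene feature exists; isoform
    CDS intervals are unioned.  BED12 blocks are taken as the CDS.
    Genes without CDS are dropped with a warning.
    """
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path) -> list[GeneModel]:
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        ivs = [
            (cds.start, cds.end)
            for cds in db.children(gene, featuretype="CDS")
        ]
        if not ivs:
            warnings.warn(f"gene {gene.id} has no CDS features; omitted")
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_intervals=ivs,
            )
        )
    if not genes:
        # annotation may carry bare CDS rows without gene parents
        for cds in db.features_of_type("CDS"):
            parents = cds.attributes.get("Parent", [cds.id])
            gid = parents[0]
            genes.append(
                GeneModel(gene_id=gid, chrom=cds.seqid, strand=cds.strand,
                          cds_intervals=[(cds.start, cds.end)])
            )
    return genes


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise MethylomeParseError(
                    f"{path}: BED12 needs 12 columns at line {lineno}"
                )
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise MethylomeParseError(
                    f"{path}: blockSizes/blockStarts mismatch at line {lineno}"
                )
            # BED is 0-based half-open: block [cs+bs, cs+bs+size) becomes
            # 1-based inclusive (cs+bs+1, cs+bs+size)
            ivs = [
                (chrom_start + bs + 1, chrom_start + bs + size)
                for bs, size in zip(starts, sizes)
            ]
            genes.append(GeneModel(name, chrom, strand, ivs))
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path) -> None:
    """Write gene models back out as BED12 (CDS blocks only)."""
    with open(path, "w") as fh:
        for g in genes:
            if not g.cds_intervals:
                continue
            start0 = g.cds_intervals[0][0] - 1
            end = g.cds_intervals[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in g.cds_intervals)
            starts = ",".join(str(s - 1 - start0) for s, _ in g.cds_intervals)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(start0),
                        str(end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(start0),
                        str(end),
                        "0",
                        str(len(g.cds_intervals)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def site_calls_to_frame(sites: Iterable[SiteCall]) -> pd.DataFrame:
    """Materialize a site-call stream into a DataFrame."""
    rows = [
        (s.chrom, s.pos, s.strand, s.context, s.meth_reads, s.total_reads)
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "meth_reads", "total_reads"],
    )


_SUMMARY_COLUMNS = []
for _c in CONTEXTS:
    _SUMMARY_COLUMNS += [
        f"n_sites_{_c}",
        f"n_covered_{_c}",
        f"meth_reads_{_c}",
        f"total_reads_{_c}",
        f"weighted_level_{_c}",
    ]


def summarize_gene_methylation(
    sites: Iterable[SiteCall] | pd.DataFrame,
    genes: Sequence[GeneModel],
    min_reads: int = 3,
) -> pd.DataFrame:
    """Aggregate site calls over each gene's CDS into per-context summaries.

    Returns a DataFrame indexed by gene_id with, per context c in
    {CG, CHG, CHH}: ``n_sites_c`` (sites inside CDS), ``n_covered_c``
    (of those, sites with total_reads >= min_reads), ``meth_reads_c``,
    ``total_reads_c`` and ``weighted_level_c`` = meth/total (0 when no
    reads).  A site falling in two genes' CDS contributes to both.
    ``p_value_*`` / ``q_value_*`` columns are left to the classifier.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not isinstance(sites, pd.DataFrame):
        sites = site_calls_to_frame(sites)

    index = pd.Index([g.gene_id for g in genes], name="gene_id")
    out = pd.DataFrame(0.0, index=index, columns=_SUMMARY_COLUMNS)
    for c in CONTEXTS:
        for col in (f"n_sites_{c}", f"n_covered_{c}", f"meth_reads_{c}",
                    f"total_reads_{c}"):
            out[col] = out[col].astype(np.int64)
    if sites.empty or not genes:
        return out

    cds_rows = []
    for gi, g in enumerate(genes):
        for s, e in g.cds_intervals:
            cds_rows.append((g.chrom, s - 1, e, gi))
    cds = pd.DataFrame(cds_rows, columns=["Chromosome", "Start", "End", "gene_idx"])
    site_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": sites["chrom"],
                "Start": sites["pos"] - 1,
                "End": sites["pos"],
                "context": sites["context"],
                "meth_reads": sites["meth_reads"],
                "total_reads": sites["total_reads"],
            }
        )
    )
    hits = site_pr.join(pr.PyRanges(cds)).df
    if hits.empty:
        return out

    hits["covered"] = (hits["total_reads"] >= min_reads).astype(np.int64)
    agg = (
        hits.groupby(["gene_idx", "context"], observed=True)
        .agg(
            n_sites=("meth_reads", "size"),
            n_covered=("covered", "sum"),
            meth=("meth_reads", "sum"),
            total=("total_reads", "sum"),
        )
        .reset_index()
    )
    gene_ids = np.asarray(index)
    for c in CONTEXTS:
        sub = agg[agg["context"] == c]
        if sub.empty:
            continue
        gid = gene_ids[sub["gene_idx"].to_numpy()]
        out.loc[gid, f"n_sites_{c}"] = sub["n_sites"].to_numpy()
        out.loc[gid, f"n_covered_{c}"] = sub["n_covered"].to_numpy()
        out.loc[gid, f"meth_reads_{c}"] = sub["meth"].to_numpy()
        out.loc[gid, f"total_reads_{c}"] = sub["total"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(sub["total"] > 0, sub["meth"] / sub["total"], 0.0)
        out.loc[gid, f"weighted_level_{c}"] = lvl
    return out


def nonconversion_rate(control_sites: Iterable[SiteCall]) -> float:
    """Bisulfite non-conversion rate from an unmethylated control genome.

    Pools all contexts: sum of methylated reads over sum of total reads.
    """
    meth = total = 0
    for s in control_sites:
        meth += s.meth_reads
        total += s.total_reads
    if total == 0:
        raise ValueError("control stream has zero total reads")
    return meth / total
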