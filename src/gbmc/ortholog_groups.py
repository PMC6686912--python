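"""One-to-one ortholog pairing and methylation-pattern group assignment.

Putative one-to-one orthologs between two gene sets are selected as
reciprocal best hits (RBH) from a pair of BLAST tabular (outfmt 6)
searches.  Pairs are then grouped by the pattern of per-sample
methylation status calls:

* Group 1 — gbM in ALL samples of set A and UM in ALL samples of set B
  (evolutionary loss of gene body methylation in the B lineage);
* Group 2 — UM in ALL samples of both sets;
* Group 3 — gbM in ALL samples of both sets; only meaningful when set B
  is a within-species comparison (e.g. a met1 epiRIL against its wild
  type), where it captures genes that retained gbM;
* unassigned — any other pattern.  A teM-like call in any sample
  disqualifies a pair, and a missing or undetermined call fails the
  ALL-quantifier.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "BLAST6_COLUMNS",
    "read_blast_table",
    "best_hits",
    "reciprocal_best_hits",
    "assign_groups",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_table(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 tabular file (12 standard columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected 12 outfmt-6 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def best_hits(blast: pd.DataFrame) -> pd.Series:
    """Top subject per query: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id."""
    missing = {"qseqid", "sseqid", "bitscore", "evalue"} - set(blast.columns)
    if missing:
        raise ValueError(f"BLAST table missing columns: {sorted(missing)}")
    ranked = blast.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    top = ranked.drop_duplicates("qseqid", keep="first")
    return top.set_index("qseqid")["sseqid"]


def reciprocal_best_hits(
    blast_ab: pd.DataFrame, blast_ba: pd.DataFrame
) -> list[tuple[str, str]]:
    """One-to-one pairs (a, b) that are mutual top hits in both searches."""
    ab = best_hits(blast_ab)
    ba = best_hits(blast_ba)
    pairs = [
        (a, b)
        for a, b in ab.items()
        if ba.get(b) == a
    ]
    return sorted(pairs)


def _pattern(
    gene: str, status_maps: Sequence[Mapping[str, str]]
) -> set[str]:
    return {m.get(gene, "undetermined") for m in status_maps}


def assign_groups(
    pairs: Sequence[tuple[str, str]],
    statuses_a: Sequence[Mapping[str, str]],
    statuses_b: Sequence[Mapping[str, str]],
    mode: str = "cross",
) -> pd.DataFrame:
    """Label each ortholog pair Group1/Group2/Group3/unassigned.

    ``statuses_a`` / ``statuses_b`` are one gene_id -> status mapping per
    sample (accession, genotype or replicate).  ``mode`` is ``cross``
    for a between-species comparison (Groups 1 and 2) or ``within`` for
    a within-species wild-type/mutant comparison (adds Group 3).
    """
    if mode not in ("cross", "within"):
        raise ValueError(f"unknown mode {mode!r}")
    if not statuses_a or not statuses_b:
        raise ValueError("need at least one status map per gene set")
    rows = []
    for a, b in pairs:
        pat_a = _pattern(a, statuses_a)
        pat_b = _pattern(b, statuses_b)
        if pat_a == {"gbM"} and pat_b == {"UM"}:
            group = "Group1"
        elif pat_a == {"UM"} and pat_b == {"UM"}:
            group = "Group2"
        elif mode == "within" and pat_a == {"gbM"} and pat_b == {"gbM"}:
            group = "Group3"
        else:
            group = "unassigned"
        row = {"gene_a": a, "gene_b": b, "group": group}
        for i, m in enumerate(statuses_a):
            row[f"status_a{i + 1}"] = m.get(a, "undetermined")
        for i, m in enumerate(statuses_b):
            row[f"status_b{i + 1}"] = m.get(b, "undetermined")
        rows.append(row)
    return pd.DataFrame(rows)
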