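"""Per-gene methylation status calls: gbM, UM, teM-like or undetermined.

A gene is gene-body methylated (gbM) when its CG-context methylation is
enriched over the coding-sequence-wide background, without significant
CHG/CHH methylation (which would indicate transposon-like methylation,
teM).  Enrichment is a one-sided binomial test of the gene's pooled CG
read counts against the background level, corrected per context with
Benjamini-Hochberg FDR across the genes that pass that context's
coverage gate.

Classification rules (per gene, with coverage gate = at least
``min_sites`` CG sites carrying >= ``min_reads_per_site`` reads):

* undetermined — CG coverage gate failed;
* gbM  — gate passed, q_CG <= q_threshold, q_CHG and q_CHH > q_threshold;
* UM   — gate passed, all three q-values > q_threshold;
* teM_like — gate passed and q_CHG <= q_threshold or q_CHH <= q_threshold.

Genes failing a non-CG context's own coverage gate are treated as
non-significant there (q = 1) rather than discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome_io import CONTEXTS

__all__ = [
    "ClassifierConfig",
    "STATUSES",
    "background_level",
    "binomial_enrichment_p",
    "bh_fdr",
    "classify_methylome",
]

STATUSES = ("gbM", "UM", "teM_like", "undetermined")

# degenerate backgrounds (all-methylated / all-unmethylated pools) are
# clamped so the binomial test stays defined
_BG_EPS = 1e-9


@dataclass(frozen=True)
class ClassifierConfig:
    """Coverage and significance thresholds for methylome classification."""

    min_reads_per_site: int = 3
    min_sites: int = 20
    q_threshold: float = 0.05
    contexts_tested: tuple[str, ...] = field(default=CONTEXTS)

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must be in (0, 1)")
        if self.min_sites < 1 or self.min_reads_per_site < 1:
            raise ValueError("min_sites and min_reads_per_site must be >= 1")


def background_level(summaries: pd.DataFrame, context: str) -> float:
    """Read-weighted methylation level pooled over all coding sequence.

    Sum of methylated reads over sum of total reads in ``context``,
    across every gene in ``summaries``.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    meth = int(summaries[f"meth_reads_{context}"].sum())
    total = int(summaries[f"total_reads_{context}"].sum())
    if total == 0:
        raise ValueError(f"no {context} reads; background undefined")
    return meth / total


def binomial_enrichment_p(meth_reads, total_reads, p_bg: float):
    """One-sided upper-tail binomial p-value P(X >= meth_reads).

    X ~ Binomial(total_reads, p_bg).  Accepts scalars or arrays.
    Zero total reads gives p = 1.
    """
    if not (0 < p_bg < 1):
        raise ValueError("p_bg must lie strictly inside (0, 1)")
    meth = np.asarray(meth_reads)
    total = np.asarray(total_reads)
    if np.any(meth < 0) or np.any(meth > total):
        raise ValueError("need 0 <= meth_reads <= total_reads")
    # sf(k) = P(X > k), so P(X >= m) = sf(m - 1)
    p = stats.binom.sf(meth - 1, total, p_bg)
    p = np.where(total == 0, 1.0, p)
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_methylome(
    summaries: pd.DataFrame, config: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Call a methylation status for every gene in a summary table.

    Returns a DataFrame indexed like ``summaries`` with a ``status``
    column and per-context ``p_value_*`` / ``q_value_*`` columns.  The
    BH correction runs within each context, over the genes passing that
    context's coverage gate only; other genes keep p = q = NaN (CG) or
    are assigned q = 1 (CHG/CHH) for the status rules.
    """
    config = config or ClassifierConfig()
    out = pd.DataFrame(index=summaries.index)
    q_eff = {}
    for c in config.contexts_tested:
        p_bg = float(
            np.clip(background_level(summaries, c), _BG_EPS, 1 - _BG_EPS)
        )
        gate = (
            summaries[f"n_covered_{c}"].to_numpy() >= config.min_sites
        )
        p = np.full(len(summaries), np.nan)
        q = np.full(len(summaries), np.nan)
        if gate.any():
            p[gate] = binomial_enrichment_p(
                summaries.loc[gate, f"meth_reads_{c}"].to_numpy(),
                summaries.loc[gate, f"total_reads_{c}"].to_numpy(),
                p_bg,
            )
            q[gate] = bh_fdr(p[gate])
        out[f"p_value_{c}"] = p
        out[f"q_value_{c}"] = q
        # unassessable non-CG contexts count as non-significant
        q_eff[c] = np.where(np.isnan(q), 1.0, q)

    t = config.q_threshold
    cg_gate = summaries["n_covered_CG"].to_numpy() >= config.min_sites
    sig = {c: q_eff[c] <= t for c in CONTEXTS}
    status = np.full(len(summaries), "undetermined", dtype=object)
    tem = cg_gate & (sig["CHG"] | sig["CHH"])
    gbm = cg_gate & sig["CG"] & ~sig["CHG"] & ~sig["CHH"]
    um = cg_gate & ~sig["CG"] & ~sig["CHG"] & ~sig["CHH"]
    status[tem] = "teM_like"
    status[gbm] = "gbM"
    status[um] = "UM"
    out.insert(0, "status", status)
    return out
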