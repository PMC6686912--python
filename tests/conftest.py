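import numpy as np
import pandas as pd
import pytest

from gbmc import (
    ClassifierConfig,
    ExpressionSimSpec,
    MethylomeSimSpec,
    simulate_expression,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def small_methylome():
    """200-gene, 2-sample simulated methylome with truth labels."""
    spec = MethylomeSimSpec(n_genes=200, seed=11)
    return simulate_methylome(spec, n_samples=2)


@pytest.fixture(scope="session")
def small_expression():
    """Modest two-set expression simulation with the default group shifts."""
    spec = ExpressionSimSpec(
        n_pairs=(("Group1", 400), ("Group2", 400)), seed=12
    )
    return simulate_expression(spec)


@pytest.fixture
def default_config():
    return ClassifierConfig()


def make_summary_frame(rows):
    """Build a gene-methylation summary DataFrame from per-gene dicts.

    Missing per-context fields default to zero; weighted levels are
    derived from the read counts.
    """
    from gbmc.methylome_io import CONTEXTS

    records = []
    for r in rows:
        rec = {"gene_id": r["gene_id"]}
        for c in CONTEXTS:
            meth = r.get(f"meth_{c}", 0)
            total = r.get(f"total_{c}", 0)
            rec[f"n_sites_{c}"] = r.get(f"n_sites_{c}", 0)
            rec[f"n_covered_{c}"] = r.get(f"n_covered_{c}", 0)
            rec[f"meth_reads_{c}"] = meth
            rec[f"total_reads_{c}"] = total
            rec[f"weighted_level_{c}"] = meth / total if total else 0.0
        records.append(rec)
    return pd.DataFrame(records).set_index("gene_id")


@pytest.fixture
def summary_builder():
    return make_summary_frame
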