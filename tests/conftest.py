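"""Shared fixtures: synthetic datasets and derived call sets.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive MNase sampling + peak calling to one run per suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from remodelscan import nucmap, synthetic


@pytest.fixture(scope="session")
def default_config() -> synthetic.SyntheticConfig:
    """Study conditions: 2 x 500 kb, 180-bp spacing, fuzziness 20, coverage 20."""
    return synthetic.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_config):
    genes, enh, sizes = synthetic.build_annotation(default_config)
    return synthetic.plant_nucleosome_truth(genes, enh, sizes, default_config)


@pytest.fixture(scope="session")
def default_tags(default_truth, default_config):
    return {
        state: synthetic.sample_mnase_reads(default_truth, default_config, state)
        for state in ("A", "B")
    }


@pytest.fixture(scope="session")
def default_calls(default_tags, default_truth):
    calls = {}
    for state, tags in default_tags.items():
        dyads, _ = nucmap.reads_to_dyads(tags, default_truth.chrom_sizes)
        calls[state] = nucmap.call_nucleosomes(dyads, len(tags))
    return calls


def dyad_recovery(calls: pd.DataFrame, planted: pd.DataFrame, dyad_col: str,
                  tol: int = 20) -> float:
    """Fraction of planted dyads with a call within ``tol`` bp."""
    hits = 0
    total = 0
    for chrom, sub in planted.groupby("chrom"):
        cd = np.sort(calls.loc[calls["chrom"] == chrom, "dyad"].to_numpy())
        d = sub[dyad_col].to_numpy()
        total += len(d)
        if len(cd) == 0:
            continue
        i = np.searchsorted(cd, d)
        near = np.minimum(
            np.abs(d - cd[np.clip(i - 1, 0, len(cd) - 1)]),
            np.abs(d - cd[np.clip(i, 0, len(cd) - 1)]),
        )
        hits += int((near <= tol).sum())
    return hits / total if total else float("nan")


@pytest.fixture(scope="session")
def recovery_fn():
    return dyad_recovery
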