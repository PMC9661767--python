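"""Shared fixtures: small simulated studies reused across test modules.

Everything is generated at test time from seeds; the heavier default-scale
study is session-scoped so the end-to-end tests share one simulation.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from rg4kit.calling import CallerConfig, RTSModel
from rg4kit.preprocess import dedup
from rg4kit.simulate import (
    SimConfig,
    generate_transcriptome,
    reads_to_frame,
    simulate_library,
)


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_tx(default_cfg):
    return generate_transcriptome(default_cfg)


@pytest.fixture(scope="session")
def default_libraries(default_cfg, default_tx):
    """K+/Li+ read tables for two replicates at default study conditions."""
    libs = {}
    for rep in (1, 2):
        for cond in ("K", "Li"):
            libs[(cond, rep)] = reads_to_frame(
                simulate_library(default_tx, default_cfg, cond, rep)
            )
    return libs


@pytest.fixture(scope="session")
def default_fits(default_cfg, default_tx, default_libraries):
    """Deduplicated reads and fitted RTS results per replicate."""
    out = {}
    for rep in (1, 2):
        pair = pd.concat(
            [default_libraries[("K", rep)], default_libraries[("Li", rep)]],
            ignore_index=True,
        )
        unique, _ = dedup(pair)
        res = RTSModel.from_reads(unique, default_tx.lengths(), CallerConfig()).fit(
            replicate=rep
        )
        out[rep] = (unique, res)
    return out


def tiny_null_cfg(seed: int) -> SimConfig:
    """A motif-free study for type-I-error measurements."""
    return dataclasses.replace(
        SimConfig(),
        seed=seed,
        n_transcripts=5,
        length_range=(500, 700),
        motif_plan={},
        depth=3000,
        complexity_per_ng=30.0,
    )
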