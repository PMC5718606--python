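"""Shared helpers: seed fan-out, test-result container, tabular I/O conventions."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed by stable hashing of the stage name.

    Toggling one pipeline stage must not shift another stage's random stream,
    so each stage owns a stream keyed by (global seed, stage name).
    """
    return int(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


@dataclass
class TestResult:
    """Outcome of a permutation test.

    p_value uses the (1 + #{perm >= obs}) / (1 + n_permutations) estimator,
    so p is never zero and never below 1/(n_permutations + 1).
    """

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and np.isfinite(self.p_value):
            floor = 1.0 / (self.n_permutations + 1)
            if self.p_value < floor - 1e-12:
                raise ValueError("permutation p below attainable floor")


def perm_pvalue(obs: float, perms: np.ndarray) -> float:
    """(1 + count) / (1 + N) permutation p for a 'large is extreme' statistic."""
    perms = np.asarray(perms, dtype=float)
    return (1.0 + np.sum(perms >= obs - 1e-12)) / (1.0 + perms.size)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
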