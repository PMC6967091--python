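"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from piphillin import (
    ReferenceGenome,
    ReferencePack,
    SimulationConfig,
    simulate_benchmark,
)


def oracle_alignment_stats(
    a: str, b: str, match: int = 2, mismatch: int = -3, gap: int = -5,
    terminal: int = -1,
) -> tuple[int, int, int]:
    """Plain-Python semi-global alignment, independent of the fast kernel.

    Maximizes (score, matches, -columns) lexicographically over all global
    alignments allowing an unaligned prefix of one sequence and an unaligned
    suffix of one sequence, each terminal residue costing ``terminal`` in
    score and contributing no column; returns (score, matches, columns).
    Quadratic and tuple-based — use on short sequences only.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    n, m = len(a), len(b)
    prev = [(terminal * j, 0, 0) for j in range(m + 1)]  # unaligned prefix of b
    end_cells = [(prev[m][0] + terminal * n, 0, 0)]
    for i in range(1, n + 1):
        cur = [(terminal * i, 0, 0)] * (m + 1)  # unaligned prefix of a
        for j in range(1, m + 1):
            ds, dm, dc = prev[j - 1]
            if a[i - 1] == b[j - 1]:
                best = (ds + match, dm + 1, dc - 1)
            else:
                best = (ds + mismatch, dm, dc - 1)
            us, um, uc = prev[j]
            up = (us + gap, um, uc - 1)
            if up > best:
                best = up
            ls, lm, lc = cur[j - 1]
            left = (ls + gap, lm, lc - 1)
            if left > best:
                best = left
            cur[j] = best
        s, mm, cc = cur[m]
        end_cells.append((s + terminal * (n - i), mm, cc))  # unaligned suffix of a
        prev = cur
    for j in range(m + 1):
        s, mm, cc = prev[j]
        end_cells.append((s + terminal * (m - j), mm, cc))  # unaligned suffix of b
    best = max(end_cells)
    return best[0], best[1], -best[2]


def oracle_identity(a: str, b: str, **kw) -> float:
    _, matches, columns = oracle_alignment_stats(a, b, **kw)
    return 100.0 * matches / columns if columns else 0.0


def toy_pack(seqs_by_genome: dict[str, list[str]],
             functions: dict[str, dict[str, int]] | None = None,
             length_bounds=(1, 10**9)) -> ReferencePack:
    """Hand-built pack helper with permissive length bounds."""
    functions = functions or {}
    return ReferencePack(
        genomes={
            gid: ReferenceGenome(gid, tuple(seqs), functions.get(gid, {}))
            for gid, seqs in seqs_by_genome.items()
        },
        length_bounds=length_bounds,
    )


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default noisy benchmark: 20 genomes, 4% divergence, 0.5% query error."""
    return simulate_benchmark(SimulationConfig(random_seed=11))


@pytest.fixture(scope="session")
def clean_bundle():
    """Deterministic error-free community for exact-recovery checks."""
    return simulate_benchmark(
        SimulationConfig(
            deterministic_counts=True, query_error_rate=0.0, random_seed=7
        )
    )


@pytest.fixture()
def small_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"s1": [10.0, 6.0, 4.0], "s2": [0.0, 2.0, 8.0]},
        index=pd.Index(["q1", "q2", "q3"], name="query_id"),
    )
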