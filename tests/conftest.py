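"""Shared fixtures and independent oracle implementations.

The oracle functions here re-derive scores with their own coverage tables
and literal loops (no shared code with the package's scanner) so that
scanner results can be checked against an exhaustive second route.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from mlconsensus.seqio import SiteRecord, SiteSet

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# the published four-site worked example
# ---------------------------------------------------------------------------

EXAMPLE_SITES = [
    "ACCTAAGCTG",
    "ATTACACCAAGTACC",
    "GGAATTTCCTGTTGATCC",
    "CTAAAGGACGTCACATTGC",
]

CLUSTALW2_ROWS = [
    "-------ATTACACCAAGTACC",
    "----GGAATTTCCTGTTGATCC",
    "-------ACCTAA-GCTG----",
    "CTAAAGGACGTCACATTGC---",
]

SIMPLE_SORTED_ROWS = [
    "-------ACCTAAGCTG--",
    "----ATTACACCAAGTACC",
    "-GGAATTTCCTGTTGATCC",
    "CTAAAGGACGTCACATTGC",
]

CLUSTALW2_CONSENSUS = "-------A--TCA---TG----"
SIMPLE_SORTED_CONSENSUS = "----A--AC-T-A--T--C"


@pytest.fixture
def example_site_set() -> SiteSet:
    return SiteSet(
        "TF_EX",
        [
            SiteRecord(f"s{i + 1}", "TF_EX", "example", seq)
            for i, seq in enumerate(EXAMPLE_SITES)
        ],
    )


def make_site_set(tf_id: str, sequences: list, species: str = "test") -> SiteSet:
    return SiteSet(
        tf_id,
        [
            SiteRecord(f"{tf_id}_s{i + 1}", tf_id, species, seq)
            for i, seq in enumerate(sequences)
        ],
    )


# ---------------------------------------------------------------------------
# independent scoring oracle (own coverage table, literal loops)
# ---------------------------------------------------------------------------

ORACLE_COVERAGE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "I": "AC", "J": "AG", "K": "AT",
    "L": "CG", "M": "CT", "N": "GT",
    "-": "",
}


def oracle_match(symbol: str, base: str) -> int:
    return 1 if base in ORACLE_COVERAGE[symbol] else 0


def oracle_overlap(t: str, cons: str, offset: int):
    """(consensus column, test base, symbol) triples at one offset, or None."""
    pairs = []
    for col in range(1, len(cons) + 1):
        p = col - offset + 1
        if 1 <= p <= len(t):
            pairs.append((col, t[p - 1], cons[col - 1]))
    return pairs or None


def oracle_overlap_score(pairs, use_ic, scope, column_ic, pair_ic) -> float:
    m = [oracle_match(sym, base) for (_, base, sym) in pairs]
    cols = [col for (col, _, _) in pairs]
    n = len(pairs)
    if scope is None:
        if use_ic:
            return sum(mi * column_ic[c - 1] for mi, c in zip(m, cols))
        return float(sum(m))
    k_max = n - 1 if scope == "full" else int(scope)
    total = 0.0
    for s in range(1, k_max + 1):
        for i in range(1, n - s + 1):
            for k in range(1, s + 1):
                if m[i - 1] and m[i + k - 1]:
                    if use_ic:
                        total += 2.0 * pair_ic[cols[i - 1] - 1, cols[i + k - 1] - 1]
                    else:
                        total += 2.0
    return total


def oracle_scan(t: str, cons: str, use_ic, scope, column_ic=None, pair_ic=None) -> float:
    best = -math.inf
    for offset in range(2 - len(t), len(cons) + 1):
        pairs = oracle_overlap(t, cons, offset)
        if pairs is None:
            continue
        best = max(best, oracle_overlap_score(pairs, use_ic, scope, column_ic, pair_ic))
    return best


# ---------------------------------------------------------------------------
# random instance helpers
# ---------------------------------------------------------------------------


def random_alignment_rows(rng: np.random.Generator, max_width: int = 12):
    n = int(rng.integers(2, 6))
    w = int(rng.integers(2, max_width + 1))
    rows = []
    for _ in range(n):
        row = "".join(rng.choice(list("ACGT-"), size=w, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
        if set(row) == {"-"}:
            row = row[:-1] + "A"
        rows.append(row)
    return rows


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
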