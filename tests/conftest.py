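"""Shared fixtures and independent oracle implementations.

The oracle helpers here deliberately re-derive statistics by brute force
(per-read recounting, exhaustive scans) so the package implementations are
checked against logic that shares no code with them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from inoseq.io import RNA_BASES, PileupTable, TranscriptRef


@pytest.fixture
def luc_ref() -> TranscriptRef:
    """Small deterministic transcript with all four bases."""
    return TranscriptRef(id="luc", seq="ACGUACGUACGUAAGGCCUU")


def make_table(ref_id: str, specs: list[dict]) -> PileupTable:
    """Build a pileup table from {pos, ref_base, counts-by-base, [N, del]}."""
    rows = []
    for s in specs:
        counts = {b: int(s.get(b, 0)) for b in RNA_BASES}
        n, dels = int(s.get("N", 0)), int(s.get("del", 0))
        matches = counts[s["ref_base"]]
        mismatches = sum(counts.values()) - matches
        rows.append({
            "pos": s["pos"], "ref_base": s["ref_base"],
            "depth": matches + mismatches + n + dels,
            "matches": matches, "mismatches": mismatches,
            "count_A": counts["A"], "count_C": counts["C"],
            "count_G": counts["G"], "count_U": counts["U"],
            "count_N": n, "count_del": dels,
        })
    return PileupTable(ref_id=ref_id, rows=pd.DataFrame(rows))


def random_table(rng: np.random.Generator, n_positions: int,
                 max_depth: int = 60) -> PileupTable:
    """Random valid pileup table for fuzzing, N/deletions included."""
    specs = []
    for pos in range(1, n_positions + 1):
        ref_base = rng.choice(RNA_BASES)
        spec = {"pos": pos, "ref_base": ref_base}
        for b in RNA_BASES:
            spec[b] = int(rng.integers(0, max_depth // 4))
        spec["N"] = int(rng.integers(0, 3))
        spec["del"] = int(rng.integers(0, 3))
        specs.append(spec)
    return make_table("fuzz", specs)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def expand_reads(row) -> list[str]:
    """Explode one pileup row into its individual called bases."""
    calls = []
    for b in RNA_BASES:
        calls.extend([b] * int(row[f"count_{b}"]))
    return calls

def naive_position_frequency(row) -> float:
    """Recount one position read by read (N/deletions never counted)."""
    calls = expand_reads(row)
    matches = sum(1 for c in calls if c == row["ref_base"])
    mismatches = sum(1 for c in calls if c != row["ref_base"])
    if matches + mismatches == 0:
        return float("nan")
    return 100.0 * mismatches / (matches + mismatches)


def naive_profile(table: PileupTable, depth_weighted: bool = False):
    """Per-position frequencies and per-base accuracies by pure recounting."""
    freqs = [naive_position_frequency(row) for _, row in table.rows.iterrows()]
    accuracy = {}
    for base in RNA_BASES:
        vals, weights = [], []
        for f, (_, row) in zip(freqs, table.rows.iterrows()):
            if row["ref_base"] == base and f == f:  # defined
                vals.append(f)
                weights.append(len(expand_reads(row)))
        if not vals:
            accuracy[base] = float("nan")
        elif depth_weighted:
            accuracy[base] = 100.0 - sum(v * w for v, w in zip(vals, weights)) / sum(weights)
        else:
            accuracy[base] = 100.0 - sum(vals) / len(vals)
    return freqs, accuracy


def naive_class_frequency(table: PileupTable, ref_base: str, alt_base: str) -> list[float]:
    """Per-position ref>alt percentages by read-level recounting."""
    out = []
    for _, row in table.rows.iterrows():
        if row["ref_base"] != ref_base:
            continue
        calls = expand_reads(row)
        if not calls:
            out.append(float("nan"))
            continue
        out.append(100.0 * sum(1 for c in calls if c == alt_base) / len(calls))
    return out


def brute_force_window(depths, window_len: int, min_depth: int):
    """Exhaustive scan over every candidate start (the find_window oracle)."""
    L = len(depths)
    for start in range(1, L - window_len + 2):
        if all(depths[i] >= min_depth for i in range(start - 1, start - 1 + window_len)):
            return (start, start + window_len - 1)
    return None
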