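"""Candidate-gene windowed substitution analysis and variant quality filtering.

The short-read arm compares class-specific substitution frequencies (A>G,
C>G, U>G — the readouts of inosine after reverse transcription) between
genotypes inside the first contiguous 1 kb window from a transcript's 5'
end where every position has at least 50x coverage. Variant calls are
pre-filtered at Q >= 20.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RNA_BASES, PileupTable, VariantRecord

DEFAULT_WINDOW_LEN = 1000
DEFAULT_MIN_DEPTH = 50
DEFAULT_MIN_Q = 20.0


@dataclass(frozen=True)
class WindowResult:
    """A qualifying window plus its pooled class substitution frequencies."""

    gene_id: str
    window_start: int
    window_end: int
    min_depth_observed: int
    class_frequencies: dict[str, float]
    replicate_frequencies: dict[str, list[float]] | None = None

    @property
    def length(self) -> int:
        return self.window_end - self.window_start + 1


def filter_variants(records: list[VariantRecord], min_q: float = DEFAULT_MIN_Q) -> list[VariantRecord]:
    """Keep records with QUAL >= min_q (boundary inclusive), order preserved."""
    return [r for r in records if r.qual >= min_q]


def count_variants_by_class(records: list[VariantRecord],
                            classes: list[str] | None = None) -> tuple[dict[str, int], int]:
    """Tally records by substitution class keyed as 'X>Y' in RNA alphabet.

    When ``classes`` is given, every requested class appears in the map
    (zero rather than a missing key); otherwise observed classes only.
    """
    counts: dict[str, int] = {c: 0 for c in classes} if classes else {}
    total = 0
    for r in records:
        key = r.substitution_class
        if classes is not None and key not in counts:
            continue
        counts[key] = counts.get(key, 0) + 1
        total += 1
    if classes is None:
        total = len(records)
    return counts, total


def find_window(depths, window_len: int = DEFAULT_WINDOW_LEN,
                min_depth: int = DEFAULT_MIN_DEPTH,
                *, criterion: str = "pointwise") -> tuple[int, int] | None:
    """First 5'-most window of ``window_len`` positions clearing ``min_depth``.

    ``depths`` indexes positions 1..L from the 5' end. Returns (start, end),
    1-based inclusive, or None when no such window exists. 'Continuous 1 kb
    50x stretch' is read pointwise by default: every position in the window
    must satisfy the depth threshold; ``criterion="mean"`` instead requires
    the window mean to clear it.
    """
    depths = np.asarray(depths, dtype=float)
    L = len(depths)
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if criterion not in ("pointwise", "mean"):
        raise ValueError("criterion must be 'pointwise' or 'mean'")
    if window_len > L:
        warnings.warn(
            f"window length {window_len} exceeds track length {L}", stacklevel=2
        )
        return None
    if criterion == "mean":
        kernel = np.ones(window_len) / window_len
        means = np.convolve(depths, kernel, mode="valid")
        hits = np.nonzero(means >= min_depth - 1e-12)[0]
        if len(hits) == 0:
            return None
        start = int(hits[0]) + 1    # 1-based
        return start, start + window_len - 1
    ok = depths >= min_depth
    # run length of consecutive qualifying positions ending at each index
    run = np.zeros(L, dtype=np.int64)
    acc = 0
    for i in range(L):
        acc = acc + 1 if ok[i] else 0
        run[i] = acc
    hits = np.nonzero(run >= window_len)[0]
    if len(hits) == 0:
        return None
    end = int(hits[0]) + 1          # 1-based
    return end - window_len + 1, end


def window_class_frequency(table: PileupTable, window: tuple[int, int],
                           ref_base: str, alt_base: str) -> float:
    """Pooled class substitution frequency inside a window (percent).

    Pools raw counts across the window's positions of the given reference
    base: 100 * sum(count_alt) / sum(matches + mismatches). NaN (flagged by
    the caller) when the window holds no position of ``ref_base``. Pooling
    equals the depth-weighted mean of positional class frequencies.
    """
    for b in (ref_base, alt_base):
        if b not in RNA_BASES:
            raise ValueError(f"invalid base symbol {b!r}")
    start, end = window
    df = table.rows
    if start < int(df["pos"].iloc[0]) or end > int(df["pos"].iloc[-1]):
        raise ValueError(f"window {window} outside table positions")
    sel = df[(df["pos"] >= start) & (df["pos"] <= end) & (df["ref_base"] == ref_base)]
    if len(sel) == 0:
        return math.nan
    total = float((sel["matches"] + sel["mismatches"]).sum())
    if total == 0:
        return math.nan
    return 100.0 * float(sel[f"count_{alt_base}"].sum()) / total


def analyze_gene(table: PileupTable, ref_base: str, alt_base: str,
                 window_len: int = DEFAULT_WINDOW_LEN,
                 min_depth: int = DEFAULT_MIN_DEPTH) -> WindowResult | None:
    """Locate the qualifying window for one gene and compute its class frequency."""
    depths = table.rows["depth"].to_numpy()
    window = find_window(depths, window_len, min_depth)
    if window is None:
        return None
    start, end = window
    in_win = table.rows[(table.rows["pos"] >= start) & (table.rows["pos"] <= end)]
    return WindowResult(
        gene_id=table.ref_id,
        window_start=start, window_end=end,
        min_depth_observed=int(in_win["depth"].min()),
        class_frequencies={
            f"{ref_base}>{alt_base}": window_class_frequency(table, window, ref_base, alt_base)
        },
    )


@dataclass(frozen=True)
class GroupComparison:
    """Replicate-level comparison of window frequencies between genotypes."""

    mean_difference: float
    statistic: float | None
    df: float | None
    p_value: float | None
    method: str
    exact_separation: bool = False


def compare_windows(group_a, group_b) -> GroupComparison:
    """Two-group comparison of replicate window frequencies.

    With >= 2 replicates per group runs a two-sided unpaired equal-variance
    t-test; with fewer, descriptive output only (no p-value). Zero pooled
    variance with unequal means is flagged as exact separation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    diff = float(b.mean() - a.mean())
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(diff, None, None, None, "descriptive")
    if np.var(a) == 0 and np.var(b) == 0:
        if diff == 0:
            return GroupComparison(diff, 0.0, float(len(a) + len(b) - 2), 1.0, "t")
        return GroupComparison(diff, None, None, None, "t", exact_separation=True)
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return GroupComparison(diff, float(t), float(len(a) + len(b) - 2), float(p), "t")


def compare_panel(control: list[float], genes: dict[str, list[float]]) -> pd.DataFrame:
    """Multi-gene panel versus a shared control: one-way ANOVA F plus
    Dunnett-adjusted comparisons against the control group.

    Returns a frame with one row per gene: mean difference, Dunnett
    statistic and adjusted p-value, plus the shared ANOVA F and p.
    """
    names = list(genes)
    samples = [np.asarray(genes[n], dtype=float) for n in names]
    ctrl = np.asarray(control, dtype=float)
    if len(ctrl) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 replicates per group for the panel test")
    f_stat, f_p = stats.f_oneway(ctrl, *samples)
    dunnett = stats.dunnett(*samples, control=ctrl)
    return pd.DataFrame({
        "gene": names,
        "mean_difference": [float(s.mean() - ctrl.mean()) for s in samples],
        "statistic": dunnett.statistic,
        "p_adjusted": dunnett.pvalue,
        "anova_F": float(f_stat),
        "anova_p": float(f_p),
    })
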