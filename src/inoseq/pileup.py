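"""Per-position substitution statistics over pileup tables.

The central statistic is the base substitution frequency at a position,

    100 * mismatches / (matches + mismatches),

the proxy for inosine misincorporation in both the direct-RNA and the
short-read arms of the analysis. Per-base accuracy is 100 minus the mean of
that base's positional frequencies; its ranking across A/C/G/U is the
accuracy hierarchy. N calls and deletions never enter the numerator or the
denominator. Positions with zero evaluated calls are undefined (NaN),
excluded from means and tallies, and reported in a QC summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RNA_BASES, PileupTable


def substitution_frequency(matches: float, mismatches: float) -> float:
    """Percent of evaluated calls that mismatch; NaN when no calls."""
    if matches < 0 or mismatches < 0:
        raise ValueError("matches and mismatches must be non-negative")
    total = matches + mismatches
    if total == 0:
        return math.nan
    return 100.0 * mismatches / total


@dataclass
class SubstitutionProfile:
    """Positional substitution frequencies and derived per-base accuracies.

    ``per_position`` columns: pos, ref_base, frequency (percent, NaN where
    matches+mismatches is 0). ``per_base_accuracy`` maps base -> percent.
    """

    ref_id: str
    per_position: pd.DataFrame
    per_base_accuracy: dict[str, float]
    class_frequencies: dict[str, float]
    n_undefined: int = 0
    depth_weighted: bool = False

    @property
    def frequencies(self) -> np.ndarray:
        return self.per_position["frequency"].to_numpy()


@dataclass
class DeltaProfile:
    """Positionwise difference of substitution frequencies (treated − control)."""

    ref_id: str
    per_position: pd.DataFrame  # pos, ref_base, delta (NaN where excluded)
    n_enriched_treated: int
    n_enriched_control: int
    n_ties: int
    n_excluded: int
    tie_epsilon: float = 0.0

    @property
    def n_evaluated(self) -> int:
        return self.n_enriched_treated + self.n_enriched_control + self.n_ties


def _position_frequencies(table: PileupTable) -> pd.DataFrame:
    df = table.rows
    total = (df["matches"] + df["mismatches"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, 100.0 * df["mismatches"].to_numpy() / total, np.nan)
    return pd.DataFrame({
        "pos": df["pos"], "ref_base": df["ref_base"],
        "frequency": freq, "evaluated": total,
    })


def profile(table: PileupTable, *, depth_weighted: bool = False) -> SubstitutionProfile:
    """Compute the substitution profile for one pileup table.

    Per-base accuracy averages positional frequencies unweighted by default
    (each position counts once); ``depth_weighted=True`` weights positions by
    their evaluated call count instead.
    """
    per_pos = _position_frequencies(table)
    defined = per_pos.dropna(subset=["frequency"])

    accuracy: dict[str, float] = {}
    for base in RNA_BASES:
        sub = defined[defined["ref_base"] == base]
        if len(sub) == 0:
            accuracy[base] = math.nan
            continue
        if depth_weighted:
            mean_freq = np.average(sub["frequency"], weights=sub["evaluated"])
        else:
            mean_freq = sub["frequency"].mean()
        accuracy[base] = 100.0 - float(mean_freq)

    class_freqs: dict[str, float] = {}
    for ref_base in RNA_BASES:
        for alt_base in RNA_BASES:
            if alt_base == ref_base:
                continue
            per, mean = class_frequency(table, ref_base, alt_base)
            class_freqs[f"{ref_base}>{alt_base}"] = mean

    return SubstitutionProfile(
        ref_id=table.ref_id,
        per_position=per_pos[["pos", "ref_base", "frequency"]],
        per_base_accuracy=accuracy,
        class_frequencies=class_freqs,
        n_undefined=int(per_pos["frequency"].isna().sum()),
        depth_weighted=depth_weighted,
    )


def class_frequency(table: PileupTable, ref_base: str, alt_base: str) -> tuple[pd.DataFrame, float]:
    """Substitution frequency restricted to one ref>alt class.

    Returns per-position percentages, 100*count_alt/(matches+mismatches), at
    positions whose reference base is ``ref_base``, and their unweighted mean
    (NaN if no such position is defined). A table with no positions of
    ``ref_base`` yields an empty frame, not an error.
    """
    for b in (ref_base, alt_base):
        if b not in RNA_BASES:
            raise ValueError(f"invalid base symbol {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref_base and alt_base must differ")
    df = table.rows[table.rows["ref_base"] == ref_base]
    total = (df["matches"] + df["mismatches"]).to_numpy(dtype=float)
    alt = df[f"count_{alt_base}"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, 100.0 * alt / total, np.nan)
    per = pd.DataFrame({"pos": df["pos"].to_numpy(), "frequency": freq})
    mean = float(np.nanmean(freq)) if np.isfinite(freq).any() else math.nan
    return per, mean


def delta_profile(control: SubstitutionProfile, treated: SubstitutionProfile,
                  *, tie_epsilon: float = 0.0) -> DeltaProfile:
    """Positionwise treated − control frequency difference with sign tallies.

    Positions undefined in either profile are excluded and counted; the
    remaining positions are tallied as enriched-treated (delta > eps),
    enriched-control (delta < −eps) or ties (|delta| ≤ eps).
    """
    if control.ref_id != treated.ref_id:
        raise ValueError(
            f"reference mismatch: {control.ref_id!r} vs {treated.ref_id!r}"
        )
    a = control.per_position.set_index("pos")
    b = treated.per_position.set_index("pos")
    if not a.index.equals(b.index):
        raise ValueError("profiles cover different position sets")
    delta = b["frequency"] - a["frequency"]
    defined = delta.dropna()
    n_treated = int((defined > tie_epsilon).sum())
    n_control = int((defined < -tie_epsilon).sum())
    n_ties = int(len(defined) - n_treated - n_control)
    out = pd.DataFrame({
        "pos": a.index, "ref_base": a["ref_base"].to_numpy(),
        "delta": delta.to_numpy(),
    })
    return DeltaProfile(
        ref_id=control.ref_id, per_position=out,
        n_enriched_treated=n_treated, n_enriched_control=n_control,
        n_ties=n_ties, n_excluded=int(delta.isna().sum()),
        tie_epsilon=tie_epsilon,
    )


def fold_change(freq_null: float, freq_wt: float) -> float:
    """Ratio of substitution frequencies (e.g. knockout over wild type).

    NaN (an undefined marker, never an exception) when the denominator is 0
    so batch computation over many positions cannot abort.
    """
    if freq_wt == 0:
        return math.nan
    return freq_null / freq_wt


def accuracy_hierarchy(prof: SubstitutionProfile) -> tuple[list[str], bool]:
    """Bases ordered by descending per-base accuracy.

    Ties are broken alphabetically and flagged; bases absent from the
    reference (NaN accuracy) are dropped from the ordering with a warning
    left to the caller via the shortened list.
    """
    defined = {b: acc for b, acc in prof.per_base_accuracy.items() if not math.isnan(acc)}
    ordered = sorted(defined, key=lambda b: (-defined[b], b))
    values = sorted(defined.values(), reverse=True)
    has_tie = any(math.isclose(x, y) for x, y in zip(values, values[1:]))
    return ordered, has_tie


def qc_summary(prof: SubstitutionProfile) -> dict:
    """Counts of defined/undefined positions and the mean defined frequency."""
    freq = prof.frequencies
    defined = freq[~np.isnan(freq)]
    return {
        "ref_id": prof.ref_id,
        "n_positions": len(freq),
        "n_undefined": prof.n_undefined,
        "mean_frequency": float(defined.mean()) if len(defined) else math.nan,
    }
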