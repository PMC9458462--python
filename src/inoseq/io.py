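"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive. DNA input (T) is normalized to the
RNA alphabet (U) at the reader boundary; ambiguity codes are rejected.

Formats
-------
* FASTA — reference transcripts (Bio.SeqIO behind the scenes).
* Pileup statistics TSV — per-position counts with header columns at least
  ``{chrom, pos, ref, reads_all, matches, mismatches, A, C, G, T, N,
  deletions}`` (the dialect emitted by standard pileup-statistics tools);
  extra columns are ignored.
* Minimal VCF 4.x — only CHROM/POS/REF/ALT/QUAL are consumed
  (pysam.VariantFile behind the scenes).
* Polysome trace CSV — two numeric columns ``position,absorbance``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")

PILEUP_COLUMNS = [
    "pos", "ref_base", "depth", "matches", "mismatches",
    "count_A", "count_C", "count_G", "count_U", "count_N", "count_del",
]

#: external TSV header -> internal column names
_PILEUP_TSV_MAP = {
    "pos": "pos", "ref": "ref_base", "reads_all": "depth",
    "matches": "matches", "mismatches": "mismatches",
    "A": "count_A", "C": "count_C", "G": "count_G", "T": "count_U",
    "N": "count_N", "deletions": "count_del",
}


class FormatError(ValueError):
    """Raised when an input file violates its expected dialect."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T->U; reject anything outside {A,C,G,U}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise FormatError(
            f"{context}: non-ACGTU characters {sorted(bad)} (ambiguity codes rejected)"
        )
    return s


# ---------------------------------------------------------------------------
# Transcript references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRef:
    """A reference transcript in the RNA alphabet with its base composition."""

    id: str
    seq: str
    length: int = field(init=False)
    base_fractions: dict[str, float] = field(init=False)

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        seq = normalize_rna(self.seq, context=f"record {self.id!r}")
        object.__setattr__(self, "seq", seq)
        object.__setattr__(self, "length", len(seq))
        fractions = {b: seq.count(b) / len(seq) for b in RNA_BASES}
        object.__setattr__(self, "base_fractions", fractions)

    def base_at(self, pos: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        return self.seq[pos - 1]


def read_fasta(path) -> list[TranscriptRef]:
    """Read all records from a FASTA file as normalized transcript refs."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(TranscriptRef(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, refs: list[TranscriptRef]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in refs],
        str(path), "fasta",
    )


# ---------------------------------------------------------------------------
# Pileup tables
# ---------------------------------------------------------------------------

@dataclass
class PileupTable:
    """Per-position tallies of aligned base calls against one reference.

    ``rows`` is a DataFrame with columns :data:`PILEUP_COLUMNS`, ordered by
    strictly increasing 1-based ``pos``. ``matches`` equals the count of the
    reference base and ``mismatches`` the sum of the three non-reference
    canonical base counts; N calls and deletions never count toward either.
    """

    ref_id: str
    rows: pd.DataFrame

    def __post_init__(self):
        self.rows = self.rows.reset_index(drop=True)[PILEUP_COLUMNS]

    def __len__(self) -> int:
        return len(self.rows)

    def validate(self, ref: TranscriptRef | None = None, *, strict: bool = True) -> "PileupTable":
        """Enforce the table invariants.

        In strict mode any disagreement between the matches/mismatches columns
        and the per-base counts is an error; in lenient mode matches and
        mismatches are recomputed from the per-base counts with a warning.
        """
        df = self.rows
        count_cols = ["count_A", "count_C", "count_G", "count_U", "count_N", "count_del"]
        num = df[["pos", "depth", "matches", "mismatches"] + count_cols]
        if (num.to_numpy() < 0).any():
            raise FormatError(f"{self.ref_id}: negative counts in pileup table")
        if len(df) == 0:
            raise FormatError(f"{self.ref_id}: empty pileup table")
        if not df["pos"].is_monotonic_increasing or df["pos"].duplicated().any():
            raise FormatError(f"{self.ref_id}: positions not strictly increasing")
        bad_base = ~df["ref_base"].isin(RNA_BASES)
        if bad_base.any():
            raise FormatError(
                f"{self.ref_id}: invalid reference base at pos "
                f"{df.loc[bad_base, 'pos'].iloc[0]}"
            )
        if ref is not None:
            if int(df["pos"].iloc[-1]) > ref.length:
                raise FormatError(
                    f"{self.ref_id}: position {int(df['pos'].iloc[-1])} beyond "
                    f"transcript length {ref.length}"
                )
            expected = np.array([ref.base_at(int(p)) for p in df["pos"]])
            disagree = expected != df["ref_base"].to_numpy()
            if disagree.any():
                p = int(df.loc[disagree, "pos"].iloc[0])
                raise FormatError(
                    f"{self.ref_id}: reference-base disagreement at pos {p} "
                    f"(table {df.loc[disagree, 'ref_base'].iloc[0]!r}, "
                    f"reference {ref.base_at(p)!r})"
                )

        ref_count = self._ref_base_counts(df)
        alt_count = df[["count_A", "count_C", "count_G", "count_U"]].sum(axis=1) - ref_count
        m_bad = (df["matches"] != ref_count) | (df["mismatches"] != alt_count)
        if m_bad.any():
            if strict:
                p = int(df.loc[m_bad, "pos"].iloc[0])
                raise FormatError(
                    f"{self.ref_id}: matches/mismatches disagree with per-base "
                    f"counts at pos {p} (strict mode)"
                )
            log.warning(
                "%s: recomputing matches/mismatches from per-base counts at %d rows",
                self.ref_id, int(m_bad.sum()),
            )
            df = df.copy()
            df["matches"] = ref_count
            df["mismatches"] = alt_count
            self.rows = df
        if ((df["matches"] + df["mismatches"]) > df["depth"]).any():
            raise FormatError(f"{self.ref_id}: matches + mismatches exceed depth")
        return self

    @staticmethod
    def _ref_base_counts(df: pd.DataFrame) -> pd.Series:
        counts = np.zeros(len(df), dtype=np.int64)
        for b in RNA_BASES:
            sel = (df["ref_base"] == b).to_numpy()
            counts[sel] = df.loc[sel, f"count_{b}"]
        return pd.Series(counts, index=df.index)


def read_pileup_tsv(path, ref: TranscriptRef | None = None, *, strict: bool = True) -> PileupTable:
    """Read a pileup statistics TSV, validating against ``ref`` if given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty pileup file") from None
    missing = set(_PILEUP_TSV_MAP) | {"chrom"}
    missing -= set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pileup columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: pileup file has a header but no rows")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise FormatError(f"{path}: expected a single chromosome, found {list(chroms)}")
    out = df.rename(columns=_PILEUP_TSV_MAP)[list(_PILEUP_TSV_MAP.values())]
    out["ref_base"] = out["ref_base"].astype(str).str.upper().str.replace("T", "U")
    table = PileupTable(ref_id=str(chroms[0]), rows=out)
    return table.validate(ref, strict=strict)


def write_pileup_tsv(path, table: PileupTable) -> None:
    inv = {v: k for k, v in _PILEUP_TSV_MAP.items()}
    df = table.rows.rename(columns=inv)
    df.insert(0, "chrom", table.ref_id)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One biallelic substitution call: CHROM/POS/REF/ALT/QUAL only."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    qual_missing: bool = False

    def __post_init__(self):
        if self.qual < 0:
            raise FormatError(f"{self.chrom}:{self.pos}: negative QUAL")
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos}: REF equals ALT")

    @property
    def substitution_class(self) -> str:
        """Class key like ``'C>G'`` in the RNA alphabet."""
        return f"{normalize_rna(self.ref)}>{normalize_rna(self.alt)}"


def read_vcf_minimal(path) -> list[VariantRecord]:
    """Read CHROM/POS/REF/ALT/QUAL from a VCF, splitting multi-allelic ALTs.

    A missing QUAL ('.') is treated as 0 and flagged so that downstream
    quality filters exclude the record (conservative).
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            qual_missing = rec.qual is None
            if qual_missing:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos}: missing QUAL treated as 0",
                    stacklevel=2,
                )
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        qual=0.0 if qual_missing else float(rec.qual),
                        qual_missing=qual_missing,
                    )
                )
    return records


def write_vcf_minimal(path, records: list[VariantRecord], contigs: dict[str, int] | None = None) -> None:
    """Write records as a minimal VCF 4.2 text file."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            qual = "." if r.qual_missing else f"{r.qual:g}"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t.\n")


# ---------------------------------------------------------------------------
# Polysome absorbance traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileTrace:
    """An A254 absorbance trace over a gradient coordinate."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if pos.ndim != 1 or ab.shape != pos.shape:
            raise FormatError("positions and absorbance must be 1-D and equal length")
        if len(pos) < 3:
            raise FormatError("trace needs at least 3 points")
        if np.isnan(pos).any() or np.isnan(ab).any():
            raise FormatError("trace contains NaN")
        if not (np.diff(pos) > 0).all():
            raise FormatError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return len(self.positions)


def read_profile_csv(path) -> ProfileTrace:
    df = pd.read_csv(path)
    if not {"position", "absorbance"} <= set(df.columns):
        raise FormatError(f"{path}: expected header 'position,absorbance'")
    df = df.sort_values("position")  # duplicates still rejected downstream
    return ProfileTrace(df["position"].to_numpy(), df["absorbance"].to_numpy())


def write_profile_csv(path, trace: ProfileTrace) -> None:
    pd.DataFrame({"position": trace.positions, "absorbance": trace.absorbance}).to_csv(
        path, index=False
    )
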