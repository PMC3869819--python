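"""Quality-filtered base counts and substitution frequencies per pool.

The upstream aligner's per-pool output is consumed as SAMtools mpileup
text (chrom, 1-based position, reference base, depth, read bases,
base qualities).  Bases at or below the Phred quality cutoff are
discarded (the default keeps bases with Phred > 20), strands are
collapsed, and indel/read-boundary markup is consumed per the mpileup
grammar without contributing to substitution counts.  Deletions and Ns
are excluded from both the numerator and the filtered depth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["amplicon", "pos", "ref", "A", "C", "G", "T", "depth"]


class PileupError(ValueError):
    """Malformed mpileup input; message carries the 1-based line number."""


@dataclass
class BaseCountMatrix:
    """Per-pool, per-position counts of A/C/G/T passing the quality filter.

    ``data`` is a DataFrame with columns amplicon, pos (1-based), ref,
    A, C, G, T, depth where depth is the filtered depth (sum of the four
    base counts).
    """

    pool_id: int
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        self.data = self.data[COUNT_COLUMNS].reset_index(drop=True)
        counts = self.data[list(BASES)].to_numpy()
        if (counts < 0).any():
            raise ValueError("negative base counts")
        if not (counts.sum(axis=1) == self.data["depth"].to_numpy()).all():
            raise ValueError("depth must equal the sum of A/C/G/T counts")

    def to_tsv(self, path) -> None:
        out = self.data.rename(
            columns={b: f"n{b}" for b in BASES}
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pool_id: int) -> "BaseCountMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns={f"n{b}": b for b in BASES})
        return cls(pool_id=pool_id, data=df)

    def equals(self, other: "BaseCountMatrix") -> bool:
        a = self.data.sort_values(["amplicon", "pos"]).reset_index(drop=True)
        b = other.data.sort_values(["amplicon", "pos"]).reset_index(drop=True)
        return a.equals(b)


def _parse_bases(bases: str, quals: str, ref: str, min_q: int, offset: int,
                 lineno: int) -> dict[str, int]:
    """Walk one mpileup base string, returning quality-passing base counts."""
    counts = dict.fromkeys(BASES, 0)
    ref = ref.upper()
    i = 0  # index into bases
    q = 0  # index into quals
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":  # read start; next char is mapping quality
            i += 2
            continue
        if ch == "$":  # read end marker
            i += 1
            continue
        if ch in "+-":  # indel: +NN<seq> / -NN<seq>, no quality char
            i += 1
            start = i
            while i < n and bases[i].isdigit():
                i += 1
            if i == start:
                raise PileupError(f"line {lineno}: indel without length")
            i += int(bases[start:i])
            continue
        # every remaining symbol consumes one base-quality character
        if q >= len(quals):
            raise PileupError(
                f"line {lineno}: base string longer than quality string"
            )
        phred = ord(quals[q]) - offset
        q += 1
        i += 1
        if phred <= min_q:
            continue
        if ch in ".,":
            if ref in counts:
                counts[ref] += 1
        elif ch.upper() in counts:
            counts[ch.upper()] += 1
        elif ch in "*#><Nn":
            continue  # deletion / reference skip / ambiguous: not counted
        else:
            raise PileupError(f"line {lineno}: unexpected symbol {ch!r}")
    if q != len(quals):
        raise PileupError(
            f"line {lineno}: quality string longer than base string"
        )
    return counts


def counts_from_pileup(stream: TextIO | str, pool_id: int = 0,
                       min_base_quality: int = 20,
                       quality_offset: int = 33) -> BaseCountMatrix:
    """Parse mpileup text into a :class:`BaseCountMatrix`.

    Bases with Phred score <= ``min_base_quality`` are excluded (the
    default mirrors a strict ">20 Phred" filter).  Qualities are decoded
    as ASCII − ``quality_offset`` (Phred+33, Illumina 1.8+).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupError(
                f"line {lineno}: expected >=6 tab-separated fields, got {len(fields)}"
            )
        chrom, pos, ref, _depth, bases, quals = fields[:6]
        try:
            pos_i = int(pos)
        except ValueError:
            raise PileupError(f"line {lineno}: non-integer position {pos!r}") from None
        counts = _parse_bases(bases, quals, ref, min_base_quality,
                              quality_offset, lineno)
        records.append(
            {"amplicon": chrom, "pos": pos_i, "ref": ref.upper(), **counts,
             "depth": sum(counts.values())}
        )
    df = pd.DataFrame(records, columns=COUNT_COLUMNS)
    if df.empty:
        df = df.astype({"pos": int, "A": int, "C": int, "G": int, "T": int,
                        "depth": int}, errors="ignore")
    return BaseCountMatrix(pool_id=pool_id, data=df)


def write_mpileup(counts: BaseCountMatrix, path, quality_char: str = "I") -> None:
    """Serialise a count matrix as mpileup text.

    Reference reads are written as '.', alternates as upper-case bases,
    all at the Phred quality encoded by ``quality_char`` (default 'I',
    Phred 40).  Round-trips exactly through :func:`counts_from_pileup`.
    """
    with open(path, "w") as fh:
        for row in counts.data.itertuples(index=False):
            ref = row.ref
            parts = []
            for base in BASES:
                k = getattr(row, base)
                parts.append(("." if base == ref else base) * k)
            bases = "".join(parts)
            fh.write(
                f"{row.amplicon}\t{row.pos}\t{ref}\t{row.depth}\t"
                f"{bases}\t{quality_char * row.depth}\n"
            )


def frequencies(counts: BaseCountMatrix) -> pd.DataFrame:
    """Long-format substitution frequency table for one pool.

    One row per (amplicon, pos, ref→alt) with alt != ref:
    freq = alt count / filtered depth.  Zero-depth positions are kept
    with freq = NaN and no_data = True rather than divided.
    """
    frames = []
    base = counts.data
    for alt in BASES:
        sub = base[base["ref"] != alt][["amplicon", "pos", "ref", "depth", alt]]
        sub = sub.rename(columns={alt: "alt_count"})
        sub["alt"] = alt
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out["pool"] = counts.pool_id
    depth = out["depth"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, out["alt_count"] / np.maximum(depth, 1), np.nan)
    out["freq"] = np.where(depth > 0, freq, np.nan)
    out["no_data"] = depth == 0
    cols = ["pool", "amplicon", "pos", "ref", "alt", "alt_count", "depth",
            "freq", "no_data"]
    return out[cols].sort_values(["amplicon", "pos", "alt"]).reset_index(drop=True)


def combined_frequencies(count_matrices: Iterable[BaseCountMatrix]) -> pd.DataFrame:
    """Concatenate per-pool frequency tables into one long table."""
    frames = [frequencies(m) for m in count_matrices]
    if not frames:
        raise ValueError("no count matrices given")
    return pd.concat(frames, ignore_index=True)
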