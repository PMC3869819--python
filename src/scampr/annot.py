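"""Effect prediction for point mutations on a gene product.

Classifies each substitution against a gene model (exon and CDS
intervals on the amplicon) into one of five classes:

* ``splice``     — within the first or last 2 bases of an intron
                   (the canonical GT–AG dinucleotides);
* ``nonsense``   — the altered codon becomes a stop;
* ``missense``   — the encoded amino acid changes;
* ``silent``     — synonymous codon change;
* ``noncoding``  — outside the CDS (introns, UTRs) and not splice.

For summary reporting the five classes collapse into three groups:
nonsense+splice (gene-truncating), missense, and silent+noncoding.
The standard nuclear genetic code is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

SPLICE_WINDOW = 2  # intronic bases at each junction treated as splice sites


class EffectClass(str, Enum):
    NONSENSE = "nonsense"
    SPLICE = "splice"
    MISSENSE = "missense"
    SILENT = "silent"
    NONCODING = "noncoding"

    @property
    def reporting_group(self) -> str:
        if self in (EffectClass.NONSENSE, EffectClass.SPLICE):
            return "nonsense"
        if self is EffectClass.MISSENSE:
            return "missense"
        return "silent"


REPORTING_GROUPS = ("nonsense", "missense", "silent")


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """Exon/CDS structure of (part of) a gene on one amplicon.

    Intervals are 1-based inclusive in amplicon coordinates and must be
    sorted and non-overlapping; ``strand`` gives the orientation of the
    coding sequence relative to the amplicon.  The modelled CDS length
    must be a whole number of codons.
    """

    amplicon: str
    sequence: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for start, end in ivs:
                if start > end:
                    raise AnnotationError(f"{name} interval {start}-{end} inverted")
                if start <= prev_end:
                    raise AnnotationError(f"{name} intervals overlap or unsorted")
                if end > len(self.sequence):
                    raise AnnotationError(f"{name} interval beyond sequence end")
                prev_end = end
        if self.cds_length % 3 != 0:
            raise AnnotationError(
                f"CDS length {self.cds_length} is not a whole number of codons"
            )
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise AnnotationError("CDS interval not contained in an exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    # -- coordinate helpers ---------------------------------------------
    def _cds_positions(self) -> list[int]:
        """Amplicon positions of CDS bases in translation order."""
        pos = [p for s, e in self.cds for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_index(self, position: int) -> int | None:
        """0-based index of ``position`` within the coding sequence, or None."""
        try:
            return self._cds_positions().index(position)
        except ValueError:
            return None

    def in_exon(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    def splice_site(self, position: int) -> bool:
        for s, e in self.introns:
            if e - s + 1 < 2 * SPLICE_WINDOW:
                # short intron: the whole of it is junction-proximal
                if s <= position <= e:
                    return True
                continue
            if s <= position <= s + SPLICE_WINDOW - 1:
                return True
            if e - SPLICE_WINDOW + 1 <= position <= e:
                return True
        return False

    def shifted(self, offset: int) -> "GeneModel":
        """The same model with all coordinates moved by ``offset``
        (padding/trimming the sequence with 'N')."""
        if offset >= 0:
            seq = "N" * offset + self.sequence
        else:
            seq = self.sequence[-offset:]
        return GeneModel(
            amplicon=self.amplicon,
            sequence=seq,
            exons=[(s + offset, e + offset) for s, e in self.exons],
            cds=[(s + offset, e + offset) for s, e in self.cds],
            strand=self.strand,
        )


def _oriented(base: str, strand: str) -> str:
    return str(Seq(base).complement()) if strand == "-" else base


def annotate_effect(model: GeneModel, position: int, ref: str, alt: str
                    ) -> EffectClass:
    """Classify a substitution at ``position`` (amplicon coordinates)."""
    ref, alt = ref.upper(), alt.upper()
    if not 1 <= position <= len(model.sequence):
        raise AnnotationError(f"position {position} outside the model")
    if model.sequence[position - 1] != ref:
        raise AnnotationError(
            f"reference mismatch at {position}: model has "
            f"{model.sequence[position - 1]!r}, mutation says {ref!r} "
            "(coordinate error?)"
        )
    if ref == alt:
        raise AnnotationError("ref and alt must differ")
    if model.splice_site(position):
        return EffectClass.SPLICE
    idx = model.cds_index(position)
    if idx is None:
        return EffectClass.NONCODING
    cds_pos = model._cds_positions()
    codon_start = (idx // 3) * 3
    codon_positions = cds_pos[codon_start:codon_start + 3]
    ref_codon = "".join(
        _oriented(model.sequence[p - 1], model.strand) for p in codon_positions
    )
    alt_codon = "".join(
        _oriented(alt if p == position else model.sequence[p - 1], model.strand)
        for p in codon_positions
    )
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_alt == "*" and aa_ref != "*":
        return EffectClass.NONSENSE
    if aa_alt != aa_ref:
        return EffectClass.MISSENSE
    return EffectClass.SILENT


def summarize_effects(effects: Iterable[EffectClass | str]) -> pd.DataFrame:
    """Counts and percentages per reporting group.

    Percentages are count/total × 100 to one decimal, so a population
    with 18 truncating, 181 missense and 233 silent records reports
    4.2% / 41.9% / 53.9%.
    """
    effects = [EffectClass(e) for e in effects]
    if not effects:
        raise ValueError("no annotated records")
    counts = dict.fromkeys(REPORTING_GROUPS, 0)
    for e in effects:
        counts[e.reporting_group] += 1
    total = len(effects)
    return pd.DataFrame({
        "group": list(REPORTING_GROUPS),
        "count": [counts[g] for g in REPORTING_GROUPS],
        "percent": [round(counts[g] / total * 100, 1) for g in REPORTING_GROUPS],
    })


# ---------------------------------------------------------------------------
# gene-model readers
# ---------------------------------------------------------------------------

def gene_model_from_gff3(gff_path, amplicon: str, sequence: str,
                         ) -> GeneModel:
    """Build a model from a GFF3 subset (exon and CDS features).

    Only features on ``amplicon`` are used; the strand is taken from the
    CDS features.  Column 4/5 are 1-based inclusive per the GFF3 spec.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    strand = "+"
    for feat in db.all_features():
        if feat.seqid != amplicon:
            continue
        iv = (int(feat.start), int(feat.end))
        if feat.featuretype.lower() == "exon":
            exons.append(iv)
        elif feat.featuretype.lower() == "cds":
            cds.append(iv)
            if feat.strand in "+-":
                strand = feat.strand
    if not exons:
        exons = list(cds)
    return GeneModel(amplicon=amplicon, sequence=sequence,
                     exons=sorted(exons), cds=sorted(cds), strand=strand)


def gene_model_from_tsv(tsv_path, amplicon: str, sequence: str) -> GeneModel:
    """Simple TSV dialect: columns feature, start, end[, strand]."""
    df = pd.read_csv(tsv_path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    exons = [
        (int(r.start), int(r.end))
        for r in df[df["feature"].str.lower() == "exon"].itertuples()
    ]
    cds_rows = df[df["feature"].str.lower() == "cds"]
    cds = [(int(r.start), int(r.end)) for r in cds_rows.itertuples()]
    strand = "+"
    if "strand" in df.columns and not cds_rows.empty:
        strand = str(cds_rows["strand"].iloc[0])
    if not exons:
        exons = list(cds)
    return GeneModel(amplicon=amplicon, sequence=sequence,
                     exons=sorted(exons), cds=sorted(cds), strand=strand)


def annotate_records(records: pd.DataFrame, model: GeneModel) -> pd.DataFrame:
    """Add an ``effect`` column to a mutation-record table."""
    effects = [
        annotate_effect(model, int(r.pos), str(r.ref), str(r.alt)).value
        for r in records.itertuples()
    ]
    out = records.copy()
    out["effect"] = effects
    return out
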