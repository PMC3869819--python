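"""Population-level TILLING statistics.

Mutation density is reported the way the field prints it — "1 mutation
per N kb screened" — where the screened length of an amplicon excludes
100 bp at each end (200 bp total) because mutations within the primer-
proximal regions cannot be scored.  Aggregate density divides the total
screened DNA by the total mutation count, and extrapolates to mutations
per genome for a given genome size.  The spectrum summary collapses
substitutions by strand (G→A and C→T are one class) and the per-line
distribution counts how many lines carry 0, 1, 2, ... mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_EDGE_EXCLUSION = 200  # bp unscreenable at the two amplicon ends
DEFAULT_GENOME_SIZE_MB = 1132.0

TRANSITION_GC_AT = "G/C->A/T"
TRANSITION_AT_GC = "A/T->G/C"
TRANSVERSION_AT_CG = "A/T->C/G"
TRANSVERSION_AT_TA = "A/T->T/A"
TRANSVERSION_GC_TA = "G/C->T/A"
TRANSVERSION_GC_CG = "G/C->C/G"
INDEL = "indel"

_SUB_CLASS = {
    ("G", "A"): TRANSITION_GC_AT, ("C", "T"): TRANSITION_GC_AT,
    ("A", "G"): TRANSITION_AT_GC, ("T", "C"): TRANSITION_AT_GC,
    ("A", "C"): TRANSVERSION_AT_CG, ("T", "G"): TRANSVERSION_AT_CG,
    ("A", "T"): TRANSVERSION_AT_TA, ("T", "A"): TRANSVERSION_AT_TA,
    ("G", "T"): TRANSVERSION_GC_TA, ("C", "A"): TRANSVERSION_GC_TA,
    ("G", "C"): TRANSVERSION_GC_CG, ("C", "G"): TRANSVERSION_GC_CG,
}


@dataclass(frozen=True)
class AmpliconScreen:
    """One screened amplicon: mutation yield and screening effort."""

    amplicon: str
    gene: str
    mutations: int
    lines_screened: int
    size_bp: int

    def __post_init__(self) -> None:
        if self.mutations < 0 or self.lines_screened < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class DensityEstimate:
    amplicon: str
    screened_bp: int
    mutations: int
    kb_per_mutation: float | None  # None when no mutations were found

    @property
    def label(self) -> str:
        """Printed form '1/N' with N the nearest-integer kb."""
        if self.kb_per_mutation is None:
            return "none found"
        return f"1/{round(self.kb_per_mutation)}"


@dataclass
class DensityReport:
    per_amplicon: list[DensityEstimate]
    total_mutations: int
    total_screened_bp: int
    aggregate_kb_per_mutation: float
    genome_size_mb: float
    mutations_per_genome: float

    @property
    def aggregate_label(self) -> str:
        return f"1/{round(self.aggregate_kb_per_mutation)}"

    @property
    def mutations_per_genome_rounded(self) -> int:
        """Per-genome projection to the nearest hundred, as reported."""
        return int(round(self.mutations_per_genome, -2))


def screened_bp(screen: AmpliconScreen,
                edge_exclusion: int = DEFAULT_EDGE_EXCLUSION) -> int:
    if screen.size_bp <= edge_exclusion:
        raise ValueError(
            f"amplicon {screen.amplicon}: size {screen.size_bp} bp does not "
            f"exceed the {edge_exclusion} bp edge exclusion"
        )
    return screen.lines_screened * (screen.size_bp - edge_exclusion)


def mutation_density(screen: AmpliconScreen,
                     edge_exclusion: int = DEFAULT_EDGE_EXCLUSION
                     ) -> DensityEstimate:
    """Per-amplicon density in kb of screened DNA per mutation."""
    bp = screened_bp(screen, edge_exclusion)
    if screen.mutations == 0:
        return DensityEstimate(screen.amplicon, bp, 0, None)
    return DensityEstimate(
        amplicon=screen.amplicon,
        screened_bp=bp,
        mutations=screen.mutations,
        kb_per_mutation=bp / screen.mutations / 1000.0,
    )


def aggregate_density(screens: Sequence[AmpliconScreen],
                      edge_exclusion: int = DEFAULT_EDGE_EXCLUSION,
                      genome_size_mb: float = DEFAULT_GENOME_SIZE_MB
                      ) -> DensityReport:
    """Aggregate density and per-genome projection over many amplicons."""
    if not screens:
        raise ValueError("no screens given")
    per = [mutation_density(s, edge_exclusion) for s in screens]
    total_mut = sum(s.mutations for s in screens)
    total_bp = sum(screened_bp(s, edge_exclusion) for s in screens)
    if total_mut == 0:
        raise ValueError("no mutations across all screens")
    agg = total_bp / total_mut / 1000.0
    per_genome = genome_size_mb * 1000.0 / agg
    return DensityReport(
        per_amplicon=per,
        total_mutations=total_mut,
        total_screened_bp=total_bp,
        aggregate_kb_per_mutation=agg,
        genome_size_mb=genome_size_mb,
        mutations_per_genome=per_genome,
    )


def substitution_class(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class (indels are their own class)."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
        return INDEL
    try:
        return _SUB_CLASS[(ref, alt)]
    except KeyError:
        raise ValueError(f"not a substitution: {ref}>{alt}") from None


def spectrum(records: pd.DataFrame) -> dict:
    """Counts per substitution class and the percent G/C→A/T.

    ``records`` needs ``ref`` and ``alt`` columns; alleles of unequal
    length count as indels.  Percent is rounded to the nearest integer,
    matching how mutagen spectra are reported.
    """
    classes = [substitution_class(str(r.ref), str(r.alt))
               for r in records.itertuples()]
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    total = len(classes)
    gc_at = counts.get(TRANSITION_GC_AT, 0)
    return {
        "counts": counts,
        "total": total,
        "percent_gc_to_at": round(gc_at / total * 100) if total else 0,
    }


def per_line_distribution(records: pd.DataFrame,
                          n_lines_total: int | None = None) -> dict:
    """Histogram of mutations per line.

    ``records`` needs a ``line`` column (any hashable id).  When
    ``n_lines_total`` is given, lines without records fill the zero bin.
    """
    per_line = records.groupby("line").size() if len(records) else pd.Series(dtype=int)
    hist: dict[int, int] = dict(per_line.value_counts().sort_index())
    hist = {int(k): int(v) for k, v in hist.items()}
    if n_lines_total is not None:
        hist[0] = n_lines_total - sum(hist.values())
    return _distribution_summary(hist)


def distribution_from_histogram(hist: Mapping[int, int],
                                n_unique_mutations: int | None = None) -> dict:
    """Summary of a pre-tabulated per-line histogram.

    ``n_unique_mutations`` is the independently known count of unique
    mutations; when it differs from the Σ k·hist[k] assignment total the
    summary reports the discrepancy instead of reconciling it (lines
    sharing a mutation, or mutations in unscreened lines, are counted
    differently by the two tallies).
    """
    out = _distribution_summary({int(k): int(v) for k, v in hist.items()})
    if n_unique_mutations is not None:
        out["n_unique_mutations"] = int(n_unique_mutations)
        out["assignment_discrepancy"] = (
            int(n_unique_mutations) - out["total_assignments"]
        )
    return out


def _distribution_summary(hist: dict[int, int]) -> dict:
    lines_with = sum(v for k, v in hist.items() if k >= 1)
    assignments = sum(k * v for k, v in hist.items())
    return {
        "histogram": dict(sorted(hist.items())),
        "lines_with_mutation": lines_with,
        "total_assignments": assignments,
    }


# ---------------------------------------------------------------------------
# packaged survey tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    from importlib.resources import files

    return files("scampr.data").joinpath(name)


def load_screens() -> pd.DataFrame:
    """The packaged 26-amplicon screening survey (with printed densities)."""
    with _data_path("screens.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def screens_from_frame(df: pd.DataFrame) -> list[AmpliconScreen]:
    return [
        AmpliconScreen(
            amplicon=str(r.amplicon), gene=str(r.gene),
            mutations=int(r.mutations), lines_screened=int(r.lines_screened),
            size_bp=int(r.size_bp),
        )
        for r in df.itertuples()
    ]


def load_per_line_histogram() -> dict[int, int]:
    """Packaged per-line mutation-count histogram."""
    with _data_path("per_line.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {int(r.mutations_per_line): int(r.n_lines) for r in df.itertuples()}


def load_effect_counts() -> dict[str, int]:
    """Packaged effect-group counts for the screened mutation set."""
    with _data_path("effects.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {str(r.group): int(r.count) for r in df.itertuples()}


def load_spectrum_counts() -> dict[str, int]:
    """Packaged substitution-class counts for the screened mutation set."""
    with _data_path("spectrum.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {str(r.substitution_class): int(r.count) for r in df.itertuples()}


def load_ngs_candidates() -> pd.DataFrame:
    """Packaged NGS-trial candidate list (position, change, pool triple,
    validation wells)."""
    with _data_path("ngs_candidates.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
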