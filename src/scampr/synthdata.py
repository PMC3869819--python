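"""Simulator for pooled-amplicon sequencing of an EMS-mutagenised population.

Generates (i) a population truth table — planted point mutations with
line, zygosity and an alkylation-dominated substitution spectrum, plus
fixed homeologous SNP positions shared by every pool — and (ii) per-pool
quality-filtered base counts with binomial/multinomial sequencing noise,
matching the statistical structure the caller assumes:

* one heterozygous carrier in a 96-line pool contributes 1 of 192
  alleles, an expected alt fraction of ~0.52% (a homozygote twice that);
* homeologous SNPs appear at ``homeolog_freq`` in *all* pools;
* sequencing error is spread uniformly over the three non-reference
  bases at ``error_rate`` per sequenced base.

Counts are sampled per position as a multinomial over the four bases at
the configured depth; read-level artefacts (insert sizes, quality decay,
PCR duplicates) are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pileup import BASES, BaseCountMatrix, COUNT_COLUMNS, write_mpileup
from .pooling import LineAddress, PoolingDesign

HET_FRACTION_DEFAULT = 317 / 432  # observed het:hom split in a screened population
EMS_FORWARD = {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults are the canonical study conditions.

    depth
        Filtered reads per pool per position (5,000x keeps a 0.5%
        heterozygote signal ~25 reads above noise).
    error_rate
        Per-base miscall probability, split evenly over the three
        non-reference bases (5e-4 ~ the "<0.05%" noise of modern
        short-read data).
    density
        Planted mutations per kb per line.
    het_fraction
        Probability a planted mutation is heterozygous.
    spectrum_fraction
        Share of planted mutations that are G→A or C→T on the reference
        strand (EMS alkylation spectrum, ~0.99).
    homeolog_freq
        Alt-allele fraction at homeologous SNP positions, present in
        every pool (0.5 for a single locus amplified alongside one
        homeologous copy).
    """

    n_plates: int = 4
    depth: int = 5000
    error_rate: float = 5e-4
    density: float = 1 / 109
    het_fraction: float = HET_FRACTION_DEFAULT
    spectrum_fraction: float = 0.99
    homeolog_freq: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        for name in ("het_fraction", "spectrum_fraction", "homeolog_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass(frozen=True)
class PlantedMutation:
    line: LineAddress
    amplicon: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"

    @property
    def allele_copies(self) -> int:
        return 1 if self.zygosity == "het" else 2


@dataclass(frozen=True)
class HomeologSNP:
    amplicon: str
    pos: int
    ref: str
    alt: str
    freq: float


@dataclass
class SimTruth:
    """Planted mutations, homeolog positions and the generating parameters."""

    mutations: list[PlantedMutation]
    homeologs: list[HomeologSNP]
    amplicons: dict[str, str]
    params: SimParams

    def __post_init__(self) -> None:
        for m in self.mutations:
            seq = self.amplicons[m.amplicon]
            if not 1 <= m.pos <= len(seq):
                raise ValueError(f"mutation position {m.pos} outside amplicon")
            if m.ref == m.alt:
                raise ValueError("planted alt must differ from ref")
            if m.zygosity not in ("het", "hom"):
                raise ValueError(f"bad zygosity {m.zygosity!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate": m.line.plate, "well": m.line.well,
                "amplicon": m.amplicon, "pos": m.pos,
                "ref": m.ref, "alt": m.alt, "zygosity": m.zygosity,
            }
            for m in self.mutations
        ]
        return pd.DataFrame(
            rows, columns=["plate", "well", "amplicon", "pos", "ref", "alt",
                           "zygosity"],
        )


def _population(n_plates: int) -> list[LineAddress]:
    return [
        LineAddress(p, r, c)
        for p in range(1, n_plates + 1)
        for r in "ABCDEFGH"
        for c in range(1, 13)
    ]


def _draw_mutation(rng: np.random.Generator, line: LineAddress,
                   amplicons: Mapping[str, str], params: SimParams,
                   gc_sites: dict[str, np.ndarray]) -> PlantedMutation:
    amp_ids = sorted(amplicons)
    lengths = np.array([len(amplicons[a]) for a in amp_ids], dtype=float)
    zyg = "het" if rng.random() < params.het_fraction else "hom"
    if rng.random() < params.spectrum_fraction:
        # EMS-type: uniform over G/C sites across amplicons
        weights = np.array([len(gc_sites[a]) for a in amp_ids], dtype=float)
        if weights.sum() == 0:
            raise ValueError("no G/C sites available for EMS-type mutations")
        amp = amp_ids[rng.choice(len(amp_ids), p=weights / weights.sum())]
        pos = int(gc_sites[amp][rng.integers(len(gc_sites[amp]))])
        ref = amplicons[amp][pos - 1]
        alt = "A" if ref == "G" else "T"
    else:
        # any substitution other than the two EMS types
        while True:
            amp = amp_ids[rng.choice(len(amp_ids), p=lengths / lengths.sum())]
            pos = int(rng.integers(1, len(amplicons[amp]) + 1))
            ref = amplicons[amp][pos - 1]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            if (ref, alt) not in EMS_FORWARD:
                break
    return PlantedMutation(line, amp, pos, ref, alt, zyg)


def simulate_population(amplicons: Mapping[str, str], params: SimParams,
                        n_mutations: int | None = None,
                        n_homeologs: int = 0) -> SimTruth:
    """Plant mutations in a population of ``8 * 12 * n_plates`` lines.

    By default each line receives Poisson(density × total kb) mutations;
    ``n_mutations`` plants an exact total instead (carriers drawn
    uniformly), which is convenient for controlled recovery experiments.
    ``n_homeologs`` fixed homeologous SNP positions are placed uniformly,
    avoiding planted-mutation positions.
    """
    amplicons = {k: v.upper() for k, v in amplicons.items()}
    if not amplicons or any(len(s) == 0 for s in amplicons.values()):
        raise ValueError("amplicon sequences must be non-empty")
    rng = np.random.default_rng([params.seed, 1])
    lines = _population(params.n_plates)
    gc_sites = {
        a: np.array([i + 1 for i, b in enumerate(s) if b in "GC"], dtype=int)
        for a, s in amplicons.items()
    }
    total_kb = sum(len(s) for s in amplicons.values()) / 1000
    mutations: list[PlantedMutation] = []
    if n_mutations is None:
        for line in lines:
            k = rng.poisson(params.density * total_kb)
            for _ in range(k):
                mutations.append(
                    _draw_mutation(rng, line, amplicons, params, gc_sites)
                )
    else:
        for _ in range(n_mutations):
            line = lines[rng.integers(len(lines))]
            mutations.append(
                _draw_mutation(rng, line, amplicons, params, gc_sites)
            )
    taken = {(m.amplicon, m.pos) for m in mutations}
    homeologs: list[HomeologSNP] = []
    amp_ids = sorted(amplicons)
    lengths = np.array([len(amplicons[a]) for a in amp_ids], dtype=float)
    guard = 0
    while len(homeologs) < n_homeologs:
        guard += 1
        if guard > 10000:
            raise ValueError("could not place homeolog positions")
        amp = amp_ids[rng.choice(len(amp_ids), p=lengths / lengths.sum())]
        pos = int(rng.integers(1, len(amplicons[amp]) + 1))
        if (amp, pos) in taken:
            continue
        taken.add((amp, pos))
        ref = amplicons[amp][pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        homeologs.append(HomeologSNP(amp, pos, ref, alt, params.homeolog_freq))
    return SimTruth(mutations=mutations, homeologs=homeologs,
                    amplicons=dict(amplicons), params=params)


def simulate_pool_counts(truth: SimTruth, design: PoolingDesign,
                         params: SimParams | None = None
                         ) -> dict[int, BaseCountMatrix]:
    """Draw per-pool base counts for every amplicon position.

    Expected alt fraction at a planted site in a pool of ``s`` lines is
    (carrier allele copies)/(2s) plus the error floor; homeolog
    positions carry ``freq`` alt fraction in every pool.  Each pool uses
    an independent, deterministically derived random stream.
    """
    params = params or truth.params
    design_lines = design.lines
    for m in truth.mutations:
        if m.line not in design_lines:
            raise ValueError(f"carrier {m.line} is not covered by the design")
    base_index = {b: i for i, b in enumerate(BASES)}
    out: dict[int, BaseCountMatrix] = {}
    for pool_id in design.pool_ids:
        rng = np.random.default_rng([params.seed, 2, pool_id])
        members = design.membership[pool_id]
        pool_alleles = 2 * len(members)
        frames = []
        for amp in sorted(truth.amplicons):
            seq = truth.amplicons[amp]
            L = len(seq)
            probs = np.zeros((L, 4))
            ref_idx = np.array([base_index[b] for b in seq])
            # uniform error over the three non-reference bases
            probs[:] = params.error_rate / 3
            probs[np.arange(L), ref_idx] = 0.0
            signal = np.zeros((L, 4))
            for m in truth.mutations:
                if m.amplicon == amp and m.line in members:
                    signal[m.pos - 1, base_index[m.alt]] += (
                        m.allele_copies / pool_alleles
                    )
            for h in truth.homeologs:
                if h.amplicon == amp:
                    signal[h.pos - 1, base_index[h.alt]] += h.freq
            probs += signal
            row_sum = probs.sum(axis=1)
            if (row_sum > 1).any():
                raise ValueError("alt fractions exceed 1 at some position")
            probs[np.arange(L), ref_idx] = 1.0 - row_sum
            counts = rng.multinomial(params.depth, probs)
            frames.append(pd.DataFrame({
                "amplicon": amp,
                "pos": np.arange(1, L + 1),
                "ref": list(seq),
                "A": counts[:, 0], "C": counts[:, 1],
                "G": counts[:, 2], "T": counts[:, 3],
                "depth": counts.sum(axis=1),
            }))
        data = pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]
        out[pool_id] = BaseCountMatrix(pool_id=pool_id, data=data)
    return out


def write_fixture(truth: SimTruth, counts: Mapping[int, BaseCountMatrix],
                  design: PoolingDesign, directory) -> dict[str, Path]:
    """Write a complete on-disk fixture: count TSVs, mpileups, truth, design.

    Byte-reproducible for a fixed seed (no timestamps are written).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for pool_id in sorted(counts):
        tsv = directory / f"pool{pool_id:02d}.counts.tsv"
        counts[pool_id].to_tsv(tsv)
        paths[f"counts:{pool_id}"] = tsv
        mp = directory / f"pool{pool_id:02d}.mpileup"
        write_mpileup(counts[pool_id], mp)
        paths[f"mpileup:{pool_id}"] = mp
    truth_path = directory / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    design_path = directory / "design.json"
    design.to_json(design_path)
    paths["design"] = design_path
    fasta_path = directory / "amplicons.fasta"
    with open(fasta_path, "w") as fh:
        for amp in sorted(truth.amplicons):
            fh.write(f">{amp}\n")
            seq = truth.amplicons[amp]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["fasta"] = fasta_path
    return paths


def expected_alt_fraction(allele_copies: int = 1, pool_size: int = 96) -> float:
    """Expected alt-allele fraction for a carrier in a diploid pool.

    One heterozygote in a 96-line pool contributes 1 of 192 alleles,
    ~0.52%; a homozygote contributes 2 of 192.
    """
    if allele_copies < 0 or pool_size < 1:
        raise ValueError("allele_copies >= 0 and pool_size >= 1 required")
    return allele_copies / (2 * pool_size)


def random_amplicon(length: int, seed: int, gc: float = 0.42) -> str:
    """A random reference amplicon with the given GC content."""
    rng = np.random.default_rng([seed, 3])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))
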