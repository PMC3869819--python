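"""File formats, run configuration and the end-to-end pipeline.

All coordinates are 1-based inclusive throughout (mpileup and VCF
conventions); no other coordinate system appears anywhere in the
package.
"""

from __future__ import annotations

import glob as globmod
import json
import logging
import re
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .caller import (
    CandidateMutation,
    DEFAULT_ALPHA,
    DEFAULT_HOMEOLOG_MIN_FREQ,
    DEFAULT_HOMEOLOG_POOL_FRACTION,
    DEFAULT_MIN_CANDIDATE_FREQ,
    DEFAULT_MIN_DEPTH,
    call_candidates,
    candidates_to_frame,
)
from .pileup import BaseCountMatrix, combined_frequencies, counts_from_pileup
from .pooling import PoolingDesign

log = logging.getLogger("scampr")

IUPAC = set("ACGTRYSWKMBDHVN")


class ConfigError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Reference amplicons as an id → uppercase-sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in {rec.id!r}: {sorted(bad)}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_vcf(candidates: Sequence[CandidateMutation],
              reference: Mapping[str, str], path) -> None:
    """Write candidates as VCF 4.2 with pool/line evidence in INFO."""
    header = pysam.VariantHeader()
    header.add_line('##source=scampr')
    for info in (
        ('POOLS', '.', 'Integer', 'Significant (positive) pool ids'),
        ('PVALS', '.', 'Float', 'Per-positive-pool one-sided t-test p-values'),
        ('LINESET', '.', 'String', 'Decoded candidate wells (plate:well)'),
        ('EMS', 0, 'Flag', 'Substitution matches the EMS G/C-to-A/T signature'),
        ('HOMEOLOG', 0, 'Flag', 'Homeologous-variation pattern'),
        ('REVIEW', 0, 'Flag', 'Significant in more pools than one triple'),
    ):
        header.info.add(*info)
    for amp, seq in reference.items():
        header.contigs.add(amp, length=len(seq))
    vcf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for c in sorted(candidates, key=lambda c: (c.amplicon, c.position)):
            ref_base = reference[c.amplicon][c.position - 1]
            if ref_base != c.ref:
                raise ValueError(
                    f"candidate {c.amplicon}:{c.position} ref {c.ref!r} does "
                    f"not match reference {ref_base!r}"
                )
            rec = vcf.new_record(
                contig=c.amplicon, start=c.position - 1,
                stop=c.position, alleles=(c.ref, c.alt),
            )
            pools = sorted(c.positive_pools)
            rec.info['POOLS'] = tuple(pools)
            rec.info['PVALS'] = tuple(
                float(c.pool_pvalues[p]) for p in pools
            )
            rec.info['LINESET'] = tuple(
                f"{a.plate}:{a.well}" for a in sorted(c.lines)
            )
            if c.ems_consistent:
                rec.info['EMS'] = True
            if c.needs_review:
                rec.info['REVIEW'] = True
            vcf.write(rec)
    finally:
        vcf.close()


def read_vcf_candidates(path) -> pd.DataFrame:
    """Round-trip reader for scampr VCF output (standard VCF parser)."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append({
                "amplicon": rec.chrom,
                "position": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "pools": tuple(rec.info.get("POOLS", ())),
                "ems": bool(rec.info.get("EMS", False)),
            })
    return pd.DataFrame(
        rows, columns=["amplicon", "position", "ref", "alt", "pools", "ems"]
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Precedence is CLI override > config file > the defaults below; each
    default is the documented operating point of the corresponding
    module.
    """

    reference: str = ""
    design: str = ""
    counts: str = ""            # glob over per-pool TSV count tables
    pileups: str = ""           # or glob over per-pool mpileup files
    out_dir: str = "scampr_out"
    min_base_quality: int = 20
    alpha: float = DEFAULT_ALPHA
    min_depth: int = DEFAULT_MIN_DEPTH
    homeolog_min_freq: float = DEFAULT_HOMEOLOG_MIN_FREQ
    homeolog_pool_fraction: float = DEFAULT_HOMEOLOG_POOL_FRACTION
    min_candidate_freq: float = DEFAULT_MIN_CANDIDATE_FREQ
    edge_exclusion: int = 200
    genome_size_mb: float = 1132.0
    ems_only: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.min_depth < 0 or self.min_base_quality < 0:
            raise ConfigError("depth/quality thresholds must be >= 0")
        if not 0 <= self.homeolog_min_freq <= 1:
            raise ConfigError("homeolog_min_freq must be in [0, 1]")
        if not 0 <= self.homeolog_pool_fraction <= 1:
            raise ConfigError("homeolog_pool_fraction must be in [0, 1]")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            payload = tomllib.load(fh)
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


_POOL_RE = re.compile(r"pool[_-]?(\d+)")


def _pool_id_from_name(path: Path) -> int:
    m = _POOL_RE.search(path.name.lower())
    if not m:
        raise ConfigError(
            f"cannot infer pool id from file name {path.name!r} "
            "(expected 'pool<N>' in the name)"
        )
    return int(m.group(1))


def load_count_matrices(config: RunConfig) -> list[BaseCountMatrix]:
    """Load per-pool counts from TSV tables or mpileup text files."""
    matrices: list[BaseCountMatrix] = []
    if config.counts:
        paths = sorted(globmod.glob(config.counts))
        if not paths:
            raise ConfigError(f"no files match counts glob {config.counts!r}")
        for p in paths:
            p = Path(p)
            matrices.append(BaseCountMatrix.from_tsv(p, _pool_id_from_name(p)))
    elif config.pileups:
        paths = sorted(globmod.glob(config.pileups))
        if not paths:
            raise ConfigError(f"no files match pileup glob {config.pileups!r}")
        for p in paths:
            p = Path(p)
            with open(p) as fh:
                matrices.append(
                    counts_from_pileup(fh, pool_id=_pool_id_from_name(p),
                                       min_base_quality=config.min_base_quality)
                )
    else:
        raise ConfigError("config must set either 'counts' or 'pileups'")
    return matrices


@dataclass
class PipelineResult:
    candidates: list[CandidateMutation]
    vcf_path: Path
    table_path: Path
    plot_path: Path | None
    summary: dict


def run_pipeline(config: RunConfig, make_plot: bool = True) -> PipelineResult:
    """counts → frequencies → background/t-tests → calls → reports.

    Deterministic for fixed inputs; each stage logs its record count.
    Any stage failure raises with a stage-tagged message.
    """
    logging.basicConfig(level=config.log_level)

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("config")
        if not config.design:
            raise ConfigError("config must set 'design'")
        for p, what in ((config.design, "design"),
                        (config.reference, "reference")):
            if p and not Path(p).exists():
                raise ConfigError(f"{what} file not found: {p}")
        design = PoolingDesign.from_json(config.design)
        reference = read_fasta(config.reference) if config.reference else {}
    except Exception as exc:
        raise RuntimeError(f"[config] {exc}") from exc

    try:
        stage("counts")
        matrices = load_count_matrices(config)
        log.info("loaded %d pools", len(matrices))
    except Exception as exc:
        raise RuntimeError(f"[counts] {exc}") from exc

    try:
        stage("frequencies")
        freqs = combined_frequencies(matrices)
        log.info("%d frequency records", len(freqs))
    except Exception as exc:
        raise RuntimeError(f"[frequencies] {exc}") from exc

    try:
        stage("call")
        candidates = call_candidates(
            freqs, design, alpha=config.alpha, min_depth=config.min_depth,
            homeolog_min_freq=config.homeolog_min_freq,
            homeolog_pool_fraction=config.homeolog_pool_fraction,
            min_candidate_freq=config.min_candidate_freq,
            ems_only=config.ems_only,
        )
        log.info("%d candidates", len(candidates))
    except Exception as exc:
        raise RuntimeError(f"[call] {exc}") from exc

    try:
        stage("report")
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = out_dir / "candidates.vcf"
        if reference:
            write_vcf(candidates, reference, vcf_path)
        table_path = out_dir / "candidates.tsv"
        candidates_to_frame(candidates).to_csv(table_path, sep="\t", index=False)
        plot_path = None
        if make_plot:
            from .plotting import frequency_profile

            plot_path = out_dir / "frequency_profile.png"
            frequency_profile(freqs, candidates, plot_path)
        summary = {
            "n_pools": len(matrices),
            "n_positions": int(freqs[["amplicon", "pos"]]
                               .drop_duplicates().shape[0]),
            "n_candidates": len(candidates),
            "n_ems_consistent": sum(c.ems_consistent for c in candidates),
            "thresholds": {
                k: v for k, v in asdict(config).items()
                if k in ("min_base_quality", "alpha", "min_depth",
                         "homeolog_min_freq", "homeolog_pool_fraction",
                         "min_candidate_freq")
            },
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"[report] {exc}") from exc

    return PipelineResult(candidates=candidates, vcf_path=vcf_path,
                          table_path=table_path, plot_path=plot_path,
                          summary=summary)
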