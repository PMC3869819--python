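"""Candidate mutation calling from per-pool substitution frequencies.

The null hypothesis at a position is that its substitution frequency is
sequencing-error background.  Background is estimated per pool and per
substitution type (ref→alt pair) from all other positions carrying the
same reference base, and each focal frequency is tested with a
one-sided, prediction-interval-style Student t-test:

    t = (f - mean) / (sd' * sqrt(1 + 1/n)),   df = n - 1,

where sd' floors the background standard deviation at one read of
resolution, 1/(2 × filtered depth).  A substitution becomes a candidate
EMS mutation when a full pool triple (one column, one row and one plate
pool) is significant at ``alpha`` and the per-pool frequencies sit in
the expected single-carrier band — above ``min_candidate_freq`` and
below the homeolog threshold.  Fixed differences between homeologous
gene copies are recognised by their presence at substantial frequency
in essentially all pools and are excluded from both the background fit
and the candidate list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pileup import BaseCountMatrix, combined_frequencies
from .pooling import DesignError, LineAddress, PoolingDesign

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DEPTH = 100
DEFAULT_HOMEOLOG_MIN_FREQ = 0.2
DEFAULT_HOMEOLOG_POOL_FRACTION = 0.9
DEFAULT_MIN_CANDIDATE_FREQ = 0.002


def ems_consistency(ref: str, alt: str) -> bool:
    """True iff the substitution is a G→A or C→T transition on the
    reference strand — the alkylation signature of EMS."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return (ref.upper(), alt.upper()) in {("G", "A"), ("C", "T")}


@dataclass
class BackgroundModel:
    """Sequencing-error background for one (pool, substitution type)."""

    pool: int
    ref: str
    alt: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("background needs at least 2 positions")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class CandidateMutation:
    """A position+substitution passing the three-pool coincidence rule."""

    amplicon: str
    position: int
    ref: str
    alt: str
    pool_freqs: dict[int, float]
    pool_pvalues: dict[int, float]
    positive_pools: frozenset[int]
    lines: frozenset[LineAddress]
    ems_consistent: bool
    needs_review: bool = False
    below_min_depth_pools: frozenset[int] = frozenset()

    @property
    def mean_positive_freq(self) -> float:
        return float(np.mean([self.pool_freqs[p] for p in self.positive_pools]))


def classify_homeolog(freqs: Sequence[float],
                      homeolog_min_freq: float = DEFAULT_HOMEOLOG_MIN_FREQ,
                      pool_fraction: float = DEFAULT_HOMEOLOG_POOL_FRACTION,
                      ) -> bool:
    """Flag a substitution as homeologous variation.

    True iff its frequency is >= ``homeolog_min_freq`` in at least
    ``pool_fraction`` of the pools with data.  A fixed difference
    between homeologous loci appears in every pool at roughly the
    homeolog allele share, unlike a single-line mutation which is
    confined to one pool triple.
    """
    vals = np.asarray([f for f in freqs if not np.isnan(f)], dtype=float)
    if vals.size == 0:
        raise ValueError("no pools with data")
    return bool(np.mean(vals >= homeolog_min_freq) >= pool_fraction)


def fit_background(freq_table: pd.DataFrame, pool: int, ref: str, alt: str,
                   exclude: Iterable[tuple[str, int]] = (),
                   ) -> BackgroundModel:
    """Fit the error background for one substitution type in one pool.

    Uses the frequency of ref→alt at every position of ``freq_table``
    (one pool's long-format frequency table) carrying that reference
    base, minus the excluded (amplicon, position) pairs — typically the
    focal position and any homeolog-flagged positions.
    """
    t = freq_table
    sel = (t["pool"] == pool) & (t["ref"] == ref) & (t["alt"] == alt)
    sel &= ~t["no_data"]
    sub = t[sel]
    if exclude:
        excl = set(exclude)
        keep = [
            (a, p) not in excl
            for a, p in zip(sub["amplicon"], sub["pos"])
        ]
        sub = sub[keep]
    vals = sub["freq"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"need >=2 background positions for {ref}->{alt} in pool {pool}, "
            f"got {vals.size}"
        )
    return BackgroundModel(pool=pool, ref=ref, alt=alt,
                           mean=float(vals.mean()),
                           sd=float(vals.std(ddof=1)),
                           n=int(vals.size))


def test_position(freq: float, background: BackgroundModel,
                  sd_floor: float = 0.0) -> float:
    """One-sided upper-tail p-value of a focal frequency vs background.

    Prediction-interval form: the focal observation is compared with the
    background distribution, not the background mean alone, so the
    standard error carries the extra sqrt(1 + 1/n) factor.  The
    background sd is floored at ``sd_floor`` (one read of resolution,
    1/(2·depth), when called from :func:`call_candidates`) so an
    all-zero background cannot produce an infinite statistic.
    """
    sd = max(background.sd, sd_floor)
    n = background.n
    if sd == 0:
        return 0.0 if freq > background.mean else 1.0
    t = (freq - background.mean) / (sd * np.sqrt(1.0 + 1.0 / n))
    return float(sps.t.sf(t, df=n - 1))


def homeolog_positions(freq_table: pd.DataFrame,
                       homeolog_min_freq: float = DEFAULT_HOMEOLOG_MIN_FREQ,
                       pool_fraction: float = DEFAULT_HOMEOLOG_POOL_FRACTION,
                       ) -> set[tuple[str, int]]:
    """(amplicon, pos) pairs whose any-substitution frequency pattern
    across pools matches homeologous variation."""
    flagged: set[tuple[str, int]] = set()
    grouped = freq_table[~freq_table["no_data"]].groupby(
        ["amplicon", "pos", "alt"], sort=False
    )
    for (amp, pos, _alt), grp in grouped:
        if classify_homeolog(grp["freq"].to_numpy(), homeolog_min_freq,
                             pool_fraction):
            flagged.add((amp, int(pos)))
    return flagged


def _loo_background(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Leave-one-out mean and sd for each entry of ``values``."""
    n = values.size
    s = values.sum()
    ss = (values ** 2).sum()
    mean = (s - values) / (n - 1)
    var = (ss - values ** 2 - (n - 1) * mean ** 2) / (n - 2)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd, n - 1


def call_candidates(counts: Iterable[BaseCountMatrix] | pd.DataFrame,
                    design: PoolingDesign,
                    alpha: float = DEFAULT_ALPHA,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    homeolog_min_freq: float = DEFAULT_HOMEOLOG_MIN_FREQ,
                    homeolog_pool_fraction: float = DEFAULT_HOMEOLOG_POOL_FRACTION,
                    min_candidate_freq: float = DEFAULT_MIN_CANDIDATE_FREQ,
                    ems_only: bool = False,
                    ) -> list[CandidateMutation]:
    """Call candidate EMS mutations across all pools of a design.

    A candidate is emitted for (amplicon, position, ref→alt) iff the set
    of significant pools (one-sided t-test p <= alpha, frequency within
    the expected single-carrier band, filtered depth >= ``min_depth``)
    contains at least one full triple — one pool from each design
    dimension — and the position is not homeolog-flagged.  Substitutions
    significant in more pools than one triple are emitted with
    ``needs_review`` set.  The decoded line set is the union of the
    decodes of every contained triple (six wells for a single triple in
    the canonical design).
    """
    if isinstance(counts, pd.DataFrame):
        freqs = counts
    else:
        freqs = combined_frequencies(list(counts))
    present = set(freqs["pool"].unique())
    missing = [p for p in design.pool_ids if p not in present]
    if missing:
        raise ValueError(f"no frequency data for pools {missing}")

    homeo = homeolog_positions(freqs, homeolog_min_freq,
                               homeolog_pool_fraction)
    key = list(zip(freqs["amplicon"], freqs["pos"]))
    is_homeo = np.array([k in homeo for k in key])
    usable = (~freqs["no_data"]).to_numpy()
    deep = (freqs["depth"].to_numpy() >= min_depth) & usable

    # per (pool, ref, alt): leave-one-out background over non-homeolog
    # positions, then a t-test for every position in the group
    pvals = np.full(len(freqs), np.nan)
    freqs = freqs.reset_index(drop=True)
    for (pool, ref, alt), grp in freqs.groupby(["pool", "ref", "alt"],
                                               sort=False):
        idx = grp.index.to_numpy()
        bg_mask = ~is_homeo[idx] & usable[idx]
        bg_idx = idx[bg_mask]
        if bg_idx.size < 3:
            continue
        vals = freqs.loc[bg_idx, "freq"].to_numpy(dtype=float)
        mean, sd, n_loo = _loo_background(vals)
        depth = freqs.loc[bg_idx, "depth"].to_numpy(dtype=float)
        sd_floor = 1.0 / (2.0 * np.maximum(depth, 1.0))
        sd_eff = np.maximum(sd, sd_floor)
        tstat = (vals - mean) / (sd_eff * np.sqrt(1.0 + 1.0 / n_loo))
        pvals[bg_idx] = sps.t.sf(tstat, df=n_loo - 1)
        # homeolog-flagged positions: test against the full background
        fg_idx = idx[~bg_mask & usable[idx]]
        if fg_idx.size:
            fdepth = freqs.loc[fg_idx, "depth"].to_numpy(dtype=float)
            fsd = np.maximum(vals.std(ddof=1),
                             1.0 / (2.0 * np.maximum(fdepth, 1.0)))
            f = freqs.loc[fg_idx, "freq"].to_numpy(dtype=float)
            ts = (f - vals.mean()) / (fsd * np.sqrt(1.0 + 1.0 / vals.size))
            pvals[fg_idx] = sps.t.sf(ts, df=vals.size - 1)

    freqs = freqs.assign(pvalue=pvals, deep=deep, homeolog=is_homeo)

    in_band = (
        (freqs["freq"].to_numpy() >= min_candidate_freq)
        & (freqs["freq"].to_numpy() < homeolog_min_freq)
    )
    significant = (
        (pvals <= alpha) & in_band & deep & ~is_homeo
    )
    freqs = freqs.assign(significant=significant)

    candidates: list[CandidateMutation] = []
    hits = freqs[freqs["significant"]]
    for (amp, pos, ref, alt), grp in hits.groupby(
            ["amplicon", "pos", "ref", "alt"], sort=True):
        sig_pools = set(int(p) for p in grp["pool"])
        by_dim: dict[str, list[int]] = {d: [] for d in design.dimensions}
        for p in sig_pools:
            by_dim[design.dimension_of(p)].append(p)
        if any(not v for v in by_dim.values()):
            continue  # no full triple
        lines: set[LineAddress] = set()
        for triple in itertools.product(*by_dim.values()):
            try:
                lines |= design.decode_pools(triple)
            except DesignError:
                continue
        if not lines:
            continue
        sub = freqs[(freqs["amplicon"] == amp) & (freqs["pos"] == pos)
                    & (freqs["alt"] == alt)]
        pool_freqs = {int(r.pool): float(r.freq) for r in sub.itertuples()}
        pool_p = {int(r.pool): float(r.pvalue) for r in sub.itertuples()}
        shallow = frozenset(int(r.pool) for r in sub.itertuples() if not r.deep)
        cand = CandidateMutation(
            amplicon=amp, position=int(pos), ref=ref, alt=alt,
            pool_freqs=pool_freqs, pool_pvalues=pool_p,
            positive_pools=frozenset(sig_pools),
            lines=frozenset(lines),
            ems_consistent=ems_consistency(ref, alt),
            needs_review=len(sig_pools) > len(design.dimensions),
            below_min_depth_pools=shallow,
        )
        if ems_only and not cand.ems_consistent:
            continue
        candidates.append(cand)
    return candidates


def candidates_to_frame(candidates: Sequence[CandidateMutation]) -> pd.DataFrame:
    """Human-review table: one row per candidate, wells spelled out."""
    rows = []
    for c in candidates:
        rows.append({
            "amplicon": c.amplicon,
            "position": c.position,
            "mutation": f"{c.ref}>{c.alt}",
            "positive_pools": ",".join(str(p) for p in sorted(c.positive_pools)),
            "wells_to_validate": "; ".join(str(a) for a in sorted(c.lines)),
            "mean_positive_freq": round(c.mean_positive_freq, 6),
            "ems_consistent": c.ems_consistent,
            "needs_review": c.needs_review,
        })
    return pd.DataFrame(rows, columns=[
        "amplicon", "position", "mutation", "positive_pools",
        "wells_to_validate", "mean_positive_freq", "ems_consistent",
        "needs_review",
    ])
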