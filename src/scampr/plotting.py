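"""Per-pool substitution-frequency profile plots.

One panel per substitution type of interest (C→T, G→A, A→G by default):
frequency against amplicon position, one trace per pool, with candidate
positions circled.  The A→G panel is the negative control — an
alkylating mutagen should produce none.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .caller import CandidateMutation

DEFAULT_PANELS = (("C", "T"), ("G", "A"), ("A", "G"))


def frequency_profile(freqs: pd.DataFrame,
                      candidates: Sequence[CandidateMutation] = (),
                      path=None,
                      panels=DEFAULT_PANELS,
                      amplicon: str | None = None):
    """Plot per-pool frequency profiles; returns the figure."""
    if amplicon is None:
        amplicon = sorted(freqs["amplicon"].unique())[0]
    data = freqs[freqs["amplicon"] == amplicon]
    fig, axes = plt.subplots(len(panels) + 1, 1, sharex=True,
                             figsize=(10, 2.2 * (len(panels) + 1)))
    depth = (data.groupby("pos")["depth"].mean())
    axes[0].fill_between(depth.index, depth.to_numpy(), color="0.7")
    axes[0].set_ylabel("mean depth")
    axes[0].set_title(f"{amplicon}: read depth and substitution frequencies")
    for ax, (ref, alt) in zip(axes[1:], panels):
        sub = data[(data["ref"] == ref) & (data["alt"] == alt)]
        for pool, grp in sub.groupby("pool"):
            ax.plot(grp["pos"], grp["freq"], lw=0.5, alpha=0.6,
                    label=f"pool {pool}")
        hits = [c for c in candidates
                if c.amplicon == amplicon and (c.ref, c.alt) == (ref, alt)]
        for c in hits:
            for p in c.positive_pools:
                ax.plot(c.position, c.pool_freqs[p], "o", mfc="none",
                        mec="red", ms=9)
        ax.set_ylabel(f"{ref}→{alt} freq")
    axes[-1].set_xlabel("amplicon position (bp)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
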