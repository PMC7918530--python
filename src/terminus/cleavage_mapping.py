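"""Histogram of cleavage-fragment 5' ends around a predicted cleavage site.

Sequenced clones of 3' UTR cleavage fragments are summarised by the signed
distance of their mapped 5' end from the predicted cleavage site, grouped in
50-nt bins.  Fragments clustering at small non-negative distances support
endonucleolytic cleavage rather than 5'->3' exonucleolytic decay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CleavageHistogram", "bin_clone_distances", "read_clone_positions"]


@dataclass
class CleavageHistogram:
    site: int
    bin_width: int
    bin_starts: list[int]  # signed distance at the left edge of each bin
    bins: list[int]
    n_clones: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if sum(self.bins) != self.n_clones:
            raise ValueError("histogram does not conserve the clone count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_starts,
                "bin_end": [s + self.bin_width for s in self.bin_starts],
                "n_clones": self.bins,
            }
        )


def bin_clone_distances(
    clone_positions: Sequence[int],
    site: int,
    bin_width: int = 50,
    strand: str = "+",
) -> CleavageHistogram:
    """Bin clone 5'-end offsets from the predicted cleavage site.

    The distance is the signed offset in transcript orientation (positive =
    downstream of the site); bin k covers [k*width, (k+1)*width) so negative
    offsets are binned symmetrically about the site.
    """
    positions = np.asarray(clone_positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("empty clone list")
    offsets = positions - site
    if strand == "-":
        offsets = -offsets
    idx = np.floor_divide(offsets, bin_width)
    lo, hi = int(idx.min()), int(idx.max())
    ks = np.arange(lo, hi + 1)
    counts = [int((idx == k).sum()) for k in ks]
    return CleavageHistogram(
        site=site,
        bin_width=bin_width,
        bin_starts=[int(k * bin_width) for k in ks],
        bins=counts,
        n_clones=int(positions.size),
    )


def read_clone_positions(path: str | Path) -> list[int]:
    """Clone 5'-end coordinates from a TSV with columns clone_id, position."""
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError("clone TSV must have a 'position' column")
    return [int(p) for p in df["position"]]
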