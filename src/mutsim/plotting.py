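"""Minimal rainfall plot: log inter-mutation distance along a chromosome."""

from __future__ import annotations

import numpy as np


def rainfall(records, chrom: str, ax=None):
    """Scatter log10 distance to the previous mutation vs position.

    Clustered mutations show up as low-lying runs. Returns the axis.
    """
    import matplotlib.pyplot as plt

    pos = sorted(r.pos for r in records if r.chrom == chrom)
    if len(pos) < 2:
        raise ValueError(f"need at least two mutations on {chrom}")
    pos = np.asarray(pos)
    dist = np.diff(pos).astype(float)
    dist[dist < 1] = 1
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.scatter(pos[1:], np.log10(dist), s=4, alpha=0.6)
    ax.set_xlabel(f"position on {chrom} (bp)")
    ax.set_ylabel("log10 inter-mutation distance")
    return ax
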