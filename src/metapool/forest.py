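"""Deterministic SVG forest plots."""

from __future__ import annotations

import io
import os
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Polygon  # noqa: E402

from .bayes import PosteriorSummary
from .pooling import PooledResult
from .records import EvidenceBase

_HASHSALT = "metapool-forest"


def render_forest(
    base: EvidenceBase,
    result: PooledResult | PosteriorSummary,
    path: str | os.PathLike | None = None,
) -> str:
    """Forest plot: one row per study, RR on a log axis, summary diamond.

    Frequentist results draw squares sized by normalized pooling weight;
    Bayesian results draw uniform point markers. Output is byte-identical
    across runs for identical input. Returns the SVG text; writes it to
    ``path`` when given.
    """
    records = list(base)
    k = len(records)
    if isinstance(result, PooledResult):
        weights = dict(zip(result.study_ids, result.weights))
        summary_lo, summary_hi = result.rr_ci
        summary_mid = result.rr
        label = {"fixed": "Fixed-effect summary", "random_dl": "Random-effects summary"}[
            result.model
        ]
    else:
        weights = None
        summary_lo, summary_hi = result.rr_cri
        summary_mid = result.rr_median
        label = "Bayesian posterior summary"

    fig, ax = plt.subplots(figsize=(6.5, 1.0 + 0.35 * (k + 2)))
    for row, rec in enumerate(records):
        ypos = k - row  # first study on top
        line, = ax.plot(
            [rec.ci_lower, rec.ci_upper], [ypos, ypos], color="0.2", lw=1.2, zorder=2
        )
        line.set_gid(f"study-ci-{rec.study_id}")
        if weights is not None:
            size = 40.0 + 360.0 * weights[rec.study_id]
            marker = ax.scatter([rec.rr], [ypos], s=size, marker="s", color="0.2", zorder=3)
        else:
            marker = ax.scatter([rec.rr], [ypos], s=40.0, marker="o", color="0.2", zorder=3)
        marker.set_gid(f"study-row-{rec.study_id}")

    # summary diamond spanning the interval at the bottom row
    dy = 0.22
    diamond = Polygon(
        [
            (summary_lo, 0.0),
            (summary_mid, dy),
            (summary_hi, 0.0),
            (summary_mid, -dy),
        ],
        closed=True,
        facecolor="0.35",
        edgecolor="black",
        zorder=3,
    )
    diamond.set_gid("summary-diamond")
    ax.add_patch(diamond)

    ax.axvline(1.0, color="0.6", lw=0.8, ls="--", zorder=1)
    ax.set_xscale("log")
    ax.set_yticks([k - i for i in range(k)] + [0])
    ax.set_yticklabels([r.study_id for r in records] + [label])
    ax.set_ylim(-1, k + 1)
    ax.set_xlabel("Relative risk (log scale)")
    fig.tight_layout()

    with plt.rc_context({"svg.hashsalt": _HASHSALT}):
        buf = io.BytesIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue().decode("utf-8")
    if path is not None:
        Path(path).write_text(svg, encoding="utf-8")
    return svg
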