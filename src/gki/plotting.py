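"""Monthly tracking chart: daily GKI as a line, target as a horizontal line.

The image is a convenience; the testable surface is the companion CSV
(day-of-month, daily GKI, constant target) written next to it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

logger = logging.getLogger(__name__)

__all__ = ["render_monthly_plot"]


def render_monthly_plot(view, path: str | Path) -> Optional[Path]:
    """Render a monthly view table (from :func:`gki.tracking.monthly_view`).

    Writes the plot image to ``path`` and the plot-ready table to the same
    path with a ``.csv`` suffix; returns the image path, or ``None`` (with a
    warning) for an empty view.
    """
    path = Path(path)
    if len(view) == 0:
        logger.warning("empty monthly view; no plot written")
        return None

    csv_path = path.with_suffix(".csv")
    view.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(view["day"], view["gki"], color="black", marker="o", label="daily GKI")
    target = float(view["target"].iloc[0])
    ax.axhline(target, color="red", label=f"target ({target:g})")
    ax.set_xlabel("day of month")
    ax.set_ylabel("Glucose Ketone Index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
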