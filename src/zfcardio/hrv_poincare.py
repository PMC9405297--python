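"""Poincaré-plot heart-rate-variability indices.

Each inter-beat interval is plotted against the next.  With
``d_n = IBI_n - IBI_{n+1}`` and ``s_n = IBI_n + IBI_{n+1}``:

    sd1 = sqrt(Var(d) / 2)      spread perpendicular to the identity line
                                (instantaneous, beat-to-beat variability)
    sd2 = sqrt(Var(s) / 2)      spread along the identity line
                                (continuous, long-term variability)

Variances use the ``n - 1`` denominator for unbiasedness at the small
beat counts of 1-minute records.  The ellipse drawn on the plot is a
descriptive overlay at a chi-square-derived confidence radius (default
0.95, 2 degrees of freedom); sd1/sd2 come from the variance formulas
above, never from an ellipse fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import DomainError, InsufficientBeatsError, ParameterError

DEFAULT_CONFIDENCE = 0.95


@dataclass(frozen=True)
class PoincareResult:
    """sd1/sd2 indices and the descriptive ellipse of a Poincaré plot.

    ``ellipse_semi_axes`` is ``(along_identity, perpendicular)`` =
    ``(sd2 * c, sd1 * c)`` with ``c = sqrt(chi2.ppf(confidence, df=2))``;
    the ellipse is centered at ``(mean IBI, mean IBI)`` and oriented at
    45 degrees to the axes.  All quantities are in seconds.
    """

    sd1: float
    sd2: float
    center: tuple[float, float]
    ellipse_semi_axes: tuple[float, float]
    confidence: float
    pairs: np.ndarray  # shape (n-1, 2): (IBI_n, IBI_{n+1})

    def to_dict(self) -> dict:
        return {
            "sd1_s": self.sd1,
            "sd2_s": self.sd2,
            "mean_ibi_s": self.center[0],
            "confidence": self.confidence,
            "n_pairs": int(self.pairs.shape[0]),
        }


def poincare(ibis, confidence: float = DEFAULT_CONFIDENCE) -> PoincareResult:
    """Compute sd1/sd2 and the confidence ellipse from inter-beat intervals.

    Requires at least 3 intervals (2 consecutive pairs) so the sample
    variances are defined.
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size < 3:
        raise InsufficientBeatsError(
            f"need at least 3 inter-beat intervals, got {ibis.size}"
        )
    if np.any(ibis <= 0):
        raise DomainError("inter-beat intervals must be positive")
    if not 0 < confidence < 1:
        raise ParameterError(f"confidence must be in (0, 1), got {confidence}")

    a, b = ibis[:-1], ibis[1:]
    d = a - b
    s = a + b
    sd1 = float(np.sqrt(np.var(d, ddof=1) / 2.0))
    sd2 = float(np.sqrt(np.var(s, ddof=1) / 2.0))
    c = float(np.sqrt(chi2.ppf(confidence, df=2)))
    m = float(np.mean(ibis))
    return PoincareResult(
        sd1=sd1,
        sd2=sd2,
        center=(m, m),
        ellipse_semi_axes=(sd2 * c, sd1 * c),
        confidence=confidence,
        pairs=np.column_stack([a, b]),
    )


def plot_poincare(result: PoincareResult, ax=None):
    """Scatter of consecutive-interval pairs with the confidence ellipse.

    Returns the matplotlib axes; creates a new figure when ``ax`` is
    omitted.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(result.pairs[:, 0], result.pairs[:, 1], s=12, alpha=0.6, zorder=2)
    along, perp = result.ellipse_semi_axes
    ax.add_patch(
        Ellipse(
            result.center,
            width=2 * along,
            height=2 * perp,
            angle=45.0,
            fill=False,
            edgecolor="crimson",
            lw=1.5,
            zorder=3,
        )
    )
    lims = np.array(ax.get_xlim() + ax.get_ylim())
    lo, hi = lims.min(), lims.max()
    ax.plot([lo, hi], [lo, hi], ls="--", c="gray", lw=0.8, zorder=1)
    ax.set_xlabel(r"IBI$_n$ (s)")
    ax.set_ylabel(r"IBI$_{n+1}$ (s)")
    ax.set_title(
        f"sd1 = {result.sd1 * 1000:.1f} ms, sd2 = {result.sd2 * 1000:.1f} ms"
    )
    ax.set_aspect("equal")
    return ax
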