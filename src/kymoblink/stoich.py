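"""Dimer-fraction inference from two-color labeling counts.

When a population is labeled with two quantum-dot colors mixed at equal
probability, a dimer's two subunits are differently colored only half the
time (AB or BA out of AA, AB, BA, BB), so the observed dual-colored fraction
underestimates the dimer fraction by a factor of two. This module computes
the expected color-category distribution for arbitrary color probabilities
and labeling efficiency, and inverts it to estimate the dimer fraction with
binomial uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import DualColorCounts

__all__ = [
    "DualColorCounts",
    "StoichEstimate",
    "expected_color_distribution",
    "p_dual_given_dimer",
    "estimate_dimer_fraction",
]


@dataclass
class StoichEstimate:
    """Dimer-fraction estimate from dual-color counts.

    ``dimer_fraction = dual_fraction / P(dual | dimer)``; with equal color
    probabilities and full labeling efficiency the correction factor is
    exactly 2. When counts are incompatible with the assumptions (estimator
    above 1) the estimate is capped at 1 and ``inconsistent`` is set.
    """

    dual_fraction: float
    dimer_fraction: float
    se_dual: float
    se_dimer: float
    n_total: int
    inconsistent: bool = False
    assumptions: dict | None = None

    def to_dict(self) -> dict:
        return {
            "dual_fraction": self.dual_fraction,
            "dimer_fraction": self.dimer_fraction,
            "se_dual": self.se_dual,
            "se_dimer": self.se_dimer,
            "n_total": self.n_total,
            "inconsistent": self.inconsistent,
            "assumptions": self.assumptions,
        }


def _check_probs(color_probs: tuple[float, float], label_efficiency: float) -> tuple[float, float]:
    pa, pb = color_probs
    if pa < 0 or pb < 0 or abs(pa + pb - 1.0) > 1e-9:
        raise ValueError("color_probs must be non-negative and sum to 1")
    if not 0.0 <= label_efficiency <= 1.0:
        raise ValueError("label_efficiency must be in [0, 1]")
    return float(pa), float(pb)


def p_dual_given_dimer(
    color_probs: tuple[float, float] = (0.5, 0.5), label_efficiency: float = 1.0
) -> float:
    """Probability that a dimer appears dual-colored: both subunits labeled
    (efficiency e each) with different colors, in either order —
    ``2 p_a p_b e^2``. Equal to 0.5 at (0.5, 0.5) and e = 1."""
    pa, pb = _check_probs(color_probs, label_efficiency)
    return 2.0 * pa * pb * label_efficiency**2


def expected_color_distribution(
    dimer_fraction: float,
    color_probs: tuple[float, float] = (0.5, 0.5),
    label_efficiency: float = 1.0,
) -> dict[str, float]:
    """Category probabilities for a population with the given dimer fraction.

    Subunit colors are independent draws from ``color_probs``; each subunit
    carries any label with probability ``label_efficiency``. A single-color-A
    observation covers monomer-A, dimer-AA, and a dimer with exactly one
    (A-colored) labeled subunit. Entities with zero labels are invisible:
    their probability is reported under ``"unlabeled"`` and the three
    observable categories are renormalized to sum to 1.
    """
    if not 0.0 <= dimer_fraction <= 1.0:
        raise ValueError("dimer_fraction must be in [0, 1]")
    pa, pb = _check_probs(color_probs, label_efficiency)
    e = label_efficiency
    f = dimer_fraction

    dual = f * 2.0 * pa * pb * e**2
    single_a = (1.0 - f) * pa * e + f * (pa**2 * e**2 + 2.0 * e * (1.0 - e) * pa)
    single_b = (1.0 - f) * pb * e + f * (pb**2 * e**2 + 2.0 * e * (1.0 - e) * pb)
    unlabeled = (1.0 - f) * (1.0 - e) + f * (1.0 - e) ** 2

    visible = dual + single_a + single_b
    if visible == 0.0:
        return {"single_a": 0.0, "single_b": 0.0, "dual": 0.0, "unlabeled": 1.0}
    return {
        "single_a": single_a / visible,
        "single_b": single_b / visible,
        "dual": dual / visible,
        "unlabeled": unlabeled,
    }


def estimate_dimer_fraction(
    counts: DualColorCounts,
    color_probs: tuple[float, float] = (0.5, 0.5),
    label_efficiency: float = 1.0,
) -> StoichEstimate:
    """Invert the dual-color correction to estimate the dimer fraction.

    ``dual_fraction = n_dual / n_total``; the dimer fraction divides out
    ``P(dual | dimer) = 2 p_a p_b e^2`` (a factor-of-2 correction in the
    default equal-color, full-efficiency case). Standard errors propagate the
    binomial SE of the dual fraction through the same constant.
    """
    n_total = counts.n_total
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if min(counts.n_dual, counts.n_color_a, counts.n_color_b) < 0:
        raise ValueError("counts must be non-negative")
    p_corr = p_dual_given_dimer(color_probs, label_efficiency)
    if p_corr == 0.0:
        raise ValueError("P(dual | dimer) is zero under these assumptions")

    dual_frac = counts.n_dual / n_total
    se_dual = float(np.sqrt(dual_frac * (1.0 - dual_frac) / n_total))
    dimer_frac = dual_frac / p_corr
    se_dimer = se_dual / p_corr
    inconsistent = dimer_frac > 1.0
    if inconsistent:
        dimer_frac = 1.0
    return StoichEstimate(
        dual_fraction=dual_frac,
        dimer_fraction=dimer_frac,
        se_dual=se_dual,
        se_dimer=se_dimer,
        n_total=n_total,
        inconsistent=inconsistent,
        assumptions={
            "color_probs": list(color_probs),
            "label_efficiency": label_efficiency,
            "p_dual_given_dimer": p_corr,
        },
    )


def read_counts_csv(path: str | Path) -> DualColorCounts:
    df = pd.read_csv(path).set_index("category")["count"]
    return DualColorCounts(
        n_dual=int(df.get("dual", 0)),
        n_color_a=int(df.get("color_a", 0)),
        n_color_b=int(df.get("color_b", 0)),
    )


def write_estimate_json(estimate: StoichEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(estimate.to_dict(), indent=1, sort_keys=True))
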