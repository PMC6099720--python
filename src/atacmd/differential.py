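"""Differential MD-score testing between two biological conditions.

For each motif shared by the two conditions the (n_small, n_large) count
pairs are compared with a pooled two-proportion Z-test,

    p_hat = (x1 + x2) / (n1 + n2)
    z     = (x2/n2 - x1/n1) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2))

with a two-sided standard-normal p-value.  No continuity correction is
applied and p-values are reported raw (an optional Bonferroni switch is
provided, off by default): significance is classified against two raw
thresholds, a strong tier (default 1e-5) and a weak tier (default 1e-4),
mirroring the red/maroon (increased) and purple (decreased) conventions of
MD-score MA plots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .mdscore import MDScoreResult

__all__ = [
    "DifferentialRecord",
    "SIG_CLASSES",
    "differential_md",
    "ma_table",
    "two_proportion_z",
    "write_differential",
]

logger = logging.getLogger(__name__)

DEFAULT_P_STRONG = 1e-5
DEFAULT_P_WEAK = 1e-4

SIG_CLASSES = ("up_strong", "up_weak", "down_strong", "down_weak", "ns")

#: Output column order of the differential TSV.
DIFF_COLUMNS = [
    "motif_id",
    "n_small_a",
    "n_large_a",
    "md_a",
    "n_small_b",
    "n_large_b",
    "md_b",
    "delta_md",
    "z",
    "p_value",
    "sig_class",
]


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test of x1/n1 vs x2/n2.

    Returns ``(z, p_value)`` with a two-sided normal p-value.  The sign of z
    follows ``x2/n2 - x1/n1``.  When the pooled proportion is degenerate
    (0 or 1) the two proportions are identical, so ``z = 0`` and ``p = 1``.

    Raises
    ------
    ValueError
        On empty trials (``n1 == 0`` or ``n2 == 0``) or out-of-range counts;
        callers must exclude undefined MD-scores first.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("two_proportion_z requires n1 > 0 and n2 > 0")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError(f"counts out of range: {x1}/{n1}, {x2}/{n2}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x2 / n2 - x1 / n1) / se
    p_value = 2.0 * float(norm.sf(abs(z)))
    return z, min(p_value, 1.0)


@dataclass(frozen=True)
class DifferentialRecord:
    """Paired-condition MD-scores and their two-proportion test for one motif."""

    motif_id: str
    md_a: float
    md_b: float
    delta_md: float
    n_small_a: int
    n_large_a: int
    n_small_b: int
    n_large_b: int
    z: float
    p_value: float
    n_motifs_large_mean: float
    sig_class: str


def classify(p_value: float, delta_md: float, p_strong: float, p_weak: float) -> str:
    """Two-tier significance class from p-value and direction of change."""
    if delta_md == 0 or p_value >= p_weak:
        return "ns"
    direction = "up" if delta_md > 0 else "down"
    tier = "strong" if p_value < p_strong else "weak"
    return f"{direction}_{tier}"


def differential_md(
    results_a: Sequence[MDScoreResult],
    results_b: Sequence[MDScoreResult],
    p_strong: float = DEFAULT_P_STRONG,
    p_weak: float = DEFAULT_P_WEAK,
    bonferroni: bool = False,
) -> list[DifferentialRecord]:
    """Join two condition result sets by motif and test each shared motif.

    Motifs missing from either condition, or with an undefined MD-score
    (``n_large == 0``) in either condition, are excluded and reported through
    the module logger.  With ``bonferroni=True`` p-values are multiplied by
    the number of motifs tested (capped at 1) before classification; default
    is raw p-values.  Output is sorted by p-value ascending, ties broken by
    |delta_md| descending then motif_id.
    """
    if p_strong > p_weak:
        raise ValueError(f"require p_strong <= p_weak, got {p_strong} > {p_weak}")
    by_a = {r.motif_id: r for r in results_a}
    by_b = {r.motif_id: r for r in results_b}
    shared = sorted(set(by_a) & set(by_b))
    missing = sorted(set(by_a) ^ set(by_b))
    usable = [
        m
        for m in shared
        if by_a[m].md_score is not None and by_b[m].md_score is not None
    ]
    undefined = sorted(set(shared) - set(usable))
    if missing:
        logger.info(
            "excluded %d motif(s) present in only one condition: %s",
            len(missing),
            ", ".join(missing),
        )
    if undefined:
        logger.info(
            "excluded %d motif(s) with undefined MD-score: %s",
            len(undefined),
            ", ".join(undefined),
        )
    if not usable:
        raise ValueError("no shared motifs with defined MD-scores in both conditions")
    n_tests = len(usable)
    records = []
    for motif_id in usable:
        a, b = by_a[motif_id], by_b[motif_id]
        z, p_value = two_proportion_z(a.n_small, a.n_large, b.n_small, b.n_large)
        if bonferroni:
            p_value = min(1.0, p_value * n_tests)
        delta = b.md_score - a.md_score
        records.append(
            DifferentialRecord(
                motif_id=motif_id,
                md_a=a.md_score,
                md_b=b.md_score,
                delta_md=delta,
                n_small_a=a.n_small,
                n_large_a=a.n_large,
                n_small_b=b.n_small,
                n_large_b=b.n_large,
                z=z,
                p_value=p_value,
                n_motifs_large_mean=(a.n_large + b.n_large) / 2.0,
                sig_class=classify(p_value, delta, p_strong, p_weak),
            )
        )
    records.sort(key=lambda r: (r.p_value, -abs(r.delta_md), r.motif_id))
    return records


def ma_table(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    """Plot-ready MA table: x = log10(mean n_large + 1), y = delta MD-score.

    The x-axis is motif abundance near peaks (count of instances within the
    large window, averaged over the two conditions); +1 guards the log at
    zero abundance.
    """
    if not records:
        raise ValueError("ma_table requires at least one record")
    return pd.DataFrame(
        {
            "motif_id": [r.motif_id for r in records],
            "x": [math.log10(r.n_motifs_large_mean + 1.0) for r in records],
            "delta_md": [r.delta_md for r in records],
            "sig_class": [r.sig_class for r in records],
        }
    )


def write_differential(
    records: Sequence[DifferentialRecord],
    path: str | Path,
    p_strong: float = DEFAULT_P_STRONG,
    p_weak: float = DEFAULT_P_WEAK,
) -> None:
    """Write the ranked differential table (floats at 6 significant digits)."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# atacmd diff v{__version__}\n")
        fh.write(f"# p_strong={p_strong:g}\n")
        fh.write(f"# p_weak={p_weak:g}\n")
        fh.write("\t".join(DIFF_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.motif_id,
                        str(r.n_small_a),
                        str(r.n_large_a),
                        f"{r.md_a:.6g}",
                        str(r.n_small_b),
                        str(r.n_large_b),
                        f"{r.md_b:.6g}",
                        f"{r.delta_md:.6g}",
                        f"{r.z:.6g}",
                        f"{r.p_value:.6g}",
                        r.sig_class,
                    ]
                )
                + "\n"
            )
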