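"""Run-level configuration shared by the command-line subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _uniform_background() -> tuple[float, float, float, float]:
    return (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class RunConfig:
    """Defaults for radii, scan stringency and significance tiers.

    r_small / r_large are the MD-score window radii in bp; pvalue_scan is the
    per-window match p-value of the PWM scanner; p_strong / p_weak are the
    two raw significance tiers of the differential test.
    """

    r_small: int = 150
    r_large: int = 1500
    pvalue_scan: float = 1e-6
    p_strong: float = 1e-5
    p_weak: float = 1e-4
    counting_mode: str = "motif_centric"
    background: tuple[float, float, float, float] = field(
        default_factory=_uniform_background
    )
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_small >= self.r_large:
            raise ValueError(
                f"require r_small < r_large, got {self.r_small} >= {self.r_large}"
            )
        if self.p_strong > self.p_weak:
            raise ValueError(
                f"require p_strong <= p_weak, got {self.p_strong} > {self.p_weak}"
            )
        if self.counting_mode not in ("motif_centric", "peak_centric"):
            raise ValueError(f"unknown counting mode {self.counting_mode!r}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError("background must be 4 positive probabilities summing to 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
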