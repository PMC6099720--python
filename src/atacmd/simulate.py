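"""Synthetic toy datasets with planted motif/peak co-localization.

The generator emulates the data regime the MD-score statistic operates on:
called accessibility peaks on a small genome, and per-motif site sets in
which a controllable fraction ``pi`` of sites is planted within the small
radius of a randomly chosen peak midpoint — the remainder placed uniformly.
Two conditions A and B share a genome but draw independent peak sets and
site sets, with per-motif planting fractions ``pi_a`` and ``pi_b``; a
difference ``pi_b - pi_a`` is the planted differential TF-activity signal.

Everything is driven by one seeded NumPy generator, so outputs (including
written files) are byte-reproducible.  Site BEDs can be generated directly
(bypassing sequence) so statistic-level tests do not depend on the scanner;
:func:`plant_consensus` supports the sequence-level route for scanner
integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PointSet, build_point_set, midpoint, write_bed
from .scanner import PWM

__all__ = [
    "MotifSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "plant_consensus",
    "sample_site_centers",
    "simulate_dataset",
    "write_fasta",
]

CONDITIONS = ("a", "b")


@dataclass(frozen=True)
class MotifSpec:
    """One simulated motif: site count and per-condition planting fractions."""

    motif_id: str
    n_sites: int
    pi_a: float
    pi_b: float
    site_width: int = 10

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError(f"{self.motif_id}: n_sites must be positive")
        if not (0 <= self.pi_a <= 1 and 0 <= self.pi_b <= 1):
            raise ValueError(f"{self.motif_id}: pi_a, pi_b must lie in [0, 1]")
        if self.site_width < 1:
            raise ValueError(f"{self.motif_id}: site_width must be >= 1")

    def pi(self, condition: str) -> float:
        return self.pi_a if condition == "a" else self.pi_b


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``genome_length`` is per chromosome.  ``with_genome=False`` skips random
    sequence generation (sites are emitted directly as intervals), which is
    the fast path for statistic-level tests.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 2
    n_peaks: int = 1000
    peak_width_range: tuple[int, int] = (200, 600)
    motifs: tuple[MotifSpec, ...] = ()
    r_small: int = 150
    r_large: int = 1500
    seed: int = 0
    no_overlap: bool = False
    with_genome: bool = True

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chroms <= 0 or self.n_peaks <= 0:
            raise ValueError("genome_length, n_chroms and n_peaks must be positive")
        lo, hi = self.peak_width_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid peak_width_range {self.peak_width_range}")
        if hi >= self.genome_length:
            raise ValueError("peak width exceeds chromosome length")
        if not 0 < self.r_small < self.r_large:
            raise ValueError("require 0 < r_small < r_large")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class SimulatedDataset:
    """In-memory simulation output; see :func:`simulate_dataset` for files."""

    config: SimulationConfig
    genome: dict[str, str] | None
    peaks: dict[str, list[GenomicInterval]]
    sites: dict[str, dict[str, list[GenomicInterval]]]  # condition -> motif -> sites
    truth: pd.DataFrame

    def peak_midpoints(self, condition: str) -> PointSet:
        return build_point_set(self.peaks[condition], mode="midpoint")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _simulate_peaks(
    rng: np.random.Generator, config: SimulationConfig, condition: str
) -> list[GenomicInterval]:
    """Place peaks on random chromosomes; optionally without overlap."""
    lo, hi = config.peak_width_range
    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_peaks)
    widths = rng.integers(lo, hi + 1, size=config.n_peaks)
    peaks: list[GenomicInterval] = []
    counter = 0
    for ci, chrom in enumerate(config.chrom_names):
        mask = chrom_idx == ci
        w = widths[mask]
        if w.size == 0:
            continue
        if config.no_overlap:
            slack = config.genome_length - int(w.sum())
            if slack < 0:
                raise ValueError(
                    f"cannot place {w.size} non-overlapping peaks of total width "
                    f"{int(w.sum())} on a {config.genome_length} bp chromosome"
                )
            gaps = np.sort(rng.integers(0, slack + 1, size=w.size))
            starts = gaps + np.concatenate([[0], np.cumsum(w[:-1])])
        else:
            starts = rng.integers(0, config.genome_length - w + 1)
        for s, width in zip(starts, w):
            peaks.append(
                GenomicInterval(
                    chrom,
                    int(s),
                    int(s) + int(width),
                    name=f"peak_{condition}_{counter}",
                )
            )
            counter += 1
    return peaks


def sample_site_centers(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_sites: int,
    pi: float,
    peaks: Sequence[GenomicInterval],
    site_width: int = 10,
) -> dict[str, np.ndarray]:
    """Draw motif-site centers grouped by chromosome.

    A fraction ``pi`` of sites is planted within ``config.r_small`` of a
    randomly chosen peak midpoint (uniform offset), the remainder placed
    uniformly over the genome.  This is the array-level core of site
    simulation; it feeds :func:`simulate_dataset` and can be passed directly
    to :func:`atacmd.mdscore.compute_md_score` for statistic-level studies
    that do not need interval objects.
    """
    mids = np.array([midpoint(p) for p in peaks], dtype=np.int64)
    peak_chroms = np.array([p.chrom for p in peaks])
    half = site_width // 2
    lo_center = half
    hi_center = config.genome_length - (site_width - half)
    planted = rng.random(n_sites) < pi
    n_planted = int(planted.sum())
    n_uniform = n_sites - n_planted

    chroms = np.empty(n_sites, dtype=object)
    centers = np.empty(n_sites, dtype=np.int64)
    if n_planted:
        pick = rng.integers(0, mids.size, size=n_planted)
        offsets = rng.integers(-config.r_small, config.r_small + 1, size=n_planted)
        centers[planted] = np.clip(mids[pick] + offsets, lo_center, hi_center)
        chroms[planted] = peak_chroms[pick]
    if n_uniform:
        ci = rng.integers(0, config.n_chroms, size=n_uniform)
        chroms[~planted] = np.array(config.chrom_names, dtype=object)[ci]
        centers[~planted] = rng.integers(lo_center, hi_center + 1, size=n_uniform)
    return {
        chrom: np.sort(centers[chroms == chrom])
        for chrom in config.chrom_names
        if np.any(chroms == chrom)
    }


def _simulate_sites(
    rng: np.random.Generator,
    config: SimulationConfig,
    spec: MotifSpec,
    condition: str,
    peaks: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Materialize sampled site centers as fixed-width intervals."""
    by_chrom = sample_site_centers(
        rng, config, spec.n_sites, spec.pi(condition), peaks, spec.site_width
    )
    half = spec.site_width // 2
    return [
        GenomicInterval(
            chrom,
            int(c) - half,
            int(c) - half + spec.site_width,
            name=spec.motif_id,
        )
        for chrom in sorted(by_chrom)
        for c in by_chrom[chrom]
    ]


def _window_cover_fraction(
    peaks: Sequence[GenomicInterval], config: SimulationConfig, radius: int
) -> float:
    """Fraction of the genome within ``radius`` of some peak midpoint."""
    total = config.genome_length * config.n_chroms
    covered = 0
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(midpoint(p))
    for mids in by_chrom.values():
        mids.sort()
        cur_lo = cur_hi = None
        for m in mids:
            lo = max(0, m - radius)
            hi = min(config.genome_length, m + radius + 1)
            if cur_hi is None or lo > cur_hi:
                if cur_hi is not None:
                    covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        if cur_hi is not None:
            covered += cur_hi - cur_lo
    return covered / total


def _expected_md(pi: float, f_small: float, f_large: float) -> float:
    """Expected MD-score: planted mass plus uniform capture, small over large."""
    num = pi + (1 - pi) * f_small
    den = pi + (1 - pi) * f_large
    return num / den if den > 0 else float("nan")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedDataset:
    """Generate a full synthetic dataset, optionally writing it to disk.

    Written layout (when ``out_dir`` is given)::

        genome.fa            random sequence (unless with_genome=False)
        peaks_a.bed          condition-A peak calls
        peaks_b.bed          condition-B peak calls
        motifs_a/<id>.bed    per-motif site sets, condition A
        motifs_b/<id>.bed    per-motif site sets, condition B
        truth.tsv            motif_id, pi_a, pi_b, n_sites, expected_md_a/b

    Deterministic given ``config.seed``: the same config writes byte-identical
    files.  The truth table's expected MD-scores combine the planted fraction
    with the uniform capture fractions of the realized peak windows.
    """
    rng = np.random.default_rng(config.seed)
    genome = (
        {c: _random_sequence(rng, config.genome_length) for c in config.chrom_names}
        if config.with_genome
        else None
    )
    peaks = {cond: _simulate_peaks(rng, config, cond) for cond in CONDITIONS}
    sites: dict[str, dict[str, list[GenomicInterval]]] = {c: {} for c in CONDITIONS}
    for spec in config.motifs:
        for cond in CONDITIONS:
            sites[cond][spec.motif_id] = _simulate_sites(
                rng, config, spec, cond, peaks[cond]
            )

    rows = []
    fracs = {
        cond: (
            _window_cover_fraction(peaks[cond], config, config.r_small),
            _window_cover_fraction(peaks[cond], config, config.r_large),
        )
        for cond in CONDITIONS
    }
    for spec in config.motifs:
        rows.append(
            {
                "motif_id": spec.motif_id,
                "pi_a": spec.pi_a,
                "pi_b": spec.pi_b,
                "n_sites": spec.n_sites,
                "expected_md_a": _expected_md(spec.pi_a, *fracs["a"]),
                "expected_md_b": _expected_md(spec.pi_b, *fracs["b"]),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["motif_id", "pi_a", "pi_b", "n_sites", "expected_md_a", "expected_md_b"],
    )

    dataset = SimulatedDataset(config, genome, peaks, sites, truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if genome is not None:
            write_fasta(genome, out_dir / "genome.fa")
        for cond in CONDITIONS:
            write_bed(peaks[cond], out_dir / f"peaks_{cond}.bed")
            motif_dir = out_dir / f"motifs_{cond}"
            motif_dir.mkdir(exist_ok=True)
            for motif_id in sorted(sites[cond]):
                write_bed(sites[cond][motif_id], motif_dir / f"{motif_id}.bed")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    return dataset


def plant_consensus(
    genome: Mapping[str, str],
    pwm: PWM,
    positions: Sequence[tuple[str, int]],
) -> dict[str, str]:
    """Overwrite the PWM consensus at each (chrom, pos); returns a new genome.

    Positions must leave room for the motif width and must not overlap one
    another (overlaps would corrupt previously planted instances).
    """
    consensus = pwm.consensus()
    w = len(consensus)
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos <= len(genome[chrom]) - w:
            raise ValueError(f"plant position {chrom}:{pos} leaves no room for width {w}")
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, plist in by_chrom.items():
        plist.sort()
        for prev, nxt in zip(plist, plist[1:]):
            if nxt < prev + w:
                raise ValueError(
                    f"overlapping plant positions {chrom}:{prev} and {chrom}:{nxt}"
                )
    modified = dict(genome)
    for chrom, plist in by_chrom.items():
        seq = list(modified[chrom])
        for pos in plist:
            seq[pos : pos + w] = consensus
        modified[chrom] = "".join(seq)
    return modified
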