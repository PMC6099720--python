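"""PWM parsing, exact p-value score thresholds, and genome scanning.

A position weight matrix (PWM) models a transcription factor's sequence
preference as per-position base probabilities over {A, C, G, T}.  Windows of
genomic sequence are scored as log2 odds against a background base
distribution (bits).  The score threshold corresponding to a match p-value is
computed *exactly* (up to an integer discretization of the score axis) by
dynamic programming over the background distribution of W-mer scores — the
same construction FIMO uses — rather than by sampling.

Scanning and thresholding share one discretization: log-odds entries are
rounded to integer units of ``1/granularity`` bits, windows are scored by
summing the integer entries, and the DP threshold is an integer in the same
units.  ``score >= threshold`` is therefore exact, with total discretization
error at most ``W / granularity`` bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "BASES",
    "DEFAULT_GRANULARITY",
    "MotifSite",
    "PWM",
    "PwmParseError",
    "parse_pwm",
    "reverse_complement",
    "scan_genome",
    "scan_sequence",
    "threshold_from_pvalue",
]

BASES = "ACGT"
DEFAULT_GRANULARITY = 1000  # integer score units per bit
_ZERO_SMOOTH = 1e-4  # probability mass added per base when a row has exact zeros
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class PwmParseError(ValueError):
    """Raised when a motif file cannot be parsed; names motif and line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """Per-position base-probability matrix with a background model.

    ``matrix`` has shape ``(W, 4)`` in A, C, G, T order; every row sums to 1
    (tolerance 1e-6) and every entry is strictly positive, guaranteed by
    pseudocount/zero smoothing at construction, so log-odds are always finite.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=_uniform_background)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "background", background)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: matrix must have shape (W>=1, 4)")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: matrix rows must sum to 1")
        if np.any(matrix <= 0):
            raise ValueError(f"{self.motif_id}: matrix entries must be positive")
        if background.shape != (4,) or np.any(background <= 0):
            raise ValueError(f"{self.motif_id}: background must be 4 positive probs")
        if not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 1.0,
    ) -> "PWM":
        """Build from a position count matrix; adds ``pseudocount`` per cell."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise PwmParseError(f"{motif_id}: negative counts")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        smoothed = counts + pseudocount
        matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
        return cls(
            motif_id,
            matrix,
            background if background is not None else _uniform_background(),
            pseudocount,
        )

    @classmethod
    def from_probabilities(
        cls,
        motif_id: str,
        probs: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 1.0,
    ) -> "PWM":
        """Build from a probability matrix; rows containing an exact zero are
        smoothed with a small fixed mass so log-odds stay finite, rows without
        zeros pass through unchanged."""
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < 0):
            raise PwmParseError(f"{motif_id}: negative probabilities")
        matrix = probs / probs.sum(axis=1, keepdims=True)
        has_zero = (matrix == 0).any(axis=1)
        if has_zero.any():
            matrix = matrix.copy()
            matrix[has_zero] = (matrix[has_zero] + _ZERO_SMOOTH) / (
                1.0 + 4 * _ZERO_SMOOTH
            )
        return cls(
            motif_id,
            matrix,
            background if background is not None else _uniform_background(),
            pseudocount,
        )

    def log_odds(self) -> np.ndarray:
        """Per-position, per-base log2(matrix / background) in bits."""
        return np.log2(self.matrix / self.background)

    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(BASES[b] for b in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifSite:
    """One scored motif match; coordinates are always forward-strand."""

    interval: GenomicInterval
    strand: str
    score: float
    motif_id: str

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


# ---------------------------------------------------------------------------
# Parsing


def parse_pwm(
    path: str | Path,
    format: str | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> list[PWM]:
    """Parse a motif file into PWMs.

    ``format`` is ``"MEME"`` (MEME text v4, possibly multi-motif, probability
    matrices) or ``"HOCOMOCO-PCM"`` (plain-text count matrix, 4 columns
    A C G T, one row per position, optional ``>ID`` header).  With
    ``format=None`` the file is sniffed: a leading ``MEME version`` line
    selects MEME.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        format = "MEME" if text.lstrip().startswith("MEME") else "HOCOMOCO-PCM"
    fmt = format.upper().replace("_", "-")
    if fmt == "MEME":
        return _parse_meme(text, str(path), background, pseudocount)
    if fmt in ("HOCOMOCO-PCM", "PCM", "HOCOMOCO"):
        return [_parse_pcm(text, str(path), path.stem, background, pseudocount)]
    raise ValueError(f"unknown motif format {format!r}")


def _parse_meme(
    text: str,
    source: str,
    background: np.ndarray | None,
    pseudocount: float,
) -> list[PWM]:
    lines = text.splitlines()
    file_bg: np.ndarray | None = None
    pwms: list[PWM] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            file_bg = np.array([freqs.get(b, 0.25) for b in BASES])
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise PwmParseError(f"{source}:{i + 1}: MOTIF line lacks an id")
            motif_id = parts[1]
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise PwmParseError(
                        f"{source}: motif {motif_id}: no probability matrix found"
                    )
                i += 1
            if i >= n:
                raise PwmParseError(
                    f"{source}: motif {motif_id}: no probability matrix found"
                )
            header = lines[i]
            width = None
            tokens = header.replace("=", " = ").split()
            for j, tok in enumerate(tokens):
                if tok == "w" and j + 2 < len(tokens) and tokens[j + 1] == "=":
                    width = int(tokens[j + 2])
            i += 1
            rows: list[list[float]] = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in stripped.split()]
                except ValueError:
                    raise PwmParseError(
                        f"{source}:{i + 1}: motif {motif_id}: bad matrix row"
                    ) from None
                if len(row) != 4:
                    raise PwmParseError(
                        f"{source}:{i + 1}: motif {motif_id}: expected 4 columns"
                    )
                rows.append(row)
                i += 1
                if width is not None and len(rows) == width:
                    break
            if not rows or (width is not None and len(rows) != width):
                raise PwmParseError(
                    f"{source}: motif {motif_id}: expected {width} matrix rows, "
                    f"got {len(rows)}"
                )
            pwms.append(
                PWM.from_probabilities(
                    motif_id,
                    np.array(rows),
                    background if background is not None else file_bg,
                    pseudocount,
                )
            )
            continue
        i += 1
    if not pwms:
        raise PwmParseError(f"{source}: no MOTIF blocks found")
    return pwms


def _parse_pcm(
    text: str,
    source: str,
    fallback_id: str,
    background: np.ndarray | None,
    pseudocount: float,
) -> PWM:
    motif_id = fallback_id
    rows: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            motif_id = line[1:].split()[0] if line[1:].split() else fallback_id
            continue
        try:
            row = [float(x) for x in line.split()]
        except ValueError:
            raise PwmParseError(
                f"{source}:{lineno}: motif {motif_id}: bad count row"
            ) from None
        if len(row) != 4:
            raise PwmParseError(
                f"{source}:{lineno}: motif {motif_id}: expected 4 columns (A C G T)"
            )
        if any(x < 0 for x in row):
            raise PwmParseError(
                f"{source}:{lineno}: motif {motif_id}: negative count"
            )
        rows.append(row)
    if not rows:
        raise PwmParseError(f"{source}: motif {motif_id}: empty matrix")
    return PWM.from_counts(motif_id, np.array(rows), background, pseudocount)


# ---------------------------------------------------------------------------
# Thresholding and scanning


def _integer_log_odds(pwm: PWM, granularity: int) -> np.ndarray:
    return np.rint(pwm.log_odds() * granularity).astype(np.int64)


def score_distribution(
    pwm: PWM, granularity: int = DEFAULT_GRANULARITY
) -> tuple[int, np.ndarray]:
    """Exact background distribution of integer-discretized W-mer scores.

    Returns ``(lowest_score, probs)`` where ``probs[k]`` is the probability,
    under independent draws from the background, that a random W-mer scores
    ``lowest_score + k`` integer units.  Computed by convolving the four-point
    per-position score distributions.
    """
    ilom = _integer_log_odds(pwm, granularity)
    dist = np.ones(1)
    low = 0
    for row in ilom:
        rmin = int(row.min())
        pos = np.zeros(int(row.max()) - rmin + 1)
        for b in range(4):
            pos[row[b] - rmin] += pwm.background[b]
        dist = np.convolve(dist, pos)
        low += rmin
    return low, dist


def threshold_from_pvalue(
    pwm: PWM, pvalue: float, granularity: int = DEFAULT_GRANULARITY
) -> float:
    """Smallest score t with background P(score >= t) <= pvalue.

    The returned threshold is an exact multiple of ``1/granularity`` bits and
    is consistent with :func:`scan_sequence`, which scores windows in the same
    integer units.  ``pvalue=1`` admits every W-mer (threshold = minimum
    attainable score); a pvalue smaller than the probability of the single
    best W-mer yields a threshold above the maximum score (nothing passes).
    """
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue}")
    low, dist = score_distribution(pwm, granularity)
    survival = np.cumsum(dist[::-1])[::-1]
    # threshold is the smallest ATTAINABLE score meeting the bound, so that
    # e.g. pvalue=1 returns the minimum attainable score rather than a value
    # inside the gap below it
    passing = np.nonzero((survival <= pvalue * (1 + 1e-12)) & (dist > 0))[0]
    t_int = low + (int(passing[0]) if passing.size else dist.size)
    return t_int / granularity


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(code: np.ndarray, ilom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window plus a validity mask (no N inside)."""
    w = ilom.shape[0]
    n_windows = code.size - w + 1
    safe = np.where(code < 0, 0, code)
    scores = np.zeros(n_windows, dtype=np.int64)
    for i in range(w):
        scores += ilom[i, safe[i : i + n_windows]]
    bad = (code < 0).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[w:] - cum[:-w]) == 0
    return scores, valid


def scan_sequence(
    seq: str,
    chrom: str,
    pwm: PWM,
    threshold: float,
    strands: str = "both",
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifSite]:
    """Report every window scoring >= threshold, on one or both strands.

    Case-insensitive over {A, C, G, T, N}; windows containing N are skipped.
    Reverse-strand matches are reported with forward-strand coordinates, so a
    palindromic match yields two sites at identical coordinates.  Sequences
    shorter than the motif width yield an empty list.
    """
    if strands not in ("both", "forward"):
        raise ValueError(f"unknown strands mode {strands!r}")
    w = pwm.width
    if len(seq) < w:
        return []
    code = _encode(seq)
    ilom = _integer_log_odds(pwm, granularity)
    t_int = int(round(threshold * granularity))
    sites: list[MotifSite] = []
    strand_matrices = [("+", ilom)]
    if strands == "both":
        # reverse-complement scoring matrix: reversed positions, complemented bases
        strand_matrices.append(("-", ilom[::-1, ::-1]))
    hits: list[tuple[int, str, int]] = []
    for strand, mat in strand_matrices:
        scores, valid = _window_scores(code, mat)
        for start in np.nonzero(valid & (scores >= t_int))[0]:
            hits.append((int(start), strand, int(scores[start])))
    hits.sort(key=lambda h: (h[0], h[1]))
    for start, strand, iscore in hits:
        sites.append(
            MotifSite(
                interval=GenomicInterval(
                    chrom, start, start + w, name=pwm.motif_id, strand=strand
                ),
                strand=strand,
                score=iscore / granularity,
                motif_id=pwm.motif_id,
            )
        )
    return sites


def sites_to_intervals(sites: Iterable[MotifSite]) -> list[GenomicInterval]:
    """BED6 representation of motif sites (name=motif_id, score=log-odds bits)."""
    return [
        GenomicInterval(
            s.interval.chrom,
            s.interval.start,
            s.interval.end,
            name=s.motif_id,
            score=s.score,
            strand=s.strand,
        )
        for s in sites
    ]


def scan_genome(
    fasta: str | Path,
    pwms: Sequence[PWM],
    pvalue: float,
    out_dir: str | Path,
    strands: str = "both",
    granularity: int = DEFAULT_GRANULARITY,
) -> dict[str, Path]:
    """Scan every FASTA record with every PWM; write one BED6 file per motif.

    Each output file ``<motif_id>.bed`` holds columns chrom, start, end,
    motif_id, score (bits, 4 decimals), strand, sorted by (chrom, start).  A
    motif with no match above threshold still produces an (empty) file.
    Returns a mapping motif_id -> written path.
    """
    import pyfaidx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fa = pyfaidx.Fasta(str(fasta))
    written: dict[str, Path] = {}
    for pwm in pwms:
        threshold = threshold_from_pvalue(pwm, pvalue, granularity)
        sites: list[MotifSite] = []
        for name in fa.keys():
            seq = str(fa[name][:].seq)
            sites.extend(
                scan_sequence(seq, name, pwm, threshold, strands, granularity)
            )
        sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
        path = out_dir / f"{pwm.motif_id}.bed"
        with open(path, "w") as fh:
            for s in sites:
                fh.write(
                    f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                    f"\t{s.motif_id}\t{s.score:.4f}\t{s.strand}\n"
                )
        written[pwm.motif_id] = path
    return written
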