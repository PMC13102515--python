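"""Position-weight-matrix models of TF binding sites and promoter scanning.

A :class:`PWM` stores per-position base probabilities for a TF-family
binding site.  Promoters are scanned on both strands with a log-odds score
relative to a background base composition; hits are reported when the
*relative* score — the window score rescaled between the analytic minimum
and maximum achievable scores — reaches a threshold.  This mirrors the
common "relative score" convention of motif-scanning servers and keeps
results comparable across motifs of different information content.

Coordinates are 0-based and forward-strand anchored: a reverse-strand hit
is reported at the offset of the leftmost forward-strand base of the
matching window.  Windows containing an ``N`` are skipped on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# A<->T, C<->G; N maps to N
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "PWM",
    "MotifLibrary",
    "pwm_log_odds",
    "scan_sequence",
    "scan_promoters",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Probability matrix of a binding-site model, one column per position.

    Parameters
    ----------
    name
        TF-family key the motif stands for.
    probs
        Array of shape ``(4, w)`` over the bases A, C, G, T; every column
        must sum to 1 within 1e-6.
    pseudocount
        Small mass mixed with the background during log-odds conversion so
        zero-probability cells stay finite.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: probs must be 4 x w with w >= 1")
        if np.any(probs < 0):
            raise ValueError(f"PWM {self.name!r}: negative probabilities")
        colsums = probs.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def reverse_complement(self) -> "PWM":
        # complement = reverse base order (A<->T, C<->G), then reverse positions
        return PWM(self.name, self.probs[::-1, ::-1].copy(), self.pseudocount)


@dataclass
class MotifLibrary:
    """Mapping of TF-family name to its PWM."""

    motifs: dict[str, PWM] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pwm in self.motifs.items():
            if name != pwm.name:
                raise ValueError(f"library key {name!r} != motif name {pwm.name!r}")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs.values())

    def __getitem__(self, name: str) -> PWM:
        return self.motifs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.motifs

    @property
    def families(self) -> list[str]:
        return sorted(self.motifs)


def pwm_log_odds(
    pwm: PWM, background: np.ndarray | None = None
) -> tuple[np.ndarray, float, float]:
    """Convert a PWM to a log2-odds score matrix against a background.

    Entry ``(b, i)`` is ``log2((p[b,i] + pc*bg[b]) / ((1 + pc)*bg[b]))``
    where ``pc`` is the pseudocount.  Also returns the analytic maximum and
    minimum achievable window scores (sum of per-column best/worst entries),
    which anchor the relative-score scale used by :func:`scan_sequence`.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or np.any(background <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    pc = pwm.pseudocount
    smoothed = (pwm.probs + pc * background[:, None]) / (1.0 + pc)
    lo = np.log2(smoothed / background[:, None])
    s_max = float(lo.max(axis=0).sum())
    s_min = float(lo.min(axis=0).sum())
    return lo, s_max, s_min


def _encode(seq: str) -> np.ndarray:
    """Map a promoter string to integer codes; N (and only N) becomes 4."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(128, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
    table[ord("N")] = 4
    out = table[codes]
    if np.any(out < 0):
        bad = seq[int(np.argmax(table[codes] < 0))]
        raise ValueError(f"illegal character {bad!r} in sequence")
    return out.astype(np.int64)


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score every forward window; returns (scores, valid_mask)."""
    w = lo.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = lo[safe, np.arange(w)].sum(axis=1)
    return scores, ~has_n


def scan_sequence(
    seq: str,
    pwm: PWM,
    rel_threshold: float = 0.85,
    background: np.ndarray | None = None,
) -> list[tuple[int, str, float]]:
    """Scan one sequence on both strands; return (position, strand, rel_score).

    The relative score of a window with raw log-odds score ``S`` is
    ``(S - S_min) / (S_max - S_min)``; hits require relative score >=
    ``rel_threshold``.  Sequences shorter than the motif yield no hits.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    seq = seq.upper()
    if len(seq) < pwm.width:
        return []
    codes = _encode(seq)
    lo, s_max, s_min = pwm_log_odds(pwm, background)
    span = s_max - s_min
    if span <= 0:
        # completely uninformative motif: every N-free window scores 1.0
        span = 1.0
        s_min = s_max - 1.0
    lo_rc, _, _ = pwm_log_odds(pwm.reverse_complement(), background)

    hits: list[tuple[int, str, float]] = []
    for strand, mat in (("+", lo), ("-", lo_rc)):
        scores, valid = _window_scores(codes, mat)
        rel = (scores - s_min) / span
        for pos in np.nonzero(valid & (rel >= rel_threshold))[0]:
            hits.append((int(pos), strand, float(rel[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def scan_promoters(
    promoters: "PromoterSet | dict[str, str]",
    library: MotifLibrary,
    rel_threshold: float = 0.85,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every promoter against every family motif.

    Returns a MotifHitTable: DataFrame with columns ``gene_id``, ``family``,
    ``position``, ``strand``, ``score``, sorted by (gene_id, family,
    position).  Deterministic; an empty promoter set yields an empty table.
    """
    if len(library) == 0:
        raise ValueError("motif library is empty")
    sequences = getattr(promoters, "sequences", promoters)
    rows = []
    for gene_id in sorted(sequences):
        seq = sequences[gene_id]
        for family in library.families:
            for pos, strand, score in scan_sequence(
                seq, library[family], rel_threshold, background
            ):
                rows.append((gene_id, family, pos, strand, score))
    table = pd.DataFrame(
        rows, columns=["gene_id", "family", "position", "strand", "score"]
    )
    return table.sort_values(
        ["gene_id", "family", "position", "strand"], ignore_index=True
    )
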