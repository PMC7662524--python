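"""Position weight matrices and their algebra.

A :class:`PositionWeightMatrix` stores per-column base probabilities
(columns indexed 5'→3', bases ordered A, C, G, T) together with a
background composition. Log-odds scores are in log2 units throughout,
so one score unit is one bit of preference over background.

Palindromic motifs — those bound by homodimeric regulators such as
CRP-family transcription factors — are exactly self-reverse-complementary;
:func:`palindromize` projects an arbitrary matrix onto that subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order

# minimal IUPAC code for each non-empty base subset
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3; other → -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT only)."""
    return decode(COMPLEMENT_INDEX[encode(seq)[::-1]])


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-column base probabilities with background and pseudocount.

    Parameters
    ----------
    probs
        Array of shape (width, 4); each row sums to 1.
    background
        Length-4 base probabilities; sums to 1.
    pseudocount
        Pseudocount per base per column used when the matrix was
        estimated from counts (kept for provenance; already applied).
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(bg <= 0):
            raise ValueError("background probabilities must be positive")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) log2(p/background); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def consensus(self) -> str:
        """Most probable base per column (ties broken by ACGT order)."""
        return decode(self.probs.argmax(axis=1))

    def score(self, seq: str) -> float:
        """Log-odds score of a sequence of exactly this width."""
        return score_sequence(self, seq)

    @classmethod
    def from_counts(cls, counts: np.ndarray,
                    background: Sequence[float] | None = None,
                    pseudocount: float = 0.25) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(probs, bg, pseudocount)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str],
                       background: Sequence[float] | None = None,
                       pseudocount: float = 0.25) -> "PositionWeightMatrix":
        mats = [encode(s) for s in seqs]
        arr = np.stack(mats)
        counts = np.zeros((arr.shape[1], 4))
        for b in range(4):
            counts[:, b] = (arr == b).sum(axis=0)
        return cls.from_counts(counts, background, pseudocount)


def revcomp_pwm(pwm: PositionWeightMatrix) -> PositionWeightMatrix:
    """Reverse-complement a PWM: reverse columns, swap A<->T and C<->G.

    An involution: ``revcomp_pwm(revcomp_pwm(p)) == p``.
    """
    probs = pwm.probs[::-1, COMPLEMENT_INDEX]
    return PositionWeightMatrix(probs, pwm.background, pwm.pseudocount)


def palindromize(pwm: PositionWeightMatrix) -> PositionWeightMatrix:
    """Project a PWM onto the palindromic (self-reverse-complementary)
    subspace by column-wise averaging with its reverse complement.

    Idempotent; the output satisfies ``revcomp_pwm(out) == out`` exactly.
    """
    probs = 0.5 * (pwm.probs + pwm.probs[::-1, COMPLEMENT_INDEX])
    # enforce exact symmetry against floating addition-order effects
    probs = 0.5 * (probs + probs[::-1, COMPLEMENT_INDEX])
    return PositionWeightMatrix(probs, pwm.background, pwm.pseudocount)


def is_palindromic(pwm: PositionWeightMatrix, atol: float = 1e-9) -> bool:
    return np.allclose(pwm.probs, pwm.probs[::-1, COMPLEMENT_INDEX],
                       atol=atol)


def score_sequence(pwm: PositionWeightMatrix, seq: str) -> float:
    """Sum of per-column log2(p/background) for a width-matched sequence.

    Raises on length mismatch or ambiguous (non-ACGT) bases; genome
    scanners skip such windows rather than scoring them.
    """
    codes = encode(seq)
    if codes.shape[0] != pwm.width:
        raise ValueError(
            f"sequence length {codes.shape[0]} != PWM width {pwm.width}")
    if np.any(codes < 0):
        raise ValueError(f"ambiguous base in sequence {seq!r}")
    return float(pwm.log_odds[np.arange(pwm.width), codes].sum())


def information_content(
        pwm: PositionWeightMatrix) -> tuple[np.ndarray, float]:
    """Per-column information content in bits, and the total.

    Under a uniform background this is the familiar ``2 + Σ p log2 p``
    logo height; for a non-uniform background the generalized
    Kullback–Leibler form ``Σ p log2(p/bg)`` is used (the two coincide
    when bg = 1/4).
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * (np.log2(p) - np.log2(pwm.background)), 0.0)
    per_col = terms.sum(axis=1)
    return per_col, float(per_col.sum())


@dataclass(frozen=True)
class ConsensusSpec:
    """Thresholds for rendering a PWM as a mixed-case/IUPAC string.

    The notation mirrors how CRP-family motifs are written in the
    literature: dominant bases uppercase, strong two-base columns as
    ``(X/y)`` pairs, uninformative columns as ``N``.
    """
    major_threshold: float = 0.75
    pair_threshold: float = 0.75
    minor_floor: float = 0.20
    n_floor: float = 0.40

    def __post_init__(self):
        for v in (self.major_threshold, self.pair_threshold,
                  self.minor_floor, self.n_floor):
            if not (0 < v <= 1):
                raise ValueError("consensus thresholds must be in (0, 1]")


def consensus_string(pwm: PositionWeightMatrix,
                     spec: ConsensusSpec | None = None) -> str:
    """Render a PWM column-by-column in mixed-case/IUPAC notation.

    Rules, applied in order per column (p1 ≥ p2 ≥ ... sorted probs):

    1. p1 ≥ major_threshold          → uppercase base
    2. p1+p2 ≥ pair_threshold and
       p2 ≥ minor_floor              → "(X/y)"; each partner uppercase
                                       iff its probability ≥ 0.5
    3. p1 < n_floor                  → "N"
    4. otherwise                     → minimal IUPAC code covering all
                                       bases with probability ≥ minor_floor
    """
    spec = spec or ConsensusSpec()
    out = []
    for col in pwm.probs:
        order = np.argsort(-col, kind="stable")   # ties -> ACGT order
        p1, p2 = col[order[0]], col[order[1]]
        b1, b2 = BASES[order[0]], BASES[order[1]]
        if p1 >= spec.major_threshold:
            out.append(b1)
        elif p1 + p2 >= spec.pair_threshold and p2 >= spec.minor_floor:
            x = b1 if p1 >= 0.5 else b1.lower()
            y = b2 if p2 >= 0.5 else b2.lower()
            out.append(f"({x}/{y})")
        elif p1 < spec.n_floor:
            out.append("N")
        else:
            covered = frozenset(BASES[i] for i in range(4)
                                if col[i] >= spec.minor_floor)
            if not covered:
                covered = frozenset(b1)
            out.append(_IUPAC[covered])
    return "".join(out)
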