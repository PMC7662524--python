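"""Genome scanning with exact PWM p-values and site annotation.

The p-value of a log-odds score is computed exactly (up to score
quantization) by dynamic programming over the background distribution
of column scores: quantize each column's four scores to a fixed
granularity, convolve the per-column probability mass functions, and
read the right tail. This is the standard approach of FIMO-style
scanners and of TFM-pvalue.

Coordinates are 1-based inclusive on the forward strand; the BED
writer in :mod:`tfdissect.io` handles the 0-based half-open conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pwm import (PositionWeightMatrix, encode, decode, revcomp_pwm,
                  is_palindromic, COMPLEMENT_INDEX)


# ---------------------------------------------------------------------------
# exact score-distribution DP
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Background distribution of quantized PWM scores.

    Column scores (log2 odds) are rounded to integer multiples of
    ``granularity``; the distribution of the quantized total score under
    the background model is the convolution of the per-column pmfs.

    Parameters
    ----------
    pwm
        The matrix whose score distribution is wanted.
    granularity
        Quantization step in log2 units (default 1/1000). The induced
        error on any total score is at most ``width * granularity / 2``.
    """

    def __init__(self, pwm: PositionWeightMatrix,
                 granularity: float = 1e-3):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = granularity
        lo = pwm.log_odds
        if not np.all(np.isfinite(lo)):
            raise ValueError("PWM has zero-probability entries; "
                             "apply a pseudocount before computing p-values")
        self.qscores = np.rint(lo / granularity).astype(np.int64)
        bg = pwm.background
        lows = self.qscores.min(axis=1)
        highs = self.qscores.max(axis=1)
        self.offset = int(lows.sum())          # minimum achievable qscore
        top = int(highs.sum())
        pmf = np.zeros(top - self.offset + 1)
        pmf[0] = 1.0
        # convolve columns; each contributes 4 point masses, so the
        # update is four shifted adds rather than a dense convolution
        pos = 0
        for j in range(pwm.width):
            span = highs[j] - lows[j]
            new = np.zeros(pos + span + 1)
            for b in range(4):
                shift = self.qscores[j, b] - lows[j]
                new[shift:shift + pos + 1] += bg[b] * pmf[:pos + 1]
            pmf[:new.shape[0]] = new
            pmf[new.shape[0]:] = 0.0
            pos += span
        self.pmf = pmf
        # right-tail: tail[k] = P(qscore >= offset + k)
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def quantize(self, score: float | np.ndarray) -> np.ndarray:
        return np.rint(np.asarray(score) / self.granularity).astype(np.int64)

    def pvalue(self, score: float | np.ndarray) -> np.ndarray:
        """P(total quantized score >= quantize(score)) under background."""
        k = self.quantize(score) - self.offset
        k = np.clip(k, 0, self.tail.shape[0])
        padded = np.append(self.tail, 0.0)
        return padded[k]

    def log_mgf(self, lam: float) -> float:
        """log E[exp(lam * S)] of the (unquantized-scale) score in nats."""
        s = (np.arange(self.pmf.shape[0]) + self.offset) * self.granularity
        mask = self.pmf > 0
        x = lam * s[mask] + np.log(self.pmf[mask])
        m = x.max()
        return float(m + np.log(np.exp(x - m).sum()))

    def mean(self) -> float:
        s = (np.arange(self.pmf.shape[0]) + self.offset) * self.granularity
        return float((s * self.pmf).sum())


def exact_pvalue(pwm: PositionWeightMatrix, threshold_score: float,
                 granularity: float = 1e-3) -> float:
    """Exact P(score >= threshold | background) via the quantized DP."""
    return float(ScoreDistribution(pwm, granularity).pvalue(threshold_score))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values,
    returned in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A PWM match on the genome (1-based inclusive coordinates)."""
    start: int
    end: int
    strand: str
    matched_sequence: str
    score: float
    p_value: float
    q_value: float


def _window_scores(codes: np.ndarray, qscores: np.ndarray) -> np.ndarray:
    """Quantized scores of all width-w windows; NaN-like minimum where a
    window contains an ambiguous base (marked with -inf sentinel)."""
    w = qscores.shape[0]
    n = codes.shape[0] - w + 1
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(w):
        cj = codes[j:j + n]
        valid = cj >= 0
        bad |= ~valid
        out += np.where(valid, qscores[j, np.clip(cj, 0, 3)], 0)
    return np.where(bad, np.iinfo(np.int64).min, out)


def scan_genome(pwm: PositionWeightMatrix, genome: str,
                p_threshold: float = 1e-4,
                strand_mode: str = "both",
                granularity: float = 1e-3,
                chunk: int = 200_000) -> list[MotifHit]:
    """Slide a PWM over a genome and report windows with exact p-value
    below ``p_threshold``.

    Both strands are scanned (a reverse-strand hit at a forward window
    means the window's reverse complement matches the PWM). For a
    palindromic PWM the two strands produce identical scores at every
    locus; such duplicate records are merged, keeping the forward-strand
    representation. q-values are Benjamini–Hochberg over every tested
    window on every scanned strand.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    dist = ScoreDistribution(pwm, granularity)
    w = pwm.width
    codes = encode(genome)
    if codes.shape[0] < w:
        import warnings
        warnings.warn("genome shorter than PWM width; no windows tested")
        return []
    strands = ["+", "-"] if strand_mode == "both" else ["+"]
    qmats = {"+": dist.qscores}
    if "-" in strands:
        # reverse-strand window score = forward score under revcomp PWM,
        # quantized per column the same way so p-values stay exact
        qmats["-"] = dist.qscores[::-1][:, COMPLEMENT_INDEX]

    records: list[tuple[int, str, int]] = []   # (win_idx, strand, qscore)
    all_p: list[np.ndarray] = []
    n_windows = codes.shape[0] - w + 1
    qthresh_tail = dist.tail
    for strand in strands:
        qs = qmats[strand]
        for lo_i in range(0, n_windows, chunk):
            hi_i = min(lo_i + chunk, n_windows)
            scores = _window_scores(codes[lo_i:hi_i + w - 1], qs)
            valid = scores > np.iinfo(np.int64).min
            k = np.clip(scores - dist.offset, 0, qthresh_tail.shape[0])
            p = np.append(qthresh_tail, 0.0)[k]
            all_p.append(p[valid])
            hit_idx = np.nonzero(valid & (p < p_threshold))[0]
            for i in hit_idx:
                records.append((lo_i + int(i), strand, int(scores[i])))

    qvals = benjamini_hochberg(np.concatenate(all_p)) if all_p else np.array([])
    # map each hit's p to its q (identical p -> identical q; use a dict)
    pcat = np.concatenate(all_p) if all_p else np.array([])
    p_to_q = {}
    for pv, qv in zip(pcat, qvals):
        p_to_q.setdefault(pv, qv)

    palindromic = is_palindromic(pwm, atol=1e-9)
    tail_pad = np.append(dist.tail, 0.0)
    hits: dict[tuple[int, int, str], MotifHit] = {}
    for win, strand, qscore in sorted(records, key=lambda r: (r[0], r[1])):
        start, end = win + 1, win + w
        if palindromic and strand == "-" and (start, end, "+") in hits:
            continue                # one record per locus, + representation
        window_codes = codes[win:win + w]
        if strand == "+":
            seq = decode(window_codes)
        else:
            seq = decode(COMPLEMENT_INDEX[window_codes[::-1]])
        score = qscore * granularity
        k = min(max(qscore - dist.offset, 0), dist.tail.shape[0])
        p = float(tail_pad[k])
        hits[(start, end, strand)] = MotifHit(
            start, end, strand, seq, score, p, float(p_to_q.get(p, 1.0)))
    return sorted(hits.values(),
                  key=lambda h: (h.p_value, h.start, h.strand))


# ---------------------------------------------------------------------------
# annotation against gene / operon / promoter tracks
# ---------------------------------------------------------------------------

PROMOTER_CLASSES = ("overlapping_core", "upstream_of_minus35",
                    "downstream_of_minus10", "no_promoter_found")


@dataclass(frozen=True)
class SiteAnnotation:
    """A hit placed relative to a gene's transcription start site.

    ``loc`` is the signed distance (bp) from the hit edge nearest the
    TSS, measured in the gene's reading direction; negative = upstream.
    ``operon_pos`` is the gene's position label within its operon
    ("k/n", or "S" for a single transcriptional unit). ``proximal``
    marks sites inside the activator-typical window around the TSS.
    """
    hit: MotifHit
    gene_id: str | None
    loc: int | None
    operon_pos: str | None
    promoter_class: str
    proximal: bool
    candidate_regulated: bool


def tss_relative_location(hit_start: int, hit_end: int,
                          tss: int, gene_strand: str) -> int:
    """Signed TSS-relative location of a hit, reading-direction signed.

    Uses the hit edge nearest the TSS; when the hit spans the TSS the
    upstream edge is used, so a spanning hit reports loc <= 0.
    """
    if gene_strand == "+":
        if hit_end < tss:
            return hit_end - tss
        if hit_start > tss:
            return hit_start - tss
        return hit_start - tss          # spanning: upstream edge, <= 0
    else:
        if hit_start > tss:
            return tss - hit_start
        if hit_end < tss:
            return tss - hit_end
        return tss - hit_end            # spanning: upstream edge, <= 0


def is_first_or_single(operon_pos: str | None) -> bool:
    if operon_pos is None:
        return False
    return operon_pos == "S" or operon_pos.startswith("1/")


def _promoter_class(hit_start: int, hit_end: int, gene_strand: str,
                    elements: pd.DataFrame) -> str:
    """Classify a hit against a gene's core promoter elements.

    Precedence: overlap with any element > entirely upstream of the
    -35 box > entirely downstream of the -10 box > no promoter found.
    'Upstream'/'downstream' follow the gene's reading direction.
    """
    if elements.empty:
        return "no_promoter_found"
    for _, el in elements.iterrows():
        if hit_start <= el["end"] and hit_end >= el["start"]:
            return "overlapping_core"
    m35 = elements[elements["element_type"] == "minus35"]
    if not m35.empty:
        el = m35.iloc[0]
        upstream = (hit_end < el["start"] if gene_strand == "+"
                    else hit_start > el["end"])
        if upstream:
            return "upstream_of_minus35"
    m10 = elements[elements["element_type"] == "minus10"]
    if not m10.empty:
        el = m10.iloc[0]
        downstream = (hit_start > el["end"] if gene_strand == "+"
                      else hit_end < el["start"])
        if downstream:
            return "downstream_of_minus10"
    return "no_promoter_found"


def annotate_hits(hits: Sequence[MotifHit], genes: pd.DataFrame,
                  elements: pd.DataFrame | None = None,
                  window: tuple[int, int] = (-200, 20),
                  max_distance: int = 1000) -> list[SiteAnnotation]:
    """Annotate genomic hits against TSS / operon / promoter tracks.

    ``genes`` needs columns gene_id, strand, tss, operon_pos (and may
    carry operon_id); ``elements`` needs gene_id, element_type
    (minus35 | minus10 | plus1), start, end — the output of an external
    promoter predictor transcribed to a table, consumed as data.

    For each hit the nearest gene on each strand (by |loc|) within
    ``max_distance`` yields one annotation, so a site in a bidirectional
    intergenic region is annotated once per flanking gene. A hit with no
    gene in range yields a single annotation with gene_id None.
    """
    if elements is None:
        elements = pd.DataFrame(
            columns=["gene_id", "element_type", "start", "end"])
    lo, hi = window
    out: list[SiteAnnotation] = []
    for hit in hits:
        found = False
        for strand in ("+", "-"):
            sub = genes[genes["strand"] == strand]
            if sub.empty:
                continue
            locs = np.array([
                tss_relative_location(hit.start, hit.end, int(t), strand)
                for t in sub["tss"]])
            i = int(np.abs(locs).argmin())
            if abs(int(locs[i])) > max_distance:
                continue
            row = sub.iloc[i]
            loc = int(locs[i])
            gene_elements = elements[elements["gene_id"] == row["gene_id"]]
            pclass = _promoter_class(hit.start, hit.end, strand,
                                     gene_elements)
            proximal = lo <= loc <= hi
            op = row.get("operon_pos")
            out.append(SiteAnnotation(
                hit=hit, gene_id=str(row["gene_id"]), loc=loc,
                operon_pos=None if pd.isna(op) else str(op),
                promoter_class=pclass, proximal=proximal,
                candidate_regulated=proximal and is_first_or_single(
                    None if pd.isna(op) else str(op))))
            found = True
        if not found:
            out.append(SiteAnnotation(
                hit=hit, gene_id=None, loc=None, operon_pos=None,
                promoter_class="no_promoter_found", proximal=False,
                candidate_regulated=False))
    return out


def proximal_filter(locs: Sequence[int],
                    window: tuple[int, int] = (-200, 20)) -> list[int]:
    """Retain TSS-relative locations inside the proximal window
    (boundary-inclusive), the region typical for activator binding."""
    lo, hi = window
    return [x for x in locs if lo <= x <= hi]
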