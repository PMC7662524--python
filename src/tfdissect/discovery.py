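"""De novo motif discovery by expectation-maximization.

The model is ZOOPS ("zero or one occurrence per sequence"): each input
sequence contains, with prior probability γ, exactly one motif instance
at a uniformly distributed position (and strand, when both strands are
searched), and otherwise is pure background. EM alternates a posterior
site-location E-step with a pseudocounted PWM / γ M-step. An optional
palindromic constraint — appropriate for homodimer-bound motifs —
replaces the M-step estimate with its projection onto the
self-reverse-complementary subspace, which is the constrained maximizer,
so the likelihood ascent property is preserved.

Candidate widths are compared by an E-value: the expected number of
equally extreme motifs in background data, computed as the number of
possible placements times a large-deviation (Chernoff) bound on the
tail probability of the summed per-site log-likelihood ratio under the
background score distribution. Low-information flanking columns are
trimmed before the comparison, as width optimizers in standard motif
discovery tools do; without the trim, overwide candidates that wrap a
true motif in near-background columns win marginal, meaningless
E-value improvements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .pwm import (PositionWeightMatrix, encode, COMPLEMENT_INDEX,
                  palindromize, information_content)
from .scan import ScoreDistribution

LN2 = np.log(2.0)


@dataclass
class MotifModel:
    """A fitted ZOOPS motif model."""
    pwm: PositionWeightMatrix
    site_prob: float                 # ZOOPS gamma
    log_likelihood: float            # nats, full data log-likelihood
    e_value: float                   # may underflow to 0; see log10_e_value
    log10_e_value: float
    n_sites: float                   # expected number of sites
    strand_mode: str = "both"
    low_complexity: bool = False
    ll_trace: list = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.pwm.width


def _estimate_background(mats: np.ndarray) -> np.ndarray:
    counts = np.bincount(mats.ravel(), minlength=4).astype(float)
    bg = (counts + 1.0) / (counts.sum() + 4.0)
    return bg / bg.sum()


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """(n, m) log2-odds scores of all width-w windows of each sequence."""
    w = lo.shape[0]
    n, L = codes.shape
    m = L - w + 1
    out = np.zeros((n, m))
    for j in range(w):
        out += lo[j, codes[:, j:j + m]]
    return out


def _em(codes: np.ndarray, bg: np.ndarray, init_probs: np.ndarray,
        palindromic: bool, strand_mode: str, pseudocount: float,
        tol: float = 1e-6, max_iter: int = 200
        ) -> tuple[PositionWeightMatrix, float, float, np.ndarray, list]:
    """Run ZOOPS EM from one start; returns (pwm, gamma, ll, Z, trace)."""
    n, L = codes.shape
    w = init_probs.shape[0]
    m = L - w + 1
    n_strands = 2 if strand_mode == "both" else 1
    probs = init_probs
    if palindromic:
        probs = 0.5 * (probs + probs[::-1, COMPLEMENT_INDEX])
    gamma = 0.5
    log_bg = float(np.log(bg)[codes].sum())   # constant part, nats
    onehot = np.eye(4)[codes]                 # (n, L, 4)
    trace: list[float] = []
    ll = -np.inf
    Z = np.zeros(n)
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lo = np.log2(probs) - np.log2(bg)
        sf = _window_scores(codes, lo)                       # (n, m)
        mats = [sf]
        if n_strands == 2:
            lo_rc = lo[::-1][:, COMPLEMENT_INDEX]
            mats.append(_window_scores(codes, lo_rc))        # reverse strand
        S = np.stack(mats, axis=1)                           # (n, st, m)
        # posterior over (no site) vs each (strand, position)
        prior_site = gamma / (n_strands * m)
        with np.errstate(over="ignore"):
            lik_site = prior_site * np.exp2(S)
        total_site = lik_site.sum(axis=(1, 2))
        denom = (1.0 - gamma) + total_site
        post = lik_site / denom[:, None, None]
        Z = total_site / denom
        new_ll = log_bg + float(np.log(denom).sum())
        trace.append(new_ll)
        # M-step: weighted counts
        counts = np.full((w, 4), pseudocount)
        pf = post[:, 0, :]
        for j in range(w):
            counts[j] += np.einsum("np,npb->b", pf, onehot[:, j:j + m, :])
        if n_strands == 2:
            pr = post[:, 1, :]
            rc_counts = np.zeros((w, 4))
            for j in range(w):
                rc_counts[j] += np.einsum("np,npb->b", pr,
                                          onehot[:, j:j + m, :])
            counts += rc_counts[::-1][:, COMPLEMENT_INDEX]
        if palindromic:
            counts = 0.5 * (counts + counts[::-1][:, COMPLEMENT_INDEX])
        probs = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(Z.mean(), 1e-6, 1.0 - 1e-6))
        if new_ll - ll < tol and np.isfinite(ll):
            ll = new_ll
            break
        ll = new_ll
    pwm = PositionWeightMatrix(probs, bg, pseudocount)
    if palindromic:
        pwm = palindromize(pwm)
    return pwm, gamma, ll, Z, trace


def _expected_site_score(codes: np.ndarray, pwm: PositionWeightMatrix,
                         gamma: float, strand_mode: str
                         ) -> tuple[float, float]:
    """One E-step under a fixed model: (expected n_sites, expected total
    site log2-odds score)."""
    n, L = codes.shape
    w = pwm.width
    m = L - w + 1
    n_strands = 2 if strand_mode == "both" else 1
    lo = pwm.log_odds
    mats = [_window_scores(codes, lo)]
    if n_strands == 2:
        mats.append(_window_scores(codes, lo[::-1][:, COMPLEMENT_INDEX]))
    S = np.stack(mats, axis=1)
    prior_site = gamma / (n_strands * m)
    lik_site = prior_site * np.exp2(S)
    denom = (1.0 - gamma) + lik_site.sum(axis=(1, 2))
    post = lik_site / denom[:, None, None]
    n_sites = float(post.sum())
    total_score = float((post * S).sum())
    return n_sites, total_score


def evalue(pwm: PositionWeightMatrix, n_sites: float, total_score: float,
           n_placements: float, granularity: float = 5e-3) -> float:
    """log10 E-value of a motif: placements × tail bound.

    The tail is P(sum of n_sites independent background site scores
    >= total_score), bounded by the Chernoff / large-deviation rate
    inf_λ [n·log M(λ) − λ·T] computed from the exact per-site score
    distribution (the same DP the genome scanner uses). The bound is
    linear in n_sites at fixed per-site score, matching how motif
    E-values scale with site count.

    Returns log10(E); callers exponentiate only when it will not
    underflow.
    """
    if n_sites <= 0 or n_placements <= 0:
        return float(np.log10(max(n_placements, 1.0)))
    dist = ScoreDistribution(pwm, granularity)
    mean = dist.mean()
    if total_score <= n_sites * mean:
        return float(np.log10(n_placements))      # no enrichment: tail ~ 1

    def objective(lam: float) -> float:
        return n_sites * dist.log_mgf(lam * LN2) - lam * LN2 * total_score

    res = minimize_scalar(objective, bounds=(0.0, 200.0), method="bounded")
    log_tail_nats = min(res.fun, 0.0)
    return float(np.log10(n_placements) + log_tail_nats / np.log(10.0))


def trim_low_information_flanks(
        pwm: PositionWeightMatrix, ic_floor: float = 0.2
        ) -> PositionWeightMatrix:
    """Drop leading/trailing columns with information content below
    ``ic_floor`` bits. A palindromic input stays palindromic because its
    information-content profile is symmetric."""
    ic, _ = information_content(pwm)
    lo, hi = 0, pwm.width
    while lo < hi - 1 and ic[lo] < ic_floor:
        lo += 1
    while hi > lo + 1 and ic[hi - 1] < ic_floor:
        hi -= 1
    if (lo, hi) == (0, pwm.width):
        return pwm
    return PositionWeightMatrix(pwm.probs[lo:hi], pwm.background,
                                pwm.pseudocount)


def discover_motif(sequences: list[str],
                   width_range: tuple[int, int] = (6, 24),
                   palindromic: bool = False,
                   n_starts: int = 10,
                   seed: int = 0,
                   strand_mode: str = "both",
                   pseudocount: float = 0.25,
                   background: np.ndarray | None = None,
                   tol: float = 1e-6,
                   max_iter: int = 200) -> MotifModel:
    """Learn the best motif over a range of widths.

    For each candidate width, EM is run from ``n_starts`` seeds (each an
    observed w-mer from the data, softened into an initial PWM), the
    highest-likelihood fit is kept, its uninformative flanks are trimmed,
    and candidates are ranked by E-value; the minimum-E-value candidate
    across widths is returned.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    min_w, max_w = width_range
    shortest = min(len(s) for s in sequences)
    if not (1 <= min_w <= max_w <= shortest):
        raise ValueError(
            f"width range ({min_w},{max_w}) incompatible with shortest "
            f"sequence length {shortest}")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    codes = np.stack([encode(s) for s in sequences])
    if np.any(codes < 0):
        raise ValueError("sequences must be unambiguous A/C/G/T")
    bg = (_estimate_background(codes) if background is None
          else np.asarray(background, dtype=float))
    low_complexity = bool(bg.max() > 0.95)
    rng = np.random.default_rng(seed)
    n, L = codes.shape
    n_strands = 2 if strand_mode == "both" else 1

    best: MotifModel | None = None
    for w in range(min_w, max_w + 1):
        m = L - w + 1
        # screen starts with a few EM iterations, then converge the best
        best_ll, best_probs = -np.inf, None
        for _ in range(n_starts):
            i = rng.integers(n)
            p = rng.integers(m)
            seed_mer = codes[i, p:p + w]
            init = np.full((w, 4), 0.1)
            init[np.arange(w), seed_mer] = 0.7
            short = _em(codes, bg, init, palindromic, strand_mode,
                        pseudocount, tol=-np.inf, max_iter=8)
            if short[2] > best_ll:
                best_ll, best_probs = short[2], short[0].probs
        assert best_probs is not None
        pwm, gamma, ll, Z, trace = _em(
            codes, bg, best_probs, palindromic, strand_mode,
            pseudocount, tol, max_iter)
        trimmed = trim_low_information_flanks(pwm)
        if trimmed.width != pwm.width:
            # refine briefly at the trimmed width
            pwm2, gamma, ll, Z, trace2 = _em(
                codes, bg, trimmed.probs, palindromic, strand_mode,
                pseudocount, tol, max_iter=50)
            pwm = pwm2
            trace = trace + trace2
        n_sites, total_score = _expected_site_score(
            codes, pwm, gamma, strand_mode)
        placements = float(n) * (L - pwm.width + 1) * n_strands
        log10_e = evalue(pwm, n_sites, total_score, placements)
        model = MotifModel(
            pwm=pwm, site_prob=gamma, log_likelihood=ll,
            e_value=float(10.0 ** log10_e) if log10_e > -300 else 0.0,
            log10_e_value=log10_e, n_sites=n_sites,
            strand_mode=strand_mode, low_complexity=low_complexity,
            ll_trace=trace)
        if best is None or model.log10_e_value < best.log10_e_value:
            best = model
    assert best is not None
    return best
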