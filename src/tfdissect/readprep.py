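"""Selection-read preparation: cassette extraction, deduplication,
subsampling.

Raw reads from an iterative-selection experiment are fixed-architecture
amplicons — 5' primer arm, randomized cassette, 3' primer arm — so
cassette recovery is Hamming-distance flank matching (no indels) with
an orientation rescue: if the forward read does not match, its reverse
complement is tried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .pwm import encode, revcomp
from .simulate import SelectionLibraryConfig


class Rejection(Enum):
    FLANKS_NOT_FOUND = "flanks_not_found"
    WRONG_CASSETTE_LENGTH = "wrong_cassette_length"
    LOW_QUALITY = "low_quality"


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: tuple | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.quality is not None and \
                len(self.quality) != len(self.sequence):
            raise ValueError("quality length != sequence length")


@dataclass
class CassetteSet:
    """Deduplicated cassettes plus per-stage bookkeeping."""
    sequences: list[str]
    provenance: dict = field(default_factory=dict)  # cassette -> read ids
    stats: dict = field(default_factory=dict)


def _find_flank(seq_codes: np.ndarray, flank_codes: np.ndarray,
                max_mismatch: int, from_end: bool = False) -> int | None:
    """Leftmost (or rightmost) Hamming match position of a flank."""
    n, k = seq_codes.shape[0], flank_codes.shape[0]
    if n < k:
        return None
    positions = range(n - k, -1, -1) if from_end else range(n - k + 1)
    for p in positions:
        if int((seq_codes[p:p + k] != flank_codes).sum()) <= max_mismatch:
            return p
    return None


def extract_cassette(read: ReadRecord, library: SelectionLibraryConfig,
                     max_mismatch: int = 1
                     ) -> str | Rejection:
    """Recover the between-flank cassette from one read.

    Both flanks must match with at most ``max_mismatch`` substitutions
    each (no indels); the cassette is accepted only at the configured
    length. A read whose forward orientation fails is retried as its
    reverse complement.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    f5 = encode(library.flank5)
    f3 = encode(library.flank3)
    for seq in (read.sequence, revcomp(read.sequence)) \
            if set(read.sequence.upper()) <= set("ACGT") \
            else (read.sequence,):
        codes = encode(seq)
        p5 = _find_flank(codes, f5, max_mismatch)
        if p5 is None:
            continue
        p3 = _find_flank(codes[p5 + f5.shape[0]:], f3, max_mismatch,
                         from_end=True)
        if p3 is None:
            continue
        start = p5 + f5.shape[0]
        cassette = seq[start:start + p3]
        if len(cassette) != library.cassette_length:
            return Rejection.WRONG_CASSETTE_LENGTH
        return cassette.upper()
    return Rejection.FLANKS_NOT_FOUND


def prepare_cassettes(reads: list[ReadRecord],
                      library: SelectionLibraryConfig,
                      max_mismatch: int = 1,
                      dedup_mode: str = "exact",
                      min_mean_quality: float | None = None
                      ) -> CassetteSet:
    """Full read → cassette pipeline with stage accounting.

    Stage counts (input ≥ quality-passed ≥ flank-matched ≥
    length-passed ≥ deduplicated) land in ``stats``; rejection reasons
    partition the rejected reads.
    """
    stats = {"input": len(reads), "rejected": {}}
    accepted: list[tuple[str, str]] = []
    for read in reads:
        if min_mean_quality is not None and read.quality is not None \
                and float(np.mean(read.quality)) < min_mean_quality:
            reason = Rejection.LOW_QUALITY.value
            stats["rejected"][reason] = stats["rejected"].get(reason, 0) + 1
            continue
        out = extract_cassette(read, library, max_mismatch)
        if isinstance(out, Rejection):
            stats["rejected"][out.value] = \
                stats["rejected"].get(out.value, 0) + 1
        else:
            accepted.append((read.id, out))
    stats["length_passed"] = len(accepted)
    result = deduplicate([c for _, c in accepted], mode=dedup_mode)
    prov: dict[str, list[str]] = {}
    for rid, c in accepted:
        key = c if dedup_mode == "exact" else min(c, revcomp(c))
        prov.setdefault(key, []).append(rid)
    result.provenance = {s: prov.get(
        s if dedup_mode == "exact" else min(s, revcomp(s)), [])
        for s in result.sequences}
    result.stats = {**stats, **result.stats}
    return result


def deduplicate(cassettes: list[str], mode: str = "exact") -> CassetteSet:
    """Collapse duplicate cassettes.

    ``exact`` keeps the first occurrence of each distinct string;
    ``strand_collapsed`` additionally identifies a cassette with its
    reverse complement (sequencing orientation is arbitrary for a
    double-stranded cassette), keeping the lexicographically smaller
    representative.
    """
    if mode not in ("exact", "strand_collapsed"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    seen: set[str] = set()
    out: list[str] = []
    for c in cassettes:
        key = c if mode == "exact" else min(c, revcomp(c))
        if key not in seen:
            seen.add(key)
            out.append(key if mode == "strand_collapsed" else c)
    return CassetteSet(sequences=out,
                       stats={"deduplicated": len(out)})


def sample_reads(cassettes: CassetteSet | list[str], n: int,
                 seed: int = 0) -> list[str]:
    """Uniform sample of ``n`` cassettes without replacement."""
    seqs = cassettes.sequences if isinstance(cassettes, CassetteSet) \
        else list(cassettes)
    if n > len(seqs):
        raise ValueError(f"requested {n} > available {len(seqs)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seqs), size=n, replace=False)
    return [seqs[i] for i in idx]
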