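"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: iterative
selection (REPSA/SELEX-style) read pools, genomes with planted binding
sites and gene/operon/promoter annotation tracks, 1:1 Langmuir
sensorgrams, and two-group log-scale expression matrices. All
generators are pure functions of their spec plus a seed.

The selection simulator models one round of restriction endonuclease
protection, selection and amplification: a cassette survives cleavage
with probability ``occupancy + (1 - occupancy) * (1 - cleavage
efficiency)``, where occupancy follows a single-site equilibrium
``[P] / ([P] + KD)`` and a cassette's KD derives from its best PWM
site on either strand via an additive log-odds → ΔΔG map. A
configurable fraction of molecules is intrinsically resistant to
enzyme A (emulating selection of cleavage-resistant artifacts, purged
by switching to an alternative, less efficient enzyme).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import PositionWeightMatrix, encode, decode, COMPLEMENT_INDEX

# synthetic 18-mer primer arms (the real ones are configurable);
# deliberately not reverse complements of each other so that read
# orientation is decidable
_DEFAULT_FLANK5 = "GGAATTCGCCTGACTGCA"
_DEFAULT_FLANK3 = "TCCAGGTCTGACGGATCC"

#: GC-rich preset approximating the Thermus thermophilus chromosome
THERMUS_BACKGROUND = np.array([0.155, 0.345, 0.345, 0.155])


@dataclass(frozen=True)
class SelectionLibraryConfig:
    """A randomized-cassette selection library: fixed primer arms
    around a ``cassette_length``-bp random core."""
    flank5: str = _DEFAULT_FLANK5
    flank3: str = _DEFAULT_FLANK3
    cassette_length: int = 24
    pool_size: int = 10_000
    seed: int = 0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        if self.cassette_length <= 0:
            raise ValueError("cassette_length must be positive")
        for fl in (self.flank5, self.flank3):
            if not fl or np.any(encode(fl) < 0):
                raise ValueError("flanks must be non-empty A/C/G/T strings")


@dataclass(frozen=True)
class RepsaRoundConfig:
    """Parameters of the per-round selection pressure.

    cleavage_efficiency maps enzyme label -> fraction of unprotected
    molecules actually cut; resistant_fraction is the pool fraction
    intrinsically uncleavable by enzyme A regardless of protein binding.
    """
    protein_concentration: float = 50.6e-9          # molar
    reference_kd: float = 2.214e-9                  # consensus-site KD, molar
    energy_scale: float = 1.0                       # kT per log2 unit deficit
    cleavage_efficiency: dict = field(
        default_factory=lambda: {"A": 0.95, "B": 0.8})
    resistant_fraction: float = 0.0
    rounds: tuple = ("A", "A", "A", "A", "B", "B", "B")

    def __post_init__(self):
        for v in self.cleavage_efficiency.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("cleavage_efficiency must be in [0, 1]")
        if not (0.0 <= self.resistant_fraction < 1.0):
            raise ValueError("resistant_fraction must be in [0, 1)")


@dataclass
class SelectionPool:
    """State of the molecule pool after each selection round."""
    cassettes: np.ndarray          # (pool_size, cassette_length) int8 codes
    resistant: np.ndarray          # (pool_size,) bool, enzyme-A-resistant
    round_index: int

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.cassettes]


@dataclass
class SelectionResult:
    pools: list[SelectionPool]
    reads: list[list[str]]                 # flank5+cassette+flank3 per round
    motif_bearing_fraction: list[float]    # ground truth per round (0 = input)
    resistant_fraction: list[float]


def _best_site_scores(cassettes: np.ndarray,
                      pwm: PositionWeightMatrix) -> np.ndarray:
    """Best log2-odds site score per cassette over positions and strands."""
    lo = pwm.log_odds
    w = pwm.width
    n, L = cassettes.shape
    m = L - w + 1
    fwd = np.zeros((n, m))
    rev = np.zeros((n, m))
    lo_rc = lo[::-1][:, COMPLEMENT_INDEX]
    for j in range(w):
        fwd += lo[j, cassettes[:, j:j + m]]
        rev += lo_rc[j, cassettes[:, j:j + m]]
    return np.maximum(fwd.max(axis=1), rev.max(axis=1))


def cassette_kd(cassettes: np.ndarray, pwm: PositionWeightMatrix,
                reference_kd: float, energy_scale: float) -> np.ndarray:
    """Per-cassette KD: reference KD scaled by exp(energy_scale x
    log2-odds deficit of the best site relative to the consensus)."""
    deficit = pwm.max_score() - _best_site_scores(cassettes, pwm)
    return reference_kd * np.exp(energy_scale * deficit)


def simulate_selection(library: SelectionLibraryConfig,
                       round_cfg: RepsaRoundConfig,
                       motif: PositionWeightMatrix,
                       bearing_kd_ratio: float = 10.0) -> SelectionResult:
    """Run Monte-Carlo rounds of bind / cleave / amplify selection.

    A cassette is counted as "motif-bearing" (ground-truth reporting
    only) when its best-site KD is within ``bearing_kd_ratio`` of the
    consensus KD. Survivors of each round are resampled with
    replacement back to pool size (uniform-multinomial PCR).
    """
    if motif.width > library.cassette_length:
        raise ValueError(
            f"motif width {motif.width} exceeds cassette length "
            f"{library.cassette_length}")
    rng = np.random.default_rng(library.seed)
    n = library.pool_size
    cassettes = rng.choice(4, size=(n, library.cassette_length),
                           p=library.background).astype(np.int8)
    resistant = rng.random(n) < round_cfg.resistant_fraction

    def bearing_frac(c: np.ndarray) -> float:
        kd = cassette_kd(c, motif, round_cfg.reference_kd,
                         round_cfg.energy_scale)
        return float((kd <= bearing_kd_ratio * round_cfg.reference_kd)
                     .mean())

    pools: list[SelectionPool] = []
    reads: list[list[str]] = []
    frac = [bearing_frac(cassettes)]
    res_frac = [float(resistant.mean())]
    for r, enzyme in enumerate(round_cfg.rounds, start=1):
        kd = cassette_kd(cassettes, motif, round_cfg.reference_kd,
                         round_cfg.energy_scale)
        occ = round_cfg.protein_concentration / (
            round_cfg.protein_concentration + kd)
        eff = round_cfg.cleavage_efficiency[enzyme]
        p_survive = occ + (1.0 - occ) * (1.0 - eff)
        if enzyme == "A":
            p_survive = np.where(resistant, 1.0, p_survive)
        alive = rng.random(n) < p_survive
        if not alive.any():
            raise RuntimeError(
                f"selection pool extinct after round {r} (enzyme {enzyme})")
        idx = np.nonzero(alive)[0]
        pick = rng.choice(idx, size=n, replace=True)
        cassettes = cassettes[pick]
        resistant = resistant[pick]
        pools.append(SelectionPool(cassettes.copy(), resistant.copy(), r))
        reads.append([library.flank5 + decode(row) + library.flank3
                      for row in cassettes])
        frac.append(bearing_frac(cassettes))
        res_frac.append(float(resistant.mean()))
    return SelectionResult(pools, reads, frac, res_frac)


def planted_read_pool(consensus: str, n_reads: int,
                      planted_fraction: float,
                      library: SelectionLibraryConfig | None = None,
                      per_base_identity: float = 1.0,
                      seed: int = 0) -> tuple[list[str], np.ndarray]:
    """Reads with motif instances planted in a fraction of cassettes.

    Emulates a late selection round directly: ``planted_fraction`` of
    cassettes carry one instance, at a uniform offset and strand,
    drawn from a per-column model placing ``per_base_identity``
    probability on the consensus base (1.0 plants the exact consensus).
    Returns (reads, planted mask).
    """
    library = library or SelectionLibraryConfig()
    rng = np.random.default_rng(seed)
    w = len(consensus)
    L = library.cassette_length
    if w > L:
        raise ValueError("consensus longer than cassette")
    cons = encode(consensus)
    cassettes = rng.choice(4, size=(n_reads, L),
                           p=library.background).astype(np.int8)
    planted = rng.random(n_reads) < planted_fraction
    offsets = rng.integers(0, L - w + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    for i in np.nonzero(planted)[0]:
        inst = cons.copy()
        if per_base_identity < 1.0:
            miss = rng.random(w) >= per_base_identity
            inst[miss] = rng.integers(0, 4, size=int(miss.sum()))
        if strands[i]:
            inst = COMPLEMENT_INDEX[inst[::-1]].astype(np.int8)
        o = offsets[i]
        cassettes[i, o:o + w] = inst
    reads = [library.flank5 + decode(row) + library.flank3
             for row in cassettes]
    return reads, planted


# ---------------------------------------------------------------------------
# sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgram(kon: float, koff: float, rmax: float,
                        concentrations: list[float],
                        t_assoc: float = 300.0, t_dissoc: float = 300.0,
                        dt: float = 1.0, noise_sd: float = 0.0,
                        seed: int = 0) -> list["pd.DataFrame"]:
    """Noisy 1:1 Langmuir sensorgrams, one per analyte concentration.

    Association: R(t) = Rmax*C/(C+KD) * (1 - exp(-(kon*C+koff)*t));
    dissociation from the association endpoint: R(t') = R_end *
    exp(-koff*t'). Additive Gaussian noise. Each frame has columns
    time_s, response, concentration_M, phase.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kon <= 0 or koff <= 0 or rmax <= 0 or t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("rates, rmax and phase durations must be positive")
    if len(set(concentrations)) != len(concentrations):
        raise ValueError("concentrations must be distinct")
    rng = np.random.default_rng(seed)
    kd = koff / kon
    out = []
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    t_d = np.arange(dt, t_dissoc + dt / 2, dt)
    for c in concentrations:
        kobs = kon * c + koff
        r_eq = rmax * c / (c + kd)
        r_assoc = r_eq * (1.0 - np.exp(-kobs * t_a))
        r_end = r_assoc[-1]
        r_dissoc = r_end * np.exp(-koff * t_d)
        t = np.concatenate([t_a, t_assoc + t_d])
        r = np.concatenate([r_assoc, r_dissoc])
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        phase = np.where(t <= t_assoc, "association", "dissociation")
        out.append(pd.DataFrame({
            "time_s": t, "response": r,
            "concentration_M": c, "phase": phase}))
    return out


# ---------------------------------------------------------------------------
# synthetic genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """A genome with planted sites and gene/operon/promoter tracks.

    planted_sites: (sequence, 1-based coordinate, strand) triples;
    gene_models: (gene_id, strand, tss, operon_id, operon_pos) tuples;
    promoter_elements: (gene_id, element_type, start, end) tuples with
    element_type in {minus35, minus10, plus1}.
    """
    length: int
    planted_sites: tuple = ()
    gene_models: tuple = ()
    promoter_elements: tuple = ()
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    seed: int = 0

    def __post_init__(self):
        for seq, pos, strand in self.planted_sites:
            if pos < 1 or pos + len(seq) - 1 > self.length:
                raise ValueError(
                    f"planted site at {pos} does not fit in genome")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
        for _, et, s, e in self.promoter_elements:
            if s > e:
                raise ValueError(f"invalid element interval {s}>{e}")
            if et not in ("minus35", "minus10", "plus1"):
                raise ValueError(f"unknown element type {et!r}")


def build_synthetic_genome(
        spec: SyntheticGenomeSpec
        ) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Background genome with sites planted at stated coordinates.

    Returns (genome string, gene table, promoter-element table).
    Minus-strand sites are written reverse-complemented into the
    forward-strand text. Overlapping planted sites raise with the
    collision list.
    """
    from .pwm import revcomp
    intervals = sorted(
        (pos, pos + len(seq) - 1, seq, strand)
        for seq, pos, strand in spec.planted_sites)
    collisions = [
        (a, b) for a, b in zip(intervals, intervals[1:]) if b[0] <= a[1]]
    if collisions:
        raise ValueError(f"overlapping planted sites: {collisions}")
    rng = np.random.default_rng(spec.seed)
    codes = rng.choice(4, size=spec.length, p=spec.background)
    genome = list(decode(codes))
    for pos, _, seq, strand in intervals:
        s = seq if strand == "+" else revcomp(seq)
        genome[pos - 1:pos - 1 + len(seq)] = list(s.upper())
    genes = pd.DataFrame(
        list(spec.gene_models),
        columns=["gene_id", "strand", "tss", "operon_id", "operon_pos"])
    elements = pd.DataFrame(
        list(spec.promoter_elements),
        columns=["gene_id", "element_type", "start", "end"])
    return "".join(genome), genes, elements


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-group (test vs control) log2-scale expression design."""
    n_genes: int = 100
    samples_per_group: int = 3
    planted_logfc: dict = field(default_factory=dict)
    noise_sd: float = 0.2
    baseline_mean: float = 8.0
    operon_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_expression(spec: ExpressionSimSpec) -> pd.DataFrame:
    """Genes x samples matrix of log2 intensities with planted effects.

    Test-group means exceed control means by the planted log2
    fold-change; i.i.d. Gaussian noise on top. Column index carries a
    (sample_id, group) MultiIndex; row index is gene_id.
    """
    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]
    for g in spec.planted_logfc:
        if g not in gene_ids:
            gene_ids.append(g)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng(spec.seed)
    k = spec.samples_per_group
    base = spec.baseline_mean + rng.normal(0, 1.0, size=len(gene_ids))
    lfc = np.array([spec.planted_logfc.get(g, 0.0) for g in gene_ids])
    control = base[:, None] + rng.normal(
        0, spec.noise_sd, size=(len(gene_ids), k))
    test = (base + lfc)[:, None] + rng.normal(
        0, spec.noise_sd, size=(len(gene_ids), k))
    cols = pd.MultiIndex.from_tuples(
        [(f"test{i+1}", "test") for i in range(k)]
        + [(f"control{i+1}", "control") for i in range(k)],
        names=["sample_id", "group"])
    return pd.DataFrame(np.hstack([test, control]),
                        index=pd.Index(gene_ids, name="gene_id"),
                        columns=cols)
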