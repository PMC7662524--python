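"""Global 1:1 Langmuir kinetic fitting of biolayer-interferometry
sensorgrams.

A single (kon, koff, Rmax) triple is fitted jointly across all analyte
concentrations — the model used when one rate pair per probe is
reported from a 4-concentration titration. The association phase is

    R(t) = Rmax * C / (C + KD) * (1 - exp(-(kon*C + koff) * t)),

KD = koff/kon, and the dissociation phase decays from the association
endpoint as R(t') = R_end * exp(-koff * t'). Optimization is
deterministic: a 5x5 log-spaced (kon, koff) grid of starts, each
refined by trust-region least squares; goodness of fit is the pooled
R² over every point of every curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class Sensorgram:
    """One concentration-labelled association/dissociation trace."""
    concentration: float            # molar
    times: np.ndarray               # s, strictly increasing
    responses: np.ndarray           # instrument response units
    phase_boundary: float           # s, association -> dissociation

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if t.shape != r.shape:
            raise ValueError("times and responses must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (t[0] <= self.phase_boundary <= t[-1]):
            raise ValueError("phase boundary outside time range")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "responses", r)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Sensorgram":
        """Build from a (time_s, response, concentration_M, phase) frame."""
        df = df.sort_values("time_s")
        assoc = df[df["phase"] == "association"]
        boundary = float(assoc["time_s"].max()) if len(assoc) else \
            float(df["time_s"].iloc[0])
        return cls(float(df["concentration_M"].iloc[0]),
                   df["time_s"].to_numpy(), df["response"].to_numpy(),
                   boundary)


@dataclass(frozen=True)
class KineticFit:
    kon: float | None               # 1/(M s)
    koff: float | None              # 1/s
    kd: float | None                # M, == koff/kon when converged
    rmax: float | None              # response units
    r_squared: float | None
    converged: bool
    no_binding: bool

    def __post_init__(self):
        if self.converged and not self.no_binding:
            assert self.kd == self.koff / self.kon


def compute_kd(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon (molar)."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    return koff / kon


def _model(theta: np.ndarray, grams: list[Sensorgram]) -> np.ndarray:
    log_kon, log_koff, rmax = theta
    kon, koff = np.exp(log_kon), np.exp(log_koff)
    kd = koff / kon
    parts = []
    for g in grams:
        c = g.concentration
        kobs = kon * c + koff
        r_eq = rmax * c / (c + kd)
        assoc = g.times <= g.phase_boundary
        r = np.empty_like(g.times)
        r[assoc] = r_eq * (1.0 - np.exp(-kobs * g.times[assoc]))
        r_end = r_eq * (1.0 - np.exp(-kobs * g.phase_boundary))
        r[~assoc] = r_end * np.exp(-koff * (g.times[~assoc]
                                            - g.phase_boundary))
        parts.append(r)
    return np.concatenate(parts)


def estimate_noise(grams: list[Sensorgram]) -> float:
    """Residual noise scale from first differences of each trace
    (sd of white noise = sd(diff)/sqrt(2))."""
    diffs = np.concatenate([np.diff(g.responses) for g in grams])
    return float(diffs.std() / np.sqrt(2.0)) if diffs.size else 0.0


def fit_global(sensorgrams: list[Sensorgram],
               kon_grid: tuple[float, float] = (1e3, 1e7),
               koff_grid: tuple[float, float] = (1e-5, 1e-1),
               n_grid: int = 5,
               no_binding_snr: float = 3.0) -> KineticFit:
    """Fit shared (kon, koff, Rmax) to all sensorgrams jointly.

    Raises on fewer than two distinct concentrations or non-overlapping
    time grids. When the largest response never exceeds
    ``no_binding_snr`` times the estimated noise, the probe is reported
    as non-binding and no rates are fitted.
    """
    concs = {g.concentration for g in sensorgrams}
    if len(concs) < 2:
        raise ValueError("need >= 2 distinct analyte concentrations")
    spans = [(g.times[0], g.times[-1]) for g in sensorgrams]
    lo = max(s for s, _ in spans)
    hi = min(e for _, e in spans)
    if lo >= hi:
        raise ValueError("sensorgram time grids do not overlap")

    y = np.concatenate([g.responses for g in sensorgrams])
    noise = estimate_noise(sensorgrams)
    if np.abs(y).max() < no_binding_snr * max(noise, 1e-12):
        return KineticFit(None, None, None, None, None,
                          converged=True, no_binding=True)

    rmax0 = float(np.abs(y).max())
    best = None
    for kon0 in np.geomspace(*kon_grid, n_grid):
        for koff0 in np.geomspace(*koff_grid, n_grid):
            theta0 = np.array([np.log(kon0), np.log(koff0), rmax0])
            try:
                res = least_squares(
                    lambda th: _model(th, sensorgrams) - y, theta0,
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=2000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None or not best.success:
        return KineticFit(None, None, None, None, None,
                          converged=False, no_binding=False)
    kon = float(np.exp(best.x[0]))
    koff = float(np.exp(best.x[1]))
    rmax = float(best.x[2])
    ss_res = float((best.fun ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return KineticFit(kon, koff, compute_kd(kon, koff), rmax, r2,
                      converged=True, no_binding=False)


@dataclass(frozen=True)
class DissectionRow:
    """One probe in a mutational-dissection table."""
    name: str
    sequence: str
    fit: KineticFit
    fold_change_vs_reference: float | None


def _mutation_position(name: str) -> tuple:
    import re
    m = re.search(r"(\d+)", name)
    return (0, name) if name in ("wt", "reference") else \
        ((int(m.group(1)), name) if m else (10**6, name))


def dissection_table(fits: dict[str, KineticFit],
                     sequences: dict[str, str],
                     reference: str = "wt") -> list[DissectionRow]:
    """Fold-change table of probe KDs against a reference probe,
    sorted by mutation position (reference first)."""
    if reference not in fits:
        raise ValueError(f"reference {reference!r} not among fits")
    ref = fits[reference]
    if ref.no_binding or not ref.converged:
        raise ValueError("reference fit unusable (no binding or "
                         "not converged)")
    rows = []
    for name in sorted(fits, key=_mutation_position):
        fit = fits[name]
        fc = None
        if fit.converged and not fit.no_binding:
            fc = fit.kd / ref.kd
        rows.append(DissectionRow(name, sequences.get(name, ""), fit, fc))
    return rows


def round_sig(x: float, sig: int = 4) -> float:
    """Round to significant figures for display (table formatting)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def compare_condition(fit_a: KineticFit, fit_b: KineticFit,
                      tolerance: float = 0.10) -> str:
    """'equivalent' iff the relative KD difference is within tolerance
    (e.g. binding with and without a candidate small-molecule cofactor)."""
    if not (fit_a.converged and fit_b.converged) or \
            fit_a.no_binding or fit_b.no_binding:
        raise ValueError("both fits must be converged binding fits")
    rel = abs(fit_a.kd - fit_b.kd) / fit_a.kd
    return "equivalent" if rel <= tolerance else "different"
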