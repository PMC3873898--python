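"""Structure ↔ mean-residue ellipticity model at 222 nm.

The CD signal of an all-α protein at 222 nm is modelled from its helix
composition with four parameters: the infinite-helix signal [θ]_helix
(−39,500 for a generic helix, −36,800 optimised for myoglobin), a
per-helix truncation penalty k (residues, default 2.57) accounting for
the reduced signal of finite helices, the residue count N_r (153 for
myoglobin), and a random-coil correction [θ]_RC (+1000) that grows with
the coil fraction (1 − f_H):

    [θ]_222 = ([θ]_helix / N_r) · Σ_i max(r_i − k, 0) + [θ]_RC · (1 − f_H)

with r_i the residues of helix i, f_H = Σ r_i / N_r, and N_h the number
of helices. The key consequence is that f_H inferred from an observed
ellipticity is NOT a simple linear rescaling: states that have lost
whole helices (smaller N_h) carry a smaller total truncation penalty
k·N_h, so assuming the native helix count overestimates helicity of
intermediates. The inverse model solves the linear (unclamped) form

    [θ]_222 = ([θ]_helix / N_r)(R − k·N_h) + [θ]_RC (1 − R/N_r)

for the total helical residue count R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from unfoldscope.secondary_structure import (
    HELIX_CLASSES_DEFAULT, MIN_SEGMENT_LENGTH, assign_ss, helix_segments,
)
from unfoldscope.structure_io import Trajectory

__all__ = [
    "EllipticityParams", "EllipticityResult",
    "forward_ellipticity", "invert_ellipticity", "sensitivity_table",
    "table2_preset", "trajectory_ellipticity",
    "THETA_HELIX_GENERIC", "THETA_HELIX_MB", "TABLE2_STATES",
    "round_half_away",
]

THETA_HELIX_GENERIC = -39500.0   # infinite helix, generic
THETA_HELIX_MB = -36800.0        # infinite helix, myoglobin-optimised
THETA_TRUNCATION = 500.0         # positive-side cap for trajectory reporting

#: The five myoglobin states: (label, observed [θ]_222, number of helices N_h)
TABLE2_STATES = (
    ("Holo, pH 7", -24000.0, 8),
    ("Apo, pH 7", -19000.0, 6),
    ("Apo, pH 6", -17500.0, 5),
    ("ApoI, pH 4", -12000.0, 4),
    ("I/U", -5000.0, 2),
)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (matches the printed tables, unlike banker's)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1.0 if x >= 0 else -1.0)


@dataclass(frozen=True)
class EllipticityParams:
    """Parameter set of the ellipticity model (units: deg·cm²·dmol⁻¹ for θ)."""

    n_r: int = 153
    n_h: int = 8
    k: float = 2.57
    theta_helix: float = THETA_HELIX_MB
    theta_rc: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_r < 1:
            raise ValueError("N_r must be ≥ 1")
        if self.n_h < 0:
            raise ValueError("N_h must be ≥ 0")
        if self.k < 0:
            raise ValueError("k must be ≥ 0")
        if self.theta_helix >= 0:
            raise ValueError("theta_helix must be negative")


@dataclass(frozen=True)
class EllipticityResult:
    """An ellipticity/helicity state: θ222, helix fraction, residue count."""

    theta222: float
    f_h: float
    helix_residues: float   # R = Σ r_i (real; may be fractional from inversion)
    n_h_used: int

    @property
    def f_h_2dp(self) -> float:
        return round_half_away(self.f_h, 2)

    @property
    def helix_residues_rounded(self) -> int:
        return int(round_half_away(self.helix_residues, 0))


def forward_ellipticity(segment_lengths: Sequence[float],
                        params: EllipticityParams = EllipticityParams()) -> EllipticityResult:
    """Predict [θ]_222 from helix segment lengths.

    Each segment contributes max(r_i − k, 0): segments no longer than the
    truncation penalty are clamped to zero signal. N_h is taken from the
    number of segments supplied (the ``n_h`` field of *params* is ignored
    here).
    """
    r = np.asarray(segment_lengths, dtype=float)
    if np.any(r < 1):
        raise ValueError("segment lengths must be ≥ 1")
    total = float(r.sum())
    if total > params.n_r:
        raise ValueError(f"Σ r_i = {total} exceeds N_r = {params.n_r}")
    f_h = total / params.n_r
    helix_term = (params.theta_helix / params.n_r) * float(
        np.maximum(r - params.k, 0.0).sum())
    theta = helix_term + params.theta_rc * (1.0 - f_h)
    return EllipticityResult(theta, f_h, total, n_h_used=len(r))


def invert_ellipticity(theta222: float,
                       params: EllipticityParams = EllipticityParams()) -> EllipticityResult:
    """Infer helix content from an observed [θ]_222.

    Solves the unclamped linear form for the total helical residue count
    R (all segments are assumed longer than k), using the ``n_h`` of
    *params* as the assumed number of helices. θ must lie between
    θ_helix and θ_RC.
    """
    if params.n_h < 1:
        raise ValueError("inversion requires N_h ≥ 1")
    if not (params.theta_helix <= theta222 <= params.theta_rc):
        raise ValueError(
            f"θ = {theta222} outside the admissible range "
            f"[{params.theta_helix}, {params.theta_rc}]")
    num = params.n_r * (theta222 - params.theta_rc) \
        + params.theta_helix * params.k * params.n_h
    den = params.theta_helix - params.theta_rc
    r_total = num / den
    return EllipticityResult(theta222, r_total / params.n_r, r_total, params.n_h)


def sensitivity_table(thetas: Iterable[float],
                      n_h_values: Iterable[int],
                      k_values: Iterable[float] = (2.57,),
                      theta_helix_values: Iterable[float] = (THETA_HELIX_MB,),
                      n_r: int = 153,
                      theta_rc: float = 1000.0) -> pd.DataFrame:
    """Inverted f_H over the full parameter cross-product.

    Columns: theta222, n_h, k, theta_helix, f_h (unrounded), f_h_2dp,
    helix_residues (unrounded), helix_residues_rounded.
    """
    thetas = list(thetas)
    n_h_values = list(n_h_values)
    k_values = list(k_values)
    theta_helix_values = list(theta_helix_values)
    if not (thetas and n_h_values and k_values and theta_helix_values):
        raise ValueError("all parameter grids must be non-empty")
    rows = []
    for th in theta_helix_values:
        for k in k_values:
            for nh in n_h_values:
                for theta in thetas:
                    res = invert_ellipticity(theta, EllipticityParams(
                        n_r=n_r, n_h=nh, k=k, theta_helix=th, theta_rc=theta_rc))
                    rows.append({
                        "theta222": theta, "n_h": nh, "k": k, "theta_helix": th,
                        "f_h": res.f_h, "f_h_2dp": res.f_h_2dp,
                        "helix_residues": res.helix_residues,
                        "helix_residues_rounded": res.helix_residues_rounded,
                    })
    return pd.DataFrame(rows)


def table2_preset(k: float = 2.57, n_r: int = 153,
                  theta_rc: float = 1000.0) -> pd.DataFrame:
    """The five-state helix-fraction table for both infinite-helix signals.

    Columns are the five myoglobin states; rows are f_H at
    θ_helix = −39,500 and −36,800 (2 dp) plus the implied helical residue
    count (nearest integer, computed at the myoglobin-optimised signal).
    """
    labels = [s[0] for s in TABLE2_STATES]
    data: dict[str, list[float]] = {lab: [] for lab in labels}
    for theta_helix in (THETA_HELIX_GENERIC, THETA_HELIX_MB):
        for lab, theta, nh in TABLE2_STATES:
            res = invert_ellipticity(theta, EllipticityParams(
                n_r=n_r, n_h=nh, k=k, theta_helix=theta_helix, theta_rc=theta_rc))
            data[lab].append(res.f_h_2dp)
    for lab, theta, nh in TABLE2_STATES:
        res = invert_ellipticity(theta, EllipticityParams(
            n_r=n_r, n_h=nh, k=k, theta_helix=THETA_HELIX_MB, theta_rc=theta_rc))
        data[lab].append(res.helix_residues_rounded)
    index = ["f_H (theta_helix = -39500)", "f_H (theta_helix = -36800)",
             "helix residues"]
    return pd.DataFrame(data, index=index)


def trajectory_ellipticity(traj: Trajectory,
                           k: float = 2.57,
                           theta_helix: float = THETA_HELIX_MB,
                           theta_rc: float = 1000.0,
                           helix_classes=HELIX_CLASSES_DEFAULT,
                           min_segment_length: int = MIN_SEGMENT_LENGTH,
                           truncate_at: float = THETA_TRUNCATION) -> pd.DataFrame:
    """Per-frame predicted [θ]_222 along a trajectory.

    Helix segments come from the per-frame secondary-structure
    assignment; N_h is the per-frame segment count. Reported values are
    capped on the positive side at +500 (the model loses meaning as N_h
    → 0), matching how unfolding time series are conventionally plotted;
    scalar calls to :func:`forward_ellipticity` are never truncated.

    Returns a DataFrame with columns time_ps, theta222, theta222_raw,
    f_h, helix_residues, n_h.
    """
    n_r = len(traj.frames[0].residues) if traj.frames else 153
    rows = []
    for frame in traj.frames:
        segs = helix_segments(assign_ss(frame), classes=helix_classes,
                              min_length=min_segment_length)
        res = forward_ellipticity(
            [s.length for s in segs],
            EllipticityParams(n_r=n_r, n_h=max(len(segs), 0), k=k,
                              theta_helix=theta_helix, theta_rc=theta_rc))
        rows.append({
            "time_ps": frame.time,
            "theta222": min(res.theta222, truncate_at),
            "theta222_raw": res.theta222,
            "f_h": res.f_h,
            "helix_residues": res.helix_residues,
            "n_h": res.n_h_used,
        })
    return pd.DataFrame(rows)
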