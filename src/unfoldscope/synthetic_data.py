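"""Seeded synthetic globin structures and unfolding trajectories.

Everything the analysis pipeline consumes can be generated here with
full ground truth: idealized backbones built from internal coordinates
(NeRF chain extension), a compact 153-residue, eight-helix globin
mimic with a heme pseudo-group 0.64 nm from residue 93, unfolding
trajectories with programmable exponential helix decay and a heme
departure schedule, and labelled 2-D Gaussian blob fixtures for the
clustering stage.

The fixtures target the observables of the real system — residue count,
helix count and content, heme geometry, decay phenomenology — not the
myoglobin sequence: residues are poly-alanine backbones with a histidine
label at position 93, since no implemented computation reads side chains.
All randomness flows from explicit seeds; identical seeds give
byte-identical PDB output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from unfoldscope.structure_io import (
    Atom, Frame, Residue, Trajectory, add_amide_hydrogens,
)

__all__ = [
    "UnfoldingConfig", "GroundTruth", "build_backbone", "make_native_globin",
    "make_unfolding_trajectory", "make_phase_trajectory", "make_cluster_blobs",
    "make_antiparallel_hairpin", "make_extended_strand", "GLOBIN_HELICES",
    "measure_dihedral",
]

# Trans-peptide internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_PSI = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}
COIL_PHI_RANGE = (-160.0, -60.0)
COIL_PSI_RANGE = (60.0, 180.0)

#: Default eight helix segments (1-based, inclusive) totalling 122 residues.
#: Segment boundaries echo the globin A–H architecture but keep ≥3 coil
#: residues between nominal segments so assignments never merge them.
GLOBIN_HELICES = ((4, 19), (23, 38), (42, 48), (52, 58),
                  (62, 81), (85, 93), (97, 115), (119, 146))
#: Indices (into GLOBIN_HELICES) of the fast-unfolding C and F segments.
FAST_SEGMENTS = (2, 5)
N_RESIDUES_DEFAULT = 153
HIS_POSITION = 93
HEME_NATIVE_A = 6.4       # Fe to His93 COM, Å
HEME_FAR_A = 25.0         # post-departure Fe distance, Å
HEME_LOSS_A = 12.8        # threshold the schedule crosses exactly at t_loss
HEME_RAMP_NS = 0.5


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of atom D from A–B–C with given internal coordinates."""
    theta = math.radians(angle_deg)
    tau = math.radians(dihedral_deg)
    u2 = _unit(c - b)
    n = _unit(np.cross(b - a, u2))
    m = np.cross(n, u2)
    d = bond * (-math.cos(theta) * u2
                + math.sin(theta) * (math.cos(tau) * m + math.sin(tau) * n))
    return c + d


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0–p1–p2–p3 in degrees (IUPAC convention)."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return math.degrees(math.atan2(y, x))


def _backbone_from_dihedrals(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """(n, 3, 3) array of N/CA/C positions for the given per-residue (φ, ψ)."""
    n_res = len(phi)
    atoms = np.zeros((n_res, 3, 3))
    atoms[0, 0] = (0.0, 0.0, 0.0)
    atoms[0, 1] = (BOND_N_CA, 0.0, 0.0)
    th = math.radians(ANGLE_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + BOND_CA_C * np.array(
        [-math.cos(th), math.sin(th), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = atoms[i - 1]
        n_i = _place(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        atoms[i] = (n_i, ca_i, c_i)
    return atoms


def _carbonyl_oxygens(atoms: np.ndarray, psi_last: float) -> np.ndarray:
    """O position per residue: in-plane anti to the next amide nitrogen."""
    n_res = len(atoms)
    oxy = np.zeros((n_res, 3))
    for i in range(n_res - 1):
        c = atoms[i, 2]
        u1 = _unit(atoms[i, 1] - c)
        u2 = _unit(atoms[i + 1, 0] - c)
        oxy[i] = c + BOND_C_O * _unit(-(u1 + u2))
    oxy[-1] = _place(atoms[-1, 0], atoms[-1, 1], atoms[-1, 2],
                     BOND_C_O, ANGLE_CA_C_O, psi_last + 180.0)
    return oxy


def _frame_from_dihedrals(phi: np.ndarray, psi: np.ndarray,
                          names: list[str] | None = None,
                          time: float = 0.0) -> Frame:
    n_res = len(phi)
    atoms = _backbone_from_dihedrals(phi, psi)
    oxy = _carbonyl_oxygens(atoms, psi[-1])
    if names is None:
        names = ["ALA"] * n_res
    residues = []
    for i in range(n_res):
        residues.append(Residue(i + 1, names[i], "A", [
            Atom("N", "N", atoms[i, 0]),
            Atom("CA", "C", atoms[i, 1]),
            Atom("C", "C", atoms[i, 2]),
            Atom("O", "O", oxy[i]),
        ]))
    return add_amide_hydrogens(Frame(time, residues))


def _coil_draw(rng: np.random.Generator, n: int) -> np.ndarray:
    phi = rng.uniform(*COIL_PHI_RANGE, size=n)
    psi = rng.uniform(*COIL_PSI_RANGE, size=n)
    return np.column_stack([phi, psi])


def build_backbone(n_residues: int, ss_string: str,
                   seed: int = 0) -> Frame:
    """Build an idealized single-chain backbone from a per-residue {H,E,C} string.

    Helical residues get (φ, ψ) = (−57°, −47°), strand residues
    (−119°, 113°), coil residues a seeded uniform draw from the extended
    coil region; ω is always 180°. Carbonyl oxygens and amide hydrogens
    are placed geometrically. Poly-alanine naming with HIS at position 93
    when the chain is long enough.
    """
    if len(ss_string) != n_residues:
        raise ValueError("ss_string length must equal n_residues")
    bad = set(ss_string) - set("HEC")
    if bad:
        raise ValueError(f"invalid symbols in ss_string: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    coil = _coil_draw(rng, n_residues)
    phi = np.empty(n_residues)
    psi = np.empty(n_residues)
    for i, s in enumerate(ss_string):
        phi[i], psi[i] = PHI_PSI.get(s, coil[i])
    names = ["ALA"] * n_residues
    if n_residues >= HIS_POSITION:
        names[HIS_POSITION - 1] = "HIS"
    return _frame_from_dihedrals(phi, psi, names)


def make_extended_strand(n_residues: int = 12) -> Frame:
    """A fully extended chain (φ = −180°, ψ = 180°): no backbone H-bonds.

    Note this is flatter than the ideal β-strand built by
    :func:`build_backbone` with 'E', whose pleat brings carbonyls and
    amides of i, i+2 into weak (≈ −0.6 kcal/mol) contact.
    """
    return _frame_from_dihedrals(np.full(n_residues, -180.0),
                                 np.full(n_residues, 180.0))


# ---------------------------------------------------------------------------
# Native globin mimic
# ---------------------------------------------------------------------------

# Helices at least this long have their C-terminal residue rendered as coil
# in the native build: solution structures lose helix ends dynamically, so
# the assigned helical count sits slightly below the nominal 122.
FRAY_MIN_LENGTH = 16


def _geometric_segments(helix_spec) -> list[tuple[int, int]]:
    """Residue ranges actually built with helical dihedrals.

    A coil-flanked geometric helix is assigned exactly its own range, so
    the nominal segments are used directly, minus one frayed C-terminal
    residue on long helices.
    """
    return [(a, b - 1 if b - a + 1 >= FRAY_MIN_LENGTH else b)
            for a, b in helix_spec]


def _ca_rg(atoms: np.ndarray) -> float:
    ca = atoms[:, 1, :]
    return float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))


def _ca_clash(atoms: np.ndarray, min_dist: float = 3.2) -> bool:
    ca = atoms[:, 1, :]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    n = len(ca)
    idx = np.arange(n)
    mask = np.abs(idx[:, None] - idx[None, :]) >= 3
    return bool(np.any(d[mask] < min_dist))


def _frame_basis(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal basis (rows) anchored at c from three points."""
    x = _unit(c - b)
    v = a - b
    v = v - np.dot(v, x) * x
    y = _unit(v)
    return np.vstack([x, y, np.cross(x, y)])


def _pivot_move(atoms: np.ndarray, p: int, phi_p: float, psi_p: float) -> np.ndarray:
    """Rebuild after changing residue p's (φ, ψ): three atoms are re-placed
    and the chain tail moves as a rigid body (O(n) with a tiny constant)."""
    trial = atoms.copy()
    n_res = len(atoms)
    if p == 0:
        trial[0, 2] = atoms[0, 2]   # first residue has no φ: C_1 is anchored
    else:
        trial[p, 2] = _place(atoms[p - 1, 2], atoms[p, 0], atoms[p, 1],
                             BOND_CA_C, ANGLE_N_CA_C, phi_p)
    if p + 1 < n_res:
        new_n = _place(atoms[p, 0], atoms[p, 1], trial[p, 2],
                       BOND_C_N, ANGLE_CA_C_N, psi_p)
        new_ca = _place(atoms[p, 1], trial[p, 2], new_n,
                        BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        trial[p + 1, 0] = new_n
        trial[p + 1, 1] = new_ca
        # everything from C_{p+1} onward rides rigidly on the (C_p, N, CA) frame
        old_basis = _frame_basis(atoms[p, 2], atoms[p + 1, 0], atoms[p + 1, 1])
        new_basis = _frame_basis(trial[p, 2], new_n, new_ca)
        tail = atoms.reshape(-1, 3)[3 * (p + 1) + 2:]
        local = (tail - atoms[p + 1, 1]) @ old_basis.T
        trial.reshape(-1, 3)[3 * (p + 1) + 2:] = new_ca + local @ new_basis
    return trial


def _compact_dihedrals(phi: np.ndarray, psi: np.ndarray, pivots: np.ndarray,
                       rng: np.random.Generator, target_rg: float = 17.0,
                       max_iter: int = 20000) -> tuple[np.ndarray, np.ndarray, float]:
    """Seeded collapse: random pivot-residue (φ, ψ) moves accepted when they
    shrink the CA radius of gyration without introducing CA clashes."""
    phi, psi = phi.copy(), psi.copy()
    atoms = _backbone_from_dihedrals(phi, psi)
    rg = _ca_rg(atoms)
    for _ in range(max_iter):
        if rg <= target_rg:
            break
        p = int(rng.choice(pivots))
        new_phi = rng.uniform(-180.0, 180.0)
        new_psi = rng.uniform(-180.0, 180.0)
        trial = _pivot_move(atoms, p, new_phi, new_psi)
        trial_rg = _ca_rg(trial)
        if trial_rg < rg and not _ca_clash(trial):
            atoms, rg = trial, trial_rg
            phi[p], psi[p] = new_phi, new_psi
    return phi, psi, rg


def _heme_group(fe_pos: np.ndarray) -> list[Atom]:
    """Five-atom heme pseudo-group: the Fe plus four porphyrin-N placeholders."""
    offsets = np.array([[0, 0, 0], [1.7, 0, 0], [-1.7, 0, 0],
                        [0, 1.7, 0], [0, -1.7, 0]], dtype=float)
    names = ["FE", "NA", "NB", "NC", "ND"]
    elements = ["FE", "N", "N", "N", "N"]
    return [Atom(nm, el, fe_pos + off, is_hetero=True)
            for nm, el, off in zip(names, elements, offsets)]


def _residue_com(res: Residue) -> np.ndarray:
    coords = np.array([a.coords for a in res.atoms])
    masses = np.array([a.mass for a in res.atoms])
    return np.average(coords, axis=0, weights=masses)


def _attach_heme(frame: Frame, dist_a: float = HEME_NATIVE_A) -> Frame:
    """Place the heme pseudo-group *dist_a* Å from the His93 centre of mass,
    pointing away from the protein centre."""
    res = frame.residue_by_index(HIS_POSITION)
    com93 = _residue_com(res)
    all_ca = frame.coords("CA")
    direction = com93 - np.nanmean(all_ca, axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    frame.heme = _heme_group(com93 + dist_a * direction)
    return frame


@dataclass
class _NativeBuild:
    frame: Frame
    phi: np.ndarray
    psi: np.ndarray
    helix_spec: tuple
    rg_a: float


def _build_native(seed: int, n_residues: int = N_RESIDUES_DEFAULT,
                  helix_spec=GLOBIN_HELICES, target_rg: float = 17.0,
                  max_retries: int = 12) -> _NativeBuild:
    from unfoldscope.secondary_structure import assign_ss, helix_segments

    geo = _geometric_segments(helix_spec)
    helical = np.zeros(n_residues, dtype=bool)
    for a, b in geo:
        helical[a - 1:b] = True
    pivots = np.where(~helical)[0]
    n_geo = int(helical.sum())
    check_band = (helix_spec == GLOBIN_HELICES and n_residues == N_RESIDUES_DEFAULT)

    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        coil = _coil_draw(rng, n_residues)
        phi = np.where(helical, PHI_PSI["H"][0], coil[:, 0])
        psi = np.where(helical, PHI_PSI["H"][1], coil[:, 1])
        phi, psi, rg = _compact_dihedrals(phi, psi, pivots, rng,
                                          target_rg=target_rg)
        if rg > target_rg + 1.0:
            continue
        names = ["ALA"] * n_residues
        if n_residues >= HIS_POSITION:
            names[HIS_POSITION - 1] = "HIS"
        frame = _frame_from_dihedrals(phi, psi, names)
        if check_band:
            # enforce the build contract: eight assigned segments and an
            # assigned helical count between the frayed minimum and the
            # nominal maximum (capping bonds can add a residue per end)
            assign = assign_ss(frame)
            count = assign.count()
            if len(helix_segments(assign)) != len(helix_spec) \
                    or not n_geo <= count <= n_geo + 4:
                continue
        frame = _attach_heme(frame)
        return _NativeBuild(frame, phi, psi, tuple(helix_spec), rg)
    raise RuntimeError(f"compaction failed to produce a valid native build "
                       f"after {max_retries} retries (seed {seed})")


def make_native_globin(seed: int = 0, n_residues: int = N_RESIDUES_DEFAULT,
                       helix_spec=GLOBIN_HELICES) -> Frame:
    """A compact native-like globin frame: eight helices (122 helical
    residues), R_g ≲ 1.8 nm, heme Fe 0.64 nm from His93."""
    return _build_native(seed, n_residues, helix_spec).frame


# ---------------------------------------------------------------------------
# Unfolding trajectories
# ---------------------------------------------------------------------------

@dataclass
class UnfoldingConfig:
    """Conditions for a synthetic thermal-unfolding trajectory.

    Defaults emulate the 500 K unfolding phenomenology of a hologlobin:
    exponential decay of the 122 native helical residues over ~20 ns with
    fast loss of the C/F segments, a residual helical core, heme
    departure crossing the 1.28 nm criterion at *t_loss_ns*, and small
    coordinate jitter standing in for thermal noise.
    """

    n_residues: int = N_RESIDUES_DEFAULT
    helix_spec: tuple = GLOBIN_HELICES
    decay_rate_per_ns: float = 0.2
    residual_helix: int = 20
    t_loss_ns: float | None = 3.7
    n_frames: int = 200
    dt_ps: float = 100.0
    seed: int = 0
    noise_sigma_a: float = 0.25
    temperature: float = 500.0

    def __post_init__(self) -> None:
        spans = sorted(self.helix_spec)
        if any(b2 <= a1 for (_, a1), (b2, _) in zip(spans, spans[1:])):
            raise ValueError("helix segments must be disjoint")
        if not all(1 <= a <= b <= self.n_residues for a, b in spans):
            raise ValueError("helix segments must lie within the chain")
        if self.decay_rate_per_ns < 0:
            raise ValueError("decay rate must be ≥ 0")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.noise_sigma_a < 0:
            raise ValueError("noise sigma must be ≥ 0")


@dataclass
class GroundTruth:
    """Construction intents of a synthetic trajectory, for recovery tests."""

    helical_sets: list[frozenset]       # per frame: intended helical residues
    fe_dist_nm: np.ndarray              # per frame: intended Fe–His93 distance
    phases: list[str]                   # native / intermediate / unfolded
    times_ps: np.ndarray
    config: UnfoldingConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.times_ps)),
            "time_ps": self.times_ps,
            "true_helix_count": [len(s) for s in self.helical_sets],
            "true_fe_dist_nm": self.fe_dist_nm,
            "phase": self.phases,
        })


def _removal_order(helix_spec, residual: int) -> list[tuple[int, int]]:
    """Deterministic residue-removal order (segment index, residue index).

    Residues unwind from segment ends, alternating ends, with the C and F
    segments depleted at twice the weight of the others; the last
    *residual* residues are never scheduled.
    """
    segs = [list(range(a, b + 1)) for a, b in helix_spec]
    weights = [2.0 if i in FAST_SEGMENTS else 1.0 for i in range(len(segs))]
    sizes = [len(s) for s in segs]
    total = sum(sizes)
    removed = [0] * len(segs)
    take_tail = [True] * len(segs)
    order: list[tuple[int, int]] = []
    for _ in range(total - residual):
        # next removal: segment with the largest weighted deficit
        best, best_deficit = None, -np.inf
        m = len(order) + 1
        wsum = sum(w * n for w, n in zip(weights, sizes))
        for i, seg in enumerate(segs):
            if removed[i] >= sizes[i]:
                continue
            deficit = m * weights[i] * sizes[i] / wsum - removed[i]
            if deficit > best_deficit:
                best, best_deficit = i, deficit
        seg = segs[best]
        res = seg.pop() if take_tail[best] else seg.pop(0)
        take_tail[best] = not take_tail[best]
        removed[best] += 1
        order.append((best, res))
    return order


def make_unfolding_trajectory(cfg: UnfoldingConfig = UnfoldingConfig()
                              ) -> tuple[Trajectory, GroundTruth]:
    """Generate an unfolding trajectory plus its construction ground truth.

    The native compacted conformation is unwound frame by frame: the
    intended helical count follows
    ``N(t) = residual + (N_helical − residual)·exp(−λ t)`` (rounded),
    residues leave from segment ends with the C/F segments depleted at
    twice the rate of the rest, unwound residues adopt fixed seeded coil
    dihedrals, and every backbone atom receives Gaussian jitter of
    *noise_sigma_a*. The heme Fe follows a distance schedule that sits at
    0.64 nm natively and crosses the 1.28 nm loss criterion exactly at
    *t_loss_ns*, ramping on toward 2.5 nm.
    """
    native = _build_native(cfg.seed, cfg.n_residues, cfg.helix_spec)
    rng = np.random.default_rng([cfg.seed, 7_777])
    n_res = cfg.n_residues
    names = ["ALA"] * n_res
    if n_res >= HIS_POSITION:
        names[HIS_POSITION - 1] = "HIS"

    helix_residues = [set(range(a, b + 1)) for a, b in cfg.helix_spec]
    n_helical = sum(len(s) for s in helix_residues)
    residual = min(cfg.residual_helix, n_helical)
    order = _removal_order(cfg.helix_spec, residual)
    coil_pool = _coil_draw(rng, n_res)   # per-residue coil dihedrals, fixed once

    times = np.arange(cfg.n_frames) * cfg.dt_ps
    lam = cfg.decay_rate_per_ns
    ramp_a_per_ns = (HEME_FAR_A - HEME_NATIVE_A) / HEME_RAMP_NS
    ramp_start_ns = None
    if cfg.t_loss_ns is not None:
        ramp_start_ns = cfg.t_loss_ns - (HEME_LOSS_A - HEME_NATIVE_A) / ramp_a_per_ns

    frames: list[Frame] = []
    truth_sets: list[frozenset] = []
    fe_dists = np.zeros(cfg.n_frames)
    phases: list[str] = []
    for fi, t_ps in enumerate(times):
        t_ns = t_ps / 1000.0
        n_target = residual + (n_helical - residual) * math.exp(-lam * t_ns)
        n_target = int(round(n_target))
        m = n_helical - n_target
        removed = {res for _, res in order[:m]}
        remaining = [sorted(s - removed) for s in helix_residues]

        phi = native.phi.copy()
        psi = native.psi.copy()
        for res in removed:
            phi[res - 1], psi[res - 1] = coil_pool[res - 1]
        for seg, (a0, b0) in zip(remaining, cfg.helix_spec):
            if not seg:
                continue
            lo = seg[0]
            hi = seg[-1]
            if hi == b0 and b0 - a0 + 1 >= FRAY_MIN_LENGTH:
                hi -= 1    # native fraying persists while the tail is intact
            phi[lo - 1:hi] = PHI_PSI["H"][0]
            psi[lo - 1:hi] = PHI_PSI["H"][1]

        frame = _frame_from_dihedrals(phi, psi, names, time=float(t_ps))
        if cfg.noise_sigma_a > 0:
            for res in frame.residues:
                for atom in res.atoms:
                    if atom.name != "H":
                        atom.coords = atom.coords + rng.normal(
                            0.0, cfg.noise_sigma_a, size=3)
            frame = add_amide_hydrogens(frame)

        if ramp_start_ns is None or t_ns < ramp_start_ns:
            d_a = HEME_NATIVE_A
        else:
            d_a = min(HEME_FAR_A, HEME_NATIVE_A + (t_ns - ramp_start_ns) * ramp_a_per_ns)
        _attach_heme(frame, dist_a=d_a)

        frames.append(frame)
        truth_sets.append(frozenset().union(*[frozenset(s) for s in remaining])
                          if remaining else frozenset())
        fe_dists[fi] = d_a / 10.0
        frac = (n_target - residual) / max(n_helical - residual, 1)
        phases.append("native" if frac >= 0.8
                      else "unfolded" if frac <= 0.15 else "intermediate")

    traj = Trajectory(frames, temperature=cfg.temperature,
                      source=f"synthetic(seed={cfg.seed})")
    truth = GroundTruth(truth_sets, fe_dists, phases, times, cfg)
    return traj, truth


def make_phase_trajectory(helix_targets=(117, 60, 20),
                          frames_per_phase: int = 40,
                          dt_ps: float = 100.0,
                          seed: int = 0,
                          noise_sigma_a: float = 0.25,
                          helix_spec=GLOBIN_HELICES,
                          n_residues: int = N_RESIDUES_DEFAULT
                          ) -> tuple[Trajectory, GroundTruth]:
    """A piecewise-stationary trajectory: one plateau per target helix count.

    Each phase holds the intended helical count constant (plus coordinate
    jitter), emulating the kinetically robust intermediates that show up
    as plateaus and as well-separated clusters in the (RMSD, H-bond)
    plane. Phases are labelled native / intermediate / unfolded in order;
    with two targets the middle label is skipped. The heme stays at its
    native distance.
    """
    if len(helix_targets) < 2:
        raise ValueError("need at least two phase targets")
    native = _build_native(seed, n_residues, helix_spec)
    rng = np.random.default_rng([seed, 31_337])
    names = ["ALA"] * n_residues
    if n_residues >= HIS_POSITION:
        names[HIS_POSITION - 1] = "HIS"
    helix_residues = [set(range(a, b + 1)) for a, b in helix_spec]
    n_helical = sum(len(s) for s in helix_residues)
    order = _removal_order(helix_spec, min(helix_targets))
    coil_pool = _coil_draw(rng, n_residues)

    if len(helix_targets) == 2:
        labels = ["native", "unfolded"]
    else:
        labels = (["native"] + ["intermediate"] * (len(helix_targets) - 2)
                  + ["unfolded"])

    frames: list[Frame] = []
    truth_sets: list[frozenset] = []
    phases: list[str] = []
    t_ps = 0.0
    for target, label in zip(helix_targets, labels):
        m = max(0, n_helical - int(target))
        removed = {res for _, res in order[:m]}
        remaining = [sorted(s - removed) for s in helix_residues]
        phi = native.phi.copy()
        psi = native.psi.copy()
        for res in removed:
            phi[res - 1], psi[res - 1] = coil_pool[res - 1]
        for seg, (a0, b0) in zip(remaining, helix_spec):
            if not seg:
                continue
            lo, hi = seg[0], seg[-1]
            if hi == b0 and b0 - a0 + 1 >= FRAY_MIN_LENGTH:
                hi -= 1
            phi[lo - 1:hi] = PHI_PSI["H"][0]
            psi[lo - 1:hi] = PHI_PSI["H"][1]
        for _ in range(frames_per_phase):
            frame = _frame_from_dihedrals(phi, psi, names, time=t_ps)
            if noise_sigma_a > 0:
                for res in frame.residues:
                    for atom in res.atoms:
                        if atom.name != "H":
                            atom.coords = atom.coords + rng.normal(
                                0.0, noise_sigma_a, size=3)
                frame = add_amide_hydrogens(frame)
            _attach_heme(frame)
            frames.append(frame)
            truth_sets.append(frozenset().union(
                *[frozenset(s) for s in remaining]) if remaining else frozenset())
            phases.append(label)
            t_ps += dt_ps

    times = np.array([f.time for f in frames])
    cfg = UnfoldingConfig(n_residues=n_residues, helix_spec=helix_spec,
                          decay_rate_per_ns=0.0, residual_helix=min(helix_targets),
                          t_loss_ns=None, n_frames=len(frames), dt_ps=dt_ps,
                          seed=seed, noise_sigma_a=noise_sigma_a)
    truth = GroundTruth(truth_sets, np.full(len(frames), HEME_NATIVE_A / 10.0),
                        phases, times, cfg)
    return Trajectory(frames, temperature=500.0,
                      source=f"synthetic-phases(seed={seed})"), truth


# ---------------------------------------------------------------------------
# Clustering fixtures
# ---------------------------------------------------------------------------

def make_cluster_blobs(centers: np.ndarray, spreads, n_per: int,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded isotropic Gaussian blobs: returns (points, integer labels)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    spreads = np.broadcast_to(np.asarray(spreads, dtype=float), (len(centers),))
    if np.any(spreads < 0):
        raise ValueError("spreads must be non-negative")
    rng = np.random.default_rng(seed)
    points, labels = [], []
    for i, (c, s) in enumerate(zip(centers, spreads)):
        points.append(c + rng.normal(0.0, s, size=(n_per, centers.shape[1]))
                      if s > 0 else np.tile(c, (n_per, 1)))
        labels.append(np.full(n_per, i))
    return np.vstack(points), np.concatenate(labels)


# ---------------------------------------------------------------------------
# Sheet fixture
# ---------------------------------------------------------------------------

def make_antiparallel_hairpin(n_per_strand: int = 8) -> Frame:
    """Two idealized antiparallel β-strands placed in H-bond register.

    The second strand is the first rotated by 180° and translated; the
    relative placement is picked deterministically from a small grid as
    the one maximising the backbone H-bond count. Residues 1..n are the
    first strand, n+1..2n the second (indices run antiparallel in space).
    """
    from unfoldscope.secondary_structure import detect_hbonds

    n = n_per_strand
    phi = np.full(n, PHI_PSI["E"][0])
    psi = np.full(n, PHI_PSI["E"][1])
    atoms = _backbone_from_dihedrals(phi, psi)
    flat = atoms.reshape(-1, 3)
    centroid = atoms[:, 1, :].mean(axis=0)
    flat = flat - centroid
    # align the strand axis with x
    u, _, vt = np.linalg.svd(atoms[:, 1, :] - centroid, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    y_axis = np.cross(z, axis)
    if np.linalg.norm(y_axis) < 1e-6:
        y_axis = np.array([0.0, 1.0, 0.0])
    y_axis = _unit(y_axis)
    z_axis = np.cross(axis, y_axis)
    rot = np.vstack([axis, y_axis, z_axis])
    strand_a = flat @ rot.T

    rot_z = np.diag([-1.0, -1.0, 1.0])       # 180° about z → antiparallel
    rot_x = np.diag([1.0, -1.0, -1.0])       # optional flip about x

    def build(b_coords):
        residues = []
        for i in range(n):
            residues.append(Residue(i + 1, "ALA", "A", [
                Atom("N", "N", strand_a[3 * i]),
                Atom("CA", "C", strand_a[3 * i + 1]),
                Atom("C", "C", strand_a[3 * i + 2]),
            ]))
        for i in range(n):
            residues.append(Residue(n + i + 1, "ALA", "A", [
                Atom("N", "N", b_coords[3 * i]),
                Atom("CA", "C", b_coords[3 * i + 1]),
                Atom("C", "C", b_coords[3 * i + 2]),
            ]))
        # carbonyl oxygens from local geometry (next N within each strand)
        for block in (residues[:n], residues[n:]):
            for r, r_next in zip(block, block[1:]):
                c = r.atom("C").coords
                u1 = _unit(r.atom("CA").coords - c)
                u2 = _unit(r_next.atom("N").coords - c)
                r.atoms.append(Atom("O", "O", c + BOND_C_O * _unit(-(u1 + u2))))
            last = block[-1]
            prev = block[-2]
            c = last.atom("C").coords
            oxy = _place(prev.atom("C").coords, last.atom("N").coords,
                         last.atom("CA").coords, 2.4, 120.0, 180.0)
            last.atoms.append(Atom("O", "O", _unit(oxy - c) * BOND_C_O + c))
        frame = Frame(0.0, residues)
        # amide hydrogens strictly within each strand
        out = add_amide_hydrogens(frame)
        bridge = out.residues[n]          # first residue of strand 2: drop the
        bridge.atoms = [a for a in bridge.atoms if a.name != "H"]  # cross-break H
        return out

    best_frame, best_bonds = None, -1
    for pre in (np.eye(3), rot_x):
        for dy in np.arange(4.0, 6.01, 0.25):
            for dx in np.arange(-3.0, 3.01, 0.5):
                b = strand_a @ pre.T @ rot_z.T + np.array([dx, dy, 0.0])
                frame = build(b)
                nb = len(detect_hbonds(frame))
                if nb > best_bonds:
                    best_bonds, best_frame = nb, frame
    return best_frame
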