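"""Ground-truth synthetic inputs for every stage of the pipeline.

Three generator families, all deterministic given a seed:

* random protein sequences with exact composition control and optional
  charge-patterning (kappa) targets reached by swap-only Monte Carlo
  annealing — composition is preserved exactly by construction;
* coarse-grained conformer ensembles: freely jointed (Gaussian) chains,
  excluded-volume chains sampled with the pivot algorithm, and ideal
  secondary-structure fixtures (alpha-helix, antiparallel strand pair)
  with full backbone atoms for hydrogen-bond tests;
* stochastic two/three-state FRET traces at 10 frames/s with Gaussian
  (camera-like) shot noise, single-step photobleaching of each dye, and a
  direct-excitation channel reflecting acceptor aliveness.

These emulate the *statistical* structure of the real inputs (state
mixing, bleaching, chain scaling), not their physics: there is no force
field and no photophysics beyond single-step bleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .ensemble import Trajectory
from .sequence import AMINO_ACIDS, ProteinRegion, charge_delta, kappa, _charge_array, _delta_max, KAPPA_WINDOWS
from .smfret import FWHM_PER_SIGMA, FretTrace

__all__ = [
    "SequenceSpec",
    "ChainSpec",
    "FretSimSpec",
    "generate_sequence",
    "generate_chain_ensemble",
    "simulate_fret_traces",
    "sample_proximity_ratios",
]


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a random sequence with fixed composition.

    ``composition`` maps residue letters to counts. ``fixed_positions``
    pins letters at given 1-based positions (they are excluded from
    shuffling and annealing moves), which lets a caller control e.g.
    arginine spacing exactly while the charge patterning is annealed.
    """

    composition: dict
    target_kappa: float | None = None
    kappa_tolerance: float = 0.01
    max_iterations: int = 100_000
    fixed_positions: dict = field(default_factory=dict)
    name: str = "synthetic"
    start: int = 1
    seed: int = 0

    @property
    def length(self) -> int:
        return sum(self.composition.values())

    def __post_init__(self):
        bad = [c for c in self.composition if c not in AMINO_ACIDS]
        if bad:
            raise ValueError(f"non-canonical letters in composition: {bad}")
        if self.target_kappa is not None and not 0.0 <= self.target_kappa <= 1.0:
            raise ValueError("target kappa must be in [0, 1]")
        for pos, letter in self.fixed_positions.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"fixed position {pos} outside sequence")
            if letter not in self.composition:
                raise ValueError(f"fixed letter {letter!r} not in composition")


def _kappa_of(seq_list, windows=KAPPA_WINDOWS) -> float:
    return kappa("".join(seq_list), windows=windows)


def generate_sequence(spec: SequenceSpec) -> ProteinRegion:
    """Random arrangement of the composition, optionally annealed to a kappa.

    Swap-only Metropolis annealing with geometric cooling moves two
    non-fixed residues at a time, so the multiset of letters never
    changes. Stops when |kappa - target| <= tolerance or the iteration cap
    is reached; an unreachable target raises with the best value found.
    """
    rng = np.random.default_rng(spec.seed)
    letters = [c for c, n in sorted(spec.composition.items()) for _ in range(n)]
    n = len(letters)

    fixed_idx = {p - 1 for p in spec.fixed_positions}
    seq = [None] * n
    pool = letters.copy()
    for pos, letter in spec.fixed_positions.items():
        seq[pos - 1] = letter
        pool.remove(letter)
    rng.shuffle(pool)
    free_idx = [i for i in range(n) if i not in fixed_idx]
    for i, letter in zip(free_idx, pool):
        seq[i] = letter

    if spec.target_kappa is not None:
        q = _charge_array("".join(seq))
        n_charged = int(np.sum(q != 0))
        if n_charged < 2 or n < max(KAPPA_WINDOWS):
            raise ValueError("kappa target requires >=2 charged residues and length >= 6")
        current = _kappa_of(seq)
        best_seq, best_err = seq.copy(), abs(current - spec.target_kappa)
        temp = 0.05
        cooling = 0.9999
        free = np.array(free_idx)
        it = 0
        while best_err > spec.kappa_tolerance and it < spec.max_iterations:
            it += 1
            i, j = rng.choice(free, size=2, replace=False)
            if seq[i] == seq[j]:
                continue
            seq[i], seq[j] = seq[j], seq[i]
            new = _kappa_of(seq)
            d_err = abs(new - spec.target_kappa) - abs(current - spec.target_kappa)
            if d_err <= 0 or rng.random() < np.exp(-d_err / temp):
                current = new
                if abs(current - spec.target_kappa) < best_err:
                    best_err = abs(current - spec.target_kappa)
                    best_seq = seq.copy()
            else:
                seq[i], seq[j] = seq[j], seq[i]
            temp *= cooling
        seq = best_seq
        if best_err > spec.kappa_tolerance:
            raise ValueError(
                f"kappa target {spec.target_kappa} unreachable within "
                f"{spec.max_iterations} iterations; best |error| = {best_err:.4f} "
                f"(kappa = {_kappa_of(seq):.4f})"
            )

    return ProteinRegion(name=spec.name, sequence="".join(seq), start=spec.start)


# ---------------------------------------------------------------------------
# chain ensembles
# ---------------------------------------------------------------------------

CHAIN_MODELS = ("gaussian", "excluded-volume", "ideal-helix", "paired-strands")


@dataclass(frozen=True)
class ChainSpec:
    """Recipe for a coarse-grained conformer ensemble."""

    n_residues: int
    model: str = "gaussian"
    bond_length: float = 3.8          # Angstrom, CA-CA
    excluded_volume_radius: float = 1.5  # Angstrom hard-core bead radius;
    # diameter < bond length so bonded neighbours never conflict
    n_frames: int = 1
    seed: int = 0
    temperatures: tuple | None = None  # optional per-frame Kelvin labels

    def __post_init__(self):
        if self.model not in CHAIN_MODELS:
            raise ValueError(f"model must be one of {CHAIN_MODELS}")
        if self.n_residues < 2 or self.n_frames < 1:
            raise ValueError("need n_residues >= 2 and n_frames >= 1")
        if self.bond_length <= 0 or self.excluded_volume_radius <= 0:
            raise ValueError("geometry parameters must be positive")
        if (
            self.model == "excluded-volume"
            and 2 * self.excluded_volume_radius > self.bond_length
        ):
            raise ValueError(
                "infeasible excluded volume: bead diameter exceeds bond length"
            )
        if self.temperatures is not None and len(self.temperatures) != self.n_frames:
            raise ValueError("one temperature per frame required")


def _bead_trajectory(frames: np.ndarray, spec: ChainSpec) -> Trajectory:
    n = spec.n_residues
    return Trajectory(
        coords=frames,
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "GLY"),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        temperatures=None if spec.temperatures is None else np.asarray(spec.temperatures, float),
    )


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _gaussian_chain_frames(spec: ChainSpec, rng) -> np.ndarray:
    steps = _random_unit_vectors(rng, spec.n_frames * (spec.n_residues - 1)) * spec.bond_length
    steps = steps.reshape(spec.n_frames, spec.n_residues - 1, 3)
    coords = np.zeros((spec.n_frames, spec.n_residues, 3))
    coords[:, 1:] = np.cumsum(steps, axis=1)
    return coords


def _pivot_overlap_free(coords, moved_lo, diameter):
    """True if no bead pair across the pivot violates the hard core."""
    fixed = coords[:moved_lo]
    moved = coords[moved_lo:]
    tree = cKDTree(fixed)
    pairs = tree.query_ball_point(moved, diameter - 1e-9)
    for m_off, hits in enumerate(pairs):
        i_moved = moved_lo + m_off
        for j in hits:
            if i_moved - j >= 2:  # bonded neighbours are exempt
                return False
            if i_moved - j == 1:
                continue
    return True


def _excluded_volume_frames(spec: ChainSpec, rng) -> np.ndarray:
    """Pivot-algorithm sampling of a hard-sphere self-avoiding chain."""
    n = spec.n_residues
    b = spec.bond_length
    diameter = 2 * spec.excluded_volume_radius
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * b  # straight rod: always overlap-free

    def attempt_pivot():
        p = int(rng.integers(1, n - 1))
        rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1)))
        tail = coords[p + 1:] - coords[p]
        new_tail = coords[p] + rot.apply(tail)
        trial = coords.copy()
        trial[p + 1:] = new_tail
        if _pivot_overlap_free(trial, p + 1, diameter):
            coords[p + 1:] = new_tail
            return True
        return False

    # burn-in until the rod memory is gone; global observables decorrelate
    # in O(1) accepted pivots, but the straight start needs many
    accepted = 0
    attempts = 0
    while accepted < 10 * n and attempts < 200 * n:
        accepted += attempt_pivot()
        attempts += 1

    frames = np.empty((spec.n_frames, n, 3))
    per_frame = max(4, n // 2)
    for f in range(spec.n_frames):
        accepted = 0
        attempts = 0
        while accepted < per_frame and attempts < 20 * per_frame:
            accepted += attempt_pivot()
            attempts += 1
        frames[f] = coords
    return frames


# -- backbone construction (NeRF internal-coordinate chain building) --------

_BB_GEOMETRY = {
    # bond lengths (A) and angles (deg) of the peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "n_h": 1.01,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5, "omega": 180.0,
}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Position d such that |cd|=bond, angle(b,c,d)=angle, torsion(a,b,c,d)=torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_chain(n_res: int, phi: float, psi: float) -> dict:
    """Ideal backbone (N, CA, C, O, H per residue) at fixed phi/psi."""
    g = _BB_GEOMETRY
    atoms = {}
    # seed first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    c0 = _place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0, g["ca_c"], g["ang_n_ca_c"], phi)
    atoms[(1, "N")], atoms[(1, "CA")], atoms[(1, "C")] = n0, ca0, c0
    for i in range(2, n_res + 1):
        n_prev, ca_prev, c_prev = atoms[(i - 1, "N")], atoms[(i - 1, "CA")], atoms[(i - 1, "C")]
        n_i = _place_atom(n_prev, ca_prev, c_prev, g["c_n"], g["ang_ca_c_n"], psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, g["n_ca"], g["ang_c_n_ca"], g["omega"])
        c_i = _place_atom(c_prev, n_i, ca_i, g["ca_c"], g["ang_n_ca_c"], phi)
        atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")] = n_i, ca_i, c_i
    # carbonyl O in the peptide plane, trans to the next N
    for i in range(1, n_res + 1):
        if (i + 1, "N") in atoms:
            atoms[(i, "O")] = _place_atom(
                atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")], g["c_o"],
                g["ang_ca_c_o"], psi + 180.0,
            )
        else:  # C-terminal O: keep the same construction relative to psi
            atoms[(i, "O")] = _place_atom(
                atoms[(i, "N")], atoms[(i, "CA")], atoms[(i, "C")], g["c_o"],
                g["ang_ca_c_o"], psi + 180.0,
            )
    # amide H on the C(prev)-N-CA bisector (first residue has none)
    for i in range(2, n_res + 1):
        n_i, ca_i, c_prev = atoms[(i, "N")], atoms[(i, "CA")], atoms[(i - 1, "C")]
        u1 = n_i - c_prev
        u2 = n_i - ca_i
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        atoms[(i, "H")] = n_i + g["n_h"] * d / np.linalg.norm(d)
    return atoms


_ATOM_ORDER = ("N", "H", "CA", "C", "O")


def _atoms_to_arrays(atom_sets: list[dict], res_offsets: list[int]):
    """Merge per-chain atom dicts into flat roster arrays (single frame)."""
    res_ids, names, elements, xyz = [], [], [], []
    for atoms, offset in zip(atom_sets, res_offsets):
        n_res = max(i for i, _ in atoms)
        for i in range(1, n_res + 1):
            for name in _ATOM_ORDER:
                if (i, name) in atoms:
                    res_ids.append(i + offset)
                    names.append(name)
                    elements.append(name[0])
                    xyz.append(atoms[(i, name)])
    return (
        np.array(xyz),
        np.array(res_ids),
        np.array(names),
        np.array(elements),
    )


def _helix_trajectory(spec: ChainSpec) -> Trajectory:
    atoms = _backbone_chain(spec.n_residues, phi=-57.0, psi=-47.0)
    xyz, res_ids, names, elements = _atoms_to_arrays([atoms], [0])
    coords = np.repeat(xyz[None, :, :], spec.n_frames, axis=0)
    return Trajectory(
        coords=coords,
        res_ids=res_ids,
        res_names=np.full(res_ids.size, "ALA"),
        atom_names=names,
        elements=elements,
        temperatures=None if spec.temperatures is None else np.asarray(spec.temperatures, float),
    )


def _extended_trajectory(spec: ChainSpec) -> Trajectory:
    atoms = _backbone_chain(spec.n_residues, phi=-139.0, psi=135.0)
    xyz, res_ids, names, elements = _atoms_to_arrays([atoms], [0])
    coords = np.repeat(xyz[None, :, :], spec.n_frames, axis=0)
    return Trajectory(
        coords=coords,
        res_ids=res_ids,
        res_names=np.full(res_ids.size, "ALA"),
        atom_names=names,
        elements=elements,
        temperatures=None if spec.temperatures is None else np.asarray(spec.temperatures, float),
    )


def _count_interchain_hbonds(atoms_a, atoms_b, n_res):
    """Cheap N-H...O criterion counter between two backbone chains."""
    count = 0
    for da, db in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        for i in range(2, n_res + 1):
            if (i, "H") not in da:
                continue
            n_i, h_i = da[(i, "N")], da[(i, "H")]
            for j in range(1, n_res + 1):
                o_j = db.get((j, "O"))
                if o_j is None:
                    continue
                if np.linalg.norm(o_j - n_i) > 3.5:
                    continue
                v1 = n_i - h_i
                v2 = o_j - h_i
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 120.0:
                    count += 1
    return count


def _paired_strands_trajectory(spec: ChainSpec) -> Trajectory:
    """Two antiparallel extended chains placed at the H-bond register.

    The second strand is the first rotated 180 degrees about the strand
    axis normal; its rigid offset is chosen by a deterministic grid search
    maximising the number of inter-strand backbone H-bonds under the
    3.5 A / 120 degree criterion.
    """
    n = spec.n_residues
    atoms_a = _backbone_chain(n, phi=-139.0, psi=135.0)

    # orient strand A along its end-to-end axis for a clean search frame
    keys = sorted(atoms_a)
    xyz = np.array([atoms_a[k] for k in keys])
    axis = atoms_a[(n, "CA")] - atoms_a[(1, "CA")]
    axis /= np.linalg.norm(axis)
    rot_align, _ = Rotation.align_vectors([[1.0, 0.0, 0.0]], [axis])
    xyz = rot_align.apply(xyz - xyz.mean(axis=0))
    atoms_a = {k: xyz[i] for i, k in enumerate(keys)}

    flip = Rotation.from_euler("z", 180, degrees=True)
    base_b = {k: flip.apply(v) for k, v in atoms_a.items()}

    best = (-1, None)
    for dy in np.arange(3.8, 5.8, 0.1):
        for dx in np.arange(-3.5, 3.5, 0.1):
            shift = np.array([dx, dy, 0.0])
            cand = {k: v + shift for k, v in base_b.items()}
            score = _count_interchain_hbonds(atoms_a, cand, n)
            if score > best[0]:
                best = (score, cand)
    atoms_b = best[1]

    xyz, res_ids, names, elements = _atoms_to_arrays([atoms_a, atoms_b], [0, n])
    coords = np.repeat(xyz[None, :, :], spec.n_frames, axis=0)
    return Trajectory(
        coords=coords,
        res_ids=res_ids,
        res_names=np.full(res_ids.size, "ALA"),
        atom_names=names,
        elements=elements,
        temperatures=None if spec.temperatures is None else np.asarray(spec.temperatures, float),
    )


def generate_chain_ensemble(spec: ChainSpec) -> Trajectory:
    """Conformer ensemble of the requested chain model (see :class:`ChainSpec`)."""
    rng = np.random.default_rng(spec.seed)
    if spec.model == "gaussian":
        return _bead_trajectory(_gaussian_chain_frames(spec, rng), spec)
    if spec.model == "excluded-volume":
        return _bead_trajectory(_excluded_volume_frames(spec, rng), spec)
    if spec.model == "ideal-helix":
        return _helix_trajectory(spec)
    if spec.model == "paired-strands":
        return _paired_strands_trajectory(spec)
    raise ValueError(spec.model)  # unreachable; validated in ChainSpec


# ---------------------------------------------------------------------------
# FRET trace simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretSimSpec:
    """Recipe for stochastic multistate smFRET traces.

    States follow a continuous-time Markov chain with off-diagonal rate
    matrix ``rates`` (per second); each dye bleaches once with an
    exponential waiting time; per-frame intensities carry Gaussian noise
    with variance proportional to the noiseless intensity (camera-like
    shot noise, ``noise_factor`` counts of variance per count of signal).
    """

    means: tuple                      # per-state true E
    fwhms: tuple                      # per-state FWHM of the E distribution
    rates: tuple | None = None        # (k, k) off-diagonal rates, 1/s
    frame_rate: float = 10.0
    n_frames: int = 400
    total_intensity: float = 500.0
    noise_factor: float = 1.0
    background_sd: float = 5.0
    donor_bleach_rate: float = 0.02   # 1/s
    acceptor_bleach_rate: float = 0.02
    direct_intensity: float = 300.0
    n_molecules: int = 100
    n_donors: int = 1
    n_acceptors: int = 1
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.means)

    def __post_init__(self):
        if len(self.fwhms) != self.n_states:
            raise ValueError("means and fwhms must have equal length")
        if any(not 0 <= e <= 1 for e in self.means):
            raise ValueError("state E values must lie in [0, 1]")
        if self.rates is not None:
            q = np.asarray(self.rates, dtype=float)
            if q.shape != (self.n_states, self.n_states) or np.any(q < 0):
                raise ValueError("rates must be a nonnegative (k, k) matrix")

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q with rows summing to zero."""
        k = self.n_states
        q = np.zeros((k, k)) if self.rates is None else np.asarray(self.rates, float).copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary occupancy of the state chain (uniform if static)."""
        q = self.rate_matrix()
        if np.allclose(q, 0.0):
            return np.full(self.n_states, 1.0 / self.n_states)
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / pi.sum()


def _state_path(spec: FretSimSpec, rng, t_end: float):
    """Exact CTMC jump chain: (jump times, states) covering [0, t_end]."""
    q = spec.rate_matrix()
    pi = spec.stationary_distribution()
    s = int(rng.choice(spec.n_states, p=pi))
    times = [0.0]
    states = [s]
    t = 0.0
    while True:
        out = -q[s, s]
        if out <= 0:
            break
        t += rng.exponential(1.0 / out)
        if t >= t_end:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(spec.n_states, p=probs))
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states)


def _frame_mean_E(spec: FretSimSpec, times, states, rng) -> np.ndarray:
    """Time-weighted state E per frame, plus within-state Gaussian spread."""
    dt = 1.0 / spec.frame_rate
    bounds = np.arange(spec.n_frames + 1) * dt
    e_states = np.asarray(spec.means)
    sig_states = np.asarray(spec.fwhms) / FWHM_PER_SIGMA
    # piecewise-constant integration of E over each frame
    edges = np.concatenate([times, [bounds[-1]]])
    e_frames = np.empty(spec.n_frames)
    sig_frames = np.empty(spec.n_frames)
    for f in range(spec.n_frames):
        lo, hi = bounds[f], bounds[f + 1]
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
        w = overlap / dt
        e_frames[f] = float(w @ e_states[states])
        sig_frames[f] = float(w @ sig_states[states])
    # within-state spread is a [0, 1]-truncated Gaussian (the same state
    # model the histogram fit assumes); clipping instead would pile a
    # point mass at the boundaries
    out = e_frames.copy()
    spread = sig_frames > 0
    if spread.any():
        a = (0.0 - e_frames[spread]) / sig_frames[spread]
        b = (1.0 - e_frames[spread]) / sig_frames[spread]
        out[spread] = truncnorm.rvs(
            a, b, loc=e_frames[spread], scale=sig_frames[spread],
            random_state=np.random.RandomState(rng.integers(2**31 - 1)),
        )
    return out


def simulate_fret_traces(spec: FretSimSpec) -> list[FretTrace]:
    """Simulate ``n_molecules`` traces (see :class:`FretSimSpec`).

    Multi-dye molecules (``n_donors``/``n_acceptors`` > 1) superpose
    independent copies — the multi-step bleaching they produce is what the
    single-pair selection stage must reject.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    t_end = spec.n_frames * dt
    traces = []
    for mol in range(spec.n_molecules):
        donor = np.zeros(spec.n_frames)
        acceptor = np.zeros(spec.n_frames)
        direct = np.zeros(spec.n_frames)
        frame_t = np.arange(spec.n_frames) * dt
        for _ in range(spec.n_donors):
            times, states = _state_path(spec, rng, t_end)
            e = _frame_mean_E(spec, times, states, rng)
            t_dbleach = (
                rng.exponential(1.0 / spec.donor_bleach_rate)
                if spec.donor_bleach_rate > 0 else np.inf
            )
            t_ableach = (
                rng.exponential(1.0 / spec.acceptor_bleach_rate)
                if spec.acceptor_bleach_rate > 0 else np.inf
            )
            d_alive = frame_t + 0.5 * dt < t_dbleach
            a_alive = frame_t + 0.5 * dt < t_ableach
            i_tot = spec.total_intensity / spec.n_donors
            transfer = np.where(a_alive, e, 0.0)
            donor += np.where(d_alive, i_tot * (1.0 - transfer), 0.0)
            acceptor += np.where(d_alive & a_alive, i_tot * transfer, 0.0)
            direct += np.where(a_alive, spec.direct_intensity / spec.n_acceptors, 0.0)
        for _ in range(spec.n_acceptors - 1):
            t_ableach = (
                rng.exponential(1.0 / spec.acceptor_bleach_rate)
                if spec.acceptor_bleach_rate > 0 else np.inf
            )
            direct += np.where(
                frame_t + 0.5 * dt < t_ableach, spec.direct_intensity / spec.n_acceptors, 0.0
            )

        def noisy(clean):
            sd = np.sqrt(spec.noise_factor * np.clip(clean, 0.0, None) + spec.background_sd**2)
            return clean + rng.normal(0.0, 1.0, clean.shape) * sd

        traces.append(
            FretTrace(
                donor=noisy(donor),
                acceptor=noisy(acceptor),
                direct_acceptor=noisy(direct),
                frame_rate=spec.frame_rate,
                molecule_id=str(mol),
            )
        )
    return traces


def sample_proximity_ratios(
    means, fwhms, weights, n: int, seed: int = 0
) -> np.ndarray:
    """Draw proximity ratios from a [0, 1]-truncated Gaussian mixture.

    A direct route to population histograms with known state parameters,
    bypassing trace-level simulation; used for mixture-fit recovery tests.
    """
    rng = np.random.default_rng(seed)
    means = np.asarray(means, float)
    sigmas = np.asarray(fwhms, float) / FWHM_PER_SIGMA
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    comp = rng.choice(means.size, size=n, p=weights)
    out = np.empty(n)
    for k in range(means.size):
        mask = comp == k
        a = (0.0 - means[k]) / sigmas[k]
        b = (1.0 - means[k]) / sigmas[k]
        out[mask] = truncnorm.rvs(
            a, b, loc=means[k], scale=sigmas[k], size=int(mask.sum()), random_state=np.random.RandomState(rng.integers(2**31 - 1))
        )
    return out
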