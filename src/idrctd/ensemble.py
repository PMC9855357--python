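"""Conformer-ensemble observables for disordered-protein trajectories.

Operates on multi-model coordinate ensembles (e.g. snapshots from a
replica-exchange simulation) and computes the observables used to compare
disordered-chain conformational landscapes:

* per-frame radius of gyration and its distribution,
* pairwise residue contact-frequency maps (heavy-atom criterion),
* backbone hydrogen bonds (N...O <= 3.5 A and N-H...O angle > 120 deg),
* a Kabsch-Sander-style secondary-structure assignment built on those
  hydrogen bonds, collapsed to {helix, sheet, turn, coil}, and its
  per-residue occupancy over the ensemble.

Frames may carry a replica-temperature label so that analysis can be
restricted to a thermal window (e.g. 300-310 K) without demultiplexing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Trajectory",
    "RgDistribution",
    "ContactFrequencyMap",
    "SecondaryStructureProfile",
    "load_trajectory",
    "write_trajectory",
    "select_temperature_window",
    "radius_of_gyration",
    "contact_frequency_map",
    "detect_hbonds",
    "assign_secondary_structure",
    "ss_occupancy",
]

SS_CLASSES = ("helix", "sheet", "turn", "coil")

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

HBOND_DISTANCE_CUTOFF = 3.5   # N...O, Angstrom
HBOND_ANGLE_CUTOFF = 120.0    # N-H...O, degrees


class StructureError(ValueError):
    """Raised for malformed or internally inconsistent coordinate files."""


@dataclass(eq=False)
class Trajectory:
    """Ordered conformer frames sharing one atom roster.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, Angstrom
    res_ids : (n_atoms,) int array, 1-based residue numbers
    res_names, atom_names, elements : (n_atoms,) string arrays
    temperatures : optional (n_frames,) float array, Kelvin replica labels
    """

    coords: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    temperatures: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(f"coords must be (F, A, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        n_atoms = self.coords.shape[1]
        for name in ("res_ids", "res_names", "atom_names", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise StructureError(f"{name} has shape {arr.shape}, expected ({n_atoms},)")
            setattr(self, name, arr)
        if self.temperatures is not None:
            self.temperatures = np.asarray(self.temperatures, dtype=float)
            if self.temperatures.shape != (self.n_frames,):
                raise StructureError("one temperature per frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue ids."""
        return np.unique(self.res_ids)

    @property
    def n_residues(self) -> int:
        return self.residue_numbers.size


@dataclass(frozen=True)
class RgDistribution:
    """Per-frame radius-of-gyration values with a density histogram."""

    values: np.ndarray            # (F,) Angstrom
    bin_edges: np.ndarray
    densities: np.ndarray         # integrates to 1

    @property
    def mode(self) -> float:
        """Center of the highest-density histogram bin."""
        i = int(np.argmax(self.densities))
        return float(0.5 * (self.bin_edges[i] + self.bin_edges[i + 1]))


@dataclass(frozen=True)
class ContactFrequencyMap:
    """Symmetric residue-pair contact probabilities in [0, 1]."""

    residue_numbers: np.ndarray
    matrix: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.residue_numbers.size


@dataclass(frozen=True)
class SecondaryStructureProfile:
    """Per-residue occupancy of {helix, sheet, turn, coil} over frames."""

    residue_numbers: np.ndarray
    probabilities: np.ndarray     # (n_res, 4), rows sum to 1
    classes: tuple[str, ...] = SS_CLASSES


# ---------------------------------------------------------------------------
# multi-model PDB I/O
# ---------------------------------------------------------------------------

_TEMP_REMARK_PREFIX = "REMARK 250 MODEL"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB; replica temperatures go into REMARK 250."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = traj.coords
    stack.res_id = traj.res_ids.astype(int)
    stack.res_name = traj.res_names.astype("U5")
    stack.atom_name = traj.atom_names.astype("U6")
    stack.element = np.char.upper(traj.elements.astype("U2"))
    stack.chain_id = np.full(traj.n_atoms, "A", dtype="U4")
    stack.hetero = np.zeros(traj.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    if traj.temperatures is not None:
        remarks = [
            f"{_TEMP_REMARK_PREFIX} {m + 1:5d} TEMPERATURE (K): {t:8.2f}"
            for m, t in enumerate(traj.temperatures)
        ]
        pdb.lines = remarks + pdb.lines
    pdb.write(str(path))


def load_trajectory(path, sidecar=None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Replica temperatures are taken from ``REMARK 250 MODEL`` records when
    present; a sidecar CSV with columns ``model`` (1-based) and
    ``temperature_K`` overrides them.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise StructureError(f"no atoms/models found in {path}")

    temperatures = None
    temps = {}
    for line in pdb.lines:
        if line.startswith(_TEMP_REMARK_PREFIX):
            try:
                fields = line.split()
                temps[int(fields[3])] = float(fields[-1])
            except (IndexError, ValueError):
                warnings.warn(f"unparseable temperature remark: {line!r}")
    if temps:
        temperatures = np.array(
            [temps.get(m + 1, np.nan) for m in range(stack.stack_depth())]
        )
    if sidecar is not None:
        import pandas as pd

        df = pd.read_csv(sidecar)
        temperatures = np.full(stack.stack_depth(), np.nan)
        for _, row in df.iterrows():
            temperatures[int(row["model"]) - 1] = float(row["temperature_K"])

    return Trajectory(
        coords=stack.coord,
        res_ids=stack.res_id,
        res_names=stack.res_name,
        atom_names=stack.atom_name,
        elements=stack.element,
        temperatures=temperatures,
    )


def select_temperature_window(traj: Trajectory, t_min: float, t_max: float) -> Trajectory:
    """Keep only frames whose replica temperature lies in [t_min, t_max]."""
    if traj.temperatures is None:
        raise ValueError(
            "trajectory carries no temperature metadata; "
            "skip temperature selection or supply a sidecar"
        )
    mask = (traj.temperatures >= t_min) & (traj.temperatures <= t_max)
    if not mask.any():
        warnings.warn(f"no frames inside temperature window [{t_min}, {t_max}] K")
    return Trajectory(
        coords=traj.coords[mask],
        res_ids=traj.res_ids,
        res_names=traj.res_names,
        atom_names=traj.atom_names,
        elements=traj.elements,
        temperatures=traj.temperatures[mask],
    )


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def _masses(traj: Trajectory) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES.get(str(e).upper(), 12.011) for e in traj.elements]
    )


def radius_of_gyration(
    traj: Trajectory, mass_weighted: bool = False, bin_width: float = 1.0
) -> RgDistribution:
    """Per-frame Rg = sqrt(sum w |r - r_cm|^2 / sum w) with a histogram."""
    if traj.n_frames == 0 or traj.n_atoms == 0:
        raise ValueError("empty trajectory")
    w = _masses(traj) if mass_weighted else np.ones(traj.n_atoms)
    wsum = w.sum()
    com = np.einsum("fad,a->fd", traj.coords, w) / wsum
    dev = traj.coords - com[:, None, :]
    rg = np.sqrt(np.einsum("fad,fad,a->f", dev, dev, w) / wsum)
    lo = np.floor(rg.min() / bin_width) * bin_width
    hi = np.ceil(rg.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    dens, edges = np.histogram(rg, bins=edges, density=True)
    return RgDistribution(values=rg, bin_edges=edges, densities=dens)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_frequency_map(
    traj: Trajectory, cutoff: float = 6.5, min_separation: int = 2
) -> ContactFrequencyMap:
    """Residue-pair contact probabilities over frames.

    Two residues are in contact in a frame iff any pair of their heavy
    atoms (element != H) lies within ``cutoff`` Angstrom; sequence
    neighbours with |i - j| < ``min_separation`` are excluded (entries
    fixed at zero).
    """
    heavy = np.array([str(e).upper() != "H" for e in traj.elements])
    if not heavy.any():
        raise ValueError("no heavy atoms in trajectory")
    res_numbers = traj.residue_numbers
    index_of = {r: i for i, r in enumerate(res_numbers)}
    atom_res = np.array([index_of[r] for r in traj.res_ids[heavy]])
    atom_resnum = traj.res_ids[heavy].astype(int)
    n_res = res_numbers.size
    counts = np.zeros((n_res, n_res))
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f][heavy])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ri = atom_res[pairs[:, 0]]
        rj = atom_res[pairs[:, 1]]
        # sequence separation uses residue *numbers*, not matrix indices
        keep = np.abs(atom_resnum[pairs[:, 0]] - atom_resnum[pairs[:, 1]]) >= min_separation
        if not keep.any():
            continue
        contact_pairs = np.unique(
            np.sort(np.stack([ri[keep], rj[keep]], axis=1), axis=1), axis=0
        )
        counts[contact_pairs[:, 0], contact_pairs[:, 1]] += 1
    prob = counts / max(traj.n_frames, 1)
    prob = prob + prob.T
    return ContactFrequencyMap(residue_numbers=res_numbers, matrix=prob)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _backbone_atoms(traj: Trajectory, frame: int):
    """Per-residue backbone coordinates {res_id: {atom_name: xyz}}."""
    out: dict[int, dict[str, np.ndarray]] = {}
    xyz = traj.coords[frame]
    for a in range(traj.n_atoms):
        name = str(traj.atom_names[a]).strip()
        if name in ("N", "CA", "C", "O", "H", "HN"):
            out.setdefault(int(traj.res_ids[a]), {})["H" if name == "HN" else name] = xyz[a]
    return out


def _amide_h(backbone, res: int) -> np.ndarray | None:
    """Amide H position: recorded, or bisector reconstruction at 1.01 A.

    The reconstructed H lies in the C(prev)-N-CA plane on the outward
    bisector of that angle. The chain's first residue has no amide donor.
    """
    atoms = backbone.get(res, {})
    if "H" in atoms:
        return atoms["H"]
    prev = backbone.get(res - 1, {})
    if "N" not in atoms or "CA" not in atoms or "C" not in prev:
        return None
    n = atoms["N"]
    u1 = n - prev["C"]
    u2 = n - atoms["CA"]
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    d = u1 + u2
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        return None
    return n + 1.01 * d / norm


def detect_hbonds(traj: Trajectory, frame: int = 0) -> list[tuple[int, int]]:
    """Backbone H-bonds (donor_res, acceptor_res) in one frame.

    A bond requires d(N, O) <= 3.5 A and angle(N-H...O) > 120 deg. Proline
    and the first residue lack an amide donor; the bond to the covalently
    preceding carbonyl (acceptor = donor - 1) and to the donor itself are
    excluded.
    """
    backbone = _backbone_atoms(traj, frame)
    res_numbers = sorted(backbone)
    resname_of = {int(r): str(n) for r, n in zip(traj.res_ids, traj.res_names)}
    skipped = []
    bonds = []
    acceptors = [
        (r, backbone[r]["O"]) for r in res_numbers if "O" in backbone[r]
    ]
    if not acceptors:
        return []
    acc_ids = np.array([r for r, _ in acceptors])
    acc_xyz = np.array([o for _, o in acceptors])
    for donor in res_numbers:
        if resname_of.get(donor) == "PRO":
            continue
        atoms = backbone[donor]
        if "N" not in atoms:
            skipped.append(donor)
            continue
        h = _amide_h(backbone, donor)
        if h is None:
            if donor != res_numbers[0]:
                skipped.append(donor)
            continue
        n = atoms["N"]
        dist = np.linalg.norm(acc_xyz - n, axis=1)
        for j in np.nonzero(dist <= HBOND_DISTANCE_CUTOFF)[0]:
            acc = int(acc_ids[j])
            if acc in (donor, donor - 1):
                continue
            v1 = n - h
            v2 = acc_xyz[j] - h
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > HBOND_ANGLE_CUTOFF:
                bonds.append((donor, acc))
    if skipped:
        warnings.warn(f"residues missing backbone atoms skipped: {skipped[:10]}")
    return bonds


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def assign_secondary_structure(traj: Trajectory, frame: int = 0) -> np.ndarray:
    """Per-residue class in {helix, sheet, turn, coil} for one frame.

    Kabsch-Sander-style pattern matching on the backbone H-bond list:
    consecutive i+4 (or i+3, i+5) turns define helices, bridge patterns
    between non-adjacent strands define sheets, isolated turns are turns,
    everything else is coil. The 8-class vocabulary {H, G, I} / {E, B} /
    {T} / {S, blank} is collapsed to 4 classes.
    """
    res_numbers = traj.residue_numbers
    bonds = set(detect_hbonds(traj, frame))

    def hbond(d, a):
        return (d, a) in bonds

    # n-turns: turn_n[i] true iff N-H(i+n) -> O(i)
    turn = {n: {i: hbond(i + n, i) for i in res_numbers} for n in (3, 4, 5)}

    helix = set()
    for n in (4, 3, 5):
        for i in res_numbers:
            # minimal helix: two consecutive n-turns starting at i-1 and i
            if turn[n].get(i - 1) and turn[n].get(i):
                helix.update(range(i, i + n))

    # bridges (parallel / antiparallel), Kabsch-Sander definitions
    sheet = set()
    for i in res_numbers:
        for j in res_numbers:
            if abs(i - j) < 3 or j <= i:
                continue
            parallel = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            antiparallel = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            if parallel or antiparallel:
                sheet.update((i, j))

    in_turn = set()
    for n in (3, 4, 5):
        for i in res_numbers:
            if turn[n].get(i):
                in_turn.update(range(i + 1, i + n))

    out = np.full(res_numbers.size, "coil", dtype="U5")
    for k, r in enumerate(res_numbers):
        if r in helix:
            out[k] = "helix"
        elif r in sheet:
            out[k] = "sheet"
        elif r in in_turn:
            out[k] = "turn"
    return out


def ss_occupancy(traj: Trajectory) -> SecondaryStructureProfile:
    """Per-residue class frequencies over all frames (rows sum to 1)."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    res_numbers = traj.residue_numbers
    counts = np.zeros((res_numbers.size, len(SS_CLASSES)))
    class_index = {c: k for k, c in enumerate(SS_CLASSES)}
    for f in range(traj.n_frames):
        labels = assign_secondary_structure(traj, f)
        for k, lab in enumerate(labels):
            counts[k, class_index[str(lab)]] += 1
    probs = counts / traj.n_frames
    return SecondaryStructureProfile(residue_numbers=res_numbers, probabilities=probs)
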