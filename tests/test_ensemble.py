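"""Trajectory observables: Rg oracle, contacts, H-bonds, secondary structure."""

import numpy as np
import pytest

from idrctd.ensemble import (
    StructureError,
    Trajectory,
    assign_secondary_structure,
    contact_frequency_map,
    detect_hbonds,
    load_trajectory,
    radius_of_gyration,
    select_temperature_window,
    ss_occupancy,
    write_trajectory,
    HBOND_ANGLE_CUTOFF,
    HBOND_DISTANCE_CUTOFF,
)
from idrctd.synthetic import ChainSpec, generate_chain_ensemble


def bead_traj(coords, res_ids=None, elements=None, temperatures=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        res_ids=np.arange(1, n + 1) if res_ids is None else np.asarray(res_ids),
        res_names=np.full(n, "GLY"),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C") if elements is None else np.asarray(elements),
        temperatures=temperatures,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip_preserves_coordinates(tmp_path):
    traj = generate_chain_ensemble(
        ChainSpec(n_residues=20, model="gaussian", n_frames=50, seed=5)
    )
    p = tmp_path / "ens.pdb"
    write_trajectory(traj, p)
    back = load_trajectory(p)
    assert back.n_frames == 50 and back.n_atoms == 20
    assert np.abs(back.coords - traj.coords).max() < 1e-3
    assert back.temperatures is None


def test_temperature_remarks_round_trip(tmp_path):
    temps = tuple(np.linspace(275, 360, 18))
    traj = generate_chain_ensemble(
        ChainSpec(n_residues=5, model="gaussian", n_frames=18, seed=1, temperatures=temps)
    )
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    back = load_trajectory(p)
    assert np.allclose(back.temperatures, temps)


def test_sidecar_overrides_temperatures(tmp_path):
    traj = generate_chain_ensemble(ChainSpec(n_residues=5, model="gaussian", n_frames=3, seed=1))
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    sc = tmp_path / "temps.csv"
    sc.write_text("model,temperature_K\n1,280\n2,305\n3,350\n")
    back = load_trajectory(p, sidecar=sc)
    assert np.allclose(back.temperatures, [280, 305, 350])


def test_inconsistent_roster_raises(tmp_path):
    traj = generate_chain_ensemble(ChainSpec(n_residues=4, model="gaussian", n_frames=2, seed=1))
    p = tmp_path / "bad.pdb"
    write_trajectory(traj, p)
    lines = p.read_text().splitlines()
    # drop one ATOM line from the second model
    seen_model2 = False
    out = []
    dropped = False
    for ln in lines:
        if ln.startswith("MODEL") and "2" in ln.split():
            seen_model2 = True
        if seen_model2 and not dropped and ln.startswith("ATOM"):
            dropped = True
            continue
        out.append(ln)
    p.write_text("\n".join(out) + "\n")
    with pytest.raises(StructureError):
        load_trajectory(p)


def test_empty_file_raises(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("")
    with pytest.raises(StructureError):
        load_trajectory(p)


# ---------------------------------------------------------------------------
# temperature window
# ---------------------------------------------------------------------------

def test_temperature_window_selection():
    temps = np.linspace(275, 360, 18)
    traj = generate_chain_ensemble(
        ChainSpec(n_residues=5, model="gaussian", n_frames=18, seed=2,
                  temperatures=tuple(temps))
    )
    sel = select_temperature_window(traj, 300, 310)
    expected = np.sum((temps >= 300) & (temps <= 310))
    assert sel.n_frames == expected
    assert np.all((sel.temperatures >= 300) & (sel.temperatures <= 310))


def test_temperature_window_all_and_none():
    traj = generate_chain_ensemble(
        ChainSpec(n_residues=4, model="gaussian", n_frames=3, seed=0,
                  temperatures=(305.0, 305.0, 305.0))
    )
    assert select_temperature_window(traj, 300, 310).n_frames == 3
    with pytest.warns(UserWarning):
        empty = select_temperature_window(traj, 400, 410)
    assert empty.n_frames == 0


def test_temperature_window_requires_metadata():
    traj = generate_chain_ensemble(ChainSpec(n_residues=4, model="gaussian", n_frames=2, seed=0))
    with pytest.raises(ValueError, match="temperature"):
        select_temperature_window(traj, 300, 310)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def test_rg_two_points():
    d = 3.0
    t = bead_traj([[[0, 0, 0], [2 * d, 0, 0]]])
    assert radius_of_gyration(t).values[0] == pytest.approx(d)


def test_rg_square_corners():
    a = 2.0
    t = bead_traj([[[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]]])
    assert radius_of_gyration(t).values[0] == pytest.approx(a / np.sqrt(2))


def test_rg_matches_pairwise_distance_oracle():
    """Equal masses: Rg^2 = (1/2N^2) sum_ij |r_i - r_j|^2."""
    rng = np.random.default_rng(7)
    coords = rng.normal(scale=10.0, size=(25, 100, 3))
    t = bead_traj(coords)
    rg = radius_of_gyration(t).values
    for f in range(coords.shape[0]):
        diff = coords[f][:, None, :] - coords[f][None, :, :]
        oracle = np.sqrt((diff**2).sum(-1).sum() / (2 * 100**2))
        assert rg[f] == pytest.approx(oracle, abs=1e-9)


def test_rg_mass_weighting_changes_result():
    t = bead_traj(
        [[[0, 0, 0], [4, 0, 0]]], elements=np.array(["C", "S"])
    )
    uniform = radius_of_gyration(t, mass_weighted=False).values[0]
    weighted = radius_of_gyration(t, mass_weighted=True).values[0]
    assert uniform == pytest.approx(2.0)
    assert weighted != pytest.approx(uniform)


def test_rg_histogram_integrates_to_one():
    traj = generate_chain_ensemble(ChainSpec(n_residues=30, model="gaussian", n_frames=200, seed=3))
    dist = radius_of_gyration(traj)
    widths = np.diff(dist.bin_edges)
    assert np.sum(dist.densities * widths) == pytest.approx(1.0)
    assert np.all(dist.values > 0)
    assert dist.bin_edges[0] <= dist.mode <= dist.bin_edges[-1]


# ---------------------------------------------------------------------------
# contact map
# ---------------------------------------------------------------------------

def two_residue_traj(distance):
    return bead_traj([[[0, 0, 0], [distance, 0, 0]]], res_ids=[1, 3])


def test_contact_inside_and_outside_cutoff():
    assert contact_frequency_map(two_residue_traj(6.4)).matrix[0, 1] == 1.0
    assert contact_frequency_map(two_residue_traj(6.6)).matrix[0, 1] == 0.0


def test_adjacent_residues_excluded():
    t = bead_traj([[[0, 0, 0], [3.0, 0, 0]]], res_ids=[1, 2])
    m = contact_frequency_map(t, min_separation=2).matrix
    assert m[0, 1] == 0.0
    m1 = contact_frequency_map(t, min_separation=1).matrix
    assert m1[0, 1] == 1.0


def test_contact_map_symmetric_and_bounded():
    traj = generate_chain_ensemble(ChainSpec(n_residues=25, model="gaussian", n_frames=40, seed=9))
    cm = contact_frequency_map(traj)
    assert np.array_equal(cm.matrix, cm.matrix.T)
    assert np.all((cm.matrix >= 0) & (cm.matrix <= 1))
    assert np.all(np.diag(cm.matrix) == 0)


def test_contact_probability_monotone_in_cutoff():
    traj = generate_chain_ensemble(ChainSpec(n_residues=25, model="gaussian", n_frames=40, seed=11))
    small = contact_frequency_map(traj, cutoff=5.0).matrix
    large = contact_frequency_map(traj, cutoff=8.0).matrix
    assert np.all(large >= small)


def test_all_hydrogen_roster_rejected():
    t = bead_traj([[[0, 0, 0], [1, 0, 0]]], elements=np.array(["H", "H"]))
    with pytest.raises(ValueError, match="heavy"):
        contact_frequency_map(t)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def geometry_traj(n_o_distance, angle_deg):
    """Donor residue 1 (N, H, CA, C) and acceptor residue 5 (O + backbone).

    The acceptor O is placed so that d(N, O) and angle(N-H...O) take the
    requested values; H sits along +x from N.
    """
    from scipy.optimize import brentq

    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.01, 0.0, 0.0])
    # O lies on the ray from H making the requested angle with H->N (which
    # points along -x), scaled so that |N - O| equals the requested distance
    phi = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(phi), np.sin(phi), 0.0])
    f = lambda s: np.linalg.norm(h + s * direction - n) - n_o_distance
    s = brentq(f, 1e-3, 10.0)
    o = h + s * direction
    atoms = {
        (1, "N"): n, (1, "H"): h, (1, "CA"): np.array([0.5, -1.3, 0.0]),
        (1, "C"): np.array([1.8, -1.8, 0.0]),
        (5, "CA"): o + np.array([2.0, 1.0, 0.0]),
        (5, "C"): o + np.array([1.2, 0.2, 0.0]),
        (5, "O"): o,
        (5, "N"): o + np.array([2.5, 2.0, 0.0]),
    }
    keys = sorted(atoms)
    coords = np.array([[atoms[k] for k in keys]])
    return Trajectory(
        coords=coords,
        res_ids=np.array([k[0] for k in keys]),
        res_names=np.full(len(keys), "ALA"),
        atom_names=np.array([k[1] for k in keys]),
        elements=np.array([k[1][0] for k in keys]),
    )


def test_hbond_satisfying_both_criteria():
    t = geometry_traj(3.4, 150.0)
    assert (1, 5) in detect_hbonds(t, 0)


def test_hbond_distance_fails():
    t = geometry_traj(3.6, 170.0)
    assert (1, 5) not in detect_hbonds(t, 0)


def test_hbond_angle_fails():
    t = geometry_traj(3.2, 100.0)
    assert (1, 5) not in detect_hbonds(t, 0)


def test_helix_has_i_to_i_plus_4_pattern(helix_traj):
    bonds = detect_hbonds(helix_traj, 0)
    n_res = helix_traj.n_residues
    expected = {(i + 4, i) for i in range(1, n_res - 3)}
    assert expected <= set(bonds)


def test_hbonds_match_independent_geometric_scan(helix_traj, strands_traj):
    """Brute-force O(N^2) re-application of the distance/angle criterion."""
    for traj in (helix_traj, strands_traj):
        xyz = traj.coords[0]
        res = {}
        for a in range(traj.n_atoms):
            res.setdefault(int(traj.res_ids[a]), {})[str(traj.atom_names[a])] = xyz[a]
        oracle = set()
        ids = sorted(res)
        for d in ids:
            if "N" not in res[d] or "H" not in res[d]:
                continue
            nd, hd = res[d]["N"], res[d]["H"]
            for a in ids:
                if a in (d, d - 1) or "O" not in res[a]:
                    continue
                o = res[a]["O"]
                if np.linalg.norm(o - nd) > HBOND_DISTANCE_CUTOFF:
                    continue
                v1, v2 = nd - hd, o - hd
                ang = np.degrees(
                    np.arccos(np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
                )
                if ang > HBOND_ANGLE_CUTOFF:
                    oracle.add((d, a))
        assert set(detect_hbonds(traj, 0)) == oracle


def test_amide_h_reconstruction_when_absent(helix_traj):
    """Stripping the explicit amide hydrogens barely changes the bond list."""
    keep = helix_traj.atom_names != "H"
    stripped = Trajectory(
        coords=helix_traj.coords[:, keep],
        res_ids=helix_traj.res_ids[keep],
        res_names=helix_traj.res_names[keep],
        atom_names=helix_traj.atom_names[keep],
        elements=helix_traj.elements[keep],
    )
    bonds = set(detect_hbonds(stripped, 0))
    n_res = stripped.n_residues
    expected = {(i + 4, i) for i in range(2, n_res - 3)}
    assert expected <= bonds


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def test_helix_assignment(helix_traj):
    labels = assign_secondary_structure(helix_traj, 0)
    interior = labels[1:-1]
    assert np.mean(interior == "helix") >= 0.9


def test_extended_chain_is_coil(extended_traj):
    labels = assign_secondary_structure(extended_traj, 0)
    assert np.all(labels == "coil")


def test_paired_strands_are_sheet(strands_traj):
    labels = assign_secondary_structure(strands_traj, 0)
    n = strands_traj.n_residues // 2
    interior = np.concatenate([labels[1:n - 1], labels[n + 1:-1]])
    assert np.mean(interior == "sheet") >= 0.7


def test_helix_assignment_agrees_with_mdtraj_dssp(tmp_path, helix_traj):
    """Independent cross-check against mdtraj's DSSP implementation."""
    mdtraj = pytest.importorskip("mdtraj")
    p = tmp_path / "helix.pdb"
    write_trajectory(helix_traj, p)
    m = mdtraj.load(str(p))
    dssp = mdtraj.compute_dssp(m, simplified=True)[0]
    ours = assign_secondary_structure(helix_traj, 0)
    interior = slice(2, helix_traj.n_residues - 2)
    agree = np.mean((dssp[interior] == "H") == (ours[interior] == "helix"))
    assert agree >= 0.9


def test_ss_occupancy_rows_sum_to_one(helix_traj):
    prof = ss_occupancy(helix_traj)
    assert np.allclose(prof.probabilities.sum(axis=1), 1.0, atol=1e-9)
    assert np.all((prof.probabilities >= 0) & (prof.probabilities <= 1))


def test_ss_occupancy_of_mixture():
    """50/50 helix + extended frames give helix probability 0.5 exactly."""
    from idrctd.synthetic import _extended_trajectory, _helix_trajectory

    spec = ChainSpec(n_residues=15, model="ideal-helix", n_frames=1)
    helix = _helix_trajectory(spec)
    ext = _extended_trajectory(spec)
    mix = Trajectory(
        coords=np.concatenate([helix.coords, ext.coords]),
        res_ids=helix.res_ids,
        res_names=helix.res_names,
        atom_names=helix.atom_names,
        elements=helix.elements,
    )
    prof = ss_occupancy(mix)
    helix_col = prof.classes.index("helix")
    interior = prof.probabilities[2:-2, helix_col]
    assert np.allclose(interior, 0.5)


def test_pure_helix_occupancy_is_one(helix_traj):
    spec = ChainSpec(n_residues=15, model="ideal-helix", n_frames=3)
    traj = generate_chain_ensemble(spec)
    prof = ss_occupancy(traj)
    helix_col = prof.classes.index("helix")
    assert np.allclose(prof.probabilities[2:-2, helix_col], 1.0)
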