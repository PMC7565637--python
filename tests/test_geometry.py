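"""Axis fitting, rise/tilt/radial measurements and the H-bond census."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from deltafiber import geometry as geo
from deltafiber.geometry import Chain, PentamerModel, Residue
from deltafiber.synthetic_data import gen_pentamer_coords, write_pentamer_pdb


def angle_between(u, v):
    return math.degrees(math.acos(min(1.0, abs(float(np.dot(u, v))))))


def make_model(chains):
    return PentamerModel([Chain(cid, res) for cid, res in chains])


# ------------------------------------------------------------- structure IO


def test_pdb_round_trip(tmp_path, ideal_pentamer):
    model, truth = ideal_pentamer
    path = tmp_path / "pentamer.pdb"
    write_pentamer_pdb(model, path)
    loaded = geo.read_structure(path)
    assert [c.id for c in loaded.chains] == ["A", "B", "C", "D", "E"]
    assert [len(c.residues) for c in loaded.chains] == [40] * 5
    orig = model.all_atoms("ca")
    back = loaded.all_atoms("ca")
    assert np.allclose(orig, back, atol=1e-3)  # PDB stores 3 decimals


def test_extra_short_chain_is_dropped(tmp_path, ideal_pentamer):
    model, _ = ideal_pentamer
    path = tmp_path / "six_chains.pdb"
    write_pentamer_pdb(model, path)
    # append a sixth, two-residue peptide chain F
    extra = [Residue(1, "GLY", {"CA": np.array([30.0, 0.0, 0.0])}),
             Residue(2, "GLY", {"CA": np.array([33.0, 0.0, 0.0])})]
    six = model.chains + [Chain("F", extra)]
    st_model = PentamerModel.__new__(PentamerModel)  # bypass 5-chain check
    st_model.chains = six
    st_model.source = "six"
    st_model.missing_residues = {}
    write_pentamer_pdb(st_model, path)
    loaded = geo.read_structure(path)
    assert [c.id for c in loaded.chains] == ["A", "B", "C", "D", "E"]


def test_too_few_chains_reports_census(tmp_path, ideal_pentamer):
    model, _ = ideal_pentamer
    path = tmp_path / "three_chains.pdb"
    partial = PentamerModel.__new__(PentamerModel)
    partial.chains = model.chains[:3]
    partial.source = "partial"
    partial.missing_residues = {}
    write_pentamer_pdb(partial, path)
    with pytest.raises(ValueError, match="5 protein chains"):
        geo.read_structure(path)


def test_missing_residue_is_flagged(tmp_path, ideal_pentamer):
    model, _ = ideal_pentamer
    trimmed = model.transform(np.eye(3), np.zeros(3))
    del trimmed.chains[4].residues[-1]  # drop the last residue of chain E
    path = tmp_path / "gap.pdb"
    write_pentamer_pdb(trimmed, path)
    loaded = geo.read_structure(path)
    assert loaded.missing_residues == {"E": [40]}


# --------------------------------------------------------------- axis fitting


def test_ideal_c5_axis_is_z(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    assert angle_between(axis.direction, np.array([0.0, 0.0, 1.0])) < 0.1
    assert axis.rotation_angle == pytest.approx(72.0, abs=1e-6)
    assert axis.mean_rotation_error == pytest.approx(0.0, abs=1e-9)
    # the axis passes through x = y = 0
    perp = axis.point - axis.point[2] * axis.direction
    assert np.linalg.norm(perp[:2]) < 1e-6


def test_axis_equivariant_under_rigid_transform(ideal_pentamer):
    model, _ = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    rot = Rotation.random(random_state=7).as_matrix()
    shift = np.array([12.0, -8.0, 30.0])
    moved = model.transform(rot, shift)
    axis2 = geo.fit_cyclic_axis(moved)
    assert angle_between(axis2.direction, rot @ axis.direction) < 1e-6
    # the transformed original axis point must lie on the new axis
    p = rot @ axis.point + shift
    assert float(axis2.radial(p)[0]) < 1e-6


def test_noisy_axis_within_one_degree():
    model, _ = gen_pentamer_coords(5, 15, 45, 6, 9.5, noise_sd=0.2, seed=3)
    axis = geo.fit_cyclic_axis(model)
    assert angle_between(axis.direction, np.array([0.0, 0.0, 1.0])) < 1.0


def test_broken_symmetry_raises():
    model, _ = gen_pentamer_coords(3, 15, 45, 6, 9.5, seed=0)
    # rotate one chain 25° further about z: its pair angles become 97°/47°
    extra = Rotation.from_euler("z", 25, degrees=True).as_matrix()
    for res in model.chains[2].residues:
        res.atoms["CA"] = extra @ res.atoms["CA"]
    with pytest.raises(geo.SymmetryError, match="rotation angle"):
        geo.fit_cyclic_axis(model)


# ------------------------------------------------------------- rise and tilt


def test_rise_recovered_exactly(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    mean, sd, z = geo.rise_per_repeat(model, axis, truth["repeat_starts"])
    assert mean == pytest.approx(15.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)
    # five repeats at 15 Å rise span ~75 Å (four spacings + one unit height)
    assert (len(truth["repeat_starts"]) - 1) * mean + mean == pytest.approx(75.0)


def test_two_repeats_have_undefined_sd():
    model, truth = gen_pentamer_coords(2, 15, 45, 6, 9.5, seed=0)
    axis = geo.fit_cyclic_axis(model)
    mean, sd, _ = geo.rise_per_repeat(model, axis, truth["repeat_starts"])
    assert mean == pytest.approx(15.0, abs=1e-9)
    assert sd is None


def test_single_repeat_is_an_error():
    model, truth = gen_pentamer_coords(1, 15, 45, 6, 9.5, seed=0)
    axis = geo.AxisFrame(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                         order=5, rotation_angle=72.0, mean_rotation_error=0.0)
    with pytest.raises(ValueError, match="at least 2 repeats"):
        geo.rise_per_repeat(model, axis, truth["repeat_starts"])


def test_non_monotone_repeat_order_is_an_error(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    shuffled = [truth["repeat_starts"][i] for i in (0, 2, 1, 3, 4)]
    with pytest.raises(ValueError, match="monotone"):
        geo.rise_per_repeat(model, axis, shuffled)


@pytest.mark.parametrize("tilt", [0.0, 45.0, 90.0])
def test_strand_tilt_recovers_planted_angle(tilt):
    model, truth = gen_pentamer_coords(5, 15, tilt, 6, 9.5, seed=0)
    axis = geo.fit_cyclic_axis(model)
    mean, sd, skipped = geo.strand_tilt(model, axis, truth["strand_spans"])
    assert mean == pytest.approx(tilt, abs=3.0)
    assert skipped == 0


def test_degenerate_strand_span_is_skipped(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    # a 1-residue span has < 3 distinct points on every chain
    mean, sd, skipped = geo.strand_tilt(
        model, axis, truth["strand_spans"] + [(1, 1)])
    assert skipped == 5
    assert mean == pytest.approx(45.0, abs=3.0)


# ------------------------------------------------------------ radial profile


def test_radial_profile_strand_and_loop_radii(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    prof = geo.radial_profile(model, axis, bin_width=2.0, atoms="ca")
    # strand rings sit at exactly the planted radius: main-chain diameter 12 Å
    assert float(prof.mean_radius.min()) == pytest.approx(6.0, abs=1e-9)
    assert 2 * float(prof.mean_radius.min()) == pytest.approx(12.0)
    # loop rings bulge to the planted loop radius
    assert float(prof.mean_radius.max()) == pytest.approx(9.5, abs=1e-9)
    assert np.all(prof.min_radius <= prof.mean_radius + 1e-12)
    assert np.all(prof.mean_radius <= prof.max_radius + 1e-12)


def test_channel_radius_is_probe_adjusted_and_floored(ideal_pentamer):
    model, truth = ideal_pentamer
    axis = geo.fit_cyclic_axis(model)
    prof = geo.radial_profile(model, axis, bin_width=2.0, atoms="ca", probe=1.4)
    assert np.all(prof.channel_radius >= 0)
    assert float(prof.channel_radius.min()) == pytest.approx(6.0 - 1.4)
    big = geo.radial_profile(model, axis, bin_width=2.0, atoms="ca", probe=50.0)
    assert np.all(big.channel_radius == 0.0)


def test_degenerate_single_ring():
    # one flat ring of atoms: a single bin with min == max
    residues = lambda phi0: [
        Residue(i + 1, "ALA",
                {"CA": np.array([6 * math.cos(phi0), 6 * math.sin(phi0), 0.0]),
                 })
        for i in range(1)
    ]
    # build 5 chains of 2 residues each on two rings so the model is valid
    chains = []
    for c in range(5):
        phi = 2 * math.pi * c / 5
        chains.append(Chain("ABCDE"[c], [
            Residue(1, "ALA", {"CA": np.array([6 * math.cos(phi), 6 * math.sin(phi), 0.0])}),
            Residue(2, "ALA", {"CA": np.array([6 * math.cos(phi + 0.3), 6 * math.sin(phi + 0.3), 0.1])}),
        ]))
    model = PentamerModel(chains)
    axis = geo.AxisFrame(point=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                         order=5, rotation_angle=72.0, mean_rotation_error=0.0)
    prof = geo.radial_profile(model, axis, bin_width=5.0, atoms="ca")
    assert len(prof.mean_radius) == 1
    assert prof.min_radius[0] == pytest.approx(prof.max_radius[0])


# ------------------------------------------------------------- hydrogen bonds


def _two_residue_model(no_distance):
    """Five chains; chains A and B carry backbone atoms NO apart by design."""
    chains = []
    for c in range(5):
        x = 20.0 * c
        r1 = Residue(1, "ALA", {
            "CA": np.array([x, 0.0, 0.0]),
            "N": np.array([x - 1.2, 0.0, 0.0]),
            "C": np.array([x + 1.2, 0.0, 0.0]),
            "O": np.array([x + 1.2, 1.2, 0.0]),
        })
        r2 = Residue(2, "ALA", {
            "CA": np.array([x, 4.0, 0.0]),
            "N": np.array([x - 1.2, 4.0, 0.0]),
            "C": np.array([x + 1.2, 4.0, 0.0]),
            "O": np.array([x + 1.2, 5.2, 0.0]),
        })
        chains.append(Chain("ABCDE"[c], [r1, r2]))
    # place an acceptor O of chain B near the donor N of chain A residue 1
    chains[1].residues[0].atoms["O"] = (
        chains[0].residues[0].atoms["N"] + np.array([0.0, no_distance, 0.0]))
    return PentamerModel(chains)


def test_close_n_o_pair_is_one_interchain_bond():
    model = _two_residue_model(no_distance=2.9)
    bonds, counts, skipped = geo.mainchain_hbonds(model)
    inter = [b for b in bonds if b.interchain]
    assert len(inter) == 1
    assert inter[0].donor == ("A", 1)
    assert inter[0].acceptor == ("B", 1)
    assert inter[0].distance == pytest.approx(2.9)
    assert counts["A"]["B"] == 1


def test_distant_n_o_pair_is_no_bond():
    model = _two_residue_model(no_distance=5.0)
    bonds, _, _ = geo.mainchain_hbonds(model)
    assert [b for b in bonds if b.interchain] == []


def test_ca_only_model_fails_loudly(ideal_pentamer):
    model, _ = ideal_pentamer
    with pytest.raises(geo.CapabilityError, match="Cα-only"):
        geo.mainchain_hbonds(model)


def test_backbone_pentamer_census_is_deterministic():
    model, _ = gen_pentamer_coords(3, 15, 45, 6, 9.5, seed=1, backbone=True)
    b1 = geo.mainchain_hbonds(model)
    b2 = geo.mainchain_hbonds(model)
    assert len(b1[0]) == len(b2[0]) > 0


# ----------------------------------------------------------- inward residues


@pytest.mark.parametrize("direction, expected_frac", [("inward", 1.0),
                                                      ("outward", 0.0)])
def test_cb_orientation_labels(direction, expected_frac):
    model, truth = gen_pentamer_coords(2, 15, 45, 6, 9.5, seed=0,
                                       cb_direction=direction)
    axis = geo.fit_cyclic_axis(model)
    anchors = {s for lo, hi in truth["strand_spans"] for s in (lo, lo + 3)}
    labels, frac = geo.inward_facing_residues(model, axis,
                                              anchor_positions=anchors)
    assert frac == expected_frac
    assert set(labels.values()) == {direction}


def test_glycine_is_undetermined():
    model, _ = gen_pentamer_coords(2, 15, 45, 6, 9.5, seed=0,
                                   cb_direction="inward")
    for ch in model.chains:
        ch.residues[0].name = "GLY"
    axis = geo.fit_cyclic_axis(model)
    labels, _ = geo.inward_facing_residues(model, axis)
    assert all(labels[(c.id, 1)] == "undetermined" for c in model.chains)


# --------------------------------------------------- recovery property grid


@pytest.mark.parametrize("rise", [10.0, 15.0, 20.0])
@pytest.mark.parametrize("tilt", [30.0, 45.0, 60.0])
@pytest.mark.parametrize("radius", [5.0, 6.0, 8.0])
def test_parameter_recovery_under_noise(rise, tilt, radius):
    seed = int(rise * 100 + tilt * 10 + radius)
    model, truth = gen_pentamer_coords(5, rise, tilt, radius, radius + 3.5,
                                       noise_sd=0.3, seed=seed)
    axis = geo.fit_cyclic_axis(model)
    assert abs(axis.rotation_angle - 72.0) < 1.0
    mean_rise, _, _ = geo.rise_per_repeat(model, axis, truth["repeat_starts"])
    assert abs(mean_rise - rise) / rise < 0.05
    mean_tilt, _, _ = geo.strand_tilt(model, axis, truth["strand_spans"])
    assert abs(mean_tilt - tilt) < 3.0
    prof = geo.radial_profile(model, axis, bin_width=2.0, atoms="ca")
    assert abs(geo.strand_radius_estimate(prof) - radius) < 0.5
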