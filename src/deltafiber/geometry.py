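"""Quantitative geometry of pentameric fiber coordinates.

Operations take a :class:`PentamerModel` (five ordered chains of
residues with at least Cα coordinates) and measure the quantities used
to characterise a C5 fiber: the symmetry axis and its rotation angle,
axial rise per bracelet repeat, β-strand tilt relative to the axis,
radial/channel profiles, a geometric main-chain hydrogen-bond census,
and inward/outward labelling of side chains.

The axis is fitted from the rigid rotations superposing each chain onto
its cyclic neighbour, which directly certifies the 72° C5 angle and is
robust for short fibers.  All outputs are equivariant under rigid-body
transforms of the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import gemmi

__all__ = [
    "Residue",
    "Chain",
    "PentamerModel",
    "AxisFrame",
    "RadialProfile",
    "HBond",
    "SymmetryError",
    "CapabilityError",
    "read_structure",
    "fit_cyclic_axis",
    "rise_per_repeat",
    "strand_tilt",
    "radial_profile",
    "strand_radius_estimate",
    "mainchain_hbonds",
    "inward_facing_residues",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class SymmetryError(ValueError):
    """The fitted rotation angle is inconsistent with the requested order."""


class CapabilityError(ValueError):
    """The model lacks the atoms an operation needs (e.g. Cα-only input)."""


@dataclass
class Residue:
    index: int
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue]

    def residue_map(self) -> dict[int, Residue]:
        return {r.index: r for r in self.residues}

    def ca_coords(self, indices: list[int] | None = None) -> np.ndarray:
        rmap = self.residue_map()
        if indices is None:
            return np.array([r.ca for r in self.residues if r.ca is not None])
        return np.array([rmap[i].ca for i in indices])


@dataclass
class PentamerModel:
    chains: list[Chain]
    source: str = "<memory>"
    missing_residues: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chains) != 5:
            raise ValueError(f"PentamerModel requires exactly 5 chains, got {len(self.chains)}")
        for ch in self.chains:
            if len(ch.residues) < 2:
                raise ValueError(f"chain {ch.id} has fewer than 2 residues")
            for r in ch.residues:
                for coord in r.atoms.values():
                    if not np.all(np.isfinite(coord)):
                        raise ValueError(f"non-finite coordinate in chain {ch.id} residue {r.index}")

    def shared_ca_indices(self) -> list[int]:
        shared: set[int] | None = None
        for ch in self.chains:
            idx = {r.index for r in ch.residues if r.ca is not None}
            shared = idx if shared is None else shared & idx
        return sorted(shared or set())

    def all_atoms(self, selector: str = "all") -> np.ndarray:
        """Coordinates of selected atoms: 'all' | 'mainchain' | 'ca'."""
        sel = selector.lower()
        coords = []
        for ch in self.chains:
            for r in ch.residues:
                for name, xyz in r.atoms.items():
                    if sel == "ca" and name != "CA":
                        continue
                    if sel == "mainchain" and name not in BACKBONE_ATOMS:
                        continue
                    coords.append(xyz)
        return np.asarray(coords, dtype=float)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "PentamerModel":
        """A rigidly transformed copy (x -> R x + t)."""
        new_chains = []
        for ch in self.chains:
            residues = [Residue(r.index, r.name,
                                {a: rotation @ xyz + translation for a, xyz in r.atoms.items()})
                        for r in ch.residues]
            new_chains.append(Chain(ch.id, residues))
        return PentamerModel(new_chains, source=self.source,
                             missing_residues=dict(self.missing_residues))


@dataclass(frozen=True)
class AxisFrame:
    point: np.ndarray
    direction: np.ndarray  # unit vector
    order: int
    rotation_angle: float  # degrees, mean over cyclic pairs
    mean_rotation_error: float  # Å, mean Cα RMSD of pair superpositions

    def axial(self, coords: np.ndarray) -> np.ndarray:
        """Axial coordinate(s) of points, Å along the axis direction."""
        return np.atleast_2d(coords - self.point) @ self.direction

    def radial(self, coords: np.ndarray) -> np.ndarray:
        """Radial distance(s) of points from the axis, Å."""
        d = np.atleast_2d(coords) - self.point
        axial = d @ self.direction
        perp = d - np.outer(axial, self.direction)
        return np.linalg.norm(perp, axis=1)


@dataclass
class RadialProfile:
    z_lo: np.ndarray
    z_hi: np.ndarray
    n_atoms: np.ndarray
    mean_radius: np.ndarray
    min_radius: np.ndarray
    max_radius: np.ndarray
    channel_radius: np.ndarray
    probe: float
    atoms: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "z_lo": self.z_lo, "z_hi": self.z_hi, "n_atoms": self.n_atoms,
            "mean_radius": self.mean_radius, "min_radius": self.min_radius,
            "max_radius": self.max_radius, "channel_radius": self.channel_radius,
        })


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int]  # (chain, residue) of backbone N
    acceptor: tuple[str, int]  # (chain, residue) of backbone O
    distance: float
    interchain: bool


def read_structure(path: str | Path) -> PentamerModel:
    """Load the five largest protein chains of a PDB file.

    Waters and heteroatoms are ignored; gaps in residue numbering are
    recorded per chain as missing residues.  Fewer than five protein
    chains is an error reporting the chain census.
    """
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    st.setup_entities()
    st.remove_waters()
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        residues = []
        for gres in gch:
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = info.is_amino_acid() if info is not None else any(
                at.name == "CA" for at in gres)
            if not is_aa:
                continue
            atoms = {at.name: np.array([at.pos.x, at.pos.y, at.pos.z])
                     for at in gres}
            residues.append(Residue(gres.seqid.num, gres.name, atoms))
        if residues:
            chains.append(Chain(gch.name, residues))
    if len(chains) < 5:
        census = {ch.id: len(ch.residues) for ch in chains}
        raise ValueError(f"need >=5 protein chains, found {len(chains)}: {census}")
    chains.sort(key=lambda ch: (-len(ch.residues), ch.id))
    chains = sorted(chains[:5], key=lambda ch: ch.id)
    missing: dict[str, list[int]] = {}
    all_idx = set()
    for ch in chains:
        all_idx |= {r.index for r in ch.residues}
    lo, hi = min(all_idx), max(all_idx)
    for ch in chains:
        have = {r.index for r in ch.residues}
        gaps = [i for i in range(lo, hi + 1) if i not in have]
        if gaps:
            missing[ch.id] = gaps
    return PentamerModel(chains, source=str(path), missing_residues=missing)


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid transform (R, t) minimising |R p + t - q|; returns RMSD too."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(q - qc, p - pc)
    r = rot.as_matrix()
    t = qc - r @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((p @ r.T + t - q) ** 2, axis=1))))
    return r, t, rmsd


def fit_cyclic_axis(model: PentamerModel, order: int = 5,
                    angle_tol: float = 5.0) -> AxisFrame:
    """Fit the Cn symmetry axis from cyclic chain-to-chain superpositions.

    Each chain is superposed onto its cyclic successor over shared Cα
    positions; the rotation axes are averaged and each rotation angle
    must be within ``angle_tol`` degrees of 360/order.
    """
    shared = model.shared_ca_indices()
    if len(shared) < 10:
        raise ValueError(f"chains share only {len(shared)} Cα positions; need >= 10")
    n = len(model.chains)
    target = 360.0 / order
    dirs, points, angles, errors = [], [], [], []
    centroid = np.mean([ch.ca_coords(shared) for ch in model.chains], axis=(0, 1))
    for i in range(n):
        p = model.chains[i].ca_coords(shared)
        q = model.chains[(i + 1) % n].ca_coords(shared)
        r, t, rmsd = _kabsch(p, q)
        rotvec = Rotation.from_matrix(r).as_rotvec()
        angle = math.degrees(np.linalg.norm(rotvec))
        if abs(angle - target) > angle_tol:
            raise SymmetryError(
                f"pair {model.chains[i].id}->{model.chains[(i + 1) % n].id}: "
                f"rotation angle {angle:.2f}° is not within {angle_tol}° of {target:.2f}°")
        d = rotvec / np.linalg.norm(rotvec)
        if dirs and np.dot(d, dirs[0]) < 0:
            d = -d
        # point on the screw axis: (I - R) p = t_perp, solved in least squares
        t_perp = t - np.dot(d, t) * d
        p_axis, *_ = np.linalg.lstsq(np.eye(3) - r, t_perp, rcond=None)
        # slide the point to the foot of the global centroid for averaging
        p_axis = p_axis + np.dot(centroid - p_axis, d) * d
        dirs.append(d)
        points.append(p_axis)
        angles.append(angle)
        errors.append(rmsd)
    direction = np.mean(dirs, axis=0)
    direction /= np.linalg.norm(direction)
    return AxisFrame(point=np.mean(points, axis=0), direction=direction,
                     order=order, rotation_angle=float(np.mean(angles)),
                     mean_rotation_error=float(np.mean(errors)))


def rise_per_repeat(model: PentamerModel, axis: AxisFrame,
                    repeat_starts: list[int], repeat_len: int = 8
                    ) -> tuple[float, float | None, np.ndarray]:
    """Mean (± sd) axial spacing of consecutive repeat centroids, Å.

    Each repeat's centroid pools the Cα atoms of residues
    ``[start, start + repeat_len - 1]`` over all five chains.  The sd is
    None with a single spacing.  Repeats must be monotone along the axis.
    """
    if len(repeat_starts) < 2:
        raise ValueError("need at least 2 repeats to measure a rise")
    zs = []
    for start in repeat_starts:
        coords = []
        for ch in model.chains:
            rmap = ch.residue_map()
            for i in range(start, start + repeat_len):
                r = rmap.get(i)
                if r is not None and r.ca is not None:
                    coords.append(r.ca)
        if not coords:
            raise ValueError(f"repeat at {start}: no Cα atoms found")
        zs.append(float(axis.axial(np.mean(coords, axis=0))[0]))
    zs = np.array(zs)
    d = np.diff(zs)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"repeats are not monotone along the axis: z = {zs.round(2).tolist()}")
    spacings = np.abs(d)
    sd = float(np.std(spacings, ddof=1)) if len(spacings) > 1 else None
    return float(np.mean(spacings)), sd, zs


def strand_tilt(model: PentamerModel, axis: AxisFrame,
                strand_spans: list[tuple[int, int]]
                ) -> tuple[float, float | None, int]:
    """Mean (± sd) acute angle between β-strands and the fiber axis.

    Each span is evaluated on every chain: a principal line is fitted
    through the span's Cα atoms (SVD) and its acute angle to the axis
    taken.  Degenerate spans (< 3 distinct points) are skipped; the
    count of skips is returned.
    """
    angles = []
    skipped = 0
    for ch in model.chains:
        rmap = ch.residue_map()
        for lo, hi in strand_spans:
            coords = np.array([rmap[i].ca for i in range(lo, hi + 1)
                               if i in rmap and rmap[i].ca is not None])
            if len(np.unique(coords.round(6), axis=0)) < 3:
                skipped += 1
                continue
            centered = coords - coords.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            v = vt[0]
            cosang = abs(float(np.dot(v, axis.direction)))
            angles.append(math.degrees(math.acos(min(1.0, cosang))))
    if not angles:
        raise ValueError("no usable strands")
    sd = float(np.std(angles, ddof=1)) if len(angles) > 1 else None
    return float(np.mean(angles)), sd, skipped


def radial_profile(model: PentamerModel, axis: AxisFrame,
                   bin_width: float = 4.0, atoms: str = "ca",
                   probe: float = 1.4) -> RadialProfile:
    """Radius statistics in axial bins, plus a probe-adjusted channel radius.

    The channel radius per bin is the minimum atom-centre radius minus
    the probe allowance (default 1.4 Å), floored at 0.  Diameters are
    2 × radius; the ``atoms`` selector ('ca' | 'mainchain' | 'all')
    controls whether side chains are included.
    """
    coords = model.all_atoms(atoms)
    if coords.size == 0:
        raise ValueError(f"no atoms selected by {atoms!r}")
    z = axis.axial(coords)
    r = axis.radial(coords)
    z0 = math.floor(z.min() / bin_width) * bin_width
    nbins = max(1, math.ceil((z.max() - z0) / bin_width + 1e-9))
    idx = np.minimum(((z - z0) / bin_width).astype(int), nbins - 1)
    rows = []
    for b in range(nbins):
        rb = r[idx == b]
        if rb.size == 0:
            continue
        rows.append((z0 + b * bin_width, z0 + (b + 1) * bin_width, rb.size,
                     rb.mean(), rb.min(), rb.max(), max(rb.min() - probe, 0.0)))
    arr = np.array(rows)
    return RadialProfile(z_lo=arr[:, 0], z_hi=arr[:, 1],
                         n_atoms=arr[:, 2].astype(int),
                         mean_radius=arr[:, 3], min_radius=arr[:, 4],
                         max_radius=arr[:, 5], channel_radius=arr[:, 6],
                         probe=probe, atoms=atoms)


def strand_radius_estimate(profile: RadialProfile,
                           min_occupancy: float = 0.5) -> float:
    """Shaft (strand-ring) radius from a radial profile, Å.

    The smallest per-bin mean radius among well-populated bins (at
    least ``min_occupancy`` × the fullest bin).  Sparsely populated
    edge bins are excluded because their means are noise-dominated;
    strand rings are the densest, lowest-radius feature of a bracelet
    profile, so this estimator recovers the main-chain shaft radius.
    """
    mask = profile.n_atoms >= min_occupancy * profile.n_atoms.max()
    return float(profile.mean_radius[mask].min())


def mainchain_hbonds(model: PentamerModel, cutoff_dist: float = 3.5,
                     cutoff_angle: float = 120.0
                     ) -> tuple[list[HBond], dict[str, dict[str, int]], int]:
    """Geometric census of backbone N-H···O=C hydrogen bonds.

    A bond requires N···O distance ≤ ``cutoff_dist`` and, when the amide
    H position can be inferred from the preceding carbonyl C and the Cα,
    an N-H···O angle ≥ ``cutoff_angle``.  Residues lacking backbone N or
    O are skipped (their count is returned).  Returns the bond list, the
    per-chain interchain partner counts, and the skip count.
    """
    donors, acceptors = [], []
    skipped = 0
    for ch in model.chains:
        prev_c: np.ndarray | None = None
        prev_idx: int | None = None
        for res in ch.residues:
            n_at, o_at = res.atoms.get("N"), res.atoms.get("O")
            if n_at is None and o_at is None:
                skipped += 1
            if n_at is not None:
                h = None
                ca = res.atoms.get("CA")
                if (prev_c is not None and prev_idx == res.index - 1
                        and ca is not None):
                    u = n_at - prev_c
                    v = n_at - ca
                    bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
                    norm = np.linalg.norm(bis)
                    if norm > 1e-9:
                        h = n_at + bis / norm  # 1.0 Å N-H
                donors.append((ch.id, res.index, n_at, h))
            if o_at is not None:
                acceptors.append((ch.id, res.index, o_at))
            prev_c = res.atoms.get("C")
            prev_idx = res.index
    if not donors or not acceptors:
        raise CapabilityError("Cα-only model: H-bond census unavailable "
                              "(no backbone N/O atoms)")
    acc_tree = cKDTree(np.array([a[2] for a in acceptors]))
    bonds: list[HBond] = []
    counts: dict[str, dict[str, int]] = {ch.id: {} for ch in model.chains}
    for d_chain, d_idx, n_at, h in donors:
        for j in acc_tree.query_ball_point(n_at, cutoff_dist):
            a_chain, a_idx, o_at = acceptors[j]
            if a_chain == d_chain and abs(a_idx - d_idx) < 2:
                continue  # same or adjacent residue: not a census bond
            dist = float(np.linalg.norm(n_at - o_at))
            if h is not None:
                hn = n_at - h
                ho = o_at - h
                cosang = np.dot(hn, ho) / (np.linalg.norm(hn) * np.linalg.norm(ho))
                ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if ang < cutoff_angle:
                    continue
            inter = a_chain != d_chain
            bonds.append(HBond(donor=(d_chain, d_idx), acceptor=(a_chain, a_idx),
                               distance=dist, interchain=inter))
            if inter:
                counts[d_chain][a_chain] = counts[d_chain].get(a_chain, 0) + 1
                counts[a_chain][d_chain] = counts[a_chain].get(d_chain, 0) + 1
    return bonds, counts, skipped


def _pseudo_cb(res: Residue) -> np.ndarray | None:
    n_at, ca, c_at = res.atoms.get("N"), res.atoms.get("CA"), res.atoms.get("C")
    if n_at is None or ca is None or c_at is None:
        return None
    v1 = n_at - ca
    v2 = c_at - ca
    bis = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
    norm = np.linalg.norm(bis)
    if norm < 1e-9:
        return None
    # approximate tetrahedral Cβ direction: opposite the N/C bisector
    return ca - 1.53 * bis / norm


def inward_facing_residues(model: PentamerModel, axis: AxisFrame,
                           threshold: float = 0.0,
                           anchor_positions: set[int] | None = None
                           ) -> tuple[dict[tuple[str, int], str], float | None]:
    """Label residues inward/outward by the radial component of Cα→Cβ.

    A residue is inward when the Cα→Cβ vector's component along the
    outward radial direction falls below ``threshold`` (i.e. the side
    chain points toward the axis).  Glycine, and residues where no Cβ
    exists and none can be constructed from the backbone, are labelled
    'undetermined'.  When ``anchor_positions`` (residue indices) is
    given, the fraction of determined anchors labelled inward is
    returned as well.
    """
    labels: dict[tuple[str, int], str] = {}
    for ch in model.chains:
        for res in ch.residues:
            ca = res.ca
            if ca is None:
                continue
            if res.name == "GLY":
                labels[(ch.id, res.index)] = "undetermined"
                continue
            cb = res.atoms.get("CB")
            if cb is None:
                cb = _pseudo_cb(res)
            if cb is None:
                labels[(ch.id, res.index)] = "undetermined"
                continue
            rel = ca - axis.point
            axial = np.dot(rel, axis.direction)
            radial = rel - axial * axis.direction
            norm = np.linalg.norm(radial)
            if norm < 1e-9:
                labels[(ch.id, res.index)] = "undetermined"
                continue
            comp = float(np.dot(cb - ca, radial / norm))
            labels[(ch.id, res.index)] = "inward" if comp < threshold else "outward"
    frac = None
    if anchor_positions:
        det = [(k, v) for k, v in labels.items()
               if k[1] in anchor_positions and v != "undetermined"]
        if det:
            frac = sum(v == "inward" for _, v in det) / len(det)
    return labels, frac
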