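"""Structure-derived residue features from heavy-atom coordinates.

All descriptors are computed directly from coordinates with published
definitions:

* **ASA / RASA** — Shrake-Rupley solvent-accessible surface area with a
  deterministic golden-spiral quadrature (probe 1.4 A), relative ASA
  normalized by theoretical Gly-X-Gly maxima.
* **DPX** (depth index) — for a buried atom, the Euclidean distance to the
  nearest solvent-accessible atom; zero for accessible atoms.
* **CX** (protrusion index) — ratio of empty to occupied volume in a 10 A
  sphere around each atom, assuming a mean heavy-atom volume of 20.1 A^3.
* **Secondary structure** — Kabsch-Sander hydrogen-bond energies with the
  amide hydrogen rebuilt from the preceding carbonyl, collapsed to three
  states (helix / strand / coil).
* **HSE** (half-sphere exposure) — CA-neighbor counts split by the
  CA->CB direction within a 13 A sphere.

Per-residue aggregation of the atomic descriptors uses mean and max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import ComplexRecord, Residue

#: van der Waals radii (A) by element; unlisted elements fall back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

#: Theoretical maximum ASA (A^2) in a Gly-X-Gly tripeptide (Tien et al. scale).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
_MEAN_MAX_ASA = float(np.mean(list(MAX_ASA.values())))

GEOMETRY_BLOCK_WIDTH = 11


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform point set on the unit sphere.

    Built as a golden-spiral hemisphere plus its antipodes, so the set is
    inversion-symmetric: mirror-image atom configurations receive exactly
    mirrored quadrature and therefore exactly equal areas.
    """
    m = (n + 1) // 2
    i = np.arange(m, dtype=float)
    z = 1.0 - (i + 0.5) / m
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    upper = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return np.vstack([upper, -upper])[:2 * m]


def _canonical_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame of an atom cloud.

    Axis signs are fixed by third moments, so the frame co-rotates with the
    molecule; anchoring the quadrature point set to it makes ASA invariant
    under rigid motions to numerical precision (a lab-fixed point set would
    only be invariant to the quadrature resolution).  Degenerate clouds
    (symmetric or < 3 atoms) fall back gracefully.
    """
    if len(coords) < 3:
        return np.eye(3)
    x = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(x.T @ x)
    vecs = vecs[:, ::-1].copy()
    for k in range(3):
        if ((x @ vecs[:, k]) ** 3).sum() < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


def atom_asa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley).

    A golden-spiral point set of size ``n_points`` is placed on each atom's
    expanded sphere (vdW radius + probe); points falling inside any other
    expanded sphere are occluded, and ASA is the surviving fraction of the
    expanded-sphere area.  The point set is oriented in the molecule's
    canonical frame (see :func:`_canonical_axes`).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe
    sphere = golden_spiral_points(n_points) @ _canonical_axes(coords).T
    n_pts = len(sphere)
    tree = cKDTree(coords)
    max_r = radii.max()
    asa = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        exposed = np.ones(n_pts, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        asa[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_pts
    return asa


def residue_asa_rasa(
    residues: list[Residue], per_atom_asa: dict[int, float] | np.ndarray,
    atom_owner: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate atomic ASA into per-residue (ASA, RASA).

    ``per_atom_asa`` is the flat ASA array over the concatenated atoms of
    ``residues`` (in order).  RASA divides by the residue type's maximum
    ASA (mean of the table for unknown letters); clipped below at 0, not
    clipped above.
    """
    flat = np.asarray(per_atom_asa, dtype=float)
    asa = np.zeros(len(residues))
    k = 0
    for idx, res in enumerate(residues):
        n_at = len(res.atoms)
        asa[idx] = flat[k:k + n_at].sum()
        k += n_at
    rasa = np.array([
        max(a / MAX_ASA.get(r.aa, _MEAN_MAX_ASA), 0.0)
        for a, r in zip(asa, residues)
    ])
    return asa, rasa


def dpx(coords: np.ndarray, per_atom_asa: np.ndarray) -> np.ndarray:
    """Per-atom depth: 0 for solvent-accessible atoms (ASA > 0), else the
    distance to the nearest accessible atom.  All-buried degenerate inputs
    yield zeros."""
    coords = np.asarray(coords, dtype=float)
    accessible = np.asarray(per_atom_asa) > 0.0
    depths = np.zeros(len(coords))
    if not accessible.any() or accessible.all():
        return depths
    tree = cKDTree(coords[accessible])
    buried = ~accessible
    depths[buried], _ = tree.query(coords[buried])
    return depths


def cx(
    coords: np.ndarray,
    sphere_radius: float = 10.0,
    atom_volume: float = 20.1,
) -> np.ndarray:
    """Per-atom protrusion index.

    The sphere of radius ``sphere_radius`` around each atom is split into
    occupied volume (heavy-atom count within the sphere, the atom itself
    included, times ``atom_volume``) and the remainder;
    CX = max(V_ext / V_int, 0).
    """
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    counts = np.array([
        len(tree.query_ball_point(c, sphere_radius)) for c in coords
    ])
    v_int = counts * atom_volume
    v_sphere = 4.0 / 3.0 * np.pi * sphere_radius ** 3
    return np.maximum((v_sphere - v_int) / v_int, 0.0)


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander, 3-state collapse)

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_PEPTIDE_BOND_MAX = 2.5   # A, C(i-1)-N(i) continuity check


def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    out = {}
    for name in ("N", "CA", "C", "O"):
        atom = res.atom(name)
        if atom is None:
            return None
        out[name] = atom.coords
    return out


def _hbond_energy(donor_n, donor_h, acc_c, acc_o) -> float:
    def inv(a, b):
        d = float(np.linalg.norm(a - b))
        return 1.0 / max(d, 0.5)
    return 0.084 * 332.0 * (
        inv(acc_o, donor_n) + inv(acc_c, donor_h)
        - inv(acc_o, donor_h) - inv(acc_c, donor_n)
    )


def secondary_structure(residues: list[Residue]) -> list[str]:
    """Assign H (helix), E (strand) or C (coil) to each residue of a chain.

    Hydrogen bonds follow the Kabsch-Sander electrostatic model with the
    amide H rebuilt 1 A from N opposite the preceding carbonyl; i->i+4
    bonded runs give helix, bridge patterns give strand, and the 8-state
    vocabulary is collapsed (310/alpha/pi -> H, bridge/extended -> E,
    rest -> C).  Residues with incomplete backbone default to coil.
    """
    n = len(residues)
    states = ["C"] * n
    bb = [_backbone(r) if r.resolved else None for r in residues]

    # amide hydrogen from the previous residue's carbonyl direction
    hpos: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if bb[i] is None or bb[i - 1] is None:
            continue
        if np.linalg.norm(bb[i]["N"] - bb[i - 1]["C"]) > _PEPTIDE_BOND_MAX:
            continue
        co = bb[i - 1]["C"] - bb[i - 1]["O"]
        norm = np.linalg.norm(co)
        if norm == 0:
            continue
        hpos[i] = bb[i]["N"] + co / norm

    def hbond(donor: int, acceptor: int) -> bool:
        if not (0 <= donor < n and 0 <= acceptor < n):
            return False
        if abs(donor - acceptor) < 2:
            return False
        if hpos[donor] is None or bb[donor] is None or bb[acceptor] is None:
            return False
        e = _hbond_energy(bb[donor]["N"], hpos[donor],
                          bb[acceptor]["C"], bb[acceptor]["O"])
        return e < _HB_ENERGY_CUTOFF

    # helices: consecutive i -> i+4 turns
    turn4 = [hbond(i + 4, i) for i in range(n)]
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                states[k] = "H"
    # 3-10 helices (i -> i+3 turns) also collapse to H
    turn3 = [hbond(i + 3, i) for i in range(n)]
    for i in range(n - 1):
        if turn3[i] and turn3[i + 1]:
            for k in range(i + 1, min(i + 4, n)):
                if states[k] == "C":
                    states[k] = "H"

    # beta bridges (parallel and antiparallel), lower priority than helix
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (hbond(j, i - 1) and hbond(i + 1, j)) or \
                       (hbond(i, j - 1) and hbond(j + 1, i))
            anti = (hbond(i, j) and hbond(j, i)) or \
                   (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))
            if parallel or anti:
                if states[i] == "C":
                    states[i] = "E"
                if states[j] == "C":
                    states[j] = "E"
    return states


SS_STATES = ["H", "E", "C"]


def ss_onehot(state: str) -> np.ndarray:
    vec = np.zeros(3)
    vec[SS_STATES.index(state)] = 1.0
    return vec


# ---------------------------------------------------------------------------
# Half-sphere exposure


def half_sphere_exposure(
    residues: list[Residue], radius: float = 13.0
) -> np.ndarray:
    """(hse_up, hse_down) per residue: CA neighbors within ``radius``
    split by the sign of their projection on the CA->CB direction.

    When CB is absent a pseudo-CB direction is built from the flanking CA
    positions (negated sum of unit vectors toward CA(i-1) and CA(i+1));
    with no usable direction all neighbors count as "up".
    """
    ca = []
    for r in residues:
        atom = r.atom("CA")
        ca.append(atom.coords if atom is not None else None)

    def cb_direction(i: int) -> np.ndarray | None:
        res = residues[i]
        cb = res.atom("CB")
        if cb is not None and ca[i] is not None:
            v = cb.coords - ca[i]
            norm = np.linalg.norm(v)
            return v / norm if norm > 0 else None
        if ca[i] is None:
            return None
        acc = np.zeros(3)
        for j in (i - 1, i + 1):
            if 0 <= j < len(residues) and ca[j] is not None:
                v = ca[j] - ca[i]
                norm = np.linalg.norm(v)
                if norm > 0:
                    acc += v / norm
        norm = np.linalg.norm(acc)
        return -acc / norm if norm > 0 else None

    out = np.zeros((len(residues), 2))
    valid = [(i, c) for i, c in enumerate(ca) if c is not None]
    if not valid:
        return out
    coords = np.array([c for _, c in valid])
    tree = cKDTree(coords)
    for i, c in enumerate(ca):
        if c is None:
            continue
        direction = cb_direction(i)
        up = down = 0
        for k in tree.query_ball_point(c, radius):
            j = valid[k][0]
            if j == i:
                continue
            if direction is None or np.dot(coords[k] - c, direction) >= 0:
                up += 1
            else:
                down += 1
        out[i] = (up, down)
    return out


# ---------------------------------------------------------------------------
# Per-complex assembly


@dataclass
class GeometricFeatureBlock:
    asa: float
    rasa: float
    dpx_mean: float
    dpx_max: float
    cx_mean: float
    cx_max: float
    ss_onehot: np.ndarray  # 3
    hse_up: float
    hse_down: float

    def to_array(self) -> np.ndarray:
        return np.concatenate([
            [self.asa, self.rasa, self.dpx_mean, self.dpx_max,
             self.cx_mean, self.cx_max],
            self.ss_onehot,
            [self.hse_up, self.hse_down],
        ])


def geometry_feature_names() -> list[str]:
    return ["asa", "rasa", "dpx_mean", "dpx_max", "cx_mean", "cx_max",
            "ss_H", "ss_E", "ss_C", "hse_up", "hse_down"]


@dataclass
class GeometryConfig:
    probe: float = 1.4
    n_points: int = 960
    cx_radius: float = 10.0
    cx_atom_volume: float = 20.1
    hse_radius: float = 13.0
    unbound: bool = False  # compute burial per partner instead of bound state


def complex_geometry(
    record: ComplexRecord, config: GeometryConfig | None = None
) -> dict[tuple[str, int], GeometricFeatureBlock]:
    """Compute the geometric block for every resolved residue of a complex.

    By default ASA/DPX/CX see the bound complex (both partners present);
    with ``config.unbound`` each partner is treated in isolation.
    Secondary structure is per chain; HSE is per partner.
    """
    config = config or GeometryConfig()
    blocks: dict[tuple[str, int], GeometricFeatureBlock] = {}

    if config.unbound:
        groups = [record.partner_residues("receptor"),
                  record.partner_residues("ligand")]
    else:
        groups = [record.partner_residues("receptor")
                  + record.partner_residues("ligand")]

    per_res_atomic: dict[tuple[str, int], dict[str, float]] = {}
    for residues in groups:
        if not residues:
            continue
        coords = np.vstack([r.coord_matrix() for r in residues])
        elements = [a.element for r in residues for a in r.atoms]
        owner = np.concatenate([
            np.full(len(r.atoms), idx) for idx, r in enumerate(residues)
        ])
        aasa = atom_asa(coords, elements, config.probe, config.n_points)
        adpx = dpx(coords, aasa)
        acx = cx(coords, config.cx_radius, config.cx_atom_volume)
        res_asa, res_rasa = residue_asa_rasa(residues, aasa)
        for idx, res in enumerate(residues):
            sel = owner == idx
            per_res_atomic[(res.chain_id, res.struct_index)] = dict(
                asa=float(res_asa[idx]), rasa=float(res_rasa[idx]),
                dpx_mean=float(adpx[sel].mean()), dpx_max=float(adpx[sel].max()),
                cx_mean=float(acx[sel].mean()), cx_max=float(acx[sel].max()),
            )

    for side in ("receptor", "ligand"):
        residues = record.partner_residues(side)
        if not residues:
            continue
        hse = half_sphere_exposure(residues, config.hse_radius)
        hse_map = {
            (r.chain_id, r.struct_index): hse[i]
            for i, r in enumerate(residues)
        }
        chains = record.receptor_chains if side == "receptor" \
            else record.ligand_chains
        for chain in chains:
            resolved = chain.resolved_residues
            states = secondary_structure(resolved)
            for res, state in zip(resolved, states):
                key = (res.chain_id, res.struct_index)
                atomic = per_res_atomic[key]
                up, down = hse_map[key]
                blocks[key] = GeometricFeatureBlock(
                    ss_onehot=ss_onehot(state),
                    hse_up=float(up), hse_down=float(down),
                    **atomic,
                )
    return blocks
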