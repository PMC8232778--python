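"""Neighbor-based features and residue/pair vector assembly.

Each residue is first described by a *primitive* block: 55 sequence values
(physicochemical scales, PSSM/PSFM rows, conservation) plus 11 geometric
values (ASA, RASA, DPX, CX, secondary structure, HSE).  On top of the
primitives, two neighborhood summaries are added:

* sequence neighbors — the residues inside a +/-4 window on the full
  sequence (center excluded, truncated at the termini);
* structure neighbors — up to the 10 nearest residues of the *same*
  partner protein whose CA lies within 10 A (cross-partner neighbors are
  deliberately excluded so features stay computable for unbound partners).

Each neighborhood contributes the element-wise minimum, maximum, mean and
sum of the neighbors' primitive blocks plus one mask flag that marks an
empty neighborhood.  A residue pair is represented receptor-first as the
concatenation of the two residue vectors.

The four feature families (sequence, structure, sequence-neighbor,
structure-neighbor) can be toggled independently for ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ToggleMismatch
from .seqfeat import (
    SEQUENCE_BLOCK_WIDTH,
    pseudo_profile,
    sequence_feature_block,
    sequence_feature_names,
)
from .structfeat import (
    GEOMETRY_BLOCK_WIDTH,
    GeometryConfig,
    complex_geometry,
    geometry_feature_names,
)
from .structio import ComplexRecord, ProfileMatrix, Residue

PRIMITIVE_WIDTH = SEQUENCE_BLOCK_WIDTH + GEOMETRY_BLOCK_WIDTH  # 66


@dataclass(frozen=True)
class FeatureToggles:
    """Feature-family switches (ablation support)."""

    sequence: bool = True
    structure: bool = True
    seq_neighbor: bool = True
    struct_neighbor: bool = True

    def __post_init__(self) -> None:
        if not any([self.sequence, self.structure,
                    self.seq_neighbor, self.struct_neighbor]):
            raise ValueError("at least one feature family must be enabled")

    @classmethod
    def only(cls, family: str) -> "FeatureToggles":
        return cls(**{
            f: (f == family)
            for f in ("sequence", "structure", "seq_neighbor", "struct_neighbor")
        })


@dataclass
class ResidueFeatureVector:
    values: np.ndarray
    toggles: FeatureToggles


@dataclass
class PairFeatureVector:
    values: np.ndarray
    toggles: FeatureToggles


# ---------------------------------------------------------------------------
# Neighborhood index construction


def sequence_neighbor_indices(
    center: int, length: int, half_width: int = 4
) -> list[int]:
    """Window indices around ``center`` (exclusive), truncated at termini."""
    if not 0 <= center < length:
        raise IndexError(f"center {center} outside [0, {length})")
    lo = max(0, center - half_width)
    hi = min(length - 1, center + half_width)
    return [i for i in range(lo, hi + 1) if i != center]


def structure_neighbor_indices(
    center: int,
    ca_coords: np.ndarray,
    k: int = 10,
    cutoff: float = 10.0,
) -> list[int]:
    """Indices of the nearest ``k`` residues with CA-CA distance < cutoff.

    ``ca_coords`` holds one CA coordinate per residue of the same protein
    (rows of NaN mark residues without CA, which never qualify).  Exact
    distance ties are broken toward the lower index.
    """
    ca_coords = np.asarray(ca_coords, dtype=float)
    center_ca = ca_coords[center]
    if np.isnan(center_ca).any():
        return []
    d = np.linalg.norm(ca_coords - center_ca, axis=1)
    candidates = [
        (d[i], i) for i in range(len(ca_coords))
        if i != center and not np.isnan(d[i]) and d[i] < cutoff
    ]
    candidates.sort()
    return [i for _, i in candidates[:k]]


def aggregate(values) -> tuple[float, float, float, float, bool]:
    """(min, max, mean, sum) of a value list; zeros + mask flag when empty."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (0.0, 0.0, 0.0, 0.0, True)
    return (float(arr.min()), float(arr.max()),
            float(arr.mean()), float(arr.sum()), False)


def _aggregate_rows(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Column-wise (min ‖ max ‖ mean ‖ sum) over neighbor rows, plus an
    empty-neighborhood mask value."""
    if matrix.shape[0] == 0:
        return np.zeros(4 * matrix.shape[1]), 1.0
    return np.concatenate([
        matrix.min(axis=0), matrix.max(axis=0),
        matrix.mean(axis=0), matrix.sum(axis=0),
    ]), 0.0


# ---------------------------------------------------------------------------
# Column schema


def primitive_feature_names() -> list[str]:
    return ([f"seq/{n}" for n in sequence_feature_names()]
            + [f"geom/{n}" for n in geometry_feature_names()])


def feature_columns(toggles: FeatureToggles = FeatureToggles()) -> list[str]:
    """Ordered residue-vector column names under the given toggles."""
    prim = primitive_feature_names()
    bare = [n.split("/", 1)[1] for n in prim]
    cols: list[str] = []
    if toggles.sequence:
        cols += prim[:SEQUENCE_BLOCK_WIDTH]
    if toggles.structure:
        cols += prim[SEQUENCE_BLOCK_WIDTH:]
    for family, on in (("nbrseq", toggles.seq_neighbor),
                       ("nbrstruct", toggles.struct_neighbor)):
        if on:
            for stat in ("min", "max", "mean", "sum"):
                cols += [f"{family}/{stat}_{n}" for n in bare]
            cols.append(f"{family}/empty_mask")
    return cols


def toggle_column_mask(toggles: FeatureToggles) -> np.ndarray:
    """Boolean mask selecting ``toggles``' columns out of the all-on layout."""
    all_cols = feature_columns(FeatureToggles())
    keep_prefixes = []
    if toggles.sequence:
        keep_prefixes.append("seq/")
    if toggles.structure:
        keep_prefixes.append("geom/")
    if toggles.seq_neighbor:
        keep_prefixes.append("nbrseq/")
    if toggles.struct_neighbor:
        keep_prefixes.append("nbrstruct/")
    return np.array([
        any(c.startswith(p) for p in keep_prefixes) for c in all_cols
    ])


def residue_vector_width(toggles: FeatureToggles = FeatureToggles()) -> int:
    return len(feature_columns(toggles))


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class NeighborConfig:
    half_width: int = 4       # sequence window half-width (window length 9)
    k_struct: int = 10        # max structural neighbors
    struct_cutoff: float = 10.0  # A, CA-CA


def _chain_profiles(
    record: ComplexRecord, profiles: dict[str, ProfileMatrix] | None
) -> dict[str, ProfileMatrix]:
    out = {}
    for chain in record.chains:
        prof = (profiles or {}).get(chain.chain_id)
        out[chain.chain_id] = prof if prof is not None \
            else pseudo_profile(chain.full_sequence)
    return out


def partner_residue_matrix(
    record: ComplexRecord,
    side: str,
    profiles: dict[str, ProfileMatrix] | None = None,
    toggles: FeatureToggles = FeatureToggles(),
    neighbor_config: NeighborConfig | None = None,
    geometry_blocks=None,
    geometry_config: GeometryConfig | None = None,
) -> tuple[np.ndarray, list[Residue]]:
    """Residue feature matrix for one partner ('receptor'/'ligand').

    Returns ``(matrix, residues)`` with one row per resolved residue.  The
    full all-family layout is always computed; the requested toggles are
    applied as a final column selection so ablation never changes the
    underlying values.
    """
    ncfg = neighbor_config or NeighborConfig()
    residues = record.partner_residues(side)
    if not residues:
        return np.zeros((0, residue_vector_width(toggles))), []
    if geometry_blocks is None:
        geometry_blocks = complex_geometry(record, geometry_config)
    chain_prof = _chain_profiles(record, profiles)
    chain_by_id = {c.chain_id: c for c in record.chains}

    # primitive block per residue
    prim = np.zeros((len(residues), PRIMITIVE_WIDTH))
    for i, res in enumerate(residues):
        chain = chain_by_id[res.chain_id]
        seq_block = sequence_feature_block(
            chain, chain_prof[res.chain_id], res.seq_position
        ).to_array()
        geom_block = geometry_blocks[(res.chain_id, res.struct_index)].to_array()
        prim[i] = np.concatenate([seq_block, geom_block])

    # sequence neighborhoods: resolved residues of the same chain, indexed
    # by full-sequence position
    by_chain_pos = {
        (r.chain_id, r.seq_position): i for i, r in enumerate(residues)
    }
    ca = np.full((len(residues), 3), np.nan)
    for i, r in enumerate(residues):
        atom = r.atom("CA")
        if atom is not None:
            ca[i] = atom.coords

    agg_width = 4 * PRIMITIVE_WIDTH + 1
    nbr_seq = np.zeros((len(residues), agg_width))
    nbr_struct = np.zeros((len(residues), agg_width))
    for i, res in enumerate(residues):
        chain = chain_by_id[res.chain_id]
        window = sequence_neighbor_indices(
            res.seq_position, len(chain.full_sequence), ncfg.half_width
        )
        rows = [by_chain_pos[(res.chain_id, p)] for p in window
                if (res.chain_id, p) in by_chain_pos]
        agg, mask = _aggregate_rows(prim[rows])
        nbr_seq[i] = np.concatenate([agg, [mask]])

        srows = structure_neighbor_indices(
            i, ca, ncfg.k_struct, ncfg.struct_cutoff
        )
        agg, mask = _aggregate_rows(prim[srows])
        nbr_struct[i] = np.concatenate([agg, [mask]])

    full = np.hstack([prim, nbr_seq, nbr_struct])
    return full[:, toggle_column_mask(toggles)], residues


def assemble_pair_vector(
    v_receptor: ResidueFeatureVector,
    v_ligand: ResidueFeatureVector,
) -> PairFeatureVector:
    """Concatenate two residue vectors, receptor first."""
    if v_receptor.toggles != v_ligand.toggles:
        raise ToggleMismatch(
            f"{v_receptor.toggles} != {v_ligand.toggles}"
        )
    return PairFeatureVector(
        values=np.concatenate([v_receptor.values, v_ligand.values]),
        toggles=v_receptor.toggles,
    )


def pair_columns(toggles: FeatureToggles = FeatureToggles()) -> list[str]:
    cols = feature_columns(toggles)
    return [f"receptor/{c}" for c in cols] + [f"ligand/{c}" for c in cols]
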