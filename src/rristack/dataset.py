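"""Pair enumeration and labeling, training-complex filtering, undersampling.

A residue pair (receptor residue, ligand residue) is *interacting* when at
least one of its heavy-atom cross distances is <= 6.0 A.  Training pools
are filtered by structural similarity to the test complex (a Q-score-style
metric over sequence-seeded CA superpositions; complexes scoring below 0.05
are dropped), and the overwhelming noninteracting majority is undersampled
to a fixed negatives-per-positive ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from scipy.spatial import cKDTree

from .errors import NoPositives
from .neighbors import (
    FeatureToggles,
    NeighborConfig,
    feature_columns,
    partner_residue_matrix,
    toggle_column_mask,
)
from .structfeat import GeometryConfig, complex_geometry
from .structio import ComplexRecord, ProfileMatrix, Residue

INTERACTION_CUTOFF = 6.0  # A, heavy-atom pair distance (inclusive)


# ---------------------------------------------------------------------------
# Labeling


@dataclass
class PairInstance:
    complex_id: str
    receptor_residue: Residue
    ligand_residue: Residue
    label: bool
    features: np.ndarray | None = None


def interaction_matrix(
    record: ComplexRecord, cutoff: float = INTERACTION_CUTOFF
) -> np.ndarray:
    """Boolean (n_receptor, n_ligand) matrix over resolved residues.

    Entry (i, j) is True iff some heavy-atom pair between the residues is
    within ``cutoff`` (inclusive).
    """
    rec = record.partner_residues("receptor")
    lig = record.partner_residues("ligand")
    labels = np.zeros((len(rec), len(lig)), dtype=bool)
    if not rec or not lig:
        return labels
    r_coords = np.vstack([r.coord_matrix() for r in rec])
    l_coords = np.vstack([r.coord_matrix() for r in lig])
    r_owner = np.concatenate([
        np.full(len(r.atoms), i) for i, r in enumerate(rec)
    ])
    l_owner = np.concatenate([
        np.full(len(r.atoms), j) for j, r in enumerate(lig)
    ])
    r_tree, l_tree = cKDTree(r_coords), cKDTree(l_coords)
    for a, hits in enumerate(r_tree.query_ball_tree(l_tree, cutoff)):
        if hits:
            labels[r_owner[a], l_owner[hits]] = True
    return labels


def label_pairs(
    record: ComplexRecord, cutoff: float = INTERACTION_CUTOFF
) -> list[PairInstance]:
    """Enumerate and label every resolved receptor x ligand residue pair."""
    rec = record.partner_residues("receptor")
    lig = record.partner_residues("ligand")
    labels = interaction_matrix(record, cutoff)
    return [
        PairInstance(record.complex_id, r, l, bool(labels[i, j]))
        for i, r in enumerate(rec)
        for j, l in enumerate(lig)
    ]


# ---------------------------------------------------------------------------
# Complex similarity (Q-score style) and filtering

_Q_R0 = 3.0  # A


def _chain_ca(chain) -> tuple[str, np.ndarray]:
    letters, coords = [], []
    for res in chain.resolved_residues:
        atom = res.atom("CA")
        if atom is not None:
            letters.append(res.aa)
            coords.append(atom.coords)
    return "".join(letters), np.array(coords, dtype=float)


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal least-squares superposition of q onto p."""
    pc, qc = p - p.mean(axis=0), q - q.mean(axis=0)
    h = qc.T @ pc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = qc @ rot - pc
    return float(np.sqrt((diff ** 2).sum() / len(p)))


def _chain_pair_q(sa: str, ca_a: np.ndarray, sb: str, ca_b: np.ndarray) -> float:
    if len(sa) < 3 or len(sb) < 3:
        return 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    alignment = aligner.align(sa, sb)[0]
    ia, ib = [], []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    if len(ia) < 3:
        return 0.0
    rmsd = _kabsch_rmsd(ca_a[ia], ca_b[ib])
    n_align = len(ia)
    q = n_align ** 2 / ((1.0 + (rmsd / _Q_R0) ** 2) * len(sa) * len(sb))
    return float(min(q, 1.0))


def complex_similarity(a: ComplexRecord, b: ComplexRecord) -> float:
    """Structural similarity of two complexes in [0, 1].

    Each chain of one complex is matched to its best-scoring chain of the
    other under a Q-score-style metric (sequence-seeded correspondence,
    least-squares CA superposition, Q = N_align^2 / ((1 + (RMSD/3)^2)
    N_a N_b)); the score is the length-weighted mean of per-chain bests,
    symmetrized by taking the larger direction.  Identical or rigidly
    moved copies score 1; complexes with no alignable chain pair score 0.
    """
    chains_a = [_chain_ca(c) for c in a.chains]
    chains_b = [_chain_ca(c) for c in b.chains]
    chains_a = [(s, c) for s, c in chains_a if len(s) >= 3]
    chains_b = [(s, c) for s, c in chains_b if len(s) >= 3]
    if not chains_a or not chains_b:
        return 0.0

    def directed(src, dst) -> float:
        total_w = total = 0.0
        for s_src, ca_src in src:
            best = max(
                _chain_pair_q(s_src, ca_src, s_dst, ca_dst)
                for s_dst, ca_dst in dst
            )
            total += len(s_src) * best
            total_w += len(s_src)
        return total / total_w

    return max(directed(chains_a, chains_b), directed(chains_b, chains_a))


@dataclass
class FilterReport:
    test_complex_id: str
    scores: dict[str, float]
    kept: dict[str, bool]
    threshold: float
    fallback: bool = False


def filter_training_complexes(
    test: ComplexRecord | str,
    pool: list,
    threshold: float = 0.05,
    scores: dict[str, float] | None = None,
) -> tuple[list, FilterReport]:
    """Drop pool complexes with similarity to the test complex < threshold.

    ``scores`` may supply precomputed (e.g. externally ingested) similarity
    values keyed by pool complex id; missing entries are computed with
    :func:`complex_similarity`.  If nothing survives, the filter falls back
    to keeping the whole pool and flags the report.
    """
    test_id = test if isinstance(test, str) else test.complex_id
    resolved_scores: dict[str, float] = {}
    for item in pool:
        record = item.record if hasattr(item, "record") else item
        if scores is not None and record.complex_id in scores:
            resolved_scores[record.complex_id] = scores[record.complex_id]
        else:
            if isinstance(test, str):
                raise ValueError("need a ComplexRecord test or full scores")
            resolved_scores[record.complex_id] = complex_similarity(test, record)
    kept = [
        item for item in pool
        if resolved_scores[
            (item.record if hasattr(item, "record") else item).complex_id
        ] >= threshold
    ]
    fallback = not kept and bool(pool)
    if fallback:
        kept = list(pool)
    report = FilterReport(
        test_complex_id=test_id,
        scores=resolved_scores,
        kept={cid: (s >= threshold) or fallback
              for cid, s in resolved_scores.items()},
        threshold=threshold,
        fallback=fallback,
    )
    return kept, report


def read_similarity_table(path) -> dict[tuple[str, str], float]:
    """Read an externally computed similarity TSV
    (complex_id_a, complex_id_b, score); stored symmetrically."""
    scores: dict[tuple[str, str], float] = {}
    from pathlib import Path
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b, s = line.split("\t")[:3]
        scores[(a, b)] = scores[(b, a)] = float(s)
    return scores


# ---------------------------------------------------------------------------
# Undersampling


def undersample_indices(
    labels: np.ndarray,
    ratio_negatives_per_positive: int = 3,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Indices keeping all positives and ``r`` negatives per positive.

    Negatives are drawn uniformly without replacement (clamped at the
    available count); the returned indices are sorted.
    """
    labels = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size == 0:
        raise NoPositives("undersampling requires at least one positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_neg = min(ratio_negatives_per_positive * pos.size, neg.size)
    chosen_neg = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(np.concatenate([pos, chosen_neg]))


def undersample(
    instances: list[PairInstance],
    ratio_negatives_per_positive: int = 3,
    seed: int = 0,
) -> list[PairInstance]:
    labels = np.array([inst.label for inst in instances], dtype=bool)
    idx = undersample_indices(labels, ratio_negatives_per_positive, seed)
    return [instances[i] for i in idx]


# ---------------------------------------------------------------------------
# Featurized complexes (the unit the LOOCV driver works on)


@dataclass
class FeaturizedComplex:
    """A complex with residue feature matrices and the pair label matrix.

    Feature matrices are stored in the full all-family column layout;
    :meth:`with_toggles` produces ablation views by column selection, so
    toggled runs reuse the same computed values.
    """

    record: ComplexRecord
    receptor: np.ndarray            # (n_r, w)
    ligand: np.ndarray              # (n_l, w)
    receptor_residues: list[Residue]
    ligand_residues: list[Residue]
    labels: np.ndarray              # (n_r, n_l) bool
    toggles: FeatureToggles = field(default_factory=FeatureToggles)

    @property
    def complex_id(self) -> str:
        return self.record.complex_id

    @property
    def columns(self) -> list[str]:
        return feature_columns(self.toggles)

    @property
    def pair_width(self) -> int:
        return 2 * self.receptor.shape[1]

    def with_toggles(self, toggles: FeatureToggles) -> "FeaturizedComplex":
        if self.toggles != FeatureToggles():
            raise ValueError("can only re-toggle an all-family featurization")
        mask = toggle_column_mask(toggles)
        return FeaturizedComplex(
            record=self.record,
            receptor=self.receptor[:, mask],
            ligand=self.ligand[:, mask],
            receptor_residues=self.receptor_residues,
            ligand_residues=self.ligand_residues,
            labels=self.labels,
            toggles=toggles,
        )

    def pair_features(self, ri: np.ndarray, lj: np.ndarray) -> np.ndarray:
        """Pair matrix for parallel index arrays (receptor-first order)."""
        return np.hstack([self.receptor[ri], self.ligand[lj]])

    def all_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ri, lj, labels) over the full pair grid, row-major."""
        n_r, n_l = self.labels.shape
        ri = np.repeat(np.arange(n_r), n_l)
        lj = np.tile(np.arange(n_l), n_r)
        return ri, lj, self.labels.ravel()


def featurize_complex(
    record: ComplexRecord,
    profiles: dict[str, ProfileMatrix] | None = None,
    neighbor_config: NeighborConfig | None = None,
    geometry_config: GeometryConfig | None = None,
    cutoff: float = INTERACTION_CUTOFF,
) -> FeaturizedComplex:
    """Compute all-family residue features and pair labels for a complex."""
    geometry_blocks = complex_geometry(record, geometry_config)
    rec_m, rec_res = partner_residue_matrix(
        record, "receptor", profiles, FeatureToggles(),
        neighbor_config, geometry_blocks,
    )
    lig_m, lig_res = partner_residue_matrix(
        record, "ligand", profiles, FeatureToggles(),
        neighbor_config, geometry_blocks,
    )
    return FeaturizedComplex(
        record=record,
        receptor=rec_m, ligand=lig_m,
        receptor_residues=rec_res, ligand_residues=lig_res,
        labels=interaction_matrix(record, cutoff),
    )
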