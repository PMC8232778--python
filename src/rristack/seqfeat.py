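"""Sequence-derived residue features.

Three ingredients describe a residue from sequence alone:

* fourteen physicochemical scale values (hydrophobicity x2, hydrophilicity,
  net charge index, polarity x2, polarizability, solvent-accessible surface
  area, side-chain volume, flexibility, accessibility, exposure, turn
  propensity, antigenicity), looked up from a packaged table;
* the residue's rows of a sequence profile (PSSM log-odds and PSFM
  frequencies), either parsed from a PSI-BLAST ASCII file or synthesized as
  a pseudo-profile from the sequence itself;
* a conservation index in [0, 1].

The conservation index is the normalized Shannon-entropy complement
``C = 1 - H / ln(20)`` over the amino-acid distribution of an alignment
column; perfectly conserved columns score 1, maximally diverse columns 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .errors import LengthMismatch
from .structio import Chain, ProfileMatrix, PROFILE_ALPHABET

#: Fixed scale-column order; frozen so trained models stay portable.
SCALE_NAMES = ["H11", "H12", "H2", "NCI", "P11", "P12", "P2",
               "SASA", "V", "F", "A1", "E", "T", "A2"]

SEQUENCE_BLOCK_WIDTH = 14 + 20 + 20 + 1  # physchem + pssm + psfm + conservation


def _load_scale_table() -> dict[str, np.ndarray]:
    table: dict[str, np.ndarray] = {}
    with resources.files("rristack.data").joinpath("physchem_scales.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["AA"]] = np.array(
                [float(row[name]) for name in SCALE_NAMES], dtype=float
            )
    assert len(table) == 20
    return table


PHYSCHEM_TABLE: dict[str, np.ndarray] = _load_scale_table()


def physchem_vector(aa: str, fix_tyr_row: bool = False) -> np.ndarray:
    """14 physicochemical scale values for one amino-acid letter.

    Unknown letters ('X' and anything non-standard) return zeros.  The
    packaged tyrosine row carries an apparent NCI/volume transposition in
    its source; ``fix_tyr_row`` swaps the two entries back but is off by
    default for fidelity to the packaged table.
    """
    values = PHYSCHEM_TABLE.get(aa)
    if values is None:
        return np.zeros(len(SCALE_NAMES))
    values = values.copy()
    if fix_tyr_row and aa == "Y":
        i, j = SCALE_NAMES.index("NCI"), SCALE_NAMES.index("V")
        values[i], values[j] = values[j], values[i]
    return values


def conservation_index(column: list[str] | str) -> float:
    """Entropy-based conservation of one alignment column, in [0, 1].

    Gaps and unknown letters are ignored; an all-gap column scores 0.
    """
    letters = [c.upper() for c in column if c.upper() in PROFILE_ALPHABET]
    if not letters:
        return 0.0
    _, counts = np.unique(letters, return_counts=True)
    freqs = counts / counts.sum()
    entropy = float(-(freqs * np.log(freqs)).sum())
    return max(0.0, 1.0 - entropy / np.log(20.0))


def conservation_from_msa(msa: list[str]) -> np.ndarray:
    """Per-column conservation for an aligned set of equal-length sequences."""
    lengths = {len(s) for s in msa}
    if len(lengths) != 1:
        raise LengthMismatch("MSA sequences differ in length")
    return np.array([
        conservation_index([s[i] for s in msa]) for i in range(lengths.pop())
    ])


def read_conservation_tsv(path: str | Path, length: int) -> np.ndarray:
    """Read an externally computed per-position conservation file
    (TSV: 0-based position, value)."""
    values = np.zeros(length)
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pos_s, val_s = line.split("\t")[:2]
        values[int(pos_s)] = float(val_s)
    return values


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pseudo_profile(sequence: str) -> ProfileMatrix:
    """Profile stand-in used when no PSI-BLAST output is supplied.

    PSFM rows are one-hot on the observed letter (uniform for unknowns);
    PSSM rows are the letter's BLOSUM62 row; conservation is 1 everywhere
    (a single sequence is trivially self-conserved).
    """
    if not sequence:
        raise ValueError("empty sequence")
    length = len(sequence)
    pssm = np.zeros((length, 20))
    psfm = np.zeros((length, 20))
    for i, aa in enumerate(sequence.upper()):
        if aa in PROFILE_ALPHABET:
            j = PROFILE_ALPHABET.index(aa)
            psfm[i, j] = 1.0
            pssm[i] = [_BLOSUM62[aa][b] for b in PROFILE_ALPHABET]
        else:
            psfm[i] = 1.0 / 20.0
    return ProfileMatrix(pssm=pssm, psfm=psfm,
                         conservation=np.ones(length))


def profile_conservation(profile: ProfileMatrix) -> np.ndarray:
    """Conservation track of a profile, deriving the entropy index from the
    PSFM when no explicit track is present."""
    if profile.conservation is not None:
        return profile.conservation
    psfm = np.clip(profile.psfm, 1e-12, None)
    psfm = psfm / psfm.sum(axis=1, keepdims=True)
    entropy = -(psfm * np.log(psfm)).sum(axis=1)
    return np.clip(1.0 - entropy / np.log(20.0), 0.0, 1.0)


@dataclass
class SequenceFeatureBlock:
    physchem: np.ndarray  # 14
    pssm_row: np.ndarray  # 20
    psfm_row: np.ndarray  # 20
    conservation: float

    def to_array(self) -> np.ndarray:
        return np.concatenate([
            self.physchem, self.pssm_row, self.psfm_row,
            [self.conservation],
        ])


def sequence_feature_block(
    chain: Chain, profile: ProfileMatrix, seq_position: int
) -> SequenceFeatureBlock:
    """Assemble the 55-wide sequence block for one full-sequence position."""
    if profile.length != len(chain.full_sequence):
        raise LengthMismatch(
            f"profile length {profile.length} != sequence length "
            f"{len(chain.full_sequence)}"
        )
    if not (0 <= seq_position < profile.length):
        raise IndexError(f"seq_position {seq_position} out of range")
    aa = chain.full_sequence[seq_position]
    return SequenceFeatureBlock(
        physchem=physchem_vector(aa),
        pssm_row=profile.pssm[seq_position].copy(),
        psfm_row=profile.psfm[seq_position].copy(),
        conservation=float(profile_conservation(profile)[seq_position]),
    )


def sequence_feature_names() -> list[str]:
    """Frozen column names of the sequence block."""
    return (
        [f"physchem_{n}" for n in SCALE_NAMES]
        + [f"pssm_{a}" for a in PROFILE_ALPHABET]
        + [f"psfm_{a}" for a in PROFILE_ALPHABET]
        + ["conservation"]
    )
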