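"""Structures, sequences and profiles: parsing, in-memory types, mapping.

The pipeline works on two-partner (receptor/ligand) protein complexes.  A
complex is read from a PDB-format coordinate file plus a FASTA file of
full-length chain sequences; resolved structure residues are mapped onto the
full sequences by global pairwise alignment, so that sequence-derived
features (profiles, conservation) can be indexed consistently even when the
crystal structure has unmodelled residues.

Only heavy atoms are retained: hydrogens, waters and non-polymer HETATM
groups are dropped at parse time, and the 6 A interaction rule downstream is
therefore evaluated over heavy-atom pairs by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import (
    EmptyFile,
    MalformedProfile,
    MappingFailure,
    NoPolymerResidues,
    UnknownChain,
)

#: Column order of profile matrices (PSI-BLAST ASCII layout).
PROFILE_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Fixed parent-residue table for common modified residues.  Modified
#: residues appear as HETATM records but belong to the polymer; anything
#: else recorded as HETATM (ligands, ions, waters) is discarded.
NONSTANDARD_PARENT = {
    "MSE": "M", "SEC": "C", "PYL": "K", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "CME": "C", "HYP": "P", "MLY": "K",
    "KCX": "K", "FME": "M", "LLP": "K", "M3L": "K", "OCS": "C",
}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Atom:
    """A single heavy atom."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class Residue:
    """One polymer residue; may be unresolved (no coordinates)."""

    chain_id: str
    struct_index: int
    aa: str
    atoms: list[Atom] = field(default_factory=list)
    seq_position: int | None = None

    @property
    def resolved(self) -> bool:
        return len(self.atoms) > 0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord_matrix(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]
    full_sequence: str = ""

    @property
    def resolved_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.resolved]

    @property
    def resolved_letters(self) -> str:
        return "".join(r.aa for r in self.residues if r.resolved)


@dataclass
class ComplexRecord:
    """A two-partner complex: receptor chains and ligand chains."""

    complex_id: str
    receptor_chains: list[Chain]
    ligand_chains: list[Chain]

    def __post_init__(self) -> None:
        rec = {c.chain_id for c in self.receptor_chains}
        lig = {c.chain_id for c in self.ligand_chains}
        if rec & lig:
            raise ValueError(f"receptor/ligand chain ids overlap: {rec & lig}")

    @property
    def chains(self) -> list[Chain]:
        return list(self.receptor_chains) + list(self.ligand_chains)

    def partner_residues(self, side: str) -> list[Residue]:
        """All resolved residues of one partner ('receptor' or 'ligand')."""
        chains = self.receptor_chains if side == "receptor" else self.ligand_chains
        return [r for c in chains for r in c.residues if r.resolved]


@dataclass
class ProfileMatrix:
    """Per-position profile: PSSM scores, PSFM frequencies, conservation.

    ``conservation`` may be None when the profile source does not provide
    one; feature assembly then derives an entropy-based index from the PSFM.
    """

    pssm: np.ndarray  # (L, 20) float
    psfm: np.ndarray  # (L, 20) float, rows sum to 1
    conservation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.psfm = np.asarray(self.psfm, dtype=float)
        if self.pssm.shape != self.psfm.shape or self.pssm.shape[1] != 20:
            raise ValueError("pssm/psfm must both be (L, 20)")
        if self.conservation is not None:
            self.conservation = np.asarray(self.conservation, dtype=float)

    @property
    def length(self) -> int:
        return self.pssm.shape[0]


# ---------------------------------------------------------------------------
# PDB parsing


def _residue_letter(resname: str) -> str:
    resname = resname.strip().upper()
    if resname in NONSTANDARD_PARENT:
        return NONSTANDARD_PARENT[resname]
    return protein_letters_3to1.get(resname, "X")


def _keep_residue(biores) -> bool:
    hetflag = biores.id[0]
    if hetflag == " ":
        return True
    if hetflag == "W":
        return False
    # HETATM polymer residues (MSE and friends) are kept; ligands dropped.
    return biores.get_resname().strip().upper() in NONSTANDARD_PARENT


def _select_altloc(bioatom):
    """Resolve disordered atoms: highest occupancy, lexicographically
    first altloc identifier on ties."""
    if not bioatom.is_disordered():
        return bioatom
    children = sorted(
        bioatom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def parse_pdb_complex(
    path: str | Path,
    receptor_ids: set[str] | list[str],
    ligand_ids: set[str] | list[str],
    complex_id: str | None = None,
) -> ComplexRecord:
    """Parse a PDB coordinate file into a :class:`ComplexRecord`.

    Only the first MODEL is read.  Hydrogens/deuteriums, waters and
    non-polymer HETATM groups are dropped; alternate locations are resolved
    to the highest-occupancy conformer.  One :class:`Residue` is created per
    (chain, resSeq, iCode).
    """
    path = Path(path)
    receptor_ids, ligand_ids = set(receptor_ids), set(ligand_ids)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(complex_id or path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise NoPolymerResidues(f"{path}: no coordinate model found")

    chains: dict[str, Chain] = {}
    for biochain in model:
        residues: list[Residue] = []
        for biores in biochain:
            if not _keep_residue(biores):
                continue
            atoms = []
            for bioatom in biores:
                at = _select_altloc(bioatom)
                element = (at.element or "").strip().upper()
                if not element:
                    element = at.get_name().strip()[:1].upper()
                if element in ("H", "D"):
                    continue
                atoms.append(Atom(at.get_name().strip(), element,
                                  np.asarray(at.get_coord(), dtype=float)))
            if not atoms:
                continue
            residues.append(Residue(
                chain_id=biochain.id,
                struct_index=len(residues),
                aa=_residue_letter(biores.get_resname()),
                atoms=atoms,
            ))
        if residues:
            chains[biochain.id] = Chain(biochain.id, residues)

    if not chains:
        raise NoPolymerResidues(f"{path}: no polymer ATOM records survive")
    for cid in sorted(receptor_ids | ligand_ids):
        if cid not in chains:
            raise UnknownChain(f"{path}: chain {cid!r} not present")

    return ComplexRecord(
        complex_id=complex_id or path.stem,
        receptor_chains=[chains[c] for c in sorted(receptor_ids)],
        ligand_chains=[chains[c] for c in sorted(ligand_ids)],
    )


def write_pdb(record: ComplexRecord, path: str | Path) -> None:
    """Write heavy-atom ATOM records (one model, TER per chain)."""
    lines = []
    serial = 1
    for chain in record.chains:
        for res in chain.residues:
            if not res.resolved:
                continue
            resname = _one_to_three(res.aa)
            for atom in res.atoms:
                name = atom.name
                # standard PDB atom-name justification
                field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:>5d} {field:<4s} {resname:<3s} "
                    f"{chain.chain_id}{res.struct_index + 1:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _one_to_three(aa: str) -> str:
    return _THREE.get(aa, "UNK")


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``.

    Stop characters (``*``) are stripped; raises :class:`EmptyFile` when the
    file holds no records.
    """
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().replace("*", "")
    if not records:
        raise EmptyFile(f"{path}: no FASTA records")
    return records


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII profiles


def parse_psiblast_profile(path: str | Path) -> ProfileMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Each position row carries 20 log-odds scores followed by 20 weighted
    percentages; percentages are divided by 100 and renormalized per row.
    The conservation track is left unset (filled later from an alignment or
    derived from the PSFM).
    """
    lines = Path(path).read_text().splitlines()
    pssm_rows, psfm_rows = [], []
    in_table = False
    for line in lines:
        tokens = line.split()
        if not in_table:
            # the column-header line repeats the 20-letter alphabet twice
            if len(tokens) == 40 and all(t in PROFILE_ALPHABET for t in tokens):
                in_table = True
            continue
        if not tokens:
            break
        if len(tokens) < 2 or not tokens[0].isdigit():
            break
        values = tokens[2:]
        if len(values) not in (40, 42):
            raise MalformedProfile(
                f"{path}: expected 40 numeric columns, got {len(values)}"
            )
        try:
            nums = [float(v) for v in values[:40]]
        except ValueError as exc:
            raise MalformedProfile(f"{path}: non-numeric entry ({exc})")
        pssm_rows.append(nums[:20])
        psfm_rows.append(nums[20:40])
    if not pssm_rows:
        raise MalformedProfile(f"{path}: no profile rows found")

    pssm = np.array(pssm_rows, dtype=float)
    psfm = np.array(psfm_rows, dtype=float) / 100.0
    sums = psfm.sum(axis=1, keepdims=True)
    uniform = np.full(20, 1.0 / 20.0)
    psfm = np.where(sums > 0, psfm / np.where(sums == 0, 1, sums), uniform)
    return ProfileMatrix(pssm=pssm, psfm=psfm, conservation=None)


# ---------------------------------------------------------------------------
# Structure -> sequence mapping


def align_structure_to_sequence(
    chain: Chain,
    identity_floor: float = 0.8,
    mismatch_tolerance: float = 0.0,
) -> Chain:
    """Fill ``seq_position`` for resolved residues by global alignment.

    The string of resolved residue letters is aligned against the chain's
    full-length sequence (match +1, mismatch -1, gap -2).  Residues that
    align to a gap are marked unresolved; mismatched alignments beyond the
    tolerated fraction are likewise unmapped.  Raises
    :class:`MappingFailure` when alignment identity over resolved residues
    falls below ``identity_floor``.
    """
    resolved = chain.resolved_residues
    if not resolved:
        return chain
    if not chain.full_sequence:
        raise MappingFailure(f"chain {chain.chain_id}: empty full sequence")
    letters = "".join(r.aa for r in resolved)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    alignment = aligner.align(chain.full_sequence, letters)[0]

    # per-resolved-residue aligned sequence position (or None)
    mapping: list[int | None] = [None] * len(letters)
    matched = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(q1 - q0):
            qi, ti = q0 + offset, t0 + offset
            mapping[qi] = ti
            if letters[qi] == chain.full_sequence[ti]:
                matched += 1
    identity = matched / len(letters)
    if identity < identity_floor:
        raise MappingFailure(
            f"chain {chain.chain_id}: alignment identity {identity:.2f} "
            f"below {identity_floor}"
        )

    mismatched = [i for i, ti in enumerate(mapping)
                  if ti is not None and letters[i] != chain.full_sequence[ti]]
    if len(mismatched) / len(letters) > mismatch_tolerance:
        for i in mismatched:
            mapping[i] = None

    for res, seq_pos in zip(resolved, mapping):
        if seq_pos is None:
            res.atoms = []  # unmappable -> unresolved
            res.seq_position = None
        else:
            res.seq_position = seq_pos
    return chain


# ---------------------------------------------------------------------------
# Manifests

MANIFEST_COLUMNS = [
    "complex_id", "pdb_path", "receptor_chains", "ligand_chains",
    "fasta_path", "profile_dir",
]


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a tab-separated complex manifest.

    Columns: complex_id, pdb_path, receptor_chains, ligand_chains,
    fasta_path, profile_dir (optional; empty allowed).  Paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    rows = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyFile(f"{path}: empty manifest")
    header = lines[0].rstrip("\n").split("\t")
    for line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        row = dict(zip(header, fields))
        row.setdefault("profile_dir", "")
        rows.append(row)
    return rows


def write_manifest(rows: list[dict[str, str]], path: str | Path) -> None:
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in MANIFEST_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def load_complex(
    row: dict[str, str], base_dir: str | Path
) -> tuple[ComplexRecord, dict[str, ProfileMatrix]]:
    """Load one manifest row: parse, attach full sequences, map positions.

    FASTA records are looked up as ``<complex_id>_<chain_id>`` (falling back
    to the bare chain id); a chain with no FASTA entry uses its resolved
    letters as the full sequence.  Profiles, when a profile directory is
    given, are read from ``<complex_id>_<chain_id>.pssm`` files.
    """
    base = Path(base_dir)
    record = parse_pdb_complex(
        base / row["pdb_path"],
        set(row["receptor_chains"].split(",")),
        set(row["ligand_chains"].split(",")),
        complex_id=row["complex_id"],
    )
    seqs = parse_fasta(base / row["fasta_path"]) if row.get("fasta_path") else {}
    profiles: dict[str, ProfileMatrix] = {}
    for chain in record.chains:
        key = f"{record.complex_id}_{chain.chain_id}"
        chain.full_sequence = seqs.get(key) or seqs.get(chain.chain_id) or \
            chain.resolved_letters
        align_structure_to_sequence(chain)
        pdir = row.get("profile_dir", "")
        if pdir:
            ppath = base / pdir / f"{key}.pssm"
            if ppath.exists():
                profiles[chain.chain_id] = parse_psiblast_profile(ppath)
    return record, profiles
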