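"""Model coordinates, observed geometry and residue annotation.

A model chain is reduced to one representative atom per residue (Cβ, or Cα
for glycine) and compared against per-residue-pair distance predictions
elsewhere in the package.  This module reads PDB/mmCIF files, derives the
observed distance matrix and contact map, annotates residues with
secondary structure and relative solvent accessibility, and renumbers a
chain onto a reference sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Residue",
    "StructureChain",
    "DistanceMatrix",
    "ContactMap",
    "read_model",
    "observed_distance_matrix",
    "observed_contact_map",
    "assign_ss_and_acc",
    "renumber_to_reference",
    "chain_to_pdb",
]

SS_CLASSES = ("helix", "sheet", "coil")

#: Maximum solvent-accessible surface areas (Å^2) per residue type
#: (theoretical values of Tien et al. 2013), used to turn raw DSSP ACC
#: into relative accessibility in [0, 1].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class Residue:
    """One reference-sequence position of a chain.

    ``rep_coord`` is the representative-atom position (Cβ; Cα for glycine)
    or ``None`` when the position is not modelled.  ``plddt`` is the 0-100
    predicted-confidence value conventionally stored in the B-factor
    column of predicted models.
    """

    seq_index: int
    aa: str = "X"
    rep_coord: Optional[np.ndarray] = None
    plddt: Optional[float] = None
    ss_class: Optional[str] = None
    acc: Optional[float] = None

    @property
    def modelled(self) -> bool:
        return self.rep_coord is not None

    def copy(self) -> "Residue":
        coord = None if self.rep_coord is None else np.array(self.rep_coord, dtype=float)
        return Residue(self.seq_index, self.aa, coord, self.plddt, self.ss_class, self.acc)


class StructureChain:
    """An ordered, 1-based list of residues covering a reference sequence.

    ``L`` is the reference-sequence length; unmodelled positions are
    present as placeholder residues with no coordinates so that indices
    always coincide with reference positions.
    """

    def __init__(self, residues: Iterable[Residue], chain_id: str = "A", L: Optional[int] = None):
        residues = sorted((r for r in residues), key=lambda r: r.seq_index)
        seen = [r.seq_index for r in residues]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate seq_index in chain")
        if residues and residues[0].seq_index < 1:
            raise ValueError("seq_index must be 1-based and positive")
        max_idx = residues[-1].seq_index if residues else 0
        self.L = int(L) if L is not None else max_idx
        if self.L < max_idx:
            raise ValueError("L smaller than largest residue index")
        by_index = {r.seq_index: r for r in residues}
        self.residues = [by_index.get(i, Residue(i)) for i in range(1, self.L + 1)]
        self.chain_id = chain_id

    def __len__(self) -> int:
        return self.L

    def __getitem__(self, seq_index: int) -> Residue:
        return self.residues[seq_index - 1]

    @property
    def modelled_mask(self) -> np.ndarray:
        return np.array([r.modelled for r in self.residues], dtype=bool)

    @property
    def n_modelled(self) -> int:
        return int(self.modelled_mask.sum())

    def coords(self) -> np.ndarray:
        """(L, 3) array of representative coordinates, NaN where unmodelled."""
        out = np.full((self.L, 3), np.nan)
        for i, r in enumerate(self.residues):
            if r.modelled:
                out[i] = r.rep_coord
        return out

    def plddt_array(self) -> Optional[np.ndarray]:
        vals = [r.plddt for r in self.residues if r.modelled]
        if not vals or all(v is None for v in vals):
            return None
        out = np.full(self.L, np.nan)
        for i, r in enumerate(self.residues):
            if r.plddt is not None:
                out[i] = r.plddt
        return out

    def sequence(self) -> str:
        return "".join(r.aa if r.modelled else "-" for r in self.residues)

    def copy(self) -> "StructureChain":
        return StructureChain([r.copy() for r in self.residues], self.chain_id, self.L)


@dataclass
class DistanceMatrix:
    """Symmetric L×L matrix of observed representative-atom distances.

    ``mask[i, j]`` is True only when both residues are modelled; masked-out
    entries are excluded from every downstream metric.
    """

    values: np.ndarray
    mask: np.ndarray

    @property
    def L(self) -> int:
        return self.values.shape[0]


class ContactMap:
    """Sparse set of residue contacts (i < j, 1-based) with weights in (0, 1]."""

    def __init__(self, pairs: Iterable[tuple], L: int):
        self.L = int(L)
        self.pairs: dict = {}
        for entry in pairs:
            if len(entry) == 2:
                i, j, w = entry[0], entry[1], 1.0
            else:
                i, j, w = entry
            if i > j:
                i, j = j, i
            if i == j:
                raise ValueError("self-contact")
            if not (1 <= i < j <= self.L):
                raise ValueError(f"contact ({i},{j}) outside [1,{self.L}]")
            if (i, j) in self.pairs:
                raise ValueError(f"duplicate contact ({i},{j})")
            self.pairs[(i, j)] = float(w)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def weight(self, i: int, j: int) -> float:
        return self.pairs.get((min(i, j), max(i, j)), 0.0)

    def total_weight(self) -> float:
        return float(sum(self.pairs.values()))

    def degrees(self) -> np.ndarray:
        """Per-residue contact counts (length L, 1-based positions at index-1)."""
        deg = np.zeros(self.L, dtype=int)
        for (i, j) in self.pairs:
            deg[i - 1] += 1
            deg[j - 1] += 1
        return deg

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((self.L, self.L))
        for (i, j), w in self.pairs.items():
            m[i - 1, j - 1] = m[j - 1, i - 1] = w
        return m


# ---------------------------------------------------------------------------
# reading models

_GEMMI = None


def _gemmi():
    global _GEMMI
    if _GEMMI is None:
        import gemmi

        _GEMMI = gemmi
    return _GEMMI


def read_model(path, chain_id: str) -> StructureChain:
    """Read a single chain from a PDB or mmCIF file.

    The representative atom is Cβ (Cα for glycine); non-glycine residues
    lacking a Cβ fall back to Cα with a warning.  pLDDT is taken from the
    B-factor of the representative atom.  Positions 1..max(seq_index) not
    present in the file are kept as unmodelled placeholders.
    """
    gemmi = _gemmi()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain {chain_id!r} not found in {path.name} "
                       f"(available: {[c.name for c in model]})")
    residues = []
    missing_cb = 0
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        idx = res.seqid.num
        if idx < 1:
            raise ValueError(f"residue number {idx} < 1; renumber the model first")
        if any(r.seq_index == idx for r in residues):
            continue  # altloc / insertion-code duplicate: keep first
        one = info.one_letter_code.upper()
        atom = None
        if one != "G":
            atom = res.find_atom("CB", "*")
            if atom is None:
                missing_cb += 1
        if atom is None:
            atom = res.find_atom("CA", "*")
        if atom is None:
            continue
        coord = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        residues.append(Residue(idx, one, coord, plddt=float(atom.b_iso)))
    if missing_cb:
        warnings.warn(f"{missing_cb} non-glycine residues lack a CB atom; used CA instead")
    if sum(1 for r in residues if r.modelled) < 3:
        raise ValueError(f"chain {chain_id!r} has fewer than 3 modelled residues")
    return StructureChain(residues, chain_id=chain_id)


def chain_to_pdb(chain: StructureChain, path) -> None:
    """Write the representative trace of a chain as a CA-only PDB file."""
    three = {one: name for name, one in [
        ("ALA", "A"), ("ARG", "R"), ("ASN", "N"), ("ASP", "D"), ("CYS", "C"),
        ("GLN", "Q"), ("GLU", "E"), ("GLY", "G"), ("HIS", "H"), ("ILE", "I"),
        ("LEU", "L"), ("LYS", "K"), ("MET", "M"), ("PHE", "F"), ("PRO", "P"),
        ("SER", "S"), ("THR", "T"), ("TRP", "W"), ("TYR", "Y"), ("VAL", "V"),
    ]}
    lines = []
    serial = 1
    for r in chain.residues:
        if not r.modelled:
            continue
        name = three.get(r.aa, "UNK")
        b = r.plddt if r.plddt is not None else 0.0
        x, y, z = r.rep_coord
        lines.append(
            f"ATOM  {serial:5d}  CA  {name:<3s} {chain.chain_id[:1]}{r.seq_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# observed geometry


def observed_distance_matrix(chain: StructureChain) -> DistanceMatrix:
    """Euclidean distances between representative atoms.

    Entries involving an unmodelled residue are zero with a False mask.
    """
    if chain.n_modelled < 2:
        raise ValueError("need at least 2 modelled residues")
    coords = chain.coords()
    modelled = chain.modelled_mask
    vals = np.zeros((chain.L, chain.L))
    idx = np.where(modelled)[0]
    sub = cdist(coords[idx], coords[idx])
    vals[np.ix_(idx, idx)] = sub
    mask = np.outer(modelled, modelled)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(values=vals, mask=mask)


def observed_contact_map(chain: StructureChain, cutoff: float = 8.0,
                         min_sep: int = 5) -> ContactMap:
    """Contacts between residues whose representative atoms are within
    ``cutoff`` Å and that are at least ``min_sep`` apart in sequence."""
    dm = observed_distance_matrix(chain)
    pairs = []
    iu, ju = np.triu_indices(chain.L, k=min_sep)
    ok = dm.mask[iu, ju] & (dm.values[iu, ju] < cutoff)
    for i, j in zip(iu[ok], ju[ok]):
        pairs.append((int(i) + 1, int(j) + 1, 1.0))
    return ContactMap(pairs, L=chain.L)


# ---------------------------------------------------------------------------
# secondary structure and accessibility

_DSSP_TO_CLASS = {"H": "helix", "G": "helix", "I": "helix",
                  "E": "sheet", "B": "sheet"}


def collapse_dssp_code(code: str) -> str:
    """Collapse an 8-state DSSP code to helix / sheet / coil."""
    return _DSSP_TO_CLASS.get(code.strip().upper(), "coil")


def _parse_dssp(path, chain_id: str):
    """Minimal reader for classic DSSP output: returns {resnum: (ss, raw_acc)}."""
    out = {}
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 38:
            continue
        if line[13] == "!":
            continue  # chain break
        if line[11].strip() and line[11] != chain_id:
            continue
        try:
            num = int(line[5:10])
            acc = float(line[34:38])
        except ValueError:
            continue
        out[num] = (line[16], acc)
    return out


def _ca_virtual_dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    # sign such that a right-handed alpha-helix scores ~ +50 degrees
    return -math.degrees(math.atan2(y, x))


def _geometric_ss(chain: StructureChain) -> list:
    """Assign helix/sheet/coil from Cα virtual dihedrals and d(i, i+3).

    Helix: dihedral in 50°±30° and d(i,i+3) < 6 Å.  Sheet: |dihedral| >
    120° and d(i,i+3) > 9 Å.  Everything else (and chain ends) is coil.
    """
    coords = chain.coords()
    modelled = chain.modelled_mask
    ss = ["coil"] * chain.L
    for i in range(1, chain.L - 2):  # needs residues i-1 .. i+2 (0-based)
        window = [i - 1, i, i + 1, i + 2]
        if not all(modelled[w] for w in window):
            continue
        dih = _ca_virtual_dihedral(*(coords[w] for w in window))
        d13 = np.linalg.norm(coords[i + 2] - coords[i - 1])
        if 20.0 <= dih <= 80.0 and d13 < 6.0:
            ss[i] = "helix"
        elif abs(dih) > 120.0 and d13 > 9.0:
            ss[i] = "sheet"
    return ss


def _neighbour_acc(chain: StructureChain, radius: float = 10.0,
                   n_buried: int = 20) -> np.ndarray:
    """Crude relative accessibility: residues with many neighbours within
    ``radius`` Å are buried.  Monotone map of neighbour count to [0, 1]."""
    dm = observed_distance_matrix(chain)
    close = (dm.values <= radius) & dm.mask
    np.fill_diagonal(close, False)
    counts = close.sum(axis=1)
    return np.clip(1.0 - counts / float(n_buried), 0.0, 1.0)


def assign_ss_and_acc(chain: StructureChain, annotation_path=None) -> StructureChain:
    """Annotate residues with 3-state secondary structure and relative
    accessibility, from a DSSP file when given, else from geometry."""
    chain = chain.copy()
    if annotation_path is not None:
        table = _parse_dssp(annotation_path, chain.chain_id)
        modelled_idx = [r.seq_index for r in chain.residues if r.modelled]
        covered = sum(1 for i in modelled_idx if i in table)
        if covered < 0.5 * max(1, len(modelled_idx)):
            raise ValueError("DSSP annotation does not cover this chain")
        for r in chain.residues:
            if not r.modelled:
                continue
            if r.seq_index in table:
                code, raw = table[r.seq_index]
                r.ss_class = collapse_dssp_code(code)
                r.acc = float(np.clip(raw / MAX_ASA.get(r.aa, 200.0), 0.0, 1.0))
            else:
                r.ss_class, r.acc = "coil", 0.5
        return chain
    ss = _geometric_ss(chain)
    acc = _neighbour_acc(chain)
    for i, r in enumerate(chain.residues):
        if r.modelled:
            r.ss_class = ss[i]
            r.acc = float(acc[i])
    return chain


# ---------------------------------------------------------------------------
# renumbering


def renumber_to_reference(chain: StructureChain, ref_seq: str,
                          min_identity: float = 0.9) -> StructureChain:
    """Renumber a chain so indices match positions in ``ref_seq``.

    The modelled sequence is globally aligned to the reference (free end
    gaps); sequence identity over the aligned modelled residues must be at
    least ``min_identity``, otherwise the chain is refused.  Residues that
    cannot be aligned are dropped with a warning.
    """
    from Bio import Align

    modelled = [r for r in chain.residues if r.modelled]
    seq = "".join(r.aa for r in modelled)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0
    aln = aligner.align(ref_seq, seq)[0]
    mapping = {}   # position in `seq` (0-based) -> reference position (1-based)
    matches = 0
    aligned = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[q0 + k] = t0 + k + 1
            aligned += 1
            if ref_seq[t0 + k] == seq[q0 + k]:
                matches += 1
    if aligned == 0 or matches / aligned < min_identity:
        raise ValueError(
            f"sequence identity {matches}/{aligned} below {min_identity:.0%}; refusing to renumber")
    new_residues = []
    dropped = 0
    for pos, res in enumerate(modelled):
        if pos in mapping:
            r = res.copy()
            r.seq_index = mapping[pos]
            new_residues.append(r)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} modelled residues could not be aligned to the reference "
                      "and were dropped")
    return StructureChain(new_residues, chain_id=chain.chain_id, L=len(ref_seq))
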