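"""Residue contact maps and 210-type contact-count vectors.

A protein (sequence, structure) pair is represented by the count of
non-bonded nearest-neighbor residue contacts of each of the 210
unordered pairs of the 20 standard amino-acid types.  Contacts are
extracted from the Delaunay triangulation of all heavy atoms, keeping
only triangulation edges shorter than a distance cutoff — a practical
stand-in for the edge simplices of an alpha complex, which selects
nearest-neighbor atoms in physical contact while discarding far pairs
that a plain distance cutoff would admit through intervening atoms.

Total contact count grows linearly with chain length, so raw counts are
normalized by the expected total from a linear regression of contacts
on length before any learning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: The 20 standard amino acids, alphabetical by 3-letter code.  This
#: order fixes the contact-type indexing used throughout the package.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Ambiguous residue codes that disqualify a chain from curation.
AMBIGUOUS_CODES = frozenset({"ASX", "GLX", "XLE", "XAA", "UNK"})

N_TYPES = 20
N_CONTACT_TYPES = 210  # 20 choose 2 + 20 diagonal pairs


class ContactTypeIndex:
    """Bijection between unordered amino-acid pairs and indices 0..209.

    Pairs are enumerated row-major over the upper triangle of the
    20 x 20 type matrix in alphabetical order: (ALA,ALA), (ALA,ARG),
    ..., (ALA,VAL), (ARG,ARG), ..., (VAL,VAL).
    """

    def __init__(self) -> None:
        self._aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        self._pair_index: dict[tuple[int, int], int] = {}
        pairs = []
        k = 0
        for i in range(N_TYPES):
            for j in range(i, N_TYPES):
                self._pair_index[(i, j)] = k
                pairs.append((AMINO_ACIDS[i], AMINO_ACIDS[j]))
                k += 1
        self.pairs: tuple[tuple[str, str], ...] = tuple(pairs)

    def __len__(self) -> int:
        return N_CONTACT_TYPES

    def index(self, a: str, b: str) -> int:
        """Index of the unordered pair {a, b} of 3-letter codes."""
        try:
            i, j = self._aa_index[a], self._aa_index[b]
        except KeyError as exc:
            raise ValueError(f"nonstandard residue code: {exc.args[0]!r}") from None
        if i > j:
            i, j = j, i
        return self._pair_index[(i, j)]

    def column_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


#: Shared default index; the mapping is fixed so one instance suffices.
CONTACT_INDEX = ContactTypeIndex()


@dataclass
class ProteinChain:
    """One polypeptide chain: residue types plus heavy-atom coordinates.

    ``residues`` holds, per residue, the 3-letter type code and an
    (n_atoms, 3) array of heavy-atom coordinates in Angstrom.  Residue
    indexing is 0-based and sequential in chain order.
    """

    chain_id: str
    residues: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a chain needs at least 2 residues")
        for name, coords in self.residues:
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
                raise ValueError(f"residue {name}: coordinates must be (n>=1, 3)")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [name for name, _ in self.residues]

    def atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and their residue indices."""
        coords = np.concatenate([np.asarray(c, dtype=float) for _, c in self.residues])
        owner = np.concatenate(
            [np.full(len(np.asarray(c)), i) for i, (_, c) in enumerate(self.residues)]
        )
        return coords, owner.astype(int)


@dataclass(frozen=True)
class ContactVector:
    """210-type contact-count vector for one (sequence, structure) pair."""

    counts: np.ndarray
    length: int
    normalized: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (N_CONTACT_TYPES,):
            raise ValueError(f"counts must have shape (210,), got {counts.shape}")
        object.__setattr__(self, "counts", counts)
        if not self.normalized:
            if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
                raise ValueError("raw counts must be non-negative integers")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class LengthModel:
    """Linear model Nc = a + b * n for total contacts vs chain length."""

    a: float
    b: float

    def predict(self, length: int | np.ndarray) -> float | np.ndarray:
        return self.a + self.b * np.asarray(length, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"a": self.a, "b": self.b}) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LengthModel":
        d = json.loads(Path(path).read_text())
        return cls(a=float(d["a"]), b=float(d["b"]))


def delaunay_edges(coords: np.ndarray) -> set[tuple[int, int]]:
    """Undirected edge list of the Delaunay triangulation of ``coords``."""
    from scipy.spatial import Delaunay

    tri = Delaunay(coords)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for u in range(len(simplex)):
            for v in range(u + 1, len(simplex)):
                i, j = int(simplex[u]), int(simplex[v])
                edges.add((i, j) if i < j else (j, i))
    return edges


def build_contact_map(
    chain: ProteinChain, cutoff: float = 4.5, min_separation: int = 2
) -> set[tuple[int, int]]:
    """Residue contact map from cutoff-filtered Delaunay edges.

    A residue pair (i, j) is a contact iff some heavy-atom pair, one
    atom from each residue, is an edge of the Delaunay triangulation of
    all heavy atoms of the chain, that edge is no longer than ``cutoff``
    Angstrom, and |i - j| >= ``min_separation`` (default 2: exclude the
    trivially bonded i, i+1 neighbors).

    Returns a set of 0-based residue index pairs with i < j.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    coords, owner = chain.atom_table()
    if len(coords) < 5:
        raise ValueError(
            f"chain has only {len(coords)} atoms; Delaunay triangulation in 3D "
            "needs at least 5"
        )
    if cutoff == 0:
        return set()
    contacts: set[tuple[int, int]] = set()
    for ai, aj in delaunay_edges(coords):
        ri, rj = int(owner[ai]), int(owner[aj])
        if ri == rj or abs(ri - rj) < min_separation:
            continue
        if np.linalg.norm(coords[ai] - coords[aj]) <= cutoff:
            contacts.add((ri, rj) if ri < rj else (rj, ri))
    return contacts


def contact_vector(
    sequence: Sequence[str],
    contact_map: Iterable[tuple[int, int]],
    length: int | None = None,
) -> ContactVector:
    """Count contacts of each of the 210 types for ``sequence``.

    The sequence need not be the chain's native sequence: threading and
    swap decoys reuse the native contact map with an alternative
    sequence, which is exactly how sequence decoys are scored.
    """
    n = len(sequence)
    counts = np.zeros(N_CONTACT_TYPES)
    for i, j in contact_map:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"contact ({i},{j}) out of range for sequence length {n}")
        counts[CONTACT_INDEX.index(sequence[i], sequence[j])] += 1
    return ContactVector(counts=counts, length=length if length is not None else n)


def fit_length_model(natives: Sequence[tuple[ContactVector, int]]) -> LengthModel:
    """Ordinary least squares of total contact count on residue count."""
    if len(natives) < 2:
        raise ValueError("need at least 2 native proteins to fit the length model")
    lengths = np.array([float(n) for _, n in natives])
    totals = np.array([v.total for v, _ in natives])
    if np.unique(lengths).size < 2:
        raise ValueError("all chains have the same length; regression is singular")
    b, a = np.polyfit(lengths, totals, 1)
    return LengthModel(a=float(a), b=float(b))


def normalize_length(
    v: ContactVector, model: LengthModel, mode: str = "fraction"
) -> ContactVector:
    """Remove the linear length dependence from a raw contact vector.

    ``mode="fraction"`` (default) divides each entry by the predicted
    total a + b*n, so entries become fractions of the expected contact
    count and the normalized total of a protein on the regression line
    is 1.  ``mode="reference"`` additionally rescales by the predicted
    total at a fixed reference length of 100 residues, keeping entries
    on a count-like scale.
    """
    if v.normalized:
        raise ValueError("vector is already normalized")
    predicted = float(model.predict(v.length))
    if predicted <= 0:
        raise ValueError(
            f"predicted contact count {predicted:.3g} <= 0 at length {v.length}"
        )
    scale = 1.0 / predicted
    if mode == "reference":
        scale *= float(model.predict(100))
    elif mode != "fraction":
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return ContactVector(counts=v.counts * scale, length=v.length, normalized=True)


def denormalize_length(
    v: ContactVector, model: LengthModel, mode: str = "fraction"
) -> ContactVector:
    """Inverse of :func:`normalize_length` (exact up to float round-off)."""
    if not v.normalized:
        raise ValueError("vector is not normalized")
    scale = float(model.predict(v.length))
    if mode == "reference":
        scale /= float(model.predict(100))
    return ContactVector(counts=v.counts * scale, length=v.length, normalized=False)


@dataclass
class CurationResult:
    accepted: bool
    reason: str = ""


@dataclass
class ChainRecord:
    """A chain plus the context needed for curation decisions."""

    chain: ProteinChain
    has_missing_residues: bool = False
    partner_chains: list[ProteinChain] = field(default_factory=list)


def _interchain_fraction(
    chain: ProteinChain, partners: Sequence[ProteinChain], cutoff: float,
    min_separation: int,
) -> float:
    """Fraction of this chain's contacting residues whose contact partner
    lies on another chain, from the joint Delaunay triangulation of the
    full complex."""
    blocks = [chain.atom_table()]
    chain_of_res: list[int] = [0] * len(chain)
    offsets = [0, len(chain)]
    for ci, partner in enumerate(partners, start=1):
        blocks.append(partner.atom_table())
        chain_of_res.extend([ci] * len(partner))
        offsets.append(offsets[-1] + len(partner))
    coords = np.concatenate([b[0] for b in blocks])
    owner = np.concatenate(
        [b[1] + off for b, off in zip(blocks, offsets[:-1])]
    )
    intra: set[int] = set()
    inter: set[int] = set()
    for ai, aj in delaunay_edges(coords):
        ri, rj = int(owner[ai]), int(owner[aj])
        if ri == rj:
            continue
        if np.linalg.norm(coords[ai] - coords[aj]) > cutoff:
            continue
        ci, cj = chain_of_res[ri], chain_of_res[rj]
        if ci == 0 and cj == 0:
            if abs(ri - rj) >= min_separation:
                intra.update((ri, rj))
        elif ci == 0:
            inter.add(ri)
        elif cj == 0:
            inter.add(rj)
    contacting = intra | inter
    if not contacting:
        return 0.0
    return len(inter) / len(contacting)


def curate_chain(
    record: ChainRecord,
    min_length: int = 46,
    max_length: int = 500,
    max_interchain_fraction: float = 0.30,
    cutoff: float = 4.5,
    min_separation: int = 2,
) -> CurationResult:
    """Accept or reject a chain for the training corpus.

    Rejects chains shorter than ``min_length`` or longer than
    ``max_length`` residues, chains with missing residues, chains
    containing ambiguous residue codes (ASX, GLX, XLE, XAA, UNK), and
    chains where more than ``max_interchain_fraction`` of contacting
    residues touch a partner chain of the same record.
    """
    chain = record.chain
    n = len(chain)
    if n < min_length:
        return CurationResult(False, f"length {n} < {min_length}")
    if n > max_length:
        return CurationResult(False, f"length {n} > {max_length}")
    if record.has_missing_residues:
        return CurationResult(False, "missing residues")
    bad = sorted({r for r in chain.sequence if r in AMBIGUOUS_CODES})
    if bad:
        return CurationResult(False, f"ambiguous residue codes: {','.join(bad)}")
    unknown = sorted({r for r in chain.sequence if r not in AMINO_ACIDS})
    if unknown:
        return CurationResult(False, f"nonstandard residues: {','.join(unknown)}")
    if record.partner_chains:
        frac = _interchain_fraction(
            chain, record.partner_chains, cutoff, min_separation
        )
        if frac > max_interchain_fraction:
            return CurationResult(
                False, f"inter-chain contact fraction {frac:.2f} > "
                f"{max_interchain_fraction:.2f}"
            )
    return CurationResult(True, "")


def parse_pdb_chain(path: str | Path, chain_id: str) -> ProteinChain:
    """Read one chain from a PDB file as a :class:`ProteinChain`.

    Uses the first model only; heavy atoms only (hydrogens skipped);
    for alternate locations the first conformer encountered is kept;
    non-amino-acid residues (waters, ligands) are skipped.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    for ch in model:
        if ch.id != chain_id:
            continue
        residues: list[tuple[str, np.ndarray]] = []
        for res in ch:
            hetflag = res.id[0]
            if hetflag != " ":
                continue
            coords = []
            seen: set[str] = set()
            for atom in res:
                if atom.element == "H":
                    continue
                if atom.name in seen:  # keep first altloc conformer
                    continue
                seen.add(atom.name)
                coords.append(atom.coord)
            if coords:
                residues.append((res.get_resname(), np.asarray(coords, dtype=float)))
        if not residues:
            raise ValueError(f"chain {chain_id!r} in {path} has no amino-acid residues")
        return ProteinChain(chain_id=chain_id, residues=residues)
    raise ValueError(f"chain {chain_id!r} not found in {path}")
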