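"""Synthetic data: toy structures and labeled contact-vector cohorts.

Every stage of the pipeline is testable offline with these generators.
Toy chains are compact self-avoiding pseudo-structures whose contact
totals grow linearly with length, like real proteins.  Vector cohorts
emulate the statistical structure of a curated native set: native
contact vectors concentrate around a shared composition profile with a
linear length-total relationship, while decoys keep the native's total
contact count (as threading and swap decoys do) but have their
composition perturbed away from the native profile by a controllable
``native_signal``.  At zero signal natives and decoys are exchangeable;
at high signal the classes are cleanly separable.

The geometry of toy chains is deliberately schematic — a jittered
space-filling path with one backbone and one side-chain pseudo-atom per
residue — not a physical protein model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fitland.contacts import (
    AMINO_ACIDS,
    N_CONTACT_TYPES,
    ContactVector,
    LengthModel,
    ProteinChain,
    fit_length_model,
    normalize_length,
)
from fitland.selection import NativeEntry


def make_toy_chain(length: int, seed: int = 0, spacing: float = 3.8,
                   jitter: float = 0.3) -> ProteinChain:
    """Compact self-avoiding toy chain with ``length`` residues.

    Residues sit on a boustrophedon path through a near-cubic grid with
    ``spacing`` Angstrom between neighbors, plus uniform coordinate
    jitter; each residue carries a backbone pseudo-atom and one
    side-chain pseudo-atom.  Self-avoidance and compactness hold by
    construction, and the number of spatial neighbor contacts grows
    linearly with length.  Deterministic under ``seed``.
    """
    if length < 5:
        raise ValueError("length must be >= 5")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(length ** (1.0 / 3.0)))
    residues: list[tuple[str, np.ndarray]] = []
    k = 0
    for z in range(side):
        for yy in range(side):
            y = yy if z % 2 == 0 else side - 1 - yy
            for xx in range(side):
                x = xx if (z * side + yy) % 2 == 0 else side - 1 - xx
                if k >= length:
                    break
                ca = spacing * np.array([x, y, z], dtype=float)
                ca += rng.uniform(-jitter, jitter, size=3)
                offset = rng.normal(size=3)
                offset *= 1.2 / np.linalg.norm(offset)
                aa = AMINO_ACIDS[int(rng.integers(0, 20))]
                residues.append((aa, np.array([ca, ca + offset])))
                k += 1
    return ProteinChain(chain_id="A", residues=residues)


def write_pdb(chain: ProteinChain, path: str | Path) -> None:
    """Write a chain as minimal PDB ATOM records (single model)."""
    lines = []
    serial = 1
    for i, (resname, coords) in enumerate(chain.residues, start=1):
        for j, xyz in enumerate(np.atleast_2d(coords)):
            name = "CA" if j == 0 else "CB"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} "
                f"{chain.chain_id}{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic contact-vector cohort.

    ``contacts_slope`` / ``contacts_intercept`` are the ground-truth
    linear length-total relationship (about two heavy-atom contacts
    gained per residue); ``native_signal`` in [0, 1] is the mixing
    weight pulling decoy composition away from the native profile; the
    lengths span the curated 46-500 residue range.
    """

    n_natives: int = 64
    length_range: tuple[int, int] = (46, 500)
    contacts_slope: float = 2.1
    contacts_intercept: float = -15.0
    contacts_noise_sd: float = 8.0
    native_signal: float = 0.8
    decoys_per_native: int = 30
    test_fraction: float = 0.25
    profile_concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid length_range")
        if not 0 <= self.native_signal <= 1:
            raise ValueError("native_signal must be in [0, 1]")
        if self.n_natives < 4:
            raise ValueError("n_natives must be >= 4")
        if self.decoys_per_native < 1:
            raise ValueError("decoys_per_native must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class Cohort:
    """Generated cohort: normalized train/test universes + raw vectors."""

    train: list[NativeEntry]
    test: list[NativeEntry]
    length_model: LengthModel
    raw_natives: list[tuple[str, ContactVector]] = field(default_factory=list)
    config: SynthConfig | None = None


def make_vector_cohort(config: SynthConfig) -> Cohort:
    """Labeled synthetic contact-vector universe with train/test split.

    Natives: counts drawn multinomially from per-protein profiles
    correlated with one shared cohort profile, totals on the configured
    length line plus Gaussian noise.  Decoys: same total as their
    native (contact conservation), composition profile mixed toward an
    independent random profile with weight ``native_signal``.  Raw
    vectors are length-normalized with a model fitted on the training
    natives only; no native is shared between train and test.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    base_profile = rng.dirichlet(
        np.full(N_CONTACT_TYPES, config.profile_concentration)
    )

    raw: list[tuple[str, ContactVector, np.ndarray]] = []
    for i in range(config.n_natives):
        n = int(rng.integers(lo, hi + 1))
        total = max(
            1,
            int(round(
                config.contacts_intercept
                + config.contacts_slope * n
                + rng.normal(0.0, config.contacts_noise_sd)
            )),
        )
        own = rng.dirichlet(np.full(N_CONTACT_TYPES, config.profile_concentration))
        profile = 0.85 * base_profile + 0.15 * own
        counts = rng.multinomial(total, profile)
        vec = ContactVector(counts=counts.astype(float), length=n)
        raw.append((f"synth{i:04d}", vec, profile))

    n_test = max(1, int(round(config.test_fraction * config.n_natives)))
    order = rng.permutation(config.n_natives)
    test_idx = set(order[:n_test].tolist())

    train_raw = [(pid, v) for k, (pid, v, _) in enumerate(raw) if k not in test_idx]
    length_model = fit_length_model([(v, v.length) for _, v in train_raw])

    def make_entries(indices: list[int]) -> list[NativeEntry]:
        entries = []
        for k in indices:
            pid, vec, profile = raw[k]
            total = int(vec.total)
            decoys = np.empty((config.decoys_per_native, N_CONTACT_TYPES))
            for j in range(config.decoys_per_native):
                other = rng.dirichlet(
                    np.full(N_CONTACT_TYPES, config.profile_concentration)
                )
                q = (1 - config.native_signal) * profile + config.native_signal * other
                dvec = ContactVector(
                    counts=rng.multinomial(total, q).astype(float),
                    length=vec.length,
                )
                decoys[j] = normalize_length(dvec, length_model).counts
            entries.append(
                NativeEntry(
                    id=pid,
                    vector=normalize_length(vec, length_model).counts,
                    decoys=decoys,
                )
            )
        return entries

    train_entries = make_entries([k for k in range(config.n_natives)
                                  if k not in test_idx])
    test_entries = make_entries(sorted(test_idx))
    return Cohort(
        train=train_entries,
        test=test_entries,
        length_model=length_model,
        raw_natives=[(pid, v) for pid, v, _ in raw],
        config=config,
    )
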