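"""Iterative construction of the training pool and basis set.

The decoy universe is far too large to train on directly, so training
alternates between fitting a reduced SVM on a small pool C with basis
Abar, scoring the whole universe with the current model, and rebuilding
C and Abar from the most informative examples:

* Strategy 1 refills C with each native's *misclassified* decoys with
  the least violation (fitness negative but closest to zero), topping
  up from the previous round when a native has fewer than the quota;
* Strategy 2 refills C with each native's hardest *correctly
  classified* decoys (fitness positive but closest to zero), and
  pre-selects the hardest correctly classified natives and the top
  decoy per native for the basis before random fill.

Iteration stops when the total misclassification count on the universe
stops improving; the best model over all rounds is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

from fitland.kernel import KernelParams, median_mu
from fitland.rsvm import (
    DECOY_LABEL,
    NATIVE_LABEL,
    BasisSet,
    FitnessModel,
    NewtonState,
    SolverParams,
    TrainingPool,
    fitness,
    train_model,
)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the iterative pool/basis construction.

    Defaults mirror the full-scale protocol: 10 candidate decoys per
    native in the working pool, a basis of 60% natives and 40% of the
    pool's decoys, and for Strategy 2 a pre-selected hard fraction of
    50% of the natives plus the top-1 hardest decoy per native.
    """

    decoys_per_native_pool: int = 10
    native_basis_fraction: float = 0.60
    decoy_basis_fraction: float = 0.40
    strategy: int = 2
    strategy2_preselect_native_fraction: float = 0.50
    strategy2_preselect_top_decoys: int = 1
    seed: int = 0
    max_rounds: int = 20

    def __post_init__(self) -> None:
        if self.decoys_per_native_pool < 1:
            raise ValueError("decoys_per_native_pool must be >= 1")
        for name in ("native_basis_fraction", "decoy_basis_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.strategy not in (1, 2):
            raise ValueError("strategy must be 1 or 2")
        if not 0 <= self.strategy2_preselect_native_fraction <= 1:
            raise ValueError("strategy2_preselect_native_fraction must be in [0, 1]")
        if self.strategy2_preselect_top_decoys < 0:
            raise ValueError("strategy2_preselect_top_decoys must be >= 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class RoundReport:
    round_index: int
    strategy: int
    misclassified_natives: int
    misclassified_decoys: int
    pool_size: int
    basis_size: int
    solver_converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def total_misclassified(self) -> int:
        return self.misclassified_natives + self.misclassified_decoys

    def to_dict(self) -> dict[str, Any]:
        return {
            "round": self.round_index,
            "strategy": self.strategy,
            "misclassified_natives": self.misclassified_natives,
            "misclassified_decoys": self.misclassified_decoys,
            "pool_size": self.pool_size,
            "basis_size": self.basis_size,
            "solver_converged": self.solver_converged,
            "notes": self.notes,
        }


@dataclass
class NativeEntry:
    """One native protein and its decoy universe block."""

    id: str
    vector: np.ndarray
    decoys: np.ndarray       # n_decoys x 210, may be empty
    decoy_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        self.decoys = np.atleast_2d(np.asarray(self.decoys, dtype=float))
        if self.decoys.size == 0:
            self.decoys = self.decoys.reshape(0, self.vector.shape[0])
        if not self.decoy_ids:
            self.decoy_ids = [f"{self.id}/d{i}" for i in range(len(self.decoys))]


def score_universe(
    model: FitnessModel, entries: Iterable[NativeEntry], chunk: int = 4096
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Fitness of every native and every decoy, streamed in chunks.

    Only ``chunk`` decoy rows are scored at a time, so the universe can
    be arbitrarily larger than memory-resident training matrices.
    """
    native_f: dict[str, float] = {}
    decoy_f: dict[str, np.ndarray] = {}
    for entry in entries:
        native_f[entry.id] = float(fitness(model, entry.vector[None, :])[0])
        parts = [
            fitness(model, entry.decoys[lo : lo + chunk])
            for lo in range(0, len(entry.decoys), chunk)
        ]
        decoy_f[entry.id] = (
            np.concatenate(parts) if parts else np.empty(0)
        )
    return native_f, decoy_f


def misclassification_counts(
    native_f: Mapping[str, float], decoy_f: Mapping[str, np.ndarray]
) -> tuple[int, int]:
    """(misclassified natives, misclassified decoys): natives with
    positive fitness; decoys with negative fitness."""
    mis_nat = sum(1 for f in native_f.values() if f > 0)
    mis_dec = sum(int(np.sum(f < 0)) for f in decoy_f.values())
    return mis_nat, mis_dec


def _build_pool(
    entries: list[NativeEntry], decoy_sel: Mapping[str, list[int]]
) -> TrainingPool:
    rows, labels, ids = [], [], []
    for entry in entries:
        rows.append(entry.vector)
        labels.append(NATIVE_LABEL)
        ids.append(entry.id)
    for entry in entries:
        for idx in decoy_sel.get(entry.id, []):
            rows.append(entry.decoys[idx])
            labels.append(DECOY_LABEL)
            ids.append(entry.decoy_ids[idx])
    return TrainingPool(A=np.array(rows), labels=np.array(labels), ids=ids)


def _build_basis(
    pool: TrainingPool,
    config: SelectionConfig,
    rng: np.random.Generator,
    preselected_native_ids: list[str] | None = None,
    preselected_decoy_ids: list[str] | None = None,
    notes: list[str] | None = None,
) -> BasisSet:
    """Basis = configured fractions of the pool, honoring pre-selections.

    Pre-selected ids are placed first; the remainder of each class quota
    is filled by seeded random sampling.  Quotas are round(fraction *
    class size), always at least 1 per class.
    """
    id_to_row = {pid: i for i, pid in enumerate(pool.ids)}
    nat_rows = [i for i in range(pool.m) if pool.labels[i] == NATIVE_LABEL]
    dec_rows = [i for i in range(pool.m) if pool.labels[i] == DECOY_LABEL]
    n_nat = max(1, round(config.native_basis_fraction * len(nat_rows)))
    n_dec = max(1, round(config.decoy_basis_fraction * len(dec_rows)))

    def pick(
        rows: list[int], quota: int, preselected: list[str] | None, what: str
    ) -> list[int]:
        chosen: list[int] = []
        if preselected:
            chosen = [id_to_row[pid] for pid in preselected if pid in id_to_row]
            chosen = chosen[:quota]
        remaining = [i for i in rows if i not in set(chosen)]
        n_fill = quota - len(chosen)
        if n_fill > len(remaining):
            if notes is not None:
                notes.append(
                    f"{what}: only {len(chosen) + len(remaining)} candidates "
                    f"for quota {quota}"
                )
            n_fill = len(remaining)
        if n_fill > 0:
            fill = rng.choice(len(remaining), size=n_fill, replace=False)
            chosen.extend(remaining[i] for i in sorted(fill))
        return chosen

    rows = pick(nat_rows, n_nat, preselected_native_ids, "basis natives") + pick(
        dec_rows, n_dec, preselected_decoy_ids, "basis decoys"
    )
    return BasisSet(
        Abar=pool.A[rows],
        labels=pool.labels[rows],
        ids=[pool.ids[i] for i in rows],
    )


def init_round(
    entries: list[NativeEntry],
    config: SelectionConfig,
    rng: np.random.Generator,
) -> tuple[TrainingPool, BasisSet, dict[str, list[int]], list[str]]:
    """Initial pool and basis before any model exists.

    Samples ``decoys_per_native_pool`` candidate decoys per native,
    keeps one of them per native for the initial pool (natives + one
    decoy each), and draws the basis as the configured random fractions
    of the pool's natives and decoys.  Returns the per-native candidate
    lists so later rounds can fall back on them.
    """
    notes: list[str] = []
    candidates: dict[str, list[int]] = {}
    chosen: dict[str, list[int]] = {}
    kept: list[NativeEntry] = []
    for entry in entries:
        n_avail = len(entry.decoys)
        if n_avail == 0:
            warnings.warn(f"native {entry.id} has no decoys; skipped", stacklevel=2)
            notes.append(f"skipped {entry.id}: no decoys")
            continue
        k = config.decoys_per_native_pool
        if n_avail < k:
            notes.append(f"{entry.id}: only {n_avail} decoys available (< {k})")
            k = n_avail
        sel = sorted(rng.choice(n_avail, size=k, replace=False).tolist())
        candidates[entry.id] = sel
        chosen[entry.id] = [sel[int(rng.integers(0, len(sel)))]]
        kept.append(entry)
    if not kept:
        raise ValueError("no native has any decoys")
    pool = _build_pool(kept, chosen)
    basis = _build_basis(pool, config, rng, notes=notes)
    return pool, basis, candidates, notes


def strategy1_round(
    model: FitnessModel,
    entries: list[NativeEntry],
    decoy_f: Mapping[str, np.ndarray],
    prev_sel: Mapping[str, list[int]],
    config: SelectionConfig,
    rng: np.random.Generator,
) -> tuple[TrainingPool, BasisSet, dict[str, list[int]], list[str]]:
    """Refill the pool with least-violating misclassified decoys.

    Per native: misclassified decoys (negative fitness) sorted by
    fitness descending, i.e. smallest violation first, up to the
    per-native quota; shortfalls are topped up from the previous
    round's selection for that native.  Ties broken by decoy index for
    reproducibility.
    """
    notes: list[str] = []
    quota = config.decoys_per_native_pool
    new_sel: dict[str, list[int]] = {}
    for entry in entries:
        f = decoy_f.get(entry.id)
        if f is None or f.size == 0:
            continue
        mis = [i for i in range(len(f)) if f[i] < 0]
        mis.sort(key=lambda i: (-f[i], i))  # descending fitness, then index
        take = mis[:quota]
        if len(take) < quota:
            for idx in prev_sel.get(entry.id, []):
                if len(take) >= quota:
                    break
                if idx not in take:
                    take.append(idx)
        if not mis and take:
            notes.append(f"{entry.id}: no misclassified decoys; kept previous")
        new_sel[entry.id] = take
    kept = [e for e in entries if new_sel.get(e.id)]
    pool = _build_pool(kept, new_sel)
    basis = _build_basis(pool, config, rng, notes=notes)
    return pool, basis, new_sel, notes


def strategy2_round(
    model: FitnessModel,
    entries: list[NativeEntry],
    native_f: Mapping[str, float],
    decoy_f: Mapping[str, np.ndarray],
    config: SelectionConfig,
    rng: np.random.Generator,
) -> tuple[TrainingPool, BasisSet, dict[str, list[int]], list[str]]:
    """Refill the pool with the hardest correctly classified decoys.

    Per native: correctly classified decoys (positive fitness) sorted
    ascending, up to the quota, random-filled from the rest if short.
    The basis pre-selects the hardest correctly classified natives
    (negative fitness closest to zero) and the top hardest decoys per
    native, then fills the remaining quotas at random.
    """
    notes: list[str] = []
    quota = config.decoys_per_native_pool
    new_sel: dict[str, list[int]] = {}
    hardest_decoy_ids: list[str] = []
    for entry in entries:
        f = decoy_f.get(entry.id)
        if f is None or f.size == 0:
            continue
        correct = [i for i in range(len(f)) if f[i] > 0]
        correct.sort(key=lambda i: (f[i], i))  # ascending fitness, then index
        take = correct[:quota]
        if len(take) < quota:
            rest = [i for i in range(len(f)) if i not in set(take)]
            n_fill = min(quota - len(take), len(rest))
            if n_fill:
                fill = rng.choice(len(rest), size=n_fill, replace=False)
                take.extend(rest[i] for i in sorted(fill))
                notes.append(
                    f"{entry.id}: only {len(correct)} correctly classified "
                    f"decoys; random-filled {n_fill}"
                )
        if take:
            new_sel[entry.id] = take
            for idx in take[: config.strategy2_preselect_top_decoys]:
                hardest_decoy_ids.append(entry.decoy_ids[idx])
    kept = [e for e in entries if new_sel.get(e.id)]
    pool = _build_pool(kept, new_sel)

    correct_natives = [
        e.id for e in kept if native_f.get(e.id, 1.0) <= 0
    ]
    # hardest = fitness closest to zero from below -> sort descending
    correct_natives.sort(key=lambda pid: (-native_f[pid], pid))
    n_pre = round(config.strategy2_preselect_native_fraction * len(kept))
    pre_natives = correct_natives[:n_pre]
    if len(pre_natives) < n_pre:
        notes.append(
            f"only {len(pre_natives)} correctly classified natives for "
            f"pre-selection quota {n_pre}"
        )
    basis = _build_basis(
        pool, config, rng,
        preselected_native_ids=pre_natives,
        preselected_decoy_ids=hardest_decoy_ids,
        notes=notes,
    )
    return pool, basis, new_sel, notes


def run_training(
    entries: list[NativeEntry],
    config: SelectionConfig,
    kernel: KernelParams | None = None,
    solver: SolverParams | None = None,
    length_model: Any | None = None,
) -> tuple[FitnessModel, list[RoundReport]]:
    """Full iterative training loop; returns the best model over rounds.

    Each round trains on the current (pool, basis), scores the whole
    universe, and rebuilds the pool and basis by the configured
    strategy.  Improvement is a strictly smaller total misclassification
    count than the previous round; the loop stops on a round with no
    improvement, on three strictly increasing rounds running
    (divergence guard, flagged in the report), or at ``max_rounds``.
    The best-scoring model over all rounds is returned, not the last.
    """
    solver = solver or SolverParams()
    rng = np.random.default_rng(config.seed)
    pool, basis, candidates, notes = init_round(entries, config, rng)
    if kernel is None:
        kernel = KernelParams(mu=median_mu(pool.A, seed=config.seed))
    prev_sel = candidates
    best_model: FitnessModel | None = None
    best_total = None
    prev_total = None
    reports: list[RoundReport] = []
    n_increase_streak = 0
    for round_index in range(config.max_rounds):
        model, state = train_model(
            pool, basis, kernel, solver,
            length_model=length_model,
            provenance={
                "strategy": config.strategy,
                "round": round_index,
                "seed": config.seed,
            },
        )
        native_f, decoy_f = score_universe(model, entries)
        mis_nat, mis_dec = misclassification_counts(native_f, decoy_f)
        report = RoundReport(
            round_index=round_index,
            strategy=config.strategy,
            misclassified_natives=mis_nat,
            misclassified_decoys=mis_dec,
            pool_size=pool.m,
            basis_size=basis.mbar,
            solver_converged=state.converged,
            notes=notes,
        )
        reports.append(report)
        total = report.total_misclassified
        if best_total is None or total < best_total:
            best_total = total
            best_model = model
        if best_total == 0:
            break
        if prev_total is not None:
            if total > prev_total:
                n_increase_streak += 1
            else:
                n_increase_streak = 0
            if n_increase_streak >= 3:
                report.notes.append(
                    "divergence: misclassifications increased 3 rounds running"
                )
                break
            if total == prev_total:
                break  # plateau: no improvement
        prev_total = total
        if round_index == config.max_rounds - 1:
            break
        if config.strategy == 1:
            pool, basis, prev_sel, notes = strategy1_round(
                model, entries, decoy_f, prev_sel, config, rng
            )
        else:
            pool, basis, prev_sel, notes = strategy2_round(
                model, entries, native_f, decoy_f, config, rng
            )
    assert best_model is not None
    return best_model, reports
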