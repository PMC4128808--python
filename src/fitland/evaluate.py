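"""Discrimination metrics: F-beta scores, misclassification tables,
design-rank verdicts, and swap-decoy misclassification curves.

Native proteins are the positive class for metric purposes: they are
the small minority against millions of decoys, so the F-beta score is
used with beta = 10 to weight native recall heavily.  This is
independent of the -1/+1 training-label convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from fitland.decoys import SwapDecoy
from fitland.rsvm import FitnessModel, fitness
from fitland.selection import NativeEntry, misclassification_counts, score_universe


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts with natives as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_natives(self) -> int:
        return self.TP + self.FN


@dataclass(frozen=True)
class FBetaParams:
    beta: float = 10.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive")


def fbeta(counts: ConfusionCounts, params: FBetaParams | None = None) -> float:
    """F-beta = (1 + beta^2) P R / (beta^2 P + R).

    P = TP / (TP + FP), R = TP / (TP + FN).  Degenerate zero
    denominators yield 0 with a warning.  beta defaults to 10, which
    emphasizes recall of the minority native class.
    """
    params = params or FBetaParams()
    if counts.TP + counts.FP == 0 or counts.TP + counts.FN == 0:
        warnings.warn("zero denominator in precision/recall; F-beta set to 0",
                      stacklevel=2)
        return 0.0
    p = counts.TP / (counts.TP + counts.FP)
    r = counts.TP / (counts.TP + counts.FN)
    if p == 0 or r == 0:
        return 0.0
    b2 = params.beta**2
    return (1 + b2) * p * r / (b2 * p + r)


@dataclass
class UniverseEvaluation:
    counts: ConfusionCounts
    design_success: dict[str, bool]
    misclassified_natives: list[tuple[str, float]]  # (id, fitness), sorted

    @property
    def design_success_rate(self) -> float:
        if not self.design_success:
            return float("nan")
        return sum(self.design_success.values()) / len(self.design_success)


def evaluate_universe(
    model: FitnessModel, entries: Sequence[NativeEntry], chunk: int = 4096
) -> UniverseEvaluation:
    """Score every native and decoy; count misclassifications.

    A native is misclassified when its fitness is positive; a decoy
    when its fitness is negative.  Per-native design-rank verdicts
    (native strictly lowest among itself and its decoys; ties fail) and
    a table of misclassified natives sorted by fitness are also
    returned.  Scoring streams decoys in chunks of ``chunk`` rows, so
    results are identical whether the universe fits in memory or not.
    """
    if not entries:
        raise ValueError("no native entries to evaluate")
    native_f, decoy_f = score_universe(model, entries, chunk=chunk)
    mis_nat, mis_dec = misclassification_counts(native_f, decoy_f)
    n_dec_total = sum(len(f) for f in decoy_f.values())
    counts = ConfusionCounts(
        TP=len(entries) - mis_nat,
        FN=mis_nat,
        FP=mis_dec,
        TN=n_dec_total - mis_dec,
    )
    design: dict[str, bool] = {}
    for entry in entries:
        f = decoy_f[entry.id]
        if f.size == 0:
            continue
        design[entry.id] = native_f[entry.id] < float(np.min(f))
    mis_table = sorted(
        ((pid, f) for pid, f in native_f.items() if f > 0),
        key=lambda t: t[1],
    )
    return UniverseEvaluation(
        counts=counts, design_success=design, misclassified_natives=mis_table
    )


def swap_curves(
    model: FitnessModel,
    decoy_sets: Mapping[str, Mapping[int, Sequence[SwapDecoy]]],
    native_lengths: Mapping[str, int],
    length_bin_width: int = 50,
    identity_bin_width: float = 0.1,
    include_zero_swaps: bool = False,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], float]]:
    """Misclassification rates of swap decoys by length and identity bins.

    Returns two tables keyed by bin indices:

    * ``by_swaps[(length_bin, n_swaps)]`` — fraction of decoys of
      natives in that length bin, at that swap count, with negative
      fitness (misclassified as native);
    * ``by_identity[(length_bin, identity_bin)]`` — the same fraction
      binned by sequence identity to the native (bin width 0.1).

    Length bins have width ``length_bin_width`` residues (bin index =
    floor(length / width)).  Zero-swap controls are identical to the
    native sequence and are excluded unless ``include_zero_swaps``.
    Empty bins are absent from the tables, not zero.
    """
    hits: dict[tuple[int, int], list[int]] = {}
    id_hits: dict[tuple[int, int], list[int]] = {}
    for native_id, per_swap in decoy_sets.items():
        lbin = int(native_lengths[native_id] // length_bin_width)
        for n_swaps, decoys in per_swap.items():
            if n_swaps == 0 and not include_zero_swaps:
                continue
            if not decoys:
                continue
            X = np.array([d.vector.counts for d in decoys])
            mis = fitness(model, X) < 0
            hits.setdefault((lbin, n_swaps), []).extend(int(m) for m in mis)
            for d, m in zip(decoys, mis):
                ibin = min(int(d.identity / identity_bin_width),
                           int(round(1.0 / identity_bin_width)) - 1)
                id_hits.setdefault((lbin, ibin), []).append(int(m))
    by_swaps = {k: float(np.mean(v)) for k, v in hits.items()}
    by_identity = {k: float(np.mean(v)) for k, v in id_hits.items()}
    return by_swaps, by_identity
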