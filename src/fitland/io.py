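"""Tabular formats: contact-vector TSV, round reports, metrics.

Contact vectors travel as tab-separated text with one row per record:
``id``, ``length``, ``label`` (native/decoy), optional provenance
columns, then the 210 count columns named by amino-acid pair
(ALA-ALA, ALA-ARG, ..., VAL-VAL; alphabetical by 3-letter code,
row-major over the upper triangle of the type matrix).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fitland.contacts import CONTACT_INDEX, ContactVector
from fitland.rsvm import DECOY_LABEL, NATIVE_LABEL
from fitland.selection import NativeEntry, RoundReport

PAIR_COLUMNS = CONTACT_INDEX.column_names()
META_COLUMNS = ["id", "length", "label"]


def vectors_to_frame(
    records: Iterable[tuple[str, str, ContactVector]],
    provenance: Sequence[dict] | None = None,
) -> pd.DataFrame:
    """Rows of (id, label, vector) to the canonical TSV frame."""
    rows = []
    for k, (rid, label, vec) in enumerate(records):
        row: dict = {"id": rid, "length": vec.length, "label": label}
        if provenance is not None:
            row.update(provenance[k])
        row.update(zip(PAIR_COLUMNS, vec.counts))
        rows.append(row)
    return pd.DataFrame(rows)


def write_vectors(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_vectors(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS + PAIR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing[:4]}"
            + ("..." if len(missing) > 4 else "")
        )
    return frame


def frame_to_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(matrix, +-1 labels, ids) from a canonical frame."""
    X = frame[PAIR_COLUMNS].to_numpy(dtype=float)
    labels = np.where(
        frame["label"].astype(str).str.lower() == "native", NATIVE_LABEL, DECOY_LABEL
    )
    return X, labels, frame["id"].astype(str).tolist()


def frame_to_entries(frame: pd.DataFrame) -> list[NativeEntry]:
    """Group a frame into per-native universe entries.

    Native rows own the decoy rows whose ``native_id`` column (or id
    prefix before '/') matches their id.
    """
    X, labels, ids = frame_to_matrix(frame)
    owner = (
        frame["native_id"].astype(str).tolist()
        if "native_id" in frame.columns
        else [i.split("/")[0] for i in ids]
    )
    entries: list[NativeEntry] = []
    for k, (rid, lab) in enumerate(zip(ids, labels)):
        if lab == NATIVE_LABEL:
            mask = [
                j
                for j, (o, l) in enumerate(zip(owner, labels))
                if o == rid and l == DECOY_LABEL
            ]
            entries.append(
                NativeEntry(
                    id=rid,
                    vector=X[k],
                    decoys=X[mask] if mask else np.empty((0, X.shape[1])),
                    decoy_ids=[ids[j] for j in mask],
                )
            )
    if not entries:
        raise ValueError("no native rows found")
    return entries


def write_round_reports(reports: Sequence[RoundReport], path: str | Path) -> None:
    """Round reports as JSON lines, one object per round."""
    with open(path, "w") as fh:
        for r in reports:
            fh.write(json.dumps(r.to_dict()) + "\n")
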