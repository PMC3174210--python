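"""23-component pseudo amino acid composition.

Components 1-20 are the occurrence frequencies of the standard residues in
alphabetical one-letter order; components 21-23 are the absolute GM(2,1)
coefficients |a1|, |a2|, |b| fitted to the numeric encoding of the
sequence.  No rescaling is applied between the two blocks.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from greybind.encoding import STANDARD_RESIDUES, ResidueCodeTable, encode_sequence
from greybind.grey_model import grey_features

#: Column order of feature matrices: A..Y then the grey block.
FEATURE_NAMES: list[str] = list(STANDARD_RESIDUES) + ["abs_a1", "abs_a2", "abs_b"]

N_FEATURES = 23

_RESIDUE_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


def amino_acid_composition(sequence: str) -> np.ndarray:
    """Occurrence frequencies of the 20 standard residues.

    Non-standard characters are excluded from both the counts and the
    denominator, so the result is a distribution over the 20 types.

    Raises
    ------
    ValueError
        If the sequence contains no standard residue.
    """
    counts = np.zeros(20, dtype=float)
    for char in sequence.upper():
        idx = _RESIDUE_INDEX.get(char)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard amino acid")
    return counts / total


def pseaac(
    sequence: str,
    table: ResidueCodeTable | None = None,
    unknown_policy: str = "skip",
) -> np.ndarray:
    """23-D pseudo amino acid composition of a sequence.

    Concatenates :func:`amino_acid_composition` with the grey features of
    the encoded series.  Requires at least 4 encodable residues.
    """
    series = encode_sequence(sequence, table=table, unknown_policy=unknown_policy)
    composition = amino_acid_composition(sequence)
    return np.concatenate([composition, grey_features(series)])


def write_feature_table(path: str | Path, ids: Sequence[str], X: np.ndarray) -> None:
    """Write a feature matrix as TSV with an ``id`` column plus 23 columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must be (n, {N_FEATURES}), got {X.shape}")
    if len(ids) != X.shape[0]:
        raise ValueError("ids and rows disagree")
    frame = pd.DataFrame(X, columns=FEATURE_NAMES)
    frame.insert(0, "id", list(ids))
    # repr-based formatting plus a round-trip parser keeps values bit-exact
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a feature TSV written by :func:`write_feature_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip")
    expected = ["id"] + FEATURE_NAMES
    if list(frame.columns) != expected:
        raise ValueError(f"unexpected feature columns {list(frame.columns)}")
    return frame["id"].tolist(), frame[FEATURE_NAMES].to_numpy(dtype=float)
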