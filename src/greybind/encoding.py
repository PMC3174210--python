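"""Residue-level numeric encoding of protein sequences.

Each of the 20 standard amino acids carries a signed factor score for
molecular volume (Atchley-style physicochemical factor).  The logistic map
``1 / (1 + exp(-score))`` squashes the score into the open interval (0, 1),
so that any protein sequence becomes a series of strictly positive reals
suitable for grey-model fitting.

The default score table ships with the package as a plain TSV resource and
can be overridden with any user-supplied table of the same shape, enabling
alternative physicochemical encodings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order. This order is
#: also the column order of the composition part of the feature vector.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

_NONSTANDARD = set("XBZUOJ*-.")


class EncodingError(ValueError):
    """A sequence contains a residue the active policy cannot encode."""


def code_from_factor(factor_score: float) -> float:
    """Map a signed factor score into (0, 1) with the logistic function.

    Parameters
    ----------
    factor_score : float
        Finite signed physicochemical factor score.

    Returns
    -------
    float
        ``1 / (1 + exp(-factor_score))``, strictly inside (0, 1) and
        strictly increasing in the score.

    Raises
    ------
    ValueError
        If ``factor_score`` is NaN or infinite.
    """
    x = float(factor_score)
    if not math.isfinite(x):
        raise ValueError(f"factor score must be finite, got {factor_score!r}")
    # math.exp overflows around 710; branch keeps both tails stable.
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class ResidueCodeTable:
    """Per-residue factor scores and their (0, 1) numeric codes.

    Parameters
    ----------
    factor_scores : mapping of str to float
        Exactly one finite score per standard amino acid.
    """

    factor_scores: Mapping[str, float]
    numeric_codes: Mapping[str, float] = field(init=False)

    def __post_init__(self) -> None:
        scores = {str(k).upper(): float(v) for k, v in self.factor_scores.items()}
        expected = set(STANDARD_RESIDUES)
        if set(scores) != expected:
            missing = sorted(expected - set(scores))
            extra = sorted(set(scores) - expected)
            raise ValueError(
                f"table must cover exactly the 20 standard residues; "
                f"missing={missing}, unexpected={extra}"
            )
        object.__setattr__(self, "factor_scores", scores)
        codes = {r: code_from_factor(s) for r, s in scores.items()}
        object.__setattr__(self, "numeric_codes", codes)

    def code(self, residue: str) -> float:
        """Numeric code in (0, 1) for a standard residue."""
        try:
            return self.numeric_codes[residue.upper()]
        except KeyError:
            raise KeyError(f"no code for non-standard residue {residue!r}") from None

    def factor_score(self, residue: str) -> float:
        return self.factor_scores[residue.upper()]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueCodeTable":
        """Load a table from a two-column ``residue<TAB>factor_score`` file.

        A single header line is permitted and detected by a non-numeric
        second column.
        """
        scores: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
                residue, raw = parts
                try:
                    score = float(raw)
                except ValueError:
                    if lineno == 1:
                        continue  # header
                    raise ValueError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
                if residue.upper() in scores:
                    raise ValueError(f"{path}:{lineno}: duplicate residue {residue!r}")
                scores[residue.upper()] = score
        return cls(scores)

    @classmethod
    def default(cls) -> "ResidueCodeTable":
        """The molecular-volume factor table shipped with the package."""
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            res = resources.files("greybind.data").joinpath("residue_factors.tsv")
            with resources.as_file(res) as path:
                _DEFAULT_TABLE = cls.from_tsv(path)
        return _DEFAULT_TABLE


_DEFAULT_TABLE: ResidueCodeTable | None = None


@dataclass(frozen=True)
class NumericSeries:
    """A protein sequence rendered as an ordered series of positive reals.

    Attributes
    ----------
    values : numpy.ndarray
        One code in (0, 1) per encoded residue, in sequence order.
    skipped : tuple of (int, str)
        Zero-based positions and characters omitted under the ``skip``
        policy.
    """

    values: np.ndarray
    skipped: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def __len__(self) -> int:
        return self.n


def encode_sequence(
    sequence: str,
    table: ResidueCodeTable | None = None,
    unknown_policy: str = "skip",
) -> NumericSeries:
    """Convert an amino-acid string to a series of codes in (0, 1).

    Parameters
    ----------
    sequence : str
        Non-empty amino-acid sequence; lower case accepted.
    table : ResidueCodeTable, optional
        Encoding table; the packaged molecular-volume table by default.
    unknown_policy : {"skip", "error"}
        ``skip`` drops non-standard characters (X, B, Z, U, O, J, gaps)
        from the series and records them; ``error`` aborts on the first
        one, naming its position.

    Returns
    -------
    NumericSeries

    Raises
    ------
    ValueError
        Empty sequence, or an unrecognised policy.
    EncodingError
        Non-standard residue under the ``error`` policy.
    """
    if table is None:
        table = ResidueCodeTable.default()
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    if unknown_policy not in ("skip", "error"):
        raise ValueError(f"unknown_policy must be 'skip' or 'error', got {unknown_policy!r}")

    codes = table.numeric_codes
    values: list[float] = []
    skipped: list[tuple[int, str]] = []
    for pos, char in enumerate(sequence.upper()):
        code = codes.get(char)
        if code is not None:
            values.append(code)
        elif unknown_policy == "error":
            raise EncodingError(
                f"non-standard residue {char!r} at position {pos + 1}"
            )
        else:
            skipped.append((pos, char))
    if skipped:
        logger.warning(
            "skipped %d non-standard residue(s) while encoding (first at position %d: %r)",
            len(skipped), skipped[0][0] + 1, skipped[0][1],
        )
    return NumericSeries(values=np.asarray(values, dtype=float), skipped=tuple(skipped))
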