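"""Canonical amino-acid alphabet and background-abundance tables.

Entropy scores compare the observed residue distribution at a subpocket
against a background amino-acid abundance.  This module owns the 20-letter
canonical alphabet, the gap/unknown symbol conventions, and validated
abundance tables (uniform, a packaged natural-abundance table, or a
user-supplied two-column file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError

#: The 20 canonical one-letter codes, in fixed alphabetical order.  All
#: count/probability matrices index rows in this order.
CANONICAL_RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_GAP = "-"
DEFAULT_UNKNOWN = frozenset("XBZJUO")

_RESIDUE_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


def residue_index(residue: str) -> int:
    """Row index of a canonical residue in matrix representations."""
    try:
        return _RESIDUE_INDEX[residue]
    except KeyError:
        raise ValidationError(f"not a canonical residue: {residue!r}") from None


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """The residue alphabet plus gap and unknown-symbol conventions.

    Invariants: exactly 20 distinct uppercase canonical residues; the gap
    symbol and unknown symbols are disjoint from the canonical set.
    """

    residues: tuple[str, ...] = CANONICAL_RESIDUES
    gap_symbol: str = DEFAULT_GAP
    unknown_symbols: frozenset[str] = DEFAULT_UNKNOWN

    def __post_init__(self):
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise ValidationError("alphabet must contain exactly 20 distinct residues")
        if any(len(r) != 1 or not r.isupper() for r in self.residues):
            raise ValidationError("residues must be single uppercase characters")
        if len(self.gap_symbol) != 1:
            raise ValidationError("gap symbol must be a single character")
        clash = ({self.gap_symbol} | set(self.unknown_symbols)) & set(self.residues)
        if clash:
            raise ValidationError(
                f"gap/unknown symbols overlap canonical residues: {sorted(clash)}"
            )

    def is_canonical(self, symbol: str) -> bool:
        return symbol in _RESIDUE_INDEX if self.residues == CANONICAL_RESIDUES else symbol in self.residues


#: Module-wide default alphabet instance.
DEFAULT_ALPHABET = AminoAcidAlphabet()


@dataclass(frozen=True)
class AbundanceTable:
    """Background frequency per canonical residue.

    Frequencies are validated to be complete and strictly positive, then
    renormalized so they sum to exactly 1 (within 1e-9 by construction).
    """

    frequencies: Mapping[str, float]
    name: str = "custom"
    _array: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        freqs = dict(self.frequencies)
        unknown = sorted(set(freqs) - set(CANONICAL_RESIDUES))
        if unknown:
            raise ValidationError(f"unknown residue code(s) in abundance table: {unknown}")
        missing = sorted(set(CANONICAL_RESIDUES) - set(freqs))
        if missing:
            raise ValidationError(f"abundance table missing residue(s): {missing}")
        bad = sorted(r for r, f in freqs.items() if not (f > 0 and np.isfinite(f)))
        if bad:
            raise ValidationError(
                f"non-positive or non-finite frequency for residue(s): {bad}"
            )
        arr = np.array([freqs[r] for r in CANONICAL_RESIDUES], dtype=float)
        arr = arr / math.fsum(arr)  # fsum: exactly-rounded total
        object.__setattr__(
            self, "frequencies", {r: float(f) for r, f in zip(CANONICAL_RESIDUES, arr)}
        )
        object.__setattr__(self, "_array", arr)

    def as_array(self) -> np.ndarray:
        """Frequencies as a length-20 vector in canonical residue order."""
        return self._array.copy()

    def frequency(self, residue: str) -> float:
        return self.frequencies[residue]

    @classmethod
    def uniform(cls) -> "AbundanceTable":
        return cls({r: 1.0 / 20.0 for r in CANONICAL_RESIDUES}, name="uniform")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "AbundanceTable":
        """Read a two-column ``residue<TAB>frequency`` table (header required)."""
        path = Path(path)
        freqs: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            lines = [
                ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")
            ]
        if not lines:
            raise ValidationError(f"empty abundance table: {path}")
        header = [c.strip().lower() for c in lines[0].replace(",", "\t").split("\t")]
        if header[:2] != ["residue", "frequency"]:
            raise ValidationError(
                f"abundance table {path} must have header 'residue<TAB>frequency'"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            cells = [c.strip() for c in line.replace(",", "\t").split("\t")]
            if len(cells) < 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns")
            residue = cells[0].upper()
            try:
                freq = float(cells[1])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: bad frequency {cells[1]!r} for residue {residue}"
                ) from None
            if residue in freqs:
                raise ValidationError(f"{path}:{lineno}: duplicate residue {residue}")
            freqs[residue] = freq
        return cls(freqs, name=name or path.stem)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("residue\tfrequency\n")
            for r in CANONICAL_RESIDUES:
                fh.write(f"{r}\t{self.frequencies[r]:.17g}\n")


def load_abundance(source: str | Path) -> AbundanceTable:
    """Load an abundance table from a preset name or a file path.

    ``"uniform"`` gives 1/20 per residue; ``"mccaldon"`` loads the packaged
    natural-abundance table; anything else is treated as a path to a
    two-column table.
    """
    if isinstance(source, str):
        key = source.lower()
        if key == "uniform":
            return AbundanceTable.uniform()
        if key == "mccaldon":
            ref = resources.files("cleavage_entropy").joinpath("data/mccaldon.tsv")
            with resources.as_file(ref) as path:
                return AbundanceTable.from_file(path, name="mccaldon")
    return AbundanceTable.from_file(source)
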