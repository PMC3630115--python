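"""Synthetic substrate generators with controlled statistical structure.

Every scoring stage is testable without external cleavage databases: these
generators produce datasets whose subpocket, total and pairwise entropies
are either exactly known (``expected_counts`` mode, largest-remainder
allocation) or known within a sampling-error bound (``sampled`` mode).
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import CANONICAL_RESIDUES, AbundanceTable, residue_index
from .errors import ValidationError
from .substrates import (
    N_SUBPOCKETS,
    CleavageRecord,
    subpocket_index,
)

SAMPLED = "sampled"
EXPECTED_COUNTS = "expected_counts"

DEFAULT_PROTEASE_ID = "synthetic"


def largest_remainder(weights: Sequence[float], n: int) -> np.ndarray:
    """Allocate n integer counts proportional to weights.

    Floors the exact shares, then hands remaining units to the largest
    fractional remainders (ties by index order).  Per-cell error < 1.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be non-negative with positive sum")
    exact = n * w / w.sum()
    counts = np.floor(exact).astype(np.int64)
    remainder = exact - counts
    short = n - int(counts.sum())
    if short:
        # argsort is stable, so equal remainders resolve by index order
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts


def _check_mode(mode: str) -> None:
    if mode not in (SAMPLED, EXPECTED_COUNTS):
        raise ValidationError(f"mode must be {SAMPLED!r} or {EXPECTED_COUNTS!r}")


def _column(n: int, bg: AbundanceTable, mode: str, rng: np.random.Generator) -> list[str]:
    """One subpocket's residues for n records, marginally following bg."""
    if mode == SAMPLED:
        return list(rng.choice(list(CANONICAL_RESIDUES), size=n, p=bg.as_array()))
    counts = largest_remainder(bg.as_array(), n)
    residues = [r for r, c in zip(CANONICAL_RESIDUES, counts) for _ in range(int(c))]
    # shuffle so distinct columns are not artificially coupled by sort order
    rng.shuffle(residues)
    return residues


def _records(columns: list[list[str]], protease_id: str) -> list[CleavageRecord]:
    n = len(columns[0])
    return [
        CleavageRecord(protease_id, tuple(columns[i][k] for i in range(N_SUBPOCKETS)))
        for k in range(n)
    ]


def _validate_residue(residue: str) -> str:
    residue = residue.upper()
    residue_index(residue)  # raises on non-canonical
    return residue


def generate_conserved(
    position_map: Mapping[str, str],
    n: int,
    fill: AbundanceTable | None = None,
    seed: int = 0,
    *,
    mode: str = SAMPLED,
    protease_id: str = DEFAULT_PROTEASE_ID,
) -> list[CleavageRecord]:
    """Fix given subpockets to single residues; fill the rest from *fill*."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    _check_mode(mode)
    fill = fill or AbundanceTable.uniform()
    fixed = {subpocket_index(k): _validate_residue(v) for k, v in position_map.items()}
    rng = np.random.default_rng(seed)
    columns = []
    for i in range(N_SUBPOCKETS):
        if i in fixed:
            columns.append([fixed[i]] * n)
        else:
            columns.append(_column(n, fill, mode, rng))
    return _records(columns, protease_id)


def generate_background(
    n: int,
    bg: AbundanceTable,
    mode: str = SAMPLED,
    seed: int = 0,
    *,
    protease_id: str = DEFAULT_PROTEASE_ID,
) -> list[CleavageRecord]:
    """Every subpocket follows the background distribution.

    ``expected_counts`` mode makes each column's residue counts exactly
    proportional to bg (largest-remainder), so each S_i is exactly 1;
    cross-column joints remain shuffled, not exact.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if mode == EXPECTED_COUNTS and n < 20:
        raise ValidationError("expected_counts mode needs n >= 20")
    _check_mode(mode)
    rng = np.random.default_rng(seed)
    columns = [_column(n, bg, mode, rng) for _ in range(N_SUBPOCKETS)]
    return _records(columns, protease_id)


def generate_coupled_pair(
    i: str | int,
    j: str | int,
    bijection: Mapping[str, str],
    n: int,
    mode: str = SAMPLED,
    seed: int = 0,
    *,
    protease_id: str = DEFAULT_PROTEASE_ID,
) -> list[CleavageRecord]:
    """Couple subpocket j deterministically to subpocket i.

    The residue at i is uniform over the 20 canonical residues; the
    residue at j is bijection(residue at i); other subpockets are uniform
    and independent.  In expected_counts mode the coupled pair has exact
    uniform support over 20 (a, bijection(a)) pairs, so S_ij is exactly
    ln(20)/ln(400) = 0.5 under a uniform background.
    """
    ii = subpocket_index(i) if isinstance(i, str) else int(i)
    jj = subpocket_index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValidationError("coupled subpockets must differ")
    bij = {_validate_residue(k): _validate_residue(v) for k, v in bijection.items()}
    if sorted(bij) != sorted(CANONICAL_RESIDUES) or sorted(
        bij.values()
    ) != sorted(CANONICAL_RESIDUES):
        raise ValidationError("bijection must be a permutation of the 20 residues")
    _check_mode(mode)
    uniform = AbundanceTable.uniform()
    rng = np.random.default_rng(seed)
    anchor = _column(n, uniform, mode, rng)
    coupled = [bij[a] for a in anchor]
    columns = []
    for pos in range(N_SUBPOCKETS):
        if pos == ii:
            columns.append(anchor)
        elif pos == jj:
            columns.append(coupled)
        else:
            columns.append(_column(n, uniform, mode, rng))
    return _records(columns, protease_id)


def generate_independent_pair(
    i: str | int,
    j: str | int,
    n: int,
    bg: AbundanceTable,
    mode: str = SAMPLED,
    seed: int = 0,
    *,
    protease_id: str = DEFAULT_PROTEASE_ID,
) -> list[CleavageRecord]:
    """Joint pair counts at (i, j) exactly proportional to f_a * f_b.

    In expected_counts mode the 400 pair counts are allocated by largest
    remainder over the independence product, so the pairwise entropy of
    (i, j) is exactly 1.  Other subpockets follow bg independently.
    """
    ii = subpocket_index(i) if isinstance(i, str) else int(i)
    jj = subpocket_index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValidationError("pair subpockets must differ")
    _check_mode(mode)
    rng = np.random.default_rng(seed)
    f = bg.as_array()
    if mode == EXPECTED_COUNTS:
        pair_counts = largest_remainder(np.outer(f, f).ravel(), n)
        pairs = [
            (CANONICAL_RESIDUES[k // 20], CANONICAL_RESIDUES[k % 20])
            for k, c in enumerate(pair_counts)
            for _ in range(int(c))
        ]
        rng.shuffle(pairs)
    else:
        idx = rng.choice(400, size=n, p=(np.outer(f, f) / np.outer(f, f).sum()).ravel())
        pairs = [(CANONICAL_RESIDUES[k // 20], CANONICAL_RESIDUES[k % 20]) for k in idx]
    columns = []
    for pos in range(N_SUBPOCKETS):
        if pos == ii:
            columns.append([a for a, _ in pairs])
        elif pos == jj:
            columns.append([b for _, b in pairs])
        else:
            columns.append(_column(n, bg, mode, rng))
    return _records(columns, protease_id)


def generate_motif_mixture(
    motif: Mapping[str, str],
    q: float,
    n: int,
    bg: AbundanceTable,
    mode: str = SAMPLED,
    seed: int = 0,
    *,
    protease_id: str = DEFAULT_PROTEASE_ID,
) -> list[CleavageRecord]:
    """Fraction q of records carry the motif; the rest follow bg.

    q=1 reduces to :func:`generate_conserved`, q=0 to
    :func:`generate_background`.  expected_counts mode allocates the motif
    count exactly as round(q*n) and draws exact background columns for
    the remainder, making motif-position entropies deterministic.
    """
    if not 0.0 <= q <= 1.0:
        raise ValidationError("motif fraction q must be in [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    _check_mode(mode)
    fixed = {subpocket_index(k): _validate_residue(v) for k, v in motif.items()}
    rng = np.random.default_rng(seed)
    if mode == EXPECTED_COUNTS:
        n_motif = int(round(q * n))
    else:
        n_motif = int(np.count_nonzero(rng.random(n) < q))
    n_bg = n - n_motif
    columns = []
    for pos in range(N_SUBPOCKETS):
        bg_part = _column(n_bg, bg, mode, rng) if n_bg else []
        if pos in fixed:
            columns.append([fixed[pos]] * n_motif + bg_part)
        else:
            motif_part = _column(n_motif, bg, mode, rng) if n_motif else []
            columns.append(motif_part + bg_part)
    return _records(columns, protease_id)


@dataclass
class GeneratorSpec:
    """Declarative description of a synthetic dataset for the CLI.

    Exactly one model is active; the seed is recorded in the output
    provenance header so runs are reproducible byte-for-byte.
    """

    model: str  # conserved | background | motif | coupled_pair | independent_pair
    n_records: int
    seed: int = 0
    mode: str = SAMPLED
    abundance: str = "uniform"
    positions: dict[str, str] = field(default_factory=dict)  # conserved/motif map
    motif_fraction: float = 1.0
    pair: tuple[str, str] | None = None
    bijection_shift: int = 1  # coupled_pair: j = alphabet rotation of i
    protease_id: str = DEFAULT_PROTEASE_ID

    def provenance(self) -> dict:
        out = {
            "model": self.model,
            "n_records": self.n_records,
            "seed": self.seed,
            "mode": self.mode,
            "abundance": self.abundance,
            "protease_id": self.protease_id,
        }
        if self.positions:
            out["positions"] = ",".join(f"{k}={v}" for k, v in self.positions.items())
        if self.model == "motif":
            out["motif_fraction"] = self.motif_fraction
        if self.pair:
            out["pair"] = ",".join(self.pair)
        if self.model == "coupled_pair":
            out["bijection_shift"] = self.bijection_shift
        return out


def shift_bijection(shift: int) -> dict[str, str]:
    """Alphabet-rotation permutation of the 20 canonical residues."""
    k = shift % 20
    return {
        a: CANONICAL_RESIDUES[(idx + k) % 20]
        for idx, a in enumerate(CANONICAL_RESIDUES)
    }


def generate(spec: GeneratorSpec, bg: AbundanceTable) -> list[CleavageRecord]:
    """Dispatch a GeneratorSpec to the matching generator."""
    common = dict(mode=spec.mode, protease_id=spec.protease_id)
    if spec.model == "conserved":
        if not spec.positions:
            raise ValidationError("conserved model needs at least one position=residue")
        return generate_conserved(
            spec.positions, spec.n_records, fill=bg, seed=spec.seed, **common
        )
    if spec.model == "background":
        return generate_background(spec.n_records, bg, seed=spec.seed, **common)
    if spec.model == "motif":
        if not spec.positions:
            raise ValidationError("motif model needs at least one position=residue")
        return generate_motif_mixture(
            spec.positions, spec.motif_fraction, spec.n_records, bg,
            seed=spec.seed, **common,
        )
    if spec.model == "coupled_pair":
        if not spec.pair:
            raise ValidationError("coupled_pair model needs --pair I,J")
        return generate_coupled_pair(
            spec.pair[0], spec.pair[1], shift_bijection(spec.bijection_shift),
            spec.n_records, seed=spec.seed, **common,
        )
    if spec.model == "independent_pair":
        if not spec.pair:
            raise ValidationError("independent_pair model needs --pair I,J")
        return generate_independent_pair(
            spec.pair[0], spec.pair[1], spec.n_records, bg,
            seed=spec.seed, **common,
        )
    raise ValidationError(f"unknown model {spec.model!r}")
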