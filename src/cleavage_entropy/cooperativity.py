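"""Pairwise cleavage entropy between subpockets.

Extends the single-subpocket score to joint residue-pair distributions:

    S_ij = -sum_ab q_(a,b) * ln(q_(a,b)) / ln(400)

with q obtained by dividing joint pair counts by the independence product
of background abundances f_a * f_b, then renormalizing over all 400 pairs.
S_ij is 0 for a single conserved residue pair and 1 when pairs occur as
expected by chance from the background.  A stringent per-pair substrate
cutoff (default 10000 effective observations) gates under-sampled pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .alphabet import AbundanceTable, residue_index
from .errors import UnavailableError, ValidationError
from .substrates import (
    N_SUBPOCKETS,
    SUBPOCKET_COLUMNS,
    SUBPOCKETS,
    CleavageRecord,
)
from .entropy import compute_profile

LN400 = float(np.log(400.0))

DEFAULT_MIN_PAIR_SUBSTRATES = 10000


def build_pair_counts(
    records: Sequence[CleavageRecord], i: int | str, j: int | str
) -> np.ndarray:
    """20x20 joint counts of canonical residue pairs at subpockets (i, j).

    Records carrying a gap or unknown at either position are excluded from
    this pair only.  Swapping i and j transposes the table.
    """
    from .substrates import subpocket_index

    ii = subpocket_index(i) if isinstance(i, str) else int(i)
    jj = subpocket_index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValidationError("pair subpockets must differ")
    if not records:
        raise ValidationError("no records")
    counts = np.zeros((20, 20), dtype=np.int64)
    for rec in records:
        a, b = rec.window[ii], rec.window[jj]
        try:
            counts[residue_index(a), residue_index(b)] += 1
        except ValidationError:
            continue  # gap/unknown at either slot: skip this pair
    return counts


def pairwise_entropy(pair_counts: np.ndarray, bg: AbundanceTable) -> float:
    """Normalized joint entropy of one 20x20 pair-count table, in [0, 1]."""
    counts = np.asarray(pair_counts, dtype=float)
    if counts.shape != (20, 20):
        raise ValidationError("pair counts must be 20x20")
    if (counts < 0).any():
        raise ValidationError("pair counts must be non-negative")
    total = counts.sum()
    if total < 1:
        raise UnavailableError("no effective observations for this pair")
    f = bg.as_array()
    weighted = counts / np.outer(f, f)
    q = weighted / weighted.sum()
    return float(-math.fsum(xlogy(q, q).ravel()) / LN400) + 0.0


@dataclass
class PairwiseEntropyMatrix:
    """S_ij over subpocket pairs with count gating, plus marginal S_i."""

    protease_id: str
    values: np.ndarray  # (8, 8) floats; NaN on diagonal and gated pairs
    gated: np.ndarray  # (8, 8) bool; True where the cutoff blocked a pair
    pair_totals: np.ndarray  # (8, 8) int effective observations per pair
    s_i: np.ndarray  # (8,) single-subpocket entropies (NaN if unavailable)
    min_pair_substrates: int

    def value(self, i: int | str, j: int | str) -> float:
        from .substrates import subpocket_index

        ii = subpocket_index(i) if isinstance(i, str) else int(i)
        jj = subpocket_index(j) if isinstance(j, str) else int(j)
        if ii == jj:
            raise ValidationError("pair subpockets must differ")
        if self.gated[ii, jj]:
            raise UnavailableError(
                f"pair ({SUBPOCKETS[ii]},{SUBPOCKETS[jj]}) gated: "
                f"{self.pair_totals[ii, jj]} < {self.min_pair_substrates}"
            )
        return float(self.values[ii, jj])

    def to_tsv(self, path: str | Path, *, decimals: int | None = 6) -> None:
        """8x8 grid with gated/diagonal cells as NA and a final S_i row."""

        def fmt(x: float) -> str:
            if np.isnan(x):
                return "NA"
            return f"{x:.{decimals}f}" if decimals is not None else repr(x)

        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subpocket\t" + "\t".join(SUBPOCKET_COLUMNS) + "\n")
            for i, name in enumerate(SUBPOCKET_COLUMNS):
                cells = [fmt(self.values[i, j]) for j in range(N_SUBPOCKETS)]
                fh.write(name + "\t" + "\t".join(cells) + "\n")
            fh.write("S_i\t" + "\t".join(fmt(v) for v in self.s_i) + "\n")


def pairwise_matrix(
    records: Sequence[CleavageRecord],
    bg: AbundanceTable,
    min_pair_substrates: int = DEFAULT_MIN_PAIR_SUBSTRATES,
) -> PairwiseEntropyMatrix:
    """Compute S_ij for every unordered subpocket pair passing the cutoff.

    The cutoff applies to effective pair totals (records with canonical
    residues at both positions), not raw record counts.  A fully gated
    matrix is legal output.
    """
    if min_pair_substrates < 1:
        raise ValidationError("min_pair_substrates must be >= 1")
    if not records:
        raise ValidationError("no records")
    pid = records[0].protease_id
    values = np.full((N_SUBPOCKETS, N_SUBPOCKETS), np.nan)
    gated = np.zeros((N_SUBPOCKETS, N_SUBPOCKETS), dtype=bool)
    totals = np.zeros((N_SUBPOCKETS, N_SUBPOCKETS), dtype=np.int64)
    for i, j in itertools.combinations(range(N_SUBPOCKETS), 2):
        counts = build_pair_counts(records, i, j)
        total = int(counts.sum())
        totals[i, j] = totals[j, i] = total
        if total < min_pair_substrates:
            gated[i, j] = gated[j, i] = True
            continue
        s = pairwise_entropy(counts, bg)
        values[i, j] = values[j, i] = s
    profile = compute_profile(records, pid, bg)
    return PairwiseEntropyMatrix(
        protease_id=pid,
        values=values,
        gated=gated,
        pair_totals=totals,
        s_i=profile.s.copy(),
        min_pair_substrates=min_pair_substrates,
    )
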