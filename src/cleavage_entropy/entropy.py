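"""Subpocket-wise and total cleavage entropy.

The score for subpocket *i* is the normalized Shannon entropy of the
abundance-corrected residue distribution observed there:

    S_i = -sum_a p_(a,i) * ln(p_(a,i)) / ln(20)

where p_(a,i) is obtained from raw counts in two normalization stages:
first each count is divided by the background abundance f_a of its residue,
then each subpocket column is renormalized to sum to 1.  S_i ranges from 0
(a single perfectly conserved residue) to 1 (a residue distribution
indistinguishable from background).  The total cleavage entropy is the sum
of the eight subpocket scores and ranges from 0 to 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .alphabet import AbundanceTable
from .errors import ContractError, UnavailableError, ValidationError
from .substrates import (
    N_SUBPOCKETS,
    SUBPOCKETS,
    CleavageRecord,
    CountMatrix,
    build_count_matrix,
    subpocket_index,
)

LN20 = float(np.log(20.0))

#: Tolerance for "this column sums to 1" checks.
COLUMN_SUM_TOL = 1e-9

P_SIDE = ("P4", "P3", "P2", "P1")
PPRIME_SIDE = ("P1'", "P2'", "P3'", "P4'")


@dataclass
class ProbabilityMatrix:
    """Abundance-normalized, column-stochastic residue probabilities.

    ``p[a, i]`` is the probability of residue *a* at subpocket *i*.
    Columns with no effective observations are flagged unavailable rather
    than silently zeroed.
    """

    protease_id: str
    p: np.ndarray  # (20, 8)
    available: np.ndarray  # (8,) bool
    effective_counts: np.ndarray  # (8,) int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        self.effective_counts = np.asarray(self.effective_counts, dtype=np.int64)
        if self.p.shape != (20, N_SUBPOCKETS):
            raise ValidationError(f"p must be 20x{N_SUBPOCKETS}")
        if (self.p < 0).any():
            raise ValidationError("probabilities must be non-negative")
        sums = self.p.sum(axis=0)
        bad = self.available & (np.abs(sums - 1.0) > COLUMN_SUM_TOL)
        if bad.any():
            raise ValidationError(
                f"available columns not normalized: {np.nonzero(bad)[0].tolist()}"
            )

    def column(self, subpocket: str) -> np.ndarray:
        i = subpocket_index(subpocket)
        if not self.available[i]:
            raise UnavailableError(f"subpocket {subpocket} has no observations")
        return self.p[:, i]


def normalize_counts(m: CountMatrix, bg: AbundanceTable) -> ProbabilityMatrix:
    """Two-stage normalization of a count matrix.

    Stage one divides each residue's counts by its background abundance;
    stage two renormalizes every subpocket column to sum to 1.  Columns
    with zero total are marked unavailable.
    """
    f = bg.as_array()  # (20,)
    weighted = m.counts / f[:, None]
    totals = weighted.sum(axis=0)
    available = m.column_totals > 0
    p = np.zeros_like(weighted)
    p[:, available] = weighted[:, available] / totals[available]
    return ProbabilityMatrix(
        protease_id=m.protease_id,
        p=p,
        available=available,
        effective_counts=m.column_totals,
    )


def subpocket_entropy(column: np.ndarray | Sequence[float]) -> float:
    """Normalized Shannon entropy of one probability column, in [0, 1].

    Uses the convention 0*ln(0) = 0.  The column must already be a
    probability vector over the 20 residues (sum 1 within tolerance).
    """
    col = np.asarray(column, dtype=float)
    if col.shape != (20,):
        raise ContractError(f"expected a length-20 probability vector, got {col.shape}")
    if (col < 0).any():
        raise ContractError("probabilities must be non-negative")
    if abs(col.sum() - 1.0) > COLUMN_SUM_TOL:
        raise ContractError(f"column sums to {col.sum()!r}, not 1")
    # xlogy gives 0*ln(0)=0; fsum keeps the uniform endpoint exact at 1.0
    return float(-math.fsum(xlogy(col, col)) / LN20) + 0.0  # +0.0 kills -0.0


def total_cleavage_entropy(
    s_values: Sequence[float],
    available: Sequence[bool] | None = None,
    *,
    allow_partial: bool = False,
) -> tuple[float, int]:
    """Sum the eight subpocket entropies.

    Returns ``(total, n_summed)``.  Unless *allow_partial* is set, all 8
    subpockets must be available; partial totals always report how many
    subpockets were summed so they cannot masquerade as full totals.
    """
    s = np.asarray(s_values, dtype=float)
    if s.shape != (N_SUBPOCKETS,):
        raise ContractError(f"expected {N_SUBPOCKETS} subpocket entropies")
    avail = (
        np.ones(N_SUBPOCKETS, dtype=bool)
        if available is None
        else np.asarray(available, dtype=bool)
    )
    if ((s[avail] < -1e-12) | (s[avail] > 1 + 1e-12)).any():
        raise ContractError("subpocket entropies must lie in [0, 1]")
    if not avail.all() and not allow_partial:
        missing = [SUBPOCKETS[i] for i in np.nonzero(~avail)[0]]
        raise UnavailableError(
            f"subpockets {missing} unavailable; pass allow_partial=True for a partial total"
        )
    return float(s[avail].sum()), int(avail.sum())


@dataclass
class SpecificityProfile:
    """The eight subpocket entropies and their total for one protease."""

    protease_id: str
    s: np.ndarray  # (8,) floats, NaN where unavailable
    available: np.ndarray  # (8,) bool
    effective_counts: np.ndarray  # (8,) int
    n_records: int

    @property
    def complete(self) -> bool:
        return bool(self.available.all())

    @property
    def s_cleavage(self) -> float:
        """Total cleavage entropy; requires all 8 subpockets."""
        total, _ = total_cleavage_entropy(np.nan_to_num(self.s), self.available)
        return total

    def partial_total(self) -> tuple[float, int]:
        return total_cleavage_entropy(
            np.nan_to_num(self.s), self.available, allow_partial=True
        )

    def s_at(self, subpocket: str) -> float:
        i = subpocket_index(subpocket)
        if not self.available[i]:
            raise UnavailableError(f"subpocket {subpocket} unavailable")
        return float(self.s[i])


def profile_from_counts(m: CountMatrix, bg: AbundanceTable) -> SpecificityProfile:
    """Score an existing count matrix."""
    pm = normalize_counts(m, bg)
    s = np.full(N_SUBPOCKETS, np.nan)
    for i in range(N_SUBPOCKETS):
        if pm.available[i]:
            s[i] = subpocket_entropy(pm.p[:, i])
    return SpecificityProfile(
        protease_id=m.protease_id,
        s=s,
        available=pm.available.copy(),
        effective_counts=pm.effective_counts.copy(),
        n_records=m.n_records,
    )


def compute_profile(
    records: Sequence[CleavageRecord], protease_id: str, bg: AbundanceTable
) -> SpecificityProfile:
    """Full chain: tally counts, normalize, score every subpocket."""
    return profile_from_counts(build_count_matrix(records, protease_id), bg)


def region_average(profile: SpecificityProfile, region: str) -> float:
    """Mean subpocket entropy over the P-side (P4..P1) or P'-side (P1'..P4')."""
    if region in ("P", "P-side", "p"):
        names = P_SIDE
    elif region in ("Pprime", "P'-side", "pprime", "P'"):
        names = PPRIME_SIDE
    else:
        raise ValidationError(f"region must be 'P' or 'Pprime', got {region!r}")
    values = [profile.s_at(name) for name in names]
    return float(np.mean(values))
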