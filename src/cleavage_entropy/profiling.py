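"""Classification, ranking, grouping and diagnostics over many profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .errors import ContractError, UndefinedCorrelationError, ValidationError
from .entropy import SpecificityProfile
from .substrates import N_SUBPOCKETS

HIGHLY_SPECIFIC = "highly_specific"
SPECIFIC = "specific"
UNSPECIFIC = "unspecific"

# Subpocket-level cutoffs (S_i scale): below red -> highly specific, up to
# and including yellow -> specific, above -> unspecific.
DEFAULT_YELLOW_CUTOFF = 0.85
DEFAULT_RED_CUTOFF = 0.5

# Protease-level cutoffs (S_cleavage scale); both strict "<".
DEFAULT_SPECIFIC_CUTOFF = 6.8
DEFAULT_HIGHLY_SPECIFIC_CUTOFF = 4.0


def classify_subpocket(
    s_i: float,
    yellow_cutoff: float = DEFAULT_YELLOW_CUTOFF,
    red_cutoff: float = DEFAULT_RED_CUTOFF,
) -> str:
    """Label one subpocket entropy.

    ``highly_specific`` below *red_cutoff*; ``specific`` up to and
    including *yellow_cutoff* (the yellow boundary is inclusive);
    ``unspecific`` above.
    """
    if not (0.0 <= s_i <= 1.0):
        raise ContractError(f"subpocket entropy out of [0,1]: {s_i}")
    if s_i < red_cutoff:
        return HIGHLY_SPECIFIC
    if s_i <= yellow_cutoff:
        return SPECIFIC
    return UNSPECIFIC


def classify_protease(
    s_cleavage: float,
    specific_cutoff: float = DEFAULT_SPECIFIC_CUTOFF,
    highly_cutoff: float = DEFAULT_HIGHLY_SPECIFIC_CUTOFF,
) -> str:
    """Label a total cleavage entropy; both cutoffs are strict ``<``."""
    if not (0.0 <= s_cleavage <= 8.0):
        raise ContractError(f"total cleavage entropy out of [0,8]: {s_cleavage}")
    if s_cleavage < highly_cutoff:
        return HIGHLY_SPECIFIC
    if s_cleavage < specific_cutoff:
        return SPECIFIC
    return UNSPECIFIC


@dataclass(frozen=True)
class RankedProfile:
    rank: int
    protease_id: str
    s_cleavage: float
    profile: SpecificityProfile


def rank_proteases(
    profiles: Sequence[SpecificityProfile],
    *,
    ascending: bool = True,
    allow_partial: bool = False,
) -> list[RankedProfile]:
    """Stable sort by total cleavage entropy; ties break by identifier.

    Mixing complete and partial profiles is an error unless
    *allow_partial* is set, in which case partial totals are used.
    """
    if not profiles:
        return []
    if not allow_partial:
        incomplete = [p.protease_id for p in profiles if not p.complete]
        if incomplete:
            raise ValidationError(
                f"profiles with unavailable subpockets: {incomplete}; "
                "pass allow_partial=True to rank on partial totals"
            )
    keyed = [(p.partial_total()[0], p.protease_id, p) for p in profiles]
    keyed.sort(key=lambda t: (t[0], t[1]), reverse=not ascending)
    return [
        RankedProfile(rank=r, protease_id=pid, s_cleavage=total, profile=p)
        for r, (total, pid, p) in enumerate(keyed, start=1)
    ]


@dataclass
class GroupSummary:
    """Mean/min/max/sd of total and per-subpocket entropies for one group."""

    key: str
    n: int
    member_ids: list[str]
    mean_total: float
    min_total: float
    max_total: float
    sd_total: float
    mean_s: np.ndarray  # (8,)
    min_s: np.ndarray
    max_s: np.ndarray
    sd_s: np.ndarray
    degenerate: bool  # n == 1: sd reported as 0 by convention


def _sd(values: np.ndarray, sample: bool, axis=0) -> np.ndarray:
    n = values.shape[axis]
    if n < 2:
        return np.zeros(values.shape[1 - axis] if values.ndim == 2 else ())
    return values.std(axis=axis, ddof=1 if sample else 0)


def group_summary(
    profiles: Sequence[SpecificityProfile],
    grouping: Mapping[str, str] | Callable[[str], str],
    *,
    sample_sd: bool = True,
) -> list[GroupSummary]:
    """Summarize profiles per group key (e.g. catalytic type or clan).

    Every profile must map to exactly one group; an unmapped protease is
    an error.  Standard deviation is sample (n-1) by default; groups of
    one report sd 0 with the degenerate flag set.
    """
    key_of = grouping if callable(grouping) else None
    groups: dict[str, list[SpecificityProfile]] = {}
    unmapped = []
    for p in profiles:
        try:
            key = key_of(p.protease_id) if key_of else grouping[p.protease_id]
        except KeyError:
            key = None
        if key is None:
            unmapped.append(p.protease_id)
            continue
        groups.setdefault(key, []).append(p)
    if unmapped:
        raise ValidationError(f"proteases without a group: {unmapped}")
    summaries = []
    for key in sorted(groups):
        members = groups[key]
        totals = np.array([m.s_cleavage for m in members])
        s_matrix = np.vstack([m.s for m in members])  # (n, 8)
        summaries.append(
            GroupSummary(
                key=key,
                n=len(members),
                member_ids=[m.protease_id for m in members],
                mean_total=float(totals.mean()),
                min_total=float(totals.min()),
                max_total=float(totals.max()),
                sd_total=float(_sd(totals[:, None], sample_sd)[0]),
                mean_s=s_matrix.mean(axis=0),
                min_s=s_matrix.min(axis=0),
                max_s=s_matrix.max(axis=0),
                sd_s=_sd(s_matrix, sample_sd),
                degenerate=len(members) == 1,
            )
        )
    return summaries


def count_correlation(
    profiles: Sequence[SpecificityProfile],
    substrate_counts: Mapping[str, int],
) -> dict[str, float]:
    """Pearson r-squared and Spearman rank correlation of S_cleavage vs counts.

    A diagnostic for whether totals merely track dataset size.  Requires at
    least 3 proteases with both quantities; constant vectors raise
    :class:`UndefinedCorrelationError` instead of returning a number.
    """
    pairs = [
        (p.s_cleavage, substrate_counts[p.protease_id])
        for p in profiles
        if p.protease_id in substrate_counts
    ]
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 proteases with counts, got {len(pairs)}")
    s = np.array([a for a, _ in pairs], dtype=float)
    c = np.array([b for _, b in pairs], dtype=float)
    if np.allclose(s, s[0]) or np.allclose(c, c[0]):
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    r = pearsonr(s, c).statistic
    rho = spearmanr(s, c).statistic
    return {"r_squared": float(r * r), "spearman": float(rho), "n": len(pairs)}
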