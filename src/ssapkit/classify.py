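"""Screening against representative structures: tiers, tallies, scatters.

TM-scores used here are normalized by the representative's length (the
fixed yardstick), so scores are comparable across queries of different
lengths.  Tier boundaries: below < 0.5 <= moderate <= 0.7 < high, and
threshold tallies use strict "greater than".
"""

from __future__ import annotations

from dataclasses import dataclass

from .structio import StructureModel
from .superpose import align_structures

__all__ = [
    "ScreenResult",
    "ThresholdTally",
    "screen",
    "tally",
    "two_rep_scatter",
    "screen_tsv",
    "tally_tsv",
    "scatter_tsv",
]

TIER_MODERATE_LO = 0.5
TIER_HIGH_LO = 0.7
DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7)


@dataclass
class ScreenResult:
    """TM-scores of one structure against each representative."""

    id: str
    tm_per_rep: dict[str, float]
    best_tm: float
    tier: str  # below | moderate | high


@dataclass
class ThresholdTally:
    """counts[(threshold, min_reps)] = #structures exceeding the threshold
    against at least ``min_reps`` representatives."""

    thresholds: tuple[float, ...]
    n_reps: int
    counts: dict[tuple[float, int], int]


def classify_tier(best_tm: float) -> str:
    if best_tm < TIER_MODERATE_LO:
        return "below"
    if best_tm <= TIER_HIGH_LO:
        return "moderate"
    return "high"


def screen(m: StructureModel,
           reps: list[StructureModel]) -> ScreenResult:
    """Align a structure against every representative.

    The reported TM is normalized by the representative's length.
    """
    if not reps:
        raise ValueError("need at least one representative")
    tm_per_rep = {}
    for rep in reps:
        res = align_structures(m, rep)
        tm_per_rep[rep.id] = res.tm_norm_b
    best = max(tm_per_rep.values())
    return ScreenResult(id=m.id, tm_per_rep=tm_per_rep, best_tm=best,
                        tier=classify_tier(best))


def tally(results: list[ScreenResult],
          thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS) -> ThresholdTally:
    """Count structures with TM strictly above each threshold for at
    least 1..n_reps representatives."""
    if not results:
        return ThresholdTally(thresholds=thresholds, n_reps=0, counts={})
    rep_ids = set(results[0].tm_per_rep)
    for r in results:
        if set(r.tm_per_rep) != rep_ids:
            raise ValueError("inconsistent representative sets in results")
    n_reps = len(rep_ids)
    counts: dict[tuple[float, int], int] = {}
    for t in thresholds:
        n_above = [sum(1 for tm in r.tm_per_rep.values() if tm > t)
                   for r in results]
        for min_reps in range(1, n_reps + 1):
            counts[(t, min_reps)] = sum(1 for na in n_above
                                        if na >= min_reps)
    return ThresholdTally(thresholds=thresholds, n_reps=n_reps,
                          counts=counts)


def two_rep_scatter(results: list[ScreenResult], rep_x: str, rep_y: str,
                    labels: dict[str, str] | None = None,
                    ) -> list[tuple[str, float, float, str]]:
    """Per-structure (id, tm vs rep_x, tm vs rep_y, family label) rows."""
    rows = []
    for r in results:
        if rep_x not in r.tm_per_rep or rep_y not in r.tm_per_rep:
            raise KeyError(f"representative {rep_x!r}/{rep_y!r} not screened "
                           f"for {r.id}")
        lab = labels.get(r.id, "") if labels else ""
        rows.append((r.id, r.tm_per_rep[rep_x], r.tm_per_rep[rep_y], lab))
    return rows


def screen_tsv(results: list[ScreenResult]) -> str:
    if not results:
        return "id\tbest_tm\ttier\n"
    rep_ids = sorted(results[0].tm_per_rep)
    lines = ["id\t" + "\t".join(f"tm_{r}" for r in rep_ids)
             + "\tbest_tm\ttier"]
    for r in results:
        tms = "\t".join(f"{r.tm_per_rep[x]:.4f}" for x in rep_ids)
        lines.append(f"{r.id}\t{tms}\t{r.best_tm:.4f}\t{r.tier}")
    return "\n".join(lines) + "\n"


def tally_tsv(t: ThresholdTally) -> str:
    lines = ["min_reps\t" + "\t".join(f">{x:g}" for x in t.thresholds)]
    for min_reps in range(1, t.n_reps + 1):
        row = "\t".join(str(t.counts[(x, min_reps)]) for x in t.thresholds)
        lines.append(f"{min_reps}\t{row}")
    return "\n".join(lines) + "\n"


def scatter_tsv(rows: list[tuple[str, float, float, str]],
                rep_x: str, rep_y: str) -> str:
    lines = [f"id\ttm_{rep_x}\ttm_{rep_y}\tlabel"]
    lines += [f"{i}\t{x:.4f}\t{y:.4f}\t{lab}" for i, x, y, lab in rows]
    return "\n".join(lines) + "\n"
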