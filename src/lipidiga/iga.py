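"""Rank-based iterative group analysis (iGA).

iGA scores a named group of species against a ranked list of all tested
species.  With N ranked species, a group of size G whose members occupy
ranks r_1 < r_2 < ... < r_G, the probability of seeing at least x members
within the top r_x ranks by chance is the hypergeometric upper tail

    p(x) = sum_{k=x}^{min(G, r_x)} C(G, k) C(N-G, r_x - k) / C(N, r_x),

and the enrichment score ("probability of change", PC) is the minimum of
p(x) over x = 1..G.  Scanning all prefix sizes makes the score adaptive:
it needs no significance cutoff on the per-species statistics, only their
ranking.  PC values are Bonferroni-corrected over groups x directions and
called significant below 5e-4.

Tail probabilities are evaluated in exact integer arithmetic (a single
big-integer ratio), so PC values are exact to double precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Collection, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PC_SIGNIFICANCE = 5e-4


def hypergeom_upper_tail(x: int, N: int, G: int, r: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, G, r), exactly."""
    if x <= max(0, G + r - N):
        return 1.0
    num = sum(comb(G, k) * comb(N - G, r - k) for k in range(x, min(G, r) + 1))
    return num / comb(N, r)


@dataclass(frozen=True)
class RankedList:
    """Species ordered by strength of change in one tested direction."""

    species: tuple[str, ...]
    direction: str  # "up" or "down"
    statistic: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError("direction must be 'up' or 'down'")
        if len(set(self.species)) != len(self.species):
            raise ValueError("ranked list contains duplicates")

    def __len__(self) -> int:
        return len(self.species)


def rank_species(results: pd.DataFrame, direction: str, by: str = "log2fc") -> RankedList:
    """Order tested species by signed effect in ``direction``.

    ``by`` selects the ranking statistic: ``"log2fc"`` (mean paired glog2
    difference, the default) or ``"t"``.  Rank 1 is the strongest change in
    the tested direction (largest statistic for "up", smallest for
    "down"); ties break on smaller p, then lexicographic name.
    """
    if results.empty:
        raise ValueError("results table is empty")
    if by not in results.columns:
        raise ValueError(f"ranking column {by!r} not in results")
    sign = -1.0 if direction == "up" else 1.0
    ordered = results.assign(_key=sign * results[by]).sort_values(
        ["_key", "p", "species"], kind="mergesort"
    )
    return RankedList(
        species=tuple(ordered["species"]),
        direction=direction,
        statistic=tuple(ordered[by]),
    )


def iga_pc_value(
    ranked: RankedList | Sequence[str], group: Collection[str]
) -> tuple[float, int, int]:
    """Minimum hypergeometric tail over group-member prefixes.

    Returns ``(PC_raw, x_star, r_star)`` where the minimum tail is attained
    counting the first ``x_star`` group members, the last of which sits at
    rank ``r_star`` (1-based).  Raises if a group member is absent from the
    ranked list.
    """
    names = list(ranked.species) if isinstance(ranked, RankedList) else list(ranked)
    pos = {name: i + 1 for i, name in enumerate(names)}
    group = set(group)
    if not group:
        raise ValueError("group is empty")
    absent = sorted(g for g in group if g not in pos)
    if absent:
        raise ValueError(f"group members absent from ranked list: {absent}")
    N = len(names)
    ranks = sorted(pos[g] for g in group)
    G = len(ranks)
    pc, x_star, r_star = 1.0, 1, ranks[0]
    for x, r in enumerate(ranks, start=1):
        p = hypergeom_upper_tail(x, N, G, r)
        if p < pc:
            pc, x_star, r_star = p, x, r
    return pc, x_star, r_star


def correct_pc(results: pd.DataFrame, n_tests: int | None = None) -> pd.DataFrame:
    """Bonferroni-correct raw PC values over all groups x directions.

    ``PC_corrected = min(1, PC_raw * n_tests)``; significance at the
    conventional 5e-4 threshold.  ``n_tests`` defaults to the number of
    rows (each row is one group x direction test).
    """
    n = n_tests if n_tests is not None else len(results)
    out = results.copy()
    out["pc_corrected"] = (out["pc_raw"] * n).clip(upper=1.0)
    out["significant"] = out["pc_corrected"] < PC_SIGNIFICANCE
    out.attrs["pc_correction"] = f"bonferroni x {n} (groups x directions)"
    out.attrs["pc_significance_threshold"] = PC_SIGNIFICANCE
    return out


def run_iga(results: pd.DataFrame, scheme, by: str = "log2fc") -> pd.DataFrame:
    """Score every group of ``scheme`` in both directions.

    Groups are intersected with the tested (post-filter) species universe;
    groups losing all members are skipped with a log entry.  Returns one
    row per group x direction with columns (group, direction, pc_raw,
    pc_corrected, x_star, r_star, significant).
    """
    universe = list(results["species"])
    restricted = scheme.restrict(universe)
    skipped = [g for g in scheme.groups if g not in restricted]
    if skipped:
        logger.info("groups with no surviving members skipped: %s", skipped)
    if not restricted:
        raise ValueError("no scheme group intersects the tested species")
    rows = []
    for direction in ("up", "down"):
        ranked = rank_species(results, direction, by=by)
        for label, members in restricted.items():
            pc, x_star, r_star = iga_pc_value(ranked, members)
            rows.append(
                {
                    "group": label,
                    "direction": direction,
                    "pc_raw": pc,
                    "x_star": x_star,
                    "r_star": r_star,
                    "n_members": len(members),
                }
            )
    table = correct_pc(pd.DataFrame(rows), n_tests=len(rows))
    attrs = dict(table.attrs)
    table = table[
        ["group", "direction", "pc_raw", "pc_corrected", "x_star", "r_star", "n_members", "significant"]
    ]
    table.attrs.update(attrs)
    table.attrs["ranking_statistic"] = by
    table.attrs["skipped_groups"] = skipped
    return table
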