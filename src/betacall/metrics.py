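"""Count-threshold baseline caller and genotype-concordance benchmarking.

The naive baseline calls a genotype from the alt-allele read fraction
r = n_alt / n_total alone: r < t → hom-ref, r > 1-t → hom-alt, otherwise het
(band boundaries inclusive to the het genotype).  Benchmarking compares hard
calls against a gold standard, stratified by the truth genotype, with the
het→hom / hom→het error taxonomy that matters for allele-specific-expression
work: a homozygote miscalled as heterozygous fabricates a perfect allelic
imbalance signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .core import AlleleCount

__all__ = [
    "BaselineCall",
    "ConcordanceTable",
    "count_threshold_call",
    "count_threshold_calls",
    "concordance_by_genotype",
    "accuracy_vs_depth",
    "dosage_concordance",
]


class BaselineCall(NamedTuple):
    """Minimal call record (duck-compatible with GenotypeCall for
    benchmarking)."""

    site_id: str
    hard_call: int | None
    n_alt: int
    n_total: int


def count_threshold_call(count: AlleleCount, t: float = 0.1) -> int | None:
    """Naive genotype from the alt-read fraction with threshold ``t``.

    Returns None (missing) when the site has no reads.
    """
    if not 0.0 < t < 0.5:
        raise ValueError(f"count threshold must lie in (0, 0.5); got {t}")
    if count.n_total == 0:
        return None
    r = count.n_alt / count.n_total
    if r < t:
        return 0
    if r > 1.0 - t:
        return 2
    return 1


def count_threshold_calls(counts: Iterable[AlleleCount], t: float = 0.1) -> list[BaselineCall]:
    return [
        BaselineCall(c.site_id, count_threshold_call(c, t), c.n_alt, c.n_total)
        for c in counts
    ]


@dataclass
class ConcordanceTable:
    """Concordant / discordant / missing tallies stratified by the truth
    genotype, plus the het↔hom error counts."""

    concordant: dict = field(default_factory=lambda: {0: 0, 1: 0, 2: 0})
    discordant: dict = field(default_factory=lambda: {0: 0, 1: 0, 2: 0})
    missing: dict = field(default_factory=lambda: {0: 0, 1: 0, 2: 0})
    het_to_hom: int = 0
    hom_to_het: int = 0

    def n_compared(self, g: int | None = None) -> int:
        if g is None:
            return sum(self.concordant.values()) + sum(self.discordant.values())
        return self.concordant[g] + self.discordant[g]

    def accuracy(self, g: int | None = None) -> float:
        """Fraction concordant among non-missing calls, overall or for one
        truth-genotype stratum; NaN when nothing was compared."""
        n = self.n_compared(g)
        if n == 0:
            return math.nan
        if g is None:
            return sum(self.concordant.values()) / n
        return self.concordant[g] / n

    def n_total(self) -> int:
        return self.n_compared() + sum(self.missing.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "truth_genotype": g,
                "concordant": self.concordant[g],
                "discordant": self.discordant[g],
                "missing": self.missing[g],
                "accuracy": self.accuracy(g),
            }
            for g in (0, 1, 2)
        ]
        rows.append(
            {
                "truth_genotype": "all",
                "concordant": sum(self.concordant.values()),
                "discordant": sum(self.discordant.values()),
                "missing": sum(self.missing.values()),
                "accuracy": self.accuracy(),
            }
        )
        return pd.DataFrame(rows)


def concordance_by_genotype(
    calls: Iterable,
    truth: Mapping[str, int],
    min_depth: int = 10,
) -> ConcordanceTable:
    """Compare hard calls against a gold standard, stratified by the truth
    genotype.

    Only sites present in ``truth`` with depth >= ``min_depth`` enter.
    Missing calls are tallied separately and excluded from the accuracy
    denominator.  Calls must expose ``site_id``, ``hard_call`` and
    ``n_total`` attributes.
    """
    if not truth:
        raise ValueError("empty truth genotype map")
    table = ConcordanceTable()
    seen: set[str] = set()
    for call in calls:
        sid = call.site_id
        if sid in seen:
            raise ValueError(f"duplicated site_id in calls: {sid}")
        seen.add(sid)
        if sid not in truth or call.n_total < min_depth:
            continue
        g_true = truth[sid]
        if g_true not in (0, 1, 2):
            continue  # ungenotyped truth entries are not errors
        g_call = call.hard_call
        if g_call is None:
            table.missing[g_true] += 1
        elif g_call == g_true:
            table.concordant[g_true] += 1
        else:
            table.discordant[g_true] += 1
            if g_true == 1:
                table.het_to_hom += 1
            elif g_call == 1:
                table.hom_to_het += 1
    return table


def accuracy_vs_depth(
    calls: Iterable,
    truth: Mapping[str, int],
    depth_grid: list[int],
) -> pd.DataFrame:
    """Aggregate call accuracy swept over minimum-depth thresholds.

    Returns one row per threshold with columns (min_depth, accuracy,
    n_calls, n_missing); n_calls is non-increasing in the threshold.
    """
    if not depth_grid:
        raise ValueError("empty depth grid")
    if list(depth_grid) != sorted(depth_grid):
        raise ValueError("depth grid must be ascending")
    calls = list(calls)
    rows = []
    for d in depth_grid:
        t = concordance_by_genotype(calls, truth, min_depth=d)
        rows.append(
            {
                "min_depth": d,
                "accuracy": t.accuracy(),
                "n_calls": t.n_compared(),
                "n_missing": sum(t.missing.values()),
            }
        )
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def dosage_concordance(
    dosages: Iterable[tuple[str, float]],
    truth: Mapping[str, int],
) -> float:
    """Fraction of sites whose dosage, rounded half-away-from-zero, equals
    the truth genotype."""
    n = hits = 0
    for sid, d in dosages:
        if not 0.0 <= d <= 2.0:
            raise ValueError(f"{sid}: dosage {d} outside [0, 2]")
        if sid not in truth:
            raise KeyError(f"{sid}: site not present in truth genotypes")
        n += 1
        hits += _round_half_away(d) == truth[sid]
    if n == 0:
        raise ValueError("no sites to compare")
    return hits / n
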