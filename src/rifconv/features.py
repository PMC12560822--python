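"""Comparative genome-feature arithmetic: density, summaries, PSG overlap.

Covers the small printed-number arithmetic of a comparative-genomics
survey: per-genome gene density (gene models per Mb), per-group mean/SD and
range summaries of assembly statistics, the percentage of positively
selected genes (PSGs) shared across foreground lineages, and a Wilcoxon
rank-sum comparison between groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RifconvError


def gene_density(protein_count: int, genome_size_bp: int) -> int:
    """Protein-coding gene models per megabase, rounded half-up to an integer."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if protein_count < 0:
        raise ValueError("protein count must be nonnegative")
    return int(math.floor(protein_count / (genome_size_bp / 1e6) + 0.5))


def group_summary(table: pd.DataFrame, field: str,
                  as_mb: bool = False) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1), min and max of one numeric field.

    With ``as_mb=True`` base-pair fields are converted to megabases and
    reported to the conventions of published assembly tables: means/SDs
    rounded to 2 decimals, ranges truncated to 1 decimal (29,490,499 bp
    prints as 29.4 Mb).  A single-record group reports SD as NA.
    """
    if field not in table.columns:
        raise RifconvError(f"unknown field {field!r}")
    if not len(table):
        raise RifconvError("empty table")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        vals = sub[field].to_numpy(dtype=float)
        if vals.size == 0:
            raise RifconvError(f"empty group {group!r}")
        if as_mb:
            vals = vals / 1e6
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        lo, hi = float(vals.min()), float(vals.max())
        if as_mb:
            mean, sd = round(mean, 2), round(sd, 2) if vals.size > 1 else sd
            lo, hi = math.floor(lo * 10) / 10, math.floor(hi * 10) / 10
        rows.append({"group": group, "n": int(vals.size), "mean": mean,
                     "sd": sd, "min": lo, "max": hi})
    return pd.DataFrame(rows)


@dataclass
class OverlapSummary:
    """Intersection of per-lineage PSG sets against a tested-gene universe."""

    universe_size: int
    set_sizes: list[int]
    intersection: frozenset
    shared_pct: float

    @property
    def n_shared(self) -> int:
        return len(self.intersection)


def shared_psg_summary(sets, universe_size: int) -> OverlapSummary:
    """Fraction of the tested-ortholog universe shared by every lineage's PSGs."""
    sets = [frozenset(s) for s in sets]
    if not sets:
        raise RifconvError("need at least one PSG set")
    union = frozenset().union(*sets)
    if universe_size < len(union):
        raise RifconvError(
            f"universe size {universe_size} smaller than union {len(union)}"
        )
    inter = sets[0]
    for s in sets[1:]:
        inter &= s
    pct = round(100.0 * len(inter) / universe_size, 2)
    return OverlapSummary(universe_size=universe_size,
                          set_sizes=[len(s) for s in sets],
                          intersection=inter, shared_pct=pct)


EXACT_N_CUTOFF = 10


def rank_sum_test(group_a, group_b, alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum comparison of two samples.

    Exact enumeration when both samples have at most :data:`EXACT_N_CUTOFF`
    values and no ties; otherwise the normal approximation with continuity
    and tie correction.  Returns ``{"p", "statistic", "method"}``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; p = 1",
                      RuntimeWarning, stacklevel=2)
        return {"p": 1.0, "statistic": float(a.size * b.size / 2),
                "method": "degenerate"}
    ties = len(np.unique(pooled)) < pooled.size
    if a.size <= EXACT_N_CUTOFF and b.size <= EXACT_N_CUTOFF and not ties:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative,
                                 method="asymptotic", use_continuity=True)
        method = "normal-approximation"
    return {"p": float(res.pvalue), "statistic": float(res.statistic),
            "method": method}
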