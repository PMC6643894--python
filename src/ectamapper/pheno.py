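"""Screen quantification: penetrance statistics and intensity-based ploidy.

Penetrance (fraction of animals of a genotype showing the phenotype) is
reported with Wilson score intervals — many screen genotypes sit near 0%
or 100%, where the Wald interval degenerates. Two-genotype contrasts use
the Newcombe hybrid score interval on the difference plus Fisher's exact
test. Ploidy of endoreduplicating nuclei is estimated from integrated
DAPI intensity normalized to diploid (2N) reference nuclei and classed to
the nearest power-of-two multiple of 2N.

The published screen reports neither intervals nor tests; those are added
quantification utilities of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PenetranceResult",
    "PloidyEstimate",
    "penetrance",
    "display_percent",
    "consistent_count",
    "compare_penetrance",
    "ComparisonResult",
    "estimate_ploidy",
    "read_counts_tsv",
    "read_nuclei_tsv",
]


def display_percent(k: int, n: int) -> float:
    """100·k/n rounded half-up to one decimal, as printed in screen tables."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(
        (Decimal(100 * k) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class PenetranceResult:
    k: int
    n: int
    proportion: float  # percent, exact
    display: float  # percent, rounded half-up to one decimal
    ci: tuple[float, float]  # percent
    level: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


def penetrance(k: int, n: int, level: float = 0.95) -> PenetranceResult:
    """Penetrance point estimate with a Wilson score interval (in percent)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the Wilson lower (upper) limit is exactly 0 (1) at k=0 (k=n);
    # clamp floating-point residue so reported CIs stay within [0, 100]
    low = 0.0 if k == 0 else max(float(low), 0.0)
    high = 1.0 if k == n else min(float(high), 1.0)
    return PenetranceResult(
        k=k,
        n=n,
        proportion=100.0 * k / n,
        display=display_percent(k, n),
        ci=(100.0 * low, 100.0 * high),
        level=level,
    )


def consistent_count(percent: float, n: int) -> Optional[int]:
    """Invert a printed percentage: the unique k with 100k/n printing as it.

    Returns the affected count k if exactly one integer in 0..n rounds
    (half-up, one decimal) to *percent*; ``None`` flags a printed figure
    that is arithmetically inconsistent with its stated n.
    """
    target = float(Decimal(str(percent)).quantize(Decimal("0.1"), ROUND_HALF_UP))
    hits = [k for k in range(n + 1) if display_percent(k, n) == target]
    return hits[0] if len(hits) == 1 else None


@dataclass(frozen=True)
class ComparisonResult:
    difference: float  # percent, a - b
    ci: tuple[float, float]  # percent, Newcombe hybrid score interval
    p_value: float  # Fisher exact, two-sided


def compare_penetrance(
    a: PenetranceResult, b: PenetranceResult, level: float = 0.95
) -> ComparisonResult:
    """Two-proportion contrast: difference, Newcombe interval, Fisher exact p.

    The Newcombe hybrid interval combines the two Wilson limits:
    lower = d − sqrt((p1−l1)² + (u2−p2)²), upper = d + sqrt((u1−p1)² + (p2−l2)²).
    """
    p1, p2 = a.k / a.n, b.k / b.n
    l1, u1 = proportion_confint(a.k, a.n, alpha=1 - level, method="wilson")
    l2, u2 = proportion_confint(b.k, b.n, alpha=1 - level, method="wilson")
    d = p1 - p2
    lower = d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    table = [[a.k, a.n - a.k], [b.k, b.n - b.k]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ComparisonResult(100 * d, (100 * lower, 100 * upper), float(p))


@dataclass(frozen=True)
class PloidyEstimate:
    nucleus_id: str
    intensity: float
    ploidy: float  # continuous estimate, 2·I / mean reference I
    ploidy_class: int  # nearest 2^j · 2N class
    is_reference: bool

    @property
    def class_label(self) -> str:
        return f"{self.ploidy_class}N"


def estimate_ploidy(nuclei: pd.DataFrame) -> list[PloidyEstimate]:
    """Estimate nuclear ploidy from integrated DNA-stain intensity.

    *nuclei* needs columns ``nucleus_id``, ``intensity`` and
    ``is_reference``; reference nuclei are diploid (2N, e.g. tail
    neurons). Each nucleus gets ploidy = 2·I / mean(reference I), and a
    discrete class 2^j·2N with j = round(log2(ploidy/2)) (ties round to
    the even exponent) — endoreduplication doubles genome content, so
    classes are powers of two times 2N. Estimates are invariant to any
    common intensity scale factor.
    """
    required = {"nucleus_id", "intensity", "is_reference"}
    missing = required - set(nuclei.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (nuclei["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    ref = nuclei.loc[nuclei["is_reference"].astype(bool), "intensity"]
    if ref.empty:
        raise ValueError("at least one reference (2N) nucleus is required")
    mean_ref = float(ref.mean())
    out = []
    for row in nuclei.itertuples(index=False):
        ploidy = 2.0 * float(row.intensity) / mean_ref
        j = int(np.round(np.log2(ploidy / 2.0)))
        ploidy_class = max(int(round(2.0 ** j * 2.0)), 1)
        out.append(
            PloidyEstimate(
                nucleus_id=str(row.nucleus_id),
                intensity=float(row.intensity),
                ploidy=ploidy,
                ploidy_class=ploidy_class,
                is_reference=bool(row.is_reference),
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV input


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a (strain, k, n) penetrance count table."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "k", "n"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_nuclei_tsv(path: str | Path) -> pd.DataFrame:
    """Read a (nucleus_id, intensity, is_reference) intensity table."""
    df = pd.read_csv(path, sep="\t")
    required = {"nucleus_id", "intensity", "is_reference"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
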