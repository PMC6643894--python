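"""Linkage mapping from pooled allele frequencies.

Phenotype-selected F2 pools deplete the mapping-strain allele around the
causal locus: observed frequency approaches 0 at the locus and 0.5 on
unlinked chromosomes. The mapping core computes per-marker observed
frequencies, smooths them per chromosome with locally weighted linear
regression (loess, implemented here from scratch with tricube weights),
calls the linked chromosome as the argmin of the fitted curves, and
reports the candidate interval as the contiguous sub-threshold run of
markers around the curve's minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cross import AlleleCounts
from .genome import GenomeBuild

__all__ = [
    "FrequencyProfile",
    "LoessConfig",
    "LinkageCall",
    "marker_allele_frequencies",
    "loess_fit",
    "fit_profiles",
    "call_linked_chromosome",
    "candidate_interval",
    "write_profile_tsv",
    "write_interval_bed",
    "plot_profiles",
]


@dataclass
class FrequencyProfile:
    """Observed (and, after fitting, smoothed) mapping-allele frequencies."""

    chrom: str
    positions: np.ndarray
    observed_freq: np.ndarray
    depth: np.ndarray
    fitted_freq: Optional[np.ndarray] = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.observed_freq) == len(self.depth)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")


@dataclass
class LoessConfig:
    """Loess settings: span (fraction of points per local fit) and degree."""

    span: float = 0.3
    degree: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if self.degree not in (0, 1):
            raise ValueError("degree must be 0 or 1")


@dataclass
class LinkageCall:
    """The called chromosome, its fitted minimum, and the candidate interval."""

    chrom: str
    min_fitted_freq: float
    linked: bool
    interval: Optional[tuple[int, int]] = None


def marker_allele_frequencies(
    counts: AlleleCounts, min_depth: int = 5
) -> dict[str, FrequencyProfile]:
    """Per-chromosome observed mapping-allele frequency at covered markers.

    f = map_count / (ref_count + map_count) wherever depth >= *min_depth*;
    shallower markers are excluded and counted, never silently dropped.
    The default floor of 5 reads suppresses error-rate-driven outliers at
    low coverage. Raises if no marker passes on any chromosome.
    """
    depth = counts.depth
    profiles: dict[str, FrequencyProfile] = {}
    chroms = list(dict.fromkeys(counts.chrom.tolist()))
    for chrom in chroms:
        on = counts.chrom == chrom
        ok = on & (depth >= min_depth)
        n_excluded = int(on.sum() - ok.sum())
        if not ok.any():
            profiles[chrom] = FrequencyProfile(
                chrom,
                np.empty(0, dtype=np.int64),
                np.empty(0),
                np.empty(0, dtype=np.int64),
                n_excluded=n_excluded,
            )
            continue
        pos = counts.pos[ok]
        order = np.argsort(pos, kind="stable")
        with np.errstate(invalid="ignore"):
            f = counts.map_count[ok] / depth[ok]
        profiles[chrom] = FrequencyProfile(
            chrom,
            pos[order],
            f[order],
            depth[ok][order],
            n_excluded=n_excluded,
        )
    if all(len(p.positions) == 0 for p in profiles.values()):
        raise ValueError(f"no marker reaches depth {min_depth} on any chromosome")
    return profiles


def loess_fit(
    x: np.ndarray, y: np.ndarray, config: Optional[LoessConfig] = None
) -> np.ndarray:
    """Locally weighted polynomial regression, evaluated at the input points.

    For each point x_i the ceil(span*n) nearest neighbors by |x - x_i| are
    taken, weighted by the tricube kernel w = (1 - (d/d_max)^3)^3, and a
    weighted least-squares polynomial of the configured degree is fitted
    and evaluated at x_i. No robustness iterations are applied (classic
    first-degree loess). Degenerate neighborhoods (all weights zero, e.g.
    heavily duplicated x) fall back to the plain neighbor mean.
    """
    if config is None:
        config = LoessConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < config.degree + 1:
        raise ValueError(f"need at least {config.degree + 1} points")
    k = max(int(np.ceil(config.span * n)), config.degree + 1)
    k = min(k, n)

    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nn = np.argsort(d, kind="stable")[:k]
        dmax = d[nn].max()
        yn = y[nn]
        if dmax == 0.0:
            fitted[i] = yn.mean()
            continue
        w = (1.0 - (d[nn] / dmax) ** 3) ** 3
        w[w < 0] = 0.0
        pos = w > 0
        if not pos.any():
            fitted[i] = yn.mean()
            continue
        if config.degree == 0 or pos.sum() < 2:
            fitted[i] = float(np.sum(w * yn) / np.sum(w))
            continue
        # weighted linear fit on centered x; value at x_i is the intercept
        xc = x[nn] - x[i]
        sw = np.sqrt(w)
        design = np.column_stack([sw, sw * xc])
        coef, *_ = np.linalg.lstsq(design, sw * yn, rcond=None)
        fitted[i] = coef[0]
    if not np.all(np.isfinite(fitted)):
        raise FloatingPointError("loess produced non-finite values")
    return fitted


def fit_profiles(
    profiles: dict[str, FrequencyProfile], config: Optional[LoessConfig] = None
) -> dict[str, FrequencyProfile]:
    """Fit the loess curve on every chromosome's profile, in place."""
    if config is None:
        config = LoessConfig()
    for p in profiles.values():
        if len(p.positions) == 0:
            p.fitted_freq = np.empty(0)
        elif len(p.positions) < config.degree + 1:
            p.fitted_freq = p.observed_freq.astype(float).copy()
        else:
            p.fitted_freq = loess_fit(
                p.positions.astype(float), p.observed_freq, config
            )
    return profiles


def call_linked_chromosome(
    profiles: dict[str, FrequencyProfile] | Sequence[FrequencyProfile],
    link_threshold: float = 0.25,
) -> LinkageCall:
    """Call the chromosome linked to the selected phenotype.

    The linked chromosome is the argmin over chromosomes of the minimum
    fitted mapping-allele frequency, provided that minimum falls below
    *link_threshold* (default 0.25, midway between the causal-locus
    expectation of 0 and the unlinked 0.5). Ties break to the earliest
    chromosome in input order, with a warning. If no chromosome passes,
    the call is returned with ``linked=False``.
    """
    plist = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    if not plist:
        raise ValueError("no profiles")
    minima: list[tuple[str, float]] = []
    for p in plist:
        if len(p.positions) == 0:
            continue
        if p.fitted_freq is None:
            raise ValueError(f"profile {p.chrom} is unfitted")
        minima.append((p.chrom, float(np.min(p.fitted_freq))))
    if not minima:
        raise ValueError("no profile carries any covered marker")
    best_val = min(v for _, v in minima)
    winners = [c for c, v in minima if v == best_val]
    if len(winners) > 1:
        warnings.warn(
            f"linkage tie between {winners}; keeping {winners[0]}", stacklevel=2
        )
    chrom = winners[0]
    return LinkageCall(chrom, best_val, linked=best_val < link_threshold)


def candidate_interval(
    profile: FrequencyProfile, interval_threshold: float = 0.25
) -> tuple[int, int]:
    """Candidate region: the sub-threshold marker run around the fitted minimum.

    The maximal contiguous run of markers whose fitted frequency is below
    *interval_threshold* and which contains the curve's argmin. Endpoints
    are the outermost such marker positions; the interval always contains
    at least the argmin marker.
    """
    if profile.fitted_freq is None or len(profile.fitted_freq) == 0:
        raise ValueError("profile is unfitted or empty")
    fitted = profile.fitted_freq
    imin = int(np.argmin(fitted))
    if fitted[imin] >= interval_threshold:
        raise ValueError(
            "profile is not linked at this threshold; no candidate interval"
        )
    lo = imin
    while lo > 0 and fitted[lo - 1] < interval_threshold:
        lo -= 1
    hi = imin
    while hi < len(fitted) - 1 and fitted[hi + 1] < interval_threshold:
        hi += 1
    return int(profile.positions[lo]), int(profile.positions[hi])


# ---------------------------------------------------------------------------
# Reports


def write_profile_tsv(
    profiles: dict[str, FrequencyProfile], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tdepth\tobserved_freq\tfitted_freq\n")
        for chrom in profiles:
            p = profiles[chrom]
            fitted = (
                p.fitted_freq
                if p.fitted_freq is not None
                else np.full(len(p.positions), np.nan)
            )
            for i in range(len(p.positions)):
                fh.write(
                    f"{chrom}\t{int(p.positions[i])}\t{int(p.depth[i])}\t"
                    f"{p.observed_freq[i]:.6f}\t{fitted[i]:.6f}\n"
                )


def write_interval_bed(
    call: LinkageCall, path: str | Path, name: str = "candidate_interval"
) -> None:
    """BED (0-based half-open) record of the candidate interval."""
    with open(path, "w") as fh:
        if call.linked and call.interval is not None:
            start, end = call.interval
            fh.write(f"{call.chrom}\t{start - 1}\t{end}\t{name}\n")


def plot_profiles(
    profiles: dict[str, FrequencyProfile],
    path: str | Path,
    call: Optional[LinkageCall] = None,
) -> None:
    """One panel per chromosome: observed frequencies with the loess curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(profiles)
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3.2 * len(chroms), 3.2), sharey=True
    )
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        p = profiles[chrom]
        mb = p.positions / 1e6
        ax.scatter(mb, p.observed_freq, s=6, alpha=0.5, color="gray")
        if p.fitted_freq is not None and len(p.fitted_freq):
            ax.plot(mb, p.fitted_freq, color="crimson", lw=1.8)
        ax.axhline(0.5, ls=":", color="black", lw=0.8)
        if call is not None and call.linked and call.chrom == chrom and call.interval:
            ax.axvspan(
                call.interval[0] / 1e6,
                call.interval[1] / 1e6,
                color="gold",
                alpha=0.3,
            )
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
        ax.set_ylim(-0.02, 1.0)
    axes[0].set_ylabel("mapping-strain allele frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
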