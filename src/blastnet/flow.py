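"""LAIP scoring of flow-cytometry marker intensities.

Each marker's log10 fluorescence distribution over the leukemic blasts is
scored on a four-level scale — negative (-), positive-dim (+), positive-
normal (++), positive-bright (+++) — against reference intervals derived
from normal bone-marrow lymphocyte subsets.  Markers with two density peaks
whose subpopulations each exceed 1% of the blasts are called bimodal and
every subpopulation is scored, with the overall score taken from the
dominant (largest) subpopulation.  A single peak whose 10%-of-maximum
density extent spans at least 1.5 score units (B-lineage and non-lineage
markers) or 1.5 log10 decades (cross-lineage markers) is called broad.

Peak detection runs on a binned kernel density estimate (Silverman
bandwidth); events are assigned to the density basin of their nearest peak,
and subpopulations at or below the 1% reporting limit are merged into the
nearest larger one before modality is decided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SCORE_LEVELS",
    "B_LINEAGE_MARKERS",
    "NONLINEAGE_MARKERS",
    "CROSS_LINEAGE_MARKERS",
    "PANEL",
    "ReferenceInterval",
    "Subpopulation",
    "MarkerScore",
    "LAIPProfile",
    "build_reference_intervals",
    "detect_subpopulations",
    "score_marker",
    "score_events",
    "binarize_score",
]

SCORE_LEVELS = ("-", "+", "++", "+++")

B_LINEAGE_MARKERS = ("CD19", "CD20", "CD22", "nTdT", "cyCD79a", "cyCD22")
NONLINEAGE_MARKERS = ("CD45", "CD34", "CD38", "CD10")
CROSS_LINEAGE_MARKERS = ("CD123", "CD66c", "CD133", "CD13", "CD33", "CD15")
PANEL = B_LINEAGE_MARKERS + NONLINEAGE_MARKERS + CROSS_LINEAGE_MARKERS

#: markers binarized as neg vs dim/pos/bright instead of neg/dim vs pos/bright
DIM_COUNTS_POSITIVE = frozenset({"CD15", "CD133"})

#: subpopulations at or below this blast fraction are merged away
MIN_SUBPOPULATION_FRACTION = 0.01

#: peaks with prominence below this fraction of the global density maximum
#: are treated as noise
DEFAULT_PROMINENCE_FLOOR = 0.05

#: minimal number of events for density-based modality calling
MIN_EVENTS = 200

#: broad expression: single peak whose 10%-of-peak extent spans at least
#: this many score units (B-/non-lineage) or log10 decades (cross-lineage)
BROAD_EXTENT = 1.5
BROAD_DENSITY_FRACTION = 0.10


@dataclass(frozen=True)
class ReferenceInterval:
    """Four-level scoring boundaries for one marker, log10 fluorescence."""

    marker: str
    marker_class: str  # "B-lineage" | "nonlineage" | "cross-lineage"
    boundaries: tuple[float, float, float]

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (b[0] < b[1] < b[2]):
            raise ValueError(
                f"{self.marker}: boundaries must be strictly ascending, got {b}"
            )

    @property
    def score_unit(self) -> float:
        """Width of one score level in log10 units."""
        return (self.boundaries[2] - self.boundaries[0]) / 3.0

    def classify(self, mfi: float) -> str:
        """Score level of an MFI; boundary values go to the higher level."""
        b = self.boundaries
        if mfi < b[0]:
            return "-"
        if mfi < b[1]:
            return "+"
        if mfi < b[2]:
            return "++"
        return "+++"


@dataclass(frozen=True)
class Subpopulation:
    fraction: float
    mfi: float
    score: str


@dataclass
class MarkerScore:
    marker: str
    modality: str  # "unimodal" | "bimodal" | "broad"
    subpopulations: list[Subpopulation]
    overall_score: str
    mfi_overall: float


@dataclass
class LAIPProfile:
    """Per-patient collection of marker scores."""

    patient_id: str
    marker_scores: dict[str, MarkerScore] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, ms in self.marker_scores.items():
            rows.append(
                {
                    "patient": self.patient_id,
                    "marker": m,
                    "score": ms.overall_score,
                    "modality": ms.modality,
                    "mfi": ms.mfi_overall,
                    "fractions": "/".join(
                        f"{sp.fraction:.3f}" for sp in ms.subpopulations
                    ),
                    "binary": binarize_score(ms),
                }
            )
        return pd.DataFrame(rows)


class DegenerateIntervalError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


def build_reference_intervals(
    control_tables: Mapping[str, pd.DataFrame],
    quantile_spec: Mapping[str, float] | None = None,
    marker_classes: Mapping[str, str] | None = None,
) -> dict[str, ReferenceInterval]:
    """Derive scoring boundaries from control bone-marrow samples.

    ``control_tables`` maps marker -> events table with columns ``value``
    (log10 fluorescence) and ``population`` ("negative" for the marker-
    negative lymphocyte subset, "positive" for the normal-positive subset).
    Tables from several control samples should be concatenated (events are
    pooled).

    The default quantile rule places the neg/dim boundary at the 99.5th
    percentile of the negative population and the dim/normal and
    normal/bright boundaries at the quartiles of the positive population.
    """
    spec = {"neg_quantile": 0.995, "pos_lower": 0.25, "pos_upper": 0.75}
    if quantile_spec:
        spec.update(quantile_spec)
    marker_classes = marker_classes or {}
    intervals: dict[str, ReferenceInterval] = {}
    for marker, table in control_tables.items():
        if table.empty:
            raise ValueError(f"{marker}: empty control table")
        neg = table.loc[table["population"] == "negative", "value"].to_numpy(float)
        pos = table.loc[table["population"] == "positive", "value"].to_numpy(float)
        if neg.size == 0 or pos.size == 0:
            raise ValueError(f"{marker}: need both negative and positive control events")
        b1 = float(np.quantile(neg, spec["neg_quantile"]))
        b2 = float(np.quantile(pos, spec["pos_lower"]))
        b3 = float(np.quantile(pos, spec["pos_upper"]))
        if not (b1 < b2 < b3):
            raise DegenerateIntervalError(
                f"{marker}: degenerate reference boundaries ({b1}, {b2}, {b3})"
            )
        intervals[marker] = ReferenceInterval(
            marker=marker,
            marker_class=marker_classes.get(marker, _default_class(marker)),
            boundaries=(b1, b2, b3),
        )
    return intervals


def _default_class(marker: str) -> str:
    if marker in B_LINEAGE_MARKERS:
        return "B-lineage"
    if marker in CROSS_LINEAGE_MARKERS:
        return "cross-lineage"
    return "nonlineage"


def _kde_grid(x: np.ndarray, n_bins: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Binned Gaussian KDE with Silverman bandwidth; returns (grid, density)."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * x.size ** (-0.2)
    if bw <= 0:
        bw = 1e-3  # all-equal events: nominal bandwidth, single sharp peak
    lo, hi = x.min() - 4 * bw, x.max() + 4 * bw
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    width = edges[1] - edges[0]
    density = gaussian_filter1d(counts.astype(float), sigma=bw / width, mode="constant")
    density /= x.size * width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def detect_subpopulations(
    events: Sequence[float] | np.ndarray | pd.Series,
    reference: ReferenceInterval,
    prominence_floor: float = DEFAULT_PROMINENCE_FLOOR,
) -> tuple[str, list[Subpopulation]]:
    """Density-based modality call and subpopulation decomposition.

    Returns (modality, subpopulations); subpopulations are ordered by
    fraction descending and each carries its own four-level score.
    """
    x = np.asarray(events, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_EVENTS:
        raise InsufficientDataError(
            f"{reference.marker}: need >= {MIN_EVENTS} events, got {x.size}"
        )
    grid, density = _kde_grid(x)
    # zero-pad so boundary maxima are still detected as peaks
    padded = np.concatenate([[0.0], density, [0.0]])
    peaks, _ = signal.find_peaks(padded, prominence=prominence_floor * padded.max())
    peaks = peaks - 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(density))])

    # basin boundaries: density minima between adjacent peaks
    cuts = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        cuts.append(grid[left + int(np.argmin(density[left : right + 1]))])
    assignment = np.digitize(x, cuts)  # event -> peak index

    fractions = np.array([(assignment == i).mean() for i in range(peaks.size)])
    groups = [x[assignment == i] for i in range(peaks.size)]
    peak_pos = list(grid[peaks])

    # merge sub-1% populations into the nearest larger population
    while fractions.size > 1 and fractions.min() <= MIN_SUBPOPULATION_FRACTION:
        i = int(np.argmin(fractions))
        candidates = [j for j in range(fractions.size) if j != i]
        j = min(candidates, key=lambda j: abs(peak_pos[j] - peak_pos[i]))
        groups[j] = np.concatenate([groups[j], groups[i]])
        fractions[j] += fractions[i]
        del groups[i], peak_pos[i]
        fractions = np.delete(fractions, i)

    if fractions.size >= 2:
        modality = "bimodal"
    else:
        modality = "broad" if _is_broad(grid, density, reference) else "unimodal"

    subpops = [
        Subpopulation(
            fraction=float(f),
            mfi=float(np.median(g)),
            score=reference.classify(float(np.median(g))),
        )
        for f, g in zip(fractions, groups)
    ]
    subpops.sort(key=lambda sp: (-sp.fraction, sp.mfi))
    return modality, subpops


def _is_broad(grid: np.ndarray, density: np.ndarray, reference: ReferenceInterval) -> bool:
    """Single-peak width at 10% of peak height against the 1.5-unit rule."""
    peak_height = density.max()
    above = density >= BROAD_DENSITY_FRACTION * peak_height
    extent = grid[above][-1] - grid[above][0]
    if reference.marker_class == "cross-lineage":
        threshold = BROAD_EXTENT  # decades of log10 fluorescence
    else:
        threshold = BROAD_EXTENT * reference.score_unit
    return bool(extent >= threshold)


def score_marker(
    modality: str,
    subpopulations: Sequence[Subpopulation],
    reference: ReferenceInterval,
    mfi_overall: float,
) -> MarkerScore:
    """Overall marker score from its subpopulation decomposition.

    The overall score is that of the dominant (largest-fraction)
    subpopulation; fraction ties go to the brighter subpopulation.
    """
    if not subpopulations:
        raise ValueError(f"{reference.marker}: no subpopulations to score")
    dominant = max(subpopulations, key=lambda sp: (sp.fraction, sp.mfi))
    return MarkerScore(
        marker=reference.marker,
        modality=modality,
        subpopulations=list(subpopulations),
        overall_score=dominant.score,
        mfi_overall=float(mfi_overall),
    )


def score_events(
    events: Sequence[float] | np.ndarray | pd.Series,
    reference: ReferenceInterval,
    prominence_floor: float = DEFAULT_PROMINENCE_FLOOR,
) -> MarkerScore:
    """Convenience wrapper: detect subpopulations and score in one call."""
    modality, subpops = detect_subpopulations(events, reference, prominence_floor)
    mfi = float(np.median(np.asarray(events, dtype=float)))
    return score_marker(modality, subpops, reference, mfi)


def binarize_score(score: MarkerScore | str, marker: str | None = None) -> int:
    """Collapse the four-level score to the binary rule used for ROC models.

    Positive means normal/bright for every marker except CD15 and CD133,
    where dim already counts as positive.
    """
    if isinstance(score, MarkerScore):
        marker, level = score.marker, score.overall_score
    else:
        level = score
        if marker is None:
            warnings.warn("marker unknown; applying the default neg/dim vs pos rule",
                          stacklevel=2)
            marker = ""
    if level not in SCORE_LEVELS:
        raise ValueError(f"unknown score level {level!r}")
    positive_levels = ("+", "++", "+++") if marker in DIM_COUNTS_POSITIVE else ("++", "+++")
    return int(level in positive_levels)
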