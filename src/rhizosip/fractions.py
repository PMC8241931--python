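"""qPCR quantification and heavy/light fraction selection.

CT values are converted to 16S copy numbers through an OLS standard curve;
the per-gradient copy-number profile then determines which fractions are
pooled into the light (L, unlabeled peak) and heavy (H, labeled) classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .models import DataError, FractionProfile, GradientRun


@dataclass(frozen=True)
class StandardCurve:
    """qPCR standard curve CT = slope·log10(copies) + intercept."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise DataError(f"standard curve slope must be negative, got {self.slope}")
        if not 0 < self.efficiency <= 1.2:
            raise DataError(f"amplification efficiency {self.efficiency:.3f} outside (0, 1.2]")
        if not 0.8 <= self.efficiency <= 1.1:
            warnings.warn(
                f"amplification efficiency {self.efficiency:.3f} outside the usual "
                "0.8-1.1 range; check the dilution series",
                stacklevel=3,
            )


@dataclass
class FractionPartition:
    """Heavy/light window assignment over fraction indices."""

    heavy_ids: frozenset[int]
    light_ids: frozenset[int]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.heavy_ids & self.light_ids:
            raise DataError("heavy and light windows overlap")
        if not self.heavy_ids or not self.light_ids:
            raise DataError("both heavy and light windows must be non-empty")


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares standard curve from (log10 copies, CT) dilution points.

    Efficiency is the per-cycle amplification gain, 10^(−1/slope) − 1;
    a perfect doubling per cycle gives slope −3.3219 and efficiency 1.
    """
    if len(points) < 3:
        raise DataError("standard curve needs at least 3 dilution points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DataError("dilution series has zero variance in log10 copies")
    if np.ptp(y) == 0:
        raise DataError("all CT values are equal; cannot fit a standard curve")
    fit = stats.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def ct_to_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: copies = 10^((ct − intercept)/slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def _contiguous_block(candidates: list[int], anchor: int) -> list[int]:
    """Maximal run of consecutive positions in `candidates` containing `anchor`."""
    block = [anchor]
    s = set(candidates)
    lo, hi = anchor - 1, anchor + 1
    while lo in s:
        block.append(lo)
        lo -= 1
    while hi in s:
        block.append(hi)
        hi += 1
    return sorted(block)


def select_heavy_light(
    run: GradientRun,
    delta_density: float = 0.015,
    background_fraction: float = 0.05,
    reference_peak_density: Optional[float] = None,
) -> FractionPartition:
    """Pick heavy and light fraction windows from the copy-number profile.

    The boundary between light and heavy is placed ``delta_density`` above
    the copy-number peak (or above ``reference_peak_density`` when the
    unlabeled peak position is known from a paired ¹²C gradient). The heavy
    window is the contiguous block of fractions above the boundary whose
    copies exceed ``background_fraction`` of the peak, anchored at the
    densest local maximum; the light window is the contiguous block around
    the copy-number peak below the heavy window.
    """
    fracs = run.sorted_by_density()
    if len(fracs) < 4:
        raise DataError("need at least 4 fractions to select heavy/light windows")
    copies = np.array([f.copies for f in fracs])
    densities = np.array([f.density for f in fracs])
    if np.ptp(copies) == 0:
        raise DataError("flat copy-number profile: no peak to anchor windows")

    peak_pos = int(np.argmax(copies))
    # sub-bin peak estimate: copy-weighted centroid of the peak and its
    # neighbors, so the boundary does not inherit the fraction-width
    # quantization of the raw argmax
    lo, hi = max(0, peak_pos - 1), min(len(fracs), peak_pos + 2)
    peak_density = float(
        (copies[lo:hi] * densities[lo:hi]).sum() / copies[lo:hi].sum()
    )
    anchor_density = (
        float(reference_peak_density)
        if reference_peak_density is not None
        else peak_density
    )
    boundary = anchor_density + delta_density
    floor = background_fraction * float(copies[peak_pos])

    heavy_cand = [
        i for i in range(len(fracs)) if densities[i] >= boundary and copies[i] >= floor
    ]
    if not heavy_cand:
        raise DataError(
            f"no fraction qualifies as heavy (density >= {boundary:.4f} g/mL and "
            f"copies >= {floor:.3g}); supply the heavy/light windows manually "
            "with partition_by_density()"
        )
    heavy_anchor = max(heavy_cand, key=lambda i: copies[i])
    heavy_pos = _contiguous_block(heavy_cand, heavy_anchor)
    heavy_min_density = densities[heavy_pos[0]]

    light_region = [i for i in range(len(fracs)) if densities[i] < heavy_min_density]
    if not light_region:
        raise DataError("no fractions below the heavy window to form a light window")
    light_anchor = max(light_region, key=lambda i: copies[i])
    light_floor = background_fraction * float(copies[light_anchor])
    light_cand = [i for i in light_region if copies[i] >= light_floor]
    light_pos = _contiguous_block(light_cand, light_anchor)

    return FractionPartition(
        heavy_ids=frozenset(fracs[i].fraction_index for i in heavy_pos),
        light_ids=frozenset(fracs[i].fraction_index for i in light_pos),
        diagnostics={
            "peak_density": peak_density,
            "peak_fraction_density": float(densities[peak_pos]),
            "anchor_density": anchor_density,
            "boundary_density": boundary,
            "rule": "peak+delta offset" if reference_peak_density is None else "reference peak+delta offset",
            "delta_density": delta_density,
            "background_fraction": background_fraction,
        },
    )


def partition_by_density(
    run: GradientRun,
    light_range: tuple[float, float],
    heavy_range: tuple[float, float],
) -> FractionPartition:
    """Manual window override: assign fractions to windows by density bounds.

    Used both as the user escape hatch and by the pipeline to carry the
    windows selected on a ¹³C gradient over to its paired ¹²C control, so
    the two pools cover matched buoyant densities.
    """
    if light_range[1] > heavy_range[0]:
        raise DataError("light density range must lie entirely below the heavy range")
    heavy, light = set(), set()
    for f in run.fractions:
        if heavy_range[0] <= f.density <= heavy_range[1]:
            heavy.add(f.fraction_index)
        elif light_range[0] <= f.density <= light_range[1]:
            light.add(f.fraction_index)
    if not heavy or not light:
        raise DataError(
            f"manual windows select {len(heavy)} heavy / {len(light)} light fractions; "
            "both must be non-empty"
        )
    return FractionPartition(
        heavy_ids=frozenset(heavy),
        light_ids=frozenset(light),
        diagnostics={
            "rule": "manual density ranges",
            "light_range": tuple(light_range),
            "heavy_range": tuple(heavy_range),
        },
    )


def window_density_ranges(
    run: GradientRun, partition: FractionPartition
) -> tuple[tuple[float, float], tuple[float, float]]:
    """(light_range, heavy_range) density bounds of an existing partition."""
    by_idx = {f.fraction_index: f.density for f in run.fractions}
    ld = [by_idx[i] for i in partition.light_ids]
    hd = [by_idx[i] for i in partition.heavy_ids]
    return (min(ld), max(ld)), (min(hd), max(hd))


def _window_composition(fracs: list[FractionProfile], label: str) -> dict[str, float]:
    genera = sorted({g for f in fracs for g in (f.counts or {})})
    comp = np.zeros(len(genera))
    for f in fracs:
        if f.counts is None:
            raise DataError(f"fraction {f.fraction_index} has no genus counts")
        total = sum(f.counts.values())
        if total <= 0:
            raise DataError(
                f"{label} window fraction {f.fraction_index} has zero total reads"
            )
        comp += np.array([f.counts.get(g, 0) for g in genera], dtype=float) / total
    comp /= len(fracs)
    return dict(zip(genera, comp))


def pool_fractions(
    run: GradientRun, partition: FractionPartition
) -> tuple[dict[str, float], dict[str, float]]:
    """Pool genus counts within each window, combining equal DNA quantities.

    Equal-quantity pooling means each fraction contributes equally to the
    pooled composition (mean of within-fraction relative abundances), which
    is then rescaled to the window's total read count.

    Returns ``(counts_H, counts_L)``.
    """
    by_idx = {f.fraction_index: f for f in run.fractions}
    unknown = (partition.heavy_ids | partition.light_ids) - set(by_idx)
    if unknown:
        raise DataError(f"partition references unknown fraction indices {sorted(unknown)}")
    out = []
    for ids, label in ((partition.heavy_ids, "heavy"), (partition.light_ids, "light")):
        fracs = [by_idx[i] for i in sorted(ids)]
        comp = _window_composition(fracs, label)
        total_reads = sum(sum(f.counts.values()) for f in fracs)
        out.append({g: p * total_reads for g, p in comp.items()})
    return out[0], out[1]
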