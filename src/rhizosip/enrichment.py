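"""Genus-level SIP enrichment analysis.

Converts pooled fraction-class counts to relative abundances, flags
autotrophs from the unplanted ¹³CO₂ controls, and classifies genera as
root-exudate metabolizers by the dual two-fold criterion: a genus is
"labeled" when its mean ¹³C-heavy abundance is at least two-fold its mean
¹³C-light abundance AND at least two-fold its mean ¹²C-heavy abundance,
and it is not an autotroph.

Fold ratios use the ratio-of-means convention (class means first, then the
ratio); printed integer folds are the truncated (floored) ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import DataError, SampleKey

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDO = 1e-6

#: substrings (case-insensitive) marking plastid-like pseudo-genera
PLASTID_MARKERS = ("chloroplast", "mitochondri", "plastid")


@dataclass
class AbundanceTable:
    """Genus × sample matrix of relative abundances.

    ``data`` has genera as the index and :class:`SampleKey` columns; every
    column sums to 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if not isinstance(col, SampleKey):
                raise DataError(f"column {col!r} is not a SampleKey")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise DataError("negative relative abundance")
        sums = vals.sum(axis=0)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            key = self.data.columns[int(np.flatnonzero(bad)[0])]
            raise DataError(f"sample {key} abundances sum to {sums[bad][0]}, expected 1")

    @property
    def genera(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[SampleKey]:
        return list(self.data.columns)

    def select(self, **selector) -> pd.DataFrame:
        cols = [k for k in self.data.columns if k.matches(**selector)]
        return self.data[cols]


def to_relative_abundance(
    counts: pd.DataFrame,
    drop_singletons: bool = True,
    drop_plastid: bool = True,
    plastid_genera: Optional[Iterable[str]] = None,
) -> AbundanceTable:
    """Filter a genus × sample count table and normalize columns to sum 1.

    Singletons (genera with a total of exactly one read across all samples)
    and plastid-like genera are removed before normalization. Counts may be
    non-integral (pooled counts are read-scaled compositions) but must be
    non-negative.
    """
    if (counts.to_numpy(dtype=float) < 0).any():
        raise DataError("negative counts")
    cols = [
        c if isinstance(c, SampleKey) else SampleKey.from_string(str(c))
        for c in counts.columns
    ]
    df = counts.copy()
    df.columns = cols

    if drop_plastid:
        flagged = set(plastid_genera or ())
        mask = [
            g in flagged or any(m in str(g).lower() for m in PLASTID_MARKERS)
            for g in df.index
        ]
        df = df.loc[[not m for m in mask]]
    if drop_singletons:
        df = df.loc[df.sum(axis=1) != 1]

    sums = df.sum(axis=0)
    empty = sums[sums <= 0]
    if len(empty) > 0:
        raise DataError(
            f"sample {empty.index[0]} has zero reads after filtering"
        )
    return AbundanceTable(df / sums)


def mean_class_abundance(
    table: AbundanceTable, genus: str, **selector
) -> tuple[float, Optional[float]]:
    """Mean (and standard error) relative abundance of a genus over a class.

    The class is given by SampleKey selectors, e.g.
    ``mean_class_abundance(t, "Pseudomonas", isotope="13C", fraction_class="H")``.
    The standard error is ``sd/sqrt(n)`` over matching samples and is
    ``None`` when only a single (e.g. pooled) sample matches.
    """
    sub = table.select(**selector)
    if sub.shape[1] == 0:
        raise DataError(f"no sample matches class {selector}")
    if genus not in table.data.index:
        raise DataError(f"genus {genus!r} not in table")
    vals = sub.loc[genus].to_numpy(dtype=float)
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    return mean, float(vals.std(ddof=1) / math.sqrt(vals.size))


@dataclass(frozen=True)
class FoldResult:
    ratio: float
    printed_fold: int
    pseudo_used: bool


def fold_enrichment(
    mean_num: float, mean_den: float, pseudo: float = DEFAULT_PSEUDO
) -> FoldResult:
    """Fold enrichment between two mean abundances.

    ``ratio = mean_num / max(mean_den, pseudo)``; the pseudo-abundance floor
    guards zero denominators and its use is logged. ``printed_fold`` is the
    ratio truncated toward zero, the convention behind printed integer folds.
    """
    if mean_num < 0 or mean_den < 0:
        raise DataError("mean abundances must be non-negative")
    pseudo_used = mean_den < pseudo
    if pseudo_used:
        logger.info(
            "pseudo-abundance floor %g applied to zero/near-zero denominator %g",
            pseudo,
            mean_den,
        )
    ratio = mean_num / max(mean_den, pseudo)
    return FoldResult(ratio=float(ratio), printed_fold=int(math.floor(ratio)), pseudo_used=pseudo_used)


def detect_autotrophs(
    table: AbundanceTable,
    threshold: float = DEFAULT_THRESHOLD,
    pseudo: float = DEFAULT_PSEUDO,
) -> dict[str, float]:
    """Genera enriched in the heavy fractions of unplanted ¹³CO₂ controls.

    Such genera are presumed capable of fixing CO₂ directly and are excluded
    from the exudate-metabolizer classification. Returns the per-genus
    H/L control fold ratios for every detected genus (for audit); the
    detected set is the dict's keys.
    """
    h = table.select(isotope="13C", compartment="unplanted_control", fraction_class="H")
    l = table.select(isotope="13C", compartment="unplanted_control", fraction_class="L")
    if h.shape[1] == 0 or l.shape[1] == 0:
        raise DataError(
            "unplanted 13C control heavy/light samples are required for the "
            "autotroph filter and are missing"
        )
    out: dict[str, float] = {}
    for genus in table.genera:
        ratio = fold_enrichment(
            float(h.loc[genus].mean()), float(l.loc[genus].mean()), pseudo
        ).ratio
        if ratio >= threshold:
            out[genus] = ratio
    return out


@dataclass(frozen=True)
class EnrichmentRecord:
    """Full audit record of the dual-fold rule for one genus."""

    genus: str
    mean_13CH: float
    mean_13CL: float
    mean_12CH: float
    se_13CH: Optional[float]
    se_13CL: Optional[float]
    se_12CH: Optional[float]
    fold_13CH_vs_13CL: float
    fold_13CH_vs_12CH: float
    printed_fold_13CH_vs_13CL: int
    printed_fold_13CH_vs_12CH: int
    autotroph: bool
    labeled: bool


def classify_labeled_genera(
    table: AbundanceTable,
    compartment: str,
    autotrophs: Iterable[str] = (),
    threshold: float = DEFAULT_THRESHOLD,
    pseudo: float = DEFAULT_PSEUDO,
) -> list[EnrichmentRecord]:
    """Apply the dual two-fold rule to every genus of one planted compartment.

    Every genus gets a record (audit completeness); records are sorted by
    fold vs the ¹²C-heavy control, descending — the "greatest overall
    enrichment" ordering.
    """
    classes = {
        "13CH": dict(isotope="13C", fraction_class="H"),
        "13CL": dict(isotope="13C", fraction_class="L"),
        "12CH": dict(isotope="12C", fraction_class="H"),
    }
    sub = {}
    for name, sel in classes.items():
        s = table.select(compartment=compartment, **sel)
        if s.shape[1] == 0:
            raise DataError(f"no {name} samples for compartment {compartment!r}")
        sub[name] = s
    autotroph_set = set(autotrophs)

    records = []
    for genus in table.genera:
        stats = {}
        for name, s in sub.items():
            vals = s.loc[genus].to_numpy(dtype=float)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
            stats[name] = (mean, se)
        f_light = fold_enrichment(stats["13CH"][0], stats["13CL"][0], pseudo)
        f_ctrl = fold_enrichment(stats["13CH"][0], stats["12CH"][0], pseudo)
        is_auto = genus in autotroph_set
        labeled = (
            f_light.ratio >= threshold and f_ctrl.ratio >= threshold and not is_auto
        )
        records.append(
            EnrichmentRecord(
                genus=genus,
                mean_13CH=stats["13CH"][0],
                mean_13CL=stats["13CL"][0],
                mean_12CH=stats["12CH"][0],
                se_13CH=stats["13CH"][1],
                se_13CL=stats["13CL"][1],
                se_12CH=stats["12CH"][1],
                fold_13CH_vs_13CL=f_light.ratio,
                fold_13CH_vs_12CH=f_ctrl.ratio,
                printed_fold_13CH_vs_13CL=f_light.printed_fold,
                printed_fold_13CH_vs_12CH=f_ctrl.printed_fold,
                autotroph=is_auto,
                labeled=labeled,
            )
        )
    records.sort(key=lambda r: r.fold_13CH_vs_12CH, reverse=True)
    return records


def labeled_genera(records: Sequence[EnrichmentRecord]) -> set[str]:
    return {r.genus for r in records if r.labeled}


@dataclass(frozen=True)
class OverlapSummary:
    labeled_rhizosphere: frozenset[str]
    labeled_endosphere: frozenset[str]
    both: frozenset[str]
    rhizosphere_only: frozenset[str]
    endosphere_only: frozenset[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "labeled_rhizosphere": sorted(self.labeled_rhizosphere),
            "labeled_endosphere": sorted(self.labeled_endosphere),
            "both": sorted(self.both),
            "rhizosphere_only": sorted(self.rhizosphere_only),
            "endosphere_only": sorted(self.endosphere_only),
        }


def compare_compartments(
    rhizosphere: Sequence[EnrichmentRecord] | Iterable[str],
    endosphere: Sequence[EnrichmentRecord] | Iterable[str],
) -> OverlapSummary:
    """Overlap of the labeled genus sets between the two planted compartments."""

    def _to_set(x) -> frozenset[str]:
        items = list(x)
        if items and isinstance(items[0], EnrichmentRecord):
            return frozenset(labeled_genera(items))
        return frozenset(items)

    r = _to_set(rhizosphere)
    e = _to_set(endosphere)
    return OverlapSummary(
        labeled_rhizosphere=r,
        labeled_endosphere=e,
        both=r & e,
        rhizosphere_only=r - e,
        endosphere_only=e - r,
    )


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular EnrichmentReport for export."""
    return pd.DataFrame([vars(r) for r in records]).set_index("genus")
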