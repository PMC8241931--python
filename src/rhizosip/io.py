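"""Plain-text table readers and writers.

All on-disk formats are tab-delimited text. Sample columns of pooled count
tables are :class:`~rhizosip.models.SampleKey` strings
(``<isotope>_<compartment>_<replicate>_<fraction_class>``); raw per-fraction
tables use ``<isotope>_<compartment>_<replicate>_<fractionIndex>`` keys with
a separate metadata table carrying densities and copy numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .models import DataError, GradientRun, Replicate, SampleKey, TaxonSpec


def _fraction_sample_key(run: GradientRun, fraction_index: int) -> str:
    return f"{run.isotope}_{run.compartment}_{run.replicate}_{fraction_index}"


def fraction_counts_frame(runs: Sequence[GradientRun]) -> pd.DataFrame:
    """Genus × fraction-sample count table over a set of gradient runs."""
    cols = {}
    for run in runs:
        for f in run.fractions:
            if f.counts is None:
                raise DataError("gradient run fraction lacks genus counts")
            cols[_fraction_sample_key(run, f.fraction_index)] = pd.Series(f.counts)
    return pd.DataFrame(cols).fillna(0).astype(int)


def fraction_metadata_frame(runs: Sequence[GradientRun]) -> pd.DataFrame:
    rows = []
    for run in runs:
        for f in run.fractions:
            rows.append(
                {
                    "sample_key": _fraction_sample_key(run, f.fraction_index),
                    "isotope": run.isotope,
                    "compartment": run.compartment,
                    "replicate": run.replicate,
                    "fraction_index": f.fraction_index,
                    "density_g_per_ml": f.density,
                    "copies_per_ul": f.copies,
                }
            )
    return pd.DataFrame(rows)


def taxon_truth_frame(taxa: Sequence[TaxonSpec]) -> pd.DataFrame:
    rows = []
    for t in taxa:
        a_vals = sorted(set(t.atom_excess.values()))
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "genus": t.genus,
                "phylum": t.phylum,
                "gc": t.gc,
                "role": t.role,
                "max_atom_excess": max(a_vals) if a_vals else 0.0,
            }
        )
    return pd.DataFrame(rows)


def pooled_counts_frame(pooled: Mapping[SampleKey, Mapping[str, float]]) -> pd.DataFrame:
    """Genus × pooled-class count table with SampleKey string columns."""
    return pd.DataFrame({str(k): pd.Series(v) for k, v in pooled.items()}).fillna(0.0)


def write_tsv(frame: pd.DataFrame, path: Path, index_label: str = "genus") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def read_counts_table(path: Path) -> pd.DataFrame:
    """Read a genus × sample table; first column is the genus index."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    return df


def read_fraction_metadata(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_key", "density_g_per_ml", "copies_per_ul"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_qpcr_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"sample_key", "ct"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_standards(path: Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"log10_copies", "ct"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(df["log10_copies"].astype(float), df["ct"].astype(float)))


def read_cfu_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def runs_from_tables(
    counts: pd.DataFrame, metadata: pd.DataFrame
) -> dict[tuple[str, str, Replicate], GradientRun]:
    """Reassemble GradientRun objects from count + metadata tables."""
    from .models import FractionProfile

    runs: dict[tuple[str, str, Replicate], GradientRun] = {}
    for (isotope, compartment, replicate), grp in metadata.groupby(
        ["isotope", "compartment", "replicate"]
    ):
        rep: Replicate = replicate if replicate == "pooled" else int(replicate)
        fractions = []
        for _, row in grp.iterrows():
            key = row["sample_key"]
            if key not in counts.columns:
                raise DataError(f"fraction sample {key} missing from count table")
            fractions.append(
                FractionProfile(
                    fraction_index=int(row["fraction_index"]),
                    density=float(row["density_g_per_ml"]),
                    copies=float(row["copies_per_ul"]),
                    counts=counts[key].to_dict(),
                )
            )
        runs[(isotope, compartment, rep)] = GradientRun(
            isotope=isotope,
            compartment=compartment,
            replicate=rep,
            dna_mass_loaded=float("nan"),
            fractions=fractions,
        )
    return runs
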