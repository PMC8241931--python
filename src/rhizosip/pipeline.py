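"""End-to-end pipeline orchestration.

Synthetic mode simulates the whole study from one seed, then runs exactly
the same analysis stages the real-data mode applies to user tables:
heavy/light window selection → equal-quantity pooling → relative-abundance
filtering → autotroph detection → dual-fold classification per planted
compartment → compartment overlap → ordination/PERMANOVA → optional CFU
statistics. A machine-readable summary (and, in synthetic mode, a confusion
matrix against the simulated truth) is written to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import fractions as fr
from . import io as rio
from .colonization import analyze_cfu
from .ecology import bray_curtis, pcoa, permanova, shannon
from .enrichment import (
    AbundanceTable,
    classify_labeled_genera,
    compare_compartments,
    detect_autotrophs,
    labeled_genera,
    records_to_frame,
    to_relative_abundance,
)
from .models import ConfigurationError, DataError, GradientRun, Replicate, SampleKey
from .synthetic import (
    CFUDesign,
    CommunityDesign,
    GradientModel,
    SequencingModel,
    StudyDataset,
    StudyDesign,
    default_community_design,
    simulate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-document pipeline configuration."""

    mode: str = "synthetic"
    seed: int = 0
    out_dir: Path = Path("sip_out")
    # analysis parameters
    threshold: float = 2.0
    pseudo: float = 1e-6
    delta_density: float = 0.015
    background_fraction: float = 0.05
    n_permutations: int = 999
    drop_singletons: bool = True
    drop_plastid: bool = True
    # synthetic-mode simulator overrides (dataclass field dicts)
    community: dict = field(default_factory=dict)
    study: dict = field(default_factory=dict)
    gradient: dict = field(default_factory=dict)
    sequencing: dict = field(default_factory=dict)
    cfu_design: dict = field(default_factory=dict)
    include_cfu: bool = False
    metabolizer_atom_excess: float = 0.5
    # real-mode input paths
    counts_path: Optional[Path] = None
    metadata_path: Optional[Path] = None
    cfu_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.mode == "real":
            for name in ("counts_path", "metadata_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(f"real mode requires {name}")
                if not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p}")
        if self.mode == "synthetic" and self.seed is None:
            raise ConfigurationError("synthetic mode requires a seed")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("out_dir", "counts_path", "metadata_path", "cfu_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


# ---------------------------------------------------------------------------
# fraction-selection stage
# ---------------------------------------------------------------------------


def partition_runs(
    runs: dict[tuple[str, str, Replicate], GradientRun],
    delta_density: float = 0.015,
    background_fraction: float = 0.05,
) -> dict[tuple[str, str, Replicate], fr.FractionPartition]:
    """Select heavy/light windows for every gradient run.

    Windows are selected on each ¹³C gradient from its own copy-number
    profile; the resulting density windows are carried over to the paired
    ¹²C gradient of the same compartment/replicate so the two pools cover
    matched buoyant densities. ¹³C gradients where no heavy shoulder clears
    the background floor (e.g. unplanted controls with little labeled DNA)
    fall back to the median windows of the successfully selected ¹³C runs.
    """
    partitions: dict[tuple[str, str, Replicate], fr.FractionPartition] = {}
    ranges: dict[tuple[str, str, Replicate], tuple] = {}
    failed: list[tuple[str, str, Replicate]] = []

    for key, run in runs.items():
        isotope = key[0]
        if isotope != "13C":
            continue
        try:
            part = fr.select_heavy_light(run, delta_density, background_fraction)
        except DataError as exc:
            logger.warning("window selection failed for %s: %s", key, exc)
            failed.append(key)
            continue
        partitions[key] = part
        ranges[key] = fr.window_density_ranges(run, part)

    if failed:
        if not ranges:
            raise DataError(
                "heavy/light window selection failed for every 13C gradient; "
                "supply windows manually"
            )
        all_ranges = list(ranges.values())
        light = (
            float(np.median([r[0][0] for r in all_ranges])),
            float(np.median([r[0][1] for r in all_ranges])),
        )
        heavy = (
            float(np.median([r[1][0] for r in all_ranges])),
            float(np.median([r[1][1] for r in all_ranges])),
        )
        for key in failed:
            part = fr.partition_by_density(runs[key], light, heavy)
            part.diagnostics["fallback"] = "median windows of selected 13C runs"
            partitions[key] = part
            ranges[key] = fr.window_density_ranges(runs[key], part)

    for key, run in runs.items():
        isotope, compartment, rep = key
        if isotope != "12C":
            continue
        paired = ("13C", compartment, rep)
        if paired not in ranges:
            raise DataError(f"no paired 13C gradient for {key} to derive windows from")
        light, heavy = ranges[paired]
        partitions[key] = fr.partition_by_density(run, light, heavy)
        partitions[key].diagnostics["windows_from"] = str(paired)
    return partitions


def pool_all(
    runs: dict[tuple[str, str, Replicate], GradientRun],
    partitions: dict[tuple[str, str, Replicate], fr.FractionPartition],
) -> dict[SampleKey, dict[str, float]]:
    pooled: dict[SampleKey, dict[str, float]] = {}
    for key, run in runs.items():
        counts_h, counts_l = fr.pool_fractions(run, partitions[key])
        isotope, compartment, rep = key
        pooled[SampleKey(isotope, compartment, "H", rep)] = counts_h
        pooled[SampleKey(isotope, compartment, "L", rep)] = counts_l
    return pooled


# ---------------------------------------------------------------------------
# analysis stages (shared between modes)
# ---------------------------------------------------------------------------


def _ecology_summary(table: AbundanceTable, config: RunConfig) -> dict[str, Any]:
    sub = table.select(compartment="rhizosphere")
    if sub.shape[1] < 4:
        return {"note": "too few rhizosphere samples for ordination"}
    dm = bray_curtis(sub)
    ordination = pcoa(dm)
    groups = {k: f"{k.isotope}{k.fraction_class}" for k in dm.sample_keys}
    perm = permanova(dm, groups, n_permutations=config.n_permutations, seed=config.seed)
    return {
        "pcoa_variance_explained": [round(float(v), 6) for v in ordination.variance_explained[:4]],
        "pcoa_note": ordination.negative_eigenvalue_note,
        "permanova": {
            "pseudo_f": perm.pseudo_f,
            "r_squared": perm.r_squared,
            "p_value": perm.p_value,
            "p_string": perm.p_string,
            "n_permutations": perm.n_permutations,
        },
        "coordinates": {
            str(k): [float(c) for c in ordination.coordinates[i, :2]]
            for i, k in enumerate(ordination.sample_keys)
        },
    }


def analyze_tables(
    counts: pd.DataFrame, config: RunConfig, cfu: Optional[pd.DataFrame] = None
) -> dict[str, Any]:
    """Run the analysis stages on a pooled genus × sample-class count table."""
    table = to_relative_abundance(
        counts, drop_singletons=config.drop_singletons, drop_plastid=config.drop_plastid
    )
    autotrophs = detect_autotrophs(table, threshold=config.threshold, pseudo=config.pseudo)

    reports = {}
    for compartment in ("rhizosphere", "endosphere"):
        if any(k.compartment == compartment for k in table.samples):
            reports[compartment] = classify_labeled_genera(
                table,
                compartment,
                autotrophs=autotrophs,
                threshold=config.threshold,
                pseudo=config.pseudo,
            )
    if not reports:
        raise DataError("no planted compartment (rhizosphere/endosphere) in table")

    result: dict[str, Any] = {
        "autotrophs": {g: float(r) for g, r in sorted(autotrophs.items())},
        "labeled": {c: sorted(labeled_genera(r)) for c, r in reports.items()},
        "reports": reports,
        "table": table,
    }
    if len(reports) == 2:
        result["overlap"] = compare_compartments(
            reports["rhizosphere"], reports["endosphere"]
        )
    result["ecology"] = _ecology_summary(table, config)
    if cfu is not None:
        result["cfu"] = analyze_cfu(cfu)
    return result


def _confusion(dataset: StudyDataset, labeled: dict[str, list[str]]) -> dict[str, Any]:
    metabolizers = dataset.genera_with_role("exudate_metabolizer")
    bystanders = dataset.genera_with_role("bystander")
    autotrophs = dataset.genera_with_role("autotroph")
    out = {}
    for compartment, genera in labeled.items():
        got = set(genera)
        tp = got & metabolizers
        out[compartment] = {
            "true_positives": len(tp),
            "false_negatives": len(metabolizers - got),
            "bystander_false_positives": len(got & bystanders),
            "autotroph_false_positives": len(got & autotrophs),
            "sensitivity": len(tp) / len(metabolizers) if metabolizers else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict[str, Any]:
    """Execute the configured pipeline; returns the summary dict."""
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "configure"
    try:
        summary: dict[str, Any] = {"config": config.echo()}
        dataset: Optional[StudyDataset] = None
        if config.mode == "synthetic":
            stage = "simulate"
            dataset = simulate_study(
                community=default_community_design(config.metabolizer_atom_excess)
                if not config.community
                else CommunityDesign(**config.community),
                study=StudyDesign(include_cfu=config.include_cfu, **config.study),
                gmodel=GradientModel(**config.gradient),
                smodel=SequencingModel(**config.sequencing),
                cfu_design=CFUDesign(**config.cfu_design) if config.cfu_design else None,
                seed=config.seed,
            )
            runs = dataset.runs
            cfu = dataset.cfu
            stage = "fractions"
            partitions = partition_runs(
                runs, config.delta_density, config.background_fraction
            )
            pooled = pool_all(runs, partitions)
            counts = rio.pooled_counts_frame(pooled)
            shannon_by_comp = {}
            for comp in ("bulk_soil", "rhizosphere", "endosphere"):
                h = [
                    shannon(list(p.proportions.values()))
                    for (iso, c, rep), p in dataset.profiles.items()
                    if c == comp
                ]
                if h:
                    shannon_by_comp[comp] = {
                        "mean": float(np.mean(h)),
                        "sd": float(np.std(h, ddof=1)) if len(h) > 1 else None,
                    }
            summary["shannon_by_compartment"] = shannon_by_comp
        else:
            stage = "load"
            counts = rio.read_counts_table(Path(config.counts_path))
            # metadata is validated for presence/consistency with the counts
            meta = pd.read_csv(Path(config.metadata_path), sep="\t")
            cfu = rio.read_cfu_table(Path(config.cfu_path)) if config.cfu_path else None

        stage = "enrich"
        result = analyze_tables(counts, config, cfu=cfu)

        summary["autotrophs"] = result["autotrophs"]
        summary["labeled"] = result["labeled"]
        if "overlap" in result:
            summary["overlap"] = result["overlap"].as_dict()
        summary["ecology"] = result["ecology"]
        if "cfu" in result:
            anova = result["cfu"]["anova"]
            summary["cfu_anova"] = {
                term: {
                    "df": int(anova.loc[term, "df"]),
                    "F": None if pd.isna(anova.loc[term, "F"]) else float(anova.loc[term, "F"]),
                    "p": None if pd.isna(anova.loc[term, "p"]) else float(anova.loc[term, "p"]),
                }
                for term in anova.index
            }
            summary["cfu_tukey_genotype"] = result["cfu"]["tukey_genotype"].to_dict("records")
        if dataset is not None:
            summary["confusion"] = _confusion(dataset, result["labeled"])
            summary["truth"] = {
                role: sorted(dataset.genera_with_role(role))
                for role in ("exudate_metabolizer", "autotroph", "bystander")
            }

        if write_outputs:
            stage = "write"
            _write_bundle(out_dir, config, summary, result, dataset, counts)
        return summary
    except (ConfigurationError, DataError) as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_bundle(out_dir, config, summary, result, dataset, counts) -> None:
    manifest = {"outputs": [], "seed": config.seed, "mode": config.mode}
    rio.write_tsv(counts, out_dir / "pooled_counts.tsv")
    manifest["outputs"].append("pooled_counts.tsv")
    for compartment, records in result["reports"].items():
        name = f"enrichment_{compartment}.tsv"
        rio.write_tsv(records_to_frame(records), out_dir / name)
        manifest["outputs"].append(name)
    if dataset is not None:
        rio.write_tsv(
            rio.fraction_counts_frame(list(dataset.runs.values())),
            out_dir / "fraction_counts.tsv",
        )
        rio.fraction_metadata_frame(list(dataset.runs.values())).to_csv(
            out_dir / "fraction_metadata.tsv", sep="\t", index=False
        )
        rio.taxon_truth_frame(dataset.taxa).to_csv(
            out_dir / "taxon_truth.tsv", sep="\t", index=False
        )
        manifest["outputs"] += ["fraction_counts.tsv", "fraction_metadata.tsv", "taxon_truth.tsv"]
        if dataset.cfu is not None:
            dataset.cfu.to_csv(out_dir / "cfu_table.tsv", sep="\t", index=False)
            manifest["outputs"].append("cfu_table.tsv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    manifest["outputs"].append("summary.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
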