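"""End-to-end driver: simulate or ingest -> filter -> classify -> features
-> population outputs, with config, logging, and provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierParams, classify_events
from .core import (
    MIN_RECORDING_DURATION_S,
    SpikeEventSeries,
    filter_by_duration,
    load_event_series,
    save_event_series,
    write_feature_table,
)
from .errors import InsufficientDataError, ValidationError
from .features import FeatureParams, extract_features
from .population import (
    CLUSTER_FEATURES,
    assemble_population,
    clusterogram,
    compare_groups,
    group_linkage,
    group_means,
    linkage_to_newick,
    tsne_pseudotimeline,
)
from .synthetic import PRESETS, LabeledSeries, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class CohortSpec:
    preset: str = "young_control"
    n_cells: int = 15
    duration_s: float = 120.0
    group_label: str | None = None


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the documented method
    (2.5 Hz frequency-mode bins, 5 ms autocorrelogram bins up to 1 s,
    20 ms doublet window, 5x mean-ISI pause threshold, 75 s minimum
    recording duration)."""

    input_dir: str | None = None
    output_dir: str = "spikephen_out"
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    min_duration_s: float = MIN_RECORDING_DURATION_S
    linkage_method: str = "average"
    distance: str = "euclidean"
    perplexity: float = 30.0
    seed: int = 0
    cohorts: list[CohortSpec] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "classifier" in kwargs and isinstance(kwargs["classifier"], dict):
            kwargs["classifier"] = ClassifierParams(**kwargs["classifier"])
        if "features" in kwargs and isinstance(kwargs["features"], dict):
            kwargs["features"] = FeatureParams(**kwargs["features"])
        if "cohorts" in kwargs:
            kwargs["cohorts"] = [
                CohortSpec(**c) if isinstance(c, dict) else c
                for c in kwargs["cohorts"]
            ]
        return cls(**kwargs)


def simulate_to_dir(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Generate the configured cohorts and write event/metadata/truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    stems = []
    rng = np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    for cohort_spec, seq in zip(config.cohorts, rng):
        cohort_seed = int(seq.generate_state(1)[0])
        cells = generate_cohort(
            cohort_spec.preset,
            cohort_spec.n_cells,
            cohort_seed,
            duration_s=cohort_spec.duration_s,
            group_label=cohort_spec.group_label,
        )
        for cell in cells:
            stem = out_dir / cell.series.cell_id
            save_event_series(
                cell.series, f"{stem}.events.tsv", f"{stem}.meta.yaml"
            )
            truth = pd.DataFrame(
                {
                    "time_s": cell.series.times_s,
                    "true_label": cell.true_labels,
                }
            )
            truth.to_csv(f"{stem}.truth.tsv", sep="\t", index=False)
            manifest.append(
                {
                    "cell_id": cell.series.cell_id,
                    "preset": cohort_spec.preset,
                    "group_label": cell.series.group_label,
                    "n_events": cell.series.n_events,
                }
            )
            stems.append(stem)
    pd.DataFrame(manifest).to_csv(
        out_dir / "cohort_manifest.tsv", sep="\t", index=False
    )
    return stems


def load_series_dir(input_dir: str | Path) -> list[SpikeEventSeries]:
    """Load every `<stem>.events.tsv` + `<stem>.meta.yaml` pair in a directory."""
    input_dir = Path(input_dir)
    event_files = sorted(input_dir.glob("*.events.tsv"))
    if not event_files:
        raise ValidationError(f"no *.events.tsv files found in {input_dir}")
    series = []
    for ev in event_files:
        meta = ev.with_name(ev.name.replace(".events.tsv", ".meta.yaml"))
        if not meta.exists():
            raise ValidationError(f"missing metadata file for {ev}")
        series.append(load_event_series(ev, meta))
    return series


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; per-cell failures are logged, not fatal.

    Returns a dict with the feature table, population outputs, the
    exclusion log, and the provenance record; all are also written under
    ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.cohorts:
        sim_dir = out_dir / "simulated"
        simulate_to_dir(config, sim_dir)
        input_dir = sim_dir
    elif config.input_dir:
        input_dir = Path(config.input_dir)
    else:
        raise ValidationError("config needs input_dir or cohorts to simulate")

    all_series = load_series_dir(input_dir)
    exclusions: list[dict] = []
    rows = []
    for series in all_series:
        decision = filter_by_duration(series, config.min_duration_s)
        if not decision.accepted:
            exclusions.append(
                {"cell_id": series.cell_id, "reason": decision.reason}
            )
            continue
        try:
            classified = classify_events(series, config.classifier)
            fv = extract_features(series, classified, config.features)
        except InsufficientDataError as exc:
            exclusions.append({"cell_id": series.cell_id, "reason": str(exc)})
            logger.warning("excluded %s: %s", series.cell_id, exc)
            continue
        rows.append(fv.as_row())

    if not rows:
        raise ValidationError("no cells survived filtering")
    feature_df = write_feature_table(rows, out_dir / "feature_table.tsv")
    pd.DataFrame(
        exclusions, columns=["cell_id", "reason"]
    ).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)

    outputs: dict = {"feature_table": feature_df, "exclusions": exclusions}

    if len(feature_df) >= 3:
        matrix = assemble_population(feature_df)
        cello = clusterogram(matrix, config.linkage_method, config.distance)
        (out_dir / "cell_dendrogram.nwk").write_text(
            linkage_to_newick(cello.linkage_matrix, matrix.cell_ids) + "\n"
        )
        perplexity = min(config.perplexity, len(feature_df) - 1)
        emb = tsne_pseudotimeline(matrix, perplexity, config.seed)
        pd.DataFrame(
            {
                "cell_id": matrix.cell_ids,
                "group_label": matrix.group_labels,
                "tsne1": emb.coordinates[:, 0],
                "tsne2": emb.coordinates[:, 1],
            }
        ).to_csv(out_dir / "tsne_coordinates.tsv", sep="\t", index=False)
        outputs["clusterogram"] = cello
        outputs["embedding"] = emb

        summary = group_means(matrix)
        if len(summary.group_names) >= 3:
            summary = group_linkage(summary, config.linkage_method)
            (out_dir / "group_dendrogram.nwk").write_text(
                linkage_to_newick(summary.linkage_matrix, summary.group_names)
                + "\n"
            )
        outputs["group_summary"] = summary

        if feature_df["group_label"].nunique() >= 2:
            stats_rows = []
            for feat in CLUSTER_FEATURES:
                try:
                    cmp_res = compare_groups(feature_df, feat)
                except ValidationError as exc:
                    logger.warning("skipping stats for %s: %s", feat, exc)
                    continue
                for _, row in cmp_res.tukey.iterrows():
                    stats_rows.append(
                        {
                            "feature": feat,
                            "anova_f": cmp_res.anova_f,
                            "anova_p": cmp_res.anova_p,
                            "group1": row["group1"],
                            "group2": row["group2"],
                            "meandiff": row["meandiff"],
                            "tukey_p_adj": row["p_adj"],
                        }
                    )
            if stats_rows:
                pd.DataFrame(stats_rows).to_csv(
                    out_dir / "group_statistics.tsv", sep="\t", index=False
                )
                outputs["group_statistics"] = pd.DataFrame(stats_rows)

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "n_cells_in": len(all_series),
        "n_cells_analyzed": len(feature_df),
        "n_cells_excluded": len(exclusions),
        "input_checksums": {
            p.name: _sha256(p) for p in sorted(Path(input_dir).glob("*.events.tsv"))
        },
    }
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    outputs["provenance"] = provenance
    return outputs
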