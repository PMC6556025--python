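"""Stage orchestration: simulate -> extract -> select -> roc, with manifests.

Each stage writes plain CSV artifacts plus a JSON manifest echoing the full
configuration, the seed and per-stage counts, so a run is reproducible
bit-for-bit from its manifest.  Stages can run individually (reading the
previous stage's files) or end-to-end in memory via :func:`run_all`.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CthistError, Group
from .histogram import HISTOGRAM_FEATURE_NAMES, HistogramConfig, compute_all
from .io import (
    read_feature_table,
    read_mask,
    read_volume,
    write_clinical_table,
    write_feature_table,
    write_mask,
    write_volume,
)
from .preprocess import PreprocessConfig, preprocess
from .roc import delong_test, fit_score_model, roc_curve
from .selection import SelectionConfig, run_selection
from .shape import SHAPE_FEATURE_NAMES, compute_shape, screen_shape_vs_histogram
from .synthetic import CohortSpec, cohort_groups, make_lesion_volume


class MissingUpstreamError(CthistError):
    """A stage input is absent; the message names the command to run."""


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    surface: str = "mesh"

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            cohort=CohortSpec(**raw.get("cohort", {})),
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            histogram=HistogramConfig(**raw.get("histogram", {})),
            selection=SelectionConfig(**raw.get("selection", {})),
            surface=raw.get("surface", "mesh"),
        )
        if seed is not None:
            cfg.cohort.seed = int(seed)
        return cfg

    def echo(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "preprocess": dataclasses.asdict(self.preprocess),
            "histogram": dataclasses.asdict(self.histogram),
            "selection": dataclasses.asdict(self.selection),
            "surface": self.surface,
        }


def _write_manifest(out: Path, payload: dict) -> None:
    payload = {"cthist_version": __version__, **payload}
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def cmd_simulate(config: RunConfig, out) -> None:
    """Write the synthetic cohort: volumes, masks and the clinical table."""
    out = Path(out)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    n = config.cohort.n_pos + config.cohort.n_neg
    for i in range(n):
        vol, mask, rec = make_lesion_volume(config.cohort, i)
        write_volume(vol, out / "volumes" / f"{rec.subject_id}.nii.gz")
        write_mask(mask, out / "masks" / f"{rec.subject_id}.nii.gz")
        records.append(rec)
    write_clinical_table(records, out / "clinical.csv")
    _write_manifest(out, {"config": config.echo(), "seed": config.cohort.seed,
                          "stages": {"simulate": {"n_subjects": n}}})


def _subject_features(config: RunConfig, vol, mask, rec) -> dict:
    vol_p, mask_p = preprocess(vol, mask, config.preprocess)
    row = {"subject_id": rec.subject_id, "group": rec.group.value}
    row.update(compute_all(vol_p, mask_p, config.histogram))
    row.update(compute_shape(mask_p, surface=config.surface).as_dict())
    return row


def _extract_rows(config: RunConfig, out: Path | None) -> pd.DataFrame:
    """Features per subject, from files under ``out`` if present else in memory."""
    rows = []
    if out is not None and (out / "volumes").is_dir():
        from .io import read_clinical_table

        records = read_clinical_table(out / "clinical.csv")
        for rec in records:
            vol = read_volume(out / "volumes" / f"{rec.subject_id}.nii.gz")
            mask = read_mask(out / "masks" / f"{rec.subject_id}.nii.gz", vol)
            rows.append(_subject_features(config, vol, mask, rec))
    else:
        n = config.cohort.n_pos + config.cohort.n_neg
        for i in range(n):
            vol, mask, rec = make_lesion_volume(config.cohort, i)
            rows.append(_subject_features(config, vol, mask, rec))
    return pd.DataFrame(rows)


def cmd_extract(config: RunConfig, out) -> pd.DataFrame:
    """Preprocess every subject and write the 42+9 feature table."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    table = _extract_rows(config, out)
    write_feature_table(table, out / "features.csv")
    _write_manifest(out, {
        "config": config.echo(), "seed": config.cohort.seed,
        "stages": {"extract": {
            "n_subjects": len(table),
            "n_histogram_features": len(HISTOGRAM_FEATURE_NAMES),
            "n_shape_features": len(SHAPE_FEATURE_NAMES),
        }},
    })
    return table


def _load_features(out: Path) -> pd.DataFrame:
    path = out / "features.csv"
    if not path.exists():
        raise MissingUpstreamError(
            f"{path} not found; run the 'extract' command first"
        )
    return read_feature_table(path)


def cmd_select(config: RunConfig, out) -> "SelectionArtifacts":
    """Run two-step selection on the histogram features; screen the shape set."""
    out = Path(out)
    table = _load_features(out)
    hist_cols = [c for c in HISTOGRAM_FEATURE_NAMES if c in table.columns]
    report = run_selection(table[["subject_id", "group", *hist_cols]], config.selection)
    report.per_feature.to_csv(out / "selection_report.csv", index=False)
    report.spearman_matrix.to_csv(out / "spearman_matrix.csv")

    shape_cols = [c for c in SHAPE_FEATURE_NAMES if c in table.columns]
    if shape_cols and report.representative_set:
        rho, screen = screen_shape_vs_histogram(
            table[shape_cols], table[report.representative_set],
            table["group"].to_numpy(), config.selection.alpha,
        )
        rho.to_csv(out / "shape_spearman.csv")
        screen.to_csv(out / "shape_screen.csv", index=False)
    _write_manifest(out, {
        "config": config.echo(), "seed": config.cohort.seed,
        "stages": {"select": {
            "n_features_tested": len(hist_cols),
            "n_step1_pass": report.n_step1,
            "n_step2_pass": report.n_step2,
            "representative_set": report.representative_set,
        }},
    })
    return report


def _models_from(representative: list[str]) -> list[tuple[str, list[str]]]:
    """Single features, all pairs and the full combination (7 when 3 survive)."""
    models = [(f, [f]) for f in representative]
    for a, b in itertools.combinations(representative, 2):
        models.append((f"{a}+{b}", [a, b]))
    if len(representative) > 2:
        models.append(("+".join(representative), list(representative)))
    return models


def cmd_roc(config: RunConfig, out) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC/AUC per representative model and all pairwise DeLong comparisons."""
    out = Path(out)
    table = _load_features(out)
    rep_path = out / "selection_report.csv"
    if not rep_path.exists():
        raise MissingUpstreamError(
            f"{rep_path} not found; run the 'select' command first"
        )
    per_feature = pd.read_csv(rep_path)
    survived = per_feature[per_feature["step2_pass"] & (per_feature["eliminated_by"].fillna("") == "")]
    representative = [f for f in HISTOGRAM_FEATURE_NAMES if f in set(survived["feature"])]
    labels = (table["group"] == Group.EGFR_POS.value).astype(int).to_numpy()

    roc_rows, scores = [], {}
    for name, feats in _models_from(representative):
        s = fit_score_model(table[feats].to_numpy(), labels, name)
        scores[name] = s
        r = roc_curve(s, labels, name)
        roc_rows.append({
            "model": name, "auc": r.auc, "ci95_low": r.ci95_low,
            "ci95_high": r.ci95_high, "threshold": r.threshold,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
        })
    pd.DataFrame(roc_rows).to_csv(out / "roc_results.csv", index=False)

    delong_rows = []
    for (na, sa), (nb, sb) in itertools.combinations(scores.items(), 2):
        c = delong_test(sa, sb, labels, na, nb)
        delong_rows.append({
            "model_a": c.model_a, "model_b": c.model_b, "auc_a": c.auc_a,
            "auc_b": c.auc_b, "auc_diff": c.auc_diff, "z": c.z, "p": c.p,
        })
    pd.DataFrame(delong_rows).to_csv(out / "delong_pairs.csv", index=False)
    return pd.DataFrame(roc_rows), pd.DataFrame(delong_rows)


def run_all(config: RunConfig, out) -> dict:
    """simulate (in memory) -> extract -> select -> roc, with one manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    table = _extract_rows(config, None)
    write_feature_table(table, out / "features.csv")
    report = cmd_select(config, out)
    stages = {
        "extract": {
            "n_subjects": len(table),
            "n_histogram_features": len(HISTOGRAM_FEATURE_NAMES),
            "n_shape_features": len(SHAPE_FEATURE_NAMES),
        },
        "select": {
            "n_features_tested": len(HISTOGRAM_FEATURE_NAMES),
            "n_step1_pass": report.n_step1,
            "n_step2_pass": report.n_step2,
            "representative_set": report.representative_set,
        },
    }
    if report.representative_set:
        roc_df, delong_df = cmd_roc(config, out)
        stages["roc"] = {"n_models": len(roc_df), "n_delong_pairs": len(delong_df)}
    else:
        stages["roc"] = {"skipped": "no representative features"}
    manifest = {"config": config.echo(), "seed": config.cohort.seed, "stages": stages}
    _write_manifest(out, manifest)
    return {"cthist_version": __version__, **manifest}
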