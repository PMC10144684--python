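"""End-to-end co-clinical analysis pipeline.

Chains the analysis stages over a study manifest, for both cohorts:

1. parameter maps — fit ADC and SER inside each lesion mask;
2. features — extract the per-lesion biomarkers at every timepoint;
3. response — T0 vs T1 response tables and waterfall orderings;
4. expression — optionally simulate on-treatment (T1) tables from T0;
5. association — Spearman association of the feature delta against
   expression for each cohort, plus cross-cohort overlap and volcano data.

All outputs are plain CSV/TSV/JSON and a run log recording seeds, versions
and the configuration, so a rerun under the same seed is byte-identical.
Stages skip work whose outputs already exist when ``resume`` is enabled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .association import cohort_overlap, spearman_associate, volcano_data
from .errors import CoclinError
from .features import extract_lesion_features
from .imaging import compute_ser_map, fit_adc_map
from .omics import harmonize_gene_sets, per_sample_r2, simulate_on_treatment
from .response import build_response_table, response_table_frame, waterfall_order

COHORTS = ("patient", "PDX")


class PipelineError(CoclinError):
    """A stage failed; the message names the stage and offending subject."""


@dataclass
class PipelineConfig:
    feature_name: str = "volume"
    delta_mode: str = "percent"       # feature delta used for association
    n_top: int = 500
    n_baseline: int = 10
    late_offset: float = 360.0
    simulate_t1: bool = True
    expr_timepoint_mode: str = "T0"   # associate baseline expression ("T0") or "delta"
    alpha: float = 0.05
    seed: int = 0
    resume: bool = False


_FLOAT_FMT = "%.10g"


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _stage_maps_and_features(manifest: dict, config: PipelineConfig, out: Path) -> Path:
    """Stages 1–2: parameter maps and lesion features for every study."""
    features_csv = out / "lesion_features.csv"
    if config.resume and features_csv.exists():
        return features_csv
    base = Path(manifest["_base"])
    rows = []
    for subject in manifest["subjects"]:
        sid = subject["subject_id"]
        cohort = subject["cohort"]
        for tp, entry in sorted(subject["timepoints"].items()):
            try:
                dwi = cio.read_series_nifti(base / entry["dwi"])
                dce = cio.read_series_nifti(base / entry["dce"])
                mask = cio.read_mask_nifti(base / entry["mask"], label=f"{sid}-lesion")
                adc_map = fit_adc_map(dwi, mask)
                ser_map = compute_ser_map(
                    dce, mask,
                    n_baseline=config.n_baseline, late_offset=config.late_offset,
                )
                feats = extract_lesion_features(
                    mask, adc_map=adc_map, ser_map=ser_map,
                    subject_id=sid, timepoint=tp,
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage 'maps/features' failed for subject {sid} {tp}: {exc}"
                ) from exc
            row = asdict(feats)
            row["cohort"] = cohort
            rows.append(row)
    frame = pd.DataFrame(rows).sort_values(["cohort", "subject_id", "timepoint"])
    _write_csv(frame, features_csv)
    return features_csv


def _stage_response(features_csv: Path, config: PipelineConfig, out: Path) -> dict:
    """Stage 3: response tables and waterfall orderings per cohort."""
    from .features import LesionFeatures

    frame = pd.read_csv(features_csv)
    deltas: dict[str, pd.Series] = {}
    for cohort in COHORTS:
        sub = frame[frame["cohort"] == cohort]
        feats = [
            LesionFeatures(**{k: row[k] for k in (
                "subject_id", "lesion_label", "timepoint", "longest_diameter",
                "volume", "adc_mean", "adc_median", "ser_mean", "ser_median",
                "modality", "study_date",
            )})
            for _, row in sub.fillna({"study_date": ""}).iterrows()
        ]
        records, exclusions = build_response_table(
            feats, config.feature_name, cohort=cohort
        )
        ordered = waterfall_order(records)
        _write_csv(response_table_frame(records), out / f"response_{cohort}.csv")
        _write_csv(response_table_frame(ordered), out / f"waterfall_{cohort}.csv")
        (out / f"response_{cohort}_exclusions.json").write_text(
            json.dumps(exclusions, indent=1, sort_keys=True)
        )
        deltas[cohort] = pd.Series(
            {r.subject_id: r.response_rate for r in records},
            name=f"{config.feature_name}_rr",
        )
    return deltas


def _stage_expression(manifest: dict, config: PipelineConfig, out: Path) -> dict:
    """Stage 4: load T0 expression and (optionally) simulate T1 per cohort."""
    base = Path(manifest["_base"])
    tables: dict[str, dict] = {}
    for cohort in COHORTS:
        t0 = cio.read_expression_tsv(
            base / manifest["expression"][cohort], cohort=cohort, timepoint="T0"
        )
        entry = {"T0": t0}
        if config.simulate_t1:
            t1, assignment = simulate_on_treatment(t0, seed=config.seed)
            cio.write_expression_tsv(t1, out / f"expression_{cohort}_T1.tsv")
            _write_tsv(assignment.to_frame(), out / f"factors_{cohort}.tsv")
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = per_sample_r2(t0, t1)
            _write_tsv(r2.to_frame(), out / f"simulation_r2_{cohort}.tsv")
            entry["T1"] = t1
        tables[cohort] = entry
    return tables


def _stage_association(
    tables: dict, deltas: dict, config: PipelineConfig, out: Path
) -> dict:
    """Stage 5: per-cohort Spearman association and cross-cohort overlap."""
    pat, pdx, _ = harmonize_gene_sets(tables["patient"]["T0"], tables["PDX"]["T0"])
    harmonized = {"patient": pat, "PDX": pdx}
    results = {}
    for cohort in COHORTS:
        expr: "object" = harmonized[cohort]
        if config.expr_timepoint_mode == "delta" and "T1" in tables[cohort]:
            genes = harmonized[cohort].gene_symbols
            # absolute per-gene expression change; signed, so passed as a frame
            expr = (
                tables[cohort]["T1"].values.loc[genes]
                - tables[cohort]["T0"].values.loc[genes]
            )
        feature = deltas[cohort]
        res = spearman_associate(
            expr, feature, n_top=config.n_top,
            feature_name=f"{config.feature_name}_delta_{config.delta_mode}",
            timepoint_mode=config.expr_timepoint_mode,
            cohort=cohort,
        )
        _write_tsv(res.table, out / f"association_{cohort}.tsv")
        _write_tsv(volcano_data(res, alpha=config.alpha), out / f"volcano_{cohort}.tsv")
        pd.DataFrame({"gene_symbol": res.top_list}).to_csv(
            out / f"top_genes_{cohort}.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene_symbol": res.bottom_list}).to_csv(
            out / f"bottom_genes_{cohort}.tsv", sep="\t", index=False
        )
        results[cohort] = res
    overlap = {
        region: cohort_overlap(results["patient"], results["PDX"], region=region)
        for region in ("top", "bottom")
    }
    (out / "overlap.json").write_text(
        json.dumps(
            {region: {"counts": o.counts, "genes": o.genes} for region, o in overlap.items()},
            indent=1, sort_keys=True,
        )
    )
    return results


def run_pipeline(
    manifest: Union[str, Path, dict],
    config: Union[PipelineConfig, None] = None,
    out_dir: Union[str, Path] = "results",
) -> Path:
    """Run the full analysis over a study manifest; returns the results dir."""
    if config is None:
        config = PipelineConfig()
    if not isinstance(manifest, dict):
        manifest = cio.load_manifest(manifest)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    features_csv = _stage_maps_and_features(manifest, config, out)
    deltas = _stage_response(features_csv, config, out)
    tables = _stage_expression(manifest, config, out)
    _stage_association(tables, deltas, config, out)

    log = {
        "version": __version__,
        "config": asdict(config),
        "numpy": np.__version__,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    return out
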