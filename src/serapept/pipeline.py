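"""End-to-end orchestration: spectra → QC → peaks → alignment → SAM →
bootstrap/regression → adduct annotation, with per-stage provenance.

Inputs are a sample manifest (CSV: sample_id, group, age, gender, files) whose
``files`` column lists per-replicate spectra — either 2-column text peak
lists (used as-is) or mzML profile scans (averaged in windows of
``scan_window`` consecutive scans, then centroided) — plus a reference peak
list for the degradation quality gate. Every stage writes its artifact and a
JSON provenance record; a single global seed derives per-stage seeds
deterministically from the stage name.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate_id import AdductRule, find_adducts
from .differential import DEFAULT_COMPARISONS, SamConfig, run_all_comparisons
from .peak_detect import PeakDetectConfig, detect_peaks
from .preprocess_align import (AlignedTable, PreprocessConfig, align_samples,
                               average_replicates, exclude_signals,
                               preprocess_sample)
from .quality_gate import FpaConfig, compute_sdqs, select_samples
from .spectra_io import PeakList, average_scans, read_peaklist_text, read_spectra
from .validation import BootstrapConfig, bootstrap_validate, regress_adjusted

logger = logging.getLogger("serapept")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the stage name."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    manifest_path: str
    reference_path: str
    output_dir: str
    fpa: FpaConfig = field(default_factory=FpaConfig)
    peaks: PeakDetectConfig = field(default_factory=PeakDetectConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sam: SamConfig = field(default_factory=SamConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    adducts: AdductRule = field(default_factory=AdductRule)
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    scan_window: int = 15
    covariates: tuple[str, ...] = ("age", "gender")
    regression_n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {"fpa": FpaConfig, "peaks": PeakDetectConfig,
                  "preprocess": PreprocessConfig, "sam": SamConfig,
                  "bootstrap": BootstrapConfig, "adducts": AdductRule}
        for key, val in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**val)
            elif key == "comparisons":
                kwargs[key] = tuple(tuple(pair) for pair in val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _load_replicates(row: pd.Series, base: Path, cfg: RunConfig) -> list[PeakList]:
    reps = []
    for k, name in enumerate(str(row["files"]).split(";")):
        path = base / name
        if path.suffix.lower() == ".mzml":
            scans = read_spectra(path, "mzML")
            spectrum = average_scans(scans, window=cfg.scan_window)
            pl = detect_peaks(spectrum, cfg.peaks)
            pl.sample_id, pl.replicate = row["sample_id"], k
        else:
            pl = read_peaklist_text(path, sample_id=row["sample_id"], replicate=k)
        reps.append(pl)
    return reps


def _write_provenance(outdir: Path, stage: str, record: dict) -> None:
    with open(outdir / f"provenance_{stage}.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in sequence and return a summary report.

    The composition is stateless: the summary counts equal what stage-by-
    stage manual invocation produces with the same per-stage seeds.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": cfg.seed}

    def _stage(name: str):
        logger.info("stage %s", name)
        return name

    # --- spectra_io: load manifest and replicate spectra -------------------
    stage = _stage("spectra_io")
    try:
        manifest = pd.read_csv(cfg.manifest_path)
        base = Path(cfg.manifest_path).parent
        replicates = {row["sample_id"]: _load_replicates(row, base, cfg)
                      for _, row in manifest.iterrows()}
        reference = read_peaklist_text(cfg.reference_path, sample_id="reference")
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["n_samples_input"] = len(manifest)
    _write_provenance(outdir, stage, {"n_samples": len(manifest),
                                      "scan_window": cfg.scan_window})

    # --- quality_gate -------------------------------------------------------
    stage = _stage("quality_gate")
    try:
        # score each sample on its raw replicate-averaged peak list
        merge_cfg = dc_replace(cfg.preprocess, replicate_min_presence=1)
        scores = {}
        for sid, reps in replicates.items():
            merged = average_replicates(reps, merge_cfg)
            merged.sample_id = sid
            scores[sid] = compute_sdqs(merged, reference, cfg.fpa)
        selected, qc_report = select_samples(manifest, scores)
        qc_report.to_csv(outdir / "qc_report.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["n_samples_selected"] = len(selected)
    _write_provenance(outdir, stage, {
        "overall_threshold": cfg.fpa.overall_threshold,
        "ratio_threshold": cfg.fpa.ratio_threshold,
        "n_in": len(manifest), "n_out": len(selected)})

    # --- preprocess_align ---------------------------------------------------
    stage = _stage("preprocess_align")
    try:
        reps_selected = {sid: replicates[sid] for sid in selected["sample_id"]}
        representatives = {sid: preprocess_sample(reps, cfg.preprocess)
                           for sid, reps in reps_selected.items()}
        table = align_samples(representatives, selected, cfg.preprocess)
        n_detected = table.abundance.shape[0]
        table = exclude_signals(table, cfg.preprocess.exclusion_masses,
                                cfg.preprocess.exclusion_tolerance)
        n_retained = table.abundance.shape[0]
        table.abundance.to_csv(outdir / "aligned_table.csv")
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["n_signals_detected"] = n_detected
    summary["n_signals_retained"] = n_retained
    logger.info("signals: %d detected -> %d retained", n_detected, n_retained)
    _write_provenance(outdir, stage, table.provenance)

    # --- differential -------------------------------------------------------
    stage = _stage("differential")
    try:
        sam_cfg = dc_replace(cfg.sam, seed=stage_seed(cfg.seed, stage))
        results, signature = run_all_comparisons(table, sam_cfg, cfg.comparisons)
        for name, res in results.items():
            res.stats.to_csv(outdir / f"sam_{name}.csv")
        signature.to_csv(outdir / "signature.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["signature"] = {name: sorted(grp["signal"].tolist())
                            for name, grp in signature.groupby("comparison")}
    summary["n_signals_tested"] = n_retained
    _write_provenance(outdir, stage, {"n_permutations": cfg.sam.n_permutations,
                                      "q_threshold": cfg.sam.q_threshold,
                                      "s0": {n: r.s0 for n, r in results.items()}})

    # --- validation ---------------------------------------------------------
    stage = _stage("validation")
    try:
        comp_map = {f"{a}_vs_{b}": (a, b) for a, b in cfg.comparisons}
        boot_cfg = BootstrapConfig(n_datasets=cfg.bootstrap.n_datasets,
                                   significance_rule=cfg.bootstrap.significance_rule,
                                   seed=stage_seed(cfg.seed, stage))
        boot_report = bootstrap_validate(table, comp_map, sam_cfg, boot_cfg)
        boot_report.to_csv(outdir / "bootstrap_report.csv", index=False)
        reg_rows = []
        for _, row in signature.iterrows():
            pair = comp_map[row["comparison"]]
            for cov in cfg.covariates:
                reg = regress_adjusted(table, row["signal"], pair, cov,
                                       n_boot=cfg.regression_n_boot,
                                       seed=stage_seed(cfg.seed, f"regress_{cov}"))
                reg_rows.append(reg.as_dict())
        reg_report = pd.DataFrame(reg_rows)
        reg_report.to_csv(outdir / "regression_report.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["bootstrap_occurrences"] = {
        f"{r.comparison}:{r.signal}": f"{r.occurrences}/{r.n_datasets}"
        for r in boot_report.itertuples()}
    _write_provenance(outdir, stage, {"n_datasets": cfg.bootstrap.n_datasets,
                                      "significance_rule": cfg.bootstrap.significance_rule})

    # --- annotate_id --------------------------------------------------------
    stage = _stage("annotate_id")
    try:
        annotations = find_adducts(table.signals, cfg.adducts)
        ann_df = pd.DataFrame([{"parent_mz": a.parent_mz, "adduct_mz": a.adduct_mz,
                                "multiplicity": a.multiplicity,
                                "mass_error": a.mass_error} for a in annotations])
        ann_df.to_csv(outdir / "adduct_annotations.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage {stage}: {exc}") from exc
    summary["n_adducts_annotated"] = len(annotations)
    _write_provenance(outdir, stage, {"adduct_mass": cfg.adducts.adduct_mass,
                                      "max_multiples": cfg.adducts.max_multiples})

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
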