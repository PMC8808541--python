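"""Configuration-driven orchestration of the full analysis.

Stages (simulate -> qc -> medians -> select -> gradients -> overlap ->
predict) exchange plain TSV/JSON artifacts in a single output directory, so
any stage can be re-run from the previous stage's files and a full run is
byte-reproducible under fixed seeds.  A manifest records parameters, per-
stage timings and record counts, and input checksums.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .age_groups import RunningMedianTransformer
from .gradients import GradientClusterer
from .overlap import overlap_probability
from .prediction import rf_cv
from .qc import filter_probes, flag_outlier_samples
from .selection import genes_multi_marker, pearson_selection, select_markers
from .synthetic import TrajectorySpec, generate_beta_matrix, generate_cohort, standard_panel

__all__ = ["RunConfig", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "medians", "select", "gradients", "overlap", "predict")

_DEFAULTS: dict = {
    "out_dir": "methylaging_run",
    "seed": 0,
    "simulate": {
        "n_samples": 400,
        "age_min": 0.0,
        "age_max": 102.0,
        "age_distribution": "uniform",
        "missing_rate": 0.0,
        "outlier_samples": 0,
        "panel": {
            "n_null": 850,
            "n_weak_linear": 100,
            "n_planted": 50,
            "amplitude": 0.3,
            "baseline": 0.1,
            "noise_sd": 0.03,
        },
    },
    "inputs": {},  # matrix / metadata / blacklists / gene_map / clock paths
    "qc": {"max_missing": 10, "bins": 10, "k_sd": 3.0},
    "medians": {"fraction": 0.1, "edge_tolerance": 2.0},
    "select": {
        "fc_threshold": 2.0,
        "delta_threshold": 0.2,
        "fdr": 0.05,
        "rel_sd_max": 0.5,
        "mode": "fc",
        "rel_sd_scope": "all",
        "equal_var": False,
    },
    "gradients": {"n_clusters": 2, "window": 21, "polyorder": 2, "perplexity": 30.0},
    "overlap": {"reference_file": None, "universe": None},
    "predict": {"folds": 5},
}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


class RunConfig(dict):
    """Validated stage parameters; missing fields take the documented defaults."""

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls(_merge(_DEFAULTS, raw or {}))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        med = self["medians"]
        if not 0 < med["fraction"] <= 1:
            raise ConfigError(f"medians.fraction must be in (0, 1], got {med['fraction']}")
        if med["edge_tolerance"] < 0:
            raise ConfigError("medians.edge_tolerance must be >= 0")
        sim = self["simulate"]
        if not 0 <= sim["missing_rate"] <= 1:
            raise ConfigError(f"simulate.missing_rate must be in [0, 1], got {sim['missing_rate']}")
        if sim["n_samples"] < 1:
            raise ConfigError("simulate.n_samples must be >= 1")
        if self["select"]["mode"] not in ("fc", "abs", "overlap"):
            raise ConfigError(f"select.mode must be fc/abs/overlap, got {self['select']['mode']!r}")
        if self["qc"]["bins"] < 2:
            raise ConfigError("qc.bins must be >= 2")
        if self["predict"]["folds"] < 2:
            raise ConfigError("predict.folds must be >= 2")


def _merge(defaults: dict, override: dict) -> dict:
    out = {}
    for key, val in defaults.items():
        if key in override and isinstance(val, dict) and isinstance(override[key], dict):
            out[key] = _merge(val, override[key])
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = val
    for key in override:
        if key not in defaults:
            raise ConfigError(f"unknown config field {key!r}")
    return out


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    meta = generate_cohort(
        sim["n_samples"], sim["age_min"], sim["age_max"], sim["age_distribution"], seed=seed
    )
    specs = standard_panel(seed=seed, **sim["panel"])
    matrix, truth = generate_beta_matrix(
        meta, specs,
        missing_rate=sim["missing_rate"],
        outlier_samples=sim["outlier_samples"],
        seed=seed + 1,
    )
    mio.write_beta_matrix(matrix, out / "beta_matrix.tsv")
    mio.write_sample_metadata(meta, out / "sample_metadata.tsv")
    mio.write_json(truth.to_dict(), out / "cohort_truth.json")
    return {"n_probes": matrix.shape[0], "n_samples": matrix.shape[1]}


def _load_matrix_meta(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    inputs = cfg["inputs"]
    mpath = Path(inputs.get("matrix") or out / "beta_matrix.tsv")
    spath = Path(inputs.get("metadata") or out / "sample_metadata.tsv")
    for p in (mpath, spath):
        if not p.exists():
            raise FileNotFoundError(
                f"required input {p} not found; run the simulate stage or point "
                f"inputs.matrix / inputs.metadata at existing files"
            )
    return mio.read_beta_matrix(mpath), mio.read_sample_metadata(spath)


def stage_qc(cfg: RunConfig, out: Path) -> dict:
    matrix, meta = _load_matrix_meta(cfg, out)
    blacklists = {}
    for path in cfg["inputs"].get("blacklists") or []:
        blacklists[Path(path).stem] = mio.read_blacklist(path)
    matrix, probe_report = filter_probes(
        matrix, blacklists or None, max_missing=cfg["qc"]["max_missing"]
    )
    matrix, flagged, sample_report = flag_outlier_samples(
        matrix, bins=cfg["qc"]["bins"], k_sd=cfg["qc"]["k_sd"]
    )
    meta = meta[meta["sample_id"].isin(matrix.columns)]
    mio.write_beta_matrix(matrix, out / "qc_matrix.tsv")
    mio.write_sample_metadata(meta, out / "qc_metadata.tsv")
    report = {"probes": probe_report, "samples": sample_report}
    mio.write_json(report, out / "qc_report.json")
    return {
        "n_probes": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "flagged_samples": flagged,
    }


def _load_qc(out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    mpath, spath = out / "qc_matrix.tsv", out / "qc_metadata.tsv"
    for p in (mpath, spath):
        if not p.exists():
            raise FileNotFoundError(f"required artifact {p} not found; run the qc stage first")
    return mio.read_beta_matrix(mpath), mio.read_sample_metadata(spath)


def stage_medians(cfg: RunConfig, out: Path) -> dict:
    matrix, meta = _load_qc(out)
    rmt = RunningMedianTransformer(
        fraction=cfg["medians"]["fraction"], edge_tolerance=cfg["medians"]["edge_tolerance"]
    )
    X = matrix.T.loc[meta["sample_id"]]
    medians = rmt.fit_transform(X, meta["age"].to_numpy())
    medians.to_csv(out / "running_medians.tsv", sep="\t")
    rmt.rel_sd_.to_csv(out / "rel_sd.tsv", sep="\t")
    rmt.n_used_.to_csv(out / "n_used.tsv", sep="\t")
    mio.write_json(rmt.index_.to_manifest(), out / "age_groups.json")
    return {
        "n_years_retained": int(len(rmt.retained_years_)),
        "age_range": list(rmt.age_range_),
    }


def stage_select(cfg: RunConfig, out: Path) -> dict:
    matrix, meta = _load_qc(out)
    med_path = out / "running_medians.tsv"
    if not med_path.exists():
        raise FileNotFoundError(f"required artifact {med_path} not found; run the medians stage first")
    medians = pd.read_csv(med_path, sep="\t", index_col=0)
    medians.columns = medians.columns.astype(int)
    rel_sd = pd.read_csv(out / "rel_sd.tsv", sep="\t", index_col=0)
    rel_sd.columns = rel_sd.columns.astype(int)
    # group membership must match the medians artifact
    from .age_groups import build_age_groups

    matrix = matrix.loc[:, meta["sample_id"]]
    index = build_age_groups(
        meta["age"].to_numpy(), cfg["medians"]["fraction"], sample_ids=list(meta["sample_id"])
    )
    sc = cfg["select"]
    sel = select_markers(
        medians, rel_sd, matrix, index,
        fc_threshold=sc["fc_threshold"], delta_threshold=sc["delta_threshold"],
        fdr=sc["fdr"], rel_sd_max=sc["rel_sd_max"], mode=sc["mode"],
        equal_var=sc["equal_var"], rel_sd_scope=sc["rel_sd_scope"],
    )
    sel.to_csv(out / "marker_selection.tsv", sep="\t")
    pearson = pearson_selection(matrix, meta["age"].to_numpy(), fdr=sc["fdr"])
    pearson.to_csv(out / "pearson_selection.tsv", sep="\t")
    gene_map_path = cfg["inputs"].get("gene_map")
    if gene_map_path:
        genes, rep = genes_multi_marker(
            sel.index[sel["selected"]], mio.read_probe_gene_map(gene_map_path)
        )
        mio.write_json({"genes": genes, "report": rep}, out / "genes_multi_marker.json")
    return {
        "n_selected": int(sel["selected"].sum()),
        "n_fc_pass": int(sel["fc_pass"].sum()),
        "n_abs_pass": int(sel["abs_pass"].sum()),
        "n_overlap_pass": int(sel["overlap_pass"].sum()),
        "n_pearson_pass": int(pearson["pearson_pass"].sum()),
    }


def stage_gradients(cfg: RunConfig, out: Path) -> dict:
    sel_path = out / "marker_selection.tsv"
    if not sel_path.exists():
        raise FileNotFoundError(f"required artifact {sel_path} not found; run the select stage first")
    sel = pd.read_csv(sel_path, sep="\t", index_col=0)
    medians = pd.read_csv(out / "running_medians.tsv", sep="\t", index_col=0)
    medians.columns = medians.columns.astype(int)
    chosen = sel.index[sel["selected"].astype(bool)]
    if len(chosen) == 0:
        mio.write_json({"note": "no markers selected; gradients skipped"}, out / "cluster_summary.json")
        return {"n_markers": 0}
    gc = cfg["gradients"]
    clus = GradientClusterer(
        n_clusters=min(int(gc["n_clusters"]), len(chosen)),
        seed=int(cfg["seed"]),
        window=gc["window"], polyorder=gc["polyorder"], perplexity=gc["perplexity"],
    ).fit(medians.loc[chosen].dropna(axis=1))
    clus.normalized_.to_csv(out / "normalized_tracks.tsv", sep="\t")
    clus.gradients_.to_csv(out / "gradients.tsv", sep="\t")
    clus.smoothed_.to_csv(out / "smoothed_gradients.tsv", sep="\t")
    labels = pd.DataFrame({"marker_id": clus.gradients_.index, "cluster": clus.labels_})
    labels.to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    if clus.embedding_ is not None:
        pd.DataFrame(
            clus.embedding_, index=clus.gradients_.index, columns=["tsne1", "tsne2"]
        ).to_csv(out / "tsne_embedding.tsv", sep="\t")
    summary = clus.summary()
    summary_out = {
        "clusters": summary,
        "suggested_k": clus.suggested_k_,
        "configured_k": int(gc["n_clusters"]),
    }
    mio.write_json(summary_out, out / "cluster_summary.json")
    return {"n_markers": int(len(chosen)), "suggested_k": clus.suggested_k_}


def stage_overlap(cfg: RunConfig, out: Path) -> dict:
    ov = cfg["overlap"]
    if not ov.get("reference_file"):
        return {"skipped": "no overlap.reference_file configured"}
    sel = pd.read_csv(out / "marker_selection.tsv", sep="\t", index_col=0)
    selected = set(sel.index[sel["selected"].astype(bool)])
    reference = set(mio.read_blacklist(ov["reference_file"]))
    universe = ov.get("universe")
    if universe is None:
        universe = len(sel)
    test = overlap_probability(
        x=len(selected & reference), n=len(selected), D=len(reference), N=int(universe)
    )
    mio.write_json(test.to_dict(), out / "overlap.json")
    return test.to_dict()


def stage_predict(cfg: RunConfig, out: Path) -> dict:
    matrix, meta = _load_qc(out)
    sel_path = out / "marker_selection.tsv"
    if not sel_path.exists():
        raise FileNotFoundError(f"required artifact {sel_path} not found; run the select stage first")
    sel = pd.read_csv(sel_path, sep="\t", index_col=0)
    chosen = sel.index[sel["selected"].astype(bool)]
    if len(chosen) == 0:
        raise ValueError("no markers selected; cannot train an age predictor")
    features = matrix.loc[chosen, meta["sample_id"]].T
    report = rf_cv(
        features, meta["age"].to_numpy(), folds=int(cfg["predict"]["folds"]), seed=int(cfg["seed"])
    )
    predictions = report.pop("predictions")
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    mio.write_json(report, out / "prediction_report.json")
    clock_path = cfg["inputs"].get("clock")
    if clock_path:
        from .prediction import ClockModel, apply_linear_clock

        intercept, coefs = mio.read_clock_table(clock_path)
        clock_pred = apply_linear_clock(
            ClockModel(intercept, coefs), matrix.loc[:, meta["sample_id"]], drop_missing=True
        )
        clock_pred.rename_axis("sample_id").to_frame().to_csv(out / "clock_predictions.tsv", sep="\t")
    return {"mae_mean": report["mae_mean"], "pearson_mean": report["pearson_mean"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "medians": stage_medians,
    "select": stage_select,
    "gradients": stage_gradients,
    "overlap": stage_overlap,
    "predict": stage_predict,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Run the configured stages in order; returns the artifact directory.

    Any stage failure propagates after the manifest records which stage
    failed and why.
    """
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dict(cfg), "stages": {}, "inputs": {}}
    for key, path in (cfg["inputs"] or {}).items():
        if isinstance(path, str) and Path(path).exists():
            manifest["inputs"][key] = {"path": path, "sha256": _sha256(Path(path))}
    skip_simulate = bool(cfg["inputs"].get("matrix"))
    try:
        for stage in stages:
            if stage == "simulate" and skip_simulate:
                manifest["stages"][stage] = {"skipped": "external matrix supplied"}
                continue
            t0 = time.perf_counter()
            info = _STAGE_FUNCS[stage](cfg, out)
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **(info or {}),
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        mio.write_json(manifest, out / "manifest.json")
        raise
    mio.write_json(manifest, out / "manifest.json")
    return out
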