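"""End-to-end orchestration of the satellite-array analysis.

Stages run in dependency order on a single validated configuration:
synthetic generation (or file loading) -> bound/unbound classification ->
consensus rebuilding and per-copy divergence -> group summaries ->
randomization enrichment tests -> coverage aggregation (fold enrichment,
profiles, per-feature means) -> occupancy subsets and repeat fractions.
A single top-level seed fans out deterministically to stage seeds, so one
integer reproduces the entire run; every parameter and per-stage wall time
is logged, and the machine-readable report echoes the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from . import __version__ as _version
from .coverage import (
    CoverageTrack,
    extract_signal_matrix,
    fold_enrichment_track,
    occupancy_subsets,
    per_feature_mean,
    repeat_fraction_of_subsets,
    trimmed_mean_profile,
)
from .enrichment import RANDOMIZATION_MODES, run_enrichment_test
from .errors import ConfigError, DataError, SatArrayError
from .intervals import IntervalSet, merge_intervals, write_bed
from .repeats import (
    build_consensus,
    classify_copies,
    divergence_from_consensus,
    group_summary,
    two_sample_t_test,
)
from .simulate import SyntheticConfig, TrackSpec, generate_dataset, write_dataset

logger = logging.getLogger("satarray")

_STAGES = ("classify", "consensus", "summary", "enrichment", "aggregate", "occupancy")

_PARAM_DEFAULTS: Dict[str, Any] = {
    "min_overlap": 1,
    "n_randomizations": 1000,
    "randomization_mode": "same_chromosome",
    "trim_fraction": 0.5,
    "bin_size": 100,
    "flank": 1000,
    "body_bins": 10,
    "consensus_max_rounds": 5,
    "consensus_sample": 40,
    "min_replicate_support": None,
    "pseudocount": None,
    "top_k": None,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "satarray_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES})
    params: Dict[str, Any] = field(default_factory=lambda: dict(_PARAM_DEFAULTS))


def validate_config(raw: Optional[Dict[str, Any]]) -> PipelineConfig:
    """Fill defaults, check ranges and reject unknown keys; all violations
    are reported at once.  An empty config is a fully defaulted synthetic
    run."""
    raw = dict(raw or {})
    problems: List[str] = []
    known_top = {"seed", "out_dir", "synthetic", "stages", "params"}
    for key in raw:
        if key not in known_top:
            problems.append(f"unknown top-level key {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    out_dir = raw.get("out_dir", "satarray_out")

    syn_raw = dict(raw.get("synthetic") or {})
    syn_fields = {f.name for f in dataclasses.fields(SyntheticConfig)}
    for key in syn_raw:
        if key not in syn_fields:
            problems.append(f"unknown synthetic key {key!r}")
    syn_raw = {k: v for k, v in syn_raw.items() if k in syn_fields}
    if "chromosomes" in syn_raw:
        syn_raw["chromosomes"] = tuple(
            (str(n), int(l)) for n, l in syn_raw["chromosomes"])
    if "array_chromosomes" in syn_raw:
        syn_raw["array_chromosomes"] = tuple(syn_raw["array_chromosomes"])
    if "track_specs" in syn_raw:
        syn_raw["track_specs"] = tuple(
            TrackSpec(str(c), str(f), float(e)) for c, f, e in syn_raw["track_specs"])
    syn_raw.setdefault("seed", seed if isinstance(seed, int) else 0)
    synthetic = SyntheticConfig(**syn_raw)
    try:
        synthetic.validate()
    except ConfigError as exc:
        problems.append(str(exc))

    stages = {s: True for s in _STAGES}
    for key, val in dict(raw.get("stages") or {}).items():
        if key not in stages:
            problems.append(f"unknown stage {key!r}")
        elif not isinstance(val, bool):
            problems.append(f"stage toggle {key!r} must be boolean")
        else:
            stages[key] = val

    params = dict(_PARAM_DEFAULTS)
    for key, val in dict(raw.get("params") or {}).items():
        if key not in params:
            problems.append(f"unknown parameter {key!r}")
        else:
            params[key] = val
    if params["n_randomizations"] < 1:
        problems.append(
            f"n_randomizations must be >= 1, got {params['n_randomizations']}")
    if not (0 <= params["trim_fraction"] < 50):
        problems.append(
            f"trim_fraction must be in [0, 50), got {params['trim_fraction']}")
    if params["min_overlap"] < 1:
        problems.append(f"min_overlap must be >= 1, got {params['min_overlap']}")
    if params["randomization_mode"] not in RANDOMIZATION_MODES:
        problems.append(
            f"randomization_mode must be one of {RANDOMIZATION_MODES}")
    for key in ("bin_size", "body_bins"):
        if params[key] < 1:
            problems.append(f"{key} must be >= 1, got {params[key]}")
    if params["flank"] % params["bin_size"] != 0:
        problems.append("flank must be a multiple of bin_size")

    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return PipelineConfig(seed=seed, out_dir=out_dir, synthetic=synthetic,
                          stages=stages, params=params)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return validate_config(raw)


@dataclass
class ReportBundle:
    outputs: Dict[str, str]
    summary: Dict[str, Any]
    config_echo: Dict[str, Any]
    version: str
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version,
            "seed": self.seed,
            "outputs": self.outputs,
            "summary": self.summary,
            "config": self.config_echo,
        }, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _echo_config(cfg: PipelineConfig) -> Dict[str, Any]:
    syn = dataclasses.asdict(cfg.synthetic)
    syn["track_specs"] = [list(t) for t in cfg.synthetic.track_specs]
    syn["chromosomes"] = [list(c) for c in cfg.synthetic.chromosomes]
    syn["array_chromosomes"] = list(cfg.synthetic.array_chromosomes)
    return {"seed": cfg.seed, "out_dir": cfg.out_dir, "synthetic": syn,
            "stages": cfg.stages, "params": cfg.params}


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute all enabled stages; outputs get stable filenames under
    ``cfg.out_dir`` and a ``report.json`` ties every number to its file.

    A stage failure writes a ``FAILED`` marker naming the stage (partial
    outputs are retained) and re-raises.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_path = os.path.join(cfg.out_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    outputs: Dict[str, str] = {"log": log_path}
    summary: Dict[str, Any] = {}
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("enrichment",),
                       np.random.SeedSequence(cfg.seed).spawn(1))}
    current_stage = "simulate"
    try:
        # ---- synthetic generation ------------------------------------
        t0 = time.perf_counter()
        logger.info("stage=simulate seed=%d config=%s", cfg.synthetic.seed,
                    dataclasses.asdict(cfg.synthetic))
        ds = generate_dataset(cfg.synthetic)
        data_dir = os.path.join(cfg.out_dir, "dataset")
        for name, path in write_dataset(ds, data_dir).items():
            outputs[f"dataset/{name}"] = path
        summary["n_copies"] = len(ds.repeats)
        logger.info("stage=simulate done wall=%.2fs", time.perf_counter() - t0)

        classification_peaks = merge_intervals(IntervalSet(
            [iv for key in ds.peaks if key.startswith("control")
             for iv in ds.peaks[key]], ds.layout, validate=False))

        labeled = None
        if cfg.stages["classify"]:
            current_stage = "classify"
            t0 = time.perf_counter()
            labeled = classify_copies(ds.repeats, classification_peaks,
                                      cfg.params["min_overlap"])
            n_bound = sum(1 for c in labeled if c.bound)
            summary["n_bound"] = n_bound
            summary["n_unbound"] = len(labeled) - n_bound
            logger.info("stage=classify n_bound=%d n_unbound=%d wall=%.2fs",
                        n_bound, len(labeled) - n_bound, time.perf_counter() - t0)

        consensus = None
        if cfg.stages["consensus"]:
            current_stage = "consensus"
            if labeled is None:
                raise DataError("stage 'consensus' requires stage 'classify'")
            t0 = time.perf_counter()
            k = min(cfg.params["consensus_sample"], len(labeled))
            # deterministic sample: shortest-first keeps alignment cost low
            sample = sorted(labeled, key=lambda c: (c.length, c.interval.chrom,
                                                    c.interval.start))[:k]
            model = build_consensus([c.sequence for c in sample],
                                    cfg.params["consensus_max_rounds"])
            consensus = model.consensus
            cons_path = os.path.join(cfg.out_dir, "consensus.fa")
            with open(cons_path, "w") as fh:
                fh.write(">rebuilt_consensus\n")
                for i in range(0, len(consensus), 80):
                    fh.write(consensus[i:i + 80] + "\n")
            outputs["consensus.fa"] = cons_path
            # Divergence is measured against the family's reference unit
            # (shipped with the dataset, as a RepeatMasker-style repeat
            # model would be); the rebuilt instance consensus above is the
            # sample-level reconstruction and is reported alongside.
            labeled = divergence_from_consensus(labeled, ds.consensus)
            lab_path = os.path.join(cfg.out_dir, "repeats_labeled.tsv")
            with open(lab_path, "w") as fh:
                fh.write("chrom\tstart\tend\tstrand\tlength\tdivergence_pct\tbound\n")
                for c in labeled:
                    fh.write(f"{c.interval.chrom}\t{c.interval.start}\t"
                             f"{c.interval.end}\t{c.interval.strand}\t{c.length}\t"
                             f"{c.divergence:.4f}\t{int(c.bound)}\n")
            outputs["repeats_labeled.tsv"] = lab_path
            summary["consensus_length"] = len(consensus)
            summary["consensus_rounds"] = model.rounds
            logger.info("stage=consensus length=%d rounds=%d wall=%.2fs",
                        len(consensus), model.rounds, time.perf_counter() - t0)

        if cfg.stages["summary"]:
            current_stage = "summary"
            if labeled is None:
                raise DataError("stage 'summary' requires stage 'classify'")
            t0 = time.perf_counter()
            gs = group_summary(labeled)
            gs_path = os.path.join(cfg.out_dir, "group_summary.tsv")
            with open(gs_path, "w") as fh:
                fh.write("group\tn\tmean_length\tsd_length\t"
                         "mean_divergence\tsd_divergence\n")
                for name, g in (("bound", gs.bound), ("unbound", gs.unbound)):
                    md = "" if g.mean_divergence is None else f"{g.mean_divergence:.4f}"
                    sd = "" if g.sd_divergence is None else f"{g.sd_divergence:.4f}"
                    fh.write(f"{name}\t{g.n}\t{g.mean_length:.2f}\t"
                             f"{g.sd_length:.2f}\t{md}\t{sd}\n")
            outputs["group_summary.tsv"] = gs_path
            summary["group_summary"] = {
                "bound": dataclasses.asdict(gs.bound),
                "unbound": dataclasses.asdict(gs.unbound),
                "length_test": dataclasses.asdict(gs.length_test),
                "divergence_test": (dataclasses.asdict(gs.divergence_test)
                                    if gs.divergence_test else None),
            }
            logger.info("stage=summary length_p=%.3g wall=%.2fs",
                        gs.length_test.p, time.perf_counter() - t0)

        if cfg.stages["enrichment"]:
            current_stage = "enrichment"
            t0 = time.perf_counter()
            res = run_enrichment_test(
                classification_peaks, ds.repeat_annotation, ds.layout,
                N=cfg.params["n_randomizations"],
                mode=cfg.params["randomization_mode"],
                min_overlap=cfg.params["min_overlap"],
                seed=stage_seeds["enrichment"])
            enr_path = os.path.join(cfg.out_dir, "enrichment.tsv")
            with open(enr_path, "w") as fh:
                fh.write("query\treference\tO\tE\tratio\tb\tN\tp\tseed\tmode\n")
                fh.write(f"peaks\trepeats\t{res.O}\t{res.E:.4f}\t{res.ratio:.4f}\t"
                         f"{res.b}\t{res.N}\t{res.p:.6g}\t{res.seed}\t{res.mode}\n")
            outputs["enrichment.tsv"] = enr_path
            summary["enrichment"] = dataclasses.asdict(res)
            logger.info("stage=enrichment O=%d E=%.2f p=%.4g mode=%s wall=%.2fs",
                        res.O, res.E, res.p, res.mode, time.perf_counter() - t0)

        if cfg.stages["aggregate"]:
            current_stage = "aggregate"
            t0 = time.perf_counter()
            bound_features = IntervalSet(
                [c.interval for c in ds.repeats if c.bound], ds.layout,
                validate=False)
            all_features = ds.repeat_annotation
            agg: Dict[str, Any] = {}
            means_by_track: Dict[str, np.ndarray] = {}
            for name, track in ds.tracks.items():
                if name == "igg":
                    continue
                features = all_features if name == "rna" else bound_features
                fe = fold_enrichment_track(track, ds.tracks["igg"],
                                           cfg.params["pseudocount"])
                fe_path = os.path.join(cfg.out_dir, f"fold_enrichment_{name}.bedGraph")
                fe.write_bedgraph(fe_path)
                outputs[f"fold_enrichment_{name}.bedGraph"] = fe_path
                mat = extract_signal_matrix(
                    fe, features, flank=cfg.params["flank"],
                    bin_size=cfg.params["bin_size"],
                    body_bins=cfg.params["body_bins"])
                prof = trimmed_mean_profile(mat, cfg.params["trim_fraction"])
                prof_path = os.path.join(cfg.out_dir, f"profile_{name}.tsv")
                with open(prof_path, "w") as fh:
                    fh.write("bin\ttrimmed_mean\n")
                    for lbl, v in zip(mat.column_labels(), prof.values):
                        fh.write(f"{lbl}\t{v:.6g}\n")
                outputs[f"profile_{name}.tsv"] = prof_path
                means = per_feature_mean(mat)
                means_by_track[name] = means
                fm_path = os.path.join(cfg.out_dir, f"feature_means_{name}.tsv")
                with open(fm_path, "w") as fh:
                    fh.write("chrom\tstart\tend\tmean_signal\n")
                    for iv, v in zip(features, means):
                        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")
                outputs[f"feature_means_{name}.tsv"] = fm_path
                agg[name] = {
                    "n_features": len(features),
                    "mean_of_means": float(np.mean(means)),
                    "profile_max": float(np.max(prof.values)),
                }
            if "control" in means_by_track and "depleted" in means_by_track:
                tt = two_sample_t_test(means_by_track["depleted"],
                                       means_by_track["control"])
                agg["depleted_vs_control"] = dataclasses.asdict(tt)
            summary["aggregate"] = agg
            logger.info("stage=aggregate tracks=%s wall=%.2fs",
                        sorted(means_by_track), time.perf_counter() - t0)

        if cfg.stages["occupancy"]:
            current_stage = "occupancy"
            t0 = time.perf_counter()
            a_reps = [ds.peaks[k] for k in sorted(ds.peaks)
                      if k.startswith("control")]
            b_reps = [ds.peaks[k] for k in sorted(ds.peaks)
                      if k.startswith("depleted")]
            subsets = occupancy_subsets(a_reps, b_reps,
                                        cfg.params["min_replicate_support"])
            for name, sub in subsets.as_dict().items():
                sub_path = os.path.join(cfg.out_dir, f"occupancy_{name}.bed")
                write_bed(sub, sub_path)
                outputs[f"occupancy_{name}.bed"] = sub_path
            fractions = repeat_fraction_of_subsets(subsets, ds.repeat_annotation)
            fr_path = os.path.join(cfg.out_dir, "occupancy_repeat_fractions.tsv")
            with open(fr_path, "w") as fh:
                fh.write("subset\trepeat_class\tfraction\n")
                for sub, classes in fractions.items():
                    for cls, frac in classes.items():
                        fh.write(f"{sub}\t{cls}\t{frac:.6g}\n")
            outputs["occupancy_repeat_fractions.tsv"] = fr_path
            summary["occupancy"] = {
                "subset_bp": {name: merge_intervals(sub).total_bp()
                              for name, sub in subsets.as_dict().items()},
                "fractions": fractions,
            }
            logger.info("stage=occupancy wall=%.2fs", time.perf_counter() - t0)
    except SatArrayError as exc:
        marker = os.path.join(cfg.out_dir, "FAILED")
        with open(marker, "w") as fh:
            fh.write(f"stage: {current_stage}\nerror: {exc}\n")
        logger.error("stage=%s failed: %s", current_stage, exc)
        raise DataError(f"stage {current_stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    report = ReportBundle(outputs=outputs, summary=summary,
                          config_echo=_echo_config(cfg), version=_version,
                          seed=cfg.seed)
    report_path = os.path.join(cfg.out_dir, "report.json")
    with open(report_path, "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
    report.outputs["report.json"] = report_path
    return report
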