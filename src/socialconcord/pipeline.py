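"""End-to-end orchestration: synthetic generation or CSV input, then the
agreement, structure and encoding stages, with a reproducible manifest.

Every random procedure takes its seed from the config; rerunning the
same config produces byte-identical text outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_report
from .encoding import compare_encodings, run_encoding
from .rating_model import (
    RatingPanel,
    exclude_unperceived_features,
    load_rating_table,
    mean_over_raters,
    mean_over_rounds,
    scale_ratings,
    write_rating_table,
)
from .structure import (
    feature_correlation_matrix,
    loading_concordance,
    mantel_test,
    pcoa,
)
from .synthetic import (
    generate_bold,
    generate_machine_ratings,
    generate_rating_panel,
    make_schedule,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either point ``human_csv``/``machine_csv`` at long-format rating
    tables, or set ``synthetic=True`` and the generator parameters
    below.  Defaults mirror the study design the synthetic data
    emulates: 10 raters, 5 machine rounds, groups of five for the split
    reliability, 0-10 analysis scale, TR 2.6 s with 467 volumes, and the
    lenient p < 0.001 / conservative FWE p < 0.05 threshold pair.
    """

    # input
    human_csv: str | None = None
    machine_csv: str | None = None
    input_scale: tuple = (0.0, 10.0)
    synthetic: bool = False
    # synthetic generator
    n_items: int = 200
    n_features: int = 50
    n_raters: int = 10
    k_latent: int = 8
    consistency: float = 0.6
    n_rounds: int = 5
    round_noise_sd: float = 1.0
    floor_bias: float = 0.2
    fail_rate: float = 0.03
    # analysis
    analysis_scale: tuple = (0.0, 10.0)
    group_size: int = 5
    mantel_permutations: int = 10_000
    pcoa_k: int = 20
    match_k: int = 8
    loading_alpha: float = 0.001
    # encoding
    run_encoding_stage: bool = True
    n_subjects: int = 10
    n_voxels: int = 500
    tr: float = 2.6
    n_volumes: int = 467
    lenient_alpha: float = 0.001
    fwe_alpha: float = 0.05
    # reproducibility
    seed: int = 0
    out_dir: str = "socialconcord_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("input_scale", "analysis_scale"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self):
        if not self.synthetic and (self.human_csv is None or self.machine_csv is None):
            raise ValueError(
                "config needs either synthetic=True or both human_csv and machine_csv"
            )
        for a in (self.lenient_alpha, self.fwe_alpha, self.loading_alpha):
            if not 0 < a < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict:
    """Derive independent per-stage seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    names = ["panel", "machine", "mantel", "bold"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns a dict of the headline numbers (also written to
    ``summary.json``).
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    out = config.out_dir
    os.makedirs(out, exist_ok=True)

    # ---- stage 0: inputs -------------------------------------------------
    try:
        if config.synthetic:
            human, truth = generate_rating_panel(
                config.n_items, config.n_features, config.n_raters,
                config.k_latent, config.consistency, seed=seeds["panel"])
            machine = generate_machine_ratings(
                truth, config.n_rounds, config.round_noise_sd,
                config.floor_bias, config.fail_rate, seed=seeds["machine"])
            write_rating_table(human, os.path.join(out, "human_ratings.csv"))
            write_rating_table(machine, os.path.join(out, "machine_ratings.csv"))
        else:
            truth = None
            human, _ = load_rating_table(
                config.human_csv, scale=config.input_scale, kind="human")
            machine, _ = load_rating_table(
                config.machine_csv, scale=config.input_scale, kind="machine")
        if human.scale != config.analysis_scale:
            human = scale_ratings(human, config.analysis_scale)
        if machine.scale != config.analysis_scale:
            machine = scale_ratings(machine, config.analysis_scale)
        human, dropped = exclude_unperceived_features(human)
        keep = [f for f in machine.features if f in set(human.features)]
        kidx = [machine.features.index(f) for f in keep]
        machine = type(machine)(machine.items, keep, machine.rounds,
                                machine.ratings[:, kidx, :], machine.scale,
                                machine.modality)
        machine_mean = mean_over_rounds(machine)
        human_mean = mean_over_raters(human)
    except Exception as err:
        raise RuntimeError(f"input stage failed: {err}") from err

    # ---- stage 1: agreement ---------------------------------------------
    try:
        report = agreement_report(human, machine_mean, config.group_size)
        report.per_feature_frame().to_csv(
            os.path.join(out, "agreement_per_feature.tsv"), sep="\t", index=False)
        _write_json(report.summary(), os.path.join(out, "agreement_summary.json"))
        # scatter data: agreement vs consistency benchmarks
        report.per_feature_frame().to_csv(
            os.path.join(out, "agreement_scatter.tsv"), sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"agreement stage failed: {err}") from err

    # ---- stage 2: structure ---------------------------------------------
    try:
        shared = [it for it in human_mean.items if it in set(machine_mean.items)]
        hm = human_mean.restrict_items(shared)
        mm = machine_mean.restrict_items(shared)
        c_h = feature_correlation_matrix(hm)
        c_m = feature_correlation_matrix(mm)
        c_h.to_frame().to_csv(os.path.join(out, "corr_human.tsv"), sep="\t")
        c_m.to_frame().to_csv(os.path.join(out, "corr_machine.tsv"), sep="\t")
        r_obs, p_mantel = mantel_test(
            c_h, c_m, config.mantel_permutations, seed=seeds["mantel"])
        _write_json(
            {"r": r_obs, "p": p_mantel,
             "n_permutations": config.mantel_permutations,
             "seed": seeds["mantel"]},
            os.path.join(out, "mantel.json"))
        k = min(config.pcoa_k, len(human.features) - 1)
        ord_h = pcoa(c_h, k)
        ord_m = pcoa(c_m, k)
        for name, o in (("human", ord_h), ("machine", ord_m)):
            pd.DataFrame(o.loadings, index=o.features,
                         columns=[f"PC{i + 1}" for i in range(o.loadings.shape[1])]
                         ).to_csv(os.path.join(out, f"pcoa_{name}.tsv"), sep="\t")
        conc = loading_concordance(ord_h, ord_m, alpha=config.loading_alpha)
        pd.DataFrame(conc.abs_r).to_csv(
            os.path.join(out, "loading_concordance.tsv"), sep="\t")
        kk = min(config.match_k, conc.abs_r.shape[0], conc.abs_r.shape[1])
        diag = np.diag(conc.abs_r)[:kk]
        diag_sig = np.diag(conc.significant)[:kk]
    except Exception as err:
        raise RuntimeError(f"structure stage failed: {err}") from err

    summary = {
        "version": __version__,
        "config_digest": config.digest(),
        "n_features_analyzed": len(human.features),
        "n_features_excluded": len(dropped),
        "n_items_shared": len(shared),
        "agreement": report.summary(),
        "mantel_r": r_obs,
        "mantel_p": p_mantel,
        "concordance_diag_abs_r_first_k": diag.tolist(),
        "concordance_diag_significant_first_k": [bool(b) for b in diag_sig],
    }

    # ---- stage 3: encoding (synthetic runs only need no NIfTI input) ----
    if config.run_encoding_stage:
        try:
            if not config.synthetic:
                raise ValueError(
                    "encoding from NIfTI inputs requires calling "
                    "encoding.run_encoding directly with loaded arrays"
                )
            schedule = make_schedule(shared, tr=config.tr,
                                     n_volumes=config.n_volumes)
            sched_items = schedule.item_ids
            item_pos = {it: i for i, it in enumerate(truth.items)}
            feat_pos = {f: j for j, f in enumerate(truth.features)}
            rows = [item_pos[it] for it in sched_items]
            cols = [feat_pos[f] for f in human.features]
            truth_vals = pd.DataFrame(
                truth.true_intensity[np.ix_(rows, cols)],
                index=sched_items, columns=human.features)
            bold, bold_truth, _ = generate_bold(
                schedule, truth_vals, config.n_subjects, config.n_voxels,
                seed=seeds["bold"])
            thresholds = {
                "lenient": (config.lenient_alpha, "none"),
                "conservative": (config.fwe_alpha, "bonferroni_fwe"),
            }
            hvals = hm.to_frame().loc[sched_items]
            mvals = mm.to_frame().loc[sched_items]
            maps_h = run_encoding(bold, schedule, hvals, thresholds)
            maps_m = run_encoding(bold, schedule, mvals, thresholds)
            comp = compare_encodings(maps_m, maps_h)
            comp.per_feature_frame().to_csv(
                os.path.join(out, "encoding_comparison.tsv"), sep="\t",
                index=False)
            schedule.to_csv(os.path.join(out, "schedule.csv"))
            summary["encoding"] = {
                "mean_spatial_r": float(np.nanmean(comp.spatial_r)),
                "cumulative_r": {k: float(v) for k, v in comp.cumulative_r.items()},
                "mean_ppv": {k: float(np.nanmean(v)) if np.isfinite(v).any()
                             else float("nan") for k, v in comp.ppv.items()},
                "mean_npv": {k: float(np.nanmean(v)) if np.isfinite(v).any()
                             else float("nan") for k, v in comp.npv.items()},
            }
        except Exception as err:
            raise RuntimeError(f"encoding stage failed: {err}") from err

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "stage_seeds": seeds,
    }
    _write_json(manifest, os.path.join(out, "manifest.json"))
    _write_json(summary, os.path.join(out, "summary.json"))
    return summary
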