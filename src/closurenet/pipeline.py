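"""Pipeline orchestration: simulate → erp → glm → gcm → report.

A run is fully determined by one YAML config and one master seed; every
stochastic stage receives a child seed spawned deterministically from
the master seed, so the same config + seed regenerates every artifact
bit-identically.  Stages communicate through files in the run directory
(CSV tables, ``.npy`` + JSON epoch containers, NIfTI volumes) and can be
re-run independently through the CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from closurenet import design as dz
from closurenet import erp as ep
from closurenet import glm as gl
from closurenet import granger as gc
from closurenet import simulate as sim
from closurenet.containers import load_epochs, save_epochs

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_erp",
           "stage_glm", "stage_gcm", "stage_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    n_controls: int = 10
    n_patients: int = 10
    # behavior
    n_erp_blocks: int = 4
    observer: dict = field(default_factory=lambda: {
        "control": {"threshold_level": 4.5, "slope": 2.5, "priming_shift": 1.0, "lapse": 0.02},
        "patient": {"threshold_level": 3.8, "slope": 2.5, "priming_shift": 1.0, "lapse": 0.02},
    })
    # EEG
    eeg: dict = field(default_factory=lambda: {
        "noise_sd": 8.0, "n_trials": 40, "subject_scale_sd": 0.15})
    # network / BOLD
    network: dict = field(default_factory=lambda: {
        "coupling": 0.4, "self_decay": 0.5, "input_gain": 1.0, "noise_scale": 1.0})
    bold: dict = field(default_factory=lambda: {"noise_sd": 0.5, "hrf": "canonical"})
    fmri_design: dict = field(default_factory=lambda: {"n_blocks": 12, "runs_per_block": 3})
    # analysis
    analysis: dict = field(default_factory=lambda: {
        "limit_uV": 120.0, "var_order": 1, "bootstrap_B": 100, "fdr_q": 0.05,
        "gcm_condition": "primed"})
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for key, val in raw.items():
            cur = getattr(base, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                merged = {**cur, **val}
                setattr(base, key, merged)
            else:
                setattr(base, key, val)
        return base

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def subjects(self) -> list[tuple[str, str]]:
        return ([(f"ctrl{i:02d}", "control") for i in range(self.n_controls)]
                + [(f"pat{i:02d}", "patient") for i in range(self.n_patients)])


def _stage_seed(config: RunConfig, stage: str, extra: int = 0) -> int:
    tag = zlib.crc32(stage.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([config.seed, tag, extra])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage '{stage}' requires missing artifact: {path}")
    return path


def stage_simulate(config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_effective.yaml")
    ana = config.analysis
    logger.info("defaults: p=%s B=%s q=%s limit_uV=%s",
                ana["var_order"], ana["bootstrap_B"], ana["fdr_q"], ana["limit_uV"])

    # --- designs
    rng = np.random.default_rng(_stage_seed(config, "design"))
    blocks = []
    for b in range(config.n_erp_blocks):
        pics = [dz.Picture(f"pic{b:02d}_{i:02d}", tuple(range(40))) for i in range(10)]
        blocks.append(dz.build_erp_block(pics, seed=int(rng.integers(2 ** 31))))
    erp_tab = pd.concat(
        [dz.erp_block_to_table(blk).assign(block=i) for i, blk in enumerate(blocks)],
        ignore_index=True)
    dz.save_design(erp_tab, {"timing_ms": dz.ERP_TIMING_MS, "seed": config.seed},
                   out / "erp_design.tsv", out / "erp_design.json")
    session = dz.build_fmri_session(config.fmri_design["n_blocks"],
                                    config.fmri_design["runs_per_block"],
                                    run_order_seed=_stage_seed(config, "fmri-design"))
    dz.save_design(dz.session_to_table(session),
                   {"tr_ms": session.tr_ms, "seed": session.seed},
                   out / "fmri_design.tsv", out / "fmri_design.json")

    # --- behavior
    beh_rows = []
    for s, (subject, group) in enumerate(config.subjects()):
        obs = sim.ObserverModel(**config.observer[group])
        df = sim.simulate_behavior(obs, blocks, seed=_stage_seed(config, "behavior", s))
        df.insert(0, "subject", subject)
        df.insert(1, "group", group)
        beh_rows.append(df)
    pd.concat(beh_rows, ignore_index=True).to_csv(out / "behavior.csv", index=False)

    # --- EEG
    (out / "epochs").mkdir(exist_ok=True)
    for s, (subject, group) in enumerate(config.subjects()):
        seed = _stage_seed(config, "eeg", s)
        rng_s = np.random.default_rng(seed)
        cfg = sim.EegSimConfig(noise_sd=config.eeg["noise_sd"],
                               n_trials=config.eeg["n_trials"])
        scale = float(abs(rng_s.normal(1.0, config.eeg.get("subject_scale_sd", 0.0))))
        for comp in cfg.components.values():
            comp.amplitudes = {g: {c: a * scale for c, a in conds.items()}
                               for g, conds in comp.amplitudes.items()}
        labels = [c for c in sim.EEG_CONDITIONS for _ in range(cfg.n_trials)]
        epochs = sim.simulate_eeg_epochs(cfg, labels, seed=seed, group=group,
                                         subject=subject)
        save_epochs(epochs, out / "epochs" / subject)

    # --- BOLD
    (out / "bold").mkdir(exist_ok=True)
    for s, (subject, group) in enumerate(config.subjects()):
        net = sim.make_group_network(group, coupling=config.network["coupling"],
                                     self_decay=config.network["self_decay"],
                                     input_gain=config.network["input_gain"],
                                     noise_scale=config.network["noise_scale"])
        bcfg = sim.BoldSimConfig(noise_sd=config.bold["noise_sd"])
        res = sim.simulate_network_bold(net, bcfg, session,
                                        seed=_stage_seed(config, "bold", s),
                                        hrf=config.bold["hrf"])
        sim.roi_mean_series(res).to_csv(out / "bold" / f"{subject}_roi.csv", index=False)
        np.save(out / "bold" / f"{subject}_series.npy", res.series)
        with open(out / "bold" / f"{subject}_truth.json", "w") as fh:
            json.dump(res.ground_truth, fh)
    with open(out / "bold" / "roi_masks.json", "w") as fh:
        json.dump({n: m.tolist() for n, m in
                   sim.default_roi_masks(sim.BoldSimConfig()).items()}, fh)


def stage_erp(config: RunConfig) -> None:
    out = Path(config.outdir)
    _require(out / "epochs", "erp")
    evoked_by_subject, groups = {}, {}
    reject_logs = []
    for subject, group in config.subjects():
        epochs = load_epochs(_require(out / "epochs" / f"{subject}.npy", "erp").with_suffix(""))
        accepted, log = ep.reject_artifacts(epochs, limit_uV=config.analysis["limit_uV"])
        log.insert(0, "subject", subject)
        reject_logs.append(log)
        evoked_by_subject[subject] = ep.baseline_and_average(accepted)
        groups[subject] = group
    pd.concat(reject_logs, ignore_index=True).to_csv(out / "erp_rejections.csv", index=False)
    table = ep.amplitude_table(evoked_by_subject, groups)
    table.to_csv(out / "amplitude_table.csv", index=False)
    ep.component_stats(table).to_csv(out / "component_stats.csv", index=False)
    ep.component_correlations(table).to_csv(out / "component_correlations.csv", index=False)


def stage_glm(config: RunConfig) -> None:
    out = Path(config.outdir)
    _require(out / "fmri_design.tsv", "glm")
    sched = pd.read_csv(out / "fmri_design.tsv", sep="\t")["condition"].tolist()
    session = dz.SessionDesign(schedule=tuple(sched))
    hrf = gl.canonical_hrf(tr_s=session.tr_ms / 1000.0)
    dm = gl.build_design_matrix(session, hrf)
    with open(out / "bold" / "roi_masks.json") as fh:
        roi_masks = {n: np.asarray(m) for n, m in json.load(fh).items()}
    rows = []
    for subject, group in config.subjects():
        series = np.load(_require(out / "bold" / f"{subject}_series.npy", "glm"))
        fit = gl.fit_glm(series, dm, whitening="ar1")
        for cond in dm.condition_names:
            est, _t, _df = gl.contrast_t(fit, {cond: 1.0})
            for roi, mask in roi_masks.items():
                rows.append({"subject": subject, "group": group, "roi": roi,
                             "condition": cond, "value": float(np.mean(est[mask]))})
    roi_values = pd.DataFrame(rows)
    roi_values.to_csv(out / "roi_contrasts.csv", index=False)
    gl.contrast_and_group(roi_values).to_csv(out / "roi_group_stats.csv", index=False)


def stage_gcm(config: RunConfig) -> None:
    out = Path(config.outdir)
    _require(out / "fmri_design.tsv", "gcm")
    sched = pd.read_csv(out / "fmri_design.tsv", sep="\t")["condition"].tolist()
    session = dz.SessionDesign(schedule=tuple(sched))
    p = config.analysis["var_order"]
    segments = gc.condition_segments(session, config.analysis["gcm_condition"], p)
    tables = []
    for subject, group in config.subjects():
        roi = pd.read_csv(_require(out / "bold" / f"{subject}_roi.csv", "gcm"))
        tables.append(gc.pairwise_gci_table(roi, p=p, segments=segments,
                                            subject=subject, group=group))
    gci = pd.concat(tables, ignore_index=True)
    gci.to_csv(out / "gci_table.csv", index=False)
    stats = gc.group_gci_stats(gci, min_per_group=min(5, config.n_controls, config.n_patients))
    stats.to_csv(out / "gci_group_stats.csv", index=False)
    # edge list sufficient to redraw the group connectivity graphs
    stats.rename(columns={"connection": "edge"}).assign(
        source=lambda d: d["edge"].str.split("->").str[0],
        target=lambda d: d["edge"].str.split("->").str[1],
    )[["source", "target", "group", "median", "iqr", "p_signed_rank", "p_rank_sum"]
      ].to_csv(out / "gci_edges.csv", index=False)
    # one demonstration voxelwise dGCM with bootstrap+FDR threshold
    subject, _ = config.subjects()[0]
    series = np.load(out / "bold" / f"{subject}_series.npy")
    with open(out / "bold" / "roi_masks.json") as fh:
        roi_masks = {n: np.asarray(m) for n, m in json.load(fh).items()}
    dmap = gc.compute_dgcm(roi_masks["DS"], series, p=p, segments=segments)
    dmap = gc.threshold_map(dmap, B=config.analysis["bootstrap_B"],
                            q=config.analysis["fdr_q"],
                            seed=_stage_seed(config, "gcm-threshold"))
    pd.DataFrame({"voxel": np.arange(len(dmap.dgci)), "dgci": dmap.dgci,
                  "f_instantaneous": dmap.f_instantaneous, "p": dmap.pvals,
                  "significant": dmap.sig_mask,
                  "in_reference_roi": dmap.ref_flag}).to_csv(
        out / "dgcm_DS.csv", index=False)


def stage_report(config: RunConfig) -> None:
    out = Path(config.outdir)
    needed = ["behavior.csv", "amplitude_table.csv", "component_stats.csv",
              "roi_group_stats.csv", "gci_group_stats.csv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"stage 'report' requires missing artifacts: {missing}")
    beh = pd.read_csv(out / "behavior.csv")
    comp = pd.read_csv(out / "component_stats.csv")
    gci = pd.read_csv(out / "gci_group_stats.csv")
    ident = (beh.drop_duplicates(["subject", "block", "sequence_slot"])
                .groupby(["group", "is_repeat"])["identification_level"].mean())
    summary = {
        "seed": config.seed,
        "n_subjects": {"control": config.n_controls, "patient": config.n_patients},
        "behavior_mean_identification_level": {
            f"{g}_{'repeat' if r else 'novel'}": float(v)
            for (g, r), v in ident.items()},
        "erp_group_effects": {
            row["component"]: {"F": row["F"], "p": row["p"]}
            for _, row in comp[comp.effect == "group"].iterrows()},
        "gci_significant_connections": {
            g: sorted(gci[(gci.group == g) & (gci.p_signed_rank < 0.05)]["connection"])
            for g in gci["group"].unique()},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    lines = ["# Run report", "",
             f"Master seed: {config.seed}",
             f"Subjects: {config.n_controls} controls, {config.n_patients} patients", "",
             "## Mean identification level (behavior)"]
    for key, val in summary["behavior_mean_identification_level"].items():
        lines.append(f"- {key}: {val:.2f}")
    lines += ["", "## ERP group effects (mixed-model F)"]
    for compname, eff in summary["erp_group_effects"].items():
        lines.append(f"- {compname}: F = {eff['F']:.2f}, p = {eff['p']:.4f}")
    lines += ["", "## Directed connections with median GCI != 0 (signed-rank p < 0.05)"]
    for g, conns in summary["gci_significant_connections"].items():
        lines.append(f"- {g}: {', '.join(conns) if conns else 'none'}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


_STAGES = {"simulate": stage_simulate, "erp": stage_erp, "glm": stage_glm,
           "gcm": stage_gcm, "report": stage_report}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; any failure aborts with a stage-named
    error.  Returns the report summary."""
    for name, fn in _STAGES.items():
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    with open(Path(config.outdir) / "report.json") as fh:
        return json.load(fh)
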