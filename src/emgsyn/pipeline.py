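"""End-to-end orchestration: synthesize -> preprocess -> synergies ->
templates/matching -> coherence -> group statistics.

A run is driven by a flat ``RunConfig`` (serializable, unknown keys
rejected) and a master seed; each stage derives its own child seed from the
master so reruns are bit-identical.  Every stage writes its outputs under
the run directory and the final machine-readable report aggregates
per-group synergy counts, template matches, band-area tables and the
statistical comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, coherence, stats, synergy, synthetic
from .io import read_events, read_manifest, read_trial
from .preprocessing import mvc_reference, process_trial

_STAGE_SEEDS = {"synth": 11, "synergy": 23, "cluster": 37, "coherence": 53}


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "run"
    cohort_dir: str | None = None      # reuse an existing cohort if set
    seed: int = 0

    n_subjects: int = 18
    trials_per_subject: int = 5
    group_specs: list[dict[str, Any]] = field(default_factory=list)

    bandpass_low: float = 20.0
    bandpass_high: float = 400.0
    bandpass_order: int = 4
    smooth_cutoff: float = 20.0
    envelope_window_ms: float = 10.0
    normalize_mode: str = "mvc"        # mvc | trial_max

    k_max: int = 14
    vaf_threshold: float = 0.9
    n_runs: int = 50

    reference_group: str = "SG"
    r_threshold: float = 0.6
    kmeans_reps: int = 1000
    gap_refs: int = 50

    coherence_pairs: list[list[str]] = field(
        default_factory=lambda: [["BB", "LD"], ["DEL", "ABS"]])
    coherence_window_len: int = 200
    coherence_overlap: float = 0.75
    coherence_fft_len: int = 512
    coherence_kernel_size: int = 5
    coherence_alpha: float = 0.05

    stats_alpha: float = 0.05

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def preprocessing_config(self) -> dict[str, Any]:
        return {"bandpass.low": self.bandpass_low,
                "bandpass.high": self.bandpass_high,
                "bandpass.order": self.bandpass_order,
                "smooth.cutoff": self.smooth_cutoff,
                "envelope.window_ms": self.envelope_window_ms}

    def coherence_config(self) -> dict[str, Any]:
        return {**self.preprocessing_config(),
                "coherence.window_len": self.coherence_window_len,
                "coherence.overlap": self.coherence_overlap,
                "coherence.fft_len": self.coherence_fft_len,
                "coherence.kernel_size": self.coherence_kernel_size,
                "coherence.alpha": self.coherence_alpha}


def _stage_seed(master: int, stage: str) -> int:
    return (master * 100_003 + _STAGE_SEEDS[stage]) % (2 ** 31 - 1)


def _group_specs(config: RunConfig) -> list[synthetic.GroupSpec]:
    if not config.group_specs:
        return synthetic.default_groups()
    specs = []
    for g in config.group_specs:
        plan = [(tuple(e["pair"]), e["band"], e["coupling"])
                for e in g.get("coherence_plan", [])]
        specs.append(synthetic.GroupSpec(
            name=g["name"], k_true=g["k_true"],
            noise_sd=g.get("noise_sd", 0.02), coherence_plan=plan,
            dominant_per_synergy=g.get("dominant_per_synergy", 3)))
    return specs


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.json").write_text(
        json.dumps(config.to_dict(), indent=1))

    # --- stage: cohort -----------------------------------------------------
    if config.cohort_dir is None:
        cohort_dir = out / "cohort"
        manifest = synthetic.generate_cohort(
            cohort_dir, n_subjects=config.n_subjects,
            groups=_group_specs(config),
            trials_per_subject=config.trials_per_subject,
            seed=_stage_seed(config.seed, "synth"))
    else:
        cohort_dir = Path(config.cohort_dir)
        manifest = read_manifest(cohort_dir / "manifest.json")

    pp_cfg = config.preprocessing_config()
    trials: list[dict[str, Any]] = []
    mvc_refs: dict[str, dict[str, float]] = {}
    for entry in manifest["trials"]:
        rec = read_trial(cohort_dir / entry["path"])
        events = read_events(cohort_dir / entry["events_path"])
        key = entry["mvc_path"]
        if config.normalize_mode == "mvc":
            if key not in mvc_refs:
                mvc_refs[key] = mvc_reference(
                    read_trial(cohort_dir / key),
                    low=config.bandpass_low, high=config.bandpass_high,
                    order=config.bandpass_order, cutoff=config.smooth_cutoff)
            ref = mvc_refs[key]
        else:
            ref = None
        env = process_trial(rec, events, ref, pp_cfg)
        trials.append({**{k: entry[k] for k in
                          ("path", "subject", "group", "trial_index")},
                       "recording": rec, "events": events, "envelope": env})

    # --- stage: synergy extraction ----------------------------------------
    syn_dir = out / "synergy"
    syn_dir.mkdir(exist_ok=True)
    syn_seed = _stage_seed(config.seed, "synergy")
    by_group: dict[str, list[synergy.SynergySet]] = {}
    nsyn_rows = []
    for i, trial in enumerate(trials):
        ss = synergy.select_nsyn(
            trial["envelope"].data, k_max=config.k_max,
            vaf_threshold=config.vaf_threshold, n_runs=config.n_runs,
            seed=(syn_seed + 977 * i) % (2 ** 31 - 1))
        trial["synergies"] = ss
        by_group.setdefault(trial["group"], []).append(ss)
        nsyn_rows.append({"subject": trial["subject"],
                          "group": trial["group"],
                          "trial_index": trial["trial_index"],
                          "nsyn": ss.nsyn, "vaf": ss.vaf,
                          "selected": ss.selected})
        stem = Path(trial["path"]).stem
        np.savetxt(syn_dir / f"{stem}_W.tsv", ss.weights, delimiter="\t",
                   header="\t".join(trial["envelope"].channels), comments="")
        np.savetxt(syn_dir / f"{stem}_C.tsv", ss.activations, delimiter="\t")
        (syn_dir / f"{stem}_vaf.json").write_text(json.dumps(
            {"nsyn": ss.nsyn, "vaf": ss.vaf, "vaf_curve": ss.vaf_curve,
             "seed": ss.seed, "selected": ss.selected}, indent=1))
    nsyn_df = pd.DataFrame(nsyn_rows)
    nsyn_df.to_csv(out / "nsyn.tsv", sep="\t", index=False)

    # --- stage: templates + matching --------------------------------------
    cl_seed = _stage_seed(config.seed, "cluster")
    group_names = [g["name"] for g in manifest["groups"]]
    templates: dict[str, clustering.TemplateSet] = {}
    for g in group_names:
        templates[g] = clustering.build_templates(
            by_group[g], seed=cl_seed, group=g, n_refs=config.gap_refs,
            n_reps=config.kmeans_reps)
        np.savetxt(out / f"templates_{g}.tsv", templates[g].templates,
                   delimiter="\t",
                   header="\t".join(manifest["muscles"]), comments="")
    ref_group = config.reference_group
    matches = {}
    for g in group_names:
        if g == ref_group:
            continue
        m = clustering.match_templates(templates[ref_group], templates[g],
                                       r_threshold=config.r_threshold)
        matches[g] = {"pairs": [{"ref_id": i, "cand_id": j, "r": r}
                                for i, j, r in m.pairs],
                      "group_specific": m.unmatched}
    (out / "matches.json").write_text(json.dumps(
        {"reference": ref_group, "matches": matches}, indent=1))

    # --- stage: coherence ---------------------------------------------------
    pairs = [tuple(p) for p in config.coherence_pairs]
    az_table = coherence.summarize_cohort(trials, pairs,
                                          config=config.coherence_config())
    az_table.to_csv(out / "band_summary.tsv", sep="\t", index=False)

    # --- stage: statistics --------------------------------------------------
    stats_results = []
    nsyn_subject = (nsyn_df.groupby(["subject", "group"], as_index=False)
                           .nsyn.mean()
                           .pivot(index="subject", columns="group",
                                  values="nsyn"))
    ordered = [g for g in group_names if g in nsyn_subject.columns]
    nsyn_subject = nsyn_subject[ordered]
    stats_results.append(_safe_compare(nsyn_subject.to_numpy(), ordered,
                                       "nsyn", config.stats_alpha))
    for (pair_label, band), sub in az_table.groupby(["pair", "band"]):
        wide = sub.pivot(index="subject", columns="group", values="az")
        cols = [g for g in group_names if g in wide.columns]
        stats_results.append(_safe_compare(
            wide[cols].to_numpy(), cols,
            f"az_{band}_{pair_label}", config.stats_alpha))
    (out / "stats_report.json").write_text(json.dumps(stats_results, indent=1))

    report = {
        "seed": config.seed,
        "groups": group_names,
        "n_trials": len(trials),
        "nsyn_group_means": {
            g: float(nsyn_df[nsyn_df.group == g]
                     .groupby("subject").nsyn.mean().mean())
            for g in group_names},
        "nsyn_group_summaries": {
            g: stats.summarize(nsyn_df[nsyn_df.group == g]
                               .groupby("subject").nsyn.mean())
            for g in group_names},
        "templates": {g: {"k": templates[g].k,
                          "templates": templates[g].templates.tolist()}
                      for g in group_names},
        "matches": {"reference": ref_group, "matches": matches},
        "az_group_means": {
            f"{p}_{b}": {g: float(v) for g, v in sub.groupby("group")
                         .az.mean().items()}
            for (p, b), sub in az_table.groupby(["pair", "band"])},
        "stats": stats_results,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _safe_compare(X: np.ndarray, groups: Sequence[str], metric: str,
                  alpha: float) -> dict[str, Any]:
    X = np.asarray(X, dtype=float)
    complete = ~np.isnan(X).any(axis=1)
    try:
        res = stats.route_and_test(X[complete], alpha=alpha, groups=groups,
                                   metric=metric)
        return res.to_jsonable()
    except ValueError as exc:
        return {"metric": metric, "groups": list(groups),
                "skipped": str(exc)}
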