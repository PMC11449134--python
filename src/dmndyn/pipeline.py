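"""File-level pipeline stages: pure functions of (input artifacts, config).

Each stage reads the artifacts of the previous one, computes, and writes its
outputs with a provenance record (config hash + seed).  The CLI in
:mod:`dmndyn.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import behavior, clustering, inference, networks, power, preprocess, simulate
from .embeddings import HashedProjectionProvider, load_word_vectors
from .errors import ValidationError
from .io import (read_channels, read_events, read_power_table, read_signals,
                 write_power_table, write_signals, write_tsv)

logger = logging.getLogger(__name__)

DEFAULT_LADDER = [
    "C(task)",
    "C(stage)",
    "C(task):C(stage)",
    "C(bin_index)",
    "C(bin_index):C(task) + C(bin_index):C(stage)",
    "C(subsystem)",
    "C(subsystem):C(task) + C(subsystem):C(stage)",
]


def provenance(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str)
    return {"config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
            "seed": seed, "package": "dmndyn"}


def stage_simulate(cfg: simulate.SimConfig, truth: simulate.GroundTruth,
                   out_dir: str | Path) -> dict:
    """Write per-subject signals, events, and channels, plus the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = provenance(dataclasses.asdict(cfg), cfg.seed)
    paths: dict = {"subjects": {}}
    for subject, rec, events, channels in simulate.simulate_cohort(cfg, truth):
        sdir = out_dir / subject
        sdir.mkdir(exist_ok=True)
        write_signals(rec, sdir / "signals.h5")
        write_tsv(events, sdir / "events.tsv", prov)
        write_tsv(channels, sdir / "channels.tsv", prov)
        paths["subjects"][subject] = str(sdir)
    truth.to_json(out_dir / "ground_truth.json")
    paths["ground_truth"] = str(out_dir / "ground_truth.json")
    return paths


def stage_power(data_dir: str | Path, out_path: str | Path,
                notch_harmonics: int = 3, target_hz: float = 500.0,
                pad_s: float = preprocess.DEFAULT_PAD_S, seed: int = 0) -> Path:
    """Preprocess every subject under ``data_dir`` and assemble the long
    power table."""
    data_dir = Path(data_dir)
    tables = []
    subject_dirs = sorted(d for d in data_dir.iterdir() if (d / "signals.h5").exists())
    if not subject_dirs:
        raise ValidationError(f"no subject directories with signals.h5 under {data_dir}")
    for sdir in subject_dirs:
        rec = read_signals(sdir / "signals.h5")
        events = read_events(sdir / "events.tsv")
        channels = read_channels(sdir / "channels.tsv")
        epochs, channels = preprocess.preprocess_recording(
            rec, channels, events, n_harmonics=notch_harmonics,
            target_hz=target_hz, pad_s=pad_s)
        tables.append(power.build_long_power_table(sdir.name, epochs, channels))
    table = pd.concat(tables, ignore_index=True)
    prov = provenance({"notch_harmonics": notch_harmonics, "target_hz": target_hz,
                       "pad_s": pad_s}, seed)
    return write_power_table(table, out_path, prov)


def stage_assign(channels_path: str | Path, parcellation_path: str | Path,
                 out_path: str | Path, radius_mm: float = networks.DEFAULT_RADIUS_MM,
                 seed: int = 0) -> Path:
    channels = read_channels(channels_path)
    parc = networks.read_parcellation(parcellation_path)
    channels = networks.assign_network(channels, parc, radius_mm)
    channels = networks.exclude_transition_zone(channels, parc, radius_mm)
    if "region" in channels.columns:
        channels = networks.assign_subsystem(channels)
    return write_tsv(channels, out_path, provenance({"radius_mm": radius_mm}, seed))


def stage_stats(power_path: str | Path, out_path: str | Path,
                ladder: list[str] | None = None, seed: int = 0) -> Path:
    """Sequential mixed-model comparison per band on DMN electrodes, plus the
    electrode-averaged RM-ANOVA cross-check when a comparison network exists."""
    table = read_power_table(power_path)
    ladder = ladder or DEFAULT_LADDER
    dmn = table[table["network"] == "default"]
    report: dict = {
        "_provenance": provenance({"ladder": ladder}, seed),
        "model": {"random_effects": "subject intercept + electrode-in-subject intercept",
                  "time_bin_coding": "categorical", "fit": "maximum likelihood"},
        "bands": {},
    }
    for band, grp in dmn.groupby("band", observed=True):
        terms = [t for t in ladder
                 if "subsystem" not in t or grp["subsystem"].nunique() > 1]
        ladder_out = []
        for term, lrt, fit in inference.sequential_model_comparison(grp, terms):
            ladder_out.append({"term": term, "chi2": lrt.chi2, "df": lrt.df,
                               "p": lrt.p, "converged": fit.converged,
                               "subject_only_fallback": fit.subject_only_fallback})
        report["bands"][band] = {"ladder": ladder_out}
        if table["network"].nunique() > 1:
            try:
                anova = inference.rm_anova_check(table[table["band"] == band])
                report["bands"][band]["rm_anova"] = anova.to_dict()
            except ValidationError as exc:
                report["bands"][band]["rm_anova"] = {"error": str(exc)}
    out_path = Path(out_path)
    out_path.write_text(json.dumps(report, indent=1, default=float))
    return out_path


def stage_cluster(power_path: str | Path, out_prefix: str | Path,
                  n_boot: int = 10_000, seed: int = 0) -> dict:
    """Variable matrix -> correlation distances -> complete linkage with
    bootstrap probabilities; writes Newick, distance TSV, and a JSON summary."""
    table = read_power_table(power_path)
    vm = clustering.build_variable_matrix(table)
    dend = clustering.bootstrap_cluster_probability(vm, n_boot=n_boot, seed=seed)
    D = clustering.correlation_distance(vm.values, vm.var_names)
    out_prefix = Path(out_prefix)
    newick_path = out_prefix.with_suffix(".nwk")
    newick_path.write_text(clustering.to_newick(dend) + "\n")
    dist = pd.DataFrame(D, index=vm.var_names, columns=vm.var_names)
    write_tsv(dist.reset_index().rename(columns={"index": "variable"}),
              out_prefix.with_suffix(".dist.tsv"),
              provenance({"n_boot": n_boot}, seed))
    summary = {
        "_provenance": provenance({"n_boot": n_boot}, seed),
        "n_observations": vm.n_obs,
        "dropped_subjects": vm.dropped_subjects,
        "clusters": [{"members": sorted(cl), "height": float(h), "bp": float(bp)}
                     for cl, h, bp in zip(dend.clusters(), dend.heights(), dend.bp)],
    }
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=1))
    return {"newick": str(newick_path), "distances": str(out_prefix.with_suffix('.dist.tsv')),
            "summary": str(json_path)}


def stage_score(responses_path: str | Path, out_prefix: str | Path,
                provider_spec: str = "hashed", seed: int = 0,
                tsne_perplexity: float = 5.0, tsne_learning_rate: float = 1.0) -> dict:
    """Score a response corpus and test stimulation effects.

    ``provider_spec`` is ``hashed`` (bundled deterministic backend) or a path
    to text-format word vectors.
    """
    responses = pd.read_csv(responses_path, sep="\t", comment="#")
    if provider_spec == "hashed":
        providers = [HashedProjectionProvider(seed=seed)]
    else:
        providers = [load_word_vectors(provider_spec)]
    scores = behavior.score_responses(responses, providers, seed=seed,
                                      tsne_perplexity=tsne_perplexity,
                                      tsne_learning_rate=tsne_learning_rate)
    report = behavior.stimulation_effect_report(scores)
    report["_provenance"] = provenance({"provider": providers[0].name}, seed)
    report["backend"] = providers[0].name
    out_prefix = Path(out_prefix)
    prov = provenance({"provider": providers[0].name}, seed)
    write_tsv(scores.originality, out_prefix.with_suffix(".originality.tsv"), prov)
    write_tsv(scores.item_scores, out_prefix.with_suffix(".items.tsv"), prov)
    write_tsv(scores.exclusions, out_prefix.with_suffix(".exclusions.tsv"), prov)
    json_path = out_prefix.with_suffix(".report.json")
    json_path.write_text(json.dumps(report, indent=1, default=float))
    return {"report": str(json_path)}
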