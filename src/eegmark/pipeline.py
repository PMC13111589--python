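"""End-to-end cohort orchestration and reporting.

``run_cohort`` takes any cohort object exposing ``manifest`` and
``iter_subjects()`` (the synthetic generator or a file-backed manifest),
computes per-subject measures for every paradigm, runs the covariate-
adjusted group statistics with cluster correction, and assembles a
``GroupReport``. Per-subject failures are logged as exclusions, never a
cohort-level crash; a subject excluded from one measure stays in the others
(per-measure exclusion, matching how missing-S1 subjects were dropped only
from the gating analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assr import ASSRConfig, score_assr
from .cluster_stats import (
    GLMDesign,
    build_adjacency_montage,
    grid_adjacency,
    permutation_cluster_test,
    posthoc_pairwise,
)
from .gating import GatingConfig, score_gating
from .spindles import detect_spindles, match_events, summarize_spindles

__all__ = [
    "PipelineConfig",
    "GroupReport",
    "run_cohort",
    "compute_sleep_measures",
    "compute_gating_measures",
    "compute_assr_measures",
    "group_statistics",
    "validate_against_truth",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_perm: int = 1000
    cluster_threshold: float = 0.05
    alpha_cluster: float = 0.05
    montage_max_dist: float = 1.5  # layout units; ~ring spacing on the synthetic cap
    spindle_k: float = 9.0
    spindle_min_dur: float = 0.4
    gating: GatingConfig = field(default_factory=GatingConfig)
    assr: ASSRConfig = field(default_factory=ASSRConfig)
    assr_stat_freq: float = 40.0
    tf_time_decim: int = 8  # decimate TF time axis for the group cluster test
    score_truth: bool = True


@dataclass
class GroupReport:
    """Tables and statistics for one cohort run."""

    spindle_table: pd.DataFrame
    gating_table: pd.DataFrame
    assr_table: pd.DataFrame
    cluster_results: dict
    posthoc: dict
    correlations: pd.DataFrame
    exclusions: pd.DataFrame
    spindle_match: pd.DataFrame
    manifest: pd.DataFrame

    def to_json_dict(self) -> dict:
        out = {
            "spindle_table": self.spindle_table.to_dict(orient="records"),
            "gating_table": self.gating_table.to_dict(orient="records"),
            "assr_table": self.assr_table.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(),
            "exclusions": self.exclusions.to_dict(orient="records"),
            "cluster_tests": {},
            "posthoc": {k: v.to_dict(orient="records") for k, v in self.posthoc.items()},
        }
        for name, res in self.cluster_results.items():
            if isinstance(res, dict):  # single-feature ANCOVA (no clustering)
                out["cluster_tests"][name] = res
                continue
            out["cluster_tests"][name] = {
                "n_permutations": res.n_permutations,
                "clusters": [
                    {
                        "n_members": int(len(c.members)),
                        "members": c.members.tolist(),
                        "f_sum": c.f_sum,
                        "p_corrected": c.p_corrected,
                        "max_partial_eta_sq": c.max_partial_eta_sq,
                    }
                    for c in res.clusters
                ],
            }
        return out

    def write(self, out_dir) -> None:
        from .io import write_json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spindle_table.to_csv(out / "spindle_measures.csv", index=False)
        self.gating_table.to_csv(out / "gating_measures.csv", index=False)
        self.assr_table.to_csv(out / "assr_measures.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        if len(self.spindle_match):
            self.spindle_match.to_csv(out / "spindle_truth_match.csv", index=False)
        write_json(self.to_json_dict(), out / "report.json")


def compute_sleep_measures(subject, cfg: PipelineConfig):
    """Spindle density/amplitude per channel x stage for one subject."""
    rec, stages, truth = subject.sleep
    events = detect_spindles(
        rec, stages, k=cfg.spindle_k, min_dur=cfg.spindle_min_dur
    )
    summary = summarize_spindles(events, stages, list(rec.channel_labels))
    summary.insert(0, "subject_id", subject.spec.subject_id)
    match = None
    if cfg.score_truth and len(truth.columns):
        m = match_events(events, truth, channel=cfg.gating.channel)
        match = {"subject_id": subject.spec.subject_id, **m}
    return summary, match


def compute_gating_measures(subject, cfg: PipelineConfig):
    rec, events = subject.p50
    score = score_gating(rec, events, cfg.gating)
    row = {"subject_id": subject.spec.subject_id, **score.to_dict()}
    return row


def compute_assr_measures(subject, cfg: PipelineConfig):
    rec, events = subject.assr
    results = score_assr(rec, events, cfg.assr)
    rows = []
    stat_maps = {}
    for f, tf in sorted(results.items()):
        s = tf.band_time_mean(cfg.assr.band_halfwidth, cfg.assr.summary_window)
        rows.append({"subject_id": subject.spec.subject_id, **s})
        if f == cfg.assr_stat_freq:
            sl = slice(None, None, cfg.tf_time_decim)
            stat_maps = {
                "itpc": tf.itpc[:, sl].copy(),
                "evoked_db": tf.evoked_power_db[:, sl].copy(),
                "freqs": tf.freqs,
                "times": tf.times[sl],
            }
    return rows, stat_maps


def run_cohort(cohort, cfg: PipelineConfig | None = None) -> GroupReport:
    """Process every subject and run the group analyses.

    Deterministic under ``cfg.seed`` for a fixed cohort: the permutation
    tests draw from generators seeded per analysis.
    """
    cfg = cfg or PipelineConfig()
    spindle_rows, gating_rows, assr_rows, match_rows, excl = [], [], [], [], []
    tf_maps = {}
    montage = None
    channel_order = None
    for subject in cohort.iter_subjects():
        sid = subject.spec.subject_id
        try:
            summary, match = compute_sleep_measures(subject, cfg)
            spindle_rows.append(summary)
            if match is not None:
                match_rows.append(match)
            if montage is None:
                montage = subject.sleep[0].montage
                channel_order = list(subject.sleep[0].channel_labels)
        except Exception as e:  # noqa: BLE001 - per-subject isolation is the contract
            excl.append({"subject_id": sid, "measure": "spindles", "reason": str(e)})
        try:
            row = compute_gating_measures(subject, cfg)
            if row["status"] == "s1_not_detected":
                excl.append(
                    {"subject_id": sid, "measure": "gating", "reason": "s1_not_detected"}
                )
            else:
                gating_rows.append(row)
        except Exception as e:  # noqa: BLE001
            excl.append({"subject_id": sid, "measure": "gating", "reason": str(e)})
        try:
            rows, maps = compute_assr_measures(subject, cfg)
            assr_rows.extend(rows)
            if maps:
                tf_maps[sid] = maps
        except Exception as e:  # noqa: BLE001
            excl.append({"subject_id": sid, "measure": "assr", "reason": str(e)})

    spindle_table = (
        pd.concat(spindle_rows, ignore_index=True) if spindle_rows else pd.DataFrame()
    )
    gating_table = pd.DataFrame(gating_rows)
    assr_table = pd.DataFrame(assr_rows)
    exclusions = pd.DataFrame(excl, columns=["subject_id", "measure", "reason"])
    spindle_match = pd.DataFrame(match_rows)

    cluster_results, posthoc, correlations = group_statistics(
        cohort.manifest,
        spindle_table,
        gating_table,
        assr_table,
        tf_maps,
        montage,
        channel_order,
        cfg,
    )
    return GroupReport(
        spindle_table=spindle_table,
        gating_table=gating_table,
        assr_table=assr_table,
        cluster_results=cluster_results,
        posthoc=posthoc,
        correlations=correlations,
        exclusions=exclusions,
        spindle_match=spindle_match,
        manifest=cohort.manifest,
    )


def _feature_matrix(table: pd.DataFrame, manifest: pd.DataFrame, stage: str, value: str, channels):
    """Subjects x channels matrix of one spindle measure; drops subjects listwise."""
    sub = table[table["stage"] == stage].pivot(
        index="subject_id", columns="channel", values=value
    )
    sub = sub.reindex(columns=channels).dropna(axis=0)
    meta = manifest.set_index("subject_id").loc[sub.index]
    return sub, meta


def group_statistics(
    manifest, spindle_table, gating_table, assr_table, tf_maps, montage, channels, cfg
):
    """Cluster tests, single-feature ANCOVAs, post-hocs and correlations."""
    cluster_results: dict = {}
    posthoc: dict = {}
    rng_seed = np.random.SeedSequence(cfg.seed)
    seeds = iter(rng_seed.spawn(16))

    # electrode-space cluster tests for spindle density and amplitude
    if len(spindle_table) and montage is not None:
        adj = build_adjacency_montage(montage, channels, cfg.montage_max_dist)
        for stage in ("N2", "N3"):
            for value in ("density", "mean_amplitude"):
                mat, meta = _feature_matrix(spindle_table, manifest, stage, value, channels)
                if len(mat) < 8 or meta["group"].value_counts().min() < 2:
                    continue
                design = GLMDesign(
                    meta["group"].to_numpy(), meta["age"].to_numpy(), mat.to_numpy()
                )
                name = f"spindle_{value}_{stage}"
                res = permutation_cluster_test(
                    design,
                    adj,
                    n_perm=cfg.n_perm,
                    threshold=cfg.cluster_threshold,
                    alpha_cluster=cfg.alpha_cluster,
                    seed=next(seeds),
                )
                cluster_results[name] = res
                if res.clusters:
                    posthoc[name] = posthoc_pairwise(design, res.clusters[0])

    # single-feature ANCOVA + post-hoc for the gating ratio
    if len(gating_table):
        ok = gating_table.dropna(subset=["ratio"])
        meta = manifest.set_index("subject_id").loc[ok["subject_id"]]
        if len(ok) >= 8 and meta["group"].value_counts().min() >= 2:
            design = GLMDesign(
                meta["group"].to_numpy(),
                meta["age"].to_numpy(),
                ok["ratio"].to_numpy(),
            )
            from .cluster_stats import ancova_f

            f, p, eta = ancova_f(design)
            cluster_results["gating_ratio_ancova"] = {"F": f, "p": p, "eta_p2": eta}
            design2 = GLMDesign(
                design.group, design.age, design.response[:, None]
            )
            posthoc["gating_ratio"] = posthoc_pairwise(design2, np.array([0]))

    # time-frequency cluster tests at the statistical stimulation frequency
    for measure in ("itpc", "evoked_db"):
        if not tf_maps:
            break
        sids = sorted(tf_maps)
        maps = np.stack([tf_maps[s][measure] for s in sids])  # (n, F, T)
        n, nf, nt = maps.shape
        meta = manifest.set_index("subject_id").loc[sids]
        if n < 8 or meta["group"].value_counts().min() < 2:
            continue
        design = GLMDesign(
            meta["group"].to_numpy(), meta["age"].to_numpy(), maps.reshape(n, nf * nt)
        )
        res = permutation_cluster_test(
            design,
            grid_adjacency((nf, nt)),
            n_perm=cfg.n_perm,
            threshold=cfg.cluster_threshold,
            alpha_cluster=cfg.alpha_cluster,
            seed=next(seeds),
        )
        name = f"assr40_{measure}"
        cluster_results[name] = res
        if res.clusters:
            posthoc[name] = posthoc_pairwise(design, res.clusters[0])

    correlations = _subject_correlations(spindle_table, gating_table, assr_table, cfg)
    return cluster_results, posthoc, correlations


def _subject_correlations(spindle_table, gating_table, assr_table, cfg) -> pd.DataFrame:
    """Pearson correlations among subject-level scalar measures (plumbing)."""
    pieces = []
    if len(spindle_table):
        cz = spindle_table[
            (spindle_table["channel"] == cfg.gating.channel)
            & (spindle_table["stage"] == "N2")
        ].set_index("subject_id")["density"]
        pieces.append(cz.rename("spindle_density_n2_cz"))
    if len(gating_table):
        pieces.append(gating_table.set_index("subject_id")["ratio"].rename("gating_ratio"))
    if len(assr_table):
        sel = assr_table[assr_table["stim_freq"] == cfg.assr_stat_freq]
        pieces.append(sel.set_index("subject_id")["itpc"].rename("assr40_itpc"))
        pieces.append(sel.set_index("subject_id")["evoked_db"].rename("assr40_evoked_db"))
    if not pieces:
        return pd.DataFrame()
    df = pd.concat(pieces, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return df.corr(method="pearson")


def validate_against_truth(report: GroupReport, manifest: pd.DataFrame | None = None, cfg=None) -> dict:
    """Bias/RMSE of estimated measures against the cohort truth manifest.

    Works only for synthetic cohorts (the manifest must carry *_true
    columns). Raises if ids do not line up.
    """
    cfg = cfg or PipelineConfig()
    manifest = manifest if manifest is not None else report.manifest
    if "spindle_density_true" not in manifest.columns:
        raise ValueError("truth columns missing: not a synthetic-cohort manifest")
    card: dict = {}
    m = manifest.set_index("subject_id")

    if len(report.spindle_table):
        cz = report.spindle_table[
            (report.spindle_table["channel"] == cfg.gating.channel)
            & (report.spindle_table["stage"] == "N2")
        ].set_index("subject_id")["density"]
        if not set(cz.index) <= set(m.index):
            raise ValueError("subject-id mismatch between report and truth manifest")
        err = cz - m.loc[cz.index, "spindle_density_true"]
        card["spindle_density_bias"] = float(err.mean())
        card["spindle_density_rmse"] = float(np.sqrt((err**2).mean()))
    if len(report.gating_table):
        g = report.gating_table.dropna(subset=["ratio"]).set_index("subject_id")["ratio"]
        if not set(g.index) <= set(m.index):
            raise ValueError("subject-id mismatch between report and truth manifest")
        err = g - m.loc[g.index, "gating_factor_true"]
        card["gating_ratio_bias"] = float(err.mean())
        card["gating_ratio_rmse"] = float(np.sqrt((err**2).mean()))
    if len(report.spindle_match):
        card["spindle_recall_mean"] = float(report.spindle_match["recall"].mean())
        card["spindle_precision_mean"] = float(report.spindle_match["precision"].mean())
        if report.spindle_match["n_truth"].sum() == 0:
            card["spindle_recall_undefined"] = True
    return card
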