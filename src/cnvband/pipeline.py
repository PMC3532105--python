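"""End-to-end orchestration: simulate -> call -> screen -> decompose ->
associate, as a pure function of a serializable RunConfig."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from .assoc import bonferroni_threshold, deletion_group_anova, regress_loading_on_feature
from .cnvcall.cbs import cbs_segment
from .cnvcall.consensus import consensus_calls, snr_filter, structural_filters
from .cnvcall.correct import correct_lrr, qc_samples
from .cnvcall.hmm import HmmParams, segments_from_path, viterbi_paths_batch
from .cnvcall.regions import define_regions, exclude_outlier_samples
from .cnvcall.types import CNVCall
from .gmc_ica import Decomposition, estimate_order_mdl, fix_signs, infomax_ica, network_group_test
from .synthdata.cohort import generate_cohort
from .synthdata.gmc import GMCTruth, GMCTruthConfig, simulate_gmc
from .synthdata.maps import generate_marker_map
from .synthdata.planting import CNVTruth, PlantingConfig, plant_cnvs
from .synthdata.signals import EmissionParams, simulate_array

logger = logging.getLogger("cnvband.pipeline")

__all__ = ["RunConfig", "RunReport", "evaluate_against_truth", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run depends on; a run is a pure function of this."""

    seed: int = 0
    # cohort
    n_case: int = 48
    n_control: int = 48
    case_ethnicity_mix: dict = field(default_factory=lambda: {"White": 0.70, "AA": 0.20, "Other": 0.10})
    control_ethnicity_mix: dict = field(default_factory=lambda: {"White": 0.85, "AA": 0.05, "Other": 0.10})
    site_mix: dict = field(default_factory=lambda: {"NM": 0.3, "MN": 0.25, "MGH": 0.2, "IA": 0.25})
    # marker map
    n_chrom: int = 2
    markers_per_band: int = 60
    bands_per_chrom: int = 8
    band_bp: int = 1_000_000
    # planting
    planting: PlantingConfig = field(
        default_factory=lambda: PlantingConfig(
            background_del_rate=0.02,
            background_ins_rate=0.015,
            effect_band="1q3",
            effect_case_rate=0.40,
            effect_control_rate=0.05,
            second_event_rate=0.15,
            homozygous_prob=0.05,
            min_markers=12,
            max_markers=40,
        )
    )
    # signal emission
    emission: EmissionParams = field(default_factory=EmissionParams)
    wave_amplitude: float = 0.25
    # correction / QC
    gc_corr_threshold: float = 0.6
    qc_sd_threshold: float = 0.28
    # CBS
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 200
    cbs_max_width: int | None = 100
    cbs_prune_tol: float = 0.05
    # HMM
    hmm: HmmParams = field(default_factory=HmmParams)
    # consensus & filters
    consensus_max_gap: int = 3
    min_markers: int = 3
    cbs_magnitude: float = 0.1
    snr_flank: int = 50
    # 2.0 is the per-call operation default; the pipeline default is lower so
    # that low-contrast insertions (LRR shift ~0.35 over noise ~0.2) survive
    snr_threshold: float = 1.5
    min_bp: int = 500
    homozygous_small_exception: bool = True
    outlier_k_sd: float = 3.0
    region_max_gap: int = 3
    rare_frequency: float = 0.01
    # screening
    screen_p1: float = 0.01
    screen_p2: float = 0.05
    # GMC / ICA
    n_voxels: int = 1500
    gmc_n_sources: int = 6
    gmc: GMCTruthConfig = field(default_factory=lambda: GMCTruthConfig(deletion_reduction=0.18, noise_sd=0.4))
    n_components: int | str = 6  # int or "mdl"
    ica_learning_rate: float = 0.1
    ica_max_iter: int = 1024
    ica_tol: float = 1e-6
    # association
    assoc_alpha: float = 0.05

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "planting" in d and isinstance(d["planting"], dict):
            p = dict(d["planting"])
            if "excluded_stains" in p and isinstance(p["excluded_stains"], list):
                p["excluded_stains"] = tuple(p["excluded_stains"])
            d["planting"] = PlantingConfig(**p)
        if "emission" in d and isinstance(d["emission"], dict):
            e = dict(d["emission"])
            for key in ("lrr_mean", "lrr_sd"):
                if key in e:
                    e[key] = {int(k): v for k, v in e[key].items()}
            d["emission"] = EmissionParams(**e)
        if "hmm" in d and isinstance(d["hmm"], dict):
            h = dict(d["hmm"])
            for key in ("lrr_mean", "lrr_sd"):
                if key in h:
                    h[key] = {int(k): v for k, v in h[key].items()}
            d["hmm"] = HmmParams(**h)
        if "gmc" in d and isinstance(d["gmc"], dict):
            d["gmc"] = GMCTruthConfig(**d["gmc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config: RunConfig
    subjects: pd.DataFrame
    truth: CNVTruth
    qc_pass: pd.Series
    calls: list[CNVCall]
    regions: list
    burden: pd.DataFrame
    burden_tests: pd.DataFrame
    screen: pd.DataFrame
    decomposition: Decomposition
    gmc_truth: GMCTruth
    network_tests: pd.DataFrame
    associations: pd.DataFrame
    deletion_groups: Any
    evaluation: dict
    stage_counts: dict

    def summary(self) -> dict:
        sel = self.screen[self.screen["selected"]]
        top = self.associations.iloc[0] if len(self.associations) else None
        return {
            "config_hash": self.config.config_hash(),
            "n_subjects": int(len(self.subjects)),
            "n_qc_pass": int(self.qc_pass.sum()),
            "n_calls": len(self.calls),
            "n_regions": len(self.regions),
            "n_selected_features": int(len(sel)),
            "selected_features": [f"{b}:{k}" for b, k in sel.index],
            "ica_k": int(self.decomposition.k),
            "ica_variance_explained": float(self.decomposition.variance_explained),
            "top_association": None
            if top is None
            else {
                "feature": str(top["feature"]),
                "component": int(top["component"]),
                "p": float(top["p"]),
                "delta_r2": float(top["delta_r2"]),
                "significant": bool(top["significant"]),
            },
            "evaluation": self.evaluation,
            "stage_counts": self.stage_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), sort_keys=True, indent=2, default=float)

    def to_text(self) -> str:
        s = self.summary()
        lines = [
            f"run {s['config_hash']}: {s['n_subjects']} subjects, {s['n_qc_pass']} pass QC",
            f"calls: {s['n_calls']} in {s['n_regions']} regions",
            f"screen: {s['n_selected_features']} selected features: {', '.join(s['selected_features']) or '-'}",
            f"ICA: k={s['ica_k']}, variance explained {s['ica_variance_explained']:.4f}",
        ]
        if s["top_association"]:
            t = s["top_association"]
            lines.append(
                f"top association: {t['feature']} ~ component {t['component']} "
                f"(p={t['p']:.3g}, dR2={t['delta_r2']:.3f}, significant={t['significant']})"
            )
        ev = s["evaluation"]
        lines.append(
            f"truth: sensitivity={ev['call_sensitivity']}, precision={ev['call_precision']}, "
            f"false/sample={ev['false_calls_per_sample']}, planted band selected={ev['planted_band_selected']}, "
            f"top pair correct={ev['top_pair_is_planted']}"
        )
        return "\n".join(lines)


class StageError(RuntimeError):
    def __init__(self, stage: str, config_hash: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed (config {config_hash}): {cause}")
        self.stage = stage


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def evaluate_against_truth(
    calls: list[CNVCall],
    truth: CNVTruth,
    subjects: pd.DataFrame | None = None,
    decomposition: Decomposition | None = None,
    gmc_truth: GMCTruth | None = None,
    min_overlap: float = 0.5,
    min_truth_markers: int = 0,
    marker_map=None,
) -> dict:
    """Call-level sensitivity/precision at reciprocal overlap >=
    ``min_overlap`` plus component-matching correlations.

    When ``subjects`` is given, planted events of subjects outside the
    analyzed table (QC failures, outlier exclusions) are not scored —
    the caller never saw them downstream.
    """
    events = truth.events
    if subjects is not None:
        analyzed_ids = set(subjects["subject_id"])
        events = [e for e in events if e.subject_id in analyzed_ids]
    if min_truth_markers and marker_map is not None:
        events = [
            e
            for e in events
            if len(marker_map.markers_in(e.chrom, e.start, e.end)) >= min_truth_markers
        ]
    calls_by_subj: dict[str, list[CNVCall]] = {}
    for c in calls:
        calls_by_subj.setdefault(c.subject_id, []).append(c)

    matched_truth = 0
    matched_call_ids: set[int] = set()
    for e in events:
        for c in calls_by_subj.get(e.subject_id, []):
            if c.chromosome == e.chrom and _reciprocal_overlap(e.start, e.end, c.start, c.end) >= min_overlap:
                matched_truth += 1
                matched_call_ids.add(id(c))
                break
    # any call matching any truth event (not only >=min_truth_markers ones) is not false
    all_events = truth.events
    for c in calls:
        if id(c) in matched_call_ids:
            continue
        for e in all_events:
            if (
                e.subject_id == c.subject_id
                and e.chrom == c.chromosome
                and _reciprocal_overlap(e.start, e.end, c.start, c.end) >= min_overlap
            ):
                matched_call_ids.add(id(c))
                break

    n_truth = len(events)
    n_calls = len(calls)
    n_false = n_calls - len(matched_call_ids)
    n_subj = len(subjects) if subjects is not None else len({e.subject_id for e in truth.events}) or 1
    out = {
        "n_truth_events": n_truth,
        "n_calls": n_calls,
        "call_sensitivity": (matched_truth / n_truth) if n_truth else None,
        "call_precision": (len(matched_call_ids) / n_calls) if n_calls else None,
        "false_calls_per_sample": n_false / max(n_subj, 1),
    }
    if decomposition is not None and gmc_truth is not None:
        C = np.corrcoef(np.vstack([gmc_truth.S_true, decomposition.S]))
        kt = gmc_truth.S_true.shape[0]
        cross = np.abs(C[:kt, kt:])
        out["component_match_r"] = [float(cross[i].max()) for i in range(kt)]
        out["component_match_idx"] = [int(cross[i].argmax()) for i in range(kt)]
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order; any stage error aborts with the
    stage name and config hash."""
    chash = config.config_hash()
    counts: dict[str, Any] = {}
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ("map", "cohort", "plant", "arrays", "gmc", "ica", "cbs", "mdl"),
            ss.spawn(8),
        )
    }

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, chash, exc) from exc
                return False

        return _Ctx()

    with stage("simulate"):
        marker_map, cyto = generate_marker_map(
            config.n_chrom,
            config.markers_per_band,
            config.bands_per_chrom,
            seed=seeds["map"],
            band_bp=config.band_bp,
        )
        subjects = generate_cohort(
            config.n_case,
            config.n_control,
            (config.case_ethnicity_mix, config.control_ethnicity_mix),
            config.site_mix,
            seed=seeds["cohort"],
        )
        truth = plant_cnvs(subjects, cyto, marker_map, config.planting, seed=seeds["plant"])
        arr_ss = np.random.SeedSequence(seeds["arrays"]).spawn(len(subjects))
        lrr = np.empty((len(subjects), marker_map.n_markers))
        baf = np.empty_like(lrr)
        for i, sid in enumerate(subjects["subject_id"]):
            s = simulate_array(
                sid, marker_map, truth, config.emission, config.wave_amplitude,
                seed=int(arr_ss[i].generate_state(1)[0]),
            )
            lrr[i], baf[i] = s.lrr, s.baf
        counts["markers"] = marker_map.n_markers
        counts["subjects"] = len(subjects)
        counts["planted_events"] = len(truth.events)

    with stage("correct_qc"):
        corrected = correct_lrr(lrr, marker_map.gc_track, gc_corr_threshold=config.gc_corr_threshold)
        qc_pass = pd.Series(
            qc_samples(corrected, config.qc_sd_threshold), index=subjects["subject_id"]
        )
        counts["qc_pass"] = int(qc_pass.sum())

    with stage("call"):
        calls: list[CNVCall] = []
        sub_ids = subjects["subject_id"].to_numpy()
        qc_idx = np.flatnonzero(qc_pass.to_numpy())
        cbs_ss = np.random.SeedSequence(seeds["cbs"]).spawn(len(subjects))
        cbs_seeds = [int(s.generate_state(1)[0]) for s in cbs_ss]
        for ci, chrom in enumerate(marker_map.chromosomes()):
            cidx = marker_map.chrom_indices(chrom)
            pos = marker_map.position[cidx]
            paths = viterbi_paths_batch(corrected[np.ix_(qc_idx, cidx)], baf[np.ix_(qc_idx, cidx)], pos, config.hmm)
            for row, i in enumerate(qc_idx):
                x = corrected[i, cidx]
                hmm_segs = segments_from_path(paths[row], x, pos, chrom)
                if all(s.state == 2 for s in hmm_segs):
                    continue  # no non-neutral evidence; skip CBS for speed
                cbs_segs = cbs_segment(
                    x,
                    pos,
                    alpha=config.cbs_alpha,
                    n_perm=config.cbs_n_perm,
                    min_markers=config.min_markers,
                    seed=(cbs_seeds[i] + 7919 * ci) % 2**63,
                    max_width=config.cbs_max_width,
                    prune_tol=config.cbs_prune_tol,
                    chromosome=chrom,
                )
                cand = consensus_calls(
                    cbs_segs,
                    hmm_segs,
                    pos,
                    subject_id=str(sub_ids[i]),
                    max_gap_markers=config.consensus_max_gap,
                    min_markers=config.min_markers,
                    cbs_magnitude=config.cbs_magnitude,
                )
                cand = snr_filter(cand, x, config.snr_flank, config.snr_threshold)
                cand = structural_filters(
                    cand,
                    cyto,
                    min_bp=config.min_bp,
                    homozygous_small_exception=config.homozygous_small_exception,
                )
                calls.extend(cand)
        counts["raw_calls"] = len(calls)

    with stage("regions"):
        qc_subjects = [str(s) for s in sub_ids[qc_idx]]
        retained = exclude_outlier_samples(calls, qc_subjects, config.outlier_k_sd)
        retained_set = set(retained)
        calls = [c for c in calls if c.subject_id in retained_set]
        analyzed = subjects[subjects["subject_id"].isin(retained_set)].reset_index(drop=True)
        regions = define_regions(
            calls, n_subjects=len(analyzed),
            max_gap_markers=config.region_max_gap, rare_frequency=config.rare_frequency,
        )
        counts["retained_subjects"] = len(analyzed)
        counts["calls"] = len(calls)
        counts["regions"] = len(regions)

    with stage("burden"):
        btab = burden_mod.compute_burden(calls, regions, analyzed)
        is_case = (analyzed["diagnosis"] == "case").to_numpy()
        rows = []
        cov = analyzed[["ethnicity", "tissue"]]
        for col in btab.columns:
            v = btab[col].to_numpy(dtype=float)
            if np.allclose(v, v[0]):
                rows.append({"metric": col, "t": np.nan, "p": np.nan, "F_adj": np.nan, "p_adj": np.nan})
                continue
            t, p = burden_mod.two_sample_t(v, is_case)
            F, p_adj = burden_mod.ancova_f(v, analyzed["diagnosis"], cov)
            rows.append({"metric": col, "t": float(t), "p": float(p), "F_adj": F, "p_adj": p_adj})
        burden_tests = pd.DataFrame(rows).set_index("metric")

    with stage("screen"):
        features = burden_mod.cytoband_features(calls, cyto, analyzed)
        white = (analyzed["ethnicity"] == "White").to_numpy()
        screen = burden_mod.screen_cytobands(
            features, is_case, white, p1=config.screen_p1, p2=config.screen_p2
        )
        counts["testable_features"] = int(screen["testable"].sum())
        counts["selected_features"] = int(screen["selected"].sum())

    with stage("gmc"):
        del_load_true = truth.deletion_load(analyzed, config.planting.effect_band) if config.planting.effect_band else None
        X, gmc_truth = simulate_gmc(
            analyzed, config.gmc_n_sources, config.n_voxels, config.gmc,
            del_load_true, seed=seeds["gmc"],
        )

    with stage("ica"):
        if config.n_components == "mdl":
            k = max(estimate_order_mdl(X, seed=seeds["mdl"]), 2)
        else:
            k = int(config.n_components)
        dec = fix_signs(
            infomax_ica(
                X, k,
                learning_rate=config.ica_learning_rate,
                max_iter=config.ica_max_iter,
                tol=config.ica_tol,
                seed=seeds["ica"],
            )
        )
        network_tests = network_group_test(
            dec.A,
            analyzed["diagnosis"].to_numpy(),
            analyzed["age"].to_numpy(),
            analyzed["gender"].to_numpy(),
            analyzed["site"].to_numpy(),
        )
        counts["ica_k"] = k

    with stage("assoc"):
        selected = screen.index[screen["selected"]]
        thr = bonferroni_threshold(dec.k, max(len(selected), 1), config.assoc_alpha)
        rows = []
        for band, kind in selected:
            f = features[(band, kind)].to_numpy(dtype=float)
            for comp in range(dec.k):
                res = regress_loading_on_feature(
                    dec.A[:, comp], f,
                    analyzed["age"].to_numpy(),
                    analyzed["gender"].to_numpy(),
                    analyzed["site"].to_numpy(),
                    component=comp,
                    feature_name=f"{band}:{kind}",
                )
                if res is None:
                    continue
                res.threshold = thr
                res.significant = res.p < thr
                rows.append(dataclasses.asdict(res))
        associations = pd.DataFrame(
            rows,
            columns=["component", "feature", "beta", "p", "delta_r2",
                     "semipartial_r2", "n", "threshold", "significant"],
        )
        if len(associations):
            associations = associations.sort_values("p", kind="stable").reset_index(drop=True)

        deletion_groups = None
        if config.planting.effect_band is not None and len(associations):
            band_dels = [
                c for c in calls
                if c.cnv_class == "deletion"
                and _band_overlap(c, cyto, config.planting.effect_band)
            ]
            load = pd.Series(0, index=analyzed["subject_id"], dtype=int)
            for c in band_dels:
                load[c.subject_id] += 1
            top_comp = int(associations.iloc[0]["component"])
            deletion_groups = deletion_group_anova(dec.A[:, top_comp], load.to_numpy())

    with stage("evaluate"):
        evaluation = evaluate_against_truth(
            calls, truth, subjects=analyzed, decomposition=dec, gmc_truth=gmc_truth,
            min_truth_markers=10, marker_map=marker_map,
        )
        planted_feature = (
            (config.planting.effect_band, "del") if config.planting.effect_band else None
        )
        evaluation["planted_band_selected"] = bool(
            planted_feature is not None
            and planted_feature in screen.index[screen["selected"]]
        )
        top_pair = None
        if len(associations):
            top = associations.iloc[0]
            top_pair = (str(top["feature"]), int(top["component"]))
        matched_comp = None
        dc = gmc_truth.effects.get("deletion_component")
        if dc is not None and "component_match_idx" in evaluation:
            matched_comp = evaluation["component_match_idx"][dc]
        # the deletion feature and the all-CNV feature of the planted band are
        # identical columns when the band carries no insertions; accept either
        top_ok = False
        if planted_feature is not None and top_pair is not None and matched_comp is not None:
            band, kind = top_pair[0].rsplit(":", 1)
            top_ok = (
                band == planted_feature[0]
                and kind in ("del", "cnv")
                and top_pair[1] == matched_comp
            )
        evaluation["top_pair_is_planted"] = top_ok

    return RunReport(
        config=config,
        subjects=subjects,
        truth=truth,
        qc_pass=qc_pass,
        calls=calls,
        regions=regions,
        burden=btab,
        burden_tests=burden_tests,
        screen=screen,
        decomposition=dec,
        gmc_truth=gmc_truth,
        network_tests=network_tests,
        associations=associations,
        deletion_groups=deletion_groups,
        evaluation=evaluation,
        stage_counts=counts,
    )


def _band_overlap(call: CNVCall, cyto, band_name: str) -> bool:
    chrom, lo, hi = cyto.band_interval(band_name)
    return call.chromosome == chrom and call.start < hi and call.end >= lo
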