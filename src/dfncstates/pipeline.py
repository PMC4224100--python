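"""End-to-end orchestration: simulate/load -> post-process -> static FNC ->
dynamic FNC -> states -> group statistics -> modularity, with provenance."""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from dfncstates import io as dio
from dfncstates.dynamic_fnc import (
    WindowSpec,
    compute_dfnc,
    select_lambda,
    window_starts,
    windowed_cov,
    make_taper,
)
from dfncstates.group_stats import state_contrast, transition_contrast
from dfncstates.modularity import component_weights, partition_signed
from dfncstates.preprocess import postprocess_timecourses
from dfncstates.states import choose_k_elbow, cluster_states, subject_summary
from dfncstates.static_fnc import group_mean_fnc, static_fnc
from dfncstates.synthetic import (
    SubjectSimSpec,
    make_state_cov_set,
    simulate_cohort,
    write_cohort,
)

log = logging.getLogger("dfncstates")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_to_dir"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to/from YAML.

    Defaults follow the study conditions: window width 22 TRs sliding in
    steps of 1 TR, 0.15 Hz low-pass cutoff, despike threshold 4, FDR alpha
    0.05, k searched over 2-10 (the elbow criterion picks the bend).
    """

    window_width: int = 22
    window_step: int = 1
    tukey_alpha: float = 0.5
    lambda_grid: list[float] = field(
        default_factory=lambda: np.logspace(-2, 0, 10).tolist()
    )
    cv_folds: int = 5
    k_min: int = 2
    k_max: int = 10
    k_fixed: int | None = None
    metric: str = "l1"
    n_replicates: int = 5
    fdr_alpha: float = 0.05
    despike_z: float = 4.0
    lowpass_hz: float = 0.15
    max_translation_mm: float = 2.0
    min_sfnr: float = 275.0
    seed: int = 0
    # synthetic-cohort settings (used by the simulate stage)
    sim_groups: dict[str, int] = field(default_factory=lambda: {"A": 20, "B": 20})
    sim_k: int = 5
    sim_C: int = 10
    sim_T: int = 206
    sim_TR: float = 1.5
    sim_separation: float = 0.5
    sim_stay_prob: float = 0.9
    sim_effect_edges: int = 4
    sim_effect_dz: float = 0.4

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def window_spec(self) -> WindowSpec:
        return WindowSpec(
            width=self.window_width,
            step=self.window_step,
            taper_param=self.tukey_alpha,
        )


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def simulate_to_dir(config: PipelineConfig, outdir: str | Path) -> None:
    """Generate a synthetic cohort per the config and write it to a directory."""
    from dfncstates.synthetic import GroupEffectSpec

    rng = np.random.default_rng(config.seed)
    states = make_state_cov_set(
        config.sim_k, config.sim_C, separation=config.sim_separation,
        seed=config.seed,
    )
    P = np.full((config.sim_k, config.sim_k), 0.0)
    off = (1.0 - config.sim_stay_prob) / max(config.sim_k - 1, 1)
    P[:] = off
    np.fill_diagonal(P, config.sim_stay_prob if config.sim_k > 1 else 1.0)
    effects = []
    groups = list(config.sim_groups)
    iu = list(zip(*np.triu_indices(config.sim_C, k=1)))
    for g in groups[1:]:  # first group is the reference
        edges_idx = rng.choice(len(iu), size=config.sim_effect_edges, replace=False)
        edges = [tuple(int(v) for v in iu[i]) for i in edges_idx]
        state = int(rng.integers(config.sim_k))
        effects.append(
            GroupEffectSpec(
                group=g,
                edges=edges,
                offsets={state: np.full(len(edges), config.sim_effect_dz)},
            )
        )
    base = SubjectSimSpec(
        T=config.sim_T, TR=config.sim_TR, markov=P, seed=config.seed,
        drift=np.array([0.0, 0.5, 0.3, 0.2]), spike_rate=1.0,
        motion_coupling=0.2,
    )
    cohort = simulate_cohort(config.sim_groups, states, effects, base)
    write_cohort(cohort, outdir)


def run_pipeline(
    config: PipelineConfig, datadir: str | Path, outdir: str | Path
) -> Path:
    """Run every stage on a directory of subject timecourse/motion files.

    Expects ``sub-*_tc.tsv`` (+ optional ``sub-*_motion.tsv``) and a
    ``truth.json`` manifest carrying group labels (as written by the
    simulate stage, or assembled by hand for real data). Writes artifacts
    and a provenance JSON to ``outdir`` and returns that path.
    """
    t0 = time.time()
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_log: list[str] = []

    manifest = dio.read_json(datadir / "truth.json")
    groups = {m["subject"]: m["group"] for m in manifest}
    spec = config.window_spec()

    # --- preprocess -------------------------------------------------------
    t = time.time()
    tcs = {}
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        for m in manifest:
            tc = dio.read_timecourses(datadir / f"{m['subject']}_tc.tsv")
            mot_path = datadir / f"{m['subject']}_motion.tsv"
            motion = dio.read_motion(mot_path) if mot_path.exists() else None
            clean, _ = postprocess_timecourses(
                tc,
                motion,
                despike_z=config.despike_z,
                cutoff_hz=config.lowpass_hz,
            )
            tcs[m["subject"]] = clean
    warnings_log += [str(w.message) for w in wrec]
    timings["preprocess"] = time.time() - t

    # --- static FNC -------------------------------------------------------
    t = time.time()
    fncs = {s: static_fnc(tc) for s, tc in tcs.items()}
    mean_fnc = group_mean_fnc(list(fncs.values()))
    dio.write_matrix(
        outdir / "static_fnc_mean.tsv", mean_fnc.values, mean_fnc.component_ids
    )
    timings["static"] = time.time() - t

    # --- dynamic FNC ------------------------------------------------------
    t = time.time()
    dfncs = {}
    lambdas = {}
    for s, tc in tcs.items():
        starts = window_starts(tc.T, spec)
        covs = [windowed_cov(tc.values, int(st), spec) for st in starts]
        lam = select_lambda(covs, np.asarray(config.lambda_grid), config.cv_folds)
        lambdas[s] = lam
        dfncs[s] = compute_dfnc(tc, spec, lam)
    timings["dynamic"] = time.time() - t

    # --- states -----------------------------------------------------------
    t = time.time()
    all_windows = np.concatenate([d.edge_vectors() for d in dfncs.values()])
    if config.k_fixed is not None:
        k_star = config.k_fixed
        ratios = None
    else:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            k_star, ratios = choose_k_elbow(
                all_windows,
                range(config.k_min, config.k_max + 1),
                metric=config.metric,
                n_replicates=config.n_replicates,
                seed=config.seed,
            )
        warnings_log += [str(w.message) for w in wrec]
    model = cluster_states(
        dfncs,
        k_star,
        metric=config.metric,
        n_replicates=config.n_replicates,
        seed=config.seed,
        groups=groups,
    )
    dio.write_matrix(outdir / "state_centroids.tsv", model.centroids)
    dio.write_json(
        outdir / "state_model.json",
        {
            "k": model.k,
            "counts": model.counts,
            "percentages": model.percentages,
            "metric": model.metric,
            "validity_ratios": ratios,
            "lambdas": lambdas,
        },
    )
    for s, lab in model.assignments.items():
        dio.write_matrix(outdir / f"{s}_states.tsv", lab[:, None])
    timings["states"] = time.time() - t

    # --- group statistics -------------------------------------------------
    t = time.time()
    summaries = {}
    centroid_vecs: dict[str, dict[int, list[np.ndarray]]] = {}
    for s, d in dfncs.items():
        summ = subject_summary(model.assignments[s], model.k, d.edge_vectors())
        summaries[s] = summ
    group_names = sorted(set(groups.values()))
    pairs = list(itertools.combinations(group_names, 2))
    contrasts = []
    C = next(iter(tcs.values())).C
    for state in range(model.k):
        for pair in pairs:
            by_group = {}
            for g in pair:
                rows = [
                    summaries[s].centroids[state]
                    for s in tcs
                    if groups[s] == g and state in summaries[s].centroids
                ]
                by_group[g] = np.array(rows) if rows else np.empty((0, 0))
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                gc = state_contrast(by_group, state, pair, C, config.fdr_alpha)
            warnings_log += [str(w.message) for w in wrec]
            if gc is not None:
                contrasts.append(
                    {
                        "state": state,
                        "pair": list(pair),
                        "n_significant": int(
                            np.nansum(
                                np.triu(gc.significant(config.fdr_alpha), k=1)
                            )
                        ),
                    }
                )
    trans = [
        transition_contrast(
            {
                g: [summaries[s] for s in tcs if groups[s] == g]
                for g in pair
            },
            pair,
            model.k,
        )
        for pair in pairs
    ]
    dio.write_json(
        outdir / "group_stats.json",
        {
            "contrasts": contrasts,
            "transitions": [
                {
                    "pair": list(tr["pair"]),
                    "per_state_q": tr["per_state_q"],
                    "total_t": tr["total_t"],
                    "total_p": tr["total_p"],
                }
                for tr in trans
            ],
        },
    )
    timings["stats"] = time.time() - t

    # --- modularity -------------------------------------------------------
    t = time.time()
    iu = np.triu_indices(C, k=1)
    mod_out = []
    for state in range(model.k):
        m = np.zeros((C, C))
        m[iu] = model.centroids[state]
        m = m + m.T
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            part = partition_signed(m)
            cw = component_weights(m, part)
        warnings_log += [str(w.message) for w in wrec]
        mod_out.append(
            {
                "state": state,
                "labels": part.labels,
                "Q": part.Q,
                "weights": cw.weights,
            }
        )
    dio.write_json(outdir / "modularity.json", mod_out)
    timings["modularity"] = time.time() - t

    dio.write_json(
        outdir / "provenance.json",
        {
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "k_star": int(model.k),
            "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
            "warnings": warnings_log,
            "total_s": round(time.time() - t0, 3),
        },
    )
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return outdir
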