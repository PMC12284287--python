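"""End-to-end orchestration: simulate -> extract -> connect -> morpho -> cluster.

A run is driven by a schema-validated :class:`RunConfig` (YAML on disk);
every stage writes CSV/JSON outputs plus a manifest hashing all artifacts,
so identical config+seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

import gpephys.traces as traces
from gpephys.morphology import metrics_table, write_swc
from gpephys.population import FEATURES_15, build_matrix, hier_cluster, pca
from gpephys.sweep import write_sweep
from gpephys.synaptic import (
    PairTest,
    connectivity_summary,
    detect_connection,
    gap_junction_test,
    pair_tests_to_frame,
)
from gpephys.synth.cohort import Cohort, ConnectionProbabilities, generate_cohort


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Model):
    simulate: bool = True
    features: bool = True
    connectivity: bool = True
    morpho: bool = True
    cluster: bool = True


class CohortConfig(_Model):
    n_arkypallidal: int = 30
    n_prototypic_pv: int = 30
    n_prototypic_nkx: int = 30
    p_proto_proto: float = 0.0115
    p_other: float = 0.0
    noise_sd_mv: float = 0.3
    sampling_rate_hz: float = 20_000.0
    include_zero_current: bool = False
    zero_duration_ms: float = 30_000.0
    n_steps: int = 8


class AnalysisConfig(_Model):
    dvdt_criterion_mv_per_ms: float = 10.0
    detection_sd_factor: float = 3.0
    detection_floor_mv: float = 0.2
    coupling_threshold: float = 0.01
    sholl_step_um: float = 10.0
    k_clusters: int = 2
    cluster_on_scores: bool = False


class RunConfig(_Model):
    seed: int = 0
    output_dir: str = "gpephys_run"
    write_sweeps: bool = False
    stages: StageToggles = StageToggles()
    cohort: CohortConfig = CohortConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def analyze_pairs(cohort: Cohort, analysis: AnalysisConfig | None = None) -> list[PairTest]:
    """Run the chemical and electrical detectors on every simulated pair."""
    analysis = analysis or AnalysisConfig()
    out = []
    for p in cohort.pairs:
        chem = detect_connection(
            p.follower_avg, p.driver_spike_times,
            sd_factor=analysis.detection_sd_factor,
            floor_mv=analysis.detection_floor_mv)
        elec = gap_junction_test(p.gap_driver, p.gap_follower,
                                 coupling_threshold=analysis.coupling_threshold)
        out.append(PairTest(
            driver_id=p.driver_id, follower_id=p.follower_id,
            driver_group=p.driver_group, follower_group=p.follower_group,
            distance_um=p.distance_um, slice_orientation=p.slice_orientation,
            chemical=chem, electrical=elec,
        ))
    return out


def extract_profiles(cohort: Cohort, dvdt_criterion: float = 10.0) -> list:
    """IntrinsicProfile per cohort cell from its simulated sweep battery."""
    profiles = []
    for cid, g in zip(cohort.cell_ids, cohort.groups):
        cs = cohort.sweeps.get(cid)
        if cs is None:
            continue
        profiles.append(traces.extract_profile(
            cid, g, ramp_sweep=cs.ramp, step_sweeps=cs.steps,
            sag_sweep=cs.sag, zero_sweeps=cs.zero,
            dvdt_criterion=dvdt_criterion))
    return profiles


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the run report (also on disk).

    Outputs land in ``config.output_dir``: per-cell profiles, pair tests and
    the connectivity summary, morphometrics and Sholl profiles, PCA and
    clustering results, and a manifest with the config and SHA-256 of every
    artifact.  Identical config and seed give byte-identical outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages_run": []}
    written: list[Path] = []

    cohort = None
    if config.stages.simulate:
        try:
            cohort = generate_cohort(
                {
                    "arkypallidal": config.cohort.n_arkypallidal,
                    "prototypic_PV": config.cohort.n_prototypic_pv,
                    "prototypic_Nkx": config.cohort.n_prototypic_nkx,
                },
                ConnectionProbabilities(config.cohort.p_proto_proto,
                                        config.cohort.p_other),
                rng_seed=config.seed,
                sampling_rate=config.cohort.sampling_rate_hz,
                noise_sd=config.cohort.noise_sd_mv,
                include_zero=config.cohort.include_zero_current,
                zero_duration_ms=config.cohort.zero_duration_ms,
                n_steps=config.cohort.n_steps,
                include_pairs=config.stages.connectivity,
                include_morphology=config.stages.morpho,
            )
        except Exception as exc:  # noqa: BLE001 - structured stage error
            raise StageError("simulate", str(exc)) from exc
        report["stages_run"].append("simulate")
        report["n_cells"] = len(cohort.cells)
        if config.write_sweeps:
            sweep_dir = out_dir / "sweeps"
            sweep_dir.mkdir(exist_ok=True)
            for cid in cohort.cell_ids:
                cs = cohort.sweeps[cid]
                for tag, sw in [("ramp", cs.ramp), ("sag", cs.sag)] + [
                    (f"step{j}", s) for j, s in enumerate(cs.steps)
                ] + [(f"zero{j}", s) for j, s in enumerate(cs.zero)]:
                    if sw is None:
                        continue
                    sw.cell_id = cid
                    written.append(write_sweep(sw, sweep_dir / f"{cid}_{tag}.csv"))
                    written.append((sweep_dir / f"{cid}_{tag}.json"))
            gt_path = out_dir / "ground_truth.json"
            gt_path.write_text(json.dumps({
                "connection_map": {f"{a}->{b}": v for (a, b), v
                                   in cohort.connection_map.items()},
            }, indent=1, sort_keys=True))
            written.append(gt_path)

    if cohort is None and any([config.stages.features, config.stages.connectivity,
                               config.stages.morpho, config.stages.cluster]):
        raise StageError("simulate", "downstream stages need the simulate stage "
                                     "in this in-memory pipeline")

    profiles = None
    if config.stages.features:
        try:
            profiles = extract_profiles(
                cohort, config.analysis.dvdt_criterion_mv_per_ms)
            df = traces.profiles_to_frame(profiles)
            path = out_dir / "profiles.csv"
            df.to_csv(path, index=False, float_format="%.6g")
            written.append(path)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("features", str(exc)) from exc
        report["stages_run"].append("features")
        report["n_profiles"] = len(profiles)

    if config.stages.connectivity:
        try:
            tests = analyze_pairs(cohort, config.analysis)
            summary = connectivity_summary(tests)
            pt_path = out_dir / "pair_tests.csv"
            pair_tests_to_frame(tests).to_csv(pt_path, index=False, float_format="%.6g")
            written.append(pt_path)
            cs_path = out_dir / "connectivity_summary.csv"
            summary.table.to_csv(cs_path, index=False, float_format="%.6g")
            written.append(cs_path)
            report["connectivity"] = {
                "total_pairs": summary.total_pairs,
                "total_connected": summary.total_connected,
                "electrical_pairs": summary.electrical_pairs,
                "electrical_coupled": summary.electrical_coupled,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("connectivity", str(exc)) from exc
        report["stages_run"].append("connectivity")

    if config.stages.morpho:
        try:
            metrics, sholl_df = metrics_table(
                cohort.morphologies, config.analysis.sholl_step_um)
            m_path = out_dir / "morphometrics.csv"
            metrics.to_csv(m_path, index=False, float_format="%.6g")
            s_path = out_dir / "sholl.csv"
            sholl_df.to_csv(s_path, index=False, float_format="%.6g")
            written += [m_path, s_path]
            if config.write_sweeps:
                swc_dir = out_dir / "swc"
                swc_dir.mkdir(exist_ok=True)
                for m in cohort.morphologies:
                    written.append(write_swc(m, swc_dir / f"{m.cell_id}.swc"))
        except Exception as exc:  # noqa: BLE001
            raise StageError("morpho", str(exc)) from exc
        report["stages_run"].append("morpho")

    if config.stages.cluster:
        try:
            if profiles is None:
                profiles = extract_profiles(
                    cohort, config.analysis.dvdt_criterion_mv_per_ms)
            matrix = build_matrix(traces.profiles_to_frame(profiles), FEATURES_15)
            pres = pca(matrix)
            cres = hier_cluster(matrix, config.analysis.k_clusters,
                                use_scores=config.analysis.cluster_on_scores)
            eig_path = out_dir / "pca_eigenvalues.csv"
            pd.DataFrame({
                "component": np.arange(1, pres.eigenvalues.size + 1),
                "eigenvalue": pres.eigenvalues,
                "explained_fraction": pres.explained,
            }).to_csv(eig_path, index=False, float_format="%.8g")
            written.append(eig_path)
            lab_path = out_dir / "cluster_labels.csv"
            pd.DataFrame({
                "cell_id": matrix.cell_ids, "group": matrix.groups,
                "cluster": cres.labels,
            }).to_csv(lab_path, index=False)
            written.append(lab_path)
            report["cluster"] = {
                "n_retained_components": pres.n_retained,
                "purity": cres.purity,
                "n_rows": len(matrix.cell_ids),
                "n_dropped": len(matrix.dropped_ids),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", str(exc)) from exc
        report["stages_run"].append("cluster")

    manifest = {
        "config": config.model_dump(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(Path(p)) for p in written},
        "report": report,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report
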