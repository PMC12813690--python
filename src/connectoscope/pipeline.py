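"""Config-driven orchestration: simulate -> preprocess -> voxel-metrics ->
connectome -> graph -> stats -> classify, with a provenance manifest.

Stages communicate only through files inside the run directory, so any
stage can be re-run or inspected in isolation; the manifest records the
package version, the seed assigned to each stage, a parameter echo, and a
SHA-256 checksum of every output file. Re-running with an identical
config reproduces identical manifests byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io
from .classify import assemble_features, consensus_connections, nested_loocv
from .connectome import (attach_network_labels, extract_roi_timeseries,
                         fisher_z, graph_series, load_network_labels,
                         pearson_matrix)
from .graph_metrics import (GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES,
                            MetricCurves, connectome_curves, metric_auc)
from .group_stats import (metric_group_tests, permutation_cluster_correct,
                          voxelwise_group_map)
from .preprocess import BoldRun, clean_run, motion_qc
from .synthetic_cohort import (AtlasVolume, GroundTruthSpec, SyntheticCohort,
                               generate_cohort)
from .voxel_metrics import (VoxelMap, alff_falff_maps, smoothed_reho_map,
                            standardize_map)

STAGES = ["simulate", "preprocess", "voxel_metrics", "connectome", "graph",
          "stats", "classify"]
VOXEL_METRICS = ["alff", "falff", "reho"]


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the analysis defaults.

    Dropped volumes 10, band 0.01-0.08 Hz, motion limits 3 mm / 3 deg,
    FWHM 6 mm, sparsity grid 0.05:0.01:0.50, selection alpha 0.05,
    voxel/cluster p 0.01.
    """

    seed: int = 0
    # cohort
    n_patients: int = 27
    n_controls: int = 25
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 90
    tr_seconds: float = 2.0
    n_volumes: int = 240
    edge_effect: dict = field(default_factory=dict)     # {"i,j": dz}
    amp_effect: dict = field(default_factory=dict)      # {node: factor}
    coherence_effect: dict = field(default_factory=dict)
    subject_z_sd: float = 0.2
    base_coherence: float = 0.6
    # preprocess
    drop: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    trans_limit_mm: float = 3.0
    rot_limit_deg: float = 3.0
    # voxel metrics
    fwhm_mm: float = 6.0
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    reho_neighborhood: int = 27
    # connectome
    s_min: float = 0.05
    s_max: float = 0.50
    s_step: float = 0.01
    fisher_clip: float = 1e-7
    # graph
    n_rand: int = 100
    n_swaps: int | None = None
    # stats
    n_perm: int = 1000
    voxel_p: float = 0.01
    cluster_p: float = 0.01
    q: float = 0.05
    # classify
    alpha: float = 0.05
    C_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 6))
    beta_step: float = 0.1
    combo: str = "C+G+N"


_TUPLE_FIELDS = {"grid_dims": 3, "band": 2, "voxel_mm": 3, "C_grid": None}


def validate_config(raw: dict | None) -> RunConfig:
    """Inject defaults, check every invariant, aggregate all problems."""
    raw = dict(raw or {})
    problems = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
        for k in unknown:
            raw.pop(k)
    for key, length in _TUPLE_FIELDS.items():
        if key in raw and isinstance(raw[key], (list, tuple)):
            if length is not None and len(raw[key]) != length:
                problems.append(f"{key} must have {length} entries")
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    if cfg.n_patients < 1 or cfg.n_controls < 1:
        problems.append("group sizes must be positive")
    if cfg.n_volumes <= cfg.drop:
        problems.append("n_volumes must exceed the number of dropped volumes")
    if not (0 <= cfg.band[0] < cfg.band[1]):
        problems.append(f"band {cfg.band} must satisfy 0 <= low < high")
    if cfg.band[1] > 0.5 / cfg.tr_seconds + 1e-12:
        problems.append("band upper edge exceeds the Nyquist frequency")
    if cfg.s_step <= 0:
        problems.append("sparsity step must be positive")
    if not (0 < cfg.s_min <= cfg.s_max <= 0.5):
        problems.append("sparsity grid must satisfy 0 < s_min <= s_max <= 0.5")
    if cfg.fwhm_mm < 0:
        problems.append("fwhm_mm must be nonnegative")
    if cfg.reho_neighborhood not in (7, 19, 27):
        problems.append("reho_neighborhood must be 7, 19 or 27")
    if cfg.n_perm < 100:
        problems.append("n_perm must be >= 100")
    if not (0 < cfg.alpha <= 1):
        problems.append("alpha must lie in (0, 1]")
    if not cfg.C_grid:
        problems.append("C_grid must be nonempty")
    if not (0 < cfg.beta_step <= 1):
        problems.append("beta_step must lie in (0, 1]")
    combo = tuple(cfg.combo.split("+"))
    if not combo or any(b not in ("C", "G", "N") for b in combo):
        problems.append("combo must look like 'C', 'C+G', 'C+G+N', ...")
    if problems:
        raise ConfigError(problems)
    return cfg


def _stage_seeds(cfg: RunConfig) -> dict[str, int]:
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2 ** 31))
            for s, c in zip(STAGES, children)}


def _cohort_spec(cfg: RunConfig, seed: int) -> GroundTruthSpec:
    edge = {tuple(int(v) for v in k.split(",")): float(dz)
            for k, dz in cfg.edge_effect.items()}
    return GroundTruthSpec(
        n_per_group=(cfg.n_patients, cfg.n_controls),
        grid_dims=cfg.grid_dims, n_rois=cfg.n_rois,
        tr_seconds=cfg.tr_seconds, n_volumes=cfg.n_volumes,
        edge_effect=edge,
        amp_effect={int(k): float(v) for k, v in cfg.amp_effect.items()},
        coherence_effect={int(k): float(v)
                          for k, v in cfg.coherence_effect.items()},
        subject_z_sd=cfg.subject_z_sd, base_coherence=cfg.base_coherence,
        seed=seed)


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(_cohort_spec(cfg, seed))
    files = [io.write_nifti(out / "atlas.nii", cohort.atlas.labels)]
    for run in cohort.runs:
        files.append(io.write_nifti(out / f"{run.subject_id}_bold.nii",
                                    run.data, run.tr_seconds))
        files.append(io.write_tsv(out / f"{run.subject_id}_motion.tsv",
                                  run.motion))
        files.append(io.write_tsv(out / f"{run.subject_id}_confounds.tsv",
                                  run.confounds))
    files.append(io.write_tsv(out / "covariates.tsv", cohort.covariates))
    files.append(io.write_json(out / "truth.json", cohort.truth))
    return files


def _load_run(sim: Path, subject: str) -> BoldRun:
    data, tr = io.read_nifti(sim / f"{subject}_bold.nii")
    atlas, _ = io.read_nifti(sim / "atlas.nii")
    return BoldRun(data=data, tr_seconds=tr, mask=atlas > 0,
                   motion=io.read_tsv(sim / f"{subject}_motion.tsv"),
                   confounds=io.read_tsv(sim / f"{subject}_confounds.tsv"),
                   subject_id=subject)


def _subjects(sim: Path) -> pd.DataFrame:
    return io.read_tsv(sim / "covariates.tsv")


def stage_preprocess(cfg: RunConfig, sim: Path, out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    cov = _subjects(sim)
    qc_report, files = [], []
    for subject in cov["subject"]:
        run = _load_run(sim, subject)
        qc = motion_qc(run, cfg.trans_limit_mm, cfg.rot_limit_deg)
        qc_report.append(qc.to_dict())
        if qc.exclude:
            continue
        band_run, _ = clean_run(run, drop=cfg.drop, band=cfg.band)
        broad_run, _ = clean_run(run, drop=cfg.drop, band=None)
        files.append(io.write_nifti(out / f"{subject}_clean-band.nii",
                                    band_run.data, band_run.tr_seconds))
        files.append(io.write_nifti(out / f"{subject}_clean-broad.nii",
                                    broad_run.data, broad_run.tr_seconds))
    files.append(io.write_json(out / "qc.json", {"runs": qc_report}))
    return files


def _retained_subjects(pre: Path) -> list[str]:
    qc = io.read_json(pre / "qc.json")["runs"]
    return [r["subject_id"] for r in qc if not r["exclude"]]


def stage_voxel_metrics(cfg: RunConfig, sim: Path, pre: Path,
                        out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    atlas_data, _ = io.read_nifti(sim / "atlas.nii")
    labels = atlas_data.astype(np.int32)
    mask = labels > 0
    files = []
    roi_rows = []
    for subject in _retained_subjects(pre):
        broad, tr = io.read_nifti(pre / f"{subject}_clean-broad.nii")
        band, _ = io.read_nifti(pre / f"{subject}_clean-band.nii")
        broad_run = BoldRun(broad, tr, mask, subject_id=subject)
        band_run = BoldRun(band, tr, mask, subject_id=subject)
        amap, fmap = alff_falff_maps(broad_run, cfg.band, cfg.fwhm_mm,
                                     cfg.voxel_mm)
        rmap = smoothed_reho_map(band_run, cfg.reho_neighborhood,
                                 cfg.fwhm_mm, cfg.voxel_mm)
        for vmap, name in ((amap, "alff"), (fmap, "falff"), (rmap, "reho")):
            z = standardize_map(vmap)
            files.append(io.write_nifti(out / f"{subject}_{name}.nii",
                                        vmap.values))
            files.append(io.write_nifti(out / f"{subject}_{name}-z.nii",
                                        z.values))
            for node in range(1, int(labels.max()) + 1):
                roi_rows.append({
                    "subject": subject, "metric": name, "node": node,
                    "mean_z": float(z.values[labels == node].mean()),
                })
    files.append(io.write_tsv(out / "roi_means.tsv", pd.DataFrame(roi_rows)))
    return files


def stage_connectome(cfg: RunConfig, sim: Path, pre: Path,
                     out: Path) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    atlas_data, _ = io.read_nifti(sim / "atlas.nii")
    labels = atlas_data.astype(np.int32)
    n_rois = int(labels.max())
    atlas = AtlasVolume(labels, n_rois)
    names = ([f"node{i:02d}" for i in range(1, n_rois + 1)] if n_rois != 90
             else list(load_network_labels()["name"]))
    files = []
    for subject in _retained_subjects(pre):
        band, tr = io.read_nifti(pre / f"{subject}_clean-band.nii")
        run = BoldRun(band, tr, atlas.mask, subject_id=subject)
        ts = extract_roi_timeseries(run, atlas)
        matrix = fisher_z(pearson_matrix(ts), clip=cfg.fisher_clip)
        if n_rois == 90:
            attach_network_labels(matrix)
        files.append(io.write_tsv(out / f"{subject}_r.tsv",
                                  pd.DataFrame(matrix.r, columns=names)))
        files.append(io.write_tsv(out / f"{subject}_z.tsv",
                                  pd.DataFrame(matrix.z, columns=names)))
    return files


def _curves_from_files(graph_dir: Path, subject: str) -> MetricCurves:
    gc = io.read_tsv(graph_dir / f"{subject}_global_curves.tsv")
    grid = gc["sparsity"].to_numpy()
    global_curves = gc[GLOBAL_METRIC_NAMES].set_axis(grid)
    nodal_auc = io.read_tsv(graph_dir / f"{subject}_nodal_auc.tsv")
    global_auc = pd.Series({m: metric_auc(global_curves[m].to_numpy(), grid)
                            for m in GLOBAL_METRIC_NAMES})
    return MetricCurves(grid, global_curves, {},
                        global_auc[GLOBAL_METRIC_NAMES],
                        nodal_auc[NODAL_METRIC_NAMES])


def stage_graph(cfg: RunConfig, con: Path, out: Path, seed: int) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    subjects = sorted(p.name.removesuffix("_z.tsv")
                      for p in con.glob("*_z.tsv"))
    rng = np.random.default_rng(seed)
    files = []
    for subject in subjects:
        r = io.read_tsv(con / f"{subject}_r.tsv").to_numpy()
        from .connectome import ConnectivityMatrix
        matrix = ConnectivityMatrix((r + r.T) / 2)
        graphs = graph_series(matrix, cfg.s_min, cfg.s_max, cfg.s_step)
        curves = connectome_curves(graphs, n_rand=cfg.n_rand, seed=rng,
                                   n_swaps=cfg.n_swaps)
        gc = curves.global_curves.copy()
        gc.insert(0, "sparsity", curves.sparsities)
        files.append(io.write_tsv(out / f"{subject}_global_curves.tsv", gc))
        files.append(io.write_tsv(out / f"{subject}_nodal_auc.tsv",
                                  curves.nodal_auc))
    files.append(io.write_json(out / "summary.json", {
        "n_rand": cfg.n_rand, "n_swaps": cfg.n_swaps, "seed": seed,
        "subjects": subjects}))
    return files


def stage_stats(cfg: RunConfig, sim: Path, pre: Path, vox: Path, graph: Path,
                out: Path, seed: int) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    cov = _subjects(sim)
    retained = _retained_subjects(pre)
    cov = cov[cov["subject"].isin(retained)].reset_index(drop=True)
    group = cov["group"].to_numpy()
    covars = cov[["age", "sex", "education", "bmi"]].to_numpy(float)
    atlas_data, _ = io.read_nifti(sim / "atlas.nii")
    mask = atlas_data > 0
    files = []
    rng = np.random.default_rng(seed)
    cluster_rows = []
    for name in VOXEL_METRICS:
        maps = []
        for subject in cov["subject"]:
            vals, _ = io.read_nifti(vox / f"{subject}_{name}-z.nii")
            maps.append(VoxelMap(vals, mask, name, standardized=True))
        stat = permutation_cluster_correct(
            maps, group, covars, n_perm=cfg.n_perm, voxel_p=cfg.voxel_p,
            cluster_p=cfg.cluster_p, seed=rng)
        files.append(io.write_nifti(out / f"{name}_t.nii", stat.t_values))
        files.append(io.write_nifti(out / f"{name}_p.nii", stat.p_values))
        for c in stat.surviving_clusters:
            cluster_rows.append({"metric": name, **{k: str(v) if k == "peak_voxel"
                                                    else v for k, v in c.items()}})
    files.append(io.write_tsv(out / "clusters.tsv", pd.DataFrame(
        cluster_rows, columns=["metric", "size", "peak_voxel", "corrected_p"])))
    curves = [_curves_from_files(graph, s) for s in cov["subject"]]
    table = metric_group_tests(curves, group, q=cfg.q)
    files.append(io.write_tsv(out / "metric_tests.tsv", table))
    files.append(io.write_json(out / "settings.json", {
        "n_perm": cfg.n_perm, "voxel_p": cfg.voxel_p,
        "cluster_p": cfg.cluster_p, "q": cfg.q, "seed": seed}))
    return files


def stage_classify(cfg: RunConfig, sim: Path, pre: Path, con: Path,
                   graph: Path, out: Path, seed: int) -> list[Path]:
    out.mkdir(parents=True, exist_ok=True)
    cov = _subjects(sim)
    retained = _retained_subjects(pre)
    cov = cov[cov["subject"].isin(retained)].reset_index(drop=True)
    from .connectome import ConnectivityMatrix
    feats = []
    names = networks = None
    for subject, grp in zip(cov["subject"], cov["group"]):
        r = io.read_tsv(con / f"{subject}_r.tsv").to_numpy()
        matrix = ConnectivityMatrix((r + r.T) / 2)
        z = io.read_tsv(con / f"{subject}_z.tsv").to_numpy()
        matrix.z = (z + z.T) / 2
        curves = _curves_from_files(graph, subject)
        feats.append(assemble_features(matrix, curves, subject, int(grp)))
        if names is None and matrix.n_nodes == 90:
            table = load_network_labels()
            names, networks = list(table["name"]), list(table["network"])
    combo = tuple(cfg.combo.split("+"))
    result = nested_loocv(feats, combo=combo, alpha=cfg.alpha,
                          C_grid=cfg.C_grid, beta_step=cfg.beta_step,
                          seed=seed)
    files = []
    folds = result.folds.copy()
    folds["betas"] = folds["betas"].map(lambda b: ",".join(f"{x:g}" for x in b))
    files.append(io.write_tsv(out / "folds.tsv", folds))
    consensus = consensus_connections(
        result.selected_C, names, networks,
        result.summary.get("consensus_mean_p"),
        n_nodes=_n_nodes_from_edges(len(feats[0].C)))
    files.append(io.write_tsv(out / "consensus.tsv", consensus))
    roc = pd.DataFrame(result.summary["roc_points"], columns=["fpr", "tpr"])
    files.append(io.write_tsv(out / "roc.tsv", roc))
    summary = {k: v for k, v in result.summary.items() if k != "roc_points"}
    summary["combo"] = cfg.combo
    files.append(io.write_json(out / "summary.json", summary))
    return files


def _n_nodes_from_edges(n_edges: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if n * (n - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a triangular number")
    return n


def run_pipeline(config: RunConfig | dict | None, out_dir: str | Path) -> dict:
    """Execute all stages in order; write and return the manifest."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg)
    dirs = {s: out_dir / s for s in STAGES}
    manifest = {"package_version": __version__,
                "config": dataclasses.asdict(cfg),
                "stage_seeds": seeds, "stages": {}}

    plan = [
        ("simulate", lambda: stage_simulate(cfg, dirs["simulate"],
                                            seeds["simulate"])),
        ("preprocess", lambda: stage_preprocess(cfg, dirs["simulate"],
                                                dirs["preprocess"])),
        ("voxel_metrics", lambda: stage_voxel_metrics(
            cfg, dirs["simulate"], dirs["preprocess"], dirs["voxel_metrics"])),
        ("connectome", lambda: stage_connectome(
            cfg, dirs["simulate"], dirs["preprocess"], dirs["connectome"])),
        ("graph", lambda: stage_graph(cfg, dirs["connectome"], dirs["graph"],
                                      seeds["graph"])),
        ("stats", lambda: stage_stats(cfg, dirs["simulate"], dirs["preprocess"],
                                      dirs["voxel_metrics"], dirs["graph"],
                                      dirs["stats"], seeds["stats"])),
        ("classify", lambda: stage_classify(cfg, dirs["simulate"],
                                            dirs["preprocess"],
                                            dirs["connectome"], dirs["graph"],
                                            dirs["classify"],
                                            seeds["classify"])),
    ]
    for name, fn in plan:
        try:
            outputs = fn()
        except Exception:
            manifest["stages"][name] = {"status": "failed"}
            io.write_json(out_dir / "manifest.json", manifest)
            raise
        manifest["stages"][name] = {
            "status": "ok",
            "outputs": {str(p.relative_to(out_dir)): io.sha256_of(p)
                        for p in sorted(outputs)},
        }
    io.write_json(out_dir / "manifest.json", manifest)
    return manifest
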