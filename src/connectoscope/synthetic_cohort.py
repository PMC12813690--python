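"""Synthetic two-group BOLD cohorts with known planted ground truth.

Real resting-state cohorts of the kind this pipeline analyses are rarely
shareable, so every downstream stage is exercised on simulated data with
known truth: band-limited (0.01-0.08 Hz) node signals drawn to match a
prescribed 90x90 correlation structure, rendered into a contiguous-parcel
voxel atlas with controllable local coherence and noise, plus nuisance
components (linear drift, white-matter/CSF confounds, motion traces).
Group 1 ("patients") receives multiplicative amplitude factors on chosen
nodes, local-coherence deltas, and additive Fisher-z connectivity deltas
on chosen edges; group 0 ("controls") uses the base parameters.

Between-subject heterogeneity is modelled as i.i.d. Gaussian dispersion of
each subject's Fisher-z connectivity around the group target
(``subject_z_sd``); without it, edge estimates would differ between
subjects only by sampling noise and any planted effect would be recovered
with unrealistically extreme statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .preprocess import BoldRun, MOTION_COLUMNS

DEFAULT_BAND = (0.01, 0.08)
MAX_ABS_R = 0.999  # correlations this close to +-1 are treated as invalid


@dataclass
class AtlasVolume:
    """Integer-labeled 3D parcellation (0 = background, 1..n nodes)."""

    labels: np.ndarray
    n_rois: int
    node_names: list[str] = field(default_factory=list)
    network_labels: list[str] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CovariateModel:
    """Per-group sampling distributions for age/sex/education/BMI.

    Defaults reproduce the demographic profile of a typical middle-aged
    endocrine-clinic cohort: age ~ N(41, 13^2) truncated to 18-60 years,
    education ~ N(13-15, 2-3^2) years, BMI ~ N(24-25, 3^2), with a
    moderately female-skewed patient group.
    """

    age_mean: tuple[float, float] = (41.1, 42.2)       # (patients, controls)
    age_sd: tuple[float, float] = (13.9, 11.1)
    age_range: tuple[float, float] = (18.0, 60.0)
    education_mean: tuple[float, float] = (13.3, 14.7)
    education_sd: tuple[float, float] = (3.1, 2.1)
    male_fraction: tuple[float, float] = (7 / 27, 11 / 25)
    bmi_mean: tuple[float, float] = (25.3, 24.0)
    bmi_sd: tuple[float, float] = (2.8, 3.1)


@dataclass
class GroundTruthSpec:
    """Full description of a synthetic cohort, including the planted effects."""

    n_per_group: tuple[int, int] = (27, 25)            # (patients, controls)
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 90
    tr_seconds: float = 2.0
    n_volumes: int = 240
    base_corr: np.ndarray | None = None                # default built from seed
    amp_effect: dict[int, float] = field(default_factory=dict)
    coherence_effect: dict[int, float] = field(default_factory=dict)
    edge_effect: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    base_coherence: float = 0.6
    subject_z_sd: float = 0.2
    drift_sd: float = 0.01
    confound_weight: float = 0.2
    motion_max_mm: float = 0.5
    motion_max_deg: float = 0.5
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must be > 10")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        for node, a in self.amp_effect.items():
            if a <= 0:
                raise ValueError(f"amplitude factor for node {node} must be > 0")
        C = self.resolved_base_corr()
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("base_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("base_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("base_corr must be positive definite")
        for (i, j), dz in self.edge_effect.items():
            r = C[i - 1, j - 1]
            # tanh saturates; anything closer to +-1 than MAX_ABS_R is a
            # degenerate correlation and rejected as if it crossed 1
            if abs(np.tanh(np.arctanh(r) + dz)) >= MAX_ABS_R:
                raise ValueError(f"edge delta on ({i},{j}) pushes |r| >= 1")
        for node, dc in self.coherence_effect.items():
            if not (0 <= self.base_coherence + dc <= 1):
                raise ValueError(f"coherence for node {node} leaves [0, 1]")

    def resolved_base_corr(self) -> np.ndarray:
        if self.base_corr is not None:
            return np.asarray(self.base_corr, float)
        return default_base_corr(self.n_rois, seed=self.seed)


@dataclass
class SyntheticCohort:
    runs: list[BoldRun]
    atlas: AtlasVolume
    covariates: pd.DataFrame
    truth: dict


def default_base_corr(n_rois: int, n_blocks: int = 8, within: float = 0.35,
                      between: float = 0.08, seed: int = 0) -> np.ndarray:
    """Block-structured SPD correlation emulating community organisation.

    Within-community correlations around ``within`` and weak background
    correlations around ``between`` give thresholded graphs realistic
    clustering, modularity, and small-world topology.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    blocks = np.sort(rng.integers(0, n_blocks, size=n_rois))
    C = np.full((n_rois, n_rois), between, float)
    same = blocks[:, None] == blocks[None, :]
    C[same] = within
    jitter = rng.normal(0, 0.02, (n_rois, n_rois))
    C = C + (jitter + jitter.T) / 2
    np.fill_diagonal(C, 1.0)
    return nearest_spd_correlation(C)


def nearest_spd_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and renormalize to unit diagonal."""
    C = (C + C.T) / 2
    w, V = np.linalg.eigh(C)
    if w.min() < floor:
        C = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def build_atlas(grid_dims: tuple[int, int, int], n_rois: int = 90,
                seed: int = 0) -> AtlasVolume:
    """Contiguous parcels by nearest-seed (Voronoi) growth on the box interior.

    Seeds are placed by farthest-point sampling, so parcels are roughly
    equal-sized; Voronoi cells of a convex voxel box are connected.
    """
    dims = tuple(int(d) for d in grid_dims)
    interior = np.zeros(dims, bool)
    if min(dims) > 2:
        interior[1:-1, 1:-1, 1:-1] = True
    else:
        interior[:] = True
    coords = np.argwhere(interior).astype(float)
    if len(coords) < n_rois:
        raise ValueError(
            f"{n_rois} parcels do not fit in {len(coords)} interior voxels")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    first = int(rng.integers(len(coords)))
    seed_idx = [first]
    d2 = ((coords - coords[first]) ** 2).sum(axis=1)
    for _ in range(n_rois - 1):
        nxt = int(np.argmax(d2))  # argmax ties -> lowest flat index
        seed_idx.append(nxt)
        d2 = np.minimum(d2, ((coords - coords[nxt]) ** 2).sum(axis=1))
    seeds = coords[seed_idx]
    dist = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(dist, axis=1) + 1  # argmin ties -> lowest label
    labels = np.zeros(dims, np.int32)
    labels[interior] = assignment
    names, networks = _default_node_tables(n_rois)
    return AtlasVolume(labels, n_rois, names, networks)


def _default_node_tables(n_rois: int) -> tuple[list[str], list[str]]:
    from .connectome import load_network_labels
    if n_rois == 90:
        table = load_network_labels()
        return list(table["name"]), list(table["network"])
    names = [f"ROI{i:03d}" for i in range(1, n_rois + 1)]
    return names, ["Unassigned"] * n_rois


def simulate_roi_signals(target_corr: np.ndarray, n_volumes: int,
                         tr_seconds: float, band: tuple[float, float] = DEFAULT_BAND,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Band-limited node signals with expected correlation ``target_corr``.

    White Gaussian noise is masked to the band in the frequency domain,
    standardized, then mixed by the symmetric square root of the target
    matrix, which makes the expected covariance exactly the target while
    keeping all spectral power inside the band.
    """
    C = np.asarray(target_corr, float)
    n = C.shape[0]
    w, V = np.linalg.eigh((C + C.T) / 2)
    if w.min() <= 0:
        raise np.linalg.LinAlgError("target correlation is not positive definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n, n_volumes))
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    keep = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
    if not keep.any():
        raise ValueError("band contains no frequency bins at this length/TR")
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0
    S = np.fft.irfft(spec, n=n_volumes, axis=1)
    S -= S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    S /= np.where(sd > 0, sd, 1.0)
    A = (V * np.sqrt(w)) @ V.T
    return A @ S


def simulate_motion(n_volumes: int, max_mm: float, max_deg: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Smoothed random-walk motion traces with controlled peak displacement."""
    walk = np.cumsum(rng.standard_normal((n_volumes, 6)), axis=0)
    walk = uniform_filter1d(walk, size=min(11, n_volumes), axis=0)
    walk -= walk[:1]
    peak = np.abs(walk).max(axis=0)
    peak[peak == 0] = 1.0
    target = np.concatenate([
        rng.uniform(0.3, 1.0, 3) * max_mm,
        rng.uniform(0.3, 1.0, 3) * max_deg,
    ])
    return pd.DataFrame(walk / peak * target, columns=MOTION_COLUMNS)


def render_bold(atlas: AtlasVolume, roi_signals: np.ndarray,
                amp: dict[int, float] | None = None,
                coherence: dict[int, float] | None = None,
                noise_sd: float = 1.0,
                seed: int | np.random.Generator = 0,
                tr_seconds: float = 2.0,
                motion_max_mm: float = 0.5, motion_max_deg: float = 0.5,
                subject_id: str = "sub-00") -> BoldRun:
    """Render node signals into a 4D voxel grid.

    Each voxel in parcel ``l`` is ``amp(l) * s_l + noise``. When a
    coherence fraction ``c`` is given for the parcel, the independent
    voxel noise is scaled so the shared node signal carries exactly the
    fraction ``c`` of voxel variance (``c = 1`` gives identical voxels,
    ``c = 0`` gives pure noise with sd ``noise_sd``); otherwise the noise
    sd is ``noise_sd``.
    """
    amp = amp or {}
    coherence = coherence or {}
    for l, c in coherence.items():
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"coherence for parcel {l} outside [0, 1]")
    n_rois, T = roi_signals.shape
    if n_rois != atlas.n_rois:
        raise ValueError("roi_signals rows do not match atlas labels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.zeros(atlas.labels.shape + (T,), float)
    for l in range(1, n_rois + 1):
        vox = atlas.labels == l
        nv = int(vox.sum())
        if nv == 0:
            continue
        a = float(amp.get(l, 1.0))
        s = roi_signals[l - 1]
        sd_s = s.std()
        if l in coherence:
            c = coherence[l]
            if c == 0.0:
                signal, sigma = 0.0, noise_sd
            elif c == 1.0:
                signal, sigma = a * s, 0.0
            else:
                signal = a * s
                sigma = a * sd_s * np.sqrt((1 - c) / c)
        else:
            signal, sigma = a * s, noise_sd
        series = np.broadcast_to(signal, (nv, T)).copy()
        if sigma > 0:
            series += sigma * rng.standard_normal((nv, T))
        data[vox] = series
    motion = simulate_motion(T, motion_max_mm, motion_max_deg, rng)
    return BoldRun(data=data, tr_seconds=tr_seconds, mask=atlas.mask.copy(),
                   motion=motion, subject_id=subject_id)


def _group_target_corr(spec: GroundTruthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Base (controls) and effect-shifted (patients) target correlations."""
    C0 = spec.resolved_base_corr()
    Z = np.arctanh(np.clip(C0, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(Z, 0.0)
    for (i, j), dz in spec.edge_effect.items():
        Z[i - 1, j - 1] += dz
        Z[j - 1, i - 1] += dz
    C1 = np.tanh(Z)
    np.fill_diagonal(C1, 1.0)
    if np.any(np.abs(C1[~np.eye(len(C1), dtype=bool)]) >= MAX_ABS_R):
        raise ValueError("edge effect pushes |r| >= 1")
    return C0, nearest_spd_correlation(C1)


def _subject_corr(group_corr: np.ndarray, z_sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Low-rank, mean-preserving subject dispersion around the group target.

    Per-subject connectivity varies through a centered rank-2 Wishart
    perturbation, C_i = C + B B' - E[B B'], which keeps E[C_i] = C (so
    planted group effects survive in expectation), yields a per-edge
    dispersion of about ``z_sd``, and stays positive definite for the
    dispersion levels of interest. Unstructured i.i.d. edge noise of
    comparable size is not representable by any valid 90-node correlation
    matrix (the perturbation's spectral radius would exceed the smallest
    eigenvalue), and projecting it back to the PD cone destroys planted
    effects; empirically, between-subject FC variability is dominated by
    a few global modes, which the low-rank model mimics.
    """
    if z_sd == 0:
        return group_corr
    n = group_corr.shape[0]
    k = 2
    s2 = z_sd / np.sqrt(k)
    B = rng.normal(0.0, np.sqrt(s2), (n, k))
    C = group_corr + B @ B.T - k * s2 * np.eye(n)
    d = np.sqrt(np.clip(np.diag(C), 1e-3, None))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return nearest_spd_correlation(C)


def _draw_covariates(spec: GroundTruthSpec, rng: np.random.Generator) -> pd.DataFrame:
    cm = spec.covariate_model
    rows = []
    idx = 0
    for g, n in ((1, spec.n_per_group[0]), (0, spec.n_per_group[1])):
        col = 0 if g == 1 else 1
        for _ in range(n):
            age = float(np.clip(rng.normal(cm.age_mean[col], cm.age_sd[col]),
                                *cm.age_range))
            rows.append({
                "subject": f"sub-{idx:03d}",
                "group": g,
                "age": age,
                "sex": int(rng.random() < cm.male_fraction[col]),
                "education": max(0.0, float(rng.normal(cm.education_mean[col],
                                                       cm.education_sd[col]))),
                "bmi": float(rng.normal(cm.bmi_mean[col], cm.bmi_sd[col])),
            })
            idx += 1
    return pd.DataFrame(rows)


def generate_cohort(spec: GroundTruthSpec) -> SyntheticCohort:
    """Generate a full two-group cohort; a pure function of ``spec``.

    Patients (group 1) come first in ``runs`` and in the covariate table.
    """
    spec.validate()
    ss = np.random.SeedSequence([int(spec.seed), 0xC0867])
    atlas_ss, cov_ss, subj_root = ss.spawn(3)
    atlas = build_atlas(spec.grid_dims, spec.n_rois,
                        seed=int(atlas_ss.generate_state(1)[0] % (2 ** 31)))
    covariates = _draw_covariates(spec, np.random.default_rng(cov_ss))
    C0, C1 = _group_target_corr(spec)
    n_pat, n_ctl = spec.n_per_group
    amp1 = dict(spec.amp_effect)
    coh0 = {l: spec.base_coherence for l in range(1, spec.n_rois + 1)}
    coh1 = dict(coh0)
    for l, dc in spec.coherence_effect.items():
        coh1[l] = float(np.clip(coh0[l] + dc, 0.0, 1.0))
    runs = []
    subj_seeds = subj_root.spawn(n_pat + n_ctl)
    for idx in range(n_pat + n_ctl):
        in_group1 = idx < n_pat
        rng = np.random.default_rng(subj_seeds[idx])
        target = _subject_corr(C1 if in_group1 else C0, spec.subject_z_sd, rng)
        signals = simulate_roi_signals(target, spec.n_volumes, spec.tr_seconds,
                                       DEFAULT_BAND, seed=rng)
        run = render_bold(atlas, signals,
                          amp=amp1 if in_group1 else {},
                          coherence=coh1 if in_group1 else coh0,
                          noise_sd=spec.noise_sd, seed=rng,
                          tr_seconds=spec.tr_seconds,
                          motion_max_mm=spec.motion_max_mm,
                          motion_max_deg=spec.motion_max_deg,
                          subject_id=f"sub-{idx:03d}")
        _inject_nuisance(run, spec, rng)
        runs.append(run)
    truth = {
        "spec": _spec_echo(spec),
        "group_target_corr": {"controls": C0, "patients": C1},
        "planted_edges": sorted(spec.edge_effect),
        "planted_amp_nodes": sorted(spec.amp_effect),
        "planted_coherence_nodes": sorted(spec.coherence_effect),
    }
    return SyntheticCohort(runs=runs, atlas=atlas, covariates=covariates, truth=truth)


def _inject_nuisance(run: BoldRun, spec: GroundTruthSpec,
                     rng: np.random.Generator) -> None:
    """Add linear drift and WM/CSF confound series in place."""
    T = run.n_volumes
    t = np.arange(T, dtype=float)
    mask = run.mask
    if spec.drift_sd > 0:
        slopes = rng.normal(0.0, spec.drift_sd, int(mask.sum()))
        run.data[mask] += slopes[:, None] * t[None, :]
    conf = simulate_roi_signals(np.eye(2), T, spec.tr_seconds, DEFAULT_BAND, seed=rng)
    if spec.confound_weight > 0:
        weights = rng.uniform(0.5, 1.0, 2) * spec.confound_weight
        run.data[mask] += weights @ conf
    run.confounds = pd.DataFrame({"white_matter": conf[0], "csf": conf[1]})


def _spec_echo(spec: GroundTruthSpec) -> dict:
    d = dataclasses.asdict(spec)
    C = spec.resolved_base_corr()
    d["base_corr"] = np.round(C, 6)
    d["edge_effect"] = {f"{i},{j}": v for (i, j), v in spec.edge_effect.items()}
    return d
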