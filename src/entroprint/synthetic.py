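"""Synthetic HCP-like cohorts with known ground truth.

The generator emulates the statistical structure the pipeline is built for,
without any imaging data: every subject has two scan days of two runs of
parcellated BOLD-like time series, a latent per-ROI "irregularity" that is
partly shared across the cohort (the blueprint) and partly individual (the
fingerprint), structural properties coupled to that irregularity at both
levels, family structure with partially shared individual deviations,
tractography-like connective-probability matrices, and cognitive scores
linearly loaded on the individual entropy deviations.

Model, per subject i and ROI n:

    a_i,n   = blueprint_sd * A_n + sum_p ic_p * dev_i,n,p + subject_sd * xi_i,n
    A_n     = sum_p bc_p * B_n,p + residual            (unit variance)
    phi_i,n,s = phi_max * sigmoid(-(a_i,n + jitter_i,n,s) / phi_scale)

where B_n,p are per-ROI structural property blueprints, dev_i,n,p individual
property deviations (siblings share a configurable fraction), and the time
series of run r in session s is a stationary AR(1) process with coefficient
phi_i,n,s and unit-variance innovations.  Larger phi means smoother signal
and lower dispersion entropy, so entropy is monotone increasing in a.  A
configurable fraction of ROIs ("noise ROIs", placed in the limbic-like
network) carry pure white noise with no subject effect: they sit at the
entropy ceiling with near-zero test-retest reliability, which is what the
reliability screen is meant to catch.

Cognitive scores load on the standardised stable individual entropy
deviations with a configured population R^2 per outcome.  The latent
irregularity, noise mask, planted weights and variance components are
returned as ground truth for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    DataError,
    MORPHOMETRY,
    NETWORKS,
    RoiTimeSeries,
    StructuralProfiles,
    read_manifest,
    read_tsv_matrix,
    write_tsv_matrix,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "default_network_partition",
    "generate_cohort",
    "assign_networks_by_overlap",
    "write_cohort",
    "read_cohort",
]

#: network sizes of the 360-ROI multimodal parcellation mapped to 7 networks
_NETWORK_RATIOS = {
    "DMN": 83, "VIS": 59, "SM": 52, "SAL": 49, "FP": 45, "ATT": 44, "LIM": 28,
}


def default_network_partition(n_rois: int) -> dict[str, int]:
    """Scale the reference network-size ratios to ``n_rois``
    (largest-remainder apportionment; DMN largest, LIM smallest)."""
    total = sum(_NETWORK_RATIOS.values())
    quotas = {k: n_rois * v / total for k, v in _NETWORK_RATIOS.items()}
    sizes = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n_rois - sum(sizes.values())
    order = sorted(quotas, key=lambda k: quotas[k] - sizes[k], reverse=True)
    for k in order[:remainder]:
        sizes[k] += 1
    return sizes


def _default_blueprint_couplings() -> dict[str, float]:
    # thickness positively, connectivity most negatively coupled to entropy
    return {
        "thickness": 0.50,
        "myelin": -0.20,
        "curv": -0.20,
        "sulc": -0.15,
        "strength": -0.25,
        "degree": -0.40,
    }


def _default_individual_couplings() -> dict[str, float]:
    # folding and myelination dominate the individual deviations
    return {
        "thickness": 0.05,
        "myelin": 0.25,
        "curv": 0.30,
        "sulc": 0.45,
        "strength": 0.05,
        "degree": 0.05,
    }


def _default_cognitive_r2() -> dict[str, float]:
    return {"g": 0.30, "vis": 0.20, "cry": 0.25, "mem": 0.15, "spd": 0.10}


#: realistic-looking location/scale used when emitting morphometry tables
_PROPERTY_UNITS = {
    "thickness": (2.6, 0.25),
    "myelin": (1.5, 0.15),
    "curv": (0.10, 0.03),
    "sulc": (0.0, 4.0),
}


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    A fixed ``seed`` makes :func:`generate_cohort` byte-deterministic.
    """

    n_subjects: int = 100
    n_rois: int = 100
    n_timepoints: int = 1200
    n_runs: int = 2
    n_sessions: int = 2
    #: probability of family sizes 1, 2, 3, ...
    family_size_probs: tuple[float, ...] = (0.55, 0.30, 0.15)
    network_partition: dict[str, int] | None = None
    noise_roi_fraction: float = 0.05
    blueprint_couplings: dict[str, float] = field(
        default_factory=_default_blueprint_couplings
    )
    individual_couplings: dict[str, float] = field(
        default_factory=_default_individual_couplings
    )
    #: sd of the blueprint component of the latent irregularity
    blueprint_sd: float = 0.70
    #: sd of the stable subject-specific residual
    subject_sd: float = 0.60
    #: sd of the per-session jitter on the latent irregularity
    session_jitter_sd: float = 0.25
    #: fraction of individual property deviations shared by siblings
    sibling_shared_fraction: float = 0.5
    #: individual-deviation fields are low-rank + noise: number of shared
    #: spatial modes and the variance fraction they carry (global and
    #: network-level effects dominate individual differences in real maps)
    n_deviation_factors: int = 6
    deviation_factor_share: float = 0.8
    #: cross-subject sd of a property relative to its blueprint sd
    property_dev_sd: float = 0.35
    cognitive_r2: dict[str, float] = field(default_factory=_default_cognitive_r2)
    cognitive_family_share: float = 0.3
    #: fraction of non-noise ROIs carrying cognitive signal
    signal_roi_fraction: float = 0.2
    phi_max: float = 0.95
    phi_scale: float = 1.5
    connectivity_density: float = 0.10
    connectivity_threshold: float = 0.001
    connectivity_beta: float = 0.8
    connectivity_noise_sd: float = 0.3
    connectivity_individual_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_roi_fraction <= 1:
            raise ValueError("noise_roi_fraction must lie in [0, 1]")
        if not 0 <= self.sibling_shared_fraction <= 1:
            raise ValueError("sibling_shared_fraction must lie in [0, 1]")
        if any(not 0 <= v < 1 for v in self.cognitive_r2.values()):
            raise ValueError("cognitive R^2 values must lie in [0, 1)")
        if abs(sum(self.family_size_probs) - 1) > 1e-9:
            raise ValueError("family_size_probs must sum to 1")
        if self.network_partition is not None:
            if sum(self.network_partition.values()) != self.n_rois:
                raise ValueError("network partition must sum to n_rois")

    def partition(self) -> dict[str, int]:
        return self.network_partition or default_network_partition(self.n_rois)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the latent ground truth that produced it."""

    config: CohortConfig
    timeseries: RoiTimeSeries
    parcellation: pd.DataFrame
    morphometry: StructuralProfiles
    connectivity: np.ndarray  # (subjects, rois, rois) directed probabilities
    scores: pd.DataFrame
    truth: dict

    @property
    def subject_ids(self) -> list[str]:
        return self.timeseries.subject_ids

    @property
    def roi_ids(self) -> list[str]:
        return self.timeseries.roi_ids


def _draw_families(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = []
    total = 0
    probs = np.asarray(cfg.family_size_probs)
    while total < cfg.n_subjects:
        s = int(rng.choice(np.arange(1, probs.size + 1), p=probs))
        s = min(s, cfg.n_subjects - total)
        sizes.append(s)
        total += s
    fam = np.repeat([f"F{i:04d}" for i in range(len(sizes))], sizes)
    return fam


try:  # pragma: no cover
    from numba import njit

    @njit(cache=False)
    def _ar1_recursion(phi, e):
        m, n_t = e.shape
        for i in range(m):
            p = phi[i]
            e[i, 0] = e[i, 0] / np.sqrt(1.0 - p * p)
            for t in range(1, n_t):
                e[i, t] = p * e[i, t - 1] + e[i, t]
        return e

except ImportError:  # pragma: no cover
    _ar1_recursion = None


def _ar1_rows(
    phi: np.ndarray, n_t: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) rows with per-row coefficient and unit-variance
    innovations (float32)."""
    m = phi.size
    e = rng.standard_normal((m, n_t), dtype=np.float32)
    phi32 = phi.astype(np.float32)
    if _ar1_recursion is not None:
        return _ar1_recursion(phi32, e)
    x = e
    x[:, 0] = e[:, 0] / np.sqrt(1.0 - phi32**2)
    for t in range(1, n_t):
        x[:, t] = phi32 * x[:, t - 1] + e[:, t]
    return x


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort from a config (deterministic in config.seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sub, n_roi, n_t = cfg.n_subjects, cfg.n_rois, cfg.n_timepoints

    subject_ids = [f"S{i:04d}" for i in range(n_sub)]
    families = _draw_families(cfg, rng)

    # --- parcellation: contiguous network blocks, alternating hemispheres
    partition = cfg.partition()
    networks = np.concatenate(
        [np.full(size, net) for net, size in partition.items()]
    )
    roi_ids = [f"R{i:03d}" for i in range(n_roi)]
    parcellation = pd.DataFrame(
        {
            "roi_id": roi_ids,
            "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(n_roi)],
            "network": networks,
        }
    )

    # --- noise ROIs: limbic-like placement (LIM first, overflow to SAL)
    n_noise = int(round(cfg.noise_roi_fraction * n_roi))
    noise_mask = np.zeros(n_roi, dtype=bool)
    candidates = np.concatenate(
        [np.flatnonzero(networks == net) for net in ("LIM", "SAL")]
    )
    if n_noise > candidates.size:
        raise ValueError("noise_roi_fraction too large for the LIM/SAL pool")
    noise_mask[rng.choice(candidates, size=n_noise, replace=False)] = True

    # --- structural property latents
    props = list(cfg.blueprint_couplings)
    morpho_bp = {p: rng.standard_normal(n_roi) for p in MORPHOMETRY}
    pair_jitter = rng.standard_normal((n_roi, n_roi)) * 0.3
    pair_jitter = (pair_jitter + pair_jitter.T) / 2.0
    conn_latent = rng.standard_normal(n_roi)

    # base connective weights: w0 = thr * exp(beta * (u - u_q)); the top
    # `density` fraction of pairs clears the threshold by construction
    u = conn_latent[:, None] + conn_latent[None, :] + pair_jitter
    np.fill_diagonal(u, -np.inf)
    off = u[np.isfinite(u)]
    u_q = np.quantile(off, 1.0 - cfg.connectivity_density)
    with np.errstate(over="ignore"):
        w0 = cfg.connectivity_threshold * np.exp(
            cfg.connectivity_beta * (u - u_q)
        )
    w0[~np.isfinite(w0)] = 0.0
    np.fill_diagonal(w0, 0.0)
    supra = w0 >= cfg.connectivity_threshold
    deg0 = supra.sum(axis=1).astype(float)
    str0 = (w0 * supra).sum(axis=1)

    def _z(v):
        return (v - v.mean()) / v.std()

    # empirical standardisation makes couplings read as correlations
    bp_z = {**{p: _z(morpho_bp[p]) for p in MORPHOMETRY},
            "strength": _z(str0), "degree": _z(deg0)}

    # --- individual property deviations (siblings share a fraction)
    fs = cfg.sibling_shared_fraction
    fam_index = pd.factorize(families)[0]
    n_fam = fam_index.max() + 1
    k_f = cfg.n_deviation_factors
    share = cfg.deviation_factor_share

    def _structured_field(n_units: int, loadings: np.ndarray) -> np.ndarray:
        """Low-rank + noise deviation field with unit per-ROI variance."""
        scores = rng.standard_normal((n_units, k_f))
        iid = rng.standard_normal((n_units, n_roi))
        return np.sqrt(share) * (scores @ loadings) + np.sqrt(1 - share) * iid

    dev = {}
    for p in props:
        lam = rng.standard_normal((k_f, n_roi))
        lam /= np.sqrt((lam**2).sum(axis=0, keepdims=True))  # unit-var modes
        fam_part = _structured_field(n_fam, lam)[fam_index]
        own_part = _structured_field(n_sub, lam)
        dev[p] = np.sqrt(fs) * fam_part + np.sqrt(1.0 - fs) * own_part

    # --- latent irregularity: blueprint + stable individual deviation
    sys = sum(cfg.blueprint_couplings[p] * bp_z[p] for p in props)
    resid_var = max(1.0 - np.var(sys), 0.0025)
    a_blueprint = _z(sys + np.sqrt(resid_var) * rng.standard_normal(n_roi))
    a_dev = sum(cfg.individual_couplings[p] * dev[p] for p in props)
    lam_resid = rng.standard_normal((k_f, n_roi))
    lam_resid /= np.sqrt((lam_resid**2).sum(axis=0, keepdims=True))
    resid_scores = rng.standard_normal((n_sub, k_f))
    resid_struct = np.sqrt(share) * (resid_scores @ lam_resid)
    resid_iid = rng.standard_normal((n_sub, n_roi))
    resid_field = resid_struct + np.sqrt(1.0 - share) * resid_iid
    a_dev = a_dev + cfg.subject_sd * resid_field
    a_stable = cfg.blueprint_sd * a_blueprint[None, :] + a_dev

    # --- session-level irregularity and AR coefficients
    jitter = cfg.session_jitter_sd * rng.standard_normal(
        (n_sub, cfg.n_sessions, n_roi)
    )
    a_session = a_stable[:, None, :] + jitter
    phi = cfg.phi_max * expit(-a_session / cfg.phi_scale)

    # --- time series
    sig_idx = np.flatnonzero(~noise_mask)
    data = np.empty(
        (n_sub, cfg.n_sessions, cfg.n_runs, n_roi, n_t), dtype=np.float32
    )
    for s in range(cfg.n_sessions):
        for r in range(cfg.n_runs):
            phi_rows = phi[:, s, :][:, sig_idx].ravel()
            rows = _ar1_rows(phi_rows, n_t, rng)
            data[:, s, r, sig_idx, :] = rows.reshape(n_sub, sig_idx.size, n_t)
            if noise_mask.any():
                data[:, s, r, noise_mask, :] = rng.standard_normal(
                    (n_sub, int(noise_mask.sum()), n_t), dtype=np.float32
                )
    ts = RoiTimeSeries(
        data=data, subject_ids=subject_ids, roi_ids=roi_ids,
        session_labels=tuple(f"REST{i + 1}" for i in range(cfg.n_sessions)),
    )

    # --- per-subject connectivity
    conn_dev = (dev["strength"] + dev["degree"]) / np.sqrt(2.0)
    connectivity = np.empty((n_sub, n_roi, n_roi))
    for i in range(n_sub):
        node = cfg.connectivity_individual_sd * conn_dev[i]
        scale = np.exp(node[:, None] + node[None, :])
        noise = np.exp(
            cfg.connectivity_noise_sd * rng.standard_normal((n_roi, n_roi))
        )
        pmat = np.clip(w0 * scale * noise, 0.0, 0.99)
        np.fill_diagonal(pmat, 0.0)
        connectivity[i] = pmat

    # --- morphometry tables in natural units
    morpho_values = {}
    for p in MORPHOMETRY:
        loc, sc = _PROPERTY_UNITS[p]
        morpho_values[p] = loc + sc * (
            bp_z[p][None, :] + cfg.property_dev_sd * dev[p]
        )
    morphometry = StructuralProfiles(morpho_values, subject_ids, roi_ids)

    # --- cognitive scores loaded on the stable individual entropy deviations
    # (on their structured component when modes are configured: behaviour
    # couples to the dominant modes of individual variation, not to
    # ROI-by-ROI measurement idiosyncrasies)
    signal_field = resid_struct if share > 0 else resid_field
    d_std = (signal_field - signal_field.mean(axis=0)) / signal_field.std(axis=0)
    signal_pool = np.flatnonzero(~noise_mask)
    k = max(1, int(round(cfg.signal_roi_fraction * signal_pool.size)))
    fam_effect = rng.standard_normal(n_fam)[fam_index]
    score_cols = {}
    weights = {}
    signal_components = {}
    for outcome, r2 in cfg.cognitive_r2.items():
        signal_rois = rng.choice(signal_pool, size=k, replace=False)
        w = np.zeros(n_roi)
        w[signal_rois] = rng.choice([-1.0, 1.0], size=k) / np.sqrt(k)
        s = d_std @ w
        if s.std() == 0:
            s = np.zeros(n_sub)
        else:
            s = (s - s.mean()) / s.std()
        fshare = cfg.cognitive_family_share
        noise = (
            np.sqrt(fshare) * fam_effect
            + np.sqrt(1.0 - fshare) * rng.standard_normal(n_sub)
        )
        noise = (noise - noise.mean()) / noise.std()
        score_cols[outcome] = np.sqrt(r2) * s + np.sqrt(1.0 - r2) * noise
        weights[outcome] = w
        signal_components[outcome] = s
    scores = pd.DataFrame(
        {"subject_id": subject_ids, "family_id": families, **score_cols}
    )

    truth = {
        "noise_mask": noise_mask,
        "a_blueprint": a_blueprint,
        "a_dev": a_dev,
        "a_stable": a_stable,
        "phi": phi,
        "property_blueprints": bp_z,
        "property_deviations": dev,
        "cognitive_weights": weights,
        "cognitive_signal": signal_components,
        "session_jitter_sd": cfg.session_jitter_sd,
        "blueprint_sd": cfg.blueprint_sd,
    }
    return SyntheticCohort(
        config=cfg,
        timeseries=ts,
        parcellation=parcellation,
        morphometry=morphometry,
        connectivity=connectivity,
        scores=scores,
        truth=truth,
    )


def assign_networks_by_overlap(fine_labels, coarse_labels) -> dict[int, int]:
    """Map each fine-atlas region to the coarse network covering the
    plurality of its vertices (ties towards the smaller coarse label)."""
    fine = np.asarray(fine_labels)
    coarse = np.asarray(coarse_labels)
    if fine.shape != coarse.shape or fine.ndim != 1:
        raise DataError("label vectors must be equal-length 1-D")
    mapping = {}
    for region in np.unique(fine):
        members = coarse[fine == region]
        if members.size == 0:
            raise DataError(f"empty fine region {region}")
        labels, counts = np.unique(members, return_counts=True)
        mapping[int(region)] = int(labels[np.argmax(counts)])
    return mapping


# ---------------------------------------------------------------------------
# on-disk round trip (plain TSV + JSON manifests)


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write a cohort to ``directory`` in the pipeline's input formats.

    Layout: ``manifest.json``, ``parcellation.tsv``, ``scores.tsv``,
    ``structure.tsv`` (long format), ``timeseries/<sub>_<ses>_run<k>.tsv``
    (ROIs x samples) each with a JSON sidecar, ``connectivity/<sub>.tsv``,
    and ``truth/`` arrays.  ``read_cohort(write_cohort(c))`` reproduces all
    arrays exactly.
    """
    root = Path(directory)
    (root / "timeseries").mkdir(parents=True, exist_ok=True)
    (root / "connectivity").mkdir(exist_ok=True)
    (root / "truth").mkdir(exist_ok=True)
    ts = cohort.timeseries
    manifest = {
        "subject_ids": ts.subject_ids,
        "roi_ids": ts.roi_ids,
        "session_labels": list(ts.session_labels),
        "n_runs": int(ts.data.shape[2]),
        "tr": ts.tr,
        "config": asdict(cohort.config),
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    cohort.parcellation.to_csv(root / "parcellation.tsv", sep="\t", index=False)
    cohort.scores.to_csv(
        root / "scores.tsv", sep="\t", index=False, float_format="%.17g"
    )
    cohort.morphometry.to_frame().to_csv(
        root / "structure.tsv", sep="\t", index=False, float_format="%.17g"
    )
    for i, sub in enumerate(ts.subject_ids):
        for s, ses in enumerate(ts.session_labels):
            for r in range(ts.data.shape[2]):
                stem = root / "timeseries" / f"{sub}_{ses}_run{r + 1}"
                write_tsv_matrix(
                    stem.with_suffix(".tsv"), ts.data[i, s, r], fmt="%.9g"
                )
                with open(stem.with_suffix(".json"), "w") as fh:
                    json.dump(
                        {"subject_id": sub, "session": ses, "run": r + 1,
                         "tr": ts.tr},
                        fh, sort_keys=True,
                    )
        write_tsv_matrix(
            root / "connectivity" / f"{sub}.tsv", cohort.connectivity[i]
        )
    t = cohort.truth
    write_tsv_matrix(root / "truth" / "a_dev.tsv", t["a_dev"])
    write_tsv_matrix(root / "truth" / "a_stable.tsv", t["a_stable"])
    write_tsv_matrix(
        root / "truth" / "phi.tsv", t["phi"].reshape(t["phi"].shape[0], -1)
    )
    scalars = {
        "noise_mask": t["noise_mask"].astype(int).tolist(),
        "a_blueprint": t["a_blueprint"].tolist(),
        "cognitive_weights": {k: v.tolist() for k, v in
                              t["cognitive_weights"].items()},
        "cognitive_signal": {k: v.tolist() for k, v in
                             t["cognitive_signal"].items()},
        "session_jitter_sd": t["session_jitter_sd"],
        "blueprint_sd": t["blueprint_sd"],
        "phi_shape": list(t["phi"].shape),
    }
    with open(root / "truth" / "truth.json", "w") as fh:
        json.dump(scalars, fh, sort_keys=True)
    return root


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    root = Path(directory)
    manifest = read_manifest(root / "manifest.json")
    cfg = CohortConfig(**manifest["config"])
    subject_ids = manifest["subject_ids"]
    roi_ids = manifest["roi_ids"]
    sessions = manifest["session_labels"]
    n_runs = manifest["n_runs"]
    parcellation = pd.read_csv(root / "parcellation.tsv", sep="\t")
    # round_trip parsing: the default float reader is not correctly rounded
    scores = pd.read_csv(root / "scores.tsv", sep="\t",
                         float_precision="round_trip")
    from .data import structural_profiles_from_frame

    morphometry = structural_profiles_from_frame(
        pd.read_csv(root / "structure.tsv", sep="\t",
                    float_precision="round_trip")
    )
    shape = None
    data = None
    for i, sub in enumerate(subject_ids):
        for s, ses in enumerate(sessions):
            for r in range(n_runs):
                path = root / "timeseries" / f"{sub}_{ses}_run{r + 1}.tsv"
                if not path.exists():
                    raise DataError(f"missing run file {path}")
                mat = read_tsv_matrix(path).astype(np.float32)
                if data is None:
                    shape = mat.shape
                    data = np.empty(
                        (len(subject_ids), len(sessions), n_runs) + shape,
                        dtype=np.float32,
                    )
                data[i, s, r] = mat
    connectivity = np.stack(
        [
            read_tsv_matrix(root / "connectivity" / f"{sub}.tsv")
            for sub in subject_ids
        ]
    )
    truth_meta = read_manifest(root / "truth" / "truth.json")
    phi_shape = tuple(truth_meta["phi_shape"])
    truth = {
        "noise_mask": np.asarray(truth_meta["noise_mask"], dtype=bool),
        "a_blueprint": np.asarray(truth_meta["a_blueprint"]),
        "a_dev": read_tsv_matrix(root / "truth" / "a_dev.tsv"),
        "a_stable": read_tsv_matrix(root / "truth" / "a_stable.tsv"),
        "phi": read_tsv_matrix(root / "truth" / "phi.tsv").reshape(phi_shape),
        "cognitive_weights": {
            k: np.asarray(v)
            for k, v in truth_meta["cognitive_weights"].items()
        },
        "cognitive_signal": {
            k: np.asarray(v)
            for k, v in truth_meta["cognitive_signal"].items()
        },
        "session_jitter_sd": truth_meta["session_jitter_sd"],
        "blueprint_sd": truth_meta["blueprint_sd"],
    }
    ts = RoiTimeSeries(
        data=data, subject_ids=subject_ids, roi_ids=roi_ids,
        session_labels=tuple(sessions), tr=manifest["tr"],
    )
    return SyntheticCohort(
        config=cfg,
        timeseries=ts,
        parcellation=parcellation,
        morphometry=morphometry,
        connectivity=connectivity,
        scores=scores,
        truth=truth,
    )
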