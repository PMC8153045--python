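"""Structural basis of cortical entropy profiles.

Two complementary analyses connect anatomy to entropy:

* **Blueprint** (cross-ROI): correlations between the group-mean entropy
  profile and the group-mean profile of each structural property (cortical
  thickness, T1w/T2w myelin proxy, curvature, sulcal depth, connectivity
  strength and degree), explaining the spatial heterogeneity every brain
  shares.
* **Fingerprint** (cross-individual): per-ROI correlations across subjects,
  and a per-ROI linear prediction of the individual entropy value from one
  structural property, cross-validated family-wise.  The assembled predicted
  profiles are scored two ways: per-subject similarity to the observed
  profile (driven by blueprint coupling) and identification specificity with
  the predictions as database (driven only by individual-deviation coupling)
  -- the dissociation at the heart of the blueprint/fingerprint distinction.

Connectivity inputs are directed connective-probability matrices; weights are
the reciprocal averages w_ij = (p_ij + p_ji)/2, thresholded at 0.001 by
default, from which node strength (row sum) and degree (suprathreshold link
count) derive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    DataError,
    EntropyProfiles,
    StructuralProfiles,
)
from .fingerprint import identify, permutation_null_accuracies
from .stats import bh_fdr, bootstrap_ci, columnwise_pearson, pearson

__all__ = [
    "ConnectivityMatrix",
    "symmetrize_and_threshold",
    "node_strength_degree",
    "add_connectivity_properties",
    "blueprint_correlations",
    "regional_individual_correlations",
    "StructureEntropyModel",
    "StructureEntropyResults",
]

DEFAULT_THRESHOLD = 0.001


@dataclass
class ConnectivityMatrix:
    """Symmetric, thresholded structural weight matrix."""

    w: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


def symmetrize_and_threshold(
    p, threshold: float = DEFAULT_THRESHOLD
) -> ConnectivityMatrix:
    """Reciprocal-average symmetrisation w_ij = (p_ij + p_ji)/2, then zero
    entries below ``threshold``.  Idempotent on already-processed matrices.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise DataError(f"connectivity matrix must be square, got {p.shape}")
    w = (p + p.T) / 2.0
    np.fill_diagonal(w, 0.0)
    w[w < threshold] = 0.0
    return ConnectivityMatrix(w=w, threshold=float(threshold))


def node_strength_degree(conn: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Node strength S_i = sum_j w_ij and degree K_i = #{j : w_ij > 0}."""
    strength = conn.w.sum(axis=1)
    degree = (conn.w > 0).sum(axis=1)
    return strength, degree


def add_connectivity_properties(
    structure: StructuralProfiles,
    probability_matrices: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
) -> StructuralProfiles:
    """Derive per-subject strength and degree from directed probability
    matrices (shape (n_subjects, n_rois, n_rois)) and merge them into the
    structural profile set."""
    mats = np.asarray(probability_matrices, dtype=float)
    n_sub, n_roi = len(structure.subject_ids), len(structure.roi_ids)
    if mats.shape != (n_sub, n_roi, n_roi):
        raise DataError(
            f"expected ({n_sub}, {n_roi}, {n_roi}) probability matrices, "
            f"got {mats.shape}"
        )
    strength = np.empty((n_sub, n_roi))
    degree = np.empty((n_sub, n_roi))
    for i in range(n_sub):
        conn = symmetrize_and_threshold(mats[i], threshold)
        strength[i], degree[i] = node_strength_degree(conn)
    values = dict(structure.values)
    values["strength"] = strength
    values["degree"] = degree.astype(float)
    return StructuralProfiles(values, structure.subject_ids, structure.roi_ids)


def blueprint_correlations(
    entropy_blueprint: np.ndarray,
    structure_blueprints: dict[str, np.ndarray],
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Cross-ROI correlation of the group-mean entropy profile with each
    structural property blueprint.

    Bootstrap CIs resample ROIs (the observation unit of this correlation);
    p-values are BH-corrected across properties.
    """
    en = np.asarray(entropy_blueprint, dtype=float)
    if en.size < 3:
        raise DataError("blueprint correlation needs at least 3 ROIs")
    rng = np.random.default_rng(seed)
    rows = []
    for prop, bp in structure_blueprints.items():
        bp = np.asarray(bp, dtype=float)
        if bp.shape != en.shape:
            raise DataError(f"blueprint for {prop!r} not ROI-aligned")
        res = pearson(en, bp)
        ci = bootstrap_ci(
            lambda e, b: np.corrcoef(e, b)[0, 1],
            (en, bp),
            n_boot=n_bootstrap,
            seed=rng,
        ) if n_bootstrap else None
        rows.append(
            {
                "property": prop,
                "r": res.r,
                "p": res.p,
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
                "n_rois": en.size,
            }
        )
    table = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(table["p"].to_numpy(), q=fdr_q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return table


def regional_individual_correlations(
    entropy: EntropyProfiles,
    structure: StructuralProfiles,
    parcellation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Cross-individual structure-entropy correlation in each ROI.

    Returns a long table (roi_id, property, r) and, if a parcellation is
    given, the network-averaged summary (network x property mean r).
    """
    if list(entropy.subject_ids) != list(structure.subject_ids):
        raise DataError("entropy and structure subjects differ")
    if list(entropy.roi_ids) != list(structure.roi_ids):
        raise DataError("entropy and structure ROIs differ")
    frames = []
    for prop, vals in structure.values.items():
        r = columnwise_pearson(entropy.values, vals)
        frames.append(
            pd.DataFrame(
                {"roi_id": entropy.roi_ids, "property": prop, "r": r}
            )
        )
    per_roi = pd.concat(frames, ignore_index=True)
    network_means = None
    if parcellation is not None:
        net = parcellation.set_index("roi_id")["network"]
        per_roi = per_roi.assign(
            network=net.loc[per_roi["roi_id"]].to_numpy()
        )
        network_means = (
            per_roi.groupby(["network", "property"], sort=False)["r"]
            .mean()
            .unstack("property")
        )
    return per_roi, network_means


@dataclass
class StructureEntropyResults:
    """Structure-based entropy-profile prediction and its specificity."""

    property: str
    predicted_profiles: EntropyProfiles
    per_subject_similarity: np.ndarray
    similarity_mean: float
    identification_accuracy: float
    permutation_p: float
    ci95: tuple[float, float] | None
    predicted_ids: list[str]
    n_permutations: int
    satisfactory: bool

    def summary(self) -> str:
        return "\n".join(
            [
                f"Entropy-profile prediction from {self.property!r}",
                "=" * 52,
                f"per-subject similarity: mean r = {self.similarity_mean:.4f}",
                f"identification specificity: accuracy = "
                f"{self.identification_accuracy:.4f} "
                f"(perm p = {self.permutation_p:.4f}, "
                f"{self.n_permutations} permutations)",
                f"satisfactory (> 60%): {'yes' if self.satisfactory else 'no'}",
            ]
        )


class StructureEntropyModel:
    """Per-ROI linear prediction of entropy from one structural property.

    For each ROI, entropy (session-averaged) is regressed on the property
    across the training subjects by ordinary least squares; out-of-fold
    predictions (leave-one-family-out) are assembled into predicted profiles.
    Similarity measures how well anatomy reconstructs the *shape* of a
    profile; identification with the predictions as database measures whether
    it reconstructs the *individual* deviations.
    """

    def __init__(
        self,
        entropy: EntropyProfiles,
        structure: StructuralProfiles,
        property: str,
        family_ids,
    ) -> None:
        if property not in structure.values:
            raise DataError(
                f"unknown property {property!r}; have {structure.properties}"
            )
        if list(entropy.subject_ids) != list(structure.subject_ids):
            raise DataError("entropy and structure subjects differ")
        if list(entropy.roi_ids) != list(structure.roi_ids):
            raise DataError("entropy and structure ROIs differ")
        family_ids = np.asarray(family_ids)
        if family_ids.size != entropy.n_subjects:
            raise DataError("family_ids length does not match subjects")
        self.entropy = entropy
        self.structure = structure
        self.property = property
        self.families = family_ids

    def fit(
        self,
        n_permutations: int = 1000,
        n_bootstrap: int = 1000,
        seed: int | np.random.Generator | None = None,
    ) -> StructureEntropyResults:
        rng = np.random.default_rng(seed)
        Y = self.entropy.values  # (subjects, rois)
        X = self.structure.values[self.property]
        n_sub, n_roi = Y.shape
        fold_ids = pd.unique(self.families)
        if len(fold_ids) < 2:
            raise DataError("LOFOV needs at least two families")
        predicted = np.empty_like(Y)
        warned = False
        for fam in fold_ids:
            test = self.families == fam
            train = ~test
            Xtr, Ytr = X[train], Y[train]
            xm = Xtr.mean(axis=0)
            ym = Ytr.mean(axis=0)
            xc = Xtr - xm
            var = (xc**2).sum(axis=0)
            dead = var == 0
            if dead.any() and not warned:
                warnings.warn(
                    f"{int(dead.sum())} ROI(s) with zero-variance regressor "
                    "in a training fold; predicted by the training mean",
                    stacklevel=2,
                )
                warned = True
            slope = np.where(
                dead, 0.0, ((Ytr - ym) * xc).sum(axis=0) / np.where(dead, 1.0, var)
            )
            predicted[test] = ym + (X[test] - xm) * slope
        pred_profiles = EntropyProfiles(
            predicted,
            list(self.entropy.subject_ids),
            list(self.entropy.roi_ids),
            session=f"predicted({self.property})",
        )
        # per-subject similarity: corr(predicted_i, observed_i) over ROIs
        pc = predicted - predicted.mean(axis=1, keepdims=True)
        oc = Y - Y.mean(axis=1, keepdims=True)
        denom = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
        similarity = (pc * oc).sum(axis=1) / denom
        # identification: predictions are the database, observations the target
        ident = identify(self.entropy, pred_profiles,
                         direction=f"{self.property}->observed")
        null = permutation_null_accuracies(ident, n_permutations, rng)
        perm_p = float(np.mean(null >= ident.accuracy))
        ci = None
        if n_bootstrap:
            ci = bootstrap_ci(
                lambda c: c.mean(),
                ident.correct.astype(float),
                n_boot=n_bootstrap,
                seed=rng,
            )
        return StructureEntropyResults(
            property=self.property,
            predicted_profiles=pred_profiles,
            per_subject_similarity=similarity,
            similarity_mean=float(similarity.mean()),
            identification_accuracy=ident.accuracy,
            permutation_p=perm_p,
            ci95=ci,
            predicted_ids=ident.predicted_ids,
            n_permutations=n_permutations,
            satisfactory=ident.accuracy > 0.60,
        )
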