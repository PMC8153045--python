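"""Fingerprint identification from entropy profiles.

An individual's per-ROI entropy vector behaves like a fingerprint: given the
profiles of all subjects from one scan day (the *database*) and the profiles
from the other day (the *target*), each target subject is predicted to be the
database subject whose profile correlates most strongly with theirs,

    r(i, j) = corr(EN_i^day1, EN_j^day2),   predicted(i) = argmax_j r(i, j).

Identification accuracy is the matched fraction; its significance comes from
a permutation null (shuffling target identities), and a fixed 60% accuracy
criterion marks identification as satisfactory.  Differentiation power (DP)
scores each ROI's contribution to identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DataError, EntropyProfiles, check_aligned
from .stats import bootstrap_ci

__all__ = [
    "ACCURACY_CRITERION",
    "identify",
    "permutation_null_accuracies",
    "differentiation_power",
    "DpProfile",
    "FingerprintIdentification",
    "FingerprintResults",
]

#: accuracy above this fixed threshold counts as satisfactory identification
ACCURACY_CRITERION = 0.60


def _zscore_rows(profiles: EntropyProfiles, what: str) -> np.ndarray:
    v = profiles.values
    sd = v.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [profiles.subject_ids[i] for i in np.flatnonzero(sd[:, 0] == 0)]
        raise DataError(
            f"zero-variance {what} profile row(s) for subject(s) {bad}; "
            "correlation undefined"
        )
    return (v - v.mean(axis=1, keepdims=True)) / sd


def similarity_matrix(
    target: EntropyProfiles, database: EntropyProfiles
) -> np.ndarray:
    """Pearson correlations r(i, j) between target rows i and database rows j."""
    check_aligned(target, database)
    if target.n_subjects < 2:
        raise DataError("need at least 2 subjects for identification")
    if target.n_rois < 3:
        raise DataError("need at least 3 ROIs for identification")
    zt = _zscore_rows(target, "target")
    zd = _zscore_rows(database, "database")
    return zt @ zd.T / target.n_rois


@dataclass
class IdentificationResult:
    """Single-direction identification outcome."""

    direction: str
    predicted_ids: list[str]
    accuracy: float
    similarity: np.ndarray
    correct: np.ndarray
    permutation_p: float | None = None
    ci95: tuple[float, float] | None = None
    n_permutations: int = 0

    @property
    def satisfactory(self) -> bool:
        return self.accuracy > ACCURACY_CRITERION


def identify(
    target: EntropyProfiles, database: EntropyProfiles, direction: str = ""
) -> IdentificationResult:
    """Predict each target subject as the most-correlated database subject.

    Ties in the argmax are broken towards the lowest subject index with a
    warning (exact ties have measure zero on real-valued data).
    """
    sim = similarity_matrix(target, database)
    pred_idx = np.argmax(sim, axis=1)
    n_max = (sim == sim.max(axis=1, keepdims=True)).sum(axis=1)
    if np.any(n_max > 1):
        warnings.warn(
            f"similarity ties for {int((n_max > 1).sum())} target subject(s); "
            "broken towards the lowest database index",
            stacklevel=2,
        )
    ids = np.asarray(database.subject_ids)
    predicted = ids[pred_idx]
    correct = predicted == np.asarray(target.subject_ids)
    return IdentificationResult(
        direction=direction,
        predicted_ids=predicted.tolist(),
        accuracy=float(correct.mean()),
        similarity=sim,
        correct=correct,
    )


def permutation_null_accuracies(
    result: IdentificationResult, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null identification accuracies obtained by permuting the target IDs.

    Shuffling which true identity each target row carries breaks the pairing
    between target and database while keeping the similarity structure; the
    accuracy of the original predictions against each shuffled labelling forms
    the null distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(result.predicted_ids)
    null = np.empty(n_perm)
    # database subjects are in target order, so the integer prediction is the
    # similarity argmax; prediction i matches permuted identity pi(i) iff
    # pred[i] == pi[i]
    pred = np.argmax(result.similarity, axis=1)
    for b in range(n_perm):
        pi = rng.permutation(n)
        null[b] = np.mean(pred == pi)
    return null


@dataclass
class DpProfile:
    """Per-ROI differentiation power.

    ``per_subject_p[i, n]`` is the empirical probability that a cross-subject
    profile product exceeds subject i's within-subject product at ROI n;
    ``dp[n] = -ln(mean_i per_subject_p[i, n])`` (zero-probability guard:
    epsilon = 1 / (2 N (N - 1)), the smallest attainable nonzero value).
    """

    dp: np.ndarray
    per_subject_p: np.ndarray
    roi_ids: list[str]


def differentiation_power(
    profiles_d1: EntropyProfiles, profiles_d2: EntropyProfiles
) -> DpProfile:
    """Differentiation power of every ROI.

    Profiles are z-scored per subject across ROIs (the Pearson-decomposition
    convention); phi_ij(n) = zEN_i^d1(n) * zEN_j^d2(n), and

        P_i(n) = (#{j!=i: phi_ij(n) > phi_ii(n)}
                  + #{j!=i: phi_ji(n) > phi_ii(n)}) / (2 (N - 1)).
    """
    check_aligned(profiles_d1, profiles_d2)
    n_sub, n_roi = profiles_d1.values.shape
    if n_sub < 2:
        raise DataError("differentiation power needs at least 2 subjects")
    z1 = _zscore_rows(profiles_d1, "day-1")
    z2 = _zscore_rows(profiles_d2, "day-2")
    per_p = np.empty((n_sub, n_roi))
    for n in range(n_roi):
        phi = np.outer(z1[:, n], z2[:, n])  # phi[i, j]
        diag = np.diag(phi)
        # strict inequality excludes j == i automatically (phi_ii == phi_ii)
        row_exceed = (phi > diag[:, None]).sum(axis=1)
        col_exceed = (phi > diag[None, :]).sum(axis=0)
        per_p[:, n] = (row_exceed + col_exceed) / (2.0 * (n_sub - 1))
    mean_p = per_p.mean(axis=0)
    eps = 1.0 / (2.0 * n_sub * (n_sub - 1))
    dp = -np.log(np.where(mean_p == 0, eps, mean_p))
    return DpProfile(dp=dp, per_subject_p=per_p, roi_ids=list(profiles_d1.roi_ids))


@dataclass
class FingerprintResults:
    """Two-direction identification with pooled permutation null.

    ``directions`` maps "R1->R2" (database day 1, target day 2) and
    "R2->R1" to their :class:`IdentificationResult`; the permutation p of
    each direction compares its observed accuracy to the pooled null over
    both directions.
    """

    directions: dict[str, IdentificationResult]
    null_accuracies: np.ndarray
    accuracy_criterion: float = ACCURACY_CRITERION
    dp: DpProfile | None = None

    def summary(self) -> str:
        lines = [
            "Fingerprint identification",
            "=" * 58,
            f"{'direction':<10}{'accuracy':>10}{'perm p':>10}"
            f"{'95% CI':>20}{'pass':>7}",
        ]
        for name, res in self.directions.items():
            ci = (
                f"[{res.ci95[0]:.3f}, {res.ci95[1]:.3f}]"
                if res.ci95
                else "-"
            )
            ok = "yes" if res.accuracy > self.accuracy_criterion else "no"
            lines.append(
                f"{name:<10}{res.accuracy:>10.4f}{res.permutation_p:>10.4f}"
                f"{ci:>20}{ok:>7}"
            )
        lines.append(
            f"criterion: accuracy > {self.accuracy_criterion:.0%}; "
            f"null pooled over {self.null_accuracies.size} permutations"
        )
        return "\n".join(lines)

    def plot_similarity(self, direction: str = "R1->R2", ax=None):
        """Heat map of the target x database similarity matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.directions[direction]
        im = ax.imshow(res.similarity, cmap="viridis")
        ax.set_xlabel("database subject")
        ax.set_ylabel("target subject")
        ax.set_title(f"profile similarity ({direction})")
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax


class FingerprintIdentification:
    """Model object for two-session fingerprint identification.

    Parameters
    ----------
    profiles_day1, profiles_day2 : EntropyProfiles
        Matched subject x ROI entropy matrices from the two scan days.
    """

    def __init__(
        self, profiles_day1: EntropyProfiles, profiles_day2: EntropyProfiles
    ) -> None:
        check_aligned(profiles_day1, profiles_day2)
        self.profiles_day1 = profiles_day1
        self.profiles_day2 = profiles_day2

    def fit(
        self,
        n_permutations_per_direction: int = 500,
        n_bootstrap: int = 1000,
        seed: int | np.random.Generator | None = None,
        compute_dp: bool = True,
    ) -> FingerprintResults:
        """Run both identification directions, the pooled permutation test,
        bootstrap CIs (resampling target subjects), and per-ROI DP."""
        rng = np.random.default_rng(seed)
        r12 = identify(self.profiles_day2, self.profiles_day1, "R1->R2")
        r21 = identify(self.profiles_day1, self.profiles_day2, "R2->R1")
        null = np.concatenate(
            [
                permutation_null_accuracies(
                    r12, n_permutations_per_direction, rng
                ),
                permutation_null_accuracies(
                    r21, n_permutations_per_direction, rng
                ),
            ]
        )
        for res in (r12, r21):
            res.permutation_p = float(np.mean(null >= res.accuracy))
            res.n_permutations = null.size
            if n_bootstrap:
                res.ci95 = bootstrap_ci(
                    lambda c: c.mean(), res.correct.astype(float),
                    n_boot=n_bootstrap, seed=rng,
                )
        dp = (
            differentiation_power(self.profiles_day1, self.profiles_day2)
            if compute_dp
            else None
        )
        return FingerprintResults(
            directions={"R1->R2": r12, "R2->R1": r21},
            null_accuracies=null,
            dp=dp,
        )
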