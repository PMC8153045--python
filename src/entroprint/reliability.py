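"""Regional test-retest reliability and the noise-ROI screening rule.

Per-ROI reliability is the across-subject Pearson correlation of entropy at
the same ROI between the two scan days.  Entropy is also sensitive to pure
noise: a noise-dominated ROI sits near the ceiling ln(c^m), where the
empirical entropy distribution of temporally permuted (randomised) signals
lives.  An ROI is flagged as unreliable/noise-dominated when BOTH

    reliability r < th_relia   (5th percentile of the per-ROI reliability
                                distribution)
    mean entropy > th_en       (5th percentile of the permuted-signal
                                entropy null)

hold; flagged ROIs are excluded from downstream reliable-profile analyses.
Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError, EntropyProfiles, RoiTimeSeries, check_aligned
from .entropy import DEFAULT_PARAMS, EntropyParams, batch_dispersion_entropy
from .stats import columnwise_pearson

__all__ = [
    "regional_reliability",
    "PermutedEntropyNull",
    "permuted_entropy_null",
    "ReliabilityProfile",
    "flag_unreliable_rois",
]


def regional_reliability(
    profiles_d1: EntropyProfiles, profiles_d2: EntropyProfiles
) -> np.ndarray:
    """Per-ROI Pearson r between the two days, computed across subjects.

    ROIs with zero cross-subject variance are reported as NaN with a warning.
    """
    check_aligned(profiles_d1, profiles_d2)
    if profiles_d1.n_subjects < 3:
        raise DataError("test-retest reliability needs at least 3 subjects")
    return columnwise_pearson(profiles_d1.values, profiles_d2.values)


@dataclass
class PermutedEntropyNull:
    """Entropy distribution of temporally permuted (randomised) signals."""

    samples: np.ndarray
    quantile_05: float
    params: EntropyParams

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def permuted_entropy_null(
    ts: RoiTimeSeries,
    params: EntropyParams = DEFAULT_PARAMS,
    session: str | int = 0,
    seed: int | np.random.Generator | None = None,
    n_repeats: int = 1,
) -> PermutedEntropyNull:
    """Empirical entropy distribution of temporally shuffled signals.

    Each run of each subject x ROI in the chosen session (the first scan by
    default) is independently shuffled along time; entropy is computed per
    shuffled run and the runs are averaged within the session, mirroring the
    real computation path.  One shuffle per signal by default; ``n_repeats``
    adds independent repetitions.
    """
    rng = np.random.default_rng(seed)
    s = ts.session_index(session)
    data = np.asarray(ts.data[:, s], dtype=float)  # (sub, runs, roi, time)
    n_sub, n_runs, n_roi, n_t = data.shape
    rows = data.reshape(n_sub * n_runs * n_roi, n_t)
    samples = []
    for _ in range(n_repeats):
        shuffled = rng.permuted(rows, axis=1)
        ent = batch_dispersion_entropy(shuffled, params).reshape(
            n_sub, n_runs, n_roi
        )
        samples.append(ent.mean(axis=1).ravel())
    samples = np.concatenate(samples)
    return PermutedEntropyNull(
        samples=samples,
        quantile_05=float(np.percentile(samples, 5)),
        params=params,
    )


@dataclass
class ReliabilityProfile:
    """Per-ROI reliability, grand-mean entropy, and the unreliable flag."""

    roi_ids: list[str]
    r: np.ndarray
    mean_entropy: np.ndarray
    flagged: np.ndarray
    th_relia: float
    th_en: float

    @property
    def retained_mask(self) -> np.ndarray:
        return ~self.flagged

    def to_frame(self, parcellation: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "r": self.r,
                "mean_entropy": self.mean_entropy,
                "flagged": self.flagged,
            }
        )
        if parcellation is not None:
            net = parcellation.set_index("roi_id")["network"]
            df.insert(1, "network", net.loc[df["roi_id"]].to_numpy())
        return df


def flag_unreliable_rois(
    reliability_r: np.ndarray,
    mean_entropy: np.ndarray,
    null: PermutedEntropyNull,
    roi_ids: list[str] | None = None,
    percentile: float = 5.0,
) -> ReliabilityProfile:
    """Two-threshold screening of noise-dominated ROIs.

    ``th_relia`` is the ``percentile``-th percentile of the observed per-ROI
    reliabilities (NaNs dropped); ``th_en`` the same percentile of the
    permuted-signal entropy null.  An ROI is flagged iff its reliability is
    below ``th_relia`` AND its grand-mean entropy exceeds ``th_en``.  Flagging
    is monotone: lowering r or raising entropy can never unflag an ROI at
    fixed thresholds.
    """
    r = np.asarray(reliability_r, dtype=float)
    en = np.asarray(mean_entropy, dtype=float)
    if r.size == 0 or en.size == 0:
        raise DataError("empty ROI set")
    if r.shape != en.shape:
        raise DataError("reliability and entropy vectors are not ROI-aligned")
    finite_r = r[np.isfinite(r)]
    if finite_r.size == 0:
        raise DataError("all reliabilities undefined")
    if finite_r.size < r.size:
        warnings.warn(
            f"{r.size - finite_r.size} ROI(s) with undefined reliability "
            "excluded from the threshold estimate and flagged",
            stacklevel=2,
        )
    th_relia = float(np.percentile(finite_r, percentile))
    th_en = float(np.percentile(null.samples, percentile))
    low_r = np.where(np.isfinite(r), r < th_relia, True)
    flagged = low_r & (en > th_en)
    if roi_ids is None:
        roi_ids = [f"ROI{i:04d}" for i in range(r.size)]
    return ReliabilityProfile(
        roi_ids=list(roi_ids),
        r=r,
        mean_entropy=en,
        flagged=flagged,
        th_relia=th_relia,
        th_en=th_en,
    )
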