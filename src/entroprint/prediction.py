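"""Prediction of cognitive ability scores from entropy profiles.

A multivariate linear model Y = bX + k is fitted by closed-form ridge
regression,

    b = (X'X + lambda I)^{-1} X'Y        (on centred, z-scored columns),

under leave-one-family-out cross-validation (LOFOV): all members of one
family form the held-out fold, so siblings never straddle the train/test
boundary.  Column standardisation (and optional feature screening) is
re-estimated inside each training fold.  Prediction accuracy is the Pearson
correlation between observed and out-of-fold predicted scores, clamped at
zero (a negative correlation reflects noise or a bad fit); the reported
result is for the grid value of lambda that maximises that correlation.
Note the selection re-uses the same cross-validated correlations it reports,
which is mildly optimistic; this mirrors the stated procedure rather than
"fixing" it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DataError, EntropyProfiles, validate_scores
from .stats import _t_based_p, bh_fdr, bootstrap_ci, pearson

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "RidgeModel",
    "ridge_fit",
    "PredictionResult",
    "CognitiveAbilityRidge",
    "per_network_prediction",
]

#: logarithmic default grid for the ridge penalty
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-2, 6))


@dataclass
class RidgeModel:
    """Closed-form ridge solution.

    ``b`` are the per-predictor coefficients on centred data; the intercept
    ``k`` equals the training mean of y when X is centred (in general
    ``k = mean(y) - mean(X) . b``).
    """

    b: np.ndarray
    k: float
    lam: float
    predictor_ids: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.b + self.k


def ridge_fit(
    X,
    y,
    lam: float,
    predictor_ids: list[str] | None = None,
) -> RidgeModel:
    """Fit b = (X'X + lambda I)^{-1} X'y on centred data.

    At ``lam = 0`` this reduces exactly to ordinary least squares; a singular
    (collinear) system at lam = 0 raises with advice to use lambda > 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("ridge penalty lambda must be >= 0")
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    G = Xc.T @ Xc
    if lam == 0:
        eigvals = np.linalg.eigvalsh(G)
        if eigvals[-1] <= 0 or eigvals[0] / eigvals[-1] < 1e-12:
            raise np.linalg.LinAlgError(
                "X'X is singular at lambda=0 (collinear predictors); "
                "use a ridge penalty lambda > 0"
            )
    b = np.linalg.solve(G + lam * np.eye(X.shape[1]), Xc.T @ yc)
    k = float(y_mean - x_mean @ b)
    return RidgeModel(b=b, k=k, lam=float(lam), predictor_ids=predictor_ids)


@dataclass
class PredictionResult:
    """Out-of-fold prediction of one outcome under LOFOV ridge."""

    outcome: str
    predicted: np.ndarray
    observed: np.ndarray
    accuracy_r: float
    r_raw: float
    p_value: float
    ci95: tuple[float, float] | None
    lambda_selected: float
    lambda_grid: tuple[float, ...]
    grid_r: np.ndarray
    mean_abs_weight: np.ndarray
    predictor_ids: list[str]
    n_folds: int

    def summary(self) -> str:
        ci = f"[{self.ci95[0]:.3f}, {self.ci95[1]:.3f}]" if self.ci95 else "-"
        top = np.argsort(self.mean_abs_weight)[::-1][:5]
        lines = [
            f"Ridge LOFOV prediction of {self.outcome!r}",
            "=" * 52,
            f"subjects: {self.observed.size}   families (folds): {self.n_folds}"
            f"   predictors: {len(self.predictor_ids)}",
            f"accuracy r (clamped at 0): {self.accuracy_r:.4f}   "
            f"p = {self.p_value:.3g}   95% CI {ci}",
            f"selected lambda: {self.lambda_selected:g}  "
            f"(grid {self.lambda_grid[0]:g} ... {self.lambda_grid[-1]:g})",
            "top ROIs by mean |weight|: "
            + ", ".join(
                f"{self.predictor_ids[i]} ({self.mean_abs_weight[i]:.3f})"
                for i in top
            ),
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter of observed vs out-of-fold predicted scores."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.observed, self.predicted, s=10, alpha=0.6)
        ax.set_xlabel(f"observed {self.outcome}")
        ax.set_ylabel(f"predicted {self.outcome}")
        ax.set_title(f"r = {self.accuracy_r:.3f} (lambda = "
                     f"{self.lambda_selected:g})")
        return ax


def _screen_features(
    Xtr: np.ndarray, ytr: np.ndarray, p_threshold: float
) -> np.ndarray:
    """Train-fold univariate screening: keep predictors whose Pearson p with
    the outcome is below the threshold."""
    n = ytr.size
    xc = Xtr - Xtr.mean(axis=0)
    yc = ytr - ytr.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc.reshape(-1, 1)).sum(axis=0) / denom, 0.0)
    return _t_based_p(r, n) < p_threshold


class CognitiveAbilityRidge:
    """Ridge-regression prediction of a cognitive factor score from a
    subject x ROI entropy profile matrix, cross-validated family-wise.

    Parameters
    ----------
    profiles : EntropyProfiles
        Session-averaged profiles with unreliable ROIs already removed.
    scores : pandas.DataFrame
        Columns ``subject_id``, ``family_id`` and one column per outcome
        (g, vis, cry, mem, spd in the standard battery).
    outcome : str
        Which score column to predict.
    lambda_grid : sequence of float
        Ridge penalties searched; the grid maximiser of the LOFOV
        observed-predicted correlation is reported.
    feature_p_threshold : float, optional
        If given, train-fold univariate screening retains predictors with
        Pearson p below the threshold (off by default).
    """

    def __init__(
        self,
        profiles: EntropyProfiles,
        scores: pd.DataFrame,
        outcome: str = "g",
        lambda_grid=DEFAULT_LAMBDA_GRID,
        feature_p_threshold: float | None = None,
    ) -> None:
        scores = validate_scores(scores)
        if outcome not in scores.columns:
            raise DataError(f"outcome {outcome!r} not in score table")
        scores = scores.set_index("subject_id")
        missing = [s for s in profiles.subject_ids if s not in scores.index]
        if missing:
            raise DataError(f"subjects missing from score table: {missing[:5]}")
        scores = scores.loc[profiles.subject_ids]
        self.profiles = profiles
        self.outcome = outcome
        self.y = scores[outcome].to_numpy(dtype=float)
        self.families = scores["family_id"].to_numpy()
        self.lambda_grid = tuple(float(l) for l in lambda_grid)
        if not self.lambda_grid:
            raise ValueError("empty lambda grid")
        self.feature_p_threshold = feature_p_threshold

    @classmethod
    def from_frames(
        cls, profile_frame: pd.DataFrame, scores: pd.DataFrame, **kwargs
    ) -> "CognitiveAbilityRidge":
        from .data import profiles_from_frame

        return cls(profiles_from_frame(profile_frame), scores, **kwargs)

    def fit(
        self,
        n_bootstrap: int = 1000,
        seed: int | np.random.Generator | None = None,
    ) -> PredictionResult:
        X = self.profiles.values
        y = self.y
        n, p = X.shape
        fold_ids = pd.unique(self.families)
        if len(fold_ids) < 2:
            raise DataError(
                "LOFOV needs at least two families (one family would leave "
                "no training data)"
            )
        grid = self.lambda_grid
        preds = np.zeros((len(grid), n))
        weight_sums = np.zeros((len(grid), p))
        for fam in fold_ids:
            test = self.families == fam
            train = ~test
            Xtr, ytr = X[train], y[train]
            keep = np.ones(p, dtype=bool)
            if self.feature_p_threshold is not None:
                keep = _screen_features(Xtr, ytr, self.feature_p_threshold)
                if not keep.any():
                    raise DataError(
                        "feature screening removed every predictor in a "
                        "training fold; raise feature_p_threshold"
                    )
            mu = Xtr[:, keep].mean(axis=0)
            sd = Xtr[:, keep].std(axis=0)
            dead = sd == 0
            if dead.any():
                warnings.warn(
                    f"{int(dead.sum())} zero-variance predictor(s) in a "
                    "training fold; their z-scores are set to 0",
                    stacklevel=2,
                )
                sd = np.where(dead, 1.0, sd)
            ztr = (Xtr[:, keep] - mu) / sd
            ztr[:, dead] = 0.0
            y_mu, y_sd = ytr.mean(), ytr.std()
            if y_sd == 0:
                raise DataError("outcome constant within a training fold")
            yz = (ytr - y_mu) / y_sd
            # one eigendecomposition serves the whole lambda grid
            G = ztr.T @ ztr
            eigval, U = np.linalg.eigh(G)
            Uty = U.T @ (ztr.T @ yz)
            zte = (X[test][:, keep] - mu) / sd
            zte[:, dead] = 0.0
            for gi, lam in enumerate(grid):
                b = U @ (Uty / (eigval + lam))
                preds[gi, test] = y_mu + y_sd * (zte @ b)
                weight_sums[gi, keep] += np.abs(b)
        grid_r = np.array(
            [np.corrcoef(y, preds[gi])[0, 1] for gi in range(len(grid))]
        )
        best = int(np.nanargmax(grid_r))
        r_raw = float(grid_r[best])
        predicted = preds[best]
        p_value = float(_t_based_p(np.array([r_raw]), n)[0])
        ci = None
        if n_bootstrap:
            rng = np.random.default_rng(seed)
            ci = bootstrap_ci(
                lambda o, pr: np.corrcoef(o, pr)[0, 1],
                (y, predicted),
                n_boot=n_bootstrap,
                seed=rng,
            )
        return PredictionResult(
            outcome=self.outcome,
            predicted=predicted,
            observed=y.copy(),
            accuracy_r=max(r_raw, 0.0),
            r_raw=r_raw,
            p_value=p_value,
            ci95=ci,
            lambda_selected=grid[best],
            lambda_grid=grid,
            grid_r=grid_r,
            mean_abs_weight=weight_sums[best] / len(fold_ids),
            predictor_ids=list(self.profiles.roi_ids),
            n_folds=len(fold_ids),
        )


def per_network_prediction(
    profiles: EntropyProfiles,
    scores: pd.DataFrame,
    parcellation: pd.DataFrame,
    outcomes=("g", "vis", "cry", "mem", "spd"),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    include_whole_cortex: bool = True,
    fdr_q: float = 0.05,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One LOFOV ridge prediction per resting-state network and outcome,
    with Benjamini-Hochberg correction across the whole family of tests.

    Networks with fewer than 2 retained ROIs are skipped with a warning
    (the limbic network is typically depleted by the reliability screen).
    Returns ``(table, results)`` where ``table`` has one row per
    network x outcome and ``results`` maps (network, outcome) to the full
    :class:`PredictionResult`.
    """
    rng = np.random.default_rng(seed)
    net_of = parcellation.set_index("roi_id")["network"]
    roi_nets = np.asarray([net_of[r] for r in profiles.roi_ids])
    networks = list(pd.unique(parcellation["network"]))
    groups: list[tuple[str, np.ndarray]] = []
    if include_whole_cortex:
        groups.append(("ALL", np.ones(profiles.n_rois, dtype=bool)))
    for net in networks:
        mask = roi_nets == net
        if mask.sum() < 2:
            warnings.warn(
                f"network {net}: fewer than 2 retained ROIs; skipped",
                stacklevel=2,
            )
            continue
        groups.append((net, mask))
    rows = []
    results = {}
    for net, mask in groups:
        sub = profiles.select_rois(mask)
        for outcome in outcomes:
            model = CognitiveAbilityRidge(
                sub, scores, outcome=outcome, lambda_grid=lambda_grid
            )
            res = model.fit(n_bootstrap=n_bootstrap, seed=rng)
            results[(net, outcome)] = res
            rows.append(
                {
                    "network": net,
                    "outcome": outcome,
                    "n_rois": int(mask.sum()),
                    "accuracy_r": res.accuracy_r,
                    "r_raw": res.r_raw,
                    "p": res.p_value,
                    "lambda": res.lambda_selected,
                }
            )
    table = pd.DataFrame(rows)
    p_adj, reject = bh_fdr(table["p"].to_numpy(), q=fdr_q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return table, results
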