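"""Surrogate regression of depth sensitivity over (SDS, depth).

The Monte Carlo pipeline produces a gridded calibration dataset: cross-head
mean SAD (%) at source-detector separations 19-39 mm (step 2) and depths
10-20 mm (step 1), 121 rows in total.  Two surrogates of the response
surface SAD(SDS, depth) are supported:

* Gaussian process regression with a squared-exponential (RBF) kernel plus
  a white-noise term; hyperparameters (signal variance, per-dimension
  length-scales, noise variance) maximise the log marginal likelihood with
  multi-restart optimisation under a fixed seed.  The posterior supplies
  predictive standard deviations.
* Support vector regression with an RBF kernel; the kernel scale follows
  the median pairwise-distance heuristic, the box constraint is
  IQR(y)/1.349 and the epsilon tube IQR(y)/13.49 (fixed data-driven
  heuristics on the standardized response).

Inputs and the response are z-score standardized before fitting; all
predictions are returned on the original percentage scale.

Usage follows the fitted-model idiom::

    model = DepthSensitivityModel.from_profiles(mean_profiles)
    res = model.fit(kind="gpr", seed=0)
    res.summary()
    res.predict(sds=29.0, depth=14.8, return_std=True)
    res.sds_for_depth(14.8)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.svm import SVR

__all__ = [
    "CalibrationDataset",
    "DepthSensitivityModel",
    "DepthSensitivityResults",
    "LoocvResult",
    "assemble_dataset",
    "fit_gpr",
    "fit_svr",
    "loocv",
    "adjusted_r2",
]

SDS_GRID = tuple(range(19, 40, 2))  # mm
DEPTH_GRID = tuple(range(10, 21))  # mm
SDS_RANGE = (19.0, 39.0)
DEPTH_RANGE = (10.0, 20.0)


def adjusted_r2(y, y_hat, p: int = 2) -> float:
    """Coefficient of determination penalised for ``p`` predictors.

    1 - (1 - R^2) (n - 1) / (n - p - 1).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 (n={n}, p={p})")
    sse = float(((y - y_hat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant response: R^2 undefined")
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class CalibrationDataset:
    """Rows of (sds, depth, sad) plus z-score standardization constants."""

    sds: np.ndarray
    depth: np.ndarray
    sad: np.ndarray
    x_mean: np.ndarray = None
    x_scale: np.ndarray = None
    y_mean: float = None
    y_scale: float = None

    def __post_init__(self):
        self.sds = np.asarray(self.sds, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.sad = np.asarray(self.sad, dtype=float)
        if not (self.sds.shape == self.depth.shape == self.sad.shape):
            raise ValueError("sds, depth and sad must have equal length")
        X = np.column_stack([self.sds, self.depth])
        if self.x_mean is None:
            self.x_mean = X.mean(axis=0)
            self.x_scale = X.std(axis=0, ddof=0)
            if np.any(self.x_scale == 0):
                raise ValueError("degenerate input column (zero variance)")
            self.y_mean = float(self.sad.mean())
            self.y_scale = float(self.sad.std(ddof=0))
            if self.y_scale == 0:
                raise ValueError("degenerate response (zero variance)")

    def __len__(self) -> int:
        return self.sds.size

    # --- standardization round-trip -------------------------------------
    def standardize_x(self, sds, depth) -> np.ndarray:
        X = np.column_stack([np.atleast_1d(sds).astype(float), np.atleast_1d(depth).astype(float)])
        return (X - self.x_mean) / self.x_scale

    def standardize_y(self, sad) -> np.ndarray:
        return (np.asarray(sad, dtype=float) - self.y_mean) / self.y_scale

    def destandardize_y(self, y_std) -> np.ndarray:
        return np.asarray(y_std, dtype=float) * self.y_scale + self.y_mean

    @property
    def X_std(self) -> np.ndarray:
        return self.standardize_x(self.sds, self.depth)

    @property
    def y_std(self) -> np.ndarray:
        return self.standardize_y(self.sad)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sds_mm": self.sds, "depth_mm": self.depth, "sad_pct": self.sad})

    def subset(self, mask: np.ndarray) -> "CalibrationDataset":
        """Row subset sharing this dataset's standardization constants."""
        ds = CalibrationDataset(
            self.sds[mask], self.depth[mask], self.sad[mask],
            x_mean=self.x_mean, x_scale=self.x_scale,
            y_mean=self.y_mean, y_scale=self.y_scale,
        )
        return ds


def assemble_dataset(
    mean_profiles,
    sds_values=SDS_GRID,
    depth_range=DEPTH_RANGE,
) -> CalibrationDataset:
    """Build the calibration dataset from per-SDS mean SAD profiles.

    ``mean_profiles`` maps SDS (mm) to a mean :class:`~nirscalib.sad.SADProfile`
    (or is an iterable of profiles carrying their own SDS).  Every SDS in
    ``sds_values`` must be present; depths outside ``depth_range`` are
    discarded.
    """
    if not isinstance(mean_profiles, dict):
        mean_profiles = {p.sds: p for p in mean_profiles}
    missing = [s for s in sds_values if float(s) not in {float(k) for k in mean_profiles}]
    if missing:
        raise ValueError(f"missing mean SAD profiles for SDS values {missing}")
    lo, hi = depth_range
    depths = np.array([d for d in range(int(np.ceil(lo)), int(np.floor(hi)) + 1)], dtype=float)
    rows_sds, rows_depth, rows_sad = [], [], []
    lookup = {float(k): v for k, v in mean_profiles.items()}
    for s in sds_values:
        prof = lookup[float(s)]
        for d in depths:
            rows_sds.append(float(s))
            rows_depth.append(d)
            rows_sad.append(float(prof.sad[int(d)]))
    return CalibrationDataset(np.array(rows_sds), np.array(rows_depth), np.array(rows_sad))


# --- estimators ----------------------------------------------------------


def _build_gpr(seed: int, n_restarts: int, fixed_kernel=None) -> GaussianProcessRegressor:
    if fixed_kernel is None:
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e2))
            + WhiteKernel(noise_level=1e-5, noise_level_bounds=(1e-12, 1e0))
        )
        return GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-8,  # jitter on the standardized scale, keeps Cholesky stable
            n_restarts_optimizer=n_restarts,
            normalize_y=False,
            random_state=seed,
        )
    return GaussianProcessRegressor(
        kernel=fixed_kernel, alpha=1e-8, optimizer=None, normalize_y=False, random_state=seed
    )


def _build_svr(X_std: np.ndarray, y_std: np.ndarray) -> SVR:
    q1, q3 = np.percentile(y_std, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("degenerate response (zero IQR): SVR heuristics undefined")
    dists = pdist(X_std)
    scale = float(np.median(dists[dists > 0]))
    return SVR(kernel="rbf", gamma=1.0 / (2.0 * scale * scale), C=iqr / 1.349, epsilon=iqr / 13.49)


def fit_gpr(dataset: CalibrationDataset, seed: int = 0, n_restarts: int = 5) -> "DepthSensitivityResults":
    """Fit the GPR surrogate (squared-exponential + white noise, MLE)."""
    return DepthSensitivityModel(dataset).fit(kind="gpr", seed=seed, n_restarts=n_restarts)


def fit_svr(dataset: CalibrationDataset) -> "DepthSensitivityResults":
    """Fit the SVR surrogate (RBF kernel, fixed data-driven heuristics)."""
    return DepthSensitivityModel(dataset).fit(kind="svr")


class DepthSensitivityModel:
    """SAD(SDS, depth) surrogate specification bound to a calibration dataset."""

    def __init__(self, dataset: CalibrationDataset):
        if len(dataset) < 10:
            raise ValueError(f"need >= 10 rows to fit a surrogate, got {len(dataset)}")
        self.dataset = dataset

    @classmethod
    def from_profiles(cls, mean_profiles, **kwargs) -> "DepthSensitivityModel":
        return cls(assemble_dataset(mean_profiles, **kwargs))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DepthSensitivityModel":
        required = {"sds_mm", "depth_mm", "sad_pct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataframe missing columns: {sorted(missing)}")
        return cls(CalibrationDataset(df["sds_mm"], df["depth_mm"], df["sad_pct"]))

    def fit(self, kind: str = "gpr", seed: int = 0, n_restarts: int = 5) -> "DepthSensitivityResults":
        ds = self.dataset
        if kind == "gpr":
            est = _build_gpr(seed, n_restarts)
            est.fit(ds.X_std, ds.y_std)
        elif kind == "svr":
            est = _build_svr(ds.X_std, ds.y_std)
            est.fit(ds.X_std, ds.y_std)
        else:
            raise ValueError(f"unknown surrogate kind {kind!r}; use 'gpr' or 'svr'")
        return DepthSensitivityResults(self, kind, est, seed=seed)


class DepthSensitivityResults:
    """Fitted surrogate with predictions, diagnostics and inversion."""

    def __init__(self, model: DepthSensitivityModel, kind: str, estimator, seed: int = 0):
        self.model = model
        self.dataset = model.dataset
        self.kind = kind
        self.estimator = estimator
        self.seed = seed
        yhat = self.predict(self.dataset.sds, self.dataset.depth)
        self.r2_train = 1.0 - float(((self.dataset.sad - yhat) ** 2).sum()) / float(
            ((self.dataset.sad - self.dataset.sad.mean()) ** 2).sum()
        )
        self.adj_r2_train = adjusted_r2(self.dataset.sad, yhat, p=2)

    # --- prediction ------------------------------------------------------
    def predict(self, sds, depth, return_std: bool = False):
        """Predicted SAD (%) at (sds, depth); optionally the posterior std.

        Scalar inputs give scalar output.  ``return_std`` is only available
        for the GPR surrogate.
        """
        scalar = np.isscalar(sds) and np.isscalar(depth)
        X = self.dataset.standardize_x(sds, depth)
        if return_std:
            if self.kind != "gpr":
                raise ValueError("predictive uncertainty is only available for the GPR surrogate")
            mu, sd = self.estimator.predict(X, return_std=True)
            mu = self.dataset.destandardize_y(mu)
            sd = sd * self.dataset.y_scale
            return (float(mu[0]), float(sd[0])) if scalar else (mu, sd)
        mu = self.dataset.destandardize_y(self.estimator.predict(X))
        return float(mu[0]) if scalar else mu

    # --- diagnostics -----------------------------------------------------
    def loocv(self, n_restarts: int = 3) -> "LoocvResult":
        return loocv(self.dataset, self.kind, seed=self.seed, n_restarts=n_restarts)

    def hyperparameters(self) -> dict:
        if self.kind == "gpr":
            k = self.estimator.kernel_
            prod, white = k.k1, k.k2
            return {
                "signal_variance": float(prod.k1.constant_value),
                "length_scales_std": [float(v) for v in np.atleast_1d(prod.k2.length_scale)],
                "noise_variance": float(white.noise_level),
                "log_marginal_likelihood": float(self.estimator.log_marginal_likelihood_value_),
            }
        return {
            "C": float(self.estimator.C),
            "epsilon": float(self.estimator.epsilon),
            "gamma": float(self.estimator.gamma),
            "n_support": int(self.estimator.support_.size),
        }

    def summary(self) -> str:
        ds = self.dataset
        lines = [
            "Depth-sensitivity surrogate results",
            "=" * 51,
            f"{'surrogate':<28}{self.kind.upper():>23}",
            f"{'n observations':<28}{len(ds):>23d}",
            f"{'SDS range (mm)':<28}{f'{ds.sds.min():g} - {ds.sds.max():g}':>23}",
            f"{'depth range (mm)':<28}{f'{ds.depth.min():g} - {ds.depth.max():g}':>23}",
            f"{'R^2 (train)':<28}{self.r2_train:>23.6f}",
            f"{'adjusted R^2 (train, p=2)':<28}{self.adj_r2_train:>23.6f}",
            "-" * 51,
        ]
        for name, val in self.hyperparameters().items():
            if isinstance(val, list):
                val = ", ".join(f"{v:.4g}" for v in val)
                lines.append(f"{name:<28}{val:>23}")
            elif isinstance(val, int):
                lines.append(f"{name:<28}{val:>23d}")
            else:
                lines.append(f"{name:<28}{val:>23.6g}")
        lines.append("=" * 51)
        return "\n".join(lines)

    # --- inversion (delegates to the calibration engine) ------------------
    def sds_for_depth(self, depth: float, levels=None):
        from .calibrate import sds_for_depth

        return sds_for_depth(self, depth, levels=levels)

    def depth_for_sds(self, sds: float, levels=None):
        from .calibrate import depth_for_sds

        return depth_for_sds(self, sds, levels=levels)

    def feasibility(self, depth: float, level: float) -> bool:
        from .calibrate import feasibility

        return feasibility(self, depth, level)

    # --- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        """Persist kind, hyperparameters, standardization and training data."""
        ds = self.dataset
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "standardization": {
                "x_mean": ds.x_mean.tolist(),
                "x_scale": ds.x_scale.tolist(),
                "y_mean": ds.y_mean,
                "y_scale": ds.y_scale,
            },
            "hyperparameters": self.hyperparameters(),
            "training": {
                "sds_mm": ds.sds.tolist(),
                "depth_mm": ds.depth.tolist(),
                "sad_pct": ds.sad.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DepthSensitivityResults":
        """Rebuild a fitted surrogate from :meth:`to_json` output.

        The estimator is refit on the stored training matrix with the stored
        hyperparameters held fixed, reproducing the persisted predictions.
        """
        with open(path) as fh:
            payload = json.load(fh)
        std = payload["standardization"]
        tr = payload["training"]
        ds = CalibrationDataset(
            np.array(tr["sds_mm"]), np.array(tr["depth_mm"]), np.array(tr["sad_pct"]),
            x_mean=np.array(std["x_mean"]), x_scale=np.array(std["x_scale"]),
            y_mean=std["y_mean"], y_scale=std["y_scale"],
        )
        model = DepthSensitivityModel(ds)
        hp = payload["hyperparameters"]
        kind = payload["kind"]
        if kind == "gpr":
            kernel = ConstantKernel(hp["signal_variance"], "fixed") * RBF(
                hp["length_scales_std"], "fixed"
            ) + WhiteKernel(hp["noise_variance"], "fixed")
            est = _build_gpr(payload["seed"], 0, fixed_kernel=kernel)
        else:
            est = SVR(kernel="rbf", gamma=hp["gamma"], C=hp["C"], epsilon=hp["epsilon"])
        est.fit(ds.X_std, ds.y_std)
        return cls(model, kind, est, seed=payload["seed"])


@dataclass
class LoocvResult:
    """Held-out predictions and aggregate score from leave-one-out CV."""

    y_true: np.ndarray
    y_pred: np.ndarray
    adj_r2: float
    kind: str


def loocv(dataset: CalibrationDataset, kind: str = "gpr", seed: int = 0, n_restarts: int = 3) -> LoocvResult:
    """Leave-one-out cross-validation with per-fold refitting.

    Each fold refits the surrogate (including its hyperparameter procedure)
    on n-1 rows and predicts the held-out row; the aggregate score is the
    adjusted R^2 of the pooled held-out predictions (the plain R^2 when n is
    too small for the p=2 penalty to be defined).  GPR folds keep several
    optimizer restarts: with a single start an occasional fold lands in a
    degenerate hyperparameter optimum and predicts the training mean.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError(f"LOOCV needs n >= 3, got {n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold = dataset.subset(mask)
        try:
            if kind == "gpr":
                est = _build_gpr(seed, n_restarts)
            else:
                est = _build_svr(fold.X_std, fold.y_std)
            est.fit(fold.X_std, fold.y_std)
            Xi = dataset.standardize_x(dataset.sds[i], dataset.depth[i])
            preds[i] = dataset.destandardize_y(est.predict(Xi))[0]
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"LOOCV fold {i} failed: {exc}") from exc
    if n > 3:
        score = adjusted_r2(dataset.sad, preds, p=2)
    else:
        sse = float(((dataset.sad - preds) ** 2).sum())
        sst = float(((dataset.sad - dataset.sad.mean()) ** 2).sum())
        score = 1.0 - sse / sst
    return LoocvResult(y_true=dataset.sad.copy(), y_pred=preds, adj_r2=score, kind=kind)
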