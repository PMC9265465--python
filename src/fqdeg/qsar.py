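"""PLS regression and the validation statistics used for 3D-QSAR models.

The model relates a high-dimensional descriptor block X (typically molecular
field energies) to a biodegradability value y by PLS1 (NIPALS), then grades
the model with the conventional QSAR battery:

* leave-one-out cross-validated determination coefficient
  ``q2 = 1 - PRESS / SS`` (internal predictivity),
* training determination coefficient ``r2`` (fitting ability),
* overfit index ``(r2 - q2) / r2`` (should stay below 30%),
* external predictive coefficient
  ``r2_pred = 1 - sum (y - yhat)^2 / sum (y - ybar)^2`` on a held-out test
  set, with the reference mean taken from the training set by default.

Acceptance thresholds follow common 3D-QSAR practice: q2 > 0.5, r2 > 0.8,
overfit < 30%, r2_pred > 0.6, all strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PlsModel",
    "QsarDataset",
    "QsarModel",
    "QsarReport",
    "fit_pls",
    "loo_q2",
    "select_components",
    "r2pred",
    "overfit_index",
    "build_report",
]

_RANK_TOL = 1e-12


@dataclass(frozen=True)
class PlsModel:
    """Fitted PLS1 model (NIPALS, column-centred, unscaled by default)."""

    n_components: int            # components actually extracted
    n_requested: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray          # ones unless block scaling requested
    weights: np.ndarray          # (p, a) orthonormal weight vectors
    loadings: np.ndarray         # (p, a) X loadings
    y_loadings: np.ndarray       # (a,)
    coef: np.ndarray             # (p,) regression vector in original X units

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + ((X - self.x_mean) / self.x_scale) @ self.coef


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            scale: bool = False) -> PlsModel:
    """Fit PLS1 by NIPALS.

    Extraction stops early (without error) if the residual X block is
    numerically rank deficient; the actual component count is recorded on
    the returned model.  The fit is fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    s, p = X.shape
    if y.shape[0] != s:
        raise ValueError("X and y have different numbers of samples")
    if not 1 <= n_components <= min(s - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(s-1, p)={min(s - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    E = (X - x_mean) / x_scale
    f = y - y_mean

    scale0 = max(np.abs(E).max(), 1.0)
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = E.T @ f
        wn = np.linalg.norm(w)
        if wn <= _RANK_TOL * scale0:
            break
        w = w / wn
        t = E @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            break
        pvec = E.T @ t / tt
        q = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - q * t
        W.append(w)
        P.append(pvec)
        Q.append(q)

    if not W:
        raise ValueError("no PLS component could be extracted (X'y is zero)")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Qv = np.asarray(Q)
    # coefficients: b = W (P'W)^-1 q
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, Qv)
    return PlsModel(
        n_components=len(W), n_requested=n_components,
        x_mean=x_mean, y_mean=y_mean, x_scale=x_scale,
        weights=Wm, loadings=Pm, y_loadings=Qv, coef=coef,
    )


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           scale: bool = False) -> float:
    """Leave-one-out ``q2 = 1 - PRESS / sum (y_i - ybar)^2``.

    The denominator uses the mean of the *full* training response, held
    fixed across folds.  The value can be negative when prediction is worse
    than the mean; it never exceeds 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    s = y.size
    if s < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    ss = float(((y - y.mean()) ** 2).sum())
    if ss <= 0:
        raise ValueError("constant response: q2 denominator is zero")
    press = 0.0
    idx = np.arange(s)
    for i in range(s):
        keep = idx != i
        ncomp = min(n_components, s - 2, X.shape[1])
        model = fit_pls(X[keep], y[keep], ncomp, scale=scale)
        press += float((y[i] - model.predict(X[i:i + 1])[0]) ** 2)
    return 1.0 - press / ss


def select_components(X: np.ndarray, y: np.ndarray, max_n: int,
                      scale: bool = False) -> tuple[int, float]:
    """Pick the component count maximising LOO q2 over ``1..max_n``.

    Ties (within 1e-12) resolve toward the smaller count.  ``max_n`` is
    capped at ``min(s_train - 2, p, 10)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    cap = min(max_n, X.shape[0] - 2, X.shape[1], 10)
    cap = max(cap, 1)
    best_n, best_q2 = 1, -np.inf
    for n in range(1, cap + 1):
        q2 = loo_q2(X, y, n, scale=scale)
        if q2 > best_q2 + 1e-12:
            best_n, best_q2 = n, q2
    return best_n, best_q2


def r2pred(y_test: np.ndarray, y_hat: np.ndarray, reference_mean: float) -> float:
    """External predictive coefficient against a fixed reference mean."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("empty test set")
    denom = float(((y_test - reference_mean) ** 2).sum())
    if denom <= 0:
        raise ValueError("zero denominator: test responses all equal the reference mean")
    return 1.0 - float(((y_test - y_hat) ** 2).sum()) / denom


def overfit_index(r2: float, q2: float) -> float:
    """Relative optimism ``(r2 - q2) / r2``; requires r2 > 0."""
    if r2 <= 0:
        raise ValueError("overfit index undefined for r2 <= 0")
    return (r2 - q2) / r2


@dataclass(frozen=True)
class QsarDataset:
    """Descriptor matrix plus activities, split into train/test roles."""

    sample_ids: tuple
    X: np.ndarray
    y: np.ndarray
    role: tuple  # 'train' or 'test' per sample

    def __init__(self, sample_ids, X, y, role=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if X.shape[0] != n or len(sample_ids) != n:
            raise ValueError("sample_ids, X and y must agree in length")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("descriptors and activities must be finite")
        if role is None:
            role = ["train"] * n
        role = tuple(role)
        if any(r not in ("train", "test") for r in role):
            raise ValueError("role entries must be 'train' or 'test'")
        if sum(r == "train" for r in role) < 3:
            raise ValueError("need at least 3 training samples")
        object.__setattr__(self, "sample_ids", tuple(sample_ids))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "role", role)

    @property
    def train_mask(self) -> np.ndarray:
        return np.array([r == "train" for r in self.role])

    @classmethod
    def from_csv(cls, descriptors_path, activities_path) -> "QsarDataset":
        """Read `sample,d1..dp` descriptors and `sample,activity,role` activities."""
        Xdf = pd.read_csv(descriptors_path)
        adf = pd.read_csv(activities_path)
        merged = adf.merge(Xdf, on="sample", validate="one_to_one")
        dcols = [c for c in Xdf.columns if c != "sample"]
        role = merged["role"] if "role" in merged else None
        return cls(merged["sample"].tolist(), merged[dcols].to_numpy(float),
                   merged["activity"].to_numpy(float),
                   role=None if role is None else role.tolist())


@dataclass(frozen=True)
class QsarReport:
    """Validation battery for one fitted QSAR model."""

    n_opt: int
    q2: float
    r2: float
    overfit: float
    r2pred: Optional[float]
    ref_mean_convention: str
    q2_ok: bool = field(init=False)
    r2_ok: bool = field(init=False)
    overfit_ok: bool = field(init=False)
    r2pred_ok: Optional[bool] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "q2_ok", self.q2 > 0.5)
        object.__setattr__(self, "r2_ok", self.r2 > 0.8)
        object.__setattr__(self, "overfit_ok", self.overfit < 0.30)
        object.__setattr__(self, "r2pred_ok",
                           None if self.r2pred is None else self.r2pred > 0.6)

    @property
    def all_ok(self) -> bool:
        flags = [self.q2_ok, self.r2_ok, self.overfit_ok]
        if self.r2pred_ok is not None:
            flags.append(self.r2pred_ok)
        return all(flags)

    def to_dict(self) -> dict:
        return {
            "n_opt": self.n_opt, "q2": self.q2, "r2": self.r2,
            "overfit": self.overfit, "r2pred": self.r2pred,
            "ref_mean": self.ref_mean_convention,
            "q2_ok": self.q2_ok, "r2_ok": self.r2_ok,
            "overfit_ok": self.overfit_ok, "r2pred_ok": self.r2pred_ok,
        }

    def summary(self) -> str:
        def flag(ok):
            return "-" if ok is None else ("pass" if ok else "FAIL")

        rows = [
            ("optimal components n", f"{self.n_opt}", ""),
            ("LOO q2 (> 0.5)", f"{self.q2:.4f}", flag(self.q2_ok)),
            ("training r2 (> 0.8)", f"{self.r2:.4f}", flag(self.r2_ok)),
            ("(r2-q2)/r2 (< 30%)", f"{100 * self.overfit:.2f}%", flag(self.overfit_ok)),
            ("external r2_pred (> 0.6)",
             "-" if self.r2pred is None else f"{self.r2pred:.4f}",
             flag(self.r2pred_ok)),
        ]
        width = max(len(r[0]) for r in rows)
        out = ["QSAR validation report", "=" * 40]
        out += [f"{name:<{width}}  {val:>10}  {ok}" for name, val, ok in rows]
        out.append(f"reference mean for r2_pred: {self.ref_mean_convention}")
        return "\n".join(out)


class QsarModel:
    """PLS QSAR model with the full internal/external validation battery.

    Parameters
    ----------
    dataset : QsarDataset
        Samples labelled 'train' are used for fitting and leave-one-out
        cross-validation; 'test' samples only enter the external r2_pred.
    max_components : int
        Upper bound for the LOO component scan (further capped at
        ``min(s_train - 2, p, 10)``).
    ref_mean : {'train', 'test'}
        Which set's mean anchors the r2_pred denominator.
    scale_blocks : bool
        Optional unit-variance scaling of descriptor columns.
    """

    def __init__(self, dataset: QsarDataset, max_components: int = 10,
                 ref_mean: Literal["train", "test"] = "train",
                 scale_blocks: bool = False):
        if ref_mean not in ("train", "test"):
            raise ValueError("ref_mean must be 'train' or 'test'")
        self.dataset = dataset
        self.max_components = max_components
        self.ref_mean = ref_mean
        self.scale_blocks = scale_blocks

    def fit(self) -> "QsarResults":
        ds = self.dataset
        train = ds.train_mask
        Xtr, ytr = ds.X[train], ds.y[train]
        n_opt, q2 = select_components(Xtr, ytr, self.max_components,
                                      scale=self.scale_blocks)
        model = fit_pls(Xtr, ytr, n_opt, scale=self.scale_blocks)
        yfit = model.predict(Xtr)
        ss = float(((ytr - ytr.mean()) ** 2).sum())
        r2 = 1.0 - float(((ytr - yfit) ** 2).sum()) / ss
        ofi = overfit_index(r2, q2)

        r2p = None
        test = ~train
        if test.any():
            ref = float(ytr.mean()) if self.ref_mean == "train" else float(ds.y[test].mean())
            r2p = r2pred(ds.y[test], model.predict(ds.X[test]), ref)
        report = QsarReport(n_opt=n_opt, q2=q2, r2=r2, overfit=ofi,
                            r2pred=r2p, ref_mean_convention=self.ref_mean)
        return QsarResults(model=model, report=report, dataset=ds,
                           fitted_train=yfit)


@dataclass(frozen=True)
class QsarResults:
    """Fitted PLS model plus its validation report and LOO predictions."""

    model: PlsModel
    report: QsarReport
    dataset: QsarDataset
    fitted_train: np.ndarray

    def loo_predictions(self) -> pd.DataFrame:
        """Per-sample leave-one-out predictions on the training set."""
        ds = self.dataset
        train = ds.train_mask
        X, y = ds.X[train], ds.y[train]
        ids = [s for s, keep in zip(ds.sample_ids, train) if keep]
        preds = []
        idx = np.arange(y.size)
        for i in range(y.size):
            keep = idx != i
            ncomp = min(self.report.n_opt, y.size - 2, X.shape[1])
            m = fit_pls(X[keep], y[keep], ncomp)
            preds.append(float(m.predict(X[i:i + 1])[0]))
        return pd.DataFrame({"sample": ids, "observed": y, "loo_predicted": preds})

    def summary(self) -> str:
        return self.report.summary()


def build_report(dataset: QsarDataset, max_n: int = 10,
                 ref_mean: str = "train", scale_blocks: bool = False) -> QsarReport:
    """One-call report construction (Model/Results wrapper)."""
    return QsarModel(dataset, max_components=max_n, ref_mean=ref_mean,
                     scale_blocks=scale_blocks).fit().report
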