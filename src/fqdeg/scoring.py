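"""Entropy-weighted composite biodegradability scoring.

A compounds x receptors matrix of docking scores is converted into a single
composite biodegradability value per compound in three steps:

1. Each receptor column is turned into a discrete distribution over compounds
   (each score divided by the column sum) and its Shannon entropy, normalised
   by ``ln m``, is computed.  A receptor whose scores are nearly uniform
   across compounds carries little discriminating information and receives a
   small *entropy weight* ``w_j = (1 - e_j) / sum_k (1 - e_k)``.
2. Each column is rescaled affinely onto a fixed grading scale (1 to 9 by
   default), anchoring the column minimum at the low end and the maximum at
   the high end.
3. The composite value of compound *i* is the weight-averaged rescaled score
   ``b_i = sum_j w_j a_ij``.

The composite value is bounded by the grading scale and is monotone in every
raw score, so it behaves as a well-posed multi-criteria ranking index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "CompositeResult",
    "CompositeScoreModel",
    "compute_proportions",
    "compute_entropy",
    "compute_weights",
    "normalize_column",
    "composite_scores",
]


class ScoreValidationError(ValueError):
    """Raised when a score matrix violates the positivity/shape contract."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Compounds x receptors docking-score table.

    Parameters
    ----------
    compound_ids : sequence of str
        Row labels (one per compound), order preserved.
    receptor_ids : sequence of str
        Column labels (one per receptor protein).
    values : (m, n) array_like
        Strictly positive, finite docking scores.  Higher means stronger
        predicted ligand-receptor interaction, i.e. easier enzymatic
        degradation.
    """

    compound_ids: tuple
    receptor_ids: tuple
    values: np.ndarray

    def __init__(self, compound_ids, receptor_ids, values):
        object.__setattr__(self, "compound_ids", tuple(compound_ids))
        object.__setattr__(self, "receptor_ids", tuple(receptor_ids))
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ScoreValidationError("values must be a 2-D matrix")
        object.__setattr__(self, "values", arr)
        self._validate()

    def _validate(self) -> None:
        m, n = self.values.shape
        if len(self.compound_ids) != m or len(self.receptor_ids) != n:
            raise ScoreValidationError(
                f"label/shape mismatch: {len(self.compound_ids)} compounds, "
                f"{len(self.receptor_ids)} receptors, matrix {m}x{n}"
            )
        if m < 2:
            raise ScoreValidationError("need at least 2 compounds (ln m = 0 for m = 1)")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ScoreValidationError(
                f"non-finite score at compound {self.compound_ids[i]!r}, "
                f"receptor {self.receptor_ids[j]!r}"
            )
        nonpos = self.values <= 0
        if nonpos.any():
            i, j = np.argwhere(nonpos)[0]
            raise ScoreValidationError(
                f"non-positive score {self.values[i, j]} at compound "
                f"{self.compound_ids[i]!r}, receptor {self.receptor_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, compound_col: str = "compound") -> "ScoreMatrix":
        """Build from a tidy frame with one label column and receptor columns."""
        receptors = [c for c in df.columns if c != compound_col]
        return cls(df[compound_col].astype(str).tolist(), receptors,
                   df[receptors].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path, compound_col: str = "compound") -> "ScoreMatrix":
        return cls.from_dataframe(pd.read_csv(path), compound_col=compound_col)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.receptor_ids))
        df.insert(0, "compound", list(self.compound_ids))
        return df


def compute_proportions(scores: ScoreMatrix) -> np.ndarray:
    """Per-receptor proportions ``P_ij = v_ij / sum_i v_ij``.

    Each receptor column becomes a discrete probability distribution over
    compounds; every entry stays strictly positive.
    """
    v = scores.values
    return v / v.sum(axis=0, keepdims=True)


def compute_entropy(proportions: np.ndarray, m: int | None = None) -> float:
    """Normalised Shannon entropy of one proportion column.

    ``e = -(1/ln m) * sum_i p_i ln p_i`` with the convention ``0*ln 0 = 0``.
    A uniform column gives 1, a one-hot column gives 0.
    """
    p = np.asarray(proportions, dtype=float)
    if m is None:
        m = p.size
    if m < 2:
        raise ValueError("entropy normalisation needs m >= 2 (ln m = 0 otherwise)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / np.log(m))


def compute_weights(entropies: Sequence[float]) -> np.ndarray:
    """Entropy weights ``w_j = (1 - e_j) / sum_k (1 - e_k)``."""
    e = np.asarray(entropies, dtype=float)
    if np.any((e < -1e-12) | (e > 1 + 1e-12)):
        raise ValueError("entropies must lie in [0, 1]")
    diff = 1.0 - e
    total = diff.sum()
    if total <= 0:
        raise ValueError("all entropies equal 1: weights undefined")
    return diff / total


def normalize_column(column: np.ndarray, low: float = 1.0, high: float = 9.0,
                     name: str | None = None) -> np.ndarray:
    """Affine range rescaling: column min -> ``low``, max -> ``high``."""
    v = np.asarray(column, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax <= vmin:
        label = f" for receptor {name!r}" if name else ""
        raise ValueError(f"constant column{label}: range normalisation undefined")
    return low + (v - vmin) * (high - low) / (vmax - vmin)


@dataclass(frozen=True)
class CompositeResult:
    """All intermediates of the composite-scoring pipeline, kept for audit.

    Attributes
    ----------
    weights : (n,) ndarray
        Entropy weights, summing to 1.
    entropies : (n,) ndarray
        Normalised column entropies in [0, 1].
    proportions : (m, n) ndarray
        Column-stochastic proportion matrix.
    normalized : (m, n) ndarray
        Range-rescaled scores on [scale_low, scale_high].
    composite : (m,) ndarray
        Weighted composite biodegradability values.
    """

    scores: ScoreMatrix
    weights: np.ndarray
    entropies: np.ndarray
    proportions: np.ndarray
    normalized: np.ndarray
    composite: np.ndarray
    scale_low: float = 1.0
    scale_high: float = 9.0

    def __post_init__(self):
        w, e = self.weights, self.entropies
        assert abs(w.sum() - 1.0) < 1e-12, "weights must sum to 1"
        assert np.all((w >= 0) & (w <= 1)), "weights out of [0,1]"
        assert np.all((e >= -1e-12) & (e <= 1 + 1e-12)), "entropies out of [0,1]"
        colsums = self.proportions.sum(axis=0)
        assert np.allclose(colsums, 1.0, atol=1e-12), "proportions not column-stochastic"
        lo, hi = self.scale_low, self.scale_high
        eps = 1e-9
        assert np.all((self.normalized >= lo - eps) & (self.normalized <= hi + eps))
        assert np.all((self.composite >= lo - eps) & (self.composite <= hi + eps))

    def to_frame(self) -> pd.DataFrame:
        """Rescaled scores plus the composite value, one row per compound."""
        df = pd.DataFrame(
            self.normalized,
            columns=[f"a_{r}" for r in self.scores.receptor_ids],
        )
        df.insert(0, "compound", list(self.scores.compound_ids))
        df["composite"] = self.composite
        return df

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "receptor": list(self.scores.receptor_ids),
            "entropy": self.entropies,
            "weight": self.weights,
            "v_min": self.scores.values.min(axis=0),
            "v_max": self.scores.values.max(axis=0),
        })

    def summary(self) -> str:
        lines = ["Entropy-weight composite biodegradability",
                 "=" * 45,
                 f"compounds: {len(self.scores.compound_ids)}   "
                 f"receptors: {len(self.scores.receptor_ids)}   "
                 f"scale: [{self.scale_low:g}, {self.scale_high:g}]",
                 "",
                 self.weights_frame().to_string(index=False,
                                                float_format=lambda x: f"{x:.6f}"),
                 "",
                 "Top compounds by composite value:"]
        top = self.to_frame().sort_values("composite", ascending=False).head(10)
        lines.append(top.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)


class CompositeScoreModel:
    """Entropy-weight + range-normalisation model over a docking-score table.

    ``fit()`` runs the full pipeline and returns a :class:`CompositeResult`.

    Examples
    --------
    >>> from fqdeg.datasets import load_score_matrix
    >>> res = CompositeScoreModel(load_score_matrix()).fit()
    >>> res.weights.sum()
    1.0
    """

    def __init__(self, scores: ScoreMatrix, scale_low: float = 1.0,
                 scale_high: float = 9.0):
        if scale_high <= scale_low:
            raise ValueError("scale_high must exceed scale_low")
        self.scores = scores
        self.scale_low = float(scale_low)
        self.scale_high = float(scale_high)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, compound_col: str = "compound",
                       **kwargs) -> "CompositeScoreModel":
        return cls(ScoreMatrix.from_dataframe(df, compound_col=compound_col), **kwargs)

    def fit(self) -> CompositeResult:
        scores = self.scores
        m, n = scores.shape
        props = compute_proportions(scores)
        entropies = np.array([compute_entropy(props[:, j], m) for j in range(n)])
        weights = compute_weights(entropies)
        normalized = np.column_stack([
            normalize_column(scores.values[:, j], self.scale_low, self.scale_high,
                             name=scores.receptor_ids[j])
            for j in range(n)
        ])
        composite = normalized @ weights
        return CompositeResult(
            scores=scores, weights=weights, entropies=entropies,
            proportions=props, normalized=normalized, composite=composite,
            scale_low=self.scale_low, scale_high=self.scale_high,
        )


def composite_scores(scores: ScoreMatrix, low: float = 1.0, high: float = 9.0) -> CompositeResult:
    """Functional one-call form of :class:`CompositeScoreModel`."""
    return CompositeScoreModel(scores, scale_low=low, scale_high=high).fit()
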