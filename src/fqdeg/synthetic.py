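"""Seeded generators emulating each stage's input data.

Every generator takes an explicit integer seed (one `numpy` Generator per
call, no global state) and returns both the data object the downstream
module consumes and, where relevant, the generating ground truth so that
recovery tests need no recomputation.

The defaults mirror the study conditions: 49 compounds x 3 receptors with
docking scores in the 40-150 range, a 30-sample QSAR set with 3 latent
components and low noise, and complete 2^k factorial designs with responses
in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .energetics import EnergyRecord, SpeciesEnergy
from .factorial import DesignTable
from .qsar import QsarDataset
from .scoring import ScoreMatrix

__all__ = [
    "gen_score_matrix",
    "gen_qsar_dataset",
    "gen_factorial_response",
    "gen_energy_records",
]

#: Default per-receptor score means/sds, matching the spread of docking
#: scores of fluoroquinolones against the 1GKQ, 1OB0 and 5M0K receptors.
SCORE_MEANS = (100.0, 73.0, 116.0)
SCORE_SDS = (10.0, 8.0, 13.0)


def gen_score_matrix(seed: int, m: int = 49, n: int = 3,
                     means: Optional[Sequence[float]] = None,
                     sds: Optional[Sequence[float]] = None) -> ScoreMatrix:
    """Truncated-normal (positive) docking-score matrix, m compounds x n receptors."""
    if m < 2 or n < 1:
        raise ValueError("need m >= 2 compounds and n >= 1 receptors")
    rng = np.random.default_rng(seed)
    if means is None:
        means = [SCORE_MEANS[j % 3] for j in range(n)]
    if sds is None:
        sds = [SCORE_SDS[j % 3] for j in range(n)]
    if len(means) != n or len(sds) != n:
        raise ValueError("means/sds must have one entry per receptor")
    cols = []
    for mu, sd in zip(means, sds):
        a = (0.0 - mu) / sd  # truncate at zero: scores must stay positive
        cols.append(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                                        size=m, random_state=rng))
    values = np.column_stack(cols)
    return ScoreMatrix(
        [f"CPD{i + 1:02d}" for i in range(m)],
        [f"R{j + 1}" for j in range(n)],
        values,
    )


@dataclass(frozen=True)
class QsarTruth:
    """Generating parameters of a synthetic QSAR dataset."""

    k: int
    beta: np.ndarray        # (p,) coefficients mapping clean X to clean y
    scores: np.ndarray      # (s, k) latent scores
    loadings: np.ndarray    # (p, k) orthonormal loadings
    noise_x: float
    noise_y: float


def gen_qsar_dataset(seed: int, s: int = 30, p: int = 60, k: int = 3,
                     noise_x: float = 0.05, noise_y: float = 0.05,
                     n_test: int = 8) -> tuple[QsarDataset, QsarTruth]:
    """Low-rank-plus-noise descriptors with a linear latent response.

    ``X = T C P' + noise`` with orthonormal loadings P and geometrically
    decreasing component strengths C; ``y = T q + noise`` where the response
    loads *inversely* on the component strengths (the strongest y driver is
    the weakest X direction).  That structure is what makes a PLS model
    genuinely need all k components: each component corrects the mismatch
    between the covariance direction and the regression direction, so the
    LOO q2 curve rises sharply up to k and flattens or drops after.  The
    implied coefficient vector ``beta = P C^-1 q`` is returned as ground
    truth.
    """
    if not (s > k >= 1):
        raise ValueError("need s > k >= 1")
    if not 0 <= n_test <= s - 3:
        raise ValueError("n_test must leave at least 3 training samples")
    rng = np.random.default_rng(seed)
    T = rng.standard_normal((s, k))
    P, _ = np.linalg.qr(rng.standard_normal((p, k)))
    c = 2.0 ** -np.arange(k)              # decreasing component strengths
    q = c[::-1].copy()                    # inverse response loadings
    X = (T * c) @ P.T + noise_x * rng.standard_normal((s, p))
    y = T @ q + noise_y * rng.standard_normal(s)
    beta = P @ (q / c)
    role = np.array(["train"] * s)
    if n_test:
        role[rng.choice(s, size=n_test, replace=False)] = "test"
    ds = QsarDataset([f"S{i + 1:02d}" for i in range(s)], X, y, role=role.tolist())
    return ds, QsarTruth(k=k, beta=beta, scores=T, loadings=P,
                         noise_x=noise_x, noise_y=noise_y)


def gen_factorial_response(seed: int, factors: Sequence[str],
                           effects: Optional[dict] = None,
                           intercept: float = -90.0, sigma: float = 1.0,
                           replicates: int = 1,
                           include_blank_id: bool = True) -> tuple[DesignTable, dict]:
    """Complete 2^k factorial responses with injected effects plus noise.

    ``effects`` maps factor-name tuples (any order) to Yates-convention
    effect sizes; the generating model is ``y = intercept +
    sum_T (effect_T / 2) * prod_{f in T} x_f + N(0, sigma)`` with +-1-coded
    x, so :func:`fqdeg.factorial.factorial_effects` recovers the map exactly
    at sigma = 0.
    """
    factors = tuple(factors)
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factor names")
    effects = {tuple(k_): float(v) for k_, v in (effects or {}).items()}
    for term in effects:
        unknown = set(term) - set(factors)
        if unknown:
            raise ValueError(f"effect term uses unknown factors {unknown}")
    rng = np.random.default_rng(seed)
    k = len(factors)
    rows, gids, ys = [], [], []
    run = 0
    for cell in product((0, 1), repeat=k):
        x = 2 * np.array(cell) - 1
        mu = intercept
        for term, eff in effects.items():
            idx = [factors.index(f) for f in term]
            mu += (eff / 2.0) * float(np.prod(x[idx]))
        for _ in range(replicates):
            rows.append(cell)
            gids.append(f"G{run}")
            ys.append(mu + sigma * rng.standard_normal())
            run += 1
    blank = None
    if include_blank_id:
        zero = tuple([0] * k)
        blank = gids[rows.index(zero)]
    design = DesignTable(gids, factors, np.array(rows), np.array(ys), blank_id=blank)
    truth = {"intercept": intercept, "effects": effects, "sigma": sigma}
    return design, truth


def gen_energy_records(seed: int, count: int = 10, mean_gbind: float = -50.0,
                       sd_gbind: float = 10.0, temperature: float = 308.0,
                       perturb_polar: float = 0.0) -> list[EnergyRecord]:
    """Energy records whose decomposition identities hold exactly.

    Components are drawn first; the complex non-polar term is solved so the
    species identity closes and the complex total realises the drawn binding
    energy.  ``perturb_polar`` injects a known residual into every complex
    polar term (without touching totals) for detector tests.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        def draw_species() -> SpeciesEnergy:
            e_gas = rng.normal(-800.0, 100.0)
            s_gas = rng.normal(1.2, 0.1)          # kJ/mol/K
            g_pol = rng.normal(-150.0, 30.0)
            g_np = rng.normal(15.0, 5.0)
            return SpeciesEnergy.from_components(e_gas, temperature, s_gas,
                                                 g_pol, g_np)

        protein = draw_species()
        ligand = draw_species()
        gbind = rng.normal(mean_gbind, sd_gbind)
        g_complex = protein.G_total + ligand.G_total + gbind
        e_gas = rng.normal(-1600.0, 150.0)
        s_gas = rng.normal(2.4, 0.2)
        g_pol = rng.normal(-300.0, 40.0)
        # close the species identity exactly through the non-polar term
        g_np = g_complex - (e_gas - temperature * s_gas + g_pol)
        complex_sp = SpeciesEnergy(G_total=g_complex, E_gas=e_gas, T=temperature,
                                   S_gas=s_gas, G_polar=g_pol + perturb_polar,
                                   G_nonpolar=g_np)
        out.append(EnergyRecord(name=f"REC{i + 1:03d}", complex=complex_sp,
                                protein=protein, ligand=ligand))
    return out
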