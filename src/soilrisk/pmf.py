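"""Positive matrix factorization (PMF) receptor model.

PMF explains a samples-by-species concentration matrix X as a nonnegative
mixture of ``a`` source factors,

    X = G F + E,      G >= 0 (n_samples x a),  F >= 0 (a x n_species),

by minimising the uncertainty-weighted objective

    Q = sum_iy (e_iy / alpha_iy)^2,

where alpha_iy is the per-cell measurement uncertainty. Uncertainties
follow the standard detection-limit rules: alpha = (5/6)*MDL for values at
or below the MDL, alpha = 0.05*X + MDL above it.

The model is exposed statsmodels-style: build a :class:`PMF` from data,
call :meth:`PMF.fit` (multi-run, seeded, best run selected by robust Q) and
work with the returned :class:`PMFResults` (profiles, contributions,
residual diagnostics, ``summary()``). The minimiser is a weighted
multiplicative-update nonnegative factorization of exactly the objective
above; any minimiser of that objective is faithful to the receptor model.

Scale indeterminacy is resolved by normalising contribution columns to unit
mean, so G is dimensionless (average contribution 1) and F carries
concentration units (the species profile of an average-strength sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core_data import SampleTable, ValidationError, load_packaged_yaml

__all__ = [
    "UncertaintyMatrix",
    "build_uncertainty",
    "default_mdl",
    "PMF",
    "PMFResults",
    "robust_q",
    "match_factors",
]

_EPS = 1e-12


def default_mdl() -> dict[str, float]:
    """Shipped per-element method detection limits (mg/kg)."""
    return {k: float(v) for k, v in load_packaged_yaml("mdl.yaml").items()}


# ---------------------------------------------------------------------------
# Uncertainty construction


@dataclass(frozen=True)
class UncertaintyMatrix:
    """Per-cell uncertainties alpha with the rule applied to each cell."""

    alpha: pd.DataFrame
    rule: pd.DataFrame  # "below_mdl" | "above_mdl"

    def __post_init__(self) -> None:
        if not (self.alpha.to_numpy() > 0).all():
            raise ValidationError("every uncertainty must be strictly positive")


def build_uncertainty(
    samples: SampleTable | pd.DataFrame,
    mdl: Mapping[str, float] | None = None,
    error_fraction: float = 0.05,
) -> UncertaintyMatrix:
    """Apply the detection-limit uncertainty rules cell by cell.

    ``alpha = (5/6) * MDL`` where ``X <= MDL`` (the boundary cell counts as
    below-detection), else ``alpha = error_fraction * X + MDL``.
    """
    if not error_fraction > 0:
        raise ValueError(f"error fraction must be positive, got {error_fraction}")
    if isinstance(samples, SampleTable):
        conc = samples.concentrations()
        mdl = {**default_mdl(), **samples.mdl, **(mdl or {})}
    else:
        conc = samples.astype(float)
        mdl = {**default_mdl(), **(mdl or {})}
    for e in conc.columns:
        if e not in mdl:
            raise ValidationError(f"no MDL configured for element {e}")
        if not mdl[e] > 0:
            raise ValidationError(f"MDL for {e} must be positive, got {mdl[e]}")
    limits = pd.Series({e: float(mdl[e]) for e in conc.columns})
    below = conc.le(limits, axis=1)
    alpha = pd.DataFrame(
        np.where(below, np.broadcast_to(5.0 / 6.0 * limits.values, conc.shape),
                 error_fraction * conc.values + limits.values),
        index=conc.index,
        columns=conc.columns,
    )
    rule = pd.DataFrame(
        np.where(below, "below_mdl", "above_mdl"),
        index=conc.index,
        columns=conc.columns,
    )
    return UncertaintyMatrix(alpha=alpha, rule=rule)


def robust_q(scaled_residuals: np.ndarray | pd.DataFrame, outlier_threshold: float = 4.0) -> float:
    """Q with outlying cells down-weighted.

    A cell whose |scaled residual| exceeds the threshold contributes
    ``threshold**2`` instead of its full squared residual, capping the
    influence of ill-fit cells. With no outliers this equals the true Q.
    """
    if not outlier_threshold > 0:
        raise ValueError(f"outlier threshold must be positive, got {outlier_threshold}")
    r2 = np.square(np.asarray(scaled_residuals, dtype=float))
    return float(np.minimum(r2, outlier_threshold**2).sum())


# ---------------------------------------------------------------------------
# Model


class PMF:
    """Weighted nonnegative factorization model for one concentration matrix.

    Parameters
    ----------
    X:
        Nonnegative samples-by-species matrix (DataFrame or array).
    uncertainty:
        Per-cell uncertainties alpha (same shape); an
        :class:`UncertaintyMatrix`, DataFrame or array.
    """

    def __init__(
        self,
        X: pd.DataFrame | np.ndarray,
        uncertainty: UncertaintyMatrix | pd.DataFrame | np.ndarray,
    ) -> None:
        if isinstance(X, pd.DataFrame):
            self.species = list(X.columns)
            self.sample_ids = list(X.index)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.species = [f"sp{j}" for j in range(Xv.shape[1])]
            self.sample_ids = list(range(Xv.shape[0]))
        if isinstance(uncertainty, UncertaintyMatrix):
            A = uncertainty.alpha.to_numpy(dtype=float)
        elif isinstance(uncertainty, pd.DataFrame):
            A = uncertainty.to_numpy(dtype=float)
        else:
            A = np.asarray(uncertainty, dtype=float)
        if A.shape != Xv.shape:
            raise ValidationError(
                f"uncertainty shape {A.shape} does not match data shape {Xv.shape}"
            )
        if np.isnan(Xv).any():
            raise ValidationError("NaN in concentration matrix")
        if (Xv < 0).any():
            raise ValidationError("concentration matrix must be nonnegative")
        if not (A > 0).all():
            raise ValidationError("uncertainties must be strictly positive")
        self.X = Xv
        self.alpha = A
        self.weights = 1.0 / A**2

    @classmethod
    def from_sample_table(
        cls,
        samples: SampleTable,
        mdl: Mapping[str, float] | None = None,
        error_fraction: float = 0.05,
        substitute: str = "half_mdl",
    ) -> "PMF":
        """Build X and alpha from a sample table.

        Concentrations at or below the MDL enter X as MDL/2 by default
        (``substitute``: ``"half_mdl"`` or ``"asis"``); their uncertainty is
        (5/6)*MDL either way.
        """
        if substitute not in ("half_mdl", "asis"):
            raise ValueError(f"unknown substitution policy {substitute!r}")
        unc = build_uncertainty(samples, mdl=mdl, error_fraction=error_fraction)
        conc = samples.concentrations()
        if substitute == "half_mdl":
            limits = {**default_mdl(), **samples.mdl, **(mdl or {})}
            for e in conc.columns:
                below = conc[e] <= limits[e]
                conc.loc[below, e] = limits[e] / 2.0
        conc.index = samples.data["sample_id"]
        unc_alpha = unc.alpha.copy()
        unc_alpha.index = conc.index
        return cls(conc, unc_alpha)

    # -- fitting ------------------------------------------------------------

    def _fit_single(
        self,
        n_factors: int,
        seed: int,
        max_iter: int,
        tol: float,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
        rng = np.random.default_rng(seed)
        n, m = self.X.shape
        col_scale = self.X.mean(axis=0).clip(min=_EPS)
        G = rng.uniform(0.5, 1.5, size=(n, n_factors))
        F = rng.uniform(0.5, 1.5, size=(n_factors, m)) * (col_scale / n_factors)
        W = self.weights
        WX = W * self.X
        q_floor = 1e-12 * self.X.size
        q_path = []
        q_prev = np.inf
        converged = False
        for _ in range(max_iter):
            GF = G @ F
            F *= (G.T @ WX) / (G.T @ (W * GF) + _EPS)
            GF = G @ F
            G *= (WX @ F.T) / ((W * GF) @ F.T + _EPS)
            q = float((W * np.square(self.X - G @ F)).sum())
            q_path.append(q)
            if q < q_floor or (
                np.isfinite(q_prev) and abs(q_prev - q) <= tol * max(q, _EPS)
            ):
                converged = True
                break
            q_prev = q
        return G, F, np.asarray(q_path), converged

    def fit(
        self,
        n_factors: int,
        n_runs: int = 20,
        seed: int = 0,
        max_iter: int = 3000,
        tol: float = 1e-8,
        outlier_threshold: float = 4.0,
    ) -> "PMFResults":
        """Run the seeded multi-start minimisation; return the best run.

        Each run starts from an independent random nonnegative
        initialisation drawn from a generator seeded off ``seed``; the run
        with the lowest robust Q among converged runs wins. All runs'
        diagnostics are kept in ``PMFResults.runs``.
        """
        n, m = self.X.shape
        if n_factors < 1 or n_factors >= min(n, m):
            raise ValueError(
                f"n_factors must be in [1, min(n_samples, n_species)) = "
                f"[1, {min(n, m)}); got {n_factors}"
            )
        if n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        root = np.random.default_rng(seed)
        run_seeds = root.integers(0, 2**31 - 1, size=n_runs)
        records = []
        best = None
        for run, run_seed in enumerate(run_seeds):
            G, F, q_path, converged = self._fit_single(
                n_factors, int(run_seed), max_iter, tol
            )
            scaled = (self.X - G @ F) / self.alpha
            q_true = float(np.square(scaled).sum())
            q_rob = robust_q(scaled, outlier_threshold)
            records.append(
                {
                    "run": run,
                    "seed": int(run_seed),
                    "q_true": q_true,
                    "q_robust": q_rob,
                    "converged": converged,
                    "n_iter": len(q_path),
                }
            )
            if converged and (best is None or q_rob < best[0]):
                best = (q_rob, G, F, q_path, int(run_seed))
        runs = pd.DataFrame.from_records(records)
        if best is None:
            raise RuntimeError(
                "no PMF run converged; Q trajectories of the final run: "
                f"{q_path.tolist()[-10:]}"
            )
        _, G, F, q_path, run_seed = best
        return PMFResults(
            model=self,
            G=G,
            F=F,
            q_path=q_path,
            run_seed=run_seed,
            runs=runs,
            outlier_threshold=outlier_threshold,
        )

    def fit_scan(
        self,
        factor_numbers: Sequence[int] = (3, 4, 5, 6),
        **fit_kwargs,
    ) -> dict[int, "PMFResults"]:
        """Fit once per candidate factor number (default scan: 3-6)."""
        return {a: self.fit(a, **fit_kwargs) for a in factor_numbers}


# ---------------------------------------------------------------------------
# Results


class PMFResults:
    """One converged PMF solution plus all-run diagnostics.

    Attributes
    ----------
    profiles:
        Factor-by-species F matrix, concentration units (DataFrame).
    contributions:
        Sample-by-factor G matrix, dimensionless, unit column means.
    runs:
        Per-run (run, seed, q_true, q_robust, converged, n_iter) table.
    """

    def __init__(
        self,
        model: PMF,
        G: np.ndarray,
        F: np.ndarray,
        q_path: np.ndarray,
        run_seed: int,
        runs: pd.DataFrame,
        outlier_threshold: float,
    ) -> None:
        # normalise: unit-mean contribution columns; F carries the units
        scale = G.mean(axis=0).clip(min=_EPS)
        G = G / scale
        F = F * scale[:, None]
        self.model = model
        self.n_factors = F.shape[0]
        factor_names = [f"F{k + 1}" for k in range(self.n_factors)]
        self.contributions = pd.DataFrame(
            G, index=model.sample_ids, columns=factor_names
        )
        self.profiles = pd.DataFrame(F, index=factor_names, columns=model.species)
        self.q_path = q_path
        self.run_seed = run_seed
        self.runs = runs
        self.outlier_threshold = outlier_threshold

    # -- diagnostics --------------------------------------------------------

    @property
    def fitted(self) -> pd.DataFrame:
        GF = self.contributions.to_numpy() @ self.profiles.to_numpy()
        return pd.DataFrame(GF, index=self.model.sample_ids, columns=self.model.species)

    @property
    def residuals(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.model.X, index=self.model.sample_ids, columns=self.model.species
        ) - self.fitted

    @property
    def scaled_residuals(self) -> pd.DataFrame:
        return self.residuals / pd.DataFrame(
            self.model.alpha, index=self.model.sample_ids, columns=self.model.species
        )

    @property
    def q_true(self) -> float:
        return float(np.square(self.scaled_residuals.to_numpy()).sum())

    @property
    def q_robust(self) -> float:
        return robust_q(self.scaled_residuals.to_numpy(), self.outlier_threshold)

    @property
    def r2(self) -> pd.Series:
        """Squared Pearson correlation, observed vs reconstructed, per species."""
        obs = self.model.X
        fit = self.fitted.to_numpy()
        out = {}
        for j, sp in enumerate(self.model.species):
            o, f = obs[:, j], fit[:, j]
            if o.std() == 0 or f.std() == 0:
                out[sp] = float("nan")
            else:
                out[sp] = float(np.corrcoef(o, f)[0, 1] ** 2)
        return pd.Series(out, name="r2")

    def factor_contributions(self) -> pd.DataFrame:
        """Percent of each species' reconstructed mass attributed to each factor.

        Rows (species) sum to 100. A species with zero reconstructed mass
        has no defined split and reports NaN.
        """
        totals = self.contributions.to_numpy().sum(axis=0)  # per-factor mass weight
        mass = totals[:, None] * self.profiles.to_numpy()  # factor x species
        col_sum = mass.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(col_sum > 0, 100.0 * mass / col_sum, np.nan)
        return pd.DataFrame(
            shares.T, index=self.model.species, columns=self.profiles.index
        )

    def summary(self) -> str:
        """Human-readable fit report, statsmodels-flavoured."""
        lines = [
            "Positive Matrix Factorization Results",
            "=" * 48,
            f"samples: {self.model.X.shape[0]}    species: {self.model.X.shape[1]}"
            f"    factors: {self.n_factors}",
            f"runs: {len(self.runs)} (converged: {int(self.runs.converged.sum())})"
            f"    best-run seed: {self.run_seed}",
            f"Q (true): {self.q_true:.4g}    Q (robust): {self.q_robust:.4g}",
            "",
            "R^2 by species:",
            self.r2.round(3).to_string(),
            "",
            "Factor profiles (concentration units):",
            self.profiles.round(3).to_string(),
            "",
            "Species apportionment (% of reconstructed mass):",
            self.factor_contributions().round(1).to_string(),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PMFResults factors={self.n_factors} "
            f"q_true={self.q_true:.4g} q_robust={self.q_robust:.4g}>"
        )


# ---------------------------------------------------------------------------
# Factor-to-source matching (validation helper)


def match_factors(
    estimated_profiles: pd.DataFrame | np.ndarray,
    true_profiles: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Best factor-to-source permutation by cosine similarity.

    Returns ``perm`` such that estimated factor ``perm[k]`` corresponds to
    true source ``k``. Resolves the permutation ambiguity of any
    factorization before comparing to ground truth.
    """
    E = np.asarray(estimated_profiles, dtype=float)
    T = np.asarray(true_profiles, dtype=float)
    if E.shape != T.shape:
        raise ValueError("profile matrices must have identical shapes")
    En = E / np.linalg.norm(E, axis=1, keepdims=True).clip(min=_EPS)
    Tn = T / np.linalg.norm(T, axis=1, keepdims=True).clip(min=_EPS)
    sim = Tn @ En.T  # true x estimated
    row, col = linear_sum_assignment(-sim)
    perm = np.empty(len(row), dtype=int)
    perm[row] = col
    return perm
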