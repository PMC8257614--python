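"""Model / Results interface for fitting the inhibitor-field model.

`PricklePatternModel` holds an observed (phi, h) prickle point pattern (from
a processed stem table, a fixture, or the synthetic generator) together with
the fitting configuration; `fit()` runs the multistart quasi-Newton search
and returns a `PricklePatternResults` carrying the estimated parameters, the
achieved correlation, the distinct optima found, and a summary table.
"""

from __future__ import annotations

from dataclasses import replace
from functools import cached_property

import numpy as np
import pandas as pd

from .field import DensityGrid, ModelParams, model_density_grid
from .fitting import (
    FitConfig,
    FitResult,
    evaluate_fit,
    kde2d_estimate,
    optimize_params,
)
from .geometry import StemRecord, process_stem

__all__ = ["PricklePatternModel", "PricklePatternResults"]


class PricklePatternModel:
    """Inhibitor-field model of a prickle point pattern on the (phi, h) plane.

    Parameters
    ----------
    points : array-like, shape (n, 2)
        Observed prickles as (phi_deg, h) pairs, phi in [-90, 270) degrees
        and h in [0, 1].
    config : FitConfig, optional
        Fitting configuration; defaults carry the full 10^4-start budget.

    Examples
    --------
    >>> from pricklemap import PricklePatternModel, aseyal_pair_fixture
    >>> model = PricklePatternModel(aseyal_pair_fixture())
    >>> res = model.fit(n_starts=100, seed=0)
    >>> res.correlation > 0.9
    True
    """

    def __init__(self, points, config: FitConfig | None = None):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 2:
            raise ValueError("points must be a non-empty (n, 2) array of "
                             "(phi_deg, h) pairs")
        self.points = pts
        self.config = config or FitConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phi_col: str = "phi_deg",
                       h_col: str = "h",
                       config: FitConfig | None = None,
                       ) -> "PricklePatternModel":
        """Build from a processed-prickle table (e.g. `process_stem` output)."""
        return cls(df[[phi_col, h_col]].to_numpy(dtype=float), config=config)

    @classmethod
    def from_stem(cls, stem: StemRecord, config: FitConfig | None = None,
                  ) -> "PricklePatternModel":
        """Run the geometry pipeline on a raw stem record, then build."""
        return cls.from_dataframe(process_stem(stem), config=config)

    @cached_property
    def kde(self) -> DensityGrid:
        """KDE of the observed pattern on the model lattice."""
        return kde2d_estimate(
            self.points, N_d=self.config.N_d,
            fallback_fraction=self.config.bandwidth_fallback_fraction,
            periodic_phi=self.config.periodic_phi)

    @property
    def nobs(self) -> int:
        return self.points.shape[0]

    def score(self, params: ModelParams) -> float:
        """Pearson correlation of the model density at ``params`` vs the KDE."""
        return evaluate_fit(params, self.kde, self.config)

    def fit(self, n_starts: int | None = None, seed: int | None = None,
            ) -> "PricklePatternResults":
        """Multistart BFGS estimation of (alpha, beta, T_a, T_b, T_c)."""
        cfg = self.config
        if n_starts is not None or seed is not None:
            cfg = replace(cfg,
                          n_starts=cfg.n_starts if n_starts is None else n_starts,
                          seed=cfg.seed if seed is None else seed)
        return PricklePatternResults(self, optimize_params(self.kde, cfg))


class PricklePatternResults:
    """Fit results: parameter estimates, correlation and distinct optima."""

    def __init__(self, model: PricklePatternModel, fitres: FitResult):
        self.model = model
        self._fitres = fitres

    @property
    def params(self) -> ModelParams:
        return self._fitres.params

    @property
    def correlation(self) -> float:
        return self._fitres.correlation

    @property
    def n_converged(self) -> int:
        return self._fitres.n_converged

    @property
    def basins(self) -> list[tuple[ModelParams, float]]:
        return self._fitres.all_optima

    def predict_density(self, N_d: int | None = None) -> DensityGrid:
        """Model density grid at the fitted parameters."""
        cfg = self.model.config
        return model_density_grid(
            self.params, N_d=N_d or cfg.N_d, epsilon=cfg.epsilon,
            reciprocal=cfg.use_reciprocal,
            corotating_frame=cfg.corotating_frame)

    def to_dict(self) -> dict:
        return self._fitres.to_dict()

    def save_json(self, path) -> None:
        self._fitres.to_json(path)

    def plot_comparison(self, axes=None):
        """Side-by-side heat maps of the observed KDE and fitted density."""
        from .plotting import plot_fit_comparison
        return plot_fit_comparison(self.model.kde, self.predict_density(),
                                   axes=axes)

    def summary(self) -> str:
        p = self.params
        cfg = self._fitres.config
        lines = [
            "Inhibitor-field prickle pattern fit",
            "=" * 51,
            f"{'No. observations:':<28}{self.model.nobs:>10}",
            f"{'Multistart count:':<28}{(cfg.n_starts if cfg else 'n/a'):>10}",
            f"{'Converged starts:':<28}{self.n_converged:>10}",
            f"{'Distinct optima:':<28}{len(self.basins):>10}",
            f"{'Pearson correlation:':<28}{self.correlation:>10.4f}",
            "-" * 51,
            f"{'param':<10}{'estimate':>12}   constraint",
            f"{'alpha':<10}{p.alpha:>12.4f}   > 0",
            f"{'beta':<10}{p.beta:>12.4f}   (free)",
            f"{'T_a':<10}{p.T_a:>12.4f}   >= -T, < T_b",
            f"{'T_b':<10}{p.T_b:>12.4f}   in (T_a, T_c)",
            f"{'T_c':<10}{p.T_c:>12.4f}   in (0, 2T]",
            "=" * 51,
            f"T = {p.T:g} (plastochron), Phi = {np.degrees(p.Phi):.2f} deg",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<PricklePatternResults corr={self.correlation:.4f} "
                f"params={tuple(np.round(self.params.vector, 4))}>")
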