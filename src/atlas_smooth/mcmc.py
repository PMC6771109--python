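"""Shared MCMC infrastructure: configuration, retained draws, adaptation.

Both samplers are Metropolis-within-Gibbs with single-site random-walk
updates for the spatial field, vectorised over colour classes of the
adjacency graph (areas within a class share no edge, so their full
conditionals are mutually independent given the rest).  Proposal steps are
adapted during burn-in towards a target acceptance rate and frozen
afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["McmcConfig", "PosteriorDraws", "StepAdapter", "leroux_quadform_delta"]


@dataclass
class McmcConfig:
    """Sampling schedule and proposal tuning.

    Defaults reproduce the production schedule: 50,000 burn-in, 100,000
    further iterations keeping every 10th, i.e. 10,000 retained draws.
    """

    burn_in: int = 50_000
    iterations: int = 100_000
    thin: int = 10
    seed: int = 0
    step_s: float = 0.5
    step_scalar: float = 0.3
    step_rho: float = 0.1
    step_sigma2: float = 0.5
    target_accept: float = 0.45
    adapt_interval: int = 100
    centre_moves: bool = True

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= 0 or self.thin <= 0:
            raise ValueError("invalid schedule")
        if self.iterations % self.thin != 0:
            raise ValueError("iterations must be divisible by thin")

    @property
    def retained(self) -> int:
        return self.iterations // self.thin


class PosteriorDraws:
    """Retained draws for all parameters of one fitted model."""

    def __init__(self, params: dict[str, np.ndarray], acceptance: dict[str, float],
                 config: McmcConfig, area_ids=None):
        rows = {v.shape[0] for v in params.values()}
        if len(rows) != 1:
            raise ValueError("parameter draw arrays disagree on row count")
        self.params = params
        self.acceptance = acceptance
        self.config = config
        self.area_ids = list(area_ids) if area_ids is not None else None

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def matrix(self) -> np.ndarray:
        cols = [np.atleast_2d(v.T).T for v in self.params.values()]
        return np.hstack(cols)

    def column_names(self) -> list[str]:
        out = []
        for name, v in self.params.items():
            if v.ndim == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{j}]" for j in range(v.shape[1]))
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix(), columns=self.column_names()).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: McmcConfig | None = None) -> "PosteriorDraws":
        import pandas as pd

        df = pd.read_csv(path)
        params: dict[str, list] = {}
        for col in df.columns:
            base = col.split("[")[0]
            params.setdefault(base, []).append(col)
        arrays = {}
        for base, cols in params.items():
            arr = df[cols].to_numpy()
            arrays[base] = arr[:, 0] if len(cols) == 1 and "[" not in cols[0] else arr
        return cls(arrays, {}, config or McmcConfig())

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".csv":
            self.to_csv(path)
        else:
            np.savez(path, **self.params)


class StepAdapter:
    """Robbins-Monro style step adaptation towards a target acceptance rate.

    ``step`` may be a scalar or per-component vector; accepted counts are
    accumulated and the step rescaled every ``interval`` iterations during
    burn-in only.
    """

    def __init__(self, step, target: float = 0.45, interval: int = 100):
        self.step = np.asarray(step, dtype=float).copy()
        self.scalar = self.step.ndim == 0
        self.target = target
        self.interval = interval
        self._acc = np.zeros_like(self.step, dtype=float)
        self._n = 0
        self.total_acc = 0.0
        self.total_n = 0

    def record(self, accepted) -> None:
        self._acc = self._acc + accepted
        self._n += 1
        self.total_acc += float(np.mean(accepted))
        self.total_n += 1
        if self._n >= self.interval:
            rate = self._acc / self._n
            self.step = self.step * np.exp(np.clip(rate - self.target, -0.5, 0.5))
            self.step = np.clip(self.step, 1e-4, 50.0)
            self._acc = np.zeros_like(self._acc)
            self._n = 0

    def record_frozen(self, accepted) -> None:
        self.total_acc += float(np.mean(accepted))
        self.total_n += 1

    @property
    def rate(self) -> float:
        return self.total_acc / max(self.total_n, 1)


def leroux_quadform_delta(Q0_diag, WS, rho, S_old, S_new, idx):
    """Change in S' Q0 S when components ``idx`` move (no edges within idx).

    Q0 = rho (D - W) + (1 - rho) I; ``WS`` is W @ S with neighbour values of
    the moving components unchanged.
    """
    so, sn = S_old[idx], S_new
    return Q0_diag[idx] * (sn**2 - so**2) - 2.0 * rho * WS[idx] * (sn - so)


def reflect_unit(x: float) -> float:
    """Reflect a real proposal into [0, 1] (symmetric proposal kernel)."""
    x = abs(float(x))
    while x > 1.0:
        x = abs(2.0 - x)
    return x
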