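"""Sequential model-based hyperparameter search (tree-structured Parzen estimator).

A compact TPE sampler: past trials are split into a "good" fraction (the top
``gamma`` by objective) and the rest; each parameter gets a pair of Parzen
density estimates (Gaussian kernels for numeric parameters, smoothed
frequencies for categorical ones) fitted to the good and bad observations.
Candidates are drawn from the good density and the one maximizing the density
ratio l(x)/g(x) is evaluated next.  The first ``n_startup`` trials are drawn
uniformly at random.

Parameter space entries::

    {"x": ("float", lo, hi), "n": ("int", lo, hi), "c": ("choice", [a, b])}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

ParamSpec = tuple


@dataclass
class Trial:
    params: dict[str, Any]
    value: float
    number: int


@dataclass
class TPESampler:
    space: dict[str, ParamSpec]
    seed: int = 0
    gamma: float = 0.25
    n_startup: int = 10
    n_candidates: int = 24
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        for name, spec in self.space.items():
            kind = spec[0]
            if kind not in ("float", "int", "choice"):
                raise ValueError(f"parameter {name!r}: unknown kind {kind!r}")
            if kind in ("float", "int") and not spec[1] <= spec[2]:
                raise ValueError(f"parameter {name!r}: empty range")

    # -- sampling helpers ---------------------------------------------------
    def _random_params(self) -> dict[str, Any]:
        params = {}
        for name, spec in self.space.items():
            kind = spec[0]
            if kind == "float":
                params[name] = float(self._rng.uniform(spec[1], spec[2]))
            elif kind == "int":
                params[name] = int(self._rng.integers(spec[1], spec[2] + 1))
            else:
                params[name] = spec[1][self._rng.integers(len(spec[1]))]
        return params

    @staticmethod
    def _numeric_density(x: float, obs: np.ndarray, lo: float, hi: float) -> float:
        """Parzen mixture of Gaussians centred on the observations."""
        if len(obs) == 0:
            return 1.0 / max(hi - lo, 1e-12)
        sigma = max((hi - lo) / max(len(obs), 4), 1e-12)
        z = (x - obs) / sigma
        return float(np.mean(np.exp(-0.5 * z * z) / (sigma * np.sqrt(2 * np.pi))) + 1e-12)

    def _sample_from(self, name: str, good_obs: list) -> Any:
        spec = self.space[name]
        kind = spec[0]
        if kind == "choice":
            values = list(spec[1])
            counts = np.array([1.0 + sum(1 for o in good_obs if o == v) for v in values])
            return values[self._rng.choice(len(values), p=counts / counts.sum())]
        lo, hi = spec[1], spec[2]
        if not good_obs:
            x = self._rng.uniform(lo, hi)
        else:
            center = good_obs[self._rng.integers(len(good_obs))]
            sigma = max((hi - lo) / max(len(good_obs), 4), 1e-12)
            x = float(np.clip(self._rng.normal(center, sigma), lo, hi))
        return int(round(x)) if kind == "int" else float(x)

    def _density_ratio(self, params: dict[str, Any], good: list[Trial],
                       bad: list[Trial]) -> float:
        ratio = 1.0
        for name, spec in self.space.items():
            kind = spec[0]
            g_obs = [t.params[name] for t in good]
            b_obs = [t.params[name] for t in bad]
            if kind == "choice":
                values = list(spec[1])
                pg = (1.0 + sum(1 for o in g_obs if o == params[name])) / (
                    len(values) + len(g_obs)
                )
                pb = (1.0 + sum(1 for o in b_obs if o == params[name])) / (
                    len(values) + len(b_obs)
                )
                ratio *= pg / pb
            else:
                lo, hi = spec[1], spec[2]
                lg = self._numeric_density(params[name], np.asarray(g_obs, float), lo, hi)
                lb = self._numeric_density(params[name], np.asarray(b_obs, float), lo, hi)
                ratio *= lg / lb
        return ratio

    # -- public API ---------------------------------------------------------
    def suggest(self) -> dict[str, Any]:
        if len(self.trials) < self.n_startup:
            return self._random_params()
        ordered = sorted(self.trials, key=lambda t: t.value, reverse=True)
        n_good = max(1, int(np.ceil(self.gamma * len(ordered))))
        good, bad = ordered[:n_good], ordered[n_good:]
        if not bad:
            return self._random_params()
        best_params, best_ratio = None, -np.inf
        for _ in range(self.n_candidates):
            cand = {
                name: self._sample_from(name, [t.params[name] for t in good])
                for name in self.space
            }
            r = self._density_ratio(cand, good, bad)
            if r > best_ratio:
                best_params, best_ratio = cand, r
        return best_params

    def tell(self, params: dict[str, Any], value: float) -> None:
        self.trials.append(Trial(params=params, value=value, number=len(self.trials)))


def is_degenerate(space: dict[str, ParamSpec]) -> bool:
    """True when the space contains exactly one configuration."""
    for spec in space.values():
        kind = spec[0]
        if kind == "choice" and len(spec[1]) > 1:
            return False
        if kind == "int" and spec[1] != spec[2]:
            return False
        if kind == "float" and spec[1] != spec[2]:
            return False
    return True


def maximize(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, ParamSpec],
    n_trials: int,
    seed: int = 0,
    **sampler_kwargs,
) -> tuple[dict[str, Any], list[Trial]]:
    """Run the TPE loop; returns (best parameters, full trial log)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = TPESampler(space=space, seed=seed, **sampler_kwargs)
    if is_degenerate(space):
        params = sampler._random_params()
        sampler.tell(params, objective(params))
        return params, sampler.trials
    for _ in range(n_trials):
        params = sampler.suggest()
        sampler.tell(params, objective(params))
    best = max(sampler.trials, key=lambda t: t.value)
    return best.params, sampler.trials
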