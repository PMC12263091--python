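"""Calibrating crappifier parameters against real image pairs.

The noise in a real low-resolution acquisition is measured by
downsampling its high-resolution partner into a "noiseless" LR image and
subtracting: the residual array is the *noise profile*.  Crappifier
parameters are then fitted by Gaussian-process Bayesian optimization so
that the residual-value distribution of semi-synthetic LR images matches
that of the real ones.  Only the value distribution is compared — noise
is assumed spatially independent, so the spatial arrangement of the
residuals carries no signal for this fit.

Divergence between residual distributions defaults to the 1-D
Wasserstein (earth mover's) distance, which is well defined for
continuous values without binning artifacts and varies smoothly with the
parameters; a histogram L1 alternative is available.

Every candidate evaluation re-crappifies the pairs with the same
fit-level seed (common random numbers), so the objective the optimizer
sees is a deterministic, smooth function of the parameter rather than
one with a fresh noise realization per candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import wasserstein_distance
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel

from .crappifiers import downsample, get_noise_fn

__all__ = ["NoiseProfile", "FitResult", "extract_noise_profile",
           "profile_divergence", "make_objective", "fit_crappifier"]

HISTOGRAM_BINS = 64


@dataclass(frozen=True)
class NoiseProfile:
    """Residual array lr_true - downsample(hr) with summary statistics."""

    residuals: np.ndarray
    mean: float
    std: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges, counts)

    @classmethod
    def from_residuals(cls, residuals: np.ndarray) -> "NoiseProfile":
        residuals = np.asarray(residuals, dtype=np.float64)
        if residuals.size == 0:
            raise ValueError("empty residual array")
        lo, hi = float(residuals.min()), float(residuals.max())
        if hi - lo <= 1e-9 * max(1.0, abs(lo)):
            # (near-)constant residuals: histogram needs a finite span
            lo, hi = lo - 0.5, hi + 0.5
        counts, edges = np.histogram(residuals, bins=HISTOGRAM_BINS,
                                     range=(lo, hi))
        return cls(residuals=residuals, mean=float(residuals.mean()),
                   std=float(residuals.std()), histogram=(edges, counts))


def extract_noise_profile(hr: np.ndarray, lr_true: np.ndarray,
                          scale: int) -> NoiseProfile:
    """Noise profile of a real pair: signed residuals, never clipped."""
    hr = np.asarray(hr, dtype=np.float64)
    lr_true = np.asarray(lr_true, dtype=np.float64)
    expected = tuple(s // scale for s in hr.shape)
    if lr_true.shape != expected:
        raise ValueError(
            f"geometry mismatch: HR {hr.shape} at scale {scale} implies LR "
            f"{expected}, got {lr_true.shape}")
    residuals = lr_true - downsample(hr, scale)
    return NoiseProfile.from_residuals(residuals)


def profile_divergence(p: NoiseProfile, q: NoiseProfile,
                       method: str = "wasserstein") -> float:
    """Distance between two residual-value distributions.

    Zero iff the empirical distributions coincide; symmetric; invariant
    to the spatial arrangement of the residuals.
    """
    if p.residuals.size == 0 or q.residuals.size == 0:
        raise ValueError("empty noise profile")
    if method == "wasserstein":
        return float(wasserstein_distance(p.residuals.ravel(),
                                          q.residuals.ravel()))
    if method == "histogram_l1":
        lo = min(p.residuals.min(), q.residuals.min())
        hi = max(p.residuals.max(), q.residuals.max())
        if hi == lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, HISTOGRAM_BINS + 1)
        hp, _ = np.histogram(p.residuals, bins=edges, density=False)
        hq, _ = np.histogram(q.residuals, bins=edges, density=False)
        hp = hp / hp.sum()
        hq = hq / hq.sum()
        return float(np.abs(hp - hq).sum())
    raise ValueError(f"unknown divergence method {method!r}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a crappifier calibration."""

    family: str
    params: dict[str, float]
    objective: float
    trace: tuple[tuple[float, float], ...]  # (parameter, objective) in order
    budget: int
    seed: int
    divergence: str

    def summary(self) -> str:
        lines = [
            "Crappifier calibration",
            f"  family:      {self.family}",
            f"  fitted:      " + ", ".join(f"{k} = {v:.6g}"
                                           for k, v in self.params.items()),
            f"  objective:   {self.objective:.6g} ({self.divergence})",
            f"  evaluations: {len(self.trace)} (budget {self.budget})",
            f"  seed:        {self.seed}",
        ]
        return "\n".join(lines)


def _infer_scale(hr: np.ndarray, lr: np.ndarray) -> int:
    ratio = hr.shape[0] / lr.shape[0]
    scale = int(round(ratio))
    if scale < 1 or hr.shape[0] != lr.shape[0] * scale or \
            hr.shape[1] != lr.shape[1] * scale:
        raise ValueError(
            f"pair shapes {hr.shape}/{lr.shape} have no integer scale")
    return scale


def make_objective(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   family: str, seed: int, gain: float = 255.0,
                   clip: bool = True, divergence: str = "wasserstein"
                   ) -> Callable[[float], float]:
    """Build the calibration objective: mean divergence, over pairs,
    between real noise profiles and profiles of semi-synthetic LRs
    generated at a candidate intensity.

    The per-pair noise seeds are fixed once from ``seed`` (common random
    numbers), so the returned callable is deterministic.
    """
    if not pairs:
        raise ValueError("at least one HR/LR pair is required")
    noise_fn = get_noise_fn(family)
    prepared = []
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    for (hr, lr_true), ss in zip(pairs, seeds):
        hr = np.asarray(hr, dtype=np.float64)
        lr_true = np.asarray(lr_true, dtype=np.float64)
        scale = _infer_scale(hr, lr_true)
        ds = downsample(hr, scale)
        true_profile = NoiseProfile.from_residuals(lr_true - ds)
        prepared.append((ds, true_profile, ss))

    def objective(theta: float) -> float:
        theta = float(theta)
        total = 0.0
        for ds, true_profile, ss in prepared:
            rng = np.random.default_rng(ss)
            synth_lr = noise_fn(ds, theta, gain, rng, clip)
            synth_profile = NoiseProfile.from_residuals(synth_lr - ds)
            total += profile_divergence(true_profile, synth_profile,
                                        method=divergence)
        value = total / len(prepared)
        if not np.isfinite(value):
            raise ValueError(f"non-finite objective at intensity {theta}")
        return value

    return objective


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray,
                          best: float, xi: float = 1e-4) -> np.ndarray:
    from scipy.stats import norm
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def fit_crappifier(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   family: str,
                   param_bounds: tuple[float, float],
                   budget: int = 50,
                   seed: int = 0,
                   gain: float = 255.0,
                   clip: bool = True,
                   divergence: str = "wasserstein") -> FitResult:
    """Fit the crappifier intensity by GP Bayesian optimization.

    Ten initial probes (the two bound endpoints plus seeded uniform
    draws) are followed by expected-improvement acquisition under a
    Matern-5/2 Gaussian process until ``budget`` objective evaluations
    have been spent.  Deterministic given ``seed``.
    """
    lo, hi = float(param_bounds[0]), float(param_bounds[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ValueError(f"invalid parameter bounds {param_bounds}")
    objective = make_objective(pairs, family, seed, gain=gain, clip=clip,
                               divergence=divergence)
    param_name = "sigma" if family == "additive_gaussian" else "intensity"

    if lo == hi:
        value = objective(lo)
        return FitResult(family=family, params={param_name: lo},
                         objective=value, trace=((lo, value),), budget=budget,
                         seed=seed, divergence=divergence)
    if budget < 10:
        raise ValueError(f"budget must be at least 10, got {budget}")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    span = hi - lo

    def to_unit(x):
        return (np.asarray(x) - lo) / span

    # initial design: both endpoints, then seeded uniform probes
    n_init = min(10, budget)
    xs = [lo, hi] + list(rng.uniform(lo, hi, size=n_init - 2))
    ys = [objective(x) for x in xs]

    while len(xs) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(length_scale=0.2, length_scale_bounds=(1e-3, 1e2),
                          nu=2.5)
            + WhiteKernel(noise_level=1e-10,
                          noise_level_bounds=(1e-14, 1e-2)),
            normalize_y=True, n_restarts_optimizer=2,
            random_state=int(rng.integers(2 ** 31 - 1)))
        with warnings.catch_warnings():
            # the GP is only an acquisition surrogate; kernel-hyperparameter
            # convergence chatter is not actionable here
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(to_unit(xs).reshape(-1, 1), np.asarray(ys))
        best_idx = int(np.argmin(ys))
        best_x, best_y = xs[best_idx], ys[best_idx]
        # candidate pool: global uniform plus local refinements around the
        # incumbent so exploitation can localize the minimum finely
        cand = np.concatenate([
            rng.uniform(0.0, 1.0, size=256),
            np.clip(to_unit(best_x) + rng.normal(0.0, 0.05, size=32), 0, 1),
            np.clip(to_unit(best_x) + rng.normal(0.0, 0.005, size=32), 0, 1),
        ])
        mu, sigma = gp.predict(cand.reshape(-1, 1), return_std=True)
        ei = _expected_improvement(mu, sigma, best_y)
        x_next = lo + span * float(cand[int(np.argmax(ei))])
        if any(abs(x_next - x) < 1e-15 for x in xs):
            x_next = float(np.clip(x_next + rng.normal(0, 1e-6 * span),
                                   lo, hi))
        xs.append(x_next)
        ys.append(objective(x_next))

    best_idx = int(np.argmin(ys))
    return FitResult(family=family, params={param_name: float(xs[best_idx])},
                     objective=float(ys[best_idx]),
                     trace=tuple(zip(map(float, xs), map(float, ys))),
                     budget=budget, seed=seed, divergence=divergence)
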