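"""Probabilistic sensitivity analysis.

Parameters are varied simultaneously: each iteration draws a fresh bundle
from per-parameter distributions (beta for quantities bounded in [0, 1],
gamma for nonnegative costs, lognormal for positive multipliers such as
calibration factors, uniform where stated), reruns both strategy arms, and
records the incremental cost and effect.  Per-iteration random streams are
derived from (seed, iteration), so iterations are independent and the
sample set does not depend on execution order.

Summaries: the cost-effectiveness plane (one point per iteration) and the
acceptability curve, the probability that the intervention's net monetary
benefit lambda * dE - dC is nonnegative as a function of the
willingness-to-pay lambda (ties count as cost-effective).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import economics, markov
from .params import ModelBundle, RiskProfile, ValidationError

__all__ = [
    "DistributionSpec",
    "PSASample",
    "PSAResult",
    "CEACCurve",
    "default_wtp_grid",
    "sample_bundle",
    "run_psa",
    "ceac",
    "ce_plane_export",
]

logger = logging.getLogger(__name__)

_FAMILIES = ("beta", "gamma", "lognormal", "uniform")

#: parameter-path suffixes that must stay within [0, 1] (probabilities,
#: utilities, efficacy fractions, coverage) -> beta; costs -> gamma;
#: positive multipliers (cf) -> lognormal.
_UNIT_INTERVAL_LEAVES = ("utility", "rti_reduction", "fatality_reduction",
                         "checkpoint_coverage", "rti_share")
_COST_LEAVES = ("cost", "checkpoint_unit_cost", "media_cost_per_case",
                "media_total_cost")
_MULTIPLIER_LEAVES = ("cf",)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one scalar parameter, addressed by its
    dotted path in the bundle (e.g. ``states.POST_WHOLLY_ALC.utility`` or
    ``hazards.ALC_DEATH.cf``)."""

    path: str
    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(
                f"{self.path}: unknown distribution family {self.family!r}")
        leaf = self.path.rsplit(".", 1)[-1]
        if leaf in _UNIT_INTERVAL_LEAVES and self.family not in ("beta", "uniform"):
            raise ValidationError(
                f"{self.path}: [0,1]-bounded parameters take beta "
                f"distributions, got {self.family}")
        if leaf in _COST_LEAVES and self.family not in ("gamma", "uniform"):
            raise ValidationError(
                f"{self.path}: cost parameters take gamma distributions, "
                f"got {self.family}")
        if leaf in _MULTIPLIER_LEAVES and self.family not in ("lognormal", "uniform"):
            raise ValidationError(
                f"{self.path}: positive multipliers take lognormal "
                f"distributions, got {self.family}")

    def draw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "beta":
            if p["alpha"] <= 0 or p["beta"] <= 0:
                return p.get("loc", 0.0)  # degenerate: point mass at mean
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "gamma":
            if p["shape"] <= 0 or p["scale"] <= 0:
                return p.get("loc", 0.0)
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        return float(rng.uniform(p["low"], p["high"]))

    @classmethod
    def point_mass(cls, path: str, value: float) -> "DistributionSpec":
        """Zero-variance spec (degenerate uniform at ``value``)."""
        return cls(path=path, family="uniform",
                   params={"low": value, "high": value})


@dataclass
class PSASample:
    iteration: int
    delta_cost: float
    delta_effect: float


@dataclass
class PSAResult:
    samples: list[PSASample]
    n_failures: int
    seed: int

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        dc = np.array([s.delta_cost for s in self.samples])
        de = np.array([s.delta_effect for s in self.samples])
        return dc, de

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iteration": [s.iteration for s in self.samples],
             "delta_cost": [s.delta_cost for s in self.samples],
             "delta_effect": [s.delta_effect for s in self.samples]})


@dataclass
class CEACCurve:
    """Probability the intervention is optimal per willingness-to-pay."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.wtp = np.asarray(self.wtp, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any(np.diff(self.wtp) <= 0):
            raise ValidationError("wtp grid must be strictly ascending")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValidationError("probabilities must be in [0, 1]")

    def at(self, wtp: float) -> float:
        idx = np.flatnonzero(np.isclose(self.wtp, wtp))
        if idx.size == 0:
            raise ValidationError(f"wtp {wtp} not on the grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def default_wtp_grid(stop: float = 400_000.0, step: float = 2_000.0) -> np.ndarray:
    """0..stop in THB/QALY steps of 2,000; includes the 160,000 threshold
    exactly."""
    return np.arange(0.0, stop + step / 2, step)


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def sample_bundle(specs: Sequence[DistributionSpec], base: ModelBundle,
                  seed: int, iteration: int,
                  max_attempts: int = 100) -> ModelBundle:
    """Draw one bundle: the base bundle with each spec'd parameter replaced
    by a sample.  Reproducible from (seed, iteration).  Draws that violate
    a type invariant are rejected and redrawn, up to ``max_attempts``."""
    rng = _iteration_rng(seed, iteration)
    bundle = base.copy()
    for spec in specs:
        base.get_path(spec.path)  # raises on unknown path
        for _ in range(max_attempts):
            value = spec.draw(rng)
            try:
                bundle.set_path(spec.path, value)
                break
            except ValidationError:
                continue
        else:
            raise ValidationError(
                f"{spec.path}: no valid draw in {max_attempts} attempts")
    bundle.validate()
    return bundle


def run_psa(bundle: ModelBundle, specs: Sequence[DistributionSpec],
            profile: RiskProfile, n_iter: int = 5_000, seed: int = 0,
            log_every: int = 1_000) -> PSAResult:
    """Monte Carlo PSA: per iteration, sample a bundle, run both arms,
    record (delta cost, delta effect).  Failed iterations are logged,
    excluded, and counted."""
    if n_iter < 1:
        raise ValidationError(f"n_iter must be >= 1, got {n_iter}")
    samples: list[PSASample] = []
    failures = 0
    for i in range(n_iter):
        try:
            b = sample_bundle(specs, bundle, seed, i)
            inc = _incremental_for(b, profile)
            samples.append(PSASample(iteration=i, delta_cost=inc.delta_cost,
                                     delta_effect=inc.delta_effect))
        except Exception as exc:  # noqa: BLE001 - record and continue
            failures += 1
            logger.warning("PSA iteration %d failed: %s", i, exc)
        if log_every and (i + 1) % log_every == 0:
            logger.info("PSA progress: %d/%d iterations", i + 1, n_iter)
    return PSAResult(samples=samples, n_failures=failures, seed=seed)


def _incremental_for(bundle: ModelBundle,
                     profile: RiskProfile) -> economics.IncrementalResult:
    results = {}
    for arm in (markov.MEDIA_ONLY, markov.RBT_PLUS_MEDIA):
        trace = markov.run_cohort(bundle, profile, arm)
        results[arm.label] = economics.accumulate(
            trace, bundle.states,
            economics.arm_annual_cost(bundle.intervention_costs, arm),
            bundle.economics, bundle.options)
    return economics.incremental(results[markov.MEDIA_ONLY.label],
                                 results[markov.RBT_PLUS_MEDIA.label])


def ceac(result: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Acceptability curve: fraction of iterations with nonnegative net
    monetary benefit lambda * dE - dC at each grid point (ties count as
    cost-effective)."""
    if not result.samples:
        raise ValidationError("CEAC requires at least one PSA sample")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    dc, de = result.as_arrays()
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return CEACCurve(wtp=grid, probability=prob)


def ce_plane_export(result: PSAResult, wtp_threshold: float,
                    out_dir: str | Path,
                    stem: str = "ce_plane") -> float:
    """Write the cost-effectiveness plane: samples CSV plus a scatter of
    (delta effect, delta cost) with the willingness-to-pay diagonal.

    Returns the fraction of iterations on or below the diagonal, i.e. with
    dC <= lambda * dE -- identical by definition to the CEAC value at the
    threshold.
    """
    if not result.samples:
        raise ValidationError("CE plane requires at least one PSA sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = result.to_frame()
    df.to_csv(out_dir / f"{stem}_samples.csv", index=False)

    dc, de = result.as_arrays()
    below = float((dc <= wtp_threshold * de).mean())

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(de, dc, s=6, alpha=0.4, edgecolors="none")
    lim = max(abs(de).max(), 1e-9)
    xs = np.array([-lim * 1.1, lim * 1.1])
    ax.plot(xs, wtp_threshold * xs, "k--", lw=1,
            label=f"WTP = {wtp_threshold:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (THB)")
    ax.set_title(f"Cost-effectiveness plane "
                 f"({below:.0%} at or below threshold)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / f"{stem}.png", dpi=150)
    plt.close(fig)
    return below
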