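"""Synthetic circadian time-course expression data.

Generates gene × sample matrices with known ground-truth collection times.
Rhythmic genes follow a 24-h cosine

    f(t) = A * cos(2*pi/24 * (t + phi)) + (A/sigma) * s,   s ~ N(0, 1)

with amplitude A ~ U(0.5, 1), phase shift phi ~ U(0, 24) hours and
signal-to-noise ratio sigma ~ U(2, 5).  Non-rhythmic genes are pure scaled
Gaussian noise, f = A * s.  Each dataset holds 200 rhythmic and 800
non-rhythmic genes on a sampling grid defined by a span, an interval, a
number of randomly missing grid points and a replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PERIOD_H = 24.0
N_RHYTHMIC = 200
N_NOISE = 800

__all__ = [
    "SamplingDesign",
    "TimeGrid",
    "GeneProfileParams",
    "SyntheticDataset",
    "BENCHMARK_DESIGNS",
    "build_time_grid",
    "simulate_gene",
    "simulate_dataset",
]


class InvalidDesignError(ValueError):
    """Raised when a sampling design cannot produce a valid time grid."""


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling scheme for one synthetic dataset.

    ``interval_hours is None`` marks a non-uniform design: ``n_samples``
    collection times are drawn i.i.d. uniformly over the span and sorted.
    """

    span_hours: float
    interval_hours: float | None
    n_missing_timepoints: int = 0
    n_replicates: int = 1
    name: str = "custom"
    n_samples: int | None = None  # required for non-uniform designs

    def __post_init__(self):
        if self.span_hours <= 0:
            raise InvalidDesignError("span_hours must be positive")
        if self.interval_hours is not None:
            if self.interval_hours <= 0:
                raise InvalidDesignError("interval_hours must be positive")
            if self.interval_hours > self.span_hours:
                raise InvalidDesignError("interval_hours exceeds span_hours")
            n_grid = int(np.ceil(self.span_hours / self.interval_hours - 1e-9))
            if self.n_missing_timepoints >= n_grid:
                raise InvalidDesignError(
                    f"{self.n_missing_timepoints} missing points >= "
                    f"{n_grid} grid points"
                )
        else:
            if self.n_samples is None:
                raise InvalidDesignError(
                    "non-uniform designs need an explicit n_samples"
                )
        if self.n_missing_timepoints < 0:
            raise InvalidDesignError("n_missing_timepoints must be >= 0")
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be >= 1")


@dataclass(frozen=True)
class TimeGrid:
    """Ordered collection times in hours, one per generated sample."""

    times: np.ndarray
    removed_indices: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GeneProfileParams:
    amplitude: float
    phase_shift: float = 0.0
    snr: float = np.inf
    is_rhythmic: bool = True


@dataclass
class SyntheticDataset:
    """Expression matrix plus the ground truth that generated it."""

    expression: pd.DataFrame  # genes x samples
    true_times: np.ndarray  # hours, one per sample
    gene_params: list[GeneProfileParams]
    rng_seed: int
    design: SamplingDesign = field(default=None)

    @property
    def rhythmic_mask(self) -> np.ndarray:
        return np.array([p.is_rhythmic for p in self.gene_params])

    @property
    def true_phase_h(self) -> np.ndarray:
        """Circadian phase of each sample: collection time modulo 24 h."""
        return np.mod(self.true_times, PERIOD_H)


#: The twelve benchmark designs (full 24/48-h cycles, missing points,
#: non-uniform sampling, and incomplete 14/18-h spans).
BENCHMARK_DESIGNS: dict[str, SamplingDesign] = {
    "SynDST1": SamplingDesign(24, 2, 0, 2, "SynDST1"),
    "SynDST2": SamplingDesign(24, 4, 0, 3, "SynDST2"),
    "SynDST3": SamplingDesign(24, 2, 2, 2, "SynDST3"),
    "SynDST4": SamplingDesign(24, None, 0, 1, "SynDST4", n_samples=24),
    "SynDST5": SamplingDesign(48, 1, 0, 1, "SynDST5"),
    "SynDST6": SamplingDesign(48, 2, 0, 2, "SynDST6"),
    "SynDST7": SamplingDesign(48, 4, 0, 3, "SynDST7"),
    "SynDST8": SamplingDesign(48, 2, 3, 2, "SynDST8"),
    "SynDST9": SamplingDesign(48, None, 0, 1, "SynDST9", n_samples=48),
    "SynDST10": SamplingDesign(14, 1, 0, 1, "SynDST10"),
    "SynDST11": SamplingDesign(18, 1, 0, 1, "SynDST11"),
    "SynDST12": SamplingDesign(18, 2, 0, 2, "SynDST12"),
}


def build_time_grid(design: SamplingDesign, rng: np.random.Generator) -> TimeGrid:
    """Materialize the ordered sample times of a sampling design.

    Uniform designs place grid points at 0, interval, 2*interval, ... within
    [0, span), drop ``n_missing_timepoints`` of them at random, and repeat
    each survivor ``n_replicates`` times.  Non-uniform designs draw
    ``n_samples`` times uniformly over [0, span) and sort them.
    """
    if design.interval_hours is None:
        times = np.sort(rng.uniform(0.0, design.span_hours, design.n_samples))
        return TimeGrid(times=times)

    grid = np.arange(0.0, design.span_hours - 1e-9, design.interval_hours)
    removed: tuple[int, ...] = ()
    if design.n_missing_timepoints > 0:
        removed = tuple(
            sorted(
                rng.choice(
                    len(grid), size=design.n_missing_timepoints, replace=False
                ).tolist()
            )
        )
        grid = np.delete(grid, removed)
    times = np.repeat(grid, design.n_replicates)
    return TimeGrid(times=times, removed_indices=removed)


def simulate_gene(
    params: GeneProfileParams,
    grid: TimeGrid,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one gene's expression over the grid.

    Rhythmic: A*cos(2*pi/24*(t+phi)) + (A/snr)*s.  Non-rhythmic: A*s.
    A ``None`` rng (or infinite snr) disables the noise term.
    """
    t = np.asarray(grid.times, dtype=float)
    if len(t) == 0:
        raise ValueError("time grid is empty")
    noise = rng.standard_normal(len(t)) if rng is not None else np.zeros(len(t))
    a = params.amplitude
    if params.is_rhythmic:
        signal = a * np.cos(2.0 * np.pi / PERIOD_H * (t + params.phase_shift))
        scale = 0.0 if np.isinf(params.snr) else a / params.snr
        return signal + scale * noise
    return a * noise


def simulate_dataset(
    design: SamplingDesign,
    seed: int,
    n_rhythmic: int = N_RHYTHMIC,
    n_noise: int = N_NOISE,
) -> SyntheticDataset:
    """Generate a full synthetic dataset for one design.

    All randomness flows from a single generator seeded with ``seed``; the
    draw order is fixed (grid, then per-gene parameters, then per-gene noise)
    so identical seeds give bitwise-identical datasets.
    """
    rng = np.random.default_rng(seed)
    grid = build_time_grid(design, rng)
    n_total = n_rhythmic + n_noise

    amplitudes = rng.uniform(0.5, 1.0, n_total)
    phases = rng.uniform(0.0, 24.0, n_rhythmic)
    snrs = rng.uniform(2.0, 5.0, n_rhythmic)

    gene_params: list[GeneProfileParams] = []
    for i in range(n_rhythmic):
        gene_params.append(
            GeneProfileParams(amplitudes[i], phases[i], snrs[i], True)
        )
    for i in range(n_rhythmic, n_total):
        gene_params.append(
            GeneProfileParams(amplitudes[i], is_rhythmic=False)
        )

    rows = [simulate_gene(p, grid, rng) for p in gene_params]
    gene_ids = [
        f"rhy_{i + 1:04d}" if i < n_rhythmic else f"noise_{i - n_rhythmic + 1:04d}"
        for i in range(n_total)
    ]
    sample_ids = [f"s{j + 1:03d}_t{grid.times[j]:05.1f}" for j in range(len(grid))]
    expr = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    return SyntheticDataset(
        expression=expr,
        true_times=np.asarray(grid.times, dtype=float),
        gene_params=gene_params,
        rng_seed=seed,
        design=design,
    )
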