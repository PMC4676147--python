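"""Synthetic multi-sample aCGH benchmark: D = X + E + epsilon.

Twelve scenarios combine six recurrent-CNV layouts (gains/losses of true
magnitude 1 shared by decades of samples within probe windows 76-125 of a
50 x 300 matrix) with two noise models: Gaussian noise with sigma = 0.3
(cases 1-6) and heavy-tailed 0.5 * t(1) noise (cases 7-12; a Cauchy scale
family with no finite variance, standing in for severe contamination).
Case k and case k+6 share the same recurrent layout.

On top of the recurrent matrix X, every sample carries exactly one
individual-specific CNV: a 20-probe segment placed uniformly at random
outside the case's recurrent probe columns, with a constant amplitude drawn
uniformly from {-2, -1, 1, 2}.  The generator therefore follows a mean-shift
contamination model — deliberately *not* the weighting model the estimator
assumes — so benchmark results speak to misspecification robustness.

Layouts are read from the versioned ``data/case_layouts.json`` shipped with
the package; no block structure is hard-coded in logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence, Tuple

import numpy as np

from .io import LogRatioMatrix

__all__ = [
    "CaseSpec",
    "SimDataset",
    "NoiseSpec",
    "load_case_spec",
    "case_truth",
    "recurrent_columns",
    "draw_individual_effects",
    "draw_noise",
    "simulate_dataset",
    "SEGMENT_LENGTH",
    "AMPLITUDES",
]

SEGMENT_LENGTH = 20
AMPLITUDES = (-2, -1, 1, 2)


@dataclass(frozen=True)
class NoiseSpec:
    kind: str  # "gaussian" | "scaled_t"
    sigma: float = 0.3  # gaussian standard deviation
    scale: float = 0.5  # multiplier of the t draw
    df: float = 1.0  # degrees of freedom of the t distribution


@dataclass(frozen=True)
class CaseSpec:
    """One benchmark scenario: block layout plus noise model."""

    case_id: int
    n: int
    p: int
    blocks: Tuple[Tuple[Tuple[int, int], Tuple[int, int], int], ...]
    noise: NoiseSpec

    def __post_init__(self):
        for (s0, s1), (p0, p1), sign in self.blocks:
            if not (1 <= s0 <= s1 <= self.n and 1 <= p0 <= p1 <= self.p):
                raise ValueError(f"block out of range in case {self.case_id}")
            if sign not in (-1, 1):
                raise ValueError("block sign must be +1 or -1")


@dataclass
class SimDataset:
    """A generated dataset with its ground truth retained."""

    D: LogRatioMatrix
    X_true: np.ndarray
    E_true: np.ndarray
    case_id: int
    seed: int
    noise: NoiseSpec

    @property
    def noise_true(self) -> np.ndarray:
        return self.D.values - self.X_true - self.E_true


@lru_cache(maxsize=1)
def _layouts() -> dict:
    with resources.files("wpla.data").joinpath("case_layouts.json").open() as fh:
        return json.load(fh)


def load_case_spec(case_id: int, n: Optional[int] = None, p: Optional[int] = None) -> CaseSpec:
    """Load a CaseSpec from the packaged layout file."""
    raw = _layouts()
    key = str(case_id)
    if key not in raw["cases"]:
        raise ValueError(f"unknown case id {case_id!r}; expected 1..12")
    entry = raw["cases"][key]
    noise_name = entry["noise"]
    noise_raw = raw["noise"][noise_name]
    noise = NoiseSpec(
        kind=noise_raw["kind"],
        sigma=noise_raw.get("sigma", 0.3),
        scale=noise_raw.get("scale", 0.5),
        df=noise_raw.get("df", 1.0),
    )
    while "same_blocks_as" in entry:
        entry = raw["cases"][str(entry["same_blocks_as"])]
    blocks = tuple(
        ((b["samples"][0], b["samples"][1]), (b["probes"][0], b["probes"][1]), b["sign"])
        for b in entry["blocks"]
    )
    return CaseSpec(
        case_id=case_id,
        n=n if n is not None else raw["n"],
        p=p if p is not None else raw["p"],
        blocks=blocks,
        noise=noise,
    )


def case_truth(case_id: int, n: Optional[int] = None, p: Optional[int] = None) -> np.ndarray:
    """Deterministic ground-truth recurrent matrix: +/-1 inside blocks, 0 elsewhere."""
    spec = load_case_spec(case_id, n=n, p=p)
    X = np.zeros((spec.n, spec.p))
    for (s0, s1), (p0, p1), sign in spec.blocks:
        X[s0 - 1 : s1, p0 - 1 : p1] = sign
    return X


def recurrent_columns(case_id: int, p: Optional[int] = None) -> np.ndarray:
    """Sorted 1-based probe columns belonging to any recurrent block of the case."""
    spec = load_case_spec(case_id, p=p)
    cols: set[int] = set()
    for _, (p0, p1), _ in spec.blocks:
        cols.update(range(p0, p1 + 1))
    return np.array(sorted(cols), dtype=int)


def draw_individual_effects(
    case_id: int,
    rng: np.random.Generator,
    n: Optional[int] = None,
    p: Optional[int] = None,
) -> np.ndarray:
    """One individual-specific CNV per sample.

    Each row gets a single run of :data:`SEGMENT_LENGTH` consecutive probes
    whose 1-based start is drawn uniformly from the positions where the whole
    segment avoids every recurrent probe column of the case, filled with one
    amplitude drawn uniformly from :data:`AMPLITUDES`.
    """
    spec = load_case_spec(case_id, n=n, p=p)
    banned = np.zeros(spec.p + 1, dtype=bool)  # 1-based
    banned[recurrent_columns(case_id, p=spec.p)] = True
    feasible = [
        s
        for s in range(1, spec.p - SEGMENT_LENGTH + 2)
        if not banned[s : s + SEGMENT_LENGTH].any()
    ]
    if not feasible:
        raise ValueError(f"no feasible individual-segment start for case {case_id}")
    feasible = np.asarray(feasible)
    E = np.zeros((spec.n, spec.p))
    starts = rng.choice(feasible, size=spec.n, replace=True)
    amps = rng.choice(np.asarray(AMPLITUDES, dtype=float), size=spec.n, replace=True)
    for i in range(spec.n):
        s = starts[i]
        E[i, s - 1 : s - 1 + SEGMENT_LENGTH] = amps[i]
    return E


def draw_noise(noise: NoiseSpec, n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. noise matrix: N(0, sigma^2) or scale * t(df)."""
    if noise.kind == "gaussian":
        return rng.normal(0.0, noise.sigma, size=(n, p))
    if noise.kind == "scaled_t":
        return noise.scale * rng.standard_t(noise.df, size=(n, p))
    raise ValueError(f"unknown noise kind {noise.kind!r}")


def simulate_dataset(
    case_id: int,
    seed: int,
    n: Optional[int] = None,
    p: Optional[int] = None,
) -> SimDataset:
    """Assemble D = X + E + epsilon for one case and seed.

    The seed is split into two independent child streams (one for the
    individual effects, one for the noise) so each component is reproducible
    on its own.
    """
    spec = load_case_spec(case_id, n=n, p=p)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(case_id,))
    rng_e, rng_eps = (np.random.default_rng(child) for child in ss.spawn(2))
    X = case_truth(case_id, n=spec.n, p=spec.p)
    E = draw_individual_effects(case_id, rng_e, n=spec.n, p=spec.p)
    eps = draw_noise(spec.noise, spec.n, spec.p, rng_eps)
    D = X + E + eps
    matrix = LogRatioMatrix(
        values=D,
        sample_ids=[f"S{i + 1}" for i in range(spec.n)],
        probe_ids=[f"P{j + 1}" for j in range(spec.p)],
    )
    return SimDataset(D=matrix, X_true=X, E_true=E, case_id=case_id, seed=seed, noise=spec.noise)
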