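"""Synthetic binary input environments.

Patterns are noisy perturbations of category prototypes. A prototype is a
fixed set of input lines valued one; a presented pattern keeps a random
subset of the prototype's lines (off-noise lines are switched off) and
activates a random subset of non-prototype lines (on-noise), so every
pattern carries exactly the same number of active lines.

Two families are provided:

* **A datasets** — 1,000 input lines, five disjoint (orthogonal) prototypes
  of 200 adjacent lines each, heavy noise (100 lines off / 100 on per
  pattern by default).
* **C datasets** — 180 input lines modelling orientation tuning in V1 (one
  line per degree, 180 not 360 because orientation is axial). Eighteen
  prototypes of 20 circularly consecutive lines, each sharing 10 lines with
  each of its two neighbours. The four variants differ only in category
  probabilities: C1/C2 stripe-tilt rearing (45 deg / 135 deg bias), C3
  unbiased retinal waves (prenatal), C4 a normal postnatal environment with
  a mild cardinal-orientation bias.

Presentation is organised in *blocks*: a block contains a fixed, well-mixed
category composition (deterministic per-category counts, uniformly shuffled
order) and each pattern is freshly perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import sample_active_indices

__all__ = [
    "DatasetSpec",
    "PrototypeSet",
    "Block",
    "InputExpectations",
    "build_prototypes",
    "sample_pattern",
    "build_block",
    "block_to_frame",
    "input_line_expectations",
    "noise_to_signal_ratio",
    "category_counts",
    "registry",
    "get_spec",
    "a2_with_noise",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Full parameterization of an input environment."""

    name: str
    n_inputs: int
    n_categories: int
    lines_per_prototype: int
    on_noise: int
    off_noise: int
    category_probs: tuple[float, ...]
    block_size: int
    overlap_per_neighbor: int = 0

    def __post_init__(self) -> None:
        if self.off_noise > self.lines_per_prototype:
            raise ValueError("off_noise exceeds lines_per_prototype")
        if self.on_noise > self.n_inputs - self.lines_per_prototype:
            raise ValueError("on_noise exceeds complement of a prototype")
        if len(self.category_probs) != self.n_categories:
            raise ValueError("category_probs length != n_categories")
        if any(p < 0 for p in self.category_probs) or sum(self.category_probs) <= 0:
            raise ValueError("category_probs must be nonnegative with positive sum")
        if self.overlap_per_neighbor == 0:
            if self.n_categories * self.lines_per_prototype > self.n_inputs:
                raise ValueError("disjoint prototypes do not fit n_inputs")
        else:
            # circular tiling: consecutive prototypes advance by (L - overlap)
            stride = self.lines_per_prototype - self.overlap_per_neighbor
            if stride <= 0 or stride * self.n_categories != self.n_inputs:
                raise ValueError(
                    "circular overlap tiling requires "
                    "(lines_per_prototype - overlap) * n_categories == n_inputs"
                )

    @property
    def active_per_pattern(self) -> int:
        """Active lines per pattern; constant by construction."""
        return self.lines_per_prototype - self.off_noise + self.on_noise

    @property
    def probs(self) -> np.ndarray:
        """Category probabilities normalized to sum to one."""
        p = np.asarray(self.category_probs, dtype=float)
        return p / p.sum()

    @property
    def realized_probs(self) -> np.ndarray:
        """Exact per-block category frequencies (counts / block_size)."""
        return category_counts(self) / self.block_size


@dataclass(frozen=True)
class PrototypeSet:
    """Per-category sets of input lines valued one in the prototype."""

    spec: DatasetSpec
    membership: np.ndarray  # (n_categories, lines_per_prototype) int32 line indices

    def as_bool(self) -> np.ndarray:
        """(n_categories, n_inputs) boolean membership matrix."""
        out = np.zeros((self.spec.n_categories, self.spec.n_inputs), dtype=bool)
        for c in range(self.spec.n_categories):
            out[c, self.membership[c]] = True
        return out

    def complements(self) -> np.ndarray:
        """(n_categories, n_inputs - L) line indices outside each prototype."""
        b = self.as_bool()
        return np.stack([np.flatnonzero(~row) for row in b]).astype(np.int32)


@dataclass
class Block:
    """One block of patterns in randomized presentation order."""

    patterns: np.ndarray  # (block_size, n_inputs) uint8
    labels: np.ndarray  # (block_size,) int32 generating category


@dataclass(frozen=True)
class InputExpectations:
    """Per-line activation probability E[x_i] under the generative process."""

    e_x: np.ndarray


def category_counts(spec: DatasetSpec) -> np.ndarray:
    """Integer per-block pattern counts via largest-remainder rounding.

    Ties on the fractional remainder break toward the lower category index.
    """
    quota = spec.probs * spec.block_size
    counts = np.floor(quota).astype(np.int64)
    short = spec.block_size - int(counts.sum())
    if short > 0:
        remainders = quota - counts
        order = np.lexsort((np.arange(spec.n_categories), -remainders))
        counts[order[:short]] += 1
    return counts


def build_prototypes(spec: DatasetSpec) -> PrototypeSet:
    """Lay out the prototypes on the input lines.

    Disjoint (A-type) prototypes occupy consecutive blocks of lines;
    overlapping (C-type) prototypes tile the lines circularly, category c
    starting at line c * (L - overlap).
    """
    L = spec.lines_per_prototype
    member = np.empty((spec.n_categories, L), dtype=np.int32)
    if spec.overlap_per_neighbor == 0:
        for c in range(spec.n_categories):
            member[c] = np.arange(c * L, (c + 1) * L, dtype=np.int32)
    else:
        stride = L - spec.overlap_per_neighbor
        for c in range(spec.n_categories):
            member[c] = (np.arange(c * stride, c * stride + L) % spec.n_inputs).astype(
                np.int32
            )
    return PrototypeSet(spec=spec, membership=member)


def sample_pattern(
    proto: PrototypeSet, category: int, spec: DatasetSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw one noisy pattern from a category.

    Keeps ``L - off_noise`` prototype lines (uniform, without replacement)
    and turns on ``on_noise`` lines drawn uniformly from the complement of
    the generating prototype.
    """
    if not 0 <= category < spec.n_categories:
        raise ValueError(f"category {category} out of range")
    keep = spec.lines_per_prototype - spec.off_noise
    x = np.zeros(spec.n_inputs, dtype=np.uint8)
    kept = rng.choice(proto.membership[category], size=keep, replace=False)
    x[kept] = 1
    if spec.on_noise:
        comp = proto.complements()[category]
        x[rng.choice(comp, size=spec.on_noise, replace=False)] = 1
    return x


def _block_active_indices(
    proto: PrototypeSet, spec: DatasetSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Active line indices for one block: (labels, (block_size, a) indices).

    Deterministic category composition, shuffled order, fresh noise per
    pattern.  This is the single sampling path used by both the public
    dense-block builder and the development loop, so a given RNG stream
    always yields the same block.
    """
    labels = rng.permutation(
        np.repeat(np.arange(spec.n_categories, dtype=np.int32), category_counts(spec))
    )
    keep = spec.lines_per_prototype - spec.off_noise
    u_keep = rng.random((spec.block_size, keep))
    u_on = rng.random((spec.block_size, spec.on_noise))
    active = sample_active_indices(
        labels, proto.membership, proto.complements(), u_keep, u_on
    )
    return labels, active


def build_block(
    proto: PrototypeSet, spec: DatasetSpec, rng: np.random.Generator
) -> Block:
    """Generate one full block as a dense 0/1 matrix plus labels."""
    labels, active = _block_active_indices(proto, spec, rng)
    patterns = np.zeros((spec.block_size, spec.n_inputs), dtype=np.uint8)
    rows = np.repeat(np.arange(spec.block_size), active.shape[1])
    patterns[rows, active.ravel()] = 1
    return Block(patterns=patterns, labels=labels)


def block_to_frame(block: Block):
    """Dense 0/1 matrix with a leading label column, for inspection/export."""
    import pandas as pd

    frame = pd.DataFrame(
        block.patterns,
        columns=[f"line_{i}" for i in range(block.patterns.shape[1])],
    )
    frame.insert(0, "category", block.labels)
    return frame


def input_line_expectations(proto: PrototypeSet, spec: DatasetSpec) -> InputExpectations:
    """Exact activation probability per input line.

    A line inside the generating prototype survives off-noise with
    probability keep/L; a line outside it is switched on with probability
    on_noise/(n - L).  Summing over categories weighted by the realized
    per-block frequencies gives the marginal.  The total equals the constant
    active-line count.
    """
    p = spec.realized_probs
    member = proto.as_bool()  # (n_cat, n_inputs)
    keep_frac = (spec.lines_per_prototype - spec.off_noise) / spec.lines_per_prototype
    on_frac = spec.on_noise / (spec.n_inputs - spec.lines_per_prototype)
    e_x = np.where(member, keep_frac, on_frac).T @ p
    return InputExpectations(e_x=e_x)


def noise_to_signal_ratio(spec: DatasetSpec) -> float:
    """Active lines outside the generating prototype over active lines inside."""
    signal = spec.lines_per_prototype - spec.off_noise
    if signal <= 0:
        raise ZeroDivisionError("all prototype lines are switched off")
    return spec.on_noise / signal


def _c_spec(name: str, probs: Sequence[float]) -> DatasetSpec:
    return DatasetSpec(
        name=name,
        n_inputs=180,
        n_categories=18,
        lines_per_prototype=20,
        on_noise=5,
        off_noise=5,
        category_probs=tuple(probs),
        block_size=180,
        overlap_per_neighbor=10,
    )


def _c_probs(spec_map: dict[int, float], default: float) -> list[float]:
    # keys are the 1-indexed category labels used for the orientation bins
    return [spec_map.get(c, default) for c in range(1, 19)]


registry: dict[str, DatasetSpec] = {
    "A1": DatasetSpec(
        name="A1",
        n_inputs=1000,
        n_categories=5,
        lines_per_prototype=200,
        on_noise=100,
        off_noise=100,
        category_probs=(0.1, 0.15, 0.2, 0.25, 0.3),
        block_size=100,
    ),
    "A2": DatasetSpec(
        name="A2",
        n_inputs=1000,
        n_categories=5,
        lines_per_prototype=200,
        on_noise=100,
        off_noise=100,
        category_probs=(0.2,) * 5,
        block_size=100,
    ),
    "C1": _c_spec("C1", _c_probs({5: 0.13, 4: 0.1, 6: 0.1}, 0.04)),
    "C2": _c_spec("C2", _c_probs({14: 0.13, 13: 0.1, 15: 0.1}, 0.04)),
    "C3": _c_spec("C3", _c_probs({}, 0.055)),
    "C4": _c_spec(
        "C4", _c_probs({1: 0.088, 9: 0.088, 2: 0.07, 8: 0.07, 10: 0.07, 18: 0.07}, 0.04)
    ),
}


def get_spec(name: str) -> DatasetSpec:
    try:
        return registry[name]
    except KeyError:
        raise KeyError(f"unknown dataset {name!r}; known: {sorted(registry)}") from None


def a2_with_noise(noise: int) -> DatasetSpec:
    """A2 variant with equal on- and off-noise, for noise-to-signal sweeps."""
    base = registry["A2"]
    return DatasetSpec(
        name=f"A2n{noise}",
        n_inputs=base.n_inputs,
        n_categories=base.n_categories,
        lines_per_prototype=base.lines_per_prototype,
        on_noise=noise,
        off_noise=noise,
        category_probs=base.category_probs,
        block_size=base.block_size,
    )
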