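"""Seeded synthetic benchmarks with the structure the predictor assumes.

Windows are (2*xi + 1)-nt strings with C fixed at the center.  Negatives are
drawn i.i.d. from a background nucleotide composition.  Positives are a
mixture: with probability ``signal_strength`` a window carries the planted
signal — flank composition shifted toward a class-specific distribution and
a fixed motif written at a stated offset — otherwise it is drawn from the
background like a negative.  The default motif is periodic (GA repeats)
because the downstream encoding is built from lagged covariances: a periodic
element produces a deterministic lag signature, so at ``signal_strength = 1``
the classes are nearly separable by construction.  At ``signal_strength = 0``
the two classes are exchangeable, so downstream cross-validated MCC
calibrates to ~0.

The generator exercises the pipeline; it makes no attempt to model real m5C
sequence biology (no methyltransferase motifs, no transcriptome composition).
Exact duplicate windows within a class are resampled so the benchmark's
dedup invariants hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .windows import NEGATIVE, POSITIVE, BenchmarkDataset, LabeledWindow

_NUCS = np.array(list("ACGU"))

#: flank composition the positive-class signal shifts toward (A,C,G,U)
_SIGNAL_COMPOSITION = (0.40, 0.10, 0.40, 0.10)

_MAX_RETRIES = 1000


@dataclass(frozen=True)
class SimConfig:
    """Synthetic benchmark parameters.

    Defaults mirror the real benchmark's scale: 475 positives, 1,425
    negatives (1:3 class ratio), xi=20 (41-nt windows), uniform background.
    ``signal_strength`` in [0, 1] is the probability that a positive window
    carries the planted signal; the default 0.8 yields a strongly but not
    perfectly separable problem.  The motif is written starting ``motif_offset``
    positions after the window start (default immediately right of the center).
    """

    n_pos: int = 475
    n_neg: int = 1425
    xi: int = 20
    signal_strength: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str | None = "GAGAGAGA"
    motif_offset: int | None = None  # default: xi + 1 (right of the center C)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise InputError("class sizes must be non-negative")
        if self.xi < 1:
            raise InputError(f"xi must be >= 1, got {self.xi}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise InputError(f"signal_strength must lie in [0, 1], got {self.signal_strength}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise InputError("background must be 4 non-negative probabilities summing to 1")
        if self.motif is not None:
            if set(self.motif) - set("ACGU"):
                raise InputError(f"motif must be over ACGU, got {self.motif!r}")
            off = self.effective_motif_offset
            if off < 0 or off + len(self.motif) > 2 * self.xi + 1:
                raise InputError(
                    f"motif of length {len(self.motif)} at offset {off} does not fit "
                    f"a window of length {2 * self.xi + 1}"
                )

    @property
    def effective_motif_offset(self) -> int:
        return self.xi + 1 if self.motif_offset is None else self.motif_offset


def _draw_window(rng: np.random.Generator, length: int, center: int, probs: np.ndarray) -> str:
    chars = rng.choice(_NUCS, size=length, p=probs)
    chars[center] = "C"
    return "".join(chars)


def simulate_benchmark(config: SimConfig | None = None, **kwargs) -> BenchmarkDataset:
    """Generate a seeded benchmark dataset; identical for identical configs."""
    config = config or SimConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    length = 2 * config.xi + 1
    bg = np.asarray(config.background, dtype=float)
    signal_probs = (1.0 - config.signal_strength) * bg + config.signal_strength * np.asarray(
        _SIGNAL_COMPOSITION
    )
    signal_probs = signal_probs / signal_probs.sum()
    off = config.effective_motif_offset

    def draw_positive() -> str:
        if rng.random() < config.signal_strength:
            w = list(_draw_window(rng, length, config.xi, signal_probs))
            if config.motif:
                w[off : off + len(config.motif)] = config.motif
                w[config.xi] = "C"  # motif may overlap the center; keep the C
            return "".join(w)
        return _draw_window(rng, length, config.xi, bg)

    subsets: dict[str, list[LabeledWindow]] = {POSITIVE: [], NEGATIVE: []}
    for label, n, draw in (
        (POSITIVE, config.n_pos, draw_positive),
        (NEGATIVE, config.n_neg, lambda: _draw_window(rng, length, config.xi, bg)),
    ):
        seen: set[str] = set()
        for i in range(n):
            for attempt in range(_MAX_RETRIES):
                w = draw()
                if w not in seen:
                    break
            else:
                raise InputError(
                    f"could not draw {n} distinct {label} windows after "
                    f"{_MAX_RETRIES} retries; composition too constrained"
                )
            seen.add(w)
            subsets[label].append(
                LabeledWindow(window=w, xi=config.xi, label=label, seq_id=f"sim_{label}", position=i + 1)
            )
    return BenchmarkDataset(positives=subsets[POSITIVE], negatives=subsets[NEGATIVE], xi=config.xi)


def shuffle_labels(dataset: BenchmarkDataset, seed: int) -> BenchmarkDataset:
    """Permute labels over the window multiset, preserving class sizes.

    The null counterpart of a dataset: any real association between window
    content and label is destroyed, so cross-validated MCC should sit near 0.
    """
    if len(dataset) == 0:
        raise InputError("cannot shuffle an empty dataset")
    windows = dataset.windows
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(windows))
    n_pos = len(dataset.positives)
    positives, negatives = [], []
    for rank, idx in enumerate(order):
        w = windows[idx]
        label = POSITIVE if rank < n_pos else NEGATIVE
        bucket = positives if rank < n_pos else negatives
        bucket.append(
            LabeledWindow(window=w.window, xi=w.xi, label=label, seq_id=w.seq_id, position=w.position)
        )
    return BenchmarkDataset(positives=positives, negatives=negatives, xi=dataset.xi)
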