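"""Detection vectors: the sufficient summary consumed by all estimators.

Every sampled offspring names exactly two parents (its mother and father),
so a sample of N_OBS offspring contributes 2·N_OBS parent detections. The
*detection vector* y holds, for each unique detected parent, the number of
sampled offspring naming it. An offspring with no sibling matches adds two
1's; a triad of maternal half-siblings adds a single 3 for the shared
mother and three 1's for the fathers.

The low-order frequency counts a1..a4 (parents seen exactly once..four
times) drive the closed-form Chao estimators; the Bayesian model uses the
full vector.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import OffspringSample

__all__ = ["DetectionVector", "build_detection_vector"]


@dataclass(frozen=True)
class DetectionVector:
    """Per-detected-parent offspring counts plus sample bookkeeping.

    Invariants: ``n_det == len(y)``; ``sum(y) == 2 * n_obs``; every entry
    of ``y`` lies in [1, n_obs].
    """

    y: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "y", y)
        if y.size == 0:
            raise ValueError("detection vector is empty: nothing detected")
        if y.min() < 1:
            raise ValueError("detection counts must be >= 1")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if y.max() > self.n_obs:
            raise ValueError("no parent can be detected more often than n_obs")

    @property
    def n_det(self) -> int:
        return int(self.y.size)

    @property
    def freq(self) -> dict[int, int]:
        """Frequency counts a_k for k = 1..4."""
        return {k: int(np.count_nonzero(self.y == k)) for k in (1, 2, 3, 4)}

    def a(self, k: int) -> int:
        """Number of parents detected exactly k times."""
        return int(np.count_nonzero(self.y == k))

    def histogram(self) -> dict[int, int]:
        """Full frequency-of-frequencies histogram {k: #parents seen k times}."""
        vals, counts = np.unique(self.y, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    # -- serialization ----------------------------------------------------
    def to_files(self, counts_path: str | Path) -> None:
        """Write one count per line plus a JSON sidecar (n_obs, n_det)."""
        counts_path = Path(counts_path)
        counts_path.write_text("\n".join(str(int(v)) for v in self.y) + "\n")
        sidecar = counts_path.with_suffix(counts_path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"n_obs": self.n_obs, "n_det": self.n_det}, indent=2) + "\n"
        )

    @classmethod
    def from_files(
        cls, counts_path: str | Path, n_obs: int | None = None
    ) -> "DetectionVector":
        """Read a single-column count file; n_obs comes from the JSON sidecar,
        the explicit argument, or (last resort) sum(y)/2."""
        counts_path = Path(counts_path)
        y = np.array(
            [int(v) for v in counts_path.read_text().split()], dtype=int
        )
        if n_obs is None:
            sidecar = counts_path.with_suffix(counts_path.suffix + ".json")
            if sidecar.exists():
                n_obs = int(json.loads(sidecar.read_text())["n_obs"])
            else:
                total = int(y.sum())
                if total % 2:
                    raise ValueError(
                        "cannot infer n_obs: sum(y) is odd and no sidecar/"
                        "explicit n_obs given"
                    )
                n_obs = total // 2
        return cls(y, n_obs)


def build_detection_vector(sample: OffspringSample) -> DetectionVector:
    """Tally parent detections in a sample into a DetectionVector.

    The order of y is irrelevant downstream; counts are emitted in
    descending order for readability.
    """
    if sample.n_obs == 0:
        raise ValueError("cannot build a detection vector from an empty sample")
    counts = Counter(sample.mother_id)
    counts.update(sample.father_id)
    y = np.sort(np.array(list(counts.values()), dtype=int))[::-1]
    return DetectionVector(y, sample.n_obs)
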