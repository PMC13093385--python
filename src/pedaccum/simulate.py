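"""Breeding-cohort simulation for pedigree-accumulation studies.

Emulates the reproductive ecology of a semelparous, polygynandrous spawning
population (salmonid-like defaults): each female takes a zero-truncated
Poisson number of distinct male mates, produces a uniformly distributed
total number of offspring split among those mates, and the resulting cohort
is sampled without replacement to mimic juvenile collection.

The cohort is held in a compact mating-pair representation (one row per
realized female x male pair with an offspring count) so that cohorts of a
million offspring cost a few kilobytes; individual offspring are only
materialized when a sample is drawn.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BreedingScenario",
    "CohortPedigree",
    "OffspringSample",
    "simulate_breeding",
    "sample_offspring",
    "zero_truncated_poisson",
]


@dataclass(frozen=True)
class BreedingScenario:
    """Configuration of one breeding population.

    Parameters
    ----------
    n_females, n_males
        Number of adult females and males. Their sum is the true parental
        abundance N_P, the estimand of every estimator in this package.
    mate_lambda
        Mean of the (zero-truncated) Poisson distribution of mates per
        female. Default 4, a typical salmonid polygynandry level.
    fecundity_min, fecundity_max
        Inclusive bounds of the discrete-uniform per-female offspring total.
        Defaults 2500-6500 emulate salmonid egg production.
    seed
        Seed for the scenario's random stream when no generator is passed
        explicitly.
    """

    n_females: int
    n_males: int
    mate_lambda: float = 4.0
    fecundity_min: int = 2500
    fecundity_max: int = 6500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("need at least one adult of each sex")
        if self.fecundity_min > self.fecundity_max:
            raise ValueError("fecundity_min must be <= fecundity_max")
        if self.fecundity_min < 1:
            raise ValueError("fecundity_min must be >= 1")
        if not self.mate_lambda > 0:
            raise ValueError("mate_lambda must be > 0")

    @property
    def true_n_p(self) -> int:
        return self.n_females + self.n_males


@dataclass
class CohortPedigree:
    """A simulated offspring cohort in mating-pair form.

    ``pair_mothers[k]``, ``pair_fathers[k]`` are integer parent indices
    (0-based within each sex) and ``pair_counts[k]`` the number of offspring
    of that pair. Every configured adult is guaranteed to parent at least
    one offspring, so ``true_n_p`` equals the configured total.
    """

    pair_mothers: np.ndarray
    pair_fathers: np.ndarray
    pair_counts: np.ndarray
    n_females: int
    n_males: int

    @property
    def n_offspring(self) -> int:
        return int(self.pair_counts.sum())

    @property
    def true_n_p(self) -> int:
        return self.n_females + self.n_males

    def female_offspring_totals(self) -> np.ndarray:
        """Per-female total offspring counts (length n_females)."""
        return np.bincount(
            self.pair_mothers, weights=self.pair_counts, minlength=self.n_females
        ).astype(int)

    def parent_sex(self, parent_id: str) -> str:
        if parent_id.startswith("F"):
            return "female"
        if parent_id.startswith("M"):
            return "male"
        raise ValueError(f"unrecognized parent id {parent_id!r}")


@dataclass
class OffspringSample:
    """A sample of offspring with their (possibly error-perturbed) parent IDs.

    Parent IDs are strings prefixed ``F`` (mothers) or ``M`` (fathers); the
    prefix encodes the sex of the parent slot and survives error injection.
    """

    offspring_id: np.ndarray  # dtype=object, unique
    mother_id: np.ndarray  # dtype=object, all 'F...'
    father_id: np.ndarray  # dtype=object, all 'M...'

    def __post_init__(self) -> None:
        n = len(self.offspring_id)
        if len(self.mother_id) != n or len(self.father_id) != n:
            raise ValueError("parallel arrays must share length")
        if len(set(self.offspring_id)) != n:
            raise ValueError("offspring ids must be distinct")

    @property
    def n_obs(self) -> int:
        return len(self.offspring_id)

    def copy(self) -> "OffspringSample":
        return OffspringSample(
            self.offspring_id.copy(), self.mother_id.copy(), self.father_id.copy()
        )

    def to_tsv(self, path: str | Path | io.TextIOBase) -> None:
        """Write the sample as a 3-column tab-delimited file with header."""
        lines = ["offspring_id\tmother_id\tfather_id"]
        for o, m, f in zip(self.offspring_id, self.mother_id, self.father_id):
            lines.append(f"{o}\t{m}\t{f}")
        text = "\n".join(lines) + "\n"
        if isinstance(path, io.TextIOBase):
            path.write(text)
        else:
            Path(path).write_text(text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OffspringSample":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].split("\t") != ["offspring_id", "mother_id", "father_id"]:
            raise ValueError(f"{path}: expected header 'offspring_id\\tmother_id\\tfather_id'")
        rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
        if any(len(r) != 3 for r in rows):
            raise ValueError(f"{path}: malformed row (need 3 tab-separated columns)")
        cols = list(zip(*rows)) if rows else ([], [], [])
        return cls(
            np.array(cols[0], dtype=object),
            np.array(cols[1], dtype=object),
            np.array(cols[2], dtype=object),
        )


def zero_truncated_poisson(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a Poisson(lam) conditioned on being >= 1 (rejection)."""
    out = rng.poisson(lam, size)
    while True:
        zero = out == 0
        n_zero = int(zero.sum())
        if n_zero == 0:
            return out
        out[zero] = rng.poisson(lam, n_zero)


def simulate_breeding(
    scenario: BreedingScenario, rng: np.random.Generator | None = None
) -> CohortPedigree:
    """Simulate one breeding event and return the resulting cohort pedigree.

    Mating is female-driven: each female draws a zero-truncated Poisson
    mate count (capped at the number of males) and picks that many distinct
    males uniformly; any male left unmated is then assigned one uniformly
    chosen female, whose mate set grows by one. Each female's fecundity is
    discrete-uniform on [fecundity_min, fecundity_max] and is split among
    her realized mates multinomially with equal probabilities, after giving
    each mate one guaranteed offspring so that no mating is sterile. These
    two devices together guarantee every configured adult is a true parent,
    making the configured N_P exactly the estimand.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    nf, nm = scenario.n_females, scenario.n_males

    mate_counts = zero_truncated_poisson(scenario.mate_lambda, nf, rng)
    mate_counts = np.minimum(mate_counts, nm)
    mates: list[np.ndarray] = [
        rng.choice(nm, size=int(m), replace=False) for m in mate_counts
    ]

    mated = np.zeros(nm, dtype=bool)
    for ms in mates:
        mated[ms] = True
    for male in np.flatnonzero(~mated):
        f = int(rng.integers(nf))
        mates[f] = np.append(mates[f], male)

    pair_mothers: list[int] = []
    pair_fathers: list[int] = []
    pair_counts: list[int] = []
    fec = rng.integers(scenario.fecundity_min, scenario.fecundity_max + 1, size=nf)
    for f in range(nf):
        ms = mates[f]
        k = len(ms)
        total = int(fec[f])
        if total < k:
            raise ValueError(
                f"female {f} has {k} mates but fecundity {total}; "
                "raise fecundity_min or lower mate_lambda"
            )
        # one guaranteed offspring per mate, remainder split evenly at random
        counts = np.ones(k, dtype=int) + rng.multinomial(total - k, np.full(k, 1.0 / k))
        pair_mothers.extend([f] * k)
        pair_fathers.extend(ms.tolist())
        pair_counts.extend(counts.tolist())

    return CohortPedigree(
        np.asarray(pair_mothers),
        np.asarray(pair_fathers),
        np.asarray(pair_counts),
        nf,
        nm,
    )


def sample_offspring(
    pedigree: CohortPedigree, n_obs: int, rng: np.random.Generator | None = None
) -> OffspringSample:
    """Draw a uniform without-replacement sample of ``n_obs`` offspring.

    Pair-level counts are drawn from the multivariate hypergeometric
    distribution (exact uniform sampling from the pooled cohort), then
    distinct within-pair indices are assigned so offspring IDs are unique.
    """
    if rng is None:
        rng = np.random.default_rng()
    total = pedigree.n_offspring
    if n_obs > total:
        raise ValueError(f"n_obs={n_obs} exceeds cohort size {total}")
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    taken = rng.multivariate_hypergeometric(pedigree.pair_counts, n_obs)
    oid: list[str] = []
    mid: list[str] = []
    fid: list[str] = []
    for k in np.flatnonzero(taken):
        m = int(pedigree.pair_mothers[k])
        f = int(pedigree.pair_fathers[k])
        idx = rng.choice(int(pedigree.pair_counts[k]), size=int(taken[k]), replace=False)
        for j in np.sort(idx):
            oid.append(f"F{m}xM{f}:{j}")
            mid.append(f"F{m}")
            fid.append(f"M{f}")
    return OffspringSample(
        np.array(oid, dtype=object), np.array(mid, dtype=object), np.array(fid, dtype=object)
    )


def split_sex_ratio(n_p: int, ratio_males: float = 1.0, ratio_females: float = 1.0) -> tuple[int, int]:
    """Split a total adult abundance into (n_females, n_males) by a male:female
    ratio, assigning the integer remainder to males."""
    if n_p < 2:
        raise ValueError("n_p must be >= 2 to have one adult of each sex")
    n_females = int(np.floor(n_p * ratio_females / (ratio_males + ratio_females)))
    n_females = max(1, min(n_p - 1, n_females))
    return n_females, n_p - n_females


def write_sidecar(path: str | Path, meta: dict) -> None:
    """Write a provenance JSON sidecar next to an output file."""
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
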