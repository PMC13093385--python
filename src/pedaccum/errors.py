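"""Pedigree-reconstruction error injection.

Real sibship reconstruction from genotypes is imperfect. Two failure modes
matter for accumulation estimators:

* **Type I (false positive)** — two unrelated offspring are inferred to
  share a parent. This merges two true parents into one and can only occur
  plausibly for offspring with no detected siblings, since sibling context
  would contradict the false link. Each flip reduces the number of detected
  parents.
* **Type II (false negative)** — a true shared-parent link is missed, so an
  offspring's parent is split off as a brand-new singleton parent. Only
  offspring that actually have a detected sibling are at risk. Each flip
  can only increase the number of detected parents.

Both injectors evaluate eligibility once on the input sample, then flip each
parent slot of each eligible offspring independently with the given rate,
mirroring a subset-then-draw protocol. The input sample is never mutated.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .simulate import OffspringSample

__all__ = ["inject_type1", "inject_type2"]

logger = logging.getLogger(__name__)


def _slot_counts(sample: OffspringSample) -> tuple[Counter, Counter]:
    return Counter(sample.mother_id), Counter(sample.father_id)


def _check_rate(rate: float) -> None:
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"error rate must be in [0, 1], got {rate}")


def inject_type1(
    sample: OffspringSample, rate: float, rng: np.random.Generator | None = None
) -> OffspringSample:
    """Inject false-positive sibship errors at the given per-parent rate.

    Eligible offspring are those sharing neither parent with any other
    sampled offspring ("true negatives"). For each eligible offspring, each
    of its two parents is flipped independently with probability ``rate``;
    a flipped parent is replaced by a uniformly chosen *different* parent of
    the same sex drawn from the unique-parent pool of the original sample.
    If no alternative same-sex parent exists the slot is left unchanged and
    a warning is logged.
    """
    _check_rate(rate)
    if rng is None:
        rng = np.random.default_rng()
    out = sample.copy()
    if rate == 0.0 or sample.n_obs == 0:
        return out
    mcount, fcount = _slot_counts(sample)
    eligible = [
        i
        for i in range(sample.n_obs)
        if mcount[sample.mother_id[i]] == 1 and fcount[sample.father_id[i]] == 1
    ]
    mother_pool = sorted(mcount)
    father_pool = sorted(fcount)
    for i in eligible:
        for ids, pool in ((out.mother_id, mother_pool), (out.father_id, father_pool)):
            if rng.random() >= rate:
                continue
            alternatives = [p for p in pool if p != ids[i]]
            if not alternatives:
                logger.warning(
                    "type-I flip requested for offspring %s but no alternative "
                    "same-sex parent exists in the sample; slot left unchanged",
                    out.offspring_id[i],
                )
                continue
            ids[i] = alternatives[int(rng.integers(len(alternatives)))]
    return out


def inject_type2(
    sample: OffspringSample, rate: float, rng: np.random.Generator | None = None
) -> OffspringSample:
    """Inject false-negative sibship errors at the given per-parent rate.

    Eligible offspring are those with at least one sampled sibling (sharing
    a mother or father with another offspring). Each of their two parents is
    flipped independently with probability ``rate``; a flipped parent
    becomes a brand-new same-sex parent ID unique to that offspring, as if
    the shared-parent link had been missed.
    """
    _check_rate(rate)
    if rng is None:
        rng = np.random.default_rng()
    out = sample.copy()
    if rate == 0.0 or sample.n_obs == 0:
        return out
    mcount, fcount = _slot_counts(sample)
    eligible = [
        i
        for i in range(sample.n_obs)
        if mcount[sample.mother_id[i]] > 1 or fcount[sample.father_id[i]] > 1
    ]
    novel = 0
    for i in eligible:
        for ids, prefix in ((out.mother_id, "F"), (out.father_id, "M")):
            if rng.random() < rate:
                ids[i] = f"{prefix}novel{novel}:{out.offspring_id[i]}"
                novel += 1
    return out
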