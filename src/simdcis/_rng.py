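"""Per-woman, per-purpose random streams.

The paired-cohort design compares a screened and an unscreened arm built
from the *same* latent life course, and compares policy variants on the
same cohorts (common random numbers).  That only works if every source of
randomness is addressable: woman ``i`` of cohort ``c`` always sees the same
deviates, regardless of cohort size, policy, or which other draws happened
first.

Streams are counter-based: one Philox engine per ``(seed, purpose)``
(keyed through :class:`numpy.random.SeedSequence`), with each woman owning
a fixed, disjoint block of the counter space.  Disjoint counter blocks of
a keyed Philox stream are independent by construction, and a whole
cohort's deviates can be drawn in a single vectorised call while staying
bit-identical to the per-woman view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Stream purposes.  natural_history drives the latent life course,
#: attendance the per-round show-up draws, screen_test the per-round
#: mammography sensitivity draws.
PURPOSES = ("natural_history", "attendance", "screen_test")
_PURPOSE_CODE = {name: i for i, name in enumerate(PURPOSES)}

#: Fixed number of deviates drawn per woman for round-indexed purposes
#: (attendance, screen_test).  Round j of any schedule consumes deviate j,
#: so policies sharing a seed share deviates by round index.  25 rounds is
#: the densest schedule considered (annual, ages 50-74); 32 leaves headroom.
N_ROUND_SLOTS = 32

#: Uniform slots consumed per annual cycle of the latent chain, in the
#: documented event order: 0=death, 1=onset-or-progression, 2=clinical
#: detection, 3=regression.
N_CYCLE_SLOTS = 4

#: 64-bit words reserved per woman and purpose (one word per uniform
#: double).  natural_history uses (max_age+1) * N_CYCLE_SLOTS = 404 words
#: for max_age 100; strides must be multiples of 4 words (one Philox
#: counter increment yields 4 words).
_STRIDE = {"natural_history": 404, "attendance": N_ROUND_SLOTS, "screen_test": N_ROUND_SLOTS}


def _purpose_key(seed: int, purpose: str) -> np.ndarray:
    """128-bit Philox key for one (seed, purpose) pair."""
    ss = np.random.SeedSequence(entropy=(int(seed), _PURPOSE_CODE[purpose]))
    return ss.generate_state(2, np.uint64)


def _bitgen_at(seed: int, purpose: str, woman_id: int) -> np.random.Philox:
    """Philox engine positioned at the start of one woman's counter block.

    ``Philox.advance(d)`` moves the counter by ``d`` increments of 4
    64-bit words, so a stride of S words is ``advance(S // 4)`` per woman.
    """
    stride = _STRIDE[purpose]
    bg = np.random.Philox(key=_purpose_key(seed, purpose))
    if woman_id:
        bg.advance(int(woman_id) * stride // 4)
    return bg


@dataclass(frozen=True)
class RandomStream:
    """Address of one woman's deviate stream for one purpose.

    Distinct ``(master_seed, woman_id, purpose)`` triples yield
    independent streams; identical triples yield identical deviate
    sequences.  At most ``512`` (natural_history) or ``32`` (attendance,
    screen_test) deviates per stream are defined.
    """

    master_seed: int
    woman_id: int
    purpose: str

    def __post_init__(self) -> None:
        if self.purpose not in _PURPOSE_CODE:
            raise ValueError(f"unknown stream purpose {self.purpose!r}")

    def generator(self) -> np.random.Generator:
        return np.random.Generator(
            _bitgen_at(self.master_seed, self.purpose, self.woman_id)
        )


def uniform_block(
    seed: int, woman_ids: np.ndarray, purpose: str, shape: tuple[int, ...]
) -> np.ndarray:
    """Stack each woman's first ``prod(shape)`` uniforms into one array.

    Output has shape ``(len(woman_ids), *shape)``; row k reproduces exactly
    what ``RandomStream(seed, woman_ids[k], purpose).generator().random(shape)``
    would return, so vectorised and per-woman code paths agree bit for bit.
    For a contiguous ascending id range the whole block is one draw of the
    keyed engine.
    """
    woman_ids = np.asarray(woman_ids)
    n = len(woman_ids)
    per_woman = int(np.prod(shape))
    stride = _STRIDE[purpose]
    if per_woman > stride:
        raise ValueError(f"{per_woman} deviates per woman exceeds the {purpose} stride {stride}")
    contiguous = n > 0 and np.array_equal(woman_ids, np.arange(woman_ids[0], woman_ids[0] + n))
    if contiguous:
        gen = np.random.Generator(_bitgen_at(seed, purpose, int(woman_ids[0])))
        block = gen.random((n, stride))
        if per_woman < stride:
            block = np.ascontiguousarray(block[:, :per_woman])
        return block.reshape((n,) + shape)
    out = np.empty((n,) + shape, dtype=np.float64)
    for k, w in enumerate(woman_ids):
        out[k] = np.random.Generator(_bitgen_at(seed, purpose, int(w))).random(shape)
    return out


def cohort_seed(master_seed: int, cohort_index: int) -> int:
    """Derive a cohort seed < 2**32 from the scenario master seed."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(cohort_index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])
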