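"""Monte-Carlo synthetic-flock pseudoreplication test.

Field observations of flocking birds carry a pseudoreplication risk:
the same individual might be sampled in more than one flock.  Within a
real flock all members are guaranteed distinct.  The test therefore
compares a real flock's laterality-index scores against those of
simulated flocks of the same size assembled by randomly drawing
individuals from *other* flocks (where hidden repeats are possible).
A non-significant omnibus Kruskal-Wallis H across the real flock and
the simulated flocks is evidence that repeated sampling does not drive
the lateralization results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stats_core import (
    DegenerateInputError,
    InvalidInputError,
    TestResult,
    kruskal_wallis,
    mann_whitney_u,
)

__all__ = ["FlockMCResult", "build_synthetic_flocks", "flock_pseudoreplication_test"]

DEFAULT_N_SIM = 10


@dataclass(frozen=True)
class FlockMCResult:
    real_flock_id: str
    n_members: int
    n_sim: int
    seed: int
    kw: TestResult
    sim_flock_rosters: tuple[tuple[str, ...], ...]
    posthoc_vs_real: tuple[TestResult, ...] | None = None

    def to_record(self) -> dict:
        return {
            "real_flock_id": self.real_flock_id,
            "n_members": self.n_members,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "kw": self.kw.to_record(),
            "sim_flock_rosters": [list(r) for r in self.sim_flock_rosters],
            "posthoc_vs_real": (
                [t.to_record() for t in self.posthoc_vs_real]
                if self.posthoc_vs_real is not None
                else None
            ),
        }


def build_synthetic_flocks(
    real_flock_members: Sequence[str],
    pool: Sequence[str],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> list[list[str]]:
    """Draw ``n_sim`` simulated rosters of the real flock's size.

    Each roster is a uniform without-replacement sample from ``pool``
    (individuals from other flocks), drawn independently across rosters
    so one individual may serve in several simulated flocks — mirroring
    the possibility that distinct flock records hide the same bird.
    Deterministic given ``seed``.
    """
    members = list(real_flock_members)
    pool = list(pool)
    if n_sim < 1:
        raise InvalidInputError("n_sim must be >= 1")
    if not members:
        raise InvalidInputError("real flock is empty")
    overlap = set(members) & set(pool)
    if overlap:
        raise InvalidInputError(f"pool overlaps real flock: {sorted(overlap)[:5]}")
    if len(pool) < len(members):
        raise InvalidInputError(
            f"pool ({len(pool)}) smaller than flock ({len(members)})"
        )
    rng = np.random.default_rng(seed)
    rosters = []
    for _ in range(n_sim):
        idx = rng.choice(len(pool), size=len(members), replace=False)
        rosters.append([pool[i] for i in idx])
    return rosters


def flock_pseudoreplication_test(
    li_by_bird: Mapping[str, float],
    real_flock_members: Sequence[str],
    pool: Sequence[str],
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    real_flock_id: str = "real",
    posthoc: bool = False,
) -> FlockMCResult:
    """Kruskal-Wallis over the real flock plus ``n_sim`` simulated flocks.

    LI values must be available for every real-flock and pool member.
    Optionally (``posthoc=True``) each simulated flock is additionally
    compared against the real flock with a Mann-Whitney test; the
    omnibus H is the primary result.
    """
    rosters = build_synthetic_flocks(real_flock_members, pool, n_sim, seed)
    missing = [
        b
        for b in list(real_flock_members) + [m for r in rosters for m in r]
        if b not in li_by_bird
    ]
    if missing:
        raise InvalidInputError(f"LI missing for: {sorted(set(missing))[:5]}")
    real_li = [li_by_bird[b] for b in real_flock_members]
    groups = [real_li] + [[li_by_bird[b] for b in r] for r in rosters]
    try:
        kw = kruskal_wallis(groups)
    except DegenerateInputError as err:
        raise DegenerateInputError(
            f"flock {real_flock_id}: all LI values identical across real and "
            f"simulated flocks ({err})"
        ) from err
    post = None
    if posthoc:
        post = tuple(mann_whitney_u(g, real_li) for g in groups[1:])
    return FlockMCResult(
        real_flock_id=real_flock_id,
        n_members=len(real_flock_members),
        n_sim=n_sim,
        seed=seed,
        kw=kw,
        sim_flock_rosters=tuple(tuple(r) for r in rosters),
        posthoc_vs_real=post,
    )
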