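"""Design-level computations for the code-reading FRP study.

A priori power analysis for a paired t-test (noncentral t), chance-level
answer correctness, sign-flip permutation counts, pseudo-randomized
presentation orders under run-length and atom-separation constraints, and
condition counterbalancing across participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "OrderConstraints",
    "chance_correctness",
    "dz_from_f",
    "paired_t_power",
    "required_sample_size",
    "count_sign_permutations",
    "generate_presentation_order",
    "counterbalance_conditions",
]


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to an a priori paired t-test power analysis.

    dz is the standardized paired effect size (mean difference / SD of the
    differences); sides selects a one- or two-sided test.
    """

    dz: float
    alpha: float = 0.05
    power: float = 0.8
    sides: int = 2

    def __post_init__(self) -> None:
        if not self.dz > 0:
            raise ValueError("dz must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("target power must lie in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


@dataclass(frozen=True)
class OrderConstraints:
    """Presentation-order constraints.

    max_run_per_condition: longest allowed run of one condition.
    min_separation_same_atom: number of other snippets required between two
    snippets sharing an atom of confusion (2 means index distance >= 3).
    """

    max_run_per_condition: int = 3
    min_separation_same_atom: int = 2

    def __post_init__(self) -> None:
        if self.max_run_per_condition < 1 or self.min_separation_same_atom < 0:
            raise ValueError("constraints must be positive")


def chance_correctness(two_option_count: int, three_option_count: int) -> float:
    """Expected correctness when guessing uniformly over the real options.

    Snippets offer either two or three answer options (the "I don't know"
    option is not a guess), so chance level is the option-count-weighted
    mean of 1/2 and 1/3.
    """
    if two_option_count < 0 or three_option_count < 0:
        raise ValueError("option counts must be non-negative")
    total = two_option_count + three_option_count
    if total == 0:
        raise ValueError("at least one snippet required")
    return (two_option_count / 2 + three_option_count / 3) / total


def dz_from_f(f_value: float, n: int) -> float:
    """Paired effect size dz from a repeated-measures F with 1 numerator df.

    F = t^2 and t = dz * sqrt(n), hence dz = sqrt(F / n).
    """
    if f_value <= 0:
        raise ValueError("F value must be positive")
    if n < 2:
        raise ValueError("n must be at least 2")
    return math.sqrt(f_value / n)


def paired_t_power(dz: float, n: int, alpha: float = 0.05, sides: int = 2) -> float:
    """Achieved power of a paired t-test at sample size n.

    The test statistic follows a noncentral t distribution with df = n - 1
    and noncentrality dz * sqrt(n).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    df = n - 1
    ncp = dz * math.sqrt(n)
    if sides == 2:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp))


def required_sample_size(spec: PowerSpec, n_cap: int = 10_000) -> int:
    """Smallest n (>= 3) whose achieved power reaches the target."""
    for n in range(3, n_cap + 1):
        if paired_t_power(spec.dz, n, spec.alpha, spec.sides) >= spec.power:
            return n
    raise ValueError(f"target power {spec.power} not reached by n = {n_cap}")


def count_sign_permutations(n: int) -> int:
    """Number of sign assignments in an exhaustive paired permutation test."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return 2**n


def _check_order(
    conditions: list[str], atoms: list[object], constraints: OrderConstraints
) -> bool:
    run = 1
    for i in range(1, len(conditions)):
        run = run + 1 if conditions[i] == conditions[i - 1] else 1
        if run > constraints.max_run_per_condition:
            return False
    min_gap = constraints.min_separation_same_atom + 1
    last_seen: dict[object, int] = {}
    for i, atom in enumerate(atoms):
        j = last_seen.get(atom)
        if j is not None and i - j < min_gap:
            return False
        last_seen[atom] = i
    return True


def generate_presentation_order(
    pairs: pd.DataFrame,
    blocks: int,
    per_block: int,
    constraints: OrderConstraints,
    condition_assignment: dict[object, str],
    seed: int,
    max_retries: int = 10_000,
) -> pd.DataFrame:
    """Pseudo-randomize trials into blocks under the order constraints.

    pairs: DataFrame with columns ``pair_id`` and ``atom``; each pair is
    presented once, in the condition given by ``condition_assignment``.
    Constraints are enforced on the concatenated order across blocks (a
    run or atom repetition spanning a block break is still rejected), and
    each block presents both conditions equally often when per_block is
    even.

    Sampling is seeded greedy construction with restarts: each slot is
    filled uniformly at random from the trials still admissible under the
    constraints; a dead end restarts the whole order. Plain reshuffling is
    astronomically unlikely to satisfy the atom-separation constraint at
    these counts, so the constructive sampler is used instead.
    """
    if {"pair_id", "atom"} - set(pairs.columns):
        raise ValueError("pairs must have columns pair_id and atom")
    if len(pairs) != blocks * per_block:
        raise ValueError("pair count must equal blocks * per_block")
    rng = np.random.default_rng(seed)
    pair_list = list(pairs["pair_id"])
    atom_of = dict(zip(pairs["pair_id"], pairs["atom"]))
    cond_of = {pid: condition_assignment[pid] for pid in pair_list}
    quota_each = per_block // 2 if per_block % 2 == 0 else None
    min_gap = constraints.min_separation_same_atom + 1
    n = blocks * per_block

    for _ in range(max_retries):
        remaining = set(pair_list)
        chosen: list[object] = []
        block_quota: dict[str, int] = {}
        ok = True
        for i in range(n):
            if i % per_block == 0:
                block_quota = {"confusing": 0, "clean": 0}
            # condition of a run of max length ending at the previous slot
            run_cond, run_len = None, 0
            if chosen:
                run_cond = cond_of[chosen[-1]]
                run_len = 1
                for prev in reversed(chosen[:-1]):
                    if cond_of[prev] == run_cond:
                        run_len += 1
                    else:
                        break
            recent_atoms = {atom_of[p] for p in chosen[-(min_gap - 1):]} if min_gap > 1 else set()
            candidates = []
            for pid in remaining:
                cond = cond_of[pid]
                if quota_each is not None and block_quota[cond] >= quota_each:
                    continue
                if cond == run_cond and run_len >= constraints.max_run_per_condition:
                    continue
                if atom_of[pid] in recent_atoms:
                    continue
                candidates.append(pid)
            if not candidates:
                ok = False
                break
            candidates.sort(key=repr)  # deterministic order before sampling
            pick = candidates[int(rng.integers(len(candidates)))]
            chosen.append(pick)
            remaining.discard(pick)
            block_quota[cond_of[pick]] += 1
        if ok:
            conds = [cond_of[p] for p in chosen]
            atoms = [atom_of[p] for p in chosen]
            assert _check_order(conds, atoms, constraints)
            return pd.DataFrame(
                {
                    "block": np.repeat(np.arange(1, blocks + 1), per_block),
                    "trial_in_block": np.tile(np.arange(1, per_block + 1), blocks),
                    "pair_id": chosen,
                    "atom": atoms,
                    "condition": conds,
                }
            )
    raise RuntimeError(f"no constraint-satisfying order found in {max_retries} restarts")


def counterbalance_conditions(
    pair_ids: list[object], n_participants: int
) -> pd.DataFrame:
    """Assign one member of each snippet pair to each participant.

    Participant p sees pair i in the confusing version iff (i + p) is even,
    which gives every participant an equal split and shows each version of
    each pair to half of the participants. With an odd participant count
    the per-pair balance is off by one (warned, not fatal).
    """
    import warnings

    if n_participants % 2:
        warnings.warn("odd participant count: per-pair balance off by one")
    rows = []
    for p in range(n_participants):
        for i, pid in enumerate(pair_ids):
            cond = "confusing" if (i + p) % 2 == 0 else "clean"
            rows.append((p, pid, cond))
    return pd.DataFrame(rows, columns=["participant", "pair_id", "condition"])
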