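"""Validation statistics for synthetic benchmark sets.

Rank recovery on mixed sets (how many structured parents beat every
shuffled offspring), exact chance probabilities for those events, ordering
checks for ablation sets, and the Spearman correlation between the ranking
metric and total expression (a low magnitude indicates the ranking is not
merely recapitulating expression level).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diffusion import DiffusionResult
from .errors import InvalidInputError, InvalidParameterError


@dataclass
class RecoveryReport:
    """Outcome of a rank-recovery check on a synthetic set."""

    n_parents: int = 0
    n_parents_on_top: int = 0
    perfect_recovery: bool = False
    chance_probability: Fraction | None = None
    ordering_correct: list[bool] = field(default_factory=list)
    spearman_rho: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_parents": int(self.n_parents),
            "n_parents_on_top": int(self.n_parents_on_top),
            "perfect_recovery": bool(self.perfect_recovery),
            "chance_probability": (
                None if self.chance_probability is None else float(self.chance_probability)
            ),
            "chance_probability_exact": (
                None
                if self.chance_probability is None
                else f"{self.chance_probability.numerator}/{self.chance_probability.denominator}"
            ),
            "ordering_correct": list(map(bool, self.ordering_correct)),
            "spearman_rho": self.spearman_rho,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def chance_probability(n_parents: int, n_offspring: int) -> Fraction:
    """Exact probability that a random ranking puts all parents on top.

    ``n_parents! * n_offspring! / (n_parents + n_offspring)!`` — equal to
    ``1 / C(n_parents + n_offspring, n_parents)``.  For 10 parents and 90
    offspring this is about 5.78e-14.
    """
    if n_parents < 1 or n_offspring < 1:
        raise InvalidParameterError("both arguments must be >= 1")
    return Fraction(
        factorial(n_parents) * factorial(n_offspring),
        factorial(n_parents + n_offspring),
    )


def ablation_chance_probability(n_members: int, n_sets: int) -> Fraction:
    """Probability that every one of ``n_sets`` ablation sets with
    ``n_members`` stages is ranked in the correct order by chance:
    ``(n_members!)^-n_sets``.  For 10 sets of 4 this is about 1.58e-14."""
    if n_members < 1 or n_sets < 1:
        raise InvalidParameterError("both arguments must be >= 1")
    return Fraction(1, factorial(n_members) ** n_sets)


def parent_recovery(result: DiffusionResult, labels: pd.DataFrame) -> RecoveryReport:
    """Count parents whose diffusion time strictly exceeds every offspring's.

    Ties count as failure (a parent must be strictly higher).  Perfect
    recovery means every labeled parent sits above all offspring.
    """
    required = {"profile", "is_parent"}
    if not required.issubset(labels.columns):
        raise InvalidInputError(f"labels must contain columns {sorted(required)}")
    t_by_name = dict(zip(map(str, result.gene_names), result.t_d))
    missing = set(map(str, labels["profile"])) - set(t_by_name)
    if missing:
        raise InvalidInputError(f"profiles missing from the ranking: {sorted(missing)[:5]}")

    parents = labels.loc[labels["is_parent"].astype(bool), "profile"].astype(str)
    offspring = labels.loc[~labels["is_parent"].astype(bool), "profile"].astype(str)
    if parents.empty:
        raise InvalidInputError("labels contain no parent profiles")
    if offspring.empty:
        raise InvalidInputError("labels contain no offspring profiles")

    max_offspring = max(t_by_name[o] for o in offspring)
    n_top = sum(t_by_name[p] > max_offspring for p in parents)
    return RecoveryReport(
        n_parents=len(parents),
        n_parents_on_top=int(n_top),
        perfect_recovery=n_top == len(parents),
        chance_probability=chance_probability(len(parents), len(offspring)),
    )


def ablation_ordering(result: DiffusionResult, labels: pd.DataFrame) -> bool:
    """True if diffusion time strictly decreases with the shuffle degree."""
    required = {"profile", "n_shuffled"}
    if not required.issubset(labels.columns):
        raise InvalidInputError(f"labels must contain columns {sorted(required)}")
    t_by_name = dict(zip(map(str, result.gene_names), result.t_d))
    try:
        ordered = labels.sort_values("n_shuffled")
        times = [t_by_name[str(p)] for p in ordered["profile"]]
    except KeyError as e:
        raise InvalidInputError(f"profile {e} missing from the ranking") from e
    return all(a > b for a, b in zip(times, times[1:]))


def rank_expression_correlation(result: DiffusionResult, raw: np.ndarray) -> float:
    """Spearman correlation between diffusion time and per-gene total counts.

    Average ranks for ties.  A small magnitude means the ranking carries
    information beyond overall expression level.
    """
    raw = np.atleast_2d(np.asarray(raw))
    if raw.shape[0] != result.n_genes:
        raise InvalidInputError(
            f"counts matrix has {raw.shape[0]} genes but result has {result.n_genes}"
        )
    if result.n_genes < 3:
        raise InvalidInputError("Spearman correlation requires at least 3 genes")
    rho, _ = spearmanr(result.t_d, raw.sum(axis=1))
    return float(rho)
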