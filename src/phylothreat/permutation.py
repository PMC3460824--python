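"""Shared permutation-test result container and p-value conventions.

All permutation p-values use the add-one convention ``(1 + count)/(1 + n_perm)``,
so the smallest attainable p with 200 permutations is ~0.005 and with 999 is
0.001. Two-tailed tests on nonnegative statistics are centered on the null
mean and compare absolute deviations, which lets them detect both excesses
and deficits; the reported direction is the sign of the observed deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationTestResult", "permutation_p"]


@dataclass
class PermutationTestResult:
    statistic: float
    null: np.ndarray
    p_value: float
    direction: str  # "+" or "-"
    n_perm: int
    seed: int | None
    tail: str  # "two-sided" | "greater" | "less"

    def __repr__(self):
        return (
            f"PermutationTestResult(statistic={self.statistic:.6g}, "
            f"p={self.p_value:.4g}, direction={self.direction!r}, "
            f"n_perm={self.n_perm}, tail={self.tail!r})"
        )

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p": float(self.p_value),
            "direction": self.direction,
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "tail": self.tail,
        }


def permutation_p(
    observed: float,
    null: np.ndarray,
    *,
    tail: str = "two-sided",
    seed: int | None = None,
) -> PermutationTestResult:
    """Build a PermutationTestResult from an observed statistic and its null.

    ``two-sided`` centers on the null mean and compares absolute deviations;
    ``greater``/``less`` are one-tailed on the raw statistic.
    """
    null = np.asarray(null, dtype=float)
    n_perm = null.size
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    m = float(null.mean())
    dev = observed - m
    if tail == "two-sided":
        count = int(np.sum(np.abs(null - m) >= abs(dev) - 1e-12))
    elif tail == "greater":
        count = int(np.sum(null >= observed - 1e-12))
    elif tail == "less":
        count = int(np.sum(null <= observed + 1e-12))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(
        statistic=float(observed),
        null=null,
        p_value=float(p),
        direction="+" if dev >= 0 else "-",
        n_perm=n_perm,
        seed=seed,
        tail=tail,
    )
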