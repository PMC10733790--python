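"""Two-level orthogonal-array screening with signed %TSS ANOVA.

A model regulated by ~36 parameters would need 2³⁶ runs for a full
two-level factorial; a Taguchi-style orthogonal array reduces the screen to
72 runs while keeping every column balanced and every column pair
orthogonal.  Arrays are built from Hadamard matrices (Sylvester doubling
combined with the Paley type-I construction — q = 71 gives the 72-run
array); orthogonality is asserted numerically, not taken from a table.

The main-effect ANOVA attributes to each factor the share of the total sum
of squares explained by its high/low contrast, signed by the direction of
the effect: positive means raising the parameter raises the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from sympy import isprime


def _legendre(a: int, p: int) -> int:
    a %= p
    if a == 0:
        return 0
    return 1 if pow(a, (p - 1) // 2, p) == 1 else -1


def _paley_hadamard(q: int) -> np.ndarray:
    """Paley type-I Hadamard matrix of order q+1 (q prime, q ≡ 3 mod 4)."""
    n = q + 1
    S = np.zeros((n, n), dtype=int)
    S[0, 1:] = 1
    S[1:, 0] = -1
    for i in range(1, n):
        for j in range(1, n):
            if i != j:
                S[i, j] = _legendre(i - j, q)
    H = np.eye(n, dtype=int) + S
    if not np.array_equal(H @ H.T, n * np.eye(n, dtype=int)):
        raise RuntimeError("Paley construction failed orthogonality check")
    # normalize rows so the first column is all ones (balanced contrasts
    # remain in the other columns); row negation preserves orthogonality
    return H * H[:, :1]


def hadamard_matrix(n: int) -> np.ndarray:
    """Hadamard matrix of order n via Sylvester doubling and Paley I."""
    if n == 1:
        return np.array([[1]])
    if n == 2:
        return np.array([[1, 1], [1, -1]])
    if n % 2 == 0:
        q = n - 1
        if n % 4 == 0 and isprime(q) and q % 4 == 3:
            return _paley_hadamard(q)
        try:
            h = hadamard_matrix(n // 2)
        except ValueError:
            raise ValueError(f"no Hadamard construction available for order {n}")
        return np.block([[h, h], [h, -h]])
    raise ValueError(f"no Hadamard construction available for order {n}")


def _smallest_run_count(n_factors: int) -> int:
    n = 4
    while True:
        if n - 1 >= n_factors:
            try:
                hadamard_matrix(n)
                return n
            except ValueError:
                pass
        n += 4


@dataclass
class ScreeningDesign:
    """Two-level orthogonal screening design.

    ``matrix01`` is the runs × factors array of 0/1 levels; ``values`` maps
    them onto the actual low/high parameter values.
    """

    factors: list[str]
    levels: dict[str, tuple[float, float]]
    matrix01: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.matrix01.shape[0]

    def values(self) -> pd.DataFrame:
        cols = {}
        for j, f in enumerate(self.factors):
            lo, hi = self.levels[f]
            cols[f] = np.where(self.matrix01[:, j] == 1, hi, lo)
        return pd.DataFrame(cols)

    def run_settings(self, i: int) -> dict[str, float]:
        return {f: (self.levels[f][1] if self.matrix01[i, j] == 1 else self.levels[f][0])
                for j, f in enumerate(self.factors)}


@dataclass
class SensitivityResult:
    """Signed %TSS per factor, ranked by influence magnitude."""

    table: pd.DataFrame  # columns: factor, effect, pct_tss, rank

    def top(self, k: int = 4) -> list[str]:
        return list(self.table.sort_values("rank")["factor"].head(k))

    def pct_tss(self, factor: str) -> float:
        row = self.table.loc[self.table["factor"] == factor]
        return float(row["pct_tss"].iloc[0])


def build_design(factors: Sequence[str],
                 low_high: Mapping[str, tuple[float, float]],
                 n_runs: int | None = None) -> ScreeningDesign:
    """Balanced two-level orthogonal array for the given factors.

    The run count defaults to the smallest constructible Hadamard order
    with enough columns (72 for 36 factors); requesting more factors than
    ``n_runs - 1`` is an error.
    """
    factors = list(factors)
    missing = [f for f in factors if f not in low_high]
    if missing:
        raise ValueError(f"missing level definitions for {missing}")
    n = n_runs if n_runs is not None else _smallest_run_count(len(factors))
    if len(factors) > n - 1:
        raise ValueError(f"{len(factors)} factors exceed the {n - 1} columns of a "
                         f"{n}-run two-level array")
    H = hadamard_matrix(n)
    # drop the all-ones column; keep the first n_factors contrast columns
    mat = (H[:, 1:len(factors) + 1] == 1).astype(int)
    return ScreeningDesign(factors=factors, levels=dict(low_high), matrix01=mat)


def levels_around(params, factors: Sequence[str],
                  rel_delta: float = 0.25) -> dict[str, tuple[float, float]]:
    """Nominal ±rel_delta levels around a parameter set's current values."""
    return {f: (params[f] * (1.0 - rel_delta), params[f] * (1.0 + rel_delta))
            for f in factors}


def anova_tss(design: ScreeningDesign, outputs: Sequence[float]) -> SensitivityResult:
    """Main-effect signed %TSS for each factor of a completed screen.

    ``pct_tss`` is the factor's contrast sum of squares over the total sum
    of squares × 100, carrying the sign of (mean at high − mean at low).
    With zero total variance every factor scores 0.
    """
    y = np.asarray(outputs, dtype=float)
    if len(y) != design.n_runs:
        raise ValueError("one output value per run required")
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []
    for j, f in enumerate(design.factors):
        hi = design.matrix01[:, j] == 1
        effect = float(y[hi].mean() - y[~hi].mean())
        ss = design.n_runs * effect**2 / 4.0
        pct = 100.0 * ss / tss if tss > 0 else 0.0
        rows.append({"factor": f, "effect": effect,
                     "pct_tss": float(np.copysign(pct, effect)) if pct else 0.0})
    table = pd.DataFrame(rows)
    table["rank"] = table["pct_tss"].abs().rank(ascending=False, method="first").astype(int)
    return SensitivityResult(table=table.sort_values("rank").reset_index(drop=True))


def run_screen(design: ScreeningDesign,
               output_fn: Callable[[dict[str, float]], float]) -> SensitivityResult:
    """Evaluate ``output_fn`` on every run of the design and ANOVA the results."""
    outputs = [output_fn(design.run_settings(i)) for i in range(design.n_runs)]
    return anova_tss(design, outputs)
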