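"""Binomial difference-of-proportions test for preferential mutation mapping.

Given a "test" cell group T and a comparison group N, pool the per-cell
molecule counts into X_T (mutation-supporting) out of N_T (mutation +
reference) and likewise X_N / N_N, and form the continuity-corrected
Z score for the difference of proportions

    Z = (|P_T - P_N| - (1/N_T + 1/N_N)/2) / (P_avg * Q_avg * sqrt(1/N_T + 1/N_N))

with P_T = X_T/N_T, P_N = X_N/N_N, P_avg = (X_T+X_N)/(N_T+N_N) and
Q_avg = 1 - P_avg. Note the pooled factor P_avg*Q_avg multiplies the square
root rather than sitting under it; this non-textbook form is the default
(``variance_form="printed"``), with the textbook pooled variance
sqrt(P_avg*Q_avg*(1/N_T+1/N_N)) available as ``variance_form="pooled"``.

The p-value is the one-sided upper tail P(Z' >= Z) under the standard
normal. Tests are only performed when P_T > P_N is actually observed; the
cases P_T <= P_N are skipped (not counted as discoveries) to avoid
over-correcting the FDR. Normality of the binomial approximation is flagged
(not enforced) by the classical heuristic N*P_avg*Q_avg >= 5 on both groups.
Benjamini-Hochberg q-values are computed across the performed tests of one
invocation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = [
    "group_t",
    "group_n",
    "X_T",
    "N_T",
    "X_N",
    "N_N",
    "P_T",
    "P_N",
    "P_avg",
    "Q_avg",
    "Z_score",
    "p",
    "q",
    "performed",
    "reason",
    "normal_approx_ok",
]


@dataclass
class TwoProportionResult:
    """One evaluated (or skipped) two-proportion contrast."""

    X_T: int
    N_T: int
    X_N: int
    N_N: int
    P_T: float = math.nan
    P_N: float = math.nan
    P_avg: float = math.nan
    Q_avg: float = math.nan
    Z_score: float = math.nan
    p: float = math.nan
    q: float = math.nan
    performed: bool = False
    reason: str = ""
    normal_approx_ok: bool = False


def compute_mapping_z(
    x_t: int,
    n_t: int,
    x_n: int,
    n_n: int,
    variance_form: str = "printed",
) -> TwoProportionResult:
    """Evaluate the continuity-corrected difference-of-proportions Z.

    Skips (``performed=False``) when either group has no coverage
    ("no-coverage"), when P_T <= P_N ("skip-pt-le-pn"), or when
    P_avg is 0 or 1 so the denominator vanishes ("degenerate-proportion").
    """
    if variance_form not in ("printed", "pooled"):
        raise ValueError("variance_form must be 'printed' or 'pooled'")
    if min(x_t, x_n) < 0 or x_t > n_t or x_n > n_n:
        raise ValueError("counts must satisfy 0 <= X <= N")
    res = TwoProportionResult(X_T=x_t, N_T=n_t, X_N=x_n, N_N=n_n)
    if n_t <= 0 or n_n <= 0:
        res.reason = "no-coverage"
        return res
    res.P_T = x_t / n_t
    res.P_N = x_n / n_n
    res.P_avg = (x_t + x_n) / (n_t + n_n)
    res.Q_avg = 1.0 - res.P_avg
    res.normal_approx_ok = bool(
        n_t * res.P_avg * res.Q_avg >= 5 and n_n * res.P_avg * res.Q_avg >= 5
    )
    if res.P_T <= res.P_N:
        res.reason = "skip-pt-le-pn"
        return res
    if res.P_avg <= 0.0 or res.P_avg >= 1.0:
        res.reason = "degenerate-proportion"
        return res
    inv = 1.0 / n_t + 1.0 / n_n
    num = abs(res.P_T - res.P_N) - inv / 2.0
    if variance_form == "printed":
        den = res.P_avg * res.Q_avg * math.sqrt(inv)
    else:
        den = math.sqrt(res.P_avg * res.Q_avg * inv)
    res.Z_score = num / den
    res.p = float(sps.norm.sf(res.Z_score))
    res.performed = True
    return res


def compute_mapping_z_table(
    x_t: np.ndarray,
    n_t: np.ndarray,
    x_n: np.ndarray,
    n_n: np.ndarray,
    variance_form: str = "printed",
) -> pd.DataFrame:
    """Vectorized form of :func:`compute_mapping_z` for simulation studies."""
    x_t = np.asarray(x_t, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    n_n = np.asarray(n_n, dtype=float)
    out = pd.DataFrame({"X_T": x_t, "N_T": n_t, "X_N": x_n, "N_N": n_n})
    with np.errstate(invalid="ignore", divide="ignore"):
        p_t = np.where(n_t > 0, x_t / np.where(n_t > 0, n_t, 1), np.nan)
        p_n = np.where(n_n > 0, x_n / np.where(n_n > 0, n_n, 1), np.nan)
        p_avg = (x_t + x_n) / (n_t + n_n)
        q_avg = 1.0 - p_avg
        inv = 1.0 / n_t + 1.0 / n_n
        num = np.abs(p_t - p_n) - inv / 2.0
        if variance_form == "printed":
            den = p_avg * q_avg * np.sqrt(inv)
        else:
            den = np.sqrt(p_avg * q_avg * inv)
        z = num / den
    no_cov = (n_t <= 0) | (n_n <= 0)
    skip = ~no_cov & (p_t <= p_n)
    degen = ~no_cov & ~skip & ((p_avg <= 0) | (p_avg >= 1))
    performed = ~(no_cov | skip | degen)
    out["P_T"], out["P_N"], out["P_avg"], out["Q_avg"] = p_t, p_n, p_avg, q_avg
    out["Z_score"] = np.where(performed, z, np.nan)
    out["p"] = np.where(performed, sps.norm.sf(np.where(performed, z, 0.0)), np.nan)
    out["performed"] = performed
    out["reason"] = np.select(
        [no_cov, skip, degen],
        ["no-coverage", "skip-pt-le-pn", "degenerate-proportion"],
        default="",
    )
    out["normal_approx_ok"] = (n_t * p_avg * q_avg >= 5) & (n_n * p_avg * q_avg >= 5)
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


class MutationEnrichmentModel:
    """Preferential-mapping model over per-cell allele counts.

    Parameters
    ----------
    counts
        Per-cell consensus counts from the mapper (``cell_barcode``,
        ``ref_molecules``, ``alt_molecules``; site columns are pooled over).
    groups
        Mapping cell_barcode -> group label (Series or dict). Every counted
        cell must be assigned exactly one group.
    contrasts
        Pairs (group_T, group_N) to test; T is the group hypothesized to
        carry the mutations.
    unit
        "molecules" (UMI-consensus counts, the default) or "reads"
        (pass raw-read counts in the same columns).
    variance_form
        "printed" (default) or the textbook "pooled" form.

    Examples
    --------
    >>> model = MutationEnrichmentModel(counts, groups,
    ...     contrasts=[("tumor", "normal_duct"), ("panin", "normal_duct")])
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: pd.Series | dict,
        contrasts: Sequence[tuple[str, str]],
        unit: str = "molecules",
        variance_form: str = "printed",
    ) -> None:
        if unit not in ("molecules", "reads"):
            raise ValueError("unit must be 'molecules' or 'reads'")
        self.counts = counts
        self.groups = pd.Series(groups) if isinstance(groups, dict) else groups
        self.contrasts = list(contrasts)
        self.unit = unit
        self.variance_form = variance_form

        cells = counts["cell_barcode"]
        unassigned = set(cells) - set(self.groups.index)
        if unassigned:
            raise ValueError(
                f"{len(unassigned)} cells lack a group assignment "
                f"(e.g. {sorted(unassigned)[:3]})"
            )
        known = set(self.groups.unique())
        for t, n in self.contrasts:
            if t not in known or n not in known:
                raise ValueError(f"contrast ({t}, {n}) references unknown group")

    def _pooled(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["group"] = df["cell_barcode"].map(self.groups)
        agg = df.groupby("group", observed=True)[
            ["alt_molecules", "ref_molecules"]
        ].sum()
        agg["X"] = agg["alt_molecules"]
        agg["N"] = agg["alt_molecules"] + agg["ref_molecules"]
        return agg

    def fit(self) -> "MutationEnrichmentResults":
        """Evaluate every contrast and BH-adjust across the performed tests."""
        pooled = self._pooled()
        rows = []
        for t, n in self.contrasts:
            xt = int(pooled["X"].get(t, 0))
            nt = int(pooled["N"].get(t, 0))
            xn = int(pooled["X"].get(n, 0))
            nn = int(pooled["N"].get(n, 0))
            r = compute_mapping_z(xt, nt, xn, nn, variance_form=self.variance_form)
            rows.append({"group_t": t, "group_n": n, **r.__dict__})
        table = pd.DataFrame(rows)
        performed = table["performed"].to_numpy(dtype=bool)
        q = np.full(len(table), np.nan)
        if performed.any():
            q[performed] = bh_qvalues(table.loc[performed, "p"].to_numpy())
        table["q"] = q
        return MutationEnrichmentResults(self, table[RESULT_COLUMNS])


class MutationEnrichmentResults:
    """Fitted contrasts: estimates, Z scores, p and BH q values."""

    def __init__(self, model: MutationEnrichmentModel, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    @property
    def n_performed(self) -> int:
        return int(self.table["performed"].sum())

    def summary(self) -> str:
        lines = [
            "Mutation mapping enrichment (difference of proportions)",
            f"unit: {self.model.unit}; variance form: {self.model.variance_form}; "
            f"performed {self.n_performed}/{len(self.table)} contrasts",
            "-" * 78,
            f"{'contrast':<28}{'P_T':>8}{'P_N':>8}{'Z':>9}{'p':>11}{'q':>11}",
        ]
        for r in self.table.itertuples(index=False):
            name = f"{r.group_t} vs {r.group_n}"
            if r.performed:
                lines.append(
                    f"{name:<28}{r.P_T:>8.4f}{r.P_N:>8.4f}{r.Z_score:>9.3f}"
                    f"{r.p:>11.3e}{r.q:>11.3e}"
                )
            else:
                lines.append(f"{name:<28}  skipped ({r.reason})")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MutationEnrichmentResults: {self.n_performed} performed>"


def run_group_tests(
    counts: pd.DataFrame,
    groups: pd.Series | dict,
    contrasts: Sequence[tuple[str, str]],
    unit: str = "molecules",
    variance_form: str = "printed",
) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`MutationEnrichmentModel`, return its table."""
    model = MutationEnrichmentModel(
        counts, groups, contrasts, unit=unit, variance_form=variance_form
    )
    return model.fit().table
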