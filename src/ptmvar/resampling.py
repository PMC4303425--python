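"""Amino-acid-weighted permutation null for rare-fraction comparisons.

Codon redundancy differs between amino acids, so a residue subset (modified
residues, flank zones, motif-breaker sites, PTM clusters) cannot be compared
to unmatched background sequence. The permutation null repeatedly samples,
without replacement and outside the test set, background residues with
exactly the test set's per-amino-acid composition, and compares the observed
statistic (by default the rare fraction of substitutions on those residues)
with its permutation distribution. P-values use the add-one (Phipson-Smyth)
estimator so a finite number of permutations never reports zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

N_PERM_DEFAULT = 1000


@dataclass
class PermutationResult:
    observed: float
    expected_mean: float
    expected_sd: float
    n_perm: int
    p_value: float | None
    n_test_residues: int
    direction: str


def rare_fraction_statistic(residues: pd.DataFrame) -> float:
    """Rare substitutions over all substitutions on a residue set.

    Expects per-residue substitution totals in n_subs / n_rare columns;
    NaN when the set carries no substitutions.
    """
    total = residues["n_subs"].sum()
    return residues["n_rare"].sum() / total if total > 0 else np.nan


def aa_weighted_sample(
    test: pd.DataFrame, background: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Sample background row positions matching the test amino-acid counts.

    Draws, per amino acid, exactly as many background residues as the test
    set contains, without replacement. Raises if any amino acid is
    under-represented in the background, naming it.
    """
    need = test["aa"].value_counts()
    bg_aa = background["aa"].to_numpy()
    chosen = []
    for aa, k in need.items():
        pool = np.flatnonzero(bg_aa == aa)
        if pool.size < k:
            raise ValueError(
                f"background has {pool.size} residues of amino acid {aa!r}, test set needs {k}"
            )
        chosen.append(rng.choice(pool, size=k, replace=False))
    return np.concatenate(chosen) if chosen else np.empty(0, dtype=int)


def _drop_test_rows(test: pd.DataFrame, background: pd.DataFrame) -> pd.DataFrame:
    if {"protein", "position"} <= set(test.columns) & set(background.columns):
        test_keys = set(zip(test["protein"], test["position"]))
        keep = [
            (p, q) not in test_keys
            for p, q in zip(background["protein"], background["position"])
        ]
        return background[np.asarray(keep)]
    return background


def permutation_test(
    test: pd.DataFrame,
    background: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float] = rare_fraction_statistic,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | np.random.Generator = 0,
    direction: str = "greater",
    exclude_test_from_background: bool = True,
) -> PermutationResult:
    """Amino-acid-matched permutation test of a residue-set statistic.

    *test* and *background* are residue tables with at least an ``aa``
    column plus whatever the statistic needs (n_subs / n_rare for the rare
    fraction). The background is the residue universe the test set is
    compared against (e.g. all residues of proteins carrying the same PTM
    type); test residues themselves are excluded from it by default.
    One-sided p in *direction* ("greater": observed above the null).
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if exclude_test_from_background:
        background = _drop_test_rows(test, background)
    background = background.reset_index(drop=True)
    observed = statistic(test)
    if not np.isfinite(observed):
        return PermutationResult(np.nan, np.nan, np.nan, n_perm, None, len(test), direction)

    # group background positions by amino acid once; sample per permutation
    need = test["aa"].value_counts()
    bg_aa = background["aa"].to_numpy()
    pools = {}
    for aa, k in need.items():
        pool = np.flatnonzero(bg_aa == aa)
        if pool.size < k:
            raise ValueError(
                f"background has {pool.size} residues of amino acid {aa!r}, test set needs {k}"
            )
        pools[aa] = (pool, int(k))
    n_subs = background["n_subs"].to_numpy() if "n_subs" in background else None
    n_rare = background["n_rare"].to_numpy() if "n_rare" in background else None
    default_stat = statistic is rare_fraction_statistic and n_subs is not None

    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = (
            np.concatenate([rng.choice(pool, size=k, replace=False) for pool, k in pools.values()])
            if pools
            else np.empty(0, dtype=int)
        )
        if default_stat:
            tot = n_subs[idx].sum()
            null[i] = n_rare[idx].sum() / tot if tot > 0 else np.nan
        else:
            null[i] = statistic(background.iloc[idx])
    finite = null[np.isfinite(null)]
    if direction == "greater":
        extreme = int((finite >= observed).sum())
    else:
        extreme = int((finite <= observed).sum())
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        observed=float(observed),
        expected_mean=float(finite.mean()) if finite.size else np.nan,
        expected_sd=float(finite.std(ddof=0)) if finite.size else np.nan,
        n_perm=n_perm,
        p_value=float(p),
        n_test_residues=int(len(test)),
        direction=direction,
    )


def residue_table(subs: pd.DataFrame, residues: pd.DataFrame) -> pd.DataFrame:
    """Attach per-residue substitution totals to a residue universe.

    *residues* has protein, position, aa rows; *subs* carries protein,
    residue_index, is_nonsyn, is_rare. Returns the residue table with
    n_subs / n_rare columns counting non-synonymous substitutions.
    """
    nonsyn = subs[subs["is_nonsyn"]]
    counts = (
        nonsyn.groupby(["protein", "residue_index"])
        .agg(n_subs=("is_rare", "size"), n_rare=("is_rare", "sum"))
        .reset_index()
        .rename(columns={"residue_index": "position"})
    )
    out = residues.merge(counts, on=["protein", "position"], how="left")
    out[["n_subs", "n_rare"]] = out[["n_subs", "n_rare"]].fillna(0).astype(int)
    return out
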