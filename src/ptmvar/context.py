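"""Group-level PTM-constraint tests across tissues, pathways and bins.

For a protein group (a tissue signature, a pathway, an expression or
conservation bin) the null logistic model classifies the group's rare vs
common substitutions from the disorder flag alone; the alternative adds the
PTM-region indicator. The 1-df likelihood-ratio test measures PTM-specific
constraint, with direction from the PTM coefficient sign, BH-corrected
across groups. Significant groups are screened for disease-gene overlap,
and binned covariate analyses correlate the per-bin PTM rare-substitution
enrichment with median expression or conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .disease import bh_adjust
from .io import read_gmt

MIN_SET_SIZE = 5
MAX_SET_SIZE = 1000
UBIQUITOUS_MIN_TISSUES = 18
ROBUST_Z = 2.0
JACCARD_EDGE = 0.25


@dataclass
class GroupTestResult:
    group: str
    n_proteins: int
    n_ptm_subs: int
    n_nonptm_subs: int
    direction: str | None
    lrt_p: float | None
    skipped_reason: str | None = None


def group_lrt(subs: pd.DataFrame, group: str = "", n_proteins: int = 0) -> GroupTestResult:
    """1-df LRT of the PTM term over a disorder-only null for one group.

    *subs* is the group's non-synonymous substitution table (is_rare,
    in_disorder, in_ptm_region columns). Degenerate groups (one response
    class, or a constant PTM flag) are skipped with a reason.
    """
    df = subs[subs["is_nonsyn"]] if "is_nonsyn" in subs.columns else subs
    n_ptm = int(df["in_ptm_region"].sum())
    n_non = int(len(df) - n_ptm)
    base = dict(group=group, n_proteins=n_proteins, n_ptm_subs=n_ptm, n_nonptm_subs=n_non)
    y = df["is_rare"].astype(int).to_numpy()
    if y.size == 0 or y.min() == y.max():
        return GroupTestResult(**base, direction=None, lrt_p=None,
                               skipped_reason="single response class")
    ptm = df["in_ptm_region"].astype(float).to_numpy()
    if ptm.min() == ptm.max():
        return GroupTestResult(**base, direction=None, lrt_p=1.0,
                               skipped_reason="constant PTM flag")
    dis = df["in_disorder"].astype(float).to_numpy()
    X0 = sm.add_constant(dis, has_constant="add")
    X1 = np.column_stack([X0, ptm])
    try:
        f0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit(maxiter=100)
        f1 = sm.GLM(y, X1, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # separation etc.
        return GroupTestResult(**base, direction=None, lrt_p=None,
                               skipped_reason=f"fit failure: {exc}")
    delta = max(f0.deviance - f1.deviance, 0.0)
    p = float(stats.chi2.sf(delta, 1))
    direction = "positive" if f1.params[-1] > 0 else "negative"
    return GroupTestResult(**base, direction=direction, lrt_p=p)


def run_group_tests(
    subs: pd.DataFrame, gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Group LRT over every gene set, with BH q-values."""
    results = []
    for name, members in sorted(gene_sets.items()):
        grp = subs[subs["protein"].isin(members)]
        results.append(group_lrt(grp, group=name, n_proteins=len(members)))
    out = pd.DataFrame([r.__dict__ for r in results])
    if len(out):
        mask = out["lrt_p"].notna()
        out["q"] = np.nan
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "lrt_p"])
    return out


def load_gene_sets(path, min_size: int = MIN_SET_SIZE, max_size: int = MAX_SET_SIZE) -> dict[str, set[str]]:
    """GMT gene sets restricted to 5..1000 proteins (inclusive bounds)."""
    return read_gmt(path, min_size=min_size, max_size=max_size)


def _merge_numbered(tissue: str) -> str:
    """Collapse numbered tissue subsets (e.g. 'skin 1', 'skin 2') to one name."""
    parts = tissue.rsplit(" ", 1)
    if len(parts) == 2 and parts[1].isdigit():
        return parts[0]
    return tissue


def define_ubiquitous(
    expression: pd.DataFrame,
    z_threshold: float = ROBUST_Z,
    min_tissues: int = UBIQUITOUS_MIN_TISSUES,
) -> tuple[set[str], dict[str, set[str]]]:
    """Ubiquitous proteins and per-tissue high-expression sets.

    *expression* is genes x tissues. A gene is called highly expressed in a
    tissue when its robust z-score within that tissue, (x - tissue median) /
    (1.4826 x tissue MAD across genes), reaches *z_threshold*; genes high in
    >= *min_tissues* tissues are ubiquitous and removed from every
    tissue-specific set. Numbered tissue subsets are merged; genes with no
    expression variation across tissues (per-gene MAD 0) are excluded, as are
    tissues whose expression is constant across genes.
    """
    if expression.shape[1] < min_tissues:
        raise ValueError(
            f"need >= {min_tissues} tissues to define ubiquitous proteins, got {expression.shape[1]}"
        )
    X = expression.to_numpy(dtype=float)
    gene_med = np.median(X, axis=1, keepdims=True)
    gene_mad = np.median(np.abs(X - gene_med), axis=1)
    valid = gene_mad > 0
    tissue_med = np.median(X, axis=0, keepdims=True)
    tissue_mad = np.median(np.abs(X - tissue_med), axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(tissue_mad > 0, (X - tissue_med) / (1.4826 * tissue_mad), np.nan)
    high = z >= z_threshold
    genes = expression.index.to_numpy()
    n_high = high.sum(axis=1)
    ubiquitous = set(genes[valid & (n_high >= min_tissues)])
    tissue_sets: dict[str, set[str]] = {}
    for j, tissue in enumerate(expression.columns):
        name = _merge_numbered(str(tissue))
        members = set(genes[valid & high[:, j]]) - ubiquitous
        tissue_sets.setdefault(name, set()).update(members)
    tissue_sets = {k: v for k, v in tissue_sets.items() if v}
    return ubiquitous, tissue_sets


def binned_trend(
    subs: pd.DataFrame, covariate: pd.Series, n_bins: int = 100
) -> tuple[pd.DataFrame, float, float]:
    """Per-bin PTM rare-substitution enrichment vs a protein covariate.

    Proteins are split into *n_bins* equal-size groups by the covariate
    (median expression or conservation). In each bin the observed rare
    fraction of PTM substitutions is compared with the disorder-confounded
    model expectation (mean predicted rare probability at the PTM
    substitutions' disorder values, with the prediction standard error);
    the log2 ratio is correlated (Pearson) with the bin's median covariate.
    Bins without PTM substitutions are excluded from the correlation.
    """
    cov = covariate.dropna()
    if cov.nunique() <= 1:
        raise ValueError("constant covariate: correlation undefined")
    if len(cov) < n_bins:
        raise ValueError(f"need >= {n_bins} proteins with the covariate, got {len(cov)}")
    order = cov.reset_index()
    order.columns = ["protein", "value"]
    order = order.sort_values(["value", "protein"], kind="stable")
    chunks = np.array_split(np.arange(len(order)), n_bins)
    bin_of = {}
    bin_median = {}
    proteins_sorted = order["protein"].to_numpy()
    values_sorted = order["value"].to_numpy(dtype=float)
    for b, idx in enumerate(chunks, start=1):
        for i in idx:
            bin_of[proteins_sorted[i]] = b
        bin_median[b] = float(np.median(values_sorted[idx]))
    df = subs[subs["is_nonsyn"]].copy()
    df["bin"] = df["protein"].map(bin_of)
    df = df.dropna(subset=["bin"])
    rows = []
    for b, grp in df.groupby("bin"):
        ptm = grp[grp["in_ptm_region"]]
        row = {"bin": int(b), "n_ptm_subs": len(ptm), "median_covariate": bin_median[int(b)]}
        y = grp["is_rare"].astype(int).to_numpy()
        if len(ptm) == 0 or y.min() == y.max():
            row.update({"log2_enrichment": np.nan, "expected": np.nan, "expected_se": np.nan})
        else:
            X = sm.add_constant(grp["in_disorder"].astype(float).to_numpy(), has_constant="add")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            Xp = sm.add_constant(ptm["in_disorder"].astype(float).to_numpy(), has_constant="add")
            pred = fit.get_prediction(Xp)
            expected = float(np.mean(pred.predicted_mean))
            se = float(np.mean(pred.se_mean)) if hasattr(pred, "se_mean") else float(np.mean(pred.se))
            observed = float(ptm["is_rare"].mean())
            row.update({
                "observed": observed,
                "expected": expected,
                "expected_se": se,
                "log2_enrichment": np.log2(observed / expected) if observed > 0 and expected > 0 else np.nan,
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["log2_enrichment"].notna() & table["median_covariate"].notna()
    if ok.sum() >= 3:
        r, p = stats.pearsonr(table.loc[ok, "median_covariate"], table.loc[ok, "log2_enrichment"])
    else:
        r, p = np.nan, np.nan
    return table, float(r), float(p)


def disease_overlap(
    significant_groups: dict[str, set[str]],
    disease_genes: set[str],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher's exact disease-gene overlap per significant group, BH-adjusted.

    Hypergeometric over the tested-protein universe; groups disjoint from
    the universe are skipped.
    """
    if not universe:
        raise ValueError("empty protein universe")
    dg = disease_genes & universe
    rows = []
    for name, members in sorted(significant_groups.items()):
        m = members & universe
        if not m:
            rows.append({"group": name, "overlap": 0, "p": np.nan, "skipped": True})
            continue
        a = len(m & dg)
        b = len(m - dg)
        c = len(dg - m)
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"group": name, "overlap": a, "p": float(p), "skipped": False})
    out = pd.DataFrame(rows, columns=["group", "overlap", "p", "skipped"])
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"])
    return out


def enrichment_map_export(
    results: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    q_threshold: float = 0.05,
    jaccard: float = JACCARD_EDGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables for enrichment-map visualisation of significant groups.

    Nodes: one row per significant group (q below threshold) with size and
    direction. Edges connect groups whose member overlap has Jaccard index
    >= the cutoff.
    """
    sig = results[(results["q"].notna()) & (results["q"] < q_threshold)]
    nodes = sig[["group", "n_proteins", "direction", "lrt_p", "q"]].drop_duplicates("group")
    names = list(nodes["group"])
    edges = []
    for a, b in combinations(names, 2):
        sa, sb = gene_sets[a], gene_sets[b]
        jac = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
        if jac >= jaccard:
            edges.append({"source": a, "target": b, "jaccard": jac})
    return nodes.reset_index(drop=True), pd.DataFrame(edges, columns=["source", "target", "jaccard"])


def word_cloud_table(disease_annotations: pd.DataFrame, proteins: set[str]) -> pd.DataFrame:
    """Disease-label annotation frequencies for a protein group.

    Replaces rendered word clouds: one row per disease label with its
    record count among the group's annotations.
    """
    sel = disease_annotations[disease_annotations["protein"].isin(proteins)]
    counts = (
        sel.groupby("disease")["n_records"].sum().sort_values(ascending=False).reset_index()
    )
    counts.columns = ["disease", "n_annotations"]
    return counts
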