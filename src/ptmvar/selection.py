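"""Selection statistics for PTM versus non-PTM protein sequence.

Two complementary signals of purifying selection are computed: the
proportion of rare substitutions (derived allele frequency <= 0.5% by
default) and the Ka/Ks ratio of non-synonymous variants per non-synonymous
site to synonymous variants per synonymous site, with fractional
(Nei-Gojobori style) site counting. PTM and non-PTM sequence are compared
with one-sided paired Wilcoxon signed-rank tests across 100 bins of
proteins matched on overall substitution rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import CODON_SITE_COUNTS

N_BINS_DEFAULT = 100
MIN_INFORMATIVE_PAIRS = 6
EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedTestResult:
    statistic: float | None
    p_value: float | None
    n_pairs: int
    n_informative: int


@dataclass
class SelectionSummary:
    stratum: str
    n_subs: int
    n_rare: int
    rare_fraction: float
    n_syn: int = 0
    syn_sites: float = np.nan
    nonsyn_sites: float = np.nan
    ka: float = np.nan
    ks: float = np.nan
    ka_ks: float = np.nan


def bin_by_variation(variation_rate: pd.Series, n_bins: int = N_BINS_DEFAULT) -> pd.Series:
    """Assign proteins to percentile bins of matched substitution rate.

    *variation_rate* is indexed by protein identifier (substituted residues
    per residue). Proteins are sorted by (rate, identifier) and split into
    *n_bins* contiguous groups whose sizes differ by at most one (remainder
    proteins go to the lowest-rate bins). Returns bin number 1..n_bins per
    protein.
    """
    n = len(variation_rate)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} proteins to form {n_bins} bins, got {n}")
    order = variation_rate.reset_index()
    order.columns = ["protein", "rate"]
    order = order.sort_values(["rate", "protein"], kind="stable")
    chunks = np.array_split(np.arange(n), n_bins)
    bins = np.empty(n, dtype=int)
    for b, idx in enumerate(chunks, start=1):
        bins[idx] = b
    return pd.Series(bins, index=order["protein"].to_numpy(), name="bin")


def site_counts(codons) -> tuple[float, float]:
    """Total (synonymous, non-synonymous) fractional sites of a codon set."""
    syn = nonsyn = 0.0
    for c in codons:
        s, ns = CODON_SITE_COUNTS[c]
        syn += s
        nonsyn += ns
    return syn, nonsyn


def ka_ks(n_nonsyn: int, n_syn: int, codons) -> dict:
    """Ka, Ks and their ratio for variant counts observed over *codons*.

    Each codon contributes fractional synonymous and non-synonymous sites
    (stop-gain changes excluded from both). The ratio is undefined (NaN,
    flagged) when there are no synonymous sites or no synonymous variants.
    """
    syn_sites, nonsyn_sites = site_counts(codons)
    ka = n_nonsyn / nonsyn_sites if nonsyn_sites > 0 else np.nan
    ks = n_syn / syn_sites if syn_sites > 0 else np.nan
    ratio = ka / ks if (ks is not np.nan and ks and np.isfinite(ks) and np.isfinite(ka)) else np.nan
    return {
        "syn_sites": syn_sites,
        "nonsyn_sites": nonsyn_sites,
        "ka": ka,
        "ks": ks,
        "ka_ks": ratio,
        "defined": bool(np.isfinite(ratio)),
    }


def paired_bin_test(
    ptm_values, nonptm_values, alternative: str = "greater"
) -> PairedTestResult:
    """One-sided paired Wilcoxon signed-rank test over matched bins.

    *alternative* refers to the PTM side: "greater" tests PTM > non-PTM
    (rare fraction), "less" tests PTM < non-PTM (Ka/Ks). Pairs with a
    missing value or a zero difference are uninformative and dropped; with
    fewer than six informative pairs no p-value is produced. The exact null
    is used for up to 25 untied informative pairs, otherwise the normal
    approximation with continuity correction.
    """
    ptm = np.asarray(ptm_values, dtype=float)
    non = np.asarray(nonptm_values, dtype=float)
    if ptm.shape != non.shape:
        raise ValueError("paired value arrays must have equal length")
    ok = np.isfinite(ptm) & np.isfinite(non)
    d = ptm[ok] - non[ok]
    d = d[d != 0]
    n_inf = d.size
    if n_inf < MIN_INFORMATIVE_PAIRS:
        warnings.warn(
            f"only {n_inf} informative pairs (<{MIN_INFORMATIVE_PAIRS}); p-value not computed",
            stacklevel=2,
        )
        return PairedTestResult(None, None, int(ok.sum()), n_inf)
    has_ties = np.unique(np.abs(d)).size < n_inf
    method = "exact" if (n_inf <= EXACT_WILCOXON_MAX_N and not has_ties) else "approx"
    kwargs = {"correction": True} if method == "approx" else {}
    res = stats.wilcoxon(d, alternative=alternative, method=method, **kwargs)
    return PairedTestResult(float(res.statistic), float(res.pvalue), int(ok.sum()), n_inf)


def per_bin_rare_fraction(subs: pd.DataFrame, bins: pd.Series) -> pd.DataFrame:
    """Rare fraction of non-synonymous substitutions per (bin, PTM side).

    *subs* needs protein, is_nonsyn, is_rare and in_ptm_region columns;
    *bins* maps protein -> bin. Returns one row per bin with ptm_value /
    nonptm_value columns (NaN where a side has no substitutions).
    """
    nonsyn = subs[subs["is_nonsyn"]].copy()
    nonsyn["bin"] = nonsyn["protein"].map(bins)
    nonsyn = nonsyn.dropna(subset=["bin"])
    grp = nonsyn.groupby(["bin", "in_ptm_region"])["is_rare"].agg(["sum", "size"])
    frac = grp["sum"] / grp["size"]
    table = frac.unstack("in_ptm_region")
    table = table.reindex(sorted(bins.unique()))
    out = pd.DataFrame(
        {
            "bin": table.index,
            "ptm_value": table.get(True, np.nan),
            "nonptm_value": table.get(False, np.nan),
        }
    ).reset_index(drop=True)
    return out


def per_bin_ka_ks(
    subs: pd.DataFrame, bins: pd.Series, protein_sites: pd.DataFrame
) -> pd.DataFrame:
    """Ka/Ks per (bin, PTM side).

    *protein_sites* has one row per protein with syn/nonsyn fractional site
    totals inside and outside PTM regions (columns syn_sites_ptm,
    nonsyn_sites_ptm, syn_sites_non, nonsyn_sites_non), as produced by
    :func:`protein_site_table`.
    """
    df = subs.copy()
    df["bin"] = df["protein"].map(bins)
    df = df.dropna(subset=["bin"])
    counts = (
        df.groupby(["bin", "in_ptm_region", "is_nonsyn"]).size().unstack(fill_value=0)
    )
    ps = protein_sites.copy()
    ps["bin"] = ps.index.map(bins)
    site_sums = ps.groupby("bin")[
        ["syn_sites_ptm", "nonsyn_sites_ptm", "syn_sites_non", "nonsyn_sites_non"]
    ].sum()
    rows = []
    for b in sorted(bins.unique()):
        row = {"bin": b}
        for side, tag in ((True, "ptm"), (False, "non")):
            try:
                n_syn = int(counts.loc[(b, side), False]) if (b, side) in counts.index else 0
                n_nonsyn = int(counts.loc[(b, side), True]) if (b, side) in counts.index else 0
            except KeyError:
                n_syn = n_nonsyn = 0
            syn_sites = site_sums.loc[b, f"syn_sites_{tag}"] if b in site_sums.index else 0.0
            nonsyn_sites = site_sums.loc[b, f"nonsyn_sites_{tag}"] if b in site_sums.index else 0.0
            ka = n_nonsyn / nonsyn_sites if nonsyn_sites > 0 else np.nan
            ks = n_syn / syn_sites if syn_sites > 0 else np.nan
            val = ka / ks if (np.isfinite(ka) and np.isfinite(ks) and ks > 0) else np.nan
            key = "ptm_value" if side else "nonptm_value"
            row[key] = val
        rows.append(row)
    return pd.DataFrame(rows)


def protein_site_table(models, region_masks) -> pd.DataFrame:
    """Per-protein fractional site totals split by PTM-region membership."""
    rows = {}
    for protein, model in models.items():
        mask = region_masks[protein]
        syn = np.empty(model.n_codons)
        nonsyn = np.empty(model.n_codons)
        for k in range(model.n_codons):
            syn[k], nonsyn[k] = CODON_SITE_COUNTS[model.codon(k + 1)]
        rows[protein] = {
            "syn_sites_ptm": syn[mask].sum(),
            "nonsyn_sites_ptm": nonsyn[mask].sum(),
            "syn_sites_non": syn[~mask].sum(),
            "nonsyn_sites_non": nonsyn[~mask].sum(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def stratified_summaries(subs: pd.DataFrame, protein_sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Selection summaries per {all, structured, disordered} x {PTM, non-PTM}.

    *subs* needs is_nonsyn, is_rare, in_disorder, in_ptm_region. Ka/Ks is
    included when a per-protein site table is supplied (all-sequence cells
    only use the region split of the table).
    """
    rows = []
    strata = [("all", None), ("structured", False), ("disordered", True)]
    for name, dis_flag in strata:
        sel = subs if dis_flag is None else subs[subs["in_disorder"] == dis_flag]
        for side in (True, False):
            cell = sel[sel["in_ptm_region"] == side]
            nonsyn = cell[cell["is_nonsyn"]]
            n_subs = len(nonsyn)
            n_rare = int(nonsyn["is_rare"].sum())
            row = SelectionSummary(
                stratum=f"{name}:{'ptm' if side else 'non-ptm'}",
                n_subs=n_subs,
                n_rare=n_rare,
                rare_fraction=n_rare / n_subs if n_subs else np.nan,
                n_syn=int((~cell["is_nonsyn"]).sum()),
            )
            if protein_sites is not None and dis_flag is None:
                tag = "ptm" if side else "non"
                syn_sites = protein_sites[f"syn_sites_{tag}"].sum()
                nonsyn_sites = protein_sites[f"nonsyn_sites_{tag}"].sum()
                row.syn_sites, row.nonsyn_sites = syn_sites, nonsyn_sites
                row.ka = n_subs / nonsyn_sites if nonsyn_sites else np.nan
                row.ks = row.n_syn / syn_sites if syn_sites else np.nan
                row.ka_ks = row.ka / row.ks if row.ks and np.isfinite(row.ks) else np.nan
            rows.append(row.__dict__)
    return pd.DataFrame(rows)
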