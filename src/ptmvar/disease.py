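"""Disease-mutation enrichment in PTM regions and the hotspot model.

Region-level enrichment of disease annotations is tested two ways: Fisher's
exact test on annotated-residue counts (split by structured vs disordered
sequence, whose variation rates differ) and an exact Poisson test on total
annotation counts, which respects residues carrying multiple disease
records. Central modified residues are tested against backgrounds of
matched amino acids (S/T/Y for phosphorylation; K for ubiquitination and
acetylation; K/R for methylation) to avoid codon bias. The per-gene hotspot
model fits a Poisson regression of per-residue mutation counts with protein
disorder as confounder and asks whether any PTM region holds more mutation
records than the protein-wide expectation; region p-values aggregate to a
gene-level score, BH-corrected across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import PTM_ALLOWED_RESIDUES, PTMRegion

FDR_SIGNIFICANT = 0.05


@dataclass
class EnrichmentResult:
    stratum: str
    observed: float
    expected: float
    expected_sd: float
    p: float
    odds_ratio: float = np.nan
    q: float = np.nan
    note: str = ""


@dataclass
class ActiveDriverResult:
    protein: str
    region_p: dict[tuple[int, int], float] = field(default_factory=dict)
    gene_p: float = 1.0
    gene_q: float = np.nan
    n_mutations: int = 0
    fallback: bool = False  # intercept-only rate used after GLM failure


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def region_enrichment_fisher(
    annotated: dict[str, np.ndarray],
    region_masks: dict[str, np.ndarray],
    disorder_masks: dict[str, np.ndarray],
) -> list[EnrichmentResult]:
    """Fisher's exact test of disease-annotated residues in PTM regions.

    All inputs are per-protein boolean arrays over residues of proteins with
    at least one PTM site. One 2x2 test per structure class: annotated? x
    in-region?, one-sided for enrichment.
    """
    results = []
    for name, want_disorder in (("structured", False), ("disordered", True)):
        a = b = c = d = 0
        for protein, ann in annotated.items():
            sel = disorder_masks[protein] == want_disorder
            reg = region_masks[protein]
            a += int((ann & reg & sel).sum())
            b += int((~ann & reg & sel).sum())
            c += int((ann & ~reg & sel).sum())
            d += int((~ann & ~reg & sel).sum())
        note = ""
        if a + c == 0:
            p, odds, note = 1.0, np.nan, "no annotated residues"
        elif c + d == 0:
            p, odds, note = 1.0, np.nan, "all residues in regions; odds ratio undefined"
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            odds = float(odds) if np.isfinite(odds) else np.nan
        n_region = a + b
        total = a + b + c + d
        rate = (a + c) / total if total else 0.0
        results.append(
            EnrichmentResult(
                stratum=name,
                observed=a,
                expected=rate * n_region,
                expected_sd=float(np.sqrt(rate * (1 - rate) * n_region)),
                p=float(p),
                odds_ratio=odds,
                note=note,
            )
        )
    return results


def region_enrichment_poisson(
    annotation_counts: dict[str, np.ndarray], region_masks: dict[str, np.ndarray]
) -> EnrichmentResult:
    """Exact Poisson test on total disease annotations in PTM regions.

    *annotation_counts* holds per-residue record counts, so residues with
    several disease annotations weigh accordingly. Expected = total records
    x (region residues / total residues); upper tail includes the observed
    value (P[X >= obs]).
    """
    total = sum(int(c.sum()) for c in annotation_counts.values())
    if total == 0:
        raise ValueError("no disease annotations; Poisson test undefined")
    region_res = sum(int(m.sum()) for m in region_masks.values())
    all_res = sum(m.size for m in region_masks.values())
    expected = total * region_res / all_res
    observed = sum(
        int(counts[region_masks[p]].sum()) for p, counts in annotation_counts.items()
    )
    if expected == 0:
        return EnrichmentResult("ptm-regions", observed, 0.0, 0.0, np.nan, note="degenerate: zero expectation")
    p = float(stats.poisson.sf(observed - 1, expected))
    return EnrichmentResult(
        "ptm-regions", observed, expected, float(np.sqrt(expected)), p
    )


def central_residue_enrichment(
    annotated: dict[str, np.ndarray],
    sites: pd.DataFrame,
    sequences: dict[str, str],
    ptm_type: str,
) -> EnrichmentResult:
    """Binomial test of disease annotations on modified vs matched residues.

    The background is every residue of the type's allowed amino acids in
    proteins carrying that PTM type; the test asks whether modified
    residues are annotated more often than that matched background rate.
    """
    allowed = PTM_ALLOWED_RESIDUES[ptm_type]
    typed = sites[sites["ptm_type"] == ptm_type]
    if typed.empty:
        return EnrichmentResult(ptm_type, 0, 0.0, 0.0, np.nan, note="no sites of this type")
    proteins = sorted(set(typed["protein"]))
    site_keys = set(zip(typed["protein"], typed["position"]))
    bg_total = bg_ann = 0
    n_sites = n_ann_sites = 0
    for protein in proteins:
        seq = sequences[protein]
        ann = annotated.get(protein, np.zeros(len(seq), dtype=bool))
        for pos0, aa in enumerate(seq):
            if aa not in allowed:
                continue
            if (protein, pos0 + 1) in site_keys:
                n_sites += 1
                n_ann_sites += int(ann[pos0])
            else:
                bg_total += 1
                bg_ann += int(ann[pos0])
    if bg_total == 0:
        raise ValueError(f"no matched background residues for {ptm_type}")
    rate = bg_ann / bg_total
    if n_sites == 0:
        return EnrichmentResult(ptm_type, 0, 0.0, 0.0, np.nan, note="no modified residues")
    res = stats.binomtest(n_ann_sites, n_sites, rate, alternative="greater")
    return EnrichmentResult(
        stratum=ptm_type,
        observed=n_ann_sites,
        expected=rate * n_sites,
        expected_sd=float(np.sqrt(n_sites * rate * (1 - rate))),
        p=float(res.pvalue),
    )


def active_driver(
    protein: str,
    length: int,
    mutation_counts: np.ndarray,
    regions: list[PTMRegion],
    disorder_mask: np.ndarray,
) -> ActiveDriverResult:
    """Per-gene PTM mutation-hotspot test.

    *mutation_counts* holds disease record counts per residue (index 0 =
    residue 1). A Poisson regression of counts on the disorder flag gives
    the protein-wide per-residue rate; each region's p-value is the upper
    Poisson tail of its observed record total against the summed model
    expectation, and region p-values aggregate to the gene score by
    Fisher's combined probability method. Regions with zero mutations score
    p = 1.
    """
    counts = np.asarray(mutation_counts, dtype=float)
    if counts.size != length or disorder_mask.size != length:
        raise ValueError(f"{protein}: track lengths disagree with protein length {length}")
    result = ActiveDriverResult(protein, n_mutations=int(counts.sum()))
    if not regions or counts.sum() == 0:
        result.region_p = {(r.start, r.end): 1.0 for r in regions}
        return result
    X = sm.add_constant(disorder_mask.astype(float), has_constant="add")
    try:
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=100)
        if not fit.converged or not np.all(np.isfinite(fit.params)):
            raise RuntimeError("non-convergence")
        mu = np.asarray(fit.predict(X))
    except Exception:
        mu = np.full(length, counts.mean())
        result.fallback = True
    for r in regions:
        sl = slice(r.start - 1, r.end)
        observed = int(counts[sl].sum())
        expected = float(mu[sl].sum())
        p = 1.0 if observed == 0 else float(stats.poisson.sf(observed - 1, expected))
        result.region_p[(r.start, r.end)] = p
    ps = np.clip(list(result.region_p.values()), 1e-300, 1.0)
    result.gene_p = float(stats.combine_pvalues(ps, method="fisher").pvalue) if len(ps) else 1.0
    return result


def active_driver_table(results: list[ActiveDriverResult]) -> pd.DataFrame:
    """Gene-level table with BH correction across genes."""
    if not results:
        return pd.DataFrame(columns=["protein", "gene_p", "gene_q", "top_region", "top_region_p", "n_mutations"])
    rows = []
    for r in results:
        if r.region_p:
            top = min(r.region_p, key=r.region_p.get)
            top_s = f"{top[0]}-{top[1]}"
            top_p = r.region_p[top]
        else:
            top_s, top_p = "", np.nan
        rows.append(
            {"protein": r.protein, "gene_p": r.gene_p, "top_region": top_s,
             "top_region_p": top_p, "n_mutations": r.n_mutations, "fallback": r.fallback}
        )
    out = pd.DataFrame(rows)
    out["gene_q"] = bh_adjust(out["gene_p"])
    for r, q in zip(results, out["gene_q"]):
        r.gene_q = float(q)
    return out[["protein", "gene_p", "gene_q", "top_region", "top_region_p", "n_mutations", "fallback"]]


def cancer_gene_enrichment(
    significant: set[str], cancer_genes: set[str], universe: set[str]
) -> EnrichmentResult:
    """Fisher's exact test of cancer-gene membership among significant genes."""
    if not universe:
        raise ValueError("empty gene universe")
    sig = significant & universe
    cg = cancer_genes & universe
    a = len(sig & cg)
    b = len(sig - cg)
    c = len(cg - sig)
    d = len(universe) - a - b - c
    note = ""
    if b + d == 0 or a + c == 0:
        odds, p = np.nan, 1.0
        note = "degenerate margins; odds ratio undefined"
    else:
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = float(odds) if np.isfinite(odds) else np.nan
    rate = len(cg) / len(universe)
    return EnrichmentResult(
        stratum="cancer-genes",
        observed=a,
        expected=rate * len(sig),
        expected_sd=float(np.sqrt(len(sig) * rate * (1 - rate))),
        p=float(p),
        odds_ratio=odds,
        note=note,
    )
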