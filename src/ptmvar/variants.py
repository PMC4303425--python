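"""Coding-variant annotation on protein gene models.

Translates single-nucleotide variants to amino-acid substitutions with the
standard nuclear codon table, classifies them synonymous / non-synonymous /
stop-gain, applies the rare/common derived-allele-frequency (DAF) split, and
computes the per-variant confounder features used by the regression models
(GC content of the ±17 bp window, codon degeneracy, nearest measured
recombination rate, alignment-based conservation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

RARE_DAF_THRESHOLD = 0.005  # "rare" means DAF <= 0.5%
GC_HALFWIDTH = 17  # 35 bp window around the SNV

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with '*' for stop codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> number of encoding codons
AA_DEGENERACY: dict[str, int] = {}
for _codon, _aa in CODON_TO_AA.items():
    if _aa != "*":
        AA_DEGENERACY[_aa] = AA_DEGENERACY.get(_aa, 0) + 1

#: amino acid -> sorted list of encoding codons
AA_CODONS: dict[str, list[str]] = {
    aa: sorted(c for c, v in CODON_TO_AA.items() if v == aa)
    for aa in AA_DEGENERACY
}


def _site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous / non-synonymous sites of one codon.

    Each of the nine single-nucleotide changes contributes 1/3 site to the
    class of its translated effect; changes creating a stop codon are
    excluded from both counts.
    """
    aa = CODON_TO_AA[codon]
    syn = nonsyn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut_aa = CODON_TO_AA[codon[:i] + b + codon[i + 1 :]]
            if mut_aa == "*":
                continue
            if mut_aa == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


#: codon -> (synonymous sites, non-synonymous sites)
CODON_SITE_COUNTS: dict[str, tuple[float, float]] = {
    c: _site_counts(c) for c in CODON_TO_AA if CODON_TO_AA[c] != "*"
}


def codon_degeneracy(aa: str) -> int:
    """Number of nucleotide triplets encoding *aa* in the standard code."""
    try:
        return AA_DEGENERACY[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid symbol {aa!r}") from None


@dataclass
class GeneModel:
    """Single-exon coding model: codon k of *cds* encodes residue k."""

    protein: str
    cds: str
    chrom: str | None = None
    cds_start: int = 1  # 1-based genomic coordinate of the first CDS base

    def __post_init__(self):
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.protein}: CDS length {len(self.cds)} not divisible by 3")
        if self.chrom is None:
            self.chrom = self.protein

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def translate(self) -> str:
        return str(Seq(self.cds).translate())

    def codon(self, residue_index: int) -> str:
        """Codon of the 1-based residue index."""
        return self.cds[(residue_index - 1) * 3 : residue_index * 3]


def validate_model(model: GeneModel, protein_seq: str) -> None:
    translated = model.translate()
    if translated != protein_seq:
        raise ValueError(f"{model.protein}: CDS translation does not match protein sequence")


# ---------------------------------------------------------------------------
# annotation

#: rejection reasons
REJECT_NOT_SNV = "not-snv"
REJECT_OUTSIDE_CDS = "outside-cds"
REJECT_REF_MISMATCH = "ref-mismatch"
REJECT_STOP_GAIN = "stop-gain"


def annotate_variant(pos: int, ref: str, alt: str, model: GeneModel) -> tuple[dict | None, str | None]:
    """Annotate one genomic SNV on a gene model.

    Returns ``(record, None)`` for accepted substitutions (synonymous or
    non-synonymous) and ``(None, reason)`` for rejected records (indels,
    out-of-CDS positions, reference mismatches, stop gains).
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
        return None, REJECT_NOT_SNV
    offset = pos - model.cds_start
    if offset < 0 or offset >= len(model.cds):
        return None, REJECT_OUTSIDE_CDS
    if model.cds[offset] != ref:
        return None, REJECT_REF_MISMATCH
    codon_index = offset // 3  # 0-based
    within = offset % 3
    codon = model.cds[codon_index * 3 : codon_index * 3 + 3]
    mut_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = CODON_TO_AA[codon]
    alt_aa = CODON_TO_AA[mut_codon]
    if alt_aa == "*":
        return None, REJECT_STOP_GAIN
    record = {
        "protein": model.protein,
        "residue_index": codon_index + 1,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "is_nonsyn": ref_aa != alt_aa,
        "cds_offset": offset,
    }
    return record, None


def annotate_variants(
    variants: pd.DataFrame, models: Mapping[str, GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate a variant table (CHROM, POS, REF, ALT, DAF[, DEPTH]).

    Variants with DAF = 0 are removed; stop gains, indels and malformed
    records are rejected with a reason. Returns (substitutions, rejected).
    """
    cols = {c.lower(): c for c in variants.columns}
    records, rejects = [], []
    for row in variants.itertuples(index=False):
        chrom = str(getattr(row, cols["chrom"]))
        daf = float(getattr(row, cols["daf"]))
        base = {
            "chrom": chrom,
            "pos": int(getattr(row, cols["pos"])),
            "ref": str(getattr(row, cols["ref"])),
            "alt": str(getattr(row, cols["alt"])),
        }
        if daf <= 0:
            rejects.append({**base, "reason": "daf-zero"})
            continue
        model = models.get(chrom)
        if model is None:
            rejects.append({**base, "reason": "no-gene-model"})
            continue
        rec, reason = annotate_variant(base["pos"], base["ref"], base["alt"], model)
        if rec is None:
            rejects.append({**base, "reason": reason})
            continue
        rec["daf"] = daf
        if "depth" in cols:
            rec["read_depth"] = getattr(row, cols["depth"])
        rec.update(base)
        records.append(rec)
    subs = pd.DataFrame(records)
    return subs, pd.DataFrame(rejects)


def filter_codon_conflicts(subs: pd.DataFrame) -> pd.DataFrame:
    """Drop non-synonymous substitutions sharing a codon with another one.

    Allele frequencies of two amino-acid changes in the same codon cannot be
    interpreted at the protein level, so all members of such groups are
    removed; synonymous records in the codon are kept.
    """
    if subs.empty:
        return subs
    nonsyn = subs[subs["is_nonsyn"]]
    counts = nonsyn.groupby(["protein", "residue_index"]).size()
    conflicted = set(counts[counts >= 2].index)
    if not conflicted:
        return subs
    keys = list(zip(subs["protein"], subs["residue_index"]))
    drop = subs["is_nonsyn"].to_numpy() & np.array([k in conflicted for k in keys])
    return subs[~drop].reset_index(drop=True)


def classify_rare(subs: pd.DataFrame, threshold: float = RARE_DAF_THRESHOLD) -> pd.DataFrame:
    """Set the is_rare flag: DAF <= threshold (boundary inclusive)."""
    if threshold <= 0:
        raise ValueError(f"rare DAF threshold must be positive, got {threshold}")
    subs = subs.copy()
    subs["is_rare"] = subs["daf"] <= threshold
    return subs


def gc_window(cds: str, cds_offset: int, halfwidth: int = GC_HALFWIDTH) -> float:
    """Percent G+C in the window of ±halfwidth bases around a CDS position.

    The window is clipped at the CDS bounds (0-based *cds_offset*).
    """
    lo = max(0, cds_offset - halfwidth)
    hi = min(len(cds), cds_offset + halfwidth + 1)
    window = cds[lo:hi]
    return 100.0 * (window.count("G") + window.count("C")) / len(window)


def nearest_recomb(
    positions: Sequence[int], track_loci: Sequence[int], track_rates: Sequence[float]
) -> np.ndarray:
    """Rate of the nearest measured recombination locus for each position.

    Ties between two equidistant loci resolve to the lower coordinate.
    """
    loci = np.asarray(track_loci)
    rates = np.asarray(track_rates, dtype=float)
    if loci.size == 0:
        raise ValueError("empty recombination rate track")
    order = np.argsort(loci, kind="stable")
    loci, rates = loci[order], rates[order]
    pos = np.asarray(positions)
    right = np.searchsorted(loci, pos, side="left")
    left = np.clip(right - 1, 0, loci.size - 1)
    right = np.clip(right, 0, loci.size - 1)
    d_left = np.abs(pos - loci[left])
    d_right = np.abs(loci[right] - pos)
    choose_left = d_left <= d_right  # tie -> lower coordinate
    return np.where(choose_left, rates[left], rates[right])


def conservation_score(residue: str, column: Sequence[str], matrix=None, gap_score: float = -10.0) -> float:
    """Mean BLOSUM62 score of *residue* against one alignment column.

    Gaps score -10; the mean (not the sum) keeps scores comparable across
    alignment depths.
    """
    if matrix is None:
        matrix = _blosum62()
    scores = [gap_score if c == "-" else float(matrix[residue, c]) for c in column]
    return float(np.mean(scores))


_B62 = None


def _blosum62():
    global _B62
    if _B62 is None:
        from Bio.Align import substitution_matrices

        _B62 = substitution_matrices.load("BLOSUM62")
    return _B62
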