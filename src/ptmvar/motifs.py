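"""Kinase motif scoring, calibration and motif-breaker enumeration.

A kinase's target preference is a 15-column position weight matrix (PWM)
centred on the phosphoacceptor. A phosphosite flank is scored as the product
of pseudocounted column probabilities (computed in log space). Score
thresholds are calibrated against positive control target windows and
negative controls sampled from non-phosphorylated S/T/Y centres: a site is
predicted bound iff its score reaches both the bottom decile of positives
and the top decile of negatives. Exhaustive substitution of bound-site
flanks yields motif-breaker residues: any substitution reducing the binding
score >= 4-fold. Kinase-level selection and disease tests and the
kinase-substrate network build on these calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .resampling import permutation_test, rare_fraction_statistic

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
WINDOW = 15
CENTER = WINDOW // 2
PSEUDOCOUNT = 1e-3
BREAKER_FOLD = 4.0  # >= 4-fold score loss defines a motif-breaker
PAD = "X"  # terminal padding symbol; scores the column mean


@dataclass
class PWM:
    """15 x 20 position probability matrix for one kinase."""

    kinase: str
    matrix: np.ndarray  # raw probabilities, rows = positions, cols = AA20
    pseudocount: float = PSEUDOCOUNT
    pos10: float | None = None  # calibrated thresholds (log10 score scale)
    neg90: float | None = None
    _logp: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (WINDOW, 20):
            raise ValueError(f"{self.kinase}: PWM must be {WINDOW}x20, got {m.shape}")
        sums = m.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{self.kinase}: PWM columns must each sum to 1")
        self.matrix = m
        probs = m + self.pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        self._logp = np.log10(probs)

    @property
    def probs(self) -> np.ndarray:
        """Pseudocounted, renormalised probabilities."""
        return 10.0 ** self._logp

    @property
    def consensus(self) -> str:
        return "".join(AA20[j] for j in self.matrix.argmax(axis=1))

    @property
    def bound_threshold(self) -> float:
        if self.pos10 is None or self.neg90 is None:
            raise ValueError(f"{self.kinase}: PWM is not calibrated")
        return max(self.pos10, self.neg90)


def score_site(pwm: PWM, window: str) -> float:
    """Log10 binding score of a 15-residue window (product of column probs).

    The padding symbol (at protein termini) scores each column's mean
    probability, a neutral contribution.
    """
    if len(window) != WINDOW:
        raise ValueError(f"window must be {WINDOW} residues, got {len(window)}")
    total = 0.0
    probs = pwm.probs
    for i, aa in enumerate(window):
        if aa == PAD:
            total += np.log10(probs[i].mean())
        elif aa in AA_INDEX:
            total += pwm._logp[i, AA_INDEX[aa]]
        else:
            raise ValueError(f"non-amino-acid symbol {aa!r} in window")
    return float(total)


def flank_window(sequence: str, position: int) -> str:
    """±7 window around a 1-based position, padded at protein termini."""
    out = []
    for p in range(position - CENTER, position + CENTER + 1):
        out.append(sequence[p - 1] if 1 <= p <= len(sequence) else PAD)
    return "".join(out)


def calibrate(pwm: PWM, positives: list[str], negatives: list[str],
              min_pos: int = 10, min_neg: int = 100) -> PWM:
    """Set the bound-site thresholds from control windows.

    pos10 is the 10th percentile of positive-control scores and neg90 the
    90th percentile of negative-control scores (type-7 linear-interpolation
    quantiles); a site is predicted bound iff its score >= max(pos10, neg90).
    """
    if len(positives) < min_pos:
        raise ValueError(f"{pwm.kinase}: need >= {min_pos} positive controls, got {len(positives)}")
    if len(negatives) < min_neg:
        raise ValueError(f"{pwm.kinase}: need >= {min_neg} negative controls, got {len(negatives)}")
    pos_scores = np.array([score_site(pwm, w) for w in positives])
    neg_scores = np.array([score_site(pwm, w) for w in negatives])
    pwm.pos10 = float(np.percentile(pos_scores, 10))
    pwm.neg90 = float(np.percentile(neg_scores, 90))
    return pwm


def is_bound(pwm: PWM, window: str) -> bool:
    return score_site(pwm, window) >= pwm.bound_threshold


def find_breakers(pwm: PWM, sites: pd.DataFrame) -> pd.DataFrame:
    """Enumerate motif-breaker residues of predicted bound sites.

    *sites* has protein, position (phosphosite) and window columns for
    sites already predicted bound by *pwm*. Every flank residue is mutated
    to every alternative amino acid; a residue is a breaker when some
    substitution loses >= 4-fold binding score (boundary inclusive). Scores
    of other columns cancel, so the fold change is the ratio of the
    pseudocounted column probabilities. One row per (residue, kinase,
    phosphosite) with the maximal fold change.
    """
    rows = []
    probs = pwm.probs
    col_min = probs.min(axis=1)
    for rec in sites.itertuples(index=False):
        window = rec.window
        for offset in range(-CENTER, CENTER + 1):
            if offset == 0:
                continue  # substitutions of the modified residue itself are handled separately
            i = CENTER + offset
            wt = window[i]
            if wt == PAD:
                continue
            fold = probs[i, AA_INDEX[wt]] / col_min[i]
            if fold >= BREAKER_FOLD:
                rows.append(
                    {
                        "protein": rec.protein,
                        "position": rec.position + offset,
                        "kinase": pwm.kinase,
                        "phosphosite": rec.position,
                        "offset": offset,
                        "wt_aa": wt,
                        "fold_change": float(fold),
                    }
                )
    return pd.DataFrame(
        rows, columns=["protein", "position", "kinase", "phosphosite", "offset", "wt_aa", "fold_change"]
    )


def predict_bound_sites(pwm: PWM, phosphosites: pd.DataFrame, sequences) -> pd.DataFrame:
    """Score every phosphosite flank and keep predicted bound sites."""
    rows = []
    for rec in phosphosites.itertuples(index=False):
        window = flank_window(sequences[rec.protein], int(rec.position))
        score = score_site(pwm, window)
        if score >= pwm.bound_threshold:
            rows.append({"protein": rec.protein, "position": int(rec.position),
                         "window": window, "score": score})
    return pd.DataFrame(rows, columns=["protein", "position", "window", "score"])


def kinase_level_tests(
    breakers: pd.DataFrame,
    background_residues: pd.DataFrame,
    disease: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-kinase selection and disease tests of motif-breaker residues.

    For each kinase: (a) amino-acid-weighted permutation test of the rare
    fraction among substitutions on its breaker residues against the
    phosphoprotein residue background; (b) Fisher's exact test of disease
    annotation counts on breaker residues vs the rest of the background,
    BH-adjusted across kinases. *background_residues* is a residue table
    (protein, position, aa, n_subs, n_rare) of all phosphoprotein residues;
    *disease* has protein, residue_index rows. Kinases whose breaker
    residues carry no substitutions are skipped.
    """
    rng = np.random.default_rng(seed)
    disease_keys = (
        set(zip(disease["protein"], disease["residue_index"])) if disease is not None and len(disease) else set()
    )
    bg_keys = list(zip(background_residues["protein"], background_residues["position"]))
    bg_disease = np.array([k in disease_keys for k in bg_keys])
    rows = []
    for kinase, grp in breakers.groupby("kinase"):
        res = grp[["protein", "position"]].drop_duplicates()
        test = background_residues.merge(res, on=["protein", "position"])
        if test["n_subs"].sum() == 0:
            rows.append({"kinase": kinase, "skipped": True})
            continue
        perm = permutation_test(
            test, background_residues, rare_fraction_statistic,
            n_perm=n_perm, seed=rng, direction="greater",
        )
        row = {
            "kinase": kinase,
            "skipped": False,
            "n_breaker_residues": len(test),
            "observed_rare_fraction": perm.observed,
            "expected_rare_fraction": perm.expected_mean,
            "expected_sd": perm.expected_sd,
            "perm_p": perm.p_value,
        }
        test_keys = set(zip(test["protein"], test["position"]))
        in_test = np.array([k in test_keys for k in bg_keys])
        a = int((in_test & bg_disease).sum())
        b = int((in_test & ~bg_disease).sum())
        c = int((~in_test & bg_disease).sum())
        d = int((~in_test & ~bg_disease).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        row.update({"disease_in_breakers": a, "fisher_or": float(odds) if np.isfinite(odds) else np.nan,
                    "fisher_p": float(p)})
        rows.append(row)
    out = pd.DataFrame(rows)
    if "fisher_p" in out and out["fisher_p"].notna().any():
        mask = out["fisher_p"].notna()
        out.loc[mask, "fisher_q"] = multipletests(out.loc[mask, "fisher_p"], method="fdr_bh")[1]
    return out


def build_network(
    bindings: pd.DataFrame, disease_genes: set[str] | None = None
) -> tuple[nx.Graph, dict]:
    """Bipartite kinase-substrate network with the disease-degree test.

    *bindings* has kinase / protein (substrate) / position columns. The
    per-substrate degree is its number of distinct bound kinases; a
    one-sided rank-sum test asks whether disease-gene substrates have more
    kinase interactions than other substrates.
    """
    g = nx.Graph()
    for rec in bindings.itertuples(index=False):
        g.add_node(f"kinase::{rec.kinase}", kind="kinase", name=rec.kinase)
        is_dg = disease_genes is not None and rec.protein in disease_genes
        g.add_node(f"substrate::{rec.protein}", kind="substrate", name=rec.protein,
                   disease_gene=bool(is_dg))
        g.add_edge(f"kinase::{rec.kinase}", f"substrate::{rec.protein}")
    degrees = {
        data["name"]: g.degree(n)
        for n, data in g.nodes(data=True)
        if data["kind"] == "substrate"
    }
    test: dict = {"p": None, "n_disease": 0, "n_other": len(degrees)}
    if disease_genes:
        dg = [d for name, d in degrees.items() if name in disease_genes]
        other = [d for name, d in degrees.items() if name not in disease_genes]
        test["n_disease"], test["n_other"] = len(dg), len(other)
        if dg and other:
            if len(set(dg) | set(other)) == 1:
                test["p"] = 1.0
            else:
                res = stats.mannwhitneyu(dg, other, alternative="greater")
                test["p"] = float(res.pvalue)
    return g, test


# ---------------------------------------------------------------------------
# PWM TSV format: columns kinase, pos (1..15), then the 20 amino acids

def pwms_to_frame(pwms: list[PWM]) -> pd.DataFrame:
    rows = []
    for pwm in pwms:
        for i in range(WINDOW):
            row = {"kinase": pwm.kinase, "pos": i + 1}
            row.update({aa: pwm.matrix[i, j] for j, aa in enumerate(AA20)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_pwms(df: pd.DataFrame) -> list[PWM]:
    pwms = []
    for kinase, grp in df.groupby("kinase", sort=True):
        grp = grp.sort_values("pos")
        matrix = grp[list(AA20)].to_numpy(dtype=float)
        pwms.append(PWM(str(kinase), matrix))
    return pwms
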