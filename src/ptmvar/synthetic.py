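"""Synthetic study cohorts with known planted effects.

Generates a complete, seeded input set for the pipeline: a proteome with
realistic amino-acid composition and codon structure, disorder masks, PTM
sites preferentially placed in disorder, coding variants whose rare-variant
odds are multiplied inside PTM regions by a configurable planted effect,
alignment-style conservation tracks, disease annotations enriched in PTM
regions, gene sets, kinase PWMs with planted specificity, enzyme and drug
link tables, and a truth file recording every planted parameter. Every
output is a deterministic function of the configuration seed, giving every
downstream statistic a parameter-recovery test surface.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .motifs import AA20, AA_INDEX, CENTER, PWM, WINDOW
from .regions import (
    PTM_ALLOWED_RESIDUES,
    PTM_TYPES,
    PTMSite,
    build_regions,
    frame_to_sites,
    region_masks,
    sites_to_frame,
)
from .variants import AA_CODONS, CODON_TO_AA, GeneModel

#: average human proteome amino-acid frequencies (UniProt reviewed set),
#: ordered as AA20 and normalised to 1
HUMAN_AA_FREQS = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0573, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}
_total = sum(HUMAN_AA_FREQS.values())
HUMAN_AA_FREQS = {a: v / _total for a, v in HUMAN_AA_FREQS.items()}

DISEASE_VOCAB = (
    "cardiomyopathy", "diabetes", "cystic fibrosis", "migraine", "deafness",
    "epilepsy", "retinitis pigmentosa", "anemia", "nephropathy", "myopathy",
    "neuropathy", "immunodeficiency", "obesity", "hypertension", "cancer",
    "sclerosis", "thrombophilia", "albinism", "rickets", "porphyria",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: codon integer (b0*16 + b1*4 + b2) -> amino-acid index in AA20, or -1 for stop
CODON_INT_TO_AA = np.full(64, -1, dtype=np.int8)
for _codon, _aa in CODON_TO_AA.items():
    _ci = _BASE_INDEX[_codon[0]] * 16 + _BASE_INDEX[_codon[1]] * 4 + _BASE_INDEX[_codon[2]]
    CODON_INT_TO_AA[_ci] = AA_INDEX[_aa] if _aa != "*" else -1


def _logit(p):
    return np.log(p / (1 - p))


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Planted parameters of a synthetic cohort; the seed fixes everything."""

    n_proteins: int = 300
    length_dist: tuple[float, float] = (400.0, 120.0)  # (mean, sd) residues
    aa_freqs: tuple[float, ...] = tuple(HUMAN_AA_FREQS[a] for a in AA20)
    ptm_site_rate: float = 2.0  # sites per 100 residues
    ptm_type_mix: tuple[float, ...] = (0.72, 0.12, 0.10, 0.06)  # phospho, ubiq, acet, methyl
    disorder_fraction: float = 0.35
    disorder_ptm_odds: float = 2.0  # odds multiplier of placing a site in disorder
    variant_rate: float = 0.06  # substitutions per residue
    rare_fraction_base: float = 0.6  # P(rare) for non-PTM substitutions
    ptm_constraint_effect: float = 1.5  # odds multiplier on rare inside regions (1 = null)
    disease_rate_base: float = 0.01  # per-residue disease annotation probability
    disease_ptm_effect: float = 1.5  # odds multiplier inside regions
    n_pwms: int = 6
    pwm_sharpness: float = 0.8  # consensus probability of informative columns
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins: must be >= 1")
        if self.length_dist[0] <= 0:
            raise ValueError("length_dist: mean protein length must be positive")
        freqs = np.asarray(self.aa_freqs, dtype=float)
        if freqs.size != 20 or (freqs < 0).any() or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("aa_freqs: must be 20 non-negative values summing to 1")
        mix = np.asarray(self.ptm_type_mix, dtype=float)
        if mix.size != len(PTM_TYPES) or (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("ptm_type_mix: proportions must cover the 4 PTM types and sum to 1")
        for name in ("disorder_fraction", "rare_fraction_base", "disease_rate_base"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}: must lie in [0, 1]")
        for name in ("ptm_constraint_effect", "disease_ptm_effect", "disorder_ptm_odds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.variant_rate < 0 or self.ptm_site_rate < 0:
            raise ValueError("variant_rate / ptm_site_rate: must be non-negative")
        if not 0 < self.pwm_sharpness < 1:
            raise ValueError("pwm_sharpness: must lie in (0, 1)")


@dataclass
class SyntheticCohort:
    """In-memory synthetic study inputs plus the planted truth."""

    config: SimulationConfig
    proteins: dict[str, str]
    models: dict[str, GeneModel]
    sites: pd.DataFrame
    variants: pd.DataFrame
    disorder_masks: dict[str, np.ndarray]
    conservation: dict[str, np.ndarray]
    disease: pd.DataFrame
    gene_sets: dict[str, set[str]]
    pwms: list[PWM]
    site_enzymes: pd.DataFrame
    drug_targets: pd.DataFrame
    recomb: pd.DataFrame  # chrom, pos, rate
    truth: dict = field(default_factory=dict)

    @property
    def protein_lengths(self) -> dict[str, int]:
        return {p: len(s) for p, s in self.proteins.items()}

    def ptm_sites(self) -> list[PTMSite]:
        return frame_to_sites(self.sites)

    def disorder_intervals(self) -> pd.DataFrame:
        rows = []
        for protein in sorted(self.disorder_masks):
            mask = self.disorder_masks[protein]
            padded = np.concatenate([[False], mask, [False]])
            starts = np.flatnonzero(~padded[:-1] & padded[1:])
            ends = np.flatnonzero(padded[:-1] & ~padded[1:])
            for s, e in zip(starts, ends):
                rows.append({"protein": protein, "start": s + 1, "end": e})
        return pd.DataFrame(rows, columns=["protein", "start", "end"])

    # -- serialisation ------------------------------------------------------

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_fasta(self.proteins, outdir / "proteins.fasta")
        pio.write_fasta({p: m.cds for p, m in self.models.items()}, outdir / "cds.fasta")
        pio.write_tsv(self.sites, outdir / "ptm_sites.tsv")
        pio.write_tsv(self.variants, outdir / "variants.tsv")
        pio.write_tsv(self.disorder_intervals(), outdir / "disorder.tsv")
        cons = pd.concat(
            [
                pd.DataFrame(
                    {"protein": p, "position": np.arange(1, len(v) + 1), "score": np.round(v, 4)}
                )
                for p, v in sorted(self.conservation.items())
            ],
            ignore_index=True,
        )
        pio.write_tsv(cons, outdir / "conservation.tsv")
        pio.write_tsv(self.disease, outdir / "disease.tsv")
        pio.write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        from .motifs import pwms_to_frame

        pio.write_tsv(pwms_to_frame(self.pwms), outdir / "pwms.tsv")
        pio.write_tsv(self.site_enzymes, outdir / "site_enzymes.tsv")
        pio.write_tsv(self.drug_targets, outdir / "drug_targets.tsv")
        pio.write_tsv(self.recomb, outdir / "recomb.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=list)

    @classmethod
    def read(cls, indir) -> "SyntheticCohort":
        indir = Path(indir)
        with open(indir / "truth.json") as fh:
            truth = json.load(fh)
        cfg = truth["config"].copy()
        for key in ("length_dist", "aa_freqs", "ptm_type_mix"):
            cfg[key] = tuple(cfg[key])
        config = SimulationConfig(**cfg)
        proteins = pio.read_fasta(indir / "proteins.fasta")
        cds = pio.read_fasta(indir / "cds.fasta")
        models = {p: GeneModel(p, c) for p, c in cds.items()}
        lengths = {p: len(s) for p, s in proteins.items()}
        disorder = pio.read_tsv(indir / "disorder.tsv")
        masks = {p: np.zeros(n, dtype=bool) for p, n in lengths.items()}
        for rec in disorder.itertuples(index=False):
            masks[rec.protein][rec.start - 1 : rec.end] = True
        cons_df = pio.read_tsv(indir / "conservation.tsv")
        conservation = {
            p: grp.sort_values("position")["score"].to_numpy(dtype=float)
            for p, grp in cons_df.groupby("protein")
        }
        from .motifs import frame_to_pwms

        return cls(
            config=config,
            proteins=proteins,
            models=models,
            sites=pio.read_tsv(indir / "ptm_sites.tsv", keep_default_na=False),
            variants=pio.read_tsv(indir / "variants.tsv"),
            disorder_masks=masks,
            conservation=conservation,
            disease=pio.read_tsv(indir / "disease.tsv"),
            gene_sets=pio.read_gmt(indir / "gene_sets.gmt"),
            pwms=frame_to_pwms(pio.read_tsv(indir / "pwms.tsv")),
            site_enzymes=pio.read_tsv(indir / "site_enzymes.tsv"),
            drug_targets=pio.read_tsv(indir / "drug_targets.tsv"),
            recomb=pio.read_tsv(indir / "recomb.tsv"),
            truth=truth,
        )


# ---------------------------------------------------------------------------
# generation


def _simulate_disorder(length: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating ordered/disordered blocks with the target disordered fraction."""
    mask = np.zeros(length, dtype=bool)
    if fraction <= 0:
        return mask
    if fraction >= 1:
        return ~mask
    mean_dis = 20.0
    mean_ord = mean_dis * (1 - fraction) / fraction
    pos = 0
    state = rng.random() < fraction
    while pos < length:
        mean = mean_dis if state else mean_ord
        run = max(1, int(round(rng.exponential(mean))))
        if state:
            mask[pos : pos + run] = True
        pos += run
        state = not state
    return mask


def _simulate_conservation(
    aa_idx: np.ndarray, disorder: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean BLOSUM62 score of each residue against a simulated depth-8 column.

    Disordered residues substitute more often, so their columns score lower
    — the correlated confounder the regression models must handle.
    """
    from .variants import _blosum62

    B = _blosum62()
    b = np.array([[float(B[x, y]) for y in AA20] for x in AA20])
    diag = np.diag(b)
    n = aa_idx.size
    depth = 8
    p_sub = np.where(disorder, 0.45, 0.12) + rng.normal(0, 0.03, size=n)
    p_sub = np.clip(p_sub, 0.02, 0.9)
    n_same = rng.binomial(depth, 1 - p_sub)
    partners = rng.integers(0, 20, size=(n, depth))
    rand_scores = b[aa_idx[:, None], partners]
    col = np.arange(depth)[None, :]
    scores = np.where(col < n_same[:, None], diag[aa_idx][:, None], rand_scores)
    return scores.mean(axis=1)


def _simulate_cds(sequence: str, rng: np.random.Generator) -> str:
    """Pick synonymous codons with a per-protein GC bias."""
    gc_bias = rng.normal(0.0, 0.8)
    codons = np.empty(len(sequence), dtype=object)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    for aa in sorted(set(sequence)):
        options = AA_CODONS[aa]
        gc_counts = np.array([c.count("G") + c.count("C") for c in options], dtype=float)
        w = np.exp(gc_bias * gc_counts)
        w /= w.sum()
        pos = np.flatnonzero(arr == ord(aa))
        picks = rng.choice(len(options), size=pos.size, p=w)
        for p, k in zip(pos, picks):
            codons[p] = options[k]
    return "".join(codons)


def _place_ptm_sites(
    protein: str,
    sequence: str,
    disorder: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PTMSite]:
    length = len(sequence)
    n_target = rng.poisson(length * config.ptm_site_rate / 100.0)
    if n_target == 0:
        return []
    type_draws = rng.choice(len(PTM_TYPES), size=n_target, p=np.asarray(config.ptm_type_mix))
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    sites: list[PTMSite] = []
    for t_idx in range(len(PTM_TYPES)):
        k = int((type_draws == t_idx).sum())
        if k == 0:
            continue
        ptm_type = PTM_TYPES[t_idx]
        allowed = PTM_ALLOWED_RESIDUES[ptm_type]
        eligible = np.flatnonzero(np.isin(arr, [ord(a) for a in allowed]))
        if eligible.size == 0:
            continue
        w = np.where(disorder[eligible], config.disorder_ptm_odds, 1.0)
        w = w / w.sum()
        k = min(k, eligible.size)
        chosen = rng.choice(eligible, size=k, replace=False, p=w)
        for pos0 in sorted(chosen.tolist()):
            n_pubs = 1 + int(rng.poisson(1.0))
            enzymes: tuple[str, ...] = ()
            if ptm_type == "phospho" and rng.random() < 0.4:
                enzymes = (f"KIN{rng.integers(config.n_pwms)}",)
            elif ptm_type != "phospho" and rng.random() < 0.3:
                enzymes = (f"{ptm_type.upper()}E{rng.integers(3)}",)
            sites.append(PTMSite(protein, pos0 + 1, sequence[pos0], ptm_type, n_pubs, enzymes))
    return sites


def _simulate_variants(
    protein: str,
    model: GeneModel,
    region_mask: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    length = model.n_codons
    n_var = rng.poisson(length * config.variant_rate)
    if n_var == 0:
        return pd.DataFrame()
    cds_arr = np.frombuffer(model.cds.encode(), dtype=np.uint8)
    base_of = np.full(256, -1, dtype=np.int8)
    for i, bch in enumerate("ACGT"):
        base_of[ord(bch)] = i
    residue0 = rng.integers(0, length, size=n_var)
    codon_pos = rng.integers(0, 3, size=n_var)
    offset = residue0 * 3 + codon_pos
    ref_idx = base_of[cds_arr[offset]]
    alt_shift = rng.integers(1, 4, size=n_var)
    alt_idx = (ref_idx + alt_shift) % 4
    # translated effect of the alternate base
    b0 = base_of[cds_arr[residue0 * 3]].astype(int)
    b1 = base_of[cds_arr[residue0 * 3 + 1]].astype(int)
    b2 = base_of[cds_arr[residue0 * 3 + 2]].astype(int)
    nb0 = np.where(codon_pos == 0, alt_idx, b0)
    nb1 = np.where(codon_pos == 1, alt_idx, b1)
    nb2 = np.where(codon_pos == 2, alt_idx, b2)
    ref_aa = CODON_INT_TO_AA[b0 * 16 + b1 * 4 + b2]
    alt_aa = CODON_INT_TO_AA[nb0 * 16 + nb1 * 4 + nb2]
    is_nonsyn = (alt_aa != ref_aa) & (alt_aa >= 0)
    in_region = region_mask[residue0]
    logit_rare = _logit(config.rare_fraction_base) + np.where(
        is_nonsyn & in_region, np.log(config.ptm_constraint_effect), 0.0
    )
    rare = rng.random(n_var) < _sigmoid(logit_rare)
    daf = np.where(
        rare,
        rng.uniform(1e-5, 0.005, size=n_var),
        rng.uniform(0.005 + 1e-9, 0.5, size=n_var),
    )
    depth = np.maximum(10, rng.normal(100, 20, size=n_var)).astype(int)
    bases = np.array(list("ACGT"))
    return pd.DataFrame(
        {
            "chrom": protein,
            "pos": offset + 1,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "daf": np.round(daf, 8),
            "depth": depth,
            "protein": protein,
            "residue_index": residue0 + 1,
        }
    )


def _make_pwm(kinase: str, sharpness: float, rng: np.random.Generator) -> PWM:
    matrix = np.full((WINDOW, 20), 1 / 20.0)
    center = np.full(20, 0.10 / 17)
    center[AA_INDEX["S"]] = 0.55
    center[AA_INDEX["T"]] = 0.25
    center[AA_INDEX["Y"]] = 0.10
    matrix[CENTER] = center / center.sum()
    informative = rng.choice([o for o in range(-5, 6) if o != 0], size=4, replace=False)
    rest = (1 - sharpness) / 19
    for off in informative:
        cons = int(rng.integers(0, 20))
        col = np.full(20, rest)
        col[cons] = sharpness
        matrix[CENTER + off] = col
    return PWM(kinase, matrix)


def make_calibration_controls(
    pwm: PWM, aa_freqs, n_pos: int = 50, n_neg: int = 200, seed: int | np.random.Generator = 0
) -> tuple[list[str], list[str]]:
    """Positive (PWM-drawn) and negative (background, S/T/Y-centred) windows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = np.array(list(AA20))
    positives = []
    for _ in range(n_pos):
        chars = [aa[rng.choice(20, p=pwm.matrix[i] / pwm.matrix[i].sum())] for i in range(WINDOW)]
        positives.append("".join(chars))
    freqs = np.asarray(aa_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    sty = np.array([AA_INDEX[x] for x in "STY"])
    sty_w = freqs[sty] / freqs[sty].sum()
    negatives = []
    for _ in range(n_neg):
        chars = aa[rng.choice(20, size=WINDOW, p=freqs)]
        chars[CENTER] = aa[sty[rng.choice(3, p=sty_w)]]
        negatives.append("".join(chars))
    return positives, negatives


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mean, sd = config.length_dist
    lengths = np.maximum(60, np.round(rng.normal(mean, sd, size=config.n_proteins))).astype(int)
    names = [f"P{i:05d}" for i in range(config.n_proteins)]
    freqs = np.asarray(config.aa_freqs, dtype=float)
    aa_arr = np.array(list(AA20))

    proteins: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    disorder_masks: dict[str, np.ndarray] = {}
    conservation: dict[str, np.ndarray] = {}
    all_sites: list[PTMSite] = []
    for name, L in zip(names, lengths):
        aa_idx = rng.choice(20, size=L, p=freqs)
        seq = "".join(aa_arr[aa_idx])
        proteins[name] = seq
        disorder_masks[name] = _simulate_disorder(L, config.disorder_fraction, rng)
        conservation[name] = _simulate_conservation(aa_idx, disorder_masks[name], rng)
        models[name] = GeneModel(name, _simulate_cds(seq, rng))
        all_sites.extend(_place_ptm_sites(name, seq, disorder_masks[name], config, rng))

    regions = build_regions(all_sites, {p: len(s) for p, s in proteins.items()})
    masks = region_masks(regions, {p: len(s) for p, s in proteins.items()})

    variant_frames = [
        _simulate_variants(name, models[name], masks[name], config, rng) for name in names
    ]
    variants = pd.concat([f for f in variant_frames if not f.empty], ignore_index=True)

    disease_rows = []
    record_counter = 0
    vocab = np.array(DISEASE_VOCAB)
    for name in names:
        mask = masks[name]
        p = _sigmoid(_logit(config.disease_rate_base) + np.where(mask, np.log(config.disease_ptm_effect), 0.0))
        hits = np.flatnonzero(rng.random(mask.size) < p)
        for pos0 in hits:
            n_records = 1 + int(rng.poisson(0.6))
            disease_rows.append(
                {
                    "protein": name,
                    "residue_index": int(pos0) + 1,
                    "disease": str(vocab[rng.integers(vocab.size)]),
                    "n_records": n_records,
                    "record_id": f"R{record_counter:06d}",
                }
            )
            record_counter += 1
    disease = pd.DataFrame(
        disease_rows, columns=["protein", "residue_index", "disease", "n_records", "record_id"]
    )

    n_sets = max(2, min(20, config.n_proteins // 10))
    gene_sets = {}
    for s in range(n_sets):
        lo = min(8, config.n_proteins)
        size = int(rng.integers(lo, min(40, config.n_proteins) + 1))
        members = rng.choice(names, size=min(size, config.n_proteins), replace=False)
        gene_sets[f"SET{s:03d}"] = set(members.tolist())

    pwms = [_make_pwm(f"KIN{k}", config.pwm_sharpness, rng) for k in range(config.n_pwms)]

    sites_df = sites_to_frame(all_sites)
    enz = sites_df[sites_df["enzymes"] != ""][["protein", "position", "enzymes"]].copy()
    enz = enz.rename(columns={"enzymes": "enzyme"})
    site_enzymes = enz.assign(enzyme=enz["enzyme"].str.split(";")).explode("enzyme").reset_index(drop=True)

    enzymes_pool = sorted(set(site_enzymes["enzyme"])) if len(site_enzymes) else [f"KIN{k}" for k in range(config.n_pwms)]
    drug_rows = []
    for j, enzyme in enumerate(enzymes_pool):
        for _ in range(int(rng.integers(0, 3))):
            drug_rows.append({"drug": f"DRUG{rng.integers(2 * max(1, config.n_pwms)):03d}", "enzyme": enzyme})
    drug_targets = pd.DataFrame(drug_rows, columns=["drug", "enzyme"]).drop_duplicates().reset_index(drop=True)

    recomb_rows = []
    for name, L in zip(names, lengths):
        loci = np.cumsum(rng.integers(20, 80, size=max(2, 3 * L // 50)))
        loci = loci[loci <= 3 * L]
        rates = np.round(rng.exponential(1.5, size=loci.size), 6)
        recomb_rows.append(pd.DataFrame({"chrom": name, "pos": loci, "rate": rates}))
    recomb = pd.concat(recomb_rows, ignore_index=True)

    truth = {
        "config": asdict(config),
        "planted_breakers": {},
        "n_sites": len(all_sites),
        "n_regions": len(regions),
        "n_variants": int(len(variants)),
    }
    return SyntheticCohort(
        config=config,
        proteins=proteins,
        models=models,
        sites=sites_df,
        variants=variants,
        disorder_masks=disorder_masks,
        conservation=conservation,
        disease=disease,
        gene_sets=gene_sets,
        pwms=pwms,
        site_enzymes=site_enzymes,
        drug_targets=drug_targets,
        recomb=recomb,
        truth=truth,
    )


def plant_motif_breakers(cohort: SyntheticCohort, pwm_id: str, n_sites: int) -> SyntheticCohort:
    """Embed a PWM's consensus 15-mer at phosphosite flanks.

    Picks phosphosites whose ±7 window lies fully inside the protein,
    contains no other PTM site and does not overlap a previously planted
    window, rewrites sequence and codons there, and records the planted
    positions in the truth file. Variants falling in a rewritten window are
    dropped (their reference bases no longer exist).
    """
    pwm = next((p for p in cohort.pwms if p.kinase == pwm_id), None)
    if pwm is None:
        raise ValueError(f"unknown PWM {pwm_id!r}")
    planted = cohort.truth.setdefault("planted_breakers", {})
    if n_sites == 0:
        planted.setdefault(pwm_id, [])
        return cohort
    taken: set[tuple[str, int]] = {
        (e["protein"], pos)
        for entries in planted.values()
        for e in entries
        for pos in range(e["position"] - CENTER, e["position"] + CENTER + 1)
    }
    site_positions = {(r.protein, r.position) for r in cohort.sites.itertuples(index=False)}
    phospho = cohort.sites[cohort.sites["ptm_type"] == "phospho"].sort_values(["protein", "position"])
    chosen: list[tuple[str, int]] = []
    for rec in phospho.itertuples(index=False):
        pos = int(rec.position)
        L = len(cohort.proteins[rec.protein])
        if pos - CENTER < 1 or pos + CENTER > L:
            continue
        window_keys = {(rec.protein, q) for q in range(pos - CENTER, pos + CENTER + 1)}
        if (window_keys - {(rec.protein, pos)}) & site_positions:
            continue
        if window_keys & taken:
            continue
        chosen.append((rec.protein, pos))
        taken |= window_keys
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        raise ValueError(
            f"only {len(chosen)} eligible phosphosites available for {pwm_id}, need {n_sites}"
        )
    consensus = pwm.consensus
    sites = cohort.sites.copy()
    for protein, pos in chosen:
        seq = cohort.proteins[protein]
        start0 = pos - 1 - CENTER
        new_seq = seq[:start0] + consensus + seq[start0 + WINDOW :]
        cohort.proteins[protein] = new_seq
        sel = (sites["protein"] == protein) & (sites["position"] == pos)
        sites.loc[sel, "residue"] = consensus[CENTER]
        cds = cohort.models[protein].cds
        new_codons = "".join(AA_CODONS[aa][0] for aa in consensus)
        cds = cds[: start0 * 3] + new_codons + cds[(start0 + WINDOW) * 3 :]
        cohort.models[protein] = GeneModel(protein, cds)
        lo, hi = pos - CENTER, pos + CENTER
        drop = (
            (cohort.variants["protein"] == protein)
            & (cohort.variants["residue_index"] >= lo)
            & (cohort.variants["residue_index"] <= hi)
        )
        cohort.variants = cohort.variants[~drop].reset_index(drop=True)
    cohort.sites = sites
    planted[pwm_id] = [{"protein": p, "position": q} for p, q in chosen]
    return cohort
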