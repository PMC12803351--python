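"""Synthetic study generator with known ground truth.

Every pipeline input can be generated here so each stage is testable
end to end without any external download: annotation files with planted
transporter counts and decoy products, qPCR Ct tables inverted from
chosen fold changes, meal logs whose lagged exposures are known
exactly, and genus abundance matrices built from the association
model's own linear structure (standardized CLR outcome =
beta * standardized exposure + noise, inverted through a softmax).

Defaults mirror the emulated study: 158 patients, 1,009 microbiome
samples, 91 genera, 4 chains x 1000 posterior draws downstream.  Genus
mean transporter counts span 0-46 (the observed genus-mean range, with
a *Blautia*-like top end).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import FeatureRecord, GenomeAnnotation

# products that satisfy gate + family token for each transporter family
_FAMILY_PRODUCTS = {
    "abc": [
        "sugar ABC transporter permease",
        "sugar ABC transporter ATP-binding protein",
        "ATP-binding cassette sugar transporter substrate-binding protein",
    ],
    "pts": [
        "PTS sugar transporter subunit IIA",
        "sugar phosphotransferase system transporter subunit IIB",
        "PTS sugar transporter EIIC component",
    ],
    "mfs": [
        "MFS sugar transporter",
        "major facilitator superfamily sugar transporter",
        "sugar transporter, MFS family",
    ],
}

# decoys that must never count: gate-term-missing, family-token-missing,
# and a lowercase "abc" trap (gate passes, but the case-sensitive
# word-bounded family token must not fire)
_DECOY_PRODUCTS = [
    "glucose ABC transporter permease",  # no "sugar"
    "ABC transporter ATP-binding protein",  # no "sugar"
    "sugar transporter",  # no family token
    "sugar porter family protein",  # no "transporter"
    "sugar abc transporter-like protein",  # lowercase trap
    "multidrug MFS efflux pump",  # no "sugar"
    "PTS mannitol permease",  # no "transporter"
    "hypothetical protein",
    "DNA polymerase III subunit alpha",
    "ribosomal protein L1",
]

# a complete EMP complement so pathway calls are exercised downstream
_EMP_PRODUCTS = ["glucokinase", "6-phosphofructokinase", "pyruvate kinase"]


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study; defaults are study scale."""

    seed: int = 0
    n_genera: int = 91
    n_genomes_per_genus: int = 3
    n_decoys_per_genome: int = 30
    max_abc_mean: float = 46.0  # genus means span 0..max
    pts_mean: float = 8.0
    mfs_mean: float = 6.0
    n_patients: int = 158
    n_samples: int = 1009
    n_days: int = 30
    sigma_noise: float = 0.5  # residual sd of the CLR outcome (z scale)
    trait_effect: float = 1.0  # slope linking normalized count to beta
    sigma_beta: float = 0.05  # scatter of beta around the trait line
    zero_fraction: float = 0.0  # abundance zero-inflation (pre-CLR)
    diet_log_mu: float = 3.4  # lognormal grams/day of sugar (median ~30 g)
    diet_log_sigma: float = 0.5
    asvs_per_genus: int = 2
    sequencing_depth: int = 1_000_000

    def __post_init__(self) -> None:
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def plant_genome_counts(config: SyntheticConfig) -> pd.DataFrame:
    """Planted per-genome transporter counts (the annotation ground truth).

    Genus ABC means are evenly spaced over [0, max_abc_mean]; per-genome
    counts are Poisson around the genus mean, so genus means of the
    planted counts recover the gradient.
    """
    rng = config.rng(1)
    genera = [f"g{i:03d}" for i in range(config.n_genera)]
    abc_means = np.linspace(0.0, config.max_abc_mean, config.n_genera)
    rows = []
    for gi, genus in enumerate(genera):
        for k in range(config.n_genomes_per_genus):
            rows.append(
                {
                    "genome_id": f"{genus}_gen{k}",
                    "genus": genus,
                    "abc": int(rng.poisson(abc_means[gi])),
                    "pts": int(rng.poisson(config.pts_mean)),
                    "mfs": int(rng.poisson(config.mfs_mean)),
                }
            )
    return pd.DataFrame(rows)


def _annotation_from_counts(
    genome_id: str,
    genus: str,
    abc: int,
    pts: int,
    mfs: int,
    n_decoys: int,
    rng: np.random.Generator,
) -> GenomeAnnotation:
    feats: list[FeatureRecord] = []
    idx = 0

    def add(product: str) -> None:
        nonlocal idx
        idx += 1
        feats.append(
            FeatureRecord(
                genome_id=genome_id,
                feature_id=f"{genome_id}_f{idx:05d}",
                product=product,
                protein_id=f"{genome_id}_p{idx:05d}",
            )
        )

    for fam, count in (("abc", abc), ("pts", pts), ("mfs", mfs)):
        opts = _FAMILY_PRODUCTS[fam]
        for i in range(count):
            add(opts[i % len(opts)])
    for i in range(n_decoys):
        add(_DECOY_PRODUCTS[int(rng.integers(len(_DECOY_PRODUCTS)))])
    for prod in _EMP_PRODUCTS:
        add(prod)
    # shuffle feature order: the census must be order-invariant
    order = rng.permutation(len(feats))
    feats = [feats[i] for i in order]
    return GenomeAnnotation(genome_id=genome_id, features=feats, genus=genus)


def gen_annotations(
    config: SyntheticConfig,
    planted: Optional[pd.DataFrame] = None,
    out_dir: Optional[str] = None,
) -> tuple[list[GenomeAnnotation], pd.DataFrame]:
    """Generate genome annotations with planted transporter counts.

    Returns the annotations and the planted-count table; with
    ``out_dir`` each genome is also written as a GFF3 file.
    """
    if planted is None:
        planted = plant_genome_counts(config)
    rng = config.rng(2)
    annotations = [
        _annotation_from_counts(
            r.genome_id, r.genus, r.abc, r.pts, r.mfs, config.n_decoys_per_genome, rng
        )
        for r in planted.itertuples(index=False)
    ]
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for ann in annotations:
            write_gff3(ann, os.path.join(out_dir, f"{ann.genome_id}.gff3"))
    return annotations, planted


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write an annotation as a minimal GFF3 file of CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        pos = 1
        for feat in annotation.features:
            start, end = pos, pos + 899
            pos = end + 101
            attrs = f"ID={feat.feature_id};product={feat.product}"
            if feat.protein_id:
                attrs += f";protein_id={feat.protein_id}"
            fh.write(
                f"{annotation.genome_id}\tsynthetic\tCDS\t{start}\t{end}"
                f"\t.\t+\t0\t{attrs}\n"
            )


def gen_ct_experiment(
    true_fold_changes: dict[str, float],
    n_replicates: int = 6,
    condition: str = "GLU",
    ct_reference: float = 20.0,
    noise_sd: float = 0.0,
    weight_reference: float = 1.0,
    weight_sample: float = 1.0,
    nd_strains: Sequence[str] = (),
    technical_duplicates: int = 2,
    horizon: float = 72.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table inverted from chosen true fold changes.

    For each strain and biological replicate a reference (t=0) and a
    sample (t=``horizon``) record are emitted with

        Ct_sample = Ct_ref - log2(F) + log2(w_sample / w_reference)

    so the delta-Ct pipeline recovers F exactly in the noise-free case.
    Gaussian cycle noise of ``noise_sd`` is added independently to every
    technical duplicate; strains in ``nd_strains`` get ND sample wells.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for strain, f in true_fold_changes.items():
        if f <= 0:
            raise ValueError("fold changes must be positive")
        for rep in range(n_replicates):
            rep_id = f"rep{rep}"
            base_ref = ct_reference
            base_smp = (
                ct_reference
                - math.log2(f)
                + math.log2(weight_sample / weight_reference)
            )
            for tp, base, w, nd in (
                (0.0, base_ref, weight_reference, False),
                (horizon, base_smp, weight_sample, strain in nd_strains),
            ):
                for _ in range(technical_duplicates):
                    ct = "ND" if nd else base + rng.normal(scale=noise_sd)
                    rows.append(
                        {
                            "sample_id": rep_id,
                            "strain": strain,
                            "condition": condition,
                            "timepoint_h": tp,
                            "ct": ct,
                            "normalizer_value": w,
                            "normalizer_kind": "volume",
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class DietAbundanceStudy:
    """A generated diet/abundance study and its ground truth."""

    meals: pd.DataFrame
    nutrients: pd.DataFrame
    samples: pd.DataFrame  # sample_id, patient_id, sample_day
    abundance: pd.DataFrame  # sample x genus relative abundances
    feature_table: pd.DataFrame  # sample x ASV counts
    asv_genus: pd.Series  # ASV -> genus label ("" = unlabeled)
    true_beta: pd.Series  # per genus, on the standardized scale
    true_exposure: pd.Series  # per sample, grams/day
    day_totals: pd.DataFrame


def _softmax_rows(c: np.ndarray) -> np.ndarray:
    z = c - c.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gen_diet_abundance(
    config: SyntheticConfig,
    true_beta: Optional[np.ndarray] = None,
) -> DietAbundanceStudy:
    """Generate a full diet-microbiome study from the association model.

    Daily sugar totals are lognormal; meal logs are constructed so the
    day sums reproduce them exactly.  For each genus the standardized
    CLR outcome is ``beta * x_std + Normal(0, sigma_noise)`` with the
    planted beta; compositions are the softmax of the per-sample
    centered outcome vector, so the CLR round trip is exact up to the
    per-sample centering.  Planted betas are centered across genera
    (only contrasts survive the CLR centering).
    """
    rng = config.rng(3)
    genera = [f"g{i:03d}" for i in range(config.n_genera)]
    if true_beta is None:
        b = rng.normal(size=config.n_genera)
    else:
        b = np.asarray(true_beta, dtype=float)
        if len(b) != config.n_genera:
            raise ValueError("true_beta length must equal n_genera")
    b = b - b.mean()

    # nutrient table: 20 foods, 8-digit codes
    codes = [f"{11100000 + 37 * i}" for i in range(20)]
    density = rng.uniform(2.0, 60.0, size=20)
    nutrients = pd.DataFrame({"food_code": codes, "sugar_g_per_100g": density})

    patients = [f"p{i:03d}" for i in range(config.n_patients)]
    meal_rows = []
    totals = {}
    for pid in patients:
        for day in range(1, config.n_days + 1):
            total = float(
                rng.lognormal(mean=config.diet_log_mu, sigma=config.diet_log_sigma)
            )
            totals[(pid, day)] = 0.0
            n_meals = int(rng.integers(1, 4))
            parts = rng.dirichlet(np.ones(n_meals)) * total
            for part in parts:
                j = int(rng.integers(len(codes)))
                grams = part / density[j] * 100.0
                meal_rows.append(
                    {
                        "patient_id": pid,
                        "day": day,
                        "food_code": codes[j],
                        "grams": grams,
                    }
                )
                totals[(pid, day)] += grams * density[j] / 100.0
    meals = pd.DataFrame(meal_rows)
    day_totals = pd.DataFrame(
        [
            {"patient_id": p, "day": d, "sugar_g": v}
            for (p, d), v in sorted(totals.items())
        ]
    )

    # samples on days >= 3 so both prior days always exist
    sample_rows = []
    exposure = []
    for i in range(config.n_samples):
        pid = patients[int(rng.integers(len(patients)))]
        day = int(rng.integers(3, config.n_days + 1))
        sample_rows.append(
            {"sample_id": f"s{i:04d}", "patient_id": pid, "sample_day": day}
        )
        exposure.append((totals[(pid, day - 1)] + totals[(pid, day - 2)]) / 2.0)
    samples = pd.DataFrame(sample_rows)
    exposure = np.asarray(exposure)
    x_std = (exposure - exposure.mean()) / exposure.std(ddof=1)

    # outcome matrix: per-genus linear model on the standardized scale
    y = x_std[:, None] * b[None, :] + rng.normal(
        scale=config.sigma_noise, size=(config.n_samples, config.n_genera)
    )
    clr_rows = y - y.mean(axis=1, keepdims=True)
    abund = _softmax_rows(clr_rows)
    if config.zero_fraction > 0:
        mask = rng.random(abund.shape) < config.zero_fraction
        # never zero a whole sample
        for i in range(abund.shape[0]):
            if mask[i].all():
                mask[i, int(rng.integers(abund.shape[1]))] = False
        abund = np.where(mask, 0.0, abund)
        abund = abund / abund.sum(axis=1, keepdims=True)
    abundance = pd.DataFrame(
        abund, index=pd.Index(samples["sample_id"], name="sample_id"), columns=genera
    )

    # split each genus across ASVs, add unlabeled decoy features
    asv_ids, asv_genera, cols = [], [], []
    for gi, genus in enumerate(genera):
        frac = rng.dirichlet(np.ones(config.asvs_per_genus))
        for k in range(config.asvs_per_genus):
            asv_ids.append(f"asv_{genus}_{k}")
            asv_genera.append(genus)
            cols.append(abund[:, gi] * frac[k])
    for k in range(3):
        asv_ids.append(f"asv_unlabeled_{k}")
        asv_genera.append("")
        cols.append(np.full(config.n_samples, 1e-5))
    counts = np.rint(np.column_stack(cols) * config.sequencing_depth).astype(int)
    feature_table = pd.DataFrame(
        counts, index=abundance.index.copy(), columns=asv_ids
    )
    return DietAbundanceStudy(
        meals=meals,
        nutrients=nutrients,
        samples=samples,
        abundance=abundance,
        feature_table=feature_table,
        asv_genus=pd.Series(asv_genera, index=asv_ids),
        true_beta=pd.Series(b, index=genera),
        true_exposure=pd.Series(exposure, index=abundance.index.copy()),
        day_totals=day_totals,
    )


def gen_trait_beta_pair(
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Genus census and beta table linked by a planted trait effect.

    Genus mean ABC counts are uniform integers on [0, max_abc_mean];
    true beta = trait_effect * (count / max) + Normal(0, sigma_beta).
    Returns (census table, summaries-style beta table, true betas).
    Refuses fewer than 3 genera.
    """
    if config.n_genera < 3:
        raise ValueError("need >= 3 genera for the trait regression")
    rng = rng or config.rng(4)
    genera = [f"g{i:03d}" for i in range(config.n_genera)]
    counts = rng.integers(0, int(config.max_abc_mean) + 1, size=config.n_genera)
    if counts.max() == 0:
        counts[int(rng.integers(config.n_genera))] = 1
    xnorm = counts / counts.max()
    beta = config.trait_effect * xnorm + rng.normal(
        scale=config.sigma_beta, size=config.n_genera
    )
    census = pd.DataFrame(
        {
            "genus": genera,
            "abc": counts.astype(float),
            "pts": rng.poisson(config.pts_mean, config.n_genera).astype(float),
            "mfs": rng.poisson(config.mfs_mean, config.n_genera).astype(float),
            "n_genomes_used": config.n_genomes_per_genus,
        }
    )
    census["total"] = census["abc"] + census["pts"] + census["mfs"]
    summaries = pd.DataFrame(
        {"genus": genera, "status": "ok", "beta_mean": beta}
    )
    return census, summaries, pd.Series(beta, index=genera)


def gen_model_datasets(
    n_datasets: int, n: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray, float, float, float]]:
    """Datasets drawn exactly from the association model's generative
    process (parameters from their priors), for calibration checks.

    Returns a list of (y, x, alpha, beta, sigma) tuples.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        alpha = float(rng.normal())
        beta = float(rng.normal())
        sigma = float(rng.exponential())
        x = rng.normal(size=n)
        y = alpha + beta * x + rng.normal(scale=sigma, size=n)
        out.append((y, x, alpha, beta, sigma))
    return out
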